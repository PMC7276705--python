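"""Reference amplicon, mutation identity, and the bundled demo gene.

The pipeline identifies every mutation by its (position, reference base,
alternate base) triple on the forward strand of the amplicon.  Positions are
0-based half-open internally; all emitted reports convert to 1-based CDS
coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
STOP = "*"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def standard_genetic_code() -> dict[str, str]:
    """Codon -> one-letter amino acid, with ``*`` as the stop sentinel."""
    table = unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for codon in table.stop_codons:
        code[codon] = STOP
    return code


class MutationKey(NamedTuple):
    """A single-base substitution on the forward strand of the amplicon."""

    pos: int  # 0-based amplicon coordinate
    ref: str
    alt: str

    def label(self, cds_start: int = 0) -> str:
        """Human-readable ``<1-based pos>:<ref>><alt>`` (CDS frame if given)."""
        return f"{self.pos - cds_start + 1}:{self.ref}>{self.alt}"


def parse_mutation_label(label: str, cds_start: int = 0) -> MutationKey:
    pos_part, change = label.split(":")
    ref, alt = change.split(">")
    return MutationKey(int(pos_part) - 1 + cds_start, ref, alt)


@dataclasses.dataclass(frozen=True)
class ReferenceAmplicon:
    """Wild-type amplicon with the coding sequence located inside it.

    ``cds_start``/``cds_end`` are 0-based half-open bounds within
    ``sequence``; the CDS length must be a multiple of three.
    """

    sequence: str
    cds_start: int
    cds_end: int
    genetic_code: dict[str, str] = field(
        default_factory=standard_genetic_code, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError("reference sequence is empty")
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValueError(f"non-ACGT characters in reference: {sorted(bad)}")
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"CDS bounds [{self.cds_start}, {self.cds_end}) fall outside "
                f"the {len(self.sequence)} bp amplicon"
            )
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError("CDS length must be a multiple of 3")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def n_residues(self) -> int:
        return self.cds_length // 3

    def as_array(self) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (read-only view)."""
        return np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)

    def base_index(self) -> np.ndarray:
        """Per-position index of the reference base into ``BASES``."""
        arr = self.as_array()
        out = np.empty(len(arr), dtype=np.int8)
        for base, idx in BASE_INDEX.items():
            out[arr == ord(base)] = idx
        return out

    def codon(self, codon_index: int) -> str:
        start = self.cds_start + 3 * codon_index
        return self.sequence[start : start + 3]

    def translate_cds(self) -> str:
        cds = self.cds
        return "".join(
            self.genetic_code[cds[i : i + 3]] for i in range(0, len(cds), 3)
        )

    def in_cds(self, pos: int) -> bool:
        return self.cds_start <= pos < self.cds_end

    def contains(self, key: MutationKey) -> bool:
        """True if the key falls inside the amplicon and its ref base matches."""
        return (
            0 <= key.pos < len(self.sequence)
            and self.sequence[key.pos] == key.ref
            and key.alt in BASES
            and key.alt != key.ref
        )

    def to_fasta(self, path: str | Path, name: str = "amplicon") -> None:
        record = SeqRecord(
            Seq(self.sequence),
            id=name,
            description=f"cds={self.cds_start}..{self.cds_end}",
        )
        SeqIO.write([record], str(path), "fasta")

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        cds_start: int | None = None,
        cds_end: int | None = None,
    ) -> "ReferenceAmplicon":
        """Load an amplicon; CDS bounds default to a ``cds=a..b`` tag in the
        FASTA description (0-based half-open)."""
        record = SeqIO.read(str(path), "fasta")
        if cds_start is None or cds_end is None:
            for token in record.description.split():
                if token.startswith("cds="):
                    a, b = token[4:].split("..")
                    cds_start, cds_end = int(a), int(b)
        if cds_start is None or cds_end is None:
            raise ValueError(f"{path}: CDS bounds not given and no cds=a..b tag")
        return cls(str(record.seq), cds_start, cds_end)


# Stable seed for the bundled demo gene; independent of any pipeline seed so
# the same reference is used across runs.
_DEMO_SEED = 7


def demo_reference(
    n_codons: int = 447, flank: int = 100, seed: int = _DEMO_SEED
) -> ReferenceAmplicon:
    """Deterministically generated maltoporin-like demo amplicon.

    The CDS is ``3 * n_codons`` long (1341 bp by default, matching a LamB-sized
    porin precursor of 447 codons including start and stop), starts with ATG,
    ends with TAA, contains no internal stop codon, and is flanked on both
    sides by ``flank`` random bases.
    """
    rng = np.random.default_rng(seed)
    code = standard_genetic_code()
    sense = sorted(c for c, aa in code.items() if aa != STOP and c != "ATG")
    body = rng.choice(sense, size=n_codons - 2)
    cds = "ATG" + "".join(body) + "TAA"
    left = "".join(rng.choice(list(BASES), size=flank))
    right = "".join(rng.choice(list(BASES), size=flank))
    return ReferenceAmplicon(left + cds + right, flank, flank + 3 * n_codons)
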