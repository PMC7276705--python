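"""Synthetic error-prone PCR libraries, dual selections, and sequencing reads.

The generator emulates the statistical structure the analysis assumes:

* an error-prone PCR library over the CDS, each base substituted
  independently at a configurable per-base rate (0.52% and 0.063% are the
  two library conditions of interest), with a transition-biased
  substitution spectrum by default;
* a two-trait fitness model in which most mutations act through a shared
  "stability" cost, phage-binding ("loop") effects are confined to a
  configurable residue window, and nonsense mutations abolish both traits;
* growth competition under selection, with expected post-selection
  frequency proportional to ``pre * 2**(generations * w)`` and an optional
  multinomial bottleneck;
* Tn5-style tagmentation into short fragments (median ~63 bp), PCR
  duplication of each fragment into several raw read pairs, and per-base
  sequencing error injected independently into every raw copy.

Ground-truth tables (variant genotypes, trait fitnesses, per-fragment
records) are emitted alongside the reads so that every downstream stage can
be tested against an oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import field
import math
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .fragproc import ReadPair
from .reference import BASE_INDEX, BASES, MutationKey, ReferenceAmplicon
from .scoring import (
    MISSENSE,
    NONSENSE,
    STOP_LOSS,
    SYNONYMOUS,
    mutation_catalog,
)

#: Error-prone PCR substitution spectrum: rows/columns in BASES order
#: (A, C, G, T), diagonal zero, each row summing to 1.  Transitions
#: (A<->G, C<->T) carry 2/3 of the probability, reflecting the strong
#: transition bias of error-prone polymerases.
TRANSITION_BIASED_SPECTRUM = np.array(
    [
        [0.0, 1 / 6, 2 / 3, 1 / 6],
        [1 / 6, 0.0, 1 / 6, 2 / 3],
        [2 / 3, 1 / 6, 0.0, 1 / 6],
        [1 / 6, 2 / 3, 1 / 6, 0.0],
    ]
)

#: Uniform alternative: each non-reference base equally likely.
UNIFORM_SPECTRUM = (1 - np.eye(4)) / 3


@dataclasses.dataclass
class LibrarySpec:
    """Error-prone PCR library parameters."""

    n_variants: int
    per_base_rate: float
    substitution_spectrum: np.ndarray = field(
        default_factory=lambda: TRANSITION_BIASED_SPECTRUM.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be positive")
        if not (0 <= self.per_base_rate < 1):
            raise ValueError("per_base_rate must lie in [0, 1)")
        spec = np.asarray(self.substitution_spectrum, dtype=float)
        if spec.shape != (4, 4) or (np.diag(spec) != 0).any():
            raise ValueError("spectrum must be 4x4 with a zero diagonal")
        if not np.allclose(spec.sum(axis=1), 1.0):
            raise ValueError("spectrum rows must sum to 1")
        self.substitution_spectrum = spec


@dataclasses.dataclass(frozen=True)
class VariantGenotype:
    variant_id: int
    mutations: frozenset[MutationKey]
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")
        positions = [k.pos for k in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValueError("mutation positions must be unique within a variant")


def generate_library(
    ref: ReferenceAmplicon, spec: LibrarySpec, rng: np.random.Generator | None = None
) -> list[VariantGenotype]:
    """Draw a library of variants, each CDS base mutating independently.

    Abundances are initialised uniform.  The alternate base at each mutated
    position is drawn from the spectrum row of the reference base.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lo, hi = ref.cds_start, ref.cds_end
    n_pos = hi - lo
    ref_idx = ref.base_index()[lo:hi]
    hit = rng.random((spec.n_variants, n_pos)) < spec.per_base_rate
    variant_rows, pos_cols = np.nonzero(hit)
    # Alternate bases: inverse-CDF draw from the spectrum row of each ref base.
    cdf = np.cumsum(spec.substitution_spectrum, axis=1)
    u = rng.random(len(pos_cols))
    alt_idx = (u[:, None] > cdf[ref_idx[pos_cols]]).sum(axis=1)
    abundance = 1.0 / spec.n_variants
    mutations_per_variant: list[list[MutationKey]] = [[] for _ in range(spec.n_variants)]
    seq = ref.sequence
    for v, p, a in zip(variant_rows, pos_cols, alt_idx):
        pos = lo + int(p)
        mutations_per_variant[v].append(MutationKey(pos, seq[pos], BASES[int(a)]))
    return [
        VariantGenotype(i, frozenset(muts), abundance)
        for i, muts in enumerate(mutations_per_variant)
    ]


def mutation_load(library: Sequence[VariantGenotype]) -> float:
    """Mean number of mutations per variant."""
    return float(np.mean([len(v.mutations) for v in library]))


def variant_sequences(
    ref: ReferenceAmplicon, library: Sequence[VariantGenotype]
) -> list[str]:
    """Full amplicon sequence of each variant."""
    out = []
    template = bytearray(ref.sequence, "ascii")
    for variant in library:
        buf = bytearray(template)
        for key in variant.mutations:
            buf[key.pos] = ord(key.alt)
        out.append(buf.decode("ascii"))
    return out


# ---------------------------------------------------------------------------
# Fitness model


@dataclasses.dataclass
class FitnessModel:
    """Per-mutation effects combined multiplicatively into variant fitness.

    ``stability_cost`` is shared across both traits; ``lambda_binding_effect``
    (nonzero only at designated loop positions) additionally abolishes phage
    binding without touching transport; ``malt_pore_effect`` is the converse.
    A nonsense mutation anywhere in the CDS nulls both traits.
    """

    stability_cost: dict[MutationKey, float]
    lambda_binding_effect: dict[MutationKey, float]
    malt_pore_effect: dict[MutationKey, float]
    nonsense_keys: frozenset[MutationKey]

    def mutation_trait_effects(self, key: MutationKey) -> tuple[float, float]:
        """(lambda-sensitivity retained, malt function retained) for a single
        mutation on the wild-type background."""
        if key in self.nonsense_keys:
            return (0.0, 0.0)
        s = self.stability_cost.get(key, 0.0)
        b = self.lambda_binding_effect.get(key, 0.0)
        p = self.malt_pore_effect.get(key, 0.0)
        return ((1 - s) * (1 - b), (1 - s) * (1 - p))


DEFAULT_LOOP_RESIDUES = range(240, 261)
DEFAULT_PORE_RESIDUES = range(105, 126)


def default_fitness_model(
    ref: ReferenceAmplicon,
    seed: int = 0,
    loop_residues: Iterable[int] = DEFAULT_LOOP_RESIDUES,
    pore_residues: Iterable[int] = DEFAULT_PORE_RESIDUES,
    p_deleterious: float = 0.12,
    p_loop_binding: float = 0.5,
    p_pore_effect: float = 0.4,
) -> FitnessModel:
    """Assign ground-truth effects to every possible CDS substitution.

    Missense stability costs follow a bimodal, fully continuous distribution
    (a near-neutral mode Beta(0.6, 14) and, with probability
    ``p_deleterious``, a deleterious mode Beta(2.5, 1.2)), mirroring the
    bimodal-but-continuous fitness-effect distributions seen in deep
    mutational scans.  Loop-window missense mutations draw only near-neutral
    stability costs (surface loops rarely destabilise) and, with probability
    ``p_loop_binding``, a strong phage-binding effect U(0.75, 1) — these are
    the planted resistant-but-transporting mutations.  Pore-window missense
    mutations carry a transport effect U(0.5, 1) with probability
    ``p_pore_effect``.  Stop-loss mutations get a fixed stability cost of
    0.9 (read-through extensions are usually strongly deleterious).
    """
    rng = np.random.default_rng(seed)
    loop = set(loop_residues)
    pore = set(pore_residues)
    catalog = mutation_catalog(ref)
    stability: dict[MutationKey, float] = {}
    binding: dict[MutationKey, float] = {}
    pore_eff: dict[MutationKey, float] = {}
    nonsense: set[MutationKey] = set()
    for (pos, ref_base, alt), row in catalog.iterrows():
        key = MutationKey(int(pos), ref_base, alt)
        effect = row["effect_class"]
        residue = int(row["residue"])
        if effect == SYNONYMOUS:
            continue
        if effect == NONSENSE:
            nonsense.add(key)
            continue
        if effect == STOP_LOSS:
            stability[key] = 0.9
            continue
        assert effect == MISSENSE
        if residue in loop:
            stability[key] = float(rng.beta(0.6, 14))
            if rng.random() < p_loop_binding:
                binding[key] = float(rng.uniform(0.75, 1.0))
        else:
            if rng.random() < p_deleterious:
                stability[key] = float(rng.beta(2.5, 1.2))
            else:
                stability[key] = float(rng.beta(0.6, 14))
            if residue in pore and rng.random() < p_pore_effect:
                pore_eff[key] = float(rng.uniform(0.5, 1.0))
    return FitnessModel(stability, binding, pore_eff, frozenset(nonsense))


def trait_fitness(
    variant: VariantGenotype, model: FitnessModel, ref: ReferenceAmplicon
) -> tuple[float, float]:
    """(lambda-sensitivity, malt function) of a variant, both in [0, 1].

    Wild type maps to (1, 1); a nonsense mutation anywhere maps to (0, 0);
    otherwise per-mutation effects compose multiplicatively.
    """
    f_sens = 1.0
    f_malt = 1.0
    for key in variant.mutations:
        if not ref.contains(key):
            raise ValueError(f"mutation {key} falls outside the amplicon")
        if key in model.nonsense_keys:
            return (0.0, 0.0)
        sens, malt = model.mutation_trait_effects(key)
        f_sens *= sens
        f_malt *= malt
    return (f_sens, f_malt)


def library_trait_fitness(
    library: Sequence[VariantGenotype], model: FitnessModel, ref: ReferenceAmplicon
) -> tuple[np.ndarray, np.ndarray]:
    sens = np.empty(len(library))
    malt = np.empty(len(library))
    for i, variant in enumerate(library):
        sens[i], malt[i] = trait_fitness(variant, model, ref)
    return sens, malt


def true_mutation_effects(
    model: FitnessModel, ref: ReferenceAmplicon
) -> pd.DataFrame:
    """Ground-truth single-mutation trait values for every CDS substitution.

    Columns ``true_lambda_sensitivity`` and ``true_malt`` give the trait
    level retained by the mutation alone on a wild-type background
    (synonymous -> 1, nonsense -> 0).
    """
    catalog = mutation_catalog(ref)
    sens = np.empty(len(catalog))
    malt = np.empty(len(catalog))
    for i, (pos, ref_base, alt) in enumerate(catalog.index):
        key = MutationKey(int(pos), ref_base, alt)
        sens[i], malt[i] = model.mutation_trait_effects(key)
    out = catalog.copy()
    out["true_lambda_sensitivity"] = sens
    out["true_malt"] = malt
    return out


# ---------------------------------------------------------------------------
# Selection


def condition_fitness(
    fitnesses: tuple[np.ndarray, np.ndarray], condition: str
) -> np.ndarray:
    """Growth fitness w per variant under a condition.

    Under phage selection resistance grows, so ``w = 1 - lambda_sensitivity``;
    under maltodextrin selection transport grows (``w = f_malt``); the
    control conditions are neutral (``w = 1``).
    """
    f_sens, f_malt = fitnesses
    if condition == "lambda":
        return 1.0 - np.asarray(f_sens)
    if condition == "malt":
        return np.asarray(f_malt)
    if condition == "control":
        return np.ones(len(np.asarray(f_sens)))
    raise ValueError(f"unknown condition {condition!r}")


def simulate_selection(
    abundances: np.ndarray,
    fitnesses: tuple[np.ndarray, np.ndarray],
    condition: str,
    generations: float,
    bottleneck: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Growth competition: expected post frequency proportional to
    ``pre * 2**(generations * w)``.

    With ``bottleneck`` set, the post-selection population is multinomially
    resampled at that size (sampling noise of a finite culture); ``None``
    returns the deterministic expectation.
    """
    pre = np.asarray(abundances, dtype=float)
    if not math.isclose(pre.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("abundances must sum to 1")
    if generations < 0:
        raise ValueError("generations must be non-negative")
    w = condition_fitness(fitnesses, condition)
    post = pre * np.exp2(generations * w)
    post = post / post.sum()
    if bottleneck is None:
        return post
    if bottleneck <= 0:
        raise ValueError("bottleneck must be positive")
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    draws = rng.multinomial(int(bottleneck), post)
    return draws / draws.sum()


# ---------------------------------------------------------------------------
# Sequencing


@dataclasses.dataclass
class SequencingSpec:
    """Tagmentation + paired-end sequencing parameters.

    ``duplication`` names the raw-read multiplicity distribution per unique
    fragment: ``("constant", k)`` or ``("shifted_poisson", minimum, mean_extra)``
    (minimum plus a Poisson draw).  The default guarantees at least five raw
    copies so that the downstream min-raw filter removes only error-split
    groups, emulating the deep duplication of the real protocol at desk scale.
    """

    n_fragments: int
    read_length: int = 38
    per_base_error: float = 0.002
    fragment_length_median: float = 63.0
    fragment_length_sigma: float = 0.35
    min_fragment_length: int = 25
    max_fragment_length: int = 250
    duplication: tuple = ("shifted_poisson", 5, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments < 1 or self.read_length < 1:
            raise ValueError("n_fragments and read_length must be positive")
        if not (0 <= self.per_base_error < 1):
            raise ValueError("per_base_error must lie in [0, 1)")
        if self.min_fragment_length < 1 or self.fragment_length_median <= 0:
            raise ValueError("fragment lengths must be positive")
        kind = self.duplication[0]
        if kind not in ("constant", "shifted_poisson"):
            raise ValueError(f"unknown duplication distribution {kind!r}")


def _draw_duplication(
    spec: SequencingSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    kind = spec.duplication[0]
    if kind == "constant":
        return np.full(n, int(spec.duplication[1]))
    _, minimum, mean_extra = spec.duplication
    return int(minimum) + rng.poisson(float(mean_extra), size=n)


def sample_fragments(
    abundances: np.ndarray,
    ref: ReferenceAmplicon,
    spec: SequencingSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw (variant, start, end, n_raw) for each tagmentation fragment."""
    n = spec.n_fragments
    length = len(ref)
    max_len = min(spec.max_fragment_length, length)
    if spec.min_fragment_length > length:
        raise ValueError("fragments longer than the amplicon")
    variant_ids = rng.choice(len(abundances), size=n, p=abundances)
    lens = np.rint(
        rng.lognormal(math.log(spec.fragment_length_median), spec.fragment_length_sigma, n)
    ).astype(int)
    lens = np.clip(lens, spec.min_fragment_length, max_len)
    starts = rng.integers(0, length - lens + 1)
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "start": starts,
            "end": starts + lens,
            "n_raw": _draw_duplication(spec, n, rng),
        }
    )


def fragment_truth(
    fragments: pd.DataFrame,
    library: Sequence[VariantGenotype],
) -> pd.DataFrame:
    """Attach the ground-truth substitution set carried by each fragment."""
    per_variant: list[list[MutationKey]] = [
        sorted(v.mutations) for v in library
    ]
    subs_col = []
    for variant_id, start, end in zip(
        fragments["variant_id"], fragments["start"], fragments["end"]
    ):
        subs_col.append(
            frozenset(
                k for k in per_variant[variant_id] if start <= k.pos < end
            )
        )
    out = fragments.copy()
    out["substitutions"] = subs_col
    return out


_QUAL_CACHE: dict[int, str] = {}


def _qual(n: int) -> str:
    if n not in _QUAL_CACHE:
        _QUAL_CACHE[n] = "I" * n
    return _QUAL_CACHE[n]


def simulate_reads(
    library: Sequence[VariantGenotype],
    abundances: np.ndarray,
    ref: ReferenceAmplicon,
    spec: SequencingSpec,
    rng: np.random.Generator | None = None,
    seqs: Sequence[str] | None = None,
) -> tuple[Iterator[tuple[ReadPair, int]], pd.DataFrame]:
    """Simulate tagmentation and paired-end sequencing of a population.

    Returns a lazy stream of ``(ReadPair, multiplicity)`` — error-free PCR
    duplicates are emitted once with their multiplicity, erroneous copies
    individually — together with the eager ground-truth fragment table.
    Read 1 covers the fragment's 5' end on the forward strand and read 2 the
    3' end on the reverse strand, each truncated to ``read_length``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if seqs is None:
        seqs = variant_sequences(ref, library)
    frags = sample_fragments(abundances, ref, spec, rng)
    truth = fragment_truth(frags, library)

    flen = (frags["end"] - frags["start"]).to_numpy()
    len1 = np.minimum(spec.read_length, flen)
    len2 = np.minimum(spec.read_length, flen)
    e = spec.per_base_error
    p_any = 1.0 - (1.0 - e) ** (len1 + len2)
    n_err_copies = rng.binomial(frags["n_raw"].to_numpy(), p_any)

    comp = str.maketrans("ACGT", "TGCA")

    def stream() -> Iterator[tuple[ReadPair, int]]:
        variant_col = frags["variant_id"].to_numpy()
        start_col = frags["start"].to_numpy()
        end_col = frags["end"].to_numpy()
        raw_col = frags["n_raw"].to_numpy()
        for i in range(len(frags)):
            fragment = seqs[variant_col[i]][start_col[i] : end_col[i]]
            l1 = int(len1[i])
            l2 = int(len2[i])
            r1 = fragment[:l1]
            r2 = fragment[len(fragment) - l2 :].translate(comp)[::-1]
            clean = ReadPair(r1, _qual(l1), r2, _qual(l2))
            k = int(n_err_copies[i])
            d = int(raw_col[i])
            if d - k > 0:
                yield (clean, d - k)
            total = l1 + l2
            for _ in range(k):
                n_err = max(1, int(rng.binomial(total, e)))
                n_err = min(n_err, total)
                positions = rng.choice(total, size=n_err, replace=False)
                b1 = bytearray(r1, "ascii")
                b2 = bytearray(r2, "ascii")
                for p in positions:
                    buf, off = (b1, int(p)) if p < l1 else (b2, int(p) - l1)
                    old = chr(buf[off])
                    choices = [b for b in BASES if b != old]
                    buf[off] = ord(choices[int(rng.integers(3))])
                yield (
                    ReadPair(b1.decode(), _qual(l1), b2.decode(), _qual(l2)),
                    1,
                )

    return stream(), truth


def write_fastq_pairs(
    pairs: Iterable[tuple[ReadPair, int]],
    path1: str | Path,
    path2: str | Path,
    name_prefix: str = "frag",
) -> int:
    """Expand multiplicities and write Phred+33 FASTQ mates; returns the
    number of raw pairs written."""
    n = 0
    with open(path1, "w") as fh1, open(path2, "w") as fh2:
        for pair, mult in pairs:
            for _ in range(mult):
                n += 1
                name = f"{name_prefix}.{n}"
                fh1.write(f"@{name}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
                fh2.write(f"@{name}/2\n{pair.seq2}\n+\n{pair.qual2}\n")
    return n


def library_truth_frame(
    library: Sequence[VariantGenotype],
    fitnesses: tuple[np.ndarray, np.ndarray],
    ref: ReferenceAmplicon,
) -> pd.DataFrame:
    """Ground-truth TSV table: variant, mutations, abundance, trait values."""
    f_sens, f_malt = fitnesses
    rows = []
    for variant, s, m in zip(library, f_sens, f_malt):
        muts = ",".join(
            k.label(ref.cds_start) for k in sorted(variant.mutations)
        ) or "."
        rows.append((variant.variant_id, muts, variant.abundance, s, m))
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "mutations",
            "abundance",
            "f_lambda_sensitivity",
            "f_malt",
        ],
    )
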