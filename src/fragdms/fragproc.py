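"""Raw paired reads -> error-corrected unique fragments -> base counts.

Tagmentation produces fragments whose (start, end) identify a transposition
event.  Sequencing errors are suppressed by collapsing identical raw read
pairs and discarding unique pairs seen fewer than ``min_raw`` times: a
sequencing error changes the pair's sequence, splitting the erroneous copies
into a separate low-multiplicity group that the filter removes.  Surviving
pairs are merged at their 3' overlap, aligned to the reference without gaps,
and deduplicated by (start, end, substitutions); each unique fragment then
contributes exactly one count at every position it covers, regardless of its
raw multiplicity (duplication reflects PCR, not molecules).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .reference import BASE_INDEX, BASES, MutationKey, ReferenceAmplicon, reverse_complement


class ReadPair(NamedTuple):
    """A raw read pair; ``pair_key`` is the canonical identity used for
    deduplication (sequence only — qualities do not enter the identity)."""

    seq1: str
    qual1: str
    seq2: str
    qual2: str

    @property
    def pair_key(self) -> tuple[str, str]:
        return (self.seq1, self.seq2)


@dataclasses.dataclass(frozen=True)
class UniqueFragment:
    """An error-corrected fragment: one transposition event.

    ``start``/``end`` are 0-based half-open amplicon coordinates of the
    whole insert on the forward strand; ``raw_count`` is the number of raw
    read pairs collapsed into it.  ``windows`` lists the sequenced
    sub-intervals: the full span for a merged pair, the two read windows for
    a pair whose mates do not overlap (the unsequenced middle of the insert
    is part of the fragment's identity but contributes no base counts).
    """

    start: int
    end: int
    substitutions: frozenset[MutationKey]
    raw_count: int
    windows: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment span [{self.start}, {self.end})")
        if self.raw_count < 1:
            raise ValueError("raw_count must be >= 1")
        if not self.windows:
            object.__setattr__(self, "windows", ((self.start, self.end),))
        for a, b in self.windows:
            if not (self.start <= a < b <= self.end):
                raise ValueError(
                    f"window [{a}, {b}) outside span [{self.start}, {self.end})"
                )
        for key in self.substitutions:
            if not any(a <= key.pos < b for a, b in self.windows):
                raise ValueError(
                    f"substitution at {key.pos} outside the sequenced "
                    f"windows of [{self.start}, {self.end})"
                )

    @property
    def sequenced_bases(self) -> int:
        return sum(b - a for a, b in self.windows)


@dataclasses.dataclass
class DropLog:
    """Per-stage attrition counters, logged by the pipeline."""

    n_raw: int = 0
    n_unique_pairs: int = 0
    n_below_min_raw: int = 0
    n_unaligned: int = 0
    n_aligned_segments: int = 0

    def __str__(self) -> str:
        return (
            f"{self.n_raw} raw pairs -> {self.n_unique_pairs} unique "
            f"({self.n_below_min_raw} below min-raw); "
            f"{self.n_aligned_segments} segments aligned, "
            f"{self.n_unaligned} rejected"
        )


# ---------------------------------------------------------------------------
# Collapse and filter


def collapse_and_filter(
    pairs: Iterable, min_raw: int = 5, log: DropLog | None = None
) -> list[tuple[ReadPair, int]]:
    """Group identical raw pairs and drop groups seen fewer than ``min_raw``
    times.

    ``pairs`` may yield ``ReadPair`` items or pre-weighted
    ``(ReadPair, count)`` tuples (the simulator emits the latter to avoid
    materialising every PCR duplicate).  Output is sorted by pair key for
    deterministic downstream order.
    """
    counts: Counter = Counter()
    quals: dict[tuple[str, str], tuple[str, str]] = {}
    n_raw = 0
    for item in pairs:
        if isinstance(item, ReadPair):
            pair, mult = item, 1
        else:
            pair, mult = item
        key = pair.pair_key
        counts[key] += mult
        n_raw += mult
        if key not in quals:
            quals[key] = (pair.qual1, pair.qual2)
    kept = [
        (ReadPair(k[0], quals[k][0], k[1], quals[k][1]), n)
        for k, n in counts.items()
        if n >= min_raw
    ]
    kept.sort(key=lambda item: item[0].pair_key)
    if log is not None:
        log.n_raw += n_raw
        log.n_unique_pairs += len(counts)
        log.n_below_min_raw += len(counts) - len(kept)
    return kept


# ---------------------------------------------------------------------------
# Pair merging


def merge_pair(
    pair: ReadPair, min_overlap: int = 10, max_overlap_mismatch: float = 0.2
) -> list[tuple[str, str]]:
    """Merge a pair at its 3' overlap, or return both mates separately.

    Read 2 is reverse-complemented onto the forward strand first.  The
    overlap is chosen as the longest suffix/prefix agreement; disagreements
    inside the overlap are resolved toward the higher-quality base, toward
    read 1 when qualities tie.  If no overlap of at least ``min_overlap``
    bases with mismatch fraction <= ``max_overlap_mismatch`` exists, the two
    mates are returned as independent segments.

    Returns a list of one (merged) or two (unmerged) ``(seq, qual)`` tuples.
    """
    seq1, qual1 = pair.seq1, pair.qual1
    seq2 = reverse_complement(pair.seq2)
    qual2 = pair.qual2[::-1]
    max_o = min(len(seq1), len(seq2))

    # Fast path: exact overlap, longest first.
    for o in range(max_o, min_overlap - 1, -1):
        if seq1[len(seq1) - o :] == seq2[:o]:
            return [(seq1 + seq2[o:], qual1 + qual2[o:])]

    # Tolerant path: best-scoring overlap with bounded mismatch fraction.
    best: tuple[int, int] | None = None  # (score, o)
    for o in range(max_o, min_overlap - 1, -1):
        tail = seq1[len(seq1) - o :]
        head = seq2[:o]
        mism = sum(a != b for a, b in zip(tail, head))
        if mism / o > max_overlap_mismatch:
            continue
        score = (o - mism) - 4 * mism
        if best is None or score > best[0]:
            best = (score, o)
    if best is None:
        return [(seq1, qual1), (seq2, qual2)]

    o = best[1]
    off = len(seq1) - o
    merged = list(seq1[:off])
    merged_q = list(qual1[:off])
    for i in range(o):
        b1, q1 = seq1[off + i], qual1[off + i]
        b2, q2 = seq2[i], qual2[i]
        if b1 == b2 or q1 >= q2:  # tie goes to read 1
            merged.append(b1)
            merged_q.append(max(q1, q2))
        else:
            merged.append(b2)
            merged_q.append(q2)
    merged.extend(seq2[o:])
    merged_q.extend(qual2[o:])
    return [("".join(merged), "".join(merged_q))]


# ---------------------------------------------------------------------------
# Ungapped alignment


class ReferenceIndex:
    """Exact-match k-mer seeds plus ungapped extension against the amplicon.

    Seeding uses k = 16 tried from both fragment ends (with a k = 12
    fallback and a mid-fragment probe), deterministically — no randomised
    hashing.  Both orientations are tried and the reverse complement is
    canonicalised to the forward strand before reporting.
    """

    def __init__(self, ref: ReferenceAmplicon, kmers: Sequence[int] = (16, 12)):
        self.ref = ref
        self.arr = ref.as_array()
        self.kmers = tuple(kmers)
        self._index: dict[int, dict[str, list[int]]] = {}
        seq = ref.sequence
        for k in self.kmers:
            table: dict[str, list[int]] = {}
            for i in range(len(seq) - k + 1):
                table.setdefault(seq[i : i + k], []).append(i)
            self._index[k] = table

    def _candidates(self, seq: str) -> set[int]:
        starts: set[int] = set()
        n = len(seq)
        for k in self.kmers:
            if n < k:
                continue
            probes = {0, n - k, (n - k) // 2}
            for off in probes:
                for hit in self._index[k].get(seq[off : off + k], ()):
                    s0 = hit - off
                    if 0 <= s0 and s0 + n <= len(self.arr):
                        starts.add(s0)
            if starts:
                return starts  # k=16 seeds suffice; fall back only when none hit
        # Last resort: dense probing with the smallest k (substitutions near
        # both ends can defeat the end/middle probes).
        k = min(self.kmers)
        if n >= k:
            for off in range(0, n - k + 1, 3):
                for hit in self._index[k].get(seq[off : off + k], ()):
                    s0 = hit - off
                    if 0 <= s0 and s0 + n <= len(self.arr):
                        starts.add(s0)
        return starts

    def _best(self, seq: str) -> tuple[int, np.ndarray] | None:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        best: tuple[int, np.ndarray] | None = None
        for s0 in sorted(self._candidates(seq)):
            mism = np.nonzero(self.arr[s0 : s0 + len(arr)] != arr)[0]
            if best is None or len(mism) < len(best[1]):
                best = (s0, mism)
        return best

    def align(
        self, seq: str, max_mismatch_frac: float = 0.1
    ) -> tuple[int, int, frozenset[MutationKey]] | None:
        """Substitution-only alignment of a fragment sequence.

        Returns ``(start, end, substitutions)`` in forward-strand amplicon
        coordinates, or ``None`` when no seed matches in either orientation
        or the best alignment exceeds the mismatch fraction.
        """
        fwd = self._best(seq)
        rc_seq = reverse_complement(seq)
        rev = self._best(rc_seq)
        if rev is not None and (fwd is None or len(rev[1]) < len(fwd[1])):
            chosen, oriented = rev, rc_seq
        elif fwd is not None:
            chosen, oriented = fwd, seq
        else:
            return None
        s0, mism = chosen
        if len(mism) / len(seq) > max_mismatch_frac:
            return None
        subs = frozenset(
            MutationKey(s0 + int(i), self.ref.sequence[s0 + int(i)], oriented[int(i)])
            for i in mism
        )
        return (s0, s0 + len(seq), subs)


def align_fragment(
    seq: str,
    ref: ReferenceAmplicon | ReferenceIndex,
    max_mismatch_frac: float = 0.1,
) -> tuple[int, int, frozenset[MutationKey]] | None:
    """Convenience wrapper around :meth:`ReferenceIndex.align`."""
    index = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref)
    return index.align(seq, max_mismatch_frac=max_mismatch_frac)


# ---------------------------------------------------------------------------
# Fragment dedup and base counting


def dedup_fragments(aligned: Iterable) -> list[UniqueFragment]:
    """Group aligned fragments by (start, end, windows, substitutions),
    summing raw multiplicities; emits each group once, in coordinate order.

    Items are ``((start, end, substitutions), raw_count)`` for contiguous
    fragments, optionally ``((start, end, substitutions, windows), raw)``.
    """
    groups: Counter = Counter()
    for hit, raw in aligned:
        if len(hit) == 3:
            start, end, subs = hit
            windows: tuple = ((start, end),)
        else:
            start, end, subs, windows = hit
        groups[(start, end, subs, windows)] += raw
    out = [
        UniqueFragment(start, end, subs, raw, windows)
        for (start, end, subs, windows), raw in groups.items()
    ]
    out.sort(
        key=lambda f: (f.start, f.end, f.windows, sorted(f.substitutions))
    )
    return out


@dataclasses.dataclass
class CountTable:
    """Per-(position, base) fragment counts over the whole amplicon.

    ``counts[p, b]`` is the number of unique fragments covering position
    ``p`` that carry base ``BASES[b]`` there; per-position sums equal the
    fragment coverage.
    """

    counts: np.ndarray  # (len(ref), 4) integer array
    ref: ReferenceAmplicon

    def __post_init__(self) -> None:
        expected = (len(self.ref), len(BASES))
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """1-based positions with per-base counts, as emitted in TSV reports."""
        frame = pd.DataFrame(self.counts, columns=list(BASES))
        frame.insert(0, "position", np.arange(1, len(self.ref) + 1))
        frame.insert(1, "ref_base", list(self.ref.sequence))
        return frame

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, ref: ReferenceAmplicon) -> "CountTable":
        frame = pd.read_csv(path, sep="\t", comment="#")
        counts = frame[list(BASES)].to_numpy()
        return cls(counts, ref)


def count_bases(
    fragments: Iterable[UniqueFragment], ref: ReferenceAmplicon
) -> CountTable:
    """Tally each unique fragment once (not ``raw_count`` times) at every
    position it covers."""
    length = len(ref)
    ref_idx = ref.base_index()
    diff = np.zeros(length + 1, dtype=np.int64)
    corrections: list[tuple[int, int, int]] = []  # (pos, ref_b, alt_b)
    for frag in fragments:
        for a, b in frag.windows:
            diff[a] += 1
            diff[b] -= 1
        for key in frag.substitutions:
            if not any(a <= key.pos < b for a, b in frag.windows):
                raise ValueError(
                    f"substitution {key} outside the sequenced windows of "
                    f"[{frag.start}, {frag.end})"
                )
            if ref.sequence[key.pos] != key.ref:
                raise ValueError(f"substitution {key} disagrees with reference")
            corrections.append((key.pos, BASE_INDEX[key.ref], BASE_INDEX[key.alt]))
    coverage = np.cumsum(diff[:-1])
    counts = np.zeros((length, len(BASES)), dtype=np.int64)
    counts[np.arange(length), ref_idx] = coverage
    for pos, ref_b, alt_b in corrections:
        counts[pos, ref_b] -= 1
        counts[pos, alt_b] += 1
    return CountTable(counts, ref)


# ---------------------------------------------------------------------------
# FASTQ I/O and the full per-sample pipeline


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream a pair of Phred+33 FASTQ files as ReadPairs (plain text)."""
    with open(path1) as fh1, open(path2) as fh2:
        while True:
            head1 = fh1.readline()
            head2 = fh2.readline()
            if not head1:
                if head2:
                    raise ValueError("FASTQ mates out of sync (R2 longer)")
                return
            if not head2:
                raise ValueError("FASTQ mates out of sync (R1 longer)")
            seq1 = fh1.readline().strip()
            fh1.readline()
            qual1 = fh1.readline().strip()
            seq2 = fh2.readline().strip()
            fh2.readline()
            qual2 = fh2.readline().strip()
            yield ReadPair(seq1, qual1, seq2, qual2)


def process_read_pairs(
    pairs: Iterable,
    ref: ReferenceAmplicon | ReferenceIndex,
    min_raw: int = 5,
    max_mismatch_frac: float = 0.1,
    min_overlap: int = 10,
) -> tuple[list[UniqueFragment], CountTable, DropLog]:
    """Run collapse -> merge -> align -> dedup -> count for one sample."""
    index = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref)
    log = DropLog()
    unique_pairs = collapse_and_filter(pairs, min_raw=min_raw, log=log)
    aligned: list[tuple[tuple, int]] = []
    for pair, raw in unique_pairs:
        segments = merge_pair(pair, min_overlap=min_overlap)
        hits = []
        for seq, _qual in segments:
            hit = index.align(seq, max_mismatch_frac=max_mismatch_frac)
            if hit is None:
                log.n_unaligned += 1
            else:
                log.n_aligned_segments += 1
                hits.append(hit)
        if len(hits) == 2:
            # Unmerged mates of one insert: the pair identifies the whole
            # fragment (start from one mate, end from the other) even though
            # only the two read windows were sequenced.
            combined = _combine_mates(hits[0], hits[1])
            if combined is None:
                # Inconsistent mates (overlap disagreement or inverted
                # order): fall back to two independent single-window
                # fragments.
                aligned.extend((hit, raw) for hit in hits)
            else:
                aligned.append((combined, raw))
        elif hits:
            aligned.append((hits[0], raw))
    fragments = dedup_fragments(aligned)
    table = count_bases(fragments, index.ref)
    return fragments, table, log


def _combine_mates(hit_a: tuple, hit_b: tuple) -> tuple | None:
    """Fuse the alignments of two non-overlapping mates into one fragment.

    Returns ``(start, end, substitutions, windows)`` or ``None`` when the
    mates are inconsistent (inverted order, or disagreeing substitutions in
    an overlapping stretch)."""
    (s1, e1, subs1), (s2, e2, subs2) = sorted(
        [hit_a[:3], hit_b[:3]], key=lambda h: (h[0], h[1])
    )
    if e2 <= s1:
        return None
    if e1 >= s2:  # mates overlap after all; require agreement there
        by_pos: dict[int, MutationKey] = {}
        for key in subs1 | subs2:
            if key.pos in by_pos and by_pos[key.pos] != key:
                return None
            by_pos[key.pos] = key
        in_both = {
            k for k in subs1 ^ subs2 if s2 <= k.pos < e1
        }
        if in_both:  # one mate saw a substitution the other denies
            return None
        windows: tuple = ((s1, max(e1, e2)),)
        return (s1, max(e1, e2), frozenset(by_pos.values()), windows)
    return (s1, e2, subs1 | subs2, ((s1, e1), (s2, e2)))


def estimate_substitution_rate(
    fragments: Iterable[UniqueFragment],
    ref: ReferenceAmplicon,
    cds_only: bool = True,
    weight_raw: bool = True,
) -> float:
    """Per-base substitution rate: mismatches over matched aligned bases.

    Restricted to CDS positions by default (the flanks carry no library
    mutations).  ``weight_raw`` weights each unique fragment by its raw
    multiplicity, which restores the multiplicity of transposition events
    whose fragments collide into one identity on a short amplicon.
    """
    lo, hi = (ref.cds_start, ref.cds_end) if cds_only else (0, len(ref))
    mismatches = 0
    aligned = 0
    for frag in fragments:
        w = frag.raw_count if weight_raw else 1
        for a, b in frag.windows:
            aligned += w * max(0, min(b, hi) - max(a, lo))
        mismatches += w * sum(1 for k in frag.substitutions if lo <= k.pos < hi)
    matched = aligned - mismatches
    if matched <= 0:
        raise ValueError("no matched aligned bases in the requested window")
    return mismatches / matched


def fragments_to_frame(
    fragments: Iterable[UniqueFragment], cds_start: int = 0
) -> pd.DataFrame:
    """Fragments as a TSV-ready table (1-based inclusive coordinates)."""
    rows = [
        (
            f.start + 1,
            f.end,
            ",".join(k.label(cds_start) for k in sorted(f.substitutions)) or ".",
            f.raw_count,
        )
        for f in fragments
    ]
    return pd.DataFrame(rows, columns=["start", "end", "substitutions", "raw_count"])
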