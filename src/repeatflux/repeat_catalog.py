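"""Genome-wide contiguous repeat-length distributions.

A simple repeat (STR, microsatellite) is counted here as a maximal run of
complete, uninterrupted copies of a short motif (1-6 nt).  Histograms are
assembled per motif *equivalence class* -- all rotations of the motif and of
its reverse complement -- and lengths are measured in repeat units.  The
lengths of the intervening non-motif segments ("B strings") are tracked
alongside, since the joint dynamics of repeats and the gaps between them is
what the mutation kernel evolves.

Interruptions split a repeat: ``AAAGAAA`` contains two A-runs (3 and 3) and
one B string of length 1, never a single interrupted repeat of length 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifClass:
    """A motif and its strand/rotation equivalence class.

    ``unit`` is the canonical (lexicographically smallest) member; ``members``
    is closed under rotation and reverse complement, e.g. A -> {A, T} and
    AC -> {AC, CA, GT, TG}.
    """

    unit: str
    members: frozenset

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.unit


@dataclass
class LengthDistribution:
    """Integer counts per repeat length, optionally normalized.

    ``counts`` maps length (in repeat units, >= 1) to a non-negative count;
    counts are real-valued so that expected counts from the deterministic
    kernel fit the same container.  ``freqs`` is populated by
    :func:`normalize` and always sums to one; raw counts are retained.
    """

    counts: Dict[int, float]
    unit_length: int = 1
    freqs: Optional[Dict[int, float]] = None
    truncation_length: Optional[int] = None

    @property
    def normalized(self) -> bool:
        return self.freqs is not None

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def max_length(self) -> int:
        return max(self.counts) if self.counts else 0

    def to_array(self, max_length: Optional[int] = None, *,
                 normalized: bool = False) -> np.ndarray:
        """Dense vector indexed 1..max_length (index 0 is a zero pad)."""
        n = max_length if max_length is not None else self.max_length()
        out = np.zeros(n + 1)
        src = self.freqs if normalized else self.counts
        if normalized and src is None:
            raise ValueError("distribution is not normalized")
        for length, value in src.items():
            if 1 <= length <= n:
                out[length] = value
        return out

    def nt_view(self) -> Dict[int, float]:
        """Counts keyed by total nucleotide length (L x unit length)."""
        return {L * self.unit_length: c for L, c in self.counts.items()}


@dataclass
class BootstrapEnvelope:
    """Per-bin 95% bootstrap envelope of a raw length distribution."""

    lower: Dict[int, float]
    upper: Dict[int, float]
    point: Dict[int, float]
    n_resamples: int
    segment_length: int


# ---------------------------------------------------------------------------
# motif equivalence classes
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def motif_class(unit: str) -> MotifClass:
    """Equivalence class of ``unit`` under rotation and reverse complement."""
    unit = unit.upper()
    if not unit or set(unit) - _VALID:
        raise ValueError(f"motif must be a non-empty string over ACGT: {unit!r}")
    members = set()
    for seq in (unit, reverse_complement(unit)):
        for i in range(len(seq)):
            members.add(seq[i:] + seq[:i])
    return MotifClass(unit=min(members), members=frozenset(members))


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _boolean_runs(mask: np.ndarray) -> Iterable[Tuple[int, int]]:
    """(start, length) of maximal True runs in a boolean vector."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[::2], edges[1::2]
    return zip(starts.tolist(), (ends - starts).tolist())


def _member_match(arr: np.ndarray, member: bytes) -> np.ndarray:
    """True at positions where a complete copy of ``member`` starts."""
    n = len(member)
    if arr.size < n:
        return np.zeros(0, dtype=bool)
    out = np.ones(arr.size - n + 1, dtype=bool)
    for j in range(n):
        out &= arr[j:arr.size - n + 1 + j] == member[j:j + 1]
    return out


def count_repeats(sequence: str, motif: MotifClass,
                  ) -> Tuple[LengthDistribution, LengthDistribution]:
    """Count maximal runs of complete motif copies and the gaps between them.

    Returns the (A-side, B-side) length distributions.  A-side lengths are in
    repeat units; B-side lengths are in nucleotides (identical for
    mononucleotide motifs).  For unit length n > 1 the sequence is scanned in
    n frames per equivalence-class member; overlapping detections of the same
    genomic interval are deduplicated keeping the longest frame-consistent
    run (ties broken by leftmost start).  ``N`` breaks runs on both sides.
    """
    n = motif.unit_length
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    counts_a: Dict[int, float] = {}
    occupied = np.zeros(arr.size, dtype=bool)

    if n == 1:
        # members sit on disjoint base sets; no dedup needed
        for member in sorted(motif.members):
            match = _member_match(arr, member.encode("ascii"))
            for start, k in _boolean_runs(match):
                counts_a[k] = counts_a.get(k, 0) + 1
                occupied[start:start + k] = True
    else:
        candidates: List[Tuple[int, int, int]] = []  # (-k, start, k)
        for member in sorted(motif.members):
            match = _member_match(arr, member.encode("ascii"))
            for f in range(n):
                sub = match[f::n]
                for s, k in _boolean_runs(sub):
                    start = f + s * n
                    candidates.append((-k, start, k))
        candidates.sort()
        for _, start, k in candidates:
            span = occupied[start:start + k * n]
            if not span.any():
                counts_a[k] = counts_a.get(k, 0) + 1
                span[:] = True

    # B strings: maximal non-N stretches not covered by an accepted run
    is_n = arr == b"N"
    counts_b: Dict[int, float] = {}
    b_mask = ~occupied & ~is_n
    for _, length in _boolean_runs(b_mask):
        counts_b[length] = counts_b.get(length, 0) + 1

    return (LengthDistribution(counts_a, unit_length=n),
            LengthDistribution(counts_b, unit_length=1))


def count_assembly(contigs: Mapping[str, str], motif: MotifClass,
                   ) -> Tuple[LengthDistribution, LengthDistribution]:
    """Sum :func:`count_repeats` over the contigs of an assembly."""
    total_a: Dict[int, float] = {}
    total_b: Dict[int, float] = {}
    for seq in contigs.values():
        dist_a, dist_b = count_repeats(seq, motif)
        for L, c in dist_a.counts.items():
            total_a[L] = total_a.get(L, 0) + c
        for L, c in dist_b.counts.items():
            total_b[L] = total_b.get(L, 0) + c
    return (LengthDistribution(total_a, unit_length=motif.unit_length),
            LengthDistribution(total_b, unit_length=1))


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def normalize(dist: LengthDistribution) -> LengthDistribution:
    """Return a copy with per-bin frequencies summing to one."""
    total = dist.total()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero distribution")
    freqs = {L: c / total for L, c in dist.counts.items()}
    return replace(dist, freqs=freqs)


def truncate_low_occupancy(dist: LengthDistribution,
                           min_count: float = 30) -> LengthDistribution:
    """Drop all bins at and above the first length with raw count < min_count.

    Truncation is at the *first* failing length: a well-populated bin beyond
    a sparse one is removed too, so that assemblies of different sizes are
    compared over the lengths they sample reliably.
    """
    if not dist.counts:
        return replace(dist, truncation_length=None)
    cutoff = None
    for L in range(1, dist.max_length() + 1):
        if dist.counts.get(L, 0) < min_count:
            cutoff = L
            break
    if cutoff is None:
        return replace(dist, truncation_length=None)
    kept = {L: c for L, c in dist.counts.items() if L < cutoff}
    freqs = None
    if dist.freqs is not None:
        freqs = {L: f for L, f in dist.freqs.items() if L < cutoff}
    return replace(dist, counts=kept, freqs=freqs, truncation_length=cutoff)


def median_distribution(dists: Sequence[LengthDistribution],
                        ) -> LengthDistribution:
    """Per-bin median of normalized distributions (absent bins count as 0).

    Used for cross-species summaries; applied without any truncation so the
    median tail reflects every assembly that samples it.
    """
    if not dists:
        raise ValueError("need at least one distribution")
    for d in dists:
        if d.freqs is None:
            raise ValueError("median_distribution expects normalized inputs")
    bins = sorted({L for d in dists for L in d.freqs})
    med = {L: float(np.median([d.freqs.get(L, 0.0) for d in dists]))
           for L in bins}
    med = {L: v for L, v in med.items() if v > 0}
    return LengthDistribution(counts=dict(med),
                              unit_length=dists[0].unit_length, freqs=med)


def filter_contigs(contigs: Mapping[str, str],
                   min_length: int = 10_000) -> Dict[str, str]:
    """Drop contigs shorter than ``min_length`` bp before counting.

    Short contigs in draft assemblies are enriched for poorly assembled,
    transposon-dense sequence and would bias the length distribution.
    """
    return {name: seq for name, seq in contigs.items()
            if len(seq) >= min_length}


# ---------------------------------------------------------------------------
# resampling and baselines
# ---------------------------------------------------------------------------

def bootstrap_envelope(contigs: Mapping[str, str], motif: MotifClass,
                       n: int = 1000, segment_length: int = 1_000_000,
                       seed: Optional[int] = None) -> BootstrapEnvelope:
    """Segment-bootstrap 95% envelope of the genome-wide A-side histogram.

    Each contig is cut into contiguous non-overlapping segments of
    ``segment_length`` bp (sub-segment tails are discarded); whole-genome
    histograms are reassembled by resampling segments with replacement.  For
    n resamples the envelope drops the top and bottom ``round(0.025 n)``
    values per bin (25 each for the default n = 1000).
    """
    segments: List[Dict[int, float]] = []
    for seq in contigs.values():
        for start in range(0, len(seq) - segment_length + 1, segment_length):
            dist_a, _ = count_repeats(seq[start:start + segment_length], motif)
            segments.append(dist_a.counts)
    if not segments:
        raise ValueError("genome shorter than one segment")

    bins = sorted({L for seg in segments for L in seg})
    matrix = np.array([[seg.get(L, 0.0) for L in bins] for seg in segments])
    point = matrix.sum(axis=0)

    rng = np.random.default_rng(seed)
    n_seg = len(segments)
    weights = rng.multinomial(n_seg, np.full(n_seg, 1.0 / n_seg), size=n)
    resampled = weights @ matrix            # (n, n_bins)
    resampled.sort(axis=0)
    drop = int(round(0.025 * n))
    lower = resampled[drop]
    upper = resampled[n - 1 - drop]

    return BootstrapEnvelope(
        lower={L: float(v) for L, v in zip(bins, lower)},
        upper={L: float(v) for L, v in zip(bins, upper)},
        point={L: float(v) for L, v in zip(bins, point)},
        n_resamples=n, segment_length=segment_length)


def shuffled_baseline(contigs: Mapping[str, str], motif: MotifClass,
                      seed: Optional[int] = None) -> LengthDistribution:
    """A-side distribution of a uniformly shuffled copy of the genome.

    Base composition is preserved exactly; runs in the shuffled sequence are
    geometric, which is the null expectation against which the genomic excess
    of long repeats is judged.
    """
    concat = "".join(seq.upper() for seq in contigs.values())
    arr = np.frombuffer(concat.encode("ascii"), dtype="S1").copy()
    rng = np.random.default_rng(seed)
    rng.shuffle(arr)
    dist_a, _ = count_repeats(arr.tobytes().decode("ascii"), motif)
    return dist_a
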