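"""Per-generation mutation-rate estimation from de novo trio tables and
popSTR-style locus tables.

Substitutions are classified into six categories by the three-unit context
around the mutated site with respect to the focal motif (A = motif unit,
B = anything else): lengthen (ABB>AAB, BBA>BAA), shorten (AAB>ABB,
BAA>BBA), fusion (ABA>AAA), fission (AAA>ABA), create_A1 (BBB>BAB) and
destroy_A1 (BAB>BBB).  Context rates are assumed independent of repeat
length.  Indels are classified as expansions, contractions or non-motif
insertions and stratified by the parental repeat length; rates are events
divided by the diploid number of targets per offspring generation.

Rate conventions: a tabulated indel rate at length L is per repeat; the
per-target (per-unit) rate consumed by the mutation kernel is that value
divided by the target size L.  Substitution context rates are per context
site.  Denominators are diploid (x2) per offspring genome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .repeat_catalog import LengthDistribution, MotifClass, count_repeats
from .mutation_kernel import ContextRates

Mask = Set[Tuple[str, int]]

CONTEXT_CATEGORIES = ("lengthen", "shorten", "fusion", "fission",
                      "create_a1", "destroy_a1")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MutationRecord:
    """One de novo call (VCF conventions: 1-based pos, ref/alt alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    proband: str = ""
    phase: Optional[str] = None       # "maternal" | "paternal" | None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class IndelCall:
    """Classification of one indel with respect to a motif."""

    type: str                 # expansion | contraction | non_motif_insertion
    #                         # | partial_deletion | b1_deletion_fusion
    #                         # | b_insertion | b_deletion | other
    units: int                # signed unit change (0 where not applicable)
    parental_length: int      # maximal motif run touching the event (units)


@dataclass
class ContextRateEstimate:
    """Context rates together with the raw counts behind them (the counts
    are what Poisson consistency resampling perturbs)."""

    rates: ContextRates
    events: Dict[str, int]
    targets: Dict[str, float]          # diploid-offspring denominators
    n_offspring: int

    def resample(self, rng: np.random.Generator) -> ContextRates:
        sampled = {}
        for cat in CONTEXT_CATEGORIES:
            denom = self.targets[cat]
            sampled[cat] = rng.poisson(self.events[cat]) / denom if denom else 0.0
        return ContextRates(
            lengthen=sampled["lengthen"], shorten=sampled["shorten"],
            fusion=sampled["fusion"], fission=sampled["fission"],
            create_a1=sampled["create_a1"], destroy_a1=sampled["destroy_a1"],
            b_insert=self.rates.b_insert, b_delete=self.rates.b_delete,
            b1_delete_fusion=self.rates.b1_delete_fusion,
            substitution_avg=self.rates.substitution_avg)


@dataclass
class LengthRateTable:
    """Per-length indel rates with raw counts, denominators and 95% CIs.

    ``events[type][i]`` counts +/-1-unit events at ``lengths[i]``;
    ``targets[i]`` is the diploid allele-transmission denominator (2 x
    repeats of that length x offspring, or 2 x passing trios for popSTR).
    ``spectrum[type]`` tallies signed unit changes of *all* events,
    including multi-unit ones that are excluded from the rate columns.
    """

    lengths: np.ndarray
    events: Dict[str, np.ndarray]
    targets: np.ndarray
    ci_low: Dict[str, np.ndarray] = field(default_factory=dict)
    ci_high: Dict[str, np.ndarray] = field(default_factory=dict)
    spectrum: Dict[str, Counter] = field(default_factory=dict)

    def per_repeat(self, type_: str) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(self.targets > 0,
                            self.events[type_] / self.targets, np.nan)
        return rate

    def per_target(self, type_: str) -> np.ndarray:
        """Per-unit rates (per-repeat divided by the target size L)."""
        return self.per_repeat(type_) / self.lengths

    def plus_minus_one_fraction(self, type_: str) -> float:
        spec = self.spectrum.get(type_, Counter())
        total = sum(spec.values())
        if total == 0:
            return float("nan")
        return (spec.get(1, 0) + spec.get(-1, 0)) / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for type_ in self.events:
            rate = self.per_target(type_)
            lo = self.ci_low.get(type_)
            hi = self.ci_high.get(type_)
            for i, L in enumerate(self.lengths):
                rows.append({
                    "type": type_, "length": int(L),
                    "events": float(self.events[type_][i]),
                    "targets": float(self.targets[i]),
                    "rate": float(rate[i]),
                    "ci_low": float(lo[i]) if lo is not None else np.nan,
                    "ci_high": float(hi[i]) if hi is not None else np.nan,
                })
        return pd.DataFrame(rows)


@dataclass
class PowerLawFit:
    """Log-log regression of a rate curve: slope = power-law exponent tau."""

    slope: float
    intercept: float
    slope_ci: Tuple[float, float]
    m: float                       # implied multiplier over the L=8 rate at L=9
    m_range: Tuple[float, float]
    fit_lengths: np.ndarray


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def window_index(pos: int, window: int) -> int:
    return (pos - 1) // window


def mask_low_coverage(records: Iterable[MutationRecord],
                      contigs: Mapping[str, str],
                      window: int = 100_000) -> Mask:
    """Windows with zero substitutions are assumed unmappable and masked.

    The trio VCFs carry no depth information for unmutated positions, so a
    window of the stated size without a single substitution across the pooled
    dataset is treated as invisible to calling and excluded from every
    denominator downstream.
    """
    hit: Set[Tuple[str, int]] = set()
    for rec in records:
        if rec.is_substitution:
            hit.add((rec.chrom, window_index(rec.pos, window)))
    mask: Mask = set()
    for chrom, seq in contigs.items():
        n_windows = (len(seq) + window - 1) // window
        for w in range(n_windows):
            if (chrom, w) not in hit:
                mask.add((chrom, w))
    return mask


def unmasked_bases(contigs: Mapping[str, str], mask: Optional[Mask],
                   window: int = 100_000) -> int:
    total = 0
    for chrom, seq in contigs.items():
        n_windows = (len(seq) + window - 1) // window
        for w in range(n_windows):
            if mask and (chrom, w) in mask:
                continue
            total += min(window, len(seq) - w * window)
    return total


def _is_masked(rec: MutationRecord, mask: Optional[Mask], window: int) -> bool:
    return bool(mask) and (rec.chrom, window_index(rec.pos, window)) in mask


# ---------------------------------------------------------------------------
# substitution context classification
# ---------------------------------------------------------------------------

def _category_code(is_a: bool, n_a_neighbors: int) -> str:
    if is_a:
        return ("destroy_a1", "shorten", "fission")[n_a_neighbors]
    return ("create_a1", "lengthen", "fusion")[n_a_neighbors]


def classify_substitution(rec: MutationRecord, contigs: Mapping[str, str],
                          motif: MotifClass) -> str:
    """Six-category trinucleotide-context classification (mononucleotide
    motifs).  Contexts off the contig end, non-ACGT flanks and substitutions
    not touching the motif return "other"."""
    if motif.unit_length != 1:
        raise ValueError("context classification is defined for "
                         "mononucleotide motifs")
    if not rec.is_substitution:
        return "other"
    seq = contigs.get(rec.chrom)
    if seq is None:
        return "other"
    i = rec.pos - 1
    if i < 1 or i >= len(seq) - 1:
        return "other"
    left, site, right = seq[i - 1].upper(), seq[i].upper(), seq[i + 1].upper()
    if site != rec.ref:
        raise ValueError(f"reference mismatch at {rec.chrom}:{rec.pos}")
    if any(b not in "ACGT" for b in (left, site, right)):
        return "other"
    if rec.ref in motif.members:
        member = rec.ref             # A -> B flavor
    elif rec.alt in motif.members:
        member = rec.alt             # B -> A flavor
    else:
        return "other"
    n_a = int(left == member) + int(right == member)
    return _category_code(site == member, n_a)


def context_target_counts(contigs: Mapping[str, str], motif: MotifClass,
                          mask: Optional[Mask] = None,
                          window: int = 100_000) -> Dict[str, int]:
    """Haploid counts of context sites per category, summed over the
    equivalence-class members, excluding masked windows."""
    totals = {cat: 0 for cat in CONTEXT_CATEGORIES}
    for chrom, seq in contigs.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
        if arr.size < 3:
            continue
        valid = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
        ok = valid[:-2] & valid[1:-1] & valid[2:]
        if mask:
            pos = np.arange(1, arr.size - 1)
            w = pos // window        # 0-based position // window
            masked_w = {wi for (c, wi) in mask if c == chrom}
            if masked_w:
                ok = ok & ~np.isin(w, list(masked_w))
        member_any = np.isin(arr, [m.encode("ascii")
                                   for m in sorted(motif.members)])
        for member in sorted(motif.members):
            xa = arr == member.encode("ascii")
            mid = xa[1:-1]
            # a B *site* must not be any class member (an A->T change is
            # classified once, on the reference-member side)
            site_ok = ok & (mid | ~member_any[1:-1])
            n_a = xa[:-2].astype(np.int8) + xa[2:].astype(np.int8)
            code = mid.astype(np.int8) * 3 + n_a
            counts = np.bincount(code[site_ok], minlength=6)
            totals["create_a1"] += int(counts[0])
            totals["lengthen"] += int(counts[1])
            totals["fusion"] += int(counts[2])
            totals["destroy_a1"] += int(counts[3])
            totals["shorten"] += int(counts[4])
            totals["fission"] += int(counts[5])
    return totals


def estimate_context_rates(records: Iterable[MutationRecord],
                           contigs: Mapping[str, str], motif: MotifClass,
                           n_offspring: int, mask: Optional[Mask] = None,
                           window: int = 100_000) -> ContextRateEstimate:
    """Per-context-site, per-generation substitution rates.

    rate = events / (2 x unmasked context sites x offspring genomes); the
    factor two is the diploid target.
    """
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    events = {cat: 0 for cat in CONTEXT_CATEGORIES}
    n_subs = 0
    for rec in records:
        if not rec.is_substitution or _is_masked(rec, mask, window):
            continue
        n_subs += 1
        cat = classify_substitution(rec, contigs, motif)
        if cat in events:
            events[cat] += 1
    site_counts = context_target_counts(contigs, motif, mask, window)
    targets = {cat: 2.0 * site_counts[cat] * n_offspring
               for cat in CONTEXT_CATEGORIES}
    rates = {}
    for cat in CONTEXT_CATEGORIES:
        if targets[cat] == 0:
            if events[cat]:
                raise ValueError(f"no targets for category {cat} but "
                                 f"{events[cat]} events observed")
            rates[cat] = 0.0
        else:
            rates[cat] = events[cat] / targets[cat]
    genome = unmasked_bases(contigs, mask, window)
    avg = n_subs / (2.0 * genome * n_offspring) if genome else 0.0
    ctx = ContextRates(substitution_avg=avg, **rates)
    return ContextRateEstimate(rates=ctx, events=events, targets=targets,
                               n_offspring=n_offspring)


# ---------------------------------------------------------------------------
# indel classification
# ---------------------------------------------------------------------------

def _left_align(seq: str, start: int, allele: str) -> int:
    """Shift an inserted/deleted segment left to its canonical position.

    ``start`` is the 0-based position of the first inserted/deleted base;
    the segment can shift left one base whenever the base before it equals
    its last base (standard VCF left-alignment in repetitive context).
    """
    k = len(allele)
    allele = list(allele)
    while start > 0 and seq[start - 1] == allele[-1]:
        allele.insert(0, allele.pop())
        start -= 1
    return start


def _run_at(seq: str, lo: int, hi: int, member: str) -> Tuple[int, int]:
    """Maximal run of ``member`` covering or touching [lo, hi) (0-based)."""
    s, e = lo, lo
    i = lo
    while i > 0 and seq[i - 1] == member:
        i -= 1
    s = i
    i = hi
    while i < len(seq) and seq[i] == member:
        i += 1
    e = i
    # include the interval itself where it consists of the member
    return s, e


def classify_indel(rec: MutationRecord, contigs: Mapping[str, str],
                   motif: MotifClass) -> IndelCall:
    """Classify a simple indel against the reference repeat structure.

    The parental sequence is assumed identical to the reference.  Events are
    normalized to their left-aligned representation and attributed to the
    maximal motif run containing or touching them.
    """
    if motif.unit_length != 1:
        raise ValueError("indel classification is defined for "
                         "mononucleotide motifs")
    seq = contigs.get(rec.chrom)
    if seq is None:
        return IndelCall("other", 0, 0)
    seq = seq.upper()
    ref, alt = rec.ref, rec.alt
    if rec.is_substitution or ref[0] != alt[0] or \
            (len(ref) > 1 and len(alt) > 1):
        return IndelCall("other", 0, 0)

    if len(alt) > len(ref):                      # insertion
        ins = alt[1:]
        point = _left_align(seq, rec.pos, ins)   # 0-based insertion index
        left = seq[point - 1] if point > 0 else ""
        right = seq[point] if point < len(seq) else ""
        for member in sorted(motif.members):
            if set(ins) == {member}:
                if left == member or right == member:
                    s, e = _run_at(seq, point, point, member)
                    return IndelCall("expansion", len(ins), e - s)
        for member in sorted(motif.members):
            if left == member and right == member and member not in ins:
                s, e = _run_at(seq, point, point, member)
                return IndelCall("non_motif_insertion", len(ins), e - s)
        return IndelCall("b_insertion", len(ins), 0)

    # deletion
    dele = ref[1:]
    start = _left_align(seq, rec.pos, dele)      # 0-based first deleted base
    end = start + len(dele)
    segment = seq[start:end]
    left = seq[start - 1] if start > 0 else ""
    right = seq[end] if end < len(seq) else ""
    for member in sorted(motif.members):
        if set(segment) == {member}:
            s, e = _run_at(seq, start, end, member)
            if e - s > len(dele):
                return IndelCall("contraction", -len(dele), e - s)
            # the whole run is deleted: removes a repeat outright
            return IndelCall("contraction", -len(dele), e - s)
    for member in sorted(motif.members):
        if len(segment) == 1 and segment not in motif.members and \
                left == member and right == member:
            return IndelCall("b1_deletion_fusion", -1, 0)
    if all(b not in motif.members for b in segment):
        return IndelCall("b_deletion", -len(dele), 0)
    return IndelCall("partial_deletion", -len(dele), 0)


def estimate_indel_rates(records: Iterable[MutationRecord],
                         contigs: Mapping[str, str], motif: MotifClass,
                         n_offspring: int,
                         repeat_counts: LengthDistribution,
                         mask: Optional[Mask] = None,
                         window: int = 100_000,
                         max_length: Optional[int] = None,
                         ci_seed: Optional[int] = 0) -> LengthRateTable:
    """Length-stratified expansion / contraction / non-motif-insertion rates.

    Rates use only +/-1-unit events (the kernel models single-unit changes);
    the full signed-unit spectrum is tabulated alongside.  The denominator
    at length L is 2 x (repeats of length L in the unmasked genome) x
    offspring genomes; a length with zero repeats yields a missing (NaN)
    rate, never zero.
    """
    if max_length is None:
        max_length = max(repeat_counts.max_length(), 1)
    lengths = np.arange(1, max_length + 1)
    types = ("expansion", "contraction", "non_motif_insertion")
    events = {t: np.zeros(max_length, dtype=float) for t in types}
    spectrum: Dict[str, Counter] = {t: Counter() for t in types}
    for rec in records:
        if rec.is_substitution or _is_masked(rec, mask, window):
            continue
        call = classify_indel(rec, contigs, motif)
        if call.type not in types:
            continue
        spectrum[call.type][call.units] += 1
        if abs(call.units) == 1 and 1 <= call.parental_length <= max_length:
            events[call.type][call.parental_length - 1] += 1
    targets = np.array([2.0 * repeat_counts.counts.get(int(L), 0) * n_offspring
                        for L in lengths])
    table = LengthRateTable(lengths=lengths.astype(float), events=events,
                            targets=targets, spectrum=spectrum)
    if ci_seed is not None:
        rng = np.random.default_rng(ci_seed)
        for t in types:
            lo, hi = poisson_ci(events[t], targets * table.lengths, rng=rng)
            table.ci_low[t], table.ci_high[t] = lo, hi
    return table


def estimate_b_rates(records: Iterable[MutationRecord],
                     contigs: Mapping[str, str], motif: MotifClass,
                     n_offspring: int, mask: Optional[Mask] = None,
                     window: int = 100_000) -> Dict[str, float]:
    """Average per-unit B-string indel rates (BB>BBB, BBB>BB, ABA>AA).

    B strings are not modeled with length-dependent instability, so a single
    per-unit average suffices for each process.
    """
    counts = {"b_insertion": 0, "b_deletion": 0, "b1_deletion_fusion": 0}
    for rec in records:
        if rec.is_substitution or _is_masked(rec, mask, window):
            continue
        call = classify_indel(rec, contigs, motif)
        if call.type in counts and abs(call.units) == 1:
            counts[call.type] += 1
    # per-unit denominator: number of B units in the unmasked genome
    b_units = 0
    for chrom, seq in contigs.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
        is_b = ~np.isin(arr, [m.encode("ascii") for m in motif.members])
        is_b &= arr != b"N"
        if mask:
            pos_w = np.arange(arr.size) // window
            masked_w = [wi for (c, wi) in mask if c == chrom]
            if masked_w:
                is_b &= ~np.isin(pos_w, masked_w)
        b_units += int(is_b.sum())
    denom = 2.0 * b_units * n_offspring
    if denom == 0:
        return {k: 0.0 for k in counts}
    return {k: v / denom for k, v in counts.items()}


# ---------------------------------------------------------------------------
# popSTR-style reanalysis
# ---------------------------------------------------------------------------

def popstr_longest_run(contigs: Mapping[str, str], chrom: str,
                       start: int, end: int, motif: MotifClass) -> int:
    """Longest contiguous motif run (in units) within [start, end), 0-based.

    Interrupted loci are scored by their longest pure tract, matching the
    length-dependence convention used throughout.
    """
    seq = contigs[chrom][start:end]
    dist_a, _ = count_repeats(seq, motif)
    return dist_a.max_length()


def popstr_assign_parent(proband_length: int,
                         parental_lengths: Sequence[int],
                         phase: Optional[str] = None) -> int:
    """Parental allele of origin for one transmission.

    Phased events keep their designated parent (alleles ordered maternal
    pair then paternal pair); unphased events take the parental length
    minimizing |proband - parental|, ties resolved to the smaller length.
    """
    alleles = list(parental_lengths)
    if phase == "maternal":
        alleles = alleles[:2]
    elif phase == "paternal":
        alleles = alleles[2:]
    return min(alleles, key=lambda a: (abs(proband_length - a), a))


def filter_popstr_loci(loci: pd.DataFrame, contigs: Mapping[str, str],
                       motif: MotifClass) -> pd.DataFrame:
    """Keep loci whose reported reference length matches our own measurement
    of the longest contiguous run in the reference interval."""
    keep = []
    for _, row in loci.iterrows():
        measured = popstr_longest_run(contigs, row["chrom"],
                                      int(row["start"]), int(row["end"]),
                                      motif)
        keep.append(measured == int(row["ref_length"]))
    return loci[np.array(keep, dtype=bool)]


def popstr_rates(events: pd.DataFrame, loci: pd.DataFrame,
                 max_length: Optional[int] = None,
                 ci_seed: Optional[int] = 0) -> LengthRateTable:
    """Insertion/deletion rates per parental length from a popSTR-style table.

    The denominator at length L is the number of allele transmissions
    ascribed to loci of reference length L: sum over such loci of
    2 x passing trios.  Insertions conflate expansions and non-motif
    insertions (the caller cannot distinguish them).
    """
    if max_length is None:
        max_length = int(loci["ref_length"].max()) if len(loci) else 1
    lengths = np.arange(1, max_length + 1)
    targets = np.zeros(max_length)
    for _, row in loci.iterrows():
        L = int(row["ref_length"])
        if 1 <= L <= max_length:
            targets[L - 1] += 2.0 * row["passing_trios"]
    ev = {"insertion": np.zeros(max_length), "deletion": np.zeros(max_length)}
    spectrum = {"insertion": Counter(), "deletion": Counter()}
    locus_lengths = dict(zip(loci["locus_id"], loci["ref_length"]))
    for _, row in events.iterrows():
        if row["locus_id"] not in locus_lengths:
            continue
        parental = int(row["parental_length"])
        units = int(row["proband_length"]) - parental
        if units == 0:
            continue
        type_ = "insertion" if units > 0 else "deletion"
        spectrum[type_][units] += 1
        if abs(units) == 1 and 1 <= parental <= max_length:
            ev[type_][parental - 1] += 1
    table = LengthRateTable(lengths=lengths.astype(float), events=ev,
                            targets=targets, spectrum=spectrum)
    if ci_seed is not None:
        rng = np.random.default_rng(ci_seed)
        for t in ev:
            lo, hi = poisson_ci(ev[t], targets * table.lengths, rng=rng)
            table.ci_low[t], table.ci_high[t] = lo, hi
    return table


# ---------------------------------------------------------------------------
# uncertainty and power-law fitting
# ---------------------------------------------------------------------------

def poisson_ci(counts: np.ndarray, denominators: np.ndarray,
               n_samples: int = 200, drop: int = 5,
               seed: Optional[int] = None,
               rng: Optional[np.random.Generator] = None,
               ) -> Tuple[np.ndarray, np.ndarray]:
    """95% rate intervals from order statistics of Poisson-resampled counts.

    Each bin's count is resampled ``n_samples`` times; after discarding the
    top and bottom ``drop`` values the interval is the min/max of the rest.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=float)
    denominators = np.asarray(denominators, dtype=float)
    samples = rng.poisson(np.broadcast_to(counts, (n_samples, counts.size)))
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(denominators > 0, samples / denominators, np.nan)
    rates = np.sort(rates, axis=0)
    return rates[drop].copy(), rates[n_samples - 1 - drop].copy()


def fit_powerlaw(table: LengthRateTable, type_: str,
                 fit_lengths: Tuple[int, int] = (12, 19),
                 rate8: Optional[float] = None,
                 ci_level: float = 0.999) -> PowerLawFit:
    """Log-log linear regression of a per-target rate curve.

    The slope estimates the power-law exponent tau; its confidence interval
    (99.9% by default) is propagated, through intercepts pinned at the
    regression centroid, to a range of predicted rates at L=9 and hence to a
    range of multipliers m over a given L=8 rate.
    """
    lo, hi = fit_lengths
    sel = (table.lengths >= lo) & (table.lengths <= hi)
    rates = table.per_target(type_)[sel]
    lengths = table.lengths[sel]
    good = np.isfinite(rates) & (rates > 0)
    if good.sum() < 3:
        raise ValueError("need at least 3 finite positive rates in the "
                         "fit range")
    x, y = np.log(lengths[good]), np.log(rates[good])
    res = stats.linregress(x, y)
    dof = good.sum() - 2
    tcrit = stats.t.ppf(0.5 + ci_level / 2, dof) if dof > 0 else np.inf
    slope_ci = (res.slope - tcrit * res.stderr,
                res.slope + tcrit * res.stderr)
    xbar, ybar = x.mean(), y.mean()

    def rate_at_9(slope: float) -> float:
        intercept = ybar - slope * xbar
        return float(np.exp(intercept + slope * np.log(9.0)))

    predicted9 = float(np.exp(res.intercept + res.slope * np.log(9.0)))
    if rate8 is not None and rate8 > 0:
        m = predicted9 / rate8
        m_range = tuple(sorted(rate_at_9(s) / rate8 for s in slope_ci))
    else:
        m = float("nan")
        m_range = (float("nan"), float("nan"))
    return PowerLawFit(slope=float(res.slope), intercept=float(res.intercept),
                       slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
                       m=m, m_range=m_range,
                       fit_lengths=lengths[good])
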