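"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here without downloads:
i.i.d. random genomes with tunable composition, de novo trio mutation
tables placed at specified context-dependent substitution rates and
length-dependent indel rates, popSTR-style locus/event tables, and
kernel-generated pseudo-empirical length distributions for closed-loop
recovery tests.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mutation_kernel import (ContextRates, InstabilityParams, JointState,
                              RateModel, ScheduleStage, SHORT_SCHEDULE,
                              build_rate_curves, evolve, iid_state)
from .rate_estimation import MutationRecord
from .repeat_catalog import LengthDistribution, MotifClass, motif_class

#: context substitution rates estimated from the pooled trio datasets
#: (per target site, per diploid offspring generation), A/T motif
DEFAULT_CONTEXT_RATES = ContextRates(
    lengthen=4.77e-9, shorten=8.08e-9,
    fusion=2.87e-9, fission=4.54e-9,
    create_a1=3.97e-9, destroy_a1=6.45e-9,
    b_insert=1.44e-10, b_delete=4.56e-12, b1_delete_fusion=2.89e-10,
    substitution_avg=1.2e-8)

#: per-target (per-unit) de novo indel rate curves for L = 1..8.  Calibrated
#: once to the qualitative features of trio-based estimates for A/T
#: mononucleotides: a steep (four-orders-of-magnitude) rise between L=1 and
#: L=8 whose per-target rate overtakes the per-site substitution rate
#: (1.2e-8) around L=6; a modest initial expansion bias
#: (eps_8/kappa_8 = 1.25), which under the shared-multiplier power laws
#: places the expansion/contraction crossing L* near 10 for strong
#: contraction bias and near 19 for best-fit-like delta_tau = 0.3; and a
#: non-motif insertion curve near the background (B-string) insertion
#: scale, so that interruption of a repeat by substitution remains the
#: dominant fission channel up to lengths around 20.
DEFAULT_DENOVO_EPS = np.array(
    [2.4e-11, 6.0e-11, 2.4e-10, 9.6e-10, 3.6e-9, 1.2e-8, 4.8e-8, 1.2e-7])
DEFAULT_DENOVO_KAPPA = np.array(
    [1.2e-11, 3.6e-11, 1.8e-10, 7.2e-10, 2.6e-9, 9.6e-9, 3.8e-8, 9.6e-8])
DEFAULT_DENOVO_IOTA = np.array(
    [1e-11, 2e-11, 5e-11, 1e-10, 2e-10, 3e-10, 4e-10, 5e-10])

#: best-fit-like instability parameters (weak contraction bias)
DEFAULT_PARAMS = InstabilityParams(m=2.0, tau_eps=1.7, tau_kappa=2.0)


@dataclass
class SyntheticTruth:
    """Generating parameters of a synthetic dataset (with the seed, they
    fully determine the output)."""

    p_a: float = 0.3
    context: ContextRates = field(
        default_factory=lambda: replace(DEFAULT_CONTEXT_RATES))
    denovo_eps: np.ndarray = field(
        default_factory=lambda: DEFAULT_DENOVO_EPS.copy())
    denovo_kappa: np.ndarray = field(
        default_factory=lambda: DEFAULT_DENOVO_KAPPA.copy())
    denovo_iota: np.ndarray = field(
        default_factory=lambda: DEFAULT_DENOVO_IOTA.copy())
    params: InstabilityParams = field(
        default_factory=lambda: replace(DEFAULT_PARAMS))

    def rate_model(self, l_boundary: int = 100) -> RateModel:
        return build_rate_curves(self.denovo_eps, self.denovo_kappa,
                                 self.denovo_iota, self.params,
                                 self.context, l_boundary)

    def scaled(self, factor: float) -> "SyntheticTruth":
        """All rates multiplied by ``factor`` (same equilibrium shape,
        faster equilibration; used to keep desk-scale runs short)."""
        ctx = ContextRates(**{k: v * factor if k != "substitution_avg"
                              else v * factor
                              for k, v in self.context.__dict__.items()})
        return replace(self, context=ctx,
                       denovo_eps=self.denovo_eps * factor,
                       denovo_kappa=self.denovo_kappa * factor,
                       denovo_iota=self.denovo_iota * factor)


DEFAULT_TRUTH = SyntheticTruth()


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def generate_iid_genome(length: int, p_a: float = 0.3,
                        composition: Optional[Mapping[str, float]] = None,
                        seed: Optional[int] = None,
                        include_t: bool = False) -> str:
    """I.i.d. random sequence; A-run lengths are geometric with ratio p_a.

    By default the non-A mass is spread over C and G only (T excluded), so
    that the A/T motif equivalence class sees a single clean geometric run
    distribution; pass ``include_t=True`` or an explicit ``composition`` for
    a four-letter genome.
    """
    rng = np.random.default_rng(seed)
    if composition is None:
        rest = 1.0 - p_a
        if include_t:
            composition = {"A": p_a, "C": rest / 3, "G": rest / 3,
                           "T": rest / 3}
        else:
            composition = {"A": p_a, "C": rest / 2, "G": rest / 2, "T": 0.0}
    bases = list(composition)
    probs = np.array([composition[b] for b in bases], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    draws = rng.choice(len(bases), size=length, p=probs)
    lookup = np.array([b.encode("ascii") for b in bases], dtype="S1")
    return lookup[draws].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# trio mutation tables
# ---------------------------------------------------------------------------

def _member_runs(seq: str, member: str) -> List[Tuple[int, int]]:
    """(start, length) of maximal member-base runs, 0-based."""
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    mask = arr == member.encode("ascii")
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2].tolist(), (edges[1::2] - edges[::2]).tolist()))


def _context_positions(seq: str, member: str) -> Dict[str, np.ndarray]:
    """0-based positions of each substitution context category for one
    equivalence-class member."""
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    valid = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    ok = valid[:-2] & valid[1:-1] & valid[2:]
    xa = arr == member.encode("ascii")
    mid = xa[1:-1]
    n_a = xa[:-2].astype(np.int8) + xa[2:].astype(np.int8)
    pos = np.arange(1, arr.size - 1)
    out = {}
    for cat, is_a, k in (("create_a1", False, 0), ("lengthen", False, 1),
                         ("fusion", False, 2), ("destroy_a1", True, 0),
                         ("shorten", True, 1), ("fission", True, 2)):
        sel = ok & (mid == is_a) & (n_a == k)
        out[cat] = pos[sel]
    return out


def _drop_member_sites(positions: Dict[str, np.ndarray], seq: str,
                       members) -> None:
    """B-site categories must not mutate a site occupied by another class
    member (those events belong to that member's A-side categories)."""
    member_set = set(members)
    for cat in ("create_a1", "lengthen", "fusion"):
        pos = positions[cat]
        keep = np.array([seq[i] not in member_set for i in pos], dtype=bool) \
            if pos.size else np.zeros(0, dtype=bool)
        positions[cat] = pos[keep]


_B2A = ("create_a1", "lengthen", "fusion")   # alt becomes the member base


def generate_trio_table(contigs: Mapping[str, str], truth: SyntheticTruth,
                        n_offspring: int, seed: Optional[int] = None,
                        motif: Optional[MotifClass] = None,
                        l_boundary: int = 60,
                        ) -> List[MutationRecord]:
    """De novo mutation records placed at the truth rates.

    Substitutions: for each context category the expected count is
    rate x 2 x (context sites) x offspring, Poisson-distributed, placed
    uniformly over the eligible sites.  Indels: +/-1-unit expansions,
    contractions and non-motif insertions placed per repeat at the
    length-dependent per-target truth rates (extended beyond L=8 with the
    truth instability parameters).
    """
    rng = np.random.default_rng(seed)
    if motif is None:
        motif = motif_class("A")
    rates = truth.rate_model(l_boundary)
    records: List[MutationRecord] = []
    non_member = [b for b in "ACGT" if b not in motif.members]

    for chrom, seq in contigs.items():
        seq = seq.upper()
        for member in sorted(motif.members):
            ctx_pos = _context_positions(seq, member)
            _drop_member_sites(ctx_pos, seq, motif.members)
            for cat, positions in ctx_pos.items():
                rate = getattr(truth.context, cat)
                mean = rate * 2.0 * positions.size * n_offspring
                if mean <= 0:
                    continue
                for pos0 in rng.choice(positions, size=rng.poisson(mean)):
                    ref = seq[pos0]
                    if cat in _B2A:
                        alt = member
                    else:
                        alt = non_member[rng.integers(len(non_member))]
                    records.append(MutationRecord(
                        chrom=chrom, pos=int(pos0) + 1, ref=ref, alt=alt,
                        proband=f"p{rng.integers(n_offspring)}"))

            runs = _member_runs(seq, member)
            by_length: Dict[int, List[int]] = {}
            for start, length in runs:
                by_length.setdefault(min(length, l_boundary), []).append(start)
            for L, starts in by_length.items():
                n_l = len(starts)
                for type_, curve in (("expansion", rates.expansion),
                                     ("contraction", rates.contraction),
                                     ("non_motif_insertion", rates.insertion)):
                    if type_ == "non_motif_insertion" and L < 2:
                        continue
                    mean = curve[L] * L * n_l * 2.0 * n_offspring
                    if mean <= 0:
                        continue
                    for start in rng.choice(starts, size=rng.poisson(mean)):
                        rec = _make_indel(seq, chrom, int(start), L, type_,
                                          member, non_member, rng,
                                          n_offspring)
                        if rec is not None:
                            records.append(rec)
    rng.shuffle(records)  # type: ignore[arg-type]
    return records


def _make_indel(seq: str, chrom: str, start: int, L: int, type_: str,
                member: str, non_member: Sequence[str],
                rng: np.random.Generator,
                n_offspring: int) -> Optional[MutationRecord]:
    proband = f"p{rng.integers(n_offspring)}"
    if type_ == "expansion":
        # insert one member unit after the first run base
        anchor = start
        ref = seq[anchor]
        return MutationRecord(chrom, anchor + 1, ref, ref + member,
                              proband=proband)
    if type_ == "contraction":
        if start == 0:
            return None                     # needs an anchor base
        anchor = start - 1
        return MutationRecord(chrom, anchor + 1, seq[anchor] + seq[start],
                              seq[anchor], proband=proband)
    # non-motif insertion strictly inside the run
    point = int(rng.integers(start + 1, start + L))
    ref = seq[point - 1]
    ins = non_member[rng.integers(len(non_member))]
    return MutationRecord(chrom, point, ref, ref + ins, proband=proband)


# ---------------------------------------------------------------------------
# pseudo-empirical distributions
# ---------------------------------------------------------------------------

def generate_pseudo_empirical(truth: SyntheticTruth,
                              schedule: Sequence[ScheduleStage] = SHORT_SCHEDULE,
                              genome_repeat_total: float = 1e6,
                              l_boundary: int = 60,
                              seed: Optional[int] = None,
                              noise: bool = True) -> LengthDistribution:
    """Kernel late-time raw counts at the truth parameters.

    The final distribution is rescaled to ``genome_repeat_total`` repeats
    and, unless ``noise=False``, Poisson-sampled per bin -- a stand-in for a
    genome-wide empirical histogram with sampling noise.
    """
    rates = truth.rate_model(l_boundary)
    p_a = truth.context.lengthen / (truth.context.lengthen
                                    + truth.context.shorten)
    state = iid_state(1.0, p_a, l_boundary)
    scale = genome_repeat_total / state.total_repeats()
    state.counts_a *= scale
    state.counts_b *= scale
    result = evolve(state, rates, schedule)
    total = result.state.total_repeats()
    counts = result.state.counts_a * (genome_repeat_total / total)
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(counts).astype(float)
    return LengthDistribution(
        {L: float(c) for L, c in enumerate(counts) if L >= 1 and c > 0})


# ---------------------------------------------------------------------------
# popSTR-style tables
# ---------------------------------------------------------------------------

def generate_popstr_table(truth: SyntheticTruth, n_loci: int = 500,
                          n_trios: int = 1000,
                          length_range: Tuple[int, int] = (11, 25),
                          seed: Optional[int] = None, l_boundary: int = 60,
                          ) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, str]]:
    """Locus table, event table and an embedding reference contig.

    Each locus is a pure A run of its reference length embedded in random
    non-A flank (so the longest contiguous run equals the reported reference
    length).  Events are +/-1-unit insertions/deletions drawn per allele
    transmission at the truth per-repeat rates; insertions conflate
    expansions and non-motif insertions, as the popSTR caller does.
    """
    rng = np.random.default_rng(seed)
    rates = truth.rate_model(l_boundary)
    lo, hi = length_range
    weights = 0.75 ** np.arange(hi - lo + 1)     # more short loci, like a genome
    weights /= weights.sum()
    ref_lengths = rng.choice(np.arange(lo, hi + 1), size=n_loci, p=weights)

    flank = 20
    parts: List[str] = []
    loci_rows = []
    cursor = 0
    non_a = np.array([b"C", b"G"], dtype="S1")
    for i, L in enumerate(ref_lengths):
        fl = non_a[rng.integers(2, size=flank)].tobytes().decode()
        parts.append(fl)
        cursor += flank
        start = cursor
        parts.append("A" * int(L))
        cursor += int(L)
        loci_rows.append({"locus_id": i, "chrom": "synth", "start": start,
                          "end": cursor, "motif": "A", "ref_length": int(L),
                          "passing_trios": int(rng.binomial(n_trios, 0.9))})
    parts.append(non_a[rng.integers(2, size=flank)].tobytes().decode())
    contig = {"synth": "".join(parts)}
    loci = pd.DataFrame(loci_rows)

    event_rows = []
    for _, row in loci.iterrows():
        L = int(row["ref_length"])
        transmissions = 2 * int(row["passing_trios"])
        ins_rate = (rates.expansion[L] + rates.insertion[L]) * L
        del_rate = rates.contraction[L] * L
        for n_ev, delta in ((rng.poisson(ins_rate * transmissions), +1),
                            (rng.poisson(del_rate * transmissions), -1)):
            for _ in range(n_ev):
                event_rows.append({
                    "locus_id": int(row["locus_id"]),
                    "proband_length": L + delta,
                    "parental_length": L,
                    "phase": None})
    events = pd.DataFrame(event_rows,
                          columns=["locus_id", "proband_length",
                                   "parental_length", "phase"])
    return loci, events, contig
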