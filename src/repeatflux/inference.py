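"""Grid-search inference of repeat-instability parameters.

The three degrees of freedom (m, tau_eps, tau_kappa) extend the reliable
L<=8 de novo rate estimates to all modeled lengths.  Each grid combination
is evolved to late time with the mutation kernel and scored against an
empirical (or pseudo-empirical) raw length distribution with a
least-squares metric in log space:

    metric = sum_L ( ln Norm[P(L)+1] - ln Norm[P_emp(L)+1] )^2

where a pseudocount of one is added to every bin of both raw count vectors
before normalizing.  Log space upweights the sparsely populated tail, which
is where instability rates leave their signature; a likelihood would be
dominated by the substitution-driven first bins instead.

Parameter combinations whose metric is within the spread produced by
Poisson-resampling the underlying mutation counts are reported as
statistically consistent with the best fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .mutation_kernel import (DEFAULT_SCHEDULE, ContextRates, EvolveResult,
                              InstabilityParams, JointState, RateModel,
                              ScheduleStage, build_rate_curves, evolve,
                              flux_decomposition, iid_state)
from .rate_estimation import ContextRateEstimate, LengthRateTable
from .repeat_catalog import LengthDistribution

#: the full inference grid: m in 2^0..2^5, tau in [0, 5] step 0.1
FULL_GRID_M = (1, 2, 4, 8, 16, 32)
FULL_GRID_TAU = tuple(np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 1))


@dataclass
class MetricResult:
    params: InstabilityParams
    metric: float
    equilibrated: bool
    boundary_flag: bool


@dataclass
class GridResult:
    table: pd.DataFrame
    best: InstabilityParams
    best_metric: float

    def consistent_set(self, threshold: float) -> pd.DataFrame:
        return self.table[self.table["metric"] <= threshold]


@dataclass
class ConsistencyResult:
    threshold: float
    metrics: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    consistent: pd.DataFrame


# ---------------------------------------------------------------------------
# metric
# ---------------------------------------------------------------------------

def _as_vector(dist: Union[LengthDistribution, np.ndarray],
               l_boundary: int) -> np.ndarray:
    if isinstance(dist, LengthDistribution):
        return dist.to_array(l_boundary)[1:]
    arr = np.asarray(dist, dtype=float)
    if arr.size == l_boundary + 1:      # index-0-padded vector
        arr = arr[1:]
    if arr.size < l_boundary:
        arr = np.pad(arr, (0, l_boundary - arr.size))
    return arr[:l_boundary]


def fit_metric(model_counts: Union[LengthDistribution, np.ndarray],
               empirical_counts: Union[LengthDistribution, np.ndarray],
               l_boundary: int) -> float:
    """Least-squares log-space distance between two raw count vectors.

    Bins beyond the longest observed repeat are zero-filled up to
    ``l_boundary`` before the pseudocount, so both vectors cover the same
    support; the pseudocount guarantees positivity everywhere.
    """
    a = _as_vector(model_counts, l_boundary) + 1.0
    b = _as_vector(empirical_counts, l_boundary) + 1.0
    qa = a / a.sum()
    qb = b / b.sum()
    return float(np.sum((np.log(qa) - np.log(qb)) ** 2))


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def substitution_p_a(context: ContextRates) -> float:
    """Equilibrium A fraction implied by the boundary substitution rates."""
    mu, nu = context.lengthen, context.shorten
    return mu / (mu + nu)


def initial_state_for(empirical_total: float, context: ContextRates,
                      l_boundary: int) -> JointState:
    """Substitution-equilibrium initial state scaled so the A-repeat total
    matches the empirical genome (the i.i.d. run-count expectation)."""
    p_a = substitution_p_a(context)
    probe = iid_state(1.0, p_a, l_boundary)
    scale = empirical_total / probe.total_repeats()
    probe.counts_a *= scale
    probe.counts_b *= scale
    return probe


def evaluate_params(params: InstabilityParams,
                    empirical: Union[LengthDistribution, np.ndarray],
                    denovo_eps: Sequence[float],
                    denovo_kappa: Sequence[float],
                    denovo_iota: Sequence[float],
                    context: ContextRates,
                    schedule: Sequence[ScheduleStage] = DEFAULT_SCHEDULE,
                    l_boundary: int = 100,
                    initial_state: Optional[JointState] = None,
                    equilibration_tol: float = 1e-3,
                    ) -> Tuple[MetricResult, EvolveResult]:
    """Build curves, evolve to late time, and score one grid point."""
    rates = build_rate_curves(denovo_eps, denovo_kappa, denovo_iota,
                              params, context, l_boundary)
    if initial_state is None:
        emp_total = float(np.sum(_as_vector(empirical, l_boundary)))
        initial_state = initial_state_for(emp_total, context, l_boundary)
    result = evolve(initial_state, rates, schedule)
    # compare per-genome counts: the pseudocount makes the metric sensitive
    # to overall scale through near-empty bins, so the model's raw counts
    # are put on the empirical genome's scale first
    emp_total = float(np.sum(_as_vector(empirical, l_boundary)))
    model_total = result.state.total_repeats()
    model_counts = result.state.counts_a * (
        emp_total / model_total if model_total > 0 else 1.0)
    metric = fit_metric(model_counts, empirical, l_boundary)
    flux = flux_decomposition(result.state, rates, normalized=False)
    gross = flux.gross()
    net = flux.net()
    counts = result.state.counts_a
    populated = counts >= 1.0
    # remove the secular self-similar growth component: with indels the
    # genome grows slowly, so a converged shape has net flux ~ g N(L)
    g = net[1:].sum() / counts[1:].sum() if counts[1:].sum() > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(gross > 0, np.abs(net - g * counts) / gross, 0.0)
    equil = bool(np.all(rel[populated] < equilibration_tol)) \
        and not result.boundary_flag
    return (MetricResult(params, metric, equil, result.boundary_flag),
            result)


def grid_search(empirical: Union[LengthDistribution, np.ndarray],
                denovo_eps: Sequence[float],
                denovo_kappa: Sequence[float],
                denovo_iota: Sequence[float],
                context: ContextRates,
                m_values: Sequence[float] = FULL_GRID_M,
                tau_values: Sequence[float] = FULL_GRID_TAU,
                schedule: Sequence[ScheduleStage] = DEFAULT_SCHEDULE,
                l_boundary: int = 100,
                initial_state: Optional[JointState] = None,
                tau_kappa_values: Optional[Sequence[float]] = None,
                ) -> GridResult:
    """Score every (m, tau_eps, tau_kappa) combination.

    Non-equilibrated (boundary-flagged) combinations are scored on their
    final state and flagged rather than excluded, so they can be masked
    downstream.  Evaluation of each combination is a pure function of its
    inputs; the iteration order does not affect results.
    """
    if initial_state is None:
        emp_total = float(np.sum(_as_vector(empirical, l_boundary)))
        initial_state = initial_state_for(emp_total, context, l_boundary)
    if tau_kappa_values is None:
        tau_kappa_values = tau_values
    rows: List[Dict] = []
    for m, te, tk in product(m_values, tau_values, tau_kappa_values):
        params = InstabilityParams(m=m, tau_eps=te, tau_kappa=tk)
        res, _ = evaluate_params(
            params, empirical, denovo_eps, denovo_kappa, denovo_iota,
            context, schedule, l_boundary, initial_state.copy())
        rows.append({"m": m, "tau_eps": te, "tau_kappa": tk,
                     "metric": res.metric, "equilibrated": res.equilibrated,
                     "boundary_flag": res.boundary_flag})
    table = pd.DataFrame(rows)
    idx = int(table["metric"].idxmin())
    best = InstabilityParams(m=float(table.loc[idx, "m"]),
                             tau_eps=float(table.loc[idx, "tau_eps"]),
                             tau_kappa=float(table.loc[idx, "tau_kappa"]))
    return GridResult(table=table, best=best,
                      best_metric=float(table.loc[idx, "metric"]))


# ---------------------------------------------------------------------------
# consistency via Poisson resampling of the input counts
# ---------------------------------------------------------------------------

def consistency_interval(grid: GridResult,
                         empirical: Union[LengthDistribution, np.ndarray],
                         context_estimate: ContextRateEstimate,
                         denovo_table: LengthRateTable,
                         schedule: Sequence[ScheduleStage] = DEFAULT_SCHEDULE,
                         l_boundary: int = 100,
                         n_resamples: int = 200,
                         drop_top: int = 10,
                         envelope_drop: int = 5,
                         seed: Optional[int] = None,
                         initial_state: Optional[JointState] = None,
                         ) -> ConsistencyResult:
    """One-sided 95% consistency threshold around the best-fit metric.

    The raw substitution and per-length indel counts are Poisson-resampled
    ``n_resamples`` times; each resample yields rate curves, a late-time
    distribution at the best-fit parameters, and a metric value.  The
    threshold is the largest metric after discarding the top ``drop_top``
    values; grid combinations at or below it are consistent with the best
    fit.  Per-bin 95% envelopes of the resampled distributions drop the top
    and bottom ``envelope_drop`` values.
    """
    rng = np.random.default_rng(seed)
    emp_vec = _as_vector(empirical, l_boundary)
    if initial_state is None:
        initial_state = initial_state_for(float(emp_vec.sum()),
                                          context_estimate.rates, l_boundary)
    lengths = denovo_table.lengths[:8]
    metrics = np.empty(n_resamples)
    dists = np.empty((n_resamples, l_boundary))
    for i in range(n_resamples):
        ctx = context_estimate.resample(rng)
        curves = {}
        for key, type_ in (("eps", "expansion"), ("kappa", "contraction"),
                           ("iota", "non_motif_insertion")):
            ev = rng.poisson(denovo_table.events[type_][:8])
            denom = denovo_table.targets[:8] * lengths
            curves[key] = np.where(denom > 0, ev / denom, 0.0)
        rates = build_rate_curves(curves["eps"], curves["kappa"],
                                  curves["iota"], grid.best, ctx, l_boundary)
        result = evolve(initial_state.copy(), rates, schedule)
        metrics[i] = fit_metric(result.state.counts_a, emp_vec, l_boundary)
        total = result.state.total_repeats()
        dists[i] = (result.state.counts_a[1:] / total) if total > 0 else 0.0
    order = np.sort(metrics)
    threshold = float(order[n_resamples - drop_top - 1])
    dists.sort(axis=0)
    env_lo = dists[envelope_drop]
    env_hi = dists[n_resamples - 1 - envelope_drop]
    return ConsistencyResult(threshold=threshold, metrics=metrics,
                             envelope_low=env_lo, envelope_high=env_hi,
                             consistent=grid.consistent_set(threshold))
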