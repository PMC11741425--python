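"""Analytic and numerical characterization of repeat-length steady states.

Short repeats (L below ~10) equilibrate under two-way substitution alone to
a geometric distribution with ratio mu/(mu+nu), where mu is the B->A
(lengthening) and nu the A->B (shortening) rate.  Long repeats obey, in the
continuum limit, a steady-state equation combining length-dependent
diffusion and drift from expansion/contraction with non-local loss and gain
from fission; fusion is neglected (subdominant for stable parameters).

Three nested approximations are solved numerically as boundary-value
problems in the variable V(L) = (eps_L + kappa_L) L P_L:

* local only (diffusion + drift)            -- valid for strongly
  contraction-biased rates (delta_tau >> 1);
* local + fission out                       -- valid for delta_tau >~ 1;
* net-flux form including fission in        -- valid for all delta_tau > 0
  (third order; obtained by differentiating the integro-differential
  steady-state equation, with the vanishing-net-flux constraint imposed
  through a third boundary value).

Solutions are constrained at the lengths of theoretical interest
L1 = round(L*) (where contraction overtakes expansion) and L2 = L_max
(where less than one repeat is expected genome-wide), plus L3 = L_max - 1
for the third-order equation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_bvp

from .mutation_kernel import (RATE_CAP, InstabilityParams, JointState,
                              RateModel)

#: the nested approximations, tightest first
EQUATIONS = ("local", "local_fission_out", "net_flux")

REGIMES = ("strongly_contraction_biased", "intermediate",
           "weakly_contraction_biased", "unstable")


@dataclass
class RegimeLabel:
    label: str
    delta_tau: float


@dataclass
class SteadyStateSolution:
    lengths: np.ndarray
    values: np.ndarray              # P(L), same normalization as reference
    equation: str
    l_star: float
    l_max: float
    constraints: Dict[float, float]
    negative: bool = False


# ---------------------------------------------------------------------------
# short-length regime
# ---------------------------------------------------------------------------

def geometric_equilibrium(mu: float, nu: float, lengths: Sequence[int],
                          reference: Optional[np.ndarray] = None,
                          ) -> np.ndarray:
    """Geometric substitution-only equilibrium P(L) ~ (mu/(mu+nu))**L.

    ``mu`` is the lengthening (B->A) and ``nu`` the shortening (A->B)
    substitution rate.  When a reference distribution (vector indexed by
    length, index 0 unused) is given, the normalization is fixed by matching
    its L=1 mass; otherwise the returned values sum to one over ``lengths``.
    """
    if mu <= 0 or nu <= 0:
        raise ValueError("mu and nu must be positive")
    lengths = np.asarray(lengths, dtype=float)
    p = mu / (mu + nu)
    values = p ** lengths
    if reference is not None:
        values = values * (reference[1] / p)
    else:
        values = values / values.sum()
    return values


# ---------------------------------------------------------------------------
# characteristic lengths
# ---------------------------------------------------------------------------

def compute_L_star(rates: RateModel) -> float:
    """Length where the contraction rate curve crosses the expansion curve.

    With shared multiplier m the crossing is
    L* = 9 (eps_8/kappa_8)**(1/delta_tau); it depends on the exponents only
    through delta_tau, so it is constant along lines of constant delta_tau.
    Clipped to [9, L_boundary].
    """
    if rates.params is None:
        raise ValueError("rate model carries no instability parameters")
    dt = rates.params.delta_tau
    if dt <= 0:
        raise ValueError("no expansion/contraction crossing for "
                         "delta_tau <= 0")
    eps8, kap8 = rates.expansion[8], rates.contraction[8]
    if eps8 <= 0 or kap8 <= 0:
        raise ValueError("need positive L=8 expansion and contraction rates")
    l_star = 9.0 * (eps8 / kap8) ** (1.0 / dt)
    return float(np.clip(l_star, 9.0, rates.l_boundary))


def compute_L_max(freqs: np.ndarray, total: float) -> int:
    """Smallest length where fewer than one repeat is expected genome-wide.

    ``freqs`` is a normalized distribution vector indexed by length (index 0
    unused); ``total`` the number of repeats in the genome.
    """
    if total <= 0:
        return 1
    expected = np.asarray(freqs, dtype=float) * total
    for L in range(1, expected.size):
        if expected[L] < 1.0:
            return L
    return expected.size - 1


def state_L_max(state: JointState) -> int:
    total = state.total_repeats()
    if total <= 0:
        return 1
    return compute_L_max(state.counts_a / total, total)


# ---------------------------------------------------------------------------
# continuum rate curves
# ---------------------------------------------------------------------------

def _continuum_curves(rates: RateModel) -> Dict[str, Callable]:
    """Smooth per-target rate functions for the continuum equations.

    Above L=9 the parameterized power laws are used (with the 0.1 cap);
    the continuum domain starts at L=10, so the discrete L<=8 values never
    enter.
    """
    if rates.params is None:
        raise ValueError("rate model carries no instability parameters")
    p = rates.params
    eps9 = p.m * rates.expansion[8]
    kap9 = p.m * rates.contraction[8]
    iot9 = p.m * rates.insertion[8]

    def eps(L):
        return np.minimum(eps9 * (np.asarray(L) / 9.0) ** p.tau_eps, RATE_CAP)

    def kap(L):
        return np.minimum(kap9 * (np.asarray(L) / 9.0) ** p.tau_kappa, RATE_CAP)

    def iot(L):
        return np.minimum(iot9 * (np.asarray(L) / 9.0) ** p.tau_iota, RATE_CAP)

    return {"eps": eps, "kappa": kap, "iota": iot}


def _coefficients(rates: RateModel) -> Dict[str, Callable]:
    """Coefficient functions of the V-form equations and their numeric
    derivatives (central differences; the curves are smooth power laws)."""
    cur = _continuum_curves(rates)
    nu = rates.context.fission        # interior A->B substitution rate

    def f(L):
        return (cur["eps"](L) + cur["kappa"](L)) * L

    def a(L):
        e, k = cur["eps"](L), cur["kappa"](L)
        return (e - k) / (e + k)

    def h_over_f(L):
        return (nu + cur["iota"](L)) * L / f(L)

    def h2_over_f(L):
        return (nu + cur["iota"](L)) / f(L)

    d = 1e-4

    def da(L):
        return (a(L + d) - a(L - d)) / (2 * d)

    def d2a(L):
        return (a(L + d) - 2 * a(L) + a(L - d)) / d ** 2

    def dhf(L):
        return (h_over_f(L + d) - h_over_f(L - d)) / (2 * d)

    return {"f": f, "a": a, "da": da, "d2a": d2a,
            "hf": h_over_f, "dhf": dhf, "h2f": h2_over_f}


# ---------------------------------------------------------------------------
# boundary-value solvers
# ---------------------------------------------------------------------------

def _guess_from_reference(reference: np.ndarray, mesh: np.ndarray,
                          f: Callable) -> np.ndarray:
    """Log-linear interpolation of the kernel distribution as initial guess."""
    L = np.arange(reference.size, dtype=float)
    pos = reference > 0
    pos[0] = False
    logp = np.interp(mesh, L[pos], np.log(reference[pos]))
    return np.exp(logp) * f(mesh)


def _solve_second_order(coef: Dict[str, Callable], include_fission_out: bool,
                        l1: float, v1: float, l2: float, v2: float,
                        guess: Optional[np.ndarray], mesh: np.ndarray,
                        ) -> Tuple[np.ndarray, np.ndarray]:
    a, da, hf = coef["a"], coef["da"], coef["hf"]

    def fun(x, y):
        c0 = da(x) + (hf(x) if include_fission_out else 0.0)
        return np.vstack([y[1], 2.0 * (a(x) * y[1] + c0 * y[0])])

    def bc(ya, yb):
        return np.array([ya[0] - v1, yb[0] - v2])

    y0 = np.zeros((2, mesh.size))
    if guess is not None:
        y0[0] = guess
        y0[1] = np.gradient(guess, mesh)
    else:
        y0[0] = np.linspace(v1, v2, mesh.size)
    sol = solve_bvp(fun, bc, mesh, y0, max_nodes=50_000, tol=1e-8)
    if not sol.success:
        raise RuntimeError(f"BVP solver failed: {sol.message}")
    return mesh, sol.sol(mesh)[0]


def _solve_third_order(coef: Dict[str, Callable],
                       l1: float, v1: float, l2: float, v2: float,
                       l3: float, v3: float,
                       guess_fn: Callable[[np.ndarray], np.ndarray],
                       n_mesh: int) -> Tuple[np.ndarray, np.ndarray]:
    """Two-region collocation for the third-order net-flux equation with the
    interior constraint at L3 = L_max - 1."""
    a, da, d2a = coef["a"], coef["da"], coef["d2a"]
    hf, dhf, h2f = coef["hf"], coef["dhf"], coef["h2f"]

    def rhs(x, y):
        # 1/2 V''' = (aV)'' + ((h/f)V)' + 2((nu+iota)/f)V
        v, dv, d2v = y
        d3v = 2.0 * (a(x) * d2v + (2.0 * da(x) + hf(x)) * dv
                     + (d2a(x) + dhf(x) + 2.0 * h2f(x)) * v)
        return np.vstack([dv, d2v, d3v])

    w1, w2 = l3 - l1, l2 - l3

    def fun(s, y):
        x1 = l1 + w1 * s
        x2 = l3 + w2 * s
        r1 = rhs(x1, y[:3]) * w1
        r2 = rhs(x2, y[3:]) * w2
        return np.vstack([r1, r2])

    def bc(ya, yb):
        # state components are x-derivatives, so continuity is direct
        return np.array([
            ya[0] - v1,                  # V(L1)
            yb[0] - v3,                  # region-1 end hits V(L3)
            yb[0] - ya[3],               # continuity V
            yb[1] - ya[4],               # continuity V'
            yb[2] - ya[5],               # continuity V''
            yb[3] - v2,                  # V(L2)
        ])

    s = np.linspace(0.0, 1.0, n_mesh)
    x1g = l1 + w1 * s
    x2g = l3 + w2 * s
    g1 = guess_fn(x1g)
    g2 = guess_fn(x2g)
    y0 = np.vstack([
        g1, np.gradient(g1, x1g), np.gradient(np.gradient(g1, x1g), x1g),
        g2, np.gradient(g2, x2g), np.gradient(np.gradient(g2, x2g), x2g),
    ])
    sol = solve_bvp(fun, bc, s, y0, max_nodes=50_000, tol=1e-8)
    if not sol.success:
        raise RuntimeError(f"BVP solver failed: {sol.message}")
    mesh = np.concatenate([l1 + w1 * s[:-1], l3 + w2 * s])
    vals = np.concatenate([sol.sol(s)[0][:-1], sol.sol(s)[3]])
    return mesh, vals


def solve_steady_ode(equation: str, rates: RateModel,
                     reference: JointState,
                     l_star: Optional[float] = None,
                     l_max: Optional[float] = None,
                     mesh_step: float = 0.25) -> SteadyStateSolution:
    """Numerical steady-state solution constrained by a kernel reference.

    ``reference`` supplies the constraint values (its normalized
    distribution at L1 = round(L*), L2 = L_max and, for the net-flux
    equation, L3 = L_max - 1) and the initial guess.  The returned values
    share the reference normalization, so they are directly comparable
    per bin.
    """
    if equation not in EQUATIONS:
        raise ValueError(f"unknown equation {equation!r}")
    total = reference.total_repeats()
    freqs = reference.counts_a / total
    if l_star is None:
        l_star = compute_L_star(rates)
    if l_max is None:
        l_max = compute_L_max(freqs, total)
    l1 = float(max(10, round(l_star)))
    l2 = float(l_max)
    if l2 <= l1 + 2:
        raise ValueError(f"degenerate domain: L1={l1}, L_max={l2}")
    coef = _coefficients(rates)
    mesh = np.arange(l1, l2 + mesh_step / 2, mesh_step)
    mesh[-1] = l2

    def log_ref(x):
        return _guess_from_reference(freqs, np.asarray(x, dtype=float),
                                     coef["f"])

    v1 = float(freqs[int(l1)] * coef["f"](l1))
    v2 = float(freqs[int(l2)] * coef["f"](l2))
    constraints = {l1: float(freqs[int(l1)]), l2: float(freqs[int(l2)])}

    if equation in ("local", "local_fission_out"):
        xs, vvals = _solve_second_order(
            coef, equation == "local_fission_out",
            l1, v1, l2, v2, log_ref(mesh), mesh)
    else:
        l3 = l2 - 1.0
        v3 = float(freqs[int(l3)] * coef["f"](l3))
        constraints[l3] = float(freqs[int(l3)])
        xs, vvals = _solve_third_order(coef, l1, v1, l2, v2, l3, v3,
                                       log_ref, mesh.size)
    pvals = vvals / coef["f"](xs)
    return SteadyStateSolution(lengths=xs, values=pvals, equation=equation,
                               l_star=float(l_star), l_max=float(l_max),
                               constraints=constraints,
                               negative=bool(np.any(pvals < 0)))


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------

def classify_regime(params: InstabilityParams,
                    thresholds: Tuple[float, float] = (0.5, 1.0),
                    ) -> RegimeLabel:
    """Dynamical regime by delta_tau = tau_kappa - tau_eps.

    delta_tau <= 0 cannot equilibrate (the tau_kappa = tau_eps edge case is
    asymptotically expansion-biased given the L=8 expansion bias).  The
    positive thresholds separating the three stable regimes are heuristics
    reflecting which nested approximation suffices.
    """
    dt = params.delta_tau
    lo, hi = thresholds
    if dt <= 0:
        label = "unstable"
    elif dt <= lo:
        label = "weakly_contraction_biased"
    elif dt <= hi:
        label = "intermediate"
    else:
        label = "strongly_contraction_biased"
    return RegimeLabel(label=label, delta_tau=dt)
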