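# Methods

## The model

The genome is abstracted to a binary alphabet: `A` is the focal repeat unit
(one base for mononucleotide motifs) and `B` is any other unit.  The state
of the system is the pair of count vectors `NA(L)`, `NB(l)` for
`L, l = 1..L_boundary`: the number of maximal runs of `L` consecutive
complete motif copies, and the number of non-motif strings of length `l`
separating them.  Repeats are *contiguous* by definition: an interrupting
unit ends one repeat and starts another, so every mutation has a well
defined effect on run lengths.

Each generation, expected counts move between bins under ten processes.
Substitutions (conserving total A+B length):

| process | context | target size | effect |
|---|---|---|---|
| lengthen | ABB>AAB | 2 per extendable junction | `L -> L+1`, donor B string `l -> l-1` |
| shorten | AAB>ABB | 2 per repeat (L >= 2) | `L -> L-1`, a B string `l -> l+1` |
| fission | AAA>ABA | `L-2` per repeat | one count leaves `L`; two fragments spread evenly over `1..L-2`; one B1 created |
| fusion | ABA>AAA | `NB(1)` | two repeats `j`, `k` join into `j+k+1`; one B1 destroyed |
| create A1 | BBB>BAB | `l-2` per B string | B fission with a new A1 between the fragments |
| destroy A1 | BAB>BBB | `NA(1)` | two B strings fuse into `j+k+1` |

Indels (not length-conserving): expansion and contraction act strictly
locally with per-repeat target `L` (the event is indistinguishable within
the run); a non-motif insertion splits the run, spreading two fragments
evenly over `1..L-1` and creating a B1; B-string insertions/deletions are
local per-unit moves, and deletion of a lone B1 fuses the flanking repeats
into `j+k`.  A reflective boundary maps any transition above `L_boundary`
into the top bin; runaway parameterizations therefore pile counts there,
which is also how they are detected.

Two allocation rules are not dictated by the counting bookkeeping and were
fixed as follows:

* **Fusion pairing.** The two partners of a fusion are drawn independently
  from the normalized repeat-length distribution (occupancy-weighted
  pairs).  This is the unique parameter-free rule consistent with
  well-mixed adjacency; a literal per-event "subtract two counts evenly
  from short bins" reading is not well defined as a total update without an
  extra choice of the product-length distribution, so no such alternative
  mode is offered.
* **Lengthening availability.** A lengthening substitution requires the
  adjacent B string to be extendable (length >= 2; a length-1 B is the
  fusion context), and each such B string carries exactly two lengthen
  contexts.  The total event count is therefore
  `2 mu_len x sum_{l>=2} NB(l)`, distributed over repeat bins in proportion
  to occupancy.  With this factor the i.i.d. run-count state is the *exact*
  fixed point of the substitution-only kernel (verified to machine
  precision in the tests); a fixed "2 per repeat" target without the
  availability factor leaves a uniform residual drift of `2 alpha p` per
  generation and a non-geometric fixed point.

The B-side mirror of a shortening event grows a B string of any length
`l >= 1` (the `l = 1` recipient case is an ordinary extension, not a
separate channel), allocated in proportion to `NB(l)`.

### Deterministic and stochastic modes

The deterministic mode applies every process's expectation simultaneously
from the pre-step state (a Jacobi update); counts are real-valued expected
values and are never rounded.  The stochastic mode replaces the summed
per-bin influx and outflux expectations by independent Poisson draws
(sums of independent Poissons are Poisson, so sampling the totals is
distributionally identical to per-process draws), flooring at zero.  The
deterministic step equals the stochastic mean wherever the zero floor is
inactive; in bins holding fractional expected counts the floor biases the
mean upward, which is why the consistency test uses a uniformly
well-populated state.

### Time rescaling and the progressive schedule

All rates can be multiplied by `10^r` so one iteration stands for `10^r`
generations.  The default schedule runs r = 5, 4, 3, 2 for 1e4 iterations
each, r = 1 for 1e5 and r = 0 for 1e6 (T >= 1e9 generations in total); a
count above 1,000 in the boundary bin ends a stage early.  The trigger
compares against `max(1000, 2 x stage-start boundary count)` so that
initial conditions that already populate the boundary (e.g. a uniform
start) do not abort stages; the final boundary flag reports accumulation
relative to the run's start.

Validity of a rescaled stage requires the summed per-repeat rate times
`10^r` to stay below 0.1 in populated bins (`check_linear_bound`).  Two
further numerical facts matter:

* Because every flux is linear in the rates, the *fixed point* of the
  unclipped step map is independent of `r`; a stage is quantitatively
  trustworthy as a relaxation scheme whenever the scaled per-repeat rate is
  below ~1 (no overshoot), even above the 0.1 realism bound.
* When a stage pushes a bin's aggregated outflow past its occupancy,
  outflows are proportionally clipped so counts empty but never go
  negative (`evolve` always clips; a direct `step_deterministic` call
  raises instead unless asked to clip).  Clipped stages distort the state;
  later, slower stages relax the distortion away.

Per-length per-target rates are capped at 0.1, so a power-law curve that
reaches the cap saturates to a constant.

With indels the genome grows (or shrinks) secularly, so a fully converged
*shape* has per-bin net flux exactly `g NA(L)` where
`g = sum(net)/sum(NA)` is the count growth rate.  Equilibration is
therefore measured on the growth-corrected residual `|net - g NA|/gross`.

## Rates and their conventions

Context substitution rates are per context site per diploid offspring
generation and are independent of repeat length.  The defaults are the
trio-based estimates for A/T mononucleotides: lengthen 4.77e-9, shorten
8.08e-9, fusion 2.87e-9, fission 4.54e-9, A1 creation 3.97e-9, A1 loss
6.45e-9; B-string insertion 1.44e-10, deletion 4.56e-12, B1 deletion
2.89e-10; genome-average substitution rate 1.2e-8.

Indel rates are tabulated per repeat (events / 2 x repeats of that length x
offspring); dividing by the target size `L` gives the per-target (per-unit)
rates `eps_L`, `kappa_L`, `iota_L` the kernel consumes.  Only +/-1-unit
events enter the rate columns (the kernel models single-unit changes); the
full signed-unit spectrum is tabulated alongside.

Trio-based estimates are reliable to `L = 8`; beyond that the three free
parameters extend them: `rate(9) = m x rate(8)` and
`rate(L) = rate(9) (L/9)^tau`, with separate exponents `tau_eps` and
`tau_kappa` for expansion and contraction and the non-motif-insertion
exponent tied to `tau_eps`.  `delta_tau = tau_kappa - tau_eps` controls
stability: only `delta_tau > 0` (asymptotic contraction bias) admits a
steady state; the `delta_tau = 0` edge case is asymptotically
expansion-biased because of the expansion bias at `L = 8`.

### Default de novo curves

The per-target L = 1..8 indel curves are not published as numbers, so the
package ships defaults calibrated once against four published constraints:
(i) the per-target instability rates overtake the per-site substitution
rate (1.2e-8) near `L = 6`, inside the stated 5-10 nt onset window;
(ii) `eps_8/kappa_8 = 1.25` (initial expansion bias), which places the
expansion/contraction crossing `L*` near 10 under strong contraction bias
and near 19 at `delta_tau = 0.3`, matching the reported ranges;
(iii) `iota_8 = 5e-10`, close to the background insertion scale, so that
substitution remains the dominant fission channel up to `L ~ 20`;
(iv) the resulting regime structure (which nested steady-state equation
suffices at `delta_tau` = 3, 1, 0.3) reproduces the published one.
Defaults: eps = [2.4e-11 ... 1.2e-7], kappa = 0.8 x eps,
iota = [1e-11 ... 5e-10]; best-fit-like parameters m = 2, tau_eps = 1.7,
tau_kappa = 2.0.

## Inference

The fit metric is a least-squares distance in natural-log space between the
pseudocounted, normalized raw count vectors, summed over `1..L_boundary`;
empty bins are zero-filled before the pseudocount.  Log space upweights the
sparsely populated tail, which carries the instability signal; a likelihood
would be dominated by the substitution-driven first bins.  Because the
pseudocount makes the metric scale-sensitive through near-empty bins, the
model's raw counts are rescaled to the empirical genome's repeat total
before scoring (a per-genome-counts comparison).

The grid search evaluates `m` in powers of two and the two exponents on a
uniform grid; non-equilibrated (boundary-flagged) combinations are scored
on their final state and flagged, not excluded.  The late-time tail
amplitude is exponentially sensitive to `delta_tau`, so the metric surface
forms ridges of near-constant `delta_tau`, collapsing to a single
dimension as `m` grows; recovery of generating parameters is exact when
they are representable on the grid and lands on the compensating ridge
one-to-two steps away when they are not.  Grid axes may therefore be
offset independently (`tau_kappa_values`).

Statistical consistency: the raw substitution and per-length indel counts
are Poisson-resampled 200 times; each resample yields rate curves, a
late-time distribution at the best-fit parameters, and a metric value.
The one-sided 95% threshold is the largest metric after dropping the top
10 values; grid combinations at or below it are consistent with the best
fit.  Per-bin 95% envelopes drop the top and bottom 5 of the 200
distributions.

## Steady-state analytics

Short repeats equilibrate under two-way substitution alone to the
geometric distribution `P(L) ~ (mu/(mu+nu))^L` with `mu` the B->A
(lengthening) and `nu` the A->B rate; the normalization is fixed on the
L = 1 mass when comparing to a reference.  With the package's
heterogeneous six-category defaults (which do not reduce to a single
two-way process), the kernel's short regime deviates from this one-ratio
geometric form by tens of percent by `L = 8`; the closed form is exact
when the six rates derive from one two-way process
(`ContextRates.from_two_way`).

Long repeats obey, in the continuum limit, a steady-state equation with
length-dependent diffusion `(1/2) d2/dL2 [(eps+kappa) L P]`, drift
`-d/dL [(eps-kappa) L P]`, fission-out loss `-(nu + iota_L) L P` and a
fission-in integral `2 int_L^inf (nu + iota_s) P_s ds`; fusion is
neglected (subdominant for stable parameters).  Three nested
approximations are solved numerically:

1. **local** - diffusion + drift only; valid for `delta_tau >> 1`;
2. **local + fission out** - adds the loss term; valid for
   `delta_tau >~ 1`;
3. **net flux** - differentiating the full equation turns the integral
   into a local boundary effect on the net flux, giving a third-order ODE
   valid for all `delta_tau > 0` once the vanishing-net-flux constraint is
   imposed through a third boundary value.

All are solved in the variable `V(L) = (eps_L + kappa_L) L P(L)` as
boundary-value problems (scipy `solve_bvp`, mesh step 0.25, coefficient
derivatives by central differences on the smooth power-law curves).
Constraints come from a kernel reference distribution at
`L1 = round(L*)` and `L2 = L_max`, plus `L3 = L_max - 1` for the
third-order equation, implemented as a two-region collocation with
continuity of `V`, `V'`, `V''` at the interior constraint.  Here
`L* = 9 (eps_8/kappa_8)^(1/delta_tau)` is the length where contraction
overtakes expansion (independent of the shared multiplier, constant along
lines of constant `delta_tau`), and `L_max` is the smallest length where
fewer than one repeat is expected genome-wide.  The continuum domain
starts at `L = 10`; below that the geometric solution applies.

Near the truncation point the distribution drops several-fold per bin and
the second-order continuum operator accrues discreteness error; in the
strongly biased regime (`delta_tau = 3`, short steep domains) this limits
the second-order equations to ~10-30% accuracy in the one or two bins
before `L_max` unless the genome (hence `L_max`) is modest.  The
steady-state comparisons therefore use 2e6 repeats.

Regime labels use `delta_tau` thresholds 0.5 and 1.0 (heuristics for which
nested equation suffices): weakly / intermediate / strongly
contraction-biased, and unstable for `delta_tau <= 0`.

## Synthetic data: what it does and does not emulate

Generators cover every input: i.i.d. genomes with tunable composition (by
default the non-A mass sits on C and G, so the A/T equivalence class sees
one clean geometric run distribution); trio mutation tables with
substitutions placed per context category and +/-1-unit indels placed per
repeat at the length-dependent truth rates (emitted as minimal
single-sample VCF 4.2, left-aligned, so the same readers run on real
data); popSTR-style locus/event tables whose loci are embedded in a
synthetic reference contig as pure runs; and kernel-generated
pseudo-empirical distributions with per-bin Poisson noise.  All are
byte-deterministic given their seed.

Not emulated: mappability and coverage structure (the synthetic genome has
no unmappable windows, so the 100 kb masking step is exercised only
logically), sequencing and calling error, context heterogeneity beyond the
three-unit model, parental genomes differing from the reference (the
generator satisfies the parental-equals-reference assumption exactly,
real data only approximately), population structure across trios, and
motif-specific secondary-structure effects.  Passing recovery tests
therefore validate the estimators' bookkeeping and calibration under the
model's own assumptions, not robustness to real-data artifacts.

## Problem sizes and study conditions

Desk-scale runs use: 2-5 Mb synthetic genomes; 150-5000 offspring;
`L_boundary` 60 for inference and stability work, 100 for steady-state
analytics; genome totals of 2e6 repeats for distribution comparisons.
The stability dichotomy is measured twice per grid point: the boundary
flag on real-scale rates with the progressive schedule and a large count
scale (counts are linear in genome size in deterministic mode, so the slow
`delta_tau = 0` runaway crosses the absolute trigger), and the
equilibration residual on uniformly x1000 rates in a single linear-regime
r = 0 stage of 6e5 iterations, where the growth-corrected residual reaches
~1e-8.  Inference tests use a 3 x 5 x 5 grid with 0.25-step exponent axes
containing the generating values.  The kernel's hot loop is a fused,
numba-compiled step identical (to machine precision, asserted in the
tests) to the reference implementation.

## Known limitations

Single-unit (+/-1) length changes only; mononucleotide instability
modeling (multi-unit motifs are counted, not evolved); no genetic drift or
selection; deterministic expectation dynamics as the primary mode; fusion
omitted from the continuum equations; the `delta_tau` regime thresholds
are heuristics; B strings carry no length-dependent instability.
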