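# repeatflux

Tools for studying how the genome-wide length distribution of simple DNA
repeats (STRs/microsatellites) arises and persists under mutation alone.
The package is aimed at population geneticists and genome scientists who
want to go from raw inputs — genome assemblies, de novo trio mutation
tables, popSTR-style locus tables — to a quantitative account of repeat
length dynamics: which mutational forces shape the distribution, what
instability rates are compatible with it, and why its long tail is stable
over evolutionary time.

## What it computes

The genome is abstracted to repeat units `A` and non-motif units `B`; the
objects of study are the count vectors `N_A(L)` of maximal runs of `L`
complete motif copies and `N_B(l)` of the gaps between them, and the
normalized distribution `P(L)`.

* **repeat_catalog** — genome-wide contiguous repeat-length histograms per
  motif equivalence class (A = A/T, AC = AC/CA/GT/TG, ...), with
  normalization, low-occupancy truncation, 1 Mb segment bootstrap
  envelopes, shuffled-genome baselines and cross-species medians.
* **rate_estimation** — per-generation rates from trio data: six
  trinucleotide-context substitution categories (lengthen ABB>AAB, shorten
  AAB>ABB, fusion ABA>AAA, fission AAA>ABA, A1 creation/loss),
  length-stratified expansion/contraction/non-motif-insertion rates,
  B-string rates, popSTR-style reanalysis, Poisson CIs and log-log
  power-law fits.
* **mutation_kernel** — the core engine: deterministic (or
  Poisson-stochastic) evolution of the joint (N_A, N_B) state under all ten
  processes, with length-dependent rates
  `rate(L) = m rate(8) (L/9)^tau` above the reliably estimated range, a
  reflective boundary, and a progressive time-rescaling schedule reaching
  T >= 1e9 generations.
* **inference** — grid search over (m, tau_eps, tau_kappa) scored with a
  tail-sensitive log-space metric
  `sum_L (ln Norm[N(L)+1] - ln Norm[N_emp(L)+1])^2`, plus
  Poisson-resampling consistency sets.
* **steady_state** — analytics: the geometric substitution equilibrium
  `P(L) ~ (mu/(mu+nu))^L` for short repeats, the characteristic lengths
  `L*` (contraction overtakes expansion) and `L_max` (fewer than one
  repeat expected), and numerical solutions of three nested steady-state
  ODEs for the long-repeat regime.
* **synthetic_data** — seeded generators for every input: i.i.d. genomes,
  trio VCFs, popSTR tables, kernel-generated pseudo-empirical
  distributions.

## Worked example

Closed-loop inference on synthetic data (scripts under `analysis/` run the
full sequence; stages 3, 5 and 6 print):

```
$ python analysis/01_simulate_inputs.py && python analysis/03_estimate_rates.py
  lengthen     rate 3.4e-09 (generating 4.77e-09, n=50)
  shorten      rate 7e-09 (generating 8.08e-09, n=44)
  ...
popSTR insertion power law: tau = 1.72 (99.9% CI 1.22..2.21), implied m = 2.00

$ python analysis/05_fit_instability.py
argmin: m=2, tau_eps=1.7, tau_kappa=2.0 (delta_tau=0.30), metric=4.723
consistency threshold: 105.023; 22 of 75 combinations consistent,
delta_tau range 0.30..0.55

$ python analysis/06_steady_state.py
delta_tau=3.00 [strongly_contraction_biased]: L*=9.7, L_max=16, ...
   max rel deviation: local 0.021 | +fission-out 0.077 | net-flux 0.051
delta_tau=1.00 [intermediate]: L*=11.2, L_max=23, ...
   max rel deviation: local 0.158 | +fission-out 0.066 | net-flux 0.015
delta_tau=0.30 [weakly_contraction_biased]: L*=18.9, L_max=42, ...
   max rel deviation: local 0.428 | +fission-out 0.123 | net-flux 0.004
```

Reading the output: the grid search recovers the generating instability
parameters exactly (`m=2, tau_eps=1.7, tau_kappa=2.0`), and the set of
parameter combinations statistically consistent with the minimum stretches
along lines of near-constant `delta_tau = tau_kappa - tau_eps` just above
the diagonal — the degeneracy the late-time dynamics impose.  The
steady-state table shows the nesting of the analytic approximations: under
strong contraction bias local transitions suffice (all three equations
within ~8%), at moderate bias fission-out is needed, and at the
best-fit-like weak bias only the full net-flux equation tracks the kernel
(0.4% vs 43% for the local-only equation).

A CLI mirrors the library (`repeatflux count | bootstrap | median | rates |
evolve | fit | steady-state | flux | simulate`); every run writes a
provenance JSON next to its output.

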