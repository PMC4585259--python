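# Methods

## The perfusion protocol model

An experiment is five consecutive perfusion periods — neutral (pH 7.3, drug
applied), acidic (6.0, drug), neutral (7.3, drug-free), alkalic (8.6, drug),
neutral (7.3, drug) — each consisting of control, drug-application and
washout phases of 10 stimulus trains delivered every 20 s (150 trains, 2980 s
total).  Only the peak current of the first depolarization of each train is
modeled and analyzed; within-train use-dependence is out of scope.  The bath
condition that feeds a given train is taken to hold over the 20-s interval
preceding it, i.e. a solution switch happens immediately after the last train
of the previous phase.  All amplitudes are normalized to the first-pulse
amplitude of the last control train of period 1, which after normalization is
exactly 1.0.  The sequence, pH levels and train counts are all configurable
(`naviph.protocol.Protocol`).

## The synthetic-trace generator

### Two-trap occupancy model

Bound drug is distributed over two kinetically distinct pools:

* **hydrophilic trap** (occupancy `b_h`): a polar compartment, putatively the
  aqueous inner vestibule, retaining the protonated form.  Egress requires
  deprotonation, so its escape rate is `k_exit_hydro · fn`, where
  `fn = 10^pH/(10^pH + 10^pKa)` is the neutral fraction of a monoprotic base.
* **lipophilic trap** (occupancy `b_l`): an apolar compartment (membrane
  phase or channel–membrane interface) retaining the neutral form.  Egress
  requires protonation: escape rate `k_exit_lipo · (1 − fn)`.

During drug application the influx into the traps is

```
u_total = conc · k_entry · [ fn·(1 − seq·fn) + charged_access·(1 − fn) ]
```

split `lipo_weight : (1 − lipo_weight)` between the lipophilic and
hydrophilic pools.  The two optional factors extend the plain
neutral-fraction gating:

* `seq` ∈ [0, 1) — *membrane sequestration*.  For very lipophilic, highly
  aromatic compounds, strong alkalization drives so much of the drug into
  the membrane phase that fewer molecules reach the pore; influx
  `∝ fn·(1 − seq·fn)` peaks at `fn = 1/(2·seq)` and declines at higher pH.
  This is the only mechanism in the model able to make a compound *most*
  potent at neutral pH (the ritanserin-like Class E pattern); with the
  default `seq = 0` influx is strictly proportional to the neutral fraction.
  A strictly fn-proportional influx provably cannot produce a non-monotone
  measured dose–response in pH: the accumulated block
  `∫ u·e^{−r(T−s)} ds` increases with `u` and decreases with `r`, and raising
  `fn` raises `u` while the escape terms only fall.
* `charged_access` ∈ [0, 1) — residual entry (and matching hydrophilic-trap
  exit) of the charged species through the activation-gate pathway.  Default
  0 everywhere, including the fixture cohort: any floor on access lets the
  hydrophilic pool reach its pH-independent equilibrium at acidic pH, which
  erases the kinetic origin of the apparent-affinity pH-dependence for
  hydrophilic-trap compounds.  The knob is kept because the gate pathway is
  mechanistically real, but it is not part of the default study conditions.

Each pool obeys `db/dt = u·(1 − b) − e·b` with coefficients that are
piecewise-constant over the schedule, so the trajectory is computed
*exactly* as a piecewise exponential (`b(t) = b_ss + (b₀ − b_ss)e^{−(u+e)t}`
per segment); no numerical integrator is involved and the only error is
floating-point.  The test suite cross-checks this against a fine-step
explicit-Euler integration at 1e-6.  Total block combines the pools
independently, `block = 1 − (1 − b_h)(1 − b_l)`, so either trap alone can
saturate; equilibrium block during application at pH 7.3 is calibrated to
`conc/(conc + kd_site)` by solving for `k_entry` in closed form (linear for
one active pool, quadratic for two).

### Rendering

Amplitude per train is `(1 − block) · proton_block(pH) · noise`:

* **proton block**: at pH 6.0 every amplitude is scaled by 0.724 (fraction
  of the control amplitude remaining under extracellular acidification);
  instantaneous and memoryless, removed the moment the bath leaves pH 6.0.
* **noise**: per-train multiplicative lognormal with coefficient of
  variation 0.03 (default), mean 1; each cell has its own stream seeded from
  `(seed, cell index)`, so cohorts are reproducible and cells independent.
  No rundown/drift term is applied by default.

Defaults: 5 cells per cohort, CV 3 %, proton-block factor 0.724.

### Class presets and cohorts

`class_preset("A")…("G")` return parameter sets whose simulated cohorts,
pushed through the full analysis, reproduce the seven qualitative
pH-dependence signatures (pH-independent/fast/reversible; pH-dependent
kinetics; alkalic trapping; acidic trapping; neutral-optimum potency;
intermediate; weakly pH-dependent).  The evidence for each preset is the
acceptance test suite.  Rates were tuned to the qualitative signatures —
no experimental rate constants exist for this protocol.  Two points deserve
emphasis:

* The alkalic-trapping (Class C) preset uses pKa 6.9.  Under the
  protonation-limited escape scaling `k_exit_lipo(1 − fn)` the
  acidic-vs-alkalic escape contrast is only large for pKa within roughly one
  unit of the working pH range; real tricyclic antidepressants (pKa ≳ 9.4)
  show the same phenotype, which this model can only produce at lower pKa.
  Conclusions drawn from the synthetic cohort about *which* pKa produces
  trapping therefore do not transfer to real compounds.
* The Class B preset pairs a hydrophilic pool (kinetic pH-dependence, onset
  rate ∝ fn) with a *fast-equilibrating* lipophilic pool (equilibrium
  affinity pH-dependence).  A slowly equilibrating lipophilic component
  would contaminate the onset fits with a second, slower exponential and
  make the acidic-onset time constant unidentifiable within a 200-s phase.

`benchmark_cohort(seed)` draws 30 drugs from the presets (4–5 per class)
with mild multiplicative parameter jitter (pKa ± 0.04, kd ×10^±0.08, escape
rates ×10^±0.05) for planted-label clustering benchmarks.
`fixture_drug_configs()` maps the synthetic 30-compound descriptor table
onto kinetics — `lipo_weight` is a logistic in logP, lipophilic-trap escape
decays with aromatic atom count, hydrophilic-trap escape with polar surface
area, and the two most lipophilic/aromatic compounds get `seq = 0.9` — so
that descriptor–property correlations have the expected direction by
construction.  Single-concentration inhibition targets span 0.45–0.70,
mirroring the experimental practice of choosing concentrations that keep
inhibition within the measurable 25–75 % band.

### What the generator does not emulate

Voltage-dependent gating and state-dependent affinity; use-dependence within
the 5-pulse trains; open-channel-only access (flecainide-like); solution
exchange artifacts and rundown; cell-quality attrition.  Passing tests
demonstrate that the *analysis* correctly recovers structure the generator
puts in, not that real recordings contain that structure.

## Analysis conventions

* `c`, `i`, `w` are the last control, last drug and last washout train
  amplitudes of a period ("inhibited" = last drug train, consistent with
  reading the exponential plateau).
* Exponential fits run per phase on the train amplitudes, times relative to
  the first point; parameters (plateau, span, log τ) are fitted by
  Levenberg–Marquardt with an analytic Jacobian, three τ starting values
  (duration/5, duration/2, 2×duration), an evaluation cap of 300 per start,
  and early exit once residuals reach the noise floor.  τ is constrained to
  (0.1 s, 10⁴ s].  Fits with |span| < 0.01 or τ pinned at a bound are
  flagged "kinetics unresolved".  On noiseless mono-exponential data the fit
  is exact to ~1e-14 relative.
* K_app is censored (NaN + flag) when measured inhibition ≤ 0; censored
  values are excluded from the geometric mean with a recorded count.  The
  censoring bound used for imputation is the 5 %-inhibition detection floor,
  `19·conc`.
* Neutral-pH values average the first and the last neutral application per
  cell (geometric for K_app and τ, arithmetic for reversibility) before
  averaging across cells.
* Offset τ is flagged unreliable when the period's reversibility is below
  0.1 and is excluded from summaries and the base cluster features.
* Paired t-tests run on log10 values for affinity and τ, raw values for
  reversibility; zero-variance differences report p = 1 with a "degenerate"
  flag; the significance threshold (default 0.01, no multiplicity
  correction) is configurable.

### Robust companion statistics

Alongside the contract aggregates, summaries carry companions used by the
profiling and metric stages, where a complete, finite matrix matters more
than unbiasedness:

* `kapp_imputed`: per-cell censored affinities pinned at `19·conc` before
  the geometric mean (never silently dropped);
* `kapp_pooled`: `conc·(1 − Ī)/Ī` with `Ī` the cell-averaged inhibition —
  inverting once after averaging is far more stable than averaging per-cell
  inversions when block at one pH sits near the detection floor; the
  affinity-*ratio* metrics use this estimator;
* `reversibility_bounded`: per-cell ratios clipped to [0, 1.2] (undefined →
  1.0, i.e. nothing measurable was left to recover) before averaging;
* `tau_onset_robust`: onsets flagged unresolved are pinned to 10⁴ s when the
  period shows < 10 % inhibition (kinetics slower than the observation
  window) or to 10 s (half a train interval) when block is present but
  faster than the sampling.  Without these pins, compounds that simply do
  not block at some pH contribute pure-noise feature columns that dominate
  within-class variance and break class recovery.

## Profiling and correlation

The 18-variable profile comprises, for K_app, reversibility and τ_onset at
the three pH levels: z-scored levels (log10 first for K_app and τ; sample
SD, n−1) and the three pairwise differences (log-ratios for K_app and τ)
divided by their column SD *without* mean-centering, so a difference keeps
its sign.  Clustering is scipy's Ward minimum-variance linkage on Euclidean
distances, cut to k = 7; column weights scale a variable's contribution to
squared distance (columns multiplied by √w).  Sensitivity variants:
city-block distances, τ_onset replaced by the log-scale average of onset and
offset τ, and weight grids {1, 1.5, 2} on analyst-designated columns
(default: the three reversibility levels); variants are compared by adjusted
Rand index.  Greedy Ward cuts are verified against exhaustive-search optima
on profile-structured instances; near-optimality is *not* a property of
structureless point sets and is not claimed for them.

Correlations are ordinary least squares on optionally log10-transformed
variables; the reported p is the two-tailed slope t-test (equivalent to the
correlation test for simple OLS); flagged/undefined values are excluded
pairwise with n reported per cell, and no imputation is used in
correlations.  The descriptor cross-matrix covers every numeric descriptor
against 24 inhibition properties (K_app, reversibility, onset and offset τ
at three pH levels plus their three pairwise differences each).

## Problem sizes in the test and acceptance runs

Stochastic suites use 20 replicate cohorts of 30 drugs × 5 cells at 3 % CV
(clustering recovery, correlation direction), 100 repetitions × 5 cells for
noisy τ recovery, and exhaustive partition enumeration up to n = 8, k = 3.
These sizes keep a full run within a few minutes on one core while leaving
the acceptance margins wide (observed: median planted-class ARI ≈ 0.96
vs the 0.8 requirement; affinity-ratio significance in 20/20 seeds vs 19/20).

## Known limitations

* The two-trap model is the smallest scheme able to produce all seven class
  signatures; it does not separate membrane-access from binding steps, so
  its rate constants are effective, not molecular.
* Apparent affinity under this protocol is kinetics-contaminated whenever a
  200-s application does not equilibrate; that is faithful to the
  experimental readout but means `K_app ≠ kd_site` away from pH 7.3.
* Reversibility values depend on the discontinuous-perfusion washout of the
  simulated platform and are not platform-independent compound properties.
* Descriptors are inputs; the bundled 30-compound table is synthetic (ranges
  realistic, anchor values cited in its docstring) and must not be used as a
  source of real compound properties.
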