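# Methods

This note documents the models and procedures implemented in `apoptosim`,
their assumptions, defaults, numerical choices and limitations.

## The execution model

The core of the package is a deterministic mass-action ODE model of the
caspase-execution phase of apoptosis. The simulation clock starts at full
mitochondrial outer-membrane permeabilisation (MOMP): SMAC is entirely
cytosolic at t = 0, all binding complexes are empty, and the five measured
tissue concentrations initialise the free pools. This reflects the fact
that the model's inputs are bulk tumour concentrations and its readout
window (15 minutes) corresponds to the post-MOMP execution phase, which in
single-cell experiments is fast and switch-like once triggered.

Fourteen species and nine reactions:

| # | Reaction | Rate constants |
|---|----------|----------------|
| R1 | APAF + PC9 → APOP (apoptosome assembly) | k_apop |
| R2 | APOP + PC3 → APOP + C3 (catalytic caspase-3 activation) | k_cat9 |
| R3 | XIAP + C3 ⇌ XC3 | k_x3_on / k_x3_off |
| R4 | XC3 → XIAP (caspase-3 degraded, XIAP recycled) | k_deg3 |
| R5 | XIAP + APOP ⇌ XAPOP | k_xa_on / k_xa_off |
| R6 | SMAC + XIAP ⇌ SX | k_sx_on / k_sx_off |
| R7 | MIM + XIAP ⇌ MX (SMAC mimetic, a distinct species) | k_mx_on / k_mx_off |
| R8 | C3 + SUB → C3 + CSUB (substrate cleavage) | k_sub |
| R9 | C3 → ∅ (turnover of free caspase-3) | k_turn3 |

Six linear combinations are conserved exactly (substrate, SMAC, mimetic,
Apaf-1, caspase-9 and XIAP pools); they are left null-vectors of the
stoichiometry matrix and serve as integration-accuracy invariants, checked
to 10⁻⁶ relative error in the test suite (observed drift is ~10⁻¹⁰).
Caspase-3 feedback onto caspase-9 and time-resolved SMAC release are
deliberately not part of this reference network: the desk-scale model is
kept fully specified and testable, with the input/output semantics (five
concentrations in, SC time course out) unchanged. Both are natural
extension points via a modified stoichiometry.

### Kinetic constants

Second-order constants default to 10 μM⁻¹·min⁻¹ (k_apop, k_cat9, k_x3_on,
k_xa_on, k_sx_on, k_mx_on and k_sub), off-rates to 0.01 min⁻¹, XIAP-driven
caspase-3 degradation to 0.1 min⁻¹ and free-caspase-3 turnover to
0.01 min⁻¹. These are order-of-magnitude physiological values for
protein–protein association and tight (nM-scale Kd) IAP binding, not
fitted quantities. Their adequacy is established by a calibration check
that runs in the test suite: a nominal apoptosis-competent profile
(Apaf-1 = 1.0, PC3 = 2.0, PC9 = 0.1, SMAC = 1.0, XIAP = 0.3 μM) must cross
80 % substrate cleavage before 15 minutes, while a nominal resistant
profile (XIAP = 2.0, SMAC = 0.1 μM) must stay at or below 80 % at
15 minutes. Should a user-modified parameter set fail this separation,
`calibrate_fallback_rates` rescales k_cat9 and k_sub by a common factor
found by bisection. The SMAC mimetic uses SMAC's binding constants by
default, consistent with its design purpose of mimicking SMAC's
XIAP-antagonism; both are exposed independently.

### Classification

The readout is SC at 15 minutes, interpolated linearly on the output grid.
A sample is resistant iff SC ≤ 80 %. The boundary value itself is assigned
to the resistant class (the "at least 80 %" reading of the threshold is the
other defensible convention; we follow the tabulated "SC ≤ 80 %" grouping
and note the ambiguity here).

### Numerics

Integration uses LSODA (stiffness-switching) with rtol = 10⁻⁸,
atol = 10⁻¹⁰, reported on a uniform 0.1-min grid over 60 min by default.
Tiny negative solver excursions are clamped to zero for reporting only; an
excursion below −10·atol (relative to the largest initial pool) raises a
diagnostic error naming the sample. The adaptive path is cross-checked
against a fixed-step classical Runge–Kutta integration (step 10⁻³ min) —
in the acceptance tests this oracle is written out independently from the
reaction scheme — with observed agreement ~10⁻⁷ % of the substrate pool,
far inside the 0.1 % acceptance band. SC is monotone non-decreasing by
construction (the cleaved pool is never consumed), and SC at 15 min is
monotone in each input (non-increasing in XIAP; non-decreasing in SMAC,
procaspase-3 and mimetic dose), verified by pairwise sweeps.

## Quantification

Calibration regresses known concentration (μM) on normalised band
intensity by ordinary least squares — the predictive orientation, since
the pipeline maps intensities to concentrations. Negative calibrated
concentrations (possible with a negative intercept at very faint bands)
are floored at zero with a warning, because the ODE model's domain is the
non-negative orthant. Batch correction is multiplicative: blotting
efficiency distorts intensities by a scale factor, so the ratio of
newly-diagnosed medians realigns the batches exactly while preserving
within-batch concentration ratios; the correction derived from the
newly-diagnosed subset is applied to recurrent samples of the same batch
as well. Mann–Whitney tests use the exact null distribution when the
combined sample size is ≤ 20 and there are no ties, and the tie-corrected
normal approximation otherwise. Medians are sample medians with linear
interpolation for even n.

## In-silico trial

The default dose grid is 13 log-spaced points over 1 nM – 1 μM, plus the
basal (dose 0) point. Rescue is judged with the same 80 % / 15-min rule as
basal classification. Responder classes partition the cohort: basal
sensitive → responsive to standard therapy; basal resistant and sensitive
at any tested dose → rescuable with mimetic; otherwise non-responsive.
Because SC is monotone in dose, class membership depends only on the basal
point and the top dose, so refining the grid can only refine the reported
minimum rescuing dose (a grid member, not interpolated), never the class.
A monotonicity flag is raised if SC drops by more than 0.5 percentage
points between consecutive doses, which would indicate a numerical
problem rather than biology.

## Survival analysis

PFS is measured in months from the analysed resection (newly-diagnosed or
recurrent) to progression, with loss to follow-up censored. Kaplan–Meier
medians carry Brookmeyer–Crowley-style 95 % CIs obtained from the log-log
confidence band of the survival curve. Cox models use the Efron tie
approximation; categorical predictors are dummy-coded against an explicit
reference level; all reported p-values are likelihood-ratio tests — for
adjusted models, the LRT compares the model with and without the predictor
on the same complete-case rows (rows missing any covariate in a given
model are dropped from that model only, and the per-model n is recorded).
Monotone-likelihood/complete-separation fits are detected post-hoc
(|log HR| ≥ 15 or se ≥ 10) and raised as errors rather than silently
reported. The class-by-history χ² is reported uncorrected, with the
Yates-corrected p-value alongside. Single-protein prognostics use
cohort-median splits with ties assigned to the ≤ median group.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:

- **Concentrations** are independent log-normals per protein
  (σ_log = 0.6), medians 0.8 / 2.0 / 0.1 / 1.0 / 0.9 μM for Apaf-1, PC3,
  PC9, SMAC and XIAP — procaspase-3 highest, procaspase-9 lowest. The
  XIAP/SMAC balance was set so that, under the default kinetics, roughly a
  fifth of samples are apoptosis-resistant, the minority-resistant
  structure this class of cohort exhibits. Recurrent samples are scaled by
  a multiplicative group effect (default 0.7) across all proteins.
- **Densitometry** is generated by inverting the calibration lines
  (synthetic standards fixture with zero intercepts), drawing β-actin
  intensities uniformly in [800, 1200], applying per-batch multiplicative
  intensity distortions and optional log-normal measurement noise.
- **Outcomes** are exponential proportional hazards: rate =
  0.063/month (median ≈ 11 months) for sensitive samples times HR
  (default 5.0) for resistant ones, with uniform administrative censoring
  on (0, 36] months (≈ 30–40 % censoring). Optional log-hazard covariate
  effects for history, age and MGMT status default to zero. Classes can
  come from actually running the simulator (the default for the fixture
  bundle) or from planted labels when isolating the survival stage.
- The study-sized fixture bundle is n = 46 with 31 newly-diagnosed and 15
  recurrent samples, split over two blotting batches with planted
  distortions, and 5 % intensity noise.

All randomness in a given operation flows through one seeded
`numpy.random.Generator`, so outputs are byte-identical under a fixed
seed.

What the generator does *not* emulate: inter-protein correlation (an
independence default; real co-expression would tighten or loosen the
class boundary), non-linear blot saturation, measurement error on
β-actin itself, non-proportional hazards, and any direct dependence of
outcome on history beyond the optional covariate effect. Passing the
recovery tests therefore demonstrates correctness of the estimators under
the generator's assumptions, not performance on real cohorts.

## Test and replication sizes

Replicate-based checks use sizes chosen to keep the whole suite within a
few minutes on one CPU while leaving comfortable statistical margins:
hazard-ratio recovery uses 100 replicates of n = 500 with a planted
resistant fraction of 0.30 (the acceptance band of [4.0, 6.25] around
HR 5 is then ≈ 2 standard errors of the per-replicate estimator);
Mann–Whitney null calibration uses 200 seeds of n = 60 cohorts; the
log-normal median-ratio convergence check runs at n = 4000, where the
sampling error (~2.4 %) sits well inside the ±10 % band; and the log-rank
vs Cox-LRT agreement check runs at HR 1.2 and n = 1000, a local
alternative where the two asymptotically equivalent tests produce
comparable moderate p-values.

## Known limitations

- The reference network is a minimal, fully specified representation of
  the cited mechanism; absolute SC values depend on the fallback rate
  constants and should not be read as calibrated predictions for real
  tumours without cohort-specific parameterisation.
- Bulk concentrations ignore intra-tumour heterogeneity; the model
  predicts an average-cell execution phenotype.
- The survival layer implements complete-case adjustment only; no
  imputation, time-dependent covariates or competing risks.
- At n ≈ 46 the Cox estimates are intrinsically noisy (the fixture
  cohort's confidence intervals span roughly a factor of six); the
  pipeline reports them with CIs rather than suppressing them.
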