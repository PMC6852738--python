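# apoptosim

Patient-specific modelling of apoptosis-execution competence in
glioblastoma (GBM).

Chemo- and radiotherapy kill tumour cells through caspase-dependent
apoptosis, and many GBM tumours evade treatment because the execution
machinery downstream of mitochondrial outer-membrane permeabilisation
(MOMP) is out of balance. `apoptosim` implements, as a tested and reusable
pipeline, the systems-biology workflow that turns five absolutely
quantified apoptosis proteins per tumour resection — Apaf-1, procaspase-3,
procaspase-9, SMAC and XIAP — into a mechanistic prediction of whether that
tumour can execute apoptosis, and relates the prediction to
progression-free survival (PFS). It is aimed at systems-medicine
researchers who want to run, stress-test or extend this class of
mechanistic prognostic biomarker on their own cohorts or on fully synthetic
ones.

## What the pipeline does

1. **Quantification** (`apoptosim.quantify`) — Western-blot band
   intensities are normalised to β-actin, converted to absolute μM
   concentrations by per-protein linear calibration against titrated
   recombinant-protein standards, and harmonised across blotting batches by
   median alignment of the newly-diagnosed samples (a multiplicative
   per-protein factor `f_p = median_ref(p) / median_target(p)` applied to
   every sample in the target batch). Newly-diagnosed vs recurrent
   expression is compared with two-sided Mann–Whitney *U* tests.
2. **Execution model** (`apoptosim.model`) — a mass-action ODE network of
   post-MOMP caspase activation: apoptosome assembly
   (Apaf-1 + procaspase-9), apoptosome-catalysed caspase-3 activation, XIAP
   sequestration of caspase-3 and of the apoptosome, XIAP-mediated
   caspase-3 degradation, SMAC (and SMAC-mimetic) neutralisation of XIAP,
   and cleavage of a normalised caspase-3 substrate pool. The readout is
   substrate cleavage, SC(t) = 100·[cleaved]/[total]; a tumour is
   **apoptosis-resistant** when SC at 15 min ≤ 80 % and
   **apoptosis-sensitive** otherwise.
3. **In-silico trial** (`apoptosim.trial`) — each patient is re-simulated
   across a log-spaced grid of SMAC-mimetic doses spanning the clinical
   range (1 nM – 1 μM) and assigned to one of three responder classes:
   responsive to standard therapy (basal-sensitive), rescuable with
   mimetic, or non-responsive.
4. **Survival** (`apoptosim.survival`) — Kaplan–Meier PFS curves with
   median CIs, log-rank tests, and univariate/adjusted Cox
   proportional-hazards models (Efron ties, likelihood-ratio p-values),
   plus the χ² association between predicted class and tumour history.
5. **Synthetic cohorts** (`apoptosim.synthetic`) — seeded generators for
   profiles, raw densitometry with planted batch distortions, and linked
   PFS outcomes with a configurable true hazard ratio, so the entire
   pipeline is testable without any external data.

## Worked example

Generate a study-sized synthetic cohort (n = 46; 31 newly-diagnosed, 15
recurrent) and run every stage from the shell:

```sh
apoptosim synthesize --n 46 --seed 7 --out demo
apoptosim quantify  --densitometry demo/densitometry.csv \
                    --standards demo/standards.csv \
                    --clinical demo/clinical.csv --out demo/profiles.csv
apoptosim simulate  --profiles demo/profiles.csv --out demo/simulations.csv
apoptosim trial     --profiles demo/profiles.csv --out demo/trial.csv
apoptosim survive   --clinical demo/clinical.csv \
                    --simulations demo/simulations.csv \
                    --profiles demo/profiles.csv --out demo/surv
```

The run above prints (abridged):

```
batch batch1 factors: {'APAF1': 0.7604, 'PC3': 1.307, 'PC9': 0.6812, 'SMAC': 1.8987, 'XIAP': 0.6446}
Mann-Whitney newly-diagnosed vs recurrent p-values:
  PC3: 0.02932
  SMAC: 0.04903
  XIAP: 0.0001616
3/46 samples apoptosis-resistant (SC <= 80% at 15 min)
       responder_class  n
   responsive_standard 43
rescuable_with_mimetic  3
        non_responsive  0
{"log_rank_p_apoptosis_class": 0.00993, ...}
```

Reading the output: the quantification stage recovered the multiplicative
scale factors that undo the planted batch distortion; three proteins are
significantly lower in recurrent samples; 3 of 46 simulated tumours fail
to cleave 80 % of substrate within 15 min and are called
apoptosis-resistant; all three resistant tumours can be re-sensitised
in-silico by a SMAC mimetic at ≤ 1 μM; and the resistant group shows
significantly shorter PFS (log-rank p ≈ 0.01).

The same pipeline is available as a library; see the module docstrings.
Each simulation run logs its fully resolved kinetic parameters and a
configuration hash, and a YAML file passed via `--params` can override any
rate constant, tolerance, the 80 % threshold or the 15-min readout.

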