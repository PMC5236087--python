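# Methods

## Model structure

State variables are drug amounts (ng) in plasma, up to two peripheral
compartments, brain extracellular fluid (ECF), optionally brain
intracellular fluid (ICF), four cerebrospinal-fluid compartments in series
(lateral ventricle LV, third+fourth ventricles TFV, cisterna magna CM,
subarachnoid space SAS) and, for clinical drain studies, an external
ventricular drain (EVD) chamber. Concentrations are `C_x = A_x / V_x`
(ng/mL); flows and clearances are in mL/min, time in minutes. With `R(t)`
the infusion rate into plasma, the mass balances are

```
dA_PL/dt  = R(t) + Q_PL_PER1 (C_PER1 − C_PL) + Q_PL_PER2 (C_PER2 − C_PL)
            − CL_net C_PL − Q_PL_ECF (f_p C_PL − C_ECF)
            + Q_DIFF C_SAS + [Q_LV_PL C_LV]
dA_PERk/dt = Q_PL_PERk (C_PL − C_PERk)
dA_ECF/dt = Q_PL_ECF (f_p C_PL − C_ECF) − Q_DIFF C_ECF
            − [Q_ECF_ICF (C_ECF − C_ICF)]
dA_ICF/dt = Q_ECF_ICF (C_ECF − C_ICF)
dA_LV/dt  = Q_DIFF (C_ECF − C_LV) − [Q_LV_PL C_LV] − [Q_LV_EVD C_LV]
dA_TFV/dt = Q_DIFF (C_LV − C_TFV)      dA_CM/dt = Q_DIFF (C_TFV − C_CM)
dA_SAS/dt = Q_DIFF (C_CM − C_SAS)
dA_EVD/dt = Q_LV_EVD (C_LV − C_EVD)
```

Bracketed terms exist only when the corresponding feature is enabled.
Assumptions worth stating explicitly:

* **Single dispersion flow.** One lumped parameter `Q_DIFF` drives the
  unidirectional ECF→CSF chain and the SAS→plasma reabsorption, standing in
  for CSF bulk flow, ECF bulk flow and turbulent mixing together. At steady
  state the whole chain equilibrates with ECF, and
  `C_ECF/(f_p C_PL) = Q_PL_ECF / (Q_PL_ECF + Q_DIFF)` in the reduced model
  (no ICF, no LV efflux) — this closed form is used as a test oracle.
* **Symmetric BBB exchange on unbound drug.** `f_p` multiplies the plasma
  side of the BBB flux; transporter inhibition scales the single clearance
  `Q_PL_ECF` (both directions) as `P_pat (1 + θ·Cov)` with a 0/1 covariate.
  Methotrexate additionally carries an LV→plasma efflux clearance
  (`Q_LV_PL`) with its own inhibitor covariate; for the other preset drugs
  blood–CSF-barrier transfer is omitted.
* **Elimination from plasma only.** Acetaminophen's enterohepatic
  recirculation is reduced to a net-clearance factor,
  `CL_net = CL_PL (1 − fraction)` with `fraction = 0.933`. Under this
  reduction `CL_PL` and `fraction` are exactly collinear, so fits on
  synthetic acetaminophen data hold `fraction` fixed; no gallbladder lag or
  reinfusion pulse is modelled.
* **Morphine dose-group effect.** The nonlinear dose dependence of
  morphine's BBB transfer is categorical: baseline `Q_PL_ECF = 0.00458`
  (10/40 mg/kg groups) with a `dosegrp_4` covariate giving exactly 0.00750
  in the 4 mg/kg group; no continuous saturation term. Translation to
  human scales the 4 mg/kg value.
* **EVD as a drained well-stirred chamber.** The drain withdraws
  `Q_LV_EVD·C_LV` from the ventricle into a chamber of volume `V_EVD` that
  is itself continuously emptied at the same flow. Per-patient drain data
  are study metadata; the packaged defaults (`Q_LV_EVD = 0.1` mL/min,
  `V_EVD = 10` mL, typical of clinical drainage at 5–10 mL/h) are synthetic
  placeholders.

## Numerical solution

Between infusion on/off events the system is linear and time-invariant, so
profiles are propagated segment-by-segment with the matrix exponential of
the input-augmented rate matrix (`scipy.linalg.expm`). Infusion starts and
stops are exact segment boundaries; there is no truncation error, no
stiffness concern, and repeated `(rate, Δt)` segments are cached. This is
what keeps a full naive-pooled fit of a 16-animal study under a second.

Dialysate and drain observations are *collection-interval averages*, not
point samples: an observation carries a midpoint time and a duration, and
its prediction is the trapezoid average of the profile over five evenly
spaced sub-times in the interval. Generator and fit predictor share the
same quadrature, so recovery tests are exact by construction; five
sub-points keep the within-bin discretization a small fraction of the bin
average for bin widths down to 10 min against distribution time constants
of ~3–8 min.

## Estimation

Rat fits are naive pooled (all animals as one subject; the data come from
highly standardized experiments on homogeneous animals) by extended least
squares:

```
OFV = Σ_ij [ (y_ij − ŷ_ij)² / var_ij + ln var_ij ],
var = σ_s² ŷ²  (proportional, per stream s)   or   σ₁² ŷ² + σ₂²  (mixed)
```

* Structural parameters are searched in log space with L-BFGS-B from three
  jittered starts (seed-controlled); for purely proportional models the
  per-stream σ are profiled out in closed form
  (`σ̂_s² = mean((y−ŷ)²/ŷ²)`), which is exact and removes them from the
  search.
* The variance is floored at `(10⁻⁶ · max|y|)²` so `ln var` stays finite as
  predictions approach zero; parameters that drift beyond e±45 in log space
  or streams whose predictions fall entirely below the floor are reported
  in the convergence diagnostics rather than silently clipped.
* Relative standard errors come from the central-difference Hessian of the
  (profiled) objective, `cov = 2 H⁻¹`; in log space the diagonal square
  roots are relative SEs directly, and the full correlation matrix is kept
  for identifiability assessment. A non-positive-definite Hessian is
  reported, not fatal.
* Nested models are compared by ΔOFV against the χ² 95th percentile
  (3.84 at 1 df). In automated model-order selection a small tolerance
  absorbs optimizer-level noise when the richer model terminates marginally
  above the nested optimum.
* Inter-individual variability is log-normal, `θ_i = θ e^η`,
  `η ~ N(0, ω²)`. Human plasma models (1/2/3 compartments, order chosen by
  LRT) quantify it two-stage: per-subject fits started from the pooled
  estimates, population value = geometric mean, ω = SD of the per-subject
  log estimates. This replaces full conditional-estimation mixed-effects
  machinery; only population means feed the translation step, for which
  two-stage is adequate at the study sizes involved.

A property worth knowing when interpreting fits: with prediction-
proportional variance the ELS objective is *not* minimized at a perfect
fit — the `ln var` term rewards smaller predictions — so even noise-free
data are recovered exactly only under a constant-variance error model.
With the real (noisy) error models the estimator is consistent and, at the
packaged study sizes, empirically unbiased to within ~2%.

## Preprocessing

Free fraction is ultrafiltrate over pooled plasma concentration; phenytoin
and remoxipride use literature protein binding of 91% and 26%
(`f_p` 0.09 / 0.74). Probe recovery from retrodialysis is
`(C_in − C_dial)/C_in`; dialysate concentrations are divided by the
recovery to yield tissue unbound concentrations. Dataset assembly converts
mg/kg doses to ng via body weight, optionally converts total plasma to
unbound via `f_p`, flags below-LLOQ records and by default excludes them
(LLOQ/2 substitution available). Rat plasma is treated as a total-plasma
assay predicted by `C_PL`; human plasma is converted to unbound before
fitting (acetaminophen `f_p` 0.85; morphine already unbound), so the
translated human model carries `f_p = 1` and its plasma state is unbound.

Noise-corrupted simulated records can be negative under the proportional
error model at the packaged σ values (brain-ECF σ up to 1.88); they are
kept in the dataset and the fit — censoring them would bias estimation —
and non-negativity is guaranteed only for noise-free concentrations.

## Validation metrics

Prediction error is the symmetric form `PE = (y − ŷ) / ((y + ŷ)/2)` and
`SMAPE = mean|PE| · 100`, bounded by 200% and scale-invariant; it is
defined only for positive pairs, so non-positive noisy measurements are
excluded from scoring. Prediction intervals are empirical 2.5/50/97.5
percentiles (linear interpolation between order statistics, so bands are
bit-reproducible given a seed) over replicate simulations — 200 by default
— each drawing subject-level parameters from the log-normal IIV model and
residual error at every time point. External validation re-estimates only
the plasma disposition parameters on the new dataset, fixes the
brain-related parameters and the physiological volumes, and scores the
brain/CSF predictions by SMAPE per compartment.

## Translation to human

`P_human = P_rat (BW_human/BW_rat)^0.75` with 70 kg / 0.25 kg defaults is
applied to `Q_PL_ECF` and `Q_DIFF`; the scaled values are fixed and
displayed at 3 significant figures (the convention for fixed translated
parameters; full precision is an option but the packaged pipeline stores
the rounded values it reports). CNS volumes are replaced by human
physiology; plasma parameters come from the human plasma fit; the EVD
compartment is attached per patient when drain records exist.

## Synthetic study designs

The generators realize the published experimental layouts — species, animal
and patient numbers, dose levels and units, infusion durations, sampling
windows and approximate totals, sampled compartments, inhibitor co-
administration arms, residual-error SDs and (human) IIV SDs — from the
packaged parameter sets. Choices made where the designs are silent:

* subjects are assigned round-robin over dose × inhibitor arms (per-arm
  counts are not published);
* plasma is drawn on a geometric (front-loaded) grid starting 2 min after
  the start of infusion; dialysate/drain streams are consecutive collection
  intervals of 10 min over the first hour, widening to cover the window
  with the printed total count. Front-loaded schedules are the faithful
  reconstruction: brain and CSF equilibrate with time constants of a few
  minutes, and evenly spaced point samples demonstrably cannot support the
  reported precision of the transfer parameters (the likelihood is flat
  along the common scale of `Q_PL_ECF` and `Q_DIFF`), whereas these
  schedules reproduce it (relative SEs ≈ 11–13% vs ≈ 10–12% reported);
* probe recoveries default to 0.25–0.55 per stream (plausible in-vivo
  microdialysis values; the study's own constants are supplementary
  material) and are recorded in the dataset metadata so the correction is
  exactly invertible;
* inhibitor arms are separate animals (no washout crossover), matching
  pre-administration of the blocker.

What the generator does **not** emulate: assay drift and LLOQ censoring
mechanisms beyond a simple threshold, circadian variation, inter-animal
variability in the rat (the rat analysis is naive-pooled by design),
within-subject changes in drain flow, and pathological blood–brain-barrier
states. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Known limitations

* Under the packaged acetaminophen design sizes and residual SDs, the
  dispersion flow `Q_DIFF` is recovered essentially without bias but with
  ~16% sampling dispersion; its likelihood is shallow along the common
  flow scale, so individual replicate estimates can deviate by ±20%.
  `CL_PL` and `Q_PL_ECF` recover to ~5% and ~3% median error.
* The enterohepatic reduction makes `fraction` unidentifiable from
  concentration data alone; only `CL_net` is estimable.
* Two-stage IIV estimates are biased upward at small n and high residual
  noise relative to full mixed-effects estimation; with 2–7 patients the
  ω values should be read as descriptive.
* The EVD drain parameters packaged as defaults are synthetic; predictions
  for drained-CSF concentrations scale directly with them.
* Human brain ICF volume is not parameterized; ICF is disabled in human
  predictions (neither packaged human drug requires it).
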