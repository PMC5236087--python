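# cnspk — multi-compartmental CNS distribution modelling

`cnspk` is a pharmacokinetic modelling toolkit for drug distribution into
the brain. Getting a drug to a target inside the central nervous system is
limited by the blood–brain barrier (BBB) and blood–CSF barrier, and the
concentration that matters pharmacologically — unbound drug in brain
extracellular fluid (ECF) or cerebrospinal fluid (CSF) — can only be
measured invasively (microdialysis in animals, ventricular drains in
patients). This package implements a generic semi-physiological
compartmental model that is fitted to rich rat microdialysis data and then
*translated* to predict human brain and CSF concentration–time profiles
from human plasma data alone. It is aimed at pharmacometricians and DMPK
scientists working on CNS drug candidates.

## The model

The structural model comprises plasma with up to two peripheral
compartments, brain ECF, optionally brain intracellular fluid, and a chain
of four physiological CSF compartments (lateral ventricle LV, third+fourth
ventricles TFV, cisterna magna CM, subarachnoid space SAS):

* BBB exchange: a single bidirectional clearance `Q_PL_ECF` acting on the
  unbound plasma concentration, `Q_PL_ECF · (f_p·C_PL − C_ECF)`;
* drug dispersion: one lumped flow `Q_DIFF` carrying drug unidirectionally
  `ECF → LV → TFV → CM → SAS → plasma`, representing the combined CSF/ECF
  bulk flow and turbulence;
* no transfer across the blood–CSF barrier, except a drug-specific efflux
  clearance `Q_LV_PL` (needed for methotrexate only);
* active transporter effects (P-gp, MRP/OAT/OATP) as categorical covariates
  `P = P_pat · (1 + θ·Cov)` on the barrier clearances;
* CNS volumes are species physiology and are fixed (rat: V_ECF 0.29, V_LV
  0.05, V_TFV 0.05, V_CM 0.017, V_SAS 0.18 mL).

Rat parameters are estimated by naive-pooled extended least squares,
`OFV = Σ [(y−ŷ)²/σ²ŷ² + ln σ²ŷ²]`, with proportional residual error per
observation stream and likelihood-ratio model comparison (ΔOFV ≥ 3.84,
p < 0.05). Translation to human replaces the CNS volumes by human values
(V_ECF 240, V_LV 22.5, V_TFV 22.5, V_CM 7.5, V_SAS 90 mL), rescales the
drug-specific brain clearances allometrically,
`P_human = P_rat · (70 / 0.25)^0.75`, re-estimates plasma disposition from
human data, and (for ventricular-drain studies) attaches an external
ventricular drain (EVD) sampling compartment. Prediction uncertainty is
reported as 200-replicate simulation bands (2.5/50/97.5 percentiles) and
accuracy as the symmetric mean absolute percentage error
SMAPE = mean |obs − pred| / ((obs + pred)/2) × 100.

Nine rat parameter sets (acetaminophen, atenolol, methotrexate, morphine,
paliperidone, phenytoin, quinidine, remoxipride, risperidone) and the two
human translation targets (acetaminophen, morphine) ship as presets,
together with synthetic-study generators that realize the corresponding
experimental designs, so the full pipeline runs without any external data.

## Worked example

Translate the rat acetaminophen model to a human patient receiving 1 g as
a 30-min infusion, with CSF sampled through a ventricular drain:

```python
import numpy as np
from cnspk import (DoseEvent, TranslationConfig, build_human_model,
                   predict_human_profiles, preset_parameters,
                   steady_state_ecf_ratio)

rat = preset_parameters("acetaminophen")
print(round(steady_state_ecf_ratio(rat), 3))      # 0.336

cfg = TranslationConfig(evd_records=[{"q_lv_evd": 0.1, "v_evd": 10.0}])
model = build_human_model(rat, cfg, preset_parameters("acetaminophen", "human"))
print(model[1].q_pl_ecf, model[1].q_diff)          # 1.92 3.81

bands = predict_human_profiles(
    model, [DoseEvent(0.0, 30.0, 1e9)], np.linspace(0, 360, 13),
    n_reps=200, seed=1,
    omegas={"cl_pl": 0.490, "v_per1": 0.235}, sigma={"plasma": 0.25})
lo, med, hi = bands.bands["csf_evd"][:, 2]
print(round(lo, 1), round(med, 1), round(hi, 1))   # 610.9 831.9 1069.5
```

The first number is the steady-state unbound brain-to-plasma ratio in the
rat: only 34% of the unbound plasma concentration is reached in brain ECF
because dispersion into CSF competes with BBB entry. The next pair are the
human BBB transfer and dispersion clearances in mL/min, obtained purely by
allometric rescaling of the rat estimates. The final triple is the 95%
prediction interval and median of the drained-CSF acetaminophen
concentration (ng/mL) one hour after the start of the infusion,
accounting for between-patient variability in clearance and peripheral
volume and for residual assay error.

A command-line layer mirrors the pipeline stages:

```bash
cnspk generate --drug acetaminophen --species rat --seed 3 --out rat.csv
cnspk fit      --data rat.csv --drug acetaminophen --seed 1 --out fit.json
cnspk translate --human-plasma human.csv --drug acetaminophen \
                --dose-mg 1000 --infusion-min 30 --seed 2
```

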