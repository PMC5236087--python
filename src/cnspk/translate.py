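"""Rat-to-human translation of the CNS distribution model.

The human model is assembled from a rat fit in five steps: (1) estimate the
plasma disposition parameters from human plasma data (1/2/3-compartment
model chosen by likelihood ratio test, log-normal inter-individual
variability by a two-stage procedure); (2) replace the system-specific CNS
volumes by human physiological values; (3) scale the drug-specific brain
parameters (Q_PL_ECF, Q_DIFF) by body-weight allometry with exponent 0.75;
(4) attach the external-ventricular-drain (EVD) sampling compartment with
patient-specific drain flow and chamber volume where clinical CSF was
collected by EVD; (5) simulate to produce median predictions and 95%
prediction intervals for plasma, brain ECF and CSF sites.

Human plasma concentrations are converted to the unbound scale before
fitting (acetaminophen f_p = 0.85; morphine data are already unbound), so
the translated model carries ``f_p = 1`` and its plasma state is the
unbound concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (DoseEvent, DrugParameters, ModelStructure,
                    SystemParameters, HUMAN_SYSTEM, round_sig)
from .preprocess import StudyDataset
from .estimation import (FitResult, _Predictor, fit_naive_pooled,
                         lrt_compare)
from .validate import PredictionAssessment, simulate_prediction_interval, smape

__all__ = [
    "TranslationConfig",
    "allometric_scale",
    "fit_human_plasma",
    "build_human_model",
    "predict_human_profiles",
    "DEFAULT_EVD_RECORD",
]

#: Synthetic default EVD drain parameters (the study's per-patient values
#: are supplementary material): drain flow ~6 mL/h, small collection chamber.
DEFAULT_EVD_RECORD = {"q_lv_evd": 0.1, "v_evd": 10.0}


@dataclass
class TranslationConfig:
    """Settings for the rat -> human translation step."""

    bw_rat: float = 0.25
    bw_human: float = 70.0
    exponent: float = 0.75
    human_system: SystemParameters = HUMAN_SYSTEM
    evd_records: list[dict] = field(default_factory=list)
    plasma_model_order: int | str = "auto"
    #: covariate state used to select the rat estimate carried forward
    #: (e.g. the morphine 4 mg/kg dose-group value)
    rat_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.bw_rat > 0 and self.bw_human > 0):
            raise ValueError("body weights must be > 0")
        if not (0.0 < self.exponent <= 1.0):
            raise ValueError("allometric exponent must be in (0, 1]")


def allometric_scale(p_rat: float, bw_human: float = 70.0,
                     bw_rat: float = 0.25, exponent: float = 0.75) -> float:
    """Body-weight allometric scaling of a clearance/flow:
    ``P_human = P_rat * (BW_human / BW_rat)^exponent``."""
    if not (p_rat > 0 and bw_human > 0 and bw_rat > 0 and exponent > 0):
        raise ValueError("all inputs to allometric scaling must be > 0")
    return p_rat * (bw_human / bw_rat) ** exponent


_ORDER_FREE = {
    1: ("cl_pl", "v_pl"),
    2: ("cl_pl", "q_pl_per1", "v_pl", "v_per1"),
    3: ("cl_pl", "q_pl_per1", "q_pl_per2", "v_pl", "v_per1", "v_per2"),
}


def _plasma_structure(order: int, species: str) -> ModelStructure:
    return ModelStructure(species=species, per1=order >= 2, per2=order >= 3)


def _heuristic_init(dataset: StudyDataset, order: int) -> DrugParameters:
    rows = dataset.fitting_frame()
    cmax = float(rows["dv"].max())
    tmax = float(rows["time"].max())
    dose = float(np.mean([sum(d.amount for d in dl)
                          for dl in dataset.doses.values()]))
    v0 = max(dose / cmax, 1e-6)
    cl0 = max(v0 * np.log(2) / max(tmax / 3.0, 1.0), 1e-6)
    kw = dict(cl_pl=cl0, v_pl=v0, q_pl_ecf=0.0, q_diff=0.0)
    if order >= 2:
        kw.update(q_pl_per1=cl0, v_per1=3.0 * v0)
    if order >= 3:
        kw.update(q_pl_per2=cl0 / 2.0, v_per2=6.0 * v0)
    return DrugParameters(**kw)


def fit_human_plasma(human_plasma: StudyDataset,
                     model_order: int | str = "auto",
                     init: DrugParameters | None = None,
                     seed: int | None = 0,
                     n_starts: int = 3) -> FitResult:
    """Fit the human plasma disposition model.

    Candidate 1-, 2- and 3-compartment mammillary models are fitted by
    naive-pooled ELS; when ``model_order='auto'`` the order is chosen by
    sequential likelihood ratio tests (2 df per added compartment,
    p < 0.05).  Inter-individual variability is then quantified two-stage:
    each subject is fitted separately from the pooled estimates, the
    population value is the geometric mean and omega the SD of the
    per-subject log estimates.
    """
    rows = human_plasma.fitting_frame()
    if (rows["compartment"] != "plasma").any():
        raise ValueError("human_plasma must contain plasma observations only")
    orders = (1, 2, 3) if model_order == "auto" else (int(model_order),)
    if any(o not in (1, 2, 3) for o in orders):
        raise ValueError("model order must be 1, 2 or 3")

    fits: dict[int, FitResult] = {}
    for order in orders:
        base = init if init is not None else _heuristic_init(human_plasma, order)
        free = _ORDER_FREE[order]
        if any(getattr(base, n) is None for n in free):
            base = _heuristic_init(human_plasma, order)
        structure = _plasma_structure(order, human_plasma.species)
        fits[order] = fit_naive_pooled(
            human_plasma, structure, base, free,
            system=HUMAN_SYSTEM if human_plasma.species == "human" else None,
            seed=seed, n_starts=n_starts)

    if model_order == "auto":
        selected = 1
        for order in (2, 3):
            # tol absorbs optimizer-level noise when the richer model's
            # search terminates marginally above the nested optimum
            _, significant = lrt_compare(fits[order].ofv,
                                         fits[selected].ofv, ddf=2, tol=0.5)
            if significant:
                selected = order
            else:
                break
    else:
        selected = orders[0]
    pooled = fits[selected]
    structure = _plasma_structure(selected, human_plasma.species)
    free = _ORDER_FREE[selected]

    # two-stage IIV: per-subject fits from the pooled estimates
    subjects = human_plasma.subjects
    logs = {n: [] for n in free}
    if len(subjects) > 1:
        for subj in subjects:
            mask = human_plasma.observations["subject"] == subj
            sub = StudyDataset(
                observations=human_plasma.observations[mask].reset_index(drop=True),
                doses={subj: human_plasma.doses[subj]},
                species=human_plasma.species,
                bw={subj: human_plasma.bw.get(subj, np.nan)},
                meta=dict(human_plasma.meta))
            try:
                sfit = fit_naive_pooled(
                    sub, structure, pooled.params, free,
                    system=HUMAN_SYSTEM if human_plasma.species == "human" else None,
                    seed=seed, n_starts=1, compute_rse=False)
            except RuntimeError:
                continue
            for n in free:
                logs[n].append(np.log(sfit.estimates[n]))
        omegas = {n: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
                  for n, v in logs.items()}
        means = {n: float(np.exp(np.mean(v))) for n, v in logs.items() if v}
        params = pooled.params.updated(**means) if means else pooled.params
    else:
        omegas = {n: 0.0 for n in free}
        params = pooled.params

    return FitResult(params=params, free=free,
                     estimates={n: float(getattr(params, n)) for n in free},
                     rse=pooled.rse, ofv=pooled.ofv, sigma=pooled.sigma,
                     correlation=pooled.correlation,
                     convergence=dict(pooled.convergence,
                                      selected_order=selected),
                     n_obs=pooled.n_obs, omegas=omegas)


def build_human_model(rat_fit: FitResult | DrugParameters,
                      cfg: TranslationConfig,
                      human_plasma_fit: FitResult | DrugParameters,
                      ) -> tuple[ModelStructure, DrugParameters, SystemParameters]:
    """Assemble the translated human model triple.

    Brain drug-specific clearances from the rat fit are allometrically
    scaled and fixed (displayed/stored at 3 significant figures, the
    convention for fixed translated parameters); system volumes come from
    the human physiology in ``cfg``; plasma disposition from the human
    plasma fit.  When ``cfg.evd_records`` is non-empty the EVD compartment
    is attached with the first record (loop over records for per-patient
    structures).
    """
    rat = rat_fit.params if isinstance(rat_fit, FitResult) else rat_fit
    human = (human_plasma_fit.params if isinstance(human_plasma_fit, FitResult)
             else human_plasma_fit)
    for name in ("q_pl_ecf", "q_diff"):
        if getattr(rat, name) in (None, 0.0):
            raise ValueError(f"rat fit must provide a positive {name}")

    eff = rat.with_covariates(cfg.rat_covariates)
    q_ecf = round_sig(allometric_scale(eff.q_pl_ecf, cfg.bw_human,
                                       cfg.bw_rat, cfg.exponent), 3)
    q_diff = round_sig(allometric_scale(eff.q_diff, cfg.bw_human,
                                        cfg.bw_rat, cfg.exponent), 3)

    evd = bool(cfg.evd_records)
    rec = cfg.evd_records[0] if evd else {}
    structure = ModelStructure(
        species="human",
        per1=human.q_pl_per1 is not None,
        per2=human.q_pl_per2 is not None,
        evd=evd,
        q_lv_evd=rec.get("q_lv_evd"),
        v_evd=rec.get("v_evd"))

    params = DrugParameters(
        cl_pl=human.cl_pl, q_pl_per1=human.q_pl_per1,
        q_pl_per2=human.q_pl_per2, v_pl=human.v_pl, v_per1=human.v_per1,
        v_per2=human.v_per2, q_pl_ecf=q_ecf, q_diff=q_diff, f_p=1.0)
    return structure, params, cfg.human_system


def predict_human_profiles(model: tuple[ModelStructure, DrugParameters,
                                        SystemParameters],
                           doses: Sequence[DoseEvent],
                           times: Sequence[float],
                           n_reps: int = 200,
                           seed: int | None = 0,
                           omegas: Mapping[str, float] | None = None,
                           sigma: float | Mapping[str, float] = 0.0,
                           observations: StudyDataset | None = None,
                           initial_amounts: Mapping[str, float] | None = None,
                           ) -> PredictionAssessment:
    """Median + 95% prediction-interval bands for the human brain/CSF sites.

    Bands cover plasma, brain ECF, CSF SAS and (when attached) the EVD
    compartment.  If ``observations`` are supplied, SMAPE of the mean
    population prediction is computed per compartment.
    """
    structure, params, system = model
    comps = [c for c in ("plasma", "brain_ecf", "csf_sas", "csf_evd")
             if c in structure.compartments]
    assessment = simulate_prediction_interval(
        structure, params, system, doses, times, sigma=sigma, omegas=omegas,
        n_reps=n_reps, seed=seed, compartments=comps,
        initial_amounts=initial_amounts)
    if observations is not None:
        predictor = _Predictor(observations, structure, system)
        pred = predictor.predict(params)
        rows = observations.fitting_frame().reset_index(drop=True)
        assessment.smape_by_stream = {
            comp: smape(grp["dv"].to_numpy(),
                        pred[np.asarray(grp.index)])
            for comp, grp in rows.groupby("compartment")}
    return assessment
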