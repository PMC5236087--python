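"""Synthetic study generation emulating the rat and human designs.

The generators realize the published study designs — doses, infusion
durations, sampling windows, sampled compartments, inhibitor co-
administration arms and approximate sample counts — from the corresponding
parameter estimates, so every pipeline stage (recovery correction, ELS
fitting, external validation, translation) is testable end-to-end without
any external data.

Exact per-animal sampling schedules and per-arm counts are not published:
subjects are assigned round-robin over the dose x inhibitor arms; plasma is
drawn on front-loaded (geometric) grids and dialysate on consecutive
collection intervals inside the printed windows, at the printed approximate
totals (see the methods note for why front-loaded schedules are the
faithful reconstruction).  Dialysate streams are recorded *raw* (true concentration times the
probe recovery, then residual error), so the preprocessing correction is
exactly invertible; residual error is proportional, ``DV = pred (1 + eps)``
with the stream SDs of the source fits.  At those SDs a draw can be
negative; such records are kept (censoring them would bias estimation) and
the non-negativity guarantee applies to the noise-free concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (DoseEvent, DrugParameters, ModelStructure,
                    SystemParameters, RAT_SYSTEM, HUMAN_SYSTEM,
                    interval_subgrid, solve_profile)
from .preprocess import StudyDataset, DIALECT_COLUMNS
from .drugs import (HUMAN_DRUGS, preset_parameters, preset_structure,
                    preset_sigma, preset_recovery)

__all__ = [
    "StudyDesign",
    "default_design",
    "generate_rat_study",
    "generate_human_study",
    "to_dialect_frame",
]


@dataclass
class StudyDesign:
    """One study arm layout: who gets what, when, and what is sampled."""

    drug: str
    species: str
    n_subjects: int
    dose_levels: list[float]          # mg/kg (rat) or mg (human/absolute)
    dose_unit: str                    # "mg/kg" | "mg"
    infusion_min: float
    n_plasma: int
    plasma_window: tuple[float, float]
    n_dialysate: int
    dialysate_window: tuple[float, float]
    observed: list[str]               # compartment labels incl. "plasma"
    inhibitor: str | None = None      # inhibitor name, None if no arm
    sigma: dict[str, float] = field(default_factory=dict)
    omegas: dict[str, float] = field(default_factory=dict)
    bw: float = 0.25

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.dose_unit not in ("mg/kg", "mg"):
            raise ValueError("dose_unit must be 'mg/kg' or 'mg'")

    def to_dict(self) -> dict:
        return asdict(self)


# (n, doses, unit, infusion, n_plasma, plasma window, n_dialysate,
#  dialysate window, inhibitor) per rat drug; sampled compartments follow
# the residual-error streams of each drug's fit.
_RAT_DESIGNS = {
    "acetaminophen": (16, [16.0], "mg/kg", 10.0, 67, (0, 240), 592, (0, 240), None),
    "atenolol": (5, [10.0], "mg/kg", 1.0, 32, (0, 120), 106, (0, 120), None),
    "methotrexate": (23, [40.0, 80.0], "mg/kg", 10.0, 186, (0, 300), 1065, (0, 300), "probenecid"),
    "morphine": (65, [4.0, 10.0, 40.0], "mg/kg", 10.0, 825, (0, 360), 238, (0, 360), "GF120918"),
    "quinidine": (41, [10.0, 20.0], "mg/kg", 10.0, 313, (0, 360), 1678, (0, 360), "tariquidar"),
    "remoxipride": (29, [4.0, 8.0, 16.0], "mg/kg", 30.0, 189, (0, 240), 125, (0, 240), None),
    "paliperidone": (21, [0.5], "mg/kg", 20.0, 182, (0, 360), 660, (0, 240), "tariquidar"),
    "phenytoin": (14, [20.0, 30.0, 40.0], "mg/kg", 10.0, 109, (0, 480), 152, (0, 480), "tariquidar"),
    "risperidone": (16, [2.0], "mg/kg", 20.0, 124, (0, 360), 436, (0, 240), "tariquidar"),
}

# external-validation experiment layouts (second datasets)
_RAT_EXTERNAL = {
    "acetaminophen": (8, [200.0], "mg", 1.0, 67, (0, 180), 72, (0, 180), None),
    "remoxipride": (65, [0.7, 5.2, 14.0], "mg/kg", 10.0, 290, (0, 240), 489, (0, 240), None),
}

# (n patients, dose mg, infusion min, n plasma, plasma window, n CNS,
#  CNS window, CNS stream)
_HUMAN_DESIGNS = {
    "acetaminophen": (7, [1000.0], 30.0, 38, (0, 360), 54, (0, 330), "csf_evd"),
    "morphine": (2, [10.0], 10.0, 23, (0, 180), 74, (0, 180), "brain_ecf"),
}


def default_design(drug: str, species: str = "rat",
                   variant: str = "development") -> StudyDesign:
    """The published design for a drug/species pair.

    ``variant='external'`` selects the second (external-validation) rat
    experiment for acetaminophen and remoxipride.
    """
    if species == "rat":
        table = _RAT_EXTERNAL if variant == "external" else _RAT_DESIGNS
        if drug not in table:
            raise KeyError(f"no rat {variant} design for {drug!r}")
        n, doses, unit, inf, n_pl, w_pl, n_dial, w_dial, inhib = table[drug]
        return StudyDesign(
            drug=drug, species="rat", n_subjects=n, dose_levels=list(doses),
            dose_unit=unit, infusion_min=inf, n_plasma=n_pl,
            plasma_window=w_pl, n_dialysate=n_dial, dialysate_window=w_dial,
            observed=list(preset_sigma(drug)), inhibitor=inhib,
            sigma=preset_sigma(drug), bw=0.25)
    if species == "human":
        if drug not in _HUMAN_DESIGNS:
            raise KeyError(f"{drug!r} is not one of the human study drugs "
                           f"({sorted(_HUMAN_DESIGNS)})")
        n, doses, inf, n_pl, w_pl, n_cns, w_cns, stream = _HUMAN_DESIGNS[drug]
        return StudyDesign(
            drug=drug, species="human", n_subjects=n, dose_levels=list(doses),
            dose_unit="mg", infusion_min=inf, n_plasma=n_pl,
            plasma_window=w_pl, n_dialysate=n_cns, dialysate_window=w_cns,
            observed=["plasma", stream], inhibitor=None,
            sigma=preset_sigma(drug, "human"),
            omegas=dict(HUMAN_DRUGS[drug]["omegas"]), bw=70.0)
    raise KeyError(f"unknown species {species!r}")


def _grid(window: tuple[float, float], count: int,
          first: float = 2.0) -> np.ndarray:
    """Front-loaded (log-spaced) point-sampling grid inside a window.

    Serial blood sampling concentrates draws in the infusion and
    distribution phases (the first draw at ~2 min, during the infusion);
    samples run from ``first`` to the end of the window on a geometric
    grid.  This layout reproduces the reported precision of the plasma and
    BBB-transfer parameters, which even late-start grids cannot.
    """
    lo, hi = window
    count = max(2, count)
    return np.geomspace(max(first, lo + first), hi, count)


def _bins(window: tuple[float, float], count: int):
    """Consecutive collection intervals covering the window, front-loaded.

    Microdialysis (and ventricular-drain) samples are collected over
    consecutive intervals starting at the dosing instant; collection
    intervals are short (10 min) over the first hour to resolve the
    distribution transient, then widen to cover the rest of the window with
    the remaining sample count.  Returns (midpoints, widths).
    """
    lo, hi = window
    count = max(2, count)
    early_span = min(60.0, (hi - lo) / 2.0)
    n_early = min(count - 1, max(1, int(round(early_span / 10.0))))
    split = lo + 10.0 * n_early
    edges = np.unique(np.concatenate([
        np.linspace(lo, split, n_early + 1),
        np.linspace(split, hi, count - n_early + 1)]))
    return 0.5 * (edges[:-1] + edges[1:]), np.diff(edges)


def _bin_average(times: np.ndarray, conc: np.ndarray, mids: np.ndarray,
                 widths: np.ndarray) -> np.ndarray:
    """Trapezoid interval averages of a solved profile at the bin grid."""
    out = np.empty(len(mids))
    pos = {t: j for j, t in enumerate(times)}
    for i, (m, width) in enumerate(zip(mids, widths)):
        sub, w = interval_subgrid(float(m), float(width))
        out[i] = float(np.sum(conc[[pos[t] for t in sub]] * w))
    return out


def _dose_amount_ng(dose: float, unit: str, bw: float) -> float:
    mg = dose * bw if unit == "mg/kg" else dose
    return mg * 1e6


def _arm_assignments(design: StudyDesign) -> list[tuple[float, int]]:
    """Per-subject (dose level, inhibitor flag), round-robin over arms."""
    arms = [(d, i) for i in ([0, 1] if design.inhibitor else [0])
            for d in design.dose_levels]
    return [arms[k % len(arms)] for k in range(design.n_subjects)]


def _grp_label(value: float) -> str:
    return str(int(value)) if float(value) == int(value) else str(value)


def generate_rat_study(design: StudyDesign,
                       params: DrugParameters | None = None,
                       structure: ModelStructure | None = None,
                       seed: int = 0,
                       recovery: Mapping[str, float] | None = None,
                       system: SystemParameters = RAT_SYSTEM) -> StudyDataset:
    """Simulate one rat microdialysis experiment.

    True profiles come from the exact solver with the subject's arm
    covariates applied (inhibitor flag, dose group); dialysate streams are
    attenuated by the probe recovery before residual error is added and are
    recorded with assay kind ``dialysate`` so preprocessing can invert the
    attenuation.  Deterministic for a given ``seed``; the generating truth,
    recovery constants and design are stored in ``meta``.
    """
    params = params if params is not None else preset_parameters(design.drug)
    structure = structure if structure is not None else preset_structure(design.drug)
    recovery = dict(recovery if recovery is not None
                    else preset_recovery(design.drug))
    rng = np.random.default_rng(seed)

    dial_streams = [s for s in design.observed if s != "plasma"]
    n_pl = max(2, round(design.n_plasma / design.n_subjects))
    n_dl = max(2, round(design.n_dialysate /
                        (design.n_subjects * max(len(dial_streams), 1))))
    t_pl = _grid(design.plasma_window, n_pl)
    t_dl, dl_widths = _bins(design.dialysate_window, n_dl)
    sub_times = np.concatenate([interval_subgrid(float(m), float(w))[0]
                                for m, w in zip(t_dl, dl_widths)])
    times = np.unique(np.concatenate([t_pl, sub_times]))

    records = []
    doses: dict[str, list[DoseEvent]] = {}
    bw_map: dict[str, float] = {}
    for k, (dose, inhib) in enumerate(_arm_assignments(design)):
        subj = f"R{k + 1:03d}"
        amount = _dose_amount_ng(dose, design.dose_unit, design.bw)
        dose_ev = DoseEvent(start=0.0, duration=design.infusion_min,
                            amount=amount)
        doses[subj] = [dose_ev]
        bw_map[subj] = design.bw
        grp = _grp_label(dose)
        cov = {"inhibitor": float(inhib), f"dosegrp_{grp}": 1.0}
        prof = solve_profile(structure, params, system, [dose_ev], times,
                             covariates=cov)
        c_pl = np.interp(t_pl, times, prof.conc("plasma"))
        eps = rng.normal(0.0, design.sigma.get("plasma", 0.0), len(t_pl))
        for t, c, e in zip(t_pl, c_pl, eps):
            records.append(dict(subject=subj, drug=design.drug, time=float(t),
                                compartment="plasma", dv=float(c * (1 + e)),
                                assay="total", below_lloq=False,
                                exclude=False, inhibitor=inhib, dosegrp=grp,
                                duration=0.0))
        for s in dial_streams:
            c_s = _bin_average(times, prof.conc(s), t_dl, dl_widths) * recovery[s]
            eps = rng.normal(0.0, design.sigma.get(s, 0.0), len(t_dl))
            for t, c, e, bw_ in zip(t_dl, c_s, eps, dl_widths):
                records.append(dict(subject=subj, drug=design.drug,
                                    time=float(t), compartment=s,
                                    dv=float(c * (1 + e)), assay="dialysate",
                                    below_lloq=False, exclude=False,
                                    inhibitor=inhib, dosegrp=grp,
                                    duration=float(bw_)))

    obs = pd.DataFrame.from_records(records)
    meta = dict(truth=params, structure=structure, recovery=recovery,
                design=design, seed=seed)
    return StudyDataset(observations=obs, doses=doses, species="rat",
                        bw=bw_map, meta=meta)


def generate_human_study(design: StudyDesign,
                         params: DrugParameters | None = None,
                         structure: ModelStructure | None = None,
                         seed: int = 0,
                         evd: Mapping[str, float] | None = None,
                         system: SystemParameters = HUMAN_SYSTEM) -> StudyDataset:
    """Simulate one clinical study (plasma + one CNS stream per patient).

    Patient-level parameters are drawn log-normally with the design's
    inter-individual SDs; plasma concentrations are on the unbound scale
    (assay ``unbound``), CSF/brain samples are direct (no probe recovery).
    When the CNS stream is ``csf_evd`` the drain compartment is attached
    with the supplied (or synthetic default) drain flow and volume.
    """
    from .translate import DEFAULT_EVD_RECORD
    params = params if params is not None else preset_parameters(design.drug, "human")
    if structure is None:
        cns = [s for s in design.observed if s != "plasma"]
        use_evd = "csf_evd" in cns
        rec = dict(evd) if evd else dict(DEFAULT_EVD_RECORD)
        structure = ModelStructure(
            species="human", per1=params.q_pl_per1 is not None,
            per2=params.q_pl_per2 is not None, evd=use_evd,
            q_lv_evd=rec["q_lv_evd"] if use_evd else None,
            v_evd=rec["v_evd"] if use_evd else None)
    rng = np.random.default_rng(seed)

    cns_streams = [s for s in design.observed if s != "plasma"]
    n_pl = max(2, round(design.n_plasma / design.n_subjects))
    n_cns = max(2, round(design.n_dialysate /
                         (design.n_subjects * max(len(cns_streams), 1))))
    t_pl = _grid(design.plasma_window, n_pl)
    t_cns, cns_widths = _bins(design.dialysate_window, n_cns)
    sub_times = np.concatenate([interval_subgrid(float(m), float(w))[0]
                                for m, w in zip(t_cns, cns_widths)])
    times = np.unique(np.concatenate([t_pl, sub_times]))

    records = []
    doses: dict[str, list[DoseEvent]] = {}
    bw_map: dict[str, float] = {}
    subject_params: dict[str, DrugParameters] = {}
    for k in range(design.n_subjects):
        subj = f"H{k + 1:03d}"
        dose = design.dose_levels[k % len(design.dose_levels)]
        amount = _dose_amount_ng(dose, design.dose_unit, design.bw)
        dose_ev = DoseEvent(start=0.0, duration=design.infusion_min,
                            amount=amount)
        doses[subj] = [dose_ev]
        bw_map[subj] = design.bw
        draws = {n: float(getattr(params, n) * np.exp(rng.normal(0.0, w)))
                 for n, w in design.omegas.items()}
        p_i = params.updated(**draws) if draws else params
        subject_params[subj] = p_i
        prof = solve_profile(structure, p_i, system, [dose_ev], times)
        c_pl = np.interp(t_pl, times, prof.conc("plasma"))
        eps = rng.normal(0.0, design.sigma.get("plasma", 0.0), len(t_pl))
        for t, c, e in zip(t_pl, c_pl, eps):
            records.append(dict(subject=subj, drug=design.drug, time=float(t),
                                compartment="plasma", dv=float(c * (1 + e)),
                                assay="unbound", below_lloq=False,
                                exclude=False, inhibitor=0, dosegrp="",
                                duration=0.0))
        for s in cns_streams:
            c_s = _bin_average(times, prof.conc(s), t_cns, cns_widths)
            eps = rng.normal(0.0, design.sigma.get(s, 0.0), len(t_cns))
            for t, c, e, bw_ in zip(t_cns, c_s, eps, cns_widths):
                records.append(dict(subject=subj, drug=design.drug,
                                    time=float(t), compartment=s,
                                    dv=float(c * (1 + e)), assay="unbound",
                                    below_lloq=False, exclude=False,
                                    inhibitor=0, dosegrp="",
                                    duration=float(bw_)))

    obs = pd.DataFrame.from_records(records)
    meta = dict(truth=params, structure=structure, design=design, seed=seed,
                subject_params=subject_params)
    return StudyDataset(observations=obs, doses=doses, species="human",
                        bw=bw_map, meta=meta)


def to_dialect_frame(dataset: StudyDataset) -> pd.DataFrame:
    """Serialize a generated dataset to the standard CSV dialect (one
    dosing row per infusion, observation rows with DV)."""
    drug = (dataset.meta.get("design").drug
            if dataset.meta.get("design") else
            dataset.observations["drug"].iloc[0])
    rows = []
    for subj in dataset.subjects:
        bw = dataset.bw.get(subj, np.nan)
        sub_obs = dataset.observations[dataset.observations["subject"] == subj]
        inhib = int(sub_obs["inhibitor"].iloc[0]) if len(sub_obs) else 0
        grp = sub_obs["dosegrp"].iloc[0] if len(sub_obs) else ""
        for d in dataset.doses[subj]:
            rows.append(dict(SUBJECT=subj, DRUG=drug, SPECIES=dataset.species,
                             BW_KG=bw, TIME_MIN=d.start, CMT="plasma",
                             DV_NGML=np.nan, ASSAY=np.nan,
                             AMT_MGKG=d.amount / 1e6 / bw, INF_MIN=d.duration,
                             INHIBITOR=inhib, DOSEGRP=grp, LLOQ_NGML=np.nan,
                             DUR_MIN=0.0))
        for r in sub_obs.itertuples(index=False):
            rows.append(dict(SUBJECT=subj, DRUG=drug, SPECIES=dataset.species,
                             BW_KG=bw, TIME_MIN=r.time, CMT=r.compartment,
                             DV_NGML=r.dv, ASSAY=r.assay, AMT_MGKG=np.nan,
                             INF_MIN=np.nan, INHIBITOR=r.inhibitor,
                             DOSEGRP=r.dosegrp, LLOQ_NGML=np.nan,
                             DUR_MIN=r.duration))
    return pd.DataFrame(rows, columns=DIALECT_COLUMNS + ["DUR_MIN"])
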