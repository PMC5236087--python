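"""Prediction-accuracy metrics and simulation-based prediction intervals.

Prediction error uses the symmetric form PE = (obs - pred) / ((obs + pred)/2)
whose mean absolute value (x100) is the symmetric mean absolute percentage
error (SMAPE), bounded by 200%.  Prediction intervals are empirical
percentile bands from repeated simulation (default 200 replicates): each
replicate draws subject-level parameters from the log-normal
inter-individual distribution and residual error from the proportional or
mixed model, and the 2.5/50/97.5 percentiles per time point form the band.

The external-validation workflow re-estimates the plasma disposition
parameters on a new plasma dataset, holds the brain-related parameters at
their previously estimated values, and scores the resulting brain/CSF
predictions by SMAPE per compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (DoseEvent, DrugParameters, ModelStructure,
                    SystemParameters, solve_profile)
from .preprocess import StudyDataset
from .estimation import FitResult, _Predictor, fit_naive_pooled

__all__ = [
    "PredictionAssessment",
    "prediction_error",
    "smape",
    "simulate_prediction_interval",
    "external_validation",
    "dose_normalize",
]


@dataclass
class PredictionAssessment:
    """Per-observation errors, per-stream SMAPE and/or percentile bands."""

    times: np.ndarray | None = None
    bands: dict[str, np.ndarray] = field(default_factory=dict)  # comp -> (3, n)
    smape_by_stream: dict[str, float] = field(default_factory=dict)
    pe: pd.DataFrame | None = None
    plasma_fit: FitResult | None = None

    def bands_frame(self) -> pd.DataFrame:
        """Long-format bands table (TIME_MIN, CMT, P2.5, P50, P97.5)."""
        rows = []
        for comp, b in self.bands.items():
            for j, t in enumerate(self.times):
                rows.append((t, comp, b[0, j], b[1, j], b[2, j]))
        return pd.DataFrame(rows, columns=["TIME_MIN", "CMT", "P2.5", "P50",
                                           "P97.5"])


def prediction_error(obs, pred):
    """Symmetric prediction error, sign-preserving and bounded by +/-2."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    denom = 0.5 * (obs + pred)
    if np.any(denom <= 0):
        raise ValueError("obs + pred must be > 0 for the symmetric "
                         "prediction error")
    out = (obs - pred) / denom
    return float(out) if out.ndim == 0 else out


def smape(observations, predictions) -> float:
    """Symmetric mean absolute percentage error (%), in [0, 200]."""
    obs = np.atleast_1d(np.asarray(observations, dtype=float))
    pred = np.atleast_1d(np.asarray(predictions, dtype=float))
    if obs.shape != pred.shape:
        raise ValueError("observations and predictions must have equal length")
    if obs.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(prediction_error(obs, pred))) * 100.0)


def dose_normalize(dv, dose_amount):
    """Scale concentrations by dose for multi-dose overlay plots."""
    if not dose_amount > 0:
        raise ValueError("dose amount must be > 0")
    return np.asarray(dv, dtype=float) / dose_amount


def simulate_prediction_interval(structure: ModelStructure,
                                 params: DrugParameters,
                                 system: SystemParameters,
                                 doses: Sequence[DoseEvent],
                                 times: Sequence[float],
                                 sigma: float | Mapping[str, float] = 0.0,
                                 omegas: Mapping[str, float] | None = None,
                                 n_reps: int = 200,
                                 seed: int | None = 0,
                                 compartments: Sequence[str] | None = None,
                                 sigma_add: float = 0.0,
                                 initial_amounts: Mapping[str, float] | None = None,
                                 ) -> PredictionAssessment:
    """Empirical 95% prediction-interval bands by repeated simulation.

    Each of ``n_reps`` replicates draws a subject-level parameter set
    (log-normal deviations with SDs ``omegas``) and a residual-error
    realization at every time point (proportional SD ``sigma`` per stream,
    optional additive ``sigma_add``), then the 2.5th, 50th and 97.5th
    percentiles per time point and compartment are computed with linear
    interpolation between order statistics.  Deterministic given ``seed``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    times = np.asarray(times, dtype=float)
    omegas = dict(omegas or {})
    rng = np.random.default_rng(seed)
    comps = list(compartments) if compartments else list(structure.compartments)

    def sig_for(comp: str) -> float:
        if isinstance(sigma, Mapping):
            return float(sigma.get(comp, 0.0))
        return float(sigma)

    no_iiv = all(w == 0 for w in omegas.values()) or not omegas
    sims = {c: np.empty((n_reps, len(times))) for c in comps}
    base_prof = None
    if no_iiv:
        base_prof = solve_profile(structure, params, system, doses, times,
                                  initial_amounts=initial_amounts)
    for r in range(n_reps):
        if no_iiv:
            prof = base_prof
        else:
            draws = {n: float(getattr(params, n) * np.exp(rng.normal(0.0, w)))
                     for n, w in omegas.items()}
            prof = solve_profile(structure, params.updated(**draws), system,
                                 doses, times, initial_amounts=initial_amounts)
        for c in comps:
            conc = prof.conc(c)
            s = sig_for(c)
            dv = conc * (1.0 + rng.normal(0.0, s, len(times))) if s > 0 else conc.copy()
            if sigma_add > 0:
                dv = dv + rng.normal(0.0, sigma_add, len(times))
            sims[c][r] = dv

    bands = {c: np.percentile(sims[c], [2.5, 50.0, 97.5], axis=0)
             for c in comps}
    return PredictionAssessment(times=times, bands=bands)


BRAIN_STREAMS = ("brain_ecf", "brain_icf", "csf_lv", "csf_tfv", "csf_cm",
                 "csf_sas", "csf_evd")

PLASMA_FREE_DEFAULT = ("cl_pl", "q_pl_per1", "v_pl", "v_per1")


def external_validation(plasma_data: StudyDataset,
                        brain_fixed: DrugParameters,
                        structure: ModelStructure,
                        system: SystemParameters,
                        brain_obs: StudyDataset,
                        free: Sequence[str] = PLASMA_FREE_DEFAULT,
                        seed: int | None = 0,
                        n_starts: int = 3) -> PredictionAssessment:
    """External-validation workflow on a new dataset.

    1) re-estimate the plasma disposition parameters from ``plasma_data``
    (plasma observations only); 2) hold the brain-related parameters
    (``q_pl_ecf``, ``q_diff`` and the physiological volumes) at the values in
    ``brain_fixed``/``system``; 3) predict the brain/CSF observations in
    ``brain_obs`` and report per-observation prediction errors and SMAPE per
    compartment.
    """
    if not len(brain_obs.fitting_frame()):
        raise ValueError("brain_obs contains no includable observations")
    pl_rows = plasma_data.fitting_frame()
    if (pl_rows["compartment"] != "plasma").any():
        raise ValueError("plasma_data must contain only plasma observations")

    free = tuple(n for n in free if getattr(brain_fixed, n) is not None)
    fit = fit_naive_pooled(plasma_data, structure, brain_fixed,
                           free, system=system, seed=seed, n_starts=n_starts)

    predictor = _Predictor(brain_obs, structure, system)
    pred = predictor.predict(fit.params)
    rows = brain_obs.fitting_frame().reset_index(drop=True)
    obs = rows["dv"].to_numpy()
    # the symmetric error is only defined (and bounded) for positive pairs;
    # heavily noise-corrupted records can carry non-positive measurements
    valid = (obs > 0) & (pred > 0)
    pe = np.full(len(obs), np.nan)
    pe[valid] = prediction_error(obs[valid], pred[valid])
    pe_frame = pd.DataFrame({
        "subject": rows["subject"], "time": rows["time"],
        "compartment": rows["compartment"], "obs": obs,
        "pred": pred, "pe": pe})
    pe_frame = pe_frame[valid].reset_index(drop=True)
    smapes = {comp: smape(grp["obs"], grp["pred"])
              for comp, grp in pe_frame.groupby("compartment")
              if comp in BRAIN_STREAMS}
    return PredictionAssessment(pe=pe_frame, smape_by_stream=smapes,
                                plasma_fit=fit)
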