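"""Naive-pooled extended least squares estimation.

All subjects' records are fitted as if from a single subject (no
inter-individual random effects), minimizing the extended least squares
objective

    OFV = sum_ij [ (Y_obs,ij - Y_pred,ij)^2 / var_ij + ln var_ij ]

which is -2 log likelihood up to a constant under normal residuals.  The
residual variance follows a proportional (var = sigma^2 pred^2) or mixed
(var = sigma1^2 pred^2 + sigma2^2) error model with a separate proportional
SD per observation stream (plasma, brain ECF, each CSF site).  For purely
proportional models the stream SDs are profiled out in closed form, so the
numerical search runs over the structural parameters only (in log space,
multi-start).  Standard errors come from the finite-difference Hessian of
the (profiled) objective; nested models are compared with a likelihood
ratio test on OFV differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .model import (DrugParameters, ModelStructure, SystemParameters,
                    interval_subgrid, solve_profile)
from .preprocess import StudyDataset

__all__ = [
    "ErrorModel",
    "CovariateEffect",
    "IIVModel",
    "FitResult",
    "apply_covariate",
    "residual_variance",
    "els_objective",
    "fit_naive_pooled",
    "lrt_compare",
    "iiv_realize",
]


@dataclass(frozen=True)
class ErrorModel:
    """Residual error magnitudes per observation stream.

    ``sigma_prop`` is either one proportional SD for all streams or a
    mapping ``stream -> SD``; ``sigma_add`` (ng/mL) is the additive SD of
    the mixed model and must be positive when ``kind='mixed'``.
    """

    kind: str = "proportional"
    sigma_prop: float | Mapping[str, float] = 0.3
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "mixed"):
            raise ValueError("kind must be 'proportional' or 'mixed'")
        sigmas = (self.sigma_prop.values()
                  if isinstance(self.sigma_prop, Mapping) else [self.sigma_prop])
        if any(s < 0 for s in sigmas) or self.sigma_add < 0:
            raise ValueError("sigma values must be >= 0")
        if self.kind == "mixed" and not self.sigma_add > 0:
            raise ValueError("mixed error model requires sigma_add > 0")
        if isinstance(self.sigma_prop, Mapping):
            object.__setattr__(self, "sigma_prop", dict(self.sigma_prop))

    def sigma_for(self, stream: str | None = None) -> float:
        if isinstance(self.sigma_prop, Mapping):
            if stream is None:
                raise ValueError("stream required for per-stream error model")
            return self.sigma_prop[stream]
        return float(self.sigma_prop)


@dataclass(frozen=True)
class CovariateEffect:
    """Categorical covariate effect ``P = P_pat * (1 + theta * cov)``."""

    parameter: str
    covariate: str
    theta: float

    def __post_init__(self) -> None:
        if self.theta <= -1.0:
            raise ValueError("theta must exceed -1 to keep the parameter "
                             "positive")

    def apply(self, p_pat: float, cov: float) -> float:
        return apply_covariate(p_pat, self.theta, cov)


@dataclass(frozen=True)
class IIVModel:
    """Log-normal inter-individual variability on one parameter."""

    parameter: str
    omega: float

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


def apply_covariate(p_pat: float, theta_cov: float, cov: float) -> float:
    """Scale a transport parameter by a categorical covariate:
    ``P = P_pat * (1 + theta * cov)`` (cov = 1 with inhibitor, 0 without)."""
    if not p_pat > 0:
        raise ValueError("P_pat must be > 0")
    out = p_pat * (1.0 + theta_cov * cov)
    if out <= 0:
        raise ValueError("covariate effect drives the parameter non-positive")
    return out


def residual_variance(pred: float | np.ndarray, error_model: ErrorModel,
                      stream: str | None = None) -> float | np.ndarray:
    """Residual variance ((ng/mL)^2) at a predicted concentration."""
    s = error_model.sigma_for(stream)
    var = (s * s) * np.square(pred)
    if error_model.kind == "mixed":
        var = var + error_model.sigma_add ** 2
    return var


def iiv_realize(theta: float, omega: float, seed=None) -> float:
    """Draw one subject-level parameter ``theta * exp(eta)``,
    ``eta ~ N(0, omega^2)``."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if omega == 0:
        return theta
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return theta * float(np.exp(rng.normal(0.0, omega)))


def lrt_compare(ofv_full: float, ofv_reduced: float, ddf: int = 1,
                alpha: float = 0.05, tol: float = 1e-6):
    """Likelihood ratio test between nested models.

    Returns ``(delta_ofv, significant)`` where the full (larger) model is a
    significant improvement iff the OFV drop reaches the chi-square
    ``1 - alpha`` quantile at ``ddf`` degrees of freedom (3.84 for one
    parameter at p < 0.05).
    """
    if ddf < 1:
        raise ValueError("ddf must be >= 1")
    delta = ofv_reduced - ofv_full
    if delta < -tol:
        raise ValueError(f"negative delta-OFV ({delta:.4g}): the models do "
                         "not appear to be nested / the full fit is worse")
    threshold = chi2.ppf(1.0 - alpha, ddf)
    return delta, bool(delta >= threshold)


# ---------------------------------------------------------------------------
# prediction engine


class _Predictor:
    """Maps a dataset once into simulation groups for fast repeated
    prediction.  Subjects sharing dosing and covariates share one solve."""

    def __init__(self, dataset: StudyDataset, structure: ModelStructure,
                 system: SystemParameters):
        self.structure = structure
        self.system = system
        rows = dataset.fitting_frame()
        if not len(rows):
            raise ValueError("dataset has no includable observations")
        subj_cov = {s: dataset.covariates_for(s) for s in dataset.subjects}
        enabled = set(structure.compartments)
        bad = set(rows["compartment"].unique()) - enabled
        if bad:
            raise ValueError(f"observations in compartments not enabled in "
                             f"the structure: {sorted(bad)}")

        keys = {}
        for i, r in enumerate(rows.itertuples(index=False)):
            subj = r.subject
            dose_key = tuple((d.start, d.duration, d.amount)
                             for d in dataset.doses[subj])
            cov = subj_cov[subj]
            key = (dose_key, tuple(sorted(cov.items())))
            if key not in keys:
                keys[key] = dict(doses=dataset.doses[subj], covariates=cov,
                                 records=[])
            keys[key]["records"].append(
                (i, r.time, r.compartment, r.dv, r.assay,
                 getattr(r, "duration", 0.0)))

        self.n_obs = len(rows)
        self.dv = np.empty(self.n_obs)
        self.stream = np.empty(self.n_obs, dtype=object)
        self.groups = []
        for g in keys.values():
            recs = g["records"]
            # each record maps to a weighted average of the profile over its
            # collection interval (a single point when duration == 0)
            expanded = []
            all_times = []
            for (i, t, comp, dv, assay, dur) in recs:
                self.dv[i] = dv
                self.stream[i] = comp
                unbound = (comp == "plasma" and assay in
                           ("unbound", "corrected_unbound"))
                sub, w = interval_subgrid(t, dur)
                expanded.append((i, comp, sub, w, unbound))
                all_times.append(sub)
            times = np.unique(np.concatenate(all_times))
            t_pos = {t: j for j, t in enumerate(times)}
            by_key: dict[tuple[str, int], list] = {}
            for (i, comp, sub, w, unbound) in expanded:
                by_key.setdefault((comp, len(sub)), []).append(
                    (i, [t_pos[t] for t in sub], w, unbound))
            slices = []
            for (comp, _), items in by_key.items():
                out_idx = np.array([i for i, _, _, _ in items])
                t_idx = np.array([j for _, j, _, _ in items])  # (R, K)
                wts = np.array([w for _, _, w, _ in items])    # (R, K)
                unb = np.array([u for _, _, _, u in items])
                slices.append((comp, t_idx, wts, out_idx, unb))
            self.groups.append(dict(doses=g["doses"],
                                    covariates=g["covariates"],
                                    times=times, slices=slices))
        self.stream_masks = {s: self.stream == s
                             for s in np.unique(self.stream)}

    def predict(self, params: DrugParameters) -> np.ndarray:
        pred = np.empty(self.n_obs)
        for g in self.groups:
            prof = solve_profile(self.structure, params, self.system,
                                 g["doses"], g["times"],
                                 covariates=g["covariates"])
            for comp, t_idx, wts, out_idx, unb in g["slices"]:
                conc = prof.conc(comp)
                c = np.sum(conc[t_idx] * wts, axis=1)
                c = np.where(unb, c * params.f_p, c)
                pred[out_idx] = c
        return pred


def _ofv_fixed_sigma(dv, pred, stream, error_model: ErrorModel,
                     floor_var: float) -> float:
    ofv = 0.0
    for s in np.unique(stream):
        m = stream == s
        var = residual_variance(pred[m], error_model, s)
        var = np.maximum(var, floor_var)
        res = dv[m] - pred[m]
        ofv += float(np.sum(res * res / var + np.log(var)))
    return ofv


def _ofv_profiled(dv, pred, stream_masks, pred_floor: float):
    """Proportional-error OFV with the per-stream SDs profiled out
    (sigma_hat^2_s = mean(res^2 / pred^2))."""
    ofv = 0.0
    sig = {}
    for s, m in stream_masks.items():
        w = np.maximum(np.abs(pred[m]), pred_floor)
        res = dv[m] - pred[m]
        n = int(m.sum())
        s2 = float(np.mean((res / w) ** 2))
        s2 = max(s2, 1e-12)
        ofv += n * (1.0 + np.log(s2)) + 2.0 * float(np.sum(np.log(w)))
        sig[s] = float(np.sqrt(s2))
    return float(ofv), sig


def els_objective(dataset: StudyDataset, params: DrugParameters,
                  error_model: ErrorModel, structure: ModelStructure,
                  system: SystemParameters,
                  floor_rel: float = 1e-6) -> float:
    """Extended least squares objective for one parameter vector.

    Naive pooling: every includable record contributes
    ``res^2/var + ln var`` with the variance from ``error_model``
    (floored at ``(floor_rel * max DV)^2`` to keep ``ln var`` finite as
    predictions approach zero).
    """
    predictor = _Predictor(dataset, structure, system)
    pred = predictor.predict(params)
    if not np.all(np.isfinite(pred)):
        bad = int(np.argmax(~np.isfinite(pred)))
        raise RuntimeError(f"non-finite prediction for record {bad} "
                           f"(stream {predictor.stream[bad]})")
    floor_var = (floor_rel * float(np.max(np.abs(predictor.dv)))) ** 2
    return _ofv_fixed_sigma(predictor.dv, pred, predictor.stream,
                            error_model, floor_var)


@dataclass
class FitResult:
    """Estimation outcome: point estimates, precision and diagnostics."""

    params: DrugParameters
    free: tuple[str, ...]
    estimates: dict[str, float]
    rse: dict[str, float]
    ofv: float
    sigma: dict[str, float]
    correlation: np.ndarray | None
    convergence: dict
    n_obs: int
    omegas: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "rse_percent": self.rse,
            "ofv": self.ofv,
            "sigma": self.sigma,
            "omegas": self.omegas,
            "correlation": (self.correlation.tolist()
                            if self.correlation is not None else None),
            "free": list(self.free),
            "convergence": {k: v for k, v in self.convergence.items()
                            if not isinstance(v, np.ndarray)},
            "n_obs": self.n_obs,
            "parameters": self.params.to_dict(),
        }


def _finite_diff_hessian(f, x, h=1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h
                xm = x.copy(); xm[i] -= h
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h ** 2
            else:
                xpp = x.copy(); xpp[i] += h; xpp[j] += h
                xpm = x.copy(); xpm[i] += h; xpm[j] -= h
                xmp = x.copy(); xmp[i] -= h; xmp[j] += h
                xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h ** 2)
    return H


def fit_naive_pooled(dataset: StudyDataset, structure: ModelStructure,
                     init: DrugParameters, free: Sequence[str],
                     system: SystemParameters | None = None,
                     error_model: ErrorModel | None = None,
                     seed: int | None = 0, n_starts: int = 3,
                     jitter: float = 0.25, maxiter: int = 400,
                     compute_rse: bool = True) -> FitResult:
    """Fit the model to pooled data by extended least squares.

    ``free`` names the :class:`DrugParameters` fields to estimate (all in
    log space; everything else, including the physiological volumes held in
    ``system``, stays fixed).  When ``error_model`` is ``None`` the
    per-stream proportional SDs are estimated by closed-form profiling.
    Optimization is multi-start L-BFGS-B from ``n_starts`` jittered
    initials; relative standard errors (%) come from the inverse Hessian of
    the objective at the optimum.
    """
    from .model import RAT_SYSTEM
    system = system or RAT_SYSTEM
    free = tuple(free)
    for name in free:
        v = getattr(init, name)
        if v is None or not v > 0:
            raise ValueError(f"free parameter {name!r} needs a positive "
                             "initial value")
    predictor = _Predictor(dataset, structure, system)
    dv_scale = float(np.max(np.abs(predictor.dv)))
    pred_floor = 1e-6 * dv_scale
    floor_var = pred_floor ** 2
    profiled = error_model is None

    def build(x: np.ndarray) -> DrugParameters:
        return init.updated(**{n: float(np.exp(v)) for n, v in zip(free, x)})

    def objective(x: np.ndarray) -> float:
        if np.any(np.abs(x) > 50):
            return 1e12
        try:
            pred = predictor.predict(build(x))
        except (RuntimeError, ValueError, FloatingPointError):
            return 1e12
        if not np.all(np.isfinite(pred)):
            return 1e12
        if profiled:
            ofv, _ = _ofv_profiled(predictor.dv, pred,
                                   predictor.stream_masks, pred_floor)
        else:
            ofv = _ofv_fixed_sigma(predictor.dv, pred, predictor.stream,
                                   error_model, floor_var)
        return ofv if np.isfinite(ofv) else 1e12

    x0 = np.log([getattr(init, n) for n in free])
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0.0, jitter, len(free))
                     for _ in range(max(0, n_starts - 1))]
    best = None
    for s in starts:
        res = optimize.minimize(objective, s, method="L-BFGS-B",
                                options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("fit failed to produce a finite objective")

    xhat = best.x
    params_hat = build(xhat)
    pred = predictor.predict(params_hat)
    if profiled:
        ofv, sigma = _ofv_profiled(predictor.dv, pred,
                                   predictor.stream_masks, pred_floor)
    else:
        ofv = _ofv_fixed_sigma(predictor.dv, pred, predictor.stream,
                               error_model, floor_var)
        sigma = ({s: error_model.sigma_for(s)
                  for s in predictor.stream_masks}
                 if isinstance(error_model.sigma_prop, Mapping)
                 else {s: error_model.sigma_for()
                       for s in predictor.stream_masks})

    rse: dict[str, float] = {}
    corr = None
    hess_pd = None
    if compute_rse:
        H = _finite_diff_hessian(objective, xhat)
        try:
            cov = 2.0 * np.linalg.inv(H)
            diag = np.diag(cov)
            hess_pd = bool(np.all(diag > 0))
            if hess_pd:
                se = np.sqrt(diag)
                rse = {n: 100.0 * float(s) for n, s in zip(free, se)}
                corr = cov / np.outer(se, se)
            else:
                rse = {n: float("nan") for n in free}
        except np.linalg.LinAlgError:
            hess_pd = False
            rse = {n: float("nan") for n in free}

    boundary = [n for n, v in zip(free, xhat) if abs(v) > 45]
    degenerate = [s for s, m in predictor.stream_masks.items()
                  if float(np.max(np.abs(pred[m]))) <= pred_floor]
    convergence = dict(success=bool(best.success), message=str(best.message),
                       n_iter=int(best.nit), n_starts=len(starts),
                       hessian_positive_definite=hess_pd,
                       boundary_parameters=boundary,
                       degenerate_streams=degenerate)
    estimates = {n: float(getattr(params_hat, n)) for n in free}
    return FitResult(params=params_hat, free=free, estimates=estimates,
                     rse=rse, ofv=float(ofv), sigma=sigma, correlation=corr,
                     convergence=convergence, n_obs=predictor.n_obs)
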