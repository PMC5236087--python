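"""Compartmental CNS distribution model core.

The model tracks drug amounts in plasma, up to two peripheral compartments,
brain extracellular fluid (ECF), optionally brain intracellular fluid (ICF),
and a chain of four cerebrospinal-fluid compartments (lateral ventricle,
third+fourth ventricles, cisterna magna, subarachnoid space).  A single
dispersion flow ``Q_DIFF`` carries drug unidirectionally from brain ECF
through the CSF chain back to plasma; exchange across the blood-brain
barrier is a symmetric clearance ``Q_PL_ECF`` acting on the unbound plasma
concentration (``f_p * C_PL``).  An optional efflux clearance across the
blood-CSF barrier (lateral ventricle -> plasma) and an optional external
ventricular drain (EVD) sampling compartment for clinical datasets complete
the topology.

All amounts are in ng, volumes in mL, flows/clearances in mL/min, times in
minutes.  Between infusion on/off events the system is linear and
time-invariant, so profiles are propagated exactly with matrix exponentials.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "SystemParameters",
    "DrugParameters",
    "ModelStructure",
    "DoseEvent",
    "ConcentrationProfile",
    "RAT_SYSTEM",
    "HUMAN_SYSTEM",
    "COMPARTMENTS",
    "build_structure",
    "ode_rhs",
    "rate_matrix",
    "solve_profile",
    "steady_state_ecf_ratio",
]

#: Canonical ordering of all possible compartments in the state vector.
COMPARTMENTS = (
    "plasma",
    "per1",
    "per2",
    "brain_ecf",
    "brain_icf",
    "csf_lv",
    "csf_tfv",
    "csf_cm",
    "csf_sas",
    "csf_evd",
)

#: Structural feature names accepted by :func:`build_structure`.
FEATURES = ("per1", "per2", "icf", "bcsfb_efflux", "enterohepatic", "evd")


@dataclass(frozen=True)
class SystemParameters:
    """Species-specific physiological CNS volumes (mL) and body weight (kg).

    ``v_icf`` may be ``None`` when the intracellular compartment is not part
    of the model (the human parameterization does not specify it).
    """

    v_ecf: float
    v_icf: float | None
    v_lv: float
    v_tfv: float
    v_cm: float
    v_sas: float
    species: str = "rat"
    bw: float = 0.25

    def __post_init__(self) -> None:
        for name in ("v_ecf", "v_lv", "v_tfv", "v_cm", "v_sas", "bw"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.v_icf is not None and not self.v_icf > 0:
            raise ValueError("v_icf must be strictly positive when given")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SystemParameters":
        return cls(**dict(d))


#: Rat physiological CNS volumes (fixed in all rat fits).
RAT_SYSTEM = SystemParameters(
    v_ecf=0.29, v_icf=1.44, v_lv=0.05, v_tfv=0.05, v_cm=0.017, v_sas=0.18,
    species="rat", bw=0.25,
)

#: Human physiological CNS volumes used for translational prediction.
HUMAN_SYSTEM = SystemParameters(
    v_ecf=240.0, v_icf=None, v_lv=22.5, v_tfv=22.5, v_cm=7.5, v_sas=90.0,
    species="human", bw=70.0,
)


@dataclass(frozen=True)
class DrugParameters:
    """Drug-specific clearances (mL/min), volumes (mL) and covariate effects.

    ``theta_cov`` maps ``(parameter_name, covariate_name)`` to the categorical
    covariate coefficient theta, applied as ``P * (1 + theta * cov)``.
    ``fraction`` is the enterohepatically recirculated fraction (0-1) and
    ``f_p`` the unbound fraction in plasma.
    """

    cl_pl: float
    q_pl_ecf: float
    q_diff: float
    v_pl: float
    q_pl_per1: float | None = None
    q_pl_per2: float | None = None
    q_lv_pl: float | None = None
    q_ecf_icf: float | None = None
    v_per1: float | None = None
    v_per2: float | None = None
    fraction: float | None = None
    f_p: float = 1.0
    theta_cov: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cl_pl", "q_pl_ecf", "q_diff", "v_pl", "q_pl_per1",
                     "q_pl_per2", "q_lv_pl", "q_ecf_icf", "v_per1", "v_per2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        if not (0.0 < self.f_p <= 1.0):
            raise ValueError(f"f_p must be in (0, 1], got {self.f_p!r}")
        if self.fraction is not None and not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        object.__setattr__(self, "theta_cov", dict(self.theta_cov))

    def with_covariates(self, covariates: Mapping[str, float] | None) -> "DrugParameters":
        """Return parameters with categorical covariate effects applied.

        Each ``theta_cov`` entry ``(param, cov)`` multiplies ``param`` by
        ``1 + theta * covariates[cov]`` (missing covariates count as 0).
        """
        if not covariates or not self.theta_cov:
            return self
        updates: dict[str, float] = {}
        for (pname, cname), theta in self.theta_cov.items():
            cov = float(covariates.get(cname, 0.0))
            if cov == 0.0:
                continue
            base = updates.get(pname, getattr(self, pname))
            if base is None:
                raise ValueError(f"covariate on absent parameter {pname!r}")
            newval = base * (1.0 + theta * cov)
            if newval <= 0:
                raise ValueError(
                    f"covariate effect drives {pname} non-positive "
                    f"(theta={theta}, cov={cov})")
            updates[pname] = newval
        return replace(self, **updates) if updates else self

    def updated(self, **kwargs) -> "DrugParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta_cov"] = {f"{p}:{c}": v for (p, c), v in self.theta_cov.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DrugParameters":
        d = dict(d)
        raw = d.pop("theta_cov", {})
        theta = {}
        for key, v in raw.items():
            if isinstance(key, str):
                p, c = key.split(":")
            else:
                p, c = key
            theta[(p, c)] = v
        return cls(theta_cov=theta, **d)


@dataclass(frozen=True)
class ModelStructure:
    """Compartment topology and enabled optional features for one drug/species.

    Plasma, brain ECF and the four CSF compartments are always present.
    ``per2`` requires ``per1``; the EVD compartment is only valid for the
    human model.  ``q_lv_evd``/``v_evd`` are the drain flow (mL/min) and
    collection-chamber volume (mL) when ``evd`` is enabled.
    """

    species: str = "rat"
    per1: bool = False
    per2: bool = False
    icf: bool = False
    bcsfb_efflux: bool = False
    enterohepatic: bool = False
    evd: bool = False
    q_lv_evd: float | None = None
    v_evd: float | None = None

    def __post_init__(self) -> None:
        if self.species not in ("rat", "human"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.per2 and not self.per1:
            raise ValueError("per2 requires per1")
        if self.evd:
            if self.species != "human":
                raise ValueError("EVD compartment is only valid for species='human'")
            if not (self.q_lv_evd and self.q_lv_evd > 0):
                raise ValueError("evd requires q_lv_evd > 0")
            if not (self.v_evd and self.v_evd > 0):
                raise ValueError("evd requires v_evd > 0")

    @property
    def compartments(self) -> tuple[str, ...]:
        """Ordered state-vector compartment labels for this structure."""
        comps = ["plasma"]
        if self.per1:
            comps.append("per1")
        if self.per2:
            comps.append("per2")
        comps.append("brain_ecf")
        if self.icf:
            comps.append("brain_icf")
        comps += ["csf_lv", "csf_tfv", "csf_cm", "csf_sas"]
        if self.evd:
            comps.append("csf_evd")
        return tuple(comps)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelStructure":
        return cls(**dict(d))


@dataclass(frozen=True)
class DoseEvent:
    """One intravenous infusion: start (min), duration (min), amount (ng).

    Boluses are represented as short infusions (duration must be > 0).
    """

    start: float
    duration: float
    amount: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("dose start must be >= 0")
        if not self.duration > 0:
            raise ValueError("infusion duration must be > 0 (use a short "
                             "infusion to represent a bolus)")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")

    @property
    def rate(self) -> float:
        return self.amount / self.duration

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class ConcentrationProfile:
    """Simulated amounts (ng) and concentrations (ng/mL) on a time grid."""

    times: np.ndarray
    amounts: dict[str, np.ndarray]
    volumes: dict[str, float]

    @property
    def concentrations(self) -> dict[str, np.ndarray]:
        return {c: self.amounts[c] / self.volumes[c] for c in self.amounts}

    def conc(self, compartment: str) -> np.ndarray:
        return self.amounts[compartment] / self.volumes[compartment]

    def total_amount(self) -> np.ndarray:
        return np.sum(list(self.amounts.values()), axis=0)


def build_structure(config) -> ModelStructure:
    """Build a :class:`ModelStructure` from a preset name or a config mapping.

    A string selects one of the built-in drug presets.  A mapping must give
    ``species`` and a ``features`` list drawn from ``per1, per2, icf,
    bcsfb_efflux, enterohepatic, evd`` (plus ``q_lv_evd``/``v_evd`` when
    ``evd`` is requested).
    """
    if isinstance(config, str):
        from .drugs import preset_structure
        return preset_structure(config)
    config = dict(config)
    features = config.get("features", [])
    unknown = [f for f in features if f not in FEATURES]
    if unknown:
        raise ValueError(f"unknown structural feature(s): {unknown}")
    return ModelStructure(
        species=config.get("species", "rat"),
        per1="per1" in features,
        per2="per2" in features,
        icf="icf" in features,
        bcsfb_efflux="bcsfb_efflux" in features,
        enterohepatic="enterohepatic" in features,
        evd="evd" in features,
        q_lv_evd=config.get("q_lv_evd"),
        v_evd=config.get("v_evd"),
    )


def _require(value, name: str, feature: str) -> float:
    if value is None:
        raise ValueError(f"{name} is required when {feature} is enabled")
    return value


def compartment_volumes(structure: ModelStructure, params: DrugParameters,
                        system: SystemParameters) -> dict[str, float]:
    """Volume (mL) of every compartment enabled in ``structure``."""
    vols = {"plasma": params.v_pl,
            "brain_ecf": system.v_ecf,
            "csf_lv": system.v_lv,
            "csf_tfv": system.v_tfv,
            "csf_cm": system.v_cm,
            "csf_sas": system.v_sas}
    if structure.per1:
        vols["per1"] = _require(params.v_per1, "v_per1", "per1")
    if structure.per2:
        vols["per2"] = _require(params.v_per2, "v_per2", "per2")
    if structure.icf:
        vols["brain_icf"] = _require(system.v_icf, "system v_icf", "icf")
    if structure.evd:
        vols["csf_evd"] = structure.v_evd
    for name, v in vols.items():
        if not v > 0:
            raise ValueError(f"volume of {name} must be strictly positive")
    return vols


def effective_clearance(params: DrugParameters, structure: ModelStructure) -> float:
    """Net plasma elimination clearance (mL/min).

    With enterohepatic recirculation enabled, the recirculated fraction is
    treated as a permanent reduction of net clearance:
    ``CL_net = CL_PL * (1 - fraction)``.
    """
    cl = params.cl_pl
    if structure.enterohepatic and params.fraction is not None:
        cl = cl * (1.0 - params.fraction)
    return cl


def rate_matrix(params: DrugParameters, system: SystemParameters,
                structure: ModelStructure) -> tuple[np.ndarray, tuple[str, ...]]:
    """First-order rate matrix ``M`` such that ``dA/dt = M A + b(t)``.

    Returns ``(M, compartments)`` where ``compartments`` gives the state
    ordering.  The (constant) input vector ``b`` has the infusion rate in the
    plasma slot and zeros elsewhere.
    """
    comps = structure.compartments
    idx = {c: i for i, c in enumerate(comps)}
    vols = compartment_volumes(structure, params, system)
    V = np.array([vols[c] for c in comps])
    n = len(comps)
    M = np.zeros((n, n))

    def flow(src: str, dst: str | None, q: float) -> None:
        # q * C_src leaves src; enters dst (or leaves the system if dst None)
        i = idx[src]
        M[i, i] -= q / V[i]
        if dst is not None:
            M[idx[dst], i] += q / V[i]

    pl, ecf = idx["plasma"], idx["brain_ecf"]

    # systemic elimination (net of enterohepatic recirculation)
    flow("plasma", None, effective_clearance(params, structure))

    # peripheral distribution
    if structure.per1:
        q1 = _require(params.q_pl_per1, "q_pl_per1", "per1")
        flow("plasma", "per1", q1)
        flow("per1", "plasma", q1)
    if structure.per2:
        q2 = _require(params.q_pl_per2, "q_pl_per2", "per2")
        flow("plasma", "per2", q2)
        flow("per2", "plasma", q2)

    # BBB exchange on unbound plasma: Q_PL_ECF * (f_p C_PL - C_ECF)
    q = params.q_pl_ecf
    M[pl, pl] -= q * params.f_p / V[pl]
    M[ecf, pl] += q * params.f_p / V[pl]
    M[ecf, ecf] -= q / V[ecf]
    M[pl, ecf] += q / V[ecf]

    # ECF <-> ICF exchange
    if structure.icf:
        qi = _require(params.q_ecf_icf, "q_ecf_icf", "icf")
        flow("brain_ecf", "brain_icf", qi)
        flow("brain_icf", "brain_ecf", qi)

    # unidirectional dispersion chain ECF -> LV -> TFV -> CM -> SAS -> plasma
    qd = params.q_diff
    flow("brain_ecf", "csf_lv", qd)
    flow("csf_lv", "csf_tfv", qd)
    flow("csf_tfv", "csf_cm", qd)
    flow("csf_cm", "csf_sas", qd)
    flow("csf_sas", "plasma", qd)

    # BCSFB efflux LV -> plasma (methotrexate only in the rat presets)
    if structure.bcsfb_efflux:
        flow("csf_lv", "plasma", _require(params.q_lv_pl, "q_lv_pl", "bcsfb_efflux"))

    # EVD: LV loses Q_LV_EVD*C_LV into a drained chamber which is itself
    # continuously emptied at the same flow
    if structure.evd:
        flow("csf_lv", "csf_evd", structure.q_lv_evd)
        flow("csf_evd", None, structure.q_lv_evd)

    return M, comps


def ode_rhs(amounts: Sequence[float], t: float, params: DrugParameters,
            system: SystemParameters, structure: ModelStructure,
            active_infusion_rate: float = 0.0) -> np.ndarray:
    """Mass-balance derivatives (ng/min) for the current state.

    ``amounts`` must follow ``structure.compartments`` ordering; the infusion
    input enters plasma only.
    """
    M, comps = rate_matrix(params, system, structure)
    a = np.asarray(amounts, dtype=float)
    if a.shape != (len(comps),):
        raise ValueError(
            f"state length {a.shape} does not match the {len(comps)} "
            f"compartments of the structure")
    b = np.zeros(len(comps))
    b[0] = active_infusion_rate
    return M @ a + b


def _infusion_rate(doses: Sequence[DoseEvent], t: float) -> float:
    return sum(d.rate for d in doses if d.start <= t < d.end)


def solve_profile(structure: ModelStructure, params: DrugParameters,
                  system: SystemParameters, doses: Sequence[DoseEvent],
                  times: Sequence[float],
                  covariates: Mapping[str, float] | None = None,
                  initial_amounts: Mapping[str, float] | None = None,
                  ) -> ConcentrationProfile:
    """Exact concentration-time profile for an arbitrary infusion regimen.

    Infusion start/stop instants bound piecewise-constant-input segments; the
    state is propagated across each segment with the matrix exponential of
    the input-augmented rate matrix, so there is no truncation error and no
    discontinuity inside an integration step.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if np.any(np.diff(times) < 0) or times[0] < 0:
        raise ValueError("times must be sorted and non-negative")
    if not doses:
        raise ValueError("at least one dose event is required")

    p = params.with_covariates(covariates)
    M, comps = rate_matrix(p, system, structure)
    n = len(comps)
    vols = compartment_volumes(structure, p, system)

    state = np.zeros(n)
    if initial_amounts:
        for c, a in initial_amounts.items():
            state[comps.index(c)] = a

    boundaries = {d.start for d in doses} | {d.end for d in doses}
    events = np.unique(np.concatenate([times, np.array(sorted(boundaries))]))
    events = events[events >= 0.0]
    if events[0] > 0.0:
        events = np.concatenate([[0.0], events])

    out = np.empty((len(times), n))
    # map each requested time to its slot(s) in the output
    from collections import defaultdict
    want: dict[float, list[int]] = defaultdict(list)
    for k, t in enumerate(times):
        want[float(t)].append(k)

    cache: dict[tuple[float, float], np.ndarray] = {}
    t_cur = 0.0
    if t_cur in want:
        for k in want[t_cur]:
            out[k] = state
    for t_next in events:
        if t_next <= t_cur:
            continue
        dt = t_next - t_cur
        rate = _infusion_rate(doses, 0.5 * (t_cur + t_next))
        key = (rate, dt)
        E = cache.get(key)
        if E is None:
            aug = np.zeros((n + 1, n + 1))
            aug[:n, :n] = M
            aug[0, n] = rate
            try:
                E = expm(aug * dt)
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"propagation failed on segment [{t_cur}, {t_next}] "
                    f"(rate={rate} ng/min): {exc}") from exc
            cache[key] = E
        state = E[:n, :n] @ state + E[:n, n]
        t_cur = t_next
        if t_cur in want:
            for k in want[t_cur]:
                out[k] = state

    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite amounts in simulated profile "
                           "(check parameter magnitudes)")
    amounts = {c: out[:, i].copy() for i, c in enumerate(comps)}
    return ConcentrationProfile(times=times.copy(), amounts=amounts,
                                volumes={c: vols[c] for c in comps})


def interval_subgrid(t_mid: float, width: float, k: int = 5):
    """Sub-times and trapezoid weights for a collection-interval average.

    Microdialysis and ventricular-drain samples are averages of the
    concentration over a collection interval; this returns ``k`` evenly
    spaced sub-times over ``[t_mid - width/2, t_mid + width/2]`` and weights
    summing to 1 such that ``sum(w * C(t_sub))`` is the trapezoid-rule
    average used consistently by the generator and the fit predictor.
    """
    if width <= 0:
        return np.array([t_mid]), np.array([1.0])
    t = np.linspace(t_mid - width / 2.0, t_mid + width / 2.0, k)
    if t[0] < 0:
        raise ValueError("collection interval extends before t=0")
    w = np.full(k, 1.0 / (k - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    return t, w


def steady_state_ecf_ratio(params: DrugParameters) -> float:
    """Closed-form steady-state ``C_ECF / (f_p * C_PL)`` of the reduced model.

    Valid when ICF and BCSFB efflux are disabled: the ECF mass balance at
    steady state gives ``Q_PL_ECF / (Q_PL_ECF + Q_DIFF)``.
    """
    denom = params.q_pl_ecf + params.q_diff
    if denom == 0:
        raise ZeroDivisionError("Q_PL_ECF + Q_DIFF must be non-zero")
    return params.q_pl_ecf / denom


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (display convention for fixed
    translated parameters)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def model_config_to_json(structure: ModelStructure, params: DrugParameters,
                         system: SystemParameters) -> str:
    """Serialize a (structure, params, system) triple to a JSON document."""
    return json.dumps({
        "structure": structure.to_dict(),
        "parameters": params.to_dict(),
        "system": system.to_dict(),
    }, indent=2)


def model_config_from_json(text: str):
    """Inverse of :func:`model_config_to_json`; lossless round-trip."""
    d = json.loads(text)
    return (ModelStructure.from_dict(d["structure"]),
            DrugParameters.from_dict(d["parameters"]),
            SystemParameters.from_dict(d["system"]))
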