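"""Raw assay quantities -> model-ready unbound concentrations.

Microdialysis reports dialysate concentrations that understate the tissue
unbound concentration by the probe's in-vivo recovery; retrodialysis
calibrates that recovery by perfusing drug and measuring relative loss.
This module implements the free-fraction and recovery calculations, the
recovery correction of dialysate streams, and assembly of NONMEM-style
tabular event records into a :class:`StudyDataset` ready for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .model import DoseEvent

__all__ = [
    "Observation",
    "StudyDataset",
    "free_fraction",
    "in_vivo_recovery",
    "correct_dialysate",
    "assemble_dataset",
    "read_dialect_csv",
    "DIALECT_COLUMNS",
    "MODEL_COMPARTMENT_LABELS",
]

#: Required header of the dataset CSV dialect.  ``DUR_MIN`` is an optional
#: extra column giving the collection-interval duration of an observation
#: (dialysate / drain samples are interval averages centred on TIME_MIN);
#: absent or 0 means an instantaneous sample.
DIALECT_COLUMNS = ["SUBJECT", "DRUG", "SPECIES", "BW_KG", "TIME_MIN", "CMT",
                   "DV_NGML", "ASSAY", "AMT_MGKG", "INF_MIN", "INHIBITOR",
                   "DOSEGRP", "LLOQ_NGML"]
OPTIONAL_COLUMNS = ["DUR_MIN"]

MODEL_COMPARTMENT_LABELS = ("plasma", "brain_ecf", "csf_lv", "csf_tfv",
                            "csf_cm", "csf_sas", "csf_evd")

ASSAY_KINDS = ("total", "unbound", "dialysate", "corrected_unbound")


@dataclass(frozen=True)
class Observation:
    """One measured concentration record."""

    subject: str
    drug: str
    time: float
    compartment: str
    concentration: float
    assay: str
    below_lloq: bool = False
    inhibitor: int = 0
    dosegrp: str = ""
    duration: float = 0.0  # collection-interval width (min); 0 = point sample

    def __post_init__(self) -> None:
        if self.compartment not in MODEL_COMPARTMENT_LABELS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.assay not in ASSAY_KINDS:
            raise ValueError(f"unknown assay kind {self.assay!r}")


@dataclass
class StudyDataset:
    """Observations plus per-subject dosing for one experiment.

    ``observations`` columns: subject, drug, time, compartment, dv, assay,
    below_lloq, exclude, inhibitor, dosegrp, duration (collection-interval
    width in minutes; 0 for instantaneous samples).  ``doses`` maps subject id to
    its list of :class:`DoseEvent` (amounts already in ng); ``bw`` maps
    subject id to body weight (kg).
    """

    observations: pd.DataFrame
    doses: dict[str, list[DoseEvent]]
    species: str = "rat"
    bw: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        obs_subjects = set(self.observations["subject"].unique())
        missing = obs_subjects - set(self.doses)
        if missing:
            raise ValueError(f"subjects with observations but no dose event: "
                             f"{sorted(missing)}")

    def fitting_frame(self) -> pd.DataFrame:
        """Observations included in estimation (excluded rows dropped)."""
        return self.observations[~self.observations["exclude"]]

    def covariates_for(self, subject: str) -> dict[str, float]:
        rows = self.observations[self.observations["subject"] == subject]
        cov: dict[str, float] = {}
        if len(rows):
            cov["inhibitor"] = float(rows["inhibitor"].iloc[0])
            grp = rows["dosegrp"].iloc[0]
            if grp not in ("", None) and not pd.isna(grp):
                cov[f"dosegrp_{_grp_label(grp)}"] = 1.0
        return cov

    @property
    def subjects(self) -> list[str]:
        return sorted(self.doses)

    def to_observations(self) -> list[Observation]:
        out = []
        for r in self.observations.itertuples(index=False):
            out.append(Observation(
                subject=r.subject, drug=r.drug, time=r.time,
                compartment=r.compartment, concentration=r.dv, assay=r.assay,
                below_lloq=bool(r.below_lloq), inhibitor=int(r.inhibitor),
                dosegrp=str(r.dosegrp), duration=float(r.duration)))
        return out


def _grp_label(value) -> str:
    try:
        f = float(value)
        return str(int(f)) if f == int(f) else str(f)
    except (TypeError, ValueError):
        return str(value)


def free_fraction(ultrafiltrate_conc: float, pooled_plasma_conc: float,
                  tol: float = 1e-6) -> float:
    """Unbound fraction in plasma from an ultrafiltration experiment:
    ultrafiltrate concentration over pooled total plasma concentration."""
    if pooled_plasma_conc <= 0:
        raise ValueError("pooled plasma concentration must be > 0")
    if ultrafiltrate_conc < 0:
        raise ValueError("ultrafiltrate concentration must be >= 0")
    ratio = ultrafiltrate_conc / pooled_plasma_conc
    if ratio > 1.0 + tol:
        raise ValueError(f"free fraction {ratio:.4g} exceeds 1: "
                         "ultrafiltrate above pooled plasma")
    return min(ratio, 1.0)


def in_vivo_recovery(c_in: float, c_dial: float) -> float:
    """Retrodialysis recovery: relative loss of perfused drug to tissue,
    ``(C_in - C_dial) / C_in``; 1 means complete loss (full exchange)."""
    if c_in <= 0:
        raise ValueError("perfusate concentration C_in must be > 0")
    if c_dial < 0:
        raise ValueError("dialysate concentration must be >= 0")
    if c_dial > c_in:
        raise ValueError("C_dial > C_in signals retrodialysis failure")
    return (c_in - c_dial) / c_in


def correct_dialysate(c_dial: float, recovery: float) -> float:
    """Convert a dialysate concentration to the tissue unbound concentration
    by dividing by the probe recovery (in (0, 1])."""
    if not 0.0 < recovery <= 1.0:
        raise ValueError(f"recovery must be in (0, 1], got {recovery!r}")
    return c_dial / recovery


def read_dialect_csv(source) -> pd.DataFrame:
    """Read and validate a dataset CSV in the standard dialect."""
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in DIALECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    if "DUR_MIN" not in df.columns:
        df["DUR_MIN"] = 0.0
    bad = set(df["CMT"].dropna().unique()) - set(MODEL_COMPARTMENT_LABELS)
    if bad:
        raise ValueError(f"unknown compartment label(s): {sorted(bad)}")
    bad_assay = set(df.loc[df["DV_NGML"].notna(), "ASSAY"].unique()) - set(ASSAY_KINDS)
    if bad_assay:
        raise ValueError(f"unknown assay kind(s): {sorted(bad_assay)}")
    return df


def assemble_dataset(source, drug_config: Mapping,
                     convert_total_plasma: bool = False,
                     lloq_policy: str = "exclude") -> StudyDataset:
    """Assemble a fit-ready :class:`StudyDataset` from raw tabular records.

    Dosing rows (non-missing ``AMT_MGKG``) are converted mg/kg -> ng via the
    subject body weight.  Dialysate rows are recovery-corrected with the
    per-drug recovery constants in ``drug_config['recovery']``; total-plasma
    rows are optionally converted to unbound via ``f_p``.  Below-LLOQ rows
    are flagged, and excluded from fitting (``lloq_policy='exclude'``,
    default) or substituted at LLOQ/2 (``lloq_policy='half'``).

    Already-corrected data pass through unchanged, so assembly is idempotent.
    """
    if lloq_policy not in ("exclude", "half"):
        raise ValueError("lloq_policy must be 'exclude' or 'half'")
    df = read_dialect_csv(source)
    recovery = dict(drug_config.get("recovery", {}))
    f_p = float(drug_config.get("f_p", 1.0))
    species = str(drug_config.get("species",
                                  df["SPECIES"].dropna().iloc[0] if len(df) else "rat"))

    dose_rows = df[df["AMT_MGKG"].notna()]
    obs_rows = df[df["DV_NGML"].notna()]

    doses: dict[str, list[DoseEvent]] = {}
    bw: dict[str, float] = {}
    for r in dose_rows.itertuples(index=False):
        subj = str(r.SUBJECT)
        weight = float(r.BW_KG)
        bw[subj] = weight
        amount_ng = float(r.AMT_MGKG) * weight * 1e6  # mg/kg * kg -> mg -> ng
        doses.setdefault(subj, []).append(
            DoseEvent(start=float(r.TIME_MIN), duration=float(r.INF_MIN),
                      amount=amount_ng))

    records = []
    for r in obs_rows.itertuples(index=False):
        subj = str(r.SUBJECT)
        dv = float(r.DV_NGML)
        assay = str(r.ASSAY)
        cmt = str(r.CMT)
        if assay == "dialysate":
            if cmt not in recovery:
                raise ValueError(f"no recovery constant for dialysate "
                                 f"stream {cmt!r} in drug_config")
            dv = correct_dialysate(dv, recovery[cmt])
            assay = "corrected_unbound"
        elif assay == "total" and convert_total_plasma:
            dv = dv * f_p
            assay = "unbound"
        lloq = getattr(r, "LLOQ_NGML")
        below = bool(not pd.isna(lloq) and dv < float(lloq))
        exclude = False
        if below:
            if lloq_policy == "exclude":
                exclude = True
            else:
                dv = float(lloq) / 2.0
        dur = getattr(r, "DUR_MIN", 0.0)
        records.append(dict(
            subject=subj, drug=str(r.DRUG), time=float(r.TIME_MIN),
            compartment=cmt, dv=dv, assay=assay, below_lloq=below,
            exclude=exclude, inhibitor=int(r.INHIBITOR),
            dosegrp=_grp_label(r.DOSEGRP) if not pd.isna(r.DOSEGRP) else "",
            duration=0.0 if pd.isna(dur) else float(dur)))

    obs = pd.DataFrame.from_records(
        records,
        columns=["subject", "drug", "time", "compartment", "dv", "assay",
                 "below_lloq", "exclude", "inhibitor", "dosegrp", "duration"])
    meta = {"drug": drug_config.get("drug"), "f_p": f_p, "recovery": recovery,
            "lloq_policy": lloq_policy}
    return StudyDataset(observations=obs, doses=doses, species=species,
                        bw=bw, meta=meta)
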