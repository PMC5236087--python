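"""Built-in drug parameterizations.

Rat parameter sets for the nine model-development compounds (naive-pooled
estimates with physiological volumes fixed), plus the human plasma
parameterizations for the two translational compounds (acetaminophen,
morphine).  Covariate coefficients encode categorical effects of active
transport inhibition (P-gp blockers for morphine, paliperidone, phenytoin,
quinidine and risperidone; an MRP/OAT/OATP blocker for methotrexate, which
also carries the only blood-CSF-barrier efflux clearance) and the morphine
dose-group effect on BBB transfer.

Unbound plasma fractions: phenytoin and remoxipride use literature protein
binding of 91% and 26% (f_p = 0.09 and 0.74).  Drugs whose model-ready data
are already unbound carry f_p = 1.
"""

from __future__ import annotations

from .model import DrugParameters, ModelStructure

__all__ = [
    "RAT_DRUGS",
    "HUMAN_DRUGS",
    "preset_parameters",
    "preset_structure",
    "preset_sigma",
    "preset_recovery",
    "drug_config",
    "morphine_q_pl_ecf_4mgkg",
]

#: Morphine BBB transfer was dose-group dependent; the 4 mg/kg group value
#: relative to the 10/40 mg/kg baseline, expressed as a categorical effect.
_MORPHINE_DG4_THETA = 0.00750 / 0.00458 - 1.0

RAT_DRUGS: dict[str, dict] = {
    "acetaminophen": dict(
        params=DrugParameters(
            cl_pl=15.9, q_pl_per1=29.2, q_pl_ecf=0.0281, q_diff=0.0556,
            v_pl=65.7, v_per1=219.0, fraction=0.933),
        structure=ModelStructure(species="rat", per1=True, enterohepatic=True),
        sigma={"plasma": 0.341, "brain_ecf": 1.88, "csf_lv": 0.607,
               "csf_cm": 0.640},
    ),
    "atenolol": dict(
        params=DrugParameters(
            cl_pl=6.09, q_pl_per1=6.55, q_pl_ecf=0.00749, q_diff=0.0205,
            v_pl=115.0, v_per1=280.0),
        structure=ModelStructure(species="rat", per1=True),
        sigma={"plasma": 0.218, "brain_ecf": 0.480},
    ),
    "methotrexate": dict(
        params=DrugParameters(
            cl_pl=8.12, q_pl_per1=28.1, q_pl_per2=1.50, q_pl_ecf=0.00109,
            q_lv_pl=0.105, q_diff=0.0598, v_pl=51.2, v_per1=210.0,
            v_per2=114.0,
            theta_cov={("q_pl_ecf", "inhibitor"): 4.09,
                       ("q_lv_pl", "inhibitor"): 0.410}),
        structure=ModelStructure(species="rat", per1=True, per2=True,
                                 bcsfb_efflux=True),
        sigma={"plasma": 0.522, "brain_ecf": 0.529, "csf_lv": 0.663,
               "csf_cm": 1.00},
    ),
    "morphine": dict(
        params=DrugParameters(
            cl_pl=21.6, q_pl_per1=8.72, q_pl_per2=53.3, q_pl_ecf=0.00458,
            q_diff=0.0200, v_pl=118.0, v_per1=1210.0, v_per2=570.0,
            theta_cov={("q_pl_ecf", "inhibitor"): 1.62,
                       ("q_pl_ecf", "dosegrp_4"): _MORPHINE_DG4_THETA}),
        structure=ModelStructure(species="rat", per1=True, per2=True),
        sigma={"plasma": 0.647, "brain_ecf": 0.779},
    ),
    "paliperidone": dict(
        params=DrugParameters(
            cl_pl=192.0, q_pl_ecf=0.0123, q_ecf_icf=0.0126, q_diff=0.0248,
            v_pl=28400.0,
            theta_cov={("q_pl_ecf", "inhibitor"): 0.434}),
        structure=ModelStructure(species="rat", icf=True),
        sigma={"plasma": 0.631, "brain_ecf": 0.946, "csf_cm": 0.770},
    ),
    "phenytoin": dict(
        params=DrugParameters(
            cl_pl=44.7, q_pl_per1=133.0, q_pl_ecf=0.00340, q_diff=0.0133,
            v_pl=2890.0, v_per1=5320.0, f_p=0.09,
            theta_cov={("q_pl_ecf", "inhibitor"): 0.355}),
        structure=ModelStructure(species="rat", per1=True),
        sigma={"plasma": 0.444, "brain_ecf": 0.415},
    ),
    "quinidine": dict(
        params=DrugParameters(
            cl_pl=152.0, q_pl_per1=1070.0, q_pl_ecf=0.0354, q_ecf_icf=0.0250,
            q_diff=0.0237, v_pl=194.0, v_per1=13300.0,
            theta_cov={("q_pl_ecf", "inhibitor"): 4.43}),
        structure=ModelStructure(species="rat", per1=True, icf=True),
        sigma={"plasma": 0.418, "brain_ecf": 0.628, "csf_lv": 0.629,
               "csf_cm": 0.466},
    ),
    "remoxipride": dict(
        params=DrugParameters(
            cl_pl=114.0, q_pl_per1=105.0, q_pl_ecf=0.0141, q_diff=0.0176,
            v_pl=286.0, v_per1=2310.0, f_p=0.74),
        structure=ModelStructure(species="rat", per1=True),
        sigma={"plasma": 0.348, "brain_ecf": 0.673},
    ),
    "risperidone": dict(
        params=DrugParameters(
            cl_pl=465.0, q_pl_ecf=0.0247, q_diff=0.0254, v_pl=60000.0,
            theta_cov={("q_pl_ecf", "inhibitor"): 1.24}),
        structure=ModelStructure(species="rat", icf=False),
        sigma={"plasma": 1.44, "brain_ecf": 0.911, "csf_cm": 0.827},
    ),
}

#: Human plasma parameterizations (2-compartment) with inter-individual
#: variability SDs and residual SDs; the scaled BBB/dispersion clearances are
#: derived at translation time, not stored here.
HUMAN_DRUGS: dict[str, dict] = {
    "acetaminophen": dict(
        # plasma state on the unbound scale (total data converted with
        # f_p_conversion before fitting), hence f_p = 1 in the parameters
        params=DrugParameters(
            cl_pl=562.0, q_pl_per1=2060.0, q_pl_ecf=0.0, q_diff=0.0,
            v_pl=9880.0, v_per1=51900.0, f_p=1.0),
        omegas={"cl_pl": 0.490, "v_per1": 0.235},
        sigma={"plasma": 0.250, "csf_evd": 0.250},
        f_p_conversion=0.85,
    ),
    "morphine": dict(
        params=DrugParameters(
            cl_pl=3070.0, q_pl_per1=3030.0, q_pl_ecf=0.0, q_diff=0.0,
            v_pl=16000.0, v_per1=95400.0, f_p=1.0),
        omegas={"cl_pl": 0.271, "v_pl": 0.596},
        sigma={"plasma": 0.0960, "brain_ecf": 0.0960},
        f_p_conversion=1.0,
    ),
}

#: Microdialysis probe recovery per sampled stream.  The study's own
#: per-drug recoveries are supplementary material; these are plausible
#: in-vivo values within the usual 0.2-0.6 range, recorded in generated
#: dataset metadata so the correction is exactly invertible.
DEFAULT_RECOVERY = {"brain_ecf": 0.25, "csf_lv": 0.40, "csf_cm": 0.55,
                    "csf_tfv": 0.40, "csf_sas": 0.40}


def _lookup(drug: str) -> dict:
    try:
        return RAT_DRUGS[drug]
    except KeyError:
        raise KeyError(f"unknown rat drug preset {drug!r}; "
                       f"choose from {sorted(RAT_DRUGS)}") from None


def preset_parameters(drug: str, species: str = "rat") -> DrugParameters:
    if species == "human":
        try:
            return HUMAN_DRUGS[drug]["params"]
        except KeyError:
            raise KeyError(f"no human preset for {drug!r}; "
                           f"choose from {sorted(HUMAN_DRUGS)}") from None
    return _lookup(drug)["params"]


def preset_structure(drug: str) -> ModelStructure:
    return _lookup(drug)["structure"]


def preset_sigma(drug: str, species: str = "rat") -> dict[str, float]:
    if species == "human":
        return dict(HUMAN_DRUGS[drug]["sigma"])
    return dict(_lookup(drug)["sigma"])


def preset_recovery(drug: str) -> dict[str, float]:
    """Probe recovery constants for the drug's dialysate streams."""
    sigma = _lookup(drug)["sigma"]
    return {s: DEFAULT_RECOVERY[s] for s in sigma if s != "plasma"}


def morphine_q_pl_ecf_4mgkg() -> float:
    """Effective morphine BBB transfer clearance in the 4 mg/kg dose group
    (the value carried forward to human scaling)."""
    p = RAT_DRUGS["morphine"]["params"]
    return p.with_covariates({"dosegrp_4": 1.0}).q_pl_ecf


def drug_config(drug: str, species: str = "rat") -> dict:
    """Full default configuration for dataset assembly and fitting."""
    if species == "human":
        entry = HUMAN_DRUGS[drug]
        return {
            "drug": drug,
            "species": "human",
            "f_p": entry["f_p_conversion"],
            "recovery": {},
            "sigma": dict(entry["sigma"]),
            "omegas": dict(entry["omegas"]),
        }
    entry = _lookup(drug)
    return {
        "drug": drug,
        "species": "rat",
        "f_p": entry["params"].f_p,
        "recovery": preset_recovery(drug),
        "sigma": dict(entry["sigma"]),
    }
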