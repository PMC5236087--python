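"""Extended least squares objective, covariates, LRT and IIV."""

import numpy as np
import pandas as pd
import pytest

from cnspk import (DoseEvent, DrugParameters, ErrorModel, ModelStructure,
                   RAT_SYSTEM, StudyDataset, apply_covariate, els_objective,
                   fit_naive_pooled, iiv_realize, lrt_compare,
                   preset_parameters, residual_variance)
from cnspk.model import interval_subgrid, solve_profile
from cnspk.estimation import _Predictor


def _obs_frame(records):
    cols = ["subject", "drug", "time", "compartment", "dv", "assay",
            "below_lloq", "exclude", "inhibitor", "dosegrp", "duration"]
    rows = []
    for r in records:
        base = dict(drug="x", assay="unbound", below_lloq=False,
                    exclude=False, inhibitor=0, dosegrp="", duration=0.0)
        base.update(r)
        rows.append(base)
    return pd.DataFrame(rows, columns=cols)


def _tiny_dataset(records, doses=None):
    doses = doses or {"S1": [DoseEvent(0.0, 10.0, 1e6)]}
    return StudyDataset(observations=_obs_frame(records), doses=doses,
                        species="rat")


def test_apply_covariate_identity_and_worked_example():
    assert apply_covariate(3.7, 1.62, 0) == 3.7
    assert apply_covariate(0.00458, 1.62, 1) == pytest.approx(0.0120, abs=5e-5)
    with pytest.raises(ValueError):
        apply_covariate(1.0, -1.5, 1)
    with pytest.raises(ValueError):
        apply_covariate(0.0, 1.0, 1)


def test_inhibitor_effects_match_reported_percent_increases():
    # P-gp / MRP-OAT-OATP inhibition raises BBB transfer by the printed %
    expected = {"morphine": 162.0, "paliperidone": 43.4, "phenytoin": 35.5,
                "quinidine": 443.0, "risperidone": 124.0,
                "methotrexate": 409.0}
    for drug, pct in expected.items():
        theta = preset_parameters(drug).theta_cov[("q_pl_ecf", "inhibitor")]
        p0 = preset_parameters(drug).q_pl_ecf
        increase = 100.0 * (apply_covariate(p0, theta, 1) / p0 - 1.0)
        assert increase == pytest.approx(pct, rel=1e-6), drug


def test_residual_variance_models():
    prop = ErrorModel("proportional", sigma_prop=0.3)
    assert residual_variance(100.0, prop) == pytest.approx(900.0)
    assert residual_variance(0.0, prop) == 0.0
    mixed = ErrorModel("mixed", sigma_prop=0.3, sigma_add=2.0)
    assert residual_variance(0.0, mixed) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        ErrorModel("mixed", sigma_prop=0.3, sigma_add=0.0)
    per_stream = ErrorModel("proportional",
                            sigma_prop={"plasma": 0.2, "brain_ecf": 0.5})
    assert residual_variance(10.0, per_stream, "brain_ecf") == pytest.approx(25.0)


def test_els_objective_zero_for_perfect_fit_unit_variance():
    p = DrugParameters(cl_pl=5.0, q_pl_ecf=0.0, q_diff=0.0, v_pl=100.0)
    structure = ModelStructure()
    times = [30.0, 60.0, 120.0]
    prof = solve_profile(structure, p, RAT_SYSTEM,
                        [DoseEvent(0.0, 10.0, 1e6)], times)
    ds = _tiny_dataset([dict(subject="S1", time=t, compartment="plasma",
                             dv=float(c))
                        for t, c in zip(times, prof.conc("plasma"))])
    em = ErrorModel("mixed", sigma_prop=0.0, sigma_add=1.0)  # var == 1
    assert els_objective(ds, p, em, structure, RAT_SYSTEM) == pytest.approx(
        0.0, abs=1e-9)


def test_els_objective_single_record_value():
    # one observation, residual 2, variance 4 -> 1 + ln 4
    p = DrugParameters(cl_pl=5.0, q_pl_ecf=0.0, q_diff=0.0, v_pl=100.0)
    structure = ModelStructure()
    prof = solve_profile(structure, p, RAT_SYSTEM,
                        [DoseEvent(0.0, 10.0, 1e6)], [60.0])
    ds = _tiny_dataset([dict(subject="S1", time=60.0, compartment="plasma",
                             dv=float(prof.conc("plasma")[0]) + 2.0)])
    em = ErrorModel("mixed", sigma_prop=0.0, sigma_add=2.0)
    assert els_objective(ds, p, em, structure, RAT_SYSTEM) == pytest.approx(
        1.0 + np.log(4.0), rel=1e-9)


def _brute_force_ofv(dataset, params, error_model, structure, system):
    """Record-by-record oracle: one solve per observation, no grouping."""
    rows = dataset.fitting_frame()
    floor_var = (1e-6 * float(np.abs(rows["dv"]).max())) ** 2
    ofv = 0.0
    for r in rows.itertuples(index=False):
        cov = dataset.covariates_for(r.subject)
        sub, w = interval_subgrid(r.time, r.duration)
        prof = solve_profile(structure, params, system,
                            dataset.doses[r.subject], sub, covariates=cov)
        pred = float(np.sum(prof.conc(r.compartment) * w))
        if r.compartment == "plasma" and r.assay in ("unbound",
                                                     "corrected_unbound"):
            pred *= params.f_p
        var = max(float(residual_variance(pred, error_model, r.compartment)),
                  floor_var)
        ofv += (r.dv - pred) ** 2 / var + np.log(var)
    return ofv


def test_els_objective_matches_record_by_record_oracle():
    rng = np.random.default_rng(5)
    p = preset_parameters("atenolol")
    structure = ModelStructure(per1=True)
    records, doses = [], {}
    for s, inhib in [("S1", 0), ("S2", 1)]:
        doses[s] = [DoseEvent(0.0, 10.0, float(rng.uniform(5e5, 2e6)))]
        for t in (15.0, 45.0, 120.0):
            records.append(dict(subject=s, time=t, compartment="plasma",
                                dv=float(rng.uniform(10, 500)),
                                inhibitor=inhib, assay="total"))
        for t, dur in ((10.0, 20.0), (40.0, 20.0)):
            records.append(dict(subject=s, time=t, duration=dur,
                                compartment="brain_ecf", assay="corrected_unbound",
                                dv=float(rng.uniform(0.01, 5)),
                                inhibitor=inhib))
    p = p.updated(theta_cov={("q_pl_ecf", "inhibitor"): 0.8})
    ds = StudyDataset(observations=_obs_frame(records), doses=doses)
    em = ErrorModel("proportional",
                    sigma_prop={"plasma": 0.3, "brain_ecf": 0.5})
    fast = els_objective(ds, p, em, ModelStructure(per1=True), RAT_SYSTEM)
    slow = _brute_force_ofv(ds, p, em, ModelStructure(per1=True), RAT_SYSTEM)
    assert fast == pytest.approx(slow, rel=1e-10)


def test_ofv_differences_invariant_to_concentration_rescaling():
    # proportional error: scaling DV and dose by k shifts OFV by a constant,
    # so OFV differences between nested parameter sets are unchanged
    rng = np.random.default_rng(9)
    structure = ModelStructure(per1=True)
    em = ErrorModel("proportional", sigma_prop=0.25)
    pA = preset_parameters("atenolol")
    pB = pA.updated(cl_pl=pA.cl_pl * 1.4)

    def build(k):
        doses = {"S1": [DoseEvent(0.0, 10.0, 1e6 * k)]}
        recs = [dict(subject="S1", time=t, compartment="plasma",
                     dv=float(rng.uniform(50, 500)) * k, assay="total")
                for t in (10.0, 30.0, 90.0, 200.0)]
        return StudyDataset(observations=_obs_frame(recs), doses=doses)

    rng = np.random.default_rng(9)
    d1 = build(1.0)
    rng = np.random.default_rng(9)
    d2 = build(137.0)
    delta1 = (els_objective(d1, pA, em, structure, RAT_SYSTEM)
              - els_objective(d1, pB, em, structure, RAT_SYSTEM))
    delta2 = (els_objective(d2, pA, em, structure, RAT_SYSTEM)
              - els_objective(d2, pB, em, structure, RAT_SYSTEM))
    assert delta1 == pytest.approx(delta2, rel=1e-9)


def test_zero_noise_fit_recovers_generating_parameters():
    from cnspk import (assemble_dataset, default_design, drug_config,
                       generate_rat_study, to_dialect_frame)
    design = default_design("atenolol")
    design.n_subjects, design.n_plasma, design.n_dialysate = 4, 32, 40
    design.sigma = {k: 0.0 for k in design.sigma}
    truth = preset_parameters("atenolol")
    raw = generate_rat_study(design, seed=0, recovery={"brain_ecf": 1.0})
    cfg = dict(drug_config("atenolol"), recovery={"brain_ecf": 1.0})
    ds = assemble_dataset(to_dialect_frame(raw), cfg)
    free = ("cl_pl", "q_pl_ecf", "q_diff", "v_pl")
    init = truth.updated(**{n: getattr(truth, n) * 1.3 for n in free})
    # constant variance: the zero-noise optimum is exactly the truth
    # (with pred-proportional variance the ln-var term displaces it)
    em = ErrorModel("mixed", sigma_prop=0.0, sigma_add=1.0)
    fit = fit_naive_pooled(ds, ModelStructure(per1=True), init, free,
                           error_model=em, seed=0, n_starts=1)
    for n in free:
        assert fit.estimates[n] == pytest.approx(getattr(truth, n), rel=1e-3)


def test_structurally_impossible_fit_reports_degenerate_stream():
    # brain observations but BBB transfer fixed at zero: predictions vanish
    recs = [dict(subject="S1", time=t, duration=20.0, compartment="brain_ecf",
                 dv=5.0, assay="corrected_unbound")
            for t in (10.0, 30.0, 50.0)]
    recs += [dict(subject="S1", time=t, compartment="plasma", dv=100.0,
                  assay="total") for t in (15.0, 60.0)]
    ds = _tiny_dataset(recs)
    init = DrugParameters(cl_pl=5.0, q_pl_ecf=0.0, q_diff=0.01, v_pl=100.0)
    fit = fit_naive_pooled(ds, ModelStructure(), init, ("cl_pl", "v_pl"),
                           seed=0, n_starts=1, compute_rse=False)
    assert "brain_ecf" in fit.convergence["degenerate_streams"]


def test_lrt_thresholds():
    delta, sig = lrt_compare(100.0, 103.85, ddf=1)
    assert sig and delta == pytest.approx(3.85)
    assert not lrt_compare(100.0, 103.83, ddf=1)[1]
    assert not lrt_compare(100.0, 105.0, ddf=2)[1]      # threshold 5.99
    assert lrt_compare(100.0, 106.0, ddf=2)[1]
    with pytest.raises(ValueError, match="nested"):
        lrt_compare(100.0, 99.0, ddf=1)


def test_iiv_realization_statistics():
    assert iiv_realize(3.5, 0.0, seed=1) == 3.5
    rng = np.random.default_rng(123)
    draws = np.array([iiv_realize(2.0, 0.5, seed=rng) for _ in range(10_000)])
    assert np.std(np.log(draws)) == pytest.approx(0.5, rel=0.03)
    assert np.median(draws) == pytest.approx(2.0, rel=0.02)
    with pytest.raises(ValueError):
        iiv_realize(1.0, -0.1)


def test_predictor_groups_subjects_sharing_design():
    # two subjects, identical dosing/covariates -> one simulation group
    recs = [dict(subject=s, time=t, compartment="plasma", dv=1.0,
                 assay="total")
            for s in ("S1", "S2") for t in (10.0, 60.0)]
    ds = StudyDataset(observations=_obs_frame(recs),
                      doses={"S1": [DoseEvent(0.0, 10.0, 1e6)],
                             "S2": [DoseEvent(0.0, 10.0, 1e6)]})
    pred = _Predictor(ds, ModelStructure(),
                      RAT_SYSTEM)
    assert len(pred.groups) == 1
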