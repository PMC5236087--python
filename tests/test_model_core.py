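"""Core compartmental model: topology, mass balance, closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cnspk import (DoseEvent, DrugParameters, ModelStructure, RAT_SYSTEM,
                   HUMAN_SYSTEM, build_structure, model_config_from_json,
                   model_config_to_json, ode_rhs, preset_structure,
                   solve_profile, steady_state_ecf_ratio)
from conftest import rand_params


@pytest.mark.parametrize("drug, expect", [
    ("methotrexate", dict(per1=True, per2=True, bcsfb_efflux=True, icf=False)),
    ("atenolol", dict(per1=True, per2=False, bcsfb_efflux=False, icf=False)),
    ("quinidine", dict(per1=True, icf=True)),
    ("paliperidone", dict(per1=False, icf=True)),
    ("risperidone", dict(per1=False, per2=False, icf=False)),
    ("acetaminophen", dict(per1=True, enterohepatic=True)),
])
def test_presets_reproduce_structural_features(drug, expect):
    s = build_structure(drug)
    for k, v in expect.items():
        assert getattr(s, k) is v, f"{drug}.{k}"


def test_structure_invariants_rejected():
    with pytest.raises(ValueError):
        ModelStructure(per2=True, per1=False)
    with pytest.raises(ValueError):
        ModelStructure(species="rat", evd=True, q_lv_evd=0.1, v_evd=10.0)
    with pytest.raises(ValueError, match="unknown structural feature"):
        build_structure({"species": "rat", "features": ["warp_drive"]})


def test_structure_always_contains_core_compartments():
    comps = ModelStructure().compartments
    for c in ("plasma", "brain_ecf", "csf_lv", "csf_tfv", "csf_cm", "csf_sas"):
        assert c in comps


def test_ode_rhs_trivial_states(acet):
    params, structure = acet
    n = len(structure.compartments)
    zero = ode_rhs(np.zeros(n), 0.0, params, RAT_SYSTEM, structure, 0.0)
    assert np.allclose(zero, 0.0)
    with_input = ode_rhs(np.zeros(n), 0.0, params, RAT_SYSTEM, structure, 7.5)
    assert with_input[0] == pytest.approx(7.5)
    assert np.allclose(with_input[1:], 0.0)
    with pytest.raises(ValueError, match="state length"):
        ode_rhs(np.zeros(n + 1), 0.0, params, RAT_SYSTEM, structure)


@given(st.integers(0, 2 ** 31 - 1))
def test_ode_rhs_conserves_mass_without_elimination(seed):
    rng = np.random.default_rng(seed)
    params = rand_params(rng, cl_pl=0.0)
    structure = ModelStructure(per1=True)
    amounts = rng.uniform(0, 1e5, len(structure.compartments))
    dadt = ode_rhs(amounts, 0.0, params, RAT_SYSTEM, structure, 0.0)
    assert abs(dadt.sum()) <= 1e-9 * max(np.abs(dadt).max(), 1.0)


def test_constant_infusion_reaches_one_compartment_steady_state():
    # degenerate plasma-only model: Css = rate / CL
    p = DrugParameters(cl_pl=5.0, q_pl_ecf=0.0, q_diff=0.0, v_pl=100.0)
    doses = [DoseEvent(0.0, 1e6, 200.0 * 1e6)]  # 200 ng/min forever
    prof = solve_profile(ModelStructure(), p, RAT_SYSTEM, doses, [8e5])
    assert prof.conc("plasma")[-1] == pytest.approx(200.0 / 5.0, rel=1e-6)


def test_acetaminophen_steady_state_returns_to_net_clearance(acet):
    # all distribution loops close, so Css,plasma = rate / CL_net
    params, structure = acet
    cl_net = params.cl_pl * (1.0 - params.fraction)
    doses = [DoseEvent(0.0, 1e7, 150.0 * 1e7)]
    prof = solve_profile(structure, params, RAT_SYSTEM, doses, [9e6])
    assert prof.conc("plasma")[-1] == pytest.approx(150.0 / cl_net, rel=1e-5)


def test_steady_state_ecf_ratio_worked_examples():
    p = DrugParameters(cl_pl=1, q_pl_ecf=0.0281, q_diff=0.0556, v_pl=1)
    assert steady_state_ecf_ratio(p) == pytest.approx(0.3357, abs=5e-5)
    assert steady_state_ecf_ratio(
        DrugParameters(cl_pl=1, q_pl_ecf=0.01, q_diff=0.0, v_pl=1)) == 1.0
    assert steady_state_ecf_ratio(
        DrugParameters(cl_pl=1, q_pl_ecf=0.0, q_diff=0.01, v_pl=1)) == 0.0
    with pytest.raises(ZeroDivisionError):
        steady_state_ecf_ratio(
            DrugParameters(cl_pl=1, q_pl_ecf=0.0, q_diff=0.0, v_pl=1))


def test_simulated_steady_state_matches_closed_form_ratio():
    # reduced model: C_ECF/(f_p C_PL) -> Q_PL_ECF/(Q_PL_ECF + Q_DIFF)
    rng = np.random.default_rng(42)
    structure = ModelStructure(per1=True)
    for _ in range(20):
        p = rand_params(rng, f_p=float(rng.uniform(0.1, 1.0)))
        doses = [DoseEvent(0.0, 5e6, 100.0 * 5e6)]
        prof = solve_profile(structure, p, RAT_SYSTEM, doses, [4.5e6])
        ratio = prof.conc("brain_ecf")[-1] / (p.f_p * prof.conc("plasma")[-1])
        assert ratio == pytest.approx(steady_state_ecf_ratio(p), rel=1e-3)


def test_csf_chain_equilibrates_at_steady_state():
    rng = np.random.default_rng(7)
    p = rand_params(rng)
    prof = solve_profile(ModelStructure(per1=True), p, RAT_SYSTEM,
                        [DoseEvent(0.0, 5e6, 100.0 * 5e6)], [4.5e6])
    ecf = prof.conc("brain_ecf")[-1]
    for c in ("csf_lv", "csf_tfv", "csf_cm", "csf_sas"):
        assert prof.conc(c)[-1] == pytest.approx(ecf, rel=1e-3)


def test_mass_conserved_after_infusion_without_elimination():
    rng = np.random.default_rng(3)
    p = rand_params(rng, cl_pl=0.0)
    doses = [DoseEvent(0.0, 10.0, 1e6)]
    times = np.linspace(15.0, 600.0, 40)
    prof = solve_profile(ModelStructure(per1=True), p, RAT_SYSTEM, doses, times)
    total = prof.total_amount()
    assert np.all(np.abs(total - 1e6) <= 1e-8 * 1e6)


@given(st.integers(0, 2 ** 31 - 1))
def test_concentrations_never_go_negative(seed):
    rng = np.random.default_rng(seed)
    p = rand_params(rng)
    prof = solve_profile(ModelStructure(per1=True), p, RAT_SYSTEM,
                        [DoseEvent(0.0, 10.0, 1e6)],
                        np.linspace(0, 480, 33))
    cmax = max(float(c.max()) for c in prof.concentrations.values())
    for c in prof.concentrations.values():
        assert np.all(c >= -1e-12 * cmax)


def test_brain_exposure_monotone_in_bbb_clearance():
    rng = np.random.default_rng(11)
    base = rand_params(rng)
    times = np.linspace(0, 360, 73)
    aucs = []
    for q in [0.002, 0.01, 0.03, 0.08]:
        p = base.updated(q_pl_ecf=q)
        prof = solve_profile(ModelStructure(per1=True), p, RAT_SYSTEM,
                            [DoseEvent(0.0, 10.0, 1e6)], times)
        aucs.append(np.trapezoid(prof.conc("brain_ecf"), times))
    assert np.all(np.diff(aucs) > 0)


def test_profile_reports_amount_concentration_consistency(acet):
    params, structure = acet
    prof = solve_profile(structure, params, RAT_SYSTEM,
                        [DoseEvent(0.0, 10.0, 4e6)], np.linspace(0, 240, 25))
    for c in structure.compartments:
        np.testing.assert_allclose(prof.conc(c) * prof.volumes[c],
                                   prof.amounts[c])


def test_infusion_events_handled_exactly():
    # profile slope changes discontinuously at infusion stop, grid point hit
    p = DrugParameters(cl_pl=2.0, q_pl_ecf=0.0, q_diff=0.0, v_pl=50.0)
    prof = solve_profile(ModelStructure(), p, RAT_SYSTEM,
                        [DoseEvent(0.0, 30.0, 3000.0)],
                        np.array([29.999, 30.0, 30.001]))
    a = prof.amounts["plasma"]
    assert a[1] >= a[0] and a[2] < a[1] + 0.2 * (a[1] - a[0])


def test_dose_event_validation():
    with pytest.raises(ValueError):
        DoseEvent(0.0, 0.0, 100.0)
    with pytest.raises(ValueError):
        DoseEvent(0.0, 10.0, -1.0)
    with pytest.raises(ValueError):
        DoseEvent(-5.0, 10.0, 100.0)


def test_model_config_json_roundtrip(acet):
    params, structure = acet
    text = model_config_to_json(structure, params, RAT_SYSTEM)
    s2, p2, sys2 = model_config_from_json(text)
    assert s2 == structure
    assert p2 == params
    assert sys2 == RAT_SYSTEM
    # and for a human structure with EVD attached
    hs = ModelStructure(species="human", per1=True, evd=True,
                        q_lv_evd=0.1, v_evd=10.0)
    text = model_config_to_json(hs, params.updated(f_p=1.0), HUMAN_SYSTEM)
    s3, _, _ = model_config_from_json(text)
    assert s3 == hs


def test_methotrexate_preset_carries_bcsfb_efflux():
    s = preset_structure("methotrexate")
    assert s.bcsfb_efflux
    from cnspk import preset_parameters
    assert preset_parameters("methotrexate").q_lv_pl == pytest.approx(0.105)
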