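import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def acet():
    """Acetaminophen rat preset (params, structure)."""
    from cnspk import preset_parameters, preset_structure
    return preset_parameters("acetaminophen"), preset_structure("acetaminophen")


@pytest.fixture(scope="session")
def acet_dataset():
    """One assembled acetaminophen rat study (seed 0), shared read-only."""
    from cnspk import (assemble_dataset, default_design, drug_config,
                       generate_rat_study, to_dialect_frame)
    raw = generate_rat_study(default_design("acetaminophen"), seed=0)
    return assemble_dataset(to_dialect_frame(raw), drug_config("acetaminophen"))


def rand_params(rng, **overrides):
    """Random positive parameter set for a reduced (per1-only) structure."""
    from cnspk import DrugParameters
    kw = dict(
        cl_pl=float(rng.uniform(1, 50)),
        q_pl_per1=float(rng.uniform(1, 50)),
        q_pl_ecf=float(rng.uniform(0.001, 0.05)),
        q_diff=float(rng.uniform(0.005, 0.08)),
        v_pl=float(rng.uniform(50, 500)),
        v_per1=float(rng.uniform(100, 2000)),
    )
    kw.update(overrides)
    return DrugParameters(**kw)
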