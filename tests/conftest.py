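import numpy as np
import pytest

from ucmbalance import (
    MarkerTrial,
    SynthScenario,
    build_jacobian,
    generate_step_trial,
    load_default_model,
)
from ucmbalance.body_model import BodyModel
from ucmbalance.marker_io import MARKER_NAMES
from ucmbalance.synthetic_data import STANCE_TEMPLATE, _ANTHROPOMETRY


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture(scope="session")
def jacobian(model):
    return build_jacobian(model)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_model(rng: np.random.Generator, base: BodyModel) -> BodyModel:
    """A valid random anthropometric table on the canonical topology."""
    mf = rng.dirichlet(np.full(14, 5.0))
    cf = rng.uniform(0.2, 0.8, size=14)
    return BodyModel(
        segments=base.segments,
        mass_fractions=mf,
        com_fractions=cf,
        proximal=base.proximal,
        distal=base.distal,
        parent=base.parent,
    )


def static_trial(T: int = 10, rate: float = 100.0, **kwargs) -> MarkerTrial:
    """A motionless quiet-stance trial built from the template posture."""
    pos = np.empty((T, 19, 3))
    for i, name in enumerate(MARKER_NAMES):
        pos[:, i, :] = STANCE_TEMPLATE[name]
    defaults = dict(
        subject_id="static",
        group_label="test",
        sampling_rate=rate,
        positions=pos,
        events={"perturbation_onset": 0},
        anthropometry=dict(_ANTHROPOMETRY),
    )
    defaults.update(kwargs)
    return MarkerTrial(**defaults)


@pytest.fixture(scope="session")
def step_trial(model):
    """One default-scenario puppet trial with its scripted ground truth."""
    scenario = SynthScenario.step_default(seed=7)
    return generate_step_trial(scenario, model)
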