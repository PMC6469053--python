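import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    from mpsjc.joint_model import default_model
    return default_model()


@pytest.fixture(scope="session")
def trajectory(model):
    from mpsjc.icr_engine import sweep
    return sweep(model)


@pytest.fixture(scope="session")
def sphere_model(model):
    """Default model with both groove flattenings set to zero."""
    from mpsjc.joint_model import JointModel
    d = model.model_dump()
    for g in ("tibial_groove", "fibular_groove"):
        d["head"][g]["flattening"] = 0.0
    return JointModel(**d)


@pytest.fixture(scope="session")
def default_stack():
    from mpsjc.synthetic_sections import StackGenSpec, generate_stack
    return generate_stack(StackGenSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
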