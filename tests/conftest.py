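import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from spineosteo.anatomy import SubjectParams, generate_phantom
from spineosteo.planner import plan_frame


@pytest.fixture(scope="session")
def default_phantom():
    """The default synthetic subject, shared across the suite."""
    return generate_phantom(SubjectParams(rng_seed=42))


@pytest.fixture(scope="session")
def default_frame(default_phantom):
    return plan_frame(default_phantom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
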