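import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gt():
    """The toy G-T cluster: (system, reference surface, base surface)."""
    from protonfes.modelsys import build_gt_toy

    return build_gt_toy()


@pytest.fixture(scope="session")
def gt_rc():
    from protonfes.modelsys import gt_reaction_coordinates

    return gt_reaction_coordinates()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
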