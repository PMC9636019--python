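import numpy as np
import pytest

from acmpose.skeleton import build_default_skeleton
from acmpose.synth import generate_scene, make_true_params, make_virtual_rig


@pytest.fixture(scope="session")
def rat():
    """Default rat skeleton bundle: (graph, limits, prior, layout)."""
    return build_default_skeleton("rat", 300.0)


@pytest.fixture(scope="session")
def rat_params(rat):
    graph, _, prior, layout = rat
    return make_true_params(graph, layout, prior)


@pytest.fixture(scope="session")
def rig():
    return make_virtual_rig()


@pytest.fixture(scope="session")
def small_scene():
    """One second of synthetic gait under the default noisy conditions."""
    return generate_scene(seed=2, duration_s=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
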