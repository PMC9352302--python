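import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fddcs.reconstruction import build_masks, reconstruct_and_normalize, temporal_filter
from fddcs.scenarios import scaled_mask_geometry, small_dynamic_scenario
from fddcs.simulator import simulate

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_masks():
    """Mask set for the 64-pixel grid used by most simulated tests."""
    return build_masks(scaled_mask_geometry(64), 64)


@pytest.fixture(scope="session")
def dynamic_stack():
    """A small dynamic-speckle acquisition with full detector noise."""
    cfg = small_dynamic_scenario(42, n_frames=80)
    return simulate(cfg).stacks[200.0]


@pytest.fixture(scope="session")
def dynamic_rec(dynamic_stack, small_masks):
    """DC-pair reconstruction of the small dynamic acquisition."""
    holo = temporal_filter(dynamic_stack.frames, "dc_pair")
    return reconstruct_and_normalize(holo, small_masks)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
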