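import numpy as np
import pytest

from gcmotility import synthetic as syn


@pytest.fixture(scope="session")
def control_stack_h0():
    """Height-0 movie at control motility parameters, default noise."""
    params = syn.MotilityParams(seed=1, n_cycles=5)
    cfg = syn.ImagingConfig(heights_um=(0.0,))
    return syn.generate_lamellipodium_stack(params, cfg)


@pytest.fixture(scope="session")
def noiseless_flat_stack():
    """Noise-free movie with no vertical lift: the cleanest tracking target."""
    params = syn.MotilityParams(seed=4, n_cycles=3, noise_sd=0.0, lift_profile=None)
    cfg = syn.ImagingConfig(heights_um=(0.0,))
    return syn.generate_lamellipodium_stack(params, cfg)


@pytest.fixture(scope="session")
def full_stack():
    """All seven heights, three cycles, default control parameters."""
    params = syn.MotilityParams(seed=2, n_cycles=3)
    return syn.generate_lamellipodium_stack(params, syn.ImagingConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
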