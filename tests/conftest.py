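import numpy as np
import pytest

from netdiv import MHConfig, EMConfig, design_from_template, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_mh():
    """Short chains for structural tests where mixing quality is irrelevant."""
    return MHConfig(burn=50, r_draws=50, seed=7)


@pytest.fixture
def fast_em():
    return EMConfig(n_iter=2)


@pytest.fixture
def small_dataset():
    """Tiny two-group dataset simulated from the model (n=8, Q=10)."""
    design = design_from_template(
        n=8, q=10, group_fraction=0.25, network_strength=0.3,
        depth_range=(2e3, 5e3), seed=42,
    )
    W, Z, Y = simulate_dataset(design, np.random.default_rng(4242))
    return design, W, Z, Y
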