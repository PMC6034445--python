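import numpy as np
import pytest

import leafvein as lv


@pytest.fixture(scope="session")
def default_spec():
    return lv.SyntheticLeafSpec(seed=1)


@pytest.fixture(scope="session")
def default_leaf(default_spec):
    leaf, stack = lv.simulate_leaf(default_spec)
    return leaf, stack


@pytest.fixture(scope="session")
def noiseless_leaf():
    """Noiseless, ambient-free pinnate leaf for exact round-trip checks."""
    spec = lv.SyntheticLeafSpec(seed=3, noise_sd=0.0, ambient=0.0)
    leaf, stack = lv.simulate_leaf(spec)
    return leaf, stack


@pytest.fixture(scope="session")
def rig():
    return lv.LightRig.default_four()


def angular_error_deg(n_true, n_est):
    cos = np.clip(np.sum(n_true * n_est, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def shadow_mask(leaf, rig):
    """Pixels in attached shadow under at least one light."""
    n = leaf.normals()
    shadow = np.zeros(leaf.height_field.shape, dtype=bool)
    for L in rig.vectors:
        shadow |= (n @ L) <= 0
    return shadow
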