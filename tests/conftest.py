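import numpy as np
import pytest

from nmfpick import Micrograph, PickingConfig, SimConfig, simulate_micrograph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def picking_config():
    return PickingConfig()


@pytest.fixture(scope="session")
def small_micrograph():
    """A 128x128 synthetic micrograph with one top and one side particle."""
    cfg = SimConfig(shape=(128, 128), n_top=1, n_side=1, seed=7)
    mic, truth = simulate_micrograph(cfg)
    return mic, truth


def make_annulus(shape, center, r_out, r_in, depth=1.0):
    """Annular (ring) phantom mask scaled by depth."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    return depth * ((dist <= r_out) & (dist >= r_in))


def make_rectangle(shape, center, length, width, angle=0.0, depth=1.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    ct, st = np.cos(angle), np.sin(angle)
    xl = (cc - center[1]) * ct + (rr - center[0]) * st
    yl = -(cc - center[1]) * st + (rr - center[0]) * ct
    return depth * ((np.abs(xl) <= length / 2) & (np.abs(yl) <= width / 2))


@pytest.fixture
def phantom_builders():
    return make_annulus, make_rectangle
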