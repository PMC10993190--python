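import numpy as np
import pytest
import scipy.ndimage as ndi

from respmoco import trajectory as tj
from respmoco.motion import MotionField, RespTranslations, bin_heartbeats


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def smooth_coils(shape, n_coils, rng, sigma=1.5):
    """Random smooth RSS-normalized complex coil maps."""
    maps = np.stack(
        [
            ndi.gaussian_filter(rng.normal(size=shape), sigma)
            + 1j * ndi.gaussian_filter(rng.normal(size=shape), sigma)
            for _ in range(n_coils)
        ]
    )
    return maps / np.sqrt((np.abs(maps) ** 2).sum(axis=0))


def smooth_velocity(shape, rng, sigma=2.0, scale=1.5):
    return np.stack(
        [ndi.gaussian_filter(rng.normal(0, 1, shape), sigma) * scale for _ in range(3)]
    )


@pytest.fixture
def tiny_motion_operator(rng):
    """Well-conditioned two-bin operator on a 4x8x8 grid with smooth motion.

    Every location is acquired once per bin, so the normal system is
    benign and the dense oracle is feasible.
    """
    from respmoco.operators import EncodingOperator

    shape = (4, 8, 8)
    g = tj.GridSpec(8, 8)
    t1 = tj.full_trajectory(g, 1, rectangular=True)
    readouts = np.concatenate([t1.readouts, t1.readouts])
    hb = np.concatenate(
        [np.zeros(t1.n_readouts, np.int32), np.ones(t1.n_readouts, np.int32)]
    )
    coils = smooth_coils(shape, 3, rng)
    bins = bin_heartbeats(RespTranslations(np.array([[1.0, 0.0], [-1.0, 0.0]])), 2, 0.0)
    motion = [
        MotionField.from_velocity(smooth_velocity(shape, rng)) for _ in range(2)
    ]
    return EncodingOperator(
        shape, coils, readouts, hb, bins, motion=motion, adjoint_mode="exact"
    )
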