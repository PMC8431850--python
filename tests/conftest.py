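import numpy as np
import pytest

from microquant import FixtureSpec, IntensityImage, LabelImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def quantized_image(values: np.ndarray, bit_depth: int = 8) -> IntensityImage:
    """Snap float values in [0, 1] onto the representable grid."""
    levels = 2**bit_depth
    v = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
    return IntensityImage(np.round(v * (levels - 1)) / (levels - 1), levels)


def square_labels(shape, boxes) -> LabelImage:
    """Label image from a list of ((r0, r1), (c0, c1)) half-open boxes."""
    lab = np.zeros(shape, dtype=np.int32)
    for k, sl in enumerate(boxes):
        lab[tuple(slice(a, b) for a, b in sl)] = k + 1
    return LabelImage(lab)


@pytest.fixture
def correlated_pair_grid():
    """Small grid of seeded correlated channel pairs (positive rho only)."""
    pairs = []
    for depth in (8, 16):
        for rho in (0.3, 0.6, 0.9):
            for seed in range(3):
                spec = FixtureSpec(rho=rho, seed=seed + 100 * depth, bit_depth=depth)
                pairs.append((spec, rho, depth))
    return pairs
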