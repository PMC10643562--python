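import numpy as np
import pytest

from misalign import (MisalignmentParams, PhantomConfig, generate_phantom)

# Small, fast phantom geometry shared by unit tests: 40 x 40 x 36 mm FOV
SMALL_SHAPE = (64, 64, 12)
SMALL_SPACING = (0.625, 0.625, 3.0)


def small_config(**overrides) -> PhantomConfig:
    base = dict(grid_shape=SMALL_SHAPE, spacing=SMALL_SPACING, n_lesions=1,
                lesion_radius_range=(5.5, 7.5), noise_sigma=0.05, seed=11)
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture
def aligned_exam():
    """A small phantom with one significant lesion, no misalignment."""
    return generate_phantom(small_config())


@pytest.fixture
def misaligned_exam():
    """The same phantom with a known (4, -3, 3) mm / 6 deg / 1.05 truth."""
    truth = MisalignmentParams((4.0, -3.0, 3.0), 6.0, 1.05)
    return generate_phantom(small_config(true_misalignment=truth))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def mask_centroid_mm(mask, spacing):
    idx = np.argwhere(np.asarray(mask) > 0)
    return idx.mean(axis=0) * np.asarray(spacing, dtype=float)
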