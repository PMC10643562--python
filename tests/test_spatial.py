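"""Misalignment sampling, transform algebra, resampling, gating, ordering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from misalign import (AugmentationPipeline, MisalignmentAugmentation,
                      MisalignmentConfig, MisalignmentParams,
                      RandomGlobalAffine, SpatialTransform,
                      apply_misalignment_augmentation, build_transform,
                      decompose_transform, dice, generate_phantom,
                      resample_with_transform, sample_misalignment)
from misalign.errors import PipelineOrderError

from conftest import mask_centroid_mm, small_config

DEFAULT_BOUNDS = MisalignmentConfig()  # (10, 10, 6) mm, 15 deg, ratio 0.1


# ---------------------------------------------------------------------------
# sampling law
# ---------------------------------------------------------------------------

def test_sampled_parameters_respect_bounds_and_uniform_law(rng):
    n = 20_000
    draws = [sample_misalignment(DEFAULT_BOUNDS, rng) for _ in range(n)]
    t = np.array([d.translation_mm for d in draws])
    rot = np.array([d.rotation_deg for d in draws])
    sq = np.array([d.squeeze_factor for d in draws])

    assert np.all(np.abs(t) <= (10, 10, 6))
    assert np.all(np.abs(rot) <= 15)
    assert np.all(np.abs(sq - 1) <= 0.1)

    # empirical means within 3 standard errors of the uniform-law means
    for vals, half_width, center in [(t[:, 0], 10, 0), (t[:, 1], 10, 0),
                                     (t[:, 2], 6, 0), (rot, 15, 0),
                                     (sq, 0.1, 1)]:
        se = half_width / np.sqrt(3 * n)
        assert abs(vals.mean() - center) < 3 * se

    # Kolmogorov-Smirnov: tx compatible with Uniform(-10, 10)
    _, p = stats.kstest(t[:, 0], stats.uniform(loc=-10, scale=20).cdf)
    assert p > 0.01


def test_zero_amplitude_config_always_yields_identity(rng):
    cfg = MisalignmentConfig(max_translation_mm=(0, 0, 0), max_rotation_deg=0,
                             max_squeeze_ratio=0, probability=1.0)
    for _ in range(50):
        params = sample_misalignment(cfg, rng)
        assert params == MisalignmentParams((0.0, 0.0, 0.0), 0.0, 1.0)


def test_config_validation():
    with pytest.raises(ValueError):
        MisalignmentConfig(probability=1.5)
    with pytest.raises(ValueError):
        MisalignmentConfig(max_translation_mm=(-1, 0, 0))


# ---------------------------------------------------------------------------
# transform algebra
# ---------------------------------------------------------------------------

def test_zero_params_build_exact_identity():
    t = build_transform(MisalignmentParams.identity(), center_mm=(5, 5, 5))
    assert np.array_equal(t.matrix, np.eye(4))


def test_pure_translation_moves_every_point():
    t = build_transform(MisalignmentParams((5, 0, 0), 0, 1.0), (7, 3, 2))
    pts = np.array([[0.0, 0, 0], [1, 2, 3], [-4, 5, 9]])
    assert np.allclose(t.apply_points(pts), pts + (5, 0, 0))


def test_quarter_turn_about_center():
    c = np.array([10.0, 12.0, 5.0])
    t = build_transform(MisalignmentParams((0, 0, 0), 90.0, 1.0), c)
    assert np.allclose(t.apply_points(c + (3, 0, 0)), c + (0, 3, 0))


def test_squeeze_scales_only_the_dorsoventral_axis():
    c = (0.0, 0.0, 0.0)
    t = build_transform(MisalignmentParams((0, 0, 0), 0.0, 0.9), c)
    assert np.allclose(t.apply_points(np.array([2.0, 4.0, 6.0])), (2, 3.6, 6))


@pytest.mark.parametrize("params", [
    MisalignmentParams((3.5, -2.0, 4.0), 12.0, 1.07),
    MisalignmentParams((-10, 10, -6), -15.0, 0.9),
    MisalignmentParams((0, 0, 0), 0.0, 1.0),
])
def test_decompose_inverts_build(params):
    t = build_transform(params, center_mm=(11.0, 9.0, 30.0))
    rec = decompose_transform(t)
    assert np.allclose(rec.translation_mm, params.translation_mm, atol=1e-9)
    assert np.isclose(rec.rotation_deg, params.rotation_deg)
    assert np.isclose(rec.squeeze_factor, params.squeeze_factor)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(tx=st.floats(-10, 10), ty=st.floats(-10, 10), tz=st.floats(-6, 6),
       rot=st.floats(-15, 15), squeeze=st.floats(0.9, 1.1))
def test_decompose_inverts_build_over_the_whole_bound_box(tx, ty, tz, rot,
                                                          squeeze):
    params = MisalignmentParams((tx, ty, tz), rot, squeeze)
    rec = decompose_transform(build_transform(params, (25.0, 25.0, 28.5)))
    assert np.allclose(rec.translation_mm, params.translation_mm, atol=1e-8)
    assert np.isclose(rec.rotation_deg, params.rotation_deg, atol=1e-8)
    assert np.isclose(rec.squeeze_factor, params.squeeze_factor, atol=1e-10)


def test_transform_invariants():
    with pytest.raises(ValueError):
        SpatialTransform(np.zeros((4, 4)))
    t = build_transform(MisalignmentParams((1, 2, 3), 10, 1.05), (0, 0, 0))
    assert np.allclose((t.compose(t.inverse())).matrix, np.eye(4))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_identity_resample_is_bit_exact(rng):
    vol = rng.normal(size=(10, 12, 6))
    out = resample_with_transform(vol, (0.5, 0.5, 3.0),
                                  SpatialTransform.identity())
    assert np.array_equal(out, vol)


def test_one_voxel_translation_equals_index_shift(rng):
    spacing = (0.5, 0.5, 3.0)
    vol = rng.integers(0, 9, size=(10, 12, 6)).astype(np.int16)
    t = build_transform(MisalignmentParams((spacing[0], 0, 0), 0, 1.0),
                        (0, 0, 0))
    out = resample_with_transform(vol, spacing, t, interpolation="nearest",
                                  fill_value=-1)
    expected = np.full_like(vol, -1)
    expected[1:] = vol[:-1]
    assert np.array_equal(out, expected)


def test_roundtrip_resampling_error_small_in_interior():
    x, y, z = np.meshgrid(*(np.linspace(0, 1, n) for n in (40, 40, 12)),
                          indexing="ij")
    vol = np.sin(4 * x) * np.cos(3 * y) + z  # smooth
    spacing = (0.625, 0.625, 3.0)
    t = build_transform(MisalignmentParams((2.1, -1.3, 1.5), 7.0, 1.05),
                        center_mm=(12.0, 12.0, 16.0))
    fwd = resample_with_transform(vol, spacing, t)
    back = resample_with_transform(fwd, spacing, t.inverse())
    interior = (slice(8, -8), slice(8, -8), slice(2, -2))
    err = np.abs(back[interior] - vol[interior]).max()
    assert err < 0.02 * np.ptp(vol)


def test_singular_transform_is_rejected():
    m = np.eye(4)
    m[1, 1] = 0.0
    with pytest.raises(ValueError, match="singular"):
        resample_with_transform(np.zeros((4, 4, 4)), (1, 1, 1),
                                SpatialTransform(m))


# ---------------------------------------------------------------------------
# the augmentation
# ---------------------------------------------------------------------------

def test_probability_zero_leaves_exam_bit_exact(aligned_exam, rng):
    out = apply_misalignment_augmentation(
        aligned_exam, MisalignmentConfig(probability=0.0), rng)
    assert out.augmentation_params is None
    assert np.array_equal(out.t2w, aligned_exam.t2w)
    assert np.array_equal(out.lesion_mask_t2w, aligned_exam.lesion_mask_t2w)


def test_forced_translation_moves_t2w_only(aligned_exam, rng):
    t = (4.0, 0.0, 0.0)
    before_hashes = {n: hash(getattr(aligned_exam, n).tobytes())
                     for n in ("dwi_high_b", "adc", "dwi_low_b",
                               "lesion_mask_dwi")}
    out = apply_misalignment_augmentation(
        aligned_exam, MisalignmentConfig(probability=1.0), rng,
        force_params=MisalignmentParams(t, 0.0, 1.0))
    shift = (mask_centroid_mm(out.lesion_mask_t2w, out.spacing)
             - mask_centroid_mm(aligned_exam.lesion_mask_t2w, out.spacing))
    assert np.all(np.abs(shift - t) <= np.asarray(out.spacing))
    for name, h in before_hashes.items():
        assert hash(getattr(out, name).tobytes()) == h, name


def test_gating_fraction_matches_probability(rng):
    from scipy.stats import binom

    exam = generate_phantom(small_config(grid_shape=(8, 8, 4),
                                         spacing=(4.0, 4.0, 4.0),
                                         lesion_radius_range=(4.5, 5.0),
                                         n_lesions=0))
    p, n = 0.4, 5000
    cfg = MisalignmentConfig(probability=p)
    applied = sum(
        apply_misalignment_augmentation(exam, cfg, rng).augmentation_params
        is not None for _ in range(n))
    lo, hi = binom.ppf((0.005, 0.995), n, p)
    assert lo <= applied <= hi


def test_image_and_label_move_together(aligned_exam, rng):
    """The resampled lesion mask stays on top of the analytically
    transformed ideal lesion."""
    params = MisalignmentParams((3.0, -2.0, 0.0), 8.0, 1.0)
    out = apply_misalignment_augmentation(
        aligned_exam, MisalignmentConfig(probability=1.0), rng,
        force_params=params)
    # analytic ideal: transform the lesion-center sphere directly
    transform = build_transform(params, aligned_exam.grid_center_mm)
    lesion = aligned_exam.lesion_catalog[0]
    moved_center = transform.apply_points(np.asarray(lesion.center_mm))
    pts = np.stack(np.meshgrid(
        *[np.arange(n) * s for n, s in zip(aligned_exam.grid_shape,
                                           aligned_exam.spacing)],
        indexing="ij"), axis=-1)
    ideal = np.linalg.norm(pts - moved_center, axis=-1) <= lesion.radius_mm
    assert (out.lesion_mask_t2w > 0).sum() >= 5
    assert dice(out.lesion_mask_t2w > 0, ideal) >= 0.9


# ---------------------------------------------------------------------------
# pipeline ordering contract
# ---------------------------------------------------------------------------

def test_misalignment_before_global_is_accepted():
    mis = MisalignmentAugmentation(MisalignmentConfig(), seed=0)
    glob = RandomGlobalAffine(seed=1)
    AugmentationPipeline([mis, glob])
    AugmentationPipeline([mis])  # vacuous ordering is fine


def test_misalignment_after_global_is_rejected():
    mis = MisalignmentAugmentation(MisalignmentConfig(), seed=0)
    glob = RandomGlobalAffine(seed=1)
    with pytest.raises(PipelineOrderError,
                       match="misalignment_augmentation.*random_global_affine"):
        AugmentationPipeline([glob, mis])


def test_pipeline_applies_stages_in_order(aligned_exam):
    mis = MisalignmentAugmentation(MisalignmentConfig(probability=1.0), seed=4)
    glob = RandomGlobalAffine(seed=5)
    out = AugmentationPipeline([mis, glob])(aligned_exam)
    assert mis.last_params is not None
    assert out.t2w.shape == aligned_exam.t2w.shape
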