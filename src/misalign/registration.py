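"""Registration stages producing the three dataset variants.

Three ways of handling inter-modality misalignment are provided:

* ``identity`` — use the exam as acquired (the unregistered variant);
* ``bspline_mi`` — deformable B-spline registration driven by mutual
  information between the T2w reference and the lowest-b DWI, the
  diffusion channel most similar to T2w; the fitted transform is then
  propagated to the high-b DWI, the ADC map and the DWI-domain masks;
* ``gt_matching`` — segmentation-driven affine registration that
  maximizes the (soft) overlap of the prostate and lesion masks between
  the two domains, used as a reference for how good alignment can get
  when ground truth is available.

The T2w domain is always the fixed side: DWI-domain data are resampled
onto the T2w grid and the fixed images are never touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk
from scipy import ndimage, optimize

from .errors import RegistrationError
from .exam import MultiModalExam
from .spatial import (MisalignmentParams, SpatialTransform, build_transform,
                      resample_with_transform)

__all__ = ["RegistrationResult", "BsplineOptions", "GtMatchingOptions",
           "mutual_information", "register_bspline", "register_gt_matching",
           "propagate", "register_exam"]


@dataclass
class RegistrationResult:
    """A fitted transform, its final similarity value and a method tag.

    ``transform`` expresses the mapping used for propagation: a
    :class:`SpatialTransform` (gt_matching / identity) is pull-resampled
    by this package, a :class:`SimpleITK.Transform` (bspline_mi) maps
    fixed-domain physical points to moving-domain sample locations.
    """

    transform: object
    similarity_value: float
    method: str  # {"bspline_mi", "gt_matching", "identity"}
    fixed_domain: Tuple[Tuple[int, int, int], Tuple[float, float, float]]
    estimated_params: Optional[MisalignmentParams] = None

    def __post_init__(self) -> None:
        if self.method not in ("bspline_mi", "gt_matching", "identity"):
            raise ValueError(f"unknown method tag '{self.method}'")
        if self.method in ("gt_matching", "identity") and not isinstance(
                self.transform, SpatialTransform):
            raise ValueError(f"method '{self.method}' requires a SpatialTransform")
        if self.method == "bspline_mi" and not isinstance(
                self.transform, sitk.Transform):
            raise ValueError("method 'bspline_mi' requires a SimpleITK transform")

    def displacement_field(self) -> np.ndarray:
        """Dense displacement (mm) on the fixed grid, shape (x, y, z, 3)."""
        shape, spacing = self.fixed_domain
        if isinstance(self.transform, SpatialTransform):
            pts = _grid_points(shape, spacing)
            return self.transform.inverse().apply_points(pts) - pts
        ref = _blank_sitk(shape, spacing)
        f = sitk.TransformToDisplacementField(
            self.transform, sitk.sitkVectorFloat64, ref.GetSize(),
            ref.GetOrigin(), ref.GetSpacing(), ref.GetDirection())
        return sitk.GetArrayFromImage(f).transpose(2, 1, 0, 3)


@dataclass(frozen=True)
class BsplineOptions:
    """Multi-resolution B-spline registration settings."""

    control_point_spacing_mm: float = 40.0
    mi_bins: int = 32
    shrink_factors: Tuple[int, ...] = (8, 4, 2)
    smoothing_sigmas: Tuple[float, ...] = (2.0, 1.0, 0.0)
    iterations: int = 20
    sampling_fraction: float = 0.2
    max_coefficient_mm: float = 20.0


@dataclass(frozen=True)
class GtMatchingOptions:
    """Mask-overlap affine registration settings.

    ``stride`` thins the voxel grid on which the soft-Dice objective is
    evaluated (the smoothed masks vary on the millimetre scale, so a
    coarser evaluation grid does not blunt the optimum but cuts the
    cost per function evaluation).
    """

    smooth_sigma_mm: float = 2.0
    lesion_weight: float = 1.0
    allow_rotation: bool = True
    allow_squeeze: bool = True
    xtol: float = 1e-3
    max_iter: int = 400
    stride: Tuple[int, int, int] = (3, 3, 1)


# ---------------------------------------------------------------------------
# numpy <-> SimpleITK plumbing (arrays are indexed [x, y, z] package-wide)
# ---------------------------------------------------------------------------

def _to_sitk(vol: np.ndarray, spacing: Sequence[float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.asarray(vol, dtype=np.float64).transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def _blank_sitk(shape, spacing) -> sitk.Image:
    img = sitk.Image([int(n) for n in shape], sitk.sitkFloat64)
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _grid_points(shape, spacing) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Mutual information (nats) of the joint intensity histogram of two
    equally shaped volumes.  A constant volume carries no information:
    MI = 0 with a warning."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("volumes must have equal shape")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant volume: mutual information is 0", stacklevel=2)
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


# ---------------------------------------------------------------------------
# B-spline mutual-information registration
# ---------------------------------------------------------------------------

def register_bspline(fixed: np.ndarray, moving: np.ndarray,
                     spacing: Sequence[float],
                     options: BsplineOptions = BsplineOptions()
                     ) -> RegistrationResult:
    """Deformable B-spline registration maximizing mutual information.

    ``fixed`` is the T2w volume, ``moving`` the lowest-b DWI (the
    diffusion image most similar to T2w).  Multi-resolution LBFGSB
    optimization of Mattes mutual information; the reported
    ``similarity_value`` is the MI between fixed and the warped moving
    image recomputed with :func:`mutual_information`.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise RegistrationError("fixed and moving volumes must share a grid")
    f_img = _to_sitk(fixed, spacing)
    m_img = _to_sitk(moving, spacing)

    physical = np.asarray(fixed.shape) * np.asarray(spacing, dtype=float)
    mesh = [max(1, int(round(p / options.control_point_spacing_mm)))
            for p in physical]
    tx0 = sitk.BSplineTransformInitializer(f_img, mesh)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(options.mi_bins)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(options.sampling_fraction)
    reg.SetInterpolator(sitk.sitkLinear)
    # LBFGSB with coefficient bounds: displacements stay within the
    # plausible misalignment range and the optimizer cannot push the
    # sampled points off the moving-image buffer
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=options.iterations,
        maximumNumberOfCorrections=5,
        maximumNumberOfFunctionEvaluations=500,
        costFunctionConvergenceFactor=1e9,
        lowerBound=-options.max_coefficient_mm,
        upperBound=options.max_coefficient_mm)
    reg.SetInitialTransform(tx0, inPlace=True)
    reg.SetShrinkFactorsPerLevel(list(options.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(options.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()

    try:
        fitted = reg.Execute(f_img, m_img)
    except RuntimeError as exc:
        raise RegistrationError(f"B-spline optimization failed: {exc}") from exc
    metric = reg.GetMetricValue()
    if not np.isfinite(metric):
        raise RegistrationError(
            f"B-spline optimizer diverged (metric={metric!r}, "
            f"stop condition: {reg.GetOptimizerStopConditionDescription()})")

    warped = _from_sitk(sitk.Resample(m_img, f_img, fitted, sitk.sitkLinear,
                                      float(moving.min())))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mi = mutual_information(fixed, warped, options.mi_bins)
    return RegistrationResult(transform=fitted, similarity_value=mi,
                              method="bspline_mi",
                              fixed_domain=(tuple(fixed.shape),
                                            tuple(float(s) for s in spacing)))


# ---------------------------------------------------------------------------
# GT-matching (segmentation-driven) registration
# ---------------------------------------------------------------------------

def _soft_masks(masks: Dict[str, np.ndarray], spacing, sigma_mm,
                lesion_weight) -> np.ndarray:
    """Gaussian-smoothed weighted blend of prostate and lesion masks."""
    sigma_vox = sigma_mm / np.asarray(spacing, dtype=float)
    out = ndimage.gaussian_filter((np.asarray(masks["prostate"]) > 0)
                                  .astype(float), sigma_vox)
    if "lesions" in masks and masks["lesions"] is not None:
        les = (np.asarray(masks["lesions"]) > 0).astype(float)
        if les.any():
            out = out + lesion_weight * ndimage.gaussian_filter(les, sigma_vox)
    return out


def _soft_dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = float((a * a).sum() + (b * b).sum())
    if denom == 0:
        return 1.0
    return float(2.0 * (a * b).sum() / denom)


def _centroid_mm(mask: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(np.asarray(mask) > 0)
    return idx.mean(axis=0) * np.asarray(spacing, dtype=float)


def register_gt_matching(fixed_masks: Dict[str, np.ndarray],
                         moving_masks: Dict[str, np.ndarray],
                         spacing: Sequence[float],
                         options: GtMatchingOptions = GtMatchingOptions()
                         ) -> RegistrationResult:
    """Affine registration by maximizing soft Dice of the paired masks.

    ``fixed_masks``/``moving_masks`` hold ``"prostate"`` (binary,
    required) and optionally ``"lesions"`` (labels) on the T2w and DWI
    domains respectively.  The affine is parameterized exactly like a
    misalignment (translation, in-plane rotation, dorsal–ventral
    squeeze) about the grid center and fitted with Powell's method on
    Gaussian-smoothed masks, initialized by prostate-centroid
    alignment.  ``estimated_params`` reports the recovered misalignment
    of the moving domain relative to the fixed one; ``transform`` is
    that motion (its inverse is what :func:`propagate` applies).
    """
    for name, masks in (("fixed", fixed_masks), ("moving", moving_masks)):
        if "prostate" not in masks or not (np.asarray(masks["prostate"]) > 0).any():
            raise RegistrationError(f"{name} prostate mask is empty")
    shape = np.asarray(fixed_masks["prostate"]).shape
    if np.asarray(moving_masks["prostate"]).shape != shape:
        raise RegistrationError("fixed and moving masks must share a grid")
    spacing = np.asarray(spacing, dtype=float)
    center = (np.asarray(shape) - 1) / 2.0 * spacing

    soft_fixed = _soft_masks(fixed_masks, spacing, options.smooth_sigma_mm,
                             options.lesion_weight)
    soft_moving = _soft_masks(moving_masks, spacing, options.smooth_sigma_mm,
                              options.lesion_weight)
    # thin the evaluation grid: smoothed masks are band-limited, so the
    # soft-Dice landscape is preserved on a coarser lattice
    st = tuple(options.stride)
    sl = tuple(slice(None, None, s) for s in st)
    soft_fixed_c = soft_fixed[sl]
    soft_moving_c = soft_moving[sl]
    spacing_c = spacing * np.asarray(st, dtype=float)

    t0 = _centroid_mm(moving_masks["prostate"], spacing) \
        - _centroid_mm(fixed_masks["prostate"], spacing)

    def unpack(x: np.ndarray) -> MisalignmentParams:
        tx, ty, tz = x[0], x[1], x[2]
        rot = x[3] if options.allow_rotation else 0.0
        sq = x[4] if options.allow_squeeze else 1.0
        return MisalignmentParams((tx, ty, tz), rot, sq)

    def objective(x: np.ndarray) -> float:
        params = unpack(x)
        motion = build_transform(params, center)
        warped = resample_with_transform(soft_moving_c, spacing_c,
                                         motion.inverse(),
                                         interpolation="linear", fill_value=0.0)
        return 1.0 - _soft_dice(soft_fixed_c, warped)

    x0 = np.array([t0[0], t0[1], t0[2], 0.0, 1.0])
    res = optimize.minimize(objective, x0, method="Powell",
                            options={"xtol": options.xtol, "ftol": 1e-8,
                                     "maxiter": options.max_iter})
    params = unpack(res.x)
    motion = build_transform(params, center)
    return RegistrationResult(transform=motion,
                              similarity_value=1.0 - float(res.fun),
                              method="gt_matching",
                              fixed_domain=(tuple(shape),
                                            tuple(float(s) for s in spacing)),
                              estimated_params=params)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def propagate(result: RegistrationResult,
              images: Sequence[np.ndarray] = (),
              masks: Sequence[np.ndarray] = (),
              spacing: Optional[Sequence[float]] = None):
    """Apply one fitted transform to DWI-domain siblings.

    The identical transform is applied to every input: linear
    interpolation for intensity images, nearest neighbor for masks.
    Returns ``(images_out, masks_out)`` as lists.
    """
    shape, fixed_spacing = result.fixed_domain
    spacing = fixed_spacing if spacing is None else tuple(spacing)
    if tuple(spacing) != tuple(fixed_spacing):
        raise RegistrationError(
            f"input spacing {spacing} does not match the registration's "
            f"fixed domain spacing {fixed_spacing}")
    for vol in list(images) + list(masks):
        if np.asarray(vol).shape != tuple(shape):
            raise RegistrationError(
                f"volume shape {np.asarray(vol).shape} does not match the "
                f"registration's fixed domain {shape}")

    images_out, masks_out = [], []
    if isinstance(result.transform, SpatialTransform):
        correction = result.transform.inverse()
        for vol in images:
            images_out.append(resample_with_transform(
                vol, spacing, correction, interpolation="linear"))
        for vol in masks:
            masks_out.append(resample_with_transform(
                vol, spacing, correction, interpolation="nearest", fill_value=0))
    else:
        ref = _blank_sitk(shape, spacing)
        for vol in images:
            img = _to_sitk(np.asarray(vol, dtype=float), spacing)
            out = sitk.Resample(img, ref, result.transform, sitk.sitkLinear,
                                float(np.asarray(vol).min()))
            images_out.append(_from_sitk(out))
        for vol in masks:
            img = _to_sitk(np.asarray(vol, dtype=float), spacing)
            out = sitk.Resample(img, ref, result.transform,
                                sitk.sitkNearestNeighbor, 0.0)
            masks_out.append(_from_sitk(out).astype(np.asarray(vol).dtype))
    return images_out, masks_out


# ---------------------------------------------------------------------------
# exam-level convenience
# ---------------------------------------------------------------------------

def register_exam(exam: MultiModalExam, method: str = "bspline_mi",
                  bspline_options: BsplineOptions = BsplineOptions(),
                  gt_options: GtMatchingOptions = GtMatchingOptions()
                  ) -> Tuple[MultiModalExam, RegistrationResult]:
    """Produce one registered dataset variant of an exam.

    ``method`` selects ``identity`` (no-op), ``bspline_mi`` (drive the
    registration with the low-b DWI, falling back to the ADC map with a
    warning when low-b is absent) or ``gt_matching`` (drive it with the
    prostate + lesion masks).  The fitted transform is propagated to
    high-b DWI, ADC, low-b DWI and the DWI-domain masks; T2w-domain
    data are returned untouched.
    """
    shape, spacing = exam.grid_shape, exam.spacing
    if method == "identity":
        result = RegistrationResult(SpatialTransform.identity(exam.grid_center_mm),
                                    similarity_value=float("nan"),
                                    method="identity",
                                    fixed_domain=(shape, spacing))
        return exam.copy(), result
    if method == "bspline_mi":
        moving = exam.dwi_low_b
        if moving is None:
            warnings.warn("dwi_low_b absent: registering with the ADC map "
                          "instead", stacklevel=2)
            moving = exam.adc
        result = register_bspline(exam.t2w, moving, spacing, bspline_options)
    elif method == "gt_matching":
        result = register_gt_matching(
            {"prostate": exam.prostate_mask, "lesions": exam.lesion_mask_t2w},
            {"prostate": exam.prostate_mask_dwi
             if exam.prostate_mask_dwi is not None else exam.prostate_mask,
             "lesions": exam.lesion_mask_dwi},
            spacing, gt_options)
    else:
        raise ValueError(f"unknown registration method '{method}'")

    image_names = [n for n in ("dwi_high_b", "adc", "dwi_low_b")
                   if getattr(exam, n) is not None]
    mask_names = [n for n in ("lesion_mask_dwi", "prostate_mask_dwi")
                  if getattr(exam, n) is not None]
    images_out, masks_out = propagate(
        result, [getattr(exam, n) for n in image_names],
        [getattr(exam, n) for n in mask_names], spacing)
    updates = dict(zip(image_names, images_out))
    updates.update(zip(mask_names, masks_out))
    return exam.copy(**updates), result
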