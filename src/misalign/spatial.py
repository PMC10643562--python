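"""Misalignment augmentation: sampling, affine construction, resampling.

Multi-modal prostate MRI is acquired sequentially, so the diffusion
sequences are routinely displaced relative to the T2w reference by
patient motion and susceptibility distortion.  The augmentation here
emulates that at training time by displacing the T2w volume (together
with its lesion annotations) relative to the DWI-domain channels with a
randomly sampled composition of three components:

* a translation with maximal amplitudes (10, 10, 6) mm along x, y, z,
* an in-plane rotation with maximal amplitude 15 degrees (the slice
  spacing is too coarse for through-plane rotation to be plausible),
* an affine squeeze along the dorsal–ventral axis with maximal ratio
  0.1, mimicking the distortion of echo-planar DWI by B0 field
  inhomogeneity.

Each amplitude is drawn uniformly on its symmetric interval; one
Bernoulli gate per exam decides whether the three components apply at
all.  The transform acts in physical millimetre coordinates so that the
amplitudes survive anisotropic voxel grids, and the augmentation is
meant to run *before* any global spatial augmentation — a constraint
the pipeline helper in this module enforces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import PipelineOrderError
from .exam import MultiModalExam

__all__ = [
    "MisalignmentConfig",
    "MisalignmentParams",
    "SpatialTransform",
    "sample_misalignment",
    "build_transform",
    "decompose_transform",
    "resample_with_transform",
    "apply_misalignment_augmentation",
    "MisalignmentAugmentation",
    "GlobalSpatialAugmentation",
    "RandomGlobalAffine",
    "AugmentationPipeline",
    "PROBABILITY_GRID",
]

#: Gating probabilities explored when tuning the augmentation.
PROBABILITY_GRID: Tuple[float, ...] = (0.0, 0.1, 0.2, 0.4)


@dataclass(frozen=True)
class MisalignmentConfig:
    """Amplitude bounds and gating probability of the augmentation.

    Defaults are the amplitudes used for prostate bpMRI: translations up
    to (10, 10, 6) mm, in-plane rotations up to 15 degrees and a
    dorsal–ventral squeeze ratio up to 0.1 (scale factor in [0.9, 1.1]).
    """

    max_translation_mm: Tuple[float, float, float] = (10.0, 10.0, 6.0)
    max_rotation_deg: float = 15.0
    max_squeeze_ratio: float = 0.1
    probability: float = 0.2

    def __post_init__(self) -> None:
        t = np.asarray(self.max_translation_mm, dtype=float)
        if t.shape != (3,) or np.any(t < 0):
            raise ValueError("max_translation_mm must be 3 non-negative floats")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if self.max_squeeze_ratio < 0:
            raise ValueError("max_squeeze_ratio must be >= 0")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


@dataclass(frozen=True)
class MisalignmentParams:
    """One sampled realization of the three misalignment components."""

    translation_mm: Tuple[float, float, float]
    rotation_deg: float
    squeeze_factor: float

    @classmethod
    def identity(cls) -> "MisalignmentParams":
        return cls((0.0, 0.0, 0.0), 0.0, 1.0)

    def is_identity(self, tol: float = 0.0) -> bool:
        t = np.abs(np.asarray(self.translation_mm))
        return bool(np.all(t <= tol)
                    and abs(self.rotation_deg) <= tol
                    and abs(self.squeeze_factor - 1.0) <= tol)


@dataclass(frozen=True)
class SpatialTransform:
    """A 4x4 homogeneous affine acting on physical (mm) coordinates.

    ``center_mm`` records the fixed point about which rotation and
    squeeze were built; it is carried along for decomposition.
    """

    matrix: np.ndarray
    center_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(m[3], (0.0, 0.0, 0.0, 1.0)):
            raise ValueError("last row of a homogeneous affine must be (0,0,0,1)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, center_mm=(0.0, 0.0, 0.0)) -> "SpatialTransform":
        return cls(np.eye(4), tuple(center_mm))

    def inverse(self) -> "SpatialTransform":
        try:
            inv = np.linalg.inv(self.matrix)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
            raise ValueError("transform matrix is singular") from exc
        return SpatialTransform(inv, self.center_mm)

    def compose(self, other: "SpatialTransform") -> "SpatialTransform":
        """Return self ∘ other (other applied first)."""
        return SpatialTransform(self.matrix @ other.matrix, self.center_mm)

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map an array of physical points with shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def is_exact_identity(self) -> bool:
        return np.array_equal(self.matrix, np.eye(4))


# ---------------------------------------------------------------------------
# sampling and affine construction
# ---------------------------------------------------------------------------

def sample_misalignment(config: MisalignmentConfig,
                        rng: np.random.Generator) -> MisalignmentParams:
    """Draw one misalignment realization.

    Each component is drawn independently and uniformly from its
    symmetric interval; the squeeze factor is uniform on
    ``[1 - r, 1 + r]``.  The draw order (tx, ty, tz, rotation, squeeze)
    is fixed so a seeded generator reproduces the same stream.
    """
    mt = config.max_translation_mm
    tx = rng.uniform(-mt[0], mt[0])
    ty = rng.uniform(-mt[1], mt[1])
    tz = rng.uniform(-mt[2], mt[2])
    rot = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    squeeze = rng.uniform(1.0 - config.max_squeeze_ratio,
                          1.0 + config.max_squeeze_ratio)
    return MisalignmentParams((tx, ty, tz), rot, squeeze)


def build_transform(params: MisalignmentParams,
                    center_mm: Sequence[float]) -> SpatialTransform:
    """Compose Translate(t) ∘ RotateZ(θ about center) ∘ ScaleY(s about center).

    The rotation is restricted to the x–y plane and the squeeze to the
    dorsal–ventral (y) axis.  The composition order is a package
    convention; at the amplitudes used here the components nearly
    commute (sub-voxel commutator error).
    """
    t = np.asarray(params.translation_mm, dtype=float)
    if not np.all(np.isfinite(t)) or not np.isfinite(params.rotation_deg) \
            or not np.isfinite(params.squeeze_factor):
        raise ValueError("misalignment parameters must be finite")
    c = np.asarray(center_mm, dtype=float)

    theta = np.deg2rad(params.rotation_deg)
    if theta == 0.0:
        rot = np.eye(4)
    else:
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        rot = np.eye(4)
        rot[0, 0], rot[0, 1] = cos_t, -sin_t
        rot[1, 0], rot[1, 1] = sin_t, cos_t

    scale = np.eye(4)
    scale[1, 1] = params.squeeze_factor

    to_origin = np.eye(4)
    to_origin[:3, 3] = -c
    back = np.eye(4)
    back[:3, 3] = c

    translate = np.eye(4)
    translate[:3, 3] = t

    matrix = translate @ back @ rot @ scale @ to_origin
    return SpatialTransform(matrix, tuple(c))


def decompose_transform(transform: SpatialTransform) -> MisalignmentParams:
    """Recover (translation, in-plane rotation, y-squeeze) from a transform
    built by :func:`build_transform` about its recorded center."""
    a = transform.matrix[:3, :3]
    theta = np.arctan2(a[1, 0], a[0, 0])
    squeeze = float(np.hypot(a[0, 1], a[1, 1]))
    c = np.asarray(transform.center_mm, dtype=float)
    translation = transform.apply_points(c) - c
    return MisalignmentParams(tuple(translation), float(np.rad2deg(theta)), squeeze)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

_ORDER = {"linear": 1, "nearest": 0}


def resample_with_transform(volume: np.ndarray,
                            spacing: Sequence[float],
                            transform: SpatialTransform,
                            interpolation: str = "linear",
                            fill_value: Optional[float] = None) -> np.ndarray:
    """Pull-resample ``volume`` under ``transform`` on its own grid.

    The output voxel at physical position ``p`` takes the value of the
    input at ``transform⁻¹(p)`` (backward warping), so ``transform``
    expresses the forward motion of the image content.  Out-of-domain
    voxels receive ``fill_value`` (per-volume minimum by default).
    ``interpolation`` must be ``nearest`` for label volumes.
    """
    if interpolation not in _ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_ORDER)}")
    vol = np.asarray(volume)
    if transform.is_exact_identity():
        return vol.copy()
    try:
        inv = np.linalg.inv(transform.matrix)
    except np.linalg.LinAlgError as exc:
        raise ValueError("cannot resample with a singular transform") from exc

    spacing = np.asarray(spacing, dtype=float)
    # index -> mm -> inverse map -> index, fused into one affine on indices
    scale = np.diag(spacing)
    index_affine = np.linalg.solve(scale, inv[:3, :3] @ scale)
    index_offset = inv[:3, 3] / spacing

    if fill_value is None:
        fill_value = float(vol.min()) if vol.size else 0.0
    out = ndimage.affine_transform(
        vol.astype(float, copy=False),
        index_affine,
        offset=index_offset,
        order=_ORDER[interpolation],
        mode="constant",
        cval=fill_value,
        prefilter=False,
    )
    if interpolation == "nearest":
        out = out.astype(vol.dtype)
    return out


# ---------------------------------------------------------------------------
# the augmentation itself
# ---------------------------------------------------------------------------

def apply_misalignment_augmentation(exam: MultiModalExam,
                                    config: MisalignmentConfig,
                                    rng: np.random.Generator,
                                    force_params: Optional[MisalignmentParams] = None,
                                    center_mm: Optional[Sequence[float]] = None,
                                    ) -> MultiModalExam:
    """Randomly displace the T2w channel (and its lesion annotations)
    relative to the DWI-domain channels.

    One Bernoulli(``config.probability``) draw gates whether the three
    components apply jointly; when the gate fires, parameters are
    sampled, an affine about the grid center is built, and ``t2w``
    (linear) plus ``lesion_mask_t2w`` (nearest) are resampled with it.
    All DWI-domain channels and masks are returned untouched.  The
    applied parameters are recorded on ``exam.augmentation_params``
    (``None`` when the exam passed through unchanged).

    ``force_params`` bypasses both the gate and the sampling — useful
    for tests that need a known displacement.  The draw order per exam
    is fixed: gate, tx, ty, tz, rotation, squeeze.
    """
    if force_params is None:
        gate = rng.random() < config.probability
        if not gate:
            return exam.copy(augmentation_params=None)
        params = sample_misalignment(config, rng)
    else:
        params = force_params

    center = exam.grid_center_mm if center_mm is None else np.asarray(center_mm)
    transform = build_transform(params, center)
    t2w_moved = resample_with_transform(exam.t2w, exam.spacing, transform,
                                        interpolation="linear")
    mask_moved = resample_with_transform(exam.lesion_mask_t2w, exam.spacing,
                                         transform, interpolation="nearest",
                                         fill_value=0)
    return exam.copy(t2w=t2w_moved, lesion_mask_t2w=mask_moved,
                     augmentation_params=params)


class MisalignmentAugmentation:
    """The augmentation as a pluggable batch transform.

    Instances are callables ``exam -> exam`` carrying their own seeded
    random stream, so they can be dropped into any augmentation
    pipeline; :class:`AugmentationPipeline` additionally enforces that
    they run before global spatial augmentation.
    """

    is_global_spatial = False
    stage_name = "misalignment_augmentation"

    def __init__(self, config: MisalignmentConfig,
                 rng: Optional[np.random.Generator] = None,
                 seed: Optional[int] = None) -> None:
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.last_params: Optional[MisalignmentParams] = None

    def __call__(self, exam: MultiModalExam) -> MultiModalExam:
        out = apply_misalignment_augmentation(exam, self.config, self.rng)
        self.last_params = out.augmentation_params
        return out


class GlobalSpatialAugmentation:
    """Marker base class for global spatial stages (applied identically to
    every channel).  Anything with ``is_global_spatial = True`` counts."""

    is_global_spatial = True
    stage_name = "global_spatial_augmentation"

    def __call__(self, exam: MultiModalExam) -> MultiModalExam:  # pragma: no cover
        raise NotImplementedError


class RandomGlobalAffine(GlobalSpatialAugmentation):
    """A minimal global affine: one sampled rigid motion applied to every
    channel and every mask jointly (inter-modal alignment preserved)."""

    stage_name = "random_global_affine"

    def __init__(self, max_translation_mm=(5.0, 5.0, 3.0),
                 max_rotation_deg: float = 10.0,
                 rng: Optional[np.random.Generator] = None,
                 seed: Optional[int] = None) -> None:
        self.config = MisalignmentConfig(max_translation_mm=max_translation_mm,
                                         max_rotation_deg=max_rotation_deg,
                                         max_squeeze_ratio=0.0, probability=1.0)
        self.rng = rng if rng is not None else np.random.default_rng(seed)

    def __call__(self, exam: MultiModalExam) -> MultiModalExam:
        params = sample_misalignment(self.config, self.rng)
        transform = build_transform(params, exam.grid_center_mm)
        updates = {}
        for name, vol in exam.image_channels():
            updates[name] = resample_with_transform(vol, exam.spacing, transform,
                                                    interpolation="linear")
        for name in ("lesion_mask_t2w", "lesion_mask_dwi", "prostate_mask",
                     "prostate_mask_dwi"):
            vol = getattr(exam, name)
            if vol is not None:
                updates[name] = resample_with_transform(
                    vol, exam.spacing, transform, interpolation="nearest",
                    fill_value=0)
        return exam.copy(**updates)


class AugmentationPipeline:
    """Ordered composition of exam transforms with an ordering contract:
    every misalignment stage must precede every global spatial stage,
    because a global transform applied first would move all channels
    jointly and the subsequent misalignment would no longer emulate an
    acquisition-time inter-modality offset."""

    def __init__(self, stages: Sequence[Callable]) -> None:
        stages = list(stages)
        first_global = None
        for stage in stages:
            name = getattr(stage, "stage_name", type(stage).__name__)
            if getattr(stage, "is_global_spatial", False):
                if first_global is None:
                    first_global = name
            elif isinstance(stage, MisalignmentAugmentation) and first_global is not None:
                raise PipelineOrderError(
                    f"misalignment stage '{name}' is ordered after global "
                    f"spatial stage '{first_global}'; misalignment "
                    "augmentation must precede any global augmentation")
        self.stages = stages

    def __call__(self, exam: MultiModalExam) -> MultiModalExam:
        for stage in self.stages:
            exam = stage(exam)
        return exam
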