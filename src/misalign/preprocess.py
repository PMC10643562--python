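"""Deterministic preprocessing: resampling, normalization, cropping, sampling.

The conventions mirror common prostate bpMRI pipelines: all channels
are linearly resampled to 0.3125 mm in-plane with the 3 mm slice
distance unchanged; T2w and high-b DWI are z-scored per exam while the
ADC map — a quasi-quantitative physical quantity — is z-scored with
statistics pooled over the training set; volumes are cropped to the
prostate bounding box with a margin; and training draws are balanced
over the csPCa classes to counter the cohort's class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .exam import MultiModalExam

__all__ = ["PreprocessConfig", "resample_to_target", "normalize",
           "compute_adc_dataset_stats", "crop_to_prostate", "balanced_indices"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Resampling target, crop margin and pooled ADC statistics.

    ``patch_size`` records the CNN input patch convention for this
    application; it is carried for provenance and not used by the
    preprocessing operators themselves.
    """

    target_spacing: Tuple[float, float, float] = (0.3125, 0.3125, 3.0)
    crop_margin_mm: Tuple[float, float, float] = (10.0, 10.0, 10.0)
    adc_dataset_stats: Optional[Tuple[float, float]] = None
    patch_size: Tuple[int, int, int] = (320, 256, 20)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.target_spacing, dtype=float) <= 0):
            raise ValueError("target_spacing must be positive")
        if np.any(np.asarray(self.crop_margin_mm, dtype=float) < 0):
            raise ValueError("crop_margin_mm must be non-negative")


def _resample_volume(vol: np.ndarray, spacing: np.ndarray,
                     target: np.ndarray, order: int) -> np.ndarray:
    new_shape = np.maximum(1, np.round(np.asarray(vol.shape) * spacing
                                       / target).astype(int))
    if np.array_equal(new_shape, vol.shape) and np.allclose(spacing, target):
        return vol.copy()
    # sample the new voxel centers (index * target, in mm) in old index units
    coords = np.meshgrid(*[np.arange(n) * t / s for n, t, s
                           in zip(new_shape, target, spacing)], indexing="ij")
    out = ndimage.map_coordinates(vol.astype(float, copy=False),
                                  coords, order=order, mode="nearest",
                                  prefilter=False)
    if order == 0:
        out = out.astype(vol.dtype)
    return out


def resample_to_target(exam: MultiModalExam,
                       config: PreprocessConfig) -> MultiModalExam:
    """Linearly resample every channel (masks: nearest) to the target
    spacing, preserving the physical extent within one voxel."""
    spacing = np.asarray(exam.spacing, dtype=float)
    target = np.asarray(config.target_spacing, dtype=float)
    updates = {}
    for name, vol in exam.image_channels():
        updates[name] = _resample_volume(vol, spacing, target, order=1)
    for name in ("lesion_mask_t2w", "lesion_mask_dwi", "prostate_mask",
                 "prostate_mask_dwi"):
        vol = getattr(exam, name)
        if vol is not None:
            updates[name] = _resample_volume(vol, spacing, target, order=0)
    return exam.copy(spacing=tuple(target), **updates)


def compute_adc_dataset_stats(exams: Sequence[MultiModalExam],
                              prostate_masked: bool = True
                              ) -> Tuple[float, float]:
    """Pooled mean/sd of ADC intensities over a training set.

    By default only prostate-masked voxels enter the pool (the gland is
    the region the statistics must stabilize); pass
    ``prostate_masked=False`` for whole-volume statistics.
    """
    chunks = []
    for exam in exams:
        adc = np.asarray(exam.adc, dtype=float)
        if prostate_masked:
            chunks.append(adc[np.asarray(exam.prostate_mask) > 0])
        else:
            chunks.append(adc.ravel())
    pooled = np.concatenate(chunks)
    if pooled.size == 0:
        raise ValueError("no voxels available for ADC statistics")
    return float(pooled.mean()), float(pooled.std())


def normalize(exam: MultiModalExam, config: PreprocessConfig) -> MultiModalExam:
    """Z-score t2w/dwi_high_b/dwi_low_b per exam; z-score adc with the
    dataset-level statistics from ``config.adc_dataset_stats``."""
    updates = {}
    for name in ("t2w", "dwi_high_b", "dwi_low_b"):
        vol = getattr(exam, name)
        if vol is None:
            continue
        vol = np.asarray(vol, dtype=float)
        sd = vol.std()
        if sd == 0:
            raise ValueError(f"cannot normalize '{name}': per-exam sd is zero")
        updates[name] = (vol - vol.mean()) / sd
    if exam.adc is not None:
        if config.adc_dataset_stats is None:
            raise ValueError("adc_dataset_stats must be set to normalize ADC")
        mean, sd = config.adc_dataset_stats
        if sd <= 0:
            raise ValueError("cannot normalize 'adc': dataset sd is zero")
        updates["adc"] = (np.asarray(exam.adc, dtype=float) - mean) / sd
    return exam.copy(**updates)


def crop_to_prostate(exam: MultiModalExam,
                     config: PreprocessConfig) -> MultiModalExam:
    """Crop every volume to the prostate-mask bounding box dilated by
    ``crop_margin_mm`` (clipped to the grid)."""
    mask = np.asarray(exam.prostate_mask) > 0
    if not mask.any():
        raise ValueError("prostate mask is empty; cannot crop")
    spacing = np.asarray(exam.spacing, dtype=float)
    margin_vox = np.ceil(np.asarray(config.crop_margin_mm, dtype=float)
                         / spacing).astype(int)
    idx = np.nonzero(mask)
    lo = np.maximum(0, np.array([ax.min() for ax in idx]) - margin_vox)
    hi = np.minimum(mask.shape, np.array([ax.max() for ax in idx]) + margin_vox + 1)
    sl = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))

    updates = {}
    for name in ("t2w", "dwi_high_b", "adc", "dwi_low_b", "lesion_mask_t2w",
                 "lesion_mask_dwi", "prostate_mask", "prostate_mask_dwi"):
        vol = getattr(exam, name)
        if vol is not None:
            updates[name] = np.asarray(vol)[sl].copy()
    return exam.copy(**updates)


def balanced_indices(labels: Sequence[int],
                     rng: np.random.Generator) -> Iterator[int]:
    """Infinite balanced index stream: each draw picks a class uniformly,
    then an exam uniformly within that class."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("balanced sampling requires both classes present")
    while True:
        pool = pos if rng.integers(2) == 1 else neg
        yield int(pool[rng.integers(pool.size)])
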