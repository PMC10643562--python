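"""The multi-modal exam container consumed by every pipeline stage.

One exam bundles the co-acquired bpMRI volumes of a single patient —
T2-weighted, highest-b-value DWI, the ADC map and (optionally) the
lowest-b-value DWI — together with lesion label masks annotated in the
T2w and in the DWI geometric domains, the prostate gland mask and the
patient-level labels (csPCa status, PI-RADS score).

All volumes live on one shared voxel grid indexed ``[x, y, z]`` with
``x`` = left–right, ``y`` = dorsal–ventral (anterior–posterior) and
``z`` = the slice axis; ``spacing`` gives millimetres per voxel along
each axis.  Physical coordinates are ``index * spacing`` so transforms
can act in millimetres on anisotropic grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = ["MultiModalExam"]


@dataclass
class MultiModalExam:
    """One patient's co-acquired multi-modal volumes, masks and labels."""

    t2w: np.ndarray
    dwi_high_b: np.ndarray
    adc: np.ndarray
    spacing: Tuple[float, float, float]
    lesion_mask_t2w: np.ndarray
    lesion_mask_dwi: np.ndarray
    prostate_mask: np.ndarray
    dwi_low_b: Optional[np.ndarray] = None
    prostate_mask_dwi: Optional[np.ndarray] = None
    cspca_label: Optional[int] = None
    pirads: Optional[int] = None
    exam_id: str = ""
    # Set by the misalignment augmentation: the parameters actually applied
    # to this exam (None when the Bernoulli gate left it untouched).
    augmentation_params: Optional[object] = None
    _skip_validation: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not self._skip_validation:
            self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        shape = np.asarray(self.t2w).shape
        if len(shape) != 3:
            raise ValueError("exam volumes must be 3-D")
        for name in ("dwi_high_b", "adc", "dwi_low_b", "lesion_mask_t2w",
                     "lesion_mask_dwi", "prostate_mask", "prostate_mask_dwi"):
            vol = getattr(self, name)
            if vol is None:
                continue
            if np.asarray(vol).shape != shape:
                raise ValueError(
                    f"{name} shape {np.asarray(vol).shape} does not match "
                    f"t2w shape {shape}; all volumes must share one grid")
        spacing = np.asarray(self.spacing, dtype=float)
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        for name in ("lesion_mask_t2w", "lesion_mask_dwi"):
            labels = np.asarray(getattr(self, name))
            if not np.issubdtype(labels.dtype, np.integer):
                raise ValueError(f"{name} must be an integer label volume")
            if labels.min() < 0:
                raise ValueError(f"{name} contains negative labels")
        if self.cspca_label is not None and self.cspca_label not in (0, 1):
            raise ValueError("cspca_label must be 0 or 1")
        if self.pirads is not None and self.pirads not in (1, 2, 3, 4, 5):
            raise ValueError("pirads must be in 1..5")

    # -- convenience ----------------------------------------------------
    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return tuple(self.t2w.shape)

    @property
    def grid_center_mm(self) -> np.ndarray:
        """Geometric center of the voxel grid in physical (mm) coordinates."""
        return (np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(self.spacing)

    def image_channels(self):
        """Name/array pairs of the intensity volumes that are present."""
        for name in ("t2w", "dwi_high_b", "adc", "dwi_low_b"):
            vol = getattr(self, name)
            if vol is not None:
                yield name, vol

    def copy(self, **updates) -> "MultiModalExam":
        """Shallow copy with field overrides (arrays are shared, not copied)."""
        return replace(self, _skip_validation=True, **updates)
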