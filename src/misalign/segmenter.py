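"""A deliberately simple threshold-based lesion scorer.

This is the stand-in for a trained segmentation CNN in end-to-end
experiments: it turns a multi-modal exam into a voxelwise lesion
probability map by multiplying per-modality evidence — bright on
high-b DWI, dark on ADC, dark on T2w — inside the prostate mask.
Because the evidence is multiplied *across* domains (the prostate mask
and T2w live in the T2w domain, DWI/ADC in the DWI domain), any
inter-modality misalignment decorrelates the factors at the lesion and
lowers the patient score, which is exactly the sensitivity to
alignment that a spatially aware segmentation model exhibits.

The evidence thresholds are fixed to the phantom's tissue contrasts
(lesions ~0.9 on high-b DWI vs <=0.35 gland, ~0.30 on ADC vs >=0.85
gland, ~0.45 on T2w vs 0.55/0.80 gland zones); this scorer is a test
harness for the alignment machinery, not a segmentation method.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .exam import MultiModalExam

__all__ = ["toy_lesion_probability", "toy_patient_score"]

# (threshold, sign) per modality: sign +1 scores values above the
# threshold, -1 below it
_EVIDENCE = {
    "dwi_high_b": (0.60, +1.0),
    "adc": (0.55, -1.0),
    "t2w": (0.50, -1.0),
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def toy_lesion_probability(exam: MultiModalExam,
                           steepness: float = 30.0,
                           smooth_sigma_mm: float = 3.0) -> np.ndarray:
    """Voxelwise lesion probability from multiplicative modality evidence.

    Each factor is ``sigmoid(steepness * sign * (intensity - threshold))``;
    the product is smoothed with a Gaussian of ``smooth_sigma_mm`` and
    masked to the prostate.  The smoothing makes the peak value grow
    with lesion extent, so clinically significant (larger) lesions peak
    higher than punctate ones — a crude surrogate for the size
    sensitivity of a learned segmenter.  ``steepness`` is in units of
    1/intensity and controls how hard the thresholds are.
    """
    gland = np.asarray(exam.prostate_mask) > 0
    if not gland.any():
        raise ValueError("prostate mask is empty")
    prob = np.ones(gland.shape, dtype=float)
    for name, (threshold, sign) in _EVIDENCE.items():
        vol = np.asarray(getattr(exam, name), dtype=float)
        prob *= _sigmoid(steepness * sign * (vol - threshold))
    if smooth_sigma_mm > 0:
        sigma_vox = smooth_sigma_mm / np.asarray(exam.spacing, dtype=float)
        prob = ndimage.gaussian_filter(prob, sigma_vox)
    return np.where(gland, np.clip(prob, 0.0, 1.0), 0.0)


def toy_patient_score(exam: MultiModalExam, steepness: float = 30.0,
                      smooth_sigma_mm: float = 3.0) -> float:
    """Patient-level score: maximum of the toy probability map."""
    return float(toy_lesion_probability(exam, steepness, smooth_sigma_mm).max())
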