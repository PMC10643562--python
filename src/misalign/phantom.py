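"""Synthetic multi-modal prostate phantoms with known misalignments.

The phantom emulates the geometric and contrast structure of a
bi-parametric prostate MRI exam: an elliptical body of soft tissue, a
prostate gland with a transition-zone core and a peripheral-zone shell,
and ellipsoidal lesions placed inside the gland.  Contrast polarity per
modality follows clinical convention — lesions are hyperintense versus
gland on high-b DWI, hypointense on the ADC map, and hypointense on T2w
(strongly so in the peripheral zone).  The lowest-b DWI is synthesized
as a smoothed, contrast-reduced version of the T2w scene rendered in
the DWI domain, reproducing the property that low-b diffusion images
resemble the anatomical T2w reference most closely.

Everything is rendered analytically from one scene description, so a
ground-truth inter-modality misalignment can be injected exactly: the
DWI-domain channels are the same scene evaluated through the inverse of
the truth transform, which makes the T2w-domain and DWI-domain lesion
masks related exactly by that transform up to voxelization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import LesionPlacementError
from .exam import MultiModalExam
from .spatial import (MisalignmentConfig, MisalignmentParams, SpatialTransform,
                      build_transform, sample_misalignment)

__all__ = ["PhantomConfig", "PhantomExam", "Lesion", "generate_phantom",
           "sample_phantom_cohort", "write_phantom_dataset"]

# Noiseless tissue intensities per modality.  Arbitrary units on [0, 1];
# only the polarity and the ordering of contrasts matter downstream.
_INTENSITY = {
    #            body   TZ     PZ     lesion-in-TZ  lesion-in-PZ
    "t2w":      (0.40,  0.55,  0.80,  0.42,         0.45),
    "dwi_high_b": (0.18, 0.35, 0.30,  0.90,         0.90),
    "adc":      (0.55,  0.85,  0.90,  0.30,         0.30),
}
_AIR = {"t2w": 0.05, "dwi_high_b": 0.05, "adc": 0.05}

#: lesions at least this radius (mm) count as clinically significant
SIGNIFICANT_RADIUS_MM = 5.0


@dataclass(frozen=True)
class Lesion:
    """Catalog entry for one phantom lesion."""

    center_mm: Tuple[float, float, float]
    radius_mm: float
    zone: str  # "PZ" or "TZ"

    @property
    def significant(self) -> bool:
        return self.radius_mm >= SIGNIFICANT_RADIUS_MM

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_mm ** 3


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast-noise and misalignment settings of one phantom.

    ``spacing`` defaults to the common prostate bpMRI grid of
    0.3125 mm in-plane with 3 mm slices; ``grid_shape`` covers a
    50 x 50 x 60 mm field of view around the gland.
    """

    grid_shape: Tuple[int, int, int] = (160, 160, 20)
    spacing: Tuple[float, float, float] = (0.3125, 0.3125, 3.0)
    n_lesions: int = 1
    lesion_radius_range: Tuple[float, float] = (4.0, 8.0)
    noise_sigma: float = 0.05
    true_misalignment: Optional[MisalignmentParams] = None
    seed: int = 0

    def __post_init__(self) -> None:
        shape = np.asarray(self.grid_shape)
        spacing = np.asarray(self.spacing, dtype=float)
        if shape.shape != (3,) or np.any(shape <= 0):
            raise ValueError("grid_shape must be 3 positive integers")
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise ValueError("spacing must be 3 positive floats")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ValueError("lesion_radius_range must satisfy 0 < lo <= hi")
        if lo <= max(spacing):
            raise ValueError(
                "lesion_radius_range lower bound must exceed the largest "
                f"voxel spacing ({max(spacing)} mm) so lesions span >= 2 voxels")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing, dtype=float)

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(self.spacing,
                                                                    dtype=float)


@dataclass
class PhantomExam(MultiModalExam):
    """A generated exam plus its ground truth: the injected DWI-domain
    misalignment and the lesion catalog."""

    truth_transform: Optional[SpatialTransform] = None
    truth_params: Optional[MisalignmentParams] = None
    lesion_catalog: List[Lesion] = field(default_factory=list)


# ---------------------------------------------------------------------------
# scene model
# ---------------------------------------------------------------------------

class _Scene:
    """Analytic scene: ellipsoids for body, gland zones and lesions,
    evaluated at arbitrary physical points."""

    def __init__(self, config: PhantomConfig, lesions: List[Lesion]) -> None:
        fov = config.fov_mm
        self.center = config.center_mm
        self.body_axes = np.array([0.47 * fov[0], 0.47 * fov[1], 10.0 * fov[2]])
        # gland half-axes scale with the field of view but stay prostate-like
        self.gland_axes = np.minimum(
            np.array([16.0, 13.0, 18.0]),
            0.40 * fov)
        self.tz_axes = 0.55 * self.gland_axes
        self.lesions = lesions

    @staticmethod
    def _inside(points: np.ndarray, center: np.ndarray,
                axes: np.ndarray) -> np.ndarray:
        d = (points - center) / axes
        return np.einsum("...i,...i->...", d, d) <= 1.0

    def masks(self, points: np.ndarray):
        body = self._inside(points, self.center, self.body_axes)
        gland = self._inside(points, self.center, self.gland_axes)
        tz = self._inside(points, self.center, self.tz_axes)
        lesion_labels = np.zeros(points.shape[:-1], dtype=np.int16)
        for k, lesion in enumerate(self.lesions, start=1):
            ball = self._inside(points, np.asarray(lesion.center_mm),
                                np.full(3, lesion.radius_mm))
            lesion_labels[ball] = k
        return body, gland, tz, lesion_labels

    def render(self, points: np.ndarray):
        """Noiseless intensity volumes plus masks at the given points."""
        body, gland, tz, lesion_labels = self.masks(points)
        pz = gland & ~tz
        volumes = {}
        for modality, (i_body, i_tz, i_pz, i_les_tz, i_les_pz) in _INTENSITY.items():
            vol = np.full(points.shape[:-1], _AIR[modality])
            vol[body] = i_body
            vol[tz] = i_tz
            vol[pz] = i_pz
            for k, lesion in enumerate(self.lesions, start=1):
                sel = lesion_labels == k
                vol[sel] = i_les_tz if lesion.zone == "TZ" else i_les_pz
            volumes[modality] = vol
        return volumes, gland, lesion_labels


def _place_lesions(config: PhantomConfig, scene_axes: np.ndarray,
                   tz_axes: np.ndarray, center: np.ndarray,
                   rng: np.random.Generator) -> List[Lesion]:
    lesions: List[Lesion] = []
    lo, hi = config.lesion_radius_range
    for idx in range(config.n_lesions):
        for _ in range(500):
            radius = rng.uniform(lo, hi)
            shrunk = scene_axes - radius
            if np.any(shrunk <= 0):
                continue
            u = rng.uniform(-1.0, 1.0, size=3)
            if u @ u > 1.0:
                continue
            cand = center + u * shrunk
            if any(np.linalg.norm(cand - np.asarray(l.center_mm))
                   < radius + l.radius_mm + 1.0 for l in lesions):
                continue
            d = (cand - center) / tz_axes
            zone = "TZ" if d @ d <= 1.0 else "PZ"
            lesions.append(Lesion(tuple(cand), float(radius), zone))
            break
        else:
            raise LesionPlacementError(
                f"could not place lesion {idx} inside the gland after 500 "
                "attempts (gland too small for the requested radius range)")
    return lesions


def _grid_points(config: PhantomConfig) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(config.grid_shape, config.spacing)]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack(grid, axis=-1)


def generate_phantom(config: PhantomConfig) -> PhantomExam:
    """Generate one phantom exam; same config (incl. seed) is bit-reproducible.

    The T2w-domain channels are the scene on the voxel grid; the
    DWI-domain channels are the scene carried through the injected
    misalignment (identity when ``true_misalignment`` is None), so the
    two lesion masks are exact analytic renderings in either domain.
    """
    rng = np.random.default_rng(config.seed)
    scene_probe = _Scene(config, [])
    lesions = _place_lesions(config, scene_probe.gland_axes,
                             scene_probe.tz_axes, config.center_mm, rng)
    scene = _Scene(config, lesions)

    points = _grid_points(config)
    truth_params = config.true_misalignment
    if truth_params is not None and not truth_params.is_identity():
        truth = build_transform(truth_params, config.center_mm)
        dwi_points = truth.inverse().apply_points(points)
    else:
        truth = SpatialTransform.identity(config.center_mm) \
            if truth_params is not None else None
        dwi_points = points

    t2w_vols, gland_t2w, lesions_t2w = scene.render(points)
    if truth is not None and not truth.is_exact_identity():
        dwi_vols, gland_dwi, lesions_dwi = scene.render(dwi_points)
    else:
        dwi_vols = {k: v.copy() for k, v in t2w_vols.items()}
        gland_dwi, lesions_dwi = gland_t2w.copy(), lesions_t2w.copy()

    t2w = t2w_vols["t2w"]
    dwi_high_b = dwi_vols["dwi_high_b"]
    adc = dwi_vols["adc"]
    # low-b DWI: smoothed, contrast-reduced T2w structure in the DWI domain
    sigma_vox = 1.5 / np.asarray(config.spacing, dtype=float)
    dwi_low_b = 0.15 + 0.55 * ndimage.gaussian_filter(dwi_vols["t2w"], sigma_vox)

    if config.noise_sigma > 0:
        # noise scaled to the tissue contrast (gland-vs-body span) per modality
        def _noisy(vol, modality):
            span = abs(_INTENSITY[modality][2] - _INTENSITY[modality][0])
            return vol + rng.normal(0.0, config.noise_sigma * span, vol.shape)
        t2w = _noisy(t2w, "t2w")
        dwi_high_b = _noisy(dwi_high_b, "dwi_high_b")
        adc = _noisy(adc, "adc")
        dwi_low_b = dwi_low_b + rng.normal(
            0.0, config.noise_sigma * 0.2, dwi_low_b.shape)

    t2w = t2w.astype(np.float32)
    dwi_high_b = dwi_high_b.astype(np.float32)
    adc = adc.astype(np.float32)
    dwi_low_b = dwi_low_b.astype(np.float32)

    significant = any(l.significant for l in lesions)
    pirads = _synthetic_pirads(lesions, rng)
    return PhantomExam(
        t2w=t2w, dwi_high_b=dwi_high_b, adc=adc, dwi_low_b=dwi_low_b,
        spacing=tuple(float(s) for s in config.spacing),
        lesion_mask_t2w=lesions_t2w, lesion_mask_dwi=lesions_dwi,
        prostate_mask=gland_t2w.astype(np.uint8),
        prostate_mask_dwi=gland_dwi.astype(np.uint8),
        cspca_label=int(significant), pirads=pirads,
        truth_transform=truth, truth_params=truth_params,
        lesion_catalog=lesions,
    )


def _synthetic_pirads(lesions: List[Lesion], rng: np.random.Generator) -> int:
    """Monotone map from lesion conspicuity (volume x DWI contrast) to a
    1..5 score, with reader noise; lesion-free exams read as 1 or 2."""
    if not lesions:
        return int(rng.integers(1, 3))
    contrast = _INTENSITY["dwi_high_b"][4] - _INTENSITY["dwi_high_b"][1]
    conspicuity = max(math.log10(l.volume_mm3 * contrast) for l in lesions)
    noisy = conspicuity + rng.normal(0.0, 0.12)
    edges = (1.80, 2.05, 2.30, 2.55)  # log10(mm^3 x contrast) bin edges
    return int(1 + np.searchsorted(edges, noisy))


# ---------------------------------------------------------------------------
# cohorts and the dataset writer
# ---------------------------------------------------------------------------

#: csPCa prevalence emulated by phantom cohorts (typical of mixed
#: PROSTATEx / clinical-routine cohorts, roughly one positive in three)
COHORT_PREVALENCE = 0.344


def sample_phantom_cohort(config: PhantomConfig, n_exams: int,
                          misalignment: Optional[MisalignmentConfig] = None,
                          prevalence: float = COHORT_PREVALENCE
                          ) -> List[PhantomExam]:
    """Generate a phantom cohort with a controlled csPCa prevalence.

    ``round(prevalence * n_exams)`` exams (positions shuffled by the
    seeded master stream) receive at least one clinically significant
    lesion (radius >= 5 mm); the rest carry either no lesion or one
    insignificant lesion.  Per-exam seeds derive deterministically from
    ``config.seed``.  When ``misalignment`` is given, each exam gets
    its own sampled ground-truth misalignment; otherwise
    ``config.true_misalignment`` applies to every exam.
    """
    if n_exams < 1:
        raise ValueError("n_exams must be >= 1")
    master = np.random.default_rng(config.seed)
    n_pos = int(round(prevalence * n_exams))
    positive = np.zeros(n_exams, dtype=bool)
    positive[master.permutation(n_exams)[:n_pos]] = True

    # The per-exam anatomy plan is drawn before any misalignment is
    # sampled, so cohorts generated with and without `misalignment`
    # from the same config are exam-by-exam twins (identical scenes,
    # identical noise) that differ only in the injected displacement.
    lo, hi = config.lesion_radius_range
    plans = []
    for i in range(n_exams):
        exam_seed = int(master.integers(0, 2 ** 31 - 1))
        if positive[i]:
            n_lesions = max(1, int(master.integers(1, config.n_lesions + 1)))
            radius_range = (max(lo, SIGNIFICANT_RADIUS_MM + 0.2),
                            max(hi, SIGNIFICANT_RADIUS_MM + 0.7))
        else:
            small_hi = SIGNIFICANT_RADIUS_MM - 0.3
            if lo < small_hi and master.random() < 0.5:
                n_lesions, radius_range = 1, (lo, small_hi)
            else:
                n_lesions, radius_range = 0, (lo, hi)
        plans.append((exam_seed, n_lesions, radius_range))

    if misalignment is not None:
        truths = [sample_misalignment(misalignment, master)
                  for _ in range(n_exams)]
    else:
        truths = [config.true_misalignment] * n_exams

    exams: List[PhantomExam] = []
    for i, ((exam_seed, n_lesions, radius_range), truth) in enumerate(
            zip(plans, truths)):
        exam_cfg = PhantomConfig(
            grid_shape=config.grid_shape, spacing=config.spacing,
            n_lesions=n_lesions, lesion_radius_range=radius_range,
            noise_sigma=config.noise_sigma, true_misalignment=truth,
            seed=exam_seed)
        exam = generate_phantom(exam_cfg)
        exam.exam_id = f"phantom_{i:04d}"
        exams.append(exam)
    return exams


def write_phantom_dataset(config: PhantomConfig, n_exams: int, out_dir,
                          misalignment: Optional[MisalignmentConfig] = None,
                          cohort: str = "phantom"):
    """Write ``n_exams`` phantoms as NIfTI volumes plus a manifest.

    The cohort comes from :func:`sample_phantom_cohort`, so runs with
    the same config are bit-reproducible and the manifest (saved as
    ``manifest.csv``, returned as a :class:`pandas.DataFrame`) carries
    csPCa labels at the emulated prevalence together with synthetic
    PI-RADS scores.
    """
    from . import io as mio  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for exam in sample_phantom_cohort(config, n_exams,
                                      misalignment=misalignment):
        exam_id = exam.exam_id
        exam_dir = out_dir / exam_id
        exam_dir.mkdir(exist_ok=True)

        paths = {}
        for name, vol, dtype in (
                ("t2w", exam.t2w, np.float32),
                ("dwi_high_b", exam.dwi_high_b, np.float32),
                ("adc", exam.adc, np.float32),
                ("dwi_low_b", exam.dwi_low_b, np.float32),
                ("lesion_mask_t2w", exam.lesion_mask_t2w, np.int16),
                ("lesion_mask_dwi", exam.lesion_mask_dwi, np.int16),
                ("prostate_mask", exam.prostate_mask, np.uint8)):
            path = exam_dir / f"{name}.nii.gz"
            mio.write_volume(path, np.asarray(vol, dtype=dtype), exam.spacing)
            paths[name] = str(path.relative_to(out_dir))
        rows.append({"exam_id": exam_id, "cohort": cohort, **paths,
                     "cspca_label": exam.cspca_label, "pirads": exam.pirads,
                     "split": "test"})

    import pandas as pd
    manifest = pd.DataFrame(rows)
    mio.save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
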