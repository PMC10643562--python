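"""NIfTI I/O, manifests and cohort arithmetic.

Volumes are canonicalized to RAS orientation on load so that the
package-wide axis convention (x = left–right, y = dorsal–ventral,
z = slices) — and with it the dorsal–ventral squeeze axis — is
unambiguous.  Manifests are CSV-first (diff-friendly) with a JSON
mirror; cohort summaries reproduce prevalence percentages with
half-up rounding to two decimals, matching the printing convention of
clinical cohort tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, NamedTuple, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ManifestError, VolumeIOError

__all__ = ["Volume", "read_volume", "write_volume", "load_manifest",
           "save_manifest", "CohortSummary", "cohort_summary",
           "stratified_split", "REQUIRED_MANIFEST_COLUMNS"]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

class Volume(NamedTuple):
    """A loaded volume: data indexed [x, y, z] in RAS, spacing in mm,
    and the RAS affine of the canonicalized image."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    affine: np.ndarray


def read_volume(path) -> Volume:
    """Load a NIfTI volume, canonicalized to RAS orientation."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"volume file not found: {path}")
    if not (path.name.endswith(".nii") or path.name.endswith(".nii.gz")):
        raise VolumeIOError(f"not a NIfTI file (.nii/.nii.gz): {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.affine is None:
        raise VolumeIOError(f"{path} carries no orientation information")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, affine=img.affine.copy())


def write_volume(path, data: np.ndarray, spacing,
                 affine: Optional[np.ndarray] = None) -> None:
    """Write a NIfTI volume.  Without an explicit affine, a diagonal RAS
    affine from ``spacing`` is used.  Round-trips data, spacing and
    orientation bit-exactly for supported dtypes."""
    path = Path(path)
    data = np.asarray(data)
    if affine is None:
        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms([float(s) for s in spacing])
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot write NIfTI file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

REQUIRED_MANIFEST_COLUMNS = ("exam_id", "cohort", "cspca_label", "pirads",
                             "split")
_PATH_COLUMNS = ("t2w", "dwi_high_b", "adc", "dwi_low_b", "lesion_mask_t2w",
                 "lesion_mask_dwi", "prostate_mask")


def load_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Load a CSV or JSON manifest and validate it.

    ``check_files=False`` (lazy mode) skips existence checks on the
    referenced volume files.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    if path.suffix == ".json":
        manifest = pd.DataFrame(json.loads(path.read_text()))
    else:
        manifest = pd.read_csv(path)

    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest {path} lacks required columns {missing}")
    dupes = manifest["exam_id"][manifest["exam_id"].duplicated()]
    if not dupes.empty:
        raise ManifestError(
            f"duplicate exam_id(s) in manifest: {sorted(set(dupes))}")
    if not manifest["cspca_label"].isin((0, 1)).all():
        raise ManifestError("cspca_label must be 0/1")

    if check_files:
        base = path.parent
        for col in _PATH_COLUMNS:
            if col not in manifest.columns:
                continue
            for value in manifest[col].dropna():
                f = Path(value)
                if not f.is_absolute():
                    f = base / f
                if not f.exists():
                    raise ManifestError(f"manifest references missing file: {f}")
    return manifest


def save_manifest(manifest: pd.DataFrame, path) -> None:
    """Save a manifest as CSV (or JSON when the path ends in .json).
    Output is byte-deterministic for a given frame."""
    path = Path(path)
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"cannot save manifest lacking columns {missing}")
    if path.suffix == ".json":
        records = manifest.to_dict(orient="records")
        path.write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")
    else:
        manifest.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# cohort arithmetic
# ---------------------------------------------------------------------------

def _prevalence_pct(n_with: int, n_without: int) -> float:
    """100 * with / (with + without), half-up rounded to two decimals."""
    total = n_with + n_without
    if total == 0:
        raise ValueError("empty cohort has no prevalence")
    pct = Decimal(100 * n_with) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortRow:
    name: str
    n_without: int
    n_with: int

    @property
    def n_total(self) -> int:
        return self.n_without + self.n_with

    @property
    def prevalence_pct(self) -> float:
        return _prevalence_pct(self.n_with, self.n_without)


@dataclass(frozen=True)
class CohortSummary:
    """Per-cohort and total csPCa counts with prevalence percentages."""

    cohorts: Tuple[CohortRow, ...]

    @property
    def total(self) -> CohortRow:
        return CohortRow("total",
                         sum(r.n_without for r in self.cohorts),
                         sum(r.n_with for r in self.cohorts))

    def __getitem__(self, name: str) -> CohortRow:
        for row in self.cohorts:
            if row.name == name:
                return row
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.cohorts) + [self.total]
        return pd.DataFrame(
            {"cohort": [r.name for r in rows],
             "without_cspca": [r.n_without for r in rows],
             "with_cspca": [r.n_with for r in rows],
             "n_exams": [r.n_total for r in rows],
             "prevalence_pct": [r.prevalence_pct for r in rows]})


def cohort_summary(manifest: pd.DataFrame,
                   by: str = "cohort") -> CohortSummary:
    """Count exams with/without csPCa per cohort (or any grouping column)
    and derive prevalence percentages."""
    if len(manifest) == 0:
        raise ManifestError("cannot summarize an empty manifest")
    if by not in manifest.columns:
        raise ManifestError(f"grouping column '{by}' missing from manifest")
    rows = []
    for name, group in manifest.groupby(by, sort=True):
        n_with = int((group["cspca_label"] == 1).sum())
        n_without = int((group["cspca_label"] == 0).sum())
        rows.append(CohortRow(str(name), n_without, n_with))
    return CohortSummary(tuple(rows))


def counts_summary(counts: Dict[str, Tuple[int, int]]) -> CohortSummary:
    """Build a summary directly from ``{name: (n_without, n_with)}`` counts
    (e.g. numbers printed in a cohort table)."""
    return CohortSummary(tuple(CohortRow(k, v[0], v[1])
                               for k, v in counts.items()))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(manifest: pd.DataFrame, test_fraction: float,
                     seed: int) -> pd.DataFrame:
    """Deterministic train/test split stratified by cohort and csPCa label.

    Within every (cohort, label) stratum, exams are ordered by exam_id,
    shuffled with the seeded generator, and the first
    ``round(test_fraction * n)`` go to the test split.  Returns a copy
    with the ``split`` column filled.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = "train"
    for (_, _), group in out.groupby(["cohort", "cspca_label"], sort=True):
        ids = sorted(group["exam_id"])
        perm = rng.permutation(len(ids))
        n_test = int(round(test_fraction * len(ids)))
        test_ids = {ids[i] for i in perm[:n_test]}
        out.loc[out["exam_id"].isin(test_ids), "split"] = "test"
    return out
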