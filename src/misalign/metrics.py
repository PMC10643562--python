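"""Evaluation layer: lesion overlap distributions and patient-level ROC.

Two complementary views of alignment quality are provided.  The
surrogate view measures how well lesion annotations from the T2w and
ADC domains overlap (per-lesion Dice scores and their probability
density).  The clinical view scores each exam by the maximum of a
voxelwise lesion-probability map and evaluates patient-level csPCa
discrimination with the AUROC, percentile-bootstrap confidence
intervals and the DeLong test for paired AUROC differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dice", "lesionwise_dice", "DiceDistribution", "dice_distribution",
    "patient_score", "auroc", "bootstrap_auroc_ci", "delong_test",
    "pirads_operating_point", "RocEvaluation", "roc_evaluation",
    "evaluate_configurations",
]


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Both masks empty is defined as perfect agreement (1.0).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def lesionwise_dice(labels_a: np.ndarray, labels_b: np.ndarray) -> List[float]:
    """Per-lesion Dice between two label volumes on a common grid.

    Lesions are paired greedily by maximal voxel overlap; every
    unmatched lesion on either side contributes a Dice of 0.  Returns
    one value per matched pair or orphan.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label volume shapes differ: {a.shape} vs {b.shape}")
    ids_a = [int(i) for i in np.unique(a) if i > 0]
    ids_b = [int(i) for i in np.unique(b) if i > 0]
    if not ids_a and not ids_b:
        warnings.warn("no lesions in either label volume", stacklevel=2)
        return []

    sizes_a = {i: int((a == i).sum()) for i in ids_a}
    sizes_b = {j: int((b == j).sum()) for j in ids_b}
    overlap = {(i, j): int(np.logical_and(a == i, b == j).sum())
               for i in ids_a for j in ids_b}

    values: List[float] = []
    free_a, free_b = set(ids_a), set(ids_b)
    pairs = sorted(overlap.items(), key=lambda kv: (-kv[1], kv[0]))
    for (i, j), ov in pairs:
        if ov == 0:
            break
        if i in free_a and j in free_b:
            values.append(2.0 * ov / (sizes_a[i] + sizes_b[j]))
            free_a.discard(i)
            free_b.discard(j)
    values.extend(0.0 for _ in free_a)
    values.extend(0.0 for _ in free_b)
    return values


@dataclass
class DiceDistribution:
    """Sample of per-lesion Dice values with summary statistics and a
    boundary-corrected kernel density on [0, 1]."""

    values: np.ndarray
    mean: float
    sd: float
    grid: np.ndarray
    density: np.ndarray

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Dice {self.mean:.2f} ± {self.sd:.2f} (n={len(self.values)})"


def dice_distribution(values: Sequence[float], grid_points: int = 512
                      ) -> DiceDistribution:
    """Summarize Dice values: sample mean, sample sd and a Gaussian-kernel
    density estimate on [0, 1] with reflection at both boundaries.

    The bandwidth follows Silverman's rule; reflection keeps the density
    mass inside the unit interval so it integrates to 1.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("dice_distribution requires at least one value")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("Dice values must lie in [0, 1]")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    grid = np.linspace(0.0, 1.0, grid_points)
    spread = vals.std(ddof=1) if vals.size > 1 else 0.0
    if spread > 0:
        kde = stats.gaussian_kde(vals, bw_method="silverman")
        # mirror images from reflecting at 0 and 1 (two orders suffice
        # for any bandwidth the rule produces on [0, 1] data)
        density = (kde(grid) + kde(-grid) + kde(2.0 - grid)
                   + kde(grid - 2.0) + kde(grid + 2.0))
    else:
        # degenerate sample: narrow Gaussian bump, still reflected
        h = 0.02
        def bump(x):
            return np.exp(-0.5 * ((x - mean) / h) ** 2) / (h * np.sqrt(2 * np.pi))
        density = bump(grid) + bump(-grid) + bump(2.0 - grid)
    return DiceDistribution(values=vals, mean=mean, sd=sd, grid=grid,
                            density=density)


def patient_score(prob_map: np.ndarray) -> float:
    """Patient-level cancer score: the global maximum of the voxelwise
    lesion-probability map."""
    prob = np.asarray(prob_map)
    if prob.size == 0:
        raise ValueError("probability map is empty")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(prob.max())


# ---------------------------------------------------------------------------
# ROC statistics
# ---------------------------------------------------------------------------

def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not np.all(np.isin(classes, (0, 1))):
        raise ValueError("labels must be 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUROC as the Mann–Whitney statistic: the fraction of
    (positive, negative) pairs ordered correctly, ties counting 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def bootstrap_auroc_ci(scores: Sequence[float], labels: Sequence[int],
                       B: int = 1000, alpha: float = 0.05,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None
                       ) -> Tuple[float, float]:
    """Percentile bootstrap CI for the AUROC over ``B`` case resamples.

    Replicates that draw a single class are redrawn so every replicate
    has a defined AUROC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    if B < 100:
        raise ValueError("B must be >= 100 for a stable percentile interval")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = labels.size
    reps = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if 0 < lab.sum() < n:
                break
        reps[b] = auroc(scores[idx], lab)
    lo, hi = np.percentile(reps, (100 * alpha / 2.0, 100 * (1 - alpha / 2.0)))
    return float(lo), float(hi)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray
                       ) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus DeLong structural components V10 (per positive) and
    V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> Tuple[float, float, float]:
    """DeLong test for the difference of two correlated AUROCs.

    Both score vectors must be paired on the same exams.  Returns
    ``(auroc_a, auroc_b, p_value)`` with a two-sided p from the normal
    approximation using the structural-component covariance estimator.
    When the estimated variance of the difference is zero (e.g. the two
    score vectors are identical) the difference carries no evidence and
    p = 1.0 is returned with a warning.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_binary(np.asarray(labels))
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("scores_a, scores_b and labels must be equally long")

    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size

    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0 or not np.isfinite(var):
        warnings.warn("DeLong variance of the AUROC difference is zero; "
                      "returning p = 1.0", stacklevel=2)
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, p


def delong_auroc_variance(scores: Sequence[float], labels: Sequence[int]
                          ) -> float:
    """DeLong variance estimate of a single AUROC."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    _, v10, v01 = _delong_components(scores, labels)
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


def pirads_operating_point(pirads: Sequence[int], labels: Sequence[int],
                           threshold: int) -> Tuple[float, float]:
    """Sensitivity/specificity of the rule ``positive iff PI-RADS >= t``."""
    pirads = np.asarray(pirads)
    labels = _check_binary(np.asarray(labels))
    if np.any((pirads < 1) | (pirads > 5)):
        raise ValueError("PI-RADS scores must lie in 1..5")
    pred = pirads >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    return tp / (tp + fn), tn / (tn + fp)


# ---------------------------------------------------------------------------
# full evaluation objects
# ---------------------------------------------------------------------------

@dataclass
class RocEvaluation:
    """Patient-level ROC evaluation of one configuration."""

    scores: np.ndarray
    labels: np.ndarray
    auroc: float
    ci_95: Tuple[float, float]
    bootstrap_B: int = 1000
    operating_points: List[Tuple[float, float, float]] = field(default_factory=list)


def roc_evaluation(scores: Sequence[float], labels: Sequence[int],
                   B: int = 1000, alpha: float = 0.05,
                   seed: Optional[int] = None,
                   thresholds: Sequence[float] = ()) -> RocEvaluation:
    """Point AUROC, bootstrap CI and optional score-threshold operating
    points for one configuration."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    point = auroc(scores, labels)
    ci = bootstrap_auroc_ci(scores, labels, B=B, alpha=alpha, seed=seed)
    ops = []
    for thr in thresholds:
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fn = int(np.sum(~pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        fp = int(np.sum(pred & (labels == 0)))
        ops.append((float(thr), tp / (tp + fn), tn / (tn + fp)))
    return RocEvaluation(scores=scores, labels=labels, auroc=point,
                         ci_95=ci, bootstrap_B=B, operating_points=ops)


def evaluate_configurations(score_sets: Dict[str, Sequence[float]],
                            labels: Sequence[int],
                            reference_name: str,
                            B: int = 1000, alpha: float = 0.05,
                            seed: Optional[int] = None) -> pd.DataFrame:
    """Tabulate AUROC, bootstrap 95% CI and DeLong p versus a reference
    configuration for several paired score sets.

    All score sets must be paired on the same exams.  The reference row
    carries ``p_value = NaN`` and ``reference = True``.
    """
    if reference_name not in score_sets:
        raise ValueError(f"reference configuration '{reference_name}' not in "
                         f"score sets {sorted(score_sets)}")
    labels = _check_binary(np.asarray(labels))
    n = labels.size
    rows = []
    ref_scores = np.asarray(score_sets[reference_name], dtype=float)
    for name, scores in score_sets.items():
        scores = np.asarray(scores, dtype=float)
        if scores.shape != labels.shape:
            raise ValueError(f"score set '{name}' is not paired with labels")
        point = auroc(scores, labels)
        ci = bootstrap_auroc_ci(scores, labels, B=B, alpha=alpha, seed=seed)
        if name == reference_name:
            p = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, p = delong_test(scores, ref_scores, labels)
        rows.append({"configuration": name, "auroc": point,
                     "ci_lo": ci[0], "ci_hi": ci[1], "p_value": p,
                     "reference": name == reference_name, "n": n})
    return pd.DataFrame(rows)
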