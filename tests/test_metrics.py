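"""Overlap metrics and the ROC/statistics stack against independent oracles."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from misalign import (auroc, bootstrap_auroc_ci, delong_test, dice,
                      dice_distribution, evaluate_configurations,
                      lesionwise_dice, patient_score, pirads_operating_point)
from misalign.metrics import delong_auroc_variance


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def test_dice_basic_identities():
    a = np.zeros((4, 4, 2), bool)
    a[1:3, 1:3, :] = True
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
    assert dice(np.zeros_like(a), np.zeros_like(a)) == 1.0  # both empty
    assert dice(a, np.zeros_like(a)) == 0.0


def test_dice_analytic_half_overlap():
    a = np.zeros(200, bool)
    b = np.zeros(200, bool)
    a[:100] = True
    b[50:150] = True  # |A|=|B|=100, overlap 50
    assert dice(a, b) == 0.5


def test_dice_shape_mismatch_raises():
    with pytest.raises(ValueError):
        dice(np.zeros((2, 2)), np.zeros((3, 2)))


def test_lesionwise_identical_labels():
    labels = np.zeros((12, 12, 3), np.int16)
    labels[1:4, 1:4, 0] = 1
    labels[6:9, 6:9, 1] = 2
    labels[1:4, 8:11, 2] = 3
    assert lesionwise_dice(labels, labels) == [1.0, 1.0, 1.0]


def test_lesionwise_disjoint_pair_scores_zero():
    a = np.zeros((10, 10, 2), np.int16)
    b = np.zeros_like(a)
    a[1:3, 1:3, :] = 1
    b[6:8, 6:8, :] = 1  # entirely shifted off its partner
    values = lesionwise_dice(a, b)
    assert 0.0 in values and len(values) == 2  # two orphans


def test_lesionwise_empty_inputs_warn():
    with pytest.warns(UserWarning):
        assert lesionwise_dice(np.zeros((3, 3, 3), np.int16),
                               np.zeros((3, 3, 3), np.int16)) == []


def test_lesionwise_matches_sphere_intersection_closed_form():
    """A 10 mm sphere shifted by 4 mm: Dice equals the analytic
    lens-volume formula 2*V_int / (V + V)."""
    r, d = 5.0, 4.0
    # lens volume of two equal spheres at center distance d
    v_int = math.pi * (2 * r - d) ** 2 * (d ** 2 + 4 * d * r) / (12 * d)
    v = 4 / 3 * math.pi * r ** 3
    expected = 2 * v_int / (2 * v)

    h = 0.25  # fine isotropic grid
    ax = np.arange(-9, 9, h)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    a = (x ** 2 + y ** 2 + z ** 2 <= r ** 2).astype(np.int16)
    b = ((x - d) ** 2 + y ** 2 + z ** 2 <= r ** 2).astype(np.int16)
    (value,) = lesionwise_dice(a, b)
    assert abs(value - expected) < 0.05


# ---------------------------------------------------------------------------
# Dice distribution
# ---------------------------------------------------------------------------

def test_distribution_single_value():
    d = dice_distribution([0.5])
    assert d.mean == 0.5 and d.sd == 0.0


def test_distribution_sample_sd():
    d = dice_distribution([0.4, 0.6])
    assert np.isclose(d.mean, 0.5)
    assert np.isclose(d.sd, np.std([0.4, 0.6], ddof=1))


@pytest.mark.parametrize("values", [
    [0.5], [0.1, 0.2, 0.9], list(np.random.default_rng(0).beta(2, 2, 200))])
def test_density_integrates_to_one(values):
    d = dice_distribution(values)
    assert abs(np.trapezoid(d.density, d.grid) - 1.0) < 1e-3


def test_distribution_rejects_bad_input():
    with pytest.raises(ValueError):
        dice_distribution([])
    with pytest.raises(ValueError):
        dice_distribution([0.5, 1.2])


# ---------------------------------------------------------------------------
# patient score
# ---------------------------------------------------------------------------

def test_patient_score_basics(rng):
    assert patient_score(np.zeros((4, 4, 4))) == 0.0
    single = np.zeros((4, 4, 4))
    single[1, 2, 3] = 0.73
    assert patient_score(single) == 0.73
    prob = rng.uniform(size=(5, 5, 5))
    assert patient_score(prob) == patient_score(
        rng.permutation(prob.ravel()).reshape(prob.shape))


def test_patient_score_is_monotone(rng):
    prob = rng.uniform(0, 0.5, size=(4, 4, 4))
    higher = prob.copy()
    higher[0, 0, 0] = 0.9
    assert patient_score(higher) >= patient_score(prob)


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def pairwise_auroc_oracle(scores, labels):
    """Exhaustive O(n_pos * n_neg) pair count with ties at 0.5."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auroc_worked_example():
    assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75


def test_auroc_degenerate_cases():
    assert auroc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
    assert auroc([0.3] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    with pytest.raises(ValueError):
        auroc([0.1, 0.2], [1, 1])


def test_auroc_equals_pairwise_oracle_with_ties(rng):
    for _ in range(60):
        n = int(rng.integers(4, 60))
        scores = rng.choice([0.1, 0.2, 0.3, 0.55, 0.9], size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        assert auroc(scores, labels) == pytest.approx(
            pairwise_auroc_oracle(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------

def test_bootstrap_interval_contains_point_and_is_deterministic(rng):
    scores = rng.uniform(size=80)
    labels = (scores + rng.normal(0, 0.3, 80) > 0.5).astype(int)
    point = auroc(scores, labels)
    ci1 = bootstrap_auroc_ci(scores, labels, B=400, seed=9)
    ci2 = bootstrap_auroc_ci(scores, labels, B=400, seed=9)
    assert ci1 == ci2
    assert ci1[0] <= point <= ci1[1]


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def test_delong_identical_scores_gives_p_one(rng):
    scores = rng.uniform(size=40)
    labels = rng.integers(0, 2, 40)
    labels[:2] = (0, 1)
    with pytest.warns(UserWarning):
        a, b, p = delong_test(scores, scores, labels)
    assert a == b and p == 1.0


def permutation_oracle(scores_a, scores_b, labels, n_rep, seed):
    """Paired-permutation p for the AUROC difference: per exam, swap the
    two scores with probability 1/2."""
    rng = np.random.default_rng(seed)
    obs = abs(auroc(scores_a, labels) - auroc(scores_b, labels))
    sa, sb = np.asarray(scores_a, float), np.asarray(scores_b, float)
    count = 0
    for _ in range(n_rep):
        flip = rng.integers(0, 2, sa.size).astype(bool)
        pa = np.where(flip, sb, sa)
        pb = np.where(flip, sa, sb)
        count += abs(auroc(pa, labels) - auroc(pb, labels)) >= obs - 1e-12
    return count / n_rep


def test_delong_agrees_with_permutation_oracle(rng):
    n = 40
    labels = np.array([0, 1] * (n // 2))
    noise = rng.normal(0, 0.35, n)
    scores_a = labels * 0.5 + noise + rng.normal(0, 0.2, n)
    scores_b = labels * 0.3 + noise + rng.normal(0, 0.2, n)
    _, _, p = delong_test(scores_a, scores_b, labels)
    p_perm = permutation_oracle(scores_a, scores_b, labels, 20_000, 5)
    assert abs(p - p_perm) < 0.05


def test_delong_variance_close_to_bootstrap_variance(rng):
    n = 200
    labels = rng.integers(0, 2, n)
    labels[:2] = (0, 1)
    scores = labels * 0.6 + rng.normal(0, 0.45, n)
    var_delong = delong_auroc_variance(scores, labels)
    boot = np.empty(5000)
    brng = np.random.default_rng(17)
    for i in range(5000):
        while True:
            idx = brng.integers(0, n, n)
            if 0 < labels[idx].sum() < n:
                break
        boot[i] = auroc(scores[idx], labels[idx])
    assert abs(var_delong - boot.var(ddof=1)) / boot.var(ddof=1) < 0.2


def test_delong_and_bootstrap_agree_on_separated_case(rng):
    labels = np.array([0] * 30 + [1] * 30)
    strong = labels + rng.normal(0, 0.05, 60)
    weak = rng.uniform(size=60)
    _, _, p = delong_test(strong, weak, labels)
    ci_strong = bootstrap_auroc_ci(strong, labels, B=400, seed=2)
    ci_weak = bootstrap_auroc_ci(weak, labels, B=400, seed=2)
    assert p < 0.05 and ci_strong[0] > ci_weak[1]  # same direction


# ---------------------------------------------------------------------------
# operating points and configuration table
# ---------------------------------------------------------------------------

def test_pirads_operating_point_contingency():
    pirads = [2, 3, 4, 5, 2, 3]
    labels = [0, 0, 1, 1, 0, 1]
    sens, spec = pirads_operating_point(pirads, labels, threshold=4)
    assert sens == pytest.approx(2 / 3)
    assert spec == 1.0
    sens1, _ = pirads_operating_point(pirads, labels, threshold=1)
    assert sens1 == 1.0


def test_evaluate_configurations_reference_and_identical_sets(rng):
    labels = rng.integers(0, 2, 30)
    labels[:2] = (0, 1)
    scores = rng.uniform(size=30)
    table = evaluate_configurations({"ref": scores}, labels, "ref",
                                    B=200, seed=0)
    assert len(table) == 1 and table["reference"].all()
    assert np.isnan(table["p_value"].iloc[0])

    table2 = evaluate_configurations({"ref": scores, "same": scores.copy()},
                                     labels, "ref", B=200, seed=0)
    assert table2.set_index("configuration").loc["same", "p_value"] == 1.0
    with pytest.raises(ValueError):
        evaluate_configurations({"a": scores}, labels, "missing")
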