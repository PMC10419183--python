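import numpy as np
import pytest

from conftest import random_scores_labels
from metscreen.roc import (
    accuracy_band,
    auc_mann_whitney,
    candidate_cutoffs,
    diagnostic_metrics,
    metrics_from_rates,
    roc_curve_points,
    youden_optimal_cutpoint,
)

# ---------------------------------------------------------------------------
# independent oracles


def auc_brute_force(scores, labels):
    """Pairwise enumeration: P(score_pos > score_neg) with ties half-weighted."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_brute_force(scores, labels):
    """Exhaustive scan of the rule `score >= t` over every observed value
    plus +/-inf; returns the maximal J."""
    best = -np.inf
    for t in np.concatenate([[-np.inf], np.unique(scores), [np.inf]]):
        pred = scores >= t
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        best = max(best, sens + spec - 1.0)
    return best


def trapezoid_area(scores, labels):
    curve = roc_curve_points(scores, labels)
    fpr = (1.0 - curve["spec"]).to_numpy()
    return np.trapezoid(curve["sens"].to_numpy(), fpr)


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
        ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),  # 4 pos-neg pairs: 3 wins, 1 loss
        ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),  # all ties -> half credit
    ],
)
def test_auc_small_instances(scores, labels, expected):
    auc, _, _ = auc_mann_whitney(np.array(scores, float), np.array(labels, bool))
    assert auc == pytest.approx(expected)


def test_auc_matches_brute_force_and_trapezoid():
    """Mann-Whitney AUC == pairwise enumeration == trapezoidal ROC area
    on 200 random instances (with and without ties)."""
    rng = np.random.default_rng(20240915)
    for _ in range(200):
        scores, labels = random_scores_labels(rng)
        auc, _, _ = auc_mann_whitney(scores, labels)
        assert auc == pytest.approx(auc_brute_force(scores, labels), abs=1e-12)
        assert auc == pytest.approx(trapezoid_area(scores, labels), abs=1e-12)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    for _ in range(25):
        scores, labels = random_scores_labels(rng)
        auc, _, _ = auc_mann_whitney(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_youden_matches_exhaustive_scan():
    rng = np.random.default_rng(20240916)
    for _ in range(200):
        scores, labels = random_scores_labels(rng)
        res = youden_optimal_cutpoint(scores, labels)
        assert res.youden_j == pytest.approx(youden_brute_force(scores, labels), abs=1e-12)


def test_auc_complement_identity():
    rng = np.random.default_rng(3)
    for _ in range(50):
        scores, labels = random_scores_labels(rng)
        a1, _, _ = auc_mann_whitney(scores, labels)
        a2, _, _ = auc_mann_whitney(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)


def test_invariance_under_monotone_transform():
    rng = np.random.default_rng(4)
    for _ in range(25):
        scores, labels = random_scores_labels(rng)
        a1, _, _ = auc_mann_whitney(scores, labels)
        a2, _, _ = auc_mann_whitney(np.exp(0.5 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)
        j1 = youden_optimal_cutpoint(scores, labels).youden_j
        j2 = youden_optimal_cutpoint(np.exp(0.5 * scores), labels).youden_j
        assert j1 == pytest.approx(j2, abs=1e-12)


def test_hanley_mcneil_se_hand_value():
    # A=0.75, n_pos=n_neg=2: Q1=A/(2-A)=0.6, Q2=2A^2/(1+A)=9/14,
    # var=(0.1875 + (0.6-0.5625) + (9/14-0.5625))/4
    scores = np.array([1.0, 2, 3, 4])
    labels = np.array([0, 1, 0, 1], bool)
    _, se, ci = auc_mann_whitney(scores, labels)
    q1, q2, a = 0.6, 9 / 14, 0.75
    expected = np.sqrt((a * (1 - a) + (q1 - a**2) + (q2 - a**2)) / 4)
    assert se == pytest.approx(expected, rel=1e-12)
    assert ci == (pytest.approx(max(0.0, a - 1.96 * se)), pytest.approx(min(1.0, a + 1.96 * se)))


def test_delong_se_close_to_hanley_on_continuous_scores():
    rng = np.random.default_rng(11)
    scores = np.concatenate([rng.normal(1, 1, 300), rng.normal(0, 1, 300)])
    labels = np.arange(600) < 300
    _, se_h, _ = auc_mann_whitney(scores, labels, se_method="hanley")
    _, se_d, _ = auc_mann_whitney(scores, labels, se_method="delong")
    assert se_d == pytest.approx(se_h, rel=0.25)


def test_perfect_split_cutpoint():
    res = youden_optimal_cutpoint(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1], bool))
    assert res.optimal_cutoff == pytest.approx(2.5)  # midpoint placement
    assert res.youden_j == pytest.approx(1.0)
    assert res.sensitivity == 1.0 and res.specificity == 1.0


def test_tie_break_prefers_sensitivity_then_lower_cutoff():
    # scores 1,2,3,4 labels 0,1,0,1: J=0.5 at cutoffs 1.5 (sens 1.0) and
    # 3.5 (sens 0.5) -> pick 1.5
    res = youden_optimal_cutpoint(np.array([1.0, 2, 3, 4]), np.array([0, 1, 0, 1], bool))
    assert res.optimal_cutoff == pytest.approx(1.5)
    assert res.sensitivity == 1.0


def test_single_class_rejected():
    with pytest.raises(ValueError):
        auc_mann_whitney(np.array([1.0, 2.0]), np.array([True, True]))
    with pytest.raises(ValueError):
        youden_optimal_cutpoint(np.array([1.0, 2.0]), np.array([False, False]))


def test_diagnostic_metrics_two_by_two_oracle():
    """TP=1109, FN=222, TN=2576, FP=433 -> sens .8332, spec .8561, LR+ 5.79."""
    scores = np.concatenate(
        [np.ones(1109), np.zeros(222), np.zeros(2576), np.ones(433)]
    )
    labels = np.concatenate([np.ones(1331, bool), np.zeros(3009, bool)])
    m = diagnostic_metrics(scores, labels, cutoff=1.0)
    assert m.sensitivity == pytest.approx(1109 / 1331, abs=1e-12)
    assert m.specificity == pytest.approx(2576 / 3009, abs=1e-12)
    assert m.lr_pos == pytest.approx((1109 / 1331) / (433 / 3009), rel=1e-9)
    assert m.ppv == pytest.approx(1109 / (1109 + 433))
    assert m.npv == pytest.approx(2576 / (2576 + 222))


def test_sentinel_cutoffs():
    scores = np.array([1.0, 2, 3, 4])
    labels = np.array([0, 1, 0, 1], bool)
    lo = diagnostic_metrics(scores, labels, -np.inf)
    assert (lo.sensitivity, lo.specificity) == (1.0, 0.0)
    assert lo.lr_neg is None  # spec 0 -> undefined, not NaN
    hi = diagnostic_metrics(scores, labels, np.inf)
    assert (hi.sensitivity, hi.specificity) == (0.0, 1.0)
    assert hi.lr_pos is None


def test_metrics_from_rates_identities():
    m = metrics_from_rates(0.853, 0.856)
    assert m["youden_j"] == pytest.approx(0.709)
    assert m["lr_pos"] == pytest.approx(5.924, abs=5e-4)
    assert m["lr_neg"] == pytest.approx(0.172, abs=5e-4)


def test_roc_curve_monotone_with_sentinels():
    rng = np.random.default_rng(5)
    scores, labels = random_scores_labels(rng)
    curve = roc_curve_points(scores, labels)
    sens = curve["sens"].to_numpy()
    fpr = 1.0 - curve["spec"].to_numpy()
    assert np.isinf(curve["cutoff"].iloc[0]) and np.isinf(curve["cutoff"].iloc[-1])
    assert sens[0] == 0.0 and sens[-1] == 1.0
    assert fpr[0] == 0.0 and fpr[-1] == 1.0
    assert np.all(np.diff(sens) >= 0) and np.all(np.diff(fpr) >= 0)


def test_candidate_cutoffs_are_midpoints():
    cands = candidate_cutoffs([1.0, 2.0, 2.0, 5.0])
    assert list(cands) == [-np.inf, 1.5, 3.5, np.inf]


def test_null_scores_give_chance_auc():
    rng = np.random.default_rng(99)
    scores = rng.normal(size=2000)
    labels = rng.random(2000) < 0.4
    auc, _, _ = auc_mann_whitney(scores, labels)
    assert 0.45 <= auc <= 0.55


@pytest.mark.parametrize(
    "auc, band",
    [(0.95, "high"), (0.9, "moderate"), (0.7, "moderate"), (0.69, "low"), (0.5, "chance")],
)
def test_accuracy_bands(auc, band):
    assert accuracy_band(auc) == band
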