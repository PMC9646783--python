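"""Aggregation features, ROC/threshold selection and repeated forest fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microstain.slide_level import (FEATURE_NAMES, aggregate, avg_pool_1d,
                                    closest_top_left, evaluate_repeated,
                                    roc_from_scores, sensitivity_specificity_at,
                                    train_slide_classifier)
from microstain.tile_classifier import TilePredictionSeries


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_features(values, pool_size=10, stride=5):
    """Reference 12-feature computation written directly from definitions."""
    v = list(map(float, values))
    n = len(v)

    def quantile(data, q):
        s = sorted(data)
        pos = q * (len(s) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return s[lo] + (pos - lo) * (s[hi] - s[lo])

    def sd(data):
        if len(data) < 2:
            return 0.0
        m = sum(data) / len(data)
        return (sum((x - m) ** 2 for x in data) / (len(data) - 1)) ** 0.5

    if n < pool_size:
        pooled = [sum(v) / n]
    else:
        pooled = []
        s = 0
        while s + pool_size <= n:
            pooled.append(sum(v[s:s + pool_size]) / pool_size)
            s += stride
    return {
        "mean": sum(v) / n, "median": quantile(v, 0.5), "min": min(v),
        "max": max(v), "sd": sd(v), "q25": quantile(v, 0.25),
        "q75": quantile(v, 0.75), "pooled_min": min(pooled),
        "pooled_max": max(pooled), "pooled_q25": quantile(pooled, 0.25),
        "pooled_q75": quantile(pooled, 0.75), "pooled_sd": sd(pooled),
    }


def mann_whitney_auc(y, scores):
    """Rank-sum AUC with half credit for tied score pairs."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def enumerate_top_left(y, scores):
    """Exhaustive closest-top-left search over all candidate thresholds."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    candidates = sorted(set(s)) + [np.inf]
    best = None
    for thr in candidates:
        calls = s >= thr
        tpr = np.sum(calls & (y == 1)) / np.sum(y == 1)
        fpr = np.sum(calls & (y == 0)) / np.sum(y == 0)
        key = ((1 - tpr) ** 2 + fpr**2, fpr, -thr)
        if best is None or key < best[0]:
            best = (key, thr)
    return best[1]


# ---------------------------------------------------------------------------
# 1-D average pooling
# ---------------------------------------------------------------------------

def test_pooling_windows_of_length_23():
    v = np.arange(23, dtype=float)
    pooled = avg_pool_1d(v, pool_size=10, stride=5)
    assert len(pooled) == 3
    np.testing.assert_allclose(pooled, [v[0:10].mean(), v[5:15].mean(),
                                        v[10:20].mean()])


def test_pooling_constant_series_stays_constant():
    for n in (1, 7, 10, 37):
        pooled = avg_pool_1d(np.full(n, 0.42))
        np.testing.assert_allclose(pooled, 0.42)


def test_pooling_short_series_single_window():
    pooled = avg_pool_1d([0.1, 0.2, 0.3, 0.4], pool_size=10, stride=5)
    assert pooled.shape == (1,)
    assert pooled[0] == pytest.approx(0.25)


def test_pooling_invalid_arguments():
    with pytest.raises(ValueError):
        avg_pool_1d([0.5], pool_size=0)
    with pytest.raises(ValueError):
        avg_pool_1d([0.5], stride=0)
    with pytest.raises(ValueError):
        avg_pool_1d([])


@given(st.integers(min_value=1, max_value=60), st.integers(min_value=1, max_value=12),
       st.integers(min_value=1, max_value=12))
@settings(max_examples=60, deadline=None)
def test_pooling_length_formula(n, pool, stride):
    v = np.linspace(0, 1, n)
    pooled = avg_pool_1d(v, pool, stride)
    expected = (n - pool) // stride + 1 if n >= pool else 1
    assert len(pooled) == expected


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_constant_series_features():
    fv = aggregate([0.5, 0.5, 0.5])
    for name in ("mean", "median", "min", "max", "q25", "q75",
                 "pooled_min", "pooled_max", "pooled_q25", "pooled_q75"):
        assert getattr(fv, name) == 0.5
    assert fv.sd == 0.0 and fv.pooled_sd == 0.0


def test_two_point_series_hand_computed():
    fv = aggregate([0.0, 1.0])
    assert fv.mean == 0.5 and fv.min == 0.0 and fv.max == 1.0
    assert fv.sd == pytest.approx(np.sqrt(0.5), abs=1e-12)
    assert fv.q25 == pytest.approx(0.25)
    assert fv.q75 == pytest.approx(0.75)
    # below pool size: one window holding the overall mean
    assert fv.pooled_min == fv.pooled_max == pytest.approx(0.5)


def test_features_match_brute_force_oracle():
    rng = np.random.default_rng(0)
    for n in (1, 3, 9, 10, 11, 23, 200):
        v = rng.uniform(size=n)
        fv = aggregate(v)
        ref = brute_force_features(v)
        for name in FEATURE_NAMES:
            assert getattr(fv, name) == pytest.approx(ref[name], abs=1e-12), name


def test_feature_invariants():
    rng = np.random.default_rng(3)
    for _ in range(25):
        v = rng.uniform(size=rng.integers(2, 60))
        fv = aggregate(v)
        assert fv.min <= fv.q25 <= fv.median <= fv.q75 <= fv.max
        # pooled values are means of subsets of the raw series
        assert fv.pooled_min >= fv.min - 1e-12
        assert fv.pooled_max <= fv.max + 1e-12


def test_aggregation_uses_exactly_the_supplied_values():
    v = [0.9, 0.8, 0.7]
    assert aggregate(v).mean != aggregate(v + [0.0]).mean


def test_empty_series_rejected():
    with pytest.raises(ValueError):
        aggregate([])


def test_aggregate_accepts_prediction_series():
    s = TilePredictionSeries("P1", "WARS1", np.array([0.2, 0.4, 0.6]))
    assert aggregate(s).mean == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

def _separated_features(rng, n_pos=6, n_neg=10):
    pos = np.clip(rng.normal(0.85, 0.03, size=(n_pos, 12)), 0, 1)
    neg = np.clip(rng.normal(0.15, 0.03, size=(n_neg, 12)), 0, 1)
    X = np.vstack([pos, neg])
    y = np.array([1] * n_pos + [0] * n_neg)
    return X, y


def test_forest_has_exactly_100_trees_by_default():
    X, y = _separated_features(np.random.default_rng(0))
    rf = train_slide_classifier(X, y, seed=0)
    assert len(rf.estimators_) == 100


def test_forest_perfect_training_auc_on_separated_features():
    X, y = _separated_features(np.random.default_rng(1))
    rf = train_slide_classifier(X, y, seed=0)
    assert roc_from_scores(y, rf.predict_proba(X)[:, 1]).auc == 1.0


def test_forest_deterministic_for_seed():
    X, y = _separated_features(np.random.default_rng(2))
    p1 = train_slide_classifier(X, y, seed=7).predict_proba(X)[:, 1]
    p2 = train_slide_classifier(X, y, seed=7).predict_proba(X)[:, 1]
    assert np.array_equal(p1, p2)


def test_forest_rejects_wrong_feature_width():
    with pytest.raises(ValueError):
        train_slide_classifier(np.zeros((4, 5)), [0, 1, 0, 1])


# ---------------------------------------------------------------------------
# ROC / threshold
# ---------------------------------------------------------------------------

def test_roc_invariants_and_auc_matches_rank_sum():
    rng = np.random.default_rng(5)
    for _ in range(30):
        n = rng.integers(4, 40)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        scores = np.round(rng.uniform(size=n), 1)  # force ties
        roc = roc_from_scores(y, scores)
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert roc.auc == pytest.approx(mann_whitney_auc(y, scores), abs=1e-12)


def test_closest_top_left_worked_example():
    roc = roc_from_scores([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2])
    assert closest_top_left(roc) == pytest.approx(0.8)


def test_closest_top_left_anti_classifier():
    y = [1, 1, 0, 0]
    s = [0.1, 0.2, 0.8, 0.9]
    assert closest_top_left(roc_from_scores(y, s)) == enumerate_top_left(y, s)


def test_closest_top_left_duplicate_scores_do_not_move_the_point():
    y = [1, 1, 0, 0]
    s = [0.9, 0.8, 0.3, 0.2]
    t1 = closest_top_left(roc_from_scores(y, s))
    t2 = closest_top_left(roc_from_scores(y + [0], s + [0.2]))
    assert t1 == t2 == pytest.approx(0.8)


def test_closest_top_left_matches_enumeration_on_random_vectors():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = rng.integers(3, 9)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        s = np.round(rng.uniform(size=n), 1)
        if np.unique(s).size < 2:
            continue
        got = closest_top_left(roc_from_scores(y, s))
        assert got == pytest.approx(enumerate_top_left(y, s))


def test_closest_top_left_undefined_for_constant_scores():
    with pytest.raises(ValueError):
        closest_top_left(roc_from_scores([1, 0], [0.5, 0.5]))


def test_sensitivity_specificity_convention():
    se, sp = sensitivity_specificity_at([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1], 0.5)
    assert se == 50.0 and sp == 50.0


# ---------------------------------------------------------------------------
# repeated evaluation
# ---------------------------------------------------------------------------

def test_single_iteration_reduces_to_single_fit():
    rng = np.random.default_rng(4)
    Xtr, ytr = _separated_features(rng)
    Xva, yva = _separated_features(rng, 3, 5)
    ev = evaluate_repeated(Xtr, ytr, Xva, yva, n_iter=1, seed=0)
    assert ev.aucs.shape == (1,)
    assert ev.mean_auc == ev.aucs[0]


def test_perfectly_separated_validation_gives_perfect_means():
    rng = np.random.default_rng(6)
    Xtr, ytr = _separated_features(rng)
    Xva, yva = _separated_features(rng, 4, 6)
    ev = evaluate_repeated(Xtr, ytr, Xva, yva, n_iter=5, seed=0)
    assert ev.mean_auc == 1.0
    assert ev.mean_sensitivity == 100.0
    assert ev.mean_specificity == 100.0


def test_repeated_evaluation_validates_inputs():
    rng = np.random.default_rng(7)
    Xtr, ytr = _separated_features(rng)
    with pytest.raises(ValueError):
        evaluate_repeated(Xtr, ytr, Xtr, ytr, n_iter=0)
    with pytest.raises(ValueError):
        evaluate_repeated(Xtr, ytr, Xtr, np.ones_like(ytr))


def test_auc_sampling_variance_shrinks_with_training_size():
    """Monte-Carlo: across cohort draws, the spread of mean validation AUCs
    narrows when the training set doubles."""
    def run(n_train, seed):
        rng = np.random.default_rng(seed)
        Xtr = np.clip(rng.normal(0.5, 0.25, size=(n_train, 12)), 0, 1)
        ytr = (Xtr[:, 0] + rng.normal(0, 0.35, n_train) > 0.5).astype(int)
        if ytr.min() == ytr.max():
            ytr[0] = 1 - ytr[0]
        Xva = np.clip(rng.normal(0.5, 0.25, size=(20, 12)), 0, 1)
        yva = (Xva[:, 0] > 0.5).astype(int)
        if yva.min() == yva.max():
            yva[0] = 1 - yva[0]
        return evaluate_repeated(Xtr, ytr, Xva, yva, n_iter=3, n_trees=25,
                                 seed=seed).mean_auc

    small = [run(12, s) for s in range(25)]
    large = [run(48, s) for s in range(25)]
    assert np.var(large) < np.var(small)
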