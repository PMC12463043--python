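"""Boosting contracts: fit rules, loss monotonicity, importance, persistence."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from enosekit.boosting import (
    EnsembleModel,
    Hyperparameters,
    fit_adaboostm1,
    fit_gentleboost,
    predict,
    predictor_importance,
    tune_hyperparameters,
)


def _blobs(n=100, sep=4.0, seed=0, n_features=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    y = np.where(np.arange(n) % 2 == 0, "neg", "pos")
    X[y == "pos", 0] += sep
    return X, y


def test_hyperparameter_validation():
    with pytest.raises(ValueError):
        Hyperparameters(learn_rate=0.0)
    with pytest.raises(ValueError):
        Hyperparameters(n_cycles=0)
    with pytest.raises(ValueError):
        Hyperparameters(method="LogitBoost")


def test_gentleboost_two_point_exact():
    X = np.array([[-1.0], [1.0]])
    y = np.array(["neg", "pos"])
    hp = Hyperparameters(n_cycles=1, learn_rate=1.0, max_splits=1, min_leaf=1)
    model = fit_gentleboost(X, y, hp)
    labels, scores = predict(model, X)
    assert list(labels) == ["neg", "pos"]
    assert np.allclose(scores, [-1.0, 1.0])
    assert model.training_meta["train_error"] == 0.0


def test_gentleboost_separable_converges():
    X, y = _blobs(100, sep=4.0, seed=1)
    hp = Hyperparameters(n_cycles=50, learn_rate=0.5, max_splits=2, min_leaf=1)
    model = fit_gentleboost(X, y, hp)
    assert model.training_meta["train_error"] == 0.0


def test_gentleboost_single_cycle_equals_weighted_tree():
    X, y = _blobs(60, sep=2.0, seed=2)
    hp = Hyperparameters(n_cycles=1, learn_rate=0.3, max_splits=4, min_leaf=2)
    model = fit_gentleboost(X, y, hp)
    ref = DecisionTreeRegressor(max_leaf_nodes=5, min_samples_leaf=2, random_state=0)
    ref.fit(X, np.where(y == "pos", 1.0, -1.0), sample_weight=np.full(60, 1 / 60))
    assert np.allclose(model.decision_scores(X), 0.3 * ref.predict(X), atol=1e-12)


def test_gentleboost_exponential_loss_nonincreasing():
    X, y = _blobs(80, sep=1.0, seed=3)  # overlapping classes
    hp = Hyperparameters(n_cycles=40, learn_rate=0.5, max_splits=3, min_leaf=2)
    model = fit_gentleboost(X, y, hp)
    path = np.asarray(model.training_meta["exp_loss_path"])
    assert np.all(np.diff(path) <= 1e-12)


def test_single_class_rejected():
    X = np.zeros((5, 2))
    with pytest.raises(ValueError):
        fit_gentleboost(X, np.array(["a"] * 5))
    with pytest.raises(ValueError):
        fit_adaboostm1(X, np.array(["a"] * 5))


def test_adaboost_perfect_stump_stops_early():
    X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    y = np.array(["neg", "neg", "pos", "pos"])
    hp = Hyperparameters(method="AdaBoostM1", n_cycles=20, learn_rate=1.0, max_splits=1)
    model = fit_adaboostm1(X, y, hp)
    assert len(model.learners) == 1
    assert model.training_meta["train_error"] == 0.0
    assert model.training_meta["weighted_error_path"] == [0.0]


def test_adaboost_weighted_error_matches_bruteforce():
    X, y = _blobs(50, sep=0.8, seed=4)
    hp = Hyperparameters(method="AdaBoostM1", n_cycles=1, learn_rate=1.0, max_splits=1)
    model = fit_adaboostm1(X, y, hp)
    h = model.learners[0].predict(np.asarray(X, dtype=float))
    ye = np.where(y == sorted(set(y))[1], 1.0, -1.0)
    eps_oracle = np.sum(np.full(50, 1 / 50)[h != ye])
    assert np.isclose(model.training_meta["weighted_error_path"][0], eps_oracle, atol=1e-12)


def test_stumps_cannot_solve_xor():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    y = np.array(["neg", "pos", "pos", "neg"])
    for fitter, method in ((fit_gentleboost, "GentleBoost"), (fit_adaboostm1, "AdaBoostM1")):
        hp = Hyperparameters(method=method, n_cycles=30, learn_rate=0.5, max_splits=1)
        model = fitter(X, y, hp)
        assert model.training_meta["train_error"] > 0.0


def test_predict_contracts():
    X, y = _blobs(40, sep=3.0, seed=5)
    model = fit_gentleboost(X, y, Hyperparameters(n_cycles=10))
    # duplicated row -> identical score
    X2 = np.vstack([X[0], X[0]])
    s = model.decision_scores(X2)
    assert s[0] == s[1]
    # feature mismatch rejected
    with pytest.raises(ValueError):
        model.decision_scores(X[:, :1])
    # empty learner list -> all-zero scores, tie to first class
    empty = EnsembleModel(
        hp=model.hp, learners=[], learner_weights=np.array([]),
        classes=model.classes, feature_names=model.feature_names,
    )
    labels, scores = predict(empty, X[:3])
    assert np.all(scores == 0.0)
    assert np.all(labels == model.classes[0])


def test_row_permutation_invariance():
    X, y = _blobs(60, sep=2.0, seed=6)
    rng = np.random.default_rng(0)
    perm = rng.permutation(60)
    m1 = fit_gentleboost(X, y, Hyperparameters(n_cycles=15))
    m2 = fit_gentleboost(X[perm], y[perm], Hyperparameters(n_cycles=15))
    probe = rng.normal(size=(20, 2))
    assert np.allclose(m1.decision_scores(probe), m2.decision_scores(probe), atol=1e-9)


def test_importance_single_stump_and_unused_feature():
    X, y = _blobs(60, sep=5.0, seed=7, n_features=3)
    hp = Hyperparameters(n_cycles=1, learn_rate=1.0, max_splits=1)
    model = fit_gentleboost(X, y, hp)
    imp = predictor_importance(model)
    assert np.isclose(imp.sum(), 100.0, atol=1e-9)
    assert imp.iloc[0] == 100.0  # the separating feature
    assert imp.iloc[1] == 0.0 and imp.iloc[2] == 0.0


def _gain_oracle(tree, X, w, target):
    """Weighted-variance-reduction gains recomputed from data, by definition."""
    gains = np.zeros(X.shape[1])

    def wvar(idx):
        if idx.sum() == 0:
            return 0.0, 0.0
        ww = w[idx]
        mu = np.average(target[idx], weights=ww)
        return ww.sum(), float(np.average((target[idx] - mu) ** 2, weights=ww))

    def descend(node, idx):
        f = tree.feature[node]
        if f < 0:
            return
        thr = tree.threshold[node]
        left = idx & (X[:, f] <= thr)
        right = idx & ~(X[:, f] <= thr)
        wn, vn = wvar(idx)
        wl, vl = wvar(left)
        wr, vr = wvar(right)
        gains[f] += wn * vn - wl * vl - wr * vr
        descend(tree.children_left[node], left)
        descend(tree.children_right[node], right)

    descend(0, np.ones(X.shape[0], dtype=bool))
    return gains


def test_importance_matches_hand_accumulated_gains():
    X, y = _blobs(80, sep=1.5, seed=8, n_features=3)
    hp = Hyperparameters(n_cycles=2, learn_rate=1.0, max_splits=3, min_leaf=2)
    model = fit_gentleboost(X, y, hp)
    ye = np.where(y == model.classes[1], 1.0, -1.0)
    # replay the boosting weights to reconstruct per-tree training weights
    n = len(ye)
    w = np.full(n, 1 / n)
    total = np.zeros(3)
    F = np.zeros(n)
    for tree in model.learners:
        total += _gain_oracle(tree, X, w, ye)
        h = tree.predict(X.astype(float))
        F += hp.learn_rate * h
        w = w * np.exp(-ye * hp.learn_rate * h)
        w /= w.sum()
    expected = total / total.sum() * 100
    got = predictor_importance(model).to_numpy()
    assert np.allclose(got, expected, atol=1e-6)


def test_serialization_roundtrip_identical_predictions():
    X, y = _blobs(50, sep=2.0, seed=9)
    model = fit_gentleboost(X, y, Hyperparameters(n_cycles=8))
    clone = EnsembleModel.from_dict(model.to_dict())
    probe = np.random.default_rng(1).normal(size=(30, 2))
    assert np.array_equal(model.decision_scores(probe), clone.decision_scores(probe))
    assert np.array_equal(model.predict(probe), clone.predict(probe))


def test_tuner_budget_and_log():
    X, y = _blobs(60, sep=3.0, seed=10)
    res1 = tune_hyperparameters(X, y, budget=1, seed=0, k_folds=3)
    assert len(res1.log) == 1
    assert res1.best == res1.log[0][0]
    point_space = {
        "method": ("GentleBoost",),
        "n_cycles": (5, 5),
        "learn_rate": (0.5, 0.5),
        "max_splits": (2, 2),
        "min_leaf": (1, 1),
    }
    res2 = tune_hyperparameters(X, y, budget=3, space=point_space, seed=0, k_folds=3)
    assert res2.best.n_cycles == 5 and res2.best.max_splits == 2
    res3 = tune_hyperparameters(X, y, budget=8, seed=1, k_folds=3)
    losses = [l for _, l in res3.log]
    assert res3.best_loss <= np.median(losses)
    assert res3.best_loss == min(losses)
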