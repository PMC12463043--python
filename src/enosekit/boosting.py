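"""Boosted shallow-tree binary classifiers: GentleBoost and AdaBoostM1.

Both ensembles combine depth-limited decision trees grown best-first to
at most ``max_splits`` internal nodes with at least ``min_leaf``
observations per leaf.

GentleBoost (Gentle AdaBoost) fits, at each cycle, a weighted
least-squares regression tree to the +/-1 class targets, adds it to the
additive score scaled by the learning rate, and reweights observations
by exp(-y * learn_rate * h(x)). AdaBoostM1 is classical discrete
AdaBoost: weighted classification trees, learner weight
alpha = learn_rate * 0.5 * ln((1 - eps)/eps) from the weighted error
eps, and early stopping when eps reaches 0 or 0.5.

Individual trees are delegated to scikit-learn's CART implementation;
the boosting loops, the additive model, per-split gain bookkeeping for
predictor importance, and JSON-portable persistence are implemented
here. Fitted models are stored as plain array-backed tree structures so
that a serialized model predicts identically after a round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

__all__ = [
    "Hyperparameters",
    "TreeStruct",
    "EnsembleModel",
    "TuningResult",
    "fit_gentleboost",
    "fit_adaboostm1",
    "fit_ensemble",
    "predict",
    "tune_hyperparameters",
    "predictor_importance",
    "DEFAULT_SEARCH_SPACE",
]

_EPS_FLOOR = 1e-12


@dataclass(frozen=True)
class Hyperparameters:
    """Boosting configuration mirroring the "optimizable ensemble" vocabulary."""

    method: str = "GentleBoost"  # or "AdaBoostM1"
    n_cycles: int = 100
    learn_rate: float = 0.1
    max_splits: int = 8
    min_leaf: int = 1

    def __post_init__(self) -> None:
        if self.method not in {"GentleBoost", "AdaBoostM1"}:
            raise ValueError("method must be GentleBoost or AdaBoostM1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not (0.0 < self.learn_rate <= 1.0):
            raise ValueError("learn_rate must lie in (0, 1]")
        if self.max_splits < 1:
            raise ValueError("max_splits must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass(frozen=True)
class TreeStruct:
    """Array-backed decision tree: leaves hold additive score values."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray  # -1 at leaves
    threshold: np.ndarray
    value: np.ndarray  # per-node score (used at leaves)
    feature_gain: np.ndarray  # impurity-reduction gain accumulated per feature

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.intp)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(
                go_left, self.children_left[nd], self.children_right[nd]
            )
            active = self.feature[node] >= 0
        return self.value[node]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "value": self.value.tolist(),
            "feature_gain": self.feature_gain.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeStruct":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=np.intp),
            children_right=np.asarray(d["children_right"], dtype=np.intp),
            feature=np.asarray(d["feature"], dtype=np.intp),
            threshold=np.asarray(d["threshold"], dtype=float),
            value=np.asarray(d["value"], dtype=float),
            feature_gain=np.asarray(d["feature_gain"], dtype=float),
        )


def _extract_tree(est, n_features: int, leaf_value) -> TreeStruct:
    """Freeze a fitted sklearn tree into arrays and collect per-split gains."""
    t = est.tree_
    gains = np.zeros(n_features)
    internal = np.flatnonzero(t.children_left >= 0)
    for nd in internal:
        l, r = t.children_left[nd], t.children_right[nd]
        gain = (
            t.weighted_n_node_samples[nd] * t.impurity[nd]
            - t.weighted_n_node_samples[l] * t.impurity[l]
            - t.weighted_n_node_samples[r] * t.impurity[r]
        )
        gains[t.feature[nd]] += max(gain, 0.0)
    return TreeStruct(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        value=leaf_value(t),
        feature_gain=gains,
    )


@dataclass
class EnsembleModel:
    """Additive boosted-tree binary classifier.

    ``classes`` is the ordered label pair; the internal target coding is
    classes[0] -> -1, classes[1] -> +1, and prediction thresholds the
    additive score at 0 (ties go to classes[0]).
    """

    hp: Hyperparameters
    learners: list[TreeStruct]
    learner_weights: np.ndarray
    classes: tuple[str, str]
    feature_names: list[str]
    training_meta: dict = field(default_factory=dict)

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise ValueError(f"missing features: {missing[:5]}...")
            return X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got shape {X.shape}"
            )
        return X

    def decision_scores(self, X) -> np.ndarray:
        Xa = self._as_array(X)
        scores = np.zeros(Xa.shape[0])
        for w, tree in zip(self.learner_weights, self.learners):
            scores += w * tree.predict(Xa)
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        return np.where(scores > 0, self.classes[1], self.classes[0])

    def to_dict(self) -> dict:
        return {
            "format": "enosekit-ensemble-v1",
            "hp": {
                "method": self.hp.method,
                "n_cycles": self.hp.n_cycles,
                "learn_rate": self.hp.learn_rate,
                "max_splits": self.hp.max_splits,
                "min_leaf": self.hp.min_leaf,
            },
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
            "learner_weights": np.asarray(self.learner_weights).tolist(),
            "learners": [t.to_dict() for t in self.learners],
            "training_meta": _jsonable(self.training_meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        if d.get("format") != "enosekit-ensemble-v1":
            raise ValueError("unrecognized model format")
        return cls(
            hp=Hyperparameters(**d["hp"]),
            learners=[TreeStruct.from_dict(t) for t in d["learners"]],
            learner_weights=np.asarray(d["learner_weights"], dtype=float),
            classes=tuple(d["classes"]),
            feature_names=list(d["feature_names"]),
            training_meta=dict(d.get("training_meta", {})),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _encode_targets(y, classes: tuple[str, str] | None):
    y = np.asarray(y)
    found = sorted(pd.unique(y).tolist())
    if classes is None:
        classes = tuple(found)
    if len(found) < 2:
        raise ValueError("training labels contain a single class")
    if len(found) > 2 or set(found) - set(classes):
        raise ValueError(f"expected two classes {classes}, got {found}")
    return np.where(y == classes[1], 1.0, -1.0), tuple(classes)


def _prepare(X, y, classes):
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feature_names = [f"f{i}" for i in range(Xa.shape[1])]
    if np.isnan(Xa).any():
        raise ValueError("feature matrix must not contain missing values")
    ye, classes = _encode_targets(y, classes)
    if len(ye) != Xa.shape[0]:
        raise ValueError("X and y must be aligned")
    return Xa, feature_names, ye, classes


def fit_gentleboost(
    X,
    y,
    hp: Hyperparameters | None = None,
    classes: tuple[str, str] | None = None,
) -> EnsembleModel:
    """Gentle AdaBoost: weighted least-squares trees on +/-1 targets.

    Records the weighted exponential-loss trajectory (under the initial
    uniform weights) in ``training_meta['exp_loss_path']``.
    """
    hp = hp or Hyperparameters(method="GentleBoost")
    if hp.method != "GentleBoost":
        raise ValueError("hp.method must be GentleBoost")
    Xa, feature_names, ye, classes = _prepare(X, y, classes)
    n = Xa.shape[0]
    w = np.full(n, 1.0 / n)
    F = np.zeros(n)
    learners: list[TreeStruct] = []
    loss_path: list[float] = []
    for _ in range(hp.n_cycles):
        est = DecisionTreeRegressor(
            max_leaf_nodes=hp.max_splits + 1,
            min_samples_leaf=hp.min_leaf,
            random_state=0,
        )
        est.fit(Xa, ye, sample_weight=w)
        tree = _extract_tree(
            est, Xa.shape[1], leaf_value=lambda t: t.value[:, 0, 0].copy()
        )
        h = tree.predict(Xa)
        F += hp.learn_rate * h
        learners.append(tree)
        loss_path.append(float(np.mean(np.exp(-ye * F))))
        w = w * np.exp(-ye * hp.learn_rate * h)
        total = w.sum()
        if total <= 0 or not np.isfinite(total):
            break
        w /= total
    weights = np.full(len(learners), hp.learn_rate)
    train_err = float(np.mean(np.where(F > 0, 1.0, -1.0) != ye))
    return EnsembleModel(
        hp=hp,
        learners=learners,
        learner_weights=weights,
        classes=classes,
        feature_names=feature_names,
        training_meta={"exp_loss_path": loss_path, "train_error": train_err},
    )


def fit_adaboostm1(
    X,
    y,
    hp: Hyperparameters | None = None,
    classes: tuple[str, str] | None = None,
) -> EnsembleModel:
    """Discrete AdaBoost (M1) over weighted classification trees."""
    hp = hp or Hyperparameters(method="AdaBoostM1")
    if hp.method != "AdaBoostM1":
        raise ValueError("hp.method must be AdaBoostM1")
    Xa, feature_names, ye, classes = _prepare(X, y, classes)
    n = Xa.shape[0]
    w = np.full(n, 1.0 / n)
    learners: list[TreeStruct] = []
    alphas: list[float] = []
    eps_path: list[float] = []
    for _ in range(hp.n_cycles):
        est = DecisionTreeClassifier(
            max_leaf_nodes=hp.max_splits + 1,
            min_samples_leaf=hp.min_leaf,
            random_state=0,
        )
        est.fit(Xa, ye, sample_weight=w)
        cls = est.classes_

        def leaf_value(t, cls=cls):
            return cls[np.argmax(t.value[:, 0, :], axis=1)].astype(float)

        tree = _extract_tree(est, Xa.shape[1], leaf_value=leaf_value)
        h = tree.predict(Xa)
        miss = h != ye
        eps = float(w[miss].sum())
        eps_path.append(eps)
        if eps >= 0.5:
            break
        eps_c = max(eps, _EPS_FLOOR)
        alpha = hp.learn_rate * 0.5 * math.log((1.0 - eps_c) / eps_c)
        learners.append(tree)
        alphas.append(alpha)
        if eps == 0.0:
            break
        w = w * np.exp(alpha * miss)
        w /= w.sum()
    # an empty learner list (first stump no better than chance) is a valid,
    # degenerate model: score 0 everywhere, predicting classes[0]
    weights = np.asarray(alphas)
    F = np.zeros(n)
    for a, tree in zip(weights, learners):
        F += a * tree.predict(Xa)
    train_err = float(np.mean(np.where(F > 0, 1.0, -1.0) != ye))
    return EnsembleModel(
        hp=hp,
        learners=learners,
        learner_weights=weights,
        classes=classes,
        feature_names=feature_names,
        training_meta={"weighted_error_path": eps_path, "train_error": train_err},
    )


def fit_ensemble(X, y, hp: Hyperparameters, classes=None) -> EnsembleModel:
    """Dispatch on hp.method."""
    if hp.method == "GentleBoost":
        return fit_gentleboost(X, y, hp, classes)
    return fit_adaboostm1(X, y, hp, classes)


def predict(model: EnsembleModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and real-valued additive scores for new observations."""
    scores = model.decision_scores(X)
    labels = np.where(scores > 0, model.classes[1], model.classes[0])
    return labels, scores


def predictor_importance(model: EnsembleModel) -> pd.Series:
    """Per-feature impurity-reduction importance, percentages summing to 100.

    Each split's gain (weighted impurity decrease) is attributed to the
    splitting feature, summed over all trees scaled by the learner weight.
    """
    total = np.zeros(len(model.feature_names))
    for w, tree in zip(model.learner_weights, model.learners):
        total += abs(float(w)) * tree.feature_gain
    s = total.sum()
    if s > 0:
        total = total / s * 100.0
    return pd.Series(total, index=model.feature_names, name="importance_pct")


# ---------------------------------------------------------------------------
# Hyperparameter search

DEFAULT_SEARCH_SPACE: dict = {
    "method": ("GentleBoost", "AdaBoostM1"),
    "n_cycles": (10, 500),
    "learn_rate": (1e-3, 1.0),
    "max_splits": (1, 64),
    "min_leaf": (1, 32),
}


@dataclass(frozen=True)
class TuningResult:
    best: Hyperparameters
    best_loss: float
    log: tuple[tuple[Hyperparameters, float], ...]


def _log_uniform_int(rng, lo, hi) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _sample_candidate(rng: np.random.Generator, space: dict) -> Hyperparameters:
    return Hyperparameters(
        method=space["method"][rng.integers(len(space["method"]))],
        n_cycles=_log_uniform_int(rng, *space["n_cycles"]),
        learn_rate=float(
            math.exp(rng.uniform(*map(math.log, space["learn_rate"])))
        ),
        max_splits=_log_uniform_int(rng, *space["max_splits"]),
        min_leaf=_log_uniform_int(rng, *space["min_leaf"]),
    )


def _cv_loss(X, y, hp: Hyperparameters, k_folds: int, seed: int) -> float:
    if isinstance(X, pd.DataFrame):
        Xa = X.to_numpy(dtype=float)
        cols = list(X.columns)
    else:
        Xa = np.asarray(X, dtype=float)
        cols = None
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    losses = []
    for tr, va in skf.split(Xa, y):
        Xtr = pd.DataFrame(Xa[tr], columns=cols) if cols else Xa[tr]
        Xva = pd.DataFrame(Xa[va], columns=cols) if cols else Xa[va]
        model = fit_ensemble(Xtr, y[tr], hp)
        losses.append(float(np.mean(model.predict(Xva) != y[va])))
    return float(np.mean(losses))


def tune_hyperparameters(
    X,
    y,
    budget: int = 30,
    space: dict | None = None,
    seed: int = 0,
    k_folds: int = 5,
) -> TuningResult:
    """Seeded sequential search minimizing 5-fold CV classification loss.

    Quasi-random exploration of the space for the first two thirds of the
    budget (the first candidate is the package default, clipped to the
    space), then local refinement around the incumbent. Returns the best
    candidate together with the full evaluation log.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = space or DEFAULT_SEARCH_SPACE
    rng = np.random.default_rng(seed)
    default = Hyperparameters(
        method=space["method"][0],
        n_cycles=int(np.clip(100, *space["n_cycles"])),
        learn_rate=float(np.clip(0.1, *space["learn_rate"])),
        max_splits=int(np.clip(8, *space["max_splits"])),
        min_leaf=int(np.clip(1, *space["min_leaf"])),
    )
    log: list[tuple[Hyperparameters, float]] = []
    best_hp, best_loss = None, math.inf
    n_explore = max(1, (2 * budget) // 3)
    for i in range(budget):
        if i == 0:
            hp = default
        elif i < n_explore or best_hp is None:
            hp = _sample_candidate(rng, space)
        else:  # jitter the incumbent
            hp = Hyperparameters(
                method=best_hp.method,
                n_cycles=int(
                    np.clip(
                        round(best_hp.n_cycles * math.exp(rng.normal(0, 0.3))),
                        *space["n_cycles"],
                    )
                ),
                learn_rate=float(
                    np.clip(
                        best_hp.learn_rate * math.exp(rng.normal(0, 0.3)),
                        *space["learn_rate"],
                    )
                ),
                max_splits=int(
                    np.clip(
                        round(best_hp.max_splits * math.exp(rng.normal(0, 0.3))),
                        *space["max_splits"],
                    )
                ),
                min_leaf=int(
                    np.clip(
                        round(best_hp.min_leaf * math.exp(rng.normal(0, 0.3))),
                        *space["min_leaf"],
                    )
                ),
            )
        loss = _cv_loss(X, y, hp, k_folds, seed)
        log.append((hp, loss))
        if loss < best_loss:
            best_hp, best_loss = hp, loss
    return TuningResult(best=best_hp, best_loss=best_loss, log=tuple(log))
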