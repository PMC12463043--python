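"""Leakage-aware splitting, cross-validation, metrics and robustness runs.

Splitting operates at two levels: *observation* level, where individual
(sample, sensor) feature rows are partitioned, and *sample* level, where
all rows of a sample move together (the leakage-safe variant, since
repeated sensor observations of one biosample are strongly dependent).
Stratified allocation uses largest-remainder rounding with a total test
size of ceil(test_frac * n_units); every sample-level split is verified
to share no sample_id across partitions.

Robustness is assessed by repeating the split/fit/evaluate cycle with
distinct derived seeds and reporting mean metrics with Student-t 95%
confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .boosting import EnsembleModel, Hyperparameters, fit_ensemble
from .features import FeatureMatrix, build_feature_matrix
from .sensors import AblationSchedule, SimilarityRanking, similarity_coefficients
from .simulate import Measurement

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "RobustnessReport",
    "stratified_split",
    "kfold",
    "compute_metrics",
    "roc_and_auc",
    "mean_roc",
    "robustness",
    "run_ablation",
    "train_only_ranked_run",
    "assert_no_group_leakage",
]


@dataclass(frozen=True)
class SplitPlan:
    """How data are partitioned: level, test fraction, folds, seed."""

    level: str = "sample"  # or "observation"
    test_frac: float = 0.10
    k_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in {"observation", "sample"}:
            raise ValueError("level must be 'observation' or 'sample'")
        if not (0.0 < self.test_frac < 1.0):
            raise ValueError("test_frac must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def assert_no_group_leakage(
    train_groups: Sequence, test_groups: Sequence
) -> None:
    shared = set(train_groups) & set(test_groups)
    if shared:
        raise AssertionError(f"sample leakage across partitions: {sorted(shared)[:5]}")


def _units(fm: FeatureMatrix, level: str):
    """Split units and their class labels: rows, or samples with their class."""
    if level == "observation":
        return np.arange(len(fm)), fm.y.to_numpy()
    g = fm.groups.to_numpy()
    y = fm.y.to_numpy()
    units, first = np.unique(g, return_index=True)
    unit_y = y[first]
    for u, uy in zip(units, unit_y):
        if not np.all(y[g == u] == uy):
            raise ValueError(f"inconsistent class label within sample {u!r}")
    return units, unit_y


def _largest_remainder_counts(n_per_stratum: np.ndarray, frac: float) -> np.ndarray:
    """Test-set counts per stratum: floor quotas topped up by largest remainder
    to a total of ceil(frac * n)."""
    quotas = frac * n_per_stratum
    base = np.floor(quotas).astype(int)
    target = math.ceil(frac * n_per_stratum.sum())
    rem = quotas - base
    # ties: larger stratum first, then stratum order
    order = np.lexsort((np.arange(len(quotas)), -n_per_stratum, -rem))
    k = int(target - base.sum())
    for i in order[: max(k, 0)]:
        base[i] += 1
    return np.minimum(base, n_per_stratum)


def stratified_split(
    fm: FeatureMatrix, plan: SplitPlan
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test split; returns row positions.

    At sample level all rows of a sample fall on one side, and the split
    is checked for group leakage before being returned.
    """
    units, unit_y = _units(fm, plan.level)
    classes = np.unique(unit_y)
    if len(classes) < 2:
        raise ValueError("need two classes to stratify")
    rng = np.random.default_rng(plan.seed)
    n_per = np.array([(unit_y == c).sum() for c in classes])
    if plan.level == "sample" and np.any(n_per < 2):
        raise ValueError("every class needs at least 2 samples at sample level")
    n_test = _largest_remainder_counts(n_per, plan.test_frac)
    test_units = []
    for c, k in zip(classes, n_test):
        members = units[unit_y == c]
        perm = rng.permutation(len(members))
        test_units.extend(members[perm[:k]])
    test_units = set(test_units)
    if plan.level == "observation":
        mask = np.zeros(len(fm), dtype=bool)
        mask[[u for u in test_units]] = True
    else:
        mask = fm.groups.isin(test_units).to_numpy()
        assert_no_group_leakage(
            fm.groups.to_numpy()[~mask], fm.groups.to_numpy()[mask]
        )
    return np.flatnonzero(~mask), np.flatnonzero(mask)


def kfold(
    fm: FeatureMatrix, plan: SplitPlan, rows: np.ndarray | None = None
) -> list[np.ndarray]:
    """k stratified disjoint folds of the given rows (default: all rows).

    Units are shuffled per class and dealt round-robin, so fold sizes
    differ by at most the number of classes; at sample level no sample
    spans folds.
    """
    sub = fm if rows is None else fm.take(np.asarray(rows))
    base_rows = np.arange(len(fm)) if rows is None else np.asarray(rows)
    units, unit_y = _units(sub, plan.level)
    rng = np.random.default_rng(plan.seed + 1)
    fold_of_unit: dict = {}
    for c in np.unique(unit_y):
        members = units[unit_y == c]
        perm = rng.permutation(len(members))
        for j, u in enumerate(members[perm]):
            fold_of_unit[u] = j % plan.k_folds
    folds: list[list[int]] = [[] for _ in range(plan.k_folds)]
    if plan.level == "observation":
        for u, f in fold_of_unit.items():
            folds[f].append(base_rows[u])
    else:
        g = sub.groups.to_numpy()
        for i, grp in enumerate(g):
            folds[fold_of_unit[grp]].append(base_rows[i])
    out = [np.sort(np.asarray(f, dtype=int)) for f in folds]
    if plan.level == "sample":
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert_no_group_leakage(
                    fm.groups.iloc[out[i]], fm.groups.iloc[out[j]]
                )
    return out


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class MetricsReport:
    """Confusion counts and the derived percentage metrics.

    confusion rows are [[TP, FN], [FP, TN]] with respect to the declared
    positive class; accuracy/sensitivity/specificity are percentages.
    """

    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    positive_class: str
    n: int
    auc: float | None = None
    roc: tuple[np.ndarray, np.ndarray] | None = None
    ci95: dict = field(default_factory=dict)
    n_runs: int = 1

    def rounded(self) -> dict:
        """Headline metrics at the conventional 1-decimal percent precision."""
        out = {
            "accuracy": round(self.accuracy, 1),
            "sensitivity": round(self.sensitivity, 1),
            "specificity": round(self.specificity, 1),
        }
        if self.auc is not None:
            out["auc"] = round(self.auc, 3)
        return out


def compute_metrics(
    predicted: Sequence, true: Sequence, positive_class
) -> MetricsReport:
    """Accuracy, sensitivity, specificity (percent) from label vectors."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true must have equal length")
    if predicted.size == 0:
        raise ValueError("empty input")
    pos_t = true == positive_class
    pos_p = predicted == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    n = tp + fn + fp + tn
    acc = 100.0 * (tp + tn) / n
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else 0.0
    return MetricsReport(
        confusion=np.array([[tp, fn], [fp, tn]]),
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        positive_class=str(positive_class),
        n=n,
    )


def roc_and_auc(
    scores: Sequence[float], labels: Sequence, positive_class
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep over the scores; AUC by the trapezoid rule."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    y = labels == positive_class
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    fpr, tpr, _ = roc_curve(y.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def mean_roc(
    curves: Sequence[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> pd.DataFrame:
    """Vertically averaged ROC on a fixed FPR grid with t-based 95% CIs."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.stack([np.interp(grid, fpr, tpr) for fpr, tpr in curves])
    mean = tprs.mean(axis=0)
    k = tprs.shape[0]
    if k > 1:
        half = stats.t.ppf(0.975, k - 1) * tprs.std(axis=0, ddof=1) / math.sqrt(k)
    else:
        half = np.zeros(n_grid)
    return pd.DataFrame(
        {"fpr": grid, "tpr_mean": mean, "tpr_lo": mean - half, "tpr_hi": mean + half}
    )


def _t_ci(values: np.ndarray) -> tuple[float, float]:
    k = len(values)
    m = float(np.mean(values))
    if k < 2:
        return m, m
    half = stats.t.ppf(0.975, k - 1) * float(np.std(values, ddof=1)) / math.sqrt(k)
    return m - half, m + half


@dataclass
class RobustnessReport:
    """Aggregate of repeated split/fit/evaluate runs."""

    runs: list[MetricsReport]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    ci95: dict
    mean_auc: float | None = None

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def _fit_and_eval(
    fm: FeatureMatrix,
    hp: Hyperparameters,
    plan: SplitPlan,
    positive_class,
    with_roc: bool = True,
) -> MetricsReport:
    tr, te = stratified_split(fm, plan)
    train, test = fm.take(tr), fm.take(te)
    model = fit_ensemble(train.X, train.y.to_numpy(), hp)
    pred = model.predict(test.X)
    rep = compute_metrics(pred, test.y.to_numpy(), positive_class)
    if with_roc:
        scores = model.decision_scores(test.X)
        if positive_class == model.classes[0]:
            scores = -scores
        try:
            fpr, tpr, auc = roc_and_auc(scores, test.y.to_numpy(), positive_class)
            rep.roc = (fpr, tpr)
            rep.auc = auc
        except ValueError:
            pass
    return rep


def robustness(
    fm: FeatureMatrix,
    hp: Hyperparameters,
    plan: SplitPlan,
    n_repeats: int = 15,
    positive_class=None,
) -> RobustnessReport:
    """Repeat the train/test cycle with distinct seeds; aggregate with t CIs."""
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    positive_class = positive_class or sorted(fm.y.unique())[-1]
    runs = []
    for r in range(n_repeats):
        p = SplitPlan(
            level=plan.level,
            test_frac=plan.test_frac,
            k_folds=plan.k_folds,
            stratified=plan.stratified,
            seed=plan.seed * 10_000 + r,
        )
        runs.append(_fit_and_eval(fm, hp, p, positive_class))
    acc = np.array([r.accuracy for r in runs])
    sens = np.array([r.sensitivity for r in runs])
    spec = np.array([r.specificity for r in runs])
    aucs = [r.auc for r in runs if r.auc is not None]
    ci = {
        "accuracy": _t_ci(acc),
        "sensitivity": _t_ci(sens),
        "specificity": _t_ci(spec),
    }
    return RobustnessReport(
        runs=runs,
        mean_accuracy=float(acc.mean()),
        mean_sensitivity=float(sens.mean()),
        mean_specificity=float(spec.mean()),
        ci95=ci,
        mean_auc=float(np.mean(aucs)) if aucs else None,
    )


def run_ablation(
    fm: FeatureMatrix,
    schedule: AblationSchedule,
    hp: Hyperparameters,
    plan: SplitPlan,
    positive_class=None,
) -> pd.DataFrame:
    """Evaluate the model at every sensor-removal step.

    The feature matrix is restricted to each step's retained sensors
    (removing a sensor removes its observation rows), re-split, refit and
    scored. Returns one table row per step.
    """
    sensors_present = set(fm.X.index.get_level_values("sensor_id"))
    if not set(schedule.steps[0]) <= sensors_present:
        raise ValueError("schedule references sensors absent from the matrix")
    positive_class = positive_class or sorted(fm.y.unique())[-1]
    rows = []
    for k, retained in enumerate(schedule.steps, start=1):
        sub = fm.subset_sensors(retained)
        rep = _fit_and_eval(sub, hp, plan, positive_class, with_roc=False)
        rows.append(
            {
                "step": k,
                "n_sensors": len(retained),
                "retained_sensors": ",".join(str(s) for s in retained),
                "accuracy": rep.accuracy,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrainOnlyRankedRun:
    """Result of a split where sensor ranking used training data only."""

    ranking: SimilarityRanking
    ranking_measurement_ids: tuple[str, ...]
    train_measurement_ids: tuple[str, ...]
    test_measurement_ids: tuple[str, ...]
    report: MetricsReport


def train_only_ranked_run(
    measurements: Sequence[Measurement],
    hp: Hyperparameters,
    plan: SplitPlan,
    n_retained: int | None = None,
    positive_class=None,
    **feature_kwargs,
) -> TrainOnlyRankedRun:
    """Leakage-disciplined pipeline: rank sensors on the training split only.

    Measurements are split at the sample level, similarity coefficients are
    computed from training measurements alone, the worst sensors are dropped
    down to ``n_retained`` (default: keep all), and the model is fit on the
    training rows and scored on the held-out rows. The returned object
    records exactly which measurement ids informed the ranking, so leakage
    can be audited.
    """
    if plan.level != "sample":
        raise ValueError("training-only ranking requires a sample-level plan")
    labels = sorted({m.class_label for m in measurements})
    if len(labels) != 2:
        raise ValueError("need exactly two classes")
    positive_class = positive_class or labels[-1]
    sample_ids = sorted({m.sample_id for m in measurements})
    sample_class = {m.sample_id: m.class_label for m in measurements}
    rng = np.random.default_rng(plan.seed)
    n_per = np.array([sum(1 for s in sample_ids if sample_class[s] == c) for c in labels])
    n_test = _largest_remainder_counts(n_per, plan.test_frac)
    test_samples: set[str] = set()
    for c, k in zip(labels, n_test):
        members = [s for s in sample_ids if sample_class[s] == c]
        perm = rng.permutation(len(members))
        test_samples.update(members[i] for i in perm[:k])
    train_meas = [m for m in measurements if m.sample_id not in test_samples]
    test_meas = [m for m in measurements if m.sample_id in test_samples]
    assert_no_group_leakage(
        [m.sample_id for m in train_meas], [m.sample_id for m in test_meas]
    )
    ranking = similarity_coefficients(train_meas)
    retained = ranking.order[: n_retained or len(ranking.order)]
    train_fm = build_feature_matrix(train_meas, retained, **feature_kwargs)
    test_fm = build_feature_matrix(test_meas, retained, **feature_kwargs)
    model = fit_ensemble(train_fm.X, train_fm.y.to_numpy(), hp)
    rep = compute_metrics(
        model.predict(test_fm.X), test_fm.y.to_numpy(), positive_class
    )
    return TrainOnlyRankedRun(
        ranking=ranking,
        ranking_measurement_ids=tuple(m.measurement_id for m in train_meas),
        train_measurement_ids=tuple(m.measurement_id for m in train_meas),
        test_measurement_ids=tuple(m.measurement_id for m in test_meas),
        report=rep,
    )
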