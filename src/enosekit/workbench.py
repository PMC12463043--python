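"""Orchestration: run manifests, configuration and end-to-end case pipelines.

The run manifest mirrors the full experiment inventory of the study
protocol: 154 model trainings for each two-class case (43 model-selection
slots, 3 x 32 sensor-ablation series, 15 robustness repeats) and 488 for
the PMI case split evenly over its four cascade classifiers, 796 in
total. Executing every slot with the paper-scale ensembles is a
protocol-level description; ``run_case`` executes a configurable reduced
protocol (fewer selection slots, ablation steps and repeats, shorter
records) with full provenance: every artifact written carries the config
hash and master seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import decision, io
from .boosting import Hyperparameters, _cv_loss, _sample_candidate, fit_ensemble
from .decision import CascadeNode, pmi_bin_for_day
from .evaluation import (
    SplitPlan,
    _fit_and_eval,
    compute_metrics,
    robustness,
    stratified_split,
)
from .features import FeatureMatrix, build_feature_matrix, features_for_measurement
from .sensors import ablation_schedule, similarity_coefficients
from .simulate import (
    CaseDesign,
    NoiseModel,
    case1_design,
    case2_design,
    case3_design,
    case3_profile_builder,
    iter_case_measurements,
    make_discriminability_scenario,
)

__all__ = [
    "ManifestEntry",
    "RunManifest",
    "build_manifest",
    "PAPER_PROTOCOL",
    "RunConfig",
    "config_hash",
    "run_case",
    "CaseResult",
    "feature_matrix_for_case",
]

#: Stage counts of the full study protocol (796 model trainings).
PAPER_PROTOCOL: dict = {
    "I": {
        "model_selection": 43,
        "ablation_random_split": 32,
        "ablation_sample_split": 32,
        "ablation_train_only": 32,
        "robustness": 15,
    },
    "II": {
        "model_selection": 43,
        "ablation_random_split": 32,
        "ablation_sample_split": 32,
        "ablation_train_only": 32,
        "robustness": 15,
    },
    "III": {
        clf: {
            "model_selection": 11,
            "ablation_random_split": 32,
            "ablation_sample_split": 32,
            "ablation_train_only": 32,
            "robustness": 15,
        }
        for clf in ("A1", "A2", "A3", "A4")
    },
}

_STAGES = (
    "model_selection",
    "ablation_random_split",
    "ablation_sample_split",
    "ablation_train_only",
    "robustness",
)


@dataclass(frozen=True)
class ManifestEntry:
    run_id: str
    case_id: str
    stage: str
    config_hash: str
    seed: int
    classifier: str | None = None


@dataclass(frozen=True)
class RunManifest:
    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.run_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("run_ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def for_case(self, case_id: str) -> "RunManifest":
        return RunManifest(
            entries=tuple(e for e in self.entries if e.case_id == case_id)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.entries])


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping/dataclass."""
    if hasattr(config, "__dataclass_fields__"):
        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_manifest(protocol: Mapping | None = None, master_seed: int = 0) -> RunManifest:
    """Enumerate every model-training slot of the protocol, deterministically."""
    protocol = protocol or PAPER_PROTOCOL
    h = config_hash(dict(protocol))
    entries: list[ManifestEntry] = []
    counter = 0
    for case_id in sorted(protocol):
        spec = protocol[case_id]
        if case_id == "III":
            for clf in sorted(spec):
                stages = spec[clf]
                _check_stages(stages, f"case III/{clf}")
                for stage in _STAGES:
                    for i in range(stages[stage]):
                        entries.append(
                            ManifestEntry(
                                run_id=f"III-{clf}-{stage}-{i + 1:03d}",
                                case_id="III",
                                stage=stage,
                                config_hash=h,
                                seed=master_seed * 100_000 + counter,
                                classifier=clf,
                            )
                        )
                        counter += 1
        else:
            _check_stages(spec, f"case {case_id}")
            for stage in _STAGES:
                for i in range(spec[stage]):
                    entries.append(
                        ManifestEntry(
                            run_id=f"{case_id}-{stage}-{i + 1:03d}",
                            case_id=case_id,
                            stage=stage,
                            config_hash=h,
                            seed=master_seed * 100_000 + counter,
                        )
                    )
                    counter += 1
    return RunManifest(entries=tuple(entries))


def _check_stages(stages: Mapping, where: str) -> None:
    missing = [s for s in _STAGES if s not in stages]
    if missing:
        raise ValueError(f"{where}: protocol missing stages {missing}")
    for s in _STAGES:
        if int(stages[s]) < 0:
            raise ValueError(f"{where}: negative count for {s}")


# ---------------------------------------------------------------------------
# Case execution


@dataclass(frozen=True)
class RunConfig:
    """Configurable (reduced) execution protocol for one case pipeline."""

    seed: int = 0
    # scenario
    effect_size: float = 1.0
    n_dead_sensors: int = 2
    day_effect: float = 1.0
    sigma_obs: float = 0.01
    sample_effect_sd: float = 0.15
    sensor_jitter_sd: float = 0.05
    # acquisition (full scale: n_time=6000, t0=30, exposure_end=300)
    n_time: int = 6000
    dt: float = 0.1
    t0: float = 30.0
    exposure_end: float = 300.0
    # preprocessing / features
    sg_window: int = 51
    sg_order: int = 3
    # model
    method: str = "GentleBoost"
    n_cycles: int = 100
    learn_rate: float = 0.1
    max_splits: int = 8
    min_leaf: int = 1
    # protocol sizes
    n_selection: int = 5
    n_ablation_steps: int = 8
    n_repeats: int = 3
    split_level: str = "sample"
    test_frac: float = 0.10
    k_folds: int = 5

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(self.sigma_obs, self.sample_effect_sd, self.sensor_jitter_sd)

    @property
    def hp(self) -> Hyperparameters:
        return Hyperparameters(
            self.method, self.n_cycles, self.learn_rate, self.max_splits, self.min_leaf
        )

    @property
    def plan(self) -> SplitPlan:
        return SplitPlan(
            level=self.split_level,
            test_frac=self.test_frac,
            k_folds=self.k_folds,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


_CASE_LABELS = {
    "I": ("antemortem", "postmortem"),
    "II": ("human", "animal"),
}


def _case_design(case_id: str, seed: int) -> CaseDesign:
    return {"I": case1_design, "II": case2_design, "III": case3_design}[case_id](seed)


def _case_profiles(case_id: str, cfg: RunConfig):
    if case_id == "III":
        return case3_profile_builder(seed=cfg.seed, day_effect=cfg.day_effect)
    labels = _CASE_LABELS[case_id]
    n_dead = cfg.n_dead_sensors if case_id == "I" else max(cfg.n_dead_sensors, 5)
    scenario = make_discriminability_scenario(
        n_dead_sensors=n_dead,
        effect_size=cfg.effect_size,
        seed=cfg.seed,
        labels=labels,
    )
    return scenario.profiles


def feature_matrix_for_case(case_id: str, cfg: RunConfig) -> FeatureMatrix:
    """Simulate a case design and featurize it measurement-by-measurement."""
    design = _case_design(case_id, cfg.seed)
    profiles = _case_profiles(case_id, cfg)
    meas_iter = iter_case_measurements(
        design,
        profiles,
        cfg.noise,
        n_time=cfg.n_time,
        dt=cfg.dt,
        t0=cfg.t0,
        exposure_end=cfg.exposure_end,
    )
    rows = []
    labels = []
    samples = []
    pmi = []
    for m in meas_iter:
        f = features_for_measurement(m, None, cfg.sg_window, cfg.sg_order)
        rows.append(f)
        labels.extend([m.class_label] * len(f))
        samples.extend([m.sample_id] * len(f))
        pmi.extend([m.pmi_days] * len(f))
    X = pd.concat(rows)
    fm = FeatureMatrix(
        X=X,
        y=pd.Series(labels, index=X.index, name="class_label"),
        groups=pd.Series(samples, index=X.index, name="sample_id"),
        meta={
            "case_id": case_id,
            "config_hash": config_hash(cfg),
            "seed": cfg.seed,
            "sg_window": cfg.sg_window,
            "sg_order": cfg.sg_order,
        },
    )
    if case_id == "III":
        fm.meta["pmi_days"] = pmi
    return fm


@dataclass
class CaseResult:
    case_id: str
    config: RunConfig
    config_hash: str
    ranking: pd.DataFrame | None
    selection: pd.DataFrame | None
    ablation: pd.DataFrame | None
    metrics: dict
    out_dir: Path | None = None
    model_paths: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)


def _model_selection_table(fm: FeatureMatrix, cfg: RunConfig) -> pd.DataFrame:
    """Evaluate the configurable model roster by k-fold CV loss."""
    rng = np.random.default_rng(cfg.seed + 7)
    candidates = [cfg.hp]
    while len(candidates) < cfg.n_selection:
        candidates.append(_sample_candidate(rng, _selection_space()))
    rows = []
    for i, hp in enumerate(candidates[: cfg.n_selection], start=1):
        loss = _cv_loss(fm.X, fm.y.to_numpy(), hp, cfg.k_folds, cfg.seed)
        rows.append(
            {
                "slot": i,
                "method": hp.method,
                "n_cycles": hp.n_cycles,
                "learn_rate": hp.learn_rate,
                "max_splits": hp.max_splits,
                "min_leaf": hp.min_leaf,
                "cv_loss": loss,
            }
        )
    return pd.DataFrame(rows)


def _selection_space() -> dict:
    return {
        "method": ("GentleBoost", "AdaBoostM1"),
        "n_cycles": (10, 120),
        "learn_rate": (1e-2, 1.0),
        "max_splits": (1, 32),
        "min_leaf": (1, 16),
    }


def run_case(case_id: str, cfg: RunConfig, out_dir=None) -> CaseResult:
    """Execute the (reduced-protocol) pipeline for one case.

    Two-class cases: simulate -> featurize -> rank sensors -> model
    selection -> ablation over the first ``n_ablation_steps`` steps ->
    robustness. The PMI case: featurize once, then train and evaluate the
    four cascade classifiers and persist them as portable JSON.
    """
    if case_id not in {"I", "II", "III"}:
        raise ValueError("case_id must be I, II or III")
    h = config_hash(cfg)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(cfg.to_yaml())

    if case_id in ("I", "II"):
        design = _case_design(case_id, cfg.seed)
        profiles = _case_profiles(case_id, cfg)
        measurements = list(
            iter_case_measurements(
                design,
                profiles,
                cfg.noise,
                n_time=cfg.n_time,
                dt=cfg.dt,
                t0=cfg.t0,
                exposure_end=cfg.exposure_end,
            )
        )
        ranking = similarity_coefficients(
            measurements, sg_window=cfg.sg_window, sg_order=cfg.sg_order
        )
        schedule = ablation_schedule(ranking)
        fm = build_feature_matrix(
            measurements, sg_window=cfg.sg_window, sg_order=cfg.sg_order
        )
        fm.meta.update({"config_hash": h, "seed": cfg.seed})
        selection = _model_selection_table(fm, cfg)
        positive = _CASE_LABELS[case_id][1]
        rows = []
        for k, retained in enumerate(schedule.steps[: cfg.n_ablation_steps], start=1):
            sub = fm.subset_sensors(retained)
            rep = _fit_and_eval(sub, cfg.hp, cfg.plan, positive, with_roc=False)
            rows.append(
                {
                    "step": k,
                    "n_sensors": len(retained),
                    "retained_sensors": ",".join(map(str, retained)),
                    "accuracy": rep.accuracy,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                }
            )
        ablation = pd.DataFrame(rows)
        rob = robustness(fm, cfg.hp, cfg.plan, n_repeats=max(cfg.n_repeats, 2), positive_class=positive)
        metrics = {
            "robust_mean_accuracy": rob.mean_accuracy,
            "robust_mean_sensitivity": rob.mean_sensitivity,
            "robust_mean_specificity": rob.mean_specificity,
            "robust_ci95": rob.ci95,
            "config_hash": h,
            "seed": cfg.seed,
        }
        result = CaseResult(case_id, cfg, h, ranking.to_frame(), selection, ablation, metrics, out)
        if out is not None:
            ranking.to_frame().to_csv(out / "sensor_ranking.csv", index=False)
            selection.to_csv(out / "model_selection.csv", index=False)
            ablation.to_csv(out / "ablation.csv", index=False)
            io.write_report_json(metrics, out / "metrics.json")
        return result

    # CASE III: train the four cascade classifiers
    fm = feature_matrix_for_case("III", cfg)
    pmi = np.asarray(fm.meta["pmi_days"], dtype=float)
    node_rows = {
        "A1": np.ones(len(fm), dtype=bool),
        "A2": pmi <= 3,
        "A3": (pmi >= 2) & (pmi <= 3),
        "A4": pmi >= 4,
    }
    retained_by_node = {
        "A1": None,
        "A2": tuple(s for s in range(1, 33) if s != 4),
        "A3": tuple(s for s in range(1, 33) if s not in (4, 12, 17)),
        "A4": None,
    }
    metrics: dict = {"config_hash": h, "seed": cfg.seed}
    model_paths: dict = {}
    models = {}
    for node, row_mask in node_rows.items():
        rows_idx = np.flatnonzero(row_mask)
        sub = fm.take(rows_idx)
        labels = np.array([pmi_bin_for_day(d, node) for d in pmi[rows_idx]])
        sub = FeatureMatrix(X=sub.X, y=pd.Series(labels, index=sub.X.index), groups=sub.groups, meta=sub.meta)
        retained = retained_by_node[node]
        if retained is not None:
            sub = sub.subset_sensors(retained)
        # observation-level split: one pig contributes measurements to both
        # classes of a node (e.g. day 1 and day 3), so sample-level
        # stratification is ill-defined for the PMI classifiers
        plan = SplitPlan(level="observation", test_frac=cfg.test_frac, k_folds=cfg.k_folds, seed=cfg.seed)
        tr, te = stratified_split(sub, plan)
        train, test = sub.take(tr), sub.take(te)
        model = fit_ensemble(train.X, train.y.to_numpy(), cfg.hp, classes=tuple(decision._NODE_LABELS[node]))
        rep = compute_metrics(model.predict(test.X), test.y.to_numpy(), decision._NODE_LABELS[node][1])
        metrics[f"{node}_test_accuracy"] = rep.accuracy
        metrics[f"{node}_test_error_rate"] = 100.0 - rep.accuracy
        models[node] = CascadeNode(model=model, retained_sensors=retained)
        if out is not None:
            p = io.save_model(model, out / f"model_{node}.json")
            model_paths[node] = p
    if out is not None:
        io.write_report_json(metrics, out / "metrics.json")
    return CaseResult(
        "III", cfg, h, None, None, None, metrics, out, model_paths, models
    )
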