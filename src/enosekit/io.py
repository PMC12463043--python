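"""File formats: long-form measurement CSV, feature CSV, model/report JSON.

Measurements travel as long-format CSV (sample_id, class_label, pmi_days,
sensor_id, time_s, voltage, measurement_id) with a JSON sidecar holding
the acquisition metadata (dt, exposure_end, sensor ids) and any design
seeds. Floats are written at full round-trip precision, so write-read is
the identity to well below 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .boosting import EnsembleModel
from .features import CATALOG_VERSION, FEATURE_NAMES_85, FeatureMatrix
from .simulate import Measurement

__all__ = [
    "write_measurements_csv",
    "read_measurements_csv",
    "write_feature_matrix_csv",
    "read_feature_matrix_csv",
    "save_model",
    "load_model",
    "write_report_json",
]

_MEAS_COLUMNS = [
    "measurement_id",
    "sample_id",
    "class_label",
    "pmi_days",
    "sensor_id",
    "time_s",
    "voltage",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_measurements_csv(
    measurements: Sequence[Measurement], path, extra_meta: dict | None = None
) -> Path:
    """Write measurements in long format plus a JSON metadata sidecar."""
    path = Path(path)
    frames = []
    meta_rows = {}
    for m in measurements:
        n = m.n_time
        for i, sid in enumerate(m.sensor_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "measurement_id": m.measurement_id,
                        "sample_id": m.sample_id,
                        "class_label": m.class_label,
                        "pmi_days": np.nan if m.pmi_days is None else m.pmi_days,
                        "sensor_id": sid,
                        "time_s": m.time,
                        "voltage": m.signals[i],
                    }
                )
            )
        meta_rows[m.measurement_id] = {
            "dt": m.dt,
            "exposure_end": m.exposure_end,
            "sensor_ids": list(m.sensor_ids),
        }
    pd.concat(frames).to_csv(path, index=False)
    sidecar = {"measurements": meta_rows, **(extra_meta or {})}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_measurements_csv(path) -> list[Measurement]:
    """Read a long-format measurement CSV (sidecar optional)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MEAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV {path.name} lacks columns: {missing}")
    sidecar = {}
    sp = _sidecar_path(path)
    if sp.exists():
        sidecar = json.loads(sp.read_text()).get("measurements", {})
    out = []
    for mid, g in df.groupby("measurement_id", sort=True):
        sensor_ids = tuple(int(s) for s in sorted(g["sensor_id"].unique()))
        times = np.sort(g["time_s"].unique())
        sig = np.empty((len(sensor_ids), len(times)))
        for i, sid in enumerate(sensor_ids):
            rows = g[g["sensor_id"] == sid].sort_values("time_s")
            if len(rows) != len(times):
                raise ValueError(
                    f"measurement {mid!r}: sensor {sid} has {len(rows)} rows, "
                    f"expected {len(times)}"
                )
            sig[i] = rows["voltage"].to_numpy()
        meta = sidecar.get(str(mid), {})
        dt = float(meta.get("dt", times[1] - times[0] if len(times) > 1 else 0.1))
        pmi = g["pmi_days"].iloc[0]
        out.append(
            Measurement(
                sample_id=str(g["sample_id"].iloc[0]),
                class_label=str(g["class_label"].iloc[0]),
                signals=sig,
                sensor_ids=sensor_ids,
                pmi_days=None if pd.isna(pmi) else float(pmi),
                dt=dt,
                exposure_end=float(meta.get("exposure_end", len(times) * dt / 2)),
                measurement_id=str(mid),
            )
        )
    return out


def write_feature_matrix_csv(fm: FeatureMatrix, path) -> Path:
    path = Path(path)
    df = fm.X.reset_index()
    df.insert(2, "class_label", fm.y.to_numpy())
    df.insert(3, "sample_id", fm.groups.to_numpy())
    df.to_csv(path, index=False)
    _sidecar_path(path).write_text(json.dumps(fm.meta, indent=1, default=str))
    return path


def read_feature_matrix_csv(path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    required = ["measurement_id", "sensor_id", "class_label", "sample_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV {path.name} lacks columns: {missing}")
    feat_cols = [c for c in FEATURE_NAMES_85 if c in df.columns]
    if len(feat_cols) != len(FEATURE_NAMES_85):
        absent = sorted(set(FEATURE_NAMES_85) - set(feat_cols))
        raise ValueError(f"feature CSV {path.name} lacks features: {absent[:5]}")
    idx = pd.MultiIndex.from_frame(
        df[["measurement_id", "sensor_id"]], names=["measurement_id", "sensor_id"]
    )
    meta = {}
    sp = _sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    return FeatureMatrix(
        X=pd.DataFrame(df[feat_cols].to_numpy(), index=idx, columns=feat_cols),
        y=pd.Series(df["class_label"].to_numpy(), index=idx, name="class_label"),
        groups=pd.Series(df["sample_id"].to_numpy(), index=idx, name="sample_id"),
        meta=meta,
    )


def save_model(model: EnsembleModel, path) -> Path:
    """Persist an ensemble as versioned JSON, stamping the catalog version."""
    path = Path(path)
    d = model.to_dict()
    d["training_meta"].setdefault("catalog_version", CATALOG_VERSION)
    path.write_text(json.dumps(d))
    return path


def load_model(path, expect_catalog: str | None = CATALOG_VERSION) -> EnsembleModel:
    """Load a model JSON; fails loudly on a catalog-version mismatch."""
    path = Path(path)
    d = json.loads(path.read_text())
    got = d.get("training_meta", {}).get("catalog_version")
    if expect_catalog is not None and got != expect_catalog:
        raise ValueError(
            f"model {path.name} was trained with feature catalog {got!r}, "
            f"expected {expect_catalog!r}"
        )
    return EnsembleModel.from_dict(d)


def write_report_json(report: dict, path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return str(o)

    path.write_text(json.dumps(report, indent=1, default=default))
    return path
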