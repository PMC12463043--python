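"""Sensor ranking by inter-class similarity coefficients and ablation.

For a two-class measurement set, each sensor's *similarity coefficient*
is the mean Pearson correlation over all inter-class signal pairs drawn
from that sensor. Because correlation is invariant to the pairing order,
the mean over the full class-A x class-B pair grid equals the inner
product of the class-mean standardized signals, which is what is
computed here (an O(n) identity verified against brute-force pair
enumeration in the tests). Low or negative coefficients mark
discriminative sensors; coefficients near 1 mark sensors that respond
the same way to both classes.

The ablation schedule removes, one per step, the sensor with the highest
remaining coefficient (the least useful), yielding 32 nested sensor
subsets for iterative retraining.

An inter-sensor correlation ranking (mean absolute correlation of each
sensor with every other sensor, the independence-seeking alternative) is
provided for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_SG_ORDER, DEFAULT_SG_WINDOW, range_normalize, savitzky_golay
from .simulate import Measurement

__all__ = [
    "SimilarityRanking",
    "AblationSchedule",
    "pearson",
    "similarity_coefficients",
    "intersensor_correlation_ranking",
    "ablation_schedule",
]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; constant inputs contribute 0 by convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    # constancy judged on the range: the sd of an exactly-flat array can be
    # a nonzero rounding residual
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0
    sx = x.std()
    sy = y.std()
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


@dataclass(frozen=True)
class SimilarityRanking:
    """Per-sensor inter-class similarity coefficients and derived order."""

    sensor_ids: tuple[int, ...]
    coefficients: np.ndarray  # aligned with sensor_ids, values in [-1, 1]
    order: tuple[int, ...]  # ascending coefficient: most discriminative first
    n_pairs: int
    signal_rep: str = "smoothed_norm"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        if self.coefficients.shape != (len(self.sensor_ids),):
            raise ValueError("coefficients must align with sensor_ids")
        if np.any(np.abs(self.coefficients) > 1 + 1e-12):
            raise ValueError("coefficients must lie in [-1, 1]")
        if sorted(self.order) != sorted(self.sensor_ids):
            raise ValueError("order must be a permutation of sensor_ids")

    def coefficient(self, sensor_id: int) -> float:
        return float(self.coefficients[self.sensor_ids.index(sensor_id)])

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table: sensor_id, coefficient, rank (1 = most useful)."""
        rank = {s: i + 1 for i, s in enumerate(self.order)}
        return pd.DataFrame(
            {
                "sensor_id": list(self.sensor_ids),
                "coefficient": self.coefficients,
                "rank": [rank[s] for s in self.sensor_ids],
            }
        )


def _standardized_signals(
    measurements: Sequence[Measurement],
    signal_rep: str,
    sg_window: int,
    sg_order: int,
) -> np.ndarray:
    """Per-signal z-scored traces, (n_meas, n_sensors, n_time).

    Constant traces become zero vectors so any pair involving them
    contributes 0 to the average (dead-sensor convention).
    """
    blocks = []
    for m in measurements:
        sig = m.signals
        if signal_rep == "smoothed_norm":
            sig = range_normalize(savitzky_golay(sig, sg_window, sg_order))
        elif signal_rep != "raw":
            raise ValueError("signal_rep must be 'smoothed_norm' or 'raw'")
        mu = sig.mean(axis=1, keepdims=True)
        sd = sig.std(axis=1, keepdims=True)
        flat = np.ptp(sig, axis=1, keepdims=True) == 0.0
        z = np.where(
            flat | (sd == 0), 0.0, (sig - mu) / np.where(sd > 0, sd, 1.0)
        )
        blocks.append(z)
    return np.stack(blocks)


def similarity_coefficients(
    measurements: Sequence[Measurement],
    signal_rep: str = "smoothed_norm",
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
) -> SimilarityRanking:
    """Mean inter-class Pearson correlation per sensor.

    Requires exactly two classes among the measurements. Symmetric under
    class swap. Ties in the derived order break toward the lower sensor id.
    """
    labels = [m.class_label for m in measurements]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    sensor_ids = measurements[0].sensor_ids
    n_time = measurements[0].n_time
    for m in measurements:
        if m.sensor_ids != sensor_ids or m.n_time != n_time:
            raise ValueError("measurements must share sensor ids and length")
    z = _standardized_signals(measurements, signal_rep, sg_window, sg_order)
    mask_a = np.array([lab == classes[0] for lab in labels])
    za = z[mask_a].mean(axis=0)  # (n_sensors, n_time)
    zb = z[~mask_a].mean(axis=0)
    coeffs = np.clip((za * zb).sum(axis=1) / n_time, -1.0, 1.0)
    order = tuple(
        int(sensor_ids[i])
        for i in sorted(range(len(sensor_ids)), key=lambda i: (coeffs[i], sensor_ids[i]))
    )
    return SimilarityRanking(
        sensor_ids=tuple(sensor_ids),
        coefficients=coeffs,
        order=order,
        n_pairs=int(mask_a.sum() * (~mask_a).sum()),
        signal_rep=signal_rep,
    )


def intersensor_correlation_ranking(
    measurements: Sequence[Measurement],
    signal_rep: str = "smoothed_norm",
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
) -> pd.Series:
    """Mean absolute Pearson correlation of each sensor with the others.

    The independence-seeking alternative ranking, reported for comparison
    with the inter-class similarity method; not used for ablation.
    """
    sensor_ids = measurements[0].sensor_ids
    n = len(sensor_ids)
    if n < 2:
        raise ValueError("need at least 2 sensors")
    z = _standardized_signals(measurements, signal_rep, sg_window, sg_order)
    n_time = z.shape[2]
    acc = np.zeros((n, n))
    for zm in z:
        acc += np.abs(zm @ zm.T / n_time)
    acc /= len(measurements)
    np.fill_diagonal(acc, 0.0)
    scores = acc.sum(axis=1) / (n - 1)
    return pd.Series(scores, index=list(sensor_ids), name="mean_abs_correlation")


@dataclass(frozen=True)
class AblationSchedule:
    """Nested sensor subsets: step 1 = all sensors, each step drops one."""

    steps: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        sizes = [len(s) for s in self.steps]
        if sizes != list(range(sizes[0], 0, -1)):
            raise ValueError("step sizes must decrease by exactly 1 down to 1")
        for a, b in zip(self.steps, self.steps[1:]):
            if not set(b) <= set(a):
                raise ValueError("each step must be a subset of the previous")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def removal_order(self) -> tuple[int, ...]:
        """Sensors in the order they are removed."""
        out = []
        for a, b in zip(self.steps, self.steps[1:]):
            out.extend(set(a) - set(b))
        out.extend(self.steps[-1])
        return tuple(out)


def ablation_schedule(ranking: SimilarityRanking) -> AblationSchedule:
    """Schedule removing the highest-coefficient sensor at each step.

    Step k retains the n - k + 1 lowest-coefficient sensors; coefficient
    ties break so the lower sensor id is removed last. Subsets are listed
    in ascending sensor-id order.
    """
    n = len(ranking.order)
    steps = tuple(tuple(sorted(ranking.order[: n - k])) for k in range(n))
    return AblationSchedule(steps=steps)
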