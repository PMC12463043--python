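"""Signal conditioning: Savitzky-Golay smoothing and range normalization.

The pipeline keeps three views of every sensor trace: the raw voltage
signal (amplitude differences are class-informative and must survive),
the smoothed-normalized signal (Savitzky-Golay filtered, then scaled to
[0, 1]) used for most features and for sensor-similarity ranking, and a
range-normalized raw signal used only for the signal-to-noise feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .simulate import Measurement

__all__ = [
    "ProcessedSignal",
    "savitzky_golay",
    "range_normalize",
    "preprocess_measurement",
    "DEFAULT_SG_WINDOW",
    "DEFAULT_SG_ORDER",
]

DEFAULT_SG_WINDOW = 51  # samples (5.1 s at 10 Hz)
DEFAULT_SG_ORDER = 3


@dataclass(frozen=True)
class ProcessedSignal:
    """Raw trace plus its two unit-scaled companions.

    ``degenerate`` flags a constant input (dead sensor): both normalized
    views are all-zero by convention so downstream features stay finite.
    """

    raw: np.ndarray
    smoothed_norm: np.ndarray
    normalized: np.ndarray
    dt: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        n = self.raw.shape[0]
        if self.smoothed_norm.shape[0] != n or self.normalized.shape[0] != n:
            raise ValueError("all series must have equal length")


def savitzky_golay(
    signal: np.ndarray, window: int = DEFAULT_SG_WINDOW, order: int = DEFAULT_SG_ORDER
) -> np.ndarray:
    """Least-squares local polynomial smoothing, length-preserving.

    Edges are handled by fitting the boundary polynomial to the first/last
    window and evaluating it over the edge samples (scipy ``mode="interp"``).
    Accepts a 1-D series or a 2-D (n_signals, n_time) block.
    """
    signal = np.asarray(signal, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be < window")
    if window > signal.shape[-1]:
        raise ValueError("window exceeds signal length")
    return savgol_filter(signal, window, order, axis=-1, mode="interp")


def range_normalize(signal: np.ndarray) -> np.ndarray:
    """Map a series to [0, 1] by (x - min) / (max - min).

    A constant series maps to all zeros (degenerate-range convention),
    keeping dead-sensor features finite.
    """
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    lo = signal.min(axis=-1, keepdims=True)
    span = signal.max(axis=-1, keepdims=True) - lo
    safe = np.where(span > 0, span, 1.0)
    out = (signal - lo) / safe
    return np.where(span > 0, out, 0.0)


def preprocess_measurement(
    m: Measurement,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
) -> dict[int, ProcessedSignal]:
    """Smooth-then-normalize every sensor trace of a measurement.

    Returns a mapping sensor_id -> ProcessedSignal. The raw trace is never
    mutated; smoothing and normalization happen on copies.
    """
    raw = m.signals
    smooth = savitzky_golay(raw, sg_window, sg_order)
    sn = range_normalize(smooth)
    norm = range_normalize(raw)
    span = raw.max(axis=1) - raw.min(axis=1)
    # a flat raw trace may leave rounding residue after filtering, which
    # range normalization would amplify; pin degenerate sensors to zero
    sn = np.where(span[:, None] > 0, sn, 0.0)
    norm = np.where(span[:, None] > 0, norm, 0.0)
    return {
        sid: ProcessedSignal(
            raw=raw[i],
            smoothed_norm=sn[i],
            normalized=norm[i],
            dt=m.dt,
            degenerate=bool(span[i] == 0),
        )
        for i, sid in enumerate(m.sensor_ids)
    }
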