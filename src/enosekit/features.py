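"""Engineered feature extraction for e-nose sensor signals.

Each sensor trace is summarized by 85 named features: a 42-descriptor
catalog applied to the raw voltage signal (suffix ``_raw``) and to the
smoothed-normalized signal (suffix ``_sn``), plus one signal-to-noise
ratio (``SNR``) comparing the range-normalized raw signal with its
smoothed counterpart. The catalog covers statistical moments and
quantiles, time-domain shape/derivative descriptors (including the
Hjorth parameters and peak counting) and frequency-domain descriptors
of the power spectrum.

Degenerate inputs (constant signals from dead sensors) map to defined
sentinel values, never NaN, so tree ensembles always receive a complete
matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal import find_peaks
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .preprocess import (
    DEFAULT_SG_ORDER,
    DEFAULT_SG_WINDOW,
    ProcessedSignal,
    preprocess_measurement,
)
from .simulate import Measurement

__all__ = [
    "FeatureCatalog",
    "DEFAULT_CATALOG",
    "CATALOG_VERSION",
    "FEATURE_NAMES_85",
    "FeatureMatrix",
    "hjorth_parameters",
    "snr_feature",
    "peak_count",
    "extract_features",
    "features_for_measurement",
    "build_feature_matrix",
    "DEFAULT_PROMINENCE_FRAC",
]

DEFAULT_PROMINENCE_FRAC = 0.05
SNR_CAP_DB = 120.0

CATALOG_VERSION = "enosekit-42-v1"

#: 42 base descriptor names, frozen order. Statistical, then time-domain,
#: then frequency-domain.
_BASE_NAMES: tuple[str, ...] = (
    # statistical (16)
    "mean",
    "median",
    "std",
    "variance",
    "skewness",
    "kurtosis",
    "min",
    "max",
    "range",
    "iqr",
    "p05",
    "p95",
    "rms",
    "energy",
    "auc",
    "hist_entropy",
    # time-domain (18)
    "t_max",
    "t_min",
    "rise_time",
    "baseline_slope",
    "response_amp",
    "crest_factor",
    "line_length",
    "max1stDeriv",
    "min1stDeriv",
    "mean_abs_deriv",
    "max2ndDeriv",
    "min2ndDeriv",
    "zero_cross_deriv",
    "autocorr_lag1",
    "activity",
    "mobility",
    "complexity",
    "PeakCount",
    # frequency-domain (8)
    "dominant_freq",
    "spectral_centroid",
    "spectral_bandwidth",
    "spectral_entropy",
    "spectral_rolloff85",
    "bp_low",
    "bp_mid",
    "bp_high",
)

_DEFINITIONS: dict[str, str] = {
    "mean": "mean(x)",
    "median": "median(x)",
    "std": "population standard deviation of x",
    "variance": "population variance of x",
    "skewness": "Fisher skewness of x (0 for constant)",
    "kurtosis": "excess kurtosis of x (0 for constant)",
    "min": "min(x)",
    "max": "max(x)",
    "range": "max(x) - min(x)",
    "iqr": "75th - 25th percentile of x",
    "p05": "5th percentile of x",
    "p95": "95th percentile of x",
    "rms": "sqrt(mean(x^2))",
    "energy": "sum(x^2)",
    "auc": "trapezoidal integral of x over time",
    "hist_entropy": "Shannon entropy (bits) of a 16-bin amplitude histogram",
    "t_max": "time of the maximum, argmax(x)*dt",
    "t_min": "time of the minimum, argmin(x)*dt",
    "rise_time": "time from first 10% crossing to next 90% crossing of range",
    "baseline_slope": "least-squares slope over the first 10% of samples",
    "response_amp": "max(x) - mean of the first 10% of samples",
    "crest_factor": "max|x| / rms(x) (0 if rms = 0)",
    "line_length": "sum |x[i+1] - x[i]|",
    "max1stDeriv": "max of the forward-difference derivative diff(x)/dt",
    "min1stDeriv": "min of diff(x)/dt",
    "mean_abs_deriv": "mean |diff(x)/dt|",
    "max2ndDeriv": "max of the second forward difference diff(x,2)/dt^2",
    "min2ndDeriv": "min of diff(x,2)/dt^2",
    "zero_cross_deriv": "sign changes of the derivative (zeros ignored)",
    "autocorr_lag1": "Pearson correlation of x[:-1] with x[1:] (0 if undefined)",
    "activity": "Hjorth activity: population variance of x",
    "mobility": "Hjorth mobility: sqrt(var(x')/var(x)), x' = diff(x)/dt",
    "complexity": "Hjorth complexity: mobility(x')/mobility(x)",
    "PeakCount": "local maxima with prominence >= frac*(max-min), frac=0.05",
    "dominant_freq": "frequency of the largest non-DC power-spectrum bin (Hz)",
    "spectral_centroid": "power-weighted mean frequency (Hz)",
    "spectral_bandwidth": "power-weighted sd of frequency around the centroid (Hz)",
    "spectral_entropy": "normalized Shannon entropy of the power spectrum in [0,1]",
    "spectral_rolloff85": "lowest frequency below which 85% of power lies (Hz)",
    "bp_low": "relative power below 0.1 Hz",
    "bp_mid": "relative power in [0.1, 1) Hz",
    "bp_high": "relative power at/above 1 Hz",
}


@dataclass(frozen=True)
class FeatureCatalog:
    """Versioned, ordered base-descriptor catalog."""

    names: tuple[str, ...] = _BASE_NAMES
    definitions: dict[str, str] = field(default_factory=lambda: dict(_DEFINITIONS))
    version: str = CATALOG_VERSION

    def __post_init__(self) -> None:
        if len(self.names) != 42:
            raise ValueError("catalog must contain exactly 42 base features")
        if len(set(self.names)) != 42:
            raise ValueError("catalog names must be unique")

    @property
    def feature_names(self) -> list[str]:
        """The 85 full feature names, frozen order."""
        return (
            [f"{n}_raw" for n in self.names]
            + [f"{n}_sn" for n in self.names]
            + ["SNR"]
        )

    def to_json_dict(self) -> dict:
        return {
            "version": self.version,
            "names": list(self.names),
            "definitions": self.definitions,
        }


DEFAULT_CATALOG = FeatureCatalog()
FEATURE_NAMES_85: list[str] = DEFAULT_CATALOG.feature_names


# ---------------------------------------------------------------------------
# Individual descriptors exposed for direct use / oracle testing


def hjorth_parameters(signal: np.ndarray, dt: float) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity of a series.

    activity = var(x); mobility = sqrt(var(x')/var(x));
    complexity = mobility(x')/mobility(x), with x' the forward-difference
    derivative diff(x)/dt. Degenerate (constant) inputs return (0, 0, 0).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    v0 = float(np.var(x))
    if v0 == 0.0:
        return 0.0, 0.0, 0.0
    d1 = np.diff(x) / dt
    v1 = float(np.var(d1))
    mob = math.sqrt(v1 / v0)
    if v1 == 0.0:
        return v0, mob, 0.0
    d2 = np.diff(d1) / dt
    v2 = float(np.var(d2))
    comp = math.sqrt(v2 / v1) / mob if mob > 0 else 0.0
    return v0, mob, comp


def snr_feature(normalized: np.ndarray, smoothed_norm: np.ndarray) -> float:
    """Signal-to-noise ratio in dB between the two normalized views.

    10*log10(var(smoothed)/var(residual)), residual = normalized - smoothed.
    Capped at +/-120 dB; a zero residual yields +120, a zero smoothed
    variance -120.
    """
    normalized = np.asarray(normalized, dtype=float)
    smoothed_norm = np.asarray(smoothed_norm, dtype=float)
    if normalized.shape != smoothed_norm.shape:
        raise ValueError("series must have equal length")
    v_sig = float(np.var(smoothed_norm))
    v_res = float(np.var(normalized - smoothed_norm))
    if v_res == 0.0:
        return SNR_CAP_DB
    if v_sig == 0.0:
        return -SNR_CAP_DB
    return float(np.clip(10.0 * math.log10(v_sig / v_res), -SNR_CAP_DB, SNR_CAP_DB))


def peak_count(
    signal: np.ndarray, prominence_frac: float = DEFAULT_PROMINENCE_FRAC
) -> int:
    """Count local maxima with prominence >= prominence_frac * signal range."""
    if not (0.0 <= prominence_frac <= 1.0):
        raise ValueError("prominence_frac must lie in [0, 1]")
    x = np.asarray(signal, dtype=float)
    span = float(x.max() - x.min()) if x.size else 0.0
    if span == 0.0:
        return 0
    peaks, _ = find_peaks(x, prominence=prominence_frac * span if prominence_frac > 0 else None)
    return int(peaks.size)


# ---------------------------------------------------------------------------
# Vectorized 42-descriptor block


def _base_features_block(
    X: np.ndarray, dt: float, prominence_frac: float
) -> np.ndarray:
    """Compute the 42 base descriptors for a (n_signals, n_time) block."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    S, T = X.shape
    t = np.arange(T) * dt
    out = np.zeros((S, 42))
    col = {n: i for i, n in enumerate(_BASE_NAMES)}

    mean = X.mean(axis=1)
    mn = X.min(axis=1)
    mx = X.max(axis=1)
    span = mx - mn
    var = X.var(axis=1)
    out[:, col["mean"]] = mean
    out[:, col["median"]] = np.median(X, axis=1)
    out[:, col["std"]] = np.sqrt(var)
    out[:, col["variance"]] = var
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows trigger scipy's precision-loss warning; they map to the
        # 0.0 sentinel anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        out[:, col["skewness"]] = np.nan_to_num(_skew(X, axis=1, bias=True))
        out[:, col["kurtosis"]] = np.nan_to_num(_kurtosis(X, axis=1, bias=True))
    out[:, col["min"]] = mn
    out[:, col["max"]] = mx
    out[:, col["range"]] = span
    q = np.percentile(X, [5, 25, 75, 95], axis=1)
    out[:, col["p05"]] = q[0]
    out[:, col["iqr"]] = q[2] - q[1]
    out[:, col["p95"]] = q[3]
    rms = np.sqrt(np.mean(X**2, axis=1))
    out[:, col["rms"]] = rms
    out[:, col["energy"]] = np.sum(X**2, axis=1)
    out[:, col["auc"]] = np.trapezoid(X, dx=dt, axis=1)
    for i in range(S):
        if span[i] > 0:
            h, _ = np.histogram(X[i], bins=16, range=(mn[i], mx[i]))
            p = h[h > 0] / T
            out[i, col["hist_entropy"]] = float(-(p * np.log2(p)).sum())

    # time-domain
    out[:, col["t_max"]] = np.argmax(X, axis=1) * dt
    out[:, col["t_min"]] = np.argmin(X, axis=1) * dt
    n0 = max(2, T // 10)
    head = X[:, :n0]
    th = t[:n0]
    th_c = th - th.mean()
    out[:, col["baseline_slope"]] = (head - head.mean(axis=1, keepdims=True)) @ th_c / (
        th_c @ th_c
    )
    out[:, col["response_amp"]] = mx - head.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cf = np.abs(X).max(axis=1) / rms
    out[:, col["crest_factor"]] = np.nan_to_num(cf)
    # rise time: first 10% crossing, then next 90% crossing
    lo10 = mn + 0.1 * span
    lo90 = mn + 0.9 * span
    idx = np.arange(T)
    i10 = np.argmax(X >= lo10[:, None], axis=1)
    mask90 = (X >= lo90[:, None]) & (idx[None, :] >= i10[:, None])
    i90 = np.argmax(mask90, axis=1)
    out[:, col["rise_time"]] = np.where(span > 0, (i90 - i10) * dt, 0.0)

    d1 = np.diff(X, axis=1) / dt
    d2 = np.diff(d1, axis=1) / dt
    out[:, col["line_length"]] = np.abs(np.diff(X, axis=1)).sum(axis=1)
    out[:, col["max1stDeriv"]] = d1.max(axis=1)
    out[:, col["min1stDeriv"]] = d1.min(axis=1)
    out[:, col["mean_abs_deriv"]] = np.abs(d1).mean(axis=1)
    out[:, col["max2ndDeriv"]] = d2.max(axis=1)
    out[:, col["min2ndDeriv"]] = d2.min(axis=1)
    for i in range(S):
        s = np.sign(d1[i])
        s = s[s != 0]
        out[i, col["zero_cross_deriv"]] = float(np.count_nonzero(s[1:] != s[:-1]))
    a, b = X[:, :-1], X[:, 1:]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = (ac * bc).sum(axis=1) / denom
    out[:, col["autocorr_lag1"]] = np.where(denom > 0, np.nan_to_num(r1), 0.0)
    v1 = d1.var(axis=1)
    v2 = d2.var(axis=1)
    out[:, col["activity"]] = var
    with np.errstate(invalid="ignore", divide="ignore"):
        mob = np.sqrt(v1 / var)
        mob_d = np.sqrt(v2 / v1)
    mob = np.where(var > 0, np.nan_to_num(mob), 0.0)
    out[:, col["mobility"]] = mob
    comp = np.where((v1 > 0) & (mob > 0), np.nan_to_num(mob_d) / np.where(mob > 0, mob, 1.0), 0.0)
    out[:, col["complexity"]] = comp
    for i in range(S):
        out[i, col["PeakCount"]] = peak_count(X[i], prominence_frac)

    # frequency-domain (on the mean-removed signal; DC bin excluded)
    Z = rfft(X - mean[:, None], axis=1)
    P = np.abs(Z) ** 2
    P[:, 0] = 0.0
    freqs = rfftfreq(T, dt)
    tot = P.sum(axis=1)
    safe_tot = np.where(tot > 0, tot, 1.0)
    dom = freqs[np.argmax(P[:, 1:], axis=1) + 1] if P.shape[1] > 1 else np.zeros(S)
    out[:, col["dominant_freq"]] = np.where(tot > 0, dom, 0.0)
    centroid = (P * freqs[None, :]).sum(axis=1) / safe_tot
    out[:, col["spectral_centroid"]] = np.where(tot > 0, centroid, 0.0)
    bw = np.sqrt((P * (freqs[None, :] - centroid[:, None]) ** 2).sum(axis=1) / safe_tot)
    out[:, col["spectral_bandwidth"]] = np.where(tot > 0, bw, 0.0)
    pn = P / safe_tot[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        ent = -np.where(pn > 0, pn * np.log(pn), 0.0).sum(axis=1)
    n_bins = max(P.shape[1] - 1, 2)
    out[:, col["spectral_entropy"]] = np.where(tot > 0, ent / math.log(n_bins), 0.0)
    cum = np.cumsum(P, axis=1)
    roll_idx = np.argmax(cum >= 0.85 * tot[:, None], axis=1)
    out[:, col["spectral_rolloff85"]] = np.where(tot > 0, freqs[roll_idx], 0.0)
    out[:, col["bp_low"]] = np.where(tot > 0, P[:, freqs < 0.1].sum(axis=1) / safe_tot, 0.0)
    out[:, col["bp_mid"]] = np.where(
        tot > 0, P[:, (freqs >= 0.1) & (freqs < 1.0)].sum(axis=1) / safe_tot, 0.0
    )
    out[:, col["bp_high"]] = np.where(tot > 0, P[:, freqs >= 1.0].sum(axis=1) / safe_tot, 0.0)
    return out


def extract_features(
    p: ProcessedSignal,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    catalog: FeatureCatalog = DEFAULT_CATALOG,
) -> pd.Series:
    """85-feature vector for one processed sensor signal."""
    raw = _base_features_block(p.raw, p.dt, prominence_frac)[0]
    sn = _base_features_block(p.smoothed_norm, p.dt, prominence_frac)[0]
    snr = snr_feature(p.normalized, p.smoothed_norm)
    values = np.concatenate([raw, sn, [snr]])
    return pd.Series(values, index=catalog.feature_names, name="features")


# ---------------------------------------------------------------------------
# Feature matrices


@dataclass
class FeatureMatrix:
    """Observation-level feature table with labels and group keys.

    One row per (measurement, sensor). ``groups`` carries the sample_id of
    each row so splits can be made leakage-safe at the sample level.
    """

    X: pd.DataFrame  # index: (measurement_id, sensor_id), columns: 85 features
    y: pd.Series  # class label per row
    groups: pd.Series  # sample_id per row
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y, groups must be aligned")
        if self.X.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_sensors(self, retained: Iterable[int]) -> "FeatureMatrix":
        """Rows restricted to a retained-sensor set (ablation step)."""
        retained = set(int(s) for s in retained)
        keep = self.X.index.get_level_values("sensor_id").isin(retained)
        return FeatureMatrix(
            X=self.X.loc[keep],
            y=self.y.loc[keep],
            groups=self.groups.loc[keep],
            meta={**self.meta, "retained_sensors": sorted(retained)},
        )

    def take(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X.iloc[rows],
            y=self.y.iloc[rows],
            groups=self.groups.iloc[rows],
            meta=dict(self.meta),
        )


def features_for_measurement(
    m: Measurement,
    retained_sensors: Sequence[int] | None = None,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    catalog: FeatureCatalog = DEFAULT_CATALOG,
) -> pd.DataFrame:
    """Feature rows (one per retained sensor) for a single measurement.

    Descriptor blocks are computed for all sensors at once; rows are
    ordered by sensor id.
    """
    if retained_sensors is None:
        retained = list(m.sensor_ids)
    else:
        retained = [int(s) for s in retained_sensors]
        unknown = set(retained) - set(m.sensor_ids)
        if unknown:
            raise ValueError(f"unknown sensor ids: {sorted(unknown)}")
    retained = sorted(retained)
    pos = [m.sensor_ids.index(s) for s in retained]

    raw = m.signals[pos]
    smooth = _sg_block(raw, sg_window, sg_order)
    from .preprocess import range_normalize  # local to avoid cycle at import time

    sn = range_normalize(smooth)
    norm = range_normalize(raw)
    span = raw.max(axis=1) - raw.min(axis=1)
    sn = np.where(span[:, None] > 0, sn, 0.0)  # degenerate-sensor convention
    norm = np.where(span[:, None] > 0, norm, 0.0)
    f_raw = _base_features_block(raw, m.dt, prominence_frac)
    f_sn = _base_features_block(sn, m.dt, prominence_frac)
    v_sig = sn.var(axis=1)
    v_res = (norm - sn).var(axis=1)
    with np.errstate(divide="ignore"):
        snr = 10.0 * np.log10(np.where(v_res > 0, v_sig, 1.0) / np.where(v_res > 0, v_res, 1.0))
    snr = np.where(v_res == 0, SNR_CAP_DB, np.where(v_sig == 0, -SNR_CAP_DB, snr))
    snr = np.clip(snr, -SNR_CAP_DB, SNR_CAP_DB)
    values = np.hstack([f_raw, f_sn, snr[:, None]])
    index = pd.MultiIndex.from_arrays(
        [[m.measurement_id] * len(retained), retained],
        names=["measurement_id", "sensor_id"],
    )
    return pd.DataFrame(values, index=index, columns=catalog.feature_names)


def _sg_block(raw: np.ndarray, window: int, order: int) -> np.ndarray:
    from .preprocess import savitzky_golay

    return savitzky_golay(raw, window, order)


def build_feature_matrix(
    measurements: Iterable[Measurement],
    retained_sensors: Sequence[int] | None = None,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    catalog: FeatureCatalog = DEFAULT_CATALOG,
) -> FeatureMatrix:
    """Assemble the observation-level matrix for a set of measurements.

    Row order is deterministic: sorted by (sample_id, measurement_id,
    sensor_id). Row count equals n_measurements x n_retained_sensors.
    """
    frames: list[pd.DataFrame] = []
    labels: list[str] = []
    sample_ids: list[str] = []
    n_meas = 0
    for m in measurements:
        n_meas += 1
        f = features_for_measurement(
            m, retained_sensors, sg_window, sg_order, prominence_frac, catalog
        )
        frames.append(f)
        labels.extend([m.class_label] * len(f))
        sample_ids.extend([m.sample_id] * len(f))
    if not frames:
        raise ValueError("no measurements supplied")
    X = pd.concat(frames)
    y = pd.Series(labels, index=X.index, name="class_label")
    groups = pd.Series(sample_ids, index=X.index, name="sample_id")
    order = np.lexsort(
        (
            X.index.get_level_values("sensor_id"),
            X.index.get_level_values("measurement_id"),
            groups.to_numpy(),
        )
    )
    X = X.iloc[order]
    y = y.iloc[order]
    groups = groups.iloc[order]
    meta = {
        "catalog_version": catalog.version,
        "sg_window": sg_window,
        "sg_order": sg_order,
        "prominence_frac": prominence_frac,
        "n_measurements": n_meas,
    }
    return FeatureMatrix(X=X, y=y, groups=groups, meta=meta)
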