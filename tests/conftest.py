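"""Shared fixtures: small sensor arrays and short-record measurement sets.

Fixture data are generated programmatically; "short" records (600 points
at 10 Hz with a 5 s onset and 30 s exposure end) keep the suite fast
while preserving the baseline/response/recovery structure of a full
10-minute acquisition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from enosekit.features import FeatureMatrix
from enosekit.simulate import (
    NoiseModel,
    SensorArraySpec,
    make_discriminability_scenario,
    simulate_measurement,
)

SHORT = dict(n_time=600, dt=0.1, t0=5.0, exposure_end=30.0)


@pytest.fixture(scope="session")
def small_array() -> SensorArraySpec:
    return SensorArraySpec.default(8)


@pytest.fixture(scope="session")
def toy_measurements(small_array):
    """5 + 5 short measurements of an 8-sensor array, strong class effect."""
    sc = make_discriminability_scenario(
        n_dead_sensors=1, effect_size=1.0, seed=3, array=small_array,
        labels=("antemortem", "postmortem"),
    )
    noise = NoiseModel(sigma_obs=0.01, sample_effect_sd=0.1, sensor_jitter_sd=0.03)
    meas = []
    for k, (label, profile) in enumerate(
        [("antemortem", sc.profile_a), ("postmortem", sc.profile_b)]
    ):
        for i in range(5):
            meas.append(
                simulate_measurement(
                    small_array,
                    profile,
                    noise,
                    sample_effect=1.0,
                    seed=100 * k + i,
                    sample_id=f"{label}_{i:03d}",
                    **SHORT,
                )
            )
    return meas


@pytest.fixture(scope="session")
def toy_fm(toy_measurements):
    from enosekit.features import build_feature_matrix

    return build_feature_matrix(toy_measurements, sg_window=21, sg_order=3)


@pytest.fixture(scope="session")
def full_measurement():
    """One full-scale acquisition (32 sensors x 6000 points)."""
    sc = make_discriminability_scenario(2, 1.0, seed=0)
    return simulate_measurement(
        SensorArraySpec.default(), sc.profile_a, NoiseModel(), seed=7
    )


def fake_feature_matrix(
    n_samples_per_class: int,
    n_sensors: int,
    n_features: int = 3,
    effect: float = 0.0,
    seed: int = 0,
    classes: tuple[str, str] = ("neg", "pos"),
) -> FeatureMatrix:
    """Synthetic stand-in feature matrix (random features, optional shift)."""
    rng = np.random.default_rng(seed)
    rows, labels, samples = [], [], []
    for c_idx, c in enumerate(classes):
        for i in range(n_samples_per_class):
            sid = f"{c}_{i:03d}"
            for s in range(1, n_sensors + 1):
                rows.append((sid, s))
                labels.append(c)
                samples.append(sid)
    idx = pd.MultiIndex.from_tuples(rows, names=["measurement_id", "sensor_id"])
    X = rng.normal(size=(len(rows), n_features))
    X[np.array(labels) == classes[1], 0] += effect
    Xdf = pd.DataFrame(X, index=idx, columns=[f"f{i}" for i in range(n_features)])
    return FeatureMatrix(
        X=Xdf,
        y=pd.Series(labels, index=idx, name="class_label"),
        groups=pd.Series(samples, index=idx, name="sample_id"),
    )
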