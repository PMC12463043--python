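"""Generator contracts: shapes, determinism, design totals, moment recovery."""

from __future__ import annotations

import numpy as np
import pytest

from enosekit.simulate import (
    CaseDesign,
    ClassProfile,
    NoiseModel,
    SensorArraySpec,
    case1_design,
    case2_design,
    case3_design,
    case3_profile_builder,
    make_discriminability_scenario,
    mean_curves,
    simulate_case,
    simulate_measurement,
)

from conftest import SHORT


def test_default_array_structure():
    a = SensorArraySpec.default()
    assert a.n_sensors == 32
    assert a.sensor_ids == tuple(range(1, 33))
    banks = {}
    for s in a.sensor_ids:
        banks.setdefault(a.bank_of[s], []).append(s)
    assert sorted(banks) == [1, 2, 3, 4]
    assert all(len(v) == 8 for v in banks.values())


def test_default_measurement_shape_and_time_axis():
    a = SensorArraySpec.default()
    sc = make_discriminability_scenario(0, 1.0, seed=1)
    m = simulate_measurement(a, sc.profile_a, NoiseModel(), seed=0)
    assert m.signals.shape == (32, 6000)
    assert np.all(np.isfinite(m.signals))
    assert m.time[0] == 0.0
    assert np.isclose(m.time[-1], 599.9)


def test_zero_response_is_constant_baseline(small_array):
    n = small_array.n_sensors
    profile = ClassProfile(
        "null",
        amplitude=np.zeros(n),
        tau_rise=np.full(n, 20.0),
        tau_recover=np.full(n, 40.0),
        baseline=np.linspace(0.1, 0.4, n),
        drift_slope=np.zeros(n),
    )
    m = simulate_measurement(
        small_array, profile, NoiseModel(0.0, 0.0, 0.0), seed=0, **SHORT
    )
    assert np.allclose(m.signals, profile.baseline[:, None])


def test_seed_determinism(small_array):
    sc = make_discriminability_scenario(1, 1.0, seed=2, array=small_array)
    kw = dict(sample_effect=1.1, **SHORT)
    m1 = simulate_measurement(small_array, sc.profile_a, NoiseModel(), seed=5, **kw)
    m2 = simulate_measurement(small_array, sc.profile_a, NoiseModel(), seed=5, **kw)
    m3 = simulate_measurement(small_array, sc.profile_a, NoiseModel(), seed=6, **kw)
    assert np.array_equal(m1.signals, m2.signals)
    assert not np.array_equal(m1.signals, m3.signals)


def test_invalid_parameters_rejected(small_array):
    n = small_array.n_sensors
    with pytest.raises(ValueError):
        ClassProfile(
            "bad",
            amplitude=np.full(n, np.nan),
            tau_rise=np.ones(n),
            tau_recover=np.ones(n),
            baseline=np.zeros(n),
            drift_slope=np.zeros(n),
        )
    with pytest.raises(ValueError):
        ClassProfile(
            "bad",
            amplitude=np.ones(n),
            tau_rise=np.zeros(n),  # tau must be > 0
            tau_recover=np.ones(n),
            baseline=np.zeros(n),
            drift_slope=np.zeros(n),
        )
    with pytest.raises(ValueError):
        NoiseModel(sigma_obs=-0.1)


def test_moment_recovery(small_array):
    """Empirical mean over replicates tracks the analytic mean curve."""
    sc = make_discriminability_scenario(0, 1.0, seed=4, array=small_array)
    profile = sc.profile_a.__class__(
        class_label="a",
        amplitude=sc.profile_a.amplitude,
        tau_rise=sc.profile_a.tau_rise,
        tau_recover=sc.profile_a.tau_recover,
        baseline=sc.profile_a.baseline,
        drift_slope=np.zeros(small_array.n_sensors),
    )
    sigma = 0.02
    noise = NoiseModel(sigma_obs=sigma, sample_effect_sd=0.0, sensor_jitter_sd=0.0)
    n_rep = 60
    acc = np.zeros((small_array.n_sensors, SHORT["n_time"]))
    for r in range(n_rep):
        acc += simulate_measurement(
            small_array, profile, noise, seed=1000 + r, **SHORT
        ).signals
    emp = acc / n_rep
    # independent analytic mean: baseline + A*(1-exp(-(t-t0)/tr)) then decay
    t = np.arange(SHORT["n_time"]) * SHORT["dt"]
    t0, te = SHORT["t0"], SHORT["exposure_end"]
    ana = np.empty_like(emp)
    for i in range(small_array.n_sensors):
        tr, tc = profile.tau_rise[i], profile.tau_recover[i]
        rise = 1 - np.exp(-np.clip(t - t0, 0, None) / tr)
        plat = 1 - np.exp(-(te - t0) / tr)
        resp = np.where(t <= te, rise, plat * np.exp(-np.clip(t - te, 0, None) / tc))
        ana[i] = profile.baseline[i] + profile.amplitude[i] * resp
    se = sigma / np.sqrt(n_rep)
    dev = np.abs(emp - ana)
    # pointwise 3-se coverage for nearly all of the 4800 grid points; the
    # global maximum of iid noise means exceeds 3 se with high probability,
    # so it gets a wider 5-se band
    assert (dev < 3 * se).mean() > 0.95
    assert dev.max() < 5 * se
    assert np.allclose(ana, mean_curves(profile, 1.0, **{
        "n_time": SHORT["n_time"], "dt": SHORT["dt"],
        "t0": SHORT["t0"], "exposure_end": SHORT["exposure_end"]}))


@pytest.mark.parametrize(
    "design_fn, n_meas, per_class",
    [(case1_design, 196, 98), (case2_design, 140, 70)],
)
def test_two_class_case_totals(design_fn, n_meas, per_class, small_array):
    design = design_fn(seed=1)
    labels = [lab for lab, _ in design.groups]
    sc = make_discriminability_scenario(
        1, 1.0, seed=0, array=small_array, labels=tuple(labels)
    )
    meas = simulate_case(design, sc.profiles, NoiseModel(), array=small_array, **SHORT)
    assert len(meas) == n_meas
    for lab in labels:
        assert sum(1 for m in meas if m.class_label == lab) == per_class
    assert len({m.sample_id for m in meas}) == n_meas  # one measurement each


def test_case3_totals_and_shared_sample_effects(small_array):
    design = case3_design(seed=2)
    profiles = case3_profile_builder(seed=2, array=small_array)
    noise = NoiseModel(sigma_obs=0.0, sample_effect_sd=0.3, sensor_jitter_sd=0.0)
    meas = simulate_case(design, profiles, noise, array=small_array, **SHORT)
    assert len(meas) == 488
    assert len({m.sample_id for m in meas}) == 50
    early = [m for m in meas if m.pmi_days <= 3]
    late = [m for m in meas if m.pmi_days >= 4]
    assert len(early) == 377 and len(late) == 111
    assert all(4 <= m.pmi_days <= 11 or 18 <= m.pmi_days <= 32 for m in late)
    # same sample, same day, zero obs-noise -> identical signals (shared effect)
    by_key = {}
    for m in meas:
        by_key.setdefault((m.sample_id, m.pmi_days), []).append(m)
    repeats = [v for v in by_key.values() if len(v) > 1]
    assert repeats, "schedule should include same-day repeats"
    a, b = repeats[0][0], repeats[0][1]
    assert np.array_equal(a.signals, b.signals)
    # distinct samples on the same day differ (different sample effects)
    day1 = [m for m in meas if m.pmi_days == 1]
    assert not np.array_equal(day1[0].signals, day1[-1].signals)


def test_design_invariants_enforced():
    with pytest.raises(ValueError):
        CaseDesign("I", (("a", 10), ("b", 10))).validate()
    with pytest.raises(ValueError):
        CaseDesign("III", (("pig", 50),), repeated_schedule=None).validate()


def test_scenario_construction(small_array):
    null = make_discriminability_scenario(0, 0.0, seed=0, array=small_array)
    for f in ("amplitude", "tau_rise", "tau_recover", "baseline", "drift_slope"):
        assert np.array_equal(getattr(null.profile_a, f), getattr(null.profile_b, f))

    sc = make_discriminability_scenario(2, 1.5, seed=0, array=small_array)
    assert len(sc.dead_sensors) == 2
    same = [
        s
        for i, s in enumerate(small_array.sensor_ids)
        if np.isclose(sc.profile_a.amplitude[i], sc.profile_b.amplitude[i])
        and np.isclose(sc.profile_a.tau_rise[i], sc.profile_b.tau_rise[i])
    ]
    assert set(same) == set(sc.dead_sensors)
    with pytest.raises(ValueError):
        make_discriminability_scenario(33, 1.0, seed=0)
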