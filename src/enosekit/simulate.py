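"""Synthetic e-nose sensor-array measurement generator.

Emulates a 32-element metal-oxide-semiconductor (MOS) gas-sensor array
sampling at 10 Hz for 10 minutes: a baseline phase, a saturating
exponential response while the sample's volatile organic compounds (VOCs)
reach the sensors, and an exponential recovery after sample removal.
Class structure is injected through per-sensor response profiles; realism
knobs cover additive measurement noise, multiplicative per-sample random
effects (shared across repeated measurements of the same sample) and
per-measurement sensor jitter.

Three study designs are provided: a two-class balanced design of 98 + 98
measurements (postmortem vs antemortem human biosamples), a 70 + 70
design (animal vs human), and a repeated-measures postmortem-interval
(PMI) design of 488 measurements on 50 pig-meat samples over 32 days
(377 in days 1-3, 111 in days 4-32).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "SensorArraySpec",
    "ClassProfile",
    "NoiseModel",
    "Measurement",
    "CaseDesign",
    "Scenario",
    "simulate_measurement",
    "simulate_case",
    "iter_case_measurements",
    "make_discriminability_scenario",
    "case1_design",
    "case2_design",
    "case3_design",
    "case3_profile",
    "case3_profile_builder",
    "DEFAULT_N_TIME",
    "DEFAULT_DT",
    "DEFAULT_T0",
    "DEFAULT_EXPOSURE_END",
]

DEFAULT_N_TIME = 6000
DEFAULT_DT = 0.1
DEFAULT_T0 = 30.0
DEFAULT_EXPOSURE_END = 300.0

#: Figaro TGS2X sensor models populating the four banks (8 models x 4 banks).
TGS_MODELS = (
    "TGS2600",
    "TGS2602",
    "TGS2603",
    "TGS2610",
    "TGS2611C",
    "TGS2611E",
    "TGS2620",
    "TGS2444",
)

#: Deterministic order in which sensors are designated non-discriminative
#: in constructed scenarios (weak sensors first, then the rest by id).
DEAD_SENSOR_PREFERENCE = (17, 25, 4, 12, 20, 28) + tuple(
    i for i in range(1, 33) if i not in {17, 25, 4, 12, 20, 28}
)


def _child_seed(master: int, *counters: int) -> np.random.SeedSequence:
    """Counter-based seed fan-out: reproducible independent streams."""
    return np.random.SeedSequence(entropy=int(master), spawn_key=tuple(counters))


@dataclass(frozen=True)
class SensorArraySpec:
    """Geometry of the sensor array: ids, bank assignment and sensor model."""

    sensor_ids: tuple[int, ...]
    bank_of: Mapping[int, int]
    model_of: Mapping[int, str]

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_ids)

    def __post_init__(self) -> None:
        if len(set(self.sensor_ids)) != len(self.sensor_ids):
            raise ValueError("sensor_ids must be unique")

    @classmethod
    def default(cls, n_sensors: int = 32) -> "SensorArraySpec":
        """The standard array: 32 TGS2X sensors in four banks of eight."""
        ids = tuple(range(1, n_sensors + 1))
        bank = {i: (i - 1) // 8 + 1 for i in ids}
        model = {i: TGS_MODELS[(i - 1) % len(TGS_MODELS)] for i in ids}
        return cls(sensor_ids=ids, bank_of=bank, model_of=model)


@dataclass(frozen=True)
class ClassProfile:
    """Per-sensor mean-response parameters for one sample class.

    The mean curve of sensor ``s`` at time ``t`` is

        baseline_s + drift_slope_s * t + eff * amplitude_s * r_s(t)

    with ``r_s`` a first-order saturating rise toward 1 during exposure
    and an exponential recovery afterwards, and ``eff`` the multiplicative
    sample/jitter effect.
    """

    class_label: str
    amplitude: np.ndarray  # V
    tau_rise: np.ndarray  # s
    tau_recover: np.ndarray  # s
    baseline: np.ndarray  # V
    drift_slope: np.ndarray  # V/s

    def __post_init__(self) -> None:
        for name in ("amplitude", "tau_rise", "tau_recover", "baseline", "drift_slope"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.amplitude.shape[0]
        for name in ("tau_rise", "tau_recover", "baseline", "drift_slope"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have the same length as amplitude")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite")
        for name in ("tau_rise", "tau_recover"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"{name} must be finite and > 0")
        for name in ("baseline", "drift_slope"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} must be finite")

    @property
    def n_sensors(self) -> int:
        return self.amplitude.shape[0]


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic components of a measurement.

    sigma_obs
        sd of additive Gaussian observation noise, volts.
    sample_effect_sd
        sd (log scale) of the log-normal per-sample amplitude multiplier,
        drawn once per sample and shared across its repeated measurements.
    sensor_jitter_sd
        sd (log scale) of the log-normal per-measurement, per-sensor
        amplitude jitter.
    """

    sigma_obs: float = 0.01
    sample_effect_sd: float = 0.15
    sensor_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("sigma_obs", "sample_effect_sd", "sensor_jitter_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass
class Measurement:
    """One acquisition: aligned voltage-time signals for every sensor."""

    sample_id: str
    class_label: str
    signals: np.ndarray  # (n_sensors, n_time), volts
    sensor_ids: tuple[int, ...]
    pmi_days: float | None = None
    dt: float = DEFAULT_DT
    exposure_end: float = DEFAULT_EXPOSURE_END
    measurement_id: str | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (n_sensors, n_time) array")
        if self.signals.shape[0] != len(self.sensor_ids):
            raise ValueError("signals row count must match sensor_ids")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must contain no missing/non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0 < self.exposure_end < self.signals.shape[1] * self.dt):
            raise ValueError("exposure_end must lie inside the record")
        if self.measurement_id is None:
            self.measurement_id = self.sample_id

    @property
    def n_sensors(self) -> int:
        return self.signals.shape[0]

    @property
    def n_time(self) -> int:
        return self.signals.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_time) * self.dt

    def signal(self, sensor_id: int) -> np.ndarray:
        return self.signals[self.sensor_ids.index(sensor_id)]


def _response_curve(
    t: np.ndarray, t0: float, t_end: float, tau_rise: np.ndarray, tau_recover: np.ndarray
) -> np.ndarray:
    """Unit response: 0 before onset, saturating rise, exponential recovery."""
    tr = tau_rise[:, None]
    tc = tau_recover[:, None]
    rise = 1.0 - np.exp(-np.clip(t - t0, 0.0, None)[None, :] / tr)
    plateau = 1.0 - np.exp(-(t_end - t0) / tr)
    decay = plateau * np.exp(-np.clip(t - t_end, 0.0, None)[None, :] / tc)
    return np.where(t[None, :] <= t_end, rise, decay)


def mean_curves(
    profile: ClassProfile,
    eff: float | np.ndarray = 1.0,
    n_time: int = DEFAULT_N_TIME,
    dt: float = DEFAULT_DT,
    t0: float = DEFAULT_T0,
    exposure_end: float = DEFAULT_EXPOSURE_END,
) -> np.ndarray:
    """Noise-free mean signals (n_sensors, n_time) for a class profile."""
    t = np.arange(n_time) * dt
    resp = _response_curve(t, t0, exposure_end, profile.tau_rise, profile.tau_recover)
    eff = np.broadcast_to(np.asarray(eff, dtype=float), (profile.n_sensors,))
    return (
        profile.baseline[:, None]
        + profile.drift_slope[:, None] * t[None, :]
        + (eff * profile.amplitude)[:, None] * resp
    )


def simulate_measurement(
    array: SensorArraySpec,
    profile: ClassProfile,
    noise: NoiseModel,
    sample_effect: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    *,
    sample_id: str = "S000",
    measurement_id: str | None = None,
    pmi_days: float | None = None,
    n_time: int = DEFAULT_N_TIME,
    dt: float = DEFAULT_DT,
    t0: float = DEFAULT_T0,
    exposure_end: float = DEFAULT_EXPOSURE_END,
) -> Measurement:
    """Simulate one acquisition; deterministic given the seed.

    The exposure window runs from ``t0`` to ``exposure_end`` (defaults 30 s
    and 300 s: baseline, then VOC detection for the first five minutes,
    then recovery after sample removal).
    """
    if profile.n_sensors != array.n_sensors:
        raise ValueError("profile length does not match the sensor array")
    if not math.isfinite(sample_effect):
        raise ValueError("sample_effect must be finite")
    if not (0.0 < t0 < exposure_end < n_time * dt):
        raise ValueError("need 0 < t0 < exposure_end < record length")
    rng = np.random.default_rng(seed)
    jitter = np.exp(rng.normal(0.0, noise.sensor_jitter_sd, array.n_sensors))
    eff = sample_effect * jitter
    signals = mean_curves(profile, eff, n_time, dt, t0, exposure_end)
    if noise.sigma_obs > 0:
        signals = signals + rng.normal(0.0, noise.sigma_obs, signals.shape)
    return Measurement(
        sample_id=sample_id,
        class_label=profile.class_label,
        signals=signals,
        sensor_ids=array.sensor_ids,
        pmi_days=pmi_days,
        dt=dt,
        exposure_end=exposure_end,
        measurement_id=measurement_id,
    )


# ---------------------------------------------------------------------------
# Study designs


@dataclass(frozen=True)
class CaseDesign:
    """A study design: which classes, how many samples, repeat schedule."""

    case_id: str  # "I", "II" or "III"
    groups: tuple[tuple[str, int], ...]
    repeated_schedule: Mapping[str, tuple[float, ...]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.case_id not in {"I", "II", "III"}:
            raise ValueError("case_id must be one of I, II, III")
        counts = [n for _, n in self.groups]
        if self.case_id == "I" and counts != [98, 98]:
            raise ValueError("CASE I requires 98 + 98 samples")
        if self.case_id == "II" and counts != [70, 70]:
            raise ValueError("CASE II requires 70 + 70 samples")
        if self.case_id == "III":
            if self.repeated_schedule is None:
                raise ValueError("CASE III requires a repeated-measurement schedule")
            if len(self.repeated_schedule) != 50:
                raise ValueError("CASE III requires 50 distinct samples")
            days = [d for ds in self.repeated_schedule.values() for d in ds]
            n_early = sum(1 for d in days if d <= 3)
            n_late = sum(1 for d in days if d >= 4)
            if len(days) != 488 or n_early != 377 or n_late != 111:
                raise ValueError(
                    "CASE III requires 488 measurements: 377 in days 1-3, 111 in days 4-32"
                )

    @property
    def n_measurements(self) -> int:
        if self.repeated_schedule is not None:
            return sum(len(d) for d in self.repeated_schedule.values())
        return sum(n for _, n in self.groups)


def case1_design(seed: int = 0) -> CaseDesign:
    """98 postmortem vs 98 antemortem human biosamples, one measurement each."""
    d = CaseDesign("I", (("postmortem", 98), ("antemortem", 98)), seed=seed)
    d.validate()
    return d


def case2_design(seed: int = 0) -> CaseDesign:
    """70 animal vs 70 human biosamples, one measurement each."""
    d = CaseDesign("II", (("animal", 70), ("human", 70)), seed=seed)
    d.validate()
    return d


#: Days eligible for late-PMI measurements; days 12-17 are unmeasured,
#: matching the two late decision bins (4-11 and 18-32 days).
LATE_DAYS = tuple(range(4, 12)) + tuple(range(18, 33))


def case3_schedule() -> dict[str, tuple[float, ...]]:
    """Deterministic repeat schedule: 50 pigs, 377 early + 111 late measurements.

    Early phase (days 1-3): every sample is measured 7 times, the first 27
    samples an 8th time, cycling through days 1, 2, 3. Late phase: 111
    measurements dealt round-robin over samples and the late-day grid.
    """
    schedule: dict[str, list[float]] = {f"pig_{i:02d}": [] for i in range(50)}
    ids = sorted(schedule)
    for i, sid in enumerate(ids):
        n_rep = 8 if i < 27 else 7
        for r in range(n_rep):
            schedule[sid].append(float((i + r) % 3 + 1))
    for j in range(111):
        sid = ids[j % 50]
        schedule[sid].append(float(LATE_DAYS[j % len(LATE_DAYS)]))
    return {sid: tuple(sorted(days)) for sid, days in schedule.items()}


def case3_design(seed: int = 0) -> CaseDesign:
    """488 repeated measurements on 50 pig-meat samples over 32 days."""
    d = CaseDesign(
        "III", (("pig_meat", 50),), repeated_schedule=case3_schedule(), seed=seed
    )
    d.validate()
    return d


ProfileFor = Callable[[str, float | None], ClassProfile]


def _as_profile_fn(
    profiles: Mapping[str, ClassProfile] | ProfileFor,
) -> ProfileFor:
    if callable(profiles):
        return profiles

    def fn(label: str, pmi_days: float | None) -> ClassProfile:
        try:
            return profiles[label]
        except KeyError:
            raise ValueError(f"no profile for class {label!r}") from None

    return fn


def iter_case_measurements(
    design: CaseDesign,
    profiles: Mapping[str, ClassProfile] | ProfileFor,
    noise: NoiseModel,
    array: SensorArraySpec | None = None,
    **measure_kwargs,
):
    """Yield the design's measurements one at a time (memory-friendly).

    The per-sample amplitude effect is drawn once per sample and reused for
    all of that sample's repeated measurements; every measurement gets an
    independent, counter-derived noise stream, so output is reproducible
    regardless of consumption order.
    """
    design.validate()
    array = array or SensorArraySpec.default()
    profile_fn = _as_profile_fn(profiles)
    sample_counter = 0
    for g_idx, (label, n_samples) in enumerate(design.groups):
        for i in range(n_samples):
            sid = f"{label}_{i:03d}" if design.case_id != "III" else f"pig_{i:02d}"
            eff_rng = np.random.default_rng(
                _child_seed(design.seed, 0, sample_counter)
            )
            eff = float(np.exp(eff_rng.normal(0.0, noise.sample_effect_sd)))
            if design.case_id == "III":
                days = design.repeated_schedule[sid]
                for rep, day in enumerate(days):
                    yield simulate_measurement(
                        array,
                        profile_fn(label, day),
                        noise,
                        sample_effect=eff,
                        seed=_child_seed(design.seed, 1, sample_counter, rep),
                        sample_id=sid,
                        measurement_id=f"{sid}_d{int(day):02d}_r{rep}",
                        pmi_days=day,
                        **measure_kwargs,
                    )
            else:
                yield simulate_measurement(
                    array,
                    profile_fn(label, None),
                    noise,
                    sample_effect=eff,
                    seed=_child_seed(design.seed, 1, sample_counter, 0),
                    sample_id=sid,
                    measurement_id=sid,
                    **measure_kwargs,
                )
            sample_counter += 1


def simulate_case(
    design: CaseDesign,
    profiles: Mapping[str, ClassProfile] | ProfileFor,
    noise: NoiseModel,
    array: SensorArraySpec | None = None,
    **measure_kwargs,
) -> list[Measurement]:
    """Materialize all measurements of a study design as a list."""
    return list(iter_case_measurements(design, profiles, noise, array, **measure_kwargs))


# ---------------------------------------------------------------------------
# Scenario construction


@dataclass(frozen=True)
class Scenario:
    """A two-class discriminability scenario with designated dead sensors."""

    profile_a: ClassProfile
    profile_b: ClassProfile
    dead_sensors: tuple[int, ...]

    @property
    def profiles(self) -> dict[str, ClassProfile]:
        return {
            self.profile_a.class_label: self.profile_a,
            self.profile_b.class_label: self.profile_b,
        }


def _base_profile(
    rng: np.random.Generator, label: str, n_sensors: int
) -> ClassProfile:
    return ClassProfile(
        class_label=label,
        amplitude=rng.uniform(0.3, 1.5, n_sensors),
        tau_rise=rng.uniform(15.0, 60.0, n_sensors),
        tau_recover=rng.uniform(30.0, 120.0, n_sensors),
        baseline=rng.uniform(0.1, 0.5, n_sensors),
        drift_slope=rng.uniform(-2e-5, 2e-5, n_sensors),
    )


def make_discriminability_scenario(
    n_dead_sensors: int = 0,
    effect_size: float = 1.0,
    seed: int = 0,
    array: SensorArraySpec | None = None,
    labels: tuple[str, str] = ("class_a", "class_b"),
) -> Scenario:
    """Build a pair of class profiles with a controlled class contrast.

    ``n_dead_sensors`` sensors (designated deterministically, weakest-known
    ids first) are given identical parameters in both classes and so carry
    no class information. The remaining sensors differ in amplitude and
    time constants by an ``effect_size``-scaled amount; every third live
    sensor additionally responds with opposite sign in class B, mimicking
    cross-reactive MOS sensors whose resistance moves the other way.
    """
    array = array or SensorArraySpec.default()
    n = array.n_sensors
    if not (0 <= n_dead_sensors <= n):
        raise ValueError("n_dead_sensors out of range")
    if not math.isfinite(effect_size) or effect_size < 0:
        raise ValueError("effect_size must be finite and >= 0")
    dead = tuple(s for s in DEAD_SENSOR_PREFERENCE if s in array.sensor_ids)[
        :n_dead_sensors
    ]
    rng = np.random.default_rng(_child_seed(seed, 99))
    a = _base_profile(rng, labels[0], n)

    d_amp = rng.uniform(0.3, 1.0, n)
    d_rise = rng.uniform(0.3, 1.0, n)
    d_rec = rng.uniform(0.3, 1.0, n)
    alive_idx = [i for i, s in enumerate(array.sensor_ids) if s not in dead]
    flip = np.ones(n)
    for k, i in enumerate(alive_idx):
        if k % 3 == 2:
            flip[i] = -1.0
    mask = np.zeros(n)
    mask[alive_idx] = 1.0
    e = effect_size * mask
    amplitude_b = a.amplitude * (1.0 + e * d_amp)
    amplitude_b = np.where((mask > 0) & (flip < 0) & (e > 0), -amplitude_b, amplitude_b)
    b = ClassProfile(
        class_label=labels[1],
        amplitude=amplitude_b,
        tau_rise=a.tau_rise * (1.0 + e * d_rise),
        tau_recover=a.tau_recover * (1.0 + e * d_rec),
        baseline=a.baseline.copy(),
        drift_slope=a.drift_slope.copy(),
    )
    return Scenario(profile_a=a, profile_b=b, dead_sensors=dead)


# ---------------------------------------------------------------------------
# CASE III day-dependent profiles


def case3_profile(
    day: float,
    seed: int = 0,
    day_effect: float = 1.0,
    array: SensorArraySpec | None = None,
    label: str = "pig_meat",
) -> ClassProfile:
    """Decomposition-stage response profile for a given postmortem day.

    Two sensor sub-populations evolve differently with PMI: "late-rising"
    sensors follow a saturating growth ``1 - exp(-day/6)`` (putrefaction
    volatiles accumulating over weeks) while "early-peaking" sensors follow
    a Gaussian bump centred on day 2 (esters/aldehydes of early breakdown).
    Rise time constants lengthen slowly with day. ``day_effect`` scales the
    strength of all day-dependent terms.
    """
    array = array or SensorArraySpec.default()
    n = array.n_sensors
    rng = np.random.default_rng(_child_seed(seed, 3))
    base = _base_profile(rng, label, n)
    w_late = rng.uniform(0.2, 1.0, n)
    w_early = rng.uniform(0.2, 1.0, n)
    is_early = (np.arange(n) % 3 == 0).astype(float)  # every third sensor
    f_late = 1.0 - math.exp(-day / 6.0)
    f_early = math.exp(-((day - 2.0) ** 2) / 8.0)
    mod = 1.0 + day_effect * (
        (1.0 - is_early) * w_late * (2.0 * f_late - 1.0)
        + is_early * w_early * (2.0 * f_early - 1.0)
    )
    return replace(
        base,
        amplitude=base.amplitude * mod,
        tau_rise=np.clip(base.tau_rise * (1.0 + 0.03 * day_effect * day), 1.0, 240.0),
    )


def case3_profile_builder(
    seed: int = 0, day_effect: float = 1.0, array: SensorArraySpec | None = None
) -> ProfileFor:
    """Profile callback for :func:`simulate_case` with CASE III designs."""

    def fn(label: str, pmi_days: float | None) -> ClassProfile:
        if pmi_days is None:
            raise ValueError("CASE III profiles require pmi_days")
        return case3_profile(pmi_days, seed=seed, day_effect=day_effect, array=array, label=label)

    return fn
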