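"""Majority voting (90% rule) and the four-classifier PMI cascade."""

from __future__ import annotations

import math

import numpy as np
import pytest

from enosekit.boosting import EnsembleModel, Hyperparameters, fit_gentleboost
from enosekit.decision import (
    A1_LABELS,
    A2_LABELS,
    A3_LABELS,
    A4_LABELS,
    INCONCLUSIVE,
    CascadeNode,
    cascade_pmi,
    classify_sample,
    majority_vote,
    pmi_bin_for_day,
)
from enosekit.features import FEATURE_NAMES_85, build_feature_matrix
from enosekit.simulate import (
    NoiseModel,
    SensorArraySpec,
    case3_profile,
    simulate_measurement,
)
from enosekit.boosting import TreeStruct

from conftest import SHORT


def test_majority_vote_hand_examples():
    votes = {s: "postmortem" for s in range(1, 31)}
    votes.update({31: "antemortem", 32: "antemortem"})
    v = majority_vote(votes)  # 30/32 = 93.75%
    assert v.final == "postmortem" and np.isclose(v.agreement_frac, 30 / 32)

    votes28 = {s: ("pm" if s <= 28 else "am") for s in range(1, 33)}
    assert majority_vote(votes28).final == INCONCLUSIVE  # 87.5%

    votes29 = {s: ("pm" if s <= 29 else "am") for s in range(1, 33)}
    assert majority_vote(votes29).final == "pm"  # ceiling(0.9*32) = 29

    with pytest.raises(ValueError):
        majority_vote({})


def test_majority_vote_exhaustive_vs_bruteforce():
    """All n in 1..32 and all vote splits against the ceiling rule."""
    for n in range(1, 33):
        required = math.ceil(0.9 * n)
        for k in range(n + 1):  # k votes for class "a"
            votes = {i: ("a" if i <= k else "b") for i in range(1, n + 1)}
            v = majority_vote(votes)
            top = max(k, n - k)
            if top >= required:
                expected = "a" if k >= n - k else "b"
            else:
                expected = INCONCLUSIVE
            assert v.final == expected, (n, k)
            assert np.isclose(v.agreement_frac, top / n)
            # flipping one vote changes the outcome only across the boundary
            if 0 < k:
                prev = majority_vote(
                    {i: ("a" if i <= k - 1 else "b") for i in range(1, n + 1)}
                )
                if prev.final != v.final:
                    assert top == required or max(k - 1, n - k + 1) == required


def _constant_model(classes: tuple[str, str], which: int) -> EnsembleModel:
    """A single-leaf ensemble always voting classes[which]."""
    leaf = TreeStruct(
        children_left=np.array([-1]),
        children_right=np.array([-1]),
        feature=np.array([-1]),
        threshold=np.array([0.0]),
        value=np.array([1.0 if which == 1 else -1.0]),
        feature_gain=np.zeros(85),
    )
    return EnsembleModel(
        hp=Hyperparameters(n_cycles=1),
        learners=[leaf],
        learner_weights=np.array([1.0]),
        classes=classes,
        feature_names=list(FEATURE_NAMES_85),
        training_meta={},
    )


@pytest.fixture(scope="module")
def short_measurement():
    sc_array = SensorArraySpec.default(8)
    profile = case3_profile(2.0, seed=5, array=sc_array)
    return simulate_measurement(
        sc_array, profile, NoiseModel(), seed=2, sample_id="pig_demo",
        pmi_days=2.0, **SHORT,
    )


def test_classify_sample_votes_and_determinism(short_measurement):
    model = _constant_model(("x", "y"), 1)
    v = classify_sample(short_measurement, model, retained_sensors=[1, 2, 3, 4, 5, 6],
                        sg_window=21, sg_order=3)
    assert v.n_sensors == 6
    assert v.final == "y" and v.agreement_frac == 1.0
    v2 = classify_sample(short_measurement, model, retained_sensors=[1, 2, 3, 4, 5, 6],
                         sg_window=21, sg_order=3)
    assert v == v2
    with pytest.raises(ValueError):
        classify_sample(short_measurement, model, retained_sensors=[99])


def _cascade_stubs(a1: int, a2: int = 0, a3: int = 0, a4: int = 0):
    return {
        "A1": _constant_model(A1_LABELS, a1),
        "A2": _constant_model(A2_LABELS, a2),
        "A3": _constant_model(A3_LABELS, a3),
        "A4": _constant_model(A4_LABELS, a4),
    }


def test_cascade_routing(short_measurement):
    kw = dict(sg_window=21, sg_order=3)
    # early -> day 1
    r = cascade_pmi(short_measurement, _cascade_stubs(0, 0), **kw)
    assert r.nodes_visited == ("A1", "A2") and r.final_bin == "1 day"
    # early -> 2-3 days -> day 3
    r = cascade_pmi(short_measurement, _cascade_stubs(0, 1, 1), **kw)
    assert r.nodes_visited == ("A1", "A2", "A3") and r.final_bin == "3 days"
    # late -> 18-32 days
    r = cascade_pmi(short_measurement, _cascade_stubs(1, a4=1), **kw)
    assert r.nodes_visited == ("A1", "A4") and r.final_bin == "18-32 days"


def test_cascade_validation(short_measurement):
    stubs = _cascade_stubs(0)
    del stubs["A3"]
    with pytest.raises(ValueError, match="missing classifier A3"):
        cascade_pmi(short_measurement, stubs, sg_window=21, sg_order=3)
    bad = _cascade_stubs(0)
    bad["A2"] = _constant_model(("foo", "bar"), 0)
    with pytest.raises(ValueError, match="classifier A2"):
        cascade_pmi(short_measurement, bad, sg_window=21, sg_order=3)


def test_cascade_inconclusive_propagates(short_measurement):
    """An A1 model whose votes split by sensor terminates the cascade."""
    feats = build_feature_matrix([short_measurement], sg_window=21, sg_order=3)
    col = "mean_raw"
    thr = float(np.median(feats.X[col]))
    split_tree = TreeStruct(
        children_left=np.array([1, -1, -1]),
        children_right=np.array([2, -1, -1]),
        feature=np.array([FEATURE_NAMES_85.index(col), -1, -1]),
        threshold=np.array([thr, 0.0, 0.0]),
        value=np.array([0.0, -1.0, 1.0]),
        feature_gain=np.zeros(85),
    )
    a1 = EnsembleModel(
        hp=Hyperparameters(n_cycles=1),
        learners=[split_tree],
        learner_weights=np.array([1.0]),
        classes=A1_LABELS,
        feature_names=list(FEATURE_NAMES_85),
    )
    stubs = _cascade_stubs(0)
    stubs["A1"] = a1
    r = cascade_pmi(short_measurement, stubs, sg_window=21, sg_order=3)
    assert r.final_bin == INCONCLUSIVE
    assert r.nodes_visited == ("A1",)
    assert not r.path[0][1].conclusive


def test_pmi_bin_labels():
    assert pmi_bin_for_day(1, "A1") == A1_LABELS[0]
    assert pmi_bin_for_day(20, "A1") == A1_LABELS[1]
    assert pmi_bin_for_day(1, "A2") == "1 day"
    assert pmi_bin_for_day(3, "A3") == "3 days"
    assert pmi_bin_for_day(5, "A4") == "4-11 days"
    with pytest.raises(ValueError):
        pmi_bin_for_day(14, "A4")  # unmeasured gap days


def test_cascade_end_to_end_with_trained_models():
    """Day-2 and day-20 samples route to the right bins with strong day effects."""
    array = SensorArraySpec.default()
    noise = NoiseModel(sigma_obs=0.01, sample_effect_sd=0.05, sensor_jitter_sd=0.02)
    day_effect = 2.0
    days_train = [1, 2, 3, 5, 8, 20, 28]
    meas = []
    for d in days_train:
        for i in range(6):
            meas.append(
                simulate_measurement(
                    array,
                    case3_profile(d, seed=5, day_effect=day_effect, array=array),
                    noise,
                    sample_effect=float(np.exp(np.random.default_rng(100 * d + i).normal(0, 0.05))),
                    seed=10_000 + 100 * d + i,
                    sample_id=f"pig_{d:02d}_{i}",
                    pmi_days=float(d),
                    **SHORT,
                )
            )
    fm = build_feature_matrix(meas, sg_window=21, sg_order=3)
    day_of = {m.measurement_id: m.pmi_days for m in meas}
    pmi = np.array(
        [day_of[mid] for mid in fm.X.index.get_level_values("measurement_id")]
    )
    hp = Hyperparameters(n_cycles=80, max_splits=16)
    masks = {
        "A1": np.ones(len(fm), dtype=bool),
        "A2": pmi <= 3,
        "A3": (pmi >= 2) & (pmi <= 3),
        "A4": pmi >= 4,
    }
    node_labels = {"A1": A1_LABELS, "A2": A2_LABELS, "A3": A3_LABELS, "A4": A4_LABELS}
    models = {}
    for node, mask in masks.items():
        sub = fm.take(np.flatnonzero(mask))
        labels = np.array([pmi_bin_for_day(d, node) for d in pmi[mask]])
        models[node] = CascadeNode(
            fit_gentleboost(sub.X, labels, hp, classes=node_labels[node])
        )

    for day, expected in ((2.0, "2 days"), (20.0, "18-32 days")):
        probe = simulate_measurement(
            array,
            case3_profile(day, seed=5, day_effect=day_effect, array=array),
            noise,
            seed=777 + int(day),
            sample_id="probe",
            pmi_days=day,
            **SHORT,
        )
        r = cascade_pmi(probe, models, sg_window=21, sg_order=3)
        assert r.final_bin == expected
        if day <= 3:
            assert r.nodes_visited == ("A1", "A2", "A3")
        else:
            assert r.nodes_visited == ("A1", "A4")
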