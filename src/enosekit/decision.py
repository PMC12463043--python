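"""Sample-level decisions: 90%-agreement majority voting and the PMI cascade.

A trained ensemble classifies each retained sensor's feature row
independently, yielding up to 32 votes per sample. The sample is assigned
a class only when at least 90% of sensors agree (required votes =
ceiling(threshold * n_sensors)); anything less is an explicit
INCONCLUSIVE outcome.

Postmortem-interval (PMI) estimation chains four binary voters:

    A1: days 1-3 vs days 4-32
    A2: day 1   vs days 2-3     (reached when A1 says early)
    A3: day 2   vs day 3        (reached when A2 says days 2-3)
    A4: days 4-11 vs days 18-32 (reached when A1 says late)

An INCONCLUSIVE vote at any node terminates the cascade with the partial
path recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .boosting import EnsembleModel
from .features import DEFAULT_PROMINENCE_FRAC, features_for_measurement
from .preprocess import DEFAULT_SG_ORDER, DEFAULT_SG_WINDOW
from .simulate import Measurement

__all__ = [
    "INCONCLUSIVE",
    "VoteResult",
    "CascadeResult",
    "CascadeNode",
    "majority_vote",
    "classify_sample",
    "cascade_pmi",
    "pmi_bin_for_day",
    "A1_LABELS",
    "A2_LABELS",
    "A3_LABELS",
    "A4_LABELS",
    "DEFAULT_VOTE_THRESHOLD",
]

INCONCLUSIVE = "INCONCLUSIVE"
DEFAULT_VOTE_THRESHOLD = 0.90

# canonical PMI bin labels per cascade node (negative class first)
A1_LABELS = ("1-3 days", "4-32 days")
A2_LABELS = ("1 day", "2-3 days")
A3_LABELS = ("2 days", "3 days")
A4_LABELS = ("4-11 days", "18-32 days")

_NODE_LABELS = {"A1": A1_LABELS, "A2": A2_LABELS, "A3": A3_LABELS, "A4": A4_LABELS}


def pmi_bin_for_day(day: float, node: str) -> str:
    """Ground-truth label of a postmortem day at a given cascade node."""
    if node == "A1":
        return A1_LABELS[0] if day <= 3 else A1_LABELS[1]
    if node == "A2":
        return A2_LABELS[0] if day <= 1 else A2_LABELS[1]
    if node == "A3":
        return A3_LABELS[0] if day <= 2 else A3_LABELS[1]
    if node == "A4":
        if not (4 <= day <= 11 or 18 <= day <= 32):
            raise ValueError(f"day {day} falls in no A4 class")
        return A4_LABELS[0] if day <= 11 else A4_LABELS[1]
    raise ValueError(f"unknown node {node!r}")


@dataclass(frozen=True)
class VoteResult:
    """Outcome of sensor-level majority voting for one sample."""

    per_sensor_votes: Mapping[int, str]
    agreement_frac: float
    final: str
    threshold: float = DEFAULT_VOTE_THRESHOLD
    n_sensors: int = 0

    @property
    def conclusive(self) -> bool:
        return self.final != INCONCLUSIVE


def majority_vote(
    per_sensor_predictions: Mapping[int, str],
    threshold: float = DEFAULT_VOTE_THRESHOLD,
) -> VoteResult:
    """Assign a class only if >= ceiling(threshold * n) sensors agree."""
    if not per_sensor_predictions:
        raise ValueError("no sensor predictions supplied")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    n = len(per_sensor_predictions)
    counts: dict[str, int] = {}
    for lab in per_sensor_predictions.values():
        counts[lab] = counts.get(lab, 0) + 1
    top_label, top_votes = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    required = math.ceil(threshold * n)
    final = top_label if top_votes >= required else INCONCLUSIVE
    return VoteResult(
        per_sensor_votes=dict(per_sensor_predictions),
        agreement_frac=top_votes / n,
        final=final,
        threshold=threshold,
        n_sensors=n,
    )


def classify_sample(
    m: Measurement,
    model: EnsembleModel,
    retained_sensors: Sequence[int] | None = None,
    threshold: float = DEFAULT_VOTE_THRESHOLD,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> VoteResult:
    """Vote a single measurement: one ensemble prediction per retained sensor."""
    retained = (
        sorted(int(s) for s in retained_sensors)
        if retained_sensors is not None
        else list(m.sensor_ids)
    )
    missing = set(retained) - set(m.sensor_ids)
    if missing:
        raise ValueError(f"measurement lacks sensors {sorted(missing)}")
    feats = features_for_measurement(
        m, retained, sg_window, sg_order, prominence_frac
    )
    labels = model.predict(feats)
    votes = {
        int(sid): str(lab)
        for sid, lab in zip(feats.index.get_level_values("sensor_id"), labels)
    }
    return majority_vote(votes, threshold)


@dataclass(frozen=True)
class CascadeNode:
    """One pre-trained cascade classifier plus its retained-sensor subset."""

    model: EnsembleModel
    retained_sensors: tuple[int, ...] | None = None


@dataclass(frozen=True)
class CascadeResult:
    """Ordered decision path through the A1-A4 cascade and the final bin."""

    path: tuple[tuple[str, VoteResult], ...]
    final_bin: str

    @property
    def nodes_visited(self) -> tuple[str, ...]:
        return tuple(node for node, _ in self.path)


def cascade_pmi(
    m: Measurement,
    models: Mapping[str, CascadeNode | EnsembleModel],
    threshold: float = DEFAULT_VOTE_THRESHOLD,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
) -> CascadeResult:
    """Estimate the PMI bin of an unknown sample via the four-node cascade.

    All four nodes are validated (present and trained on the expected label
    pairs) before any classification happens. Node routing: A1 early ->
    A2; A2 "2-3 days" -> A3; A1 late -> A4. INCONCLUSIVE terminates.
    """
    nodes: dict[str, CascadeNode] = {}
    for nid in ("A1", "A2", "A3", "A4"):
        if nid not in models:
            raise ValueError(f"cascade is missing classifier {nid}")
        node = models[nid]
        if isinstance(node, EnsembleModel):
            node = CascadeNode(model=node)
        if set(node.model.classes) != set(_NODE_LABELS[nid]):
            raise ValueError(
                f"classifier {nid} trained on {node.model.classes}, "
                f"expected {_NODE_LABELS[nid]}"
            )
        nodes[nid] = node

    def vote_at(nid: str) -> VoteResult:
        node = nodes[nid]
        return classify_sample(
            m,
            node.model,
            node.retained_sensors,
            threshold,
            sg_window,
            sg_order,
        )

    path: list[tuple[str, VoteResult]] = []
    v1 = vote_at("A1")
    path.append(("A1", v1))
    if not v1.conclusive:
        return CascadeResult(path=tuple(path), final_bin=INCONCLUSIVE)
    if v1.final == A1_LABELS[0]:  # early: 1-3 days
        v2 = vote_at("A2")
        path.append(("A2", v2))
        if not v2.conclusive:
            return CascadeResult(path=tuple(path), final_bin=INCONCLUSIVE)
        if v2.final == A2_LABELS[0]:
            return CascadeResult(path=tuple(path), final_bin="1 day")
        v3 = vote_at("A3")
        path.append(("A3", v3))
        if not v3.conclusive:
            return CascadeResult(path=tuple(path), final_bin=INCONCLUSIVE)
        return CascadeResult(path=tuple(path), final_bin=v3.final)
    v4 = vote_at("A4")
    path.append(("A4", v4))
    if not v4.conclusive:
        return CascadeResult(path=tuple(path), final_bin=INCONCLUSIVE)
    return CascadeResult(path=tuple(path), final_bin=v4.final)
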