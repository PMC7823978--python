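"""Ethogram event streams, behaviour outcome measures and transforms.

Coded walk videos yield an event stream per walk: *point events* are counted
occurrences (e.g. a gaze at the handler, a verbal command), *state events*
carry a start and stop time (e.g. tracking a scent, tail held high).  The
behaviour outcome measures are percentages of a denominator duration for
state events and per-second rates for point events.  Two denominators exist:
total walking time, and the time the dog's head was visible on the
head-mounted camera (used for pant, gaze and lip-lick, which can only be
coded when the head is in frame).

The module also houses Cohen's kappa for intra-observer reliability on
recoded walks, and the transformation ledger: the per-outcome map of the
monotone transforms (log10 for tensions and pulling frequencies, powers
between 0.3 and 10 elsewhere) applied to each outcome before model fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Actor = Literal["dog", "human_verbal", "human_body"]
EventKind = Literal["point", "state"]

# vocabulary: behaviour -> (actor, kind)
ETHOGRAM_VOCABULARY: dict[str, tuple[str, str]] = {
    # canine behaviours
    "track": ("dog", "state"),
    "sniff": ("dog", "state"),
    "eliminate": ("dog", "point"),
    "shake": ("dog", "point"),
    "pant": ("dog", "state"),
    "gaze": ("dog", "point"),
    "lip_lick": ("dog", "point"),
    "tail_wag": ("dog", "state"),
    "tail_high": ("dog", "state"),
    # human verbal cues
    "sit": ("human_verbal", "point"),
    "command": ("human_verbal", "point"),
    "attention": ("human_verbal", "point"),
    "high_pitch": ("human_verbal", "point"),
    "praise": ("human_verbal", "point"),
    "negative": ("human_verbal", "point"),
    "communication": ("human_verbal", "point"),
    # human body language
    "gesture": ("human_body", "point"),
    "contact": ("human_body", "point"),
    "food": ("human_body", "point"),
}

# behaviours whose denominator is head-visible time rather than walk time
HEAD_VISIBLE_BEHAVIOURS = {"pant", "gaze", "lip_lick"}

VERBAL_BEHAVIOURS = ("sit", "command", "attention", "high_pitch",
                     "praise", "negative", "communication")
BODY_BEHAVIOURS = ("gesture", "contact", "food")


@dataclass
class EthogramEvent:
    walk_id: str
    actor: Actor
    behaviour: str
    kind: EventKind
    onset: float              # s
    offset: float | None = None  # s, state events only


@dataclass
class EthogramLog:
    walk_id: str
    events: list[EthogramEvent]
    walk_duration: float          # s
    head_visible_duration: float  # s

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "walk_id": e.walk_id, "actor": e.actor, "behaviour": e.behaviour,
            "kind": e.kind, "onset_s": e.onset,
            "offset_s": e.offset if e.offset is not None else np.nan,
        } for e in self.events]
        cols = ["walk_id", "actor", "behaviour", "kind", "onset_s", "offset_s"]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, walk_id: str,
                   walk_duration: float, head_visible_duration: float
                   ) -> "EthogramLog":
        events = []
        for row in df.itertuples(index=False):
            offset = getattr(row, "offset_s", np.nan)
            events.append(EthogramEvent(
                walk_id=walk_id, actor=row.actor, behaviour=row.behaviour,
                kind=row.kind, onset=float(row.onset_s),
                offset=None if pd.isna(offset) else float(offset),
            ))
        return cls(walk_id, events, walk_duration, head_visible_duration)


def validate_log(log: EthogramLog) -> list[str]:
    """Return every invariant violation, each naming the offending event.

    The validator reports; it never raises.  An empty list means the log is
    valid: positive denominators, point events without offsets, state events
    with onset < offset, all events inside the walk, and no overlap between
    state events of the same behaviour.
    """
    violations: list[str] = []
    if not (0 < log.head_visible_duration <= log.walk_duration):
        violations.append(
            "log: head_visible_duration must be in (0, walk_duration]"
        )
    states: dict[str, list[tuple[float, float, int]]] = {}
    for i, e in enumerate(log.events):
        tag = f"event {i} ({e.behaviour})"
        if e.kind == "point":
            if e.offset is not None:
                violations.append(f"{tag}: point event carries an offset")
            if not (0 <= e.onset <= log.walk_duration):
                violations.append(f"{tag}: onset outside [0, walk_duration]")
        elif e.kind == "state":
            if e.offset is None:
                violations.append(f"{tag}: state event missing offset")
                continue
            if not e.onset < e.offset:
                violations.append(f"{tag}: state event needs onset < offset")
                continue
            if e.onset < 0 or e.offset > log.walk_duration:
                violations.append(f"{tag}: interval outside [0, walk_duration]")
            states.setdefault(e.behaviour, []).append((e.onset, e.offset, i))
        else:
            violations.append(f"{tag}: unknown kind {e.kind!r}")
    for behaviour, intervals in states.items():
        intervals.sort()
        for (a0, a1, i), (b0, b1, j) in zip(intervals, intervals[1:]):
            if b0 < a1:
                violations.append(
                    f"event {j} ({behaviour}): overlaps state event {i}"
                )
    return violations


@dataclass
class BehaviourMetrics:
    """Per-walk behaviour outcome measures.

    Percentages (track, sniff, tail_high, tail_wag on walk time; pant on
    head-visible time) lie in [0, 100]; rates are events per second of the
    stated denominator.  ``total_verbal`` and ``total_body`` sum their
    component point events before dividing by walk time.
    """

    track_pct: float
    sniff_pct: float
    tail_high_pct: float
    tail_wag_pct: float
    pant_pct: float
    gaze_rate: float
    liplick_rate: float
    eliminate_rate: float
    shake_rate: float
    total_verbal_rate: float
    sit_rate: float
    command_rate: float
    attention_rate: float
    high_pitch_rate: float
    praise_rate: float
    negative_rate: float
    communication_rate: float
    total_body_rate: float
    gesture_rate: float
    contact_rate: float
    food_rate: float

    def to_dict(self) -> dict:
        return asdict(self)


# metric field -> (behaviour label, metric kind)
_STATE_METRICS = {
    "track_pct": "track",
    "sniff_pct": "sniff",
    "tail_high_pct": "tail_high",
    "tail_wag_pct": "tail_wag",
    "pant_pct": "pant",
}
_POINT_METRICS = {
    "gaze_rate": "gaze",
    "liplick_rate": "lip_lick",
    "eliminate_rate": "eliminate",
    "shake_rate": "shake",
    "sit_rate": "sit",
    "command_rate": "command",
    "attention_rate": "attention",
    "high_pitch_rate": "high_pitch",
    "praise_rate": "praise",
    "negative_rate": "negative",
    "communication_rate": "communication",
    "gesture_rate": "gesture",
    "contact_rate": "contact",
    "food_rate": "food",
}


def compute_behaviour_metrics(log: EthogramLog) -> BehaviourMetrics:
    """Percentages and per-second rates with the behaviour-specific denominators.

    State percentages = summed bout duration / denominator x 100; point rates
    = count / denominator.  Pant, gaze and lip-lick use the head-visible
    time; every other behaviour uses the total walking time.
    """
    problems = validate_log(log)
    if problems:
        raise ValueError("invalid ethogram log: " + "; ".join(problems))
    if log.walk_duration <= 0:
        raise ValueError("walk_duration must be positive")

    durations: dict[str, float] = {}
    counts: dict[str, int] = {}
    for e in log.events:
        if e.kind == "state":
            durations[e.behaviour] = durations.get(e.behaviour, 0.0) + (e.offset - e.onset)
        else:
            counts[e.behaviour] = counts.get(e.behaviour, 0) + 1

    def denom(behaviour: str) -> float:
        return (log.head_visible_duration
                if behaviour in HEAD_VISIBLE_BEHAVIOURS
                else log.walk_duration)

    values: dict[str, float] = {}
    for metric, behaviour in _STATE_METRICS.items():
        values[metric] = durations.get(behaviour, 0.0) / denom(behaviour) * 100.0
    for metric, behaviour in _POINT_METRICS.items():
        values[metric] = counts.get(behaviour, 0) / denom(behaviour)
    values["total_verbal_rate"] = (
        sum(counts.get(b, 0) for b in VERBAL_BEHAVIOURS) / log.walk_duration
    )
    values["total_body_rate"] = (
        sum(counts.get(b, 0) for b in BODY_BEHAVIOURS) / log.walk_duration
    )
    return BehaviourMetrics(**values)


# ---------------------------------------------------------------------------
# intra-observer reliability
# ---------------------------------------------------------------------------

def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa for two equal-length categorical sequences.

    kappa = (p_o - p_e) / (1 - p_e) with p_e the chance agreement from
    marginal products.  When both raters are constant and identical
    (p_e = 1) kappa is defined as 1.0 by convention.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labels_a and labels_b must be equal-length 1-d sequences")
    if len(a) == 0:
        raise ValueError("empty label sequences")
    cats = np.union1d(np.unique(a), np.unique(b))
    n = len(a)
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for c in cats:
        p_e += float(np.mean(a == c)) * float(np.mean(b == c))
    if math.isclose(p_e, 1.0, abs_tol=1e-12):
        # both raters constant and equal: perfect, if vacuous, agreement
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def windowed_state_labels(log: EthogramLog, behaviours: Sequence[str],
                          window: float = 1.0, fill: str = "none") -> list[str]:
    """Majority state label per fixed window, for kappa between recodings.

    Each window of the walk is labelled with the behaviour (from
    ``behaviours``) covering the largest share of it, or ``fill`` when none
    is present.  1 s windows by default.
    """
    n_win = int(math.ceil(log.walk_duration / window))
    cover = np.zeros((n_win, len(behaviours)))
    idx = {b: k for k, b in enumerate(behaviours)}
    for e in log.events:
        if e.kind != "state" or e.behaviour not in idx:
            continue
        lo = int(e.onset // window)
        hi = int(math.ceil(e.offset / window))
        for w in range(lo, min(hi, n_win)):
            w0, w1 = w * window, (w + 1) * window
            cover[w, idx[e.behaviour]] += max(
                0.0, min(e.offset, w1) - max(e.onset, w0)
            )
    labels = []
    for w in range(n_win):
        if cover[w].max() <= 0:
            labels.append(fill)
        else:
            labels.append(behaviours[int(np.argmax(cover[w]))])
    return labels


# ---------------------------------------------------------------------------
# outcome transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformSpec:
    """One monotone outcome transform.

    kind
        ``log10_offset``: x -> log10(x + delta); ``power``: x -> x**p;
        ``identity``: x unchanged.
    delta
        Offset for log transforms.  ``delta_from_duration`` marks outcomes
        (the pulling frequencies) whose offset is one event per walk,
        1/duration, resolved per walk at transform time.
    scale
        ``percent`` (default for percentage outcomes) or ``proportion``:
        tail-high's 7th power is evaluated on the 0-1 proportion scale to
        keep magnitudes finite.
    """

    kind: Literal["log10_offset", "power", "identity"]
    delta: float = 0.0
    power: float = 1.0
    delta_from_duration: bool = False
    scale: Literal["natural", "proportion"] = "natural"

    def resolve_delta(self, duration: float | None) -> float:
        if self.delta_from_duration:
            if duration is None:
                raise ValueError("this transform needs a walk duration for its offset")
            return 1.0 / duration
        return self.delta


def apply_transform(x, spec: TransformSpec, duration: float | None = None):
    """Apply a transform to a value or array of non-negative outcome values."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("outcome values must be non-negative")
    if spec.kind == "identity":
        out = arr
    elif spec.kind == "log10_offset":
        delta = spec.resolve_delta(duration)
        if delta == 0.0 and np.any(arr == 0):
            raise ValueError("log10 of zero: supply a positive offset delta")
        out = np.log10(arr + delta)
    elif spec.kind == "power":
        base = arr / 100.0 if spec.scale == "proportion" else arr
        out = np.power(base, spec.power)
    else:  # pragma: no cover - dataclass restricts kinds
        raise ValueError(f"unknown transform kind {spec.kind!r}")
    return float(out) if np.isscalar(x) else out


def invert_transform(y, spec: TransformSpec, duration: float | None = None):
    """Inverse of :func:`apply_transform` (used by the study simulator)."""
    arr = np.asarray(y, dtype=float)
    if spec.kind == "identity":
        out = arr
    elif spec.kind == "log10_offset":
        out = np.power(10.0, arr) - spec.resolve_delta(duration)
    elif spec.kind == "power":
        out = np.power(np.clip(arr, 0.0, None), 1.0 / spec.power)
        if spec.scale == "proportion":
            out = out * 100.0
    else:  # pragma: no cover
        raise ValueError(f"unknown transform kind {spec.kind!r}")
    return float(out) if np.isscalar(y) else out


def _log10_tension() -> TransformSpec:
    # offset: half the meter resolution, so zero tensions stay finite
    return TransformSpec("log10_offset", delta=0.05)


#: outcome -> transform, as printed in the result-table footnotes.
TRANSFORM_LEDGER: dict[str, TransformSpec] = {
    # tension / pulling frequency (log10; frequencies offset by 1/duration)
    "nt_max": _log10_tension(),
    "nt_mean": _log10_tension(),
    "dt_max": _log10_tension(),
    "dt_mean": _log10_tension(),
    "ht_max": _log10_tension(),
    "ht_mean": _log10_tension(),
    "dpf": TransformSpec("log10_offset", delta_from_duration=True),
    "hpf": TransformSpec("log10_offset", delta_from_duration=True),
    # canine behaviours
    "track_pct": TransformSpec("identity"),
    "tail_high_pct": TransformSpec("power", power=7.0, scale="proportion"),
    "tail_wag_pct": TransformSpec("power", power=0.3),
    "gaze_rate": TransformSpec("power", power=0.4),
    "liplick_rate": TransformSpec("power", power=0.4),
    "eliminate_rate": TransformSpec("power", power=0.6),
    "shake_rate": TransformSpec("power", power=0.8),
    "pant_pct": TransformSpec("power", power=0.5),
    "sniff_pct": TransformSpec("power", power=0.5),
    # human verbal cues
    "total_verbal_rate": TransformSpec("power", power=0.5),
    "attention_rate": TransformSpec("power", power=0.4),
    "communication_rate": TransformSpec("power", power=0.4),
    "negative_rate": TransformSpec("power", power=0.4),
    "praise_rate": TransformSpec("power", power=0.5),
    "high_pitch_rate": TransformSpec("power", power=0.5),
    "command_rate": TransformSpec("power", power=0.5),
    # human body language
    "total_body_rate": TransformSpec("power", power=0.5),
    "food_rate": TransformSpec("identity"),
    "gesture_rate": TransformSpec("power", power=0.4),
    "contact_rate": TransformSpec("power", power=0.5),
    # exit questionnaire factors
    "factor_h": TransformSpec("power", power=10.0),
    "factor_d": TransformSpec("identity"),
}

#: outcome families, mirroring the result-table layout
OUTCOME_FAMILIES: dict[str, tuple[str, ...]] = {
    "tension": ("nt_max", "nt_mean", "dt_max", "dt_mean", "dpf",
                "ht_max", "ht_mean", "hpf"),
    "dog_behaviour": ("track_pct", "tail_high_pct", "tail_wag_pct",
                      "gaze_rate", "liplick_rate", "eliminate_rate",
                      "shake_rate", "pant_pct", "sniff_pct"),
    "verbal_cue": ("total_verbal_rate", "attention_rate", "communication_rate",
                   "negative_rate", "praise_rate", "high_pitch_rate",
                   "command_rate"),
    "body_language": ("total_body_rate", "food_rate", "gesture_rate",
                      "contact_rate"),
    "questionnaire": ("factor_h", "factor_d"),
}


def behaviour_metrics_frame(logs: Iterable[EthogramLog]) -> pd.DataFrame:
    """One row of behaviour metrics per walk."""
    rows = []
    for log in logs:
        d = {"walk_id": log.walk_id}
        d.update(compute_behaviour_metrics(log).to_dict())
        rows.append(d)
    return pd.DataFrame(rows)
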