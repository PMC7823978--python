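"""Pull-episode detection and leash-tension outcome measures.

A walk is recorded by a leash-mounted tension meter sampling at 10 Hz with a
0-100 kg-force range and 0.1 kgf resolution, together with a single-axis
accelerometer whose positive direction points toward the dog.  A *pull
episode* is a bout of leash force exceeding 0.1% of the dog's body-weight
force.  Each episode divides into three phases:

1. initiation - tension rises, the device accelerates toward the initiator;
2. contest - the other party counteracts: a sharp tension increase and an
   acceleration pulse opposite to the initiator;
3. resolution (losing/winning) - tension decreases, the device accelerates
   toward the winner.

From the detected episodes the eight walk-level outcome measures are
computed: net / dog-initiated / handler-initiated maximal and mean tensions
(NT_max, NT_mean, DT_max, DT_mean, HT_max, HT_mean, all in kgf) and the dog
and handler pulling frequencies (DPF, HPF, pulls per second of walk).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

SAMPLE_DT = 0.1  # seconds; 10 Hz meter
TENSION_RANGE = (0.0, 100.0)  # kgf
TENSION_RESOLUTION = 0.1  # kgf (100 g-force)

Party = Literal["dog", "handler", "ambiguous"]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class WalkTrace:
    """Synchronised tension/acceleration samples for one walk.

    ``accel`` uses the device convention that the positive axis points toward
    the dog; only the sign of windowed means is ever interpreted.
    """

    walk_id: str
    t: np.ndarray          # seconds, uniform 10 Hz grid
    tension: np.ndarray    # kgf per sample
    accel: np.ndarray      # signed device-axis acceleration per sample
    dog_weight: float      # kg, used for thresholding

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.tension = np.asarray(self.tension, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Walk duration in seconds (number of samples x 0.1 s)."""
        return self.n_samples * SAMPLE_DT

    def validate(self) -> None:
        if not (len(self.t) == len(self.tension) == len(self.accel)):
            raise ValueError("t, tension and accel must have equal length")
        if len(self.t) < 2:
            raise ValueError("a walk trace needs at least 2 samples")
        steps = np.diff(self.t)
        if not np.allclose(steps, SAMPLE_DT, atol=1e-6):
            raise ValueError("t must be a uniform 10 Hz grid (0.1 s steps)")
        lo, hi = TENSION_RANGE
        if self.tension.min() < lo - 1e-9 or self.tension.max() > hi + 1e-9:
            raise ValueError(f"tension must lie in [{lo}, {hi}] kgf")
        if self.dog_weight <= 0:
            raise ValueError("dog_weight must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "tension_kgf": self.tension, "accel_signed": self.accel}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, walk_id: str, dog_weight: float) -> "WalkTrace":
        df = pd.read_csv(path)
        return cls(
            walk_id=walk_id,
            t=df["t_s"].to_numpy(),
            tension=df["tension_kgf"].to_numpy(),
            accel=df["accel_signed"].to_numpy(),
            dog_weight=dog_weight,
        )


@dataclass
class DetectorConfig:
    """Tunable parameters of the pull-episode detector.

    threshold_fraction
        Fraction of the dog's body weight defining the pull threshold
        (0.001, i.e. 0.1% of body-weight force).
    merge_gap
        Sub-threshold gaps shorter than this (s) are bridged, so the meter's
        0.1 kgf quantization chatter does not split one pull into several.
    min_duration
        Super-threshold runs shorter than this (s) are dropped.
    accel_tie_tol
        Windowed-mean accelerations within +/- this of zero are treated as
        ambiguous instead of being attributed to a party.
    ambiguous_policy
        ``exclude``: ambiguous episodes count toward neither DPF nor HPF
        (they still contribute to the net measures). ``assign_dog``: fold
        them into the dog-initiated set.
    median_filter
        Optionally apply a 3-sample median filter to the tension before
        detection; off by default since the device already quantizes.
    """

    threshold_fraction: float = 0.001
    merge_gap: float = 0.3
    min_duration: float = 0.2
    accel_tie_tol: float = 0.01
    ambiguous_policy: Literal["exclude", "assign_dog"] = "exclude"
    median_filter: bool = False

    def __post_init__(self) -> None:
        if self.threshold_fraction <= 0:
            raise ValueError("threshold_fraction must be > 0")
        if self.merge_gap < 0 or self.min_duration < 0:
            raise ValueError("merge_gap and min_duration must be >= 0")
        if self.accel_tie_tol < 0:
            raise ValueError("accel_tie_tol must be >= 0")
        if self.ambiguous_policy not in ("exclude", "assign_dog"):
            raise ValueError(f"unknown ambiguous_policy {self.ambiguous_policy!r}")


@dataclass
class PullEpisode:
    """One detected pull with phase boundaries (half-open sample indices)."""

    start_idx: int
    contest_idx: int
    resolution_idx: int
    end_idx: int
    initiator: Party
    winner: Party
    peak_tension: float
    mean_tension: float
    degenerate: bool = False  # all-equal tension; phases collapsed

    def __post_init__(self) -> None:
        if not (self.start_idx <= self.contest_idx <= self.resolution_idx <= self.end_idx):
            raise ValueError("episode phase indices must be monotone")


@dataclass
class WalkTensionMetrics:
    """The eight tension/frequency outcome measures for one walk."""

    nt_max: float
    nt_mean: float
    dt_max: float
    dt_mean: float
    ht_max: float
    ht_mean: float
    dpf: float
    hpf: float
    n_dog: int
    n_handler: int
    n_ambiguous: int
    duration: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# detector operations
# ---------------------------------------------------------------------------

def pull_threshold(dog_weight: float, threshold_fraction: float = 0.001) -> float:
    """Pull threshold in kgf: ``threshold_fraction`` of the dog's body weight.

    With the default fraction this is 0.1% of the body-weight force, e.g.
    0.020 kgf for a 20 kg dog.
    """
    if dog_weight <= 0:
        raise ValueError("dog_weight must be positive")
    return dog_weight * threshold_fraction


def _median3(x: np.ndarray) -> np.ndarray:
    from scipy.ndimage import median_filter
    return median_filter(x, size=3, mode="nearest")


def find_bouts(trace: WalkTrace, config: DetectorConfig | None = None
               ) -> list[tuple[int, int]]:
    """Locate super-threshold runs, with gap merging and a minimum duration.

    Returns sorted, non-overlapping half-open ``(start, end)`` sample index
    pairs.  A sample belongs to a run when its tension strictly exceeds the
    pull threshold.  Runs separated by sub-threshold gaps shorter than
    ``merge_gap`` are merged; merged runs shorter than ``min_duration`` are
    dropped (a run of k samples spans k x 0.1 s).
    """
    config = config or DetectorConfig()
    thr = pull_threshold(trace.dog_weight, config.threshold_fraction)
    tension = _median3(trace.tension) if config.median_filter else trace.tension
    above = tension > thr
    if not above.any():
        return []

    # maximal runs of True
    padded = np.concatenate(([False], above, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)

    # merge runs across short gaps (< merge_gap seconds)
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        gap = (s - merged[-1][1]) * SAMPLE_DT
        if gap < config.merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    # drop runs shorter than min_duration
    return [
        (s, e) for s, e in merged
        if (e - s) * SAMPLE_DT >= config.min_duration
    ]


def _last_of_first_max_run(x: np.ndarray, atol: float = 1e-9) -> int:
    """Index of the last element of the first contiguous run of maxima.

    For a plateau of equal maxima this is the plateau end (the value
    decreases afterwards); for two separated equal maxima it is the earliest
    maximum.
    """
    m = x.max()
    is_max = np.isclose(x, m, rtol=0.0, atol=atol)
    first = int(np.argmax(is_max))
    i = first
    while i + 1 < len(x) and is_max[i + 1]:
        i += 1
    return i


def segment_phases(trace: WalkTrace, bout: tuple[int, int]
                   ) -> tuple[int, int, int, int, bool]:
    """Split one bout into initiation / contest / resolution phase boundaries.

    The contest marker is the sharpest tension increase after onset ("a sharp
    increase in the leash tension"); the resolution phase starts at the
    tension peak, after which tension decreases.  Ties take the last index of
    the first contiguous maximal run.  Returns
    ``(start_idx, contest_idx, resolution_idx, end_idx, degenerate)``;
    a degenerate (all-equal-tension) bout collapses to
    ``(start, start, start, end)``.
    """
    s, e = bout
    seg = trace.tension[s:e]
    if np.allclose(seg, seg[0], rtol=0.0, atol=1e-12):
        return s, s, s, e, True
    resolution = s + _last_of_first_max_run(seg)
    if resolution == s:
        return s, s, resolution, e, False
    grad = np.diff(seg[: resolution - s + 1])
    # diff[i] is the step landing on sample i+1
    contest = s + 1 + _last_of_first_max_run(grad)
    contest = min(contest, resolution)
    return s, contest, resolution, e, False


def _window_party(accel: np.ndarray, lo: int, hi: int, tol: float) -> Party:
    if hi <= lo:
        return "ambiguous"
    m = float(np.mean(accel[lo:hi]))
    if m > tol:
        return "dog"
    if m < -tol:
        return "handler"
    return "ambiguous"


def attribute_episode(trace: WalkTrace,
                      phases: tuple[int, int, int, int],
                      config: DetectorConfig | None = None
                      ) -> tuple[Party, Party]:
    """Attribute initiator and winner from windowed acceleration sign.

    The initiator is the party toward whom the device accelerates over the
    initiation window ``[start, contest)``; the winner analogously over the
    resolution window ``[resolution, end)``.  Positive axis points toward
    the dog.  Windowed means within ``accel_tie_tol`` of zero (or empty
    windows) give ``ambiguous``.
    """
    config = config or DetectorConfig()
    s, c, r, e = phases[:4]
    initiator = _window_party(trace.accel, s, c, config.accel_tie_tol)
    winner = _window_party(trace.accel, r, e, config.accel_tie_tol)
    return initiator, winner


def compute_metrics(trace: WalkTrace,
                    episodes: Sequence[PullEpisode],
                    config: DetectorConfig | None = None) -> WalkTensionMetrics:
    """Compute the eight outcome measures from a trace and its episodes.

    Net measures run over *all* samples of the walk; dog/handler measures run
    over the samples inside dog-/handler-initiated episodes (0 if none).
    Ambiguous episodes contribute to the net measures but (under the default
    policy) to neither pulling frequency.
    """
    config = config or DetectorConfig()
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    duration = trace.duration

    def party_of(ep: PullEpisode) -> Party:
        if ep.initiator == "ambiguous" and config.ambiguous_policy == "assign_dog":
            return "dog"
        return ep.initiator

    samples: dict[str, list[np.ndarray]] = {"dog": [], "handler": []}
    counts = {"dog": 0, "handler": 0, "ambiguous": 0}
    for ep in episodes:
        p = party_of(ep)
        counts[p] += 1
        if p in samples:
            samples[p].append(trace.tension[ep.start_idx:ep.end_idx])

    def mx(chunks: list[np.ndarray]) -> float:
        return float(np.max(np.concatenate(chunks))) if chunks else 0.0

    def mn(chunks: list[np.ndarray]) -> float:
        return float(np.mean(np.concatenate(chunks))) if chunks else 0.0

    return WalkTensionMetrics(
        nt_max=float(trace.tension.max()),
        nt_mean=float(trace.tension.mean()),
        dt_max=mx(samples["dog"]),
        dt_mean=mn(samples["dog"]),
        ht_max=mx(samples["handler"]),
        ht_mean=mn(samples["handler"]),
        dpf=counts["dog"] / duration,
        hpf=counts["handler"] / duration,
        n_dog=counts["dog"],
        n_handler=counts["handler"],
        n_ambiguous=counts["ambiguous"],
        duration=duration,
    )


def detect_pull_episodes(trace: WalkTrace,
                         config: DetectorConfig | None = None
                         ) -> tuple[list[PullEpisode], WalkTensionMetrics]:
    """Full deterministic detector: bouts -> phases -> attribution -> metrics."""
    config = config or DetectorConfig()
    episodes: list[PullEpisode] = []
    for bout in find_bouts(trace, config):
        s, c, r, e, degenerate = segment_phases(trace, bout)
        initiator, winner = attribute_episode(trace, (s, c, r, e), config)
        seg = trace.tension[s:e]
        episodes.append(PullEpisode(
            start_idx=s, contest_idx=c, resolution_idx=r, end_idx=e,
            initiator=initiator, winner=winner,
            peak_tension=float(seg.max()), mean_tension=float(seg.mean()),
            degenerate=degenerate,
        ))
    return episodes, compute_metrics(trace, episodes, config)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def episodes_frame(walk_id: str, episodes: Sequence[PullEpisode]) -> pd.DataFrame:
    rows = []
    for ep in episodes:
        rows.append({
            "walk_id": walk_id,
            "start_s": ep.start_idx * SAMPLE_DT,
            "contest_s": ep.contest_idx * SAMPLE_DT,
            "resolution_s": ep.resolution_idx * SAMPLE_DT,
            "end_s": ep.end_idx * SAMPLE_DT,
            "start_idx": ep.start_idx,
            "contest_idx": ep.contest_idx,
            "resolution_idx": ep.resolution_idx,
            "end_idx": ep.end_idx,
            "initiator": ep.initiator,
            "winner": ep.winner,
            "peak_tension_kgf": ep.peak_tension,
            "mean_tension_kgf": ep.mean_tension,
            "degenerate": ep.degenerate,
        })
    cols = ["walk_id", "start_s", "contest_s", "resolution_s", "end_s",
            "start_idx", "contest_idx", "resolution_idx", "end_idx",
            "initiator", "winner", "peak_tension_kgf", "mean_tension_kgf",
            "degenerate"]
    return pd.DataFrame(rows, columns=cols)


def metrics_frame(walk_id: str, metrics: WalkTensionMetrics) -> pd.DataFrame:
    d = {"walk_id": walk_id}
    d.update(metrics.to_dict())
    return pd.DataFrame([d])
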