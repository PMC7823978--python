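"""Synthetic on-leash walking studies with known ground truth.

The generator emulates a shelter walking study: a cohort of dogs with
demographic covariates drawn from configured moments, a crossed design in
which each volunteer walker walks several different dogs (dogs reused across
walkers), 10 Hz leash tension / acceleration traces containing injected pull
events with known initiator and winner, ethogram event streams, behavioural
assessment scores, and exit questionnaires.  Covariate effects on outcomes
are *planted* on the transformed scale of the outcome (the same scale the
statistical stage models), together with crossed dog and walker random
intercepts and Gaussian residual noise, so that the downstream detector and
inference pipeline can be tested against known truth.

Every generator is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tension_meter import (
    SAMPLE_DT, TENSION_RESOLUTION, WalkTrace, pull_threshold,
)
from .ethogram_metrics import (
    ETHOGRAM_VOCABULARY, HEAD_VISIBLE_BEHAVIOURS, TRANSFORM_LEDGER,
    EthogramEvent, EthogramLog, apply_transform, invert_transform,
)
from .scoring import SUBTESTS, NEGATIVE_ITEMS, N_ITEMS


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class DogProfile:
    """Demographics and morphometrics of one shelter dog.

    ``cephalic_index`` is skull width over skull length (wider-headed dogs
    have higher values); ``level`` is the shelter's walking-difficulty
    classification (1 = loose leash ... 3+ = severe behavioural issues).
    """

    dog_id: str
    age: float          # months
    sex: Literal["female", "male"]
    weight: float       # kg
    height: float       # cm
    length: float       # cm
    bcs: int            # body condition score, 1-9
    skull_width: float  # cm
    skull_length: float  # cm
    cephalic_index: float
    source: Literal["stray", "surrendered", "returned", "other"]
    level: Literal["1", "2", "3", "3+"]

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if not 1 <= self.bcs <= 9:
            raise ValueError("bcs must be in 1..9")
        ci = self.skull_width / self.skull_length
        if abs(ci - self.cephalic_index) > 1e-9:
            raise ValueError("cephalic_index must equal skull_width/skull_length")
        if not 0 < self.cephalic_index < 1.5:
            raise ValueError("cephalic_index out of plausible range")


@dataclass
class CohortMoments:
    """Moments and proportions the cohort generator targets.

    Defaults reproduce the study cohort: age 44.82 +/- 29.37 months, weight
    24.87 +/- 6.65 kg, height 52.04 +/- 6.29 cm, length 56.05 +/- 5.93 cm,
    BCS 4.59 +/- 1.07 (9-point scale), cephalic index 0.58 +/- 0.058,
    52.3% female, and intake sources stray/surrendered/returned/other with
    probabilities 0.3874/0.2793/0.1712/0.1622.  Continuous covariates use
    truncated normals (truncation at physical bounds).
    """

    age_mean: float = 44.82
    age_sd: float = 29.37
    age_min: float = 2.0
    weight_mean: float = 24.87
    weight_sd: float = 6.65
    weight_min: float = 2.0
    height_mean: float = 52.04
    height_sd: float = 6.29
    length_mean: float = 56.05
    length_sd: float = 5.93
    bcs_mean: float = 4.59
    bcs_sd: float = 1.07
    ci_mean: float = 0.58
    ci_sd: float = 0.058
    ci_bounds: tuple[float, float] = (0.3, 1.0)
    skull_length_mean: float = 20.0
    skull_length_sd: float = 2.5
    p_female: float = 0.523
    source_probs: tuple[float, float, float, float] = (0.3874, 0.2793, 0.1712, 0.1622)
    level_probs: tuple[float, float, float, float] = (0.20, 0.40, 0.30, 0.10)


_SOURCES = ("stray", "surrendered", "returned", "other")
_LEVELS = ("1", "2", "3", "3+")

#: continuous dog covariates usable as model predictors
DOG_COVARIATES = ("age", "weight", "height", "length", "bcs", "cephalic_index")


from functools import lru_cache


@lru_cache(maxsize=None)
def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float
                       ) -> tuple[float, float]:
    """(loc, scale) such that the [lo, hi]-truncated normal has the target
    mean and SD.  With a far-tail truncation this is essentially (mean, sd);
    with a nearby bound (e.g. age > 2 months) the naive parameters would
    bias the sample moments."""
    from scipy import optimize

    def residual(p):
        loc, log_scale = p
        scale = float(np.exp(log_scale))
        a, b = (lo - loc) / scale, (hi - loc) / scale
        mu, var = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(mu) - mean, float(np.sqrt(var)) - sd]

    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = optimize.fsolve(residual, x0=[mean, np.log(sd)], xtol=1e-12)
    loc, scale = float(sol[0]), float(np.exp(sol[1]))
    if not (np.isfinite(loc) and np.isfinite(scale) and scale > 0):
        return mean, sd
    return loc, scale


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float = -np.inf, hi: float = np.inf, size: int = 1
               ) -> np.ndarray:
    loc, scale = _matched_truncnorm(mean, sd, lo, hi)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                               random_state=rng)


def generate_cohort(n_dogs: int, seed: int,
                    moments: CohortMoments | None = None) -> list[DogProfile]:
    """Draw a seeded cohort of dogs matching the configured moments."""
    if n_dogs < 1:
        raise ValueError("n_dogs must be >= 1")
    m = moments or CohortMoments()
    rng = np.random.default_rng(seed)
    # reported proportions may not sum exactly to 1 after rounding
    source_p = np.asarray(m.source_probs) / np.sum(m.source_probs)
    level_p = np.asarray(m.level_probs) / np.sum(m.level_probs)
    n = n_dogs
    age = _truncnorm(rng, m.age_mean, m.age_sd, lo=m.age_min, size=n)
    weight = _truncnorm(rng, m.weight_mean, m.weight_sd, lo=m.weight_min, size=n)
    height = _truncnorm(rng, m.height_mean, m.height_sd, lo=20.0, size=n)
    length = _truncnorm(rng, m.length_mean, m.length_sd, lo=20.0, size=n)
    bcs = np.clip(np.round(rng.normal(m.bcs_mean, m.bcs_sd, size=n)), 1, 9)
    ci = _truncnorm(rng, m.ci_mean, m.ci_sd, *m.ci_bounds, size=n)
    skull_length = _truncnorm(rng, m.skull_length_mean, m.skull_length_sd,
                              lo=10.0, size=n)
    sex = np.where(rng.random(n) < m.p_female, "female", "male")
    source = rng.choice(np.array(_SOURCES), size=n, p=source_p)
    level = rng.choice(np.array(_LEVELS), size=n, p=level_p)
    dogs: list[DogProfile] = []
    for i in range(n):
        sw = float(ci[i] * skull_length[i])
        dogs.append(DogProfile(
            dog_id=f"D{i + 1:03d}", age=float(age[i]), sex=str(sex[i]),
            weight=float(weight[i]), height=float(height[i]),
            length=float(length[i]), bcs=int(bcs[i]), skull_width=sw,
            skull_length=float(skull_length[i]),
            cephalic_index=sw / float(skull_length[i]),
            source=str(source[i]), level=str(level[i]),
        ))
    return dogs


def cohort_frame(dogs: Sequence[DogProfile]) -> pd.DataFrame:
    return pd.DataFrame([asdict(d) for d in dogs])


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Crossed walker x dog assignment: one walk per (walker, dog) pair."""

    n_dogs: int
    n_walkers: int
    walks_per_walker: int
    assignment: list[tuple[str, str]]  # (walker_id, dog_id) pairs

    @property
    def n_walks(self) -> int:
        return len(self.assignment)

    def validate(self) -> None:
        from collections import Counter
        walker_counts = Counter(w for w, _ in self.assignment)
        if any(c != self.walks_per_walker for c in walker_counts.values()):
            raise ValueError("each walker must appear exactly walks_per_walker times")
        if len(walker_counts) != self.n_walkers:
            raise ValueError("wrong number of walkers in the assignment")
        if len(set(self.assignment)) != len(self.assignment):
            raise ValueError("a walker never repeats a dog")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"walk_id": f"K{i + 1:04d}", "walker_id": w, "dog_id": d}
             for i, (w, d) in enumerate(self.assignment)]
        )


def build_design(n_dogs: int, n_walkers: int, walks_per_walker: int,
                 seed: int) -> StudyDesign:
    """Assign each walker ``walks_per_walker`` *different* dogs.

    Dogs are reused across walkers as needed; a greedy rule keeps dog usage
    balanced (each walker takes the currently least-walked dogs, random
    ties).  Infeasible when a walker cannot get enough distinct dogs.
    """
    if n_dogs < 1 or n_walkers < 1 or walks_per_walker < 1:
        raise ValueError("design counts must be positive")
    if n_dogs < walks_per_walker:
        raise ValueError(
            f"need at least {walks_per_walker} dogs so a walker never repeats a dog"
        )
    rng = np.random.default_rng(seed)
    usage = np.zeros(n_dogs, dtype=int)
    assignment: list[tuple[str, str]] = []
    for w in range(n_walkers):
        tiebreak = rng.permutation(n_dogs)
        order = np.lexsort((tiebreak, usage))
        chosen = order[:walks_per_walker]
        usage[chosen] += 1
        for d in chosen:
            assignment.append((f"W{w + 1:03d}", f"D{d + 1:03d}"))
    design = StudyDesign(n_dogs, n_walkers, walks_per_walker, assignment)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# simulation parameters and ground truth
# ---------------------------------------------------------------------------

#: raw-scale baseline outcome levels the generator targets when no effect is
#: planted (tensions in kgf, frequencies and rates in events/s, percentages
#: in % of their denominator).
OUTCOME_BASELINES: dict[str, float] = {
    "nt_max": 2.0,
    "dpf": 0.02,
    "track_pct": 20.0,
    "sniff_pct": 15.0,
    "tail_high_pct": 15.0,
    "tail_wag_pct": 10.0,
    "pant_pct": 30.0,
    "gaze_rate": 0.05,
    "liplick_rate": 0.02,
    "eliminate_rate": 0.005,
    "shake_rate": 0.003,
    "sit_rate": 0.01,
    "command_rate": 0.02,
    "attention_rate": 0.02,
    "high_pitch_rate": 0.01,
    "praise_rate": 0.02,
    "negative_rate": 0.005,
    "communication_rate": 0.01,
    "gesture_rate": 0.01,
    "contact_rate": 0.01,
    "food_rate": 0.005,
    "latent_satisfaction": 3.5,
}

#: default per-subtest score centres; the cohort medians the assessments target
SUBTEST_LOCS: dict[str, float] = {
    "socialisation": 3.0, "tolerance": 4.0, "toy": 1.0, "run_freeze": 3.5,
    "resource_guarding": -3.0, "toddler": 4.0, "time_alone": -1.0,
}


@dataclass
class SimulationParams:
    """Tunable data-generating parameters of a synthetic study.

    ``covariate_effects`` maps an outcome name (a transform-ledger entry such
    as ``nt_max`` or ``dpf``, or ``latent_satisfaction`` for the
    questionnaire) to a ``{covariate: slope}`` map; slopes act on the
    *transformed* outcome scale per unit of the (raw) covariate, which may be
    a demographic (``age`` in months, ``weight`` in kg, ...) or a behavioural
    assessment subtest score.  Random intercepts for dog and walker and the
    Gaussian residual act on the same transformed scale.
    """

    seed: int = 0
    walk_duration: float = 600.0      # s
    dog_pull_rate: float = 0.02       # events/s
    handler_pull_rate: float = 0.01   # events/s
    pull_amplitude_mean: float = 2.0  # kgf
    pull_amplitude_sd: float = 0.8
    min_pull_amplitude: float = 1.0   # kgf floor (keeps the contest jump sharp)
    pull_duration_mean: float = 2.5   # s
    pull_duration_sd: float = 0.7
    min_pull_duration: float = 1.5
    max_pull_duration: float = 5.0
    baseline_tension: float = 0.0     # kgf
    noise_sd: float = 0.02            # kgf; sub-resolution, rarely survives quantization
    accel_pulse: float = 1.0          # device units
    accel_pulse_width: float = 0.3    # s
    accel_noise_sd: float = 0.1
    head_visible_fraction: float = 0.8
    item_sd: float = 0.7              # questionnaire item noise (latent scale)
    subtest_sd: float = 1.0
    subtest_score_range: tuple[int, int] = (-5, 5)
    subtest_locs: dict = field(default_factory=lambda: dict(SUBTEST_LOCS))
    covariate_effects: dict = field(default_factory=dict)
    random_sd_dog: float = 0.1        # transformed-outcome units
    random_sd_walker: float = 0.05
    residual_sd: float = 0.1
    #: per-outcome residual sds where the transformed scale differs wildly
    #: from unit magnitude (track is raw percentage points, food a raw rate)
    residual_sd_overrides: dict = field(default_factory=lambda: {
        "track_pct": 4.0, "food_rate": 0.002, "latent_satisfaction": 0.4,
    })

    def outcome_residual_sd(self, outcome: str) -> float:
        return float(self.residual_sd_overrides.get(outcome, self.residual_sd))

    def validate(self) -> None:
        if self.walk_duration <= 0:
            raise ValueError("walk_duration must be positive")
        for name in ("dog_pull_rate", "handler_pull_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("pull_amplitude_sd", "pull_duration_sd", "noise_sd",
                     "accel_noise_sd", "random_sd_dog", "random_sd_walker",
                     "residual_sd", "subtest_sd", "item_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.head_visible_fraction <= 1:
            raise ValueError("head_visible_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "subtest_score_range" in raw:
            raw["subtest_score_range"] = tuple(raw["subtest_score_range"])
        p = cls(**raw)
        p.validate()
        return p


@dataclass
class InjectedEvent:
    """Ground truth for one injected pull event."""

    onset_s: float
    duration_s: float
    amplitude_kgf: float
    initiator: Literal["dog", "handler"]
    winner: Literal["dog", "handler"]


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------

def _quantize(tension: np.ndarray) -> np.ndarray:
    return np.round(np.clip(tension, 0.0, 100.0) / TENSION_RESOLUTION) \
        * TENSION_RESOLUTION


#: sub-threshold clearance kept around every injected event (s); comfortably
#: wider than the detector's default merge gap so events never fuse.
EVENT_GUARD = 1.0


def _draw_events(rng: np.random.Generator, params: SimulationParams,
                 dog_rate: float, handler_rate: float,
                 threshold: float, amplitude: float | None
                 ) -> list[InjectedEvent]:
    """Non-overlapping pull events from two independent Poisson processes.

    Poisson counts are drawn per initiator and preserved exactly whenever
    the walk can hold them; events are then laid out with uniform random
    spacing (a Dirichlet split of the free time), each followed by a
    sub-threshold guard gap.  When the drawn events cannot all fit, randomly
    chosen ones are thinned out.
    """
    T = params.walk_duration
    amp_floor = max(params.min_pull_amplitude, 2.0 * threshold)
    specs: list[tuple[float, float, str, str]] = []  # (dur, amp, initiator, winner)
    for rate, who in ((dog_rate, "dog"), (handler_rate, "handler")):
        n = rng.poisson(rate * T)
        for _ in range(n):
            dur = float(np.clip(rng.normal(params.pull_duration_mean,
                                           params.pull_duration_sd),
                                params.min_pull_duration,
                                params.max_pull_duration))
            amp = amplitude if amplitude is not None else float(
                rng.normal(params.pull_amplitude_mean, params.pull_amplitude_sd))
            amp = float(np.clip(max(amp, amp_floor), amp_floor, 60.0))
            other = "handler" if who == "dog" else "dog"
            winner = who if rng.random() < 0.5 else other
            specs.append((dur, amp, who, winner))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    # thin randomly until everything fits with its guard gap
    while specs and sum(d for d, *_ in specs) + EVENT_GUARD * (len(specs) + 1) > T:
        specs.pop(int(rng.integers(len(specs))))
    if not specs:
        return []
    k = len(specs)
    busy = sum(d for d, *_ in specs) + EVENT_GUARD * k
    gaps = (T - busy) * rng.dirichlet(np.ones(k + 1))
    events: list[InjectedEvent] = []
    t = EVENT_GUARD / 2 + gaps[0]
    for j, (dur, amp, who, winner) in enumerate(specs):
        events.append(InjectedEvent(float(t), dur, amp, who, winner))
        t += dur + EVENT_GUARD + gaps[j + 1]
    return events


def _render_event(tension: np.ndarray, accel: np.ndarray,
                  ev: InjectedEvent, params: SimulationParams) -> None:
    """Shape one pull: linear rise, plateau, one-sample contest jump to
    1.5x amplitude, short peak hold, linear decay; 0.3 s acceleration pulses
    at the phase boundaries (onset toward the initiator, contest opposite,
    resolution toward the winner, the last at double magnitude so its sign
    survives the counter-pulse)."""
    i0 = int(round(ev.onset_s / SAMPLE_DT))
    n = max(6, int(round(ev.duration_s / SAMPLE_DT)))
    A = ev.amplitude_kgf
    i_rise = max(1, int(0.4 * n))
    i_contest = max(i_rise + 1, int(0.7 * n))
    i_hold = max(i_contest + 1, int(0.8 * n))
    shape = np.empty(n)
    shape[:i_rise] = np.linspace(A / i_rise, A, i_rise)
    shape[i_rise:i_contest] = A
    shape[i_contest:i_hold] = 1.5 * A
    n_decay = n - i_hold
    shape[i_hold:] = np.linspace(1.5 * A, 0.0, n_decay + 1)[:-1] if n_decay else []
    tension[i0:i0 + n] += shape[: len(tension) - i0]

    pw = max(1, int(round(params.accel_pulse_width / SAMPLE_DT)))
    s_init = 1.0 if ev.initiator == "dog" else -1.0
    s_win = 1.0 if ev.winner == "dog" else -1.0
    for start, sign, gain in ((i0, s_init, 1.0),
                              (i0 + i_contest, -s_init, 1.0),
                              (i0 + i_hold, s_win, 2.0)):
        accel[start:start + pw] += sign * gain * params.accel_pulse


def simulate_walk_trace(dog: DogProfile, params: SimulationParams, seed: int,
                        walk_id: str = "walk",
                        dog_pull_rate: float | None = None,
                        handler_pull_rate: float | None = None,
                        amplitude: float | None = None,
                        ) -> tuple[WalkTrace, list[InjectedEvent]]:
    """Simulate one 10 Hz walk trace with injected ground-truth pull events.

    Tension is clipped to the meter's 0-100 kgf range and quantized to its
    0.1 kgf resolution.  Event amplitudes are floored at twice the dog's
    pull threshold so injected events are detectable; thinning guarantees
    events never overlap and stay clear of the detector's merge gap.
    ``dog_pull_rate`` / ``handler_pull_rate`` / ``amplitude`` override the
    corresponding parameter for this walk (used to plant outcome effects).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(params.walk_duration / SAMPLE_DT))
    t = np.arange(n) * SAMPLE_DT
    thr = pull_threshold(dog.weight)
    events = _draw_events(
        rng, params,
        params.dog_pull_rate if dog_pull_rate is None else dog_pull_rate,
        params.handler_pull_rate if handler_pull_rate is None else handler_pull_rate,
        thr, amplitude,
    )
    tension = np.full(n, params.baseline_tension)
    accel = np.zeros(n)
    for ev in events:
        _render_event(tension, accel, ev, params)
    if params.noise_sd > 0:
        tension = tension + rng.normal(0.0, params.noise_sd, size=n)
    if params.accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, params.accel_noise_sd, size=n)
    trace = WalkTrace(walk_id=walk_id, t=t, tension=_quantize(tension),
                      accel=accel, dog_weight=dog.weight)
    return trace, events


# ---------------------------------------------------------------------------
# study-level simulation
# ---------------------------------------------------------------------------

def _covariate_row(dog: DogProfile, subtest_scores: dict[str, float]) -> dict:
    row = {c: getattr(dog, c) for c in DOG_COVARIATES}
    row["sex"] = dog.sex
    row["source"] = dog.source
    row["level"] = dog.level
    row.update(subtest_scores)
    return row


def _draw_subtest_scores(rng: np.random.Generator, params: SimulationParams
                         ) -> dict[str, float]:
    lo, hi = params.subtest_score_range
    return {
        s: float(np.clip(round(rng.normal(params.subtest_locs[s],
                                          params.subtest_sd)), lo, hi))
        for s in SUBTESTS
    }


def _linear_predictor(base: float, effects: dict[str, float], cov: dict,
                      u: float, v: float, eps: float) -> float:
    eta = base + u + v + eps
    for name, slope in effects.items():
        eta += slope * float(cov[name])
    return eta


def simulate_outcome_table(design: StudyDesign, cohort: Sequence[DogProfile],
                           params: SimulationParams, seed: int,
                           outcome: str = "nt_max",
                           ) -> tuple[pd.DataFrame, dict]:
    """Model-level simulation of one transformed outcome per walk.

    Draws the transformed outcome directly from the linear mixed model the
    study-level generator embeds: fixed planted effects + crossed dog and
    walker random intercepts + Gaussian residual, without synthesising
    traces.  Returns the per-walk table (covariates and the transformed
    outcome column ``y``) plus the ground-truth parameters.  Used for
    statistical calibration at many replicates.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    dogs = {d.dog_id: d for d in cohort}
    dog_ids = sorted({d for _, d in design.assignment})
    walker_ids = sorted({w for w, _ in design.assignment})
    missing = [d for d in dog_ids if d not in dogs]
    if missing:
        raise ValueError(f"design references unknown dogs: {missing}")

    subtests = {d: _draw_subtest_scores(rng, params) for d in dog_ids}
    u = {d: rng.normal(0.0, params.random_sd_dog) for d in dog_ids}
    v = {w: rng.normal(0.0, params.random_sd_walker) for w in walker_ids}
    effects = params.covariate_effects.get(outcome, {})
    if outcome in TRANSFORM_LEDGER:
        base = float(apply_transform(OUTCOME_BASELINES.get(outcome, 1.0),
                                     TRANSFORM_LEDGER[outcome],
                                     duration=params.walk_duration))
    else:
        base = OUTCOME_BASELINES.get(outcome, 0.0)

    rows = []
    for i, (w, d) in enumerate(design.assignment):
        cov = _covariate_row(dogs[d], subtests[d])
        eps = rng.normal(0.0, params.residual_sd)
        y = _linear_predictor(base, effects, cov, u[d], v[w], eps)
        rows.append({"walk_id": f"K{i + 1:04d}", "walker_id": w, "dog_id": d,
                     **cov, "y": y})
    truth = {
        "outcome": outcome, "intercept": base, "effects": dict(effects),
        "random_sd_dog": params.random_sd_dog,
        "random_sd_walker": params.random_sd_walker,
        "residual_sd": params.residual_sd,
        "dog_intercepts": u, "walker_intercepts": v,
    }
    return pd.DataFrame(rows), truth


# behaviour outcomes the ethogram generator realises
_BEHAVIOUR_OUTCOMES: dict[str, str] = {
    "track_pct": "track", "sniff_pct": "sniff", "tail_high_pct": "tail_high",
    "tail_wag_pct": "tail_wag", "pant_pct": "pant",
    "gaze_rate": "gaze", "liplick_rate": "lip_lick",
    "eliminate_rate": "eliminate", "shake_rate": "shake",
    "sit_rate": "sit", "command_rate": "command", "attention_rate": "attention",
    "high_pitch_rate": "high_pitch", "praise_rate": "praise",
    "negative_rate": "negative", "communication_rate": "communication",
    "gesture_rate": "gesture", "contact_rate": "contact", "food_rate": "food",
}


@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    dogs: pd.DataFrame
    design: pd.DataFrame            # walk_id, walker_id, dog_id
    traces: dict[str, WalkTrace]
    ethograms: dict[str, EthogramLog]
    assessments: pd.DataFrame       # dog_id, date, seven subtest columns
    questionnaires: pd.DataFrame    # walk_id, q1..q13
    ground_truth: dict


def _transformed_target(outcome: str, effects: dict, cov: dict,
                        u: float, v: float, rng: np.random.Generator,
                        params: SimulationParams) -> float:
    spec = TRANSFORM_LEDGER[outcome]
    base = float(apply_transform(OUTCOME_BASELINES[outcome], spec,
                                 duration=params.walk_duration))
    eps = rng.normal(0.0, params.outcome_residual_sd(outcome))
    return _linear_predictor(base, effects.get(outcome, {}), cov, u, v, eps)


def _place_state_intervals(rng: np.random.Generator, total: float,
                           T: float, k: int = 3) -> list[tuple[float, float]]:
    """k equal non-overlapping intervals summing to ``total`` within [0, T]."""
    total = min(total, 0.9 * T)
    if total <= 0:
        return []
    piece = total / k
    slot = T / k
    out = []
    for j in range(k):
        jitter = rng.uniform(0.0, max(slot - piece, 1e-9))
        start = j * slot + min(jitter, slot - piece)
        out.append((start, start + piece))
    return out


def _simulate_ethogram(rng: np.random.Generator, walk_id: str,
                       params: SimulationParams, effects: dict, cov: dict,
                       re_u: dict, re_v: dict, walker: str, dog: str
                       ) -> EthogramLog:
    T = params.walk_duration
    head_T = params.head_visible_fraction * T
    events: list[EthogramEvent] = []
    for outcome, behaviour in _BEHAVIOUR_OUTCOMES.items():
        actor, kind = ETHOGRAM_VOCABULARY[behaviour]
        u = re_u[outcome][dog]
        v = re_v[outcome][walker]
        if outcome in TRANSFORM_LEDGER:
            eta = _transformed_target(outcome, effects, cov, u, v, rng, params)
            raw = float(invert_transform(eta, TRANSFORM_LEDGER[outcome],
                                         duration=T))
        else:  # sit has no analysed transform; generate on the raw scale
            raw = OUTCOME_BASELINES[outcome] + u + v \
                + rng.normal(0.0, params.residual_sd) * OUTCOME_BASELINES[outcome]
        raw = max(raw, 0.0)
        denom = head_T if behaviour in HEAD_VISIBLE_BEHAVIOURS else T
        if kind == "state":
            total = raw / 100.0 * denom
            for onset, offset in _place_state_intervals(rng, total, T):
                events.append(EthogramEvent(walk_id, actor, behaviour, "state",
                                            onset, offset))
        else:
            count = rng.poisson(raw * denom)
            for onset in np.sort(rng.uniform(0.0, T, size=count)):
                events.append(EthogramEvent(walk_id, actor, behaviour, "point",
                                            float(onset)))
    return EthogramLog(walk_id, events, walk_duration=T,
                       head_visible_duration=head_T)


def _simulate_questionnaire(rng: np.random.Generator, latent: float,
                            params: SimulationParams) -> list[int]:
    """Ordered-threshold item model: each item discretises a noisy copy of
    the latent satisfaction at thresholds symmetric around the scale centre;
    negatively worded items are stored on their original (un-reversed)
    wording."""
    thresholds = np.array([1.5, 2.5, 3.5, 4.5])
    items = []
    for i in range(1, N_ITEMS + 1):
        x = latent + rng.normal(0.0, params.item_sd)
        cat = int(np.digitize(x, thresholds)) + 1  # 1..5
        items.append(6 - cat if i in NEGATIVE_ITEMS else cat)
    return items


def simulate_study(design: StudyDesign, cohort: Sequence[DogProfile],
                   params: SimulationParams, seed: int | None = None
                   ) -> StudyBundle:
    """Generate one complete synthetic study with ground truth.

    Per walk, the dog pulling rate and the pull amplitude are set so that
    the transformed outcomes ``dpf`` (log10 of pulls/s) and ``nt_max``
    (log10 of the walk's maximal tension) follow the configured linear
    model: planted fixed effects + crossed dog/walker random intercepts +
    residual.  Behaviour rates and the questionnaire latent satisfaction
    follow the same structure on their own transformed scales.
    """
    params.validate()
    if seed is None:
        seed = params.seed
    root = np.random.SeedSequence(seed)
    s_master, s_traces, s_etho, s_quest = root.spawn(4)
    rng = np.random.default_rng(s_master)

    dogs = {d.dog_id: d for d in cohort}
    dog_ids = sorted({d for _, d in design.assignment})
    walker_ids = sorted({w for w, _ in design.assignment})
    missing = [d for d in dog_ids if d not in dogs]
    if missing:
        raise ValueError(f"design references unknown dogs: {missing}")

    subtests = {d: _draw_subtest_scores(rng, params) for d in dog_ids}
    outcome_names = (["nt_max", "dpf", "latent_satisfaction"]
                     + list(_BEHAVIOUR_OUTCOMES))
    re_u = {o: {d: float(rng.normal(0.0, params.random_sd_dog)) for d in dog_ids}
            for o in outcome_names}
    re_v = {o: {w: float(rng.normal(0.0, params.random_sd_walker))
                for w in walker_ids}
            for o in outcome_names}
    effects = params.covariate_effects

    design_df = design.to_frame()
    traces: dict[str, WalkTrace] = {}
    ethograms: dict[str, EthogramLog] = {}
    quest_rows = []
    gt_events: dict[str, list[dict]] = {}

    trace_seeds = s_traces.spawn(design.n_walks)
    etho_seeds = s_etho.spawn(design.n_walks)
    quest_seeds = s_quest.spawn(design.n_walks)

    for i, row in enumerate(design_df.itertuples(index=False)):
        walk_id, walker, dog_id = row.walk_id, row.walker_id, row.dog_id
        dog = dogs[dog_id]
        cov = _covariate_row(dog, subtests[dog_id])
        eta_seed, walk_seed = trace_seeds[i].spawn(2)
        wrng = np.random.default_rng(eta_seed)

        eta_dpf = _transformed_target("dpf", effects, cov,
                                      re_u["dpf"][dog_id], re_v["dpf"][walker],
                                      wrng, params)
        dog_rate = float(np.clip(
            invert_transform(eta_dpf, TRANSFORM_LEDGER["dpf"],
                             duration=params.walk_duration), 0.0, 0.08))
        eta_nt = _transformed_target("nt_max", effects, cov,
                                     re_u["nt_max"][dog_id],
                                     re_v["nt_max"][walker], wrng, params)
        nt_target = float(invert_transform(eta_nt, TRANSFORM_LEDGER["nt_max"]))
        amplitude = float(np.clip(nt_target / 1.5, 0.45, 60.0))

        trace, events = simulate_walk_trace(
            dog, params, seed=int(walk_seed.generate_state(1)[0] % (2**31)),
            walk_id=walk_id, dog_pull_rate=dog_rate, amplitude=amplitude)
        traces[walk_id] = trace
        gt_events[walk_id] = [asdict(e) for e in events]

        erng = np.random.default_rng(etho_seeds[i])
        ethograms[walk_id] = _simulate_ethogram(
            erng, walk_id, params, effects, cov, re_u, re_v, walker, dog_id)

        qrng = np.random.default_rng(quest_seeds[i])
        latent = _linear_predictor(
            OUTCOME_BASELINES["latent_satisfaction"],
            effects.get("latent_satisfaction", {}), cov,
            re_u["latent_satisfaction"][dog_id],
            re_v["latent_satisfaction"][walker],
            qrng.normal(0.0, params.outcome_residual_sd("latent_satisfaction")))
        items = _simulate_questionnaire(qrng, float(np.clip(latent, 1.0, 5.0)),
                                        params)
        quest_rows.append({"walk_id": walk_id,
                           **{f"q{j + 1}": items[j] for j in range(N_ITEMS)}})

    assessments = pd.DataFrame(
        [{"dog_id": d, "date": "2020-01-01", **subtests[d]} for d in dog_ids]
    )
    ground_truth = {
        "seed": seed,
        "covariate_effects": {k: dict(vv) for k, vv in effects.items()},
        "random_sd_dog": params.random_sd_dog,
        "random_sd_walker": params.random_sd_walker,
        "residual_sd": params.residual_sd,
        "events": gt_events,
        "dog_intercepts": {o: re_u[o] for o in ("nt_max", "dpf",
                                                "latent_satisfaction")},
        "walker_intercepts": {o: re_v[o] for o in ("nt_max", "dpf",
                                                   "latent_satisfaction")},
    }
    return StudyBundle(
        dogs=cohort_frame([dogs[d] for d in dog_ids]),
        design=design_df,
        traces=traces,
        ethograms=ethograms,
        assessments=assessments,
        questionnaires=pd.DataFrame(quest_rows),
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_study(bundle: StudyBundle, out_dir: str | Path) -> None:
    """Write a study bundle in the on-disk layout the analysis stage reads."""
    out = Path(out_dir)
    (out / "walks").mkdir(parents=True, exist_ok=True)
    (out / "ethogram").mkdir(parents=True, exist_ok=True)
    bundle.dogs.to_csv(out / "dogs.csv", index=False, float_format="%.6f")
    bundle.design.to_csv(out / "design.csv", index=False)
    bundle.assessments.to_csv(out / "assessments.csv", index=False,
                              float_format="%.6f")
    bundle.questionnaires.to_csv(out / "questionnaires.csv", index=False)
    for walk_id, trace in bundle.traces.items():
        df = trace.to_frame()
        df.to_csv(out / "walks" / f"{walk_id}.csv", index=False,
                  float_format="%.6f")
    for walk_id, log in bundle.ethograms.items():
        df = log.to_frame()
        df.insert(1, "walk_duration_s", log.walk_duration)
        df.insert(2, "head_visible_s", log.head_visible_duration)
        df.to_csv(out / "ethogram" / f"{walk_id}.csv", index=False,
                  float_format="%.6f")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True)


def read_study(study_dir: str | Path) -> StudyBundle:
    """Load a study bundle previously written by :func:`write_study`."""
    d = Path(study_dir)
    dogs = pd.read_csv(d / "dogs.csv")
    design = pd.read_csv(d / "design.csv")
    weights = dict(zip(dogs["dog_id"], dogs["weight"]))
    traces = {}
    ethograms = {}
    for row in design.itertuples(index=False):
        traces[row.walk_id] = WalkTrace.from_csv(
            d / "walks" / f"{row.walk_id}.csv", row.walk_id,
            weights[row.dog_id])
        edf = pd.read_csv(d / "ethogram" / f"{row.walk_id}.csv")
        if len(edf):
            T = float(edf["walk_duration_s"].iloc[0])
            head = float(edf["head_visible_s"].iloc[0])
        else:
            T = traces[row.walk_id].duration
            head = T
        ethograms[row.walk_id] = EthogramLog.from_frame(edf, row.walk_id, T, head)
    gt_path = d / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    return StudyBundle(
        dogs=dogs, design=design, traces=traces, ethograms=ethograms,
        assessments=pd.read_csv(d / "assessments.csv"),
        questionnaires=pd.read_csv(d / "questionnaires.csv"),
        ground_truth=ground_truth,
    )
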