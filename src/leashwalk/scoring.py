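"""Behavioural-assessment and exit-questionnaire scoring.

Shelter dogs are behaviourally assessed within days of intake on seven
subtests (socialisation, tolerance of handling, toy play, run-and-freeze,
resource guarding, toddler doll, time alone); each observed behavioural
presentation maps to a score increment, oriented so that a higher subtest
score means presentations that favour safe human-dog interaction.  The
dog-to-dog subtest concerns dog-dog dyads and is out of scope here.  A dog
assessed more than once gets the element-wise average of its records.

After each walk the handler answers a 13-item exit questionnaire on a
5-point Likert scale.  Negatively worded items are reverse-coded
(s -> 6 - s); factor H (handler satisfaction) is the mean of items
2,3,4,5,6,10,11 and factor D (the handler's perception of the dog) the mean
of items 1,7,8,9,12,13, both after reversal, so both stay on the 1-5 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SUBTESTS = ("socialisation", "tolerance", "toy", "run_freeze",
            "resource_guarding", "toddler", "time_alone")

N_ITEMS = 13
LIKERT_RANGE = (1, 5)
#: negatively worded questionnaire items ("I could not handle...", "I was
#: physically tense", "challenging", "did not understand", "not helping",
#: "did not enjoy", "not suitable"); overridable where a different wording
#: set is used.
NEGATIVE_ITEMS = frozenset({2, 4, 6, 7, 8, 10, 12})
FACTOR_H_ITEMS = (2, 3, 4, 5, 6, 10, 11)
FACTOR_D_ITEMS = (1, 7, 8, 9, 12, 13)


@dataclass
class AssessmentRecord:
    """One behavioural-assessment result: a score per subtest (may be negative)."""

    dog_id: str
    assessment_date: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        missing = [s for s in SUBTESTS if s not in self.scores]
        if missing:
            raise ValueError(f"missing subtest scores: {missing}")
        for name, v in self.scores.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite score for subtest {name!r}")


@dataclass
class ScoringRubric:
    """Behaviour-category -> score-increment map per subtest, with a score range.

    The rubric is user-supplied data (each shelter's assessment defines its
    own); :func:`example_rubric` ships an illustrative synthetic one for
    tests and documentation.
    """

    increments: dict[str, dict[str, float]]  # subtest -> category -> increment
    score_range: tuple[float, float] = (-5.0, 5.0)

    def __post_init__(self) -> None:
        lo, hi = self.score_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("score_range bounds must be finite with lo < hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringRubric":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(increments=raw["increments"],
                   score_range=tuple(raw.get("score_range", (-5.0, 5.0))))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"increments": self.increments,
                 "score_range": list(self.score_range)}, fh)


def example_rubric() -> ScoringRubric:
    """A small synthetic rubric, for tests and worked examples only.

    Its categories and increments are illustrative; safer presentations map
    to positive increments so the orientation invariant (safer => higher)
    holds.
    """
    inc = {
        "socialisation": {"approaches_calmly": 2, "explores_room": 1,
                          "avoids_handler": -2, "freezes": -3},
        "tolerance": {"relaxed_handling": 2, "leans_in": 1,
                      "pulls_away": -1, "snaps": -4},
        "toy": {"engages_play": 2, "releases_on_cue": 2,
                "ignores_toy": 0, "guards_toy": -3},
        "run_freeze": {"calm_watch": 2, "playful_follow": 1,
                       "startles": -1, "chases_hard": -2},
        "resource_guarding": {"keeps_eating": 2, "lifts_head": 0,
                              "stiffens": -2, "snaps_at_hand": -4},
        "toddler": {"gentle_sniff": 2, "ignores_doll": 1,
                    "barks_at_doll": -2, "lunges": -4},
        "time_alone": {"settles": 2, "paces": -1,
                       "vocalises": -2, "destroys": -3},
    }
    return ScoringRubric(increments=inc, score_range=(-5.0, 5.0))


def apply_rubric(observations: Mapping[str, Sequence[str]],
                 rubric: ScoringRubric,
                 dog_id: str = "unknown",
                 assessment_date: str = "") -> AssessmentRecord:
    """Score observed behaviour categories: per subtest, sum the mapped
    increments and clip to the rubric's score range.

    ``observations`` maps subtest -> list of observed category labels;
    subtests without observations score 0.  An observed category absent from
    the rubric is an error naming the category.
    """
    scores: dict[str, float] = {}
    lo, hi = rubric.score_range
    for subtest in SUBTESTS:
        total = 0.0
        table = rubric.increments.get(subtest, {})
        for category in observations.get(subtest, ()):
            if category not in table:
                raise ValueError(
                    f"category {category!r} not in the {subtest!r} rubric")
            total += table[category]
        scores[subtest] = float(np.clip(total, lo, hi))
    return AssessmentRecord(dog_id=dog_id, assessment_date=assessment_date,
                            scores=scores)


def aggregate_assessments(records: Sequence[AssessmentRecord]) -> AssessmentRecord:
    """Element-wise mean score per subtest over one dog's records.

    Used when a dog was assessed more than once (e.g. staff reconfirming a
    result).  A single record is returned unchanged in content.
    """
    if not records:
        raise ValueError("need at least one assessment record")
    dog_ids = {r.dog_id for r in records}
    if len(dog_ids) > 1:
        raise ValueError(f"records mix dogs: {sorted(dog_ids)}")
    scores = {
        s: float(np.mean([r.scores[s] for r in records])) for s in SUBTESTS
    }
    return AssessmentRecord(
        dog_id=records[0].dog_id,
        assessment_date=records[-1].assessment_date,
        scores=scores,
    )


def summarise_subtests(records: Sequence[AssessmentRecord]) -> pd.DataFrame:
    """Cohort summary per subtest: median and IQR (Q3 - Q1).

    Quantiles use linear interpolation (numpy's default, the type-7 rule).
    """
    if not records:
        raise ValueError("need at least one assessment record")
    rows = []
    for s in SUBTESTS:
        vals = np.array([r.scores[s] for r in records], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"subtest": s, "median": med, "iqr": q3 - q1})
    return pd.DataFrame(rows).set_index("subtest")


# ---------------------------------------------------------------------------
# exit questionnaire
# ---------------------------------------------------------------------------

@dataclass
class ExitQuestionnaire:
    walk_id: str
    items: Sequence[int]  # 13 Likert responses, 1..5

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} items, got {len(self.items)}")
        lo, hi = LIKERT_RANGE
        for i, v in enumerate(self.items, start=1):
            if not (isinstance(v, (int, np.integer)) and lo <= v <= hi):
                raise ValueError(f"item {i} out of range: {v!r}")


@dataclass
class QuestionnaireScores:
    factor_h: float  # handler satisfaction, 1..5
    factor_d: float  # handler's perception of the dog, 1..5


def reverse_items(items: Sequence[int],
                  negative: frozenset[int] = NEGATIVE_ITEMS) -> list[int]:
    """Reverse-code negatively worded items: s -> 6 - s. An involution."""
    return [6 - v if i in negative else v
            for i, v in enumerate(items, start=1)]


def score_questionnaire(q: ExitQuestionnaire,
                        negative: frozenset[int] = NEGATIVE_ITEMS
                        ) -> QuestionnaireScores:
    """Factor H and D as means of their item sets after reverse coding."""
    rev = reverse_items(q.items, negative)
    h = float(np.mean([rev[i - 1] for i in FACTOR_H_ITEMS]))
    d = float(np.mean([rev[i - 1] for i in FACTOR_D_ITEMS]))
    return QuestionnaireScores(factor_h=h, factor_d=d)


def score_questionnaire_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Score a table of questionnaires (columns walk_id, q1..q13)."""
    out = []
    for row in df.itertuples(index=False):
        items = [int(getattr(row, f"q{i}")) for i in range(1, N_ITEMS + 1)]
        s = score_questionnaire(ExitQuestionnaire(row.walk_id, items))
        out.append({"walk_id": row.walk_id,
                    "factor_h": s.factor_h, "factor_d": s.factor_d})
    return pd.DataFrame(out)


def assessments_from_frame(df: pd.DataFrame) -> list[AssessmentRecord]:
    """Parse an assessments table (dog_id, date, seven score columns)."""
    records = []
    for row in df.itertuples(index=False):
        records.append(AssessmentRecord(
            dog_id=str(row.dog_id),
            assessment_date=str(getattr(row, "date", "")),
            scores={s: float(getattr(row, s)) for s in SUBTESTS},
        ))
    return records


def aggregate_assessment_frame(df: pd.DataFrame) -> pd.DataFrame:
    """One averaged score row per dog from a possibly-duplicated table."""
    records = assessments_from_frame(df)
    by_dog: dict[str, list[AssessmentRecord]] = {}
    for r in records:
        by_dog.setdefault(r.dog_id, []).append(r)
    rows = []
    for dog_id, recs in by_dog.items():
        agg = aggregate_assessments(recs)
        rows.append({"dog_id": dog_id, **agg.scores})
    return pd.DataFrame(rows)
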