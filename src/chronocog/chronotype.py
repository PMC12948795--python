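"""Composite Morningness Questionnaire scoring and chronotype grouping.

The CMQ is a 13-item self-report morningness instrument. Each item is
answered on a 4- or 5-option scale whose options carry integer point values;
the total (13-55) increases with morningness, so *higher score = earlier
chronotype*. Cohorts are split into quintile groups on the observed score
distribution: the lowest-scoring fifth is the ``late`` group and the
highest-scoring fifth the ``early`` group.

The scoring key ships as a JSON data file (``data/cmq_key.json``) with ten
4-point and three 5-point items, which is the only layout compatible with
the 13-55 total range. The item wordings in the shipped key are synthetic
placeholders; drop in a replacement file to score the published instrument
verbatim.

Also here, because they share the questionnaire/demographics CSV: body mass
index (kg/m^2) and waist-to-height ratio (dimensionless).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from chronocog.errors import ValidationError

#: Quintile group labels ordered from lowest CMQ score to highest.
GROUP_LABELS = ("late", "late_intermediate", "neutral", "early_intermediate", "early")

CMQ_MIN_SCORE = 13
CMQ_MAX_SCORE = 55


@dataclass(frozen=True)
class CMQItem:
    """One questionnaire item: its identifier and per-option point values."""

    id: str
    prompt: str
    points: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.points) not in (4, 5):
            raise ValidationError(f"item {self.id}: expected 4 or 5 options, got {len(self.points)}")
        if min(self.points) < 1:
            raise ValidationError(f"item {self.id}: option points must be >= 1")

    @property
    def min_points(self) -> int:
        return min(self.points)

    @property
    def max_points(self) -> int:
        return max(self.points)


@dataclass(frozen=True)
class CMQKey:
    """Ordered 13-item scoring key; totals must span exactly 13-55."""

    items: tuple[CMQItem, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 13:
            raise ValidationError(f"CMQ key must have exactly 13 items, got {len(self.items)}")
        lo = sum(item.min_points for item in self.items)
        hi = sum(item.max_points for item in self.items)
        if lo != CMQ_MIN_SCORE or hi != CMQ_MAX_SCORE:
            raise ValidationError(
                f"CMQ key totals must range {CMQ_MIN_SCORE}-{CMQ_MAX_SCORE}, got {lo}-{hi}"
            )


@dataclass(frozen=True)
class CMQResponse:
    """One participant's answers: 13 selected option indices (0-based)."""

    participant_id: str
    selections: tuple[int, ...]


@dataclass(frozen=True)
class ChronotypeAssignment:
    """Scored chronotype for one participant: total and quintile group."""

    participant_id: str
    score: int
    group: str


def load_cmq_key(path: str | Path | None = None) -> CMQKey:
    """Load a CMQ scoring key from JSON; defaults to the shipped key."""
    if path is None:
        raw = resources.files("chronocog.data").joinpath("cmq_key.json").read_text("utf-8")
    else:
        raw = Path(path).read_text("utf-8")
    spec = json.loads(raw)
    items = tuple(
        CMQItem(id=i["id"], prompt=i.get("prompt", ""), points=tuple(int(p) for p in i["points"]))
        for i in spec["items"]
    )
    return CMQKey(items=items)


def score_cmq(response: CMQResponse, key: CMQKey | None = None) -> int:
    """Sum the selected option points of all 13 items.

    Raises :class:`ValidationError` naming the offending item if a selection
    is missing or out of range.
    """
    if key is None:
        key = load_cmq_key()
    if len(response.selections) != len(key.items):
        raise ValidationError(
            f"response for {response.participant_id}: expected {len(key.items)} "
            f"selections, got {len(response.selections)}"
        )
    total = 0
    for item, sel in zip(key.items, response.selections):
        if sel is None or not 0 <= int(sel) < len(item.points):
            raise ValidationError(
                f"item {item.id}: selection {sel!r} outside 0..{len(item.points) - 1}"
            )
        total += item.points[int(sel)]
    return total


def assign_quintiles(
    scores: Iterable[tuple[str, int]],
    labels: Sequence[str] = GROUP_LABELS,
) -> list[ChronotypeAssignment]:
    """Split scored participants into quintile chronotype groups.

    Cut points are the empirical 20/40/60/80th percentiles of the observed
    scores; a participant's group index is the number of cut points strictly
    below their score, so tied scores never straddle a boundary (ties fall in
    the lower group) and group sizes may be unequal. Lowest scores are
    ``late``; highest are ``early`` (higher CMQ score = earlier chronotype).
    """
    pairs = list(scores)
    if len(pairs) < 5:
        raise ValidationError(f"quintile grouping needs >= 5 participants, got {len(pairs)}")
    values = np.asarray([s for _, s in pairs], dtype=float)
    cuts = np.percentile(values, [20, 40, 60, 80])
    out = []
    for pid, score in pairs:
        idx = int(np.sum(score > cuts))
        out.append(ChronotypeAssignment(participant_id=pid, score=int(score), group=labels[idx]))
    if len({a.group for a in out}) == 1:
        warnings.warn(
            "all participants share one chronotype group (tied scores); "
            "group comparisons are degenerate",
            stacklevel=2,
        )
    return out


def assignments_frame(assignments: Iterable[ChronotypeAssignment]) -> pd.DataFrame:
    """Tabulate assignments as (participant_id, cmq_score, chronotype_group)."""
    return pd.DataFrame(
        [(a.participant_id, a.score, a.group) for a in assignments],
        columns=["participant_id", "cmq_score", "chronotype_group"],
    )


def compute_bmi(mass_kg: float, height_m: float) -> float:
    """Body mass index: mass in kg divided by squared height in metres."""
    if mass_kg <= 0:
        raise ValidationError(f"mass_kg must be positive, got {mass_kg}")
    if height_m <= 0:
        raise ValidationError(f"height_m must be positive, got {height_m}")
    return mass_kg / height_m**2


def compute_wthr(waist_cm: float, height_cm: float) -> float:
    """Waist-to-height ratio: both circumference and height in centimetres."""
    if waist_cm <= 0:
        raise ValidationError(f"waist_cm must be positive, got {waist_cm}")
    if height_cm <= 0:
        raise ValidationError(f"height_cm must be positive, got {height_cm}")
    return waist_cm / height_cm
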