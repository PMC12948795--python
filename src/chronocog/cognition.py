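"""Cleaning of XNA trial logs into per-session cognitive outcomes.

The XNA (eXogenous-eNdogenous Attending) task has two parts completed on a
mobile phone: XNA1 (stimulus-oriented attending, 17 trials) and XNA2
(stimulus-independent attending with working-memory updating, 27 trials).
For each session x task we derive:

* ``mean_rt_ms`` — mean reaction time over *correct* trials after dropping
  implausible latencies (shorter than 125 ms or longer than 5000 ms;
  trials at exactly the bounds survive);
* ``n_errors`` — the count of incorrect responses, taken *before* RT
  filtering (errors are response-based, not latency-based);
* an engagement exclusion: sessions with >= 8 errors on XNA1 or >= 10 on
  XNA2 are removed on the assumption the participant disengaged;
* a caffeine flag: "yes" iff the reported caffeine in the prior hour is at
  least one espresso's worth (200 mg).

Reaction-time outcomes are typically right-skewed; ``boxcox_if_needed``
implements the normality gate (Shapiro-Wilk at alpha = 0.05) followed by a
profile-likelihood Box-Cox transform when the gate fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from chronocog.errors import ValidationError

RT_LOWER_MS = 125.0
RT_UPPER_MS = 5000.0
CAFFEINE_THRESHOLD_MG = 200.0
TRIALS_PER_TASK = {"XNA1": 17, "XNA2": 27}
ENGAGEMENT_ERROR_THRESHOLDS = {"XNA1": 8, "XNA2": 10}


@dataclass(frozen=True)
class TrialRecord:
    """One trial: task, position in the block, latency and correctness."""

    task: str
    trial_index: int
    rt_ms: float
    correct: bool

    def __post_init__(self) -> None:
        if self.task not in TRIALS_PER_TASK:
            raise ValidationError(f"unknown task {self.task!r}")
        if not self.rt_ms > 0:
            raise ValidationError(f"rt_ms must be positive, got {self.rt_ms}")
        if not 0 <= self.trial_index < TRIALS_PER_TASK[self.task]:
            raise ValidationError(
                f"trial_index {self.trial_index} outside 0..{TRIALS_PER_TASK[self.task] - 1} "
                f"for {self.task}"
            )


@dataclass(frozen=True)
class SessionRecord:
    """One task block within one cognitive session."""

    participant_id: str
    task: str
    session_timestamp: pd.Timestamp
    trials: tuple[TrialRecord, ...]
    caffeine_mg_prior_hour: float = 0.0

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValidationError("session has no trials")
        if any(t.task != self.task for t in self.trials):
            raise ValidationError("mixed tasks within one session record")


@dataclass(frozen=True)
class SessionSummary:
    """Cleaned per-session outcomes for one task block."""

    participant_id: str
    task: str
    session_timestamp: pd.Timestamp
    time_of_day_h: float
    mean_rt_ms: float | None
    n_errors: int
    n_valid_rt: int
    caffeine_flag: bool
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class TransformResult:
    """Outcome of the normality gate: Shapiro p, Box-Cox lambda and values.

    ``lmbda = 1`` with ``applied = False`` encodes the identity (no
    transform needed). The transform is strictly increasing on its input
    range for every lambda, so ranks are preserved.
    """

    lmbda: float
    shift: float
    shapiro_p: float
    applied: bool
    transformed: np.ndarray = field(repr=False, default=None)

    def apply(self, values: Sequence[float]) -> np.ndarray:
        x = np.asarray(values, dtype=float) + self.shift
        if not self.applied:
            return np.asarray(values, dtype=float)
        if np.any(x <= 0):
            raise ValidationError("values must be positive after shift for Box-Cox")
        return special.boxcox(x, self.lmbda)


def filter_rt_validity(
    trials: Iterable[TrialRecord],
    lower_ms: float = RT_LOWER_MS,
    upper_ms: float = RT_UPPER_MS,
) -> list[TrialRecord]:
    """Drop trials with implausible latencies.

    Removal is for RTs *shorter than* ``lower_ms`` or *longer than*
    ``upper_ms``; trials at exactly the bounds are retained. May return an
    empty list.
    """
    return [t for t in trials if lower_ms <= t.rt_ms <= upper_ms]


def summarize_session(
    session: SessionRecord,
    rt_bounds_ms: tuple[float, float] = (RT_LOWER_MS, RT_UPPER_MS),
    caffeine_threshold_mg: float = CAFFEINE_THRESHOLD_MG,
) -> SessionSummary:
    """Collapse a trial block to its session-level outcomes.

    Errors are counted over all trials, before any RT filtering; the mean
    RT is taken over correct trials that survive the validity filter. If no
    correct trial survives, the mean is missing and a warning is emitted.
    """
    n_errors = sum(1 for t in session.trials if not t.correct)
    valid = filter_rt_validity(session.trials, *rt_bounds_ms)
    correct_valid = [t.rt_ms for t in valid if t.correct]
    if correct_valid:
        mean_rt = float(np.mean(correct_valid))
    else:
        mean_rt = None
        warnings.warn(
            f"{session.participant_id} {session.task} @ {session.session_timestamp}: "
            "no correct trial survived the RT filter; mean RT missing",
            stacklevel=2,
        )
    ts = pd.Timestamp(session.session_timestamp)
    return SessionSummary(
        participant_id=session.participant_id,
        task=session.task,
        session_timestamp=ts,
        time_of_day_h=(ts - ts.normalize()).total_seconds() / 3600.0,
        mean_rt_ms=mean_rt,
        n_errors=n_errors,
        n_valid_rt=len(correct_valid),
        caffeine_flag=session.caffeine_mg_prior_hour >= caffeine_threshold_mg,
    )


def exclude_low_engagement(
    summary: SessionSummary,
    thresholds: dict[str, int] | None = None,
) -> SessionSummary:
    """Flag sessions whose error count suggests disengagement.

    A session is excluded when its error count is at or above the task
    threshold (8 for XNA1, 10 for XNA2). Idempotent.
    """
    thresholds = thresholds or ENGAGEMENT_ERROR_THRESHOLDS
    if summary.task in thresholds and summary.n_errors >= thresholds[summary.task]:
        return replace(summary, excluded=True, exclusion_reason="low engagement")
    return summary


def boxcox_if_needed(
    values: Sequence[float],
    alpha: float = 0.05,
    shift: float = 0.0,
    grid: tuple[float, float, float] = (-5.0, 5.0, 0.01),
) -> TransformResult:
    """Shapiro-Wilk normality gate with Box-Cox fallback.

    If the Shapiro-Wilk p-value is below ``alpha``, lambda is estimated by
    profile maximum likelihood on the grid ``[lo, hi]`` with the given step
    and the transformed values are returned; otherwise the identity
    transform is returned with the Shapiro p recorded. Nonpositive values
    require an explicit ``shift``.
    """
    x = np.asarray(values, dtype=float) + shift
    if x.size < 3:
        raise ValidationError("need at least 3 values for the normality gate")
    if np.any(x <= 0):
        raise ValidationError(
            "nonpositive values: pass a shift making all values positive before Box-Cox"
        )
    shapiro_p = float(stats.shapiro(x).pvalue)
    if shapiro_p >= alpha:
        return TransformResult(
            lmbda=1.0, shift=shift, shapiro_p=shapiro_p, applied=False, transformed=x - shift
        )
    lo, hi, step = grid
    lambdas = np.arange(lo, hi + step / 2, step)
    lls = np.array([stats.boxcox_llf(l, x) for l in lambdas])
    best = float(lambdas[int(np.argmax(lls))])
    return TransformResult(
        lmbda=best,
        shift=shift,
        shapiro_p=shapiro_p,
        applied=True,
        transformed=special.boxcox(x, best),
    )


def summaries_frame(summaries: Iterable[SessionSummary]) -> pd.DataFrame:
    """Tabulate session summaries for the sessions CSV."""
    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "task": s.task,
                "session_timestamp": s.session_timestamp.isoformat(),
                "time_of_day_h": s.time_of_day_h,
                "mean_rt_ms": s.mean_rt_ms,
                "n_errors": s.n_errors,
                "n_valid_rt": s.n_valid_rt,
                "caffeine_flag": s.caffeine_flag,
                "excluded": s.excluded,
                "exclusion_reason": s.exclusion_reason,
            }
            for s in summaries
        ]
    )


def sessions_from_trials_frame(trials: pd.DataFrame) -> list[SessionRecord]:
    """Group a trials table into SessionRecords.

    Expects columns participant_id, task, session_timestamp, trial_index,
    rt_ms, correct, caffeine_mg.
    """
    records = []
    for (pid, task, ts), grp in trials.groupby(
        ["participant_id", "task", "session_timestamp"], sort=True
    ):
        grp = grp.sort_values("trial_index")
        recs = tuple(
            TrialRecord(task=task, trial_index=int(r.trial_index), rt_ms=float(r.rt_ms), correct=bool(r.correct))
            for r in grp.itertuples()
        )
        records.append(
            SessionRecord(
                participant_id=str(pid),
                task=str(task),
                session_timestamp=pd.Timestamp(ts),
                trials=recs,
                caffeine_mg_prior_hour=float(grp["caffeine_mg"].iloc[0]),
            )
        )
    return records
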