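"""Actigraphy feature extraction from 60-s vector-magnitude epoch series.

A wrist accelerometer worn continuously for seven days yields one vector
magnitude (the Euclidean norm of triaxial counts) per 60-s epoch. From that
series the analysis needs four things:

* a **wear-time fraction** — devices off-wrist produce long runs of zeros;
  participants with < 90% wear are excluded (strict inequality: exactly 90%
  is retained);
* the **60-min rolling AUC** — a trailing-window discrete area under the
  vector-magnitude curve, the study's activity-intensity feature;
* **daily peak-activity times** and their across-day **circular mean** — the
  clock time at which the rolling AUC peaks each midnight-to-midnight day,
  vector-averaged so that peaks straddling midnight average correctly;
* the **7-day total AUC** — the plain sum of all observed epochs, an
  arbitrary overall-activity measure — and the **prior-hour activity**
  covariate evaluated at each cognitive-session timestamp.

Conventions (documented, replaceable): AUC is the left-Riemann sum of epoch
values (units arbitrary); rolling windows are trailing and half-open,
``(t - 60 min, t]``, indexed by their end time, so the rolling AUC and the
prior-hour covariate share one definition; non-wear is "any maximal run of
>= 60 consecutive zero-or-missing epochs, plus every missing epoch"; daily
peaks tie-break to the earliest window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from chronocog.errors import ExclusionError, UndefinedCircularMeanError, ValidationError

WEAR_FRACTION_THRESHOLD = 0.9
NONWEAR_ZERO_RUN_MINUTES = 60


@dataclass
class EpochSeries:
    """A regular epoch grid of nonnegative vector magnitudes for one person.

    ``values`` is a pandas Series on a strictly increasing, constant-spacing
    DatetimeIndex; missing epochs are explicit NaN entries on the grid,
    never silent jumps.
    """

    participant_id: str
    values: pd.Series
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex) or len(idx) == 0:
            raise ValidationError("EpochSeries requires a nonempty DatetimeIndex")
        deltas = np.diff(idx.asi8)
        step = self.epoch_seconds * 1_000_000_000
        if len(deltas) and not np.all(deltas == step):
            raise ValidationError(
                f"EpochSeries timestamps must be strictly increasing with "
                f"constant {self.epoch_seconds}-s spacing"
            )
        observed = self.values.dropna()
        if (observed < 0).any():
            raise ValidationError("vector magnitudes must be nonnegative")

    @classmethod
    def from_observations(
        cls,
        participant_id: str,
        timestamps: Sequence[pd.Timestamp] | pd.DatetimeIndex,
        values: Sequence[float],
        epoch_seconds: int = 60,
    ) -> "EpochSeries":
        """Build a series from possibly gappy observations.

        The observations are placed on the full regular grid spanning the
        first to last timestamp; unobserved grid epochs become NaN.
        """
        s = pd.Series(np.asarray(values, dtype=float), index=pd.DatetimeIndex(timestamps))
        s = s.sort_index()
        grid = pd.date_range(s.index[0], s.index[-1], freq=pd.Timedelta(seconds=epoch_seconds))
        return cls(participant_id, s.reindex(grid), epoch_seconds)

    @property
    def n_epochs(self) -> int:
        return len(self.values)

    @property
    def start(self) -> pd.Timestamp:
        return self.values.index[0]

    @property
    def end(self) -> pd.Timestamp:
        """End of the last epoch (exclusive of nothing: epochs are labelled by start)."""
        return self.values.index[-1] + pd.Timedelta(seconds=self.epoch_seconds)


@dataclass
class RollingAUCSeries:
    """Trailing-window AUC values indexed by window-end timestamp.

    Each value is the sum of the epoch values in its trailing window;
    windows containing any missing epoch are NaN.
    """

    participant_id: str
    values: pd.Series
    window_minutes: int = 60
    epoch_seconds: int = 60


@dataclass
class ActivitySummary:
    """Per-participant activity features and the wear-based inclusion flag."""

    participant_id: str
    wear_fraction: float
    included: bool
    total_auc_7day: float | None
    daily_peak_times: list[float] = field(default_factory=list)
    mean_peak_time: float | None = None


def _nonwear_mask(series: EpochSeries, zero_run_minutes: int) -> np.ndarray:
    vals = series.values.to_numpy()
    off = np.isnan(vals) | (vals == 0)
    run_len = int(round(zero_run_minutes * 60 / series.epoch_seconds))
    nonwear = np.isnan(vals).copy()
    # mark maximal zero-or-missing runs of >= run_len epochs
    if off.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], off.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start >= run_len:
                nonwear[start:stop] = True
    return nonwear


def compute_wear_fraction(
    series: EpochSeries, zero_run_minutes: int = NONWEAR_ZERO_RUN_MINUTES
) -> float:
    """Fraction of the epoch grid judged worn.

    Non-wear epochs are missing epochs plus any maximal run of at least
    ``zero_run_minutes`` consecutive zero (or missing) epochs.
    """
    if series.n_epochs == 0:
        raise ValidationError("empty epoch series")
    nonwear = _nonwear_mask(series, zero_run_minutes)
    return 1.0 - float(nonwear.mean())


def rolling_auc(series: EpochSeries, window_minutes: int = 60) -> RollingAUCSeries:
    """Trailing 60-min (by default) sum of epoch values, indexed by window end.

    Defined only where the full window is observed; windows touching a
    missing epoch are NaN. The window is half-open ``(t - w, t]`` so the
    value at end time ``t`` covers the epochs whose starts lie in
    ``[t - w, t)``.
    """
    w_seconds = window_minutes * 60
    if w_seconds % series.epoch_seconds != 0:
        raise ValidationError(
            f"window of {window_minutes} min is not a multiple of the "
            f"{series.epoch_seconds}-s epoch length"
        )
    w = w_seconds // series.epoch_seconds
    sums = series.values.rolling(window=w, min_periods=w).sum()
    sums.index = sums.index + pd.Timedelta(seconds=series.epoch_seconds)
    return RollingAUCSeries(
        participant_id=series.participant_id,
        values=sums,
        window_minutes=window_minutes,
        epoch_seconds=series.epoch_seconds,
    )


def _time_of_day_hours(ts: pd.Timestamp) -> float:
    return (ts - ts.normalize()).total_seconds() / 3600.0


def daily_peak_times(auc: RollingAUCSeries, min_day_coverage: float = 0.5) -> list[float]:
    """Clock hour of the maximum rolling AUC in each calendar day.

    Days (local midnight to midnight, by window-end timestamp) with fewer
    than ``min_day_coverage`` of their nominal windows observed are skipped;
    ties go to the earliest window of the day.
    """
    s = auc.values
    if len(s) == 0:
        raise ValidationError("empty rolling AUC series")
    windows_per_day = int(round(86400 / auc.epoch_seconds))
    peaks: list[float] = []
    for _, day in s.groupby(s.index.normalize()):
        if day.notna().sum() < min_day_coverage * windows_per_day:
            continue
        peaks.append(_time_of_day_hours(day.idxmax(skipna=True)))
    if not peaks:
        raise ValidationError("no day met the rolling-AUC coverage requirement")
    return peaks


def mean_peak_time(peaks: Iterable[float], method: str = "circular") -> float:
    """Average clock hours across days.

    The default is the circular mean: map each hour h to the angle
    2*pi*h/24, average the unit vectors and map back, so peaks either side
    of midnight average to midnight rather than noon. ``method="arithmetic"``
    is available for sensitivity analysis. A fully dispersed set of peaks
    (resultant vector length < 1e-9) has no defined circular mean.
    """
    hours = np.asarray(list(peaks), dtype=float)
    if hours.size == 0:
        raise ValidationError("mean_peak_time requires at least one peak")
    if method == "arithmetic":
        return float(np.mean(hours))
    if method != "circular":
        raise ValidationError(f"unknown averaging method {method!r}")
    angles = hours * (2 * np.pi / 24.0)
    x, y = np.cos(angles).mean(), np.sin(angles).mean()
    if np.hypot(x, y) < 1e-9:
        raise UndefinedCircularMeanError(
            "peak times are fully dispersed; circular mean undefined"
        )
    mean_h = float(np.arctan2(y, x) * (24.0 / (2 * np.pi)) % 24.0)
    # a tiny negative angle can round the modulus up to exactly 24.0;
    # keep the result in the half-open day [0, 24)
    return 0.0 if mean_h >= 24.0 else mean_h


def total_auc(
    series: EpochSeries,
    wear_threshold: float = WEAR_FRACTION_THRESHOLD,
    zero_run_minutes: int = NONWEAR_ZERO_RUN_MINUTES,
) -> float:
    """Sum of all observed epoch values over the monitoring period.

    Refuses (``ExclusionError``) for participants failing the wear filter,
    i.e. wear fraction strictly below ``wear_threshold``.
    """
    wf = compute_wear_fraction(series, zero_run_minutes)
    if wf < wear_threshold:
        raise ExclusionError(
            f"participant {series.participant_id} excluded: wear fraction "
            f"{wf:.3f} < {wear_threshold:.0%}"
        )
    return float(series.values.sum(skipna=True))


def activity_prior_window(
    series: EpochSeries, at: pd.Timestamp, window_minutes: int = 60
) -> float:
    """Activity in the hour before ``at``: sum over ``(at - w, at]``.

    ``at`` is truncated down to the nearest epoch-end boundary; the value is
    NaN when any epoch in the window is missing (including windows that
    extend before the start of recording). Raises for timestamps outside
    the recorded span.
    """
    at = pd.Timestamp(at)
    if not (series.start <= at <= series.end):
        raise ValidationError(
            f"timestamp {at} outside recorded span [{series.start}, {series.end}]"
        )
    w_seconds = window_minutes * 60
    if w_seconds % series.epoch_seconds != 0:
        raise ValidationError("window is not a multiple of the epoch length")
    w = w_seconds // series.epoch_seconds
    # epoch ends are grid starts shifted by one epoch; k epochs are complete by `at`
    k = int((at - series.start).total_seconds() // series.epoch_seconds)
    if k < w:
        return float("nan")
    window = series.values.iloc[k - w : k]
    if window.isna().any():
        return float("nan")
    return float(window.sum())


def summarize_activity(
    series: EpochSeries,
    window_minutes: int = 60,
    wear_threshold: float = WEAR_FRACTION_THRESHOLD,
    zero_run_minutes: int = NONWEAR_ZERO_RUN_MINUTES,
    peak_mean_method: str = "circular",
) -> ActivitySummary:
    """Full per-participant feature set; excluded participants get flags only."""
    wf = compute_wear_fraction(series, zero_run_minutes)
    included = wf >= wear_threshold
    if not included:
        return ActivitySummary(series.participant_id, wf, False, None, [], None)
    auc = rolling_auc(series, window_minutes)
    peaks = daily_peak_times(auc)
    return ActivitySummary(
        participant_id=series.participant_id,
        wear_fraction=wf,
        included=True,
        total_auc_7day=total_auc(series, wear_threshold, zero_run_minutes),
        daily_peak_times=peaks,
        mean_peak_time=mean_peak_time(peaks, method=peak_mean_method),
    )


def read_epoch_csv(
    path, participant_id: str | None = None, epoch_seconds: int = 60, skip_preamble: bool = False
) -> EpochSeries:
    """Read an epoch CSV (columns ``timestamp``, ``vector_magnitude``).

    ``skip_preamble=True`` tolerates ActiLife-style exports with a 10-line
    header block before the column row.
    """
    df = pd.read_csv(path, skiprows=10 if skip_preamble else 0)
    if participant_id is not None:
        pid = participant_id
    elif "participant_id" in df.columns:
        pid = str(df["participant_id"].iloc[0])
    else:
        import os

        pid = os.path.splitext(os.path.basename(str(path)))[0]
    return EpochSeries.from_observations(
        pid, pd.to_datetime(df["timestamp"]), df["vector_magnitude"].to_numpy(), epoch_seconds
    )


def features_frame(summaries: Iterable[ActivitySummary]) -> pd.DataFrame:
    """Tabulate activity summaries for the features CSV."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "participant_id": s.participant_id,
                "wear_fraction": s.wear_fraction,
                "included": s.included,
                "total_auc_7day": s.total_auc_7day,
                "mean_peak_time_h": s.mean_peak_time,
                "daily_peak_times_h": ";".join(f"{p:.4f}" for p in s.daily_peak_times),
            }
        )
    return pd.DataFrame(rows)
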