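"""Synthetic free-living cohort generator.

Emulates the structure of a naturalistic chronotype study: ~75 young adults
(ages truncated-normal 25 +/- 7 on [18, 30], 57% female) wear a wrist
accelerometer for 7 days (one vector-magnitude value per 60-s epoch) and
complete six mobile cognitive sessions (XNA1, 17 trials; XNA2, 27 trials)
near 09:00 and 21:00 on alternating days.

Generative components
---------------------
* **Activity**: a cosinor (mesor + amplitude * cos(2*pi*(t - acrophase)/24))
  clipped at zero, plus Poisson-timed activity bouts whose clock times
  concentrate (von Mises) around the person's acrophase, plus nonnegative
  half-normal noise. The acrophase decreases linearly with the latent
  morningness score — earlier chronotypes peak earlier. Optional non-wear
  gaps (>= 60-min zero runs) exercise the wear filter.
* **Questionnaire**: a 13-item CMQ response sheet whose rescored total
  equals the rounded latent chronotype (greedy point allocation; exact
  round trip).
* **Sessions**: timestamps are the 09:00/21:00 targets plus Gaussian jitter
  plus a lateness term proportional to (55 - latent score), so later
  chronotypes log on later. Per-trial reaction times are shifted lognormal
  (shift 125 ms) whose *median* equals the session's linear predictor
  (intercept, time of day, chronotype, chronotype x time, age, sex,
  caffeine flag, prior-hour activity, plus a participant random intercept);
  per-trial correctness is Bernoulli with a logit-linear analogue. A small
  contamination share (fast guesses / lapses) falls outside the 125-5000 ms
  validity bounds and exercises the RT filter.

Everything is deterministic under ``rng_seed``: identical config + seed
produce byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from chronocog import actigraphy as act
from chronocog.chronotype import CMQKey, CMQResponse, load_cmq_key, score_cmq
from chronocog.cognition import SessionRecord, TrialRecord
from chronocog.errors import ConfigurationError, GenerationError


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model; defaults are the study conditions.

    Reaction-time fixed effects default to the fitted XNA1 values that the
    inference layer is meant to recover (time of day in hours since
    midnight, chronotype as the 13-55 CMQ score, their product, age in
    years, male indicator, prior-hour caffeine flag, prior-hour activity
    AUC). Activity parameters are in arbitrary vector-magnitude units per
    60-s epoch.
    """

    n_participants: int = 75
    n_days: int = 7
    epoch_seconds: int = 60
    start_date: str = "2024-01-01"
    session_days: tuple[int, ...] = (0, 2, 4)
    session_times_h: tuple[float, ...] = (9.0, 21.0)
    rng_seed: int = 0

    # cohort marginals
    age_mean: float = 25.0
    age_sd: float = 7.0
    age_range: tuple[float, float] = (18.0, 30.0)
    p_female: float = 0.57
    chronotype_range: tuple[float, float] = (13.0, 55.0)

    # reaction-time model (ms)
    beta_intercept: float = 1195.21
    beta_time: float = -15.65
    beta_chronotype: float = -13.39
    beta_interaction: float = 0.54
    beta_age: float = 7.39
    beta_sex: float = 12.15
    beta_caffeine: float = 29.68
    beta_activity: float = -3e-5
    random_intercept_sd: float = 100.0
    residual_rt_sd: float = 150.0
    rt_shift_ms: float = 125.0
    rt_contamination_rate: float = 0.02

    # per-trial error model (logit scale, same predictors)
    error_logit_intercept: float = -1.2
    error_logit_time: float = -0.03
    error_logit_chronotype: float = -0.03
    error_logit_interaction: float = 1.6e-3
    error_logit_age: float = 0.0
    error_logit_sex: float = 0.0
    error_logit_caffeine: float = 0.0
    error_logit_activity: float = 0.0

    # activity model
    mesor: float = 1500.0
    amplitude: float = 1200.0
    amplitude_cv: float = 0.1
    acrophase_base_h: float = 15.0
    acrophase_slope_h_per_point: float = -0.1
    acrophase_reference_score: float = 34.0
    bout_rate_per_day: float = 1.5
    bout_duration_mean_min: float = 30.0
    bout_magnitude: float = 1000.0
    bout_time_kappa: float = 2.0
    activity_noise_sd: float = 300.0
    nonwear_gap_probability: float = 0.05
    nonwear_gap_minutes: float = 90.0

    # session timing and caffeine
    session_jitter_sd_min: float = 20.0
    lateness_slope_min_per_point: float = 1.0
    caffeine_propensity_range: tuple[float, float] = (0.0, 0.5)

    def validate(self) -> None:
        if self.n_participants < 5:
            raise ConfigurationError("n_participants: must be >= 5 (quintile grouping)")
        if self.n_days < 1:
            raise ConfigurationError("n_days: must be >= 1")
        if self.epoch_seconds <= 0 or 3600 % self.epoch_seconds != 0:
            raise ConfigurationError("epoch_seconds: must be positive and divide 3600")
        for name in (
            "age_sd",
            "random_intercept_sd",
            "residual_rt_sd",
            "activity_noise_sd",
            "session_jitter_sd_min",
            "amplitude_cv",
            "bout_rate_per_day",
            "bout_duration_mean_min",
            "bout_magnitude",
            "amplitude",
            "mesor",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be nonnegative")
        for name in ("p_female", "nonwear_gap_probability", "rt_contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: must be a probability in [0, 1]")
        lo, hi = self.chronotype_range
        if not (13.0 <= lo < hi <= 55.0):
            raise ConfigurationError("chronotype_range: must be within [13, 55] with lo < hi")
        if any(d < 0 or d >= self.n_days for d in self.session_days):
            raise ConfigurationError("session_days: every day must lie within 0..n_days-1")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent person-level state driving all of a participant's data."""

    index: int
    participant_id: str
    age: float
    sex: str  # "female" | "male"
    latent_chronotype: float
    random_intercept: float
    activity_amplitude: float
    activity_acrophase: float  # local clock hour in [0, 24)
    caffeine_propensity: float
    height_m: float
    mass_kg: float
    waist_cm: float

    def __post_init__(self) -> None:
        if not 13.0 <= self.latent_chronotype <= 55.0:
            raise ConfigurationError("latent_chronotype: must lie in [13, 55]")
        if not 0.0 <= self.activity_acrophase < 24.0:
            raise ConfigurationError("activity_acrophase: must lie in [0, 24)")


@dataclass
class StudyData:
    """One complete simulated study: people, questionnaires, epochs, trials."""

    config: SimulationConfig
    profiles: list[ParticipantProfile]
    responses: list[CMQResponse]
    series: dict[str, act.EpochSeries]
    sessions: list[SessionRecord]


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def acrophase_for_chronotype(latent_chronotype: float, config: SimulationConfig) -> float:
    """Clock hour of peak activity implied by a morningness score (wrapped)."""
    h = config.acrophase_base_h + config.acrophase_slope_h_per_point * (
        latent_chronotype - config.acrophase_reference_score
    )
    return float(h % 24.0)


def linear_predictor(
    config: SimulationConfig,
    time_of_day_h: float,
    chronotype: float,
    age: float,
    male: bool,
    caffeine: bool,
    activity_prior_60min: float,
    random_intercept: float = 0.0,
) -> float:
    """Median trial reaction time (ms) for one session's predictor values."""
    return (
        config.beta_intercept
        + config.beta_time * time_of_day_h
        + config.beta_chronotype * chronotype
        + config.beta_interaction * chronotype * time_of_day_h
        + config.beta_age * age
        + config.beta_sex * float(male)
        + config.beta_caffeine * float(caffeine)
        + config.beta_activity * activity_prior_60min
        + random_intercept
    )


def error_probability(
    config: SimulationConfig,
    time_of_day_h: float,
    chronotype: float,
    age: float,
    male: bool,
    caffeine: bool,
    activity_prior_60min: float,
) -> float:
    """Per-trial probability of an incorrect response."""
    logit = (
        config.error_logit_intercept
        + config.error_logit_time * time_of_day_h
        + config.error_logit_chronotype * chronotype
        + config.error_logit_interaction * chronotype * time_of_day_h
        + config.error_logit_age * age
        + config.error_logit_sex * float(male)
        + config.error_logit_caffeine * float(caffeine)
        + config.error_logit_activity * activity_prior_60min
    )
    return float(expit(logit))


def reference_log_sigma(config: SimulationConfig) -> float:
    """Log-scale SD of the trial RT lognormal.

    The trial noise has a constant coefficient of variation: sigma is set
    so that the trial-level SD equals ``residual_rt_sd`` at a cohort-central
    linear predictor (time of day 15 h, chronotype 34, age 25, female, no
    caffeine, no prior-hour activity). A constant log-sigma keeps the
    expected trial RT exactly linear in the predictor (up to one global
    factor exp(sigma^2/2) ~= 1.016 at defaults), so session means inherit
    the generative linear structure without curvature artefacts.
    """
    ref = linear_predictor(config, 15.0, 34.0, 25.0, False, False, 0.0)
    return config.residual_rt_sd / max(ref - config.rt_shift_ms, 1.0)


def null_interaction_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """Study conditions with the chronotype x time interaction removed.

    Used for type-I-error calibration of the interaction test. The default
    positive interaction is what keeps the evening reaction-time scale of
    early chronotypes away from the 125-ms shift, so removing it alone
    would push the linear predictor negative for extreme score/time
    combinations; the intercept is therefore raised to keep the generative
    model well defined while every slope, noise source and design feature
    stays at its study value.
    """
    base = config or SimulationConfig()
    return base.replace(beta_interaction=0.0, beta_intercept=1700.0)


def generate_cohort(config: SimulationConfig) -> list[ParticipantProfile]:
    """Draw participant profiles matching the cohort marginals.

    Ages are truncated-normal (mean 25, SD 7) on [18, 30]; sex is female
    with probability 0.57; the latent morningness score is uniform over the
    configured range (all five quintiles populated by construction).
    """
    config.validate()
    rng = _rng(config.rng_seed, 0)
    n = config.n_participants
    a, b = config.age_range
    ages = stats.truncnorm.rvs(
        (a - config.age_mean) / config.age_sd,
        (b - config.age_mean) / config.age_sd,
        loc=config.age_mean,
        scale=config.age_sd,
        size=n,
        random_state=rng,
    )
    female = rng.random(n) < config.p_female
    lo, hi = config.chronotype_range
    latent = rng.uniform(lo, hi, n)
    u = rng.normal(0.0, config.random_intercept_sd, n)
    amp = config.amplitude * np.exp(rng.normal(0.0, config.amplitude_cv, n))
    propensity = rng.uniform(*config.caffeine_propensity_range, n)
    height = rng.normal(1.70, 0.09, n).clip(1.45, 2.05)
    bmi = rng.normal(22.9, 2.8, n).clip(16.0, 35.0)
    wthr = rng.normal(0.47, 0.05, n).clip(0.35, 0.65)
    return [
        ParticipantProfile(
            index=i,
            participant_id=f"P{i:03d}",
            age=float(ages[i]),
            sex="female" if female[i] else "male",
            latent_chronotype=float(latent[i]),
            random_intercept=float(u[i]),
            activity_amplitude=float(amp[i]),
            activity_acrophase=acrophase_for_chronotype(float(latent[i]), config),
            caffeine_propensity=float(propensity[i]),
            height_m=float(height[i]),
            mass_kg=float(bmi[i] * height[i] ** 2),
            waist_cm=float(wthr[i] * height[i] * 100.0),
        )
        for i in range(n)
    ]


def simulate_actigraphy(profile: ParticipantProfile, config: SimulationConfig) -> act.EpochSeries:
    """One participant's epoch series: cosinor + bouts + noise + gaps."""
    config.validate()
    rng = _rng(config.rng_seed, 1, profile.index)
    eps = config.epoch_seconds
    per_day = 86400 // eps
    n = config.n_days * per_day
    t0 = pd.Timestamp(config.start_date)
    hours = (np.arange(n) * eps / 3600.0) % 24.0
    vals = profile.activity_amplitude * np.cos(
        2 * np.pi * (hours - profile.activity_acrophase) / 24.0
    )
    vals = np.clip(config.mesor + vals, 0.0, None)

    n_bouts = rng.poisson(config.bout_rate_per_day * config.n_days) if config.bout_rate_per_day > 0 else 0
    for _ in range(n_bouts):
        day = rng.integers(config.n_days)
        angle = rng.vonmises(2 * np.pi * profile.activity_acrophase / 24.0, config.bout_time_kappa)
        tod_h = (angle % (2 * np.pi)) * 24.0 / (2 * np.pi)
        dur = max(1, int(round(rng.exponential(config.bout_duration_mean_min) * 60 / eps)))
        start = int(day) * per_day + int(tod_h / 24.0 * per_day)
        vals[start : min(start + dur, n)] += config.bout_magnitude

    if config.activity_noise_sd > 0:
        vals = vals + np.abs(rng.normal(0.0, config.activity_noise_sd, n))

    if config.nonwear_gap_probability > 0:
        gap_epochs = int(round(config.nonwear_gap_minutes * 60 / eps))
        for day in range(config.n_days):
            if rng.random() < config.nonwear_gap_probability:
                start = day * per_day + int(rng.integers(0, max(1, per_day - gap_epochs)))
                vals[start : start + gap_epochs] = 0.0

    idx = pd.date_range(t0, periods=n, freq=pd.Timedelta(seconds=eps))
    return act.EpochSeries(profile.participant_id, pd.Series(vals, index=idx), eps)


def simulate_cmq(
    profile: ParticipantProfile, config: SimulationConfig, key: CMQKey | None = None
) -> CMQResponse:
    """A response sheet whose rescored total equals the rounded latent score.

    Greedy allocation: start every item at its minimum-point option, then
    hand out the remaining points item by item up to each item's maximum.
    The round trip ``score_cmq(simulate_cmq(p)) == round(latent)`` is exact
    for any key whose items carry contiguous integer point values.
    """
    if key is None:
        key = load_cmq_key()
    target = int(round(profile.latent_chronotype))
    target = min(max(target, 13), 55)
    remaining = target - sum(item.min_points for item in key.items)
    selections = []
    for item in key.items:
        give = min(remaining, item.max_points - item.min_points)
        # pick the option worth exactly min + give points
        want = item.min_points + give
        try:
            sel = item.points.index(want)
        except ValueError as exc:  # non-contiguous custom key
            raise GenerationError(
                f"item {item.id}: no option worth {want} points; greedy allocation "
                "requires contiguous point values"
            ) from exc
        selections.append(sel)
        remaining -= give
    response = CMQResponse(participant_id=profile.participant_id, selections=tuple(selections))
    assert score_cmq(response, key) == target
    return response


def simulate_sessions(
    profile: ParticipantProfile,
    series: act.EpochSeries,
    config: SimulationConfig,
    auc: act.RollingAUCSeries | None = None,
) -> list[SessionRecord]:
    """Six cognitive sessions (XNA1 + XNA2 blocks) for one participant."""
    config.validate()
    rng = _rng(config.rng_seed, 2, profile.index)
    shift = config.rt_shift_ms
    sigma = reference_log_sigma(config)
    male = profile.sex == "male"
    chron = profile.latent_chronotype
    records: list[SessionRecord] = []
    day0 = pd.Timestamp(config.start_date)
    for day in config.session_days:
        for target_h in config.session_times_h:
            jitter_min = rng.normal(0.0, config.session_jitter_sd_min)
            late_min = config.lateness_slope_min_per_point * (55.0 - chron)
            t_h = float(np.clip(target_h + (jitter_min + late_min) / 60.0, 0.5, 23.5))
            ts = (day0 + pd.Timedelta(days=int(day), hours=t_h)).round("s")
            if not (series.start <= ts <= series.end):
                raise GenerationError(
                    f"session time {ts} outside the simulated actigraphy span"
                )
            auc60 = act.activity_prior_window(series, ts)
            if np.isnan(auc60):
                auc60 = 0.0
            drank = rng.random() < profile.caffeine_propensity
            caffeine_mg = float(np.round(rng.gamma(2.0, 90.0), 1)) if drank else 0.0
            caffeine = caffeine_mg >= 200.0
            tod = (ts - ts.normalize()).total_seconds() / 3600.0
            lp = linear_predictor(
                config, tod, chron, profile.age, male, caffeine, auc60, profile.random_intercept
            )
            if lp <= shift:
                raise GenerationError(
                    f"linear predictor {lp:.1f} ms not above the {shift:.0f}-ms shift; "
                    "RT model undefined for this configuration"
                )
            p_err = error_probability(config, tod, chron, profile.age, male, caffeine, auc60)
            for task, n_trials in (("XNA1", 17), ("XNA2", 27)):
                mu = np.log(lp - shift)
                rt = shift + np.exp(rng.normal(mu, sigma, n_trials))
                correct = rng.random(n_trials) >= p_err
                if config.rt_contamination_rate > 0:
                    contam = rng.random(n_trials) < config.rt_contamination_rate
                    if contam.any():
                        k = int(contam.sum())
                        fast = rng.random(k) < 0.8
                        junk = np.where(
                            fast, rng.uniform(50.0, 120.0, k), rng.uniform(5001.0, 8000.0, k)
                        )
                        rt = rt.copy()
                        rt[contam] = junk
                        correct = correct.copy()
                        correct[contam] = rng.random(k) < 0.5
                trials = tuple(
                    TrialRecord(task=task, trial_index=j, rt_ms=float(rt[j]), correct=bool(correct[j]))
                    for j in range(n_trials)
                )
                records.append(
                    SessionRecord(
                        participant_id=profile.participant_id,
                        task=task,
                        session_timestamp=ts,
                        trials=trials,
                        caffeine_mg_prior_hour=caffeine_mg,
                    )
                )
    return records


def simulate_study(config: SimulationConfig, key: CMQKey | None = None) -> StudyData:
    """Generate a complete in-memory study dataset."""
    config.validate()
    if key is None:
        key = load_cmq_key()
    profiles = generate_cohort(config)
    responses, series, sessions = [], {}, []
    for p in profiles:
        s = simulate_actigraphy(p, config)
        series[p.participant_id] = s
        responses.append(simulate_cmq(p, config, key))
        sessions.extend(simulate_sessions(p, s, config))
    return StudyData(config=config, profiles=profiles, responses=responses, series=series, sessions=sessions)


def cohort_frame(study: StudyData) -> pd.DataFrame:
    """Cohort CSV table: demographics plus the 13 CMQ item selections (1-based)."""
    rows = []
    for p, r in zip(study.profiles, study.responses):
        row = {
            "participant_id": p.participant_id,
            "age": round(p.age, 1),
            "sex": p.sex,
            "height_m": round(p.height_m, 3),
            "mass_kg": round(p.mass_kg, 1),
            "waist_cm": round(p.waist_cm, 1),
        }
        for j, sel in enumerate(r.selections, start=1):
            row[f"cmq_{j:02d}"] = sel + 1
        rows.append(row)
    return pd.DataFrame(rows)


def trials_frame(study: StudyData) -> pd.DataFrame:
    """Trials CSV table: one row per trial across all sessions and tasks."""
    rows = []
    for rec in study.sessions:
        for t in rec.trials:
            rows.append(
                (
                    rec.participant_id,
                    t.task,
                    rec.session_timestamp.isoformat(),
                    t.trial_index,
                    round(t.rt_ms, 1),
                    int(t.correct),
                    rec.caffeine_mg_prior_hour,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "task",
            "session_timestamp",
            "trial_index",
            "rt_ms",
            "correct",
            "caffeine_mg",
        ],
    )


def write_dataset(config: SimulationConfig, out_dir: str | Path) -> StudyData:
    """Write the full dataset as UTF-8 RFC-4180 CSVs; returns the study.

    Layout: ``cohort.csv``, ``trials.csv`` and one ``epochs_<id>.csv`` per
    participant (columns ``timestamp``, ``vector_magnitude``). Fixed float
    formatting makes output byte-identical for identical config + seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    cohort_frame(study).to_csv(out / "cohort.csv", index=False, float_format="%.3f")
    trials_frame(study).to_csv(out / "trials.csv", index=False, float_format="%.1f")
    for pid, s in study.series.items():
        df = pd.DataFrame(
            {
                "timestamp": s.values.index.strftime("%Y-%m-%dT%H:%M:%S"),
                "vector_magnitude": s.values.to_numpy(),
            }
        )
        df.to_csv(out / f"epochs_{pid}.csv", index=False, float_format="%.3f")
    return study
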