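"""The synthetic cohort generator: marginals, determinism, generative laws."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronocog import simulate as sim
from chronocog.chronotype import score_cmq
from chronocog.errors import ConfigurationError
from chronocog.simulate import ParticipantProfile, SimulationConfig


def _profile(
    latent=34.0,
    u=0.0,
    acrophase=15.0,
    amplitude=1200.0,
    age=25.0,
    sex="female",
    propensity=0.0,
    index=0,
):
    return ParticipantProfile(
        index=index,
        participant_id=f"P{index:03d}",
        age=age,
        sex=sex,
        latent_chronotype=latent,
        random_intercept=u,
        activity_amplitude=amplitude,
        activity_acrophase=acrophase,
        caffeine_propensity=propensity,
        height_m=1.7,
        mass_kg=65.0,
        waist_cm=75.0,
    )


class TestCohort:
    def test_size_and_age_range(self):
        profiles = sim.generate_cohort(SimulationConfig(n_participants=75, rng_seed=1))
        assert len(profiles) == 75
        assert all(18 <= p.age <= 30 for p in profiles)
        assert all(13 <= p.latent_chronotype <= 55 for p in profiles)

    def test_determinism_under_seed(self):
        cfg = SimulationConfig(n_participants=5, rng_seed=1)
        assert sim.generate_cohort(cfg) == sim.generate_cohort(cfg)

    def test_age_mean_large_sample(self):
        """Truncated-normal(25, 7) on [18, 30] has mean ~24.2; check by LLN."""
        profiles = sim.generate_cohort(SimulationConfig(n_participants=10_000, rng_seed=2))
        assert 24 <= np.mean([p.age for p in profiles]) <= 26

    def test_sex_marginal(self):
        profiles = sim.generate_cohort(SimulationConfig(n_participants=10_000, rng_seed=3))
        frac_female = np.mean([p.sex == "female" for p in profiles])
        assert frac_female == pytest.approx(0.57, abs=0.02)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="n_participants"):
            sim.generate_cohort(SimulationConfig(n_participants=3))
        with pytest.raises(ConfigurationError, match="epoch_seconds"):
            SimulationConfig(epoch_seconds=7).validate()
        with pytest.raises(ConfigurationError, match="residual_rt_sd"):
            SimulationConfig(residual_rt_sd=-1).validate()


class TestActigraphySimulation:
    def _quiet(self, **kw):
        base = dict(
            amplitude=0.0,
            amplitude_cv=0.0,
            activity_noise_sd=0.0,
            bout_rate_per_day=0.0,
            nonwear_gap_probability=0.0,
            mesor=500.0,
            rng_seed=0,
            n_days=2,
            session_days=(0, 1),
        )
        base.update(kw)
        return SimulationConfig(**base)

    def test_degenerate_cosinor_constant(self):
        cfg = self._quiet()
        series = sim.simulate_actigraphy(_profile(amplitude=0.0), cfg)
        assert np.allclose(series.values.to_numpy(), 500.0)
        assert series.n_epochs == 2 * 1440

    def test_argmax_at_acrophase(self):
        cfg = self._quiet(amplitude=300.0)
        series = sim.simulate_actigraphy(_profile(acrophase=14.0, amplitude=300.0), cfg)
        day1 = series.values.iloc[:1440]
        peak = day1.idxmax()
        assert (peak - peak.normalize()).total_seconds() / 3600 == pytest.approx(14.0)

    def test_acrophase_linear_in_chronotype(self):
        cfg = SimulationConfig(acrophase_slope_h_per_point=-0.1)
        a = sim.acrophase_for_chronotype(30.0, cfg)
        b = sim.acrophase_for_chronotype(40.0, cfg)
        assert b - a == pytest.approx(-1.0)

    def test_nonwear_gap_is_zero_run(self):
        cfg = self._quiet(nonwear_gap_probability=1.0, nonwear_gap_minutes=90.0)
        series = sim.simulate_actigraphy(_profile(amplitude=0.0), cfg)
        vals = series.values.to_numpy()
        assert (vals == 0).sum() >= 90  # at least one inserted gap


class TestCMQSimulation:
    def test_saturation(self, key):
        cfg = SimulationConfig()
        hi = sim.simulate_cmq(_profile(latent=55.0), cfg, key)
        assert score_cmq(hi, key) == 55
        assert all(key.items[i].points[s] == key.items[i].max_points for i, s in enumerate(hi.selections))
        lo = sim.simulate_cmq(_profile(latent=13.0), cfg, key)
        assert score_cmq(lo, key) == 13

    def test_fractional_latent_rounds(self, key):
        resp = sim.simulate_cmq(_profile(latent=34.2), SimulationConfig(), key)
        assert score_cmq(resp, key) == 34

    @given(st.floats(13.0, 55.0))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_roundtrip_property(self, key, latent):
        resp = sim.simulate_cmq(_profile(latent=latent), SimulationConfig(), key)
        assert score_cmq(resp, key) == int(round(latent))


class TestSessionSimulation:
    def test_six_sessions_with_fixed_trial_counts(self, small_config):
        profile = _profile()
        series = sim.simulate_actigraphy(profile, small_config)
        records = sim.simulate_sessions(profile, series, small_config)
        assert len(records) == 12  # 6 sessions x 2 task blocks
        for rec in records:
            assert len(rec.trials) == {"XNA1": 17, "XNA2": 27}[rec.task]
        times = sorted({r.session_timestamp for r in records})
        assert len(times) == 6
        mornings = [t for t in times if t.hour < 12]
        assert len(mornings) == 3

    def test_degenerate_model_constant_rt(self):
        cfg = SimulationConfig(
            n_days=1,
            session_days=(0,),
            beta_time=0.0,
            beta_chronotype=0.0,
            beta_interaction=0.0,
            beta_age=0.0,
            beta_sex=0.0,
            beta_caffeine=0.0,
            beta_activity=0.0,
            residual_rt_sd=0.0,
            rt_contamination_rate=0.0,
            amplitude=0.0,
            activity_noise_sd=0.0,
            bout_rate_per_day=0.0,
            nonwear_gap_probability=0.0,
        )
        profile = _profile(u=0.0, amplitude=0.0)
        series = sim.simulate_actigraphy(profile, cfg)
        records = sim.simulate_sessions(profile, series, cfg)
        for rec in records:
            for t in rec.trials:
                assert t.rt_ms == pytest.approx(cfg.beta_intercept)

    def test_later_chronotypes_log_on_later(self):
        cfg = SimulationConfig(session_jitter_sd_min=0.0, lateness_slope_min_per_point=1.0)
        early, late = _profile(latent=55.0, index=0), _profile(latent=13.0, index=0)
        s_early = sim.simulate_actigraphy(early, cfg)
        rec_e = sim.simulate_sessions(early, s_early, cfg)
        rec_l = sim.simulate_sessions(late, sim.simulate_actigraphy(late, cfg), cfg)
        # identical rng stream, so the timing difference is purely the lateness term
        dt = rec_l[0].session_timestamp - rec_e[0].session_timestamp
        assert dt == pd.Timedelta(minutes=42)

    def test_synchrony_gap_shrinks_with_time_of_day(self):
        """With beta_c < 0 < beta_ct, the expected morning RT disadvantage of
        late chronotypes narrows monotonically toward the evening."""
        cfg = SimulationConfig()
        t_grid = np.linspace(8, 22, 15)
        gap = [
            sim.linear_predictor(cfg, t, 17.0, 25, False, False, 0.0)
            - sim.linear_predictor(cfg, t, 51.0, 25, False, False, 0.0)
            for t in t_grid
        ]
        assert gap[0] > 0
        assert all(a > b for a, b in zip(gap, gap[1:]))

    def test_marginal_time_slope_at_scale(self):
        """OLS slope of session-mean RT on time of day converges to
        beta_t + beta_ct * E[chronotype] when session timing is chronotype-free."""
        cfg = SimulationConfig(
            n_participants=2000,
            rng_seed=17,
            lateness_slope_min_per_point=0.0,
            nonwear_gap_probability=0.0,
        )
        profiles = sim.generate_cohort(cfg)
        xs, ys = [], []
        for p in profiles:
            series = sim.simulate_actigraphy(p, cfg)
            for rec in sim.simulate_sessions(p, series, cfg):
                if rec.task != "XNA1":
                    continue
                rts = [t.rt_ms for t in rec.trials if t.correct and 125 <= t.rt_ms <= 5000]
                if not rts:
                    continue
                ts = rec.session_timestamp
                xs.append((ts - ts.normalize()).total_seconds() / 3600)
                ys.append(np.mean(rts))
        slope = np.polyfit(xs, ys, 1)[0]
        expected = cfg.beta_time + cfg.beta_interaction * 34.0
        assert slope == pytest.approx(expected, abs=1.0)


class TestDatasetDeterminism:
    def test_identical_csv_bytes(self, tmp_path, small_config):
        a, b = tmp_path / "a", tmp_path / "b"
        sim.write_dataset(small_config, a)
        sim.write_dataset(small_config, b)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        assert mismatch == [] and errors == []

    def test_trials_frame_counts(self, small_config):
        study = sim.simulate_study(small_config)
        trials = sim.trials_frame(study)
        n_sessions = small_config.n_participants * 6
        assert len(trials) == n_sessions * (17 + 27)
        assert set(trials["task"]) == {"XNA1", "XNA2"}
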