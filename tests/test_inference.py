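"""ANOVA, mixed-model fitting, table assembly and the power calculation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronocog import inference
from chronocog import simulate as sim
from chronocog.chronotype import ChronotypeAssignment
from chronocog.cognition import SessionSummary
from chronocog.errors import ValidationError
from tests.conftest import make_series


def _anova_oracle(groups):
    """Brute-force sums-of-squares one-way ANOVA."""
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(sum((x - np.mean(v)) ** 2 for x in v) for v in groups.values())
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, dfb, dfw, ssb / (ssb + ssw)


class TestAnova:
    def test_identical_groups_zero_effect(self):
        res = inference.oneway_anova_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.partial_eta_sq == pytest.approx(0.0, abs=1e-12)

    def test_df_formula_unequal_groups(self):
        rng = np.random.default_rng(12)
        sizes = {"early": 15, "early_intermediate": 15, "neutral": 13, "late_intermediate": 16, "late": 16}
        groups = {g: rng.normal(0, 1, n) for g, n in sizes.items()}
        res = inference.oneway_anova_posthoc(groups)
        assert (res.df_between, res.df_within) == (4, 70)
        assert len(res.pairwise) == 10

    def test_matches_ss_oracle(self):
        rng = np.random.default_rng(13)
        groups = {f"g{i}": list(rng.normal(i * 0.3, 1.0, rng.integers(3, 20))) for i in range(4)}
        res = inference.oneway_anova_posthoc(groups)
        F, dfb, dfw, eta = _anova_oracle(groups)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert (res.df_between, res.df_within) == (dfb, dfw)
        assert res.partial_eta_sq == pytest.approx(eta, abs=1e-10)

    def test_bonferroni_correction(self):
        rng = np.random.default_rng(14)
        groups = {g: rng.normal(0, 1, 10) for g in "abc"}
        res = inference.oneway_anova_posthoc(groups)
        # recompute one raw pairwise p and check the x3 correction
        allv = groups["a"], groups["b"]
        _, _, dfw, _ = _anova_oracle(groups)
        ssw = sum(sum((x - np.mean(v)) ** 2 for x in v) for v in groups.values())
        msw = ssw / dfw
        t = (np.mean(allv[0]) - np.mean(allv[1])) / np.sqrt(msw * (1 / 10 + 1 / 10))
        raw = 2 * stats.t.sf(abs(t), dfw)
        pair = next(p for p in res.pairwise if {p[0], p[1]} == {"a", "b"})
        assert pair[2] == pytest.approx(min(1.0, raw * 3), abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            inference.oneway_anova_posthoc({"a": [1.0], "b": [1, 2, 3]})


def _manual_inputs(n_participants=5, n_sessions=6, excluded_flags=None):
    """Deterministic hand-built inputs for assemble_analysis_table."""
    pids = [f"P{i:03d}" for i in range(n_participants)]
    series = {pid: make_series(np.full(7 * 1440, 100.0), participant_id=pid) for pid in pids}
    assignments = [ChronotypeAssignment(pid, 20 + i, "neutral") for i, pid in enumerate(pids)]
    demographics = pd.DataFrame(
        {"participant_id": pids, "age": [25.0] * n_participants, "sex": ["female"] * n_participants}
    )
    summaries = []
    for pid in pids:
        for s in range(n_sessions):
            for task in ("XNA1", "XNA2"):
                ts = pd.Timestamp("2024-01-01") + pd.Timedelta(days=s, hours=10)
                summaries.append(
                    SessionSummary(
                        participant_id=pid,
                        task=task,
                        session_timestamp=ts,
                        time_of_day_h=10.0,
                        mean_rt_ms=500.0,
                        n_errors=1,
                        n_valid_rt=15,
                        caffeine_flag=False,
                        excluded=bool(excluded_flags and (pid, s, task) in excluded_flags),
                        exclusion_reason="low engagement" if excluded_flags and (pid, s, task) in excluded_flags else "",
                    )
                )
    return series, assignments, summaries, demographics


class TestAssemble:
    def test_row_count_without_exclusions(self):
        df = inference.assemble_analysis_table(*_manual_inputs())
        # 5 participants x 6 sessions x 2 tasks x 2 outcomes
        assert len(df) == 5 * 6 * 2 * 2
        for outcome in ("rt", "errors"):
            assert (df["outcome_name"] == outcome).sum() == 60

    def test_excluded_sessions_drop_rows_exactly(self):
        excluded = {("P000", 0, "XNA1"), ("P001", 2, "XNA1"), ("P002", 4, "XNA1")}
        df = inference.assemble_analysis_table(*_manual_inputs(excluded_flags=excluded))
        rt_xna1 = df[(df["outcome_name"] == "rt") & (df["task"] == "XNA1")]
        err_xna1 = df[(df["outcome_name"] == "errors") & (df["task"] == "XNA1")]
        assert len(rt_xna1) == 30 - 3
        assert len(err_xna1) == 30 - 3
        assert df.attrs["dropped"]["session_excluded"] == 3

    def test_wear_excluded_participant_absent(self):
        series, assignments, summaries, demo = _manual_inputs()
        del series["P003"]  # participant removed by the wear filter upstream
        df = inference.assemble_analysis_table(series, assignments, summaries, demo)
        assert "P003" not in set(df["participant_id"])

    def test_corrupt_join_raises(self):
        series, assignments, summaries, demo = _manual_inputs()
        assignments = [a for a in assignments if a.participant_id != "P002"]
        with pytest.raises(ValidationError, match="P002"):
            inference.assemble_analysis_table(series, assignments, summaries, demo)

    def test_activity_covariate_from_prior_hour(self):
        df = inference.assemble_analysis_table(*_manual_inputs())
        assert np.allclose(df["activity_prior_60min"], 60 * 100.0)


class TestFitLmm:
    def test_wald_consistency(self):
        table = inference.simulate_analysis_table(sim.SimulationConfig(rng_seed=21))
        res = inference.fit_lmm(table, "rt", "XNA1")
        for _, row in res.terms.iterrows():
            excludes_zero = row["ci_lower"] > 0 or row["ci_upper"] < 0
            assert excludes_zero == (row["p"] < 0.05)

    def test_pure_fixed_model_coincides_with_ols(self):
        """With no participant-level variation, REML collapses to OLS."""
        cfg = sim.SimulationConfig(
            n_participants=30,
            rng_seed=22,
            random_intercept_sd=0.0,
            nonwear_gap_probability=0.0,
        )
        table = inference.simulate_analysis_table(cfg)
        res = inference.fit_lmm(table, "rt", "XNA1")
        d = table[(table["outcome_name"] == "rt") & (table["task"] == "XNA1")]
        X = inference._design_matrix(d).to_numpy()
        y = d["outcome_value"].to_numpy()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(res.terms["estimate"].to_numpy(), ols, rtol=1e-3, atol=0.5)

    def test_null_slopes_covered_in_most_replicates(self):
        cfg = sim.SimulationConfig(
            beta_time=0.0,
            beta_chronotype=0.0,
            beta_interaction=0.0,
            beta_age=0.0,
            beta_sex=0.0,
            beta_caffeine=0.0,
            beta_activity=0.0,
            n_participants=40,
        )
        covered = []
        for seed in range(12):
            table = inference.simulate_analysis_table(cfg.replace(rng_seed=100 + seed))
            res = inference.fit_lmm(table, "rt", "XNA1")
            slopes = res.terms.drop(index="Intercept")
            covered.append(((slopes["ci_lower"] <= 0) & (0 <= slopes["ci_upper"])).to_numpy())
        coverage = np.mean(covered, axis=0)
        assert (coverage >= 0.75).all()
        assert coverage.mean() >= 0.85

    def test_collinear_design_rejected(self):
        df = inference.assemble_analysis_table(*_manual_inputs())
        # time_of_day constant at 10 h -> chronotype_x_time is 10x chronotype
        with pytest.raises(ValidationError, match="collinear"):
            inference.fit_lmm(df, "rt", "XNA1")

    def test_missing_subset_rejected(self):
        table = inference.simulate_analysis_table(sim.SimulationConfig(n_participants=6, rng_seed=23))
        with pytest.raises(ValidationError):
            inference.fit_lmm(table, "rt", task="XNA9")


class TestRequiredSample:
    @staticmethod
    def _oracle(f, k, m, alpha, power, rho):
        df1 = k - 1
        n = 2 * k
        while True:
            lam = n * m * f**2 / (1 + (m - 1) * rho)
            crit = stats.f.ppf(1 - alpha, df1, n - k)
            if 1 - stats.ncf.cdf(crit, df1, n - k, lam) >= power:
                return n
            n += 1

    def test_degenerate_power_floor(self):
        assert inference.required_sample_anova_rm(0.2, 5, 6, power=1e-9) == 10

    def test_monotone_in_effect_size(self):
        n1 = inference.required_sample_anova_rm(0.2, 5, 6)
        n2 = inference.required_sample_anova_rm(0.4, 5, 6)
        assert n2 < n1

    def test_matches_search_oracle(self):
        ours = inference.required_sample_anova_rm(0.2, 5, 6, alpha=0.05, power=0.8, corr_rm=0.5)
        assert ours == self._oracle(0.2, 5, 6, 0.05, 0.8, 0.5)

    def test_invalid_arguments(self):
        with pytest.raises(ValidationError):
            inference.required_sample_anova_rm(0.0, 5, 6)
        with pytest.raises(ValidationError):
            inference.required_sample_anova_rm(0.2, 5, 6, power=1.5)
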