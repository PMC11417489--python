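"""Inferential stage: group tests, GG ANOVA, log-linear regression."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from wearadhere import (
    CohortConfig,
    CollinearityError,
    DegenerateGroupError,
    compare_by_group,
    fit_log_linear,
    generate_cohort,
    gg_epsilon,
    rm_anova_gg,
    seasonality_profile,
    sensitivity_split,
)
from wearadhere.stats import RegressionSpec, prepare_daily_matrix
from wearadhere.day_accounting import build_day_records
from wearadhere.adherence import summarize_cohort
from wearadhere.synthetic import profiles_to_frame


class TestCompareByGroup:
    def test_identical_values_give_statistic_zero_p_one(self):
        res = compare_by_group([5.0] * 30, ["a"] * 10 + ["b"] * 10 + ["c"] * 10, "continuous")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateGroupError):
            compare_by_group([1.0, 2.0], ["a", "a"], "continuous")

    def test_two_group_continuous_uses_rank_sum(self):
        rng = np.random.default_rng(0)
        res = compare_by_group(
            rng.normal(size=40), ["a"] * 20 + ["b"] * 20, "continuous"
        )
        assert res.test_name == "wilcoxon-rank-sum"

    def test_three_group_continuous_uses_kruskal_wallis(self):
        rng = np.random.default_rng(0)
        res = compare_by_group(
            rng.normal(size=30), ["a", "b", "c"] * 10, "continuous"
        )
        assert res.test_name == "kruskal-wallis"

    def test_fisher_2x2_matches_hypergeometric_enumeration(self):
        """Diagonal 2x2 table (9,0 / 0,9) has expected cells of 4.5, so the
        exact fallback fires; exhaustive enumeration of all tables with the
        observed margins gives the two-sided p = 2 / C(18,9)."""
        values = ["x"] * 9 + ["y"] * 9
        groups = ["g1"] * 9 + ["g2"] * 9
        res = compare_by_group(values, groups, "categorical")
        assert res.test_name == "fisher-exact"
        # oracle: enumerate a in [0,9]; P(table) hypergeometric; two-sided
        probs = np.array(
            [comb(9, a) * comb(9, 9 - a) / comb(18, 9) for a in range(10)]
        )
        p_obs = probs[9]
        expected = probs[probs <= p_obs + 1e-12].sum()
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert res.p_value == pytest.approx(2 / comb(18, 9), rel=1e-9)

    def test_expected_cells_of_exactly_5_keep_chi_squared(self):
        # strict fallback trigger: any expected cell strictly below 5
        res = compare_by_group(
            ["x"] * 10 + ["y"] * 10, ["g1"] * 10 + ["g2"] * 10, "categorical"
        )
        assert res.test_name == "chi-squared"

    def test_small_cells_trigger_exact_fallback_rxc(self):
        values = ["x"] * 4 + ["y"] * 3 + ["z"] * 5
        groups = (["g1", "g2", "g3"] * 4)[:12]
        res = compare_by_group(values, groups, "categorical", random_state=1)
        assert res.test_name == "exact-monte-carlo"
        assert 0 < res.p_value <= 1

    def test_power_grows_with_sample_size(self):
        """A real location gradient across groups yields smaller p at
        larger n (Monte-Carlo power check)."""

        def median_p(n_per_group, seeds=range(15)):
            ps = []
            for s in seeds:
                rng = np.random.default_rng(s)
                vals = np.concatenate(
                    [rng.normal(loc, 1.0, n_per_group) for loc in (0.0, 0.3, 0.6)]
                )
                groups = np.repeat(["a", "b", "c"], n_per_group)
                ps.append(compare_by_group(vals, groups, "continuous").p_value)
            return np.median(ps)

        assert median_p(120) < median_p(15)


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        k = 5
        cov = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert gg_epsilon(cov) == pytest.approx(1.0, abs=1e-12)

    def test_two_timepoints_exactly_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 2))
        assert gg_epsilon(np.cov(a, rowvar=False)) == 1.0

    def test_bounds_hold_for_random_covariances(self):
        rng = np.random.default_rng(1)
        for k in (3, 4, 6):
            for _ in range(20):
                a = rng.normal(size=(k + 5, k))
                eps = gg_epsilon(np.cov(a, rowvar=False))
                assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_matches_independent_textbook_formula_6x4(self):
        """Direct evaluation from the elements of the covariance matrix
        (mean-of-row/column form), coded independently of the package."""
        rng = np.random.default_rng(42)
        y = rng.normal(size=(6, 4)) + 2.0 * rng.normal(size=(6, 1))
        s = np.cov(y, rowvar=False)
        k = s.shape[0]
        sbar = s.mean()
        row_means = s.mean(axis=1)
        num = (k * (np.trace(s) / k - sbar)) ** 2
        den = (k - 1) * (
            (s**2).sum() - 2 * k * (row_means**2).sum() + k**2 * sbar**2
        )
        assert gg_epsilon(s) == pytest.approx(num / den, rel=1e-10)


class TestRMAnova:
    def _data(self, n=12, k=4, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        g = np.array(["a", "b", "c"] * (n // 3))
        return y, g

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        y, g = self._data()
        res = rm_anova_gg(y, g)
        df = pd.DataFrame(y, columns=[f"t{j}" for j in range(y.shape[1])])
        df["subj"] = [f"s{i}" for i in range(len(y))]
        df["grp"] = g
        long = df.melt(id_vars=["subj", "grp"], var_name="time", value_name="val")
        ref = pg.mixed_anova(
            data=long, dv="val", within="time", subject="subj", between="grp"
        ).set_index("Source")
        assert res.f_group == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
        assert res.f_time == pytest.approx(ref.loc["time", "F"], rel=1e-9)
        assert res.f_interaction == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)

    def test_two_timepoints_epsilon_exactly_one(self):
        y, g = self._data(k=2)
        assert rm_anova_gg(y, g).epsilon == 1.0

    def test_group_effect_detected_when_present(self):
        rng = np.random.default_rng(3)
        k = 6
        y = rng.normal(size=(30, k))
        g = np.repeat(["lo", "hi"], 15)
        y[15:] += 2.0
        res = rm_anova_gg(y, g)
        assert res.p_group < 0.001

    def test_prepare_daily_matrix_drops_sparse_days_and_incomplete_subjects(
        self, small_day_records, small_summaries
    ):
        groups = small_summaries.set_index("participant_id")["daily_group"]
        mat, g, days = prepare_daily_matrix(small_day_records, groups, min_coverage=0.8)
        assert not np.isnan(mat).any()
        assert mat.shape[0] == len(g)
        assert mat.shape[1] == len(days)
        assert ((mat >= 0) & (mat <= 1)).all()


def _exact_log_linear_data(n=260, seed=0):
    """Profiles plus adherence constructed exactly log-linear (no noise)."""
    rng = np.random.default_rng(seed)
    profiles = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "age_years": rng.uniform(40, 85, n),
            "sex": rng.choice(["male", "female"], n),
            "device_type": rng.choice(["ICD", "CRT-D"], n),
            "known_af": rng.random(n) < 0.4,
            "hf_hospitalization": rng.random(n) < 0.3,
            "cardiovascular_comorbidity": rng.random(n) < 0.6,
            "smoking": rng.choice(["never", "active", "previous"], n),
            "kccq_clinical": rng.uniform(20, 100, n),
            "schedule_type": rng.choice(["biweekly", "monthly", "both"], n),
        }
    )
    truth = {
        "age_per_decade": 1.14,
        "female_sex": 0.96,
        "schedule_monthly": 1.24,
        "schedule_both": 1.09,
        "smoking_active": 0.90,
    }
    eta = (
        math.log(0.2)
        + np.log(truth["age_per_decade"]) * profiles["age_years"] / 10
        + np.log(truth["female_sex"]) * (profiles["sex"] == "female")
        + np.log(truth["schedule_monthly"]) * (profiles["schedule_type"] == "monthly")
        + np.log(truth["schedule_both"]) * (profiles["schedule_type"] == "both")
        + np.log(truth["smoking_active"]) * (profiles["smoking"] == "active")
    )
    summaries = pd.DataFrame(
        {
            "participant_id": profiles["participant_id"],
            "long_term_adherence": np.exp(eta),
        }
    )
    return profiles, summaries, truth


class TestLogLinearRegression:
    def test_noiseless_recovery_to_1e6(self):
        profiles, summaries, truth = _exact_log_linear_data()
        effects = {e.term: e for e in fit_log_linear(summaries, profiles)}
        for term, value in truth.items():
            assert effects[term].relative_effect == pytest.approx(value, rel=1e-6)
        # covariates absent from the generating law recover the null 1.0
        assert effects["kccq_clinical"].relative_effect == pytest.approx(1.0, rel=1e-6)

    def test_ci_brackets_point_estimate(self):
        profiles, summaries, _ = _exact_log_linear_data()
        summaries = summaries.assign(
            long_term_adherence=summaries["long_term_adherence"]
            * np.exp(np.random.default_rng(1).normal(0, 0.1, len(summaries)))
        )
        for e in fit_log_linear(summaries, profiles):
            assert e.ci95[0] <= e.relative_effect <= e.ci95[1]

    def test_duplicated_covariate_raises_collinearity_error(self):
        profiles, summaries, _ = _exact_log_linear_data()
        spec = RegressionSpec(
            covariates=("age_per_decade", "age_per_decade__dup", "female_sex")
        )
        with pytest.raises(CollinearityError) as err:
            fit_log_linear(summaries, profiles, spec)
        assert any("age_per_decade" in t for t in err.value.terms)

    def test_zero_handling_modes(self):
        profiles, summaries, _ = _exact_log_linear_data()
        summaries.loc[:10, "long_term_adherence"] = 0.0
        excl = fit_log_linear(summaries, profiles, RegressionSpec(zero_handling="exclude"))
        offs = fit_log_linear(
            summaries, profiles, RegressionSpec(zero_handling="offset_epsilon")
        )
        assert len(excl) == len(offs)

    def test_null_simulation_ci_covers_one(self):
        """With no covariate effects every relative effect's CI should
        cover 1.0 at roughly the nominal 95% rate."""
        rng = np.random.default_rng(7)
        hits = total = 0
        for s in range(30):
            profiles, summaries, _ = _exact_log_linear_data(n=160, seed=100 + s)
            null = summaries.assign(
                long_term_adherence=np.exp(math.log(0.5) + rng.normal(0, 0.3, 160))
            )
            for e in fit_log_linear(null, profiles):
                hits += e.ci95[0] <= 1.0 <= e.ci95[1]
                total += 1
        assert 0.90 <= hits / total <= 0.99


class TestSensitivitySplit:
    def test_degenerate_threshold_rejected(self, small_summaries, small_profiles_frame):
        with pytest.raises(DegenerateGroupError):
            sensitivity_split(small_summaries, small_profiles_frame, threshold=0.0)

    def test_binary_split_merges_optimal_and_moderate(
        self, small_summaries, small_profiles_frame
    ):
        res = sensitivity_split(small_summaries, small_profiles_frame, threshold=0.75)
        n_adh = res["n_adherent"].iloc[0]
        n_non = res["n_non_adherent"].iloc[0]
        assert n_adh + n_non == len(small_summaries)
        # membership oracle: >= 0.75 is exactly optimal+moderate except the
        # closed low bound at 0.75 itself
        direct = (
            small_summaries["long_term_adherence"].fillna(-1) >= 0.75
        ).sum()
        assert n_adh == direct


class TestSeasonality:
    def test_single_month_participant(self):
        recs = pd.DataFrame(
            {
                "participant_id": "P1",
                "study_day": range(1, 32),
                "date": pd.date_range("2022-01-01", periods=31).date,
                "wear_hours": 24.0,
                "day_class": "VALID",
            }
        )
        prof = seasonality_profile(recs)
        assert prof[1] == pytest.approx(1.0)
        assert prof.drop(index=1).isna().all()

    def test_sinusoidal_seasonal_effect_peak_recovered(self):
        cfg = CohortConfig(
            n_participants=80,
            seed=13,
            seasonal_amplitude=0.5,
            seasonal_peak_month=7,
            npc_nonwear_rate=0.0,
            withdrawal_hazard_low=0.0,
        )
        profiles, schedules, day_wear = generate_cohort(cfg)
        records = build_day_records(day_wear, schedules, protocol_days=cfg.protocol_days)
        prof = seasonality_profile(records)
        peak = int(prof.idxmax())
        assert peak in (6, 7, 8)
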