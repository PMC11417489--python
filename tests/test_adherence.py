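"""Adherence scores, group cut points, trajectories, data return."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wearadhere import (
    DayClass,
    classify_groups,
    cohort_summary,
    daily_adherence,
    data_return,
    group_share_pct,
    long_term_adherence,
    period_trajectory,
)
from wearadhere.types import AccountingError


class TestLongTermAdherence:
    @pytest.mark.parametrize(
        "valid,expected,value", [(166, 166, 1.0), (0, 166, 0.0), (90, 120, 0.75)]
    )
    def test_forced_arithmetic(self, valid, expected, value):
        assert long_term_adherence(valid, expected) == pytest.approx(value)

    def test_zero_expected_days_is_flagged_undefined(self):
        assert math.isnan(long_term_adherence(0, 0))

    def test_valid_above_expected_rejected(self):
        with pytest.raises(AccountingError):
            long_term_adherence(10, 5)


def _records(wears, classes):
    return pd.DataFrame(
        {
            "participant_id": "P1",
            "study_day": range(1, len(wears) + 1),
            "wear_hours": wears,
            "day_class": [c.value for c in classes],
        }
    )


class TestDailyAdherence:
    def test_all_full_days(self):
        recs = _records([24.0] * 5, [DayClass.VALID] * 5)
        assert daily_adherence(recs) == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        recs = _records([24.0, 22.0, 23.0], [DayClass.VALID] * 3)
        assert daily_adherence(recs) == pytest.approx((24 + 22 + 23) / (3 * 24))

    def test_zero_wear_and_logistics_days_excluded_by_default(self):
        recs = _records(
            [24.0, 0.0, 12.0, 20.0],
            [DayClass.VALID, DayClass.PC_NONWEAR, DayClass.CHANGEOVER, DayClass.PC_NONWEAR],
        )
        # changeover and zero-wear days drop; mean of 24 and 20
        assert daily_adherence(recs) == pytest.approx((24 + 20) / (2 * 24))
        assert daily_adherence(recs, denominator="expected") == pytest.approx(
            (24 + 0 + 20) / (3 * 24)
        )

    def test_no_qualifying_day_is_undefined(self):
        recs = _records([0.0, 0.0], [DayClass.PC_NONWEAR] * 2)
        assert math.isnan(daily_adherence(recs))


class TestGroupCutPoints:
    @pytest.mark.parametrize(
        "lt,expected",
        [
            (0.965, "optimal"),  # upper IQR bound of the reported distribution
            (0.882, "moderate"),  # reported median long-term adherence
            (0.95, "optimal"),
            (0.75, "low"),
            (0.7501, "moderate"),
            (0.0, "low"),
        ],
    )
    def test_long_term_labels(self, lt, expected):
        assert classify_groups(lt, lt)[0] == expected

    def test_daily_uses_90_cut(self):
        assert classify_groups(0.92, 0.90)[1] == "optimal"
        assert classify_groups(0.92, 0.899)[1] == "moderate"

    def test_undefined_classifies_low(self):
        assert classify_groups(float("nan"), float("nan")) == ("low", "low")

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_monotone_raising_adherence_never_lowers_group(self, a, b):
        order = {"low": 0, "moderate": 1, "optimal": 2}
        lo, hi = sorted((a, b))
        assert order[classify_groups(hi, hi)[0]] >= order[classify_groups(lo, lo)[0]]
        assert order[classify_groups(hi, hi)[1]] >= order[classify_groups(lo, lo)[1]]


class TestPeriodTrajectory:
    def test_all_valid_days_optimal_everywhere(self):
        recs = _records([24.0] * 182, [DayClass.VALID] * 182)
        adh, groups = period_trajectory(recs)
        assert groups == ("optimal", "optimal", "optimal")
        assert adh == pytest.approx((1.0, 1.0, 1.0))

    def test_withdrawal_at_day_61_drops_periods_two_and_three(self):
        classes = [DayClass.VALID] * 60 + [DayClass.POST_WITHDRAWAL] * 122
        recs = _records([24.0] * 60 + [0.0] * 122, classes)
        adh, groups = period_trajectory(recs)
        assert groups == ("optimal", "dropped_out", "dropped_out")
        assert math.isnan(adh[1]) and math.isnan(adh[2])

    def test_trajectory_counts_sum_to_cohort_size(self, small_summaries):
        report = cohort_summary(small_summaries)
        assert report["trajectories"]["count"].sum() == len(small_summaries)


class TestDataReturn:
    @pytest.mark.parametrize("valid,total,value", [(182, 182, 1.0), (91, 182, 0.5)])
    def test_fraction(self, valid, total, value):
        assert data_return(valid, total) == pytest.approx(value)

    def test_theoretical_cohort_maximum(self):
        # 296 participants x 182 protocol days
        summaries = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(296)],
                "valid_days": 0,
                "expected_days": 182,
                "long_term_adherence": 0.0,
                "mean_daily_adherence": 0.0,
                "lt_group": "low",
                "daily_group": "low",
                "period1_group": "low",
                "period2_group": "low",
                "period3_group": "low",
                "data_return": 0.0,
            }
        )
        report = cohort_summary(summaries, protocol_days=182)
        assert report["theoretical_max_days"] == 53872

    def test_never_exceeds_long_term_adherence(self, small_summaries):
        ok = small_summaries["expected_days"] > 0
        sub = small_summaries[ok]
        assert (
            sub["data_return"] <= sub["long_term_adherence"] + 1e-12
        ).all()
        equal = sub["expected_days"] == 182
        assert np.allclose(
            sub.loc[equal, "data_return"], sub.loc[equal, "long_term_adherence"]
        )


class TestCohortSummary:
    def test_reported_group_share_arithmetic(self):
        assert group_share_pct(127, 296) == 42.9
        assert group_share_pct(163, 296) == 55.1
        assert group_share_pct(83, 296) == 28.0

    def test_group_percentages_sum_to_100_within_rounding(self, small_summaries):
        report = cohort_summary(small_summaries)
        for key in ("lt_group_counts", "daily_group_counts"):
            assert report[key]["pct"].sum() == pytest.approx(100.0, abs=0.2)
            assert report[key]["count"].sum() == len(small_summaries)

    def test_single_participant_median_is_value_iqr_zero(self):
        one = pd.DataFrame(
            {
                "participant_id": ["P1"],
                "valid_days": [100],
                "expected_days": [170],
                "long_term_adherence": [100 / 170],
                "mean_daily_adherence": [0.97],
                "lt_group": ["moderate"],
                "daily_group": ["optimal"],
                "period1_group": ["moderate"],
                "period2_group": ["moderate"],
                "period3_group": ["moderate"],
                "data_return": [100 / 182],
            }
        )
        med, lo, hi = cohort_summary(one)["long_term_adherence_median_iqr"]
        assert med == pytest.approx(100 / 170)
        assert hi - lo == pytest.approx(0.0)

    def test_median_matches_direct_sort_oracle(self, small_summaries):
        report = cohort_summary(small_summaries)
        vals = np.sort(small_summaries["long_term_adherence"].dropna().to_numpy())
        n = len(vals)
        direct = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
        assert report["long_term_adherence_median_iqr"][0] == pytest.approx(direct)

    def test_equal_period_weights_bracket_full_adherence(self):
        """With equal expected days per period the overall adherence is a
        mean of the period adherences, hence inside their min-max."""
        classes = (
            [DayClass.VALID] * 30 + [DayClass.PC_NONWEAR] * 30
            + [DayClass.VALID] * 45 + [DayClass.PC_NONWEAR] * 15
            + [DayClass.VALID] * 62
        )
        recs = _records([24.0] * len(classes), classes)
        recs.loc[recs["day_class"] == DayClass.PC_NONWEAR.value, "wear_hours"] = 10.0
        adh, _ = period_trajectory(recs, period_edges=(60, 120), protocol_days=182)
        overall = sum(
            1 for c in classes if c is DayClass.VALID
        ) / len(classes)
        assert min(adh) - 1e-9 <= overall <= max(adh) + 1e-9
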