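"""Coverage tables: rounding convention, row conservation, hand tallies."""

import pytest

from conftest import build_cohort
from vaxtiming.classify import classify_cohort, end_of_study_doses
from vaxtiming.tables import (
    compression_summary,
    cumulative_table,
    percentage,
    round_half_away,
    timing_histograms,
    window_table,
)


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(61.95, 62.0), (61.94, 61.9), (0.05, 0.1), (-0.05, -0.1), (93.35, 93.4), (7.0, 7.0)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x, 1) == expected

    def test_differs_from_bankers(self):
        assert round_half_away(0.25, 1) == 0.3  # round() would give 0.2
        assert round(0.25, 1) == 0.2

    def test_percentage_zero_denominator_nan(self):
        import math

        assert math.isnan(percentage(1, 0))


@pytest.fixture
def hand_cohort():
    """10 infants with a mix of timely, late, early, compressed and no doses."""
    return build_cohort(
        {
            "T1": {"visit_ages": [42, 70, 98], "dose_ages": [43, 71, 99]},   # timely x3
            "T2": {"visit_ages": [45, 72, 100], "dose_ages": [45, 73, 101]},  # timely x3
            "L1": {"visit_ages": [42, 75, 103], "dose_ages": [75, 103]},      # dose1 in w2
            "E1": {"visit_ages": [38, 90], "dose_ages": [38, 60]},            # early + compressed, no w1 visit
            "H1": {"visit_ages": [42, 70, 98]},                               # attends, no doses
            "H2": {"visit_ages": [44, 71]},
            "D1": {"visit_ages": [42], "dose_ages": [42]},                    # dropout after w1
            "D2": {"visit_ages": [20]},                                       # left before w1
            "M1": {"visit_ages": [50, 80, 110], "dose_ages": [50, 110]},      # missed w2 dose
            "C1": {"visit_ages": [42, 96, 98], "dose_ages": [68, 90, 120]},   # compressed dose 2 in w2
        }
    )


class TestWindowTable:
    def test_hand_tally(self, schedule, hand_cohort):
        wt = window_table(schedule, classify_cohort(schedule, hand_cohort)).set_index("window_index")
        # window 1 visitors: T1,T2,L1,H1,H2,D1,M1,C1 (E1's 60-d visit not in w1; D2 never in w1)
        w1 = wt.loc[1]
        assert w1["visits"] == 8
        assert w1["received"] == 5  # T1,T2,D1,M1,C1(68)
        assert w1["missed"] == 3
        # up-to-date in w1 among visitors: T1,T2,D1,M1,C1 (E1 possesses early dose but didn't visit w1)
        assert w1["up_to_date"] == 5
        assert w1["unvaccinated"] == 3  # L1,H1,H2
        w2 = wt.loc[2]
        # w2 visitors: T1,T2,L1,H1,H2,M1,C1,E1(90)
        assert w2["visits"] == 8
        assert w2["received"] == 4  # T1(71),T2(73),L1(75),C1(90); E1's doses are at 38/60
        assert w2["missed"] == 4  # H1,H2,M1,E1
        assert w2["compressed"] == 1  # C1: 90-68=22 < 28
        assert w2["up_to_date"] == 4  # T1,T2,C1,E1 (early dose counts toward possession)
        assert w2["unvaccinated"] == 2  # H1,H2

    def test_row_conservation(self, schedule, hand_cohort):
        wt = window_table(schedule, classify_cohort(schedule, hand_cohort))
        assert (wt["received"] + wt["missed"] == wt["visits"]).all()

    def test_perfect_cohort_all_up_to_date(self, schedule):
        cohort = build_cohort(
            {f"I{i}": {"visit_ages": [42, 70, 98], "dose_ages": [42, 70, 98]} for i in range(6)}
        )
        wt = window_table(schedule, classify_cohort(schedule, cohort))
        assert (wt["missed"] == 0).all()
        assert (wt["up_to_date_pct"] == 100.0).all()


class TestCumulativeTable:
    def test_per_range_and_cumulative(self, schedule, hand_cohort):
        ct = cumulative_table(schedule, classify_cohort(schedule, hand_cohort))
        # dose 1 first receipts: early E1(38); w1 T1,T2,D1,M1,C1; w2 L1
        assert ct.per_range.loc["DTP1"].tolist() == [1, 5, 1, 0, 0]
        assert ct.cumulative.loc["DTP1"].tolist() == [6, 7, 7]
        # each dose row non-decreasing across window ends
        assert (ct.cumulative.diff(axis=1).fillna(0) >= 0).all().all()

    def test_doses_per_window_margin(self, schedule, hand_cohort):
        ct = cumulative_table(schedule, classify_cohort(schedule, hand_cohort))
        # window 2 events: L1 75, T1 71, T2 73, E1? (60 is w1? no, 60 is in 41-69 w1) -> C1 96, M1? none
        assert ct.doses_per_window["window2"] == 4

    def test_two_doses_in_one_window_counted_as_events(self, schedule):
        cohort = build_cohort({"A": {"visit_ages": [98, 126], "dose_ages": [98, 126]}})
        ct = cumulative_table(schedule, classify_cohort(schedule, cohort))
        assert ct.doses_per_window["window3"] == 2
        assert ct.per_range.loc["DTP1", "window3"] == 1
        assert ct.per_range.loc["DTP2", "window3"] == 1

    def test_empty_cohort_zeros(self, schedule):
        cohort = build_cohort({"A": {"visit_ages": [42]}})
        ct = cumulative_table(schedule, classify_cohort(schedule, cohort))
        assert (ct.per_range.to_numpy() == 0).all()


class TestHistograms:
    def test_single_spike_week_six(self, schedule):
        cohort = build_cohort({f"I{i}": {"visit_ages": [45], "dose_ages": [45]} for i in range(5)})
        h = timing_histograms(schedule, classify_cohort(schedule, cohort))
        assert h["weekly"].to_dict("records") == [{"dose_number": 1, "week": 6, "count": 5}]

    def test_early_mass_confined(self, schedule):
        cohort = build_cohort(
            {f"I{i}": {"visit_ages": [35 + i], "dose_ages": [35 + i]} for i in range(6)}
        )
        h = timing_histograms(schedule, classify_cohort(schedule, cohort))
        assert h["early_ages"]["age"].between(35, 40).all()
        assert h["early_ages"]["count"].sum() == 6

    def test_spacing_split_by_compression(self, schedule):
        cohort = build_cohort(
            {
                "A": {"visit_ages": [42, 70], "dose_ages": [42, 70]},  # spacing 28, appropriate
                "B": {"visit_ages": [42, 60], "dose_ages": [42, 60]},  # spacing 18, compressed
            }
        )
        h = timing_histograms(schedule, classify_cohort(schedule, cohort))
        sp = h["spacing"].set_index("spacing")
        assert not sp.loc[28, "compressed"]
        assert sp.loc[18, "compressed"].item() is True


def test_compression_summary_thresholds(schedule):
    cohort = build_cohort(
        {
            "A": {"visit_ages": [42, 66, 90], "dose_ages": [42, 66, 90]},  # gaps 24, 24
            "B": {"visit_ages": [42, 61], "dose_ages": [42, 61]},          # gap 19
            "C": {"visit_ages": [42, 70], "dose_ages": [42, 70]},          # gap 28
        }
    )
    cs = compression_summary(classify_cohort(schedule, cohort)).set_index("threshold")
    assert cs.loc[28, "infants"] == 2 and cs.loc[28, "events"] == 3
    assert cs.loc[25, "infants"] == 2 and cs.loc[25, "events"] == 3
    assert cs.loc[20, "infants"] == 1 and cs.loc[20, "events"] == 1
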