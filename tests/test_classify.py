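"""Adherence classifier: worked examples, brute-force agreement, invariants."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_cohort
from oracles import brute_classify
from vaxtiming.classify import (
    attending_unvaccinated_fraction,
    classify_cohort,
    classify_infant,
    end_of_study_doses,
)
from vaxtiming.schedule import zambia_epi_schedule


class TestWorkedExamples:
    def test_on_schedule_trajectory(self, schedule):
        c = classify_infant(schedule, "A", [42, 70, 98], [45, 75, 103])
        assert all(ws.up_to_date for ws in c.window_statuses)
        assert not any(a.early or a.compressed for a in c.dose_assessments)
        assert c.total_doses == 3

    def test_missed_first_window_never_recovers(self, schedule):
        """Dose 1 arriving in window 2 leaves the infant behind for good."""
        c = classify_infant(schedule, "A", [42, 70, 98], [75, 103])
        assert [ws.up_to_date for ws in c.window_statuses] == [False, False, False]
        assert c.total_doses == 2
        assert c.cumulative_by_window_end == (0, 1, 2)

    def test_early_and_compressed_flags(self, schedule):
        c = classify_infant(schedule, "A", [42, 56], [38, 60])
        d1, d2 = c.dose_assessments
        assert d1.early and not d1.compressed
        assert d2.spacing_from_previous == 22 and d2.compressed and not d2.early
        # an early dose still counts toward window-1 possession
        assert c.window_statuses[0].up_to_date

    def test_unvaccinated_tracks_cumulative_zero(self, schedule):
        c = classify_infant(schedule, "A", [42, 70, 98], [99])
        assert [ws.unvaccinated for ws in c.window_statuses] == [True, True, False]

    def test_dose_after_all_windows_excluded_from_windows(self, schedule):
        """A lone dose at age 272 d stays in the data but in no window."""
        c = classify_infant(schedule, "A", [42], [272])
        assert c.total_doses == 1
        assert c.cumulative_by_window_end == (0, 0, 0)
        assert c.dose_assessments[0].window_kind == "after"

    def test_too_many_doses_rejected(self, schedule):
        with pytest.raises(ValueError, match="exceed"):
            classify_infant(schedule, "A", [42], [42, 70, 98, 126])


CANDIDATE_AGES = [30, 38, 41, 55, 69, 70, 83, 97, 98, 120, 127, 130]


class TestBruteForceAgreement:
    def _check(self, schedule, visits, doses):
        c = classify_infant(schedule, "x", visits, doses)
        o = brute_classify(schedule, visits, doses)
        got = [
            {
                "visited": ws.visited,
                "received": ws.received_dose,
                "up_to_date": ws.up_to_date,
                "unvaccinated": ws.unvaccinated,
            }
            for ws in c.window_statuses
        ]
        assert got == o["windows"]
        assert list(c.cumulative_by_window_end) == o["cumulative"]
        assert [a.early for a in c.dose_assessments] == [a["early"] for a in o["assessments"]]
        assert [a.compressed for a in c.dose_assessments] == [a["compressed"] for a in o["assessments"]]

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        visits=st.lists(st.sampled_from(CANDIDATE_AGES), max_size=4, unique=True),
        doses=st.lists(st.integers(min_value=20, max_value=140), min_size=0, max_size=3, unique=True),
    )
    def test_random_patterns_match_oracle(self, visits, doses):
        self._check(zambia_epi_schedule(), sorted(visits), sorted(doses))

    def test_all_single_dose_ages_match_oracle(self, schedule):
        for age in range(0, 140):
            self._check(schedule, [42, 70, 98], [age])


class TestInvariants:
    def test_up_to_date_monotone_decay_exhaustive(self, schedule):
        """Up-to-date never recovers: checked over all small dose patterns."""
        for doses in itertools.chain.from_iterable(
            itertools.combinations(CANDIDATE_AGES, k) for k in range(4)
        ):
            c = classify_infant(schedule, "x", [42, 70, 98], sorted(doses))
            flags = [ws.up_to_date for ws in c.window_statuses]
            assert flags == sorted(flags, reverse=True)
            cum = c.cumulative_by_window_end
            assert list(cum) == sorted(cum)

    def test_flag_structure(self, schedule):
        """No compressed dose 1; early only before window 1."""
        for doses in itertools.combinations([38, 40, 41, 69, 70, 99], 3):
            c = classify_infant(schedule, "x", [], list(doses))
            assert c.dose_assessments[0].compressed is False
            for a in c.dose_assessments[1:]:
                if a.early:  # only possible if the previous dose was even earlier
                    assert a.admin_age <= schedule.early_cutoff


class TestEndOfStudy:
    def test_suffix_sum_identity(self, schedule):
        cohort = build_cohort(
            {
                "A": {"visit_ages": [42], "dose_ages": []},
                "B": {"visit_ages": [42], "dose_ages": [45]},
                "C": {"visit_ages": [42, 70], "dose_ages": [45, 75]},
                "D": {"visit_ages": [42, 70, 98], "dose_ages": [45, 75, 100]},
                "E": {"visit_ages": [42, 70, 98], "dose_ages": [45, 75, 101]},
            }
        )
        eos = end_of_study_doses(classify_cohort(schedule, cohort))
        assert eos["exact"].tolist() == [1, 1, 1, 2]
        assert eos["at_least"].tolist() == [5, 4, 3, 2]
        assert eos["exact"].sum() == 5

    def test_all_zero_cohort(self, schedule):
        cohort = build_cohort({f"I{i}": {"visit_ages": [42]} for i in range(4)})
        eos = end_of_study_doses(classify_cohort(schedule, cohort))
        assert eos["exact"].tolist() == [4, 0, 0, 0]
        assert eos["at_least"].tolist() == [4, 0, 0, 0]

    def test_single_infant_two_doses(self, schedule):
        cohort = build_cohort({"A": {"visit_ages": [42, 70], "dose_ages": [45, 75]}})
        eos = end_of_study_doses(classify_cohort(schedule, cohort))
        assert eos.set_index("n_doses")["exact"].to_dict() == {0: 0, 1: 0, 2: 1, 3: 0}
        assert eos.set_index("n_doses")["at_least"].to_dict() == {0: 1, 1: 1, 2: 1, 3: 0}


def test_attending_unvaccinated_fraction(schedule):
    """Hesitant core: attends into window 3 with zero doses."""
    cohort = build_cohort(
        {
            "H1": {"visit_ages": [42, 70, 98]},  # hesitant pattern
            "H2": {"visit_ages": [42, 70, 110]},
            "V1": {"visit_ages": [42, 70, 98], "dose_ages": [42, 70, 98]},
            "L1": {"visit_ages": [42]},  # left before window 2
        }
    )
    frac = attending_unvaccinated_fraction(schedule, cohort)
    w3 = frac[frac["window_index"] == 3].iloc[0]
    assert w3["attending_into_window"] == 3
    assert w3["unvaccinated"] == 2
    assert w3["fraction"] == pytest.approx(2 / 3)
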