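"""Code matching, windowed labelling, harmonisation, aggregation, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdnlp import cohort as ch
from tests.conftest import OBSERVATION


def _visits(rows):
    return pd.DataFrame(rows, columns=["patient_id", "visit_date", "text"]).assign(
        visit_date=lambda d: pd.to_datetime(d["visit_date"])
    )


def _registry(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "discharge_date", "diagnosis_codes", "intervention_codes"]
    ).assign(discharge_date=lambda d: pd.to_datetime(d["discharge_date"]))


def _eligibility(rows):
    return pd.DataFrame(rows, columns=["patient_id", "start_date", "end_date"]).assign(
        start_date=lambda d: pd.to_datetime(d["start_date"]),
        end_date=lambda d: pd.to_datetime(d["end_date"]),
    )


WIDE_ELIG = _eligibility([("P1", "1990-01-01", "2030-01-01")])


class TestCodeMatching:
    def test_circulatory_category_matches(self):
        assert ch.is_cvd_hospitalisation(["41071"], [])

    def test_diabetes_category_does_not_match(self):
        assert not ch.is_cvd_hospitalisation(["25000"], [])

    def test_revascularisation_intervention_matches(self):
        assert ch.is_cvd_hospitalisation([], ["3606"])

    def test_dotted_codes_are_cleaned(self):
        assert ch.is_cvd_hospitalisation(["410.71"], [])
        assert ch.is_cvd_hospitalisation([], ["36.06"])

    def test_intervention_prefix_match_at_stated_precision(self):
        # longer code inherits its 4-digit procedure family
        assert ch.is_cvd_hospitalisation([], ["361012"])
        assert not ch.is_cvd_hospitalisation([], ["3605"])

    def test_range_boundaries(self):
        assert ch.is_cvd_hospitalisation(["390"], [])
        assert ch.is_cvd_hospitalisation(["45999"], [])
        assert not ch.is_cvd_hospitalisation(["38999"], [])
        assert not ch.is_cvd_hospitalisation(["460"], [])

    def test_empty_code_skipped(self):
        assert not ch.is_cvd_hospitalisation([""], [""])

    def test_intervention_range_expansion(self):
        codes = ch.expand_intervention_ranges()
        assert {"0061", "0066", "3603", "3606", "3607", "3610", "3619", "0055",
                "3950", "3952", "3848", "3971", "3990"} <= codes
        assert len(codes) == 25
        assert "3602" not in codes and "3620" not in codes


class TestLabelVisits:
    def test_discharge_six_months_back_within_twelve_month_window(self):
        visits = _visits([("P1", "2015-06-01", "note")])
        registry = _registry([("P1", "2014-12-01", ["41071"], [])])
        out = ch.label_visits(visits, registry, None, ch.WindowSpec(12), eligibility=WIDE_ELIG)
        assert out["label"].tolist() == [1]

    def test_discharge_before_six_month_window_start(self):
        visits = _visits([("P1", "2015-06-01", "note")])
        registry = _registry([("P1", "2014-11-30", ["41071"], [])])
        out = ch.label_visits(visits, registry, None, ch.WindowSpec(6), eligibility=WIDE_ELIG)
        assert out["label"].tolist() == [0]

    def test_discharge_on_inclusive_window_start(self):
        # exactly w months back is inside the window (inclusive endpoints)
        visits = _visits([("P1", "2015-06-01", "note")])
        registry = _registry([("P1", "2014-12-01", ["41071"], [])])
        out = ch.label_visits(visits, registry, None, ch.WindowSpec(6), eligibility=WIDE_ELIG)
        assert out["label"].tolist() == [1]

    def test_infinite_window_ignores_time_distance(self):
        visits = _visits([("P1", "2015-06-01", "note")])
        registry = _registry([("P1", "2001-01-01", ["41071"], [])])
        out = ch.label_visits(visits, registry, None, ch.INFINITE)
        assert out["label"].tolist() == [1]

    def test_discharge_on_visit_date_counts_as_prior(self):
        visits = _visits([("P1", "2015-06-01", "note")])
        registry = _registry([("P1", "2015-06-01", ["41071"], [])])
        out = ch.label_visits(visits, registry, None, ch.WindowSpec(6), eligibility=WIDE_ELIG)
        assert out["label"].tolist() == [1]

    def test_month_arithmetic_clamps_day_overflow(self):
        visits = _visits([("P1", "2015-03-31", "note")])
        inside = _registry([("P1", "2015-02-28", ["41071"], [])])
        outside = _registry([("P1", "2015-02-27", ["41071"], [])])
        w = ch.WindowSpec(1)
        assert ch.label_visits(visits, inside, None, w, eligibility=WIDE_ELIG)["label"].tolist() == [1]
        assert ch.label_visits(visits, outside, None, w, eligibility=WIDE_ELIG)["label"].tolist() == [0]

    def test_non_cvd_discharge_never_labels(self):
        visits = _visits([("P1", "2015-06-01", "note")])
        registry = _registry([("P1", "2015-05-01", ["25000"], ["8952"])])
        out = ch.label_visits(visits, registry, None, ch.INFINITE)
        assert out["label"].tolist() == [0]

    def test_incomplete_window_visit_removed(self):
        elig = _eligibility([("P1", "2015-01-01", "2018-01-01")])
        visits = _visits([("P1", "2015-06-01", "early"), ("P1", "2017-06-01", "late")])
        registry = _registry([])
        out = ch.label_visits(visits, registry, None, ch.WindowSpec(24), eligibility=elig)
        assert out["text"].tolist() == ["late"]

    def test_finite_window_requires_eligibility(self):
        with pytest.raises(ValueError, match="eligibility"):
            ch.label_visits(_visits([("P1", "2015-06-01", "x")]), _registry([]), None, ch.WindowSpec(6))

    def test_discharge_after_observation_end_rejected(self):
        visits = _visits([("P1", "2015-06-01", "note")])
        registry = _registry([("P1", "2019-06-01", ["41071"], [])])
        with pytest.raises(ValueError, match="observation"):
            ch.label_visits(
                visits, registry, None, ch.INFINITE, observation_end=pd.Timestamp("2018-09-30")
            )


class TestHarmonise:
    def test_three_distinct_years_retained(self):
        visits = _visits(
            [("P1", "2012-03-01", "a"), ("P1", "2013-03-01", "b"), ("P1", "2014-03-01", "c")]
        )
        elig = _eligibility([("P1", "2011-01-01", "2018-09-30")])
        out = ch.harmonise(visits, elig, OBSERVATION)
        assert len(out) == 3

    def test_single_year_patient_dropped(self):
        visits = _visits([("P1", f"2012-0{m}-01", "x") for m in range(1, 6)])
        elig = _eligibility([("P1", "2011-01-01", "2018-09-30")])
        assert len(ch.harmonise(visits, elig, OBSERVATION)) == 0

    def test_visit_outside_eligibility_dropped_before_year_count(self):
        visits = _visits(
            [("P1", "2012-03-01", "a"), ("P1", "2013-03-01", "b"), ("P1", "2014-03-01", "c")]
        )
        elig = _eligibility([("P1", "2011-01-01", "2013-12-31")])  # 2014 visit ineligible
        assert len(ch.harmonise(visits, elig, OBSERVATION)) == 0

    def test_visit_outside_observation_dropped(self):
        visits = _visits(
            [("P1", "2009-03-01", "a"), ("P1", "2012-03-01", "b"),
             ("P1", "2013-03-01", "c"), ("P1", "2014-03-01", "d")]
        )
        elig = _eligibility([("P1", "2005-01-01", "2018-09-30")])
        out = ch.harmonise(visits, elig, OBSERVATION)
        assert out["visit_date"].min() >= OBSERVATION[0]
        assert len(out) == 3


class TestAggregation:
    @pytest.mark.parametrize(
        "labels,expected", [([0, 0, 1], 1), ([0, 0, 0], 0), ([1], 1), ([0], 0)]
    )
    def test_or_aggregation(self, labels, expected):
        df = pd.DataFrame({"patient_id": ["P"] * len(labels), "label": labels})
        assert ch.aggregate_by_patient(df).loc["P"] == expected

    def test_matches_brute_force_max(self, dense_cohort):
        visits, registry, elig = dense_cohort
        labelled = ch.label_visits(visits, registry, None, ch.INFINITE)
        agg = ch.aggregate_by_patient(labelled)
        brute = {
            pid: max(g["label"]) for pid, g in labelled.groupby("patient_id")
        }
        assert agg.to_dict() == brute


class TestSplit:
    def test_deterministic(self):
        pids = [f"P{i}" for i in range(10)]
        a = ch.split_by_patient(pids, seed=5)
        b = ch.split_by_patient(pids, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_all_train(self):
        s = ch.split_by_patient([f"P{i}" for i in range(7)], fractions=(1.0, 0.0, 0.0), seed=0)
        assert (s == "train").all()

    def test_largest_remainder_counts(self):
        s = ch.split_by_patient([f"P{i}" for i in range(1000)], seed=0)
        counts = s.value_counts()
        assert counts["train"] == 800 and counts["validation"] == 100 and counts["test"] == 100

    def test_odd_count_apportionment(self):
        s = ch.split_by_patient([f"P{i}" for i in range(17)], seed=0)
        counts = s.value_counts()
        # 13.6 / 1.7 / 1.7 -> floors 13/1/1 + two largest remainders
        assert counts.sum() == 17
        assert abs(counts["train"] - 13.6) <= 1
        assert abs(counts.get("validation", 0) - 1.7) <= 1

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            ch.split_by_patient(["P1", "P2"], seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            ch.split_by_patient(["P1", "P2", "P3"], fractions=(0.5, 0.2, 0.2), seed=0)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_window_monotonicity_property(seed):
    """On any random visit/discharge layout, narrower windows never add
    positives: label_6 <= label_12 <= label_24 <= label_inf."""
    rng = np.random.default_rng(seed)
    n = 30
    visits = _visits(
        [("P1", pd.Timestamp("2011-01-01") + pd.Timedelta(days=int(d)), "x")
         for d in rng.integers(900, 2800, size=n)]
    )
    registry = _registry(
        [("P1", pd.Timestamp("2011-01-01") + pd.Timedelta(days=int(d)), ["41071"], [])
         for d in rng.integers(0, 2800, size=4)]
    )
    elig = _eligibility([("P1", "2008-01-01", "2020-01-01")])
    labels = {}
    for w in ch.STANDARD_WINDOWS:
        out = ch.label_visits(visits, registry, None, w, eligibility=elig)
        labels[w.name] = out.set_index("visit_date")["label"]
    common = labels["6m"].index
    for narrow, wide in [("6m", "12m"), ("12m", "24m"), ("24m", "infinite")]:
        assert (labels[narrow].loc[common] <= labels[wide].loc[common]).all()
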