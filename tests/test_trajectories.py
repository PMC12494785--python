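"""Delta-ctDNA event classification, pairing and dynamics summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctdna_burden import (classify_delta_event, compute_delta_events,
                          concordance_table, percent_decrease, slope_correlation)
from ctdna_burden.exceptions import DomainError
from ctdna_burden.trajectories import CATEGORIES, HIGH, LOW

HIGH_CATS = {"decrease_below_cutoff", "stays_above_cutoff"}
LOW_CATS = {"decrease", "stable", "increase_below_cutoff", "increase_above_cutoff"}


@pytest.mark.parametrize("prev,next_,group,expected", [
    (800, 200, HIGH, "decrease_below_cutoff"),
    (800, 400, HIGH, "stays_above_cutoff"),
    (800, 350, HIGH, "stays_above_cutoff"),     # landing exactly on the cutoff
    (400, 349.9, HIGH, "decrease_below_cutoff"),
    (100, 110, LOW, "stable"),
    (100, 500, LOW, "increase_above_cutoff"),
    (100, 200, LOW, "increase_below_cutoff"),
    (100, 75, LOW, "decrease"),                  # drop of exactly one band width
    (100, 125, LOW, "increase_below_cutoff"),    # rise of exactly one band width
    (100, 124.9, LOW, "stable"),
    (0, 10, LOW, "stable"),
])
def test_classification_semantics(prev, next_, group, expected):
    assert classify_delta_event(prev, next_, group) == expected


@settings(max_examples=300, deadline=None, derandomize=True)
@given(prev=st.floats(0, 1000), next_=st.floats(0, 1000),
       group=st.sampled_from([HIGH, LOW]))
def test_categories_partition_all_inputs(prev, next_, group):
    cat = classify_delta_event(prev, next_, group)
    assert cat in CATEGORIES
    assert cat in (HIGH_CATS if group == HIGH else LOW_CATS)


def test_translation_covariance_in_low_group():
    # shifting both measurements (staying on one side of the cutoff) never
    # changes the decrease/stable/increase verdict
    for prev, next_ in [(10, 80), (50, 20), (100, 110)]:
        base = classify_delta_event(prev, next_, LOW).split("_")[0]
        for shift in (5, 50, 120):
            shifted = classify_delta_event(prev + shift, next_ + shift, LOW).split("_")[0]
            assert shifted == base


def test_unassigned_group_rejected():
    with pytest.raises(DomainError):
        classify_delta_event(10, 20, "unassigned")


@pytest.mark.parametrize("prev,next_,expected", [
    (1000, 45, 95.5),
    (100, 100, 0.0),
    (100, 37, 63.0),
])
def test_percent_decrease(prev, next_, expected):
    assert percent_decrease(prev, next_) == pytest.approx(expected)


def test_percent_decrease_zero_rejected():
    with pytest.raises(DomainError):
        percent_decrease(0, 10)


def _mk_samples(pid, mges, days=None, status=None):
    days = days or [28 * i for i in range(len(mges))]
    status = status or ["positive" if m > 0 else "negative" for m in mges]
    return pd.DataFrame({
        "patient_id": pid, "sample_id": [f"{pid}_S{i}" for i in range(len(mges))],
        "days_from_baseline": days, "ctdna_status": status, "mge_per_ml": mges,
    })


def _mk_workups(pid, days, status=None):
    status = status or ["stable"] * len(days)
    return pd.DataFrame({"patient_id": pid,
                         "workup_id": [f"{pid}_W{i}" for i in range(len(days))],
                         "days_from_baseline": days, "disease_status": status})


def _mk_patient(pid, group=LOW, os_months=20.0, death=False):
    return pd.DataFrame({"patient_id": [pid], "group": [group],
                         "os_months": [os_months], "death_event": [death]})


class TestComputeDeltaEvents:
    def test_single_sample_yields_no_events(self):
        ev = compute_delta_events(_mk_samples("A", [100.0]), _mk_workups("A", [14]),
                                  _mk_patient("A"))
        assert len(ev) == 0

    def test_all_negative_yields_no_events(self):
        ev = compute_delta_events(_mk_samples("A", [0.0, 0.0, 0.0]),
                                  _mk_workups("A", [14, 42]), _mk_patient("A"))
        assert len(ev) == 0

    def test_three_samples_two_workups(self):
        ev = compute_delta_events(_mk_samples("A", [100.0, 50.0, 200.0]),
                                  _mk_workups("A", [14, 42]), _mk_patient("A"))
        assert len(ev) == 2
        assert list(ev["delta_mge"]) == [-50.0, 150.0]
        assert list(ev["category"]) == ["decrease", "increase_below_cutoff"]

    def test_workups_in_same_bracket_collapse(self):
        ev = compute_delta_events(_mk_samples("A", [100.0, 50.0]),
                                  _mk_workups("A", [10, 20]), _mk_patient("A"))
        assert len(ev) == 1

    def test_undated_workup_rejected(self):
        w = _mk_workups("A", [14.0])
        w.loc[0, "days_from_baseline"] = np.nan
        with pytest.raises(DomainError):
            compute_delta_events(_mk_samples("A", [100.0, 50.0]), w, _mk_patient("A"))

    def test_death_within_window_counts_as_progression(self):
        # workup reads stable, but the patient dies 2 months after the next draw
        samples = _mk_samples("A", [500.0, 600.0], days=[0, 28])
        pat = _mk_patient("A", group=HIGH, os_months=(28 / 30.4375) + 2.0, death=True)
        ev = compute_delta_events(samples, _mk_workups("A", [14]), pat)
        assert ev.iloc[0]["disease_status"] == "progression_or_death_within_3m"
        assert ev.iloc[0]["category"] == "stays_above_cutoff"

    def test_percent_decrease_recorded(self):
        ev = compute_delta_events(_mk_samples("A", [1000.0, 45.0]),
                                  _mk_workups("A", [14]),
                                  _mk_patient("A", group=HIGH))
        assert ev.iloc[0]["percent_decrease"] == pytest.approx(95.5)


class TestConcordanceTable:
    def test_empty(self):
        t = concordance_table(pd.DataFrame(columns=["group", "category", "disease_status"]))
        assert len(t) == 0 and "proportion" in t.columns

    def test_hand_tabulated_counts(self):
        ev = pd.DataFrame({
            "group": [HIGH] * 3 + [LOW] * 5,
            "category": ["decrease_below_cutoff"] * 2 + ["stays_above_cutoff"]
                        + ["stable"] * 3 + ["increase_above_cutoff"] * 2,
            "disease_status": ["regression_or_stable", "progression_or_death_within_3m",
                               "progression_or_death_within_3m",
                               "regression_or_stable", "regression_or_stable",
                               "progression_or_death_within_3m",
                               "progression_or_death_within_3m",
                               "progression_or_death_within_3m"],
        })
        t = concordance_table(ev)
        row = t[(t.group == LOW) & (t.category == "stable")
                & (t.disease_status == "regression_or_stable")].iloc[0]
        assert row["count"] == 2 and row["category_total"] == 3
        assert row["proportion"] == pytest.approx(2 / 3)
        assert t["count"].sum() == len(ev)  # marginal conservation

    def test_marginals_conserved_on_simulation(self, small_cohort):
        from ctdna_burden import quantify_samples, filter_ctdna, assign_groups
        from ctdna_burden.pipeline import baseline_burden
        q = quantify_samples(small_cohort.samples, filter_ctdna(small_cohort.variants),
                             small_cohort.copy_states)
        pats = assign_groups(baseline_burden(small_cohort.patients, q), 350.0)
        ev = compute_delta_events(q, small_cohort.workups, pats)
        t = concordance_table(ev)
        assert t["count"].sum() == len(ev)


class TestSlopeCorrelation:
    @staticmethod
    def _series(pid, days, vals, col):
        return pd.DataFrame({"patient_id": pid, "days_from_baseline": days, col: vals})

    def _paired(self, slopes_a, slopes_b):
        ct, ca = [], []
        for i, (sa, sb) in enumerate(zip(slopes_a, slopes_b)):
            ct.append(self._series(f"P{i}", [0, 10], [100, 100 + 10 * sa], "mge_per_ml"))
            ca.append(self._series(f"P{i}", [0, 10], [50, 50 + 10 * sb], "ca19_9"))
        return pd.concat(ct), pd.concat(ca)

    def test_perfect_concordance(self):
        ct, ca = self._paired([1, 2, 3, 4], [10, 20, 30, 40])
        assert slope_correlation(ct, ca) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        ct, ca = self._paired([1, 2, 3, 4], [40, 30, 20, 10])
        assert slope_correlation(ct, ca) == pytest.approx(-1.0)

    def test_matches_rank_arithmetic(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=10)
        b = 0.5 * a + rng.normal(size=10)
        ct, ca = self._paired(a, b)
        # independent oracle: Pearson correlation of the rank vectors
        ra = np.argsort(np.argsort(a)).astype(float)
        rb = np.argsort(np.argsort(b)).astype(float)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert slope_correlation(ct, ca) == pytest.approx(expected, abs=1e-10)

    def test_too_few_patients_rejected(self):
        ct, ca = self._paired([1, 2], [3, 4])
        with pytest.raises(DomainError):
            slope_correlation(ct, ca)
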