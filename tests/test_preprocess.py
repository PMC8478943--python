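"""Trimester binning, outcome threshold, eligibility filters and
absolute-count derivation."""

import logging

import numpy as np
import pandas as pd
import pytest

from trimtrack import (ValidationError, aggregate_trimesters,
                       build_wide_matrix, derive_absolute_counts,
                       derive_outcome, filter_complete_three_trimester,
                       outcome_analysis_set)


def make_table(rows):
    """rows: (woman_id, week, PLATE value, loss, mode)"""
    return pd.DataFrame(
        [{"woman_id": w, "gestational_week": wk, "PLATE": v, "age": 30.0,
          "origin": "EUR", "delivery_mode": mode, "blood_loss_ml": loss}
         for (w, wk, v, loss, mode) in rows])


class TestAggregateTrimesters:
    def test_single_draw_fills_only_its_bin(self):
        t = make_table([("A", 12, 250.0, 100.0, "vaginal")])
        out = aggregate_trimesters(t, "PLATE")
        assert out.loc[0, "value_t1"] == 250.0
        assert np.isnan(out.loc[0, "value_t2"]) and np.isnan(out.loc[0, "value_t3"])

    def test_within_bin_draws_are_averaged(self):
        t = make_table([("A", 15, 100.0, 100.0, "vaginal"),
                        ("A", 20, 110.0, 100.0, "vaginal")])
        out = aggregate_trimesters(t, "PLATE")
        assert out.loc[0, "value_t2"] == 105.0

    def test_bin_boundaries_are_inclusive_integers(self):
        t = make_table([("A", 13, 1.0, 100.0, "vaginal"),
                        ("B", 14, 2.0, 100.0, "vaginal"),
                        ("C", 27, 3.0, 100.0, "vaginal"),
                        ("D", 28, 4.0, 100.0, "vaginal")])
        out = aggregate_trimesters(t, "PLATE").set_index("woman_id")
        assert out.loc["A", "value_t1"] == 1.0
        assert out.loc["B", "value_t2"] == 2.0
        assert out.loc["C", "value_t2"] == 3.0
        assert out.loc["D", "value_t3"] == 4.0

    def test_week_out_of_range_names_row(self):
        t = make_table([("A", 45, 1.0, 100.0, "vaginal")])
        with pytest.raises(ValidationError, match=r"\[0, 42\]"):
            aggregate_trimesters(t, "PLATE")

    def test_unknown_measure_errors(self):
        t = make_table([("A", 10, 1.0, 100.0, "vaginal")])
        with pytest.raises(ValidationError, match="unknown"):
            aggregate_trimesters(t, "HBX")

    def test_permutation_invariance_and_idempotence(self, small_cohort):
        ref = aggregate_trimesters(small_cohort, "MPV")
        shuffled = small_cohort.sample(frac=1.0, random_state=0)
        pd.testing.assert_frame_equal(
            aggregate_trimesters(shuffled, "MPV"), ref)
        # re-expanding one draw per trimester and re-aggregating is a no-op
        complete = filter_complete_three_trimester(ref)
        rows = []
        for _, r in complete.iterrows():
            for wk, v in zip((5, 20, 35), (r.value_t1, r.value_t2, r.value_t3)):
                rows.append({"woman_id": r.woman_id, "gestational_week": wk,
                             "MPV": v, "age": r.age, "origin": r.origin,
                             "delivery_mode": r.delivery_mode,
                             "blood_loss_ml": 100.0})
        again = aggregate_trimesters(pd.DataFrame(rows), "MPV")
        np.testing.assert_allclose(
            again[["value_t1", "value_t2", "value_t3"]],
            complete[["value_t1", "value_t2", "value_t3"]])


class TestDeriveOutcome:
    def test_threshold_is_500_inclusive(self):
        t = make_table([("A", 10, 1.0, 500.0, "vaginal"),
                        ("B", 10, 1.0, 499.0, "vaginal")])
        pph = derive_outcome(t)
        assert pph["A"] == 1.0 and pph["B"] == 0.0

    def test_cesarean_excluded_from_outcome_set(self):
        t = make_table([("A", 10, 1.0, 800.0, "cesarean"),
                        ("B", 10, 1.0, 800.0, "vaginal")])
        pph = derive_outcome(t)
        assert np.isnan(pph["A"]) and pph["B"] == 1.0
        tm = aggregate_trimesters(t, "PLATE")
        assert list(outcome_analysis_set(
            pd.concat([tm.assign(value_t2=1.0, value_t3=1.0)])).woman_id) == ["B"]

    def test_negative_blood_loss_errors(self):
        t = make_table([("A", 10, 1.0, -5.0, "vaginal")])
        with pytest.raises(ValidationError, match="negative"):
            derive_outcome(t)

    def test_monotone_in_blood_loss(self):
        losses = np.linspace(0, 1200, 25)
        t = make_table([(f"W{i}", 10, 1.0, l, "vaginal")
                        for i, l in enumerate(losses)])
        pph = derive_outcome(t)
        ordered = pph[[f"W{i}" for i in range(25)]].to_numpy()
        assert (np.diff(ordered) >= 0).all()


def test_filter_complete_three_trimester():
    t = make_table([("A", 5, 1.0, 100.0, "vaginal"),
                    ("A", 20, 1.0, 100.0, "vaginal"),
                    ("A", 35, 1.0, 100.0, "vaginal"),
                    ("B", 5, 1.0, 100.0, "vaginal"),
                    ("B", 35, 1.0, 100.0, "vaginal")])
    out = filter_complete_three_trimester(aggregate_trimesters(t, "PLATE"))
    assert list(out.woman_id) == ["A"]


def test_generator_guarantees_full_trimester_coverage(small_cohort):
    tm = aggregate_trimesters(small_cohort, "HB")
    assert len(filter_complete_three_trimester(tm)) == tm.woman_id.nunique()


class TestDeriveAbsoluteCounts:
    def base(self, **over):
        d = {"woman_id": ["A"], "gestational_week": [10], "LEUC": [10.0],
             "NEUT": [60.0], "LYMPH": [25.0], "MONO": [10.0], "EOSI": [0.0]}
        d.update(over)
        return pd.DataFrame(d)

    def test_percentage_times_leuc(self):
        out = derive_absolute_counts(self.base(), percent_subtypes=True)
        assert out.loc[0, "NEUT"] == 6.0
        assert out.loc[0, "EOSI"] == 0.0

    def test_passthrough_when_not_percentages(self):
        t = self.base()
        pd.testing.assert_frame_equal(derive_absolute_counts(t, False), t)

    def test_percentage_out_of_range_errors(self):
        with pytest.raises(ValidationError, match=r"\[0, 100\]"):
            derive_absolute_counts(self.base(NEUT=[120.0]), percent_subtypes=True)

    def test_sum_above_100_warns_but_proceeds(self, caplog):
        t = self.base(NEUT=[70.0], LYMPH=[25.0], MONO=[6.0])  # sums to 101
        with caplog.at_level(logging.WARNING, logger="trimtrack.preprocess"):
            out = derive_absolute_counts(t, percent_subtypes=True)
        assert "exceed 100" in caplog.text
        assert out.loc[0, "NEUT"] == 7.0


def test_build_wide_matrix_has_all_measure_columns(small_cohort):
    wide = build_wide_matrix(small_cohort)
    from trimtrack import MEASURES
    for m in MEASURES:
        for j in (1, 2, 3):
            assert f"{m}_t{j}" in wide.columns
    assert wide.woman_id.is_unique
    # wide values agree with single-measure aggregation
    tm = aggregate_trimesters(small_cohort, "RDW").set_index("woman_id")
    np.testing.assert_allclose(
        wide.set_index("woman_id")["RDW_t2"], tm["value_t2"])
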