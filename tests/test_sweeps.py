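"""Tests for the sweep engine: crossover detection, shape contracts, determinism."""

import io

import numpy as np
import pytest

from hrventropy.errors import InvalidInputError, PlanError
from hrventropy.sweeps import (
    SweepPlan,
    detect_crossovers,
    run_plan,
    run_test_case_1,
    run_test_case_2,
    run_test_case_3,
    run_test_case_4,
    run_test_case_5,
)
from hrventropy.thresholds import ThresholdSpec


class TestDetectCrossovers:
    def test_single_sign_change(self):
        rep = detect_crossovers([1, 2, 3, 4], [1, 0.5, -0.2, -0.4], [0, 0, 0, 0])
        assert len(rep.crossings) == 1
        c = rep.crossings[0]
        assert (c.left_r, c.right_r, c.kind) == (2.0, 3.0, "interval")

    def test_equal_curves_touch_points_only(self):
        rep = detect_crossovers([1, 2, 3], [5, 5, 5], [5, 5, 5])
        assert rep.crossings == ()
        assert rep.touch_points == (1.0, 2.0, 3.0)

    def test_zero_flanked_by_opposite_signs_counts_once(self):
        rep = detect_crossovers([1, 2, 3], [1, 0, -1], [0, 0, 0])
        assert len(rep.crossings) == 1
        assert rep.crossings[0].kind == "zero"
        assert rep.crossings[0].left_r == rep.crossings[0].right_r == 2.0

    def test_zero_flanked_by_same_sign_is_touch_only(self):
        rep = detect_crossovers([1, 2, 3], [1, 0, 1], [0, 0, 0])
        assert rep.crossings == ()
        assert rep.touch_points == (2.0,)

    def test_multiple_crossings(self):
        rep = detect_crossovers([1, 2, 3, 4, 5], [1, -1, 1, -1, 1], np.zeros(5))
        assert len(rep.crossings) == 4

    def test_grid_mismatch(self):
        with pytest.raises(InvalidInputError):
            detect_crossovers([1, 2, 3], [1, 2], [0, 0])

    def test_single_point_grid_no_crossing(self):
        rep = detect_crossovers([1], [2], [1])
        assert rep.crossings == ()


class TestCase1:
    def test_identical_cohorts_zero_difference(self, small_cohorts):
        a, _ = small_cohorts
        result, reports = run_test_case_1(
            a, a.__class__(label="copy", records=a.records),
            r_coeffs=(0.1, 0.175, 0.25), n_length=300,
            estimators=("apen", "sampen"),
        )
        assert np.allclose(result.rows["mean_a"], result.rows["mean_b"])
        for rep in reports.values():
            assert rep.crossings == ()
            assert len(rep.touch_points) == 3

    def test_shape_and_columns(self, small_cohorts):
        a, b = small_cohorts
        result, reports = run_test_case_1(
            a, b, r_coeffs=(0.15, 0.2), n_length=300, estimators=("sampen", "fuzzyen")
        )
        assert len(result.rows) == 2 * 2
        assert set(reports) == {"sampen", "fuzzyen"}
        assert {"estimator", "r_coeff", "p_value", "test_used", "significant"} <= set(
            result.rows.columns
        )
        # one subset => a single statistical test across all rows
        assert result.rows["test_used"].nunique() == 1

    def test_empty_grid_rejected(self, small_cohorts):
        a, b = small_cohorts
        with pytest.raises(PlanError):
            run_test_case_1(a, b, r_coeffs=(), n_length=300)


class TestCase2:
    def test_single_length_grid(self, small_cohorts):
        a, b = small_cohorts
        result = run_test_case_2(
            a, b, n_grid=(150,), r_modes=(ThresholdSpec("sigma_multiple", 0.2),),
            estimators=("sampen",),
        )
        assert len(result.rows) == 1
        assert result.rows["N"].tolist() == [150]

    def test_rows_per_length_and_mode(self, small_cohorts):
        a, b = small_cohorts
        result = run_test_case_2(
            a, b, n_grid=(120, 150),
            r_modes=(ThresholdSpec("chon"), ThresholdSpec("sigma_multiple", 0.2)),
            estimators=("apen", "sampen"),
        )
        assert len(result.rows) == 2 * 2 * 2
        # uniform test holds within each (pair, r_mode) subset
        for _, grp in result.rows.groupby("subset_id"):
            assert grp["test_used"].nunique() == 1


class TestCase3To5:
    def test_case_3_shape(self, small_cohorts):
        a, b = small_cohorts
        result = run_test_case_3(
            a, b, n_grid=(1.0, 3.0), r_modes=(ThresholdSpec("sigma_multiple", 0.2),),
            n_length=300,
        )
        assert len(result.rows) == 2
        assert set(result.rows["estimator"]) == {"fuzzyen"}

    def test_case_3_invalid_weight(self, small_cohorts):
        a, b = small_cohorts
        with pytest.raises(PlanError):
            run_test_case_3(a, b, n_grid=(0.0, 1.0), n_length=300)

    def test_case_4_grid_shape(self, small_cohorts):
        a, b = small_cohorts
        result = run_test_case_4(
            a, b, nl_grid=(1.0, 2.0), nf_grid=(1.0, 2.0, 3.0),
            r_modes=(ThresholdSpec("sigma_multiple", 0.2),), n_length=300,
        )
        assert len(result.rows) == 2 * 3
        assert {"n_L", "n_F"} <= set(result.rows.columns)

    def test_case_5_grid_shape_and_weights(self, small_cohorts):
        a, b = small_cohorts
        result = run_test_case_5(
            a, b, chon_multiples=(0.5, 1.0), sigma_multiples=(0.15, 0.2),
            n_length=300,
        )
        assert len(result.rows) == 2 * 2 + 2 * 2
        chon_rows = result.rows[result.rows["r_mode"] == "chon"]
        sigma_rows = result.rows[result.rows["r_mode"] == "sigma"]
        assert set(zip(chon_rows["n_L"], chon_rows["n_F"])) == {(2.0, 1.0)}
        assert set(zip(sigma_rows["n_L"], sigma_rows["n_F"])) == {(1.0, 3.0)}

    def test_determinism_of_repeated_runs(self, small_cohorts):
        a, b = small_cohorts
        kwargs = dict(n_grid=(1.0, 2.0), r_modes=(ThresholdSpec("sigma_multiple", 0.2),),
                      n_length=300, seed=5)
        r1 = run_test_case_3(a, b, **kwargs)
        r2 = run_test_case_3(a, b, **kwargs)
        buf1, buf2 = io.StringIO(), io.StringIO()
        r1.rows.to_csv(buf1)
        r2.rows.to_csv(buf2)
        assert buf1.getvalue() == buf2.getvalue()


class TestSweepPlan:
    def test_valid_plan_round_trip(self):
        plan = SweepPlan.from_dict({"test_case": 3, "n_grid": [1, 2], "alpha": 0.05})
        assert plan.test_case == 3
        assert plan.hash() == SweepPlan.from_dict(
            {"test_case": 3, "n_grid": [1, 2], "alpha": 0.05}
        ).hash()

    def test_unknown_test_case(self):
        with pytest.raises(PlanError):
            SweepPlan.from_dict({"test_case": 6})

    def test_unknown_keys_listed(self):
        with pytest.raises(PlanError, match="bogus"):
            SweepPlan.from_dict({"test_case": 1, "bogus": 1})

    def test_r_modes_parsed_from_strings(self):
        plan = SweepPlan.from_dict(
            {"test_case": 3, "r_modes": ["0.2sigma", "chon"], "n_length": 300}
        )
        assert plan.options["r_modes"][0] == ThresholdSpec("sigma_multiple", 0.2)

    def test_run_plan_attaches_hash(self, small_cohorts):
        a, b = small_cohorts
        plan = SweepPlan.from_dict(
            {"test_case": 3, "n_grid": [2.0], "r_modes": ["0.2sigma"], "n_length": 300}
        )
        result, reports = run_plan(plan, a, b, seed=1)
        assert reports is None
        assert result.provenance["plan_hash"] == plan.hash()
        assert result.provenance["seed"] == 1
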