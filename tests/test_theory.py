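"""Quintile microsimulation: four-stage incomes and the two scenarios."""

import numpy as np
import pytest

from urrbmi_redist.policy import PolicySchedule
from urrbmi_redist.theory import (
    Calibration,
    ExpenditureProbabilityMatrix,
    emit_tables,
    scenario1,
    scenario2,
    stage_incomes,
    uninsured_incomes,
)

# Published after-OOP and after-reimbursement income vectors (multiples of
# the reference income), one row per expenditure bracket, poorest first.
AFTER_OOP = np.array(
    [
        [0.288, 0.587, 0.986, 1.985, 2.984],
        [0.278, 0.576, 0.974, 1.972, 2.970],
        [0.262, 0.562, 0.962, 1.962, 2.962],
        [0.240, 0.545, 0.950, 1.955, 2.960],
        [0.212, 0.525, 0.938, 1.951, 2.964],
    ]
)
AFTER_REIMB = np.array(
    [
        [0.2880, 0.5870, 0.9860, 1.9850, 2.9840],
        [0.3248, 0.6228, 1.0208, 2.0188, 3.0168],
        [0.3556, 0.6556, 1.0556, 2.0556, 3.0556],
        [0.3804, 0.6854, 1.0904, 2.0954, 3.1004],
        [0.3992, 0.7122, 1.1252, 2.1382, 3.1512],
    ]
)
UNINSURED = np.array(
    [
        [0.298, 0.597, 0.996, 1.995, 2.994],
        [0.288, 0.586, 0.984, 1.982, 2.980],
        [0.272, 0.572, 0.972, 1.972, 2.972],
        [0.250, 0.555, 0.960, 1.965, 2.970],
        [0.222, 0.535, 0.948, 1.961, 2.974],
    ]
)


class TestStageIncomes:
    def test_reproduces_published_income_grid(self, calibration, prob_matrix):
        si = stage_incomes(calibration, prob_matrix)
        np.testing.assert_allclose(si.initial, [0.3, 0.6, 1.0, 2.0, 3.0])
        np.testing.assert_allclose(si.after_premium, [0.29, 0.59, 0.99, 1.99, 2.99])
        np.testing.assert_allclose(si.after_oop, AFTER_OOP, atol=5e-5)
        np.testing.assert_allclose(si.after_reimbursement, AFTER_REIMB, atol=5e-5)

    def test_middle_income_worked_trace(self, calibration, prob_matrix):
        """Reference income, mid-tier 0.20 claim at probability 0.2:
        after-OOP 0.95, after reimbursement 1.0904 (~1.09)."""
        si = stage_incomes(calibration, prob_matrix)
        assert si.after_oop[3, 2] == pytest.approx(0.95, abs=1e-12)
        assert si.after_reimbursement[3, 2] == pytest.approx(1.0904, abs=1e-12)

    def test_deductible_bracket_gets_no_payout(self, calibration, prob_matrix):
        si = stage_incomes(calibration, prob_matrix)
        np.testing.assert_allclose(si.after_reimbursement[0], si.after_oop[0])

    def test_zero_probability_leaves_income_at_post_premium(self, calibration):
        probs = ExpenditureProbabilityMatrix(
            np.array([[0.0, 1.0, 0, 0, 0]] * 5, dtype=float)
        )
        si = stage_incomes(calibration, probs)
        np.testing.assert_allclose(si.after_oop[0], si.after_premium)

    def test_negative_income_names_the_cell(self):
        cal = Calibration(
            quintile_multipliers=(0.3, 0.6, 1.0, 2.0, 3.0),
            bracket_multipliers=(0.02, 1.5),
        )
        probs = ExpenditureProbabilityMatrix(np.full((5, 2), 0.5))
        with pytest.raises(ValueError, match="quintile 1"):
            stage_incomes(cal, probs)

    def test_ceiling_binding_warns(self):
        sched = PolicySchedule(premium=0.01, deductible=0.02,
                               coinsurance_rate=0.78, ceiling=0.05, units="W_r")
        cal = Calibration(schedule=sched)
        with pytest.warns(UserWarning, match="ceiling"):
            stage_incomes(cal)

    def test_matrix_shape_mismatch_rejected(self, calibration):
        probs = ExpenditureProbabilityMatrix(np.full((5, 4), 0.25))
        with pytest.raises(ValueError, match="shape"):
            stage_incomes(calibration, probs)


class TestScenario1:
    def test_published_indices(self, calibration, prob_matrix):
        tbl = scenario1(calibration, prob_matrix).to_frame()
        np.testing.assert_allclose(
            tbl["gini_after_oop"], [0.3977, 0.4006, 0.4054, 0.4120, 0.4206], atol=5e-5
        )
        np.testing.assert_allclose(
            tbl["gini_after_reimbursement"],
            [0.3977, 0.3872, 0.3789, 0.3727, 0.3683],
            atol=5e-5,
        )
        np.testing.assert_allclose(
            tbl["mt"], [0, 0.0134, 0.0265, 0.0393, 0.0523], atol=5e-5
        )
        np.testing.assert_allclose(
            tbl["rmt_percent"], [0.00, 3.34, 6.54, 9.54, 12.43], atol=5e-3
        )

    def test_mt_and_rmt_strictly_increase_above_deductible(
        self, calibration, prob_matrix
    ):
        res = scenario1(calibration, prob_matrix)
        assert res.mt[0] == pytest.approx(0.0, abs=1e-12)
        assert (np.diff(res.mt[1:]) > 0).all()
        assert (np.diff(res.rmt_percent[1:]) > 0).all()

    def test_gini_monotone_in_bracket(self, calibration, prob_matrix):
        res = scenario1(calibration, prob_matrix)
        assert (np.diff(res.gini_before) > 0).all()  # bigger bills, wider gap
        assert (np.diff(res.gini_after[1:]) < 0).all()  # bigger payouts, narrower

    def test_zero_coinsurance_rate_kills_redistribution(self):
        sched = PolicySchedule(premium=0.01, deductible=0.02,
                               coinsurance_rate=0.0, ceiling=6.0, units="W_r")
        cal = Calibration(schedule=sched)
        probs = ExpenditureProbabilityMatrix(np.full((5, 5), 0.2))
        res = scenario1(cal, probs)
        np.testing.assert_allclose(res.mt, 0.0, atol=1e-15)

    def test_numeraire_invariance(self, prob_matrix):
        in_multiples = scenario1(Calibration(w_r=1.0), prob_matrix)
        in_rmb = scenario1(Calibration(w_r=40_000.0), prob_matrix)
        np.testing.assert_allclose(in_multiples.gini_before, in_rmb.gini_before,
                                   atol=1e-12)
        np.testing.assert_allclose(in_multiples.gini_after, in_rmb.gini_after,
                                   atol=1e-12)


class TestScenario2:
    def test_uninsured_income_grid(self, calibration, prob_matrix):
        np.testing.assert_allclose(
            uninsured_incomes(calibration, prob_matrix), UNINSURED, atol=5e-5
        )

    def test_published_indices(self, calibration, prob_matrix):
        tbl = scenario2(calibration, prob_matrix).to_frame()
        np.testing.assert_allclose(
            tbl["gini_uninsured"], [0.3948, 0.3977, 0.4024, 0.4090, 0.4175], atol=5e-5
        )
        np.testing.assert_allclose(
            tbl["mt"], [-0.0029, 0.0105, 0.0235, 0.0363, 0.0492], atol=5e-5
        )

    def test_sign_pattern(self, calibration, prob_matrix):
        res = scenario2(calibration, prob_matrix)
        assert res.mt[0] < 0  # at the deductible the uninsured fare better
        assert (res.mt[1:] > 0).all()

    def test_no_scheme_means_no_difference(self, prob_matrix):
        sched = PolicySchedule(premium=0.0, deductible=0.02,
                               coinsurance_rate=0.0, ceiling=6.0, units="W_r")
        res = scenario2(Calibration(schedule=sched), prob_matrix)
        np.testing.assert_allclose(res.mt, 0.0, atol=1e-15)


class TestTablesAndConfig:
    def test_emitted_tables_shape(self):
        tables = emit_tables()
        assert set(tables) == {
            "insured_stage_incomes",
            "insured_redistribution",
            "uninsured_incomes",
            "insured_vs_uninsured",
        }
        assert len(tables["insured_redistribution"]) == 5
        assert len(tables["insured_vs_uninsured"]) == 5
        # 2 baseline rows + 5 after-OOP + 5 after-reimbursement
        assert len(tables["insured_stage_incomes"]) == 12

    def test_probability_matrix_row_sums_enforced(self):
        bad = np.full((5, 5), 0.2)
        bad[2, 0] = 0.3
        with pytest.raises(ValueError, match="sum to 1"):
            ExpenditureProbabilityMatrix(bad)

    def test_bracket_must_start_at_deductible(self):
        with pytest.raises(ValueError, match="deductible"):
            Calibration(bracket_multipliers=(0.05, 0.08, 0.14, 0.20, 0.26))

    def test_multipliers_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            Calibration(quintile_multipliers=(0.3, 0.3, 1.0, 2.0, 3.0))

    def test_yaml_config_round_trip(self, tmp_path):
        import yaml

        cfg = {
            "w_r": 40_000.0,
            "quintile_multipliers": [0.3, 0.6, 1.0, 2.0, 3.0],
            "bracket_multipliers": [0.02, 0.08, 0.14, 0.20, 0.26],
            "schedule": {
                "premium": 400.0, "deductible": 800.0,
                "coinsurance_rate": 0.78, "ceiling": 240_000.0, "units": "RMB",
            },
            "probability_matrix": ExpenditureProbabilityMatrix.default().probs.tolist(),
        }
        p = tmp_path / "cal.yaml"
        p.write_text(yaml.safe_dump(cfg))
        from urrbmi_redist.theory import load_config

        cal, probs = load_config(p)
        assert cal.w_r == 40_000.0
        res = scenario1(cal, probs).to_frame()
        np.testing.assert_allclose(res["mt"], [0, 0.0134, 0.0265, 0.0393, 0.0523],
                                   atol=5e-5)
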