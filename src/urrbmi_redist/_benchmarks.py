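"""Published reference results for the default calibration.

The quintile model with the default calibration (W_r = RMB 40,000, flat
premium 0.01 W_r, secondary-tier deductible 0.02 W_r, coinsurance 78%,
quintiles 0.3/0.6/1/2/3, brackets 0.02..0.26 W_r and the default gradient
probability matrix) has a published set of results.  They are kept here so
the command-line ``theory`` run can print a PASS/FAIL comparison; they are
reference values for regression, never inputs to any computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Ginis printed to 4 decimals, RMT to 2-decimal percent.
REFERENCE = {
    "gini_initial": 0.3942,
    "gini_after_premium": 0.3971,
    "gini_after_oop": (0.3977, 0.4006, 0.4054, 0.4120, 0.4206),
    "gini_after_reimbursement": (0.3977, 0.3872, 0.3789, 0.3727, 0.3683),
    "mt_scenario1": (0.0, 0.0134, 0.0265, 0.0393, 0.0523),
    "rmt_percent_scenario1": (0.00, 3.34, 6.54, 9.54, 12.43),
    "gini_uninsured": (0.3948, 0.3977, 0.4024, 0.4090, 0.4175),
    "mt_scenario2": (-0.0029, 0.0105, 0.0235, 0.0363, 0.0492),
}

GINI_TOL = 5e-5  # printed 4-dp precision
RMT_TOL = 5e-3  # printed 2-dp percent precision


def compare_tables(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Compare emitted result tables against the reference values.

    ``tables`` is the output of :func:`urrbmi_redist.theory.emit_tables`
    under the default calibration.  Returns one row per checked quantity
    with columns (quantity, bracket, computed, reference, passed).
    """
    stages = tables["insured_stage_incomes"]
    s1 = tables["insured_redistribution"]
    s2 = tables["insured_vs_uninsured"]
    unins = tables["uninsured_incomes"]

    rows = []

    def check(quantity, bracket, computed, reference, tol):
        rows.append(
            {
                "quantity": quantity,
                "bracket": bracket,
                "computed": computed,
                "reference": reference,
                "passed": bool(abs(computed - reference) <= tol),
            }
        )

    base = stages[stages["stage"] == "baseline"]["gini"].to_numpy()
    check("gini_initial", "-", float(base[0]), REFERENCE["gini_initial"], GINI_TOL)
    check("gini_after_premium", "-", float(base[1]), REFERENCE["gini_after_premium"], GINI_TOL)

    brackets = s1["bracket_w_r"].tolist()
    for name, col, frame, tol in (
        ("gini_after_oop", "gini_after_oop", s1, GINI_TOL),
        ("gini_after_reimbursement", "gini_after_reimbursement", s1, GINI_TOL),
        ("mt_scenario1", "mt", s1, GINI_TOL),
        ("rmt_percent_scenario1", "rmt_percent", s1, RMT_TOL),
        ("gini_uninsured", "gini", unins, GINI_TOL),
        ("mt_scenario2", "mt", s2, GINI_TOL),
    ):
        ref = REFERENCE[name]
        for b, computed, r in zip(brackets, frame[col].to_numpy(), ref):
            check(name, b, float(computed), float(r), tol)

    return pd.DataFrame.from_records(rows)


def n_failures(report: pd.DataFrame) -> int:
    return int((~report["passed"]).sum())
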