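import numpy as np
import pandas as pd
import pytest

from urrbmi_redist.theory import Calibration, ExpenditureProbabilityMatrix


@pytest.fixture
def calibration() -> Calibration:
    """Default calibration in multiples of the reference income."""
    return Calibration()


@pytest.fixture
def prob_matrix() -> ExpenditureProbabilityMatrix:
    return ExpenditureProbabilityMatrix.default()


def _person(hhid, pid, province, a2000, comps, a3137, **kw):
    row = {
        "hhid": hhid,
        "pid": pid,
        "province": province,
        "a2000": a2000,
        "a3137": a3137,
        "wage_income": comps[0],
        "agricultural_income": comps[1],
        "business_income": comps[2],
        "property_income": comps[3],
        "transfer_income": comps[4],
        "f2001a": np.nan,
        "f2004": 0.0,
        "f2024": np.nan,
        "f2028": np.nan,
        "f1008": 0.0,
        "f1008a": 0.0,
        "is_worker": 0,
    }
    for i in range(1, 6):
        row[f"f2025_{i}"] = 0.0
        row[f"f2029_{i}"] = 0.0
    row.update(kw)
    return row


@pytest.fixture
def tiny_survey() -> pd.DataFrame:
    """Three hand-built households: an insured claimant, an insured
    household below the deductible, and an uninsured employee household."""
    rows = [
        # household 1: two members, URRBMI, one inpatient claim above deductible
        _person(1, 1, "Sichuan", 2, (50_000, 0, 0, 0, 0), 1_000,
                f2001a=4, f2004=400, f1008a=500, is_worker=1,
                f2024=8_000.0, f2025_4=5_616.0),
        _person(1, 2, "Sichuan", 2, (50_000, 0, 0, 0, 0), 1_000,
                f2001a=4, f2004=400),
        # household 2: one member, URRBMI (rural code), tiny expense below deductible
        _person(2, 1, "Henan", 1, (18_000, 2_000, 0, 0, 1_000), 0,
                f2001a=3, f2004=400, f2024=500.0),
        # household 3: one member, employee scheme, non-inpatient spending
        _person(3, 1, "Beijing", 1, (120_000, 0, 0, 6_000, 0), 4_000,
                f2001a=1, f2004=1_800, f1008=300, is_worker=1,
                f2028=2_000.0, f2029_1=800.0),
    ]
    return pd.DataFrame(rows)
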