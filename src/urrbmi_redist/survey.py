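"""Household-survey estimation pipeline for URRBMI redistribution.

Consumes person-level rows in a CHFS-style schema (variable names kept
verbatim: ``f2001a`` insurance type, ``f2004`` premium, ``f2024``/``f2028``
inpatient / non-inpatient expense, ``f2025_*``/``f2029_*`` reimbursement by
scheme, ``a3137`` income tax, ``f1008``/``f1008a`` pension contributions,
``a2000`` household size) and produces before/after-reimbursement Gini and
MT indices nationally, by macro-region and by expenditure tercile.

Income construction: household gross income is the sum of wage,
agricultural, business, property and transfer components; disposable income
subtracts income tax, resident-pension and annualised employee-pension
contributions, medical premiums and a flat per-worker unemployment
contribution; dividing by household size gives per-capita disposable
income, already net of all social-insurance contributions.

The Gini comparison is then: before = per-capita disposable income minus
the out-of-pocket expense, after = before plus the URRBMI reimbursement
(the sum of the resident-scheme components of ``f2025``/``f2029``, labelled
R2 and Q2).  Units of analysis and whether the expense is attached to the
reporting individual or spread per capita are configuration switches; the
defaults are person-level observations with individually attached amounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .inequality import gini, mt_index
from .regions import REGIONS, map_provinces

__all__ = [
    "INCOME_COMPONENTS",
    "PERSON_COLUMNS",
    "PipelineConfig",
    "PersonRecord",
    "HouseholdRecord",
    "classify_urrbmi",
    "aggregate_reimbursement",
    "per_capita_disposable_income",
    "tercile_brackets",
    "build_analysis_rows",
    "redistribution_by_stratum",
]

INCOME_COMPONENTS = (
    "wage_income",
    "agricultural_income",
    "business_income",
    "property_income",
    "transfer_income",
)

#: Columns a survey CSV must provide (person-level rows; household-level
#: fields repeated on every member's row).
PERSON_COLUMNS = (
    ("hhid", "pid", "province", "a2000", "a3137")
    + INCOME_COMPONENTS
    + ("f2001a", "f2004", "f2024", "f2028", "f1008", "f1008a", "is_worker")
    + tuple(f"f2025_{i}" for i in range(1, 6))
    + tuple(f"f2029_{i}" for i in range(1, 6))
)

UNEMPLOYMENT_FLAT_DEFAULT = 230.0  # flat annual contribution per worker, RMB

Channel = Literal["inpatient", "noninpatient"]
_CHANNEL_PREFIX = {"inpatient": "f2025", "noninpatient": "f2029"}
_CHANNEL_EXPENSE = {"inpatient": "f2024", "noninpatient": "f2028"}
BRACKET_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class PipelineConfig:
    """Switches of the empirical pipeline.

    unit
        ``"person"``: every individual is one observation carrying the
        household's per-capita disposable income (default).
        ``"household"``: one observation per household, member expenses
        and reimbursements pooled and divided by household size.
    oop_per_capita
        If True, a person's expense/reimbursement is divided by household
        size before adjusting their per-capita income; if False (default)
        the full amount is attached to the reporting individual.
    insured_only
        Restrict the comparison to URRBMI enrollees.
    """

    unemployment_flat: float = UNEMPLOYMENT_FLAT_DEFAULT
    pension_months: int = 12
    unit: Literal["person", "household"] = "person"
    oop_per_capita: bool = False
    insured_only: bool = False
    region_lookup_path: str | None = None


@dataclass
class PersonRecord:
    """One household member's insurance and medical variables."""

    insurance_code: int | None = None
    premium_paid: float = 0.0
    inpatient_expense: float | None = None
    noninpatient_expense: float | None = None
    inpatient_reimb_by_scheme: tuple = (0.0,) * 5
    noninpatient_reimb_by_scheme: tuple = (0.0,) * 5
    monthly_employee_pension: float = 0.0
    annual_resident_pension: float = 0.0
    is_worker: bool = False


@dataclass
class HouseholdRecord:
    """Household income components plus the member list."""

    wage: float = 0.0
    agricultural: float = 0.0
    business: float = 0.0
    property: float = 0.0
    transfer: float = 0.0
    income_tax: float = 0.0
    n_members: int = 1
    region: str | None = None
    persons: list = field(default_factory=list)


def classify_urrbmi(code) -> bool:
    """True iff the insurance-type code denotes residents' coverage.

    Codes 2 (urban resident scheme), 3 (rural cooperative scheme) and
    4 (merged urban-rural scheme) all count as URRBMI enrolment; 1 is the
    employee scheme, 5 government-funded care, missing means no evidence of
    coverage.  Out-of-range codes raise.
    """
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return False
    code = int(code)
    if code not in (1, 2, 3, 4, 5):
        raise ValueError(f"insurance code must be 1..5 or missing, got {code}")
    return code in (2, 3, 4)


def aggregate_reimbursement(person, channel: Channel) -> float:
    """Sum the residents'-scheme reimbursement components (2 + 3 + 4).

    ``person`` is a mapping / pandas row with ``f2025_*`` (inpatient) or
    ``f2029_*`` (non-inpatient) fields, or a :class:`PersonRecord`.
    Missing components count as zero (absence of a claim).
    Inpatient gives the series R2, non-inpatient Q2.
    """
    if channel not in _CHANNEL_PREFIX:
        raise ValueError(f"channel must be 'inpatient' or 'noninpatient', got {channel!r}")
    if isinstance(person, PersonRecord):
        vals = (
            person.inpatient_reimb_by_scheme
            if channel == "inpatient"
            else person.noninpatient_reimb_by_scheme
        )
        picked = vals[1:4]
    else:
        prefix = _CHANNEL_PREFIX[channel]
        picked = [person.get(f"{prefix}_{i}", 0.0) for i in (2, 3, 4)]
    return float(sum(0.0 if v is None or pd.isna(v) else float(v) for v in picked))


def per_capita_disposable_income(
    h: HouseholdRecord, unemployment_flat: float = UNEMPLOYMENT_FLAT_DEFAULT
) -> float:
    """Per-capita disposable income of one household.

    Gross income (five components) minus income tax, each member's annual
    resident-pension contribution, twelve times the monthly employee-pension
    contribution, medical premiums, and a flat unemployment-insurance
    contribution per worker; divided by household size.
    """
    if h.n_members < 1:
        raise ValueError(f"household size must be >= 1, got {h.n_members}")
    if h.persons and len(h.persons) > h.n_members:
        raise ValueError(
            f"{len(h.persons)} person records exceed household size {h.n_members}"
        )
    gross = h.wage + h.agricultural + h.business + h.property + h.transfer
    deductions = h.income_tax
    for p in h.persons:
        deductions += p.annual_resident_pension
        deductions += 12.0 * p.monthly_employee_pension
        deductions += p.premium_paid
        deductions += unemployment_flat if p.is_worker else 0.0
    return (gross - deductions) / h.n_members


def tercile_brackets(expenses) -> pd.Series:
    """Label positive expenses low / medium / high by empirical terciles.

    Cut points are the 33.33rd and 66.67th percentiles of the *positive*
    expenses; values at a cut point fall in the lower bracket.  Zero or
    missing expenses are returned as NaN (excluded from bracketed strata).
    Needs at least three positive observations.
    """
    e = pd.Series(np.asarray(expenses, dtype=float))
    pos = e[e > 0]
    if pos.size < 3:
        raise ValueError(f"need >= 3 positive expenses to form terciles, got {pos.size}")
    c1, c2 = np.percentile(pos, [100 / 3, 200 / 3])
    out = pd.Series(pd.NA, index=e.index, dtype="object")
    out[e > 0] = np.where(pos <= c1, "low", np.where(pos <= c2, "medium", "high"))
    return out


def _household_frame(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Collapse person rows to one row per household with disposable income."""
    hh_first = df.groupby("hhid", sort=True).first()
    gross = sum(hh_first[c].fillna(0.0) for c in INCOME_COMPONENTS)
    per_person = df.groupby("hhid", sort=True).agg(
        resident_pension=("f1008a", lambda s: s.fillna(0.0).sum()),
        employee_pension=("f1008", lambda s: s.fillna(0.0).sum()),
        premiums=("f2004", lambda s: s.fillna(0.0).sum()),
        n_workers=("is_worker", lambda s: s.fillna(0).astype(float).sum()),
    )
    disposable = (
        gross
        - hh_first["a3137"].fillna(0.0)
        - per_person["resident_pension"]
        - config.pension_months * per_person["employee_pension"]
        - per_person["premiums"]
        - config.unemployment_flat * per_person["n_workers"]
    )
    out = pd.DataFrame(
        {
            "hh_size": hh_first["a2000"],
            "hh_disposable": disposable,
            "province": hh_first["province"],
        }
    )
    return out


def build_analysis_rows(
    df: pd.DataFrame, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Turn raw survey rows into analysis rows plus a drop log.

    Returns ``(rows, log)`` where ``rows`` has one record per person with
    per-capita disposable income, out-of-pocket and URRBMI reimbursement
    amounts per channel, region, URRBMI flag and tercile bracket labels,
    and ``log`` counts every exclusion so that rows in equal rows kept plus
    rows dropped.
    """
    config = config or PipelineConfig()
    missing = [c for c in PERSON_COLUMNS if c not in df.columns and c != "province"]
    if "province" not in df.columns and "region" not in df.columns:
        missing.append("province (or region)")
    if missing:
        raise ValueError(f"survey table lacks required columns: {missing}")
    if len(df) == 0:
        raise ValueError("no records in survey table")

    log: dict = {"rows_in": int(len(df))}
    df = df.copy()
    if "province" not in df.columns:
        df["province"] = pd.NA

    bad_size = df["a2000"].isna() | (df["a2000"] < 1)
    log["dropped_bad_household_size"] = int(bad_size.sum())
    df = df[~bad_size]
    if len(df) == 0:
        raise ValueError("no records with a valid household size")

    hh = _household_frame(df, config)
    hh["income"] = hh["hh_disposable"] / hh["hh_size"]

    rows = df.merge(
        hh[["income", "hh_size"]], left_on="hhid", right_index=True, how="left"
    )
    negative = rows["income"] < 0
    log["dropped_negative_income"] = int(negative.sum())
    rows = rows[~negative]
    if len(rows) == 0:
        raise ValueError("no records with nonnegative per-capita disposable income")

    codes = rows["f2001a"]
    valid = codes.isna() | codes.isin([1, 2, 3, 4, 5])
    if not valid.all():
        raise ValueError(
            f"invalid insurance codes: {sorted(codes[~valid].unique().tolist())}"
        )
    rows["insured_urrbmi"] = codes.isin([2, 3, 4])
    rows["insurance_known"] = codes.notna()

    if "region" in rows.columns and rows["region"].notna().any():
        region = rows["region"]
    else:
        region = map_provinces(rows["province"], config.region_lookup_path)
    log["unmapped_region"] = int(region.isna().sum())
    rows["region"] = region

    for channel in ("inpatient", "noninpatient"):
        expense_col = _CHANNEL_EXPENSE[channel]
        prefix = _CHANNEL_PREFIX[channel]
        reimb = sum(rows[f"{prefix}_{i}"].fillna(0.0) for i in (2, 3, 4))
        rows[f"reimb_{channel}"] = reimb
        rows[f"oop_{channel}"] = rows[expense_col]
        expense = rows[expense_col].astype(float)
        n_pos = int((expense > 0).sum())
        if n_pos >= 3:
            rows[f"bracket_{channel}"] = tercile_brackets(expense.to_numpy()).to_numpy()
        else:
            rows[f"bracket_{channel}"] = pd.NA
        log[f"bracketed_{channel}"] = n_pos
        log[f"excluded_from_brackets_{channel}"] = int(len(rows) - n_pos)

    keep = [
        "hhid",
        "pid",
        "income",
        "hh_size",
        "region",
        "insured_urrbmi",
        "insurance_known",
        "oop_inpatient",
        "reimb_inpatient",
        "bracket_inpatient",
        "oop_noninpatient",
        "reimb_noninpatient",
        "bracket_noninpatient",
    ]
    rows = rows[keep].reset_index(drop=True)
    log["rows_out"] = int(len(rows))
    return rows, log


def _before_after(
    sub: pd.DataFrame, channel: Channel, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, int]:
    """Income vectors before and after reimbursement for one stratum.

    Returns (before, after, n_dropped_negative)."""
    oop = sub[f"oop_{channel}"].fillna(0.0).to_numpy(dtype=float)
    reimb = sub[f"reimb_{channel}"].fillna(0.0).to_numpy(dtype=float)
    income = sub["income"].to_numpy(dtype=float)
    if config.unit == "household":
        g = pd.DataFrame(
            {"hhid": sub["hhid"], "income": income, "size": sub["hh_size"],
             "oop": oop, "reimb": reimb}
        ).groupby("hhid", sort=True)
        income = g["income"].first().to_numpy()
        size = g["size"].first().to_numpy(dtype=float)
        oop = g["oop"].sum().to_numpy() / size
        reimb = g["reimb"].sum().to_numpy() / size
    elif config.oop_per_capita:
        size = sub["hh_size"].to_numpy(dtype=float)
        oop = oop / size
        reimb = reimb / size
    before = income - oop
    after = before + reimb
    ok = before >= 0
    return before[ok], after[ok], int((~ok).sum())


def redistribution_by_stratum(
    rows: pd.DataFrame,
    stratifier: Literal["national", "region", "bracket"] = "national",
    channel: Channel = "inpatient",
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Before/after-reimbursement Gini and MT index per stratum.

    ``before`` is per-capita disposable income minus the out-of-pocket
    expense for the chosen channel; ``after`` adds back the URRBMI
    reimbursement (R2 or Q2).  Strata: ``national`` (plus the four regions
    appended for context when stratifier is ``region``) or expenditure
    ``bracket`` (low / medium / high; only rows with a positive expense).
    Strata with fewer than two usable observations are reported as missing
    (NaN row), not zero.
    """
    config = config or PipelineConfig()
    if channel not in _CHANNEL_PREFIX:
        raise ValueError(f"unknown channel {channel!r}")
    work = rows[rows["insured_urrbmi"]] if config.insured_only else rows

    if stratifier == "national":
        strata = [("National", work)]
    elif stratifier == "region":
        strata = [("National", work)] + [
            (r, work[work["region"] == r]) for r in REGIONS
        ]
    elif stratifier == "bracket":
        col = f"bracket_{channel}"
        strata = [(b, work[work[col] == b]) for b in BRACKET_LABELS]
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")

    records = []
    for name, sub in strata:
        if len(sub) == 0:
            records.append(
                {"stratum": name, "gini_before": np.nan, "gini_after": np.nan,
                 "mt": np.nan, "rmt_percent": np.nan, "n": 0, "n_dropped": 0}
            )
            continue
        before, after, dropped = _before_after(sub, channel, config)
        if before.size < 2 or before.sum() <= 0:
            records.append(
                {"stratum": name, "gini_before": np.nan, "gini_after": np.nan,
                 "mt": np.nan, "rmt_percent": np.nan, "n": int(before.size),
                 "n_dropped": dropped}
            )
            continue
        g_before = gini(before).gini
        g_after = gini(after).gini
        idx = mt_index(g_before, g_after)
        records.append(
            {
                "stratum": name,
                "gini_before": idx.gini_before,
                "gini_after": idx.gini_after,
                "mt": idx.mt,
                "rmt_percent": idx.rmt_percent,
                "n": int(before.size),
                "n_dropped": dropped,
            }
        )
    return pd.DataFrame.from_records(records).set_index("stratum")
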