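"""Synthetic CHFS-style survey generator.

Emits person-level rows in the exact schema the empirical pipeline
consumes, with the statistical structure the analysis assumes: right-skewed
(lognormal) household per-capita incomes with regional level differences,
the four NBS macro-regions, residents'-scheme enrolment by region, banded
inpatient expenditures whose band probabilities tilt against income rank
(poorer households are more likely to incur the expensive episodes, richer
ones the cheap ones), and reimbursements produced by the benefit-rule
engine — URRBMI payouts for enrollees, zero for the uninsured.

The generator is deterministic given the seed, and
:func:`embed_known_truth` also returns the population redistribution
indices computed directly from the generated microdata, so pipeline output
can be checked for exact recovery.

It is a stand-in with the right qualitative structure, not a calibration
to the real survey's marginals; see the package methods note for what that
does and does not validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .inequality import gini
from .policy import PolicySchedule
from .regions import REGIONS, load_region_map
from .survey import BRACKET_LABELS, tercile_brackets

__all__ = ["GeneratorConfig", "generate", "embed_known_truth"]

#: Expenditure band midpoints as multiples of the reference income
#: (RMB 40,000), matching the calibrated bracket ladder of the quintile
#: model; the lowest band sits at the secondary-tier deductible.
EXPENSE_BAND_MULTIPLIERS = (0.02, 0.08, 0.14, 0.20, 0.26)
W_R = 40_000.0


def _default_inpatient_schedule() -> PolicySchedule:
    return PolicySchedule(
        premium=400.0,
        deductible=800.0,
        coinsurance_rate=0.78,
        ceiling=240_000.0,
        label="secondary-tier",
        units="RMB",
    )


def _default_outpatient_schedule() -> PolicySchedule:
    # outpatient pooling benefit: low deductible, 50% rate, tight ceiling
    return PolicySchedule(
        premium=0.0,
        deductible=100.0,
        coinsurance_rate=0.5,
        ceiling=4_000.0,
        label="outpatient-pooling",
        units="RMB",
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic survey.

    Regional income levels are lognormal (meanlog, sdlog) for per-capita
    disposable income in RMB; sdlog around 0.85 puts the national Gini in
    the mid-0.4s to low-0.5s, the range household finance surveys report
    for China.  ``expense_gradient`` is the per-band probability step per
    unit of centred income rank: 0.05 reproduces the calibrated ladder in
    which the poorest face band probabilities 0.10..0.30 (cheapest to
    dearest) and the richest the reverse.
    """

    n_households: int = 10_000
    seed: int = 20190101
    region_shares: dict = field(
        default_factory=lambda: {
            "East": 0.40, "Central": 0.26, "West": 0.27, "Northeast": 0.07
        }
    )
    income_lognormal_params: dict = field(
        default_factory=lambda: {
            "East": (10.35, 0.88),
            "Central": (9.95, 0.82),
            "West": (9.88, 0.85),
            "Northeast": (10.05, 0.78),
        }
    )
    urrbmi_enrolment_rate: dict = field(
        default_factory=lambda: {
            "East": 0.62, "Central": 0.75, "West": 0.80, "Northeast": 0.70
        }
    )
    expense_gradient: float = 0.05
    inpatient_rate: float = 0.12
    noninpatient_rate: float = 0.55
    schedule: PolicySchedule = field(default_factory=_default_inpatient_schedule)
    outpatient_schedule: PolicySchedule = field(
        default_factory=_default_outpatient_schedule
    )
    household_size_distribution: dict = field(
        default_factory=lambda: {1: 0.15, 2: 0.25, 3: 0.25, 4: 0.20, 5: 0.10, 6: 0.05}
    )
    worker_rate: float = 0.55

    def __post_init__(self) -> None:
        errors = []
        if self.n_households < 1:
            errors.append(f"n_households must be >= 1, got {self.n_households}")
        if set(self.region_shares) != set(REGIONS):
            errors.append(f"region_shares must cover exactly {REGIONS}")
        elif not np.isclose(sum(self.region_shares.values()), 1.0, atol=1e-9):
            errors.append("region_shares must sum to 1")
        for name, d in (
            ("income_lognormal_params", self.income_lognormal_params),
            ("urrbmi_enrolment_rate", self.urrbmi_enrolment_rate),
        ):
            if set(d) != set(REGIONS):
                errors.append(f"{name} must cover exactly {REGIONS}")
        for name, v in (
            ("inpatient_rate", self.inpatient_rate),
            ("noninpatient_rate", self.noninpatient_rate),
            ("worker_rate", self.worker_rate),
        ):
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must lie in [0, 1], got {v}")
        if set(self.region_shares) == set(REGIONS):
            for r, v in self.urrbmi_enrolment_rate.items():
                if not 0.0 <= v <= 1.0:
                    errors.append(f"urrbmi_enrolment_rate[{r}] must lie in [0, 1]")
        sizes = self.household_size_distribution
        if not sizes or any(k < 1 for k in sizes):
            errors.append("household sizes must be >= 1")
        elif not np.isclose(sum(sizes.values()), 1.0, atol=1e-9):
            errors.append("household_size_distribution must sum to 1")
        if not 0.0 <= self.expense_gradient <= 0.1:
            errors.append(
                f"expense_gradient must lie in [0, 0.1] so band probabilities "
                f"stay nonnegative, got {self.expense_gradient}"
            )
        if errors:
            raise ValueError("invalid generator config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("schedule", "outpatient_schedule"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = PolicySchedule.from_mapping(raw[key])
        for key in ("income_lognormal_params",):
            if key in raw:
                raw[key] = {r: tuple(v) for r, v in raw[key].items()}
        if "household_size_distribution" in raw:
            raw["household_size_distribution"] = {
                int(k): v for k, v in raw["household_size_distribution"].items()
            }
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = self.schedule.to_dict()
        d["outpatient_schedule"] = self.outpatient_schedule.to_dict()
        return d


def _band_probabilities(rank_pct: np.ndarray, gradient: float) -> np.ndarray:
    """Per-person probabilities over the five expense bands.

    ``rank_pct`` in [0, 1] is the within-region income rank; the band
    probabilities are uniform 0.2 tilted by ±gradient steps so the poorest
    get the rising ladder and the richest the falling one.
    """
    t = 2.0 * rank_pct - 1.0  # -1 poorest .. +1 richest
    k = np.arange(len(EXPENSE_BAND_MULTIPLIERS)) - 2.0  # centred band index
    p = 0.2 - gradient * t[:, None] * k[None, :]
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


def generate(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Draw a synthetic person-level survey table.

    Deterministic given ``config.seed``.  Monetary values are rounded to
    cents so a CSV round trip is exact.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    n_h = config.n_households
    regions = list(REGIONS)
    region_of_hh = rng.choice(
        regions, size=n_h, p=[config.region_shares[r] for r in regions]
    )
    sizes_support = sorted(config.household_size_distribution)
    size_of_hh = rng.choice(
        sizes_support,
        size=n_h,
        p=[config.household_size_distribution[s] for s in sizes_support],
    )

    # provinces within region, uniform over the NBS lookup
    by_region: dict[str, list[str]] = {r: [] for r in REGIONS}
    for prov, reg in load_region_map().items():
        by_region[reg].append(prov)
    province_of_hh = np.array(
        [by_region[r][i] for r, i in zip(
            region_of_hh,
            (rng.random(n_h) * np.array([len(by_region[r]) for r in region_of_hh])).astype(int),
        )]
    )

    percap = np.empty(n_h)
    for r in regions:
        m = region_of_hh == r
        mu, sd = config.income_lognormal_params[r]
        percap[m] = rng.lognormal(mu, sd, size=int(m.sum()))
    percap = np.round(percap, 2)
    hh_disposable = percap * size_of_hh

    # person-level frame
    hhid = np.repeat(np.arange(1, n_h + 1), size_of_hh)
    n_p = hhid.size
    pid = np.concatenate([np.arange(1, s + 1) for s in size_of_hh])
    region_p = np.repeat(region_of_hh, size_of_hh)
    province_p = np.repeat(province_of_hh, size_of_hh)
    size_p = np.repeat(size_of_hh, size_of_hh)
    percap_p = np.repeat(percap, size_of_hh)

    is_worker = rng.random(n_p) < config.worker_rate

    # insurance: URRBMI at the regional rate; remainder mostly employee
    # scheme, a sliver of government-funded care and of no coverage
    enrol_p = np.array([config.urrbmi_enrolment_rate[r] for r in region_p])
    u = rng.random(n_p)
    urrbmi = u < enrol_p
    rest = (u - enrol_p) / np.maximum(1.0 - enrol_p, 1e-12)
    code = np.full(n_p, np.nan)
    code[urrbmi] = rng.choice([2, 3, 4], size=int(urrbmi.sum()), p=[0.2, 0.2, 0.6])
    uebmi = ~urrbmi & (rest < 0.80)
    gov = ~urrbmi & ~uebmi & (rest < 0.85)
    code[uebmi] = 1
    code[gov] = 5  # remaining NaN = uninsured / unknown

    # premiums: flat residents' premium; employee medical contributions
    # are payroll-based, drawn lognormal around RMB 1,500
    f2004 = np.zeros(n_p)
    f2004[urrbmi] = config.schedule.premium
    f2004[uebmi] = np.round(rng.lognormal(7.2, 0.5, size=int(uebmi.sum())), 2)

    # pensions: residents pay small annual amounts, workers monthly ones
    f1008a = np.where(
        (~is_worker) & urrbmi, rng.choice([100.0, 200.0, 500.0], size=n_p), 0.0
    )
    f1008 = np.where(is_worker, np.round(rng.lognormal(5.5, 0.6, size=n_p), 2), 0.0)

    # inpatient expenses: banded, probabilities tilted against income rank
    rank = pd.Series(percap_p).groupby(pd.Series(region_p)).rank(pct=True).to_numpy()
    has_inpatient = rng.random(n_p) < config.inpatient_rate
    band_p = _band_probabilities(rank, config.expense_gradient)
    band = (rng.random(n_p)[:, None] > band_p.cumsum(axis=1)).sum(axis=1)
    band = np.minimum(band, len(EXPENSE_BAND_MULTIPLIERS) - 1)
    noise = rng.uniform(0.8, 1.2, size=n_p)
    f2024 = np.where(
        has_inpatient,
        np.round(np.array(EXPENSE_BAND_MULTIPLIERS)[band] * W_R * noise, 2),
        np.nan,
    )

    # non-inpatient expenses: smaller, right-skewed, same gradient via rank
    has_noninpatient = rng.random(n_p) < config.noninpatient_rate
    f2028 = np.where(
        has_noninpatient,
        np.round(rng.lognormal(6.5, 1.0, size=n_p) * (1.2 - 0.4 * rank), 2),
        np.nan,
    )

    # reimbursements via the benefit rules; paid into the component of the
    # scheme actually held (f2025_2/3/4 for the residents' codes)
    f2025 = np.zeros((n_p, 5))
    f2029 = np.zeros((n_p, 5))
    inp_claim = has_inpatient & ~np.isnan(f2024)
    out_claim = has_noninpatient & ~np.isnan(f2028)
    inp_pay = np.zeros(n_p)
    out_pay = np.zeros(n_p)
    inp_pay[inp_claim] = config.schedule.reimbursement(f2024[inp_claim])
    out_pay[out_claim] = config.outpatient_schedule.reimbursement(f2028[out_claim])
    inp_pay = np.round(inp_pay, 2)
    out_pay = np.round(out_pay, 2)
    for c in (2, 3, 4):
        m = urrbmi & (code == c)
        f2025[m, c - 1] = inp_pay[m]
        f2029[m, c - 1] = out_pay[m]
    # employee-scheme payouts, so R2 genuinely isolates the residents' scheme
    uebmi_sched = PolicySchedule(
        premium=0.0, deductible=1300.0, coinsurance_rate=0.85,
        ceiling=500_000.0, label="employee", units="RMB",
    )
    m = uebmi & inp_claim
    f2025[m, 0] = np.round(uebmi_sched.reimbursement(f2024[m]), 2)
    m = uebmi & out_claim
    f2029[m, 0] = np.round(0.6 * np.minimum(f2028[m], 5_000.0), 2)

    # taxes: only on comfortable incomes, roughly progressive
    hh_tax = np.round(np.maximum(hh_disposable - 100_000.0, 0.0) * 0.05, 2)

    # gross household income = disposable + all deductions, so the
    # pipeline's construction inverts the draw exactly
    per_hh = pd.DataFrame(
        {
            "hhid": hhid,
            "f1008a": f1008a,
            "f1008": f1008,
            "f2004": f2004,
            "worker": is_worker.astype(float),
        }
    ).groupby("hhid", sort=True).sum()
    deductions = (
        hh_tax
        + per_hh["f1008a"].to_numpy()
        + 12.0 * per_hh["f1008"].to_numpy()
        + per_hh["f2004"].to_numpy()
        + 230.0 * per_hh["worker"].to_numpy()
    )
    gross = hh_disposable + deductions

    # split gross into components, wage-dominant with household jitter
    shares = rng.dirichlet([12.0, 1.6, 2.4, 1.0, 3.0], size=n_h)
    comps = np.round(gross[:, None] * shares[:, :4], 2)
    transfer = np.round(gross - comps.sum(axis=1), 2)

    df = pd.DataFrame(
        {
            "hhid": hhid,
            "pid": pid,
            "province": province_p,
            "a2000": size_p,
            "wage_income": np.repeat(comps[:, 0], size_of_hh),
            "agricultural_income": np.repeat(comps[:, 1], size_of_hh),
            "business_income": np.repeat(comps[:, 2], size_of_hh),
            "property_income": np.repeat(comps[:, 3], size_of_hh),
            "transfer_income": np.repeat(transfer, size_of_hh),
            "a3137": np.repeat(hh_tax, size_of_hh),
            "f2001a": code,
            "f2004": f2004,
            "f2024": f2024,
            "f2028": f2028,
            "f1008": f1008,
            "f1008a": f1008a,
            "is_worker": is_worker.astype(int),
        }
    )
    for i in range(5):
        df[f"f2025_{i + 1}"] = f2025[:, i]
        df[f"f2029_{i + 1}"] = f2029[:, i]
    return df


def _truth_indices(income: np.ndarray, oop: np.ndarray, reimb: np.ndarray) -> dict:
    """Population Gini before/after reimbursement on the given microdata.

    Persons whose post-out-of-pocket income would be negative are excluded,
    mirroring the pipeline's exclusion rule."""
    before = income - oop
    ok = before >= 0
    before = before[ok]
    after = before + reimb[ok]
    g_before = gini(before).gini
    g_after = gini(after).gini
    return {
        "gini_before": g_before,
        "gini_after": g_after,
        "mt": g_before - g_after,
        "n": int(before.size),
    }


def embed_known_truth(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a survey table plus its ground-truth redistribution indices.

    The truth sheet recomputes per-capita disposable income from the
    generated columns (the same arithmetic the pipeline applies) and
    reports national before/after-reimbursement Gini and MT per channel
    and per inpatient expenditure tercile — an internal oracle for exact-
    recovery checks of the pipeline.
    """
    config = config or GeneratorConfig()
    df = generate(config)

    hh = df.groupby("hhid", sort=True)
    gross = hh[
        ["wage_income", "agricultural_income", "business_income",
         "property_income", "transfer_income"]
    ].first().sum(axis=1)
    disposable = (
        gross
        - hh["a3137"].first()
        - hh["f1008a"].sum()
        - 12.0 * hh["f1008"].sum()
        - hh["f2004"].sum()
        - 230.0 * hh["is_worker"].sum()
    )
    percap = (disposable / hh["a2000"].first()).rename("income")
    rows = df.merge(percap, left_on="hhid", right_index=True, how="left")
    # mirror the pipeline: households with negative disposable income are
    # excluded before any stratification
    rows = rows[rows["income"] >= 0].reset_index(drop=True)

    truth: dict = {"config_seed": config.seed, "n_persons": int(len(rows))}
    for channel, expense_col, prefix in (
        ("inpatient", "f2024", "f2025"),
        ("noninpatient", "f2028", "f2029"),
    ):
        income = rows["income"].to_numpy(dtype=float)
        oop = rows[expense_col].fillna(0.0).to_numpy(dtype=float)
        reimb = sum(
            rows[f"{prefix}_{i}"].fillna(0.0) for i in (2, 3, 4)
        ).to_numpy(dtype=float)
        truth[channel] = {"national": _truth_indices(income, oop, reimb)}

    expense = rows["f2024"].astype(float)
    if int((expense > 0).sum()) >= 3:
        labels = tercile_brackets(expense.to_numpy())
        brackets = {}
        for b in BRACKET_LABELS:
            m = (labels == b).to_numpy()
            brackets[b] = _truth_indices(
                rows["income"].to_numpy(dtype=float)[m],
                rows["f2024"].fillna(0.0).to_numpy(dtype=float)[m],
                sum(rows[f"f2025_{i}"].fillna(0.0) for i in (2, 3, 4)).to_numpy()[m],
            )
        truth["inpatient"]["brackets"] = brackets
    return df, truth
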