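# Methods

## The quintile model

The theoretical module (`urrbmi_redist.theory`) evaluates the
redistributive effect of a residents' medical insurance benefit package
on a stylised population of five equally sized income quintiles at 0.3,
0.6, 1, 2 and 3 times the reference per-capita disposable income W_r
(RMB 40,000 by default; all computations are numeraire-invariant, so the
default working unit is multiples of W_r).

Benefit parameters follow a secondary-tier hospital schedule: flat
premium 0.01 W_r, deductible 0.02 W_r, coinsurance rate 78%, per-claim
ceiling 6 W_r.  Inpatient expenditure takes one of five bracket values
(0.02, 0.08, 0.14, 0.20, 0.26 W_r); the lowest bracket coincides with the
deductible and also stands for the no-spending case, which is why the
`Calibration` validator requires it to equal the deductible.  Each
quintile faces bracket-specific probabilities arranged as a gradient:
the poorest quintile's probabilities rise 0.10 → 0.30 in 0.05 steps from
the cheapest to the dearest bracket, the richest quintile's fall
0.30 → 0.10, the middle is uniform at 0.20.  Probabilities are normalised
per quintile across brackets (each row of the matrix sums to one).

Disposable income evolves through four states per quintile × bracket:

1. initial income;
2. after the flat premium;
3. after out-of-pocket payment — the expense enters **weighted by the
   probability** of incurring that bracket's episode, i.e. the expected
   position of the bracket's risk pool;
4. after reimbursement — the payout
   `coinsurance_rate × (expense − deductible)` is added back **in full**,
   the position of the member who actually filed the claim.

The asymmetry between stages 3 and 4 is a defining convention of the
model, not an error; the implementation reproduces it as specified and
does not reinterpret it.  The ceiling never binds under the default
calibration (maximum claim 0.26 W_r ≪ 6 W_r); `stage_incomes` emits a
warning if a user calibration makes it bind, because the piecewise-linear
payout then changes regime and the published monotonicity patterns need
not hold.

Scenario 1 compares, per bracket, the Gini after out-of-pocket payment
with the Gini after reimbursement among the insured (MT and RMT).
Scenario 2 compares an uninsured counterfactual — full bill, no premium,
no payout — with the insured post-reimbursement distribution (MT only).

### Rounding convention for reported tables

Internal computation is full double precision.  Emitted tables round
Ginis and incomes to 4 decimals and then derive MT as the difference of
the **rounded** Ginis and RMT from the rounded MT and rounded
pre-reimbursement Gini (2-decimal percent).  This keeps every reported
index exactly consistent with the reported Ginis; at full precision the
fourth decimal of MT can differ by one unit from the difference of the
rounded values.  `ScenarioResult.mt`/`.rmt_percent` expose the
full-precision quantities for anyone who prefers them.

## Inequality primitives

`gini` uses the trapezoid rule on the grouped Lorenz curve; for equal
group weights this is algebraically identical to the pairwise
mean-difference form `Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄)`, which `gini_pairwise`
implements by brute force as an independent O(n²) cross-check (the test
suite asserts agreement to 1e-9 on random vectors).  Micro samples are
treated as n groups of one, so the same estimator serves the survey
pipeline.  Equal weighting of entries is assumed throughout; survey
design weights are out of scope.  RMT is reported as `None` when the
pre-benefit Gini is zero — a relative effect on a perfectly equal
distribution is undefined, and silently returning zero would hide that.

## Survey pipeline

`urrbmi_redist.survey` consumes person-level CSV rows using the CHFS 2019
variable names (`f2001a`, `f2004`, `f2024`, `f2028`, `f2025_1..5`,
`f2029_1..5`, `a3137`, `f1008`, `f1008a`, `a2000`, five household income
components, province).  Decisions where the construction was genuinely
open:

- **Employee-pension annualisation.** `f1008` is a monthly amount listed
  among annual deductions; the only consistent reading is a ×12
  annualisation, exposed as `PipelineConfig.pension_months`.
- **Unit of analysis.** The Gini's unit is not pinned down by the income
  construction, which is per capita.  Default: each person is one
  observation carrying their household's per-capita disposable income
  (`unit="person"`); a household-level alternative pools member expenses
  and divides by household size (`unit="household"`).
- **Attachment of expenses.** By default an expense/reimbursement adjusts
  the income of the person who reported it in full
  (`oop_per_capita=False`); the per-capita alternative divides by
  household size.
- **Missing values.** Reimbursement components missing ⇒ 0 (absence of a
  claim); expenses missing or zero ⇒ excluded from bracketed strata but
  kept, with zero out-of-pocket, in national/regional strata.  Households
  with negative constructed disposable income are excluded and counted in
  the drop log, as are person rows whose post-out-of-pocket income would
  be negative.  Every exclusion is logged so rows in = rows kept + rows
  dropped.
- **Premium subtraction happens once**, inside disposable-income
  construction (income is "net of all social-insurance contributions");
  the before-reimbursement income is that net income minus the
  out-of-pocket expense only.
- **Terciles.** Low/medium/high brackets cut positive expenses at the
  33.33rd/66.67th percentiles (linear interpolation); ties at a cut point
  fall to the lower bracket, so an all-ties vector is all-low rather than
  arbitrary.
- **Regions.** Provinces map to East/Central/West/Northeast via the
  standard NBS classification, shipped as an editable CSV
  (`data/province_regions.csv`).

The pipeline does not attempt to reproduce published point estimates for
the real survey: the CHFS microdata are access-restricted.  Validation is
against the synthetic generator instead (below).

## Synthetic survey generator

`urrbmi_redist.synthetic` emits the exact input schema of the pipeline
with the structure the analysis assumes.  Study conditions (defaults):

- 10,000 households; one `numpy.random.default_rng` stream seeded from
  `GeneratorConfig.seed`, so output is bit-reproducible across platforms.
- Region shares 0.40/0.26/0.27/0.07 (East/Central/West/Northeast),
  roughly census population shares.  Household sizes 1–6 with mean ≈ 2.9.
- Per-capita disposable income lognormal per region (meanlog 9.88–10.35,
  sdlog 0.78–0.88), giving right-skewed incomes and a national Gini in
  the high-0.4s — the order of magnitude household finance surveys report
  for China.  Gross income is built *backwards* from the disposable draw
  by adding taxes, pensions, premiums and the flat per-worker
  unemployment contribution, then split into wage-dominant components,
  so the pipeline's income construction inverts the draw exactly.
- Residents'-scheme enrolment 0.62–0.80 by region (lower where the
  employee scheme dominates); codes 2/3/4 drawn 0.2/0.2/0.6.
- Inpatient episodes for 12% of persons, banded at the quintile model's
  bracket ladder (0.02–0.26 × RMB 40,000, ±20% noise); band probabilities
  tilt linearly with within-region income rank at 0.05 per step, the same
  gradient direction as the calibrated matrix (`expense_gradient=0`
  switches it off).  Non-inpatient spending is smaller, lognormal, for
  55% of persons.
- Reimbursements come from the benefit-rule engine: the secondary-tier
  schedule for inpatient claims of enrollees, an outpatient-pooling
  schedule (deductible 100, rate 50%, ceiling 4,000) for non-inpatient
  claims, zero for the uninsured.  Employee-scheme members get payouts in
  the `*_1` components only, so the resident aggregate R2/Q2 isolates the
  scheme under study.

`embed_known_truth` recomputes, directly from the generated microdata,
the national and per-tercile before/after Ginis the pipeline should
report — an internal oracle enabling exact-recovery tests (agreement to
1e-12, in practice bit-exact because generator truth and pipeline apply
the same arithmetic to the same columns; monetary values are rounded to
cents so the CSV round trip is lossless).

**What passing these tests shows** — that the pipeline's construction,
classification, aggregation, stratification and index computation are
internally correct, and that the qualitative patterns (positive national
MT, MT nondecreasing across expenditure terciles, no redistribution
without enrolment) emerge under realistic conditions.  **What it does not
show** — anything about the real survey's magnitudes: the generator does
not match CHFS marginals, sample size, skip logic, item nonresponse or
design weights, and its regional income parameters are plausible rather
than estimated.

## Problem sizes and runtime

The quintile model is 5×5 and runs in milliseconds.  The default
synthetic round trip (10,000 households, ≈ 30,000 persons) generates,
writes, re-reads and analyses in a few seconds on one CPU; the full test
suite takes well under a minute.  The pairwise Gini cross-check uses
1,000 random vectors of length ≤ 30, where the O(n²) oracle is
instantaneous.
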