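# urrbmi-redist

Does China's Urban–Rural Resident Basic Medical Insurance (URRBMI) — a
flat-premium scheme with a deductible, a coinsurance rate and a per-claim
ceiling — narrow or widen the income distribution, and by how much?  This
package implements the standard toolkit for answering that question:
inequality indices on grouped income data, a benefit-rule engine, a
calibrated quintile microsimulation, and a survey estimation pipeline in
the schema of the China Household Finance Survey (CHFS), exercised on a
synthetic generator because the real microdata are access-restricted.

It is aimed at health-financing and social-security researchers who want
reproducible before/after-reimbursement inequality comparisons.

## The indices

After ranking a covered population from poorest to richest and splitting
it into *n* equally sized groups, let *p*<sub>t</sub> be the cumulative
population share and *q*<sub>t</sub> the cumulative income share.  The
Gini coefficient is one minus twice the trapezoid area under the Lorenz
curve:

    B = 1/2 Σₜ (p_{t+1} − p_t)(q_{t+1} + q_t),      G = 1 − 2B

Redistribution of a benefit is measured by the Musgrave–Thin index
**MT = G − G\***, where *G* is the Gini after out-of-pocket medical
payment and *G\** the Gini after reimbursement, and by its relative form
**RMT = 100 · MT / G** (percent).  MT > 0 means the payout narrowed the
income gap.

Reimbursement for a claim of size *x* under a schedule with deductible
*d*, coinsurance rate *r* and per-claim ceiling *c* is
`min(r · max(0, x − d), c)`.

## Worked example

The default calibration sets the reference income W_r = RMB 40,000,
quintile incomes 0.3/0.6/1/2/3 W_r, flat premium 0.01 W_r, secondary-tier
deductible 0.02 W_r, coinsurance 78%, ceiling 6 W_r, and a probability
matrix in which poorer quintiles are more likely to incur the expensive
inpatient episodes.

```python
from urrbmi_redist import Calibration, ExpenditureProbabilityMatrix, scenario1

res = scenario1(Calibration(), ExpenditureProbabilityMatrix.default())
print(res.to_frame().to_string(index=False))
```

```
 bracket_w_r  gini_after_oop  gini_after_reimbursement     mt  rmt_percent
        0.02          0.3977                    0.3977 0.0000         0.00
        0.08          0.4006                    0.3872 0.0134         3.34
        0.14          0.4054                    0.3789 0.0265         6.54
        0.20          0.4120                    0.3727 0.0393         9.54
        0.26          0.4206                    0.3683 0.0523        12.43
```

Reading the rows: a claim equal to the deductible (0.02 W_r) triggers no
payout, so MT = 0.  Above the deductible the post-reimbursement Gini falls
below the post-out-of-pocket Gini, and both the absolute (MT) and relative
(RMT) redistributive effect rise monotonically with the size of the claim
— a 0.26 W_r hospital bill ends with the payout compressing the Gini by
0.0523 points, 12.43% of the pre-reimbursement dispersion.

The same machinery runs from the shell:

```bash
urrbmi-redist theory --out tables/          # four result tables + PASS/FAIL check
urrbmi-redist simulate --n 10000 --seed 7 --out survey.csv --truth truth.json
urrbmi-redist analyze --in survey.csv --out results/
```

`analyze` writes a national/regional MT table and an
expenditure-tercile table (low/medium/high, inpatient and non-inpatient
channels) plus a drop-count log of every excluded record.

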