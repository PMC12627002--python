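"""URRBMI benefit rules: flat premium, deductible, coinsurance rate, payout ceiling.

A :class:`PolicySchedule` holds the four parameters of a residents' medical
insurance benefit package.  Reimbursement for a claim is

    payout = min(coinsurance_rate * max(0, expense - deductible), ceiling)

i.e. nothing below the deductible, a fixed share of the excess between the
deductible and the point where the per-claim ceiling binds, and the ceiling
beyond that.  Amounts may be expressed either in currency (RMB) or as
multiples of the reference per-capita disposable income W_r; the ``units``
field records which, all formulas are unit-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

__all__ = ["PolicySchedule", "reimbursement", "apply_premium"]


@dataclass(frozen=True)
class PolicySchedule:
    """Benefit parameters of one hospital tier of a residents' scheme.

    Parameters
    ----------
    premium
        Flat annual contribution per enrollee (>= 0).
    deductible
        Out-of-pocket threshold below which no reimbursement is paid (>= 0).
    coinsurance_rate
        Fraction of the expense above the deductible that is reimbursed,
        in [0, 1].
    ceiling
        Maximum payout per reimbursement claim; must exceed the deductible.
    label
        Free text, e.g. the hospital tier the schedule applies to.
    units
        ``"RMB"`` or ``"W_r"`` — the unit all monetary fields are stated in.
    """

    premium: float
    deductible: float
    coinsurance_rate: float
    ceiling: float
    label: str = ""
    units: str = "RMB"

    def __post_init__(self) -> None:
        if self.premium < 0:
            raise ValueError(f"premium must be >= 0, got {self.premium}")
        if self.deductible < 0:
            raise ValueError(f"deductible must be >= 0, got {self.deductible}")
        if not 0.0 <= self.coinsurance_rate <= 1.0:
            raise ValueError(
                f"coinsurance_rate must lie in [0, 1], got {self.coinsurance_rate}"
            )
        if self.ceiling <= self.deductible:
            raise ValueError(
                f"ceiling ({self.ceiling}) must exceed deductible ({self.deductible})"
            )
        if self.units not in ("RMB", "W_r"):
            raise ValueError(f"units must be 'RMB' or 'W_r', got {self.units!r}")

    # -- benefit rule ------------------------------------------------------

    def reimbursement(self, expense):
        """Payout for a claim of ``expense``; accepts scalars or arrays."""
        e = np.asarray(expense, dtype=float)
        if (e < 0).any():
            raise ValueError("expense must be >= 0")
        payout = np.minimum(
            self.coinsurance_rate * np.maximum(e - self.deductible, 0.0),
            self.ceiling,
        )
        return float(payout) if np.isscalar(expense) else payout

    def apply_premium(self, income):
        """Disposable income after paying the flat premium."""
        y = np.asarray(income, dtype=float)
        if (y < self.premium).any():
            raise ValueError(
                f"income below the premium {self.premium}: would go negative"
            )
        out = y - self.premium
        return float(out) if np.isscalar(income) else out

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, m: dict) -> "PolicySchedule":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(m) - known
        if extra:
            raise ValueError(f"unknown policy-schedule fields: {sorted(extra)}")
        return cls(**m)

    @classmethod
    def from_yaml(cls, path) -> "PolicySchedule":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def reimbursement(expense, schedule: PolicySchedule):
    """Functional alias for :meth:`PolicySchedule.reimbursement`."""
    return schedule.reimbursement(expense)


def apply_premium(income, schedule: PolicySchedule):
    """Functional alias for :meth:`PolicySchedule.apply_premium`."""
    return schedule.apply_premium(income)
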