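"""Lorenz curves, Gini coefficients and redistributive indices on grouped income data.

The central object is a vector of per-capita incomes for *n* equally sized
population groups (income quintiles in the theoretical model, individual
survey records in the empirical pipeline — a micro sample is simply the
n-groups-of-one special case).  From the ascending-sorted vector the Lorenz
curve is formed from cumulative population shares ``p_t = t/n`` and
cumulative income shares ``q_t``; the Gini coefficient is one minus twice
the trapezoid area beneath the curve,

    B = 1/2 * sum_t (p_{t+1} - p_t) * (q_{t+1} + q_t)
    G = 1 - 2B = sum_t (p_t * q_{t+1} - p_{t+1} * q_t).

Redistribution of a benefit scheme is summarised by the Musgrave-Thin (MT)
index, the drop in the Gini from the pre-benefit to the post-benefit income
distribution, and by its relative form RMT = 100 * MT / G_before.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InequalityResult",
    "RedistributionIndices",
    "lorenz_points",
    "gini",
    "gini_pairwise",
    "mt_index",
]


def _as_income_vector(incomes) -> np.ndarray:
    """Validate a grouped income vector: length >= 2, finite, nonnegative, positive total."""
    x = np.asarray(incomes, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"income vector must be one-dimensional, got shape {x.shape}")
    if x.size < 2:
        raise ValueError(f"need at least 2 income groups, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("income vector contains NaN or infinite values")
    if (x < 0).any():
        raise ValueError("negative incomes are not allowed")
    if x.sum() <= 0:
        raise ValueError("total income must be positive")
    return x


@dataclass(frozen=True)
class InequalityResult:
    """Gini coefficient together with the area B beneath the Lorenz curve.

    The two are redundant (``gini == 1 - 2 * area_b``) but both are kept so
    downstream code can report whichever the convention at hand uses.
    """

    gini: float
    area_b: float

    def to_dict(self) -> dict:
        return {"gini": self.gini, "area_b": self.area_b}


@dataclass(frozen=True)
class RedistributionIndices:
    """Before/after Gini pair with the MT and RMT redistributive indices.

    ``rmt_percent`` is ``None`` when the pre-benefit Gini is zero: a relative
    effect on a perfectly equal distribution is undefined, not zero.
    """

    gini_before: float
    gini_after: float
    mt: float
    rmt_percent: float | None

    def to_dict(self) -> dict:
        return {
            "gini_before": self.gini_before,
            "gini_after": self.gini_after,
            "mt": self.mt,
            "rmt_percent": self.rmt_percent,
        }


def lorenz_points(incomes) -> np.ndarray:
    """Lorenz curve of a grouped income vector.

    Parameters
    ----------
    incomes
        Per-capita incomes of equally sized groups, in any order.

    Returns
    -------
    ndarray of shape (n + 1, 2)
        Rows are ``(p_t, q_t)`` starting at ``(0, 0)`` and ending at
        ``(1, 1)``; incomes are sorted ascending (stable) before cumulating.
    """
    x = _as_income_vector(incomes)
    x = np.sort(x, kind="stable")
    q = np.concatenate(([0.0], np.cumsum(x) / x.sum()))
    p = np.linspace(0.0, 1.0, x.size + 1)
    return np.column_stack([p, q])


def gini(incomes) -> InequalityResult:
    """Gini coefficient via the trapezoid rule on the grouped Lorenz curve."""
    pts = lorenz_points(incomes)
    p, q = pts[:, 0], pts[:, 1]
    area_b = float(np.sum(np.diff(p) * (q[1:] + q[:-1])) / 2.0)
    return InequalityResult(gini=1.0 - 2.0 * area_b, area_b=area_b)


def gini_pairwise(incomes) -> InequalityResult:
    """Gini coefficient as the normalised mean absolute difference.

    Brute-force double sum ``G = sum_ij |x_i - x_j| / (2 n^2 mean(x))`` over
    all ordered pairs.  For equally weighted groups this is algebraically
    identical to :func:`gini`; it is O(n^2) and intended as an independent
    cross-check, not for large samples.
    """
    x = _as_income_vector(incomes)
    n = x.size
    g = float(np.abs(x[:, None] - x[None, :]).sum() / (2.0 * n * n * x.mean()))
    return InequalityResult(gini=g, area_b=(1.0 - g) / 2.0)


def mt_index(gini_before: float, gini_after: float) -> RedistributionIndices:
    """Musgrave-Thin index MT = G_before - G_after and its relative form.

    MT > 0 means the benefit narrowed the income gap (positive
    redistribution); MT < 0 means it widened it.  RMT expresses MT as a
    percentage of the pre-benefit Gini and is undefined (``None``) when
    ``gini_before == 0``.
    """
    for name, g in (("gini_before", gini_before), ("gini_after", gini_after)):
        if not np.isfinite(g) or not (0.0 <= g <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {g}")
    mt = gini_before - gini_after
    rmt = None if gini_before == 0.0 else 100.0 * mt / gini_before
    return RedistributionIndices(
        gini_before=gini_before, gini_after=gini_after, mt=mt, rmt_percent=rmt
    )
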