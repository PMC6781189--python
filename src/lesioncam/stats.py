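"""Contingency statistics for the univariable factor analysis.

2x2 tables are laid out rows = exposure level (reference first),
columns = outcome (accurate, inaccurate):

            accurate   inaccurate
reference       a           b
comparison      c           d

The odds ratio of an accurate outcome for the comparison level versus the
reference is (c/d) / (a/b) = (b*c) / (a*d), with a 95% Wald interval on
the log scale,  exp( ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d) ).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

__all__ = ["Table2x2", "OddsRatioResult", "odds_ratio_wald", "chi_squared",
           "fisher_exact", "proportion_summary"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class Table2x2:
    """Counts a, b (reference row) and c, d (comparison row)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("cell counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    reference: str = "row 1"
    continuity_corrected: bool = False


def odds_ratio_wald(table: Table2x2, *, continuity: bool = False,
                    reference: str = "row 1") -> OddsRatioResult:
    """Odds ratio (comparison vs reference row) with 95% Wald CI.

    A zero cell makes the estimate degenerate; with ``continuity=True`` the
    Haldane 0.5 correction is added to every cell and the result flagged.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    corrected = False
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ValueError(
                "zero cell: enable continuity=True for the 0.5 correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (b * c) / (a * d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    return OddsRatioResult(
        odds_ratio=float(or_),
        ci_low=float(np.exp(log_or - _Z95 * se)),
        ci_high=float(np.exp(log_or + _Z95 * se)),
        reference=reference, continuity_corrected=corrected)


def chi_squared(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared without continuity correction on a 2xK table.

    Returns (statistic, degrees of freedom, p-value).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)


def fisher_exact(table: Table2x2) -> float:
    """Two-sided Fisher exact p: the hypergeometric mass of all tables with
    the observed margins whose probability does not exceed the observed."""
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


def proportion_summary(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in the
    clinical summary tables (e.g. 589/800 -> 73.6)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= count <= total):
        raise ValueError("count must lie in [0, total]")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
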