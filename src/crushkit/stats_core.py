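"""Elementary inferential statistics implemented from their defining formulas.

These are the non-mixed-model tests used throughout the analysis: the Welch
(unequal-variance) two-sample t test computable from printed summary
statistics, exact and chi-square inference on 2x2 contingency tables, the
Šidák multiplicity correction, and median/IQR summaries.  Each statistic is
computed from its closed form; SciPy supplies only the t and chi-square
distribution tail areas.  Group comparisons that the study design delegates
to linear mixed models are out of scope here — the pipeline exports tidy
per-timepoint tables for external mixed-model tools instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "SummaryStats2",
    "ContingencyTable2x2",
    "welch_t",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "sidak_adjust",
    "median_iqr",
]


@dataclass(frozen=True)
class SummaryStats2:
    """Two-group summary: mean, standard deviation and n per group."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def __post_init__(self) -> None:
        if self.sd_a < 0 or self.sd_b < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("each group needs n >= 2")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("table total must be > 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: float
    p: float

    def to_record(self, p_adjusted: float | None = None, m: int | None = None) -> dict:
        rec = {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_raw": self.p,
        }
        if p_adjusted is not None:
            rec["p_adjusted"] = p_adjusted
            rec["m"] = m
        return rec


def welch_t(summary: SummaryStats2) -> TestResult:
    """Welch two-sample t test from summary statistics.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b), with
    Welch–Satterthwaite degrees of freedom and a two-sided p value.
    """
    va = summary.sd_a**2 / summary.n_a
    vb = summary.sd_b**2 / summary.n_b
    if va + vb == 0:
        raise ValueError("both group variances are zero; t is undefined")
    t = (summary.mean_a - summary.mean_b) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (
        va**2 / (summary.n_a - 1) + vb**2 / (summary.n_b - 1)
    )
    p = 2.0 * _sps.t.sf(abs(t), df)
    return TestResult("welch_t", t, df, min(p, 1.0))


def _hypergeom_numerators(r1: int, r2: int, c1: int) -> tuple[range, list[int]]:
    """Exact integer numerators C(r1,x)*C(r2,c1-x) over the support of x."""
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = range(lo, hi + 1)
    return support, [math.comb(r1, x) * math.comb(r2, c1 - x) for x in support]


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact test by full hypergeometric enumeration.

    Conditions on both margins and sums the probabilities of every table no
    more probable than the observed one (the probability-mass rule, as in R's
    ``fisher.test``).  The enumeration is carried out in exact integer
    arithmetic, so ties at the observed probability are handled exactly.

    Returns 1.0 by convention when any margin is zero (no information).
    """
    r1, r2 = table.row_margins
    c1, _ = table.col_margins
    if r1 == 0 or r2 == 0 or c1 == 0 or table.col_margins[1] == 0:
        return 1.0
    support, nums = _hypergeom_numerators(r1, r2, c1)
    obs = nums[table.a - support.start]
    num_sum = sum(n for n in nums if n <= obs)
    denom = math.comb(table.total, c1)
    return num_sum / denom


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Pearson chi-square for a 2x2 table, optional Yates continuity correction.

    chi2 = N (|ad - bc| - correction)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, r2 = table.row_margins
    c1, c2 = table.col_margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a row or column margin is zero")
    det = abs(a * d - b * c)
    if yates:
        det = max(0.0, det - n / 2.0)
    stat = n * det**2 / (r1 * r2 * c1 * c2)
    p = _sps.chi2.sf(stat, 1)
    return TestResult("chi_square_yates" if yates else "chi_square", stat, 1.0, p)


def sidak_adjust(p: float, m: int) -> float:
    """Šidák multiplicity adjustment p_adj = 1 - (1 - p)^m for m comparisons."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1 or m != int(m):
        raise ValueError("m must be an integer >= 1")
    return float(min(1.0, max(0.0, 1.0 - (1.0 - p) ** m)))


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (25th, 75th) by linear interpolation between
    order statistics — numpy's default quantile rule, fixed here as the
    reporting convention."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires a non-empty input")
    med, q25, q75 = np.percentile(arr, [50.0, 25.0, 75.0])
    return float(med), float(q25), float(q75)
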