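"""Contingency-table and set-overlap statistics.

Implements the 2x2 chi-squared test (Yates continuity correction on by
default), the two-sided Fisher exact test by hypergeometric summation,
one-tailed t-tests (paired Student / unpaired Welch) and exact Venn
partitions of gene sets.

The chi-squared statistic for a table ``[[a, b], [c, d]]`` with margins
``R1, R2, C1, C2`` and grand total ``N`` is

    X^2 = N * (|ad - bc| - corr)^2 / (R1 * R2 * C1 * C2)

with ``corr = N/2`` under the Yates correction (clamped so the corrected
difference never goes negative) and 0 otherwise.  The p-value is the upper
tail of the 1-df chi-squared distribution, computed via the complementary
error function: ``p = erfc(sqrt(X^2 / 2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import erfc

from .errors import DataError, UsageError

__all__ = [
    "ContingencyTable",
    "TestResult",
    "chisq_2x2",
    "fisher_exact",
    "t_test_one_tailed",
    "venn_counts",
]


@dataclass
class ContingencyTable:
    """A labelled 2x2 table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise DataError(f"expected a 2x2 table, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise DataError("negative counts in contingency table")
        if self.counts.sum() == 0:
            raise DataError("contingency table grand total is zero")

    @property
    def margins(self) -> tuple[np.ndarray, np.ndarray]:
        return self.counts.sum(axis=1), self.counts.sum(axis=0)

    def to_record(self) -> dict:
        return {
            "rows": list(self.row_labels),
            "cols": list(self.col_labels),
            "counts": self.counts.tolist(),
        }


@dataclass
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str
    correction: bool = False
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p_value = float(min(max(self.p_value, 0.0), 1.0))

    def to_record(self) -> dict:
        rec = {
            "method": self.method,
            "statistic": float(self.statistic),
            # 3 significant digits, scientific notation: reporting precision
            "p": float(f"{self.p_value:.3g}") if self.p_value > 0 else 0.0,
            "p_exact": self.p_value,
            "correction": self.correction,
        }
        rec.update(self.extra)
        return rec


def _check_margins(table: ContingencyTable) -> None:
    rows, cols = table.margins
    if (rows == 0).any() or (cols == 0).any():
        raise DataError("contingency table has a zero marginal")


def chisq_2x2(table: ContingencyTable, continuity: bool = True) -> TestResult:
    """Pearson chi-squared test for a 2x2 table, 1 df.

    ``continuity=True`` applies the Yates correction; the corrected
    ``|ad - bc| - N/2`` term is clamped at zero so near-homogeneous tables
    cannot inflate the statistic.
    """
    _check_margins(table)
    (a, b), (c, d) = table.counts
    n = int(table.counts.sum())
    diff = abs(int(a) * int(d) - int(b) * int(c))
    if continuity:
        diff = max(diff - n / 2.0, 0.0)
    r1, r2 = int(a + b), int(c + d)
    c1, c2 = int(a + c), int(b + d)
    stat = n * diff * diff / (float(r1) * r2 * c1 * c2)
    p = float(erfc(math.sqrt(stat / 2.0)))
    return TestResult(stat, p, method="chisq_2x2", correction=continuity,
                      extra={"table": table.to_record()})


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities that do not exceed the observed table's probability.
    """
    _check_margins(table)
    a, b, c, d = (int(v) for v in table.counts.ravel())
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    rv = sps.hypergeom(n, c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    # tolerance guards against ties broken by floating-point noise
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return TestResult(odds, p, method="fisher_exact",
                      extra={"table": table.to_record()})


def t_test_one_tailed(x, y, alternative: str = "less",
                      paired: bool = False) -> TestResult:
    """One-tailed t-test: paired Student on differences, or unpaired Welch.

    ``alternative="less"`` tests mean(x) < mean(y).  Zero-variance inputs
    with zero mean difference return p = 0.5 flagged as degenerate; zero
    variance with a non-zero difference returns p -> 0 (or 1), also flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if alternative not in ("less", "greater"):
        raise UsageError(f"unknown alternative {alternative!r}")
    if x.size < 2 or y.size < 2:
        raise DataError("need at least 2 observations per sample")
    if paired:
        if x.size != y.size:
            raise DataError("paired samples must have equal length")
        diff = x - y
        if np.allclose(diff.std(ddof=1), 0.0):
            mean = float(diff.mean())
            if math.isclose(mean, 0.0, abs_tol=1e-300):
                return TestResult(0.0, 0.5, "t_paired", degenerate=True)
            favoured = (mean < 0) == (alternative == "less")
            return TestResult(math.copysign(math.inf, mean), 0.0 if favoured else 1.0,
                              "t_paired", degenerate=True)
        res = sps.ttest_rel(x, y, alternative=alternative)
        return TestResult(float(res.statistic), float(res.pvalue), "t_paired")
    if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
        mean = float(x.mean() - y.mean())
        if math.isclose(mean, 0.0, abs_tol=1e-300):
            return TestResult(0.0, 0.5, "t_welch", degenerate=True)
        favoured = (mean < 0) == (alternative == "less")
        return TestResult(math.copysign(math.inf, mean), 0.0 if favoured else 1.0,
                          "t_welch", degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return TestResult(float(res.statistic), float(res.pvalue), "t_welch")


def venn_counts(set_a, set_b) -> tuple[int, int, int]:
    """Exact two-set partition sizes: (only_A, only_B, both)."""
    sa, sb = set(set_a), set(set_b)
    both = len(sa & sb)
    return len(sa) - both, len(sb) - both, both
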