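"""Cell-type representation shifts and the proportional-dropout null.

Droplet capture is commonly assumed to discard the same fraction of every
cell type.  ``proportional_dropout_test`` checks that assumption: under H0
each cell is retained independently with the common plug-in rate
``r_hat = sum(post) / sum(pre)``; each type's retained count is tested
two-sided against ``Binomial(pre_t, r_hat)`` with Benjamini-Hochberg
correction across types.

With thousands of cells, the pure p-value is rejected for *every* type
whenever one abundant type collapses (the pooled rate is dragged away from
everybody's individual rate), so the ``flagged`` verdict additionally
requires the type's retention rate to deviate from ``r_hat`` by at least
``effect_threshold``-fold (default 1.5).  The p-values themselves are the
plain binomial construction throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .overlap_stats import TestResult

__all__ = [
    "CompositionTable",
    "cluster_proportions",
    "representation_reduction",
    "proportional_dropout_test",
]


@dataclass
class CompositionTable:
    """Per-condition cell-type counts and fractions."""

    per_condition: dict = field(default_factory=dict)

    def add(self, condition: str, labels: pd.Series) -> None:
        counts = labels.value_counts().sort_index()
        total = int(counts.sum())
        self.per_condition[condition] = {
            "total_cells": total,
            "types": {
                str(t): {"count": int(c), "fraction": float(c) / total}
                for t, c in counts.items()
            },
        }

    def fraction(self, condition: str, cell_type: str) -> float:
        return self.per_condition[condition]["types"][cell_type]["fraction"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, entry in self.per_condition.items():
            for ctype, v in entry["types"].items():
                rows.append({"condition": cond, "cell_type": ctype,
                             "count": v["count"],
                             "fraction": round(v["fraction"], 4)})
        return pd.DataFrame(rows)


def cluster_proportions(adata, condition_key: str = "condition",
                        type_key: str = "cell_type") -> CompositionTable:
    """Exact per-label counts and fractions from an annotated cell matrix."""
    if type_key not in adata.obs:
        raise DataError(f"cells carry no {type_key!r} label")
    labels = adata.obs[type_key]
    if labels.isna().any():
        raise DataError("unlabeled cells present")
    table = CompositionTable()
    if condition_key in adata.obs:
        for cond, sub in adata.obs.groupby(condition_key, observed=True):
            table.add(str(cond), sub[type_key])
    else:
        table.add("all", labels)
    return table


def representation_reduction(p_before: float, p_after: float) -> float:
    """Percent reduction in representation: 100 * (1 - p_after / p_before)."""
    if p_before <= 0:
        raise DataError("p_before must be positive")
    return 100.0 * (1.0 - p_after / p_before)


def proportional_dropout_test(pre_counts: dict[str, int],
                              post_counts: dict[str, int],
                              alpha: float = 0.05,
                              effect_threshold: float = 1.5
                              ) -> dict[str, TestResult]:
    """Per-type test of the common-retention-rate (proportional dropout) H0.

    ``pre_counts`` / ``post_counts`` map cell type to cell numbers before and
    after capture.  Returns per-type TestResults whose ``extra`` carries the
    observed and pooled retention rates, the BH-adjusted p-value, and the
    ``flagged`` verdict (adjusted p < alpha AND >= effect_threshold-fold
    rate deviation).
    """
    types = list(pre_counts)
    missing = [t for t in post_counts if t not in pre_counts]
    if missing:
        raise DataError(f"type(s) present post but absent pre: {missing}")
    pre = np.array([int(pre_counts[t]) for t in types])
    post = np.array([int(post_counts.get(t, 0)) for t in types])
    if (post > pre).any():
        raise DataError("post counts exceed pre counts")
    if pre.sum() == 0:
        raise DataError("no cells pre-capture")
    r_hat = post.sum() / pre.sum()
    p_values = []
    for n, k in zip(pre, post):
        if n == 0:
            p_values.append(1.0)
        elif r_hat >= 1.0:
            p_values.append(1.0 if k == n else 0.0)
        else:
            p_values.append(sps.binomtest(int(k), int(n), r_hat,
                                          alternative="two-sided").pvalue)
    adjusted = multipletests(p_values, method="fdr_bh")[1]
    results: dict[str, TestResult] = {}
    for t, n, k, p, padj in zip(types, pre, post, p_values, adjusted):
        rate = k / n if n else float("nan")
        if r_hat > 0 and rate > 0:
            fold = max(rate / r_hat, r_hat / rate)
        else:
            fold = float("inf") if rate != r_hat else 1.0
        flagged = bool(padj < alpha and fold >= effect_threshold)
        results[t] = TestResult(
            statistic=rate, p_value=float(p), method="binomial_dropout",
            extra={"p_adjusted": float(padj), "rate": float(rate),
                   "pooled_rate": float(r_hat), "fold_deviation": float(fold),
                   "flagged": flagged, "pre": int(n), "post": int(k)})
    return results
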