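"""Normalization and differential-expression calling.

The selection rule for a differentially expressed gene (DEG) is raw
``p < 0.01`` together with ``|log2 fold change| >= 1`` (p strict, LFC
inclusive); no multiple-testing correction is applied by default, an
optional Benjamini-Hochberg flag is available for sensitivity analysis.

Three tests are provided:

``nb_wald``
    The default for replicate-level (bulk / pseudo-bulk) tables.  Counts are
    modelled per gene as negative binomial with a common dispersion alpha
    shared across genes, estimated by a method-of-moments median.  The Wald
    statistic is the difference of log group means divided by its
    delta-method standard error, ``Var(log mean) ~ (1/n^2) sum_j (c_j/mu +
    alpha)`` with per-sample CPM scale factors ``c_j = 1e6 / depth_j``; the
    two-sided p-value comes from the normal reference.

``welch``
    Welch's t on log2(CPM + pseudocount), an alternative for sensitivity
    analysis.

``wilcoxon``
    Two-sided rank-sum per gene for per-cell comparisons within a cluster;
    exact enumeration over rank assignments when both groups have <= 8
    observations (midranks under ties), tie-corrected normal approximation
    otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import erfc
from statsmodels.stats.multitest import multipletests

from .errors import DataError, UsageError
from .io_formats import CountTable

__all__ = [
    "DEGParams",
    "DEGResult",
    "normalize_cpm",
    "log2_fold_change",
    "nb_wald_test",
    "welch_test",
    "wilcoxon_test",
    "call_degs",
    "compare_tables",
]

# floor (CPM units) applied inside the Wald log to keep all-zero groups finite
_MEAN_FLOOR = 0.5


@dataclass
class DEGParams:
    """Thresholds of the DEG selection rule."""

    p_threshold: float = 0.01
    lfc_threshold: float = 1.0
    pseudocount: float = 1.0
    test: str = "nb_wald"
    adjust: bool = False  # optional BH-FDR; off by default

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0:
            raise UsageError("lfc_threshold must be non-negative")
        if self.pseudocount <= 0:
            raise UsageError("pseudocount must be positive")
        if self.test not in ("nb_wald", "welch", "wilcoxon"):
            raise UsageError(f"unknown test {self.test!r}")


@dataclass
class DEGResult:
    """Per-gene DE outcome for one labelled two-group comparison."""

    comparison: str
    table: pd.DataFrame  # columns: log2fc, p_value, mean_a, mean_b, call
    params: DEGParams = field(default_factory=DEGParams)

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())

    def deg_genes(self) -> pd.Index:
        return self.table.index[self.table["call"] != "ns"]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def normalize_cpm(table: CountTable) -> CountTable:
    """Scale every column to sum to 1e6 (counts per million)."""
    sums = table.counts.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise DataError(f"zero-sum column(s): {list(zero)}")
    cpm = table.counts / sums * 1e6
    return CountTable(cpm, label=table.label, normalized=True)


def log2_fold_change(mean_a, mean_b, pseudocount: float = 1.0) -> np.ndarray:
    """log2((mean_a + pc) / (mean_b + pc)) elementwise."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    if (mean_a < 0).any() or (mean_b < 0).any():
        raise DataError("negative means passed to log2_fold_change")
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def _common_dispersion(cpm_a: np.ndarray, cpm_b: np.ndarray,
                       scale_a: np.ndarray, scale_b: np.ndarray) -> float:
    """Method-of-moments common NB dispersion across genes.

    For CPM values y = c*x with x ~ NB(mu, alpha), Var(y) = c*E[y] +
    alpha*E[y]^2, so alpha_g = (s2 - cbar*m) / m^2 pooled within groups;
    the across-gene median of positive estimates is returned.
    """
    ests = []
    for y, c in ((cpm_a, scale_a), (cpm_b, scale_b)):
        if y.shape[1] < 2:
            continue
        m = y.mean(axis=1)
        s2 = y.var(axis=1, ddof=1)
        cbar = float(np.mean(c))
        # E[(s2 - c*m)/m^2] = alpha exactly; restrict to well-measured
        # genes (>= ~20 raw counts) where the per-gene sampling variance of
        # this quantity is of order alpha^2, then average — a sum-weighted
        # estimator would instead ride on the few most abundant genes'
        # noisy variances
        use = m >= 20.0 * cbar
        if use.sum() < 10:
            use = m > cbar
        if use.any():
            ests.append((s2[use] - cbar * m[use]) / np.square(m[use]))
    if not ests:
        return 1e-8
    pooled = np.concatenate(ests)
    lo, hi = np.percentile(pooled, [1.0, 99.0])
    pooled = np.clip(pooled, lo, hi)  # guard the mean against outliers
    return float(max(np.mean(pooled), 1e-8))


def nb_wald_test(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
                 return_disp: bool = False):
    """Per-gene negative-binomial Wald test on raw count tables.

    Both inputs are genes x replicates raw counts over the same gene index;
    requires >= 2 replicates per group.  Returns a Series of two-sided
    p-values (normal reference on the Wald statistic).
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise UsageError(
            "nb_wald_test needs >= 2 replicates per group; "
            "choose test='wilcoxon' explicitly for single-replicate designs"
        )
    if not counts_a.index.equals(counts_b.index):
        raise DataError("gene indices differ between groups")
    depth_a = counts_a.sum(axis=0).to_numpy(dtype=float)
    depth_b = counts_b.sum(axis=0).to_numpy(dtype=float)
    if (depth_a == 0).any() or (depth_b == 0).any():
        raise DataError("zero-depth replicate")
    scale_a = 1e6 / depth_a
    scale_b = 1e6 / depth_b
    cpm_a = counts_a.to_numpy(dtype=float) * scale_a
    cpm_b = counts_b.to_numpy(dtype=float) * scale_b
    alpha = _common_dispersion(cpm_a, cpm_b, scale_a, scale_b)

    na, nb_ = cpm_a.shape[1], cpm_b.shape[1]
    mu_a = np.maximum(cpm_a.mean(axis=1), _MEAN_FLOOR)
    mu_b = np.maximum(cpm_b.mean(axis=1), _MEAN_FLOOR)
    var_log_a = (np.mean(scale_a) / mu_a + alpha) / na
    var_log_b = (np.mean(scale_b) / mu_b + alpha) / nb_
    se = np.sqrt(var_log_a + var_log_b)
    z = (np.log(mu_a) - np.log(mu_b)) / se
    p = erfc(np.abs(z) / math.sqrt(2.0))
    out = pd.Series(np.clip(p, 0.0, 1.0), index=counts_a.index, name="p_value")
    if return_disp:
        return out, alpha
    return out


def welch_test(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
               pseudocount: float = 1.0) -> pd.Series:
    """Welch's t-test per gene on log2(CPM + pseudocount)."""
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise UsageError("welch_test needs >= 2 replicates per group")
    la = np.log2(counts_a.to_numpy(float) / counts_a.sum(0).to_numpy(float)
                 * 1e6 + pseudocount)
    lb = np.log2(counts_b.to_numpy(float) / counts_b.sum(0).to_numpy(float)
                 * 1e6 + pseudocount)
    res = sps.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.Series(p, index=counts_a.index, name="p_value")


def _wilcoxon_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of all rank assignments.

    Uses midranks, so ties are handled; the two-sided p is the probability
    of a rank-sum deviation from its mean at least as large as observed.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, m = len(a), len(pooled)
    w_obs = ranks[:n].sum()
    mean_w = ranks.sum() * n / m
    dev = abs(w_obs - mean_w)
    total = 0
    hits = 0
    for combo in itertools.combinations(range(m), n):
        total += 1
        w = ranks[list(combo)].sum()
        if abs(w - mean_w) >= dev - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_test(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum test, vectorized over genes (columns).

    Inputs are observations x genes arrays (1-D inputs are treated as a
    single gene).  Exact enumeration when both groups have <= 8 rows,
    tie-corrected normal approximation otherwise.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.ndim == 2 and np.asarray(values_a).ndim == 1:
        a, b = a.T, b.T
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise DataError("empty group in wilcoxon_test")
    if a.shape[1] != b.shape[1]:
        raise DataError("gene dimensions differ between groups")
    n, m = a.shape[0], b.shape[0]
    if n <= 8 and m <= 8:
        return np.array([_wilcoxon_exact(a[:, g], b[:, g])
                         for g in range(a.shape[1])])
    pooled = np.vstack([a, b])
    ranks = sps.rankdata(pooled, axis=0)
    w = ranks[:n].sum(axis=0)
    total = n + m
    mean_w = n * (total + 1) / 2.0
    # tie correction on the variance, per column
    tie_term = np.zeros(pooled.shape[1])
    for g in range(pooled.shape[1]):
        _, counts = np.unique(pooled[:, g], return_counts=True)
        tie_term[g] = float(((counts ** 3) - counts).sum())
    var_w = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(w - mean_w) - 0.5) / np.sqrt(var_w)  # continuity corr.
    p = erfc(np.maximum(z, 0.0) / math.sqrt(2.0))
    p = np.where(var_w <= 0, 1.0, p)  # all-tied column
    return np.clip(p, 0.0, 1.0)


def call_degs(genes: pd.Index, log2fc: np.ndarray, p_values: np.ndarray,
              params: DEGParams, comparison: str = "",
              mean_a: np.ndarray | None = None,
              mean_b: np.ndarray | None = None) -> DEGResult:
    """Apply the DEG selection rule: strict p, inclusive |LFC| boundary."""
    p = np.asarray(p_values, dtype=float)
    if params.adjust:
        p = multipletests(p, method="fdr_bh")[1]
    lfc = np.asarray(log2fc, dtype=float)
    call = np.full(len(genes), "ns", dtype=object)
    sig = p < params.p_threshold
    call[sig & (lfc >= params.lfc_threshold)] = "up"
    call[sig & (lfc <= -params.lfc_threshold)] = "down"
    df = pd.DataFrame({"log2fc": lfc, "p_value": p, "call": call}, index=genes)
    if mean_a is not None:
        df.insert(0, "mean_a", np.asarray(mean_a, dtype=float))
        df.insert(1, "mean_b", np.asarray(mean_b, dtype=float))
    return DEGResult(comparison=comparison, table=df, params=params)


def compare_tables(table_a: CountTable, table_b: CountTable,
                   params: DEGParams | None = None,
                   comparison: str = "") -> DEGResult:
    """Full replicate-level comparison: normalize, test, threshold.

    Group A is the first (e.g. treated) table; the fold change is
    log2((CPM mean A + pc) / (CPM mean B + pc)).
    """
    params = params or DEGParams()
    if not table_a.genes.equals(table_b.genes):
        raise DataError("count tables share no common gene universe")
    cpm_a = normalize_cpm(table_a).counts
    cpm_b = normalize_cpm(table_b).counts
    mean_a = cpm_a.mean(axis=1).to_numpy()
    mean_b = cpm_b.mean(axis=1).to_numpy()
    lfc = log2_fold_change(mean_a, mean_b, params.pseudocount)
    if params.test == "nb_wald":
        p = nb_wald_test(table_a.counts, table_b.counts).to_numpy()
    elif params.test == "welch":
        p = welch_test(table_a.counts, table_b.counts,
                       params.pseudocount).to_numpy()
    else:
        p = wilcoxon_test(cpm_a.to_numpy().T, cpm_b.to_numpy().T)
    comparison = comparison or f"{table_a.label}x{table_b.label}"
    return call_degs(table_a.genes, lfc, p, params, comparison,
                     mean_a=mean_a, mean_b=mean_b)
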