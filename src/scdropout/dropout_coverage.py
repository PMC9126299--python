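"""Low-expressor transcriptome coverage and the TF detection-dropout proxy.

Definitions
-----------
detected transcript
    Gene with total raw count >= 1 summed across a dataset's replicates.
low expressor
    Detected gene whose normalized (CPM) read-count sum lies between
    ``min_count`` (default 1) and ``max_fraction`` (default 1%) of the
    maximum per-gene sum within the dataset, both bounds inclusive.
coverage
    100 * |low expressors| / |detected genes| within the same dataset.
matched filter
    The minimum detected count sum of a reference (pseudo-bulk) dataset,
    applied as an inclusive lower detection limit to another dataset — it
    emulates how the same data would look at single-cell sensitivity.

``coverage_analysis`` computes, per replicate, unfiltered and
reference-matched-filtered coverage and a paired one-tailed t-test of the
hypothesis that the filter reduces coverage; supplying a DEG set restricts
the whole computation to significant DEGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import DEGResult, normalize_cpm
from .errors import DataError, UsageError
from .io_formats import CountTable, GeneList
from .overlap_stats import ContingencyTable, TestResult, chisq_2x2, t_test_one_tailed

logger = logging.getLogger("scdropout.coverage")

__all__ = [
    "LowExpressorParams",
    "CoverageReport",
    "count_sums",
    "low_expressor_set",
    "coverage_percent",
    "matched_filter",
    "reference_lower_limit",
    "coverage_analysis",
    "tf_detection_table",
]


@dataclass
class LowExpressorParams:
    """Bounds of the low-expressor window (both inclusive)."""

    max_fraction: float = 0.01
    min_count: float = 1.0
    use_raw_sums: bool = False  # raw-count mode instead of CPM

    def __post_init__(self) -> None:
        if not 0 < self.max_fraction <= 1:
            raise UsageError("max_fraction must be in (0, 1]")
        if self.min_count <= 0:
            raise UsageError("min_count must be positive")


@dataclass
class CoverageReport:
    """Per-dataset coverage summary with per-replicate values."""

    per_dataset: dict = field(default_factory=dict)
    filter_limit: float = float("nan")
    reference: str = ""
    restricted_to: str = ""  # DEG comparison label when restricted

    def to_record(self) -> dict:
        return {
            "reference": self.reference,
            "filter_limit": self.filter_limit,
            "restricted_to": self.restricted_to,
            "datasets": self.per_dataset,
        }


def count_sums(table: CountTable, replicates=None) -> pd.Series:
    """Per-gene sum across the named replicates (all when None)."""
    if replicates is None:
        replicates = table.samples
    replicates = list(replicates)
    if not replicates:
        raise UsageError("empty replicate subset")
    unknown = [r for r in replicates if r not in table.counts.columns]
    if unknown:
        raise UsageError(f"unknown replicate(s): {unknown}")
    return table.counts[replicates].sum(axis=1)


def low_expressor_set(sums: pd.Series, params: LowExpressorParams) -> pd.Index:
    """Genes with min_count <= sum <= max_fraction * max(sums), inclusive."""
    sums = sums.astype(float)
    if (sums <= 0).all():
        raise DataError("all-zero count sums")
    if not (sums >= params.min_count).any():
        raise DataError("no gene reaches min_count")
    cutoff = params.max_fraction * float(sums.max())
    mask = (sums >= params.min_count) & (sums <= cutoff)
    return sums.index[mask]


def coverage_percent(low_set, detected_set) -> float:
    """100 * |low| / |detected|; low must be a subset of detected."""
    low, detected = set(low_set), set(detected_set)
    if not detected:
        raise DataError("empty detected set")
    if not low <= detected:
        raise DataError("low-expressor set is not a subset of detected set")
    return round(100.0 * len(low) / len(detected), 1)


def matched_filter(sums: pd.Series, lower_limit: float) -> pd.Series:
    """Retain genes with sum >= lower_limit (inclusive boundary)."""
    if lower_limit <= 0:
        raise UsageError("lower_limit must be positive")
    out = sums[sums >= lower_limit]
    if out.empty:
        logger.warning("matched filter at %g removed every gene", lower_limit)
    return out


def reference_lower_limit(reference: CountTable,
                          params: LowExpressorParams) -> float:
    """Per-replicate detection floor of the reference dataset.

    The smallest positive per-replicate (CPM or raw) value the reference
    method reports among its detected genes — the signal level below which
    the reference simply does not see a transcript.
    """
    detected = reference.detected_genes()
    if len(detected) == 0:
        raise DataError(f"reference {reference.label!r} detects no genes")
    values = (reference.counts if params.use_raw_sums
              else normalize_cpm(reference).counts)
    entries = values.loc[detected].to_numpy().ravel()
    entries = entries[entries > 0]
    return float(entries.min())


def _coverage_on_sums(raw_sums: pd.Series, sums: pd.Series,
                      params: LowExpressorParams, limit: float) -> dict:
    """Coverage before/after the matched filter on one replicate (or pooled).

    ``raw_sums`` decides detection (raw count >= min_count, the "one read
    count" lower bound); ``sums`` carries the working scale (CPM unless
    ``use_raw_sums``) on which the 1%-of-max cutoff and the filter apply.
    """
    detected = raw_sums.index[raw_sums >= params.min_count]
    if len(detected) == 0:
        raise DataError("no detected genes for coverage analysis")
    sums = sums.loc[detected]
    cutoff = params.max_fraction * float(sums.max())
    low = sums.index[sums <= cutoff]
    # full precision here; coverage_percent's one-decimal rounding is a
    # reporting convention and would mask sub-decimal filter effects
    unfiltered = 100.0 * len(low) / len(detected)
    kept = matched_filter(sums, limit)
    if kept.empty:
        filtered = 0.0
    else:
        filtered = 100.0 * len(low.intersection(kept.index)) / len(kept)
    return {
        "detected": int(len(detected)),
        "low_expressors": int(len(low)),
        "coverage_unfiltered": unfiltered,
        "coverage_filtered": filtered,
        "sum_range_unfiltered": [float(sums.min()), float(sums.max())],
        "sum_range_filtered": ([float(kept.min()), float(kept.max())]
                               if not kept.empty else [np.nan, np.nan]),
    }


def _replicate_coverage(table: CountTable, replicate: str,
                        params: LowExpressorParams, limit: float,
                        gene_subset: pd.Index | None) -> dict:
    values = table.counts if params.use_raw_sums else normalize_cpm(table).counts
    raw = table.counts[replicate]
    sums = values[replicate]
    if gene_subset is not None:
        raw = raw.loc[raw.index.intersection(gene_subset)]
        sums = sums.loc[raw.index]
    try:
        row = _coverage_on_sums(raw, sums, params, limit)
    except DataError as exc:
        raise DataError(f"replicate {replicate!r}: {exc}") from exc
    row["replicate"] = replicate
    return row


def coverage_analysis(datasets: dict[str, CountTable], reference_label: str,
                      params: LowExpressorParams | None = None,
                      degs: DEGResult | None = None) -> CoverageReport:
    """Table-4 style procedure over one or more datasets.

    For every dataset and replicate: unfiltered low-expressor coverage, then
    coverage after applying the reference's detection lower limit as a
    matched filter; a paired one-tailed t-test (filtered < unfiltered)
    across replicates summarizes the reduction.  When ``degs`` is given,
    genes are first restricted to its significant DEG set.
    """
    params = params or LowExpressorParams()
    if reference_label not in datasets:
        raise UsageError(f"reference {reference_label!r} not among datasets")
    limit = reference_lower_limit(datasets[reference_label], params)
    subset = None
    restricted = ""
    if degs is not None:
        subset = degs.deg_genes()
        restricted = degs.comparison
        if len(subset) == 0:
            raise DataError("DEG restriction is empty")
    report = CoverageReport(filter_limit=limit, reference=reference_label,
                            restricted_to=restricted)
    for label, table in datasets.items():
        rows = [_replicate_coverage(table, rep, params, limit, subset)
                for rep in table.samples]
        # pooled, dataset-level view: per-gene sums across replicates, with
        # the per-replicate limit scaled up to the pooled-sum scale
        values = table.counts if params.use_raw_sums else normalize_cpm(table).counts
        raw_pooled = table.counts.sum(axis=1)
        pooled_sums = values.sum(axis=1)
        if subset is not None:
            raw_pooled = raw_pooled.loc[raw_pooled.index.intersection(subset)]
            pooled_sums = pooled_sums.loc[raw_pooled.index]
        pooled = _coverage_on_sums(raw_pooled, pooled_sums, params,
                                   limit * table.counts.shape[1])
        entry: dict = {
            "pooled": pooled,
            "replicates": rows,
            "coverage_unfiltered_mean": round(
                float(np.mean([r["coverage_unfiltered"] for r in rows])), 2),
            "coverage_filtered_mean": round(
                float(np.mean([r["coverage_filtered"] for r in rows])), 2),
        }
        if len(rows) >= 2:
            test = t_test_one_tailed(
                [r["coverage_filtered"] for r in rows],
                [r["coverage_unfiltered"] for r in rows],
                alternative="less", paired=True)
            entry["t_test"] = test.to_record()
        else:
            logger.warning("%s: <2 replicates, t-test omitted", label)
        report.per_dataset[label] = entry
    return report


def tf_detection_table(genes_a, genes_b, tf_list: GeneList,
                       label_a: str = "A", label_b: str = "B"):
    """2x2 method x TF/non-TF table plus per-method TF percentages.

    ``genes_a`` / ``genes_b`` are the detected (or significant-DEG) gene
    sets of the two methods.  Returns ``(ContingencyTable, fractions,
    TestResult-or-None)`` where fractions maps method label to its TF
    percentage at one decimal; the chi-squared test is flagged as
    unavailable (None) on degenerate tables.
    """
    sa, sb = set(genes_a), set(genes_b)
    if not sa or not sb:
        raise DataError("empty gene set in tf_detection_table")
    tf = set(tf_list)
    a_tf, b_tf = len(sa & tf), len(sb & tf)
    table = ContingencyTable(
        np.array([[a_tf, len(sa) - a_tf], [b_tf, len(sb) - b_tf]]),
        row_labels=(label_a, label_b), col_labels=("TF", "non-TF"))
    fractions = {
        label_a: round(100.0 * a_tf / len(sa), 1),
        label_b: round(100.0 * b_tf / len(sb), 1),
    }
    test: TestResult | None
    try:
        test = chisq_2x2(table)
    except DataError:
        logger.warning("degenerate TF table (zero marginal); chi-squared skipped")
        test = None
    return table, fractions, test
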