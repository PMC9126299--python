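"""End-to-end orchestration of the paired bulk / pseudo-bulk comparison.

Stage order: simulate -> QC + pseudo-bulk -> differential expression for
the six comparisons (CDxCI, CPxCB, TPxTB, TBxCB, TPxCP, per-cluster
TCxCC) -> low-expressor coverage with the sensitivity-matched filter ->
TF detection tables -> DEG set overlaps -> cell-type composition and the
proportional-dropout test -> PCA sample summary -> one aggregated JSON
report plus a run manifest.

Numeric outputs land in files only; logging goes to stderr with
stage-scoped prefixes.  Rerunning with the same config and seed
reproduces the report byte for byte (the manifest carries timestamps,
the report does not).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import (cluster_proportions, proportional_dropout_test,
                          representation_reduction)
from .diffexpr import (DEGParams, DEGResult, call_degs, compare_tables,
                       log2_fold_change, wilcoxon_test)
from .dropout_coverage import (LowExpressorParams, coverage_analysis,
                               tf_detection_table)
from .errors import ConfigurationError, DataError, UsageError
from .io_formats import CountTable, GeneList, write_count_table
from .overlap_stats import venn_counts
from .qc_pseudobulk import CellQCParams, run_qc
from .synthdata import ExperimentBundle, ScenarioConfig, generate_experiment

logger = logging.getLogger("scdropout.pipeline")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "pca_summary",
           "validate_report"]

_COMPARISONS = ("CDxCI", "CPxCB", "TPxTB", "TBxCB", "TPxCP")
_REQUIRED_LABELS = ("CI", "CD", "CB", "TB", "CP", "TP")


@dataclass
class PipelineConfig:
    """Scenario plus analysis-stage parameters (study-standard defaults)."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    qc: CellQCParams = field(default_factory=CellQCParams)
    deg: DEGParams = field(default_factory=DEGParams)
    low_expressor: LowExpressorParams = field(default_factory=LowExpressorParams)
    dropout_alpha: float = 0.05
    dropout_effect_threshold: float = 1.5

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.to_dict(),
            "qc": {"min_features": self.qc.min_features,
                   "min_cluster_size": self.qc.min_cluster_size,
                   "max_mito_fraction": self.qc.max_mito_fraction},
            "deg": {"p_threshold": self.deg.p_threshold,
                    "lfc_threshold": self.deg.lfc_threshold,
                    "pseudocount": self.deg.pseudocount,
                    "test": self.deg.test, "adjust": self.deg.adjust},
            "low_expressor": {"max_fraction": self.low_expressor.max_fraction,
                              "min_count": self.low_expressor.min_count,
                              "use_raw_sums": self.low_expressor.use_raw_sums},
            "dropout_alpha": self.dropout_alpha,
            "dropout_effect_threshold": self.dropout_effect_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        scenario = ScenarioConfig.from_dict(d.pop("scenario", {}))
        qc = CellQCParams(**d.pop("qc", {}))
        deg = DEGParams(**d.pop("deg", {}))
        low = LowExpressorParams(**d.pop("low_expressor", {}))
        return cls(scenario=scenario, qc=qc, deg=deg, low_expressor=low, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """What ran, from what inputs, producing which files."""

    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def record(self, stage: str, outputs: list[str]) -> None:
        self.stages.append({
            "stage": stage,
            "outputs": outputs,
            "timestamp": datetime.datetime.now(datetime.timezone.utc)
            .isoformat(),
        })

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
        }, indent=2))


def _validate_config(config: PipelineConfig) -> None:
    missing = [lab for lab in _REQUIRED_LABELS
               if not config.scenario.replicates.get(lab)]
    if missing:
        raise ConfigurationError(
            f"scenario lacks replicates for dataset label(s): {missing}")


def pca_summary(tables: dict[str, CountTable], n_components: int = 2
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA of log2(CPM + 1), centered per gene.

    Returns per-sample coordinates (with a ``dataset`` column) and the
    variance-explained ratios, sorted non-increasing.
    """
    columns, labels = [], []
    for label, table in tables.items():
        cpm = table.counts / table.counts.sum(axis=0) * 1e6
        for s in table.samples:
            columns.append(np.log2(cpm[s].to_numpy() + 1.0))
            labels.append((label, s))
    if len(columns) < 3:
        raise UsageError("pca_summary needs at least 3 samples")
    mat = np.vstack(columns)                      # samples x genes
    mat = mat - mat.mean(axis=0, keepdims=True)   # center per gene
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    var = s ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    df = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(k)])
    df.insert(0, "dataset", [lab for lab, _ in labels])
    df.insert(1, "sample", [smp for _, smp in labels])
    return df, explained


def _silhouette_1d(values: np.ndarray, groups: np.ndarray) -> float:
    """Mean silhouette width of a two-group 1-D labelling."""
    scores = []
    for i, (v, g) in enumerate(zip(values, groups)):
        same = values[(groups == g) & (np.arange(len(values)) != i)]
        other = values[groups != g]
        if len(same) == 0 or len(other) == 0:
            continue
        a = np.abs(same - v).mean()
        b = np.abs(other - v).mean()
        scores.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scores)) if scores else 0.0


def _per_cluster_degs(cp_cells, tp_cells, params: DEGParams,
                      min_cells: int) -> dict[str, DEGResult]:
    """FindMarkers-style per-cluster DE: rank-sum on per-cell CPM."""
    results: dict[str, DEGResult] = {}
    shared = sorted(set(cp_cells.obs["cell_type"].unique())
                    & set(tp_cells.obs["cell_type"].unique()))
    genes = cp_cells.var_names
    for ctype in shared:
        a = np.asarray(tp_cells[tp_cells.obs["cell_type"] == ctype].X)
        b = np.asarray(cp_cells[cp_cells.obs["cell_type"] == ctype].X)
        if a.shape[0] < min_cells or b.shape[0] < min_cells:
            continue
        cpm_a = a / np.maximum(a.sum(axis=1, keepdims=True), 1) * 1e6
        cpm_b = b / np.maximum(b.sum(axis=1, keepdims=True), 1) * 1e6
        p = wilcoxon_test(cpm_a, cpm_b)
        lfc = log2_fold_change(cpm_a.mean(axis=0), cpm_b.mean(axis=0),
                               params.pseudocount)
        results[str(ctype)] = call_degs(genes, lfc, p, params,
                                        comparison=f"TCxCC:{ctype}")
    return results


def run_pipeline(config: PipelineConfig | str | Path,
                 outdir: str | Path = "scdropout_run") -> RunManifest:
    """Execute the full comparative analysis and write all reports."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(),
                           seed=config.scenario.seed, version=__version__)
    report: dict = {"seed": config.scenario.seed,
                    "config_hash": config.config_hash(),
                    "version": __version__}

    # ---- simulate -------------------------------------------------------
    logger.info("[simulate] generating experiment bundle (seed=%d)",
                config.scenario.seed)
    bundle = generate_experiment(config.scenario)
    bundle_dir = outdir / "bundle"
    bundle.save(bundle_dir)
    manifest.record("simulate", [str(bundle_dir)])

    # ---- QC + pseudo-bulk ----------------------------------------------
    logger.info("[qc] filtering cells and collapsing pseudo-bulk")
    pseudo: dict[str, CountTable] = {}
    filtered_cells = {}
    qc_records = {}
    for label in ("CP", "TP"):
        table, cells, qc_report = run_qc(bundle.sc_matrices[label],
                                         config.qc, label=label)
        pseudo[label] = table
        filtered_cells[label] = cells
        qc_records[label] = qc_report.to_record()
        write_count_table(table, outdir / f"{label}.tsv")
    report["qc"] = qc_records
    manifest.record("qc_pseudobulk", [str(outdir / "CP.tsv"),
                                      str(outdir / "TP.tsv")])

    # ---- differential expression ---------------------------------------
    logger.info("[deg] six comparisons at p<%g, |LFC|>=%g",
                config.deg.p_threshold, config.deg.lfc_threshold)
    tables = dict(bundle.bulk_tables)
    tables["CP"] = pseudo["CP"]
    tables["TP"] = pseudo["TP"]
    pairs = {"CDxCI": ("CD", "CI"), "CPxCB": ("CP", "CB"),
             "TPxTB": ("TP", "TB"), "TBxCB": ("TB", "CB"),
             "TPxCP": ("TP", "CP")}
    degs: dict[str, DEGResult] = {}
    deg_files = []
    for name, (a, b) in pairs.items():
        degs[name] = compare_tables(tables[a], tables[b], config.deg,
                                    comparison=name)
        path = outdir / f"{name}.tsv"
        degs[name].write_tsv(path)
        deg_files.append(str(path))
    cluster_degs = _per_cluster_degs(filtered_cells["CP"],
                                     filtered_cells["TP"], config.deg,
                                     config.qc.min_cluster_size)
    for ctype, res in cluster_degs.items():
        path = outdir / f"TCxCC_{ctype}.tsv"
        res.write_tsv(path)
        deg_files.append(str(path))
    report["degs"] = {
        name: {"n_up": r.n_up, "n_down": r.n_down,
               "n_total": r.n_up + r.n_down}
        for name, r in degs.items()}
    report["degs_per_cluster"] = {
        ctype: {"n_up": r.n_up, "n_down": r.n_down}
        for ctype, r in cluster_degs.items()}
    manifest.record("deg", deg_files)

    # ---- low-expressor coverage ----------------------------------------
    logger.info("[coverage] matched-filter coverage against reference CP")
    cov_datasets = {lab: tables[lab] for lab in ("CI", "CD", "CB", "CP")}
    coverage = coverage_analysis(cov_datasets, "CP", config.low_expressor)
    coverage_deg = coverage_analysis(
        {lab: tables[lab] for lab in ("CB", "CP")}, "CP",
        config.low_expressor, degs=degs["TBxCB"])
    report["coverage"] = coverage.to_record()
    report["coverage_significant_degs"] = coverage_deg.to_record()
    (outdir / "coverage.json").write_text(
        json.dumps(report["coverage"], indent=2, sort_keys=True))
    manifest.record("coverage", [str(outdir / "coverage.json")])

    # ---- TF detection ---------------------------------------------------
    logger.info("[tfdetect] TF detection-dropout proxy")
    tf_list = GeneList(list(bundle.gene_catalog.tf_genes), label="TF")
    detected_bulk = set(tables["TB"].detected_genes()) \
        | set(tables["CB"].detected_genes())
    detected_pseudo = set(tables["TP"].detected_genes()) \
        | set(tables["CP"].detected_genes())
    det_table, det_frac, det_test = tf_detection_table(
        detected_bulk, detected_pseudo, tf_list, "bulk", "pseudobulk")
    deg_table, deg_frac, deg_test = tf_detection_table(
        set(degs["TBxCB"].deg_genes()), set(degs["TPxCP"].deg_genes()),
        tf_list, "bulk", "pseudobulk")
    report["tf_detection"] = {
        "detected": {"table": det_table.to_record(), "tf_percent": det_frac,
                     "chisq": det_test.to_record() if det_test else None},
        "significant_degs": {"table": deg_table.to_record(),
                             "tf_percent": deg_frac,
                             "chisq": deg_test.to_record() if deg_test else None},
    }
    manifest.record("tfdetect", [])

    # ---- overlap --------------------------------------------------------
    logger.info("[overlap] DEG set overlaps")
    pseudo_degs = set(degs["TPxCP"].deg_genes())
    bulk_degs = set(degs["TBxCB"].deg_genes())
    cluster_union = set()
    for res in cluster_degs.values():
        cluster_union |= set(res.deg_genes())
    only_p, only_b, both = venn_counts(pseudo_degs, bulk_degs)
    report["overlap"] = {
        "TPxCP_vs_TBxCB": {"only_pseudobulk": only_p, "only_bulk": only_b,
                           "shared": both},
        "clusters_vs_TPxCP": dict(zip(
            ("only_clusters", "only_pseudobulk", "shared"),
            venn_counts(cluster_union, pseudo_degs))),
        "clusters_vs_TBxCB": dict(zip(
            ("only_clusters", "only_bulk", "shared"),
            venn_counts(cluster_union, bulk_degs))),
        "n_cluster_degs": len(cluster_union),
    }
    manifest.record("overlap", [])

    # ---- composition ----------------------------------------------------
    logger.info("[composition] cell-type representation and dropout test")
    import anndata as ad
    merged = ad.concat([filtered_cells["CP"], filtered_cells["TP"]],
                       merge="same", index_unique=None)
    comp = cluster_proportions(merged)
    comp_frame = comp.to_frame()
    comp_frame.to_csv(outdir / "composition.tsv", sep="\t", index=False)
    reductions = {}
    for ctype in sorted(set(comp_frame["cell_type"])):
        try:
            before = comp.fraction("control", ctype)
            after = (comp.fraction("exposed", ctype)
                     if ctype in comp.per_condition.get("exposed", {})
                     .get("types", {}) else 0.0)
            reductions[ctype] = round(representation_reduction(before, after), 1)
        except (KeyError, DataError):
            continue
    pre: dict[str, int] = {}
    post: dict[str, int] = {}
    for sample_truth in bundle.truth["capture"]["TP"].values():
        for t, c in sample_truth["pre_type_counts"].items():
            pre[t] = pre.get(t, 0) + c
        for t, c in sample_truth["post_type_counts"].items():
            post[t] = post.get(t, 0) + c
    dropout = proportional_dropout_test(
        pre, post, alpha=config.dropout_alpha,
        effect_threshold=config.dropout_effect_threshold)
    report["composition"] = {
        "proportions": comp.per_condition,
        "representation_reduction_percent": reductions,
        "proportional_dropout": {t: r.to_record()
                                 for t, r in dropout.items()},
        "flagged_types": sorted(t for t, r in dropout.items()
                                if r.extra["flagged"]),
    }
    manifest.record("composition", [str(outdir / "composition.tsv")])

    # ---- PCA ------------------------------------------------------------
    logger.info("[pca] sample-level principal components")
    coords, explained = pca_summary(
        {lab: tables[lab] for lab in ("CB", "TB", "CP", "TP")})
    coords.to_csv(outdir / "pca.tsv", sep="\t", index=False)
    method = np.array(["pseudobulk" if d in ("CP", "TP") else "bulk"
                       for d in coords["dataset"]])
    report["pca"] = {
        "variance_explained": [round(float(v), 4) for v in explained[:5]],
        "pc1_method_silhouette": round(
            _silhouette_1d(coords["PC1"].to_numpy(), method), 3),
    }
    manifest.record("pca", [str(outdir / "pca.tsv")])

    # ---- report ---------------------------------------------------------
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest.record("report", [str(report_path)])
    manifest.write(outdir / "manifest.json")
    logger.info("[report] wrote %s", report_path)
    return manifest


_SCHEMA_PATH = Path(__file__).parent / "report.schema.json"


def validate_report(report: dict) -> None:
    """Check a pipeline report against the published schema.

    A minimal structural validator (required keys + JSON types) driven by
    ``report.schema.json`` shipped with the package.
    """
    schema = json.loads(_SCHEMA_PATH.read_text())
    _validate_node(report, schema, "$")


_JSON_TYPES = {"object": dict, "array": list, "string": str,
               "number": (int, float), "integer": int, "boolean": bool}


def _validate_node(node, schema: dict, path: str) -> None:
    expected = schema.get("type")
    if expected:
        py = _JSON_TYPES[expected]
        if expected == "number" and isinstance(node, bool):
            raise DataError(f"{path}: expected number, got bool")
        if not isinstance(node, py) or (expected == "integer"
                                        and isinstance(node, bool)):
            raise DataError(f"{path}: expected {expected}, "
                            f"got {type(node).__name__}")
    for key in schema.get("required", []):
        if key not in node:
            raise DataError(f"{path}: missing required key {key!r}")
    for key, subschema in schema.get("properties", {}).items():
        if isinstance(node, dict) and key in node:
            _validate_node(node[key], subschema, f"{path}.{key}")
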