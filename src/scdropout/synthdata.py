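"""Paired bulk / single-cell count-data generator.

The scenario is a testis-like tissue of ~10 germ-cell maturation stages
under a toxicant exposure.  Six datasets are produced, mirroring a paired
design:

====== ===========================================================
label  preparation
====== ===========================================================
CI     control, intact tissue, bulk-sequenced
CD     control, enzymatically dissociated, bulk-sequenced
CB     control, dissociated, bulk-sequenced (paired with CP)
TB     exposed, dissociated, bulk-sequenced (paired with TP)
CP     control, dissociated, droplet-captured single cells
TP     exposed, dissociated, droplet-captured single cells
====== ===========================================================

The generative model, per cell: cell type drawn multinomially from the
condition's proportions; gene counts negative binomial (gamma-Poisson) with
mean ``library_factor * baseline_mean[type] * 2^(sum of active program
LFCs)`` and a dispersion shared across genes.  Dissociation scales a stress
program up/down and inflates mitochondrial content proportionally to each
cell's stress score.  Droplet capture retains each cell with probability
``(1 - capture_cell_loss) * (1 - stress_score)`` and thins each retained
count binomially with detection rate ``sigmoid(capture_slope *
(log(count+1) - capture_midpoint) + length_offset)`` — abundant transcripts
survive, low expressors drop out.  Bulk libraries are a single multinomial
draw of the configured depth over the pooled pre-capture suspension.

All randomness flows from ``ScenarioConfig.seed`` through per-dataset
substreams, so the same seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError, StateError, UsageError
from .io_formats import CountTable, write_cell_matrix, write_count_table

__all__ = [
    "CellTypeSpec",
    "ScenarioConfig",
    "GeneCatalog",
    "ExperimentBundle",
    "default_cell_types",
    "generate_gene_catalog",
    "simulate_cells",
    "apply_dissociation_stress",
    "apply_droplet_capture",
    "simulate_bulk_library",
    "simulate_dataset",
    "generate_experiment",
]

EXPOSURE_PROGRAM_PREFIX = "exposure_"


@dataclass(frozen=True)
class CellTypeSpec:
    """One cell type: name, per-condition tissue proportions, and how
    vulnerable its cells are to dissociation/capture stress (in [0, 1])."""

    name: str
    control_proportion: float
    exposed_proportion: float
    stress_susceptibility: float


def default_cell_types() -> list[CellTypeSpec]:
    """Germ-cell maturation stages of an adult zebrafish-like testis.

    Control proportions put sperm at ~23% (sperm + spermatids ~30%) and
    spermatogonia + early spermatocytes at ~30%; late germ cells (sperm,
    spermatids) carry high stress susceptibility so that, under exposure,
    droplet capture collapses their observed share to a few percent.
    """
    return [
        CellTypeSpec("SSC", 0.06, 0.06, 0.05),
        CellTypeSpec("SPG", 0.14, 0.16, 0.05),
        CellTypeSpec("SPC_I", 0.16, 0.18, 0.05),
        CellTypeSpec("SPC_II", 0.14, 0.14, 0.10),
        CellTypeSpec("SPC_III", 0.12, 0.12, 0.20),
        CellTypeSpec("SPC_IV", 0.08, 0.08, 0.20),
        CellTypeSpec("spermatid_round", 0.04, 0.03, 0.90),
        CellTypeSpec("spermatid_elong", 0.03, 0.03, 0.90),
        CellTypeSpec("sperm_1", 0.12, 0.10, 1.00),
        CellTypeSpec("sperm_2", 0.11, 0.10, 1.00),
    ]


@dataclass
class ScenarioConfig:
    """Every knob of the synthetic scenario, with study-calibrated defaults."""

    n_genes: int = 2000
    tf_fraction: float = 0.15
    # mtDNA encodes few, abundant transcripts: a small gene set carrying a
    # fixed share of cellular output keeps per-gene abundance realistic
    mito_fraction: float = 0.01
    cell_types: list[CellTypeSpec] = field(default_factory=default_cell_types)
    program_sizes: dict = field(default_factory=lambda: {
        "dissociation_up": 100,
        "dissociation_down": 100,
        "droplet_up": 80,
        "exposure_per_celltype": 25,
    })
    program_lfc: dict = field(default_factory=lambda: {
        "dissociation_up": 2.0,
        "dissociation_down": 2.0,
        "droplet_up": 1.5,
        "exposure": 4.0,
    })
    nb_dispersion: float = 0.3
    sc_cells_per_sample: int = 4000
    # captured transcript (UMI-like) counts per cell, not sequencing reads
    sc_reads_per_cell: int = 14000
    bulk_cells_per_sample: int = 2000
    bulk_depth: int = 60_000_000
    capture_cell_loss: float = 1.0 / 3.0
    # near-threshold capture: a transcript species either clears the
    # droplet detection threshold (~3-4 copies) and is captured almost
    # fully, or drops out — the all-or-nothing dropout of 3' droplet data
    capture_midpoint: float = 1.5
    capture_slope: float = 12.0
    length_offset_short: float = -0.25  # 3'-bias proxy on the detection logit
    control_stress: float = 0.05
    exposure_stress_increment: float = 0.80
    mito_stress_gain: float = 3.0
    mito_baseline_share: float = 0.04  # pre-capture share of a healthy cell
    tf_logmean_shift: float = -0.5
    baseline_sigma: float = 1.6
    # trace component: genes effectively silent in this tissue; bulk still
    # catches a few reads of them, droplet capture does not
    off_fraction: float = 0.30
    tf_off_fraction: float = 0.55
    off_logshift: float = -6.0
    type_variation_sigma: float = 0.8
    # exposure programs live in the low-mid band of *expressed* genes: deep
    # bulk still measures them precisely, but their enriched share cannot
    # come to dominate an exposed cell's library (which would distort every
    # other gene's CPM)
    exposure_program_enrichment: float = 12.0
    exposure_program_min_quantile: float = 0.05
    exposure_program_max_quantile: float = 0.35
    library_sigma: float = 0.3
    replicates: dict = field(default_factory=lambda: {
        "CI": 3, "CD": 3, "CB": 3, "TB": 2, "CP": 3, "TP": 2})
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        for name, value in (("tf_fraction", self.tf_fraction),
                            ("mito_fraction", self.mito_fraction),
                            ("capture_cell_loss", self.capture_cell_loss)):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for attr in ("nb_dispersion", "sc_cells_per_sample",
                     "sc_reads_per_cell", "bulk_cells_per_sample",
                     "bulk_depth"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"{attr} must be positive")
        for cond in ("control_proportion", "exposed_proportion"):
            total = sum(getattr(ct, cond) for ct in self.cell_types)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{cond}s sum to {total!r}, expected 1")
        for ct in self.cell_types:
            if not 0.0 <= ct.stress_susceptibility <= 1.0:
                raise ConfigurationError(
                    f"{ct.name}: stress_susceptibility outside [0, 1]")
        n_exposure = (self.program_sizes.get("exposure_per_celltype", 0)
                      * len(self.cell_types))
        n_fixed = sum(v for k, v in self.program_sizes.items()
                      if k != "exposure_per_celltype")
        if n_fixed + n_exposure > self.n_genes:
            raise ConfigurationError(
                f"program gene sets ({n_fixed + n_exposure}) exceed "
                f"n_genes ({self.n_genes})")
        for k, v in self.program_sizes.items():
            if v > self.n_genes:
                raise ConfigurationError(f"program {k!r} larger than gene universe")

    # -- condition helpers ------------------------------------------------
    def proportions(self, condition: str) -> dict[str, float]:
        if condition == "control":
            return {ct.name: ct.control_proportion for ct in self.cell_types}
        if condition == "exposed":
            return {ct.name: ct.exposed_proportion for ct in self.cell_types}
        raise UsageError(f"unknown condition {condition!r}")

    def stress_score(self, cell_type: str, condition: str) -> float:
        susc = {ct.name: ct.stress_susceptibility for ct in self.cell_types}
        if cell_type not in susc:
            raise UsageError(f"unknown cell type {cell_type!r}")
        level = self.control_stress
        if condition == "exposed":
            level += self.exposure_stress_increment
        return float(min(susc[cell_type] * level, 1.0))

    def null_exposure(self) -> "ScenarioConfig":
        """A copy with every exposure effect switched off (null scenario)."""
        cfg = self.copy()
        cfg.program_lfc = dict(cfg.program_lfc, exposure=0.0)
        cfg.exposure_stress_increment = 0.0
        cfg.cell_types = [
            CellTypeSpec(ct.name, ct.control_proportion,
                         ct.control_proportion, ct.stress_susceptibility)
            for ct in cfg.cell_types]
        return cfg

    def copy(self) -> "ScenarioConfig":
        return ScenarioConfig.from_dict(self.to_dict())

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = [asdict(ct) for ct in self.cell_types]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "cell_types" in d:
            d["cell_types"] = [CellTypeSpec(**ct) if isinstance(ct, dict) else ct
                               for ct in d["cell_types"]]
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GeneCatalog:
    """Per-gene ground truth of the scenario.

    ``genes``: DataFrame indexed by gene id with ``is_tf``, ``is_mito`` and
    ``length_class`` columns.  ``baseline``: genes x cell-types expected
    transcripts per cell (columns sum to ``sc_reads_per_cell``).
    ``programs``: program name -> Index of member genes.
    """

    genes: pd.DataFrame
    baseline: pd.DataFrame
    programs: dict[str, pd.Index]

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def tf_genes(self) -> pd.Index:
        return self.genes.index[self.genes["is_tf"]]

    @property
    def mito_genes(self) -> pd.Index:
        return self.genes.index[self.genes["is_mito"]]

    def program_membership(self, gene: str) -> set[str]:
        return {name for name, members in self.programs.items()
                if gene in members}

    def exposure_genes(self) -> pd.Index:
        """Union of all cell-type exposure programs."""
        out: pd.Index = pd.Index([], dtype=object)
        for name, members in self.programs.items():
            if name.startswith(EXPOSURE_PROGRAM_PREFIX):
                out = out.union(members)
        return out


def _substream(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    tokens = [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([seed, *tokens]))


def generate_gene_catalog(config: ScenarioConfig,
                          rng: np.random.Generator) -> GeneCatalog:
    """Draw per-gene classes, baselines and program memberships.

    Baselines are log-normal so a sizeable fraction of genes is
    low-expressing; TF genes are shifted toward low expression and short
    length (they proxy low-expressor detection downstream); mitochondrial
    genes are a small, high-expression set disjoint from TFs; antagonistic
    programs never share genes.
    """
    n = config.n_genes
    width = max(4, len(str(n - 1)))
    gene_ids = pd.Index([f"g{i:0{width}d}" for i in range(n)], name="gene_id")

    n_tf = int(round(config.tf_fraction * n))
    tf_idx = rng.choice(n, size=n_tf, replace=False)
    is_tf = np.zeros(n, dtype=bool)
    is_tf[tf_idx] = True
    n_mito = int(round(config.mito_fraction * n))
    non_tf = np.flatnonzero(~is_tf)
    if n_mito > len(non_tf):
        raise ConfigurationError("mito_fraction leaves no non-TF genes")
    mito_idx = rng.choice(non_tf, size=n_mito, replace=False)
    is_mito = np.zeros(n, dtype=bool)
    is_mito[mito_idx] = True

    p_short = np.where(is_tf, 0.8, 0.4)
    length_class = np.where(rng.random(n) < p_short, "short", "long")

    z = rng.normal(0.0, config.baseline_sigma, size=n)
    z[is_tf] += config.tf_logmean_shift
    # trace (tissue-silent) component, TF-enriched: the deep low tail that
    # bulk sequencing skims but droplet capture loses entirely
    p_off = np.where(is_tf, config.tf_off_fraction, config.off_fraction)
    is_off = rng.random(n) < p_off
    z[is_off] += config.off_logshift
    base = np.exp(z)
    # mito baselines: tight relative spread; their per-type total is pinned
    # to mito_baseline_share below
    base[is_mito] = rng.lognormal(0.0, 0.5, size=n_mito)

    type_names = [ct.name for ct in config.cell_types]
    type_factor = rng.lognormal(0.0, config.type_variation_sigma,
                                size=(n, len(type_names)))
    # mito content is shared cellular machinery, not a cell-type marker:
    # flat across types so QC contrasts reflect stress, not identity
    type_factor[is_mito, :] = 1.0
    weights = base[:, None] * type_factor

    # program gene sets
    programs: dict[str, np.ndarray] = {}
    taken = np.zeros(n, dtype=bool)

    def _draw(name: str, size: int, pool: np.ndarray) -> np.ndarray:
        pool = pool[~taken[pool]]
        if size > len(pool):
            raise ConfigurationError(
                f"program {name!r} ({size} genes) does not fit the gene universe")
        chosen = rng.choice(pool, size=size, replace=False)
        taken[chosen] = True
        return np.sort(chosen)

    # mito genes stay out of every program: their share is governed solely
    # by the stress channel (the droplet/OXPHOS-like artifact is nuclear)
    all_genes = np.arange(n)
    nuclear = all_genes[~is_mito]
    programs["dissociation_up"] = _draw(
        "dissociation_up", config.program_sizes.get("dissociation_up", 0), nuclear)
    programs["dissociation_down"] = _draw(
        "dissociation_down", config.program_sizes.get("dissociation_down", 0), nuclear)
    # droplet artifact: expressed nuclear genes below the very top of the
    # abundance range — an artifact on the single dominant transcript would
    # rescale the whole library rather than add a program signature
    aggregate_all = weights.sum(axis=1)
    expressed_agg = aggregate_all[~is_off]
    droplet_pool = nuclear[(~is_off[nuclear])
                           & (aggregate_all[nuclear]
                              <= np.quantile(expressed_agg, 0.90))]
    if len(droplet_pool) < config.program_sizes.get("droplet_up", 0):
        droplet_pool = nuclear
    programs["droplet_up"] = _draw(
        "droplet_up", config.program_sizes.get("droplet_up", 0), droplet_pool)

    # exposure programs: marker-like responsive genes per cell type, drawn
    # from the low-mid band of *expressed* genes and enriched in their
    # target type (see module docstring for why the band matters)
    n_exp = config.program_sizes.get("exposure_per_celltype", 0)
    if n_exp:
        aggregate = weights.sum(axis=1)
        expressed = aggregate[~is_off]
        floor = np.quantile(expressed, config.exposure_program_min_quantile)
        ceil = np.quantile(expressed, config.exposure_program_max_quantile)
        eligible = np.flatnonzero((aggregate >= floor) & (aggregate <= ceil)
                                  & ~is_mito & ~is_off)
        for j, t in enumerate(type_names):
            members = _draw(f"{EXPOSURE_PROGRAM_PREFIX}{t}", n_exp, eligible)
            weights[members, j] *= config.exposure_program_enrichment
            programs[f"{EXPOSURE_PROGRAM_PREFIX}{t}"] = members

    # pin the mitochondrial share of every type's library: mito content is a
    # fixed fraction of healthy cellular output, whatever the type's markers
    if n_mito and 0.0 < config.mito_baseline_share < 1.0:
        target = config.mito_baseline_share
        for j in range(len(type_names)):
            wm = weights[is_mito, j].sum()
            wn = weights[~is_mito, j].sum()
            if wm > 0:
                weights[is_mito, j] *= (target / (1.0 - target)) * wn / wm

    shares = weights / weights.sum(axis=0, keepdims=True)
    baseline = pd.DataFrame(shares * config.sc_reads_per_cell,
                            index=gene_ids, columns=type_names)
    genes = pd.DataFrame({
        "is_tf": is_tf,
        "is_mito": is_mito,
        "is_trace": is_off,
        "length_class": length_class,
    }, index=gene_ids)
    program_index = {name: gene_ids[idx] for name, idx in programs.items()}
    return GeneCatalog(genes=genes, baseline=baseline, programs=program_index)


def simulate_cells(catalog: GeneCatalog, config: ScenarioConfig,
                   condition: str, n_cells: int,
                   rng: np.random.Generator, sample: str = "S1",
                   bulk_destined: bool = False) -> ad.AnnData:
    """Draw a pre-dissociation cell population for one sample.

    Cell types are multinomial in the condition's proportions; counts are
    negative binomial around ``library_factor * baseline * 2^(exposure
    program LFC)`` (exposure programs act only on exposed cells of their
    own type).  Dissociation and capture are separate, subsequent steps.
    """
    props = config.proportions(condition)
    type_names = list(catalog.baseline.columns)
    p = np.array([props[t] for t in type_names])
    type_codes = rng.choice(len(type_names), size=n_cells, p=p)
    lib = rng.lognormal(0.0, config.library_sigma, size=n_cells)

    exposure_lfc = config.program_lfc.get("exposure", 0.0)
    n_genes = catalog.baseline.shape[0]
    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    disp = config.nb_dispersion
    gene_pos = pd.Series(np.arange(n_genes), index=catalog.gene_ids)
    for j, t in enumerate(type_names):
        rows = np.flatnonzero(type_codes == j)
        if rows.size == 0:
            continue
        mu_gene = catalog.baseline[t].to_numpy(copy=True)
        if condition == "exposed" and exposure_lfc != 0.0:
            members = catalog.programs.get(f"{EXPOSURE_PROGRAM_PREFIX}{t}")
            if members is not None and len(members):
                mu_gene[gene_pos[members].to_numpy()] *= 2.0 ** exposure_lfc
        mu = lib[rows, None] * mu_gene[None, :]
        if disp < 1e-8:
            counts[rows] = rng.poisson(mu)
        else:
            lam = rng.gamma(1.0 / disp, disp * mu)
            counts[rows] = rng.poisson(lam)

    stress = np.array([config.stress_score(type_names[c], condition)
                       for c in type_codes])
    obs = pd.DataFrame({
        "sample": sample,
        "condition": condition,
        "cell_type": pd.Categorical([type_names[c] for c in type_codes],
                                    categories=type_names),
        "stress_score": stress,
    }, index=pd.Index([f"{sample}_cell{i:06d}" for i in range(n_cells)],
                      name="barcode"))
    adata = ad.AnnData(X=counts, obs=obs,
                       var=catalog.genes.copy())
    adata.uns["dissociated"] = False
    adata.uns["captured"] = False
    adata.uns["bulk_destined"] = bool(bulk_destined)
    return adata


def apply_dissociation_stress(adata: ad.AnnData, catalog: GeneCatalog,
                              config: ScenarioConfig,
                              rng: np.random.Generator) -> ad.AnnData:
    """Overlay the dissociation stress program on a cell population.

    Up-program counts are Poisson-resampled around 2^lfc times their value,
    down-program counts binomially thinned to 2^-lfc; mitochondrial counts
    grow with each cell's stress score.  Refuses double application.
    """
    if adata.uns.get("dissociated"):
        raise StateError("dissociation stress already applied")
    out = adata.copy()
    X = np.asarray(out.X)
    gene_pos = pd.Series(np.arange(out.n_vars), index=out.var_names)

    lfc_up = config.program_lfc.get("dissociation_up", 0.0)
    up = gene_pos[catalog.programs["dissociation_up"]].to_numpy()
    if lfc_up != 0.0 and len(up):
        X[:, up] = rng.poisson(X[:, up] * (2.0 ** lfc_up))
    lfc_down = config.program_lfc.get("dissociation_down", 0.0)
    down = gene_pos[catalog.programs["dissociation_down"]].to_numpy()
    if lfc_down != 0.0 and len(down):
        X[:, down] = rng.binomial(X[:, down], 2.0 ** (-lfc_down))

    mito = gene_pos[catalog.mito_genes].to_numpy()
    stress = out.obs["stress_score"].to_numpy()
    if len(mito) and config.mito_stress_gain > 0 and (stress > 0).any():
        gain = 1.0 + config.mito_stress_gain * stress
        X[:, mito] = rng.poisson(X[:, mito] * gain[:, None])

    out.X = X
    out.uns["dissociated"] = True
    return out


def _detection_probability(X: np.ndarray, config: ScenarioConfig,
                           length_class: np.ndarray) -> np.ndarray:
    offset = np.where(length_class == "short", config.length_offset_short, 0.0)
    logit = config.capture_slope * (np.log1p(X) - config.capture_midpoint)
    logit = logit + offset[None, :]
    return 1.0 / (1.0 + np.exp(-logit))


def apply_droplet_capture(adata: ad.AnnData, config: ScenarioConfig,
                          rng: np.random.Generator) -> ad.AnnData:
    """Cell loss plus abundance-dependent transcript thinning.

    Each cell survives capture with probability ``(1 - capture_cell_loss) *
    (1 - stress_score)`` — the stress factor multiplies the baseline loss,
    so unstressed populations lose the standard ~1/3 while stressed ones
    lose far more.  Retained counts are binomially thinned with a logistic
    detection curve in log(count+1).  Ground-truth pre/post per-type counts
    live in ``.uns["capture_truth"]``.
    """
    if adata.uns.get("bulk_destined"):
        raise UsageError("droplet capture does not apply to a bulk-destined "
                         "suspension (bulk skips the droplet system)")
    if not adata.uns.get("dissociated"):
        raise StateError("capture requires a dissociated suspension")
    if adata.uns.get("captured"):
        raise StateError("droplet capture already applied")

    stress = adata.obs["stress_score"].to_numpy()
    g = np.clip(1.0 - stress, 0.0, 1.0)
    p_keep = (1.0 - config.capture_cell_loss) * g
    retained = rng.random(adata.n_obs) < p_keep

    pre_counts = adata.obs["cell_type"].value_counts().to_dict()
    out = adata[retained].copy()
    X = np.asarray(out.X)
    det = _detection_probability(X, config,
                                 out.var["length_class"].to_numpy())
    X = rng.binomial(X, det)
    out.X = X
    post_counts = out.obs["cell_type"].value_counts().to_dict()
    out.uns["captured"] = True
    out.uns["capture_truth"] = {
        "pre_type_counts": {str(k): int(v) for k, v in pre_counts.items()},
        "post_type_counts": {str(k): int(v) for k, v in post_counts.items()},
        "retained_fraction": float(retained.mean()),
    }
    return out


def simulate_bulk_library(adata: ad.AnnData, depth: int,
                          rng: np.random.Generator) -> pd.Series:
    """One multinomial draw of ``depth`` reads over the pooled suspension."""
    if adata.uns.get("captured"):
        raise UsageError("bulk libraries are sequenced from the pre-capture "
                         "suspension")
    if adata.n_obs == 0:
        raise DataError("empty cell matrix")
    pooled = np.asarray(np.asarray(adata.X).sum(axis=0)).ravel().astype(float)
    total = pooled.sum()
    if total <= 0:
        raise DataError("suspension contains no transcripts")
    column = rng.multinomial(int(depth), pooled / total)
    return pd.Series(column, index=adata.var_names, name="bulk")


def _apply_droplet_program(adata: ad.AnnData, catalog: GeneCatalog,
                           config: ScenarioConfig,
                           rng: np.random.Generator) -> ad.AnnData:
    """The droplet-specific expression artifact (OXPHOS/mito-like up)."""
    lfc = config.program_lfc.get("droplet_up", 0.0)
    members = catalog.programs.get("droplet_up")
    if lfc == 0.0 or members is None or not len(members):
        return adata
    out = adata.copy()
    X = np.asarray(out.X)
    pos = pd.Series(np.arange(out.n_vars), index=out.var_names)[members].to_numpy()
    X[:, pos] = rng.poisson(X[:, pos] * (2.0 ** lfc))
    out.X = X
    return out


_DATASET_CONDITION = {"CI": "control", "CD": "control", "CB": "control",
                      "TB": "exposed", "CP": "control", "TP": "exposed"}
_SC_LABELS = ("CP", "TP")
_BULK_LABELS = ("CI", "CD", "CB", "TB")


def simulate_dataset(config: ScenarioConfig, catalog: GeneCatalog,
                     label: str):
    """Generate one dataset (all replicates) of the paired design.

    Returns a :class:`CountTable` for bulk labels and a post-capture
    AnnData (replicates concatenated, ``obs["sample"]``) for single-cell
    labels.  Substreams are derived from the config seed and the label, so
    any dataset can be generated alone, identically to the full bundle.
    """
    if label not in _DATASET_CONDITION:
        raise UsageError(f"unknown dataset label {label!r}")
    condition = _DATASET_CONDITION[label]
    n_reps = int(config.replicates.get(label, 0))
    if n_reps <= 0:
        raise ConfigurationError(f"no replicates configured for {label!r}")

    if label in _BULK_LABELS:
        columns = {}
        for r in range(1, n_reps + 1):
            rng = _substream(config.seed, label, f"rep{r}")
            cells = simulate_cells(catalog, config, condition,
                                   config.bulk_cells_per_sample, rng,
                                   sample=f"{label}_{r}", bulk_destined=True)
            if label != "CI":  # intact tissue skips dissociation
                cells = apply_dissociation_stress(cells, catalog, config, rng)
            columns[f"{label}_{r}"] = simulate_bulk_library(
                cells, config.bulk_depth, rng)
        df = pd.DataFrame(columns)
        df.index.name = "gene_id"
        return CountTable(df, label=label)

    parts = []
    for r in range(1, n_reps + 1):
        rng = _substream(config.seed, label, f"rep{r}")
        cells = simulate_cells(catalog, config, condition,
                               config.sc_cells_per_sample, rng,
                               sample=f"{label}_{r}")
        cells = apply_dissociation_stress(cells, catalog, config, rng)
        cells = _apply_droplet_program(cells, catalog, config, rng)
        cells = apply_droplet_capture(cells, config, rng)
        parts.append(cells)
    merged = ad.concat(parts, merge="same", uns_merge=None,
                       index_unique=None)
    merged.var = parts[0].var.copy()
    merged.uns["dissociated"] = True
    merged.uns["captured"] = True
    merged.uns["capture_truth"] = {
        p.obs["sample"].iloc[0]: p.uns["capture_truth"] for p in parts}
    return merged


@dataclass
class ExperimentBundle:
    """Everything the downstream comparison consumes, plus ground truth."""

    gene_catalog: GeneCatalog
    bulk_tables: dict[str, CountTable]
    sc_matrices: dict[str, ad.AnnData]
    truth: dict

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for label, table in self.bulk_tables.items():
            write_count_table(table, directory / f"{label}.tsv")
        for label, adata in self.sc_matrices.items():
            write_cell_matrix(adata, directory, prefix=f"{label}_")
            adata.obs.to_csv(directory / f"{label}_cells.tsv", sep="\t")
        self.gene_catalog.genes.to_csv(directory / "gene_catalog.tsv", sep="\t")
        self.gene_catalog.baseline.to_csv(directory / "gene_baseline.tsv",
                                          sep="\t")
        (directory / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True))
        return directory


def generate_experiment(config: ScenarioConfig) -> ExperimentBundle:
    """Produce the full paired design of the study scenario.

    CI is intact bulk; CD/CB/TB are dissociated bulk; CP/TP are dissociated,
    droplet-program-bearing, droplet-captured single-cell matrices.
    Deterministic given ``config.seed``.
    """
    catalog = generate_gene_catalog(config, _substream(config.seed, "catalog"))
    bulk_tables = {label: simulate_dataset(config, catalog, label)
                   for label in _BULK_LABELS if config.replicates.get(label)}
    sc_matrices = {label: simulate_dataset(config, catalog, label)
                   for label in _SC_LABELS if config.replicates.get(label)}
    truth = {
        "seed": config.seed,
        "proportions": {c: config.proportions(c)
                        for c in ("control", "exposed")},
        "programs": {name: list(map(str, members))
                     for name, members in catalog.programs.items()},
        "capture": {label: adata.uns["capture_truth"]
                    for label, adata in sc_matrices.items()},
    }
    return ExperimentBundle(gene_catalog=catalog, bulk_tables=bulk_tables,
                            sc_matrices=sc_matrices, truth=truth)
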