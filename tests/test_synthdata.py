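import numpy as np
import pytest

from scdropout import (ConfigurationError, DataError, ScenarioConfig,
                       StateError, UsageError, apply_dissociation_stress,
                       apply_droplet_capture, generate_experiment,
                       generate_gene_catalog, simulate_bulk_library,
                       simulate_cells, simulate_dataset)
from scdropout.synthdata import _substream

from conftest import small_config, two_types


class TestConfig:
    def test_tf_count_forced_by_rounding(self):
        cfg = small_config(n_genes=1000, tf_fraction=0.15)
        cat = generate_gene_catalog(cfg, np.random.default_rng(0))
        assert int(cat.genes["is_tf"].sum()) == 150

    def test_oversized_program_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(n_genes=100,
                         program_sizes={"dissociation_up": 200})

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            small_config(cell_types=two_types(p_a=0.6)[:1])

    def test_unknown_condition_rejected(self):
        cfg = small_config()
        with pytest.raises(UsageError):
            cfg.proportions("mock")

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=99)
        path = cfg.to_yaml(tmp_path / "cfg.yaml")
        assert ScenarioConfig.from_yaml(path) == cfg


class TestCatalog:
    def test_determinism(self, cfg_small):
        a = generate_gene_catalog(cfg_small, np.random.default_rng(5))
        b = generate_gene_catalog(cfg_small, np.random.default_rng(5))
        assert a.genes.equals(b.genes)
        assert np.allclose(a.baseline.to_numpy(), b.baseline.to_numpy())
        assert all(a.programs[k].equals(b.programs[k]) for k in a.programs)

    def test_tf_genes_are_low_expressed(self, catalog_small):
        agg = catalog_small.baseline.sum(axis=1)
        tf_median = agg[catalog_small.genes["is_tf"]].median()
        other_median = agg[~catalog_small.genes["is_tf"]].median()
        assert tf_median < other_median

    def test_mito_set_small_and_disjoint_from_tf(self, catalog_small):
        genes = catalog_small.genes
        assert 0 < genes["is_mito"].sum() <= 0.05 * len(genes)
        assert not (genes["is_tf"] & genes["is_mito"]).any()

    def test_antagonistic_programs_disjoint(self, catalog_small):
        up = set(catalog_small.programs["dissociation_up"])
        down = set(catalog_small.programs["dissociation_down"])
        assert not up & down

    def test_baseline_columns_sum_to_library(self, cfg_small, catalog_small):
        sums = catalog_small.baseline.sum(axis=0)
        assert np.allclose(sums, cfg_small.sc_reads_per_cell)


class TestSimulateCells:
    def test_composition_within_binomial_noise(self, catalog_small,
                                               cfg_small, rng):
        n = 4000
        cells = simulate_cells(catalog_small, cfg_small, "control", n, rng)
        p = cfg_small.proportions("control")["sperm_1"]
        observed = (cells.obs["cell_type"] == "sperm_1").sum()
        sd = np.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) < 3 * sd

    def test_null_exposure_means_match(self, rng):
        cfg = small_config(
            cell_types=two_types(),
            program_lfc={"dissociation_up": 0, "dissociation_down": 0,
                         "droplet_up": 0, "exposure": 0})
        cat = generate_gene_catalog(cfg, np.random.default_rng(1))
        a = simulate_cells(cat, cfg, "control", 3000, rng)
        b = simulate_cells(cat, cfg, "exposed", 3000, rng)
        ma = np.asarray(a.X).mean(axis=0)
        mb = np.asarray(b.X).mean(axis=0)
        # per-gene means agree within pooled sampling error, in aggregate
        pooled_sd = np.sqrt(np.asarray(a.X).var(axis=0) / 3000
                            + np.asarray(b.X).var(axis=0) / 3000)
        z = (ma - mb) / np.maximum(pooled_sd, 1e-9)
        assert np.mean(np.abs(z) < 4) > 0.99

    def test_poisson_limit_of_dispersion(self, rng):
        cfg = small_config(nb_dispersion=1e-12, library_sigma=0.0,
                           cell_types=two_types())
        cat = generate_gene_catalog(cfg, np.random.default_rng(2))
        cells = simulate_cells(cat, cfg, "control", 10_000, rng)
        X = np.asarray(cells.X).astype(float)
        mask = (cells.obs["cell_type"] == "A").to_numpy()
        m = X[mask].mean(axis=0)
        v = X[mask].var(axis=0)
        ratio = v[m > 5] / m[m > 5]
        assert abs(np.median(ratio) - 1.0) < 0.1


class TestDissociation:
    def _setup(self, lfc=1.0, stress=0.0, seed=3):
        cfg = small_config(
            cell_types=two_types(susc_a=stress, susc_b=stress),
            control_stress=1.0 if stress else 0.0,
            program_lfc={"dissociation_up": lfc, "dissociation_down": lfc,
                         "droplet_up": 0, "exposure": 0})
        cat = generate_gene_catalog(cfg, np.random.default_rng(seed))
        rng = np.random.default_rng(seed + 100)
        cells = simulate_cells(cat, cfg, "control", 10_000, rng)
        return cfg, cat, cells, rng

    def test_lfc_one_doubles_up_program_means(self):
        cfg, cat, cells, rng = self._setup(lfc=1.0)
        out = apply_dissociation_stress(cells, cat, cfg, rng)
        up = cat.baseline.index.get_indexer(cat.programs["dissociation_up"])
        before = np.asarray(cells.X)[:, up].mean(axis=0)
        after = np.asarray(out.X)[:, up].mean(axis=0)
        big = before > 1
        assert np.allclose(after[big] / before[big], 2.0, rtol=0.15)

    def test_zero_lfc_zero_stress_preserves_means(self):
        cfg, cat, cells, rng = self._setup(lfc=0.0)
        out = apply_dissociation_stress(cells, cat, cfg, rng)
        assert np.array_equal(np.asarray(out.X), np.asarray(cells.X))

    def test_zero_stress_mito_unchanged(self):
        cfg, cat, cells, rng = self._setup(lfc=0.0, stress=0.0)
        out = apply_dissociation_stress(cells, cat, cfg, rng)
        mito = cat.genes["is_mito"].to_numpy()
        assert np.array_equal(np.asarray(out.X)[:, mito],
                              np.asarray(cells.X)[:, mito])

    def test_double_application_rejected(self):
        cfg, cat, cells, rng = self._setup()
        once = apply_dissociation_stress(cells, cat, cfg, rng)
        with pytest.raises(StateError):
            apply_dissociation_stress(once, cat, cfg, rng)


class TestCapture:
    def _dissociated(self, cfg, seed=4):
        cat = generate_gene_catalog(cfg, np.random.default_rng(seed))
        rng = np.random.default_rng(seed + 50)
        cells = simulate_cells(cat, cfg, "control", 3000, rng)
        return cat, apply_dissociation_stress(cells, cat, cfg, rng), rng

    def test_one_third_cell_loss(self):
        cfg = small_config(cell_types=two_types(), control_stress=0.0,
                           capture_cell_loss=1 / 3)
        cat, cells, rng = self._dissociated(cfg)
        out = apply_droplet_capture(cells, cfg, rng)
        p = 2 / 3
        sd = np.sqrt(3000 * p * (1 - p))
        assert abs(out.n_obs - 3000 * p) < 3 * sd

    def test_identity_thinning_when_detection_saturates(self):
        cfg = small_config(cell_types=two_types(), control_stress=0.0,
                           capture_cell_loss=0.0, capture_slope=1.0,
                           capture_midpoint=-60.0, length_offset_short=0.0)
        cat, cells, rng = self._dissociated(cfg)
        out = apply_droplet_capture(cells, cfg, rng)
        assert out.n_obs == cells.n_obs
        assert np.array_equal(np.asarray(out.X), np.asarray(cells.X))

    def test_low_abundance_class_detected_less(self, rng):
        # two gene classes with true means ~2 and ~200
        cfg = small_config(n_genes=100, cell_types=two_types(),
                           control_stress=0.0, capture_cell_loss=0.0,
                           sc_reads_per_cell=100 * 101,
                           program_sizes={}, length_offset_short=0.0)
        cat = generate_gene_catalog(cfg, np.random.default_rng(8))
        cat.baseline.iloc[:50, :] = 2.0
        cat.baseline.iloc[50:, :] = 200.0
        cells = simulate_cells(cat, cfg, "control", 10_000, rng)
        cells.uns["dissociated"] = True
        out = apply_droplet_capture(cells, cfg, rng)
        pre = np.asarray(cells.X)
        post = np.asarray(out.X)
        rate_low = post[:, :50].sum() / pre[:, :50].sum()
        rate_high = post[:, 50:].sum() / pre[:, 50:].sum()
        assert rate_low < rate_high

    def test_capture_requires_dissociation(self, catalog_small, cfg_small,
                                           rng):
        cells = simulate_cells(catalog_small, cfg_small, "control", 50, rng)
        with pytest.raises(StateError):
            apply_droplet_capture(cells, cfg_small, rng)

    def test_bulk_destined_matrix_rejected(self, catalog_small, cfg_small,
                                           rng):
        cells = simulate_cells(catalog_small, cfg_small, "control", 50, rng,
                               bulk_destined=True)
        cells.uns["dissociated"] = True
        with pytest.raises(UsageError):
            apply_droplet_capture(cells, cfg_small, rng)

    def test_monotone_dropout_in_abundance(self, rng):
        cfg = small_config(cell_types=two_types(), control_stress=0.0,
                           capture_cell_loss=0.0)
        cat, cells, rng2 = self._dissociated(cfg, seed=9)
        out = apply_droplet_capture(cells, cfg, rng2)
        pre = np.asarray(cells.X).sum(axis=0).astype(float)
        post = np.asarray(out.X).sum(axis=0).astype(float)
        mean_pre = np.asarray(cells.X).mean(axis=0)
        order = np.argsort(mean_pre)
        with np.errstate(invalid="ignore"):
            rates = np.where(pre > 0, post / np.maximum(pre, 1), np.nan)
        # detection rate non-decreasing across abundance bins
        bins = np.array_split(order[pre[order] > 0], 5)
        bin_rates = [np.nanmean(rates[b]) for b in bins if len(b)]
        assert all(a <= b + 0.02 for a, b in zip(bin_rates, bin_rates[1:]))


class TestBulkLibrary:
    def test_column_sums_to_depth_exactly(self, catalog_small, cfg_small,
                                          rng):
        cells = simulate_cells(catalog_small, cfg_small, "control", 200, rng)
        col = simulate_bulk_library(cells, 10 ** 6, rng)
        assert col.sum() == 10 ** 6

    def test_equal_pools_split_evenly(self, rng):
        import anndata as ad
        import pandas as pd
        X = np.full((10, 4), 25, dtype=np.int64)
        adata = ad.AnnData(
            X=X, obs=pd.DataFrame(index=[f"c{i}" for i in range(10)]),
            var=pd.DataFrame(index=list("abcd")))
        col = simulate_bulk_library(adata, 400_000, rng)
        sd = np.sqrt(400_000 * 0.25 * 0.75)
        assert np.all(np.abs(col - 100_000) < 3 * sd)

    def test_zero_support_gene_stays_zero(self, rng):
        import anndata as ad
        import pandas as pd
        X = np.array([[5, 0], [7, 0]], dtype=np.int64)
        adata = ad.AnnData(
            X=X, obs=pd.DataFrame(index=["c0", "c1"]),
            var=pd.DataFrame(index=["a", "b"]))
        col = simulate_bulk_library(adata, 1000, rng)
        assert col["b"] == 0

    def test_captured_matrix_rejected(self, rng):
        cfg = small_config(cell_types=two_types(), control_stress=0.0)
        cat = generate_gene_catalog(cfg, np.random.default_rng(3))
        cells = simulate_cells(cat, cfg, "control", 100, rng)
        cells = apply_dissociation_stress(cells, cat, cfg, rng)
        captured = apply_droplet_capture(cells, cfg, rng)
        with pytest.raises(UsageError):
            simulate_bulk_library(captured, 1000, rng)

    def test_empty_matrix_rejected(self, catalog_small, cfg_small, rng):
        cells = simulate_cells(catalog_small, cfg_small, "control", 5, rng)
        with pytest.raises(DataError):
            simulate_bulk_library(cells[:0], 1000, rng)


class TestExperiment:
    def test_replicate_structure(self, cfg_small):
        bundle = generate_experiment(cfg_small)
        for label, n in cfg_small.replicates.items():
            if label in bundle.bulk_tables:
                assert len(bundle.bulk_tables[label].samples) == n
        for label in ("CP", "TP"):
            assert bundle.sc_matrices[label].obs["sample"].nunique() \
                == cfg_small.replicates[label]

    def test_default_design_counts(self):
        cfg = ScenarioConfig()
        assert {k: cfg.replicates[k] for k in ("CI", "CD", "CB", "TB",
                                               "CP", "TP")} \
            == {"CI": 3, "CD": 3, "CB": 3, "TB": 2, "CP": 3, "TP": 2}

    def test_byte_identical_saves(self, cfg_small, tmp_path):
        d1 = generate_experiment(cfg_small).save(tmp_path / "a")
        d2 = generate_experiment(cfg_small).save(tmp_path / "b")
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_dataset_substreams_match_bundle(self, cfg_small, catalog_small):
        bundle = generate_experiment(cfg_small)
        solo = simulate_dataset(cfg_small, catalog_small, "CB")
        assert solo.counts.equals(bundle.bulk_tables["CB"].counts)

    def test_truth_programs_subset_of_catalog(self, cfg_small):
        bundle = generate_experiment(cfg_small)
        universe = set(bundle.gene_catalog.gene_ids)
        for members in bundle.truth["programs"].values():
            assert set(members) <= universe
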