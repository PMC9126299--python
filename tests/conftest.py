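import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scdropout import CellTypeSpec, ScenarioConfig, generate_gene_catalog
from scdropout.synthdata import _substream

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def small_config(**overrides) -> ScenarioConfig:
    """A fast, reduced-scale scenario for unit tests (not the study scale)."""
    defaults = dict(
        n_genes=300,
        program_sizes={"dissociation_up": 20, "dissociation_down": 20,
                       "droplet_up": 15, "exposure_per_celltype": 5},
        sc_cells_per_sample=400,
        sc_reads_per_cell=3000,
        # the tiny gene universe leaves a narrow expressed low-mid band;
        # widen it so the per-type programs always fit
        exposure_program_min_quantile=0.05,
        exposure_program_max_quantile=0.80,
        bulk_cells_per_sample=300,
        bulk_depth=500_000,
        replicates={"CI": 2, "CD": 2, "CB": 2, "TB": 2, "CP": 2, "TP": 2},
        seed=11,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def cfg_small():
    return small_config()


@pytest.fixture(scope="session")
def catalog_small(cfg_small):
    return generate_gene_catalog(cfg_small, _substream(cfg_small.seed, "catalog"))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def two_types(p_a=0.5, susc_a=0.0, susc_b=0.0, p_a_exposed=None):
    """Minimal two-cell-type layout for targeted simulations."""
    pae = p_a if p_a_exposed is None else p_a_exposed
    return [
        CellTypeSpec("A", p_a, pae, susc_a),
        CellTypeSpec("B", 1 - p_a, 1 - pae, susc_b),
    ]
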