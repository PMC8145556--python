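import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isoqc import simulate_benchmark as sb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Desk-scale panel conditions shared across the suite: the same study design
# as the full benchmark (4 genera, 50x, 1% error, 10/20/30% ratios), with
# smaller genomes so the whole suite stays fast.
SMALL_PANEL = dict(
    genome_length=40_000,
    n_core_genes=20,
    gene_len=1000,
    gc_targets=(0.35, 0.45, 0.55, 0.65),
    coverage=50.0,
    ratios=(0.10, 0.20, 0.30),
)


@pytest.fixture(scope="session")
def panel_cfg():
    return sb.PanelConfig(replicates=2, **SMALL_PANEL)


@pytest.fixture(scope="session")
def taxa(panel_cfg):
    return panel_cfg.make_taxa(seed=1)


@pytest.fixture(scope="session")
def panel_index(taxa):
    return sb.panel_taxonomy_index(taxa)


@pytest.fixture(scope="session")
def panel_thresholds(taxa):
    return sb.derive_panel_thresholds(taxa, n_per_species=100, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
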