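import numpy as np
import pytest

import g2vec as gv
from g2vec.corrnet import CorrelationNetwork
from g2vec.datagen import GOOD, POOR

FIXTURE_SEED = 11
PIPELINE_SEED = 3


@pytest.fixture(scope="session")
def cohort():
    """Synthetic cohort: 500 genes, 60 samples/group, two planted 20-gene
    modules with a 1.0 mean shift (2x noise SD) and 0.9 within-module
    correlation — the standard recovery conditions used across the suite."""
    cfg = gv.SyntheticCohortConfig(
        n_genes=500,
        n_samples_per_group=60,
        n_network_edges=2000,
        planted_module_sizes=[20, 20],
        planted_effect=1.0,
        within_module_corr=0.9,
        noise_sd=0.5,
        seed=FIXTURE_SEED,
    )
    return gv.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def selection(cohort):
    data, _, edges, _ = cohort
    return gv.select_markers(data, edges, gv.PipelineConfig(), seed=PIPELINE_SEED)


@pytest.fixture
def line_network():
    """Path graph A-B-C with equal weights."""
    return CorrelationNetwork(
        group=GOOD, nodes=["A", "B", "C"],
        edges={("A", "B"): 0.8, ("B", "C"): 0.8},
    )


@pytest.fixture
def star_network():
    """Star K_{1,3} centered at H."""
    return CorrelationNetwork(
        group=POOR, nodes=["H", "L1", "L2", "L3"],
        edges={("H", "L1"): 0.7, ("H", "L2"): 0.7, ("H", "L3"): 0.7},
    )


def make_dataset(matrix, labels_by_sample, gene_prefix="g"):
    matrix = np.asarray(matrix, dtype=float)
    gene_ids = [f"{gene_prefix}{i}" for i in range(matrix.shape[0])]
    sample_ids = list(labels_by_sample)
    return gv.ExpressionDataset(gene_ids, matrix, sample_ids, dict(labels_by_sample))
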