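import numpy as np
import pytest

from ifselect import generate_dataset, imbalance_preset


@pytest.fixture(scope="session")
def small_config():
    """Endothelial-style imbalance at desk scale: 300 cells, 150 genes,
    6 planted markers with 3-sigma shifts, 30% dropout."""
    return imbalance_preset(
        "endothelial", total=300, n_genes=150, n_markers=6, seed=11
    )


@pytest.fixture(scope="session")
def small_matrix(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_marker_ids(small_config, small_matrix):
    return sorted(
        small_matrix.gene_ids[i] for i in small_config.marker_gene_indices
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
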