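"""Shared fixtures: a small synthetic study and its feature matrix."""

import numpy as np
import pytest

from pathdsp import FixtureConfig, generate_fixture
from pathdsp.pipeline import build_features

SMALL_CONFIG = FixtureConfig(
    n_genes=120, n_cells=30, n_drugs=8, n_pathways=12,
    pathway_size_range=(6, 10), seed=11,
)

FAST_FNN = dict(
    hidden_layer_sizes=(64, 32), learning_rate=1e-3,
    batch_size=32, max_epochs=120, patience=12,
)


@pytest.fixture(scope="session")
def small_fixture():
    return generate_fixture(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_features(small_fixture):
    fx = small_fixture
    return build_features(
        fx.gene_sets, fx.network, fx.omics, fx.drugs, fx.responses,
        n_perm=100, rng_seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
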