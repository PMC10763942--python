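import warnings

import numpy as np
import pandas as pd
import pytest

from xsp import (
    ExpressionMatrix,
    RunConfig,
    SimConfig,
    run_homology,
    simulate_pair,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but structurally complete two-species instance.

    Dispersion is raised relative to the default: with only ~600 genes
    the similarity rankings of pseudo-cell profiles become nearly
    deterministic, which over-states how separable residual types are.
    """
    return SimConfig(
        n_orthologs=600, n_private_genes=50, n_markers_per_type=16,
        cells_per_type=100, nb_dispersion=0.4, seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_pair(small_config)


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Full pipeline result on the small instance (shared across tests)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_homology(
            small_sim.expr_a, small_sim.labels_a, small_sim.libraries_a,
            small_sim.expr_b, small_sim.labels_b, small_sim.libraries_b,
            small_sim.candidates, RunConfig(seed=11),
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_expression(rng, n_genes=20, n_cells=12, scale="raw_counts"):
    vals = rng.poisson(3.0, size=(n_genes, n_cells)).astype(float)
    if scale == "lognorm":
        vals = np.log1p(vals)
    return ExpressionMatrix(
        vals,
        pd.Index([f"g{i}" for i in range(n_genes)]),
        pd.Index([f"c{i}" for i in range(n_cells)]),
        scale,
    )
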