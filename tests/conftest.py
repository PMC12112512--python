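"""Shared fixtures: the default synthetic study system, generated once."""

import numpy as np
import pytest
from hypothesis import settings

from genebirth import simulate as sim
from genebirth.io_formats import default_species_tree

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def tree():
    return default_species_tree()


@pytest.fixture(scope="session")
def gene_fixture():
    """Default gene-set fixture: 300 background + 30 planted births, seed 42."""
    return sim.simulate_gene_set(sim.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def full_fixture():
    """Gene set plus matched expression matrix from one RNG stream."""
    cfg = sim.SimulationConfig(seed=42)
    rng = np.random.default_rng(42)
    fx = sim.simulate_gene_set(cfg, rng)
    expr = sim.simulate_expression(cfg, gene_ids=[g.gene_id for g in fx.genes],
                                   branch_by_gene=fx.truth.branch,
                                   truth=fx.truth, rng=rng)
    return fx, expr
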