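"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from netwas.simulate import SimConfig, generate_cohort, generate_gene_models


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_subjects=500,
        n_genes=40,
        snps_per_gene=5,
        n_disease_genes=8,
        effect_size=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genes(small_config):
    return generate_gene_models(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_genes):
    return generate_cohort(small_config, small_genes)


@pytest.fixture(scope="session")
def toy_network():
    """12-gene network with random weights; 6 labeled (3 pos, 3 neg)."""
    from netwas.reprioritize import TissueNetwork

    rng = np.random.default_rng(5)
    A = rng.uniform(0, 1, (12, 12))
    W = np.triu(A, 1)
    W = W + W.T
    gene_ids = [f"T{i:02d}" for i in range(12)]
    return TissueNetwork(gene_ids=gene_ids, W=W)
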