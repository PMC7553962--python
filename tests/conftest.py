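"""Shared fixtures: synthetic study data generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from csgcn import preprocess as prep
from csgcn.simulate import default_config, simulate_gem


@pytest.fixture(scope="session")
def study():
    """The full synthetic study: 6 regions x 60 samples, 300 genes,
    one 10-gene module per region, lambda = 0.95, log2-transformed."""
    cfg = default_config(n_regions=6, samples_per_region=60, n_genes=300,
                         genes_per_module=10, factor_loading=0.95, seed=1)
    gem, labels, lengths, truth = simulate_gem(cfg)
    log2 = prep.log2_transform(gem)
    return {"config": cfg, "gem": gem, "log2": log2, "labels": labels,
            "lengths": lengths, "truth": truth}


@pytest.fixture(scope="session")
def small_study():
    """A compact study (3 regions x 30 samples, 60 genes, one planted
    module) for classifier and decomposition tests."""
    cfg = default_config(n_regions=3, samples_per_region=30, n_genes=60,
                         genes_per_module=10, n_modules=1, seed=7)
    gem, labels, lengths, truth = simulate_gem(cfg)
    log2 = prep.log2_transform(gem)
    return {"config": cfg, "gem": gem, "log2": log2, "labels": labels,
            "lengths": lengths, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
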