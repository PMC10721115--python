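import numpy as np
import pandas as pd
import pytest

import cocoex as cx


@pytest.fixture(scope="session")
def small_config() -> cx.SimConfig:
    """Small but fully featured simulation: fast enough for per-test reuse."""
    return cx.SimConfig(n_human_genes=400, n_mouse_genes=300,
                        n_responsive_genes=30, n_mouse_responsive_genes=20,
                        seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return cx.simulate_coculture(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_counts() -> cx.CountMatrix:
    counts = np.array([[100, 200, 50], [500, 900, 260], [80, 150, 40],
                       [1000, 2100, 520], [250, 480, 130]])
    return cx.CountMatrix([f"g{i}" for i in range(5)], ["s1", "s2", "s3"], counts)


def make_normmat(values, gene_ids=None, sample_ids=None, lib_sizes=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return cx.NormalizedMatrix(
        gene_ids or [f"g{i}" for i in range(g)],
        sample_ids or [f"s{j}" for j in range(n)],
        values, np.ones(n), lib_sizes=lib_sizes)


@pytest.fixture
def normmat_factory():
    return make_normmat
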