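import itertools

import numpy as np
import pandas as pd
import pytest

from nemacge import Connectome, SynthConfig, simulate


@pytest.fixture(scope="session")
def planted_ds():
    """Default planted-signal synthetic dataset (16 hubs, 20 hub genes)."""
    return simulate(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_ds():
    """Small synthetic dataset for fast end-to-end checks."""
    cfg = SynthConfig(
        n_head=50, n_body=30, n_tail=12, n_hubs=8, n_genes=120,
        n_hub_genes=8, n_bilateral_pairs=20, seed=3,
    )
    return simulate(cfg)


def make_connectome(neurons, chem_edges, gap_edges=(), neuron_table=None):
    chem = pd.DataFrame(
        [(a, b, w) for a, b, w in chem_edges], columns=["pre", "post", "weight"]
    )
    gap = pd.DataFrame(
        [(a, b, w) for a, b, w in gap_edges], columns=["a", "b", "weight"]
    )
    if not len(chem):
        chem = pd.DataFrame({"pre": [], "post": [], "weight": []})
    if not len(gap):
        gap = pd.DataFrame({"a": [], "b": [], "weight": []})
    return Connectome(list(neurons), chem, gap, neuron_table=neuron_table)


@pytest.fixture()
def toy_chain():
    """Chemical A->B plus gap B-C."""
    return make_connectome("ABC", [("A", "B", 1)], [("B", "C", 1)])


@pytest.fixture()
def complete_digraph4():
    edges = [(a, b, 1) for a, b in itertools.permutations("ABCD", 2)]
    return make_connectome("ABCD", edges)


def random_connectome(n, p, seed, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"N{i}" for i in range(n)]
    A = rng.random((n, n)) < p
    np.fill_diagonal(A, False)
    edges = [(names[i], names[j], 1) for i, j in zip(*np.nonzero(A))]
    return make_connectome(names, edges)
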