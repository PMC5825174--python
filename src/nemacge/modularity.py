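"""Louvain consensus partitioning of the connectome.

Directed edges are symmetrized (OR) for community detection.  The
consensus procedure runs Louvain many times with distinct sub-seeds,
builds a modularity(Q)-weighted co-assignment (agreement) matrix,
thresholds it, and re-clusters the agreement graph iteratively until the
partition is stable across runs.  An externally derived partition (e.g. a
stochastic block model decomposition) can be loaded instead of being
re-derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import Connectome
from .errors import ArgumentError, DataError

logger = logging.getLogger(__name__)


@dataclass
class ModularPartition:
    """Per-neuron module assignment with contiguous ids from 1."""

    labels: pd.Series  # index: neuron name, values: module id
    Q: float
    n_runs: int
    source: str  # "louvain_consensus" | "external"

    @property
    def n_modules(self) -> int:
        return int(self.labels.nunique())

    def module_sizes(self) -> list[int]:
        return sorted(self.labels.value_counts().tolist(), reverse=True)

    def as_array(self, neurons: list[str]) -> np.ndarray:
        return self.labels.reindex(neurons).to_numpy()


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Contiguous ids from 1, in decreasing module size (ties by smallest
    original id)."""
    ids, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    mapping = {ids[o]: rank + 1 for rank, o in enumerate(order)}
    return np.asarray([mapping[x] for x in labels])


def _louvain_once(G: nx.Graph, seed: int) -> tuple[np.ndarray, float]:
    comms = nx.community.louvain_communities(G, weight="weight", seed=seed)
    labels = np.empty(G.number_of_nodes(), dtype=np.int64)
    for mid, members in enumerate(comms):
        for node in members:
            labels[node] = mid
    q = nx.community.modularity(G, comms, weight="weight")
    return labels, q


def _symmetrized_graph(c: Connectome) -> nx.Graph:
    A = c.adjacency()
    U = A | A.T
    G = nx.Graph()
    G.add_nodes_from(range(c.n_neurons))
    iu, ju = np.nonzero(np.triu(U, 1))
    G.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return G


def louvain_consensus(
    c: Connectome,
    n_runs: int = 1000,
    tau: float = 0.4,
    seed: int = 0,
    max_consensus_iter: int = 20,
) -> ModularPartition:
    """Q-weighted Louvain consensus partition of the symmetrized connectome.

    ``tau`` is the agreement threshold below which co-assignment weights
    are zeroed before re-clustering the agreement matrix.  The procedure
    iterates until all re-clustering runs agree (deterministic given
    ``seed``).
    """
    if n_runs < 2:
        raise ArgumentError("n_runs must be >= 2")
    G = _symmetrized_graph(c)
    if G.number_of_edges() < 1:
        raise DataError("graph has no edges; cannot partition")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_runs * (max_consensus_iter + 1)) % (2**31)
    si = 0

    n = c.n_neurons
    parts = np.empty((n_runs, n), dtype=np.int64)
    qs = np.empty(n_runs)
    for r in range(n_runs):
        parts[r], qs[r] = _louvain_once(G, int(seeds[si]))
        si += 1

    for _ in range(max_consensus_iter):
        # Q-weighted agreement matrix
        w = np.clip(qs, 0, None)
        if w.sum() == 0:
            w = np.ones_like(qs)
        agree = np.zeros((n, n))
        for r in range(len(parts)):
            agree += w[r] * (parts[r][:, None] == parts[r][None, :])
        agree /= w.sum()
        if _all_identical(parts):
            break
        thresholded = np.where(agree >= tau, agree, 0.0)
        np.fill_diagonal(thresholded, 0.0)
        Ga = nx.from_numpy_array(thresholded)
        if Ga.number_of_edges() == 0:
            logger.warning("agreement matrix empty after thresholding at tau=%.2f", tau)
            break
        new_parts = np.empty_like(parts)
        new_qs = np.empty_like(qs)
        for r in range(len(parts)):
            new_parts[r], _ = _louvain_once(Ga, int(seeds[si]))
            # score each candidate partition on the *original* graph
            new_qs[r] = _modularity_of_labels(G, new_parts[r])
            si += 1
        parts, qs = new_parts, new_qs
    labels = _relabel(parts[0])
    q = _modularity_of_labels(G, labels)
    return ModularPartition(
        labels=pd.Series(labels, index=c.neurons, name="module"),
        Q=float(q), n_runs=n_runs, source="louvain_consensus",
    )


def _modularity_of_labels(G: nx.Graph, labels: np.ndarray) -> float:
    comms = [set(np.nonzero(labels == m)[0].tolist()) for m in np.unique(labels)]
    return nx.community.modularity(G, comms, weight="weight")


def _all_identical(parts: np.ndarray) -> bool:
    first = parts[0]
    for r in range(1, len(parts)):
        # identical up to label permutation
        pair = set(zip(first.tolist(), parts[r].tolist()))
        if len({a for a, _ in pair}) != len(pair) or len({b for _, b in pair}) != len(pair):
            return False
    return True


def load_partition(tsv: str | Path, neurons: list[str]) -> ModularPartition:
    """Load an external partition TSV (columns ``neuron  module``)."""
    t = pd.read_csv(tsv, sep="\t", dtype={"neuron": str}, comment="#")
    for col in ("neuron", "module"):
        if col not in t.columns:
            raise DataError(f"partition table missing column {col!r}")
    t["neuron"] = t["neuron"].str.strip()
    missing = [n for n in neurons if n not in set(t["neuron"])]
    if missing:
        raise DataError(f"partition missing neuron {missing[0]!r}")
    t = t.set_index("neuron").loc[neurons]
    labels = _relabel(t["module"].to_numpy())
    return ModularPartition(
        labels=pd.Series(labels, index=neurons, name="module"),
        Q=float("nan"), n_runs=0, source="external",
    )


def partition_pair_masks(
    partition: ModularPartition, neurons: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean matrices of intra- and inter-module unordered pairs."""
    lab = partition.as_array(neurons)
    intra = lab[:, None] == lab[None, :]
    np.fill_diagonal(intra, False)
    inter = lab[:, None] != lab[None, :]
    return intra, inter
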