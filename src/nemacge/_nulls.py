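"""Degree-preserving rewiring kernels (numba-compiled).

Directed double-edge swaps: pick two edges (a->b, c->d) and rewire to
(a->d, c->b) unless that would create a self-edge or a duplicate.  Each
accepted swap leaves every node's in- and out-degree unchanged.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _directed_swap_kernel(src, dst, adj, n_attempts, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    m = src.shape[0]
    successes = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a = src[e1]
        b = dst[e1]
        c = src[e2]
        d = dst[e2]
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[c, d] = False
        adj[a, d] = True
        adj[c, b] = True
        dst[e1] = d
        dst[e2] = b
        successes += 1
    return successes


@njit(cache=True)
def _undirected_swap_kernel(ea, eb, adj, n_attempts, seed):  # pragma: no cover - jit
    """Double-edge swap on undirected pairs; ``adj`` is kept symmetric."""
    np.random.seed(seed)
    m = ea.shape[0]
    successes = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a = ea[e1]
        b = eb[e1]
        c = ea[e2]
        d = eb[e2]
        # randomly choose one of the two rewirings
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        eb[e1] = d
        ea[e2] = c
        eb[e2] = b
        successes += 1
    return successes


def directed_double_edge_swaps(
    src: np.ndarray, dst: np.ndarray, n_nodes: int, n_attempts: int, seed: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Run ``n_attempts`` directed swap attempts on an edge list.

    Returns rewired (src, dst) copies and the number of successful swaps.
    """
    src = np.ascontiguousarray(src, dtype=np.int64).copy()
    dst = np.ascontiguousarray(dst, dtype=np.int64).copy()
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    adj[src, dst] = True
    successes = _directed_swap_kernel(src, dst, adj, n_attempts, seed)
    return src, dst, int(successes)


def undirected_double_edge_swaps(
    ea: np.ndarray, eb: np.ndarray, n_nodes: int, n_attempts: int, seed: int
) -> tuple[np.ndarray, np.ndarray, int]:
    ea = np.ascontiguousarray(ea, dtype=np.int64).copy()
    eb = np.ascontiguousarray(eb, dtype=np.int64).copy()
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    adj[ea, eb] = True
    adj[eb, ea] = True
    successes = _undirected_swap_kernel(ea, eb, adj, n_attempts, seed)
    return ea, eb, int(successes)
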