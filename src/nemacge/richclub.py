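"""Rich-club coefficients, degree-preserving nulls, and hub-distance statistics.

The rich-club coefficient phi(k) measures link density among the nodes
whose degree exceeds k:

    phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1)),

where, by default, E_{>k} counts *unordered connected pairs* within the
subgraph (the factor 2 is only consistent with a directed graph under
this reading, and it keeps phi <= 1).  An alternative directed-density
mode E / (N (N-1)) over directed edges is available via
``edge_count="directed"``.

Because phi(k) rises with k even in random graphs, it is normalized
against an ensemble of degree-preserving rewired nulls:

    Phi_norm(k) = phi(k) / <phi_rand(k)>,

with a permutation p-value from the empirical null distribution using the
add-one estimator (p is never exactly zero).

Within this module node degree is the in+out degree of the *binarized*
combined adjacency (gap junctions bidirectional, parallel mechanisms
collapsed); this is exactly the quantity the rewiring null preserves, so
the node sets {degree > k} are identical in every null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._nulls import directed_double_edge_swaps, undirected_double_edge_swaps
from .connectome import Connectome
from .errors import ArgumentError

logger = logging.getLogger(__name__)


def binary_degrees(A: np.ndarray) -> np.ndarray:
    """Total degree (in + out) of a binary directed adjacency matrix."""
    return A.sum(axis=0) + A.sum(axis=1)


def rich_club_phi(c: Connectome, k: int, edge_count: str = "pairs") -> float:
    """Rich-club coefficient at a single degree threshold.

    Returns NaN (flagged undefined) when fewer than two nodes exceed k.
    """
    if k < 0:
        raise ArgumentError("k must be >= 0")
    A = c.adjacency()
    deg = binary_degrees(A)
    keep = deg > k
    n = int(keep.sum())
    if n < 2:
        return float("nan")
    sub = A[np.ix_(keep, keep)]
    if edge_count == "pairs":
        e = int(np.triu(sub | sub.T, 1).sum())
        return 2.0 * e / (n * (n - 1))
    if edge_count == "directed":
        return float(sub.sum()) / (n * (n - 1))
    raise ArgumentError(f"unknown edge_count mode {edge_count!r}")


def _phi_profile(A: np.ndarray, order: np.ndarray, n_at_k: np.ndarray,
                 edge_count: str) -> np.ndarray:
    """phi at every threshold in one O(N^2) pass.

    ``order`` sorts nodes by decreasing degree; ``n_at_k[k]`` is the number
    of nodes with degree > k.  Degree ties are unambiguous: every
    threshold keeps a full prefix of the sorted order.
    """
    S = A[np.ix_(order, order)]
    if edge_count == "pairs":
        # pairs added when node j joins the prefix = earlier nodes linked
        # to j in either direction
        U = S | S.T
        col_counts = np.asarray([U[:j, j].sum() for j in range(S.shape[0])])
        cum = np.concatenate([[0], np.cumsum(col_counts)])
        denom = n_at_k * (n_at_k - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                n_at_k >= 2, 2.0 * cum[n_at_k] / np.where(denom > 0, denom, 1), np.nan
            )
    # directed edge density
    col_counts = np.asarray([S[:j, j].sum() + S[j, :j].sum() for j in range(S.shape[0])])
    cum = np.concatenate([[0], np.cumsum(col_counts)])
    denom = n_at_k * (n_at_k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_at_k >= 2, cum[n_at_k] / np.where(denom > 0, denom, 1), np.nan)


def phi_curve(A: np.ndarray, edge_count: str = "pairs") -> pd.DataFrame:
    """phi(k) for k = 0 .. max degree of a binary directed adjacency."""
    deg = binary_degrees(A)
    kmax = int(deg.max(initial=0))
    order = np.argsort(-deg, kind="stable")
    ks = np.arange(kmax + 1)
    n_at_k = (deg[None, :] > ks[:, None]).sum(axis=1)
    phi = _phi_profile(A, order, n_at_k, edge_count)
    return pd.DataFrame({"k": ks, "N_gt": n_at_k, "phi": phi})


def rewire_null(
    c: Connectome,
    iters_per_edge: int = 50,
    seed: int = 0,
    preserve_gap_reciprocity: bool = False,
) -> tuple[Connectome, int]:
    """Degree-preserving rewired null of the binarized combined network.

    By default all unique directed connections (gap junctions expanded to
    both directions, parallel mechanisms collapsed) are swapped
    independently; ``preserve_gap_reciprocity=True`` instead swaps
    chemical edges among themselves (directed) and gap pairs among
    themselves (undirected), preserving gap reciprocity.

    Returns the rewired connectome and the number of successful swaps.
    Graphs too small or rigid to swap return unchanged with 0 successes
    (logged as a warning).
    """
    rng = np.random.SeedSequence(seed)
    names = np.asarray(c.neurons, dtype=object)
    if preserve_gap_reciprocity:
        cp, cq = c.chem_indices()
        ga, gb = c.gap_indices()
        s_chem, s_gap = (int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(2))
        succ = 0
        if len(cp) >= 2:
            cp, cq, s1 = directed_double_edge_swaps(
                cp, cq, c.n_neurons, iters_per_edge * len(cp), s_chem)
            succ += s1
        if len(ga) >= 2:
            ga, gb, s2 = undirected_double_edge_swaps(
                ga, gb, c.n_neurons, iters_per_edge * len(ga), s_gap)
            succ += s2
        chem = pd.DataFrame({"pre": names[cp], "post": names[cq], "weight": 1})
        lo, hi = np.minimum(ga, gb), np.maximum(ga, gb)
        gap = pd.DataFrame({"a": names[lo], "b": names[hi], "weight": 1})
        null = Connectome(list(c.neurons), chem, gap, neuron_table=c.neuron_table)
    else:
        A = c.adjacency()
        src, dst = (x.astype(np.int64) for x in np.nonzero(A))
        if len(src) < 2:
            logger.warning("graph too small to rewire; returning input")
            return c, 0
        s = int(rng.generate_state(1)[0] % (2**31))
        src, dst, succ = directed_double_edge_swaps(
            src, dst, c.n_neurons, iters_per_edge * len(src), s)
        chem = pd.DataFrame({"pre": names[src], "post": names[dst], "weight": 1})
        gap = pd.DataFrame({"a": [], "b": [], "weight": []})
        null = Connectome(list(c.neurons), chem, gap, neuron_table=c.neuron_table)
    if succ == 0:
        logger.warning("no legal swaps found; null equals input graph")
    return null, succ


def _null_adjacency(A: np.ndarray, iters_per_edge: int, seed: int) -> np.ndarray:
    src, dst = (x.astype(np.int64) for x in np.nonzero(A))
    src, dst, _ = directed_double_edge_swaps(src, dst, A.shape[0], iters_per_edge * len(src), seed)
    N = np.zeros_like(A)
    N[src, dst] = True
    return N


def normalized_rich_club(
    c: Connectome,
    n_null: int = 1000,
    iters_per_edge: int = 50,
    seed: int = 0,
    edge_count: str = "pairs",
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Normalized rich-club curve with permutation p-values.

    One null ensemble is generated and reused across all thresholds k.
    When 2-D neuron ``positions`` are given (or available from the neuron
    table), each row also carries the mean Euclidean distance over
    connected pairs among the k-hubs and a right-tailed Welch t-test
    p-value against the distances of all other connected pairs.
    """
    if n_null < 1:
        raise ArgumentError("n_null must be >= 1")
    A = c.adjacency()
    deg = binary_degrees(A)
    curve = phi_curve(A, edge_count=edge_count)
    ks = curve["k"].to_numpy()
    n_at_k = curve["N_gt"].to_numpy()
    phi = curve["phi"].to_numpy()

    seeds = np.random.SeedSequence(seed).generate_state(n_null) % (2**31)
    order = np.argsort(-deg, kind="stable")
    phi_rand = np.empty((n_null, len(ks)))
    for i in range(n_null):
        Nadj = _null_adjacency(A, iters_per_edge, int(seeds[i]))
        phi_rand[i] = _phi_profile(Nadj, order, n_at_k, edge_count)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN at N_gt < 2
        phi_rand_mean = np.nanmean(phi_rand, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = phi / phi_rand_mean
    # add-one permutation p: fraction of nulls with phi_rand >= phi
    exceed = np.nansum(phi_rand >= phi[None, :], axis=0)
    p_perm = (1.0 + exceed) / (n_null + 1.0)
    p_perm = np.where(np.isnan(phi), np.nan, p_perm)

    out = curve.assign(
        phi_rand_mean=phi_rand_mean, Phi_norm=phi_norm, p_perm=p_perm
    )

    if positions is None and c.neuron_table is not None:
        try:
            positions = c.positions()
        except Exception:
            positions = None
    if positions is not None:
        P = A | A.T
        iu, ju = np.nonzero(np.triu(P, 1))
        d = np.linalg.norm(positions[iu] - positions[ju], axis=1)
        mean_d = np.full(len(ks), np.nan)
        p_dist = np.full(len(ks), np.nan)
        for idx, k in enumerate(ks):
            hub = deg > k
            in_club = hub[iu] & hub[ju]
            a, b = d[in_club], d[~in_club]
            if len(a) >= 2 and len(b) >= 2:
                mean_d[idx] = a.mean()
                if a.std() > 0 or b.std() > 0:
                    p_dist[idx] = stats.ttest_ind(
                        a, b, equal_var=False, alternative="greater"
                    ).pvalue
            elif len(a) >= 1:
                mean_d[idx] = a.mean()
        out["mean_hub_distance"] = mean_d
        out["p_distance"] = p_dist
    return out


def significant_regime(curve: pd.DataFrame, alpha: float = 0.05) -> tuple[int, int] | None:
    """Longest contiguous run of thresholds with Phi_norm > 1 and p < alpha.

    Returns (k_lo, k_hi) inclusive, or None when no threshold qualifies.
    """
    ok = (curve["Phi_norm"].to_numpy() > 1.0) & (curve["p_perm"].to_numpy() < alpha)
    ks = curve["k"].to_numpy()
    best: tuple[int, int] | None = None
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or (i - 1 - start) > (best[1] - best[0]):
                best = (int(ks[start]), int(ks[i - 1]))
            start = None
    return best


# ---------------------------------------------------------------------------
# weighted variants

def _weighted_adjacency(c: Connectome) -> np.ndarray:
    """Directed weight matrix: chemical synapse counts plus gap-junction
    counts applied in both directions."""
    n = c.n_neurons
    W = np.zeros((n, n))
    cp, cq = c.chem_indices()
    if len(cp):
        W[cp, cq] += c.chem["weight"].to_numpy(dtype=float)
    ga, gb = c.gap_indices()
    if len(ga):
        w = c.gap["weight"].to_numpy(dtype=float)
        W[ga, gb] += w
        W[gb, ga] += w
    return W


def _phi_weighted(W: np.ndarray, deg: np.ndarray, sorted_weights: np.ndarray,
                  ks: np.ndarray) -> np.ndarray:
    """Weighted coefficient: club weight sum over the sum of the E-largest
    weights in the whole network, E the number of club edges."""
    out = np.full(len(ks), np.nan)
    cumw = np.concatenate([[0.0], np.cumsum(sorted_weights)])
    for i, k in enumerate(ks):
        keep = deg > k
        if keep.sum() < 2:
            continue
        sub = W[np.ix_(keep, keep)]
        e = int((sub > 0).sum())
        if e == 0:
            out[i] = np.nan
            continue
        out[i] = sub.sum() / cumw[e]
    return out


def weighted_rich_club(
    c: Connectome,
    null_type: str = "weight_shuffle",
    n_null: int = 1000,
    iters_per_edge: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Weighted rich-club curve normalized by one of two null models.

    ``weight_shuffle`` keeps the topology fixed and permutes weights over
    the existing edges; ``topology_and_weights`` additionally rewires the
    topology (degree-preserving) before permuting weights.
    """
    if null_type not in ("weight_shuffle", "topology_and_weights"):
        raise ArgumentError(f"unknown null_type {null_type!r}")
    if n_null < 1:
        raise ArgumentError("n_null must be >= 1")
    W = _weighted_adjacency(c)
    A = W > 0
    deg = binary_degrees(A)
    kmax = int(deg.max(initial=0))
    ks = np.arange(kmax + 1)
    weights = W[A]
    sorted_w = np.sort(weights)[::-1]
    phi_w = _phi_weighted(W, deg, sorted_w, ks)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seeds = np.random.SeedSequence(seed).generate_state(n_null) % (2**31)
    phi_rand = np.empty((n_null, len(ks)))
    for i in range(n_null):
        if null_type == "weight_shuffle":
            Anull = A
        else:
            Anull = _null_adjacency(A, iters_per_edge, int(seeds[i]))
        Wnull = np.zeros_like(W)
        Wnull[Anull] = rng.permutation(weights)
        deg_null = deg  # degree sequence preserved by both null types
        phi_rand[i] = _phi_weighted(Wnull, deg_null, sorted_w, ks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN at N_gt < 2
        phi_rand_mean = np.nanmean(phi_rand, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = phi_w / phi_rand_mean
    exceed = np.nansum(phi_rand >= phi_w[None, :], axis=0)
    p_perm = np.where(np.isnan(phi_w), np.nan, (1.0 + exceed) / (n_null + 1.0))
    n_at_k = (deg[None, :] > ks[:, None]).sum(axis=1)
    return pd.DataFrame(
        {
            "k": ks,
            "N_gt": n_at_k,
            "phi_weighted": phi_w,
            "phi_rand_mean": phi_rand_mean,
            "Phi_norm": phi_norm,
            "p_perm": p_perm,
        }
    )
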