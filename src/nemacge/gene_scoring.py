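"""Per-gene contribution scores for CGE differences between connection classes.

Each gene is scored by asking whether its expression *matches* (expressed
in both neurons of a pair) land on a class of neuron pairs of interest
more often than chance.  With m matches on the class of interest out of n
matches over all pairs considered, and p_class the proportion of pairs in
that class, the score is the binomial upper tail

    p(a) = P(X >= m),   X ~ Binomial(n, p_class),

computed with a numerically stable survival function.  Genes must have
n >= 10 matches to receive a hit call; scores are corrected across genes
with Benjamini-Hochberg FDR, and hits are called at p_corr < 1e-4.

Two standard comparisons are provided: connected vs unconnected pairs,
and connected pairs involving a hub (rich, feed-in or feed-out) vs
peripheral connected pairs.  Bilateral homolog pairs are excluded from
every pair universe.  A hit list can then be tested for category
over-representation with a hypergeometric ORA.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cge import ExpressionMatrix
from .connectome import Connectome, degree_sequence, label_hubs
from .errors import ArgumentError, DataError

logger = logging.getLogger(__name__)

COMPARISONS = ("connected_vs_unconnected", "hub_involved_vs_peripheral")


def edge_match_counts(
    e: ExpressionMatrix,
    class_pairs: np.ndarray,
    alternative_pairs: np.ndarray,
) -> pd.DataFrame:
    """Per-gene match counts over a class pair set and its alternative.

    ``class_pairs`` and ``alternative_pairs`` are (n, 2) integer arrays of
    neuron indices forming disjoint sets of unordered pairs (bilateral
    pairs must already be excluded).  Returns one row per gene with
    columns ``m`` (matches on the class), ``n`` (matches over the union),
    ``M`` (total pairs considered) and ``n_class``.
    """
    class_pairs = np.asarray(class_pairs, dtype=np.int64).reshape(-1, 2)
    alternative_pairs = np.asarray(alternative_pairs, dtype=np.int64).reshape(-1, 2)
    key = lambda p: set(map(frozenset, map(tuple, p)))
    if key(class_pairs) & key(alternative_pairs):
        raise ArgumentError("class and alternative pair sets overlap")
    X = e.values.astype(bool)
    m = (X[class_pairs[:, 0]] & X[class_pairs[:, 1]]).sum(axis=0)
    n_alt = (X[alternative_pairs[:, 0]] & X[alternative_pairs[:, 1]]).sum(axis=0)
    return pd.DataFrame(
        {
            "gene": e.genes,
            "m": m.astype(int),
            "n": (m + n_alt).astype(int),
            "M": len(class_pairs) + len(alternative_pairs),
            "n_class": len(class_pairs),
        }
    )


def binomial_score(m, n, p_class):
    """Upper-tail binomial probability P(X >= m), X ~ Binomial(n, p_class).

    Accepts scalars or arrays; m = 0 returns exactly 1.
    """
    p_class = np.asarray(p_class, dtype=float)
    if ((p_class <= 0) | (p_class >= 1)).any():
        raise ArgumentError("p_class must lie strictly in (0, 1)")
    m = np.asarray(m)
    n = np.asarray(n)
    if (m < 0).any() or (m > n).any():
        raise ArgumentError("need 0 <= m <= n")
    out = stats.binom.sf(m - 1, n, p_class)
    return out if out.shape else float(out)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _pair_universe(
    c: Connectome, bilateral_pairs: list[tuple[str, str]] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All unordered non-bilateral pairs as index arrays, plus the
    symmetric connected-pair matrix."""
    n = c.n_neurons
    iu, ju = np.triu_indices(n, 1)
    if bilateral_pairs:
        excl = np.zeros((n, n), dtype=bool)
        for a, b in bilateral_pairs:
            i, j = c.index_of(a), c.index_of(b)
            excl[i, j] = excl[j, i] = True
        keep = ~excl[iu, ju]
        iu, ju = iu[keep], ju[keep]
    return iu, ju, c.pair_matrix()


def score_genes(
    e: ExpressionMatrix,
    c: Connectome,
    comparison: str = "connected_vs_unconnected",
    k_threshold: int = 44,
    min_n: int = 10,
    alpha: float = 1e-4,
    bilateral_pairs: list[tuple[str, str]] | None = None,
    per_gene_M: bool = False,
) -> pd.DataFrame:
    """Score every gene's contribution to a CGE contrast.

    ``connected_vs_unconnected`` contrasts connected against unconnected
    unordered pairs over the whole (non-bilateral) pair universe;
    ``hub_involved_vs_peripheral`` contrasts, among connected pairs, those
    with at least one hub endpoint (degree > ``k_threshold``) against
    peripheral (nonhub-nonhub) pairs.  p_class is recomputed from the
    actual pair universe after bilateral exclusion.  With ``per_gene_M``
    the class probability is instead computed per gene over the pairs the
    gene could possibly match (both endpoints annotated at least once).
    """
    if comparison not in COMPARISONS:
        raise ArgumentError(f"unknown comparison {comparison!r}")
    if e.neurons != c.neurons:
        raise DataError("expression and connectome neuron universes differ")
    iu, ju, P = _pair_universe(c, bilateral_pairs)
    connected = P[iu, ju]
    if comparison == "connected_vs_unconnected":
        in_class = connected
        considered = np.ones_like(connected, dtype=bool)
    else:
        deg = degree_sequence(c)
        hub = label_hubs(deg, k_threshold).to_numpy()
        in_class = connected & (hub[iu] | hub[ju])
        considered = connected
    class_pairs = np.column_stack([iu[in_class], ju[in_class]])
    alt_mask = considered & ~in_class
    alternative_pairs = np.column_stack([iu[alt_mask], ju[alt_mask]])
    if len(class_pairs) == 0 or len(alternative_pairs) == 0:
        raise DataError(f"empty pair class for comparison {comparison!r}")

    X = e.values.astype(bool)
    m = (X[class_pairs[:, 0]] & X[class_pairs[:, 1]]).sum(axis=0)
    n_tot = m + (X[alternative_pairs[:, 0]] & X[alternative_pairs[:, 1]]).sum(axis=0)
    M = len(class_pairs) + len(alternative_pairs)
    n_class = len(class_pairs)
    if per_gene_M:
        # restrict the universe to pairs where both neurons carry at least
        # one annotation (the pairs any gene could possibly match)
        annotated = X.any(axis=1)
        keep = annotated[iu] & annotated[ju]
        M_g = int((keep & considered).sum())
        n_class_g = int((keep & in_class).sum())
        p_class = n_class_g / M_g
        M, n_class = M_g, n_class_g
    else:
        p_class = n_class / M
    logger.info("comparison %s: p_class = %.4g (%d / %d pairs)",
                comparison, p_class, n_class, M)

    p_a = np.ones(e.n_genes)
    nz = n_tot > 0
    p_a[nz] = binomial_score(m[nz], n_tot[nz], p_class)
    passes = n_tot >= min_n
    p_corr = np.full(e.n_genes, np.nan)
    if passes.any():
        p_corr[passes] = bh_fdr(p_a[passes])
    hit = passes & (p_corr < alpha)
    table = pd.DataFrame(
        {
            "gene": e.genes,
            "m": m.astype(int),
            "n": n_tot.astype(int),
            "M": M,
            "n_class": n_class,
            "p_class": p_class,
            "p_a": p_a,
            "p_corr": p_corr,
            "passes_min_n": passes,
            "hit": hit,
        }
    )
    return table.sort_values("p_a", kind="stable").reset_index(drop=True)


def ora(
    hits: set[str],
    background: set[str],
    annotations: pd.DataFrame,
    min_size: int = 5,
    max_size: int = 100,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list across categories.

    ``annotations`` has columns ``gene, category_id, category_name``.
    Category size is counted within the background; categories outside
    [min_size, max_size] are excluded.  Returns one row per tested
    category with the upper-tail p and BH-FDR.
    """
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise ArgumentError("hit list must be a subset of the background")
    for col in ("gene", "category_id", "category_name"):
        if col not in annotations.columns:
            raise DataError(f"annotation table missing column {col!r}")
    ann = annotations[annotations["gene"].isin(background)]
    if ann.empty:
        warnings.warn("no annotations overlap the background; empty ORA result")
        return pd.DataFrame(
            columns=["category_id", "category_name", "size", "overlap", "p", "p_fdr"]
        )
    N, K = len(background), len(hits)
    rows = []
    for (cid, cname), grp in ann.groupby(["category_id", "category_name"]):
        genes = set(grp["gene"])
        size = len(genes)
        if not (min_size <= size <= max_size):
            continue
        overlap = len(genes & hits)
        p = float(stats.hypergeom.sf(overlap - 1, N, size, K))
        rows.append({"category_id": cid, "category_name": cname,
                     "size": size, "overlap": overlap, "p": p})
    if not rows:
        warnings.warn("no categories within the size window; empty ORA result")
        return pd.DataFrame(
            columns=["category_id", "category_name", "size", "overlap", "p", "p_fdr"]
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)
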