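"""Correlated gene expression (CGE) between binary expression profiles.

Expression is a binary neurons x genes indicator matrix: a 1 records an
annotation that the gene is expressed in that neuron; a 0 means the gene
is *either* not expressed *or* there is no information (absence of
annotation is not evidence of absence).  Pairwise similarity between two
neurons' profiles is, by default, the mean square contingency (phi)
coefficient

    r_phi = (n11 n00 - n10 n01) / sqrt(n1. n0. n.1 n.0),

the binary analogue of the Pearson correlation, which is unbiased with
respect to annotation density (unlike the Jaccard index or Yule's Q, both
also provided).  A fourth measure, ``p_match``, is the probability of
observing at least the seen number of co-expressions under fixed
marginals (hypergeometric upper tail), reported as 1 - p so that larger
means more similar; it is a constructed stand-in with the documented
properties (probability of mutual expression, density-unbiased).

Bilateral homolog pairs have near-identical profiles and are masked out
of the pairwise CGE matrix by default so they cannot drive group
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, DataError

logger = logging.getLogger(__name__)

METHODS = ("r_phi", "jaccard", "yule_q", "p_match")

#: mask reason codes used in CGEMatrix.mask_reason
MASK_OK, MASK_SELF, MASK_BILATERAL, MASK_UNDEFINED = 0, 1, 2, 3


@dataclass
class ExpressionMatrix:
    """Binary neurons x genes expression indicator matrix."""

    neurons: list[str]
    genes: list[str]
    values: np.ndarray  # (n_neurons, n_genes) of {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.neurons), len(self.genes)):
            raise DataError("expression matrix shape does not match labels")
        if not np.isin(self.values, [0, 1]).all():
            raise DataError("expression entries must be binary 0/1")
        self.values = self.values.astype(np.uint8)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def load_expression(
    long_tsv: str | Path,
    neurons: list[str],
    drop_uncertain: bool = True,
) -> ExpressionMatrix:
    """Load long-format expression annotations (``neuron  gene  [evidence]``).

    Rows whose optional evidence column equals ``uncertain`` are ignored
    when ``drop_uncertain`` is set.  Genes are the sorted distinct genes
    with at least one retained annotation.
    """
    t = pd.read_csv(long_tsv, sep="\t", dtype=str, comment="#")
    if "neuron" not in t.columns or "gene" not in t.columns:
        raise DataError("expression table needs 'neuron' and 'gene' columns")
    if drop_uncertain and "evidence" in t.columns:
        t = t[t["evidence"].str.lower() != "uncertain"]
    t["neuron"] = t["neuron"].str.strip()
    known = set(neurons)
    bad = set(t["neuron"]) - known
    if bad:
        raise DataError(f"expression rows reference unknown neurons {sorted(bad)[:5]}")
    genes = sorted(t["gene"].unique())
    gi = {g: j for j, g in enumerate(genes)}
    ni = {n: i for i, n in enumerate(neurons)}
    X = np.zeros((len(neurons), len(genes)), dtype=np.uint8)
    X[t["neuron"].map(ni), t["gene"].map(gi)] = 1
    return ExpressionMatrix(list(neurons), genes, X)


def load_expression_dense(csv: str | Path) -> ExpressionMatrix:
    """Dense alternative: CSV with neurons as the index column, genes as columns."""
    t = pd.read_csv(csv, index_col=0)
    return ExpressionMatrix(list(t.index.astype(str)), list(t.columns.astype(str)),
                            t.to_numpy())


# ---------------------------------------------------------------------------
# contingency counts and similarity measures

@dataclass
class ContingencyCounts:
    """2x2 contingency counts between two equal-length binary vectors."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def L(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    # marginals: first index is x, second is y
    @property
    def n1x(self) -> int:
        return self.n11 + self.n10

    @property
    def n0x(self) -> int:
        return self.n01 + self.n00

    @property
    def nx1(self) -> int:
        return self.n11 + self.n01

    @property
    def nx0(self) -> int:
        return self.n10 + self.n00


def contingency(x: np.ndarray, y: np.ndarray) -> ContingencyCounts:
    """Exact 2x2 contingency counts of two binary vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ArgumentError("vectors must be 1-D and of equal length")
    if not (np.isin(x, [0, 1]).all() and np.isin(y, [0, 1]).all()):
        raise DataError("vectors must be binary 0/1")
    x = x.astype(bool)
    y = y.astype(bool)
    return ContingencyCounts(
        n11=int((x & y).sum()),
        n10=int((x & ~y).sum()),
        n01=int((~x & y).sum()),
        n00=int((~x & ~y).sum()),
    )


def _similarity_arrays(
    n11: np.ndarray, n10: np.ndarray, n01: np.ndarray, n00: np.ndarray, method: str
) -> np.ndarray:
    """Vectorized similarity; undefined cells become NaN."""
    n11 = np.asarray(n11, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n00 = np.asarray(n00, dtype=float)
    if method == "r_phi":
        denom2 = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (n11 * n00 - n10 * n01) / np.sqrt(denom2)
        return np.where(denom2 > 0, out, np.nan)
    if method == "jaccard":
        denom = n11 + n10 + n01
        with np.errstate(invalid="ignore", divide="ignore"):
            out = n11 / denom
        return np.where(denom > 0, out, np.nan)
    if method == "yule_q":
        denom = n11 * n00 + n10 * n01
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (n11 * n00 - n10 * n01) / denom
        return np.where(denom > 0, out, np.nan)
    if method == "p_match":
        L = n11 + n10 + n01 + n00
        # upper tail P(X >= n11) with X ~ Hypergeom(L, K=x-ones, n=y-ones)
        tail = stats.hypergeom.sf(n11 - 1, L.astype(int), (n11 + n10).astype(int),
                                  (n11 + n01).astype(int))
        return 1.0 - tail
    raise ArgumentError(f"unknown similarity method {method!r}")


def similarity(counts: ContingencyCounts, method: str = "r_phi") -> float:
    """Similarity of one pair from its contingency counts (NaN when undefined)."""
    return float(
        _similarity_arrays(
            np.array(counts.n11), np.array(counts.n10),
            np.array(counts.n01), np.array(counts.n00), method
        )
    )


# ---------------------------------------------------------------------------
# pairwise CGE matrix

@dataclass
class CGEMatrix:
    """Symmetric neuron-pair similarity matrix with an exclusion mask.

    Masked entries (diagonal, bilateral homolog pairs, undefined
    similarities) are NaN in ``values``; ``mask_reason`` explains why.
    """

    neurons: list[str]
    values: np.ndarray
    mask_reason: np.ndarray
    method: str
    bilateral_pairs: list[tuple[str, str]] = field(default_factory=list)

    def pair_values(self, pairs_i: np.ndarray, pairs_j: np.ndarray) -> np.ndarray:
        """Values for given index pairs; masked entries come back NaN."""
        return self.values[pairs_i, pairs_j]

    def unmasked_upper(self) -> np.ndarray:
        """All unmasked pair values (upper triangle)."""
        iu, ju = np.triu_indices(len(self.neurons), 1)
        v = self.values[iu, ju]
        return v[~np.isnan(v)]


def pairwise_counts(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs contingency counts via matrix products."""
    Xf = X.astype(np.float64)
    L = X.shape[1]
    n11 = Xf @ Xf.T
    ones = Xf.sum(axis=1)
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = L - n11 - n10 - n01
    return n11, n10, n01, n00


def cge_matrix(
    e: ExpressionMatrix,
    method: str = "r_phi",
    bilateral_pairs: list[tuple[str, str]] | None = None,
    mask_bilateral: bool = True,
) -> CGEMatrix:
    """Score all unordered neuron pairs; mask self and bilateral pairs.

    Undefined similarities (e.g. r_phi with a constant profile) are masked
    with their own reason code and propagate as missing — they are never
    imputed as 0.
    """
    if method not in METHODS:
        raise ArgumentError(f"unknown similarity method {method!r}")
    bilateral_pairs = bilateral_pairs or []
    idx = {n: i for i, n in enumerate(e.neurons)}
    for a, b in bilateral_pairs:
        if a not in idx or b not in idx:
            raise DataError(f"bilateral pair ({a!r}, {b!r}) references unknown neuron")
    n11, n10, n01, n00 = pairwise_counts(e.values)
    vals = _similarity_arrays(n11, n10, n01, n00, method)
    reason = np.full(vals.shape, MASK_OK, dtype=np.int8)
    reason[np.isnan(vals)] = MASK_UNDEFINED
    np.fill_diagonal(vals, np.nan)
    np.fill_diagonal(reason, MASK_SELF)
    if mask_bilateral:
        for a, b in bilateral_pairs:
            i, j = idx[a], idx[b]
            vals[i, j] = vals[j, i] = np.nan
            reason[i, j] = reason[j, i] = MASK_BILATERAL
    return CGEMatrix(list(e.neurons), vals, reason, method, list(bilateral_pairs))


def write_cge_tsv(m: CGEMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.neurons, columns=m.neurons)
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# annotation-density bias simulation

def bias_simulation(
    L: int = 948,
    density_grid: np.ndarray | None = None,
    n_pairs: int = 1000,
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean similarity between independent random binary vectors as a
    function of the two vectors' annotation densities.

    For each (density_a, density_b) cell, ``n_pairs`` pairs of vectors of
    length ``L`` are drawn with exactly ``round(L * density)`` ones placed
    uniformly at random, and the mean of each similarity measure is
    recorded.  A density-unbiased measure shows a flat grid centred on its
    independence value; a biased one trends with density.
    """
    if density_grid is None:
        density_grid = np.linspace(0.0, 0.15, 7)
    density_grid = np.asarray(density_grid, dtype=float)
    if (density_grid < 0).any() or (density_grid > 1).any():
        raise ArgumentError("densities must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for da in density_grid:
        ma = int(round(L * da))
        for db in density_grid:
            mb = int(round(L * db))
            X = np.zeros((n_pairs, L), dtype=bool)
            Y = np.zeros((n_pairs, L), dtype=bool)
            if ma:
                X[np.arange(n_pairs)[:, None],
                  _random_columns(rng, n_pairs, L, ma)] = True
            if mb:
                Y[np.arange(n_pairs)[:, None],
                  _random_columns(rng, n_pairs, L, mb)] = True
            n11 = (X & Y).sum(axis=1)
            n10 = (X & ~Y).sum(axis=1)
            n01 = (~X & Y).sum(axis=1)
            n00 = L - n11 - n10 - n01
            row = {"density_a": da, "density_b": db}
            for method in methods:
                v = _similarity_arrays(n11, n10, n01, n00, method)
                row[method] = float(np.nanmean(v)) if np.isfinite(v).any() else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def _random_columns(rng: np.random.Generator, n_rows: int, L: int, m: int) -> np.ndarray:
    """(n_rows, m) column indices, each row a uniform m-subset of range(L)."""
    # argpartition of uniform noise gives a uniform random subset per row
    u = rng.random((n_rows, L))
    return np.argpartition(u, m - 1, axis=1)[:, :m]
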