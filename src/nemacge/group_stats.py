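"""Pairwise-group comparisons and permutation nulls over CGE values.

All group statistics operate on unmasked CGE values of named sets of
unordered neuron pairs: edge-class medians across hub thresholds, driver
analyses (interneurons, modules, birth time, lineage, neurochemistry,
anatomy, command interneurons), and composition-matched permutation
nulls.  One-sided directions are always stated by the caller, never
inferred from the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cge import CGEMatrix
from .connectome import Connectome, classify_edges, degree_sequence, label_hubs
from .errors import ArgumentError, DataError

logger = logging.getLogger(__name__)


@dataclass
class PairSet:
    """Named set of unordered neuron pairs (integer index pairs)."""

    name: str
    pairs: np.ndarray  # (n, 2) integer indices

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if (self.pairs[:, 0] == self.pairs[:, 1]).any():
            raise DataError(f"pair set {self.name!r} contains self-pairs")
        lo = self.pairs.min(axis=1)
        hi = self.pairs.max(axis=1)
        self.pairs = np.column_stack([lo, hi])

    def keys(self) -> set[tuple[int, int]]:
        return set(map(tuple, self.pairs))

    def values(self, cge: CGEMatrix) -> np.ndarray:
        """Unmasked CGE values of this set (masked entries dropped)."""
        v = cge.values[self.pairs[:, 0], self.pairs[:, 1]]
        return v[~np.isnan(v)]


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p: float
    alternative: str
    n_a: int
    n_b: int
    median_a: float = float("nan")
    median_b: float = float("nan")
    undefined: bool = False
    extra: dict = field(default_factory=dict)

    def as_row(self, analysis: str, group_a: str, group_b: str) -> dict:
        return {
            "analysis": analysis, "group_a": group_a, "group_b": group_b,
            "n_a": self.n_a, "n_b": self.n_b,
            "median_a": self.median_a, "median_b": self.median_b,
            "test": self.test, "statistic": self.statistic, "p": self.p,
            "alternative": self.alternative,
        }


def _as_clean(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[~np.isnan(a)]


def ranksum(a, b, alternative: str = "two-sided") -> ComparisonResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of a vs b.

    Exact p for min(|a|, |b|) <= 8 without ties; otherwise the normal
    approximation with tie correction.  ``alternative='greater'`` tests
    whether a tends to exceed b.
    """
    a, b = _as_clean(a), _as_clean(b)
    if len(a) == 0 or len(b) == 0:
        raise ArgumentError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return ComparisonResult(
        test="ranksum", statistic=float(res.statistic), p=float(res.pvalue),
        alternative=alternative, n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        extra={"method": method},
    )


def welch_t(a, b, alternative: str = "two-sided") -> ComparisonResult:
    """Welch's t-test (Satterthwaite degrees of freedom)."""
    a, b = _as_clean(a), _as_clean(b)
    if len(a) < 2 or len(b) < 2:
        raise ArgumentError("Welch's t needs at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return ComparisonResult(
            test="welch", statistic=float("nan"), p=float("nan"),
            alternative=alternative, n_a=len(a), n_b=len(b),
            median_a=float(np.median(a)), median_b=float(np.median(b)),
            undefined=True,
        )
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return ComparisonResult(
        test="welch", statistic=float(res.statistic), p=float(res.pvalue),
        alternative=alternative, n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
    )


def spearman(x, y, alternative: str = "two-sided") -> ComparisonResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ArgumentError("spearman needs at least 3 paired values")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        return ComparisonResult(
            test="spearman", statistic=float("nan"), p=float("nan"),
            alternative=alternative, n_a=len(x), n_b=len(y), undefined=True,
        )
    res = stats.spearmanr(x, y, alternative=alternative)
    return ComparisonResult(
        test="spearman", statistic=float(res.statistic), p=float(res.pvalue),
        alternative=alternative, n_a=len(x), n_b=len(y),
    )


TESTS = {"ranksum": ranksum, "welch": welch_t}


def compare_pair_sets(
    cge: CGEMatrix,
    set_a: PairSet,
    set_b: PairSet,
    test: str = "ranksum",
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Run a two-sample test on the CGE values of two disjoint pair sets."""
    if test not in TESTS:
        raise ArgumentError(f"unknown test {test!r}")
    if set_a.keys() & set_b.keys():
        raise ArgumentError(f"pair sets {set_a.name!r} and {set_b.name!r} overlap")
    return TESTS[test](set_a.values(cge), set_b.values(cge), alternative=alternative)


def edge_class_cge_curve(
    cge: CGEMatrix,
    c: Connectome,
    k_range,
    reference: str = "other_connected",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median CGE per edge class across hub thresholds, with one-sided
    rank-sum significance flags.

    For each k and each class of directed edge (rich, feed-in, feed-out,
    peripheral; gap junctions expanded to both directions) the median
    unmasked CGE over that class's connections is compared one-sidedly
    (greater) against either all other connected pairs
    (``reference='other_connected'``) or all other pairs (``'all'``).
    """
    if cge.neurons != c.neurons:
        raise DataError("CGE and connectome neuron universes differ")
    deg = degree_sequence(c)
    iu, ju = np.triu_indices(c.n_neurons, 1)
    all_vals = cge.values[iu, ju]
    P = c.pair_matrix()
    conn_mask = P[iu, ju]
    rows = []
    for k in k_range:
        hub = label_hubs(deg, int(k))
        edges = classify_edges(c, hub)
        idx = {n: i for i, n in enumerate(c.neurons)}
        ei = edges["pre"].map(idx).to_numpy()
        ej = edges["post"].map(idx).to_numpy()
        ev = cge.values[ei, ej]
        for cls in ("rich", "feed-in", "feed-out", "peripheral"):
            sel = (edges["edge_class"] == cls).to_numpy()
            vals = ev[sel]
            vals = vals[~np.isnan(vals)]
            if reference == "other_connected":
                other = ev[~sel]
            elif reference == "all":
                other = np.concatenate([ev[~sel], all_vals[~conn_mask]])
            else:
                raise ArgumentError(f"unknown reference {reference!r}")
            other = other[~np.isnan(other)]
            row = {"k": int(k), "edge_class": cls, "n": int(len(vals))}
            if len(vals) == 0:
                row.update(median=np.nan, p=np.nan, significant=False)
            elif len(other) == 0 or (len(np.unique(np.concatenate([vals, other]))) == 1):
                row.update(median=float(np.median(vals)), p=np.nan, significant=False)
            else:
                r = ranksum(vals, other, alternative="greater")
                row.update(median=r.median_a, p=r.p, significant=bool(r.p < alpha))
            rows.append(row)
    return pd.DataFrame(rows)


def composition_matched_null(
    neurons: pd.DataFrame,
    target_set: list[str],
    cge: CGEMatrix,
    match_on: str | None = "neurotransmitter",
    n_perm: int = 100_000,
    seed: int = 0,
    composition: dict[str, int] | None = None,
) -> ComparisonResult:
    """Permutation test of a neuron set's median pairwise CGE against
    attribute-composition-matched random sets.

    Random sets reproduce the target set's composition over the levels of
    ``match_on`` (e.g. 13 cholinergic + 2 glutamatergic + 1 unknown, or 13
    head + 3 tail neurons); ``match_on=None`` degenerates to simple random
    subsets of the same size.  ``composition`` overrides the target-derived
    level counts (a level requiring more neurons than exist is a data
    error).  The p-value is the add-one right tail
    (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ArgumentError("n_perm must be >= 1")
    names = list(cge.neurons)
    idx = {n: i for i, n in enumerate(names)}
    for n_ in target_set:
        if n_ not in idx:
            raise DataError(f"unknown neuron {n_!r} in target set")
    t = neurons.set_index("neuron")
    target_idx = np.array([idx[n_] for n_ in target_set])
    size = len(target_idx)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if match_on is None:
        pools = [np.arange(len(names))]
        counts = [size]
    else:
        attr = t.loc[names, match_on].fillna("unknown").astype(str).to_numpy()
        levels, level_of = np.unique(attr, return_inverse=True)
        target_levels = attr[target_idx]
        if composition is not None:
            need_of = dict(composition)
        else:
            need_of = {lev: int((target_levels == lev).sum()) for lev in levels}
        unknown_levels = set(need_of) - set(levels)
        if unknown_levels:
            lev = sorted(unknown_levels)[0]
            raise DataError(
                f"composition unsatisfiable: no neurons with {match_on}={lev!r}")
        pools, counts = [], []
        for li, lev in enumerate(levels):
            need = int(need_of.get(lev, 0))
            if need == 0:
                continue
            pool = np.nonzero(level_of == li)[0]
            if len(pool) < need:
                raise DataError(
                    f"composition unsatisfiable: need {need} neurons of "
                    f"{match_on}={lev!r}, only {len(pool)} available"
                )
            pools.append(pool)
            counts.append(need)

    pi, pj = np.triu_indices(size, 1)

    def median_cge(members: np.ndarray) -> float:
        v = cge.values[members[pi], members[pj]]
        v = v[~np.isnan(v)]
        return float(np.median(v)) if len(v) else float("nan")

    observed = median_cge(target_idx)
    null = np.empty(n_perm)
    draw = np.empty(size, dtype=np.int64)
    for p in range(n_perm):
        pos = 0
        for pool, need in zip(pools, counts):
            draw[pos:pos + need] = rng.choice(pool, size=need, replace=False)
            pos += need
        null[p] = median_cge(draw)
    exceed = int(np.nansum(null >= observed))
    pval = (1.0 + exceed) / (n_perm + 1.0)
    return ComparisonResult(
        test="permutation", statistic=observed, p=pval, alternative="greater",
        n_a=size, n_b=n_perm, median_a=observed,
        median_b=float(np.nanmedian(null)),
        extra={"match_on": match_on},
    )
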