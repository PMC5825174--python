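"""Connectome container, loaders, degrees, hub labels and edge classes.

The network is a combined directed binary graph over named neurons:
chemical synapses are directed edges, electrical gap junctions are stored
once per unordered pair and treated as bidirectional connections wherever
a directed view is needed.  Synapse counts are retained as per-edge weight
metadata but the analysis operates on the binarized graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError

logger = logging.getLogger(__name__)

#: Edge classes by hub status of (source, target).
EDGE_CLASSES = ("rich", "feed-in", "feed-out", "peripheral")

NEURON_COLUMNS = [
    "neuron",
    "x_um",
    "y_um",
    "region",
    "types",
    "neurotransmitter",
    "birth_time_min",
    "bilateral_partner",
    "command_interneuron",
]


@dataclass
class Connectome:
    """Directed binary connectome with chemical and gap-junction edges.

    Parameters
    ----------
    neurons :
        Ordered list of neuron names (canonical identity strings; matching
        is case-sensitive after whitespace trimming).
    chem :
        DataFrame with columns ``pre, post, weight`` — one row per ordered
        pair connected by at least one chemical synapse.
    gap :
        DataFrame with columns ``a, b, weight`` — one row per unordered
        pair connected by at least one gap junction (stored with
        ``index(a) < index(b)``).
    """

    neurons: list[str]
    chem: pd.DataFrame
    gap: pd.DataFrame
    neuron_table: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._index = {name: i for i, name in enumerate(self.neurons)}
        if len(self._index) != len(self.neurons):
            raise DataError("duplicate neuron names in neuron list")
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        idx = self._index
        for col_pair, df, kind in (
            (("pre", "post"), self.chem, "chemical"),
            (("a", "b"), self.gap, "gap"),
        ):
            u, v = col_pair
            for name in pd.concat([df[u], df[v]]).unique():
                if name not in idx:
                    raise DataError(f"{kind} edge references unknown neuron {name!r}")
            if (df[u] == df[v]).any():
                bad = df.loc[df[u] == df[v], u].iloc[0]
                raise DataError(f"self-edge on neuron {bad!r} not allowed")
        # canonicalize gap pair order and check uniqueness
        if len(self.gap):
            a_i = self.gap["a"].map(idx).to_numpy()
            b_i = self.gap["b"].map(idx).to_numpy()
            flip = a_i > b_i
            if flip.any():
                ga = self.gap["a"].to_numpy().copy()
                gb = self.gap["b"].to_numpy().copy()
                ga[flip], gb[flip] = gb[flip], ga[flip].copy()
                self.gap = self.gap.assign(a=ga, b=gb)
            if self.gap.duplicated(subset=["a", "b"]).any():
                raise DataError("duplicate gap record for an unordered pair")
        if self.chem.duplicated(subset=["pre", "post"]).any():
            raise DataError("duplicate chemical record for an ordered pair")
        if (self.chem["weight"] < 1).any() or (len(self.gap) and (self.gap["weight"] < 1).any()):
            raise DataError("edge weights must be >= 1")

    # -- basic properties -------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise DataError(f"unknown neuron {name!r}") from None

    def chem_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Chemical edges as (pre, post) integer index arrays."""
        if not len(self.chem):
            z = np.empty(0, dtype=np.int64)
            return z, z.copy()
        return (
            self.chem["pre"].map(self._index).to_numpy(dtype=np.int64),
            self.chem["post"].map(self._index).to_numpy(dtype=np.int64),
        )

    def gap_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Gap edges as (a, b) integer index arrays (a < b)."""
        if not len(self.gap):
            z = np.empty(0, dtype=np.int64)
            return z, z.copy()
        return (
            self.gap["a"].map(self._index).to_numpy(dtype=np.int64),
            self.gap["b"].map(self._index).to_numpy(dtype=np.int64),
        )

    def directed_edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """All directed edges: chemical as-is, each gap expanded to both directions.

        A pair linked by both mechanisms contributes its chemical edge(s)
        and both gap directions (each mechanism counts in degrees).
        """
        cp, cq = self.chem_indices()
        ga, gb = self.gap_indices()
        src = np.concatenate([cp, ga, gb])
        dst = np.concatenate([cq, gb, ga])
        return src, dst

    def adjacency(self) -> np.ndarray:
        """Binary directed adjacency (bool), gap junctions bidirectional."""
        n = self.n_neurons
        A = np.zeros((n, n), dtype=bool)
        src, dst = self.directed_edge_arrays()
        A[src, dst] = True
        return A

    def pair_matrix(self) -> np.ndarray:
        """Symmetric bool matrix: True where an unordered pair is connected
        by at least one chemical or electrical synapse."""
        A = self.adjacency()
        return A | A.T

    def connected_pairs(self) -> set[tuple[int, int]]:
        """Set of connected unordered pairs as (i, j) with i < j."""
        P = self.pair_matrix()
        iu, ju = np.nonzero(np.triu(P, 1))
        return set(zip(iu.tolist(), ju.tolist()))

    def n_connected_pairs(self) -> int:
        return int(np.triu(self.pair_matrix(), 1).sum())

    def positions(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates in micrometres, from the neuron table."""
        if self.neuron_table is None:
            raise DataError("connectome carries no neuron table with positions")
        t = self.neuron_table.set_index("neuron").loc[self.neurons]
        pos = t[["x_um", "y_um"]].to_numpy(dtype=float)
        if np.isnan(pos).any():
            missing = [self.neurons[i] for i in np.nonzero(np.isnan(pos).any(axis=1))[0]]
            raise DataError(f"neurons lacking positions: {missing}")
        return pos


# ---------------------------------------------------------------------------
# loaders

def load_neuron_table(neuron_tsv: str | Path) -> pd.DataFrame:
    """Read a neuron metadata TSV.

    Expected columns: ``neuron x_um y_um region types neurotransmitter
    birth_time_min bilateral_partner command_interneuron``.  ``types`` is a
    semicolon-separated multi-label list.  An optional ``mirror_from``
    column names a contralateral partner whose coordinates are copied when
    a neuron's own coordinates are missing.
    """
    t = pd.read_csv(neuron_tsv, sep="\t", dtype={"neuron": str}, comment="#")
    missing = [c for c in NEURON_COLUMNS if c not in t.columns]
    if missing:
        raise DataError(f"neuron table missing columns {missing}")
    t["neuron"] = t["neuron"].str.strip()
    if t["neuron"].duplicated().any():
        dup = t.loc[t["neuron"].duplicated(), "neuron"].iloc[0]
        raise DataError(f"duplicate neuron row {dup!r}")
    if "mirror_from" in t.columns:
        coord_missing = t["x_um"].isna() | t["y_um"].isna()
        by_name = t.set_index("neuron")
        for i in t.index[coord_missing]:
            src = t.at[i, "mirror_from"]
            if isinstance(src, str) and src.strip() in by_name.index:
                t.at[i, "x_um"] = by_name.at[src.strip(), "x_um"]
                t.at[i, "y_um"] = by_name.at[src.strip(), "y_um"]
    bad_region = ~t["region"].isin(["head", "body", "tail"])
    if bad_region.any():
        raise DataError(
            f"invalid region value {t.loc[bad_region, 'region'].iloc[0]!r} "
            f"for neuron {t.loc[bad_region, 'neuron'].iloc[0]!r}"
        )
    return t


def load_connectome(edge_tsv: str | Path, neuron_tsv: str | Path) -> Connectome:
    """Load a connectome from edge and neuron TSV files.

    Edge TSV columns: ``pre post type weight`` with ``type`` in
    ``{chem, gap}``.  Logs counts of chemical records, gap records and
    distinct connected unordered pairs.
    """
    neuron_table = load_neuron_table(neuron_tsv)
    neurons = neuron_table["neuron"].tolist()
    known = set(neurons)

    e = pd.read_csv(edge_tsv, sep="\t", dtype={"pre": str, "post": str}, comment="#")
    for col in ("pre", "post", "type", "weight"):
        if col not in e.columns:
            raise DataError(f"edge table missing column {col!r}")
    e["pre"] = e["pre"].str.strip()
    e["post"] = e["post"].str.strip()
    for row_i, row in enumerate(e.itertuples(index=False)):
        for name in (row.pre, row.post):
            if name not in known:
                raise DataError(f"edge row {row_i}: unknown neuron {name!r}")
        if row.type not in ("chem", "gap"):
            raise DataError(f"edge row {row_i}: unknown edge type {row.type!r}")
    # duplicate (pre, post, type) is a data error; gap duplicates are
    # checked on the unordered pair
    chem = e[e["type"] == "chem"][["pre", "post", "weight"]].reset_index(drop=True)
    if chem.duplicated(subset=["pre", "post"]).any():
        dup = chem[chem.duplicated(subset=["pre", "post"])].iloc[0]
        raise DataError(f"duplicate chemical edge {dup['pre']}->{dup['post']}")
    gap = (
        e[e["type"] == "gap"][["pre", "post", "weight"]]
        .rename(columns={"pre": "a", "post": "b"})
        .reset_index(drop=True)
    )
    c = Connectome(neurons=neurons, chem=chem, gap=gap, neuron_table=neuron_table)
    logger.info(
        "loaded connectome: %d neurons, %d chemical records, %d gap records, "
        "%d directed connections, %d connected unordered pairs",
        c.n_neurons,
        len(chem),
        len(gap),
        len(chem) + 2 * len(gap),
        c.n_connected_pairs(),
    )
    return c


# ---------------------------------------------------------------------------
# degrees and edge classes

def degree_sequence(c: Connectome) -> pd.DataFrame:
    """Per-neuron in/out/total degree, gap junctions counted bidirectionally.

    A pair linked by both a chemical and a gap record contributes once per
    mechanism, so the total degree k = k_in + k_out sums mechanisms.
    """
    n = c.n_neurons
    k_in = np.zeros(n, dtype=np.int64)
    k_out = np.zeros(n, dtype=np.int64)
    src, dst = c.directed_edge_arrays()
    np.add.at(k_out, src, 1)
    np.add.at(k_in, dst, 1)
    return pd.DataFrame(
        {"neuron": c.neurons, "k_in": k_in, "k_out": k_out, "k": k_in + k_out}
    )


def label_hubs(degrees: pd.DataFrame, k_threshold: int) -> pd.Series:
    """Boolean hub labels: hub iff total degree strictly exceeds ``k_threshold``."""
    if k_threshold < -1:
        raise ArgumentError("k_threshold must be >= -1")
    return pd.Series(
        degrees["k"].to_numpy() > k_threshold, index=degrees["neuron"], name="is_hub"
    )


def classify_edges(c: Connectome, is_hub: pd.Series) -> pd.DataFrame:
    """Classify every directed edge (gap expanded to both directions) as
    rich / feed-in / feed-out / peripheral by the hub status of its
    source and target."""
    missing = [n for n in c.neurons if n not in is_hub.index]
    if missing:
        raise DataError(f"hub labels missing for neurons {missing[:5]}")
    hub = is_hub.reindex(c.neurons).to_numpy(dtype=bool)
    src, dst = c.directed_edge_arrays()
    cls = np.where(
        hub[src] & hub[dst],
        "rich",
        np.where(hub[dst], "feed-in", np.where(hub[src], "feed-out", "peripheral")),
    )
    names = np.asarray(c.neurons, dtype=object)
    return pd.DataFrame({"pre": names[src], "post": names[dst], "edge_class": cls})


def edge_class_counts(edge_classes: pd.DataFrame) -> dict[str, int]:
    counts = edge_classes["edge_class"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in EDGE_CLASSES}


def pair_classes(c: Connectome, is_hub: pd.Series) -> pd.DataFrame:
    """Unordered connected pairs with their class.

    Pair classes collapse direction: a pair is ``rich`` when both
    endpoints are hubs, ``feeder`` when exactly one is, ``peripheral``
    when neither is.  Used where expression similarity (a neuron-level,
    undirected quantity) is compared across connection types.
    """
    hub = is_hub.reindex(c.neurons).to_numpy(dtype=bool)
    P = c.pair_matrix()
    iu, ju = np.nonzero(np.triu(P, 1))
    n_hubs = hub[iu].astype(int) + hub[ju].astype(int)
    cls = np.where(n_hubs == 2, "rich", np.where(n_hubs == 1, "feeder", "peripheral"))
    names = np.asarray(c.neurons, dtype=object)
    return pd.DataFrame({"a": names[iu], "b": names[ju], "i": iu, "j": ju, "pair_class": cls})
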