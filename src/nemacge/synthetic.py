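"""Synthetic connectome + expression datasets with planted structure.

The generator emulates the statistical shape of the nematode somatic
nervous system and its binary expression annotations: three spatial
clusters (a dense head, a sparse elongated body of mostly motor neurons,
a dense tail), a directed binary graph whose connection probability
decays exponentially with Euclidean distance, a planted set of densely
interconnected hub neurons drawn from the head and tail, a sparse binary
neurons x genes expression matrix with a planted set of genes
co-expressed in hubs, and bilateral homolog pairs whose expression
profiles are near-identical copies.

A single global seed is expanded into independent per-generator streams
(neurons, hubs, connectome, expression, lineage), so e.g. changing the
number of genes does not perturb the connectome draw.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cge import ExpressionMatrix
from .connectome import Connectome
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

_STREAMS = {"neurons": 0, "hubs": 1, "connectome": 2, "expression": 3, "lineage": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SynthConfig:
    """Parameters of the synthetic dataset generator.

    Spatial layout is 2-D in micrometres: the head cluster fits within
    ``head_extent_um`` (diameter), the tail within ``tail_extent_um``, and
    body neurons spread over ``body_span_um`` along the
    anterior-posterior axis.  Connection probability for an ordered pair
    at distance d is ``A_conn * exp(-lambda_conn * d) + B_conn``; on top
    of this, each unordered pair of planted hubs is connected
    (reciprocally) with probability ``hub_density``.  Expression entries
    are Bernoulli(``p_base``) except planted hub genes in hub neurons
    (Bernoulli(``p_hub``)); bilateral partners receive their partner's
    row with independent entry flips (probability ``flip_prob``).
    """

    n_head: int = 147
    n_body: int = 105
    n_tail: int = 27
    head_extent_um: float = 130.0
    tail_extent_um: float = 90.0
    body_span_um: float = 1020.0
    lambda_conn: float = 0.012  # 1/um
    A_conn: float = 0.15
    B_conn: float = 0.005
    n_hubs: int = 16
    hub_density: float = 0.8
    gap_fraction: float = 0.2
    n_genes: int = 948
    p_base: float = 0.05
    n_hub_genes: int = 20
    p_hub: float = 0.9
    n_bilateral_pairs: int = 92
    flip_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_head, self.n_body, self.n_tail, self.n_hubs,
                  self.n_genes, self.n_hub_genes, self.n_bilateral_pairs)
        if any(x < 0 for x in counts):
            raise ConfigurationError("counts must be >= 0")
        if any(x < 0 for x in (self.head_extent_um, self.tail_extent_um,
                               self.body_span_um)):
            raise ConfigurationError("extents must be >= 0")
        for name in ("A_conn", "B_conn", "hub_density", "gap_fraction",
                     "p_base", "p_hub", "flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.lambda_conn < 0:
            raise ConfigurationError("lambda_conn must be >= 0")
        if self.n_hubs > self.n_head + self.n_tail:
            raise ConfigurationError("n_hubs must not exceed n_head + n_tail")
        if self.n_hub_genes > self.n_genes:
            raise ConfigurationError("n_hub_genes must not exceed n_genes")
        if self.n_bilateral_pairs * 2 > self.n_head + self.n_body + self.n_tail:
            raise ConfigurationError("too many bilateral pairs for the neuron count")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


_TYPE_PROBS = {
    # per region: (sensory, motor, interneuron) marginal probabilities;
    # multi-label allowed, at least one label forced
    "head": (0.35, 0.15, 0.55),
    "body": (0.12, 0.78, 0.18),
    "tail": (0.35, 0.25, 0.45),
}
_NEUROTRANSMITTERS = (
    ("ACh", 0.52), ("Glu", 0.25), ("GABA", 0.10), ("unknown", 0.13),
)


def generate_neurons(config: SynthConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the neuron metadata table.

    Head/tail neurons fall within discs of the configured extents around
    their cluster centroids; body neurons spread along the A-P axis over
    ``body_span_um``.  Functional types are multi-label (the body is
    predominantly motor), birth times are bimodal (early < 550 min, late
    > 1200 min, nothing in between), and ``n_bilateral_pairs`` disjoint
    same-region pairs are linked as bilateral homologs at near-identical
    positions.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "neurons")
    n = config.n_head + config.n_body + config.n_tail
    regions = (["head"] * config.n_head + ["body"] * config.n_body
               + ["tail"] * config.n_tail)
    names = (
        [f"HN{i:03d}" for i in range(config.n_head)]
        + [f"BN{i:03d}" for i in range(config.n_body)]
        + [f"TN{i:03d}" for i in range(config.n_tail)]
    )
    margin = 150.0
    head_c = np.array([0.0, 0.0])
    tail_c = np.array([margin + config.body_span_um + margin, 0.0])

    def disc(center, diameter, m):
        r = (diameter / 2.0) * np.sqrt(rng.random(m))
        theta = rng.random(m) * 2 * np.pi
        return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    pos = np.empty((n, 2))
    pos[: config.n_head] = disc(head_c, config.head_extent_um, config.n_head)
    body_x = margin + rng.random(config.n_body) * config.body_span_um
    body_y = rng.normal(0, 10, config.n_body)
    pos[config.n_head: config.n_head + config.n_body] = np.column_stack([body_x, body_y])
    pos[config.n_head + config.n_body:] = disc(
        tail_c, config.tail_extent_um, config.n_tail)

    types = []
    for reg in regions:
        ps, pm, pi = _TYPE_PROBS[reg]
        labels = [t for t, p in zip(("sensory", "motor", "interneuron"),
                                    (ps, pm, pi)) if rng.random() < p]
        if not labels:
            labels = [("sensory", "motor", "interneuron")[rng.integers(3)]]
        types.append(";".join(labels))

    nt_names = [t for t, _ in _NEUROTRANSMITTERS]
    nt_p = np.array([p for _, p in _NEUROTRANSMITTERS])
    neurotransmitter = rng.choice(nt_names, size=n, p=nt_p / nt_p.sum())

    early = rng.random(n) < 0.7
    birth = np.where(early, rng.uniform(250, 550, n), rng.uniform(1200, 3000, n))

    partner = np.array([""] * n, dtype=object)
    # pair within regions, preferring the head (where most real homolog
    # pairs live), without reusing a neuron
    order = np.concatenate([
        rng.permutation(np.nonzero(np.asarray(regions) == reg)[0])
        for reg in ("head", "tail", "body")
    ])
    paired = 0
    used = np.zeros(n, dtype=bool)
    by_region: dict[str, list[int]] = {"head": [], "body": [], "tail": []}
    for i in order:
        by_region[regions[i]].append(i)
    for reg in ("head", "tail", "body"):
        pool = by_region[reg]
        for a, b in zip(pool[0::2], pool[1::2]):
            if paired >= config.n_bilateral_pairs:
                break
            partner[a], partner[b] = names[b], names[a]
            used[a] = used[b] = True
            # homologs sit at (near) mirrored positions: same x, same |y|
            pos[b] = pos[a] + rng.normal(0, 1.0, 2)
            paired += 1
    if paired < config.n_bilateral_pairs:
        raise ConfigurationError(
            f"could only form {paired} same-region bilateral pairs")

    return pd.DataFrame(
        {
            "neuron": names,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "region": regions,
            "types": types,
            "neurotransmitter": neurotransmitter,
            "birth_time_min": birth,
            "bilateral_partner": partner,
            "command_interneuron": 0,
        }
    )


def select_hubs(neurons: pd.DataFrame, config: SynthConfig,
                seed: int | None = None) -> list[str]:
    """Deterministically sample the planted hub set from head and tail
    neurons, proportionally to cluster size."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "hubs")
    head = neurons.loc[neurons["region"] == "head", "neuron"].to_numpy()
    tail = neurons.loc[neurons["region"] == "tail", "neuron"].to_numpy()
    if config.n_hubs == 0:
        return []
    n_tail_hubs = int(round(config.n_hubs * len(tail) / max(len(head) + len(tail), 1)))
    n_tail_hubs = min(n_tail_hubs, len(tail))
    n_head_hubs = config.n_hubs - n_tail_hubs
    hubs = list(rng.choice(head, size=n_head_hubs, replace=False))
    if n_tail_hubs:
        hubs += list(rng.choice(tail, size=n_tail_hubs, replace=False))
    return hubs


def generate_connectome(
    neurons: pd.DataFrame,
    config: SynthConfig,
    hubs: list[str] | None = None,
    seed: int | None = None,
) -> tuple[Connectome, list[str]]:
    """Generate the directed connectome; returns it with the hub list.

    Every ordered non-self pair is connected independently with
    probability A exp(-lambda d) + B; planted hub pairs are additionally
    connected reciprocally with probability ``hub_density``.  A fraction
    ``gap_fraction`` of connected unordered pairs is stored as a single
    undirected gap record; the remaining directed edges are chemical.
    """
    seed = config.seed if seed is None else seed
    if neurons[["x_um", "y_um"]].isna().any().any():
        missing = neurons.loc[neurons[["x_um", "y_um"]].isna().any(axis=1),
                              "neuron"].tolist()
        raise DataError(f"neurons lacking positions: {missing}")
    if hubs is None:
        hubs = select_hubs(neurons, config, seed=seed)
    rng = _rng(seed, "connectome")
    names = neurons["neuron"].tolist()
    idx = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    pos = neurons[["x_um", "y_um"]].to_numpy(dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    p = np.clip(config.A_conn * np.exp(-config.lambda_conn * d) + config.B_conn, 0, 1)
    C = rng.random((n, n)) < p
    np.fill_diagonal(C, False)
    hub_idx = np.array([idx[h] for h in hubs], dtype=int)
    for ai in range(len(hub_idx)):
        for bi in range(ai + 1, len(hub_idx)):
            if rng.random() < config.hub_density:
                a, b = hub_idx[ai], hub_idx[bi]
                C[a, b] = C[b, a] = True

    U = C | C.T
    iu, ju = np.nonzero(np.triu(U, 1))
    is_gap = rng.random(len(iu)) < config.gap_fraction
    weights = rng.geometric(0.5, size=len(iu))
    name_arr = np.asarray(names, dtype=object)
    gap = pd.DataFrame({
        "a": name_arr[iu[is_gap]],
        "b": name_arr[ju[is_gap]],
        "weight": weights[is_gap],
    })
    chem_rows = {"pre": [], "post": [], "weight": []}
    keep = ~is_gap
    for a, b, w in zip(iu[keep], ju[keep], weights[keep]):
        if C[a, b]:
            chem_rows["pre"].append(names[a])
            chem_rows["post"].append(names[b])
            chem_rows["weight"].append(int(w))
        if C[b, a]:
            chem_rows["pre"].append(names[b])
            chem_rows["post"].append(names[a])
            chem_rows["weight"].append(int(w))
    chem = pd.DataFrame(chem_rows)
    if not len(chem):
        chem = pd.DataFrame({"pre": [], "post": [], "weight": []})
    c = Connectome(names, chem, gap, neuron_table=neurons)
    logger.info("synthetic connectome: %d neurons, %d chem records, %d gap records",
                n, len(chem), len(gap))
    return c, list(hubs)


def planted_gene_names(config: SynthConfig) -> list[str]:
    return [f"hubgene{i:02d}" for i in range(config.n_hub_genes)]


def generate_expression(
    neurons: pd.DataFrame,
    hubs: set[str] | list[str],
    config: SynthConfig,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Generate the binary expression matrix with planted hub genes.

    Entries are Bernoulli(p_base); planted genes (named ``hubgeneNN``) are
    Bernoulli(p_hub) in hub neurons.  Each bilateral pair's second member
    then receives a copy of its partner's row with independent flips
    (probability ``flip_prob``).
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "expression")
    names = neurons["neuron"].tolist()
    idx = {nm: i for i, nm in enumerate(names)}
    for h in hubs:
        if h not in idx:
            raise DataError(f"unknown hub id {h!r}")
    n = len(names)
    genes = planted_gene_names(config) + [
        f"gene{i:04d}" for i in range(config.n_genes - config.n_hub_genes)
    ]
    X = (rng.random((n, config.n_genes)) < config.p_base).astype(np.uint8)
    if hubs and config.n_hub_genes:
        hub_rows = np.array([idx[h] for h in hubs])
        X[np.ix_(hub_rows, np.arange(config.n_hub_genes))] = (
            rng.random((len(hub_rows), config.n_hub_genes)) < config.p_hub
        ).astype(np.uint8)
    # bilateral partners: copy with symmetric flips.  The hub member of a
    # pair (if exactly one) serves as template so planted hub expression
    # survives and is shared with the homolog, as in real mirror pairs.
    hub_set = set(hubs)
    done = set()
    partner = neurons["bilateral_partner"].to_numpy()
    for i, pname in enumerate(partner):
        if not isinstance(pname, str) or not pname or i in done:
            continue
        j = idx[pname]
        done.update((i, j))
        if names[j] in hub_set and names[i] not in hub_set:
            i, j = j, i
        flips = rng.random(config.n_genes) < config.flip_prob
        X[j] = np.where(flips, 1 - X[i], X[i])
    return ExpressionMatrix(names, genes, X)


def generate_lineage(neurons: pd.DataFrame, config: SynthConfig,
                     seed: int | None = None) -> pd.DataFrame:
    """Pairwise lineage distances drawn as small random integers.

    Real developmental lineage trees are not emulated; this is plumbing so
    lineage-based analyses can run end to end on synthetic data.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "lineage")
    n = len(neurons)
    upper = rng.integers(2, 15, size=(n, n))
    m = np.triu(upper, 1)
    m = m + m.T
    return pd.DataFrame(m, index=neurons["neuron"], columns=neurons["neuron"])


@dataclass
class SynthDataset:
    """Bundle of all synthetic inputs for one seed."""

    config: SynthConfig
    neurons: pd.DataFrame
    connectome: Connectome
    hubs: list[str]
    expression: ExpressionMatrix
    lineage: pd.DataFrame
    bilateral_pairs: list[tuple[str, str]] = field(default_factory=list)


def simulate(config: SynthConfig, seed: int | None = None) -> SynthDataset:
    """Run all generators with independent streams from one seed.

    Ten of the planted hubs (or all, if fewer) are flagged as command
    interneurons in the neuron table.
    """
    seed = config.seed if seed is None else seed
    neurons = generate_neurons(config, seed=seed)
    conn, hubs = generate_connectome(neurons, config, seed=seed)
    expr = generate_expression(neurons, hubs, config, seed=seed)
    lineage = generate_lineage(neurons, config, seed=seed)
    command = hubs[: min(10, len(hubs))]
    neurons.loc[neurons["neuron"].isin(command), "command_interneuron"] = 1
    pairs = []
    seen = set()
    for _, row in neurons.iterrows():
        p = row["bilateral_partner"]
        if isinstance(p, str) and p and (p, row["neuron"]) not in seen:
            pairs.append((row["neuron"], p))
            seen.add((row["neuron"], p))
    return SynthDataset(config, neurons, conn, hubs, expr, lineage, pairs)


def write_dataset(ds: SynthDataset, outdir: str | Path) -> None:
    """Write the bundle in the TSV formats the loaders consume, plus a
    JSON sidecar with the config and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.neurons.to_csv(outdir / "neurons.tsv", sep="\t", index=False)
    edges = pd.concat([
        ds.connectome.chem.assign(type="chem").rename(columns={})[
            ["pre", "post", "type", "weight"]],
        ds.connectome.gap.rename(columns={"a": "pre", "b": "post"}).assign(
            type="gap")[["pre", "post", "type", "weight"]],
    ])
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    ii, jj = np.nonzero(ds.expression.values)
    pd.DataFrame({
        "neuron": np.asarray(ds.expression.neurons, dtype=object)[ii],
        "gene": np.asarray(ds.expression.genes, dtype=object)[jj],
    }).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    ds.lineage.to_csv(outdir / "lineage.csv")
    sidecar = {"config": dataclasses.asdict(ds.config), "hubs": ds.hubs}
    (outdir / "simulation.json").write_text(json.dumps(sidecar, indent=2))
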