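"""End-to-end analysis pipeline: load or simulate, then run every stage.

Stage order: load/simulate -> spatial curves -> rich club -> modularity ->
CGE matrix -> edge-class comparisons -> driver analyses -> gene scoring ->
ORA.  All stage tables are written as TSV/JSON under the output
directory together with a machine-readable summary and a log recording
the configuration hash and seeds.  Re-running the same configuration
reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cge import CGEMatrix, cge_matrix, load_expression
from .connectome import (Connectome, degree_sequence, label_hubs,
                         load_connectome, pair_classes)
from .errors import ConfigurationError
from .gene_scoring import ora, score_genes
from .group_stats import (PairSet, compare_pair_sets, edge_class_cge_curve,
                          spearman)
from .modularity import louvain_consensus
from .richclub import normalized_rich_club, significant_regime
from .spatial import (cge_distance_curve, connection_probability_curve,
                      pairwise_distances)
from .synthetic import SynthConfig, SynthDataset, planted_gene_names, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; either file inputs or a simulate block.

    Defaults mirror the study's printed choices: hub threshold k = 44,
    1000 rewiring nulls at 50 swaps per edge, 10 distance bins for
    connection probability and 7 for CGE, n >= 10 gene filter and hit
    threshold 1e-4.
    """

    edge_tsv: str | None = None
    neuron_tsv: str | None = None
    expression_tsv: str | None = None
    simulate: SynthConfig | None = None
    k_threshold: int = 44
    n_null: int = 1000
    iters_per_edge: int = 50
    n_perm: int = 100_000
    louvain_runs: int = 1000
    conn_bins: int = 10
    cge_bins: int = 7
    method: str = "r_phi"
    alpha: float = 1e-4
    min_n: int = 10
    seed: int = 0
    out_dir: str = "nemacge_out"

    def __post_init__(self) -> None:
        has_files = self.edge_tsv and self.neuron_tsv and self.expression_tsv
        if not has_files and self.simulate is None:
            raise ConfigurationError(
                "config needs either input paths or a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(
            simulate=SynthConfig(**sim) if sim is not None else None, **raw)
        return cfg

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # where outputs land is not part of the analysis
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_inputs(cfg: RunConfig) -> tuple[Connectome, object, list[tuple[str, str]], list[str]]:
    if cfg.simulate is not None:
        ds: SynthDataset = simulate(cfg.simulate, seed=cfg.simulate.seed)
        return ds.connectome, ds.expression, ds.bilateral_pairs, ds.hubs
    c = load_connectome(cfg.edge_tsv, cfg.neuron_tsv)
    e = load_expression(cfg.expression_tsv, c.neurons)
    pairs = []
    seen = set()
    t = c.neuron_table
    for _, row in t.iterrows():
        p = row["bilateral_partner"]
        if isinstance(p, str) and p and (p, row["neuron"]) not in seen:
            pairs.append((row["neuron"], p))
            seen.add((row["neuron"], p))
    return c, e, pairs, []


def planted_gene_top_decile(scores: pd.DataFrame, planted: list[str]) -> int:
    """How many planted genes rank in the top 10% of gene scores."""
    ranked = scores.sort_values("p_a", kind="stable")["gene"].tolist()
    top = set(ranked[: max(1, len(ranked) // 10)])
    return sum(1 for g in planted if g in top)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the report bundle; returns the summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "exclusions": {"bilateral_pairs": True, "min_n": cfg.min_n},
    }
    stage = "load"
    try:
        c, e, bilateral, hubs_planted = _load_inputs(cfg)
        deg = degree_sequence(c)
        deg.to_csv(out / "degrees.tsv", sep="\t", index=False)
        summary["n_neurons"] = c.n_neurons
        summary["n_connected_pairs"] = c.n_connected_pairs()

        stage = "spatial"
        t = c.neuron_table
        dist = pairwise_distances(t)
        fits = {}
        for s, tgt in (("head", "head"), ("body", "body"), ("tail", "tail")):
            try:
                curve, fit = connection_probability_curve(
                    c, dist, s, tgt, n_bins=cfg.conn_bins)
                curve.to_csv(out / f"connprob_{s}_{tgt}.tsv", sep="\t", index=False)
                if fit is not None:
                    fits[f"{s}->{tgt}"] = dataclasses.asdict(fit)
            except Exception as exc:  # pragma: no cover - degenerate strata
                logger.warning("stratum %s->%s skipped: %s", s, tgt, exc)
        (out / "connprob_fits.json").write_text(json.dumps(fits, indent=2))

        stage = "richclub"
        rc = normalized_rich_club(
            c, n_null=cfg.n_null, iters_per_edge=cfg.iters_per_edge, seed=cfg.seed)
        rc.to_csv(out / "richclub.tsv", sep="\t", index=False)
        regime = significant_regime(rc)
        summary["richclub_regime"] = regime
        hub_labels = label_hubs(deg, cfg.k_threshold)
        summary["n_hubs"] = int(hub_labels.sum())

        stage = "modularity"
        part = louvain_consensus(c, n_runs=cfg.louvain_runs, seed=cfg.seed)
        part.labels.rename("module").to_csv(out / "modules.tsv", sep="\t")
        summary["module_sizes"] = part.module_sizes()
        summary["modularity_Q"] = part.Q

        stage = "cge"
        m = cge_matrix(e, method=cfg.method, bilateral_pairs=bilateral)
        head_mask = (t.set_index("neuron").loc[c.neurons, "region"] == "head").to_numpy()
        cge_curve, cge_fit = cge_distance_curve(
            m, dist, stratum=head_mask, n_bins=cfg.cge_bins)
        cge_curve.to_csv(out / "cge_distance_head.tsv", sep="\t", index=False)

        stage = "edge_classes"
        kmax = int(deg["k"].max())
        curve = edge_class_cge_curve(m, c, range(0, kmax, max(1, kmax // 40)))
        curve.to_csv(out / "edge_class_cge.tsv", sep="\t", index=False)

        stage = "drivers"
        pc = pair_classes(c, hub_labels)
        bil = {frozenset(p) for p in bilateral}
        keep = [frozenset((a, b)) not in bil for a, b in zip(pc["a"], pc["b"])]
        pc = pc[keep]
        rich = PairSet("rich", pc.loc[pc["pair_class"] == "rich", ["i", "j"]].to_numpy())
        peri = PairSet("peripheral",
                       pc.loc[pc["pair_class"] == "peripheral", ["i", "j"]].to_numpy())
        results = []
        if len(rich.pairs) and len(peri.pairs):
            r = compare_pair_sets(m, rich, peri, test="ranksum", alternative="greater")
            results.append(r.as_row("rich_vs_peripheral", "rich", "peripheral"))
            summary["rich_vs_peripheral_p"] = r.p
            summary["rich_median"] = r.median_a
            summary["peripheral_median"] = r.median_b
        pd.DataFrame(results).to_csv(out / "drivers.tsv", sep="\t", index=False)

        stage = "gene_scoring"
        scores_conn = score_genes(
            e, c, "connected_vs_unconnected", k_threshold=cfg.k_threshold,
            min_n=cfg.min_n, alpha=cfg.alpha, bilateral_pairs=bilateral)
        scores_conn.to_csv(out / "gene_scores_connected.tsv", sep="\t", index=False)
        scores_hub = score_genes(
            e, c, "hub_involved_vs_peripheral", k_threshold=cfg.k_threshold,
            min_n=cfg.min_n, alpha=cfg.alpha, bilateral_pairs=bilateral)
        scores_hub.to_csv(out / "gene_scores_hub.tsv", sep="\t", index=False)
        summary["n_pass_min_n_connected"] = int(scores_conn["passes_min_n"].sum())
        summary["n_pass_min_n_hub"] = int(scores_hub["passes_min_n"].sum())
        if cfg.simulate is not None and cfg.simulate.n_hub_genes:
            planted = planted_gene_names(cfg.simulate)
            summary["planted_genes_top_decile"] = planted_gene_top_decile(
                scores_hub, planted)
    except Exception as exc:
        logger.error("pipeline aborted at stage %r: %s", stage, exc)
        (out / "summary.json").write_text(
            json.dumps({"aborted_at": stage, "error": str(exc), **summary},
                       indent=2, default=_json_default))
        raise

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, default=_json_default))
    return summary


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
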