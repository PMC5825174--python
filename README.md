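# nemacge

Hub connectivity and correlated gene expression in the *C. elegans*
neuronal connectome.

The somatic nervous system of the adult hermaphrodite nematode — 279
neurons joined by directed chemical synapses and bidirectional electrical
gap junctions — contains a small set of highly connected hub neurons that
are more densely interconnected among themselves than degree-matched
chance predicts (a *rich club*). This package implements, as a tested
reusable library, an analysis linking that topological organization to
*correlated gene expression* (CGE): the similarity between two neurons'
binary gene-expression profiles. It is aimed at systems-biology and
network-neuroscience researchers who want to run the full analysis on
connectome + expression tables of their own, or to study the method's
behaviour on synthetic data with known planted structure.

## What it computes

**Rich-club organization.** For a degree threshold *k* (total degree
*k* = *k*_in + *k*_out, gap junctions counted bidirectionally), the
rich-club coefficient is the link density among neurons with degree > *k*:

    phi(k) = 2 E_{>k} / ( N_{>k} (N_{>k} - 1) )

where E_{>k} counts connected unordered pairs within the subgraph. Because
phi rises with *k* even in random graphs, it is normalized by the mean
coefficient of an ensemble of degree-preserving rewired null networks
(directed double-edge swaps, 50 swaps per edge):

    Phi_norm(k) = phi(k) / < phi_rand(k) >

with a permutation p-value taken directly from the null ensemble.
Weighted variants (weights shuffled on a fixed topology, or topology and
weights both randomized) are included.

**Correlated gene expression.** Expression is a binary 279 x ~950
neurons-by-genes indicator matrix (1 = annotated expressed; 0 = not
expressed *or* unknown). Pairwise CGE is the mean square contingency (phi)
coefficient, the binary analogue of Pearson's r:

    r_phi = (n11 n00 - n10 n01) / sqrt(n1. n0. n.1 n.0)

which, unlike the Jaccard index or Yule's Q (both provided, with a
density-bias simulation to demonstrate the difference), is unbiased with
respect to annotation density. Bilateral homolog pairs (left/right mirror
neurons with near-identical profiles) are masked from all pairwise
statistics.

**Edge classes and drivers.** Each connection is classed by the hub
status of its endpoints — rich (hub→hub), feed-in (nonhub→hub), feed-out
(hub→nonhub), peripheral (nonhub→nonhub) — and CGE is compared across
classes (Wilcoxon rank-sum), across distance strata (equiprobable binning
with exponential fits A·exp(−λx)+B), within/between Louvain consensus
modules, and against composition-matched permutation nulls (random neuron
sets matching the hubs' neurotransmitter or anatomical composition).

**Gene scoring.** Each gene *a* is scored for contributing matches
(expression in both neurons of a pair) to a class of pairs more often
than chance, with the binomial upper tail

    p(a) = P(X >= m),  X ~ Binomial(n, p_class)

over m matches on the class of interest out of n matches total, followed
by an n ≥ 10 quality filter, Benjamini–Hochberg FDR, hit calling at
p_corr < 1e-4, and hypergeometric over-representation analysis of the hit
list against annotation categories.

**Synthetic data.** A first-class generator produces datasets with the
same statistical structure: three spatial clusters (dense head, sparse
body, dense tail), distance-decaying connection probability, a planted
densely interconnected hub set, sparse binary expression with planted
hub-coexpressed genes, and bilateral homolog pairs as near-identical row
copies. Every downstream stage is therefore testable end to end with no
download.

## Worked example

Run the full pipeline on a simulated dataset with planted structure
(16 hubs, pairwise connection density 0.8; 20 genes co-expressed in hubs):

```sh
cat > demo.yaml <<EOF
simulate:
  seed: 7
k_threshold: 44
n_null: 200
louvain_runs: 200
seed: 7
out_dir: demo
EOF
nemacge run --config demo.yaml
```

prints (abridged):

```json
{
  "n_neurons": 279,
  "n_connected_pairs": 2380,
  "richclub_regime": [38, 57],
  "n_hubs": 13,
  "module_sizes": [135, 99, 23, 22],
  "rich_vs_peripheral_p": 9.190817538008038e-35,
  "rich_median": 0.2224423497811977,
  "peripheral_median": -0.004531223201035781,
  "planted_genes_top_decile": 20
}
```

Reading: the network shows a contiguous rich-club regime (Phi_norm > 1,
permutation p < 0.05) across degree thresholds 38–57, covering the
planted hubs; 13 neurons exceed the default hub threshold k = 44; the
median CGE of hub–hub connections (0.22) far exceeds that of peripheral
connections (−0.005; one-sided rank-sum p ≈ 1e-35); and all 20 planted
genes rank in the top decile of the gene-contribution scores. Stage
tables (degree sequence, rich-club curve, module assignments, CGE matrix,
distance curves, gene scores) are written under `demo/`.

Subcommands (`nemacge simulate|degrees|classify|richclub|modules|cge|spatial|score-genes`)
expose each stage separately; the library functions accept any
connectome/expression tables in the documented TSV formats.

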