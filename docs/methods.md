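# Methods

This note documents the models and procedures the package implements,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical and design decisions taken where
the problem left them open.

## Network representation and degrees

The connectome is a combined directed binary graph over named neurons.
Chemical synapses are directed records (one per ordered pair); gap
junctions are undirected records (one per unordered pair) treated as
bidirectional connections wherever a directed view is needed. Synapse
counts are kept as edge weights but all topology statistics operate on
the binarized graph; a documented consequence is that multiple synapses
between a pair contribute once to degree, not weight-times.

Two degree conventions coexist and are kept deliberately distinct:

- `connectome.degree_sequence` sums mechanisms: a pair linked by both a
  chemical and a gap record contributes once per mechanism, with gap
  junctions counting toward both `k_in` and `k_out` of both endpoints.
  This is the canonical degree used for hub labelling (`hub ⇔ k > k_threshold`,
  strict) and edge classing, and it reproduces both the heavy degree
  tail and the distinct connected-pair count of real data.
- `richclub` uses the in+out degree of the binarized union adjacency,
  because that is exactly the quantity its rewiring null preserves; the
  node sets {degree > k} are then identical in every null. The two
  conventions differ only for pairs connected by both mechanisms.

## Rich club and nulls

phi(k) = 2·E/(N(N−1)) with E counting *unordered connected pairs* among
the N nodes with degree > k. With a directed graph the factor 2 is only
consistent under this pair reading, which also keeps phi ≤ 1; a
directed-density mode (E_dir/(N(N−1))) is available for users who prefer
counting directed edges.

Nulls are directed double-edge swaps — two edges (a→b, c→d) become
(a→d, c→b) unless that creates a self-edge or duplicate — applied an
average of 50 times per edge (default). This conserves every node's in-
and out-degree exactly; the property is asserted, not assumed, in the
test suite. One ensemble (default 1000 networks) is generated per run
and reused across all thresholds. Permutation p-values use the add-one
estimator (1 + #{phi_rand ≥ phi})/(n_null + 1), so p is never zero. By
default the two directed images of a gap junction are swapped
independently; `preserve_gap_reciprocity=True` swaps chemical edges among
themselves and gap pairs among themselves (undirected), for users who
consider reciprocity part of the null.

The weighted coefficient divides the weight sum inside the club by the
sum of the E largest weights in the whole network (E = club edge count),
normalized against either weight permutation on the fixed topology or
rewiring plus weight permutation.

The "significant rich-club regime" is reported as the longest contiguous
run of thresholds with Phi_norm > 1 and permutation p < 0.05.

## Correlated gene expression

A 0 in the expression matrix means "not expressed **or** no
information"; annotations flagged uncertain are dropped by the loader
(flag-controlled). r_phi is undefined when any marginal is zero
(constant profile); undefined values are propagated as missing and
excluded from medians and tests, never imputed as 0 — imputation would
bias class medians toward whatever value was imputed.

The `p_match` measure is a hypergeometric construction: the probability
of at least the observed number of co-expressions under fixed marginals,
reported as 1 − p so larger means more coupled. It is this package's own
measure with the two properties that motivate it — it scores only
positive matches (mutual expression, which has the clearer biological
reading than mutual absence) and is unbiased with respect to annotation
density, as the bias sweep demonstrates.

The density-bias simulation draws vector pairs with exact annotation
counts (round(L·density) ones placed uniformly) rather than Bernoulli
entries, so each grid cell isolates one density pair exactly.

Bilateral homolog pairs are masked (with an explicit reason code, never
a 0) from the CGE matrix before any group statistic; their profiles are
near-identical and would otherwise dominate connected-pair contrasts.

## Spatial curves and fits

Connection probability uses ordered (directed) pairs per
source-region → target-region stratum; CGE curves use unordered pairs.
Both are binned into equiprobable (quantile) bins — 10 for connectivity,
7 for CGE by default — with ties assigned to the lower bin. The
exponential f(x) = A·exp(−λx) + B is fitted to bin centres by bounded
least squares (A ≥ 0, λ ≥ 0; tolerances 1e-8), initialized at
A₀ = max−min, B₀ = min, λ₀ = 1/median(x). Noiseless inputs are recovered
exactly. Residualization (value − f(distance)) is provided chiefly to
demonstrate its failure mode: when a short-distance trend is driven by a
few very similar nearby pairs rather than a bulk effect, residuals turn
artifactually negative for ordinary short-range pairs.

Bilateral exclusion is applied to CGE distance curves but not to
connectivity curves (connectivity is not contaminated by the homolog
expression artefact).

## Gene scoring

For a contrast between a class of neuron pairs and an alternative set,
each gene's score is the binomial upper tail P(X ≥ m), X ~ Binomial(n,
p_class), with m the gene's matches on the class, n its matches over the
union, and p_class the class share of the pair universe — recomputed
from the actual universe after bilateral exclusion, not hard-coded. The
tail is evaluated with a numerically stable survival function rather
than literal 1 − Σ (which cancels catastrophically for large n). The
n ≥ 10 filter gates hit calling; BH-FDR runs across the filtered genes;
hits are p_corr < 1e-4. "Hub-involved" pairs are unordered (expression
is neuron-level; direction is irrelevant to matching). M defaults to the
comparison-wide pair count, with a per-gene option restricting to pairs
of annotated neurons.

**Calibration caveat.** The binomial null assumes a gene's matches fall
on the class of interest independently with fixed probability. That
assumption holds exactly only when pair class membership is homogeneous
and independent across the pairs a gene matches — e.g. a distance-free
random graph with the connected/unconnected contrast, where the test
suite verifies the score distribution is exactly super-uniform. Under
realistic structure it is violated twice over: distance-decaying
connectivity makes per-pair connection probability depend on the spatial
composition of the expressing set (overdispersion), and a single
high-degree neuron in the expressing set contributes many
hub-involved pairs at once (correlated class membership). The scores are
therefore mildly anti-conservative on structured data even without any
planted signal; they should be read as a ranking device — the use the
stringent 1e-4 threshold and the planted-recovery tests support — rather
than literal p-values.

## Group statistics

Rank-sum tests use the exact null distribution for min(n) ≤ 8 without
ties and the tie-corrected normal approximation otherwise (the two agree
within 0.01 at n = 30, cross-checked in tests). Welch's t uses
Satterthwaite degrees of freedom; zero variance in both groups is
flagged undefined. One-sided directions are always supplied by the
caller per analysis, never inferred from data. Composition-matched nulls
draw random neuron sets reproducing the target set's composition over a
chosen attribute (neurotransmitter, region, or none = size-matched),
with the add-one right-tail p. The default permutation count is 1e5
(configurable); effects at the magnitudes this analysis reports
(p ≳ 3e-4) are resolvable at that scale without the cost of 1e8 draws.

## Modularity

Directed edges are symmetrized (OR) before community detection, since
the modularity being optimized is the undirected one. The consensus
procedure runs Louvain `n_runs` times with distinct sub-seeds, weights
each partition's co-assignment matrix by its modularity Q, thresholds
the agreement at tau = 0.4 (a common consensus default, exposed in
config), re-clusters the agreement graph, and iterates until all runs
agree up to label permutation. Modules are relabelled 1..M in
size-descending order (ties by smallest original label). Externally
derived partitions (e.g. a stochastic block model decomposition) are
consumed via `load_partition`, not re-derived.

## Synthetic data: what it emulates, what it does not

Defaults place 147 head neurons within a 130 μm disc, 105 body neurons
(predominantly motor) along a 1.02 mm axis, and 27 tail neurons within
90 μm. Ordered pairs connect with probability A·exp(−λd) + B with
A = 0.15, λ = 0.012 μm⁻¹, B = 0.005 — chosen once so that the simulated
network's edge count, connected-pair count, degree tail, and hub-degree
range land near the real connectome's printed values. A planted hub set
(16 neurons drawn from head and tail proportionally to cluster size) is
reciprocally connected pair-by-pair with probability 0.8; 20% of
connected pairs are stored as gap junctions; weights are geometric.
Expression is Bernoulli(0.05) per entry, with 20 planted genes at
Bernoulli(0.9) in hubs; 92 bilateral pairs are generated as row copies
with 2% independent entry flips, which yields homolog r_phi ≈ 0.85
(median), matching the observation that real homolog pairs exceed 0.8.
When a bilateral pair contains exactly one hub, the hub's row is the
copy template, so planted hub expression survives pairing and is shared
with the homolog, as in real mirror-pair hubs. A single global seed is
expanded into independent streams (neurons, hubs, connectome,
expression, lineage), so changing one block's parameters never perturbs
another block's draw.

Not emulated: real developmental lineage trees (pairwise lineage
distances are small random integers — plumbing so lineage analyses run,
nothing more), axon trajectories (distances are straight-line 2-D
Euclidean), anatomical ontologies, and any gene–gene correlation
structure beyond the planted hub genes and homolog copying. Passing
tests on synthetic data therefore demonstrate that the machinery
detects (and, on null data, does not hallucinate) the planted
statistical structure; they do not validate biological conclusions
about real annotation data, whose curation biases (e.g. functionally
related neurons annotated as a group) the generator does not model.

## Numerical and degenerate-input conventions

- phi(k) with fewer than two qualifying nodes is NaN (flagged), never 0.
- Permutation and rank-sum p-values are strictly positive (add-one).
- Equiprobable binning warns and collapses on mass ties; per-bin counts
  otherwise differ by at most one.
- Rewiring on graphs too small or rigid to swap returns the input with a
  swap count of 0 and a warning.
- Loaders name the offending row/neuron in every data error.
- All analysis randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; byte-identical reruns are asserted in the
  test suite for the generator and the pipeline.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the full 279-neuron, 948-gene
configuration for planted-signal recovery (10 seeds, 60-network null
ensembles), 200 seeds for null calibration, 1000 rewired nulls of a
100-node graph for degree conservation, and the full L = 948,
1000-pair-per-cell density-bias sweep. The rich-club null ensemble size
and Louvain run count are the two knobs that trade precision for time;
both default to 1000 in the pipeline and are reduced in the shipped
checks, where only the Monte-Carlo resolution, not the inference, is
affected.
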