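# Methods

`egosig` extracts compact, functionally coherent "active signaling"
networks from phosphoproteomics fold-change tables by combining semantic
similarity, network propagation, and local (ego-network) decomposition.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic test system does and does not show.

## The base network

The input protein–protein interaction graph is undirected and simple;
proteins without at least one ontology annotation are removed at load.
Each edge (i, j) is weighted by the simGIC semantic similarity of its
endpoints,

    simGIC(i, j) = Σ_{t ∈ A_i ∩ A_j} ic(t) / Σ_{t ∈ A_i ∪ A_j} ic(t),

where A_i is protein i's ancestor-closed annotation set and
ic(t) = −log₂(n(t)/N) is the corpus information content of term t in bits
(n(t) = proteins annotated to t or a descendant, N = all annotated
proteins). All ontology namespaces are joined under a single *virtual
root* whose IC is 0, so every annotated pair has a defined similarity.
The log base is a free choice — it cancels in the simGIC ratio — and bits
are used for reporting. Pairwise similarities are memoized; the
per-protein closure is computed once at load.

Hub bias is corrected by square-root-degree ("Laplacian") normalization,
w_ij ← w_ij / √(d_i d_j), with d the *weighted* degree on the raw
weights. The normalized network stores the raw degrees, so raw weights
are exactly recoverable (a tested invariant). Structurally isolated nodes
are dropped with a warning; an edge of raw weight 0 keeps normalized
weight 0 (0/0 := 0), which preserves the node set of weight-degenerate
rewired replicates.

Each node also carries a *semantic profile*: the mean and population
standard deviation of its simGIC against every other network node. These
global statistics calibrate the per-ego z-filter below.

## The null model

Significance of propagation scores is assessed against an ensemble of
degree-preserving rewirings of the raw graph (double-edge-swap Markov
chain, ≥ 10·|E| accepted swaps per replicate, simple-graph constraint, so
every node's degree is conserved exactly). Each replicate's edges are
re-weighted by simGIC of the *new* endpoint pairs and Laplacian-
normalized. The ensemble is a pure function of its seed. The production
default is 1000 replicates; fixture-scale tests use 100 (see "Problem
sizes" below).

## Seed selection and layered propagation

Phosphosites are aggregated to protein level per direction of change:
the maximum |log₂ fold change| and maximum functional score over a
protein's direction-consistent sites. A protein with sites of both signs
participates in both directions. Proteins are partitioned into tyrosine
kinases, other kinases, and substrates (tyrosine listing wins);
kinase layers keep proteins with a functional score whose |LFC| and score
both exceed their layer's 20th percentile (strict, linear-interpolation
percentiles), substrates must exceed the 80th percentile of both. A
top-N-per-direction mode is available instead. Degenerate layers (< 2
scoreable proteins, or all-identical values) pass through unfiltered with
a warning, since a strict percentile would silently empty them.

Each layer's restart vector scales the |LFC| values onto [0.01, 1]
(the floor keeps the weakest seed alive) and normalizes to sum 1. The
random walk with restart iterates p ← d·T·p + (1−d)·r to an L1 fixed
point (tolerance 1e-10, cap 10⁴ iterations), where T column-normalizes
the Laplacian-normalized weights and d is the *continuation* probability
(default 0.85; restart probability 0.15). Dangling mass re-enters through
the restart distribution. On graphs small enough to solve directly, the
iterate matches (I − dT)⁻¹(1−d)r to 1e-8 (a tested oracle).

A node survives a layer iff its real score strictly exceeds more than
(1−α)·R of its R null scores (α = 0.05); ties count against retention.
The direction network is the base-network subgraph induced on the union
of survivors across layers plus all of the direction's seeds (seeds are
always kept). Proteins present in both direction networks are resolved to
the direction with the larger mean RWR score over the *configured* layers
(zeros included for layers where the protein was unscored — dividing by
the populated-layer count instead would favor sparsely seeded
directions); exact ties go to the up network; seeds exclusive to a
direction are never removed from it. The resolution can be disabled.

## Ego decomposition

Every seed of a direction network becomes an ego. Candidates are all
nodes within two steps of the ego inside the direction network; candidate
j is kept iff

    (simGIC(ego, j) − mean_ego) / std_ego > 1.64,

the one-tailed 95% normal quantile against the ego's global semantic
profile (a zero-variance profile degenerates to a mean comparison, with a
warning). Edges of the surviving ego network are re-weighted ego-
centrically — simGIC(i, j) on edges at the ego, the mean of the two
endpoints' ego-similarities elsewhere — and Laplacian-normalized.

Each member j is then placed in a 2-D plane:
topological affinity 1000·log₂(2 − JSD(p_ego, p_j)) (one-hot-restart RWR
vectors inside the ego network, base-2 Jensen–Shannon distance, so the
value spans [0, 1000]), and functional distance
1000·log₂(1 + simGIC(ego, j)). A Gaussian product-kernel KDE with
per-dimension Silverman bandwidth h_d = σ_d·n^(−1/6) is fitted to the
rescaled points; each node's joint lower-tail CDF
P(X ≤ x_j, Y ≤ y_j) is evaluated in closed form from normal CDFs, and
nodes with CDF ≥ the threshold (default 0.85) join the ego in its
*supernode*. The per-node-CDF reading of the selection rule is the one
design choice this package makes where the selection semantics were
genuinely open; it makes the user threshold act as the probability cutoff
it is named as. Ego networks with ≤ 5 neighbors are kept whole
(decomposition needs a meaningful point cloud); an empty selection leaves
the ego alone; a degenerate (zero-variance) cloud selects everything,
with a warning.

## Supernode graph and modules

For each supernode pair, the base network is induced on the union of
their members and re-normalized; if the two egos are connected in that
subgraph, the edge weight is the JSD between the egos' one-hot RWR
vectors on it (0 = strongest). Isolated supernodes are removed; connected
components with ≥ 4 supernodes are partitioned by the Leiden algorithm
(modularity objective, resolution 1.0, fixed seed) on similarity weights
1 − JSD — Leiden needs similarities and the inversion preserves ranking
inside [0, 1] — while smaller components (including size 3, which the
selection rules leave formally unassigned) are kept whole as modules. A
module's protein content is the union of its supernodes' members.

## Evaluation statistics

Over-representation uses the one-sided Fisher exact test on the 2×2 table
(foreground ∩ set vs background), Bonferroni-corrected over the sets
tested; fold enrichment is observed/expected. The one-sided tail is the
enrichment-appropriate convention. Module-vs-pathway similarity uses the
Szymkiewicz–Simpson overlap coefficient |X∩Y|/min(|X|,|Y|) and its
complement distance; modules under 10 proteins are excluded from
best-match searches to avoid inflated coefficients, ties going to the
larger module.

## The synthetic study system

The fixture generator plants a fully known truth: 300 proteins in 12
functional communities of 25, each split into 5 "kinase subfamilies" of
5; a nested stochastic-block-model graph (subfamily edge probability 0.5,
within-community 0.2, between 0.002, plus a per-community spanning tree);
a term DAG with one branch per community carrying 5 community-wide
general terms and 5 subfamily pools; annotations drawn 80%/20% from the
subfamily/general pools with 5% cross-community contamination; and 120
phosphosites — 90% strong up-regulated sites on one designated active
community (every kinase gets one; a logistic link ties functional score
to |LFC|, as strongly responding sites are the likelier-regulatory ones),
10% low-score noise of random sign spread over the whole network.

Two scale-driven facts shaped these choices. First, on small dense
graphs the configuration-model null assigns any node a noticeable chance
of landing adjacent to a seed, which floors the achievable empirical
p-value; the geometry must be sparse enough, with enough seeds per layer,
for real community signal to clear the 95% bar. Second, the KDE
selection needs either a small ego network (kept whole) or a large point
cloud with a small dominant cluster; subfamilies provide the tight
"most similar" sets the decomposition is meant to find. What the fixture
does *not* emulate: mass-spectrometry missingness, site-localization
ambiguity, hub-heavy degree distributions, annotation-depth bias, or
realistic kinase fractions. Passing tests therefore show the machinery
implements its definitions and recovers planted structure at toy scale —
not that it would rank pathways correctly on real proteome-scale data.

## Problem sizes and tolerances

Tests and the acceptance script run the full pipeline on the 300-protein
fixture with 100 random-network replicates per run (the production
default is 1000) and ten generator seeds; one such sweep takes about two
minutes on a single CPU. RWR convergence is 1e-10 (L1); the RWR-vs-
direct-solve oracle is asserted at 1e-8; Laplacian inversion at 1e-12;
Fisher p against exhaustive hypergeometric summation at 1e-9 relative.
At this scale the largest-module recovery of the planted community
averages a little under one half with zero off-community contamination;
per-seed values vary widely (roughly 0.25–0.7) because Leiden partitions
of ~7-supernode graphs are discrete — one split decision halves the
largest module. The per-stage counts of every run are logged and written
to the manifest.

## Known limitations

* Propagation is symmetric; no directed kinase→substrate edges.
* Modules are per direction; up and down networks are never linked.
* Enrichment requires identifiers already matching the network's
  namespace; no built-in symbol↔accession mapping.
* The double-edge-swap chain is a Python-level loop; ensembles of 1000
  replicates on large networks are the dominant cost and are best cached
  via the library API.
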