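# Methods

## The analysis

`tissuenet` reconstructs and compares *associative gene networks*: subgraphs
of a typed gene/protein knowledge graph induced by a gene set of interest.
Genes and proteins are separate vertices; the only tie between a protein and
its encoding gene is a directed `expression` edge (gene → protein).  Given a
seed gene set, the reconstruction keeps the seed genes found in the knowledge
graph, adds every protein one expression edge downstream, and induces all
knowledge-graph edges among these vertices.  The unfiltered result is the
*combined* network.

A *tissue-specific* network restricts the combined network to genes with a
*present* expression call in one tissue (Bgee-style binary presence/absence
calls under normal conditions).  Proteins carry no expression calls of their
own, so a protein is kept iff at least one of its encoding genes is kept.
Genes expressed but isolated after filtering are retained: node and component
counts are reported quantities.  Filtering is idempotent and monotone.

## Structural characteristics

All metrics are computed on the undirected simple projection of a network
(typed/directed edges collapse to undirected edges, self-loops dropped).
Eight characteristics are reported:

| characteristic | definition | convention |
|---|---|---|
| nodes | vertex count | — |
| clustering | mean local clustering coefficient Cᵥ = 2eᵥ/(kᵥ(kᵥ−1)) | mean over vertices with kᵥ ≥ 2 (NetworkAnalyzer convention); `all_nodes` flag counts kᵥ < 2 vertices as 0 |
| components | connected components | isolated vertices count |
| centralization | (n/(n−2))·(k_max/(n−1) − density) | Freeman degree form; 0 for n < 3 |
| shortest paths | Σ over ordered pairs (s,t) of geodesic multiplicity σ_st | unit edge weights; `pairs_only` flag counts reachable ordered pairs once |
| average neighbors | mean degree 2E/n | 0 for empty graph |
| density | 2E/(n(n−1)) | 0 for n < 2 (degenerate flag) |
| heterogeneity | CV of degree: population SD / mean | 0 when mean degree is 0 |

The geodesic-multiplicity convention for shortest-path counts was chosen
because published values of this statistic exceed the ordered-pair count for
the corresponding node counts, which is only possible when multiplicities are
included; the pair-count-only mode is provided as a flag.

Betweenness centrality is shortest-path betweenness (Brandes), each unordered
pair counted once, normalized by (n−1)(n−2)/2 (values in [0, 1]); raw scores
are available.  Per-column positive rescaling leaves Pearson correlations
unchanged, so cross-network correlation matrices are identical under the raw
and normalized scales.

`count_shortest_paths` uses one BFS per source accumulating σ over integer
adjacency lists; for graphs of 150–1500 vertices a level-synchronous variant
propagates the whole σ matrix by repeated multiplication with the adjacency
matrix (float64 matmul — exact for counts below 2⁵³, far above anything these
networks produce).  Both routes are validated against an exhaustive
geodesic-enumeration oracle (`tissuenet.bruteforce`) and against each other.

## The pseudo-random null test

Significance of a combined-vs-tissue difference is assessed against networks
induced by uniform gene resampling: each replicate draws, without
replacement from the full gene universe, one gene set size-matched to each
network of the pair, reconstructs both networks with the same rule as the
real ones, and records the seven difference indicators (all characteristics
except node count, which is matched by construction).  The replicates form a
single index-paired ensemble shared by all indicators — one null sample of
paired differences, matching a single pseudo-random ensemble design.
Default: 1000 replicates.

Size matching uses the network's **gene** count by default (the universe
holds genes; proteins follow automatically); a `vertex_budget="nodes"` flag
matches total vertex count instead.

The observed indicator is flagged when it falls strictly below the 5% or
strictly above the 95% empirical quantile of its null sample (ties at the
quantile are non-significant — conservative).  Quantiles are order statistics
with linear interpolation between closest ranks (numpy's `linear` method).
Reports mark an indicator with `*` when **either** tail fires, following the
single-superscript convention of combined-vs-tissue tables; note that two 5%
tails imply a ~10% two-sided level, and the strict empirical-quantile rule at
R replicates has true two-sided level ≈ (2·(1+(R−1)·0.05+0.95))/(R+1) ≈ 0.109
at R = 200 — the calibration checks test against the binomial band around
0.10 accordingly.

Randomness: one root seed; replicate *i* draws its two gene samples from
`default_rng([seed, i, 0])` and `default_rng([seed, i, 1])`.  The counter
scheme makes every replicate reproducible independently of evaluation order.

## Synthetic data

The generators emulate the statistical *shape* of the real substrate at desk
scale, not its size or its fitted marginals:

* **Knowledge graph** — `n_genes` genes (default 500), a seeded fraction
  (default 0.7) carrying a protein joined by an expression edge; a backbone
  topology over gene indices (Barabási–Albert preferential attachment,
  default m = 5, or G(n, p)) lifted to typed edges: `interaction` between
  proteins, `association` otherwise.  m = 5 gives a mean unit degree near 10,
  in line with the average-neighbor range (9–13) that literature-derived
  pathway networks show.
* **Expression catalog** — a base tissue draws each gene present with
  probability `coverage` (default 0.6, echoing the observation that roughly
  half to two-thirds of the genome is called present in most tissues); other
  tissues copy the base call with probability `tissue_correlation`
  (default 0.5) and redraw otherwise.  `hub_bias` is the designed signal
  knob: it removes the top `top_degree_fraction` of genes (by interaction
  degree of the gene/protein unit) from one tissue after the draw, making
  that tissue's filtered network measurably less central.
* **Pathway gene set** — a snowball (breadth-first, seeded random frontier
  order) sample of `pathway_size` genes (default 60), so the induced network
  is non-trivially connected the way curated process annotations are.

Not emulated: ontology structure among tissues, call quality labels,
per-interaction organism/cell-line attributes, and the real interactome's
degree-mixing patterns.  Passing tests therefore demonstrate correctness of
the *procedures* (reconstruction, filtering, metrics, null calibration), not
biological fidelity of any particular network.

## Problem sizes used in the checks

Chosen so the full suite runs comfortably on one CPU:

* metric-oracle agreement: 200 random graphs, n ≤ 12 (exhaustive oracles
  feasible), edge probability up to 0.6;
* null-test calibration: 500-gene knowledge base, two 60-gene pseudo-random
  networks per run, 200 replicates, 100 runs; per-indicator two-tail
  rejection rate tested against the 99% binomial band around 0.10;
* hub-exclusion recovery: 120-gene universe, combined network over the whole
  universe, tissue excluding the top-5%-degree genes, 100 replicates,
  50 runs; both centralization and average-neighbors must be flagged in
  ≥ 95% of runs.  (The effect is tested on the KB-wide network because the
  hub-excluding filter is a property of the whole universe; on a small
  snowball pathway the same effect competes with sampling noise.)
* identity limit and determinism: default-scale synthetic data and the
  12-gene worked fixture, 50 replicates.

## Reproduction mode for published betweenness tables

`reproduce_supplementary(path)` reads a per-vertex betweenness spreadsheet
(one id column, one column per network; Excel or TSV), zero-imputes vertices
absent from a network, and recomputes the pairwise Pearson matrix over all
rows, comparing it side by side with the printed correlations.  Because
Pearson correlation is invariant to per-column positive scaling, the result
does not depend on whether the published table stores raw or normalized
betweenness.  Whether published correlations were taken over genes only or
genes + proteins is not documented; when a node-kind map is supplied the
genes-only matrix is reported alongside.

## Known limitations

* The expression catalog ignores call quality (gold/silver) — calls are
  binary.
* The null model is vertex resampling only; degree-preserving edge rewiring
  nulls are deliberately out of scope.
* Betweenness is exact (no sampling approximation); networks are expected to
  be desk-scale (≤ a few thousand vertices).
* The interactions TSV represents isolated vertices via `#node` comment
  declarations; third-party edge lists without them lose isolated vertices.
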