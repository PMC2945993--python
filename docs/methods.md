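# Methods

## Problem and model

`gridwave` looks for *coordinated* differential regulation in metabolic
pathways: not just "many genes of the pathway shifted", but spatially
organized patterns on the reaction network, including switch-like contrasts
where one reaction is up- and a neighboring reaction down-regulated.
Gene-set tests that ignore topology (Fisher's exact enrichment, rank-based
enrichment scores) average such contrasts away; the combination of a
lattice embedding and a 2x2 Haar transform preserves them.

The analysis has four stages.

### 1. Reaction-neighborhood graphs

Each pathway is a graph with enzymatic reactions as nodes. Two reactions
are adjacent when some metabolite is the product of one and the substrate
of the other (checked in both directions by default — reversibility of the
catalyzed step is not trusted). Metabolites are not nodes; they only induce
the adjacency. Pathways without a single connected reaction carry no
neighborhood signal and are discarded. Reactions annotated with exactly the
same non-empty gene set are indistinguishable on the expression level and
are merged into one node (union of edges); the merge map is retained so
regulated-reaction counts refer to distinguishable reactions.

Currency-metabolite filtering (ATP, H2O, ...) is supported through an
exclusion list but empty by default: the neighbor rule is applied to the
pathway definition as given.

### 2. Lattice embedding

Reactions are placed injectively on an s x s lattice, s = ceil(sqrt(|V|))
(optionally +1 slack), minimizing the total Manhattan length of graph
edges. Minimizing *total* length (rather than the longest edge, as in VLSI
placement) keeps adjacent reactions tightly packed. The problem is a
quadratic assignment instance, NP-hard; three backends are provided:

- **Exact ILP** (default): binary variables x[v,i,j] ("v sits on (i,j)")
  with one-placement and one-occupancy constraints; a continuous distance
  variable per *adjacent* pair bounded below by the four sign combinations
  of the coordinate differences (non-adjacent pairs contribute nothing to
  the objective and get no variable). Solved by HiGHS through
  `scipy.optimize.milp`. On timeout the best incumbent is returned together
  with the proven gap (ratio of dual bound to incumbent; 1 means proven
  optimal).
- **Brute force**: exhaustive enumeration of injective placements, refused
  above 7 nodes. This is the test oracle; the ILP optimum equals it on all
  142 connected graphs with 2-6 nodes (exhaustive up to isomorphism).
- **Simulated annealing**: swap/relocate moves, geometric cooling,
  deterministic per seed, for large pathways or as a solver-free fallback.
  Its gap uses a combinatorial bound (see below); if the incumbent attains
  that bound the embedding is optimal by certificate, and the optimality
  flag is set accordingly.

Optional *motif cuts* add valid inequalities of the form
sum of motif-edge distances >= lb(motif) for statically detected stars,
cliques (k <= 10), odd cycles (lengths 3, 5) and BFS spanning trees with
maximum degree <= 4. The right-hand sides are host-graph independent: star
bounds come from the closed form (4d lattice points at distance d from the
center), cycle/clique bounds from one-off exact optimization of the motif
on a generous grid, tree bounds from the edge count. Cuts never change the
optimum, only the relaxation — verified on the exhaustive small-graph
suite. Dynamic separation inside the solver is deliberately replaced by
up-front detection: the feasible region is identical and the engineering is
far simpler. *Symmetry breaking* restricts one maximum-degree node to a
fundamental domain of the grid's dihedral group (i <= (s-1)/2,
j <= (s-1)/2, i <= j), eliminating rotation/reflection copies of each
solution without touching the optimal value.

The per-node star bounds also give the solver-free lower bound used by the
heuristic: every edge has length >= 1, and summing each node's star bound
counts every edge twice, so max(|E|, ceil(sum of star bounds / 2)) is valid.

Multiple optimal embeddings generally exist; the solver's incumbent is
accepted as-is, so embeddings are reproducible only per backend and seed.
All downstream outputs carry the embedding (JSON serialization plus
provenance headers) for exactly this reason.

### 3. Expression images and Haar features

Samples are labeled from the clinical table: recurrence-free beyond 5 years
is favorable, recurrence before 3 years with metastasis is unfavorable,
everything else — including the exact boundaries t = 3 and t = 5, which the
strict inequalities exclude — is discarded. Gene-level log-ratios are
aggregated per reaction (mean by default; median/max configurable).
Reactions with no measured gene get the neutral log-ratio 0 but are tracked
in an occupied/measured mask so that downstream decisions are structural,
not value-based.

Each sample's reaction values are painted onto the embedding grid (zeros in
empty cells) and transformed by a 2x2 Haar cascade. Per 2x2 block with rows
(a, b) and (c, d), with row means m_u, m_l and row differences d_u, d_l:

    f1 = (m_u + m_l)/2    f2 = m_u - m_l
    f3 = (d_u + d_l)/2    f4 = d_u - d_l

f1 is the low-pass (coordinated regulation of the four cells), f2-f4 are
contrasts (switch-like patterns). "Mean" is a plain average and
"difference" a plain difference — no orthonormal sqrt(2) scaling. This is
deliberate: the downstream test is rank-based, so any fixed positive
rescaling of a coefficient leaves its p-value unchanged (asserted as a
test), and the plain form keeps f1 an interpretable mean (the top-level f1
equals the grand mean of the padded image). The f1 matrix recurses —
detail coefficients are not cascaded — with zero re-padding of odd
dimensions at every level, until a single block remains. By default the
cascade is repeated for the four shift origins (0,0), (0,1), (1,0), (1,1),
so every 2x2 neighborhood of the grid appears in some block; a single
aligned tiling is available as `offsets_mode="single"`.

A feature is *non-trivial* when its spatial footprint contains at least one
reaction-bearing cell and its value varies across samples; only non-trivial
features are tested. (Zero-filled cells make value-based emptiness
undetectable, hence the structural mask.)

### 4. Testing and ranking

Every non-trivial feature is compared between groups with a two-sided
Wilcoxon rank-sum test (exact enumeration for small tie-free samples,
tie-corrected normal approximation otherwise; cohort-scale matrices use the
approximation). Per pathway the best (smallest) raw p is Bonferroni
corrected; the default family is *all* non-trivial features across all
pathways in the run — the most conservative, globally valid choice, since
the original family definition is not recoverable — with a per-pathway
family available by configuration. A pathway is significant when the
adjusted p passes alpha (0.05) AND it has more than `min_reactions` = 3
differentially regulated reactions (strict: >= 4), counting merged
duplicate-gene-set reactions once. Per-reaction regulation (for those
counts) is a two-sided rank-sum at uncorrected 0.05 with direction from the
median difference (unfavorable minus favorable); unmeasured reactions are
always "unchanged". Output tables report both raw and adjusted best-feature
p-values.

Two gene-set baselines are included for comparison: Fisher's exact test on
the 2x2 table of DE membership (DE = per-gene rank-sum p <= 0.05) versus
pathway membership, and a simplified rank-based enrichment score (weighted
Kolmogorov-Smirnov running sum over genes ranked by a signed rank-sum z,
two-sided sample-label permutation null). The latter is a deliberately
small stand-in for full GSEA, used only as a benchmark comparator.

## Synthetic data: what it emulates and what it does not

The generator produces the pipeline's three inputs without any external
database: connected random reaction networks (uniform random spanning tree
via Pruefer sequences plus 25% extra edges, metabolites synthesized to
realize the adjacency), iid Gaussian gene log-ratios, and a clinical table
that encodes the intended labels (t = 6 vs t = 2 with metastasis).

Default design (chosen once as a moderate two-group cohort): 6 pathways x
8 reactions x 2 genes, 30 favorable + 30 unfavorable samples, noise SD 1.0
(log-ratio units), one planted pathway, effect 2 SD. Patterns: `block_up` /
`block_down` shift a connected 4-reaction block; `switch` shifts one
graph-adjacent reaction pair by +delta/-delta — the contrasting-neighbor
signal the high-pass coefficients target; `null` plants nothing.

What it does not emulate: probe-level artifacts, dye effects, correlated
gene noise, isoenzyme redundancy, missing annotations, unequal pathway
sizes. Passing simulation-based checks therefore demonstrates statistical
correctness (calibration, error control, recovery under the stated
conditions), not robustness to real microarray pathologies.

Replicated evaluations (FWER under the null, planted-pattern recovery, the
ROC benchmark) keep pathway topology and embeddings fixed at the design
seed and redraw expression per replicate: the cohort is the random
quantity, while the embedding is a deterministic function of the pathway.

## Numerical choices and problem sizes

- Exact Wilcoxon refuses ties and falls back to the approximation with a
  warning; constant feature rows get p = 1.
- Haar round-trip inversion is exact to float precision (< 1e-12 observed
  over 10^4 random blocks).
- ILP time limit defaults to 300 s per pathway; incumbents plus gap are
  accepted on timeout.
- Annealing: 10^4 iterations by default, initial temperature objective/4,
  geometric cooling to 0.05; matches the brute-force optimum on >= 95% of
  a seeded suite of 50 random graphs with <= 6 nodes.
- Evaluation sizes: 142-graph exhaustive oracle suite; 500 null replicates
  for the family-wise error rate; 100 replicates for switch recovery
  (delta = 2 SD); 50 replicates for the ROC benchmark. The benchmark's
  comparison point uses delta = 0.5 SD: per-gene power is below 50% there,
  which is precisely the regime where coordinated-neighbor detection should
  (and does) beat per-gene enrichment; at delta = 2 SD every method
  saturates and the comparison is uninformative.

## Known limitations

- Optimal embeddings are not unique; feature identities (block indices)
  are only meaningful relative to the serialized embedding.
- The global Bonferroni family over strongly correlated wavelet features is
  conservative (observed FWER ~0.01-0.02 at nominal 0.05 under the default
  null design).
- The ">3 regulated reactions" filter makes pure two-reaction switches
  detectable but never *significant* by the combined criterion; they still
  rank first by p-value, which is what the ranked output reports.
- KGML parsing covers reaction/substrate/product/gene-entry structure only;
  no compound ontology resolution or KEGG downloads.
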