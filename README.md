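# gridwave

Network-pattern analysis of metabolic pathway regulation. `gridwave` ranks
metabolic pathways by their ability to separate two phenotype groups (e.g.
favorable vs unfavorable cancer prognosis) using *spatially organized*
expression patterns on the reaction network — including switch-like
contrasts where one reaction is up- and its network neighbor down-regulated,
which classical gene-set enrichment tests average away.

## Method in brief

1. **Reaction graphs.** Reactions are nodes; two reactions are adjacent
   when a metabolite is the product of one and the substrate of the other.
   Pathways without any connected reaction are discarded; reactions with
   identical gene sets are merged.
2. **Lattice embedding.** Each pathway is placed on the smallest square
   grid (side ceil(sqrt(|V|))) minimizing the total Manhattan edge length

       min Σ_{(a,b)∈E} d_ab,   d_ab = |i_a − i_b| + |j_a − j_b|,

   an NP-hard quadratic assignment problem solved exactly as an integer
   linear program (HiGHS), with optional motif-based valid inequalities
   (stars, cliques ≤ 10, odd cycles, bounded-degree trees) and symmetry
   breaking. A brute-force oracle and a simulated-annealing fallback are
   included.
3. **Haar features.** Per sample, reaction-level expression (mean of the
   annotated genes' log-ratios) is painted onto the grid, zero elsewhere,
   and transformed by a recursive 2×2 Haar cascade. Each block yields the
   mean-of-means f1 (coordinated regulation) and three contrast
   coefficients f2–f4 (switch patterns); f1 recurses. All four block
   arrangements (shift origins) are used by default.
4. **Testing.** Every non-trivial feature is tested with a two-sided
   Wilcoxon rank-sum test; the best feature per pathway is Bonferroni
   corrected over the full feature family. A pathway is significant at
   α = 0.05 if it additionally has more than 3 differentially regulated
   reactions. Fisher's-exact enrichment and a simplified rank-enrichment
   score are provided as baselines.

Everything runs on synthetic data generated by the package (random
connected reaction networks, two-group log-ratio expression with planted
block or switch patterns), so no pathway database or cohort download is
needed.

## Worked example

Simulate a dataset with a ±2 SD switch planted on one adjacent reaction
pair of pathway SP00, embed, and rank:

```sh
gridwave simulate --out-dir demo --pattern switch --effect-size 2.0 --seed 7
gridwave embed demo/pathways.tsv --out demo/embeddings.json --seed 7
gridwave rank demo/pathways.tsv demo/expression.tsv demo/clinical.tsv \
    --embeddings demo/embeddings.json --out demo/results.tsv --seed 7
```

which prints

```
wrote dataset to demo (planted: ['SP00'])
SP00    objective=11    gap=1.000
SP01    objective=11    gap=1.000
SP02    objective=11    gap=1.000
SP03    objective=10    gap=1.000
SP04    objective=11    gap=1.000
SP05    objective=10    gap=1.000
tested 6 pathways over m=464 features; 0 significant
top pathway: SP00 (p=6.07e-11)
```

Each `objective` is the proven-minimal total Manhattan edge length of that
pathway's embedding (`gap=1.000` marks proven optimality). 464 non-trivial
wavelet features were tested in total; the planted pathway tops the ranking
with raw p ≈ 6e-11 (Bonferroni-adjusted 2.8e-08 in `results.tsv`). It is
*ranked* first but not flagged significant: a two-reaction switch cannot
pass the "more than 3 regulated reactions" filter, which the combined
significance criterion requires. The first lines of `demo/results.tsv`:

```
rank  pathway  n_diff_regulated  n_reactions  n_down  n_up  p_value    p_adjusted  significant
1     SP00     2                 8            1       1     6.07e-11   2.81e-08    False
2     SP04     0                 8            0       0     0.031      1.0         False
```

The same workflow is available as library calls (`gridwave.analyze`,
`gridwave.embed_pathways`, `gridwave.benchmark_sensitivity`, ...).

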