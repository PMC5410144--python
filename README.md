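# phylopace

Tools for asking whether a genome's **evolutionary rate** is linked to the
**dispersion of its gene trees across branch-length patterns**.

Across a genome, every gene evolves down the same species tree, but each gene
tree carries its own branch lengths. Three forces shape them: *gene effects*
(a gene's overall rate, set by its selective constraint), *lineage effects*
(genome-wide rate differences between branches, e.g. generation time), and
*gene-by-lineage interactions* (lineage-specific deviations peculiar to one
gene, expected under strong selection). Genes governed by the same
combination of lineage effects share the same **relative** branch-length
pattern and can be clustered together — sometimes called "pacemakers". The
hypothesis this package tests: drift-dominated, fast-evolving genes should
collapse into few pattern clusters, while strongly selected, slow-evolving
genes should be dispersed into many.

## What the package does

- **`trees_io`** — Newick parsing/writing (via dendropy), a canonical edge
  order over a shared unrooted topology (so branch-length vectors are
  comparable across genes), tree lengths, and the PH85 / Robinson–Foulds
  topology distance.
- **`topology_clustering`** — congruence screening: pairwise PH85 distances,
  classical (Torgerson) MDS to 2-D, PAM (k-medoids by Voronoi iteration)
  and the Gap statistic to choose the number of topology clusters. The
  analysis requires a single cluster (one shared topology).
- **`phylo_engine`** — amino-acid likelihood on the fixed topology:
  reversible 20-state models (Poisson by default, any empirical
  exchangeability matrix loadable), discrete-Γ rate heterogeneity,
  Felsenstein pruning, per-gene ML branch-length optimization, and sequence
  simulation.
- **`pattern_clustering`** — branch vectors divided by tree length (removing
  gene effects exactly) and clustered with a diagonal-covariance Gaussian
  mixture model at each scheme K.
- **`krkc`** — model-free radical/conservative amino-acid substitution ratio
  (Kr/Kc), opportunity-normalized so the neutral expectation is 1.
- **`rate_selection`** — tree-length deciles, clusters represented per
  decile, Kendall tau-b tests (with exclusion sensitivity), EC-class
  summaries, and random-forest feature importance.
- **`synthetic_data`** — ensembles with planted lineage patterns, lognormal
  gene rates and rate-coupled interaction noise, plus a no-bias null design
  with identical pattern inventories across tree-length classes.
- **`pipeline` / CLI** — `phylopace run-all` orchestrates gate → branch
  lengths → Kr/Kc → clustering → reports, with a manifest for reproducible
  reruns; each stage is also available as its own subcommand.

## Worked example

Generate a synthetic ensemble with the planted selection coupling, then test
for the rate–dispersion relationship:

```python
import phylopace as pp
from phylopace.rate_selection import (
    rank_into_deciles, clusters_per_decile, rate_dispersion_test)

cfg = pp.EnsembleConfig(n_genes=1000, n_patterns=40,
                        interaction_sigma0=0.6, seed=2)
ens = pp.generate_ensemble(cfg)

pm = pp.normalize_branch_vectors(ens.gene_trees)   # genes x 27 edges, rows sum to 1
deciles = rank_into_deciles(ens.tree_lengths)      # decile 10 = fastest 10%
assignment = pp.fit_gmm(pm, 40, seed=2)            # 40-component GMM scheme
rep = clusters_per_decile(deciles, assignment)
print(rep[["decile", "clusters_represented"]].to_string(index=False))
kt = rate_dispersion_test(rep)
print(f"tau = {kt.tau:.2f}, p = {kt.p_value:.4f}")
```

Output:

```
 decile  clusters_represented
      1                    30
      2                    26
      3                    31
      4                    30
      5                    29
      6                    25
      7                    20
      8                    17
      9                    13
     10                     9
tau = -0.81, p = 0.0012
```

The slowest decile of genes is spread over 30 of the 40 mixture components
while the fastest decile occupies only 9; the Kendall test quantifies the
negative rate–dispersion association (τ = −0.81, two-sided p ≈ 0.001).

The same analysis runs from the shell on a tree table
(`phylopace simulate --preset selection-coupled --out ens`, then
`phylopace run-all --trees ens/trees.tsv --out run`); `run/kendall.tsv`
holds τ and p per clustering scheme, with and without the slowest two
deciles excluded.

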