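# Methods

This note documents the models and procedures implemented in `phylopace`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## The analysis

Given per-gene amino-acid alignments and/or per-gene trees over one shared
set of taxa, the pipeline:

1. **Congruence gate.** Computes all pairwise PH85 (Robinson–Foulds)
   distances between gene-tree topologies, embeds them in 2-D by classical
   (Torgerson) multidimensional scaling, clusters the embedded points with
   PAM, and selects the number of clusters with the Gap statistic. The
   downstream analysis assumes a single shared topology, so it proceeds only
   when the chosen k is 1 (overridable).
2. **Branch lengths.** For each gene, maximum-likelihood branch lengths are
   laid over the fixed shared topology under a reversible amino-acid model.
   Tree length — the sum of all branch lengths in expected substitutions per
   site — is the gene's rate proxy.
3. **Kr/Kc.** A model-free selection proxy per gene: radical (cross
   physicochemical category) versus conservative (within-category) residue
   differences, counted over all sequence pairs and columns, normalized by
   the category opportunity fractions.
4. **Pattern clustering.** Branch vectors are divided by tree length, which
   removes the gene-effect scale exactly (rows sum to 1), and the resulting
   genes × edges matrix is clustered with a diagonal-covariance Gaussian
   mixture at each scheme K ∈ {20, 30, 40, 50, 100} by default.
5. **Rate–dispersion tests.** Genes are ranked by tree length into deciles
   (decile 10 = fastest 10%; sizes differ by at most one; ties broken by
   gene id). Per decile, the number of distinct mixture components
   represented is counted, and the decile-index-versus-count association is
   tested with Kendall tau-b (tie-corrected, two-sided asymptotic p; exact
   permutation available for n ≤ 10). A sensitivity variant repeats the test
   after dropping the slowest two deciles, where short trees make branch
   lengths noisiest. EC-class summaries report distinct clusters per gene
   for each top-level enzyme class, and a random forest measures how well
   tree length, Kr/Kc and EC class predict cluster labels.

## Likelihood machinery

* **Models.** Q = S·diag(π) with symmetric exchangeabilities S and
  stationary frequencies π, diagonal set to zero row sums, scaled so
  −Σᵢ πᵢ Qᵢᵢ = 1 (branch lengths in substitutions/site). The default is the
  Poisson model (equal S, uniform π); any 20×20 empirical matrix can be
  loaded from a whitespace-delimited file. Rate-matrix estimation is out of
  scope: the analysis target is branch-length *patterns*, which are robust
  to the exchangeability choice, not model fit.
* **Rate heterogeneity.** Discrete Γ with equal-probability categories whose
  rates are the conditional means of the quantile sections (renormalized to
  mean exactly 1); 4 categories by default; 1 category reduces exactly to
  the homogeneous model.
* **Pruning.** Felsenstein pruning over compressed site patterns; gaps and
  ambiguity codes (`- . ? X B Z J *`) contribute all-ones partials; site
  likelihoods are averaged over Γ categories with equal weights.
* **Optimization.** Coordinate-wise bracketed scalar optimization (bounded
  Brent) of each branch in [1e−8, 20]. Each sweep maintains exact inside
  ("below the edge") and outside ("rest of the tree, frequencies included")
  partials in a single tree recursion, so a one-branch objective costs one
  20×20 transition product per site pattern; the inside caches are refreshed
  on the way back up, which keeps every single-edge step an exact ascent of
  the full likelihood. Sweeps repeat until the total log-likelihood improves
  by < `tol` (default 1e−6); the Γ shape is optionally co-estimated by the
  same scalar method on log-shape in [log 0.02, log 100], alternating with
  branch sweeps. Ten random restarts are the default (the best fit is
  kept); branch-length likelihood surfaces on a fixed topology are
  well-behaved, so large-scale batch runs in this package use 1–2 restarts.
* **Simulation.** Per site: draw a Γ category, a root state from π, and
  propagate along edges with P(rate·t); deterministic per seed.

Degenerate inputs: identical sequences drive all branches to the lower
bound; zero-length trees are excluded from pattern clustering with a logged
warning; an all-zero topology distance matrix short-circuits the gate to
"one cluster" since the Gap machinery is degenerate there.

## Congruence machinery

* **PAM** follows the Voronoi-iteration description (random k medoids;
  assign to nearest medoid, ties to the lowest medoid index; replace each
  medoid by the member minimizing within-cluster total distance; stop when
  assignments stabilize), with 10 random restarts by default and a
  monotone-cost assertion each iteration. This variant, rather than the
  BUILD/SWAP original, is what the analysis describes.
* **Gap statistic.** W_k = Σ_clusters (sum of pairwise distances)/(2·size),
  references drawn uniformly over the per-feature bounding box (B = 50),
  gap(k) = mean_b log W_k(ref) − log W_k(data), chosen k = global argmax
  (first on ties); the 1-SE rule is available as an option. Distances are
  Euclidean in the 2-D MDS embedding; negative MDS eigenvalues are clamped
  to zero because PH85 matrices need not be Euclidean.

## Kr/Kc details

Counting is pairwise over observed sequences, with no tree or ancestral
reconstruction — that is what "model-free, non-parametric" means here. The
default classification is charge (positive {K,R,H}, negative {D,E}, neutral
rest); polarity and polarity+volume tables ship as alternatives. The
opportunity fractions f_r (cross-category fraction of the 190 unordered
residue pairs; 81/190 for charge) and f_c = 1 − f_r are always recomputed
from the table. The normalized ratio (n_r/f_r)/(n_c/f_c) has neutral
expectation 1 — verified by simulation under the Poisson model — and is
undefined (reported with a reason) when no conservative difference is
observed. Pairwise counting without correction is biased toward radical
changes at high divergence; that bias is accepted as a property of the
statistic, and the raw-count ratio is reported alongside.

## The synthetic-data generator

`generate_ensemble` plants the mechanism the analysis is designed to
detect. With shared topology (uniform random, by sequential leaf
attachment), gene g's length on edge e is

    b_ge = r_g · m_{p(g),e} · base_e · exp(ε_ge),   ε_ge ~ N(0, σ_I(r_g)²)

* `base_e` — per-edge scale, Exp(mean 0.05) unless supplied (a 27-edge tree
  then has unit-rate length ≈ 1.35 substitutions/site, a plausible scale
  for deep phylogenomic amino-acid data).
* `m_{p,e}` — lineage-effect pattern multipliers, log-normal with log-SD
  σ_L (`pattern_spread`, default 0.15); each gene draws one of `n_patterns`
  (default 40) patterns uniformly.
* `r_g` — gene effect, log-normal with log-SD 1 by default (roughly two
  orders of magnitude of rate variation, a heavy right tail).
* `σ_I(r) = σ0/(1 + r/r0)` — gene-by-lineage interaction noise, decreasing
  in gene rate; defaults σ0 = 0.6 and r0 = median rate. The hypothesis
  states only the direction of the coupling; this smooth two-knob form is
  the package's choice.

The default σ_L = 0.15 is deliberately *small* relative to σ0: the
hypothesis being emulated is that fast (drift-dominated) genes share a
compact set of genome-wide patterns — their residual noise (σ_I ≈ 0.13 at
~4× the median rate) blurs the 40 nominal patterns into a small effective
number — while slow genes (σ_I ≈ 0.5) are dispersed far beyond the pattern
spread into idiosyncratic positions. Under these defaults the mixture
spends its components where the dispersion is (slow genes) and the decile
representation counts fall with rate, reproducing the predicted negative
Kendall association. With σ_L large the generator instead plants
well-separated clumps for all rates, which is the *absence* of the
hypothesized structure; planted-recovery tests use that regime (σ_L = 1,
σ0 ≈ 0) on purpose.

`generate_null_ensemble` is the matching no-bias control: classes of trees
rescaled exactly to short/median/long tree-length targets, each class
holding the same round-robin inventory of patterns (σ_L = 1 so patterns are
resolvable), with alignments simulated so the full
simulate → re-estimate → cluster loop can be run. Because inventories are
identical by construction, any class-vs-count trend would be a bias of the
estimation/clustering loop; the control verifies there is none.

What the generator does **not** emulate: topology discordance between genes
(the analysis premise is a single shared topology), indels and alignment
error, non-stationary or site-heterogeneous composition, correlated rates
among neighboring branches, and real lineage-effect structure (generation
time, body size). Passing tests therefore show the method detects the
planted coupling and is unbiased under the planted null — not that real
genomes contain such coupling.

## Problem sizes and numerical choices

The standing test/replication conditions are: mechanism runs with G = 1000
genes, 15 taxa, 40 patterns, schemes K ∈ {20, 40}, ten seeds; recovery runs
with 8 taxa × 10,000 sites (Poisson+Γ, shape 0.5); the null control with
three classes × 100 trees, 20 patterns, 200 sites, ten replicates, fit with
tolerance 1e−3 and one restart (batch setting). GMM: diagonal covariance
(27-dimensional rows and up to 100 components make full covariance
ill-conditioned), k-means++ seeding, 10 initializations, variance floor
1e−10, seeded and deterministic. K is user-specified per scheme; no
automatic K selection is attempted at the pattern stage, by design.

Tie-breaking is deterministic everywhere: decile ties by gene id, PAM
assignment ties by lowest medoid index, Gap ties by first k, GMM labels by
argmax responsibility.

## Known limitations

* The mechanism's statistical power falls at low K (coarse schemes): with
  40 planted patterns, the 20-component scheme sits near the detection
  threshold at G = 1000, mirroring the general observation that few-cluster
  schemes lack resolution for this question.
* The edge-wise optimizer stores per-node partials without underflow
  rescaling; it is intended for the tens-of-taxa regime this analysis
  operates in, not for hundreds of taxa.
* Kr/Kc is pairwise and uncorrected for multiple hits; values are
  comparable across genes evolving over the same timescale, not across
  datasets.
* The Gap statistic's reference distribution is the bounding-box uniform
  (the simpler of Tibshirani's two options); with strongly elongated
  embeddings the principal-component variant could differ.
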