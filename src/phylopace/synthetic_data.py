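"""Synthetic gene-tree ensembles with planted structure.

The generator emulates the structure the rate-dispersion analysis is built
to detect: a single species topology shared by all genes; a small set of
lineage-effect *patterns* (per-edge rate multipliers shared genome-wide);
a heavy-tailed distribution of per-gene overall rates (gene effects); and
gene-by-lineage *interaction* noise whose magnitude decreases with gene
rate — the generative counterpart of the hypothesis that strongly selected
(slow) genes are dispersed into many idiosyncratic branch-length patterns
while drift-dominated (fast) genes share a few genome-wide patterns.

A separate null design plants no rate coupling at all: three classes of
trees rescaled to fixed short/median/long tree lengths, each class holding
the same round-robin inventory of patterns, with sequence alignments
simulated so the full estimate-then-cluster loop can be checked for bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_engine import Alignment, SubstitutionModel, poisson_model, simulate_alignment
from .trees_io import GeneTree, PhyloTree, Topology


def generate_topology(n_taxa: int, seed: int) -> Topology:
    """Random unrooted binary topology by sequential random leaf attachment.

    Starting from the 3-leaf star, each new leaf is attached to a uniformly
    chosen existing edge, which yields the uniform distribution over
    unrooted binary topologies.  Leaf labels are ``t01 .. tNN``.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_taxa)))
    labels = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    # node ids: 0..n_taxa-1 leaves, internal nodes appended after
    adj: dict[int, dict[int, float]] = {i: {} for i in range(3)}
    center = n_taxa
    adj[center] = {}
    for i in range(3):
        adj[i][center] = 1.0
        adj[center][i] = 1.0
    next_internal = n_taxa + 1
    for leaf in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = next_internal
        next_internal += 1
        del adj[u][v]
        del adj[v][u]
        adj[w] = {u: 1.0, v: 1.0, leaf: 1.0}
        adj[u][w] = 1.0
        adj[v][w] = 1.0
        adj[leaf] = {w: 1.0}
    leaf_label = {i: labels[i] for i in range(n_taxa)}
    return Topology.from_tree(PhyloTree(adj, leaf_label))


@dataclass
class EnsembleConfig:
    """Parameters of the planted-structure generator.

    Defaults are the package's standing study conditions: 15 taxa, 1000
    genes, 40 lineage-effect patterns whose per-edge log-multipliers have
    SD ``pattern_spread`` = 0.15 (subtle genome-wide patterns, comparable
    to the residual noise of the fastest genes), lognormal gene rates with
    log-SD 1 (roughly two orders of magnitude of rate variation), and
    interaction noise sigma_I(r) = sigma0 / (1 + r / r0) with sigma0 = 0.6
    and r0 at the median gene rate, so slow genes are dispersed and fast
    genes are not.
    """

    n_taxa: int = 15
    n_genes: int = 1000
    n_patterns: int = 40
    base_edge_lengths: np.ndarray | None = None  # drawn Exp(mean 0.05) if None
    pattern_spread: float = 0.15      # sigma_L, log-scale SD of pattern multipliers
    gene_rate_mu: float = 0.0         # lognormal log-mean of gene rates
    gene_rate_sigma: float = 1.0      # lognormal log-SD of gene rates
    interaction_sigma0: float = 0.6   # sigma0, interaction noise at rate 0
    interaction_r0: float | None = None  # r0; median rate exp(gene_rate_mu) if None
    n_sites: int | None = None        # simulate alignments when set
    model: SubstitutionModel = field(default_factory=poisson_model)
    seed: int = 0

    def __post_init__(self):
        if self.n_patterns > self.n_genes:
            raise ValueError("n_patterns must not exceed n_genes")
        if min(self.pattern_spread, self.gene_rate_sigma, self.interaction_sigma0) < 0:
            raise ValueError("spread parameters must be >= 0")

    def interaction_sigma(self, rate: float) -> float:
        r0 = self.interaction_r0 if self.interaction_r0 is not None else np.exp(self.gene_rate_mu)
        return self.interaction_sigma0 / (1.0 + rate / r0)


@dataclass
class SimulatedEnsemble:
    topology: Topology
    gene_trees: list[GeneTree]
    truth: pd.DataFrame  # gene_id, pattern, rate
    patterns: np.ndarray  # (n_patterns, n_edges) per-edge multipliers
    alignments: list[Alignment] | None = None

    @property
    def tree_lengths(self) -> dict[str, float]:
        return {gt.gene_id: gt.tree_length for gt in self.gene_trees}


def _draw_patterns(rng, n_patterns: int, n_edges: int, spread: float) -> np.ndarray:
    return np.exp(rng.normal(0.0, spread, size=(n_patterns, n_edges)))


def generate_ensemble(config: EnsembleConfig) -> SimulatedEnsemble:
    """Planted lineage patterns + gene effects + rate-coupled interaction noise.

    Branch length of gene g on edge e:
        b_ge = r_g * m_{p(g),e} * base_e * exp(N(0, sigma_I(r_g)^2))
    with pattern p(g) uniform over the pattern inventory and r_g lognormal.
    """
    rng = np.random.default_rng(config.seed)
    topology = generate_topology(config.n_taxa, int(rng.integers(2**31 - 1)))
    n_edges = topology.n_edges
    base = config.base_edge_lengths
    if base is None:
        base = rng.exponential(0.05, size=n_edges) + 1e-4
    base = np.asarray(base, dtype=float)
    if base.shape != (n_edges,) or np.any(base <= 0):
        raise ValueError(f"base_edge_lengths must be {n_edges} positive reals")

    patterns = _draw_patterns(rng, config.n_patterns, n_edges, config.pattern_spread)
    pattern_of = rng.integers(0, config.n_patterns, size=config.n_genes)
    rates = np.exp(rng.normal(config.gene_rate_mu, config.gene_rate_sigma, config.n_genes))

    width = len(str(config.n_genes))
    gene_trees = []
    rows = []
    for g in range(config.n_genes):
        sig = config.interaction_sigma(rates[g])
        noise = np.exp(rng.normal(0.0, sig, size=n_edges)) if sig > 0 else 1.0
        lengths = rates[g] * patterns[pattern_of[g]] * base * noise
        gid = f"g{g + 1:0{width}d}"
        gene_trees.append(GeneTree(gid, topology, lengths))
        rows.append({"gene_id": gid, "pattern": int(pattern_of[g]), "rate": rates[g]})
    truth = pd.DataFrame(rows)

    alignments = None
    if config.n_sites is not None:
        align_seeds = rng.integers(0, 2**31 - 1, size=config.n_genes)
        alignments = [
            simulate_alignment(
                topology, gt.branch_lengths, config.model, config.n_sites,
                seed=int(s), gene_id=gt.gene_id,
            )
            for gt, s in zip(gene_trees, align_seeds)
        ]
    return SimulatedEnsemble(topology, gene_trees, truth, patterns, alignments)


def generate_null_ensemble(
    tree_length_targets: dict[str, float],
    n_per_class: int = 300,
    n_patterns: int = 40,
    n_sites: int = 353,
    seed: int = 0,
    n_taxa: int = 15,
    pattern_spread: float = 1.0,
    model: SubstitutionModel | None = None,
    simulate_sequences: bool = True,
) -> dict[str, SimulatedEnsemble]:
    """The no-bias control: tree-length classes with identical pattern inventories.

    Each class (e.g. short / median / long) gets ``n_per_class`` gene trees;
    the pattern inventory is assigned round-robin so every pattern appears in
    every class, and each tree is rescaled so its tree length equals the
    class target exactly.  Alignments of ``n_sites`` residues are simulated
    per tree so branch lengths can be re-estimated before clustering.  If the
    clustering method is unbiased, each class should represent the same
    number of patterns.
    """
    if len(tree_length_targets) < 2:
        raise ValueError("need at least 2 tree-length classes")
    if any(t <= 0 for t in tree_length_targets.values()):
        raise ValueError("tree-length targets must be positive")
    if n_per_class < n_patterns:
        raise ValueError("n_per_class must be >= n_patterns so every pattern fits")
    model = model or poisson_model()
    rng = np.random.default_rng(seed)
    topology = generate_topology(n_taxa, int(rng.integers(2**31 - 1)))
    n_edges = topology.n_edges
    base = rng.exponential(0.05, size=n_edges) + 1e-4
    patterns = _draw_patterns(rng, n_patterns, n_edges, pattern_spread)

    out: dict[str, SimulatedEnsemble] = {}
    for cls, target in tree_length_targets.items():
        gene_trees, rows, alignments = [], [], [] if simulate_sequences else None
        for g in range(n_per_class):
            p = g % n_patterns  # round-robin: identical inventories by construction
            raw = patterns[p] * base
            lengths = raw * (target / raw.sum())
            gid = f"{cls}_{g + 1:04d}"
            gt = GeneTree(gid, topology, lengths)
            gene_trees.append(gt)
            rows.append({"gene_id": gid, "pattern": p, "rate": target})
            if simulate_sequences:
                alignments.append(
                    simulate_alignment(
                        topology, lengths, model, n_sites,
                        seed=int(rng.integers(2**31 - 1)), gene_id=gid,
                    )
                )
        out[cls] = SimulatedEnsemble(
            topology, gene_trees, pd.DataFrame(rows), patterns, alignments
        )
    return out


def write_ensemble(ensemble: SimulatedEnsemble, out_dir) -> None:
    """Write tree table, truth table and (if present) FASTA alignments."""
    import os

    from .trees_io import write_tree_table

    os.makedirs(out_dir, exist_ok=True)
    write_tree_table(os.path.join(out_dir, "trees.tsv"), ensemble.gene_trees)
    ensemble.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    if ensemble.alignments:
        aln_dir = os.path.join(out_dir, "alignments")
        os.makedirs(aln_dir, exist_ok=True)
        for aln in ensemble.alignments:
            aln.to_fasta(os.path.join(aln_dir, f"{aln.gene_id}.fasta"))
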