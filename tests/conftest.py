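import numpy as np
import pytest

import phylopace as pp


@pytest.fixture
def quartet():
    """4-taxon tree AB|CD with known branch lengths."""
    tree = pp.parse_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.15);")
    topology = pp.Topology.from_tree(tree)
    return tree, topology


@pytest.fixture
def quartet_topology(quartet):
    return quartet[1]


def random_gene_trees(topology, n_genes, seed, scale=0.1):
    """Helper: gene trees with iid exponential branch lengths."""
    rng = np.random.default_rng(seed)
    return [
        pp.GeneTree(f"g{i:03d}", topology, rng.exponential(scale, topology.n_edges) + 1e-6)
        for i in range(n_genes)
    ]


def all_six_taxon_topologies():
    """All 105 unrooted binary topologies on 6 labeled leaves.

    Built by sequential insertion: each topology corresponds to one choice
    of insertion edge per added leaf (3 * 5 * 7 = 105, all distinct).
    """
    labels = [f"t{i}" for i in range(1, 7)]

    def build(choices):
        adj = {i: {} for i in range(3)}
        center = 6
        adj[center] = {}
        for i in range(3):
            adj[i][center] = 1.0
            adj[center][i] = 1.0
        nxt = 7
        for leaf, pick in zip(range(3, 6), choices):
            edges = sorted((u, v) for u in adj for v in adj[u] if u < v)
            u, v = edges[pick]
            w = nxt
            nxt += 1
            del adj[u][v]
            del adj[v][u]
            adj[w] = {u: 1.0, v: 1.0, leaf: 1.0}
            adj[u][w] = 1.0
            adj[v][w] = 1.0
            adj[leaf] = {w: 1.0}
        return pp.PhyloTree(adj, {i: labels[i] for i in range(6)})

    trees = []
    for a in range(3):
        for b in range(5):
            for c in range(7):
                trees.append(build((a, b, c)))
    return trees
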