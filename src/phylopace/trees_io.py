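"""Unrooted gene trees with a canonical edge order.

Every gene tree in a pacemaker-style analysis shares one species topology;
what differs between genes is the vector of branch lengths laid over that
topology.  To make those vectors comparable across genes this module imposes
a *canonical edge order*: each edge is keyed by the bipartition it induces,
stored as the sorted tuple of leaf labels on the side NOT containing the
lexicographically smallest leaf, and edges are listed in lexicographic order
of those keys.  The ordering is therefore independent of Newick rotation and
root placement.

Trees are treated as unrooted throughout: a degree-2 root read from a Newick
string is collapsed by summing its two incident branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

EdgeKey = tuple[str, ...]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class UnsupportedStructureError(ValueError):
    """Tree structure outside the supported class (e.g. polytomies)."""


class IncongruenceError(ValueError):
    """Two trees that were required to share a topology do not."""

    def __init__(self, message: str, only_in_a=(), only_in_b=()):
        super().__init__(message)
        self.only_in_a = tuple(only_in_a)
        self.only_in_b = tuple(only_in_b)


class PhyloTree:
    """An unrooted tree with branch lengths.

    Stored as a symmetric adjacency map ``{node: {neighbor: length}}`` with
    integer node ids; leaves carry labels.  This is the parse product; the
    immutable :class:`Topology` and :class:`GeneTree` views are derived from it.
    """

    def __init__(self, adj: dict[int, dict[int, float]], leaf_label: dict[int, str]):
        self.adj = adj
        self.leaf_label = leaf_label
        self._label_to_node = {v: k for k, v in leaf_label.items()}
        if len(self._label_to_node) != len(leaf_label):
            raise NewickParseError("duplicate leaf labels in tree")
        for lab in leaf_label.values():
            if not lab:
                raise NewickParseError("empty leaf label")

    # -- basic structure ---------------------------------------------------
    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaf_label.values()))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)

    def edges(self):
        """Yield each unordered edge once as ``(u, v, length)``."""
        for u, nbrs in self.adj.items():
            for v, ln in nbrs.items():
                if u < v:
                    yield u, v, ln

    @property
    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    @property
    def tree_length(self) -> float:
        return float(sum(ln for _, _, ln in self.edges()))

    def is_binary(self) -> bool:
        return all(
            len(nbrs) in (1, 3) for nbrs in self.adj.values()
        ) and self.n_leaves >= 2

    # -- bipartitions ------------------------------------------------------
    def split_lengths(self) -> dict[EdgeKey, float]:
        """Map every edge to its canonical bipartition key and branch length."""
        smallest = min(self.leaf_label.values())
        root = self._label_to_node[smallest]
        out: dict[EdgeKey, float] = {}
        # iterative post-order from the smallest leaf: child-side leaf sets
        # never contain the smallest label, so they are already canonical.
        parent = {root: None}
        order = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    order.append(v)
                    stack.append(v)
        leafset: dict[int, frozenset[str]] = {}
        for u in reversed(order):
            if u in self.leaf_label:
                leafset[u] = frozenset([self.leaf_label[u]])
            else:
                leafset[u] = frozenset().union(
                    *(leafset[v] for v in self.adj[u] if v != parent[u])
                )
            if parent[u] is not None:
                key = tuple(sorted(leafset[u]))
                out[key] = self.adj[u][parent[u]]
        return out

    def bipartitions(self, include_trivial: bool = False) -> frozenset[EdgeKey]:
        T = self.n_leaves
        keys = self.split_lengths().keys()
        if include_trivial:
            return frozenset(keys)
        return frozenset(k for k in keys if 1 < len(k) < T - 1)

    # -- output ------------------------------------------------------------
    def to_newick(self) -> str:
        """Serialize unrooted: root the output at an internal node."""
        if self.n_leaves == 2:
            (a, b, ln) = next(self.edges())
            la, lb = self.leaf_label[a], self.leaf_label[b]
            return f"({la}:{ln!r},{lb}:0.0);"
        start = next(
            (u for u in self.adj if len(self.adj[u]) >= 3), next(iter(self.adj))
        )

        def sub(u: int, parent: int | None) -> str:
            children = [v for v in self.adj[u] if v != parent]
            if not children:
                return self.leaf_label[u]
            inner = ",".join(
                f"{sub(v, u)}:{self.adj[u][v]!r}" for v in children
            )
            return f"({inner})"

        return sub(start, None) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick tree into an unrooted :class:`PhyloTree`.

    A degree-2 root is collapsed by summing its two incident branch lengths.
    Missing branch lengths on non-root edges default to an error.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    adj: dict[int, dict[int, float]] = {}
    leaf_label: dict[int, str] = {}
    ids: dict[int, int] = {}

    def nid(node) -> int:
        key = id(node)
        if key not in ids:
            ids[key] = len(ids)
            adj[ids[key]] = {}
        return ids[key]

    root = dtree.seed_node
    for node in dtree.preorder_node_iter():
        u = nid(node)
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise NewickParseError("leaf without a label")
            leaf_label[u] = node.taxon.label
        if node is not root:
            ln = node.edge.length
            if ln is None:
                raise NewickParseError(
                    f"missing branch length on edge above node {node!r}"
                )
            if ln < 0:
                raise NewickParseError(f"negative branch length {ln}")
            p = nid(node.parent_node)
            adj[p][u] = float(ln)
            adj[u][p] = float(ln)

    if len(leaf_label) < 2:
        raise NewickParseError("need at least 2 leaves for an unrooted tree")

    # collapse a degree-2 root (rooted input): sum the two incident lengths
    r = ids[id(root)]
    if len(adj[r]) == 2:
        (a, la), (b, lb) = adj[r].items()
        del adj[a][r]
        del adj[b][r]
        del adj[r]
        adj[a][b] = la + lb
        adj[b][a] = la + lb

    return PhyloTree(adj, leaf_label)


def write_newick(tree: "PhyloTree | GeneTree") -> str:
    if isinstance(tree, GeneTree):
        tree = tree.to_phylo_tree()
    return tree.to_newick()


@dataclass(frozen=True)
class Topology:
    """An unrooted binary topology with its canonical edge order.

    ``edge_order`` lists every edge (pendant and internal) by its canonical
    bipartition key, lexicographically sorted; for ``T`` leaves there are
    exactly ``2T - 3`` edges.
    """

    leaf_labels: tuple[str, ...]
    edge_order: tuple[EdgeKey, ...]
    nontrivial_bipartitions: frozenset[EdgeKey]
    _skeleton: PhyloTree = field(compare=False, repr=False, hash=False)

    @classmethod
    def from_tree(cls, tree: PhyloTree) -> "Topology":
        if not tree.is_binary():
            raise UnsupportedStructureError(
                "polytomous or degenerate topology: every internal node must "
                "have degree 3"
            )
        keys = tuple(sorted(tree.split_lengths().keys()))
        return cls(
            leaf_labels=tree.leaf_labels,
            edge_order=keys,
            nontrivial_bipartitions=tree.bipartitions(include_trivial=False),
            _skeleton=tree,
        )

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edge_order)

    def edge_index(self, key: EdgeKey) -> int:
        return self.edge_order.index(key)

    def same_topology(self, other: "Topology") -> bool:
        return (
            self.leaf_labels == other.leaf_labels
            and self.nontrivial_bipartitions == other.nontrivial_bipartitions
        )

    def __eq__(self, other):
        if not isinstance(other, Topology):
            return NotImplemented
        return self.same_topology(other)

    def __hash__(self):
        return hash((self.leaf_labels, self.nontrivial_bipartitions))


def canonical_edge_order(tree_or_topology: "PhyloTree | Topology") -> tuple[EdgeKey, ...]:
    """Canonical edge keys for an unrooted binary topology (length ``2T-3``)."""
    if isinstance(tree_or_topology, Topology):
        return tree_or_topology.edge_order
    return Topology.from_tree(tree_or_topology).edge_order


@dataclass
class GeneTree:
    """A gene's branch lengths laid over the shared topology.

    ``branch_lengths`` is aligned to ``topology.edge_order``; lengths are in
    expected substitutions per site.  ``loglik`` is populated when the tree
    came out of a likelihood optimization.
    """

    gene_id: str
    topology: Topology
    branch_lengths: np.ndarray
    loglik: float | None = None

    def __post_init__(self):
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        if self.branch_lengths.shape != (self.topology.n_edges,):
            raise ValueError(
                f"gene {self.gene_id}: expected {self.topology.n_edges} branch "
                f"lengths, got {self.branch_lengths.shape}"
            )
        if np.any(self.branch_lengths < 0) or not np.all(
            np.isfinite(self.branch_lengths)
        ):
            raise ValueError(f"gene {self.gene_id}: branch lengths must be finite and >= 0")

    @property
    def tree_length(self) -> float:
        return float(self.branch_lengths.sum())

    def to_phylo_tree(self) -> PhyloTree:
        skel = self.topology._skeleton
        lengths = dict(zip(self.topology.edge_order, self.branch_lengths))
        adj = {u: dict(nbrs) for u, nbrs in skel.adj.items()}
        tmp = PhyloTree(adj, dict(skel.leaf_label))
        # walk the skeleton once to know which (u, v) edge carries which key
        smallest = min(skel.leaf_label.values())
        root = tmp._label_to_node[smallest]
        parent = {root: None}
        stack = [root]
        order = [root]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    order.append(v)
                    stack.append(v)
        leafset: dict[int, frozenset] = {}
        for u in reversed(order):
            if u in tmp.leaf_label:
                leafset[u] = frozenset([tmp.leaf_label[u]])
            else:
                leafset[u] = frozenset().union(
                    *(leafset[v] for v in adj[u] if v != parent[u])
                )
            if parent[u] is not None:
                key = tuple(sorted(leafset[u]))
                ln = float(lengths[key])
                adj[u][parent[u]] = ln
                adj[parent[u]][u] = ln
        return tmp

    @classmethod
    def from_phylo_tree(
        cls, gene_id: str, tree: PhyloTree, reference: Topology
    ) -> "GeneTree":
        return cls(gene_id, reference, branch_vector(tree, reference))


def branch_vector(tree: PhyloTree, reference: Topology) -> np.ndarray:
    """Branch lengths of ``tree`` aligned to ``reference.edge_order``.

    Raises :class:`IncongruenceError` (listing the symmetric-difference
    bipartitions) if the tree's topology differs from the reference.
    """
    if tree.leaf_labels != reference.leaf_labels:
        raise IncongruenceError(
            f"leaf sets differ: {sorted(set(tree.leaf_labels) ^ set(reference.leaf_labels))}"
        )
    lengths = tree.split_lengths()
    got = frozenset(k for k in lengths if 1 < len(k) < len(tree.leaf_labels) - 1)
    want = reference.nontrivial_bipartitions
    if got != want:
        raise IncongruenceError(
            "topology mismatch with reference",
            only_in_a=sorted(got - want),
            only_in_b=sorted(want - got),
        )
    return np.array([lengths[k] for k in reference.edge_order], dtype=float)


def rf_distance(a: "PhyloTree | Topology", b: "PhyloTree | Topology") -> int:
    """Robinson–Foulds (PH85) symmetric-difference distance.

    Counts non-trivial bipartitions present in exactly one of the two
    unrooted topologies; 0 iff the topologies are identical.
    """
    la = a.leaf_labels
    lb = b.leaf_labels
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(set(la) ^ set(lb))}")
    ba = a.nontrivial_bipartitions if isinstance(a, Topology) else a.bipartitions()
    bb = b.nontrivial_bipartitions if isinstance(b, Topology) else b.bipartitions()
    return len(ba ^ bb)


# -- tree-table TSV ---------------------------------------------------------

def read_tree_table(path) -> list[tuple[str, PhyloTree]]:
    """Read a two-column TSV (gene_id, newick) with a header row."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty tree table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene_id, newick = parts
            out.append((gene_id, parse_newick(newick)))
    return out


def write_tree_table(path, trees: "list[tuple[str, PhyloTree]] | list[GeneTree]") -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tnewick\n")
        for item in trees:
            if isinstance(item, GeneTree):
                gene_id, nwk = item.gene_id, write_newick(item)
            else:
                gene_id, nwk = item[0], item[1].to_newick()
            fh.write(f"{gene_id}\t{nwk}\n")
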