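"""Amino-acid likelihood on a fixed topology.

Implements the machinery needed to lay maximum-likelihood branch lengths over
a shared species topology, gene by gene: a reversible 20-state substitution
model (fixed exchangeabilities, Poisson by default, optionally +Γ rate
heterogeneity with Yang-style mean-of-quantile-section categories),
Felsenstein pruning, coordinate-wise branch-length optimization with exact
inside/outside partial caching, and sequence simulation.

Branch lengths are in expected substitutions per site (the rate matrix is
scaled so that -sum_i pi_i Q_ii = 1).  Gaps and ambiguity codes are treated
as missing data (all-ones partials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees_io import GeneTree, Topology

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
# treated as missing data (all-ones partial likelihood)
MISSING_CHARS = set("-.?XBZJ*")

BL_MIN, BL_MAX = 1e-8, 20.0


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Category rates for a discrete-Γ model (mean of equal-probability sections).

    For X ~ Γ(shape, mean 1) the unit interval is cut into ``n_categories``
    equal-probability sections and each category rate is the conditional mean
    of its section; rates are renormalized to mean exactly 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), shape, scale=1.0 / shape)
    # E[X ; X <= x] for Gamma(shape, mean 1) equals gammainc(shape+1, shape*x)
    mass = gammainc(shape + 1, shape * edges)
    rates = k * np.diff(mass)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Reversible amino-acid CTMC with optional discrete-Γ rate variation.

    ``exchangeabilities`` is the symmetric matrix S (diagonal ignored);
    Q = S diag(pi) with the diagonal set so rows sum to zero, scaled to one
    expected substitution per site per unit branch length.
    """

    exchangeabilities: np.ndarray = None
    stationary_freqs: np.ndarray = None
    gamma_shape: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        if self.exchangeabilities is None:
            self.exchangeabilities = np.ones((20, 20))
        if self.stationary_freqs is None:
            self.stationary_freqs = np.full(20, 1.0 / 20.0)
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.stationary_freqs, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        if np.any(S < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if pi.shape != (20,) or np.any(pi <= 0):
            raise ValueError("stationary_freqs must be 20 positive probabilities")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("stationary_freqs must sum to 1 within 1e-12")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive or None")
        self.stationary_freqs = pi
        self.exchangeabilities = S
        self._build()

    def _build(self):
        S = self.exchangeabilities.copy()
        np.fill_diagonal(S, 0.0)
        pi = self.stationary_freqs
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        Q /= scale
        self.rate_matrix = Q
        # symmetrized eigendecomposition: B = D^{1/2} Q D^{-1/2} is symmetric
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
        # P(t) = U exp(evals t) Ut with U = D^{-1/2} V, Ut = V^T D^{1/2}
        self._evals = evals
        self._U = evecs / sq[:, None]
        self._Ut = (evecs * sq[:, None]).T

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def with_gamma_shape(self, shape: float | None) -> "SubstitutionModel":
        return SubstitutionModel(
            exchangeabilities=self.exchangeabilities.copy(),
            stationary_freqs=self.stationary_freqs.copy(),
            gamma_shape=shape,
            n_categories=self.n_categories,
        )


def poisson_model(gamma_shape: float | None = None, n_categories: int = 4) -> SubstitutionModel:
    """Poisson (equal-rates, uniform-frequency) amino-acid model."""
    return SubstitutionModel(gamma_shape=gamma_shape, n_categories=n_categories)


def load_model_file(path, gamma_shape: float | None = None, n_categories: int = 4) -> SubstitutionModel:
    """Read a whitespace-delimited 20x20 exchangeability matrix + 20 frequencies."""
    vals = np.loadtxt(path).ravel()
    if vals.size != 420:
        raise ValueError(f"{path}: expected 400 matrix entries + 20 frequencies")
    S = vals[:400].reshape(20, 20)
    pi = vals[400:]
    pi = pi / pi.sum()
    return SubstitutionModel(S, pi, gamma_shape, n_categories)


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries clamped at >= 0."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    P = (model._U * np.exp(model._evals * t)[None, :]) @ model._Ut
    np.maximum(P, 0.0, out=P)
    return P


def _transition_matrices(model, t: float, rates: np.ndarray) -> np.ndarray:
    """(ncat, 20, 20) stack of P(rate_c * t)."""
    ex = np.exp(model._evals[None, :] * (rates[:, None] * t))
    return np.einsum("ik,ck,kj->cij", model._U, ex, model._Ut)


# -- alignments -------------------------------------------------------------

@dataclass
class Alignment:
    """A fixed-length amino-acid alignment keyed by taxon label."""

    sequences: dict[str, str]
    gene_id: str = "gene"

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        if not self.sequences:
            raise ValueError("empty alignment")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.sequences))

    def encoded(self, taxa_order) -> np.ndarray:
        """Integer matrix (n_taxa, n_sites); 20 marks missing data."""
        lut = np.full(256, 255, dtype=np.uint8)
        for ch, i in _AA_INDEX.items():
            lut[ord(ch)] = i
            lut[ord(ch.lower())] = i
        for ch in MISSING_CHARS:
            lut[ord(ch)] = 20
            lut[ord(ch.lower())] = 20
        mat = np.empty((len(taxa_order), self.length), dtype=np.uint8)
        for r, taxon in enumerate(taxa_order):
            raw = np.frombuffer(self.sequences[taxon].encode("ascii"), dtype=np.uint8)
            row = lut[raw]
            if np.any(row == 255):
                c = int(np.argmax(row == 255))
                raise ValueError(
                    f"unknown residue {self.sequences[taxon][c]!r} at column "
                    f"{c + 1} of taxon {taxon!r}"
                )
            mat[r] = row
        return mat

    @classmethod
    def from_fasta(cls, path, gene_id: str | None = None) -> "Alignment":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"{path}: no sequences")
        import os

        gid = gene_id or os.path.splitext(os.path.basename(str(path)))[0]
        return cls(seqs, gene_id=gid)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon in self.taxa:
                fh.write(f">{taxon}\n{self.sequences[taxon]}\n")


# -- rooted computation view ------------------------------------------------

class _RootedView:
    """A rooted traversal of an unrooted topology for pruning.

    Root is the internal node adjacent to the lexicographically smallest
    leaf (deterministic).  ``edge_of[node]`` maps each non-root node to the
    index of its parent edge in the topology's canonical edge order.
    """

    def __init__(self, topology: Topology):
        skel = topology._skeleton
        adj = skel.adj
        smallest = min(skel.leaf_label.values())
        leaf0 = skel._label_to_node[smallest]
        root = next(iter(adj[leaf0]))
        parent: dict[int, int | None] = {root: None}
        order = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    order.append(v)
                    stack.append(v)
        leafset: dict[int, frozenset] = {}
        key_of: dict[int, tuple] = {}
        for u in reversed(order):
            if u in skel.leaf_label:
                leafset[u] = frozenset([skel.leaf_label[u]])
            else:
                leafset[u] = frozenset().union(
                    *(leafset[v] for v in adj[u] if v != parent[u])
                )
            if parent[u] is not None:
                side = leafset[u]
                if smallest in side:
                    side = frozenset(skel.leaf_label.values()) - side
                key_of[u] = tuple(sorted(side))

        index = {k: i for i, k in enumerate(topology.edge_order)}
        self.root = root
        self.parent = parent
        self.preorder = order
        self.postorder = list(reversed(order))
        self.children = {u: [v for v in adj[u] if v != parent[u]] for u in order}
        self.leaf_name = dict(skel.leaf_label)
        self.edge_of = {u: index[k] for u, k in key_of.items()}
        self.nodes = order


def _rooted_view(topology: Topology) -> _RootedView:
    view = getattr(topology, "_rooted_view", None)
    if view is None:
        view = _RootedView(topology)
        object.__setattr__(topology, "_rooted_view", view)
    return view


def _compress(alignment: Alignment, taxa_order) -> tuple[np.ndarray, np.ndarray]:
    mat = alignment.encoded(taxa_order)
    patterns, weights = np.unique(mat.T, axis=0, return_counts=True)
    return patterns.T, weights.astype(float)  # (n_taxa, n_patterns)


class _Pruner:
    """Shared state for likelihood evaluation of one gene."""

    def __init__(self, alignment: Alignment, topology: Topology, model: SubstitutionModel):
        taxa = set(alignment.sequences)
        leaves = set(topology.leaf_labels)
        if taxa != leaves:
            raise ValueError(
                f"alignment taxa do not match topology leaves: {sorted(taxa ^ leaves)}"
            )
        self.view = _rooted_view(topology)
        self.model = model
        self.topology = topology
        taxa_order = [
            self.view.leaf_name[u] for u in self.view.nodes if u in self.view.leaf_name
        ]
        self.leaf_nodes = [u for u in self.view.nodes if u in self.view.leaf_name]
        pats, self.weights = _compress(alignment, taxa_order)
        self.n_patterns = pats.shape[1]
        self.leaf_partial = {}
        eye = np.vstack([np.eye(20), np.ones(20)])  # row 20 = missing
        for row, node in enumerate(self.leaf_nodes):
            self.leaf_partial[node] = eye[pats[row]]  # (npat, 20)
        self.rates = model.category_rates()
        self.ncat = len(self.rates)
        self.pi = model.stationary_freqs

    def set_gamma_shape(self, shape: float | None):
        self.model = self.model.with_gamma_shape(shape)
        self.rates = self.model.category_rates()
        self.ncat = len(self.rates)

    def _P(self, t: float) -> np.ndarray:
        return _transition_matrices(self.model, max(t, 0.0), self.rates)

    def down_partials(self, lengths: np.ndarray) -> dict[int, np.ndarray]:
        """Post-order conditional likelihoods, (ncat, npat, 20) per node."""
        view = self.view
        down: dict[int, np.ndarray] = {}
        for u in view.postorder:
            acc = None
            for v in view.children[u]:
                P = self._P(lengths[view.edge_of[v]])
                term = np.einsum("cij,cpj->cpi", P, down[v])
                acc = term if acc is None else acc * term
            if u in self.leaf_partial:
                lp = np.broadcast_to(
                    self.leaf_partial[u], (self.ncat,) + self.leaf_partial[u].shape
                )
                acc = lp if acc is None else acc * lp
            down[u] = acc
        return down

    def loglik_from_down(self, down) -> float:
        L = np.einsum("cpi,i->p", down[self.view.root], self.pi) / self.ncat
        if np.any(L <= 0) or not np.all(np.isfinite(L)):
            bad = int(np.argmin(L))
            raise FloatingPointError(
                f"non-finite site likelihood at pattern {bad}"
            )
        return float(self.weights @ np.log(L))

    def loglik(self, lengths: np.ndarray) -> float:
        return self.loglik_from_down(self.down_partials(lengths))


def pruning_loglik(
    alignment: Alignment,
    topology: Topology,
    branch_lengths: np.ndarray,
    model: SubstitutionModel,
) -> float:
    """Log-likelihood of the alignment on the fixed topology.

    Felsenstein pruning over compressed site patterns; each site's likelihood
    is averaged over the discrete-Γ categories with equal weights; gaps and
    ambiguities contribute all-ones partials.
    """
    branch_lengths = np.asarray(branch_lengths, dtype=float)
    if branch_lengths.shape != (topology.n_edges,):
        raise ValueError("branch_lengths must align with topology.edge_order")
    if np.any(branch_lengths < 0):
        raise ValueError("branch lengths must be >= 0")
    return _Pruner(alignment, topology, model).loglik(branch_lengths)


def _optimize_edges_sweep(pruner: _Pruner, lengths: np.ndarray, xatol: float) -> None:
    """One exact coordinate sweep over all edges (in place).

    Maintains inside (``down``) and outside (``A``) partials so each
    single-edge objective costs one small matrix product per evaluation.
    The outside vector at node u already includes the stationary frequencies,
    so the likelihood of pattern p as a function of one branch length t is
    mean_c  A[c,p,:] . P_c(t) . down[c,p,:].
    """
    view = pruner.view
    down = pruner.down_partials(lengths)

    def edge_objective(A, d):
        def nll(t):
            P = pruner._P(t)
            Pd = np.einsum("cij,cpj->cpi", P, d)
            L = np.einsum("cpi,cpi->p", A, Pd) / pruner.ncat
            if np.any(L <= 0):
                return np.inf
            return -float(pruner.weights @ np.log(L))

        return nll

    def recurse(u: int, a_u: np.ndarray):
        for v in view.children[u]:
            sib = a_u
            for w in view.children[u]:
                if w is v:
                    continue
                P = pruner._P(lengths[view.edge_of[w]])
                sib = sib * np.einsum("cij,cpj->cpi", P, down[w])
            e = view.edge_of[v]
            res = minimize_scalar(
                edge_objective(sib, down[v]),
                bounds=(BL_MIN, BL_MAX),
                method="bounded",
                options={"xatol": xatol},
            )
            if np.isfinite(res.fun):
                lengths[e] = float(res.x)
            P = pruner._P(lengths[e])
            a_v = np.einsum("cij,cpi->cpj", P, sib)
            recurse(v, a_v)
            if view.children[v]:  # refresh down[v] with updated subtree
                acc = None
                for w in view.children[v]:
                    Pw = pruner._P(lengths[view.edge_of[w]])
                    term = np.einsum("cij,cpj->cpi", Pw, down[w])
                    acc = term if acc is None else acc * term
                down[v] = acc

    a_root = np.broadcast_to(
        pruner.pi, (pruner.ncat, pruner.n_patterns, 20)
    ).copy()
    if view.root in pruner.leaf_partial:  # 2-taxon tree rooted at a leaf
        a_root *= pruner.leaf_partial[view.root][None, :, :]
    recurse(view.root, a_root)


def optimize_branch_lengths(
    alignment: Alignment,
    topology: Topology,
    model: SubstitutionModel,
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    n_restarts: int = 10,
    optimize_gamma: bool = False,
    seed: int = 0,
    max_sweeps: int = 100,
    gene_id: str | None = None,
) -> GeneTree:
    """Maximum-likelihood branch lengths on the fixed topology.

    Coordinate-wise bracketed scalar optimization of each branch, swept until
    the total log-likelihood improves by less than ``tol``; the best of
    ``n_restarts`` random initializations (the supplied ``init`` seeds the
    first) is kept.  With ``optimize_gamma`` the Γ shape is co-estimated by
    the same scalar method, alternating with branch sweeps.
    """
    rng = np.random.default_rng(seed)
    pruner = _Pruner(alignment, topology, model)
    n_edges = topology.n_edges
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape != (n_edges,):
            raise ValueError("init must align with topology.edge_order")
        if np.any(init < BL_MIN) or np.any(init > BL_MAX):
            raise ValueError(f"init lengths must lie in [{BL_MIN}, {BL_MAX}]")

    xatol = min(1e-7, tol)
    best_ll = -np.inf
    best_lengths = None
    best_shape = model.gamma_shape

    for restart in range(max(1, n_restarts)):
        if restart == 0 and init is not None:
            lengths = init.copy()
        else:
            lengths = np.exp(rng.uniform(np.log(0.005), np.log(1.0), size=n_edges))
        if optimize_gamma:
            pruner.set_gamma_shape(model.gamma_shape or 1.0)
        ll = pruner.loglik(lengths)
        for _ in range(max_sweeps):
            _optimize_edges_sweep(pruner, lengths, xatol)
            if optimize_gamma:
                def neg(shape_log):
                    pruner.set_gamma_shape(float(np.exp(shape_log)))
                    return -pruner.loglik(lengths)

                res = minimize_scalar(
                    neg, bounds=(np.log(0.02), np.log(100.0)), method="bounded",
                    options={"xatol": 1e-4},
                )
                pruner.set_gamma_shape(float(np.exp(res.x)))
            new_ll = pruner.loglik(lengths)
            if new_ll < ll - 1e-6:
                raise FloatingPointError(
                    f"log-likelihood decreased during sweep ({ll} -> {new_ll})"
                )
            if new_ll - ll < tol:
                ll = new_ll
                break
            ll = new_ll
        if ll > best_ll:
            best_ll = ll
            best_lengths = lengths.copy()
            best_shape = pruner.model.gamma_shape if optimize_gamma else model.gamma_shape

    tree = GeneTree(
        gene_id or alignment.gene_id, topology, best_lengths, loglik=best_ll
    )
    tree.gamma_shape = best_shape
    return tree


def simulate_alignment(
    topology: Topology,
    branch_lengths: np.ndarray,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
    gene_id: str = "sim",
) -> Alignment:
    """Simulate an alignment down the fixed topology.

    Per site: draw a Γ category, draw the root state from the stationary
    frequencies, and propagate state changes along each edge with
    P(rate * t).  Deterministic for a fixed seed.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    branch_lengths = np.asarray(branch_lengths, dtype=float)
    if branch_lengths.shape != (topology.n_edges,):
        raise ValueError("branch_lengths must align with topology.edge_order")
    rng = np.random.default_rng(seed)
    view = _rooted_view(topology)
    rates = model.category_rates()
    ncat = len(rates)
    cat = rng.integers(0, ncat, size=n_sites)
    pi = model.stationary_freqs

    states = {view.root: rng.choice(20, size=n_sites, p=pi)}
    for u in view.preorder:
        if u is view.root:
            continue
        t = branch_lengths[view.edge_of[u]]
        parent_states = states[view.parent[u]]
        child = np.empty(n_sites, dtype=np.int64)
        for c in range(ncat):
            mask = cat == c
            if not np.any(mask):
                continue
            P = transition_matrix(model, rates[c] * t)
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0
            u01 = rng.random(mask.sum())
            child[mask] = (u01[:, None] > cum[parent_states[mask]]).sum(axis=1)
        states[u] = child

    seqs = {}
    for node, name in view.leaf_name.items():
        seqs[name] = "".join(AA_ALPHABET[s] for s in states[node])
    return Alignment(seqs, gene_id=gene_id)
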