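"""Topology-congruence screening.

Before branch-length patterns can be compared across genes, all gene trees
must share one topology.  This module screens for incongruence the way the
pacemaker analysis does: pairwise PH85 (Robinson-Foulds) distances between
gene-tree topologies, a classical (Torgerson) 2-D multidimensional-scaling
embedding of that distance matrix, k-medoids (PAM, Voronoi-iteration
variant) clustering of the embedded points, and the Gap statistic of
Tibshirani to choose the number of clusters.  A single chosen cluster means
the gene trees are mutually congruent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .trees_io import PhyloTree, Topology, rf_distance


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("distance matrix must be exactly symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class MdsEmbedding:
    ids: tuple[str, ...]
    coordinates: np.ndarray  # (n, dims)


@dataclass
class PamResult:
    k: int
    medoid_indices: tuple[int, ...]
    assignment: np.ndarray  # point -> medoid position in medoid_indices
    cost: float

    def medoid_ids(self, ids):
        return tuple(ids[m] for m in self.medoid_indices)


@dataclass
class GapCurve:
    k_values: np.ndarray
    gap: np.ndarray
    sd: np.ndarray
    chosen_k: int


def pairwise_topology_distances(
    gene_trees: "list[tuple[str, PhyloTree]] | list",
) -> DistanceMatrix:
    """PH85 distance between every pair of gene-tree topologies."""
    items = []
    for entry in gene_trees:
        if isinstance(entry, tuple):
            items.append(entry)
        else:  # GeneTree
            items.append((entry.gene_id, entry.topology))
    if len(items) < 2:
        raise ValueError("need at least 2 trees")
    ids = tuple(g for g, _ in items)
    n = len(items)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = rf_distance(items[i][1], items[j][1])
    return DistanceMatrix(ids, D)


def classical_mds(distance_matrix: DistanceMatrix, dims: int = 2) -> MdsEmbedding:
    """Torgerson scaling of a distance matrix.

    Double-centers -D^2/2, takes the top ``dims`` eigenpairs and scales the
    eigenvectors by the square roots of the (non-negative-clamped)
    eigenvalues.  Reproduces a Euclidean input exactly when its intrinsic
    dimension is at most ``dims``.
    """
    D = distance_matrix.values
    n = D.shape[0]
    B = -0.5 * D**2
    B = B - B.mean(axis=0, keepdims=True) - B.mean(axis=1, keepdims=True) + B.mean()
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    if coords.shape[1] < dims:
        coords = np.pad(coords, ((0, 0), (0, dims - coords.shape[1])))
    return MdsEmbedding(distance_matrix.ids, coords)


def _assign(D_to_medoids: np.ndarray) -> np.ndarray:
    # argmin breaks ties by lowest medoid index
    return np.argmin(D_to_medoids, axis=1)


def pam_cluster(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 200,
) -> PamResult:
    """k-medoids by Voronoi iteration with random restarts.

    Start from ``k`` random data points as medoids; alternate (a) assigning
    every point to its nearest medoid and (b) replacing each medoid by the
    cluster member minimizing the total within-cluster distance, until the
    assignment stabilizes.  The cost (sum of distances to assigned medoids)
    never increases across iterations; the best of ``n_restarts`` runs wins.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    D = squareform(pdist(points))
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_restarts)):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        assignment = _assign(D[:, medoids])
        cost = D[np.arange(n), medoids[assignment]].sum()
        for _ in range(max_iter):
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(assignment == c)
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=0)
                new_medoids[c] = members[np.argmin(within)]
            new_assignment = _assign(D[:, new_medoids])
            new_cost = D[np.arange(n), new_medoids[new_assignment]].sum()
            if new_cost > cost + 1e-12:
                raise AssertionError("PAM cost increased; medoid update is broken")
            if np.array_equal(new_assignment, assignment) and np.array_equal(
                new_medoids, medoids
            ):
                break
            medoids, assignment, cost = new_medoids, new_assignment, new_cost
        if best is None or cost < best.cost:
            best = PamResult(k, tuple(int(m) for m in medoids), assignment.copy(), float(cost))
    return best


def _pooled_within_dispersion(points: np.ndarray, labels: np.ndarray) -> float:
    """W_k = sum over clusters of (sum of pairwise distances) / (2 * size)."""
    W = 0.0
    for c in np.unique(labels):
        members = points[labels == c]
        if members.shape[0] < 2:
            continue
        W += pdist(members).sum() / members.shape[0]  # pdist counts each pair once
    return W


def gap_statistic(
    points: np.ndarray,
    k_max: int = 50,
    n_reference: int = 50,
    seed: int = 0,
    n_restarts: int = 10,
    use_one_se_rule: bool = False,
) -> GapCurve:
    """Gap statistic for choosing the number of PAM clusters.

    For each k in 1..k_max, the within-cluster dispersion W_k of the data is
    compared with W_k of ``n_reference`` datasets drawn uniformly over the
    per-feature bounding box of the points: gap(k) = mean_b log W_k(ref_b) -
    log W_k(data).  ``chosen_k`` is the global argmax (first occurrence on
    ties); the 1-SE rule of Tibshirani is available as an option.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if k_max > n:
        raise ValueError("k_max must not exceed the number of points")
    rng = np.random.default_rng(seed)

    lo = points.min(axis=0)
    hi = points.max(axis=0)
    if np.all(hi - lo == 0):
        warnings.warn("degenerate bounding box (all points identical); choosing k=1")
        ks = np.arange(1, k_max + 1)
        return GapCurve(ks, np.zeros(k_max), np.zeros(k_max), 1)

    ks = np.arange(1, k_max + 1)
    log_w = np.empty(k_max)
    log_w_ref = np.empty((n_reference, k_max))
    refs = [rng.uniform(lo, hi, size=points.shape) for _ in range(n_reference)]
    ref_seeds = rng.integers(0, 2**31 - 1, size=(n_reference, k_max))
    data_seeds = rng.integers(0, 2**31 - 1, size=k_max)

    def _log_w(pts, k, s):
        if k == 1:
            labels = np.zeros(pts.shape[0], dtype=int)
        else:
            labels = pam_cluster(pts, k, seed=int(s), n_restarts=n_restarts).assignment
        w = _pooled_within_dispersion(pts, labels)
        return np.log(w) if w > 0 else -np.inf

    for ki, k in enumerate(ks):
        log_w[ki] = _log_w(points, k, data_seeds[ki])
        for b in range(n_reference):
            log_w_ref[b, ki] = _log_w(refs[b], k, ref_seeds[b, ki])

    gap = log_w_ref.mean(axis=0) - log_w
    sd = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_reference)

    if use_one_se_rule:
        chosen = int(ks[-1])
        for ki in range(k_max - 1):
            if gap[ki] >= gap[ki + 1] - sd[ki + 1]:
                chosen = int(ks[ki])
                break
    else:
        chosen = int(ks[np.argmax(gap)])
    return GapCurve(ks, gap, sd, chosen)
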