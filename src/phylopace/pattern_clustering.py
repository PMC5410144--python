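"""Clustering genes by branch-length *pattern*.

A gene's overall rate (its "gene effect") scales every branch of its tree by
the same factor; the lineage-effect signal lives in the *relative* branch
lengths.  Dividing each branch vector by its tree length (row sum 1) removes
the gene effect exactly, so two genes with proportional trees land on the
same point.  The normalized genes-by-edges matrix is then clustered with a
diagonal-covariance Gaussian mixture model fitted by EM (scikit-learn),
at a user-chosen number of components K per clustering scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .trees_io import GeneTree

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-10


@dataclass
class PatternMatrix:
    """Genes x edges matrix of rate-normalized (unit-sum) branch lengths."""

    gene_ids: tuple[str, ...]
    matrix: np.ndarray
    dropped: tuple[str, ...] = ()

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.gene_ids):
            raise ValueError("row count does not match gene_ids")
        if self.matrix.shape[0] and not np.allclose(
            self.matrix.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("pattern rows must sum to 1 (rate-normalized)")


@dataclass
class ClusterAssignment:
    """Gene-to-component labels for one GMM clustering scheme."""

    n_clusters: int
    gene_ids: tuple[str, ...]
    labels: np.ndarray
    responsibilities: np.ndarray
    loglik: float
    seed: int

    def label_of(self) -> dict[str, int]:
        return dict(zip(self.gene_ids, (int(x) for x in self.labels)))


def normalize_branch_vectors(
    gene_trees: list[GeneTree], log_ratio: bool = False
) -> PatternMatrix:
    """Divide each gene's branch vector by its tree length.

    Genes with zero tree length carry no pattern information and are dropped
    with a logged warning (ids recorded in ``dropped``).  The off-by-default
    ``log_ratio`` variant returns centered log-ratios of the normalized
    vectors instead (rows then no longer sum to 1, so it returns a plain
    matrix wrapped with ``dropped`` bookkeeping only).
    """
    kept, rows, dropped = [], [], []
    for gt in gene_trees:
        tl = gt.tree_length
        if tl <= 0:
            dropped.append(gt.gene_id)
            continue
        kept.append(gt.gene_id)
        rows.append(gt.branch_lengths / tl)
    if dropped:
        logger.warning(
            "dropped %d zero-length gene trees from pattern matrix: %s",
            len(dropped),
            ", ".join(dropped[:10]),
        )
    mat = np.array(rows) if rows else np.empty((0, 0))
    if log_ratio:
        eps = 1e-12
        logm = np.log(mat + eps)
        clr = logm - logm.mean(axis=1, keepdims=True)
        pm = PatternMatrix.__new__(PatternMatrix)
        pm.gene_ids = tuple(kept)
        pm.matrix = clr
        pm.dropped = tuple(dropped)
        return pm
    return PatternMatrix(tuple(kept), mat, tuple(dropped))


def fit_gmm(
    pattern_matrix: PatternMatrix,
    n_clusters: int,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusterAssignment:
    """Fit a K-component diagonal-covariance Gaussian mixture by EM.

    Best of ``n_init`` k-means++-seeded initializations by log-likelihood;
    deterministic for a fixed seed.  Component variances are floored at
    ``VARIANCE_FLOOR`` so exact duplicate rows cannot collapse a component.
    """
    X = pattern_matrix.matrix
    n = X.shape[0]
    if n_clusters > n:
        raise ValueError(f"K={n_clusters} exceeds the number of genes ({n})")
    gmm = GaussianMixture(
        n_components=n_clusters,
        covariance_type="diag",
        n_init=n_init,
        tol=tol,
        max_iter=max_iter,
        reg_covar=VARIANCE_FLOOR,
        init_params="k-means++",
        random_state=seed,
    )
    gmm.fit(X)
    if not gmm.converged_:
        logger.warning("GMM (K=%d) did not converge within %d iterations", n_clusters, max_iter)
    resp = gmm.predict_proba(X)
    labels = np.argmax(resp, axis=1)
    loglik = float(gmm.score(X) * n)
    return ClusterAssignment(
        n_clusters=n_clusters,
        gene_ids=pattern_matrix.gene_ids,
        labels=labels,
        responsibilities=resp,
        loglik=loglik,
        seed=seed,
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same genes.

    Accepts dicts (gene -> label) or aligned sequences; dicts are matched by
    gene id and must cover the same set.
    """
    if isinstance(labels_a, dict) or isinstance(labels_b, dict):
        if not (isinstance(labels_a, dict) and isinstance(labels_b, dict)):
            raise ValueError("labelings must both be dicts or both sequences")
        if set(labels_a) != set(labels_b):
            raise ValueError("labelings cover different gene sets")
        keys = sorted(labels_a)
        a = [labels_a[k] for k in keys]
        b = [labels_b[k] for k in keys]
    else:
        a, b = list(labels_a), list(labels_b)
        if len(a) != len(b):
            raise ValueError("labelings have different lengths")
    return float(adjusted_rand_score(a, b))
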