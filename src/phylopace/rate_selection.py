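"""Evolutionary rate versus branch-length-pattern dispersion.

The headline analysis: genes are ranked by tree length (the rate proxy) and
split into deciles (decile 10 = fastest 10%); for each clustering scheme the
number of distinct branch-length-pattern clusters represented in each decile
is counted; the decile-vs-count association is tested with a Kendall rank
correlation (tau-b, tie-corrected).  A sensitivity variant drops the slowest
deciles, an EC summary reports clusters-per-gene by top-level enzyme class,
and a random-forest classifier measures how well tree length, Kr/Kc and EC
class predict a gene's cluster assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.ensemble import RandomForestClassifier

from .pattern_clustering import ClusterAssignment


@dataclass
class KendallResult:
    tau: float
    p_value: float
    n: int
    method: str = "asymptotic"


@dataclass
class ImportanceReport:
    importances: dict[str, float]            # unnormalized mean decrease in impurity
    importances_normalized: dict[str, float]  # scaled to sum 1
    single_feature_accuracy: dict[str, float]  # per-feature OOB accuracy
    oob_accuracy: float


def rank_into_deciles(tree_lengths: "dict[str, float] | pd.Series") -> pd.DataFrame:
    """Assign each gene to a tree-length decile (1 = slowest, 10 = fastest).

    Stable ascending sort with ties broken by gene id; the gene of 1-based
    rank r among n genes gets decile ceil(10 r / n), so decile sizes differ
    by at most one.
    """
    s = pd.Series(tree_lengths, dtype=float)
    n = len(s)
    if n < 10:
        raise ValueError(f"need at least 10 genes to form deciles, got {n}")
    if not np.all(np.isfinite(s.to_numpy())) or np.any(s.to_numpy() <= 0):
        raise ValueError("tree lengths must be finite and positive")
    df = pd.DataFrame({"gene_id": s.index.astype(str), "tree_length": s.to_numpy()})
    df = df.sort_values(["tree_length", "gene_id"], kind="stable").reset_index(drop=True)
    ranks = np.arange(1, n + 1)
    df["decile"] = np.ceil(10 * ranks / n).astype(int)
    return df


def clusters_per_decile(
    decile_table: pd.DataFrame, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Distinct cluster labels represented in each tree-length decile."""
    label_of = assignment.label_of()
    missing = [g for g in decile_table["gene_id"] if g not in label_of]
    if missing:
        raise ValueError(f"genes missing a cluster label: {missing[:5]}")
    df = decile_table.copy()
    df["label"] = [label_of[g] for g in df["gene_id"]]
    out = (
        df.groupby("decile")
        .agg(n_genes=("gene_id", "size"), clusters_represented=("label", "nunique"))
        .reset_index()
    )
    out.insert(0, "scheme", assignment.n_clusters)
    return out


def _tau_b_stats(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            conc += s > 0
            disc += s < 0

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return sum(c * (c - 1) / 2 for c in counts)

    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tie_term(x)) * (n0 - tie_term(y)))
    if denom == 0:
        raise ValueError("tau undefined: zero variance in x or y")
    return (conc - disc) / denom


def kendall_tau(x, y, method: str = "asymptotic") -> KendallResult:
    """Kendall tau-b with a two-sided p-value.

    ``asymptotic`` uses the tie-adjusted normal approximation; ``exact``
    enumerates all permutations of y (n <= 10) and reports the fraction with
    |tau| at least the observed value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined: zero variance in x or y")

    if method == "asymptotic":
        res = kendalltau(x, y, variant="b", method="asymptotic")
        return KendallResult(float(res.statistic), float(res.pvalue), n, "asymptotic")
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        tau_obs = _tau_b_stats(x, y)
        count = total = 0
        for perm in permutations(y):
            t = _tau_b_stats(x, np.asarray(perm))
            count += abs(t) >= abs(tau_obs) - 1e-12
            total += 1
        return KendallResult(float(tau_obs), count / total, n, "exact")
    raise ValueError(f"unknown method {method!r}")


def rate_dispersion_test(
    representation: pd.DataFrame, method: str = "asymptotic"
) -> KendallResult:
    """Kendall test of decile index against clusters represented."""
    rep = representation.sort_values("decile")
    return kendall_tau(
        rep["decile"].to_numpy(), rep["clusters_represented"].to_numpy(), method=method
    )


def exclusion_sensitivity(
    decile_table: pd.DataFrame,
    assignment: ClusterAssignment,
    n_excluded: int = 2,
    method: str = "asymptotic",
) -> KendallResult:
    """Re-test after dropping the slowest ``n_excluded`` deciles of genes."""
    if not 0 <= n_excluded <= 8:
        raise ValueError("n_excluded must be in [0, 8]")
    rep = clusters_per_decile(decile_table, assignment)
    rep = rep[rep["decile"] > n_excluded]
    return rate_dispersion_test(rep, method=method)


def ec_cluster_representation(
    annotations: pd.DataFrame, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Clusters-per-gene for each top-level EC class.

    ``annotations`` maps a subset of gene ids to one EC class in 1..6;
    unannotated genes are excluded.  The clusters-per-gene ratio corrects
    for the imbalance in gene counts across classes.
    """
    ann = annotations[["gene_id", "ec_class"]].copy()
    ann["ec_class"] = ann["ec_class"].astype(int)
    if not ann["ec_class"].isin(range(1, 7)).all():
        bad = sorted(set(ann["ec_class"]) - set(range(1, 7)))
        raise ValueError(f"EC classes outside 1-6: {bad}")
    label_of = assignment.label_of()
    ann = ann[ann["gene_id"].isin(label_of)]
    ann["label"] = [label_of[g] for g in ann["gene_id"]]
    out = (
        ann.groupby("ec_class")
        .agg(n_genes=("gene_id", "size"), n_clusters_represented=("label", "nunique"))
        .reset_index()
    )
    out["clusters_per_gene"] = out["n_clusters_represented"] / out["n_genes"]
    return out


def fit_importance_classifier(
    features: pd.DataFrame,
    labels,
    seed: int = 0,
    n_trees: int = 500,
) -> ImportanceReport:
    """Random-forest prediction of cluster labels from gene-level features.

    ``features`` columns: ``tree_length`` and ``krkc`` (numeric; NaN Kr/Kc
    imputed with the median) and ``ec`` (categorical; missing becomes an
    explicit ``unknown`` category).  Reports per-feature Gini
    (mean-decrease-impurity) importance both unnormalized and normalized,
    a per-feature single-variable OOB accuracy, and the full-model OOB
    accuracy.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 distinct cluster labels")
    cols = ["tree_length", "krkc", "ec"]
    X = features[cols].copy()
    X["ec"] = X["ec"].fillna("unknown").astype(str)
    X["ec"] = pd.Categorical(X["ec"]).codes
    X["krkc"] = X["krkc"].astype(float)
    X["krkc"] = X["krkc"].fillna(X["krkc"].median())
    Xv = X.to_numpy(dtype=float)

    def forest(data):
        rf = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
        )
        rf.fit(data, y)
        return rf

    rf = forest(Xv)
    raw = np.mean(
        [t.tree_.compute_feature_importances(normalize=False) for t in rf.estimators_],
        axis=0,
    )
    total = raw.sum()
    norm = raw / total if total > 0 else raw
    single = {}
    for i, c in enumerate(cols):
        single[c] = float(forest(Xv[:, [i]]).oob_score_)
    return ImportanceReport(
        importances=dict(zip(cols, map(float, raw))),
        importances_normalized=dict(zip(cols, map(float, norm))),
        single_feature_accuracy=single,
        oob_accuracy=float(rf.oob_score_),
    )
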