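"""Deciles, cluster representation, Kendall tests, EC and importance reports."""

import math
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest

import phylopace as pp
from phylopace.pattern_clustering import ClusterAssignment
from phylopace.rate_selection import rate_dispersion_test


def make_assignment(label_map, K=None):
    ids = tuple(sorted(label_map))
    labels = np.array([label_map[g] for g in ids])
    K = K or int(labels.max()) + 1
    return ClusterAssignment(
        n_clusters=K, gene_ids=ids, labels=labels,
        responsibilities=np.eye(K)[labels], loglik=0.0, seed=0,
    )


def brute_force_tau_b(x, y):
    n = len(x)
    conc = disc = 0
    for i, j in combinations(range(n), 2):
        s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        conc += s > 0
        disc += s < 0
    n0 = n * (n - 1) / 2

    def ties(v):
        _, c = np.unique(v, return_counts=True)
        return sum(k * (k - 1) / 2 for k in c)

    return (conc - disc) / math.sqrt((n0 - ties(x)) * (n0 - ties(y)))


class TestDeciles:
    def test_twenty_genes_two_per_decile(self):
        lengths = {f"g{i:02d}": float(i + 1) for i in range(20)}
        df = pp.rank_into_deciles(lengths)
        assert df.groupby("decile").size().tolist() == [2] * 10
        top = set(df[df["decile"] == 10]["tree_length"])
        assert top == {19.0, 20.0}

    def test_955_genes_decile_sizes(self):
        lengths = {f"g{i:04d}": float(i + 1) for i in range(955)}
        df = pp.rank_into_deciles(lengths)
        sizes = df.groupby("decile").size()
        assert set(sizes) == {95, 96}
        assert sizes.sum() == 955
        # ceil(10 r / 955) partition arithmetic, checked directly
        expected = [
            sum(1 for r in range(1, 956) if math.ceil(10 * r / 955) == d)
            for d in range(1, 11)
        ]
        assert sizes.tolist() == expected

    def test_ties_broken_by_gene_id(self):
        lengths = {f"g{i:02d}": 1.0 for i in range(10)}
        df = pp.rank_into_deciles(lengths)
        assert df["gene_id"].tolist() == sorted(lengths)
        assert df["decile"].tolist() == list(range(1, 11))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            pp.rank_into_deciles({f"g{i}": 1.0 * (i + 1) for i in range(9)})


class TestClustersPerDecile:
    def test_hand_case(self):
        lengths = {f"g{i:02d}": float(i + 1) for i in range(20)}
        deciles = pp.rank_into_deciles(lengths)
        labels = {g: (0 if i < 3 else 1) for i, g in enumerate(sorted(lengths))}
        rep = pp.clusters_per_decile(deciles, make_assignment(labels))
        # decile 1 holds g00,g01 -> {0}; decile 2 holds g02,g03 -> {0,1}
        assert rep[rep["decile"] == 1]["clusters_represented"].item() == 1
        assert rep[rep["decile"] == 2]["clusters_represented"].item() == 2

    def test_single_label_everywhere(self):
        lengths = {f"g{i:02d}": float(i + 1) for i in range(20)}
        deciles = pp.rank_into_deciles(lengths)
        rep = pp.clusters_per_decile(
            deciles, make_assignment({g: 0 for g in lengths}, K=3)
        )
        assert rep["clusters_represented"].tolist() == [1] * 10

    def test_all_distinct_labels(self):
        lengths = {f"g{i:02d}": float(i + 1) for i in range(20)}
        deciles = pp.rank_into_deciles(lengths)
        rep = pp.clusters_per_decile(
            deciles, make_assignment({g: i for i, g in enumerate(sorted(lengths))})
        )
        assert rep["clusters_represented"].tolist() == rep["n_genes"].tolist()

    def test_invariant_under_label_permutation(self):
        rng = np.random.default_rng(0)
        lengths = {f"g{i:02d}": float(rng.exponential() + 0.1) for i in range(40)}
        deciles = pp.rank_into_deciles(lengths)
        labels = {g: int(rng.integers(0, 4)) for g in lengths}
        permuted = {g: (v + 2) % 4 for g, v in labels.items()}
        a = pp.clusters_per_decile(deciles, make_assignment(labels, K=4))
        b = pp.clusters_per_decile(deciles, make_assignment(permuted, K=4))
        assert a["clusters_represented"].tolist() == b["clusters_represented"].tolist()

    def test_missing_label_rejected(self):
        lengths = {f"g{i:02d}": float(i + 1) for i in range(20)}
        deciles = pp.rank_into_deciles(lengths)
        partial = make_assignment({g: 0 for g in list(sorted(lengths))[:10]})
        with pytest.raises(ValueError):
            pp.clusters_per_decile(deciles, partial)


class TestKendall:
    def test_strictly_decreasing_gives_minus_one(self):
        r = pp.kendall_tau(np.arange(1, 11), np.arange(30, 20, -1))
        assert r.tau == pytest.approx(-1.0)
        assert r.p_value < 0.01

    @pytest.mark.parametrize("seed", range(8))
    def test_tau_b_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.integers(0, 5, n).astype(float)
        y = rng.integers(0, 5, n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        r = pp.kendall_tau(x, y)
        assert r.tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(5)
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = rng.integers(0, 4, 6).astype(float)
        r = pp.kendall_tau(x, y, method="exact")
        tau_obs = brute_force_tau_b(x, y)
        count = sum(
            abs(brute_force_tau_b(x, np.array(p))) >= abs(tau_obs) - 1e-12
            for p in permutations(y)
        )
        assert r.p_value == pytest.approx(count / math.factorial(6))

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 8, 10).astype(float)
        y = rng.integers(0, 8, 10).astype(float)
        assert pp.kendall_tau(x, y).tau == pytest.approx(
            -pp.kendall_tau(x, -y).tau, abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pp.kendall_tau([1, 1, 1, 1], [1, 2, 3, 4])


class TestExclusionSensitivity:
    def _deciles_and_assignment(self, counts):
        """Build 100 genes whose clusters-per-decile match ``counts``."""
        lengths = {f"g{i:03d}": float(i + 1) for i in range(100)}
        deciles = pp.rank_into_deciles(lengths)
        labels = {}
        for d, cnt in zip(range(1, 11), counts):
            members = deciles[deciles["decile"] == d]["gene_id"]
            for i, g in enumerate(members):
                labels[g] = i % cnt
        return deciles, make_assignment(labels, K=10)

    def test_monotone_counts_give_minus_one_on_eight_points(self):
        deciles, asg = self._deciles_and_assignment([10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        r = pp.exclusion_sensitivity(deciles, asg, n_excluded=2)
        assert r.n == 8
        assert r.tau == pytest.approx(-1.0)

    def test_flat_head_exclusion_strengthens_trend(self):
        counts = [5, 5, 8, 7, 6, 5, 4, 3, 2, 1]
        deciles, asg = self._deciles_and_assignment(counts)
        full = rate_dispersion_test(pp.clusters_per_decile(deciles, asg))
        excl = pp.exclusion_sensitivity(deciles, asg, n_excluded=2)
        assert abs(excl.tau) > abs(full.tau)

    def test_excluding_too_many_rejected(self):
        deciles, asg = self._deciles_and_assignment([2] * 10)
        with pytest.raises(ValueError):
            pp.exclusion_sensitivity(deciles, asg, n_excluded=9)


class TestEcSummary:
    def test_ratio_examples(self):
        ann = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(13)],
                "ec_class": [1] * 3 + [2] * 10,
            }
        )
        labels = {f"g{i}": i for i in range(3)}  # class 1: three clusters
        labels.update({f"g{i}": 7 for i in range(3, 13)})  # class 2: one cluster
        out = pp.ec_cluster_representation(ann, make_assignment(labels, K=10))
        row1 = out[out["ec_class"] == 1].iloc[0]
        row2 = out[out["ec_class"] == 2].iloc[0]
        assert row1["clusters_per_gene"] == pytest.approx(1.0)
        assert row2["clusters_per_gene"] == pytest.approx(0.1)

    def test_unannotated_genes_excluded(self):
        ann = pd.DataFrame({"gene_id": ["g0", "g1"], "ec_class": [1, 2]})
        asg = make_assignment({"g0": 0, "g1": 1, "g2": 2})
        out = pp.ec_cluster_representation(ann, asg)
        assert out["n_genes"].sum() == 2

    def test_invalid_class_rejected(self):
        ann = pd.DataFrame({"gene_id": ["g0"], "ec_class": [7]})
        with pytest.raises(ValueError):
            pp.ec_cluster_representation(ann, make_assignment({"g0": 0, "g1": 1}))


class TestImportance:
    def test_planted_signal_dominates(self):
        rng = np.random.default_rng(0)
        n = 300
        labels = rng.integers(0, 3, n)
        feats = pd.DataFrame(
            {
                "tree_length": labels * 10.0 + rng.normal(0, 0.1, n),  # separates
                "krkc": rng.normal(0, 1, n),                            # noise
                "ec": rng.integers(1, 7, n).astype(str),                # noise
            }
        )
        rep = pp.fit_importance_classifier(feats, labels, seed=0, n_trees=200)
        # deep noise splits soak up a little impurity, so dominance not purity
        assert rep.importances_normalized["tree_length"] >= 0.8
        assert rep.importances_normalized["krkc"] <= 0.12
        assert rep.importances_normalized["ec"] <= 0.12
        assert rep.single_feature_accuracy["tree_length"] > 0.95
        assert rep.oob_accuracy > 0.95

    def test_pure_noise_symmetric(self):
        rng = np.random.default_rng(1)
        n = 400
        labels = rng.integers(0, 2, n)
        feats = pd.DataFrame(
            {
                "tree_length": rng.normal(size=n),
                "krkc": rng.normal(size=n),
                "ec": rng.integers(1, 7, n).astype(str),
            }
        )
        rep = pp.fit_importance_classifier(feats, labels, seed=0, n_trees=200)
        # the two continuous noise features split MDI evenly; the 6-level EC
        # code draws less (impurity importance is cardinality-biased)
        imp = rep.importances_normalized
        assert abs(imp["tree_length"] - imp["krkc"]) < 0.1
        assert imp["ec"] < min(imp["tree_length"], imp["krkc"])
        for acc in rep.single_feature_accuracy.values():
            assert abs(acc - 0.5) < 0.1  # chance-level prediction

    def test_single_label_rejected(self):
        feats = pd.DataFrame(
            {"tree_length": [1.0, 2.0], "krkc": [1.0, 2.0], "ec": ["1", "2"]}
        )
        with pytest.raises(ValueError):
            pp.fit_importance_classifier(feats, [0, 0])

    def test_missing_values_handled(self):
        rng = np.random.default_rng(2)
        n = 60
        labels = rng.integers(0, 2, n)
        feats = pd.DataFrame(
            {
                "tree_length": rng.normal(size=n),
                "krkc": [np.nan if i % 3 == 0 else float(i) for i in range(n)],
                "ec": [None if i % 2 == 0 else "3" for i in range(n)],
            }
        )
        rep = pp.fit_importance_classifier(feats, labels, seed=0, n_trees=50)
        assert set(rep.importances) == {"tree_length", "krkc", "ec"}
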