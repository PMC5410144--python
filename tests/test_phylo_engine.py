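"""Substitution model, pruning likelihood, optimization and simulation."""

import itertools

import numpy as np
import pytest

import phylopace as pp
from phylopace.phylo_engine import AA_ALPHABET, BL_MIN, discrete_gamma_rates


def exhaustive_loglik(alignment, topology, branch_lengths, model):
    """Oracle: sum over all internal-node state combinations (<= 5 taxa)."""
    from phylopace.phylo_engine import _rooted_view, transition_matrix

    view = _rooted_view(topology)
    rates = model.category_rates()
    pi = model.stationary_freqs
    idx = {a: i for i, a in enumerate(AA_ALPHABET)}
    internal = [u for u in view.nodes if u not in view.leaf_name]
    total = 0.0
    ncol = alignment.length
    for c in range(ncol):
        site = 0.0
        for r in rates:
            P = {
                u: transition_matrix(model, r * branch_lengths[view.edge_of[u]])
                for u in view.nodes
                if view.parent[u] is not None
            }
            s = 0.0
            for states in itertools.product(range(20), repeat=len(internal)):
                st = dict(zip(internal, states))
                for u, name in view.leaf_name.items():
                    ch = alignment.sequences[name][c]
                    st[u] = idx.get(ch)
                term = pi[st[view.root]]
                for u in view.nodes:
                    if view.parent[u] is None:
                        continue
                    if st[u] is None:  # missing residue: sum over states = row sum 1
                        continue
                    if st[view.parent[u]] is None:
                        raise AssertionError("missing data only supported at leaves")
                    term *= P[u][st[view.parent[u]], st[u]]
                s += term
            site += s / len(rates)
        total += np.log(site)
    return total


class TestTransitionMatrix:
    def test_t_zero_is_identity(self):
        m = pp.poisson_model()
        assert pp.transition_matrix(m, 0.0) == pytest.approx(np.eye(20), abs=1e-12)

    @pytest.mark.parametrize("t", [0.1, 1.0, 5.0])
    def test_poisson_closed_form(self, t):
        m = pp.poisson_model()
        P = pp.transition_matrix(m, t)
        diag = 1 / 20 + (19 / 20) * np.exp(-20 * t / 19)
        assert np.diag(P) == pytest.approx(np.full(20, diag), abs=1e-12)
        assert P.sum(axis=1) == pytest.approx(np.ones(20), abs=1e-10)

    def test_ergodic_limit(self):
        m = pp.poisson_model()
        P = pp.transition_matrix(m, 50.0)
        assert P == pytest.approx(
            np.tile(m.stationary_freqs, (20, 1)), abs=1e-8
        )

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            pp.transition_matrix(pp.poisson_model(), -0.1)


class TestDiscreteGamma:
    def test_category_rates_mean_one(self):
        for shape in (0.1, 0.5, 1.0, 5.0):
            rates = discrete_gamma_rates(shape, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-9)
            assert np.all(np.diff(rates) > 0)

    def test_one_category_equals_no_gamma(self, quartet):
        tree, top = quartet
        bl = pp.branch_vector(tree, top)
        aln = pp.simulate_alignment(top, bl, pp.poisson_model(), 50, seed=0)
        ll_none = pp.pruning_loglik(aln, top, bl, pp.poisson_model())
        ll_one = pp.pruning_loglik(
            aln, top, bl, pp.poisson_model(gamma_shape=0.7, n_categories=1)
        )
        assert ll_one == pytest.approx(ll_none, abs=1e-12)


class TestPruningLoglik:
    def test_two_taxa_single_site(self):
        t = pp.parse_newick("(A:0.2,B:0.1);")
        top = pp.Topology.from_tree(t)
        bl = pp.branch_vector(t, top)
        m = pp.poisson_model()
        aln = pp.Alignment({"A": "R", "B": "R"})
        P = pp.transition_matrix(m, bl.sum())
        assert pp.pruning_loglik(aln, top, bl, m) == pytest.approx(
            np.log(P[1, 1] / 20), abs=1e-12
        )
        # at t = 0 with identical residues, the likelihood is pi_i
        assert pp.pruning_loglik(aln, top, np.zeros(1), m) == pytest.approx(
            np.log(1 / 20), abs=1e-12
        )

    def test_matches_exhaustive_oracle_four_taxa(self, quartet):
        tree, top = quartet
        bl = pp.branch_vector(tree, top)
        m = pp.poisson_model(gamma_shape=0.5, n_categories=3)
        aln = pp.Alignment({"A": "ARN", "B": "ARD", "C": "A-N", "D": "ARN"})
        got = pp.pruning_loglik(aln, top, bl, m)
        want = exhaustive_loglik(aln, top, bl, m)
        assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_newick_rotation(self):
        texts = [
            "((A:0.1,B:0.2):0.15,((C:0.3,D:0.05):0.08,E:0.4):0.07);",
            "((C:0.3,D:0.05):0.08,(E:0.4,(A:0.1,B:0.2):0.22):0.0);",
            "(E:0.4,(A:0.1,B:0.2):0.22,(C:0.3,D:0.05):0.08);",
        ]
        m = pp.poisson_model(gamma_shape=0.8, n_categories=4)
        ref = pp.Topology.from_tree(pp.parse_newick(texts[0]))
        aln = pp.simulate_alignment(
            ref, pp.branch_vector(pp.parse_newick(texts[0]), ref), m, 40, seed=5
        )
        lls = []
        for text in texts:
            t = pp.parse_newick(text)
            top = pp.Topology.from_tree(t)
            lls.append(pp.pruning_loglik(aln, top, pp.branch_vector(t, top), m))
        assert lls[1] == pytest.approx(lls[0], abs=1e-9)
        assert lls[2] == pytest.approx(lls[0], abs=1e-9)

    def test_unknown_residue_names_column_and_taxon(self, quartet):
        tree, top = quartet
        aln = pp.Alignment({"A": "AO", "B": "AR", "C": "AR", "D": "AR"})
        with pytest.raises(ValueError, match="column 2.*'A'"):
            pp.pruning_loglik(aln, top, pp.branch_vector(tree, top), pp.poisson_model())

    def test_pattern_compression_consistency(self, quartet):
        tree, top = quartet
        bl = pp.branch_vector(tree, top)
        m = pp.poisson_model()
        aln = pp.Alignment({"A": "ARN", "B": "ARD", "C": "AAN", "D": "ARN"})
        dup = pp.Alignment({k: v * 2 for k, v in aln.sequences.items()})
        assert pp.pruning_loglik(dup, top, bl, m) == pytest.approx(
            2 * pp.pruning_loglik(aln, top, bl, m), rel=1e-12
        )


class TestSimulateAlignment:
    def test_zero_lengths_identical_sequences(self, quartet_topology):
        aln = pp.simulate_alignment(
            quartet_topology, np.zeros(5), pp.poisson_model(), 30, seed=0
        )
        seqs = set(aln.sequences.values())
        assert len(seqs) == 1

    def test_deterministic_given_seed(self, quartet_topology):
        m = pp.poisson_model(gamma_shape=0.5)
        a = pp.simulate_alignment(quartet_topology, np.full(5, 0.2), m, 100, seed=42)
        b = pp.simulate_alignment(quartet_topology, np.full(5, 0.2), m, 100, seed=42)
        assert a.sequences == b.sequences

    def test_pairwise_identity_matches_closed_form(self):
        t = pp.parse_newick("(A:0.25,B:0.25);")
        top = pp.Topology.from_tree(t)
        m = pp.poisson_model()
        n = 20000
        aln = pp.simulate_alignment(top, np.array([0.5]), m, n, seed=7)
        obs = np.mean(
            [a == b for a, b in zip(aln.sequences["A"], aln.sequences["B"])]
        )
        expect = pp.transition_matrix(m, 0.5)[0, 0]  # P(identical) under uniform pi
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(obs - expect) < 3 * se


class TestOptimizeBranchLengths:
    def test_identical_sequences_hit_lower_bound(self, quartet_topology):
        aln = pp.Alignment({x: "ARNDCQ" for x in "ABCD"})
        fit = pp.optimize_branch_lengths(
            aln, quartet_topology, pp.poisson_model(), n_restarts=1, seed=0
        )
        assert np.all(fit.branch_lengths < 1e-6)

    def test_loglik_not_below_init(self, quartet):
        tree, top = quartet
        m = pp.poisson_model()
        aln = pp.simulate_alignment(top, pp.branch_vector(tree, top), m, 200, seed=1)
        init = np.full(5, 0.5)
        fit = pp.optimize_branch_lengths(
            aln, top, m, init=init, n_restarts=1, seed=0
        )
        assert fit.loglik >= pp.pruning_loglik(aln, top, init, m) - 1e-9

    def test_recovery_on_simulated_data(self):
        top = pp.generate_topology(6, 11)
        rng = np.random.default_rng(8)
        true = np.exp(rng.uniform(np.log(0.08), np.log(0.8), top.n_edges))
        m = pp.poisson_model()
        aln = pp.simulate_alignment(top, true, m, 4000, seed=2)
        fit = pp.optimize_branch_lengths(aln, top, m, n_restarts=2, seed=0)
        rel = np.abs(fit.branch_lengths - true) / true
        assert np.median(rel) < 0.1
        assert rel.max() < 0.25

    def test_error_shrinks_with_more_sites(self):
        top = pp.generate_topology(5, 3)
        true = np.full(top.n_edges, 0.3)
        m = pp.poisson_model()
        errs = []
        for n_sites in (500, 8000):
            aln = pp.simulate_alignment(top, true, m, n_sites, seed=9)
            fit = pp.optimize_branch_lengths(aln, top, m, n_restarts=1, seed=0)
            errs.append(np.median(np.abs(fit.branch_lengths - true) / true))
        assert errs[1] < errs[0]

    def test_init_out_of_bounds_rejected(self, quartet_topology):
        aln = pp.Alignment({x: "ARND" for x in "ABCD"})
        with pytest.raises(ValueError):
            pp.optimize_branch_lengths(
                aln, quartet_topology, pp.poisson_model(), init=np.full(5, 30.0)
            )
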