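"""Tests of tree I/O, phylogenetic covariance, signal statistics and
Brownian-motion ancestral state reconstruction."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from thermotraits import phylo_signal as ps
from thermotraits import synthetic_data as synth


class TestNewickIO:
    def test_two_tips(self):
        tree = ps.parse_newick("(A:1,B:1);")
        assert sorted(ps.tip_labels(tree)) == ["A", "B"]
        cov = ps.phylo_covariance(tree)
        assert np.allclose(cov.to_numpy(), np.eye(2))

    def test_three_tips_with_internal(self):
        tree = ps.parse_newick("((A:1,B:1):1,C:2);")
        cov = ps.phylo_covariance(tree).loc[["A", "B", "C"], ["A", "B", "C"]]
        assert np.allclose(np.diag(cov), 2.0)
        assert cov.loc["A", "B"] == pytest.approx(1.0)
        assert cov.loc["A", "C"] == 0.0 and cov.loc["B", "C"] == 0.0

    def test_polytomy_covariance(self):
        cov = ps.phylo_covariance(ps.parse_newick("(A:1,B:1,C:1);"))
        assert np.allclose(cov.to_numpy(), np.eye(3))

    @pytest.mark.parametrize("bad", ["(A:1,B:1", "(A:1,A:1);", "(A:1,B);"])
    def test_malformed_newick_rejected(self, bad):
        with pytest.raises(ValueError):
            ps.parse_newick(bad)

    def test_roundtrip_preserves_lengths(self):
        tree = synth.generate_yule_tree(20, seed=5)
        text = ps.write_newick(tree)
        back = ps.parse_newick(text)
        c1 = ps.phylo_covariance(tree)
        c2 = ps.phylo_covariance(back).loc[c1.index, c1.columns]
        assert np.allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-9)


def _direct_mvn_loglik(x, cov):
    """Oracle: plain multivariate-normal density with GLS-profiled mean
    and ML variance, computed with scipy only."""
    n = len(x)
    ci = np.linalg.inv(cov)
    ones = np.ones(n)
    mu = (ones @ ci @ x) / (ones @ ci @ ones)
    sigma2 = (x - mu) @ ci @ (x - mu) / n
    return stats.multivariate_normal(mean=np.full(n, mu),
                                     cov=sigma2 * cov).logpdf(x)


class TestLambda:
    def test_loglik_matches_direct_mvn(self):
        tree = synth.generate_yule_tree(15, seed=3)
        x = synth.simulate_lambda_bm(tree, 1.5, 4.0, 1.0, seed=4)
        est = ps.estimate_lambda(tree, x)
        cov = ps.phylo_covariance(tree).to_numpy()
        lam_cov = cov * est.value
        np.fill_diagonal(lam_cov, np.diag(cov))
        assert est.log_likelihood == pytest.approx(
            _direct_mvn_loglik(x.to_numpy(), lam_cov), abs=1e-9
        )

    def test_reference_values_from_r_phytools(self):
        """Frozen cross-check against R phytools::phylosig on the same
        seeded tree/trait (independent reference implementation)."""
        tree = synth.generate_yule_tree(12, seed=42)
        x = synth.simulate_lambda_bm(tree, 2.0, 10.0, 0.7, seed=7)
        est = ps.estimate_lambda(tree, x)
        assert est.value == pytest.approx(0.368104, abs=1e-4)
        assert est.log_likelihood == pytest.approx(-11.963, abs=1e-3)
        assert est.log_likelihood_null == pytest.approx(-12.66625, abs=1e-3)
        assert est.p_value == pytest.approx(0.2356384, abs=1e-4)
        k = ps.blomberg_k(tree, x, n_permutations=None)
        assert k.value == pytest.approx(0.1260223, abs=1e-5)

    def test_zero_lambda_gives_p_one(self):
        # a star tree carries no shared history, so lambda is undefined
        # and the LRT statistic is 0
        tree = ps.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        x = {"A": 0.3, "B": -1.2, "C": 0.8, "D": 2.0, "E": -0.5}
        est = ps.estimate_lambda(tree, x)
        assert est.p_value == 1.0

    def test_affine_invariance(self):
        tree = synth.generate_yule_tree(25, seed=9)
        x = synth.simulate_lambda_bm(tree, 1.0, 0.0, 0.8, seed=10)
        e1 = ps.estimate_lambda(tree, x)
        e2 = ps.estimate_lambda(tree, 3.5 * x - 7.0)
        assert e2.value == pytest.approx(e1.value, abs=1e-5)
        assert e2.p_value == pytest.approx(e1.p_value, abs=1e-6)

    def test_branch_rescaling_invariance(self):
        tree = synth.generate_yule_tree(25, seed=11)
        x = synth.simulate_lambda_bm(tree, 1.0, 0.0, 0.9, seed=12)
        e1 = ps.estimate_lambda(tree, x)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 100.0
        e2 = ps.estimate_lambda(tree, x)
        assert e2.value == pytest.approx(e1.value, abs=1e-5)

    def test_too_few_tips_rejected(self):
        tree = ps.parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            ps.estimate_lambda(tree, {"A": 1.0, "B": 2.0})


class TestBlombergK:
    def test_affine_invariance_and_determinism(self):
        tree = synth.generate_yule_tree(20, seed=13)
        x = synth.simulate_lambda_bm(tree, 1.0, 0.0, 1.0, seed=14)
        k1 = ps.blomberg_k(tree, x, n_permutations=199, seed=5)
        k2 = ps.blomberg_k(tree, 2.0 * x + 3.0, n_permutations=199, seed=5)
        assert k2.value == pytest.approx(k1.value, rel=1e-9)
        assert k2.p_value == k1.p_value  # same seed, same permutations

    def test_branch_rescaling_invariance(self):
        tree = synth.generate_yule_tree(20, seed=15)
        x = synth.simulate_lambda_bm(tree, 1.0, 0.0, 1.0, seed=16)
        k1 = ps.blomberg_k(tree, x, n_permutations=None)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 42.0
        k2 = ps.blomberg_k(tree, x, n_permutations=None)
        assert k2.value == pytest.approx(k1.value, rel=1e-9)

    def test_permutation_count_validated(self):
        tree = synth.generate_yule_tree(10, seed=17)
        x = synth.simulate_lambda_bm(tree, 1.0, 0.0, 1.0, seed=18)
        with pytest.raises(ValueError):
            ps.blomberg_k(tree, x, n_permutations=10)


def _joint_ml_oracle(tree, trait):
    """Independent ancestral-state oracle.

    Maximising the joint Brownian likelihood over all internal states
    makes every internal state the branch-length-weighted harmonic
    average of its neighbours; solve that sparse linear system directly.
    """
    nodes = list(tree.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    b = np.zeros(n)
    x = pd.Series(trait, dtype=float)
    for node in nodes:
        i = idx[id(node)]
        if node.is_leaf():
            A[i, i] = 1.0
            b[i] = x[node.taxon.label]
            continue
        neighbours = list(node.child_nodes())
        weights = [1.0 / c.edge.length for c in neighbours]
        if node.parent_node is not None:
            neighbours.append(node.parent_node)
            weights.append(1.0 / node.edge.length)
        A[i, i] = sum(weights)
        for nb, w in zip(neighbours, weights):
            A[i, idx[id(nb)]] = -w
    sol = np.linalg.solve(A, b)
    return {
        f"node{j}": sol[idx[id(node)]]
        for j, node in enumerate(tree.preorder_internal_node_iter())
    }


class TestAncestralStates:
    def test_two_tip_closed_forms(self):
        asr = ps.ancestral_states_bm(ps.parse_newick("(A:1,B:1);"),
                                     {"A": 0.0, "B": 2.0})
        assert asr.root_state == pytest.approx(1.0, abs=1e-12)
        asr = ps.ancestral_states_bm(ps.parse_newick("(A:1,B:3);"),
                                     {"A": 0.0, "B": 2.0})
        # GLS: (0/1 + 2/3) / (1/1 + 1/3)
        assert asr.root_state == pytest.approx(0.5, abs=1e-12)

    def test_constant_trait(self):
        tree = synth.generate_yule_tree(8, seed=19)
        asr = ps.ancestral_states_bm(
            tree, {l: 3.14 for l in ps.tip_labels(tree)})
        assert all(v == pytest.approx(3.14, abs=1e-9)
                   for v in asr.node_states.values())
        assert asr.sigma2_hat == pytest.approx(0.0, abs=1e-12)

    def test_matches_joint_ml_oracle_on_random_trees(self):
        """GLS extra-tip construction equals the joint-likelihood linear
        system on 50 random 10-tip trees."""
        for seed in range(50):
            tree = synth.generate_yule_tree(10, seed=1000 + seed)
            x = synth.simulate_lambda_bm(tree, 1.0, 0.0, 1.0, seed=seed)
            asr = ps.ancestral_states_bm(tree, x)
            oracle = _joint_ml_oracle(tree, x)
            for node, val in oracle.items():
                assert asr.node_states[node] == pytest.approx(val, abs=1e-8)

    def test_reference_values_from_r_fastanc(self):
        """Frozen cross-check against R phytools::fastAnc (first five
        preorder internal nodes of the seeded tree)."""
        tree = synth.generate_yule_tree(12, seed=42)
        x = synth.simulate_lambda_bm(tree, 2.0, 10.0, 0.7, seed=7)
        asr = ps.ancestral_states_bm(tree, x)
        expected = [9.426641, 9.950436, 10.113058, 9.122014, 8.937292]
        got = [asr.node_states[f"node{i}"] for i in range(5)]
        assert got == pytest.approx(expected, abs=1e-5)

    def test_root_within_tip_range(self, rng):
        for seed in range(10):
            tree = synth.generate_yule_tree(12, seed=2000 + seed)
            x = synth.simulate_lambda_bm(tree, 2.0, 1.0, 1.0, seed=seed)
            asr = ps.ancestral_states_bm(tree, x)
            assert x.min() <= asr.root_state <= x.max()
            assert all(v >= 0 for v in asr.node_variances.values())


class TestAlignTrait:
    def test_missing_tip_errors(self):
        tree = ps.parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="missing"):
            ps.align_trait(tree, {"A": 1.0, "B": 2.0})

    def test_strict_extra_key_errors_permissive_drops(self):
        tree = ps.parse_newick("((A:1,B:1):1,C:2);")
        trait = {"A": 1.0, "B": 2.0, "C": 3.0, "Z": 9.0}
        with pytest.raises(ValueError, match="Z"):
            ps.align_trait(tree, trait, strict=True)
        x = ps.align_trait(tree, trait, strict=False)
        assert list(x.index) == ["A", "B", "C"]

    def test_log_transform_requires_positive(self):
        tree = ps.parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="positive"):
            ps.align_trait(tree, {"A": 1.0, "B": -2.0, "C": 3.0},
                           transform="log")
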