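"""Beta-mixture EM, recursive partitioning, permutation test, AUC statistic."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from methmark.datatypes import ValidationError
from methmark.rpmm import (
    RPMM,
    class_auc,
    eb_membership,
    fit_one_class,
    fit_two_class,
    permutation_chisq,
    rank_loci_by_auc,
    recursive_partition,
)

from conftest import make_leaf, make_tree


def two_class_data(rng, n=200, J=50, means=(0.2, 0.8), precision=20.0):
    labels = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
    mu = np.asarray(means)[labels][:, None]
    X = rng.beta(mu * precision, (1 - mu) * precision, (n, J))
    return X, labels


class TestTwoClassEM:
    def test_recovers_separated_classes(self, rng):
        X, labels = two_class_data(rng)
        node = fit_two_class(X, seed=0)
        fitted_means = np.sort((node.a / (node.a + node.b)).mean(axis=1))
        assert np.all(np.abs(fitted_means - [0.2, 0.8]) < 0.05)
        assert adjusted_rand_score(labels, node.resp.argmax(axis=1)) > 0.95

    def test_loglik_nondecreasing(self, rng):
        for _ in range(5):
            X = rng.beta(2, 5, (40, 10))
            node = fit_two_class(X, seed=1)
            d = np.diff(node.loglik_trace)
            assert np.all(d >= -1e-6 * np.abs(node.loglik_trace[:-1]) - 1e-8)

    def test_single_population_prefers_one_class(self, rng):
        X = rng.beta(3, 6, (120, 30))
        assert fit_two_class(X, seed=2).bic > fit_one_class(X).bic

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_two_class(rng.beta(2, 2, (3, 5)))

    def test_parameter_recovery_across_seeds(self):
        """Median fitted-class-mean error over 20 seeded 2-class runs < 0.02."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            X, _ = two_class_data(rng, n=200, J=40)
            node = fit_two_class(X, seed=seed)
            fitted = np.sort((node.a / (node.a + node.b)).mean(axis=1))
            errs.append(np.abs(fitted - [0.2, 0.8]).mean())
        assert np.median(errs) < 0.02


class TestRecursivePartition:
    def test_homogeneous_single_leaf(self, rng):
        X = rng.beta(4, 4, (100, 20))
        tree = recursive_partition(X, seed=0)
        assert tree.n_leaves == 1

    def test_four_class_recovery(self, rng):
        means = np.repeat([0.15, 0.35, 0.60, 0.85], 60)
        X = rng.beta(means[:, None] * 20, (1 - means[:, None]) * 20, (240, 100))
        tree = recursive_partition(X, seed=0)
        assert tree.n_leaves == 4
        truth = np.repeat([0, 1, 2, 3], 60)
        assert adjusted_rand_score(truth, tree.assignment) > 0.95
        leaf_means = sorted(
            float((lp["a"] / (lp["a"] + lp["b"])).mean()) for lp in tree.leaf_params
        )
        assert np.all(np.abs(np.array(leaf_means) - [0.15, 0.35, 0.60, 0.85]) < 0.05)

    def test_nested_split_consistency(self, rng):
        """Refitting a 2-class model on two sibling leaves' samples recovers
        the parent split's class means."""
        means = np.repeat([0.2, 0.8], 80)
        X = rng.beta(means[:, None] * 25, (1 - means[:, None]) * 25, (160, 40))
        tree = recursive_partition(X, seed=1)
        assert tree.n_leaves == 2
        node = fit_two_class(X, seed=5)
        tree_means = sorted(
            float((lp["a"] / (lp["a"] + lp["b"])).mean()) for lp in tree.leaf_params
        )
        refit_means = sorted((node.a / (node.a + node.b)).mean(axis=1))
        assert np.allclose(tree_means, refit_means, atol=0.02)

    def test_deterministic_given_seed(self, rng):
        X = rng.beta(2, 4, (60, 15))
        t1 = recursive_partition(X, seed=3)
        t2 = recursive_partition(X, seed=3)
        assert t1.n_leaves == t2.n_leaves
        assert np.array_equal(t1.assignment, t2.assignment)


class TestMembership:
    def test_rows_sum_to_one(self, rng):
        means = np.repeat([0.2, 0.8], 50)
        X = rng.beta(means[:, None] * 20, (1 - means[:, None]) * 20, (100, 30))
        tree = recursive_partition(X, seed=0)
        post = eb_membership(tree, X)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_mode_sample_assigned_confidently(self, rng):
        means = np.repeat([0.15, 0.85], 50)
        X = rng.beta(means[:, None] * 30, (1 - means[:, None]) * 30, (100, 30))
        tree = recursive_partition(X, seed=0)
        assert tree.n_leaves == 2
        probe = np.full((1, 30), 0.15)
        post = eb_membership(tree, probe)
        assert post.max() > 0.99

    def test_symmetric_sample_splits_evenly(self):
        J = 10
        leaf1 = make_leaf(np.full(J, 2.0), np.full(J, 8.0), 5, "rL")
        leaf2 = make_leaf(np.full(J, 8.0), np.full(J, 2.0), 5, "rR")
        tree = make_tree([leaf1, leaf2])
        from methmark.rpmm import BetaMixtureNode

        root = tree.root
        root.children = [
            BetaMixtureNode(
                eta=np.array([1.0]), a=leaf.copy()["a"][None, :], b=leaf["b"][None, :],
                resp=np.ones((1, 1)), loglik=0.0, bic=0.0, n_effective=5.0,
            )
            for leaf in [leaf1, leaf2]
        ]
        post = eb_membership(tree, np.full((1, J), 0.5))
        assert np.allclose(post, [[0.5, 0.5]])


class TestPermutationChisq:
    def test_perfect_alignment_hits_floor(self, rng):
        classes = np.repeat([0, 1], 50)
        stat, p = permutation_chisq(classes, classes, B=10000, seed=0)
        assert p == pytest.approx(1.0 / 10001.0)
        assert p < 1e-4  # matches the headline permutation bound
        assert stat == pytest.approx(100.0)  # chi2 of a perfect 2x2 is n

    def test_zero_statistic_p_one(self):
        classes = [0, 0, 1, 1]
        pheno = [0, 1, 0, 1]
        stat, p = permutation_chisq(classes, pheno, B=200, seed=1)
        assert stat == pytest.approx(0.0)
        assert p == 1.0

    def test_constant_phenotype_errors(self):
        with pytest.raises(ValidationError):
            permutation_chisq([0, 1, 0, 1], [1, 1, 1, 1], B=10)

    def test_uniform_under_independence(self):
        """p approximately Uniform: fraction <= 0.1 within MC bounds."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(900 + seed)
            classes = rng.integers(0, 2, 60)
            pheno = rng.integers(0, 2, 60)
            _, p = permutation_chisq(classes, pheno, B=199, seed=seed)
            hits += p <= 0.1
        assert abs(hits / n_rep - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n_rep) + 0.02


class TestClassAUC:
    def test_identical_distributions_half(self):
        # symmetric beta: the moment-matched normal complement is unbiased,
        # so identical class and complement distributions give AUC 0.5
        J = 3
        leaves = [
            make_leaf(np.full(J, 20.0), np.full(J, 20.0), 5, "rL"),
            make_leaf(np.full(J, 20.0), np.full(J, 20.0), 5, "rR"),
        ]
        tree = make_tree(leaves)
        assert class_auc(tree, 0, 0) == pytest.approx(0.5, abs=0.01)

    def test_disjoint_supports_near_one(self):
        leaves = [
            make_leaf(np.array([50.0]), np.array([2.0]), 5, "rL"),
            make_leaf(np.array([2.0]), np.array([50.0]), 5, "rR"),
        ]
        tree = make_tree(leaves)
        assert class_auc(tree, 0, 0) >= 0.999

    def test_matches_monte_carlo_oracle(self, rng):
        # class k: Beta(2, 8); complement leaf chosen so its moment-matched
        # normal is N(0.6, 0.1): mean 0.6, var 0.01 -> precision 23
        a_o, b_o = 0.6 * 23.0, 0.4 * 23.0
        leaves = [
            make_leaf(np.array([2.0]), np.array([8.0]), 5, "rL"),
            make_leaf(np.array([a_o]), np.array([b_o]), 5, "rR"),
        ]
        tree = make_tree(leaves)
        auc = class_auc(tree, 0, 0)
        n_mc = 10**6
        xk = rng.beta(2.0, 8.0, n_mc)
        xo = rng.normal(0.6, 0.1, n_mc)
        keep = (xo >= 0) & (xo <= 1)  # G is truncated to [0, 1]
        mc = (xk[keep] > xo[keep]).mean()
        mc = max(mc, 1 - mc)
        assert auc == pytest.approx(mc, abs=0.005)

    def test_folding_invariance(self):
        leaves = [
            make_leaf(np.array([2.0]), np.array([8.0]), 4, "rL"),
            make_leaf(np.array([8.0]), np.array([2.0]), 6, "rR"),
        ]
        tree = make_tree(leaves)
        flipped = make_tree(list(reversed(leaves)))
        assert class_auc(tree, 0, 0) == pytest.approx(class_auc(flipped, 0, 1), abs=1e-9)
        assert class_auc(tree, 0, 0) >= 0.5

    def test_single_leaf_errors(self):
        tree = make_tree([make_leaf(np.array([2.0]), np.array([2.0]), 5)])
        with pytest.raises(ValidationError):
            class_auc(tree, 0, 0)
        with pytest.raises(ValidationError):
            rank_loci_by_auc(tree)


class TestAUCRanking:
    def test_exchangeable_loci_no_selection(self):
        J = 8
        leaves = [
            make_leaf(np.full(J, 4.0), np.full(J, 6.0), 5, "rL"),
            make_leaf(np.full(J, 4.0), np.full(J, 6.0), 5, "rR"),
        ]
        rank = rank_loci_by_auc(make_tree(leaves))
        assert (rank["auc_max"] < 0.55).all()
        assert (rank["auc_max"] > 0.75).sum() == 0

    def test_spiked_loci_only_exceed_cut(self):
        J = 10
        a1, b1 = np.full(J, 4.0), np.full(J, 6.0)
        a2, b2 = a1.copy(), b1.copy()
        a2[:3], b2[:3] = 27.0, 3.0  # spiked: mean 0.9 in class 2 vs 0.4
        rank = rank_loci_by_auc(
            make_tree([make_leaf(a1, b1, 5, "rL"), make_leaf(a2, b2, 5, "rR")])
        )
        assert set(rank.index[rank["auc_max"] > 0.9]) == {"L0", "L1", "L2"}


def test_model_results_interface(rng):
    means = np.repeat([0.2, 0.8], 40)
    X = pd.DataFrame(rng.beta(means[:, None] * 20, (1 - means[:, None]) * 20, (80, 25)))
    res = RPMM(X).fit(seed=0)
    assert res.n_classes == 2
    assert res.membership().shape == (80, 2)
    phenotype = (means > 0.5).astype(int)
    assert res.class_of_interest(phenotype) in (0, 1)
    stat, p = res.phenotype_test(phenotype, B=499, seed=1)
    assert p == pytest.approx(1.0 / 500.0)
    assert "methylation classes" in res.summary()
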