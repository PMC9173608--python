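import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reefscore.diversity import (
    evolutionary_distinctiveness,
    gower_distinctiveness,
    gower_matrix,
    group_compare,
    harmonic_mean_p,
    pagels_lambda,
    pgls_over_trees,
    pgls_slope,
    species_age,
)
from reefscore.synth.trees import simulate_tree, simulate_trait_on_tree


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


class TestSpeciesAge:
    def test_cherry_pendant_lengths(self):
        ages = species_age(_tree("(A:2,B:3);"))
        assert ages["A"] == 2.0
        assert ages["B"] == 3.0

    def test_hand_built_five_tip_tree(self):
        t = _tree("((A:2,B:3):1,(C:1,(D:0.5,E:0.5):1):2);")
        ages = species_age(t)
        assert ages.to_dict() == {"A": 2.0, "B": 3.0, "C": 1.0, "D": 0.5, "E": 0.5}

    def test_age_bounded_by_depth_on_ultrametric_tree(self):
        from reefscore.phylo import tree_depths

        tree = simulate_tree(30, seed=0)
        depth = tree_depths(tree).max()
        assert (species_age(tree) <= depth + 1e-9).all()

    def test_zero_pendant_warns(self):
        with pytest.warns(UserWarning, match="zero-length"):
            species_age(_tree("(A:0,B:1);"))


class TestEvolutionaryDistinctiveness:
    def test_two_tip_tree(self):
        ed = evolutionary_distinctiveness(_tree("(A:1.5,B:2.5);"))
        assert ed["A"] == pytest.approx(1.5)
        assert ed["B"] == pytest.approx(2.5)

    def test_fair_proportion_conservation(self):
        for seed in range(10):
            tree = simulate_tree(25, seed=seed)
            total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
            ed = evolutionary_distinctiveness(tree)
            assert ed.sum() == pytest.approx(total, rel=1e-12)

    def test_four_tip_asymmetric_hand_oracle(self):
        # ((A:1,B:2):3,(C:4,D:5):6)
        # edge sharing: A gets 1 + 3/2; B gets 2 + 3/2; C gets 4 + 6/2; D 5 + 6/2
        ed = evolutionary_distinctiveness(_tree("((A:1,B:2):3,(C:4,D:5):6);"))
        assert ed["A"] == pytest.approx(2.5)
        assert ed["B"] == pytest.approx(3.5)
        assert ed["C"] == pytest.approx(7.0)
        assert ed["D"] == pytest.approx(8.0)


class TestPagelsLambda:
    def test_star_tree_reports_zero_by_tiebreak(self):
        tree = _tree("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(0)
        trait = dict(zip("ABCDE", rng.standard_normal(5)))
        res = pagels_lambda(tree, trait, n_perm=0)
        assert res.lambda_hat == 0.0

    def test_recovery_lambda_one(self):
        tree = simulate_tree(100, seed=1)
        traits, _ = simulate_trait_on_tree(tree, 1.0, 1.0, seed=2, n_replicates=20)
        lams = [pagels_lambda(tree, t, n_perm=0).lambda_hat for t in traits]
        assert np.mean(lams) >= 0.9

    def test_recovery_lambda_zero(self):
        tree = simulate_tree(100, seed=3)
        traits, _ = simulate_trait_on_tree(tree, 0.0, 1.0, seed=4, n_replicates=20)
        lams = [pagels_lambda(tree, t, n_perm=0).lambda_hat for t in traits]
        assert np.mean(lams) <= 0.1

    def test_signal_detected_with_small_p(self):
        tree = simulate_tree(80, seed=5)
        traits, _ = simulate_trait_on_tree(tree, 1.0, 1.0, seed=6)
        res = pagels_lambda(tree, traits[0], n_perm=199, seed=7)
        assert res.p_value < 0.05
        assert 0 < res.p_value <= 1

    def test_lambda_bias_at_half(self):
        tree = simulate_tree(200, seed=8)
        traits, _ = simulate_trait_on_tree(tree, 0.5, 1.0, seed=9, n_replicates=30)
        lams = [pagels_lambda(tree, t, n_perm=0).lambda_hat for t in traits]
        assert abs(np.mean(lams) - 0.5) <= 0.1

    def test_too_few_tips(self):
        tree = _tree("(A:1,B:1,C:1);")
        with pytest.raises(ValueError):
            pagels_lambda(tree, {"A": 1.0, "B": 2.0, "C": 3.0}, n_perm=0)


class TestGower:
    def test_identical_rows_zero(self):
        df = pd.DataFrame({"x": [1.0, 1.0], "c": ["a", "a"]}, index=["s1", "s2"])
        D = gower_matrix(df, {"x": "numeric", "c": "categorical"})
        assert D.iloc[0, 1] == 0.0
        di = gower_distinctiveness(df, {"x": "numeric", "c": "categorical"})
        assert (di == 0.0).all()

    def test_three_species_hand_table(self):
        # numeric in [0, 10], binary category; hand-computed 3x3 matrix
        df = pd.DataFrame(
            {"num": [0.0, 5.0, 10.0], "cat": ["a", "a", "b"]},
            index=["s1", "s2", "s3"],
        )
        D = gower_matrix(df, {"num": "numeric", "cat": "categorical"})
        expected = np.array([[0.0, 0.25, 1.0], [0.25, 0.0, 0.75], [1.0, 0.75, 0.0]])
        assert np.allclose(D.to_numpy(), expected, atol=1e-12)
        di = gower_distinctiveness(df, {"num": "numeric", "cat": "categorical"})
        assert di["s1"] == pytest.approx((0.25 + 1.0) / 2, abs=1e-12)

    def test_symmetry_zero_diagonal_bounds(self):
        from reefscore.synth.traits import simulate_trait_table

        table, types = simulate_trait_table(25, seed=10)
        D = gower_matrix(table, types).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all() and (D <= 1 + 1e-12).all()

    def test_ordinal_rank_scaling(self):
        df = pd.DataFrame({"o": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        D = gower_matrix(df, {"o": "ordinal"})
        # ranks 1, 2, 3: equally spaced regardless of raw gaps
        assert D.loc["a", "b"] == pytest.approx(0.5)
        assert D.loc["a", "c"] == pytest.approx(1.0)

    def test_missing_values_reweighted(self):
        df = pd.DataFrame(
            {"x": [0.0, 1.0, 0.5], "c": ["a", None, "b"]}, index=["s1", "s2", "s3"]
        )
        D = gower_matrix(df, {"x": "numeric", "c": "categorical"})
        # s1-s2 pair only observes the numeric column
        assert D.loc["s1", "s2"] == pytest.approx(1.0)

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"x": [None, None]}, index=["a", "b"], dtype=float)
        with pytest.raises(ValueError):
            gower_matrix(df, {"x": "numeric"})


class TestPgls:
    def test_star_tree_equals_ols(self):
        tree = _tree("(A:1,B:1,C:1,D:1,E:1,F:1);")
        rng = np.random.default_rng(11)
        labels = list("ABCDEF")
        x = dict(zip(labels, rng.standard_normal(6)))
        y = dict(zip(labels, rng.standard_normal(6)))
        res = pgls_slope(tree, x, y)
        ols = stats.linregress([x[l] for l in labels], [y[l] for l in labels])
        assert res.slope == pytest.approx(ols.slope, abs=1e-10)
        assert res.p_value == pytest.approx(ols.pvalue, abs=1e-10)

    def test_three_tip_hand_matrix_arithmetic(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        x = {"A": 1.0, "B": 2.0, "C": 3.0}
        y = {"A": 1.1, "B": 2.3, "C": 2.8}
        res = pgls_slope(tree, x, y)
        # oracle: explicit (X' C^-1 X)^-1 X' C^-1 y with C from shared paths
        from reefscore.phylo import tip_covariance

        C, labels = tip_covariance(tree)
        X = np.column_stack([np.ones(3), [x[l] for l in labels]])
        yv = np.array([y[l] for l in labels])
        Ci = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ yv)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)

    def test_harmonic_mean_identical_ps(self):
        assert harmonic_mean_p([0.03, 0.03, 0.03]) == pytest.approx(0.03)

    def test_harmonic_mean_formula(self):
        ps = [0.01, 0.5, 0.2]
        assert harmonic_mean_p(ps) == pytest.approx(3 / sum(1 / p for p in ps))
        with pytest.raises(ValueError):
            harmonic_mean_p([0.0, 0.5])

    def test_over_trees(self):
        trees = [simulate_tree(20, seed=s) for s in range(3)]
        labels = [l.taxon.label for l in trees[0].leaf_node_iter()]
        rng = np.random.default_rng(12)
        x = dict(zip(labels, rng.standard_normal(20)))
        y = {k: 2 * v + rng.normal(0, 0.1) for k, v in x.items()}
        df, hmp = pgls_over_trees(trees, x, y)
        assert len(df) == 3
        assert 0 < hmp <= 1
        assert df["slope"].mean() == pytest.approx(2.0, abs=0.2)


class TestGroupCompare:
    def test_textbook_balanced_anova(self):
        # 3 groups x 5: hand sums of squares give SSB=10, SSW=30, F=2.0
        values = [1, 2, 3, 4, 5, 2, 3, 4, 5, 6, 3, 4, 5, 6, 7]
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = group_compare(values, groups)
        assert res.f_statistic == pytest.approx(2.0)
        assert res.p_value == pytest.approx(stats.f.sf(2.0, 2, 12))

    def test_identical_means_tukey_near_one(self):
        rng = np.random.default_rng(13)
        base = rng.standard_normal(30)
        values = np.concatenate([base, base + 0.0, base])
        groups = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        res = group_compare(values, groups)
        assert (res.tukey.to_numpy() >= 0.89).all()

    def test_two_groups_tukey_equals_pooled_t(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 25)
        res = group_compare(np.concatenate([a, b]), ["a"] * 20 + ["b"] * 25)
        t = stats.ttest_ind(a, b)  # pooled-variance two-sample t
        assert res.tukey.loc["a", "b"] == pytest.approx(t.pvalue, rel=0.02)

    def test_errors(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], ["a", "a"])
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])
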