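"""PGLS machinery, collinearity screen, model set and averaging."""

import numpy as np
import pandas as pd
import pytest

from attini import comparative as cmp
from attini.comparative import ModelSpec, PGLSFit
from attini.synthetic_data import simulate_lambda_traits, simulate_yule_tree
from conftest import rooted


def star_tree(n, depth=1.0):
    labels = [f"s{i}" for i in range(n)]
    return rooted("(" + ",".join(f"{l}:{depth}" for l in labels) + ");"), labels


class TestPhyloCovariance:
    def test_lambda_zero_is_diagonal(self):
        t = rooted("((A:4,B:4):6,C:10);")
        C, taxa = cmp.phylo_covariance(t, 0.0)
        assert np.allclose(C, np.diag([10.0, 10.0, 10.0]))

    def test_lambda_one_is_shared_path_lengths(self):
        t = rooted("((A:4,B:4):6,C:10);")
        C, taxa = cmp.phylo_covariance(t, 1.0)
        assert C[taxa.index("A"), taxa.index("B")] == pytest.approx(6.0)
        assert C[taxa.index("A"), taxa.index("C")] == pytest.approx(0.0)

    def test_sister_pair_off_diagonal_scales_with_lambda(self):
        t = rooted("((A:4,B:4):6,C:10);")
        for lam in (0.25, 0.5, 0.9):
            C, taxa = cmp.phylo_covariance(t, lam)
            assert C[taxa.index("A"), taxa.index("B")] == pytest.approx(6 * lam)
            assert C[0, 0] == pytest.approx(10.0)

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            cmp.phylo_covariance(rooted("(A:1,B:1);"), 1.5)


class TestPGLS:
    def test_star_tree_lambda_zero_equals_ols(self):
        tree, labels = star_tree(12)
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = 0.5 + 1.5 * x + rng.normal(size=12) * 0.3
        data = pd.DataFrame({"x": x, "y": y}, index=labels)
        fit = cmp.pgls_fit(ModelSpec("y", ("x",)), data, tree,
                           lam_mode="fixed", lam=0.0)
        X = np.column_stack([np.ones(12), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        s2 = resid @ resid / (12 - 2)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert fit.beta["(intercept)"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.beta["x"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.se["(intercept)"] == pytest.approx(se[0], abs=1e-8)
        assert fit.se["x"] == pytest.approx(se[1], abs=1e-8)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_exact_linear_data_any_lambda(self, lam):
        tree = simulate_yule_tree(10, seed=2)
        taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        x = np.linspace(-1, 1, 10)
        data = pd.DataFrame({"x": x, "y": 2 * x + 1}, index=taxa)
        fit = cmp.pgls_fit(ModelSpec("y", ("x",)), data, tree,
                           lam_mode="fixed", lam=lam)
        assert fit.beta["(intercept)"] == pytest.approx(1.0, abs=1e-8)
        assert fit.beta["x"] == pytest.approx(2.0, abs=1e-8)

    def test_profile_loglik_dominates_grid(self):
        """ML lambda beats every grid value of the profile likelihood."""
        for seed in range(5):
            tree = simulate_yule_tree(40, seed=seed)
            y, x = simulate_lambda_traits(tree, 0.7, beta=(0.0, 0.3),
                                          sigma2=1.0, seed=100 + seed)
            data = pd.DataFrame({"y": y, "x": x})
            fit = cmp.pgls_fit(ModelSpec("y", ("x",)), data, tree)
            C, taxa = cmp.phylo_covariance(tree, 1.0, taxa=list(data.index))
            X = np.column_stack([np.ones(len(data)), data["x"]])
            yv = data["y"].to_numpy()
            ll_hat = cmp._profile_loglik(fit.lam, yv, X, C)[0]
            for g in (0.0, 0.25, 0.5, 0.75, 1.0):
                assert ll_hat >= cmp._profile_loglik(g, yv, X, C)[0] - 1e-6

    def test_singular_design_names_columns(self):
        tree, labels = star_tree(10)
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        data = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.normal(size=10)},
                            index=labels)
        with pytest.raises(ValueError, match="collinear"):
            cmp.pgls_fit(ModelSpec("y", ("x", "x2")), data, tree)

    def test_aicc_undefined_for_tiny_samples(self):
        tree, labels = star_tree(5)
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"x": rng.normal(size=5),
                             "z": rng.normal(size=5),
                             "y": rng.normal(size=5)}, index=labels)
        with pytest.raises(ValueError):
            cmp.pgls_fit(ModelSpec("y", ("x", "z")), data, tree)


class TestPhylogeneticSignal:
    def test_brownian_traits_recover_high_lambda(self):
        lams = []
        for seed in range(40):
            tree = simulate_yule_tree(64, seed=seed)
            y, _ = simulate_lambda_traits(tree, 1.0, beta=(0.0, 0.0),
                                          sigma2=1.0, seed=500 + seed)
            lams.append(cmp.phylogenetic_signal(y, tree))
        assert np.median(lams) >= 0.9

    def test_iid_traits_recover_low_lambda(self):
        lams = []
        for seed in range(40):
            tree = simulate_yule_tree(64, seed=seed)
            taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
            rng = np.random.default_rng(900 + seed)
            y = pd.Series(rng.normal(size=64), index=taxa)
            lams.append(cmp.phylogenetic_signal(y, tree))
        assert np.median(lams) <= 0.1

    def test_degenerate_inputs(self):
        tree = rooted("(A:1,B:1);")
        with pytest.raises(ValueError):
            cmp.phylogenetic_signal(pd.Series([1.0, 1.0], index=["A", "B"]),
                                    tree)
        with pytest.raises(ValueError):
            cmp.phylogenetic_signal(pd.Series([1.0, 2.0], index=["A", "B"]),
                                    tree)


class TestVIF:
    def test_orthogonal_covariates_all_retained(self):
        rng = np.random.default_rng(3)
        base = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        q, _ = np.linalg.qr(base)
        design = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])
        retained, dropped, vifs = cmp.vif_eliminate(design)
        assert retained == ["a", "b", "c"] and dropped == []
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in vifs.values())

    def test_duplicate_covariate_dropped_with_infinite_vif(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        design = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=25)})
        retained, dropped, _ = cmp.vif_eliminate(design)
        assert len(retained) == 2 and "c" in retained
        assert np.isinf(dropped[0][1])

    def test_vif_values_match_hand_computed_r2(self):
        """Correlated design: VIF_j = 1/(1-R^2_j) against a direct OLS."""
        rng = np.random.default_rng(7)
        z = rng.normal(size=60)
        design = pd.DataFrame({
            "a": z + 0.3 * rng.normal(size=60),
            "b": z + 0.3 * rng.normal(size=60),
            "c": rng.normal(size=60),
        })
        _, _, _ = cmp.vif_eliminate(design, threshold=1e9)  # no elimination
        retained, dropped, vifs = cmp.vif_eliminate(design, threshold=1e9)
        for col in design.columns:
            others = [c for c in design.columns if c != col]
            X = np.column_stack([np.ones(60)] +
                                [design[c].to_numpy() for c in others])
            yv = design[col].to_numpy()
            coef = np.linalg.lstsq(X, yv, rcond=None)[0]
            r2 = 1 - np.sum((yv - X @ coef) ** 2) / np.sum((yv - yv.mean()) ** 2)
            assert vifs[col] == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_elimination_order_is_largest_first(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=50)
        design = pd.DataFrame({
            "a": z + 0.1 * rng.normal(size=50),
            "b": z + 0.1 * rng.normal(size=50),
            "c": z + 0.5 * rng.normal(size=50),
        })
        retained, dropped, vifs = cmp.vif_eliminate(design, threshold=3.0)
        assert all(v < 3.0 for v in vifs.values())
        assert len(dropped) >= 1


class TestModelSet:
    def test_subset_counts(self):
        assert len(cmp.enumerate_models("y", ["a", "b", "c"])) == 8
        assert len(cmp.enumerate_models("y", [])) == 1

    def test_interaction_requires_main_effects(self):
        specs = cmp.enumerate_models("y", ["a", "b"], interactions=["a:b"])
        assert len(specs) == 5
        for s in specs:
            if "a:b" in s.covariates:
                assert {"a", "b"} <= set(s.covariates)

    def test_invalid_interaction_spec(self):
        with pytest.raises(ValueError):
            ModelSpec("y", ("a", "a:b"))


def fake_fit(covs, aicc, beta=None, se=None, n=20):
    names = ("(intercept)",) + tuple(covs)
    beta = beta or {}
    return PGLSFit(
        spec=ModelSpec("y", tuple(covs)),
        beta={nm: beta.get(nm, 0.0) for nm in names},
        se={nm: (se or {}).get(nm, 0.1) for nm in names},
        lam=0.5, sigma2=1.0, loglik=-aicc / 2, k=len(covs) + 2,
        aicc=aicc, r2=0.5, r2_pred=0.5, n=n, species=frozenset(range(n)))


class TestAICcWeights:
    def test_equal_aicc_gives_equal_weights(self):
        fits = [fake_fit(["a"], 100.0), fake_fit(["b"], 100.0),
                fake_fit([], 100.0)]
        table = cmp.aicc_weights(fits)
        assert np.allclose(table["weight"], 1 / 3)
        assert table["weight"].sum() == pytest.approx(1.0)

    def test_delta_two_closed_form(self):
        table = cmp.aicc_weights([fake_fit(["a"], 100.0),
                                  fake_fit(["b"], 102.0)])
        assert table["weight"].iloc[0] == pytest.approx(0.7311, abs=5e-5)
        assert table["weight"].iloc[1] == pytest.approx(0.2689, abs=5e-5)

    def test_uninformative_model_stays_in_denominator(self):
        fits = [fake_fit(["a"], 100.0), fake_fit(["b"], 108.0)]
        table = cmp.aicc_weights(fits)
        assert not table["informative"].iloc[1]
        assert table["weight"].sum() == pytest.approx(1.0)
        assert table["weight"].iloc[1] > 0

    def test_mismatched_species_sets_rejected(self):
        a = fake_fit(["a"], 100.0, n=20)
        b = fake_fit(["b"], 100.0, n=21)
        with pytest.raises(ValueError):
            cmp.aicc_weights([a, b])


class TestModelAverage:
    def test_single_informative_model_passes_through(self):
        fits = [fake_fit(["a"], 100.0, beta={"a": 0.7}),
                fake_fit([], 120.0)]
        av = cmp.model_average(fits)
        assert av.beta["a"] == pytest.approx(0.7)
        assert av.cumulative_weight["a"] == pytest.approx(
            cmp.aicc_weights(fits)["weight"].iloc[0])

    def test_weighted_mean_by_hand(self):
        # weights 0.6 / 0.4 arise from delta = 2*ln(0.6/0.4)
        d = 2 * np.log(0.6 / 0.4)
        fits = [fake_fit(["a"], 100.0, beta={"a": 1.0}),
                fake_fit(["a", "b"], 100.0 + d, beta={"a": 2.0})]
        av = cmp.model_average(fits)
        assert av.beta["a"] == pytest.approx(1.4, abs=1e-6)
        assert min(1.0, 2.0) <= av.beta["a"] <= max(1.0, 2.0)

    def test_covariate_only_in_uninformative_models_reports_w_only(self):
        fits = [fake_fit(["a"], 100.0, beta={"a": 1.0}),
                fake_fit(["b"], 110.0, beta={"b": 5.0})]
        av = cmp.model_average(fits)
        assert "b" not in av.beta
        assert 0 < av.cumulative_weight["b"] < 0.01

    def test_cumulative_weight_is_presence_sum(self):
        fits = [fake_fit(["a"], 100.0), fake_fit(["a", "b"], 101.0),
                fake_fit(["b"], 103.0), fake_fit([], 102.0)]
        table = cmp.aicc_weights(fits)
        av = cmp.model_average(fits)
        expect = table["weight"][[0, 1]].sum()
        assert av.cumulative_weight["a"] == pytest.approx(expect)


class TestTreeSampleIntervals:
    def test_identical_trees_zero_width(self):
        tree = simulate_yule_tree(15, seed=1)
        y, x = simulate_lambda_traits(tree, 0.8, beta=(0.0, 0.5),
                                      sigma2=1.0, seed=2)
        data = pd.DataFrame({"y": y, "x": x})
        summ = cmp.tree_sample_intervals(ModelSpec("y", ("x",)), data,
                                         [tree, tree, tree])
        assert summ.half_width["x"] == pytest.approx(0.0, abs=1e-10)
        assert summ.n_trees == 3

    def test_perturbed_sample_contains_reference_estimate(self):
        from attini.synthetic_data import make_source_trees
        from attini.dating import (Calibration, apply_calibrations,
                                   branch_lengths_from_ages, impute_node_ages)
        tree = simulate_yule_tree(16, seed=3, root_age=10.0)
        y, x = simulate_lambda_traits(tree, 0.9, beta=(0.0, 0.5),
                                      sigma2=1.0, seed=4)
        data = pd.DataFrame({"y": y, "x": x})
        ref = cmp.pgls_fit(ModelSpec("y", ("x",)), data, tree)
        taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        trees = []
        for t in make_source_trees(tree, 20, keep_fraction=1.0, spr_moves=1,
                                   seed=5):
            t = apply_calibrations(t, [Calibration(age=10.0, taxa=taxa)])
            trees.append(branch_lengths_from_ages(impute_node_ages(t)))
        summ = cmp.tree_sample_intervals(ModelSpec("y", ("x",)), data, trees)
        lo, hi = summ.interval["x"]
        assert lo <= ref.beta["x"] <= hi
        assert lo <= summ.mean_beta["x"] <= hi

    def test_too_few_trees(self):
        tree = simulate_yule_tree(8, seed=1)
        with pytest.raises(ValueError):
            cmp.tree_sample_intervals(ModelSpec("y", ("x",)),
                                      pd.DataFrame(), [tree])


class TestRunAveragedAnalysis:
    def test_low_weight_covariates_excluded_from_uncertainty_model(self):
        tree = simulate_yule_tree(30, seed=9, root_age=1.0)
        y, x = simulate_lambda_traits(tree, 0.9, beta=(0.0, 0.8),
                                      sigma2=0.5, seed=10)
        rng = np.random.default_rng(11)
        data = pd.DataFrame({"y": y, "x": x,
                             "noise": rng.normal(size=len(y))},
                            index=y.index)
        res = cmp.run_averaged_analysis(data, tree, "y", ["x", "noise"],
                                        trees=[tree, tree])
        assert "x" in res["uncertainty_spec"].covariates
        W = res["averaged"].cumulative_weight
        if W["noise"] <= 0.4:
            assert "noise" not in res["uncertainty_spec"].covariates
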