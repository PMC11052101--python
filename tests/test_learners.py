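"""Model zoo: splitting, grid search, presets, segmented fitting and the
full derivation pipeline."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.linear_model import Ridge

from lipedema_rmr import (
    EquationDocument,
    PCRegressionRMR,
    SegmentedSVR,
    derive_published_style_equation,
    fit_segmented,
    grid_search_cv,
    make_learner,
    split_cohort,
)

class TestSplit:
    def test_study_sized_split_is_12_107(self, default_cohort):
        train, test = split_cohort(default_cohort, test_fraction=0.1, seed=0)
        assert (len(train), len(test)) == (107, 12)

    def test_same_seed_identical_and_partition_exhaustive(self, default_cohort):
        t1, s1 = split_cohort(default_cohort, 0.1, seed=5)
        t2, s2 = split_cohort(default_cohort, 0.1, seed=5)
        assert t1.frame.equals(t2.frame) and s1.frame.equals(s2.frame)
        merged = pd.concat([t1.frame, s1.frame]).sort_values("age").reset_index(drop=True)
        orig = default_cohort.frame.sort_values("age").reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, orig)

    def test_half_split_of_four(self, default_cohort):
        small = default_cohort.frame.iloc[:4]
        from lipedema_rmr import Cohort

        train, test = split_cohort(Cohort(small), test_fraction=0.5, seed=1)
        assert (len(train), len(test)) == (2, 2)

    def test_bad_fraction_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            split_cohort(default_cohort, test_fraction=1.5, seed=0)


class TestGridSearch:
    def test_singleton_grid_returned(self, rng):
        X = rng.standard_normal((40, 2))
        y = X @ [1.0, 2.0] + 5.0
        res = grid_search_cv(Ridge(), {"alpha": [0.5]}, X, y, cv_folds=5, seed=0)
        assert res.best_params == {"alpha": 0.5}
        assert len(res.table) == 1

    def test_shrinkage_loses_on_noiseless_linear_data(self, rng):
        X = rng.standard_normal((60, 1))
        y = 2.0 * X[:, 0] + 10.0  # keep y away from 0 so MAPE is defined
        res = grid_search_cv(
            Ridge(), {"alpha": [1e-4, 1e4]}, X, y, cv_folds=5, seed=0
        )
        assert res.best_params == {"alpha": 1e-4}
        assert res.best_score < 1.0

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            grid_search_cv(Ridge(), {"alpha": []}, np.zeros((10, 1)),
                           np.ones(10), seed=0)

    def test_tie_broken_by_grid_order(self, rng):
        X = rng.standard_normal((30, 1))
        y = X[:, 0] + 5.0
        # duplicate candidate: identical scores, first wins
        res = grid_search_cv(
            Ridge(), [{"alpha": [0.1]}, {"alpha": [0.1], "fit_intercept": [True]}],
            X, y, cv_folds=3, seed=0,
        )
        assert res.best_params == {"alpha": 0.1}


class TestPresets:
    def test_published_hyperparameters(self):
        svr = make_learner("svr")
        assert (svr.C, svr.kernel, svr.degree) == (1.0, "poly", 1)
        rfr = make_learner("rfr", random_state=0)
        assert (rfr.n_estimators, rfr.max_depth, rfr.max_features) == (200, 10, "sqrt")
        assert (rfr.min_samples_leaf, rfr.min_samples_split) == (4, 2)
        knn = make_learner("knn")
        assert (knn.n_neighbors, knn.weights) == (6, "uniform")
        assert make_learner("ridge").alpha == pytest.approx(1e-4)
        seg = make_learner("segmented")
        assert (seg.C_lower, seg.C_upper) == (1.5, 1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown learner"):
            make_learner("mlp")

    def test_knn_one_neighbor_memorizes(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        knn = make_learner("knn", n_neighbors=1).fit(X, y)
        np.testing.assert_allclose(knn.predict(X), y)

    def test_ridge_limit_recovers_generating_weights(self, rng):
        X = rng.standard_normal((50, 3))
        w_true = np.array([1.5, -2.0, 0.5])
        y = X @ w_true + 1.0
        ridge = make_learner("ridge", alpha=1e-10).fit(X, y)
        np.testing.assert_allclose(ridge.coef_, w_true, atol=1e-6)

    def test_rfr_predictions_bounded_by_training_targets(self, rng):
        X = rng.standard_normal((80, 3))
        y = rng.normal(1700, 300, 80)
        rfr = make_learner("rfr", random_state=0).fit(X, y)
        pred = rfr.predict(rng.standard_normal((200, 3)))
        assert pred.min() >= y.min() and pred.max() <= y.max()


class TestSegmentedSVR:
    def test_equation_reproduces_branch_svrs(self, rng):
        X = rng.standard_normal((200, 3))
        y = np.tanh(X @ [1.0, 0.5, -0.2]) + rng.normal(0, 0.05, 200)
        seg = fit_segmented(X, y)
        eq = seg.equation_
        # on each branch's own side, the equation equals that branch's SVR
        pts = rng.standard_normal((500, 3))
        g = eq.gate_values(pts)
        lo = g <= eq.gate_threshold
        w1, b1 = eq.branch1_weights, eq.branch1_intercept
        np.testing.assert_allclose(
            eq.predict_standardized(pts)[lo], seg.svr_lower_.predict(pts[lo]),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            eq.predict_standardized(pts)[~lo], seg.svr_upper_.predict(pts[~lo]),
            atol=1e-9,
        )

    def test_threshold_defaults_to_median(self, rng):
        X = rng.standard_normal((100, 2))
        y = X @ [1.0, 1.0] + rng.normal(0, 0.1, 100)
        seg = SegmentedSVR().fit(X, y)
        assert seg.threshold_ == pytest.approx(float(np.median(y)))

    def test_predetermined_threshold_respected(self, rng):
        X = rng.standard_normal((100, 2))
        y = X @ [1.0, 1.0]
        seg = SegmentedSVR(threshold=0.123).fit(X, y)
        assert seg.equation_.gate_threshold == 0.123

    def test_constant_target_degenerates_to_constant_branches(self, rng):
        X = rng.standard_normal((20, 2))
        y = np.full(20, 0.7)
        seg = SegmentedSVR().fit(X, y)
        np.testing.assert_allclose(
            seg.predict(rng.standard_normal((50, 2))), 0.7, atol=1e-6
        )

    def test_tiny_part_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        y = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        with pytest.raises(ValueError, match=">= 2 records"):
            SegmentedSVR().fit(X, y)

    def test_sklearn_clone_compatible(self):
        seg = SegmentedSVR(C_lower=2.0, epsilon=0.01)
        c = clone(seg)
        assert c.get_params() == seg.get_params()


class TestPCRegressionRMR:
    @pytest.mark.parametrize("learner", ["svr", "rfr", "knn", "ridge", "segmented"])
    def test_fit_predict_all_learners(self, default_cohort, learner):
        model = PCRegressionRMR(learner=learner, random_state=0)
        model.fit(default_cohort.predictors, default_cohort.rmr)
        pred = model.predict(default_cohort.predictors)
        assert pred.shape == (119,)
        assert np.all((pred > 600) & (pred < 5000))

    def test_back_transform_correctness(self, default_cohort):
        # with an interpolation-free linear learner, predictions on the raw
        # scale must not depend on the internal target standardization
        X = default_cohort.predictors
        y = default_cohort.rmr
        model = PCRegressionRMR(learner="ridge", learner_params={"alpha": 0.0})
        model.fit(X, y)
        scores = model.pca_.project(X, convention="standard")
        direct = Ridge(alpha=0.0).fit(scores, y).predict(scores)
        np.testing.assert_allclose(model.predict(X), direct, atol=1e-6)

    def test_get_set_params_round_trip(self):
        model = PCRegressionRMR(learner="knn", n_components=2)
        c = clone(model)
        assert c.get_params()["learner"] == "knn"
        assert c.get_params()["n_components"] == 2


class TestDerivation:
    def test_pipeline_completes_with_reasonable_error(self, default_cohort):
        res = derive_published_style_equation(default_cohort, seed=42)
        assert res.n == 119
        assert res.test_mape < 20.0
        assert res.train_mape < 20.0
        assert (res.predictions["split"] == "test").sum() == 12

    def test_threshold_is_full_dataset_median(self, default_cohort):
        res = derive_published_style_equation(default_cohort, seed=42)
        y = default_cohort.rmr
        y_st = (y - y.mean()) / y.std(ddof=1)
        assert res.equation.gate_threshold == pytest.approx(float(np.median(y_st)))

    def test_document_round_trip_bit_identical(self, default_cohort):
        res = derive_published_style_equation(default_cohort, seed=42)
        doc = res.document
        back = EquationDocument.from_json(doc.to_json())
        X = default_cohort.predictors
        assert np.array_equal(back.predict(X), doc.predict(X))
        assert back.to_json() == doc.to_json()

    def test_document_predictions_match_pipeline(self, default_cohort):
        res = derive_published_style_equation(default_cohort, seed=42)
        np.testing.assert_allclose(
            res.document.predict(default_cohort.predictors),
            res.predictions["predicted"].to_numpy(),
            atol=1e-9,
        )

    def test_near_noiseless_linear_cohort_recovered(self):
        # cohort whose predictors sit close to the 3-dim latent manifold
        # (adiposity, age, height) and whose RMR is an exact linear function
        # of observables in that manifold, plus 1% noise
        import dataclasses

        from lipedema_rmr import Cohort, default_config, generate_cohort

        cfg = default_config(n=400, seed=3)

        def shrink(m):
            return dataclasses.replace(m, loading=0.98 * m.sd if m.loading else 0.0)

        cfg = dataclasses.replace(
            cfg, weight=shrink(cfg.weight), pbf=shrink(cfg.pbf),
            waist=shrink(cfg.waist), hips=shrink(cfg.hips),
            vfl=shrink(cfg.vfl), tbw_residual_sd=0.2,
        )
        frame = generate_cohort(cfg).frame
        rng = np.random.default_rng(99)
        signal = -50 + 14 * frame["weight"] + 4 * frame["height"] - 3 * frame["age"]
        frame["rmr"] = signal + rng.normal(0, 0.01 * signal.std(), len(frame))
        res = derive_published_style_equation(
            Cohort(frame), seed=3, learner_params={"epsilon": 0.01}
        )
        assert res.test_mape < 2.0

    def test_missing_rmr_rejected(self, default_cohort):
        from lipedema_rmr import Cohort

        no_rmr = Cohort(default_cohort.predictors)
        with pytest.raises(ValueError, match="measured rmr"):
            derive_published_style_equation(no_rmr, seed=0)
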