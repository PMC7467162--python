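"""Boosted-model training mechanics on a small synthetic dataset.

Statistical recovery quality is exercised at scale in the acceptance
suite; here the contracts are checked: determinism, variant bookkeeping,
grouped CV, baselines, importances.
"""

import numpy as np
import pandas as pd
import pytest

from waxshelix import boosted_models as bm
from waxshelix import dataset_builder as db


class TestTrain:
    def test_deterministic_given_seed_and_config(self, small_dataset, fast_config):
        a = bm.train(small_dataset, "radius", fast_config)
        b = bm.train(small_dataset, "radius", fast_config)
        assert a.report == b.report

    def test_untagged_dataset_rejected(self, small_dataset, fast_config):
        bare = small_dataset.copy()
        bare.split = np.full(bare.n_rows, "", dtype=object)
        with pytest.raises(bm.ModelError, match="split tags"):
            bm.train(bare, "radius", fast_config)

    def test_unknown_descriptor_rejected(self, small_dataset, fast_config):
        with pytest.raises(bm.ModelError, match="unknown descriptor"):
            bm.train(small_dataset, "minor_groove", fast_config)

    def test_report_has_split_metrics_and_confusion(self, small_dataset, fast_config):
        reg = bm.train(small_dataset, "rise", fast_config)
        assert {"train_mse", "validation_mse", "test_mse", "test_r2"} <= set(reg.report)
        assert np.shape(reg.report["test_confusion_discretized"]) == (10, 10)
        clf = bm.train(small_dataset, "aform_class", fast_config)
        assert {"train_accuracy", "test_accuracy"} <= set(clf.report)
        assert np.shape(clf.report["test_confusion"]) == (12, 12)

    def test_mutated_test_rows_block_evaluation(self, small_dataset, fast_config):
        ds = small_dataset.copy()
        ds.features[ds.rows("test")[0], 5] *= 1.01
        with pytest.raises(db.DatasetError, match="test rows changed"):
            bm.train(ds, "radius", fast_config)


class TestVariants:
    def test_five_variants_with_expected_feature_widths(self, small_dataset,
                                                        fast_config):
        bundles = bm.train_variants(small_dataset, "radius", fast_config)
        assert set(bundles) == set(bm.VARIANTS)
        assert bundles["noise-free"].report["n_features"] == 191
        assert bundles["sparse"].report["n_features"] == 100
        assert bundles["dense"].report["n_features"] == 400
        # noisy training data is harder to fit than clean data
        assert (bundles["noisy"].report["train_mse"]
                >= bundles["noise-free"].report["train_mse"])

    def test_random_control_much_worse_than_real_labels(self, small_dataset,
                                                        fast_config):
        bundles = bm.train_variants(small_dataset, "radius", fast_config)
        assert (bundles["random"].report["test_mse"]
                > 3 * bundles["noise-free"].report["test_mse"])


class TestCrossValidate:
    def test_folds_partition_conformations(self, small_dataset, fast_config):
        mean, sd, scores = bm.cross_validate(small_dataset, "radius", k=5,
                                             config=fast_config)
        assert len(scores) == 5
        assert sd >= 0
        assert mean == pytest.approx(np.mean(scores))

    def test_constant_labels_give_zero_mse(self, small_dataset, fast_config):
        ds = small_dataset.copy()
        ds.labels["radius"] = 5.0
        ds.meta["test_hash"] = db._test_hash(ds)
        mean, sd, _ = bm.cross_validate(ds, "radius", k=4, config=fast_config)
        assert mean == pytest.approx(0.0, abs=1e-4)
        assert sd == pytest.approx(0.0, abs=1e-4)

    def test_too_many_folds_rejected(self, small_dataset, fast_config):
        with pytest.raises(bm.ModelError, match="exceeds"):
            bm.cross_validate(small_dataset, "radius", k=200, config=fast_config)


class TestLearningCurve:
    def test_full_size_reproduces_train_metric(self, small_dataset, fast_config):
        n_train = len(small_dataset.rows("train"))
        curve = bm.learning_curve(small_dataset, "radius", [n_train],
                                  fast_config, seeds=(fast_config.seed,))
        direct = bm.train(small_dataset, "radius", fast_config)
        assert curve.iloc[0]["test_metric"] == pytest.approx(
            direct.report["test_mse"]
        )

    def test_unsorted_sizes_rejected(self, small_dataset, fast_config):
        with pytest.raises(bm.ModelError, match="ascending"):
            bm.learning_curve(small_dataset, "radius", [90, 45], fast_config)


class TestLinearBaselines:
    def test_linear_toy_is_solved_by_linear_models(self, small_dataset):
        """Labels = a fixed linear functional of features -> near-zero MSE."""
        ds = small_dataset.copy()
        w = np.zeros(ds.features.shape[1])
        w[[10, 50, 120]] = [1.0, -2.0, 0.5]
        ds.labels["radius"] = ds.features @ w + 3.0
        ds.meta["test_hash"] = db._test_hash(ds)
        out = bm.linear_baselines(ds, "radius", lasso_alpha=1e-6)
        assert out["linear"]["test_mse"] < 1e-8
        assert out["lasso"]["test_mse"] < 1e-3

    def test_ridge_at_zero_penalty_equals_ols(self):
        """On a well-conditioned design the ridge solution at zero penalty
        coincides with ordinary least squares (log-profile features are too
        collinear for the solver identity to hold numerically)."""
        rng = np.random.default_rng(1)
        n, k = 270, 15
        feats = rng.normal(size=(n, k))
        labels = pd.DataFrame({
            "radius": feats @ rng.normal(size=k) + rng.normal(0, 0.1, n),
            "twist": np.ones(n), "rise": np.ones(n),
            "major_groove_width": np.ones(n),
            "aform_class": np.ones(n, dtype=int),
        })
        split = np.array(
            ["train"] * 180 + ["validation"] * 45 + ["test"] * 45, dtype=object
        )
        ds = db.LabeledDataset(
            features=feats, labels=labels,
            groups=np.array([f"c{i}" for i in range(n)], dtype=object),
            conditions=np.full(n, "x", dtype=object), split=split,
            qgrid=__import__("waxshelix.scattering", fromlist=["QGrid"]).QGrid(
                np.linspace(0.0, 1.0, k)),
        )
        ds.meta["test_hash"] = db._test_hash(ds)
        out = bm.linear_baselines(ds, "radius", ridge_alpha=0.0)
        assert out["ridge"]["test_mse"] == pytest.approx(
            out["linear"]["test_mse"], rel=1e-6
        )

    def test_classifier_descriptor_rejected(self, small_dataset):
        with pytest.raises(bm.ModelError, match="regression"):
            bm.linear_baselines(small_dataset, "aform_class")


class TestImportance:
    def test_traces_normalized_and_nonnegative(self, small_dataset, fast_config):
        bundle = bm.train(small_dataset, "radius", fast_config)
        trace = bm.importance(bundle)
        for kind in ("gain", "weight"):
            v = trace.trace(kind)
            assert v.min() >= 0
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
            assert len(v) == 191

    def test_unused_feature_has_zero_weight(self, small_dataset, fast_config):
        bundle = bm.train(small_dataset, "radius", fast_config)
        trace = bm.importance(bundle)
        used = bundle.model.get_booster().get_score(importance_type="weight")
        used_idx = {int(k[1:]) for k in used}
        unused = set(range(191)) - used_idx
        assert unused  # a 60-tree model cannot touch all 191 features
        assert all(trace.weight[i] == 0 for i in unused)

    def test_untrained_model_rejected(self, small_dataset, fast_config):
        from xgboost import XGBRegressor

        bundle = bm.ModelBundle(
            descriptor="radius", task="regression", variant="noise-free",
            model=XGBRegressor(), config=fast_config,
            qgrid=small_dataset.qgrid, report={},
        )
        with pytest.raises(bm.ModelError, match="not trained"):
            bm.importance(bundle)


class TestSerialization:
    def test_bundle_round_trip_predictions_identical(self, small_dataset,
                                                     fast_config, tmp_path):
        for descriptor in ("radius", "aform_class"):
            bundle = bm.train(small_dataset, descriptor, fast_config)
            bm.save_bundle(bundle, tmp_path / descriptor)
            back = bm.load_bundle(tmp_path / descriptor)
            X = small_dataset.features[small_dataset.rows("test")]
            assert np.array_equal(back.predict(X), bundle.predict(X))
            assert back.report == bundle.report

    def test_grid_mismatch_raises_on_predict(self, small_dataset, fast_config):
        bundle = bm.train(small_dataset, "radius", fast_config)
        with pytest.raises(bm.ModelError, match="resample"):
            bundle.predict(np.zeros((3, 100)))


def test_shannon_channels_formula():
    """n_s = q_max * D_max / pi for a ~30 A duplex at q_max = 0.95."""
    n_s = bm.shannon_channels(0.95, 30.0)
    assert n_s == pytest.approx(0.95 * 30.0 / np.pi)
    assert 9 < n_s < 10
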