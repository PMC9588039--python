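"""Score normalization, augmentation, loss, splits, training, and statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfgcn.model import ModelConfig, build_model
from surfgcn.training import (
    Adam,
    TrainConfig,
    augment,
    benjamini_hochberg,
    compare_models,
    compute_loss,
    ensemble_predict,
    evaluate,
    hcp_preset,
    loss_prediction_gradient,
    make_nested_splits,
    quantile_normalize,
    train_fold,
    train_model,
)


class TestQuantileNormalize:
    def test_three_value_worked_example(self):
        out = quantile_normalize([10.0, 30.0, 20.0])
        np.testing.assert_allclose(out, [-0.9674, 0.9674, 0.0], atol=1e-3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60, unique=True))
    def test_rank_order_preserved(self, scores):
        out = quantile_normalize(scores)
        assert np.array_equal(np.argsort(scores, kind="stable"),
                              np.argsort(out, kind="stable"))

    def test_moments_near_standard_normal(self):
        rng = np.random.default_rng(0)
        out = quantile_normalize(rng.gamma(2.0, size=500))
        assert abs(out.mean()) < 0.05
        assert abs(out.std() - 1.0) < 0.05

    def test_sampled_mode_same_ranks_different_values(self):
        scores = [5.0, 1.0, 3.0]
        a = quantile_normalize(scores, mode="sampled", seed=1)
        b = quantile_normalize(scores, mode="sampled", seed=2)
        assert np.array_equal(np.argsort(a), np.argsort(b))
        assert not np.allclose(a, b)

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize([1.0])


class TestAugment:
    def test_probability_zero_is_identity(self):
        cfg = TrainConfig(p_a=0.0)
        coords = np.random.default_rng(0).normal(size=(50, 3))
        out = augment(coords, cfg, np.random.default_rng(1))
        np.testing.assert_array_equal(out, coords)

    def test_rotation_preserves_pairwise_distances(self):
        cfg = TrainConfig(p_a=1.0, noise_sigma=0.0, rotation_limit_deg=20.0)
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(40, 3)) * 30
        out = augment(coords, cfg, np.random.default_rng(3))
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(out), pdist(coords), atol=1e-9)
        assert not np.allclose(out, coords)  # it did rotate

    def test_noise_has_stated_standard_deviation(self):
        cfg = TrainConfig(p_a=1.0, noise_sigma=0.02, rotation_limit_deg=0.0)
        coords = np.zeros((40000, 3))  # > 1e5 coordinate values
        out = augment(coords, cfg, np.random.default_rng(4))
        sd = (out - coords).std()
        assert abs(sd - 0.02) / 0.02 < 0.02

    def test_rotation_angles_bounded(self):
        cfg = TrainConfig(p_a=1.0, noise_sigma=0.0, rotation_limit_deg=20.0)
        coords = np.eye(3) * 100
        for seed in range(20):
            out = augment(coords, cfg, np.random.default_rng(seed))
            # a composition of three rotations <= 20 deg each cannot rotate
            # any vector by more than 60 degrees
            c = coords - coords.mean(0)
            o = out - out.mean(0)
            cos = np.sum(c * o, axis=1) / (
                np.linalg.norm(c, axis=1) * np.linalg.norm(o, axis=1)
            )
            assert np.all(np.degrees(np.arccos(np.clip(cos, -1, 1))) < 60.0 + 1e-6)


class TestLoss:
    def test_reduces_to_mse_without_penalties(self):
        loss = compute_loss([1.0, 2.0], [0.0, 0.0], None, 0.0, 0.0)
        assert loss.total == pytest.approx(2.5, abs=1e-12)
        assert loss.total == loss.mse_term

    def test_perfect_prediction_with_corr_only(self):
        loss = compute_loss([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], None, 0.0, 1.0)
        assert loss.total == pytest.approx(-1.0, abs=1e-10)
        assert loss.corr_term == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_guard(self):
        loss = compute_loss([0.0, 0.0], [1.0, -1.0], None, 0.0, 1.0)
        assert loss.corr_term == 0.0
        assert loss.total == pytest.approx(1.0, abs=1e-12)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(5)
        y_p, y_t = rng.normal(size=(2, 20))
        w = [rng.normal(size=(3, 4))]
        loss = compute_loss(y_p, y_t, w, 0.3, 0.7)
        assert loss.total == pytest.approx(
            loss.mse_term + 0.3 * loss.reg_term - 0.7 * loss.corr_term, abs=1e-10
        )
        assert -1.0 <= loss.corr_term <= 1.0

    def test_reg_counts_weight_arrays(self):
        w = [np.array([[1.0, 2.0]]), np.array([3.0])]
        loss = compute_loss([0.0], [0.0], w, 1.0, 0.0)
        assert loss.reg_term == pytest.approx(14.0)

    def test_prediction_gradient_matches_numeric(self):
        rng = np.random.default_rng(6)
        y_p = rng.normal(size=12)
        y_t = rng.normal(size=12)
        g = loss_prediction_gradient(y_p, y_t, lambda2=0.8)
        eps = 1e-7
        for i in [0, 5, 11]:
            up = y_p.copy(); up[i] += eps
            dn = y_p.copy(); dn[i] -= eps
            num = (
                compute_loss(up, y_t, None, 0.0, 0.8).total
                - compute_loss(dn, y_t, None, 0.0, 0.8).total
            ) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-5, abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_loss([1.0], [1.0, 2.0])


class TestNestedSplits:
    def test_even_folds_for_12_subjects(self):
        split = make_nested_splits([f"s{i}" for i in range(12)], 6, 5, seed=0)
        sizes = [len(f) for f in split.outer_folds]
        assert sizes == [2] * 6
        all_ids = np.concatenate(split.outer_folds)
        assert len(np.unique(all_ids)) == 12

    def test_abcd_scale_fold_sizes(self):
        split = make_nested_splits([f"s{i}" for i in range(8070)], 6, 5, seed=1)
        assert all(len(f) == 1345 for f in split.outer_folds)

    def test_hcp_scale_fold_sizes(self):
        split = make_nested_splits([f"s{i}" for i in range(1097)], 6, 5, seed=1)
        sizes = [len(f) for f in split.outer_folds]
        assert max(sizes) == 183
        assert sum(sizes) == 1097
        assert len(split.outer_train(0)) == 1097 - 183 == 914

    def test_no_leakage_across_many_seeds(self):
        ids = [f"s{i}" for i in range(61)]
        for seed in range(1000):
            split = make_nested_splits(ids, 6, 5, seed=seed)
            for k in range(6):
                test = set(split.outer_folds[k].tolist())
                inner = split.inner_folds[k]
                inner_sets = [set(f.tolist()) for f in inner]
                union = set().union(*inner_sets)
                assert union.isdisjoint(test)
                assert union == set(split.outer_train(k).tolist())
                for a in range(5):
                    for b in range(a + 1, 5):
                        assert inner_sets[a].isdisjoint(inner_sets[b])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_nested_splits(["a", "b"], outer_k=6)


@pytest.fixture(scope="module")
def tiny_train_cfg():
    return TrainConfig(max_epochs=5, learning_rate=1e-3, p_a=0.0, patience=5,
                       batch_size=4, seed=0)


@pytest.fixture(scope="module")
def tiny_model_cfg():
    return ModelConfig(input_features=9, channels=(4, 4, 6, 6), dropout_rate=0.0,
                       seed=0)


class TestTrainModel:
    def test_zero_learning_rate_leaves_parameters(self, tiny_dataset, tiny_model_cfg,
                                                  tiny_train_cfg):
        from dataclasses import replace

        cfg = replace(tiny_train_cfg, learning_rate=0.0, max_epochs=2,
                      center_features=False)
        model = build_model(tiny_model_cfg, tiny_dataset.hierarchy)
        before = {k: v.copy() for k, v in model.state_dict().items()
                  if "running" not in k}
        trained, _ = train_model(tiny_dataset, np.arange(6), np.arange(6, 8),
                                 tiny_model_cfg, cfg, model=model)
        after = trained.state_dict()
        for k, v in before.items():
            np.testing.assert_array_equal(after[k], v)

    def test_overfits_tiny_cohort(self):
        # 16 subjects, strong signal, no augmentation: training MSE must
        # collapse by at least half within the epoch budget
        from surfgcn.experiments import build_synthetic_dataset
        from surfgcn.synthetic_data import SyntheticSpec

        spec = SyntheticSpec(cortex_subdivisions=1, subcortical_subdivisions=0,
                             n_subjects=16, effect_geodesic_radius=30.0,
                             noise_sd=0.0, seed=3)
        ds, _, _ = build_synthetic_dataset(spec)
        mcfg = ModelConfig(input_features=9, channels=(4, 4, 8, 8),
                           dropout_rate=0.0, seed=1)
        tcfg = TrainConfig(max_epochs=60, learning_rate=2e-3, p_a=0.0,
                           patience=60, batch_size=8, lambda1=0.0, seed=1)
        idx = np.arange(16)
        model, logs = train_model(ds, idx, idx, mcfg, tcfg)
        first = logs[0]["train_loss"]
        best = min(l["train_loss"] for l in logs)
        assert best <= 0.5 * first

    def test_early_stopping_halts_patience_epochs_after_best(self, tiny_dataset,
                                                             tiny_model_cfg):
        cfg = TrainConfig(max_epochs=50, learning_rate=0.0, p_a=0.0, patience=3,
                          batch_size=4, seed=0)
        _, logs = train_model(tiny_dataset, np.arange(6), np.arange(6, 8),
                              tiny_model_cfg, cfg)
        assert len(logs) < 50
        best_epoch = int(np.argmin([l["val_mse"] for l in logs]))
        assert len(logs) == best_epoch + cfg.patience + 1

    def test_empty_fold_raises(self, tiny_dataset, tiny_model_cfg, tiny_train_cfg):
        with pytest.raises(ValueError):
            train_model(tiny_dataset, np.array([], dtype=int), np.arange(2),
                        tiny_model_cfg, tiny_train_cfg)


class TestEnsemble:
    def test_identical_members_equal_single_model(self, tiny_dataset, tiny_model_cfg):
        model = build_model(tiny_model_cfg, tiny_dataset.hierarchy)
        model.eval_mode()
        single = model.forward(tiny_dataset.padded_features([0, 1]))
        ens = ensemble_predict([model, model, model], tiny_dataset, [0, 1])
        np.testing.assert_allclose(ens, single, atol=1e-12)

    def test_two_members_average(self, tiny_dataset, tiny_model_cfg):
        from dataclasses import replace

        m1 = build_model(tiny_model_cfg, tiny_dataset.hierarchy)
        m2 = build_model(replace(tiny_model_cfg, seed=9), tiny_dataset.hierarchy)
        for m in (m1, m2):
            m.eval_mode()
        x = tiny_dataset.padded_features([0, 1, 2])
        expected = (m1.forward(x) + m2.forward(x)) / 2.0
        np.testing.assert_allclose(ensemble_predict([m1, m2], tiny_dataset,
                                                    [0, 1, 2]), expected, atol=1e-10)

    def test_ensembling_never_hurts_mse(self):
        # convexity: MSE of the mean prediction <= mean of member MSEs
        rng = np.random.default_rng(7)
        for _ in range(50):
            preds = rng.normal(size=(5, 30))
            target = rng.normal(size=30)
            ens_mse = np.mean((preds.mean(axis=0) - target) ** 2)
            member_mse = np.mean((preds - target) ** 2, axis=1).mean()
            assert ens_mse <= member_mse + 1e-12

    def test_config_mismatch_rejected(self, tiny_dataset, tiny_model_cfg):
        from dataclasses import replace

        m1 = build_model(tiny_model_cfg, tiny_dataset.hierarchy)
        m2 = build_model(replace(tiny_model_cfg, channels=(4, 4, 8, 8)),
                         tiny_dataset.hierarchy)
        with pytest.raises(ValueError):
            ensemble_predict([m1, m2], tiny_dataset, [0])


class TestEvaluate:
    def test_perfect_prediction(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.mse == 0.0 and m.pearson_r == pytest.approx(1.0)

    def test_shifted_prediction(self):
        m = evaluate([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
        assert m.mse == pytest.approx(1.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_anticorrelation(self):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        m = evaluate(-y, y)
        assert m.pearson_r == pytest.approx(-1.0)

    def test_confidence_interval_brackets_r(self):
        rng = np.random.default_rng(8)
        y_t = rng.normal(size=200)
        y_p = 0.6 * y_t + rng.normal(size=200) * 0.8
        m = evaluate(y_p, y_t)
        lo, hi = m.r_ci
        assert lo < m.pearson_r < hi
        assert -1.0 <= lo and hi <= 1.0

    def test_prediction_interval_width_covers_residuals(self):
        # the interval is centered at the regression line at the mean
        # prediction; its half-width should cover ~95% of residuals
        rng = np.random.default_rng(9)
        y_t = rng.normal(size=500)
        y_p = 0.9 * y_t + rng.normal(size=500) * 0.3
        m = evaluate(y_p, y_t)
        lo, hi = m.prediction_interval
        assert lo < hi
        half = (hi - lo) / 2.0
        slope, intercept = np.polyfit(y_p, y_t, 1)
        resid = y_t - (slope * y_p + intercept)
        cover = np.mean(np.abs(resid) <= half)
        assert 0.9 < cover <= 1.0

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestModelComparison:
    def test_identical_samples_give_p_one(self):
        r = np.array([0.3, 0.31, 0.29, 0.32, 0.3, 0.28])
        out = compare_models({("all", "cor"): (r, r.copy())})
        res = out[("all", "cor")]
        assert res["t"] == 0.0 and res["p_raw"] == 1.0
        assert res["p_adjusted"] == 1.0 and not res["significant"]

    def test_bh_worked_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_comparison_unchanged(self):
        adj = benjamini_hochberg([0.0421])
        np.testing.assert_allclose(adj, [0.0421])

    def test_detects_consistent_difference(self):
        a = np.array([0.40, 0.42, 0.41, 0.43, 0.39, 0.44])
        b = a - 0.1
        out = compare_models({("all", "sub"): (a, b)})
        assert out[("all", "sub")]["p_adjusted"] < 0.05
        assert out[("all", "sub")]["significant"]


class TestAdamSchedule:
    def test_learning_rate_decays_every_10_steps(self, tiny_dataset, tiny_model_cfg):
        model = build_model(tiny_model_cfg, tiny_dataset.hierarchy)
        opt = Adam(model, TrainConfig(learning_rate=1e-3, lr_decay=0.99,
                                      lr_decay_every=10))
        assert opt.lr == 1e-3
        for _ in range(10):
            model.zero_grad()
            opt.step()
        assert opt.lr == pytest.approx(1e-3 * 0.99)


def test_hcp_preset_values():
    cfg = hcp_preset()
    assert cfg.batch_size == 50
    assert cfg.lambda1 == pytest.approx(5e-4)
    assert cfg.max_epochs == 80
    assert cfg.learning_rate == pytest.approx(5e-4)
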