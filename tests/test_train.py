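"""Training harness: metrics, schedules, checkpointing, determinism."""

import numpy as np
import pytest

from ecgage import models
from ecgage.train import (TrainConfig, cross_validate, evaluate, train_fold)


def _toy_graph(seed=0, L=1024):
    return models.build_attianet(
        models.AttiaConfig(filters=(4, 4), kernels=(7, 3), pools=(8, 8),
                           spatial_filters=4, spatial_pool=2, head=(4, 4, 4)),
        input_len=L, seed=seed)


class TestEvaluate:
    def test_perfect_predictions(self):
        g = _toy_graph()
        X = np.zeros((2, 12, 1024), dtype=np.float32)
        ages = np.array([0.0, 0.0])
        for p in g.parameters():
            p.value[...] = 0.0
        res = evaluate(g, X, ages)
        assert res.mse == 0.0 and res.mae == 0.0 and res.mae_sd == 0.0

    def test_constant_predictor_closed_form(self):
        # predictor stuck at 60 on ages {50, 70}: MSE 100, MAE 10 +/- 0
        g = _toy_graph()
        for p in g.parameters():
            p.value[...] = 0.0
        out_bias = next(p for p in g.parameters() if p.name == "head.out.bias")
        out_bias.value[...] = 60.0
        X = np.random.default_rng(0).normal(0, 1, (2, 12, 1024)).astype(np.float32)
        res = evaluate(g, X, np.array([50.0, 70.0]))
        assert res.mse == pytest.approx(100.0)
        assert res.mae == pytest.approx(10.0)
        assert res.mae_sd == pytest.approx(0.0)
        assert res.pred_mean == pytest.approx(60.0)

    def test_permutation_invariance(self, small_cohort):
        _, _, cache = small_cohort
        g = _toy_graph(seed=3)
        X = np.pad(cache.signals, ((0, 0), (0, 0), (0, 24)))
        ages = cache.ages
        perm = np.random.default_rng(1).permutation(len(X))
        a = evaluate(g, X, ages)
        b = evaluate(g, X[perm], ages[perm])
        assert a.mse == pytest.approx(b.mse)
        assert a.mae == pytest.approx(b.mae)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ages"):
            evaluate(_toy_graph(), np.zeros((3, 12, 1024), dtype=np.float32),
                     np.zeros(2))


class TestSchedule:
    def test_learning_rate_trace_under_defaults(self):
        cfg = TrainConfig()
        assert cfg.lr_at(1) == pytest.approx(1e-3)
        assert cfg.lr_at(80) == pytest.approx(1e-3)
        assert cfg.lr_at(81) == pytest.approx(1e-4)
        assert cfg.lr_at(160) == pytest.approx(1e-4)
        assert cfg.lr_at(161) == pytest.approx(1e-5)

    def test_defaults_match_protocol(self):
        cfg = TrainConfig()
        assert cfg.epochs == 200
        assert cfg.batch_size == 96
        assert cfg.lr == pytest.approx(0.001)


class TestTrainFold:
    def test_zero_epochs_returns_initial_weights(self, small_cohort):
        _, _, cache = small_cohort
        g = _toy_graph(seed=9)
        before = {p.name: p.value.copy() for p in g.parameters()}
        res = train_fold(g, cache, 0, TrainConfig(epochs=0, seed=1))
        for p in g.parameters():
            assert np.array_equal(p.value, before[p.name])
        assert np.isfinite(res.test_mse)
        assert res.best_epoch == 0

    def test_same_seed_identical_fold_result(self, small_cohort):
        _, _, cache = small_cohort
        cfg = TrainConfig(epochs=2, batch_size=16, seed=5)
        r1 = train_fold(_toy_graph(seed=2), cache, 0, cfg)
        r2 = train_fold(_toy_graph(seed=2), cache, 0, cfg)
        assert r1.test_mse == r2.test_mse
        assert r1.test_mae == r2.test_mae
        assert [h["val_mse"] for h in r1.history] == [h["val_mse"]
                                                      for h in r2.history]

    def test_checkpoint_restores_minimum_of_val_curve(self, learnability_run):
        res = learnability_run["result"]
        curve = [h["val_mse"] for h in res.history]
        assert res.best_val_mse == pytest.approx(min(curve))
        assert all(res.best_val_mse <= v for v in curve)

    def test_training_reduces_mse_below_learnability_floor(self,
                                                           learnability_run):
        # the synthetic age signal is learnable: final train MSE must beat a
        # quarter of the age variance (the mean predictor's MSE)
        res = learnability_run["result"]
        ages = learnability_run["cohort"].ages
        assert res.history[-1]["train_mse"] < 0.25 * ages.var()

    def test_missing_fold_rejected(self, small_cohort):
        _, _, cache = small_cohort
        with pytest.raises(ValueError, match="fold"):
            train_fold(_toy_graph(), cache, 23, TrainConfig(epochs=0))


class TestCrossValidate:
    def test_constant_stub_matches_closed_form(self, small_cohort):
        # a constant predictor's per-fold test MSE is the second moment of
        # the test ages about that constant
        _, _, cache = small_cohort

        def builder(fold):
            g = _toy_graph(seed=fold)
            for p in g.parameters():
                p.value[...] = 0.0
            next(p for p in g.parameters()
                 if p.name == "head.out.bias").value[...] = 55.0
            return g

        results, mean = cross_validate(builder, cache,
                                       TrainConfig(epochs=0, seed=0),
                                       folds=[0, 1, 2])
        for r in results:
            idx = np.flatnonzero(cache.folds == r.fold)
            want = np.mean((cache.ages[idx] - 55.0) ** 2)
            assert r.test_mse == pytest.approx(want)
        assert mean["test_mse"] == pytest.approx(
            np.mean([r.test_mse for r in results]))

    def test_ten_folds_yield_ten_results(self, small_cohort):
        _, _, cache = small_cohort
        results, _ = cross_validate(lambda f: _toy_graph(seed=f), cache,
                                    TrainConfig(epochs=0, seed=0))
        assert len(results) == 10
        assert sorted(r.fold for r in results) == list(range(10))

    def test_missing_fold_detected(self, small_cohort):
        _, _, cache = small_cohort
        trimmed = cache.folds.copy()
        import dataclasses
        broken = dataclasses.replace(
            cache, folds=np.where(trimmed == 9, 0, trimmed))
        with pytest.raises(ValueError, match="9"):
            cross_validate(lambda f: _toy_graph(), broken,
                           TrainConfig(epochs=0))
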