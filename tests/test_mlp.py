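"""Network forward pass, trainer behavior and cross-validated evaluation."""

import numpy as np
import pytest

from fungicast import (
    MLPModel,
    ScalerParams,
    TrainConfig,
    crossval_evaluate,
    make_cv_plan,
    r_squared,
    rmse,
    train_mlp,
)
from fungicast.errors import DegenerateDataError, DomainError


def _identity_scaler(ncols):
    return ScalerParams(center=np.zeros(ncols), half=np.ones(ncols))


class TestMetrics:
    def test_perfect_prediction(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        assert r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        obs, pred = [1.0, 2.0, 3.0], [1.0, 2.0, 5.0]
        assert rmse(obs, pred) == pytest.approx(np.sqrt(4 / 3))
        assert r_squared(obs, pred) == pytest.approx(-1.0)

    def test_constant_observed_undefined(self):
        with pytest.raises(DegenerateDataError):
            r_squared([2.0, 2.0], [1.0, 3.0])


class TestForward:
    def test_hand_set_single_neuron(self):
        """w1=1, b1=0, w2=2, b2=0.5 at scaled input 0 gives tanh(0)*2+0.5."""
        model = MLPModel(
            W1=np.array([[1.0]]),
            b1=np.zeros(1),
            w2=np.array([2.0]),
            b2=0.5,
            input_scaler=_identity_scaler(1),
            target_scaler=_identity_scaler(1),
        )
        assert model.forward_scaled([[0.0]])[0] == pytest.approx(0.5)
        # and a non-trivial point: 2*tanh(1) + 0.5
        assert model.forward_scaled([[1.0]])[0] == pytest.approx(2 * np.tanh(1.0) + 0.5)

    def test_zero_weights_give_constant_inverse_transform_of_bias(self):
        target_scaler = ScalerParams(center=np.array([10.0]), half=np.array([5.0]))
        model = MLPModel(
            W1=np.zeros((3, 4)),
            b1=np.zeros(3),
            w2=np.zeros(3),
            b2=0.0,
            input_scaler=_identity_scaler(4),
            target_scaler=target_scaler,
        )
        X = np.random.default_rng(0).normal(size=(7, 4))
        assert np.allclose(model.predict(X), 10.0)  # inverse transform of 0

    def test_tanh_saturation(self):
        model = MLPModel(
            W1=np.array([[1.0]]),
            b1=np.zeros(1),
            w2=np.array([1.0]),
            b2=0.0,
            input_scaler=_identity_scaler(1),
            target_scaler=_identity_scaler(1),
        )
        assert model.forward_scaled([[1e3]])[0] == pytest.approx(1.0, abs=1e-9)

    def test_wrong_arity_raises(self):
        model = MLPModel(
            W1=np.zeros((2, 4)),
            b1=np.zeros(2),
            w2=np.zeros(2),
            b2=0.0,
            input_scaler=_identity_scaler(4),
            target_scaler=_identity_scaler(1),
        )
        with pytest.raises(DomainError):
            model.forward_scaled(np.ones((3, 5)))


class TestTraining:
    def test_representability_noiseless_linear(self, smooth_benchmark):
        from fungicast import generate_linear_benchmark

        bench = generate_linear_benchmark((2, 0, 0, 0), intercept=5, noise_sd=0,
                                          n_records=200, seed=7)
        y = bench.frame["response"].to_numpy()
        model = train_mlp(bench.X, y, 3, TrainConfig(seed=1))
        assert r_squared(y, model.predict(bench.X)) >= 0.999

    def test_constant_target_reaches_bias_solution(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 100, size=(40, 4))
        y = np.full(40, 7.5)
        model = train_mlp(X, y, 2, TrainConfig(seed=3))
        assert rmse(y, model.predict(X)) <= 1e-6

    def test_xor_representability(self):
        """Classic parity on the 4 corner points needs a hidden layer."""
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0.0, 1.0, 1.0, 0.0])
        cfg = TrainConfig(
            seed=5, val_fraction=0.0, min_records_per_neuron=0,
            max_epochs=4000, n_restarts=5,
        )
        model = train_mlp(X, y, 3, cfg)
        assert np.max(np.abs(model.predict(X) - y)) < 0.1

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 100, size=(60, 4))
        y = X[:, 0] * 0.3 + rng.normal(0, 1, 60) + 10
        m1 = train_mlp(X, y, 3, TrainConfig(seed=11))
        m2 = train_mlp(X, y, 3, TrainConfig(seed=11))
        assert np.array_equal(m1.W1, m2.W1)
        assert np.array_equal(m1.w2, m2.w2)
        assert np.allclose(m1.predict(X), m2.predict(X))

    def test_overparameterization_guard(self):
        X = np.random.default_rng(1).uniform(size=(20, 4))
        with pytest.raises(DomainError, match="too few"):
            train_mlp(X, X[:, 0], 10, TrainConfig(seed=0))

    def test_monotone_capacity_on_smooth_benchmark(self, smooth_benchmark):
        """Best-of-restarts training RMSE does not increase with hidden size."""
        y = smooth_benchmark.frame["response"].to_numpy()
        best = []
        for h in (1, 2, 4, 8):
            runs = [
                rmse(y, train_mlp(
                    smooth_benchmark.X, y, h,
                    TrainConfig(seed=s, val_fraction=0.0, min_records_per_neuron=0),
                ).predict(smooth_benchmark.X))
                for s in range(5)
            ]
            best.append(min(runs))
        tol = 1.05  # small slack: finite-epoch optimization is not exact
        assert all(b2 <= b1 * tol for b1, b2 in zip(best, best[1:]))


class TestCrossval:
    def test_fold_count_and_plan_hash(self, synth_dataset, full_plan):
        sub = full_plan.subset_replicates(2)
        report = crossval_evaluate(synth_dataset, "YIELD", 2, sub, TrainConfig(seed=3))
        assert len(report.per_fold) == 2 * 5
        assert report.plan_hash == sub.plan_hash

    def test_smooth_noiseless_target_is_learned(self, smooth_benchmark):
        plan = make_cv_plan(len(smooth_benchmark.frame), seed=7, n_replicates=2)
        report = crossval_evaluate(
            smooth_benchmark, "response", 4, plan, TrainConfig(seed=2), boxcox=None
        )
        assert report.test_r2 >= 0.99

    def test_shuffled_target_negative_control(self, synth_dataset, full_plan):
        """Permuting the labels destroys the signal: pooled test R² collapses."""
        frame = synth_dataset.frame.copy()
        rng = np.random.default_rng(13)
        frame["yield_g"] = rng.permutation(frame["yield_g"].to_numpy())
        shuffled = type(synth_dataset)(frame=frame, provenance={})
        report = crossval_evaluate(
            shuffled, "YIELD", 3, full_plan.subset_replicates(1), TrainConfig(seed=3)
        )
        assert report.test_r2 <= 0.2

    def test_pooled_metrics_derive_from_held_out_predictions(self, synth_dataset, full_plan):
        """With one shuffle replicate, every record is held out exactly once and
        the pooled test metrics must equal metrics recomputed from the per-record
        held-out predictions — the test pool cannot contain training rows."""
        plan1 = full_plan.subset_replicates(1)
        report = crossval_evaluate(synth_dataset, "BE", 2, plan1, TrainConfig(seed=5))
        preds = report.predictions
        assert (preds["n_test_appearances"] == 1).all()
        assert r_squared(preds["observed"], preds["predicted_test_mean"]) == pytest.approx(
            report.test_r2
        )
        assert rmse(preds["observed"], preds["predicted_test_mean"]) == pytest.approx(
            report.test_rmse
        )

    def test_train_test_splits_disjoint(self, full_plan):
        for _, _, train_idx, test_idx in full_plan.iter_splits():
            assert np.intersect1d(train_idx, test_idx).size == 0
            assert len(train_idx) + len(test_idx) == full_plan.n_records
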