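"""Three-layer feedforward network with backpropagation training.

The architecture is the classic regression perceptron: a single hidden layer
of ``hidden_n`` tanh ("tansig") units and a linear ("purelin") scalar output.
Inputs and Box-Cox-transformed targets are scaled to [−1, 1]; training is
full-batch gradient descent with momentum, plateau-halved learning rate and
early stopping on an internal validation split, restarted from several random
initializations. Evaluation (R², RMSE) is reported on original response units
under a shared cross-validation plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import Dataset, resolve_response
from .errors import DegenerateDataError, DomainError, TrainingDivergenceError
from .preprocess import (
    BoxCoxFit,
    CVPlan,
    ScalerParams,
    boxcox_mle,
    boxcox_transform,
    inv_boxcox_transform,
)

# ---------------------------------------------------------------------------
# Metrics


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise DomainError("observed and predicted must share length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("R^2 undefined for constant observed values")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def rmse(observed, predicted) -> float:
    """Root mean squared error, in the units of the observations."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 1:
        raise DomainError("observed and predicted must share length >= 1")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


# ---------------------------------------------------------------------------
# Model and trainer configuration


@dataclass
class TrainConfig:
    """Backpropagation settings.

    Full-batch gradient descent with momentum; the learning rate is halved
    when the monitored RMSE fails to improve for ``lr_patience`` epochs and
    training stops after ``patience`` stagnant epochs. ``val_fraction`` of the
    training records form an internal validation split used for epoch
    selection (0 selects on training loss — needed for tiny representability
    checks). ``min_records_per_neuron`` guards gross overparameterization.
    """

    max_epochs: int = 800
    learning_rate: float = 0.2
    momentum: float = 0.9
    patience: int = 100
    lr_patience: int = 40
    min_lr: float = 1e-5
    val_fraction: float = 0.15
    init_scale: float = 0.5
    n_restarts: int = 3
    min_records_per_neuron: int = 6
    seed: int = 0

    def __post_init__(self):
        if min(self.max_epochs, self.learning_rate, self.patience, self.n_restarts) <= 0:
            raise DomainError("max_epochs, learning_rate, patience, n_restarts must be positive")
        if not 0 <= self.val_fraction < 0.5:
            raise DomainError("val_fraction must lie in [0, 0.5)")


@dataclass
class MLPModel:
    """A fitted tanh-hidden / linear-output network with its preprocessing.

    Prediction is deterministic: inputs are scaled by ``input_scaler``, passed
    through tanh(W1·x + b1) and the linear output layer, then un-scaled by
    ``target_scaler`` and inverse Box-Cox transformed (if ``boxcox`` is set) to
    original response units.
    """

    W1: np.ndarray  # hidden_n × n_inputs
    b1: np.ndarray  # hidden_n
    w2: np.ndarray  # hidden_n
    b2: float
    input_scaler: ScalerParams
    target_scaler: ScalerParams
    boxcox: BoxCoxFit | None = None
    seed: int = 0

    @property
    def hidden_n(self) -> int:
        return int(self.W1.shape[0])

    @property
    def n_inputs(self) -> int:
        return int(self.W1.shape[1])

    def forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        """purelin(W2·tansig(W1·x̃ + b1) + b2) on already-scaled inputs."""
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        if Xs.shape[1] != self.n_inputs:
            raise DomainError(
                f"expected {self.n_inputs} input columns, got {Xs.shape[1]}"
            )
        return np.tanh(Xs @ self.W1.T + self.b1) @ self.w2 + self.b2

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions in original response units."""
        ys = self.forward_scaled(self.input_scaler.transform(np.atleast_2d(X)))
        yt = self.target_scaler.inverse_transform(ys)
        if self.boxcox is not None:
            yt = inv_boxcox_transform(yt, self.boxcox.lam)
        return yt


def mlp_forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`MLPModel.predict`."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# Training


def _init_params(rng: np.random.Generator, hidden_n: int, n_inputs: int, scale: float):
    # uniform on [−scale, scale], scaled by 1/sqrt(fan-in)
    W1 = rng.uniform(-scale, scale, size=(hidden_n, n_inputs)) / np.sqrt(n_inputs)
    b1 = rng.uniform(-scale, scale, size=hidden_n) / np.sqrt(n_inputs)
    w2 = rng.uniform(-scale, scale, size=hidden_n) / np.sqrt(hidden_n)
    b2 = float(rng.uniform(-scale, scale) / np.sqrt(hidden_n))
    return W1, b1, w2, b2


def _rmse_scaled(params, Xs, ys) -> float:
    W1, b1, w2, b2 = params
    pred = np.tanh(Xs @ W1.T + b1) @ w2 + b2
    return float(np.sqrt(np.mean((pred - ys) ** 2)))


def _train_once(Xs, ys, hidden_n: int, cfg: TrainConfig, rng: np.random.Generator):
    """One gradient-descent run in scaled space; returns (params, monitor_rmse)."""
    n = Xs.shape[0]
    n_val = int(round(cfg.val_fraction * n))
    if n_val >= 1 and n - n_val >= 2:
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx, tr_idx = np.array([], dtype=int), np.arange(n)
    Xtr, ytr = Xs[tr_idx], ys[tr_idx]
    Xval, yval = Xs[val_idx], ys[val_idx]
    monitor_on_val = len(val_idx) > 0

    params = _init_params(rng, hidden_n, Xs.shape[1], cfg.init_scale)
    velocity = [np.zeros_like(p) if isinstance(p, np.ndarray) else 0.0 for p in params]

    def monitor(p):
        return _rmse_scaled(p, Xval, yval) if monitor_on_val else _rmse_scaled(p, Xtr, ytr)

    init = tuple(np.copy(p) if isinstance(p, np.ndarray) else p for p in params)
    best = init
    best_metric = monitor(params)
    lr = cfg.learning_rate
    stagnant = lr_stagnant = 0
    ntr = len(tr_idx)

    for epoch in range(cfg.max_epochs):
        W1, b1, w2, b2 = params
        H = np.tanh(Xtr @ W1.T + b1)
        pred = H @ w2 + b2
        err = pred - ytr
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise TrainingDivergenceError(epoch)
        dpred = 2.0 * err / ntr
        dw2 = H.T @ dpred
        db2 = float(dpred.sum())
        dH = np.outer(dpred, w2) * (1.0 - H**2)
        dW1 = dH.T @ Xtr
        db1 = dH.sum(axis=0)

        grads = (dW1, db1, dw2, db2)
        new_params, new_velocity = [], []
        for p, v, g in zip(params, velocity, grads):
            v = cfg.momentum * v - lr * g
            new_velocity.append(v)
            new_params.append(p + v)
        params = tuple(new_params)
        velocity = new_velocity

        metric = monitor(params)
        if metric < best_metric - 1e-12:
            best_metric = metric
            best = tuple(np.copy(p) if isinstance(p, np.ndarray) else p for p in params)
            stagnant = lr_stagnant = 0
        else:
            stagnant += 1
            lr_stagnant += 1
            if stagnant >= cfg.patience:
                break
            if lr_stagnant >= cfg.lr_patience:
                lr = max(lr / 2.0, cfg.min_lr)
                lr_stagnant = 0
    # Guarantee: never return a model fitting the training data worse than
    # its own random initialization (epoch selection runs on the monitor set).
    if _rmse_scaled(best, Xtr, ytr) > _rmse_scaled(init, Xtr, ytr):
        best, best_metric = init, monitor(init)
    return best, best_metric


def train_mlp(
    X,
    y,
    hidden_n: int,
    cfg: TrainConfig | None = None,
    *,
    boxcox: BoxCoxFit | None = None,
) -> MLPModel:
    """Fit the network on raw inputs/targets.

    Applies the supplied Box-Cox transform to the target (if any), fits the
    [−1, 1] scalers on these training records only, and keeps the best of
    ``n_restarts`` seeded gradient-descent runs by monitored RMSE. The returned
    model never fits the training data worse than its own random
    initialization, and the same seed reproduces the same model.
    """
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if hidden_n < 1:
        raise DomainError("hidden_n must be >= 1")
    n = X.shape[0]
    if cfg.min_records_per_neuron and n < hidden_n * cfg.min_records_per_neuron:
        raise DomainError(
            f"{n} records are too few for hidden_n={hidden_n} "
            f"(need >= {hidden_n * cfg.min_records_per_neuron})"
        )

    yt = boxcox_transform(y, boxcox.lam) if boxcox is not None else y
    input_scaler = ScalerParams.fit(X, columns=tuple(range(X.shape[1])))
    target_scaler = ScalerParams.fit(yt[:, None], allow_constant=True)
    Xs = input_scaler.transform(X)
    ys = target_scaler.transform(yt[:, None])[:, 0]

    rng = np.random.default_rng(cfg.seed)
    restart_rngs = rng.spawn(cfg.n_restarts)
    best_params, best_metric = None, np.inf
    for r_rng in restart_rngs:
        params, metric = _train_once(Xs, ys, hidden_n, cfg, r_rng)
        if metric < best_metric:
            best_params, best_metric = params, metric

    W1, b1, w2, b2 = best_params
    model = MLPModel(
        W1=W1,
        b1=b1,
        w2=w2,
        b2=b2,
        input_scaler=input_scaler,
        target_scaler=target_scaler,
        boxcox=boxcox,
        seed=cfg.seed,
    )
    return model


# ---------------------------------------------------------------------------
# Cross-validated evaluation


@dataclass
class FitReport:
    """Pooled and per-fold R²/RMSE for one response and one model family."""

    response: str
    model: str
    hidden_n: int | None
    train_r2: float
    train_rmse: float
    test_r2: float
    test_rmse: float
    per_fold: pd.DataFrame = field(repr=False, default=None)
    predictions: pd.DataFrame = field(repr=False, default=None)
    plan_hash: str = ""

    def to_row(self) -> dict:
        return {
            "response": self.response,
            "model": self.model,
            "hidden_n": self.hidden_n,
            "train_r2": self.train_r2,
            "train_rmse": self.train_rmse,
            "test_r2": self.test_r2,
            "test_rmse": self.test_rmse,
        }


def derive_seed(base: int, *parts: int) -> int:
    """Deterministic child seed below 2^31 from a base seed and index parts."""
    h = np.uint64(base % (2**31))
    for p in parts:
        h = (h * np.uint64(1000003) + np.uint64(p + 1)) % np.uint64(2**31 - 1)
    return int(h)


def crossval_evaluate(
    dataset: Dataset,
    response,
    hidden_n: int,
    plan: CVPlan,
    cfg: TrainConfig | None = None,
    *,
    boxcox: str | BoxCoxFit | None = "global",
    model_label: str = "MLP-GA",
) -> FitReport:
    """Evaluate the network under a shared CV plan.

    For every shuffle replicate and fold, scalers and the model are fitted on
    the training folds only and the held-out fold is predicted; pooled R²/RMSE
    (train and test pools concatenated across all replicate×fold fits) and a
    per-fold breakdown are reported in original response units.

    ``boxcox="global"`` fits the target's λ once on the whole dataset (the
    leaky whole-dataset convention; see docs/methods.md), ``"per_fold"``
    refits λ within each training fold, ``None`` disables the transform, and a
    :class:`BoxCoxFit` uses that fixed λ.
    """
    cfg = cfg or TrainConfig()
    resp = _response_key(dataset, response)
    X = _input_matrix(dataset)
    y = _response_vector(dataset, response)
    if plan.n_records != len(y):
        raise DomainError("plan size does not match dataset size")

    global_bc: BoxCoxFit | None
    if boxcox == "global":
        global_bc = boxcox_mle(y, response=resp)
    elif boxcox == "per_fold" or boxcox is None:
        global_bc = None
    elif isinstance(boxcox, BoxCoxFit):
        global_bc = boxcox
    else:
        raise DomainError(f"unknown boxcox mode {boxcox!r}")

    train_obs, train_pred, test_obs, test_pred = [], [], [], []
    rows = []
    pred_sum = np.zeros(len(y))
    pred_cnt = np.zeros(len(y))
    for r, f, train_idx, test_idx in plan.iter_splits():
        bc = (
            boxcox_mle(y[train_idx], response=resp)
            if boxcox == "per_fold"
            else global_bc
        )
        fold_cfg = replace(cfg, seed=derive_seed(cfg.seed, r, f))
        try:
            model = train_mlp(X[train_idx], y[train_idx], hidden_n, fold_cfg, boxcox=bc)
        except TrainingDivergenceError as exc:  # pragma: no cover - defensive
            raise TrainingDivergenceError(
                exc.epoch, f"replicate {r}, fold {f}: {exc}"
            ) from exc
        p_tr = model.predict(X[train_idx])
        p_te = model.predict(X[test_idx])
        train_obs.append(y[train_idx])
        train_pred.append(p_tr)
        test_obs.append(y[test_idx])
        test_pred.append(p_te)
        pred_sum[test_idx] += p_te
        pred_cnt[test_idx] += 1
        rows.append(
            {
                "replicate": r,
                "fold": f,
                "train_r2": r_squared(y[train_idx], p_tr),
                "train_rmse": rmse(y[train_idx], p_tr),
                "test_r2": r_squared(y[test_idx], p_te),
                "test_rmse": rmse(y[test_idx], p_te),
            }
        )

    train_obs = np.concatenate(train_obs)
    train_pred = np.concatenate(train_pred)
    test_obs = np.concatenate(test_obs)
    test_pred = np.concatenate(test_pred)
    predictions = pd.DataFrame(
        {
            "record": np.arange(len(y)),
            "observed": y,
            "predicted_test_mean": np.where(pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan),
            "n_test_appearances": pred_cnt.astype(int),
        }
    )
    return FitReport(
        response=resp,
        model=model_label,
        hidden_n=hidden_n,
        train_r2=r_squared(train_obs, train_pred),
        train_rmse=rmse(train_obs, train_pred),
        test_r2=r_squared(test_obs, test_pred),
        test_rmse=rmse(test_obs, test_pred),
        per_fold=pd.DataFrame(rows),
        predictions=predictions,
        plan_hash=plan.plan_hash,
    )


# --- small adapters so benchmarks (plain frames) and Dataset both work -----


def _input_matrix(dataset) -> np.ndarray:
    if isinstance(dataset, Dataset):
        return dataset.X
    from .dataset import COMPONENTS

    return np.asarray(dataset.loc[:, list(COMPONENTS)], dtype=float)


def _response_vector(dataset, response) -> np.ndarray:
    if isinstance(dataset, Dataset) and response != "response":
        return dataset.y(response)
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    col = response if response in frame.columns else resolve_response(response).column
    return frame[col].to_numpy(dtype=float)


def _response_key(dataset, response) -> str:
    if response == "response" or (
        not isinstance(dataset, Dataset) and response in getattr(dataset, "columns", [])
    ):
        return str(response)
    return resolve_response(response).name
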