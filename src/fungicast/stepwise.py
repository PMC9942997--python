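"""Bidirectional stepwise linear regression baseline.

Classic p-value-driven selection over the linear main effects of the four
composition inputs: repeatedly enter the excluded variable with the smallest
partial p-value if it clears ``p_enter``, then drop any included variable
whose p-value exceeds ``p_remove``. Because the compositions sum to 100, the
fourth component together with the intercept is exactly collinear with the
other three; such candidates are skipped rather than fitted. Evaluated under
the same cross-validation plan as the network for a like-for-like comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import COMPONENTS
from .errors import DegenerateDataError, DomainError
from .mlp import (
    FitReport,
    _input_matrix,
    _response_key,
    _response_vector,
    r_squared,
    rmse,
)
from .preprocess import (
    BoxCoxFit,
    CVPlan,
    boxcox_mle,
    boxcox_transform,
    inv_boxcox_transform,
)

_COND_LIMIT = 1e10


@dataclass
class StepwiseModel:
    """A fitted stepwise-selected linear model."""

    selected: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    p_enter: float
    p_remove: float
    trace: list[tuple] = field(default_factory=list)  # (step, action, var, p)
    boxcox: BoxCoxFit | None = None

    def predict(self, X: pd.DataFrame | np.ndarray, columns=COMPONENTS) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            frame = X
        else:
            frame = pd.DataFrame(np.atleast_2d(X), columns=list(columns))
        pred = np.full(len(frame), self.coefficients["intercept"], dtype=float)
        for name in self.selected:
            pred += self.coefficients[name] * frame[name].to_numpy(dtype=float)
        if self.boxcox is not None:
            pred = inv_boxcox_transform(pred, self.boxcox.lam)
        return pred


def _design(frame: pd.DataFrame, cols: list[str]) -> np.ndarray:
    return sm.add_constant(frame.loc[:, cols].to_numpy(dtype=float), has_constant="add")


def _is_singular(design: np.ndarray) -> bool:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return True
    return np.linalg.cond(design) > _COND_LIMIT


def stepwise_fit(
    X: pd.DataFrame,
    y,
    *,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 50,
    boxcox: BoxCoxFit | None = None,
) -> StepwiseModel:
    """Bidirectional stepwise OLS on the columns of ``X``.

    Entry uses the partial t-test p-value of each candidate added to the
    current model; removal drops the worst included variable with p above
    ``p_remove``. Candidates that would make the design singular (e.g. the
    fourth compositional component plus intercept) are skipped. A variable
    dropped in a step may not re-enter in that same step; the loop is capped
    at ``max_steps``.
    """
    if p_enter > p_remove:
        raise DomainError("p_enter must be <= p_remove")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.atleast_2d(np.asarray(X, float)), columns=list(COMPONENTS))
    y = np.asarray(y, dtype=float)
    if len(X) < 10:
        raise DomainError("need at least 10 training records")
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant response; nothing to fit")
    yt = boxcox_transform(y, boxcox.lam) if boxcox is not None else y

    candidates = list(X.columns)
    selected: list[str] = []
    trace: list[tuple] = []

    for step in range(max_steps):
        changed = False
        just_dropped: set[str] = set()

        # backward: drop worst included variable with p > p_remove
        while selected:
            res = sm.OLS(yt, _design(X, selected)).fit()
            pvals = pd.Series(res.pvalues[1:], index=selected)
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                selected.remove(worst)
                just_dropped.add(worst)
                trace.append((step, "drop", worst, float(pvals[worst])))
                changed = True
            else:
                break

        # forward: add best excluded variable with p <= p_enter
        best_var, best_p = None, None
        for var in candidates:
            if var in selected or var in just_dropped:
                continue
            design = _design(X, selected + [var])
            if _is_singular(design):
                trace.append((step, "skip-singular", var, np.nan))
                continue
            res = sm.OLS(yt, design).fit()
            p = float(res.pvalues[-1])
            if p <= p_enter and (best_p is None or p < best_p):
                best_var, best_p = var, p
        if best_var is not None:
            selected.append(best_var)
            trace.append((step, "add", best_var, best_p))
            changed = True

        if not changed:
            break

    final = sm.OLS(yt, _design(X, selected)).fit()
    coefs = {"intercept": float(final.params[0])}
    for i, name in enumerate(selected):
        coefs[name] = float(final.params[i + 1])
    return StepwiseModel(
        selected=list(selected),
        coefficients=coefs,
        p_enter=p_enter,
        p_remove=p_remove,
        trace=trace,
        boxcox=boxcox,
    )


def sr_crossval(
    dataset,
    response,
    plan: CVPlan,
    *,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    boxcox: str | None = "global",
    model_label: str = "SR",
) -> tuple[FitReport, pd.DataFrame]:
    """Stepwise regression refit per training fold under a shared CV plan.

    Returns the pooled/per-fold :class:`FitReport` (metrics on original units)
    and a selection-stability table counting how often each input entered the
    per-fold models.
    """
    X = _input_matrix(dataset)
    y = _response_vector(dataset, response)
    resp = _response_key(dataset, response)
    if plan.n_records != len(y):
        raise DomainError("plan size does not match dataset size")
    frame = pd.DataFrame(X, columns=list(COMPONENTS))

    global_bc = boxcox_mle(y, response=resp) if boxcox == "global" else None

    train_obs, train_pred, test_obs, test_pred = [], [], [], []
    rows, counts = [], {c: 0 for c in COMPONENTS}
    pred_sum = np.zeros(len(y))
    pred_cnt = np.zeros(len(y))
    n_fits = 0
    for r, f, train_idx, test_idx in plan.iter_splits():
        bc = boxcox_mle(y[train_idx], response=resp) if boxcox == "per_fold" else global_bc
        model = stepwise_fit(
            frame.iloc[train_idx], y[train_idx],
            p_enter=p_enter, p_remove=p_remove, boxcox=bc,
        )
        n_fits += 1
        for var in model.selected:
            counts[var] += 1
        p_tr = model.predict(frame.iloc[train_idx])
        p_te = model.predict(frame.iloc[test_idx])
        train_obs.append(y[train_idx]); train_pred.append(p_tr)
        test_obs.append(y[test_idx]); test_pred.append(p_te)
        pred_sum[test_idx] += p_te
        pred_cnt[test_idx] += 1
        rows.append(
            {
                "replicate": r, "fold": f,
                "train_r2": r_squared(y[train_idx], p_tr),
                "train_rmse": rmse(y[train_idx], p_tr),
                "test_r2": r_squared(y[test_idx], p_te),
                "test_rmse": rmse(y[test_idx], p_te),
            }
        )

    train_obs = np.concatenate(train_obs); train_pred = np.concatenate(train_pred)
    test_obs = np.concatenate(test_obs); test_pred = np.concatenate(test_pred)
    predictions = pd.DataFrame(
        {
            "record": np.arange(len(y)),
            "observed": y,
            "predicted_test_mean": np.where(pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan),
            "n_test_appearances": pred_cnt.astype(int),
        }
    )
    report = FitReport(
        response=resp,
        model=model_label,
        hidden_n=None,
        train_r2=r_squared(train_obs, train_pred),
        train_rmse=rmse(train_obs, train_pred),
        test_r2=r_squared(test_obs, test_pred),
        test_rmse=rmse(test_obs, test_pred),
        per_fold=pd.DataFrame(rows),
        predictions=predictions,
        plan_hash=plan.plan_hash,
    )
    stability = pd.DataFrame(
        {
            "input": list(counts),
            "times_selected": list(counts.values()),
            "n_fits": n_fits,
        }
    )
    return report, stability
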