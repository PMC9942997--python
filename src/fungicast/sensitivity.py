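"""Leave-variable-out importance analysis (VSE/VSR) of a fitted network.

For each input variable v, the variable sensitivity error VSE(v) is the
model's RMSE on all records when v is absent — either by retraining with the
remaining inputs (default) or by ablating the input to its mean with frozen
weights. The variable sensitivity ratio VSR(v) = VSE(v)/RMSE_all divides by
the all-inputs model's RMSE, and the four VSRs are min-max rescaled to [0, 1]
for reporting, so the most influential input reads 1.000 and the least 0.000.

One caveat is structural: the four composition percentages sum to 100, so any
three inputs determine the fourth; a retrained three-input model therefore
retains all the information, and VSRs measure how hard the network finds it
to exploit the remaining encoding rather than pure information loss. No
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import COMPONENTS
from .errors import DegenerateDataError, DomainError
from .mlp import (
    TrainConfig,
    _input_matrix,
    _response_key,
    _response_vector,
    derive_seed,
    rmse,
    train_mlp,
)
from .preprocess import boxcox_mle

#: Relative VSR spread below which min-max rescaling is reported as unstable.
UNSTABLE_REL_SPREAD = 0.05


def rescale_unit_interval(values):
    """Min-max rescale to [0, 1]; an all-equal vector maps to 0.5s and is
    flagged unstable. Returns ``(rescaled, unstable)``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DomainError("need at least 2 values to rescale")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.full_like(values, 0.5), True
    return (values - lo) / (hi - lo), False


@dataclass
class SensitivityReport:
    """Per-input VSE/VSR table for one response."""

    response: str
    hidden_n: int
    mode: str
    baseline_rmse: float
    inputs: tuple[str, ...]
    vse: np.ndarray
    vsr: np.ndarray
    rescaled_vsr: np.ndarray
    unstable: bool
    dataset_descriptor: str = ""

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "response": self.response,
                "input": list(self.inputs),
                "vse": self.vse,
                "vsr": self.vsr,
                "rescaled_vsr": self.rescaled_vsr,
                "mode": self.mode,
                "hidden_n": self.hidden_n,
                "unstable": self.unstable,
            }
        )

    def ranking(self) -> list[str]:
        """Inputs ordered from most to least influential (by VSR)."""
        order = np.argsort(-self.vsr, kind="stable")
        return [self.inputs[i] for i in order]


def variable_sensitivity(
    dataset,
    response,
    hidden_n: int,
    train_cfg: TrainConfig | None = None,
    *,
    mode: str = "retrain",
    boxcox: str | None = "global",
    inputs: tuple[str, ...] = COMPONENTS,
) -> SensitivityReport:
    """Compute VSE/VSR/rescaled-VSR on all records (training and testing data).

    The all-inputs baseline model and, in ``retrain`` mode, each three-input
    model are fitted on the full dataset with the architecture chosen by the
    search (``hidden_n``) and deterministic derived seeds. ``ablate`` mode
    keeps the baseline weights and replaces the left-out input by its mean.
    """
    train_cfg = train_cfg or TrainConfig()
    if len(inputs) < 2:
        raise DomainError("need at least 2 input variables")
    X = _input_matrix(dataset)
    y = _response_vector(dataset, response)
    resp = _response_key(dataset, response)
    if len(y) < 20:
        raise DomainError("need at least 20 records for a sensitivity analysis")
    if mode not in ("retrain", "ablate"):
        raise DomainError(f"unknown sensitivity mode {mode!r}")

    bc = boxcox_mle(y, response=resp) if boxcox == "global" else None
    base_cfg = replace(train_cfg, seed=derive_seed(train_cfg.seed, hidden_n, 0))
    baseline = train_mlp(X, y, hidden_n, base_cfg, boxcox=bc)
    baseline_rmse = rmse(y, baseline.predict(X))
    if baseline_rmse == 0:
        raise DegenerateDataError("baseline RMSE is zero; VSR undefined")

    vse = np.empty(len(inputs))
    for j, name in enumerate(inputs):
        if mode == "retrain":
            keep = [i for i in range(len(inputs)) if i != j]
            cfg_j = replace(train_cfg, seed=derive_seed(train_cfg.seed, hidden_n, j + 1))
            model_j = train_mlp(X[:, keep], y, hidden_n, cfg_j, boxcox=bc)
            pred = model_j.predict(X[:, keep])
        else:
            X_abl = X.copy()
            X_abl[:, j] = X[:, j].mean()
            pred = baseline.predict(X_abl)
        vse[j] = rmse(y, pred)

    vsr = vse / baseline_rmse
    rescaled, degenerate = rescale_unit_interval(vsr)
    spread_unstable = (
        float(vsr.max() - vsr.min()) <= UNSTABLE_REL_SPREAD * float(np.abs(vsr).max())
    )
    return SensitivityReport(
        response=resp,
        hidden_n=hidden_n,
        mode=mode,
        baseline_rmse=baseline_rmse,
        inputs=tuple(inputs),
        vse=vse,
        vsr=vsr,
        rescaled_vsr=rescaled,
        unstable=degenerate or spread_unstable,
        dataset_descriptor=f"n={len(y)}",
    )
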