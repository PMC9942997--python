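"""Normalization, outlier screening and the cross-validation plan.

Targets are Box-Cox normalized (profile-likelihood λ on a fixed grid), inputs
and transformed targets are affinely mapped to [−1, 1] — required by the
saturating tanh hidden layer — and model comparison runs under a 5-fold plan
repeated with 10 independent shuffles. A principal-component screen flags
(never drops) records with outlying Hotelling-style score distances.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .errors import DegenerateDataError, DomainError

# ---------------------------------------------------------------------------
# Box-Cox


@dataclass(frozen=True)
class BoxCoxFit:
    """A fitted Box-Cox transform: λ, its profile log-likelihood and the grid."""

    lam: float
    log_likelihood: float
    grid: tuple[float, float, float] = (-5.0, 5.0, 0.01)
    response: str | None = None


def boxcox_transform(x, lam: float):
    """(x^λ − 1)/λ for λ ≠ 0, ln x for λ = 0; requires x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise DomainError("Box-Cox requires strictly positive finite values")
    if lam == 0.0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def inv_boxcox_transform(y, lam: float, *, eps: float = 1e-12):
    """Inverse Box-Cox. The argument λ·y + 1 is floored at ``eps`` so that
    predictions from an unbounded linear output layer always map back into the
    (positive) response domain."""
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        return np.exp(y)
    base = np.maximum(lam * y + 1.0, eps)
    return np.power(base, 1.0 / lam)


def boxcox_mle(
    x,
    *,
    grid: tuple[float, float, float] = (-5.0, 5.0, 0.01),
    response: str | None = None,
) -> BoxCoxFit:
    """Maximize the Box-Cox profile log-likelihood over a λ grid.

    Exact ties are broken toward the λ closest to 1 (the no-transform end).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DomainError("need at least 3 observations")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise DomainError("Box-Cox requires strictly positive finite values")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant vector: Box-Cox lambda is undefined")
    lo, hi, step = grid
    lams = np.linspace(lo, hi, int(round((hi - lo) / step)) + 1)
    llf = np.array([stats.boxcox_llf(lam, x) for lam in lams])
    best = llf.max()
    ties = lams[llf == best]
    lam = float(ties[np.argmin(np.abs(ties - 1.0))])
    return BoxCoxFit(lam=round(lam, 10), log_likelihood=float(best), grid=grid, response=response)


# ---------------------------------------------------------------------------
# PCA outlier screen


def pca_outlier_screen(X, *, var_threshold: float = 0.95, z: float = 3.0):
    """Flag records with outlying PCA score distances.

    Variables are standardized internally; on the leading components covering
    ``var_threshold`` of the variance, each record's Hotelling-style score
    distance d_i = √(Σ_j t_ij²/λ_j) is computed and records with
    d > mean(d) + z·SD(d) are flagged. Flags are advisory — nothing is dropped.

    Returns ``(flags, distances)`` as numpy arrays.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise DomainError("need a 2-D array with at least 3 records")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns carry no outlier signal
    Z = (X - mu) / sd

    pca = PCA()
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, var_threshold) + 1)
    ev = pca.explained_variance_[:m]
    ev = np.where(ev > 0, ev, np.finfo(float).tiny)
    d = np.sqrt(np.sum(scores[:, :m] ** 2 / ev, axis=1))
    flags = d > d.mean() + z * d.std(ddof=1)
    return flags, d


# ---------------------------------------------------------------------------
# Scaling


@dataclass
class ScalerParams:
    """Affine per-column map onto [−1, 1], fitted on the training partition only.

    Columns are mapped by (x − center)/half with center = (max+min)/2 and
    half = (max−min)/2. Values outside the training range map outside [−1, 1]
    and are passed through unclipped. A zero-range column raises, unless
    ``allow_constant`` (used for degenerate targets) substitutes half = 1.
    """

    center: np.ndarray = field(default=None)
    half: np.ndarray = field(default=None)
    columns: tuple = ()

    @classmethod
    def fit(cls, X, *, columns=None, allow_constant: bool = False) -> "ScalerParams":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            raise DomainError("cannot fit a scaler on an empty partition")
        mn, mx = X.min(axis=0), X.max(axis=0)
        half = (mx - mn) / 2.0
        if np.any(half == 0):
            if not allow_constant:
                names = (
                    [columns[i] for i in np.where(half == 0)[0]]
                    if columns
                    else np.where(half == 0)[0].tolist()
                )
                raise DegenerateDataError(f"constant column(s), cannot scale: {names}")
            half = np.where(half == 0, 1.0, half)
        return cls(center=(mx + mn) / 2.0, half=half, columns=tuple(columns or ()))

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.center) / self.half

    def inverse_transform(self, Xs):
        Xs = np.asarray(Xs, dtype=float)
        return Xs * self.half + self.center


# ---------------------------------------------------------------------------
# Cross-validation plan


@dataclass(frozen=True)
class CVPlan:
    """k-fold × replicate held-out index sets; a pure function of (n, seed).

    ``folds[r][f]`` is the array of record indices held out in fold ``f`` of
    shuffle replicate ``r``. Within each replicate the folds partition all
    records and sizes differ by at most one.
    """

    n_records: int
    k: int
    n_replicates: int
    seed: int
    folds: tuple  # tuple[replicate] of tuple[fold] of np.ndarray

    @property
    def plan_hash(self) -> str:
        h = hashlib.sha256()
        h.update(f"{self.n_records}/{self.k}/{self.n_replicates}".encode())
        for rep in self.folds:
            for fold in rep:
                h.update(np.asarray(fold, dtype=np.int64).tobytes())
        return h.hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_records": self.n_records,
                "k": self.k,
                "n_replicates": self.n_replicates,
                "seed": self.seed,
                "folds": [
                    [fold.tolist() for fold in rep] for rep in self.folds
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CVPlan":
        d = json.loads(text)
        folds = tuple(
            tuple(np.asarray(f, dtype=np.int64) for f in rep) for rep in d["folds"]
        )
        return cls(d["n_records"], d["k"], d["n_replicates"], d["seed"], folds)

    def subset_replicates(self, n: int) -> "CVPlan":
        """Plan restricted to the first ``n`` shuffle replicates (for cheap search)."""
        if not 1 <= n <= self.n_replicates:
            raise DomainError(f"need 1 <= n <= {self.n_replicates}")
        return CVPlan(self.n_records, self.k, n, self.seed, self.folds[:n])

    def iter_splits(self):
        """Yield (replicate, fold, train_idx, test_idx)."""
        all_idx = np.arange(self.n_records)
        for r, rep in enumerate(self.folds):
            for f, test in enumerate(rep):
                train = np.setdiff1d(all_idx, test, assume_unique=False)
                yield r, f, train, test


def make_cv_plan(
    n_records: int, seed: int, *, k: int = 5, n_replicates: int = 10
) -> CVPlan:
    """Build the k-fold × replicate plan: independent shuffles split into
    contiguous folds (sizes differ by ≤ 1)."""
    if n_records < k:
        raise DomainError(f"need at least k={k} records, got {n_records}")
    if n_records < 10:
        raise DomainError("need at least 10 records")
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_replicates):
        perm = rng.permutation(n_records)
        folds.append(tuple(np.sort(chunk) for chunk in np.array_split(perm, k)))
    return CVPlan(n_records, k, n_replicates, seed, tuple(folds))
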