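"""Learning the fingerprint -> optimum relation.

The driver accumulates couples (fingerprint, optimum) from the resamples
it has already solved and models the relation so the optimum of a new
resample can be predicted from its fingerprint alone.  The interpolator
is a least-squares support vector machine for regression (LS-SVM): an RBF
kernel regression with ridge penalty and unpenalized bias, whose training
reduces to one symmetric linear system

    [[K + lambda*I, 1], [1', 0]] [alpha; b] = [y; 0],

and which admits exact closed-form leave-one-out residuals
``r_i = alpha_i / (M^-1)_ii`` (M the bordered system matrix).  The LOO
residuals do double duty: they select the hyperparameters (penalty and
kernel width, small logarithmic grid) and their RMS per output dimension
is the prediction error eps_k that scales the warm-start simplex.

One single-output model is fitted per parameter dimension.  Inputs
(fingerprint components) are standardized before training.  Couples whose
optimum sits on a constraint boundary in dimension k are excluded from
dimension k's model — an active constraint makes the fingerprint ->
optimum relation non-smooth — and any prediction violating a constraint
is clipped to the constraint value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .fingerprints import Fingerprint, fingerprint_distance

__all__ = [
    "TrainingPool",
    "FittedInterpolator",
    "NotFittedError",
    "fit",
    "nearest_neighbor_predict",
    "PENALTY_GRID",
    "WIDTH_FACTORS",
]

#: ridge-penalty grid (logarithmic); extends low so that noiseless,
#: exactly-learnable relations can be interpolated to near machine accuracy
PENALTY_GRID = tuple(10.0**k for k in range(-8, 4))
#: kernel widths as multiples of the median pairwise distance
WIDTH_FACTORS = (0.3, 1.0, 3.0)


class NotFittedError(RuntimeError):
    """Too few usable training couples to fit the interpolator."""


@dataclass
class TrainingPool:
    """Accumulated (fingerprint, optimum) couples from solved resamples."""

    fingerprints: list[Fingerprint] = field(default_factory=list)
    optima: list[np.ndarray] = field(default_factory=list)
    indices: list[int] = field(default_factory=list)
    boundary_flags: list[np.ndarray] = field(default_factory=list)  # bool per dim

    def add(
        self,
        fingerprint: Fingerprint,
        optimum: np.ndarray,
        index: int,
        on_boundary: np.ndarray | None = None,
    ) -> None:
        if self.fingerprints and (
            fingerprint.order != self.fingerprints[0].order
            or len(fingerprint) != len(self.fingerprints[0])
        ):
            raise ValueError("all pool fingerprints must share order and length")
        if index in self.indices:
            raise ValueError(f"duplicate resample index {index}")
        optimum = np.asarray(optimum, dtype=float)
        if on_boundary is None:
            on_boundary = np.zeros(optimum.size, dtype=bool)
        self.fingerprints.append(fingerprint)
        self.optima.append(optimum)
        self.indices.append(index)
        self.boundary_flags.append(np.asarray(on_boundary, dtype=bool))

    def __len__(self) -> int:
        return len(self.fingerprints)


@dataclass
class _DimensionModel:
    """Single-output LS-SVM for one parameter dimension."""

    X: np.ndarray  # standardized training inputs (n, d)
    alpha: np.ndarray
    bias: float
    width: float
    penalty: float
    loo_rmse: float

    def predict(self, x_std: np.ndarray) -> float:
        d2 = np.sum((self.X - x_std) ** 2, axis=1)
        k = np.exp(-d2 / (2.0 * self.width**2))
        return float(k @ self.alpha + self.bias)


def _lssvm_solve(K: np.ndarray, y: np.ndarray, lam: float):
    """Solve the bordered LS-SVM system; return (alpha, bias, loo_residuals)."""
    n = K.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = K + lam * np.eye(n)
    M[:n, n] = 1.0
    M[n, :n] = 1.0
    Minv = np.linalg.inv(M)
    sol = Minv @ np.concatenate([y, [0.0]])
    alpha, bias = sol[:n], float(sol[n])
    # Closed-form leave-one-out residuals: r_i = alpha_i / (M^-1)_ii
    loo = alpha / np.diag(Minv)[:n]
    return alpha, bias, loo


def _fit_dimension(X_std: np.ndarray, y: np.ndarray) -> _DimensionModel:
    n = X_std.shape[0]
    d = pdist(X_std)
    med = float(np.median(d)) if d.size else 1.0
    if med == 0.0:
        med = 1.0
    d2 = np.sum((X_std[:, None, :] - X_std[None, :, :]) ** 2, axis=-1)
    best = None
    for wf in WIDTH_FACTORS:
        width = wf * med
        K = np.exp(-d2 / (2.0 * width**2))
        for lam in PENALTY_GRID:
            try:
                alpha, bias, loo = _lssvm_solve(K, y, lam)
            except np.linalg.LinAlgError:
                continue
            mse = float(np.mean(loo**2))
            if not np.isfinite(mse):
                continue
            if best is None or mse < best[0]:
                best = (mse, width, lam, alpha, bias, loo)
    if best is None:
        raise NotFittedError("LS-SVM system singular for every hyperparameter")
    mse, width, lam, alpha, bias, loo = best
    return _DimensionModel(
        X=X_std,
        alpha=alpha,
        bias=bias,
        width=width,
        penalty=lam,
        loo_rmse=float(np.sqrt(mse)),
    )


@dataclass
class FittedInterpolator:
    """Per-dimension LS-SVM models plus input standardization constants."""

    models: list[_DimensionModel]
    mean: np.ndarray
    scale: np.ndarray
    training_size: int
    lower: np.ndarray
    upper: np.ndarray

    @property
    def loo_error(self) -> np.ndarray:
        """Prediction error eps_k per output dimension (RMS LOO residual)."""
        return np.array([m.loo_rmse for m in self.models])

    def predict(self, fingerprint: Fingerprint) -> tuple[np.ndarray, np.ndarray]:
        """Predicted optimum (constraint-clipped) and eps per dimension."""
        if not fingerprint.valid:
            raise ValueError("cannot predict from an invalid fingerprint")
        x_std = (fingerprint.values - self.mean) / self.scale
        raw = np.array([m.predict(x_std) for m in self.models])
        clipped = np.clip(raw, self.lower, self.upper)
        return clipped, self.loo_error


def fit(
    pool: TrainingPool,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> FittedInterpolator:
    """Fit one LS-SVM per parameter dimension from the pool.

    Couples with a boundary optimum in dimension k are dropped from
    dimension k's model only.  Raises :class:`NotFittedError` when any
    dimension has fewer than 2 interior couples.
    """
    if len(pool) < 2:
        raise NotFittedError("need at least 2 training couples")
    X = np.vstack([f.values for f in pool.fingerprints])
    Y = np.vstack(pool.optima)
    flags = np.vstack(pool.boundary_flags)
    out_dim = Y.shape[1]
    if lower is None:
        lower = np.full(out_dim, -np.inf)
    if upper is None:
        upper = np.full(out_dim, np.inf)

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    X_std = (X - mean) / scale

    models = []
    for k in range(out_dim):
        interior = ~flags[:, k]
        if interior.sum() < 2:
            raise NotFittedError(f"fewer than 2 interior couples for dimension {k}")
        models.append(_fit_dimension(X_std[interior], Y[interior, k]))
    return FittedInterpolator(
        models=models,
        mean=mean,
        scale=scale,
        training_size=len(pool),
        lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float),
    )


def nearest_neighbor_predict(pool: TrainingPool, fingerprint: Fingerprint) -> np.ndarray:
    """Optimum of the pool couple nearest in squared Euclidean distance.

    Ties are broken toward the lowest resample index.
    """
    if len(pool) == 0:
        raise ValueError("empty training pool")
    order = np.argsort(pool.indices, kind="stable")
    best_i, best_d = None, np.inf
    for i in order:
        d = fingerprint_distance(pool.fingerprints[i], fingerprint)
        if d < best_d:
            best_i, best_d = i, d
    return pool.optima[best_i].copy()
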