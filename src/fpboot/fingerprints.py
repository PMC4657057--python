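"""Derivative-based fingerprints of a resampled data set's objective.

A fingerprint summarizes a resampled data set by the partial derivatives
of its *log-likelihood*, evaluated at the optimum of the original
(unresampled) fit.  Near that expansion point, gradient and curvature of
the resample's objective carry direct information about where its own
optimum lies — the same information a Newton step would use — which makes
fingerprints good inputs for predicting optima.

Order g=1 keeps the gradient (``dim`` values); g=2 appends the unique
(upper-triangular) Hessian entries (``dim*(dim+1)/2`` more).  Derivatives
are approximated by central finite differences, and every objective
evaluation spent on the stencil is counted in ``eval_cost`` so the
driver's function-evaluation budget stays exact:

* g=1: 2*dim evaluations,
* g=2: 2*dim (gradient, reused for the Hessian diagonal) + 1 (center)
  + 4 per off-diagonal pair = 2*dim + 1 + 2*dim*(dim-1).

If the objective is undefined at any stencil point (e.g. a GEV resample
violating the support condition at the original optimum), computation
stops at the first non-finite value: the fingerprint is flagged invalid,
``eval_cost`` records the evaluations actually spent, and the driver
routes the resample to a full optimization instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models.base import ObjectiveModel

__all__ = ["Fingerprint", "compute_fingerprint", "fingerprint_distance", "stencil_cost"]

#: relative finite-difference step per dimension: h_k = STEP_SCALE * (1 + |theta0_k|)
STEP_SCALE = 1e-4


@dataclass
class Fingerprint:
    """Vector of unique partial derivatives up to order ``order``."""

    values: np.ndarray
    order: int
    eval_cost: int
    valid: bool = True
    index: int | None = field(default=None)  # resample index, set by the driver

    def __len__(self) -> int:
        return self.values.size


def stencil_cost(dim: int, g: int) -> int:
    """Objective evaluations a valid order-``g`` fingerprint costs."""
    if g == 1:
        return 2 * dim
    if g == 2:
        return 2 * dim + 1 + 2 * dim * (dim - 1)
    raise ValueError("fingerprint order must be 1 or 2")


def compute_fingerprint(
    model: ObjectiveModel,
    data: pd.DataFrame,
    theta0: np.ndarray,
    g: int = 1,
    step_scale: float = STEP_SCALE,
) -> Fingerprint:
    """Finite-difference fingerprint of ``data``'s log-likelihood at ``theta0``.

    Derivatives are of the log-likelihood (the maximization objective), so
    for a one-dimensional model the Newton relation
    ``theta_hat = theta0 - F1/F2`` holds with F2 < 0 near a maximum.
    """
    if g not in (1, 2):
        raise ValueError("fingerprint order must be 1 or 2")
    theta0 = np.asarray(theta0, dtype=float)
    dim = theta0.size
    negloglik = model.make_objective(data)

    n_evals = 0

    def ll(theta: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return -negloglik(theta)

    h = step_scale * (1.0 + np.abs(theta0))

    def invalid() -> Fingerprint:
        return Fingerprint(values=np.empty(0), order=g, eval_cost=n_evals, valid=False)

    # central-difference gradient; +/- values kept for the Hessian diagonal
    fplus = np.empty(dim)
    fminus = np.empty(dim)
    for k in range(dim):
        e = np.zeros(dim)
        e[k] = h[k]
        fplus[k] = ll(theta0 + e)
        if not np.isfinite(fplus[k]):
            return invalid()
        fminus[k] = ll(theta0 - e)
        if not np.isfinite(fminus[k]):
            return invalid()
    grad = (fplus - fminus) / (2.0 * h)
    if g == 1:
        return Fingerprint(values=grad, order=1, eval_cost=n_evals)

    f0 = ll(theta0)
    if not np.isfinite(f0):
        return invalid()
    hess = np.empty((dim, dim))
    np.fill_diagonal(hess, (fplus - 2.0 * f0 + fminus) / h**2)
    for j in range(dim):
        for k in range(j + 1, dim):
            ej = np.zeros(dim)
            ek = np.zeros(dim)
            ej[j], ek[k] = h[j], h[k]
            quad = []
            for sj, sk in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                v = ll(theta0 + sj * ej + sk * ek)
                if not np.isfinite(v):
                    return invalid()
                quad.append(v)
            hess[j, k] = (quad[0] - quad[1] - quad[2] + quad[3]) / (4.0 * h[j] * h[k])
    upper = hess[np.triu_indices(dim)]
    return Fingerprint(values=np.concatenate([grad, upper]), order=2, eval_cost=n_evals)


def fingerprint_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Squared Euclidean distance between two fingerprints of equal order."""
    if a.order != b.order or len(a) != len(b):
        raise ValueError("fingerprints must have the same order and length")
    if not (a.valid and b.valid):
        raise ValueError("cannot compare invalid fingerprints")
    d = a.values - b.values
    return float(d @ d)
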