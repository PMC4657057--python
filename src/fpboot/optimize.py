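"""Nelder-Mead simplex minimization with exact function-evaluation accounting.

The resampling driver charges every optimization run by the number of
objective evaluations it spends, so the optimizer is written from scratch
around an instrumented objective: every call is counted, including the
evaluations of the initial simplex vertices.

Two simplex initializations are provided:

* :func:`init_simplex_default` — the classic ``fminsearch`` rule (perturb
  each coordinate multiplicatively by 5%, or to a small absolute value when
  the coordinate is zero).  Used for naive and original-optimum starts.
* :func:`init_simplex_predicted` — offsets each coordinate by the
  interpolator's per-dimension leave-one-out prediction error, floored at
  the parameter-space convergence tolerance so the simplex never starts
  degenerate.  Used for warm starts at predicted optima: when the predicted
  optimum is accurate, the simplex starts small and convergence is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Simplex",
    "OptimizationResult",
    "OptimizationError",
    "init_simplex_default",
    "init_simplex_predicted",
    "nelder_mead",
    "bounded_objective",
]

# fminsearch initial-simplex constants
_USUAL_DELTA = 0.05
_ZERO_TERM_DELTA = 0.00025

# standard Nelder-Mead coefficients: reflection, expansion, contraction, shrink
_RHO, _CHI, _PSI, _SIGMA = 1.0, 2.0, 0.5, 0.5


class OptimizationError(RuntimeError):
    """Raised when optimization cannot proceed (e.g. no finite vertex)."""


@dataclass
class Simplex:
    """dim+1 vertices of a Nelder-Mead simplex (values filled lazily)."""

    vertices: np.ndarray  # shape (dim+1, dim)
    values: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.vertices.shape[1]


@dataclass
class OptimizationResult:
    optimum: np.ndarray
    value: float
    n_evals: int
    converged: bool


def init_simplex_default(start: Sequence[float]) -> Simplex:
    """Initial simplex around ``start`` using the fminsearch convention.

    Vertex 1 is the start itself; vertex k+1 multiplies component k by 1.05
    (i.e. adds 5%), or sets it to 0.00025 when it is exactly zero.
    """
    x0 = np.asarray(start, dtype=float)
    dim = x0.size
    vertices = np.tile(x0, (dim + 1, 1))
    for k in range(dim):
        if x0[k] != 0.0:
            vertices[k + 1, k] = x0[k] * (1.0 + _USUAL_DELTA)
        else:
            vertices[k + 1, k] = _ZERO_TERM_DELTA
    return Simplex(vertices=vertices)


def init_simplex_predicted(
    start: Sequence[float], eps: Sequence[float], tol_x: float = 1e-6
) -> Simplex:
    """Initial simplex scaled by per-dimension prediction errors.

    Vertex k+1 offsets component k of the start additively by
    ``max(eps[k], tol_x)``: the simplex spans the region in which the true
    optimum plausibly lies given the interpolator's leave-one-out error,
    with ``tol_x`` as a non-degeneracy floor.
    """
    x0 = np.asarray(start, dtype=float)
    e = np.asarray(eps, dtype=float)
    if e.shape != x0.shape:
        raise ValueError("eps must have one entry per parameter dimension")
    dim = x0.size
    vertices = np.tile(x0, (dim + 1, 1))
    for k in range(dim):
        vertices[k + 1, k] = x0[k] + max(float(e[k]), float(tol_x))
    return Simplex(vertices=vertices)


def bounded_objective(
    objective: Callable[[np.ndarray], float],
    lower: Sequence[float] | None,
    upper: Sequence[float] | None,
) -> Callable[[np.ndarray], float]:
    """Wrap an objective so it returns +inf outside box constraints.

    Constraint handling for the simplex search: infeasible proposals are
    rejected through their value, no projection is performed.  Bounds are
    treated as open when the underlying objective diverges there (e.g.
    a scale parameter at zero).
    """
    lo = None if lower is None else np.asarray(lower, dtype=float)
    hi = None if upper is None else np.asarray(upper, dtype=float)

    def wrapped(theta: np.ndarray) -> float:
        if lo is not None and np.any(theta < lo):
            return np.inf
        if hi is not None and np.any(theta > hi):
            return np.inf
        return objective(theta)

    return wrapped


def nelder_mead(
    objective: Callable[[np.ndarray], float],
    simplex: Simplex,
    tol_x: float = 1e-6,
    tol_f: float = 1e-6,
    max_evals: int | None = None,
) -> OptimizationResult:
    """Minimize ``objective`` from an explicit initial simplex.

    Standard reflection/expansion/contraction/shrink moves with
    coefficients (1, 2, 0.5, 0.5).  Convergence is declared when both the
    infinity-norm spread of the vertices around the best vertex and the
    spread of their function values drop below ``tol_x`` and ``tol_f``.
    ``n_evals`` counts every objective call, including the initial
    vertices.  Non-finite objective values (infeasible points) are allowed
    and sort worst; if no initial vertex is finite an
    :class:`OptimizationError` is raised.
    """
    verts = np.array(simplex.vertices, dtype=float)
    npts, dim = verts.shape
    if npts != dim + 1:
        raise ValueError("simplex must have dim+1 vertices")
    if max_evals is None:
        max_evals = 2000 * dim

    n_evals = 0

    def f(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        v = float(objective(x))
        return v if np.isfinite(v) else np.inf

    vals = np.array([f(v) for v in verts])
    if not np.any(np.isfinite(vals)):
        raise OptimizationError("objective is non-finite at every initial vertex")

    converged = False
    while n_evals < max_evals:
        order = np.argsort(vals, kind="stable")
        verts, vals = verts[order], vals[order]

        spread_x = np.max(np.abs(verts[1:] - verts[0]))
        finite = np.isfinite(vals)
        spread_f = (
            np.max(np.abs(vals[1:] - vals[0])) if finite.all() else np.inf
        )
        if spread_x <= tol_x and spread_f <= tol_f:
            converged = True
            break

        centroid = verts[:-1].mean(axis=0)
        worst = verts[-1]
        xr = centroid + _RHO * (centroid - worst)
        fr = f(xr)

        if fr < vals[0]:
            xe = centroid + _RHO * _CHI * (centroid - worst)
            fe = f(xe)
            if fe < fr:
                verts[-1], vals[-1] = xe, fe
            else:
                verts[-1], vals[-1] = xr, fr
        elif fr < vals[-2]:
            verts[-1], vals[-1] = xr, fr
        else:
            if fr < vals[-1]:  # outside contraction
                xc = centroid + _PSI * _RHO * (centroid - worst)
                fc = f(xc)
                if fc <= fr:
                    verts[-1], vals[-1] = xc, fc
                else:
                    _shrink(verts, vals, f)
            else:  # inside contraction
                xcc = centroid - _PSI * (centroid - worst)
                fcc = f(xcc)
                if fcc < vals[-1]:
                    verts[-1], vals[-1] = xcc, fcc
                else:
                    _shrink(verts, vals, f)

    order = np.argsort(vals, kind="stable")
    verts, vals = verts[order], vals[order]
    return OptimizationResult(
        optimum=verts[0].copy(),
        value=float(vals[0]),
        n_evals=n_evals,
        converged=converged,
    )


def _shrink(verts: np.ndarray, vals: np.ndarray, f) -> None:
    for i in range(1, verts.shape[0]):
        verts[i] = verts[0] + _SIGMA * (verts[i] - verts[0])
        vals[i] = f(verts[i])
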