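"""Orchestration of a full fingerprint-resampling run.

A run takes an objective model, an original data set and a
:class:`VariantPlan`, and produces one :class:`ResampleRecord` per
bootstrap resample.  Four variants are supported:

* ``naive`` — every resample is optimized from the model's naive start.
* ``original_optimum`` — every resample is optimized from the original
  fit's optimum (the natural centrality argument: with zero estimated
  bias, the original optimum is the mean of the bootstrap optima).
* ``warm_start`` — fingerprints of all resamples are computed up front;
  after an initial phase of fully optimized resamples, an interpolator
  predicts each remaining optimum, which seeds the optimizer together
  with an uncertainty-scaled initial simplex.
* ``bypass`` — as ``warm_start``, but for every optimized estimate up to
  ``p`` further resamples take the prediction *as* their estimate, with
  zero optimizer cost.  ``bypass`` with p=0 is exactly ``warm_start``.

The initial phase exists to avoid extrapolation: the resamples attaining
the minimum or maximum in any fingerprint dimension, plus a number of
randomly chosen ones, are solved first (from the original optimum) so the
interpolator trains on a broad, stable range of fingerprints.

Cost accounting is exact: each record carries the optimizer evaluation
count and the finite-difference cost of its fingerprint; interpolator
algebra is free by design (it does not evaluate the objective and does
not scale with the difficulty of the estimation problem).

Serial learning vs. parallel execution is modeled by ``plan.cores``:
solved couples enter the training pool only at batch boundaries of that
size, so resamples inside one batch cannot learn from each other.
``cores=1`` is the fully serial schedule; ``cores >= B`` disables
learning entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fingerprints import Fingerprint, compute_fingerprint
from .interpolate import FittedInterpolator, NotFittedError, TrainingPool, fit
from .models.base import ObjectiveModel
from .optimize import (
    OptimizationResult,
    bounded_objective,
    init_simplex_default,
    init_simplex_predicted,
    nelder_mead,
)

__all__ = [
    "VariantPlan",
    "ResampleRecord",
    "RunResult",
    "fit_original",
    "initial_phase_order",
    "planned_bypass_count",
    "run",
    "total_cost",
]

OPTIONS = ("naive", "original_optimum", "warm_start", "bypass")


@dataclass
class VariantPlan:
    """Configuration of one resampling run."""

    option: str = "original_optimum"
    g: int = 1  # fingerprint order (warm_start / bypass)
    p: float = 0.0  # bypass ratio: predicted estimates per optimized one
    B: int = 200  # total resample budget
    n_random_initial: int = 20  # random resamples added to the initial phase
    seed: int = 0
    tol_x: float = 1e-6
    tol_f: float = 1e-6
    max_evals: int | None = None
    cores: int = 1  # batch size for the parallel-learning schedule
    refit_min: int = 10  # refit the interpolator after this many new couples...
    refit_frac: float = 0.1  # ...or 10% of the last training size, if larger
    pool_cap: int = 1000  # stop refitting once the pool exceeds this

    def __post_init__(self) -> None:
        if self.option not in OPTIONS:
            raise ValueError(f"option must be one of {OPTIONS}")
        if self.g not in (1, 2):
            raise ValueError("fingerprint order g must be 1 or 2")
        if self.p < 0:
            raise ValueError("bypass ratio p must be >= 0")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.cores < 1:
            raise ValueError("cores must be >= 1")


@dataclass
class ResampleRecord:
    """Outcome of one resample: estimate, costs and provenance flags."""

    index: int  # original resample index (0-based)
    estimate: np.ndarray
    n_evals: int  # optimizer objective evaluations (0 if bypassed)
    fingerprint_cost: int = 0
    start_used: np.ndarray | None = None
    bypassed: bool = False
    prioritized: bool = False  # solved in the extrapolation-avoiding phase
    weight: float = 1.0

    @property
    def cost(self) -> int:
        return self.n_evals + self.fingerprint_cost


@dataclass
class RunResult:
    """Records (in processing order) plus run-level context."""

    records: list[ResampleRecord]
    theta0: np.ndarray
    n_evals_original: int
    plan: VariantPlan
    model_name: str
    n_refits: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        dim = self.theta0.size
        rows = []
        for r in self.records:
            row = {
                "index": r.index,
                "bypassed": r.bypassed,
                "prioritized": r.prioritized,
                "n_evals": r.n_evals,
                "fingerprint_cost": r.fingerprint_cost,
                "weight": r.weight,
            }
            for k in range(dim):
                row[f"estimate_{k}"] = r.estimate[k]
            for k in range(dim):
                row[f"start_{k}"] = np.nan if r.start_used is None else r.start_used[k]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        recs = self.records
        optimized = [r for r in recs if not r.bypassed]
        return {
            "model": self.model_name,
            "option": self.plan.option,
            "g": self.plan.g,
            "p": self.plan.p,
            "B": self.plan.B,
            "seed": self.plan.seed,
            "theta0": [float(v) for v in self.theta0],
            "n_records": len(recs),
            "n_optimized": len(optimized),
            "n_bypassed": sum(r.bypassed for r in recs),
            "n_refits": self.n_refits,
            "total_cost": total_cost(recs),
            "total_optimizer_evals": int(sum(r.n_evals for r in recs)),
            "total_fingerprint_cost": int(sum(r.fingerprint_cost for r in recs)),
            "mean_evals_per_optimized": (
                float(np.mean([r.n_evals for r in optimized])) if optimized else 0.0
            ),
        }


def planned_bypass_count(n_optimized: int, p: float, B: int) -> int:
    """Predicted estimates added for ``n_optimized`` optimizer-based ones.

    The ratio semantics of the bypass variant: p predicted estimates per
    fully optimized estimate, capped so the total never exceeds B.  E.g.
    with p=3, 200 optimized estimates are topped up with 600 predictions
    (800 total); with 1800 optimized and B=2000 only 200 fit.
    """
    if n_optimized < 0 or B < n_optimized:
        raise ValueError("need 0 <= n_optimized <= B")
    return min(int(math.floor(p * n_optimized)), B - n_optimized)


def fit_original(
    model: ObjectiveModel,
    data: pd.DataFrame,
    tol_x: float = 1e-6,
    tol_f: float = 1e-6,
    max_evals: int | None = None,
) -> tuple[np.ndarray, OptimizationResult]:
    """Full fit of the original data from the model's naive start."""
    model.validate_data(data)
    objective = bounded_objective(model.make_objective(data), model.lower, model.upper)
    simplex = init_simplex_default(model.naive_start(data))
    result = nelder_mead(objective, simplex, tol_x=tol_x, tol_f=tol_f, max_evals=max_evals)
    return model.canonicalize(result.optimum), result


def initial_phase_order(
    fingerprints: Sequence[Fingerprint],
    n_random: int,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    """Select the extrapolation-avoiding initial phase.

    For each fingerprint dimension the resamples attaining the minimum and
    the maximum are prioritized (deduplicated, at most 2 per dimension);
    ``n_random`` further resamples are drawn uniformly without replacement
    from the rest.  Returns (initial phase indices, remaining indices in
    original order).  Invalid fingerprints are never prioritized.
    """
    valid = [i for i, f in enumerate(fingerprints) if f.valid]
    prioritized: list[int] = []
    if valid:
        V = np.vstack([fingerprints[i].values for i in valid])
        for k in range(V.shape[1]):
            for pick in (valid[int(np.argmin(V[:, k]))], valid[int(np.argmax(V[:, k]))]):
                if pick not in prioritized:
                    prioritized.append(pick)
    rest = [i for i in valid if i not in prioritized]
    n_pick = min(n_random, len(rest))
    random_picks = (
        [rest[j] for j in rng.choice(len(rest), size=n_pick, replace=False)]
        if n_pick
        else []
    )
    initial = prioritized + random_picks
    chosen = set(initial)
    remaining = [i for i in range(len(fingerprints)) if i not in chosen]
    return initial, remaining


def total_cost(records: Sequence[ResampleRecord]) -> int:
    """Total function-evaluation cost: optimizer evals + fingerprint costs."""
    return int(sum(r.n_evals + r.fingerprint_cost for r in records))


def run(plan: VariantPlan, model: ObjectiveModel, data: pd.DataFrame) -> RunResult:
    """Execute a full fingerprint-resampling run.

    Deterministic given ``plan.seed``: the resampling stream and the
    initial-phase random picks use independent child streams of the root
    seed, so different variants with the same seed see identical
    resamples.
    """
    model.validate_data(data)
    root = np.random.SeedSequence(plan.seed)
    resample_ss, _initial_ss = root.spawn(2)
    rng_resample = np.random.default_rng(resample_ss)

    theta0, orig = fit_original(
        model, data, tol_x=plan.tol_x, tol_f=plan.tol_f, max_evals=plan.max_evals
    )
    resamples = [model.resample(data, rng_resample) for _ in range(plan.B)]

    if plan.option in ("naive", "original_optimum"):
        records = []
        for b, rd in enumerate(resamples):
            start = model.naive_start(rd) if plan.option == "naive" else theta0
            rec = _optimize_one(model, rd, start, None, plan, b)
            records.append(rec)
        return RunResult(records, theta0, orig.n_evals, plan, model.name)

    return _run_fingerprint_variant(plan, model, resamples, theta0, orig.n_evals)


def _optimize_one(
    model: ObjectiveModel,
    data_b: pd.DataFrame,
    start: np.ndarray,
    eps: np.ndarray | None,
    plan: VariantPlan,
    index: int,
    fingerprint_cost: int = 0,
    prioritized: bool = False,
) -> ResampleRecord:
    objective = bounded_objective(model.make_objective(data_b), model.lower, model.upper)
    if eps is None:
        simplex = init_simplex_default(start)
    else:
        simplex = init_simplex_predicted(start, eps, tol_x=plan.tol_x)
    result = nelder_mead(
        objective, simplex, tol_x=plan.tol_x, tol_f=plan.tol_f, max_evals=plan.max_evals
    )
    return ResampleRecord(
        index=index,
        estimate=model.canonicalize(result.optimum),
        n_evals=result.n_evals,
        fingerprint_cost=fingerprint_cost,
        start_used=np.asarray(start, dtype=float),
        prioritized=prioritized,
    )


def _run_fingerprint_variant(
    plan: VariantPlan,
    model: ObjectiveModel,
    resamples: list[pd.DataFrame],
    theta0: np.ndarray,
    n_evals_original: int,
) -> RunResult:
    # All B fingerprints up front: the extrapolation scan needs them, and
    # their finite-difference cost is charged per record regardless.
    fps = [
        compute_fingerprint(model, rd, theta0, g=plan.g) for rd in resamples
    ]
    for b, f in enumerate(fps):
        f.index = b

    rng_initial = np.random.default_rng(np.random.SeedSequence(plan.seed).spawn(2)[1])
    initial, remaining = initial_phase_order(fps, plan.n_random_initial, rng_initial)

    pool = TrainingPool()
    pending: list[tuple[Fingerprint, np.ndarray, int, np.ndarray]] = []
    interp: FittedInterpolator | None = None
    last_fit_size = 0
    n_refits = 0
    records: list[ResampleRecord] = []
    n_since_flush = 0
    n_bypassed_since_opt = 0.0

    def boundary_flags(est: np.ndarray) -> np.ndarray:
        tol = 10.0 * plan.tol_x
        return (np.abs(est - model.lower) <= tol) | (np.abs(est - model.upper) <= tol)

    def flush_and_maybe_refit() -> None:
        nonlocal interp, last_fit_size, n_refits, pending
        for f, est, idx, flags in pending:
            pool.add(f, est, idx, flags)
        pending = []
        if last_fit_size > plan.pool_cap:
            return  # modeling stopped: the last model is reused
        grown = len(pool) - last_fit_size
        threshold = max(plan.refit_min, int(math.ceil(plan.refit_frac * last_fit_size)))
        if grown >= threshold:
            try:
                refit = fit(pool, model.lower, model.upper)
            except NotFittedError:
                return
            interp = refit
            last_fit_size = len(pool)
            n_refits += 1

    def process(b: int, rec: ResampleRecord) -> None:
        nonlocal n_since_flush
        records.append(rec)
        if not rec.bypassed and fps[b].valid:
            pending.append((fps[b], rec.estimate, b, boundary_flags(rec.estimate)))
        n_since_flush += 1
        if n_since_flush >= plan.cores:
            flush_and_maybe_refit()
            n_since_flush = 0

    # --- initial phase: extremes + random picks, original optimum start ---
    for b in initial:
        rec = _optimize_one(
            model, resamples[b], theta0, None, plan, b,
            fingerprint_cost=fps[b].eval_cost, prioritized=True,
        )
        process(b, rec)

    # --- main phase: warm starts and (optionally) bypassed predictions ---
    for b in remaining:
        f = fps[b]
        if not f.valid:
            # no fingerprint -> no prediction; full fit from the naive start
            rec = _optimize_one(
                model, resamples[b], model.naive_start(resamples[b]), None, plan, b,
                fingerprint_cost=f.eval_cost,
            )
            n_bypassed_since_opt = 0.0
        elif interp is not None:
            pred, eps = interp.predict(f)
            can_bypass = (
                plan.option == "bypass"
                and plan.p > 0
                and n_bypassed_since_opt + 1.0 <= plan.p
            )
            if can_bypass:
                rec = ResampleRecord(
                    index=b,
                    estimate=model.canonicalize(pred),
                    n_evals=0,
                    fingerprint_cost=f.eval_cost,
                    start_used=None,
                    bypassed=True,
                )
                n_bypassed_since_opt += 1.0
            else:
                rec = _optimize_one(
                    model, resamples[b], pred, eps, plan, b,
                    fingerprint_cost=f.eval_cost,
                )
                n_bypassed_since_opt = 0.0
        else:
            # interpolator not available yet: fall back to the original optimum
            rec = _optimize_one(
                model, resamples[b], theta0, None, plan, b,
                fingerprint_cost=f.eval_cost,
            )
            n_bypassed_since_opt = 0.0
        process(b, rec)

    flush_and_maybe_refit()
    return RunResult(records, theta0, n_evals_original, plan, model.name, n_refits)
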