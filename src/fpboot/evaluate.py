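"""Bootstrap summaries and the speed-accuracy trade-off.

The end product of the bootstrap here is a percentile confidence bound
(by default the 2.5% bound of a 95% interval), estimated as an order
statistic of the bootstrap estimates.  This module measures how fast each
variant drives the error of that bound down per function evaluation:

* :func:`percentile_estimate` — the floored-rank percentile estimator,
  with an optional weighted form used to discount prioritized optima that
  were deliberately solved out of order (extreme fingerprints first);
* :func:`accuracy_curve` — error of the percentile estimate versus
  cumulative function evaluations, as estimates accrue in processing
  order;
* :func:`speedup_at_accuracy` — the cost ratio between a baseline and a
  variant at the first crossing of an accuracy level (``high`` is the
  baseline's terminal error; ``medium`` is twice that);
* :func:`parallel_replay` — re-runs the learning schedule with the
  training pool frozen at batch boundaries, emulating C-core execution
  where resamples in one batch cannot learn from each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .driver import ResampleRecord, RunResult, VariantPlan, run
from .models.base import ObjectiveModel

__all__ = [
    "AccuracyCurve",
    "ReferencePercentile",
    "percentile_estimate",
    "bootstrap_bias",
    "reference_percentile",
    "accuracy_curve",
    "accuracy_levels",
    "speedup_at_accuracy",
    "parallel_replay",
    "LevelNotReachedError",
]


class LevelNotReachedError(RuntimeError):
    """A curve never attains the requested accuracy level."""


def percentile_estimate(
    estimates: Sequence[float],
    alpha: float,
    weights: Sequence[float] | None = None,
) -> float:
    """Percentile bootstrap estimate of the alpha-quantile.

    Unweighted: the ascending order statistic at rank
    ``max(1, floor(alpha * B))`` (1-based).  Weighted: the smallest value
    whose cumulative weight reaches ``max(1, floor(alpha * W))`` with W
    the total weight — chosen so uniform unit weights reproduce the
    unweighted rank exactly.
    """
    vals = np.asarray(estimates, dtype=float)
    if vals.size == 0:
        raise ValueError("no estimates")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    order = np.argsort(vals, kind="stable")
    if weights is None:
        rank = max(1, math.floor(alpha * vals.size))
        return float(vals[order[rank - 1]])
    w = np.asarray(weights, dtype=float)[order]
    if w.size != vals.size or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative, one per estimate")
    target = max(1.0, math.floor(alpha * w.sum()))
    cum = np.cumsum(w)
    pos = int(np.searchsorted(cum, target - 1e-12))
    pos = min(pos, vals.size - 1)
    return float(vals[order[pos]])


def bootstrap_bias(estimates: np.ndarray, theta0: np.ndarray) -> np.ndarray:
    """Estimated bias: mean of the bootstrap optima minus the original optimum."""
    est = np.asarray(estimates, dtype=float)
    est = est.reshape(est.shape[0], -1)  # 1-d input: scalar estimates
    return est.mean(axis=0) - np.atleast_1d(np.asarray(theta0, dtype=float))


@dataclass
class ReferencePercentile:
    """Best available stand-in for the infinite-bootstrap percentile."""

    value: float
    provenance: str = ""
    n_pooled: int = 0


def reference_percentile(
    pooled_estimates: Sequence[float], alpha: float, provenance: str = "pooled runs"
) -> ReferencePercentile:
    """Reference bound from estimates pooled across independent runs.

    Pooling across seeded runs of the same original data is legitimate:
    every resample is generated independently from the same original data
    set, so the union is one large bootstrap.
    """
    vals = np.asarray(pooled_estimates, dtype=float)
    return ReferencePercentile(
        value=percentile_estimate(vals, alpha),
        provenance=provenance,
        n_pooled=vals.size,
    )


@dataclass
class AccuracyCurve:
    """Cumulative function evaluations vs. percentile-estimate error."""

    costs: np.ndarray  # non-decreasing cumulative evaluations
    errors: np.ndarray  # |q_hat_b - q_ref| after b estimates
    variant: str = ""
    parameter: str = ""

    def cost_to_reach(self, level: float) -> int:
        """First cumulative cost at which the error drops to <= level."""
        hit = np.nonzero(self.errors <= level)[0]
        if hit.size == 0:
            raise LevelNotReachedError(
                f"curve {self.variant!r} never reaches error {level}"
            )
        return int(self.costs[hit[0]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_estimates": np.arange(1, self.errors.size + 1),
                "cost": self.costs,
                "error": self.errors,
                "variant": self.variant,
                "parameter": self.parameter,
            }
        )


def accuracy_curve(
    records: Sequence[ResampleRecord],
    alpha: float,
    reference: ReferencePercentile | float,
    select: Callable[[np.ndarray], float] | int = 0,
    variant: str = "",
    parameter: str = "",
) -> AccuracyCurve:
    """Speed-accuracy curve of a run for one scalar parameter.

    ``select`` maps an estimate vector to the scalar of interest (an int
    selects that component; the mixed model passes a callable recovering
    a D entry).  Estimates accrue in processing order.  Prioritized
    records (solved out of order in the initial phase) are down-weighted
    early on with weight ``min(1, b / (index + 1))`` after b estimates —
    related to the inverse of their original resample index — which has
    no effect once all estimates are in.  Fingerprint costs for the whole
    run are charged up front on the cost axis (they are all computed
    before any resample is solved).
    """
    ref = reference.value if isinstance(reference, ReferencePercentile) else float(reference)
    if isinstance(select, int):
        k = select
        select = lambda est: float(est[k])  # noqa: E731
    vals = np.array([select(r.estimate) for r in records])
    idx = np.array([r.index for r in records])
    prio = np.array([r.prioritized for r in records])
    upfront = int(sum(r.fingerprint_cost for r in records))
    cum_evals = np.cumsum([r.n_evals for r in records])
    costs = upfront + cum_evals
    errors = np.empty(len(records))
    for b in range(1, len(records) + 1):
        w = np.ones(b)
        mask = prio[:b]
        if mask.any():
            w[mask] = np.minimum(1.0, b / (idx[:b][mask] + 1.0))
        errors[b - 1] = abs(percentile_estimate(vals[:b], alpha, weights=w) - ref)
    return AccuracyCurve(
        costs=costs.astype(int), errors=errors, variant=variant, parameter=parameter
    )


def accuracy_levels(baseline: AccuracyCurve) -> tuple[float, float]:
    """(high, medium) accuracy levels from the baseline curve.

    High accuracy is the error the baseline (original-optimum variant)
    attains at the end of its full budget; medium accuracy is twice that.
    """
    high = float(baseline.errors[-1])
    return high, 2.0 * high


def speedup_at_accuracy(
    curve_variant: AccuracyCurve, curve_baseline: AccuracyCurve, level: float
) -> float:
    """Cost ratio baseline/variant at the first crossing of ``level``."""
    cost_b = curve_baseline.cost_to_reach(level)
    cost_v = curve_variant.cost_to_reach(level)
    return cost_b / cost_v


def parallel_replay(
    plan: VariantPlan, model: ObjectiveModel, data: pd.DataFrame, cores: int
) -> RunResult:
    """Re-run the schedule as if executed in batches of ``cores``.

    Couples enter the training pool only at batch boundaries, so warm
    starts and bypasses are recomputed with strictly less information.
    ``cores=1`` reproduces the serial run exactly; ``cores >= B``
    disables learning (fingerprint costs are still incurred).
    """
    return run(replace(plan, cores=cores), model, data)
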