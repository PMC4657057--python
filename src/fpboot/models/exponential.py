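"""Exponential distribution, mean parametrization.

The first toy problem: i.i.d. exponential data with log-likelihood

    l(theta) = -n log(theta) - sum(x) / theta,   theta > 0,

whose maximizer is the sample average.  The mean parametrization is chosen
deliberately so the closed-form optimum is ``mean(x)`` and the first-order
fingerprint relates affinely to it — the problem where warm-start
prediction is exactly learnable from two solved resamples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .base import InvalidParameterError, ObjectiveModel, register_model

__all__ = ["ExponentialModel", "simulate_exponential"]


class ExponentialModel(ObjectiveModel):
    name = "exponential"
    dim = 1
    columns = ("x",)

    def loglik(self, theta: np.ndarray, data: pd.DataFrame) -> float:
        th = float(np.atleast_1d(theta)[0])
        if th <= 0:
            raise InvalidParameterError("exponential mean must be positive")
        x = data["x"].to_numpy()
        return float(-len(x) * np.log(th) - x.sum() / th)

    def make_objective(self, data: pd.DataFrame):
        x = data["x"].to_numpy()
        n, s = len(x), float(x.sum())

        def negloglik(theta: np.ndarray) -> float:
            th = float(np.atleast_1d(theta)[0])
            if th <= 0:
                return np.inf
            return n * np.log(th) + s / th

        return negloglik

    @property
    def lower(self) -> np.ndarray:
        return np.array([0.0])

    def naive_start(self, data: pd.DataFrame) -> np.ndarray:
        return np.array([1.0])

    def oracle(self, data: pd.DataFrame) -> np.ndarray:
        return np.array([data["x"].mean()])


register_model(ExponentialModel)


def simulate_exponential(
    theta: float = 2.0, n: int = 100, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """i.i.d. exponential sample with mean ``theta``."""
    if theta <= 0:
        raise InvalidParameterError("theta must be positive")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({"x": rng.exponential(scale=theta, size=n)})
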