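"""No-intercept linear regression with known unit error variance.

The second toy problem: y_i = beta * x_i + e_i with e_i ~ N(0, 1), so

    l(beta) = -(n/2) log(2*pi) - 0.5 * sum((y - beta*x)^2)

is maximized at beta_hat = sum(x*y) / sum(x^2).  A first-order fingerprint
does not determine the optimum (resamples with equal gradient can have
different curvature), which is why this model exercises the second-order
fingerprint: with F1 = sum(x*(y - beta0*x)) and F2 = -sum(x^2) one has the
exact Newton relation beta_hat = beta0 - F1/F2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .base import ObjectiveModel, register_model

__all__ = ["RegressionModel", "simulate_regression"]

_LOG2PI = float(np.log(2.0 * np.pi))


class RegressionModel(ObjectiveModel):
    name = "regression"
    dim = 1
    columns = ("x", "y")

    def loglik(self, theta: np.ndarray, data: pd.DataFrame) -> float:
        b = float(np.atleast_1d(theta)[0])
        x = data["x"].to_numpy()
        y = data["y"].to_numpy()
        resid = y - b * x
        return float(-0.5 * len(x) * _LOG2PI - 0.5 * resid @ resid)

    def make_objective(self, data: pd.DataFrame):
        x = data["x"].to_numpy()
        y = data["y"].to_numpy()
        n = len(x)
        # sufficient statistics of the quadratic objective
        sxx, sxy, syy = float(x @ x), float(x @ y), float(y @ y)
        const = 0.5 * n * _LOG2PI

        def negloglik(theta: np.ndarray) -> float:
            b = float(np.atleast_1d(theta)[0])
            return const + 0.5 * (syy - 2.0 * b * sxy + b * b * sxx)

        return negloglik

    def naive_start(self, data: pd.DataFrame) -> np.ndarray:
        return np.array([0.0])

    def oracle(self, data: pd.DataFrame) -> np.ndarray:
        x = data["x"].to_numpy()
        y = data["y"].to_numpy()
        sxx = float(x @ x)
        if sxx == 0.0:
            raise ValueError("degenerate design: sum(x^2) = 0")
        return np.array([float(x @ y) / sxx])


register_model(RegressionModel)


def simulate_regression(
    beta: float = 2.0,
    n: int = 100,
    x_max: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Fixed-design regression data: x ~ U(0, x_max), y = beta*x + N(0,1)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, x_max, size=n)
    y = beta * x + rng.standard_normal(n)
    return pd.DataFrame({"x": x, "y": y})
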