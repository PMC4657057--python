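"""Objective-model contract shared by all bootstrap targets.

An :class:`ObjectiveModel` bundles everything the resampling driver needs
to know about one estimation problem:

* a log-likelihood ``loglik(theta, data)`` over a ``dim``-dimensional
  parameter vector (the driver minimizes its negative),
* box constraints on the parameters,
* a naive starting value,
* a resampler mapping (data, rng) to a bootstrap replicate,
* optionally a closed-form optimum (``oracle``) used for verification.

Data sets are plain :class:`pandas.DataFrame` objects with model-specific
column conventions; they round-trip through CSV with a one-line header.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["ObjectiveModel", "InvalidParameterError", "get_model", "register_model"]


class InvalidParameterError(ValueError):
    """Parameter vector outside the model's domain."""


class ObjectiveModel(ABC):
    """Contract for a bootstrap estimation problem."""

    #: model identifier used in configs and the CLI
    name: str
    #: parameter dimension
    dim: int
    #: data columns expected in the data frame
    columns: tuple[str, ...]

    # ---- likelihood -----------------------------------------------------

    @abstractmethod
    def loglik(self, theta: np.ndarray, data: pd.DataFrame) -> float:
        """Log-likelihood at ``theta``; -inf where the model has no support."""

    def make_objective(self, data: pd.DataFrame) -> Callable[[np.ndarray], float]:
        """Return a fast negative-log-likelihood closure for ``data``.

        Models with nontrivial per-dataset sufficient statistics override
        this to precompute them once, so repeated evaluations during an
        optimization or a finite-difference stencil stay cheap.  The value
        is always ``-loglik`` (a minimization objective).
        """
        return lambda theta: -self.loglik(theta, data)

    # ---- constraints ----------------------------------------------------

    @property
    def lower(self) -> np.ndarray:
        return np.full(self.dim, -np.inf)

    @property
    def upper(self) -> np.ndarray:
        return np.full(self.dim, np.inf)

    # ---- starts, resampling, oracles ------------------------------------

    @abstractmethod
    def naive_start(self, data: pd.DataFrame) -> np.ndarray:
        """Starting value a user with no prior information would pick."""

    def resample(self, data: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        """Nonparametric bootstrap: rows drawn with replacement, same n."""
        n = len(data)
        idx = rng.integers(0, n, size=n)
        return data.iloc[idx].reset_index(drop=True)

    oracle: Callable[[pd.DataFrame], np.ndarray] | None = None

    # ---- housekeeping ---------------------------------------------------

    def validate_data(self, data: pd.DataFrame) -> None:
        missing = [c for c in self.columns if c not in data.columns]
        if missing:
            raise ValueError(f"{self.name}: data lacks columns {missing}")
        if len(data) < 1:
            raise ValueError(f"{self.name}: empty data set")
        if data[list(self.columns)].isna().any().any():
            raise ValueError(f"{self.name}: missing values are not supported")

    def canonicalize(self, theta: np.ndarray) -> np.ndarray:
        """Map a parameter vector to its canonical representative.

        Identity except for models with parameter symmetries (the mixed
        model's Cholesky sign symmetry).
        """
        return np.asarray(theta, dtype=float)


_REGISTRY: dict[str, Callable[[], ObjectiveModel]] = {}


def register_model(factory: Callable[[], ObjectiveModel]) -> Callable[[], ObjectiveModel]:
    probe = factory()
    _REGISTRY[probe.name] = factory
    return factory


def get_model(name: str) -> ObjectiveModel:
    """Instantiate a registered model by name."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(_REGISTRY)}")
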