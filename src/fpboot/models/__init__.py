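"""Objective models: likelihoods, resamplers, oracles and data generators."""

from .base import InvalidParameterError, ObjectiveModel, get_model, register_model
from .exponential import ExponentialModel, simulate_exponential
from .regression import RegressionModel, simulate_regression
from .mixed import MixedModel, MixedModelParams, full_negloglik, simulate_mixed
from .gev import GevModel, GevParams, gev_negloglik, simulate_gev

__all__ = [
    "InvalidParameterError",
    "ObjectiveModel",
    "get_model",
    "register_model",
    "ExponentialModel",
    "simulate_exponential",
    "RegressionModel",
    "simulate_regression",
    "MixedModel",
    "MixedModelParams",
    "full_negloglik",
    "simulate_mixed",
    "GevModel",
    "GevParams",
    "gev_negloglik",
    "simulate_gev",
    "simulate",
]

_SIMULATORS = {
    "exponential": simulate_exponential,
    "regression": simulate_regression,
    "mixed": simulate_mixed,
    "gev": simulate_gev,
}


def simulate(model_name: str, seed: int = 0, **params):
    """Dispatch to a model's synthetic-data generator by name."""
    try:
        gen = _SIMULATORS[model_name]
    except KeyError:
        raise KeyError(f"unknown model {model_name!r}; available: {sorted(_SIMULATORS)}")
    return gen(seed=seed, **params)
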