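"""Linear mixed model with random intercept and slope, profiled likelihood.

Model for clustered longitudinal data (cluster i, observation t):

    y_it = beta0 + beta1 * x_it + b0_i + b1_i * x_it + e_it,
    b_i ~ N(0, D),   e_it ~ N(0, sigma2 * I),  independent,

i.e. the marginal model Y_i ~ N(X_i beta, Z_i D Z_i' + sigma2 I) with
X_i = Z_i = [1, x_i].  Maximum likelihood is performed on a reduced
3-parameter surface: write D = sigma2 * L L' with L lower triangular
(Cholesky factor of the scaled random-effects covariance, free parameters
L11, L21, L22); for fixed Gamma = L L' both beta and sigma2 have
closed-form maximizers (GLS and the scaled generalized RSS), which are
profiled out.  The optimizer therefore works on (L11, L21, L22) only, and
the fitted triple is translated back to (beta, sigma2, D) afterwards.

Because D depends on L only through L L', the sign of each Cholesky column
is unidentified; optima are canonicalized to a nonnegative diagonal so the
fingerprint -> optimum relation stays single-valued.  Comparisons and
bootstrap percentiles are taken on the recovered D entries, which are
invariant to this choice.

All per-cluster linear algebra is reduced to 2x2 operations via the
Woodbury identity and the matrix determinant lemma on the cluster
cross-products, so one likelihood evaluation is O(#clusters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .base import InvalidParameterError, ObjectiveModel, register_model

__all__ = ["MixedModel", "MixedModelParams", "simulate_mixed", "full_negloglik"]


@dataclass
class MixedModelParams:
    """Mixed-model fit translated back to its original parametrization."""

    beta: np.ndarray  # fixed effects (2,)
    sigma2: float  # residual variance
    D: np.ndarray  # random-effects covariance (2, 2), symmetric PSD
    chol: np.ndarray  # scaled Cholesky free parameters (L11, L21, L22)

    @property
    def d_entries(self) -> np.ndarray:
        """(D11, D12, D22) — the quantities bootstrap percentiles target."""
        return np.array([self.D[0, 0], self.D[0, 1], self.D[1, 1]])


def _chol_to_gamma(chol: np.ndarray) -> np.ndarray:
    l11, l21, l22 = chol
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


class _SuffStats:
    """Per-cluster cross-products; everything the likelihood needs."""

    def __init__(self, data: pd.DataFrame):
        ids = data["cluster_id"].to_numpy()
        x = data["x"].to_numpy(dtype=float)
        y = data["y"].to_numpy(dtype=float)
        self.G = []  # Z'Z per cluster (2,2)
        self.zty = []  # Z'y per cluster (2,)
        self.yty = []
        self.sizes = []
        for cid in pd.unique(ids):
            m = ids == cid
            xi, yi = x[m], y[m]
            Z = np.column_stack([np.ones(xi.size), xi])
            self.G.append(Z.T @ Z)
            self.zty.append(Z.T @ yi)
            self.yty.append(float(yi @ yi))
            self.sizes.append(xi.size)
        self.n_clusters = len(self.sizes)
        self.N = int(sum(self.sizes))

    def profile(self, gamma: np.ndarray):
        """GLS beta, ML sigma2 and the profiled negative log-likelihood.

        Returns (beta, sigma2, negloglik); (None, None, inf) on numerical
        failure (singular marginal covariance or normal equations).
        """
        A = np.zeros((2, 2))  # sum X'V*^-1 X
        c = np.zeros(2)  # sum X'V*^-1 y
        logdet = 0.0
        Ws = []
        for G in self.G:
            M = np.eye(2) + G @ gamma
            det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
            if det <= 0:
                return None, None, np.inf
            logdet += np.log(det)
            W = gamma @ np.linalg.inv(M)  # Gamma (I + G Gamma)^-1, symmetric
            Ws.append(W)
        for G, zty, W in zip(self.G, self.zty, Ws):
            GW = G @ W
            A += G - GW @ G
            c += zty - GW @ zty
        try:
            beta = np.linalg.solve(A, c)
        except np.linalg.LinAlgError:
            return None, None, np.inf
        quad = 0.0
        for G, zty, yty, W in zip(self.G, self.zty, self.yty, Ws):
            u = zty - G @ beta
            rtr = yty - 2.0 * beta @ zty + beta @ G @ beta
            quad += rtr - u @ W @ u
        if not np.isfinite(quad) or quad <= 0:
            return None, None, np.inf
        sigma2 = quad / self.N
        nll = 0.5 * (self.N * np.log(2.0 * np.pi * sigma2) + logdet + self.N)
        return beta, float(sigma2), float(nll)


class MixedModel(ObjectiveModel):
    name = "mixed"
    dim = 3
    columns = ("cluster_id", "x", "y")

    def loglik(self, theta: np.ndarray, data: pd.DataFrame) -> float:
        return -self.make_objective(data)(np.asarray(theta, dtype=float))

    def make_objective(self, data: pd.DataFrame):
        stats = _SuffStats(data)

        def negloglik(theta: np.ndarray) -> float:
            gamma = _chol_to_gamma(np.asarray(theta, dtype=float))
            _, _, nll = stats.profile(gamma)
            return nll

        return negloglik

    def naive_start(self, data: pd.DataFrame) -> np.ndarray:
        return np.array([0.1, 0.0, 0.1])

    def resample(self, data: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        """Case bootstrap: clusters are the exchangeable units.

        Draws the same number of clusters with replacement and relabels
        them 1..N so a cluster drawn twice enters as two distinct units.
        """
        ids = data["cluster_id"].to_numpy()
        unique = pd.unique(ids)
        chosen = unique[rng.integers(0, len(unique), size=len(unique))]
        parts = []
        for new_id, cid in enumerate(chosen, start=1):
            part = data.loc[ids == cid].copy()
            part["cluster_id"] = new_id
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    def canonicalize(self, theta: np.ndarray) -> np.ndarray:
        l11, l21, l22 = np.asarray(theta, dtype=float)
        if l11 < 0:
            l11, l21 = -l11, -l21
        if l22 < 0:
            l22 = -l22
        return np.array([l11, l21, l22])

    def recover(self, chol: np.ndarray, data: pd.DataFrame) -> MixedModelParams:
        """Translate a profiled-surface point back to (beta, sigma2, D)."""
        chol = np.asarray(chol, dtype=float)
        gamma = _chol_to_gamma(chol)
        beta, sigma2, nll = _SuffStats(data).profile(gamma)
        if beta is None or not np.isfinite(nll):
            raise np.linalg.LinAlgError("profiled likelihood undefined at this point")
        return MixedModelParams(
            beta=beta, sigma2=sigma2, D=sigma2 * gamma, chol=self.canonicalize(chol)
        )


register_model(MixedModel)


def full_negloglik(eta: np.ndarray, data: pd.DataFrame) -> float:
    """Unprofiled marginal negative log-likelihood.

    ``eta = (beta0, beta1, sigma2, D11, D12, D22)``.  Serves as the
    independent check that profiling (beta, sigma2) out leaves the optimum
    untouched, and as the likelihood whose observed information yields
    standard errors on the natural parameters.  Returns +inf outside the
    domain (sigma2 <= 0 or D not PSD).
    """
    eta = np.asarray(eta, dtype=float)
    beta, sigma2 = eta[:2], eta[2]
    d11, d12, d22 = eta[3:]
    if sigma2 <= 0 or d11 < 0 or d22 < 0 or d11 * d22 - d12 * d12 < 0:
        return np.inf
    gamma = np.array([[d11, d12], [d12, d22]]) / sigma2
    stats = _SuffStats(data)
    nll = 0.0
    for G, zty, yty, n_i in zip(stats.G, stats.zty, stats.yty, stats.sizes):
        M = np.eye(2) + G @ gamma
        det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        if det <= 0:
            return np.inf
        W = gamma @ np.linalg.inv(M)
        u = zty - G @ beta
        rtr = yty - 2.0 * beta @ zty + beta @ G @ beta
        quad = rtr - u @ W @ u
        nll += 0.5 * (n_i * np.log(2.0 * np.pi * sigma2) + np.log(det) + quad / sigma2)
    return float(nll)


def simulate_mixed(
    beta: tuple[float, float] = (1.0, 0.5),
    D: np.ndarray | None = None,
    sigma2: float = 1.0,
    n_clusters: int = 30,
    size_range: tuple[int, int] = (40, 100),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Unbalanced clustered data with correlated random intercept + slope.

    Emulates experience-sampling style longitudinal data: every cluster
    (subject) contributes a different number of observations, drawn
    uniformly from ``size_range``, with a continuous within-cluster
    predictor x ~ N(0, 1).
    """
    if D is None:
        D = np.array([[0.5, 0.1], [0.1, 0.2]])
    D = np.asarray(D, dtype=float)
    if sigma2 <= 0:
        raise InvalidParameterError("sigma2 must be positive")
    if np.any(np.linalg.eigvalsh(D) < -1e-12):
        raise InvalidParameterError("D must be positive semidefinite")
    rng = np.random.default_rng(seed)
    b = np.asarray(beta, dtype=float)
    frames = []
    for cid in range(1, n_clusters + 1):
        n_i = int(rng.integers(size_range[0], size_range[1] + 1))
        x = rng.standard_normal(n_i)
        bi = rng.multivariate_normal(np.zeros(2), D)
        y = (b[0] + bi[0]) + (b[1] + bi[1]) * x + np.sqrt(sigma2) * rng.standard_normal(n_i)
        frames.append(pd.DataFrame({"cluster_id": cid, "x": x, "y": y}))
    return pd.concat(frames, ignore_index=True)
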