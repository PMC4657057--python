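import numpy as np
import pytest

import fpboot as fb


@pytest.fixture(scope="session")
def exp_model():
    return fb.get_model("exponential")


@pytest.fixture(scope="session")
def reg_model():
    return fb.get_model("regression")


@pytest.fixture(scope="session")
def mixed_model():
    return fb.get_model("mixed")


@pytest.fixture(scope="session")
def gev_model():
    return fb.get_model("gev")


@pytest.fixture(scope="session")
def exp_data():
    """Original exponential sample: mean 2, n=100."""
    return fb.simulate_exponential(theta=2.0, n=100, seed=11)


@pytest.fixture(scope="session")
def reg_data():
    return fb.simulate_regression(beta=2.0, n=100, seed=11)


@pytest.fixture(scope="session")
def mixed_small():
    """Small clustered set where brute-force joint fits are cheap."""
    return fb.simulate_mixed(n_clusters=5, size_range=(8, 8), seed=11)


@pytest.fixture(scope="session")
def gev_data():
    return fb.simulate_gev(n=300, seed=11)


@pytest.fixture(scope="session")
def joint_mixed_fit():
    """Brute-force joint fit of the 6-parameter marginal likelihood.

    Independent oracle: scipy's Nelder-Mead on (beta, sigma2, chol(D)),
    restarted from its own solution until no further improvement.  The
    Cholesky parametrization of D keeps the search smooth when the MLE
    sits near the positive-semidefinite boundary.  Returns the optimum in
    natural coordinates (beta0, beta1, sigma2, D11, D12, D22).
    """
    from scipy.optimize import minimize

    from fpboot.models.mixed import full_negloglik

    def to_eta(z):
        b0, b1, s2, l11, l21, l22 = z
        return np.array(
            [b0, b1, s2, l11 * l11, l11 * l21, l21 * l21 + l22 * l22]
        )

    def fit_joint(data, start_eta):
        e = np.asarray(start_eta, dtype=float)
        l11 = np.sqrt(max(e[3], 1e-4))
        l21 = e[4] / l11
        l22 = np.sqrt(max(e[5] - l21 * l21, 1e-4))
        x = np.array([e[0], e[1], e[2], l11, l21, l22])
        best = np.inf
        for _ in range(8):
            r = minimize(
                lambda z: full_negloglik(to_eta(z), data),
                x,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-10, "maxfev": 40000},
            )
            x = r.x
            if best - r.fun < 1e-12:
                break
            best = r.fun
        return to_eta(x), best

    return fit_joint


@pytest.fixture(scope="session")
def hessian():
    """Central-difference Hessian helper for standard-error computations."""
    return central_hessian


def central_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian; shared by parameter-recovery tests."""
    x = np.asarray(x, dtype=float)
    d = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for j in range(d):
        ej = np.zeros(d)
        ej[j] = h[j]
        H[j, j] = (f(x + ej) - 2.0 * f0 + f(x - ej)) / h[j] ** 2
        for k in range(j + 1, d):
            ek = np.zeros(d)
            ek[k] = h[k]
            H[j, k] = H[k, j] = (
                f(x + ej + ek) - f(x + ej - ek) - f(x - ej + ek) + f(x - ej - ek)
            ) / (4.0 * h[j] * h[k])
    return H
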