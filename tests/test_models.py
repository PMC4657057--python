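"""Likelihoods, oracles, resamplers and generators of the four models."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import fpboot as fb
from fpboot.models import InvalidParameterError
from fpboot.models.gev import gev_negloglik
from fpboot.models.mixed import full_negloglik


class TestExponential:
    def test_closed_form_values(self, exp_model):
        d = pd.DataFrame({"x": [1.0, 1.0]})
        assert exp_model.loglik(np.array([1.0]), d) == pytest.approx(-2.0)
        d1 = pd.DataFrame({"x": [2.0]})
        assert exp_model.loglik(np.array([2.0]), d1) == pytest.approx(-np.log(2) - 1)

    def test_oracle_is_sample_mean_and_maximizes(self, exp_model):
        d = pd.DataFrame({"x": [1.0, 3.0]})
        assert exp_model.oracle(d)[0] == pytest.approx(2.0)
        r = minimize_scalar(
            lambda t: -exp_model.loglik(np.array([t]), d), bounds=(0.1, 20), method="bounded"
        )
        assert r.x == pytest.approx(2.0, abs=1e-4)

    def test_invalid_parameter_signals(self, exp_model, exp_data):
        with pytest.raises(InvalidParameterError):
            exp_model.loglik(np.array([-1.0]), exp_data)
        assert exp_model.make_objective(exp_data)(np.array([-1.0])) == np.inf


class TestRegression:
    def test_closed_form_values(self, reg_model):
        d = pd.DataFrame({"x": [1.0], "y": [1.0]})
        c = -0.5 * np.log(2 * np.pi)
        assert reg_model.loglik(np.array([1.0]), d) == pytest.approx(c)
        assert reg_model.loglik(np.array([0.0]), d) == pytest.approx(c - 0.5)

    def test_oracle(self, reg_model):
        d = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 4.0]})
        assert reg_model.oracle(d)[0] == pytest.approx(2.0)

    def test_degenerate_design_signals(self, reg_model):
        d = pd.DataFrame({"x": [0.0, 0.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            reg_model.oracle(d)


class TestMixed:
    def test_dimension_is_three(self, mixed_model):
        assert mixed_model.dim == 3

    def test_chol_zero_collapses_to_ols(self, mixed_model, mixed_small):
        y = mixed_small["y"].to_numpy()
        A = np.column_stack([np.ones(len(y)), mixed_small["x"].to_numpy()])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        s2 = ((y - A @ beta) ** 2).sum() / len(y)
        ols_nll = 0.5 * (len(y) * np.log(2 * np.pi * s2) + len(y))
        nll = mixed_model.make_objective(mixed_small)(np.zeros(3))
        assert nll == pytest.approx(ols_nll, rel=1e-12)

    def test_cholesky_sign_symmetry(self, mixed_model, mixed_small):
        f = mixed_model.make_objective(mixed_small)
        c = np.array([0.4, -0.15, 0.3])
        assert f(c) == pytest.approx(f(-c), rel=1e-12)
        assert f(c) == pytest.approx(f(np.array([-0.4, 0.15, 0.3])), rel=1e-12)

    def test_profiled_matches_full_likelihood_value(self, mixed_model, mixed_small):
        theta0, _ = fb.fit_original(mixed_model, mixed_small)
        p = mixed_model.recover(theta0, mixed_small)
        eta = np.concatenate([p.beta, [p.sigma2], p.d_entries])
        prof = mixed_model.make_objective(mixed_small)(theta0)
        assert full_negloglik(eta, mixed_small) == pytest.approx(prof, abs=1e-10)

    def test_profiled_optimum_matches_joint_optimum(
        self, mixed_model, mixed_small, joint_mixed_fit
    ):
        """Profiling beta and sigma2 out must not move the optimum."""
        theta0, _ = fb.fit_original(mixed_model, mixed_small)
        p = mixed_model.recover(theta0, mixed_small)
        eta = np.concatenate([p.beta, [p.sigma2], p.d_entries])
        x, fun = joint_mixed_fit(mixed_small, [1.0, 0.5, 1.0, 0.5, 0.1, 0.2])
        assert abs(fun - full_negloglik(eta, mixed_small)) < 1e-6
        assert np.max(np.abs(x - eta)) < 1e-3

    def test_recover_identities(self, mixed_model, mixed_small):
        p0 = mixed_model.recover(np.zeros(3), mixed_small)
        assert np.allclose(p0.D, 0.0)
        p1 = mixed_model.recover(np.array([1.0, 0.0, 1.0]), mixed_small)
        assert np.allclose(p1.D, p1.sigma2 * np.eye(2))

    def test_case_bootstrap_preserves_clusters(self, mixed_model, mixed_small):
        rng = np.random.default_rng(5)
        rb = mixed_model.resample(mixed_small, rng)
        assert rb["cluster_id"].nunique() == mixed_small["cluster_id"].nunique()
        # every resampled cluster is a copy of some original cluster's rows
        orig = {
            cid: np.sort(g["y"].to_numpy())
            for cid, g in mixed_small.groupby("cluster_id")
        }
        for _, g in rb.groupby("cluster_id"):
            ys = np.sort(g["y"].to_numpy())
            assert any(
                len(v) == len(ys) and np.allclose(v, ys) for v in orig.values()
            )


class TestGev:
    def test_dimension_is_four(self, gev_model):
        assert gev_model.dim == 4

    def test_support_violation_is_infinite(self):
        x, t = np.array([-1.5]), np.array([0.0])
        assert gev_negloglik(np.array([1.0, 1.0, 0.0, 0.0]), x, t) == np.inf

    def test_gumbel_value_at_location(self):
        x, t = np.array([0.0]), np.array([0.0])
        assert gev_negloglik(np.array([0.0, 1.0, 0.0, 0.0]), x, t) == pytest.approx(1.0)

    def test_continuity_at_shape_boundary(self, gev_data):
        x = gev_data["x"].to_numpy()
        t = gev_data["t"].to_numpy()
        base = np.array([0.0, 1.2, 9.5, 0.4])
        v0 = gev_negloglik(base, x, t)
        for xi in (1e-10, -1e-10):
            th = base.copy()
            th[0] = xi
            assert gev_negloglik(th, x, t) == pytest.approx(v0, abs=1e-6)

    def test_location_shift_invariance(self, gev_data):
        x = gev_data["x"].to_numpy()
        t = gev_data["t"].to_numpy()
        th = np.array([0.15, 1.1, 9.0, 0.3])
        v = gev_negloglik(th, x, t)
        delta = 3.7
        shifted = th.copy()
        shifted[2] += delta
        assert gev_negloglik(shifted, x + delta, t) == pytest.approx(v, rel=1e-12)

    def test_naive_start_properties(self, gev_model):
        d = fb.simulate_gev(fb.GevParams(0.0, 1.0, 5.0, 2.0), n=400, seed=3)
        th = gev_model.naive_start(d)
        assert -0.5 <= th[0] <= 0.5
        assert th[1] > 0
        # trend recovered by least squares
        A = np.column_stack([np.ones(len(d)), d["t"]])
        coef, *_ = np.linalg.lstsq(A, d["x"].to_numpy(), rcond=None)
        assert th[3] == pytest.approx(coef[1])
        # constant shift moves only the intercept
        d2 = d.copy()
        d2["x"] += 4.0
        th2 = gev_model.naive_start(d2)
        assert th2[2] == pytest.approx(th[2] + 4.0)
        assert np.allclose(th2[[0, 1, 3]], th[[0, 1, 3]])


class TestResampleAndSimulate:
    def test_one_row_resample_repeats_it(self, exp_model):
        d = pd.DataFrame({"x": [3.3]})
        rb = exp_model.resample(d, np.random.default_rng(0))
        assert (rb["x"] == 3.3).all() and len(rb) == 1

    def test_resample_deterministic_given_seed(self, exp_model, exp_data):
        a = exp_model.resample(exp_data, np.random.default_rng(42))
        b = exp_model.resample(exp_data, np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)

    def test_exponential_generator_mean(self):
        d = fb.simulate_exponential(theta=2.0, n=100, seed=7)
        assert abs(d["x"].mean() - 2.0) < 2 * 2.0 / np.sqrt(100)

    def test_mixed_generator_zero_d_residual_variance(self):
        d = fb.simulate_mixed(D=np.zeros((2, 2)), sigma2=1.0, n_clusters=40, seed=7)
        resid_vars = []
        for _, g in d.groupby("cluster_id"):
            A = np.column_stack([np.ones(len(g)), g["x"]])
            beta, *_ = np.linalg.lstsq(A, g["y"].to_numpy(), rcond=None)
            resid_vars.append(((g["y"].to_numpy() - A @ beta) ** 2).mean())
        assert np.mean(resid_vars) == pytest.approx(1.0, abs=0.1)

    def test_invalid_generator_params_signal(self):
        with pytest.raises(InvalidParameterError):
            fb.simulate_exponential(theta=-1.0)
        with pytest.raises(InvalidParameterError):
            fb.simulate_mixed(sigma2=-1.0)
        with pytest.raises(InvalidParameterError):
            fb.simulate_mixed(D=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(InvalidParameterError):
            fb.simulate_gev(fb.GevParams(0.1, -1.0, 0.0, 0.0))

    def test_simulate_dispatch(self):
        d = fb.simulate("exponential", seed=1, theta=3.0, n=10)
        assert list(d.columns) == ["x"] and len(d) == 10
        with pytest.raises(KeyError):
            fb.simulate("nope")


def test_every_oracle_maximizes_its_loglik(exp_model, reg_model):
    """Perturbing a closed-form optimum never increases the log-likelihood."""
    rng = np.random.default_rng(123)
    for _ in range(50):
        d = fb.simulate_exponential(theta=rng.uniform(0.5, 5), n=30, seed=int(rng.integers(1 << 31)))
        th = exp_model.oracle(d)
        base = exp_model.loglik(th, d)
        for delta in (-1e-3, 1e-3):
            assert exp_model.loglik(th + delta, d) <= base + 1e-12
    for _ in range(50):
        d = fb.simulate_regression(beta=rng.uniform(-2, 2), n=30, seed=int(rng.integers(1 << 31)))
        th = reg_model.oracle(d)
        base = reg_model.loglik(th, d)
        for delta in (-1e-3, 1e-3):
            assert reg_model.loglik(th + delta, d) <= base + 1e-12
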