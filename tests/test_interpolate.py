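"""LS-SVM interpolator: LOO identity, learning behavior, constraints."""

import numpy as np
import pytest

import fpboot as fb
from fpboot.fingerprints import Fingerprint
from fpboot.interpolate import (
    NotFittedError,
    PENALTY_GRID,
    TrainingPool,
    WIDTH_FACTORS,
    _lssvm_solve,
    fit,
    nearest_neighbor_predict,
)


def _pool_from_xy(X, Y, boundary=None):
    pool = TrainingPool()
    X = np.atleast_2d(X)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).reshape(len(X), -1))
    for i, (x, y) in enumerate(zip(X, Y)):
        flags = None if boundary is None else boundary[i]
        pool.add(Fingerprint(np.atleast_1d(x), 1, 2), y, i, flags)
    return pool


class TestClosedFormLoo:
    def test_matches_explicit_refit_on_size_12_pools(self):
        """alpha_i / (M^-1)_ii equals the refit-without-i residual."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + 0.1 * rng.normal(size=12)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        med = np.median(d2[np.triu_indices(12, 1)]) ** 0.5
        for wf in WIDTH_FACTORS:
            K = np.exp(-d2 / (2.0 * (wf * med) ** 2))
            for lam in PENALTY_GRID:
                _, _, loo = _lssvm_solve(K, y, lam)
                for i in range(12):
                    mask = np.ones(12, bool)
                    mask[i] = False
                    ai, bi, _ = _lssvm_solve(K[np.ix_(mask, mask)], y[mask], lam)
                    pred = K[i, mask] @ ai + bi
                    assert loo[i] == pytest.approx(y[i] - pred, abs=1e-8)


class TestFitPredict:
    def test_learns_exact_affine_relation(self, exp_model, exp_data):
        """On the exponential toy the fingerprint->optimum map is affine and
        interpolation should be nearly exact in range."""
        theta0 = np.array([2.0])
        n = len(exp_data)
        rng = np.random.default_rng(8)
        fps, opts = [], []
        for _ in range(40):
            rb = exp_model.resample(exp_data, rng)
            fps.append(fb.compute_fingerprint(exp_model, rb, theta0, g=1))
            opts.append(exp_model.oracle(rb))
        pool = TrainingPool()
        for i in range(12):
            pool.add(fps[i], opts[i], i)
        f = fit(pool, exp_model.lower, exp_model.upper)
        lo = min(fp.values[0] for fp in fps[:12])
        hi = max(fp.values[0] for fp in fps[:12])
        spread = max(o[0] for o in opts) - min(o[0] for o in opts)
        errs = []
        for fp, opt in zip(fps[12:], opts[12:]):
            if lo <= fp.values[0] <= hi:  # in-range queries only
                pred, _ = f.predict(fp)
                errs.append(abs(pred[0] - opt[0]))
        assert errs and np.median(errs) < 1e-3 * spread

    def test_training_fingerprint_predicts_its_own_optimum(self):
        X = np.linspace(-1, 1, 15)
        Y = 2.0 + 0.5 * X  # noiseless affine
        f = fit(_pool_from_xy(X[:, None], Y))
        i = 7
        pred, eps = f.predict(Fingerprint(np.array([X[i]]), 1, 2))
        assert abs(pred[0] - Y[i]) <= max(eps[0], 1e-6)

    def test_prediction_clipped_to_constraints(self):
        X = np.linspace(0, 1, 10)
        Y = -1.0 + 0.1 * X  # all targets below the lower bound 0
        f = fit(_pool_from_xy(X[:, None], Y), lower=np.array([0.0]))
        pred, _ = f.predict(Fingerprint(np.array([0.5]), 1, 2))
        assert pred[0] == 0.0

    def test_unconstrained_prediction_unchanged(self):
        X = np.linspace(0, 1, 10)
        Y = 3.0 + X
        f = fit(_pool_from_xy(X[:, None], Y))
        raw, _ = f.predict(Fingerprint(np.array([0.5]), 1, 2))
        fc = fit(_pool_from_xy(X[:, None], Y), lower=np.array([-np.inf]))
        clipped, _ = fc.predict(Fingerprint(np.array([0.5]), 1, 2))
        assert raw[0] == clipped[0]

    def test_standardization_absorbs_affine_input_rescaling(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 2))
        Y = X[:, 0] - 2 * X[:, 1] + 0.05 * rng.normal(size=25)
        f1 = fit(_pool_from_xy(X, Y))
        X2 = X.copy()
        X2[:, 0] = 100.0 * X2[:, 0] + 7.0  # affine rescale of one component
        f2 = fit(_pool_from_xy(X2, Y))
        q = np.array([0.3, -0.4])
        q2 = q.copy()
        q2[0] = 100.0 * q2[0] + 7.0
        p1, _ = f1.predict(Fingerprint(q, 1, 2))
        p2, _ = f2.predict(Fingerprint(q2, 1, 2))
        assert p1[0] == pytest.approx(p2[0], abs=1e-6)

    def test_boundary_couples_excluded_per_dimension(self):
        X = np.linspace(0, 1, 12)[:, None]
        Y = 1.0 + X.ravel()
        boundary = [np.array([i < 6]) for i in range(12)]
        # corrupt the flagged half: if they entered training, predictions would shift
        Yc = Y.copy()
        Yc[:6] = -99.0
        f = fit(_pool_from_xy(X, Yc, boundary))
        pred, _ = f.predict(Fingerprint(np.array([0.75]), 1, 2))
        assert pred[0] == pytest.approx(1.75, abs=0.05)

    def test_too_few_interior_couples_signals(self):
        X = np.array([[0.0], [1.0], [2.0]])
        Y = np.array([1.0, 2.0, 3.0])
        boundary = [np.array([True]), np.array([True]), np.array([False])]
        with pytest.raises(NotFittedError):
            fit(_pool_from_xy(X, Y, boundary))
        with pytest.raises(NotFittedError):
            fit(_pool_from_xy(X[:1], Y[:1]))

    def test_learning_curve_improves_with_training_size(self, exp_model, exp_data):
        """Median prediction error decreases through pool sizes 5 -> 20 -> 80."""
        theta0 = np.array([2.0])
        med_errs = {5: [], 20: [], 80: []}
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            fps, opts = [], []
            for _ in range(100):
                rb = exp_model.resample(exp_data, rng)
                fps.append(fb.compute_fingerprint(exp_model, rb, theta0, g=1))
                opts.append(exp_model.oracle(rb))
            for size in med_errs:
                pool = TrainingPool()
                for i in range(size):
                    pool.add(fps[i], opts[i], i)
                f = fit(pool)
                lo = min(fp.values[0] for fp in fps[:size])
                hi = max(fp.values[0] for fp in fps[:size])
                errs = [
                    abs(f.predict(fp)[0][0] - opt[0])
                    for fp, opt in zip(fps[size:], opts[size:])
                    if lo <= fp.values[0] <= hi
                ]
                med_errs[size].append(np.median(errs))
        m5, m20, m80 = (np.median(med_errs[s]) for s in (5, 20, 80))
        assert m20 < m5 and m80 < m5
        # beyond ~20 couples the error saturates at the finite-difference
        # stencil floor; require both larger sizes to sit at that floor
        assert m80 < 1e-4 and m20 < 1e-4


class TestNearestNeighbor:
    def test_single_couple(self):
        pool = _pool_from_xy(np.array([[1.0]]), np.array([4.0]))
        assert nearest_neighbor_predict(pool, Fingerprint(np.array([9.0]), 1, 2))[0] == 4.0

    def test_exact_match_returns_stored_optimum(self):
        pool = _pool_from_xy(np.array([[0.0], [1.0], [2.0]]), np.array([5.0, 6.0, 7.0]))
        got = nearest_neighbor_predict(pool, Fingerprint(np.array([1.0]), 1, 2))
        assert got[0] == 6.0

    def test_tie_broken_by_lowest_index(self):
        pool = TrainingPool()
        pool.add(Fingerprint(np.array([2.0]), 1, 2), np.array([10.0]), 3)
        pool.add(Fingerprint(np.array([0.0]), 1, 2), np.array([20.0]), 1)
        # query at 1.0 is equidistant; index 1 wins
        got = nearest_neighbor_predict(pool, Fingerprint(np.array([1.0]), 1, 2))
        assert got[0] == 20.0

    def test_empty_pool_signals(self):
        with pytest.raises(ValueError):
            nearest_neighbor_predict(TrainingPool(), Fingerprint(np.array([0.0]), 1, 2))
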