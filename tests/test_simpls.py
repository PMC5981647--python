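"""SIMPLS calibration against independent oracles and its algebraic contracts.

Oracles used here, each implemented independently of `pamix.simpls`:

* minimum-norm ordinary least squares via the pseudoinverse — PLS with as
  many factors as the rank of the centered predictors must reproduce it;
* a NIPALS PLS1 implementation — for a univariate response, NIPALS and
  SIMPLS are algebraically equivalent;
* a plain textbook transcription of the SIMPLS recursion using an
  eigendecomposition of the small cross-product Gram matrix (a different
  numerical route from the production code's SVD);
* scikit-learn's NIPALS-based PLSRegression for univariate responses.
"""

import warnings

import numpy as np
import pytest

from pamix import GasMixture, fit_simpls, normalize_by_power, pa_signal, predict, variance_explained
from pamix.simpls import PLSModel


# --------------------------------------------------------------------------
# independent oracles


def ols_minimum_norm(X, Y, x):
    """Minimum-norm least squares on centered data."""
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    B = np.linalg.pinv(X - xm) @ (Y - ym)
    return ym + (np.atleast_2d(x) - xm) @ B


def nipals_pls1(X, y, n_factors):
    """Classic NIPALS PLS1 for a single response column."""
    xm, ym = X.mean(axis=0), y.mean()
    E, f = X - xm, y - ym
    W, P, Q = [], [], []
    for _ in range(n_factors):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        q = (f @ t) / tt
        E = E - np.outer(t, p)
        f = f - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    B = W @ np.linalg.solve(P.T @ W, Q)

    def predict_fn(x):
        return ym + (np.atleast_2d(x) - xm) @ B

    return predict_fn


def simpls_textbook(X, Y, n_factors):
    """Direct transcription of the SIMPLS recursion (de Jong, 1993).

    Uses eigh on the m x m Gram matrix of the cross-product instead of an
    SVD, and makes no sign choice: predictions are sign-invariant.
    """
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xm, Y - ym
    S = X0.T @ Y0
    R, Q, V = [], [], []
    for _ in range(n_factors):
        vals, vecs = np.linalg.eigh(S.T @ S)
        q_dom = vecs[:, -1]
        r = S @ q_dom
        t = X0 @ r
        nt = np.linalg.norm(t)
        r, t = r / nt, t / nt
        p = X0.T @ t
        q = Y0.T @ t
        v = p.copy()
        for vj in V:
            v = v - vj * (vj @ p)
        v = v / np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R.append(r)
        Q.append(q)
        V.append(v)
    B = np.array(R).T @ np.array(Q)

    def predict_fn(x):
        return ym + (np.atleast_2d(x) - xm) @ B

    return predict_fn


def random_problem(rng, n=8, p=5, m=2):
    X = rng.normal(size=(n, p))
    Y = rng.normal(size=(n, m))
    return X, Y


# --------------------------------------------------------------------------


class TestFitContracts:
    def test_exact_interpolation_limit(self):
        """Y exactly linear in full-rank X is reproduced at n_factors = rank."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        B_true = rng.normal(size=(5, 2))
        Y = X @ B_true
        model = fit_simpls(X, Y, n_factors=5)
        res = predict(model, X)
        assert np.max(np.abs(res.raw - Y)) / np.max(np.abs(Y)) < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_full_rank_matches_minimum_norm_ols(self, seed):
        rng = np.random.default_rng(100 + seed)
        X, Y = random_problem(rng, n=12, p=6, m=3)
        x_new = rng.normal(size=(4, 6))
        model = fit_simpls(X, Y, n_factors=6)
        np.testing.assert_allclose(
            predict(model, x_new).raw, ols_minimum_norm(X, Y, x_new), atol=1e-6
        )

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n_factors", [1, 2, 3, 4])
    def test_univariate_response_matches_nipals_pls1(self, seed, n_factors):
        rng = np.random.default_rng(200 + seed)
        X = rng.normal(size=(15, 7))
        y = rng.normal(size=15)
        x_new = rng.normal(size=(5, 7))
        model = fit_simpls(X, y, n_factors=n_factors)
        oracle = nipals_pls1(X, y, n_factors)
        np.testing.assert_allclose(
            predict(model, x_new).raw.ravel(), oracle(x_new).ravel(), atol=1e-8
        )

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("n_factors", [1, 2, 3, 4])
    def test_matches_textbook_simpls_on_small_multivariate_problems(self, seed, n_factors):
        rng = np.random.default_rng(300 + seed)
        X, Y = random_problem(rng, n=8, p=5, m=2)
        x_new = rng.normal(size=(3, 5))
        model = fit_simpls(X, Y, n_factors=n_factors)
        oracle = simpls_textbook(X, Y, n_factors)
        np.testing.assert_allclose(predict(model, x_new).raw, oracle(x_new), atol=1e-6)

    def test_univariate_matches_sklearn_pls(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        x_new = rng.normal(size=(6, 10))
        for a in (1, 2, 4):
            ours = predict(fit_simpls(X, y, n_factors=a), x_new).raw.ravel()
            ref = sklearn.PLSRegression(n_components=a, scale=False).fit(X, y[:, None])
            np.testing.assert_allclose(ours, ref.predict(x_new).ravel(), atol=1e-8)

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(1)
        X, Y = random_problem(rng, n=20, p=8, m=3)
        a = fit_simpls(X, Y, n_factors=4)
        b = fit_simpls(X, Y, n_factors=4)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(2)
        X, Y = random_problem(rng, n=30, p=12, m=3)
        model = fit_simpls(X, Y, n_factors=5)
        T = (X - model.x_mean) @ model.weights
        G = T.T @ T
        np.testing.assert_allclose(G, np.diag(np.diag(G)), atol=1e-8)

    def test_shift_invariance(self):
        """Adding a constant to every X entry changes no prediction."""
        rng = np.random.default_rng(3)
        X, Y = random_problem(rng, n=16, p=6, m=2)
        x_new = rng.normal(size=(3, 6))
        a = predict(fit_simpls(X, Y, n_factors=3), x_new).raw
        b = predict(fit_simpls(X + 5.0, Y, n_factors=3), x_new + 5.0).raw
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(4)
        X = np.ones((10, 4))
        Y = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="variance"):
            fit_simpls(X, Y, n_factors=2)
        with pytest.raises(ValueError, match="n_factors"):
            fit_simpls(rng.normal(size=(10, 4)), Y, n_factors=5)
        with pytest.raises(ValueError, match="samples"):
            fit_simpls(rng.normal(size=(4, 10)), Y[:4], n_factors=4)

    def test_rank_deficiency_stops_early_with_warning(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(20, 2))
        X = base @ rng.normal(size=(2, 6))  # rank 2
        Y = base @ rng.normal(size=(2, 3))
        with pytest.warns(UserWarning, match="factors"):
            model = fit_simpls(X, Y, n_factors=5)
        assert model.n_factors == 2


class TestPredict:
    def test_predicting_the_mean_spectrum_returns_mean_concentrations(self):
        rng = np.random.default_rng(6)
        X, Y = random_problem(rng, n=20, p=7, m=2)
        model = fit_simpls(X, Y, n_factors=3)
        np.testing.assert_allclose(predict(model, model.x_mean).raw, model.y_mean, atol=1e-10)

    def test_noiseless_two_component_mixture_recovery(self, library, grid, instrument, clean_ref):
        model = fit_simpls(
            clean_ref.X, clean_ref.Y, n_factors=6, component_names=clean_ref.component_names
        )
        mix = GasMixture({"2-butanone": 30.0, "1-propanol": 70.0})
        s = normalize_by_power(pa_signal(instrument, library, mix, grid), instrument)
        res = predict(model, s.signal)
        expected = [30.0, 70.0, 0.0, 0.0, 0.0, 0.0]
        np.testing.assert_allclose(res.raw, expected, atol=1e-6)

    def test_noiseless_random_mixture_recovery(self, library, grid, instrument, clean_ref):
        """100 random in-range mixtures recovered to <= 1e-6 ppm max error."""
        model = fit_simpls(clean_ref.X, clean_ref.Y, n_factors=6)
        rng = np.random.default_rng(17)
        names = clean_ref.component_names
        truths = rng.uniform(0.0, 100.0, size=(100, 6))
        spectra = np.vstack([
            normalize_by_power(
                pa_signal(instrument, library, GasMixture(dict(zip(names, row))), grid),
                instrument,
            ).signal
            for row in truths
        ])
        res = predict(model, spectra)
        assert np.max(np.abs(res.raw - truths)) <= 1e-6

    def test_negative_prediction_clamps_to_zero(self):
        rng = np.random.default_rng(8)
        X, Y = random_problem(rng, n=20, p=7, m=2)
        model = fit_simpls(X, Y, n_factors=3)
        res = predict(model, rng.normal(size=7) * 10)
        np.testing.assert_array_equal(res.clamped, np.maximum(res.raw, 0.0))
        assert np.all(res.clamped >= 0.0)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        X, Y = random_problem(rng)
        model = fit_simpls(X, Y, n_factors=2)
        with pytest.raises(ValueError, match="length"):
            predict(model, np.ones(4))


class TestVarianceExplained:
    def test_noiseless_full_rank_explains_all_y_variance(self, clean_ref):
        model = fit_simpls(clean_ref.X, clean_ref.Y, n_factors=6)
        v = variance_explained(model)
        assert v["y_cumulative"][-1] == pytest.approx(1.0, abs=1e-10)

    def test_cumulative_fractions_nondecreasing_and_bounded(self, noisy_ref):
        model = fit_simpls(noisy_ref.X, noisy_ref.Y, n_factors=6)
        v = variance_explained(model)
        for key in ("x_cumulative", "y_cumulative"):
            assert np.all(np.diff(v[key]) >= -1e-12)
            assert v[key][-1] <= 1.0 + 1e-12

    def test_noisy_library_retains_most_y_variance(self, noisy_ref):
        """At 10% per-row noise six factors still capture most of the
        concentration variance (high-90s X-variance, near 0.9 Y-variance
        under this deliberately hard synthetic library)."""
        model = fit_simpls(noisy_ref.X, noisy_ref.Y, n_factors=6)
        v = variance_explained(model)
        assert v["x_cumulative"][-1] > 0.90
        assert v["y_cumulative"][-1] > 0.85


class TestSerialization:
    def test_json_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(10)
        X, Y = random_problem(rng, n=20, p=7, m=2)
        model = fit_simpls(X, Y, n_factors=3, component_names=("a", "b"))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = PLSModel.load(path)
        np.testing.assert_array_equal(model.coefficients, loaded.coefficients)
        np.testing.assert_array_equal(model.x_mean, loaded.x_mean)
        assert loaded.component_names == ("a", "b")
        x = rng.normal(size=7)
        np.testing.assert_array_equal(predict(model, x).raw, predict(loaded, x).raw)

    def test_wrong_container_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="container"):
            PLSModel.load(p)
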