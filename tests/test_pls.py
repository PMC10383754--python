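import numpy as np
import pytest

from softsense.pls import (CVCurve, RankExhaustedError, cross_validate, fit_pls,
                           nipals_fit, predict, r2, rmse, select_components,
                           standardize, PLSModel)


def oracle_nipals_coefficients(Xs, ys, A, tol=1e-12, max_iter=200):
    """Straight transcription of the textbook NIPALS recipe (independent of
    the implementation under test): u from the response, alternating
    weight/score updates to convergence, rank-one deflation, then
    B = W (P'W)^-1 Q'."""
    X = np.array(Xs, float)
    Y = np.array(ys, float).reshape(len(Xs), -1)
    W, P, Q = [], [], []
    for _ in range(A):
        u = Y[:, 0].copy()
        t_prev = None
        for _ in range(max_iter):
            w = X.T @ u / (u @ u)
            w = w / np.linalg.norm(w)
            t = X @ w
            q = Y.T @ t / (t @ t)
            u = Y @ q / (q @ q)
            if t_prev is not None and np.linalg.norm(t - t_prev) <= tol * np.linalg.norm(t_prev):
                break
            t_prev = t
        p = X.T @ t / (t @ t)
        q = Y.T @ t / (t @ t)
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, q)
        W.append(w), P.append(p), Q.append(q)
    W = np.column_stack(W)
    P = np.column_stack(P)
    Q = np.column_stack(Q)  # (p, A)
    return W @ np.linalg.solve(P.T @ W, Q.T)


class TestStandardize:
    def test_direct_column(self):
        Xs, Ys, _ = standardize(np.array([[2.0], [4.0], [6.0]]), [1.0, 2.0, 4.0])
        np.testing.assert_allclose(Xs.ravel(), [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(20, 4)), rng.normal(size=20)
        Xs, Ys, _ = standardize(X, y)
        Xs2, Ys2, _ = standardize(Xs, Ys)
        np.testing.assert_allclose(Xs2, Xs, atol=1e-12)
        np.testing.assert_allclose(Ys2, Ys, atol=1e-12)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="response"):
            standardize(np.random.default_rng(0).normal(size=(5, 2)), np.ones(5))

    def test_zero_variance_predictor_masked(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        X[:, 1] = 4.0
        Xs, _, constants = standardize(X, rng.normal(size=10))
        np.testing.assert_array_equal(constants["mask"], [0, 2])
        assert Xs.shape[1] == 2


class TestNipals:
    def test_univariate_proportionality(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 1))
        y = 3.0 * x[:, 0]
        model = fit_pls(x, y, A=1)
        np.testing.assert_allclose(predict(model, x), y, atol=1e-10)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        Xs, Ys, c = standardize(X, y)
        model = nipals_fit(Xs, Ys, 5, constants=c)
        beta = np.linalg.lstsq(Xs, Ys, rcond=None)[0]
        np.testing.assert_allclose(Xs @ model.B, Xs @ beta, atol=1e-8)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            X = rng.normal(size=(8, 5))
            y = rng.normal(size=8)
            Xs, Ys, c = standardize(X, y)
            model = nipals_fit(Xs, Ys, 3, constants=c)
            B_oracle = oracle_nipals_coefficients(Xs, Ys, 3)
            np.testing.assert_allclose(model.B, B_oracle, atol=1e-8)

    def test_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8) + 0.2 * rng.normal(size=25)
        ours = predict(fit_pls(X, y, A=4), X)
        theirs = sklearn.PLSRegression(n_components=4, scale=True).fit(X, y)
        np.testing.assert_allclose(ours, theirs.predict(X).ravel(), atol=1e-6)

    def test_scores_orthogonal_and_deflation_exhausts(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        Xs, Ys, c = standardize(X, y)
        model = nipals_fit(Xs, Ys, 4, constants=c)
        G = model.T.T @ model.T
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8
        residual = Xs - model.T @ model.P.T
        assert np.linalg.norm(residual) < 1e-8

    def test_pls1_single_inner_pass(self):
        # for one response the converged weight is reached after one pass
        rng = np.random.default_rng(7)
        Xs, Ys, _ = standardize(rng.normal(size=(15, 6)), rng.normal(size=15))
        u = Ys[:, 0]
        w = Xs.T @ u / (u @ u)
        w /= np.linalg.norm(w)
        model = nipals_fit(Xs, Ys, 1)
        np.testing.assert_allclose(np.abs(model.W[:, 0]), np.abs(w), atol=1e-12)

    def test_noiseless_recovery_at_full_rank(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 6))
        b = rng.normal(size=6)
        model = fit_pls(X, X @ b, A=6)
        np.testing.assert_allclose(predict(model, X), X @ b, atol=1e-6)

    def test_rank_exhaustion_reports_achieved(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(20, 2))
        X = np.hstack([base, base @ rng.normal(size=(2, 3))])  # rank 2
        Xs, Ys, c = standardize(X, rng.normal(size=20))
        with pytest.raises(RankExhaustedError) as err:
            nipals_fit(Xs, Ys, 5, constants=c)
        assert 1 <= err.value.achieved < 5

    def test_weight_columns_unit_norm(self):
        rng = np.random.default_rng(10)
        model = fit_pls(rng.normal(size=(20, 6)), rng.normal(size=20), A=3)
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-12)


class TestPredict:
    def test_training_fit_beats_mean_model(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=30)
        model = fit_pls(X, y, A=3)
        assert rmse(y, predict(model, X)) <= rmse(y, np.full_like(y, y.mean()))

    def test_mean_row_predicts_mean_response(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        model = fit_pls(X, y, A=2)
        pred = predict(model, X.mean(axis=0, keepdims=True))
        assert pred[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_orthogonal_perturbation_leaves_prediction_unchanged(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        model = fit_pls(X, y, A=2)
        # perturb along the orthogonal complement of span(W), standardised scale
        q, _ = np.linalg.qr(model.W)
        delta_s = rng.normal(size=6)
        delta_s -= q @ (q.T @ delta_s)
        row = X[:1] + (delta_s * model.x_scale)[None, :]
        np.testing.assert_allclose(predict(model, row), predict(model, X[:1]),
                                   atol=1e-8)

    def test_dimension_mismatch(self):
        model = fit_pls(np.random.default_rng(14).normal(size=(10, 4)),
                        np.arange(10.0), A=1)
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 7)))

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(15, 5))
        y = rng.normal(size=15)
        model = fit_pls(X, y, A=2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PLSModel.from_json(path)
        np.testing.assert_allclose(predict(back, X), predict(model, X), atol=1e-12)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0.0 and r2(y, y) == 1.0

    def test_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_computed_rmse(self):
        assert rmse([0, 1, 2], [0, 1, 3]) == pytest.approx(np.sqrt(1 / 3))

    def test_errors(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            r2([1.0, 1.0], [1.0, 2.0])


class TestCrossValidation:
    def test_loo_deterministic(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        a = cross_validate(X, y, a_max=2, folds=6, scheme="random", seed=1)
        b = cross_validate(X, y, a_max=2, folds=6, scheme="random", seed=999)
        np.testing.assert_allclose(a.rmsecv, b.rmsecv)

    def test_pure_noise_overfits_on_average(self):
        curves = []
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            X = rng.normal(size=(40, 20))
            y = rng.normal(size=40)
            curves.append(cross_validate(X, y, a_max=8, folds=5,
                                         scheme="random", seed=s).rmsecv)
        avg = np.mean(curves, axis=0)
        assert np.all(np.diff(avg[1:]) >= -1e-9)

    def test_four_latent_directions_selected(self):
        # staircase design: four orthogonal directions of decreasing
        # X-variance, all equally predictive of y
        hits = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            n, m, k = 120, 30, 4
            T, _ = np.linalg.qr(rng.normal(size=(n, k)))
            P, _ = np.linalg.qr(rng.normal(size=(m, k)))
            X = (T * np.array([10, 6, 3.5, 2])) @ P.T + 0.02 * rng.normal(size=(n, m))
            y = T @ np.ones(k) + 0.04 * rng.normal(size=n)
            hits += cross_validate(X, y, a_max=8, folds=5, scheme="random",
                                   seed=s).chosen == 4
        assert hits >= 40  # >= 80% of 50 seeds

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        a = cross_validate(X, y, a_max=4, folds=5, scheme="random", seed=3)
        b = cross_validate(X, y, a_max=4, folds=5, scheme="random", seed=3)
        np.testing.assert_array_equal(a.rmsecv, b.rmsecv)

    def test_block_scheme_default_and_validation(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        curve = cross_validate(X, y, a_max=3, folds=4)
        assert curve.scheme == "blocks-4fold"
        with pytest.raises(ValueError):
            cross_validate(X, y, folds=1)


class TestSelectComponents:
    @pytest.mark.parametrize("curve,expected", [
        ((5, 2, 1.0, 0.99, 0.99), 3),
        ((1.0, 1.0, 1.0), 1),
        ((2.5,), 1),
    ])
    def test_parsimony_rule(self, curve, expected):
        assert select_components(np.array(curve), rel_tol=0.05) == expected

    def test_empty_curve(self):
        with pytest.raises(ValueError):
            select_components(np.array([]))
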