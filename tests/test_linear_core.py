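"""OLS, NIPALS-PLS and elastic-net engines against independent oracles."""

import numpy as np
import pytest

from enetbeta.datamodel import SpectraDataset, standardize
from enetbeta.linear_core import (
    EnetPenalty,
    default_penalty_grids,
    enet_grid_search,
    fit_enet,
    fit_ols,
    fit_pls,
    kkt_residual,
    predict,
)


def _soft(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def nipals_oracle(X, y, h):
    """Textbook NIPALS recursion, written independently of the package:
    weights from the covariance with the residual response, X deflation,
    regression vector W (P'W)^{-1} q."""
    X = X.copy()
    y = y.astype(float).copy()
    W, P, Q = [], [], []
    for _ in range(h):
        w = X.T @ y
        w = w / np.sqrt(w @ w)
        t = X @ w
        p_ = (X.T @ t) / (t @ t)
        q_ = (y @ t) / (t @ t)
        X = X - np.outer(t, p_)
        y = y - q_ * t
        W.append(w), P.append(p_), Q.append(q_)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    return W @ np.linalg.solve(P.T @ W, Q)


class TestOLS:
    def test_exact_interpolation(self, rng):
        X = rng.standard_normal((20, 4))
        beta = rng.standard_normal(4)
        model = fit_ols(X, X @ beta)
        np.testing.assert_allclose(model.beta_std, beta, atol=1e-10)

    def test_orthonormal_collapse(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((25, 5)))
        y = rng.standard_normal(25)
        model = fit_ols(Q, y)
        np.testing.assert_allclose(model.beta_std, Q.T @ y, atol=1e-10)

    def test_matches_normal_equations(self, rng):
        X = rng.standard_normal((5, 2))
        y = rng.standard_normal(5)
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit_ols(X, y).beta_std, expected, atol=1e-10)

    def test_residual_orthogonality(self, rng):
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        r = y - X @ fit_ols(X, y).beta_std
        np.testing.assert_allclose(X.T @ r, 0, atol=1e-9)

    def test_wide_matrix_needs_pinv_flag(self, rng):
        X = rng.standard_normal((4, 6))
        with pytest.raises(ValueError, match="n > p"):
            fit_ols(X, rng.standard_normal(4))
        model = fit_ols(X, rng.standard_normal(4), allow_pinv=True)
        assert model.p == 6


class TestPLS:
    def test_full_rank_equals_ols(self, rng):
        X = rng.standard_normal((25, 7))
        y = rng.standard_normal(25)
        mo = fit_ols(X, y)
        mp, _ = fit_pls(X, y, h=7)
        np.testing.assert_allclose(
            X @ mp.beta_std, X @ mo.beta_std, atol=1e-8
        )

    def test_single_channel_slope(self, rng):
        x = rng.standard_normal((15, 1))
        y = rng.standard_normal(15)
        slope = float(x[:, 0] @ y / (x[:, 0] @ x[:, 0]))
        model, _ = fit_pls(x, y, h=1)
        assert model.beta_std[0] == pytest.approx(slope)

    def test_matches_independent_nipals(self, rng):
        X = rng.standard_normal((20, 8))
        y = X @ rng.standard_normal(8) + 0.2 * rng.standard_normal(20)
        model, _ = fit_pls(X, y, h=3)
        np.testing.assert_allclose(model.beta_std, nipals_oracle(X, y, 3), atol=1e-8)

    def test_scores_orthogonal_and_rss_monotone(self, rng):
        X = rng.standard_normal((30, 10))
        y = X @ rng.standard_normal(10) + rng.standard_normal(30)
        rss_prev = np.inf
        for h in range(1, 6):
            model, dec = fit_pls(X, y, h)
            gram = dec.T.T @ dec.T
            np.testing.assert_allclose(
                gram - np.diag(np.diag(gram)), 0, atol=1e-8
            )
            rss = float(np.sum((y - X @ model.beta_std) ** 2))
            assert rss <= rss_prev + 1e-10
            rss_prev = rss

    def test_h_out_of_range(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="h must"):
            fit_pls(X, rng.standard_normal(10), h=4)

    def test_exhausted_response_warns_and_truncates(self, rng):
        # rank-2 X with y in its column space: two components exhaust y
        F = rng.standard_normal((20, 2))
        X = F @ rng.standard_normal((2, 5))
        y = X @ rng.standard_normal(5)
        with pytest.warns(UserWarning, match="stopped early"):
            model, dec = fit_pls(X, y, h=4)
        assert dec.h < 4
        np.testing.assert_allclose(X @ model.beta_std, y, atol=1e-7)


class TestEnet:
    def test_full_shrinkage_above_lambda_max(self, rng):
        X = rng.standard_normal((30, 8))
        y = rng.standard_normal(30)
        lam_max = 2.0 * np.abs(X.T @ y).max()
        model = fit_enet(X, y, EnetPenalty(lam_max * 1.01, 0.0))
        assert model.n_nonzero == 0

    def test_unpenalized_limit_equals_ols(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        m_enet = fit_enet(X, y, EnetPenalty(0.0, 0.0))
        m_ols = fit_ols(X, y)
        np.testing.assert_allclose(m_enet.beta_std, m_ols.beta_std, atol=1e-8)

    def test_orthonormal_closed_form(self, rng):
        n = 30
        Q, _ = np.linalg.qr(rng.standard_normal((n, 9)))
        y = rng.standard_normal(n)
        bols = Q.T @ y
        for lam1, lam2 in [(0.1, 0.0), (0.3, 0.7), (0.0, 2.0), (0.5, 5.0)]:
            model = fit_enet(Q, y, EnetPenalty(lam1, lam2))
            closed = _soft(bols, lam1 / 2.0) / (1.0 + lam2) * (1.0 + lam2 / n)
            np.testing.assert_allclose(model.beta_std, closed, atol=1e-8)

    def test_kkt_certificate(self, rng):
        X = rng.standard_normal((25, 40))
        y = rng.standard_normal(25)
        pen = EnetPenalty(3.0, 1.5)
        model = fit_enet(X, y, pen)
        assert kkt_residual(X, y, model.hyperparams["beta_naive"], pen) < 1e-6

    def test_sparsity_monotone_in_lambda1(self, rng):
        X = rng.standard_normal((40, 20))
        y = X @ (rng.standard_normal(20) * (rng.random(20) < 0.3)) + rng.standard_normal(40)
        lam_max = 2.0 * np.abs(X.T @ y).max()
        nnz = [
            fit_enet(X, y, EnetPenalty(f * lam_max, 2.0)).n_nonzero
            for f in (0.01, 0.05, 0.2, 0.5, 0.9)
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_grouping_effect_identical_columns(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, x, rng.standard_normal(50)])
        y = 2 * x + rng.standard_normal(50) * 0.1
        model = fit_enet(X, y, EnetPenalty(1.0, 5.0))
        assert model.beta_std[0] == pytest.approx(model.beta_std[1], abs=1e-6)

    def test_matches_sklearn_cross_check(self, rng):
        """Independent oracle: sklearn's ElasticNet under the penalty map
        alpha*l1_ratio = lam1/(2n), alpha*(1-l1_ratio) = lam2/n."""
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        n, p = 60, 30
        X = rng.standard_normal((n, p))
        y = X @ (rng.standard_normal(p) * (rng.random(p) < 0.3)) + rng.standard_normal(n)
        lam1, lam2 = 8.0, 4.0
        a_l1, a_l2 = lam1 / (2 * n), lam2 / n
        sk = sklearn_lm.ElasticNet(
            alpha=a_l1 + a_l2, l1_ratio=a_l1 / (a_l1 + a_l2),
            fit_intercept=False, tol=1e-12, max_iter=100_000,
        ).fit(X, y)
        model = fit_enet(X, y, EnetPenalty(lam1, lam2))
        np.testing.assert_allclose(
            model.hyperparams["beta_naive"], sk.coef_, atol=1e-6
        )


class TestPredict:
    def test_two_pathways_agree(self, small_dataset):
        std, stats = standardize(small_dataset)
        model = fit_ols(std.X, std.y, stats=stats)
        via_std = predict(model, small_dataset.X)
        via_raw = small_dataset.X @ model.beta_raw + model.intercept_raw
        np.testing.assert_allclose(via_std, via_raw, rtol=1e-10, atol=1e-10)

    def test_zero_beta_predicts_training_mean(self, small_dataset):
        std, stats = standardize(small_dataset)
        model = fit_enet(std.X, std.y, EnetPenalty(1e6, 0.0), stats=stats)
        np.testing.assert_allclose(
            predict(model, small_dataset.X), small_dataset.y.mean(), rtol=1e-10
        )

    def test_column_mismatch(self, small_dataset):
        std, stats = standardize(small_dataset)
        model = fit_ols(std.X, std.y, stats=stats)
        with pytest.raises(ValueError, match="columns"):
            predict(model, small_dataset.X[:, :3])


class TestGridSearch:
    def test_single_point_grid(self, small_dataset):
        pen, model = enet_grid_search(small_dataset, [1.0], [2.0], folds=3, seed=0)
        assert (pen.lambda1, pen.lambda2) == (1.0, 2.0)
        assert model.method == "ENET"

    def test_realizable_truth_reaches_small_cv_error(self, rng):
        X = rng.standard_normal((60, 10))
        y = X @ np.array([3.0, -2.0] + [0.0] * 8)  # noiseless sparse truth
        ds = SpectraDataset(X, y)
        from enetbeta.criteria import kfold_cv
        from enetbeta.datamodel import standardize as stdz

        pen, _ = enet_grid_search(ds, [1e-4, 1.0], [0.0, 1.0], folds=3, seed=1)

        def fitter(train):
            std, stats = stdz(train)
            return fit_enet(std.X, std.y, pen, stats=stats)

        assert kfold_cv(ds, fitter, 3, seed=1) < 0.05 * y.std(ddof=1)

    def test_matches_exhaustive_cv_oracle(self, rng):
        """Selected pair equals the argmin of independently recomputed CV
        scores over the full 3x3 grid."""
        from enetbeta.criteria import fold_indices, rmsep
        from enetbeta.datamodel import standardize as stdz

        X = rng.standard_normal((60, 30))
        beta = np.zeros(30)
        beta[:4] = [2, -3, 1.5, 2.5]
        y = X @ beta + rng.standard_normal(60)
        ds = SpectraDataset(X, y)
        g1, g2 = [0.5, 5.0, 50.0], [0.1, 1.0, 10.0]
        pen, _ = enet_grid_search(ds, g1, g2, folds=5, seed=3)

        def cv_score(l1, l2):
            folds = fold_indices(60, 5, seed=3)
            outs = []
            for held in folds:
                tr = np.setdiff1d(np.arange(60), held)
                std, stats = stdz(ds.take(tr))
                m = fit_enet(std.X, std.y, EnetPenalty(l1, l2), stats=stats)
                outs.append(rmsep(ds.y[held], predict(m, ds.X[held])))
            return np.mean(outs)

        scores = {(l1, l2): cv_score(l1, l2) for l1 in g1 for l2 in g2}
        best = min(scores, key=scores.get)
        assert (pen.lambda1, pen.lambda2) == best
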