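"""PLSR engine: oracle equivalences, leakage safety, permutation conventions."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

import interobattery as ib
from interobattery import _engine
from interobattery.plsr import _coef_path, _modal_k, _pls1_path


def _standardise(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


class TestFit:
    def test_rank_one_problem_fits_exactly_at_k1(self, rng):
        t = rng.normal(size=40)
        v = rng.normal(size=3)
        X = np.outer(t, v)
        y = 2.0 + 3.0 * X[:, 0]
        fit = ib.plsr_fit(X, y, 1)
        resid = y - ib.plsr_predict(fit, X)
        assert np.linalg.norm(resid) < 1e-8

    def test_full_component_fit_equals_ols(self, rng):
        X = rng.normal(size=(50, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=50)
        fit = ib.plsr_fit(X, y, 5)
        Xd = np.c_[np.ones(50), _standardise(X)]
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert np.allclose(ib.plsr_predict(fit, X), Xd @ beta, atol=1e-6)

    def test_orthonormal_predictors_give_covariance_weights(self, rng):
        # closed form: with orthonormal columns the K=p coefficients are X^T y
        Q, _ = np.linalg.qr(rng.normal(size=(60, 4)))
        y = rng.normal(size=60)
        yc = y - y.mean()
        W, P, q = _pls1_path(Q.copy(), yc, 4)
        B = _coef_path(W, P, q)
        assert np.allclose(B[:, -1], Q.T @ yc, atol=1e-8)

    def test_score_vectors_mutually_orthogonal(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        fit = ib.plsr_fit(X, y, 5)
        G = fit.x_scores.T @ fit.x_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_matches_sklearn_coefficients(self, rng):
        X = rng.normal(size=(50, 8))
        y = X[:, 0] * 2 - X[:, 3] + rng.normal(size=50)
        for k in (1, 3, 6):
            fit = ib.plsr_fit(X, y, k)
            sk = PLSRegression(n_components=k, scale=True).fit(X, y)
            assert np.allclose(sk.coef_.ravel() * X.std(axis=0), fit.weights, atol=1e-8)

    def test_constant_column_named(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="b_const"):
            ib.plsr_fit(X, rng.normal(size=30), 2, predictor_names=["a", "b_const", "c"])

    def test_k_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 3] = X[:, 0] + X[:, 1]  # rank 3
        with pytest.raises(ValueError, match="rank"):
            ib.plsr_fit(X, rng.normal(size=30), 4)

    def test_engine_path_matches_reference(self, rng):
        X = rng.normal(size=(40, 9))
        y = rng.normal(size=40)
        Xs, yc = _standardise(X), y - y.mean()
        W1, P1, q1 = _pls1_path(Xs.copy(), yc, 6)
        W2, P2, q2, k_eff = _engine.pls1_path(np.ascontiguousarray(Xs), yc, 6)
        assert k_eff == q1.size
        assert np.allclose(W1, W2[:, :k_eff], atol=1e-10)
        assert np.allclose(_coef_path(W1, P1, q1), _engine.coef_path(W2, P2, q2, k_eff),
                           atol=1e-10)


class TestNestedCv:
    def test_duplicated_outcome_column_gives_near_perfect_r(self, rng):
        y = rng.normal(size=24)
        X = np.c_[y, rng.normal(size=(24, 3))]
        res = ib.nested_loo_cv(X, y, k_max=3)
        assert res.r >= 0.99

    def test_left_out_row_never_leaks(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        base = ib.nested_loo_cv(X, y, k_max=3)
        y2 = y.copy()
        y2[6] += 100.0  # only the held-out value changes
        again = ib.nested_loo_cv(X, y2, k_max=3)
        assert again.predictions[6] == pytest.approx(base.predictions[6], abs=1e-10)

    def test_r_invariant_to_affine_outcome_rescaling(self, rng):
        X = rng.normal(size=(20, 5))
        y = X[:, 0] + rng.normal(size=20)
        a = ib.nested_loo_cv(X, y, k_max=4)
        b = ib.nested_loo_cv(X, 3.0 + 2.0 * y, k_max=4)
        assert a.r == pytest.approx(b.r, abs=1e-10)

    def test_null_outcome_r_centres_near_zero(self):
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 10))
            rs.append(ib.nested_loo_cv(X, rng.normal(size=40), k_max=6).r)
        assert abs(np.mean(rs)) < 0.12

    def test_planted_two_component_structure_predicts_well(self):
        rs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(60, 12))
            signal = X[:, 0] - X[:, 1] + 0.8 * X[:, 5]
            noise = rng.normal(size=60) * signal.std() * np.sqrt(1 / 0.6 - 1)
            rs.append(ib.nested_loo_cv(X, signal + noise, k_max=8).r)
        assert np.median(rs) >= 0.6

    def test_small_cohort_rejected(self, rng):
        with pytest.raises(ValueError):
            ib.nested_loo_cv(rng.normal(size=(5, 3)), rng.normal(size=5), k_max=2)


class TestPermutationInference:
    def test_noiseless_signal_reaches_minimum_p(self, rng):
        X = rng.normal(size=(20, 4))
        y = X @ np.array([1.0, -0.5, 0.3, 0.8])
        res = ib.permutation_inference(X, y, k_max=3, n_perm=200, seed=0)
        assert res.p_perm == pytest.approx(1.0 / 201.0)

    def test_add_one_convention_lower_bound(self, rng):
        X = rng.normal(size=(15, 4))
        res = ib.permutation_inference(X, rng.normal(size=15), k_max=2,
                                       n_perm=200, seed=1)
        assert res.p_perm >= 1.0 / 201.0

    def test_small_n_perm_rejected(self, rng):
        with pytest.raises(ValueError):
            ib.permutation_inference(rng.normal(size=(15, 4)), rng.normal(size=15),
                                     n_perm=100, seed=0)

    def test_strong_planted_weight_flagged(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 10))
        y = 0.9 * X[:, 4] + rng.normal(size=60) * 0.5
        names = [f"v{i}" for i in range(10)]
        res = ib.permutation_inference(X, y, k_max=5, n_perm=300, seed=2,
                                       predictor_names=names)
        assert "v4" in res.significant_predictors()

    def test_significance_flags_match_quantiles(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        res = ib.permutation_inference(X, y, k_max=4, n_perm=250, seed=3)
        expected = (res.weights < res.null_lo) | (res.weights > res.null_hi)
        assert np.array_equal(res.significant, expected)


class TestFinalWeights:
    def test_single_strong_predictor_keeps_covariance_sign(self, rng):
        X = rng.normal(size=(40, 2))
        y = -2.0 * X[:, 0] + 0.1 * rng.normal(size=40)
        w = ib.final_weights(X, y, 1)
        assert np.sign(w[0]) == np.sign(np.cov(X[:, 0], y)[0, 1])

    def test_duplicated_predictors_share_weight(self, rng):
        x = rng.normal(size=35)
        X = np.c_[x, x, rng.normal(size=35)]
        y = x + rng.normal(size=35)
        w = ib.final_weights(X, y, 1)
        assert w[0] == pytest.approx(w[1], abs=1e-8)

    def test_modal_k_tie_breaks(self):
        assert _modal_k(np.array([2, 2, 3, 3, 1])) == 2  # smallest mode
        assert _modal_k(np.array([1, 2, 3, 4])) == 2  # all distinct: floor median
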