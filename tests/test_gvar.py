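import numpy as np
import pytest

from lingvar import (
    FitConfig,
    estimate_network,
    fit_at,
    lambda_grid,
    make_lag_pairs,
    pcc_from_precision,
    standardise_series,
)
from lingvar.gvar import _Candidate, ebic_of, select_ebic
from lingvar.simulate import chain_precision, default_temporal_matrix

from conftest import make_matrix, simulated_matrix


class TestMakeLagPairs:
    def test_consecutive_days_both_policies(self):
        m = make_matrix(np.random.default_rng(0).uniform(0, 100, (30, 3)))
        for policy in ("concatenate", "calendar"):
            cur, lag = make_lag_pairs(m, policy)
            assert cur.shape == (29, 3)
            np.testing.assert_array_equal(cur, m.values[1:])
            np.testing.assert_array_equal(lag, m.values[:-1])

    def test_gap_handling_differs(self):
        full = make_matrix(np.random.default_rng(1).uniform(0, 100, (6, 2)))
        # keep observed days {1,2,5,6} (0-based rows 0,1,4,5)
        m = full.select_days(np.array([True, True, False, False, True, True]))
        cur_c, _ = make_lag_pairs(m, "concatenate")
        assert cur_c.shape[0] == 3
        cur_k, lag_k = make_lag_pairs(m, "calendar")
        assert cur_k.shape[0] == 2
        np.testing.assert_array_equal(cur_k[0], full.values[1])
        np.testing.assert_array_equal(lag_k[1], full.values[4])

    def test_single_row_errors(self):
        m = make_matrix(np.full((1, 2), 50.0))
        with pytest.raises(ValueError, match="insufficient data"):
            make_lag_pairs(m)

    def test_two_rows_one_pair_errors(self):
        m = make_matrix(np.full((2, 2), 50.0))
        with pytest.raises(ValueError, match="fewer than 2 usable pairs"):
            make_lag_pairs(m)


class TestStandardise:
    def test_constant_column_errors(self):
        x = np.random.default_rng(0).normal(size=(20, 3))
        x[:, 1] = 4.2
        with pytest.raises(ValueError, match="zero-variance node.*mid"):
            standardise_series(x[1:], x[:-1], node_names=["a", "mid", "c"])

    def test_output_standardised_with_given_stats(self):
        x = np.random.default_rng(1).normal(5, 3, size=(200, 4))
        stats = (x.mean(axis=0), x.std(axis=0, ddof=1))
        cur, lag, mean, sd = standardise_series(x[1:], x[:-1], stats=stats)
        full = np.vstack([lag[:1], cur])
        np.testing.assert_allclose(full.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(full.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_idempotent_on_standardised_data(self):
        x = np.random.default_rng(2).normal(size=(100, 3))
        cur1, lag1, *_ = standardise_series(x[1:], x[:-1])
        cur2, lag2, *_ = standardise_series(cur1, lag1)
        np.testing.assert_allclose(cur1, cur2, atol=0.15)


class TestPcc:
    def test_identity_gives_zero(self):
        np.testing.assert_array_equal(pcc_from_precision(np.eye(4)), np.zeros((4, 4)))

    def test_two_node_closed_form(self):
        K = np.array([[1.0, -0.3], [-0.3, 1.0]])
        omega = pcc_from_precision(K)
        assert omega[0, 1] == pytest.approx(0.3)
        assert omega[0, 0] == 0.0

    def test_matches_conditioning_oracle(self):
        # brute force: partial corr of (i, j) given the rest, via the
        # conditional covariance of Sigma = K^{-1}
        rng = np.random.default_rng(3)
        A = rng.normal(size=(5, 5))
        K = A @ A.T + 5 * np.eye(5)
        omega = pcc_from_precision(K)
        sigma = np.linalg.inv(K)
        p = 5
        for i in range(p):
            for j in range(i + 1, p):
                rest = [k for k in range(p) if k not in (i, j)]
                s_aa = sigma[np.ix_([i, j], [i, j])]
                s_ab = sigma[np.ix_([i, j], rest)]
                s_bb = sigma[np.ix_(rest, rest)]
                cond = s_aa - s_ab @ np.linalg.solve(s_bb, s_ab.T)
                expected = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
                assert omega[i, j] == pytest.approx(expected, abs=1e-10)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcc_from_precision(np.array([[1.0, 0.5], [0.1, 1.0]]))

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            pcc_from_precision(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestLambdaGrid:
    def test_single_point_grid_is_maximum(self):
        m = simulated_matrix(default_temporal_matrix(3), chain_precision(3), 100, seed=0)
        cur, lag, *_ = standardise_series(*make_lag_pairs(m))
        bg, kg = lambda_grid(cur, lag, FitConfig(n_lambda=1))
        n = cur.shape[0]
        S0 = cur.T @ cur / n
        assert kg[0] == pytest.approx(np.max(np.abs(S0 - np.diag(np.diag(S0)))))
        assert bg[0] == pytest.approx(np.max(np.abs(lag.T @ cur)) / n)

    def test_default_grids_strictly_decreasing_length_10(self):
        m = simulated_matrix(default_temporal_matrix(3), chain_precision(3), 100, seed=1)
        cur, lag, *_ = standardise_series(*make_lag_pairs(m))
        bg, kg = lambda_grid(cur, lag, FitConfig())
        for g in (bg, kg):
            assert len(g) == 10
            assert np.all(np.diff(g) < 0)
            assert g[-1] == pytest.approx(g[0] * 0.01)

    def test_full_shrinkage_at_grid_top(self):
        m = simulated_matrix(default_temporal_matrix(4), chain_precision(4), 200, seed=2)
        cur, lag, *_ = standardise_series(*make_lag_pairs(m))
        bg, kg = lambda_grid(cur, lag, FitConfig())
        B, K, *_ = fit_at(cur, lag, bg[0] * 1.001, kg[0] * 1.001, FitConfig())
        assert np.all(B == 0)
        off = K - np.diag(np.diag(K))
        np.testing.assert_allclose(off, 0, atol=1e-10)


class TestFitAt:
    def test_full_shrinkage_far_above_grid(self):
        m = simulated_matrix(default_temporal_matrix(4), chain_precision(4), 150, seed=3)
        cur, lag, *_ = standardise_series(*make_lag_pairs(m))
        B, K, _, conv = fit_at(cur, lag, 10.0, 10.0, FitConfig())
        assert np.all(B == 0) and conv
        assert np.count_nonzero(K - np.diag(np.diag(K))) == 0
        assert np.all(pcc_from_precision(K) == 0)

    def test_unpenalised_matches_ols_oracle(self):
        m = simulated_matrix(default_temporal_matrix(4), chain_precision(4, 0.35), 5000, seed=4)
        cur, lag, *_ = standardise_series(*make_lag_pairs(m))
        B, K, ll, conv = fit_at(cur, lag, 0.0, 0.0, FitConfig())
        coef, *_ = np.linalg.lstsq(lag, cur, rcond=None)
        resid = cur - lag @ coef
        K_oracle = np.linalg.inv(resid.T @ resid / len(resid))
        assert np.max(np.abs(K - K_oracle)) < 0.05
        assert conv

    def test_independent_columns_near_zero_network(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.uniform(20, 80, size=(500, 4)))
        fit = estimate_network(m)
        assert np.max(np.abs(fit.pcc)) < 0.05

    def test_shrinkage_monotonicity_in_kappa(self):
        m = simulated_matrix(default_temporal_matrix(5), chain_precision(5), 150, seed=6)
        cur, lag, *_ = standardise_series(*make_lag_pairs(m))
        _, kg = lambda_grid(cur, lag, FitConfig(n_lambda=6))
        nnz = []
        for lk in kg[::-1]:  # increasing penalty
            _, K, *_ = fit_at(cur, lag, 0.05, float(lk), FitConfig())
            nnz.append(np.count_nonzero(np.abs(K - np.diag(np.diag(K))) > 1e-8))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestSelectEbic:
    def _candidates(self, seed=0, n=120):
        m = simulated_matrix(default_temporal_matrix(4), chain_precision(4), n, seed=seed)
        cur, lag, *_ = standardise_series(*make_lag_pairs(m))
        bg, kg = lambda_grid(cur, lag, FitConfig(n_lambda=4))
        cands = []
        for lb in bg:
            for lk in kg:
                B, K, ll, conv = fit_at(cur, lag, float(lb), float(lk), FitConfig())
                cands.append(_Candidate(float(lb), float(lk), B, K, ll,
                                        ebic_of(B, K, ll, cur.shape[0], 0.0), conv))
        return cands, cur.shape[0]

    def test_single_candidate_returned(self):
        cands, n = self._candidates()
        fit = select_ebic(cands[:1], 0.0, list("abcd"), n_days=n + 1, n_pairs=n)
        assert fit.lambda_beta == cands[0].lambda_beta

    def test_gamma_zero_is_bic(self):
        cands, n = self._candidates()
        # independent BIC: -2 ll + E log n, E re-counted here
        def bic(c):
            E = int(np.sum(np.abs(c.B) > 1e-8))
            E += int(np.sum(np.abs(c.K[np.triu_indices(4, 1)]) > 1e-8))
            return -2 * c.loglik + E * np.log(n)
        best_bic = min(cands, key=lambda c: (round(bic(c), 10), c.lambda_beta, c.lambda_kappa))
        fit = select_ebic(cands, 0.0, list("abcd"), n_days=n + 1, n_pairs=n)
        assert (fit.lambda_beta, fit.lambda_kappa) == (best_bic.lambda_beta, best_bic.lambda_kappa)

    def test_ties_broken_toward_denser(self):
        cands, n = self._candidates()
        tied = [_Candidate(0.5, 0.5, cands[0].B, cands[0].K, cands[0].loglik, 1.0, True),
                _Candidate(0.1, 0.1, cands[0].B, cands[0].K, cands[0].loglik, 1.0, True)]
        fit = select_ebic(tied, 0.0, list("abcd"), n_days=n, n_pairs=n)
        assert fit.lambda_beta == 0.1


class TestEstimateNetwork:
    def test_deterministic(self):
        m = simulated_matrix(default_temporal_matrix(4), chain_precision(4), 120, seed=7)
        f1 = estimate_network(m)
        f2 = estimate_network(m)
        np.testing.assert_array_equal(f1.pcc, f2.pcc)
        assert f1.lambda_kappa == f2.lambda_kappa

    def test_node_subset(self):
        m = simulated_matrix(default_temporal_matrix(9), chain_precision(9), 120, seed=8)
        fit = estimate_network(m, nodes=[f"f{i}" for i in range(8)])
        assert len(fit.node_names) == 8
        assert np.isfinite(fit.pcc).all()

    def test_empty_subset_rejected(self):
        m = simulated_matrix(default_temporal_matrix(3), chain_precision(3), 50, seed=9)
        with pytest.raises(ValueError, match="empty"):
            estimate_network(m, nodes=[])

    def test_symmetry_and_bounds_always(self):
        for seed in range(4):
            m = simulated_matrix(default_temporal_matrix(5), chain_precision(5), 80, seed=seed)
            fit = estimate_network(m, config=FitConfig(n_lambda=3))
            np.testing.assert_allclose(fit.pcc, fit.pcc.T)
            assert np.all(np.abs(fit.pcc) <= 1.0)
            assert np.all(np.diag(fit.pcc) == 0)

    def test_f1_improves_with_length(self):
        # edge-recovery F1 non-decreasing in expectation; compare short vs long
        B, K = default_temporal_matrix(5), chain_precision(5, 0.35)
        truth = np.abs(pcc_from_precision(K)) > 1e-9
        iu = np.triu_indices(5, 1)

        def mean_f1(T):
            scores = []
            for seed in range(6):
                fit = estimate_network(simulated_matrix(B, K, T, seed=100 + seed))
                est = np.abs(fit.pcc) > 1e-9
                tp = (est & truth)[iu].sum()
                fp = (est & ~truth)[iu].sum()
                fn = (~est & truth)[iu].sum()
                scores.append(2 * tp / max(2 * tp + fp + fn, 1))
            return np.mean(scores)

        assert mean_f1(400) >= mean_f1(40) - 0.05
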