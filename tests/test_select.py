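"""Graph selection: thresholding, median-probability edges, refit, BIC."""

import numpy as np
import pytest

from npnchol.select import (
    bic_select,
    constrained_mle,
    horseshoe_edges,
    median_probability_edges,
    partial_corr,
    threshold_01,
    wishart_reference,
)


class TestPartialCorr:
    def test_identity(self):
        pc = partial_corr(np.eye(4))
        assert np.all(pc[~np.eye(4, dtype=bool)] == 0.0)
        assert np.all(np.diag(pc) == 1.0)

    def test_sign_flip(self):
        om = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert partial_corr(om)[0, 1] == pytest.approx(0.5)

    def test_matches_residual_correlation_oracle(self, random_spd):
        # partial correlation of (i, j) equals the correlation of the
        # residuals of each on all remaining variables
        rng = np.random.default_rng(1)
        om = random_spd(5, seed=2)
        cov = np.linalg.inv(om)
        Z = rng.multivariate_normal(np.zeros(5), cov, 200_000)
        pc = partial_corr(om)
        for (i, j) in [(0, 1), (2, 4)]:
            rest = [k for k in range(5) if k not in (i, j)]
            Zi = Z[:, i] - Z[:, rest] @ np.linalg.lstsq(Z[:, rest], Z[:, i], rcond=None)[0]
            Zj = Z[:, j] - Z[:, rest] @ np.linalg.lstsq(Z[:, rest], Z[:, j], rcond=None)[0]
            emp = np.corrcoef(Zi, Zj)[0, 1]
            assert pc[i, j] == pytest.approx(emp, abs=0.01)


class TestWishartReference:
    def test_prior_mean_no_data(self):
        j = wishart_reference(np.zeros((0, 3)))
        assert np.all(j[~np.eye(3, dtype=bool)] == 0.0)

    def test_diagonal_case(self):
        # S = I at n = 1: H = 4 (2I)^{-1} = 2I, all partials zero
        Z = np.array([[1.0, 1.0]])  # S has ones everywhere; use explicit S path
        H_expect = 3.0 * np.linalg.inv(np.eye(2) + Z.T @ Z + np.zeros((2, 2)))
        j = wishart_reference(Z)
        # direct dense evaluation
        S = Z.T @ Z
        H = (1 + 3) * np.linalg.inv(np.eye(2) + S)
        np.testing.assert_allclose(j, partial_corr(H), atol=1e-12)

    def test_matches_dense_formula(self, rng):
        Z = rng.standard_normal((20, 4))
        H = (20 + 3) * np.linalg.inv(np.eye(4) + Z.T @ Z)
        np.testing.assert_allclose(
            wishart_reference(Z), partial_corr(H), atol=1e-12
        )


class TestThreshold:
    def test_above(self):
        j = np.array([[1.0]])
        assert threshold_01(np.array([[0.6]]), j)[0, 0]

    def test_zero_estimate(self):
        assert not threshold_01(np.zeros((1, 1)), np.ones((1, 1)))[0, 0]

    def test_exact_half_excluded(self):
        # the rule is a strict inequality
        assert not threshold_01(np.array([[0.5]]), np.array([[1.0]]))[0, 0]

    def test_zero_reference_conventions(self):
        e = np.array([[0.0, 0.3], [0.3, 0.0]])
        j = np.zeros((2, 2))
        out = threshold_01(e, j)
        assert not out[0, 0] and out[0, 1]

    def test_scale_invariance(self, rng):
        e = rng.standard_normal((5, 5))
        j = rng.standard_normal((5, 5))
        np.testing.assert_array_equal(threshold_01(e, j), threshold_01(3.7 * e, 3.7 * j))

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            threshold_01(np.array([[np.nan]]), np.array([[1.0]]))


class TestMedianProbability:
    def test_always_present(self):
        draw = np.zeros((3, 3), dtype=bool)
        draw[0, 1] = draw[1, 0] = True
        edges = median_probability_edges([draw] * 5)
        assert edges[0, 1] and edges[1, 0]

    def test_exact_half_excluded(self):
        on = np.zeros((3, 3), dtype=bool)
        on[0, 1] = on[1, 0] = True
        off = np.zeros((3, 3), dtype=bool)
        edges = median_probability_edges([on, off] * 500)
        assert not edges.any()

    def test_rate_07_included(self, rng):
        on = np.zeros((2, 2), dtype=bool)
        on[0, 1] = on[1, 0] = True
        off = np.zeros((2, 2), dtype=bool)
        draws = [on if rng.random() < 0.7 else off for _ in range(1000)]
        assert median_probability_edges(draws)[0, 1]

    def test_order_invariance(self, rng):
        draws = [rng.random((4, 4)) < 0.5 for _ in range(30)]
        draws = [d | d.T for d in draws]
        for d in draws:
            np.fill_diagonal(d, False)
        a = median_probability_edges(draws)
        b = median_probability_edges(draws[::-1])
        np.testing.assert_array_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_probability_edges([])


class TestConstrainedMLE:
    def test_unconstrained_closed_form(self, random_spd):
        S = random_spd(4, seed=5)
        n = 50
        edges = ~np.eye(4, dtype=bool)
        om = constrained_mle(S, edges, n)
        np.testing.assert_allclose(om, n * np.linalg.inv(S), rtol=1e-6)

    def test_diagonal_pattern(self, random_spd):
        S = random_spd(5, seed=6)
        n = 40
        om = constrained_mle(S, np.zeros((5, 5), dtype=bool), n)
        np.testing.assert_allclose(np.diag(om), n / np.diag(S), rtol=1e-8)
        assert np.abs(om[~np.eye(5, dtype=bool)]).max() < 1e-10

    def test_single_zero_pattern_matches_bruteforce(self, random_spd):
        from scipy.optimize import minimize

        S = random_spd(3, seed=7)
        n = 30
        edges = np.ones((3, 3), dtype=bool)
        np.fill_diagonal(edges, False)
        edges[0, 2] = edges[2, 0] = False
        om = constrained_mle(S, edges, n)
        assert om[0, 2] == 0.0

        def embed(x):
            m = np.array([[x[0], x[3], 0.0], [x[3], x[1], x[4]], [0.0, x[4], x[2]]])
            return m

        def nll(x):
            m = embed(x)
            sign, ld = np.linalg.slogdet(m)
            if sign <= 0:
                return 1e10
            return -n * ld + np.sum(m * S)

        x0 = np.array([om[0, 0], om[1, 1], om[2, 2], om[0, 1], om[1, 2]]) * 1.1
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000})
        np.testing.assert_allclose(om, embed(res.x), rtol=1e-4, atol=1e-6)

    def test_kkt_residual(self, random_spd):
        S = random_spd(6, seed=8)
        n = 100
        rngl = np.random.default_rng(3)
        edges = rngl.random((6, 6)) < 0.3
        edges = np.triu(edges, 1)
        edges = edges | edges.T
        om = constrained_mle(S, edges, n)
        grad = S - n * np.linalg.inv(om)
        free = edges | np.eye(6, dtype=bool)
        assert np.abs(grad[free]).max() < 1e-6
        assert np.abs(om[~free]).max() == 0.0


class TestBIC:
    def test_printed_formula(self):
        # Omega = I, S = I, p = 3, n = 10, k = 3: BIC = 2*3 + 3 log 10
        om = np.eye(3)
        S = np.eye(3)
        n = 10
        neg_ll = -n * np.linalg.slogdet(om)[1] + np.sum(om * S)
        k = 3
        assert 2 * neg_ll + k * np.log(n) == pytest.approx(6 + 3 * np.log(10))

    def test_penalty_monotone_in_k(self):
        n = 25
        base = 2 * 5.0
        assert base + 4 * np.log(n) < base + 7 * np.log(n)

    def test_selects_reasonable_c_on_circle(self, circle_data):
        from npnchol.gibbs import gibbs_horseshoe

        Z, truth, omega_true = circle_data
        chains = {
            c: gibbs_horseshoe(Z, c_sparsity=c, n_iter=1_500, burn=500, seed=13)
            for c in (0.1, 1.0, 10.0)
        }
        c_star, edges, om_hat, table = bic_select(chains, Z)
        assert c_star in (0.1, 1.0, 10.0)
        assert len(table) == 3
        # selected model keeps sparsity within the order of the truth
        n_true = truth[np.triu_indices(10, 1)].sum()
        n_est = edges[np.triu_indices(10, 1)].sum()
        assert n_est <= 4 * n_true

    def test_empty_chains_rejected(self, circle_data):
        Z, _, _ = circle_data
        with pytest.raises(ValueError):
            bic_select({}, Z)


def test_horseshoe_edges_shape(circle_data):
    from npnchol.gibbs import gibbs_horseshoe

    Z, truth, _ = circle_data
    chain = gibbs_horseshoe(Z, 0.1, n_iter=800, burn=300, seed=2)
    edges = horseshoe_edges(chain, Z)
    assert edges.shape == (10, 10)
    assert not edges.diagonal().any()
    np.testing.assert_array_equal(edges, edges.T)
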