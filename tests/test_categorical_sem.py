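import numpy as np
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from dichrel import (
    bivariate_normal_cdf,
    green_yang_from_responses,
    green_yang_reliability,
    icc,
    make_grid,
    probit_loadings,
    reliability_quadrature,
    sample_item_parameters,
    sample_theta,
    tetrachoric,
    tetrachoric_matrix,
    threshold,
)
from dichrel.categorical_sem import (
    CategoricalFactorSolution,
    _cell_probs,
    loading_from_discrimination,
    threshold_from_parameters,
)


class TestThreshold:
    def test_half_zeros(self):
        x = np.array([0, 1] * 50)
        assert threshold(x) == pytest.approx(0.0, abs=1e-12)

    def test_standard_quantile(self):
        n0 = 8413
        x = np.array([0] * n0 + [1] * (10000 - n0))
        assert threshold(x) == pytest.approx(stats.norm.ppf(0.8413), abs=1e-9)
        assert threshold(x) == pytest.approx(1.0, abs=1e-3)

    def test_symmetry(self):
        x = np.array([0] * 30 + [1] * 70)
        assert threshold(x) == pytest.approx(-threshold(1 - x), abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            threshold(np.ones(10, dtype=int))


class TestBivariateNormalCdf:
    def test_independence(self):
        assert bivariate_normal_cdf(0.0, 0.0, 0.0) == pytest.approx(0.25, abs=1e-14)

    def test_comonotone_limit(self):
        for t in (-1.2, 0.0, 0.8):
            assert bivariate_normal_cdf(t, t, 1.0) == pytest.approx(
                stats.norm.cdf(t), abs=1e-14
            )

    def test_closed_form_median_orthant(self):
        for rho in (-0.95, -0.4, 0.3, 0.925, 0.93, 0.999):
            exact = 0.25 + np.arcsin(rho) / (2 * np.pi)
            assert bivariate_normal_cdf(0.0, 0.0, rho) == pytest.approx(exact, abs=1e-12)

    def test_against_numerical_integration(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            h, k = rng.normal(0, 1.5, 2)
            rho = float(rng.uniform(-0.999, 0.999))
            ref = multivariate_normal(
                mean=[0, 0], cov=[[1, rho], [rho, 1]]
            ).cdf([h, k])
            assert bivariate_normal_cdf(h, k, rho) == pytest.approx(ref, abs=1e-8)


class TestTetrachoric:
    def test_independent_table_zero(self):
        # counts exactly proportional to independent margins
        t = np.outer([60, 40], [30, 70]) / 100.0
        assert tetrachoric(t) == pytest.approx(0.0, abs=1e-5)

    def test_brute_force_likelihood_grid(self):
        counts = np.array([40.0, 10.0, 10.0, 40.0])
        grid = np.linspace(-0.998, 0.998, 99801)
        lls = np.array([counts @ np.log(_cell_probs(0.0, 0.0, r)) for r in grid[::100]])
        # refine around coarse argmax
        coarse = grid[::100][np.argmax(lls)]
        fine = np.linspace(coarse - 0.02, coarse + 0.02, 4001)
        lls_f = np.array([counts @ np.log(_cell_probs(0.0, 0.0, r)) for r in fine])
        ref = fine[np.argmax(lls_f)]
        assert tetrachoric([[40, 10], [10, 40]]) == pytest.approx(ref, abs=1e-4)

    def test_simulation_consistency(self):
        # bivariate probit data with rho = 0.5
        rng = np.random.default_rng(6)
        z = sample_theta(10**6, correlation=0.5, rng=rng)
        x = (z > 0.2).astype(np.int8)
        t = np.zeros((2, 2))
        for u in (0, 1):
            for v in (0, 1):
                t[u, v] = np.sum((x[:, 0] == u) & (x[:, 1] == v))
        assert tetrachoric(t) == pytest.approx(0.5, abs=0.01)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            tetrachoric([[0, 0], [10, 20]])

    def test_zero_cell_strict_mode(self):
        with pytest.raises(ValueError):
            tetrachoric([[20, 0], [5, 25]], zero_cell="error")

    def test_zero_cell_continuity_correction(self):
        with pytest.warns(UserWarning):
            r = tetrachoric([[20, 0], [5, 25]])
        assert 0 < r < 1


class TestProbitLoadings:
    def test_exact_recovery(self):
        lam = np.array([0.7, 0.6, 0.5, 0.4])
        r = np.outer(lam, lam)
        np.fill_diagonal(r, 1.0)
        assert np.allclose(probit_loadings(r), lam, atol=1e-6)

    def test_identity_degenerate(self):
        with pytest.warns(UserWarning):
            lam = probit_loadings(np.eye(5))
        assert np.all(np.abs(lam) < 0.05)

    def test_permutation_invariance(self):
        lam = np.array([0.72, 0.55, 0.61, 0.48, 0.66])
        r = np.outer(lam, lam)
        np.fill_diagonal(r, 1.0)
        perm = [4, 2, 0, 3, 1]
        assert np.allclose(
            probit_loadings(r)[perm], probit_loadings(r[np.ix_(perm, perm)]), atol=1e-6
        )


class TestGreenYang:
    def test_zero_loadings_zero_reliability(self):
        tau = np.array([-0.5, 0.0, 0.7])
        rho = np.eye(3)
        sol = CategoricalFactorSolution(tau, np.zeros(3), rho)
        assert green_yang_reliability(sol) == pytest.approx(0.0, abs=1e-12)

    def test_inadmissible_rejected(self):
        sol = CategoricalFactorSolution(np.zeros(3), np.array([1.0, 0.5, 0.5]), np.eye(3))
        with pytest.raises(ValueError):
            green_yang_reliability(sol)

    def test_population_equivalence_with_probit_quadrature(self):
        # the categorical factor model is the probit-link twin of the 2PL
        bank = sample_item_parameters(15, 5)
        lam = loading_from_discrimination(bank.a)
        tau = threshold_from_parameters(bank.a, bank.b)
        rho = np.outer(lam, lam)
        np.fill_diagonal(rho, 1.0)
        gy = green_yang_reliability(CategoricalFactorSolution(tau, lam, rho))
        dq = reliability_quadrature(bank, make_grid(501, -8, 8), link="probit")
        assert gy == pytest.approx(dq.reliability, abs=1e-3)

    def test_denominator_matches_simulated_sum_variance(self):
        # model-implied total variance at true parameters equals the
        # population variance of the sum score
        bank = sample_item_parameters(8, 14)
        lam = loading_from_discrimination(bank.a)
        tau = threshold_from_parameters(bank.a, bank.b)
        rho = np.outer(lam, lam)
        np.fill_diagonal(rho, 1.0)
        from dichrel.categorical_sem import _implied_cov_sum

        den = _implied_cov_sum(tau, lambda i, j: 1.0 if i == j else float(rho[i, j]))
        rng = np.random.default_rng(15)
        theta = sample_theta(400_000, rng=rng)
        p = icc(theta[:, None], bank.a[None, :], bank.b[None, :], link="probit")
        x = (rng.random(p.shape) < p).astype(np.int8)
        sim_var = x.sum(axis=1).var(ddof=1)
        se = sim_var * np.sqrt(2 / 400_000)  # rough chi-square SE
        assert den == pytest.approx(sim_var, abs=4 * se)

    def test_item_reversal_invariance(self):
        rng = np.random.default_rng(3)
        bank = sample_item_parameters(6, rng)
        x = (rng.random((4000, 6)) < icc(
            sample_theta(4000, rng=rng)[:, None], bank.a, bank.b, link="probit"
        )).astype(np.int8)
        gy = green_yang_from_responses(x)
        gy_rev = green_yang_from_responses(1 - x)
        assert gy == pytest.approx(gy_rev, abs=1e-6)

    def test_full_pipeline_converges_to_population_value(self):
        bank = sample_item_parameters(10, 8)
        rng = np.random.default_rng(9)
        theta = sample_theta(50_000, rng=rng)
        p = icc(theta[:, None], bank.a[None, :], bank.b[None, :], link="probit")
        x = (rng.random(p.shape) < p).astype(np.int8)
        gy_est = green_yang_from_responses(x)
        lam = loading_from_discrimination(bank.a)
        tau = threshold_from_parameters(bank.a, bank.b)
        rho = np.outer(lam, lam)
        np.fill_diagonal(rho, 1.0)
        gy_pop = green_yang_reliability(CategoricalFactorSolution(tau, lam, rho))
        assert gy_est == pytest.approx(gy_pop, abs=0.01)

    def test_dwls_close_to_uls_on_good_data(self):
        rng = np.random.default_rng(11)
        bank = sample_item_parameters(6, rng)
        x = (rng.random((8000, 6)) < icc(
            sample_theta(8000, rng=rng)[:, None], bank.a, bank.b, link="probit"
        )).astype(np.int8)
        assert green_yang_from_responses(x, "uls") == pytest.approx(
            green_yang_from_responses(x, "dwls"), abs=0.02
        )
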