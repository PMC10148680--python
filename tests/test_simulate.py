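"""Tests of the synthetic cohort generator and study drivers."""

import numpy as np
import pytest
from scipy import stats

from poirot.simulate import (
    CORRELATION_RANGES,
    SimScenario,
    draw_trait_covariance,
    fleishman_coefficients,
    null_grid,
    power_grid,
    run_null_study,
    simulate_cohort,
    simulate_gxe_phenotypes,
    simulate_phenotypes,
    simulate_trio_genotypes,
    trio_meanbased_test,
    vale_maurelli_errors,
)


class TestTraitCovariance:
    @pytest.mark.parametrize("level", ["low", "medium", "high"])
    def test_unit_diagonal_and_range(self, level, rng):
        Sigma = draw_trait_covariance(6, level, rng)
        lo, hi = CORRELATION_RANGES[level]
        assert np.array_equal(np.diag(Sigma), np.ones(6))
        off = Sigma[np.triu_indices(6, 1)]
        assert np.all((off >= lo) & (off <= hi))
        assert np.array_equal(Sigma, Sigma.T)

    def test_positive_definite(self, rng):
        for _ in range(20):
            Sigma = draw_trait_covariance(10, "high", rng)
            assert np.linalg.eigvalsh(Sigma)[0] > 0


class TestTrioGenotypes:
    def test_hardy_weinberg_frequencies(self, rng):
        n = 200_000
        g, _ = simulate_trio_genotypes(n, 0.25, rng)
        freqs = np.bincount(g, minlength=3) / n
        # independent Bernoulli(0.25) alleles => (0.5625, 0.375, 0.0625)
        assert freqs == pytest.approx([0.5625, 0.375, 0.0625], abs=0.005)

    def test_maternal_origin_is_fair_coin(self, rng):
        g, origin = simulate_trio_genotypes(100_000, 0.25, rng)
        het = g == 1
        assert np.all(origin[~het] == -1)
        assert np.mean(origin[het]) == pytest.approx(0.5, abs=0.01)

    def test_monomorphic_edge_case(self, rng):
        g, origin = simulate_trio_genotypes(50, 0.0, rng)
        assert np.all(g == 0)
        assert np.all(origin == -1)


class TestFleishman:
    def test_normal_targets_give_identity(self):
        fit = fleishman_coefficients(0.0, 0.0)
        assert fit.coefficients == pytest.approx((0.0, 1.0, 0.0, 0.0), abs=1e-10)
        assert fit.feasible

    def test_feasible_target_moments_by_simulation(self, rng):
        fit = fleishman_coefficients(1.0, 1.5)
        assert fit.feasible and fit.residual < 1e-8
        z = rng.standard_normal(1_000_000)
        y = fit.a + z * (fit.b + z * (fit.c + z * fit.d))
        assert np.var(y) == pytest.approx(1.0, abs=0.02)
        assert stats.skew(y) == pytest.approx(1.0, abs=0.05)
        assert stats.kurtosis(y) == pytest.approx(1.5, abs=0.25)

    def test_solution_reproduces_its_own_achieved_targets(self):
        for target in [(0.5, 1.0), (1.5, 4.0), (2.0, 2.0)]:
            fit = fleishman_coefficients(*target)
            # analytic moments of the returned cubic match the reported
            # achieved values by construction; variance is exactly 1
            from poirot.simulate import _fleishman_moments

            var, s, k = _fleishman_moments(fit.b, fit.c, fit.d)
            assert var == pytest.approx(1.0, abs=1e-10)
            assert s == pytest.approx(fit.achieved_skew, abs=1e-10)
            assert k == pytest.approx(fit.achieved_excess_kurtosis, abs=1e-10)

    def test_infeasible_region_flagged(self):
        # excess kurtosis = skew^2 - 2 is the universal lower bound; the
        # Fleishman cubic cannot reach (2, 2)
        fit = fleishman_coefficients(2.0, 2.0)
        assert not fit.feasible
        assert fit.achieved_skew < 2.0


class TestValeMaurelli:
    def test_zero_targets_reduce_to_normal(self, rng):
        Sigma = np.array([[1.0, 0.4], [0.4, 1.0]])
        e = vale_maurelli_errors(200_000, Sigma, 0.0, 0.0, rng)
        assert stats.skew(e[:, 0]) == pytest.approx(0.0, abs=0.05)
        assert np.corrcoef(e.T)[0, 1] == pytest.approx(0.4, abs=0.01)

    def test_correlation_targeting_with_skewness(self, rng):
        sc = SimScenario(K=3, corr_level="medium", replicates=1, seed=1)
        Sigma = draw_trait_covariance(3, "medium", rng)
        e = vale_maurelli_errors(100_000, Sigma, 1.0, 1.5, rng)
        emp = np.corrcoef(e.T)
        assert np.max(np.abs(emp - Sigma)) < 0.02
        for k in range(3):
            assert stats.skew(e[:, k]) == pytest.approx(1.0, abs=0.1)
            assert np.var(e[:, k]) == pytest.approx(1.0, abs=0.03)


class TestPhenotypeModel:
    def test_group_covariances_match_sigma_under_null(self, rng):
        Sigma = draw_trait_covariance(3, "medium", rng)
        g, origin = simulate_trio_genotypes(150_000, 0.25, rng)
        Y = simulate_phenotypes(g, origin, np.zeros(3), Sigma,
                                np.zeros(3), np.zeros(3), rng)
        for code in (0, 1, 2):
            emp = np.cov(Y[g == code], rowvar=False)
            assert np.max(np.abs(emp - Sigma)) < 0.05

    def test_heterozygote_covariance_inflation_identity(self, rng):
        # Sigma_het - Sigma_hom = (1/4) b b' with b = beta_M - beta_P
        Sigma = draw_trait_covariance(3, "medium", rng)
        beta_M = np.array([0.75, 0.75, 0.0])
        g, origin = simulate_trio_genotypes(200_000, 0.25, rng)
        Y = simulate_phenotypes(g, origin, np.zeros(3), Sigma,
                                beta_M, np.zeros(3), rng)
        S_het = np.cov(Y[g == 1], rowvar=False)
        # Sigma_hom is the common within-group covariance: pool AA and BB
        # covariances after removing each group's own mean (a raw pooled
        # covariance would also absorb the BB marginal mean shift)
        n0, n2 = (g == 0).sum(), (g == 2).sum()
        S_hom = (
            (n0 - 1) * np.cov(Y[g == 0], rowvar=False)
            + (n2 - 1) * np.cov(Y[g == 2], rowvar=False)
        ) / (n0 + n2 - 2)
        expected = 0.25 * np.outer(beta_M, beta_M)
        assert np.max(np.abs((S_het - S_hom) - expected)) < 0.02

    def test_equal_parental_effects_shift_groups_only(self, rng):
        # same error draws: beta_M = beta_P = c moves each genotype group
        # by a constant, nothing else
        Sigma = np.eye(2)
        g, origin = simulate_trio_genotypes(500, 0.3, rng)
        eps = rng.standard_normal((500, 2))
        y0 = simulate_phenotypes(g, origin, np.zeros(2), Sigma,
                                 np.zeros(2), np.zeros(2), rng, eps=eps)
        y1 = simulate_phenotypes(g, origin, np.zeros(2), Sigma,
                                 np.full(2, 0.5), np.full(2, 0.5), rng, eps=eps)
        diff = y1 - y0
        for code, shift in ((0, 0.0), (1, 0.5), (2, 1.0)):
            assert np.allclose(diff[g == code], shift, atol=1e-12)


class TestGxePhenotypes:
    def test_zero_interaction_matches_main_effect_model(self, rng):
        g, _ = simulate_trio_genotypes(2000, 0.25, rng)
        u = rng.standard_normal(2000)
        seed_state = rng.bit_generator.state
        Y0 = simulate_gxe_phenotypes(g, u, [0.5, 0.0], [0.0, 0.0],
                                     np.zeros(2), np.eye(2), rng, maf=0.25)
        rng.bit_generator.state = seed_state
        Y1 = simulate_gxe_phenotypes(g, u, [0.5, 0.0], [0.0, 0.0],
                                     np.zeros(2), np.eye(2), rng, maf=0.25)
        assert np.array_equal(Y0, Y1)
        # covariate main effect present on trait 0 only
        assert abs(np.corrcoef(Y0[:, 0], u)[0, 1]) > 0.3
        assert abs(np.corrcoef(Y0[:, 1], u)[0, 1]) < 0.1

    def test_variance_decomposition_matches_requested_fraction(self, rng):
        n = 200_000
        g, _ = simulate_trio_genotypes(n, 0.25, rng)
        u = rng.standard_normal(n)
        frac = 0.01
        Y = simulate_gxe_phenotypes(g, u, [0.5], [frac], np.zeros(1),
                                    np.eye(1), rng, maf=0.25)
        var_g = 2 * 0.25 * 0.75
        gamma2 = frac * (1 + 0.25) / ((1 - frac) * var_g)
        interaction = np.sqrt(gamma2) * (g - 0.5) * u
        ratio = np.var(interaction) / np.var(Y[:, 0])
        assert ratio == pytest.approx(frac, rel=0.15)

    def test_fraction_bounds_enforced(self, rng):
        g, _ = simulate_trio_genotypes(100, 0.25, rng)
        with pytest.raises(ValueError):
            simulate_gxe_phenotypes(g, np.zeros(100), [0.5], [0.2],
                                    np.zeros(1), np.eye(1), rng, maf=0.25)


class TestStudyDrivers:
    def test_bitwise_reproducibility_from_seed(self):
        sc = SimScenario(K=3, n=800, replicates=5, seed=123)
        a = run_null_study(sc)
        b = run_null_study(sc)
        assert np.array_equal(a.pvalues["poirot"], b.pvalues["poirot"])

    def test_summary_bookkeeping(self):
        sc = SimScenario(K=3, n=800, replicates=20, seed=5)
        s = run_null_study(sc)
        for a in s.alphas:
            r = s.rejection["poirot"][a]
            assert 0.0 <= r <= 1.0
            assert s.mcse["poirot"][a] == pytest.approx(
                np.sqrt(r * (1 - r) / s.n_effective)
            )

    def test_null_study_rejects_unequal_betas(self):
        sc = SimScenario(K=3, beta_M=0.5, beta_P=0.0, replicates=2, seed=0)
        with pytest.raises(ValueError):
            run_null_study(sc)

    def test_factorial_grid_sizes(self):
        assert len(null_grid()) == 27
        assert len(power_grid()) == 162


class TestTrioMeanTest:
    def test_detects_large_origin_difference(self, rng):
        n_het = 120
        origin = np.repeat([1, 0], n_het // 2)
        Y = rng.standard_normal((n_het, 3))
        Y[origin == 1, :2] += 1.0
        assert trio_meanbased_test(Y, origin) < 1e-6

    def test_null_calibration(self):
        pvals = []
        for child in np.random.SeedSequence(77).spawn(300):
            rng = np.random.default_rng(child)
            origin = rng.integers(0, 2, size=100)
            if origin.min() == origin.max():
                continue
            pvals.append(trio_meanbased_test(rng.standard_normal((100, 3)), origin))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            trio_meanbased_test(rng.standard_normal((10, 2)), np.ones(10))
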