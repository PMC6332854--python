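"""Per-locus additive variance formulas and the gamma threshold machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from hapgwas.variance import (
    fit_gamma_mom,
    gamma_threshold,
    haplotype_variance,
    smooth_params,
    snp_variance,
    threshold_table,
    call_significant,
    GammaClassFit,
)


class TestSnpVariance:
    @pytest.mark.parametrize("p,a,expected", [
        (0.094, 0.40, 0.027),  # published SNP with the largest effect-frequency product
        (0.185, 0.30, 0.027),
        (0.163, 0.51, 0.071),
    ])
    def test_published_values(self, p, a, expected):
        assert round(snp_variance(p, a), 3) == expected

    def test_zero_effect(self):
        assert snp_variance(0.3, 0.0) == 0.0

    def test_symmetry_and_sign_invariance(self):
        assert snp_variance(0.2, 0.5) == pytest.approx(snp_variance(0.8, 0.5))
        assert snp_variance(0.2, 0.5) == pytest.approx(snp_variance(0.2, -0.5))

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.3])
    def test_bad_frequency(self, p):
        with pytest.raises(ValueError):
            snp_variance(p, 0.5)


def brute_force_pairwise(p, a):
    """Independent oracle: explicit double loop over ordered pairs l > i."""
    total = 0.0
    k = len(p)
    for i in range(k - 1):
        for l in range(i + 1, k):
            total += (a[i] - a[l]) ** 2 * p[i] * p[l]
    return total


class TestHaplotypeVariance:
    def test_single_allele_is_zero(self):
        assert haplotype_variance([1.0], [0.7]) == 0.0

    def test_two_allele_closed_form(self):
        assert haplotype_variance([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.25)

    def test_matches_brute_force_and_weighted_variance(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = rng.integers(1, 9)
            p = rng.dirichlet(np.ones(k))
            a = rng.normal(0, 1, size=k)
            v = haplotype_variance(p, a)
            assert v == pytest.approx(brute_force_pairwise(p, a), abs=1e-10)
            # frequency-weighted variance identity Var_p(a)
            assert v == pytest.approx(float(p @ a**2 - (p @ a) ** 2), abs=1e-10)

    def test_k2_is_half_the_snp_formula(self):
        """Documented factor-1/2 relation between the two published formulas."""
        p, a1, a2 = 0.3, 0.9, 0.1
        hap = haplotype_variance([p, 1 - p], [a1, a2])
        assert hap == pytest.approx(0.5 * snp_variance(p, a1 - a2))
        both = haplotype_variance([p, 1 - p], [a1, a2], scale="snp_consistent")
        assert both == pytest.approx(snp_variance(p, a1 - a2))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 8))
    def test_permutation_invariance(self, seed, k):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k))
        a = rng.normal(size=k)
        perm = rng.permutation(k)
        assert haplotype_variance(p, a) == pytest.approx(haplotype_variance(p[perm], a[perm]))

    def test_frequency_sum_checked(self):
        with pytest.raises(ValueError, match="sum to 1"):
            haplotype_variance([0.5, 0.4], [1.0, 0.0])


class TestGammaFit:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(7)
        draws = rng.gamma(shape=2.0, scale=1.0 / 3.0, size=10_000)
        fit = fit_gamma_mom(draws)
        assert 1.9 <= fit.alpha <= 2.1
        assert 2.85 <= fit.beta <= 3.15

    def test_agrees_with_ml_oracle(self):
        rng = np.random.default_rng(8)
        draws = rng.gamma(shape=2.0, scale=1.0 / 3.0, size=10_000)
        fit = fit_gamma_mom(draws)
        a_ml, loc, scale = stats.gamma.fit(draws, floc=0)
        assert abs(fit.alpha - a_ml) / a_ml < 0.02
        assert abs(fit.beta - 1.0 / scale) / (1.0 / scale) < 0.02

    def test_moment_statistic_definition(self):
        v = np.array([0.5, 1.0, 2.0, 4.0])
        fit = fit_gamma_mom(v)
        s = np.log(v.mean()) - np.log(v).mean()
        assert fit.s == pytest.approx(s)
        assert fit.alpha == pytest.approx((3 - s + np.sqrt((3 - s) ** 2 + 24 * s)) / (12 * s))
        assert fit.beta == pytest.approx(fit.alpha / v.mean())

    def test_rejects_nonpositive_and_constant(self):
        with pytest.raises(ValueError):
            fit_gamma_mom([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            fit_gamma_mom([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            fit_gamma_mom([1.0])


class TestThresholds:
    def test_exponential_closed_form(self):
        # Gamma(1, 1) is Exp(1); the 0.95 quantile is -ln(0.05)
        assert gamma_threshold(1.0, 1.0, 1) == pytest.approx(-np.log(0.05), abs=1e-9)

    def test_monotone_in_n_tests(self):
        cuts = [gamma_threshold(2.0, 3.0, n) for n in (1, 20, 1000, 413_355)]
        assert all(a < b for a, b in zip(cuts, cuts[1:]))

    def test_matches_root_finding_oracle(self):
        alpha, beta, n = 2.0, 3.0, 413_355
        cut = gamma_threshold(alpha, beta, n)
        target = 1.0 - 0.05 / n
        # invert the regularized incomplete gamma P(alpha, beta x) numerically
        root = optimize.brentq(lambda x: special.gammainc(alpha, beta * x) - target, 1e-12, 100.0,
                               xtol=1e-12)
        assert cut == pytest.approx(root, abs=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gamma_threshold(-1.0, 1.0, 10)
        with pytest.raises(ValueError):
            gamma_threshold(1.0, 1.0, 0)


class TestSmoothing:
    def test_cubic_exact_interpolation(self):
        ks = np.arange(2, 10)
        coef = np.array([0.5, 0.2, -0.01, 0.001])
        alphas = coef[0] + coef[1] * ks + coef[2] * ks**2 + coef[3] * ks**3
        fits = {int(k): GammaClassFit(k=int(k), n_loci=100, s=0.1, alpha=float(al),
                                      beta=5.0 - 4.0 * np.exp(-0.3 * k), mean=1.0)
                for k, al in zip(ks, alphas)}
        sm = smooth_params(fits)
        assert np.allclose(sm.cubic, coef, atol=1e-8)

    def test_brody_recovery_with_noise(self):
        rng = np.random.default_rng(3)
        ks = np.arange(2, 12)
        A, B, kappa = 5.0, 0.8, 0.3
        betas = A * (1 - B * np.exp(-kappa * ks)) + rng.normal(0, 0.01, size=len(ks))
        fits = {int(k): GammaClassFit(k=int(k), n_loci=100, s=0.1, alpha=2.0 + 0.1 * k,
                                      beta=float(b), mean=1.0)
                for k, b in zip(ks, betas)}
        sm = smooth_params(fits)
        assert sm.brody[0] == pytest.approx(A, rel=0.05)
        assert sm.brody[1] == pytest.approx(B, rel=0.05)
        assert sm.brody[2] == pytest.approx(kappa, rel=0.05)
        # asymptote property: beta(t) -> A for large t
        assert float(sm.beta(1000)) == pytest.approx(sm.brody[0], rel=1e-6)

    def test_needs_five_classes(self):
        fits = {k: GammaClassFit(k=k, n_loci=50, s=0.1, alpha=2.0, beta=3.0, mean=1.0)
                for k in (2, 3, 4, 5)}
        with pytest.raises(ValueError, match=">= 5"):
            smooth_params(fits)


class TestCallSignificant:
    def test_boundary_is_flagged_at_cutoff(self):
        import pandas as pd
        fit = GammaClassFit(k=2, n_loci=100, s=0.2, alpha=2.0, beta=3.0, mean=0.5)
        thr = threshold_table(fit, n_tests=100)
        cut = float(thr["cutoff"].iloc[0])
        res = pd.DataFrame({"sigma2": [cut - 1e-9, cut, cut + 1e-9], "k": [2, 2, 2]})
        out = call_significant(res, thr)
        assert out["flagged"].tolist() == [False, True, True]

    def test_missing_k_raises(self):
        import pandas as pd
        fit = GammaClassFit(k=2, n_loci=100, s=0.2, alpha=2.0, beta=3.0, mean=0.5)
        thr = threshold_table(fit, n_tests=100)
        with pytest.raises(ValueError, match="allele counts"):
            call_significant(pd.DataFrame({"sigma2": [0.1], "k": [3]}), thr)
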