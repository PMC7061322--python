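"""Directional correlation suite: frequentist, Bayesian, comparisons."""

import numpy as np
import pingouin as pg
import pytest
from scipy import integrate, special, stats as sps

from navlearn import (
    CorrelationPosterior,
    bonferroni_alpha,
    bootstrap_compare_dependent_correlations,
    default_bf_correlation,
    jzs_bf_partial_correlation,
    partial_correlation,
    pearson_directional,
    posterior_credible_interval,
    spearman_directional,
    steiger_z_dependent,
)


def gaussian_pair(n, r, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = r * x + np.sqrt(1 - r * r) * rng.standard_normal(n)
    return x, y


class TestPearsonDirectional:
    def test_identity_correlation(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        res = pearson_directional(x, x, "greater")
        assert res.estimate == pytest.approx(1.0)

    def test_p_matches_closed_form_t_tail(self):
        """One-sided p equals the t transform computed independently."""
        x, y = gaussian_pair(40, 0.3, 1)
        res = pearson_directional(x, y, "greater", bayes=False)
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt((40 - 2) / (1 - r * r))
        assert res.p == pytest.approx(sps.t.sf(t, 38), abs=1e-12)

    def test_tail_complementarity(self):
        x, y = gaussian_pair(30, -0.2, 2)
        pg_ = pearson_directional(x, y, "greater", bayes=False).p
        pl = pearson_directional(x, y, "less", bayes=False).p
        assert pg_ + pl == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_directional([1, 1, 1, 1], [1, 2, 3, 4])

    def test_affine_invariance_of_p_and_bf(self):
        x, y = gaussian_pair(30, 0.4, 3)
        a = pearson_directional(x, y, "greater")
        b = pearson_directional(2.5 * x + 7, 0.5 * y - 3, "greater")
        assert b.p == pytest.approx(a.p, abs=1e-12)
        assert b.bf == pytest.approx(a.bf, rel=1e-9)


class TestSpearmanDirectional:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 9.0])
        res = spearman_directional(x, np.exp(x), "greater", bayes=False)
        assert res.estimate == pytest.approx(1.0)

    def test_midrank_ties_hand_value(self):
        """(1,1,2,2) vs (1,2,1,2): mid-ranks give rho = 0 exactly."""
        res = spearman_directional([1, 1, 2, 2], [1, 2, 1, 2], bayes=False)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_robust_to_single_outlier(self):
        """One extreme point barely moves rho but swings Pearson r."""
        x, y = gaussian_pair(60, 0.5, 4)
        rho0 = spearman_directional(x, y, bayes=False).estimate
        r0 = pearson_directional(x, y, bayes=False).estimate
        x2 = np.append(x, 30.0)
        y2 = np.append(y, -30.0)
        rho1 = spearman_directional(x2, y2, bayes=False).estimate
        r1 = pearson_directional(x2, y2, bayes=False).estimate
        assert abs(rho1 - rho0) < 0.1
        assert abs(r1 - r0) > 0.2

    def test_monotone_invariance_of_p(self):
        x, y = gaussian_pair(25, 0.3, 5)
        a = spearman_directional(x, y, "greater", bayes=False)
        b = spearman_directional(np.exp(x), y**3, "greater", bayes=False)
        assert b.estimate == pytest.approx(a.estimate, abs=1e-12)
        assert b.p == pytest.approx(a.p, abs=1e-12)


class TestSteigerZ:
    def test_equal_correlations_give_null(self):
        res = steiger_z_dependent(0.4, 0.4, 0.3, 30, "greater")
        assert res.z == 0.0
        assert res.p == pytest.approx(0.5)

    def test_antisymmetry(self):
        a = steiger_z_dependent(0.5, 0.3, 0.2, 50, "two_sided")
        b = steiger_z_dependent(0.3, 0.5, 0.2, 50, "two_sided")
        assert a.z == pytest.approx(-b.z, abs=1e-14)

    def test_matches_independent_formula_evaluation(self):
        """Step-by-step evaluation of the published pooled-r formula,
        written here with no shared code, over 100 random configurations."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            rjk, rjh = rng.uniform(-0.85, 0.85, 2)
            # keep the implied 3x3 correlation matrix positive definite
            centre = rjk * rjh
            width = np.sqrt((1 - rjk**2) * (1 - rjh**2))
            rkh = centre + 0.95 * width * rng.uniform(-1, 1)
            n = int(rng.integers(10, 200))
            res = steiger_z_dependent(rjk, rjh, rkh, n, "greater")
            # independent evaluation
            z1 = 0.5 * np.log((1 + rjk) / (1 - rjk))
            z2 = 0.5 * np.log((1 + rjh) / (1 - rjh))
            rb = (rjk + rjh) / 2
            cov = (
                rkh * (1 - rb**2 - rb**2)
                - 0.5 * (rb**2) * (1 - rb**2 - rb**2 - rkh**2)
            ) / ((1 - rb**2) * (1 - rb**2))
            expected = (z1 - z2) * np.sqrt((n - 3) / (2 - 2 * cov))
            assert res.z == pytest.approx(expected, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            steiger_z_dependent(1.0, 0.3, 0.2, 30)
        with pytest.raises(ValueError):
            steiger_z_dependent(0.5, 0.3, 0.2, 4)


class TestDefaultBayesFactor:
    @pytest.mark.parametrize(
        "r,n",
        [(0.44, 27), (-0.24, 26), (-0.07, 28), (0.3, 15), (0.0, 40)],
    )
    def test_matches_independent_implementation(self, r, n):
        """pingouin implements the same exact reduced-likelihood Bayes
        factor independently; the quadrature agrees to high precision."""
        for alt, pg_alt in [
            ("two_sided", "two-sided"), ("greater", "greater"), ("less", "less")
        ]:
            bf, _ = default_bf_correlation(r, n, alt)
            assert bf == pytest.approx(
                float(pg.bayesfactor_pearson(r, n, alternative=pg_alt)), rel=1e-6
            )

    def test_prior_symmetry_identities(self):
        """At r = 0 the one-sided factors coincide, and in general
        BF10 = (BF+0 + BF-0)/2 for the symmetric prior."""
        bf_plus, _ = default_bf_correlation(0.0, 30, "greater")
        bf_minus, _ = default_bf_correlation(0.0, 30, "less")
        assert bf_plus == pytest.approx(bf_minus, abs=1e-9)
        for r, n in [(-0.5, 12), (0.2, 27), (0.6, 50)]:
            b10, _ = default_bf_correlation(r, n, "two_sided")
            bp, _ = default_bf_correlation(r, n, "greater")
            bm, _ = default_bf_correlation(r, n, "less")
            assert b10 == pytest.approx((bp + bm) / 2, abs=1e-6)

    def test_narrow_prior_shrinks_evidence(self):
        wide, _ = default_bf_correlation(0.4, 30, "greater", prior_width=1.0)
        narrow, _ = default_bf_correlation(0.4, 30, "greater", prior_width=0.5)
        assert narrow != wide

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            default_bf_correlation(1.0, 30)
        with pytest.raises(ValueError):
            default_bf_correlation(0.3, 3)
        with pytest.raises(ValueError):
            default_bf_correlation(0.3, 30, prior_width=0.0)


class TestCredibleInterval:
    def test_endpoints_hit_nominal_tail_mass(self):
        _, post = default_bf_correlation(0.44, 27, "greater")
        lo, hi = posterior_credible_interval(post)
        assert post.cdf(lo) == pytest.approx(0.025, abs=1e-6)
        assert post.cdf(hi) == pytest.approx(0.975, abs=1e-6)

    def test_interval_widens_as_n_shrinks(self):
        widths = []
        for n in (100, 27, 10):
            post = CorrelationPosterior(0.3, n)
            lo, hi = posterior_credible_interval(post)
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_symmetric_at_zero(self):
        post = CorrelationPosterior(0.0, 25)
        lo, hi = posterior_credible_interval(post)
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_posterior_normalised(self):
        post = CorrelationPosterior(0.44, 27)
        assert post.normalization() == pytest.approx(1.0, abs=1e-6)

    def test_unnormalised_posterior_rejected(self):
        post = CorrelationPosterior(0.2, 20)
        post._norm *= 1.5  # corrupt the normalisation
        with pytest.raises(ValueError):
            posterior_credible_interval(post)


class TestPartialCorrelation:
    def test_single_covariate_closed_form(self):
        """Residual method equals the textbook closed form
        (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(10, 80))
            z = rng.standard_normal(n)
            x = 0.5 * z + rng.standard_normal(n)
            y = -0.3 * z + rng.standard_normal(n)
            res = partial_correlation(x, y, z, bayes=False)
            rxy = np.corrcoef(x, y)[0, 1]
            rxz = np.corrcoef(x, z)[0, 1]
            ryz = np.corrcoef(y, z)[0, 1]
            expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            assert res.estimate == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd

        rng = np.random.default_rng(15)
        z = rng.standard_normal(40)
        x = 0.6 * z + rng.standard_normal(40)
        y = 0.4 * z + 0.3 * x + rng.standard_normal(40)
        res = partial_correlation(x, y, z, "two_sided", bayes=False)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        oracle = pg.partial_corr(df, x="x", y="y", covar="z")
        assert res.estimate == pytest.approx(float(oracle["r"].iloc[0]), abs=1e-8)
        assert res.p == pytest.approx(float(oracle["p_val"].iloc[0]), abs=1e-8)

    def test_orthogonal_covariate_reduces_to_zero_order(self):
        rng = np.random.default_rng(9)
        x, y = gaussian_pair(30, 0.5, 10)
        z = rng.standard_normal(30)
        # residualise z against {1, x, y} so it is exactly sample-orthogonal
        X = np.column_stack([np.ones(30), x, y])
        z = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        res = partial_correlation(x, y, z, bayes=False)
        r0 = np.corrcoef(x, y)[0, 1]
        assert res.estimate == pytest.approx(r0, abs=1e-10)

    def test_zero_covariates_equals_zero_order(self):
        x, y = gaussian_pair(25, 0.4, 11)
        res = partial_correlation(x, y, None, "greater", bayes=False)
        zero = pearson_directional(x, y, "greater", bayes=False)
        assert res.estimate == pytest.approx(zero.estimate, abs=1e-12)
        assert res.p == pytest.approx(zero.p, abs=1e-12)

    def test_duplicated_covariate_rejected(self):
        x, y = gaussian_pair(20, 0.3, 12)
        z = np.random.default_rng(0).standard_normal(20)
        with pytest.raises(ValueError):
            partial_correlation(x, y, np.column_stack([z, z]))


class TestJZSPartialBF:
    def test_reduces_to_jzs_correlation_bf(self):
        """With no covariates the BF equals the Zellner-Siow regression
        Bayes factor computed by an independent direct quadrature over g."""
        x, y = gaussian_pair(35, 0.45, 13)
        bf = jzs_bf_partial_correlation(x, y, None, "two_sided")
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        n = 35

        def integrand(g):
            return (
                (1 + g) ** ((n - 2) / 2)
                * (1 + g * (1 - r2)) ** (-(n - 1) / 2)
                * np.sqrt(n / 2) / special.gamma(0.5)
                * g**-1.5 * np.exp(-n / (2 * g))
            )

        oracle, _ = integrate.quad(integrand, 0, np.inf, limit=400)
        assert bf == pytest.approx(oracle, rel=1e-6)

    def test_null_data_favour_null(self):
        rng = np.random.default_rng(16)
        n = 300
        z = rng.standard_normal(n)
        x = 0.5 * z + rng.standard_normal(n)
        y = 0.5 * z + rng.standard_normal(n)  # related only through z
        bf = jzs_bf_partial_correlation(x, y, z, "two_sided")
        assert bf < 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(17)
        z = rng.standard_normal(30)
        x = 0.4 * z + rng.standard_normal(30)
        y = 0.4 * x + rng.standard_normal(30)
        bf1 = jzs_bf_partial_correlation(x, y, z, "greater")
        bf2 = jzs_bf_partial_correlation(1000 * x, y, z, "greater")
        assert bf1 == pytest.approx(bf2, rel=1e-8)

    def test_directional_splits_two_sided(self):
        x, y = gaussian_pair(30, 0.5, 18)
        b10 = jzs_bf_partial_correlation(x, y, None, "two_sided")
        bp = jzs_bf_partial_correlation(x, y, None, "greater")
        bm = jzs_bf_partial_correlation(x, y, None, "less")
        assert bp + bm == pytest.approx(2 * b10, rel=1e-10)
        assert bp > b10 > bm  # evidence concentrates in the observed direction


class TestBootstrapComparison:
    def test_identical_predictors_degenerate(self):
        rng = np.random.default_rng(19)
        y = rng.standard_normal(30)
        x = rng.standard_normal(30)
        res = bootstrap_compare_dependent_correlations(
            y, x, x, n_boot=200, rng=np.random.default_rng(0)
        )
        assert res.observed_difference == 0.0
        assert res.ci_low == res.ci_high == 0.0
        assert not res.significant

    def test_detects_constructed_difference(self):
        """corr(y,x1)=.6 vs corr(y,x2)=0 in the population: the bootstrap
        interval excludes zero at n=500."""
        rng = np.random.default_rng(20)
        n = 500
        y = rng.standard_normal(n)
        x1 = 0.6 * y + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        res = bootstrap_compare_dependent_correlations(
            y, x1, x2, n_boot=500, rng=np.random.default_rng(1)
        )
        assert res.significant
        assert res.ci_low > 0

    def test_deterministic_given_seed(self, rng):
        y, x1 = gaussian_pair(40, 0.5, 21)
        x2 = rng.standard_normal(40)
        a = bootstrap_compare_dependent_correlations(
            y, x1, x2, n_boot=200, rng=np.random.default_rng(5)
        )
        b = bootstrap_compare_dependent_correlations(
            y, x1, x2, n_boot=200, rng=np.random.default_rng(5)
        )
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_observed_difference_within_ci(self, rng):
        y, x1 = gaussian_pair(60, 0.4, 22)
        x2 = rng.standard_normal(60)
        res = bootstrap_compare_dependent_correlations(
            y, x1, x2, n_boot=400, rng=np.random.default_rng(2)
        )
        assert res.ci_low <= res.observed_difference <= res.ci_high

    def test_too_few_resamples_rejected(self, rng):
        y, x1 = gaussian_pair(20, 0.4, 23)
        with pytest.raises(ValueError):
            bootstrap_compare_dependent_correlations(
                y, x1, x1, n_boot=50, rng=rng
            )


class TestBonferroni:
    def test_paper_setting(self):
        assert bonferroni_alpha(0.05, 2) == 0.025

    def test_identity(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
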