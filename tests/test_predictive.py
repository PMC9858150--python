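"""Closed-form prior predictive Student-t densities, Bayes factors and the
hierarchical samplers under each hypothesis."""

import numpy as np
import pytest
from scipy import integrate, stats

from fbstlm import (
    HypothesisModel,
    NIGParams,
    Partition,
    StudentTSpec,
    log_bayes_factor,
    log_bayes_factor_batch,
    mvt_log_density,
    predictive_under_A,
    predictive_under_H,
    sample_under_A,
    sample_under_H,
)
from fbstlm.predictive import mvt_log_density_batch


def nig_pdf_1d(theta, sigma2, m, v, a, b):
    return np.exp(
        stats.invgamma.logpdf(sigma2, a, scale=b)
        + stats.norm.logpdf(theta, loc=m, scale=np.sqrt(sigma2 * v))
    )


class TestPredictiveSpecs:
    def test_under_H_with_centred_identity_prior(self, rng):
        X = np.column_stack([np.ones(6), rng.standard_normal((6, 2))])
        model = HypothesisModel(NIGParams(np.zeros(3), np.eye(3), 3.0, 2.0),
                                Partition(2, 1), X)
        spec = predictive_under_H(model)
        np.testing.assert_allclose(spec.loc, np.zeros(6))
        assert spec.df == 2 * 3.0 + 1
        # bH = b0 (zero prior location), aH = a0 + r/2
        assert spec.coeff == pytest.approx(2.0 / 3.5)
        X1 = X[:, :2]
        np.testing.assert_allclose(spec.scale, spec.coeff * (np.eye(6) + X1 @ X1.T))

    def test_under_A_zero_design(self):
        model = HypothesisModel(NIGParams([0.0], [[1.0]], 3.0, 2.0),
                                Partition(0, 1), np.zeros((4, 1)))
        spec = predictive_under_A(model)
        assert spec.df == 6.0
        np.testing.assert_allclose(spec.scale, (2.0 / 3.0) * np.eye(4))

    def test_under_A_intercept_only_reference_prior(self):
        n = 5
        model = HypothesisModel(NIGParams([0.0], [[1.0]], 3.0, 2.0),
                                Partition(0, 1), np.ones((n, 1)))
        spec = predictive_under_A(model)
        assert spec.df == 6.0
        np.testing.assert_allclose(spec.loc, np.zeros(n))
        np.testing.assert_allclose(
            spec.scale, (2.0 / 3.0) * (np.eye(n) + np.ones((n, n)))
        )

    def test_under_H_quadrature_scalar_case(self, unit_prior_1d):
        """n=1, p=1, s=0: fH(y) = integral of N(y|0, s2) against the
        conditional prior of sigma2 given theta = 0."""
        model = HypothesisModel(unit_prior_1d, Partition(0, 1), np.array([[0.7]]))
        spec = predictive_under_H(model)
        aH, bH = 3.5, 2.0  # a0 + r/2, b0 (m0 = 0)
        for y in (-1.0, 0.0, 0.8, 2.5):
            expected, _ = integrate.quad(
                lambda s2: stats.norm.pdf(y, scale=np.sqrt(s2))
                * stats.invgamma.pdf(s2, aH, scale=bH),
                1e-6, 200.0,
            )
            assert np.exp(mvt_log_density(spec, [y])) == pytest.approx(expected, abs=1e-6)

    def test_under_A_quadrature_scalar_case(self, unit_prior_1d):
        model = HypothesisModel(unit_prior_1d, Partition(0, 1), np.array([[0.7]]))
        spec = predictive_under_A(model)
        for y in (0.0, 1.2):
            expected, _ = integrate.dblquad(
                lambda theta, s2: stats.norm.pdf(y, loc=0.7 * theta, scale=np.sqrt(s2))
                * nig_pdf_1d(theta, s2, 0.0, 1.0, 3.0, 2.0),
                1e-4, 120.0, -25.0, 25.0, epsabs=1e-10,
            )
            assert np.exp(mvt_log_density(spec, [y])) == pytest.approx(expected, abs=1e-6)


class TestMvtDensity:
    def test_normal_limit(self):
        spec = StudentTSpec(df=1e6, loc=[0.0], coeff=1.0)
        for y in (0.0, 1.0, 2.0):
            assert mvt_log_density(spec, [y]) == pytest.approx(
                stats.norm.logpdf(y), abs=1e-3
            )

    def test_univariate_normalisation(self):
        spec = StudentTSpec(df=6.0, loc=[0.3], coeff=0.8)
        total, _ = integrate.quad(
            lambda y: np.exp(mvt_log_density(spec, [y])), -60, 60
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_matches_scipy_multivariate_t(self, rng):
        A = rng.standard_normal((3, 2))
        W = np.array([[1.0, 0.2], [0.2, 0.5]])
        spec = StudentTSpec(df=7.0, loc=[0.1, -0.2, 0.3], coeff=1.3, factor=A, inner=W)
        mvt = stats.multivariate_t(loc=spec.loc, shape=spec.scale, df=7.0)
        Y = rng.standard_normal((20, 3))
        np.testing.assert_allclose(
            mvt_log_density_batch(spec, Y), mvt.logpdf(Y), rtol=1e-10
        )

    def test_bivariate_marginalisation(self):
        """Integrating the second coordinate out of a correlated bivariate t
        must recover the univariate t marginal (same df, scale Sigma11)."""
        A = np.array([[1.0], [0.6]])
        spec = StudentTSpec(df=6.0, loc=[0.0, 0.0], coeff=0.7, factor=A, inner=[[1.0]])
        marg = StudentTSpec(df=6.0, loc=[0.0], coeff=spec.scale[0, 0])
        for y1 in (-1.0, 0.5, 2.0):
            got, _ = integrate.quad(
                lambda y2: np.exp(mvt_log_density(spec, [y1, y2])), -80, 80
            )
            assert got == pytest.approx(np.exp(mvt_log_density(marg, [y1])), rel=1e-6)

    def test_predictives_integrate_to_one_n2(self, unit_prior_1d):
        model = HypothesisModel(unit_prior_1d, Partition(0, 1), np.ones((2, 1)))
        for spec in (predictive_under_H(model), predictive_under_A(model)):
            total, _ = integrate.dblquad(
                lambda y1, y2: np.exp(mvt_log_density(spec, [y1, y2])),
                -40, 40, -40, 40, epsabs=1e-8,
            )
            assert total == pytest.approx(1.0, abs=1e-4)

    def test_monte_carlo_matches_closed_form(self, intercept_model):
        """Averaging the Gaussian likelihood over prior draws converges to
        the closed-form predictive density at a fixed y."""
        model = HypothesisModel(intercept_model.prior, intercept_model.part,
                                np.ones((2, 1)))
        y = np.array([0.4, -0.2])
        rng = np.random.default_rng(11)
        M = 200_000
        sigma2 = model.prior.b / rng.gamma(model.prior.a, size=M)
        theta = rng.normal(0.0, np.sqrt(sigma2))
        lik = np.exp(
            stats.norm.logpdf(y[0], theta, np.sqrt(sigma2))
            + stats.norm.logpdf(y[1], theta, np.sqrt(sigma2))
        )
        mc = lik.mean()
        closed = np.exp(mvt_log_density(predictive_under_A(model), y))
        assert abs(mc - closed) / closed < 0.05


class TestBayesFactor:
    def test_row_permutation_invariance(self, covariate_model, rng):
        y = rng.standard_normal(covariate_model.n)
        perm = rng.permutation(covariate_model.n)
        permuted = HypothesisModel(covariate_model.prior, covariate_model.part,
                                   covariate_model.X[perm])
        assert log_bayes_factor(covariate_model, y) == pytest.approx(
            log_bayes_factor(permuted, y[perm]), rel=1e-10
        )

    def test_quadrature_scalar_case(self, unit_prior_1d):
        model = HypothesisModel(unit_prior_1d, Partition(0, 1), np.array([[1.0]]))
        y0 = 0.9
        fH, _ = integrate.quad(
            lambda s2: stats.norm.pdf(y0, scale=np.sqrt(s2))
            * stats.invgamma.pdf(s2, 3.5, scale=2.0),
            1e-6, 200.0,
        )
        fA, _ = integrate.dblquad(
            lambda theta, s2: stats.norm.pdf(y0, loc=theta, scale=np.sqrt(s2))
            * nig_pdf_1d(theta, s2, 0.0, 1.0, 3.0, 2.0),
            1e-4, 120.0, -25.0, 25.0, epsabs=1e-10,
        )
        assert log_bayes_factor(model, [y0]) == pytest.approx(np.log(fH / fA), abs=1e-6)

    def test_pit_of_bf_under_H_is_uniform(self, intercept_model):
        """F(BF(Y)) with F the fH-sampling CDF of BF must be uniform when
        Y ~ fH (probability integral transform)."""
        M = 2000
        Y = sample_under_H(intercept_model, M, 303).y
        lbf = log_bayes_factor_batch(intercept_model, Y)
        ranks = stats.rankdata(lbf, method="average") / (M + 1)
        assert stats.kstest(ranks, "uniform").pvalue > 0.01


class TestSamplers:
    def test_H_pins_tested_block_to_zero(self, covariate_model):
        sample = sample_under_H(covariate_model, 200, 5)
        assert np.all(sample.draws.theta[:, -1] == 0.0)

    def test_deterministic_under_same_seed(self, covariate_model):
        a = sample_under_A(covariate_model, 100, 17)
        b = sample_under_A(covariate_model, 100, 17)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.draws.sigma2, b.draws.sigma2)

    def test_mean_under_A_matches_prior_predictive_location(self):
        n = 4
        model = HypothesisModel(NIGParams([1.0], [[1.0]], 4.0, 2.0),
                                Partition(0, 1), np.ones((n, 1)))
        sample = sample_under_A(model, 50_000, 23)
        se = sample.y[:, 0].std() / np.sqrt(len(sample))
        assert abs(sample.y[:, 0].mean() - 1.0) < 3 * se

    @pytest.mark.parametrize("which", ["H", "A"])
    def test_first_coordinate_matches_mixture_representation(self, which,
                                                             covariate_model):
        """Two-sample KS between hierarchical draws of y1 and draws from the
        closed-form Student-t via its normal-inverse-gamma mixture."""
        M = 5000
        rng = np.random.default_rng(91)
        if which == "H":
            sample = sample_under_H(covariate_model, M, 7)
            spec = predictive_under_H(covariate_model)
            df = spec.df
        else:
            sample = sample_under_A(covariate_model, M, 7)
            spec = predictive_under_A(covariate_model)
            df = spec.df
        # mixture representation of t_df(loc, Sigma): scale an N(0, Sigma)
        # draw by sqrt(df / chi2_df)
        s11 = spec.scale[0, 0]
        z = rng.normal(0.0, np.sqrt(s11), size=M)
        w = rng.chisquare(df, size=M)
        ref = spec.loc[0] + z * np.sqrt(df / w)
        assert stats.ks_2samp(sample.y[:, 0], ref).pvalue > 0.01

    def test_sigma_first_and_theta_first_schemes_agree(self, covariate_model):
        M = 5000
        a = sample_under_H(covariate_model, M, 31, scheme="sigma-first")
        b = sample_under_H(covariate_model, M, 77, scheme="theta-first")
        assert stats.ks_2samp(a.draws.sigma2, b.draws.sigma2).pvalue > 0.01
        assert stats.ks_2samp(a.y[:, 0], b.y[:, 0]).pvalue > 0.01

    def test_unknown_scheme_rejected(self, covariate_model):
        with pytest.raises(ValueError, match="scheme"):
            sample_under_H(covariate_model, 10, 1, scheme="bogus")
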