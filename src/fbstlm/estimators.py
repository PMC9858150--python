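"""Estimator-style front end: conjugate Bayesian regression and the
per-coefficient significance report.

`BayesLinearRegression` is a scikit-learn regressor whose `fit` performs the
exact normal-inverse-gamma conjugate update; `CoefficientSignificanceTest`
runs, for each requested coefficient, the FBST e-value against its adaptive
cutoff k*, the capital-P P-value against its adaptive level alpha*, and the
classical t-test p-value for reference.  Both compose with sklearn
pipelines and clone/get_params/set_params.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .adaptive import (
    ErrorWeights,
    evalue_error_curves,
    find_kstar,
    optimal_error_rates,
    p_value,
    pvalue_decision,
)
from .conjugate import (
    NIGParams,
    Partition,
    RegressionData,
    move_tested_last,
    ols_estimate,
    permute_params,
    posterior_update,
)
from .fbst import evalue, fbst_decision
from .predictive import HypothesisModel

__all__ = ["BayesLinearRegression", "CoefficientSignificanceTest", "classical_pvalue"]


def classical_pvalue(data: RegressionData, index: int) -> float:
    """Two-sided t-test p-value for nullity of one OLS coefficient.

    Uses the t distribution with n - p degrees of freedom.  A (numerically)
    zero residual variance leaves the statistic undefined and is an error.
    """
    n, p = data.n, data.p
    if n <= p:
        raise ValueError("need n > p for the residual t-test")
    theta = ols_estimate(data)
    resid = data.y - data.X @ theta
    rss = float(resid @ resid)
    scale = float(data.y @ data.y) if data.y.any() else 1.0
    if rss <= 1e-12 * max(scale, 1.0):
        raise ValueError("zero residual variance: t statistic undefined")
    s2 = rss / (n - p)
    XtX_inv = np.linalg.inv(data.X.T @ data.X)
    se = np.sqrt(s2 * XtX_inv[index, index])
    t = theta[index] / se
    return float(2.0 * stats.t.sf(abs(t), n - p))


def _build_prior(p, prior_mean, prior_scale, prior_shape, prior_rate) -> NIGParams:
    m0 = np.broadcast_to(np.asarray(prior_mean, dtype=float).ravel(), (p,)).copy() \
        if np.ndim(prior_mean) <= 1 and np.size(prior_mean) in (1, p) else None
    if m0 is None:
        raise ValueError("prior_mean must be a scalar or length-p vector")
    V0 = np.asarray(prior_scale, dtype=float)
    if V0.ndim == 0:
        V0 = float(V0) * np.eye(p)
    elif V0.ndim == 1:
        V0 = np.diag(V0)
    return NIGParams(m0, V0, prior_shape, prior_rate)


class BayesLinearRegression(RegressorMixin, BaseEstimator):
    """Conjugate Bayesian linear regression with unknown noise variance.

    Parameters
    ----------
    prior_mean : float or array, default 0.0
        Location of the coefficient prior (broadcast over coefficients,
        intercept included).
    prior_scale : float, 1-D or 2-D array, default 1.0
        V0 in theta | sigma2 ~ N(m0, sigma2 V0); a scalar means V0 = c I.
    prior_shape, prior_rate : float, default 3.0 and 2.0
        Inverse-gamma prior on sigma2.
    fit_intercept : bool, default True
        Prepend a column of ones to the design.

    Attributes
    ----------
    posterior_ : NIGParams over the full coefficient vector (intercept first).
    coef_, intercept_ : posterior-mean point estimates.
    sigma2_ : posterior mean of the noise variance (b1 / (a1 - 1)).
    """

    def __init__(self, prior_mean=0.0, prior_scale=1.0, prior_shape=3.0,
                 prior_rate=2.0, fit_intercept=True):
        self.prior_mean = prior_mean
        self.prior_scale = prior_scale
        self.prior_shape = prior_shape
        self.prior_rate = prior_rate
        self.fit_intercept = fit_intercept

    def _design(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(X.shape[0]), X]) if self.fit_intercept else X

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        D = self._design(X)
        prior = _build_prior(D.shape[1], self.prior_mean, self.prior_scale,
                             self.prior_shape, self.prior_rate)
        self.prior_ = prior
        self.posterior_ = posterior_update(prior, RegressionData(D, y))
        mean = self.posterior_.m
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(mean[0]), mean[1:]
        else:
            self.intercept_, self.coef_ = 0.0, mean
        a1, b1 = self.posterior_.a, self.posterior_.b
        self.sigma2_ = b1 / (a1 - 1.0) if a1 > 1 else np.inf
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X @ self.coef_ + self.intercept_


class CoefficientSignificanceTest(BaseEstimator):
    """Per-coefficient sharp-null testing with adaptive thresholds.

    For each tested coefficient j the null H: theta_j = 0 is evaluated
    three ways on the same conjugate model: the FBST e-value against its
    adaptive cutoff k*(n, d), the capital-P P-value against the adaptive
    significance level alpha*, and the classical t-test p-value.  Testing a
    coefficient permutes it to the last position (the canonical tested
    block) together with the prior.

    Parameters
    ----------
    tested : "each", int, or sequence of ints, default "each"
        Which coefficients of the full design (intercept = 0 when
        ``fit_intercept``) to test, one at a time.
    weight_a, weight_b : float, default 1.0
        Relative seriousness of type-I and type-II errors.
    m_outer, m_inner : int, default 1000
        Datasets per hypothesis for the k* error curves, and posterior
        draws per e-value inside them.
    m_evidence : int, default 1000
        Monte Carlo size for the observed e-value and P-value.
    random_state : int or None
        Master seed; every stream below derives from it.

    Attributes
    ----------
    report_ : pandas.DataFrame, one row per tested coefficient with the
        estimates, evidence values, adaptive thresholds and decisions.
    """

    def __init__(self, tested="each", prior_mean=0.0, prior_scale=1.0,
                 prior_shape=3.0, prior_rate=2.0, weight_a=1.0, weight_b=1.0,
                 m_outer=1000, m_inner=1000, m_evidence=1000,
                 fit_intercept=True, random_state=None):
        self.tested = tested
        self.prior_mean = prior_mean
        self.prior_scale = prior_scale
        self.prior_shape = prior_shape
        self.prior_rate = prior_rate
        self.weight_a = weight_a
        self.weight_b = weight_b
        self.m_outer = m_outer
        self.m_inner = m_inner
        self.m_evidence = m_evidence
        self.fit_intercept = fit_intercept
        self.random_state = random_state

    def _tested_indices(self, p: int):
        if isinstance(self.tested, str):
            if self.tested != "each":
                raise ValueError("tested must be 'each', an int, or a sequence")
            return list(range(p))
        return [int(j) for j in np.atleast_1d(self.tested)]

    def fit(self, X, y, feature_names=None):
        X, y = validate_data(self, X, y, y_numeric=True)
        D = np.column_stack([np.ones(X.shape[0]), X]) if self.fit_intercept else X
        n, p = D.shape
        data = RegressionData(D, y)
        prior = _build_prior(p, self.prior_mean, self.prior_scale,
                             self.prior_shape, self.prior_rate)
        w = ErrorWeights(self.weight_a, self.weight_b)
        theta_ols = ols_estimate(data)
        theta_bayes = posterior_update(prior, data).m
        if feature_names is None:
            names = [f"x{j}" for j in range(1, X.shape[1] + 1)]
        else:
            names = list(feature_names)
        if self.fit_intercept:
            names = ["intercept"] + names
        master = self.random_state if self.random_state is not None else 0

        rows = []
        for j in self._tested_indices(p):
            perm = move_tested_last(p, [j])
            part = Partition(s=p - 1, r=1)
            model = HypothesisModel(permute_params(prior, perm), part, D[:, perm])
            post = posterior_update(model.prior, RegressionData(model.X, y))

            seeds = {
                stage: np.random.SeedSequence(master, spawn_key=(j, k))
                for k, stage in enumerate(("ev", "curve", "pv", "rates"))
            }
            ev = evalue(post, part, self.m_evidence, np.random.default_rng(seeds["ev"]))
            ks = find_kstar(
                evalue_error_curves(model, self.m_outer, self.m_inner, seeds["curve"]), w
            )
            pv = p_value(model, y, self.m_evidence, seeds["pv"])
            rates = optimal_error_rates(model, w, self.m_outer, seeds["rates"])
            rows.append({
                "coef": names[j],
                "theta_ols": float(theta_ols[j]),
                "theta_bayes": float(theta_bayes[j]),
                "p_classical": classical_pvalue(data, j),
                "evalue": ev.evalue,
                "evalue_se": ev.mc_se,
                "kstar": ks.kstar,
                "reject_fbst": fbst_decision(ev, ks.kstar),
                "alpha_e": ks.alpha,
                "beta_e": ks.beta,
                "p_value": pv,
                "alpha_star": rates.alpha,
                "beta_star": rates.beta,
                "reject_pvalue": pvalue_decision(pv, rates.alpha),
            })
        self.report_ = pd.DataFrame(rows)
        return self
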