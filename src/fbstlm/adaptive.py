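"""Adaptive decision thresholds: the e-value cutoff k* and the P-value test.

Both tests calibrate themselves against the *averaged* (prior-predictive)
error probabilities rather than a fixed 5% level:

* phi_e rejects H when the e-value falls at or below k*(n, d), the cutoff
  minimising a weighted sum a*alpha(k) + b*beta(k) of the averaged type-I
  and type-II error probabilities, estimated by Monte Carlo over datasets
  drawn from the predictive densities fH and fA.
* phi* rejects H when the Bayes factor BF = fH/fA is at most b/a; the
  generalized Neyman-Pearson lemma makes this the minimiser of
  a*alpha + b*beta among all tests of fH against fA.  Its evidence scale is
  the capital-P P-value, the fH-probability of observing a Bayes factor no
  larger than the observed one, and its adaptive significance level is
  alpha* = P_fH(BF <= b/a).

Both thresholds shrink as the sample size grows, which is the point: with a
fixed level, large samples reject every sharp null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .conjugate import _symmetrize
from .fbst import _evalues_from_summaries
from .predictive import (
    HypothesisModel,
    log_bayes_factor_batch,
    sample_under_A,
    sample_under_H,
)

__all__ = [
    "ErrorWeights",
    "ErrorCurve",
    "AdaptiveResult",
    "evalue_error_curves",
    "find_kstar",
    "p_value",
    "optimal_error_rates",
    "pvalue_decision",
]


def _streams(seed, count: int):
    """Independent child generators derived from one master seed.

    The split is a fixed-order SeedSequence spawn, so every consumer sees
    the same stream for the same master seed regardless of call order.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(count)]


@dataclass(frozen=True)
class ErrorWeights:
    """Relative seriousness of type-I (a) and type-II (b) errors; only the
    ratio b/a enters the Bayes-factor test."""

    a: float = 1.0
    b: float = 1.0

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("error weights must be positive")

    @property
    def log_threshold(self) -> float:
        return float(np.log(self.b / self.a))


@dataclass(frozen=True)
class ErrorCurve:
    """Sorted e-value samples under fH and fA with the induced step functions
    alpha(k) = frac(ev_H <= k) and beta(k) = frac(ev_A > k)."""

    ev_H: np.ndarray
    ev_A: np.ndarray

    def __post_init__(self):
        for name in ("ev_H", "ev_A"):
            v = np.sort(np.asarray(getattr(self, name), dtype=float).ravel())
            if v.size == 0:
                raise ValueError(f"{name} must be nonempty")
            if v[0] < 0 or v[-1] > 1:
                raise ValueError("e-values must lie in [0, 1]")
            object.__setattr__(self, name, v)

    def alpha(self, k):
        """Averaged type-I error of rejecting when the e-value is <= k."""
        return np.searchsorted(self.ev_H, k, side="right") / self.ev_H.size

    def beta(self, k):
        """Averaged type-II error of accepting when the e-value is > k."""
        return 1.0 - np.searchsorted(self.ev_A, k, side="right") / self.ev_A.size


@dataclass(frozen=True)
class AdaptiveResult:
    """An adaptive threshold with the error rates attained at it."""

    kstar: float | None = None
    alpha: float = np.nan
    beta: float = np.nan
    objective: float = np.nan
    weights: ErrorWeights = field(default_factory=ErrorWeights)
    alpha_se: float = np.nan
    beta_se: float = np.nan
    mc_sizes: tuple = ()
    seed: int | None = None


def _posterior_null_summaries(model: HypothesisModel, Y: np.ndarray):
    """(a1, u) for a batch of datasets sharing the design X.

    u_j = Q_H / (2 b1) per dataset, where Q_H = m*2' (V*22)^-1 m*2 is the
    null offset of the posterior location; with X fixed, V* is shared and
    only m* and b1 vary across datasets.
    """
    prior, X, s = model.prior, model.X, model.part.s
    n, p = X.shape
    c0 = cho_factor(prior.V, lower=True)
    V0inv_m0 = cho_solve(c0, prior.m)
    prec = _symmetrize(cho_solve(c0, np.eye(p)) + X.T @ X)  # V*^-1
    cP = cho_factor(prec, lower=True)
    B = V0inv_m0[:, None] + X.T @ Y.T  # (p, M)
    Mstar = cho_solve(cP, B)
    quad_m = (B * Mstar).sum(axis=0)  # m*' V*^-1 m*
    b1 = prior.b + (prior.m @ V0inv_m0 + (Y * Y).sum(axis=1) - quad_m) / 2.0
    if s == 0:
        QH = quad_m
    else:
        # (V*22)^-1 is the Schur complement prec22 - prec21 prec11^-1 prec12
        c11 = cho_factor(prec[:s, :s], lower=True)
        S22 = _symmetrize(prec[s:, s:] - prec[s:, :s] @ cho_solve(c11, prec[:s, s:]))
        m2 = Mstar[s:, :]
        QH = (m2 * (S22 @ m2)).sum(axis=0)
    a1 = prior.a + n / 2.0
    return a1, QH / (2.0 * b1)


def evalue_error_curves(
    model: HypothesisModel, M_outer: int, M_inner: int, seed=None
) -> ErrorCurve:
    """Monte Carlo error curves for the FBST test over cutoffs k.

    Draws ``M_outer`` datasets from each of fH and fA, computes each
    dataset's posterior and its e-value from ``M_inner`` posterior draws
    (via the scalar sufficient-statistic reduction of the tangential-set
    indicator), and returns the two sorted e-value samples.
    """
    if M_outer < 1 or M_inner < 1:
        raise ValueError("Monte Carlo sizes must be >= 1")
    rng_H, rng_A, rng_eH, rng_eA = _streams(seed, 4)
    YH = sample_under_H(model, M_outer, rng_H).y
    YA = sample_under_A(model, M_outer, rng_A).y
    a1, uH = _posterior_null_summaries(model, YH)
    _, uA = _posterior_null_summaries(model, YA)
    p = model.p
    ev_H = _evalues_from_summaries(a1, p, uH, M_inner, rng_eH)
    ev_A = _evalues_from_summaries(a1, p, uA, M_inner, rng_eA)
    return ErrorCurve(ev_H, ev_A)


def find_kstar(curve: ErrorCurve, w: ErrorWeights = ErrorWeights()) -> AdaptiveResult:
    """Exact minimiser of a*alpha(k) + b*beta(k) over cutoffs k.

    The Monte Carlo objective is a step function whose jumps sit at the
    sampled e-values, so the minimum over [0, 1] is attained on the finite
    candidate set {0} U ev_H U ev_A; ties go to the smallest k.
    """
    cand = np.unique(np.concatenate([[0.0], curve.ev_H, curve.ev_A]))
    alpha = curve.alpha(cand)
    beta = curve.beta(cand)
    obj = w.a * alpha + w.b * beta
    i = int(np.argmin(obj))  # argmin returns the first (smallest-k) minimiser
    nH, nA = curve.ev_H.size, curve.ev_A.size
    return AdaptiveResult(
        kstar=float(cand[i]),
        alpha=float(alpha[i]),
        beta=float(beta[i]),
        objective=float(obj[i]),
        weights=w,
        alpha_se=float(np.sqrt(alpha[i] * (1 - alpha[i]) / nH)),
        beta_se=float(np.sqrt(beta[i] * (1 - beta[i]) / nA)),
        mc_sizes=(nH, nA),
    )


def p_value(model: HypothesisModel, y0: np.ndarray, M: int = 1000, seed=None) -> float:
    """Capital-P P-value: fH-probability that BF(Y) <= BF(y0), by Monte Carlo."""
    if M < 1:
        raise ValueError("M must be >= 1")
    (rng,) = _streams(seed, 1)
    y0 = np.asarray(y0, dtype=float).ravel()
    log_bf0 = log_bayes_factor_batch(model, y0[None, :])[0]
    Y = sample_under_H(model, M, rng).y
    return float(np.mean(log_bayes_factor_batch(model, Y) <= log_bf0))


def optimal_error_rates(
    model: HypothesisModel, w: ErrorWeights = ErrorWeights(), M: int = 1000, seed=None
) -> AdaptiveResult:
    """Averaged error rates of the optimal Bayes-factor test phi*.

    alpha* = P_fH(BF <= b/a) is the adaptive significance level; beta* =
    P_fA(BF > b/a).  Estimated from M predictive draws under each hypothesis.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng_H, rng_A = _streams(seed, 2)
    t = w.log_threshold
    YH = sample_under_H(model, M, rng_H).y
    YA = sample_under_A(model, M, rng_A).y
    alpha = float(np.mean(log_bayes_factor_batch(model, YH) <= t))
    beta = float(np.mean(log_bayes_factor_batch(model, YA) > t))
    return AdaptiveResult(
        kstar=None,
        alpha=alpha,
        beta=beta,
        objective=w.a * alpha + w.b * beta,
        weights=w,
        alpha_se=float(np.sqrt(alpha * (1 - alpha) / M)),
        beta_se=float(np.sqrt(beta * (1 - beta) / M)),
        mc_sizes=(M, M),
    )


def pvalue_decision(pv: float, alpha_star: float) -> bool:
    """Reject H iff the P-value is strictly below the adaptive level."""
    if not (0.0 <= pv <= 1.0 and 0.0 <= alpha_star <= 1.0):
        raise ValueError("P-value and level must lie in [0, 1]")
    return pv < alpha_star
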