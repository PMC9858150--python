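"""Prior predictive densities under the null and alternative hypotheses.

For the sharp hypothesis H: theta2 = 0 on the last r coefficients, the prior
predictive law of y (the marginal likelihood viewed as a density over the
sample space) is multivariate Student-t under both hypotheses:

* under A (full prior):        t_n(2 a0;  X m0,  (b0/a0) (I_n + X V0 X'))
* under H (prior given theta2=0):
      t_n(2 a0 + r;  X1 mH,  (bH/aH) (I_n + X1 VH X1'))
  where (mH, VH, aH, bH) is the conditional NIG law of (theta1, sigma2)
  given theta2 = 0 and X1 holds the first s design columns.

The ratio fH(y)/fA(y) is the Bayes factor for H against A.  Scale matrices
are kept in the low-rank form c (I_n + A W A') so density evaluation costs
O(n p^2) via the Woodbury identity and the matrix determinant lemma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

from .conjugate import (
    NIGParams,
    ParamDraws,
    Partition,
    _as_rng,
    _chol_lower,
    _symmetrize,
    condition_on_block,
)

__all__ = [
    "StudentTSpec",
    "HypothesisModel",
    "PredictiveSample",
    "predictive_under_H",
    "predictive_under_A",
    "mvt_log_density",
    "mvt_log_density_batch",
    "log_bayes_factor",
    "log_bayes_factor_batch",
    "sample_under_H",
    "sample_under_A",
]


@dataclass(frozen=True)
class StudentTSpec:
    """An n-variate Student-t density t_n(df; loc, Sigma).

    The scale matrix is stored structurally as ``Sigma = coeff * (I_n + A W A')``
    with ``A`` an n x q factor and ``W`` a q x q PD matrix; ``A = None`` means
    ``Sigma = coeff * I_n``.  ``scale`` materialises the dense matrix.
    """

    df: float
    loc: np.ndarray
    coeff: float
    factor: np.ndarray | None = None
    inner: np.ndarray | None = None

    def __post_init__(self):
        if not self.df > 0:
            raise ValueError("degrees of freedom must be positive")
        if not self.coeff > 0:
            raise ValueError("scale coefficient must be positive")
        loc = np.asarray(self.loc, dtype=float).ravel()
        object.__setattr__(self, "loc", loc)
        if self.factor is not None:
            A = np.atleast_2d(np.asarray(self.factor, dtype=float))
            W = _symmetrize(np.atleast_2d(np.asarray(self.inner, dtype=float)))
            if A.shape[0] != loc.size or A.shape[1] != W.shape[0]:
                raise ValueError("factor/inner dimensions inconsistent with loc")
            if A.shape[1] == 0:
                A, W = None, None
            else:
                _chol_lower(W, "inner scale matrix")
            object.__setattr__(self, "factor", A)
            object.__setattr__(self, "inner", W)

    @property
    def dim(self) -> int:
        return self.loc.size

    @property
    def scale(self) -> np.ndarray:
        """Dense scale matrix (avoid for very large n)."""
        n = self.dim
        S = np.eye(n)
        if self.factor is not None:
            S = S + self.factor @ self.inner @ self.factor.T
        return self.coeff * S


@dataclass(frozen=True)
class HypothesisModel:
    """A testing problem: NIG prior, coefficient partition, fixed design X."""

    prior: NIGParams
    part: Partition
    X: np.ndarray

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[1] != self.prior.p or self.part.p != self.prior.p:
            raise ValueError(
                f"inconsistent dimensions: X has {X.shape[1]} columns, "
                f"prior p={self.prior.p}, partition p={self.part.p}"
            )
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class PredictiveSample:
    """Hierarchically sampled datasets with their latent parameter draws."""

    y: np.ndarray  # (count, n)
    draws: ParamDraws

    def __len__(self) -> int:
        return self.y.shape[0]

    def __iter__(self):
        for j in range(len(self)):
            yield self.y[j], self.draws[j]


def _conditional_under_H(model: HypothesisModel) -> NIGParams:
    return condition_on_block(model.prior, model.part, np.zeros(model.part.r))


def predictive_under_H(model: HypothesisModel) -> StudentTSpec:
    """Prior predictive t-density of y given theta2 = 0."""
    cond = _conditional_under_H(model)
    s = model.part.s
    X1 = model.X[:, :s]
    loc = X1 @ cond.m if s else np.zeros(model.n)
    return StudentTSpec(
        df=2.0 * model.prior.a + model.part.r,
        loc=loc,
        coeff=cond.b / cond.a,
        factor=X1 if s else None,
        inner=cond.V if s else None,
    )


def predictive_under_A(model: HypothesisModel) -> StudentTSpec:
    """Prior predictive t-density of y under the unrestricted prior."""
    prior = model.prior
    return StudentTSpec(
        df=2.0 * prior.a,
        loc=model.X @ prior.m,
        coeff=prior.b / prior.a,
        factor=model.X,
        inner=prior.V,
    )


def mvt_log_density_batch(spec: StudentTSpec, Y: np.ndarray) -> np.ndarray:
    """Log density of t_n(df; loc, Sigma) at each row of Y (shape (M, n))."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = spec.dim
    if Y.shape[1] != n:
        raise ValueError(f"Y rows must have length {n}")
    R = Y - spec.loc
    if spec.factor is None:
        quad = (R * R).sum(axis=1) / spec.coeff
        logdet = n * np.log(spec.coeff)
    else:
        A, W = spec.factor, spec.inner
        cW = cho_factor(W, lower=True)
        # Woodbury: (I + A W A')^-1 = I - A (W^-1 + A'A)^-1 A'
        Minner = _symmetrize(cho_solve(cW, np.eye(W.shape[0])) + A.T @ A)
        cM = cho_factor(Minner, lower=True)
        AtR = A.T @ R.T  # (q, M)
        quad = ((R * R).sum(axis=1) - (AtR * cho_solve(cM, AtR)).sum(axis=0)) / spec.coeff
        # determinant lemma: |I + A W A'| = |W| |W^-1 + A'A|
        logdet = (
            n * np.log(spec.coeff)
            + 2.0 * np.log(np.diag(cW[0])).sum()
            + 2.0 * np.log(np.diag(cM[0])).sum()
        )
    df = spec.df
    return (
        gammaln((df + n) / 2.0)
        - gammaln(df / 2.0)
        - n / 2.0 * np.log(df * np.pi)
        - logdet / 2.0
        - (df + n) / 2.0 * np.log1p(quad / df)
    )


def mvt_log_density(spec: StudentTSpec, y: np.ndarray) -> float:
    """Log density of the multivariate Student-t at a single point y."""
    y = np.asarray(y, dtype=float).ravel()
    return float(mvt_log_density_batch(spec, y[None, :])[0])


def log_bayes_factor(model: HypothesisModel, y: np.ndarray) -> float:
    """log BF(y) = log fH(y) - log fA(y); BF <= 1 favours the alternative."""
    return mvt_log_density(predictive_under_H(model), y) - mvt_log_density(
        predictive_under_A(model), y
    )


def log_bayes_factor_batch(model: HypothesisModel, Y: np.ndarray) -> np.ndarray:
    specH = predictive_under_H(model)
    specA = predictive_under_A(model)
    return mvt_log_density_batch(specH, Y) - mvt_log_density_batch(specA, Y)


def sample_under_H(
    model: HypothesisModel, count: int, seed, scheme: str = "sigma-first"
) -> PredictiveSample:
    """Hierarchical draws of (y, theta, sigma2) with theta2 pinned at zero.

    ``sigma-first`` draws sigma2 ~ IG(aH, bH) then theta1 | sigma2 from the
    conditional normal; ``theta-first`` draws theta1 from its marginal
    Student-t and sigma2 from its inverse-gamma conditional given theta.
    The two factorisations of the same joint law are distributionally equal
    (the second is kept as a cross-check).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = _as_rng(seed)
    cond = _conditional_under_H(model)
    s, r, p = model.part.s, model.part.r, model.p
    theta = np.zeros((count, p))
    if scheme == "sigma-first":
        sigma2 = cond.b / rng.gamma(cond.a, size=count)
        if s:
            z = rng.standard_normal((count, s))
            theta[:, :s] = cond.m + np.sqrt(sigma2)[:, None] * (z @ _chol_lower(cond.V).T)
    elif scheme == "theta-first":
        prior = model.prior
        if s:
            df = 2.0 * prior.a + r
            L = _chol_lower((cond.b / cond.a) * cond.V)
            z = rng.standard_normal((count, s))
            q = rng.chisquare(df, size=count)
            theta[:, :s] = cond.m + np.sqrt(df / q)[:, None] * (z @ L.T)
        c0 = cho_factor(prior.V, lower=True)
        diff = theta - prior.m
        quad = (diff.T * cho_solve(c0, diff.T)).sum(axis=0)
        sigma2 = (prior.b + quad / 2.0) / rng.gamma(prior.a + p / 2.0, size=count)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    eps = rng.standard_normal((count, model.n))
    y = theta @ model.X.T + np.sqrt(sigma2)[:, None] * eps
    return PredictiveSample(y, ParamDraws(theta, sigma2))


def sample_under_A(model: HypothesisModel, count: int, seed) -> PredictiveSample:
    """Hierarchical draws under the unrestricted prior:
    sigma2 ~ IG(a0, b0), theta | sigma2 ~ N_p(m0, sigma2 V0), y | . ~ N_n."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = _as_rng(seed)
    prior = model.prior
    sigma2 = prior.b / rng.gamma(prior.a, size=count)
    z = rng.standard_normal((count, prior.p))
    theta = prior.m + np.sqrt(sigma2)[:, None] * (z @ _chol_lower(prior.V).T)
    eps = rng.standard_normal((count, model.n))
    y = theta @ model.X.T + np.sqrt(sigma2)[:, None] * eps
    return PredictiveSample(y, ParamDraws(theta, sigma2))
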