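"""Conjugate normal-inverse-gamma inference for the Gaussian linear model.

The sampling model is ``y = X theta + eps`` with ``eps ~ N_n(0, sigma2 I_n)``
and unknown variance.  The natural conjugate prior on ``(theta, sigma2)`` is
the p-variate normal-inverse-gamma law NIG(m, V, a, b): ``sigma2`` is
inverse-gamma(a, b) and ``theta | sigma2`` is N_p(m, sigma2 V).  Conjugacy
gives a closed-form posterior, closed-form conditionals on any coefficient
block (Schur complements), and cheap exact sampling -- the three ingredients
every test in this package is built from.

All density work is done in log space and all solves go through Cholesky
factorisations; explicit inverses appear only where a quadratic form demands
the precision matrix, and then as a triangular solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import gammaln

__all__ = [
    "RegressionData",
    "NIGParams",
    "Partition",
    "ParamDraw",
    "ParamDraws",
    "posterior_update",
    "condition_on_block",
    "nig_log_density",
    "nig_sample",
    "ols_estimate",
    "move_tested_last",
    "permute_params",
]

_SYM_TOL = 1e-8


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence or a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _symmetrize(V: np.ndarray) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.size and not np.allclose(V, V.T, rtol=_SYM_TOL, atol=_SYM_TOL):
        raise ValueError("scale matrix is not symmetric within tolerance")
    return (V + V.T) / 2.0


def _chol_lower(V: np.ndarray, what: str = "scale matrix") -> np.ndarray:
    """Lower Cholesky factor; raises ValueError if V is not positive definite."""
    if V.shape[0] == 0:
        return V.copy()
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{what} is not positive definite") from exc


@dataclass(frozen=True)
class RegressionData:
    """Design matrix and response for one regression dataset.

    By convention the first column of ``X`` is all ones (the intercept)
    unless the model deliberately omits it.
    """

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
            )
        if X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("need at least one observation and one coefficient")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite (no missing values)")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class NIGParams:
    """Hyperparameters of a normal-inverse-gamma law on (theta, sigma2).

    ``m``: location of theta (length p); ``V``: symmetric positive-definite
    scale so that theta | sigma2 ~ N_p(m, sigma2 V); ``a``/``b``: shape and
    rate of the inverse-gamma law of sigma2.  p = 0 (an empty coefficient
    block, as arises when conditioning on every coefficient) is allowed.
    """

    m: np.ndarray
    V: np.ndarray
    a: float
    b: float

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float).ravel()
        V = _symmetrize(np.atleast_2d(np.asarray(self.V, dtype=float)))
        if m.size == 0:
            V = np.zeros((0, 0))
        if V.shape != (m.size, m.size):
            raise ValueError(f"V must be {m.size}x{m.size}, got {V.shape}")
        if not (self.a > 0 and self.b > 0):
            raise ValueError("shape a and rate b must be positive")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "a", float(self.a))
        object.__setattr__(self, "b", float(self.b))
        # validate positive definiteness eagerly
        _chol_lower(V)

    @property
    def p(self) -> int:
        return self.m.size

    def chol_V(self) -> np.ndarray:
        return _chol_lower(self.V)


@dataclass(frozen=True)
class Partition:
    """Split of the p coefficients into a free block theta1 (first s) and a
    tested block theta2 (last r).  d = s + r + 1 counts sigma2 as well."""

    s: int
    r: int

    def __post_init__(self):
        if self.s < 0 or self.r < 1:
            raise ValueError("need s >= 0 and r >= 1")

    @property
    def p(self) -> int:
        return self.s + self.r

    @property
    def d(self) -> int:
        return self.p + 1


@dataclass(frozen=True)
class ParamDraw:
    """One point (theta, sigma2) of the parameter space."""

    theta: np.ndarray
    sigma2: float

    def __post_init__(self):
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float).ravel())
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")


@dataclass(frozen=True)
class ParamDraws:
    """Array-backed collection of posterior draws (rows of theta, sigma2)."""

    theta: np.ndarray  # (M, p)
    sigma2: np.ndarray  # (M,)
    seed: int | None = field(default=None)

    def __len__(self) -> int:
        return self.sigma2.shape[0]

    def __getitem__(self, j: int) -> ParamDraw:
        return ParamDraw(self.theta[j], float(self.sigma2[j]))

    def __iter__(self):
        for j in range(len(self)):
            yield self[j]


def posterior_update(prior: NIGParams, data: RegressionData) -> NIGParams:
    """Exact conjugate update of a NIG prior with a Gaussian regression dataset.

    Returns NIG(m*, V*, a1, b1) with

        V* = (V0^-1 + X'X)^-1
        m* = V* (V0^-1 m0 + X'y)
        a1 = a0 + n/2
        b1 = b0 + (m0' V0^-1 m0 + y'y - m*' V*^-1 m*) / 2
    """
    X, y = data.X, data.y
    if data.p != prior.p:
        raise ValueError(f"prior has p={prior.p} but design has p={data.p}")
    c0 = cho_factor(prior.V, lower=True)
    V0inv = cho_solve(c0, np.eye(prior.p))
    V0inv_m0 = cho_solve(c0, prior.m)
    prec = V0inv + X.T @ X  # V*^-1, PD whenever V0 is
    cP = cho_factor(_symmetrize(prec), lower=True)
    m_star = cho_solve(cP, V0inv_m0 + X.T @ y)
    V_star = _symmetrize(cho_solve(cP, np.eye(prior.p)))
    a1 = prior.a + data.n / 2.0
    b1 = prior.b + (prior.m @ V0inv_m0 + y @ y - m_star @ prec @ m_star) / 2.0
    # b1 > 0 holds analytically (it is b0 plus half a residual sum of squares
    # in the augmented system); guard against catastrophic cancellation.
    assert b1 > 0, "posterior rate must be positive"
    return NIGParams(m_star, V_star, a1, b1)


def condition_on_block(
    params: NIGParams, part: Partition, theta2: np.ndarray
) -> NIGParams:
    """NIG law of (theta1, sigma2) given the tested block theta2.

    Schur-complement conditioning of the joint NIG: location
    ``m1 + V12 V22^-1 (theta2 - m2)``, scale ``V11 - V12 V22^-1 V21``, shape
    ``a + r/2`` and rate ``b + (theta2 - m2)' V22^-1 (theta2 - m2) / 2``.
    With s = 0 the location/scale are empty and only (a, b) update.
    """
    s, r = part.s, part.r
    if part.p != params.p:
        raise ValueError(f"partition covers p={part.p} but params have p={params.p}")
    theta2 = np.asarray(theta2, dtype=float).ravel()
    if theta2.size != r:
        raise ValueError(f"theta2 must have length r={r}")
    V = params.V
    V22 = V[s:, s:]
    try:
        c22 = cho_factor(V22, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise np.linalg.LinAlgError("tested-block scale V22 is singular") from exc
    diff = theta2 - params.m[s:]
    w = cho_solve(c22, diff)
    a_new = params.a + r / 2.0
    b_new = params.b + diff @ w / 2.0
    if s == 0:
        return NIGParams(np.zeros(0), np.zeros((0, 0)), a_new, b_new)
    V12 = V[:s, s:]
    m_cond = params.m[:s] + V12 @ w
    V_cond = _symmetrize(V[:s, :s] - V12 @ cho_solve(c22, V12.T))
    return NIGParams(m_cond, V_cond, a_new, b_new)


def _nig_log_density_arrays(
    params: NIGParams, theta: np.ndarray, sigma2: np.ndarray
) -> np.ndarray:
    """Vectorised log NIG density; theta (M, p), sigma2 (M,)."""
    p = params.p
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    sigma2 = np.asarray(sigma2, dtype=float).ravel()
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    a, b = params.a, params.b
    log_norm = a * np.log(b) - gammaln(a)
    if p:
        L = params.chol_V()
        z = solve_triangular(L, (theta - params.m).T, lower=True)
        quad = (z * z).sum(axis=0)
        log_norm -= p / 2.0 * np.log(2.0 * np.pi) + np.log(np.diag(L)).sum()
    else:
        quad = np.zeros_like(sigma2)
    return (
        log_norm
        - (a + p / 2.0 + 1.0) * np.log(sigma2)
        - (quad + 2.0 * b) / (2.0 * sigma2)
    )


def nig_log_density(params: NIGParams, draw: ParamDraw) -> float:
    """Log of the normalised joint NIG density at one (theta, sigma2) point."""
    if draw.theta.size != params.p:
        raise ValueError("theta dimension does not match params")
    return float(
        _nig_log_density_arrays(params, draw.theta[None, :], np.array([draw.sigma2]))[0]
    )


def nig_sample(params: NIGParams, count: int, seed) -> ParamDraws:
    """Draw ``count`` exact samples: sigma2 ~ IG(a, b), theta | sigma2 ~ N(m, sigma2 V)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = _as_rng(seed)
    sigma2 = params.b / rng.gamma(params.a, size=count)
    if params.p:
        z = rng.standard_normal((count, params.p))
        theta = params.m + np.sqrt(sigma2)[:, None] * (z @ params.chol_V().T)
    else:
        theta = np.zeros((count, 0))
    return ParamDraws(theta, sigma2, seed=seed if isinstance(seed, int) else None)


def ols_estimate(data: RegressionData) -> np.ndarray:
    """Least-squares estimate (X'X)^-1 X'y; raises if X'X is singular."""
    XtX = data.X.T @ data.X
    try:
        c = cho_factor(_symmetrize(XtX), lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X'X is singular: the least-squares estimator is not defined "
            "(collinear or too few rows)"
        ) from exc
    return cho_solve(c, data.X.T @ data.y)


def move_tested_last(p: int, tested: "list[int] | np.ndarray") -> np.ndarray:
    """Permutation placing the tested coefficient indices last, in order.

    Returns an index array ``perm`` such that ``X[:, perm]`` has the tested
    columns as its last block, matching the canonical partition convention.
    """
    tested = list(dict.fromkeys(int(j) for j in np.atleast_1d(tested)))
    if not tested:
        raise ValueError("tested index set must be nonempty")
    if any(j < 0 or j >= p for j in tested):
        raise ValueError(f"tested indices must lie in [0, {p})")
    free = [j for j in range(p) if j not in tested]
    return np.array(free + tested, dtype=int)


def permute_params(params: NIGParams, perm: np.ndarray) -> NIGParams:
    """Apply a coefficient permutation to a NIG law (m and V jointly)."""
    perm = np.asarray(perm, dtype=int)
    return NIGParams(params.m[perm], params.V[np.ix_(perm, perm)], params.a, params.b)
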