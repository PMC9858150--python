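"""Simulation-study driver: adaptive thresholds over (n, d) scenario grids.

A scenario is a sample size n and a parameter-space dimensionality d (p =
d - 1 regression coefficients plus the variance).  The design matrix holds
an intercept column plus d - 2 standard-normal covariates, generated once
per scenario and held fixed across Monte Carlo replicates -- the predictive
densities condition on X, so the averaged error probabilities are
X-conditional.  The tested block is always the last coefficient (for d = 2
that is the intercept itself, i.e. the intercept-only model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptive import (
    ErrorWeights,
    evalue_error_curves,
    find_kstar,
    optimal_error_rates,
)
from .conjugate import NIGParams, Partition
from .predictive import HypothesisModel

__all__ = [
    "ScenarioGrid",
    "generate_design",
    "default_prior",
    "scenario_model",
    "run_kstar_table",
    "run_alphastar_table",
]

log = logging.getLogger(__name__)


def default_prior(p: int, a0: float = 3.0, b0: float = 2.0) -> NIGParams:
    """Reference prior used throughout the studies: m0 = 0, V0 = I_p,
    sigma2 ~ inverse-gamma(3, 2)."""
    return NIGParams(np.zeros(p), np.eye(p), a0, b0)


@dataclass(frozen=True)
class ScenarioGrid:
    """A reproducible set of (n, d) scenarios with shared Monte Carlo sizes."""

    scenarios: tuple
    M_outer: int = 1000
    M_inner: int = 1000
    weights: ErrorWeights = field(default_factory=ErrorWeights)
    prior_a: float = 3.0
    prior_b: float = 2.0
    master_seed: int = 0

    def __post_init__(self):
        scen = tuple((int(n), int(d)) for n, d in self.scenarios)
        for n, d in scen:
            if n < 1 or d < 2:
                raise ValueError(f"need n >= 1 and d >= 2, got {(n, d)}")
        object.__setattr__(self, "scenarios", scen)


def _scenario_seed(master_seed: int, n: int, d: int, stage: int) -> np.random.SeedSequence:
    # spawn_key makes each cell a pure function of (master_seed, n, d, stage),
    # independent of grid order
    return np.random.SeedSequence(master_seed, spawn_key=(n, d, stage))


def generate_design(n: int, d: int, seed) -> np.ndarray:
    """n x (d-1) design: a column of ones then d-2 standard-normal covariates."""
    if n < 1 or d < 2:
        raise ValueError("need n >= 1 and d >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.ones((n, d - 1))
    if d > 2:
        X[:, 1:] = rng.standard_normal((n, d - 2))
    return X


def scenario_model(grid: ScenarioGrid, n: int, d: int) -> HypothesisModel:
    """Testing problem for one cell: nullity of the last coefficient
    (s = d - 2 free coefficients, r = 1 tested)."""
    X = generate_design(n, d, np.random.default_rng(_scenario_seed(grid.master_seed, n, d, 0)))
    return HypothesisModel(
        prior=default_prior(d - 1, grid.prior_a, grid.prior_b),
        part=Partition(s=d - 2, r=1),
        X=X,
    )


def run_kstar_table(grid: ScenarioGrid) -> pd.DataFrame:
    """Adaptive e-value cutoff k* (and the error rates attained at it) for
    every scenario in the grid.  A failing scenario is logged and its row
    filled with NaN rather than aborting the sweep."""
    rows = []
    for n, d in grid.scenarios:
        row = {"n": n, "d": d, "seed": grid.master_seed}
        try:
            model = scenario_model(grid, n, d)
            curve = evalue_error_curves(
                model, grid.M_outer, grid.M_inner, _scenario_seed(grid.master_seed, n, d, 1)
            )
            res = find_kstar(curve, grid.weights)
            row.update(
                kstar=res.kstar,
                alpha_e=res.alpha,
                beta_e=res.beta,
                se_alpha_e=res.alpha_se,
                se_beta_e=res.beta_se,
            )
        except Exception:
            log.exception("scenario (n=%d, d=%d) failed; recording as missing", n, d)
            row.update(kstar=np.nan, alpha_e=np.nan, beta_e=np.nan,
                       se_alpha_e=np.nan, se_beta_e=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def run_alphastar_table(grid: ScenarioGrid) -> pd.DataFrame:
    """Adaptive significance level alpha* and type-II rate beta* of the
    optimal Bayes-factor test, for every scenario in the grid."""
    rows = []
    for n, d in grid.scenarios:
        row = {"n": n, "d": d, "seed": grid.master_seed}
        try:
            model = scenario_model(grid, n, d)
            res = optimal_error_rates(
                model, grid.weights, grid.M_outer, _scenario_seed(grid.master_seed, n, d, 2)
            )
            row.update(
                alpha_star=res.alpha,
                beta_star=res.beta,
                se_alpha_star=res.alpha_se,
                se_beta_star=res.beta_se,
            )
        except Exception:
            log.exception("scenario (n=%d, d=%d) failed; recording as missing", n, d)
            row.update(alpha_star=np.nan, beta_star=np.nan,
                       se_alpha_star=np.nan, se_beta_star=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_error_curves(curve, w: ErrorWeights = ErrorWeights(), ax=None):
    """Plot alpha(k), beta(k) and their weighted sum over k (optional)."""
    import matplotlib.pyplot as plt  # deferred: plotting is an optional extra

    if ax is None:
        _, ax = plt.subplots()
    k = np.linspace(0.0, 1.0, 1001)
    alpha = curve.alpha(k)
    beta = curve.beta(k)
    ax.plot(k, alpha, label=r"$\alpha(k)$")
    ax.plot(k, beta, label=r"$\beta(k)$")
    ax.plot(k, w.a * alpha + w.b * beta, label=r"$a\,\alpha + b\,\beta$")
    ax.set_xlabel("cutoff $k$")
    ax.set_ylabel("averaged error probability")
    ax.legend()
    return ax
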