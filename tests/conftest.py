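import numpy as np
import pytest

from fbstlm import HypothesisModel, NIGParams, Partition, RegressionData


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def unit_prior_1d():
    """Scalar-coefficient reference prior: m0=0, V0=1, sigma2 ~ IG(3, 2)."""
    return NIGParams([0.0], [[1.0]], 3.0, 2.0)


@pytest.fixture
def toy_posterior():
    """Posterior from X=(1,1,1)', y=(1,2,3)' under the unit 1-D prior."""
    return NIGParams([1.5], [[0.25]], 4.5, 4.5)


@pytest.fixture
def intercept_model(unit_prior_1d):
    """Intercept-only testing problem (d=2) at n=10: H: theta1 = 0."""
    return HypothesisModel(unit_prior_1d, Partition(0, 1), np.ones((10, 1)))


@pytest.fixture
def covariate_model(rng):
    """Intercept + one covariate (d=3) at n=15, testing the slope."""
    X = np.column_stack([np.ones(15), rng.standard_normal(15)])
    return HypothesisModel(
        NIGParams(np.zeros(2), np.eye(2), 3.0, 2.0), Partition(1, 1), X
    )


@pytest.fixture
def small_dataset(rng):
    X = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
    theta = np.array([0.5, 1.0, 0.0])
    y = X @ theta + 0.7 * rng.standard_normal(20)
    return RegressionData(X, y)
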