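import numpy as np
import pytest

from mediprod import (
    Dataset,
    SimulationScenario,
    assemble_theta,
    fit_mediator_model,
    fit_outcome_model,
    generate_dataset,
    solve_scenario,
    theta_from_params,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


def make_case1_dataset(n=500, te=0.5, mp=0.2, seed=7):
    """A calibrated Case-1 dataset plus its generating scenario/params."""
    sc = SimulationScenario(case=1, n=n, te=te, mp=mp, reps=1, seed=seed)
    params = solve_scenario(sc)
    data = generate_dataset(sc, params, np.random.default_rng(seed))
    return data, sc, params


def fit_theta(data, cov_out=None, cov_med=None):
    return assemble_theta(
        fit_outcome_model(data, covariates=cov_out),
        fit_mediator_model(data, covariates=cov_med),
    )


@pytest.fixture
def case1_data():
    return make_case1_dataset()


@pytest.fixture
def case1_theta(case1_data):
    data, _, _ = case1_data
    return fit_theta(data)


@pytest.fixture
def simple_theta():
    """Known parameters wrapped as a theta with zero covariance."""
    return theta_from_params(beta=[-3.476, 0.4, 0.8], gamma=[-1.386, 0.903])


def binary_dataset(n=400, seed=11):
    """Small well-behaved case-4 dataset (common outcome so fits are stable)."""
    g = np.random.default_rng(seed)
    x = g.binomial(1, 0.5, n).astype(float)
    m = g.binomial(1, 1 / (1 + np.exp(-(-0.5 + 0.9 * x))), n).astype(float)
    p = 1 / (1 + np.exp(-(-1.0 + 0.4 * x + 0.8 * m)))
    y = g.binomial(1, p, n).astype(float)
    return Dataset(y=y, x=x, m=m, y_type="binary", m_type="binary")
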