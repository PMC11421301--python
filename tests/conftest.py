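import numpy as np
import pytest

from dcsm import AgeGrid, DCSMParams, DCSMSpec


@pytest.fixture
def small_grid() -> AgeGrid:
    return AgeGrid(n_bins=3)


@pytest.fixture
def toy_bivariate(small_grid):
    """A small bivariate model with every parameter class populated."""
    spec = DCSMSpec(
        traits=("fi", "clock"),
        proportional=(True, False),
        coupling=((1, 0),),
        pair_level="full",
        residual_cross_trait=True,
        grid=small_grid,
    )
    params = DCSMParams.zeros(spec)
    params.mu_intercept[:] = [6.0, 10.0]
    params.mu_slope[:] = [-0.7, 0.1]
    params.beta[:] = [0.1, 0.0]
    params.gamma[0, 1] = 0.5
    params.sex_intercept[:] = [2.0, -0.5]
    params.sex_slope[:] = [-0.3, 0.05]
    A = np.array([
        [3.0, -0.5, 0.8, 0.1],
        [-0.5, 0.6, -0.2, 0.05],
        [0.8, -0.2, 1.5, -0.1],
        [0.1, 0.05, -0.1, 0.3],
    ])
    params.sigma_ind = A @ A.T / 4.0
    B = np.diag([1.0, 0.3, 0.8, 0.2])
    params.sigma_pair = B @ B.T
    params.resid_var[:] = [2.0, 1.0]
    params.resid_cov = 0.3
    return spec, params


@pytest.fixture
def toy_univariate(small_grid):
    spec = DCSMSpec(
        traits=("fi",),
        proportional=(True,),
        coupling=(),
        pair_level="full",
        residual_cross_trait=False,
        grid=small_grid,
    )
    params = DCSMParams.zeros(spec)
    params.mu_intercept[:] = 6.0
    params.mu_slope[:] = -0.7
    params.beta[:] = 0.15
    params.sex_intercept[:] = 2.0
    params.sex_slope[:] = -0.3
    params.sigma_ind = np.array([[4.0, -0.5], [-0.5, 0.4]])
    params.sigma_pair = np.array([[1.5, -0.1], [-0.1, 0.1]])
    params.resid_var[:] = 3.0
    return spec, params
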