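"""Shared fixtures: small simulated datasets and fitted models."""

from dataclasses import dataclass

import numpy as np
import pytest

from stdsurv import (
    CovariateSpec,
    ModelParams,
    MultilevelWeibullPH,
    SimulationConfig,
    simulate_dataset,
)


@dataclass
class PlugInFit:
    """Fit-like object with known parameters, for oracle tests that bypass
    estimation."""

    params: ModelParams
    converged: bool = True
    vcov: np.ndarray | None = None
    vcov_ok: bool = False
    transformed: np.ndarray | None = None
    parametrization: object = None


@pytest.fixture
def plug_in_fit():
    return PlugInFit


@pytest.fixture(scope="session")
def toy_cluster():
    """One center, one surgeon, five subjects — small enough for dense-grid
    posterior oracles."""
    cfg = SimulationConfig(
        n_centers=1, surgeons_per_center=1, patients_per_surgeon=5,
        shape=1.3, scale=0.2, beta=[0.5], var_surgeon=0.3, var_center=0.2,
        covariates=[CovariateSpec("x", "normal")], admin_censoring=5.0,
        seed=3,
    )
    ds, truth = simulate_dataset(cfg)
    params = ModelParams(1.3, 0.2, [0.5], 0.3, 0.2)
    return ds, params


@pytest.fixture(scope="session")
def small_config():
    # variances generous enough that both components are well identified
    # in a dataset this small (the fixture backs covariance-based tests)
    return SimulationConfig(
        n_centers=10, surgeons_per_center=3, patients_per_surgeon=15,
        shape=1.2, scale=0.1, beta=[0.5, -0.3], var_surgeon=0.15,
        var_center=0.2,
        covariates=[CovariateSpec("x1", "normal"),
                    CovariateSpec("x2", "bernoulli", prob=0.5)],
        admin_censoring=8.0, censoring_rate=0.05, seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ds, truth = simulate_dataset(small_config, seed=12)
    return ds


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Converged fit with covariance, shared across test modules."""
    res = MultilevelWeibullPH(small_dataset).fit(nodes=11)
    assert res.converged and res.vcov_ok
    return res


@pytest.fixture(scope="session")
def small_eb(small_fit, small_dataset):
    from stdsurv import predict_all

    return predict_all(small_fit, small_dataset, method="mean")
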