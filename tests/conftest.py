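import numpy as np
import pytest

from habinfo.params import ModelParams, SignalProtocol, derive_energies
from habinfo.tss import TSSSolver


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return derive_energies(ModelParams())


@pytest.fixture(scope="session")
def default_solver(default_params) -> TSSSolver:
    return TSSSolver(default_params)


@pytest.fixture(scope="session")
def fig2_protocol() -> SignalProtocol:
    """Square-wave stimulation: background 0.1, stimulus 10, 100-long epochs."""
    return SignalProtocol(H_min=0.1, H_max=10.0, T_s=100.0, Delta_T=100.0,
                          n_stimuli=25)


@pytest.fixture(scope="session")
def reduced_params() -> ModelParams:
    from habinfo.gillespie import reduced_model_params

    return reduced_model_params()


@pytest.fixture(scope="session")
def reduced_solver(reduced_params) -> TSSSolver:
    return TSSSolver(reduced_params)


@pytest.fixture(scope="session")
def reduced_protocol() -> SignalProtocol:
    from habinfo.gillespie import reduced_validation_protocol

    return reduced_validation_protocol()


@pytest.fixture(scope="session")
def hallmark_report(default_params):
    """One full hallmark run shared by the hallmark and acceptance tests."""
    from habinfo.hallmarks import hallmark_suite

    return hallmark_suite(default_params)


@pytest.fixture(scope="session")
def info_scan_table(default_params):
    """Coarse (beta, sigma) information scan shared across tests."""
    from habinfo.info import info_scan

    beta_grid = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0])
    sigma_grid = np.array([0.15, 0.3, 0.45, 0.6, 0.8, 1.0, 1.2, 1.4])
    df = info_scan(default_params, beta_grid, sigma_grid,
                   SignalProtocol(n_stimuli=25), track_min_dIf=True)
    df.attrs["beta_grid"] = beta_grid
    df.attrs["sigma_grid"] = sigma_grid
    return df
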