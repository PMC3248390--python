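"""Shared fixtures: small simulation configs and the (expensive) FACS fit."""

import numpy as np
import pytest

import replikinetics as rk
from replikinetics import facs


@pytest.fixture(scope="session")
def small_config() -> rk.SimConfig:
    """2 Mb genome, origins every 40 kb, asynchronous lognormal firing."""
    return rk.SimConfig(
        genome_length=2000,
        origin_positions=tuple(rk.evenly_spaced_origins(2000, 40, 20)),
        firing_law=("lognormal", 120.0, 60.0),
        fork_velocity=0.68,
        n_cells=200,
        seed=11,
    )


@pytest.fixture(scope="session")
def synchronous_config() -> rk.SimConfig:
    """Near-synchronous firing: almost every origin visible in the pulses."""
    return rk.SimConfig(
        genome_length=3000,
        origin_positions=tuple(rk.evenly_spaced_origins(3000, 36, 18)),
        firing_law=("normal", 15.0, 6.0),
        fork_velocity=0.68,
        n_cells=60,
        fiber_length_law=("lognormal", 250.0, 0.4),
        seed=5,
    )


@pytest.fixture(scope="session")
def facs_truth() -> facs.SynthesisRateModel:
    """A synthesis-rate model off the fitting grid, T_S near 8 h."""
    return facs.SynthesisRateModel(
        amplitudes=2 * np.array([0.06, 0.03, 0.05, 0.02, 0.045, 0.055]),
        means=np.array([1.05, 1.22, 1.41, 1.55, 1.78, 1.95]),
        sds=np.array([0.12, 0.09, 0.14, 0.11, 0.10, 0.13]),
        cv=0.03,
    )


@pytest.fixture(scope="session")
def facs_histogram(facs_truth):
    return rk.simulate_facs_histogram(facs_truth, theta1=0.45, theta2=0.2,
                                      cv=0.03, n_cells=100_000, seed=7)


@pytest.fixture(scope="session")
def facs_fitted(facs_histogram, facs_truth):
    """One shared simplex fit of the synthetic histogram (slow)."""
    return facs.fit(facs_histogram, n_restarts=4, seed=1,
                    t_s_hours=facs_truth.t_s)
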