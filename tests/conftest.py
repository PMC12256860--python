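"""Shared fixtures: session-scoped simulations reused across test modules.

The heavy fixtures follow the canonical acquisition (2 kHz, >= 5 s) on a
512-emplacement contour; the "fast" fixtures use a lower microviscosity so
every mode decorrelates many times within the run, making time-averaged
statistics converge tightly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from flickerlab import (
    ActivityParams,
    MembraneParams,
    compute_psd,
    gser_modulus,
    simulate_active_contour,
    simulate_passive_contour,
)

warnings.filterwarnings("ignore", category=RuntimeWarning, module="flickerlab")


@pytest.fixture(scope="session")
def membrane_default() -> MembraneParams:
    return MembraneParams()


@pytest.fixture(scope="session")
def membrane_fast() -> MembraneParams:
    """Bending membrane whose slowest mode relaxes at ~25 rad/s."""
    return MembraneParams(eta=0.005)


@pytest.fixture(scope="session")
def membrane_crossover() -> MembraneParams:
    """Tension + bending membrane with the knee inside the 2 kHz band."""
    return MembraneParams(gamma=1.15e-4, kappa=2.9e-18, eta=0.5)


@pytest.fixture(scope="session")
def sim_passive_512(membrane_default):
    """Canonical bending-dominated passive run: N=512, 1e5 frames, 2 kHz."""
    return simulate_passive_contour(
        membrane_default, N=512, T_frames=100_000, dt=0.5e-3, seed=11
    )


@pytest.fixture(scope="session")
def spectrum_passive_512(sim_passive_512):
    return compute_psd(sim_passive_512, segment_length=8192)


@pytest.fixture(scope="session")
def rheo_passive_512(sim_passive_512, spectrum_passive_512, membrane_default):
    return gser_modulus(
        spectrum_passive_512, sim_passive_512.L, membrane_default.T
    )


@pytest.fixture(scope="session")
def sim_active_only(membrane_default):
    """Telegraph kickers only (T = 0): the pure active component."""
    return simulate_active_contour(
        membrane_default.replace(T=0.0),
        ActivityParams(),
        N=512,
        T_frames=100_000,
        dt=0.5e-3,
        seed=12,
    )


@pytest.fixture(scope="session")
def sim_crossover(membrane_crossover):
    return simulate_passive_contour(
        membrane_crossover, N=512, T_frames=100_000, dt=0.5e-3, seed=13
    )


@pytest.fixture(scope="session")
def rheo_crossover(sim_crossover, membrane_crossover):
    sp = compute_psd(sim_crossover, segment_length=16384)
    return gser_modulus(sp, sim_crossover.L, membrane_crossover.T)


@pytest.fixture(scope="session")
def sim_fast_long(membrane_fast):
    """Long, fast-relaxing passive run for tightly converged averages."""
    return simulate_passive_contour(
        membrane_fast, N=64, T_frames=65_536, dt=2.0e-3, seed=21
    )


def gov_activity(m: MembraneParams, Lambda0: float = 50e-9, **kwargs) -> ActivityParams:
    """Activity whose spring f0/Lambda0 equals the passive stiffness
    kB*T/Sigma_pass^2, making Teff/T = 1 + phi*f0*Lambda0/(kB*T) exact."""
    from flickerlab import KB, analytic_site_variance

    sigma2 = analytic_site_variance(m, kwargs.pop("n_modes", 63))
    f0 = KB * m.T * Lambda0 / sigma2
    return ActivityParams(f0=f0, Lambda0=Lambda0, **kwargs)


@pytest.fixture(scope="session")
def sim_active_fast(membrane_fast):
    """Active run with Gov-consistent kickers on the fast membrane."""
    act = gov_activity(membrane_fast, rate_mode="single_rate", phi=0.3)
    series = simulate_active_contour(
        membrane_fast, act, N=128, T_frames=60_000, dt=1.0e-3, seed=22
    )
    return series, act
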