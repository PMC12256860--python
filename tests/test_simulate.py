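"""Synthetic generator: dispersion, equipartition, Gaussianity, activity."""

import decimal

import numpy as np
import pytest
from scipy import stats as sps

from flickerlab import (
    KB,
    ActivityParams,
    MembraneParams,
    ShapeSpec,
    analytic_site_variance,
    dispersion_rate,
    generate_shape,
    mode_variance,
    mode_wavenumbers,
    simulate_active_contour,
    simulate_passive_contour,
)
from flickerlab.simulate import mode_indices


@pytest.mark.parametrize(
    "gamma, kappa, expected",
    [(1e-6, 0.0, 250.0), (0.0, 1e-19, 25.0), (1e-6, 1e-19, 275.0)],
)
def test_dispersion_rate_single_terms(gamma, kappa, expected):
    """(gamma*q + kappa*q^3)/(4*eta) term by term and additively."""
    m = MembraneParams(gamma=gamma, kappa=kappa, eta=1e-3)
    assert dispersion_rate(m, 1e6) == pytest.approx(expected)


def test_dispersion_rate_monotone_and_domain():
    m = MembraneParams()
    q = np.geomspace(1e4, 1e8, 50)
    rates = dispersion_rate(m, q)
    assert np.all(np.diff(rates) > 0)
    with pytest.raises(ValueError):
        dispersion_rate(m, -1.0)


def test_mode_variance_zero_temperature():
    m = MembraneParams(T=0.0)
    assert mode_variance(m, 2e6) == 0.0


def test_mode_variance_crossover_symmetry():
    """At gamma = kappa*q^2 tension and bending contribute equally."""
    q = 2e6
    kappa = 1e-19
    m = MembraneParams(gamma=kappa * q**2, kappa=kappa)
    tension_only = mode_variance(m.replace(kappa=0.0), q)
    bending_only = mode_variance(m.replace(gamma=0.0), q)
    assert tension_only == pytest.approx(bending_only, rel=1e-12)
    assert mode_variance(m, q) == pytest.approx(tension_only / 2.0, rel=1e-12)


def test_mode_variance_against_arbitrary_precision():
    """Float evaluation agrees with a 50-digit decimal computation."""
    T, R, gamma, kappa, q = 310.15, 3.6e-6, 6.4e-6, 1e-19, 2e6
    m = MembraneParams(gamma=gamma, kappa=kappa, T=T, R_bar=R)
    decimal.getcontext().prec = 50
    D = decimal.Decimal
    two_pi = D(2) * D(
        "3.14159265358979323846264338327950288419716939937510"
    )
    exact = (D("1.380649e-23") * D(str(T))) / (
        two_pi * D(str(R)) * (D(str(gamma)) * D(str(q)) + D(str(kappa)) * D(str(q)) ** 3)
    )
    assert mode_variance(m, q) == pytest.approx(float(exact), rel=1e-12)


def test_mode_variance_degenerate_error():
    m = MembraneParams(gamma=1e-6, kappa=0.0)
    with pytest.raises(ValueError):
        # zero restoring only reachable with q -> 0, which is rejected
        mode_variance(m, 0.0)


def test_zero_temperature_series_is_identically_zero():
    m = MembraneParams(T=0.0)
    s = simulate_passive_contour(m, N=64, T_frames=200, dt=1e-3, seed=0)
    assert np.all(s.dh == 0.0)


def test_seed_determinism():
    m = MembraneParams()
    a = simulate_passive_contour(m, N=64, T_frames=500, dt=1e-3, seed=7)
    b = simulate_passive_contour(m, N=64, T_frames=500, dt=1e-3, seed=7)
    c = simulate_passive_contour(m, N=64, T_frames=500, dt=1e-3, seed=8)
    assert np.array_equal(a.dh, b.dh)
    assert not np.array_equal(a.dh, c.dh)


def _variance_of_ou_square_average(sigma2, rate, dt, n):
    """Var of the sample variance of an OU process observed at n steps dt.

    The squared process is AR(1) with lag-1 correlation rho^2
    (rho = exp(-rate*dt)): Var = (2*sigma^4/n)*(1+rho^2)/(1-rho^2), exact
    in both the independent-sample and the continuous-time limits.
    """
    rho2 = np.exp(-2.0 * rate * dt)
    return (2.0 * sigma2**2 / n) * (1.0 + rho2) / (1.0 - rho2)


def test_total_variance_matches_mode_sum(membrane_fast, sim_fast_long):
    """Sample Sigma^2 agrees with the analytic mode sum within 3 SE."""
    s = sim_fast_long
    n_modes = 31
    q = mode_wavenumbers(membrane_fast, n_modes)
    rates = np.atleast_1d(dispersion_rate(membrane_fast, q))
    variances = np.atleast_1d(mode_variance(membrane_fast, q))
    # Sigma2_hat = sum over modes of avg (a^2+b^2)/2 -> independent OU terms
    var_est = sum(
        2.0 * _variance_of_ou_square_average(v, w, s.dt, s.n_frames) / 4.0
        for v, w in zip(variances, rates)
    )
    se = np.sqrt(var_est)
    sample = float(np.mean(np.var(s.dh, axis=1)))
    expected = analytic_site_variance(membrane_fast, n_modes)
    assert abs(sample - expected) < 3.0 * se


def test_per_mode_equipartition(membrane_fast, sim_fast_long):
    """Every simulated mode's quadrature variance matches mode_variance
    within 4 standard errors."""
    s = sim_fast_long
    n_modes = 31
    coeff = np.fft.rfft(s.dh, axis=0) * (2.0 / s.n_sites)
    q = mode_wavenumbers(membrane_fast, n_modes)
    rates = np.atleast_1d(dispersion_rate(membrane_fast, q))
    variances = np.atleast_1d(mode_variance(membrane_fast, q))
    for n, rate, var in zip(mode_indices(n_modes), rates, variances):
        for quad in (coeff[n].real, coeff[n].imag):
            sample = float(np.var(quad))
            se = np.sqrt(
                _variance_of_ou_square_average(var, rate, s.dt, s.n_frames)
            )
            assert abs(sample - var) < 4.0 * se, f"mode {n}"


def test_pooled_gaussianity(sim_fast_long):
    """Passive displacements pooled over sites: excess kurtosis < 0.1.

    Uses the fast-relaxing run so the kurtosis estimator is converged (the
    canonical run is dominated by the slow n = 2 mode, whose handful of
    correlation times per run leaves the estimator itself fluctuating at
    the 0.1 level).
    """
    pooled = sim_fast_long.dh.ravel()
    assert abs(sps.kurtosis(pooled)) < 0.1


def test_point_msd_zilman_granek_exponent(sim_passive_512):
    """Bending-dominated point MSD grows as tau^(2/3) (+- 0.07)."""
    s = sim_passive_512
    dh = s.dh
    n = s.n_frames
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(dh - dh.mean(axis=1, keepdims=True), nfft, axis=1)
    acov = np.fft.irfft(fx * np.conj(fx), nfft, axis=1)[:, : n // 2] / n
    msd = 2.0 * (acov[:, :1] - acov).mean(axis=0).ravel()
    lags = np.arange(n // 2) * s.dt
    sel = (lags >= 2e-3) & (lags <= 5e-2)
    slope = np.polyfit(np.log(lags[sel]), np.log(msd[sel]), 1)[0]
    assert slope == pytest.approx(2.0 / 3.0, abs=0.07)


def test_aliasing_warning():
    m = MembraneParams()
    with pytest.warns(RuntimeWarning, match="undersample"):
        simulate_passive_contour(m, N=64, T_frames=16, dt=0.5, seed=0)


# ---------------------------------------------------------------------------
# active kickers
# ---------------------------------------------------------------------------


def test_phi_zero_is_bitwise_passive():
    m = MembraneParams()
    a = ActivityParams(phi=0.0)
    s_act = simulate_active_contour(m, a, N=64, T_frames=300, dt=1e-3, seed=9)
    s_pas = simulate_passive_contour(m, N=64, T_frames=300, dt=1e-3, seed=9)
    assert np.array_equal(s_act.dh, s_pas.dh)


def test_activity_adds_variance():
    m = MembraneParams()
    a = ActivityParams()
    s_act = simulate_active_contour(m, a, N=128, T_frames=5000, dt=1e-3, seed=4)
    s_pas = simulate_passive_contour(m, N=128, T_frames=5000, dt=1e-3, seed=4)
    assert s_act.dh.var() > s_pas.dh.var()


def test_unphysical_kick_amplitude_rejected():
    m = MembraneParams()
    a = ActivityParams(Lambda0=2e-6)  # >= R_bar/2
    with pytest.raises(ValueError, match="unphysical"):
        simulate_active_contour(m, a, N=64, T_frames=10, dt=1e-3, seed=0)


def test_effective_temperature_recovery(membrane_fast, sim_active_fast):
    """Long-run Teff/T = 1 + phi*f0*Lambda0/(kB*T) within 10%."""
    series, act = sim_active_fast
    sample = float(np.mean(np.var(series.dh, axis=1)))
    passive = analytic_site_variance(membrane_fast, 63)
    teff_ratio = sample / passive
    predicted = 1.0 + act.phi * act.f0 * act.Lambda0 / (KB * membrane_fast.T)
    assert teff_ratio == pytest.approx(predicted, rel=0.10)


# ---------------------------------------------------------------------------
# morphotype fixture shapes
# ---------------------------------------------------------------------------


def test_shape_circle_constant_radius():
    r = generate_shape(ShapeSpec(kind="circle", R=3.6e-6), 256)
    assert np.allclose(r, 3.6e-6)


def test_shape_ellipse_radial_form():
    spec = ShapeSpec(kind="ellipse", R=3.6e-6, axis_ratio=0.9)
    r = generate_shape(spec, 512)
    assert r.max() == pytest.approx(3.6e-6, rel=1e-9)
    assert r.min() == pytest.approx(0.9 * 3.6e-6, rel=1e-9)


def test_shape_spiculated_perimeter_matches_quadrature():
    R, mlobes, amp = 3.6e-6, 12, 0.15
    radii = generate_shape(
        ShapeSpec(kind="spiculated", R=R, lobes=mlobes, lobe_amplitude=amp), 4096
    )
    theta = 2.0 * np.pi * np.arange(4096) / 4096
    x, y = radii * np.cos(theta), radii * np.sin(theta)
    poly_len = np.sum(np.hypot(np.diff(np.append(x, x[0])), np.diff(np.append(y, y[0]))))
    tq = np.linspace(0, 2 * np.pi, 400_001)
    Rq = R * (1 + amp * np.cos(mlobes * tq))
    dRq = -R * amp * mlobes * np.sin(mlobes * tq)
    quad_len = np.trapezoid(np.hypot(Rq, dRq), tq)
    assert poly_len == pytest.approx(quad_len, rel=1e-4)
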