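"""GSER inversion, the activity kernel, crossover detection and the
fractional viscoelastic model fits."""

import numpy as np
import pytest
from scipy.signal import lfilter

from flickerlab import (
    KB,
    ActivityParams,
    ContourSeries,
    MembraneParams,
    RheoSpectrum,
    Spectrum,
    analytic_site_variance,
    compute_psd,
    effective_temperature_kernel,
    gser_modulus,
    maxwell_viscosity,
    simulate_active_contour,
    simulate_passive_contour,
    viscoelastic_ratio_and_crossovers,
)
from flickerlab.rheology import (
    BicomponentSpectrumModel,
    FractionalRigidityModel,
    FractionalViscosityModel,
    fit_fractional_rigidity,
)
from flickerlab.simulate import (
    dispersion_rate,
    mode_variance,
    mode_wavenumbers,
    telegraph_ensemble_psd,
)

T_BODY = 310.15


# ---------------------------------------------------------------------------
# effective-temperature kernel
# ---------------------------------------------------------------------------


def test_kernel_passive_limit():
    omega = np.geomspace(1, 1e4, 20)
    np.testing.assert_allclose(
        effective_temperature_kernel(omega, 0.0, 1e-19, 0.02, T_BODY), T_BODY
    )


def test_kernel_zero_frequency_limit():
    phi, eps = 0.3, 20 * KB * T_BODY
    val = effective_temperature_kernel(1e-9, phi, eps, 0.02, T_BODY)
    assert val == pytest.approx(T_BODY + phi * eps / KB, rel=1e-6)


def test_kernel_at_pi():
    """K(pi) = 4/pi^2 ~ 0.405 of the zero-frequency activity boost."""
    phi, eps, tau = 0.2, 1e-19, 0.02
    val = effective_temperature_kernel(np.pi / tau, phi, eps, tau, T_BODY)
    boost = phi * eps / KB
    assert (val - T_BODY) / boost == pytest.approx(4.0 / np.pi**2, rel=1e-9)


# ---------------------------------------------------------------------------
# GSER calibration
# ---------------------------------------------------------------------------


def _ou_trap_series(G_trap, L, eta, dt, n, seed=0):
    zeta = 6 * np.pi * L * eta
    rate = G_trap / zeta
    var = KB * T_BODY / G_trap
    rng = np.random.default_rng(seed)
    rho = np.exp(-rate * dt)
    x = lfilter(
        [1.0], [1.0, -rho], np.sqrt(var * (1 - rho**2)) * rng.standard_normal(n)
    )
    return ContourSeries(x[None, :], 3.6e-6, dt), rate


def test_gser_ou_trap_plateau_recovers_stiffness():
    """Low-frequency G' plateau = trap stiffness within 5%."""
    L, eta, G_trap = 4.4e-8, 1e-3, 1e-6
    s, rate = _ou_trap_series(G_trap, L, eta, 0.5e-3, 200_000, seed=0)
    r = gser_modulus(compute_psd(s, segment_length=8192), L, T_BODY)
    plateau = (r.omega > 3) & (r.omega < rate / 10)
    assert np.median(r.G_prime[plateau]) == pytest.approx(G_trap, rel=0.05)


def test_gser_free_diffusion_recovers_viscosity():
    """Free diffusion: G' ~ 0 and flat eta_eff = zeta/(6*pi*L) within 10%."""
    L, eta, dt, n = 4.4e-8, 1e-3, 0.5e-3, 200_000
    zeta = 6 * np.pi * L * eta
    D = KB * T_BODY / zeta
    rng = np.random.default_rng(1)
    x = np.cumsum(np.sqrt(2 * D * dt) * rng.standard_normal(n))
    r = gser_modulus(
        compute_psd(ContourSeries(x[None, :], 3.6e-6, dt), segment_length=4096),
        L,
        T_BODY,
    )
    band = (r.omega > 50) & (r.omega < 2000)
    assert np.median(r.eta_eff[band]) == pytest.approx(eta, rel=0.10)
    assert np.median(r.G_prime[band]) < 0.1 * np.median(r.G_loss[band])


def test_gser_passive_bending_scaling(rheo_passive_512):
    """G' ~ omega^(2/3) (+-0.1) above the bending onset; eta_eff falls as
    ~ omega^(-1/3) there."""
    r = rheo_passive_512
    band = (r.omega > 100) & (r.omega < 1500)
    slope = np.polyfit(np.log(r.omega[band]), np.log(r.G_prime[band]), 1)[0]
    assert slope == pytest.approx(2.0 / 3.0, abs=0.10)
    eta_slope = np.polyfit(np.log(r.omega[band]), np.log(r.eta_eff[band]), 1)[0]
    assert eta_slope == pytest.approx(-1.0 / 3.0, abs=0.10)


def test_gser_passive_viscosity_lubrication_decay(rheo_crossover):
    """Deep in the tension plateau (well below the relaxation knee) the
    effective viscosity decays as ~ omega^-1 (lubrication limit)."""
    r = rheo_crossover
    band = (r.omega > 0.8) & (r.omega < 3.0)
    slope = np.polyfit(np.log(r.omega[band]), np.log(r.eta_eff[band]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.25)


# ---------------------------------------------------------------------------
# crossovers
# ---------------------------------------------------------------------------


def _maxwell_rheo(G, eta_s, omega):
    tau = eta_s / G
    G_p = G * (omega * tau) ** 2 / (1 + (omega * tau) ** 2)
    G_l = G * (omega * tau) / (1 + (omega * tau) ** 2)
    return RheoSpectrum(
        omega, np.hypot(G_p, G_l), G_p, G_l, G_l / (omega * 6 * np.pi * 1e-7),
        np.zeros_like(omega), 1e-7, T_BODY,
    )


def test_maxwell_element_crossover_exact():
    G, eta_s = 1e-5, 2e-8  # crossing at G/eta_s = 500 rad/s
    omega = np.geomspace(1, 1e4, 400)
    r = _maxwell_rheo(G, eta_s, omega)
    _, omega_D, _ = viscoelastic_ratio_and_crossovers(r)
    assert omega_D == pytest.approx(G / eta_s, rel=1e-3)


def test_noise_floor_onset_detected():
    """A white floor injected above 2000 rad/s is located within x1.5."""
    omega = np.geomspace(1, 2e4, 600)
    psd = 1e-22 * omega ** (-5.0 / 3.0)
    floor = psd[np.argmin(np.abs(omega - 2000.0))]
    sp = Spectrum(omega, psd + floor)
    r = gser_modulus(sp, 4.4e-8, T_BODY)
    _, _, omega_C = viscoelastic_ratio_and_crossovers(r)
    assert omega_C is not None
    assert 2000.0 / 1.5 < omega_C < 2000.0 * 1.5


# ---------------------------------------------------------------------------
# fractional model fits
# ---------------------------------------------------------------------------


def test_rigidity_model_noiseless_self_consistency():
    """Noiseless model curve: parameters back to 4 significant digits."""
    omega = np.geomspace(1, 5000, 200)
    true = {"G_gamma": 2e-5, "G_kappa": 1e-4, "tau_D": 1 / 300.0, "alpha": 0.25}
    x = omega * true["tau_D"]
    g = true["G_gamma"] + true["G_kappa"] * x**0.5 / (1 + x**0.5)
    res = FractionalRigidityModel(omega, g, R_bar=3.6e-6).fit()
    for k, v in true.items():
        assert res.params[k] == pytest.approx(v, rel=1e-4), k
    assert res.params["gamma_eff"] == pytest.approx(2e-5 * 3.6e-6, rel=1e-4)


def test_rigidity_alpha_quarter_gives_half_exponent():
    """The curvature branch of the alpha = 1/4 model rises as omega^(1/2)
    below saturation."""
    alpha, tau_D, G_kappa = 0.25, 1 / 300.0, 1e-4
    omega = np.geomspace(1e-6, 1e-3, 60) / tau_D
    x = omega * tau_D
    branch = G_kappa * x ** (2 * alpha) / (1 + x ** (2 * alpha))
    slope = np.polyfit(np.log(omega), np.log(branch), 1)[0]
    assert slope == pytest.approx(0.5, abs=0.02)


def test_viscosity_model_maxwell_reduction_exact():
    """phi = 0, alpha = 1 reduces to eta0 + G0*wD/(w^2 + wD^2)."""
    omega = np.geomspace(1, 5000, 150)
    eta_true = maxwell_viscosity(omega, 2e-3, 1e-4, 300.0)
    res = FractionalViscosityModel(omega, eta_true).fit()
    assert res.params["alpha"] == pytest.approx(1.0, abs=1e-5)
    assert res.params["eta0"] == pytest.approx(2e-3, rel=1e-4)
    assert res.params["G0"] == pytest.approx(1e-4, rel=1e-3)
    assert 1.0 / res.params["tau_D"] == pytest.approx(300.0, rel=1e-3)
    summary = res.summary()
    assert "eta0" in summary and "alpha" in summary


def test_staged_fit_recovers_generator_parameters(
    membrane_crossover, sim_crossover, rheo_crossover
):
    """Tension plateau, bending exponent and knee recovered within 20%
    against the analytic mode-sum oracle."""
    m = membrane_crossover
    r = rheo_crossover.band(0.8, 1500.0)
    res = fit_fractional_rigidity(r, R_bar=m.R_bar, T=m.T)
    G_plateau_true = KB * m.T / analytic_site_variance(m, 255)
    assert res.params["G_gamma"] == pytest.approx(G_plateau_true, rel=0.20)
    assert res.params["alpha"] == pytest.approx(1.0 / 3.0, abs=0.07)
    # knee oracle: same estimator applied to the analytic spectrum
    q = mode_wavenumbers(m, 255)
    wn = dispersion_rate(m, q)
    var = mode_variance(m, q)
    S = np.sum(
        (2 / np.pi) * var[None, :] * wn[None, :] / (wn[None, :] ** 2 + r.omega[:, None] ** 2),
        axis=1,
    )
    r_true = gser_modulus(Spectrum(r.omega, S), sim_crossover.L, m.T)
    res_true = fit_fractional_rigidity(r_true, R_bar=m.R_bar, T=m.T)
    assert res.params["omega_knee"] == pytest.approx(
        res_true.params["omega_knee"], rel=0.20
    )
    assert not res.plateau_only


def test_bending_only_fit_alpha_one_third(rheo_passive_512, membrane_default):
    res = fit_fractional_rigidity(
        rheo_passive_512.band(2.0, 1500.0),
        R_bar=membrane_default.R_bar,
        T=membrane_default.T,
    )
    assert res.params["alpha"] == pytest.approx(1.0 / 3.0, abs=0.07)


# ---------------------------------------------------------------------------
# bicomponent spectral decomposition
# ---------------------------------------------------------------------------


def _synthetic_bicomponent(A_act, omega):
    S_pass = KB * T_BODY / (omega * (2e-5 + 3e-6 * omega ** (2.0 / 3.0)))
    S_act = A_act * telegraph_ensemble_psd(omega, 1.0, 50.0, 5000.0)
    return S_pass + S_act


def test_bicomponent_amplitude_recovery():
    omega = np.geomspace(1, 6000, 300)
    A_true = 0.3 * (50e-9) ** 2
    psd = _synthetic_bicomponent(A_true, omega)
    res = BicomponentSpectrumModel(omega, psd, T_BODY).fit()
    assert not res.passive_only
    assert res.params["A_act"] == pytest.approx(A_true, rel=0.15)
    assert res.params["omega_A"] == pytest.approx(50.0, rel=0.5)
    assert res.params["omega_D"] > 0


def test_bicomponent_passive_null_flagged():
    omega = np.geomspace(1, 6000, 300)
    psd = _synthetic_bicomponent(0.0, omega)
    res = BicomponentSpectrumModel(omega, psd, T_BODY).fit()
    assert res.passive_only


def test_bicomponent_stiffer_membrane_means_less_power():
    """Fitted total power decreases strictly along an increasing-G0
    fixture sequence."""
    omega = np.geomspace(1, 6000, 200)
    powers = []
    for G in (1e-5, 3e-5, 1e-4):
        psd = KB * T_BODY / (omega * (G + 3e-6 * omega ** (2.0 / 3.0)))
        res = BicomponentSpectrumModel(omega, psd, T_BODY).fit()
        powers.append(np.trapezoid(res.best_fit, res.omega))
    assert powers[0] > powers[1] > powers[2]


# ---------------------------------------------------------------------------
# activity ordering (passivation sequence)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def phi_sequence_spectra():
    m = MembraneParams()
    spectra = {}
    for phi in (0.0, 0.15, 0.3):
        s = simulate_active_contour(
            m, ActivityParams(phi=phi), N=256, T_frames=30_000, dt=0.5e-3, seed=31
        )
        spectra[phi] = (s, compute_psd(s, segment_length=4096))
    return m, spectra


def test_phi_ordered_spectra_pointwise(phi_sequence_spectra):
    """Spectra of decreasing phi are pointwise ordered at low frequency:
    the passivation sequence."""
    _, spectra = phi_sequence_spectra
    band = (spectra[0.0][1].omega > 50) & (spectra[0.0][1].omega < 500)
    p0 = spectra[0.0][1].psd[band]
    p1 = spectra[0.15][1].psd[band]
    p2 = spectra[0.3][1].psd[band]
    assert np.mean(p1 / p0) > 1.5
    assert np.mean(p2 / p1) > 1.2
    assert np.all(np.median(p2 / p0) > 1)


def test_active_softening_drops_viscoelastic_ratio(phi_sequence_spectra):
    """Active kicking softens the membrane: the effective rigidity
    (magnitude and elastic part) drops pointwise relative to the passive
    twin -- the -DeltaG signature."""
    m, spectra = phi_sequence_spectra
    rheo = {}
    for phi in (0.0, 0.3):
        s, sp = spectra[phi]
        rheo[phi] = gser_modulus(sp, s.L, m.T)
    band = (rheo[0.0].omega > 50) & (rheo[0.0].omega < 1000)
    softening = np.mean(rheo[0.3].G_prime[band] < rheo[0.0].G_prime[band])
    assert softening > 0.95  # -Delta G: pointwise drop of the rigidity
    assert np.mean(rheo[0.3].G_mag[band]) < np.mean(rheo[0.0].G_mag[band])
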