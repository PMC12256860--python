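"""Synthetic membrane-fluctuation generator.

The equatorial contour is simulated as a bank of ring Fourier modes
q_n = n/R_bar (n = 1..n_modes).  Each mode is an exactly discretized
Ornstein-Uhlenbeck process with relaxation rate

    omega(q) = (gamma*q + kappa*q^3) / (4*eta)

and stationary variance

    <|h_q|^2> = kB*T / (2*pi*R_bar * (gamma*q + kappa*q^3)),

the equatorial-section spectrum of a quasi-2D membrane (the 1D contour
observable of a fluctuating surface decays one power of q slower than the
surface modes themselves).  This pairing makes the per-mode power plateau
sigma_q^2 * omega_q = kB*T/(8*pi*eta*R_bar) mode-independent and yields the
bimodal fluctuation spectrum PSD ~ kB*T/(omega*G_eff(omega)): a 1/omega
decay in the tension window and the Zilman-Granek omega^(-5/3) decay in the
bending window.  The real
displacement field is assembled by inverse Fourier transform, giving a
stationary zero-mean Gaussian series whose per-site variance equals the
analytic mode sum at any frame interval (the OU update is exact, so there
is no time-discretization bias; sampling faster than the fastest mode is
not required for correctness, only for resolving its spectrum).

Active (nonequilibrium) flickering adds, on a random fraction ``phi`` of
emplacements, a dichotomous kicking force +-f0 relaxed through the local
friction zeta = 6*pi*L*eta toward excursions of scale Lambda0, switching at
a telegraph corner rate omega_A (or a log-uniform ensemble of rates, whose
superposition of Lorentzians yields a 1/omega spectrum inside the span).
Active and passive components are statistically independent.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import lfilter

from ._constants import KB
from .params import ActivityParams, MembraneParams, RateMode
from .series import ContourSeries

__all__ = [
    "dispersion_rate",
    "mode_variance",
    "mode_wavenumbers",
    "analytic_site_variance",
    "simulate_passive_contour",
    "simulate_active_contour",
    "telegraph_ensemble_psd",
]


def dispersion_rate(m: MembraneParams, q):
    """Relaxation rate omega(q) = (gamma*q + kappa*q^3)/(4*eta) in rad/s.

    Strictly increasing in q; the viscoelastic ratio of restoring stress to
    friction for a contour mode of wavenumber ``q`` (1/m).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("wavenumber q must be > 0")
    rate = (m.gamma * q + m.kappa * q**3) / (4.0 * m.eta)
    return rate if rate.ndim else float(rate)


def mode_variance(m: MembraneParams, q):
    """Equilibrium variance kB*T/(2*pi*R_bar*(gamma*q + kappa*q^3)) in m^2.

    Equipartition amplitude of a contour mode under the equatorial-section
    normalization C = 2*pi*R_bar.  Positive and decreasing in q; tension and
    bending contribute equally at the crossover gamma = kappa*q^2.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("wavenumber q must be > 0")
    restoring = m.gamma * q + m.kappa * q**3
    if np.any(restoring <= 0):
        raise ValueError("degenerate mode: zero restoring coefficient")
    var = KB * m.T / (2.0 * np.pi * m.R_bar * restoring)
    return var if var.ndim else float(var)


def mode_indices(n_modes: int) -> np.ndarray:
    """Deformation mode indices n = 2..n_modes.

    The n = 1 ring mode is a rigid translation to first order and is
    excluded (it is exactly what barycenter drift correction removes); the
    flickering observable starts at the elliptical mode n = 2.
    """
    if n_modes < 2:
        raise ValueError("need n_modes >= 2")
    return np.arange(2, n_modes + 1)


def mode_wavenumbers(m: MembraneParams, n_modes: int) -> np.ndarray:
    """Ring wavenumbers q_n = n/R_bar for n = 2..n_modes (1/m)."""
    return mode_indices(n_modes) / m.R_bar


def analytic_site_variance(m: MembraneParams, n_modes: int) -> float:
    """Closed-form per-site variance: the mode sum of mode_variance (m^2)."""
    if m.T == 0:
        return 0.0
    return float(np.sum(mode_variance(m, mode_wavenumbers(m, n_modes))))


def _ou_bank(rates, variances, n_frames, dt, rng):
    """Exact stationary OU paths, one row per process.

    x_{t+1} = x_t * exp(-w*dt) + N(0, var*(1 - exp(-2*w*dt))); x_0 drawn from
    the stationary distribution, so statistics are stationary from frame 0.
    """
    rates = np.asarray(rates, float)
    variances = np.asarray(variances, float)
    n = rates.size
    decay = np.exp(-rates * dt)
    innov_sd = np.sqrt(variances * (1.0 - decay**2))
    x = np.empty((n, n_frames))
    noise = rng.standard_normal((n, n_frames))
    x0 = np.sqrt(variances) * rng.standard_normal(n)
    for j in range(n):
        # lag-1 recursion as an IIR filter; zi carries the stationary start
        x[j] = lfilter(
            [1.0], [1.0, -decay[j]], innov_sd[j] * noise[j], zi=[decay[j] * x0[j]]
        )[0]
    return x


def simulate_passive_contour(
    m: MembraneParams,
    N: int = 512,
    T_frames: int = 10_000,
    dt: float = 0.5e-3,
    n_modes: int | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ContourSeries:
    """Simulate passive thermal contour fluctuations.

    Parameters
    ----------
    m : MembraneParams
    N : int
        Number of contour emplacements.
    T_frames : int
        Number of frames.
    dt : float
        Frame interval (s).
    n_modes : int, optional
        Number of ring modes; defaults to N//2 and may not exceed it.
    seed : int or numpy SeedSequence
        Root seed; identical inputs and seed give identical output.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if n_modes is None:
        n_modes = N // 2 - 1
    if n_modes > N // 2 - 1:
        # the n = N/2 ring mode has no sine quadrature on the site grid
        raise ValueError("n_modes may not exceed N/2 - 1 (ring Nyquist)")
    q = mode_wavenumbers(m, n_modes)
    rates = dispersion_rate(m, q)
    if dt >= 1.0 / (2.0 * rates.max()):
        warnings.warn(
            "frame interval undersamples the fastest mode "
            f"(dt={dt:g} s >= {1.0 / (2.0 * rates.max()):g} s); the exact OU "
            "update remains unbiased but fast-mode spectra alias",
            RuntimeWarning,
            stacklevel=2,
        )
    meta = {
        "kind": "passive",
        "seed": int(seed) if isinstance(seed, (int, np.integer)) else "spawned",
        "n_modes": n_modes,
        "params": {
            "gamma": m.gamma,
            "kappa": m.kappa,
            "eta": m.eta,
            "T": m.T,
            "R_bar": m.R_bar,
        },
    }
    if m.T == 0:
        return ContourSeries(np.zeros((N, T_frames)), m.R_bar, dt, meta)

    variances = mode_variance(m, q)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    # two quadratures (cos/sin) per mode, each carrying the full mode
    # variance: at any fixed site cos^2 + sin^2 = 1, so the per-site
    # variance is exactly the mode sum of mode_variance(q_n)
    quad = _ou_bank(
        np.repeat(rates, 2), np.repeat(variances, 2), T_frames, dt, rng
    )
    a = quad[0::2]  # cos amplitudes, (n_modes - 1, T)
    b = quad[1::2]  # sin amplitudes
    coeff = np.zeros((N // 2 + 1, T_frames), dtype=complex)
    coeff[2 : n_modes + 1] = (N / 2.0) * (a - 1j * b)
    dh = np.empty((N, T_frames))
    block = max(1, int(2e7) // max(N, 1))  # bound transform memory
    for t0 in range(0, T_frames, block):
        dh[:, t0 : t0 + block] = np.fft.irfft(coeff[:, t0 : t0 + block], n=N, axis=0)
    return ContourSeries(dh, m.R_bar, dt, meta)


def _draw_corner_rates(a: ActivityParams, n_sites: int, rng) -> np.ndarray:
    if a.rate_mode is RateMode.SINGLE_RATE:
        return np.full(n_sites, a.omega_A)
    lo, hi = a.rate_span
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_sites))


def _telegraph(signs0, p_flip, n_frames, rng):
    """Vectorized +-1 telegraph paths: cumulative product of flip signs."""
    flips = rng.random((signs0.size, n_frames - 1)) < p_flip[:, None]
    steps = np.concatenate(
        [signs0[:, None].astype(float), np.where(flips, -1.0, 1.0)], axis=1
    )
    return np.cumprod(steps, axis=1)


def simulate_active_contour(
    m: MembraneParams,
    a: ActivityParams,
    N: int = 512,
    T_frames: int = 10_000,
    dt: float = 0.5e-3,
    n_modes: int | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ContourSeries:
    """Simulate passive thermal modes plus dichotomous active kickers.

    A random fraction ``a.phi`` of emplacements receives an independent
    telegraph-driven excursion of scale ``a.Lambda0``; with ``phi = 0`` the
    output is bitwise identical to :func:`simulate_passive_contour` at the
    same seed.
    """
    if a.Lambda0 >= m.R_bar / 2.0:
        raise ValueError(
            "unphysical kicking amplitude: Lambda0 must be < R_bar/2"
        )
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # the passive field uses the root stream itself so that phi = 0 is
    # bitwise identical to simulate_passive_contour at the same seed
    (ss_active,) = root.spawn(1)
    series = simulate_passive_contour(
        m, N=N, T_frames=T_frames, dt=dt, n_modes=n_modes, seed=root
    )
    series.meta.update(
        kind="active",
        seed=int(seed) if isinstance(seed, (int, np.integer)) else "spawned",
        activity={
            "phi": a.phi,
            "p_on": a.p_on,
            "f0": a.f0,
            "Lambda0": a.Lambda0,
            "omega_A": a.omega_A,
            "rate_mode": str(a.rate_mode.value),
            "rate_span": list(a.rate_span),
        },
    )
    n_active = int(round(a.phi * N))
    if n_active == 0 or a.f0 == 0 or a.Lambda0 == 0:
        series.meta["active_sites"] = []
        return series

    rng = np.random.default_rng(ss_active)
    sites = np.sort(rng.choice(N, size=n_active, replace=False))
    corner = _draw_corner_rates(a, n_active, rng)  # spectral corner rates
    flip = corner / 2.0  # telegraph flip rate: corr decay exp(-2*nu*|tau|)
    p_flip = (1.0 - np.exp(-2.0 * flip * dt)) / 2.0
    s0 = np.where(rng.random(n_active) < 0.5, 1.0, -1.0)
    s = _telegraph(s0, p_flip, T_frames, rng)

    if a.p_on < 1.0:
        # independent two-state occupancy gate: duty p_on, switching corner
        g = np.empty((n_active, T_frames))
        g[:, 0] = (rng.random(n_active) < a.p_on).astype(float)
        p_on_step = a.p_on * (1.0 - np.exp(-corner * dt))
        p_off_step = (1.0 - a.p_on) * (1.0 - np.exp(-corner * dt))
        u = rng.random((n_active, T_frames - 1))
        for t in range(1, T_frames):
            on = g[:, t - 1] > 0.5
            g[:, t] = np.where(
                on, u[:, t - 1] >= p_off_step, u[:, t - 1] < p_on_step
            ).astype(float)
        s = s * g

    target = a.Lambda0 * s
    zeta = 6.0 * np.pi * series.L * a.eta_solvent
    relax = a.relaxation_rate(zeta)
    decay = np.exp(-relax * dt)
    # first-order relaxation toward the telegraph target through friction
    x = lfilter(
        [1.0 - decay], [1.0, -decay], target, axis=1, zi=(decay * target[:, :1])
    )[0]
    series.dh[sites] += x
    series.meta["active_sites"] = sites.tolist()
    series.meta["corner_rates"] = corner.tolist()
    return series


def telegraph_ensemble_psd(omega, sigma2: float, rate_low: float, rate_high: float):
    """Closed-form ensemble PSD of log-uniform telegraph corner rates.

    One-sided density (m^2*s per rad/s, integral over omega = sigma2) of the
    superposition of Lorentzians with corner rates log-uniform in
    [rate_low, rate_high]; falls off as 1/omega inside the span.
    """
    omega = np.asarray(omega, float)
    norm = 2.0 * sigma2 / (np.pi * np.log(rate_high / rate_low))
    return norm * (np.arctan(rate_high / omega) - np.arctan(rate_low / omega)) / omega
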