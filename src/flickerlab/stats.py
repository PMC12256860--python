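"""Real-space flickering statistics.

Local deformation variances and their ensemble average, displacement
probability densities, the equipartition elasticity G = kB*T/Sigma^2,
variance-based effective temperature maps with hot-spot detection, frame
velocities and Green-Kubo diffusivities, and the mobility-deformability
density map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._constants import KB
from .series import ContourSeries

__all__ = [
    "FlickerStats",
    "local_variance",
    "ensemble_variance",
    "displacement_pdf",
    "effective_elasticity",
    "effective_temperature_map",
    "hot_spot_mask",
    "flicker_velocity",
    "greenkubo_diffusivity",
    "mobility_deformability_map",
    "compute_flicker_stats",
]


def local_variance(s: ContourSeries) -> np.ndarray:
    """Per-emplacement time variance sigma_i^2 (m^2), site mean removed."""
    if s.n_frames < 100:
        raise ValueError("need at least 100 frames for local variances")
    return np.var(s.dh, axis=1)


def ensemble_variance(sigma2: np.ndarray) -> tuple[float, float]:
    """Ensemble variance Sigma^2 = mean_i(sigma_i^2) and 2*Sigma (m)."""
    sigma2 = np.asarray(sigma2, float)
    if sigma2.size < 1:
        raise ValueError("need at least one site variance")
    Sigma2 = float(np.mean(sigma2))
    return Sigma2, 2.0 * float(np.sqrt(Sigma2))


@dataclass
class DisplacementPdf:
    """Pooled displacement histogram with a Gaussian maximum-likelihood fit."""

    edges: np.ndarray
    density: np.ndarray
    mean: float
    sigma_fit: float
    frac_within_2sigma: float
    n_samples: int


def displacement_pdf(s: ContourSeries, bins: int = 101) -> DisplacementPdf:
    """Normalized PDF of pooled displacements with a Gaussian ML fit.

    The Gaussian fit is the sample (mean, std); the fraction of events
    within +-2*Sigma of the mean is reported (Gaussian expectation 0.954).
    """
    pooled = s.dh.ravel()
    if pooled.size < 10_000:
        raise ValueError("need >= 1e4 pooled samples for a stable PDF")
    sigma = float(np.std(pooled))
    if sigma == 0:
        raise ValueError("degenerate input: zero variance")
    mu = float(np.mean(pooled))
    density, edges = np.histogram(pooled, bins=bins, density=True)
    frac = float(np.mean(np.abs(pooled - mu) <= 2.0 * sigma))
    return DisplacementPdf(edges, density, mu, sigma, frac, pooled.size)


def effective_elasticity(Sigma2: float, T: float) -> float:
    """Equipartition elasticity G = kB*T/Sigma^2 (N/m)."""
    if Sigma2 <= 0:
        raise ValueError("Sigma2 must be > 0")
    return KB * T / Sigma2


def effective_temperature_map(sigma2: np.ndarray, G0: float, T: float) -> np.ndarray:
    """Local effective temperatures Teff_i = G0*sigma_i^2/kB (K).

    Normalized so a site fluctuating at the basal passive variance
    kB*T/G0 maps to Teff = T; linear in sigma_i^2.
    """
    if G0 <= 0:
        raise ValueError("G0 must be > 0")
    del T  # fixed point Teff(kB*T/G0) = T holds by construction
    return G0 * np.asarray(sigma2, float) / KB


def hot_spot_mask(
    sigma2: np.ndarray, Sigma2_ref: float, k: float = 2.0
) -> tuple[np.ndarray, float]:
    """Hot-spot mask and activated fraction estimate.

    A site is hot iff sigma_i^2 >= k^2 * Sigma2_ref (boundary inclusive;
    default k = 2 ties the criterion to the Lambda0 = 2*Sigma displacement
    scale).  Returns ``(mask, phi_est = N_hot/N)``.
    """
    if Sigma2_ref <= 0:
        raise ValueError("Sigma2_ref must be > 0")
    sigma2 = np.asarray(sigma2, float)
    mask = sigma2 >= k**2 * Sigma2_ref
    return mask, float(np.mean(mask))


def flicker_velocity(s: ContourSeries) -> np.ndarray:
    """Frame velocities v_i(t) = (dh_i(t+dt) - dh_i(t))/dt, shape (N, T-1)."""
    if s.n_frames < 2:
        raise ValueError("need at least 2 frames")
    return np.diff(s.dh, axis=1) / s.dt


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocovariance of rows of x up to max_lag (FFT-based)."""
    n = x.shape[-1]
    xc = x - x.mean(axis=-1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(xc, nfft, axis=-1)
    acov = np.fft.irfft(fx * np.conj(fx), nfft, axis=-1)[..., : max_lag + 1]
    return acov / n


def greenkubo_diffusivity(
    v: np.ndarray, dt: float, lag_cap: int = 100
) -> np.ndarray:
    """Green-Kubo diffusivities D_i from velocity autocorrelation (m^2/s).

    Integrates the per-site velocity autocovariance (trapezoid) up to its
    first zero crossing, interpolating the crossing; lags are capped at
    ``lag_cap``.  For memoryless (free Brownian) input this equals
    MSD(dt)/(2*dt); a non-decaying autocorrelation triggers a warning and
    truncation at the cap.
    """
    v = np.atleast_2d(np.asarray(v, float))
    if v.shape[1] < 1000:
        raise ValueError("need >= 1e3 velocity samples per site")
    max_lag = min(lag_cap, v.shape[1] - 1)
    acov = _acf(v, max_lag)
    D = np.empty(v.shape[0])
    truncated = False
    for i, c in enumerate(acov):
        sign_change = np.nonzero(np.signbit(c[1:]) != np.signbit(c[0]))[0]
        if sign_change.size == 0:
            truncated = True
            k = max_lag
            area = np.trapezoid(c[: k + 1], dx=dt)
        else:
            k = int(sign_change[0]) + 1  # first lag past the crossing
            area = np.trapezoid(c[:k], dx=dt)
            # triangle out to the interpolated zero between lags k-1 and k
            frac = c[k - 1] / (c[k - 1] - c[k])
            area += 0.5 * c[k - 1] * frac * dt
        D[i] = area
    if truncated:
        warnings.warn(
            "velocity autocorrelation did not decay within the lag cap; "
            "diffusivity truncated",
            RuntimeWarning,
            stacklevel=2,
        )
    return D


def mobility_deformability_map(
    Dloc: np.ndarray, sigma: np.ndarray, bins: int | tuple = 40
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized 2D density of (sigma_i, D_i) pooled over cells.

    Returns ``(density, sigma_edges, D_edges)`` with
    sum(density)*bin_area = 1.
    """
    Dloc = np.asarray(Dloc, float).ravel()
    sigma = np.asarray(sigma, float).ravel()
    if Dloc.size == 0 or sigma.size != Dloc.size:
        raise ValueError("need equal-length, non-empty sigma and D arrays")
    density, se, de = np.histogram2d(sigma, Dloc, bins=bins, density=True)
    return density, se, de


@dataclass
class FlickerStats:
    """Bundle of real-space flickering statistics for one contour series."""

    sigma2: np.ndarray
    Sigma2: float
    two_Sigma: float
    G_eff: float
    Teff_map: np.ndarray
    hot_mask: np.ndarray
    phi_est: float
    Dloc: np.ndarray
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "Sigma_nm": 1e9 * np.sqrt(self.Sigma2),
            "two_Sigma_nm": 1e9 * self.two_Sigma,
            "G_eff_uN_per_m": 1e6 * self.G_eff,
            "phi_est": self.phi_est,
            "mean_Teff_K": float(np.mean(self.Teff_map)),
            "mean_D_um2_per_s": 1e12 * float(np.mean(self.Dloc)),
        }


def compute_flicker_stats(
    s: ContourSeries,
    T: float,
    G0: float | None = None,
    Sigma2_ref: float | None = None,
    k_hot: float = 2.0,
    lag_cap: int = 100,
) -> FlickerStats:
    """Compute the full real-space statistics bundle for a series.

    ``G0`` defaults to the equipartition elasticity of the series itself;
    ``Sigma2_ref`` (hot-spot reference variance) defaults to the *median*
    site variance, a robust estimate of the passive background that is not
    inflated by the hot spots themselves.
    """
    sigma2 = local_variance(s)
    Sigma2, two_Sigma = ensemble_variance(sigma2)
    G_eff = effective_elasticity(Sigma2, T)
    if G0 is None:
        G0 = G_eff
    if Sigma2_ref is None:
        Sigma2_ref = float(np.median(sigma2))
    Teff = effective_temperature_map(sigma2, G0, T)
    mask, phi_est = hot_spot_mask(sigma2, Sigma2_ref, k=k_hot)
    v = flicker_velocity(s)
    Dloc = greenkubo_diffusivity(v, s.dt, lag_cap=lag_cap)
    return FlickerStats(
        sigma2=sigma2,
        Sigma2=Sigma2,
        two_Sigma=two_Sigma,
        G_eff=G_eff,
        Teff_map=Teff,
        hot_mask=mask,
        phi_est=phi_est,
        Dloc=Dloc,
        meta={"T": T, "G0": G0, "Sigma2_ref": Sigma2_ref, "k_hot": k_hot},
    )
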