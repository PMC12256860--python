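"""Power spectral density estimation of flickering displacement series.

The one-sided PSD is estimated per emplacement with Welch's method (Hann
window, 50% overlap, per-segment mean removal) and averaged over the
contour ensemble.  Densities are expressed on an angular-frequency grid
(rad/s) normalized so the integral over ordinary frequency equals the
series variance:  psd(omega) = S_f(f)/(2*pi) with omega = 2*pi*f, hence
sum(psd)*d_omega ~= var.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .series import ContourSeries

__all__ = ["Spectrum", "compute_psd", "fit_powerlaw"]


@dataclass
class Spectrum:
    """One-sided displacement PSD on an angular-frequency grid.

    ``psd`` is the ensemble mean over emplacements; ``psd_sites`` optionally
    retains the per-site densities.
    """

    omega: np.ndarray  # rad/s, strictly increasing, > 0
    psd: np.ndarray  # m^2 * s (per rad/s)
    n_segments: int = 1
    scope: str = "ensemble"
    psd_sites: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, float)
        self.psd = np.asarray(self.psd, float)
        if self.omega.ndim != 1 or np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be strictly increasing")
        if np.any(self.omega <= 0):
            raise ValueError("omega grid must be positive")
        if self.psd.shape != self.omega.shape:
            raise ValueError("psd and omega shapes differ")
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")

    def integral(self) -> float:
        """Total spectral power = integral of psd over omega (m^2)."""
        domega = self.omega[1] - self.omega[0]
        return float(np.sum(self.psd) * domega)

    def local_slope(self, smooth: int = 5) -> np.ndarray:
        """Local log-log slope d(log psd)/d(log omega), lightly smoothed."""
        logw = np.log(self.omega)
        logp = np.log(np.maximum(self.psd, np.finfo(float).tiny))
        slope = np.gradient(logp, logw)
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            slope = np.convolve(slope, kernel, mode="same")
        return slope

    def band(self, omega_lo: float, omega_hi: float) -> "Spectrum":
        sel = (self.omega >= omega_lo) & (self.omega <= omega_hi)
        return Spectrum(
            self.omega[sel],
            self.psd[sel],
            n_segments=self.n_segments,
            scope=self.scope,
            meta=dict(self.meta),
        )

    def plot(self, ax=None, **kwargs):
        """Log-log PSD plot; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(self.omega, self.psd, **kwargs)
        ax.set_xlabel(r"$\omega$ (rad/s)")
        ax.set_ylabel(r"PSD (m$^2\,$s)")
        return ax


def compute_psd(
    s: ContourSeries,
    segment_length: int = 4096,
    window: str = "hann",
    sites: np.ndarray | None = None,
    keep_sites: bool = False,
) -> Spectrum:
    """Welch-averaged one-sided PSD, ensemble-averaged over emplacements.

    Parameters
    ----------
    s : ContourSeries
    segment_length : int
        Welch segment length (frames); 50% overlap, Hann window,
        per-segment mean removal.
    sites : array of int, optional
        Restrict the ensemble average to these emplacements.
    keep_sites : bool
        Retain the per-site PSD matrix on the returned Spectrum.
    """
    if s.n_frames < 2 * segment_length:
        raise ValueError(
            f"series too short: need >= {2 * segment_length} frames for "
            f"segment_length={segment_length}"
        )
    dh = s.dh if sites is None else s.dh[np.asarray(sites)]
    fs = 1.0 / s.dt
    f, S = signal.welch(
        dh,
        fs=fs,
        window=window,
        nperseg=segment_length,
        noverlap=segment_length // 2,
        detrend="constant",
        axis=1,
    )
    # drop the DC bin; convert to angular frequency density
    omega = 2.0 * np.pi * f[1:]
    psd_sites = S[:, 1:] / (2.0 * np.pi)
    n_segments = max(1, (dh.shape[1] - segment_length // 2) // (segment_length // 2))
    return Spectrum(
        omega=omega,
        psd=psd_sites.mean(axis=0),
        n_segments=n_segments,
        scope="ensemble" if dh.shape[0] > 1 else "site",
        psd_sites=psd_sites if keep_sites else None,
        meta={"segment_length": segment_length, "window": window, "dt": s.dt},
    )


def fit_powerlaw(sp: Spectrum, omega_range: tuple[float, float]):
    """Least-squares log-log slope of the PSD over ``omega_range``.

    Returns ``(exponent, stderr)``.  Requires >= 8 grid points in range.
    """
    lo, hi = omega_range
    if lo >= hi:
        raise ValueError("omega_range must be (low, high) with low < high")
    if lo < sp.omega[0] or hi > sp.omega[-1]:
        raise ValueError(
            f"omega_range ({lo:g}, {hi:g}) outside spectral grid "
            f"({sp.omega[0]:g}, {sp.omega[-1]:g})"
        )
    sel = (sp.omega >= lo) & (sp.omega <= hi)
    if np.count_nonzero(sel) < 8:
        raise ValueError("need at least 8 grid points inside omega_range")
    x = np.log(sp.omega[sel])
    y = np.log(sp.psd[sel])
    # polyfit covariance is scaled by chi2/dof, i.e. stderr from residuals
    (slope, _), cov = np.polyfit(x, y, 1, cov=True)
    return float(slope), float(np.sqrt(cov[0, 0]))
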