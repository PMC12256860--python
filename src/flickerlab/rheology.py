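"""Flickering microrheology: GSER inversion and fractional viscoelastic fits.

The displacement PSD is converted to a complex effective modulus
G_eff(omega) = G'(omega) + i*omega*eta_eff(omega) through the generalized
Stokes-Einstein relation in the Mason-Weitz local power-law form: the
spectral mean-square displacement MSD(1/omega) is computed from the PSD,
its local log-log slope beta in [0, 1] sets the loss angle pi*beta/2, and

    |G_eff(omega)| = C_cal * kB*T / (MSD(1/omega) * Gamma(1 + beta)),

with the calibration constant C_cal = 2 fixed once, analytically, by the
requirement that a harmonically trapped overdamped bead (an OU process)
returns its trap stiffness kB*T/Var exactly on the low-frequency plateau.
It is never refit.

Model classes (statsmodels-style, ``Model(...).fit() -> Results``):

* :class:`FractionalRigidityModel` -- effective rigidity
  G(omega) = G_gamma + G_kappa * x^(2a)/(1 + x^(2a)),  x = omega*tau_D,
  the fractional Maxwell (Cole-Cole) rigidity with tension plateau
  G_gamma = gamma_eff/R and anomalous exponent 0 <= alpha <= 1 (alpha = 1
  normal diffusion, 1/3 pure bending); optionally scaled by the active
  effective-temperature kernel.
* :class:`FractionalViscosityModel` -- conjugate fractional viscosity
  eta(omega) = eta0 + (G0/omega_D) * x^(a-1)/(1 + x^(2a)) + eta_kick,
  reducing exactly to the Maxwell form eta0 + G0*omega_D/(omega^2+omega_D^2)
  for alpha = 1 and no kickers.
* :class:`BicomponentSpectrumModel` -- passive + active PSD decomposition
  PSD = kB*T/(omega*(G_gamma + c_kappa*omega^(2/3)))
        + A_act * telegraph-ensemble shape(omega; omega_A, omega_hi),
  with the active amplitude proportional to phi*f0*Lambda0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import gamma as gamma_fn

import numpy as np
import lmfit

from ._constants import KB
from .spectral import Spectrum

__all__ = [
    "RheoSpectrum",
    "gser_modulus",
    "effective_temperature_kernel",
    "viscoelastic_ratio_and_crossovers",
    "estimate_knee",
    "maxwell_viscosity",
    "FractionalFitResults",
    "FractionalRigidityModel",
    "FractionalViscosityModel",
    "BicomponentSpectrumModel",
    "fit_fractional_rigidity",
    "fit_fractional_viscosity",
    "GSER_CALIBRATION",
]

#: GSER calibration constant, fixed by the OU-trap plateau identity
#: G_plateau = kB*T/Var = C_cal*kB*T/MSD(inf) with MSD(inf) = 2*Var.
GSER_CALIBRATION = 2.0


@dataclass
class RheoSpectrum:
    """Viscoelastic spectrum derived from a displacement PSD.

    ``eta_eff`` is the bulk-equivalent microviscosity G''/(omega*6*pi*L)
    in Pa*s; ``ratio`` the viscoelastic ratio G'/(G''/omega) in 1/s.
    """

    omega: np.ndarray
    G_mag: np.ndarray  # |G_eff| (N/m)
    G_prime: np.ndarray  # elastic part (N/m)
    G_loss: np.ndarray  # viscous part omega*eta (N/m)
    eta_eff: np.ndarray  # Pa*s
    alpha_local: np.ndarray  # local MSD log-slope beta(omega) in [0, 1]
    L: float
    T: float
    psd: np.ndarray | None = None  # source PSD on the same grid
    meta: dict = field(default_factory=dict)

    @property
    def ratio(self) -> np.ndarray:
        """Viscoelastic ratio G'/eta_surface = omega*G'/G'' (1/s)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.omega * self.G_prime / self.G_loss

    def band(self, omega_lo: float, omega_hi: float) -> "RheoSpectrum":
        sel = (self.omega >= omega_lo) & (self.omega <= omega_hi)
        return RheoSpectrum(
            self.omega[sel],
            self.G_mag[sel],
            self.G_prime[sel],
            self.G_loss[sel],
            self.eta_eff[sel],
            self.alpha_local[sel],
            self.L,
            self.T,
            psd=None if self.psd is None else self.psd[sel],
            meta=dict(self.meta),
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(self.omega, self.G_prime, label="G'")
        ax.loglog(self.omega, self.G_loss, label='G"')
        ax.set_xlabel(r"$\omega$ (rad/s)")
        ax.set_ylabel("modulus (N/m)")
        ax.legend()
        return ax


def _spectral_msd(
    omega: np.ndarray,
    psd: np.ndarray,
    dt_eff: float,
    max_lags: int = 20_000,
    sampled: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """MSD on the sampling-lag grid tau_k = k*dt_eff from a one-sided PSD.

    For a PSD estimated from data sampled at dt_eff, the in-band (aliased)
    spectrum integrated against (1 - cos(omega*tau_k)) at integer lag
    multiples reproduces the time-domain MSD exactly, so no out-of-band
    correction is needed (``sampled=True``).  For a continuous synthetic
    spectrum (``sampled=False``) the power above the grid is added as a
    constant: at lags >= dt_eff = pi/omega_max the tail's (1 - cos) factor
    averages to one.
    """
    K = int(min(max_lags, max(3, np.floor(1.0 / (omega[0] * dt_eff)))))
    tau = dt_eff * np.arange(1, K + 1)
    domega = np.gradient(omega)
    weight = psd * domega
    msd = np.empty(K)
    block = max(1, int(2e7) // omega.size)
    for k0 in range(0, K, block):
        phase = np.outer(tau[k0 : k0 + block], omega)
        msd[k0 : k0 + block] = 2.0 * np.sum(weight * (1.0 - np.cos(phase)), axis=1)
    if not sampled:
        top = omega >= omega[-1] / 2.0
        if np.count_nonzero(top) >= 4:
            p = -np.polyfit(np.log(omega[top]), np.log(psd[top]), 1)[0]
            if p > 1.05:
                tail_power = psd[-1] * omega[-1] / (p - 1.0)
                msd = msd + 2.0 * tail_power
    return tau, msd


def gser_modulus(sp: Spectrum, L: float, T: float) -> RheoSpectrum:
    """Convert a displacement PSD to an effective viscoelastic spectrum.

    Mason-Weitz local power-law GSER (see module docstring).  Points where
    the PSD vanishes are masked out.
    """
    if L <= 0 or T <= 0:
        raise ValueError("need L > 0 and T > 0")
    keep = sp.psd > 0
    omega_full = sp.omega[keep]
    psd_full = sp.psd[keep]
    dt_meta = sp.meta.get("dt") if isinstance(sp.meta, dict) else None
    nyq_dt = np.pi / omega_full[-1]
    sampled = dt_meta is not None and abs(dt_meta - nyq_dt) < 0.25 * nyq_dt
    dt_eff = dt_meta if sampled else nyq_dt
    tau, msd = _spectral_msd(omega_full, psd_full, dt_eff, sampled=sampled)
    logtau = np.log(tau)
    logmsd = np.log(msd)
    # local log-log regression (half-decade window): slope -> beta, fitted
    # value -> smoothed MSD
    half_window = 0.5 * np.log(10.0) / 2.0
    beta_l = np.empty_like(logmsd)
    smoothed = np.empty_like(logmsd)
    for i, lt in enumerate(logtau):
        lo = np.searchsorted(logtau, lt - half_window)
        hi = np.searchsorted(logtau, lt + half_window)
        sl = slice(min(lo, len(logtau) - 3), max(hi, lo + 3))
        xw = logtau[sl] - logtau[sl].mean()
        yw = logmsd[sl]
        denom = np.dot(xw, xw)
        b = np.dot(xw, yw - yw.mean()) / denom if denom > 0 else 0.0
        beta_l[i] = b
        smoothed[i] = yw.mean() + b * (lt - logtau[sl].mean())
    # loss-angle floor: at an elastic plateau the measured slope -> 0 and
    # the viscous branch would vanish identically; a small floor keeps
    # eta_eff defined (and ~ 1/omega there) without affecting G'
    beta_l = np.clip(beta_l, 5e-3, 1.0)
    msd_s = np.exp(smoothed)
    # output frequency grid: tau = 1/omega must lie on the lag grid
    out = (omega_full >= 1.0 / tau[-1]) & (omega_full <= 1.0 / tau[0])
    omega = omega_full[out]
    psd = psd_full[out]
    tau_eval = 1.0 / omega
    msd_w = np.exp(np.interp(np.log(tau_eval), logtau, np.log(msd_s)))
    beta_w = np.interp(np.log(tau_eval), logtau, beta_l)
    gamma_corr = np.array([gamma_fn(1.0 + b) for b in beta_w])
    G_mag = GSER_CALIBRATION * KB * T / (msd_w * gamma_corr)
    G_prime = G_mag * np.cos(np.pi * beta_w / 2.0)
    G_loss = G_mag * np.sin(np.pi * beta_w / 2.0)
    eta_eff = G_loss / (omega * 6.0 * np.pi * L)
    return RheoSpectrum(
        omega=omega,
        G_mag=G_mag,
        G_prime=G_prime,
        G_loss=G_loss,
        eta_eff=eta_eff,
        alpha_local=beta_w,
        L=L,
        T=T,
        psd=psd,
        meta={
            "calibration": GSER_CALIBRATION,
            # untrimmed source spectrum, kept for noise-floor detection
            "omega_full": omega_full,
            "psd_full": psd_full,
        },
    )


def effective_temperature_kernel(omega, phi, f0Lambda0, tau_A, T):
    """Frequency-dependent active temperature Teff(omega) (K).

    Teff = T + (phi*f0*Lambda0/kB) * K(omega*tau_A) with the activity
    kernel K(x) = 2*(1 - cos x)/x^2 normalized so K(0) = 1, hence the
    zero-frequency limit Teff = T + phi*f0*Lambda0/kB.
    """
    if tau_A <= 0:
        raise ValueError("tau_A must be > 0")
    x = np.asarray(omega, float) * tau_A
    small = np.abs(x) < 1e-4
    x_safe = np.where(small, 1.0, x)
    # Taylor branch avoids catastrophic cancellation of 1 - cos(x)
    K = np.where(small, 1.0 - x**2 / 12.0, 2.0 * (1.0 - np.cos(x_safe)) / x_safe**2)
    out = T + (phi * f0Lambda0 / KB) * K
    return out if out.ndim else float(out)


def viscoelastic_ratio_and_crossovers(
    r: RheoSpectrum, floor_slope: float = -0.2
) -> tuple[np.ndarray, float, float | None]:
    """Viscoelastic ratio and the diffusive / noise-floor crossovers.

    Returns ``(ratio, omega_D, omega_C)``: omega_D is the Maxwell crossing
    G' = G'' (log-interpolated; reported as the nearest band edge if no
    crossing exists in band) and omega_C the onset of the flat instrumental
    noise floor, i.e. the first frequency beyond which the local PSD slope
    stays above ``floor_slope`` (None when no floor is visible).
    """
    ratio = r.ratio
    diff = np.log(r.G_prime) - np.log(np.maximum(r.G_loss, np.finfo(float).tiny))
    sign = np.sign(diff)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size:
        i = int(crossings[-1])  # highest-frequency elastic->viscous crossing
        w = np.log(r.omega)
        frac = diff[i] / (diff[i] - diff[i + 1])
        omega_D = float(np.exp(w[i] + frac * (w[i + 1] - w[i])))
    else:
        omega_D = float(r.omega[0] if diff[0] < 0 else r.omega[-1])
        warnings.warn(
            "no Maxwell crossing in band; omega_D reported as band edge",
            RuntimeWarning,
            stacklevel=2,
        )
    omega_C = None
    omega_src = r.meta.get("omega_full") if isinstance(r.meta, dict) else None
    psd_src = r.meta.get("psd_full") if isinstance(r.meta, dict) else None
    if psd_src is None and r.psd is not None:
        omega_src, psd_src = r.omega, r.psd
    if psd_src is not None:
        sp = Spectrum(omega_src, psd_src)
        slope = sp.local_slope(smooth=5)
        # a flat instrumental floor at the top of the band: estimate its
        # level from the top octave, then place the onset where the
        # spectrum falls to twice that level
        top = omega_src >= omega_src[-1] / 2.0
        if np.count_nonzero(top) >= 3 and np.median(slope[top]) > floor_slope:
            level = float(np.median(psd_src[top]))
            below = np.nonzero(psd_src <= 2.0 * level)[0]
            if below.size:
                omega_C = float(omega_src[below[0]])
    return ratio, omega_D, omega_C


def estimate_knee(r: RheoSpectrum, beta_mid: float = 1.0 / 3.0) -> float | None:
    """Onset of the relaxation branch: first omega where the local MSD
    exponent beta rises through ``beta_mid`` and stays above it.

    Returns None when beta never reaches the threshold (plateau-only band).
    """
    above = r.alpha_local >= beta_mid
    if not above.any():
        return None
    below = np.nonzero(~above)[0]
    if below.size == 0:
        return float(r.omega[0])
    first = below[-1] + 1
    if first >= r.omega.size:
        return None
    return float(r.omega[first])


def fit_fractional_rigidity(
    r: RheoSpectrum,
    R_bar: float | None = None,
    T: float | None = None,
) -> FractionalFitResults:
    """Staged fractional-rigidity fit of a measured G'(omega).

    The crossover is estimated first and then held fixed (a free Cole-Cole
    fit is degenerate on spectra whose relaxation knee is broader than the
    model's): (1) the knee frequency omega_knee is located from the
    local-exponent profile; (2) the tension plateau G_gamma is the median
    G' below omega_knee/3; (3) the anomalous exponent alpha and branch
    amplitude come from a log-log regression of G' - G_gamma between
    3*omega_knee and the noise-floor onset (band top if none), i.e. the
    sub-saturation limit G_gamma + G_kappa*(omega*tau_D)^(2*alpha) of the
    fractional Maxwell rigidity with tau_D = 1/omega_knee.  A band with no
    emerging relaxation branch is flagged plateau-only.
    """
    T = r.T if T is None else T
    knee = estimate_knee(r)
    _, _, omega_C = viscoelastic_ratio_and_crossovers(r)
    top = r.omega[-1] if omega_C is None else min(omega_C / 3.0, r.omega[-1])
    if knee is None or np.count_nonzero(
        (r.omega >= 3.0 * knee) & (r.omega <= top)
    ) < 4:
        plateau = float(np.median(r.G_prime))
        params = {
            "G_gamma": plateau,
            "G_kappa": 0.0,
            "tau_D": float("nan"),
            "alpha": float("nan"),
        }
        if R_bar is not None:
            params["gamma_eff"] = plateau * R_bar
        return FractionalFitResults(
            params=params,
            stderr={"G_gamma": float(np.std(r.G_prime) / np.sqrt(r.omega.size))},
            goodness=float(np.std(np.log(r.G_prime))),
            model_name="fractional rigidity (staged)",
            omega=r.omega,
            data=r.G_prime,
            best_fit=np.full_like(r.G_prime, plateau),
            plateau_only=True,
        )
    low = r.omega < knee / 3.0
    gamma_visible = np.count_nonzero(low) >= 3
    plateau = float(np.median(r.G_prime[low])) if gamma_visible else 0.0
    mid = (r.omega >= 3.0 * knee) & (r.omega <= top)
    branch = np.maximum(r.G_prime[mid] - plateau, np.finfo(float).tiny)
    x = np.log(r.omega[mid])
    (slope, intercept), cov = np.polyfit(x, np.log(branch), 1, cov=True)
    alpha = float(np.clip(slope / 2.0, 0.0, 1.0))
    alpha_se = float(np.sqrt(cov[0, 0]) / 2.0)
    A = float(np.exp(intercept))
    tau_D = 1.0 / knee
    G_kappa = A * knee ** (2.0 * alpha)
    best = plateau + A * r.omega ** (2.0 * alpha)
    resid = np.log(best) - np.log(np.maximum(r.G_prime, np.finfo(float).tiny))
    params = {
        "G_gamma": plateau,
        "G_kappa": G_kappa,
        "tau_D": tau_D,
        "alpha": alpha,
        "omega_knee": knee,
        "omega_C": omega_C,
    }
    stderr = {"alpha": alpha_se}
    if gamma_visible:
        stderr["G_gamma"] = float(
            np.std(r.G_prime[low]) / np.sqrt(np.count_nonzero(low))
        )
    if R_bar is not None:
        params["gamma_eff"] = plateau * R_bar
        stderr["gamma_eff"] = stderr.get("G_gamma", float("nan")) * R_bar
    return FractionalFitResults(
        params=params,
        stderr=stderr,
        goodness=float(np.sqrt(np.mean(resid**2))),
        model_name="fractional rigidity (staged)",
        omega=r.omega,
        data=r.G_prime,
        best_fit=best,
    )


def fit_fractional_viscosity(
    r: RheoSpectrum, with_activity: bool = False
) -> FractionalFitResults:
    """Conjugate fractional-viscosity fit of eta_eff(omega).

    A free deterministic multistart fit of the fractional Maxwell
    viscosity; flagged plateau-only when no relaxation knee is visible in
    the local-exponent profile.
    """
    knee = estimate_knee(r)
    model = FractionalViscosityModel(r.omega, r.eta_eff, with_activity=with_activity)
    out = model.fit()
    if knee is None:
        out.plateau_only = True
    else:
        out.params["omega_knee"] = knee
    return out


def maxwell_viscosity(omega, eta0, G0, omega_D):
    """Closed-form Maxwell viscosity eta0 + G0*omega_D/(omega^2 + omega_D^2)."""
    omega = np.asarray(omega, float)
    return eta0 + G0 * omega_D / (omega**2 + omega_D**2)


# ---------------------------------------------------------------------------
# model/results classes
# ---------------------------------------------------------------------------


@dataclass
class FractionalFitResults:
    """Fit results of a fractional viscoelastic model.

    ``params``/``stderr`` are plain dicts; ``goodness`` is the residual
    norm of the weighted log-space fit; ``plateau_only`` flags fits whose
    relaxation branch never emerges inside the fitted band.
    """

    params: dict
    stderr: dict
    goodness: float
    model_name: str
    omega: np.ndarray
    data: np.ndarray
    best_fit: np.ndarray
    plateau_only: bool = False
    passive_only: bool = False
    lmfit_result: object | None = None

    def summary(self) -> str:
        lines = [
            f"{self.model_name} fit",
            "=" * (len(self.model_name) + 4),
            f"{'parameter':>12}  {'value':>12}  {'stderr':>12}",
        ]
        for k, v in self.params.items():
            se = self.stderr.get(k)
            se_s = f"{se:12.4g}" if se is not None and np.isfinite(se) else "         ---"
            v_s = f"{v:12.5g}" if isinstance(v, (int, float)) else f"{v!s:>12}"
            lines.append(f"{k:>12}  {v_s}  {se_s}")
        lines.append(f"residual norm: {self.goodness:.4g}")
        if self.plateau_only:
            lines.append("flag: plateau-only (no relaxation crossover in band)")
        if self.passive_only:
            lines.append("flag: passive-only (active amplitude not identifiable)")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(self.omega, self.data, "o", ms=3, label="data")
        ax.loglog(self.omega, self.best_fit, "-", label="fit")
        ax.set_xlabel(r"$\omega$ (rad/s)")
        ax.legend()
        return ax


def _fit_log_residual(params, model_fn, omega, data, weights):
    model = model_fn(params, omega)
    resid = np.log(model) - np.log(data)
    return resid if weights is None else resid * weights


class _LogSpaceModel:
    """Shared multistart weighted log-space least-squares machinery."""

    model_name = "fractional"

    def __init__(self, omega, data, weights=None):
        omega = np.asarray(omega, float)
        data = np.asarray(data, float)
        keep = (data > 0) & np.isfinite(data)
        self.omega = omega[keep]
        self.data = data[keep]
        self.weights = None if weights is None else np.asarray(weights, float)[keep]
        if self.omega.size < 8:
            raise ValueError("need at least 8 positive data points")

    def _eval(self, params, omega):  # pragma: no cover - abstract
        raise NotImplementedError

    def _make_params(self) -> lmfit.Parameters:  # pragma: no cover - abstract
        raise NotImplementedError

    def _starts(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self) -> FractionalFitResults:
        """Deterministic multistart fit; best start wins, then is polished."""
        best = None
        for start in self._starts():
            params = self._make_params()
            for k, v in start.items():
                params[k].set(value=v)
            try:
                res = lmfit.minimize(
                    _fit_log_residual,
                    params,
                    args=(self._eval, self.omega, self.data, self.weights),
                    method="leastsq",
                    nan_policy="raise",
                )
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError("all fit starts failed")
        return self._package(best)

    def _package(self, res) -> FractionalFitResults:
        params = {k: float(v.value) for k, v in res.params.items()}
        stderr = {
            k: (float(v.stderr) if v.stderr is not None else float("nan"))
            for k, v in res.params.items()
        }
        best_fit = self._eval(res.params, self.omega)
        out = FractionalFitResults(
            params=params,
            stderr=stderr,
            goodness=float(np.sqrt(res.chisqr)),
            model_name=self.model_name,
            omega=self.omega,
            data=self.data,
            best_fit=best_fit,
            lmfit_result=res,
        )
        self._postprocess(out)
        return out

    def _postprocess(self, out: FractionalFitResults) -> None:
        pass

    @staticmethod
    def _tau_starts(omega) -> list[float]:
        """Decade grid of relaxation-time starts spanning the band."""
        lo, hi = 1.0 / omega[-1], 1.0 / omega[0]
        return list(np.geomspace(lo / 3.0, hi * 3.0, 6))


class FractionalRigidityModel(_LogSpaceModel):
    """Fractional Maxwell effective rigidity fitted to G'(omega).

    G(omega) = G_gamma + G_kappa * x^(2a) / (1 + x^(2a)),  x = omega*tau_D,

    with 0 <= alpha <= 1.  ``R_bar`` converts the tension plateau into an
    effective tension gamma_eff = G_gamma * R_bar.  With
    ``with_activity=True`` the relaxation branch is scaled by the active
    temperature kernel Teff(omega; phi, f0*Lambda0, tau_A)/T.
    """

    model_name = "fractional rigidity"

    def __init__(self, omega, g_prime, R_bar=None, T=None, weights=None,
                 with_activity=False):
        super().__init__(omega, g_prime, weights)
        self.R_bar = R_bar
        self.T = T
        self.with_activity = with_activity
        if with_activity and T is None:
            raise ValueError("activity scaling needs the bath temperature T")

    def _eval(self, params, omega):
        p = {k: (v.value if hasattr(v, "value") else v) for k, v in params.items()}
        x = omega * p["tau_D"]
        xa = x ** (2.0 * p["alpha"])
        branch = p["G_kappa"] * xa / (1.0 + xa)
        if self.with_activity:
            scale = (
                effective_temperature_kernel(
                    omega, p["phi"], p["f0Lambda0"], p["tau_A"], self.T
                )
                / self.T
            )
            branch = branch * scale
        return p["G_gamma"] + branch

    def _make_params(self) -> lmfit.Parameters:
        params = lmfit.Parameters()
        scale = float(np.median(self.data))
        params.add("G_gamma", value=max(self.data[0], 1e-30), min=0.0)
        params.add("G_kappa", value=scale, min=1e-30)
        params.add("tau_D", value=1.0 / np.median(self.omega), min=1e-12)
        params.add("alpha", value=1.0 / 3.0, min=0.0, max=1.0)
        if self.with_activity:
            params.add("phi", value=0.3, min=0.0, max=1.0)
            params.add("f0Lambda0", value=10.0 * KB * self.T, min=0.0)
            params.add("tau_A", value=0.02, min=1e-6, vary=False)
        return params

    def _starts(self):
        for alpha0 in (0.15, 1.0 / 3.0, 0.5, 0.8):
            for tau0 in self._tau_starts(self.omega):
                yield {"alpha": alpha0, "tau_D": tau0}

    def _postprocess(self, out: FractionalFitResults) -> None:
        if self.R_bar is not None:
            out.params["gamma_eff"] = out.params["G_gamma"] * self.R_bar
            se = out.stderr.get("G_gamma", float("nan"))
            out.stderr["gamma_eff"] = se * self.R_bar
        x_hi = self.omega[-1] * out.params["tau_D"]
        out.plateau_only = x_hi ** (2.0 * out.params["alpha"]) < 0.5


class FractionalViscosityModel(_LogSpaceModel):
    """Conjugate fractional relaxation fitted to eta_eff(omega).

    eta(omega) = eta0 + (G0/omega_D) * x^(a-1)/(1 + x^(2a)) + eta_kick,
    x = omega*tau_D, omega_D = 1/tau_D.  For alpha = 1 and eta_kick = 0
    this is exactly the Maxwell form eta0 + G0*omega_D/(omega^2+omega_D^2).
    ``eta_kick`` (the active thickening term phi*f0^2/(4*eta0*L)) is held
    fixed at 0 unless ``with_activity=True``.
    """

    model_name = "fractional viscosity"

    def __init__(self, omega, eta_eff, weights=None, with_activity=False):
        super().__init__(omega, eta_eff, weights)
        self.with_activity = with_activity

    def _eval(self, params, omega):
        p = {k: (v.value if hasattr(v, "value") else v) for k, v in params.items()}
        x = omega * p["tau_D"]
        xa2 = x ** (2.0 * p["alpha"])
        branch = p["G0"] * p["tau_D"] * x ** (p["alpha"] - 1.0) / (1.0 + xa2)
        return p["eta0"] + branch + p["eta_kick"]

    def _make_params(self) -> lmfit.Parameters:
        params = lmfit.Parameters()
        params.add("eta0", value=float(self.data[-1]), min=1e-30)
        params.add(
            "G0", value=float(self.data[0] * np.median(self.omega)), min=1e-30
        )
        params.add("tau_D", value=1.0 / np.median(self.omega), min=1e-12)
        params.add("alpha", value=1.0, min=0.0, max=1.0)
        params.add("eta_kick", value=0.0, min=0.0, vary=self.with_activity)
        return params

    def _starts(self):
        for alpha0 in (0.25, 0.5, 1.0):
            for tau0 in self._tau_starts(self.omega):
                yield {"alpha": alpha0, "tau_D": tau0}

    def _postprocess(self, out: FractionalFitResults) -> None:
        x_hi = self.omega[-1] * out.params["tau_D"]
        out.plateau_only = x_hi ** (2.0 * out.params["alpha"]) < 0.5


class BicomponentSpectrumModel(_LogSpaceModel):
    """Passive + active decomposition of an ensemble flickering PSD.

    Passive branch: kB*T / (omega * (G_gamma + c_kappa*omega^(2/3)))
    (tension plateau + bending stress).  Active branch: the closed-form
    telegraph-ensemble spectrum with corner rates log-uniform between
    omega_A and omega_hi, amplitude A_act proportional to phi*f0*Lambda0.

    ``fit`` compares the full model against the passive-only null by AIC
    and flags ``passive_only`` when the active amplitude is not
    identifiable (CI spanning zero or null preferred).
    """

    model_name = "bicomponent spectrum"

    def __init__(self, omega, psd, T, weights=None):
        super().__init__(omega, psd, weights)
        self.T = T

    def _eval(self, params, omega):
        p = {k: (v.value if hasattr(v, "value") else v) for k, v in params.items()}
        passive = KB * self.T / (
            omega
            * (10.0 ** p["lg_G_gamma"] + 10.0 ** p["lg_c_kappa"] * omega ** (2.0 / 3.0))
        )
        r1 = 10.0 ** p["lg_omega_A"]
        r2 = r1 * p["span"]
        active = (
            10.0 ** p["lg_A_act"]
            * 2.0
            / (np.pi * np.log(p["span"]))
            * (np.arctan(r2 / omega) - np.arctan(r1 / omega))
            / omega
        )
        return passive + active

    def _make_params(self) -> lmfit.Parameters:
        # log10 parametrization: the natural scales span ~20 decades
        params = lmfit.Parameters()
        guess_G = abs(KB * self.T / (self.data[0] * self.omega[0]))
        total_power = float(np.trapezoid(self.data, self.omega))
        params.add("lg_G_gamma", value=np.log10(guess_G))
        params.add(
            "lg_c_kappa",
            value=np.log10(guess_G / float(np.median(self.omega)) ** (2.0 / 3.0)),
        )
        params.add("lg_A_act", value=np.log10(total_power))
        params.add(
            "lg_omega_A",
            value=np.log10(50.0),
            min=np.log10(self.omega[0] / 10.0),
            max=np.log10(self.omega[-1]),
        )
        params.add("span", value=100.0, min=3.0, vary=False)
        return params

    def _starts(self):
        for wa in (5.0, 50.0, 500.0):
            yield {"lg_omega_A": np.log10(wa)}

    def _postprocess(self, out: FractionalFitResults) -> None:
        # convert the log10 parameters back to natural units; stderr of
        # 10^x is ln(10)*10^x*stderr(x)
        mapping = {
            "lg_G_gamma": "G_gamma",
            "lg_c_kappa": "c_kappa",
            "lg_A_act": "A_act",
            "lg_omega_A": "omega_A",
        }
        for lg, name in mapping.items():
            value = 10.0 ** out.params.pop(lg)
            out.params[name] = value
            se = out.stderr.pop(lg, float("nan"))
            out.stderr[name] = np.log(10.0) * value * se

    def fit(self) -> FractionalFitResults:
        full = super().fit()
        # passive-only null: active amplitude pinned at (effectively) zero
        null_best = None
        params = self._make_params()
        params["lg_A_act"].set(value=-60.0, vary=False)
        try:
            null_best = lmfit.minimize(
                _fit_log_residual,
                params,
                args=(self._eval, self.omega, self.data, self.weights),
                method="leastsq",
            )
        except Exception:
            pass
        if null_best is not None:
            res = full.lmfit_result
            se = full.stderr.get("A_act", float("nan"))
            amp_ci_spans_zero = (
                not np.isfinite(se) or full.params["A_act"] - 2.0 * se <= 0.0
            )
            if null_best.aic <= res.aic or amp_ci_spans_zero:
                full.passive_only = True
        # crossovers implied by the fitted components
        full.params["omega_D"] = (
            full.params["G_gamma"] / full.params["c_kappa"]
        ) ** 1.5
        return full
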