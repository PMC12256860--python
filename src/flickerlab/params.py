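"""Parameter containers for the membrane simulator.

Two dataclasses describe a simulable cell: :class:`MembraneParams` holds the
passive mechanics of the equatorial contour (tension, bending, viscosity,
geometry, temperature) and :class:`ActivityParams` the cytoskeletal kicker
ensemble (active-site fraction, dichotomous force, excursion scale and
switching rates).  All quantities are SI; angular rates are rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from ._constants import KB, R_BAR_RBC, SIGMA0_RBC, T_BODY

__all__ = ["MembraneParams", "ActivityParams", "RateMode"]

#: Effective ring bending modulus (J) reproducing the healthy ensemble
#: fluctuation scale Sigma ~ 25 nm under the equatorial-section mode
#: normalization (deformation modes n >= 2; n = 1 is rigid translation and
#: is removed by drift correction).  The 1D contour observable compresses
#: the full 2D membrane mode sum, so this is a renormalized, not a
#: molecular, bending modulus.
KAPPA_RING_EFF = 2.9e-18

#: Effective membrane microviscosity (Pa*s) placing the bending-mode
#: relaxation rates inside the 2 kHz acquisition band.
ETA_RING_EFF = 0.5


@dataclass(frozen=True)
class MembraneParams:
    """Passive mechanical parameters of the equatorial membrane contour.

    Parameters
    ----------
    gamma : float
        Lateral (surface) tension, N/m.  Governs long-wavelength modes.
    kappa : float
        Bending modulus, J.  Governs short-wavelength curvature modes.
    eta : float
        Local microviscosity of the membrane environment, Pa*s.
    d : float
        Effective membrane thickness, m (50-100 nm scale; an apparent
        parameter much larger than the bilayer thickness).
    R_bar : float
        Mean equatorial radius, m.
    T : float
        Bath temperature, K.
    G0 : float or None
        Basal passive rigidity, N/m.  Defaults to kB*T/Sigma0^2 with
        Sigma0 the rigidized basal fluctuation scale.
    Sigma0 : float
        Basal fluctuation scale used when ``G0`` is None, m.
    """

    gamma: float = 0.0
    kappa: float = KAPPA_RING_EFF
    eta: float = ETA_RING_EFF
    d: float = 75e-9
    R_bar: float = R_BAR_RBC
    T: float = T_BODY
    G0: float | None = None
    Sigma0: float = SIGMA0_RBC

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("surface tension gamma must be >= 0")
        if self.kappa < 0:
            raise ValueError("bending modulus kappa must be >= 0")
        if self.gamma == 0 and self.kappa == 0:
            raise ValueError("a simulable membrane needs gamma > 0 or kappa > 0")
        if self.eta <= 0:
            raise ValueError("microviscosity eta must be > 0")
        if self.T < 0:
            raise ValueError("temperature T must be >= 0")
        if self.R_bar <= 0:
            raise ValueError("mean radius R_bar must be > 0")
        if self.Sigma0 <= 0:
            raise ValueError("Sigma0 must be > 0")

    @property
    def basal_rigidity(self) -> float:
        """Basal passive rigidity G0 = kB*T/Sigma0^2 unless given (N/m)."""
        if self.G0 is not None:
            return self.G0
        return KB * self.T / self.Sigma0**2

    def replace(self, **kwargs) -> "MembraneParams":
        return replace(self, **kwargs)


class RateMode(str, Enum):
    """How kicker switching rates are assigned across active sites."""

    SINGLE_RATE = "single_rate"
    LOG_UNIFORM_ENSEMBLE = "log_uniform_ensemble"


@dataclass(frozen=True)
class ActivityParams:
    """Cytoskeletal kicker ensemble parameters (Gov-type active sites).

    A fraction ``phi`` of contour emplacements carries a dichotomous
    (telegraph) force +-f0 relaxed through the local friction zeta = 6*pi*L*eta
    toward excursions of scale ``Lambda0``; ``p_on`` is the duty cycle of the
    on-state, ``omega_A`` the spectral corner rate of a single kicker (rad/s;
    the telegraph flip rate is omega_A/2).  In ``log_uniform_ensemble`` mode
    each active site draws its corner rate log-uniformly over ``rate_span``,
    producing a 1/omega (pink) ensemble spectrum inside the span.

    The kicker excursion relaxes against the *solvent* viscosity
    ``eta_solvent`` surrounding the pushed membrane element (not the
    effective in-plane microviscosity governing mode relaxation), so the
    relaxation rate f0/(Lambda0 * 6*pi*L*eta_solvent) sits well above the
    telegraph corners.  The default f0 = kB*T*Lambda0/Sigma^2 of the default
    membrane keeps the Gov identity Teff/T = 1 + phi*f0*Lambda0/(kB*T) exact.
    """

    phi: float = 0.3
    p_on: float = 1.0
    f0: float = 3.4e-13
    Lambda0: float = 50e-9
    omega_A: float = 50.0
    rate_mode: RateMode = RateMode.LOG_UNIFORM_ENSEMBLE
    rate_span: tuple[float, float] = (50.0, 5000.0)
    eta_solvent: float = 1.0e-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("active fraction phi must be in [0, 1]")
        if not 0.0 <= self.p_on <= 1.0:
            raise ValueError("duty cycle p_on must be in [0, 1]")
        if self.f0 < 0:
            raise ValueError("kicking force f0 must be >= 0")
        if self.Lambda0 < 0:
            raise ValueError("kicking displacement Lambda0 must be >= 0")
        if self.omega_A <= 0:
            raise ValueError("kicking rate omega_A must be > 0")
        lo, hi = self.rate_span
        if not (0 < lo < hi):
            raise ValueError("rate_span must satisfy 0 < low < high")
        if self.eta_solvent <= 0:
            raise ValueError("eta_solvent must be > 0")
        object.__setattr__(self, "rate_mode", RateMode(self.rate_mode))

    @property
    def kick_energy(self) -> float:
        """Unitary kicker energy epsilon_kick = f0 * Lambda0 (J)."""
        return self.f0 * self.Lambda0

    def spring_constant(self) -> float:
        """Effective spring f0/Lambda0 confining a kicker excursion (N/m)."""
        if self.Lambda0 == 0:
            raise ValueError("Lambda0 = 0 has no finite excursion spring")
        return self.f0 / self.Lambda0

    def relaxation_rate(self, zeta: float) -> float:
        """Excursion relaxation rate f0/(Lambda0*zeta) for friction zeta."""
        return self.spring_constant() / zeta

    def replace(self, **kwargs) -> "ActivityParams":
        return replace(self, **kwargs)
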