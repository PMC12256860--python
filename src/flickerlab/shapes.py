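"""Morphotype fixture shapes: closed contours in radial form R(theta).

Generates the four erythrocyte morphotype classes used to exercise the
classifier and the imaging chain: circular discocytes, elliptical cells,
spiculated echinocytes and low-contrast ghosts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["ShapeKind", "ShapeSpec", "generate_shape"]


class ShapeKind(str, Enum):
    CIRCLE = "circle"
    ELLIPSE = "ellipse"
    SPICULATED = "spiculated"
    GHOST = "ghost"


@dataclass(frozen=True)
class ShapeSpec:
    """Specification of a test contour.

    ``R`` is the reference radius (m); ``axis_ratio`` the minor/major ratio
    for ellipses; ``lobes``/``lobe_amplitude`` the spicule count m and
    fractional amplitude a of R(theta) = R*(1 + a*cos(m*theta));
    ``contrast`` the ring contrast used when rendering (ghosts are low).
    """

    kind: ShapeKind = ShapeKind.CIRCLE
    R: float = 3.6e-6
    axis_ratio: float = 1.0
    lobes: int = 0
    lobe_amplitude: float = 0.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ShapeKind(self.kind))
        if not 0.0 < self.axis_ratio <= 1.0:
            raise ValueError("axis_ratio must be in (0, 1]")
        if self.lobes < 0:
            raise ValueError("lobes must be >= 0")
        if not 0.0 <= self.lobe_amplitude < 1.0:
            raise ValueError("lobe_amplitude must be in [0, 1)")
        if self.R <= 0:
            raise ValueError("R must be > 0")


def generate_shape(spec: ShapeSpec, n_angles: int = 2048) -> np.ndarray:
    """Radii of the closed contour over ``n_angles`` uniform angles (m).

    circle/ghost -> constant radius; ellipse -> radial form of an ellipse
    with semi-axes (R*axis_ratio, R); spiculated -> R*(1 + a*cos(m*theta)).
    """
    theta = 2.0 * np.pi * np.arange(n_angles) / n_angles
    if spec.kind in (ShapeKind.CIRCLE, ShapeKind.GHOST):
        return np.full(n_angles, spec.R)
    if spec.kind is ShapeKind.ELLIPSE:
        a_major = spec.R
        b_minor = spec.R * spec.axis_ratio
        return (
            a_major
            * b_minor
            / np.sqrt((b_minor * np.cos(theta)) ** 2 + (a_major * np.sin(theta)) ** 2)
        )
    if spec.kind is ShapeKind.SPICULATED:
        return spec.R * (1.0 + spec.lobe_amplitude * np.cos(spec.lobes * theta))
    raise ValueError(f"unknown shape kind {spec.kind!r}")
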