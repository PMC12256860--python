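"""Erythrocyte morphotype classification from equatorial contours.

Implements the circularity/contourness screen: principal radii from the
second area moments of the enclosed polygon (equivalent-ellipse estimator,
robust to spiculation), circularity c = R1/R2 with the discocyte threshold
c > 0.95, relative contourness Delta = (D - 2*pi*R_bar)/(2*pi*R_bar) with
the echinocyte threshold Delta > 0.1, and a ring-contrast test for ghosts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Morphotype",
    "MorphotypeRecord",
    "principal_radii",
    "circularity_index",
    "contourness",
    "classify_morphotype",
    "population_distribution",
    "record_from_contour",
    "CIRCULARITY_THRESHOLD",
    "CONTOURNESS_THRESHOLD",
]

#: Discocyte circularity threshold: c = R1/R2 > 0.95.
CIRCULARITY_THRESHOLD = 0.95
#: Echinocyte relative-contourness threshold: Delta > 0.1.
CONTOURNESS_THRESHOLD = 0.1


class Morphotype(str, Enum):
    DISCOCYTE = "discocyte"
    ELLIPTOCYTE = "elliptocyte"
    ECHINOCYTE = "echinocyte"
    GHOST = "ghost"
    DEBRIS = "debris"


@dataclass
class MorphotypeRecord:
    """Shape metrics of one cell contour.

    R1 <= R2 are the principal radii (m), c = R1/R2 the circularity,
    D the contour length (m), Delta the relative contourness, and
    ``contrast`` the ring contrast used for the ghost test.
    """

    R1: float
    R2: float
    c: float
    D: float
    Delta: float
    contrast: float = 1.0
    label: Morphotype | None = None
    valid: bool = True


def _polygon_xy(radii: np.ndarray, angles: np.ndarray | None = None):
    radii = np.asarray(radii, float)
    if angles is None:
        angles = 2.0 * np.pi * np.arange(radii.size) / radii.size
    return radii * np.cos(angles), radii * np.sin(angles)


def _polygon_moments(x: np.ndarray, y: np.ndarray):
    """Signed area, centroid and second central area moments of a polygon."""
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = 0.5 * np.sum(cross)
    if A == 0:
        raise ValueError("degenerate polygon (zero area)")
    cx = np.sum((x + x1) * cross) / (6.0 * A)
    cy = np.sum((y + y1) * cross) / (6.0 * A)
    Ixx = np.sum((x**2 + x * x1 + x1**2) * cross) / (12.0 * A) - cx**2
    Iyy = np.sum((y**2 + y * y1 + y1**2) * cross) / (12.0 * A) - cy**2
    Ixy = (
        np.sum((x * y1 + 2.0 * x * y + 2.0 * x1 * y1 + x1 * y) * cross) / (24.0 * A)
        - cx * cy
    )
    return A, (cx, cy), np.array([[Ixx, Ixy], [Ixy, Iyy]])


def principal_radii(
    contour: np.ndarray, angles: np.ndarray | None = None
) -> tuple[float, float]:
    """Principal radii (R1 <= R2) of the equivalent ellipse of a contour.

    The contour is a closed polygon given as radii over uniform angles (or
    with explicit ``angles``).  The semi-axes follow from the second
    central area moments of the enclosed region: a uniform ellipse with
    semi-axes (a, b) has eigen-moments (a^2/4, b^2/4), so R = 2*sqrt(lam).
    """
    radii = np.asarray(contour, float)
    if radii.size < 16:
        raise ValueError("need a closed contour with >= 16 points")
    if not np.all(np.isfinite(radii)) or np.any(radii <= 0):
        # a radial contour with nonpositive radius crosses itself through
        # the origin
        raise ValueError("self-intersecting or degenerate contour")
    x, y = _polygon_xy(radii, angles)
    A, _, cov = _polygon_moments(x, y)
    if A < 0:  # orientation only; moments formulas handle either sign
        pass
    lam = np.linalg.eigvalsh(cov)
    if np.any(lam <= 0):
        raise ValueError("self-intersecting or degenerate contour")
    R = 2.0 * np.sqrt(lam)
    return float(R[0]), float(R[1])


def circularity_index(R1: float, R2: float) -> float:
    """Canonical circularity c = R1/R2 in (0, 1]."""
    if R2 <= 0:
        raise ValueError("R2 must be > 0")
    return R1 / R2


def contourness(
    contour: np.ndarray,
    R_bar: float | None = None,
    angles: np.ndarray | None = None,
) -> float:
    """Relative contourness Delta = (D - 2*pi*R_bar) / (2*pi*R_bar).

    D is the polygonal arc length; R_bar defaults to the angular mean
    radius of the contour (per-cell convention), for which D >= 2*pi*R_bar
    and hence Delta >= 0 (tiny negative discretization residuals clamp to
    zero).
    """
    radii = np.asarray(contour, float)
    x, y = _polygon_xy(radii, angles)
    D = float(np.sum(np.hypot(np.diff(np.append(x, x[0])), np.diff(np.append(y, y[0])))))
    if R_bar is None:
        R_bar = float(np.mean(radii))
    return max((D - 2.0 * np.pi * R_bar) / (2.0 * np.pi * R_bar), 0.0)


def classify_morphotype(
    rec: MorphotypeRecord, contrast_min: float = 0.2
) -> Morphotype:
    """Threshold classification with precedence ghost > echinocyte >
    elliptocyte > discocyte.

    Contrast failure invalidates the shape metrics (ghost); contourness
    supersedes circularity because echinocytes can be globally circular.
    Invalid records are debris.
    """
    if not rec.valid or not np.isfinite(rec.c):
        label = Morphotype.DEBRIS
    elif rec.contrast < contrast_min:
        label = Morphotype.GHOST
    elif rec.Delta > CONTOURNESS_THRESHOLD:
        label = Morphotype.ECHINOCYTE
    elif rec.c <= CIRCULARITY_THRESHOLD:
        label = Morphotype.ELLIPTOCYTE
    else:
        label = Morphotype.DISCOCYTE
    rec.label = label
    return label


def population_distribution(labels) -> dict:
    """Percentage distribution per class; debris excluded from the
    denominator and reported separately as ``debris_fraction``."""
    labels = [Morphotype(lbl) for lbl in labels]
    if not labels:
        raise ValueError("empty label list")
    n_debris = sum(1 for lbl in labels if lbl is Morphotype.DEBRIS)
    counted = [lbl for lbl in labels if lbl is not Morphotype.DEBRIS]
    out = {}
    if counted:
        for kind in Morphotype:
            if kind is Morphotype.DEBRIS:
                continue
            n = sum(1 for lbl in counted if lbl is kind)
            if n:
                out[kind.value] = 100.0 * n / len(counted)
    out["debris_fraction"] = n_debris / len(labels)
    return out


def record_from_contour(
    contour: np.ndarray,
    contrast: float = 1.0,
    angles: np.ndarray | None = None,
    contrast_min: float = 0.2,
) -> MorphotypeRecord:
    """Build and classify a record from a radial contour polygon."""
    try:
        R1, R2 = principal_radii(contour, angles)
        rec = MorphotypeRecord(
            R1=R1,
            R2=R2,
            c=circularity_index(R1, R2),
            D=contourness(contour, angles=angles) * 2.0 * np.pi * float(np.mean(contour))
            + 2.0 * np.pi * float(np.mean(contour)),
            Delta=contourness(contour, angles=angles),
            contrast=contrast,
        )
    except ValueError:
        rec = MorphotypeRecord(
            R1=np.nan, R2=np.nan, c=np.nan, D=np.nan, Delta=np.nan,
            contrast=contrast, valid=False,
        )
    classify_morphotype(rec, contrast_min=contrast_min)
    return rec
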