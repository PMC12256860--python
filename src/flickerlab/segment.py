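"""Contour extraction from ring-image stacks.

The imaging chain: Gaussian denoising + Otsu binarization for cell-disk
masks, subpixel radial contour extraction (ring-intensity extremum along
rays, cubic interpolation with parabolic vertex refinement), rigid drift
correction (barycenter re-centering and rotational registration against a
running reference profile), and assembly of the drift-corrected radii into
a :class:`~flickerlab.series.ContourSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian as sk_gaussian, threshold_otsu

from .imaging import ImageStack
from .series import ContourSeries

__all__ = [
    "RadialProfileStack",
    "denoise_binarize",
    "extract_contour",
    "correct_drift",
    "assemble_series",
    "segment_stack",
]


@dataclass
class RadialProfileStack:
    """Per-frame contour radii on a common angular grid.

    ``radii`` is T x N in pixels; ``center`` the per-frame ray origin
    (row, col); ``angles`` the N angular coordinates in [0, 2*pi).
    """

    radii: np.ndarray
    center: np.ndarray
    angles: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.radii = np.atleast_2d(np.asarray(self.radii, float))
        self.center = np.atleast_2d(np.asarray(self.center, float))
        self.angles = np.asarray(self.angles, float)
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if np.any(np.diff(self.angles) <= 0) or self.angles[0] < 0:
            raise ValueError("angles must be strictly increasing in [0, 2*pi)")

    @property
    def n_frames(self) -> int:
        return self.radii.shape[0]

    @property
    def n_angles(self) -> int:
        return self.radii.shape[1]


def denoise_binarize(frame: np.ndarray, sigma_px: float = 2.0) -> np.ndarray:
    """Gaussian-denoise then Otsu-binarize a frame into a cell-disk mask.

    The frame is blurred with the stated sigma and thresholded at the
    cutoff maximizing the between-class variance; the dark foreground
    (cell rim/body) is hole-filled to return the disk mask.
    """
    frame = np.asarray(frame, float)
    if np.ptp(frame) == 0:
        raise ValueError("degenerate threshold: constant frame")
    blurred = sk_gaussian(frame, sigma=sigma_px, preserve_range=True)
    if np.ptp(blurred) == 0:
        raise ValueError("degenerate threshold: constant frame after blur")
    thresh = threshold_otsu(blurred)
    dark = blurred < thresh
    return ndimage.binary_fill_holes(dark)


def _sample_rays(
    frame: np.ndarray,
    center: tuple[float, float],
    N: int,
    r_max: float,
    dr: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-interpolated intensity along N rays; returns (profiles, r_grid)."""
    theta = 2.0 * np.pi * np.arange(N) / N
    r = np.arange(1.0, r_max, dr)
    cy, cx = center
    rows = cy + np.outer(np.sin(theta), r)
    cols = cx + np.outer(np.cos(theta), r)
    profiles = ndimage.map_coordinates(
        np.asarray(frame, float), [rows, cols], order=3, mode="nearest"
    )
    return profiles, r


def extract_contour(
    frame: np.ndarray,
    center: tuple[float, float],
    N: int = 2048,
    r_max: float | None = None,
    dark_ring: bool = True,
    dr: float = 0.5,
    max_missing_frac: float = 0.01,
) -> np.ndarray:
    """Subpixel contour radii over N rays from ``center`` (px).

    For each ray the contour radius is the position of the ring-intensity
    extremum (minimum for a dark ring), refined by fitting a parabola
    through the extremum and its neighbors on the cubic-interpolated
    profile.  Rays whose extremum sits at the search boundary are treated
    as missing and linearly interpolated; more than ``max_missing_frac``
    missing rays rejects the frame.
    """
    frame = np.asarray(frame, float)
    H, W = frame.shape
    cy, cx = center
    if not (0 <= cy < H and 0 <= cx < W):
        raise ValueError("center outside frame")
    if r_max is None:
        r_max = min(cy, cx, H - 1 - cy, W - 1 - cx)
    profiles, r = _sample_rays(frame, (cy, cx), N, r_max, dr)
    if not dark_ring:
        profiles = -profiles
    idx = np.argmin(profiles, axis=1)
    missing = (idx == 0) | (idx == r.size - 1)
    idx_c = np.clip(idx, 1, r.size - 2)
    f0 = profiles[np.arange(N), idx_c - 1]
    f1 = profiles[np.arange(N), idx_c]
    f2 = profiles[np.arange(N), idx_c + 1]
    denom = f0 - 2.0 * f1 + f2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(denom != 0, 0.5 * (f0 - f2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    radii = r[idx_c] + shift * dr
    if missing.any():
        frac = missing.mean()
        if frac > max_missing_frac:
            raise ValueError(
                f"frame rejected: {100 * frac:.1f}% rays without a "
                "detectable ring extremum"
            )
        good = ~missing
        # periodic linear interpolation across missing rays
        theta = 2.0 * np.pi * np.arange(N) / N
        radii[missing] = np.interp(
            theta[missing],
            np.concatenate([theta[good], theta[good][:1] + 2.0 * np.pi]),
            np.concatenate([radii[good], radii[good][:1]]),
        )
    return radii


def _recenter_profile(
    radii: np.ndarray, angles: np.ndarray, center: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Shift the ray origin to the contour barycenter and re-grid radii.

    Returns the re-centered radii on the same angular grid and the new
    center.  One iteration removes first-order (cos/sin) center offset.
    """
    x = center[1] + radii * np.cos(angles)
    y = center[0] + radii * np.sin(angles)
    # area centroid (shoelace): unbiased by the angular sampling density,
    # unlike the vertex average
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * np.sum(cross)
    cx = np.sum((x + x1) * cross) / (6.0 * area)
    cy = np.sum((y + y1) * cross) / (6.0 * area)
    theta_new = np.mod(np.arctan2(y - cy, x - cx), 2.0 * np.pi)
    r_new = np.hypot(x - cx, y - cy)
    order = np.argsort(theta_new)
    theta_s = theta_new[order]
    r_s = r_new[order]
    radii_out = np.interp(
        angles,
        np.concatenate([theta_s, theta_s[:1] + 2.0 * np.pi]),
        np.concatenate([r_s, r_s[:1]]),
        period=None,
    )
    return radii_out, np.array([cy, cx])


def correct_drift(
    stack: RadialProfileStack,
    n_center_iter: int = 3,
    min_correlation: float = 0.2,
    rotate: bool = True,
) -> RadialProfileStack:
    """Remove rigid translation and rotation from a radius-profile stack.

    Translation: per-frame contour barycenter re-centering (iterated).
    Rotation: each frame's radius profile is registered against the running
    mean of the already-registered frames by maximizing the circular
    cross-correlation (integer multiples of the angular step).  Frames
    whose peak correlation coefficient falls below ``min_correlation`` are
    flagged in ``meta['flagged_frames']``.

    Rotational registration assumes rigid-body rotation; on freely
    fluctuating contours the phase diffusion of the dominant deformation
    mode is degenerate with rotation and would be spuriously removed, so
    ``rotate=False`` disables it.
    """
    if stack.n_frames < 2:
        raise ValueError("drift correction needs at least 2 frames")
    radii = stack.radii.copy()
    centers = stack.center.copy()
    if centers.shape[0] == 1:
        centers = np.repeat(centers, stack.n_frames, axis=0)
    for t in range(stack.n_frames):
        for _ in range(n_center_iter):
            new_r, new_c = _recenter_profile(radii[t], stack.angles, centers[t])
            shift = np.hypot(*(new_c - centers[t]))
            radii[t], centers[t] = new_r, new_c
            if shift < 0.01:
                break
    # rotational registration against the running mean profile
    flagged: list[int] = []
    shifts = np.zeros(stack.n_frames, dtype=int)
    reference = radii[0] - radii[0].mean()
    ref_count = 1
    for t in range(1, stack.n_frames if rotate else 1):
        prof = radii[t] - radii[t].mean()
        xc = np.fft.irfft(
            np.fft.rfft(reference) * np.conj(np.fft.rfft(prof)), n=prof.size
        )
        k = int(np.argmax(xc))
        denom = np.linalg.norm(reference) * np.linalg.norm(prof)
        corr = xc[k] / denom if denom > 0 else 0.0
        if corr < min_correlation:
            flagged.append(t)
            k = 0
        radii[t] = np.roll(radii[t], k)
        shifts[t] = k
        prof_reg = radii[t] - radii[t].mean()
        reference = (reference * ref_count + prof_reg) / (ref_count + 1)
        ref_count += 1
    meta = dict(stack.meta)
    meta.update(
        drift_corrected=True, rotation_shifts=shifts.tolist(), flagged_frames=flagged
    )
    return RadialProfileStack(radii, centers, stack.angles, meta)


def assemble_series(
    stack: RadialProfileStack,
    dt: float,
    pixel_size: float,
    expected_frames: int | None = None,
) -> ContourSeries:
    """Convert a drift-corrected radius stack into displacement series.

    R_bar is the global (time-and-angle) mean radius; the per-frame mean is
    deliberately retained so the breathing mode survives.  Displacements
    are converted to meters with ``pixel_size``.
    """
    if expected_frames is not None and stack.n_frames != expected_frames:
        raise ValueError(
            f"frame count {stack.n_frames} inconsistent with metadata "
            f"({expected_frames})"
        )
    R_bar_px = float(stack.radii.mean())
    dh = (stack.radii.T - R_bar_px) * pixel_size  # (N, T)
    return ContourSeries(
        dh=dh,
        R_bar=R_bar_px * pixel_size,
        dt=dt,
        meta={**stack.meta, "pixel_size": pixel_size, "R_bar_px": R_bar_px},
    )


def segment_stack(
    stack: ImageStack,
    N: int = 2048,
    dark_ring: bool = True,
    drift_correct: bool = True,
    rotation_correct: bool = False,
) -> ContourSeries:
    """Full imaging chain: stack -> radii -> drift correction -> series.

    The per-frame ray origin is the intensity barycenter of the ring
    (computed on the contrast-inverted frame for dark rings).  Rotational
    registration is off by default: deformation-mode phase diffusion is
    degenerate with rigid rotation for freely fluctuating contours (enable
    it for stacks of tumbling cells).
    """
    frames = stack.frames.astype(float)
    radii = np.empty((stack.n_frames, N))
    centers = np.empty((stack.n_frames, 2))
    for t, frame in enumerate(frames):
        weight = frame.max() - frame if dark_ring else frame - frame.min()
        total = weight.sum()
        yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
        cy = float((weight * yy).sum() / total)
        cx = float((weight * xx).sum() / total)
        centers[t] = (cy, cx)
        radii[t] = extract_contour(frame, (cy, cx), N=N, dark_ring=dark_ring)
    prof = RadialProfileStack(
        radii,
        centers,
        2.0 * np.pi * np.arange(N) / N,
        meta={"source": "segment_stack"},
    )
    if drift_correct and stack.n_frames >= 2:
        prof = correct_drift(prof, rotate=rotation_correct)
    return assemble_series(prof, stack.dt, stack.pixel_size)
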