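"""Synthetic ring-image rendering and image-stack I/O.

Renders equatorial contour series as grayscale frames mimicking
phase-contrast views of a cell rim: a dark ring of Gaussian radial
cross-section centered on the instantaneous contour R(theta, t), on a
bright background, optionally blurred and corrupted with additive Gaussian
noise.  Stacks round-trip through multi-page TIFF with a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .series import ContourSeries

__all__ = [
    "Optics",
    "ImageStack",
    "render_contour_frames",
    "render_radii_frame",
    "write_imagestack",
    "read_imagestack",
]


@dataclass(frozen=True)
class Optics:
    """Rendering/acquisition parameters of the synthetic microscope.

    ``pixel_size`` in m/px; ``ring_width`` the Gaussian sigma of the ring
    cross-section (px); ``blur_sigma`` extra image blur (px); ``noise_sd``
    additive Gaussian noise as a fraction of the ring contrast;
    ``dark_ring`` selects contrast polarity.
    """

    pixel_size: float = 20e-9
    frame_shape: tuple[int, int] = (512, 512)
    ring_width: float = 2.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    contrast: float = 0.5
    background: float = 0.75
    dark_ring: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.ring_width <= 0:
            raise ValueError("ring_width must be > 0")
        if not 0 < self.contrast <= self.background <= 1:
            raise ValueError("need 0 < contrast <= background <= 1")


@dataclass
class ImageStack:
    """T grayscale frames with acquisition metadata."""

    frames: np.ndarray  # (T, H, W), uint8/uint16 or float
    pixel_size: float  # m/px
    dt: float  # s
    optics: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def render_radii_frame(
    radii_px: np.ndarray,
    optics: Optics,
    center: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one frame from contour radii (px) over uniform angles.

    Returns a float image in [0, 1]; the intensity extremum along any ray
    from the center lies at the contour radius (up to interpolation).
    """
    radii_px = np.asarray(radii_px, float)
    H, W = optics.frame_shape
    cy, cx = center if center is not None else ((H - 1) / 2.0, (W - 1) / 2.0)
    if radii_px.min() < 10:
        raise ValueError("ring radius must be >= 10 px for a resolvable ring")
    margin = 3.0 * optics.ring_width + 2.0
    if (
        cy - radii_px.max() < margin
        or cx - radii_px.max() < margin
        or cy + radii_px.max() > H - 1 - margin
        or cx + radii_px.max() > W - 1 - margin
    ):
        raise ValueError("contour exits the frame (geometry error)")
    yy, xx = np.mgrid[0:H, 0:W]
    r = np.hypot(yy - cy, xx - cx)
    theta = np.mod(np.arctan2(yy - cy, xx - cx), 2.0 * np.pi)
    # periodic interpolation of R(theta)
    n = radii_px.size
    angles = 2.0 * np.pi * np.arange(n + 1) / n
    R_theta = np.interp(theta, angles, np.append(radii_px, radii_px[0]))
    profile = np.exp(-((r - R_theta) ** 2) / (2.0 * optics.ring_width**2))
    img = optics.background - optics.contrast * profile
    if not optics.dark_ring:
        img = (1.0 - optics.background) + optics.contrast * profile
    if optics.blur_sigma > 0:
        img = gaussian_filter(img, optics.blur_sigma)
    if optics.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        img = img + optics.noise_sd * optics.contrast * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


def render_contour_frames(
    s: ContourSeries,
    optics: Optics | None = None,
    seed: int = 0,
    dtype=np.uint16,
) -> ImageStack:
    """Render a contour series as a synthetic ring-image stack.

    Each frame shows the instantaneous contour R(theta, t) = R_bar + dh;
    16-bit by default.
    """
    optics = optics or Optics()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    radii_px = (s.R_bar + s.dh) / optics.pixel_size  # (N, T)
    H, W = optics.frame_shape
    frames = np.empty((s.n_frames, H, W), dtype=dtype)
    scale = np.iinfo(dtype).max if np.issubdtype(dtype, np.integer) else 1.0
    for t in range(s.n_frames):
        img = render_radii_frame(radii_px[:, t], optics, rng=rng)
        frames[t] = (img * scale).astype(dtype)
    return ImageStack(
        frames=frames,
        pixel_size=optics.pixel_size,
        dt=s.dt,
        optics=asdict(optics),
        meta={"seed": seed, "R_bar": s.R_bar, "source": "render_contour_frames"},
    )


def write_imagestack(path: str | Path, stack: ImageStack) -> Path:
    """Write a stack as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    sidecar = path.with_suffix(path.suffix + ".json")
    payload = {
        "pixel_size_m": stack.pixel_size,
        "dt_s": stack.dt,
        "n_frames": stack.n_frames,
        "optics": stack.optics,
        "meta": stack.meta,
    }
    sidecar.write_text(json.dumps(payload, indent=2, default=str))
    return path


def read_imagestack(path: str | Path) -> ImageStack:
    """Read a TIFF stack written by :func:`write_imagestack`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar JSON: {sidecar}")
    payload = json.loads(sidecar.read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != payload["n_frames"]:
        raise ValueError(
            f"frame-count mismatch: TIFF has {frames.shape[0]}, sidecar "
            f"declares {payload['n_frames']}"
        )
    return ImageStack(
        frames=frames,
        pixel_size=payload["pixel_size_m"],
        dt=payload["dt_s"],
        optics=payload.get("optics", {}),
        meta=payload.get("meta", {}),
    )
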