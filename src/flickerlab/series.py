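"""The central data container: contour displacement time series.

A :class:`ContourSeries` holds the N x T matrix of radial displacements
delta-h_i(l_i, t) of the equatorial membrane contour around its mean radius,
together with the emplacement arc-coordinates, frame interval and provenance
metadata.  Tabular (text) and binary (npz) round-trip I/O live here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ContourSeries",
    "read_contour_table",
    "write_contour_table",
    "read_contour_binary",
    "write_contour_binary",
]


@dataclass
class ContourSeries:
    """Radial displacement series of an equatorial contour.

    Attributes
    ----------
    dh : ndarray, shape (N, T)
        Displacements delta-h_i(l_i, t) = R_i(t) - R_bar in meters.
    R_bar : float
        Mean equatorial radius (m).
    dt : float
        Frame interval (s).
    meta : dict
        Provenance (seed, parameters, cell id, ...).
    """

    dh: np.ndarray
    R_bar: float
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dh = np.asarray(self.dh, dtype=float)
        if self.dh.ndim != 2:
            raise ValueError("dh must be an N x T matrix")
        if self.dh.shape[0] < 1 or self.dh.shape[1] < 1:
            raise ValueError("need N > 0 emplacements and T >= 1 frames")
        if not np.all(np.isfinite(self.dh)):
            raise ValueError("dh contains non-finite values")
        if self.R_bar <= 0:
            raise ValueError("R_bar must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def n_sites(self) -> int:
        return self.dh.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dh.shape[1]

    @property
    def L(self) -> float:
        """Emplacement lateral size L = 2*pi*R_bar/N (m)."""
        return 2.0 * np.pi * self.R_bar / self.n_sites

    @property
    def l(self) -> np.ndarray:
        """Emplacement arc-coordinates l_i = i*L (m)."""
        return self.L * np.arange(self.n_sites)

    @property
    def angles(self) -> np.ndarray:
        """Angular coordinates theta_i in [0, 2*pi) (rad)."""
        return 2.0 * np.pi * np.arange(self.n_sites) / self.n_sites

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt

    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_frames)

    def radii(self) -> np.ndarray:
        """Instantaneous radii R_i(t) = R_bar + dh (m)."""
        return self.R_bar + self.dh


_HEADER_FIELDS = ("R_bar_m", "dt_s", "N")


def write_contour_table(path: str | Path, series: ContourSeries) -> Path:
    """Write a series as delimited text: header lines then T rows x N cols."""
    path = Path(path)
    meta_line = json.dumps(series.meta, default=str)
    header = (
        f"R_bar_m={series.R_bar!r}\n"
        f"dt_s={series.dt!r}\n"
        f"N={series.n_sites}\n"
        f"meta={meta_line}"
    )
    np.savetxt(path, series.dh.T, header=header, fmt="%.9e")
    return path


def read_contour_table(path: str | Path) -> ContourSeries:
    """Read a series written by :func:`write_contour_table`."""
    path = Path(path)
    fields: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key:
                fields[key.strip()] = value.strip()
    for name in _HEADER_FIELDS:
        if name not in fields:
            raise ValueError(
                f"{path}: malformed header, missing required field '{name}'"
            )
    R_bar = float(fields["R_bar_m"])
    dt = float(fields["dt_s"])
    n_sites = int(fields["N"])
    meta = json.loads(fields.get("meta", "{}"))
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != n_sites:
        raise ValueError(
            f"{path}: header declares N={n_sites} but rows have "
            f"{data.shape[1]} columns"
        )
    return ContourSeries(dh=data.T, R_bar=R_bar, dt=dt, meta=meta)


def write_contour_binary(path: str | Path, series: ContourSeries) -> Path:
    """Single-file binary container (compressed npz) for large runs."""
    path = Path(path)
    np.savez_compressed(
        path,
        dh=series.dh,
        R_bar=series.R_bar,
        dt=series.dt,
        meta=json.dumps(series.meta, default=str),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_contour_binary(path: str | Path) -> ContourSeries:
    with np.load(path, allow_pickle=False) as data:
        return ContourSeries(
            dh=data["dh"],
            R_bar=float(data["R_bar"]),
            dt=float(data["dt"]),
            meta=json.loads(str(data["meta"])),
        )
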