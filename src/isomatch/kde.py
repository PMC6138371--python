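"""Kernel-density non-breeding ranges from geolocator position fixes.

Fixes are projected to a per-individual azimuthal-equidistant plane centered
on their centroid (so the metric bandwidth is honored), smoothed with a
quartic (biweight) kernel of compact support equal to the search radius —
the kernel used by the classic GIS kernel-density tool —

    K(r) = 3 / (pi h^2) * (1 - (r/h)^2)^2      for r < h,

and the 50%/75% volume contours are read off as the smallest sets of
highest-density working cells accumulating that much probability mass.
A Gaussian kernel is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assignment import BinaryMask, _mass_mask
from .grid import GridSpec

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GeoFix:
    """One geolocator position estimate."""

    id: str
    date: _date | None
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -180 <= self.lon <= 180:
            raise ValueError(f"lon {self.lon} out of range")
        if not -90 <= self.lat <= 90:
            raise ValueError(f"lat {self.lat} out of range")


def read_fixes(path) -> list[GeoFix]:
    """Read fixes from a CSV with columns id, date (ISO-8601), lon, lat."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        d = row.get("date")
        out.append(GeoFix(id=str(row["id"]),
                          date=None if pd.isna(d) else pd.Timestamp(d).date(),
                          lon=float(row["lon"]), lat=float(row["lat"])))
    return out


def nonbreeding_filter(fixes: Iterable[GeoFix], start_month: int = 10,
                       end_month: int = 3) -> list[GeoFix]:
    """Keep fixes in the stationary non-breeding window (October–March).

    Fixes without a date are kept (positions are taken as given).
    """
    kept = []
    for f in fixes:
        if f.date is None or f.date.month >= start_month or f.date.month < end_month:
            kept.append(f)
    return kept


# ---------------------------------------------------------------------------
# Azimuthal equidistant projection (spherical)


def aeqd_forward(lon: np.ndarray, lat: np.ndarray, lon0: float,
                 lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to x/y km on a plane centered at (lon0, lat0)."""
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(c), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def aeqd_inverse(x: np.ndarray, y: np.ndarray, lon0: float,
                 lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`aeqd_forward` (returns lon/lat in degrees)."""
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_KM
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(
            rho > 1e-12,
            np.arcsin(np.clip(np.cos(c) * math.sin(phi0)
                              + y * np.sin(c) * math.cos(phi0) / np.where(rho > 1e-12, rho, 1.0),
                              -1.0, 1.0)),
            phi0,
        )
        lam = np.where(
            rho > 1e-12,
            lam0 + np.arctan2(x * np.sin(c),
                              rho * math.cos(phi0) * np.cos(c) - y * math.sin(phi0) * np.sin(c)),
            lam0,
        )
    return np.degrees(lam), np.degrees(phi)


# ---------------------------------------------------------------------------


@dataclass
class TrackKDE:
    """A kernel-density surface on an equal-distance working grid.

    The working grid is square with cell size ``working_res`` km; ``density``
    integrates to 1 over the plane. ``contours`` maps a probability level to
    (boolean cell set, area in km^2); ``grid_cells`` holds the projection of
    each contour onto a geographic assignment grid, filled by
    :func:`kde_to_grid`.
    """

    id: str
    bandwidth: float
    working_res: float
    center: tuple[float, float]  # (lon0, lat0) of the projection
    x_edges: np.ndarray  # working-cell x centers, km (1D, ascending)
    y_edges: np.ndarray  # working-cell y centers, km (1D, ascending)
    density: np.ndarray  # (n_y, n_x)
    contours: dict[float, tuple[np.ndarray, float]] = field(default_factory=dict)
    grid_cells: dict[float, BinaryMask] = field(default_factory=dict)

    def cell_mass(self) -> np.ndarray:
        return self.density * self.working_res**2

    def centroid_lonlat(self) -> tuple[float, float]:
        """Density-weighted centroid, in lon/lat degrees."""
        mass = self.cell_mass()
        total = mass.sum()
        xx, yy = np.meshgrid(self.x_edges, self.y_edges)
        x = float((xx * mass).sum() / total)
        y = float((yy * mass).sum() / total)
        lon, lat = aeqd_inverse(np.array([x]), np.array([y]), *self.center)
        return float(lon[0]), float(lat[0])


def _quartic(r2: np.ndarray, h: float) -> np.ndarray:
    """Quartic (biweight) kernel density at squared distances r2."""
    u2 = r2 / (h * h)
    out = np.zeros_like(u2)
    inside = u2 < 1.0
    out[inside] = 3.0 / (math.pi * h * h) * (1.0 - u2[inside]) ** 2
    return out


def _gaussian(r2: np.ndarray, h: float) -> np.ndarray:
    """Bivariate Gaussian kernel with SD = h (no truncation)."""
    return np.exp(-0.5 * r2 / (h * h)) / (2 * math.pi * h * h)


def quartic_mass_radius(level: float, h: float) -> float:
    """Radius containing ``level`` of a single quartic kernel's mass.

    The mass within radius r is 1 - (1 - (r/h)^2)^3; closed-form inverse.
    """
    return h * math.sqrt(1.0 - (1.0 - level) ** (1.0 / 3.0))


def kde_surface(fixes: Sequence[GeoFix], bandwidth: float = 300.0,
                working_res: float = 10.0, kernel: str = "quartic") -> TrackKDE:
    """Kernel density of position fixes on an azimuthal-equidistant grid.

    ``bandwidth`` is the kernel search radius in km (support radius for the
    quartic kernel; SD for the Gaussian, whose grid is padded to 4 SD).
    """
    fixes = list(fixes)
    if not fixes:
        raise ValueError("need at least one fix")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    kfun = {"quartic": _quartic, "gaussian": _gaussian}.get(kernel)
    if kfun is None:
        raise ValueError(f"unknown kernel {kernel!r}")
    lon = np.array([f.lon for f in fixes])
    lat = np.array([f.lat for f in fixes])
    lon0, lat0 = float(lon.mean()), float(lat.mean())
    fx, fy = aeqd_forward(lon, lat, lon0, lat0)
    pad = bandwidth * (1.0 if kernel == "quartic" else 4.0) + working_res
    x_lo, x_hi = fx.min() - pad, fx.max() + pad
    y_lo, y_hi = fy.min() - pad, fy.max() + pad
    nx = int(math.ceil((x_hi - x_lo) / working_res))
    ny = int(math.ceil((y_hi - y_lo) / working_res))
    xc = x_lo + (np.arange(nx) + 0.5) * working_res
    yc = y_lo + (np.arange(ny) + 0.5) * working_res
    xx, yy = np.meshgrid(xc, yc)
    density = np.zeros((ny, nx))
    for px, py in zip(fx, fy):
        r2 = (xx - px) ** 2 + (yy - py) ** 2
        density += kfun(r2, bandwidth)
    density /= len(fixes)
    return TrackKDE(id=fixes[0].id, bandwidth=bandwidth, working_res=working_res,
                    center=(lon0, lat0), x_edges=xc, y_edges=yc, density=density)


def volume_contour(kde: TrackKDE, level: float) -> tuple[np.ndarray, float]:
    """Smallest set of working cells holding ``level`` of the density mass.

    Returns (boolean cell set, area in km^2); also stored on the TrackKDE.
    Cells are accumulated by descending density with the same tie rule as
    the assignment odds masks.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    mass = kde.cell_mass()
    total = mass.sum()
    sel_flat = _mass_mask((mass / total).ravel(), level)
    cells = sel_flat.reshape(mass.shape)
    area = float(cells.sum()) * kde.working_res**2
    kde.contours[level] = (cells, area)
    return cells, area


def kde_to_grid(kde: TrackKDE, grid: GridSpec, level: float,
                mode: str = "center", min_overlap: float = 0.5,
                subsamples: int = 5) -> BinaryMask:
    """Project a volume contour onto a geographic assignment grid.

    ``mode="center"`` (default) marks a geographic cell when its center
    falls in a contour cell; ``mode="overlap"`` marks it when at least
    ``min_overlap`` of a ``subsamples x subsamples`` lattice of interior
    points does.
    """
    if level not in kde.contours:
        volume_contour(kde, level)
    cells_w, _ = kde.contours[level]
    if mode == "center":
        offsets = [0.5]
    elif mode == "overlap":
        offsets = [(i + 0.5) / subsamples for i in range(subsamples)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    lonc = grid.lon_centers()
    latc = grid.lat_centers()
    out = np.zeros(grid.shape, dtype=bool)
    x0 = kde.x_edges[0] - kde.working_res / 2
    y0 = kde.y_edges[0] - kde.working_res / 2
    ny, nx = cells_w.shape

    hits = np.zeros(grid.shape, dtype=float)
    for oy in offsets:
        for ox in offsets:
            lon_pts = grid.lon_min + (np.arange(grid.n_cols) + ox) * grid.resolution
            lat_pts = grid.lat_max - (np.arange(grid.n_rows) + oy) * grid.resolution
            gl, gp = np.meshgrid(lon_pts, lat_pts)
            px, py = aeqd_forward(gl, gp, *kde.center)
            ix = np.floor((px - x0) / kde.working_res).astype(int)
            iy = np.floor((py - y0) / kde.working_res).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            inside = np.zeros(grid.shape, dtype=bool)
            inside[ok] = cells_w[iy[ok], ix[ok]]
            hits += inside
    frac = hits / (len(offsets) ** 2)
    out = frac >= (min_overlap if mode == "overlap" else 0.999)
    if not out.any():
        raise ValueError("contour is disjoint from the target grid")
    return BinaryMask(grid=grid, id=kde.id, q=level, cells=out)
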