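"""Isoscape rasters and their transformation to feather-equivalent surfaces.

An *isoscape* is a gridded map of predicted stable-isotope values (per mil)
across a landscape, e.g. amount-weighted growing-season delta-2H in
precipitation, or plant delta-13C / delta-15N. Assignment operates on
*feather* isoscapes obtained from these sources by:

* a linear calibration (transfer function) for hydrogen,
  mean_f = slope * mean_p + intercept, with a regression residual SD added
  in quadrature to any per-cell isoscape SD; and
* a constant diet-to-feather discrimination offset for carbon (+2 permil)
  and nitrogen (+5 permil).

Rasters are read and written as single-band ESRI ASCII grids (.asc) with an
optional JSON sidecar carrying the isotope label, reference scale and a
constant or per-cell SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grid import GridSpec

ISOTOPES = ("2H", "13C", "15N")
DEFAULT_SCALES = {"2H": "V-SMOW", "13C": "V-PDB", "15N": "Air"}


@dataclass
class IsoscapeRaster:
    """One isotope's gridded mean (and optional SD) surface, in per mil."""

    grid: GridSpec
    isotope: str
    mean: np.ndarray
    sd: np.ndarray | None = None
    scale: str = ""
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.isotope not in ISOTOPES:
            raise ValueError(f"unknown isotope {self.isotope!r}; expected one of {ISOTOPES}")
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.shape != self.grid.shape:
            raise ValueError("mean array shape does not match grid")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.mean)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.grid.shape:
                raise ValueError("valid_mask shape does not match grid")
        if not np.all(np.isfinite(self.mean[self.valid_mask])):
            raise ValueError("mean must be finite on valid cells")
        if self.sd is not None:
            self.sd = np.broadcast_to(np.asarray(self.sd, dtype=float), self.grid.shape).copy()
            if np.any(self.sd[self.valid_mask] < 0):
                raise ValueError("sd must be non-negative")
        if not self.scale:
            self.scale = DEFAULT_SCALES[self.isotope]

    def sd_or_zero(self) -> np.ndarray:
        """Per-cell SD, treating an absent SD layer as zero."""
        if self.sd is None:
            return np.zeros(self.grid.shape)
        return np.where(np.isfinite(self.sd), self.sd, 0.0)

    def masked(self, mask: np.ndarray) -> "IsoscapeRaster":
        """Restrict validity to ``valid_mask & mask`` (cellwise)."""
        return replace(self, valid_mask=self.valid_mask & np.asarray(mask, dtype=bool))


@dataclass(frozen=True)
class CalibrationModel:
    """Source-to-feather transfer parameters (all in per mil where dimensional).

    ``h_slope``/``h_intercept`` rescale a precipitation delta-2H isoscape to
    the expected feather values; ``h_residual_sd`` is the regression residual
    SD. Carbon and nitrogen use additive discrimination offsets (+2 and +5 by
    convention for plant-to-feather in insectivorous birds) with their own
    residual SDs.
    """

    h_slope: float = 1.0
    h_intercept: float = 0.0
    h_residual_sd: float = 0.0
    c13_offset: float = 2.0
    n15_offset: float = 5.0
    c13_residual_sd: float = 0.0
    n15_residual_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("h_residual_sd", "c13_residual_sd", "n15_residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("h_slope", "h_intercept", "c13_offset", "n15_offset"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_file(cls, path: str | Path) -> "CalibrationModel":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class IsoscapeStack:
    """Several isoscapes on one shared grid, with a joint validity mask."""

    layers: Sequence[IsoscapeRaster]
    joint_valid_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        g = self.layers[0].grid
        labels = [lyr.isotope for lyr in self.layers]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate isotope labels in stack")
        for lyr in self.layers[1:]:
            if not lyr.grid.same_geometry(g):
                raise ValueError("all layers must share one grid")
        mask = np.ones(g.shape, dtype=bool)
        for lyr in self.layers:
            mask &= lyr.valid_mask
        self.joint_valid_mask = mask

    @property
    def grid(self) -> GridSpec:
        return self.layers[0].grid

    @property
    def isotopes(self) -> tuple[str, ...]:
        return tuple(lyr.isotope for lyr in self.layers)

    def layer(self, isotope: str) -> IsoscapeRaster:
        for lyr in self.layers:
            if lyr.isotope == isotope:
                return lyr
        raise KeyError(f"no layer for isotope {isotope!r}")

    def subset(self, isotopes: Iterable[str]) -> "IsoscapeStack":
        return IsoscapeStack([self.layer(i) for i in isotopes])


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def _read_ascii_grid(path: Path) -> tuple[GridSpec, np.ndarray, float | None]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII-grid header key {key!r}")
    data = np.loadtxt(lines[n_header:], dtype=float)
    data = np.atleast_2d(data)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({n_rows}, {n_cols})")
    res = header["cellsize"]
    if "xllcorner" in header:
        lon_min = header["xllcorner"]
    else:
        lon_min = header["xllcenter"] - res / 2
    if "yllcorner" in header:
        lat_min = header["yllcorner"]
    else:
        lat_min = header["yllcenter"] - res / 2
    grid = GridSpec(lon_min=lon_min, lat_max=lat_min + n_rows * res,
                    n_rows=n_rows, n_cols=n_cols, resolution=res)
    nodata = header.get("nodata_value")
    return grid, data, nodata


def load_isoscape(path: str | Path, isotope: str, scale: str = "",
                  sd: float | str | Path | None = None) -> IsoscapeRaster:
    """Read a single-band georeferenced ASCII-grid raster.

    A JSON sidecar ``<path>.json`` may carry ``isotope``, ``scale``, ``crs``
    and ``sd`` (a constant in per mil, or the path of an SD raster); explicit
    arguments win over sidecar values. Cells equal to the grid's nodata value
    become invalid. Only geographic (lon/lat) rasters are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    crs = str(meta.get("crs", "EPSG:4326"))
    if crs.upper() not in {"EPSG:4326", "WGS84", "OGC:CRS84"}:
        raise ValueError(
            f"{path}: CRS {crs!r} is not geographic lon/lat; reproject before loading"
        )
    grid, data, nodata = _read_ascii_grid(path)
    mask = np.isfinite(data)
    if nodata is not None:
        mask &= data != nodata
    mean = np.where(mask, data, np.nan)
    if sd is None:
        sd = meta.get("sd")
    sd_arr: np.ndarray | None = None
    if sd is not None:
        if isinstance(sd, (int, float)):
            sd_arr = np.full(grid.shape, float(sd))
        else:
            sd_grid, sd_data, sd_nodata = _read_ascii_grid(Path(sd))
            if not sd_grid.same_geometry(grid):
                raise ValueError("sd raster grid does not match mean raster grid")
            if sd_nodata is not None:
                sd_data = np.where(sd_data == sd_nodata, np.nan, sd_data)
            sd_arr = sd_data
    return IsoscapeRaster(grid=grid, isotope=isotope or meta.get("isotope", ""),
                          mean=mean, sd=sd_arr,
                          scale=scale or meta.get("scale", ""), valid_mask=mask)


def write_ascii_grid(grid: GridSpec, data: np.ndarray, path: str | Path,
                     nodata: float = -9999.0, fmt: str = "%.6f") -> Path:
    """Write any per-cell array as an ESRI ASCII grid."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.lon_min!r}\n")
        fh.write(f"yllcorner {grid.lat_min!r}\n")
        fh.write(f"cellsize {grid.resolution!r}\n")
        fh.write(f"nodata_value {nodata!r}\n")
        np.savetxt(fh, np.asarray(data, dtype=float), fmt=fmt)
    return path


def save_isoscape(raster: IsoscapeRaster, path: str | Path,
                  nodata: float = -9999.0, fmt: str = "%.6f") -> Path:
    """Write an IsoscapeRaster as an ESRI ASCII grid plus JSON sidecar."""
    path = Path(path)
    data = np.where(raster.valid_mask, raster.mean, nodata)
    write_ascii_grid(raster.grid, data, path, nodata=nodata, fmt=fmt)
    meta: dict = {"isotope": raster.isotope, "scale": raster.scale, "crs": "EPSG:4326"}
    if raster.sd is not None:
        sds = raster.sd[raster.valid_mask]
        if sds.size and np.allclose(sds, sds.flat[0]):
            meta["sd"] = float(sds.flat[0])
        else:
            sd_path = path.with_name(path.stem + "_sd" + path.suffix)
            save_isoscape(replace(raster, mean=raster.sd, sd=None), sd_path,
                          nodata=nodata, fmt=fmt)
            meta["sd"] = str(sd_path)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


# ---------------------------------------------------------------------------
# Source -> feather transformations


def calibrate_hydrogen(precip: IsoscapeRaster, cal: CalibrationModel) -> IsoscapeRaster:
    """Rescale a precipitation delta-2H isoscape to feather-equivalent values.

    mean_f = h_slope * mean_p + h_intercept per cell; the calibration residual
    SD combines in quadrature with any per-cell isoscape SD. The validity mask
    is unchanged.
    """
    if precip.isotope != "2H":
        raise ValueError(f"calibrate_hydrogen expects a 2H isoscape, got {precip.isotope!r}")
    mean_f = cal.h_slope * precip.mean + cal.h_intercept
    sd_f = np.sqrt(precip.sd_or_zero() ** 2 + cal.h_residual_sd**2)
    return IsoscapeRaster(grid=precip.grid, isotope="2H", mean=mean_f, sd=sd_f,
                          scale=precip.scale, valid_mask=precip.valid_mask.copy())


def apply_discrimination(plant: IsoscapeRaster, offset: float,
                         residual_sd: float = 0.0) -> IsoscapeRaster:
    """Shift a plant isoscape by a diet-to-feather discrimination offset."""
    if plant.isotope not in ("13C", "15N"):
        raise ValueError(f"discrimination applies to 13C/15N, got {plant.isotope!r}")
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    if residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")
    mean_f = plant.mean + offset
    sd_f = np.sqrt(plant.sd_or_zero() ** 2 + residual_sd**2)
    return IsoscapeRaster(grid=plant.grid, isotope=plant.isotope, mean=mean_f, sd=sd_f,
                          scale=plant.scale, valid_mask=plant.valid_mask.copy())


def feather_stack(precip_2h: IsoscapeRaster | None, plant_13c: IsoscapeRaster,
                  plant_15n: IsoscapeRaster, cal: CalibrationModel) -> IsoscapeStack:
    """Build the feather-equivalent stack used for assignment."""
    layers = []
    if precip_2h is not None:
        layers.append(calibrate_hydrogen(precip_2h, cal))
    layers.append(apply_discrimination(plant_13c, cal.c13_offset, cal.c13_residual_sd))
    layers.append(apply_discrimination(plant_15n, cal.n15_offset, cal.n15_residual_sd))
    return IsoscapeStack(layers)


def regrid(r: IsoscapeRaster, target: GridSpec, method: str = "bilinear") -> IsoscapeRaster:
    """Resample a raster onto a target grid by cell-center sampling.

    ``bilinear`` interpolates between the four surrounding source cell
    centers and never extrapolates beyond the source center hull (cells
    outside it, or supported by any invalid source cell, become invalid);
    ``nearest`` copies the nearest source cell.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown regrid method {method!r}")
    if (target.lon_min >= r.grid.lon_max or target.lon_max <= r.grid.lon_min
            or target.lat_min >= r.grid.lat_max or target.lat_max <= r.grid.lat_min):
        raise ValueError("target grid extent is disjoint from the source raster")
    if target.same_geometry(r.grid):
        return replace(r, grid=target, mean=r.mean.copy(),
                       sd=None if r.sd is None else r.sd.copy(),
                       valid_mask=r.valid_mask.copy())

    # interpolate on (lat asc, lon asc) axes of source cell centers
    src_lat = r.grid.lat_centers()[::-1]
    src_lon = r.grid.lon_centers()
    scipy_method = "linear" if method == "bilinear" else "nearest"

    def _interp(values: np.ndarray) -> np.ndarray:
        itp = RegularGridInterpolator((src_lat, src_lon), values[::-1, :],
                                      method=scipy_method, bounds_error=False,
                                      fill_value=np.nan)
        tlat = target.lat_centers()
        tlon = target.lon_centers()
        pts_lat, pts_lon = np.meshgrid(tlat, tlon, indexing="ij")
        return itp(np.column_stack([pts_lat.ravel(), pts_lon.ravel()])).reshape(target.shape)

    mean_src = np.where(r.valid_mask, r.mean, np.nan)
    mean_t = _interp(mean_src)
    mask_t = np.isfinite(mean_t)
    sd_t = None
    if r.sd is not None:
        sd_t = _interp(np.where(r.valid_mask, r.sd, np.nan))
    return IsoscapeRaster(grid=target, isotope=r.isotope,
                          mean=np.where(mask_t, mean_t, np.nan), sd=sd_t,
                          scale=r.scale, valid_mask=mask_t)
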