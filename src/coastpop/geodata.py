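"""Core raster data model, GeoTIFF I/O, resampling, terrain and zonal operators.

All rasters in a run share one :class:`GridSpec`. The grid convention is the
usual north-up one: row 0 is the northernmost row and the centre of cell
``(r, c)`` sits at ``(origin_x + (c + 0.5) * cell_size,
origin_y - (r + 0.5) * cell_size)`` in planar map units (metres).
Reprojection is out of scope — the CRS is carried as an opaque tag and only
checked for equality, mirroring a workflow where everything has already been
brought into one equal-area projection.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "GridSpec",
    "Raster",
    "AdminLayer",
    "read_raster",
    "write_raster",
    "resample",
    "slope_from_dem",
    "zonal_aggregate",
    "distance_to_coast",
]

# GeoTIFF tag codes used for round-tripping grid geometry.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up regular grid in planar metric coordinates."""

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 100.0
    crs_tag: str = "local-metric"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) index of map coordinates (cell centres at integers)."""
        col = (np.asarray(x, dtype=float) - self.origin_x) / self.cell_size - 0.5
        row = (self.origin_y - np.asarray(y, dtype=float)) / self.cell_size - 0.5
        return row, col


@dataclass(eq=False)
class Raster:
    """A single-band raster: a 2-D value array plus its grid geometry.

    ``nodata`` cells are never compared arithmetically — use :meth:`mask`.
    NaN is the default nodata sentinel for floating-point rasters.
    """

    spec: GridSpec
    values: np.ndarray
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            if np.issubdtype(self.values.dtype, np.floating):
                return ~np.isnan(self.values)
            return np.ones(self.values.shape, dtype=bool)
        return self.values != self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask()]

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy(), self.nodata)

    def filled(self, fill: float = 0.0) -> np.ndarray:
        out = self.values.astype(float, copy=True)
        out[~self.mask()] = fill
        return out


def _check_aligned(*rasters: Raster) -> None:
    ref = rasters[0].spec
    for r in rasters[1:]:
        if r.spec != ref:
            raise ValueError(f"rasters are not aligned: {r.spec} != {ref}")


def write_raster(raster: Raster, path: str | os.PathLike) -> None:
    """Write a single-band GeoTIFF with grid geometry and nodata tags."""
    spec = raster.spec
    values = raster.values
    if values.dtype.kind in "ui":
        data = values
    else:
        data = values.astype(np.float64, copy=False)
    # %.17g round-trips IEEE doubles exactly through the ASCII GDAL_NODATA tag.
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "%.17g" % raster.nodata),
    ]
    description = json.dumps({"crs_tag": spec.crs_tag})
    tifffile.imwrite(
        os.fspath(path),
        data,
        extratags=extratags,
        description=description,
        photometric="minisblack",
    )


def read_raster(path: str | os.PathLike) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or similar)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"expected a single-band GeoTIFF, got {len(tif.pages)} pages")
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise ValueError("expected a single-band (2-D) GeoTIFF")
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value if _TAG_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_TAG_TIEPOINT].value if _TAG_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0.0)
        nodata = float(tags[_TAG_GDAL_NODATA].value) if _TAG_GDAL_NODATA in tags else float("nan")
        crs_tag = "local-metric"
        desc = page.description
        if desc:
            try:
                crs_tag = json.loads(desc).get("crs_tag", crs_tag)
            except (ValueError, AttributeError):
                pass
    spec = GridSpec(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        cell_size=float(scale[0]),
        crs_tag=crs_tag,
    )
    return Raster(spec, values, nodata)


def resample(src: Raster, target: GridSpec, method: str = "nearest") -> Raster:
    """Resample ``src`` onto ``target`` by nearest-neighbour or bilinear interpolation.

    Nearest picks the value of the nearest source cell centre (ties go to the
    upper/left cell, i.e. the lower index). Bilinear interpolates the four
    surrounding centres and propagates nodata; beyond the outermost centres the
    neighbourhood is clamped (flat extrapolation), matching common GIS practice.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if src.spec.crs_tag != target.crs_tag:
        raise ValueError(
            f"CRS mismatch: {src.spec.crs_tag!r} != {target.crs_tag!r}"
        )
    if src.spec == target:
        return src.copy()

    x, y = target.cell_centers()
    row_f, col_f = src.spec.xy_to_rowcol(x, y)

    # Reject a target that lies entirely outside the source extent.
    n_r, n_c = src.spec.shape
    inside = (row_f > -0.5) & (row_f < n_r - 0.5) & (col_f > -0.5) & (col_f < n_c - 0.5)
    if not inside.any():
        raise ValueError("target grid does not overlap the source raster")

    valid = src.mask()
    vals = src.values.astype(float, copy=False)

    if method == "nearest":
        # ceil(f - 0.5) rounds halves down, matching a first-match argmin over
        # source centres in row-major order.
        ri = np.clip(np.ceil(row_f - 0.5).astype(int), 0, n_r - 1)
        ci = np.clip(np.ceil(col_f - 0.5).astype(int), 0, n_c - 1)
        out = vals[ri, ci].astype(float)
        out[~valid[ri, ci]] = np.nan
    else:
        rf = np.clip(row_f, 0.0, n_r - 1.0)
        cf = np.clip(col_f, 0.0, n_c - 1.0)
        r0 = np.floor(rf).astype(int)
        c0 = np.floor(cf).astype(int)
        r1 = np.minimum(r0 + 1, n_r - 1)
        c1 = np.minimum(c0 + 1, n_c - 1)
        wr = rf - r0
        wc = cf - c0
        corners = [
            (r0, c0, (1 - wr) * (1 - wc)),
            (r0, c1, (1 - wr) * wc),
            (r1, c0, wr * (1 - wc)),
            (r1, c1, wr * wc),
        ]
        out = np.zeros(target.shape, dtype=float)
        bad = np.zeros(target.shape, dtype=bool)
        for ri, ci, w in corners:
            out += w * np.where(valid[ri, ci], vals[ri, ci], 0.0)
            bad |= (w > 0) & ~valid[ri, ci]
        out[bad] = np.nan
    return Raster(target, out, float("nan"))


def slope_from_dem(dem: Raster) -> Raster:
    """Terrain slope in degrees from a metric DEM (Horn's 3x3 method).

    Edge cells use edge-replicated neighbourhoods; a cell whose 3x3
    neighbourhood contains nodata becomes nodata.
    """
    s = dem.spec.cell_size
    valid = dem.mask()
    z = dem.values.astype(float, copy=True)
    z[~valid] = np.nan
    zp = np.pad(z, 1, mode="edge")
    vp = np.pad(valid, 1, mode="edge")

    def sh(dr, dc):
        return zp[1 + dr : 1 + dr + z.shape[0], 1 + dc : 1 + dc + z.shape[1]]

    gx = (
        (sh(-1, 1) + 2 * sh(0, 1) + sh(1, 1))
        - (sh(-1, -1) + 2 * sh(0, -1) + sh(1, -1))
    ) / (8 * s)
    gy = (
        (sh(1, -1) + 2 * sh(1, 0) + sh(1, 1))
        - (sh(-1, -1) + 2 * sh(-1, 0) + sh(-1, 1))
    ) / (8 * s)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    vsh = lambda dr, dc: vp[1 + dr : 1 + dr + z.shape[0], 1 + dc : 1 + dc + z.shape[1]]
    all_valid = np.ones_like(valid)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            all_valid &= vsh(dr, dc)
    slope[~all_valid] = np.nan
    return Raster(dem.spec, slope, float("nan"))


def zonal_aggregate(value: Raster, labels: Raster, stat: str = "mean") -> pd.Series:
    """Per-label statistic (mean/sum/count) of ``value`` over non-nodata cells.

    Returns a Series indexed by unit id covering every nonzero label present
    in ``labels``; labels with zero valid cells get NaN (flagged missing),
    except ``count`` which reports 0.
    """
    if stat not in ("mean", "sum", "count"):
        raise ValueError(f"unknown statistic {stat!r}")
    _check_aligned(value, labels)
    lab = labels.values.astype(np.int64, copy=False)
    present = np.unique(lab)
    present = present[present != 0]
    valid = value.mask() & (lab != 0)
    v = value.values.astype(float, copy=False)

    n = int(lab.max()) + 1 if lab.size else 1
    counts = np.bincount(lab[valid], minlength=n).astype(float)
    sums = np.bincount(lab[valid], weights=v[valid], minlength=n)

    if stat == "count":
        out = counts[present]
    elif stat == "sum":
        out = np.where(counts[present] > 0, sums[present], np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(counts[present] > 0, sums[present] / counts[present], np.nan)
    return pd.Series(out, index=pd.Index(present, name="unit_id"), name=stat)


def distance_to_coast(land_mask: Raster) -> Raster:
    """Euclidean distance (metres, centre-to-centre) from each land cell to the
    nearest sea cell; sea cells are 0."""
    land = land_mask.values.astype(bool)
    if land.all():
        raise ValueError("land mask contains no sea cells — no coastline to measure from")
    dist = ndimage.distance_transform_edt(land, sampling=land_mask.spec.cell_size)
    return Raster(land_mask.spec, dist.astype(float), float("nan"))


_LEVELS = ("province", "county", "township")


@dataclass(eq=False)
class AdminLayer:
    """Nested administrative units rasterised onto the common grid.

    ``labels`` holds the finest (township) unit id per cell, 0 outside the
    mapped area; coarser label rasters are derived through the parent links in
    ``units`` (columns: unit_id, level, parent_id, census_pop, area_km2).
    """

    labels: Raster
    units: pd.DataFrame
    _level_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        present = np.unique(self.labels.values)
        present = present[present != 0]
        known = set(self.units.loc[self.units["level"] == "township", "unit_id"])
        missing = [int(u) for u in present if int(u) not in known]
        if missing:
            raise ValueError(f"labels present but not in unit table: {missing[:5]}")

    def units_at(self, level: str) -> pd.DataFrame:
        if level not in _LEVELS:
            raise ValueError(f"unknown admin level {level!r}")
        return self.units[self.units["level"] == level].reset_index(drop=True)

    def parent_map(self, level: str) -> dict[int, int]:
        """unit_id -> parent_id for all units of ``level``."""
        sub = self.units_at(level)
        return dict(zip(sub["unit_id"].astype(int), sub["parent_id"].astype(int)))

    def label_raster(self, level: str = "township") -> Raster:
        """Label raster at the requested level (derived via parent links)."""
        if level not in _LEVELS:
            raise ValueError(f"unknown admin level {level!r}")
        if level in self._level_cache:
            return self._level_cache[level]
        lab = self.labels.values.astype(np.int64)
        if level != "township":
            remap = self.parent_map("township")
            if level == "province":
                county_parent = self.parent_map("county")
                remap = {k: county_parent[v] for k, v in remap.items()}
            lut = np.zeros(int(lab.max()) + 1, dtype=np.int64)
            for k, v in remap.items():
                lut[k] = v
            lab = lut[lab]
        out = Raster(self.labels.spec, lab, 0)
        self._level_cache[level] = out
        return out

    def with_census(self, census: pd.Series, level: str) -> "AdminLayer":
        """Return a copy with census_pop set for the given level."""
        units = self.units.copy()
        sel = units["level"] == level
        units.loc[sel, "census_pop"] = (
            units.loc[sel, "unit_id"].map(census).astype(float).values
        )
        return AdminLayer(self.labels, units)

    def census_at(self, level: str) -> pd.Series:
        sub = self.units_at(level)
        return pd.Series(
            sub["census_pop"].values, index=pd.Index(sub["unit_id"].astype(int), name="unit_id")
        )
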