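"""Raster data model, GeoTIFF I/O, alignment, masking and block aggregation.

Every spatial layer in the pipeline — landcover, reflectance bands, NDVI,
binary masks, access fractions, population — travels as a :class:`Grid`:
a rectangular array of cell values on an axis-aligned grid in a projected
(metre-unit) coordinate system.  Grids never get reprojected here; inputs
must arrive on a common projected grid, and mismatches are an error.

GeoTIFF round-tripping uses tifffile and the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA, GeoKeyDirectory), so files
written here open in GDAL/QGIS with correct georeferencing and nodata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import tifffile

__all__ = [
    "Grid",
    "CityMask",
    "read_raster",
    "write_raster",
    "block_aggregate",
    "masked_cells",
    "GridAlignmentError",
    "RasterIOError",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113
_IMAGE_DESCRIPTION = 270

# GTModelTypeGeoKey values
_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2


class GridAlignmentError(ValueError):
    """Two grids that must share a lattice do not."""


class RasterIOError(OSError):
    """A raster file could not be read or written."""


def _invalid_mask(values: np.ndarray, nodata) -> np.ndarray:
    """Boolean array of cells equal to the nodata sentinel (NaN-aware)."""
    if nodata is None:
        return np.zeros(values.shape, dtype=bool)
    if isinstance(nodata, float) and np.isnan(nodata):
        if np.issubdtype(values.dtype, np.floating):
            return np.isnan(values)
        return np.zeros(values.shape, dtype=bool)
    return values == nodata


@dataclass
class Grid:
    """A single-band raster on an axis-aligned projected grid.

    Parameters
    ----------
    values
        2-D array, row 0 at the top (north).  Float or integer dtype;
        categorical layers use integer codes.
    cell_size
        Edge length of one square cell in metres (10 for native Sentinel-2
        resolution, 100 for the population-scale grid).
    origin
        Projected (x, y) of the *upper-left corner* of cell [0, 0].
    nodata
        Sentinel value marking invalid cells, or None if every cell is
        valid.  NaN is a legal sentinel for float grids.
    crs_tag
        Opaque identifier of the projected CRS (e.g. ``"EPSG:32618"``).
        Carried through unchanged and compared for equality; never
        interpreted or reprojected.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | int | None = None
    crs_tag: str = "EPSG:32618"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("Grid values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if np.issubdtype(self.values.dtype, np.floating):
            bad = ~np.isfinite(self.values) & ~self.invalid_mask()
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} cell(s) are non-finite but not nodata"
                )

    # ---- basic queries -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def invalid_mask(self) -> np.ndarray:
        return _invalid_mask(self.values, self.nodata)

    def valid_mask(self) -> np.ndarray:
        return ~self.invalid_mask()

    def valid_values(self) -> np.ndarray:
        """Values of all valid cells, row-major."""
        return self.values[self.valid_mask()]

    def aligned_with(self, other: "Grid", atol: float = 1e-6) -> bool:
        """Same cell size, same shape, origins on the same cell lattice."""
        if self.shape != other.shape:
            return False
        if abs(self.cell_size - other.cell_size) > atol:
            return False
        dx = (self.origin[0] - other.origin[0]) % self.cell_size
        dy = (self.origin[1] - other.origin[1]) % self.cell_size
        near = lambda d: min(d, self.cell_size - d) <= atol
        return near(dx) and near(dy)

    def require_aligned(self, other: "Grid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise GridAlignmentError(
                f"{what} are not aligned: "
                f"shape {self.shape} vs {other.shape}, "
                f"cell_size {self.cell_size} vs {other.cell_size}, "
                f"origin {self.origin} vs {other.origin}"
            )
        if self.crs_tag != other.crs_tag:
            raise GridAlignmentError(
                f"{what} carry different CRS tags "
                f"({self.crs_tag!r} vs {other.crs_tag!r}); reproject upstream"
            )

    def with_values(self, values: np.ndarray, nodata=None) -> "Grid":
        """New grid on the same lattice with different cell values."""
        return Grid(
            values=values,
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=nodata,
            crs_tag=self.crs_tag,
        )

    def astype_float(self) -> np.ndarray:
        """Values as float64 with nodata replaced by NaN (a working copy)."""
        out = self.values.astype(np.float64, copy=True)
        out[self.invalid_mask()] = np.nan
        return out


@dataclass
class CityMask:
    """Boolean grid marking cells inside the urban boundary."""

    grid: Grid

    def __post_init__(self) -> None:
        vals = self.grid.values
        if not np.isin(vals[~self.grid.invalid_mask()], (0, 1)).all():
            raise ValueError("CityMask cells must be 0/1 (or nodata)")
        if not self.bool_array().any():
            raise ValueError("CityMask has no interior cells")

    def bool_array(self) -> np.ndarray:
        inside = self.grid.values == 1
        inside &= self.grid.valid_mask()
        return inside

    @property
    def n_inside(self) -> int:
        return int(self.bool_array().sum())


# ---- GeoTIFF I/O -------------------------------------------------------


def write_raster(grid: Grid, path: str | Path) -> None:
    """Write a grid as a single-band GeoTIFF.

    Georeferencing goes into ModelPixelScale/ModelTiepoint, the nodata
    sentinel into the GDAL_NODATA ASCII tag, and the opaque CRS tag into
    the image description (JSON) alongside a minimal projected-CRS geokey
    directory.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise RasterIOError(f"directory does not exist: {path.parent}")
    # version 1.1.0, 2 keys: GTModelType=projected, GTRasterType=PixelIsArea
    geokeys = (1, 1, 0, 2, 1024, 0, 1, _MODEL_TYPE_PROJECTED, 1025, 0, 1, 1)
    desc = json.dumps({"crs_tag": grid.crs_tag})
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
    ]
    if grid.nodata is not None:
        extratags.append((_GDAL_NODATA, "s", 0, repr(grid.nodata)))
    try:
        tifffile.imwrite(
            path,
            grid.values,
            description=desc,
            extratags=extratags,
            photometric="minisblack",
        )
    except OSError as exc:  # pragma: no cover - unwritable path
        raise RasterIOError(f"cannot write raster {path}: {exc}") from exc


def read_raster(path: str | Path) -> Grid:
    """Read a single-band projected GeoTIFF into a :class:`Grid`.

    Rejects multi-band files and files whose geokeys declare a geographic
    (degree-unit) CRS, since every downstream distance and area is in
    metres.
    """
    path = Path(path)
    if not path.is_file():
        raise RasterIOError(f"no such raster file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise RasterIOError(
                    f"multi-page raster not supported: {path} has {len(tif.pages)} pages"
                )
            page = tif.pages[0]
            if page.samplesperpixel != 1:
                raise RasterIOError(
                    f"multi-band raster not supported: {path} has "
                    f"{page.samplesperpixel} samples per pixel"
                )
            tags = page.tags
            values = page.asarray()
            geokeys = tags.valueof(_GEO_KEY_DIRECTORY)
            if geokeys is not None and _is_geographic(geokeys):
                raise RasterIOError(
                    f"{path}: geographic (degree) CRS; supply a projected raster in metres"
                )
            scale = tags.valueof(_MODEL_PIXEL_SCALE)
            tiepoint = tags.valueof(_MODEL_TIEPOINT)
            nodata_s = tags.valueof(_GDAL_NODATA)
            desc = tags.valueof(_IMAGE_DESCRIPTION)
    except tifffile.TiffFileError as exc:
        raise RasterIOError(f"unreadable raster: {path}") from exc

    if scale is None or tiepoint is None:
        raise RasterIOError(f"{path}: missing GeoTIFF georeferencing tags")
    cell_size = float(scale[0])
    origin = (float(tiepoint[3]), float(tiepoint[4]))
    nodata = None
    if nodata_s is not None:
        nodata_val = float(str(nodata_s).strip())
        if np.issubdtype(values.dtype, np.integer) and not np.isnan(nodata_val):
            nodata = int(nodata_val)
        else:
            nodata = nodata_val
    crs_tag = "unknown"
    if desc:
        try:
            crs_tag = json.loads(desc).get("crs_tag", "unknown")
        except (json.JSONDecodeError, AttributeError):
            pass
    return Grid(values=values, cell_size=cell_size, origin=origin,
                nodata=nodata, crs_tag=crs_tag)


def _is_geographic(geokeys: Sequence[int]) -> bool:
    """True if a GeoKeyDirectory declares GTModelType geographic."""
    keys = np.asarray(geokeys).ravel()
    # entries of 4 shorts after the 4-short header
    for i in range(4, len(keys) - 3, 4):
        if keys[i] == 1024:
            return keys[i + 3] == _MODEL_TYPE_GEOGRAPHIC
    return False


# ---- aggregation and masking ------------------------------------------


def block_aggregate(
    fine: Grid, factor: int, reducer: Literal["mean", "max"] = "mean"
) -> Grid:
    """Aggregate a fine grid to coarse cells of ``factor`` x ``factor`` blocks.

    This is the 10 m -> 100 m "area-weighted mean" step: with a binary
    input and ``reducer="mean"`` each coarse cell holds the fraction of
    its valid fine cells that are 1.  Nodata fine cells are excluded from
    the reduction; a coarse cell is nodata only when its whole block is.
    Partial blocks at the right/bottom edge are treated as nodata-padded,
    so their statistic runs over the cells that exist.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if reducer not in ("mean", "max"):
        raise ValueError(f"reducer must be 'mean' or 'max', got {reducer!r}")

    work = fine.astype_float()
    nr, nc = work.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    if pr or pc:
        work = np.pad(work, ((0, pr), (0, pc)), constant_values=np.nan)
    cr, cc = work.shape[0] // factor, work.shape[1] // factor
    blocks = work.reshape(cr, factor, cc, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(cr, cc, factor * factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN blocks
        if reducer == "mean":
            coarse = np.nanmean(blocks, axis=-1)
        else:
            coarse = np.nanmax(blocks, axis=-1)
    return Grid(
        values=coarse,
        cell_size=fine.cell_size * factor,
        origin=fine.origin,
        nodata=np.nan,
        crs_tag=fine.crs_tag,
    )


def masked_cells(grid: Grid, mask: CityMask) -> np.ndarray:
    """Valid cell values inside the city boundary, row-major."""
    grid.require_aligned(mask.grid, "grid and city mask")
    keep = mask.bool_array() & grid.valid_mask()
    return grid.values[keep]
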