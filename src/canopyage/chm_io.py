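"""Reading, writing and cropping canopy height model rasters and plot tables.

Supported raster formats are single-band float GeoTIFF (georeferencing via the
standard ModelPixelScale / ModelTiepoint tags, nodata via the GDAL_NODATA tag)
and ESRI ASCII grid.  Heights are metres stored as float; nodata cells are
represented in memory as NaN.  Pixels must be square.

The plot table is a CSV with header columns

    plot_id, stand_age_yr, rainfall_mm_yr, plot_area_ha, x_km, y_km,
    h_max_m, cover_5m_pct, h_cv, rumple_norm, basal_area_m2ha, tree_density_ha

of which the first four are required; unknown columns are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CHMRaster", "read_chm", "write_chm", "crop_chm",
    "read_plot_table", "write_plot_table",
    "REQUIRED_PLOT_COLUMNS", "PLOT_TABLE_COLUMNS",
]

REQUIRED_PLOT_COLUMNS = ("plot_id", "stand_age_yr", "rainfall_mm_yr", "plot_area_ha")
PLOT_TABLE_COLUMNS = REQUIRED_PLOT_COLUMNS + (
    "x_km", "y_km", "h_max_m", "cover_5m_pct", "h_cv", "rumple_norm",
    "basal_area_m2ha", "tree_density_ha",
)

_GEOTIFF_PIXEL_SCALE = 33550
_GEOTIFF_TIEPOINT = 33922
_GDAL_NODATA = 42113

#: Values in [NEGATIVE_TOL, 0) are clamped to 0 on read; anything lower is an error.
NEGATIVE_TOL = -0.01


@dataclass
class CHMRaster:
    """A georeferenced grid of canopy heights (m).

    ``heights`` is row-major with row 0 the northernmost row; nodata is NaN.
    ``origin`` is the map coordinate of the grid's upper-left corner.
    """

    heights: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str | None = None
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ValueError("heights must be a non-empty 2D grid")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        valid = self.heights[np.isfinite(self.heights)]
        if valid.size and valid.min() < NEGATIVE_TOL:
            raise ValueError(f"negative canopy heights below {NEGATIVE_TOL} m")
        np.clip(self.heights, 0.0, None, out=self.heights,
                where=np.isfinite(self.heights))

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where the pixel holds a valid height."""
        return np.isfinite(self.heights)

    @property
    def valid_heights(self) -> np.ndarray:
        return self.heights[self.mask]

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x per column, y per row) of pixel centers."""
        nrows, ncols = self.heights.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.resolution
        ys = y0 - (np.arange(nrows) + 0.5) * self.resolution
        return xs, ys


# ---------------------------------------------------------------------------
# raster I/O

def _clean_heights(arr: np.ndarray, nodata: float | None) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if nodata is not None:
        arr = np.where(np.isclose(arr, nodata), np.nan, arr)
    return arr


def read_chm(path: str | Path) -> CHMRaster:
    """Read a CHM from GeoTIFF or ESRI ASCII grid (chosen by extension/content)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_geotiff(path)
    return _read_ascii_grid(path)


def _read_geotiff(path: Path) -> CHMRaster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = {tag.code: tag.value for tag in page.tags.values()}
        if _GEOTIFF_PIXEL_SCALE not in tags or _GEOTIFF_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = float(tags[_GEOTIFF_PIXEL_SCALE][0]), float(tags[_GEOTIFF_PIXEL_SCALE][1])
        if not np.isclose(sx, sy):
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy})")
        tie = tags[_GEOTIFF_TIEPOINT]
        # (i, j, k, x, y, z): raster point (i, j) pinned to map point (x, y).
        origin = (float(tie[3]) - float(tie[0]) * sx,
                  float(tie[4]) + float(tie[1]) * sy)
        nodata = None
        if _GDAL_NODATA in tags:
            nodata = float(str(tags[_GDAL_NODATA]).strip("\x00 "))
        arr = _clean_heights(page.asarray(), nodata)
    return CHMRaster(arr, resolution=sx, origin=origin,
                     nodata=nodata if nodata is not None else -9999.0)


def _read_ascii_grid(path: Path) -> CHMRaster:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                       "yllcenter", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: ESRI ASCII grid missing '{req}' header")
    arr = np.concatenate(rows).reshape(int(header["nrows"]), int(header["ncols"]))
    res = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)
    else:  # llcenter variant: shift by half a cell
        xll = header.get("xllcenter", 0.0) - res / 2.0
        yll = header.get("yllcenter", 0.0) - res / 2.0
    nodata = header.get("nodata_value")
    origin = (xll, yll + int(header["nrows"]) * res)
    return CHMRaster(_clean_heights(arr, nodata), resolution=res, origin=origin,
                     nodata=nodata if nodata is not None else -9999.0)


def write_chm(chm: CHMRaster, path: str | Path) -> None:
    """Write a CHM as GeoTIFF (.tif/.tiff) or ESRI ASCII grid (anything else)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(chm, path)
    else:
        _write_ascii_grid(chm, path)


def _write_geotiff(chm: CHMRaster, path: Path) -> None:
    arr = np.where(chm.mask, chm.heights, chm.nodata).astype(np.float32)
    res = float(chm.resolution)
    extratags = [
        (_GEOTIFF_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_GEOTIFF_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(chm.origin[0]), float(chm.origin[1]), 0.0)),
        (_GDAL_NODATA, "s", 0, str(chm.nodata)),
    ]
    tifffile.imwrite(path, arr, extratags=extratags)


def _write_ascii_grid(chm: CHMRaster, path: Path) -> None:
    nrows, ncols = chm.shape
    res = chm.resolution
    xll = chm.origin[0]
    yll = chm.origin[1] - nrows * res
    arr = np.where(chm.mask, chm.heights, chm.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {xll:.6f}\nyllcorner {yll:.6f}\n")
        fh.write(f"cellsize {res:.6f}\nNODATA_value {chm.nodata}\n")
        for row in arr:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# cropping

def crop_chm(chm: CHMRaster, bbox: tuple[float, float, float, float]) -> CHMRaster:
    """Sub-grid of pixels whose centers fall inside bbox = (xmin, ymin, xmax, ymax).

    Intervals are half-open: the min edge is inclusive, the max edge exclusive.
    Raises ``ValueError`` when no pixel center falls inside the box.
    """
    xmin, ymin, xmax, ymax = bbox
    xs, ys = chm.pixel_centers()
    keep_c = (xs >= xmin) & (xs < xmax)
    keep_r = (ys >= ymin) & (ys < ymax)
    if not keep_c.any() or not keep_r.any():
        raise ValueError("bbox does not contain any pixel center")
    c0, c1 = np.flatnonzero(keep_c)[[0, -1]]
    r0, r1 = np.flatnonzero(keep_r)[[0, -1]]
    sub = chm.heights[r0:r1 + 1, c0:c1 + 1].copy()
    origin = (chm.origin[0] + c0 * chm.resolution,
              chm.origin[1] - r0 * chm.resolution)
    return CHMRaster(sub, resolution=chm.resolution, origin=origin,
                     crs=chm.crs, nodata=chm.nodata)


# ---------------------------------------------------------------------------
# plot tables

def _validate_plot_table(df: pd.DataFrame, source: str) -> None:
    missing = [c for c in REQUIRED_PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")
    for col, what in [("stand_age_yr", "stand age"), ("rainfall_mm_yr", "rainfall"),
                      ("plot_area_ha", "plot area")]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(f"{source}: non-numeric {what} in row(s) {list(bad[:5])}")
        bad = df.index[vals <= 0]
        if len(bad):
            raise ValueError(f"{source}: non-positive {what} in row(s) {list(bad[:5])}")


def read_plot_table(path: str | Path) -> pd.DataFrame:
    """Load and validate the plot CSV; unknown columns are preserved."""
    df = pd.read_csv(path)
    _validate_plot_table(df, str(path))
    for col in df.columns:
        if col != "plot_id":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["plot_id"] = df["plot_id"].astype(str)
    return df


def write_plot_table(df: pd.DataFrame, path: str | Path) -> None:
    _validate_plot_table(df, "plot table")
    df.to_csv(path, index=False)
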