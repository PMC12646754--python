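"""Canopy 3D structural metrics computed from a canopy height model.

Four metrics describe complementary facets of canopy structure:

* ``h_max`` — 98th percentile of all valid pixel heights (ground zeros
  included); a robust top-of-canopy height.
* ``canopy_cover`` — percentage of valid pixels strictly above a height
  threshold (default 5 m, chosen to exclude low regrowth and most standing
  dead wood).
* ``h_cv`` — coefficient of variation (sample sd / mean) of heights over
  pixels strictly above the threshold; computing it over canopy pixels only
  keeps the statistic bounded and interpretable as canopy-height
  heterogeneity.  Fewer than two qualifying pixels yields NaN (an
  undefined-result, logged, not an error).
* ``rumple_norm`` — canopy surface area over ground-projected area, divided by
  h_max (units 1/m).  The surface is triangulated on the pixel-center grid
  with a fixed lower-left→upper-right diagonal per cell.

Conventions (strict ">" for cover, linear-interpolation quantile, n−1
standard deviation) are configurable keyword arguments with these defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chm_io import CHMRaster

__all__ = ["StructuralMetrics", "h_max", "canopy_cover", "h_cv",
           "rumple_norm", "compute_all"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructuralMetrics:
    h_max: float
    cover: float
    h_cv: float            # NaN when fewer than 2 canopy pixels
    rumple_norm: float     # NaN when h_max == 0
    mean_height: float
    threshold_used: float
    n_valid_pixels: int

    def as_dict(self) -> dict[str, float]:
        return {"h_max_m": self.h_max, "cover_5m_pct": self.cover,
                "h_cv": self.h_cv, "rumple_norm": self.rumple_norm}


def _valid(chm: CHMRaster) -> np.ndarray:
    v = chm.valid_heights
    if v.size == 0:
        raise ValueError("raster has no valid pixels")
    return v


def h_max(chm: CHMRaster, q: float = 0.98) -> float:
    """Linear-interpolation quantile ``q`` of all valid pixel heights."""
    if not 0 <= q <= 1:
        raise ValueError("quantile must be in [0, 1]")
    return float(np.quantile(_valid(chm), q))


def canopy_cover(chm: CHMRaster, threshold: float = 5.0) -> float:
    """Percent of valid pixels strictly above ``threshold`` metres."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    v = _valid(chm)
    return 100.0 * float(np.count_nonzero(v > threshold)) / v.size


def h_cv(chm: CHMRaster, threshold: float = 5.0) -> float:
    """Coefficient of variation of heights over pixels above ``threshold``.

    Returns NaN (undefined result) when fewer than two pixels qualify.
    """
    v = _valid(chm)
    canopy = v[v > threshold]
    if canopy.size < 2:
        log.warning("h_cv undefined: %d pixel(s) above %.3g m", canopy.size, threshold)
        return float("nan")
    return float(np.std(canopy, ddof=1) / np.mean(canopy))


def surface_area(chm: CHMRaster) -> float:
    """3D canopy surface area (m²) of the triangulated pixel-center grid.

    Each cell between four adjacent pixel centers is split along its
    lower-left→upper-right diagonal; cells touching a nodata pixel are
    skipped.  Requires at least a 2×2 grid.
    """
    z = chm.heights
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("raster must be at least 2x2 for surface area")
    r = chm.resolution
    # Corners of each cell: a=(0,0) upper-left, b=(0,1), c=(1,0), d=(1,1)
    # in array terms; the "lower-left to upper-right" map diagonal joins
    # c (row+1, col) and b (row, col+1).
    a, b = z[:-1, :-1], z[:-1, 1:]
    c, d = z[1:, :-1], z[1:, 1:]
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & np.isfinite(d)
    # Triangle (a, b, c): area = r²/2 · sqrt(1 + ((b−a)² + (c−a)²)/r²)
    t1 = np.sqrt(r ** 4 + r ** 2 * ((b - a) ** 2 + (c - a) ** 2)) / 2.0
    # Triangle (d, b, c) on the other side of the diagonal.
    t2 = np.sqrt(r ** 4 + r ** 2 * ((b - d) ** 2 + (c - d) ** 2)) / 2.0
    return float(np.sum((t1 + t2)[ok]))


def _ground_area(chm: CHMRaster) -> float:
    z = chm.heights
    a, b = z[:-1, :-1], z[:-1, 1:]
    c, d = z[1:, :-1], z[1:, 1:]
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & np.isfinite(d)
    return float(np.count_nonzero(ok)) * chm.resolution ** 2


def rumple_norm(chm: CHMRaster, q: float = 0.98) -> float:
    """(surface area / ground area) / h_max, in 1/m.

    Raises ``ValueError`` when h_max is zero (normalization undefined).
    """
    hm = h_max(chm, q=q)
    if hm <= 0:
        raise ValueError("rumple_norm undefined for h_max = 0")
    ground = _ground_area(chm)
    if ground <= 0:
        raise ValueError("no fully-valid 2x2 cell for surface triangulation")
    return surface_area(chm) / ground / hm


def compute_all(chm: CHMRaster, threshold: float = 5.0, q: float = 0.98) -> StructuralMetrics:
    """All structural metrics of one raster; component failures become NaN."""
    v = _valid(chm)
    hm = h_max(chm, q=q)
    try:
        rn = rumple_norm(chm, q=q)
    except ValueError:
        rn = float("nan")
    return StructuralMetrics(
        h_max=hm,
        cover=canopy_cover(chm, threshold=threshold),
        h_cv=h_cv(chm, threshold=threshold),
        rumple_norm=rn,
        mean_height=float(np.mean(v)),
        threshold_used=threshold,
        n_valid_pixels=int(v.size),
    )
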