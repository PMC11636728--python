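"""Hexagonal aggregation of the parameter space over a 2-D embedding.

Hexagons give a compact tiling without the directional bias of squares, so
an aggregate of the full space (mean predicted yield, acquisition value,
experiment count, ...) can be drawn beneath a scatter plot of the filtered
subset.  The grid is pointy-top with axial coordinates; point-in-hexagon
assignment uses cube-coordinate rounding (hexagons are the Voronoi cells of
their centers, so containment = nearest center), with boundary ties broken
toward the lexicographically smaller (q, r).  Resolution adapts to a
discrete zoom level: each zoom step doubles the horizontal hexagon count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .ro_dataset import RoDatasetError

__all__ = [
    "HexGrid",
    "HexBinLayer",
    "grid_for_zoom",
    "assign_hex",
    "aggregate_layer",
    "DEFAULT_BASE_BINS_ACROSS",
]

SQRT3 = np.sqrt(3.0)

#: Horizontal hexagon count across the extent at zoom level 0.
DEFAULT_BASE_BINS_ACROSS = 20

_AGG_FUNCS: dict[str, Callable] = {
    "min": np.min,
    "max": np.max,
    "median": np.median,
    "mean": np.mean,
    "count": len,
}


@dataclass(frozen=True)
class HexGrid:
    """Pointy-top hexagonal grid: radius is center-to-vertex."""

    radius: float
    origin: tuple[float, float]
    extent: tuple[float, float, float, float]  # (x_min, x_max, y_min, y_max)

    def __post_init__(self):
        if self.radius <= 0:
            raise RoDatasetError("hex radius must be positive")

    def center(self, q, r) -> tuple[np.ndarray, np.ndarray]:
        """Cartesian center of axial hex (q, r); accepts arrays."""
        q = np.asarray(q, dtype=float)
        r = np.asarray(r, dtype=float)
        x = self.origin[0] + self.radius * SQRT3 * (q + r / 2.0)
        y = self.origin[1] + self.radius * 1.5 * r
        return x, y


@dataclass
class HexBinLayer:
    """Aggregated values per occupied hexagon.

    ``bins`` maps axial (q, r) to the aggregate; ``counts`` to the number of
    contributing (non-missing) points.  Empty hexes are simply absent.
    """

    bins: dict[tuple[int, int], float]
    counts: dict[tuple[int, int], int]
    agg_func: str
    grid: HexGrid
    source_column: str = ""
    n_points_total: int = 0
    uncertainty: dict[tuple[int, int], float] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: q, r, center_x, center_y, value, count[, uncertainty]."""
        keys = sorted(self.bins)
        q = np.array([k[0] for k in keys], dtype=int)
        r = np.array([k[1] for k in keys], dtype=int)
        cx, cy = self.grid.center(q, r)
        out = pd.DataFrame(
            {
                "q": q,
                "r": r,
                "center_x": cx,
                "center_y": cy,
                "value": [self.bins[k] for k in keys],
                "count": [self.counts[k] for k in keys],
            }
        )
        if self.uncertainty is not None:
            out["uncertainty"] = [self.uncertainty[k] for k in keys]
        return out


def grid_for_zoom(
    extent: tuple[float, float, float, float],
    zoom_level: int = 0,
    base_bins_across: int = DEFAULT_BASE_BINS_ACROSS,
) -> HexGrid:
    """Build the hex grid for a discrete zoom level.

    radius = width / (base_bins_across * 2^zoom * sqrt(3)), so the number of
    hexagons across the extent's width doubles with each zoom step (the
    horizontal pitch of a pointy-top hexagon is sqrt(3) * radius).  The
    origin is pinned to the extent's lower-left corner so grids at all zoom
    levels are deterministic.
    """
    x_min, x_max, y_min, y_max = extent
    width = x_max - x_min
    if not np.isfinite(width) or width <= 0:
        raise RoDatasetError("extent must have positive width")
    if zoom_level < 0 or base_bins_across < 1:
        raise RoDatasetError("zoom_level must be >= 0 and base_bins_across >= 1")
    radius = width / (base_bins_across * 2**zoom_level * SQRT3)
    return HexGrid(radius=radius, origin=(x_min, y_min), extent=tuple(extent))


def _axial_fractional(x, y, grid: HexGrid):
    px = (np.asarray(x, float) - grid.origin[0]) / grid.radius
    py = (np.asarray(y, float) - grid.origin[1]) / grid.radius
    q = SQRT3 / 3.0 * px - py / 3.0
    r = 2.0 / 3.0 * py
    return q, r


def _cube_round(qf, rf):
    xf, zf, yf = qf, rf, -qf - rf
    x, y, z = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(x - xf), np.abs(y - yf), np.abs(z - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    x = np.where(fix_x, -y - z, x)
    z = np.where(fix_z, -x - y, z)
    return x.astype(int), z.astype(int)


# relative tolerance for "equidistant" boundary ties
_TIE_RTOL = 1e-9


def assign_hex(point, grid: HexGrid) -> tuple[int, int]:
    """Axial coordinate of the hexagon containing a point.

    Exact containment via cube rounding, then a nearest-center check over
    the rounded hexagon and its six neighbours so that boundary ties (a
    point on a shared edge or vertex) resolve to the lexicographically
    smallest (q, r).
    """
    x, y = point
    if not (np.isfinite(x) and np.isfinite(y)):
        raise RoDatasetError("assign_hex requires finite coordinates")
    q, r = assign_hex_vec(np.array([x]), np.array([y]), grid)
    return int(q[0]), int(r[0])


_NEIGHBOR_OFFSETS = np.array(
    [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)], dtype=int
)


def assign_hex_vec(x: np.ndarray, y: np.ndarray, grid: HexGrid):
    """Vectorized assign_hex over coordinate arrays."""
    qf, rf = _axial_fractional(x, y, grid)
    q0, r0 = _cube_round(qf, rf)
    # candidate hexes: rounded hex + 6 neighbours
    qc = q0[:, None] + _NEIGHBOR_OFFSETS[:, 0][None, :]
    rc = r0[:, None] + _NEIGHBOR_OFFSETS[:, 1][None, :]
    cx, cy = grid.center(qc, rc)
    d2 = (cx - np.asarray(x, float)[:, None]) ** 2 + (cy - np.asarray(y, float)[:, None]) ** 2
    dmin = d2.min(axis=1)
    tol = _TIE_RTOL * grid.radius**2
    best_q = np.full(len(q0), np.iinfo(np.int64).max, dtype=np.int64)
    best_r = np.full(len(r0), np.iinfo(np.int64).max, dtype=np.int64)
    for k in range(_NEIGHBOR_OFFSETS.shape[0]):
        is_tie = d2[:, k] <= dmin + tol
        better = is_tie & (
            (qc[:, k] < best_q) | ((qc[:, k] == best_q) & (rc[:, k] < best_r))
        )
        best_q = np.where(better, qc[:, k], best_q)
        best_r = np.where(better, rc[:, k], best_r)
    return best_q, best_r


def aggregate_layer(
    embedding,
    values,
    grid: HexGrid,
    agg_func: str = "mean",
    uncertainty_values=None,
    source_column: str = "",
) -> HexBinLayer:
    """Aggregate per-point values over the hexagons of a grid.

    Missing values are excluded from every aggregation function, including
    ``count`` (which counts non-missing points), so the per-bin counts
    always sum to the number of points with finite coordinates and a
    non-missing value.  If ``uncertainty_values`` is given, the same
    grouping aggregates them by mean (feeding uncertainty-aware palettes).
    """
    coords = getattr(embedding, "coords", embedding)
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) != len(coords):
        raise RoDatasetError("values must align with embedding rows")
    if agg_func not in _AGG_FUNCS:
        raise RoDatasetError(f"unknown aggregation function {agg_func!r}")
    if uncertainty_values is not None:
        uncertainty_values = np.asarray(uncertainty_values, dtype=float)
        if len(uncertainty_values) != len(coords):
            raise RoDatasetError("uncertainty values must align with embedding rows")

    finite = np.isfinite(coords).all(axis=1)
    keep = finite & ~np.isnan(values)
    x, y = coords[keep, 0], coords[keep, 1]
    v = values[keep]
    q, r = assign_hex_vec(x, y, grid)

    df = pd.DataFrame({"q": q, "r": r, "v": v})
    if uncertainty_values is not None:
        df["u"] = uncertainty_values[keep]
    grouped = df.groupby(["q", "r"], sort=True)

    bins: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    unc: dict[tuple[int, int], float] | None = (
        {} if uncertainty_values is not None else None
    )
    func = _AGG_FUNCS[agg_func]
    for key, sub in grouped:
        key = (int(key[0]), int(key[1]))
        vals = sub["v"].to_numpy()
        bins[key] = float(func(vals))
        counts[key] = int(len(vals))
        if unc is not None:
            unc[key] = float(np.nanmean(sub["u"].to_numpy()))
    return HexBinLayer(
        bins=bins,
        counts=counts,
        agg_func=agg_func,
        grid=grid,
        source_column=source_column,
        n_points_total=int(keep.sum()),
        uncertainty=unc,
    )
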