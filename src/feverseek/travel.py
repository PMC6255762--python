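"""Friction surfaces and least-cost travel time to health facilities.

A desk-scale cost-distance engine: per-cell traversal speeds are derived from
land class, a road mask and elevation (walking speeds slope-corrected by
Tobler's hiking function), and minutes-to-nearest-facility grids are computed
by exact multi-source Dijkstra over the 8-connected cell graph.

Model choices
-------------
* Isotropic slope correction: each cell carries one scalar speed; the slope
  factor uses the steepest local slope magnitude. This keeps edge weights
  symmetric, so a single multi-source shortest-path run is exact.
* Edge traversal time between adjacent cells is centre-to-centre distance
  divided by the harmonic mean of the two cell speeds (time additivity across
  the shared boundary).
* 8-connectivity with sqrt(2) diagonal distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .raster import Raster, assert_coregistered

__all__ = [
    "FrictionRaster",
    "TravelTimeRaster",
    "DEFAULT_SPEEDS_KMH",
    "DEFAULT_WALKING",
    "build_friction",
    "cost_distance",
    "extract_travel_time",
]

#: default land-class travel speeds (km/h). Walking classes are slope-adjusted;
#: water is impassable (speed 0 -> nodata).
DEFAULT_SPEEDS_KMH = {
    "builtup": 5.0,
    "agriculture": 4.0,
    "savanna": 4.0,
    "forest": 2.0,
    "water": 0.0,
}
DEFAULT_WALKING = {"builtup", "agriculture", "savanna", "forest"}

DEFAULT_ROAD_SPEED_KMH = 50.0

_TOBLER_NORM = np.exp(-3.5 * 0.05)


@dataclass
class FrictionRaster:
    """Per-cell traversal speed in km/h; NaN marks impassable cells."""

    speed: Raster

    def __post_init__(self) -> None:
        s = self.speed.data
        finite = s[np.isfinite(s)]
        if finite.size and finite.min() <= 0:
            raise ValueError("friction speeds must be positive on traversable cells")

    @property
    def cell_size(self) -> float:
        return self.speed.cell_size


@dataclass
class TravelTimeRaster:
    """Minutes to the nearest source facility of one tier; NaN = unreachable."""

    minutes: Raster
    tier: str = "any"

    def value_at(self, x: float, y: float) -> float:
        return self.minutes.value_at(x, y)


def tobler_factor(slope: np.ndarray) -> np.ndarray:
    """Walking-speed multiplier for slope ``s`` (rise/run), normalised to 1 on
    flat ground: exp(-3.5*|s + 0.05|) / exp(-3.5*0.05)."""
    return np.exp(-3.5 * np.abs(slope + 0.05)) / _TOBLER_NORM


def steepest_slope(elevation: Raster) -> np.ndarray:
    """Per-cell steepest slope magnitude (rise/run) over the 8 neighbours."""
    z = elevation.data
    cs = elevation.cell_size
    out = np.zeros_like(z)
    for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1),
                   (-1, -1), (-1, 1), (1, -1), (1, 1)]:
        run = cs * (np.sqrt(2.0) if dr and dc else 1.0)
        nb = np.full_like(z, np.nan)
        src = (slice(max(dr, 0), z.shape[0] + min(dr, 0)),
               slice(max(dc, 0), z.shape[1] + min(dc, 0)))
        dst = (slice(max(-dr, 0), z.shape[0] + min(-dr, 0)),
               slice(max(-dc, 0), z.shape[1] + min(-dc, 0)))
        nb[dst] = z[src]
        grad = np.abs(nb - z) / run
        out = np.fmax(out, np.nan_to_num(grad, nan=0.0))
    return out


def build_friction(
    land_class: Raster,
    road_mask: Raster,
    elevation: Raster,
    land_classes: list[str],
    speed_table: dict[str, float] | None = None,
    road_speed: float = DEFAULT_ROAD_SPEED_KMH,
    walking: set[str] | None = None,
) -> FrictionRaster:
    """Combine land class, roads and elevation into a traversal-speed surface.

    Walking-class cells take the land-class speed scaled by the Tobler slope
    factor at the cell; road cells take ``road_speed`` (motorised transport,
    slope-independent); classes with non-positive speed become nodata
    (impassable). ``land_classes`` maps the integer codes of ``land_class`` to
    class names used by ``speed_table``.
    """
    assert_coregistered(land_class, road_mask, elevation)
    speed_table = DEFAULT_SPEEDS_KMH if speed_table is None else speed_table
    walking = DEFAULT_WALKING if walking is None else walking
    missing = [c for c in land_classes if c not in speed_table]
    if missing:
        raise ValueError(f"land classes missing from speed table: {missing}")

    codes = land_class.data.astype(int)
    base = np.array([speed_table[c] for c in land_classes], dtype=float)[codes]
    walk = np.array([c in walking for c in land_classes], dtype=bool)[codes]

    factor = tobler_factor(steepest_slope(elevation))
    speed = np.where(walk, base * factor, base)
    speed = np.where(road_mask.data > 0, road_speed, speed)
    speed = np.where(speed > 0, speed, np.nan)
    return FrictionRaster(Raster(speed, land_class.cell_size))


def _edge_minutes(dist_m: float, v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    # time over the harmonic-mean speed: d * (1/v1 + 1/v2) / 2, in minutes
    return (dist_m / 1000.0) * (1.0 / v1 + 1.0 / v2) / 2.0 * 60.0


def cost_distance(
    friction: FrictionRaster,
    sources: np.ndarray,
    tier: str = "any",
) -> TravelTimeRaster:
    """Exact multi-source least-cost travel time over the 8-connected grid.

    ``sources`` is an (n, 2) array of facility (x, y) world coordinates;
    facilities are snapped to their containing cell centre, duplicates in one
    cell collapse to one source. Output cells hold minutes to the nearest
    source (0 at source cells); unreachable or impassable cells are NaN.
    """
    speed = friction.speed.data
    cs = friction.cell_size
    nrows, ncols = speed.shape

    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if sources.size == 0:
        raise ValueError("no sources for cost distance")
    src_cells = set()
    n_outside = 0
    for x, y in sources:
        try:
            src_cells.add(friction.speed.index_of(x, y))
        except ValueError:
            n_outside += 1
    if not src_cells:
        raise ValueError("no source facility inside the raster extent")
    src_nodes = [r * ncols + c for r, c in src_cells if np.isfinite(speed[r, c])]
    if not src_nodes:
        raise ValueError("all source facilities fall on impassable (nodata) cells")

    valid = np.isfinite(speed)
    rows_i, cols_i, weights = [], [], []
    # build undirected edges once per offset (right, down, down-right, down-left)
    for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
        dist = cs * (np.sqrt(2.0) if dr and dc else 1.0)
        a_sl = (slice(0, nrows - dr), slice(max(-dc, 0), ncols - max(dc, 0)))
        b_sl = (slice(dr, nrows), slice(max(dc, 0), ncols - max(-dc, 0)))
        ok = valid[a_sl] & valid[b_sl]
        r_a, c_a = np.nonzero(ok)
        r_a = r_a + a_sl[0].start
        c_a = c_a + a_sl[1].start
        r_b, c_b = r_a + dr, c_a + dc
        w = _edge_minutes(dist, speed[r_a, c_a], speed[r_b, c_b])
        rows_i.append(r_a * ncols + c_a)
        cols_i.append(r_b * ncols + c_b)
        weights.append(w)
    n = nrows * ncols
    if rows_i:
        graph = csr_matrix(
            (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_i))),
            shape=(n, n),
        )
    else:  # single-cell raster
        graph = csr_matrix((n, n))

    dist = dijkstra(graph, directed=False, indices=src_nodes, min_only=True)
    minutes = dist.reshape(nrows, ncols)
    minutes[~valid] = np.nan
    minutes[np.isinf(minutes)] = np.nan
    return TravelTimeRaster(Raster(minutes, cs), tier=tier)


def extract_travel_time(raster: TravelTimeRaster, coords) -> float:
    """Travel time (minutes) at world coordinates, nearest-cell rule.

    Returns NaN when the containing cell is nodata; raises ``ValueError`` when
    the point is outside the raster extent.
    """
    x, y = coords
    return raster.minutes.value_at(x, y)
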