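import itertools

import networkx as nx
import numpy as np
import pytest

from feverseek.raster import Raster
from feverseek.travel import (
    FrictionRaster,
    build_friction,
    cost_distance,
    extract_travel_time,
    steepest_slope,
    tobler_factor,
)


def friction_from_speeds(speeds, cell=1000.0):
    return FrictionRaster(Raster(np.asarray(speeds, dtype=float), cell))


def _edge_graph(friction: FrictionRaster) -> nx.Graph:
    speed = friction.speed.data
    cs = friction.cell_size
    nrows, ncols = speed.shape
    g = nx.Graph()
    for r, c in itertools.product(range(nrows), range(ncols)):
        if not np.isfinite(speed[r, c]):
            continue
        g.add_node((r, c))
        for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nrows and 0 <= c2 < ncols and np.isfinite(speed[r2, c2]):
                dist_km = cs / 1000.0 * (np.sqrt(2.0) if dr and dc else 1.0)
                w = dist_km * (1.0 / speed[r, c] + 1.0 / speed[r2, c2]) / 2.0 * 60.0
                g.add_edge((r, c), (r2, c2), weight=w)
    return g


def enumerate_all_paths_minutes(friction: FrictionRaster, source_cells):
    """Independent oracle 1: exhaustive enumeration of every simple path on
    the 8-connected cell graph (tractable on tiny grids)."""
    g = _edge_graph(friction)
    speed = friction.speed.data
    out = np.full(speed.shape, np.nan)
    for cell in itertools.product(*map(range, speed.shape)):
        if not np.isfinite(speed[cell]):
            continue
        best = np.inf
        for src in source_cells:
            if cell == src:
                best = 0.0
                break
            for path in nx.all_simple_paths(g, src, cell):
                cost = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
                best = min(best, cost)
        if np.isfinite(best):
            out[cell] = best
    return out


def relaxation_minutes(friction: FrictionRaster, source_cells):
    """Independent oracle 2: Bellman-Ford-style sweeps relaxing every edge
    until a fixpoint — exact for non-negative weights, no priority queue."""
    g = _edge_graph(friction)
    dist = {n: np.inf for n in g.nodes}
    for src in source_cells:
        dist[src] = 0.0
    changed = True
    while changed:
        changed = False
        for u, v, data in g.edges(data=True):
            w = data["weight"]
            if dist[u] + w < dist[v] - 1e-15:
                dist[v] = dist[u] + w
                changed = True
            if dist[v] + w < dist[u] - 1e-15:
                dist[u] = dist[v] + w
                changed = True
    out = np.full(friction.speed.data.shape, np.nan)
    for (r, c), d in dist.items():
        if np.isfinite(d):
            out[r, c] = d
    return out


# ---------------------------------------------------------------------------
# friction construction
# ---------------------------------------------------------------------------

def test_flat_walking_speed_unchanged():
    land = Raster(np.zeros((3, 3)), 1000.0)
    roads = Raster(np.zeros((3, 3)), 1000.0)
    elev = Raster(np.zeros((3, 3)), 1000.0)
    fr = build_friction(land, roads, elev, ["savanna"], {"savanna": 5.0})
    np.testing.assert_allclose(fr.speed.data, 5.0)


def test_road_cells_ignore_slope():
    land = Raster(np.zeros((1, 4)), 1000.0)
    roads = Raster(np.ones((1, 4)), 1000.0)
    elev = Raster(np.array([[0.0, 400.0, 800.0, 1200.0]]), 1000.0)
    fr = build_friction(land, roads, elev, ["savanna"], {"savanna": 5.0},
                        road_speed=50.0)
    np.testing.assert_allclose(fr.speed.data, 50.0)


def test_tobler_slope_factor_closed_form():
    # s = 0.10, v_flat = 5 -> 5 * exp(-3.5*0.15)/exp(-0.175)
    expected = 5.0 * np.exp(-3.5 * 0.15) / np.exp(-0.175)
    land = Raster(np.zeros((1, 3)), 1000.0)
    roads = Raster(np.zeros((1, 3)), 1000.0)
    elev = Raster(np.array([[0.0, 100.0, 200.0]]), 1000.0)  # slope 0.10
    fr = build_friction(land, roads, elev, ["savanna"], {"savanna": 5.0})
    assert fr.speed.data[0, 1] == pytest.approx(expected, rel=1e-12)
    assert tobler_factor(np.array(0.0)) == pytest.approx(1.0, abs=1e-15)


def test_unmapped_land_class_listed_in_error():
    land = Raster(np.array([[0.0, 1.0]]), 1000.0)
    roads = Raster(np.zeros((1, 2)), 1000.0)
    elev = Raster(np.zeros((1, 2)), 1000.0)
    with pytest.raises(ValueError, match="wetland"):
        build_friction(land, roads, elev, ["savanna", "wetland"],
                       {"savanna": 5.0})


def test_impassable_class_becomes_nodata():
    land = Raster(np.array([[0.0, 1.0]]), 1000.0)
    roads = Raster(np.zeros((1, 2)), 1000.0)
    elev = Raster(np.zeros((1, 2)), 1000.0)
    fr = build_friction(land, roads, elev, ["savanna", "water"],
                        {"savanna": 5.0, "water": 0.0})
    assert np.isnan(fr.speed.data[0, 1])


def test_steepest_slope_on_uniform_gradient():
    elev = Raster(np.tile(np.arange(4.0) * 100.0, (3, 1)), 1000.0)
    s = steepest_slope(elev)
    np.testing.assert_allclose(s[:, 1:3], 0.1)


# ---------------------------------------------------------------------------
# cost distance
# ---------------------------------------------------------------------------

def test_uniform_speed_line():
    # 1-km cells at 60 km/h: cell k is k minutes from the source at cell 0
    fr = friction_from_speeds(np.full((1, 6), 60.0))
    tt = cost_distance(fr, [(500.0, 500.0)])
    np.testing.assert_allclose(tt.minutes.data[0], np.arange(6.0), atol=1e-12)


def test_source_cell_is_zero():
    fr = friction_from_speeds(np.full((4, 4), 10.0))
    tt = cost_distance(fr, [(2500.0, 1500.0)])
    assert tt.minutes.data[1, 2] == 0.0


def test_matches_exhaustive_path_enumeration_3x3():
    rng = np.random.default_rng(0)
    speeds = rng.uniform(2.0, 60.0, (3, 3))
    fr = friction_from_speeds(speeds)
    src_cell = (1, 0)
    tt = cost_distance(fr, [fr.speed.coords_of(*src_cell)])
    oracle = enumerate_all_paths_minutes(fr, [src_cell])
    np.testing.assert_allclose(tt.minutes.data, oracle, rtol=1e-10)
    # the two oracles agree with each other too
    np.testing.assert_allclose(relaxation_minutes(fr, [src_cell]), oracle,
                               rtol=1e-10)


@pytest.mark.parametrize("shape,seed,n_src", [((4, 4), 1, 1), ((5, 5), 2, 1),
                                              ((5, 5), 3, 2)])
def test_matches_relaxation_oracle(shape, seed, n_src):
    rng = np.random.default_rng(seed)
    speeds = rng.uniform(2.0, 60.0, shape)
    fr = friction_from_speeds(speeds)
    src_cells = {
        (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
        for _ in range(n_src)
    }
    src_xy = [fr.speed.coords_of(*s) for s in src_cells]
    tt = cost_distance(fr, src_xy)
    oracle = relaxation_minutes(fr, list(src_cells))
    np.testing.assert_allclose(tt.minutes.data, oracle, rtol=1e-10)


def test_adding_source_never_increases_time():
    rng = np.random.default_rng(7)
    fr = friction_from_speeds(rng.uniform(2.0, 60.0, (12, 12)))
    one = cost_distance(fr, [(500.0, 500.0)])
    two = cost_distance(fr, [(500.0, 500.0), (11_500.0, 11_500.0)])
    assert np.all(two.minutes.data <= one.minutes.data + 1e-12)


def test_doubling_speeds_halves_times():
    rng = np.random.default_rng(8)
    speeds = rng.uniform(2.0, 30.0, (8, 8))
    t1 = cost_distance(friction_from_speeds(speeds), [(500.0, 500.0)])
    t2 = cost_distance(friction_from_speeds(2.0 * speeds), [(500.0, 500.0)])
    np.testing.assert_allclose(t2.minutes.data, t1.minutes.data / 2.0,
                               rtol=1e-12)


def test_nodata_barrier_and_unreachable():
    speeds = np.full((3, 3), 10.0)
    speeds[:, 1] = np.nan  # impassable wall
    fr = friction_from_speeds(speeds)
    tt = cost_distance(fr, [(500.0, 500.0)])
    assert np.isnan(tt.minutes.data[:, 1]).all()
    assert np.isnan(tt.minutes.data[:, 2]).all()  # unreachable beyond wall


def test_source_errors():
    fr = friction_from_speeds(np.full((3, 3), 10.0))
    with pytest.raises(ValueError, match="no source"):
        cost_distance(fr, [(1e6, 1e6)])
    speeds = np.full((3, 3), 10.0)
    speeds[0, 0] = np.nan
    with pytest.raises(ValueError, match="impassable"):
        cost_distance(friction_from_speeds(speeds), [(500.0, 500.0)])


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_extract_travel_time_reads_cell_value():
    fr = friction_from_speeds(np.full((2, 2), 10.0))
    tt = cost_distance(fr, [(500.0, 500.0)])
    assert extract_travel_time(tt, (500.0, 500.0)) == 0.0
    assert extract_travel_time(tt, (1500.0, 500.0)) == pytest.approx(6.0)
    with pytest.raises(ValueError):
        extract_travel_time(tt, (5000.0, 500.0))


def test_extract_nodata_returns_nan():
    speeds = np.array([[10.0, np.nan]])
    tt = cost_distance(friction_from_speeds(speeds), [(500.0, 500.0)])
    assert np.isnan(extract_travel_time(tt, (1500.0, 500.0)))
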