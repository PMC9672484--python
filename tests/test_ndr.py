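"""Nutrient-transport stage: D8 routing against a brute-force neighbor
scan, delivery ratios against explicit path-walk products, zonal sums
against independent accumulation, and the two-run theta differencing."""

import numpy as np
import pandas as pd
import pytest

from nitroplan import (
    RoutingError,
    compute_flow_field,
    delivery_ratios,
    fertilizer_theta,
    read_ascii_grid,
    run_ndr,
    write_ascii_grid,
)
from nitroplan.ndr import NEIGHBOR_OFFSETS, OUTLET

from conftest import random_pit_free_dem


# -- independent oracles -----------------------------------------------------

def d8_oracle(dem):
    """Exhaustive neighbor comparison, written independently of the
    implementation's scan loop."""
    rows, cols = dem.shape
    out = np.full((rows, cols), OUTLET, dtype=int)
    for r in range(rows):
        for c in range(cols):
            candidates = []
            for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    candidates.append((dem[rr, cc], k))
            z = min(v for v, _ in candidates)
            if z < dem[r, c]:
                out[r, c] = next(k for v, k in candidates if v == z)
    return out


def path_product_oracle(flow, retention, stream):
    """Per-pixel delivery ratio by explicit recursive path enumeration."""

    def walk(r, c):
        if stream[r, c]:
            return 1.0
        nxt = flow.downstream(r, c)
        assert nxt is not None
        rr, cc = nxt
        if stream[rr, cc]:
            return 1.0
        return (1.0 - retention[rr, cc]) * walk(rr, cc)

    rows, cols = flow.shape
    return np.array([[walk(r, c) for c in range(cols)] for r in range(rows)])


# -- flow field --------------------------------------------------------------

def test_flow_directions_match_bruteforce_on_random_dems():
    rng = np.random.default_rng(42)
    for _ in range(5):
        dem = random_pit_free_dem(rng)
        flow = compute_flow_field(dem)
        np.testing.assert_array_equal(flow.direction, d8_oracle(dem))


def test_tilted_plane_drains_to_the_low_corner():
    # plane tilted toward the SE corner
    r_idx, c_idx = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    dem = 10.0 - r_idx - c_idx
    flow = compute_flow_field(dem)
    for r in range(3):
        for c in range(3):
            rr, cc = r, c
            for _ in range(10):
                nxt = flow.downstream(rr, cc)
                if nxt is None:
                    break
                rr, cc = nxt
            assert (rr, cc) == (2, 2)


def test_v_valley_gives_parallel_flow_lines():
    # a V-shaped valley toward a lowered outlet column (with a slight
    # along-valley tilt so the outlet column itself drains): all pixels of
    # one flank share a single direction -- parallel flow lines
    dem = np.abs(np.arange(7)[None, :] - 2.0) + 0.001 * (
        4 - np.arange(5)
    )[:, None] * np.ones((1, 7))
    flow = compute_flow_field(dem)
    left = flow.direction[:-1, :2]
    right = flow.direction[:-1, 3:]
    assert len(np.unique(left)) == 1
    assert len(np.unique(right)) == 1
    # every pixel's path ends in the outlet column
    for r in range(5):
        for c in range(7):
            rr, cc = r, c
            for _ in range(20):
                nxt = flow.downstream(rr, cc)
                if nxt is None:
                    break
                rr, cc = nxt
            assert cc == 2


def test_interior_pit_raises_and_names_pixel():
    dem = np.ones((5, 5))
    dem += np.arange(5)[:, None] * 0.1
    dem[2, 2] = -1.0  # interior pit
    with pytest.raises(RoutingError, match=r"\(2, 2\)"):
        compute_flow_field(dem)


def test_topological_order_visits_downstream_first():
    rng = np.random.default_rng(1)
    dem = random_pit_free_dem(rng, 6, 6)
    flow = compute_flow_field(dem)
    seen = set()
    for flat in flow.order:
        r, c = divmod(int(flat), 6)
        nxt = flow.downstream(r, c)
        if nxt is not None:
            assert (nxt[0] * 6 + nxt[1]) in seen
        seen.add(r * 6 + c)
    assert len(seen) == 36


# -- delivery ratios ---------------------------------------------------------

def _fixture_grids(rng, rows=6, cols=6):
    dem = random_pit_free_dem(rng, rows, cols)
    retention = rng.uniform(0.0, 0.9, size=(rows, cols))
    stream = np.zeros((rows, cols), dtype=bool)
    stream[rows - 1, :] = True
    return dem, retention, stream


def test_delivery_ratio_matches_path_walk_product():
    rng = np.random.default_rng(7)
    for _ in range(5):
        dem, retention, stream = _fixture_grids(rng)
        flow = compute_flow_field(dem)
        got = delivery_ratios(flow, retention, stream)
        np.testing.assert_array_equal(got, path_product_oracle(flow, retention, stream))


def test_no_retention_delivers_everything():
    rng = np.random.default_rng(8)
    dem, _, stream = _fixture_grids(rng)
    flow = compute_flow_field(dem)
    ratios = delivery_ratios(flow, np.zeros_like(dem), stream)
    np.testing.assert_array_equal(ratios, np.ones_like(dem))


def test_single_intermediate_cell_ratio():
    # one source draining through one cell with retention 0.8 into a stream
    dem = np.array([[3.0, 9, 9], [9, 2.0, 9], [9, 9, 1.0]])
    stream = np.zeros((3, 3), dtype=bool)
    stream[2, 2] = True
    retention = np.full((3, 3), 0.8)
    flow = compute_flow_field(dem)
    ratios = delivery_ratios(flow, retention, stream)
    assert ratios[0, 0] == pytest.approx(0.2, abs=1e-15)
    assert ratios[1, 1] == 1.0  # drains directly into the stream
    assert ratios[2, 2] == 1.0


def test_path_not_reaching_stream_raises():
    dem = random_pit_free_dem(np.random.default_rng(9), 4, 4)
    flow = compute_flow_field(dem)
    stream = np.zeros((4, 4), dtype=bool)  # no stream anywhere
    with pytest.raises(RoutingError, match="without"):
        delivery_ratios(flow, np.zeros((4, 4)), stream)


# -- export runs and theta ---------------------------------------------------

def test_zonal_sums_match_independent_accumulation():
    rng = np.random.default_rng(10)
    dem, retention, stream = _fixture_grids(rng)
    flow = compute_flow_field(dem)
    ratios = delivery_ratios(flow, retention, stream)
    load = rng.uniform(0, 50, size=dem.shape)
    zones = rng.integers(1, 4, size=dem.shape)
    run = run_ndr(load, ratios, zones)
    expected: dict[int, list[float]] = {}
    for r in range(dem.shape[0]):
        for c in range(dem.shape[1]):
            z = int(zones[r, c])
            acc = expected.setdefault(z, [0.0, 0.0])
            acc[0] += load[r, c]
            acc[1] += load[r, c] * ratios[r, c]
    for _, row in run.district_totals.iterrows():
        exp = expected[int(row["district_id"])]
        assert row["load"] == pytest.approx(exp[0], rel=1e-12)
        assert row["export"] == pytest.approx(exp[1], rel=1e-12)
    # per-pixel export never exceeds the load
    assert (run.export <= run.load + 1e-12).all()


def test_zero_load_zero_export():
    ratios = np.full((3, 3), 0.5)
    run = run_ndr(np.zeros((3, 3)), ratios, np.ones((3, 3), dtype=int))
    assert (run.export == 0).all()
    assert run.district_totals["export"].iloc[0] == 0.0


def test_single_pixel_arithmetic():
    load = np.zeros((3, 3))
    load[0, 0] = 10.0
    ratios = np.full((3, 3), 0.5)
    run = run_ndr(load, ratios, np.ones((3, 3), dtype=int))
    assert run.district_totals["export"].iloc[0] == pytest.approx(5.0)


def test_theta_two_district_difference_quotient():
    ratios = np.array([[0.5, 0.25], [1.0, 1.0]])
    zones = np.array([[1, 2], [1, 2]])
    fert = np.array([[10.0, 8.0], [0.0, 0.0]])
    nat = np.array([[1.0, 1.0], [1.0, 1.0]])
    run_f = run_ndr(fert + nat, ratios, zones)
    run_n = run_ndr(nat, ratios, zones)
    table = fertilizer_theta(run_f, run_n).table.set_index("district_id")
    # district 1: extra export 10*0.5 over extra load 10
    assert table.loc[1, "theta"] == pytest.approx(0.5, rel=1e-12)
    assert table.loc[2, "theta"] == pytest.approx(0.25, rel=1e-12)


def test_theta_reduces_to_simple_ratio_without_natural_load():
    rng = np.random.default_rng(11)
    dem, retention, stream = _fixture_grids(rng)
    flow = compute_flow_field(dem)
    ratios = delivery_ratios(flow, retention, stream)
    load = rng.uniform(0, 30, size=dem.shape)
    zones = rng.integers(1, 3, size=dem.shape)
    run_f = run_ndr(load, ratios, zones)
    run_0 = run_ndr(np.zeros_like(load), ratios, zones)
    table = fertilizer_theta(run_f, run_0).table
    tot = run_f.district_totals.set_index("district_id")
    for _, row in table.iterrows():
        d = int(row["district_id"])
        assert row["theta"] == pytest.approx(
            tot.loc[d, "export"] / tot.loc[d, "load"], rel=1e-12
        )


def test_theta_invariant_to_natural_load_magnitude():
    rng = np.random.default_rng(12)
    dem, retention, stream = _fixture_grids(rng)
    flow = compute_flow_field(dem)
    ratios = delivery_ratios(flow, retention, stream)
    fert = rng.uniform(0, 30, size=dem.shape)
    nat = rng.uniform(0, 5, size=dem.shape)
    zones = rng.integers(1, 3, size=dem.shape)
    t1 = fertilizer_theta(
        run_ndr(fert + nat, ratios, zones), run_ndr(nat, ratios, zones)
    ).table
    t2 = fertilizer_theta(
        run_ndr(fert + 3 * nat, ratios, zones), run_ndr(3 * nat, ratios, zones)
    ).table
    np.testing.assert_allclose(t1["theta"], t2["theta"], rtol=1e-9)
    assert t1["theta"].between(0, 1).all()


def test_identical_runs_flagged_undefined():
    ratios = np.full((2, 2), 0.5)
    zones = np.ones((2, 2), dtype=int)
    run = run_ndr(np.ones((2, 2)), ratios, zones)
    table = fertilizer_theta(run, run).table
    assert not table["valid"].any()
    assert table["theta"].isna().all()


def test_retention_increase_never_increases_export():
    rng = np.random.default_rng(13)
    dem, retention, stream = _fixture_grids(rng)
    flow = compute_flow_field(dem)
    load = rng.uniform(0, 30, size=dem.shape)
    zones = rng.integers(1, 3, size=dem.shape)
    base = run_ndr(
        load, delivery_ratios(flow, retention, stream), zones
    ).district_totals.set_index("district_id")["export"]
    for _ in range(10):
        bumped = retention.copy()
        r, c = rng.integers(0, dem.shape[0]), rng.integers(0, dem.shape[1])
        bumped[r, c] = min(1.0, bumped[r, c] + rng.uniform(0, 0.5))
        new = run_ndr(
            load, delivery_ratios(flow, bumped, stream), zones
        ).district_totals.set_index("district_id")["export"]
        assert (new <= base + 1e-12).all()


# -- raster text I/O ---------------------------------------------------------

def test_ascii_grid_round_trip(tmp_path):
    rng = np.random.default_rng(14)
    grid = rng.uniform(-5, 5, size=(4, 6))
    grid[1, 2] = np.nan
    path = tmp_path / "g.asc"
    write_ascii_grid(path, grid)
    back = read_ascii_grid(path)
    np.testing.assert_array_equal(np.isnan(back), np.isnan(grid))
    np.testing.assert_allclose(
        back[~np.isnan(grid)], grid[~np.isnan(grid)], rtol=0, atol=0
    )
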