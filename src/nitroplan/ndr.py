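"""Toy-scale nutrient delivery ratio (NDR) stage.

Routes per-pixel nitrogen loads downslope along D8 (single steepest-descent
neighbor) flow paths with a fraction of the load removed in each traversed
cell, aggregates export by district, and isolates the fertilizer-
attributable delivery ratio theta by differencing a with-fertilizer run
against a natural-load-only run.

Delivery here is deliberately a simple product of (1 - retention) along the
downstream path, stopping at the first stream pixel; the optimizer consumes
only the district ratios theta, which are what this stage exists to supply.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import InputError

__all__ = [
    "FlowField",
    "NdrRun",
    "DeliveryRatioTable",
    "RoutingError",
    "compute_flow_field",
    "delivery_ratios",
    "run_ndr",
    "fertilizer_theta",
    "read_ascii_grid",
    "write_ascii_grid",
]


class RoutingError(ValueError):
    """Flow routing failed (interior pit, path not reaching a stream)."""


#: D8 neighbor scan order: E, SE, S, SW, W, NW, N, NE (row, col offsets).
#: Ties in neighbor elevation break toward the first neighbor in this order.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
)

#: direction code for a border pixel with no lower neighbor (drains off-grid)
OUTLET: int = -1


@dataclass
class FlowField:
    """Single-direction (D8) flow field.

    ``direction``: per-pixel index into :data:`NEIGHBOR_OFFSETS`, or
    :data:`OUTLET` for border pixels draining off the grid.
    ``order``: flat pixel indices sorted downstream-first (ascending
    elevation), a topological order of the flow graph.
    """

    direction: np.ndarray
    order: np.ndarray
    shape: tuple[int, int]

    def downstream(self, row: int, col: int) -> tuple[int, int] | None:
        d = int(self.direction[row, col])
        if d == OUTLET:
            return None
        dr, dc = NEIGHBOR_OFFSETS[d]
        return row + dr, col + dc


def compute_flow_field(dem: np.ndarray) -> FlowField:
    """D8 flow directions: each pixel drains to its lowest 8-neighbor.

    Ties break toward the first neighbor in the fixed E, SE, S, SW, W, NW,
    N, NE scan order.  An interior pixel with no strictly lower neighbor is
    a pit and raises :class:`RoutingError` naming the pixel; border pixels
    with no lower neighbor are marked as off-grid outlets.
    """
    dem = np.asarray(dem, dtype=float)
    if dem.ndim != 2:
        raise InputError("DEM must be a 2-D grid")
    rows, cols = dem.shape
    direction = np.full((rows, cols), OUTLET, dtype=np.int8)
    for r in range(rows):
        for c in range(cols):
            best = None
            best_z = dem[r, c]
            for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and dem[nr, nc] < best_z:
                    best_z = dem[nr, nc]
                    best = k
            if best is None:
                on_border = r in (0, rows - 1) or c in (0, cols - 1)
                if not on_border:
                    raise RoutingError(f"interior pit at pixel ({r}, {c})")
            else:
                direction[r, c] = best
    # flow is strictly downhill, so ascending elevation is a topological
    # order with downstream pixels first
    order = np.argsort(dem, axis=None, kind="stable")
    return FlowField(direction=direction, order=order, shape=(rows, cols))


def delivery_ratios(
    flow: FlowField, retention: np.ndarray, stream_mask: np.ndarray
) -> np.ndarray:
    """Per-pixel delivery ratio: product of (1 - retention) over the pixels
    strictly downstream on the flow path, stopping at (and excluding) the
    first stream pixel.  Stream pixels deliver fully (ratio 1).

    Computed in one pass over the topological order.  A path that leaves
    the grid without reaching a stream raises :class:`RoutingError`.
    """
    retention = np.asarray(retention, dtype=float)
    stream = np.asarray(stream_mask, dtype=bool)
    rows, cols = flow.shape
    if retention.shape != (rows, cols) or stream.shape != (rows, cols):
        raise InputError("retention/stream grids must match the flow field shape")
    if ((retention < 0) | (retention > 1)).any():
        raise InputError("retention efficiencies must lie in [0, 1]")
    ratio = np.full((rows, cols), np.nan)
    for flat in flow.order:
        r, c = divmod(int(flat), cols)
        if stream[r, c]:
            ratio[r, c] = 1.0
            continue
        down = flow.downstream(r, c)
        if down is None:
            raise RoutingError(
                f"flow path from pixel ({r}, {c}) leaves the grid without "
                "reaching a stream"
            )
        nr, nc = down
        if stream[nr, nc]:
            ratio[r, c] = 1.0
        else:
            ratio[r, c] = (1.0 - retention[nr, nc]) * ratio[nr, nc]
    return ratio


@dataclass
class NdrRun:
    """One transport run: per-pixel load, delivery ratio and export, plus
    district totals of load and export (zonal sums)."""

    load: np.ndarray
    ratio: np.ndarray
    export: np.ndarray
    district_totals: pd.DataFrame  # district_id, load, export
    retention: np.ndarray | None = None
    stream_mask: np.ndarray | None = None


def run_ndr(
    load: np.ndarray,
    ratios: np.ndarray,
    district_map: np.ndarray,
    retention: np.ndarray | None = None,
    stream_mask: np.ndarray | None = None,
) -> NdrRun:
    """Apply delivery ratios to a load grid and aggregate by district.

    export_pixel = load_pixel * ratio_pixel; district export (load) is the
    sum of pixel exports (loads) over the district's pixels.  District ids
    <= 0 are treated as nodata and excluded from the totals.
    """
    load = np.asarray(load, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    zones = np.asarray(district_map)
    if not (load.shape == ratios.shape == zones.shape):
        raise InputError("load, ratio and district grids must share a shape")
    if (load < 0).any():
        raise InputError("nitrogen loads must be >= 0")
    export = load * ratios
    valid = zones.ravel() > 0
    df = (
        pd.DataFrame(
            dict(
                district_id=zones.ravel()[valid].astype(int),
                load=load.ravel()[valid],
                export=export.ravel()[valid],
            )
        )
        .groupby("district_id", as_index=False)
        .sum()
    )
    return NdrRun(
        load=load,
        ratio=ratios,
        export=export,
        district_totals=df,
        retention=retention,
        stream_mask=stream_mask,
    )


@dataclass
class DeliveryRatioTable:
    """District fertilizer-attributable delivery ratios.

    ``table`` columns: ``district_id``, optional ``season``, ``theta``,
    ``valid`` (False where the fertilizer load difference is zero and theta
    is undefined -- flagged, never silently dropped).
    """

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DeliveryRatioTable":
        return cls(pd.read_csv(path))


def fertilizer_theta(
    run_with_fert: NdrRun,
    run_natural_only: NdrRun,
    season: int | None = None,
    atol: float = 1e-12,
) -> DeliveryRatioTable:
    """Fertilizer-attributable delivery ratio by two-run differencing.

    theta_i = (export_i^fert - export_i^nat) / (load_i^fert - load_i^nat).
    Districts whose fertilizer load difference is ~0 are flagged invalid
    (theta = NaN).  Because export is linear in load, the difference
    quotient isolates the fertilizer-attributable component exactly and is
    invariant to the magnitude of the natural load.
    """
    a = run_with_fert.district_totals.set_index("district_id")
    b = run_natural_only.district_totals.set_index("district_id")
    if not a.index.equals(b.index):
        raise InputError("the two runs cover different districts")
    dload = a["load"] - b["load"]
    if (dload < -atol).any():
        raise InputError("natural-only load exceeds with-fertilizer load")
    dexp = a["export"] - b["export"]
    valid = dload > atol
    theta = np.where(valid, dexp / dload.where(valid, 1.0), np.nan)
    out = pd.DataFrame(
        dict(district_id=a.index.to_numpy(), theta=theta, valid=valid.to_numpy())
    )
    if season is not None:
        out.insert(1, "season", season)
    return DeliveryRatioTable(out)


# ---------------------------------------------------------------------------
# Esri ASCII grid I/O (single band, row-major, NODATA honored)
# ---------------------------------------------------------------------------

def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    cellsize: float = 30.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = -9999.0,
) -> Path:
    """Write a 2-D array as an Esri ASCII grid; NaNs become NODATA."""
    grid = np.asarray(grid, dtype=float)
    path = Path(path)
    rows, cols = grid.shape
    body = np.where(np.isnan(grid), nodata, grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for r in range(rows):
            fh.write(" ".join(format(float(v), ".17g") for v in body[r]) + "\n")
    return path


def read_ascii_grid(path: str | Path) -> np.ndarray:
    """Read an Esri ASCII grid; NODATA values become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header:
        raise InputError(f"{path}: missing ASCII grid header")
    data = np.loadtxt(lines[i:], dtype=float)
    data = data.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data
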