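"""Accumulated-cost shortest paths over a friction grid.

Least-cost distance (LCD) between two points is the minimum, over all
8-connected lattice paths, of the accumulated traversal cost.  Following
the de-facto GIS convention, the cost of stepping between adjacent cells
i and j is the mean of their per-cell frictions times the step length:

    w(i, j) = (c_i + c_j) / 2 * cell_size * (sqrt(2) for diagonal moves)

which makes LCD symmetric by construction.  Impassable cells (+inf
friction) are excluded from the graph; unreachable pairs get +inf.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .friction import FrictionGrid, Raster
from .geno_io import PopulationTable

logger = logging.getLogger(__name__)

__all__ = [
    "LCDMatrix",
    "LeastCostPath",
    "accumulate_cost",
    "lcd_matrix",
    "backtrack_path",
    "path_to_geojson",
]

_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)]


@dataclass
class LCDMatrix:
    """Pairwise least-cost distances (cost x km) between population sites."""

    ids: list[str]
    values: np.ndarray
    model: object | None = None  # FrictionModel provenance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("LCD matrix shape does not match ids")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


@dataclass
class LeastCostPath:
    """Ordered (row, col) cells from source to target and the total cost."""

    cells: list[tuple[int, int]]
    total_cost: float


def _grid_graph(grid: FrictionGrid):
    """Sparse undirected edge-weight matrix over passable cells."""
    cost = grid.cost.values
    nrows, ncols = cost.shape
    h = grid.cost.cell_size
    passable = np.isfinite(cost)
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)

    rows_out, cols_out, weights = [], [], []
    # enumerate each undirected edge once (E, SE, S, SW neighbors)
    for dr, dc in ((0, 1), (1, 1), (1, 0), (1, -1)):
        rs = slice(max(dr, 0), nrows + min(dr, 0) if dr else nrows)
        src_r = slice(0, nrows - dr)
        if dc >= 0:
            src_c, dst_c = slice(0, ncols - dc), slice(dc, ncols)
        else:
            src_c, dst_c = slice(-dc, ncols), slice(0, ncols + dc)
        dst_r = slice(dr, nrows)
        ok = passable[src_r, src_c] & passable[dst_r, dst_c]
        if not ok.any():
            continue
        a = idx[src_r, src_c][ok]
        b = idx[dst_r, dst_c][ok]
        w = 0.5 * (cost[src_r, src_c][ok] + cost[dst_r, dst_c][ok]) * h
        if dr != 0 and dc != 0:
            w = w * math.sqrt(2.0)
        rows_out.append(a)
        cols_out.append(b)
        weights.append(w)
    if rows_out:
        r = np.concatenate(rows_out)
        c = np.concatenate(cols_out)
        w = np.concatenate(weights)
    else:
        r = c = np.array([], dtype=int)
        w = np.array([], dtype=float)
    graph = coo_matrix((w, (r, c)), shape=(nrows * ncols, nrows * ncols))
    return (graph + graph.T).tocsr()


def accumulate_cost(
    grid: FrictionGrid, source: tuple[int, int]
) -> tuple[Raster, np.ndarray]:
    """Single-source accumulated cost (Dijkstra) and predecessor map.

    Returns the accumulated-cost raster (+inf where unreachable) and a
    flat predecessor array (-9999 sentinel) for path backtracking.
    """
    cost = grid.cost.values
    nrows, ncols = cost.shape
    r0, c0 = source
    if not (0 <= r0 < nrows and 0 <= c0 < ncols) or not np.isfinite(cost[r0, c0]):
        raise ValueError(f"source cell {source} is impassable or out of bounds")
    graph = _grid_graph(grid)
    dist, pred = dijkstra(
        graph, directed=False, indices=r0 * ncols + c0, return_predecessors=True
    )
    acc = grid.cost.like(dist.reshape(nrows, ncols))
    return acc, pred


def backtrack_path(
    predecessors: np.ndarray,
    target: tuple[int, int],
    accumulated: Raster,
) -> LeastCostPath:
    """Reconstruct the least-cost path ending at ``target``."""
    nrows, ncols = accumulated.shape
    r, c = target
    total = float(accumulated.values[r, c])
    if not np.isfinite(total):
        raise ValueError(f"target cell {target} is unreachable")
    node = r * ncols + c
    cells = [(r, c)]
    while predecessors[node] >= 0:
        node = int(predecessors[node])
        cells.append((node // ncols, node % ncols))
    cells.reverse()
    for (r1, c1), (r2, c2) in zip(cells, cells[1:]):
        if max(abs(r1 - r2), abs(c1 - c2)) != 1:
            raise AssertionError("path cells are not 8-adjacent")
    return LeastCostPath(cells=cells, total_cost=total)


def path_to_geojson(path: LeastCostPath, raster: Raster) -> dict:
    """LineString of cell centers in the raster's projected coordinates."""
    coords = [list(raster.cell_center(r, c)) for r, c in path.cells]
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {"total_cost": path.total_cost},
    }


def snap_to_passable(
    grid: FrictionGrid, x: float, y: float, snap_radius: float = 10.0
) -> tuple[int, int, float]:
    """Nearest passable cell (Euclidean cell distance, row-major ties) to a
    projected point; returns (row, col, snap distance in cells)."""
    r0, c0 = grid.cost.cell_of(x, y)
    passable = grid.passable
    nrows, ncols = passable.shape
    rr, cc = np.nonzero(passable)
    if rr.size == 0:
        raise ValueError("no passable cells in grid")
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    best = np.lexsort((cc, rr, d2))[0]  # ties broken row-major
    dist = math.sqrt(float(d2[best]))
    if dist > snap_radius:
        raise ValueError(
            f"point ({x}, {y}) is {dist:.1f} cells from the nearest passable "
            f"cell (snap radius {snap_radius})"
        )
    return int(rr[best]), int(cc[best]), dist


def lcd_matrix(
    grid: FrictionGrid,
    pops: PopulationTable,
    snap_radius: float = 10.0,
    pop_ids: list[str] | None = None,
) -> LCDMatrix:
    """Pairwise least-cost distances between population sites.

    Each population is snapped to the nearest passable cell to its
    coordinates; one Dijkstra run per unique source cell.  Unreachable
    pairs are +inf.
    """
    ids = pop_ids if pop_ids is not None else pops.pop_ids
    cells: dict[str, tuple[int, int]] = {}
    for pop in ids:
        x, y = pops.coords(pop)
        try:
            r, c, snap = snap_to_passable(grid, x, y, snap_radius)
        except ValueError as err:
            raise ValueError(f"population {pop!r}: {err}") from err
        if snap > 0:
            logger.info("lcd_matrix: snapped %s by %.2f cells", pop, snap)
        cells[pop] = (r, c)

    ncols = grid.cost.shape[1]
    unique_cells = sorted(set(cells.values()))
    dist_by_cell: dict[tuple[int, int], np.ndarray] = {}
    for cell in unique_cells:
        acc, _ = accumulate_cost(grid, cell)
        dist_by_cell[cell] = acc.values.ravel()

    n = len(ids)
    values = np.zeros((n, n))
    for i, a in enumerate(ids):
        da = dist_by_cell[cells[a]]
        for j, b in enumerate(ids):
            r, c = cells[b]
            values[i, j] = da[r * ncols + c]
    values = 0.5 * (values + values.T)  # symmetric up to float accumulation
    np.fill_diagonal(values, 0.0)
    return LCDMatrix(ids=list(ids), values=values, model=grid.model)
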