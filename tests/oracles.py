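"""Independent brute-force oracles shared by unit and acceptance tests."""

import math

import numpy as np


def brute_force_lcd(cost: np.ndarray, source: tuple[int, int],
                    target: tuple[int, int], cell_size: float = 1.0) -> float:
    """Minimum accumulated cost over ALL simple 8-connected paths, by
    exhaustive depth-first enumeration.  Exponential: grids <= ~4x4 only."""
    nrows, ncols = cost.shape
    if not np.isfinite(cost[source]) or not np.isfinite(cost[target]):
        return math.inf
    best = math.inf
    visited = np.zeros_like(cost, dtype=bool)

    def dfs(cell, acc):
        nonlocal best
        if acc >= best:
            return
        if cell == target:
            best = acc
            return
        r, c = cell
        visited[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nrows and 0 <= cc < ncols):
                    continue
                if visited[rr, cc] or not np.isfinite(cost[rr, cc]):
                    continue
                step = 0.5 * (cost[r, c] + cost[rr, cc]) * cell_size
                if dr != 0 and dc != 0:
                    step *= math.sqrt(2.0)
                dfs((rr, cc), acc + step)
        visited[r, c] = False

    dfs(source, 0.0)
    return best
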