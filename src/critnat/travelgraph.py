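"""Least-cost travel time over a friction surface.

Edge cost between two adjacent cells is the mean of their friction values
(minutes/km) times the step length (cell size, or cell size x sqrt(2) on
diagonals).  The mid-point rule makes costs symmetric, so fields expanded
from population cells equal fields expanded from targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra

from .grids import GridSpec, require_raster

__all__ = ["TravelField", "travel_time", "population_within", "friction_graph"]

_CHUNK = 512  # dijkstra source rows per batch; bounds the dense distance block


@dataclass(frozen=True)
class TravelField:
    grid: GridSpec
    minutes: np.ndarray   # float64, inf where unreachable
    sources: np.ndarray   # bool

    def __post_init__(self) -> None:
        require_raster(self.minutes, self.grid, "minutes")
        require_raster(self.sources, self.grid, "sources")


def friction_graph(friction_min_per_km: np.ndarray, spec: GridSpec) -> csr_matrix:
    """8-connected sparse graph with mid-point-rule edge costs in minutes."""
    f = np.asarray(require_raster(friction_min_per_km, spec, "friction"), dtype=np.float64)
    if not (f > 0).all():
        raise ValueError("friction must be strictly positive everywhere")
    n_rows, n_cols = spec.shape
    idx = np.arange(spec.n_cells).reshape(spec.shape)
    rows_list, cols_list, costs = [], [], []
    # Undirected graph: emit each edge once (E, SE, S, SW offsets cover all).
    for dr, dc, dist in ((0, 1, 1.0), (1, 1, np.sqrt(2.0)), (1, 0, 1.0), (1, -1, np.sqrt(2.0))):
        r0 = slice(0, n_rows - dr)
        r1 = slice(dr, n_rows)
        c0 = slice(max(0, -dc), n_cols - max(0, dc))
        c1 = slice(max(0, dc), n_cols + min(0, dc))
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        w = 0.5 * (f.ravel()[a] + f.ravel()[b]) * dist * spec.cell_size_km
        rows_list.append(a)
        cols_list.append(b)
        costs.append(w)
    r = np.concatenate(rows_list)
    c = np.concatenate(cols_list)
    w = np.concatenate(costs)
    return coo_matrix((w, (r, c)), shape=(spec.n_cells, spec.n_cells)).tocsr()


def travel_time(friction_min_per_km: np.ndarray, sources: np.ndarray,
                spec: GridSpec) -> TravelField:
    """Exact multi-source shortest-path minutes from any source cell."""
    sources = np.asarray(require_raster(sources, spec, "sources"), dtype=bool)
    src_idx = np.nonzero(sources.ravel())[0]
    if src_idx.size == 0:
        raise ValueError("travel_time requires at least one source cell")
    graph = friction_graph(friction_min_per_km, spec)
    minutes = dijkstra(graph, directed=False, indices=src_idx, min_only=True)
    return TravelField(grid=spec, minutes=minutes.reshape(spec.shape), sources=sources)


def population_within(friction_min_per_km: np.ndarray, population: np.ndarray,
                      max_minutes: float, targets: np.ndarray,
                      spec: GridSpec) -> np.ndarray:
    """Population reachable within ``max_minutes`` of each target cell.

    Expands truncated shortest-path fields from every populated cell and
    accumulates its population onto all cells reached in time; symmetric
    friction makes this equal the per-target definition.  Returns a raster
    that is zero off the target mask.
    """
    if max_minutes <= 0:
        raise ValueError("max_minutes must be positive")
    population = np.asarray(require_raster(population, spec, "population"), dtype=np.float64)
    targets = np.asarray(require_raster(targets, spec, "targets"), dtype=bool)
    graph = friction_graph(friction_min_per_km, spec)
    pop_flat = population.ravel()
    pop_idx = np.nonzero(pop_flat > 0)[0]
    out = np.zeros(spec.n_cells, dtype=np.float64)
    for start in range(0, pop_idx.size, _CHUNK):
        batch = pop_idx[start:start + _CHUNK]
        dist = dijkstra(graph, directed=False, indices=batch, limit=max_minutes)
        reach = dist <= max_minutes
        out += pop_flat[batch] @ reach
    out[~targets.ravel()] = 0.0
    return out.reshape(spec.shape)
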