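"""Hydrologic plumbing: pit filling, D8 routing, downstream accounting.

Direction codes (uint8): 0=E, 1=SE, 2=S, 3=SW, 4=W, 5=NW, 6=N, 7=NE,
8=outlet.  Marine cells and land cells with no lower neighbour that sit on
the map edge or against the sea are outlets.  Flow accumulation counts
contributing cells *including* the cell itself; "people downstream" counts
population strictly downstream, excluding the cell's own residents (a
``include_self`` switch flips that convention).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import NEIGHBOR_DISTANCES, NEIGHBOR_OFFSETS, GridSpec, require_raster

__all__ = [
    "OUTLET",
    "FlowDirection",
    "DownstreamPopulation",
    "fill_pits",
    "d8_directions",
    "downstream_population",
    "flow_accumulation",
    "accumulate_downstream",
    "downstream_of",
    "floodplain_mask",
    "basin_labels",
    "slope_percent",
]

OUTLET: int = 8
_EPS = 1e-6


class RoutingError(RuntimeError):
    """Raised when a flow field cannot be resolved or contains a cycle."""


@dataclass(frozen=True)
class FlowDirection:
    """Per-cell D8 direction codes plus cached topological machinery."""

    grid: GridSpec
    direction: np.ndarray  # uint8, codes 0..8
    land: np.ndarray       # bool; cells that participate in routing

    def __post_init__(self) -> None:
        require_raster(self.direction, self.grid, "direction")
        require_raster(self.land, self.grid, "land")

    def downstream_flat(self) -> np.ndarray:
        """Flat index of the receiving cell, or -1 for outlets."""
        n_rows, n_cols = self.grid.shape
        out = np.full(self.grid.n_cells, -1, dtype=np.int64)
        rows, cols = np.nonzero(self.direction != OUTLET)
        codes = self.direction[rows, cols]
        dr = np.array([o[0] for o in NEIGHBOR_OFFSETS])[codes]
        dc = np.array([o[1] for o in NEIGHBOR_OFFSETS])[codes]
        out[rows * n_cols + cols] = (rows + dr) * n_cols + (cols + dc)
        return out

    def topological_order(self) -> np.ndarray:
        """Flat indices of routed cells, upstream before downstream.

        Kahn's algorithm on the flow graph; raises on cycles.
        """
        dest = self.downstream_flat()
        active = self.land.ravel()
        indeg = np.zeros(self.grid.n_cells, dtype=np.int64)
        valid = active & (dest >= 0)
        np.add.at(indeg, dest[valid], 1)
        order: list[int] = []
        stack = [int(i) for i in np.nonzero(active & (indeg == 0))[0]]
        while stack:
            c = stack.pop()
            order.append(c)
            d = dest[c]
            if d >= 0:
                indeg[d] -= 1
                if indeg[d] == 0 and active[d]:
                    stack.append(int(d))
        if len(order) != int(active.sum()):
            raise RoutingError("cycle detected in flow directions")
        return np.asarray(order, dtype=np.int64)


@dataclass(frozen=True)
class DownstreamPopulation:
    grid: GridSpec
    people_downstream: np.ndarray

    def __post_init__(self) -> None:
        require_raster(self.people_downstream, self.grid, "people_downstream")


def fill_pits(elevation: np.ndarray, marine: np.ndarray, spec: GridSpec,
              epsilon: float = _EPS) -> np.ndarray:
    """Priority-flood pit filling with an epsilon gradient.

    Floods inward from all outlets (marine cells and map-edge land cells),
    raising interior cells to at least ``spill + epsilon`` so that every land
    cell acquires a strictly descending D8 path to an outlet.  Marine cells
    are left untouched; the output is pointwise >= the input.
    """
    elevation = np.asarray(require_raster(elevation, spec, "elevation"), dtype=np.float64)
    marine = np.asarray(require_raster(marine, spec, "marine"), dtype=bool)
    land = ~marine
    if not land.any():
        raise ValueError("fill_pits: no land cells (all-marine input)")
    if not np.isfinite(elevation[land]).all():
        raise ValueError("fill_pits: non-finite elevation on land")

    n_rows, n_cols = spec.shape
    filled = elevation.copy()
    visited = np.zeros(spec.shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0

    def push(r: int, c: int, z: float) -> None:
        nonlocal counter
        heapq.heappush(heap, (z, counter, r, c))
        counter += 1

    # Seeds: marine cells (flood from the sea) and land cells on the map edge.
    for r in range(n_rows):
        for c in range(n_cols):
            on_edge = r == 0 or c == 0 or r == n_rows - 1 or c == n_cols - 1
            if marine[r, c] or (on_edge and land[r, c]):
                visited[r, c] = True
                push(r, c, filled[r, c])

    while heap:
        z, _, r, c = heapq.heappop(heap)
        for dr, dc in NEIGHBOR_OFFSETS:
            nr, nc = r + dr, c + dc
            if not spec.in_bounds(nr, nc) or visited[nr, nc]:
                continue
            visited[nr, nc] = True
            if land[nr, nc]:
                filled[nr, nc] = max(filled[nr, nc], z + epsilon)
            push(nr, nc, filled[nr, nc])
    return filled


def d8_directions(elevation: np.ndarray, marine: np.ndarray, spec: GridSpec) -> FlowDirection:
    """Steepest-descent D8 directions on a pit-filled surface.

    Drop is divided by horizontal distance (diagonals sqrt(2) longer); ties
    break by the fixed code order E, SE, S, SW, W, NW, N, NE.  Marine
    neighbours count as candidates (a coastal cell flows into the sea);
    marine cells themselves are outlets, as are land cells with no lower
    neighbour that touch the edge or the sea.
    """
    elevation = np.asarray(require_raster(elevation, spec, "elevation"), dtype=np.float64)
    marine = np.asarray(require_raster(marine, spec, "marine"), dtype=bool)
    land = ~marine
    n_rows, n_cols = spec.shape
    direction = np.full(spec.shape, OUTLET, dtype=np.uint8)

    for r in range(n_rows):
        for c in range(n_cols):
            if marine[r, c]:
                continue
            best_slope = 0.0
            best_code = OUTLET
            touches_sea = False
            for code, ((dr, dc), dist) in enumerate(zip(NEIGHBOR_OFFSETS, NEIGHBOR_DISTANCES)):
                nr, nc = r + dr, c + dc
                if not spec.in_bounds(nr, nc):
                    continue
                if marine[nr, nc]:
                    touches_sea = True
                drop = elevation[r, c] - elevation[nr, nc]
                if drop <= 0:
                    continue
                slope = drop / dist
                if slope > best_slope:
                    best_slope = slope
                    best_code = code
            if best_code == OUTLET:
                on_edge = r == 0 or c == 0 or r == n_rows - 1 or c == n_cols - 1
                if not (on_edge or touches_sea):
                    raise RoutingError(
                        f"unresolved flat or pit at ({r}, {c}); run fill_pits first"
                    )
            direction[r, c] = best_code
    return FlowDirection(grid=spec, direction=direction, land=land)


def downstream_population(flow: FlowDirection, population: np.ndarray,
                          include_self: bool = False) -> DownstreamPopulation:
    """Population strictly downstream of each cell, in one reverse-topological pass.

    ``include_self=True`` adds the cell's own residents (configuration switch;
    the default excludes them).
    """
    population = np.asarray(require_raster(population, flow.grid, "population"), dtype=np.float64)
    pop_flat = population.ravel()
    dest = flow.downstream_flat()
    order = flow.topological_order()
    down = np.zeros(flow.grid.n_cells, dtype=np.float64)
    for c in order[::-1]:
        d = dest[c]
        if d >= 0:
            down[c] = down[d] + pop_flat[d]
    if include_self:
        down[order] += pop_flat[order]
    return DownstreamPopulation(grid=flow.grid, people_downstream=down.reshape(flow.grid.shape))


def flow_accumulation(flow: FlowDirection) -> np.ndarray:
    """Contributing-cell count per cell, including the cell itself."""
    return accumulate_downstream(flow, np.ones(flow.grid.shape))


def accumulate_downstream(flow: FlowDirection, weights: np.ndarray) -> np.ndarray:
    """Sum of *weights* over each cell's upstream area (self included).

    Marine outlet cells receive the inflow from upstream land plus their own
    weight, which makes conservation checks at outlets straightforward.
    """
    weights = np.asarray(require_raster(weights, flow.grid, "weights"), dtype=np.float64)
    accum = weights.ravel().copy()
    accum[~flow.land.ravel()] = weights.ravel()[~flow.land.ravel()]
    dest = flow.downstream_flat()
    for c in flow.topological_order():
        d = dest[c]
        if d >= 0:
            accum[d] += accum[c]
    return accum.reshape(flow.grid.shape)


def downstream_of(flow: FlowDirection, source_mask: np.ndarray) -> np.ndarray:
    """Boolean mask of cells strictly downstream of any cell in *source_mask*."""
    src = np.asarray(require_raster(source_mask, flow.grid, "source_mask"), dtype=bool).ravel()
    dest = flow.downstream_flat()
    reached = np.zeros(flow.grid.n_cells, dtype=bool)
    for c in flow.topological_order():
        d = dest[c]
        if d >= 0 and (src[c] or reached[c]):
            reached[d] = True
    return reached.reshape(flow.grid.shape)


def floodplain_mask(flow: FlowDirection, accum_threshold_cells: int = 25,
                    buffer_km: float = 10.0) -> np.ndarray:
    """High-accumulation channel cells dilated by a metric buffer.

    Proxy floodplain: land cells whose D8 flow accumulation reaches
    ``accum_threshold_cells``, then every cell within ``buffer_km``
    (Euclidean, default 10 km) of one.
    """
    if accum_threshold_cells < 0:
        raise ValueError("accum_threshold_cells must be >= 0")
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    accum = flow_accumulation(flow)
    channels = (accum >= accum_threshold_cells) & flow.land
    if buffer_km == 0 or not channels.any():
        return channels
    dist = ndimage.distance_transform_edt(~channels, sampling=flow.grid.cell_size_km)
    return dist <= buffer_km


def basin_labels(flow: FlowDirection) -> np.ndarray:
    """Label each routed cell by its terminal outlet; -1 off the land realm.

    Labels are compacted to 0..n_basins-1 in outlet flat-index order.
    """
    dest = flow.downstream_flat()
    order = flow.topological_order()
    terminal = np.full(flow.grid.n_cells, -1, dtype=np.int64)
    for c in order[::-1]:  # downstream-first so the receiver is already labelled
        d = dest[c]
        terminal[c] = c if d < 0 else terminal[d] if terminal[d] >= 0 else d
    # Marine receiving cells carry their own flat index as terminal.
    outlets = np.unique(terminal[order])
    remap = {int(o): i for i, o in enumerate(sorted(outlets))}
    labels = np.full(flow.grid.n_cells, -1, dtype=np.int64)
    for c in order:
        labels[c] = remap[int(terminal[c])]
    return labels.reshape(flow.grid.shape)


def slope_percent(elevation: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Slope magnitude in percent (rise over run x 100) via central differences."""
    elevation = np.asarray(require_raster(elevation, spec, "elevation"), dtype=np.float64)
    cell_m = spec.cell_size_km * 1000.0
    gy, gx = np.gradient(elevation, cell_m)
    return 100.0 * np.hypot(gx, gy)
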