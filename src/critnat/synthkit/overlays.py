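"""Species AOH and language-extent overlays.

Species range areas are drawn log-uniformly between configurable bounds
(default 4 km2 up to a quarter of the land area) so realized ranges span
2-4 orders of magnitude; each range is one connected blob grown on land.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..grids import GridSpec
from .landscape import LandscapeBundle

__all__ = ["SpeciesRange", "LanguageExtent", "OverlayBundle", "make_overlays"]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SpeciesRange:
    species_id: str
    aoh_mask: np.ndarray
    range_area_km2: float


@dataclass(frozen=True)
class LanguageExtent:
    language_id: str
    extent_mask: np.ndarray


@dataclass(frozen=True)
class OverlayBundle:
    grid: GridSpec
    species: list[SpeciesRange]
    languages: list[LanguageExtent]


def _grow_blob(land: np.ndarray, spec: GridSpec, n_cells: int,
               rng: np.random.Generator) -> np.ndarray:
    """Grow a connected blob of ``n_cells`` on the largest land component."""
    labels, n = ndimage.label(land, structure=np.ones((3, 3)))
    if n == 0:
        raise GenerationError("no land to place a range on")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    comp = int(np.argmax(sizes)) + 1
    component = labels == comp
    comp_cells = np.nonzero(component.ravel())[0]
    if n_cells > comp_cells.size:
        raise GenerationError(
            f"requested range of {n_cells} cells exceeds contiguous land ({comp_cells.size})")
    seed_cell = int(rng.choice(comp_cells))
    mask = np.zeros(spec.shape, dtype=bool)
    # randomized Prim growth: frontier heap keyed by random priority
    heap: list[tuple[float, int]] = [(0.0, seed_cell)]
    in_frontier = {seed_cell}
    grown = 0
    while heap and grown < n_cells:
        _, cell = heapq.heappop(heap)
        r, c = spec.rowcol(cell)
        if mask[r, c]:
            continue
        mask[r, c] = True
        grown += 1
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nr, nc = r + dr, c + dc
                if (dr or dc) and spec.in_bounds(nr, nc) and component[nr, nc] and not mask[nr, nc]:
                    flat = spec.flat_index(nr, nc)
                    if flat not in in_frontier:
                        in_frontier.add(flat)
                        heapq.heappush(heap, (float(rng.random()), flat))
    return mask


def make_overlays(landscape: LandscapeBundle, n_species: int, n_languages: int,
                  seed: int, min_range_km2: float = 4.0,
                  max_range_km2: float | None = None,
                  language_cells: tuple[int, int] = (8, 120)) -> OverlayBundle:
    if n_species < 0 or n_languages < 0:
        raise ValueError("counts must be non-negative")
    spec = landscape.grid
    land = landscape.land
    cell_area = spec.cell_area_km2
    land_area = float(land.sum()) * cell_area
    if max_range_km2 is None:
        max_range_km2 = land_area / 4.0
    if max_range_km2 < min_range_km2:
        raise GenerationError("max_range_km2 smaller than min_range_km2")
    if max_range_km2 > land_area:
        raise GenerationError("requested ranges exceed the land area")

    lo_cells = max(1, int(np.ceil(min_range_km2 / cell_area)))
    hi_cells = max(lo_cells, int(np.floor(max_range_km2 / cell_area)))

    rng = np.random.default_rng([seed, 16])
    species: list[SpeciesRange] = []
    for i in range(n_species):
        area = 10.0 ** rng.uniform(np.log10(min_range_km2), np.log10(max_range_km2))
        n_cells = int(np.clip(round(area / cell_area), lo_cells, hi_cells))
        mask = _grow_blob(land, spec, n_cells, rng)
        species.append(SpeciesRange(
            species_id=f"sp{i:04d}", aoh_mask=mask,
            range_area_km2=float(mask.sum()) * cell_area))

    rng = np.random.default_rng([seed, 17])
    languages: list[LanguageExtent] = []
    max_lang = min(language_cells[1], int(land.sum()))
    for i in range(n_languages):
        n_cells = int(rng.integers(min(language_cells[0], max_lang), max_lang + 1))
        mask = _grow_blob(land, spec, n_cells, rng)
        languages.append(LanguageExtent(language_id=f"lang{i:03d}", extent_mask=mask))

    return OverlayBundle(grid=spec, species=species, languages=languages)
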