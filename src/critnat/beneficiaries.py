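"""Benefitting areas and unique-beneficiary counts for a solution mask.

Only the spatially delineable services are covered: downstream water
quality (nitrogen, sediment), flood mitigation, nature access, fuelwood and
coastal protection.  Unique beneficiaries are counted once if they fall in
at least one service's benefit-and-relevant area (union at person level),
which is how double-counting across overlapping areas is avoided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridSpec, require_raster
from .terrain_flow import FlowDirection, downstream_of
from .travelgraph import travel_time

__all__ = ["DELINEABLE_NCP", "BeneficiaryReport", "benefit_mask", "count_beneficiaries"]

DELINEABLE_NCP = ("nitrogen_retention", "sediment_retention", "flood_regulation",
                  "nature_access", "fuelwood", "coastal_protection")


class UnsupportedNCPError(ValueError):
    pass


@dataclass
class PerNCPCount:
    ncp: str
    benefit_mask: np.ndarray
    relevant_pop_mask: np.ndarray
    beneficiaries: float
    relevant_total: float


@dataclass
class BeneficiaryReport:
    per_ncp: list[PerNCPCount]
    union_beneficiaries: float
    residents: float
    population_total: float

    def as_dict(self) -> dict:
        return {
            "per_ncp": [{"ncp": p.ncp, "beneficiaries": p.beneficiaries,
                         "relevant_total": p.relevant_total} for p in self.per_ncp],
            "union_beneficiaries": self.union_beneficiaries,
            "residents": self.residents,
            "population_total": self.population_total,
        }


def _within_km(mask: np.ndarray, radius_km: float, spec: GridSpec) -> np.ndarray:
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spec.cell_size_km)
    return dist <= radius_km


def benefit_mask(ncp: str, solution_mask: np.ndarray, spec: GridSpec, *,
                 flow: FlowDirection | None = None,
                 friction: np.ndarray | None = None,
                 floodplain: np.ndarray | None = None,
                 elevation_m: np.ndarray | None = None,
                 rural_poor: np.ndarray | None = None,
                 max_minutes: float = 60.0,
                 gather_radius_km: float = 10.0,
                 protective_distance_cells: float = 2.0,
                 elevation_cutoff_m: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Benefit and relevant-population masks for one delineable service.

    Water-quality and flood benefits flow to cells strictly downstream of
    selected assets; access reaches people within the travel budget;
    fuelwood within a gathering radius; coastal within the protective
    distance.  Relevant population is everyone except: flood (within 10 km
    of floodplains), coastal (below the elevation cutoff) and fuelwood
    (rural poor).
    """
    if ncp not in DELINEABLE_NCP:
        raise UnsupportedNCPError(
            f"beneficiaries of {ncp!r} cannot be spatially delineated")
    solution_mask = np.asarray(require_raster(solution_mask, spec, "solution_mask"), dtype=bool)
    everyone = np.ones(spec.shape, dtype=bool)

    if ncp in ("nitrogen_retention", "sediment_retention", "flood_regulation"):
        if flow is None:
            raise ValueError(f"{ncp} needs a flow field")
        benefit = downstream_of(flow, solution_mask)
        if ncp == "flood_regulation":
            if floodplain is None:
                raise ValueError("flood_regulation needs the floodplain mask")
            relevant = np.asarray(floodplain, dtype=bool)
        else:
            relevant = everyone
    elif ncp == "nature_access":
        if friction is None:
            raise ValueError("nature_access needs the friction surface")
        if solution_mask.any():
            field = travel_time(friction, solution_mask, spec)
            benefit = field.minutes <= max_minutes
        else:
            benefit = np.zeros(spec.shape, dtype=bool)
        relevant = everyone
    elif ncp == "fuelwood":
        if rural_poor is None:
            raise ValueError("fuelwood needs the rural_poor raster")
        benefit = _within_km(solution_mask, gather_radius_km, spec)
        relevant = np.asarray(rural_poor, dtype=np.float64) > 0
    else:  # coastal_protection
        if elevation_m is None:
            raise ValueError("coastal_protection needs elevation")
        radius_km = protective_distance_cells * spec.cell_size_km
        benefit = _within_km(solution_mask, radius_km, spec)
        relevant = np.asarray(elevation_m, dtype=np.float64) < elevation_cutoff_m
    return benefit, relevant


def count_beneficiaries(masks: dict[str, tuple[np.ndarray, np.ndarray]],
                        solution_mask: np.ndarray, population: np.ndarray,
                        spec: GridSpec) -> BeneficiaryReport:
    """Per-service and unique beneficiary counts plus resident count.

    ``masks`` maps service name to ``(benefit_mask, relevant_pop_mask)``.
    """
    population = np.asarray(require_raster(population, spec, "population"), dtype=np.float64)
    solution_mask = np.asarray(require_raster(solution_mask, spec, "solution_mask"), dtype=bool)
    per_ncp: list[PerNCPCount] = []
    union = np.zeros(spec.shape, dtype=bool)
    for ncp, (benefit, relevant) in masks.items():
        benefit = np.asarray(benefit, dtype=bool)
        relevant = np.asarray(relevant, dtype=bool)
        both = benefit & relevant
        union |= both
        per_ncp.append(PerNCPCount(
            ncp=ncp, benefit_mask=benefit, relevant_pop_mask=relevant,
            beneficiaries=float(population[both].sum()),
            relevant_total=float(population[relevant].sum())))
    return BeneficiaryReport(
        per_ncp=per_ncp,
        union_beneficiaries=float(population[union].sum()),
        residents=float(population[solution_mask].sum()),
        population_total=float(population.sum()))
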