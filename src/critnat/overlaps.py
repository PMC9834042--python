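"""Overlap statistics: local/global partition, protected share, species and
language representation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthkit.overlays import OverlayBundle

__all__ = [
    "RepresentationRule", "representation_target", "species_coverage",
    "language_coverage", "partition_local_global", "mask_share",
]


@dataclass(frozen=True)
class RepresentationRule:
    """Target rule mapping a species' range area to a required AOH fraction.

    ``log_linear``: full representation below the lower threshold, 10% above
    the upper, log-linear in between.  ``minimum_area``: a fixed persistence
    floor, capped at the whole range.
    """

    kind: str = "log_linear"
    lower_threshold_km2: float = 1_000.0
    upper_threshold_km2: float = 250_000.0
    lower_fraction: float = 1.0
    upper_fraction: float = 0.1
    min_area_km2: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("log_linear", "minimum_area"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.lower_threshold_km2 >= self.upper_threshold_km2:
            raise ValueError("lower threshold must be below upper threshold")
        for f in (self.lower_fraction, self.upper_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def representation_target(range_area_km2: float, rule: RepresentationRule) -> float:
    if range_area_km2 <= 0:
        raise ValueError("range area must be positive")
    if rule.kind == "minimum_area":
        return min(1.0, rule.min_area_km2 / range_area_km2)
    if range_area_km2 <= rule.lower_threshold_km2:
        return rule.lower_fraction
    if range_area_km2 >= rule.upper_threshold_km2:
        return rule.upper_fraction
    # interpolate on log range area
    t = ((np.log(range_area_km2) - np.log(rule.lower_threshold_km2))
         / (np.log(rule.upper_threshold_km2) - np.log(rule.lower_threshold_km2)))
    return float(rule.lower_fraction + t * (rule.upper_fraction - rule.lower_fraction))


def species_coverage(overlays: OverlayBundle, solution_mask: np.ndarray,
                     rule: RepresentationRule
                     ) -> tuple[int, float, pd.DataFrame, int]:
    """Count species whose AOH coverage by the solution meets the target.

    A species is met when ``area(AOH intersect solution) >= target x range``
    (equality counts).  Species whose target area exceeds their existing AOH
    are flagged unachievable.
    """
    solution_mask = np.asarray(solution_mask, dtype=bool)
    cell_area = overlays.grid.cell_area_km2
    rows = []
    for sp in overlays.species:
        target_frac = representation_target(sp.range_area_km2, rule)
        target_area = target_frac * sp.range_area_km2
        aoh_area = float(sp.aoh_mask.sum()) * cell_area
        covered = float((sp.aoh_mask & solution_mask).sum()) * cell_area
        unachievable = target_area > aoh_area + 1e-9
        met = covered >= target_area - 1e-9
        rows.append({"species_id": sp.species_id, "range_area_km2": sp.range_area_km2,
                     "target_fraction": target_frac, "target_area_km2": target_area,
                     "covered_area_km2": covered, "met": met,
                     "unachievable": unachievable})
    table = pd.DataFrame(rows)
    n_met = int(table["met"].sum()) if len(table) else 0
    frac = n_met / len(table) if len(table) else 0.0
    n_unachievable = int(table["unachievable"].sum()) if len(table) else 0
    return n_met, frac, table, n_unachievable


def language_coverage(overlays: OverlayBundle, solution_mask: np.ndarray
                      ) -> tuple[int, float]:
    """Languages partially intersecting the solution (a single shared cell counts)."""
    solution_mask = np.asarray(solution_mask, dtype=bool)
    n = sum(1 for lang in overlays.languages
            if (lang.extent_mask & solution_mask).any())
    frac = n / len(overlays.languages) if overlays.languages else 0.0
    return n, frac


def partition_local_global(local_mask: np.ndarray, global_mask: np.ndarray,
                           land_area_km2: float, cell_area_km2: float) -> dict[str, float]:
    """Exact three-way partition of the two solutions plus union, as areas and
    shares of total land area."""
    local_mask = np.asarray(local_mask, dtype=bool)
    global_mask = np.asarray(global_mask, dtype=bool)
    both = int((local_mask & global_mask).sum())
    local_only = int(local_mask.sum()) - both
    global_only = int(global_mask.sum()) - both
    union = local_only + global_only + both
    out: dict[str, float] = {}
    for key, cells in (("local_only", local_only), ("global_only", global_only),
                       ("both", both), ("union", union)):
        area = cells * cell_area_km2
        out[f"{key}_km2"] = area
        out[f"{key}_pct"] = 100.0 * area / land_area_km2 if land_area_km2 else 0.0
    return out


def mask_share(subject_mask: np.ndarray, reference_mask: np.ndarray) -> float:
    """Percent of the reference area that the subject covers."""
    subject_mask = np.asarray(subject_mask, dtype=bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    ref = int(reference_mask.sum())
    if ref == 0:
        raise ValueError("reference mask is empty; share undefined")
    return 100.0 * int((subject_mask & reference_mask).sum()) / ref
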