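"""Minimum-area prioritization: weighted set multicover over raster cells.

Each planning problem selects the smallest set of equal-area asset cells
whose summed values reach a proportional target of every NCP's total within
the region.  The exact path is a binary integer program (HiGHS via
scipy.optimize.milp); the greedy path is a scalable surrogate whose output
is always audited for feasibility.  Accumulation curves, drop-one
sensitivity and solution-overlap statistics are built on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds

from .grids import GridSpec, require_raster
from .ncp_layers.assets import NCPLayer

__all__ = [
    "ProblemInstance", "Solution", "AccumulationCurve",
    "build_problems", "solve_exact", "solve_greedy", "solve",
    "accumulation_curve", "drop_one_sensitivity", "solution_overlap",
    "audit_solution",
]

EXACT_CELL_CAP = 5000
_REL_TOL = 1e-9


class SolverError(RuntimeError):
    pass


@dataclass
class ProblemInstance:
    """Values matrix + proportional targets for one region and realm."""

    region_id: int
    realm: str
    cells: np.ndarray            # flat indices into the grid
    values: np.ndarray           # (n_ncp, n_cells), >= 0
    ncp_names: tuple[str, ...]
    targets: np.ndarray          # per-NCP fractions in [0, 1]
    cell_area_km2: float
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape != (len(self.ncp_names), self.cells.size):
            raise ValueError("values must be (n_ncp, n_cells)")
        if (self.values < 0).any():
            raise ValueError("values must be non-negative")
        if ((self.targets < 0) | (self.targets > 1)).any():
            raise ValueError("targets must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return int(self.cells.size)

    @property
    def totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def constrained(self) -> np.ndarray:
        """Indices of NCP with positive totals (zero-total constraints are vacuous)."""
        return np.nonzero(self.totals > 0)[0]

    def with_targets(self, target) -> "ProblemInstance":
        t = np.full(len(self.ncp_names), float(target)) if np.isscalar(target) \
            else np.asarray(target, dtype=np.float64)
        return ProblemInstance(self.region_id, self.realm, self.cells, self.values,
                               self.ncp_names, t, self.cell_area_km2, self.grid)

    def drop_ncp(self, name: str) -> "ProblemInstance":
        keep = [i for i, n in enumerate(self.ncp_names) if n != name]
        return ProblemInstance(self.region_id, self.realm, self.cells,
                               self.values[keep], tuple(self.ncp_names[i] for i in keep),
                               self.targets[keep], self.cell_area_km2, self.grid)


@dataclass
class Solution:
    problem: ProblemInstance
    selected: np.ndarray         # bool per problem cell
    solver: str                  # "exact" | "greedy"
    optimality_gap: float = 0.0

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.size != self.problem.n_cells:
            raise ValueError("selected length must match problem cells")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def area_km2(self) -> float:
        return self.n_selected * self.problem.cell_area_km2

    @property
    def achieved(self) -> np.ndarray:
        totals = self.problem.totals
        got = self.problem.values[:, self.selected].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, got / totals, 1.0)

    def selected_mask(self, grid: GridSpec) -> np.ndarray:
        mask = np.zeros(grid.n_cells, dtype=bool)
        mask[self.problem.cells[self.selected]] = True
        return mask.reshape(grid.shape)


@dataclass
class AccumulationCurve:
    label: str
    points: list[tuple[float, float, float]] = field(default_factory=list)
    # each point: (target_level, area_km2, area_fraction_of_assets)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points,
                            columns=["target_level", "area_km2", "area_fraction_of_assets"])


def build_problems(layers: list[NCPLayer], region_id: np.ndarray, realm: np.ndarray,
                   scale: str, grid: GridSpec) -> list[ProblemInstance]:
    """One instance per region (country scale) or one pooled instance (global).

    Only layers of the requested scale enter.  Problems are split by realm
    (land vs marine); a layer with realm "both" contributes to each.  Cells
    with region id 0 (overlapping claims) are excluded from national
    instances.  Regions with no asset cells yield no instance.
    """
    if scale not in ("country", "global"):
        raise ValueError("scale must be 'country' or 'global'")
    layers = [l for l in layers if l.scale == scale]
    if not layers:
        return []
    region_id = require_raster(region_id, grid, "region_id")
    realm = require_raster(realm, grid, "realm")

    problems: list[ProblemInstance] = []
    for realm_name, realm_code in (("land", 0), ("marine", 1)):
        active = [l for l in layers if l.realm in (realm_name, "both")]
        if not active:
            continue
        asset_union = np.zeros(grid.shape, dtype=bool)
        for l in active:
            asset_union |= l.asset.is_asset
        domain = asset_union & (realm == realm_code)
        if scale == "global":
            groups = [(0, domain)]
        else:
            groups = [(rid, domain & (region_id == rid))
                      for rid in np.unique(region_id) if rid > 0]
        for rid, cell_mask in groups:
            cells = np.nonzero(cell_mask.ravel())[0]
            if cells.size == 0:
                continue
            values = np.stack([l.values.ravel()[cells] for l in active])
            problems.append(ProblemInstance(
                region_id=int(rid), realm=realm_name, cells=cells, values=values,
                ncp_names=tuple(l.name for l in active),
                targets=np.zeros(len(active)), cell_area_km2=grid.cell_area_km2,
                grid=grid))
    return problems


def solve_exact(problem: ProblemInstance, mip_gap: float = 0.0,
                cell_cap: int = EXACT_CELL_CAP) -> Solution:
    """Provably optimal selection via a binary integer program."""
    if problem.n_cells > cell_cap:
        raise SolverError(
            f"{problem.n_cells} cells exceeds exact-solver cap {cell_cap}; use solve_greedy")
    idx = problem.constrained()
    need = problem.targets[idx] * problem.totals[idx]
    n = problem.n_cells
    if idx.size == 0 or (need <= 0).all():
        return Solution(problem, np.zeros(n, dtype=bool), "exact", 0.0)
    # tiny relative slack absorbs accumulated float error in the constraint rows
    slack = _REL_TOL * problem.totals[idx]
    constraints = LinearConstraint(problem.values[idx], lb=need - slack, ub=np.inf)
    res = milp(c=np.ones(n), constraints=constraints, integrality=np.ones(n),
               bounds=Bounds(0, 1), options={"mip_rel_gap": mip_gap})
    if not res.success:
        raise SolverError(f"MIP failed: {res.message}")
    selected = res.x > 0.5
    return Solution(problem, selected, "exact", float(res.mip_gap or 0.0))


def solve_greedy(problem: ProblemInstance) -> Solution:
    """Greedy multicover: repeatedly take the cell with the largest summed
    normalized contribution toward the remaining deficits; first index wins ties."""
    idx = problem.constrained()
    totals = problem.totals[idx]
    values = problem.values[idx]
    need = problem.targets[idx] * totals
    n = problem.n_cells
    selected = np.zeros(n, dtype=bool)
    achieved = np.zeros(idx.size)
    tol = _REL_TOL * totals  # relative: constrained NCP always have totals > 0
    while (need - achieved > tol).any():
        deficit = np.maximum(need - achieved, 0.0)
        gain = (np.minimum(values, deficit[:, None]) / totals[:, None]).sum(axis=0)
        gain[selected] = -np.inf
        best = int(np.argmax(gain))
        if not np.isfinite(gain[best]) or gain[best] <= 0:
            break  # nothing can still contribute; targets met within tolerance
        selected[best] = True
        achieved += values[:, best]
    return Solution(problem, selected, "greedy", np.nan)


def solve(problem: ProblemInstance, policy: str = "auto",
          cell_cap: int = EXACT_CELL_CAP) -> Solution:
    """Solver policy: exact when the instance fits under the cap, else greedy."""
    if policy == "exact":
        return solve_exact(problem, cell_cap=cell_cap)
    if policy == "greedy":
        return solve_greedy(problem)
    if policy == "auto":
        if problem.n_cells <= cell_cap:
            return solve_exact(problem, cell_cap=cell_cap)
        return solve_greedy(problem)
    raise ValueError(f"unknown solver policy {policy!r}")


def audit_solution(solution: Solution, rel_tol: float = 1e-9) -> bool:
    """Independent feasibility audit: achieved >= target for every constrained NCP."""
    problem = solution.problem
    idx = problem.constrained()
    return bool((solution.achieved[idx] >= problem.targets[idx] - rel_tol).all())


def accumulation_curve(problems: list[ProblemInstance],
                       targets_grid: np.ndarray | list[float] | None = None,
                       policy: str = "auto",
                       cell_cap: int = EXACT_CELL_CAP
                       ) -> tuple[dict[str, AccumulationCurve], AccumulationCurve]:
    """Solve every problem at every target level; return per-problem curves
    plus the aggregated (summed-area) curve."""
    if targets_grid is None:
        targets_grid = np.round(np.arange(0.05, 1.0001, 0.05), 10)
    targets_grid = np.asarray(sorted(targets_grid), dtype=np.float64)
    if ((targets_grid < 0) | (targets_grid > 1)).any():
        raise ValueError("targets must lie in [0, 1]")

    total_assets = sum(p.n_cells for p in problems)
    per_problem: dict[str, AccumulationCurve] = {}
    agg = AccumulationCurve(label="aggregated")
    areas_by_level = np.zeros(targets_grid.size)
    for p in problems:
        label = f"{p.realm}:{p.region_id}"
        curve = AccumulationCurve(label=label)
        for i, level in enumerate(targets_grid):
            sol = solve(p.with_targets(level), policy=policy, cell_cap=cell_cap)
            frac = sol.n_selected / p.n_cells if p.n_cells else 0.0
            curve.points.append((float(level), sol.area_km2, frac))
            areas_by_level[i] += sol.area_km2
        per_problem[label] = curve
    cell_area = problems[0].cell_area_km2 if problems else 1.0
    for i, level in enumerate(targets_grid):
        frac = areas_by_level[i] / (total_assets * cell_area) if total_assets else 0.0
        agg.points.append((float(level), float(areas_by_level[i]), frac))
    return per_problem, agg


def _union_mask(solutions: list[Solution], grid: GridSpec) -> np.ndarray:
    out = np.zeros(grid.shape, dtype=bool)
    for s in solutions:
        out |= s.selected_mask(grid)
    return out


def drop_one_sensitivity(problems: list[ProblemInstance], target: float,
                         policy: str = "auto",
                         cell_cap: int = EXACT_CELL_CAP) -> pd.DataFrame:
    """Re-solve with each NCP excluded in turn.

    Reports, per dropped NCP, the percent change in aggregate area relative
    to the full solve and the fraction of the full solution's area shared
    with the reduced solution; the ``all_reduced`` row gives the fraction of
    the full solution present in every reduced solution.
    """
    if not problems:
        raise ValueError("no problems to solve")
    names = problems[0].ncp_names
    if len(names) < 2:
        raise ValueError("drop-one sensitivity needs at least 2 NCP")
    grid = problems[0].grid
    full_solutions = [solve(p.with_targets(target), policy, cell_cap) for p in problems]
    full_area = sum(s.area_km2 for s in full_solutions)
    full_mask = _union_mask(full_solutions, grid)
    full_cells = max(int(full_mask.sum()), 1)

    rows = []
    shared_all = full_mask.copy()
    for name in names:
        reduced = [solve(p.drop_ncp(name).with_targets(target), policy, cell_cap)
                   for p in problems]
        area = sum(s.area_km2 for s in reduced)
        mask = _union_mask(reduced, grid)
        shared = int((full_mask & mask).sum()) / full_cells
        shared_all &= mask
        delta_pct = 100.0 * (area - full_area) / full_area if full_area else 0.0
        rows.append({"dropped_ncp": name, "area_km2": area,
                     "delta_area_pct": delta_pct, "shared_area_fraction": shared})
    df = pd.DataFrame(rows)
    df.attrs["full_area_km2"] = full_area
    df.attrs["all_solutions_shared_fraction"] = int(shared_all.sum()) / full_cells
    return df


def solution_overlap(masks: dict[str, np.ndarray]) -> tuple[pd.DataFrame, float]:
    """Directional pairwise shared-area percentages and the all-shared fraction.

    ``shared[a][b]`` = share of *a*'s area also selected by *b*, in percent.
    The second return value is the fraction of the union contained in every
    solution.
    """
    names = list(masks)
    if not names:
        raise ValueError("no solutions supplied")
    areas = {n: int(np.asarray(m, dtype=bool).sum()) for n, m in masks.items()}
    table = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        if areas[a] == 0:
            warnings.warn(f"solution {a!r} is empty; shares reported as 0", stacklevel=2)
        for b in names:
            inter = int((np.asarray(masks[a], dtype=bool)
                         & np.asarray(masks[b], dtype=bool)).sum())
            table.loc[a, b] = 100.0 * inter / areas[a] if areas[a] else 0.0
    union = np.zeros_like(np.asarray(masks[names[0]], dtype=bool))
    common = np.ones_like(union)
    for m in masks.values():
        union |= np.asarray(m, dtype=bool)
        common &= np.asarray(m, dtype=bool)
    n_union = int(union.sum())
    all_shared = int(common.sum()) / n_union if n_union else 0.0
    return table, all_shared
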