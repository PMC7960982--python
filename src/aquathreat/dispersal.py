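"""Sub-basin dispersal units and the maximal-dispersal threat metric.

Under "no dispersal" a species is confined to its current range.  Under
"maximal dispersal" it can reach any cell of the sub-basin units that
its range touches, provided the cell's baseline conditions sit inside
the species' tolerance window.  Sub-basin units are the connected
components of the intersection between drainage basins and freshwater
ecoregions; units smaller than a minimum area are merged into an
edge-adjacent neighbour (the one sharing the longest boundary).

With an expanded range the threat metric becomes
RT = 100 * AT / (A + (AE - AET)), where AE is the area of the expansion
and AET the threatened area within it — habitable expansion area grows
the denominator, threatened expansion area is discounted from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import ExposureResult, flag_cell_exceedance
from .synthetic_world import GridDefinition, _neighbors
from .thresholds import SpeciesThresholds


@dataclass(frozen=True)
class SubBasinUnits:
    """Partition of valid cells into dispersal units."""

    unit_id: np.ndarray        # flat (n_cells,), -1 outside valid cells
    unit_area: pd.Series       # km^2 per unit id

    @property
    def n_units(self) -> int:
        return int(self.unit_area.size)

    def cells_of(self, unit: int) -> np.ndarray:
        return np.flatnonzero(self.unit_id == unit)


@dataclass(frozen=True)
class ExpandedRange:
    species_id: str
    original_cells: frozenset[int]
    expanded_cells: frozenset[int]   # cells added under maximal dispersal
    ae_km2: float

    def __post_init__(self) -> None:
        if self.expanded_cells & self.original_cells:
            raise ValueError("expansion must be disjoint from the original range")


def _connected_components(grid: GridDefinition, key: np.ndarray) -> np.ndarray:
    """Label connected components (4-connectivity) of equal-key valid cells."""
    n = grid.n_cells
    labels = np.full(n, -1, dtype=int)
    valid = grid.valid_mask.ravel()
    nxt = 0
    for start in range(n):
        if not valid[start] or labels[start] != -1:
            continue
        stack = [start]
        labels[start] = nxt
        while stack:
            cur = stack.pop()
            for nb in _neighbors(cur, grid.n_rows, grid.n_cols):
                if valid[nb] and labels[nb] == -1 and key[nb] == key[cur]:
                    labels[nb] = nxt
                    stack.append(nb)
        nxt += 1
    return labels


def _boundary_lengths(grid: GridDefinition, labels: np.ndarray) -> dict[tuple[int, int], int]:
    """Shared-edge counts between distinct adjacent units."""
    shared: dict[tuple[int, int], int] = {}
    valid = grid.valid_mask.ravel()
    n_cols = grid.n_cols
    for cell in range(grid.n_cells):
        if not valid[cell]:
            continue
        for nb in (cell + 1, cell + n_cols):     # right and down edges once each
            if nb >= grid.n_cells or not valid[nb]:
                continue
            if nb == cell + 1 and nb // n_cols != cell // n_cols:
                continue
            a, b = labels[cell], labels[nb]
            if a != b:
                key = (min(a, b), max(a, b))
                shared[key] = shared.get(key, 0) + 1
    return shared


def delineate_subbasins(
    grid: GridDefinition, min_unit_area: float = 1000.0
) -> SubBasinUnits:
    """Dispersal units from the basin x ecoregion intersection.

    Raw units are connected components of cells sharing the same
    (basin, ecoregion) pair.  Units below ``min_unit_area`` km^2 are
    merged, smallest first, into the edge-adjacent neighbour sharing the
    longest boundary (ties broken toward the larger, then the
    lower-numbered, unit), re-evaluating until every remaining unit is
    either large enough or has no neighbour.  Unit ids are relabelled
    densely from 0 at the end.
    """
    pair_key = grid.basin_id.ravel() * (grid.ecoregion_id.max() + 2) + grid.ecoregion_id.ravel()
    labels = _connected_components(grid, pair_key)
    areas_flat = grid.cell_area.ravel()

    def unit_areas(lab: np.ndarray) -> dict[int, float]:
        out: dict[int, float] = {}
        for cell in np.flatnonzero(lab >= 0):
            out[lab[cell]] = out.get(lab[cell], 0.0) + areas_flat[cell]
        return out

    areas = unit_areas(labels)
    while True:
        shared = _boundary_lengths(grid, labels)
        neighbors_of: dict[int, dict[int, int]] = {}
        for (a, b), length in shared.items():
            neighbors_of.setdefault(a, {})[b] = length
            neighbors_of.setdefault(b, {})[a] = length
        small = [
            u for u, area in areas.items()
            if area < min_unit_area and neighbors_of.get(u)
        ]
        if not small:
            break
        u = min(small, key=lambda k: (areas[k], k))
        nbs = neighbors_of[u]
        target = min(
            nbs, key=lambda v: (-nbs[v], -areas[v], v)
        )  # longest boundary, then larger area, then lower id
        labels[labels == u] = target
        areas[target] += areas.pop(u)

    # dense relabel
    old_ids = sorted(areas)
    remap = {old: new for new, old in enumerate(old_ids)}
    dense = np.array([remap.get(l, -1) for l in labels], dtype=int)
    area_series = pd.Series(
        [areas[o] for o in old_ids], index=pd.RangeIndex(len(old_ids), name="unit_id")
    )
    return SubBasinUnits(unit_id=dense, unit_area=area_series)


def expand_range(
    species_id: str,
    range_cells: frozenset[int],
    units: SubBasinUnits,
    baseline_extremes: pd.DataFrame,
    thresholds: SpeciesThresholds,
    grid: GridDefinition,
) -> ExpandedRange:
    """Habitable cells reachable under maximal dispersal.

    Candidates are every cell of every unit containing at least one
    range cell, minus the range itself; a candidate is added when its
    baseline indicators violate none of the species' five thresholds
    (same strict-exceedance convention as future exposure).
    """
    touched_units = {int(units.unit_id[c]) for c in range_cells if units.unit_id[c] >= 0}
    candidates = sorted(
        set(int(c) for u in touched_units for c in units.cells_of(u)) - set(range_cells)
    )
    if candidates:
        flags = flag_cell_exceedance(baseline_extremes.loc[candidates], thresholds)
        suitable = [c for c, bad in zip(candidates, flags.to_numpy().any(axis=1)) if not bad]
    else:
        suitable = []
    expanded = frozenset(suitable)
    return ExpandedRange(
        species_id=species_id,
        original_cells=frozenset(range_cells),
        expanded_cells=expanded,
        ae_km2=grid.area_of(expanded) if expanded else 0.0,
    )


def range_threatened_maximal(
    expanded: ExpandedRange,
    scenario_id: str,
    grouped_flags: pd.DataFrame,
    grid: GridDefinition,
) -> dict[str, ExposureResult]:
    """RT% under maximal dispersal, per variable group.

    The numerator AT covers the original range only; threatened
    expansion area AET merely shrinks the habitable expansion in the
    denominator: RT = 100 * AT / (A + (AE - AET)).  With AE = 0 this is
    the no-dispersal metric; with AET = AE it degenerates to it too.
    """
    areas = grid.cell_area.ravel()
    orig = np.array(sorted(expanded.original_cells), dtype=int)
    ext = np.array(sorted(expanded.expanded_cells), dtype=int)
    a_total = float(areas[orig].sum())
    out: dict[str, ExposureResult] = {}
    for group in ("flow", "temperature", "any", "both"):
        orig_hit = grouped_flags.loc[orig, group].to_numpy(bool)
        at = float(areas[orig[orig_hit]].sum())
        if ext.size:
            ext_hit = grouped_flags.loc[ext, group].to_numpy(bool)
            aet = float(areas[ext[ext_hit]].sum())
        else:
            aet = 0.0
        denom = a_total + (expanded.ae_km2 - aet)
        threatened = frozenset(int(c) for c in orig[orig_hit])
        out[group] = ExposureResult(
            species_id=expanded.species_id,
            scenario_id=scenario_id,
            variable_group=group,
            threatened_cells=threatened,
            at_km2=at,
            rt_percent=min(100.0 * at / denom, 100.0),
        )
    return out
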