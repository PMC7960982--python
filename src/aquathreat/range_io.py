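"""Species range rasterization, merging and inclusion filtering.

Ranges arrive either as polygons (rasterized with the >= 50%
cell-overlap rule) or as cell lists.  Species are excluded from the
analysis when exclusively lentic (the hydrological indicators describe
flowing water) or when their range covers fewer than a minimum number
of grid cells (default 10, ~1,000 km^2 at a ~10 km resolution).

Grid geometry for rasterization is planar: cell (row, col) spans
``[col, col+1) x [row, row+1)`` in grid units scaled by ``cell_size``.
Overlap fractions are computed against the planar cell square; the
per-cell km^2 areas of the grid affect area bookkeeping downstream,
not the overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .synthetic_world import GridDefinition

HABITAT_CLASSES = ("lotic", "lentic", "lotic-lentic", "lotic-marine")


@dataclass(frozen=True)
class SpeciesRange:
    species_id: str
    cells: frozenset[int]              # flat row-major cell indices
    area_km2: float
    habitat_class: str = "lotic"

    def __post_init__(self) -> None:
        if self.cells and self.area_km2 <= 0:
            raise ValueError("non-empty range must have positive area")


def make_range(
    species_id: str,
    cells: frozenset[int] | set[int],
    grid: GridDefinition,
    habitat_class: str = "lotic",
) -> SpeciesRange:
    cells = frozenset(int(c) for c in cells)
    invalid = [c for c in cells if not grid.valid_mask.ravel()[c]]
    if invalid:
        raise ValueError(f"{species_id}: cells outside the valid grid: {sorted(invalid)[:5]}")
    return SpeciesRange(
        species_id=species_id,
        cells=cells,
        area_km2=grid.area_of(cells) if cells else 0.0,
        habitat_class=habitat_class,
    )


def rasterize_range(
    polygon: BaseGeometry,
    grid: GridDefinition,
    species_id: str = "sp",
    habitat_class: str = "lotic",
    *,
    cell_size: float = 1.0,
    min_overlap: float = 0.5,
) -> SpeciesRange:
    """Mark a species as occurring in every cell the polygon covers by
    at least ``min_overlap`` of the cell's area (>= comparison, so an
    exact 50% overlap is included).  An empty result is allowed."""
    if polygon.is_empty:
        raise ValueError("empty polygon")
    if not polygon.is_valid:
        from shapely.validation import explain_validity

        raise ValueError(f"invalid geometry: {explain_validity(polygon)}")

    minx, miny, maxx, maxy = polygon.bounds
    c0 = max(int(np.floor(minx / cell_size)), 0)
    c1 = min(int(np.ceil(maxx / cell_size)), grid.n_cols - 1)
    r0 = max(int(np.floor(miny / cell_size)), 0)
    r1 = min(int(np.ceil(maxy / cell_size)), grid.n_rows - 1)
    cell_area_planar = cell_size * cell_size

    cells = set()
    valid = grid.valid_mask.ravel()
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            idx = r * grid.n_cols + c
            if not valid[idx]:
                continue
            square = box(c * cell_size, r * cell_size, (c + 1) * cell_size, (r + 1) * cell_size)
            frac = polygon.intersection(square).area / cell_area_planar
            if frac >= min_overlap or np.isclose(frac, min_overlap):
                cells.add(idx)
    return make_range(species_id, cells, grid, habitat_class)


def merge_ranges(*ranges: SpeciesRange, grid: GridDefinition) -> SpeciesRange:
    """Union of several source ranges for the same species.

    Commutative, associative and idempotent; the area is recomputed
    from the merged cell set.  Habitat classes are combined: lotic +
    lentic evidence yields lotic-lentic, any marine evidence yields
    lotic-marine.
    """
    if not ranges:
        raise ValueError("nothing to merge")
    ids = {r.species_id for r in ranges}
    if len(ids) > 1:
        raise ValueError(f"refusing to merge different species: {sorted(ids)}")
    cells = frozenset().union(*(r.cells for r in ranges))
    classes = {r.habitat_class for r in ranges}
    if "lotic-marine" in classes:
        habitat = "lotic-marine"
    elif classes >= {"lotic", "lentic"} or "lotic-lentic" in classes:
        habitat = "lotic-lentic"
    else:
        (habitat,) = classes
    return make_range(ranges[0].species_id, cells, grid, habitat)


def filter_species(
    ranges: list[SpeciesRange], min_cells: int = 10
) -> tuple[list[SpeciesRange], pd.DataFrame]:
    """Apply the inclusion rules; return retained ranges + exclusion report.

    Exclusively lentic species are dropped (reason ``lentic``), then
    species with fewer than ``min_cells`` range cells (reason
    ``too_small``).  The report has one row per input species with its
    outcome, so exclusions + retained always sum to the input count.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    retained: list[SpeciesRange] = []
    rows = []
    for r in ranges:
        if r.habitat_class == "lentic":
            rows.append({"species_id": r.species_id, "outcome": "excluded", "reason": "lentic"})
        elif len(r.cells) < min_cells:
            rows.append(
                {
                    "species_id": r.species_id,
                    "outcome": "excluded",
                    "reason": f"too_small ({len(r.cells)} < {min_cells} cells)",
                }
            )
        else:
            retained.append(r)
            rows.append({"species_id": r.species_id, "outcome": "retained", "reason": ""})
    return retained, pd.DataFrame(rows)


def ranges_to_frame(ranges: list[SpeciesRange], grid: GridDefinition) -> pd.DataFrame:
    """Cell-list table: species_id, cell, cell_row, cell_col."""
    rows = []
    for r in ranges:
        for c in sorted(r.cells):
            rows.append(
                {
                    "species_id": r.species_id,
                    "cell": c,
                    "cell_row": c // grid.n_cols,
                    "cell_col": c % grid.n_cols,
                }
            )
    return pd.DataFrame(rows)


def ranges_from_frame(
    df: pd.DataFrame, grid: GridDefinition, habitat: dict[str, str] | None = None
) -> list[SpeciesRange]:
    """Read ranges from a cell-list table (species_id + cell or row/col)."""
    if "cell" not in df.columns:
        df = df.assign(cell=df["cell_row"] * grid.n_cols + df["cell_col"])
    out = []
    for sp, sub in df.groupby("species_id", sort=True):
        out.append(
            make_range(
                str(sp),
                frozenset(int(c) for c in sub["cell"]),
                grid,
                (habitat or {}).get(str(sp), "lotic"),
            )
        )
    return out
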