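"""Ensemble summaries, per-cell potentially-affected-fraction (PAF) maps,
and watershed means.

PAF for cell i at warming level w is the median, across the ensemble
members realising that warming level, of the fraction of the cell's
species pool whose tolerance window is exceeded in that cell:
PAF_{i,w} = median_c(1 - S_{i,w} / S_{i,present}).  The median rather
than the mean is used because per-scenario fractions are skewed; with
an even member count the midpoint of the two middle values is taken.
Cells with an empty species pool are no-data (NaN), never zero.

The headline ensemble summary is the proportion of species with more
than half (strictly > 50%) of their (expanded) range threatened, with
mean and standard deviation across ensemble members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PafMap:
    """Per-cell PAF for one warming level and variable group."""

    paf: np.ndarray            # flat (n_cells,), NaN = no data
    s_present: np.ndarray      # flat species pool size per cell
    scenario_count: int
    warming_level: float
    variable_group: str

    def __post_init__(self) -> None:
        data = self.paf[self.s_present > 0]
        if data.size and (np.nanmin(data) < -1e-12 or np.nanmax(data) > 1 + 1e-12):
            raise ValueError("PAF outside [0, 1]")


@dataclass(frozen=True)
class EnsembleSummary:
    warming_level: float
    dispersal: str
    fraction_over_half_mean: float
    fraction_over_half_sd: float
    per_scenario_fractions: tuple[float, ...]
    mean_rt_by_species: pd.Series     # mean RT(any) across members

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_over_half_mean <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def summarize_ensemble(
    exposure: pd.DataFrame,
    warming_level: float,
    dispersal: str,
    *,
    rt_cutoff: float = 50.0,
    variable_group: str = "any",
    ddof: int = 1,
) -> EnsembleSummary:
    """Fraction of species with RT strictly above the cutoff, per member.

    ``exposure`` is the long table (species_id, scenario_id,
    warming_level, variable_group, rt_percent, dispersal).  Mean and
    sample standard deviation (``ddof=1`` by default) are taken across
    the ensemble members at the warming level; a single-member ensemble
    reports SD 0 with a warning.
    """
    sub = exposure[
        (exposure["warming_level"] == warming_level)
        & (exposure["variable_group"] == variable_group)
        & (exposure["dispersal"] == dispersal)
    ]
    if sub.empty:
        raise ValueError(f"no exposure rows for warming level {warming_level}")
    if sub["species_id"].nunique() == 0:
        raise ValueError("empty species set")
    fractions = (
        sub.assign(over=sub["rt_percent"] > rt_cutoff)
        .groupby("scenario_id", sort=True)["over"]
        .mean()
    )
    if len(fractions) == 1:
        warnings.warn("single-member ensemble: SD reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(fractions.std(ddof=ddof))
    mean_rt = sub.groupby("species_id", sort=True)["rt_percent"].mean()
    return EnsembleSummary(
        warming_level=warming_level,
        dispersal=dispersal,
        fraction_over_half_mean=float(fractions.mean()),
        fraction_over_half_sd=sd,
        per_scenario_fractions=tuple(float(f) for f in fractions),
        mean_rt_by_species=mean_rt,
    )


def cell_paf(
    pools: Mapping[str, frozenset[int]],
    exceedance: Mapping[tuple[str, str], frozenset[int]],
    scenario_ids: Sequence[str],
    n_cells: int,
    *,
    warming_level: float = float("nan"),
    variable_group: str = "any",
) -> PafMap:
    """Median-over-members PAF map from per-species threatened-cell sets.

    ``pools`` maps species to the cells where it occurs (its current or
    expanded range); ``exceedance[(species, scenario)]`` is the set of
    pool cells where that species' thresholds are exceeded under that
    member.  For each member the affected fraction in a cell is the
    share of its pooled species exceeded there; PAF is the member-wise
    median (midpoint convention for even counts).
    """
    present = np.zeros(n_cells, dtype=int)
    for cells in pools.values():
        idx = np.fromiter(cells, dtype=int)
        present[idx] += 1

    fractions = np.full((len(scenario_ids), n_cells), np.nan)
    for s, scen in enumerate(scenario_ids):
        affected = np.zeros(n_cells, dtype=int)
        for sp, cells in pools.items():
            hit = exceedance.get((sp, scen), frozenset())
            if hit:
                idx = np.fromiter(hit, dtype=int)
                affected[idx] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            fractions[s] = np.where(present > 0, affected / present, np.nan)

    paf = np.full(n_cells, np.nan)
    data = present > 0
    if len(scenario_ids) and data.any():
        paf[data] = np.nanmedian(fractions[:, data], axis=0)
    return PafMap(
        paf=paf,
        s_present=present,
        scenario_count=len(scenario_ids),
        warming_level=warming_level,
        variable_group=variable_group,
    )


def watershed_paf(paf_map: PafMap, basin_id: np.ndarray) -> pd.DataFrame:
    """Unweighted mean PAF over each basin's data cells.

    ``basin_id`` is the flat per-cell basin label (-1 = invalid).
    Basins containing no data cells get NaN.
    """
    flat = np.asarray(basin_id).ravel()
    rows = []
    for basin in sorted(set(int(b) for b in flat if b >= 0)):
        vals = paf_map.paf[flat == basin]
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "basin_id": basin,
                "mean_paf": float(vals.mean()) if vals.size else np.nan,
                "n_cells": int(vals.size),
            }
        )
    return pd.DataFrame(rows).set_index("basin_id")


def attribution_maps(
    pools: Mapping[str, frozenset[int]],
    exceedance_by_group: Mapping[str, Mapping[tuple[str, str], frozenset[int]]],
    scenario_ids: Sequence[str],
    n_cells: int,
    *,
    warming_level: float = float("nan"),
    groups: Sequence[str] = ("temperature", "flow", "both"),
) -> dict[str, PafMap]:
    """PAF maps per variable group (temperature / flow / both).

    The "both" map counts species whose flow AND temperature tolerances
    are exceeded in the same cell, attributing the threat to the joint
    occurrence of the two extreme types.
    """
    return {
        g: cell_paf(
            pools,
            exceedance_by_group[g],
            scenario_ids,
            n_cells,
            warming_level=warming_level,
            variable_group=g,
        )
        for g in groups
    }


def top_basins_by_richness(
    basin_id: np.ndarray, pools: Mapping[str, frozenset[int]], k: int = 6
) -> list[int]:
    """Basins ranked by species richness (distinct species present)."""
    flat = np.asarray(basin_id).ravel()
    richness: dict[int, set[str]] = {}
    for sp, cells in pools.items():
        for c in cells:
            b = int(flat[c])
            if b >= 0:
                richness.setdefault(b, set()).add(sp)
    ranked = sorted(richness, key=lambda b: (-len(richness[b]), b))
    return ranked[:k]
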