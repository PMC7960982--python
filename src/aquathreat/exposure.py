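"""Threat exposure: threshold exceedance flags and range threatened (RT%).

A range cell is threatened under a future scenario when a projected
indicator exceeds the species' baseline-derived tolerance window:
minimum flow or temperature falling strictly below the low threshold,
maximum flow or temperature or zero-flow frequency rising strictly
above the high threshold.  Equality is within current experience, not
exceedance, hence the strict inequalities.

Flags are grouped into flow (q_min | q_max | q_zf), temperature
(t_min | t_max), any (either group) and both (both groups in the same
cell), and summarised as the percentage of range area threatened,
RT = 100 * AT / A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_world import GridDefinition
from .thresholds import SpeciesThresholds

VARIABLE_GROUPS = ("flow", "temperature", "any", "both")
FLAG_COLUMNS = ("q_min", "q_max", "q_zf", "t_min", "t_max")


@dataclass(frozen=True)
class ExposureResult:
    species_id: str
    scenario_id: str
    variable_group: str
    threatened_cells: frozenset[int]
    at_km2: float
    rt_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rt_percent <= 100.0 + 1e-9:
            raise ValueError(f"RT {self.rt_percent} outside [0, 100]")


def flag_cell_exceedance(
    future_metrics: pd.DataFrame, thresholds: SpeciesThresholds
) -> pd.DataFrame:
    """Per-cell boolean exceedance flags for the five indicators.

    ``future_metrics`` is a per-cell indicator table (columns q_min,
    q_max, q_zf, t_min, t_max).  Returns a boolean DataFrame with the
    same index and one column per indicator, True where the projected
    value strictly exceeds the species' tolerance in the threatening
    direction.
    """
    return pd.DataFrame(
        {
            "q_min": future_metrics["q_min"] < thresholds.q_min_thr,
            "q_max": future_metrics["q_max"] > thresholds.q_max_thr,
            "q_zf": future_metrics["q_zf"] > thresholds.q_zf_thr,
            "t_min": future_metrics["t_min"] < thresholds.t_min_thr,
            "t_max": future_metrics["t_max"] > thresholds.t_max_thr,
        },
        index=future_metrics.index,
    )


def group_flags(flags: pd.DataFrame) -> pd.DataFrame:
    """Collapse the five indicator flags into the four variable groups."""
    flow = flags["q_min"] | flags["q_max"] | flags["q_zf"]
    temperature = flags["t_min"] | flags["t_max"]
    return pd.DataFrame(
        {
            "flow": flow,
            "temperature": temperature,
            "any": flow | temperature,
            "both": flow & temperature,
        },
        index=flags.index,
    )


def range_threatened(
    species_id: str,
    scenario_id: str,
    range_cells: frozenset[int],
    grouped: pd.DataFrame,
    grid: GridDefinition,
) -> dict[str, ExposureResult]:
    """RT% per variable group for one species under one scenario.

    ``grouped`` must carry group flags for (at least) every range cell.
    RT = 100 * AT / A with AT and A in km^2 from the grid's cell areas.
    """
    cells = np.array(sorted(range_cells), dtype=int)
    areas = grid.cell_area.ravel()[cells]
    a_total = float(areas.sum())
    sub = grouped.loc[cells]
    out: dict[str, ExposureResult] = {}
    for group in VARIABLE_GROUPS:
        hit = sub[group].to_numpy(bool)
        threatened = frozenset(int(c) for c in cells[hit])
        at = float(areas[hit].sum())
        out[group] = ExposureResult(
            species_id=species_id,
            scenario_id=scenario_id,
            variable_group=group,
            threatened_cells=threatened,
            at_km2=at,
            # AT <= A holds exactly; clamp float summation-order residue
            rt_percent=min(100.0 * at / a_total, 100.0),
        )
    return out


def exposure_table(results: list[ExposureResult], **extra) -> pd.DataFrame:
    """Long-format table of exposure results (one row per result)."""
    df = pd.DataFrame(
        {
            "species_id": [r.species_id for r in results],
            "scenario_id": [r.scenario_id for r in results],
            "variable_group": [r.variable_group for r in results],
            "at_km2": [r.at_km2 for r in results],
            "rt_percent": [r.rt_percent for r in results],
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df
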