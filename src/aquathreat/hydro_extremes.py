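"""Long-term weekly extreme indicators per grid cell.

From an N-year weekly hydrograph/thermograph the indicators are the
long-term means, over years, of the yearly minimum and maximum weekly
flow (Q_min, Q_max), the yearly count of zero-flow weeks (Q_zf), and the
yearly minimum and maximum weekly water temperature (T_min, T_max).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_world import GridDefinition, WeeklySeries

METRICS = ("q_min", "q_max", "q_zf", "t_min", "t_max")


@dataclass(frozen=True)
class ExtremeMetrics:
    """Extreme indicators for a single cell: flows in m^3/s, q_zf in
    weeks/year, temperatures in deg C."""

    q_min: float
    q_max: float
    q_zf: float
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if self.q_min > self.q_max or self.t_min > self.t_max:
            raise ValueError("min indicator exceeds max indicator")
        if self.q_min < 0 or self.q_zf < 0:
            raise ValueError("flow indicators must be non-negative")


def _check_finite(values: np.ndarray, label: str) -> None:
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        year, week = bad[0][-2], bad[0][-1]
        raise ValueError(
            f"non-finite {label} value at year {year}, week {week} "
            f"({bad.shape[0]} bad entries in total); gap-filling is not applied"
        )


def compute_cell_extremes(
    flow: np.ndarray,
    temp: np.ndarray,
    zero_flow_tolerance: float = 0.0,
) -> ExtremeMetrics:
    """Indicators for one cell from (n_years, weeks) flow and temperature.

    A week counts as zero-flow when its flow is <= ``zero_flow_tolerance``
    (default 0; a small positive tolerance accommodates floating-point
    routed flows that never reach exactly zero).
    """
    flow = np.asarray(flow, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if flow.shape != temp.shape:
        raise ValueError(f"flow shape {flow.shape} != temperature shape {temp.shape}")
    if flow.ndim != 2 or flow.shape[0] < 1:
        raise ValueError("series must be (n_years, weeks_per_year) with n_years >= 1")
    _check_finite(flow, "flow")
    _check_finite(temp, "temperature")

    return ExtremeMetrics(
        q_min=float(flow.min(axis=1).mean()),
        q_max=float(flow.max(axis=1).mean()),
        q_zf=float((flow <= zero_flow_tolerance).sum(axis=1).mean()),
        t_min=float(temp.min(axis=1).mean()),
        t_max=float(temp.max(axis=1).mean()),
    )


def compute_grid_extremes(
    grid: GridDefinition,
    flow_series: WeeklySeries,
    temp_series: WeeklySeries,
    scenario_id: str | None = None,
    zero_flow_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Indicator table for every valid cell, indexed by flat cell index.

    Columns: q_min, q_max, q_zf, t_min, t_max (+ scenario_id when given).
    Vectorised over cells; equivalent to :func:`compute_cell_extremes`
    applied cell by cell.
    """
    if flow_series.values.shape != temp_series.values.shape:
        raise ValueError("flow and temperature series must share the grid and window")
    if flow_series.values.shape[:2] != (grid.n_rows, grid.n_cols):
        missing = (grid.n_rows, grid.n_cols)
        raise ValueError(
            f"series cover {flow_series.values.shape[:2]} cells, grid expects {missing}"
        )
    valid = grid.valid_cells
    Rv, Cv = np.divmod(valid, grid.n_cols)
    flow = flow_series.values[Rv, Cv]       # (n_valid, N, M)
    temp = temp_series.values[Rv, Cv]
    _check_finite(flow, "flow")
    _check_finite(temp, "temperature")

    df = pd.DataFrame(
        {
            "q_min": flow.min(axis=2).mean(axis=1),
            "q_max": flow.max(axis=2).mean(axis=1),
            "q_zf": (flow <= zero_flow_tolerance).sum(axis=2).mean(axis=1),
            "t_min": temp.min(axis=2).mean(axis=1),
            "t_max": temp.max(axis=2).mean(axis=1),
        },
        index=pd.Index(valid, name="cell"),
    )
    if scenario_id is not None:
        df["scenario_id"] = scenario_id
    return df
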