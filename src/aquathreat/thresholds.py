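"""Species-specific tolerance thresholds from baseline extremes.

A species' tolerance window for each indicator is taken from the spatial
distribution of that indicator across its range cells in the baseline
period: the 2.5th percentile for the low-side indicators (minimum flow,
minimum temperature), the 97.5th percentile for the high-side ones
(maximum temperature, zero-flow weeks) — percentiles rather than
absolute extremes damp the influence of outlier cells — and the plain
within-range maximum for maximum flow, whose within-range distribution
is strongly right-skewed.

Two percentile conventions are offered.  The default, ``outer``, takes
the outer order statistic: the high threshold is the smallest
within-range value with at most 2.5% of the range (by weight) strictly
above it, and symmetrically for the low threshold.  This makes the
robustness property the percentiles exist for — at most 2.5% of the
range beyond the threshold at baseline — hold exactly for every range
size, which interpolated percentiles do not (e.g. two of fifty distinct
values lie strictly above their interpolated 97.5th percentile).
``linear`` interpolation between order statistics (Hyndman-Fan type 7,
the numpy/R default) is available for compatibility.  Cells are
unweighted by default; area weighting is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SpeciesThresholds:
    species_id: str
    q_min_thr: float   # m^3/s, 2.5th pct of within-range q_min
    q_max_thr: float   # m^3/s, max of within-range q_max
    q_zf_thr: float    # weeks/yr, 97.5th pct of within-range q_zf
    t_min_thr: float   # deg C, 2.5th pct of within-range t_min
    t_max_thr: float   # deg C, 97.5th pct of within-range t_max

    def __post_init__(self) -> None:
        vals = (self.q_min_thr, self.q_max_thr, self.q_zf_thr, self.t_min_thr, self.t_max_thr)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("thresholds must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "q_min_thr": self.q_min_thr,
                "q_max_thr": self.q_max_thr,
                "q_zf_thr": self.q_zf_thr,
                "t_min_thr": self.t_min_thr,
                "t_max_thr": self.t_max_thr,
            },
            name=self.species_id,
        )


def _weighted_percentile(values: np.ndarray, q: float, weights: np.ndarray) -> float:
    """Weighted percentile with linear interpolation on cumulative weight."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(q / 100.0, cum, v))


def _outer_quantile(values: np.ndarray, weights: np.ndarray, tail: float, side: str) -> float:
    """Outer order statistic: smallest value with at most ``tail`` of the
    total weight strictly above it (side="high"), or the mirror
    (side="low")."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    budget = tail * w.sum()
    if side == "high":
        # weight strictly above v[j]: sum of weights of values > v[j]
        for j in range(v.size):
            above = w[np.searchsorted(v, v[j], side="right"):].sum()
            if above <= budget:
                return float(v[j])
        return float(v[-1])
    for j in range(v.size - 1, -1, -1):
        below = w[: np.searchsorted(v, v[j], side="left")].sum()
        if below <= budget:
            return float(v[j])
    return float(v[0])


def derive_species_thresholds(
    species_id: str,
    range_cells: Iterable[int],
    baseline_extremes: pd.DataFrame,
    *,
    low_pct: float = 2.5,
    high_pct: float = 97.5,
    method: str = "outer",
    area_weights: pd.Series | None = None,
) -> SpeciesThresholds:
    """Thresholds for one species from its range's baseline indicators.

    ``baseline_extremes`` is the per-cell table from
    :func:`aquathreat.hydro_extremes.compute_grid_extremes` (indexed by
    flat cell index).  Every range cell must have a record.  For a
    single-cell range all thresholds collapse to that cell's values.
    ``method`` is ``outer`` (default, see module docstring) or
    ``linear``.
    """
    cells = np.array(sorted(range_cells), dtype=int)
    if cells.size == 0:
        raise ValueError(f"species {species_id}: empty range")
    missing = [int(c) for c in cells if c not in baseline_extremes.index]
    if missing:
        raise ValueError(f"species {species_id}: no baseline extremes for cells {missing}")
    sub = baseline_extremes.loc[cells]

    w = (
        area_weights.loc[cells].to_numpy(float)
        if area_weights is not None
        else np.ones(cells.size)
    )
    if method == "outer":
        lo = lambda col: _outer_quantile(sub[col].to_numpy(float), w, low_pct / 100.0, "low")
        hi = lambda col: _outer_quantile(
            sub[col].to_numpy(float), w, (100.0 - high_pct) / 100.0, "high"
        )
    elif method == "linear":
        if area_weights is not None:
            lo = lambda col: _weighted_percentile(sub[col].to_numpy(float), low_pct, w)
            hi = lambda col: _weighted_percentile(sub[col].to_numpy(float), high_pct, w)
        else:
            lo = lambda col: float(np.percentile(sub[col], low_pct))
            hi = lambda col: float(np.percentile(sub[col], high_pct))
    else:
        raise ValueError(f"unknown percentile method {method!r}")

    return SpeciesThresholds(
        species_id=species_id,
        q_min_thr=lo("q_min"),
        q_max_thr=float(sub["q_max"].max()),
        q_zf_thr=hi("q_zf"),
        t_min_thr=lo("t_min"),
        t_max_thr=hi("t_max"),
    )


def derive_all_thresholds(
    ranges: dict[str, frozenset[int]],
    baseline_extremes: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Threshold table for every species, indexed by species_id."""
    rows = [
        derive_species_thresholds(sp, cells, baseline_extremes, **kwargs).as_series()
        for sp, cells in sorted(ranges.items())
    ]
    out = pd.DataFrame(rows)
    out.index.name = "species_id"
    return out
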