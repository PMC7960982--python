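"""Synthetic world generator: grids, hydro-thermal series, ranges, traits, trees.

Every downstream stage of the threat-assessment pipeline is exercised on
worlds built here, with planted ground truth recorded in
:class:`SyntheticTruth`.  The generator emulates the structure of gridded
hydrological-model output (weekly streamflow and water temperature over a
multi-decade window), basin/ecoregion partitions, rasterized species
ranges, and a trait table tied to a phylogeny with a known regression
signal — not the physics or geography of any real dataset.

All randomness flows through :func:`numpy.random.default_rng` seeded
explicitly; identical seeds reproduce bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
import random as _pyrandom
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

logger = logging.getLogger(__name__)

BASELINE = 0.0
#: Warming levels (deg C above pre-industrial, 30-year mean) used throughout.
WARMING_LEVELS = (1.5, 2.0, 3.2, 4.5)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridDefinition:
    """A rectangular analysis grid with areas, basins and ecoregions.

    Cells are addressed by 0-based row-major flat indices.  ``basin_id``
    and ``ecoregion_id`` are -1 on invalid (non-river) cells.  Areas vary
    by row to mimic the latitude dependence of equal-angle grids.
    """

    n_rows: int
    n_cols: int
    cell_area: np.ndarray      # (n_rows, n_cols) km^2
    basin_id: np.ndarray       # (n_rows, n_cols) int, -1 outside valid_mask
    ecoregion_id: np.ndarray   # (n_rows, n_cols) int, -1 outside valid_mask
    valid_mask: np.ndarray     # (n_rows, n_cols) bool

    def __post_init__(self) -> None:
        shape = (self.n_rows, self.n_cols)
        for name in ("cell_area", "basin_id", "ecoregion_id", "valid_mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.cell_area[self.valid_mask] <= 0):
            raise ValueError("cell_area must be positive on valid cells")
        if np.any(self.basin_id[self.valid_mask] < 0):
            raise ValueError("every valid cell needs a basin_id")
        if np.any(self.ecoregion_id[self.valid_mask] < 0):
            raise ValueError("every valid cell needs an ecoregion_id")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def valid_cells(self) -> np.ndarray:
        """Flat indices of valid cells, ascending."""
        return np.flatnonzero(self.valid_mask.ravel())

    def area_of(self, cells: Sequence[int] | np.ndarray) -> float:
        """Total area (km^2) of the given flat cell indices."""
        return float(self.cell_area.ravel()[np.asarray(list(cells), dtype=int)].sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format cell table (one row per grid cell)."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        return pd.DataFrame(
            {
                "cell": np.arange(self.n_cells),
                "row": rows,
                "col": cols,
                "area_km2": self.cell_area.ravel(),
                "basin_id": self.basin_id.ravel(),
                "ecoregion_id": self.ecoregion_id.ravel(),
                "valid": self.valid_mask.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GridDefinition":
        n_rows = int(df["row"].max()) + 1
        n_cols = int(df["col"].max()) + 1
        df = df.sort_values("cell")
        shape = (n_rows, n_cols)
        return cls(
            n_rows=n_rows,
            n_cols=n_cols,
            cell_area=df["area_km2"].to_numpy(float).reshape(shape),
            basin_id=df["basin_id"].to_numpy(int).reshape(shape),
            ecoregion_id=df["ecoregion_id"].to_numpy(int).reshape(shape),
            valid_mask=df["valid"].to_numpy(bool).reshape(shape),
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """One ensemble member at one warming level.

    A member stands in for a GCM-RCP combination reaching the warming
    level in some future window.  ``temp_delta_field`` is an additive
    per-cell water-temperature offset (deg C); ``flow_scale_field`` is a
    multiplicative factor applied to low-season flow (drought-prone cells
    get factors < 1 under warming).  The baseline has zero deltas and
    unit scales.
    """

    scenario_id: str
    warming_level: float                 # 0.0 = baseline
    ensemble_member: int
    temp_delta_field: np.ndarray         # (n_rows, n_cols) deg C
    flow_scale_field: np.ndarray         # (n_rows, n_cols) unitless
    seed: int

    def __post_init__(self) -> None:
        if self.warming_level == BASELINE:
            if np.any(self.temp_delta_field != 0) or np.any(self.flow_scale_field != 1):
                raise ValueError("baseline scenario must have zero deltas and unit scales")
        elif np.any(self.temp_delta_field < 0):
            raise ValueError("temp_delta_field must be >= 0 for warming scenarios")

    @property
    def is_baseline(self) -> bool:
        return self.warming_level == BASELINE


@dataclass(frozen=True)
class WeeklySeries:
    """Weekly values for every grid cell over N years of M weeks.

    ``values`` has shape (n_rows, n_cols, n_years, weeks_per_year).
    Flow is m^3/s (non-negative); temperature is deg C.
    """

    values: np.ndarray
    variable: str                        # "flow" | "temperature"
    n_years: int
    weeks_per_year: int

    def __post_init__(self) -> None:
        if self.variable not in ("flow", "temperature"):
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.values.ndim != 4 or self.values.shape[2:] != (self.n_years, self.weeks_per_year):
            raise ValueError("values must be (rows, cols, n_years, weeks_per_year)")
        if self.n_years < 1 or self.weeks_per_year < 1:
            raise ValueError("need at least one year and one week")
        if self.variable == "flow" and np.any(self.values < 0):
            raise ValueError("flow must be non-negative")

    def cell(self, flat_index: int) -> np.ndarray:
        """(n_years, weeks_per_year) series for one flat cell index."""
        r, c = divmod(flat_index, self.values.shape[1])
        return self.values[r, c]


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators."""

    planted_rt: dict = field(default_factory=dict)         # (species, scenario) -> RT%
    regression_beta: dict = field(default_factory=dict)     # design column -> coefficient
    regression_lambda: float | None = None
    drought_cells: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Grid generation
# ---------------------------------------------------------------------------

def _neighbors(idx: int, n_rows: int, n_cols: int) -> list[int]:
    r, c = divmod(idx, n_cols)
    out = []
    if r > 0:
        out.append(idx - n_cols)
    if r < n_rows - 1:
        out.append(idx + n_cols)
    if c > 0:
        out.append(idx - 1)
    if c < n_cols - 1:
        out.append(idx + 1)
    return out


def generate_grid(
    n_rows: int,
    n_cols: int,
    n_basins: int,
    n_ecoregions: int,
    seed: int,
    *,
    base_area_km2: float = 100.0,
    valid_fraction: float = 1.0,
) -> GridDefinition:
    """Build a grid with connected basins and banded ecoregions.

    Basins are grown as connected components from random seed cells by
    multi-source breadth-first flooding, so they partition the valid
    cells exhaustively.  Ecoregions are contiguous horizontal bands, so
    each typically overlaps several basins (their intersection later
    yields sub-basin dispersal units).  Cell area shrinks with row index
    via a cosine latitude proxy, ``area(row) = A0 * cos(phi_row)`` with
    phi spanning [-60, 60] degrees.
    """
    n_cells_total = n_rows * n_cols
    rng = np.random.default_rng(seed)

    valid = np.ones(n_cells_total, dtype=bool)
    if valid_fraction < 1.0:
        n_invalid = int(round((1 - valid_fraction) * n_cells_total))
        invalid_idx = rng.choice(n_cells_total, size=n_invalid, replace=False)
        valid[invalid_idx] = False
    valid_idx = np.flatnonzero(valid)
    n_valid = valid_idx.size
    if n_basins < 1 or n_ecoregions < 1:
        raise ValueError("need at least one basin and one ecoregion")
    if n_basins > n_valid or n_ecoregions > n_rows:
        raise ValueError(
            f"impossible partition: {n_basins} basins / {n_ecoregions} ecoregions "
            f"do not fit a grid with {n_valid} valid cells and {n_rows} rows"
        )

    # Multi-source BFS flood fill from random seeds -> connected basins.
    basin = np.full(n_cells_total, -1, dtype=int)
    seeds = rng.choice(valid_idx, size=n_basins, replace=False)
    frontier: list[int] = []
    for b, s in enumerate(seeds):
        basin[s] = b
        frontier.append(int(s))
    head = 0
    while head < len(frontier):
        cur = frontier[head]
        head += 1
        for nb in _neighbors(cur, n_rows, n_cols):
            if valid[nb] and basin[nb] == -1:
                basin[nb] = basin[cur]
                frontier.append(nb)
    # Valid cells unreachable from any seed (isolated pockets) get their own
    # connected labels so the partition stays exhaustive and connected.
    next_label = n_basins
    for idx in valid_idx:
        if basin[idx] == -1:
            stack = [int(idx)]
            basin[idx] = next_label
            while stack:
                cur = stack.pop()
                for nb in _neighbors(cur, n_rows, n_cols):
                    if valid[nb] and basin[nb] == -1:
                        basin[nb] = next_label
                        stack.append(nb)
            next_label += 1

    # Ecoregions: contiguous row bands of near-equal height.
    row_of = np.arange(n_cells_total) // n_cols
    band_edges = np.linspace(0, n_rows, n_ecoregions + 1)
    ecoregion = np.searchsorted(band_edges, row_of, side="right") - 1
    ecoregion = np.clip(ecoregion, 0, n_ecoregions - 1)
    ecoregion[~valid] = -1
    basin[~valid] = -1

    lat = np.linspace(-60.0, 60.0, n_rows) if n_rows > 1 else np.array([0.0])
    area_row = base_area_km2 * np.cos(np.radians(lat))
    area = np.repeat(area_row, n_cols)

    shape = (n_rows, n_cols)
    return GridDefinition(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_area=area.reshape(shape),
        basin_id=basin.reshape(shape),
        ecoregion_id=ecoregion.reshape(shape),
        valid_mask=valid.reshape(shape),
    )


# ---------------------------------------------------------------------------
# Scenario families
# ---------------------------------------------------------------------------

def baseline_scenario(grid: GridDefinition, seed: int = 0) -> ScenarioSpec:
    """The historical reference: zero deltas, unit flow scales."""
    shape = (grid.n_rows, grid.n_cols)
    return ScenarioSpec(
        scenario_id="baseline",
        warming_level=BASELINE,
        ensemble_member=0,
        temp_delta_field=np.zeros(shape),
        flow_scale_field=np.ones(shape),
        seed=seed,
    )


def generate_scenarios(
    grid: GridDefinition,
    seed: int,
    *,
    warming_levels: Sequence[float] = WARMING_LEVELS,
    members_per_level: int = 3,
    drought_fraction: float = 0.2,
    temp_jitter_sd: float = 0.15,
    flow_depression_per_degree: float = 0.12,
) -> tuple[list[ScenarioSpec], set[int]]:
    """Scenario ensemble: per warming level, several jittered members.

    Each ensemble member gets one multiplicative per-cell jitter field
    (1 + N(0, temp_jitter_sd), floored at 0) drawn once and shared
    across warming levels; its temperature delta is the warming level
    times that field.  A member's scenarios are therefore cell-wise
    nested in warming level.  A fixed random subset of cells
    (``drought_fraction``) is drought-prone: their low-season flow is
    scaled by ``1 - flow_depression_per_degree * warming`` (floored at
    0.05), also monotone in warming.  Returns the scenarios (baseline
    first) and the drought-cell flat-index set.
    """
    rng = np.random.default_rng(seed)
    shape = (grid.n_rows, grid.n_cols)
    valid_idx = grid.valid_cells
    n_drought = int(round(drought_fraction * valid_idx.size))
    drought_cells = set(
        int(i) for i in rng.choice(valid_idx, size=n_drought, replace=False)
    )
    drought_mask = np.zeros(grid.n_cells, dtype=bool)
    drought_mask[list(drought_cells)] = True
    drought_mask = drought_mask.reshape(shape)

    scenarios: list[ScenarioSpec] = [baseline_scenario(grid, seed=seed)]
    member_seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(members_per_level)]
    member_fields = [
        np.clip(
            1.0 + np.random.default_rng(s).normal(0.0, temp_jitter_sd, size=shape), 0.0, None
        )
        for s in member_seeds
    ]
    for level in warming_levels:
        for member in range(members_per_level):
            member_seed = member_seeds[member]
            delta = level * member_fields[member]
            delta[~grid.valid_mask] = 0.0
            scale = np.ones(shape)
            depress = max(0.05, 1.0 - flow_depression_per_degree * level)
            scale[drought_mask] = depress
            scenarios.append(
                ScenarioSpec(
                    scenario_id=f"w{level:g}_m{member}",
                    warming_level=level,
                    ensemble_member=member,
                    temp_delta_field=delta,
                    flow_scale_field=scale,
                    seed=member_seed,
                )
            )
    return scenarios, drought_cells


# ---------------------------------------------------------------------------
# Weekly series
# ---------------------------------------------------------------------------

def generate_weekly_series(
    grid: GridDefinition,
    scenario: ScenarioSpec,
    *,
    n_years: int = 30,
    weeks_per_year: int = 52,
    base_temp: float = 15.0,
    temp_amplitude: float = 8.0,
    base_flow: float = 20.0,
    flow_amplitude: float = 15.0,
    noise_sd: float = 0.5,
    ar1_coef: float = 0.3,
    zero_flow_prob: float = 0.0,
    intermittent_mask: np.ndarray | None = None,
    temp_gradient: float = 10.0,
    seed: int = 0,
) -> tuple[WeeklySeries, WeeklySeries]:
    """Seasonal weekly flow and temperature series under one scenario.

    Temperature: row-dependent mean (warmer toward the low-latitude
    middle rows, controlled by ``temp_gradient``) + seasonal sinusoid of
    amplitude ``temp_amplitude`` + per-cell AR(1) interannual anomalies
    (coefficient ``ar1_coef``, innovation sd ``noise_sd``) + the
    scenario's ``temp_delta_field``.

    Flow: seasonal sinusoid around ``base_flow`` with the same AR(1)
    anomaly machinery (scaled to flow units), clipped at zero.  In weeks
    whose seasonal component is negative (the low season) flow is
    multiplied by the scenario's ``flow_scale_field``.  Cells flagged in
    ``intermittent_mask`` (default: all cells) have weeks zeroed
    independently with probability ``zero_flow_prob``.

    The noise realisation depends only on ``seed``, never on the scenario
    fields, so two scenarios sharing a seed differ exactly by their
    deltas and scales.
    """
    if base_flow < 0:
        raise ValueError("base_flow must be non-negative")
    if temp_amplitude < 0 or flow_amplitude < 0:
        raise ValueError("amplitudes must be non-negative")
    if not 0.0 <= zero_flow_prob < 1.0:
        raise ValueError("zero_flow_prob must lie in [0, 1)")

    R, C, N, M = grid.n_rows, grid.n_cols, n_years, weeks_per_year
    rng = np.random.default_rng(seed)

    week_phase = np.sin(2 * np.pi * np.arange(M) / M)      # (M,)
    lat_proxy = (
        np.cos(np.linspace(-np.pi / 3, np.pi / 3, R)) if R > 1 else np.ones(1)
    )
    temp_mean_row = base_temp + temp_gradient * (lat_proxy - lat_proxy.mean())

    # AR(1) interannual anomaly per cell, constant within a year.
    innov = rng.normal(0.0, noise_sd, size=(R, C, N)) if noise_sd > 0 else np.zeros((R, C, N))
    anomaly = np.empty((R, C, N))
    anomaly[..., 0] = innov[..., 0]
    for y in range(1, N):
        anomaly[..., y] = ar1_coef * anomaly[..., y - 1] + innov[..., y]

    temp = (
        temp_mean_row[:, None, None, None]
        + temp_amplitude * week_phase[None, None, None, :]
        + anomaly[..., None]
        + scenario.temp_delta_field[:, :, None, None]
    )

    seasonal_flow = flow_amplitude * week_phase                     # (M,)
    # flow shares the AR(1) anomaly (same units, m^3/s per deg C of anomaly)
    flow = base_flow + seasonal_flow[None, None, None, :] + anomaly[..., None]
    low_season = seasonal_flow < 0                                   # (M,)
    scale = np.where(
        low_season[None, None, None, :],
        scenario.flow_scale_field[:, :, None, None],
        1.0,
    )
    flow = np.clip(flow * scale, 0.0, None)

    if zero_flow_prob > 0:
        zero_draw = rng.random(size=(R, C, N, M)) < zero_flow_prob
        if intermittent_mask is not None:
            zero_draw &= intermittent_mask[:, :, None, None]
        flow = np.where(zero_draw, 0.0, flow)

    return (
        WeeklySeries(values=flow, variable="flow", n_years=N, weeks_per_year=M),
        WeeklySeries(values=temp, variable="temperature", n_years=N, weeks_per_year=M),
    )


# ---------------------------------------------------------------------------
# Species ranges
# ---------------------------------------------------------------------------

def generate_species_ranges(
    grid: GridDefinition,
    n_species: int,
    size_distribution: Callable[[np.random.Generator], int] | Sequence[int] | None = None,
    seed: int = 0,
    *,
    allow_multi_basin: bool = False,
) -> dict[str, frozenset[int]]:
    """Connected random ranges, one per species, each within a single basin.

    Sizes come from ``size_distribution`` — either a sequence of target
    sizes (one per species) or a callable drawing a size from the rng;
    the default draws lognormal sizes with median ~15 cells.  A range is
    grown by seeded random breadth-first accretion from a random start
    cell.  Ranges larger than their basin are truncated to the basin
    with a logged warning (or allowed to spill into adjacent basins if
    ``allow_multi_basin``).
    """
    rng = np.random.default_rng(seed)
    if size_distribution is None:
        def size_distribution(r: np.random.Generator) -> int:  # type: ignore[misc]
            return max(1, int(round(r.lognormal(mean=math.log(15), sigma=0.6))))

    if callable(size_distribution):
        sizes = [size_distribution(rng) for _ in range(n_species)]
    else:
        sizes = [int(s) for s in size_distribution]
        if len(sizes) != n_species:
            raise ValueError("size_distribution sequence length must equal n_species")
    if any(s < 1 for s in sizes):
        raise ValueError("range sizes must be >= 1 cell")

    basin_flat = grid.basin_id.ravel()
    valid_idx = grid.valid_cells
    ranges: dict[str, frozenset[int]] = {}
    for k, target in enumerate(sizes):
        start = int(rng.choice(valid_idx))
        home_basin = basin_flat[start]
        members = {start}
        frontier = [start]
        while len(members) < target and frontier:
            # random-order BFS accretion keeps the range connected
            pick = int(rng.integers(len(frontier)))
            cur = frontier.pop(pick)
            nbs = _neighbors(cur, grid.n_rows, grid.n_cols)
            rng.shuffle(nbs)
            for nb in nbs:
                if len(members) >= target:
                    break
                if nb in members or not grid.valid_mask.ravel()[nb]:
                    continue
                if not allow_multi_basin and basin_flat[nb] != home_basin:
                    continue
                members.add(nb)
                frontier.append(nb)
        if len(members) < target:
            logger.warning(
                "species sp%04d: requested %d cells, basin %d allows only %d; truncated",
                k, target, home_basin, len(members),
            )
        ranges[f"sp{k:04d}"] = frozenset(members)
    return ranges


# ---------------------------------------------------------------------------
# Traits and tree
# ---------------------------------------------------------------------------

#: Categorical covariates with their levels and sampling weights.
TRAIT_CATEGORIES: Mapping[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "climate_zone": (("A", "B", "C", "D", "E"), (0.35, 0.15, 0.25, 0.2, 0.05)),
    "habitat_type": (
        ("lotic", "lotic-lentic", "lotic-marine", "lentic"),
        (0.5, 0.3, 0.1, 0.1),
    ),
    "trophic_group": (("Carnivore", "Omnivore", "Herbivore"), (0.5, 0.35, 0.15)),
    "iucn_category": (("LC", "NT", "VU", "EN", "CR", "DD"), (0.55, 0.1, 0.1, 0.07, 0.03, 0.15)),
    "commercial_importance": (
        ("none", "minor", "commercial", "highly"),
        (0.55, 0.25, 0.15, 0.05),
    ),
}

CONTINUOUS_COVARIATES = ("log10_range_km2", "log10_body_length_cm")


def _shared_branch_matrix(tree: dendropy.Tree, taxa: Sequence[str]) -> np.ndarray:
    """Phylogenetic covariance C: shared root-to-MRCA branch length per pair.

    Accumulated edge-by-edge: every edge of length l adds l to C[i, j]
    for all tip pairs (i, j) below it, giving C_ii = root-to-tip depth.
    The root's own edge, shared by every tip, is excluded (the standard
    convention of comparative methods).
    """
    order = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    leafsets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in order:
                continue
            idx = np.array([order[label]], dtype=int)
        else:
            parts = [leafsets[id(ch)] for ch in node.child_nodes() if id(ch) in leafsets]
            idx = np.concatenate(parts) if parts else np.array([], dtype=int)
        leafsets[id(node)] = idx
        length = node.edge.length or 0.0
        if length and idx.size and node.parent_node is not None:
            C[np.ix_(idx, idx)] += length
    return C


def simulate_tree(species_ids: Sequence[str], seed: int) -> dendropy.Tree:
    """Ultrametric pure-birth tree over the species, depth normalised to 1.

    Terminal edges are extended by a small epsilon before rescaling so
    every branch length is strictly positive even when the simulation
    stops exactly at a speciation event.
    """
    n = len(species_ids)
    pyrng = _pyrandom.Random(seed)
    taxa = dendropy.TaxonNamespace([str(s) for s in species_ids])
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n,
        taxon_namespace=taxa,
        rng=pyrng,
    )
    eps = 1e-3
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + eps
    depth = max(l.distance_from_root() for l in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    # bind taxa to tips in simulation order
    labels = [str(s) for s in species_ids]
    for leaf, label in zip(tree.leaf_node_iter(), labels):
        leaf.taxon = taxa.get_taxon(label)
    return tree


def pagel_covariance(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonals scaled by lambda."""
    return lam * (C - np.diag(np.diag(C))) + np.diag(np.diag(C))


def generate_traits_and_tree(
    species_ids: Sequence[str],
    beta: Mapping[str, float],
    lam: float,
    noise_sd: float,
    seed: int,
    *,
    range_sizes_km2: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dendropy.Tree, SyntheticTruth]:
    """Trait table + ultrametric tree with a planted regression signal.

    The response is ``X beta + eps`` with ``eps ~ N(0, noise_sd^2 V)``
    and ``V = lambda * (C - diag C) + diag C`` the Pagel-lambda
    transform of the tree's shared-branch-length matrix C.  ``beta``
    keys name design columns (``intercept``, a continuous covariate, or
    ``"<covariate>[<level>]"`` for a categorical level effect);
    unnamed columns get coefficient 0.  If ``range_sizes_km2`` is given
    (e.g. actual synthetic range areas) it overrides the sampled
    range-size covariate.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n = len(species_ids)
    rng = np.random.default_rng(seed)

    traits = pd.DataFrame({"species_id": [str(s) for s in species_ids]})
    if range_sizes_km2 is not None:
        traits["range_size_km2"] = [float(range_sizes_km2[s]) for s in traits["species_id"]]
    else:
        traits["range_size_km2"] = 10 ** rng.normal(3.0, 0.8, size=n)
    traits["body_length_cm"] = 10 ** rng.normal(1.2, 0.35, size=n)
    traits["trophic_level"] = rng.uniform(1.5, 4.0, size=n)
    for cov, (levels, weights) in TRAIT_CATEGORIES.items():
        if cov == "trophic_group":
            continue  # derived from trophic_level downstream; sampled here too
        traits[cov] = rng.choice(levels, size=n, p=np.asarray(weights) / np.sum(weights))
    from .phylo_traits import classify_trophic  # deferred: avoids import cycle

    traits["trophic_group"] = [classify_trophic(t) for t in traits["trophic_level"]]
    traits["log10_range_km2"] = np.log10(traits["range_size_km2"])
    traits["log10_body_length_cm"] = np.log10(traits["body_length_cm"])

    tree = simulate_tree(traits["species_id"].tolist(), seed=seed + 1)
    C = _shared_branch_matrix(tree, traits["species_id"].tolist())

    from .phylo_traits import build_design

    X, colnames, _ = build_design(traits, covariates=None)
    beta_vec = np.array([float(beta.get(c, 0.0)) for c in colnames])
    mean = X @ beta_vec
    if noise_sd > 0:
        V = pagel_covariance(C, lam)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        eps = noise_sd * (L @ rng.standard_normal(n))
    else:
        eps = np.zeros(n)
    traits["response"] = mean + eps

    truth = SyntheticTruth(
        regression_beta={c: float(b) for c, b in zip(colnames, beta_vec)},
        regression_lambda=float(lam),
    )
    return traits, tree, truth


# ---------------------------------------------------------------------------
# Exact threat planting
# ---------------------------------------------------------------------------

def _subset_with_area(
    cells: Sequence[int], areas: np.ndarray, target_area: float, tol: float
) -> list[int] | None:
    """A subset of cells whose summed area hits target_area within tol.

    Greedy largest-first, falling back to exhaustive search for small
    ranges (<= 22 cells).
    """
    order = sorted(cells, key=lambda c: -areas[c])
    chosen: list[int] = []
    acc = 0.0
    for c in order:
        if acc + areas[c] <= target_area + tol:
            chosen.append(c)
            acc += areas[c]
    if abs(acc - target_area) <= tol:
        return chosen
    if len(cells) <= 22:
        for k in range(len(cells) + 1):
            for combo in combinations(cells, k):
                if abs(sum(areas[c] for c in combo) - target_area) <= tol:
                    return list(combo)
    return None


def plant_exact_threat(
    grid: GridDefinition,
    baseline_flow: WeeklySeries,
    baseline_temp: WeeklySeries,
    species_range: frozenset[int] | set[int],
    target_rt_percent: float,
    *,
    scenario_id: str = "planted",
    warming_level: float = 3.2,
    margin: float = 3.0,
    rel_tol: float = 1e-9,
) -> ScenarioSpec:
    """A scenario whose temperature deltas threaten exactly the target RT%.

    Picks a subset of range cells whose area fraction equals
    ``target_rt_percent`` and raises their temperature far enough above
    the species' maximum-temperature threshold (derived from the same
    baseline) that exactly those cells — and no others — exceed it.
    Requires a baseline in which no range cell exceeds any threshold
    (e.g. noise-free, spatially uniform temperature within the range);
    otherwise the planted fraction would not be exact and the call is
    rejected.  Targets not achievable as a cell-subset area fraction are
    rejected with the achievable fractions listed.
    """
    from .exposure import flag_cell_exceedance
    from .hydro_extremes import compute_grid_extremes
    from .thresholds import derive_species_thresholds

    if not 0.0 <= target_rt_percent <= 100.0:
        raise ValueError("target RT must be in [0, 100]")

    cells = sorted(species_range)
    areas = grid.cell_area.ravel()
    total = float(areas[cells].sum())

    base_extremes = compute_grid_extremes(grid, baseline_flow, baseline_temp, scenario_id="baseline")
    thr = derive_species_thresholds("planted", species_range, base_extremes)
    base_flags = flag_cell_exceedance(base_extremes.loc[cells], thr)
    if base_flags.to_numpy().any():
        raise ValueError(
            "baseline already exceeds thresholds within the range; "
            "exact planting requires an exceedance-free baseline"
        )

    if target_rt_percent == 0.0:
        return baseline_scenario(grid, seed=0)

    target_area = target_rt_percent / 100.0 * total
    tol = max(rel_tol * total, 1e-9)
    chosen = _subset_with_area(cells, areas, target_area, tol)
    if chosen is None:
        achievable = sorted(
            {
                round(100.0 * sum(areas[c] for c in combo) / total, 6)
                for k in range(min(len(cells), 12) + 1)
                for combo in combinations(cells[:12], k)
            }
        )
        raise ValueError(
            f"target RT {target_rt_percent}% is not a cell-subset area fraction; "
            f"achievable (first cells): {achievable}"
        )

    delta = np.zeros((grid.n_rows, grid.n_cols))
    t_max_cell = base_extremes["t_max"]
    for c in chosen:
        delta.ravel()[c] = max(thr.t_max_thr - float(t_max_cell.loc[c]), 0.0) + margin
    return ScenarioSpec(
        scenario_id=scenario_id,
        warming_level=warming_level,
        ensemble_member=0,
        temp_delta_field=delta,
        flow_scale_field=np.ones((grid.n_rows, grid.n_cols)),
        seed=0,
    )
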