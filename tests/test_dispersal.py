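"""Sub-basin units, range expansion, and the maximal-dispersal metric."""

import numpy as np
import pandas as pd
import pytest

from aquathreat import synthetic_world as world
from aquathreat.dispersal import (
    ExpandedRange,
    delineate_subbasins,
    expand_range,
    range_threatened_maximal,
)
from aquathreat.exposure import flag_cell_exceedance, group_flags, range_threatened
from aquathreat.hydro_extremes import compute_grid_extremes
from aquathreat.thresholds import SpeciesThresholds, derive_species_thresholds

from conftest import uniform_grid


def test_single_basin_single_ecoregion_is_one_unit():
    g = uniform_grid(3, 3)
    units = delineate_subbasins(g, min_unit_area=0.0)
    assert units.n_units == 1
    assert units.unit_area.iloc[0] == pytest.approx(9.0)


def test_two_by_two_block_arrangement_gives_four_units():
    basin = np.zeros((4, 4), dtype=int)
    basin[:, 2:] = 1
    eco = np.zeros((4, 4), dtype=int)
    eco[2:, :] = 1
    g = uniform_grid(4, 4, basin_map=basin, ecoregion_map=eco)
    units = delineate_subbasins(g, min_unit_area=0.0)
    assert units.n_units == 4
    assert units.unit_area.sum() == pytest.approx(16.0)


def brute_force_merge(grid, min_area):
    """Reference merge simulator: same rules, independent bookkeeping."""
    from aquathreat.dispersal import _boundary_lengths, _connected_components

    key = grid.basin_id.ravel() * (grid.ecoregion_id.max() + 2) + grid.ecoregion_id.ravel()
    labels = _connected_components(grid, key).copy()
    areas_flat = grid.cell_area.ravel()
    while True:
        areas = {}
        for cell in np.flatnonzero(labels >= 0):
            areas[labels[cell]] = areas.get(labels[cell], 0.0) + areas_flat[cell]
        shared = _boundary_lengths(grid, labels)
        nbrs = {}
        for (a, b), ln in shared.items():
            nbrs.setdefault(a, {})[b] = ln
            nbrs.setdefault(b, {})[a] = ln
        small = sorted(
            [u for u in areas if areas[u] < min_area and u in nbrs and nbrs[u]],
            key=lambda u: (areas[u], u),
        )
        if not small:
            return labels, areas
        u = small[0]
        target = sorted(nbrs[u], key=lambda v: (-nbrs[u][v], -areas[v], v))[0]
        labels[labels == u] = target


def test_small_unit_merges_into_large_neighbor():
    # left strip 2 cells (~200 km^2) beside a 5,000 km^2 block
    basin = np.zeros((2, 6), dtype=int)
    basin[:, 0] = 1
    g = uniform_grid(2, 6, area=500.0, basin_map=basin)
    units = delineate_subbasins(g, min_unit_area=1000.0)
    # the 2-cell basin strip (1000 km2 at 500 each) is exactly at the limit;
    # shrink areas to force the merge
    g2 = uniform_grid(2, 6, area=100.0, basin_map=basin)
    units2 = delineate_subbasins(g2, min_unit_area=1000.0)
    assert units2.n_units == 1
    labels, areas = brute_force_merge(g2, 1000.0)
    assert len(set(labels)) == 1
    assert units.unit_area.sum() == pytest.approx(g.cell_area.sum())


def test_merge_matches_brute_force_simulator_on_random_grids():
    for seed in range(10):
        g = world.generate_grid(8, 8, 3, 3, seed=seed, base_area_km2=400.0)
        units = delineate_subbasins(g, min_unit_area=1500.0)
        labels, areas = brute_force_merge(g, 1500.0)
        # same partition up to relabelling
        ours = {}
        for cell in np.flatnonzero(units.unit_id >= 0):
            ours.setdefault(units.unit_id[cell], set()).add(cell)
        theirs = {}
        for cell in np.flatnonzero(labels >= 0):
            theirs.setdefault(labels[cell], set()).add(cell)
        assert sorted(map(sorted, ours.values())) == sorted(map(sorted, theirs.values()))
        assert units.unit_area.sum() == pytest.approx(g.cell_area[g.valid_mask].sum())


def _baseline_world(n_cols=12):
    g = uniform_grid(1, n_cols)
    scen = world.baseline_scenario(g)
    flow, temp = world.generate_weekly_series(
        g, scen, n_years=5, noise_sd=0.0, temp_gradient=0.0, zero_flow_prob=0.0, seed=0
    )
    return g, compute_grid_extremes(g, flow, temp)


def test_expansion_adds_all_identical_condition_cells():
    g, base = _baseline_world()
    units = delineate_subbasins(g, min_unit_area=0.0)
    rng_cells = frozenset({0, 1, 2})
    thr = derive_species_thresholds("sp", rng_cells, base)
    exp = expand_range("sp", rng_cells, units, base, thr, g)
    assert exp.expanded_cells == frozenset(range(3, 12))
    assert exp.ae_km2 == pytest.approx(9.0)


def test_unsuitable_candidate_not_added():
    g, base = _baseline_world()
    units = delineate_subbasins(g, min_unit_area=0.0)
    rng_cells = frozenset({0, 1, 2})
    base = base.copy()
    base.loc[7, "t_max"] += 10.0  # cell 7 hotter than the range has ever been
    thr = derive_species_thresholds("sp", rng_cells, base)
    exp = expand_range("sp", rng_cells, units, base, thr, g)
    assert 7 not in exp.expanded_cells
    assert exp.expanded_cells == frozenset(range(3, 12)) - {7}


def test_expansion_matches_cell_by_cell_exceedance_oracle():
    rng = np.random.default_rng(0)
    g = uniform_grid(1, 23)
    units = delineate_subbasins(g, min_unit_area=0.0)
    base = pd.DataFrame(
        {
            "q_min": rng.uniform(1, 5, 23), "q_max": rng.uniform(5, 15, 23),
            "q_zf": rng.uniform(0, 2, 23), "t_min": rng.uniform(2, 8, 23),
            "t_max": rng.uniform(20, 30, 23),
        },
        index=pd.Index(range(23), name="cell"),
    )
    rng_cells = frozenset(range(3))
    thr = derive_species_thresholds("sp", rng_cells, base)
    exp = expand_range("sp", rng_cells, units, base, thr, g)
    for cand in range(3, 23):
        flags = flag_cell_exceedance(base.loc[[cand]], thr)
        assert (cand in exp.expanded_cells) == (not flags.to_numpy().any())


def _flags(n, threatened):
    g = pd.DataFrame(
        {k: [False] * n for k in ("flow", "temperature", "any", "both")},
        index=pd.Index(range(n), name="cell"),
    )
    for c in threatened:
        g.loc[c, ["temperature", "any"]] = True
    return g


def test_eq7_arithmetic_with_expansion():
    # A=100 (cells 0-9 at 10 km2), AE=50 (cells 10-14), AT=20, AET=10
    g = uniform_grid(1, 15, area=10.0)
    exp = ExpandedRange(
        species_id="sp", original_cells=frozenset(range(10)),
        expanded_cells=frozenset(range(10, 15)), ae_km2=50.0,
    )
    flags = _flags(15, [0, 1, 10])  # 20 km2 original + 10 km2 expanded threatened
    res = range_threatened_maximal(exp, "s", flags, g)
    assert res["temperature"].rt_percent == pytest.approx(20.0 / 140.0 * 100.0)


def test_eq7_reduces_to_eq6_when_no_expansion_or_all_expansion_threatened():
    g = uniform_grid(1, 15, area=10.0)
    orig = frozenset(range(10))
    flags = _flags(15, [0, 1, 2])
    no_exp = ExpandedRange("sp", orig, frozenset(), 0.0)
    res0 = range_threatened_maximal(no_exp, "s", flags, g)
    res_nodisp = range_threatened("sp", "s", orig, flags, g)
    assert res0["any"].rt_percent == pytest.approx(res_nodisp["any"].rt_percent)
    # entire expansion threatened: denominator collapses to A
    exp = ExpandedRange("sp", orig, frozenset(range(10, 15)), 50.0)
    flags_all = _flags(15, [0, 1, 2, 10, 11, 12, 13, 14])
    res1 = range_threatened_maximal(exp, "s", flags_all, g)
    assert res1["any"].rt_percent == pytest.approx(res_nodisp["any"].rt_percent)


def test_maximal_rt_never_exceeds_no_dispersal_rt_on_random_worlds():
    rng = np.random.default_rng(5)
    comparisons = 0
    for seed in range(6):
        g = world.generate_grid(10, 10, 3, 2, seed=seed, base_area_km2=50.0)
        units = delineate_subbasins(g, min_unit_area=0.0)
        n_valid = g.n_cells
        base = pd.DataFrame(
            {
                "q_min": rng.uniform(1, 5, n_valid), "q_max": rng.uniform(5, 15, n_valid),
                "q_zf": rng.uniform(0, 2, n_valid), "t_min": rng.uniform(2, 8, n_valid),
                "t_max": rng.uniform(20, 30, n_valid),
            },
            index=pd.Index(range(n_valid), name="cell"),
        )
        ranges = world.generate_species_ranges(g, 12, seed=seed + 50)
        for scen in range(4):
            future = base.copy()
            future["t_max"] += rng.uniform(0, 4, n_valid)
            future["q_min"] -= rng.uniform(0, 2, n_valid)
            for sp, cells in ranges.items():
                thr = derive_species_thresholds(sp, cells, base)
                exp = expand_range(sp, cells, units, base, thr, g)
                universe = sorted(cells | exp.expanded_cells)
                grouped = group_flags(flag_cell_exceedance(future.loc[universe], thr))
                res_none = range_threatened(sp, "s", frozenset(cells), grouped, g)
                res_max = range_threatened_maximal(exp, "s", grouped, g)
                for group in ("flow", "temperature", "any", "both"):
                    assert (
                        res_max[group].rt_percent
                        <= res_none[group].rt_percent + 1e-9
                    )
                    comparisons += 1
    assert comparisons >= 1000


def test_expansion_confined_to_touched_units():
    basin = np.zeros((4, 8), dtype=int)
    basin[:, 4:] = 1
    g = uniform_grid(4, 8, basin_map=basin)
    units = delineate_subbasins(g, min_unit_area=0.0)
    base = pd.DataFrame(
        {
            "q_min": 1.0, "q_max": 5.0, "q_zf": 0.0, "t_min": 5.0, "t_max": 20.0,
        },
        index=pd.Index(range(32), name="cell"),
    )
    rng_cells = frozenset({0, 1})  # entirely in basin 0
    thr = derive_species_thresholds("sp", rng_cells, base)
    exp = expand_range("sp", rng_cells, units, base, thr, g)
    basin_flat = g.basin_id.ravel()
    assert all(basin_flat[c] == 0 for c in exp.expanded_cells)
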