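"""Shared fixtures: one small synthetic world reused across test modules.

Everything is generated programmatically at test time with fixed seeds;
session scope keeps the suite fast.
"""

import pytest

import droughtmort as dm


@pytest.fixture(scope="session")
def grid_spec():
    return dm.GridSpec(n_lat=4, n_lon=4)


@pytest.fixture(scope="session")
def climate(grid_spec):
    return dm.generate_climate(grid_spec, years=45, seed=7)


@pytest.fixture(scope="session")
def spei_grid(climate):
    return dm.spei_pipeline(climate)


@pytest.fixture(scope="session")
def cohort(climate, spei_grid):
    """Survey under the default ground-truth process (60 x 25 children)."""
    dgp = dm.DGPParams(seed=11)
    clusters, children, assets = dm.generate_survey(
        60, 25, climate, spei_grid, dgp
    )
    wq = dm.wealth_index(assets)
    children = children.merge(
        wq[["household_id", "wealth_quintile"]], on="household_id", how="left"
    )
    return {"clusters": clusters, "children": children, "assets": assets,
            "dgp": dgp}


@pytest.fixture(scope="session")
def person_months(cohort, spei_grid, climate):
    return dm.build_person_months(
        cohort["children"], cohort["clusters"], spei_grid,
        severity_mode="any", climate=climate,
    )


@pytest.fixture(scope="session")
def person_months_strat(cohort, spei_grid):
    return dm.build_person_months(
        cohort["children"], cohort["clusters"], spei_grid,
        severity_mode="stratified",
    )


def survey_factory(climate, spei_grid, n_clusters, children_per_cluster, dgp):
    """Regenerate a survey on the shared climate with given DGP params."""
    clusters, children, assets = dm.generate_survey(
        n_clusters, children_per_cluster, climate, spei_grid, dgp
    )
    wq = dm.wealth_index(assets)
    children = children.merge(
        wq[["household_id", "wealth_quintile"]], on="household_id", how="left"
    )
    return clusters, children
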