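"""Shared fixtures: maps, population panels and simulation tables.

Heavy reference tables are session-scoped so the acceptance-style tests
share a single set of simulations.  Problem sizes are desk-scale choices
(see docs/methods.md): 80 simulations per scenario on the default 24x18
map for model choice and the diversity gradient, and 300 Overlapping
simulations on the 12x9 map for posterior-estimation checks.
"""

from __future__ import annotations

import numpy as np
import pytest

import routesim as rs
from routesim.inference import ReferenceTable
from routesim.pipeline import pooled_reference_table, simulate_reference_table


@pytest.fixture(scope="session")
def small_map():
    return rs.build_map(rs.SMALL_MAP_CONFIG)


@pytest.fixture(scope="session")
def default_map():
    return rs.build_map(rs.DEFAULT_MAP_CONFIG)


@pytest.fixture(scope="session")
def small_sites(small_map):
    return rs.default_sample_spec(small_map)


@pytest.fixture(scope="session")
def default_sites(default_map):
    return rs.default_sample_spec(default_map)


@pytest.fixture(scope="session")
def pooled_default_table(default_map, default_sites):
    """Pooled three-scenario table on the default map (80 per scenario)."""
    tables = [
        simulate_reference_table(
            default_map, default_sites, scen, 80, seed=20260901 + i
        )
        for i, scen in enumerate(("southern", "pincer", "overlapping"))
    ]
    return pooled_reference_table(tables)


@pytest.fixture(scope="session")
def southern_table(pooled_default_table):
    df = pooled_default_table.table
    sub = df[df["model"] == "southern"].reset_index(drop=True)
    return ReferenceTable(
        sub, pooled_default_table.param_names, pooled_default_table.stat_names
    )


@pytest.fixture(scope="session")
def overlapping_small_table(small_map, small_sites):
    """Overlapping-scenario table on the desk-scale map for GLM checks."""
    return simulate_reference_table(
        small_map, small_sites, "overlapping", 300, seed=20260955
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
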