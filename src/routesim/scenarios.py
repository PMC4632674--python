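"""Demographic scenarios and their parameter priors.

Three colonization scenarios of East Asia are encoded:

* ``southern`` — one expansion from the southwestern-most deme; the 29-33N
  band is a complete barrier until ``t1`` (0 < t1 < 2000); 2500 generations.
* ``pincer`` — two expansions (southwestern-most and northwestern-most
  demes) from a common ancestral source; the 29-33N band is closed until
  ``t1`` (0 < t1 < 2500); 2500 generations.
* ``overlapping`` — two expansions (southeastern-most and northeastern-most
  demes); the 41-45N band is closed until ``t1`` (0 < t1 < 2500) and the
  29-33N band becomes a partial barrier (0.1 m) at ``t2``
  (2500 < t2 < 3000); 3000 generations.

Each scenario has 12 free parameters: the number of ancestral lineages
``A``, the balancing-selection coefficient ``s``, the barrier-release time
``t1``, and zone-wise carrying capacity ``N``, migration rate ``m`` and
growth rate ``r`` for the northern area, the southern area and the barrier
zone.  The overlapping scenario adds ``t2``.  All priors are uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .landscape import DemeMap

SCENARIOS = ("southern", "pincer", "overlapping")
SELECTION_MODELS = ("sos", "los", "nfds")

#: generations -> calendar years conversion used in reports
YEARS_PER_GENERATION = 25.0

TOTAL_GENERATIONS = {"southern": 2500, "pincer": 2500, "overlapping": 3000}
T1_UPPER = {"southern": 2000, "pincer": 2500, "overlapping": 2500}
T2_BOUNDS = (2500, 3000)


@dataclass(frozen=True)
class Priors:
    """Uniform prior intervals for the scenario parameters."""

    A: tuple[int, int] = (10, 50)
    s: tuple[float, float] = (0.0, 0.025)
    N: tuple[float, float] = (0.0, 5000.0)
    m: tuple[float, float] = (0.01, 0.20)
    r: tuple[float, float] = (0.01, 0.20)

    def validate(self) -> None:
        for name in ("A", "s", "N", "m", "r"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"prior interval for {name} is empty: ({lo}, {hi})")


DEFAULT_PRIORS = Priors()

ZONE_PARAM_NAMES = [
    "N_nea", "m_nea", "r_nea",
    "N_sea", "m_sea", "r_sea",
    "N_bar", "m_bar", "r_bar",
]
PARAM_NAMES = ["A", "s", "t1", "t2"] + ZONE_PARAM_NAMES
DERIVED_NAMES = ["T", "Nm_nea", "Nm_sea"]


@dataclass(frozen=True)
class ScenarioParams:
    """One draw of the model parameters for a given scenario."""

    scenario: str
    selection_model: str
    A: int
    s: float
    t1: int
    N_nea: float
    m_nea: float
    r_nea: float
    N_sea: float
    m_sea: float
    r_sea: float
    N_bar: float
    m_bar: float
    r_bar: float
    t2: int | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.selection_model not in SELECTION_MODELS:
            raise ValueError(f"unknown selection model {self.selection_model!r}")
        if self.A < 1:
            raise ValueError("need at least one ancestral lineage")
        if (self.t2 is None) == (self.scenario == "overlapping"):
            raise ValueError("t2 must be present iff scenario is overlapping")

    @property
    def total_generations(self) -> int:
        return TOTAL_GENERATIONS[self.scenario]

    def as_record(self) -> dict:
        """Flat dict of free + derived parameters (reference-table row)."""
        rec = asdict(self)
        rec["t2"] = math.nan if self.t2 is None else self.t2
        rec["T"] = math.nan
        if self.scenario != "southern":
            rec["T"] = admixture_time(self)
        rec["Nm_nea"] = self.N_nea * self.m_nea
        rec["Nm_sea"] = self.N_sea * self.m_sea
        return rec


def draw_parameters(
    scenario: str,
    priors: Priors = DEFAULT_PRIORS,
    selection_model: str = "sos",
    seed: int | np.random.Generator = 0,
) -> ScenarioParams:
    """Draw one parameter vector uniformly from the priors.

    ``t1`` is an integer uniform on the open interval (0, 2000) for the
    southern scenario and (0, 2500) otherwise; ``t2`` (overlapping only) is
    uniform on (2500, 3000).  Reproducible given a seed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if selection_model not in SELECTION_MODELS:
        raise ValueError(f"unknown selection model {selection_model!r}")
    priors.validate()
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    zone_draws = {}
    for zone in ("nea", "sea", "bar"):
        zone_draws[f"N_{zone}"] = rng.uniform(*priors.N)
        zone_draws[f"m_{zone}"] = rng.uniform(*priors.m)
        zone_draws[f"r_{zone}"] = rng.uniform(*priors.r)
    t1 = int(rng.integers(1, T1_UPPER[scenario]))
    t2 = None
    if scenario == "overlapping":
        t2 = int(rng.integers(T2_BOUNDS[0] + 1, T2_BOUNDS[1]))
    return ScenarioParams(
        scenario=scenario,
        selection_model=selection_model,
        A=int(rng.integers(priors.A[0], priors.A[1] + 1)),
        s=rng.uniform(*priors.s),
        t1=t1,
        t2=t2,
        **zone_draws,
    )


def admixture_time(params: ScenarioParams) -> int:
    """Duration T of north-south genetic exchange, in generations.

    ``T = 2500 - t1`` under the pincer scenario and ``T = t2 - t1`` under
    the overlapping scenario; it is undefined for the one-route southern
    scenario.
    """
    if params.scenario == "southern":
        raise ValueError("admixture time is undefined for the southern scenario")
    if params.scenario == "pincer":
        return 2500 - params.t1
    return params.t2 - params.t1


def origin_cells(scenario: str, dememap: DemeMap) -> list[tuple[int, int]]:
    """Expansion origin demes of a scenario.

    Southern: the habitable deme closest to the southwestern corner.
    Pincer: southwestern-most and northwestern-most demes.  Overlapping:
    southeastern-most and northeastern-most demes.  Each origin is the
    habitable cell closest (Euclidean) to its named corner.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    last_r, last_c = dememap.n_rows - 1, dememap.n_cols - 1
    corners = {
        "SW": (last_r, 0),
        "NW": (0, 0),
        "SE": (last_r, last_c),
        "NE": (0, last_c),
    }
    wanted = {"southern": ["SW"], "pincer": ["SW", "NW"], "overlapping": ["SE", "NE"]}
    habitable = np.argwhere(dememap.habitable())
    if habitable.size == 0:
        raise ValueError("map has no habitable cells")
    cells = []
    for name in wanted[scenario]:
        cr, cc = corners[name]
        d2 = (habitable[:, 0] - cr) ** 2 + (habitable[:, 1] - cc) ** 2
        best = habitable[np.argmin(d2)]
        cell = (int(best[0]), int(best[1]))
        # sanity: the origin must sit in the right quadrant of the map
        if abs(cell[0] - cr) > dememap.n_rows / 2 or abs(cell[1] - cc) > dememap.n_cols / 2:
            raise ValueError(f"no habitable cell near the {name} corner")
        cells.append(cell)
    if len(cells) == 2 and cells[0] == cells[1]:
        raise ValueError("two-route origins collapse to a single cell")
    return cells


def capacity_by_zone(params: ScenarioParams) -> dict[int, float]:
    """Zone-code -> carrying-capacity mapping of a parameter draw.

    Zone 1 uses the northern parameter set and zone 2 the southern one.
    The scenario's barrier zone(s) use the barrier parameter set: the
    29-33N band under southern/pincer, both bands under overlapping (where
    the 41-45N band is the ancient barrier and the 29-33N band the recent
    one).  Under southern/pincer the 41-45N band is ordinary northern
    habitat.
    """
    if params.scenario == "overlapping":
        return {1: params.N_nea, 2: params.N_sea, 3: params.N_bar, 4: params.N_bar}
    return {1: params.N_nea, 2: params.N_sea, 3: params.N_bar, 4: params.N_nea}


def migration_by_zone(params: ScenarioParams) -> dict[int, float]:
    if params.scenario == "overlapping":
        return {1: params.m_nea, 2: params.m_sea, 3: params.m_bar, 4: params.m_bar}
    return {1: params.m_nea, 2: params.m_sea, 3: params.m_bar, 4: params.m_nea}


def growth_by_zone(params: ScenarioParams) -> dict[int, float]:
    if params.scenario == "overlapping":
        return {1: params.r_nea, 2: params.r_sea, 3: params.r_bar, 4: params.r_bar}
    return {1: params.r_nea, 2: params.r_sea, 3: params.r_bar, 4: params.r_nea}
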