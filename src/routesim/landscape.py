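"""Zoned deme lattice for spatially explicit forward simulations.

The study region is a rectangular stepping-stone lattice of square demes
(200 km side by default).  Each cell carries a zone code:

* ``0`` — permanently uninhabitable (sea, high mountains),
* ``1`` — northern habitable area (NEA),
* ``2`` — southern habitable area (SEA),
* ``3`` — the 29–33°N band (Qinling–Huaihe line / Yangtze),
* ``4`` — the 41–45°N band (the more northern, older contact zone).

Zones 3 and 4 act as migration barriers whose permeability changes through
time according to the demographic scenario (see :func:`barrier_schedule`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ZONE_UNINHABITABLE = 0
ZONE_NORTH = 1
ZONE_SOUTH = 2
ZONE_BAND_SOUTH = 3  # 29-33 degrees N
ZONE_BAND_NORTH = 4  # 41-45 degrees N

BAND_SOUTH_LAT = (29.0, 33.0)
BAND_NORTH_LAT = (41.0, 45.0)

#: neighbor offsets in fixed N, E, S, W order (row 0 is the northernmost row)
NEIGHBOR_OFFSETS = ((-1, 0), (0, 1), (1, 0), (0, -1))
NEIGHBOR_OFFSETS_8 = NEIGHBOR_OFFSETS + ((-1, 1), (1, 1), (1, -1), (-1, -1))


class MapConfigError(ValueError):
    """Raised when a map configuration violates the lattice invariants."""


@dataclass(frozen=True)
class DemeMap:
    """Zoned lattice of demes.

    Attributes
    ----------
    zone:
        ``(n_rows, n_cols)`` integer array of zone codes in ``{0..4}``.
    latitude:
        Per-row latitude (degrees N) of the row center; strictly decreasing
        with row index (row 0 is the northernmost row).
    carrying_capacity:
        Per-cell carrying capacity; zero until bound to a scenario's
        zone-wise ``N`` parameters (see :meth:`with_capacity`).
    """

    n_rows: int
    n_cols: int
    zone: np.ndarray
    latitude: np.ndarray
    deme_side_km: float = 200.0
    carrying_capacity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        zone = np.asarray(self.zone, dtype=np.int8)
        if zone.shape != (self.n_rows, self.n_cols):
            raise MapConfigError("zone grid shape does not match declared dims")
        if not np.isin(zone, [0, 1, 2, 3, 4]).all():
            raise MapConfigError("zone codes must lie in {0,1,2,3,4}")
        lat = np.asarray(self.latitude, dtype=float)
        if lat.shape != (self.n_rows,):
            raise MapConfigError("need one latitude per row")
        if not (np.diff(lat) < 0).all():
            raise MapConfigError("latitude must be strictly monotone across rows")
        object.__setattr__(self, "zone", zone)
        object.__setattr__(self, "latitude", lat)
        if self.carrying_capacity is None:
            object.__setattr__(
                self, "carrying_capacity", np.zeros((self.n_rows, self.n_cols))
            )
        self._check_bands()

    def _check_bands(self):
        lat = self.latitude
        for r in range(self.n_rows):
            row_zone = set(np.unique(self.zone[r])) - {ZONE_UNINHABITABLE}
            if BAND_SOUTH_LAT[0] <= lat[r] <= BAND_SOUTH_LAT[1]:
                if row_zone - {ZONE_BAND_SOUTH}:
                    raise MapConfigError(
                        f"row {r} (lat {lat[r]:.2f}) lies in the 29-33N band "
                        "but carries non-band zones"
                    )
            elif BAND_NORTH_LAT[0] <= lat[r] <= BAND_NORTH_LAT[1]:
                if row_zone - {ZONE_BAND_NORTH}:
                    raise MapConfigError(
                        f"row {r} (lat {lat[r]:.2f}) lies in the 41-45N band "
                        "but carries non-band zones"
                    )
            elif ZONE_BAND_SOUTH in row_zone or ZONE_BAND_NORTH in row_zone:
                raise MapConfigError(f"band zone outside its latitude band in row {r}")
            if ZONE_NORTH in row_zone and lat[r] <= BAND_SOUTH_LAT[1]:
                raise MapConfigError("zone-1 rows must lie north of the 29-33N band")
            if ZONE_SOUTH in row_zone and lat[r] >= BAND_SOUTH_LAT[0]:
                raise MapConfigError("zone-2 rows must lie south of the 29-33N band")

    # -- geometry ---------------------------------------------------------

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        r, c = cell
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def habitable(self) -> np.ndarray:
        """Boolean mask of cells that are ever habitable (zone != 0)."""
        return self.zone != ZONE_UNINHABITABLE

    def with_capacity(self, capacity_by_zone: dict[int, float]) -> "DemeMap":
        """Bind zone-wise carrying capacities, returning a new map."""
        cap = np.zeros((self.n_rows, self.n_cols))
        for z, k in capacity_by_zone.items():
            cap[self.zone == z] = k
        cap[self.zone == ZONE_UNINHABITABLE] = 0.0
        return DemeMap(
            self.n_rows, self.n_cols, self.zone, self.latitude,
            self.deme_side_km, cap,
        )


@dataclass(frozen=True)
class BarrierSchedule:
    """Piecewise-constant migration multiplier per zone.

    ``multiplier(zone, generation)`` scales immigration into and emigration
    out of cells of that zone; a multiplier of 0 makes the zone
    uninhabitable at that generation.  At most two change points (``t1``,
    ``t2``) exist, per the demographic scenarios.
    """

    scenario: str
    t1: int
    t2: int | None = None

    def multiplier(self, zone: int, generation: int) -> float:
        if zone == ZONE_UNINHABITABLE:
            return 0.0
        if self.scenario in ("southern", "pincer"):
            if zone == ZONE_BAND_SOUTH:
                return 0.0 if generation < self.t1 else 1.0
            return 1.0
        # overlapping: ancient barrier in the 41-45N band, recent partial
        # barrier (0.1 m) in the 29-33N band from t2 on
        if zone == ZONE_BAND_NORTH:
            return 0.0 if generation < self.t1 else 1.0
        if zone == ZONE_BAND_SOUTH:
            return 1.0 if generation < self.t2 else 0.1
        return 1.0

    def zone_multipliers(self, generation: int) -> np.ndarray:
        return np.array(
            [self.multiplier(z, generation) for z in range(5)], dtype=float
        )


def barrier_schedule(scenario: str, t1: int, t2: int | None = None) -> BarrierSchedule:
    """Build the barrier schedule of a scenario.

    Southern-origin and Pincer keep the 29-33N band fully closed until
    ``t1`` (bounds: ``0 < t1 < 2000`` for Southern, ``0 < t1 < 2500`` for
    Pincer).  Overlapping keeps the 41-45N band closed until ``t1``
    (``0 < t1 < 2500``) and downgrades the 29-33N band to a partial barrier
    (migration rate ``0.1 m``) from ``t2`` on (``2500 < t2 < 3000``).
    """
    scenario = scenario.lower()
    if scenario == "southern":
        hi = 2000
    elif scenario in ("pincer", "overlapping"):
        hi = 2500
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if not 0 < t1 < hi:
        raise ValueError(f"t1={t1} outside (0, {hi}) for scenario {scenario!r}")
    if scenario == "overlapping":
        if t2 is None or not 2500 < t2 < 3000:
            raise ValueError(f"t2={t2} outside (2500, 3000) for overlapping")
    else:
        if t2 is not None:
            raise ValueError(f"t2 is only defined for the overlapping scenario")
        t2 = None
    return BarrierSchedule(scenario, int(t1), None if t2 is None else int(t2))


# -- map construction ------------------------------------------------------

#: Default study-region lattice: 24x18 demes spanning 18-55N with a western
#: uninhabitable margin standing in for the Tibetan plateau / Himalayas.
DEFAULT_MAP_CONFIG = {
    "n_rows": 24,
    "n_cols": 18,
    "lat_min": 18.0,
    "lat_max": 55.0,
    "deme_side_km": 200.0,
    # [row_first, row_last, col_first, col_last] rectangles of zone-0 cells
    "zone0": [[9, 23, 0, 3]],
}

#: Half-resolution lattice used for desk-scale reference tables; same
#: latitude span and zone-band structure as the default map.
SMALL_MAP_CONFIG = {
    "n_rows": 12,
    "n_cols": 9,
    "lat_min": 18.0,
    "lat_max": 55.0,
    "deme_side_km": 400.0,
    "zone0": [[5, 11, 0, 1]],
}


def build_map(map_config: dict) -> DemeMap:
    """Build a :class:`DemeMap` from a structured configuration.

    The configuration declares grid dimensions, the latitude range covered
    (row 0 is the northernmost row), the deme side length and rectangles of
    uninhabitable cells.  Zone bands are placed automatically on the rows
    whose center latitude falls in 29-33N / 41-45N; the latitude range must
    cover both bands.  Deterministic: the same config yields the same map.
    """
    cfg = dict(map_config)
    n_rows, n_cols = int(cfg["n_rows"]), int(cfg["n_cols"])
    lat_min, lat_max = float(cfg["lat_min"]), float(cfg["lat_max"])
    if n_rows < 2 or n_cols < 1:
        raise MapConfigError("grid must have at least 2 rows and 1 column")
    if lat_min >= BAND_SOUTH_LAT[0] or lat_max <= BAND_NORTH_LAT[1]:
        raise MapConfigError("latitude range must cover both zone bands")
    step = (lat_max - lat_min) / n_rows
    latitude = lat_max - step * (np.arange(n_rows) + 0.5)

    zone = np.empty((n_rows, n_cols), dtype=np.int8)
    for r, lat in enumerate(latitude):
        if BAND_SOUTH_LAT[0] <= lat <= BAND_SOUTH_LAT[1]:
            z = ZONE_BAND_SOUTH
        elif BAND_NORTH_LAT[0] <= lat <= BAND_NORTH_LAT[1]:
            z = ZONE_BAND_NORTH
        elif lat > BAND_SOUTH_LAT[1]:
            z = ZONE_NORTH
        else:
            z = ZONE_SOUTH
        zone[r, :] = z
    for r0, r1, c0, c1 in cfg.get("zone0", []):
        zone[r0 : r1 + 1, c0 : c1 + 1] = ZONE_UNINHABITABLE
    for band_zone in (ZONE_BAND_SOUTH, ZONE_BAND_NORTH):
        if not (zone == band_zone).any():
            raise MapConfigError(f"map has no habitable zone-{band_zone} cells")
    return DemeMap(n_rows, n_cols, zone, latitude, float(cfg.get("deme_side_km", 200.0)))


def neighbors(
    dememap: DemeMap,
    cell: tuple[int, int],
    generation: int,
    schedule: BarrierSchedule,
    system: int = 4,
) -> list[tuple[int, int]]:
    """Habitable neighbors of ``cell`` at ``generation``.

    Returns the adjacent on-grid cells (von Neumann 4-neighborhood by
    default, in fixed N, E, S, W order; ``system=8`` adds diagonals) whose
    zone multiplier at ``generation`` is positive.  Cells of a fully closed
    barrier zone are excluded, so a complete barrier blocks both settlement
    and through-migration.
    """
    if not dememap.in_bounds(cell):
        raise IndexError(f"cell {cell} is off the {dememap.n_rows}x{dememap.n_cols} grid")
    offsets = NEIGHBOR_OFFSETS if system == 4 else NEIGHBOR_OFFSETS_8
    r, c = cell
    out = []
    for dr, dc in offsets:
        nb = (r + dr, c + dc)
        if not dememap.in_bounds(nb):
            continue
        if schedule.multiplier(int(dememap.zone[nb]), generation) > 0:
            out.append(nb)
    return out


# -- map file IO -----------------------------------------------------------

def write_map(dememap: DemeMap, path, header_comments: list[str] | None = None) -> None:
    """Write a map as a plain-text digit grid with a small header."""
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write(f"n_rows\t{dememap.n_rows}\n")
        fh.write(f"n_cols\t{dememap.n_cols}\n")
        fh.write(f"lat_min\t{dememap.latitude[-1] - _lat_step(dememap) / 2:.6g}\n")
        fh.write(f"lat_max\t{dememap.latitude[0] + _lat_step(dememap) / 2:.6g}\n")
        fh.write(f"deme_side_km\t{dememap.deme_side_km:.6g}\n")
        for r in range(dememap.n_rows):
            fh.write("".join(str(int(z)) for z in dememap.zone[r]) + "\n")


def _lat_step(dememap: DemeMap) -> float:
    return float(dememap.latitude[0] - dememap.latitude[1])


def read_map(path) -> DemeMap:
    """Read a map written by :func:`write_map`."""
    header: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                key, val = line.split("\t", 1)
                header[key] = val
            else:
                rows.append(line)
    try:
        n_rows, n_cols = int(header["n_rows"]), int(header["n_cols"])
        lat_min, lat_max = float(header["lat_min"]), float(header["lat_max"])
        side = float(header.get("deme_side_km", 200.0))
    except KeyError as exc:
        raise MapConfigError(f"map header missing field {exc}") from exc
    if len(rows) != n_rows or any(len(r) != n_cols for r in rows):
        raise MapConfigError("map grid does not match declared dimensions")
    zone = np.array([[int(ch) for ch in r] for r in rows], dtype=np.int8)
    step = (lat_max - lat_min) / n_rows
    latitude = lat_max - step * (np.arange(n_rows) + 0.5)
    return DemeMap(n_rows, n_cols, zone, latitude, side)
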