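"""Fixtures, file IO and end-to-end orchestration.

This module carries the packaged observed inputs (the published
12-statistic vectors and model marginal densities for the HLA-A, -B and
-DRB1 loci), a synthetic 19-population sampling design standing in for the
real population panel (whose exact coordinates and sizes are not part of
the packaged data), plain-text readers/writers for maps, sample specs,
statistic vectors, frequency tables and reference tables, and the
``run_pipeline`` orchestration that chains simulation, summary statistics,
model choice and posterior estimation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .landscape import (
    DEFAULT_MAP_CONFIG,
    SMALL_MAP_CONFIG,
    DemeMap,
    barrier_schedule,
    build_map,
    write_map,
)
from .scenarios import (
    DEFAULT_PRIORS,
    PARAM_NAMES,
    DERIVED_NAMES,
    Priors,
    draw_parameters,
)
from .engine import SamplingError, run_simulation, sample_populations
from .sumstats import (
    PCOA_STAT,
    STAT_NAMES,
    PopulationSample,
    StatVector,
    compute_stats,
)
from .inference import (
    DEFAULT_RETENTIONS,
    ReferenceTable,
    bayes_factor,
    fit_p_value,
    glm_estimate,
    model_choice,
)

LOCI = ("HLA-A", "HLA-B", "HLA-DRB1")

#: Published observed summary statistics per locus (19 East Asian
#: populations), in the fixed 12-statistic column order.
OBSERVED_STATS = {
    "HLA-A": {
        "M_A": 14.47, "SD_A": 3.96, "M_H": 0.79, "SD_H": 0.054,
        "M_H_north": 0.84, "SD_H_north": 0.012,
        "M_H_south": 0.75, "SD_H_south": 0.044,
        "R_H_lat": 0.78, "F_ST": 0.017, "F_CT": 0.015, "F_SC": 0.0023,
    },
    "HLA-B": {
        "M_A": 27.26, "SD_A": 6.64, "M_H": 0.91, "SD_H": 0.021,
        "M_H_north": 0.92, "SD_H_north": 0.0056,
        "M_H_south": 0.89, "SD_H_south": 0.010,
        "R_H_lat": 0.84, "F_ST": 0.011, "F_CT": 0.0092, "F_SC": 0.0016,
    },
    "HLA-DRB1": {
        "M_A": 12.84, "SD_A": 1.01, "M_H": 0.89, "SD_H": 0.019,
        "M_H_north": 0.90, "SD_H_north": 0.0070,
        "M_H_south": 0.88, "SD_H_south": 0.021,
        "R_H_lat": 0.65, "F_ST": 0.0075, "F_CT": 0.0055, "F_SC": 0.0020,
    },
}

#: Published model marginal densities at the observed statistics (full-scale
#: analysis, 1% retention), used for Bayes-factor arithmetic.
MARGINAL_DENSITIES = {
    "southern": {"HLA-A": 3.58e-27, "HLA-B": 1.93e-90, "HLA-DRB1": 198.0},
    "pincer": {"HLA-A": 0.79, "HLA-B": 1.17e4, "HLA-DRB1": 1.22e6},
    "overlapping": {"HLA-A": 8.20e3, "HLA-B": 6.00e7, "HLA-DRB1": 4.99e10},
}

#: Published Bayes factors between model pairs per locus.
PUBLISHED_BAYES_FACTORS = {
    ("pincer", "southern"): {"HLA-A": 2.20e26, "HLA-B": 6.06e93, "HLA-DRB1": 6.16e3},
    ("overlapping", "southern"): {"HLA-A": 2.29e30, "HLA-B": 3.12e97, "HLA-DRB1": 2.52e8},
    ("overlapping", "pincer"): {"HLA-A": 1.04e4, "HLA-B": 5.12e3, "HLA-DRB1": 4.09e4},
}


# --------------------------------------------------------------------------
# sample specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSite:
    """One sampled population: deme coordinate, latitude, group, size."""

    id: str
    row: int
    col: int
    latitude: float
    group: str
    n: int


#: Synthetic stand-in for the 19-population panel: latitudes spread on both
#: sides of the two barrier bands (avoiding the bands themselves), sample
#: sizes in [52, 9678] with mean 2662 as in the real panel.  ``frac`` is
#: the relative east-west position on the map.
_SITE_TEMPLATE = [
    # (id, latitude, frac, n)
    ("north01", 52.5, 0.55, 600),
    ("north02", 50.9, 0.75, 120),
    ("north03", 49.3, 0.40, 1000),
    ("north04", 47.6, 0.60, 300),
    ("north05", 46.3, 0.82, 450),
    ("north06", 39.2, 0.50, 3500),
    ("north07", 38.3, 0.70, 4200),
    ("north08", 37.1, 0.45, 2600),
    ("north09", 36.0, 0.62, 5000),
    ("north10", 34.5, 0.55, 3000),
    ("south01", 28.3, 0.58, 9678),
    ("south02", 26.9, 0.42, 6500),
    ("south03", 25.6, 0.68, 6078),
    ("south04", 24.2, 0.52, 2200),
    ("south05", 22.9, 0.78, 1800),
    ("south06", 21.5, 0.48, 1500),
    ("south07", 20.1, 0.65, 1200),
    ("south08", 19.2, 0.55, 800),
    ("south09", 18.6, 0.45, 52),
]


def default_sample_spec(dememap: DemeMap) -> list[PopulationSite]:
    """Bind the synthetic 19-population panel to a map's demes.

    Each site is placed on the row whose latitude span contains it, at the
    column given by its east-west fraction, shifted east if that cell is
    uninhabitable.  Groups are split by the 29-33N band: NEA above, SEA
    below.
    """
    sites = []
    lat_top = dememap.latitude[0] + (dememap.latitude[0] - dememap.latitude[1]) / 2
    step = dememap.latitude[0] - dememap.latitude[1]
    for pid, lat, frac, n in _SITE_TEMPLATE:
        row = int((lat_top - lat) / step)
        row = min(max(row, 0), dememap.n_rows - 1)
        col = int(round(frac * (dememap.n_cols - 1)))
        while col < dememap.n_cols and dememap.zone[row, col] == 0:
            col += 1
        if col >= dememap.n_cols:
            raise ValueError(f"no habitable cell for site {pid} on row {row}")
        group = "NEA" if lat > 33.0 else "SEA"
        sites.append(PopulationSite(pid, row, col, lat, group, n))
    return sites


def write_sample_spec(sites: list[PopulationSite], path, comments=None) -> None:
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write("id\trow\tcol\tlatitude\tgroup\tn\n")
        for s in sites:
            fh.write(f"{s.id}\t{s.row}\t{s.col}\t{s.latitude}\t{s.group}\t{s.n}\n")


def read_sample_spec(path) -> list[PopulationSite]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        PopulationSite(str(r.id), int(r.row), int(r.col), float(r.latitude),
                       str(r.group), int(r.n))
        for r in df.itertuples(index=False)
    ]


# --------------------------------------------------------------------------
# statistic vectors, frequency tables, reference tables
# --------------------------------------------------------------------------


def observed_statvector(locus: str) -> StatVector:
    """The packaged observed 12-statistic vector of one HLA locus."""
    if locus not in OBSERVED_STATS:
        raise KeyError(f"unknown locus {locus!r}; choose from {LOCI}")
    return StatVector(dict(OBSERVED_STATS[locus]))


def write_statvector(sv: StatVector, path, comments=None) -> None:
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(sv.names) + "\n")
        fh.write("\t".join(f"{sv[n]:.6g}" for n in sv.names) + "\n")


def read_statvector(path) -> StatVector:
    df = pd.read_csv(path, sep="\t", comment="#")
    if len(df) != 1:
        raise ValueError(f"{path}: expected exactly one statistic row")
    return StatVector({c: float(df[c].iloc[0]) for c in df.columns})


def read_frequency_table(path) -> list[PopulationSample]:
    """Read a population x lineage frequency (or count) table.

    Tab-delimited with columns ``id latitude group n`` followed by lineage
    labels; entries may be gene-copy counts or relative frequencies (then
    each row must sum to 1 within 0.01 and is converted to counts out of
    2n gene copies).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = ["id", "latitude", "group", "n"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    lineage_cols = [c for c in df.columns if c not in meta]
    if not lineage_cols:
        raise ValueError(f"{path}: no lineage columns")
    samples = []
    for i, row in df.iterrows():
        vals = row[lineage_cols].to_numpy(dtype=float)
        n = int(row["n"])
        if (vals < 0).any():
            raise ValueError(f"{path} line {i + 2}: negative entries")
        if vals.sum() == 0:
            raise ValueError(f"{path} line {i + 2}: empty population")
        if abs(vals.sum() - 2 * n) <= 0.5:  # gene-copy counts
            counts = np.rint(vals).astype(np.int64)
        elif vals.max() <= 1.0:  # relative frequencies
            if abs(vals.sum() - 1.0) > 0.01:
                raise ValueError(
                    f"{path} line {i + 2}: frequencies sum to {vals.sum():.4f}, not 1"
                )
            counts = np.rint(vals * 2 * n).astype(np.int64)
        else:
            raise ValueError(
                f"{path} line {i + 2}: entries sum to {vals.sum():.4f}, "
                f"neither 2n={2 * n} (counts) nor 1 (frequencies)"
            )
        samples.append(
            PopulationSample(str(row["id"]), float(row["latitude"]),
                             str(row["group"]), counts)
        )
    return samples


ALL_PARAM_COLS = PARAM_NAMES + DERIVED_NAMES


def header_comments(seed, scenario=None, extra=None) -> list[str]:
    out = [f"routesim {__version__}", f"seed={seed}"]
    if scenario:
        out.append(f"scenario={scenario}")
    out.extend(extra or [])
    return out


def write_reference_table(ref: ReferenceTable, path, seed=None) -> None:
    with open(path, "w") as fh:
        for line in header_comments(seed):
            fh.write(f"# {line}\n")
        fh.write(f"# params={','.join(ref.param_names)}\n")
        fh.write(f"# stats={','.join(ref.stat_names)}\n")
        ref.table.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_reference_table(path) -> ReferenceTable:
    params, stats = None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("params="):
                params = body[len("params="):].split(",")
            elif body.startswith("stats="):
                stats = body[len("stats="):].split(",")
    df = pd.read_csv(path, sep="\t", comment="#")
    if params is None:
        params = [c for c in ALL_PARAM_COLS if c in df.columns]
    if stats is None:
        stats = [c for c in STAT_NAMES + [PCOA_STAT] if c in df.columns]
    return ReferenceTable(df, params, stats)


# --------------------------------------------------------------------------
# reference-table simulation
# --------------------------------------------------------------------------


def simulate_one(
    dememap: DemeMap,
    params,
    sites: list[PopulationSite],
    seed: int,
    include_pcoa: bool = False,
) -> StatVector | None:
    """Run one simulation and summarise the sampled populations.

    Returns ``None`` when the parameter draw leaves a sampled deme empty
    (no colonization) or yields an undefined statistic — such draws do not
    produce analyzable data and are not recorded.
    """
    ss = np.random.SeedSequence(seed)
    run_seed, samp_seed = (int(s) for s in ss.generate_state(2))
    schedule = barrier_schedule(params.scenario, params.t1, params.t2)
    state = run_simulation(dememap, params, schedule, seed=run_seed)
    try:
        samples = sample_populations(state, sites, np.random.default_rng(samp_seed))
    except SamplingError:
        return None
    sv = compute_stats(samples, include_pcoa=include_pcoa)
    if any(math.isnan(v) for v in sv.values.values()):
        return None
    return sv


def simulate_reference_table(
    dememap: DemeMap,
    sites: list[PopulationSite],
    scenario: str,
    n_simulations: int,
    seed: int,
    selection_model: str = "sos",
    priors: Priors = DEFAULT_PRIORS,
    include_pcoa: bool = False,
    max_attempts: int | None = None,
) -> ReferenceTable:
    """Build a single-scenario reference table of ``n_simulations`` records.

    Parameter vectors are drawn from the priors; draws whose simulation
    leaves a sampled deme empty are discarded and redrawn (the reference
    table is implicitly conditioned on colonization of the sampling sites,
    identically for all scenarios).
    """
    max_attempts = max_attempts or 20 * n_simulations
    master = np.random.SeedSequence(seed)
    records = []
    attempts = 0
    child_iter = iter(master.spawn(max_attempts))
    stat_cols = STAT_NAMES + ([PCOA_STAT] if include_pcoa else [])
    while len(records) < n_simulations and attempts < max_attempts:
        attempts += 1
        child = next(child_iter)
        par_seed, sim_seed = (int(s) for s in child.generate_state(2))
        params = draw_parameters(scenario, priors, selection_model, par_seed)
        sv = simulate_one(dememap, params, sites, sim_seed, include_pcoa)
        if sv is None:
            continue
        rec = {"model": scenario}
        rec.update(params.as_record())
        rec.pop("scenario")
        rec.pop("selection_model")
        rec.update({k: sv[k] for k in stat_cols})
        records.append(rec)
    if len(records) < n_simulations:
        raise RuntimeError(
            f"only {len(records)}/{n_simulations} valid simulations in "
            f"{max_attempts} attempts under {scenario!r}"
        )
    df = pd.DataFrame(records)
    return ReferenceTable(df, ALL_PARAM_COLS, stat_cols)


def pooled_reference_table(tables: list[ReferenceTable]) -> ReferenceTable:
    df = pd.concat([t.table for t in tables], ignore_index=True)
    stat_names = tables[0].stat_names
    return ReferenceTable(df, tables[0].param_names, stat_names)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    map_config: dict = dataclasses.field(default_factory=lambda: dict(SMALL_MAP_CONFIG))
    scenarios: tuple = ("southern", "pincer", "overlapping")
    selection_model: str = "sos"
    n_simulations: int = 100
    seed: int = 0
    deltas: tuple = DEFAULT_RETENTIONS
    retain: float = 0.005
    n_pls: int | None = None
    loci: tuple = LOCI
    estimate_retain: float = 0.1  # retention for GLM at desk scale
    include_pcoa: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig, ref_tables: dict | None = None) -> dict:
    """Simulate, compare models and estimate parameters for each locus.

    Returns a structured report: per-locus model-choice proportions for
    each retention fraction, Bayes factors between model pairs (from GLM
    marginal densities), fit p-values, and posterior summaries (mode and
    95% HPD) under the best model, with times also converted to years at
    25 years per generation.  If ``ref_tables`` (scenario -> table) is
    given, simulation is skipped and the report is regenerated from them.
    """
    from .scenarios import YEARS_PER_GENERATION

    dememap = build_map(config.map_config)
    sites = default_sample_spec(dememap)
    if ref_tables is None:
        ref_tables = {}
        for i, scen in enumerate(config.scenarios):
            ref_tables[scen] = simulate_reference_table(
                dememap, sites, scen, config.n_simulations,
                seed=np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % 2**31,
                selection_model=config.selection_model,
                include_pcoa=config.include_pcoa,
            )
    pooled = pooled_reference_table([ref_tables[s] for s in config.scenarios])

    report = {"config": dataclasses.asdict(config), "loci": {}}
    for locus in config.loci:
        obs = observed_statvector(locus)
        entry = {"model_choice": {}, "bayes_factors": {}, "p_values": {},
                 "marginal_densities": {}, "posterior": {}}
        for delta in config.deltas:
            mc = model_choice(pooled, obs, delta)
            entry["model_choice"][delta] = {
                "n_retained": mc.n_retained,
                "proportions": mc.proportions,
            }
        glms = {}
        for scen in config.scenarios:
            glms[scen] = glm_estimate(
                ref_tables[scen], obs, retain=config.estimate_retain
            )
            entry["marginal_densities"][scen] = glms[scen].marginal_density
            entry["p_values"][scen] = fit_p_value(glms[scen])
        for a in config.scenarios:
            for b in config.scenarios:
                if a != b:
                    entry["bayes_factors"][f"{a}/{b}"] = bayes_factor(
                        entry["marginal_densities"][a], entry["marginal_densities"][b]
                    )
        best = max(entry["marginal_densities"], key=entry["marginal_densities"].get)
        entry["best_model"] = best
        post = glms[best]
        summary = {}
        for name in post.param_names:
            mode, hpd = post.modes[name], post.hpd_intervals[name]
            summary[name] = {"mode": mode, "hpd95": list(hpd)}
            if name in ("t1", "t2", "T"):
                summary[name]["mode_years"] = mode * YEARS_PER_GENERATION
                summary[name]["hpd95_years"] = [v * YEARS_PER_GENERATION for v in hpd]
        entry["posterior"] = summary
        report["loci"][locus] = entry
    return report


def make_default_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the packaged fixtures to ``out_dir``.

    Produces the default (24x18) and desk-scale (12x9) maps, the bound
    19-population sample specs, and the three observed statistic vectors.
    The population panel is a synthetic stand-in (the published statistics
    are the authoritative observed inputs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, cfg in [("default", DEFAULT_MAP_CONFIG), ("small", SMALL_MAP_CONFIG)]:
        dememap = build_map(cfg)
        p = out / f"map_{name}.txt"
        write_map(dememap, p, header_comments(seed))
        paths[f"map_{name}"] = p
        sp = out / f"sample_spec_{name}.tsv"
        write_sample_spec(
            default_sample_spec(dememap), sp,
            header_comments(seed, extra=["synthetic population panel"]),
        )
        paths[f"sample_spec_{name}"] = sp
    for locus in LOCI:
        p = out / f"observed_{locus.lower().replace('-', '_')}.tsv"
        write_statvector(observed_statvector(locus), p, header_comments(seed))
        paths[f"observed_{locus}"] = p
    return paths
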