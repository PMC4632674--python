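"""Forward-in-time lattice Wright–Fisher engine.

Populations of diploid individuals evolve on a zoned deme lattice,
generation by generation: a fraction ``m`` of each deme's census emigrates
to the habitable orthogonal neighbors (spread as equally as possible),
census sizes grow logistically toward the zone carrying capacity, balancing
selection deterministically reweights lineage frequencies, and the next
generation's ``2N`` gene copies are drawn multinomially (Wright–Fisher)
from the post-selection frequencies.  Only lineage frequencies are tracked:
at that level the drift/selection dynamics match an individual-based
replacement scheme, while staying fast enough for ABC reference tables.

No mutation: lineages can only be lost, never created, so all variation
descends from the ``A`` ancestral lineages seeded at the origin deme(s).

The per-generation kernels are numba-compiled; they use numba's internal
``np.random`` state, seeded once per simulation for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .landscape import DemeMap, BarrierSchedule, NEIGHBOR_OFFSETS
from .scenarios import (
    ScenarioParams,
    capacity_by_zone,
    growth_by_zone,
    migration_by_zone,
    origin_cells,
)

__all__ = [
    "SimState",
    "SamplingError",
    "init_state",
    "grow",
    "selection_update",
    "migrate",
    "step",
    "run_simulation",
    "sample_populations",
]

SEL_SOS = 0  # symmetric overdominance (also LOS via a per-cell coefficient)
SEL_NFDS = 1  # negative frequency-dependent selection


class SamplingError(RuntimeError):
    """A sampled deme is empty at the end of the simulation."""


@dataclass
class SimState:
    """Per-deme census and lineage gene-copy counts at one generation."""

    generation: int
    census: np.ndarray  # (n_rows, n_cols) int64
    copies: np.ndarray  # (n_rows, n_cols, A) int64

    @property
    def n_lineages(self) -> int:
        return self.copies.shape[2]

    def total_copies(self) -> int:
        return int(self.copies.sum())

    def copy(self) -> "SimState":
        return SimState(self.generation, self.census.copy(), self.copies.copy())


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------


@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _std_normal_icdf():
    """Standard-normal draw via Acklam's inverse-CDF approximation.

    One uniform per draw; relative quantile error below 1.2e-9, ample for
    the moment-matched Gaussian fast path of the Wright-Fisher sampler.
    """
    p = np.random.random()
    if p < 1e-300:
        p = 1e-300
    elif p > 1.0 - 1e-16:
        p = 1.0 - 1e-16
    if p < 0.02425:
        q = np.sqrt(-2.0 * np.log(p))
        return (((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                   - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
                 + 4.374664141464968e+00) * q + 2.938163982698783e+00) / (
            (((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
              + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    if p > 1.0 - 0.02425:
        q = np.sqrt(-2.0 * np.log(1.0 - p))
        return -(((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                    - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
                  + 4.374664141464968e+00) * q + 2.938163982698783e+00) / (
            (((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
              + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    q = p - 0.5
    r = q * q
    return (((((-3.969683028665376e+01 * r + 2.209460984245205e+02) * r
               - 2.759285104469687e+02) * r + 1.383577518672690e+02) * r
             - 3.066479806614716e+01) * r + 2.506628277459239e+00) * q / (
        ((((-5.447609879822406e+01 * r + 1.615858368580409e+02) * r
           - 1.556989798598866e+02) * r + 6.680131188771972e+01) * r
         - 1.328068155288572e+01) * r + 1.0)


@njit(cache=True)
def _grow_scalar(n, r, k):
    """Logistic update round(n + r*n*(1-n/k)), clamped to [0, k]."""
    if k <= 0:
        return np.int64(0)
    n_new = np.int64(np.floor(n + r * n * (1.0 - n / k) + 0.5))
    if n_new < 0:
        n_new = np.int64(0)
    k_int = np.int64(k)
    if n_new > k_int:
        n_new = k_int
    return n_new


@njit(cache=True)
def _apply_selection(p, s_eff, s_nfds, sel_code):
    """In-place deterministic selection update of a frequency vector.

    ``sel_code`` 0: heterozygote advantage under random mating — homozygote
    fitness 1-s, heterozygote 1, giving p_i' = p_i (1 - s p_i) / (1 - s sum p_j^2).
    ``sel_code`` 1: negative frequency dependence with fitness
    w_i = max(0, 1 - s (p_i - 1/k)), k = number of segregating lineages.
    """
    A = p.shape[0]
    if sel_code == SEL_SOS:
        sum_sq = 0.0
        for i in range(A):
            sum_sq += p[i] * p[i]
        denom = 1.0 - s_eff * sum_sq
        for i in range(A):
            p[i] = p[i] * (1.0 - s_eff * p[i]) / denom
    else:
        k = 0
        for i in range(A):
            if p[i] > 0.0:
                k += 1
        if k == 0:
            return
        wbar = 0.0
        for i in range(A):
            if p[i] > 0.0:
                w = 1.0 - s_nfds * (p[i] - 1.0 / k)
                if w < 0.0:
                    w = 0.0
                p[i] = p[i] * w
                wbar += p[i]
        if wbar > 0.0:
            for i in range(A):
                p[i] /= wbar


@njit(cache=True)
def _draw_capped_pool(copies_row, take, emig):
    """Draw ``take`` emigrant copies from a cell's counts.

    Conditional binomial chain on the cell's frequencies, capped at the
    per-lineage counts so the drawn copies can be removed from the source
    exactly (copy conservation).  Writes the drawn counts to ``emig`` and
    subtracts them from ``copies_row``.  Returns the number drawn.
    """
    A = copies_row.shape[0]
    rem = 0
    for l in range(A):
        emig[l] = 0
        rem += copies_row[l]
    if take > rem:
        take = rem
    left = take
    if take > 128:
        # large flows: expected composition with floor rounding; the
        # sampling noise of a draw this size is negligible next to the
        # Wright-Fisher resampling that follows.  The rounding shortfall
        # is assigned by systematic sampling with inclusion probability
        # equal to each lineage's fractional part, so per-lineage
        # expectations are exact.
        for l in range(A):
            c = copies_row[l]
            if c > 0:
                x = take * c // rem
                emig[l] = x
                left -= x
        if left > 0:
            thresh = np.random.random()
            cum = 0.0
            for l in range(A):
                c = copies_row[l]
                if c == 0:
                    continue
                cum += (take * c % rem) / rem
                if cum >= thresh:
                    emig[l] += 1
                    thresh += 1.0
                    left -= 1
                    if left == 0:
                        break
        while left > 0:  # float-rounding guard
            for l in range(A):
                if left > 0 and copies_row[l] > emig[l]:
                    emig[l] += 1
                    left -= 1
        for l in range(A):
            copies_row[l] -= emig[l]
        return take
    for l in range(A):
        if left == 0:
            break
        c = copies_row[l]
        if c == 0:
            continue
        if c >= rem:
            x = left
        else:
            x = np.random.binomial(left, c / rem)
            if x > c:
                x = c
        emig[l] = x
        left -= x
        rem -= c
    if left > 0:  # caps fired; top up from lineages with spare copies
        for l in range(A):
            if left == 0:
                break
            spare = copies_row[l] - emig[l]
            if spare > 0:
                add = spare if spare < left else left
                emig[l] += add
                left -= add
    for l in range(A):
        copies_row[l] -= emig[l]
    return take - left


@njit(cache=True)
def _migrate_gen(
    census, copies, zone, valid_nbr, m_eff_zone,
    imm_census, imm_copies, emig, nb_idx, q_tot, last_l,
):
    """One generation of emigration on the flattened lattice.

    Each deme emits ``E = round(m_eff * N)`` individuals.  The ``2E``
    emigrant gene copies are drawn from the source counts in one pooled
    capped-multinomial draw; each lineage's drawn copies are then divided
    as equally as possible among the habitable neighbors (remainder slots
    rotated per lineage), with a final parity repair so every neighbor
    receives an even number of copies (whole diploid immigrants).
    """
    H, A = copies.shape
    for i in range(H):
        imm_census[i] = 0
        for l in range(A):
            imm_copies[i, l] = 0
    for i in range(H):
        N = census[i]
        if N == 0:
            continue
        me = m_eff_zone[zone[i]]
        if me <= 0.0:
            continue
        E = int(np.floor(me * N + 0.5))
        if E == 0:
            continue
        nnb = 0
        for k in range(4):
            if valid_nbr[i, k] >= 0:
                nnb += 1
        if nnb == 0:
            continue
        drawn = _draw_capped_pool(copies[i], 2 * E, emig)
        E = drawn // 2
        if E == 0:
            # give the odd leftover copy back
            for l in range(A):
                copies[i, l] += emig[l]
            continue
        census[i] -= E
        nn = 0
        for k in range(4):
            j = valid_nbr[i, k]
            if j >= 0:
                nb_idx[nn] = j
                nn += 1
        if drawn <= 64:
            # small flows (wavefront founding): exact random allocation of
            # each copy to a neighbor quota slot, preserving full founder
            # sampling noise
            base = E // nn
            extra = E - base * nn
            rem_slots = 0
            for kk in range(nn):
                q_tot[kk] = 2 * (base + (1 if kk < extra else 0))
                rem_slots += q_tot[kk]
                imm_census[nb_idx[kk]] += q_tot[kk] // 2
            for l in range(A):
                for _ in range(emig[l]):
                    u = np.random.randint(0, rem_slots)
                    acc = 0
                    for kk in range(nn):
                        acc += q_tot[kk]
                        if u < acc:
                            imm_copies[nb_idx[kk], l] += 1
                            q_tot[kk] -= 1
                            rem_slots -= 1
                            break
            continue
        rot = np.random.randint(0, nn)  # rotate remainder slots
        for kk in range(nn):
            q_tot[kk] = 0
            last_l[kk] = -1
        for l in range(A):
            e = emig[l]
            if e == 0:
                continue
            base = e // nn
            extra = e - base * nn
            for kk in range(nn):
                q = base + (1 if (kk - l - rot) % nn < extra else 0)
                if q > 0:
                    imm_copies[nb_idx[kk], l] += q
                    q_tot[kk] += q
                    last_l[kk] = l
        # parity repair: each neighbor must receive whole individuals
        pending = -1
        for kk in range(nn):
            if q_tot[kk] % 2 == 1:
                j = nb_idx[kk]
                if pending < 0:
                    pending = last_l[kk]
                    imm_copies[j, pending] -= 1
                    q_tot[kk] -= 1
                else:
                    imm_copies[j, pending] += 1
                    q_tot[kk] += 1
                    pending = -1
        for kk in range(nn):
            imm_census[nb_idx[kk]] += q_tot[kk] // 2
    for i in range(H):
        if imm_census[i] > 0:
            census[i] += imm_census[i]
            for l in range(A):
                copies[i, l] += imm_copies[i, l]


@njit(cache=True)
def _regulate_select_resample_gen(
    census, copies, zone, k_zone, r_zone, s_cell, s, sel_code, p_buf
):
    """Logistic regulation, selection and Wright–Fisher resampling."""
    H, A = copies.shape
    for i in range(H):
        tot = 0
        for l in range(A):
            tot += copies[i, l]
        if tot == 0:
            census[i] = 0
            continue
        z = zone[i]
        n_new = _grow_scalar(census[i], r_zone[z], k_zone[z])
        census[i] = n_new
        if n_new == 0:
            for l in range(A):
                copies[i, l] = 0
            continue
        # monomorphic cells need no sampling
        occ = 0
        last = -1
        for l in range(A):
            if copies[i, l] > 0:
                occ += 1
                last = l
        if occ == 1:
            for l in range(A):
                copies[i, l] = 0
            copies[i, last] = 2 * n_new
            continue
        for l in range(A):
            p_buf[l] = copies[i, l] / tot
        _apply_selection(p_buf, s_cell[i], s, sel_code)
        # conditional binomial chain for multinomial(2 n_new, p_buf)
        take = 2 * n_new
        remp = 1.0
        for l in range(A):
            pl = p_buf[l]
            if pl <= 0.0:
                copies[i, l] = 0
                continue
            if take == 0:
                copies[i, l] = 0
                continue
            if l == last or remp <= pl:
                copies[i, l] = take
                take = 0
                continue
            q = pl / remp
            if q > 1.0:
                q = 1.0
            mu = take * q
            var = mu * (1.0 - q)
            if var > 30.0:
                # Gaussian fast path: exact mean/variance; higher-moment
                # error is negligible at this scale and drift dynamics
                # depend only on the first two moments
                x = np.int64(np.floor(mu + np.sqrt(var) * _std_normal_icdf() + 0.5))
                if x < 0:
                    x = np.int64(0)
                if x > take:
                    x = take
            else:
                x = np.random.binomial(take, q)
            copies[i, l] = x
            take -= x
            remp -= pl


# --------------------------------------------------------------------------
# python-facing operations
# --------------------------------------------------------------------------


def grow(n: int, r: float, k: float) -> int:
    """Logistic census update ``round(N + r N (1 - N/K))``, clamped to [0, K]."""
    if n < 0 or k < 0:
        raise ValueError("census and capacity must be non-negative")
    return int(_grow_scalar(float(n), float(r), float(int(round(k)))))


def selection_update(
    p: np.ndarray,
    model: str = "sos",
    s: float = 0.0,
    latitude: float | None = None,
    lat_range: tuple[float, float] = (18.0, 55.0),
) -> np.ndarray:
    """Deterministic selection update of a lineage frequency vector.

    ``model`` is one of ``sos`` (uniform heterozygote advantage), ``los``
    (heterozygote advantage scaled linearly with latitude: twice as strong
    at the southern edge of ``lat_range``, zero at the northern edge) or
    ``nfds`` (negative frequency dependence).  With ``s=0`` all three
    reduce to the identity.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative frequencies")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    out = p.copy()
    if model == "los":
        if latitude is None:
            raise ValueError("los selection needs a latitude")
        s_eff = s * los_profile(latitude, lat_range)
        _apply_selection(out, s_eff, 0.0, SEL_SOS)
    elif model == "sos":
        _apply_selection(out, s, 0.0, SEL_SOS)
    elif model == "nfds":
        _apply_selection(out, 0.0, s, SEL_NFDS)
    else:
        raise ValueError(f"unknown selection model {model!r}")
    return out / out.sum()


def los_profile(latitude: float, lat_range: tuple[float, float] = (18.0, 55.0)) -> float:
    """Latitudinal scaling of the selection coefficient (mean 1 over the map)."""
    lo, hi = lat_range
    return 2.0 * (hi - latitude) / (hi - lo)


class _BoundSim:
    """Arrays binding a (map, params, schedule) triple for the kernels."""

    def __init__(self, dememap: DemeMap, params: ScenarioParams, schedule: BarrierSchedule):
        self.dememap = dememap
        self.params = params
        self.schedule = schedule
        self.H = dememap.n_rows * dememap.n_cols
        self.zone = dememap.zone.reshape(-1).astype(np.int64)
        cap = capacity_by_zone(params)
        mig = migration_by_zone(params)
        gro = growth_by_zone(params)
        self.k_zone = np.zeros(5)
        self.m_zone = np.zeros(5)
        self.r_zone = np.zeros(5)
        for z in range(1, 5):
            self.k_zone[z] = float(int(round(cap.get(z, 0.0))))
            self.m_zone[z] = mig.get(z, 0.0)
            self.r_zone[z] = gro.get(z, 0.0)
        if params.selection_model == "los":
            prof = np.array(
                [los_profile(lat, (dememap.latitude[-1], dememap.latitude[0]))
                 for lat in dememap.latitude]
            )
            self.s_cell = np.repeat(params.s * prof, dememap.n_cols)
            self.sel_code = SEL_SOS
        elif params.selection_model == "sos":
            self.s_cell = np.full(self.H, params.s)
            self.sel_code = SEL_SOS
        else:
            self.s_cell = np.zeros(self.H)
            self.sel_code = SEL_NFDS
        # work buffers
        A = params.A
        self.imm_census = np.zeros(self.H, dtype=np.int64)
        self.imm_copies = np.zeros((self.H, A), dtype=np.int64)
        self.emig = np.zeros(A, dtype=np.int64)
        self.nb_idx = np.zeros(4, dtype=np.int64)
        self.q_tot = np.zeros(4, dtype=np.int64)
        self.last_l = np.zeros(4, dtype=np.int64)
        self.p_buf = np.zeros(A, dtype=np.float64)
        self._phase_gen = None
        self._mult = None
        self.valid_nbr = np.full((self.H, 4), -1, dtype=np.int64)
        self.m_eff = np.zeros(5)
        self.k_eff = np.zeros(5)

    def bind_generation(self, generation: int) -> None:
        """Refresh barrier multipliers / neighbor validity if needed."""
        mult = self.schedule.zone_multipliers(generation)
        if self._mult is not None and np.array_equal(mult, self._mult):
            return
        self._mult = mult
        self.m_eff = self.m_zone * mult
        self.k_eff = np.where(mult > 0, self.k_zone, 0.0)
        nr, nc = self.dememap.n_rows, self.dememap.n_cols
        self.valid_nbr.fill(-1)
        for r in range(nr):
            for c in range(nc):
                i = r * nc + c
                if mult[self.zone[i]] <= 0:
                    continue
                for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc:
                        j = rr * nc + cc
                        if mult[self.zone[j]] > 0:
                            self.valid_nbr[i, k] = j


def init_state(
    dememap: DemeMap, params: ScenarioParams, seed: int | np.random.Generator = 0
) -> SimState:
    """Found the origin deme(s) at carrying capacity from the ancestral pool.

    Each of the ``2K`` gene copies of an origin deme is drawn uniformly
    from the ``A`` ancestral lineages; for two-route scenarios both origin
    demes are seeded from the same ancestral pool (common source
    population), giving identical expected frequencies.
    """
    if params.A < 1:
        raise ValueError("need at least one ancestral lineage")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    census = np.zeros((dememap.n_rows, dememap.n_cols), dtype=np.int64)
    copies = np.zeros((dememap.n_rows, dememap.n_cols, params.A), dtype=np.int64)
    cap = capacity_by_zone(params)
    for cell in origin_cells(params.scenario, dememap):
        k = int(round(cap.get(int(dememap.zone[cell]), 0.0)))
        census[cell] = k
        if k > 0:
            copies[cell] = rng.multinomial(2 * k, np.full(params.A, 1.0 / params.A))
    return SimState(0, census, copies)


def _flat_views(state: SimState):
    H = state.census.size
    return state.census.reshape(H), state.copies.reshape(H, -1)


def migrate(
    state: SimState,
    params: ScenarioParams,
    dememap: DemeMap,
    schedule: BarrierSchedule,
    seed: int | None = None,
) -> SimState:
    """One round of emigration; returns a new state (same generation).

    Gene copies are conserved: every copy removed from a source deme
    arrives in a neighbor.  Empty habitable demes can be colonized.
    """
    out = state.copy()
    sim = _BoundSim(dememap, params, schedule)
    sim.bind_generation(state.generation)
    if seed is not None:
        _seed_kernel(seed % 2**31)
    census, copies = _flat_views(out)
    _migrate_gen(
        census, copies, sim.zone, sim.valid_nbr, sim.m_eff,
        sim.imm_census, sim.imm_copies, sim.emig,
        sim.nb_idx, sim.q_tot, sim.last_l,
    )
    return out


def step(
    state: SimState,
    params: ScenarioParams,
    dememap: DemeMap,
    schedule: BarrierSchedule,
    seed: int | None = None,
) -> SimState:
    """Advance one generation: migration, regulation, selection, resampling."""
    out = state.copy()
    sim = _BoundSim(dememap, params, schedule)
    if seed is not None:
        _seed_kernel(seed % 2**31)
    _step_inplace(out, sim)
    return out


def _step_inplace(state: SimState, sim: _BoundSim) -> None:
    sim.bind_generation(state.generation)
    census, copies = _flat_views(state)
    _migrate_gen(
        census, copies, sim.zone, sim.valid_nbr, sim.m_eff,
        sim.imm_census, sim.imm_copies, sim.emig,
        sim.nb_idx, sim.q_tot, sim.last_l,
    )
    _regulate_select_resample_gen(
        census, copies, sim.zone, sim.k_eff, sim.r_zone,
        sim.s_cell, sim.params.s, sim.sel_code, sim.p_buf,
    )
    state.generation += 1


def run_simulation(
    dememap: DemeMap,
    params: ScenarioParams,
    schedule: BarrierSchedule | None = None,
    seed: int = 0,
    n_generations: int | None = None,
) -> SimState:
    """Run a scenario for its full duration and return the final state."""
    from .landscape import barrier_schedule

    if schedule is None:
        schedule = barrier_schedule(params.scenario, params.t1, params.t2)
    ss = np.random.SeedSequence(seed)
    init_seed, kernel_seed = ss.generate_state(2)
    state = init_state(dememap, params, np.random.default_rng(init_seed))
    _seed_kernel(int(kernel_seed) % 2**31)
    sim = _BoundSim(dememap, params, schedule)
    total = params.total_generations if n_generations is None else n_generations
    for _ in range(total):
        _step_inplace(state, sim)
    return state


def sample_populations(state: SimState, sample_spec, seed: int | np.random.Generator = 0):
    """Draw population samples from the final state.

    For each population of the spec, ``2n`` gene copies are drawn
    multinomially (with replacement) from its deme's final lineage
    frequencies — real sample sizes can exceed the deme census.  Raises
    :class:`SamplingError` naming the population if its deme is empty.
    """
    from .sumstats import PopulationSample

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = []
    for pop in sample_spec:
        cell = (pop.row, pop.col)
        tot = int(state.copies[cell].sum())
        if tot == 0 or state.census[cell] == 0:
            raise SamplingError(
                f"population {pop.id!r}: deme {cell} is empty at generation "
                f"{state.generation}"
            )
        p = state.copies[cell] / tot
        counts = rng.multinomial(2 * pop.n, p)
        samples.append(
            PopulationSample(
                id=pop.id, latitude=pop.latitude, group=pop.group, counts=counts
            )
        )
    return samples
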