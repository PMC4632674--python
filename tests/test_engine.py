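"""Forward-simulation engine: growth, selection, migration, drift."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import routesim as rs
from routesim.engine import (
    SamplingError,
    grow,
    init_state,
    migrate,
    run_simulation,
    sample_populations,
    selection_update,
    step,
)
from routesim.landscape import barrier_schedule
from routesim.scenarios import ScenarioParams
from routesim.sumstats import gene_diversity


def make_params(scenario="southern", selection="sos", **kw):
    base = dict(
        A=10, s=0.0, t1=1000,
        N_nea=1000.0, m_nea=0.05, r_nea=0.1,
        N_sea=1000.0, m_sea=0.05, r_sea=0.1,
        N_bar=1000.0, m_bar=0.05, r_bar=0.1,
    )
    if scenario == "overlapping":
        base["t2"] = 2700
    base.update(kw)
    return ScenarioParams(scenario=scenario, selection_model=selection, **base)


def selection_oracle_sos(p, s):
    """Genotype-enumeration oracle for heterozygote advantage.

    Hardy-Weinberg genotype frequencies, homozygotes weighted by 1-s,
    allele frequencies recomputed from the post-selection genotypes.
    """
    p = np.asarray(p, dtype=float)
    k = len(p)
    geno = np.outer(p, p)
    w = np.ones((k, k))
    np.fill_diagonal(w, 1.0 - s)
    post = geno * w
    post /= post.sum()
    return post.sum(axis=1)


class TestGrow:
    def test_logistic_closed_form(self):
        assert grow(1000, 0.1, 5000) == 1080

    def test_capacity_is_fixed_point(self):
        assert grow(5000, 0.17, 5000) == 5000

    def test_extinction_absorbing(self):
        assert grow(0, 0.1, 5000) == 0

    def test_zero_capacity_collapses(self):
        assert grow(123, 0.1, 0) == 0

    def test_overshoot_clamped_to_capacity(self):
        # census above K (immigration overflow) regulates back to K
        assert grow(5200, 0.1, 5000) == 5000


class TestSelectionUpdate:
    def test_frozen_sos_example(self):
        p = selection_update([0.8, 0.2], "sos", s=0.025)
        expected = 0.8 * (1 - 0.025 * 0.8) / (1 - 0.025 * 0.68)
        assert abs(p[0] - expected) < 1e-12
        assert abs(p[0] - 0.7975584944048831) < 1e-12

    def test_symmetric_point_is_fixed(self):
        for model in ("sos", "nfds"):
            p = selection_update([0.5, 0.5], model, s=0.02, latitude=30.0)
            assert np.allclose(p, [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("model", ["sos", "los", "nfds"])
    def test_neutral_when_s_zero(self, model):
        p0 = np.array([0.1, 0.2, 0.3, 0.4])
        p = selection_update(p0, model, s=0.0, latitude=25.0)
        assert np.allclose(p, p0, atol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(2, 5),
        st.integers(0, 2**31 - 1),
        st.floats(0.0, 0.025),
    )
    def test_sos_matches_enumeration_oracle(self, k, seed, s):
        """Marginal-fitness update equals full genotype enumeration."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k))
        got = selection_update(p, "sos", s=s)
        want = selection_oracle_sos(p, s)
        assert np.allclose(got, want, atol=1e-12)

    def test_los_scales_with_latitude(self):
        p = np.array([0.8, 0.2])
        south = selection_update(p, "los", s=0.02, latitude=18.0)
        north = selection_update(p, "los", s=0.02, latitude=55.0)
        # selection twice as strong at the southern edge, zero at the north
        assert np.allclose(north, p, atol=1e-12)
        assert np.allclose(south, selection_update(p, "sos", s=0.04), atol=1e-12)

    def test_nfds_disadvantages_common_lineage(self):
        p = selection_update([0.7, 0.2, 0.1], "nfds", s=0.02)
        assert p[0] < 0.7 and p[2] > 0.1
        assert abs(p.sum() - 1.0) < 1e-12

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            selection_update([0.9, -0.1, 0.2], "sos", s=0.01)
        with pytest.raises(ValueError):
            selection_update([0.5, 0.4], "sos", s=0.01)


class TestInitState:
    def test_origin_at_capacity_with_ancestral_pool(self, small_map):
        params = make_params(A=10, N_sea=1000.0)
        state = init_state(small_map, params, seed=5)
        origin = rs.origin_cells("southern", small_map)[0]
        assert state.census[origin] == 1000
        assert state.copies[origin].sum() == 2000
        assert (state.copies[origin] > 0).sum() <= 10
        assert state.census.sum() == 1000  # all other demes empty

    def test_single_lineage_is_monomorphic(self, small_map):
        params = make_params(A=1)
        state = init_state(small_map, params, seed=5)
        origin = rs.origin_cells("southern", small_map)[0]
        assert gene_diversity(state.copies[origin]) == 0.0

    def test_pincer_seeds_both_origins_from_common_pool(self, small_map):
        params = make_params("pincer", A=20, N_nea=2000.0, N_sea=2000.0)
        state = init_state(small_map, params, seed=5)
        cells = rs.origin_cells("pincer", small_map)
        for cell in cells:
            assert state.census[cell] == 2000
        # same ancestral pool: expected frequencies are uniform in both
        for cell in cells:
            p = state.copies[cell] / state.copies[cell].sum()
            assert abs(p.mean() - 1.0 / 20) < 1e-12

    def test_invalid_lineage_count_raises(self, small_map):
        with pytest.raises(ValueError):
            make_params(A=0)


class TestMigrate:
    def test_zero_migration_is_identity(self, small_map):
        params = make_params(m_nea=0.0, m_sea=0.0, m_bar=0.0)
        sched = barrier_schedule("southern", params.t1)
        state = init_state(small_map, params, seed=1)
        out = migrate(state, params, small_map, sched, seed=2)
        assert np.array_equal(out.copies, state.copies)

    def test_gene_copies_conserved(self, small_map):
        params = make_params(m_nea=0.2, m_sea=0.2, m_bar=0.2)
        sched = barrier_schedule("southern", params.t1)
        state = init_state(small_map, params, seed=1)
        before = state.total_copies()
        out = migrate(state, params, small_map, sched, seed=2)
        assert out.total_copies() == before
        assert (out.copies >= 0).all()
        assert np.array_equal(out.copies.sum(axis=2), 2 * out.census)

    def test_colonizes_empty_neighbors(self, small_map):
        params = make_params(m_sea=0.2)
        sched = barrier_schedule("southern", params.t1)
        state = init_state(small_map, params, seed=1)
        out = migrate(state, params, small_map, sched, seed=2)
        origin = rs.origin_cells("southern", small_map)[0]
        occupied = np.argwhere(out.census > 0)
        assert len(occupied) > 1
        for cell in map(tuple, occupied):
            assert abs(cell[0] - origin[0]) + abs(cell[1] - origin[1]) <= 1

    def test_uniform_state_keeps_expected_frequencies(self, small_map):
        """With identical frequencies everywhere, migration leaves the
        per-deme expected frequencies unchanged (symmetry)."""
        params = make_params(A=4, m_nea=0.2, m_sea=0.2, m_bar=0.2)
        sched = barrier_schedule("southern", 1000)
        state = init_state(small_map, params, seed=1)
        # fill every habitable cell with the same composition
        comp = np.array([500, 300, 150, 50], dtype=np.int64)
        for r in range(small_map.n_rows):
            for c in range(small_map.n_cols):
                if small_map.zone[r, c] in (1, 2):  # skip closed zone-3
                    state.copies[r, c] = comp
                    state.census[r, c] = comp.sum() // 2
                else:
                    state.copies[r, c] = 0
                    state.census[r, c] = 0
        reps = 200
        acc = np.zeros(4)
        cell = (9, 5)
        for rep in range(reps):
            out = migrate(state, params, small_map, sched, seed=rep)
            acc += out.copies[cell] / out.copies[cell].sum()
        p_hat = acc / reps
        p0 = comp / comp.sum()
        se = np.sqrt(p0 * (1 - p0) / (comp.sum() * reps))
        assert (np.abs(p_hat - p0) < 5 * se + 1e-3).all()


class TestStep:
    def test_isolated_deme_reduces_to_wright_fisher(self, small_map):
        params = make_params(m_nea=0.0, m_sea=0.0, m_bar=0.0, N_sea=500.0)
        sched = barrier_schedule("southern", params.t1)
        state = init_state(small_map, params, seed=1)
        origin = rs.origin_cells("southern", small_map)[0]
        out = step(state, params, small_map, sched, seed=9)
        assert out.generation == 1
        assert out.census[origin] == 500
        assert out.copies[origin].sum() == 1000
        assert out.census.sum() == 500

    def test_empty_cells_stay_empty_without_immigrants(self, small_map):
        params = make_params(m_nea=0.0, m_sea=0.0, m_bar=0.0)
        sched = barrier_schedule("southern", params.t1)
        state = init_state(small_map, params, seed=1)
        out = step(state, params, small_map, sched, seed=9)
        assert (out.census > 0).sum() == 1

    def test_same_seed_identical_trajectory(self, small_map):
        params = make_params(m_sea=0.1, s=0.01)
        a = run_simulation(small_map, params, seed=42, n_generations=50)
        b = run_simulation(small_map, params, seed=42, n_generations=50)
        assert np.array_equal(a.copies, b.copies)

    def test_copy_census_consistency_through_steps(self, small_map):
        params = make_params(m_sea=0.2, m_nea=0.2, m_bar=0.2, s=0.01)
        state = run_simulation(small_map, params, seed=3, n_generations=40)
        assert np.array_equal(state.copies.sum(axis=2), 2 * state.census)


class TestRunSimulation:
    def test_southern_north_empty_before_t1(self, small_map):
        params = make_params(t1=400, m_sea=0.2)
        state = run_simulation(small_map, params, seed=11, n_generations=399)
        assert state.census[(small_map.zone == 1)].sum() == 0
        assert state.census[(small_map.zone == 4)].sum() == 0
        assert state.census[(small_map.zone == 2)].sum() > 0

    def test_overlapping_zone4_empty_before_t1(self, small_map):
        params = make_params(
            "overlapping", t1=600, t2=2700, m_nea=0.2, m_sea=0.2, m_bar=0.2
        )
        state = run_simulation(small_map, params, seed=11, n_generations=599)
        assert state.census[small_map.zone == 4].sum() == 0
        assert state.census[small_map.zone == 1].sum() > 0

    @pytest.mark.parametrize("selection", ["los", "nfds"])
    def test_alternative_selection_models_run(self, small_map, selection):
        params = make_params(
            selection=selection, s=0.02, t1=200, m_sea=0.2, m_nea=0.2, m_bar=0.2
        )
        state = run_simulation(small_map, params, seed=5, n_generations=300)
        assert state.census.sum() > 0
        assert np.array_equal(state.copies.sum(axis=2), 2 * state.census)

    def test_high_migration_colonizes_everything(self, small_map):
        params = make_params(
            t1=500, m_nea=0.2, m_sea=0.2, m_bar=0.2,
            N_nea=2000.0, N_sea=2000.0, N_bar=2000.0,
        )
        state = run_simulation(small_map, params, seed=11)
        habitable = small_map.zone != 0
        assert (state.census[habitable] > 0).all()


class TestSamplePopulations:
    def test_sample_size_in_gene_copies(self, small_map, small_sites):
        params = make_params(t1=500, m_sea=0.2, m_nea=0.2, m_bar=0.2)
        state = run_simulation(small_map, params, seed=2)
        samples = sample_populations(state, small_sites, seed=3)
        assert len(samples) == 19
        by_id = {s.id: s for s in samples}
        site = small_sites[0]
        assert by_id[site.id].n_copies == 2 * site.n

    def test_monomorphic_deme_gives_monomorphic_sample(self, small_map, small_sites):
        params = make_params(A=1, t1=500, m_sea=0.2, m_nea=0.2, m_bar=0.2)
        state = run_simulation(small_map, params, seed=2)
        samples = sample_populations(state, small_sites, seed=3)
        assert all(np.count_nonzero(s.counts) == 1 for s in samples)

    def test_deterministic_given_seed(self, small_map, small_sites):
        params = make_params(t1=500, m_sea=0.2, m_nea=0.2, m_bar=0.2)
        state = run_simulation(small_map, params, seed=2)
        a = sample_populations(state, small_sites, seed=3)
        b = sample_populations(state, small_sites, seed=3)
        assert all(np.array_equal(x.counts, y.counts) for x, y in zip(a, b))

    def test_empty_deme_raises_with_population_name(self, small_map, small_sites):
        params = make_params(t1=1999)  # north never sampled in time
        state = init_state(small_map, params, seed=1)
        with pytest.raises(SamplingError, match=small_sites[0].id):
            sample_populations(state, small_sites, seed=3)


class TestDriftCalibration:
    def test_neutral_gene_diversity_decay(self, small_map):
        """Mean gene diversity of an isolated deme decays as
        H0 (1 - 1/2N)^t (neutral Wright-Fisher)."""
        N = 500
        params = make_params(
            A=4, s=0.0, m_nea=0.0, m_sea=0.0, m_bar=0.0,
            N_nea=0.0, N_bar=0.0, N_sea=float(N), r_sea=0.1,
        )
        origin = rs.origin_cells("southern", small_map)[0]
        # the founding multinomial draw from the ancestral pool is itself
        # one round of sampling, so H starts at h0 (1 - 1/2N)
        h0 = (1.0 - 4 * 0.25**2) * (1.0 - 1.0 / (2 * N))
        reps = 1000
        for t in (10, 100, 500):
            hs = np.empty(reps)
            for rep in range(reps):
                stt = run_simulation(small_map, params, seed=rep, n_generations=t)
                c = stt.copies[origin]
                p = c / c.sum()
                hs[rep] = 1.0 - np.square(p).sum()
            expected = h0 * (1.0 - 1.0 / (2 * N)) ** t
            se = hs.std(ddof=1) / np.sqrt(reps)
            assert abs(hs.mean() - expected) < 3 * se, f"t={t}"

    def test_sos_equilibrium_evens_frequencies(self, small_map):
        """Symmetric overdominance holds all lineages at the uniform point.

        At stationarity the selection-drift balance is an
        Ornstein-Uhlenbeck process around 1/k with restoring rate
        lambda = s/k and per-generation variance p(1-p)/2N, hence a
        stationary standard deviation sqrt(p(1-p)/(2N * 2 lambda))
        (about 0.039 here, vs ~0.12 drifting freely without selection).
        """
        N, s, k = 5000, 0.025, 4
        params = make_params(
            A=k, s=s, m_nea=0.0, m_sea=0.0, m_bar=0.0,
            N_nea=0.0, N_bar=0.0, N_sea=float(N),
        )
        origin = rs.origin_cells("southern", small_map)[0]
        reps = 40
        devs = []
        for rep in range(reps):
            stt = run_simulation(small_map, params, seed=rep, n_generations=2000)
            p = stt.copies[origin] / stt.copies[origin].sum()
            devs.extend(p - 1.0 / k)
        devs = np.array(devs)
        sd_pred = np.sqrt((0.25 * 0.75 / (2 * N)) / (2 * s / k))
        assert abs(devs.mean()) < 0.01
        assert 0.7 * sd_pred < devs.std() < 1.4 * sd_pred
        # virtually all frequencies stay within ~2.6 stationary SDs of 1/k
        assert (np.abs(devs) < 0.10).mean() >= 0.95

    def test_island_model_fst_order_of_magnitude(self, small_map):
        """Quasi-equilibrium F_ST of a compact block of demes is within a
        factor two of the island-model value 1/(1+4Nm)."""
        N, m = 200, 0.2
        params = make_params(
            A=50, s=0.0, t1=500,
            N_nea=float(N), m_nea=m, r_nea=0.2,
            N_sea=float(N), m_sea=m, r_sea=0.2,
            N_bar=float(N), m_bar=m, r_bar=0.2,
        )
        block = [(r, c) for r in (9, 10) for c in (3, 4, 5, 6, 7)]
        ratios = []
        for rep in range(20):
            stt = run_simulation(small_map, params, seed=rep, n_generations=300)
            counts = np.array([stt.copies[cell] for cell in block], dtype=float)
            p = counts / counts.sum(axis=1, keepdims=True)
            hs = 1.0 - np.square(p).sum(axis=1)
            pbar = counts.sum(axis=0) / counts.sum()
            ht = 1.0 - np.square(pbar).sum()
            ratios.append(1.0 - hs.mean() / ht)
        fst = float(np.mean(ratios))
        expected = 1.0 / (1.0 + 4 * N * m)
        assert expected / 2 < fst < expected * 2
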