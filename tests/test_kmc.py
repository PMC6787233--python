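import numpy as np
import pytest
from scipy import stats

from excitube.kmc import (
    STATUS_ALIVE,
    STATUS_ANNIHILATED,
    STATUS_CENSORED,
    STATUS_DECAYED,
    SimParams,
    ThermalParams,
    annihilation_sweep,
    detailed_balance_ratio,
    plant_excitons,
    run_ensemble,
    run_from_state,
    run_realization,
    state_from_positions,
)
from excitube.lattice import Layer, TubeSystem

SINGLE = TubeSystem.single_wall()
SMALL = TubeSystem.single_wall(10, 100)
DOUBLE = TubeSystem.double_wall()


class TestSimParams:
    def test_probability_budget_enforced(self):
        with pytest.raises(ValueError, match="budget"):
            SimParams(density=20, t_max_ps=1.0, hop_prob=0.999, k_oi=0.5)

    def test_density_below_one_rejected(self):
        with pytest.raises(ValueError):
            SimParams(density=0.5, t_max_ps=1.0)

    def test_table_defaults(self):
        p = SimParams.double_wall(density=625, t_max_ps=30)
        assert (p.hop_prob, p.ann_radius) == (0.04, 3.0)
        assert (p.k_io, p.k_oi) == (0.0013, 0.0031)
        assert p.lifetime_ps == 33.0
        q = SimParams.inner_tube(density=20, t_max_ps=30)
        assert q.lifetime_ps == 58.0 and q.k_io == q.k_oi == 0.0


class TestPlanting:
    def test_single_exciton_at_extreme_density(self):
        p = SimParams.inner_tube(density=30_000, t_max_ps=1.0)
        state = plant_excitons(SINGLE, p, seed=1)
        assert state.n_excitons == 1

    def test_experimental_density_all_distinct(self):
        p = SimParams.inner_tube(density=20, t_max_ps=1.0)
        state = plant_excitons(SINGLE, p, seed=2, sweep=False)
        assert state.n_in == 1500
        lay, x, y = state.positions()
        assert len({(int(a), int(b)) for a, b in zip(x, y)}) == 1500

    def test_full_occupancy_boundary(self):
        p = SimParams.inner_tube(density=1.0, t_max_ps=1.0, ann_radius=0.0)
        state = plant_excitons(SMALL, p, seed=3)
        assert state.n_in == SMALL.inner.n_sites
        assert state.alive_count() == SMALL.inner.n_sites

    def test_zero_time_sweep_thins_dense_planting(self):
        p = SimParams.inner_tube(density=5, t_max_ps=1.0)
        state = plant_excitons(SINGLE, p, seed=4)
        assert state.alive_count() < state.n_excitons
        assert state.n_events > 0

    def test_double_wall_same_density_both_layers(self):
        p = SimParams.double_wall(density=625, t_max_ps=1.0)
        state = plant_excitons(DOUBLE, p, seed=5, sweep=False)
        assert state.n_in == round(30_000 / 625)
        assert state.n_out == round(55_000 / 625)


class TestMovement:
    def test_frozen_dynamics_leaves_positions_invariant(self):
        p = SimParams.inner_tube(
            density=100, t_max_ps=1.0, hop_prob=0.0, lifetime_ps=1e9, ann_radius=0.0
        )
        res = run_realization(SMALL, p, np.array([0.0, 1.0]), seed=6)
        assert np.all(res.records.n_hops == 0)
        assert np.all(res.records.ux == 0) and np.all(res.records.uy == 0)

    def test_hop_every_step_when_certain(self):
        p = SimParams.inner_tube(
            density=1000, t_max_ps=1.0, hop_prob=1.0, lifetime_ps=1e9, ann_radius=0.0
        )
        res = run_realization(SINGLE, p, np.array([0.0, 1.0]), seed=7)
        assert np.all(res.records.n_hops == 1000)

    def test_hop_count_binomial_mean(self):
        # single exciton, 1000 steps: hops ~ Binomial(1000, 0.04)
        p = SimParams.inner_tube(
            density=30_000,
            t_max_ps=1.0,
            lifetime_ps=1e9,
            ann_radius=0.0,
            n_real=200,
            seed=8,
        )
        ens = run_ensemble(SINGLE, p, np.array([0.0, 1.0]))
        hops = ens.records.n_hops
        sem = np.sqrt(1000 * 0.04 * 0.96 / len(hops))
        assert abs(hops.mean() - 40.0) < 5 * sem

    def test_transfer_blocked_on_fully_occupied_wall(self):
        # both walls fully occupied, no hopping: every transfer target is
        # occupied, so no exciton may change wall
        small_double = TubeSystem.double_wall(10, 18, 50)
        p = SimParams.double_wall(
            density=1.0,
            t_max_ps=0.1,
            hop_prob=0.0,
            lifetime_ps=1e9,
            ann_radius=0.0,
            k_io=0.004,
            k_oi=0.004,
        )
        res = run_realization(small_double, p, np.array([0.0, 0.1]), seed=9)
        assert np.all(res.records.n_transfers == 0)
        assert np.array_equal(res.records.current_layer, res.records.origin_layer)


class TestDecay:
    def test_pure_decay_terminal_times_exponential(self):
        p = SimParams.inner_tube(
            density=30,
            t_max_ps=10.0,
            lifetime_ps=1.0,
            hop_prob=0.0,
            ann_radius=0.0,
        )
        res = run_realization(SINGLE, p, np.array([0.0, 10.0]), seed=10)
        rec = res.records
        t = rec.term_time_ps[rec.status == STATUS_DECAYED]
        assert len(t) > 900
        # truncated exponential on [0, 10*tau]
        cdf = lambda x: (1 - np.exp(-x)) / (1 - np.exp(-10.0))
        assert stats.kstest(t, cdf).pvalue > 0.01

    def test_alive_curve_matches_exponential(self):
        p = SimParams.inner_tube(
            density=30,
            t_max_ps=3.0,
            lifetime_ps=1.0,
            hop_prob=0.0,
            ann_radius=0.0,
            n_real=5,
            seed=11,
        )
        times = np.array([0.0, 1.0, 2.0, 3.0])
        ens = run_ensemble(SINGLE, p, times)
        alive = ens.counts16.sum(axis=2).mean(axis=0)
        expect = 1000 * np.exp(-times)
        tol = 4 * np.sqrt(1000 * np.exp(-times) / 5)
        assert np.all(np.abs(alive - expect) < np.maximum(tol, 6))


class TestAnnihilationSweep:
    def _params(self, **kw):
        kw.setdefault("density", 500)
        kw.setdefault("t_max_ps", 1.0)
        kw.setdefault("hop_prob", 0.0)
        kw.setdefault("lifetime_ps", 1e9)
        return SimParams.inner_tube(**kw)

    def test_pair_within_radius_one_deleted(self):
        state = state_from_positions(SMALL, self._params(), [(0, 0), (0, 2)], seed=1)
        annihilation_sweep(state)
        a = state.arrays
        assert sorted(a["status"]) == [STATUS_ALIVE, STATUS_ANNIHILATED]
        survivor = int(np.flatnonzero(a["status"] == STATUS_ALIVE)[0])
        assert a["n_surv"][survivor] == 1
        assert a["n_tot"][survivor] == 1
        assert a["n_same"][survivor] == 1

    def test_distance_exactly_radius_is_safe(self):
        # strict inequality: 'closer than' the annihilation radius
        state = state_from_positions(SMALL, self._params(), [(0, 0), (0, 3)], seed=2)
        annihilation_sweep(state)
        assert state.alive_count() == 2
        assert state.n_events == 0

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_triple_cluster_resolved_in_one_sweep(self, seed):
        # mutually violating triple: the sweep iterates until clear, so
        # exactly two deletions happen within the step and one exciton
        # participates in both sequential events
        state = state_from_positions(
            SMALL, self._params(), [(0, 0), (0, 2), (2, 1)], seed=seed
        )
        annihilation_sweep(state)
        a = state.arrays
        assert state.alive_count() == 1
        assert state.n_events == 2
        survivor = int(np.flatnonzero(a["status"] == STATUS_ALIVE)[0])
        # the second event always involves the survivor; the first one may
        # have deleted either of the other two
        assert a["n_surv"][survivor] in (1, 2)
        assert a["n_tot"].max() == 2
        assert np.sum(a["n_tot"] >= 1) == 3

    def test_no_violating_pair_survives_sweep(self):
        p = SimParams.inner_tube(density=3, t_max_ps=1.0)
        state = plant_excitons(TubeSystem.single_wall(20, 60), p, seed=4)
        lay, x, y = state.positions()
        dx = np.abs(x[:, None] - x[None, :])
        dx = np.minimum(dx, 20 - dx)
        dy = np.abs(y[:, None] - y[None, :])
        dy = np.minimum(dy, 60 - dy)
        d2 = dx**2 + dy**2
        np.fill_diagonal(d2, 10**6)
        assert d2.min() >= 9

    def test_cross_layer_pairs_never_annihilate(self):
        # one exciton per wall, radially adjacent: no annihilation possible
        p = SimParams.double_wall(
            density=50_000, t_max_ps=1.0, hop_prob=0.0, lifetime_ps=1e9
        )
        state = state_from_positions(
            DOUBLE, p, [(0, 0, 10), (1, 0, 10)], seed=5
        )
        annihilation_sweep(state)
        assert state.alive_count() == 2

    def test_single_exciton_never_annihilates(self):
        p = SimParams.inner_tube(density=30_000, t_max_ps=2.0, seed=12)
        res = run_realization(SINGLE, p, np.array([0.0, 2.0]))
        assert res.records.n_ann_total[0] == 0


class TestBookkeeping:
    def test_exciton_count_conservation(self, annihilating_ensemble):
        ens = annihilating_ensemble
        rec = ens.records
        n_real = ens.n_real
        for k, t in enumerate(ens.sample_times_ps[:-1]):
            alive = ens.counts16[:, k, :].sum()
            expected = (rec.term_time_ps > t).sum()
            assert alive == expected

    def test_every_loss_is_a_decay_or_deletion(self, annihilating_ensemble):
        rec = annihilating_ensemble.records
        planted = len(rec)
        terminal = np.bincount(rec.status, minlength=4)
        assert terminal[STATUS_ALIVE] == 0
        assert planted == terminal[1:].sum()

    def test_alive_count_non_increasing(self, annihilating_ensemble):
        alive = annihilating_ensemble.counts16.sum(axis=2)
        assert np.all(np.diff(alive, axis=1) <= 0)

    def test_single_wall_layers_conserved(self, annihilating_ensemble):
        rec = annihilating_ensemble.records
        assert np.all(rec.origin_layer == int(Layer.INNER))
        assert np.all(rec.term_layer == int(Layer.INNER))

    def test_determinism_same_seed(self):
        p = SimParams.inner_tube(density=100, t_max_ps=1.0, n_real=3, seed=77)
        a = run_ensemble(SMALL, p, np.array([0.0, 0.5, 1.0]))
        b = run_ensemble(SMALL, p, np.array([0.0, 0.5, 1.0]))
        assert np.array_equal(a.counts16, b.counts16)
        assert np.array_equal(a.records.term_time_ps, b.records.term_time_ps)

    def test_sem_shrinks_with_realizations(self):
        from excitube.observables import transient

        base = dict(density=50, t_max_ps=2.0, seed=31)
        t = np.array([0.0, 1.0, 2.0])
        small = run_ensemble(SMALL, SimParams.inner_tube(n_real=8, **base), t)
        big = run_ensemble(SMALL, SimParams.inner_tube(n_real=32, **base), t)
        s_small = transient(small, "abs_total").sem[1:].mean()
        s_big = transient(big, "abs_total").sem[1:].mean()
        assert s_big < s_small  # ~1/2 expected, allow noise


class TestDetailedBalance:
    def test_ratio_matches_measured_rates(self):
        th = ThermalParams()
        r = detailed_balance_ratio(th)
        assert r == pytest.approx(0.409, abs=0.005)
        assert 0.0013 / 0.0031 == pytest.approx(r, abs=0.015)

    def test_degenerate_gap_gives_unity(self):
        th = ThermalParams(delta_E_cm1=1e-12, kBT_cm1=200.0, dos_ratio=1.0)
        assert detailed_balance_ratio(th) == pytest.approx(1.0)

    def test_equilibrium_inner_fraction(self):
        # annihilation- and decay-free double wall: population settles at
        # k_oi/(k_io+k_oi) = 0.705 on the inner wall
        p = SimParams.double_wall(
            density=2000,
            t_max_ps=20.0,
            lifetime_ps=1e9,
            ann_radius=0.0,
            n_real=30,
            seed=13,
        )
        times = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        ens = run_ensemble(DOUBLE, p, times)
        inner_cells = [c for c in range(16) if (c >> 2) & 1 == 0]  # current = inner
        on_inner = ens.counts16[:, 1:, inner_cells].sum(axis=2)
        total = ens.counts16[:, 1:, :].sum(axis=2)
        frac = on_inner.sum(axis=1) / total.sum(axis=1)
        target = 0.0031 / 0.0044
        sem = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - target) < 3 * sem + 0.005
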