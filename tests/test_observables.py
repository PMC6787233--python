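import numpy as np
import pytest

from excitube.kmc import (
    SimParams,
    default_time_grid,
    run_ensemble,
    run_from_state,
    state_from_positions,
)
from excitube.lattice import Layer, TubeSystem
from excitube.observables import (
    OBSERVABLES,
    DiffusionEstimate,
    TransientSeries,
    count_matching,
    diffusion_constant,
    msd_series,
    multi_annihilation_fraction,
    peak_time,
    transfer_efficiency,
    transient,
)

SMALL = TubeSystem.single_wall(10, 100)
SINGLE = TubeSystem.single_wall()
DOUBLE = TubeSystem.double_wall()


class TestPredicates:
    def test_registry_consistency(self):
        for oid, p in OBSERVABLES.items():
            assert p.observable_id == oid
            if oid.startswith("eei"):
                assert p.min_annihilations == 1
            else:
                assert p.min_annihilations == 0

    def test_eei_requires_annihilation_flag(self):
        from excitube.observables import ObservablePredicate

        with pytest.raises(ValueError):
            ObservablePredicate("eei_bad", None, None, 0)

    def test_unknown_observable_rejected(self, annihilating_ensemble):
        with pytest.raises(ValueError, match="unknown observable"):
            transient(annihilating_ensemble, "no_such_signal")


class TestCountMatching:
    def _frozen(self, positions, seed=1):
        p = SimParams.inner_tube(
            density=500, t_max_ps=0.01, hop_prob=0.0, lifetime_ps=1e9
        )
        state = state_from_positions(SMALL, p, positions, seed=seed)
        return run_from_state(state, np.array([0.0, 0.01]))

    def test_collision_pair_counts(self):
        # two excitons 2 sites apart with R0 = 3: one annihilates at t=0,
        # the survivor is both the absorptive and the EEI signal
        res = self._frozen([(0, 0), (0, 2)])
        assert count_matching(res, "abs_total", 0.0) == 1
        assert count_matching(res, "eei_total", 0.0) == 1

    def test_separated_pair_gives_no_eei(self):
        res = self._frozen([(0, 0), (0, 50)])
        assert count_matching(res, "abs_total", 0.0) == 2
        assert count_matching(res, "eei_total", 0.0) == 0

    def test_unsampled_time_rejected(self):
        res = self._frozen([(0, 0), (0, 50)])
        with pytest.raises(ValueError, match="not sampled"):
            count_matching(res, "abs_total", 0.005)

    def test_cross_peak_prerequisites(self):
        # outer-origin pair annihilates on the outer wall; the survivor is
        # then moved to the inner wall by transfer: eei_cross_oi counts it
        p = SimParams.double_wall(
            density=50_000,
            t_max_ps=3.0,
            hop_prob=0.0,
            lifetime_ps=1e9,
            k_io=0.0,
            k_oi=0.01,
        )
        state = state_from_positions(DOUBLE, p, [(1, 5, 5), (1, 5, 7)], seed=3)
        res = run_from_state(state, np.array([0.0, 3.0]))
        rec = res.records
        assert rec.n_ann_same_origin.max() >= 1
        survivor = rec.status != 2
        assert rec.current_layer[survivor][0] == int(Layer.INNER)  # transferred
        assert count_matching(res, "eei_cross_oi", 3.0) == 1
        assert count_matching(res, "abs_cross_oi", 3.0) == 1


class TestTransient:
    def test_single_realization_has_zero_sem(self):
        p = SimParams.inner_tube(density=50, t_max_ps=1.0, seed=5)
        ens = run_ensemble(SMALL, p, np.array([0.0, 0.5, 1.0]))
        s = transient(ens, "abs_total")
        assert np.all(s.sem == 0)

    def test_abs_dominates_eei_pointwise(self, annihilating_ensemble):
        s_abs = transient(annihilating_ensemble, "abs_total")
        s_eei = transient(annihilating_ensemble, "eei_total")
        assert np.all(s_abs.values >= s_eei.values)

    def test_low_density_eei_peaks_at_interior_time(self):
        # delayed formation of the annihilation signal: excitons must
        # diffuse together before the first events occur
        p = SimParams.inner_tube(density=404, t_max_ps=30.0, n_real=20, seed=6)
        ens = run_ensemble(SINGLE, p, default_time_grid(30.0, 30))
        s = transient(ens, "eei_total")
        k = int(np.argmax(s.values))
        assert 0 < k < len(s) - 1
        assert peak_time(s) > 0.5

    def test_validation(self):
        with pytest.raises(ValueError):
            TransientSeries([0, 1], [1.0], [0.0])
        with pytest.raises(ValueError):
            TransientSeries([0, 0], [1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            TransientSeries([0, 1], [1.0, 1.0], [0.0, -1.0])


@pytest.fixture(scope="module")
def msd():
    p = SimParams.inner_tube(
        density=500,
        t_max_ps=10.0,
        ann_radius=0.0,
        lifetime_ps=1e9,
        n_real=40,
        seed=7,
    )
    ens = run_ensemble(SINGLE, p, np.linspace(0.0, 10.0, 21))
    return msd_series(ens)


class TestDiffusion:
    def test_msd_starts_at_zero(self, msd):
        t, m = msd
        assert m[0] == 0.0

    def test_msd_linear(self, msd):
        t, m = msd
        est = diffusion_constant(t, m)
        assert est.r_squared > 0.999

    def test_diffusion_constant_near_closed_form(self, msd):
        # D = H a^2/(4 dt) = 0.04 * 0.74^2 / 4 nm^2/fs = 5.476 nm^2/ps
        t, m = msd
        est = diffusion_constant(t, m)
        assert est.D_nm2_ps == pytest.approx(5.476, rel=0.05)
        assert est.D_mol_ps == pytest.approx(est.D_nm2_ps / 0.74**2, rel=1e-12)

    def test_frozen_walk_has_zero_msd(self):
        p = SimParams.inner_tube(
            density=100, t_max_ps=1.0, hop_prob=0.0, ann_radius=0.0, lifetime_ps=1e9
        )
        ens = run_ensemble(SMALL, p, np.array([0.0, 0.5, 1.0]))
        _, m = msd_series(ens)
        assert np.all(m == 0)

    def test_exact_on_synthetic_msd(self):
        t = np.linspace(0, 10, 21)
        est = diffusion_constant(t, 4 * 2.5 * t)
        assert est.D_nm2_ps == pytest.approx(2.5, rel=1e-12)

    def test_doubling_hop_prob_doubles_estimate(self):
        def run(h, seed):
            p = SimParams.inner_tube(
                density=1000,
                t_max_ps=5.0,
                hop_prob=h,
                ann_radius=0.0,
                lifetime_ps=1e9,
                n_real=30,
                seed=seed,
            )
            ens = run_ensemble(SINGLE, p, np.linspace(0.0, 5.0, 11))
            return diffusion_constant(*msd_series(ens)).D_nm2_ps

        assert run(0.08, 8) / run(0.04, 9) == pytest.approx(2.0, rel=0.1)

    def test_annihilating_run_rejected(self, annihilating_ensemble):
        with pytest.raises(ValueError, match="annihilation-free"):
            msd_series(annihilating_ensemble)


class TestTransferEfficiency:
    def test_no_transfer_means_zero(self):
        p = SimParams.double_wall(
            density=5000, t_max_ps=5.0, lifetime_ps=0.5, k_io=0.0, k_oi=0.0, seed=10
        )
        ens = run_ensemble(DOUBLE, p, np.array([0.0, 5.0]))
        assert transfer_efficiency(ens) == 0.0

    def test_symmetric_rates_give_half(self):
        p = SimParams.double_wall(
            density=5000,
            t_max_ps=20.0,
            lifetime_ps=2.0,
            ann_radius=0.0,
            k_io=0.003,
            k_oi=0.003,
            n_real=10,
            seed=11,
        )
        ens = run_ensemble(DOUBLE, p, np.array([0.0, 20.0]))
        n_outer = (ens.records.origin_layer == 1).sum()
        tol = 4 / np.sqrt(n_outer)
        assert transfer_efficiency(ens) == pytest.approx(0.5, abs=tol)

    def test_single_wall_rejected(self, annihilating_ensemble):
        with pytest.raises(ValueError):
            transfer_efficiency(annihilating_ensemble)


class TestPeakTime:
    def test_known_gaussian_bump_recovered(self):
        t = np.concatenate([[0.0], np.geomspace(0.1, 50, 39)])
        y = np.exp(-((np.log(t + 1) - np.log(9.0)) ** 2))
        s = TransientSeries(t, y, np.zeros_like(t))
        grid_step = np.diff(t)[np.argmin(np.abs(t - 8))]
        assert peak_time(s) == pytest.approx(8.0, abs=grid_step)

    def test_strictly_decreasing_series_peaks_at_zero(self):
        t = np.linspace(0, 10, 11)
        s = TransientSeries(t, np.exp(-t), np.zeros_like(t))
        assert peak_time(s) == 0.0

    def test_all_zero_series_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            peak_time(TransientSeries(t, np.zeros_like(t), np.zeros_like(t)))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            peak_time(TransientSeries([0, 1, 2], [0, 1, 0], [0, 0, 0]))


class TestMultiAnnihilation:
    def test_no_events_gives_zero(self):
        p = SimParams.inner_tube(density=30_000, t_max_ps=1.0, seed=12)
        ens = run_ensemble(SINGLE, p, np.array([0.0, 1.0]))
        assert multi_annihilation_fraction(ens.records).fraction == 0.0

    def test_single_pair_single_event(self):
        p = SimParams.inner_tube(
            density=500, t_max_ps=0.01, hop_prob=0.0, lifetime_ps=1e9
        )
        state = state_from_positions(SMALL, p, [(0, 0), (0, 2)], seed=13)
        res = run_from_state(state, np.array([0.0, 0.01]))
        f = multi_annihilation_fraction(res.records)
        assert f.fraction == 0.0
        assert f.n_participants == 2

    def test_triple_cluster_fraction_one_third(self):
        p = SimParams.inner_tube(
            density=500, t_max_ps=0.01, hop_prob=0.0, lifetime_ps=1e9
        )
        state = state_from_positions(
            SMALL, p, [(0, 0), (0, 2), (2, 1)], seed=14
        )
        res = run_from_state(state, np.array([0.0, 0.01]))
        f = multi_annihilation_fraction(res.records)
        assert f.n_participants == 3
        assert f.n_multi == 1
        assert f.fraction == pytest.approx(1 / 3)
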