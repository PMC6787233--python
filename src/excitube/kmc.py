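"""Kinetic Monte Carlo engine for exciton populations on tubular lattices.

The model follows the standard lattice picture of incoherent Frenkel
exciton transport: excitons are planted at random grid sites at time zero
and then, with a 1 fs time step, each exciton may (i) decay with
first-order probability ``dt/tau``, (ii) hop to one of its four nearest
neighbours with total probability ``H`` per step, or (iii) attempt
transfer to the radially adjacent molecule on the other wall with
probability ``k*dt``, allowed only when that molecule is unoccupied.
After every step an annihilation sweep instantly deletes one member of
each same-wall pair closer than the annihilation radius ``R0``, iterating
until no violating pair remains; excitons may survive several sequential
annihilation events.  Cross-wall pairs never annihilate: the inter-wall
dipole coupling is far too weak for exciton-exciton interaction across
the ~3.5 nm wall gap.

Every exciton carries its origin wall, annihilation history and terminal
event, which is what the observable predicates (absorptive / EEI,
diagonal / cross peaks) are evaluated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel
from ._kernel import (
    STATUS_ALIVE,
    STATUS_ANNIHILATED,
    STATUS_CENSORED,
    STATUS_DECAYED,
)
from .lattice import TubeSystem, interlayer_map

__all__ = [
    "SimParams",
    "ThermalParams",
    "SimState",
    "ExcitonRecords",
    "EventLog",
    "RealizationResult",
    "EnsembleResult",
    "detailed_balance_ratio",
    "plant_excitons",
    "state_from_positions",
    "advance_step",
    "advance_steps",
    "annihilation_sweep",
    "run_realization",
    "run_from_state",
    "run_ensemble",
    "default_time_grid",
]


@dataclass(frozen=True)
class SimParams:
    """Kinetic parameters of one simulation.

    Defaults are the double-wall parameter set: hopping probability
    H = 0.04 per 1 fs step (the total probability to move, shared equally
    among the four neighbours), annihilation radius R0 = 3 lattice units,
    inter-wall transfer rates k_io = 0.0013 / k_oi = 0.0031 per fs and a
    33 ps one-exciton lifetime (58 ps for isolated inner tubes).
    ``density`` is molecules per exciton, identical on both walls.
    """

    density: float
    t_max_ps: float
    dt_fs: float = 1.0
    hop_prob: float = 0.04
    lifetime_ps: float = 33.0
    ann_radius: float = 3.0
    k_io: float = 0.0013
    k_oi: float = 0.0031
    n_real: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("dt_fs must be > 0")
        if self.lifetime_ps <= 0:
            raise ValueError("lifetime_ps must be > 0")
        if self.ann_radius < 0:
            raise ValueError("ann_radius must be >= 0")
        if self.density < 1:
            raise ValueError("density (molecules per exciton) must be >= 1")
        if not 0 <= self.hop_prob <= 1:
            raise ValueError("hop_prob must be in [0, 1]")
        if self.k_io < 0 or self.k_oi < 0:
            raise ValueError("transfer rates must be >= 0")
        if self.n_real < 1:
            raise ValueError("n_real must be >= 1")
        budget = (
            self.p_decay + self.hop_prob + max(self.k_io, self.k_oi) * self.dt_fs
        )
        if budget > 1.0 + 1e-12:
            raise ValueError(
                f"per-step probability budget {budget:.3g} exceeds 1; "
                "reduce dt, H or the transfer rates"
            )

    @property
    def p_decay(self) -> float:
        return self.dt_fs / (self.lifetime_ps * 1e3)

    @property
    def n_steps(self) -> int:
        if self.t_max_ps <= 0:
            raise ValueError("t_max_ps must be > 0")
        return int(round(self.t_max_ps * 1e3 / self.dt_fs))

    @classmethod
    def inner_tube(cls, density: float, t_max_ps: float, **kw) -> "SimParams":
        """Isolated inner tube set: tau = 58 ps, no inter-wall transfer."""
        kw.setdefault("lifetime_ps", 58.0)
        kw.setdefault("k_io", 0.0)
        kw.setdefault("k_oi", 0.0)
        return cls(density=density, t_max_ps=t_max_ps, **kw)

    @classmethod
    def double_wall(cls, density: float, t_max_ps: float, **kw) -> "SimParams":
        """Complete nanotube set: tau = 33 ps, measured transfer rates."""
        return cls(density=density, t_max_ps=t_max_ps, **kw)


@dataclass(frozen=True)
class ThermalParams:
    """Thermal quantities fixing the uphill (inner->outer) transfer rate.

    ``delta_E_cm1`` is the inner/outer exciton energy gap, ``kBT_cm1`` the
    thermal energy at room temperature and ``dos_ratio`` the outer/inner
    molecule-count ratio (density of states scales with the wall radius).
    """

    delta_E_cm1: float = 300.0
    kBT_cm1: float = 200.0
    dos_ratio: float = 55.0 / 30.0

    def __post_init__(self) -> None:
        if self.delta_E_cm1 < 0 or self.kBT_cm1 <= 0 or self.dos_ratio <= 0:
            raise ValueError("thermal parameters must be positive")


def detailed_balance_ratio(thermal: ThermalParams) -> float:
    """Uphill/downhill transfer-rate ratio k_io/k_oi at thermal equilibrium.

    Detailed balance fixes it as the Boltzmann factor of the energy gap
    times the density-of-states ratio of the two walls:
    ``exp(-dE/kBT) * dos_ratio`` (~0.41 for the C8S3 defaults, consistent
    with the measured 0.0013/0.0031).
    """
    return math.exp(-thermal.delta_E_cm1 / thermal.kBT_cm1) * thermal.dos_ratio


# ---------------------------------------------------------------------------
# state container and kernel plumbing


_STATE_FIELDS = (
    ("x", np.int64),
    ("y", np.int64),
    ("layer", np.int8),
    ("status", np.int8),
    ("origin", np.int8),
    ("ox", np.int64),
    ("oy", np.int64),
    ("ux", np.int64),
    ("uy", np.int64),
    ("n_surv", np.int64),
    ("n_tot", np.int64),
    ("n_same", np.int64),
    ("n_hops", np.int64),
    ("n_transfers", np.int64),
    ("term_time", np.float64),
    ("term_layer", np.int8),
)


def planted_count(n_sites: int, density: float) -> int:
    """Excitons planted on a wall of ``n_sites`` molecules: round(sites/density)."""
    n = int(round(n_sites / density))
    if n > n_sites:
        raise ValueError("more excitons than sites requested")
    return n


def _ann_offsets(r0: float) -> tuple[np.ndarray, np.ndarray]:
    m = int(math.floor(r0))
    dx, dy = [], []
    for a in range(-m, m + 1):
        for b in range(-m, m + 1):
            if a * a + b * b < r0 * r0:
                dx.append(a)
                dy.append(b)
    if not dx:  # r0 == 0: sweep disabled in the kernel anyway
        dx, dy = [0], [0]
    return np.asarray(dx, dtype=np.int64), np.asarray(dy, dtype=np.int64)


class SimState:
    """Mutable population state plus scratch grids for the kernel."""

    def __init__(self, system: TubeSystem, params: SimParams, seed: int):
        self.system = system
        self.params = params
        self.step = 0
        self._seed_entropy = int(seed)
        self._seed_counter = 0
        inner, outer = system.inner, system.outer
        self.n_in = planted_count(inner.n_sites, params.density)
        if outer is not None:
            self.n_out = planted_count(outer.n_sites, params.density)
        else:
            self.n_out = 0
        n = self.n_in + self.n_out
        if n == 0:
            raise ValueError("density too low: zero excitons planted")
        self.n_excitons = n
        self.arrays = {
            name: np.zeros(n, dtype=dt) for name, dt in _STATE_FIELDS
        }
        self._occ_in = np.zeros((inner.n_circ, inner.n_axial), dtype=np.int16)
        if outer is not None:
            self._occ_out = np.zeros((outer.n_circ, outer.n_axial), dtype=np.int16)
            self._head_out = np.full((outer.n_circ, outer.n_axial), -1, np.int64)
            self._map_io = interlayer_map(inner, outer)
            self._map_oi = interlayer_map(outer, inner)
            self._n_circ_out = outer.n_circ
        else:
            self._occ_out = np.zeros((1, 1), dtype=np.int16)
            self._head_out = np.full((1, 1), -1, np.int64)
            self._map_io = np.zeros(0, dtype=np.int64)
            self._map_oi = np.zeros(0, dtype=np.int64)
            self._n_circ_out = 0
        self._head_in = np.full((inner.n_circ, inner.n_axial), -1, np.int64)
        self._nxt = np.full(n, -1, np.int64)
        self._off_dx, self._off_dy = _ann_offsets(params.ann_radius)
        # event log buffers (at most one deletion per exciton)
        self._ev_step = np.zeros(n, dtype=np.int64)
        self._ev_deleted = np.zeros(n, dtype=np.int64)
        self._ev_survivor = np.zeros(n, dtype=np.int64)
        self._ev_layer = np.zeros(n, dtype=np.int8)
        self.n_events = 0
        self._planted = False

    def _next_seed(self) -> int:
        s = np.random.SeedSequence(
            entropy=self._seed_entropy, spawn_key=(self._seed_counter,)
        ).generate_state(1, dtype=np.uint32)[0]
        self._seed_counter += 1
        return int(s)

    def _call_kernel(
        self,
        plant: bool,
        initial_sweep: bool,
        n_steps: int,
        sample_steps: np.ndarray | None = None,
    ):
        if sample_steps is None:
            sample_steps = np.zeros(0, dtype=np.int64)
        n_samp = len(sample_steps)
        counts = np.zeros((n_samp, 16), dtype=np.int64)
        msd_sum = np.zeros(n_samp, dtype=np.float64)
        msd_n = np.zeros(n_samp, dtype=np.int64)
        p = self.params
        inner = self.system.inner
        a = self.arrays
        n_events, _ = _kernel.kmc_kernel(
            self._next_seed(),
            plant,
            initial_sweep,
            n_steps,
            self.step,
            sample_steps,
            p.dt_fs,
            p.p_decay,
            p.hop_prob,
            p.k_io if self.system.double_walled else 0.0,
            p.k_oi if self.system.double_walled else 0.0,
            p.ann_radius,
            inner.n_circ,
            self._n_circ_out,
            inner.n_axial,
            self.n_in,
            self.n_out,
            self._map_io,
            self._map_oi,
            self._off_dx,
            self._off_dy,
            a["x"], a["y"], a["layer"], a["status"], a["origin"],
            a["ox"], a["oy"], a["ux"], a["uy"],
            a["n_surv"], a["n_tot"], a["n_same"], a["n_hops"], a["n_transfers"],
            a["term_time"], a["term_layer"],
            self._occ_in, self._occ_out,
            self._head_in, self._head_out, self._nxt,
            counts, msd_sum, msd_n,
            self._ev_step, self._ev_deleted, self._ev_survivor, self._ev_layer,
            0 if plant else self.n_events,
        )
        self.n_events = n_events
        self.step += n_steps
        return counts, msd_sum, msd_n

    @property
    def time_ps(self) -> float:
        return self.step * self.params.dt_fs * 1e-3

    def alive_count(self) -> int:
        return int(np.sum(self.arrays["status"] == STATUS_ALIVE))

    def positions(self):
        """(layer, i_circ, j_axial) arrays of the alive excitons."""
        alive = self.arrays["status"] == STATUS_ALIVE
        return (
            self.arrays["layer"][alive],
            self.arrays["x"][alive],
            self.arrays["y"][alive],
        )


def state_from_positions(
    system: TubeSystem,
    params: SimParams,
    positions: list[tuple],
    seed: int = 0,
) -> SimState:
    """Build a state with excitons at explicit (layer, i_circ, j_axial) or
    (i_circ, j_axial) sites — for controlled scenarios and tests.  No
    t = 0 sweep is applied; call :func:`annihilation_sweep` explicitly."""
    state = SimState(system, params, seed)
    n = len(positions)
    state.n_excitons = n
    state.n_in = sum(1 for p in positions if len(p) == 2 or p[0] == 0)
    state.n_out = n - state.n_in
    state.arrays = {name: np.zeros(n, dtype=dt) for name, dt in _STATE_FIELDS}
    state._nxt = np.full(n, -1, np.int64)
    state._ev_step = np.zeros(n, dtype=np.int64)
    state._ev_deleted = np.zeros(n, dtype=np.int64)
    state._ev_survivor = np.zeros(n, dtype=np.int64)
    state._ev_layer = np.zeros(n, dtype=np.int8)
    a = state.arrays
    for i, pos in enumerate(positions):
        if len(pos) == 3:
            lay, xi, yi = pos
        else:
            lay, (xi, yi) = 0, pos
        spec = system.inner if lay == 0 else system.outer
        if spec is None or not (0 <= xi < spec.n_circ and 0 <= yi < spec.n_axial):
            raise ValueError(f"position {pos} outside the lattice")
        a["layer"][i] = lay
        a["x"][i] = xi
        a["y"][i] = yi
        a["origin"][i] = lay
        a["ox"][i] = xi
        a["oy"][i] = yi
        a["term_time"][i] = np.nan
        a["term_layer"][i] = -1
    seen = {(int(l), int(x), int(y)) for l, x, y in zip(a["layer"], a["x"], a["y"])}
    if len(seen) != n:
        raise ValueError("double occupancy in explicit positions")
    state._planted = True
    return state


def plant_excitons(
    system: TubeSystem, params: SimParams, seed: int | None = None, sweep: bool = True
) -> SimState:
    """Plant ``round(sites/density)`` excitons per wall uniformly at random
    without double occupancy, then (by default) apply the t = 0
    annihilation sweep, mirroring the instantaneous-annihilation rule."""
    state = SimState(system, params, params.seed if seed is None else seed)
    state._call_kernel(plant=True, initial_sweep=sweep, n_steps=0)
    state._planted = True
    return state


def advance_steps(state: SimState, n_steps: int) -> SimState:
    """Advance the population by ``n_steps`` time steps (sweep after each)."""
    if not state._planted:
        raise RuntimeError("state must be planted first")
    state._call_kernel(plant=False, initial_sweep=False, n_steps=n_steps)
    return state


def advance_step(state: SimState) -> SimState:
    return advance_steps(state, 1)


def annihilation_sweep(state: SimState) -> SimState:
    """Run one annihilation sweep on the current positions (no movement)."""
    state._call_kernel(plant=False, initial_sweep=True, n_steps=0)
    return state


# ---------------------------------------------------------------------------
# records / results containers


@dataclass
class ExcitonRecords:
    """Columnar per-exciton bookkeeping of one or more realizations.

    ``status`` uses the codes alive=0 (never present in finished runs),
    decayed=1, annihilated_deleted=2, censored=3.  ``n_ann_total`` counts
    every annihilation event the exciton participated in (including the
    one that deleted it), ``n_ann_survived`` the events it survived, and
    ``n_ann_same_origin`` the events whose partner was planted on the same
    wall.  Unwrapped displacements (``ux``, ``uy``) are in lattice units.
    """

    origin_layer: np.ndarray
    status: np.ndarray
    current_layer: np.ndarray
    term_time_ps: np.ndarray
    term_layer: np.ndarray
    n_ann_survived: np.ndarray
    n_ann_total: np.ndarray
    n_ann_same_origin: np.ndarray
    n_hops: np.ndarray
    n_transfers: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    realization: np.ndarray

    def __len__(self) -> int:
        return len(self.status)

    @property
    def partner_same_origin(self) -> np.ndarray:
        """True where every annihilation partner shared the origin wall."""
        return self.n_ann_same_origin == self.n_ann_total

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {k: getattr(self, k) for k in self.__dataclass_fields__}
        )

    @classmethod
    def concat(cls, parts: list["ExcitonRecords"]) -> "ExcitonRecords":
        return cls(
            **{
                k: np.concatenate([getattr(p, k) for p in parts])
                for k in cls.__dataclass_fields__
            }
        )


@dataclass
class EventLog:
    """Time-ordered annihilation events plus terminal decay times.

    Hops and transfers are tallied per exciton (``n_hops``,
    ``n_transfers`` on the records) rather than logged individually; a
    per-hop log at 1 fs resolution would dwarf the physics output.
    """

    ann_step: np.ndarray
    ann_time_ps: np.ndarray
    ann_deleted: np.ndarray
    ann_survivor: np.ndarray
    ann_layer: np.ndarray

    def __len__(self) -> int:
        return len(self.ann_step)


@dataclass
class RealizationResult:
    """One stochastic realization: snapshot counts plus full bookkeeping."""

    sample_times_ps: np.ndarray
    counts16: np.ndarray  # (n_times, 16): origin*8 + layer*4 + same*2 + any
    msd_sum: np.ndarray  # sum over alive excitons of |u|^2, lattice units^2
    msd_n: np.ndarray
    records: ExcitonRecords
    events: EventLog
    n_planted_inner: int
    n_planted_outer: int
    seed: int

    @property
    def alive(self) -> np.ndarray:
        return self.counts16.sum(axis=1)


def sample_steps_for(params: SimParams, sample_times_ps: np.ndarray) -> np.ndarray:
    """Map requested waiting times (ps) onto the fs step grid."""
    t = np.asarray(sample_times_ps, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("sample_times_ps must be a non-empty 1-d array")
    steps = np.round(t * 1e3 / params.dt_fs).astype(np.int64)
    if np.any(np.diff(steps) <= 0):
        raise ValueError("sample times must be strictly increasing on the step grid")
    if steps[0] < 0 or steps[-1] > params.n_steps:
        raise ValueError("sample times outside the simulated range")
    return steps


def default_time_grid(t_max_ps: float, n_points: int = 40, t_min_ps: float = 0.1):
    """0 plus a log-spaced grid, emulating log-sampled waiting times."""
    grid = np.concatenate(
        [[0.0], np.geomspace(t_min_ps, t_max_ps, n_points - 1)]
    )
    return grid


def run_realization(
    system: TubeSystem,
    params: SimParams,
    sample_times_ps: np.ndarray,
    seed: int | None = None,
) -> RealizationResult:
    """Plant, sweep at t = 0, and advance to ``t_max`` in one kernel call.

    Snapshot counts are taken after the step's annihilation sweep.  At the
    horizon every still-alive exciton is censored at its current wall.
    """
    steps = sample_steps_for(params, sample_times_ps)
    state = SimState(system, params, params.seed if seed is None else seed)
    counts, msd_sum, msd_n = state._call_kernel(
        plant=True, initial_sweep=True, n_steps=params.n_steps, sample_steps=steps
    )
    state._planted = True
    return finalize_realization(state, steps, counts, msd_sum, msd_n)


def finalize_realization(
    state: SimState,
    steps: np.ndarray,
    counts: np.ndarray,
    msd_sum: np.ndarray,
    msd_n: np.ndarray,
) -> RealizationResult:
    a = state.arrays
    p = state.params
    status = a["status"].copy()
    term_time = a["term_time"].copy()
    term_layer = a["term_layer"].copy()
    alive = status == STATUS_ALIVE
    status[alive] = STATUS_CENSORED
    term_time[alive] = state.time_ps
    term_layer[alive] = a["layer"][alive]
    records = ExcitonRecords(
        origin_layer=a["origin"].copy(),
        status=status,
        current_layer=a["layer"].copy(),
        term_time_ps=term_time,
        term_layer=term_layer,
        n_ann_survived=a["n_surv"].copy(),
        n_ann_total=a["n_tot"].copy(),
        n_ann_same_origin=a["n_same"].copy(),
        n_hops=a["n_hops"].copy(),
        n_transfers=a["n_transfers"].copy(),
        ux=a["ux"].copy(),
        uy=a["uy"].copy(),
        realization=np.zeros(state.n_excitons, dtype=np.int64),
    )
    ne = state.n_events
    events = EventLog(
        ann_step=state._ev_step[:ne].copy(),
        ann_time_ps=state._ev_step[:ne] * p.dt_fs * 1e-3,
        ann_deleted=state._ev_deleted[:ne].copy(),
        ann_survivor=state._ev_survivor[:ne].copy(),
        ann_layer=state._ev_layer[:ne].copy(),
    )
    return RealizationResult(
        sample_times_ps=steps * p.dt_fs * 1e-3,
        counts16=counts,
        msd_sum=msd_sum,
        msd_n=msd_n,
        records=records,
        events=events,
        n_planted_inner=state.n_in,
        n_planted_outer=state.n_out,
        seed=state._seed_entropy,
    )


def run_from_state(
    state: SimState,
    sample_times_ps: np.ndarray,
    initial_sweep: bool = True,
) -> RealizationResult:
    """Advance an explicitly constructed state to ``t_max`` and finalize."""
    steps = sample_steps_for(state.params, sample_times_ps)
    counts, msd_sum, msd_n = state._call_kernel(
        plant=False,
        initial_sweep=initial_sweep,
        n_steps=state.params.n_steps - state.step,
        sample_steps=steps,
    )
    return finalize_realization(state, steps, counts, msd_sum, msd_n)


@dataclass
class EnsembleResult:
    """Stacked realizations sharing one parameter set.

    ``counts16`` has shape (n_real, n_times, 16); observable extraction
    and ensemble statistics live in :mod:`excitube.observables`.
    """

    system: TubeSystem
    params: SimParams
    sample_times_ps: np.ndarray
    counts16: np.ndarray
    msd_sum: np.ndarray  # (n_real, n_times)
    msd_n: np.ndarray
    records: ExcitonRecords
    seeds: np.ndarray
    n_planted_inner: int
    n_planted_outer: int

    @property
    def n_real(self) -> int:
        return self.counts16.shape[0]


def run_ensemble(
    system: TubeSystem,
    params: SimParams,
    sample_times_ps: np.ndarray | None = None,
) -> EnsembleResult:
    """Run ``params.n_real`` independent realizations.

    The master seed spawns one child seed per realization, so results are
    reproducible bit-for-bit for a given (seed, n_real, parameters).
    """
    if sample_times_ps is None:
        sample_times_ps = default_time_grid(params.t_max_ps)
    seeds = np.random.SeedSequence(params.seed).generate_state(
        params.n_real, dtype=np.uint32
    )
    all_counts, all_msd, all_msdn, recs = [], [], [], []
    for r in range(params.n_real):
        res = run_realization(system, params, sample_times_ps, seed=int(seeds[r]))
        all_counts.append(res.counts16)
        all_msd.append(res.msd_sum)
        all_msdn.append(res.msd_n)
        res.records.realization[:] = r
        recs.append(res.records)
    return EnsembleResult(
        system=system,
        params=params,
        sample_times_ps=res.sample_times_ps,
        counts16=np.stack(all_counts),
        msd_sum=np.stack(all_msd),
        msd_n=np.stack(all_msdn),
        records=ExcitonRecords.concat(recs),
        seeds=seeds,
        n_planted_inner=res.n_planted_inner,
        n_planted_outer=res.n_planted_outer,
    )
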