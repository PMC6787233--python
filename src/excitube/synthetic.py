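"""Experiment-shaped synthetic datasets with known ground truth.

Generates per-fluence bundles of waiting-time transients exactly as the
experiment delivers them — absorptive and EEI signals on a log-sampled
0-50 ps grid, one bundle entry per (density, observable) — from forward
kinetic Monte Carlo runs, with additive white Gaussian detection noise
whose standard deviation is a fixed fraction of each series' maximum.
The default density lists reproduce the two experimental fluence series:
19/64/625 molecules per exciton for complete nanotubes and 18/83/165/404
for flash-diluted (isolated inner) tubes.

Every stage of the pipeline can therefore be tested end-to-end without
measured data; the truth sidecar round-trips the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .fitting import BundleEntry, ExperimentBundle
from .kmc import SimParams, default_time_grid, run_ensemble
from .lattice import TubeSystem
from .observables import TransientSeries, transient

__all__ = [
    "DOUBLE_WALL_DENSITIES",
    "INNER_TUBE_DENSITIES",
    "TruthParams",
    "SyntheticBundle",
    "generate_bundle",
    "write_bundle",
    "read_truth",
    "toy_fixture",
]

# molecules per exciton in the two experimental fluence series
DOUBLE_WALL_DENSITIES = (19.0, 64.0, 625.0)
INNER_TUBE_DENSITIES = (18.0, 83.0, 165.0, 404.0)

_SINGLE_OBS = ("abs_total", "eei_total")
_DOUBLE_OBS = (
    "abs_inner_diag",
    "abs_outer_diag",
    "abs_cross_oi",
    "eei_inner_diag",
    "eei_outer_diag",
    "eei_cross_oi",
)


@dataclass(frozen=True)
class TruthParams:
    """Ground truth for one synthetic dataset.

    ``base_params.density`` is overridden by each entry of ``densities``.
    ``noise_sigma`` is the relative detection-noise level: each series
    gets additive Gaussian noise with SD = sigma * max(series).
    """

    system: TubeSystem
    base_params: SimParams
    densities: tuple = INNER_TUBE_DENSITIES
    noise_sigma: float = 0.05
    time_grid_ps: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(d < 1 for d in self.densities):
            raise ValueError("densities must be >= 1 molecule per exciton")

    def grid(self) -> np.ndarray:
        if self.time_grid_ps is not None:
            return np.asarray(self.time_grid_ps, float)
        return default_time_grid(self.base_params.t_max_ps)

    @classmethod
    def inner_tube_default(cls, seed: int = 0, n_real: int = 10, **kw):
        """Flash-diluted (single-wall) study conditions on the 30x1000 grid."""
        p = SimParams.inner_tube(
            density=INNER_TUBE_DENSITIES[0], t_max_ps=50.0, n_real=n_real, seed=seed
        )
        kw.setdefault("densities", INNER_TUBE_DENSITIES)
        return cls(TubeSystem.single_wall(), p, seed=seed, **kw)

    @classmethod
    def double_wall_default(cls, seed: int = 0, n_real: int = 10, **kw):
        """Complete-nanotube study conditions (30x1000 + 55x1000 grids)."""
        p = SimParams.double_wall(
            density=DOUBLE_WALL_DENSITIES[0], t_max_ps=50.0, n_real=n_real, seed=seed
        )
        kw.setdefault("densities", DOUBLE_WALL_DENSITIES)
        return cls(TubeSystem.double_wall(), p, seed=seed, **kw)


@dataclass
class SyntheticBundle:
    """Noisy bundle plus its clean forward curves and generating truth."""

    bundle: ExperimentBundle
    clean: ExperimentBundle
    truth: TruthParams


def generate_bundle(truth: TruthParams) -> SyntheticBundle:
    """Forward-simulate every density and add detection noise.

    Noise is drawn independently per point from N(0, (sigma*max)^2) with
    a generator seeded from ``truth.seed``, after all forward ensembles
    are complete, so the clean curves are identical across noise seeds.
    """
    obs_ids = _DOUBLE_OBS if truth.system.double_walled else _SINGLE_OBS
    grid = truth.grid()
    clean_entries: list[BundleEntry] = []
    for d in truth.densities:
        p = replace(truth.base_params, density=float(d), seed=_density_seed(truth, d))
        ens = run_ensemble(truth.system, p, grid)
        for oid in obs_ids:
            clean_entries.append(BundleEntry(float(d), oid, transient(ens, oid)))
    rng = np.random.default_rng(truth.seed)
    noisy_entries = []
    for e in clean_entries:
        sd = truth.noise_sigma * float(np.max(e.series.values))
        noise = rng.normal(0.0, sd, size=len(e.series)) if sd > 0 else 0.0
        meta = dict(e.series.meta)
        meta["noise_sigma"] = truth.noise_sigma
        noisy = TransientSeries(
            e.series.times,
            e.series.values + noise,
            np.full(len(e.series), sd),
            meta,
        )
        noisy_entries.append(BundleEntry(e.density, e.observable_id, noisy))
    dw = truth.system.double_walled
    return SyntheticBundle(
        bundle=ExperimentBundle(noisy_entries, dw),
        clean=ExperimentBundle(clean_entries, dw),
        truth=truth,
    )


def _density_seed(truth: TruthParams, density: float) -> int:
    import zlib

    return zlib.crc32(f"{truth.seed}|{density:.8g}".encode()) & 0x7FFFFFFF


def write_bundle(synth: SyntheticBundle, out_dir) -> list[Path]:
    """Write one transient table per entry plus a ``truth.txt`` sidecar."""
    from .tables import write_transient

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for e in synth.bundle.entries:
        name = f"d{e.density:g}_{e.observable_id}.tsv"
        write_transient(e.series, out_dir / name)
        written.append(out_dir / name)
    t = synth.truth
    p = t.base_params
    lines = [
        f"seed={t.seed}",
        f"noise_sigma={t.noise_sigma:.10g}",
        f"densities={','.join(f'{d:g}' for d in t.densities)}",
        f"double_walled={t.system.double_walled}",
        f"hop_prob={p.hop_prob:.10g}",
        f"ann_radius={p.ann_radius:.10g}",
        f"lifetime_ps={p.lifetime_ps:.10g}",
        f"k_io_per_fs={p.k_io:.10g}",
        f"k_oi_per_fs={p.k_oi:.10g}",
        f"t_max_ps={p.t_max_ps:.10g}",
        f"n_real={p.n_real}",
    ]
    (out_dir / "truth.txt").write_text("\n".join(lines) + "\n")
    written.append(out_dir / "truth.txt")
    return written


def read_truth(path) -> dict:
    """Parse the key=value truth sidecar."""
    out: dict = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        k, v = ln.split("=", 1)
        if k == "densities":
            out[k] = tuple(float(x) for x in v.split(","))
        elif k == "double_walled":
            out[k] = v == "True"
        else:
            try:
                out[k] = int(v)
            except ValueError:
                out[k] = float(v)
    return out


# ---------------------------------------------------------------------------
# miniature deterministic scenarios shared across test suites


def toy_fixture(name: str):
    """Small systems with analytically known outcomes.

    ``pure_decay``     1000-site wall, immobile excitons, tau = 1 ps.
    ``two_exciton_collision``  two excitons 2 sites apart, R0 = 3.
    ``dimer_hsr``      symmetric dimer: eigenvalues E +/- J.
    ``ring_hsr``       uniform ring: circulant spectrum E + 2J cos(2 pi k/N).
    """
    from . import hsr

    if name == "pure_decay":
        system = TubeSystem.single_wall(10, 100)
        params = SimParams.inner_tube(
            density=10.0,
            t_max_ps=5.0,
            lifetime_ps=1.0,
            hop_prob=0.0,
            ann_radius=0.0,
        )
        expected = {"alive_curve": lambda t: np.exp(-np.asarray(t, float) / 1.0)}
        return system, params, expected
    if name == "two_exciton_collision":
        system = TubeSystem.single_wall(10, 100)
        params = SimParams.inner_tube(
            density=500.0, t_max_ps=1.0, hop_prob=0.0, ann_radius=3.0
        )
        positions = [(0, 0), (0, 2)]  # distance 2 < R0: annihilate at t = 0
        expected = {"eei_count_t0": 1, "abs_count_t0": 1}
        return system, params, positions, expected
    if name == "dimer_hsr":
        model = hsr.build_chain(2, spacing=1.0, l=0.2, q=0.3, site_energy=18000.0)
        J = model.coupling_matrix()[0, 1]
        expected = {"eigenvalues": np.sort([18000.0 - abs(J), 18000.0 + abs(J)])}
        return model, expected
    if name == "ring_hsr":
        n = 8
        model = hsr.build_ring(n, radius=2.0, l=0.2, q=0.3, site_energy=18000.0)
        return model, {"n": n}
    raise ValueError(f"unknown fixture {name!r}")
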