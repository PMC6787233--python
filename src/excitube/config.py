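"""YAML run configuration.

A config file has blocks ``lattice``, ``kinetics``, ``run`` and
optionally ``thermal``, ``hsr`` and ``output``.  Every physical quantity
carries its unit in the key name (``*_fs``, ``*_ps``, ``*_nm``,
``*_cm1``).  The defaults of the optional keys reproduce the reference
C8S3 double-wall parameter set; the HSR block has no silent defaults, as
its microscopic structure parameters are sample-specific inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kmc import SimParams, ThermalParams
from .lattice import TubeSystem

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


def _get(block: dict, block_name: str, key: str, default=..., types=(int, float)):
    if key not in block:
        if default is ...:
            raise ConfigError(f"missing required key {block_name}.{key}")
        return default
    v = block[key]
    if types and not isinstance(v, types):
        raise ConfigError(f"{block_name}.{key} has invalid type {type(v).__name__}")
    return v


@dataclass
class RunConfig:
    """Validated run configuration."""

    system: TubeSystem
    params: SimParams
    thermal: ThermalParams
    hsr: dict | None
    sampling_n_points: int
    sampling_t_min_ps: float
    output_dir: Path
    raw: dict = field(repr=False, default_factory=dict)


def load_config(path) -> RunConfig:
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    lat = raw.get("lattice", {})
    if not isinstance(lat, dict):
        raise ConfigError("lattice block must be a mapping")
    n_circ_inner = int(_get(lat, "lattice", "n_circ_inner", 30))
    n_axial = int(_get(lat, "lattice", "n_axial", 1000))
    a = float(_get(lat, "lattice", "lattice_const_nm", 0.74))
    n_circ_outer = lat.get("n_circ_outer")
    double = bool(_get(lat, "lattice", "double_walled", n_circ_outer is not None,
                       types=(bool,)))
    if double:
        n_circ_outer = int(n_circ_outer if n_circ_outer is not None else 55)
        system = TubeSystem.double_wall(n_circ_inner, n_circ_outer, n_axial, a)
    else:
        system = TubeSystem.single_wall(n_circ_inner, n_axial, a)

    kin = raw.get("kinetics", {})
    if not isinstance(kin, dict):
        raise ConfigError("kinetics block must be a mapping")
    run = raw.get("run", {})
    if not isinstance(run, dict):
        raise ConfigError("run block must be a mapping")
    try:
        params = SimParams(
            density=float(_get(kin, "kinetics", "density")),
            t_max_ps=float(_get(run, "run", "t_max_ps")),
            dt_fs=float(_get(kin, "kinetics", "dt_fs", 1.0)),
            hop_prob=float(_get(kin, "kinetics", "hop_prob", 0.04)),
            lifetime_ps=float(
                _get(kin, "kinetics", "lifetime_ps", 33.0 if double else 58.0)
            ),
            ann_radius=float(_get(kin, "kinetics", "ann_radius_sites", 3.0)),
            k_io=float(_get(kin, "kinetics", "k_io_per_fs", 0.0013 if double else 0.0)),
            k_oi=float(_get(kin, "kinetics", "k_oi_per_fs", 0.0031 if double else 0.0)),
            n_real=int(_get(run, "run", "n_real", 1)),
            seed=int(_get(run, "run", "seed", 0)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    th = raw.get("thermal", {})
    if not isinstance(th, dict):
        raise ConfigError("thermal block must be a mapping")
    thermal = ThermalParams(
        delta_E_cm1=float(_get(th, "thermal", "delta_E_cm1", 300.0)),
        kBT_cm1=float(_get(th, "thermal", "kBT_cm1", 200.0)),
        dos_ratio=float(
            _get(th, "thermal", "dos_ratio",
                 (n_circ_outer / n_circ_inner) if double else 55.0 / 30.0)
        ),
    )

    hsr_block = raw.get("hsr")
    if hsr_block is not None:
        if not isinstance(hsr_block, dict):
            raise ConfigError("hsr block must be a mapping")
        for key in ("l_nm", "q_e", "gamma_cm1", "kBT_cm1", "geometry"):
            if key not in hsr_block:
                raise ConfigError(f"missing required key hsr.{key}")

    samp = raw.get("sampling", {})
    if not isinstance(samp, dict):
        raise ConfigError("sampling block must be a mapping")
    n_points = int(_get(samp, "sampling", "n_points", 40))
    t_min = float(_get(samp, "sampling", "t_min_ps", 0.1))
    if n_points < 2:
        raise ConfigError("sampling.n_points must be >= 2")

    out = raw.get("output", {})
    if not isinstance(out, dict):
        raise ConfigError("output block must be a mapping")
    out_dir = Path(_get(out, "output", "dir", ".", types=(str,)))

    return RunConfig(
        system=system,
        params=params,
        thermal=thermal,
        hsr=hsr_block,
        sampling_n_points=n_points,
        sampling_t_min_ps=t_min,
        output_dir=out_dir,
        raw=raw,
    )
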