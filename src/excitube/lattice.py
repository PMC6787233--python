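"""Periodic molecular grids wrapped on cylinders.

Each nanotube wall is modelled as a rectangular grid of molecules rolled
up along its circumference: ``n_circ`` sites around the tube, ``n_axial``
sites along the tube axis, lattice constant ``a`` in nm.  Both index
directions are periodic.  All distances used by the kinetic Monte Carlo
stage are measured on the unrolled grid in lattice units (1 unit = a);
multiply by ``lattice_const`` for nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum


class Layer(IntEnum):
    """Wall identity of a double-walled nanotube."""

    INNER = 0
    OUTER = 1


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of one wall: a periodic ``n_circ x n_axial`` molecular grid."""

    layer: Layer
    n_circ: int
    n_axial: int
    lattice_const: float = 0.74  # nm

    def __post_init__(self) -> None:
        if self.n_circ < 1 or self.n_axial < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.lattice_const <= 0:
            raise ValueError("lattice_const must be > 0")

    @property
    def n_sites(self) -> int:
        return self.n_circ * self.n_axial


@dataclass(frozen=True)
class SiteAddress:
    """0-based (circumferential, axial) index of one molecule on one wall."""

    layer: Layer
    i_circ: int
    j_axial: int


def _check_on(site: SiteAddress, spec: LatticeSpec) -> None:
    if site.layer != spec.layer:
        raise ValueError(
            f"site layer {site.layer!r} does not match spec layer {spec.layer!r}"
        )
    if not (0 <= site.i_circ < spec.n_circ and 0 <= site.j_axial < spec.n_axial):
        raise ValueError(f"site {site} outside {spec.n_circ}x{spec.n_axial} grid")


def neighbors(site: SiteAddress, spec: LatticeSpec) -> list[SiteAddress]:
    """The four nearest neighbours of ``site`` under periodic wrap.

    On degenerate grids (``n_circ`` or ``n_axial`` <= 2) entries may
    coincide; four slots are always returned.
    """
    _check_on(site, spec)
    i, j = site.i_circ, site.j_axial
    return [
        SiteAddress(spec.layer, (i + 1) % spec.n_circ, j),
        SiteAddress(spec.layer, (i - 1) % spec.n_circ, j),
        SiteAddress(spec.layer, i, (j + 1) % spec.n_axial),
        SiteAddress(spec.layer, i, (j - 1) % spec.n_axial),
    ]


def min_image_distance(a: SiteAddress, b: SiteAddress, spec: LatticeSpec) -> float:
    """Euclidean minimum-image distance between two same-layer sites.

    Result is in lattice units.  Exciton-exciton annihilation is an
    intra-wall process, so requesting a cross-layer distance is an error.
    """
    if a.layer != b.layer:
        raise ValueError("min_image_distance is defined within one layer only")
    _check_on(a, spec)
    _check_on(b, spec)
    di = abs(a.i_circ - b.i_circ)
    di = min(di, spec.n_circ - di)
    dj = abs(a.j_axial - b.j_axial)
    dj = min(dj, spec.n_axial - dj)
    return math.hypot(di, dj)


def interlayer_partner(
    site: SiteAddress, from_spec: LatticeSpec, to_spec: LatticeSpec
) -> SiteAddress:
    """Radially adjacent site on the other wall.

    The walls have different circumferences (e.g. 30 vs 55 molecules), so
    the circumferential coordinate is rescaled to the target circumference
    and rounded (half-up); the axial index is preserved.  Requires equal
    axial lengths.
    """
    _check_on(site, from_spec)
    if from_spec.n_axial != to_spec.n_axial:
        raise ValueError("interlayer_partner requires equal n_axial")
    # round-half-up, deterministic (avoids banker's rounding of round())
    scaled = site.i_circ * to_spec.n_circ / from_spec.n_circ
    i_new = math.floor(scaled + 0.5) % to_spec.n_circ
    return SiteAddress(to_spec.layer, i_new, site.j_axial)


def interlayer_map(from_spec: LatticeSpec, to_spec: LatticeSpec):
    """Vectorised circumferential partner map ``i -> i'`` as an int array."""
    import numpy as np

    i = np.arange(from_spec.n_circ)
    scaled = i * to_spec.n_circ / from_spec.n_circ
    return (np.floor(scaled + 0.5).astype(np.int64)) % to_spec.n_circ


def tube_diameter(spec: LatticeSpec) -> float:
    """Tube diameter in nm implied by the circumference: n_circ * a / pi."""
    return spec.n_circ * spec.lattice_const / math.pi


@dataclass(frozen=True)
class TubeSystem:
    """A single wall or a pair of radially coupled walls.

    The double-wall defaults reproduce the C8S3 nanotube geometry used
    throughout: inner wall 30 x 1000, outer wall 55 x 1000, a = 0.74 nm.
    """

    inner: LatticeSpec
    outer: LatticeSpec | None = None

    def __post_init__(self) -> None:
        if self.inner.layer != Layer.INNER:
            raise ValueError("first wall must be the inner layer")
        if self.outer is not None:
            if self.outer.layer != Layer.OUTER:
                raise ValueError("second wall must be the outer layer")
            if self.outer.n_axial != self.inner.n_axial:
                raise ValueError("walls must share n_axial")

    @property
    def double_walled(self) -> bool:
        return self.outer is not None

    @property
    def n_sites(self) -> int:
        n = self.inner.n_sites
        if self.outer is not None:
            n += self.outer.n_sites
        return n

    @classmethod
    def single_wall(
        cls, n_circ: int = 30, n_axial: int = 1000, lattice_const: float = 0.74
    ) -> "TubeSystem":
        return cls(LatticeSpec(Layer.INNER, n_circ, n_axial, lattice_const))

    @classmethod
    def double_wall(
        cls,
        n_circ_inner: int = 30,
        n_circ_outer: int = 55,
        n_axial: int = 1000,
        lattice_const: float = 0.74,
    ) -> "TubeSystem":
        return cls(
            LatticeSpec(Layer.INNER, n_circ_inner, n_axial, lattice_const),
            LatticeSpec(Layer.OUTER, n_circ_outer, n_axial, lattice_const),
        )
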