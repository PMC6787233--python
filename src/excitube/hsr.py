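"""Frenkel-exciton Hamiltonians and the Haken-Strobl-Reineker (HSR)
diffusion tensor for tubular molecular aggregates.

The aggregate is a set of molecules with positions, transition-dipole
axes and site energies.  Excitation-transfer couplings J_nm use the
extended-dipole approximation (two point charges +/-q separated by l
along the dipole axis), which is more faithful than point dipoles at the
sub-nm separations of tightly packed aggregates.  Diagonalising

    H_nm = delta_nm E_n + (1 - delta_nm) J_nm

gives the exciton eigenstates; in the HSR white-noise dephasing model the
diffusion tensor follows from the flux operators

    j_{mu nu}(u) = i sum_{n,m} <mu|m> (u . r_mn) J_nm <n|nu>

as a Lorentzian-weighted, thermally averaged sum

    D_{u,w} = (1/Z) sum_{mu,nu} Gamma / (Gamma^2 + omega_{mu nu}^2)
              j*_{mu nu}(u) j_{mu nu}(w) exp(-hbar omega_nu / kB T),

with Z the exciton partition function.  Internally site energies and
couplings are kept in cm^-1 and converted to angular frequency (rad/fs)
before the tensor is assembled, so Gamma and omega share units and D
emerges in nm^2/fs (reported as nm^2/ps).  Boltzmann weights are
referenced to the band bottom, which leaves the temperature average
unchanged (the reference cancels against Z) but avoids overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

__all__ = [
    "CM1_TO_RAD_FS",
    "COULOMB_CM1_NM",
    "Molecule",
    "AggregateModel",
    "ExcitonBasis",
    "DiffusionTensor",
    "extended_dipole_coupling",
    "build_basis",
    "flux_operator",
    "diffusion_tensor",
    "molecular_units",
    "build_chain",
    "build_ring",
    "build_helical_cylinder",
]

# 1 cm^-1 expressed as angular frequency in rad/fs
CM1_TO_RAD_FS = 2.0 * math.pi * constants.c * 1e2 * 1e-15

# e^2/(4 pi eps0) for r in nm, energy in cm^-1
COULOMB_CM1_NM = (
    constants.e**2
    / (4.0 * math.pi * constants.epsilon_0 * 1e-9)
    / (constants.h * constants.c * 1e2)
)


@dataclass(frozen=True)
class Molecule:
    """One chromophore: position (nm), unit dipole axis, site energy (cm^-1)."""

    position: tuple[float, float, float]
    dipole_axis: tuple[float, float, float]
    site_energy: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.dipole_axis, float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("dipole_axis must be a non-zero vector")
        if abs(n - 1.0) > 1e-8:
            object.__setattr__(self, "dipole_axis", tuple(d / n))

    @property
    def r(self) -> np.ndarray:
        return np.asarray(self.position, float)

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.dipole_axis, float)


def extended_dipole_coupling(
    mol_a: Molecule, mol_b: Molecule, l: float, q: float
) -> float:
    """Extended-dipole coupling J_ab in cm^-1.

    Each molecule carries charges +/-q (units of the elementary charge) at
    ``r +/- (l/2) * dipole_axis``; J is the Coulomb sum over the four
    charge pairs.  In the far field this reduces to the point-dipole
    interaction with dipole moment mu = q*l.
    """
    if l <= 0:
        raise ValueError("extended dipole length must be > 0")
    ap = mol_a.r + 0.5 * l * mol_a.d
    am = mol_a.r - 0.5 * l * mol_a.d
    bp = mol_b.r + 0.5 * l * mol_b.d
    bm = mol_b.r - 0.5 * l * mol_b.d
    total = 0.0
    for ra, sa in ((ap, 1.0), (am, -1.0)):
        for rb, sb in ((bp, 1.0), (bm, -1.0)):
            dist = np.linalg.norm(ra - rb)
            if dist == 0:
                raise ValueError("overlapping charges: molecules coincide")
            total += sa * sb / dist
    return q * q * COULOMB_CM1_NM * total


@dataclass
class AggregateModel:
    """Molecular aggregate with derived coupling matrix.

    ``geometry_kind`` records how the molecules were generated; it decides
    how the circumferential (phi) displacement used by the flux operator
    is measured (arc length on the unrolled cylinder surface, with
    minimum-image wrap, for ring/cylinder geometries).
    """

    molecules: list[Molecule]
    extended_dipole_length: float
    extended_dipole_charge: float
    geometry_kind: str = "explicit"
    _couplings: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.geometry_kind not in {"chain", "ring", "helical_cylinder", "explicit"}:
            raise ValueError(f"unknown geometry_kind {self.geometry_kind!r}")
        if len(self.molecules) < 1:
            raise ValueError("aggregate needs at least one molecule")

    @property
    def n(self) -> int:
        return len(self.molecules)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.r for m in self.molecules])

    @property
    def site_energies(self) -> np.ndarray:
        return np.array([m.site_energy for m in self.molecules])

    def coupling_matrix(self) -> np.ndarray:
        """Symmetric J_nm in cm^-1 with zero diagonal (cached)."""
        if self._couplings is None:
            n = self.n
            J = np.zeros((n, n))
            l, q = self.extended_dipole_length, self.extended_dipole_charge
            for i in range(n):
                for j in range(i + 1, n):
                    J[i, j] = J[j, i] = extended_dipole_coupling(
                        self.molecules[i], self.molecules[j], l, q
                    )
            self._couplings = J
        return self._couplings

    def translated(self, shift) -> "AggregateModel":
        shift = np.asarray(shift, float)
        return AggregateModel(
            [
                Molecule(tuple(m.r + shift), m.dipole_axis, m.site_energy)
                for m in self.molecules
            ],
            self.extended_dipole_length,
            self.extended_dipole_charge,
            self.geometry_kind,
        )


@dataclass
class ExcitonBasis:
    """Eigenpairs of the exciton Hamiltonian.

    ``energies_cm1`` ascending; ``omega_rad_fs`` the same energies as
    angular frequencies; ``coeffs[:, mu]`` the site amplitudes <n|mu>.
    """

    energies_cm1: np.ndarray
    omega_rad_fs: np.ndarray
    coeffs: np.ndarray

    @property
    def n(self) -> int:
        return len(self.energies_cm1)


def build_basis(model: AggregateModel) -> ExcitonBasis:
    """Dense symmetric eigendecomposition of the Frenkel Hamiltonian."""
    J = model.coupling_matrix()
    if not np.all(np.isfinite(J)):
        raise ValueError("non-finite couplings in the Hamiltonian")
    H = J + np.diag(model.site_energies)
    evals, evecs = np.linalg.eigh(H)
    return ExcitonBasis(evals, evals * CM1_TO_RAD_FS, evecs)


def _displacement_matrix(model: AggregateModel, direction) -> np.ndarray:
    """(u . r_mn) with r_mn = r_m - r_n, indexed [m, n], in nm.

    ``direction`` is ``"z"`` (axial), ``"phi"`` (arc length on the
    unrolled surface, minimum image) or an explicit 3-vector.
    """
    r = model.positions
    if isinstance(direction, str):
        if direction == "z":
            coord = r[:, 2]
            return coord[:, None] - coord[None, :]
        if direction == "phi":
            if model.geometry_kind not in {"ring", "helical_cylinder"}:
                raise ValueError(
                    "phi direction requires a cylindrical geometry_kind"
                )
            # cylinder axis from the molecular centroid, so a rigidly
            # translated aggregate yields identical arc displacements
            xc = r[:, 0] - r[:, 0].mean()
            yc = r[:, 1] - r[:, 1].mean()
            theta = np.arctan2(yc, xc)
            radius = np.hypot(xc, yc).mean()
            dth = theta[:, None] - theta[None, :]
            dth = (dth + math.pi) % (2 * math.pi) - math.pi
            return radius * dth
        raise ValueError(f"unknown direction {direction!r}")
    u = np.asarray(direction, float)
    coord = r @ u
    return coord[:, None] - coord[None, :]


def flux_operator(basis: ExcitonBasis, model: AggregateModel, direction) -> np.ndarray:
    """Flux operator j(u) in the exciton eigenbasis (nm * rad/fs, Hermitian)."""
    disp = _displacement_matrix(model, direction)
    Jrad = model.coupling_matrix() * CM1_TO_RAD_FS
    core = disp * Jrad  # antisymmetric: disp antisym, J sym
    V = basis.coeffs
    return 1j * (V.T @ core @ V)


@dataclass
class DiffusionTensor:
    """HSR diffusion tensor of one wall, in nm^2/ps.

    ``tensor`` is the 2x2 matrix over (z, phi); the off-diagonal elements
    are complex conjugates of each other, diagonals are real and
    non-negative.  ``partition_function`` is reported with Boltzmann
    weights referenced to the band bottom.
    """

    wall: str
    tensor: np.ndarray
    gamma_rad_fs: float
    kBT_cm1: float
    partition_function: float

    @property
    def D_zz(self) -> float:
        return float(self.tensor[0, 0].real)

    @property
    def D_phiphi(self) -> float:
        return float(self.tensor[1, 1].real)

    @property
    def D_zphi(self) -> complex:
        return complex(self.tensor[0, 1])

    @property
    def D_phiz(self) -> complex:
        return complex(self.tensor[1, 0])


def diffusion_tensor(
    basis: ExcitonBasis,
    flux_z: np.ndarray,
    flux_phi: np.ndarray,
    gamma_rad_fs: float,
    kBT_cm1: float,
    wall: str = "",
) -> DiffusionTensor:
    """Evaluate the HSR tensor from eigenpairs and flux operators.

    The Lorentzian weight ``Gamma/(Gamma^2 + omega_mu_nu^2)`` damps
    contributions of eigenstate pairs split by more than the dephasing
    rate; the Boltzmann factor weights the initial state nu thermally.
    """
    if gamma_rad_fs <= 0:
        raise ValueError("dephasing rate Gamma must be > 0")
    if kBT_cm1 <= 0:
        raise ValueError("kBT must be > 0")
    w = basis.omega_rad_fs
    dw = w[:, None] - w[None, :]
    lor = gamma_rad_fs / (gamma_rad_fs**2 + dw**2)
    e_rel = basis.energies_cm1 - basis.energies_cm1.min()
    boltz = np.exp(-e_rel / kBT_cm1)
    Z = float(boltz.sum())
    fluxes = (flux_z, flux_phi)
    D = np.empty((2, 2), dtype=complex)
    for i in range(2):
        for j in range(2):
            D[i, j] = np.sum(
                lor * np.conj(fluxes[i]) * fluxes[j] * boltz[None, :]
            ) / Z
    D *= 1e3  # nm^2/fs -> nm^2/ps
    return DiffusionTensor(wall, D, gamma_rad_fs, kBT_cm1, Z)


def molecular_units(D_nm2_ps: float, surface_density: float) -> float:
    """Convert nm^2/ps to molecules/ps via the molecular surface density."""
    if D_nm2_ps < 0 or surface_density <= 0:
        raise ValueError("inputs must be positive")
    return D_nm2_ps * surface_density


# ---------------------------------------------------------------------------
# geometry builders


def build_chain(
    n: int, spacing: float, l: float, q: float, site_energy: float = 0.0
) -> AggregateModel:
    """Linear head-to-tail chain along z (classic J-aggregate geometry)."""
    mols = [
        Molecule((0.0, 0.0, i * spacing), (0.0, 0.0, 1.0), site_energy)
        for i in range(n)
    ]
    return AggregateModel(mols, l, q, "chain")


def build_ring(
    n: int, radius: float, l: float, q: float, site_energy: float = 0.0
) -> AggregateModel:
    """Planar ring with dipoles tangential to the circle."""
    mols = []
    for i in range(n):
        th = 2 * math.pi * i / n
        mols.append(
            Molecule(
                (radius * math.cos(th), radius * math.sin(th), 0.0),
                (-math.sin(th), math.cos(th), 0.0),
                site_energy,
            )
        )
    return AggregateModel(mols, l, q, "ring")


def build_helical_cylinder(
    radius: float,
    n_rings: int,
    sites_per_ring: int,
    pitch: float,
    dipole_tilt_deg: float,
    l: float,
    q: float,
    twist_deg: float = 0.0,
    site_energy: float = 0.0,
) -> AggregateModel:
    """Molecules on a helical lattice wrapped on a cylinder.

    Ring ``j`` sits at ``z = j * pitch`` and is rotated by ``j * twist``;
    dipoles lie in the local tangent plane, tilted by ``dipole_tilt_deg``
    away from the cylinder axis.  With ``pitch = 0`` and one ring this
    degenerates to a planar ring.
    """
    if radius <= 0 or n_rings < 1 or sites_per_ring < 1:
        raise ValueError("degenerate cylinder dimensions")
    if pitch < 0:
        raise ValueError("pitch must be >= 0")
    alpha = math.radians(dipole_tilt_deg)
    twist = math.radians(twist_deg)
    mols = []
    for j in range(n_rings):
        for i in range(sites_per_ring):
            th = 2 * math.pi * i / sites_per_ring + j * twist
            phi_hat = (-math.sin(th), math.cos(th), 0.0)
            d = (
                math.sin(alpha) * phi_hat[0],
                math.sin(alpha) * phi_hat[1],
                math.cos(alpha),
            )
            mols.append(
                Molecule(
                    (radius * math.cos(th), radius * math.sin(th), j * pitch),
                    d,
                    site_energy,
                )
            )
    return AggregateModel(mols, l, q, "helical_cylinder")
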