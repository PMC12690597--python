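"""Force field and core types of the coarse-grained polyplex model.

The model represents RNA and linear polycation ("PEI") chains as
bead–spring polyelectrolytes in reduced Lennard-Jones units: every bead has
diameter sigma, mass m, and the thermal energy is fixed at k_B T = epsilon.
One RNA bead carries one nucleotide charge (-e); one PEI bead represents two
monomers at 50% protonation (+e).  Monovalent counterions (+e) and co-ions
(-e) neutralize the polymers.  Three interaction terms act between beads:

* excluded volume — purely repulsive truncated Lennard-Jones (WCA),
* chain connectivity — harmonic springs with stiffness 5000 eps/sigma^2,
* electrostatics — Coulomb with Bjerrum length l_b = 1.168 sigma,
  evaluated under periodic boundary conditions by classical Ewald summation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants as sc

from . import _kernels

__all__ = [
    "Species",
    "ReducedUnitSystem",
    "ForceFieldParams",
    "BeadTable",
    "SystemState",
    "EwaldSetup",
    "setup_ewald",
    "wca_energy",
    "bond_energy",
    "coulomb_pair_energy",
    "total_energy_forces",
    "direct_lattice_sum",
    "coulomb_constant_kj_nm",
    "kelvin_per_epsilon",
    "gromacs_dielectric",
]

#: number of real-space image shells considered "converged" for the
#: reference lattice sum used in tests
_DEFAULT_IMAGE_SHELLS = 8


class Species(enum.IntEnum):
    """Bead species; charge conventions are fixed per species."""

    RNA = 0
    PEI = 1
    COUNTERION = 2
    COION = 3


#: charge in units of e carried by each species
SPECIES_CHARGE = {
    Species.RNA: -1,
    Species.PEI: +1,
    Species.COUNTERION: +1,
    Species.COION: -1,
}


@dataclass(frozen=True)
class ReducedUnitSystem:
    """Reduced Lennard-Jones unit conventions.

    Lengths are measured in the bead diameter sigma (0.6 nm, the mean P–P
    distance of adjacent nucleotides), energies in epsilon with
    k_B T = epsilon, masses in the bead mass m.  The time unit is
    tau = sqrt(m sigma^2 / epsilon).  The Bjerrum length 1.168 sigma maps to
    ~0.7 nm, the value for water at room temperature, which anchors the
    model temperature to experimental conditions.
    """

    sigma_nm: float = 0.6
    epsilon: float = 1.0
    mass: float = 1.0
    bjerrum_length: float = 1.168

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0 or self.bjerrum_length <= 0:
            raise ValueError("sigma_nm and bjerrum_length must be positive")
        if self.epsilon <= 0 or self.mass <= 0:
            raise ValueError("epsilon and mass must be positive")

    @property
    def tau(self) -> float:
        """LJ time unit sqrt(m sigma^2 / eps); sigma = 1 in reduced length."""
        return math.sqrt(self.mass / self.epsilon)

    @property
    def kbt(self) -> float:
        """Thermal energy; fixed at epsilon (strong-polyelectrolyte regime)."""
        return self.epsilon

    @property
    def bjerrum_nm(self) -> float:
        """Physical Bjerrum length in nm."""
        return self.bjerrum_length * self.sigma_nm


def coulomb_constant_kj_nm() -> float:
    """1/(4 pi eps0) in kJ mol^-1 nm e^-2, from CODATA constants."""
    joule_m = sc.e ** 2 / (4 * math.pi * sc.epsilon_0)
    return joule_m * sc.Avogadro * 1e9 / 1e3


def kelvin_per_epsilon(epsilon_kj_mol: float = 1.0) -> float:
    """Temperature in K at which k_B T equals ``epsilon_kj_mol`` kJ/mol."""
    return epsilon_kj_mol * 1e3 / sc.R


def gromacs_dielectric(units: ReducedUnitSystem) -> float:
    """Relative dielectric constant that realizes U = k_B T l_b / r.

    Engines implementing V = f q_i q_j / (eps_r r) with
    f = 1/(4 pi eps0) = 138.935458 kJ/mol nm e^-2 reproduce the model's
    Coulomb term when eps_r = f / l_b[sigma], absorbing the solvent
    dielectric into the Bjerrum length.
    """
    return coulomb_constant_kj_nm() / units.bjerrum_length


@dataclass(frozen=True)
class ForceFieldParams:
    """Interaction parameters of the three-term force field."""

    k_bond: float = 5000.0
    wca_cutoff: float = 2.0 ** (1.0 / 6.0)
    coulomb_realspace_cutoff: float = 10.0
    coulomb_accuracy: float = 1.0e-4
    equilibrium_bond_length: float = 1.0
    #: continuous (shifted) WCA by default; the piecewise truncated form
    #: without the +epsilon shift is available for comparison
    wca_shifted: bool = True

    def __post_init__(self) -> None:
        if not math.isclose(self.wca_cutoff, 2.0 ** (1.0 / 6.0)):
            raise ValueError("wca_cutoff must be 2^(1/6) sigma")
        if self.coulomb_accuracy <= 0 or self.coulomb_accuracy >= 1:
            raise ValueError("coulomb_accuracy must be in (0, 1)")


@dataclass
class BeadTable:
    """Per-bead arrays: positions, velocities, charges, species, chain ids.

    Free ions carry chain_id = -1.  Charges are integers in units of e and
    must follow the species convention (RNA -1, PEI +1, counterion +1,
    co-ion -1).
    """

    positions: np.ndarray
    velocities: np.ndarray
    charge: np.ndarray
    species: np.ndarray
    chain_id: np.ndarray

    def __post_init__(self) -> None:
        n = self.positions.shape[0]
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.charge = np.asarray(self.charge, dtype=np.int64)
        self.species = np.asarray(self.species, dtype=np.int64)
        self.chain_id = np.asarray(self.chain_id, dtype=np.int64)
        for arr, nd in ((self.positions, 2), (self.velocities, 2),
                        (self.charge, 1), (self.species, 1), (self.chain_id, 1)):
            if arr.ndim != nd or arr.shape[0] != n:
                raise ValueError("inconsistent bead array shapes")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return len(self)

    def validate_charges(self) -> None:
        """Check the species/charge convention and global neutrality."""
        for sp, q in SPECIES_CHARGE.items():
            if not np.all(self.charge[self.species == sp] == q):
                raise ValueError(f"species {sp.name} must carry charge {q:+d}e")
        if int(self.charge.sum()) != 0:
            raise ValueError("system is not charge neutral")

    def copy(self) -> "BeadTable":
        return BeadTable(self.positions.copy(), self.velocities.copy(),
                         self.charge.copy(), self.species.copy(),
                         self.chain_id.copy())


def concatenate_beads(a: BeadTable, b: BeadTable) -> BeadTable:
    return BeadTable(
        np.vstack([a.positions, b.positions]),
        np.vstack([a.velocities, b.velocities]),
        np.concatenate([a.charge, b.charge]),
        np.concatenate([a.species, b.species]),
        np.concatenate([a.chain_id, b.chain_id]),
    )


@dataclass
class SystemState:
    """Beads + bonds in a cubic periodic box, in reduced units."""

    box_edge: float
    beads: BeadTable
    bonds: np.ndarray
    step: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def wrap(self) -> None:
        np.mod(self.beads.positions, self.box_edge, out=self.beads.positions)

    def copy(self) -> "SystemState":
        return SystemState(self.box_edge, self.beads.copy(),
                           self.bonds.copy(), self.step, self.rng_seed)

    def validate(self) -> None:
        self.beads.validate_charges()
        if self.bonds.size:
            ci = self.beads.chain_id
            if np.any(ci[self.bonds[:, 0]] != ci[self.bonds[:, 1]]):
                raise ValueError("bonded beads must share a chain id")
            if np.any(ci[self.bonds[:, 0]] < 0):
                raise ValueError("free ions cannot be bonded")
            if np.any(np.abs(self.bonds[:, 0] - self.bonds[:, 1]) != 1):
                raise ValueError("bonds must connect consecutive beads")


# ---------------------------------------------------------------------------
# pairwise potentials (scalar forms, used for oracles and documentation)
# ---------------------------------------------------------------------------

def wca_energy(r: float, params: ForceFieldParams | None = None,
               shifted: bool | None = None) -> float:
    """WCA excluded-volume energy at separation ``r`` (sigma units).

    The repulsive part of the Lennard-Jones potential, truncated at
    2^(1/6) sigma.  ``shifted=True`` adds the +epsilon constant that makes
    the energy continuous at the cutoff (forces are identical either way).
    """
    params = params or ForceFieldParams()
    if shifted is None:
        shifted = params.wca_shifted
    if r <= 0:
        raise ValueError("separation must be positive")
    if r >= params.wca_cutoff:
        return 0.0
    inv6 = (1.0 / r) ** 6
    e = 4.0 * (inv6 * inv6 - inv6)
    return e + 1.0 if shifted else e


def bond_energy(r: float, params: ForceFieldParams | None = None) -> float:
    """Harmonic bond energy 1/2 k (r - sigma)^2."""
    params = params or ForceFieldParams()
    if r < 0:
        raise ValueError("separation must be non-negative")
    dr = r - params.equilibrium_bond_length
    return 0.5 * params.k_bond * dr * dr


def coulomb_pair_energy(r: float, q_i: float, q_j: float,
                        units: ReducedUnitSystem | None = None) -> float:
    """Bare Coulomb pair energy k_B T l_b q_i q_j / r (epsilon units)."""
    units = units or ReducedUnitSystem()
    if r <= 0:
        raise ValueError("separation must be positive")
    return units.kbt * units.bjerrum_length * q_i * q_j / r


# ---------------------------------------------------------------------------
# Ewald summation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EwaldSetup:
    """Splitting parameters and reciprocal vectors for one box size."""

    box: float
    r_cut: float
    alpha: float
    n_max: int
    k_ints: np.ndarray = field(repr=False)
    a_k: np.ndarray = field(repr=False)
    #: True when the requested real-space cutoff had to be reduced to fit
    #: the minimum-image convention (box < 2 * requested cutoff)
    cutoff_reduced: bool = False


def setup_ewald(box: float, params: ForceFieldParams) -> EwaldSetup:
    """Tune (r_cut, alpha, n_max) for a target relative force accuracy.

    Uses the standard splitting heuristic: with p = sqrt(-ln delta), take
    alpha = p / r_cut and include reciprocal vectors up to
    n_max = ceil(alpha L p / pi), which balances real- and k-space
    truncation errors at ~delta.  When the box is too small for the
    requested real-space cutoff, the cutoff is reduced to just under half
    the box edge and the splitting is re-tuned (flagged on the result).
    """
    p = math.sqrt(-math.log(params.coulomb_accuracy))
    r_req = params.coulomb_realspace_cutoff
    r_cut = min(r_req, 0.49 * box)
    reduced = r_cut < r_req
    alpha = p / r_cut
    n_max = max(1, math.ceil(alpha * box * p / math.pi))
    ints = []
    n2_max = n_max * n_max
    for nx in range(0, n_max + 1):
        for ny in range(-n_max, n_max + 1):
            for nz in range(-n_max, n_max + 1):
                if nx == 0 and (ny < 0 or (ny == 0 and nz <= 0)):
                    continue
                n2 = nx * nx + ny * ny + nz * nz
                if 0 < n2 <= n2_max:
                    ints.append((nx, ny, nz))
    k_ints = np.array(ints, dtype=np.int64)
    k2 = (2.0 * math.pi / box) ** 2 * (k_ints ** 2).sum(axis=1)
    a_k = 2.0 * np.exp(-k2 / (4.0 * alpha * alpha)) / k2  # 2 = half-space
    return EwaldSetup(box, r_cut, alpha, n_max, k_ints, a_k, reduced)


def total_energy_forces(state: SystemState,
                        params: ForceFieldParams | None = None,
                        units: ReducedUnitSystem | None = None,
                        pairs: np.ndarray | None = None,
                        ewald: EwaldSetup | None = None,
                        ) -> tuple[float, np.ndarray]:
    """Potential energy and per-bead forces of a state.

    Energy = sum of WCA + harmonic bonds + full periodic electrostatics
    (real-space erfc part over the minimum image, reciprocal sum, self
    term).  Forces are the exact analytic negative gradients of the
    returned energy.  Requires a charge-neutral system whenever any bead is
    charged, and cutoffs no larger than half the box edge.
    """
    params = params or ForceFieldParams()
    units = units or ReducedUnitSystem()
    pos = state.beads.positions
    q = state.beads.charge.astype(np.float64)
    box = state.box_edge
    charged = bool(np.any(q != 0.0))
    if charged and int(round(q.sum())) != 0:
        raise ValueError("Ewald electrostatics require a neutral system")
    forces = np.zeros_like(pos)
    lb = units.bjerrum_length * units.kbt
    if charged:
        if ewald is None:
            ewald = setup_ewald(box, params)
        r_cut = ewald.r_cut
    else:
        r_cut = 0.0
    if max(r_cut, params.wca_cutoff) > 0.5 * box:
        raise ValueError("cutoff exceeds half the box edge")
    if pairs is None:
        pairs = _kernels.build_pairs(pos, box, max(r_cut, params.wca_cutoff))
    shift = 1.0 if params.wca_shifted else 0.0
    e_wca, e_real = _kernels.short_range_energy_forces(
        pos, q, pairs, box, params.wca_cutoff, shift, r_cut,
        ewald.alpha if charged else 1.0, lb if charged else 0.0, forces)
    e_bond = 0.0
    if state.bonds.size:
        e_bond = _kernels.bond_energy_forces(
            pos, state.bonds, box, params.k_bond,
            params.equilibrium_bond_length, forces)
    e_k = 0.0
    e_self = 0.0
    if charged:
        e_k = _kernels.ewald_kspace_energy_forces(
            pos, q, box, ewald.k_ints, ewald.a_k, lb, forces)
        e_self = -lb * ewald.alpha / math.sqrt(math.pi) * float((q * q).sum())
    return e_wca + e_bond + e_real + e_k + e_self, forces


def direct_lattice_sum(positions: np.ndarray, charges: np.ndarray,
                       box: float, n_shells: int = _DEFAULT_IMAGE_SHELLS,
                       units: ReducedUnitSystem | None = None) -> float:
    """Reference electrostatic energy by explicit summation over images.

    Sums the bare Coulomb interaction over all periodic images within
    ``n_shells`` whole image boxes and subtracts the cube-summation dipole
    term 2 pi |P|^2 / (3V), which converts the vacuum-boundary limit of the
    cube sum to the tin-foil boundary condition implied by Ewald summation.
    Slow; intended as an independent oracle on tiny systems.
    """
    units = units or ReducedUnitSystem()
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    if abs(q.sum()) > 1e-12:
        raise ValueError("lattice sum requires a neutral cell")
    lb = units.bjerrum_length * units.kbt
    n = len(q)
    e = 0.0
    rng = range(-n_shells, n_shells + 1)
    for ix in rng:
        for iy in rng:
            for iz in rng:
                shift = np.array([ix, iy, iz], dtype=float) * box
                central = ix == 0 and iy == 0 and iz == 0
                d = pos[:, None, :] - pos[None, :, :] + shift
                r = np.sqrt((d ** 2).sum(axis=-1))
                qq = q[:, None] * q[None, :]
                if central:
                    iu = np.triu_indices(n, 1)
                    e += (qq[iu] / r[iu]).sum()
                else:
                    e += 0.5 * (qq / r).sum()
    dipole = (q[:, None] * pos).sum(axis=0)
    e -= 2.0 * math.pi * float(dipole @ dipole) / (3.0 * box ** 3)
    return lb * e
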