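"""Construction of initial configurations and composition descriptors.

Systems contain N_RNA anionic chains of l_RNA beads and N_PEI cationic
chains of l_PEI beads in a cubic periodic box, plus one counterion (+e) per
RNA bead and one co-ion (-e) per PEI bead, so every system is exactly
neutral.  Chains are inserted as self-avoiding random walks with fixed bond
length sigma and no overlaps below 0.9 sigma; the assembly protocol prepares
the polycation and RNA subsystems in separate boxes, relaxes and
equilibrates each, then merges them and equilibrates again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .model_core import (BeadTable, ForceFieldParams, ReducedUnitSystem,
                         Species, SystemState, concatenate_beads,
                         setup_ewald, total_energy_forces)

__all__ = [
    "SystemSpec",
    "CompositionDescriptor",
    "EquilibrationParams",
    "DensityError",
    "InstabilityError",
    "alpha_np",
    "concentrations",
    "build_random_system",
    "relax_and_equilibrate",
    "build_equilibrated_system",
    "build_aggregated_start",
    "FULL_SCALE_EQUILIBRATION_STEPS",
]

#: equilibration length used for the full-scale production protocol
FULL_SCALE_EQUILIBRATION_STEPS = 2_000_000

#: hard-sphere-like overlap threshold for insertion (sigma units)
OVERLAP_THRESHOLD = 0.9


class DensityError(RuntimeError):
    """Raised when non-overlapping insertion fails at the requested density."""


class InstabilityError(RuntimeError):
    """Raised when a preparation stage produces non-finite energies."""

    def __init__(self, stage: str, detail: str = ""):
        super().__init__(f"non-finite energy during stage '{stage}' {detail}")
        self.stage = stage


@dataclass(frozen=True)
class SystemSpec:
    """Composition of a simulated system (counts, chain lengths, box)."""

    n_rna: int
    l_rna: int
    n_pei: int
    l_pei: int
    box_edge: float
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rna, self.n_pei) < 0:
            raise ValueError("chain counts must be non-negative")
        if min(self.l_rna, self.l_pei) < 1:
            raise ValueError("chain lengths must be at least 1")
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")

    @property
    def n_counterions(self) -> int:
        """One +e counterion per RNA bead."""
        return self.n_rna * self.l_rna

    @property
    def n_coions(self) -> int:
        """One -e co-ion per PEI bead."""
        return self.n_pei * self.l_pei

    @property
    def n_beads(self) -> int:
        return 2 * (self.n_rna * self.l_rna + self.n_pei * self.l_pei)


@dataclass(frozen=True)
class CompositionDescriptor:
    """Charge ratio and monomer concentrations of a composition."""

    alpha_np: float
    c_rna: float          # RNA beads per sigma^3
    c_pei: float          # PEI beads per sigma^3
    c_rna_mm: float       # the same in mmol/L via the sigma -> nm mapping
    c_pei_mm: float
    c_pei_excess: float   # c_PEI - c_RNA (beads per sigma^3)


def alpha_np(spec: SystemSpec) -> float:
    """Charge ratio alphaN/P = N_PEI l_PEI / (N_RNA l_RNA).

    With one +e per PEI bead (two monomers at 50% protonation) and one -e
    per RNA bead, this equals the ratio of polycation to RNA charge;
    alphaN/P = 1 is the isoelectric composition.
    """
    denom = spec.n_rna * spec.l_rna
    if denom == 0:
        raise ValueError("alphaN/P undefined without RNA content")
    return spec.n_pei * spec.l_pei / denom


def _beads_per_sigma3_to_mm(c: float, units: ReducedUnitSystem) -> float:
    """Convert a bead number density (sigma^-3) to mmol/L."""
    sigma_dm = units.sigma_nm * 1e-8  # nm -> dm
    per_liter = c / sigma_dm ** 3
    from scipy.constants import Avogadro
    return per_liter / Avogadro * 1e3


def concentrations(spec: SystemSpec,
                   units: ReducedUnitSystem | None = None) -> CompositionDescriptor:
    """Monomer concentrations c = N l / V_box and the excess c_PEI - c_RNA."""
    units = units or ReducedUnitSystem()
    v = spec.box_edge ** 3
    c_rna = spec.n_rna * spec.l_rna / v
    c_pei = spec.n_pei * spec.l_pei / v
    return CompositionDescriptor(
        alpha_np=c_pei / c_rna if c_rna > 0 else math.inf if c_pei else 0.0,
        c_rna=c_rna,
        c_pei=c_pei,
        c_rna_mm=_beads_per_sigma3_to_mm(c_rna, units),
        c_pei_mm=_beads_per_sigma3_to_mm(c_pei, units),
        c_pei_excess=c_pei - c_rna,
    )


# ---------------------------------------------------------------------------
# random insertion
# ---------------------------------------------------------------------------

def _min_image_dist2(points: np.ndarray, x: np.ndarray, box: float) -> np.ndarray:
    d = points - x
    d -= box * np.round(d / box)
    return (d * d).sum(axis=1)


def _insert_chain(rng: np.random.Generator, occupied: list[np.ndarray],
                  length: int, box: float, max_restarts: int = 200,
                  max_tries: int = 60) -> np.ndarray:
    """Grow one self-avoiding walk with bond length sigma, min gap 0.9 sigma."""
    thr2 = OVERLAP_THRESHOLD ** 2
    occ = np.vstack(occupied) if occupied else np.empty((0, 3))
    for _ in range(max_restarts):
        chain = np.empty((length, 3))
        chain[0] = rng.uniform(0.0, box, 3)
        if occ.size and (_min_image_dist2(occ, chain[0], box) < thr2).any():
            continue
        ok = True
        for b in range(1, length):
            placed = False
            for _ in range(max_tries):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = np.mod(chain[b - 1] + v, box)
                if occ.size and (_min_image_dist2(occ, cand, box) < thr2).any():
                    continue
                if b > 1 and (_min_image_dist2(chain[:b - 1], cand, box) < thr2).any():
                    continue
                chain[b] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return chain
    raise DensityError("self-avoiding chain insertion failed; box too dense")


def _insert_ions(rng: np.random.Generator, occupied: list[np.ndarray],
                 count: int, box: float, max_tries: int = 2000) -> np.ndarray:
    thr2 = OVERLAP_THRESHOLD ** 2
    out = np.empty((count, 3))
    occ = np.vstack(occupied) if occupied else np.empty((0, 3))
    placed = 0
    for _ in range(max_tries * max(count, 1)):
        if placed == count:
            break
        cand = rng.uniform(0.0, box, 3)
        if occ.size and (_min_image_dist2(occ, cand, box) < thr2).any():
            continue
        if placed and (_min_image_dist2(out[:placed], cand, box) < thr2).any():
            continue
        out[placed] = cand
        placed += 1
    if placed < count:
        raise DensityError("ion insertion failed; box too dense")
    return out


def _draw_velocities(rng: np.random.Generator, n: int,
                     units: ReducedUnitSystem) -> np.ndarray:
    """Maxwell-Boltzmann at T = eps/k_B, zero total momentum, exact T."""
    v = rng.normal(0.0, math.sqrt(units.kbt / units.mass), size=(n, 3))
    if n > 1:
        v -= v.mean(axis=0)
        ke = 0.5 * units.mass * (v * v).sum()
        target = 0.5 * (3 * n - 3) * units.kbt
        if ke > 0:
            v *= math.sqrt(target / ke)
    return v


def build_random_system(spec: SystemSpec,
                        units: ReducedUnitSystem | None = None,
                        species_subset: tuple[Species, ...] | None = None,
                        ) -> SystemState:
    """Random non-overlapping initial configuration for a composition.

    Chains are self-avoiding random walks with bond length sigma; one
    counterion per RNA bead and one co-ion per PEI bead are scattered in
    the remaining free volume; velocities are Maxwell-Boltzmann at
    T = eps/k_B.  ``species_subset`` restricts which species are placed
    (used by the two-box preparation protocol); ion counts follow their
    polymer species automatically.
    """
    units = units or ReducedUnitSystem()
    subset = species_subset or tuple(Species)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB111D]))
    box = spec.box_edge
    occupied: list[np.ndarray] = []
    pos_parts, species, chain_ids, bonds = [], [], [], []
    next_chain = 0
    offset = 0

    def add_chains(n_chains: int, length: int, sp: Species) -> None:
        nonlocal next_chain, offset
        for _ in range(n_chains):
            chain = _insert_chain(rng, occupied, length, box)
            occupied.append(chain)
            pos_parts.append(chain)
            species.extend([int(sp)] * length)
            chain_ids.extend([next_chain] * length)
            bonds.extend([[offset + b, offset + b + 1] for b in range(length - 1)])
            next_chain += 1
            offset += length

    def add_ions(count: int, sp: Species) -> None:
        nonlocal offset
        if count == 0:
            return
        ions = _insert_ions(rng, occupied, count, box)
        occupied.append(ions)
        pos_parts.append(ions)
        species.extend([int(sp)] * count)
        chain_ids.extend([-1] * count)
        offset += count

    if Species.RNA in subset:
        add_chains(spec.n_rna, spec.l_rna, Species.RNA)
    if Species.PEI in subset:
        add_chains(spec.n_pei, spec.l_pei, Species.PEI)
    if Species.COUNTERION in subset and Species.RNA in subset:
        add_ions(spec.n_counterions, Species.COUNTERION)
    if Species.COION in subset and Species.PEI in subset:
        add_ions(spec.n_coions, Species.COION)

    positions = np.vstack(pos_parts) if pos_parts else np.empty((0, 3))
    sp_arr = np.array(species, dtype=np.int64)
    charge = np.zeros(len(sp_arr), dtype=np.int64)
    charge[sp_arr == Species.RNA] = -1
    charge[sp_arr == Species.PEI] = 1
    charge[sp_arr == Species.COUNTERION] = 1
    charge[sp_arr == Species.COION] = -1
    beads = BeadTable(positions, _draw_velocities(rng, len(sp_arr), units),
                      charge, sp_arr,
                      np.array(chain_ids, dtype=np.int64))
    state = SystemState(box, beads,
                        np.array(bonds, dtype=np.int64).reshape(-1, 2),
                        step=0, rng_seed=spec.seed)
    state.wrap()
    return state


# ---------------------------------------------------------------------------
# relaxation and equilibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibrationParams:
    """Knobs of the relax/minimize/equilibrate protocol.

    ``eq_steps`` defaults to a desk-scale value; the full-scale protocol
    uses FULL_SCALE_EQUILIBRATION_STEPS (2e6).
    """

    softcore_steps: int = 100
    softcore_force_cap: float = 500.0
    minimize_max_iter: int = 300
    minimize_fmax: float = 20.0
    eq_steps: int = 100_000
    dt: float = 0.005
    thermostat_tau: float = 0.5
    trajectory_stride: int = 1000
    seed: int = 0


def _softcore_relax(state: SystemState, ff: ForceFieldParams,
                    units: ReducedUnitSystem, params: EquilibrationParams) -> None:
    """A few MD steps with force-capped WCA only, to remove insertion overlaps."""
    pos = state.beads.positions
    vel = state.beads.velocities
    dt = params.dt
    for _ in range(params.softcore_steps):
        pairs = _kernels.build_pairs(pos, state.box_edge, ff.wca_cutoff)
        forces = np.zeros_like(pos)
        _kernels.softcore_forces(pos, pairs, state.box_edge, ff.wca_cutoff,
                                 params.softcore_force_cap, forces)
        vel += forces / units.mass * dt
        speed = np.linalg.norm(vel, axis=1)
        fast = speed > 10.0
        if fast.any():  # cap runaway beads during overlap resolution
            vel[fast] *= (10.0 / speed[fast])[:, None]
        pos += vel * dt
        np.mod(pos, state.box_edge, out=pos)
        if not np.isfinite(pos).all():
            raise InstabilityError("softcore")


def minimize_energy(state: SystemState, ff: ForceFieldParams,
                    units: ReducedUnitSystem,
                    max_iter: int = 300, fmax: float = 20.0,
                    step0: float = 0.01) -> float:
    """Adaptive steepest descent on the full potential.

    Moves along F/max|F| with a step that grows on accepted moves and
    shrinks on rejected ones; the energy never increases because uphill
    moves are reverted.  Returns the final potential energy.
    """
    ewald = (setup_ewald(state.box_edge, ff)
             if np.any(state.beads.charge != 0) else None)
    e, f = total_energy_forces(state, ff, units, ewald=ewald)
    if not np.isfinite(e):
        raise InstabilityError("minimization", "(initial energy)")
    step = step0
    pos = state.beads.positions
    for _ in range(max_iter):
        fnorm = float(np.abs(f).max())
        if fnorm < fmax:
            break
        trial = np.mod(pos + step * f / fnorm, state.box_edge)
        st = SystemState(state.box_edge, BeadTable(
            trial, state.beads.velocities, state.beads.charge,
            state.beads.species, state.beads.chain_id), state.bonds)
        e_new, f_new = total_energy_forces(st, ff, units, ewald=ewald)
        if np.isfinite(e_new) and e_new <= e:
            pos[:] = trial
            e, f = e_new, f_new
            step = min(step * 1.2, 0.2)
        else:
            step *= 0.5
            if step < 1e-8:
                break
    return e


def relax_and_equilibrate(state: SystemState,
                          eq: EquilibrationParams | None = None,
                          ff: ForceFieldParams | None = None,
                          units: ReducedUnitSystem | None = None,
                          ) -> SystemState:
    """Soft-core relaxation, energy minimization, thermostatted equilibration.

    The standard preparation applied to freshly built (or merged) states:
    100 force-capped MD steps dissolve overlaps, steepest descent removes
    the remaining strain, and a thermostatted run at T = eps/k_B
    equilibrates the configuration.
    """
    from .md_engine import IntegratorParams, integrate

    eq = eq or EquilibrationParams()
    ff = ff or ForceFieldParams()
    units = units or ReducedUnitSystem()
    out = state.copy()
    _softcore_relax(out, ff, units, eq)
    minimize_energy(out, ff, units, eq.minimize_max_iter, eq.minimize_fmax)
    if eq.eq_steps > 0:
        rng = np.random.default_rng(np.random.SeedSequence([eq.seed, 0xE9]))
        out.beads.velocities[:] = _draw_velocities(rng, out.n_beads, units)
        params = IntegratorParams(dt=eq.dt, thermostat_target=units.kbt,
                                  thermostat_tau=eq.thermostat_tau,
                                  n_steps=eq.eq_steps,
                                  trajectory_stride=max(eq.eq_steps, 1),
                                  seed=eq.seed)
        traj = integrate(out, params, ff, units)
        if not np.isfinite(traj.potential).all():
            raise InstabilityError("equilibration")
        out = traj.final_state
    return out


def build_equilibrated_system(spec: SystemSpec,
                              eq: EquilibrationParams | None = None,
                              ff: ForceFieldParams | None = None,
                              units: ReducedUnitSystem | None = None,
                              ) -> SystemState:
    """Two-box preparation: RNA+counterions and PEI+co-ions separately.

    Each subsystem is built, relaxed, and equilibrated in its own box of
    the full volume; the two are then merged into one box and the combined
    system is relaxed and equilibrated again.
    """
    eq = eq or EquilibrationParams()
    units = units or ReducedUnitSystem()
    ff = ff or ForceFieldParams()
    halves = []
    for i, subset in enumerate(((Species.RNA, Species.COUNTERION),
                                (Species.PEI, Species.COION))):
        sub_spec = replace(spec, seed=spec.seed + i)
        sub = build_random_system(sub_spec, units, species_subset=subset)
        if sub.n_beads:
            sub = relax_and_equilibrate(
                sub, replace(eq, eq_steps=eq.eq_steps // 2, seed=eq.seed + i),
                ff, units)
        halves.append(sub)
    rna_half, pei_half = halves
    if pei_half.n_beads == 0:
        merged = rna_half
    elif rna_half.n_beads == 0:
        merged = pei_half
    else:
        beads = concatenate_beads(rna_half.beads, pei_half.beads)
        # re-key PEI chain ids after the RNA block
        n_rna_beads = rna_half.n_beads
        shift = rna_half.beads.chain_id.max() + 1 if spec.n_rna else 0
        mask = beads.chain_id[n_rna_beads:] >= 0
        beads.chain_id[n_rna_beads:][mask] += shift
        bonds = np.vstack([rna_half.bonds,
                           pei_half.bonds + n_rna_beads]).astype(np.int64)
        merged = SystemState(spec.box_edge, beads, bonds, rng_seed=spec.seed)
    merged = relax_and_equilibrate(merged, eq, ff, units)
    merged.validate()
    return merged


def build_aggregated_start(isoelectric_final: SystemState,
                           target_alpha_np: float,
                           seed: int,
                           eq: EquilibrationParams | None = None,
                           ff: ForceFieldParams | None = None,
                           units: ReducedUnitSystem | None = None,
                           equilibrate: bool = True) -> SystemState:
    """Aggregated-start state: add PEI + co-ions to an isoelectric aggregate.

    Takes a converged alphaN/P = 1 frame (all chains in one nanoparticle),
    inserts the additional PEI chains and matching co-ions at random
    non-overlapping positions to reach ``target_alpha_np``, re-seeds
    velocities, and (optionally) re-minimizes and equilibrates.  Only
    defined for added PEI, i.e. targets >= 1.
    """
    units = units or ReducedUnitSystem()
    ff = ff or ForceFieldParams()
    if target_alpha_np < 1:
        raise ValueError("aggregated-start protocol requires target >= 1")
    sp = isoelectric_final.beads.species
    n_rna_charge = int((sp == Species.RNA).sum())
    n_pei_charge = int((sp == Species.PEI).sum())
    if n_rna_charge == 0 or n_pei_charge != n_rna_charge:
        raise ValueError("input state must be an isoelectric (alphaN/P = 1) frame")
    pei_chains = np.unique(isoelectric_final.beads.chain_id[sp == Species.PEI])
    l_pei = n_pei_charge // len(pei_chains)
    n_add_beads = int(round((target_alpha_np - 1.0) * n_rna_charge))
    n_add_chains = n_add_beads // l_pei
    n_add_beads = n_add_chains * l_pei
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA99]))
    state = isoelectric_final.copy()
    state.rng_seed = seed
    box = state.box_edge
    if n_add_chains:
        occupied = [state.beads.positions]
        pos_parts, chain_ids, bonds = [], [], []
        next_chain = int(state.beads.chain_id.max()) + 1
        offset = state.n_beads
        for _ in range(n_add_chains):
            chain = _insert_chain(rng, occupied, l_pei, box)
            occupied.append(chain)
            pos_parts.append(chain)
            chain_ids.extend([next_chain] * l_pei)
            bonds.extend([[offset + b, offset + b + 1] for b in range(l_pei - 1)])
            next_chain += 1
            offset += l_pei
        ions = _insert_ions(rng, occupied, n_add_beads, box)
        pos_parts.append(ions)
        chain_ids.extend([-1] * n_add_beads)
        new_pos = np.vstack(pos_parts)
        n_new = len(new_pos)
        new_sp = np.concatenate([np.full(n_add_beads, int(Species.PEI)),
                                 np.full(n_add_beads, int(Species.COION))])
        new_q = np.concatenate([np.ones(n_add_beads, dtype=np.int64),
                                -np.ones(n_add_beads, dtype=np.int64)])
        extra = BeadTable(new_pos, np.zeros((n_new, 3)), new_q, new_sp,
                          np.array(chain_ids, dtype=np.int64))
        state.beads = concatenate_beads(state.beads, extra)
        state.bonds = np.vstack([state.bonds,
                                 np.array(bonds, dtype=np.int64)])
    state.beads.velocities[:] = _draw_velocities(rng, state.n_beads, units)
    state.wrap()
    state.validate()
    if equilibrate:
        state = relax_and_equilibrate(state, eq or EquilibrationParams(), ff, units)
    return state
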