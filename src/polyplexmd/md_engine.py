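"""Canonical-ensemble time integration and the diffusivity diagnostic.

Leapfrog integration with the stochastic velocity-rescaling (v-rescale)
thermostat.  The thermostat rescales all velocities by a common factor, so
it preserves zero total momentum and does not impose any friction on
collective motion — nanoparticle diffusion arises physically from
collisions with free ions and chains.  With the thermostat disabled, the
integrator is plain (symplectic) leapfrog and conserves energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model_core import (EwaldSetup, ForceFieldParams, ReducedUnitSystem,
                         Species, SystemState, setup_ewald,
                         total_energy_forces)

__all__ = ["IntegratorParams", "Trajectory", "integrate", "msd",
           "kinetic_temperature", "BlowUpError"]

#: Verlet-list skin added to the interaction cutoff (sigma units)
VERLET_SKIN = 0.4


class BlowUpError(RuntimeError):
    """Raised when coordinates become non-finite during integration."""

    def __init__(self, step: int):
        super().__init__(f"non-finite coordinates at step {step}")
        self.step = step


@dataclass(frozen=True)
class IntegratorParams:
    """Time step, thermostat coupling and sampling controls.

    ``thermostat_target = None`` disables coupling (NVE).  The coupling
    time defaults to 0.5 tau (100 time steps) — weak enough not to distort
    diffusive dynamics while keeping the kinetic temperature pinned.
    """

    dt: float = 0.005
    thermostat_target: float | None = 1.0
    thermostat_tau: float = 0.5
    n_steps: int = 1000
    trajectory_stride: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.trajectory_stride < 1:
            raise ValueError("stride must be >= 1")
        if self.thermostat_target is not None and self.thermostat_tau <= self.dt:
            raise ValueError("thermostat_tau must exceed dt")


@dataclass
class Trajectory:
    """Time-ordered snapshots of one run.

    ``positions`` are wrapped into the box; ``unwrapped`` accumulates true
    displacements for diffusion analysis.  Composition (species, charges,
    chain ids, bonds) is constant across frames.
    """

    steps: np.ndarray
    positions: np.ndarray      # (F, N, 3), wrapped
    unwrapped: np.ndarray      # (F, N, 3)
    potential: np.ndarray      # (F,)
    kinetic: np.ndarray        # (F,)
    box_edge: float
    dt: float
    stride: int
    species: np.ndarray
    charges: np.ndarray
    chain_ids: np.ndarray
    bonds: np.ndarray
    replicate_id: int = 0
    seed: int = 0
    final_state: SystemState | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    @property
    def times(self) -> np.ndarray:
        """Frame times in tau."""
        return self.steps * self.dt

    def frame_state(self, index: int) -> SystemState:
        """Materialize one frame as a SystemState (zero velocities)."""
        from .model_core import BeadTable
        beads = BeadTable(self.positions[index].copy(),
                          np.zeros_like(self.positions[index]),
                          self.charges.copy(), self.species.copy(),
                          self.chain_ids.copy())
        return SystemState(self.box_edge, beads, self.bonds.copy(),
                           step=int(self.steps[index]), rng_seed=self.seed)


def kinetic_temperature(velocities: np.ndarray, mass: float = 1.0) -> float:
    """Instantaneous kinetic temperature 2 KE / (3N - 3) in eps/k_B."""
    n = len(velocities)
    ke = 0.5 * mass * float((velocities * velocities).sum())
    return 2.0 * ke / (3 * n - 3) if n > 1 else 0.0


def _vrescale_factor(ke: float, ke_target: float, ndof: int, c: float,
                     rng: np.random.Generator) -> float:
    """Bussi stochastic velocity-rescaling: new KE / old KE scale factor.

    Propagates the kinetic energy by the exact solution of its
    Ornstein-Uhlenbeck-like stochastic dynamics with decay c = exp(-dt/tau);
    samples of the canonical KE distribution use one Gaussian plus a
    chi-squared variate over the remaining degrees of freedom.
    """
    r1 = rng.normal()
    rsum = rng.chisquare(ndof - 1) if ndof > 1 else 0.0
    kebar = ke_target / ndof
    ke_new = (ke + (1.0 - c) * (kebar * (rsum + r1 * r1) - ke)
              + 2.0 * r1 * math.sqrt(c * (1.0 - c) * kebar * ke))
    ke_new = max(ke_new, 1e-12)
    return math.sqrt(ke_new / ke) if ke > 0 else 1.0


def integrate(state: SystemState, params: IntegratorParams,
              ff: ForceFieldParams | None = None,
              units: ReducedUnitSystem | None = None,
              replicate_id: int = 0) -> Trajectory:
    """Run leapfrog dynamics and capture a trajectory.

    The input state is not modified; the advanced state is available as
    ``Trajectory.final_state``.  Identical inputs and seed give a
    bit-identical trajectory.
    """
    ff = ff or ForceFieldParams()
    units = units or ReducedUnitSystem()
    st = state.copy()
    st.wrap()
    pos = st.beads.positions
    vel = st.beads.velocities
    q = st.beads.charge.astype(np.float64)
    box = st.box_edge
    n = st.n_beads
    mass = units.mass
    dt = params.dt
    charged = bool(np.any(q != 0.0))
    ewald: EwaldSetup | None = setup_ewald(box, ff) if charged else None
    r_cut = max(ewald.r_cut if charged else 0.0, ff.wca_cutoff)
    r_list = r_cut + VERLET_SKIN
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x7E]))
    ndof = 3 * n - 3 if n > 1 else 3
    thermo = params.thermostat_target is not None
    if thermo:
        c_decay = math.exp(-dt / params.thermostat_tau)
        ke_target = 0.5 * ndof * params.thermostat_target

    unwrapped = pos.copy()
    pairs = _kernels.build_pairs(pos, box, r_list)
    ref_pos = pos.copy()
    e_pot, forces = total_energy_forces(st, ff, units, pairs=pairs, ewald=ewald)

    n_frames = params.n_steps // params.trajectory_stride + 1
    steps_out = np.empty(n_frames, dtype=np.int64)
    pos_out = np.empty((n_frames, n, 3))
    unw_out = np.empty((n_frames, n, 3))
    pot_out = np.empty(n_frames)
    kin_out = np.empty(n_frames)

    def record(fi: int, step: int) -> None:
        steps_out[fi] = st.step
        pos_out[fi] = pos
        unw_out[fi] = unwrapped
        pot_out[fi] = e_pot
        kin_out[fi] = 0.5 * mass * float((vel * vel).sum())

    record(0, st.step)
    fi = 1
    skin2 = (0.5 * VERLET_SKIN) ** 2
    for step in range(1, params.n_steps + 1):
        vel += forces / mass * dt
        if thermo:
            ke = 0.5 * mass * float((vel * vel).sum())
            vel *= _vrescale_factor(ke, ke_target, ndof, c_decay, rng)
        disp = vel * dt
        unwrapped += disp
        pos += disp
        np.mod(pos, box, out=pos)
        if not np.isfinite(pos).all():
            raise BlowUpError(st.step + 1)
        st.step += 1
        # displacement-based Verlet rebuild criterion
        d = pos - ref_pos
        d -= box * np.round(d / box)
        if float((d * d).sum(axis=1).max()) > skin2:
            pairs = _kernels.build_pairs(pos, box, r_list)
            ref_pos = pos.copy()
        e_pot, forces = total_energy_forces(st, ff, units, pairs=pairs,
                                            ewald=ewald)
        if step % params.trajectory_stride == 0:
            record(fi, st.step)
            fi += 1

    return Trajectory(steps_out[:fi], pos_out[:fi], unw_out[:fi],
                      pot_out[:fi], kin_out[:fi], box, dt,
                      params.trajectory_stride,
                      st.beads.species.copy(), st.beads.charge.copy(),
                      st.beads.chain_id.copy(), st.bonds.copy(),
                      replicate_id=replicate_id, seed=params.seed,
                      final_state=st)


# ---------------------------------------------------------------------------
# mean-square displacement
# ---------------------------------------------------------------------------

def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Multiple-time-origin MSD of columns of x via the FFT identity."""
    f, m = x.shape
    nfft = 1 << (2 * f - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * fx.conj(), n=nfft, axis=0)[:f].real
    sq = x * x
    ssum = sq.sum(axis=0)
    msd = np.empty((f, m))
    tail_head = np.zeros(m)
    for lag in range(f):
        if lag > 0:
            tail_head += sq[lag - 1] + sq[f - lag]
        msd[lag] = (2.0 * ssum - tail_head - 2.0 * acf[lag]) / (f - lag)
    return msd


def msd(traj: Trajectory, species: Species | None = None,
        max_lag_frames: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean-square displacement vs lag time, averaged over time origins.

    Uses the unwrapped coordinates of the selected beads (all beads when
    ``species`` is None; RNA beads are the usual choice for polyplexes).
    Returns (lag times in tau, MSD in sigma^2) for lags 0..max_lag.
    """
    if species is None:
        sel = slice(None)
    else:
        sel = traj.species == int(species)
    x = traj.unwrapped[:, sel, :]
    f = x.shape[0]
    if max_lag_frames is None:
        max_lag_frames = f - 1
    if max_lag_frames >= f:
        raise ValueError("lag exceeds trajectory length")
    flat = x.reshape(f, -1)
    per_col = _msd_fft_1d(flat)[: max_lag_frames + 1]
    msd_vals = per_col.reshape(max_lag_frames + 1, -1, 3).sum(axis=2).mean(axis=1)
    lags = np.arange(max_lag_frames + 1) * traj.stride * traj.dt
    return lags, msd_vals


def loglog_slope(lags: np.ndarray, values: np.ndarray,
                 window: tuple[float, float]) -> float:
    """Least-squares slope of log(MSD) vs log(lag) inside a lag window."""
    mask = (lags >= window[0]) & (lags <= window[1]) & (values > 0)
    if mask.sum() < 2:
        raise ValueError("fewer than two points in the fit window")
    return float(np.polyfit(np.log(lags[mask]), np.log(values[mask]), 1)[0])
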