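"""Trajectory and table I/O: extended XYZ (text) and an npz container."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .model_core import BeadTable, Species, SystemState

__all__ = ["write_extxyz", "read_extxyz", "save_trajectory", "load_trajectory"]

_SPECIES_NAMES = {int(s): s.name for s in Species}
_SPECIES_IDS = {s.name: int(s) for s in Species}


def _frame_lines(positions, box, species, charge, chain_id, comment_extra=""):
    n = len(positions)
    lattice = f"{box:.10g} 0 0 0 {box:.10g} 0 0 0 {box:.10g}"
    props = "species:S:1:pos:R:3:charge:I:1:chain_id:I:1"
    lines = [str(n),
             f'Lattice="{lattice}" Properties={props} pbc="T T T"'
             + (" " + comment_extra if comment_extra else "")]
    for i in range(n):
        x, y, z = positions[i]
        lines.append(f"{_SPECIES_NAMES[int(species[i])]} "
                     f"{x:.8f} {y:.8f} {z:.8f} "
                     f"{int(charge[i])} {int(chain_id[i])}")
    return lines


def write_extxyz(path, frames, box, species, charge, chain_id,
                 steps=None, dt=None, stride=None) -> None:
    """Write one or more frames as extended XYZ with per-atom columns."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    steps = steps if steps is not None else range(len(frames))
    meta = []
    if dt is not None:
        meta.append(f"dt={dt}")
    if stride is not None:
        meta.append(f"stride={stride}")
    lines = []
    for fi, step in zip(range(len(frames)), steps):
        extra = " ".join([f"step={int(step)}"] + meta)
        lines.extend(_frame_lines(frames[fi], box, species, charge,
                                  chain_id, extra))
    Path(path).write_text("\n".join(lines) + "\n")


def read_extxyz(path):
    """Read an extended-XYZ file written by :func:`write_extxyz`.

    Returns (positions (F, N, 3), box, species, charge, chain_id, steps).
    """
    text = Path(path).read_text().splitlines()
    pos_frames, steps = [], []
    species = charge = chain_id = None
    box = None
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        n = int(text[i])
        comment = text[i + 1]
        m = re.search(r'Lattice="([^"]+)"', comment)
        lattice = [float(v) for v in m.group(1).split()]
        box = lattice[0]
        m = re.search(r"step=(\d+)", comment)
        steps.append(int(m.group(1)) if m else len(pos_frames))
        pos = np.empty((n, 3))
        sp = np.empty(n, dtype=np.int64)
        q = np.empty(n, dtype=np.int64)
        cid = np.empty(n, dtype=np.int64)
        for k in range(n):
            parts = text[i + 2 + k].split()
            sp[k] = _SPECIES_IDS[parts[0]]
            pos[k] = [float(v) for v in parts[1:4]]
            q[k] = int(parts[4])
            cid[k] = int(parts[5])
        pos_frames.append(pos)
        species, charge, chain_id = sp, q, cid
        i += 2 + n
    return (np.array(pos_frames), box, species, charge, chain_id,
            np.array(steps, dtype=np.int64))


def state_to_extxyz(state: SystemState, path) -> None:
    b = state.beads
    write_extxyz(path, b.positions, state.box_edge, b.species, b.charge,
                 b.chain_id, steps=[state.step])


def save_trajectory(traj, path) -> None:
    """Binary (npz) container for a Trajectory, including metadata."""
    np.savez_compressed(
        path, steps=traj.steps, positions=traj.positions,
        unwrapped=traj.unwrapped, potential=traj.potential,
        kinetic=traj.kinetic, box_edge=traj.box_edge, dt=traj.dt,
        stride=traj.stride, species=traj.species, charges=traj.charges,
        chain_ids=traj.chain_ids, bonds=traj.bonds,
        replicate_id=traj.replicate_id, seed=traj.seed)


def load_trajectory(path):
    from .md_engine import Trajectory
    with np.load(path) as z:
        return Trajectory(
            steps=z["steps"], positions=z["positions"],
            unwrapped=z["unwrapped"], potential=z["potential"],
            kinetic=z["kinetic"], box_edge=float(z["box_edge"]),
            dt=float(z["dt"]), stride=int(z["stride"]),
            species=z["species"], charges=z["charges"],
            chain_ids=z["chain_ids"], bonds=z["bonds"],
            replicate_id=int(z["replicate_id"]), seed=int(z["seed"]))
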