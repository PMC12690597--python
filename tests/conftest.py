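import numpy as np
import pytest

from polyplexmd.model_core import (SPECIES_CHARGE, BeadTable, ForceFieldParams,
                                   ReducedUnitSystem, Species, SystemState)


@pytest.fixture(scope="session")
def units():
    return ReducedUnitSystem()


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams()


@pytest.fixture
def make_frame():
    """Factory for synthetic SystemStates from explicit coordinates.

    ``chains`` is a list of (species, (n, 3) coords); ``ions`` a list of
    (species, (m, 3) coords).  Bonds connect consecutive beads of each
    chain; charges follow the species convention.
    """

    def _make(box, chains=(), ions=()):
        pos, vel, charge, species, chain_id, bonds = [], [], [], [], [], []
        offset = 0
        for cid, (sp, coords) in enumerate(chains):
            coords = np.atleast_2d(np.asarray(coords, dtype=float))
            n = len(coords)
            pos.append(coords)
            charge.extend([SPECIES_CHARGE[Species(sp)]] * n)
            species.extend([int(sp)] * n)
            chain_id.extend([cid] * n)
            bonds.extend([[offset + i, offset + i + 1] for i in range(n - 1)])
            offset += n
        for sp, coords in ions:
            coords = np.atleast_2d(np.asarray(coords, dtype=float))
            n = len(coords)
            pos.append(coords)
            charge.extend([SPECIES_CHARGE[Species(sp)]] * n)
            species.extend([int(sp)] * n)
            chain_id.extend([-1] * n)
            offset += n
        positions = np.vstack(pos) if pos else np.empty((0, 3))
        beads = BeadTable(positions, np.zeros_like(positions),
                          np.array(charge, dtype=np.int64),
                          np.array(species, dtype=np.int64),
                          np.array(chain_id, dtype=np.int64))
        state = SystemState(box, beads,
                            np.array(bonds, dtype=np.int64).reshape(-1, 2))
        state.wrap()
        return state

    return _make


def random_neutral_state(rng, n=20, box=6.0, with_chain=True):
    """Random neutral ion gas, optionally with one short bonded RNA chain.

    Positions are rejection-sampled to keep pair separations above
    0.9 sigma, like any physically prepared configuration.
    """
    pos = np.empty((n, 3))
    placed = 0
    if with_chain and n >= 6:
        start = rng.uniform(0, box, 3)
        for k in range(3):
            pos[k] = np.mod(start + [k, 0.0, 0.0], box)
        placed = 3
    while placed < n:
        cand = rng.uniform(0, box, 3)
        d = pos[:placed] - cand
        d -= box * np.round(d / box)
        if placed and ((d * d).sum(axis=1) < 0.81).any():
            continue
        pos[placed] = cand
        placed += 1
    charge = np.tile([1, -1], n // 2 + 1)[:n].astype(np.int64)
    if charge.sum() != 0:
        charge[-1] = -charge[:-1].sum()
    species = np.where(charge > 0, int(Species.COUNTERION),
                       int(Species.COION)).astype(np.int64)
    chain_id = -np.ones(n, dtype=np.int64)
    bonds = np.empty((0, 2), dtype=np.int64)
    if with_chain and n >= 6:
        species[:3] = int(Species.RNA)
        charge[:3] = -1
        chain_id[:3] = 0
        flip = np.flatnonzero(charge[3:] < 0)[: max(0, -int(charge.sum()) // 2)]
        charge[3 + flip] = 1
        species[3 + flip] = int(Species.COUNTERION)
        bonds = np.array([[0, 1], [1, 2]], dtype=np.int64)
        # keep the chain bonded at reasonable separations
        pos[1] = np.mod(pos[0] + [1.0, 0, 0], box)
        pos[2] = np.mod(pos[0] + [2.0, 0, 0], box)
    beads = BeadTable(pos, np.zeros_like(pos), charge, species, chain_id)
    return SystemState(box, beads, bonds)
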