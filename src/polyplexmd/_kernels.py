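"""Numba-compiled inner loops for the force field and integrator.

All kernels work in reduced units (lengths in sigma, energies in epsilon,
charges in e).  Positions are assumed wrapped into [0, box).  Forces are
accumulated into a caller-provided (N, 3) array.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT_PI = math.sqrt(math.pi)


@njit(cache=True)
def count_pairs_within(pos, box, r_list):
    """Number of minimum-image pairs with r < r_list (brute force)."""
    n = pos.shape[0]
    r2 = r_list * r_list
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            if dx * dx + dy * dy + dz * dz < r2:
                count += 1
    return count


@njit(cache=True)
def build_pairs(pos, box, r_list):
    """Verlet pair list: all minimum-image pairs with r < r_list.

    Brute-force O(N^2) rebuild; amortized over many steps by the skin.
    """
    n = pos.shape[0]
    count = count_pairs_within(pos, box, r_list)
    pairs = np.empty((count, 2), dtype=np.int64)
    r2 = r_list * r_list
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            if dx * dx + dy * dy + dz * dz < r2:
                pairs[k, 0] = i
                pairs[k, 1] = j
                k += 1
    return pairs


@njit(cache=True, fastmath=True, error_model="numpy")
def short_range_energy_forces(pos, q, pairs, box, wca_cut, wca_shift,
                              r_cut_coul, alpha, lb, forces):
    """WCA + real-space Ewald over a pair list.

    Returns (E_wca, E_coulomb_real).  ``wca_shift`` is the constant added to
    the Lennard-Jones repulsion inside the cutoff (epsilon for the
    continuous convention, 0 for the printed piecewise form).  erfc is
    evaluated by the Abramowitz–Stegun 7.1.26 rational approximation
    (|error| < 1.5e-7), sharing one exponential with the force term.
    """
    e_wca = 0.0
    e_real = 0.0
    wca2 = wca_cut * wca_cut
    rc2 = r_cut_coul * r_cut_coul
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= rc2 and d2 >= wca2:
            continue
        fmag = 0.0  # force magnitude divided by r
        if d2 < wca2:
            inv2 = 1.0 / d2
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            e_wca += 4.0 * (inv12 - inv6) + wca_shift
            fmag += (48.0 * inv12 - 24.0 * inv6) * inv2
        qq = q[i] * q[j]
        if qq != 0.0 and d2 < rc2:
            r = math.sqrt(d2)
            x = alpha * r
            expx2 = math.exp(-x * x)
            t = 1.0 / (1.0 + 0.3275911 * x)
            erfc_t = t * (0.254829592 + t * (-0.284496736 + t * (
                1.421413741 + t * (-1.453152027 + t * 1.061405429)))) * expx2
            e_real += lb * qq * erfc_t / r
            fmag += lb * qq * (erfc_t / (d2 * r)
                               + 2.0 * alpha / _SQRT_PI * expx2 / d2)
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e_wca, e_real


@njit(cache=True, fastmath=True, error_model="numpy")
def bond_energy_forces(pos, bonds, box, k_bond, r0, forces):
    """Harmonic bonds U = 1/2 k (r - r0)^2 with minimum-image bond vectors."""
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        e += 0.5 * k_bond * dr * dr
        if r > 0.0:
            fmag = -k_bond * dr / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    return e


@njit(cache=True, fastmath=True, error_model="numpy")
def ewald_kspace_energy_forces(pos, q, box, k_ints, a_k, lb, forces):
    """Reciprocal-space Ewald energy and forces via structure factors.

    ``k_ints`` are half-space integer triples, ``a_k`` the corresponding
    exp(-k^2/4 alpha^2)/k^2 factors already including the half-space
    degeneracy factor 2.
    """
    n = pos.shape[0]
    nk = k_ints.shape[0]
    # max |integer index| per dimension
    nmax = 0
    for m in range(nk):
        for d in range(3):
            a = abs(k_ints[m, d])
            if a > nmax:
                nmax = a
    two_pi = 2.0 * math.pi
    # e^{i 2 pi n x / L} tables via recursion
    exr = np.empty((n, nmax + 1))
    exi = np.empty((n, nmax + 1))
    eyr = np.empty((n, nmax + 1))
    eyi = np.empty((n, nmax + 1))
    ezr = np.empty((n, nmax + 1))
    ezi = np.empty((n, nmax + 1))
    for i in range(n):
        exr[i, 0] = 1.0
        exi[i, 0] = 0.0
        eyr[i, 0] = 1.0
        eyi[i, 0] = 0.0
        ezr[i, 0] = 1.0
        ezi[i, 0] = 0.0
        cx = math.cos(two_pi * pos[i, 0] / box)
        sx = math.sin(two_pi * pos[i, 0] / box)
        cy = math.cos(two_pi * pos[i, 1] / box)
        sy = math.sin(two_pi * pos[i, 1] / box)
        cz = math.cos(two_pi * pos[i, 2] / box)
        sz = math.sin(two_pi * pos[i, 2] / box)
        for m in range(1, nmax + 1):
            exr[i, m] = exr[i, m - 1] * cx - exi[i, m - 1] * sx
            exi[i, m] = exr[i, m - 1] * sx + exi[i, m - 1] * cx
            eyr[i, m] = eyr[i, m - 1] * cy - eyi[i, m - 1] * sy
            eyi[i, m] = eyr[i, m - 1] * sy + eyi[i, m - 1] * cy
            ezr[i, m] = ezr[i, m - 1] * cz - ezi[i, m - 1] * sz
            ezi[i, m] = ezr[i, m - 1] * sz + ezi[i, m - 1] * cz
    vol = box * box * box
    pref = 2.0 * math.pi * lb / vol
    energy = 0.0
    cr_i = np.empty(n)
    ci_i = np.empty(n)
    for m in range(nk):
        nx = k_ints[m, 0]
        ny = k_ints[m, 1]
        nz = k_ints[m, 2]
        sr = 0.0
        si = 0.0
        for i in range(n):
            # e^{ik.r} = ex * ey * ez with conjugates for negative indices
            ar = exr[i, nx]  # nx > 0 by half-space construction (or 0)
            ai = exi[i, nx]
            if ny >= 0:
                br = eyr[i, ny]
                bi = eyi[i, ny]
            else:
                br = eyr[i, -ny]
                bi = -eyi[i, -ny]
            if nz >= 0:
                cr = ezr[i, nz]
                ci = ezi[i, nz]
            else:
                cr = ezr[i, -nz]
                ci = -ezi[i, -nz]
            tr = ar * br - ai * bi
            ti = ar * bi + ai * br
            er = tr * cr - ti * ci
            ei = tr * ci + ti * cr
            cr_i[i] = er
            ci_i[i] = ei
            sr += q[i] * er
            si += q[i] * ei
        energy += pref * a_k[m] * (sr * sr + si * si)
        kx = two_pi * nx / box
        ky = two_pi * ny / box
        kz = two_pi * nz / box
        for i in range(n):
            # F_i = 2 pref q_i a_k k [sin(k.r_i) Re S - cos(k.r_i) Im S]
            g = 2.0 * pref * q[i] * a_k[m] * (ci_i[i] * sr - cr_i[i] * si)
            forces[i, 0] += g * kx
            forces[i, 1] += g * ky
            forces[i, 2] += g * kz
    return energy


@njit(cache=True, error_model="numpy")
def softcore_forces(pos, pairs, box, wca_cut, f_cap, forces):
    """Force-capped WCA repulsion used to relax overlaps after insertion."""
    wca2 = wca_cut * wca_cut
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= wca2 or d2 == 0.0:
            continue
        inv2 = 1.0 / d2
        inv6 = inv2 * inv2 * inv2
        fmag = (48.0 * inv6 * inv6 - 24.0 * inv6) * inv2  # F/r
        r = math.sqrt(d2)
        if fmag * r > f_cap:
            fmag = f_cap / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz


@njit(cache=True)
def min_distance(pos_a, pos_b, box):
    """Smallest minimum-image distance between two coordinate sets."""
    best = 1.0e300
    for i in range(pos_a.shape[0]):
        for j in range(pos_b.shape[0]):
            dx = pos_a[i, 0] - pos_b[j, 0]
            dy = pos_a[i, 1] - pos_b[j, 1]
            dz = pos_a[i, 2] - pos_b[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best:
                best = d2
    return math.sqrt(best)
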