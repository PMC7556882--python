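"""Numba kernels for pairwise energies and forces.

All kernels use the minimum-image convention for periodic axes, accumulate
forces in place into a caller-provided array, and return energy terms.
Intramolecular pairs (equal molecule id) are excluded from non-bonded sums;
molecular connectivity enters only through the bonded kernels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["nonbonded", "tagged_vdw", "tagged_coulomb", "bonded"]


@njit(cache=True, fastmath=False)
def _min_image_r2(pos, i, j, lengths, periodic, dr):
    d = pos.shape[1]
    r2 = 0.0
    for k in range(d):
        x = pos[i, k] - pos[j, k]
        if periodic[k]:
            L = lengths[k]
            x -= L * np.rint(x / L)
        dr[k] = x
        r2 += x * x
    return r2


@njit(cache=True, fastmath=False)
def nonbonded(
    pos, lengths, periodic, typ, q, mol,
    eps, sig, rc_v, shifted,
    cpre, krf, crf, rc_c,
    skip_a, skip_b, forces,
):
    """Shifted LJ + reaction-field Coulomb over all unlike-molecule pairs.

    Pairs involving particle ``skip_a`` or ``skip_b`` are omitted (they are
    handled by the tagged kernels during an alchemical move); pass -1 to
    include everything.  Returns ``(e_vdw, e_coulomb)``.
    """
    n, d = pos.shape
    dr = np.empty(3)
    rc_v2 = rc_v * rc_v
    rc_c2 = rc_c * rc_c
    e_vdw = 0.0
    e_coul = 0.0
    for i in range(n - 1):
        if i == skip_a or i == skip_b:
            continue
        for j in range(i + 1, n):
            if j == skip_a or j == skip_b:
                continue
            if mol[i] == mol[j]:
                continue
            r2 = _min_image_r2(pos, i, j, lengths, periodic, dr)
            fcoef = 0.0
            if r2 < rc_v2:
                e = eps[typ[i], typ[j]]
                if e > 0.0:
                    s = sig[typ[i], typ[j]]
                    sr6 = (s * s / r2) ** 3
                    e_vdw += 4.0 * e * (sr6 * sr6 - sr6)
                    if shifted:
                        src6 = (s * s / rc_v2) ** 3
                        e_vdw -= 4.0 * e * (src6 * src6 - src6)
                    fcoef += 24.0 * e * sr6 * (2.0 * sr6 - 1.0) / r2
            if r2 < rc_c2:
                qq = q[i] * q[j]
                if qq != 0.0:
                    r = np.sqrt(r2)
                    kq = cpre * qq
                    e_coul += kq * (1.0 / r + krf * r2 - crf)
                    fcoef += kq * (1.0 / (r2 * r) - 2.0 * krf)
            if fcoef != 0.0:
                for k in range(d):
                    f = fcoef * dr[k]
                    forces[i, k] += f
                    forces[j, k] -= f
    return e_vdw, e_coul


@njit(cache=True, fastmath=False)
def _lj_terms(e, s, r2, rc2, shifted):
    """(energy, fcoef) of the shifted 6-12 LJ at squared separation r2."""
    sr6 = (s * s / r2) ** 3
    u = 4.0 * e * (sr6 * sr6 - sr6)
    if shifted:
        src6 = (s * s / rc2) ** 3
        u -= 4.0 * e * (src6 * src6 - src6)
    fcoef = 24.0 * e * sr6 * (2.0 * sr6 - 1.0) / r2
    return u, fcoef


@njit(cache=True, fastmath=False)
def _softcore_terms(e, s, r2, rc2, shifted, lam, delta):
    """(energy, fcoef) of the soft-core LJ: U = 4 e lam (A^6 - A^3),
    A = s^2 / (r^2 + delta (1 - lam)); finite at r = 0 for lam < 1, delta > 0."""
    if lam == 0.0:
        return 0.0, 0.0
    pad = delta * (1.0 - lam)
    a = s * s / (r2 + pad)
    a3 = a * a * a
    u = 4.0 * e * lam * (a3 * a3 - a3)
    if shifted:
        ac = s * s / (rc2 + pad)
        ac3 = ac * ac * ac
        u -= 4.0 * e * lam * (ac3 * ac3 - ac3)
    # dU/dr2 = 4 e lam (6A^5 - 3A^2) dA/dr2, dA/dr2 = -A^2/s^2
    du_dr2 = -4.0 * e * lam * (6.0 * a3 * a3 - 3.0 * a3) / (r2 + pad)
    fcoef = -2.0 * du_dr2
    return u, fcoef


@njit(cache=True, fastmath=False)
def tagged_vdw(
    pos, lengths, periodic, typ, mol,
    ia, ib, ta, tb,
    eps, sig, rc_v, shifted,
    softcore, sc_lam, delta,
    scale, forces,
):
    """vdW interactions of the two tagged head beads with everything else.

    The tagged beads carry override types ``ta`` (bead ia) and ``tb``
    (bead ib).  ``softcore`` selects the soft-core form with internal
    coupling ``sc_lam``; otherwise plain (shifted) LJ is used.  Energy and
    accumulated forces are multiplied by ``scale``.  Returns the scaled
    vdW energy.
    """
    n, d = pos.shape
    dr = np.empty(3)
    rc2 = rc_v * rc_v
    e_tot = 0.0
    if scale == 0.0:
        return 0.0
    for pick in range(2):
        i = ia if pick == 0 else ib
        ti = ta if pick == 0 else tb
        for j in range(n):
            if j == i:
                continue
            if pick == 1 and j == ia:
                continue  # the (ia, ib) pair was counted from ia's side
            if mol[j] == mol[i]:
                continue
            tj = typ[j]
            if pick == 0 and j == ib:
                tj = tb
            r2 = _min_image_r2(pos, i, j, lengths, periodic, dr)
            if r2 >= rc2:
                continue
            e = eps[ti, tj]
            if e == 0.0:
                continue
            s = sig[ti, tj]
            if softcore:
                u, fcoef = _softcore_terms(e, s, r2, rc2, shifted, sc_lam, delta)
            else:
                u, fcoef = _lj_terms(e, s, r2, rc2, shifted)
            e_tot += u
            fcoef *= scale
            for k in range(d):
                f = fcoef * dr[k]
                forces[i, k] += f
                forces[j, k] -= f
    return scale * e_tot


@njit(cache=True, fastmath=False)
def tagged_coulomb(
    pos, lengths, periodic, q, mol,
    ia, ib, qa, qb,
    cpre, krf, crf, rc_c,
    scale, forces,
):
    """Reaction-field Coulomb of the tagged heads (override charges qa, qb)
    with everything else, scaled by ``scale``.  Returns the scaled energy."""
    n, d = pos.shape
    dr = np.empty(3)
    rc2 = rc_c * rc_c
    e_tot = 0.0
    if scale == 0.0:
        return 0.0
    for pick in range(2):
        i = ia if pick == 0 else ib
        qi = qa if pick == 0 else qb
        if qi == 0.0:
            continue  # every pair of this bead has zero charge product
        for j in range(n):
            if j == i:
                continue
            if pick == 1 and j == ia:
                continue
            if mol[j] == mol[i]:
                continue
            qj = q[j]
            if pick == 0 and j == ib:
                qj = qb
            qq = qi * qj
            if qq == 0.0:
                continue
            r2 = _min_image_r2(pos, i, j, lengths, periodic, dr)
            if r2 >= rc2:
                continue
            r = np.sqrt(r2)
            kq = cpre * qq
            e_tot += kq * (1.0 / r + krf * r2 - crf)
            fcoef = scale * kq * (1.0 / (r2 * r) - 2.0 * krf)
            for k in range(d):
                f = fcoef * dr[k]
                forces[i, k] += f
                forces[j, k] -= f
    return scale * e_tot


@njit(cache=True, fastmath=False)
def bonded(
    pos, lengths, periodic,
    bond_idx, bond_k, bond_r0,
    angle_idx, angle_k, angle_cos0,
    forces,
):
    """Harmonic bonds + cosine-harmonic angles.  Returns the bonded energy."""
    d = pos.shape[1]
    dr = np.empty(3)
    u = np.empty(3)
    v = np.empty(3)
    e_tot = 0.0
    for b in range(bond_idx.shape[0]):
        i = bond_idx[b, 0]
        j = bond_idx[b, 1]
        r2 = _min_image_r2(pos, i, j, lengths, periodic, dr)
        r = np.sqrt(r2)
        x = r - bond_r0[b]
        e_tot += 0.5 * bond_k[b] * x * x
        fcoef = -bond_k[b] * x / r
        for k in range(d):
            f = fcoef * dr[k]
            forces[i, k] += f
            forces[j, k] -= f
    for a in range(angle_idx.shape[0]):
        i = angle_idx[a, 0]
        j = angle_idx[a, 1]
        kk = angle_idx[a, 2]
        ru2 = _min_image_r2(pos, i, j, lengths, periodic, u)
        rv2 = _min_image_r2(pos, kk, j, lengths, periodic, v)
        ru = np.sqrt(ru2)
        rv = np.sqrt(rv2)
        c = 0.0
        for k in range(d):
            c += u[k] * v[k]
        c /= ru * rv
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        dc = c - angle_cos0[a]
        e_tot += 0.5 * angle_k[a] * dc * dc
        g = -angle_k[a] * dc  # -dU/dc
        for k in range(d):
            fi = g * (v[k] / (ru * rv) - c * u[k] / ru2)
            fk = g * (u[k] / (ru * rv) - c * v[k] / rv2)
            forces[i, k] += fi
            forces[kk, k] += fk
            forces[j, k] -= fi + fk
    return e_tot
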