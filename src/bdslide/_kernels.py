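"""Numba kernels for energies, forces and Monte Carlo moves.

All kernels operate on flat numpy arrays extracted from a
:class:`~bdslide.model.SystemSpec`; the wrapper layer lives in
:mod:`bdslide.energy`.  Energies in kcal/mol, lengths in Å.

The electrostatic screening mode is encoded as an integer:
0 = bare Debye–Hückel, 1 = per-sphere DLVO finite-size factors (folded into
the per-bead charge prefactor by the caller), 2 = a single DLVO factor
evaluated at the pair effective radius sqrt((a_i²+a_j²)/2).
"""

import numpy as np
from numba import njit

_TINY = 1e-12


@njit(cache=True, fastmath=False)
def bond_terms(x, bonds, bond_k, bond_r0, F):
    e = 0.0
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _TINY:
            # coincident bonded beads: energy defined, gradient direction is not
            e += 0.5 * bond_k[b] * bond_r0[b] ** 2
            continue
        dr = r - bond_r0[b]
        e += 0.5 * bond_k[b] * dr * dr
        g = bond_k[b] * dr / r
        F[i, 0] -= g * dx
        F[i, 1] -= g * dy
        F[i, 2] -= g * dz
        F[j, 0] += g * dx
        F[j, 1] += g * dy
        F[j, 2] += g * dz
    return e


@njit(cache=True, fastmath=False)
def angle_terms(x, angles, angle_k, angle_t0, F):
    e = 0.0
    for t in range(angles.shape[0]):
        i, j, k = angles[t, 0], angles[t, 1], angles[t, 2]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - angle_t0[t]
        e += 0.5 * angle_k[t] * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8  # guarded collinear branch; prefactor dth -> 0 at theta0 = pi
        coef = angle_k[t] * dth / s
        inunv = 1.0 / (nu * nv)
        inu2 = c / (nu * nu)
        inv2 = c / (nv * nv)
        gix = coef * (vx * inunv - ux * inu2)
        giy = coef * (vy * inunv - uy * inu2)
        giz = coef * (vz * inunv - uz * inu2)
        gkx = coef * (ux * inunv - vx * inv2)
        gky = coef * (uy * inunv - vy * inv2)
        gkz = coef * (uz * inunv - vz * inv2)
        F[i, 0] += gix
        F[i, 1] += giy
        F[i, 2] += giz
        F[k, 0] += gkx
        F[k, 1] += gky
        F[k, 2] += gkz
        F[j, 0] -= gix + gkx
        F[j, 1] -= giy + gky
        F[j, 2] -= giz + gkz
    return e


@njit(cache=True, fastmath=False)
def _dihedral(x, i, j, k, l):
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.sqrt((b2 * b2).sum())
    m1 = np.cross(n1, b2 / nb2)
    xx = (n1 * n2).sum()
    # sign convention: a right-handed helix (the B-DNA build) has positive
    # torsion angles
    yy = -(m1 * n2).sum()
    return np.arctan2(yy, xx), b1, b2, b3, n1, n2, nb2


@njit(cache=True, fastmath=False)
def torsion_terms(x, tors, tor_k, tor_p0, F):
    e = 0.0
    for t in range(tors.shape[0]):
        i, j, k, l = tors[t, 0], tors[t, 1], tors[t, 2], tors[t, 3]
        b1x = x[j, 0] - x[i, 0]
        b1y = x[j, 1] - x[i, 1]
        b1z = x[j, 2] - x[i, 2]
        b2x = x[k, 0] - x[j, 0]
        b2y = x[k, 1] - x[j, 1]
        b2z = x[k, 2] - x[j, 2]
        b3x = x[l, 0] - x[k, 0]
        b3y = x[l, 1] - x[k, 1]
        b3z = x[l, 2] - x[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        # phi = atan2((n1 x n2)·b2_hat, n1·n2): right-handed helix positive
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        yy = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        xx = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(yy, xx)
        dphi = phi - tor_p0[t]
        while dphi > np.pi:
            dphi -= 2 * np.pi
        while dphi <= -np.pi:
            dphi += 2 * np.pi
        e += 0.5 * tor_k[t] * dphi * dphi
        dV = tor_k[t] * dphi
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < _TINY or n2sq < _TINY:
            continue  # degenerate dihedral: torque direction undefined
        # analytic dihedral gradient dphi/dr (validated against central
        # differences for this sign convention)
        ci = -nb2 / n1sq
        cl = nb2 / n2sq
        dix = ci * n1x
        diy = ci * n1y
        diz = ci * n1z
        dlx = cl * n2x
        dly = cl * n2y
        dlz = cl * n2z
        c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        djx = -(1.0 + c12) * dix + c32 * dlx
        djy = -(1.0 + c12) * diy + c32 * dly
        djz = -(1.0 + c12) * diz + c32 * dlz
        dkx = c12 * dix - (1.0 + c32) * dlx
        dky = c12 * diy - (1.0 + c32) * dly
        dkz = c12 * diz - (1.0 + c32) * dlz
        F[i, 0] -= dV * dix
        F[i, 1] -= dV * diy
        F[i, 2] -= dV * diz
        F[j, 0] -= dV * djx
        F[j, 1] -= dV * djy
        F[j, 2] -= dV * djz
        F[k, 0] -= dV * dkx
        F[k, 1] -= dV * dky
        F[k, 2] -= dV * dkz
        F[l, 0] -= dV * dlx
        F[l, 1] -= dV * dly
        F[l, 2] -= dV * dlz
    return e


@njit(cache=True, fastmath=False)
def pair_screen_factor(mode, kappa, ai, aj):
    if mode == 2:
        ab = np.sqrt((ai * ai + aj * aj) / 2.0)
        ka = kappa * ab
        return np.exp(ka) / (1.0 + ka)
    return 1.0


@njit(cache=True, fastmath=False)
def nonbonded_terms(x, sigma, qpref, fradii, mol, res, kappa, cutoff, kex,
                    mode, F):
    """Excluded-volume + screened-electrostatic energies and forces.

    Pairs within the same molecule with residue separation <= 4 are skipped.
    ``qpref`` is q_i*sqrt(C/eps) with any per-sphere DLVO factor already
    folded in by the caller (mode 1).
    """
    e_ex = 0.0
    e_el = 0.0
    n = x.shape[0]
    cut2 = cutoff * cutoff
    for i in range(n):
        xi = x[i, 0]
        yi = x[i, 1]
        zi = x[i, 2]
        for j in range(i + 1, n):
            if mol[i] == mol[j] and abs(res[i] - res[j]) <= 4:
                continue
            dx = xi - x[j, 0]
            dy = yi - x[j, 1]
            dz = zi - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cut2 or r2 < _TINY:
                continue
            r = np.sqrt(r2)
            g = 0.0
            s = sigma[i] + sigma[j]
            if r < s:
                ov = s - r
                e_ex += 0.5 * kex * ov * ov
                g -= kex * ov / r  # dV/dr / r
            qq = qpref[i] * qpref[j]
            if qq != 0.0:
                qq *= pair_screen_factor(mode, kappa, fradii[i], fradii[j])
                v = qq * np.exp(-kappa * r) / r
                e_el += v
                g -= v * (kappa + 1.0 / r) / r
            if g != 0.0:
                F[i, 0] -= g * dx
                F[i, 1] -= g * dy
                F[i, 2] -= g * dz
                F[j, 0] += g * dx
                F[j, 1] += g * dy
                F[j, 2] += g * dz
    return e_ex, e_el


@njit(cache=True, fastmath=False)
def restraint_terms(x, rest_idx, rest_k, rest_anchor, F):
    e = 0.0
    for m in range(rest_idx.shape[0]):
        i = rest_idx[m]
        dx = x[i] - rest_anchor[m]
        e += 0.5 * rest_k[m] * (dx * dx).sum()
        for d in range(3):
            F[i, d] -= rest_k[m] * dx[d]
    return e


@njit(cache=True, fastmath=False)
def bias_terms(x, dist_bias, plane_bias, F):
    """Umbrella biases: harmonic distance terms and harmonic Z-plane terms.

    ``dist_bias`` rows: (i, j, k, r0) — ½k(|x_i-x_j|-r0)².
    ``plane_bias`` rows: (i, k, z0) — ½k(z_i-z0)².
    """
    e = 0.0
    for m in range(dist_bias.shape[0]):
        i = int(dist_bias[m, 0])
        j = int(dist_bias[m, 1])
        kk = dist_bias[m, 2]
        r0 = dist_bias[m, 3]
        dx = x[i] - x[j]
        r = np.sqrt((dx * dx).sum())
        if r < _TINY:
            continue
        dr = r - r0
        e += 0.5 * kk * dr * dr
        g = kk * dr / r
        for d in range(3):
            F[i, d] -= g * dx[d]
            F[j, d] += g * dx[d]
    for m in range(plane_bias.shape[0]):
        i = int(plane_bias[m, 0])
        kk = plane_bias[m, 1]
        z0 = plane_bias[m, 2]
        dz = x[i, 2] - z0
        e += 0.5 * kk * dz * dz
        F[i, 2] -= kk * dz
    return e


@njit(cache=True, fastmath=False)
def external_force_terms(x, ext_force, F):
    """Constant external forces: rows (i, fx, fy, fz); energy -f·x."""
    e = 0.0
    for m in range(ext_force.shape[0]):
        i = int(ext_force[m, 0])
        for d in range(3):
            F[i, d] += ext_force[m, 1 + d]
            e -= ext_force[m, 1 + d] * x[i, d]
    return e


@njit(cache=True, fastmath=False)
def total_energy_forces(x, bonds, bond_k, bond_r0, angles, angle_k, angle_t0,
                        tors, tor_k, tor_p0, sigma, qpref, fradii, mol, res,
                        kappa, cutoff, kex, mode,
                        rest_idx, rest_k, rest_anchor, dist_bias, plane_bias,
                        ext_force):
    F = np.zeros_like(x)
    e = np.zeros(7)
    e[0] = bond_terms(x, bonds, bond_k, bond_r0, F)
    e[1] = angle_terms(x, angles, angle_k, angle_t0, F)
    e[2] = torsion_terms(x, tors, tor_k, tor_p0, F)
    e[3], e[4] = nonbonded_terms(x, sigma, qpref, fradii, mol, res,
                                 kappa, cutoff, kex, mode, F)
    e[5] = restraint_terms(x, rest_idx, rest_k, rest_anchor, F)
    e[6] = bias_terms(x, dist_bias, plane_bias, F)
    e[6] += external_force_terms(x, ext_force, F)
    return e, F


# --- BD propagation ---------------------------------------------------------

@njit(cache=True, fastmath=False)
def rk2_chunk(x, B, S_block, bonds, bond_k, bond_r0, angles, angle_k,
              angle_t0, tors, tor_k, tor_p0, sigma, qpref, fradii, mol, res,
              kappa, cutoff, kex, mode, rest_idx, rest_k, rest_anchor,
              dist_bias, plane_bias, ext_force, max_disp):
    """Advance ``S_block.shape[0]`` predictor–corrector BD steps in place.

    ``B`` = D·Δt/kBT (3N×3N, Å²·step/kcal·mol⁻¹ units folded), ``S_block``
    rows are the pre-correlated Brownian displacements (Å).  The same noise
    row and the same diffusion matrix are used in both stages.  Returns the
    index of the step at which the per-step displacement exceeded
    ``max_disp`` (Å), or -1 on success.
    """
    n = x.shape[0]
    nsteps = S_block.shape[0]
    for s in range(nsteps):
        _, F0 = total_energy_forces(x, bonds, bond_k, bond_r0, angles,
                                    angle_k, angle_t0, tors, tor_k, tor_p0,
                                    sigma, qpref, fradii, mol, res, kappa,
                                    cutoff, kex, mode, rest_idx, rest_k,
                                    rest_anchor, dist_bias, plane_bias,
                                    ext_force)
        drift0 = B @ F0.ravel()
        xs = x + (drift0 + S_block[s]).reshape(n, 3)
        _, F1 = total_energy_forces(xs, bonds, bond_k, bond_r0, angles,
                                    angle_k, angle_t0, tors, tor_k, tor_p0,
                                    sigma, qpref, fradii, mol, res, kappa,
                                    cutoff, kex, mode, rest_idx, rest_k,
                                    rest_anchor, dist_bias, plane_bias,
                                    ext_force)
        drift = 0.5 * (drift0 + B @ F1.ravel())
        step = (drift + S_block[s]).reshape(n, 3)
        for i in range(n):
            if (step[i] * step[i]).sum() > max_disp * max_disp:
                return s
        x += step
    return -1


# --- Monte Carlo ------------------------------------------------------------

@njit(cache=True, fastmath=False)
def bead_nonbonded_energy(x, xi, i, sigma, qpref, fradii, mol, res,
                          kappa, cutoff, kex, mode):
    """Nonbonded energy of bead ``i`` at trial position ``xi``."""
    e = 0.0
    cut2 = cutoff * cutoff
    ax = xi[0]
    ay = xi[1]
    az = xi[2]
    for j in range(x.shape[0]):
        if j == i:
            continue
        if mol[i] == mol[j] and abs(res[i] - res[j]) <= 4:
            continue
        dx = ax - x[j, 0]
        dy = ay - x[j, 1]
        dz = az - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2:
            continue
        r = np.sqrt(r2)
        s = sigma[i] + sigma[j]
        if r < s:
            e += 0.5 * kex * (s - r) ** 2
        qq = qpref[i] * qpref[j]
        if qq != 0.0:
            qq *= pair_screen_factor(mode, kappa, fradii[i], fradii[j])
            e += qq * np.exp(-kappa * r) / r
    return e


@njit(cache=True, fastmath=False)
def bead_bonded_energy(x, bonds, bond_k, bond_r0, angles, angle_k, angle_t0,
                       tors, tor_k, tor_p0,
                       bstart, bids, astart, aids, tstart, tids, i):
    """Bonded energy of all terms touching bead ``i`` (CSR adjacency)."""
    e = 0.0
    for q in range(bstart[i], bstart[i + 1]):
        b = bids[q]
        dx = x[bonds[b, 0]] - x[bonds[b, 1]]
        r = np.sqrt((dx * dx).sum())
        e += 0.5 * bond_k[b] * (r - bond_r0[b]) ** 2
    for q in range(astart[i], astart[i + 1]):
        t = aids[q]
        u = x[angles[t, 0]] - x[angles[t, 1]]
        v = x[angles[t, 2]] - x[angles[t, 1]]
        c = (u * v).sum() / np.sqrt((u * u).sum() * (v * v).sum())
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        e += 0.5 * angle_k[t] * (np.arccos(c) - angle_t0[t]) ** 2
    for q in range(tstart[i], tstart[i + 1]):
        t = tids[q]
        phi, b1, b2, b3, n1, n2, nb2 = _dihedral(x, tors[t, 0], tors[t, 1],
                                                 tors[t, 2], tors[t, 3])
        d = phi - tor_p0[t]
        while d > np.pi:
            d -= 2 * np.pi
        while d <= -np.pi:
            d += 2 * np.pi
        e += 0.5 * tor_k[t] * d * d
    return e


@njit(cache=True, fastmath=False)
def rotation_matrix(axis, angle):
    ax, ay, az = axis[0], axis[1], axis[2]
    c = np.cos(angle)
    s = np.sin(angle)
    C = 1.0 - c
    R = np.empty((3, 3))
    R[0, 0] = c + ax * ax * C
    R[0, 1] = ax * ay * C - az * s
    R[0, 2] = ax * az * C + ay * s
    R[1, 0] = ay * ax * C + az * s
    R[1, 1] = c + ay * ay * C
    R[1, 2] = ay * az * C - ax * s
    R[2, 0] = az * ax * C - ay * s
    R[2, 1] = az * ay * C + ax * s
    R[2, 2] = c + az * az * C
    return R
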