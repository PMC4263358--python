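"""Metropolis Monte Carlo samplers targeting the same potential as the BD engine.

Two samplers are provided:

* a DNA conformational sampler combining pivot moves (global, rejection-free
  decorrelation of the chain direction) with single-bead displacement moves
  (local relaxation of bond lengths and phosphate orientations) — used for
  equilibrium chain statistics such as the persistence length;
* an umbrella-window sampler for the protein–DNA system, with single-bead
  and rigid-protein moves — used as the fast equilibrium path for free-energy
  profiles (equilibrium averages do not depend on hydrodynamics, so Metropolis
  sampling of the identical potential is a valid substitute for BD here).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import _kernels
from .constants import KBT
from .energy import ForceFieldParams, charge_prefactors, size_factor_radii
from .model import DnaModel, SystemSpec, build_dna


def topology_csr(system: SystemSpec):
    """Per-bead adjacency (CSR) into the bond/angle/torsion tables."""
    t = system.topology
    n = system.n_beads

    def csr(idx_arr):
        per = [[] for _ in range(n)]
        for tid, row in enumerate(idx_arr):
            for b in row:
                per[int(b)].append(tid)
        start = np.zeros(n + 1, np.int64)
        flat = []
        for b in range(n):
            start[b + 1] = start[b] + len(per[b])
            flat.extend(per[b])
        return start, np.array(flat, np.int64)

    bs, bi = csr(t.bonds)
    as_, ai = csr(t.angles)
    ts, ti = csr(t.torsions)
    return bs, bi, as_, ai, ts, ti


# --- DNA chain sampler ------------------------------------------------------

@njit(cache=True)
def _pivot_delta_e(x, n, a, has_pp, angles_k_bb, theta0_bb):
    """Energy of the terms affected by a pivot at residue ``a``."""
    e = 0.0
    u = x[a - 1] - x[a]
    v = x[a + 1] - x[a]
    c = (u * v).sum() / np.sqrt((u * u).sum() * (v * v).sum())
    if c > 1.0:
        c = 1.0
    if c < -1.0:
        c = -1.0
    e += 0.5 * angles_k_bb * (np.arccos(c) - theta0_bb) ** 2
    if has_pp:
        w = x[n + a] - x[a]
        c2 = (w * v).sum() / np.sqrt((w * w).sum() * (v * v).sum())
        if c2 > 1.0:
            c2 = 1.0
        if c2 < -1.0:
            c2 = -1.0
        e += 0.5 * 100.0 * (np.arccos(c2) - np.pi / 2) ** 2
        phi, b1, b2, b3, n1, n2, nb2 = _kernels._dihedral(x, n + a, a, a + 1, n + a + 1)
        d = phi - np.deg2rad(36.0)
        while d > np.pi:
            d -= 2 * np.pi
        while d <= -np.pi:
            d += 2 * np.pi
        e += 0.5 * 131.6 * d * d
    return e


@njit(cache=True)
def _dna_mc(x, n, has_pp, bonds, bond_k, bond_r0, angles, angle_k, angle_t0,
            tors, tor_k, tor_p0, bs, bi, as_, ai, ts, ti,
            k_bb, theta0_bb, n_sweeps, burn_in, sample_every,
            pivot_sigma, disp_sigma, seed, out):
    np.random.seed(seed)
    nb = x.shape[0]
    nsamp = 0
    for sw in range(n_sweeps):
        for _ in range(n):
            a = 1 + np.random.randint(n - 2)
            axis = np.random.randn(3)
            axis /= np.sqrt((axis * axis).sum())
            ang = pivot_sigma * np.random.randn()
            e0 = _pivot_delta_e(x, n, a, has_pp, k_bb, theta0_bb)
            R = _kernels.rotation_matrix(axis, ang)
            piv = x[a].copy()
            old_bb = x[a + 1:n].copy()
            x[a + 1:n] = (x[a + 1:n] - piv) @ R.T + piv
            if has_pp:
                old_pp = x[n + a + 1:2 * n].copy()
                x[n + a + 1:2 * n] = (x[n + a + 1:2 * n] - piv) @ R.T + piv
            e1 = _pivot_delta_e(x, n, a, has_pp, k_bb, theta0_bb)
            if np.random.rand() >= np.exp(min(0.0, -(e1 - e0) / KBT)):
                x[a + 1:n] = old_bb
                if has_pp:
                    x[n + a + 1:2 * n] = old_pp
        for _ in range(nb):
            i = np.random.randint(nb)
            d = disp_sigma * np.random.randn(3)
            e0 = _kernels.bead_bonded_energy(x, bonds, bond_k, bond_r0,
                                             angles, angle_k, angle_t0,
                                             tors, tor_k, tor_p0,
                                             bs, bi, as_, ai, ts, ti, i)
            old = x[i].copy()
            x[i] = x[i] + d
            e1 = _kernels.bead_bonded_energy(x, bonds, bond_k, bond_r0,
                                             angles, angle_k, angle_t0,
                                             tors, tor_k, tor_p0,
                                             bs, bi, as_, ai, ts, ti, i)
            if np.random.rand() >= np.exp(min(0.0, -(e1 - e0) / KBT)):
                x[i] = old
        if sw >= burn_in and (sw - burn_in) % sample_every == 0:
            if nsamp < out.shape[0]:
                out[nsamp] = x
                nsamp += 1
    return nsamp


def backbone_chain(n_residues: int, k_angle: float = 87.7,
                   theta0_deg: float = 180.0) -> DnaModel:
    """The worm-like-chain reduction of the CG-DNA: PB beads only.

    Bonds and the backbone bending term, nothing else — the discrete chain
    whose stiffness k_angle directly encodes the persistence length
    Lp = k·b/kBT.
    """
    full = build_dna(n_residues, backbone_theta0_deg=theta0_deg)
    n = n_residues
    t = full.topology
    keep_b = np.array([i for i, b in enumerate(t.bonds)
                       if b[0] < n and b[1] < n])
    keep_a = np.array([i for i, a in enumerate(t.angles)
                       if a.max() < n])
    from .model import Topology
    topo = Topology(t.bonds[keep_b], np.full(len(keep_b), t.bond_k[keep_b][0]),
                    t.bond_r0[keep_b],
                    t.angles[keep_a], np.full(len(keep_a), k_angle),
                    t.angle_t0[keep_a])
    return DnaModel(full.positions[:n].copy(), full.sigma[:n].copy(),
                    full.stokes[:n].copy(), full.charge[:n].copy(),
                    full.molecule[:n].copy(), full.residue[:n].copy(),
                    full.names[:n], topo, n_residues=n)


def sample_dna_conformations(n_residues: int, n_samples: int, seed: int, *,
                             include_phosphates: bool = True,
                             k_angle: float = 87.7,
                             theta0_deg: float = 180.0,
                             sample_every: int = 5,
                             burn_in_fraction: float = 0.2,
                             pivot_sigma: float = 0.10,
                             disp_sigma: float = 0.12) -> np.ndarray:
    """Equilibrium conformations of a free CG-DNA chain (bonded terms only).

    Returns an array of shape (n_samples, n_beads, 3).  With
    ``include_phosphates=False`` the chain is the PB-backbone worm-like
    chain (bonds + bending term with stiffness ``k_angle``); with
    phosphates, the full DNA bonded topology (including the phosphate
    angles and the helical torsion) is sampled.  Nonbonded terms are
    excluded: the sampler measures the elastic backbone statistics.
    """
    if include_phosphates:
        dna = build_dna(n_residues, backbone_theta0_deg=theta0_deg)
        k_bb = 87.7
    else:
        dna = backbone_chain(n_residues, k_angle, theta0_deg)
        k_bb = k_angle
    bs, bi, as_, ai, ts, ti = topology_csr(dna)
    t = dna.topology
    total_sweeps = int(np.ceil(n_samples * sample_every
                               / (1.0 - burn_in_fraction))) + sample_every
    burn_in = int(total_sweeps * burn_in_fraction)
    out = np.empty((n_samples, dna.n_beads, 3))
    x = dna.positions.copy()
    got = _dna_mc(x, n_residues, include_phosphates,
                  t.bonds, t.bond_k, t.bond_r0, t.angles, t.angle_k,
                  t.angle_t0, t.torsions, t.torsion_k, t.torsion_p0,
                  bs, bi, as_, ai, ts, ti, k_bb, np.deg2rad(theta0_deg),
                  total_sweeps, burn_in, sample_every, pivot_sigma,
                  disp_sigma, seed % 2 ** 31, out)
    return out[:got]


# --- umbrella-window sampler ------------------------------------------------

@njit(cache=True)
def _bias_energy(x, ip, ic, kumb, r0, kplane, z0):
    dx = x[ip] - x[ic]
    r = np.sqrt((dx * dx).sum())
    return 0.5 * kumb * (r - r0) ** 2 + 0.5 * kplane * (x[ip, 2] - z0) ** 2, r


@njit(cache=True)
def _mc_window(x, sigma, qpref, stokes, mol, res, mode, kappa, cutoff, kex,
               bonds, bond_k, bond_r0, angles, angle_k, angle_t0,
               tors, tor_k, tor_p0, bs, bi, as_, ai, ts, ti,
               rest_k, rest_anchor, movable, prot, ic,
               kumb, r0, kplane, z0,
               n_equil, n_prod, disp_sigma, rigid_sigma, seed, samples):
    np.random.seed(seed)
    ip = prot[0]
    nmov = movable.shape[0]
    for sw in range(n_equil + n_prod):
        for m in range(nmov):
            i = movable[m]
            d = disp_sigma * np.random.randn(3)
            xi = x[i] + d
            e0 = (_kernels.bead_nonbonded_energy(x, x[i], i, sigma, qpref,
                                                 stokes, mol, res, kappa,
                                                 cutoff, kex, mode)
                  + _kernels.bead_bonded_energy(x, bonds, bond_k, bond_r0,
                                                angles, angle_k, angle_t0,
                                                tors, tor_k, tor_p0,
                                                bs, bi, as_, ai, ts, ti, i)
                  + 0.5 * rest_k[i] * ((x[i] - rest_anchor[i]) ** 2).sum())
            if i == ip or i == ic:
                b0, _ = _bias_energy(x, ip, ic, kumb, r0, kplane, z0)
            else:
                b0 = 0.0
            old = x[i].copy()
            x[i] = xi
            e1 = (_kernels.bead_nonbonded_energy(x, xi, i, sigma, qpref,
                                                 stokes, mol, res, kappa,
                                                 cutoff, kex, mode)
                  + _kernels.bead_bonded_energy(x, bonds, bond_k, bond_r0,
                                                angles, angle_k, angle_t0,
                                                tors, tor_k, tor_p0,
                                                bs, bi, as_, ai, ts, ti, i)
                  + 0.5 * rest_k[i] * ((xi - rest_anchor[i]) ** 2).sum())
            if i == ip or i == ic:
                b1, _ = _bias_energy(x, ip, ic, kumb, r0, kplane, z0)
            else:
                b1 = 0.0
            if np.random.rand() >= np.exp(min(0.0, -((e1 + b1) - (e0 + b0)) / KBT)):
                x[i] = old
        # rigid protein rotation about the DNA (Z) axis: preserves both the
        # umbrella distance (PB beads sit on the axis) and the Z-plane bias,
        # while translating the DBP beads along the groove — efficient
        # sampling of the helix-phase registry of the bound state.
        for _ in range(4):
            ang = 0.10 * np.random.randn()
            R = _kernels.rotation_matrix(np.array([0.0, 0.0, 1.0]), ang)
            e0 = 0.0
            for pidx in prot:
                e0 += _kernels.bead_nonbonded_energy(x, x[pidx], pidx, sigma,
                                                     qpref, stokes, mol, res,
                                                     kappa, cutoff, kex, mode)
            old0 = x[prot[0]].copy()
            old1 = x[prot[1]].copy()
            old2 = x[prot[2]].copy()
            for pidx in prot:
                x[pidx] = R @ x[pidx]
            e1 = 0.0
            for pidx in prot:
                e1 += _kernels.bead_nonbonded_energy(x, x[pidx], pidx, sigma,
                                                     qpref, stokes, mol, res,
                                                     kappa, cutoff, kex, mode)
            if np.random.rand() >= np.exp(min(0.0, -(e1 - e0) / KBT)):
                x[prot[0]] = old0
                x[prot[1]] = old1
                x[prot[2]] = old2
        # rigid protein rotations about the PBP bead (bond-preserving;
        # orientational decorrelation). Only the DBP beads move and the
        # bias depends on the PBP alone, so only their nonbonded terms enter.
        for _ in range(4):
            axis = np.random.randn(3)
            axis /= np.sqrt((axis * axis).sum())
            R = _kernels.rotation_matrix(axis, 0.08 * np.random.randn())
            e0 = 0.0
            for pidx in prot[1:]:
                e0 += _kernels.bead_nonbonded_energy(x, x[pidx], pidx, sigma,
                                                     qpref, stokes, mol, res,
                                                     kappa, cutoff, kex, mode)
            old1 = x[prot[1]].copy()
            old2 = x[prot[2]].copy()
            piv = x[ip]
            x[prot[1]] = R @ (x[prot[1]] - piv) + piv
            x[prot[2]] = R @ (x[prot[2]] - piv) + piv
            e1 = 0.0
            for pidx in prot[1:]:
                e1 += _kernels.bead_nonbonded_energy(x, x[pidx], pidx, sigma,
                                                     qpref, stokes, mol, res,
                                                     kappa, cutoff, kex, mode)
            if np.random.rand() >= np.exp(min(0.0, -(e1 - e0) / KBT)):
                x[prot[1]] = old1
                x[prot[2]] = old2
        # rigid protein translations
        for _ in range(4):
            d = rigid_sigma * np.random.randn(3)
            e0 = 0.0
            e1 = 0.0
            for pidx in prot:
                e0 += _kernels.bead_nonbonded_energy(x, x[pidx], pidx, sigma,
                                                     qpref, stokes, mol, res,
                                                     kappa, cutoff, kex, mode)
            b0, _ = _bias_energy(x, ip, ic, kumb, r0, kplane, z0)
            old0 = x[prot[0]].copy()
            old1 = x[prot[1]].copy()
            old2 = x[prot[2]].copy()
            for pidx in prot:
                x[pidx] = x[pidx] + d
            for pidx in prot:
                e1 += _kernels.bead_nonbonded_energy(x, x[pidx], pidx, sigma,
                                                     qpref, stokes, mol, res,
                                                     kappa, cutoff, kex, mode)
            b1, _ = _bias_energy(x, ip, ic, kumb, r0, kplane, z0)
            if np.random.rand() >= np.exp(min(0.0, -((e1 + b1) - (e0 + b0)) / KBT)):
                x[prot[0]] = old0
                x[prot[1]] = old1
                x[prot[2]] = old2
        if sw >= n_equil:
            _, r = _bias_energy(x, ip, ic, kumb, r0, kplane, z0)
            samples[sw - n_equil] = r


def run_mc_window(system: SystemSpec, params: ForceFieldParams,
                  x: np.ndarray, *, reaction_bead: int, protein_beads,
                  r0: float, k_umb: float, plane_k: float, plane_z: float,
                  rest_k: np.ndarray, rest_anchor: np.ndarray,
                  movable: np.ndarray, n_equil: int, n_prod: int,
                  seed: int, disp_sigma: float = 0.45,
                  rigid_sigma: float = 0.45) -> np.ndarray:
    """Sample one umbrella window in place; returns reaction-coordinate samples."""
    bs, bi, as_, ai, ts, ti = topology_csr(system)
    t = system.topology
    samples = np.empty(n_prod)
    _mc_window(x, system.sigma, charge_prefactors(system, params),
               size_factor_radii(system, params),
               system.molecule, system.residue, params.mode,
               params.kappa, params.cutoff, params.k_ex,
               t.bonds, t.bond_k, t.bond_r0, t.angles, t.angle_k, t.angle_t0,
               t.torsions, t.torsion_k, t.torsion_p0, bs, bi, as_, ai, ts, ti,
               rest_k, rest_anchor, np.asarray(movable, np.int64),
               np.asarray(protein_beads, np.int64), int(reaction_bead),
               k_umb, r0, plane_k, plane_z, n_equil, n_prod,
               disp_sigma, rigid_sigma, seed % 2 ** 31, samples)
    return samples
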