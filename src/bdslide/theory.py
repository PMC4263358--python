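"""Analytic hydrodynamic theory for sliding proteins.

Contents:

* rigid-particle (bead-model) hydrodynamics: translational and rotational
  diffusion coefficients of a rigid bead assembly at its centre of
  diffusion, and the corresponding translational / rotational Stokes radii;
* the helical-sliding ("BBX") expression for the apparent one-dimensional
  diffusion coefficient of a protein tracking the DNA groove, and its
  corrected form using separate translational and rotational Stokes radii;
* the Zwanzig rough-landscape reduction factor;
* the Debye screening length of a 1:1 electrolyte;
* the two-mode (1D sliding + 3D diffusion) facilitated-search association
  rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (E_CHARGE_SI, EPS0_SI, ETA_DEFAULT, KB_SI, N_AVOGADRO,
                        T_DEFAULT, mobility_scale, rotational_mobility_scale)
from .hydrodynamics import SingularGeometryError
from .model import PITCH

#: Base-pair spacing used in the search-rate theory, Å.
BP_SPACING = 3.4


@dataclass
class RigidBodyHydro:
    """Rigid-body diffusion properties at the centre of diffusion.

    ``d_t``: orientation-averaged translational diffusion coefficient, Å²/ns.
    ``d_r``: orientation-averaged rotational diffusion coefficient, 1/ns.
    ``a_t``, ``a_r``: the equivalent-sphere Stokes radii via
    D_T = kBT/(6πη a_T) and D_R = kBT/(8πη a_R³).
    ``center_of_diffusion``: body-frame coordinates, Å.
    """

    d_t: float
    d_r: float
    a_t: float
    a_r: float
    center_of_diffusion: np.ndarray
    d_tt: np.ndarray | None = None
    d_rr: np.ndarray | None = None


def _skew(v):
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def _mobility_6x6(positions, stokes, origin, mob, rot_mob, bead_rotation):
    from .hydrodynamics import _grand_matrix
    x = np.ascontiguousarray(positions, float)
    n = len(x)
    D = _grand_matrix(x, np.asarray(stokes, float),
                      np.zeros(n, np.int64), 1, mob)
    Z = np.linalg.inv(D)
    A = [_skew(p - origin) for p in x]
    Xtt = np.zeros((3, 3))
    Xrt = np.zeros((3, 3))
    Xrr = np.zeros((3, 3))
    for i in range(n):
        for j in range(n):
            z = Z[3 * i:3 * i + 3, 3 * j:3 * j + 3]
            Xtt += z
            Xrt += A[i] @ z
            Xrr += -A[i] @ z @ A[j]
    if bead_rotation:
        # each bead's own rotational (spin) friction, 8πη a³
        Xrr += (np.asarray(stokes, float) ** 3).sum() / rot_mob * np.eye(3)
    R6 = np.block([[Xtt, Xrt.T], [Xrt, Xrr]])
    return np.linalg.inv(R6)


def rigid_body_diffusion(positions, stokes, eta: float = ETA_DEFAULT,
                         T: float = T_DEFAULT, *,
                         include_bead_rotation: bool = False) -> RigidBodyHydro:
    """Diffusion properties of a rigid bead assembly via RPY bead-model theory.

    The grand RPY mobility is inverted to the bead friction matrix, summed
    into the 6×6 rigid-body resistance, and inverted back to the rigid-body
    mobility.  The centre of diffusion is located from the rotational and
    coupling blocks; there the rotation–translation coupling is symmetric
    and the trace of the translational block is minimal.

    ``include_bead_rotation`` adds each bead's own spin friction 8πη·a³ to
    the rotational resistance (the volume correction of classical bead-model
    programs).  The default is off: the beads of this model are pure
    translational point mobilities, and the rotational friction of the
    assembly arises solely from the constrained translation of its beads.
    The correction is needed to recover the single-sphere limit
    a_R = a; without it a single bead has no rotational friction.
    """
    x = np.asarray(positions, float).reshape(-1, 3)
    a = np.asarray(stokes, float).ravel()
    if len(x) < 1:
        raise ValueError("need at least one bead")
    if len(x) > 1:
        d2 = ((x[:, None] - x[None, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() == 0:
            raise SingularGeometryError("coincident beads")
    mob = mobility_scale(T, eta)
    rot_mob = rotational_mobility_scale(T, eta)
    origin = x.mean(axis=0)
    M6 = _mobility_6x6(x, a, origin, mob, rot_mob, include_bead_rotation)
    Drr = M6[3:, 3:]
    Drt = M6[3:, :3]  # rotation–translation coupling at the origin
    # centre of diffusion relative to the current origin (the shift that
    # symmetrises the coupling block; verified against direct minimisation
    # of the translational trace)
    Amat = np.trace(Drr) * np.eye(3) - Drr
    bvec = np.array([Drt[1, 2] - Drt[2, 1],
                     Drt[2, 0] - Drt[0, 2],
                     Drt[0, 1] - Drt[1, 0]])
    if len(x) == 1 and not include_bead_rotation:
        cod = x[0].copy()
        d_t = mob / a[0]
        return RigidBodyHydro(d_t, np.inf, a[0], 0.0, cod,
                              d_tt=M6[:3, :3], d_rr=Drr)
    if np.linalg.cond(Amat) > 1e12:
        raise SingularGeometryError(
            "rotational mobility degenerate (collinear beads have no spin "
            "friction in the translational-bead convention); use "
            "include_bead_rotation=True")
    shift = np.linalg.solve(Amat, bvec)
    cod = origin + shift
    M6c = _mobility_6x6(x, a, cod, mob, rot_mob, include_bead_rotation)
    d_t = float(np.trace(M6c[:3, :3]) / 3.0)
    d_r = float(np.trace(M6c[3:, 3:]) / 3.0)
    a_t = mob / d_t
    a_r = (rot_mob / d_r) ** (1.0 / 3.0)
    return RigidBodyHydro(d_t, d_r, a_t, a_r, cod,
                          d_tt=M6c[:3, :3], d_rr=M6c[3:, 3:])


def protein_rigid_hydro(a_pbp: float, eta: float = ETA_DEFAULT,
                        T: float = T_DEFAULT, *,
                        a_dbp: float = 8.0) -> RigidBodyHydro:
    """Rigid-body hydrodynamics of the three-bead CG-protein geometry."""
    from .model import build_protein
    prot = build_protein(a_pbp=a_pbp, q_dbp=0.0)
    prot.stokes[1:] = a_dbp
    return rigid_body_diffusion(prot.positions, prot.stokes, eta, T)


def protein_roc(a_pbp: float, *, dbp_radius: float | None = None) -> float:
    """Off-axis distance of the protein's centre of diffusion when docked.

    The body-frame centre of diffusion lies on the PBP–(DBP midpoint) line;
    docked, the DBP midpoint sits on the DNA axis offset radially by the
    phosphate radius, so R_OC = phosphate radius + body-frame distance.
    """
    from .model import PHOSPHATE_RADIUS
    h = protein_rigid_hydro(a_pbp)
    r = dbp_radius if dbp_radius is not None else PHOSPHATE_RADIUS
    return r + float(h.center_of_diffusion[0])


def bbx_d1d(a_pro: float, r_oc: float, pitch: float = PITCH,
            T: float = T_DEFAULT, eta: float = ETA_DEFAULT, *,
            include_off_axis: bool = True) -> float:
    """Apparent 1D diffusion coefficient of rotation-coupled sliding, Å²/ns.

    D_1D = (kBT/6πη) / { a·[1 + (4/3)k²a² + k²R_OC²] } with k = 2π/pitch.
    The three denominator terms are translational friction along the helix
    axis, rotational (spin) friction about it, and the translational
    friction of the circular off-axis motion of the protein centre.  With
    ``include_off_axis=False`` the third term is dropped (the on-axis
    spinning-sphere model).
    """
    if min(a_pro, r_oc if include_off_axis else 1.0, pitch) <= 0:
        raise ValueError("inputs must be positive")
    k2 = (2.0 * np.pi / pitch) ** 2
    denom = a_pro * (1.0 + (4.0 / 3.0) * k2 * a_pro ** 2
                     + (k2 * r_oc ** 2 if include_off_axis else 0.0))
    return mobility_scale(T, eta) / denom


def bbx_corrected_d1d(a_t: float, a_r: float, r_oc: float,
                      pitch: float = PITCH, T: float = T_DEFAULT,
                      eta: float = ETA_DEFAULT) -> float:
    """Helical-sliding D_1D with the spin term at the rotational Stokes radius.

    D_1D* = (kBT/6πη) / { a_T + (4/3)k²·a_R³ + k²·R_OC²·a_T }.  Identical to
    :func:`bbx_d1d` when a_R = a_T.
    """
    if min(a_t, a_r, r_oc, pitch) <= 0:
        raise ValueError("inputs must be positive")
    k2 = (2.0 * np.pi / pitch) ** 2
    denom = a_t + (4.0 / 3.0) * k2 * a_r ** 3 + k2 * r_oc ** 2 * a_t
    return mobility_scale(T, eta) / denom


def zwanzig_reduction(epsilon_over_kbt: float) -> float:
    """Diffusivity reduction exp[-(ε/kBT)²] on a Gaussian-rough landscape."""
    if epsilon_over_kbt < 0:
        raise ValueError("roughness must be >= 0")
    return float(np.exp(-epsilon_over_kbt ** 2))


def debye_length(ionic_strength: float, T: float = T_DEFAULT,
                 eps: float = 78.5) -> float:
    """Debye screening length 1/κ of a 1:1 electrolyte, Å.

    ``ionic_strength`` in mol/L.  0.15 M at 298 K in water (ε = 78.5)
    gives ≈7.8 Å.
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    n = 2.0 * N_AVOGADRO * ionic_strength * 1e3  # ions/m³ (both signs)
    lam = np.sqrt(eps * EPS0_SI * KB_SI * T / (n * E_CHARGE_SI ** 2))
    return float(lam * 1e10)


@dataclass
class SearchRate:
    """Facilitated-search association rate and sliding length."""

    k_smol: float    # Smoluchowski rate to the bare target, 1/(M·s)
    n_bar: float     # mean sliding length per 1D episode, bp
    k_s: float       # facilitated association rate, 1/(M·s)


def search_rate(d_3d: float, d_1d: float, tau_1d: float, tau_3d: float,
                f: float = 0.3, *, b: float = BP_SPACING,
                sliding_prefactor: float = 2.0) -> SearchRate:
    """Association rate of the two-mode (sliding + 3D) search, 1/(M·s).

    Parameters are in CGS-flavoured lab units: ``d_3d`` and ``d_1d`` in
    cm²/s, ``tau_1d``/``tau_3d`` in s, target size ``b`` in Å, ``f`` the
    reactive fraction of the protein surface.

    k_Smol = 4π·D_3D·b·f·N_A;  n̄ = sqrt(c·D_1D·τ_1D)/b with the documented
    prefactor c (default 2, the 1D mean-squared-displacement convention);
    k_s = k_Smol·n̄·τ_3D/(τ_1D+τ_3D).
    """
    if min(d_3d, tau_1d, tau_3d) <= 0 or d_1d < 0:
        raise ValueError("rates and durations must be positive")
    b_cm = b * 1e-8
    k_smol = 4.0 * np.pi * d_3d * b_cm * f * N_AVOGADRO / 1e3  # cm³ -> L
    n_bar = np.sqrt(sliding_prefactor * d_1d * tau_1d) / b_cm
    k_s = k_smol * n_bar * tau_3d / (tau_1d + tau_3d)
    return SearchRate(float(k_smol), float(n_bar), float(k_s))
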