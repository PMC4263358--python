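"""Configuration-dependent diffusion matrices from the Rotne–Prager–Yamakawa tensor.

The grand diffusion matrix D is the 3N×3N positive-definite mobility (in
diffusion units, Å²/ns) coupling the Brownian displacements of all beads.
Off-diagonal 3×3 blocks use the RPY tensor; for overlapping pairs the
positive-definiteness-preserving overlap form is used with the pair
effective radius ā = sqrt((a_i²+a_j²)/2), which generalises the equal-sphere
overlap expression to unequal radii.

Three modes mirror the simulation protocols:

* ``full_hi``      — all hydrodynamic couplings;
* ``intra_hi``     — couplings between beads of different molecules zeroed
                     (intramolecular HI only);
* ``free_draining``— diagonal (Stokes–Einstein) mobilities only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import cholesky

from .constants import ETA_DEFAULT, T_DEFAULT, mobility_scale
from .model import SystemSpec

HI_MODES = ("full_hi", "intra_hi", "free_draining")


class MatrixConstructionError(RuntimeError):
    """Raised when the diffusion matrix is not usable (e.g. not PD)."""


class SingularGeometryError(ValueError):
    pass


@njit(cache=True)
def _rpy_pair(dx, ai, aj, mob):
    """Off-diagonal RPY block in diffusion units; ``mob`` = kBT/(6πη)."""
    r2 = (dx * dx).sum()
    r = np.sqrt(r2)
    out = np.empty((3, 3))
    if r >= ai + aj:
        c = mob * 6.0 / (8.0 * r)
        a2 = ai * ai + aj * aj
        f1 = 1.0 + a2 / (3.0 * r2)
        f2 = 1.0 - a2 / r2
        for u in range(3):
            for v in range(3):
                out[u, v] = c * f2 * dx[u] * dx[v] / r2
            out[u, u] += c * f1
    else:
        ab = np.sqrt((ai * ai + aj * aj) / 2.0)
        c = mob / ab
        f1 = 1.0 - 9.0 * r / (32.0 * ab)
        f2 = 3.0 / (32.0 * ab * r) if r > 0 else 0.0
        for u in range(3):
            for v in range(3):
                out[u, v] = c * f2 * dx[u] * dx[v]
            out[u, u] += c * f1
    return out


@njit(cache=True)
def _grand_matrix(x, a, mol, mode, mob):
    n = x.shape[0]
    D = np.zeros((3 * n, 3 * n))
    for i in range(n):
        di = mob / a[i]
        for d in range(3):
            D[3 * i + d, 3 * i + d] = di
        if mode == 0:
            continue
        for j in range(i + 1, n):
            if mode == 2 and mol[i] != mol[j]:
                continue
            blk = _rpy_pair(x[i] - x[j], a[i], a[j], mob)
            for u in range(3):
                for v in range(3):
                    D[3 * i + u, 3 * j + v] = blk[u, v]
                    D[3 * j + u, 3 * i + v] = blk[u, v]
    return D


_MODE_CODE = {"free_draining": 0, "full_hi": 1, "intra_hi": 2}


@dataclass
class GrandDiffusionMatrix:
    """Dense symmetric 3N×3N diffusion matrix (Å²/ns) with its HI mode."""

    matrix: np.ndarray
    mode: str
    temperature: float = T_DEFAULT
    eta: float = ETA_DEFAULT

    @property
    def n_beads(self) -> int:
        return self.matrix.shape[0] // 3

    def save(self, path) -> None:
        """Dump the dense matrix (``.npy``) for offline inspection."""
        np.save(path, self.matrix)

    def cholesky_factor(self) -> np.ndarray:
        """Lower Cholesky factor of D (raises if not positive definite)."""
        try:
            return cholesky(self.matrix, lower=True)
        except np.linalg.LinAlgError as exc:
            lam = float(np.linalg.eigvalsh(self.matrix).min())
            raise MatrixConstructionError(
                f"diffusion matrix not positive definite "
                f"(min eigenvalue {lam:.3e})") from exc


def rpy_block(r_i, r_j, a_i: float, a_j: float,
              eta: float = ETA_DEFAULT, T: float = T_DEFAULT) -> np.ndarray:
    """3×3 RPY diffusion tensor block for a bead pair, Å²/ns.

    With ``r_i is r_j`` semantics handled by the caller: pass identical
    positions only for the self block via :func:`rpy_self`.
    """
    dx = np.asarray(r_i, float) - np.asarray(r_j, float)
    r = np.linalg.norm(dx)
    if r == 0.0:
        raise SingularGeometryError("coincident distinct beads")
    return _rpy_pair(dx, a_i, a_j, mobility_scale(T, eta))


def rpy_self(a: float, eta: float = ETA_DEFAULT, T: float = T_DEFAULT) -> np.ndarray:
    """Self (Stokes–Einstein) diffusion block kBT/(6πηa)·I, Å²/ns."""
    return (mobility_scale(T, eta) / a) * np.eye(3)


def grand_matrix(system: SystemSpec, conformation: np.ndarray | None = None,
                 mode: str = "full_hi", eta: float = ETA_DEFAULT,
                 T: float = T_DEFAULT) -> GrandDiffusionMatrix:
    """Assemble the grand diffusion matrix for a conformation."""
    if mode not in _MODE_CODE:
        raise ValueError(f"unknown HI mode {mode!r}; choose from {HI_MODES}")
    x = np.ascontiguousarray(
        system.positions if conformation is None else conformation, float)
    if mode != "free_draining":
        # coincident distinct beads make the pair block singular in intent
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() == 0.0:
            raise SingularGeometryError("coincident distinct beads")
    D = _grand_matrix(x, system.stokes, system.molecule, _MODE_CODE[mode],
                      mobility_scale(T, eta))
    return GrandDiffusionMatrix(D, mode, T, eta)


def correlated_displacement(D: GrandDiffusionMatrix, dt_ps: float,
                            rng: np.random.Generator,
                            L: np.ndarray | None = None) -> np.ndarray:
    """One Brownian displacement draw with covariance 2·D·Δt, flat 3N array (Å).

    ``L`` may carry a precomputed Cholesky factor of D to amortise the
    factorisation across tensor-refresh intervals.
    """
    if L is None:
        L = D.cholesky_factor()
    scale = np.sqrt(2.0 * dt_ps * 1e-3)  # dt in ps, D in Å²/ns
    z = rng.standard_normal(D.matrix.shape[0])
    return scale * (L @ z)
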