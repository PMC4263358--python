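"""Brownian dynamics propagation.

The integrator is a predictor–corrector (second-order Runge–Kutta) scheme
for overdamped Langevin dynamics with configuration-dependent hydrodynamic
coupling:

    x* = x + (Δt/kBT)·D·F(x) + S,          S ~ N(0, 2·D·Δt)
    x' = x + (Δt/2kBT)·D·[F(x) + F(x*)] + S

with the *same* noise realisation S and the same diffusion matrix D in both
stages.  D and its Cholesky factor are refreshed every
``tensor_update_interval`` steps (200 by default); between refreshes the
matrix is frozen.  The spurious-drift term ∇·D is not needed: the RPY
tensor is divergence-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import kbt
from .energy import Bias, ForceFieldParams, Restraints, charge_prefactors, \
    size_factor_radii, total_energy_forces
from .hydrodynamics import GrandDiffusionMatrix, HI_MODES, grand_matrix
from .model import SystemSpec


class BlowUpError(RuntimeError):
    """A bead moved farther than the sanity bound in one step."""

    def __init__(self, step: int, trajectory: "Trajectory | None" = None):
        super().__init__(f"per-step displacement exceeded the sanity bound "
                         f"at step {step}")
        self.step = step
        self.trajectory = trajectory


@dataclass
class Protocol:
    """Simulation protocol: time step, durations, HI and restraint modes."""

    dt_ps: float = 0.25
    n_steps: int = 10_000
    tensor_update_interval: int = 200
    sample_interval: int = 1_000
    hi_mode: str = "full_hi"
    dna_mode: str | None = "restrained"   # restrained | flexible | None
    temperature: float = 298.0
    eta: float = 0.89
    seed: int = 0
    max_step_displacement: float = 5.0
    record_energies: bool = True

    def __post_init__(self):
        if self.dt_ps <= 0:
            raise ValueError("dt must be positive")
        if self.tensor_update_interval < 1 or self.sample_interval < 1:
            raise ValueError("intervals must be >= 1")
        if self.hi_mode not in HI_MODES:
            raise ValueError(f"hi_mode must be one of {HI_MODES}")
        if self.dna_mode not in ("restrained", "flexible", None):
            raise ValueError("dna_mode must be 'restrained', 'flexible' or None")


@dataclass
class Trajectory:
    """Sampled conformations (F, N, 3) Å with times in ns."""

    times_ns: np.ndarray
    frames: np.ndarray
    energies: np.ndarray | None = None   # (F, 7) per-term breakdown
    protocol: Protocol | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times_ns)

    def __post_init__(self):
        if len(self.frames) != len(self.times_ns):
            raise ValueError("frame/time count mismatch")
        if len(self.times_ns) > 1 and not (np.diff(self.times_ns) > 0).all():
            raise ValueError("times must be strictly increasing")


def dna_bead_indices(system: SystemSpec) -> np.ndarray:
    return np.array([i for i, nm in enumerate(system.names) if nm in ("PB", "PP")],
                    np.int64)


def dna_restraints(system: SystemSpec, mode: str | None,
                   anchors: np.ndarray) -> Restraints:
    """Restraint set for the two DNA treatments.

    ``restrained``: every DNA bead held at its anchor with k = 1 kcal/mol/Å².
    ``flexible``: only the PB+PP beads of the two terminal residues at each
    end, with k = 0.01 kcal/mol/Å² (keeps the molecule from drifting while
    leaving the interior free).
    """
    if mode is None:
        return Restraints.none()
    idx = dna_bead_indices(system)
    if len(idx) == 0:
        return Restraints.none()
    if mode == "restrained":
        return Restraints.uniform(idx, 1.0, anchors[idx])
    res = system.residue[idx]
    n = int(res.max()) + 1
    sel = idx[(res <= 1) | (res >= n - 2)]
    return Restraints.uniform(sel, 0.01, anchors[sel])


def rk2_step(conformation: np.ndarray, D: GrandDiffusionMatrix, forces_fn,
             dt_ps: float, rng: np.random.Generator,
             noise: np.ndarray | None = None,
             temperature: float = 298.0) -> np.ndarray:
    """One predictor–corrector BD step (reference implementation).

    ``forces_fn(x) -> (N, 3)`` in kcal/mol/Å.  ``noise`` may inject a fixed
    Brownian displacement (flat 3N, Å); otherwise it is drawn from
    N(0, 2·D·Δt).  Returns the new conformation.
    """
    x = np.asarray(conformation, float)
    n = x.shape[0]
    kt = kbt(temperature)
    dt_ns = dt_ps * 1e-3
    B = D.matrix * (dt_ns / kt)
    if noise is None:
        L = D.cholesky_factor()
        noise = np.sqrt(2.0 * dt_ns) * (L @ rng.standard_normal(3 * n))
    drift0 = B @ forces_fn(x).ravel()
    xs = x + (drift0 + noise).reshape(n, 3)
    drift = 0.5 * (drift0 + B @ forces_fn(xs).ravel())
    return x + (drift + noise).reshape(n, 3)


def run_simulation(system: SystemSpec, params: ForceFieldParams | None,
                   protocol: Protocol, bias: Bias | None = None,
                   extra_restraints: Restraints | None = None,
                   initial: np.ndarray | None = None) -> Trajectory:
    """Propagate the system and return the sampled trajectory.

    Restraint anchors are captured from the initial conformation.  The
    trajectory always includes the initial frame; with ``n_steps`` steps and
    sampling every ``sample_interval`` the frame count is
    ``n_steps // sample_interval + 1``.
    """
    params = params or ForceFieldParams()
    x = np.ascontiguousarray(
        system.positions if initial is None else initial, float).copy()
    rng = np.random.default_rng(protocol.seed)
    kt = kbt(protocol.temperature)
    dt_ns = protocol.dt_ps * 1e-3

    rest = dna_restraints(system, protocol.dna_mode, x)
    if extra_restraints is not None and len(extra_restraints.indices):
        rest = Restraints(
            np.concatenate([rest.indices, extra_restraints.indices]),
            np.concatenate([rest.k, extra_restraints.k]),
            np.vstack([rest.anchors.reshape(-1, 3),
                       extra_restraints.anchors.reshape(-1, 3)]))
    b = bias or Bias()
    t = system.topology
    qpref = charge_prefactors(system, params)
    fradii = size_factor_radii(system, params)

    n3 = 3 * system.n_beads
    frames = [x.copy()]
    times = [0.0]

    step = 0
    B = np.empty((n3, n3))
    Lscaled = np.empty((n3, n3))

    def refresh():
        D = grand_matrix(system, x, protocol.hi_mode,
                         eta=protocol.eta, T=protocol.temperature)
        np.copyto(B, D.matrix * (dt_ns / kt))
        np.copyto(Lscaled, D.cholesky_factor() * np.sqrt(2.0 * dt_ns))

    refresh()
    fail_step = None
    while step < protocol.n_steps and fail_step is None:
        upto_refresh = protocol.tensor_update_interval - \
            step % protocol.tensor_update_interval
        upto_sample = protocol.sample_interval - step % protocol.sample_interval
        chunk = min(upto_refresh, upto_sample, protocol.n_steps - step)
        S = rng.standard_normal((chunk, n3)) @ Lscaled.T
        rc = _kernels.rk2_chunk(
            x, B, S, t.bonds, t.bond_k, t.bond_r0, t.angles, t.angle_k,
            t.angle_t0, t.torsions, t.torsion_k, t.torsion_p0,
            system.sigma, qpref, fradii, system.molecule,
            system.residue, params.kappa, params.cutoff, params.k_ex,
            params.mode, rest.indices, rest.k, rest.anchors, b.dist, b.plane,
            b.ext_force, protocol.max_step_displacement)
        if rc >= 0:
            fail_step = step + rc
            break
        step += chunk
        if step % protocol.sample_interval == 0:
            frames.append(x.copy())
            times.append(step * dt_ns)
        if step % protocol.tensor_update_interval == 0 and step < protocol.n_steps:
            refresh()

    energies = None
    if protocol.record_energies:
        energies = np.array([
            _energy_row(system, f, params, rest, b) for f in frames])
    traj = Trajectory(np.array(times), np.array(frames), energies, protocol,
                      provenance={"seed": protocol.seed,
                                  "hi_mode": protocol.hi_mode,
                                  "dna_mode": protocol.dna_mode,
                                  "dt_ps": protocol.dt_ps})
    if fail_step is not None:
        raise BlowUpError(fail_step, traj)
    return traj


def _energy_row(system, frame, params, rest, bias):
    rep = total_energy_forces(system, frame, params, rest, bias)
    return np.array([rep.bond, rep.angle, rep.torsion, rep.excluded,
                     rep.electrostatic, rep.restraint, rep.umbrella])
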