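"""Umbrella sampling along the protein–DNA separation and WHAM reconstruction.

The reaction coordinate is the 3D distance between the protein-body bead
(PBP) and the backbone bead nearest the DNA centre.  The PBP is confined to
the Z-plane of that bead by a harmonic term (k = 1 kcal/mol/Å²), so the
coordinate is effectively the in-plane separation.  Windows are harmonic
biases ½·k_umb·(r-r₀)²; the default ladder is r₀ = 90, 89, …, 31 Å (60
windows) with k_umb = 5 kcal/mol/Å².

The potential of mean force is reconstructed with the standard
self-consistent WHAM iteration, and the binding free energy is read off as
the mean PMF over the unbound plateau (80–90 Å by default) minus the PMF
minimum.  No standard-state volume correction is applied: the number is the
well depth of the confined-geometry profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import kbt
from .energy import Bias, ForceFieldParams
from .engine import Protocol, dna_bead_indices, run_simulation
from .model import SystemSpec

DEFAULT_WINDOWS = tuple(float(r) for r in range(90, 30, -1))
DEFAULT_K_UMB = 5.0
DEFAULT_PLANE_K = 1.0


class SamplingError(RuntimeError):
    pass


class IllPosedInputError(ValueError):
    pass


class NotConvergedWarning(UserWarning):
    pass


@dataclass
class UmbrellaWindow:
    """Reaction-coordinate samples collected under one harmonic bias."""

    r0: float
    k_umb: float
    samples: np.ndarray
    n_equilibration: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.samples.size == 0:
            raise SamplingError(f"window r0={self.r0}: no production samples")
        if (self.samples <= 0).any():
            raise SamplingError(f"window r0={self.r0}: non-positive distances")


@dataclass
class PMFProfile:
    """Potential of mean force on a distance grid, minimum-anchored."""

    r: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray
    n_iterations: int = 0
    residual: float = np.nan
    metadata: dict = field(default_factory=dict)

    def value_at(self, r: float) -> float:
        return float(np.interp(r, self.r, self.free_energy))

    def to_tsv(self) -> str:
        head = "".join(f"# {k} = {v}\n" for k, v in sorted(
            self.metadata.items()))
        head += (f"# wham_iterations = {self.n_iterations}\n"
                 f"# wham_residual = {self.residual:.3e}\n")
        rows = "\n".join(f"{r:.4f}\t{g:.6f}\t{int(c)}" for r, g, c in
                         zip(self.r, self.free_energy, self.counts))
        return head + "r_angstrom\tpmf_kcal_mol\tcount\n" + rows


def window_histograms_tsv(windows, bin_width: float = 0.5) -> str:
    """Per-window reaction-coordinate histograms as TSV."""
    lo = min(w.samples.min() for w in windows) - bin_width
    hi = max(w.samples.max() for w in windows) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    mids = 0.5 * (edges[:-1] + edges[1:])
    cols = ["r_angstrom"] + [f"r0_{w.r0:g}" for w in windows]
    hists = [np.histogram(w.samples, bins=edges)[0] for w in windows]
    lines = ["\t".join(cols)]
    for b, m in enumerate(mids):
        lines.append("\t".join([f"{m:.4f}"] + [str(int(h[b])) for h in hists]))
    return "\n".join(lines)


def umbrella_system_center(system: SystemSpec) -> int:
    """Index of the PB bead nearest the coordinate origin (DNA centre)."""
    idx = [i for i, nm in enumerate(system.names) if nm == "PB"]
    if not idx:
        raise ValueError("system has no PB beads")
    z = np.abs(np.linalg.norm(system.positions[idx], axis=1))
    return int(idx[int(np.argmin(z))])


def protein_bead_indices(system: SystemSpec) -> np.ndarray:
    prot = [i for i, nm in enumerate(system.names) if nm in ("PBP", "DBP")]
    if len(prot) != 3 or system.names[prot[0]] != "PBP":
        raise ValueError("expected a three-bead protein with leading PBP")
    return np.array(prot, np.int64)


def umbrella_start_conformation(system: SystemSpec, r_start: float = 90.0) -> np.ndarray:
    """Place the protein with its PBP on the +X axis at ``r_start`` Å."""
    x = system.positions.copy()
    prot = protein_bead_indices(system)
    ic = umbrella_system_center(system)
    target = system.positions[ic] + np.array([r_start, 0.0, 0.0])
    shift = target - x[prot[0]]
    x[prot] += shift
    return x


def run_umbrella(system: SystemSpec, params: ForceFieldParams | None = None,
                 windows=DEFAULT_WINDOWS, *, k_umb: float = DEFAULT_K_UMB,
                 sampler: str = "mc", seed: int = 0,
                 n_equil: int = 2000, n_prod: int = 10000,
                 dna_fluctuates: bool = True,
                 protocol: Protocol | None = None,
                 equilibration_fraction: float = 0.2,
                 reseed_below: float | None = 48.0) -> list[UmbrellaWindow]:
    """Run the umbrella ladder and collect reaction-coordinate samples.

    ``sampler="mc"`` uses the Metropolis sampler on the identical potential
    (fast equilibrium path); ``sampler="bd"`` runs Brownian dynamics per
    window with the supplied ``protocol`` (its first
    ``equilibration_fraction`` of samples are discarded).  Windows are
    visited in the given order and each starts from the final conformation
    of the previous one.  The DNA is fully restrained (k = 1 kcal/mol/Å²);
    with ``dna_fluctuates=False`` the MC path freezes the DNA instead of
    sampling its restrained fluctuations.
    """
    params = params or ForceFieldParams()
    prot = protein_bead_indices(system)
    ic = umbrella_system_center(system)
    z0 = float(system.positions[ic, 2])
    x = umbrella_start_conformation(system, max(windows))
    out = []
    if sampler == "mc":
        from .mc import run_mc_window
        dna_idx = dna_bead_indices(system)
        rest_k = np.zeros(system.n_beads)
        rest_k[dna_idx] = 1.0
        rest_anchor = system.positions.copy()
        movable = (np.concatenate([dna_idx, prot]) if dna_fluctuates
                   else prot.copy())
        for w, r0 in enumerate(windows):
            if reseed_below is not None and r0 <= reseed_below:
                # start contact windows from the docked build: the assembled
                # pose has the DBP beads in their groove registry, which the
                # pulled-in continuation state may not have found yet
                x[prot] = system.positions[prot]
            samples = run_mc_window(
                system, params, x, reaction_bead=ic, protein_beads=prot,
                r0=float(r0), k_umb=k_umb, plane_k=DEFAULT_PLANE_K,
                plane_z=z0, rest_k=rest_k, rest_anchor=rest_anchor,
                movable=movable, n_equil=n_equil, n_prod=n_prod,
                seed=seed * 100003 + w)
            out.append(UmbrellaWindow(float(r0), k_umb, samples, n_equil))
    elif sampler == "bd":
        if protocol is None:
            raise ValueError("BD umbrella sampling needs a Protocol")
        for w, r0 in enumerate(windows):
            p = Protocol(**{**protocol.__dict__,
                            "seed": protocol.seed * 100003 + w,
                            "dna_mode": "restrained"})
            bias = Bias.umbrella(int(prot[0]), ic, k_umb, float(r0),
                                 plane_bead=int(prot[0]),
                                 plane_k=DEFAULT_PLANE_K, plane_z=z0)
            traj = run_simulation(system, params, p, bias=bias, initial=x)
            x = traj.frames[-1].copy()
            r = np.linalg.norm(traj.frames[:, prot[0]] - traj.frames[:, ic],
                               axis=1)
            n_eq = int(len(r) * equilibration_fraction)
            out.append(UmbrellaWindow(float(r0), k_umb, r[n_eq:], n_eq))
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    return out


def wham(windows: list[UmbrellaWindow], bin_width: float = 0.5,
         tol: float = 1e-6, max_iter: int = 100_000,
         temperature: float = 298.0, min_count: int = 5) -> PMFProfile:
    """Self-consistent WHAM reconstruction of the PMF from biased histograms.

    Iterates the window free-energy offsets until they change by less than
    ``tol`` (kcal/mol).  Bins with fewer than ``min_count`` total samples
    are reported as NaN.  Raises :class:`IllPosedInputError` when adjacent
    windows share no populated bin.
    """
    if not windows:
        raise IllPosedInputError("no umbrella windows")
    kt = kbt(temperature)
    lo = min(w.samples.min() for w in windows) - bin_width
    hi = max(w.samples.max() for w in windows) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    mids = 0.5 * (edges[:-1] + edges[1:])
    K, B = len(windows), len(mids)
    H = np.zeros((K, B))
    N = np.zeros(K)
    for k, w in enumerate(windows):
        H[k], _ = np.histogram(w.samples, bins=edges)
        N[k] = len(w.samples)

    order = np.argsort([w.r0 for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not ((H[a] > 0) & (H[b] > 0)).any():
            raise IllPosedInputError(
                f"windows r0={windows[a].r0} and r0={windows[b].r0} share no "
                f"populated histogram bin")

    r0s = np.array([w.r0 for w in windows])
    ku = np.array([w.k_umb for w in windows])
    bias = 0.5 * ku[:, None] * (mids[None, :] - r0s[:, None]) ** 2
    c = np.exp(-bias / kt)
    num = H.sum(0)
    f = np.zeros(K)
    residual = np.inf
    it = 0
    p = np.zeros(B)
    for it in range(1, max_iter + 1):
        denom = (N[:, None] * np.exp(f[:, None] / kt) * c).sum(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, num / denom, 0.0)
        with np.errstate(divide="ignore"):
            fn = -kt * np.log((c * p[None, :]).sum(1))
        fn -= fn[0]
        residual = float(np.max(np.abs(fn - f)))
        f = fn
        if residual < tol:
            break
    with np.errstate(divide="ignore"):
        G = -kt * np.log(p)
    G[num < min_count] = np.nan
    G -= np.nanmin(G)
    return PMFProfile(mids, G, num, it, residual,
                      metadata={"bin_width": bin_width, "tol": tol,
                                "window_r0": r0s.tolist()})


@dataclass
class BindingFreeEnergy:
    """Binding free energy ΔG = plateau − minimum, kcal/mol."""

    delta_g: float
    error: float = np.nan
    plateau: tuple = (80.0, 90.0)
    converged: bool = True


def binding_free_energy(pmf: PMFProfile, unbound_range=(80.0, 90.0), *,
                        slope_tolerance: float = 0.05) -> BindingFreeEnergy:
    """Extract ΔG as the unbound-plateau mean minus the PMF minimum.

    Emits :class:`NotConvergedWarning` (and flags the result) when the PMF
    slope across the plateau exceeds ``slope_tolerance`` kcal/mol/Å.
    """
    lo, hi = unbound_range
    sel = (pmf.r >= lo) & (pmf.r <= hi) & np.isfinite(pmf.free_energy)
    if not sel.any() or not np.isfinite(pmf.free_energy).any():
        raise IllPosedInputError("PMF not defined over the unbound range")
    g = pmf.free_energy[sel]
    r = pmf.r[sel]
    plateau = float(g.mean())
    slope = 0.0 if len(r) < 2 else float(np.polyfit(r, g, 1)[0])
    converged = abs(slope) <= slope_tolerance
    if not converged:
        warnings.warn(f"PMF plateau slope {slope:.3f} kcal/mol/Å exceeds "
                      f"{slope_tolerance}", NotConvergedWarning)
    dg = plateau - float(np.nanmin(pmf.free_energy))
    return BindingFreeEnergy(dg, plateau=(lo, hi), converged=converged)


def binding_free_energy_repeats(dgs) -> BindingFreeEnergy:
    """Combine independent repeats into a mean ± standard error."""
    vals = np.asarray(dgs, float)
    err = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
    return BindingFreeEnergy(float(vals.mean()), float(err))


def well_depth_integral(pmf: PMFProfile, unbound_range=(80.0, 90.0),
                        temperature: float = 298.0) -> float:
    """Alternative ΔG estimator: Boltzmann-integrated well depth.

    -kBT·ln[ Σ_well exp(-G/kBT) / Σ_plateau exp(-G/kBT) ] with the well
    taken as everything below the plateau range.  Provided for comparison
    with the plateau-minus-minimum convention.
    """
    kt = kbt(temperature)
    lo, _ = unbound_range
    g = pmf.free_energy
    ok = np.isfinite(g)
    well = ok & (pmf.r < lo)
    plat = ok & (pmf.r >= lo) & (pmf.r <= unbound_range[1])
    if not well.any() or not plat.any():
        raise IllPosedInputError("PMF does not span well and plateau")
    zw = np.exp(-g[well] / kt).sum()
    zp = np.exp(-g[plat] / kt).mean()
    return float(kt * np.log(zw / zp))
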