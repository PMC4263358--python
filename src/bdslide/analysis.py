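"""Trajectory observables: 1D diffusion, rotation coupling, hopping, stiffness.

These estimators back the quantitative comparison of simulated sliding
against helical-sliding theory: apparent 1D diffusion coefficients from
mean-squared displacements along the DNA axis, the off-axis distance of the
protein's centre of diffusion, the z–azimuth coupling of groove tracking,
detachment ("hopping") events, and the DNA persistence length from tangent
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Trajectory


class InvalidTrajectoryError(ValueError):
    pass


@dataclass
class MsdCurve:
    """Time-averaged mean-squared displacement vs lag."""

    lag_ns: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    axis: str = "z"

    def __post_init__(self):
        if self.msd[0] != 0.0 or (self.msd < 0).any():
            raise ValueError("MSD must start at 0 and be non-negative")


@dataclass
class HopEvent:
    """A microscopic detachment–reattachment excursion."""

    start_ns: float
    end_ns: float
    z_before: float
    z_after: float
    max_distance: float

    def __post_init__(self):
        if self.end_ns <= self.start_ns:
            raise ValueError("hop must end after it starts")


def _series_times(traj_or_series, series=None):
    if isinstance(traj_or_series, Trajectory):
        return traj_or_series.times_ns, traj_or_series.frames
    return np.asarray(traj_or_series, float), np.asarray(series, float)


def msd_1d(traj: Trajectory | np.ndarray, bead: int | None = None,
           axis: str = "z", max_lag_fraction: float = 0.25,
           series: np.ndarray | None = None) -> MsdCurve:
    """Time-averaged 1D MSD of one bead (or an explicit coordinate series).

    All frame pairs contribute at each lag, up to ``max_lag_fraction`` of
    the trajectory length.  Sampling must be uniform.
    """
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    if isinstance(traj, Trajectory):
        t = traj.times_ns
        u = traj.frames[:, bead, ax]
    else:
        t = np.asarray(traj, float)
        u = np.asarray(series, float)
    if len(t) < 2:
        raise InvalidTrajectoryError("need at least 2 frames")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise InvalidTrajectoryError("non-uniform sampling interval")
    nmax = max(1, int(len(u) * max_lag_fraction))
    lags = np.arange(nmax + 1)
    msd = np.zeros(nmax + 1)
    npairs = np.zeros(nmax + 1, int)
    npairs[0] = len(u)
    for k in range(1, nmax + 1):
        d = u[k:] - u[:-k]
        msd[k] = (d * d).mean()
        npairs[k] = len(d)
    return MsdCurve(lags * dt[0], msd, npairs, axis)


@dataclass
class DiffusionEstimate:
    d: float          # Å²/ns
    se: float = np.nan
    fit_window: tuple = (np.nan, np.nan)
    negative_slope: bool = False


def apparent_d1d(msd: MsdCurve, fit_window: tuple | None = None) -> DiffusionEstimate:
    """D from the slope of MSD vs lag over a window: MSD = 2·D·τ (+ offset).

    Weighted least squares with weights ∝ number of contributing pairs.  A
    negative fitted slope is reported (flagged), not clamped.
    """
    if fit_window is None:
        fit_window = (msd.lag_ns[1], msd.lag_ns[-1])
    lo, hi = fit_window
    sel = (msd.lag_ns >= lo) & (msd.lag_ns <= hi)
    if sel.sum() < 5:
        raise ValueError("need at least 5 lags in the fit window")
    x = msd.lag_ns[sel]
    y = msd.msd[sel]
    w = msd.n_pairs[sel].astype(float)
    W = np.diag(w)
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(np.sqrt(W) @ A, np.sqrt(w) * y, rcond=None)
    slope = coef[0]
    resid = y - A @ coef
    dof = max(1, len(x) - 2)
    var = (w * resid ** 2).sum() / (w.sum() * dof)
    xvar = (w * (x - (w * x).sum() / w.sum()) ** 2).sum() / w.sum()
    se = np.sqrt(var / (len(x) * xvar)) / 2.0 if xvar > 0 else np.nan
    return DiffusionEstimate(float(slope / 2.0), float(se), (lo, hi),
                             negative_slope=slope < 0)


def d1d_from_replicas(trajs, bead: int, fit_window=None,
                      max_lag_fraction: float = 0.25) -> DiffusionEstimate:
    """Mean ± SD-based standard error of D over independent replicas."""
    ds = []
    for tr in trajs:
        m = msd_1d(tr, bead, max_lag_fraction=max_lag_fraction)
        ds.append(apparent_d1d(m, fit_window).d)
    ds = np.asarray(ds)
    se = ds.std(ddof=1) if len(ds) > 1 else np.nan
    return DiffusionEstimate(float(ds.mean()), float(se))


def unwrap_angle(phi: np.ndarray) -> np.ndarray:
    return np.unwrap(phi)


@dataclass
class RotationCoupling:
    slope: float       # Å/rad
    correlation: float


def rotation_coupling(traj: Trajectory, bead: int,
                      bound_mask: np.ndarray | None = None) -> RotationCoupling:
    """Regress Δz of a bead against its unwrapped azimuth about the Z axis.

    An ideal groove-tracking trajectory has slope pitch/2π ≈ 5.38 Å/rad and
    correlation 1.  ``bound_mask`` restricts the analysis to bound frames.
    """
    x = traj.frames[:, bead]
    if bound_mask is not None:
        if not bound_mask.any():
            raise InvalidTrajectoryError("no bound frames to analyse")
        x = x[bound_mask]
    z = x[:, 2]
    phi = unwrap_angle(np.arctan2(x[:, 1], x[:, 0]))
    dz = z - z[0]
    dphi = phi - phi[0]
    if np.ptp(dphi) == 0:
        return RotationCoupling(np.nan, 0.0)
    slope = float(np.polyfit(dphi, dz, 1)[0])
    corr = float(np.corrcoef(dphi, dz)[0, 1])
    return RotationCoupling(slope, corr)


def detect_hops(traj: Trajectory, dna_pp_indices, dbp_indices, *,
                r_off: float = 40.0, min_duration_ns: float = 0.0) -> list[HopEvent]:
    """Detachment events: all DBP beads farther than ``r_off`` from every PP.

    An event opens when the minimum DBP–PP centre distance exceeds the
    threshold (default: the nonbonded cutoff, beyond which the protein
    feels no DNA attraction) for at least ``min_duration_ns``, and closes
    on re-approach.
    """
    pp = traj.frames[:, list(dna_pp_indices)]
    dbp = traj.frames[:, list(dbp_indices)]
    d = np.linalg.norm(dbp[:, :, None, :] - pp[:, None, :, :], axis=-1)
    mind = d.min(axis=(1, 2))
    t = traj.times_ns
    z = dbp[..., 2].mean(axis=1)
    events = []
    off = mind > r_off
    i = 0
    while i < len(off):
        if off[i]:
            j = i
            while j < len(off) and off[j]:
                j += 1
            dur = t[min(j, len(t) - 1)] - t[i]
            if dur >= min_duration_ns and j < len(off):
                events.append(HopEvent(float(t[i]), float(t[j]),
                                       float(z[max(i - 1, 0)]), float(z[j]),
                                       float(mind[i:j].max())))
            i = j
        else:
            i += 1
    return events


@dataclass
class PersistenceLength:
    lp: float                  # Å
    se: float = np.nan
    lower_bound: bool = False  # True when correlations did not decay


def persistence_length(conformations: np.ndarray, *, rise: float = 3.38,
                       end_exclusion: int = 5, max_lag: int = 30,
                       min_lag: int = 1) -> PersistenceLength:
    """Persistence length from the tangent-correlation decay of PB backbones.

    ``conformations``: (F, n, 3) array of backbone bead positions.  Fits
    ⟨t̂(s)·t̂(s+k)⟩ = exp(-k·b/Lp) over lags [min_lag, max_lag], excluding
    ``end_exclusion`` residues at each end.  If the correlation has not
    decayed measurably (rigid rod), Lp is reported as a lower bound.
    """
    x = np.asarray(conformations, float)
    if x.ndim == 2:
        x = x[None]
    F, n, _ = x.shape
    tvec = x[:, 1:] - x[:, :-1]
    tvec /= np.linalg.norm(tvec, axis=-1, keepdims=True)
    lo, hi = end_exclusion, n - 1 - end_exclusion
    max_lag = min(max_lag, hi - lo - 1)
    corr = np.zeros(max_lag + 1)
    for k in range(1, max_lag + 1):
        dots = (tvec[:, lo:hi - k] * tvec[:, lo + k:hi]).sum(-1)
        corr[k] = dots.mean()
    corr[0] = 1.0
    ks = np.arange(min_lag, max_lag + 1)
    c = corr[min_lag:]
    if (c[:3] <= 0).any():
        raise InvalidTrajectoryError(
            "tangent correlation non-positive at short lags; chain too "
            "short or too flexible for this estimator")
    decay = 1.0 - c.min()
    if decay < 1e-6:
        return PersistenceLength(np.inf, lower_bound=True)
    mask = c > 0
    coef, cov = np.polyfit(ks[mask], np.log(c[mask]), 1, cov=True)
    slope = coef[0]
    if slope >= 0:
        return PersistenceLength(np.inf, lower_bound=True)
    lp = -rise / slope
    se = rise * np.sqrt(cov[0, 0]) / slope ** 2
    return PersistenceLength(float(lp), float(se))


def roc_from_traj(traj: Trajectory, protein_indices, cod_body: np.ndarray,
                  build_positions: np.ndarray) -> tuple[float, float]:
    """Off-axis distance of the protein's centre of diffusion along a trajectory.

    ``cod_body`` is the centre of diffusion in the protein build (body)
    frame and ``build_positions`` the (3, 3) build coordinates of the
    protein beads.  Each frame's rigid transform from build to lab frame is
    obtained by Kabsch superposition; the transformed centre's distance
    from the Z axis is averaged.  Returns (mean, SD) in Å.
    """
    prot = traj.frames[:, list(protein_indices)]
    ref = build_positions - build_positions.mean(axis=0)
    cod0 = cod_body - build_positions.mean(axis=0)
    dists = np.empty(len(prot))
    for f, p in enumerate(prot):
        cen = p.mean(axis=0)
        H = ref.T @ (p - cen)
        U, S, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        cod_lab = R @ cod0 + cen
        dists[f] = np.hypot(cod_lab[0], cod_lab[1])
    return float(dists.mean()), float(dists.std())
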