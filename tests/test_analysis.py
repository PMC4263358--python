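"""Trajectory estimators: MSD/D fits, rotation coupling, hops, persistence."""

import numpy as np
import pytest

from bdslide import Trajectory, apparent_d1d, detect_hops, msd_1d
from bdslide.analysis import (InvalidTrajectoryError, MsdCurve,
                              persistence_length, rotation_coupling,
                              roc_from_traj)
from bdslide.constants import KBT
from bdslide.mc import sample_dna_conformations
from bdslide.model import PITCH, RISE


def traj_from_series(times, coords):
    frames = np.asarray(coords, float).reshape(len(times), -1, 3)
    return Trajectory(np.asarray(times, float), frames)


class TestMsd:
    def test_static_trajectory_is_zero(self):
        t = np.arange(50) * 1.0
        traj = traj_from_series(t, np.tile([1.0, 2.0, 3.0], (50, 1)))
        m = msd_1d(traj, 0)
        assert np.all(m.msd == 0.0)

    def test_random_walk_recovers_diffusion_constant(self):
        rng = np.random.default_rng(1)
        d_in, dt = 0.05, 2.5
        est = []
        for _ in range(10):
            steps = rng.normal(0, np.sqrt(2 * d_in * dt), 4000)
            z = np.concatenate([[0.0], np.cumsum(steps)])
            t = np.arange(len(z)) * dt
            m = msd_1d(t, series=z)
            est.append(apparent_d1d(m).d)
        assert np.mean(est) == pytest.approx(d_in, rel=0.05)

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(2)
        z = np.cumsum(rng.standard_normal(300))
        t = np.arange(300) * 1.0
        a = msd_1d(t, series=z)
        b = msd_1d(t, series=z[::-1])
        assert np.allclose(a.msd, b.msd)

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 4.0])
        with pytest.raises(InvalidTrajectoryError):
            msd_1d(t, series=np.zeros(4))

    def test_exact_linear_msd(self):
        lag = np.arange(20) * 1.0
        m = MsdCurve(lag, 2 * 0.05 * lag, np.full(20, 100))
        est = apparent_d1d(m)
        assert est.d == pytest.approx(0.05, abs=1e-12)
        assert not est.negative_slope

    def test_negative_slope_flagged_not_clamped(self):
        lag = np.arange(10) * 1.0
        m = MsdCurve(lag, np.maximum(0, 1.0 - 0.1 * lag) * lag / (lag + 1e-9),
                     np.full(10, 50))
        m.msd[0] = 0.0
        est = apparent_d1d(MsdCurve(lag, np.concatenate([[0], 1 - 0.05 * lag[1:]]),
                                    np.full(10, 50)))
        assert est.negative_slope and est.d < 0


class TestRotationCoupling:
    def test_ideal_helical_track(self):
        phi = np.linspace(0, 6 * np.pi, 400)
        r = 9.0
        coords = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                                  PITCH * phi / (2 * np.pi)])
        traj = traj_from_series(np.arange(400) * 1.0, coords)
        rc = rotation_coupling(traj, 0)
        assert rc.slope == pytest.approx(PITCH / (2 * np.pi), rel=1e-6)
        assert rc.correlation == pytest.approx(1.0, abs=1e-9)

    def test_uncorrelated_motion(self):
        rng = np.random.default_rng(3)
        n = 10_000
        phi = np.cumsum(rng.normal(0, 0.05, n))
        z = np.cumsum(rng.normal(0, 0.1, n))
        coords = np.column_stack([9 * np.cos(phi), 9 * np.sin(phi), z])
        traj = traj_from_series(np.arange(n) * 1.0, coords)
        rc = rotation_coupling(traj, 0)
        assert abs(rc.correlation) < 0.1 or abs(rc.slope) < 0.5


class TestHops:
    def _bound_frames(self, n):
        # one PP bead at origin, one DBP orbiting 15 A away
        pp = np.zeros((n, 1, 3))
        dbp = np.tile([15.0, 0, 0], (n, 1, 1))
        return np.concatenate([pp, dbp], axis=1)

    def test_bound_trajectory_has_no_events(self):
        frames = self._bound_frames(200)
        traj = Trajectory(np.arange(200) * 1.0, frames)
        assert detect_hops(traj, [0], [1]) == []

    def test_constructed_excursion_is_one_event(self):
        frames = self._bound_frames(200)
        frames[80:90, 1, 0] = 65.0   # 50 A excursion for 10 frames
        traj = Trajectory(np.arange(200) * 1.0, frames)
        events = detect_hops(traj, [0], [1], r_off=40.0, min_duration_ns=5.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.end_ns > ev.start_ns
        assert ev.max_distance == pytest.approx(65.0)

    def test_strongly_bound_protein_never_detaches(self):
        """A q(DBP)=20 protein stays on the DNA throughout a BD run."""
        from bdslide import (Protocol, assemble_system, build_dna,
                             build_protein, run_simulation)
        system = assemble_system(build_dna(30), build_protein(40.0, 20.0))
        p = Protocol(n_steps=40_000, sample_interval=400,
                     hi_mode="free_draining", dna_mode="restrained", seed=9,
                     record_energies=False)
        traj = run_simulation(system, None, p)
        pp = range(30, 60)
        dbp = [61, 62]
        assert detect_hops(traj, pp, dbp, r_off=40.0) == []
        d = np.linalg.norm(traj.frames[:, dbp][:, :, None]
                           - traj.frames[:, pp][:, None], axis=-1)
        assert d.min(axis=(1, 2)).max() < 40.0

    def test_short_blips_filtered_by_min_duration(self):
        frames = self._bound_frames(100)
        frames[50, 1, 0] = 65.0
        traj = Trajectory(np.arange(100) * 1.0, frames)
        assert detect_hops(traj, [0], [1], min_duration_ns=5.0) == []


class TestPersistenceLength:
    def test_rigid_rod_reports_lower_bound(self):
        z = np.arange(40) * RISE
        conf = np.column_stack([np.zeros(40), np.zeros(40), z])[None]
        res = persistence_length(np.repeat(conf, 3, axis=0))
        assert res.lower_bound and np.isinf(res.lp)

    def test_backbone_stiffness_sets_persistence_length(self):
        """Lp = k b / kBT for the worm-like-chain backbone (500 A at k=87.7)."""
        conf = sample_dna_conformations(100, 400, seed=4,
                                        include_phosphates=False)
        res = persistence_length(conf, max_lag=25)
        assert res.lp == pytest.approx(87.7 * RISE / KBT, rel=0.10)

    def test_persistence_length_linear_in_stiffness(self):
        conf = sample_dna_conformations(100, 400, seed=5,
                                        include_phosphates=False,
                                        k_angle=87.7 / 2)
        res = persistence_length(conf, max_lag=18)
        assert res.lp == pytest.approx(87.7 / 2 * RISE / KBT, rel=0.15)

    def test_full_model_is_stiffer_than_backbone(self):
        """Phosphate-frame coupling adds bending stiffness beyond the
        backbone term, so the full bonded chain is measurably stiffer."""
        conf = sample_dna_conformations(100, 300, seed=6,
                                        include_phosphates=True)
        res = persistence_length(conf[:, :100], max_lag=25)
        assert res.lp > 87.7 * RISE / KBT


class TestRocFromTraj:
    def test_frozen_protein_reproduces_build_geometry(self):
        from bdslide import assemble_system, build_dna, build_protein
        from bdslide.theory import protein_rigid_hydro
        sysm = assemble_system(build_dna(20), build_protein(40, 8))
        prot_idx = [40, 41, 42]
        frames = np.repeat(sysm.positions[None], 4, axis=0)
        traj = Trajectory(np.arange(4) * 1.0, frames)
        h = protein_rigid_hydro(40)
        from bdslide import build_protein as bp
        build_pos = bp(40, 8).positions
        mean, sd = roc_from_traj(traj, prot_idx, h.center_of_diffusion,
                                 build_pos)
        assert 40.0 <= mean <= 50.0
        assert sd == pytest.approx(0.0, abs=1e-9)
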