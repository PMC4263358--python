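"""BD integrator: deterministic limits, free and confined diffusion, protocols."""

import numpy as np
import pytest
from scipy import stats

from bdslide import (Protocol, Restraints, Trajectory, grand_matrix,
                     rk2_step, run_simulation)
from bdslide.constants import KBT, mobility_scale
from bdslide.engine import BlowUpError
from bdslide.fixtures import make_fixture


class TestRk2Step:
    def test_zero_force_zero_noise_is_identity(self, dimer):
        D = grand_matrix(dimer)
        x = dimer.positions.copy()
        x2 = rk2_step(x, D, lambda y: np.zeros_like(y), 0.25,
                      np.random.default_rng(0), noise=np.zeros(6))
        assert np.array_equal(x, x2)

    def test_free_diffusion_msd(self):
        """Single free bead: MSD(t) = 6 D t within a few percent.

        Time-averaged MSD at short lags over three replicas; endpoint-based
        estimators from a single run have too few effective degrees of
        freedom to resolve 3%.
        """
        s = make_fixture("single")
        d_in = mobility_scale() / 20.0
        est = []
        for seed in (11, 12, 13, 14, 15):
            p = Protocol(n_steps=20_000, sample_interval=5, dna_mode=None,
                         hi_mode="free_draining", seed=seed,
                         record_energies=False)
            traj = run_simulation(s, None, p)
            dt = traj.times_ns[1] - traj.times_ns[0]
            for lag in (4, 8, 16):
                d = traj.frames[lag:, 0] - traj.frames[:-lag, 0]
                est.append((d ** 2).sum(axis=1).mean() / (6 * lag * dt))
        assert np.mean(est) == pytest.approx(d_in, rel=0.03)

    def test_harmonic_well_boltzmann_variance(self):
        """Positional variance in a k=1 well equals kBT/k per axis."""
        s = make_fixture("single")
        rest = Restraints.uniform([0], 1.0, s.positions[[0]])
        p = Protocol(n_steps=100_000, sample_interval=20, dna_mode=None,
                     hi_mode="free_draining", seed=5, record_energies=False)
        traj = run_simulation(s, None, p, extra_restraints=rest)
        x = traj.frames[10:, 0]  # discard approach to equilibrium
        var = x.var(axis=0).mean()
        assert var == pytest.approx(KBT, rel=0.05)


class TestRunSimulation:
    def test_frame_count(self, dimer):
        p = Protocol(n_steps=10_000, sample_interval=1_000, dna_mode=None,
                     seed=1, record_energies=False)
        traj = run_simulation(dimer, None, p)
        assert traj.n_frames == 11
        assert np.all(np.diff(traj.times_ns) > 0)

    def test_identical_seeds_bit_identical(self, dna20):
        p = Protocol(n_steps=2_000, sample_interval=500, seed=9,
                     record_energies=False)
        a = run_simulation(dna20, None, p)
        b = run_simulation(dna20, None, p)
        assert np.array_equal(a.frames, b.frames)
        c = run_simulation(dna20, None,
                           Protocol(**{**p.__dict__, "seed": 10}))
        assert not np.array_equal(a.frames, c.frames)

    def test_restrained_dna_stays_near_anchors(self, dna20):
        p = Protocol(n_steps=20_000, sample_interval=500,
                     dna_mode="restrained", seed=2, record_energies=False)
        traj = run_simulation(dna20, None, p)
        dev = np.linalg.norm(traj.frames - dna20.positions, axis=-1)
        # fluctuation scale sqrt(3 kBT / k_r) ~ 1.3 A, never anywhere near 5 A
        assert dev.max() < 5.0
        assert 0.5 < dev[5:].mean() < 2.5

    def test_flexible_mode_restrains_only_termini(self, dna20):
        from bdslide.engine import dna_restraints
        rest = dna_restraints(dna20, "flexible", dna20.positions)
        assert len(rest.indices) == 8  # PB+PP of two residues at each end
        assert np.all(rest.k == 0.01)

    def test_blow_up_reports_step_and_partial_trajectory(self, dimer):
        p = Protocol(n_steps=1_000, sample_interval=100, dna_mode=None,
                     seed=3, max_step_displacement=1e-4,
                     record_energies=False)
        with pytest.raises(BlowUpError) as err:
            run_simulation(dimer, None, p)
        assert err.value.step >= 0
        assert err.value.trajectory is not None

    def test_bond_length_distribution_is_boltzmann(self):
        """Detailed-balance proxy: bond lengths follow r^2 exp(-beta k dr^2/2)."""
        s = make_fixture("dimer")
        from bdslide.model import SystemSpec, Topology
        k, r0 = 2.0, 50.0
        topo = Topology(bonds=np.array([[0, 1]], np.int64),
                        bond_k=np.array([k]), bond_r0=np.array([r0]))
        s = SystemSpec(s.positions, s.sigma, s.stokes, s.charge, s.molecule,
                       s.residue, s.names, topo)
        # relaxation time ~46 steps: sample every 200 steps so draws are
        # effectively independent for the KS test
        p = Protocol(n_steps=400_000, sample_interval=200, dna_mode=None,
                     seed=17, record_energies=False)
        traj = run_simulation(s, None, p)
        r = np.linalg.norm(traj.frames[20:, 0] - traj.frames[20:, 1], axis=1)

        grid = np.linspace(r0 - 4, r0 + 4, 2001)
        pdf = grid ** 2 * np.exp(-0.5 * k * (grid - r0) ** 2 / KBT)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        ks = stats.ks_1samp(r, lambda v: np.interp(v, grid, cdf))
        assert ks.pvalue > 0.01

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.0]), np.zeros((2, 1, 3)))

    def test_energies_recorded(self, dna20):
        p = Protocol(n_steps=1_000, sample_interval=500, seed=4)
        traj = run_simulation(dna20, None, p)
        assert traj.energies.shape == (3, 7)
        assert np.isfinite(traj.energies).all()
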