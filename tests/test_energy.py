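"""Force-field terms: scalar oracles, analytic forces, invariances."""

import numpy as np
import pytest

from bdslide import Bias, ForceFieldParams, Restraints, total_energy_forces
from bdslide.constants import KBT
from bdslide.energy import (InvalidConformationError, SingularGeometryError,
                            angle_energy, bond_energy, electrostatic_energy,
                            excluded_volume_energy, torsion_energy)
from tests.conftest import numerical_forces


class TestScalarTerms:
    @pytest.mark.parametrize("r,k,r0,expected", [
        (41.59, 1.0, 41.59, 0.0),
        (42.59, 1.0, 41.59, 0.5),
        # PP-PB bond: k = 100 kBT/r0^2 displaced by 0.1 A
        (9.073, 100 * KBT / 8.973 ** 2, 8.973, 0.5 * (100 * KBT / 8.973 ** 2) * 0.01),
    ])
    def test_bond(self, r, k, r0, expected):
        assert bond_energy(r, k, r0) == pytest.approx(expected, abs=1e-12)

    def test_bond_rejects_zero_length(self):
        with pytest.raises(SingularGeometryError):
            bond_energy(0.0, 1.0, 1.0)

    @pytest.mark.parametrize("theta,k,theta0,expected", [
        (np.pi / 2, 87.7, np.pi / 2, 0.0),
        (1.0 + 0.1, 87.7, 1.0, 0.4385),
    ])
    def test_angle(self, theta, k, theta0, expected):
        assert angle_energy(theta, k, theta0) == pytest.approx(expected)

    def test_torsion_values_and_wrap(self):
        phi0 = np.deg2rad(36.0)
        assert torsion_energy(phi0, 131.6, phi0) == 0.0
        assert torsion_energy(phi0 + 0.05, 131.6, phi0) == pytest.approx(0.16450)
        # +pi and -pi offsets are the same physical configuration
        assert torsion_energy(phi0 + np.pi, 131.6, phi0) == pytest.approx(
            torsion_energy(phi0 - np.pi, 131.6, phi0))

    def test_excluded_volume_contact(self):
        # PP-PP contact distance 20.8 A from the radii table
        assert excluded_volume_energy(20.8, 10.4, 10.4) == 0.0
        assert excluded_volume_energy(21.8, 10.4, 10.4) == 0.0
        assert excluded_volume_energy(19.8, 10.4, 10.4) == pytest.approx(0.5)

    def test_electrostatic_per_sphere_oracle(self):
        # two PP beads, eps=78.5, Debye length 7.8 A, r=20 A:
        # (332.06/78.5)*4*(e^{0.8974}/1.8974)^2*e^{-2.5641}/20
        v = electrostatic_energy(20.0, -2.0, -2.0, 7.0, 7.0,
                                 size_factor="per_sphere")
        assert v == pytest.approx(0.1088, abs=2e-4)

    def test_electrostatic_limits(self):
        assert electrostatic_energy(15.0, 0.0, 5.0, 7, 8) == 0.0
        # kappa -> 0: bare Coulomb / eps regardless of size factors
        for mode in ("none", "per_sphere", "pair_effective"):
            v = electrostatic_energy(10.0, 1.0, 1.0, 7, 8, eps=78.5,
                                     kappa=0.0, size_factor=mode)
            assert v == pytest.approx(332.06 / 78.5 / 10.0)

    def test_electrostatic_singular(self):
        with pytest.raises(SingularGeometryError):
            electrostatic_energy(0.0, 1.0, 1.0)


class TestTotalEnergyForces:
    def test_forces_match_numerical_gradient(self, mini_system, rng):
        x = mini_system.positions + 0.05 * rng.standard_normal(
            mini_system.positions.shape)
        rep = total_energy_forces(mini_system, x)
        num = numerical_forces(mini_system, x)
        assert np.abs(rep.forces - num).max() < 1e-5

    def test_forces_with_restraints_and_bias(self, mini_system, rng):
        x = mini_system.positions + 0.03 * rng.standard_normal(
            mini_system.positions.shape)
        rest = Restraints.uniform(np.arange(5), 1.0, mini_system.positions[:5])
        bias = Bias.umbrella(40, 10, 5.0, 50.0, plane_bead=40, plane_z=0.0)
        rep = total_energy_forces(mini_system, x, restraints=rest, bias=bias)
        num = numerical_forces(mini_system, x, restraints=rest, bias=bias)
        assert np.abs(rep.forces - num).max() < 1e-5
        assert rep.restraint > 0 and rep.umbrella > 0

    def test_restraint_energy_value(self, dna20):
        x = dna20.positions.copy()
        x[3] += [1.0, 0.0, 0.0]
        rest = Restraints.uniform([3], 1.0, dna20.positions[[3]])
        rep = total_energy_forces(dna20, x, restraints=rest)
        assert rep.restraint == pytest.approx(0.5)

    def test_net_force_and_torque_vanish(self, mini_system, rng):
        x = mini_system.positions + 0.05 * rng.standard_normal(
            mini_system.positions.shape)
        F = total_energy_forces(mini_system, x).forces
        assert np.abs(F.sum(axis=0)).max() < 1e-9
        assert np.abs(np.cross(x, F).sum(axis=0)).max() < 1e-9

    def test_energy_invariant_under_rigid_motion(self, mini_system, rng):
        x = mini_system.positions + 0.05 * rng.standard_normal(
            mini_system.positions.shape)
        e0 = total_energy_forces(mini_system, x).total
        # random rotation + translation
        q = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(q)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        x2 = x @ Q.T + np.array([5.0, -3.0, 11.0])
        e1 = total_energy_forces(mini_system, x2).total
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_total_is_sum_of_terms(self, mini_system):
        rep = total_energy_forces(mini_system, mini_system.positions)
        s = (rep.bond + rep.angle + rep.torsion + rep.excluded +
             rep.electrostatic + rep.restraint + rep.umbrella)
        assert rep.total == pytest.approx(s, abs=1e-12)

    def test_intramolecular_exclusion_rule(self, dna20):
        """Residue pairs closer than 5 apart do not interact nonbonded."""
        # the ideal helix has PP(a)..PP(a+4) inside the 20.8 A contact:
        # only the exclusion rule keeps the strain-free build at zero
        rep = total_energy_forces(dna20, dna20.positions)
        assert rep.excluded == 0.0
        # but intermolecular pairs always interact (protein-DNA attraction)
        from bdslide import assemble_system, build_protein
        sysm = assemble_system(
            __import__("bdslide").build_dna(20), build_protein(40, 8))
        rep2 = total_energy_forces(sysm, sysm.positions)
        assert rep2.electrostatic < -1.0

    def test_invalid_conformation_rejected(self, dna20):
        bad = dna20.positions.copy()
        bad[0, 0] = np.nan
        with pytest.raises(InvalidConformationError):
            total_energy_forces(dna20, bad)
        with pytest.raises(InvalidConformationError):
            total_energy_forces(dna20, dna20.positions[:-1])

    def test_size_factor_modes_are_ordered(self, mini_system):
        """Attraction strength: per_sphere > pair_effective > bare DH."""
        es = {}
        for mode in ("none", "pair_effective", "per_sphere"):
            rep = total_energy_forces(mini_system, mini_system.positions,
                                      ForceFieldParams(elec_size_factor=mode))
            es[mode] = rep.electrostatic
        assert es["per_sphere"] < es["pair_effective"] < es["none"] < 0
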