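import numpy as np
import pytest

from torsiongen import forcefield as ff
from torsiongen import molgraph, molio
from torsiongen.constants import COULOMB_CONSTANT
from torsiongen.errors import ContractError, SingularityError, ValidationError
from torsiongen.molio import (
    AtomRecord,
    BondTerm,
    Conformation,
    ForceFieldParameters,
    MolecularSystem,
    TorsionTerm,
)


def _lj_dimer(r, sigma=0.34, epsilon=0.36):
    atoms = [
        AtomRecord(1, "C1", "C", "LIG", 1, "A", np.zeros(3)),
        AtomRecord(2, "C2", "C", "LIG", 1, "A", np.array([r, 0.0, 0.0])),
    ]
    params = ForceFieldParameters(
        charges=np.zeros(2),
        sigmas=np.full(2, sigma),
        epsilons=np.full(2, epsilon),
        born_radii=np.full(2, 0.2),
    )
    return MolecularSystem(atoms=atoms, bonds=set(), params=params)


class TestBondedEnergies:
    def test_zero_at_equilibrium(self):
        atoms = [
            AtomRecord(1, "C1", "C", "LIG", 1, "A", np.zeros(3)),
            AtomRecord(2, "C2", "C", "LIG", 1, "A", np.array([0.15, 0.0, 0.0])),
        ]
        params = ForceFieldParameters(
            charges=np.zeros(2), sigmas=np.full(2, 0.3),
            epsilons=np.zeros(2), born_radii=np.full(2, 0.2),
            bond_terms=[BondTerm(0, 1, 1000.0, 0.15)],
        )
        sys2 = MolecularSystem(atoms=atoms, bonds={(0, 1)}, params=params)
        b, a, t = ff.bonded_energies(Conformation(sys2.positions()), params)
        assert (b, a, t) == (0.0, 0.0, 0.0)

    def test_bond_displacement_value(self):
        atoms = [
            AtomRecord(1, "C1", "C", "LIG", 1, "A", np.zeros(3)),
            AtomRecord(2, "C2", "C", "LIG", 1, "A", np.array([0.16, 0.0, 0.0])),
        ]
        params = ForceFieldParameters(
            charges=np.zeros(2), sigmas=np.full(2, 0.3),
            epsilons=np.zeros(2), born_radii=np.full(2, 0.2),
            bond_terms=[BondTerm(0, 1, 1000.0, 0.15)],
        )
        b, _, _ = ff.bonded_energies(Conformation(np.array([a.position for a in atoms])), params)
        assert b == pytest.approx(1000.0 * 0.01**2)  # 0.1 kJ/mol

    def test_torsion_maximum_value(self):
        # planar cis quadruple: phi = 0, k_t (1 + cos 0) = 2 k_t
        pos = np.array([[0, 0.1, 0], [0, 0, 0], [0.1, 0, 0], [0.1, 0.1, 0.0]])
        params = ForceFieldParameters(
            charges=np.zeros(4), sigmas=np.full(4, 0.3),
            epsilons=np.zeros(4), born_radii=np.full(4, 0.2),
            torsion_terms=[TorsionTerm(0, 1, 2, 3, 2.0, 1, 0.0)],
        )
        _, _, t = ff.bonded_energies(Conformation(pos), params)
        assert t == pytest.approx(4.0)


class TestLJ:
    def test_zero_at_sigma(self):
        assert ff.lj_energy_regularized(0.34, 0.34, 0.5, 0.0) == pytest.approx(0.0)

    def test_minimum_depth(self):
        r = 2 ** (1 / 6) * 0.34
        assert ff.lj_energy_regularized(r, 0.34, 0.5, 0.0) == pytest.approx(-0.5)

    def test_soft_core_value_at_contact(self):
        sigma, eps = 0.3, 0.7
        val = ff.lj_energy_regularized(0.0, sigma, eps, sigma / 2)
        assert val == pytest.approx(4 * eps * (2**12 - 2**6))

    def test_singularity_without_soft_core(self):
        with pytest.raises(SingularityError):
            ff.lj_energy_regularized(0.0, 0.3, 0.5, 0.0)


class TestCoulomb:
    def test_unit_charges_at_1nm(self):
        assert ff.coulomb_energy(1.0, 1.0, 1.0) == pytest.approx(COULOMB_CONSTANT)

    def test_opposite_charges(self):
        assert ff.coulomb_energy(1.0, 1.0, -1.0) == pytest.approx(-COULOMB_CONSTANT)

    def test_one_four_scaling(self):
        assert ff.coulomb_energy(1.0, 1.0, 1.0, scale=1 / 1.2) == pytest.approx(
            COULOMB_CONSTANT / 1.2
        )

    def test_singular_at_zero(self):
        with pytest.raises(SingularityError):
            ff.coulomb_energy(0.0, 1.0, 1.0)


class TestGeneralizedBorn:
    def test_born_self_energy(self):
        conf = Conformation(np.zeros((1, 3)))
        q, R = 0.8, 0.15
        expected = -(COULOMB_CONSTANT / 2) * (1 - 1 / 78.5) * q * q / R
        assert ff.gb_energy(conf, np.array([q]), np.array([R])) == pytest.approx(expected)

    def test_zero_charges(self):
        conf = Conformation(np.random.default_rng(0).normal(size=(4, 3)))
        assert ff.gb_energy(conf, np.zeros(4), np.full(4, 0.2)) == 0.0

    def test_screened_coulomb_limit(self):
        R = 0.1
        r = 20 * R
        conf = Conformation(np.array([[0, 0, 0], [r, 0, 0.0]]))
        total = ff.gb_energy(conf, np.array([1.0, -1.0]), np.array([R, R]))
        self_term = -COULOMB_CONSTANT * (1 - 1 / 78.5) / R  # two identical selves
        pair = total - self_term
        limit = -COULOMB_CONSTANT * (1 - 1 / 78.5) * (-1.0) / r
        assert pair == pytest.approx(limit, rel=0.01)

    def test_nonpositive_radius_rejected(self):
        conf = Conformation(np.zeros((1, 3)))
        with pytest.raises(ValidationError):
            ff.gb_energy(conf, np.array([1.0]), np.array([0.0]))


class TestPairing:
    def test_butane_classification(self, butane):
        pairing = ff.build_pairing(butane)
        assert (0, 3) in pairing.scaled14
        assert (0, 2) in pairing.excluded
        assert (0, 1) in pairing.excluded
        assert pairing.full == set()

    def test_dimer_no_nonbonded(self):
        atoms = [
            AtomRecord(1, "C1", "C", "LIG", 1, "A", np.zeros(3)),
            AtomRecord(2, "C2", "C", "LIG", 1, "A", np.array([0.15, 0, 0.0])),
        ]
        sys2 = MolecularSystem(atoms=atoms, bonds={(0, 1)})
        pairing = ff.build_pairing(sys2)
        assert pairing.scaled14 == set() and pairing.full == set()

    def test_sets_disjoint_and_cover(self, polyala):
        pairing = ff.build_pairing(polyala)
        n = polyala.n_atoms
        all_pairs = {(i, j) for i in range(n) for j in range(i + 1, n)}
        assert pairing.excluded | pairing.scaled14 | pairing.full == all_pairs
        assert not (pairing.excluded & pairing.scaled14)
        assert not (pairing.excluded & pairing.full)
        assert not (pairing.scaled14 & pairing.full)


class TestTotalEnergy:
    def test_lj_dimer_at_minimum(self):
        sys2 = _lj_dimer(2 ** (1 / 6) * 0.34, epsilon=0.5)
        bd = ff.total_energy(Conformation(sys2.positions()), sys2)
        assert bd.lj == pytest.approx(-0.5)
        assert bd.bond == bd.angle == bd.torsion == 0.0

    def test_total_is_sum_of_terms(self, polyala):
        conf = Conformation(polyala.positions())
        bd = ff.total_energy(conf, polyala)
        assert bd.total == pytest.approx(
            bd.bond + bd.angle + bd.torsion + bd.lj + bd.coulomb + bd.gb, abs=1e-9
        )
        # term-wise recomputation through the standalone operations
        b, a, t = ff.bonded_energies(conf, polyala.params)
        assert (b, a, t) == pytest.approx((bd.bond, bd.angle, bd.torsion), abs=1e-9)
        assert ff.gb_energy(
            conf, polyala.params.charges, polyala.params.born_radii,
            polyala.params.eps_solute, polyala.params.eps_solvent,
        ) == pytest.approx(bd.gb, abs=1e-9)

    def test_rigid_motion_invariance(self, all_fixtures, rng):
        from torsiongen.align import quaternion_to_rotation

        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        R = quaternion_to_rotation(q)
        t = rng.normal(size=3)
        for system in all_fixtures.values():
            conf = Conformation(system.positions())
            moved = Conformation(system.positions() @ R.T + t)
            e0 = ff.total_energy(conf, system, 0.05).total
            e1 = ff.total_energy(moved, system, 0.05).total
            assert e1 == pytest.approx(e0, abs=1e-8)

    def test_finite_for_overlapping_atoms_with_soft_core(self):
        system = molio.make_fixture("chain", 5, 1)
        pos = system.positions()
        pos[4] = pos[0]  # fully overlapping nonbonded pair
        bd = ff.total_energy(Conformation(pos), system, 0.05)
        g = ff.forces(Conformation(pos), system, 0.05).gradient
        assert np.isfinite(bd.total)
        assert np.all(np.isfinite(g))


class TestForces:
    def test_dimer_at_minimum_stationary(self):
        sys2 = _lj_dimer(2 ** (1 / 6) * 0.34)
        g = ff.forces(Conformation(sys2.positions()), sys2).gradient
        assert np.abs(g).max() < 1e-8

    @pytest.mark.parametrize("delta", [0.0, 0.05])
    def test_matches_finite_differences(self, all_fixtures, delta):
        h = 1e-6
        for name, system in all_fixtures.items():
            rng = np.random.default_rng(hash(name) % 2**31)
            for _ in range(5):
                pos = system.positions() + rng.normal(scale=0.01,
                                                      size=(system.n_atoms, 3))
                conf = Conformation(pos)
                g = ff.forces(conf, system, delta).gradient
                fd = np.zeros_like(g)
                for i in range(system.n_atoms):
                    for k in range(3):
                        pp = pos.copy()
                        pp[i, k] += h
                        pm = pos.copy()
                        pm[i, k] -= h
                        fd[i, k] = (
                            ff.total_energy(Conformation(pp), system, delta).total
                            - ff.total_energy(Conformation(pm), system, delta).total
                        ) / (2 * h)
                scale = np.abs(fd).max()
                assert np.abs(g - fd).max() / scale < 1e-4

    def test_translation_and_torque_free(self, polyala, rng):
        pos = polyala.positions() + rng.normal(scale=0.01, size=(polyala.n_atoms, 3))
        g = ff.forces(Conformation(pos), polyala, 0.05).gradient
        assert np.abs(g.sum(axis=0)).max() < 1e-6
        torque = np.cross(pos - pos.mean(axis=0), -g).sum(axis=0)
        assert np.abs(torque).max() < 1e-6


class TestEnergyOfAngles:
    def test_zero_angles_match_input_energy(self, polyala, polyala_topo):
        conf = Conformation(polyala.positions())
        u0 = ff.total_energy(conf, polyala, 0.05).total
        u = ff.energy_of_angles(conf, polyala_topo, np.zeros(polyala_topo.M),
                                polyala, 0.05)
        assert u == pytest.approx(u0)

    def test_angle_gradient_matches_fd(self, polyala, polyala_topo, rng):
        conf = Conformation(polyala.positions())
        angles = rng.uniform(-0.5, 0.5, polyala_topo.M)
        u, du = ff.energy_of_angles(conf, polyala_topo, angles, polyala, 0.05,
                                    gradient=True)
        h = 1e-5
        for j in range(polyala_topo.M):
            e = np.zeros(polyala_topo.M)
            e[j] = h
            fd = (
                ff.energy_of_angles(conf, polyala_topo, angles + e, polyala, 0.05)
                - ff.energy_of_angles(conf, polyala_topo, angles - e, polyala, 0.05)
            ) / (2 * h)
            assert abs(du[j] - fd) / (abs(fd) + 1.0) < 1e-4

    def test_periodic_in_2pi(self, butane, butane_topo):
        conf = Conformation(butane.positions())
        lo = ff.energy_of_angles(conf, butane_topo, [-np.pi], butane, 0.0)
        hi = ff.energy_of_angles(conf, butane_topo, [np.pi - 1e-9], butane, 0.0)
        assert abs(lo - hi) < 1e-6


class TestExternalBridge:
    def test_quadratic_functional(self, rng):
        conf = Conformation(rng.normal(size=(5, 3)))

        def external(x):
            return float(np.sum(x**2)), 2.0 * x

        value, field = ff.external_energy_bridge(conf, external)
        assert value == pytest.approx(np.sum(conf.positions**2))
        np.testing.assert_allclose(field.gradient, 2 * conf.positions)

    def test_zero_force_field(self, rng):
        conf = Conformation(rng.normal(size=(3, 3)))
        value, field = ff.external_energy_bridge(
            conf, lambda x: (42.0, np.zeros_like(x))
        )
        assert value == 42.0
        assert np.all(field.gradient == 0)

    def test_wrong_shape_rejected(self, rng):
        conf = Conformation(rng.normal(size=(3, 3)))
        with pytest.raises(ContractError):
            ff.external_energy_bridge(conf, lambda x: (0.0, np.zeros((2, 3))))
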