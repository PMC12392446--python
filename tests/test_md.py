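import numpy as np
import pytest

from mlmmfe import (AlchemicalState, AtomicSystem, DecoupledMMPotential,
                    LangevinParams, MMPotential, MixedPotential,
                    SwitchProtocol, alchemical_potential, run_md,
                    run_neq_switch)
from mlmmfe.constants import BOLTZMANN_CONSTANT
from mlmmfe.toy import ToyForceField, ToyTopology
from mlmmfe.workflow import movable_mask


class _Harmonic:
    """Single particle tethered to the origin, spring constant k."""

    def __init__(self, k):
        self.k = k

    def energy_forces(self, pos):
        return 0.5 * self.k * float(np.sum(pos ** 2)), -self.k * pos


def _single_atom():
    return AtomicSystem(["C"], [[0.2, 0, 0]], ["QM"], [0.0])


class TestLangevin:
    def test_same_seed_reproduces_trajectory(self, solvated_ligand):
        system, top = solvated_ligand
        pot = MMPotential(system, top)
        p = LangevinParams(1.0, 0.05, 300.0, seed=4)
        t1 = run_md(system, pot, p, 50, stride=10)
        t2 = run_md(system, pot, p, 50, stride=10)
        np.testing.assert_array_equal(t1.positions, t2.positions)

    def test_overdamped_low_t_relaxes_energy(self, solvated_ligand):
        """High friction, near-zero T approaches steepest descent."""
        system, top = solvated_ligand
        distorted = system.positions.copy()
        distorted[:6] *= 1.10  # stretch the ligand
        s = system.with_positions(distorted)
        pot = MMPotential(system, top)
        e0 = pot.energy_forces(distorted)[0]
        p = LangevinParams(0.2, 5.0, 1e-6, seed=0)
        traj = run_md(s, pot, p, 100, stride=100)
        e1 = pot.energy_forces(traj.final_positions)[0]
        assert e1 < e0

    def test_harmonic_equipartition(self):
        """Sampled position variance matches k_B T / k within 5%."""
        k, temp = 50.0, 300.0
        p = LangevinParams(dt=1.0, friction=0.05, temperature=temp, seed=8)
        traj = run_md(_single_atom(), _Harmonic(k), p, 120_000, stride=20)
        var = traj.positions[500:, 0, :].var()
        expected = BOLTZMANN_CONSTANT * temp / k
        assert abs(var - expected) / expected < 0.05

    def test_frozen_atoms_do_not_move(self, complex_fixture):
        system, top = complex_fixture
        pot = MMPotential(system, top)
        mov = movable_mask(top)
        traj = run_md(system, pot, LangevinParams(seed=1), 30, stride=30,
                      movable=mov)
        np.testing.assert_array_equal(traj.final_positions[~mov],
                                      system.positions[~mov])

    def test_nve_energy_conservation_with_ml_forces(self, small_config):
        """Microcanonical drift < 1% of kinetic energy over 1000 steps.

        Frictionless BAOAB is velocity Verlet; driving it with an HDNNP's
        analytic forces checks that predicted forces are the exact gradient
        of the predicted energy at integrator accuracy.
        """
        from mlmmfe import HDNNPModel, partition_regions
        from mlmmfe.constants import ACCEL_UNIT
        from mlmmfe.elements import ATOMIC_MASSES
        from test_nnp import _ALL_ELEMENTS, _make_frames

        model = HDNNPModel(_ALL_ELEMENTS, (6, 6), small_config, init_seed=3)
        model.set_standardization(
            _make_frames(np.random.default_rng(0), small_config))
        system, _ = __import__("mlmmfe").generate_fixtures(
            "solvated_ligand", n_solvent=0, seed=1)

        class MLOnly:
            def energy_forces(self, pos):
                s = system.with_positions(pos)
                return model.predict(s, partition_regions(s, 4.0))

        p = LangevinParams(dt=0.2, friction=0.0, temperature=300.0, seed=9)
        traj = run_md(system, MLOnly(), p, 1000, stride=50)
        m = np.array([ATOMIC_MASSES[e] for e in system.elements])[:, None]
        e_tot = []
        for pos, vel in zip(traj.positions, traj.velocities):
            ke = 0.5 * float(np.sum(m * vel ** 2)) / ACCEL_UNIT
            e_tot.append(MLOnly().energy_forces(pos)[0] + ke)
        ke_scale = 0.5 * float(np.sum(m * traj.velocities[0] ** 2)) / ACCEL_UNIT
        drift = max(e_tot) - min(e_tot)
        assert drift < 0.01 * ke_scale

    def test_nonfinite_force_raises(self):
        class Bad:
            def energy_forces(self, pos):
                return np.nan, np.full_like(pos, np.nan)

        with pytest.raises(FloatingPointError):
            run_md(_single_atom(), Bad(), LangevinParams(seed=0), 5)


class TestAlchemicalPotentials:
    def test_lambda_outside_unit_interval_rejected(self, solvated_ligand):
        system, top = solvated_ligand
        with pytest.raises(ValueError):
            DecoupledMMPotential(system, top, 1.2)
        with pytest.raises(ValueError):
            AlchemicalState(lam=-0.1)

    def test_fully_coupled_matches_plain_mm(self, solvated_ligand):
        system, top = solvated_ligand
        e_mm, f_mm = MMPotential(system, top).energy_forces(system.positions)
        pot = alchemical_potential(AlchemicalState(1.0), system, top)
        e, f = pot.energy_forces(system.positions)
        assert e == pytest.approx(e_mm, rel=1e-12)
        np.testing.assert_allclose(f, f_mm, atol=1e-9)

    def test_decoupled_ligand_sees_no_environment(self, solvated_ligand):
        system, top = solvated_ligand
        pot0 = alchemical_potential(AlchemicalState(0.0), system, top)
        e0, _ = pot0.energy_forces(system.positions)
        # energy must be intra-ligand + environment-environment only
        ff = ToyForceField(top)
        comp = ff.components(system)
        assert e0 == pytest.approx(comp["intra_q"][0] + comp["env"][0],
                                   rel=1e-10)

    def test_softcore_regularizes_overlap(self, solvated_ligand):
        system, top = solvated_ligand
        clash = system.positions.copy()
        clash[6] = clash[0] + [0.05, 0, 0]  # solvent atom inside the ligand
        s = system.with_positions(clash)
        pot = DecoupledMMPotential(system, top, lam=0.05, softcore_alpha=0.5)
        e, f = pot.energy_forces(clash)
        assert np.isfinite(e) and np.all(np.isfinite(f))
        assert abs(e) < 1e7

    def test_mixed_potential_endpoints(self, solvated_ligand):
        system, top = solvated_ligand
        mm = MMPotential(system, top)
        k = _Harmonic(10.0)
        for lam, ref in ((0.0, mm), (1.0, k)):
            mixed = MixedPotential(mm, k, lam)
            e_mix, _ = mixed.energy_forces(system.positions)
            assert e_mix == pytest.approx(
                ref.energy_forces(system.positions)[0])

    def test_decoupling_forces_match_finite_differences(self,
                                                        solvated_ligand):
        system, top = solvated_ligand
        pot = DecoupledMMPotential(system, top, lam=0.4, softcore_alpha=0.5)
        _, f = pot.energy_forces(system.positions)
        h = 1e-6
        for a, x in ((0, 0), (7, 1), (12, 2)):
            p1 = system.positions.copy()
            p2 = system.positions.copy()
            p1[a, x] += h
            p2[a, x] -= h
            fd = -(pot.energy_forces(p1)[0] - pot.energy_forces(p2)[0]) \
                / (2 * h)
            assert abs(fd - f[a, x]) / max(abs(fd), 1.0) < 1e-6


class TestSwitching:
    def test_identical_end_potentials_give_zero_work(self, solvated_ligand):
        system, top = solvated_ligand
        mm = MMPotential(system, top)
        protocol = SwitchProtocol(t_switch=0.01, n_switches=1, n_segments=5)
        rec = run_neq_switch(system.positions, protocol, "forward",
                             lambda lam: MixedPotential(mm, mm, lam),
                             system, LangevinParams(seed=2))
        assert rec.work == pytest.approx(0.0, abs=1e-9)

    def test_instantaneous_switch_is_the_energy_gap(self, solvated_ligand):
        system, top = solvated_ligand
        mm = MMPotential(system, top)
        target = _HarmonicAll()
        protocol = SwitchProtocol(t_switch=0.0, n_switches=1, n_segments=4)
        rec = run_neq_switch(system.positions, protocol, "forward",
                             lambda lam: MixedPotential(mm, target, lam),
                             system, LangevinParams(seed=2))
        gap = (target.energy_forces(system.positions)[0]
               - mm.energy_forces(system.positions)[0])
        assert rec.work == pytest.approx(gap, rel=1e-10)

    def test_backward_runs_reversed_schedule(self, solvated_ligand):
        system, top = solvated_ligand
        mm = MMPotential(system, top)
        target = _HarmonicAll()
        protocol = SwitchProtocol(t_switch=0.0, n_switches=1, n_segments=4)
        fwd = run_neq_switch(system.positions, protocol, "forward",
                             lambda lam: MixedPotential(mm, target, lam),
                             system, LangevinParams(seed=2))
        bwd = run_neq_switch(system.positions, protocol, "backward",
                             lambda lam: MixedPotential(mm, target, lam),
                             system, LangevinParams(seed=2))
        assert bwd.work == pytest.approx(-fwd.work, rel=1e-10)


class _HarmonicAll:
    def energy_forces(self, pos):
        return 0.5 * 3.0 * float(np.sum(pos ** 2)), -3.0 * pos
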