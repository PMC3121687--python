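"""Integrator, bonded forces, neighbor search, diagnostics, barostat."""

import numpy as np
import pytest

from memdpd import (DPDSimulation, ForceFieldParams, InstabilityError,
                    SimulationState, Topology, barostat_area_step,
                    bonded_energy, bonded_forces, build_neighbor_pairs,
                    measure_diagnostics)
from memdpd.builders import LipidSpec, ProteinSpec, build_lipid, build_protein


def _state_from(positions, box=None, species=None):
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if box is None:
        box = np.array([20.0, 20.0, 20.0])
    return SimulationState(
        positions=positions, velocities=np.zeros((n, 3)),
        species=np.zeros(n, dtype=int) if species is None else species,
        molecule_id=np.zeros(n, dtype=int), box=box)


class TestBondedForces:
    def test_bond_at_rest_length_is_force_free(self):
        topo = Topology(bonds=[[0, 1]], bond_params=[[100.0, 0.45]])
        st = _state_from([[5, 5, 5], [5.45, 5, 5]])
        np.testing.assert_allclose(bonded_forces(st, topo), 0.0, atol=1e-12)

    def test_stretched_bond_restores_harmonically(self):
        delta = 0.1
        topo = Topology(bonds=[[0, 1]], bond_params=[[100.0, 0.45]])
        st = _state_from([[5, 5, 5], [5.45 + delta, 5, 5]])
        f = bonded_forces(st, topo)
        assert f[0, 0] == pytest.approx(100.0 * delta)
        np.testing.assert_allclose(f[0], -f[1])

    def test_straight_angle_at_rest_is_force_free(self):
        topo = Topology(angles=[[0, 1, 2]], angle_params=[[20.0, np.pi]])
        st = _state_from([[5, 5, 5], [5.45, 5, 5], [5.9, 5, 5]])
        np.testing.assert_allclose(bonded_forces(st, topo), 0.0, atol=1e-8)

    @pytest.mark.parametrize("builder,spec", [
        (build_lipid, LipidSpec(n_tail=3)),
        (build_lipid, LipidSpec(n_tail=5, species_tag="long")),
        (build_protein, ProteinSpec(side_beads=2, n_hydrophobic_layers=2)),
    ])
    def test_forces_are_exact_gradients(self, builder, spec):
        """Finite differences of the potential match the analytic forces."""
        rng = np.random.default_rng(3)
        mol = builder(spec)
        pos = mol.positions + rng.normal(scale=0.12, size=mol.positions.shape)
        st = _state_from(pos + 10.0, species=mol.species)
        topo = mol.topology
        f = bonded_forces(st, topo)
        eps = 1e-6
        fd = np.zeros_like(f)
        for i in range(pos.shape[0]):
            for k in range(3):
                up = st.copy(); up.positions[i, k] += eps
                dn = st.copy(); dn.positions[i, k] -= eps
                fd[i, k] = -(bonded_energy(up, topo)
                             - bonded_energy(dn, topo)) / (2 * eps)
        np.testing.assert_allclose(f, fd, atol=1e-5 * max(1, np.abs(f).max()))

    def test_isolated_molecule_has_no_net_force_or_torque(self):
        rng = np.random.default_rng(4)
        mol = build_lipid(LipidSpec(n_tail=4))
        pos = mol.positions + rng.normal(scale=0.1, size=mol.positions.shape)
        st = _state_from(pos + 10.0, species=mol.species)
        f = bonded_forces(st, mol.topology)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)
        com = st.positions.mean(axis=0)
        torque = np.cross(st.positions - com, f).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-10)

    def test_invalid_indices_rejected(self):
        topo = Topology(bonds=[[0, 5]], bond_params=[[100.0, 0.45]])
        st = _state_from([[1, 1, 1], [2, 2, 2]])
        with pytest.raises(IndexError):
            bonded_forces(st, topo)


class TestNeighborSearch:
    def test_distant_beads_not_paired(self):
        st = _state_from([[1, 1, 1], [5, 5, 5]], box=np.array([12.0] * 3))
        assert build_neighbor_pairs(st) == set()

    def test_pairs_through_periodic_boundary(self):
        st = _state_from([[0.1, 5, 5], [11.7, 5, 5]], box=np.array([12.0] * 3))
        assert build_neighbor_pairs(st) == {(0, 1)}

    def test_kernel_enumerates_same_pairs_as_brute_force(self, ff):
        """The cell-list force loop touches exactly the brute-force pairs."""
        from memdpd import _kernels
        rng = np.random.default_rng(11)
        n = 500
        box = np.array([8.0, 6.5, 7.0])
        st = _state_from(rng.uniform(0, box, (n, 3)), box=box)
        ref = build_neighbor_pairs(st)
        # conservative-only forces: nonzero exactly for in-range pairs
        f = np.zeros((n, 3)); vir = np.zeros(3)
        _kernels.nonbonded_forces(st.positions, st.velocities, st.species,
                                  st.box, np.full((7, 7), 25.0), 0.0, 0.0,
                                  1.0, 1.0, 0, 0, f, vir)
        f2 = np.zeros((n, 3)); vir2 = np.zeros(3)
        for (i, j) in ref:
            d = st.positions[i] - st.positions[j]
            d -= box * np.round(d / box)
            r = np.linalg.norm(d)
            fm = 25.0 * (1 - r) / r * d
            f2[i] += fm; f2[j] -= fm
        np.testing.assert_allclose(f, f2, atol=1e-10)


class TestIntegrator:
    def test_force_free_streaming_with_wrap(self, ff):
        st = _state_from([[9.5, 5, 5]], box=np.array([10.0] * 3))
        st.velocities[0] = [1.0, 0.0, 0.0]
        sim = DPDSimulation(st, ff, dt=0.1, seed=1)
        sim.step(10)   # travels 1.0, wraps at 10
        assert st.positions[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert st.images[0, 0] == 1

    def test_constant_force_matches_uniform_acceleration(self):
        ff0 = ForceFieldParams(a=np.zeros((7, 7)), gamma=0.0)
        st = _state_from([[5.0, 5.0, 5.0]], box=np.array([100.0] * 3))
        g = np.array([0.3, 0.0, -0.1])
        sim = DPDSimulation(st, ff0, dt=0.02, seed=1,
                            external_force=lambda s: np.tile(g, (1, 1)))
        sim.step(10)
        t = 10 * 0.02
        expected = np.array([5.0, 5.0, 5.0]) + 0.5 * g * t ** 2
        np.testing.assert_allclose(st.unwrapped_positions[0], expected,
                                   atol=1e-9)
        np.testing.assert_allclose(st.velocities[0], g * t, atol=1e-9)

    def test_momentum_conserved_over_thousand_steps(self, ff, fluid_state):
        sim = DPDSimulation(fluid_state, ff, seed=3)
        p0 = fluid_state.velocities.sum(axis=0)
        sim.step(1000)
        drift = np.abs(fluid_state.velocities.sum(axis=0) - p0).max()
        assert drift < 1e-8

    def test_identical_seeds_are_bit_identical(self, ff, fluid_state):
        s1 = fluid_state.copy()
        s2 = fluid_state.copy()
        DPDSimulation(s1, ff, seed=9).step(50)
        DPDSimulation(s2, ff, seed=9).step(50)
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(s1.velocities, s2.velocities)

    def test_different_seeds_diverge(self, ff, fluid_state):
        s1 = fluid_state.copy()
        s2 = fluid_state.copy()
        DPDSimulation(s1, ff, seed=9).step(50)
        DPDSimulation(s2, ff, seed=10).step(50)
        assert not np.allclose(s1.positions, s2.positions)

    def test_instability_names_the_offending_bead(self, ff, fluid_state):
        sim = DPDSimulation(fluid_state, ff, seed=1)
        sim.forces = np.zeros_like(sim.forces)
        sim.forces[17] = np.inf
        with pytest.raises(InstabilityError, match="bead 17"):
            sim.step()

    @pytest.mark.parametrize("kwargs", [dict(dt=0.0), dict(lam=0.0),
                                        dict(lam=1.5)])
    def test_bad_integrator_parameters(self, ff, fluid_state, kwargs):
        with pytest.raises(ValueError):
            DPDSimulation(fluid_state, ff, seed=1, **kwargs)


class TestDiagnostics:
    def test_zero_velocities_zero_temperature(self):
        st = _state_from(np.random.default_rng(0).uniform(1, 9, (50, 3)))
        d = measure_diagnostics(st, np.zeros(3))
        assert d.kinetic_temperature == 0.0

    def test_maxwell_boltzmann_temperature(self):
        rng = np.random.default_rng(12)
        n = 10000
        st = _state_from(rng.uniform(0, 20, (n, 3)))
        st.velocities = rng.normal(size=(n, 3))    # T = 1, m = 1
        d = measure_diagnostics(st, np.zeros(3))
        assert d.kinetic_temperature == pytest.approx(1.0, abs=0.02)

    def test_ideal_gas_has_no_lateral_tension(self):
        """Without interactions the kinetic pressure is isotropic."""
        rng = np.random.default_rng(13)
        tensions = []
        for rep in range(20):
            n = 4000
            st = _state_from(rng.uniform(0, 10, (n, 3)),
                             box=np.array([10.0, 10.0, 10.0]))
            st.velocities = rng.normal(size=(n, 3))
            tensions.append(measure_diagnostics(st, np.zeros(3)).lateral_tension)
        # mean over independent samples ~ 0 within 4 standard errors
        se = np.std(tensions) / np.sqrt(len(tensions))
        assert abs(np.mean(tensions)) < 4 * se


class TestBarostat:
    def _state(self):
        return _state_from(np.random.default_rng(1).uniform(0, 10, (100, 3)),
                           box=np.array([10.0, 10.0, 10.0]))

    def test_zero_tension_leaves_box_unchanged(self):
        st = self._state()
        barostat_area_step(st, tension=0.0)
        np.testing.assert_allclose(st.box, [10.0, 10.0, 10.0])

    def test_positive_tension_shrinks_area_conserving_volume(self):
        st = self._state()
        v0 = np.prod(st.box)
        barostat_area_step(st, tension=5.0)
        assert st.box[0] < 10.0 and st.box[1] < 10.0
        assert np.prod(st.box) == pytest.approx(v0)

    def test_extreme_tension_is_clamped(self):
        st = self._state()
        barostat_area_step(st, tension=1e4)
        assert st.box[0] == pytest.approx(10.0 * 0.99)
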