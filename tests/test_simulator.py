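"""Simulator tests: slab construction, neighbor lists, force consistency,
and the Langevin integrator's statistical mechanics."""

import numpy as np
import pytest
from scipy import stats

from llpsmd.fixtures import langevin_gas
from llpsmd.forcefield import (KB, AVOGADRO_FACTOR, BeadParams,
                               ElectrostaticsParams, build_interaction_table,
                               default_params)
from llpsmd.sequences import ProteinSequence
from llpsmd.simulator import (
    ChainTopology, SimulationConfig, SimulationDivergedError, SystemState,
    build_slab_system, compute_forces, minimize_energy, neighbor_list,
    run_langevin, read_extxyz, write_extxyz,
)


@pytest.fixture(scope="module")
def homopolymer_table():
    f = default_params()["F"]
    bead = BeadParams("F", f.mass, 0.0, f.sigma, 1.0)
    return build_interaction_table([bead], cation_pi_pairs={})


@pytest.fixture(scope="module")
def slab(homopolymer_table):
    topo = ChainTopology.from_sequences(
        [(ProteinSequence("homoF10", "F" * 10), 30)], homopolymer_table)
    state = build_slab_system(topo, homopolymer_table, 0.35, seed=3)
    return topo, state


class TestBuildSlab:
    def test_density_bookkeeping(self, slab, homopolymer_table):
        topo, state = slab
        s = state.box[0]
        slab_volume = s * s * s           # central cube spanning x, y
        placed = topo.total_mass / (slab_volume * AVOGADRO_FACTOR)
        assert placed == pytest.approx(0.35, rel=0.02)
        z = state.positions[:, 2]
        lo, hi = (state.box[2] - s) / 2, (state.box[2] + s) / 2
        assert np.all((z >= lo) & (z <= hi))

    def test_no_overlaps_below_threshold(self, slab, homopolymer_table):
        topo, state = slab
        pairs = neighbor_list(state, 1.0)
        d = state.positions[pairs[:, 0]] - state.positions[pairs[:, 1]]
        d -= state.box * np.rint(d / state.box)
        r = np.linalg.norm(d, axis=1)
        sig = homopolymer_table.pair_sigma[0, 0]
        bonded = np.abs(pairs[:, 0] - pairs[:, 1]) == 1
        same_chain = (topo.chain_id[pairs[:, 0]] == topo.chain_id[pairs[:, 1]])
        nonbonded = ~(bonded & same_chain)
        assert np.all(r[nonbonded] >= 0.7 * sig - 1e-9)

    def test_deterministic_given_seed(self, homopolymer_table):
        topo = ChainTopology.from_sequences(
            [(ProteinSequence("homoF10", "F" * 10), 4)], homopolymer_table)
        s1 = build_slab_system(topo, homopolymer_table, 0.3, seed=42)
        s2 = build_slab_system(topo, homopolymer_table, 0.3, seed=42)
        assert np.array_equal(s1.positions, s2.positions)

    def test_infeasible_density_rejected(self, homopolymer_table):
        topo = ChainTopology.from_sequences(
            [(ProteinSequence("homoF10", "F" * 10), 12)], homopolymer_table)
        with pytest.raises(ValueError):
            build_slab_system(topo, homopolymer_table, 5.0, seed=0)

    def test_density_equals_placed_mass_over_slab_volume(self, slab):
        topo, state = slab
        s = state.box[0]
        assert topo.total_mass / (s ** 3 * AVOGADRO_FACTOR) == pytest.approx(
            0.35, rel=0.02)


class TestNeighborList:
    def test_dilute_cluster_large_cutoff_lists_all_pairs(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(4.0, 6.0, size=(10, 3))   # 2-nm blob, 12-nm box
        state = SystemState(pos, np.zeros_like(pos), np.array([12.0] * 3))
        pairs = neighbor_list(state, 5.0)
        assert len(pairs) == 10 * 9 // 2

    def test_list_energy_equals_brute_force(self, table, toy_mixed_system):
        topo, state = toy_mixed_system
        ep = ElectrostaticsParams()
        listed = compute_forces(state, topo, table, ep)
        all_pairs = np.array([(i, j) for i in range(topo.n_beads)
                              for j in range(i + 1, topo.n_beads)],
                             dtype=np.int64)
        from llpsmd.simulator import _bonded_pair_mask
        all_pairs = all_pairs[_bonded_pair_mask(all_pairs, topo.bonds,
                                                topo.n_beads)]
        brute = compute_forces(state, topo, table, ep, pairs=all_pairs)
        assert listed.total_energy == pytest.approx(brute.total_energy,
                                                    abs=1e-10)
        assert np.allclose(listed.forces, brute.forces, atol=1e-10)

    def test_empty_system(self):
        state = SystemState(np.empty((0, 3)), np.empty((0, 3)),
                            np.array([5.0, 5.0, 5.0]))
        assert len(neighbor_list(state, 1.0)) == 0

    def test_cutoff_exceeding_half_box_rejected(self):
        _, state, _ = langevin_gas(n_beads=5, box=6.0, seed=0)
        with pytest.raises(ValueError):
            neighbor_list(state, 2.9, 0.2)


class TestComputeForces:
    def test_bonded_pair_at_r0_has_zero_force(self, aa_params):
        t = build_interaction_table([aa_params["G"]], cation_pi_pairs={})
        topo = ChainTopology.from_sequences(
            [(ProteinSequence("gg", "GG"), 1)], t)
        r0 = topo.bond_r0[0]
        pos = np.array([[4.0, 4.0, 4.0], [4.0, 4.0, 4.0 + r0]])
        state = SystemState(pos, np.zeros_like(pos), np.array([8.0] * 3))
        res = compute_forces(state, topo, t)
        assert res.energies["bond"] == pytest.approx(0.0, abs=1e-12)
        # only the (continuous, repulsive-free at r0 > 2^(1/6) sigma?) AH term
        # remains; bond contribution itself is zero
        bond_only = ChainTopology.from_sequences(
            [(ProteinSequence("gg", "GG"), 1)], t)
        assert np.abs(res.forces.sum(axis=0)).max() < 1e-9

    def test_newtons_third_law(self, table, toy_mixed_system):
        topo, state = toy_mixed_system
        res = compute_forces(state, topo, table, ElectrostaticsParams())
        assert np.abs(res.forces.sum(axis=0)).max() <= 1e-9

    def test_forces_match_finite_differences(self, table, toy_mixed_system):
        topo, state = toy_mixed_system
        ep = ElectrostaticsParams()
        res = compute_forces(state, topo, table, ep)
        h = 1e-6
        rng = np.random.default_rng(0)
        for i in rng.choice(topo.n_beads, size=8, replace=False):
            for k in range(3):
                sp, sm = state.copy(), state.copy()
                sp.positions[i, k] += h
                sm.positions[i, k] -= h
                fnum = -(compute_forces(sp, topo, table, ep).total_energy
                         - compute_forces(sm, topo, table, ep).total_energy
                         ) / (2 * h)
                scale = max(1.0, abs(res.forces[i, k]))
                assert abs(fnum - res.forces[i, k]) / scale <= 1e-5

    def test_translation_and_rotation_invariance(self, table,
                                                 toy_mixed_system):
        topo, state = toy_mixed_system
        ep = ElectrostaticsParams()
        e0 = compute_forces(state, topo, table, ep).total_energy
        shifted = state.copy()
        shifted.positions = shifted.positions + np.array([1.3, -0.7, 2.1])
        e1 = compute_forces(shifted, topo, table, ep).total_energy
        assert abs(e1 - e0) / abs(e0) <= 1e-9
        # rigid rotation about the box center (configuration must stay
        # compact enough that periodic images do not change)
        theta = 0.3
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        center = np.array([4.0, 4.0, 4.0])
        rotated = state.copy()
        rotated.positions = (state.positions - center) @ rot.T + center
        e2 = compute_forces(rotated, topo, table, ep).total_energy
        assert abs(e2 - e0) / abs(e0) <= 1e-9

    def test_nonfinite_coordinates_rejected(self, table, toy_mixed_system):
        topo, state = toy_mixed_system
        bad = state.copy()
        bad.positions[0, 0] = np.nan
        with pytest.raises(ValueError):
            compute_forces(bad, topo, table)


class TestLangevin:
    def test_equipartition_free_bead(self):
        # velocity variance of a free bead must equal kBT/m per component
        topo, state, t = langevin_gas(n_beads=64, mass=80.0, box=25.0, seed=5)
        cfg = SimulationConfig(timestep=0.02, friction=1.0, temperature=300.0,
                               n_steps=30000, save_interval=30, seed=6)
        traj, _ = run_langevin(state, topo, cfg, t)
        t_mean = traj.kinetic_temperature[20:].mean()
        assert t_mean == pytest.approx(300.0, rel=0.03)

    def test_nve_limit_conserves_energy(self, aa_params):
        # friction -> 0 reduces BAOAB to velocity Verlet: bounded energy error
        t = build_interaction_table([aa_params["G"]], cation_pi_pairs={})
        topo = ChainTopology.from_sequences(
            [(ProteinSequence("gg", "GG"), 1)], t)
        pos = np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0 + topo.bond_r0[0] + 0.02]])
        state = SystemState(pos, np.zeros((2, 3)), np.array([10.0] * 3))
        cfg = SimulationConfig(timestep=0.001, friction=0.0, temperature=300.0,
                               n_steps=100000, save_interval=500, seed=1)
        traj, _ = run_langevin(state, topo, cfg, t)
        total = (1.5 * topo.n_beads * KB * traj.kinetic_temperature
                 + sum(traj.energies.values()))
        assert (total.max() - total.min()) / abs(total.mean()) <= 1e-4

    def test_identical_seeds_identical_trajectories(self):
        topo, state, t = langevin_gas(n_beads=20, box=15.0, seed=2)
        cfg = SimulationConfig(n_steps=500, save_interval=100, seed=9)
        t1, _ = run_langevin(state, topo, cfg, t)
        t2, _ = run_langevin(state, topo, cfg, t)
        assert np.array_equal(t1.positions, t2.positions)

    def test_thermostat_unbiased_across_seeds(self):
        # mean kinetic temperature over 5 seeds: t-test against target
        topo, state, t = langevin_gas(n_beads=40, mass=100.0, box=20.0, seed=3)
        means = []
        for seed in range(5):
            cfg = SimulationConfig(timestep=0.02, friction=1.0,
                                   temperature=250.0, n_steps=8000,
                                   save_interval=40, seed=seed)
            traj, _ = run_langevin(state, topo, cfg, t)
            means.append(traj.kinetic_temperature[20:].mean())
        _, p = stats.ttest_1samp(means, 250.0)
        assert p > 0.01

    def test_divergence_aborts_with_diagnostic(self):
        topo, state, t = langevin_gas(n_beads=4, box=12.0, seed=0)
        state.velocities[:] = 1e4
        cfg = SimulationConfig(timestep=0.01, friction=0.0, n_steps=10,
                               save_interval=10, seed=0)
        with pytest.raises(SimulationDivergedError):
            run_langevin(state, topo, cfg, t)

    def test_momentum_conserved_with_pair_forces_only(self, slab,
                                                      homopolymer_table):
        topo, state = slab
        res = compute_forces(state, topo, homopolymer_table)
        assert np.abs(res.forces.sum(axis=0)).max() <= 1e-9


class TestMinimize:
    def test_reduces_energy(self, slab, homopolymer_table):
        topo, state = slab
        e0 = compute_forces(state, topo, homopolymer_table).total_energy
        relaxed = minimize_energy(state, topo, homopolymer_table, n_steps=100)
        e1 = compute_forces(relaxed, topo, homopolymer_table).total_energy
        assert e1 < e0


class TestTrajectoryIO:
    def test_extxyz_roundtrip(self, homopolymer_table, tmp_path):
        topo = ChainTopology.from_sequences(
            [(ProteinSequence("homoF10", "F" * 10), 30)], homopolymer_table)
        state = build_slab_system(topo, homopolymer_table, 0.35, seed=1)
        cfg = SimulationConfig(n_steps=100, save_interval=50, seed=4)
        traj, _ = run_langevin(state, topo, cfg, homopolymer_table)
        path = tmp_path / "t.extxyz"
        write_extxyz(traj, path)
        back = read_extxyz(path)
        assert back.n_frames == traj.n_frames
        assert np.allclose(back.positions, traj.positions, atol=1e-6)
        assert np.allclose(back.pressure, traj.pressure, rtol=1e-6)
        assert np.allclose(back.times, traj.times)
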