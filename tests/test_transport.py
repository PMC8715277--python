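"""Transport-observable tests: Rg statistics, MSD/diffusion, Green-Kubo
relaxation modulus, Maxwell-mode fits and viscosity."""

import numpy as np
import pytest

from llpsmd.fixtures import langevin_gas, stress_series
from llpsmd.forcefield import KB
from llpsmd.simulator import (ChainTopology, SimulationConfig, Trajectory,
                              run_langevin)
from llpsmd.transport import (
    MSD, NoDiffusiveRegimeError, diffusion_coefficient, fit_maxwell_modes,
    msd, radius_of_gyration, relaxation_modulus, rg_distribution, viscosity,
    VISCOSITY_UNIT,
)


def _single_chain_traj(positions_frames, masses, box=50.0):
    pos = np.asarray(positions_frames, dtype=float)
    f, n, _ = pos.shape
    topo = ChainTopology(
        codes=["A"] * n, type_index=np.zeros(n, dtype=np.int64),
        chain_id=np.zeros(n, dtype=np.int64), mass=np.asarray(masses, float),
        charge=np.zeros(n), lam_scale=np.ones(n),
        bonds=np.empty((0, 2), dtype=np.int64), bond_pref=np.empty(0),
        bond_r0=np.empty(0), chain_species=["chain"],
        chain_slices=[(0, n)])
    return Trajectory(positions=pos, times=np.arange(f, dtype=float),
                      box=np.array([box] * 3), pressure=np.zeros((f, 3, 3)),
                      energies={}, kinetic_temperature=np.zeros(f),
                      topology=topo)


class TestRadiusOfGyration:
    def test_coincident_beads_give_zero(self):
        pos = np.zeros((5, 3))
        assert radius_of_gyration(pos, np.ones(5)) == 0.0

    def test_two_equal_masses_at_distance_d(self):
        d = 1.4
        pos = np.array([[0.0, 0, 0], [d, 0, 0]])
        assert radius_of_gyration(pos, np.ones(2)) == pytest.approx(d / 2)

    def test_ideal_chain_mean_square_rg(self):
        # freely jointed chain: <Rg^2> ~ N b^2 / 6
        rng = np.random.default_rng(13)
        n, b, reps = 100, 0.38, 1000
        rgs2 = []
        for _ in range(reps):
            steps = rng.normal(size=(n - 1, 3))
            steps *= b / np.linalg.norm(steps, axis=1)[:, None]
            pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
            rgs2.append(radius_of_gyration(pos, np.ones(n)) ** 2)
        assert np.mean(rgs2) == pytest.approx(n * b * b / 6, rel=0.05)

    def test_wrapped_chain_detected(self):
        frames = np.zeros((2, 3, 3))
        frames[:, 1, 0] = 30.0      # bond longer than half the box
        traj = _single_chain_traj(frames, np.ones(3))
        with pytest.raises(ValueError, match="wrap"):
            rg_distribution(traj, bins=5)

    def test_histogram_normalized(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(scale=0.5, size=(40, 8, 3)) + 10.0
        traj = _single_chain_traj(frames, np.ones(8))
        h = rg_distribution(traj, bins=10)
        width = h.bin_centers[1] - h.bin_centers[0]
        assert np.sum(h.density) * width == pytest.approx(1.0, abs=1e-6)


class TestMSD:
    def test_immobile_particles_give_zero(self):
        frames = np.broadcast_to(np.arange(9.0).reshape(3, 3),
                                 (20, 3, 3)).copy() + 5
        topo_traj = _single_chain_traj(frames, np.ones(3))
        m = msd(topo_traj, remove_drift=False)
        assert np.allclose(m.msd, 0.0, atol=1e-10)   # FFT roundoff only
        assert abs(m.msd[0]) < 1e-10

    def test_uniform_motion_is_ballistic(self):
        v = np.array([0.3, 0.0, 0.0])
        frames = np.array([np.zeros((1, 3)) + v * t for t in range(30)]) + 10
        traj = _single_chain_traj(frames, np.ones(1))
        m = msd(traj, remove_drift=False)
        assert np.allclose(m.msd, (0.3 * m.times) ** 2, rtol=1e-10)

    def test_single_frame_rejected(self):
        traj = _single_chain_traj(np.zeros((1, 2, 3)), np.ones(2))
        with pytest.raises(ValueError):
            msd(traj)


class TestDiffusion:
    def test_exact_linear_msd_returns_d0(self):
        t = np.arange(200, dtype=float)
        d0 = 0.05
        m = MSD(times=t, msd=6 * d0 * t)
        d, err, _ = diffusion_coefficient(m)
        assert d == pytest.approx(d0, rel=1e-12)

    def test_ballistic_input_signals_no_regime(self):
        t = np.arange(100, dtype=float)
        m = MSD(times=t, msd=0.1 * t ** 2)
        with pytest.raises(NoDiffusiveRegimeError):
            diffusion_coefficient(m)

    def test_langevin_gas_matches_einstein_relation(self):
        # overdamped beads: D = kB T / (m gamma)
        topo, state, table = langevin_gas(n_beads=100, mass=100.0, box=30.0,
                                          seed=1)
        gamma_f = 0.5
        cfg = SimulationConfig(timestep=0.02, friction=gamma_f,
                               temperature=300.0, n_steps=100000,
                               save_interval=20, seed=4)
        traj, _ = run_langevin(state, topo, cfg, table)
        m = msd(traj, species="gas")
        d, err, _ = diffusion_coefficient(m, fit_window=(25, 150))
        d0 = KB * 300.0 / (100.0 * gamma_f)
        assert d == pytest.approx(d0, rel=0.03)


class TestRelaxationModulus:
    def test_white_noise_decays_to_zero(self):
        rng = np.random.default_rng(6)
        p = rng.standard_normal((20000, 3, 3)) * 0.01
        p = (p + p.transpose(0, 2, 1)) / 2
        mod = relaxation_modulus(p, temperature=300.0, volume=1000.0, dt=1.0,
                                 max_lag=100)
        assert np.abs(mod.g[5:]).max() < 0.05 * mod.g[0]

    def test_g0_equals_stress_variance_identity(self):
        rng = np.random.default_rng(7)
        p = np.zeros((5000, 3, 3))
        xy = rng.standard_normal(5000) * 0.02
        p[:, 0, 1] = p[:, 1, 0] = xy
        v, t = 800.0, 250.0
        mod = relaxation_modulus(p, temperature=t, volume=v, dt=1.0,
                                 max_lag=10)
        # only one of five averaged components carries variance
        expected = v / (KB * t) * np.var(xy) / 5
        assert mod.g[0] == pytest.approx(expected, rel=1e-6)

    def test_ou_fixture_matches_closed_form(self):
        g0, tau = 0.02, 50.0
        series = stress_series([(g0, tau)], 300.0, 1000.0, 400000, 1.0,
                               seed=3)
        mod = relaxation_modulus(series, temperature=300.0, volume=1000.0,
                                 dt=1.0, max_lag=int(3 * tau))
        target = g0 * np.exp(-mod.times / tau)
        mask = mod.times <= 3 * tau
        assert np.allclose(mod.g[mask], target[mask], atol=0.05 * g0)

    def test_short_series_rejected(self):
        p = np.zeros((50, 3, 3))
        with pytest.raises(ValueError):
            relaxation_modulus(p, temperature=300.0, volume=1.0, dt=1.0,
                               max_lag=40)


class TestMaxwellFit:
    def test_single_mode_recovered_within_one_percent(self):
        g0, tau = 0.02, 50.0
        t = np.arange(0, 500.0, 1.0)
        mod = type("M", (), {})()
        from llpsmd.transport import RelaxationModulus
        mod = RelaxationModulus(times=t, g=g0 * np.exp(-t / tau),
                                temperature=300.0, volume=1000.0)
        fit = fit_maxwell_modes(mod, n_modes=1)
        assert len(fit.modes) == 1
        assert fit.modes[0].g == pytest.approx(g0, rel=0.01)
        assert fit.modes[0].tau == pytest.approx(tau, rel=0.01)

    def test_two_separated_modes_with_noise(self):
        from llpsmd.transport import RelaxationModulus
        rng = np.random.default_rng(10)
        modes = [(0.03, 5.0), (0.01, 500.0)]
        t = np.arange(0, 3000.0, 0.5)
        g = sum(gi * np.exp(-t / ti) for gi, ti in modes)
        g = g * (1 + 0.02 * rng.standard_normal(len(t)))
        mod = RelaxationModulus(times=t, g=g, temperature=300.0, volume=1000.0)
        fit = fit_maxwell_modes(mod, n_modes=2)
        taus = sorted(m.tau for m in fit.modes)
        assert taus[0] == pytest.approx(5.0, rel=0.10)
        assert taus[-1] == pytest.approx(500.0, rel=0.10)

    def test_fit_monotone_for_single_mode(self):
        from llpsmd.transport import RelaxationModulus
        t = np.arange(0, 300.0, 1.0)
        mod = RelaxationModulus(times=t, g=0.05 * np.exp(-t / 30.0),
                                temperature=300.0, volume=1.0)
        fit = fit_maxwell_modes(mod, n_modes=1)
        curve = fit.g_fit(t)
        assert curve[0] >= 0
        assert np.all(np.diff(curve) <= 1e-12)

    def test_all_zero_input_rejected(self):
        from llpsmd.transport import RelaxationModulus
        mod = RelaxationModulus(times=np.arange(10.0), g=np.zeros(10),
                                temperature=300.0, volume=1.0)
        with pytest.raises(ValueError):
            fit_maxwell_modes(mod)


class TestViscosity:
    def _modulus_with_modes(self, modes):
        from llpsmd.transport import MaxwellMode, RelaxationModulus
        t = np.arange(0, 5000.0, 1.0)
        g = sum(gi * np.exp(-t / ti) for gi, ti in modes)
        mod = RelaxationModulus(times=t, g=g, temperature=300.0, volume=1.0,
                                modes=[MaxwellMode(gi, ti)
                                       for gi, ti in modes])
        return mod

    def test_single_mode_analytic_integral(self):
        mod = self._modulus_with_modes([(0.02, 50.0)])
        eta, _ = viscosity(mod)
        assert eta == pytest.approx(0.02 * 50.0 * VISCOSITY_UNIT, rel=1e-12)

    def test_two_modes_linearity(self):
        mod = self._modulus_with_modes([(0.02, 50.0), (0.005, 500.0)])
        eta, _ = viscosity(mod)
        assert eta == pytest.approx(
            (0.02 * 50 + 0.005 * 500) * VISCOSITY_UNIT, rel=1e-12)

    def test_mode_sum_matches_trapezoid_of_fit(self):
        # window spans >= 5x the longest tau: integral and sum agree to 1%
        mod = self._modulus_with_modes([(0.02, 50.0), (0.005, 500.0)])
        eta, _ = viscosity(mod)
        integral = np.trapezoid(mod.g_fit(mod.times), mod.times)
        assert eta == pytest.approx(integral * VISCOSITY_UNIT, rel=0.01)

    def test_no_fit_rejected(self):
        from llpsmd.transport import RelaxationModulus
        mod = RelaxationModulus(times=np.arange(10.0), g=np.ones(10),
                                temperature=300.0, volume=1.0)
        with pytest.raises(ValueError):
            viscosity(mod)

    def test_stokes_einstein_coherence_across_interaction_strengths(self):
        """At fixed density, strengthening cohesion must raise viscosity and
        slow diffusion together: Spearman rank correlation of η and 1/D
        above 0.8 across a series of bulk melts."""
        from scipy import stats
        from llpsmd.forcefield import BeadParams, build_interaction_table, default_params
        from llpsmd.sequences import ProteinSequence
        from llpsmd.simulator import (ChainTopology, build_slab_system,
                                      minimize_energy)

        f = default_params()["F"]
        etas, dinvs = [], []
        for eps in (0.3, 0.8368, 1.6, 2.4, 3.2):
            bead = BeadParams("F", f.mass, 0.0, f.sigma, 1.0)
            table = build_interaction_table([bead], epsilon=eps,
                                            cation_pi_pairs={})
            topo = ChainTopology.from_sequences(
                [(ProteinSequence("c6", "F" * 6), 56)], table)
            state = build_slab_system(topo, table, 0.55, box_aspect=1.0,
                                      seed=3)
            state = minimize_energy(state, topo, table)
            eq = SimulationConfig(timestep=0.01, friction=1.0,
                                  temperature=300.0, n_steps=3000,
                                  save_interval=3000, seed=4)
            _, state = run_langevin(state, topo, eq, table)
            cfg = SimulationConfig(timestep=0.01, friction=0.1,
                                   temperature=300.0, n_steps=25000,
                                   save_interval=5, seed=5)
            traj, _ = run_langevin(state, topo, cfg, table)
            mod = relaxation_modulus(traj, temperature=300.0)
            eta, _ = viscosity(fit_maxwell_modes(mod, n_modes=4))
            d, _, _ = diffusion_coefficient(msd(traj, species="c6"))
            etas.append(eta)
            dinvs.append(1.0 / d)
        rho = stats.spearmanr(etas, dinvs).statistic
        assert rho > 0.8

    def test_ou_fixture_within_seven_percent_of_closed_form(self):
        modes = [(0.02, 50.0)]
        series = stress_series(modes, 300.0, 1000.0, 400000, 0.5, seed=5)
        mod = relaxation_modulus(series, temperature=300.0, volume=1000.0,
                                 dt=0.5, max_lag=2000)
        fit = fit_maxwell_modes(mod, n_modes=2)
        eta, err = viscosity(fit)
        target = 0.02 * 50.0 * VISCOSITY_UNIT
        assert eta == pytest.approx(target, rel=0.07)
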