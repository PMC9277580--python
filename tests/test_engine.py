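import numpy as np
import pytest
from scipy import stats as sps

import milestonekit as mk


class TestReflectOnCrossing:
    def test_velocity_sign_flip(self):
        prev = mk.State(np.array([0.1, 0.2]), np.array([1.0, -2.0]))
        crossed = mk.State(np.array([0.2, 0.3]), np.array([1.1, -2.1]))
        out = mk.reflect_on_crossing(prev, crossed)
        assert np.array_equal(out.positions, prev.positions)
        assert np.array_equal(out.velocities, np.array([-1.0, 2.0]))

    def test_zero_velocity_fixed_point(self):
        prev = mk.State(np.array([0.1]), np.array([0.0]))
        out = mk.reflect_on_crossing(prev, mk.State(np.array([0.2]), np.array([0.5])))
        assert np.array_equal(out.velocities, np.array([0.0]))

    def test_involution(self):
        prev = mk.State(np.array([0.3]), np.array([1.7]))
        once = mk.reflect_on_crossing(prev, mk.State(np.array([0.4]), np.array([1.8])))
        twice = mk.reflect_on_crossing(once, prev)
        assert np.array_equal(twice.velocities, prev.velocities)

    def test_overdamped_states_have_no_velocities(self):
        out = mk.reflect_on_crossing(mk.State(np.array([0.3])), mk.State(np.array([0.4])))
        assert out.velocities is None


class TestMMVTRun:
    def test_zero_duration_empty_log(self, linear_chain, flat_potential, overdamped_params):
        log = mk.mmvt_run(linear_chain, 0, flat_potential, overdamped_params, duration_ps=0.0)
        assert log.n_collisions == 0
        assert log.total_time_ps == 0.0

    def test_start_outside_cell_errors(self, linear_chain, flat_potential, overdamped_params):
        with pytest.raises(ValueError, match="not strictly inside"):
            mk.mmvt_run(
                linear_chain, 0, flat_potential, overdamped_params, 1.0, x0=np.array([2.5])
            )
        # exactly on a boundary counts as crossed, hence not strictly inside
        with pytest.raises(ValueError, match="not strictly inside"):
            mk.mmvt_run(
                linear_chain, 0, flat_potential, overdamped_params, 1.0, x0=np.array([1.0])
            )

    def test_seed_determinism(self, linear_chain, flat_potential, overdamped_params):
        a = mk.mmvt_run(linear_chain, 1, flat_potential, overdamped_params, 20.0, seed=5)
        b = mk.mmvt_run(linear_chain, 1, flat_potential, overdamped_params, 20.0, seed=5)
        assert np.array_equal(a.milestones, b.milestones)
        assert np.array_equal(a.times_ps, b.times_ps)
        c = mk.mmvt_run(linear_chain, 1, flat_potential, overdamped_params, 20.0, seed=6)
        assert not np.array_equal(a.times_ps, c.times_ps)

    def test_confinement_invariant(self, linear_chain, overdamped_params):
        pot = mk.HarmonicPotential(k=1.0, center=(0.0,))
        log = mk.mmvt_run(
            linear_chain, 1, pot, overdamped_params, 50.0, seed=2, traj_stride=50
        )
        lo, hi = linear_chain.cell_bounds(1)
        assert log.trajectory is not None
        assert np.all(log.trajectory[:, 0] >= lo)
        assert np.all(log.trajectory[:, 0] <= hi)

    def test_flat_cell_boundary_symmetry(self, flat_potential):
        """Flat potential, symmetric cell: equal collision rates (3 SE)."""
        model = mk.build_linear_model([0.0, 1.0, 2.0])
        params = mk.DynamicsParams(
            timestep_ps=1e-4, temperature_K=298.15, diffusion_A2_per_ps=1.0, seed=0
        )
        log = mk.mmvt_run(model, 0, flat_potential, params, duration_ps=400.0, seed=8)
        stats = mk.aggregate(log)
        n_lo, n_hi = stats.collision_totals[0], stats.collision_totals[1]
        # collision counts cluster in bursts: standard error from the number
        # of distinct boundary visits (cross-transitions), not raw counts
        n_visits = sum(stats.transition_counts.values()) + 2
        se = (n_lo + n_hi) / np.sqrt(n_visits)
        assert abs(n_lo - n_hi) < 3 * se

    def test_harmonic_collision_ratio_vs_brute_force(self):
        """Boundary collision-rate ratio matches a 10x-longer plain run."""
        from milestonekit._kernels import overdamped_trajectory

        k, kT, D, dt = 0.5, 0.5925, 1.0, 1e-4
        model = mk.build_linear_model([1.0, 2.0, 3.0])
        params = mk.DynamicsParams(
            timestep_ps=dt, temperature_K=298.15, diffusion_A2_per_ps=D, seed=0
        )
        pot = mk.HarmonicPotential(k=k, center=(0.0,))
        log = mk.mmvt_run(model, 0, pot, params, duration_ps=600.0, seed=3)
        stats = mk.aggregate(log)
        ratio_mmvt = stats.collision_totals[0] / stats.collision_totals[1]

        traj, _ = overdamped_trajectory(
            np.array([1.5]), pot.kind_code, pot.params_array(), D, kT, dt,
            60_000_000, 12345, 1,
        )
        x = traj[:, 0]
        down_1 = int(np.sum((x[:-1] > 1.0) & (x[1:] <= 1.0)))
        up_2 = int(np.sum((x[:-1] < 2.0) & (x[1:] >= 2.0)))
        ratio_brute = down_1 / up_2
        # Boltzmann check of the oracle itself: ratio = exp(-beta (U(1)-U(2)))
        assert ratio_brute == pytest.approx(np.exp((0.5 * k * (4 - 1)) / kT), rel=0.2)
        assert ratio_mmvt == pytest.approx(ratio_brute, rel=0.2)

    def test_equilibrium_histogram_in_harmonic_cell(self):
        """Confined MMVT sampling reproduces the cell-restricted Boltzmann law.

        KS distance against the truncated-Gaussian CDF, with the tolerance
        calibrated on an unconfined brute-force run of equal length.
        """
        from milestonekit._kernels import overdamped_trajectory

        k, kT, D, dt = 2.0, 0.5925, 1.0, 1e-4
        model = mk.build_linear_model([1.0, 2.0, 3.0])
        params = mk.DynamicsParams(
            timestep_ps=dt, temperature_K=298.15, diffusion_A2_per_ps=D, seed=0
        )
        pot = mk.HarmonicPotential(k=k, center=(0.0,))
        duration = 2000.0
        log = mk.mmvt_run(
            model, 0, pot, params, duration, seed=4, traj_stride=10_000
        )  # one sample per ps >> the 0.3 ps relaxation time
        x_mmvt = log.trajectory[:, 0]

        sigma = np.sqrt(kT / k)
        trunc = sps.truncnorm(1.0 / sigma, 2.0 / sigma, loc=0.0, scale=sigma)
        ks_mmvt = sps.kstest(x_mmvt, trunc.cdf).statistic

        traj, _ = overdamped_trajectory(
            np.array([1.5]), pot.kind_code, pot.params_array(), D, kT, dt,
            int(duration / dt), 999, 10_000,
        )
        x_brute = traj[(traj[:, 0] >= 1.0) & (traj[:, 0] <= 2.0), 0]
        ks_brute = sps.kstest(x_brute, trunc.cdf).statistic if x_brute.size >= 5 else 1.0
        assert ks_mmvt < max(0.06, ks_brute)

    def test_langevin_confinement_and_equilibrium(self):
        model = mk.build_linear_model([-2.0, 0.0, 2.0])
        params = mk.DynamicsParams(
            timestep_ps=2e-3, temperature_K=298.15, friction_per_ps=5.0, mass_amu=12.0, seed=0
        )
        pot = mk.HarmonicPotential(k=2.0, center=(0.0,))
        log = mk.mmvt_run(model, 0, pot, params, 400.0, seed=9, traj_stride=50)
        x = log.trajectory[:, 0]
        assert np.all(x >= -2.0) and np.all(x <= 0.0)
        # left half of a centred Gaussian: E[x] = -sigma*sqrt(2/pi)
        sigma = np.sqrt(0.5925 / 2.0)
        assert x.mean() == pytest.approx(-sigma * np.sqrt(2 / np.pi), abs=0.05)


class TestElberRun:
    def test_single_neighbor_always_hits_it(self, flat_potential, overdamped_params):
        # lowest milestone doubles as a reflecting end of the toy domain
        model = mk.build_linear_model([0.0, 1.0])
        records = mk.elber_run(
            model, 0, flat_potential, overdamped_params, 50, seed=1, reflecting_wall=0.0
        )
        assert all(r.hit == 1 for r in records)
        assert all(r.time_ps > 0 for r in records)

    def test_brownian_splitting_probability(self, flat_potential):
        """From x0 = 0.25 between absorbers at 0 and 1: P(hit 1) = 0.25."""
        model = mk.build_linear_model([0.0, 0.25, 1.0])
        params = mk.DynamicsParams(
            timestep_ps=2e-5, temperature_K=298.15, diffusion_A2_per_ps=1.0, seed=0
        )
        n = 2000
        records = mk.elber_run(model, 1, flat_potential, params, n, seed=21)
        frac_b = np.mean([r.hit == 2 for r in records])
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac_b - 0.25) < 3 * se

    def test_mean_exit_time_flat_interval(self, flat_potential):
        """Mean exit time from the midpoint of (0, 1) is (x-a)(b-x)/2D."""
        model = mk.build_linear_model([0.0, 0.5, 1.0])
        params = mk.DynamicsParams(
            timestep_ps=2e-5, temperature_K=298.15, diffusion_A2_per_ps=1.0, seed=0
        )
        records = mk.elber_run(model, 1, flat_potential, params, 1500, seed=22)
        times = np.array([r.time_ps for r in records])
        expected = 0.5 * 0.5 / 2.0  # 0.125 ps
        assert times.mean() == pytest.approx(expected, abs=3 * times.std() / np.sqrt(times.size))


class TestSMDPull:
    def test_zero_displacement_schedule(self, flat_potential, overdamped_params):
        k_spring = 100.0
        result = mk.smd_pull(
            flat_potential, overdamped_params, k_spring, (1.0, 1.0, 10.0), seed=3
        )
        width = np.sqrt(0.5925 / k_spring)
        assert abs(result.cv_values[-1] - 1.0) < 3 * width

    def test_stiff_spring_tracks_schedule(self, flat_potential):
        params = mk.DynamicsParams(
            timestep_ps=1e-5, temperature_K=298.15, diffusion_A2_per_ps=1.0, seed=0
        )
        result = mk.smd_pull(
            flat_potential, params, 5000.0, (0.0, 2.0, 20.0), seed=4, record_stride=100
        )
        lam = 0.0 + (2.0 - 0.0) * result.times_ps / 20.0
        assert np.max(np.abs(result.cv_values - lam)) < 0.1

    def test_unstable_spring_timestep_rejected(self, flat_potential, overdamped_params):
        with pytest.raises(ValueError, match="unstable"):
            mk.smd_pull(flat_potential, overdamped_params, 1e5, (0.0, 2.0, 20.0))

    def test_pull_covers_every_cell_of_spherical_model(self, flat_potential):
        model = mk.build_spherical_model(range(1, 14))
        params = mk.DynamicsParams(
            timestep_ps=1e-4, temperature_K=298.15, diffusion_A2_per_ps=1.0, seed=0
        )
        result = mk.smd_pull(
            flat_potential, params, 50.0, (1.0, 13.0, 50.0), model=model, seed=5
        )
        assert result.missing_cells == []
        assert set(result.cell_states) == {c.id for c in model.cells}
        for cell_id, state in result.cell_states.items():
            lo, hi = model.cell_bounds(cell_id)
            assert lo < model.cv_value(state.positions) < hi

    def test_unvisited_cells_reported_missing(self, flat_potential):
        model = mk.build_spherical_model(range(1, 14))
        params = mk.DynamicsParams(
            timestep_ps=1e-4, temperature_K=298.15, diffusion_A2_per_ps=1.0, seed=0
        )
        result = mk.smd_pull(
            flat_potential, params, 200.0, (1.0, 3.0, 10.0), model=model, seed=6
        )
        assert set(result.missing_cells).issuperset(set(range(4, 12)))

    def test_invalid_schedule_rejected(self, flat_potential, overdamped_params):
        with pytest.raises(ValueError):
            mk.smd_pull(flat_potential, overdamped_params, 10.0, (0.0, 1.0, -5.0))
        with pytest.raises(ValueError):
            mk.smd_pull(flat_potential, overdamped_params, -1.0, (0.0, 1.0, 5.0))


class TestHMR:
    def test_methane_example(self):
        masses = [12.011, 1.008, 1.008, 1.008, 1.008]
        flags = [False, True, True, True, True]
        bonds = [(0, 1), (0, 2), (0, 3), (0, 4)]
        new = mk.hmr_repartition(masses, flags, bonds, target_hydrogen_mass=3.024)
        assert np.allclose(new[1:], 3.024)
        assert new[0] == pytest.approx(12.011 - 4 * 2.016)
        assert new.sum() == pytest.approx(sum(masses), abs=1e-12)

    def test_identity_when_target_is_original(self):
        masses = [12.011, 1.008]
        new = mk.hmr_repartition(masses, [False, True], [(0, 1)], 1.008)
        assert np.array_equal(new, masses)

    def test_no_hydrogens_unchanged(self):
        masses = [12.0, 16.0]
        new = mk.hmr_repartition(masses, [False, False], [(0, 1)], 4.0)
        assert np.array_equal(new, masses)

    def test_overdraining_heavy_atom_errors(self):
        masses = [12.011, 1.008, 1.008, 1.008, 1.008]
        flags = [False, True, True, True, True]
        bonds = [(0, 1), (0, 2), (0, 3), (0, 4)]
        with pytest.raises(ValueError, match="heavy atom 0"):
            mk.hmr_repartition(masses, flags, bonds, target_hydrogen_mass=4.5)

    def test_hydrogen_with_two_heavies_rejected(self):
        with pytest.raises(ValueError, match="exactly one heavy"):
            mk.hmr_repartition([12.0, 1.0, 12.0], [False, True, False], [(0, 1), (1, 2)], 3.0)

    def test_total_mass_conserved_exactly(self):
        rng = np.random.default_rng(0)
        n_heavy = 6
        masses = list(rng.uniform(12, 32, n_heavy)) + [1.008] * n_heavy
        flags = [False] * n_heavy + [True] * n_heavy
        bonds = [(i, n_heavy + i) for i in range(n_heavy)]
        new = mk.hmr_repartition(masses, flags, bonds, 3.024)
        assert new.sum() == pytest.approx(sum(masses), rel=0, abs=1e-10)
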