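import numpy as np
import pytest

import milestonekit as mk
from milestonekit.kinetics import InsufficientSamplingError
from milestonekit.mmvt import cell_flux_matrix


def _stats(cell_id, T, counts=None, recol=None, incub=None, totals=None):
    s = mk.CellStatistics(cell_id=cell_id, T_ps=T)
    s.transition_counts = counts or {}
    s.recollision_counts = recol or {}
    s.incubation_ps = incub or {}
    s.collision_totals = totals or {}
    return s


class TestAggregate:
    def test_hand_trace(self, hand_trace_log):
        stats = mk.aggregate(hand_trace_log)
        assert stats.T_ps == 10.0
        assert stats.transition_counts == {(1, 2): 1, (2, 1): 1}
        assert stats.incubation_ps == {1: 3.0, 2: 4.0}
        assert stats.recollision_counts == {}
        # the pre-first-collision span (2 ps) is excluded
        assert sum(stats.incubation_ps.values()) == pytest.approx(7.0)

    def test_empty_log(self):
        log = mk.CollisionLog(0, np.empty(0, np.int32), np.empty(0), total_time_ps=5.0)
        stats = mk.aggregate(log)
        assert stats.T_ps == 5.0
        assert stats.transition_counts == {} and stats.incubation_ps == {}

    def test_recollisions_tracked_but_not_cross_counted(self):
        log = mk.CollisionLog(
            0, np.array([1, 1, 1], np.int32), np.array([1.0, 2.0, 3.0]), total_time_ps=4.0
        )
        stats = mk.aggregate(log)
        assert stats.recollision_counts == {1: 2}
        assert stats.transition_counts == {}
        assert stats.incubation_ps == {1: 2.0}

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            mk.CollisionLog(0, np.array([1, 2], np.int32), np.array([3.0, 2.0]), 5.0)


class TestCellWeights:
    def test_symmetric_two_cells(self):
        model = mk.build_linear_model([0.0, 1.0, 2.0, 3.0])
        stats = [
            _stats(0, 10.0, totals={0: 50, 1: 40}),
            _stats(1, 10.0, totals={1: 40, 2: 50}),
        ]
        pi = mk.cell_weights(stats, model)
        assert pi == pytest.approx([0.5, 0.5])

    def test_two_to_one_flux_ratio(self):
        # Q01 = 2/ps, Q10 = 1/ps  ->  pi = (1/3, 2/3)
        model = mk.build_linear_model([0.0, 1.0, 2.0, 3.0])
        stats = [
            _stats(0, 10.0, totals={1: 20}),
            _stats(1, 10.0, totals={1: 10}),
        ]
        pi = mk.cell_weights(stats, model)
        assert pi == pytest.approx([1 / 3, 2 / 3])

    def test_stationary_residual_small(self):
        model = mk.build_linear_model([0.0, 1.0, 2.0, 3.0, 4.0])
        rng = np.random.default_rng(3)
        stats = [
            _stats(c, 10.0, totals={c: int(rng.integers(50, 200)), c + 1: int(rng.integers(50, 200))})
            for c in range(4)
        ]
        pi = mk.cell_weights(stats, model)
        Q = cell_flux_matrix(stats, model)
        assert np.linalg.norm(pi @ Q) < 1e-10 * max(1.0, np.abs(Q).max())
        assert pi.sum() == pytest.approx(1.0)

    def test_disconnected_graph_rejected(self):
        model = mk.build_linear_model([0.0, 1.0, 2.0, 3.0, 4.0])
        stats = [
            _stats(0, 10.0, totals={1: 20}),
            _stats(1, 10.0, totals={1: 10}),  # no upper collisions: 1-2 edge missing
            _stats(2, 10.0, totals={3: 10}),
            _stats(3, 10.0, totals={3: 10}),
        ]
        with pytest.raises(ValueError, match="disconnected"):
            mk.cell_weights(stats, model)

    def test_zero_time_cell_rejected(self):
        model = mk.build_linear_model([0.0, 1.0, 2.0])
        stats = [_stats(0, 0.0, totals={1: 5})]
        with pytest.raises(ValueError, match="zero total"):
            mk.cell_weights(stats, model)

    def test_flat_potential_uniform_weights(self, flat_mmvt_fit):
        """Equal-width cells on a flat landscape: π uniform (Boltzmann)."""
        model, params, logs, res = flat_mmvt_fit
        pi = res.cell_weights
        # collision-count fluxes cluster heavily; 3-sigma band from the
        # observed spread across cells rather than naive counting statistics
        assert np.all(np.abs(pi - 0.25) < 0.05)


class TestMilestoneKernel:
    def test_hand_trace_substitution(self, hand_trace_log):
        stats = [mk.aggregate(hand_trace_log)]
        kin = mk.milestone_kernel(stats, np.ones(1))
        assert kin.K[1, 2] == pytest.approx(1.0)
        assert kin.K[2, 1] == pytest.approx(1.0)
        assert kin.t_ps[1] == pytest.approx(3.0)
        assert kin.t_ps[2] == pytest.approx(4.0)

    def test_symmetric_two_cell_doubly_stochastic(self):
        model = mk.build_linear_model([0.0, 1.0, 2.0])
        stats = [
            _stats(
                0, 10.0,
                counts={(0, 1): 30, (1, 0): 30},
                incub={0: 4.0, 1: 4.0},
                totals={0: 100, 1: 100},
            ),
            _stats(
                1, 10.0,
                counts={(1, 2): 30, (2, 1): 30},
                incub={1: 4.0, 2: 4.0},
                totals={1: 100, 2: 100},
            ),
        ]
        pi = mk.cell_weights(stats, model)
        kin = mk.milestone_kernel(stats, pi, model)
        interior = kin.K[1]
        assert interior[0] == pytest.approx(0.5) and interior[2] == pytest.approx(0.5)
        assert kin.K.sum(axis=1) == pytest.approx([1.0, 1.0, 1.0])

    def test_unsampled_milestone_named(self):
        stats = [
            _stats(0, 10.0, counts={(0, 1): 5}, incub={0: 2.0, 1: 3.0}, totals={0: 5, 1: 5})
        ]
        with pytest.raises(InsufficientSamplingError, match="milestone 1"):
            mk.milestone_kernel(stats, np.ones(1))
        # designating it absorbing is the way out
        kin = mk.milestone_kernel(stats, np.ones(1), absorbing={1})
        assert kin.K[1].sum() == 0.0

    def test_row_sums_stochastic(self, flat_mmvt_fit):
        model, params, logs, res = flat_mmvt_fit
        K = res.kernel
        assert np.allclose(K.sum(axis=1), 1.0, atol=1e-12)


class TestFreeEnergyProfile:
    def test_uniform_probabilities_flat_profile(self):
        dg = mk.free_energy_profile(np.full(4, 0.25), 298.15)
        assert dg == pytest.approx([0.0, 0.0, 0.0, 0.0])

    def test_worked_example(self):
        dg = mk.free_energy_profile(np.array([0.8, 0.2]), 298.15)
        assert dg[0] == 0.0
        assert dg[1] == pytest.approx(-1.9872e-3 * 298.15 * np.log(0.25), abs=1e-6)
        assert dg[1] == pytest.approx(0.821, abs=5e-4)

    def test_zero_probability_reported_infinite(self):
        dg = mk.free_energy_profile(np.array([0.7, 0.3, 0.0]), 300.0)
        assert np.isinf(dg[2])

    def test_harmonic_milestone_profile_matches_quadrature(self):
        """MMVT milestone ΔG vs the Boltzmann/backward-committor quadrature.

        The stationary milestone weight is the equilibrium measure of "the
        last milestone touched was i": p_i = Σ_cells ∫ ρ(x) q_i(x) dx with
        ρ ∝ e^{-U/kT} and q_i the backward committor toward milestone i
        (for reversible 1-D diffusion q_lo(x) ∝ ∫_x^b e^{U/kT}).
        """
        from scipy.integrate import quad

        k, kT = 1.0, 0.5925
        positions = [0.0, 0.6, 1.2, 1.8]

        def U(x):
            return 0.5 * k * x * x

        def rho(x):
            return np.exp(-U(x) / kT)

        def ebu(x):
            return np.exp(U(x) / kT)

        M = len(positions)
        p = np.zeros(M)
        for c in range(M - 1):
            a, b = positions[c], positions[c + 1]
            Z = quad(ebu, a, b)[0]
            p[c] += quad(lambda x: rho(x) * quad(ebu, x, b)[0] / Z, a, b)[0]
            p[c + 1] += quad(lambda x: rho(x) * (1 - quad(ebu, x, b)[0] / Z), a, b)[0]
        p /= p.sum()
        dg_oracle = -kT * np.log(p / p.max())

        model = mk.build_linear_model(positions)
        params = mk.DynamicsParams(
            timestep_ps=5e-5, temperature_K=298.15, diffusion_A2_per_ps=1.0, seed=0
        )
        pot = mk.HarmonicPotential(k=k, center=(0.0,))
        logs = [
            mk.mmvt_run(model, c, pot, params, duration_ps=1500.0, seed=40 + c)
            for c in range(model.n_cells)
        ]
        res = mk.MMVTMilestoningModel(logs, model).fit()
        assert np.max(np.abs(res.free_energy_profile() - dg_oracle)) < 0.08  # kcal/mol


class TestMFPT:
    def test_one_step_chain(self):
        kin = mk.MilestoneKinetics(
            K=np.array([[0.0, 1.0], [0.0, 0.0]]), t_ps=np.array([7.0, 0.0]), absorbing={1}
        )
        assert mk.mfpt(kin, 0, {1}) == pytest.approx(7.0)

    @pytest.mark.parametrize("n_milestones", [3, 5, 9])
    def test_reflecting_random_walk_closed_form(self, n_milestones):
        """Uniform-lifetime symmetric walk: T_i = tau (N^2 - i^2)."""
        N = n_milestones - 1
        tau = 0.3
        K = np.zeros((n_milestones, n_milestones))
        K[0, 1] = 1.0
        for i in range(1, N):
            K[i, i - 1] = K[i, i + 1] = 0.5
        kin = mk.MilestoneKinetics(K=K, t_ps=np.full(n_milestones, tau), absorbing={N})
        for i in range(N):
            assert mk.mfpt(kin, i, {N}) == pytest.approx(tau * (N**2 - i**2))

    def test_unreachable_absorbing_rejected(self):
        K = np.zeros((3, 3))
        K[0, 1] = 1.0
        K[1, 0] = 1.0
        kin = mk.MilestoneKinetics(K=K, t_ps=np.array([1.0, 1.0, 0.0]), absorbing={2})
        with pytest.raises(ValueError, match="unreachable"):
            mk.mfpt(kin, 0, {2})

    def test_empty_absorbing_set_rejected(self):
        kin = mk.MilestoneKinetics(
            K=np.array([[0.0, 1.0], [1.0, 0.0]]), t_ps=np.array([1.0, 1.0])
        )
        with pytest.raises(ValueError):
            mk.mfpt(kin, 0, set())


class TestKOff:
    def test_reciprocal_of_mfpt(self):
        kin = mk.MilestoneKinetics(
            K=np.array([[0.0, 1.0], [0.0, 0.0]]),
            t_ps=np.array([1e9, 0.0]),  # 1 ms in ps
            absorbing={1},
        )
        assert mk.k_off(kin, 0, 1) == pytest.approx(1000.0)  # s^-1

    def test_doubling_lifetimes_halves_k_off(self):
        K = np.zeros((4, 4))
        K[0, 1] = 1.0
        K[1, 0] = K[1, 2] = 0.5
        K[2, 1] = K[2, 3] = 0.5
        t = np.array([0.2, 0.4, 0.3, 0.0])
        k1 = mk.k_off(mk.MilestoneKinetics(K=K, t_ps=t, absorbing={3}), 0, 3)
        k2 = mk.k_off(mk.MilestoneKinetics(K=K, t_ps=2 * t, absorbing={3}), 0, 3)
        assert k2 == pytest.approx(k1 / 2, rel=1e-12)

    def test_double_well_escape_vs_brute_force(self):
        """MMVT k_off agrees with direct first-passage simulation (3 SE)."""
        from milestonekit._kernels import first_hitting_overdamped

        pot = mk.DoubleWellPotential(barrier_height=1.2, well_position=1.0)
        positions = [-1.0, -0.5, 0.0, 0.5, 1.0]
        model = mk.build_linear_model(positions)
        params = mk.DynamicsParams(
            timestep_ps=1e-4, temperature_K=298.15, diffusion_A2_per_ps=1.0, seed=0
        )
        logs = [
            mk.mmvt_run(model, c, pot, params, duration_ps=400.0, seed=70 + c)
            for c in range(model.n_cells)
        ]
        res = mk.MMVTMilestoningModel(logs, model).fit()
        mfpt_mmvt = res.mfpt(0, {4})
        sd_mmvt = np.std(
            [1e12 / v for v in res.k_off_samples(300, seed=5)]
        )

        # brute force: trajectories from x = -1 with the domain's reflecting
        # end at -1, absorbed at +1 (identical dynamics and timestep)
        rng = np.random.default_rng(17)
        times = []
        for _ in range(300):
            side, steps = first_hitting_overdamped(
                np.array([-1.0]), pot.kind_code, pot.params_array(), 0,
                0.0, 1.0, False, True, 1.0, params.kT_kcal, params.timestep_ps,
                10**8, int(rng.integers(2**31 - 1)), -1.0, True,
            )
            assert side == 1
            times.append(steps * params.timestep_ps)
        times = np.array(times)
        se_brute = times.std(ddof=1) / np.sqrt(times.size)
        assert abs(mfpt_mmvt - times.mean()) < 3 * np.hypot(sd_mmvt, se_brute)
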