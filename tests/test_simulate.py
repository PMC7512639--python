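import numpy as np
import pytest

from sigentropy import (
    CascadeSpec,
    CascadeState,
    Trajectory,
    read_trajectory,
    run_ssa,
    solve_steady_state,
    time_averaged_occupancy,
    write_trajectory,
)
from sigentropy.simulate import holding_time_integrals, occupancy_standard_error


def push_pull(k_act, k_deact, total=100, stimulus=1.0):
    """Single-step push-pull cycle; per-molecule activation rate k_act*stimulus."""
    return CascadeSpec(
        n=1, k_fwd=(k_act,), k_bwd=(k_deact,), totals=(total,), tau=(1.0,),
        stimulus=stimulus,
    )


def stationary_mean_active(spec):
    """Analytic stationary mean of the n=1 birth-death chain.

    Molecules flip independently (activation rate a per inactive,
    deactivation rate b per active), so the stationary count is
    Binomial(N, a/(a+b)) and the mean is N*a/(a+b).
    """
    a = spec.k_fwd[0] * spec.stimulus
    b = spec.k_bwd[0]
    return spec.totals[0] * a / (a + b)


class TestRunSsa:
    def test_determinism_same_seed(self, driven_spec):
        t1 = run_ssa(driven_spec, t_max=2.0, seed=11)
        t2 = run_ssa(driven_spec, t_max=2.0, seed=11)
        np.testing.assert_array_equal(t1.times, t2.times)
        np.testing.assert_array_equal(t1.steps, t2.steps)
        np.testing.assert_array_equal(t1.directions, t2.directions)

    def test_different_seed_differs(self, driven_spec):
        t1 = run_ssa(driven_spec, t_max=2.0, seed=11)
        t2 = run_ssa(driven_spec, t_max=2.0, seed=12)
        assert not np.array_equal(t1.times, t2.times)

    def test_irreversible_limit_absorbs_fully_active(self):
        spec = push_pull(1.0, 0.0, total=10)
        traj = run_ssa(spec, t_max=1e6, seed=3)
        assert traj.truncated
        final = traj.final_state()
        assert final.active[0] == 10 and final.inactive[0] == 0

    def test_rejects_nonpositive_horizon(self, driven_spec):
        with pytest.raises(ValueError):
            run_ssa(driven_spec, t_max=0.0, seed=1)

    def test_conservation_along_trajectory(self, driven_traj):
        totals = np.array(driven_traj.spec.totals)
        for state in driven_traj.states():
            np.testing.assert_array_equal(state.totals, totals)

    def test_stationary_occupancy_matches_birth_death_oracle(self):
        """Long-run active fraction of the push-pull cycle agrees with the
        Binomial(N, a/(a+b)) stationary mean within 3 Monte-Carlo SE."""
        spec = push_pull(2.0, 1.0, total=200)
        traj = run_ssa(spec, t_max=100.0, seed=5)
        occ = time_averaged_occupancy(traj)
        se = occupancy_standard_error(traj)[0]
        mean = stationary_mean_active(spec) / spec.totals[0]
        assert abs(occ.p_star[0] / occ.p0[0] - mean) < 3 * se


class TestSteadyState:
    def test_single_step_linear_balance(self):
        spec = push_pull(0.7, 1.3, total=100, stimulus=2.0)
        occ = solve_steady_state(spec)
        a = 0.7 * 2.0
        expected = a * 100 / (a + 1.3)
        np.testing.assert_allclose(occ.p_star[0] * occ.X, expected, rtol=1e-14)

    def test_symmetric_rates_give_equal_occupancies(self, equilibrium_spec):
        occ = solve_steady_state(equilibrium_spec)
        np.testing.assert_allclose(occ.p, occ.p_star, rtol=1e-12)

    def test_ssa_matches_ode_within_monte_carlo_error(self, driven_spec):
        traj = run_ssa(driven_spec, t_max=20.0, seed=8)
        occ_ssa = time_averaged_occupancy(traj)
        occ_ode = solve_steady_state(driven_spec)
        se = occupancy_standard_error(traj)
        frac_ssa = occ_ssa.p_star / occ_ssa.p0
        frac_ode = occ_ode.p_star / occ_ode.p0
        assert np.all(np.abs(frac_ssa - frac_ode) < 3 * se)


class TestTimeAveragedOccupancy:
    def test_constant_trajectory_returns_initial_occupancy(self, driven_spec):
        init = CascadeState(inactive=(600, 700, 800), active=(400, 300, 200))
        traj = Trajectory(
            times=np.array([]), steps=np.array([]), directions=np.array([]),
            initial_state=init, spec=driven_spec, t_end=5.0,
        )
        occ = time_averaged_occupancy(traj, burn_in=0.0)
        np.testing.assert_allclose(occ.p_star * occ.X, init.active)

    def test_two_event_holding_time_weights(self, driven_spec):
        """With events at t=0.25 and t=0.5 on a unit window, occupation
        integrals are hand-computable from the three holding intervals."""
        init = CascadeState(inactive=(1000, 1000, 1000), active=(0, 0, 0))
        traj = Trajectory(
            times=np.array([0.25, 0.5]),
            steps=np.array([1, 1]),
            directions=np.array([1, 1]),
            initial_state=init, spec=driven_spec, t_end=1.0,
        )
        occ = time_averaged_occupancy(traj, burn_in=0.0)
        # active_1: 0 for 0.25, 1 for 0.25, 2 for 0.5 -> integral 0.25 + 1.0
        np.testing.assert_allclose(occ.p_star[0] * occ.X, 1.25, rtol=1e-12)
        np.testing.assert_allclose(occ.p[0] * occ.X, 1000 - 1.25, rtol=1e-12)

    def test_empty_window_rejected(self, driven_traj):
        with pytest.raises(ValueError):
            time_averaged_occupancy(driven_traj, burn_in=driven_traj.t_end)

    def test_holding_integrals_sum_to_pool_times_window(self, driven_traj):
        T_in, T_act, window = holding_time_integrals(driven_traj, burn_in=2.0)
        np.testing.assert_allclose(
            T_in + T_act, np.array(driven_traj.spec.totals) * window, rtol=1e-9
        )


class TestTrajectoryIO:
    def test_csv_round_trip(self, driven_spec, tmp_path):
        traj = run_ssa(driven_spec, t_max=1.0, seed=9)
        path = tmp_path / "traj.csv"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        np.testing.assert_allclose(back.times, traj.times)
        np.testing.assert_array_equal(back.steps, traj.steps)
        np.testing.assert_array_equal(back.directions, traj.directions)
        assert back.spec == traj.spec
        assert back.t_end == traj.t_end

    def test_event_times_strictly_increasing(self, driven_traj):
        assert np.all(np.diff(driven_traj.times) > 0)
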