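import math

import numpy as np
import pytest

from sigentropy import (
    CascadeState,
    FixtureConfig,
    InsufficientEventsError,
    Trajectory,
    ft_consistency_check,
    ft_log_ratio,
    make_cascade,
    run_ssa,
    solve_steady_state,
    transition_counts,
)


def hand_trajectory(spec):
    """Six hand-placed events on a 2-step cascade: fwd1, fwd1, fwd2,
    bwd1, fwd2, bwd2."""
    init = CascadeState(
        inactive=np.array(spec.totals), active=np.zeros(spec.n, dtype=int)
    )
    return Trajectory(
        times=np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]),
        steps=np.array([1, 1, 2, 1, 2, 2]),
        directions=np.array([1, 1, 1, -1, 1, -1]),
        initial_state=init,
        spec=spec,
        t_end=1.0,
    )


@pytest.fixture(scope="module")
def two_step_spec():
    return make_cascade(FixtureConfig(regime="driven", n=2, totals=100))


class TestTransitionCounts:
    def test_manual_tally(self, two_step_spec):
        n_fwd, n_bwd = transition_counts(hand_trajectory(two_step_spec), burn_in=0.0)
        np.testing.assert_array_equal(n_fwd, [2, 2])
        np.testing.assert_array_equal(n_bwd, [1, 1])

    def test_burn_in_drops_early_events(self, two_step_spec):
        n_fwd, n_bwd = transition_counts(hand_trajectory(two_step_spec), burn_in=0.35)
        np.testing.assert_array_equal(n_fwd, [0, 1])
        np.testing.assert_array_equal(n_bwd, [1, 1])

    def test_counts_additive_over_disjoint_windows(self, two_step_spec):
        traj = hand_trajectory(two_step_spec)
        full = transition_counts(traj, burn_in=0.0)
        tail = transition_counts(traj, burn_in=0.35)
        head_fwd = np.bincount(
            traj.steps[(traj.times <= 0.35) & (traj.directions > 0)] - 1, minlength=2
        )
        np.testing.assert_array_equal(full[0], head_fwd + tail[0])

    def test_no_deactivations_in_irreversible_run(self):
        spec = make_cascade(FixtureConfig(regime="driven", n=1, totals=50))
        spec = type(spec)(**{**spec.to_dict(), "k_bwd": [0.0]})
        traj = run_ssa(spec, t_max=50.0, seed=2)
        _, n_bwd = transition_counts(traj, burn_in=0.0)
        assert n_bwd[0] == 0


class TestFtLogRatio:
    def test_detailed_balance_counts_give_zero(self):
        est = ft_log_ratio(250, 250, tau_j=1.0)
        assert est.log_ratio == 0.0

    def test_four_to_one_counts(self):
        est = ft_log_ratio(400, 100, tau_j=2.0)
        assert est.log_ratio == pytest.approx(math.log(4), rel=1e-12)
        assert est.rate_log_ratio == pytest.approx(math.log(4) / 2, rel=1e-12)
        assert est.ci == pytest.approx(1.96 * math.sqrt(1 / 400 + 1 / 100), rel=1e-3)

    def test_scale_invariance_and_ci_shrinkage(self):
        a = ft_log_ratio(400, 100, 1.0)
        b = ft_log_ratio(800, 200, 1.0)
        assert b.log_ratio == pytest.approx(a.log_ratio, abs=1e-14)
        assert b.ci == pytest.approx(a.ci / math.sqrt(2), rel=1e-12)

    def test_zero_counts_signalled_not_infinite(self):
        with pytest.raises(InsufficientEventsError):
            ft_log_ratio(0, 10, 1.0)
        with pytest.raises(InsufficientEventsError):
            ft_log_ratio(10, 0, 1.0)


class TestFtConsistency:
    def test_equilibrium_chain_is_symmetric(self):
        """Detailed-balance-like fixture: conditional-rate log-ratio and
        occupancy log-odds are both ~0 and agree inside the CI."""
        spec = make_cascade(FixtureConfig(regime="equilibrium", n=1, totals=500))
        traj = run_ssa(spec, t_max=40.0, seed=21)
        occ = solve_steady_state(spec)
        rep = ft_consistency_check(traj, occ, spec.tau)
        step = rep.steps[0]
        assert step.occ_log_odds == pytest.approx(0.0, abs=1e-12)
        assert step.inside_ci
        assert abs(step.log_ratio) < 0.1

    def test_driven_chain_matches_analytic_odds(self):
        """Driven push-pull: the trajectory estimate of the transition
        log-ratio matches -ln(p/p*) from the analytic stationary state."""
        spec = make_cascade(FixtureConfig(regime="driven", n=1, totals=1000))
        traj = run_ssa(spec, t_max=15.0, seed=77)
        assert traj.n_events >= 10_000
        occ = solve_steady_state(spec)  # analytic odds: p*/p = 2
        rep = ft_consistency_check(traj, occ, spec.tau)
        step = rep.steps[0]
        assert step.expected_log_ratio == pytest.approx(math.log(2), rel=1e-12)
        assert step.inside_ci

    def test_label_reversal_flips_sign_exactly(self, two_step_spec):
        """Swapping activation/deactivation labels (and the molecular
        forms accordingly) is a time-reversal surrogate: it negates the
        conditional-rate log-ratio exactly."""
        spec = make_cascade(FixtureConfig(regime="driven", n=1, totals=300))
        traj = run_ssa(spec, t_max=20.0, seed=5)
        occ = solve_steady_state(spec)
        rep = ft_consistency_check(traj, occ, spec.tau)
        flipped = Trajectory(
            times=traj.times,
            steps=traj.steps,
            directions=-traj.directions,
            initial_state=CascadeState(
                inactive=traj.initial_state.active.copy(),
                active=traj.initial_state.inactive.copy(),
            ),
            spec=spec,
            t_end=traj.t_end,
        )
        flipped_rep = ft_consistency_check(flipped, occ, spec.tau)
        assert flipped_rep.steps[0].log_ratio == pytest.approx(
            -rep.steps[0].log_ratio, rel=1e-12
        )

    def test_estimate_error_shrinks_with_trajectory_length(self):
        """Convergence toward the analytic odds as events accumulate."""
        spec = make_cascade(FixtureConfig(regime="driven", n=1, totals=400))
        occ = solve_steady_state(spec)
        errs = []
        for t_max in (4.0, 16.0, 64.0):
            diffs = [
                abs(
                    ft_consistency_check(
                        run_ssa(spec, t_max=t_max, seed=100 + k), occ, spec.tau
                    ).steps[0].difference
                )
                for k in range(5)
            ]
            errs.append(np.mean(diffs))
        assert errs[2] < errs[0]

    def test_insufficient_events_propagated(self, two_step_spec):
        traj = hand_trajectory(two_step_spec)
        occ = solve_steady_state(two_step_spec)
        short = Trajectory(
            times=traj.times[:2], steps=traj.steps[:2], directions=traj.directions[:2],
            initial_state=traj.initial_state, spec=two_step_spec, t_end=1.0,
        )
        with pytest.raises(InsufficientEventsError):
            ft_consistency_check(short, occ, two_step_spec.tau, burn_in=0.0)
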