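"""Steady-state fluctuation-theorem statistics from trajectories.

A cascade step's forward transition is an activation event of its
species (catalysed by the upstream active form); the backward transition
is the phosphatase deactivation.  In a stationary trajectory the
*per-molecule conditional rates* of the two transitions obey an exact
balance with the occupancy odds:

    r_fwd * p_j = r_bwd * p_j*   =>   ln(r_fwd / r_bwd) = ln(p_j* / p_j)

so the log-ratio of conditional transition probabilities equals the
occupancy log-odds up to orientation.  This module estimates the
left-hand side from event counts normalised by species holding times and
compares it against the log-odds of a reference occupancy (analytic,
deterministic, or trajectory-averaged), with a delta-method confidence
band.  Raw event counts alone cannot carry this information: in steady
state activation and deactivation counts of the same species balance to
within one pool size, whatever the drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import OccupancyDistribution
from .simulate import Trajectory, holding_time_integrals

__all__ = [
    "FtEstimate",
    "FtStepReport",
    "FtReport",
    "InsufficientEventsError",
    "transition_counts",
    "ft_log_ratio",
    "ft_consistency_check",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class InsufficientEventsError(ValueError):
    """A log-ratio was requested with zero forward or backward events."""


@dataclass(frozen=True)
class FtEstimate:
    """Raw-count log-ratio for one step (the spec-level arithmetic)."""

    n_fwd: int
    n_bwd: int
    log_ratio: float
    rate_log_ratio: float
    ci: float


@dataclass(frozen=True)
class FtStepReport:
    step: int
    n_fwd: int
    n_bwd: int
    log_ratio: float          # ln(r_fwd / r_bwd), conditional-rate estimate
    rate_log_ratio: float     # log_ratio / tau_j
    occ_log_odds: float       # ln(p_j / p_j*) of the reference occupancy
    expected_log_ratio: float  # -occ_log_odds (stationary balance)
    difference: float
    ci: float
    inside_ci: bool


@dataclass(frozen=True)
class FtReport:
    steps: tuple[FtStepReport, ...]
    passed: bool


def transition_counts(
    traj: Trajectory, burn_in: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Forward (activation) and backward (deactivation) event counts per step.

    Counts are additive over disjoint windows; only events after
    ``burn_in`` are tallied (default: the trajectory's 20% convention).
    """
    if burn_in is None:
        burn_in = 0.2 * traj.t_end
    if burn_in >= traj.t_end:
        raise ValueError("burn_in must be smaller than the trajectory duration")
    n = traj.spec.n
    mask = traj.times > burn_in
    steps = traj.steps[mask]
    dirs = traj.directions[mask]
    n_fwd = np.bincount(steps[dirs > 0] - 1, minlength=n).astype(np.int64)
    n_bwd = np.bincount(steps[dirs < 0] - 1, minlength=n).astype(np.int64)
    return n_fwd, n_bwd


def ft_log_ratio(n_fwd: int, n_bwd: int, tau_j: float) -> FtEstimate:
    """Log-ratio of raw forward/backward counts with a 95% CI.

    ci is the delta-method half-width 1.96*sqrt(1/n_fwd + 1/n_bwd); the
    estimate is scale-invariant (doubling both counts leaves it fixed)
    while the CI shrinks by sqrt(2).
    """
    if tau_j <= 0:
        raise ValueError("tau_j must be positive")
    if n_fwd <= 0 or n_bwd <= 0:
        raise InsufficientEventsError(
            f"cannot form a log-ratio from counts ({n_fwd}, {n_bwd}); "
            "both directions need at least one event"
        )
    lr = float(np.log(n_fwd / n_bwd))
    ci = Z_95 * float(np.sqrt(1.0 / n_fwd + 1.0 / n_bwd))
    return FtEstimate(
        n_fwd=int(n_fwd),
        n_bwd=int(n_bwd),
        log_ratio=lr,
        rate_log_ratio=lr / tau_j,
        ci=ci,
    )


def ft_consistency_check(
    traj: Trajectory,
    occ: OccupancyDistribution,
    tau,
    burn_in: float | None = None,
) -> FtReport:
    """Check the stationary FT relation between transitions and occupancies.

    For each step the conditional-rate log-ratio
    ``ln[(n_fwd / ∫X_j dt) / (n_bwd / ∫X_j* dt)]`` is compared against
    ``-ln(p_j/p_j*)`` from the reference occupancy ``occ``; the step
    passes when the difference lies inside the 95% delta-method band.
    The cascade passes when every step does.

    Supplying an independent occupancy (analytic or deterministic steady
    state) makes this a genuine test of the simulated dynamics; supplying
    the occupancy of the same trajectory reduces the difference to the
    raw count log-ratio, which vanishes in stationarity by flux balance.
    """
    tau = np.asarray(tau, dtype=float)
    n = traj.spec.n
    if tau.shape != (n,):
        raise ValueError(f"tau must have length {n}")
    if occ.n != n:
        raise ValueError("occupancy and trajectory cascade sizes differ")
    n_fwd, n_bwd = transition_counts(traj, burn_in)
    T_in, T_act, _ = holding_time_integrals(traj, burn_in)
    log_odds = occ.log_odds()
    reports: list[FtStepReport] = []
    all_pass = True
    for j in range(n):
        if n_fwd[j] == 0 or n_bwd[j] == 0:
            raise InsufficientEventsError(
                f"step {j + 1}: counts ({n_fwd[j]}, {n_bwd[j]}) — "
                "trajectory too short for an FT estimate"
            )
        if T_in[j] <= 0 or T_act[j] <= 0:
            raise InsufficientEventsError(
                f"step {j + 1}: a form was never occupied after burn-in"
            )
        r_fwd = n_fwd[j] / T_in[j]
        r_bwd = n_bwd[j] / T_act[j]
        lr = float(np.log(r_fwd / r_bwd))
        ci = Z_95 * float(np.sqrt(1.0 / n_fwd[j] + 1.0 / n_bwd[j]))
        expected = float(-log_odds[j])
        diff = lr - expected
        inside = bool(abs(diff) <= ci)
        all_pass &= inside
        reports.append(
            FtStepReport(
                step=j + 1,
                n_fwd=int(n_fwd[j]),
                n_bwd=int(n_bwd[j]),
                log_ratio=lr,
                rate_log_ratio=lr / float(tau[j]),
                occ_log_odds=float(log_odds[j]),
                expected_log_ratio=expected,
                difference=diff,
                ci=ci,
                inside_ci=inside,
            )
        )
    return FtReport(steps=tuple(reports), passed=all_pass)
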