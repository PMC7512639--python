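"""Synthetic cascade generators for the three study regimes.

All test inputs are generated here; no external data exist.  Three
regimes cover the physics the estimators must resolve:

- ``equilibrium``: rates tuned so the deterministic steady state has
  p_j = p_j* at every step — zero current density, the detailed-balance
  null for the fluctuation-theorem machinery.
- ``driven``: a stated forward asymmetry (stationary active fraction 2/3
  at every step), giving a uniform nonzero drive c_j = -ln 2.
- ``eq19_consistent``: rates solved so the steady-state inactive
  occurrence probabilities follow the maximal-rate coding law
  p_j = exp(-zeta * tau_j) for one step-independent zeta — the regime in
  which the per-step entropy production current J_j = kB T zeta_j is
  constant along the cascade.

Defaults (n = 3 steps, 1000 molecules per step, tau = (1, 1, 1),
seed = 42) keep every regime solvable in well under a second while
making the Stirling approximation accurate to below 1%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CascadeSpec
from .simulate import Trajectory, run_ssa, solve_steady_state

__all__ = ["FixtureConfig", "make_cascade", "make_reference_trajectory"]

REGIMES = ("equilibrium", "driven", "eq19_consistent")


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of a synthetic cascade fixture."""

    n: int = 3
    regime: str = "driven"
    totals: int = 1000
    zeta: float = 1.5
    tau: tuple[float, ...] | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.n < 1 or self.totals < 1:
            raise ValueError("n and totals must be >= 1")
        if self.tau is None:
            object.__setattr__(self, "tau", tuple(1.0 for _ in range(self.n)))
        if len(self.tau) != self.n:
            raise ValueError("tau must have length n")


def make_cascade(config: FixtureConfig) -> CascadeSpec:
    """Build a CascadeSpec realising the requested regime's steady state."""
    n, T = config.n, float(config.totals)
    tau = tuple(config.tau)
    if config.regime == "equilibrium":
        # symmetric occupancy: active fraction 1/2 at every step
        k_fwd = [1.0] + [2.0 / T] * (n - 1)
        k_bwd = [1.0] * n
        return CascadeSpec(
            n=n, k_fwd=tuple(k_fwd), k_bwd=tuple(k_bwd),
            totals=(config.totals,) * n, tau=tau, stimulus=1.0,
        )
    if config.regime == "driven":
        # stationary active fraction 2/3 at every step: odds a/(T-a) = 2
        k_fwd = [2.0] + [3.0 / T] * (n - 1)
        k_bwd = [1.0] * n
        return CascadeSpec(
            n=n, k_fwd=tuple(k_fwd), k_bwd=tuple(k_bwd),
            totals=(config.totals,) * n, tau=tau, stimulus=1.0,
        )
    # eq19_consistent: target inactive occurrence probabilities
    # p_j = exp(-zeta * tau_j) relative to the whole pool X = n * totals.
    zeta = float(config.zeta)
    if zeta <= 0:
        raise ValueError("eq19_consistent regime requires zeta > 0")
    p_target = np.exp(-zeta * np.asarray(tau))
    if p_target.sum() > 1.0 + 1e-12:
        raise ValueError(
            "infeasible coding law: sum exp(-zeta*tau) = "
            f"{p_target.sum():.6f} > 1; increase zeta or the durations"
        )
    X = n * T
    inact = p_target * X
    act = T - inact
    if abs(p_target.sum() - 1.0) <= 1e-9:
        # Kraft-equality boundary: the whole pool is inactive, realisable
        # only by an unstimulated cascade with uniform step pools.
        if not np.allclose(inact, T, rtol=1e-9):
            raise ValueError(
                "infeasible coding law at the Kraft-equality boundary: "
                "targets must match the per-step pool fractions"
            )
        return CascadeSpec(
            n=n, k_fwd=(1.0,) * n, k_bwd=(1.0,) * n,
            totals=(config.totals,) * n, tau=tau, stimulus=0.0,
        )
    bad = np.where((inact <= 0) | (act <= 0))[0]
    if bad.size:
        raise ValueError(
            f"infeasible coding law at steps {list(bad + 1)}: target inactive "
            f"counts {inact[bad]} must lie strictly inside (0, {T}); "
            "each step's pool must hold both forms"
        )
    # back-solve mass-action balance with unit phosphatase rates
    k_bwd = [1.0] * n
    k_fwd = [float(act[0] / inact[0])]
    for j in range(1, n):
        k_fwd.append(float(act[j] / (act[j - 1] * inact[j])))
    return CascadeSpec(
        n=n, k_fwd=tuple(k_fwd), k_bwd=tuple(k_bwd),
        totals=(config.totals,) * n, tau=tau, stimulus=1.0,
    )


def make_reference_trajectory(config: FixtureConfig, t_max: float) -> Trajectory:
    """Seeded SSA run of the fixture cascade (all-inactive start)."""
    spec = make_cascade(config)
    return run_ssa(spec, t_max=t_max, seed=config.seed)


def expected_occupancy(config: FixtureConfig):
    """Deterministic steady-state occupancy of the fixture cascade."""
    return solve_steady_state(make_cascade(config))
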