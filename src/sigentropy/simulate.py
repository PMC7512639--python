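"""Stochastic simulation and deterministic steady state of the cascade.

`run_ssa` is an exact direct-method (Gillespie) sampler of the jump
process defined by the mass-action network; `solve_steady_state` solves
the corresponding deterministic rate equations.  Trajectories carry the
event log from which all downstream estimators (occupancy, transition
counts, fluctuation-theorem ratios) are computed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .model import (
    CascadeSpec,
    CascadeState,
    OccupancyDistribution,
    build_network,
    occupancy_from_state,
)

__all__ = [
    "Trajectory",
    "run_ssa",
    "solve_steady_state",
    "time_averaged_occupancy",
    "occupancy_standard_error",
    "holding_time_integrals",
    "write_trajectory",
    "read_trajectory",
]

DEFAULT_BURN_IN_FRACTION = 0.2
"""Fraction of t_max discarded as transient when no burn-in is given."""


@dataclass
class Trajectory:
    """Event log of one stochastic cascade run.

    ``times`` are strictly increasing event times, ``steps`` the 1-based
    step index of each event and ``directions`` +1 for activation
    ("fwd") or -1 for deactivation ("bwd").  ``t_end`` is the time up to
    which the trajectory is valid (t_max, or the last event time if the
    process was absorbed earlier, in which case ``truncated`` is set).
    """

    times: np.ndarray
    steps: np.ndarray
    directions: np.ndarray
    initial_state: CascadeState
    spec: CascadeSpec
    t_end: float
    seed: int | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.directions = np.asarray(self.directions, dtype=np.int64)
        if not (self.times.shape == self.steps.shape == self.directions.shape):
            raise ValueError("times, steps and directions must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if not set(np.unique(self.directions)) <= {-1, 1}:
            raise ValueError("directions must be +1 (fwd) or -1 (bwd)")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def events(self) -> Iterator[tuple[float, int, str]]:
        for t, s, d in zip(self.times, self.steps, self.directions):
            yield float(t), int(s), "fwd" if d > 0 else "bwd"

    def states(self) -> Iterator[CascadeState]:
        """Replay the event log, yielding the state after each event."""
        state = self.initial_state.copy()
        for t, s, d in zip(self.times, self.steps, self.directions):
            j = int(s) - 1
            state.inactive[j] -= d
            state.active[j] += d
            state.time = float(t)
            if state.inactive[j] < 0 or state.active[j] < 0:
                raise ValueError(f"negative count while replaying event at t={t}")
            yield state

    def final_state(self) -> CascadeState:
        inact = self.initial_state.inactive.copy()
        act = self.initial_state.active.copy()
        for s, d in zip(self.steps, self.directions):
            inact[s - 1] -= d
            act[s - 1] += d
        return CascadeState(inact, act, self.t_end)


def run_ssa(
    spec: CascadeSpec,
    t_max: float,
    seed: int,
    initial_state: CascadeState | None = None,
) -> Trajectory:
    """Exact stochastic simulation (direct method) up to ``t_max``.

    The initial condition defaults to all-inactive.  If every propensity
    vanishes before ``t_max`` the trajectory is returned with
    ``truncated=True`` (absorbing state reached).
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    rng = np.random.default_rng(seed)
    if initial_state is None:
        initial_state = CascadeState(
            inactive=np.array(spec.totals, dtype=np.int64),
            active=np.zeros(spec.n, dtype=np.int64),
        )
    if not np.array_equal(initial_state.totals, np.array(spec.totals)):
        raise ValueError("initial_state totals do not match spec totals")

    n = spec.n
    # Plain-Python state and rate bookkeeping: the channel set is tiny
    # (2n), so recomputing all propensities per event beats array overhead.
    inact = [int(x) for x in initial_state.inactive]
    act = [int(x) for x in initial_state.active]
    k_fwd = list(spec.k_fwd)
    k_bwd = list(spec.k_bwd)
    stim = spec.stimulus

    times: list[float] = []
    steps: list[int] = []
    dirs: list[int] = []
    t = 0.0
    truncated = False
    # pre-draw random numbers in blocks to cut per-event RNG overhead
    block = 65536
    u = rng.random(block * 2)
    iu = 0
    while True:
        props = [k_fwd[0] * stim * inact[0], k_bwd[0] * act[0]]
        for j in range(1, n):
            props.append(k_fwd[j] * act[j - 1] * inact[j])
            props.append(k_bwd[j] * act[j])
        a0 = sum(props)
        if a0 <= 0.0:
            truncated = True
            break
        if iu + 2 > u.size:
            u = rng.random(block * 2)
            iu = 0
        t += -np.log1p(-u[iu]) / a0
        if t > t_max:
            break
        r = u[iu + 1] * a0
        iu += 2
        acc = 0.0
        for idx, p in enumerate(props):
            acc += p
            if r < acc:
                break
        j, fwd = divmod(idx, 2)
        if fwd == 0:  # activation channel of step j+1
            inact[j] -= 1
            act[j] += 1
            d = 1
        else:
            inact[j] += 1
            act[j] -= 1
            d = -1
        times.append(t)
        steps.append(j + 1)
        dirs.append(d)

    # After absorption the state persists, so the log remains valid to t_max.
    return Trajectory(
        times=np.array(times),
        steps=np.array(steps, dtype=np.int64),
        directions=np.array(dirs, dtype=np.int64),
        initial_state=initial_state.copy(),
        spec=spec,
        t_end=float(t_max),
        seed=seed,
        truncated=truncated,
    )


def solve_steady_state(spec: CascadeSpec) -> OccupancyDistribution:
    """Deterministic mass-action steady state of the cascade.

    The chain is feed-forward in its catalysis (step j's steady active
    level depends only on step j-1's), so the flux balance
    ``k_fwd[j]·a_{j-1}·(totals[j] − a_j) = k_bwd[j]·a_j`` solves exactly
    step by step — no iteration is required.
    """
    a = np.empty(spec.n)
    drive = spec.k_fwd[0] * spec.stimulus
    a[0] = drive * spec.totals[0] / (drive + spec.k_bwd[0])
    for j in range(1, spec.n):
        drive = spec.k_fwd[j] * a[j - 1]
        a[j] = drive * spec.totals[j] / (drive + spec.k_bwd[j])
    X = spec.X_total
    inact = np.array(spec.totals, dtype=float) - a
    return OccupancyDistribution(p=inact / X, p_star=a / X, X=X)


def holding_time_integrals(
    traj: Trajectory, burn_in: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-species occupation time ∫X_j dt and ∫X_j* dt after burn-in.

    Returns ``(T_inactive, T_active, window)`` where ``window`` is the
    post-burn-in duration.  These integrals normalise event counts into
    per-molecule conditional rates.
    """
    if burn_in is None:
        burn_in = DEFAULT_BURN_IN_FRACTION * traj.t_end
    if burn_in >= traj.t_end:
        raise ValueError(
            f"burn_in ({burn_in}) must be smaller than trajectory duration "
            f"({traj.t_end})"
        )
    n = traj.spec.n
    T_in = np.zeros(n)
    T_act = np.zeros(n)
    inact = traj.initial_state.inactive.astype(float).copy()
    act = traj.initial_state.active.astype(float).copy()
    t_prev = 0.0
    for t, s, d in zip(traj.times, traj.steps, traj.directions):
        t = float(t)
        lo = max(t_prev, burn_in)
        if t > lo:
            dt = t - lo
            T_in += inact * dt
            T_act += act * dt
        j = int(s) - 1
        inact[j] -= d
        act[j] += d
        t_prev = t
    lo = max(t_prev, burn_in)
    if traj.t_end > lo:
        dt = traj.t_end - lo
        T_in += inact * dt
        T_act += act * dt
    return T_in, T_act, traj.t_end - burn_in


def time_averaged_occupancy(
    traj: Trajectory, burn_in: float | None = None
) -> OccupancyDistribution:
    """Holding-time-weighted occupancy estimate over the post-burn-in window."""
    T_in, T_act, window = holding_time_integrals(traj, burn_in)
    X = traj.spec.X_total
    return OccupancyDistribution(
        p=T_in / (window * X), p_star=T_act / (window * X), X=X
    )


def occupancy_standard_error(
    traj: Trajectory, burn_in: float | None = None, n_batches: int = 20
) -> np.ndarray:
    """Monte-Carlo SE of the mean active fraction per step, by batch means.

    The post-burn-in window is split into ``n_batches`` equal slabs; the
    SE of the slab means accounts for the autocorrelation of the jump
    process at the slab scale.
    """
    if burn_in is None:
        burn_in = DEFAULT_BURN_IN_FRACTION * traj.t_end
    edges = np.linspace(burn_in, traj.t_end, n_batches + 1)
    n = traj.spec.n
    means = np.zeros((n_batches, n))
    act = traj.initial_state.active.astype(float).copy()
    t_prev = 0.0
    acc = np.zeros((n_batches, n))
    for t, s, d in zip(traj.times, traj.steps, traj.directions):
        t = float(t)
        _accumulate(acc, edges, t_prev, t, act)
        act[int(s) - 1] += d
        t_prev = t
    _accumulate(acc, edges, t_prev, traj.t_end, act)
    widths = np.diff(edges)[:, None]
    means = acc / widths
    totals = np.array(traj.spec.totals, dtype=float)
    frac = means / totals
    return frac.std(axis=0, ddof=1) / np.sqrt(n_batches)


def _accumulate(acc, edges, t0, t1, act):
    """Add act * overlap(t0,t1; batch) to each batch row."""
    if t1 <= edges[0] or t0 >= edges[-1] or t1 <= t0:
        return
    i0 = max(0, int(np.searchsorted(edges, t0, side="right")) - 1)
    i1 = min(len(edges) - 2, int(np.searchsorted(edges, t1, side="left")) - 1)
    for b in range(i0, i1 + 1):
        lo = max(t0, edges[b])
        hi = min(t1, edges[b + 1])
        if hi > lo:
            acc[b] += act * (hi - lo)


# ---------------------------------------------------------------------------
# Trajectory I/O: plain CSV event log + JSON metadata sidecar


def _spec_hash(spec: CascadeSpec) -> str:
    blob = json.dumps(spec.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the event log as CSV (`time,step,direction`) plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": traj.times,
            "step": traj.steps,
            "direction": np.where(traj.directions > 0, "fwd", "bwd"),
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "spec": traj.spec.to_dict(),
        "spec_hash": _spec_hash(traj.spec),
        "seed": traj.seed,
        "t_end": traj.t_end,
        "truncated": traj.truncated,
        "initial_inactive": [int(x) for x in traj.initial_state.inactive],
        "initial_active": [int(x) for x in traj.initial_state.active],
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    spec = CascadeSpec(**meta["spec"])
    init = CascadeState(
        inactive=np.array(meta["initial_inactive"], dtype=np.int64),
        active=np.array(meta["initial_active"], dtype=np.int64),
    )
    directions = np.where(df["direction"].to_numpy() == "fwd", 1, -1)
    return Trajectory(
        times=df["time"].to_numpy(),
        steps=df["step"].to_numpy(),
        directions=directions,
        initial_state=init,
        spec=spec,
        t_end=float(meta["t_end"]),
        seed=meta.get("seed"),
        truncated=bool(meta.get("truncated", False)),
    )
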