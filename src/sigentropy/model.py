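"""Cascade model: parameters, states, occupancies and the reaction network.

A signalling cascade of ``n`` steps is a chain of push--pull
(kinase/phosphatase) cycles.  Each step ``j`` holds a fixed pool of
``totals[j]`` molecules partitioned between an inactive form ``X_j`` and a
phosphorylated active form ``X_j*``.  The active form of step ``j``
catalyses activation of step ``j+1``; a phosphatase deactivates each step
independently.  ATP/ADP/Pi are chemostatted and folded into the effective
rate coefficients, and the receptor stimulus driving step 1 is a constant
scalar multiplying its activation propensity.

Steps are 1-based in all user-facing I/O; arrays are 0-based internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "CascadeSpec",
    "CascadeState",
    "OccupancyDistribution",
    "ReactionChannel",
    "ReactionNetwork",
    "build_network",
    "occupancy_from_state",
    "load_spec",
    "save_spec",
    "SpecError",
]

_NORM_TOL = 1e-12


class SpecError(ValueError):
    """Raised when a cascade specification violates its invariants."""


def _as_float_array(x: Sequence[float], name: str, n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (n,):
        raise SpecError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class CascadeSpec:
    """Parameters of an ``n``-step cascade.

    Parameters
    ----------
    n
        Number of cascade steps (>= 1).
    k_fwd
        Activation rate coefficient per step.  ``k_fwd[j]`` scales the
        activation propensity of step ``j+1`` (1-based): for step 1 the
        propensity is ``k_fwd[0] * stimulus * X_1``; for step j > 1 it is
        ``k_fwd[j-1] * X_{j-1}* * X_j``.
    k_bwd
        Phosphatase (deactivation) rate coefficient per step; the
        deactivation propensity of step j is ``k_bwd[j-1] * X_j*``.
    totals
        Total molecule count per step; ``X_j + X_j* = totals[j]`` is
        conserved (protein turnover is slow on signalling timescales).
    tau
        Signal step durations (time units), used by the coding and
        current layers.
    stimulus
        Constant receptor drive on step 1 (dimensionless multiplier).
    temperature, kB
        Unit convention.  Default ``kB = T = 1`` reports energies in
        units of kB*T.
    """

    n: int
    k_fwd: tuple[float, ...]
    k_bwd: tuple[float, ...]
    totals: tuple[int, ...]
    tau: tuple[float, ...]
    stimulus: float = 1.0
    temperature: float = 1.0
    kB: float = 1.0

    def __post_init__(self) -> None:
        if int(self.n) < 1:
            raise SpecError(f"n must be >= 1, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        for name in ("k_fwd", "tau"):
            arr = _as_float_array(getattr(self, name), name, self.n)
            if np.any(arr <= 0):
                raise SpecError(f"all {name} entries must be > 0")
            object.__setattr__(self, name, tuple(float(x) for x in arr))
        # a vanishing phosphatase rate is legal: it is the irreversible limit
        kb = _as_float_array(self.k_bwd, "k_bwd", self.n)
        if np.any(kb < 0):
            raise SpecError("all k_bwd entries must be >= 0")
        object.__setattr__(self, "k_bwd", tuple(float(x) for x in kb))
        tot = np.asarray(self.totals)
        if tot.shape != (self.n,):
            raise SpecError(f"totals must have length {self.n}")
        if np.any(tot < 1) or np.any(tot != np.floor(tot)):
            raise SpecError("totals must be integers >= 1")
        object.__setattr__(self, "totals", tuple(int(t) for t in tot))
        if self.stimulus < 0:
            raise SpecError("stimulus must be >= 0")
        if self.temperature <= 0 or self.kB <= 0:
            raise SpecError("temperature and kB must be > 0")

    @property
    def X_total(self) -> int:
        """Total molecule count across all steps (Σ totals)."""
        return int(sum(self.totals))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "k_fwd": list(self.k_fwd),
            "k_bwd": list(self.k_bwd),
            "totals": list(self.totals),
            "tau": list(self.tau),
            "stimulus": self.stimulus,
            "temperature": self.temperature,
            "kB": self.kB,
        }


@dataclass
class CascadeState:
    """Molecule counts per step at a moment in time."""

    inactive: np.ndarray
    active: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.inactive = np.asarray(self.inactive, dtype=np.int64)
        self.active = np.asarray(self.active, dtype=np.int64)
        if self.inactive.shape != self.active.shape or self.inactive.ndim != 1:
            raise ValueError("inactive and active must be 1-D arrays of equal length")
        if np.any(self.inactive < 0) or np.any(self.active < 0):
            raise ValueError("molecule counts must be nonnegative")
        if self.time < 0:
            raise ValueError("time must be nonnegative")

    @property
    def totals(self) -> np.ndarray:
        return self.inactive + self.active

    def copy(self) -> "CascadeState":
        return CascadeState(self.inactive.copy(), self.active.copy(), self.time)


@dataclass(frozen=True)
class OccupancyDistribution:
    """Occurrence probabilities of the 2n molecular forms.

    ``p[j]`` is the fraction of the whole pool in the inactive form of
    step j+1 and ``p_star[j]`` the fraction in its active form; they sum
    to 1 over all forms.  These double as the selection probabilities of
    the symbols in the message-coding picture.
    """

    p: np.ndarray
    p_star: np.ndarray
    X: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        object.__setattr__(self, "p_star", np.asarray(self.p_star, dtype=float))
        if self.p.shape != self.p_star.shape or self.p.ndim != 1:
            raise ValueError("p and p_star must be 1-D arrays of equal length")
        if np.any(self.p < -_NORM_TOL) or np.any(self.p_star < -_NORM_TOL):
            raise ValueError("probabilities must be nonnegative")
        if np.any(self.p > 1 + _NORM_TOL) or np.any(self.p_star > 1 + _NORM_TOL):
            raise ValueError("probabilities must be <= 1")
        total = float(self.p.sum() + self.p_star.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancies must sum to 1, got {total!r}")
        if self.X < 1:
            raise ValueError("X must be >= 1")

    @property
    def n(self) -> int:
        return self.p.shape[0]

    @property
    def p0(self) -> np.ndarray:
        """Conserved per-step pool fraction p_j + p_j* = totals[j]/X."""
        return self.p + self.p_star

    def log_odds(self) -> np.ndarray:
        """ln(p_j / p_j*) per step; rejects degenerate occupancies.

        The log-odds diverge when either form is absent, which corrupts
        every downstream current, so zeros raise instead of returning inf.
        """
        if np.any(self.p <= 0) or np.any(self.p_star <= 0):
            raise ValueError(
                "log-odds undefined: some occupancy is zero; "
                "currents require both forms present at every step"
            )
        return np.log(self.p / self.p_star)


# ---------------------------------------------------------------------------
# Reaction network


@dataclass(frozen=True)
class ReactionChannel:
    """One mass-action channel of the cascade network.

    ``step`` is the 1-based index of the species whose state changes;
    ``direction`` is "fwd" (activation, X_step -> X_step*) or "bwd"
    (deactivation).  ``propensity`` maps a CascadeState to the channel's
    mass-action rate.
    """

    step: int
    direction: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    propensity: Callable[[CascadeState], float] = field(compare=False)

    def __post_init__(self) -> None:
        if self.direction not in ("fwd", "bwd"):
            raise ValueError("direction must be 'fwd' or 'bwd'")


@dataclass(frozen=True)
class ReactionNetwork:
    spec: CascadeSpec
    channels: tuple[ReactionChannel, ...]

    def propensities(self, state: CascadeState) -> np.ndarray:
        return np.array([ch.propensity(state) for ch in self.channels])


def build_network(spec: CascadeSpec) -> ReactionNetwork:
    """Construct the 2n reaction channels of the cascade.

    For each step j (1-based) there is an activation channel
    (catalysed by the active form of step j-1, or by the constant
    stimulus for j = 1) and a phosphatase deactivation channel.
    ATP/ADP/Pi never appear: they are chemostatted baths absorbed into
    the effective coefficients.
    """
    channels: list[ReactionChannel] = []
    for j in range(spec.n):  # 0-based internal index
        if j == 0:
            prop = _stimulus_propensity(spec.k_fwd[0], spec.stimulus)
            reactants = ("stimulus", "X1")
            products = ("stimulus", "X1*")
        else:
            prop = _catalytic_propensity(spec.k_fwd[j], j)
            reactants = (f"X{j}*", f"X{j + 1}")
            products = (f"X{j}*", f"X{j + 1}*")
        channels.append(
            ReactionChannel(
                step=j + 1,
                direction="fwd",
                reactants=reactants,
                products=products,
                propensity=prop,
            )
        )
        channels.append(
            ReactionChannel(
                step=j + 1,
                direction="bwd",
                reactants=(f"X{j + 1}*",),
                products=(f"X{j + 1}",),
                propensity=_decay_propensity(spec.k_bwd[j], j),
            )
        )
    return ReactionNetwork(spec=spec, channels=tuple(channels))


def _stimulus_propensity(k: float, stimulus: float):
    def prop(state: CascadeState) -> float:
        return k * stimulus * state.inactive[0]

    return prop


def _catalytic_propensity(k: float, j: int):
    def prop(state: CascadeState) -> float:
        return k * state.active[j - 1] * state.inactive[j]

    return prop


def _decay_propensity(k: float, j: int):
    def prop(state: CascadeState) -> float:
        return k * state.active[j]

    return prop


def occupancy_from_state(state: CascadeState) -> OccupancyDistribution:
    """Occurrence probabilities p_j = X_j / X, p_j* = X_j* / X."""
    X = int(state.inactive.sum() + state.active.sum())
    if X == 0:
        raise ValueError("cannot form occupancies from an empty state (X = 0)")
    return OccupancyDistribution(
        p=state.inactive / X, p_star=state.active / X, X=X
    )


# ---------------------------------------------------------------------------
# Spec file I/O

_SPEC_KEYS = {"n", "k_fwd", "k_bwd", "totals", "tau", "stimulus", "temperature", "kB"}


def load_spec(path: str | Path) -> CascadeSpec:
    """Load a cascade spec from YAML or JSON with schema validation."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise SpecError(f"{path}: cannot parse spec file: {exc}") from exc
    if not isinstance(data, dict):
        raise SpecError(f"{path}: spec file must contain a mapping")
    unknown = set(data) - _SPEC_KEYS
    if unknown:
        raise SpecError(f"{path}: unknown keys {sorted(unknown)}")
    missing = {"n", "k_fwd", "k_bwd", "totals", "tau"} - set(data)
    if missing:
        raise SpecError(f"{path}: missing required keys {sorted(missing)}")
    try:
        return CascadeSpec(**data)
    except SpecError as exc:
        raise SpecError(f"{path}: {exc}") from exc


def save_spec(spec: CascadeSpec, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(spec.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))
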