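"""Entropy signal currents, the rate parameter zeta, and the average
entropy production current J.

The current density c_j = kB T ln(p_j/p_j*) is the per-molecule
thermodynamic drive of step j; the signal current C_j = c_j * dX_j* is
the drive times the active-count fluctuation it moves.  For a cascade
whose occurrence probabilities follow the maximal-rate coding law
-ln p_j = zeta * tau_j with a step-independent zeta, the average entropy
production current J = kB T zeta is the same at every step.

Sign convention: as printed, the defining relations carry opposite signs
(zeta = -C_j/(kB T tau_j) versus J = kB T zeta > 0).  This module reports
magnitudes together with an explicit sign field rather than silently
choosing one orientation; `zeta_from_occurrence` itself is unambiguous
(-ln p_j / tau_j > 0 whenever p_j < 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import OccupancyDistribution

__all__ = [
    "CurrentReport",
    "current_density",
    "signal_current",
    "zeta_from_occurrence",
    "solve_capacity_zeta",
    "average_entropy_production",
    "current_report",
]


@dataclass(frozen=True)
class CurrentReport:
    """Per-step currents and the pooled cascade-level quantities."""

    c: np.ndarray                  # current density kB T ln(p_j/p_j*)
    C: np.ndarray                  # signal current c_j * dX_j*
    zeta_per_step: np.ndarray      # -ln(p_j)/tau_j
    zeta: float                    # pooled
    zeta_dispersion: float         # max relative deviation from pooled
    J: np.ndarray                  # kB T zeta_j, per step
    sign: np.ndarray               # sign of c_j (direction of the drive)


def current_density(p_j: float, p_star_j: float, kB: float = 1.0, T: float = 1.0) -> float:
    """c_j = kB T ln(p_j / p_j*); antisymmetric in (p_j, p_j*), zero at p = p*."""
    if p_j <= 0 or p_star_j <= 0:
        raise ValueError("current density undefined for zero or negative occupancies")
    if p_j >= 1 or p_star_j >= 1:
        raise ValueError("occupancies must lie in (0, 1)")
    return float(kB * T * np.log(p_j / p_star_j))


def signal_current(
    p_j: float,
    p_star_j: float,
    delta_X_star: float,
    kB: float = 1.0,
    T: float = 1.0,
) -> float:
    """C_j = c_j * dX_j*, the entropy carried by an active-count fluctuation."""
    return current_density(p_j, p_star_j, kB, T) * delta_X_star


def zeta_from_occurrence(
    p, tau, weighted: bool = True
) -> tuple[np.ndarray, float, float]:
    """Per-step rate parameter zeta_j = -ln(p_j)/tau_j and its pooling.

    Returns ``(zeta_per_step, zeta_pooled, dispersion)``.  ``dispersion``
    is max_j |zeta_j - zeta_pooled| / zeta_pooled: it vanishes exactly
    when the occupancies obey -ln p_j = zeta tau_j with one zeta, i.e.
    when the cascade's entropy production rate is step-independent.
    Pooling is duration-weighted by default (``weighted=False`` gives the
    plain mean).
    """
    p = np.asarray(p, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if p.shape != tau.shape or p.ndim != 1:
        raise ValueError("p and tau must be 1-D arrays of equal length")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("occurrence probabilities must lie in (0, 1)")
    if np.any(tau <= 0):
        raise ValueError("durations must be positive")
    zeta_j = -np.log(p) / tau
    if weighted:
        pooled = float(np.sum(zeta_j * tau) / np.sum(tau))
    else:
        pooled = float(zeta_j.mean())
    dispersion = float(np.max(np.abs(zeta_j - pooled)) / pooled) if pooled else np.inf
    return zeta_j, pooled, dispersion


def solve_capacity_zeta(tau, tol: float = 1e-14) -> float:
    """Rate parameter of a maximal-rate code with symbol durations tau.

    Solves sum_j exp(-zeta tau_j) = 1 for the unique zeta > 0 (the
    Kraft-equality closure: occurrence probabilities p_j = exp(-zeta
    tau_j) exhaust the pool when the message rate is maximised).
    Requires n >= 2 — a single symbol admits no positive root.

    Satisfies the rescaling law zeta(a*tau) = zeta(tau)/a.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 1 or tau.size < 1:
        raise ValueError("tau must be a 1-D array")
    if np.any(tau <= 0):
        raise ValueError("durations must be positive")
    if tau.size == 1:
        raise ValueError(
            "capacity rate undefined for a single symbol: "
            "sum exp(-zeta*tau) = 1 has no positive root"
        )

    def f(z: float) -> float:
        return np.exp(-z * tau).sum() - 1.0

    lo = 1e-12
    hi = np.log(tau.size) / tau.min() + 1.0  # f(hi) < 0 guaranteed
    while f(hi) > 0:
        hi *= 2
    return float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


def average_entropy_production(zeta: float, kB: float = 1.0, T: float = 1.0) -> float:
    """J = kB T zeta, the average entropy production current per step."""
    return float(kB * T * zeta)


def current_report(
    occ: OccupancyDistribution,
    tau,
    delta_X_star=None,
    kB: float = 1.0,
    T: float = 1.0,
    weighted: bool = True,
) -> CurrentReport:
    """Assemble the full per-step current report from an occupancy.

    ``delta_X_star`` (scalar or per-step) sets the fluctuation amplitude
    used for the signal currents C_j; it defaults to 1 (a single
    activation event).
    """
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (occ.n,):
        raise ValueError(f"tau must have length {occ.n}")
    if delta_X_star is None:
        delta_X_star = 1.0
    dX = np.broadcast_to(np.asarray(delta_X_star, dtype=float), (occ.n,))
    log_odds = occ.log_odds()
    c = kB * T * log_odds
    C = c * dX
    zeta_j, zeta_pooled, disp = zeta_from_occurrence(occ.p, tau, weighted=weighted)
    J = kB * T * zeta_j
    return CurrentReport(
        c=c,
        C=C,
        zeta_per_step=zeta_j,
        zeta=zeta_pooled,
        zeta_dispersion=disp,
        J=J,
        sign=np.sign(c),
    )
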