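"""Multiplicity, Shannon/Stirling entropy and mixing-entropy changes.

The number of distinguishable arrangements of X molecules over the 2n
forms is the multinomial multiplicity psi = X! / (prod X_j! prod X_j*!);
its logarithm, via Stirling's approximation, is the mixing (Shannon)
entropy S = -kB X sum (p log p) in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

from .model import OccupancyDistribution

__all__ = [
    "EntropyReport",
    "log_multiplicity",
    "stirling_entropy",
    "mixing_entropy_change",
    "entropy_report",
]


@dataclass(frozen=True)
class EntropyReport:
    """Exact log-multiplicity, Stirling entropy and per-step mixing changes."""

    log_psi_exact: float
    S_stirling: float
    dS_mix: np.ndarray | None = None
    dS_baseline: np.ndarray | None = None


def log_multiplicity(counts_inactive, counts_active) -> float:
    """ln psi = ln X! - sum ln X_j! - sum ln X_j*!, exact via log-gamma.

    Symmetric under any permutation of the counts; 0 when all molecules
    sit in a single form (only one arrangement).
    """
    ci = np.asarray(counts_inactive, dtype=float)
    ca = np.asarray(counts_active, dtype=float)
    if np.any(ci < 0) or np.any(ca < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(ci != np.floor(ci)) or np.any(ca != np.floor(ca)):
        raise ValueError("counts must be integers")
    X = ci.sum() + ca.sum()
    if X < 1:
        raise ValueError("at least one count must be positive")
    return float(gammaln(X + 1) - gammaln(ci + 1).sum() - gammaln(ca + 1).sum())


def stirling_entropy(occ: OccupancyDistribution, kB: float = 1.0) -> float:
    """Mixing entropy S = -kB X (sum p_j ln p_j + sum p_j* ln p_j*).

    Zero-probability forms contribute 0 (the p ln p -> 0 limit); the
    entropy, unlike the currents, is continuous there.
    """
    s = xlogy(occ.p, occ.p).sum() + xlogy(occ.p_star, occ.p_star).sum()
    return float(-kB * occ.X * s)


def mixing_entropy_change(
    p_j: float,
    p_star_j: float,
    dp_star: float,
    X: float,
    kB: float = 1.0,
) -> tuple[float, float]:
    """Mixing entropy of step j under an active-form fluctuation.

    A fluctuation moves probability dp_star from the inactive to the
    active form (dp_j = -dp_star, conservation within the step).  Returns
    ``(dS_mix, dS_baseline)``:

    - ``dS_mix``: the step's binary mixing entropy at the perturbed
      occupancies, -kB X [(p_j - dp*) ln(p_j - dp*) + (p_j* + dp*) ln(p_j* + dp*)];
    - ``dS_baseline``: the same expression at the unperturbed
      occupancies (the adjacent step, which has not yet responded).

    Their difference is the entropy change that drives the signal; its
    derivative at dp_star = 0 is kB X ln(p_j/p_j*), the current density
    per molecule.
    """
    if not (0 < p_j < 1 and 0 < p_star_j < 1):
        raise ValueError("p_j and p_star_j must lie in (0, 1)")
    p_new = p_j - dp_star
    ps_new = p_star_j + dp_star
    if not (0 < p_new < 1 and 0 < ps_new < 1):
        raise ValueError(
            "perturbation pushes occupancies out of (0, 1): "
            f"p -> {p_new}, p* -> {ps_new}"
        )
    dS_mix = -kB * X * (p_new * np.log(p_new) + ps_new * np.log(ps_new))
    dS_base = -kB * X * (p_j * np.log(p_j) + p_star_j * np.log(p_star_j))
    return float(dS_mix), float(dS_base)


def entropy_report(
    counts_inactive,
    counts_active,
    kB: float = 1.0,
    dp_star: float | None = None,
) -> EntropyReport:
    """Build an EntropyReport from raw per-step counts.

    When ``dp_star`` is given, per-step mixing-entropy changes are
    evaluated at that common fluctuation size.
    """
    ci = np.asarray(counts_inactive, dtype=float)
    ca = np.asarray(counts_active, dtype=float)
    X = ci.sum() + ca.sum()
    from .model import OccupancyDistribution as _OD

    occ = _OD(p=ci / X, p_star=ca / X, X=X)
    log_psi = log_multiplicity(counts_inactive, counts_active)
    S = stirling_entropy(occ, kB=kB)
    dS_mix = dS_base = None
    if dp_star is not None:
        dS_mix = np.empty(occ.n)
        dS_base = np.empty(occ.n)
        for j in range(occ.n):
            dS_mix[j], dS_base[j] = mixing_entropy_change(
                occ.p[j], occ.p_star[j], dp_star, X, kB
            )
    return EntropyReport(
        log_psi_exact=log_psi, S_stirling=S, dS_mix=dS_mix, dS_baseline=dS_base
    )
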