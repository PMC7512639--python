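"""Transport picture: diffusion/mobility identities and spatial entropy
current gradients.

In model units (kB = T = 1) the current density c_j is identified with a
diffusion coefficient D_j of the signal, and the Einstein relation
D_j = kB T omega_j defines the signal mobility omega_j = ln(p_j/p_j*).
The identification equates an energy-scaled log-odds with a diffusion
coefficient; interpreting it in SI units requires a user-supplied
length^2/time conversion factor, which this module does not invent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpatialProfile",
    "diffusion_from_density",
    "mobility",
    "entropy_current_gradient",
    "GradientField",
]


@dataclass(frozen=True)
class SpatialProfile:
    """Active-count densities X_j*(r) on a uniform 1-D grid.

    ``X_star_profile`` has shape (n_steps, n_grid).
    """

    r: np.ndarray
    X_star_profile: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        object.__setattr__(
            self, "X_star_profile", np.atleast_2d(np.asarray(self.X_star_profile, dtype=float))
        )
        if self.r.ndim != 1 or self.r.size < 3:
            raise ValueError("grid must be 1-D with at least 3 points")
        d = np.diff(self.r)
        if np.any(d <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=0):
            raise ValueError("grid must be uniform")
        if self.X_star_profile.shape[1] != self.r.size:
            raise ValueError("profile width must match grid length")
        if np.any(self.X_star_profile < 0):
            raise ValueError("densities must be nonnegative")

    @property
    def spacing(self) -> float:
        return float(self.r[1] - self.r[0])


@dataclass(frozen=True)
class GradientField:
    """Per-step spatial fields derived from an active-count profile."""

    grad_X_star: np.ndarray    # ∇_r X_j*(r)
    grad_C: np.ndarray         # -c_j ∇_r X_j*  (entropy current gradient)
    grad_J: np.ndarray         # -c_j ∇_r X_j* / tau_j (per signal duration)


def diffusion_from_density(c_j: float) -> float:
    """Identify the diffusion coefficient with the current density, D_j = c_j."""
    if not np.isfinite(c_j):
        raise ValueError("current density must be finite")
    return float(c_j)


def mobility(D_j: float, kB: float = 1.0, T: float = 1.0) -> float:
    """Signal mobility from the Einstein relation, omega_j = D_j / (kB T)."""
    if kB * T <= 0:
        raise ValueError("kB*T must be positive")
    return float(D_j / (kB * T))


def entropy_current_gradient(profile: SpatialProfile, c, tau) -> GradientField:
    """Spatial gradient fields of the entropy current.

    Uses second-order central differences (second-order one-sided at the
    boundaries), so linear profiles give exactly constant fields and
    quadratic profiles are differentiated exactly.
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    n = profile.X_star_profile.shape[0]
    if c.shape != (n,) or tau.shape != (n,):
        raise ValueError(f"c and tau must have length {n}")
    if np.any(tau <= 0):
        raise ValueError("durations must be positive")
    grad = np.gradient(profile.X_star_profile, profile.spacing, axis=1, edge_order=2)
    grad_C = -c[:, None] * grad
    grad_J = grad_C / tau[:, None]
    return GradientField(grad_X_star=grad, grad_C=grad_C, grad_J=grad_J)
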