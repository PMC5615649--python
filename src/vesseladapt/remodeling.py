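"""Collagen turnover and prescribed elastin degradation on the slow time scale.

Collagen in the wall is continuously degraded and redeposited; new fibers are
integrated at the *attachment stretch* ``lambda_a``, so the gap between the
current fiber stretch and the attachment stretch is the mechanosensed signal
driving turnover.  In terms of squared stretches the normalized stimulus is

    xi = (I4c - I4a) / (I4a - 1),       I4a = lambda_a**2,

which vanishes at homeostasis (fibers loaded exactly at attachment stretch)
and equals -1 for a fully slack fiber.  The stimulus drives two state
variables per fiber family on the remodeling time tau (years):

    d(lambda_r)/d(tau) = alpha * xi          (recruitment-stretch remodeling)
    d(m_hat_c)/d(tau)  = beta * m_hat_c * xi (net mass production)

integrated with explicit forward Euler (rates are O(1)/year and trajectories
smooth; convergence is exercised in the tests rather than assumed).

Elastin is not regenerated in the adult aorta; aneurysm onset is emulated by
the prescribed axial degradation profile

    m_hat_e(z, tau) = 1 - (1 - c_min**(tau/T)) * exp(-m1 (2 z/L - 1)**2),

which leaves the fraction ``c_min`` at the vessel center ``z = L/2`` after
the degradation time ``T`` and keeps decaying for ``tau > T``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RemodelingParams",
    "CollagenState",
    "stimulus",
    "step_recruitment",
    "step_collagen_mass",
    "elastin_mass",
]

#: lower bound applied to the recruitment stretch; values below 1 have no
#: physical reading in the recruitment picture (fibers deposited longer than
#: the tissue) and only arise from prolonged slackness.
LAMBDA_R_FLOOR = 1.0


@dataclass
class RemodelingParams:
    """Rates and targets of collagen turnover plus elastin-decay parameters.

    alpha, beta : year^-1
        Recruitment-stretch remodeling rate and collagen net-growth rate.
    lambda_a : attachment (deposition) stretch of new collagen, > 1.
    lambda_rec0 : initial recruitment stretch before homeostasis.
    c_min, T, m1, L : elastin degradation law — residual central fraction,
        degradation time (years), axial shape parameter, vessel length (mm).
    """

    alpha: float = 0.6
    beta: float = 1.0
    lambda_a: float = 1.093
    lambda_rec0: float = 1.13
    c_min: float = 0.6
    T: float = 10.0
    m1: float = 20.0
    L: float = 147.4

    def __post_init__(self) -> None:
        if self.alpha <= 0.0 or self.beta <= 0.0 or self.T <= 0.0:
            raise ValueError("alpha, beta and T must be positive")
        if self.lambda_a <= 1.0:
            raise ValueError("attachment stretch lambda_a must exceed 1")
        if not 0.0 < self.c_min <= 1.0:
            raise ValueError("c_min must lie in (0, 1]")
        if self.m1 < 0.0:
            raise ValueError("m1 must be non-negative")

    @property
    def I4a(self) -> float:
        """Squared attachment stretch."""
        return self.lambda_a**2


@dataclass
class CollagenState:
    """Remodeling state of one collagen family at a material point."""

    lambda_r: float
    m_hat_c: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_r <= 0.0:
            raise ValueError("lambda_r must be positive")
        if self.m_hat_c <= 0.0:
            raise ValueError("m_hat_c must be positive")


def stimulus(I4c, params: RemodelingParams, form: str = "difference"):
    """Normalized stretch-based turnover stimulus.

    ``form="difference"`` (default) uses ``(I4c - I4a)/(I4a - 1)``;
    ``form="ratio"`` is an alternative normalization ``I4c/I4a - 1`` kept as
    a sensitivity switch.  Both vanish at homeostasis; the difference form
    maps a fully slack fiber (``I4c = 1``) to exactly -1.
    """
    if params.lambda_a <= 1.0:
        raise ValueError("lambda_a must exceed 1 (degenerate stimulus denominator)")
    I4c = np.asarray(I4c, dtype=float)
    if np.any(I4c < 1.0):
        raise ValueError("I4c must be >= 1")
    I4a = params.I4a
    if form == "difference":
        out = (I4c - I4a) / (I4a - 1.0)
    elif form == "ratio":
        out = I4c / I4a - 1.0
    else:
        raise ValueError(f"unknown stimulus form {form!r}")
    return float(out) if np.ndim(out) == 0 else out


def step_recruitment(
    s: CollagenState, xi: float, params: RemodelingParams, dtau: float
) -> CollagenState:
    """One forward-Euler step of the recruitment stretch: ``+ alpha xi dtau``."""
    if dtau <= 0.0:
        raise ValueError("dtau must be positive")
    lam = s.lambda_r + params.alpha * xi * dtau
    if lam <= 0.0:
        raise ValueError(
            f"recruitment stretch stepped to {lam}; reduce the step size"
        )
    if lam < LAMBDA_R_FLOOR:
        warnings.warn(
            "recruitment stretch fell below 1 and was floored", stacklevel=2
        )
        lam = LAMBDA_R_FLOOR
    return replace(s, lambda_r=lam)


def step_collagen_mass(
    s: CollagenState, xi: float, params: RemodelingParams, dtau: float
) -> CollagenState:
    """One forward-Euler step of collagen mass: ``*= (1 + beta xi dtau)``."""
    if dtau <= 0.0:
        raise ValueError("dtau must be positive")
    m = s.m_hat_c * (1.0 + params.beta * xi * dtau)
    if m <= 0.0:
        raise ValueError(f"collagen mass stepped to {m}; reduce the step size")
    return replace(s, m_hat_c=m)


def elastin_mass(z, tau, params: RemodelingParams):
    """Prescribed normalized elastin mass ``m_hat_e(z, tau)``.

    Monotone non-increasing in ``tau`` (equal to 1 at ``tau = 0``), minimal at
    the vessel center ``z = L/2`` where it reaches ``c_min`` at ``tau = T``
    and keeps decaying as ``c_min**(tau/T)`` thereafter.  ``z`` is the axial
    Lagrangian coordinate in [0, L]; vectorized in both arguments.
    """
    z = np.asarray(z, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(z < 0.0) or np.any(z > params.L):
        raise ValueError(f"z must lie in [0, L={params.L}]")
    if np.any(tau < 0.0):
        raise ValueError("tau must be non-negative")
    decay = 1.0 - params.c_min ** (tau / params.T)
    profile = np.exp(-params.m1 * np.square(2.0 * z / params.L - 1.0))
    out = 1.0 - decay * profile
    return float(out) if np.ndim(out) == 0 else out
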