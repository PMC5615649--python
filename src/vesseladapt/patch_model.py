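"""Closed-form equi-biaxial patch model: growth kinematics made visible.

A square patch of vessel wall (referential dimensions L x L x H, only ratios
matter) is stretched equi-biaxially in its plane, ``F = diag(lam, lam, lam3)``
with the out-of-plane stretch ``lam3`` following from elastic
incompressibility ``det Fe = 1``.  The wall is taken as a single-constituent
neo-Hookean material, so the first Piola-Kirchhoff stress has closed forms
per growth kinematics:

    IVG:  P = rho_hat * v_hat**(1/3) * mu * (lam - v_hat**2 * lam**-5)
    PVG:  P = rho_hat * mu * (lam - v_hat**3 * lam**-5)
    TVG:  P = rho_hat * v_hat * mu * (lam - lam**-5) = m_hat * mu * (lam - lam**-5)
    NVG:  the v_hat = 1 form of any of the above.

These expressions expose what each kinematics does to the patch: in-plane
growth (PVG) changes the stress-free edge length (stress-free at
``lam = sqrt(v_hat)``), in-thickness growth (TVG) only rescales the stress
level, and isotropic growth (IVG) mixes both effects.  The module doubles as
the analytic oracle for the generic kinematics + constitutive pipeline.

``rho_hat`` and ``v_hat`` enter as independent inputs here; the CCD/CCV link
between them is applied only when states are built through the mixture
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import KinematicsKind

__all__ = [
    "PatchState",
    "patch_elastic_deformation",
    "patch_biaxial_stress",
    "patch_curves",
]


@dataclass
class PatchState:
    """Equi-biaxial patch state: stretch, growth, density and stiffness."""

    lam: float
    v_hat: float = 1.0
    rho_hat: float = 1.0
    mu: float = 1.0
    kind: KinematicsKind = KinematicsKind.NVG

    def __post_init__(self) -> None:
        self.kind = KinematicsKind(self.kind)
        if self.lam <= 0.0:
            raise ValueError("in-plane stretch must be positive")
        if self.v_hat <= 0.0:
            raise ValueError("v_hat must be positive")
        if self.kind is KinematicsKind.NVG and abs(self.v_hat - 1.0) > 1e-12:
            raise ValueError("NVG kinematics requires v_hat == 1")


def patch_elastic_deformation(s: PatchState) -> np.ndarray:
    """Elastic deformation ``Fe`` of the patch, with ``det Fe = 1`` exactly.

    The total out-of-plane stretch ``lam3 = v_hat / lam**2`` follows from the
    incompressible elastic response for every kinematics kind; the returned
    diagonal tensors are the growth-specific elastic splits.
    """
    lam, v = s.lam, s.v_hat
    lam3 = v / lam**2
    if s.kind is KinematicsKind.IVG:
        diag = v ** (-1.0 / 3.0) * np.array([lam, lam, lam3])
    elif s.kind is KinematicsKind.PVG:
        rv = v ** (-0.5)
        diag = np.array([rv * lam, rv * lam, lam3])
    elif s.kind is KinematicsKind.TVG:
        diag = np.array([lam, lam, lam3 / v])
    else:  # NVG, v_hat == 1
        diag = np.array([lam, lam, lam3])
    return np.diag(diag)


def patch_biaxial_stress(s: PatchState) -> float:
    """First Piola-Kirchhoff stress ``P = F0 / (L H)`` (kPa) of the patch."""
    lam, v, rho, mu = s.lam, s.v_hat, s.rho_hat, s.mu
    if s.kind is KinematicsKind.IVG:
        return rho * v ** (1.0 / 3.0) * mu * (lam - v**2 * lam**-5)
    if s.kind is KinematicsKind.PVG:
        return rho * mu * (lam - v**3 * lam**-5)
    if s.kind is KinematicsKind.TVG:
        return rho * v * mu * (lam - lam**-5)
    return rho * mu * (lam - lam**-5)


def patch_curves(
    kinds,
    v_hat_list,
    lam_grid,
    rho_hat: float = 1.0,
    mu: float = 1.0,
) -> pd.DataFrame:
    """Stress-stretch curves ``P/mu`` over a grid, long format.

    One row per (kind, v_hat, lam), deterministic order (kinds, then v_hat,
    then lam).  ``kinds`` may be a single kind or an iterable.
    """
    if isinstance(kinds, (str, KinematicsKind)):
        kinds = [kinds]
    kinds = [KinematicsKind(k) for k in kinds]
    v_hat_list = list(np.atleast_1d(np.asarray(v_hat_list, dtype=float)))
    lam_grid = list(np.atleast_1d(np.asarray(lam_grid, dtype=float)))
    if not kinds or not v_hat_list or not lam_grid:
        raise ValueError("kinds, v_hat_list and lam_grid must be non-empty")
    rows = []
    for kind in kinds:
        for v in v_hat_list:
            if kind is KinematicsKind.NVG and abs(v - 1.0) > 1e-12:
                continue  # NVG admits only v_hat = 1
            for lam in lam_grid:
                st = PatchState(lam=lam, v_hat=v, rho_hat=rho_hat, mu=mu, kind=kind)
                rows.append(
                    {
                        "kind": kind.value,
                        "v_hat": v,
                        "lam": lam,
                        "P_over_mu": patch_biaxial_stress(st) / mu,
                    }
                )
    return pd.DataFrame(rows, columns=["kind", "v_hat", "lam", "P_over_mu"])
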