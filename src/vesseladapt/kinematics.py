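"""Growth kinematics: multiplicative split, growth tensors, fiber invariants.

The total deformation gradient of an adapting tissue is decomposed as
``F = Fe @ Fg``: the growth tensor ``Fg`` carries the slow (weeks-to-years)
change of the stress-free configuration, the elastic part ``Fe`` the fast,
nearly incompressible response to loading.  The scalar tissue volume change
``v_hat`` (from the mixture bookkeeping) constrains ``det Fg = v_hat`` but
not the *shape* of growth, which is prescribed by a transversely anisotropic
family

    Fg = a * I + b * n (x) n,

with ``n`` the unit normal of the collagen tangent plane (radial direction
in a vessel wall).  Four particularizations are used:

* ``IVG`` — isotropic volume growth, ``Fg = v_hat**(1/3) I``;
* ``PVG`` — in-plane growth, ``Fg = sqrt(v_hat) I + (1 - sqrt(v_hat)) n(x)n``;
* ``TVG`` — in-thickness growth, ``Fg = I + (v_hat - 1) n(x)n``;
* ``NVG`` — no volume growth, ``Fg = I`` (requires ``v_hat == 1``, i.e. an
  all-CCV deposition assignment).

The module also provides the isochoric elastic invariants and the clamped
squared collagen-fiber stretch ``I4c = max(I4bar / lambda_r**2, 1)``, where
the recruitment stretch ``lambda_r`` is the tissue stretch along the fiber
at which the undulated fiber starts to bear load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "KinematicsKind",
    "GrowthState",
    "DeformationState",
    "FiberFamily",
    "growth_tensor",
    "elastic_part",
    "isochoric_invariants",
    "fiber_stretch_sq",
    "wall_normal",
]

_I3 = np.eye(3)


class KinematicsKind(str, Enum):
    """How the scalar volume change maps onto the growth tensor."""

    IVG = "IVG"
    PVG = "PVG"
    TVG = "TVG"
    NVG = "NVG"


@dataclass
class GrowthState:
    """Local growth state: volume change, wall normal and kinematics kind."""

    v_hat: float
    n: np.ndarray
    kind: KinematicsKind

    def __post_init__(self) -> None:
        self.kind = KinematicsKind(self.kind)
        self.n = np.asarray(self.n, dtype=float)
        if self.v_hat <= 0.0:
            raise ValueError(f"v_hat must be positive, got {self.v_hat}")
        if self.n.shape != (3,):
            raise ValueError("wall normal must be a 3-vector")
        if abs(np.linalg.norm(self.n) - 1.0) > 1e-12:
            raise ValueError("wall normal must be a unit vector")


@dataclass
class FiberFamily:
    """A collagen fiber family: referential direction and recruitment stretch."""

    a0: np.ndarray
    lambda_r: float = 1.0
    index: int = 1

    def __post_init__(self) -> None:
        self.a0 = np.asarray(self.a0, dtype=float)
        nrm = np.linalg.norm(self.a0)
        if not np.isfinite(nrm) or abs(nrm - 1.0) > 1e-9:
            raise ValueError("fiber direction a0 must be a unit vector")
        if self.lambda_r <= 0.0:
            raise ValueError(f"recruitment stretch must be positive, got {self.lambda_r}")

    @property
    def A0(self) -> np.ndarray:
        """Referential structural tensor ``a0 (x) a0``."""
        return np.outer(self.a0, self.a0)


@dataclass
class DeformationState:
    """Bundle of the multiplicative split ``F = Fe @ Fg`` with derived parts."""

    F: np.ndarray
    Fg: np.ndarray
    Fe: np.ndarray = field(init=False)
    Je: float = field(init=False)
    Fbar: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.Fg = np.asarray(self.Fg, dtype=float)
        self.Fe = elastic_part(self.F, self.Fg)
        self.Je = float(np.linalg.det(self.Fe))
        if self.Je <= 0.0:
            raise ValueError("elastic deformation must have positive determinant")
        self.Fbar = self.Je ** (-1.0 / 3.0) * self.Fe


def wall_normal(a01: np.ndarray, a02: np.ndarray) -> np.ndarray:
    """Unit normal of the collagen tangent plane, ``n = a01 x a02 / |.|``.

    Raises for (anti)parallel fiber directions, which leave the plane
    undefined.
    """
    n = np.cross(np.asarray(a01, float), np.asarray(a02, float))
    nrm = np.linalg.norm(n)
    if nrm < 1e-12:
        raise ValueError("fiber directions are parallel; tangent plane undefined")
    return n / nrm


def growth_tensor(g: GrowthState) -> np.ndarray:
    """Growth tensor ``Fg`` for the given kinematics kind.

    Satisfies ``det Fg = v_hat`` for IVG/PVG/TVG and ``Fg = I`` for NVG.
    """
    v = float(g.v_hat)
    if v <= 0.0:
        raise ValueError(f"v_hat must be positive, got {v}")
    nn = np.outer(g.n, g.n)
    if g.kind is KinematicsKind.IVG:
        return v ** (1.0 / 3.0) * _I3
    if g.kind is KinematicsKind.PVG:
        s = np.sqrt(v)
        return s * _I3 + (1.0 - s) * nn
    if g.kind is KinematicsKind.TVG:
        return _I3 + (v - 1.0) * nn
    # NVG: isochoric growth; the configuration layer guarantees v_hat == 1.
    return _I3.copy()


def growth_stretches(v_hat, kind: KinematicsKind):
    """Principal growth stretches ``(normal, in-plane)`` in the ``n`` frame.

    Vectorized over ``v_hat``; the in-plane stretch applies to both tangent
    directions.  This is the diagonal form of :func:`growth_tensor` used by
    the patch and vessel solvers, where the local frame is aligned with the
    wall normal.
    """
    v = np.asarray(v_hat, dtype=float)
    kind = KinematicsKind(kind)
    if kind is KinematicsKind.IVG:
        g = np.cbrt(v)
        return g, g
    if kind is KinematicsKind.PVG:
        return np.ones_like(v), np.sqrt(v)
    if kind is KinematicsKind.TVG:
        return v, np.ones_like(v)
    return np.ones_like(v), np.ones_like(v)


def elastic_part(F: np.ndarray, Fg: np.ndarray) -> np.ndarray:
    """Elastic deformation ``Fe = F @ inv(Fg)`` of the multiplicative split."""
    Fg = np.asarray(Fg, dtype=float)
    det = np.linalg.det(Fg)
    if abs(det) < 1e-14:
        raise ValueError("growth tensor is singular")
    return np.asarray(F, dtype=float) @ np.linalg.inv(Fg)


def isochoric_invariants(Fe: np.ndarray, fam: FiberFamily) -> tuple[float, float]:
    """Isochoric invariants ``(I1bar, I4bar)`` of the elastic deformation.

    ``I1bar = tr(Cbar)`` and ``I4bar = Cbar : A0`` with
    ``Cbar = Je**(-2/3) Fe.T @ Fe``; ``I1bar >= 3`` with equality iff the
    isochoric deformation is a pure rotation.
    """
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    if Je <= 0.0:
        raise ValueError("elastic deformation must have positive determinant")
    Cbar = Je ** (-2.0 / 3.0) * (Fe.T @ Fe)
    I1 = float(np.trace(Cbar))
    I4 = float(fam.a0 @ Cbar @ fam.a0)
    return I1, I4


def fiber_stretch_sq(I4bar: float, lambda_r: float) -> float:
    """Squared collagen fiber stretch with recruitment clamp.

    ``I4c = max(I4bar / lambda_r**2, 1)``: an undulated fiber carries no load
    (and stores no energy) until the tissue stretch along it exceeds the
    recruitment stretch; fibers have neither compressive nor bending
    stiffness, hence the clamp at 1.
    """
    if np.any(np.asarray(I4bar) <= 0.0):
        raise ValueError(f"I4bar must be positive, got {I4bar}")
    if np.any(np.asarray(lambda_r) <= 0.0):
        raise ValueError(f"lambda_r must be positive, got {lambda_r}")
    out = np.maximum(np.asarray(I4bar) / np.square(lambda_r), 1.0)
    return float(out) if np.ndim(out) == 0 else out
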