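"""Layered hyperelastic constitutive model of the vessel wall mixture.

The strain energy per unit reference (intermediate-configuration) volume is
split additively into a volumetric penalty and an isochoric part,

    Psi = U(Je) + rho_e * Psi_e(I1bar) + rho_g * Psi_g(I1bar)
               + sum_i rho_ci * Psi_c(I4c_i),

with ``U(Je) = kappa/2 (Je - 1)**2`` enforcing quasi-incompressibility,
neo-Hookean energies ``Psi_z = mu_z/2 (I1bar - 3)`` for elastin and ground
matrix, and the exponential fiber energy

    Psi_c = k1/(2 k2) [exp(k2 (I4c - 1)**2) - 1]

for each collagen family, measured relative to the recruitment configuration
through the clamped squared fiber stretch ``I4c = max(I4bar/I4r, 1)``.
The normalized partial densities ``rho_*`` couple the mixture bookkeeping to
the elastic response; the adventitia carries no elastin (``rho_e = 0``).

Two pressure treatments are supported: *penalty* mode derives the hydrostatic
pressure from the volumetric energy (``ph = kappa (Je - 1)``), while
*incompressible* mode takes ``ph`` as a Lagrange multiplier supplied by an
equilibrium solver with ``det Fe = 1``.

All operations broadcast over leading array dimensions: ``Fe`` may be
``(..., 3, 3)`` with matching ``(...,)``-shaped composition fields, which is
how the radially discretized vessel solver evaluates whole walls at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParams",
    "LocalComposition",
    "strain_energy",
    "stress_factors",
    "second_pk_stress",
    "cauchy_stress",
]

_I3 = np.eye(3)

# exponent guard: exp argument is clipped here to keep runaway remodeling
# states finite (stress then saturates at ~1e304, still unambiguous in sign)
_EXP_CLIP = 700.0


@dataclass
class MaterialParams:
    """Material constants of one wall layer (kPa where dimensional).

    ``mu_e``/``mu_g`` are the elastin and ground-matrix shear moduli, ``k1``
    (kPa) and ``k2`` (-) the collagen fiber parameters, and ``kappa`` the
    fictitious bulk modulus used as incompressibility penalty.  Fields may be
    scalars or broadcastable arrays (per-point values).
    """

    mu_e: float = 133.81
    mu_g: float = 33.45
    k1: float = 3.52
    k2: float = 40.0
    kappa: float = 100.0

    def __post_init__(self) -> None:
        for name in ("mu_e", "mu_g", "k1"):
            if np.any(np.asarray(getattr(self, name)) < 0.0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(np.asarray(self.k2) <= 0.0):
            raise ValueError("k2 must be positive")
        if np.any(np.asarray(self.kappa) <= 0.0):
            raise ValueError("kappa must be positive")


@dataclass
class LocalComposition:
    """Normalized partial densities and collagen structure at a point.

    ``rho_c`` and ``lambda_r`` have a trailing fiber-family axis; ``a0`` holds
    the referential unit fiber directions with shape ``(n_families, 3)`` (or
    broadcastable ``(..., n_families, 3)``).
    """

    rho_e: float | np.ndarray = 1.0
    rho_g: float | np.ndarray = 1.0
    rho_c: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lambda_r: np.ndarray = field(default_factory=lambda: np.zeros(0))
    a0: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.rho_c = np.asarray(self.rho_c, dtype=float)
        self.lambda_r = np.asarray(self.lambda_r, dtype=float)
        self.a0 = np.asarray(self.a0, dtype=float)
        if np.any(np.asarray(self.rho_e) < 0.0) or np.any(np.asarray(self.rho_g) < 0.0):
            raise ValueError("normalized partial densities must be non-negative")
        if np.any(self.rho_c < 0.0):
            raise ValueError("normalized partial densities must be non-negative")
        if self.n_families and np.any(self.lambda_r <= 0.0):
            raise ValueError("recruitment stretches must be positive")

    @property
    def n_families(self) -> int:
        return self.a0.shape[-2] if self.a0.size else 0


def _isochoric_state(Fe: np.ndarray):
    """Return (Je, Cbar, bbar) for a stacked ``(..., 3, 3)`` deformation."""
    Fe = np.asarray(Fe, dtype=float)
    Je = np.asarray(np.linalg.det(Fe))
    if np.any(Je <= 0.0) or not np.all(np.isfinite(Je)):
        raise ValueError("elastic deformation must have positive determinant")
    scale = Je ** (-2.0 / 3.0)
    Cbar = scale[..., None, None] * np.einsum("...ji,...jk->...ik", Fe, Fe)
    bbar = scale[..., None, None] * np.einsum("...ij,...kj->...ik", Fe, Fe)
    return Je, Cbar, bbar


def _per_family(value):
    """Append a fiber-family axis to per-point parameter arrays."""
    v = np.asarray(value, dtype=float)
    return v[..., None] if v.ndim else v


def _fiber_invariants(Cbar: np.ndarray, comp: LocalComposition):
    """Per-family (I4bar, I4r, I4c) with recruitment clamp."""
    if not comp.n_families:
        shape = Cbar.shape[:-2] + (0,)
        z = np.zeros(shape)
        return z, z, z
    I4bar = np.einsum("...fi,...ij,...fj->...f", comp.a0, Cbar, comp.a0)
    I4r = np.square(comp.lambda_r)
    I4r = np.broadcast_to(I4r, I4bar.shape)
    I4c = np.maximum(I4bar / I4r, 1.0)
    return I4bar, I4r, I4c


def stress_factors(I1bar, I4c, I4r, p: MaterialParams):
    """Stress factors: energy derivatives w.r.t. the isochoric invariants.

    Returns ``(Psi_e1, Psi_g1, Psi_c4)`` where the isotropic factors are the
    constants ``mu_z / 2`` and the collagen factor is the derivative of the
    fiber energy with respect to ``I4bar``,

        Psi_c4 = k1 / I4r * (I4c - 1) * exp(k2 (I4c - 1)**2),

    the ``1/I4r`` arising from the chain rule through ``I4c = I4bar/I4r``.
    ``Psi_c4`` vanishes exactly on the recruitment clamp (``I4c == 1``).
    """
    I4c = np.asarray(I4c, dtype=float)
    if np.any(I4c < 1.0):
        raise ValueError("I4c must be >= 1 (clamped squared fiber stretch)")
    e = np.asarray(I4c) - 1.0
    k1, k2 = _per_family(p.k1), _per_family(p.k2)
    expo = np.exp(np.minimum(k2 * e * e, _EXP_CLIP))
    psi_c4 = k1 / np.asarray(I4r) * e * expo
    mu_e2 = 0.5 * np.asarray(p.mu_e)
    mu_g2 = 0.5 * np.asarray(p.mu_g)
    return mu_e2, mu_g2, psi_c4


def strain_energy(Fe: np.ndarray, comp: LocalComposition, p: MaterialParams):
    """Strain energy density (kPa) of the mixture, volumetric part included."""
    Je, Cbar, _ = _isochoric_state(Fe)
    I1 = np.trace(Cbar, axis1=-2, axis2=-1)
    _, _, I4c = _fiber_invariants(Cbar, comp)
    U = 0.5 * np.asarray(p.kappa) * np.square(Je - 1.0)
    iso = (comp.rho_e * 0.5 * np.asarray(p.mu_e) + comp.rho_g * 0.5 * np.asarray(p.mu_g)) * (
        I1 - 3.0
    )
    if comp.n_families:
        e = I4c - 1.0
        k1, k2 = _per_family(p.k1), _per_family(p.k2)
        fib = k1 / (2.0 * k2) * (np.exp(np.minimum(k2 * e * e, _EXP_CLIP)) - 1.0)
        iso = iso + np.sum(comp.rho_c * fib, axis=-1)
    out = U + iso
    return float(out) if np.ndim(out) == 0 else out


def _resolve_ph(Je, p: MaterialParams, mode: str, ph):
    if mode == "penalty":
        if ph is not None:
            raise ValueError("penalty mode derives ph internally; do not supply it")
        return np.asarray(p.kappa) * (Je - 1.0)
    if mode == "incompressible":
        if ph is None:
            raise ValueError("incompressible mode requires the Lagrange pressure ph")
        return np.asarray(ph, dtype=float)
    raise ValueError(f"unknown pressure mode {mode!r}")


def second_pk_stress(
    Fe: np.ndarray,
    comp: LocalComposition,
    p: MaterialParams,
    mode: str = "penalty",
    ph=None,
) -> np.ndarray:
    """Second Piola-Kirchhoff stress on the grown (intermediate) configuration.

    ``Se = Je ph Ce^-1 + 2 Je^(-2/3) [ (rho_e Psi_e1 + rho_g Psi_g1) Dev(I)
    + sum_i rho_ci Psi_c4_i Dev(A0_i) ]`` with the material deviator
    ``Dev(X) = X - 1/3 (X : Ce) Ce^-1``.
    """
    Fe = np.asarray(Fe, dtype=float)
    Je, Cbar, _ = _isochoric_state(Fe)
    Ce = np.einsum("...ji,...jk->...ik", Fe, Fe)
    Ce_inv = np.linalg.inv(Ce)
    I1 = np.trace(Cbar, axis1=-2, axis2=-1)
    I4bar, I4r, I4c = _fiber_invariants(Cbar, comp)
    psi_e1, psi_g1, psi_c4 = stress_factors(I1, I4c, I4r, p)
    ph_val = _resolve_ph(Je, p, mode, ph)

    trCe = np.trace(Ce, axis1=-2, axis2=-1)
    iso_coeff = comp.rho_e * psi_e1 + comp.rho_g * psi_g1
    dev_I = _I3 - (trCe / 3.0)[..., None, None] * Ce_inv
    S = (Je * ph_val)[..., None, None] * Ce_inv
    S = S + 2.0 * (Je ** (-2.0 / 3.0) * iso_coeff)[..., None, None] * dev_I
    if comp.n_families:
        A0 = np.einsum("...fi,...fj->...fij", comp.a0, comp.a0)
        A0Ce = np.einsum("...fij,...ij->...f", A0, Ce)
        dev_A0 = A0 - (A0Ce / 3.0)[..., None, None] * Ce_inv[..., None, :, :]
        w = (comp.rho_c * psi_c4) * Je[..., None] ** (-2.0 / 3.0)
        S = S + 2.0 * np.einsum("...f,...fij->...ij", w, dev_A0)
    return S


def cauchy_stress(
    Fe: np.ndarray,
    comp: LocalComposition,
    p: MaterialParams,
    mode: str = "penalty",
    ph=None,
) -> np.ndarray:
    """Cauchy stress of the wall mixture.

    ``sigma = ph I + 2/Je [ (rho_e Psi_e1 + rho_g Psi_g1) dev(bbar)
    + sum_i rho_ci Psi_c4_i dev(Abar_i) ]`` with the spatial deviator
    ``dev(X) = X - tr(X)/3 I`` and ``Abar_i = (Fbar a0_i) (x) (Fbar a0_i)``.
    Equals the push-forward ``Je^-1 Fe Se Fe^T`` of :func:`second_pk_stress`.
    """
    Fe = np.asarray(Fe, dtype=float)
    Je, Cbar, bbar = _isochoric_state(Fe)
    I1 = np.trace(Cbar, axis1=-2, axis2=-1)
    I4bar, I4r, I4c = _fiber_invariants(Cbar, comp)
    psi_e1, psi_g1, psi_c4 = stress_factors(I1, I4c, I4r, p)
    ph_val = _resolve_ph(Je, p, mode, ph)

    iso_coeff = comp.rho_e * psi_e1 + comp.rho_g * psi_g1
    dev_b = bbar - (I1 / 3.0)[..., None, None] * _I3
    sigma = ph_val[..., None, None] * _I3
    sigma = sigma + (2.0 / Je * iso_coeff)[..., None, None] * dev_b
    if comp.n_families:
        Fbar = Je[..., None, None] ** (-1.0 / 3.0) * Fe
        abar = np.einsum("...ij,...fj->...fi", Fbar, comp.a0)
        Abar = np.einsum("...fi,...fj->...fij", abar, abar)
        # tr(Abar_f) = I4bar_f
        dev_A = Abar - (I4bar / 3.0)[..., None, None] * _I3
        w = (comp.rho_c * psi_c4) * (2.0 / Je)[..., None]
        sigma = sigma + np.einsum("...f,...fij->...ij", w, dev_A)
    return sigma
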