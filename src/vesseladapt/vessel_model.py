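"""Reduced thick-walled two-layer cylinder model of aneurysm evolution.

The infrarenal aorta is modeled as a two-layer (media + adventitia) cylinder
under fixed axial pre-stretch ``lambda_z`` and inner pressure ``p_i``.  Each
wall layer is discretized radially into quadrature cells (one-point
Gauss-Legendre per cell, i.e. composite midpoint, so cumulative radial
integrals are consistent with the cell weights); every cell carries its own
mixture composition, collagen remodeling state and growth state with the
wall normal along the radial direction.

With exact elastic incompressibility the radial map follows in closed form
from ``det F = v_hat``,

    r(R)**2 = ri**2 + (2 / lambda_z) * int_Ri^R v_hat(rho) rho d rho,

and radial equilibrium ``d sigma_rr / dr = (sigma_tt - sigma_rr)/r`` with
``sigma_rr(ri) = -p_i`` reduces the solve to scalar root finding on the
inner radius so that ``sigma_rr(ro) = 0``.  A penalty-compressible mode
(volumetric energy ``kappa/2 (Je-1)**2``) solves instead for the radial
stretch at every cell plus the inner radius by collocation.

The simulation protocol has two phases: (1) *homeostasis* — collagen turns
over at fixed mass until the fiber stretch is spatially uniform and equal to
the attachment stretch; (2) *growth* — elastin mass decays along the vessel
axis, collagen recruitment stretch and mass evolve with the stretch
stimulus, the tissue volume change feeds the growth tensor, and the section
is re-equilibrated each time step.  Axial stations evolve independently
(quasi-1D reduction): each station feels its local elastin loss but no
axial coupling, which keeps the model desk-scale while retaining every
constitutive and growth mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from . import constitutive, remodeling
from .constitutive import LocalComposition, MaterialParams
from .kinematics import GrowthState, KinematicsKind, growth_stretches
from .mixture import ConstituentState, DepositionRule, MixtureComposition
from .remodeling import RemodelingParams, elastin_mass, stimulus

__all__ = [
    "VesselGeometry",
    "WallPoint",
    "VesselSection",
    "SimulationRecord",
    "GrowthSchedule",
    "build_section",
    "equilibrium_solve",
    "homeostasis_solve",
    "calibrate_fiber_angle",
    "grow",
    "measure",
]

_CONSTITUENTS = ("elastin", "ground", "collagen_1", "collagen_2")
_MEDIA, _ADVENTITIA = 0, 1


@dataclass
class VesselGeometry:
    """Reference geometry and loading of the vessel segment."""

    Ri: float = 8.4  # inner radius, mm
    HM: float = 1.18  # media thickness, mm
    HA: float = 0.59  # adventitia thickness, mm
    L: float = 147.4  # segment length, mm
    lambda_z: float = 1.2  # axial pre-stretch
    p_i: float = 16.0  # inner pressure, kPa

    def __post_init__(self) -> None:
        for name in ("Ri", "HM", "HA", "L", "lambda_z"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.p_i < 0.0:
            raise ValueError("p_i must be non-negative")


@dataclass
class WallPoint:
    """Read-only view of one radial quadrature cell of a section."""

    R: float
    layer: str
    weight: float
    composition: MixtureComposition
    collagen: tuple[remodeling.CollagenState, remodeling.CollagenState]
    growth: GrowthState


class VesselSection:
    """Radially discretized two-layer ring at one axial station.

    State is stored as arrays over the radial cells; :attr:`points` exposes
    the per-cell view mandated by the public API.  ``m_hat`` columns follow
    the constituent order ``(elastin, ground, collagen_1, collagen_2)``.
    """

    def __init__(
        self,
        geom: VesselGeometry,
        materials: dict[str, MaterialParams],
        composition: dict[str, MixtureComposition],
        n_radial_per_layer: int,
        gamma_deg: float,
        kind: KinematicsKind,
        lambda_rec0: float,
        z: float,
    ):
        if n_radial_per_layer < 2:
            raise ValueError("need at least 2 radial cells per layer")
        self.geom = geom
        self.z = float(z)
        self.kind = KinematicsKind(kind)
        self.gamma_deg = float(gamma_deg)
        self.materials = materials

        edges_m = np.linspace(geom.Ri, geom.Ri + geom.HM, n_radial_per_layer + 1)
        edges_a = np.linspace(
            geom.Ri + geom.HM, geom.Ri + geom.HM + geom.HA, n_radial_per_layer + 1
        )
        self.edges = np.concatenate([edges_m, edges_a[1:]])
        self.R = 0.5 * (self.edges[:-1] + self.edges[1:])
        self.w = np.diff(self.edges)
        n = self.R.size
        self.layer = np.where(np.arange(n) < n_radial_per_layer, _MEDIA, _ADVENTITIA)

        # per-cell initial fractions and deposition rules from the layer mixes
        self.phi0 = np.zeros((n, 4))
        rules: dict[str, DepositionRule] = {}
        for lay_idx, lay_name in ((_MEDIA, "media"), (_ADVENTITIA, "adventitia")):
            mix = composition[lay_name]
            for c in mix:
                if c.name not in _CONSTITUENTS:
                    raise ValueError(f"unknown constituent {c.name!r}")
                col = _CONSTITUENTS.index(c.name)
                self.phi0[self.layer == lay_idx, col] = c.phi0
                prev = rules.get(c.name)
                if prev is not None and prev is not c.rule:
                    raise ValueError(
                        f"deposition rule for {c.name!r} differs between layers"
                    )
                rules[c.name] = c.rule
        self.is_ccd = np.array(
            [rules.get(name, DepositionRule.CCV) is DepositionRule.CCD
             for name in _CONSTITUENTS]
        )
        if self.kind is KinematicsKind.NVG and self.is_ccd.any():
            raise ValueError("NVG kinematics requires an all-CCV deposition assignment")

        self.m_hat = np.ones((n, 4))
        self.lambda_r = np.full((n, 2), float(lambda_rec0))
        self.solved: dict | None = None

        # per-cell material constants (elastin modulus is media-only anyway,
        # but carrying it per cell keeps a single constitutive call)
        med, adv = materials["media"], materials["adventitia"]
        self.mu_e = np.where(self.layer == _MEDIA, med.mu_e, adv.mu_e)
        self.mu_g = np.where(self.layer == _MEDIA, med.mu_g, adv.mu_g)
        self.k1 = np.where(self.layer == _MEDIA, med.k1, adv.k1)
        self.k2 = np.where(self.layer == _MEDIA, med.k2, adv.k2)
        self.kappa = np.where(self.layer == _MEDIA, med.kappa, adv.kappa)

    # -- derived state -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.R.size

    @property
    def v_hat(self) -> np.ndarray:
        """Tissue volume change per cell from the mixture rule."""
        v_c = np.where(self.is_ccd, self.m_hat, 1.0)
        return np.sum(v_c * self.phi0, axis=-1)

    @property
    def a0(self) -> np.ndarray:
        """Referential fiber directions (2, 3) in the local (r, t, z) frame."""
        g = np.deg2rad(self.gamma_deg)
        c, s = np.cos(g), np.sin(g)
        return np.array([[0.0, c, s], [0.0, c, -s]])

    def local_composition(self) -> LocalComposition:
        v = self.v_hat
        return LocalComposition(
            rho_e=np.where(self.layer == _MEDIA, self.m_hat[:, 0] / v, 0.0),
            rho_g=self.m_hat[:, 1] / v,
            rho_c=self.m_hat[:, 2:4] / v[:, None],
            lambda_r=self.lambda_r,
            a0=self.a0,
        )

    def material_params(self) -> MaterialParams:
        return MaterialParams(
            mu_e=self.mu_e, mu_g=self.mu_g, k1=self.k1, k2=self.k2, kappa=self.kappa
        )

    @property
    def points(self) -> list[WallPoint]:
        pts = []
        for j in range(self.n_cells):
            lay = "media" if self.layer[j] == _MEDIA else "adventitia"
            cons = [
                ConstituentState(
                    name=name,
                    rule=DepositionRule.CCD if self.is_ccd[k] else DepositionRule.CCV,
                    phi0=float(self.phi0[j, k]),
                    m_hat=float(self.m_hat[j, k]),
                )
                for k, name in enumerate(_CONSTITUENTS)
                if self.phi0[j, k] > 0.0
            ]
            # re-normalization guard for views of layers missing a constituent
            total = sum(c.phi0 for c in cons)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cell fractions sum to {total}, expected 1")
            pts.append(
                WallPoint(
                    R=float(self.R[j]),
                    layer=lay,
                    weight=float(self.w[j]),
                    composition=MixtureComposition(cons),
                    collagen=tuple(
                        remodeling.CollagenState(
                            lambda_r=float(self.lambda_r[j, f]),
                            m_hat_c=float(self.m_hat[j, 2 + f]),
                        )
                        for f in range(2)
                    ),
                    growth=GrowthState(
                        v_hat=float(self.v_hat[j]),
                        n=np.array([1.0, 0.0, 0.0]),
                        kind=self.kind,
                    ),
                )
            )
        return pts


def build_section(
    geom: VesselGeometry,
    materials: dict[str, MaterialParams],
    composition: dict[str, MixtureComposition],
    n_radial_per_layer: int = 4,
    *,
    gamma_deg: float = 45.0,
    kind: KinematicsKind | str = KinematicsKind.TVG,
    lambda_rec0: float = 1.13,
    z: float | None = None,
) -> VesselSection:
    """Build a section at homeostatic initials (``m_hat = 1``, ``Fg = I``)."""
    if z is None:
        z = geom.L / 2.0
    return VesselSection(
        geom=geom,
        materials=materials,
        composition=composition,
        n_radial_per_layer=n_radial_per_layer,
        gamma_deg=gamma_deg,
        kind=KinematicsKind(kind),
        lambda_rec0=lambda_rec0,
        z=z,
    )


# ---------------------------------------------------------------------------
# exact-incompressibility equilibrium
# ---------------------------------------------------------------------------


def _radial_map(edges, R, v_hat, lambda_z, ri):
    """Current radii at cell midpoints and the outer radius.

    ``v_hat`` is piecewise constant per cell, so the cumulative integral
    ``int v_hat rho d rho`` is evaluated exactly cell by cell; ``ri`` may be
    an array over stacked sections (leading axis).
    """
    ri = np.asarray(ri, dtype=float)
    full = v_hat * 0.5 * (edges[1:] ** 2 - edges[:-1] ** 2)
    prior = np.concatenate(
        [np.zeros(full.shape[:-1] + (1,)), np.cumsum(full, axis=-1)[..., :-1]], axis=-1
    )
    to_mid = prior + v_hat * 0.5 * (R**2 - edges[:-1] ** 2)
    r_sq = ri[..., None] ** 2 + (2.0 / lambda_z) * to_mid
    ro_sq = ri**2 + (2.0 / lambda_z) * np.sum(full, axis=-1)
    if np.any(r_sq <= 0.0) or np.any(ro_sq <= 0.0):
        raise ValueError("non-positive current radius; inner radius too small")
    return np.sqrt(r_sq), np.sqrt(ro_sq)


def _elastic_stretches(section_arrays, r, kind, lambda_z):
    """Elastic principal stretches (r, t, z) under exact incompressibility."""
    R, v_hat = section_arrays
    fg_n, fg_t = growth_stretches(v_hat, kind)
    lam_t = (r / R) / fg_t
    lam_z = lambda_z / fg_t
    lam_r = 1.0 / (lam_t * lam_z)
    return lam_r, lam_t, lam_z


def _diag_F(lam_r, lam_t, lam_z):
    F = np.zeros(lam_r.shape + (3, 3))
    F[..., 0, 0] = lam_r
    F[..., 1, 1] = lam_t
    F[..., 2, 2] = lam_z
    return F


def _stress_dev_diag(section: "VesselSection", comp, params, lam_r, lam_t, lam_z):
    """Diagonal of the pressure-free Cauchy stress (ph = 0 incompressible)."""
    Fe = _diag_F(lam_r, lam_t, lam_z)
    sig = constitutive.cauchy_stress(Fe, comp, params, mode="incompressible", ph=0.0)
    return sig[..., 0, 0], sig[..., 1, 1], sig[..., 2, 2]


def _wall_residual(section: VesselSection, comp, params, ri):
    """Equilibrium residual f(ri) = int (s_tt - s_rr)/r dr - p_i, plus state."""
    geom = section.geom
    v_hat = section.v_hat
    r, ro = _radial_map(section.edges, section.R, v_hat, geom.lambda_z, ri)
    lam_r, lam_t, lam_z = _elastic_stretches((section.R, v_hat), r, section.kind, geom.lambda_z)
    s_rr, s_tt, s_zz = _stress_dev_diag(section, comp, params, lam_r, lam_t, lam_z)
    # dr = v_hat R / (lambda_z r) dR  ->  integrand in R
    g = (s_tt - s_rr) * v_hat * section.R / (geom.lambda_z * r**2)
    f = np.sum(g * section.w, axis=-1) - geom.p_i
    return f, dict(
        r=r, ro=ro, lam=(lam_r, lam_t, lam_z), sig_dev=(s_rr, s_tt, s_zz), g=g
    )


def _find_ri(fun, x0, xtol=1e-12, ftol=1e-10, max_expand=60):
    """Scalar root find with secant warm start and bracketed fallback."""
    f0 = fun(x0)
    if abs(f0) < ftol:
        return x0
    x1 = x0 * 1.01
    f1 = fun(x1)
    for _ in range(60):
        if f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        if not np.isfinite(x2) or x2 <= 0.0:
            break
        if abs(x2 - x1) < xtol * max(1.0, abs(x1)):
            return x2
        x0, f0, x1 = x1, f1, x2
        f1 = fun(x1)
        if abs(f1) < ftol:
            return x1
    # bracket by geometric expansion around the warm start
    lo = hi = max(x0, 1e-3)
    flo = fhi = fun(lo)
    for _ in range(max_expand):
        if flo > 0:
            lo *= 0.9
            flo = fun(lo)
        elif fhi < 0:
            hi *= 1.1
            fhi = fun(hi)
        if flo <= 0.0 <= fhi:
            return optimize.brentq(fun, lo, hi, xtol=xtol)
    raise RuntimeError(
        f"no equilibrium root bracketed: f({lo:.4g})={flo:.4g}, f({hi:.4g})={fhi:.4g}"
    )


def _integrate_sigma_rr(g, w, p_i):
    """sigma_rr at cell midpoints from the piecewise-constant integrand."""
    full = g * w
    prior = np.concatenate(
        [np.zeros(full.shape[:-1] + (1,)), np.cumsum(full, axis=-1)[..., :-1]], axis=-1
    )
    return -p_i + prior + 0.5 * full


def equilibrium_solve(
    section: VesselSection,
    geom: VesselGeometry | None = None,
    mode: str = "incompressible",
    ri_guess: float | None = None,
) -> VesselSection:
    """Solve radial equilibrium of the section; fills ``section.solved``.

    ``mode="incompressible"`` enforces ``det Fe = 1`` exactly and finds the
    inner radius by scalar root finding on the outer traction condition;
    ``mode="penalty"`` solves the compressible collocation system with the
    volumetric penalty ``kappa`` of the material parameters.
    """
    if geom is not None:
        section.geom = geom
    geom = section.geom
    comp = section.local_composition()
    params = section.material_params()

    if mode == "incompressible":
        def fun(ri):
            return _wall_residual(section, comp, params, ri)[0]

        x0 = ri_guess
        if x0 is None:
            x0 = section.solved["ri"] if section.solved else geom.Ri * 1.1
        ri = _find_ri(fun, x0)
        f, state = _wall_residual(section, comp, params, ri)
        s_rr_dev, s_tt_dev, s_zz_dev = state["sig_dev"]
        sigma_rr = _integrate_sigma_rr(state["g"], section.w, geom.p_i)
        ph = sigma_rr - s_rr_dev
        lam_r, lam_t, lam_z = state["lam"]
        Je = lam_r * lam_t * lam_z
    elif mode == "penalty":
        ri, state = _penalty_solve(section, comp, params, ri_guess)
        sigma_rr = state["sigma_rr"]
        ph = state["ph"]
        s_rr_dev = state["sig_dev"][0]
        s_tt_dev, s_zz_dev = state["sig_dev"][1], state["sig_dev"][2]
        lam_r, lam_t, lam_z = state["lam"]
        Je = state["Je"]
        f = 0.0
    else:
        raise ValueError(f"unknown equilibrium mode {mode!r}")

    I1b, I4b = _isochoric_wall_invariants(section, lam_r, lam_t, lam_z)
    I4c = np.maximum(I4b[..., None] / section.lambda_r**2, 1.0)
    section.solved = dict(
        mode=mode,
        ri=float(ri),
        ro=float(state["ro"]),
        thickness=float(state["ro"] - ri),
        r=state["r"],
        lam=(lam_r, lam_t, lam_z),
        Je=Je,
        sigma_rr=sigma_rr,
        sigma_tt=s_tt_dev + ph,
        sigma_zz=s_zz_dev + ph,
        ph=ph,
        I4bar=I4b,
        I4c=I4c,
        lam_c=np.sqrt(I4c),
        residual=float(np.max(np.abs(f))),
    )
    if mode == "penalty":
        section.solved["lam_rad"] = state["lam_rad"]
    return section


def _isochoric_wall_invariants(section, lam_r, lam_t, lam_z):
    """(I1bar, I4bar) from the principal elastic stretches."""
    Je = lam_r * lam_t * lam_z
    s = Je ** (-2.0 / 3.0)
    I1b = s * (lam_r**2 + lam_t**2 + lam_z**2)
    g = np.deg2rad(section.gamma_deg)
    I4b = s * (lam_t**2 * np.cos(g) ** 2 + lam_z**2 * np.sin(g) ** 2)
    return I1b, I4b


# ---------------------------------------------------------------------------
# penalty-compressible equilibrium (collocation)
# ---------------------------------------------------------------------------


def _penalty_state(section, comp, params, ri, lam_rad):
    geom = section.geom
    v_hat = section.v_hat
    fg_n, fg_t = growth_stretches(v_hat, section.kind)
    # current midpoint radii from the cumulative radial stretch
    full = lam_rad * section.w
    prior = np.concatenate([[0.0], np.cumsum(full)[:-1]])
    r = ri + prior + 0.5 * full
    ro = ri + np.sum(full)
    lam_r = lam_rad / fg_n
    lam_t = (r / section.R) / fg_t
    lam_z = geom.lambda_z / fg_t
    Fe = _diag_F(lam_r, lam_t, lam_z)
    sig = constitutive.cauchy_stress(Fe, comp, params, mode="penalty")
    s_rr, s_tt, s_zz = sig[..., 0, 0], sig[..., 1, 1], sig[..., 2, 2]
    # equilibrium ODE in the reference coordinate: d s_rr/dR = lam_rad (s_tt - s_rr)/r
    h = lam_rad * (s_tt - s_rr) / r
    sigma_rr_int = _integrate_sigma_rr(h, section.w, geom.p_i)
    outer_bc = -geom.p_i + np.sum(h * section.w)
    Je = lam_r * lam_t * lam_z
    return dict(
        r=r,
        ro=ro,
        lam=(lam_r, lam_t, lam_z),
        Je=Je,
        ph=np.asarray(params.kappa) * (Je - 1.0),
        sig_dev=(s_rr - np.asarray(params.kappa) * (Je - 1.0),
                 s_tt - np.asarray(params.kappa) * (Je - 1.0),
                 s_zz - np.asarray(params.kappa) * (Je - 1.0)),
        sigma_rr=sigma_rr_int,
        s_rr_pointwise=s_rr,
        outer_bc=outer_bc,
    )


def _penalty_solve(section, comp, params, ri_guess=None):
    """Collocation solve of the compressible wall: unknowns (ri, lam_rad[j])."""
    geom = section.geom
    starts = []
    prev = section.solved
    if prev and prev.get("mode") == "penalty" and "lam_rad" in prev:
        starts.append((prev["ri"], np.asarray(prev["lam_rad"])))
    # fallback start from the exact-incompressibility solution
    try:
        def fun(ri):
            return _wall_residual(section, comp, params, ri)[0]

        x0 = ri_guess if ri_guess is not None else geom.Ri * 1.1
        ri0 = _find_ri(fun, x0)
        _, st = _wall_residual(section, comp, params, ri0)
        lam_r0 = st["lam"][0]
        fg_n, _ = growth_stretches(section.v_hat, section.kind)
        starts.append((ri0, lam_r0 * fg_n))
    except RuntimeError:
        starts.append((geom.Ri, np.ones(section.n_cells)))
    ri0, lam_rad0 = starts[0]

    def residuals(x):
        ri, lam_rad = x[0], x[1:]
        if (
            not np.all(np.isfinite(x))
            or ri <= 0.0
            or np.any(lam_rad <= 1e-6)
            or np.any(lam_rad > 1e3)
        ):
            # smooth, repulsive penalty steering the solver back to admissible
            # states (a constant residual would have a singular Jacobian)
            dist = np.where(np.isfinite(x), x, 1e3) - x0
            return 1e6 * (1.0 + np.abs(dist))
        st = _penalty_state(section, comp, params, ri, lam_rad)
        res = np.empty_like(x)
        res[0] = st["outer_bc"]
        res[1:] = st["s_rr_pointwise"] - st["sigma_rr"]
        return res

    sol = None
    for ri_s, lam_s in starts:
        x0 = np.concatenate([[ri_s], lam_s])
        sol = optimize.root(residuals, x0, method="hybr")
        if np.max(np.abs(sol.fun)) > 1e-5:
            sol = optimize.root(residuals, sol.x, method="lm")
        if np.max(np.abs(sol.fun)) <= 1e-5:
            break
    if sol is None or np.max(np.abs(sol.fun)) > 1e-5:
        raise RuntimeError(f"penalty equilibrium failed: {sol.message}")
    ri, lam_rad = sol.x[0], sol.x[1:]
    state = _penalty_state(section, comp, params, ri, lam_rad)
    state["lam_rad"] = lam_rad
    return ri, state


# ---------------------------------------------------------------------------
# phase 1: homeostasis
# ---------------------------------------------------------------------------


def homeostasis_solve(
    section: VesselSection,
    geom: VesselGeometry | None = None,
    remodeling_params: RemodelingParams | None = None,
    mode: str = "incompressible",
    tol: float = 1e-10,
    max_iter: int = 400,
) -> VesselSection:
    """Converge the recruitment-stretch field to the homeostatic fixed point.

    Collagen mass is held at ``m_hat = 1`` while the recruitment stretch is
    driven to the state where the fiber stretch equals the attachment stretch
    everywhere.  The update uses the fixed point of the recruitment rate
    equation directly (``lambda_r <- lambda_fiber / lambda_a``, the state at
    which the stimulus vanishes), alternating with re-equilibration; this
    converges to the same stationary state as time stepping the rate
    equation, just without the transient.
    """
    if remodeling_params is None:
        remodeling_params = RemodelingParams()
    lam_a = remodeling_params.lambda_a
    for it in range(max_iter):
        equilibrium_solve(section, geom, mode=mode)
        lam_fiber = np.sqrt(section.solved["I4bar"])
        err = float(np.max(np.abs(np.sqrt(section.solved["I4c"]) - lam_a)))
        if err < tol:
            section.solved["homeostasis_iterations"] = it
            section.solved["d0"] = 2.0 * section.solved["ri"]
            section.solved["h0"] = section.solved["thickness"]
            return section
        section.lambda_r = np.repeat(
            (lam_fiber / lam_a)[:, None], 2, axis=1
        )
    raise RuntimeError(
        f"homeostasis did not converge within {max_iter} iterations (err={err:.3e})"
    )


def calibrate_fiber_angle(
    geom: VesselGeometry,
    materials: dict[str, MaterialParams],
    composition: dict[str, MixtureComposition],
    remodeling_params: RemodelingParams | None = None,
    target_diameter: float = 23.0,
    n_radial_per_layer: int = 4,
    mode: str = "incompressible",
    bracket: tuple[float, float] = (5.0, 85.0),
) -> float:
    """Fiber angle (deg from circumferential) hitting a homeostatic diameter.

    The collagen fiber angle is not fixed by the baseline parameter set, yet
    the homeostatic caliber depends on it; this utility tunes the angle so
    the loaded homeostatic inner diameter matches ``target_diameter`` (mm).
    Raises if the target is outside the range spanned by the bracket.
    """

    # phase 1 holds all masses at 1, so v_hat = 1 and the homeostatic state
    # is independent of the growth kinematics kind
    def d0_of(gamma):
        sec = build_section(
            geom, materials, composition, n_radial_per_layer, gamma_deg=gamma
        )
        homeostasis_solve(sec, geom, remodeling_params, mode=mode)
        return sec.solved["d0"] - target_diameter

    f_lo, f_hi = d0_of(bracket[0]), d0_of(bracket[1])
    if f_lo * f_hi > 0.0:
        raise RuntimeError(
            "target diameter not bracketed by fiber angles "
            f"{bracket}: d0-target = ({f_lo:.3f}, {f_hi:.3f}) mm"
        )
    return float(optimize.brentq(d0_of, bracket[0], bracket[1], xtol=1e-4))


# ---------------------------------------------------------------------------
# phase 2: growth
# ---------------------------------------------------------------------------


@dataclass
class GrowthSchedule:
    """Time stepping and termination settings of a growth run."""

    dtau: float = 0.01  # years
    tau_end: float = 15.0  # years
    stop_dhat: float | None = None  # stop once di/d0 reaches this value
    max_halvings: int = 4  # step-halving attempts on equilibrium failure
    stimulus_form: str = "difference"

    def __post_init__(self) -> None:
        if self.dtau <= 0.0 or self.tau_end <= 0.0:
            raise ValueError("dtau and tau_end must be positive")


@dataclass
class SimulationRecord:
    """Time series of a growth run plus milestone snapshots.

    Series are sampled every accepted time step; the tracked station (point
    A quantities) is the innermost cell of the section at ``z = L/2``.
    """

    tau: np.ndarray
    di: np.ndarray
    dhat: np.ndarray
    thickness_mid: np.ndarray
    lam_c_A: np.ndarray
    m_c_A: np.ndarray
    v_hat_A: np.ndarray
    total_volume_ratio: np.ndarray
    z: np.ndarray
    thickness_z: np.ndarray  # final thickness profile along z
    d0: float
    h0: float
    status: str
    milestones: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tau": self.tau,
                "di": self.di,
                "dhat": self.dhat,
                "thickness_mid": self.thickness_mid,
                "lam_c_A": self.lam_c_A,
                "m_c_A": self.m_c_A,
                "v_hat_A": self.v_hat_A,
                "total_volume_ratio": self.total_volume_ratio,
            }
        )


class _AxialState:
    """Stacked growth state over axial stations (vectorized inner loop)."""

    def __init__(self, template: VesselSection, z_stations: np.ndarray):
        self.template = template
        self.z = z_stations
        ns, n = z_stations.size, template.n_cells
        self.lambda_r = np.tile(template.lambda_r, (ns, 1, 1))
        self.m_hat = np.tile(template.m_hat, (ns, 1, 1))
        self.ri = np.full(ns, template.solved["ri"])
        self.I4bar = np.tile(template.solved["I4bar"], (ns, 1))
        self.floored = 0

    def v_hat(self):
        t = self.template
        v_c = np.where(t.is_ccd, self.m_hat, 1.0)
        return np.sum(v_c * t.phi0, axis=-1)

    def composition(self):
        t = self.template
        v = self.v_hat()
        media = t.layer == _MEDIA
        return LocalComposition(
            rho_e=np.where(media, self.m_hat[..., 0] / v, 0.0),
            rho_g=self.m_hat[..., 1] / v,
            rho_c=self.m_hat[..., 2:4] / v[..., None],
            lambda_r=self.lambda_r,
            a0=t.a0,
        )

    def copy_state(self):
        return (self.lambda_r.copy(), self.m_hat.copy(), self.ri.copy(),
                self.I4bar.copy())

    def restore(self, snap):
        self.lambda_r, self.m_hat, self.ri, self.I4bar = (
            snap[0].copy(), snap[1].copy(), snap[2].copy(), snap[3].copy()
        )


def _equilibrate_stack(state: _AxialState):
    """Vectorized equilibrium across stations (secant, brentq fallback)."""
    t = state.template
    geom = t.geom
    v_hat = state.v_hat()
    comp = state.composition()
    params = t.material_params()

    def f_vec(ri):
        r, ro = _radial_map(t.edges, t.R, v_hat, geom.lambda_z, ri)
        fg_n, fg_t = growth_stretches(v_hat, t.kind)
        lam_t = (r / t.R) / fg_t
        lam_z = geom.lambda_z / fg_t
        lam_r = 1.0 / (lam_t * lam_z)
        Fe = _diag_F(lam_r, lam_t, lam_z)
        sig = constitutive.cauchy_stress(Fe, comp, params, mode="incompressible", ph=0.0)
        g = (sig[..., 1, 1] - sig[..., 0, 0]) * v_hat * t.R / (geom.lambda_z * r**2)
        return np.sum(g * t.w, axis=-1) - geom.p_i, (r, ro, lam_r, lam_t, lam_z, sig, g)

    x0 = state.ri.copy()
    f0, _ = f_vec(x0)
    x1 = x0 * 1.002
    f1, aux = f_vec(x1)
    for _ in range(40):
        denom = f1 - f0
        bad = np.abs(denom) < 1e-300
        step = np.where(bad, 0.0, f1 * (x1 - x0) / np.where(bad, 1.0, denom))
        x2 = np.clip(x1 - step, 0.2 * geom.Ri, 50.0 * geom.Ri)
        x0, f0 = x1, f1
        x1 = x2
        f1, aux = f_vec(x1)
        if np.all(np.abs(f1) < 1e-9) or not np.all(np.isfinite(f1)):
            break
    if not np.all(np.isfinite(f1)) or np.any(np.abs(f1) > 1e-8):
        # per-station fallback
        for k in np.nonzero(~(np.abs(f1) < 1e-8))[0]:
            def fk(ri, k=k):
                ri_vec = x1.copy()
                ri_vec[k] = ri
                return f_vec(ri_vec)[0][k]

            x1[k] = _find_ri(fk, max(state.ri[k], 0.3 * geom.Ri))
        f1, aux = f_vec(x1)
        if not np.all(np.isfinite(f1)) or np.any(np.abs(f1) > 1e-6):
            raise RuntimeError("stacked equilibrium failed to converge")
    r, ro, lam_r, lam_t, lam_z, sig, g = aux
    state.ri = x1
    s = (lam_r * lam_t * lam_z) ** (-2.0 / 3.0)  # = 1 up to round-off
    gam = np.deg2rad(t.gamma_deg)
    state.I4bar = s * (lam_t**2 * np.cos(gam) ** 2 + lam_z**2 * np.sin(gam) ** 2)
    return dict(r=r, ro=ro, lam=(lam_r, lam_t, lam_z), sig=sig, g=g, v_hat=v_hat)


def grow(
    sections: Sequence[VesselSection] | VesselSection,
    geom: VesselGeometry | None = None,
    remodeling_params: RemodelingParams | None = None,
    schedule: GrowthSchedule | None = None,
) -> SimulationRecord:
    """Phase-2 aneurysm growth along the axial station array.

    All sections must be homeostatic (phase 1 converged) and identical up to
    their axial coordinate; the first section must sit at ``z = L/2`` (the
    tracked point-A station).  Per step: prescribe the elastin mass at each
    station, evaluate the stretch stimulus per cell and family, step the
    recruitment stretch and collagen mass (forward Euler), recompute the
    tissue volume change and growth tensor, and re-equilibrate.  On an
    equilibrium failure the step is retried with up to ``max_halvings``
    halvings of the local step before the run is truncated with an explicit
    status.
    """
    if isinstance(sections, VesselSection):
        sections = [sections]
    template = sections[0]
    if template.solved is None or "d0" not in template.solved:
        raise ValueError("sections must be homeostatic before growth")
    if remodeling_params is None:
        remodeling_params = RemodelingParams(L=template.geom.L)
    if schedule is None:
        schedule = GrowthSchedule()
    if geom is not None:
        template.geom = geom

    z = np.array([s.z for s in sections], dtype=float)
    if abs(z[0] - template.geom.L / 2.0) > 1e-9:
        raise ValueError("the first section must sit at z = L/2")
    # trapezoidal weights along z for the total-volume integral
    if z.size > 1:
        wz = np.zeros_like(z)
        wz[:-1] += 0.5 * np.diff(z)
        wz[1:] += 0.5 * np.diff(z)
    else:
        wz = np.ones(1)

    state = _AxialState(template, z)
    d0 = template.solved["d0"]
    h0 = template.solved["h0"]
    lam_a = remodeling_params.lambda_a

    ref_vol = np.sum(wz[:, None] * template.R[None, :] * template.w[None, :])

    series: dict[str, list] = {k: [] for k in (
        "tau", "di", "thickness_mid", "lam_c_A", "m_c_A", "v_hat_A", "total_vol"
    )}
    milestones: dict = {}
    status = "completed"
    tau = 0.0
    eq = _equilibrate_stack(state)

    def record_step(tau, eq):
        v_hat = eq["v_hat"]
        series["tau"].append(tau)
        series["di"].append(2.0 * state.ri[0])
        series["thickness_mid"].append(eq["ro"][0] - state.ri[0])
        I4c_A = max(state.I4bar[0, 0] / state.lambda_r[0, 0, 0] ** 2, 1.0)
        series["lam_c_A"].append(np.sqrt(I4c_A))
        series["m_c_A"].append(state.m_hat[0, 0, 2])
        series["v_hat_A"].append(v_hat[0, 0])
        series["total_vol"].append(
            np.sum(wz[:, None] * v_hat * template.R[None, :] * template.w[None, :])
            / ref_vol
        )

    record_step(tau, eq)

    while tau < schedule.tau_end - 1e-12:
        snap = state.copy_state()
        advanced = False
        for halving in range(schedule.max_halvings + 1):
            n_sub = 2**halving
            dt = schedule.dtau / n_sub
            try:
                for _ in range(n_sub):
                    sub_tau = tau + dt
                    m_e = elastin_mass(z, sub_tau, remodeling_params)
                    media = template.layer == _MEDIA
                    state.m_hat[..., 0] = np.where(media, m_e[:, None], 1.0)
                    I4c = np.maximum(
                        state.I4bar[..., None] / state.lambda_r**2, 1.0
                    )
                    xi = stimulus(I4c, remodeling_params, form=schedule.stimulus_form)
                    new_lr = state.lambda_r + remodeling_params.alpha * xi * dt
                    n_floor = int(np.sum(new_lr < remodeling.LAMBDA_R_FLOOR))
                    if n_floor:
                        state.floored += n_floor
                        new_lr = np.maximum(new_lr, remodeling.LAMBDA_R_FLOOR)
                    state.lambda_r = new_lr
                    state.m_hat[..., 2:4] *= 1.0 + remodeling_params.beta * xi * dt
                    if np.any(state.m_hat[..., 2:4] <= 0.0):
                        raise RuntimeError("collagen mass became non-positive")
                    eq = _equilibrate_stack(state)
                    tau = sub_tau
                advanced = True
                break
            except (RuntimeError, ValueError):
                state.restore(snap)
                tau = series["tau"][-1]
        if not advanced:
            status = "truncated"
            break
        record_step(tau, eq)
        dhat_now = series["di"][-1] / d0
        if "dhat2" not in milestones and dhat_now >= 2.0:
            milestones["dhat2"] = _snapshot(state, eq, template, tau, lam_a)
        if schedule.stop_dhat is not None and dhat_now >= schedule.stop_dhat:
            status = "reached_target"
            break

    thickness_z = eq["ro"] - state.ri
    rec = SimulationRecord(
        tau=np.asarray(series["tau"]),
        di=np.asarray(series["di"]),
        dhat=np.asarray(series["di"]) / d0,
        thickness_mid=np.asarray(series["thickness_mid"]),
        lam_c_A=np.asarray(series["lam_c_A"]),
        m_c_A=np.asarray(series["m_c_A"]),
        v_hat_A=np.asarray(series["v_hat_A"]),
        total_volume_ratio=np.asarray(series["total_vol"]),
        z=z,
        thickness_z=thickness_z,
        d0=d0,
        h0=h0,
        status=status,
        milestones=milestones,
        meta=dict(
            kind=template.kind.value,
            gamma_deg=template.gamma_deg,
            floored_lambda_r=state.floored,
            dtau=schedule.dtau,
            tau_end=schedule.tau_end,
        ),
    )
    # write final state back into the section objects
    for k, sec in enumerate(sections):
        sec.lambda_r = state.lambda_r[k]
        sec.m_hat = state.m_hat[k]
    if state.floored:
        warnings.warn(
            f"recruitment stretch floored at 1.0 in {state.floored} cell-steps",
            stacklevel=2,
        )
    return rec


def _snapshot(state: _AxialState, eq, template, tau, lam_a):
    """Transmural snapshot at the tracked station (z = L/2)."""
    lam_r, lam_t, lam_z = eq["lam"]
    sig = eq["sig"]
    g = eq["g"]
    sigma_rr = _integrate_sigma_rr(g, template.w, template.geom.p_i)
    ph = sigma_rr - sig[..., 0, 0]
    I4c = np.maximum(state.I4bar[..., None] / state.lambda_r**2, 1.0)
    return dict(
        tau=tau,
        R=template.R.copy(),
        lam_c=np.sqrt(I4c[0, :, 0]),
        v_hat=state.v_hat()[0],
        sigma_tt=(sig[..., 1, 1] + ph)[0],
        thickness_mid=float(eq["ro"][0] - state.ri[0]),
        thickness_z=(eq["ro"] - state.ri).copy(),
        m_c=state.m_hat[0, :, 2].copy(),
    )


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------


def measure(record: SimulationRecord, window: float = 1.0) -> dict:
    """Derived series and scalars of a growth run.

    Returns the centered finite-difference diameter growth rate over a
    ``window``-year window (mm/year), threshold-crossing times, the peak
    total volume change, and the thickness profile normalized by ``h0``.
    """
    tau, di = record.tau, record.di
    if tau.size < 2 or tau[-1] - tau[0] < window:
        raise ValueError("record shorter than the measurement window")
    half = window / 2.0
    lo = np.interp(tau - half, tau, di)
    hi = np.interp(tau + half, tau, di)
    denom = np.minimum(tau + half, tau[-1]) - np.maximum(tau - half, tau[0])
    rate = (hi - lo) / denom

    def crossing(series, threshold):
        above = series >= threshold
        if not above.any():
            return None
        k = int(np.argmax(above))
        if k == 0:
            return float(tau[0])
        # linear interpolation within the crossing step
        t0, t1 = tau[k - 1], tau[k]
        s0, s1 = series[k - 1], series[k]
        return float(t0 + (threshold - s0) / (s1 - s0) * (t1 - t0))

    t_d55 = crossing(di, 55.0)
    t_rate10 = crossing(rate, 10.0)
    candidates = [t for t in (t_d55, t_rate10) if t is not None]
    return dict(
        growth_rate=rate,
        peak_growth_rate=float(rate.max()),
        time_to_dhat_1_5=crossing(record.dhat, 1.5),
        time_to_dhat_2=crossing(record.dhat, 2.0),
        time_to_55mm=t_d55,
        time_to_rate_10=t_rate10,
        time_to_repair=min(candidates) if candidates else None,
        max_total_volume_ratio=float(record.total_volume_ratio.max()),
        max_v_hat_A=float(record.v_hat_A.max()),
        thickness_z_normalized=record.thickness_z / record.h0,
    )
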