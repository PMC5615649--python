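"""Two-layer cylinder: equilibrium, homeostasis, growth and measurements."""

import numpy as np
import pytest

from vesseladapt.constitutive import MaterialParams
from vesseladapt.mixture import ConstituentState, MixtureComposition
from vesseladapt.remodeling import RemodelingParams
from vesseladapt.vessel_model import (
    GrowthSchedule,
    SimulationRecord,
    VesselGeometry,
    build_section,
    equilibrium_solve,
    grow,
    homeostasis_solve,
    measure,
)


def neo_hookean_mix():
    return MixtureComposition([ConstituentState("ground", "CCV", 1.0)])


class TestBuildSection:
    def test_weights_sum_to_layer_thickness(self, vessel_inputs):
        geom, mats, comp, _ = vessel_inputs
        sec = build_section(geom, mats, comp, 4)
        assert sec.w[sec.layer == 0].sum() == pytest.approx(1.18, abs=1e-12)
        assert sec.w[sec.layer == 1].sum() == pytest.approx(0.59, abs=1e-12)

    def test_layers_contiguous(self, vessel_inputs):
        geom, mats, comp, _ = vessel_inputs
        sec = build_section(geom, mats, comp, 4)
        media_edge = geom.Ri + geom.HM
        assert sec.R[sec.layer == 0].max() < media_edge < sec.R[sec.layer == 1].min()
        assert np.all(np.diff(sec.R) > 0)

    def test_homeostatic_initials(self, vessel_inputs):
        geom, mats, comp, _ = vessel_inputs
        sec = build_section(geom, mats, comp, 3, lambda_rec0=1.13)
        assert np.all(sec.m_hat == 1.0)
        assert np.all(sec.lambda_r == 1.13)
        assert np.allclose(sec.v_hat, 1.0)
        pts = sec.points
        assert len(pts) == 6
        assert pts[0].layer == "media" and pts[-1].layer == "adventitia"
        assert pts[0].growth.v_hat == pytest.approx(1.0, abs=1e-12)
        assert pts[0].composition["elastin"].phi0 == pytest.approx(0.12)

    def test_too_few_cells_rejected(self, vessel_inputs):
        geom, mats, comp, _ = vessel_inputs
        with pytest.raises(ValueError):
            build_section(geom, mats, comp, 1)

    def test_nvg_with_ccd_rejected(self, vessel_inputs):
        geom, mats, comp, _ = vessel_inputs
        with pytest.raises(ValueError):
            build_section(geom, mats, comp, 4, kind="NVG")  # baseline collagen is CCD

    def test_refinement_changes_little(self, vessel_inputs, gamma_cal):
        """Solved inner radius converges as the radial mesh is refined."""
        geom, mats, comp, rem = vessel_inputs
        ri = {}
        for n in (4, 8, 16):
            sec = build_section(geom, mats, comp, n, gamma_deg=gamma_cal)
            homeostasis_solve(sec, geom, rem)
            ri[n] = sec.solved["ri"]
        assert abs(ri[4] - ri[8]) < 2e-3  # mm
        assert abs(ri[8] - ri[16]) < abs(ri[4] - ri[8])  # converging


class TestEquilibrium:
    def test_unloaded_state_is_stress_free(self, vessel_inputs):
        geom, mats, comp, _ = vessel_inputs
        unloaded = VesselGeometry(
            Ri=geom.Ri, HM=geom.HM, HA=geom.HA, L=geom.L, lambda_z=1.0, p_i=0.0
        )
        sec = build_section(unloaded, mats, comp, 4, lambda_rec0=10.0)  # slack fibers
        equilibrium_solve(sec)
        assert sec.solved["ri"] == pytest.approx(geom.Ri, abs=1e-8)
        for key in ("sigma_rr", "sigma_tt", "sigma_zz"):
            assert np.allclose(sec.solved[key], 0.0, atol=1e-8)

    def test_thin_wall_laplace(self, vessel_inputs):
        """Mean hoop stress matches p r/h for a thin neo-Hookean ring."""
        _, mats, _, _ = vessel_inputs
        thin = VesselGeometry(Ri=8.4, HM=0.084, HA=0.084, L=147.4, lambda_z=1.0, p_i=0.5)
        mix = neo_hookean_mix()
        sec = build_section(thin, mats, {"media": mix, "adventitia": mix}, 4)
        equilibrium_solve(sec)
        ri, ro = sec.solved["ri"], sec.solved["ro"]
        laplace = thin.p_i * 0.5 * (ri + ro) / (ro - ri)
        assert sec.solved["sigma_tt"].mean() == pytest.approx(laplace, rel=0.05)

    def test_solved_state_invariants(self, homeostatic_section):
        s = homeostatic_section.solved
        geom = homeostatic_section.geom
        # incompressibility at every quadrature point
        lam_r, lam_t, lam_z = s["lam"]
        assert np.allclose(lam_r * lam_t * lam_z, 1.0, atol=1e-9)
        # radial equilibrium in integral form: int (s_tt - s_rr)/r dr = p_i
        v_hat = homeostatic_section.v_hat
        g = (s["sigma_tt"] - s["sigma_rr"]) * v_hat * homeostatic_section.R / (
            geom.lambda_z * s["r"] ** 2
        )
        assert np.sum(g * homeostatic_section.w) == pytest.approx(geom.p_i, rel=1e-6)
        assert s["residual"] < 1e-6 * geom.p_i
        # boundary conditions bracket the radial stress profile
        assert np.all(s["sigma_rr"] > -geom.p_i) and np.all(s["sigma_rr"] < 0.0)

    def test_radial_map_consistent_with_det(self, vessel_inputs):
        """Kinematic radial stretch equals v_hat R / (lambda_z r)."""
        geom, mats, comp, rem = vessel_inputs
        sec = build_section(geom, mats, comp, 4, kind="TVG")
        # impose a non-uniform collagen mass so v_hat varies across the wall
        sec.m_hat[:, 2:4] = np.linspace(1.0, 1.5, sec.n_cells)[:, None]
        equilibrium_solve(sec)
        lam_r, lam_t, lam_z = sec.solved["lam"]
        fg_n = sec.v_hat  # TVG: radial growth stretch = v_hat
        lam_rad_total = lam_r * fg_n
        expected = sec.v_hat * sec.R / (geom.lambda_z * sec.solved["r"])
        assert np.allclose(lam_rad_total, expected, atol=1e-10)

    def test_penalty_approaches_incompressible(self, vessel_inputs, homeostatic_section):
        """Je -> 1 monotonically over three decades of the bulk modulus."""
        geom, mats, comp, _ = vessel_inputs
        gaps, ris = [], []
        for kappa in (1e2, 1e3, 1e4):
            m = {
                lay: MaterialParams(
                    mu_e=mats[lay].mu_e, mu_g=mats[lay].mu_g,
                    k1=mats[lay].k1, k2=mats[lay].k2, kappa=kappa,
                )
                for lay in mats
            }
            sec = build_section(geom, m, comp, 4, gamma_deg=homeostatic_section.gamma_deg)
            sec.lambda_r = homeostatic_section.lambda_r.copy()
            equilibrium_solve(sec, mode="penalty")
            gaps.append(np.max(np.abs(sec.solved["Je"] - 1.0)))
            ris.append(sec.solved["ri"])
        assert gaps[0] > gaps[1] > gaps[2]
        assert abs(ris[-1] - homeostatic_section.solved["ri"]) < 0.2  # mm


class TestHomeostasis:
    def test_fiber_stretch_uniform_at_attachment(self, homeostatic_section):
        lam_c = np.sqrt(homeostatic_section.solved["I4c"])
        assert np.max(np.abs(lam_c - 1.093)) < 1e-6

    def test_fixed_point(self, vessel_inputs, homeostatic_section):
        """One more homeostasis sweep moves the recruitment field < 1e-9."""
        import copy

        geom, _, _, rem = vessel_inputs
        sec = copy.deepcopy(homeostatic_section)
        before = sec.lambda_r.copy()
        equilibrium_solve(sec, geom)
        lam_fiber = np.sqrt(sec.solved["I4bar"])
        after = np.repeat((lam_fiber / rem.lambda_a)[:, None], 2, axis=1)
        assert np.max(np.abs(after - before)) < 1e-9

    def test_recruitment_in_sanity_envelope(self, homeostatic_section):
        assert np.all(homeostatic_section.lambda_r >= 1.0)
        assert np.all(homeostatic_section.lambda_r <= 1.3)

    def test_records_reference_state(self, homeostatic_section):
        s = homeostatic_section.solved
        assert s["d0"] == pytest.approx(2 * s["ri"])
        assert s["h0"] == pytest.approx(s["ro"] - s["ri"])


def quick_sections(config, n_axial=3, n_radial=3):
    """Small homeostatic axial model for fast growth tests."""
    geom = config.geometry
    mats = {lay: config.materials(lay) for lay in ("media", "adventitia")}
    comp = {lay: config.composition(lay) for lay in ("media", "adventitia")}
    z = np.linspace(geom.L / 2, geom.L, n_axial)
    template = build_section(
        geom, mats, comp, n_radial, gamma_deg=49.2, kind=config.kind, z=z[0]
    )
    homeostasis_solve(template, geom, config.remodeling)
    sections = [template]
    for zk in z[1:]:
        s = build_section(
            geom, mats, comp, n_radial, gamma_deg=49.2, kind=config.kind, z=zk
        )
        s.lambda_r = template.lambda_r.copy()
        sections.append(s)
    return sections


class TestGrow:
    def test_homeostasis_preserved_without_degradation(self, baseline):
        """With intact elastin (c_min = 1) the run is a fixed point."""
        cfg = baseline.replace(remodeling={"c_min": 1.0})
        secs = quick_sections(cfg)
        lam_r0 = secs[0].lambda_r.copy()
        rec = grow(secs, cfg.geometry, cfg.remodeling, GrowthSchedule(dtau=0.05, tau_end=1.0))
        assert np.max(np.abs(rec.dhat - 1.0)) < 1e-7
        assert np.max(np.abs(secs[0].lambda_r - lam_r0)) < 1e-7
        assert rec.status == "completed"

    def test_nvg_conserves_total_volume(self, baseline):
        cfg = baseline.with_kind("NVG")
        secs = quick_sections(cfg)
        rec = grow(secs, cfg.geometry, cfg.remodeling, GrowthSchedule(dtau=0.02, tau_end=2.0))
        assert np.max(np.abs(rec.total_volume_ratio - 1.0)) < 1e-8
        assert np.all(np.diff(rec.tau) > 0)
        assert rec.dhat[0] == pytest.approx(1.0)

    def test_growth_monotone_under_degradation(self, baseline):
        secs = quick_sections(baseline)  # TVG, collagen CCD
        rec = grow(secs, baseline.geometry, baseline.remodeling,
                   GrowthSchedule(dtau=0.02, tau_end=2.0))
        assert rec.dhat[-1] > 1.005
        assert np.all(np.diff(rec.di) > -1e-9)

    def test_requires_homeostatic_input(self, baseline):
        geom = baseline.geometry
        mats = {lay: baseline.materials(lay) for lay in ("media", "adventitia")}
        comp = {lay: baseline.composition(lay) for lay in ("media", "adventitia")}
        sec = build_section(geom, mats, comp, 3)
        with pytest.raises(ValueError):
            grow([sec], geom, baseline.remodeling, GrowthSchedule())


def synthetic_record(tau, di, d0=23.0):
    tau = np.asarray(tau, dtype=float)
    di = np.asarray(di, dtype=float)
    n = tau.size
    return SimulationRecord(
        tau=tau,
        di=di,
        dhat=di / d0,
        thickness_mid=np.full(n, 1.0),
        lam_c_A=np.full(n, 1.093),
        m_c_A=np.ones(n),
        v_hat_A=np.ones(n),
        total_volume_ratio=np.ones(n),
        z=np.array([73.7]),
        thickness_z=np.array([1.0]),
        d0=d0,
        h0=1.0,
        status="completed",
    )


class TestMeasure:
    def test_constant_diameter_zero_rate(self):
        tau = np.linspace(0, 5, 101)
        m = measure(synthetic_record(tau, np.full(101, 23.0)))
        assert np.allclose(m["growth_rate"], 0.0, atol=1e-12)
        assert m["time_to_dhat_2"] is None
        assert m["time_to_repair"] is None

    def test_linear_growth_rate(self):
        c, d0 = 0.15, 23.0
        tau = np.linspace(0, 10, 501)
        m = measure(synthetic_record(tau, d0 * (1 + c * tau), d0=d0))
        interior = slice(60, -60)
        assert np.allclose(m["growth_rate"][interior], c * d0, rtol=1e-6)
        assert m["time_to_dhat_2"] == pytest.approx(1 / c, rel=1e-6)
        assert m["time_to_55mm"] == pytest.approx((55 / d0 - 1) / c, rel=1e-6)

    def test_window_longer_than_series_rejected(self):
        tau = np.linspace(0, 0.5, 10)
        with pytest.raises(ValueError):
            measure(synthetic_record(tau, np.full(10, 23.0)))
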