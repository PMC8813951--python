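"""Flow/transport solver: closed-form oracles, conservation, diagnostics."""

import numpy as np
import numpy.testing as npt
import pytest

from biofilmscape import synth
from biofilmscape.hydro import (
    FlowConvergenceError,
    GridConfig,
    build_domain,
    fit_inlet_profile,
    flux_decomposition,
    internal_velocity_stats,
    mass_conservation_residual,
    scalar_balance,
    solve_flow,
    solve_transport,
    wall_shear_dbl,
)
from biofilmscape.types import ModelParams

H = 0.005  # domain height (m)


class TestBuildDomain:
    def test_flat_zero_elevation_pure_free_flow(self):
        dom = build_domain(np.zeros(10), 2.0)
        assert not dom.bio.any()
        assert dom.biofilm_area_m2() == 0.0

    def test_flat_slab_area_exact(self):
        dom = build_domain(np.full(10, 0.4), 2.0)
        assert dom.biofilm_area_m2() == pytest.approx(2e-3 * 0.4e-3, rel=1e-12)

    def test_bump_area_matches_trapezoid_quadrature(self):
        x = np.linspace(0, 4, 200)
        elev = 0.2 + 0.9 * np.exp(-(((x - 2) / 0.7) ** 2))
        dom = build_domain(elev, 4.0, GridConfig(nx=64))
        exact = np.trapezoid(elev, x) * 1e-6  # mm^2 -> m^2
        assert dom.biofilm_area_m2() == pytest.approx(exact, rel=0.005)

    def test_excess_elevation_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clip"):
            dom = build_domain(np.full(10, 6.0), 2.0)  # 6 mm > 5 mm domain
        assert dom.elevation_m.max() <= dom.height_m + 1e-15

    def test_interface_resolved_by_fine_band(self):
        dom = build_domain(np.full(10, 0.4), 2.0, GridConfig(dz_fine_m=2.5e-5))
        # at least 3 fine cells straddle the interface band
        near = np.abs(dom.zc - 0.4e-3) < 1e-4
        assert near.sum() >= 3


class TestSolveFlow:
    def test_half_poiseuille_oracle(self, column_grid_config, still_water_params):
        """Pressure-driven channel (no-slip bottom, slip top) matches
        u(z) = (G/nu)(Hz - z^2/2) on a 64-cell column."""
        L = 0.002
        dom = build_domain(np.zeros(8), L * 1e3, column_grid_config)
        dpdx = 1.0  # Pa/m
        fl = solve_flow(
            dom,
            still_water_params,
            None,
            inlet="pressure",
            inlet_pressure_pa=dpdx * L,
            advection=False,
        )
        G = dpdx / still_water_params.rho_kgm3
        nu = still_water_params.nu_m2s
        u_exact = (G / nu) * (H * dom.zc - dom.zc**2 / 2)
        uc = 0.5 * (fl.u[:-1, :] + fl.u[1:, :])
        npt.assert_allclose(uc[4, :], u_exact, rtol=0.005)

    def test_darcy_slab_oracle(self, still_water_params):
        """Fully porous slab under a fixed pressure drop matches the
        Darcy closed form |u| = (K/mu)(dp/L)."""
        cfg = GridConfig(nx=8, height_m=H, dz_fine_m=H / 64, dz_max_m=H / 64, band_m=0.0)
        dom = build_domain(np.full(8, H * 1e3), 2.0, cfg)
        assert dom.bio.all()
        K = 1e-10
        params = still_water_params.replace(permeability_m2=K, porosity=0.5)
        dpdx = 1.0
        fl = solve_flow(
            dom,
            params,
            None,
            inlet="pressure",
            inlet_pressure_pa=dpdx * 0.002,
            bottom="slip",
            advection=False,
        )
        u_exact = K / (params.nu_m2s * params.rho_kgm3) * dpdx
        uc = 0.5 * (fl.u[:-1, :] + fl.u[1:, :])
        npt.assert_allclose(uc, u_exact, rtol=0.01)

    def test_zero_forcing_zero_field(self, column_grid_config, still_water_params):
        dom = build_domain(np.zeros(8), 2.0, column_grid_config)
        fl = solve_flow(dom, still_water_params, None, advection=False)
        assert np.abs(fl.u).max() == 0.0
        assert np.abs(fl.v).max() == 0.0

    def test_mass_conservation(self, bump_domain):
        params = ModelParams(eddy_visc_m2s=1e-5, porosity=0.5)
        inlet = fit_inlet_profile(synth.gen_inlet_profile(0.06))
        fl = solve_flow(bump_domain, params, inlet, advection=True)
        assert mass_conservation_residual(bump_domain, fl) < 1e-6

    def test_nonconvergence_raises_with_history(self, bump_domain):
        params = ModelParams(eddy_visc_m2s=1e-5)
        inlet = fit_inlet_profile(synth.gen_inlet_profile(0.13))
        with pytest.raises(FlowConvergenceError) as exc:
            solve_flow(bump_domain, params, inlet, advection=True, max_picard=2)
        assert len(exc.value.history) == 2


class TestSolveTransport:
    def test_reaction_diffusion_parabola_oracle(self):
        """Still slab with top Dirichlet c0 and uniform consumption r:
        c(z) = c0 - (r/2D)(L^2 - z^2); c(0) = 0.2375 mol/m^3 at the
        worked values."""
        L = 5e-4
        cfg = GridConfig(nx=4, height_m=L, dz_fine_m=L / 64, dz_max_m=L / 64, band_m=0.0)
        dom = build_domain(np.full(8, L * 1e3), 1.0, cfg)
        D = 2e-9
        params = ModelParams(c_eff_diff=1.0, d_aq_m2s=D, eddy_visc_m2s=0.0)
        fl = solve_flow(dom, params, None, advection=False)
        conc = solve_transport(
            dom, fl, params, inlet_conc=None, rate=-1e-3,
            top="dirichlet", top_value=0.3, n_correct=0,
        )
        c_exact = 0.3 - (1e-3 / (2 * D)) * (L**2 - dom.zc**2)
        assert c_exact[0] == pytest.approx(0.2375, abs=1e-4)
        npt.assert_allclose(conc.c[2, :], c_exact, rtol=0.005)

    def test_zero_rate_uniform_inlet_gives_constant_field(self, bump_domain):
        params = ModelParams(eddy_visc_m2s=1e-5)
        inlet = fit_inlet_profile(synth.gen_inlet_profile(0.06))
        fl = solve_flow(bump_domain, params, inlet, advection=False)
        conc = solve_transport(bump_domain, fl, params, inlet_conc=0.3, rate=0.0)
        npt.assert_allclose(conc.c, 0.3, rtol=1e-10)

    def test_deficit_linear_in_rate_without_flow(self):
        L = 5e-4
        cfg = GridConfig(nx=4, height_m=L, dz_fine_m=L / 32, dz_max_m=L / 32, band_m=0.0)
        dom = build_domain(np.full(8, L * 1e3), 1.0, cfg)
        params = ModelParams(c_eff_diff=1.0, d_aq_m2s=2e-9, eddy_visc_m2s=0.0)
        fl = solve_flow(dom, params, None, advection=False)
        kw = dict(inlet_conc=None, top="dirichlet", top_value=0.3, n_correct=0)
        c1 = solve_transport(dom, fl, params, rate=-5e-4, **kw).c
        c2 = solve_transport(dom, fl, params, rate=-1e-3, **kw).c
        npt.assert_allclose(0.3 - c2, 2 * (0.3 - c1), rtol=1e-10)

    def test_scalar_balance_at_steady_state(self, bump_domain):
        """Integral of R over the biofilm equals the net boundary flux
        within 1% (it is machine-exact for the conservative scheme)."""
        params = ModelParams(
            porosity=0.5, permeability_m2=1e-10, c_eff_diff=0.7,
            eddy_visc_m2s=1e-5, rate_mol_m3s=-1e-3,
        )
        inlet = fit_inlet_profile(synth.gen_inlet_profile(0.06))
        fl = solve_flow(bump_domain, params, inlet, advection=True)
        conc = solve_transport(bump_domain, fl, params, inlet_conc=0.3)
        bal = scalar_balance(bump_domain, fl, conc, params)
        assert bal["relative_imbalance"] < 0.01

    def test_excess_consumption_flagged_not_clipped(self):
        dom = build_domain(np.full(10, 2.0), 2.0, GridConfig(nx=10))
        params = ModelParams(c_eff_diff=0.5, eddy_visc_m2s=0.0, porosity=0.5)
        fl = solve_flow(dom, params, None, advection=False)
        with pytest.warns(UserWarning, match="consumption exceeds supply"):
            conc = solve_transport(
                dom, fl, params, inlet_conc=None, rate=-1e-2,
                top="dirichlet", top_value=0.3, n_correct=0,
            )
        assert conc.negative_warning
        assert conc.min_conc < 0  # preserved, not clipped

    def test_grid_convergence_biofilm_mean(self):
        """Halving the cell size changes the biofilm-mean concentration
        by less than 1%."""
        x = np.linspace(0, 4, 40)
        elev = 0.3 + 0.5 * np.exp(-(((x - 2) / 0.8) ** 2))
        params = ModelParams(
            porosity=0.5, permeability_m2=1e-10, c_eff_diff=0.7,
            eddy_visc_m2s=1e-5, rate_mol_m3s=-1e-3,
        )
        inlet = fit_inlet_profile(synth.gen_inlet_profile(0.06))
        means = []
        for nx, dz in [(24, 7e-5), (48, 3.5e-5)]:
            dom = build_domain(elev, 4.0, GridConfig(nx=nx, dz_fine_m=dz, dz_max_m=3e-4))
            fl = solve_flow(dom, params, inlet, advection=False)
            conc = solve_transport(dom, fl, params, inlet_conc=0.3)
            means.append(conc.c[dom.bio].mean())
        assert abs(means[1] - means[0]) / means[1] < 0.01


class TestFluxDecomposition:
    def test_zero_flow_zero_ratio(self):
        dom = build_domain(np.full(10, 0.5), 2.0, GridConfig(nx=10))
        params = ModelParams(eddy_visc_m2s=0.0, porosity=0.5, c_eff_diff=0.7)
        fl = solve_flow(dom, params, None, advection=False)
        conc = solve_transport(
            dom, fl, params, inlet_conc=None, rate=-1e-4,
            top="dirichlet", top_value=0.3, n_correct=0,
        )
        fd = flux_decomposition(dom, fl, conc, params)
        finite = np.isfinite(fd.ratio)
        assert fd.ratio[finite].max() == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_of_ratio(self):
        """|u c| / (D_eff |grad c|) = (1e-4 * 0.25)/(1.4e-9 * 100) ~ 1.79e2."""
        assert (1e-4 * 0.25) / (1.4e-9 * 100) == pytest.approx(178.57, rel=1e-3)

    def test_ratio_invariant_under_concentration_rescaling(self, bump_domain):
        params = ModelParams(
            porosity=0.5, permeability_m2=1e-10, c_eff_diff=0.7,
            eddy_visc_m2s=1e-5,
        )
        inlet = fit_inlet_profile(synth.gen_inlet_profile(0.06))
        fl = solve_flow(bump_domain, params, inlet, advection=False)
        c1 = solve_transport(bump_domain, fl, params, inlet_conc=0.3, rate=-1e-3)
        c2 = solve_transport(bump_domain, fl, params, inlet_conc=0.6, rate=-2e-3)
        fd1 = flux_decomposition(bump_domain, fl, c1, params)
        fd2 = flux_decomposition(bump_domain, fl, c2, params)
        assert fd2.biofilm_mean == pytest.approx(fd1.biofilm_mean, rel=1e-6)


class TestWallShearDbl:
    def test_friction_velocity_arithmetic(self):
        assert np.sqrt(1e-2 / 1000.0) == pytest.approx(3.1623e-3, rel=1e-4)

    def test_scale_chain_arithmetic(self):
        nu, u_star, sc = 1e-6, 1e-2, 400.0
        delta = nu / u_star
        assert delta == pytest.approx(1e-4)
        assert delta / np.sqrt(sc) == pytest.approx(5e-6)

    def test_poiseuille_wall_shear_matches_closed_form(
        self, column_grid_config, still_water_params
    ):
        """tau = mu_eff du/dz at the wall = rho G H analytically."""
        L = 0.002
        dom = build_domain(np.zeros(8), L * 1e3, column_grid_config)
        dpdx = 1.0
        fl = solve_flow(
            dom, still_water_params, None,
            inlet="pressure", inlet_pressure_pa=dpdx * L, advection=False,
        )
        ws = wall_shear_dbl(dom, fl, still_water_params)
        tau_exact = dpdx * H  # G*H in stress units
        assert ws["tau_pa"] == pytest.approx(tau_exact, rel=0.01)

    def test_zero_flow_degenerate(self, column_grid_config, still_water_params):
        dom = build_domain(np.zeros(8), 2.0, column_grid_config)
        fl = solve_flow(dom, still_water_params, None, advection=False)
        ws = wall_shear_dbl(dom, fl, still_water_params)
        assert ws["degenerate"]
        assert np.isinf(ws["delta_m"])


class TestInternalVelocityStats:
    def test_zero_flow_zero_speed(self):
        dom = build_domain(np.full(10, 0.5), 2.0, GridConfig(nx=10))
        params = ModelParams(eddy_visc_m2s=0.0, porosity=0.5)
        fl = solve_flow(dom, params, None, advection=False)
        assert internal_velocity_stats(dom, fl)["mean_speed_ms"] == 0.0

    def test_darcy_slab_mean_speed(self, still_water_params):
        cfg = GridConfig(nx=8, height_m=H, dz_fine_m=H / 32, dz_max_m=H / 32, band_m=0.0)
        dom = build_domain(np.full(8, H * 1e3), 2.0, cfg)
        K = 1e-10
        params = still_water_params.replace(permeability_m2=K, porosity=0.5)
        dpdx = 1.0
        fl = solve_flow(
            dom, params, None, inlet="pressure",
            inlet_pressure_pa=dpdx * 0.002, bottom="slip", advection=False,
        )
        u_exact = K / (params.nu_m2s * params.rho_kgm3) * dpdx
        stats = internal_velocity_stats(dom, fl)
        assert stats["mean_speed_ms"] == pytest.approx(u_exact, rel=0.01)

    def test_faster_flow_thins_viscous_sublayer(self, still_water_params):
        """Sublayer thickness scales like 1/u*: doubling the driving
        pressure shrinks the mean sublayer thickness."""
        L = 0.002
        cfg = GridConfig(nx=8, height_m=H, dz_fine_m=H / 96, dz_max_m=H / 96, band_m=0.0)
        dom = build_domain(np.zeros(8), L * 1e3, cfg)
        thick = []
        for dpdx in (1.0, 4.0):
            fl = solve_flow(
                dom, still_water_params, None,
                inlet="pressure", inlet_pressure_pa=dpdx * L, advection=False,
            )
            stats = internal_velocity_stats(dom, fl, still_water_params)
            thick.append(np.nanmean(stats["sublayer_thickness_m"]))
        assert thick[1] <= thick[0]
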