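"""Pressure rescaling, ΔP, WSS/TAWSS and sector analysis."""

import numpy as np
import pytest

from coarct import metrics
from coarct.geometry import VesselSpec, voxelize_spec
from coarct.lbm_core import LatticeSpec, Simulation, pressure_lb
from coarct.metrics import (
    EARLY_TIMES_S,
    CoverageError,
    InvalidPlaneError,
    PressureSeries,
    WSSSlice,
    delta_p,
    early_wss_features,
    fit_pressure_scaling,
    plane_average,
    reference_pressure_waveform,
    sector_tawss,
    tawss,
    wss_field,
)

from conftest import NU_BLOOD, SteadyTubeRun


class TestPressureScaling:
    def test_exact_linear_recovery(self):
        x = np.linspace(0.3, 0.4, 20)
        slope, intercept = fit_pressure_scaling(x, 3.0 * x + 7.0)
        assert slope == pytest.approx(3.0, abs=1e-10)
        assert intercept == pytest.approx(7.0, abs=1e-10)

    def test_constant_series_is_singular(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_pressure_scaling(np.full(20, 0.33), np.linspace(60, 120, 20))

    def test_rest_preset_attains_systolic_and_diastolic_anchors(self):
        t = np.linspace(0, 0.7, 20, endpoint=False)
        p = reference_pressure_waveform(t, 0.7, "rest")
        assert p.max() == pytest.approx(115.0)
        assert p.min() == pytest.approx(65.0)

    def test_mapped_series_reproduces_anchor_bounds(self):
        # a lattice trace affinely related to the reference maps back onto
        # the 115/65 mmHg anchors
        t = np.linspace(0, 0.7, 20, endpoint=False)
        p_ref = reference_pressure_waveform(t, 0.7, "rest")
        p_lb = 0.002 * p_ref + 0.31  # arbitrary affine lattice pressure
        slope, intercept = fit_pressure_scaling(p_lb, p_ref)
        mapped = slope * p_lb + intercept
        assert mapped.max() == pytest.approx(115.0, abs=1e-8)
        assert mapped.min() == pytest.approx(65.0, abs=1e-8)

    def test_noisy_slope_within_three_standard_errors(self, rng):
        x = np.linspace(0.3, 0.4, 20)
        sigma = 2.0
        y = 400.0 * x + 5.0 + rng.normal(0, sigma, size=20)
        slope, _ = fit_pressure_scaling(x, y)
        se = sigma / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(slope - 400.0) < 3 * se

    def test_roundtrip_identity_on_noiseless_data(self):
        x = np.linspace(0.3, 0.4, 20)
        y = -2.0 * x + 1.0
        slope, intercept = fit_pressure_scaling(x, y)
        x_back = (y - intercept) / slope
        assert np.allclose(x_back, x, atol=1e-12)


class TestDeltaP:
    def test_uniform_field_gives_zero(self):
        t = np.linspace(0, 0.7, 30)
        series = PressureSeries(times=t, p_prox=np.full(30, 90.0),
                                p_dist=np.full(30, 90.0))
        assert delta_p(series) == 0.0
        assert delta_p(series, t_peak=0.2) == 0.0

    def test_reported_at_peak_systole(self):
        t = np.linspace(0, 0.7, 71)
        dp_t = np.sin(np.pi * t / 0.7)  # peaks mid-cycle
        series = PressureSeries(times=t, p_prox=dp_t, p_dist=np.zeros_like(t))
        assert delta_p(series, t_peak=0.35) == pytest.approx(1.0, rel=1e-3)
        assert delta_p(series) == pytest.approx(1.0, rel=1e-3)

    def test_plane_outside_fluid_rejected(self):
        grid = voxelize_spec(VesselSpec(1.2e-3, 2.4e-3, dos=0.0), 1e-4)
        field = np.ones(grid.shape)
        with pytest.raises(InvalidPlaneError):
            plane_average(field, grid, grid.shape[0] + 5)

    def test_steady_poiseuille_pressure_drop(self, steady_tube):
        run = steady_tube
        rho, _ = run.sim.moments()
        p = pressure_lb(rho)
        n = run.grid.shape[0]
        i1, i2 = int(0.25 * n), int(0.75 * n)
        dp = plane_average(p, run.grid, i1) - plane_average(p, run.grid, i2)
        Qm = run.measured_flow_lb()
        D_eff = 2 * run.R_eff_lu  # area-equivalent lumen diameter
        L = i2 - i1
        mu_lb = run.spec.nu_lb  # lattice rho_ref = 1
        dp_analytic = 128 * mu_lb * L * Qm / (np.pi * D_eff**4)
        assert dp == pytest.approx(dp_analytic, rel=0.05)

    def test_dp_increases_with_flow_in_stenosed_tube(self):
        # fixed viscosity, increasing steady flow -> monotone ΔP
        dx = 1e-4
        spec_g = VesselSpec(16 * dx, 40 * dx, dos=0.5, stenosis_span=12 * dx)
        grid = voxelize_spec(spec_g, dx)
        spec = LatticeSpec(dx=dx, tau=0.8, nu_phys=NU_BLOOD)
        from coarct import boundaries

        area = (grid.node_class[1] != 0).sum()
        dps = []
        for u_mean in (0.004, 0.008, 0.016):
            sim = Simulation(grid, spec)
            bcs = (
                boundaries.InletBC(
                    grid, spec, Q_steady=u_mean * area * dx**3 / spec.dt
                ),
                boundaries.ResistanceOutletBC(grid, spec, 0.0),
            )
            sim.run_to_steady(boundaries=bcs, tol=1e-8, window=200, max_steps=8000)
            rho, _ = sim.moments()
            p = pressure_lb(rho)
            dps.append(plane_average(p, grid, 2) - plane_average(p, grid, 37))
        assert dps[0] < dps[1] < dps[2]


class TestWSS:
    def test_zero_flow_gives_zero_wss(self):
        dx = 1e-4
        grid = voxelize_spec(VesselSpec(12 * dx, 20 * dx, dos=0.0), dx)
        sim = Simulation(grid, LatticeSpec(dx=dx, tau=0.8, nu_phys=NU_BLOOD))
        assert np.allclose(wss_field(sim), 0.0, atol=1e-14)

    def test_poiseuille_wall_shear(self, steady_tube):
        run = steady_tube
        w = wss_field(run.sim)
        mid_mask = np.abs(run.grid.wall_nodes[:, 0] - run.mid) <= 2
        w_lb = w[mid_mask].mean() / (
            run.spec.rho_phys * run.spec.dx**2 / run.spec.dt**2
        )
        R = run.R_eff_lu
        u_bar = run.measured_flow_lb() / (np.pi * R**2)
        w_analytic = 4 * run.spec.nu_lb * u_bar / R  # 4 mu u_bar / R, rho_ref=1
        assert w_lb == pytest.approx(w_analytic, rel=0.10)

    def test_wss_doubles_with_viscosity_at_matched_flow(self):
        runs = {}
        for tau in (0.65, 0.8):  # nu_lb 0.05 and 0.10 at matched lattice flow
            runs[tau] = SteadyTubeRun(D_lu=12, L_over_D=2, tau=tau,
                                      u_mean_lb=0.008, max_steps=12_000)
        w = {}
        for tau, run in runs.items():
            mid_mask = np.abs(run.grid.wall_nodes[:, 0] - run.mid) <= 2
            w[tau] = wss_field(run.sim)[mid_mask].mean() / (
                run.spec.rho_phys * run.spec.dx**2 / run.spec.dt**2
            )
        assert w[0.8] / w[0.65] == pytest.approx(2.0, rel=0.10)


class TestTAWSS:
    def test_constant_series(self):
        t = np.linspace(0, 0.7, 80)
        assert tawss(np.full(80, 2.5), t, 0.7) == pytest.approx(2.5)

    def test_rectified_sine_integral(self):
        T, A = 0.7, 3.0
        t = np.linspace(0, T, 2000)
        w = A * np.abs(np.sin(2 * np.pi * t / T))
        assert tawss(w, t, T) == pytest.approx(2 * A / np.pi, rel=1e-4)

    def test_short_series_rejected(self):
        t = np.linspace(0, 0.3, 30)
        with pytest.raises(CoverageError):
            tawss(np.ones(30), t, 0.7)

    def test_time_shift_invariance(self):
        T = 0.7
        t = np.linspace(0, T, 500, endpoint=False)
        w = 1.0 + 0.5 * np.sin(2 * np.pi * t / T + 0.3)
        shifted = 1.0 + 0.5 * np.sin(2 * np.pi * (t + 0.123) / T + 0.3)
        assert tawss(shifted, t, T) == pytest.approx(tawss(w, t, T), rel=1e-3)


class TestSectors:
    def _slice(self, wss_fn, n=40, nt=30):
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        sectors = (ang // (np.pi / 2)).astype(int) + 1
        t = np.linspace(0, 0.7, nt)
        wss = np.array([wss_fn(a) * np.ones(nt) for a in ang])
        return WSSSlice(angles=ang, sectors=sectors, times=t, wss=wss)

    def test_axisymmetric_slice_has_equal_sectors(self):
        sl = self._slice(lambda a: 1.7)
        sector_means, circ = sector_tawss(sl, 0.7)
        assert np.allclose(sector_means, circ)
        assert circ == pytest.approx(1.7)

    def test_single_hot_sector(self):
        sl = self._slice(lambda a: 2.0 if a < np.pi / 2 else 0.0)
        sector_means, _ = sector_tawss(sl, 0.7)
        assert sector_means[0] == pytest.approx(2.0)
        assert np.allclose(sector_means[1:], 0.0)

    def test_circumferential_mean_is_count_weighted_sector_mean(self, rng):
        ang = rng.uniform(0, 2 * np.pi, 57)
        sectors = (ang // (np.pi / 2)).astype(int) + 1
        t = np.linspace(0, 0.7, 20)
        wss = rng.uniform(0, 3, size=(57, 20))
        sl = WSSSlice(angles=ang, sectors=sectors, times=t, wss=wss)
        sector_means, circ = sector_tawss(sl, 0.7)
        counts = np.array([(sectors == s).sum() for s in (1, 2, 3, 4)])
        weighted = np.nansum(sector_means * counts) / counts.sum()
        assert circ == pytest.approx(weighted, rel=1e-12)

    def test_empty_sector_warns_and_reports_nan(self):
        ang = np.linspace(0.1, np.pi - 0.1, 10)  # sectors 1-2 only
        sectors = (ang // (np.pi / 2)).astype(int) + 1
        t = np.linspace(0, 0.7, 5)
        sl = WSSSlice(angles=ang, sectors=sectors, times=t,
                      wss=np.ones((10, 5)))
        with pytest.warns(UserWarning, match="sector"):
            sector_means, _ = sector_tawss(sl, 0.7)
        assert np.isnan(sector_means[2]) and np.isnan(sector_means[3])


class TestEarlyWSS:
    def test_constant_series(self):
        t = np.linspace(0, 0.2, 50)
        assert early_wss_features(t, np.full(50, 1.3)) == pytest.approx(
            (1.3, 1.3, 1.3)
        )

    def test_linear_series_matches_interpolation(self):
        t = np.linspace(0, 0.2, 50)
        w = 10.0 * t
        feats = early_wss_features(t, w)
        assert feats == pytest.approx(tuple(10.0 * np.array(EARLY_TIMES_S)))

    def test_truncated_run_uses_15_percent_of_rest_cycle(self):
        # stopping at the last feature time (0.105 s) costs 15% of a 0.7 s cycle
        assert max(EARLY_TIMES_S) / 0.7 == pytest.approx(0.15)

    def test_coverage_error_before_last_feature_time(self):
        t = np.linspace(0, 0.09, 20)
        with pytest.raises(CoverageError):
            early_wss_features(t, np.ones(20))
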