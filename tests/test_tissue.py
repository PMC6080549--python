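"""Monodomain solver: symmetry, conservation, CV measurement/calibration
and activation maps."""

import numpy as np
import pytest

from shortqt._kernels import run_diffusion
from shortqt.geometry import (GeometrySpec, TissueGrid, make_fixture_field,
                              make_transmural_cable)
from shortqt.tissue import (ActivationMaps, FieldTrace, StimulusSchedule,
                            _edge_stim, activation_maps,
                            calibrate_conductivity, compute_wavelength,
                            measure_cv, simulate_monodomain)


def small_cable(n=60, dx=0.02, ct=2):
    return TissueGrid(n, 1, dx, np.full(n, ct, dtype=np.int8),
                      0.3247, 0.3247)


def field_trace_from(grid, t, V):
    stim = StimulusSchedule((np.empty(0, dtype=np.int64),),
                            np.array([0.0]))
    n = grid.n_nodes
    return FieldTrace(grid=grid, t=t, V=V.astype(np.float32),
                      probe_t=np.array([0.0]), probe_V=np.zeros((1, 1)),
                      probe_nodes=np.array([0]), stim=stim,
                      eat=np.full(n, np.nan), edt=np.full(n, np.nan),
                      map_start=0.0)


class TestSolverBasics:
    def test_resting_tissue_stays_uniform(self):
        g = TissueGrid(20, 20, 0.05, np.full(400, 2, dtype=np.int8),
                       0.3247, 0.3247 * 2.25)
        stim = StimulusSchedule((np.empty(0, dtype=np.int64),),
                                np.array([-1.0]))
        tr = simulate_monodomain(g, "wt", stim, 200.0, record_dt=200.0)
        spread = tr.V[-1].max() - tr.V[-1].min()
        assert spread < 1e-6

    def test_point_stimulus_symmetric_propagation(self):
        g = small_cable(81)
        mid = 40
        nodes = np.arange(mid - 2, mid + 3, dtype=np.int64)
        stim = StimulusSchedule((nodes,), np.array([5.0]))
        tr = simulate_monodomain(g, "wt", stim, 120.0, record_dt=1e9)
        eat = tr.eat
        left, right = eat[:mid][::-1], eat[mid + 1:]
        m = min(len(left), len(right))
        np.testing.assert_allclose(left[:m], right[:m], atol=1e-6)

    def test_diffusion_conserves_total_voltage(self):
        """No-flux diffusion (reaction disabled) conserves sum(V)."""
        rng = np.random.default_rng(3)
        V = rng.uniform(-90.0, 30.0, 32 * 32)
        total0 = V.sum()
        run_diffusion(V, 32, 32, 0.1, 0.05, 200)
        assert abs(V.sum() - total0) < 1e-8 * abs(total0) * 200

    def test_unstable_step_rejected(self):
        g = small_cable()
        g = g.with_rho(g.rho_x / 100.0)   # huge diffusivity
        stim = StimulusSchedule((_edge_stim(g),), np.array([5.0]))
        with pytest.raises(ValueError):
            simulate_monodomain(g, "wt", stim, 10.0)


class TestMeasureCV:
    def test_analytic_traveling_wave(self):
        t, V, truth = make_fixture_field("analytic_wave", cv_cm_s=50.0,
                                         dt_ms=0.5)
        grid = small_cable(V.shape[1])
        tr = field_trace_from(grid, t, V)
        assert measure_cv(tr, grid) == pytest.approx(50.0, abs=0.5)

    def test_time_rescaling_halves_cv(self):
        t, V, _ = make_fixture_field("analytic_wave", cv_cm_s=50.0,
                                     dt_ms=0.5)
        grid = small_cable(V.shape[1])
        slow = field_trace_from(grid, 2.0 * t, V)
        assert measure_cv(slow, grid) == pytest.approx(25.0, abs=0.5)

    def test_no_traversal_rejected(self):
        grid = small_cable(50)
        t = np.arange(0.0, 50.0, 1.0)
        V = np.full((t.size, 50), -85.0)
        with pytest.raises(ValueError):
            measure_cv(field_trace_from(grid, t, V), grid)


class TestCalibration:
    def test_cv_scales_with_root_diffusivity(self):
        """CV ratio follows sqrt(D) across a 4x resistivity change."""
        g = small_cable(100)
        cvs = []
        for rho in (g.rho_x / 2, g.rho_x, 2 * g.rho_x):
            gg = g.with_rho(rho)
            stim = StimulusSchedule((_edge_stim(gg),), np.array([5.0]))
            tr = simulate_monodomain(gg, "wt", stim, 120.0, record_dt=1e9)
            cvs.append(measure_cv(tr, gg))
        assert cvs[0] / cvs[1] == pytest.approx(np.sqrt(2.0), rel=0.06)
        assert cvs[1] / cvs[2] == pytest.approx(np.sqrt(2.0), rel=0.06)

    def test_calibration_hits_target(self, cable_runs):
        assert cable_runs["wt"]["cv"] == pytest.approx(67.4, rel=0.02)
        assert cable_runs["s140g"]["cv"] == pytest.approx(64.7, rel=0.02)

    def test_cv_grid_convergence(self):
        """|CV(dx) - CV(dx/2)| / CV < 5% at matched diffusivity.

        Checked in the asymptotic regime (dx = 0.01 -> 0.005 cm, dt scaled
        with dx); production grids are conductivity-calibrated at their own
        resolution, which pins CV regardless of residual dx bias.
        """
        cvs = []
        for dx, dt in ((0.01, 0.02), (0.005, 0.005)):
            spec = GeometrySpec(shape="cable", length_cm=2.0, dx=dx,
                                layer_fractions=(0.0, 0.0, 1.0))
            g = make_transmural_cable(spec)
            stim = StimulusSchedule((_edge_stim(g),), np.array([5.0]))
            tr = simulate_monodomain(g, "wt", stim, 80.0, record_dt=1e9,
                                     dt=dt)
            cvs.append(measure_cv(tr, g))
        assert abs(cvs[0] - cvs[1]) / cvs[1] < 0.05

    def test_out_of_range_target_rejected(self):
        g = small_cable()
        with pytest.raises(ValueError):
            calibrate_conductivity(g, 500.0)


class TestActivationMaps:
    def test_exact_recovery_on_constructed_field(self):
        grid = small_cable(5)
        t = np.arange(0.0, 400.0, 1.0)
        V = np.full((t.size, 5), -85.0)
        on = np.array([10, 20, 30, 40, 50])
        off = on + 200
        for i in range(5):
            V[(t >= on[i]) & (t < off[i]), i] = 20.0
        maps = activation_maps(field_trace_from(grid, t, V))
        np.testing.assert_allclose(maps.eat, on - 0.5, atol=0.55)
        np.testing.assert_allclose(maps.edt, off - 0.5, atol=0.55)
        assert maps.qrs_proxy == pytest.approx(40.0, abs=1.0)

    def test_edt_after_eat_enforced(self):
        with pytest.raises(ValueError):
            ActivationMaps(eat=np.array([10.0]), edt=np.array([5.0]))

    def test_unactivated_nodes_flagged_absent(self):
        grid = small_cable(3)
        t = np.arange(0.0, 100.0, 1.0)
        V = np.full((t.size, 3), -85.0)
        V[(t >= 10) & (t < 60), 0] = 0.0
        maps = activation_maps(field_trace_from(grid, t, V))
        assert np.isfinite(maps.eat[0])
        assert np.isnan(maps.eat[1]) and np.isnan(maps.eat[2])


class TestWavelength:
    def test_arithmetic(self):
        assert compute_wavelength(67.4, 309.0) == pytest.approx(20.83,
                                                                abs=0.01)
        assert compute_wavelength(64.7, 126.0) == pytest.approx(8.15,
                                                                abs=0.01)
        assert compute_wavelength(50.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_wavelength(-1.0, 100.0)

    def test_mutant_wavelength_shorter_on_matched_cable(self, cable_runs):
        assert (cable_runs["s140g"]["wavelength"]
                < cable_runs["wt"]["wavelength"])

    def test_qrs_proxy_similar_qt_proxy_shorter(self, cable_runs):
        wt, mut = cable_runs["wt"]["maps"], cable_runs["s140g"]["maps"]
        assert abs(mut.qrs_proxy - wt.qrs_proxy) / wt.qrs_proxy < 0.10
        assert mut.qt_proxy < wt.qt_proxy
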