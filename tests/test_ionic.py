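"""Myocyte model: I_Ks formulations, calcium fluxes, bookkeeping and the
wild-type limit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shortqt import rates as rt
from shortqt.ionic import (CellParams, CellState, cell_derivatives,
                           cell_params, calcium_fluxes, compute_iks_mutant,
                           compute_iks_wt, membrane_currents, resting_state,
                           step_cell)


class TestIKs:
    def test_reversal_potential_zeroes_current(self):
        assert compute_iks_wt(-70.0, 0.5, -70.0, 0.5096) == 0.0

    def test_closed_gate_zeroes_current(self):
        assert compute_iks_wt(20.0, 0.0, -70.0, 0.5096) == 0.0

    def test_hand_value(self):
        # G_Ks x_s^2 (V - E_Ks) = 0.5096 * 0.01 * 90
        assert compute_iks_wt(20.0, 0.1, -70.0, 0.5096) == pytest.approx(
            0.45864, rel=1e-12)

    def test_mutant_reduces_to_wt_at_phi_zero(self):
        p = cell_params("endo", "wt")
        for V in (-80.0, -20.0, 30.0):
            assert compute_iks_mutant(V, 0.3, -70.0, p) == compute_iks_wt(
                V, 0.3, -70.0, p.g_ks)

    def test_mutant_component_vanishes_at_mutant_reversal(self):
        p = cell_params("endo", "s140g")
        wt = compute_iks_wt(-75.3, 0.2, -70.0, p.g_ks)
        assert compute_iks_mutant(-75.3, 0.2, -70.0, p) == pytest.approx(wt)

    def test_mutant_instantaneous_component_value(self):
        # phi G_Ks (V - E'_rev) = 0.1 * 0.5096 * 20 with the gated term zero
        p = CellParams(cell_type="endo", phi=0.1, g_ks=0.5096)
        assert compute_iks_mutant(-55.3, 0.0, -70.0, p) == pytest.approx(
            1.0192, rel=1e-12)

    @given(st.floats(-90, 50), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_mutant_exceeds_wt_above_mutant_reversal(self, V, xs):
        p = cell_params("M", "s140g")
        diff = compute_iks_mutant(V, xs, -70.0, p) - compute_iks_wt(
            V, xs, -70.0, p.g_ks)
        assert diff == pytest.approx(p.phi * p.g_ks * (V + 75.3), rel=1e-9)


class TestCalciumFluxes:
    def test_equal_concentrations_zero_leak(self):
        s = resting_state()
        s.y[14] = s.y[15] = 0.5  # Cai = Casr
        leak, _, _ = calcium_fluxes(s, cell_params("endo"))
        assert leak == 0.0

    def test_leak_hand_value(self):
        s = resting_state()
        s.y[15] = 3.0
        s.y[14] = 0.0002
        leak, _, _ = calcium_fluxes(s, cell_params("endo"), v_leak=8e-5)
        assert leak == pytest.approx(8e-5 * (3.0 - 0.0002), rel=1e-12)

    def test_release_zero_when_recovery_gate_closed(self):
        s = resting_state()
        s.y[13] = 0.0  # RyR recovery variable
        _, _, rel = calcium_fluxes(s, cell_params("endo"))
        assert rel == 0.0

    def test_nonpositive_concentration_rejected(self):
        s = resting_state()
        s.y[14] = 0.0
        with pytest.raises(ValueError):
            calcium_fluxes(s, cell_params("endo"))


class TestDerivatives:
    def test_quiescent_equilibrium(self):
        """After 10 s without stimulus the state is stationary."""
        p = cell_params("endo", "wt")
        s = resting_state()
        for _ in range(5000):
            s = step_cell(s, p, 0.1)
        dy = cell_derivatives(s, p)
        assert abs(dy[0]) < 1e-3  # dV/dt in mV/ms

    def test_stimulus_enters_voltage_equation(self):
        p = cell_params("endo", "wt")
        s = resting_state()
        d0 = cell_derivatives(s, p, I_stim=0.0)
        d1 = cell_derivatives(s, p, I_stim=-52.0)
        assert d1[0] - d0[0] == pytest.approx(52.0, rel=1e-12)

    def test_continuity_in_phi(self):
        s = resting_state()
        d0 = cell_derivatives(s, cell_params("endo", "wt"))
        p_eps = CellParams(cell_type="endo", phi=1e-12)
        d1 = cell_derivatives(s, p_eps)
        # difference is exactly the phi-term, |phi G_Ks (V-E'_rev)| ~ 1e-11
        np.testing.assert_allclose(d0, d1, rtol=1e-9, atol=2e-11)

    def test_charge_bookkeeping(self):
        """I_ion equals the sum of the listed membrane currents exactly."""
        s = resting_state()
        s.y[0] = -20.0
        cur = membrane_currents(s, cell_params("M", "s140g"))
        manual = (cur.I_Na + cur.I_K1 + cur.I_to + cur.I_Kr + cur.I_Ks
                  + cur.I_CaL + cur.I_NaCa + cur.I_NaK + cur.I_pCa
                  + cur.I_pK + cur.I_bCa + cur.I_bNa)
        assert cur.I_ion == manual

    def test_kernel_matches_reference_derivatives(self):
        """One compiled step agrees with the reference vector field."""
        p = cell_params("epi", "s140g")
        s = resting_state()
        s.y[0] = -30.0  # mid-repolarization, all currents active
        dt = 1e-5
        nxt = step_cell(s, p, dt)
        dy = cell_derivatives(s, p)
        # voltage and concentrations advance by dt * derivative
        for idx in (0, 14, 15, 17, 18):
            assert nxt.y[idx] - s.y[idx] == pytest.approx(
                dt * dy[idx], rel=5e-3, abs=1e-12)


class TestPacedProperties:
    def test_gate_boundedness_and_positivity(self):
        p = cell_params("M", "s140g")
        s = resting_state()
        for k in range(25000):  # one 500 ms beat at dt 0.02
            s = step_cell(s, p, 0.02, I_stim=-52.0 if k < 50 else 0.0)
            if k % 500 == 0:
                s.validate()
        s.validate()

    def test_mutation_direction(self, paced_traces, apd_table):
        """phi > 0: larger I'_Ks averaged over the AP, shorter APD90."""
        for ct in ("endo", "M", "epi"):
            wt, mut = paced_traces[(ct, "wt")], paced_traces[(ct, "s140g")]

            def ap_mean(tr, apd):
                t0 = tr.stim_times[-1]
                sel = (tr.t >= t0) & (tr.t <= t0 + apd)
                return tr.IKs[sel].mean()

            assert (ap_mean(mut, apd_table[(ct, "s140g")])
                    > ap_mean(wt, apd_table[(ct, "wt")]))
            assert apd_table[(ct, "s140g")] < apd_table[(ct, "wt")]

    def test_validation_rejects_bad_params(self):
        with pytest.raises(ValueError):
            CellParams(cell_type="atrial")
        with pytest.raises(ValueError):
            CellParams(phi=1.5)
        with pytest.raises(ValueError):
            cell_params("endo", "sqts1")
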