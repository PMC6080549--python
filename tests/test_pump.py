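"""Material law, ventricular pressure law and the closed circulation."""

import numpy as np
import pytest

from shortqt.pump import (CirculationParams, CirculationState,
                          MaterialParams, VentriclePumpParams,
                          activation_from_calcium, circulation_step,
                          green_strain, passive_strain_energy,
                          ventricular_pressure)


class TestStrainEnergy:
    def test_reference_state_zero(self):
        assert passive_strain_energy({}) == 0.0

    def test_fiber_stretch_hand_value(self):
        # Q = 8 * 0.1^2 = 0.08 -> W = (2/2)(e^0.08 - 1)
        W = passive_strain_energy({"Eff": 0.1})
        assert W == pytest.approx(np.exp(0.08) - 1.0, rel=1e-12)

    def test_monotone_in_fiber_strain(self):
        vals = [passive_strain_energy({"Eff": e})
                for e in (0.0, 0.05, 0.1, 0.2, -0.25)]
        assert vals[0] < vals[1] < vals[2] < vals[3]
        assert vals[4] > vals[2]   # even in |E_ff|

    def test_convex_about_reference(self):
        h = 0.01
        for comp in ("Eff", "Err", "Ecc", "Erc", "Efr", "Efc"):
            w0 = passive_strain_energy({comp: 0.0})
            wp = passive_strain_energy({comp: h})
            wm = passive_strain_energy({comp: -h})
            assert wp + wm - 2 * w0 > 0

    def test_overflow_guard(self):
        with pytest.raises(OverflowError):
            passive_strain_energy({"Eff": 3.0})

    def test_matrix_input_matches_dict(self):
        E = np.zeros((3, 3))
        E[0, 0] = 0.1
        assert passive_strain_energy(E) == passive_strain_energy(
            {"Eff": 0.1})


class TestGreenStrain:
    def test_identity_is_strain_free(self):
        np.testing.assert_allclose(green_strain(np.eye(3)), 0.0)

    def test_uniaxial_stretch(self):
        F = np.diag([1.1, 1.0, 1.0])
        E = green_strain(F)
        assert E[0, 0] == pytest.approx(0.105, rel=1e-12)

    def test_rigid_rotation_objectivity(self):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        np.testing.assert_allclose(green_strain(R), 0.0, atol=1e-12)

    def test_singular_gradient_rejected(self):
        with pytest.raises(ValueError):
            green_strain(np.zeros((3, 3)))


class TestVentricularPressure:
    par = VentriclePumpParams(c_active=0.4, c_passive=12.0,
                              v_rest_d=10.0, v_rest_s=15.0)

    def test_zero_at_diastolic_rest_volume(self):
        assert ventricular_pressure(10.0, 0.0, self.par) == 0.0

    def test_zero_at_systolic_rest_volume_full_activation(self):
        assert ventricular_pressure(15.0, 1.0, self.par) == 0.0

    def test_activated_stiffness_hand_value(self):
        # V - V_rest,s = 10 mL over C_act = 0.4 -> 25 mmHg
        assert ventricular_pressure(25.0, 1.0, self.par) == pytest.approx(
            25.0)

    def test_activation_ordering(self):
        assert (ventricular_pressure(80.0, 1.0, self.par)
                > ventricular_pressure(80.0, 0.3, self.par)
                > ventricular_pressure(80.0, 0.0, self.par))

    def test_invalid_compliances_rejected(self):
        with pytest.raises(ValueError):
            VentriclePumpParams(c_active=5.0, c_passive=1.0,
                                v_rest_d=10.0, v_rest_s=15.0)


def equilibrium_state(par: CirculationParams, p: float = 5.0
                      ) -> CirculationState:
    """Volumes chosen so every compartment sits at the same pressure."""
    return CirculationState({
        "LV": par.lv.v_rest_d + par.lv.c_passive * p,
        "RV": par.rv.v_rest_d + par.rv.c_passive * p,
        "SA": par.v0_sa + par.c_sa * p,
        "SV": par.v0_sv + par.c_sv * p,
        "PA": par.v0_pa + par.c_pa * p,
        "PV": par.v0_pv + par.c_pv * p,
        "LA": par.v0_la + par.c_la * p,
        "RA": par.v0_ra + par.c_ra * p,
    })


class TestCirculation:
    def test_equal_pressures_no_flow(self):
        par = CirculationParams()
        st = equilibrium_state(par)
        nxt, flows = circulation_step(st, par, 0.0, 0.0, 0.5)
        assert all(q == 0.0 for q in flows.values())
        assert nxt.volumes == st.volumes

    def test_aortic_valve_forward_flow(self):
        par = CirculationParams()
        st = equilibrium_state(par)
        st.volumes["LV"] += 50.0   # raise LV pressure above SA
        p = st.pressures(par, 1.0, 0.0)
        _, flows = circulation_step(st, par, 1.0, 0.0, 0.5)
        assert flows["AO"] == pytest.approx((p["LV"] - p["SA"]) / par.r_ao)
        assert flows["MI"] == 0.0   # mitral shut against the gradient

    def test_valves_never_conduct_backward(self):
        par = CirculationParams()
        st = equilibrium_state(par)
        st.volumes["SA"] += 200.0   # arterial pressure above everything
        _, flows = circulation_step(st, par, 0.0, 0.0, 0.5)
        assert flows["AO"] == 0.0

    def test_volume_conservation_over_cycles(self):
        """Closed loop conserves total blood volume to 1e-4 relative."""
        par = CirculationParams()
        st = CirculationState()
        total0 = st.total_volume()
        t = np.arange(0.0, 600.0, 1.0)
        yv = np.clip(np.sin(np.pi * (t - 50) / 250.0), 0, 1) ** 2
        for _ in range(20):           # 20 cycles of 600 ms at dt 0.5
            for k in range(1200):
                y = float(np.interp(k * 0.5, t, yv))
                st, _ = circulation_step(st, par, y, y, 0.5)
        assert abs(st.total_volume() - total0) / total0 < 1e-4

    def test_oversized_step_rejected(self):
        par = CirculationParams()
        with pytest.raises(ValueError):
            circulation_step(CirculationState(), par, 0.0, 0.0, 5.0)


class TestActivation:
    def test_zero_force_gives_zero_activation(self):
        import pandas as pd
        f = pd.DataFrame({"t_ms": np.arange(10.0), "force": np.zeros(10)})
        t, yv, ref = activation_from_calcium(f)
        assert np.all(yv == 0.0) and ref == 0.0

    def test_wt_reference_peak_is_unity(self):
        import pandas as pd
        f = pd.DataFrame({"t_ms": np.arange(5.0),
                          "force": [0.0, 0.2, 0.7, 0.4, 0.1]})
        _, yv, ref = activation_from_calcium(f)
        assert yv.max() == 1.0 and ref == 0.7

    def test_shared_reference_keeps_mutant_below_unity(self):
        import pandas as pd
        f = pd.DataFrame({"t_ms": np.arange(3.0),
                          "force": [0.0, 0.1, 0.05]})
        _, yv, _ = activation_from_calcium(f, reference_peak=0.7)
        assert yv.max() == pytest.approx(0.1 / 0.7)
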