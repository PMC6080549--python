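"""Rice-style myofilament cross-bridge cycling driven by the calcium
transient, producing normalized active force and a contractile
ATP-consumption rate.

Four regulatory/cross-bridge states — nonpermissive ``N``, permissive
``P``, strongly-bound pre-rotation ``XB_PreR`` and post-rotation
``XB_PostR`` — cycle with rates f_appT, g_appT, h_fT, h_bT and the
ATP-consuming detachment rate g_xbT.  The nonpermissive↔permissive
transition is steeply cooperative in regulatory-troponin calcium
(exponent ±7.5 on the occupied fraction).  Mean cross-bridge distortions
(xXB_PreR, xXB_PostR) evolve alongside; the sarcomere is held isometric
at 2.0 µm, so the sarcomere-length overlap factors are constants.

Normalized active force:

    F = SOVF_thick · (xXB_PreR·XB_PreR + xXB_PostR·XB_PostR)
        / (x_0 · XB_PostR_Max)

Contractile ATP consumption is the beat average of the detachment flux
g_xbT · XB_PostR (the g_xbT transition hydrolyses one ATP per cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = ["MyofilamentParams", "MyofilamentState", "xb_derivatives",
           "active_force", "atp_rate", "run_myofilament",
           "MYO_STATE_NAMES"]

MYO_STATE_NAMES = ("N", "P", "XBprer", "XBpostr", "xXBprer", "xXBpostr",
                   "TRPNCaL", "TRPNCaH")


def _sovf(sl_um: float) -> tuple[float, float]:
    """Thick/thin single-overlap fractions at sarcomere length ``sl_um``."""
    len_thin, len_thick, len_hbare = 1.2, 1.65, 0.1
    sovr_ze = min(len_thick / 2, sl_um / 2)
    sovr_cle = max(sl_um / 2 - (sl_um - len_thin), len_hbare / 2)
    len_sovr = max(sovr_ze - sovr_cle, 0.0)
    return (2.0 * len_sovr / (len_thick - len_hbare),
            len_sovr / len_thin)


@dataclass(frozen=True)
class MyofilamentParams:
    """Transition rates (per ms) and geometry of the cross-bridge cycle."""

    f_app: float = 0.5       # P -> XB_PreR attachment
    g_app: float = 0.07      # XB_PreR -> P reverse
    h_f: float = 2.0         # XB_PreR -> XB_PostR rotation
    h_b: float = 0.4         # XB_PostR -> XB_PreR reverse
    g_xb: float = 0.07       # XB_PostR -> P ATP-consuming detachment
    kn_p: float = 0.5        # N -> P base rate
    kp_n: float = 0.05       # P -> N base rate
    perm50: float = 0.5      # half-activation of the cooperative switch
    n_perm: float = 15.0     # 2 x 7.5 cooperativity exponent
    k_on: float = 50.0       # Ca on-rate, 1/(mM ms)
    k_off_l: float = 0.25    # low-affinity troponin off-rate
    k_off_h: float = 0.025   # high-affinity troponin off-rate
    x0: float = 0.007        # power-stroke distortion (µm)
    hfmdc: float = 5.0
    sigma_p: float = 8.0
    sigma_n: float = 1.0
    x_psi: float = 2.0
    sl_um: float = 2.0       # isometric sarcomere length

    @property
    def sovf_thick(self) -> float:
        return _sovf(self.sl_um)[0]

    @property
    def sovf_thin(self) -> float:
        return _sovf(self.sl_um)[1]

    @property
    def xb_postr_max(self) -> float:
        """Optimal-condition occupancy used to normalize force."""
        f, g, hf, hb, gxb = self.f_app, self.g_app, self.h_f, self.h_b, self.g_xb
        denom = gxb * hf + f * hf + gxb * g + hb * f + hb * g + gxb * f
        return f * hf / denom

    @property
    def xb_prer_max(self) -> float:
        f, g, hf, hb, gxb = self.f_app, self.g_app, self.h_f, self.h_b, self.g_xb
        denom = gxb * hf + f * hf + gxb * g + hb * f + hb * g + gxb * f
        return (hb * f + gxb * f) / denom


@dataclass
class MyofilamentState:
    """State vector wrapper (order fixed by ``MYO_STATE_NAMES``)."""

    y: np.ndarray = field(default_factory=lambda: np.array(
        [0.98, 0.02, 0.0, 0.0, 0.0, 0.007, 0.015, 0.13]))

    def __getattr__(self, name):
        try:
            return self.y[MYO_STATE_NAMES.index(name)]
        except ValueError:
            raise AttributeError(name) from None

    @property
    def occupancy_sum(self) -> float:
        return float(self.y[:4].sum())


def _rates(y: np.ndarray, p: MyofilamentParams):
    """Instantaneous transition rates given the current state."""
    xprer, xpostr = y[4], y[5]
    trop_reg = ((1.0 - p.sovf_thin) * y[6] + p.sovf_thin * y[7])
    trop_reg = max(trop_reg, 1e-9)
    permtot = np.sqrt(1.0 / (1.0 + (p.perm50 / trop_reg) ** p.n_perm))
    inprmt = min(1.0 / permtot, 100.0)
    knp = p.kn_p * permtot
    kpn = p.kp_n * inprmt
    hf = p.h_f * np.exp(-np.sign(xprer) * p.hfmdc * (xprer / p.x0) ** 2)
    if xpostr < p.x0:
        gxb = p.g_xb * np.exp(p.sigma_p * ((p.x0 - xpostr) / p.x0) ** 2)
    else:
        gxb = p.g_xb * np.exp(p.sigma_n * ((xpostr - p.x0) / p.x0) ** 2)
    return knp, kpn, p.f_app, p.g_app, hf, p.h_b, gxb


def xb_derivatives(mf: MyofilamentState | np.ndarray, Ca_mM: float,
                   params: MyofilamentParams = MyofilamentParams()
                   ) -> np.ndarray:
    """Time derivative of the myofilament state (per ms).

    The four occupancy derivatives sum to zero by construction; a
    negative-occupancy excursion beyond tolerance raises.
    """
    y = mf.y if isinstance(mf, MyofilamentState) else np.asarray(mf, float)
    # tolerance accommodates stiff-solver trial states slightly below zero
    if np.any(y[:4] < -1e-3):
        raise ValueError("negative cross-bridge occupancy")
    N, P, prer, postr = y[:4]
    knp, kpn, fapp, gapp, hf, hb, gxb = _rates(y, params)

    dy = np.empty_like(y)
    dy[0] = -knp * N + kpn * P
    dy[1] = knp * N - kpn * P - fapp * P + gapp * prer + gxb * postr
    dy[2] = fapp * P - (gapp + hf) * prer + hb * postr
    dy[3] = hf * prer - (hb + gxb) * postr

    duty_prer = max(params.xb_prer_max, 1e-9)
    duty_postr = max(params.xb_postr_max, 1e-9)
    dy[4] = params.x_psi / duty_prer * (
        -fapp * y[4] + hb * (y[5] - params.x0 - y[4]))
    dy[5] = params.x_psi / duty_postr * hf * (y[4] + params.x0 - y[5])

    dy[6] = params.k_on * Ca_mM * (1.0 - y[6]) - params.k_off_l * y[6]
    dy[7] = params.k_on * Ca_mM * (1.0 - y[7]) - params.k_off_h * y[7]
    return dy


def active_force(mf: MyofilamentState | np.ndarray,
                 params: MyofilamentParams = MyofilamentParams()) -> float:
    """Normalized active force (dimensionless, ~1 at optimal activation)."""
    y = mf.y if isinstance(mf, MyofilamentState) else np.asarray(mf, float)
    norm = params.x0 * params.xb_postr_max
    if norm <= 0:
        raise ZeroDivisionError("force normalization constant is zero")
    return float(params.sovf_thick * (y[4] * y[2] + y[5] * y[3]) / norm)


def run_myofilament(ca_t_ms: np.ndarray, ca_mm: np.ndarray,
                    params: MyofilamentParams = MyofilamentParams(),
                    n_beats: int = 3, bcl_ms: float | None = None,
                    dt_out: float = 1.0) -> pd.DataFrame:
    """Drive the cross-bridge model with a periodic Ca transient.

    The single-beat transient is repeated ``n_beats`` times to reach a
    cyclic steady state; the returned frame covers the final beat with
    columns t_ms, force, atp_flux (1/ms) and all state variables.
    """
    ca_t_ms = np.asarray(ca_t_ms, float) - ca_t_ms[0]
    if bcl_ms is None:
        bcl_ms = float(ca_t_ms[-1])

    def ca_of(t):
        return np.interp(t % bcl_ms, ca_t_ms, ca_mm)

    def rhs(t, y):
        return xb_derivatives(y, ca_of(t), params)

    y0 = MyofilamentState().y.copy()
    sol_last = None
    for b in range(n_beats):
        t_eval = (np.arange(0.0, bcl_ms, dt_out) if b == n_beats - 1
                  else None)
        sol = solve_ivp(rhs, (0.0, bcl_ms), y0, method="LSODA",
                        t_eval=t_eval, max_step=5.0, rtol=1e-6, atol=1e-9)
        if not sol.success:
            raise RuntimeError(f"myofilament integration failed: {sol.message}")
        y0 = sol.y[:, -1]
        sol_last = sol

    t = sol_last.t
    Y = sol_last.y
    force = np.array([active_force(Y[:, k], params) for k in range(t.size)])
    atp = np.array([_rates(Y[:, k], params)[6] * Y[3, k]
                    for k in range(t.size)])
    df = pd.DataFrame({"t_ms": t, "force": force, "atp_flux": atp})
    for i, nm in enumerate(MYO_STATE_NAMES):
        df[nm] = Y[i]
    return df


def atp_rate(trace: pd.DataFrame, bcl_ms: float | None = None) -> float:
    """Contractile ATP consumption rate (per second).

    Cycle integral of the g_xbT·XB_PostR detachment flux divided by the
    beat duration.
    """
    if bcl_ms is None:
        bcl_ms = float(trace["t_ms"].iloc[-1] - trace["t_ms"].iloc[0])
    if bcl_ms <= 0 or len(trace) < 2:
        raise ValueError("trace must span at least one full beat")
    t = trace["t_ms"].to_numpy()
    flux = trace["atp_flux"].to_numpy()
    integral = np.trapezoid(flux, t)            # dimensionless cycles
    return float(integral / bcl_ms * 1000.0)    # per second
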