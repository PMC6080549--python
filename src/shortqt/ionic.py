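"""Human ventricular myocyte model (ten Tusscher family, 2006 base
formulation) with a wild-type and an S140G-mutant slow delayed rectifier.

The S140G gain-of-function substitution in KCNQ1 adds a constitutively
active, instantaneous component to I_Ks:

    I'_Ks = I_Ks + phi * G_Ks * (V - E'_rev)

with expressivity ``phi`` (0.1 for the intermediate-expressivity condition
studied here) and mutant reversal potential E'_rev = −75.3 mV.  With
``phi = 0`` the model reduces exactly to the wild-type base model.

Transmural heterogeneity enters through the I_Ks and I_to conductances:
endocardial/epicardial cells use G_Ks = 0.392·1.3 mS/µF, mid-myocardial
cells G_Ks = 0.098·2.0 mS/µF; G_to is 0.073 mS/µF in endocardium and
0.294 mS/µF in mid-myocardium and epicardium.

This module holds the readable reference implementation (scalar NumPy)
used for tests and current bookkeeping; production integration runs in the
compiled kernels of :mod:`shortqt._kernels`, which are generated from the
same rate functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import rates as rt
from . import _kernels as kern

__all__ = [
    "CellParams", "CellState", "CurrentBreakdown", "resting_state",
    "compute_iks_wt", "compute_iks_mutant", "calcium_fluxes",
    "cell_derivatives", "step_cell", "cell_params", "membrane_currents",
]

#: study conductance overrides, (G_Ks, G_to) in mS/µF per cell type
CONDUCTANCES = {
    "endo": (0.392 * 1.3, 0.073),
    "M": (0.098 * 2.0, 0.294),
    "epi": (0.392 * 1.3, 0.294),
}

CELL_TYPE_INDEX = {"endo": 0, "M": 1, "epi": 2}


@dataclass(frozen=True)
class CellParams:
    """Per-cell electrophysiological parameters."""

    cell_type: str = "endo"
    phi: float = 0.0                 # mutant expressivity, 0 = wild type
    e_rev_mut: float = -75.3         # mV, mutant instantaneous reversal
    g_ks: float | None = None        # mS/µF; default by cell type
    g_to: float | None = None        # mS/µF; default by cell type
    stim_amplitude: float = -52.0    # pA/pF
    stim_duration: float = 1.0       # ms
    dt: float = 0.02                 # ms

    def __post_init__(self):
        if self.cell_type not in CONDUCTANCES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        gks, gto = CONDUCTANCES[self.cell_type]
        if self.g_ks is None:
            object.__setattr__(self, "g_ks", gks)
        if self.g_to is None:
            object.__setattr__(self, "g_to", gto)
        if self.g_ks <= 0:
            raise ValueError("G_Ks must be positive")

    def with_condition(self, condition: str) -> "CellParams":
        """Return params for ``'wt'`` (phi=0) or ``'s140g'`` (phi=0.1)."""
        if condition not in ("wt", "s140g"):
            raise ValueError(f"unknown condition {condition!r}")
        return replace(self, phi=0.1 if condition == "s140g" else 0.0)


@dataclass
class CellState:
    """Full ionic state of one myocyte (vector order fixed by ``rates``)."""

    y: np.ndarray = field(default_factory=lambda: rt.REST_STATE.copy())

    def __getattr__(self, name):
        try:
            return self.y[rt.STATE_NAMES.index(name)]
        except ValueError:
            raise AttributeError(name) from None

    def copy(self) -> "CellState":
        return CellState(self.y.copy())

    def validate(self) -> None:
        gates = self.y[1:14]
        if np.any((gates < -1e-9) | (gates > 1 + 1e-9)):
            raise ValueError("gate variable escaped [0, 1]")
        if np.any(self.y[14:19] <= 0):
            raise ValueError("ion concentration must stay positive")


def resting_state() -> CellState:
    """Published resting state of the base model (x_s = 0.00357)."""
    return CellState()


@dataclass(frozen=True)
class CurrentBreakdown:
    """All membrane currents (pA/pF) and SR fluxes (mM/ms) at one instant."""

    I_Na: float
    I_K1: float
    I_to: float
    I_Kr: float
    I_Ks: float      # I'_Ks when phi > 0
    I_CaL: float
    I_NaCa: float
    I_NaK: float
    I_pCa: float
    I_pK: float
    I_bCa: float
    I_bNa: float
    I_leak: float
    I_up: float
    I_rel: float
    I_xfer: float

    @property
    def I_ion(self) -> float:
        return (self.I_Na + self.I_K1 + self.I_to + self.I_Kr + self.I_Ks
                + self.I_CaL + self.I_NaCa + self.I_NaK + self.I_pCa
                + self.I_pK + self.I_bCa + self.I_bNa)


def compute_iks_wt(V: float, x_s: float, E_Ks: float, G_Ks: float) -> float:
    """Wild-type slow delayed rectifier, G_Ks·x_s²·(V − E_Ks) (pA/pF)."""
    return G_Ks * x_s * x_s * (V - E_Ks)


def compute_iks_mutant(V: float, x_s: float, E_Ks: float,
                       params: CellParams) -> float:
    """Mutant I'_Ks: the WT current plus the instantaneous S140G component."""
    iks = compute_iks_wt(V, x_s, E_Ks, params.g_ks)
    if params.phi > 0.0:
        iks += params.phi * params.g_ks * (V - params.e_rev_mut)
    return iks


def calcium_fluxes(state: CellState, params: CellParams,
                   v_leak: float | None = None
                   ) -> tuple[float, float, float]:
    """SR leak, SERCA uptake and CICR release fluxes (mM/ms).

    ``v_leak`` overrides the maximal leak rate (useful for sensitivity
    checks); release follows the load-sensitive RyR open probability.
    """
    Cai, Casr, Cass = state.Cai, state.Casr, state.Cass
    if Cai <= 0 or Casr <= 0 or Cass <= 0:
        raise ValueError("calcium concentrations must be positive")
    vl = rt.V_LEAK if v_leak is None else v_leak
    i_leak = vl * (Casr - Cai)
    i_up = rt.V_MAXUP / (1.0 + rt.K_UP ** 2 / Cai ** 2)
    i_rel = rt.V_REL * rt.ryr_open(Cass, Casr, state.Rbar) * (Casr - Cass)
    return i_leak, i_up, i_rel


def membrane_currents(state: CellState, params: CellParams) -> CurrentBreakdown:
    """Evaluate every current of the model at the given state."""
    y = state.y
    (V, m, h, j, d, f, f2, fcass, r, s, xs, xr1, xr2, _rbar, Cai, Casr,
     Cass, Nai, Ki) = y

    EK = rt.RTF * np.log(rt.K_O / Ki)
    ENa = rt.RTF * np.log(rt.NA_O / Nai)
    EKs = rt.RTF * np.log((rt.K_O + rt.P_KNA * rt.NA_O)
                          / (Ki + rt.P_KNA * Nai))
    ECa = 0.5 * rt.RTF * np.log(rt.CA_O / Cai)

    a1, a2 = rt.ical_factors(V)
    t1, t2 = rt.naca_factors(V)
    sqko = np.sqrt(rt.K_O / 5.4)
    i_leak, i_up, i_rel = calcium_fluxes(state, params)

    return CurrentBreakdown(
        I_Na=rt.G_NA * m ** 3 * h * j * (V - ENa),
        I_K1=rt.G_K1 * sqko * float(rt.xk1_inf(V - EK)) * (V - EK),
        I_to=params.g_to * r * s * (V - EK),
        I_Kr=rt.G_KR * sqko * xr1 * xr2 * (V - EK),
        I_Ks=compute_iks_mutant(V, xs, EKs, params),
        I_CaL=rt.G_CAL * d * f * f2 * fcass * (float(a1) * Cass - float(a2)),
        I_NaCa=float(t1) * Nai ** 3 - float(t2) * Cai,
        I_NaK=float(rt.nak_factor(V)) * Nai / (Nai + rt.K_MNA),
        I_pCa=rt.G_PCA * Cai / (rt.K_PCA + Cai),
        I_pK=rt.G_PK * float(rt.ipk_factor(V)) * (V - EK),
        I_bCa=rt.G_BCA * (V - ECa),
        I_bNa=rt.G_BNA * (V - ENa),
        I_leak=i_leak, I_up=i_up, I_rel=i_rel,
        I_xfer=rt.V_XFER * (Cass - Cai),
    )


def cell_derivatives(state: CellState, params: CellParams,
                     I_stim: float = 0.0) -> np.ndarray:
    """Time derivative of the full state vector (reference path).

    dV/dt = −(I_ion + I_stim) in mV/ms with currents in pA/pF; gates
    follow their (inf, tau) kinetics; calcium, sodium and potassium
    balances carry the capacitance-to-volume factors of the base model
    and rapid-equilibrium buffering in cytosol, SR and subspace.
    """
    y = state.y
    V, Cai, Casr, Cass = y[0], y[14], y[15], y[16]
    cur = membrane_currents(state, params)

    dy = np.empty_like(y)
    dy[0] = -(cur.I_ion + I_stim)

    gate_kinetics = {
        1: rt.m_gate(V), 2: rt.h_gate(V), 3: rt.j_gate(V), 4: rt.d_gate(V),
        5: rt.f_gate(V), 6: rt.f2_gate(V), 7: rt.fcass_gate(Cass),
        8: rt.r_gate(V), 9: rt.s_gate(V, params.cell_type),
        10: rt.xs_gate(V), 11: rt.xr1_gate(V), 12: rt.xr2_gate(V),
    }
    for idx, (inf, tau) in gate_kinetics.items():
        dy[idx] = (inf - y[idx]) / tau

    k2 = rt.K2_PRIME * rt.kcasr(Casr)
    dy[13] = -k2 * Cass * y[13] + rt.K4_RYR * (1.0 - y[13])

    cm_2vcf = rt.CM / (2.0 * rt.V_C * rt.F)
    cm_2vssf = rt.CM / (2.0 * rt.V_SS * rt.F)
    cm_vcf = rt.CM / (rt.V_C * rt.F)

    buf_c = 1.0 / (1.0 + rt.BUF_C * rt.K_BUFC / (Cai + rt.K_BUFC) ** 2)
    buf_sr = 1.0 / (1.0 + rt.BUF_SR * rt.K_BUFSR / (Casr + rt.K_BUFSR) ** 2)
    buf_ss = 1.0 / (1.0 + rt.BUF_SS * rt.K_BUFSS / (Cass + rt.K_BUFSS) ** 2)

    dy[14] = buf_c * ((cur.I_leak - cur.I_up) * rt.V_SR / rt.V_C
                      + cur.I_xfer
                      - (cur.I_bCa + cur.I_pCa - 2.0 * cur.I_NaCa) * cm_2vcf)
    dy[15] = buf_sr * (cur.I_up - cur.I_leak - cur.I_rel)
    dy[16] = buf_ss * (-cur.I_CaL * cm_2vssf + cur.I_rel * rt.V_SR / rt.V_SS
                       - cur.I_xfer * rt.V_C / rt.V_SS)
    dy[17] = -(cur.I_Na + cur.I_bNa + 3.0 * cur.I_NaK
               + 3.0 * cur.I_NaCa) * cm_vcf
    dy[18] = -(cur.I_K1 + cur.I_to + cur.I_Kr + cur.I_Ks + cur.I_pK
               - 2.0 * cur.I_NaK + I_stim) * cm_vcf

    if not np.all(np.isfinite(dy)):
        raise FloatingPointError("non-finite state derivative (blow-up)")
    return dy


def step_cell(state: CellState, params: CellParams, dt: float,
              I_stim: float = 0.0) -> CellState:
    """Advance one step: Rush–Larsen gates, explicit Euler elsewhere.

    Uses the compiled kernel, so long integrations via repeated calls agree
    exactly with the production drivers.
    """
    lut, lutk = kern.build_tables(dt)
    S = state.y.reshape(1, -1).copy()
    stype = np.array([CELL_TYPE_INDEX[params.cell_type]], dtype=np.int8)
    kern._reaction_step(
        S, stype, np.array([params.g_ks]), np.array([params.g_to]),
        params.phi, params.e_rev_mut, np.array([float(I_stim)]), dt,
        lut, lutk)
    if not np.all(np.isfinite(S)):
        raise FloatingPointError("cell state became non-finite")
    return CellState(S[0])


def cell_params(cell_type: str, condition: str = "wt", **kw) -> CellParams:
    """Convenience constructor: ``cell_params('M', 's140g')``."""
    return CellParams(cell_type=cell_type, **kw).with_condition(condition)
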