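"""Gating kinetics and voltage-dependent current factors of the base
human ventricular myocyte model (ten Tusscher–Panfilov 2006 formulation).

Every function here is written for scalar or ndarray ``V`` (mV) and is the
single source of truth for both the slow reference implementation in
:mod:`shortqt.ionic` and the tabulated fast kernels in
:mod:`shortqt._kernels`.
"""

from __future__ import annotations

import numpy as np

# physical constants
R = 8314.472      # mJ/(mol K)
T = 310.0         # K
F = 96485.3415    # C/mol
RTF = R * T / F   # mV

# extracellular concentrations (mM)
K_O = 5.4
NA_O = 140.0
CA_O = 2.0

# maximal conductances / permeabilities (base model)
G_NA = 14.838
G_K1 = 5.405
G_KR = 0.153
G_CAL = 3.98e-5
G_BNA = 0.00029
G_BCA = 0.000592
G_PCA = 0.1238
K_PCA = 0.0005
G_PK = 0.0146
P_KNA = 0.03

# Na/K pump and Na/Ca exchanger
P_NAK = 2.724
K_MK = 1.0
K_MNA = 40.0
K_NACA = 1000.0
K_SAT = 0.1
ALPHA_NACA = 2.5
GAMMA_NACA = 0.35
KM_NAI = 87.5
KM_CA = 1.38

# calcium subsystem: SERCA uptake, SR leak, diffusional transfer and the
# ryanodine-receptor CICR release with its Casr-modulated open probability
V_MAXUP = 0.006375
K_UP = 0.00025
V_LEAK = 0.00036
V_XFER = 0.0038
V_REL = 0.102
K1_PRIME = 0.15
K2_PRIME = 0.045
K3_RYR = 0.06
K4_RYR = 0.005
MAX_SR = 2.5
MIN_SR = 1.0
EC_SR = 1.5
BUF_C = 0.2
K_BUFC = 0.001
BUF_SR = 10.0
K_BUFSR = 0.3
BUF_SS = 0.4
K_BUFSS = 0.00025

# cell geometry / capacitance used in the ion-balance factors
CM = 0.185        # membrane capacitance (uF)
V_C = 0.016404    # cytoplasmic volume
V_SR = 0.001094   # SR volume
V_SS = 5.468e-5   # dyadic subspace volume

# published 1 Hz steady state of the base model; the I_Ks activation gate
# is started at 0.00357 (the stated steady-state value) and every
# simulation is re-conditioned by pacing before metrics are read.
REST_STATE = np.array([
    -85.23,      # V
    0.00172,     # m
    0.7444,      # h
    0.7045,      # j
    3.373e-5,    # d
    0.7888,      # f
    0.9755,      # f2
    0.9953,      # fCass
    2.42e-8,     # r
    0.999998,    # s
    0.00357,     # xs
    0.00621,     # xr1
    0.4712,      # xr2
    0.9073,      # Rbar (RyR recovery)
    0.000126,    # Cai
    3.64,        # Casr
    0.00036,     # Cass
    8.604,       # Nai
    136.89,      # Ki
])

STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "f2", "fCass", "r", "s", "xs", "xr1",
    "xr2", "Rbar", "Cai", "Casr", "Cass", "Nai", "Ki",
)


def m_gate(V):
    inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    a = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    b = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    return inf, a * b


def h_gate(V):
    inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    lo = V < -40.0
    a = np.where(lo, 0.057 * np.exp(-(V + 80.0) / 6.8), 0.0)
    b = np.where(
        lo,
        2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V),
        0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
    )
    return inf, 1.0 / (a + b)


def j_gate(V):
    inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    lo = V < -40.0
    a = np.where(
        lo,
        (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0,
    )
    b = np.where(
        lo,
        0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )
    return inf, 1.0 / (a + b)


def d_gate(V):
    inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    a = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    b = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    c = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    return inf, a * b + c


def f_gate(V):
    inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau = (1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
           + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
           + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    return inf, tau


def f2_gate(V):
    inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau = (562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
           + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
           + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    return inf, tau


def fcass_gate(Cass):
    """Subspace-Ca-dependent I_CaL inactivation (not voltage dependent)."""
    x = (Cass / 0.05) ** 2
    inf = 0.6 / (1.0 + x) + 0.4
    tau = 80.0 / (1.0 + x) + 2.0
    return inf, tau


def r_gate(V):
    inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    return inf, tau


def s_gate(V, cell_type: str):
    """Slow I_to inactivation; the endocardial variant differs."""
    if cell_type == "endo":
        inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:  # epi and M share the epicardial kinetics
        inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau = 85.0 * np.exp(-((V + 45.0) ** 2) / 320.0) + 5.0 / (
            1.0 + np.exp((V - 20.0) / 5.0)) + 3.0
    return inf, tau


def xs_gate(V):
    inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    a = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    b = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    return inf, a * b + 80.0


def xr1_gate(V):
    inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    a = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    b = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    return inf, a * b


def xr2_gate(V):
    inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    a = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    b = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    return inf, a * b


def xk1_inf(u):
    """Inward-rectifier gating as a function of u = V - E_K."""
    a = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    b = (3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0))) / (
        1.0 + np.exp(-0.5 * u))
    return a / (a + b)


def kcasr(Casr):
    """SR-load modulation of the RyR rate constants."""
    return MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / Casr) ** 2)


def ryr_open(Cass, Casr, Rbar):
    """RyR open probability O = k1 Cass^2 Rbar / (k3 + k1 Cass^2)."""
    k1 = K1_PRIME / kcasr(Casr)
    return k1 * Cass ** 2 * Rbar / (K3_RYR + k1 * Cass ** 2)


def ical_factors(V):
    """I_CaL = G_CaL * d*f*f2*fCass * (a1(V)*Cass - a2(V)).

    GHK-type driving force centred at +15 mV; the removable singularity
    there is handled analytically.
    """
    V = np.asarray(V, dtype=float)
    z = 2.0 * (V - 15.0) / RTF
    with np.errstate(over="ignore"):
        e2 = np.exp(z)
    pref = 4.0 * (V - 15.0) * F / RTF  # 4 (V-15) F^2 / (R T)
    small = np.abs(V - 15.0) < 1e-9
    denom = np.where(small, 1.0, e2 - 1.0)
    a1 = np.where(small, 2.0 * F * 0.25, pref * 0.25 * e2 / denom)
    a2 = np.where(small, 2.0 * F * CA_O, pref * CA_O / denom)
    return a1, a2


def naca_factors(V):
    """I_NaCa = t1(V)*Nai^3 - t2(V)*Cai."""
    evf = np.exp(GAMMA_NACA * V / RTF)
    evr = np.exp((GAMMA_NACA - 1.0) * V / RTF)
    denom = (KM_NAI ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * evr)
    t1 = K_NACA * evf * CA_O / denom
    t2 = K_NACA * evr * NA_O ** 3 * ALPHA_NACA / denom
    return t1, t2


def nak_factor(V):
    """I_NaK = nak(V) * Nai / (Nai + K_mNa)."""
    return P_NAK * (K_O / (K_O + K_MK)) / (
        1.0 + 0.1245 * np.exp(-0.1 * V / RTF) + 0.0353 * np.exp(-V / RTF))


def ipk_factor(V):
    return 1.0 / (1.0 + np.exp((25.0 - V) / 5.98))
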