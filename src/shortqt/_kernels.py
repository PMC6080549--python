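"""Compiled integration kernels for the myocyte and monodomain models.

The voltage-dependent gate kinetics and current factors are tabulated once
per time step size (Rush–Larsen exponentials are baked into the table) and
looked up with linear interpolation inside the numba kernels; the
calcium-driven gates (fCass, the RyR recovery variable) and the ion
balances are evaluated directly.  The tables are generated from
:mod:`shortqt.rates`, which is also what the slow reference implementation
uses, so the two code paths cannot drift apart.

State vector layout (19 per node):
V, m, h, j, d, f, f2, fCass, r, s, xs, xr1, xr2, Rbar, Cai, Casr, Cass,
Nai, Ki.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import rates as rt

N_STATE = 19

# voltage grids for the lookup tables
VMIN, VMAX, DV = -100.0, 80.0, 0.02
UMIN, UMAX, DU = -160.0, 160.0, 0.02

# column layout of the main table
(C_MINF, C_MB, C_HINF, C_HB, C_JINF, C_JB, C_DINF, C_DB, C_FINF, C_FB,
 C_F2INF, C_F2B, C_RINF, C_RB, C_SINF_EPI, C_SB_EPI, C_SINF_ENDO,
 C_SB_ENDO, C_XSINF, C_XSB, C_XR1INF, C_XR1B, C_XR2INF, C_XR2B,
 C_A1, C_A2, C_T1, C_T2, C_NAK, C_IPK) = range(30)

_lut_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def build_tables(dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate gate updates (for fixed ``dt``) and V-dependent factors."""
    key = round(float(dt), 9)
    if key in _lut_cache:
        return _lut_cache[key]
    V = np.arange(VMIN, VMAX + DV / 2, DV)
    lut = np.empty((V.size, 30))

    def put(cinf, cb, inf, tau):
        lut[:, cinf] = inf
        lut[:, cb] = np.exp(-dt / tau)

    put(C_MINF, C_MB, *rt.m_gate(V))
    put(C_HINF, C_HB, *rt.h_gate(V))
    put(C_JINF, C_JB, *rt.j_gate(V))
    put(C_DINF, C_DB, *rt.d_gate(V))
    put(C_FINF, C_FB, *rt.f_gate(V))
    put(C_F2INF, C_F2B, *rt.f2_gate(V))
    put(C_RINF, C_RB, *rt.r_gate(V))
    put(C_SINF_EPI, C_SB_EPI, *rt.s_gate(V, "epi"))
    put(C_SINF_ENDO, C_SB_ENDO, *rt.s_gate(V, "endo"))
    put(C_XSINF, C_XSB, *rt.xs_gate(V))
    put(C_XR1INF, C_XR1B, *rt.xr1_gate(V))
    put(C_XR2INF, C_XR2B, *rt.xr2_gate(V))
    lut[:, C_A1], lut[:, C_A2] = rt.ical_factors(V)
    lut[:, C_T1], lut[:, C_T2] = rt.naca_factors(V)
    lut[:, C_NAK] = rt.nak_factor(V)
    lut[:, C_IPK] = rt.ipk_factor(V)

    u = np.arange(UMIN, UMAX + DU / 2, DU)
    lutk = rt.xk1_inf(u)
    _lut_cache[key] = (lut, lutk)
    return lut, lutk


# constants pulled in as compile-time literals
RTF = rt.RTF
K_O, NA_O, CA_O = rt.K_O, rt.NA_O, rt.CA_O
G_NA, G_K1, G_KR, G_CAL = rt.G_NA, rt.G_K1, rt.G_KR, rt.G_CAL
G_BNA, G_BCA, G_PCA, K_PCA, G_PK = rt.G_BNA, rt.G_BCA, rt.G_PCA, rt.K_PCA, rt.G_PK
P_KNA, K_MNA = rt.P_KNA, rt.K_MNA
V_MAXUP, K_UP, V_LEAK, V_XFER, V_REL = (rt.V_MAXUP, rt.K_UP, rt.V_LEAK,
                                        rt.V_XFER, rt.V_REL)
K1P, K2P, K3R, K4R = rt.K1_PRIME, rt.K2_PRIME, rt.K3_RYR, rt.K4_RYR
MAX_SR, MIN_SR, EC_SR = rt.MAX_SR, rt.MIN_SR, rt.EC_SR
BUF_C, K_BUFC = rt.BUF_C, rt.K_BUFC
BUF_SR, K_BUFSR = rt.BUF_SR, rt.K_BUFSR
BUF_SS, K_BUFSS = rt.BUF_SS, rt.K_BUFSS
CM, V_C, V_SR, V_SS = rt.CM, rt.V_C, rt.V_SR, rt.V_SS
SQRT_KO = np.sqrt(K_O / 5.4)
CM_2VCF = CM / (2.0 * V_C * rt.F)
CM_VCF = CM / (V_C * rt.F)
CM_2VSSF = CM / (2.0 * V_SS * rt.F)
VSR_VC = V_SR / V_C
VSR_VSS = V_SR / V_SS
VC_VSS = V_C / V_SS


@njit(cache=True, fastmath=True)
def _reaction_step(S, stype, gks, gto, phi, erev, istim, dt, lut, lutk):
    """Advance every node one ``dt``: Rush–Larsen gates, explicit ions.

    Returns the I_ion of the *first* node (handy for single-cell traces).
    """
    nvl = lut.shape[0] - 2
    nul = lutk.shape[0] - 2
    iion0 = 0.0
    for i in range(S.shape[0]):
        V = S[i, 0]
        pos = (V - VMIN) * (1.0 / DV)
        if pos < 0.0:
            pos = 0.0
        elif pos > nvl:
            pos = float(nvl)
        k = int(pos)
        w = pos - k

        def _lk(c):
            return lut[k, c] + w * (lut[k + 1, c] - lut[k, c])

        # Rush-Larsen gate updates from the table
        m = _lk(C_MINF) + (S[i, 1] - _lk(C_MINF)) * _lk(C_MB)
        h = _lk(C_HINF) + (S[i, 2] - _lk(C_HINF)) * _lk(C_HB)
        j = _lk(C_JINF) + (S[i, 3] - _lk(C_JINF)) * _lk(C_JB)
        d = _lk(C_DINF) + (S[i, 4] - _lk(C_DINF)) * _lk(C_DB)
        f = _lk(C_FINF) + (S[i, 5] - _lk(C_FINF)) * _lk(C_FB)
        f2 = _lk(C_F2INF) + (S[i, 6] - _lk(C_F2INF)) * _lk(C_F2B)
        r = _lk(C_RINF) + (S[i, 8] - _lk(C_RINF)) * _lk(C_RB)
        if stype[i] == 0:
            s = _lk(C_SINF_ENDO) + (S[i, 9] - _lk(C_SINF_ENDO)) * _lk(C_SB_ENDO)
        else:
            s = _lk(C_SINF_EPI) + (S[i, 9] - _lk(C_SINF_EPI)) * _lk(C_SB_EPI)
        xs = _lk(C_XSINF) + (S[i, 10] - _lk(C_XSINF)) * _lk(C_XSB)
        xr1 = _lk(C_XR1INF) + (S[i, 11] - _lk(C_XR1INF)) * _lk(C_XR1B)
        xr2 = _lk(C_XR2INF) + (S[i, 12] - _lk(C_XR2INF)) * _lk(C_XR2B)

        Rbar = S[i, 13]
        Cai = S[i, 14]
        Casr = S[i, 15]
        Cass = S[i, 16]
        Nai = S[i, 17]
        Ki = S[i, 18]

        # subspace-Ca-dependent I_CaL inactivation (exact exponential)
        x2 = (Cass / 0.05) * (Cass / 0.05)
        fc_inf = 0.6 / (1.0 + x2) + 0.4
        fc_tau = 80.0 / (1.0 + x2) + 2.0
        fCass = fc_inf + (S[i, 7] - fc_inf) * np.exp(-dt / fc_tau)

        # reversal potentials
        EK = RTF * np.log(K_O / Ki)
        ENa = RTF * np.log(NA_O / Nai)
        EKs = RTF * np.log((K_O + P_KNA * NA_O) / (Ki + P_KNA * Nai))
        ECa = 0.5 * RTF * np.log(CA_O / Cai)

        # membrane currents (pA/pF)
        INa = G_NA * m * m * m * h * j * (V - ENa)
        ICaL = G_CAL * d * f * f2 * fCass * (_lk(C_A1) * Cass - _lk(C_A2))
        Ito = gto[i] * r * s * (V - EK)
        IKr = G_KR * SQRT_KO * xr1 * xr2 * (V - EK)
        IKs = gks[i] * xs * xs * (V - EKs)
        if phi > 0.0:
            IKs = IKs + phi * gks[i] * (V - erev)
        u = V - EK
        up = (u - UMIN) * (1.0 / DU)
        if up < 0.0:
            up = 0.0
        elif up > nul:
            up = float(nul)
        ku = int(up)
        wu = up - ku
        xk1 = lutk[ku] + wu * (lutk[ku + 1] - lutk[ku])
        IK1 = G_K1 * SQRT_KO * xk1 * u
        INaCa = _lk(C_T1) * Nai * Nai * Nai - _lk(C_T2) * Cai
        INaK = _lk(C_NAK) * Nai / (Nai + K_MNA)
        IpCa = G_PCA * Cai / (K_PCA + Cai)
        IpK = G_PK * _lk(C_IPK) * u
        IbNa = G_BNA * (V - ENa)
        IbCa = G_BCA * (V - ECa)

        Iion = (INa + IK1 + Ito + IKr + IKs + ICaL + INaCa + INaK
                + IpCa + IpK + IbCa + IbNa)
        if i == 0:
            iion0 = Iion

        # SR calcium fluxes and the RyR release gate
        kc = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / Casr) ** 2)
        k1 = K1P / kc
        k2 = K2P * kc
        O = k1 * Cass * Cass * Rbar / (K3R + k1 * Cass * Cass)
        Irel = V_REL * O * (Casr - Cass)
        Ileak = V_LEAK * (Casr - Cai)
        Iup = V_MAXUP / (1.0 + (K_UP * K_UP) / (Cai * Cai))
        Ixfer = V_XFER * (Cass - Cai)
        dRbar = -k2 * Cass * Rbar + K4R * (1.0 - Rbar)

        bc = Cai + K_BUFC
        dCai = (1.0 / (1.0 + BUF_C * K_BUFC / (bc * bc))) * (
            (Ileak - Iup) * VSR_VC + Ixfer
            - (IbCa + IpCa - 2.0 * INaCa) * CM_2VCF)
        bs = Casr + K_BUFSR
        dCasr = (1.0 / (1.0 + BUF_SR * K_BUFSR / (bs * bs))) * (
            Iup - Ileak - Irel)
        bss = Cass + K_BUFSS
        dCass = (1.0 / (1.0 + BUF_SS * K_BUFSS / (bss * bss))) * (
            -ICaL * CM_2VSSF + Irel * VSR_VSS - Ixfer * VC_VSS)
        dNai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * CM_VCF
        dKi = -(IK1 + Ito + IKr + IKs + IpK - 2.0 * INaK + istim[i]) * CM_VCF

        S[i, 0] = V - dt * (Iion + istim[i])
        S[i, 1] = m
        S[i, 2] = h
        S[i, 3] = j
        S[i, 4] = d
        S[i, 5] = f
        S[i, 6] = f2
        S[i, 7] = fCass
        S[i, 8] = r
        S[i, 9] = s
        S[i, 10] = xs
        S[i, 11] = xr1
        S[i, 12] = xr2
        S[i, 13] = Rbar + dt * dRbar
        S[i, 14] = Cai + dt * dCai
        S[i, 15] = Casr + dt * dCasr
        S[i, 16] = Cass + dt * dCass
        S[i, 17] = Nai + dt * dNai
        S[i, 18] = Ki + dt * dKi
    return iion0


@njit(cache=True, fastmath=True)
def _diffusion_step(V, Vn, nx, ny, cx, cy):
    """One explicit no-flux diffusion step; cx = D_x*dt/dx^2 etc."""
    # zero-gradient ghost (ghost = boundary value) keeps the scheme
    # strictly conservative under no-flux boundaries
    for y in range(ny):
        for x in range(nx):
            n = y * nx + x
            v = V[n]
            vl = V[n - 1] if x > 0 else v
            vr = V[n + 1] if x < nx - 1 else v
            acc = cx * (vl + vr - 2.0 * v)
            if ny > 1:
                vd = V[n - nx] if y > 0 else v
                vu = V[n + nx] if y < ny - 1 else v
                acc += cy * (vd + vu - 2.0 * v)
            Vn[n] = v + acc
    for n in range(nx * ny):
        V[n] = Vn[n]


@njit(cache=True, fastmath=True)
def run_cell(S, stype_i, gks_v, gto_v, phi, erev, dt, stim_times, stim_dur,
             stim_amp, t_end, rec_stride, lut, lutk):
    """Integrate a single cell; record t, V, Cai and I'_Ks every
    ``rec_stride`` steps.  ``S`` is a (1, 19) state array mutated in place."""
    nsteps = int(np.round(t_end / dt))
    nrec = nsteps // rec_stride + 1
    rec = np.empty((nrec, 4))
    stype = np.empty(1, dtype=np.int8)
    stype[0] = stype_i
    gks = np.full(1, gks_v)
    gto = np.full(1, gto_v)
    istim = np.zeros(1)
    ns = stim_times.shape[0]
    si = 0
    jrec = 0
    for step in range(nsteps + 1):
        t = step * dt
        if step % rec_stride == 0:
            V = S[0, 0]
            xs = S[0, 10]
            Nai = S[0, 17]
            Ki = S[0, 18]
            EKs = RTF * np.log((K_O + P_KNA * NA_O) / (Ki + P_KNA * Nai))
            iks = gks_v * xs * xs * (V - EKs)
            if phi > 0.0:
                iks += phi * gks_v * (V - erev)
            rec[jrec, 0] = t
            rec[jrec, 1] = V
            rec[jrec, 2] = S[0, 14]
            rec[jrec, 3] = iks
            jrec += 1
        if step == nsteps:
            break
        while si < ns and t >= stim_times[si] + stim_dur:
            si += 1
        active = si < ns and stim_times[si] <= t < stim_times[si] + stim_dur
        istim[0] = stim_amp if active else 0.0
        _reaction_step(S, stype, gks, gto, phi, erev, istim, dt, lut, lutk)
        if not np.isfinite(S[0, 0]):
            raise ValueError("membrane potential diverged (NaN/Inf)")
    return rec[:jrec]


@njit(cache=True, fastmath=True)
def run_tissue(S, stype, gks, gto, phi, erev, nx, ny, cx, cy, dt, t_end,
               stim_offsets, stim_nodes, stim_start, stim_dur, stim_amp,
               rec_stride, vrec, probe_idx, probe_stride, probe_rec,
               eat, edt, map_start,
               s2_enabled, s2_watch, s2_nodes, s2_earliest, s2_dur, s2_amp,
               term_check_after, lut, lutk):
    """Monodomain reaction–diffusion driver (1D cable or 2D sheet).

    Mutates ``S`` and fills ``vrec`` (float32 field samples), probe traces,
    and online EAT/EDT maps (first −30 mV upstroke / last −75 mV downstroke
    after ``map_start``).  Optionally fires a premature S2 stimulus once all
    watched nodes have repolarized below −75 mV (re-entry induction).

    Returns (n_field_samples, n_probe_samples, s2_time, termination_time);
    times are −1.0 when the event did not occur.
    """
    n = nx * ny
    nsteps = int(np.round(t_end / dt))
    istim = np.zeros(n)
    Vn = np.empty(n)
    Vold = np.empty(n)
    nstim = stim_start.shape[0]
    s2_time = -1.0
    s2_fired = not s2_enabled
    term_time = -1.0
    quiet_since = -1.0
    jrec = 0
    jprobe = 0
    for step in range(nsteps + 1):
        t = step * dt
        if step % rec_stride == 0 and jrec < vrec.shape[0]:
            for i in range(n):
                vrec[jrec, i] = np.float32(S[i, 0])
            jrec += 1
        if step % probe_stride == 0 and jprobe < probe_rec.shape[0]:
            for p in range(probe_idx.shape[0]):
                probe_rec[jprobe, p] = S[probe_idx[p], 0]
            jprobe += 1
        if step == nsteps:
            break

        # stimulus assembly
        for i in range(n):
            istim[i] = 0.0
        for kk in range(nstim):
            if stim_start[kk] <= t < stim_start[kk] + stim_dur:
                for q in range(stim_offsets[kk], stim_offsets[kk + 1]):
                    istim[stim_nodes[q]] = stim_amp
        if s2_fired and s2_enabled and s2_time <= t < s2_time + s2_dur:
            for q in range(s2_nodes.shape[0]):
                istim[s2_nodes[q]] = s2_amp
        if not s2_fired and t >= s2_earliest:
            tail_clear = True
            for q in range(s2_watch.shape[0]):
                if S[s2_watch[q], 0] > -75.0:
                    tail_clear = False
                    break
            if tail_clear:
                s2_fired = True
                s2_time = t
                for q in range(s2_nodes.shape[0]):
                    istim[s2_nodes[q]] = s2_amp

        for i in range(n):
            Vold[i] = S[i, 0]
        _reaction_step(S, stype, gks, gto, phi, erev, istim, dt, lut, lutk)
        _diffusion_step(S[:, 0], Vn, nx, ny, cx, cy)

        # activation / repolarization maps with linear time interpolation
        # (maps use a -1 sentinel for "not seen"; fastmath forbids NaN tests)
        if t >= map_start:
            for i in range(n):
                v0 = Vold[i]
                v1 = S[i, 0]
                if v0 < -30.0 <= v1 and eat[i] < -0.5:
                    eat[i] = t + dt * (-30.0 - v0) / (v1 - v0)
                if v0 > -75.0 >= v1:
                    edt[i] = t + dt * (-75.0 - v0) / (v1 - v0)

        vmax = S[0, 0]
        for i in range(1, n):
            if S[i, 0] > vmax:
                vmax = S[i, 0]
        if vmax > 200.0 or not np.isfinite(vmax):
            raise ValueError("tissue simulation unstable (|V| > 200 mV)")

        # early termination on sustained quiescence
        if t > term_check_after and s2_fired:
            if vmax < -70.0:
                if quiet_since < 0.0:
                    quiet_since = t
                elif t - quiet_since >= 100.0:
                    term_time = quiet_since
                    break
            else:
                quiet_since = -1.0
    return jrec, jprobe, s2_time, term_time


@njit(cache=True, fastmath=True)
def run_diffusion(V, nx, ny, cx, cy, nsteps):
    """Diffusion-only stepping (reaction disabled), for conservation tests."""
    Vn = np.empty_like(V)
    for _ in range(nsteps):
        _diffusion_step(V, Vn, nx, ny, cx, cy)
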