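"""Single-cell pacing protocols and action-potential metrics.

Covers steady-state pacing, APD₉₀ measurement, the dynamic restitution
protocol (APD–BCL and APD–DI curves with maximum slope), alternans-onset
detection, and the I_Ks summary used to characterise the mutant current.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as kern
from .ionic import CELL_TYPE_INDEX, CellParams, resting_state

__all__ = [
    "Trace", "RestitutionCurve", "pace_to_steady_state", "measure_apd",
    "beat_apds", "dynamic_restitution", "detect_alternans_onset",
    "iks_summary",
]

#: default conditioning length before any reported metric
N_CONDITIONING_BEATS = 100

#: alternans convention: APD swing (ms) that must persist over 4 beats
ALTERNANS_THRESHOLD = 5.0
ALTERNANS_PERSIST = 4


@dataclass
class Trace:
    """Uniformly sampled single-cell recording."""

    t: np.ndarray            # ms
    V: np.ndarray            # mV
    Cai: np.ndarray          # mM
    IKs: np.ndarray          # pA/pF (I'_Ks under the mutant condition)
    stim_times: np.ndarray   # ms, one marker per delivered stimulus
    alternans: bool = False  # steady-state check found a persistent swing

    def __post_init__(self):
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trace time base must increase strictly")
        if np.asarray(self.stim_times).size < 1:
            raise ValueError("trace needs at least one beat marker")

    def window(self, t0: float, t1: float) -> "Trace":
        sel = (self.t >= t0) & (self.t <= t1)
        marks = self.stim_times[(self.stim_times >= t0)
                                & (self.stim_times <= t1)]
        if marks.size == 0:
            marks = np.array([t0])
        return Trace(self.t[sel], self.V[sel], self.Cai[sel],
                     self.IKs[sel], marks, self.alternans)


@dataclass
class RestitutionCurve:
    """APD restitution: one row per BCL level of the dynamic protocol."""

    points: pd.DataFrame = field(repr=False)  # bcl, di, apd, apd_prev, alternans, captured
    max_slope: float = np.nan                 # max dAPD/dDI
    alternans_onset_bcl: float | None = None  # ms; None if never seen

    def __post_init__(self):
        bcl = self.points["bcl"].to_numpy()
        if bcl.size > 1 and not np.all(np.diff(bcl) < 0):
            raise ValueError("protocol order requires decreasing BCL")


def _run_paced(params: CellParams, bcl: float, n_beats: int,
               state: np.ndarray | None = None, rec_dt: float = 0.2
               ) -> tuple[Trace, np.ndarray]:
    dt = params.dt
    lut, lutk = kern.build_tables(dt)
    if state is None:
        state = resting_state().y.copy()
    S = state.reshape(1, -1)
    stim_times = np.arange(n_beats) * float(bcl)
    rec_stride = max(1, int(round(rec_dt / dt)))
    rec = kern.run_cell(
        S, CELL_TYPE_INDEX[params.cell_type], params.g_ks, params.g_to,
        params.phi, params.e_rev_mut, dt, stim_times,
        params.stim_duration, params.stim_amplitude,
        n_beats * float(bcl), rec_stride, lut, lutk)
    tr = Trace(rec[:, 0], rec[:, 1], rec[:, 2], rec[:, 3], stim_times)
    return tr, S[0]


def beat_apds(trace: Trace, repol_fraction: float = 0.9) -> pd.DataFrame:
    """Per-beat APD table (t_up, apd, v_peak, v_rest, captured).

    A beat is *captured* when the stimulus elicits a full upstroke
    (peak above −30 mV); APD runs from the maximum-dV/dt fiducial to the
    linear-interpolated crossing of V_rest + (1−fraction)·(V_peak−V_rest).
    """
    t, V = trace.t, trace.V
    rows = []
    marks = np.asarray(trace.stim_times, dtype=float)
    ends = np.append(marks[1:], t[-1])
    for t0, t1 in zip(marks, ends):
        sel = (t >= t0) & (t <= t1)
        if sel.sum() < 4:
            continue
        tb, vb = t[sel], V[sel]
        dv = np.gradient(vb, tb)
        iup = int(np.argmax(dv))
        v_rest = vb[0]
        v_peak = float(vb.max())
        captured = v_peak > -30.0 and dv[iup] > 1.0
        apd = np.nan
        if captured:
            thresh = v_rest + (1.0 - repol_fraction) * (v_peak - v_rest)
            ipk = int(np.argmax(vb))
            below = np.nonzero(vb[ipk:] <= thresh)[0]
            if below.size:
                k = ipk + below[0]
                # linear interpolation of the crossing
                if k > 0 and vb[k] != vb[k - 1]:
                    tc = tb[k - 1] + (thresh - vb[k - 1]) * (
                        tb[k] - tb[k - 1]) / (vb[k] - vb[k - 1])
                else:
                    tc = tb[k]
                apd = tc - tb[iup]
        rows.append((t0, tb[iup], apd, v_peak, v_rest, captured))
    return pd.DataFrame(
        rows, columns=["t_stim", "t_up", "apd", "v_peak", "v_rest",
                       "captured"])


def measure_apd(trace: Trace, repol_fraction: float = 0.9) -> float:
    """APD of the last captured beat in the trace (ms)."""
    df = beat_apds(trace, repol_fraction)
    good = df[df["captured"] & np.isfinite(df["apd"])]
    if good.empty:
        raise ValueError("no action potential with a repolarization "
                         "crossing found in trace")
    return float(good["apd"].iloc[-1])


def pace_to_steady_state(params: CellParams, bcl: float,
                         n_beats: int = N_CONDITIONING_BEATS,
                         record_beats: int = 2) -> Trace:
    """Pace from rest for ``n_beats`` and return the final beats.

    The returned trace is flagged ``alternans=True`` when the last two
    APDs differ by more than 1 ms (the steady-state criterion).
    """
    if bcl < 20:
        raise ValueError("BCL below 20 ms is outside the studied range")
    full, _ = _run_paced(params, bcl, n_beats)
    df = beat_apds(full)
    tail = df["apd"].to_numpy()[-2:]
    alt = bool(tail.size == 2 and np.all(np.isfinite(tail))
               and abs(tail[1] - tail[0]) > 1.0)
    out = full.window((n_beats - record_beats) * bcl, n_beats * bcl)
    out.alternans = alt
    return out


def _bcl_schedule(bcl_start: float, bcl_end: float) -> np.ndarray:
    """Decreasing BCL ladder: 50 ms steps above 400 ms, 10 ms below."""
    coarse = np.arange(bcl_start, 400.0 - 1e-9, -50.0)
    fine = np.arange(min(400.0, bcl_start), bcl_end - 1e-9, -10.0)
    sched = np.unique(np.concatenate([coarse, fine, [bcl_end]]))[::-1]
    return sched[(sched <= bcl_start) & (sched >= bcl_end)]


def dynamic_restitution(params: CellParams, bcl_start: float = 1000.0,
                        bcl_end: float = 20.0, beats_per_level: int = 30,
                        conditioning_beats: int = N_CONDITIONING_BEATS
                        ) -> RestitutionCurve:
    """Dynamic restitution protocol.

    The cell is conditioned at ``bcl_start`` and then paced down a
    decreasing BCL ladder, carrying the state from level to level.  For
    each level the last beats give the steady APD, the diastolic interval
    DI = BCL − APD_prev, and an alternans flag (persistent >5 ms swing
    over the final 4 captured beats).  The maximum restitution slope is
    taken as the largest finite-difference dAPD/dDI along the curve.
    """
    if bcl_start <= bcl_end:
        raise ValueError("schedule must decrease")
    sched = _bcl_schedule(bcl_start, bcl_end)
    _, state = _run_paced(params, bcl_start, conditioning_beats)
    rows = []
    for bcl in sched:
        try:
            tr, state = _run_paced(params, bcl, beats_per_level, state)
            df = beat_apds(tr)
        except (ValueError, FloatingPointError):
            rows.append((bcl, np.nan, np.nan, np.nan, False, False))
            continue
        tail = df.tail(ALTERNANS_PERSIST)
        apds = tail["apd"].to_numpy()
        captured = bool(tail["captured"].all()
                        and np.all(np.isfinite(apds))
                        and len(tail) == ALTERNANS_PERSIST)
        alternans = bool(captured and np.all(
            np.abs(np.diff(apds)) > ALTERNANS_THRESHOLD))
        apd = float(apds[-1]) if captured else np.nan
        apd_prev = float(apds[-2]) if captured else np.nan
        di = bcl - apd_prev if captured else np.nan
        rows.append((bcl, di, apd, apd_prev, alternans, captured))
    pts = pd.DataFrame(rows, columns=["bcl", "di", "apd", "apd_prev",
                                      "alternans", "captured"])

    steady = pts[pts["captured"] & ~pts["alternans"]].sort_values("di")
    max_slope = np.nan
    if len(steady) >= 2:
        di = steady["di"].to_numpy()
        apd = steady["apd"].to_numpy()
        dslope = np.diff(apd) / np.diff(di)
        dslope = dslope[np.isfinite(dslope)]
        if dslope.size:
            max_slope = float(dslope.max())
    flagged = pts[pts["alternans"]]
    onset = float(flagged["bcl"].max()) if not flagged.empty else None
    return RestitutionCurve(points=pts, max_slope=max_slope,
                            alternans_onset_bcl=onset)


def detect_alternans_onset(params: CellParams,
                           bcl_schedule: np.ndarray | None = None,
                           **kw) -> float | None:
    """Largest BCL (ms) with persistent APD alternans; None if absent."""
    if bcl_schedule is not None:
        sched = np.asarray(bcl_schedule, dtype=float)
        if sched.size > 1 and not np.all(np.diff(sched) < 0):
            raise ValueError("schedule must decrease")
        curve = dynamic_restitution(params, float(sched[0]),
                                    float(sched[-1]), **kw)
    else:
        curve = dynamic_restitution(params, **kw)
    return curve.alternans_onset_bcl


def iks_summary(trace: Trace, threshold_fraction: float = 0.05
                ) -> tuple[float, float]:
    """(sustained duration ms, mean current pA/pF) of the last beat.

    The sustained window is where I_Ks exceeds ``threshold_fraction`` of
    its beat maximum; the mean is the time average over that window.
    """
    t0 = trace.stim_times[-1]
    sel = trace.t >= t0
    t, iks = trace.t[sel], trace.IKs[sel]
    peak = iks.max() if iks.size else 0.0
    if peak <= 0:
        return 0.0, 0.0
    above = iks >= threshold_fraction * peak
    if not above.any():
        return 0.0, 0.0
    idx = np.nonzero(above)[0]
    # use the first contiguous run that contains the peak
    dt = float(np.median(np.diff(t)))
    duration = idx.size * dt
    mean = float(iks[idx].mean())
    return float(duration), mean
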