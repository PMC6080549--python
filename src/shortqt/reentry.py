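"""Frequency-domain and rotor analysis of re-entrant field traces.

Dominant frequency (DF) is the argmax of the mean-detrended periodogram
above a 0.5 Hz drift cutoff; field traces sampled at 100 Hz are analysed
over the final 3 s of an episode with zero-padding to 2¹⁴ samples
(bin width ≈ 0.006 Hz).  Rotation rate counts −30 mV upstrokes at a probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .tissue import FieldTrace

__all__ = ["DFMap", "dominant_frequency", "df_map", "rotation_rate",
           "classify_sustainment", "Sustainment"]

LOW_CUTOFF_HZ = 0.5
NFFT = 2 ** 14
ANALYSIS_WINDOW_MS = 3000.0
QUIESCENT_MV = -70.0
QUIESCENT_HOLD_MS = 100.0


@dataclass
class DFMap:
    """Per-node dominant frequency with summary scalars."""

    df_hz: np.ndarray          # NaN for constant/quiescent nodes
    fs_hz: float
    window_ms: float
    n_excluded: int            # constant-signal nodes

    def __post_init__(self):
        finite = self.df_hz[np.isfinite(self.df_hz)]
        if finite.size and finite.max() > self.fs_hz / 2 + 1e-9:
            raise ValueError("dominant frequency above Nyquist")

    @property
    def min(self) -> float:
        return float(np.nanmin(self.df_hz))

    @property
    def max(self) -> float:
        return float(np.nanmax(self.df_hz))

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.df_hz))

    @property
    def bandwidth(self) -> float:
        return self.max - self.min


def dominant_frequency(x: np.ndarray, fs_hz: float) -> float:
    """Periodogram-argmax dominant frequency of one signal (Hz)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fs_hz:
        raise ValueError("need at least 2 s of signal")
    if np.ptp(x) < 1e-9:
        raise ValueError("constant signal has no spectral peak")
    f, p = sps.periodogram(x, fs=fs_hz, detrend="constant", nfft=NFFT)
    band = (f > LOW_CUTOFF_HZ) & (f <= fs_hz / 2)
    return float(f[band][np.argmax(p[band])])


def _df_of_matrix(V: np.ndarray, fs_hz: float,
                  chunk: int = 1024) -> tuple[np.ndarray, int]:
    """Column-wise DF of a (n_t, n_nodes) field; constant columns → NaN.

    Nodes are processed in chunks: the zero-padded FFT of a full 2D-sheet
    field would otherwise allocate several GiB.
    """
    V = np.asarray(V, dtype=float)
    out = np.full(V.shape[1], np.nan)
    live = np.ptp(V, axis=0) >= 1e-6
    n_excl = int(np.count_nonzero(~live))
    idx = np.flatnonzero(live)
    for k in range(0, idx.size, chunk):
        cols = idx[k:k + chunk]
        f, p = sps.periodogram(V[:, cols], fs=fs_hz, detrend="constant",
                               nfft=NFFT, axis=0)
        band = (f > LOW_CUTOFF_HZ) & (f <= fs_hz / 2)
        out[cols] = f[band][np.argmax(p[band], axis=0)]
    return out, n_excl


def df_map(trace: FieldTrace, window_ms: float = ANALYSIS_WINDOW_MS) -> DFMap:
    """Per-node dominant frequency over the trailing analysis window."""
    t = trace.t
    if t.size < 2:
        raise ValueError("field trace too short")
    dt = float(np.median(np.diff(t)))
    fs = 1000.0 / dt
    sel = t >= t[-1] - window_ms
    dfs, n_excl = _df_of_matrix(trace.V[sel], fs)
    return DFMap(df_hz=dfs, fs_hz=fs, window_ms=window_ms, n_excluded=n_excl)


def rotation_rate(probe_v: np.ndarray, probe_t_ms: np.ndarray,
                  window_ms: float = ANALYSIS_WINDOW_MS,
                  threshold_mv: float = -30.0) -> float:
    """AP firing frequency at a probe: upward threshold crossings per s."""
    t = np.asarray(probe_t_ms, dtype=float)
    v = np.asarray(probe_v, dtype=float)
    sel = t >= t[-1] - window_ms
    t, v = t[sel], v[sel]
    if v.size < 2:
        return 0.0
    up = (v[:-1] < threshold_mv) & (v[1:] >= threshold_mv)
    span_s = (t[-1] - t[0]) / 1000.0
    if span_s <= 0:
        return 0.0
    return float(np.count_nonzero(up) / span_s)


@dataclass(frozen=True)
class Sustainment:
    sustained: bool
    termination_time_ms: float | None = None


def classify_sustainment(trace: FieldTrace, horizon_ms: float | None = None
                         ) -> Sustainment:
    """Terminated iff every node stays below −70 mV for a contiguous 100 ms.

    Uses the solver's online termination record when present (runs may stop
    early once quiescent); otherwise scans the recorded field samples.
    """
    if trace.term_time >= 0:
        return Sustainment(False, float(trace.term_time))
    t, V = trace.t, trace.V
    if horizon_ms is not None and t[-1] + 1e-6 < horizon_ms:
        raise ValueError("trace does not span the requested horizon")
    # only quiescence after the episode starts counts as termination
    # (diastole between conditioning stimuli must not be mislabeled)
    start = trace.s2_time if trace.s2_time >= 0 else (
        float(trace.stim.times.max()) + trace.stim.duration
        if trace.stim.times.size else 0.0)
    sel = t >= start
    t, V = t[sel], V[sel]
    quiet = (V < QUIESCENT_MV).all(axis=1)
    dt = float(np.median(np.diff(t))) if t.size > 1 else np.inf
    need = max(1, int(np.ceil(QUIESCENT_HOLD_MS / dt)))
    run = 0
    for k, q in enumerate(quiet):
        run = run + 1 if q else 0
        if run >= need:
            return Sustainment(False, float(t[k - run + 1]))
    return Sustainment(True, None)
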