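"""Dominant frequency, rotor rate and sustainment classification on
analytic fixtures."""

import numpy as np
import pytest
from scipy import signal as sps

from shortqt.geometry import TissueGrid, make_fixture_field
from shortqt.reentry import (DFMap, classify_sustainment, df_map,
                             dominant_frequency, rotation_rate)
from shortqt.tissue import FieldTrace, StimulusSchedule

FS = 100.0
# one natural frequency bin of the 3 s analysis window
BIN_HZ = 1.0 / 3.0


def make_trace(t_ms, V):
    n = V.shape[1]
    grid = TissueGrid(n, 1, 0.05, np.full(n, 2, dtype=np.int8),
                      0.3247, 0.3247)
    stim = StimulusSchedule((np.empty(0, dtype=np.int64),), np.array([0.0]))
    return FieldTrace(grid=grid, t=t_ms, V=V.astype(np.float32),
                      probe_t=t_ms, probe_V=V[:, :1].astype(float),
                      probe_nodes=np.array([0]), stim=stim,
                      eat=np.full(n, np.nan), edt=np.full(n, np.nan),
                      map_start=0.0)


class TestDominantFrequency:
    def test_pure_sinusoid(self):
        t, V, truth = make_fixture_field("sinusoid", freq_hz=3.0)
        assert dominant_frequency(V, FS) == pytest.approx(3.0,
                                                          abs=2 * BIN_HZ)

    def test_square_wave_fundamental(self):
        t = np.arange(0, 4000.0, 10.0)
        sq = sps.square(2 * np.pi * 5.0 * t / 1000.0)
        assert dominant_frequency(sq, FS) == pytest.approx(5.0,
                                                           abs=2 * BIN_HZ)

    def test_two_tone_larger_peak_wins(self):
        t = np.arange(0, 4000.0, 10.0) / 1000.0
        x = np.sin(2 * np.pi * 2 * t) + 0.3 * np.sin(2 * np.pi * 7 * t)
        assert dominant_frequency(x, FS) == pytest.approx(2.0,
                                                          abs=2 * BIN_HZ)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            dominant_frequency(np.full(500, -85.0), FS)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            dominant_frequency(np.sin(np.arange(100.0)), FS)


class TestDFMap:
    def test_uniform_forced_rhythm(self):
        """All nodes paced at BCL 500 ms -> DF = 2 Hz everywhere."""
        t = np.arange(0, 4000.0, 10.0)
        ap = np.where((t % 500.0) < 150.0, 20.0, -85.0)
        V = np.tile(ap[:, None], (1, 12))
        dfm = df_map(make_trace(t, V))
        np.testing.assert_allclose(dfm.df_hz, 2.0, atol=2 * BIN_HZ)
        assert dfm.bandwidth == pytest.approx(0.0, abs=2 * BIN_HZ)

    def test_constant_nodes_excluded_and_counted(self):
        t = np.arange(0, 4000.0, 10.0)
        V = np.tile(np.sin(2 * np.pi * 3 * t / 1000.0)[:, None], (1, 4))
        V[:, 2] = -85.0
        dfm = df_map(make_trace(t, V))
        assert dfm.n_excluded == 1
        assert np.isnan(dfm.df_hz[2])
        assert dfm.mean == pytest.approx(3.0, abs=2 * BIN_HZ)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            DFMap(df_hz=np.array([60.0]), fs_hz=100.0, window_ms=3000.0,
                  n_excluded=0)


class TestRotationRate:
    def test_periodic_ap_train(self):
        # 200 ms period, first upstroke inside the window
        t = np.arange(0, 3000.0, 1.0)
        v = np.where(((t + 100.0) % 200.0) < 60.0, 10.0, -80.0)
        assert rotation_rate(v, t) == pytest.approx(5.0, rel=0.05)

    def test_quiescent_probe(self):
        t = np.arange(0, 3000.0, 1.0)
        assert rotation_rate(np.full_like(t, -85.0), t) == 0.0


class TestSustainment:
    def test_all_resting_terminated_immediately(self):
        t = np.arange(0, 1000.0, 10.0)
        V = np.full((t.size, 6), -85.0)
        s = classify_sustainment(make_trace(t, V))
        assert not s.sustained
        assert s.termination_time_ms == pytest.approx(0.0, abs=10.0)

    def test_continuous_activity_sustained(self):
        t = np.arange(0, 4000.0, 10.0)
        ap = np.where((t % 250.0) < 120.0, 15.0, -85.0)
        # stagger phases so some node is always depolarized
        V = np.stack([np.roll(ap, k) for k in range(0, 24, 4)], axis=1)
        assert classify_sustainment(make_trace(t, V)).sustained

    def test_termination_time_recovered(self):
        t = np.arange(0, 2000.0, 10.0)
        V = np.full((t.size, 4), -85.0)
        V[t < 800.0, :] = 10.0
        s = classify_sustainment(make_trace(t, V))
        assert not s.sustained
        assert s.termination_time_ms == pytest.approx(800.0, abs=15.0)

    def test_horizon_check(self):
        t = np.arange(0, 1000.0, 10.0)
        V = np.full((t.size, 2), -85.0)
        with pytest.raises(ValueError):
            classify_sustainment(make_trace(t, V), horizon_ms=4000.0)
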