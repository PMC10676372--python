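"""Spike detection, zone mapping and circular statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdlamina import experiments as ex
from sdlamina import mua_phase as mp
from sdlamina.signal_model import LaminarRecording, filter_trace


class TestWaveletFilter:
    def test_passband_and_stopband(self, rng):
        fs = 10_000.0
        t = np.arange(int(4 * fs)) / fs
        inband = np.sin(2 * np.pi * 1000.0 * t)
        slow = np.sin(2 * np.pi * 5.0 * t)
        y_in = mp.wavelet_bandpass(inband, fs)
        y_slow = mp.wavelet_bandpass(slow, fs)
        assert y_in.std() > 0.5 * inband.std()
        assert y_slow.std() < 0.05 * slow.std()


class TestDetectSpikes:
    def test_sensitivity_and_fdr_on_planted_spikes(self):
        rec, planted, _ = ex.spike_scenario(seed=3, duration_s=110.0)
        st_ = mp.detect_spikes(rec, control_epoch_s=(0.0, 105.0))
        det = st_.spike_times_s
        hits = sum(np.min(np.abs(det - t)) <= 5e-4 for t in planted)
        assert hits / planted.size > 0.95
        false = sum(np.min(np.abs(planted - t)) > 5e-4 for t in det)
        assert false / max(det.size, 1) < 0.05

    def test_gaussian_noise_rate_below_level_crossing_bound(self, rng):
        fs = 10_000.0
        x = rng.standard_normal(int(110 * fs)) * 0.01
        rec = LaminarRecording(x[None, :], [500.0], fs, coupling="DC")
        st_ = mp.detect_spikes(rec, control_epoch_s=(0.0, 110.0))
        rate = st_.spike_times_s.size / 110.0
        bound = (fs / 2) * np.exp(-(4.0**2) / 2)  # Rice bound, f0 <= Nyquist
        assert rate < bound

    def test_threshold_monotonicity(self):
        rec, _, _ = ex.spike_scenario(seed=4, duration_s=110.0, amp_factor=5.0)
        t_hi = mp.detect_spikes(rec, (0.0, 105.0), n_std=5.0).spike_times_s
        t_lo = mp.detect_spikes(rec, (0.0, 105.0), n_std=4.0).spike_times_s
        assert np.all(np.isin(np.round(t_hi, 6), np.round(t_lo, 6)))

    def test_adaptive_threshold_suppresses_noise_doubling(self):
        sd_win = (110.0, 125.0)
        rec, _, _ = ex.spike_scenario(seed=5, sd_window_s=sd_win, sd_noise_gain=2.0)
        ad = mp.detect_spikes(rec, (0.0, 108.0), sd_windows_s=[(108.0, 127.0)])
        fx = mp.detect_spikes(rec, (0.0, 108.0), adaptive=False)
        in_win = lambda t: np.count_nonzero((t >= sd_win[0]) & (t < sd_win[1]))
        assert in_win(ad.spike_times_s) == 0
        assert in_win(fx.spike_times_s) > 10

    def test_short_control_rejected(self, rng):
        rec = LaminarRecording(rng.standard_normal((1, 400_000)), [500.0], 10_000.0)
        with pytest.raises(ValueError):
            mp.detect_spikes(rec, control_epoch_s=(0.0, 30.0))


class TestRateMetrics:
    def test_mua_ratio_reads_planted_rates(self, rng):
        pre = np.sort(rng.uniform(0.0, 120.0, 1200))  # 10 Hz
        sd = 125.0 + np.sort(rng.uniform(0.0, 15.0, 8))  # ~0.5 Hz
        st_ = mp.SpikeTrain(0, np.concatenate([pre, sd]))
        out = mp.mua_change([st_], earliest_onset_s=120.0, deepest_onset_s=125.0)
        assert out.loc[0, "ratio"] == pytest.approx(0.05, abs=0.02)

    def test_unchanged_rate_ratio_one(self, rng):
        t = np.sort(rng.uniform(0.0, 200.0, 2000))
        st_ = mp.SpikeTrain(0, t)
        out = mp.mua_change([st_], 120.0, 125.0)
        assert out.loc[0, "ratio"] == pytest.approx(1.0, abs=0.3)
        assert out.loc[0, "p"] > 0.05

    def test_zero_pre_rate_flagged(self):
        st_ = mp.SpikeTrain(0, np.array([130.0, 131.0]))
        out = mp.mua_change([st_], 120.0, 125.0)
        assert np.isnan(out.loc[0, "ratio"])

    def test_burst_duration_constant_rate_is_zero(self, rng):
        t = np.arange(0.0, 200.0, 0.2)  # perfectly regular 5 Hz
        assert mp.burst_duration(mp.SpikeTrain(0, t), (0.0, 100.0), (100.0, 200.0)) == 0.0

    def test_burst_duration_reads_planted_excursion(self, rng):
        base = np.sort(rng.uniform(0.0, 200.0, 1000))  # 5 Hz
        burst = np.sort(rng.uniform(120.0, 132.0, 600))  # 50 Hz for 12 s
        st_ = mp.SpikeTrain(0, np.sort(np.concatenate([base, burst])))
        dur = mp.burst_duration(st_, (0.0, 100.0), (100.0, 160.0))
        assert dur == pytest.approx(12.0, abs=1.5)

    def test_empty_train_zero(self):
        assert mp.burst_duration(mp.SpikeTrain(0, []), (0.0, 100.0)) == 0.0


class TestZoneProfile:
    def _table(self, rng, n_sd=12):
        rows = []
        for _ in range(n_sd):
            for rel in np.arange(-400.0, 501.0, 100.0):
                if rel <= 0:
                    mua, gamma, delta = 0.03, 0.3, 0.4
                elif rel <= 300:
                    mua, gamma, delta = 3.0, 4.0, 0.6
                else:
                    mua, gamma, delta = 1.0, 1.0, 1.0
                jitter = rng.lognormal(0.0, 0.15, 3)
                rows.append(
                    dict(
                        rel_depth_um=rel,
                        delta_ratio=delta * jitter[0],
                        gamma_ratio=gamma * jitter[1],
                        mua_ratio=mua * jitter[2],
                    )
                )
        return pd.DataFrame(rows)

    def test_planted_band_recovered(self, rng):
        prof = mp.zone_profile(self._table(rng))
        assert prof.subsd_top_um == 0.0
        assert prof.subsd_bottom_um == 300.0
        assert list(prof.labels[prof.rel_depth_um <= 0]) == ["depressed"] * 5

    def test_no_change_table_all_unchanged(self, rng):
        df = self._table(rng)
        for c in ("delta_ratio", "gamma_ratio", "mua_ratio"):
            df[c] = rng.lognormal(0.0, 0.2, len(df))
        prof = mp.zone_profile(df)
        assert set(prof.labels) == {"unchanged"}
        assert prof.subsd_top_um is None

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            mp.zone_profile(pd.DataFrame({"rel_depth_um": [0.0]}))


class TestCircularStatistics:
    def test_perfect_trough_locking(self):
        fs = 1000.0
        t = np.arange(int(120 * fs)) / fs
        lfp = np.cos(2 * np.pi * 60.0 * t)
        trough_times = (np.arange(200) + 0.5) / 60.0 + 10.0
        rec = LaminarRecording(lfp[None, :], [500.0], fs)
        out = mp.gamma_phase_coupling(trough_times, rec, 0)
        assert out["resultant_length"] > 0.99
        assert abs(abs(out["mean_direction"]) - np.pi) < np.deg2rad(5)
        assert out["rayleigh_p"] < 1e-6

    def test_statistics_omitted_below_ten_spikes(self, rng):
        fs = 1000.0
        rec = LaminarRecording(rng.standard_normal((1, 60_000)), [500.0], fs)
        out = mp.gamma_phase_coupling(np.arange(5) + 1.0, rec, 0)
        assert "rayleigh_p" not in out and out["phases"].size == 5

    def test_rayleigh_agrees_with_independent_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for n in (20, 200):
            ph = rng.vonmises(0.5, 0.8, n)
            z, p_ref = pingouin.circ_rayleigh(ph)
            assert mp.rayleigh_test(ph) == pytest.approx(p_ref, rel=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=-3.1, max_value=3.1))
    def test_rotation_invariance(self, shift):
        rng = np.random.default_rng(7)
        ph = rng.vonmises(0.0, 1.0, 150)
        mu0, r0 = mp.circular_mean(ph)
        mu1, r1 = mp.circular_mean(ph + shift)
        assert r1 == pytest.approx(r0, rel=1e-9)
        assert mp.rayleigh_test(ph + shift) == pytest.approx(mp.rayleigh_test(ph), rel=1e-6)
        d = np.angle(np.exp(1j * (mu1 - mu0 - shift)))
        assert abs(d) < 1e-9
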