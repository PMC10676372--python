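"""Spectral power estimation and the depression / no-change / boom call."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps
from scipy import stats

from sdlamina import power_class as pc
from sdlamina.signal_model import ECoGRecording, LaminarRecording


def _noise_rec(rng, dur=300.0, fs=200.0):
    return ECoGRecording(rng.standard_normal(int(dur * fs)), fs=fs)


class TestEpochPower:
    @pytest.mark.parametrize("mode,fs", [("human", 200.0), ("rat", 1000.0)])
    def test_stationary_noise_ratio_near_one(self, rng, mode, fs):
        if mode == "human":
            rec = ECoGRecording(rng.standard_normal(int(300 * fs)), fs=fs)
            onset = 150.0
        else:
            rec = LaminarRecording(
                rng.standard_normal((1, int(160 * fs))), [100.0], fs=fs
            )
            onset = 70.0
        pre, sd = pc.epoch_power(rec, onset, mode=mode)
        assert 25 <= len(pre) <= 30
        assert sd.mean() / pre.mean() == pytest.approx(1.0, abs=0.25)

    def test_amplitude_scaling_squares_the_ratio(self, rng):
        fs = 200.0
        x = rng.standard_normal(int(300 * fs))
        t = np.arange(x.size) / fs
        x[(t >= 155.0) & (t <= 195.0)] *= 0.3
        rec = ECoGRecording(x, fs=fs)
        pre, sd = pc.epoch_power(rec, 150.0, mode="human")
        assert sd.mean() / pre.mean() == pytest.approx(0.09, rel=0.30)

    def test_delta_sine_power_concentrates_in_delta_band(self):
        fs = 1000.0
        x = np.sin(2 * np.pi * 2.0 * np.arange(int(40 * fs)) / fs)
        delta = pc.sliding_band_power(x, fs, (0.5, 4.0), mode="rat")
        total = pc.sliding_band_power(x, fs, (0.5, 45.0), mode="rat")
        assert delta.mean() / total.mean() > 0.95

    def test_out_of_range_epoch_raises(self, rng):
        rec = _noise_rec(rng, dur=100.0)
        with pytest.raises(ValueError):
            pc.epoch_power(rec, 30.0, mode="human")

    def test_human_and_rat_estimates_agree_on_stationary_signal(self, rng):
        fs = 1000.0
        x = rng.standard_normal(int(200 * fs))
        rec = LaminarRecording(x[None, :], [100.0], fs=fs)
        r_h = pc.band_ratios(rec, 130.0, mode="human")["ac"].ratio
        r_r = pc.band_ratios(rec, 130.0, mode="rat")["ac"].ratio
        assert r_h == pytest.approx(r_r, rel=0.25)


class TestClassify:
    def test_identical_vectors_are_no_change(self):
        x = np.linspace(1.0, 2.0, 30)
        out = pc.classify_sd_change(x, x)
        assert out.label == "no_change" and out.ratio == 1.0

    def test_separated_samples_match_rank_sum_oracle(self, rng):
        pre = rng.normal(10.0, 1.0, 30)
        sd = rng.normal(1.0, 0.1, 30)
        out = pc.classify_sd_change(pre, sd)
        assert out.label == "depression"
        assert out.ratio == pytest.approx(0.1, rel=0.3)
        oracle = stats.mannwhitneyu(pre, sd, alternative="two-sided").pvalue
        assert out.p_value == pytest.approx(oracle, rel=1e-6)

    def test_label_follows_ratio_sign_when_significant(self, rng):
        for _ in range(50):
            pre = rng.chisquare(5, 30)
            sd = rng.chisquare(5, 30) * rng.uniform(0.2, 5.0)
            out = pc.classify_sd_change(pre, sd)
            if out.p_value <= 0.05:
                assert out.label == ("boom" if out.ratio > 1 else "depression")
            else:
                assert out.label == "no_change"

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pc.classify_sd_change(np.zeros(10), np.zeros(10))

    def test_scale_invariance(self, rng):
        fs = 200.0
        x = rng.standard_normal(int(300 * fs))
        r1 = pc.band_ratios(ECoGRecording(x, fs=fs), 150.0, mode="human")
        r2 = pc.band_ratios(ECoGRecording(3.0 * x, fs=fs), 150.0, mode="human")
        for band in r1:
            assert r1[band].label == r2[band].label
            assert r1[band].p_value == pytest.approx(r2[band].p_value, rel=1e-9)
            np.testing.assert_allclose(9.0 * r1[band].pre_powers, r2[band].pre_powers, rtol=1e-9)


class TestBandRatios:
    def test_band_separable_suppression(self, rng):
        fs = 200.0
        n = int(300 * fs)
        t = np.arange(n) / fs
        from sdlamina.signal_model import filter_trace

        slow = filter_trace(rng.standard_normal(n), fs, 0.5, 4.0)
        fast = filter_trace(rng.standard_normal(n), fs, 8.0, 45.0)
        sd_mask = (t >= 155.0) & (t <= 195.0)
        slow[sd_mask] *= 0.2  # suppress only delta during SD
        rec = ECoGRecording(slow + fast, fs=fs)
        res = pc.band_ratios(rec, 150.0, mode="human")
        assert res["delta"].label == "depression"
        assert res["fast"].label == "no_change"

    def test_uniform_scaling_booms_all_bands(self, rng):
        fs = 200.0
        x = rng.standard_normal(int(300 * fs))
        t = np.arange(x.size) / fs
        x[(t >= 155.0) & (t <= 195.0)] *= 2.0
        res = pc.band_ratios(ECoGRecording(x, fs=fs), 150.0, mode="human")
        assert all(res[b].label == "boom" for b in res)


class TestNormalizedSpectrum:
    def test_identical_epochs_give_flat_unit_ratio(self, rng):
        fs = 200.0
        items = []
        for s in range(6):
            x = np.tile(np.random.default_rng(s).standard_normal(int(65 * fs)), 6)
            items.append((ECoGRecording(x, fs=fs), 150.0))
        # epochs [30,60] and [160,190] are 130 s = 2 periods apart -> identical
        out = pc.normalized_spectrum(items, mode="human")
        np.testing.assert_allclose(out["median"], 1.0, atol=1e-9)
        assert np.all(out["p"] > 0.999)

    def test_delta_suppressed_population_significant_only_below_4hz(self, rng):
        fs = 200.0
        items = []
        from sdlamina.signal_model import filter_trace

        for s in range(8):
            r = np.random.default_rng(100 + s)
            n = int(300 * fs)
            t = np.arange(n) / fs
            slow = filter_trace(r.standard_normal(n), fs, 0.5, 4.0)
            fast = filter_trace(r.standard_normal(n), fs, 8.0, 45.0)
            slow[(t >= 155.0) & (t <= 195.0)] *= 0.5  # power x0.25
            items.append((ECoGRecording(slow + fast, fs=fs), 150.0))
        out = pc.normalized_spectrum(items, mode="human")
        f = out["freqs"]
        in_delta = (f >= 0.8) & (f <= 3.5)
        in_fast = (f >= 10.0) & (f <= 40.0)
        assert np.median(out["median"][in_delta]) < 0.5
        assert (out["p"][in_delta] < 0.05).mean() > 0.9
        assert (out["p"][in_fast] < 0.05).mean() < 0.2

    def test_single_sd_omits_population_p(self, rng):
        rec = _noise_rec(rng)
        out = pc.normalized_spectrum([(rec, 150.0)], mode="human")
        assert out["p"] is None

    def test_ratio_agrees_with_welch_oracle(self, rng):
        fs = 200.0
        rec = _noise_rec(rng)
        out = pc.normalized_spectrum([(rec, 150.0)], mode="human")
        x = rec.data
        f_w, p_pre = sps.welch(x[int(30 * fs) : int(60 * fs)], fs, nperseg=1000)
        _, p_sd = sps.welch(x[int(160 * fs) : int(190 * fs)], fs, nperseg=1000)
        ratio_w = np.interp(out["freqs"], f_w, p_sd / p_pre)
        band = (out["freqs"] > 1) & (out["freqs"] < 40)
        assert np.median(np.abs(out["ratios"][0][band] - ratio_w[band])) < 0.2


class TestStopDepthRelation:
    def test_too_few_events_raises(self):
        df = pd.DataFrame({"stop_depth_um": [400, 900], "ratio": [1.0, 0.5], "label": ["a", "b"]})
        with pytest.raises(ValueError):
            pc.ratio_stopdepth_relation(df)

    def test_constant_ratios_reported_undefined(self):
        df = pd.DataFrame(
            {
                "stop_depth_um": np.arange(400, 1600, 100),
                "ratio": np.ones(12),
                "label": ["no_change"] * 12,
            }
        )
        out = pc.ratio_stopdepth_relation(df)
        assert out.get("undefined") and np.isnan(out["spearman_r"])

    def test_permutation_p_matches_construction(self, rng):
        stops = rng.uniform(400, 1600, 40)
        ratios = 1.5 - stops / 1600 + rng.normal(0, 0.1, 40)
        df = pd.DataFrame(
            {"stop_depth_um": stops, "ratio": ratios, "label": rng.choice(["a", "b"], 40)}
        )
        out = pc.ratio_stopdepth_relation(df, n_perm=500, seed=0)
        assert out["spearman_r"] < -0.5
        assert out["perm_p"] < 0.01
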