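"""CSD, UP/gamma event detection and ICA decomposition."""

import numpy as np
import pytest

from sdlamina import laminar_generators as lg
from sdlamina import synthetic_cortex as sc
from sdlamina.signal_model import LaminarRecording, filter_trace


class TestCSD:
    def test_linear_field_nulls(self, rng):
        depths = np.arange(100.0, 1700.0, 100.0)
        data = np.outer(depths, rng.standard_normal(500)) + 3.0
        rec = LaminarRecording(data, depths, fs=1000.0)
        assert np.abs(lg.compute_csd(rec).csd).max() < 1e-12

    def test_quadratic_field_gives_constant(self):
        depths = np.arange(100.0, 1700.0, 100.0)
        data = np.outer(depths**2, np.ones(100))
        rec = LaminarRecording(data, depths, fs=1000.0)
        csd = lg.compute_csd(rec).csd
        np.testing.assert_allclose(csd, 2.0, atol=1e-9)  # d2(z^2)/dz2 = 2

    def test_linearity(self, rng):
        depths = np.arange(100.0, 1700.0, 100.0)
        a = rng.standard_normal((16, 200))
        b = rng.standard_normal((16, 200))
        csd = lambda d: lg.compute_csd(LaminarRecording(d, depths, fs=1e3)).csd
        np.testing.assert_allclose(csd(2 * a - b), 2 * csd(a) - csd(b), atol=1e-12)

    def test_nonuniform_spacing_rejected(self):
        rec = LaminarRecording(np.zeros((4, 10)), [100, 200, 350, 500], fs=1e3)
        with pytest.raises(ValueError):
            lg.compute_csd(rec)


class TestEventDetection:
    def _rec_with_planted_negative_events(self, rng, amp=5.0):
        fs = 1000.0
        n = int(120 * fs)
        x = filter_trace(rng.standard_normal(n), fs, 0.5, 4.0)
        x /= x.std()
        times = np.arange(40.0, 115.0, 1.7)  # baseline before 40 s stays quiet
        t = np.arange(n) / fs
        for tt in times:
            x -= amp * np.exp(-(((t - tt) / 0.15) ** 2))
        data = np.tile(x, (3, 1))
        return LaminarRecording(data, [100, 200, 300], fs=fs), times

    def test_planted_up_events_all_recalled(self, rng):
        rec, times = self._rec_with_planted_negative_events(rng)
        det = lg.detect_up_states(rec, channel_ref=0, baseline_s=(0.0, 35.0))
        recalled = sum(np.min(np.abs(det - tt)) < 0.1 for tt in times)
        assert recalled == len(times)

    def test_noise_counts_match_threshold_crossing_oracle(self, rng):
        fs = 1000.0
        x = rng.standard_normal(int(120 * fs))
        rec = LaminarRecording(np.tile(x, (2, 1)), [100, 200], fs=fs)
        det = lg.detect_up_states(rec, channel_ref=0)
        xf = filter_trace(x, fs, 0.5, 4.0)
        crossings = np.count_nonzero(np.diff((xf < -xf.std()).astype(int)) == 1)
        assert abs(len(det) - crossings) <= 0.25 * crossings

    def test_silent_trace_has_no_events(self):
        rec = LaminarRecording(np.zeros((2, 70_000)), [100, 200], fs=1000.0)
        assert len(lg.detect_up_states(rec, 0)) == 0
        assert len(lg.detect_gamma_troughs(rec, 0)) == 0

    def test_gamma_troughs_at_60hz_period(self, rng):
        fs = 1000.0
        n = int(90 * fs)
        t = np.arange(n) / fs
        noise = filter_trace(rng.standard_normal(n), fs, 30.0, 150.0)
        x = noise / noise.std() * 0.3 + 1.0 * np.sin(2 * np.pi * 60.0 * t)
        rec = LaminarRecording(x[None, :], [100.0], fs=fs)
        det = lg.detect_gamma_troughs(rec, 0)
        iti = np.diff(det)
        iti = iti[iti < 0.05]
        assert np.median(iti) * 1000 == pytest.approx(16.7, abs=1.0)

    def test_short_baseline_rejected(self, rng):
        rec = LaminarRecording(rng.standard_normal((1, 70_000)), [100.0], fs=1000.0)
        with pytest.raises(ValueError):
            lg.detect_up_states(rec, 0, baseline_s=(0.0, 20.0))


class TestDecomposition:
    def test_single_source_rank_one_recovery(self, rng):
        depths = sc.default_depths()
        profile = np.exp(-(((depths - 600.0) / 200.0) ** 2))
        fs = 500.0
        src = filter_trace(rng.standard_normal(int(90 * fs)), fs, 1.0, 4.0)
        rec = LaminarRecording(np.outer(profile, src), depths, fs=fs)
        dec = lg.decompose_generators(rec, n_pca=5, seed=0)
        assert dec.n_components == 1
        assert dec.variance_fraction[0] > 0.99
        r = np.corrcoef(dec.profiles[:, 0], profile)[0, 1]
        assert abs(r) > 0.999

    def test_same_seed_reproducible_and_seeds_agree(self, rng):
        cfg = sc.SessionConfig(
            duration_s=90.0,
            generators=sc.default_generator_specs(sc.default_depths(), include_fast=False),
            sd_plans=[],
            local_delta_mv=0.0,
            gamma_noise_mv=0.0,
            subsd_gamma_mv=0.0,
            noise_mv=0.01,
            spikes=False,
        )
        rec, _, truth = sc.simulate_laminar_session(cfg, 9)
        dec1 = lg.decompose_generators(rec, n_pca=5, seed=3)
        dec2 = lg.decompose_generators(rec, n_pca=5, seed=3)
        np.testing.assert_array_equal(dec1.profiles, dec2.profiles)
        cortical = np.column_stack(
            [g.profile for g in truth.generators if g.name != "Remote"]
        )
        for seed in range(4):
            dec = lg.decompose_generators(rec, n_pca=5, seed=seed)
            _, corrs = lg.align_profiles(dec.profiles, cortical)
            assert np.min(corrs) > 0.9

    def test_reconstruction_residual_bounded_by_discarded_variance(self, partial_session):
        rec, _ = partial_session
        dec = lg.decompose_generators(rec, n_pca=5, seed=0)
        assert dec.residual_fraction <= dec.discarded_fraction + 0.01
        assert np.all(dec.variance_fraction >= 0.01)

    def test_profile_sign_and_scale_convention(self, partial_session):
        rec, _ = partial_session
        dec = lg.decompose_generators(rec, n_pca=5, seed=0)
        for j in range(dec.n_components):
            p = dec.profiles[:, j]
            assert np.linalg.norm(p) == pytest.approx(1.0)
            assert p[np.argmax(np.abs(p))] > 0

    def test_short_epoch_rejected(self, rng):
        rec = LaminarRecording(
            rng.standard_normal((16, 10_000)), sc.default_depths(), fs=1000.0
        )
        with pytest.raises(ValueError):
            lg.decompose_generators(rec, n_pca=5, seed=0)


class TestGeneratorPowerChange:
    def _dec(self, rng):
        fs = 100.0
        src = rng.standard_normal((2, int(160 * fs)))
        profiles = np.eye(16)[:, :2] + 0.01
        return lg.GeneratorDecomposition(
            profiles=profiles,
            sources=src,
            variance_fraction=np.array([0.6, 0.4]),
            mean=np.zeros(16),
            fs=fs,
            discarded_fraction=0.0,
        )

    def test_identical_epochs_ratio_one(self, rng):
        dec = self._dec(rng)
        out = lg.generator_power_change(dec, (10.0, 50.0), (10.0, 50.0))
        np.testing.assert_allclose(out, 1.0)

    def test_epoch_overlapping_sd_rise_rejected(self, rng):
        dec = self._dec(rng)
        with pytest.raises(ValueError):
            lg.generator_power_change(dec, (10.0, 50.0), (78.0, 118.0), sd_onset_s=80.0)

    def test_stop_depth_grouping_separates_spared_deep_generator(self, rng):
        import pandas as pd

        stops = np.concatenate(
            [rng.uniform(400, 1000, 20), rng.uniform(1000, 1500, 20), rng.uniform(1500, 1700, 20)]
        )
        deep = np.where(stops < 1000, 2.5, 0.1) * rng.lognormal(0, 0.2, 60)
        df = pd.DataFrame({"stop_depth_um": stops, "L56": deep})
        out = lg.group_ratios_by_stop_depth(df)
        assert out["L56"]["kruskal_p"] < 0.001
        assert out["L56"]["medians"]["lt_1mm"] > 1.0 > out["L56"]["medians"]["gt_1.5mm"]

    def test_full_sd_silences_cortical_generators_but_not_remote(self, full_session):
        rec, truth = full_session
        dec = lg.decompose_generators(rec, n_pca=5, seed=1)
        onset = truth.sd_onsets[0][0]
        ratios = lg.generator_power_change(
            dec, (20.0, 60.0), (onset + 21.0, onset + 61.0), sd_onset_s=onset
        )
        cortical = np.column_stack(
            [g.profile for g in truth.generators if g.name in ("Main", "L56")]
        )
        perm, corrs = lg.align_profiles(dec.profiles, cortical)
        matched = [perm[i] for i in range(cortical.shape[1]) if corrs[i] > 0.8]
        assert matched, "no cortical generator recovered"
        for j in matched:
            assert ratios[j] < 0.2
        # the flat (remote) generator: smallest profile coefficient of variation
        cv = np.abs(np.std(dec.profiles, axis=0) / np.mean(dec.profiles, axis=0))
        j_remote = int(np.argmin(cv))
        assert ratios[j_remote] == pytest.approx(1.0, abs=0.3)
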