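"""Reusable simulation-plus-analysis experiments.

Each function generates synthetic sessions under the default study
conditions, runs the corresponding analysis stage end-to-end and returns a
dict of summary quantities.  They back both the acceptance test suite and
``scripts/acceptance.py``.  Problem sizes are desk-scale (tens of sessions,
1 kHz LFP, 10 kHz wideband) so a full battery runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import intracellular as ic
from . import laminar_generators as lg
from . import mua_phase as mp
from . import power_class as pc
from . import sd_detect as sdd
from . import synthetic_cortex as sc
from .signal_model import ECoGRecording, LaminarRecording

__all__ = [
    "sd_recovery_batch",
    "classification_calibration",
    "depth_ratio_batch",
    "volume_conduction_summary",
    "csd_checks",
    "ica_recovery",
    "spike_detection_summary",
    "zone_recovery_batch",
    "circular_calibration",
    "intracellular_batch",
]


def _session(stop_um, seed, duration_s=120.0, onset_s=70.0, spikes=False, **kw):
    cfg = sc.SessionConfig(
        duration_s=duration_s,
        sd_plans=[sc.SDPlan(onset_top_s=onset_s, stop_depth_um=stop_um)],
        spikes=spikes,
        **kw,
    )
    return sc.simulate_laminar_session(cfg, seed)


# ---------------------------------------------------------------------------


def sd_recovery_batch(n_events: int = 50, seed: int = 0) -> dict:
    """Onset and stop-depth recovery over SDs with random planted stop depths."""
    rng = np.random.default_rng(seed)
    onset_err, stop_err = [], []
    for i in range(n_events):
        stop = float(rng.uniform(400.0, 1600.0))
        rec, _, truth = _session(stop, seed=int(rng.integers(2**31)))
        events = sdd.detect_sd_onsets(rec)
        true_onsets = truth.sd_onsets[0]
        true_stop = max(
            rec.depths_um[ci] for ci in true_onsets
        )  # deepest channel actually receiving the shift
        if not events:
            onset_err.append(np.inf)
            stop_err.append(np.inf)
            continue
        ev = max(events, key=lambda e: len(e.onsets_s))
        top_ch = min(true_onsets)
        err = (
            abs(ev.onsets_s[top_ch] - true_onsets[top_ch])
            if top_ch in ev.onsets_s
            else np.inf
        )
        onset_err.append(err)
        stop_err.append(abs(ev.stop_depth_um - true_stop))
    onset_err, stop_err = np.asarray(onset_err), np.asarray(stop_err)
    ok = (onset_err <= 1.0) & (stop_err <= 100.0)
    return {
        "n": n_events,
        "recovery_rate": float(ok.mean()),
        "median_onset_error_s": float(np.median(onset_err)),
        "median_stop_error_um": float(np.median(stop_err)),
    }


# ---------------------------------------------------------------------------


def classification_calibration(
    n_null: int = 1000, n_scaled: int = 100, seed: int = 0
) -> dict:
    """Type-I calibration and sensitivity of the depression/boom classifier."""
    rng = np.random.default_rng(seed)
    labels = []
    for _ in range(n_null):
        pre = rng.chisquare(6, size=30)
        sd = rng.chisquare(6, size=30)
        labels.append(pc.classify_sd_change(pre, sd).label)
    no_change_rate = float(np.mean([l == "no_change" for l in labels]))

    hits = {0.3: 0, 2.0: 0}
    onset = 130.0
    fs = 200.0
    n = int(180.0 * fs)
    for scale, want in ((0.3, "depression"), (2.0, "boom")):
        for _ in range(n_scaled):
            x = rng.standard_normal(n)
            t = np.arange(n) / fs
            x[(t >= onset + 5) & (t <= onset + 45)] *= scale
            rec = ECoGRecording(x, fs=fs)
            pre, sd = pc.epoch_power(rec, onset, mode="human")
            if pc.classify_sd_change(pre, sd).label == want:
                hits[scale] += 1
    return {
        "n_null": n_null,
        "no_change_rate": no_change_rate,
        "depression_hit_rate": hits[0.3] / n_scaled,
        "boom_hit_rate": hits[2.0] / n_scaled,
    }


# ---------------------------------------------------------------------------


def depth_ratio_batch(n_events: int = 60, seed: int = 0, n_perm: int = 1000) -> dict:
    """Stop-depth vs top-channel power-ratio relation over a simulated batch."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_events):
        stop = float(rng.uniform(400.0, 1600.0))
        rec, _, truth = _session(stop, seed=int(rng.integers(2**31)))
        events = sdd.detect_sd_onsets(rec)
        if not events:
            continue
        ev = max(events, key=lambda e: len(e.onsets_s))
        top_ch = min(ev.onsets_s)
        res = pc.band_ratios(rec, ev.onsets_s[top_ch], mode="rat", channel=0)
        rows.append(
            {
                "stop_depth_um": ev.stop_depth_um,
                "ratio": res["ac"].ratio,
                "ratio_delta": res["delta"].ratio,
                "ratio_fast": res["fast"].ratio,
                "label": res["ac"].label,
            }
        )
    df = pd.DataFrame(rows)
    rel = pc.ratio_stopdepth_relation(df, n_perm=n_perm, seed=seed)
    rel["n"] = len(df)
    rel["events"] = df
    return rel


# ---------------------------------------------------------------------------


def _channel_band_ratio(rec, channel, band, pre_s, sd_s):
    pre = pc.sliding_band_power(
        rec.data[channel, int(pre_s[0] * rec.fs) : int(pre_s[1] * rec.fs)], rec.fs, band, "rat"
    )
    sd = pc.sliding_band_power(
        rec.data[channel, int(sd_s[0] * rec.fs) : int(sd_s[1] * rec.fs)], rec.fs, band, "rat"
    )
    return float(sd.mean() / pre.mean())


def volume_conduction_summary(seed: int = 0) -> dict:
    """Superficial-SD volume-conduction mechanism, with and without the deep
    generator (isoguvacine configuration)."""
    out = {}
    for tag, iso in (("control", False), ("isoguvacine", True)):
        rec, _, truth = _session(
            500.0, seed=seed, duration_s=160.0, isoguvacine=iso
        )
        onset_top = truth.sd_onsets[0][0]
        res = pc.band_ratios(rec, onset_top, mode="rat", channel=0)
        out[f"top_delta_ratio_{tag}"] = res["delta"].ratio
        if not iso:
            # invaded mid-depth channel: local sources suppressed during SD
            mid = rec.channel_at_depth(500.0)
            plan = truth.sd_plans[0]
            a_stop = plan.arrival_s(plan.stop_depth_um, rec.depths_um[0])
            out["mid_delta_ratio"] = _channel_band_ratio(
                rec, mid, (0.5, 4.0), (30.0, 60.0), (a_stop + 15.0, a_stop + 45.0)
            )
    return out


# ---------------------------------------------------------------------------


def csd_checks() -> dict:
    """Closed-form CSD checks: linear nulling, quadratic constancy, dipole."""
    depths = sc.default_depths()
    n_ch, n_t = depths.size, 200
    rng = np.random.default_rng(0)
    a, b = rng.standard_normal(n_t), rng.standard_normal(n_t)
    lin = np.outer(depths, a) + np.outer(np.ones(n_ch), b)
    rec = LaminarRecording(lin, depths, fs=100.0)
    lin_max = float(np.abs(lg.compute_csd(rec).csd).max())

    quad = np.outer(depths**2, np.ones(n_t))
    rec = LaminarRecording(quad, depths, fs=100.0)
    csd_q = lg.compute_csd(rec).csd
    quad_dev = float(np.abs(csd_q - 2.0).max())  # d2/dz2 of z^2 = 2 (per um^2 x h^2 scale)

    # dipole: plant a CSD with a source at ch 5 and sink at ch 8, integrate
    # twice along depth to get the potential, then invert
    csd_true = np.zeros(n_ch)
    csd_true[4], csd_true[7] = 1.0, -1.0
    h = 100.0
    u = np.zeros(n_ch)
    for i in range(1, n_ch - 1):  # centred double integration: D2(u)[i] = csd[i]
        u[i + 1] = 2 * u[i] - u[i - 1] + csd_true[i] * h**2
    rec = LaminarRecording(np.outer(u, np.ones(n_t)), depths, fs=100.0)
    csd_est = lg.compute_csd(rec).csd[:, 0]
    # compare to the triangular-smoothed plant on interior channels
    pad = np.concatenate([csd_true[:1], csd_true, csd_true[-1:]])
    sm = (pad[:-2] + 2 * pad[1:-1] + pad[2:])[1:-1] / 4.0
    resid = float(np.linalg.norm(csd_est - sm) / np.linalg.norm(sm))
    src = int(np.argmax(csd_est)) + 1
    snk = int(np.argmin(csd_est)) + 1
    return {
        "linear_max_abs": lin_max,
        "quadratic_deviation": quad_dev,
        "dipole_residual": resid,
        "dipole_source_channel": src,
        "dipole_sink_channel": snk,
    }


# ---------------------------------------------------------------------------


def _snr10_config(depths, extra_gen=None, seed=0):
    gens = sc.default_generator_specs(depths, include_fast=False)
    if extra_gen is not None:
        gens = gens + [extra_gen]
    sig_var = 0.0
    for g in gens:
        sig_var += g.gain**2 * (g.profile**2).mean()
    noise = float(np.sqrt(sig_var / 10.0))
    return sc.SessionConfig(
        duration_s=160.0,
        generators=gens,
        sd_plans=[],
        noise_mv=noise,
        gamma_noise_mv=0.0,
        subsd_gamma_mv=0.0,
        local_delta_mv=0.0,
        spikes=False,
    )


def ica_recovery(seed: int = 0) -> dict:
    """Plant-recovery of the ICA generator decomposition at SNR 10."""
    depths = sc.default_depths()
    cfg = _snr10_config(depths)
    rec, _, truth = sc.simulate_laminar_session(cfg, seed)
    dec = lg.decompose_generators(rec, n_pca=5, seed=seed)
    true_profiles = np.column_stack(
        [g.profile for g in truth.generators if g.name != "Remote"]
    )
    _, corrs = lg.align_profiles(dec.profiles, true_profiles)
    # remote generator: flat profile, identified by coefficient of variation
    cvs = np.abs(np.std(dec.profiles, axis=0) / np.mean(dec.profiles, axis=0))
    resid = dec.residual_fraction

    # sub-cutoff plant: a 0.5%-variance generator must be discarded
    z = depths
    tiny_profile = np.exp(-(((z - 800.0) / 150.0) ** 2))
    base_var = sum(g.gain**2 * (g.profile**2).mean() for g in cfg.resolved_generators())
    tiny_gain = float(np.sqrt(0.005 * base_var / (tiny_profile**2).mean()))
    tiny = sc.GeneratorSpec("Tiny", tiny_profile, "delta_updown", gain=tiny_gain)
    cfg2 = _snr10_config(depths, extra_gen=tiny)
    rec2, _, _ = sc.simulate_laminar_session(cfg2, seed + 1)
    dec2 = lg.decompose_generators(rec2, n_pca=5, seed=seed)
    tiny_corr = max(
        abs(np.corrcoef(tiny.profile, dec2.profiles[:, j])[0, 1])
        for j in range(dec2.n_components)
    )
    return {
        "min_cortical_profile_r": float(np.min(corrs)),
        "remote_profile_cv": float(np.min(cvs)),
        "reconstruction_residual": resid,
        "discarded_fraction": dec.discarded_fraction,
        "n_components": dec.n_components,
        "tiny_plant_max_r": float(tiny_corr),
        "tiny_n_components": dec2.n_components,
    }


# ---------------------------------------------------------------------------


def spike_scenario(
    seed: int,
    duration_s: float = 130.0,
    fs: float = 10000.0,
    noise_mv: float = 0.01,
    spike_rate_hz: float = 10.0,
    amp_factor: float = 8.0,
    sd_window_s=None,
    sd_noise_gain: float = 1.0,
):
    """Single wideband channel with planted spikes and optional SD noise rise.

    Spikes are planted only outside ``sd_window_s``; inside it the noise STD
    is scaled by ``sd_noise_gain`` (emulating the tissue-resistance rise).
    Returns (recording, spike_times, sigma_band) where ``sigma_band`` is the
    STD of the spike-band filtered noise alone.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    noise = sc._bounded_noise(rng, n, noise_mv)
    if sd_window_s is not None and sd_noise_gain != 1.0:
        lo, hi = sd_window_s
        noise[(t >= lo) & (t < hi)] *= sd_noise_gain
    sigma_band = float(
        mp.wavelet_bandpass(noise[: int(30 * fs)], fs, 250.0, 4000.0).std()
    )
    x = noise.copy()
    tmpl = sc._spike_template(fs, amp_factor * sigma_band)
    n_spk = rng.poisson(spike_rate_hz * duration_s)
    times = np.sort(rng.uniform(0.005, duration_s - 0.005, n_spk))
    times = times[np.concatenate([[True], np.diff(times) > 3e-3])]
    if sd_window_s is not None:
        lo, hi = sd_window_s
        times = times[(times < lo - 0.01) | (times >= hi + 0.01)]
    for st in times:
        i0 = int(round(st * fs))
        x[i0 : i0 + tmpl.size] += tmpl[: n - i0]
    rec = LaminarRecording(x[None, :], [500.0], fs, coupling="DC")
    return rec, times, sigma_band


def spike_detection_summary(seed: int = 0) -> dict:
    """Sensitivity/FDR of spike detection and the adaptive-threshold rescue."""
    rec, planted, _ = spike_scenario(seed)
    st = mp.detect_spikes(rec, control_epoch_s=(0.0, 110.0))
    det = st.spike_times_s
    tol = 5e-4
    hits = 0
    used = np.zeros(det.size, bool)
    for pt in planted:
        i = np.searchsorted(det, pt)
        for j in (i - 1, i):
            if 0 <= j < det.size and not used[j] and abs(det[j] - pt) <= tol:
                used[j] = True
                hits += 1
                break
    sens = hits / planted.size
    fdr = 1.0 - used.sum() / det.size if det.size else 0.0

    sd_win = (110.0, 125.0)
    rec2, planted2, _ = spike_scenario(
        seed + 1, sd_window_s=sd_win, sd_noise_gain=2.0
    )
    st_ad = mp.detect_spikes(
        rec2, control_epoch_s=(0.0, 108.0), sd_windows_s=[(108.0, 127.0)], adaptive=True
    )
    st_fx = mp.detect_spikes(rec2, control_epoch_s=(0.0, 108.0), adaptive=False)

    def _count(times):
        return int(np.count_nonzero((times >= sd_win[0]) & (times < sd_win[1])))

    return {
        "n_planted": int(planted.size),
        "sensitivity": float(sens),
        "fdr": float(fdr),
        "adaptive_sd_false_detections": _count(st_ad.spike_times_s),
        "fixed_sd_false_detections": _count(st_fx.spike_times_s),
    }


# ---------------------------------------------------------------------------


def zone_recovery_batch(n_events: int = 30, seed: int = 0) -> dict:
    """Three-zone recovery pooled over partial SDs with a planted sub-SD band."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_events):
        stop = float(rng.choice(np.arange(600.0, 1201.0, 100.0)))
        rec, _, truth = _session(stop, seed=int(rng.integers(2**31)), duration_s=160.0, spikes=True)
        plan = truth.sd_plans[0]
        onsets = truth.sd_onsets[0]
        earliest, deepest = min(onsets.values()), max(onsets.values())
        trains = [
            mp.SpikeTrain(ci, truth.spike_times[ci]) for ci in range(rec.n_channels)
        ]
        mua = mp.mua_change(trains, earliest, deepest)
        pre_s = (30.0, 60.0)
        sd_s = (deepest, deepest + 15.0)
        for ci in range(rec.n_channels):
            rows.append(
                {
                    "rel_depth_um": rec.depths_um[ci] - plan.stop_depth_um,
                    "delta_ratio": _channel_band_ratio(rec, ci, (0.5, 4.0), pre_s, sd_s),
                    "gamma_ratio": _channel_band_ratio(rec, ci, (30.0, 150.0), pre_s, sd_s),
                    "mua_ratio": mua.loc[ci, "ratio"],
                }
            )
    prof = mp.zone_profile(pd.DataFrame(rows))
    order_ok = _zones_ordered(prof.labels)
    return {
        "n": n_events,
        "subsd_top_um": prof.subsd_top_um,
        "subsd_bottom_um": prof.subsd_bottom_um,
        "zones_ordered": bool(order_ok),
        "peak_mua_increase": prof.peak_mua_increase,
        "profile": prof,
    }


def _zones_ordered(labels) -> bool:
    """True when labels form contiguous depressed -> excited -> unchanged runs."""
    seq = [labels[0]]
    for l in labels[1:]:
        if l != seq[-1]:
            seq.append(l)
    return seq in (
        ["depressed", "subsd_excited", "unchanged"],
        ["depressed", "unchanged"],
        ["depressed", "subsd_excited"],
        ["depressed"],
        ["unchanged"],
    )


# ---------------------------------------------------------------------------


def circular_calibration(seed: int = 0, n_runs: int = 1000, n_phases: int = 1000) -> dict:
    """Rayleigh type-I error under uniform phases and von Mises recovery."""
    rng = np.random.default_rng(seed)
    phases = rng.uniform(-np.pi, np.pi, size=(n_runs, n_phases))
    z = np.exp(1j * phases).mean(axis=1)
    rn = n_phases * np.abs(z)
    p = np.exp(
        np.sqrt(1.0 + 4.0 * n_phases + 4.0 * (n_phases**2 - rn**2)) - (1.0 + 2.0 * n_phases)
    )
    rej = float((p < 0.05).mean())
    mu_true = np.pi / 3.0
    vm = rng.vonmises(mu_true, 1.0, size=200)
    mu, r = mp.circular_mean(vm)
    err_deg = abs(np.angle(np.exp(1j * (mu - mu_true)))) * 180.0 / np.pi
    return {
        "n_runs": n_runs,
        "rayleigh_type1_rate": rej,
        "vonmises_direction_error_deg": float(err_deg),
        "vonmises_resultant": float(r),
    }


# ---------------------------------------------------------------------------


def _cell_metrics(rec, truth, cell_depth, seed):
    trace, info = sc.simulate_intracellular(rec, truth, cell_depth, seed=seed)
    corr = ic.correct_membrane_potential(trace, rec)
    ap = ic.detect_action_potentials(corr.em, corr.fs)
    lo, hi = info["sd_window"]
    plan = truth.sd_plans[0]
    m = ic.depolarization_metrics(
        corr,
        ap,
        sd_window_s=(lo, hi),
        cell_depth_um=cell_depth,
        stop_depth_um=plan.stop_depth_um,
        baseline_s=(5.0, lo - 15.0),
    )
    return m, info


def intracellular_batch(seed: int = 0) -> dict:
    """Block-threshold / sub-SD plateau recovery and the depth relation."""
    # sub-SD cell below a partial SD
    rec_p, _, truth_p = _session(900.0, seed=seed, duration_s=160.0)
    m_sub, _ = _cell_metrics(rec_p, truth_p, 1100.0, seed + 1)
    # invaded cell under a full SD
    rec_f, _, truth_f = _session(1600.0, seed=seed + 2, duration_s=160.0)
    m_blk, _ = _cell_metrics(rec_f, truth_f, 1100.0, seed + 3)

    # mixed batch for the depolarization vs distance relation
    depths = [800.0, 1000.0, 1200.0]
    stops = [400.0, 700.0, 1000.0, 1300.0, 1600.0]
    depol, penetration = [], []
    k = 10
    for stop in stops:
        rec, _, truth = _session(stop, seed=seed + k, duration_s=160.0)
        for cd in depths:
            m, _ = _cell_metrics(rec, truth, cd, seed + k + 1)
            depol.append(m.depol_from_rest_mv)
            penetration.append(stop - cd)
            k += 1
    r, p = stats.spearmanr(penetration, depol)
    return {
        "subsd_peak_em_mv": m_sub.peak_em_mv,
        "subsd_sustained": bool(m_sub.sustained_firing),
        "subsd_block": m_sub.block_threshold_mv,
        "block_threshold_mv": m_blk.block_threshold_mv,
        "invaded_peak_em_mv": m_blk.peak_em_mv,
        "depth_relation_r": float(r),
        "depth_relation_p": float(p),
        "n_cells_sds": len(depol),
    }
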