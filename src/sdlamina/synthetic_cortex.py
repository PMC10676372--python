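"""Synthetic cortical-column forward model with ground truth.

The simulator emulates the statistical structure that the laminar SD
analysis assumes, not the biophysics of SD.  Laminar field potentials are a
weighted sum of a small number of fixed spatial generators times their time
courses (volume-conduction mixing), plus per-channel local delta sources,
gamma-band components, SD DC shifts and sensor noise:

    u_m(t) = sum_n V_mn s_n(t) + local_m(t) + DC_m(t) + noise_m(t)

Delta sources are UP/DOWN event trains (UP events 150-400 ms, rhythm in the
0.5-4 Hz band).  An SD is a negative DC shift propagating vertically from
the top channel at a configurable speed and stopping at a configurable
depth: channels deeper than the stop depth receive no shift.  Generators
whose spatial mass lies above the stop depth are silenced while the SD
lasts; deep generators spared by a partial SD carry delta activity to the
surface by volume conduction (and are moderately boosted, emulating the
roughly two-fold power increase of the deep generator seen during
superficial SDs).  Spiking is inhomogeneous Poisson, UP-locked, silenced in
invaded layers after a brief pre-SD gamma burst, elevated and
gamma-modulated in a ~300 um band just below the stop depth, and unchanged
below.

Everything planted is returned in :class:`GroundTruth`; identical
(config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .signal_model import ECoGRecording, IntracellularTrace, LaminarRecording, filter_trace

__all__ = [
    "GeneratorSpec",
    "SDPlan",
    "SessionConfig",
    "GroundTruth",
    "default_depths",
    "default_generator_specs",
    "simulate_laminar_session",
    "simulate_human_ecog",
    "simulate_intracellular",
]

CORTICAL_KINDS = ("delta_updown", "fast_local")


def default_depths() -> np.ndarray:
    """Default rat geometry: 16 channels, 100-1600 um, 100 um spacing."""
    return np.arange(100.0, 1601.0, 100.0)


@dataclass
class GeneratorSpec:
    """A spatially fixed field-potential generator.

    ``profile`` holds the per-channel spatial weights (unit maximum absolute
    weight); ``gain`` scales a unit-variance source time course into mV.
    """

    name: str
    profile: np.ndarray
    source_kind: str = "delta_updown"  # delta_updown | flat_remote | fast_local
    band: tuple = (0.5, 4.0)
    gain: float = 0.3

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        peak = np.abs(self.profile).max()
        if peak > 0:
            self.profile = self.profile / peak

    def mass_depth_quantile(self, depths_um: np.ndarray, q: float) -> float:
        """Depth above which the fraction ``q`` of |profile| mass lies."""
        w = np.abs(self.profile)
        c = np.cumsum(w) / w.sum()
        return float(np.interp(q, c, depths_um))


def default_generator_specs(depths_um: np.ndarray, include_fast: bool = True):
    """The default generator set: Main, L3, L5/6, Remote (+ superficial fast).

    Main has a polarity reversal between 300 and 400 um and a broad maximum
    over layers 4-5; Remote is flat (extracortical); L5/6 carries a surface
    tail realizing volume conduction of deep delta toward the pia.
    """
    z = np.asarray(depths_um, dtype=float)
    main = np.exp(-(((z - 520.0) / 130.0) ** 2)) - 0.35 * np.exp(-(((z - 130.0) / 150.0) ** 2))
    l3 = np.exp(-(((z - 300.0) / 130.0) ** 2))
    l56 = np.exp(-(((z - 1350.0) / 230.0) ** 2)) + 0.62 * np.exp(-(((z - 100.0) / 600.0) ** 2))
    remote = np.ones_like(z)
    gens = [
        GeneratorSpec("Main", main, "delta_updown", (0.5, 4.0), gain=0.30),
        GeneratorSpec("L3", l3, "delta_updown", (0.5, 4.0), gain=0.18),
        GeneratorSpec("L56", l56, "delta_updown", (0.5, 4.0), gain=0.18),
        GeneratorSpec("Remote", remote, "flat_remote", (0.5, 4.0), gain=0.072),
    ]
    if include_fast:
        fast = np.exp(-(((z - 150.0) / 120.0) ** 2))
        gens.append(GeneratorSpec("Fast", fast, "fast_local", (8.0, 45.0), gain=0.09))
    return gens


@dataclass
class SDPlan:
    """One planted SD: a negative DC shift propagating downward.

    The fall is logistic with time constant ``fall_tau_s`` (derivative peak
    |dc_amplitude|/(4 tau) at 4 tau after arrival), followed by a plateau of
    ``dc_duration_s`` and an exponential recovery.
    """

    onset_top_s: float
    stop_depth_um: float
    vertical_speed_um_per_s: float = 50.0
    dc_amplitude_mv: float = -20.0
    dc_duration_s: float = 60.0
    fall_tau_s: float = 1.25
    recovery_tau_s: float = 10.0
    presd_burst: bool = True
    subsd_zone_um: float = 300.0
    amplitude_taper: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.dc_amplitude_mv >= 0:
            raise ValueError("SD DC amplitude must be negative (negative DC shift)")

    def arrival_s(self, depth_um: float, top_depth_um: float) -> float:
        """Time the SD wavefront reaches ``depth_um``."""
        return self.onset_top_s + (depth_um - top_depth_um) / self.vertical_speed_um_per_s

    def onset_s(self, depth_um: float, top_depth_um: float) -> float:
        """Per-channel onset = time of the derivative peak (logistic centre)."""
        return self.arrival_s(depth_um, top_depth_um) + 4.0 * self.fall_tau_s

    @property
    def sdprime_peak_mv_per_s(self) -> float:
        return abs(self.dc_amplitude_mv) / (4.0 * self.fall_tau_s)

    def dc_trace(self, t_rel: np.ndarray) -> np.ndarray:
        """Unit-amplitude (0..1) DC waveform vs time since wavefront arrival."""
        tau = self.fall_tau_s
        t_fall_end = 8.0 * tau
        t_rec = t_fall_end + self.dc_duration_s
        out = 1.0 / (1.0 + np.exp(-np.clip((t_rel - 4.0 * tau) / tau, -40, 40)))
        plateau = (t_rel > t_fall_end) & (t_rel <= t_rec)
        out[plateau] = 1.0
        rec = t_rel > t_rec
        out[rec] = np.exp(-(t_rel[rec] - t_rec) / self.recovery_tau_s)
        return out

    def end_s(self, top_depth_um: float) -> float:
        """Time by which activity silenced by this SD has recovered."""
        return (
            self.arrival_s(self.stop_depth_um, top_depth_um)
            + 8.0 * self.fall_tau_s
            + self.dc_duration_s
            + 2.0 * self.recovery_tau_s
        )


@dataclass
class SessionConfig:
    """Study conditions for one simulated laminar session."""

    duration_s: float = 160.0
    fs_lfp: float = 1000.0
    depths_um: Optional[np.ndarray] = None
    generators: Optional[Sequence[GeneratorSpec]] = None
    sd_plans: Sequence[SDPlan] = ()
    noise_mv: float = 0.03
    gamma_noise_mv: float = 0.012
    subsd_gamma_mv: float = 0.05
    subsd_gamma_hz: float = 60.0
    local_delta_mv: float = 0.072
    deep_gain_during_partial: float = 1.6
    isoguvacine: bool = False
    iso_depth_um: float = 1000.0  # generators/channels at or below are silenced
    spikes: bool = True
    base_rate_hz: float = 8.0
    subsd_rate_gain: float = 3.0
    presd_burst_gain: float = 4.0
    sd_silence_rate_factor: float = 0.02
    wideband_channels: Sequence[int] = ()
    fs_wideband: float = 10000.0
    wideband_noise_mv: float = 0.01
    sd_wideband_noise_gain: float = 1.0
    spike_amp_mv: float = 0.08

    def resolved_depths(self) -> np.ndarray:
        return default_depths() if self.depths_um is None else np.asarray(self.depths_um, float)

    def resolved_generators(self):
        if self.generators is None:
            return default_generator_specs(self.resolved_depths())
        return list(self.generators)


@dataclass
class GroundTruth:
    """Everything planted by the simulator, for recovery tests."""

    generators: list
    sources: np.ndarray  # (n_generators, n_samples), masked time courses
    up_times: dict  # generator name -> UP event centre times (s)
    sd_plans: list
    sd_onsets: list  # per plan: {channel_index: onset_s}
    sd_amplitudes: list  # per plan: {channel_index: mV}
    zone_labels: list  # per plan: array[str] per channel
    spared: list  # per plan: {generator name: bool}
    spike_times: Optional[list] = None  # per channel, np.ndarray (s)
    rates_hz: Optional[np.ndarray] = None  # (channels, samples) planted rate
    fs: float = 1000.0
    local_up_times: Optional[list] = None  # per channel


# ---------------------------------------------------------------------------
# sources


def _up_down_source(rng: np.random.Generator, n: int, fs: float, base_cycle_s: float = None):
    """Negative-going UP event train; unit variance; returns (trace, times).

    The UP/DOWN alternation is quasi-periodic (~2 Hz with mild jitter), so
    the source's power is concentrated inside the delta band and its
    infraslow content stays far below the SD derivative scale.
    """
    t_end = n / fs
    env = np.zeros(n)
    times = []
    # each source gets its own base cycle so distinct generators are
    # mutually incoherent (their cross terms beat and average out)
    if base_cycle_s is None:
        base_cycle_s = float(rng.uniform(0.36, 0.62))
    base_dur = 0.45 * base_cycle_s
    base_gap = 0.55 * base_cycle_s
    t = float(rng.uniform(0.05, 0.4))
    while t < t_end:
        dur = base_dur + float(rng.uniform(-0.04, 0.04))
        amp = float(rng.uniform(0.9, 1.1))
        i0 = int(t * fs)
        i1 = min(int((t + dur) * fs), n)
        if i1 > i0:
            env[i0:i1] -= amp
            times.append(t + dur / 2.0)
        t += dur + base_gap + float(rng.uniform(-0.04, 0.04))
    env = gaussian_filter1d(env, sigma=0.05 * fs)
    env -= env.mean()
    sd = env.std()
    if sd > 0:
        env /= sd
    return env, np.asarray(times)


def _band_noise(rng: np.random.Generator, n: int, fs: float, low: float, high: float):
    x = rng.standard_normal(n)
    high = min(high, 0.45 * fs)
    x = filter_trace(x, fs, low, high)
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_gate(
    n: int, fs: float, t_lo: float, t_hi: float, floor: float = 0.0, ramp_s: float = 1.0
):
    """1 outside [t_lo, t_hi], ``floor`` inside, with linear ``ramp_s`` edges."""
    if t_hi <= t_lo:
        return np.ones(n)
    t = np.arange(n) / fs
    return np.interp(
        t,
        [t_lo - ramp_s, t_lo, t_hi, t_hi + ramp_s],
        [1.0, floor, floor, 1.0],
    )


def _window(n: int, fs: float, t_lo: float, t_hi: float, ramp_s: float = 1.0):
    """Box window with linear ramps, 1 inside [t_lo, t_hi]."""
    return 1.0 - _smooth_gate(n, fs, t_lo, t_hi, floor=0.0, ramp_s=ramp_s)


# ---------------------------------------------------------------------------
# laminar session


def _spike_template(fs: float, amp_mv: float) -> np.ndarray:
    """Biphasic ~1 ms extracellular spike, negative main phase."""
    t = np.arange(int(round(1.4e-3 * fs))) / fs
    w = -np.exp(-(((t - 0.25e-3) / 0.12e-3) ** 2)) + 0.45 * np.exp(
        -(((t - 0.6e-3) / 0.2e-3) ** 2)
    )
    return amp_mv * w / np.abs(w).max()


def simulate_laminar_session(config: SessionConfig, seed: int):
    """Generate (DC-LFP recording, wideband recording or None, ground truth)."""
    rng = np.random.default_rng(seed)
    fs = config.fs_lfp
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    depths = config.resolved_depths()
    n_ch = depths.size
    top_depth = depths[0]
    gens = config.resolved_generators()
    if not gens:
        raise ValueError("at least one generator is required")
    for plan in config.sd_plans:
        if plan.stop_depth_um < top_depth:
            raise ValueError("SD stop depth shallower than the shallowest channel")
    if config.wideband_channels and config.fs_wideband < 8000.0:
        raise ValueError("wideband sampling rate too low for the spike band")

    # --- generator sources and silencing masks -----------------------------
    sources = np.zeros((len(gens), n))
    up_times: dict = {}
    spared_per_plan = [dict() for _ in config.sd_plans]
    masks = np.ones((len(gens), n))
    medians = {g.name: g.mass_depth_quantile(depths, 0.5) for g in gens}
    q25s = {g.name: g.mass_depth_quantile(depths, 0.25) for g in gens}

    cycle_slots = 0.40 + 0.06 * np.arange(len(gens))  # distinct delta rhythms
    for gi, g in enumerate(gens):
        if g.source_kind in ("delta_updown", "flat_remote"):
            s, ev = _up_down_source(rng, n, fs, base_cycle_s=float(cycle_slots[gi]))
            up_times[g.name] = ev
        elif g.source_kind == "fast_local":
            s = _band_noise(rng, n, fs, *g.band)
            up_times[g.name] = np.asarray([])
        else:
            raise ValueError(f"unknown source kind {g.source_kind!r}")
        sources[gi] = s

        for pi, plan in enumerate(config.sd_plans):
            if g.source_kind == "flat_remote":
                spared_per_plan[pi][g.name] = True
                continue
            spared = medians[g.name] > plan.stop_depth_um
            spared_per_plan[pi][g.name] = spared
            if spared:
                if g.source_kind == "delta_updown" and config.deep_gain_during_partial != 1.0:
                    a0 = plan.arrival_s(plan.stop_depth_um, top_depth) + 4 * plan.fall_tau_s
                    boost = 1.0 + (config.deep_gain_during_partial - 1.0) * _window(
                        n, fs, a0, a0 + plan.dc_duration_s
                    )
                    masks[gi] *= boost
            else:
                t_sil = plan.arrival_s(q25s[g.name], top_depth)
                masks[gi] *= _smooth_gate(n, fs, t_sil, plan.end_s(top_depth))
        if config.isoguvacine and medians[g.name] >= config.iso_depth_um:
            masks[gi] *= 0.0

    masked = sources * masks
    lfp = np.zeros((n_ch, n))
    for gi, g in enumerate(gens):
        lfp += g.gain * np.outer(g.profile, masked[gi])

    # --- per-channel local delta sources ------------------------------------
    local_up = []
    local_sources = np.zeros((n_ch, n)) if config.local_delta_mv > 0 else None
    for ci, d in enumerate(depths):
        if config.local_delta_mv <= 0:
            local_up.append(np.asarray([]))
            continue
        s_loc, ev = _up_down_source(rng, n, fs)
        m = np.ones(n)
        for plan in config.sd_plans:
            if d <= plan.stop_depth_um + plan.subsd_zone_um:
                t_sil = plan.arrival_s(min(d, plan.stop_depth_um), top_depth)
                m *= _smooth_gate(n, fs, t_sil, plan.end_s(top_depth))
        if config.isoguvacine and d >= config.iso_depth_um:
            m *= 0.0
        local_sources[ci] = config.local_delta_mv * s_loc * m
        local_up.append(ev)
    if local_sources is not None:
        lfp += local_sources

    # --- SD DC shifts --------------------------------------------------------
    sd_onsets, sd_amplitudes, zone_labels = [], [], []
    for plan in config.sd_plans:
        onsets, amps = {}, {}
        labels = np.full(n_ch, "unchanged", dtype=object)
        for ci, d in enumerate(depths):
            if d <= plan.stop_depth_um:
                scale = plan.amplitude_taper(d) if plan.amplitude_taper else 1.0
                amp = plan.dc_amplitude_mv * scale
                lfp[ci] += amp * plan.dc_trace(t - plan.arrival_s(d, top_depth))
                onsets[ci] = plan.onset_s(d, top_depth)
                amps[ci] = amp
                labels[ci] = "depressed"
            elif d <= plan.stop_depth_um + plan.subsd_zone_um:
                labels[ci] = "subsd_excited"
        sd_onsets.append(onsets)
        sd_amplitudes.append(amps)
        zone_labels.append(labels)

    # --- gamma-band components ----------------------------------------------
    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    for ci, d in enumerate(depths):
        g = config.gamma_noise_mv * _band_noise(rng, n, fs, 30.0, min(150.0, 0.45 * fs))
        for plan in config.sd_plans:
            a_stop = plan.arrival_s(plan.stop_depth_um, top_depth)
            if d <= plan.stop_depth_um:
                g *= _smooth_gate(
                    n,
                    fs,
                    plan.onset_s(d, top_depth),
                    a_stop + 8 * plan.fall_tau_s + plan.dc_duration_s + plan.recovery_tau_s,
                    floor=0.1,
                )
                if plan.presd_burst:
                    on = plan.onset_s(d, top_depth)
                    burst = np.exp(-(((t - (on - 1.5)) / 0.6) ** 2))
                    g = g + 0.06 * np.cos(2 * np.pi * 70.0 * t + phases[ci]) * burst
            elif d <= plan.stop_depth_um + plan.subsd_zone_um:
                w = _window(n, fs, a_stop + 4 * plan.fall_tau_s, a_stop + 4 * plan.fall_tau_s + plan.dc_duration_s)
                g = g + config.subsd_gamma_mv * np.cos(
                    2 * np.pi * config.subsd_gamma_hz * t + phases[ci]
                ) * w
        lfp[ci] += g

    lfp += config.noise_mv * rng.standard_normal((n_ch, n))

    # --- spiking -------------------------------------------------------------
    spike_times, rates = None, None
    if config.spikes:
        spike_times, rates = _simulate_spikes(
            config, rng, t, depths, gens, sources, masks, phases
        )

    rec = LaminarRecording(lfp, depths, fs, coupling="DC", meta={"seed": seed})
    truth = GroundTruth(
        generators=gens,
        sources=masked.astype(np.float32),
        up_times=up_times,
        sd_plans=list(config.sd_plans),
        sd_onsets=sd_onsets,
        sd_amplitudes=sd_amplitudes,
        zone_labels=zone_labels,
        spared=spared_per_plan,
        spike_times=spike_times,
        rates_hz=rates,
        fs=fs,
        local_up_times=local_up,
    )

    wideband = None
    if config.wideband_channels:
        wideband = _simulate_wideband(config, rng, rec, truth)
    return rec, wideband, truth


def _simulate_spikes(config, rng, t, depths, gens, sources, masks, phases):
    fs = config.fs_lfp
    n = t.size
    top_depth = depths[0]
    # dominant cortical delta generator per channel drives the UP envelope
    delta_idx = [i for i, g in enumerate(gens) if g.source_kind == "delta_updown"]
    rates = np.zeros((depths.size, n), dtype=np.float32)
    spike_times = []
    for ci, d in enumerate(depths):
        if delta_idx:
            weights = [abs(gens[i].gain * gens[i].profile[ci]) for i in delta_idx]
            gi = delta_idx[int(np.argmax(weights))]
            env = np.maximum(-sources[gi], 0.0)
            m = env[env > 0].mean() if np.any(env > 0) else 1.0
            drive = 0.3 + 0.7 * env / m
        else:
            drive = np.ones(n)
        rate = config.base_rate_hz * drive
        for pi, plan in enumerate(config.sd_plans):
            a_stop = plan.arrival_s(plan.stop_depth_um, top_depth)
            sd_lo = a_stop + 4 * plan.fall_tau_s
            sd_hi = sd_lo + plan.dc_duration_s
            if d <= plan.stop_depth_um:
                on = plan.onset_s(d, top_depth)
                end = a_stop + 8 * plan.fall_tau_s + plan.dc_duration_s + plan.recovery_tau_s
                factor = _smooth_gate(n, fs, on, end, floor=config.sd_silence_rate_factor)
                if plan.presd_burst:
                    burst = np.exp(-(((t - (on - 1.5)) / 0.6) ** 2))
                    factor = factor + (config.presd_burst_gain - 1.0) * burst
                rate = rate * factor
            elif d <= plan.stop_depth_um + plan.subsd_zone_um:
                w = _window(n, fs, sd_lo, sd_hi)
                gamma_rate = (
                    config.base_rate_hz
                    * config.subsd_rate_gain
                    * (1.0 - 0.8 * np.cos(2 * np.pi * config.subsd_gamma_hz * t + phases[ci]))
                )
                rate = rate * (1.0 - w) + gamma_rate * w
        if config.isoguvacine and d >= config.iso_depth_um:
            rate = rate * 0.05
        rates[ci] = rate
        rmax = float(rate.max())
        if rmax <= 0:
            spike_times.append(np.asarray([]))
            continue
        n_hom = rng.poisson(rmax * t[-1])
        cand = np.sort(rng.uniform(0.0, t[-1], size=n_hom))
        accept = rng.uniform(0.0, 1.0, size=n_hom) < rate[
            np.minimum((cand * fs).astype(int), n - 1)
        ] / rmax
        spike_times.append(cand[accept])
    return spike_times, rates


def _bounded_noise(rng, n, sigma):
    """Soft-clipped Gaussian noise (tails bounded near 3 sigma)."""
    g = rng.standard_normal(n)
    return sigma * 3.0 * np.tanh(g / 3.0)


def _simulate_wideband(config, rng, rec, truth):
    fs_wb = config.fs_wideband
    n_wb = int(round(rec.duration_s * fs_wb))
    t_wb = np.arange(n_wb) / fs_wb
    chans = sorted(config.wideband_channels)
    depths = rec.depths_um[chans]
    data = np.zeros((len(chans), n_wb))
    tmpl = _spike_template(fs_wb, 1.0)
    top_depth = rec.depths_um[0]
    for k, ci in enumerate(chans):
        x = np.interp(t_wb, rec.times - rec.t0, rec.data[ci])
        sigma = np.full(n_wb, config.wideband_noise_mv)
        for plan in truth.sd_plans:
            if rec.depths_um[ci] <= plan.stop_depth_um and config.sd_wideband_noise_gain != 1.0:
                on = plan.onset_s(rec.depths_um[ci], top_depth)
                end = on + plan.dc_duration_s
                i0, i1 = int(on * fs_wb), min(int(end * fs_wb), n_wb)
                sigma[i0:i1] *= config.sd_wideband_noise_gain
        x = x + _bounded_noise(rng, n_wb, 1.0) * sigma
        if truth.spike_times is not None:
            for st in truth.spike_times[ci]:
                amp = config.spike_amp_mv * float(np.clip(rng.lognormal(0.0, 0.15), 0.6, 1.6))
                i0 = int(round(st * fs_wb))
                if i0 + tmpl.size <= n_wb:
                    data[k, i0 : i0 + tmpl.size] += amp * tmpl
        data[k] += x
    return LaminarRecording(
        data, depths, fs_wb, coupling="DC", meta={"channels": list(chans)}
    )


# ---------------------------------------------------------------------------
# human-style single-channel ECoG


def simulate_human_ecog(
    sd_type: str,
    seed: int,
    fs: float = 200.0,
    fragment_len_s: float = 540.0,
    onset_s: float = 180.0,
    dc_amplitude_mv: float = -20.0,
    suppression: float = 0.1,
    boom_boost: float = 2.2,
    noise_mv: float = 0.008,
):
    """Single-channel DC-ECoG fragment with one SD of a given phenotype.

    The surface signal mixes a surface-negative and a surface-positive delta
    source.  ``depression`` suppresses both during SD, ``no_change`` neither,
    ``boom`` suppresses the negative one and boosts the positive one.
    """
    if sd_type not in ("depression", "no_change", "boom"):
        raise ValueError(f"unknown SD type {sd_type!r}")
    if onset_s < 120.0 or fragment_len_s - onset_s < 60.0 or fragment_len_s < 540.0:
        raise ValueError("fragment must be >= 9 min with SD onset >= 120 s from start")
    rng = np.random.default_rng(seed)
    n = int(round(fragment_len_s * fs))
    t = np.arange(n) / fs
    s_neg, _ = _up_down_source(rng, n, fs)
    s_pos, _ = _up_down_source(rng, n, fs)
    g_neg, g_pos = 0.05, 0.035  # mV, surface-negative / surface-positive weights

    plan = SDPlan(onset_top_s=onset_s, stop_depth_um=1e9, dc_amplitude_mv=min(dc_amplitude_mv, -1e-9))
    sd_win = _window(n, fs, onset_s, onset_s + plan.dc_duration_s)
    m_neg = np.ones(n)
    m_pos = np.ones(n)
    if sd_type == "depression":
        m_neg = 1.0 - (1.0 - suppression) * sd_win
        m_pos = 1.0 - (1.0 - suppression) * sd_win
    elif sd_type == "boom":
        m_neg = 1.0 - (1.0 - suppression) * sd_win
        m_pos = 1.0 + (boom_boost - 1.0) * sd_win

    x = -g_neg * s_neg * m_neg + g_pos * s_pos * m_pos
    if dc_amplitude_mv < 0:
        x = x + dc_amplitude_mv * plan.dc_trace(t - (onset_s - 4.0 * plan.fall_tau_s))
    x = x + noise_mv * rng.standard_normal(n)
    truth = {
        "sd_type": sd_type,
        "onset_s": onset_s,
        "suppression": suppression,
        "boom_boost": boom_boost,
        "dc_amplitude_mv": dc_amplitude_mv,
    }
    return ECoGRecording(x, fs=fs, meta={"seed": seed, "sd_type": sd_type}), truth


# ---------------------------------------------------------------------------
# intracellular


def simulate_intracellular(
    rec: LaminarRecording,
    truth: GroundTruth,
    cell_depth_um: float,
    cell_class: str = "RS",
    seed: int = 0,
    fs: float = 5000.0,
    rest_mv: float = -65.0,
    peak_block_mv: float = -26.0,
    block_threshold_mv: float = -36.0,
    subsd_em_mv: float = -47.0,
    up_amp_mv: float = 8.0,
    sd_up_suppression: float = 0.5,
    ap_amp_mv: float = 60.0,
    noise_mv: float = 0.2,
):
    """Membrane-potential trace of a neuron at ``cell_depth_um``.

    If the session's SD invades the cell depth the cell ramps toward
    ``peak_block_mv`` and APs cease when Em crosses the planted block
    threshold; within ``subsd_zone_um`` below the stop depth the cell
    plateaus near ``subsd_em_mv`` with sustained gamma-locked firing; far
    below, the membrane potential barely changes.  The recorded trace is
    Em + local FP, so field-subtraction correction is testable.
    """
    if cell_class not in ("RS", "IB", "FS"):
        raise ValueError(f"unknown cell class {cell_class!r}")
    depths = rec.depths_um
    if not (depths[0] - 200 <= cell_depth_um <= depths[-1] + 200):
        raise ValueError("cell depth outside the cortical span")
    rng = np.random.default_rng(seed)
    n = int(round(rec.duration_s * fs))
    t = np.arange(n) / fs
    nearest = rec.channel_at_depth(cell_depth_um)
    fp = np.interp(t, rec.times - rec.t0, rec.data[nearest])

    # baseline: rest + UP depolarizations locked to the deep delta generator
    deep_delta = [g.name for g in truth.generators if g.source_kind == "delta_updown"]
    up_src = deep_delta[-1] if deep_delta else None
    ups = truth.up_times.get(up_src, np.asarray([])) if up_src else np.asarray([])
    em = np.full(n, rest_mv)
    up_env = np.zeros(n)
    for ut in ups:
        up_env += np.exp(-(((t - ut) / 0.08) ** 2))
    up_scale = np.ones(n)

    info = {
        "cell_depth_um": cell_depth_um,
        "nearest_channel": nearest,
        "zone": "no_sd",
        "block_threshold_mv": None,
        "peak_em_mv": rest_mv,
        "ap_times": np.asarray([]),
        "rest_mv": rest_mv,
        "up_times": ups,
        "sd_window": None,
    }

    ap_times = []
    # baseline UP-locked firing
    base_rate = 4.0 * np.clip(up_env, 0, 1.5)
    fire_mask = np.ones(n)

    if truth.sd_plans:
        plan = truth.sd_plans[0]
        top_depth = depths[0]
        rel = cell_depth_um - plan.stop_depth_um
        a_stop = plan.arrival_s(plan.stop_depth_um, top_depth)
        sd_lo = a_stop + 4 * plan.fall_tau_s
        sd_hi = sd_lo + plan.dc_duration_s
        info["sd_window"] = (sd_lo, sd_hi)
        info["distance_to_stop_um"] = rel
        if rel <= 0:
            on = plan.onset_s(cell_depth_um, top_depth)
            info["sd_window"] = (on - 2.0, sd_hi)
            ramp = (peak_block_mv - rest_mv) / (
                1.0 + np.exp(-np.clip((t - (on + 4.0)) / 1.5, -40, 40))
            )
            hold = _window(n, fs, on, sd_hi)
            dep = ramp * _window(n, fs, on - 2.0, sd_hi)
            # exponential recovery after plateau
            after = t > sd_hi
            dep[after] = (peak_block_mv - rest_mv) * np.exp(-(t[after] - sd_hi) / 10.0)
            em = em + dep
            up_scale = 1.0 - 0.95 * hold
            info["zone"] = "invaded"
            info["block_threshold_mv"] = block_threshold_mv
            info["peak_em_mv"] = peak_block_mv
            # burst firing from SD onset until Em crosses the block threshold
            base = rest_mv + dep
            above = (base >= block_threshold_mv) & (t >= on)
            t_cross = t[np.argmax(above)] if above.any() else sd_hi
            info["block_cross_s"] = float(t_cross)
            burst = rng.uniform(on - 1.0, t_cross, size=int(15 * max(t_cross - (on - 1.0), 0)))
            ap_times.extend(np.sort(burst))
            fire_mask *= _smooth_gate(n, fs, t_cross, plan.end_s(top_depth))
        elif rel <= plan.subsd_zone_um:
            dep = (subsd_em_mv - rest_mv) * _window(n, fs, sd_lo, sd_hi)
            em = em + dep
            up_scale = 1.0 - 0.9 * _window(n, fs, sd_lo, sd_hi)
            info["zone"] = "subsd"
            info["peak_em_mv"] = subsd_em_mv
            # sustained gamma-locked firing through the SD above
            w = (t >= sd_lo) & (t <= sd_hi)
            gr = 20.0 * (1.0 - 0.8 * np.cos(2 * np.pi * config_gamma_hz(truth) * t))
            rate = np.where(w, gr, 0.0)
            rmax = rate.max()
            if rmax > 0:
                n_hom = rng.poisson(rmax * t[-1])
                cand = np.sort(rng.uniform(0, t[-1], n_hom))
                keep = rng.uniform(0, 1, n_hom) < rate[
                    np.minimum((cand * fs).astype(int), n - 1)
                ] / rmax
                ap_times.extend(cand[keep])
        else:
            em = em + (-2.0) * _window(n, fs, sd_lo, sd_hi)
            up_scale = 1.0 - (1.0 - sd_up_suppression) * _window(n, fs, sd_lo, sd_hi)
            info["zone"] = "below"
            info["peak_em_mv"] = rest_mv - 0.0

    em = em + up_amp_mv * up_env * up_scale

    # baseline UP-locked APs (thinned Poisson)
    rate = base_rate * fire_mask
    rmax = float(rate.max()) if rate.size else 0.0
    if rmax > 0:
        n_hom = rng.poisson(rmax * t[-1])
        cand = np.sort(rng.uniform(0, t[-1], n_hom))
        keep = rng.uniform(0, 1, n_hom) < rate[np.minimum((cand * fs).astype(int), n - 1)] / rmax
        ap_times.extend(cand[keep])

    ap_times = np.sort(np.asarray(ap_times))
    # enforce a 3 ms refractory period
    if ap_times.size:
        keep = np.ones(ap_times.size, bool)
        last = -np.inf
        for i, at in enumerate(ap_times):
            if at - last < 3e-3:
                keep[i] = False
            else:
                last = at
        ap_times = ap_times[keep]
    info["ap_times"] = ap_times

    ap_wave = np.zeros(n)
    half = int(round(0.4e-3 * fs)) * 4
    tt = (np.arange(2 * half + 1) - half) / fs
    shape = np.exp(-((tt / 0.3e-3) ** 2))
    for at in ap_times:
        i0 = int(round(at * fs)) - half
        lo, hi = max(i0, 0), min(i0 + shape.size, n)
        if hi > lo:
            ap_wave[lo:hi] += ap_amp_mv * shape[lo - i0 : hi - i0]
    em_true = em + ap_wave
    info["em_true"] = em_true
    em_rec = em_true + fp + noise_mv * rng.standard_normal(n)

    trace = IntracellularTrace(
        em_rec,
        fs=fs,
        cell_depth_um=cell_depth_um,
        nearest_channel=nearest,
        meta={"cell_class": cell_class, "seed": seed},
    )
    return trace, info


def config_gamma_hz(truth: GroundTruth) -> float:
    return 60.0
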