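"""Multi-unit spike detection, laminar zone mapping and gamma phase coupling.

Spikes are negative peaks of the 250-4000 Hz wavelet-filtered (stationary
db4 decomposition) wideband trace exceeding 4x the STD of the quietest
100 s control fragment.  Because electrical tissue resistance rises during
an SD, the noise floor rises with it; during each SD the threshold adapts:

    thr(t) = 4 * STD_hi(t) * [ STD_band(control) / STD_hi(control) ]

where STD_hi is the STD of the >4 kHz reference band on a 10 s sliding
window.  The reference band falls back to the top octave below Nyquist for
desk-scale sampling rates at or below 8 kHz.

Zone mapping pools per-channel delta-power, gamma-power and MUA changes
across SDs, aligned on depth relative to the SD stop depth, and assigns the
three vertical zones (depressed / sub-SD excited / unchanged) from the MUA
and gamma signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .signal_model import LaminarRecording, filter_trace

__all__ = [
    "SpikeTrain",
    "ZoneProfile",
    "wavelet_bandpass",
    "detect_spikes",
    "mua_change",
    "burst_duration",
    "zone_profile",
    "gamma_phase_coupling",
    "rayleigh_test",
    "circular_mean",
]


@dataclass
class SpikeTrain:
    """Detected (or planted) spikes on one channel."""

    channel: int
    spike_times_s: np.ndarray
    threshold_trace: Optional[np.ndarray] = None  # mV, at fs
    fs: Optional[float] = None

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if np.any(np.diff(self.spike_times_s) < 0):
            raise ValueError("spike times must be increasing")

    def rate(self, t_lo: float, t_hi: float) -> float:
        n = np.count_nonzero((self.spike_times_s >= t_lo) & (self.spike_times_s < t_hi))
        return n / (t_hi - t_lo)


@dataclass
class ZoneProfile:
    """Pooled per-relative-depth changes and the three-zone labelling."""

    rel_depth_um: np.ndarray
    delta_change: np.ndarray  # median log2 ratio per bin
    gamma_change: np.ndarray
    mua_ratio: np.ndarray  # median ratio per bin
    p_delta: np.ndarray
    p_gamma: np.ndarray
    p_mua: np.ndarray
    labels: np.ndarray  # str per bin
    subsd_top_um: Optional[float] = None
    subsd_bottom_um: Optional[float] = None
    peak_mua_increase: Optional[float] = None
    excitation_durations_s: np.ndarray = field(default_factory=lambda: np.asarray([]))


def wavelet_bandpass(x: np.ndarray, fs: float, low: float = 250.0, high: float = 4000.0):
    """Stationary db4 wavelet filter: reconstruct detail levels spanning the band."""
    n = x.size
    max_level = int(np.floor(np.log2(fs / (2.0 * low))))
    max_level = max(min(max_level, pywt.swt_max_level(1 << int(np.ceil(np.log2(n)))), 8), 1)
    pad = (-n) % (1 << max_level)
    xp = np.pad(x, (0, pad), mode="reflect") if pad else x
    coeffs = pywt.swt(xp, "db4", level=max_level, trim_approx=False, norm=False)
    # coeffs[k] corresponds to level (max_level - k); level l detail covers
    # roughly fs/2^(l+1) .. fs/2^l
    out = []
    for k, (cA, cD) in enumerate(coeffs):
        level = max_level - k
        f_lo, f_hi = fs / 2 ** (level + 1), fs / 2**level
        mid = 0.5 * (f_lo + f_hi)
        keep = low <= mid <= high
        out.append((np.zeros_like(cA), cD if keep else np.zeros_like(cD)))
    y = pywt.iswt(out, "db4", norm=False)
    return np.asarray(y[:n])


def _sliding_std(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    w = max(int(round(window_s * fs)), 2)
    m2 = uniform_filter1d(x.astype(float) ** 2, size=w, mode="nearest")
    m1 = uniform_filter1d(x.astype(float), size=w, mode="nearest")
    return np.sqrt(np.maximum(m2 - m1**2, 0.0))


def _quietest_fragment_std(x: np.ndarray, fs: float, frag_s: float = 100.0, hop_s: float = 10.0):
    """STD of the minimum-RMS ``frag_s`` sliding window (``hop_s`` hop)."""
    n_frag = int(frag_s * fs)
    if x.size < n_frag:
        raise ValueError("control epoch shorter than the 100 s quiet-fragment window")
    hop = max(int(hop_s * fs), 1)
    starts = np.arange(0, x.size - n_frag + 1, hop)
    rms = np.array([np.sqrt(np.mean(x[s : s + n_frag] ** 2)) for s in starts])
    s0 = starts[int(np.argmin(rms))]
    return float(x[s0 : s0 + n_frag].std())


def detect_spikes(
    rec,
    control_epoch_s: Tuple[float, float],
    sd_windows_s: Optional[Sequence[Tuple[float, float]]] = None,
    channel: int = 0,
    n_std: float = 4.0,
    dead_time_s: float = 1e-3,
    adaptive: bool = True,
) -> SpikeTrain:
    """Detect multi-unit spikes on one wideband channel.

    ``rec`` is a wideband :class:`LaminarRecording` (or a 1-D array wrapped
    in one).  ``control_epoch_s`` must span at least 100 s before the first
    SD.  ``sd_windows_s`` lists (start, end) intervals where the adaptive
    threshold replaces the fixed one.
    """
    x = rec.data[channel] if isinstance(rec, LaminarRecording) else np.asarray(rec, float)
    fs = rec.fs
    lo, hi = control_epoch_s
    if hi - lo < 100.0:
        raise ValueError("control epoch must be at least 100 s")
    band_hi = min(4000.0, 0.45 * fs)
    xb = wavelet_bandpass(x, fs, 250.0, band_hi)
    ctrl = xb[int(lo * fs) : int(hi * fs)]
    sigma_band = _quietest_fragment_std(ctrl, fs)
    thr = np.full(x.size, n_std * sigma_band)

    if adaptive and sd_windows_s:
        if fs > 8000.0:
            ref_lo = 4000.0
        else:
            ref_lo = fs / 4.0  # top octave below Nyquist fallback
        xh = filter_trace(x, fs, ref_lo, fs / 2.0)
        sigma_hi_ctrl = float(xh[int(lo * fs) : int(hi * fs)].std())
        mult = sigma_band / sigma_hi_ctrl
        sig_hi = _sliding_std(xh, fs, 10.0)
        for w_lo, w_hi in sd_windows_s:
            i0, i1 = max(int(w_lo * fs), 0), min(int(w_hi * fs), x.size)
            thr[i0:i1] = n_std * sig_hi[i0:i1] * mult

    peaks, _ = sps.find_peaks(-xb, distance=max(int(dead_time_s * fs), 1))
    keep = -xb[peaks] > thr[peaks]
    times = peaks[keep] / fs + rec.t0
    ch = rec.meta.get("channels", [channel])[channel] if isinstance(rec, LaminarRecording) else channel
    return SpikeTrain(channel=int(ch), spike_times_s=times, threshold_trace=thr, fs=fs)


def mua_change(
    spiketrains: Sequence[SpikeTrain],
    earliest_onset_s: float,
    deepest_onset_s: float,
    pre_window=(-25.0, -10.0),
    sd_window=(0.0, 15.0),
    bin_s: float = 1.0,
):
    """Per-channel MUA SD/pre ratio and signed-rank significance.

    Pre rates are taken at ``pre_window`` relative to the earliest SD onset,
    SD rates at ``sd_window`` relative to the deepest onset.  Returns a
    DataFrame with columns channel, pre_rate, sd_rate, ratio, p.
    """
    rows = []
    pre_lo, pre_hi = earliest_onset_s + pre_window[0], earliest_onset_s + pre_window[1]
    sd_lo, sd_hi = deepest_onset_s + sd_window[0], deepest_onset_s + sd_window[1]
    nbins = int(min(pre_hi - pre_lo, sd_hi - sd_lo) / bin_s)
    for st in spiketrains:
        pre_counts = np.histogram(
            st.spike_times_s, bins=nbins, range=(pre_lo, pre_lo + nbins * bin_s)
        )[0]
        sd_counts = np.histogram(
            st.spike_times_s, bins=nbins, range=(sd_lo, sd_lo + nbins * bin_s)
        )[0]
        pre_rate = pre_counts.mean() / bin_s
        sd_rate = sd_counts.mean() / bin_s
        if pre_rate == 0:
            rows.append((st.channel, 0.0, sd_rate, np.nan, np.nan))
            continue
        diff = sd_counts - pre_counts
        p = 1.0 if not diff.any() else float(stats.wilcoxon(diff).pvalue)
        rows.append((st.channel, pre_rate, sd_rate, sd_rate / pre_rate, p))
    return pd.DataFrame(rows, columns=["channel", "pre_rate", "sd_rate", "ratio", "p"])


def burst_duration(
    spiketrain: SpikeTrain,
    control_epoch_s: Tuple[float, float],
    sd_window_s: Optional[Tuple[float, float]] = None,
    bin_s: float = 0.1,
    n_std: float = 3.0,
) -> float:
    """Total time (s) the MUA rate exceeds control mean + 3 STD.

    The rate function uses 100 ms bins with 3-bin smoothing; the excursion
    time is evaluated inside ``sd_window_s`` (whole record if omitted).
    """
    lo, hi = control_epoch_s
    if hi - lo < 60.0:
        raise ValueError("control epoch must be at least 60 s")
    t = spiketrain.spike_times_s
    if t.size == 0:
        return 0.0
    t_end = max(t.max(), hi, sd_window_s[1] if sd_window_s else 0.0)
    edges = np.arange(0.0, t_end + bin_s, bin_s)
    rate = np.histogram(t, bins=edges)[0] / bin_s
    rate = uniform_filter1d(rate.astype(float), size=3, mode="nearest")
    centers = edges[:-1] + bin_s / 2
    ctrl = rate[(centers >= lo) & (centers < hi)]
    thr = ctrl.mean() + n_std * ctrl.std()
    sel = np.ones(centers.size, bool)
    if sd_window_s is not None:
        sel = (centers >= sd_window_s[0]) & (centers < sd_window_s[1])
    return float(np.count_nonzero((rate > thr) & sel) * bin_s)


def zone_profile(
    changes: pd.DataFrame,
    bin_um: float = 100.0,
    alpha: float = 0.05,
    min_events: int = 6,  # the two-sided signed-rank needs n >= 6 to reach 0.05
    excitation_durations_s: Optional[np.ndarray] = None,
) -> ZoneProfile:
    """Three-zone laminar map pooled across SDs.

    ``changes`` holds one row per (SD, channel) with columns
    ``rel_depth_um`` (channel depth minus SD stop depth), ``delta_ratio``,
    ``gamma_ratio`` and ``mua_ratio``.  Per relative-depth bin the median
    change and a signed-rank p (log-ratio vs 0) are computed for each
    measure, and labels are assigned by priority: significant MUA decrease
    -> depressed; significant MUA and gamma increase -> subsd_excited;
    otherwise unchanged.
    """
    req = {"rel_depth_um", "delta_ratio", "gamma_ratio", "mua_ratio"}
    if not req <= set(changes.columns):
        raise ValueError(f"changes must have columns {sorted(req)}")
    if changes["rel_depth_um"].isna().all():
        raise ValueError("unbinnable geometry: no relative depths")
    bins = np.round(changes["rel_depth_um"].to_numpy(float) / bin_um) * bin_um
    changes = changes.assign(_bin=bins)
    rows = []
    for b, g in changes.groupby("_bin"):
        if len(g) < min_events:
            continue
        med, pvals = {}, {}
        for col in ("delta_ratio", "gamma_ratio", "mua_ratio"):
            r = g[col].to_numpy(float)
            # a zero ratio (e.g. fully silenced MUA) is strong evidence of
            # depression, not missing data: clip rather than drop
            r = np.clip(r[np.isfinite(r)], 1e-6, None)
            if r.size < min_events:
                med[col], pvals[col] = np.nan, np.nan
                continue
            logr = np.log2(r)
            med[col] = float(np.median(r))
            pvals[col] = 1.0 if np.allclose(logr, 0) else float(stats.wilcoxon(logr).pvalue)
        rows.append((b, med, pvals))
    rows.sort()
    rel = np.array([r[0] for r in rows])
    med_d = np.array([r[1]["delta_ratio"] for r in rows])
    med_g = np.array([r[1]["gamma_ratio"] for r in rows])
    med_m = np.array([r[1]["mua_ratio"] for r in rows])
    p_d = np.array([r[2]["delta_ratio"] for r in rows])
    p_g = np.array([r[2]["gamma_ratio"] for r in rows])
    p_m = np.array([r[2]["mua_ratio"] for r in rows])

    labels = np.full(rel.size, "unchanged", dtype=object)
    for i in range(rel.size):
        if np.isfinite(p_m[i]) and p_m[i] <= alpha and med_m[i] < 1.0:
            labels[i] = "depressed"
        elif (
            np.isfinite(p_m[i])
            and p_m[i] <= alpha
            and med_m[i] > 1.0
            and np.isfinite(p_g[i])
            and p_g[i] <= alpha
            and med_g[i] > 1.0
        ):
            labels[i] = "subsd_excited"

    exc = np.nonzero(labels == "subsd_excited")[0]
    top = bottom = peak = None
    if exc.size:
        top = float(rel[exc.min()] - bin_um)
        bottom = float(rel[exc.max()])
        peak = float(np.nanmax(med_m[exc]))
    return ZoneProfile(
        rel_depth_um=rel,
        delta_change=np.log2(med_d),
        gamma_change=np.log2(med_g),
        mua_ratio=med_m,
        p_delta=p_d,
        p_gamma=p_g,
        p_mua=p_m,
        labels=labels,
        subsd_top_um=top,
        subsd_bottom_um=bottom,
        peak_mua_increase=peak,
        excitation_durations_s=(
            np.asarray(excitation_durations_s) if excitation_durations_s is not None else np.asarray([])
        ),
    )


# ---------------------------------------------------------------------------
# circular statistics


def circular_mean(phases: np.ndarray) -> Tuple[float, float]:
    """Mean direction (rad) and resultant length of a phase sample."""
    z = np.exp(1j * np.asarray(phases, float)).mean()
    return float(np.angle(z)), float(np.abs(z))


def rayleigh_test(phases: np.ndarray) -> float:
    """Rayleigh test p-value for non-uniformity of circular data.

    Uses the standard finite-n approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)) with Rn = n * R.
    """
    phases = np.asarray(phases, float)
    n = phases.size
    _, r = circular_mean(phases)
    rn = n * r
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - rn**2)) - (1.0 + 2.0 * n))
    return float(min(p, 1.0))


def gamma_phase_coupling(
    spike_times_s: np.ndarray,
    rec: LaminarRecording,
    channel: int,
    band: Tuple[float, float] = (30.0, 150.0),
) -> dict:
    """Spike phases w.r.t. the gamma-band analytic signal of one LFP channel.

    Returns spike phases, the circular mean direction, resultant length and
    the Rayleigh p (statistics omitted below 10 spikes).  Phase 0 is the
    gamma peak; +-pi is the trough.
    """
    spike_times_s = np.asarray(spike_times_s, float)
    xf = filter_trace(rec.data[channel], rec.fs, band[0], min(band[1], 0.45 * rec.fs))
    phase = np.angle(sps.hilbert(xf))
    idx = np.clip(((spike_times_s - rec.t0) * rec.fs).round().astype(int), 0, phase.size - 1)
    phases = phase[idx]
    out = {"phases": phases, "n": phases.size}
    if phases.size >= 10:
        mu, r = circular_mean(phases)
        out.update(
            mean_direction=mu, resultant_length=r, rayleigh_p=rayleigh_test(phases)
        )
    return out
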