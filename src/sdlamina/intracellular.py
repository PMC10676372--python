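"""Membrane-potential correction, AP detection and SD depolarization metrics.

During an SD the extracellular potential at the cell's depth shifts by tens
of mV, so the raw pipette potential confounds the transmembrane potential
with the field: the correction subtracts the FP of the probe channel
nearest to the cell.  Slow depolarization metrics (peak Em, depolarization
block threshold) are read from a <0.2 Hz sliding-median filtered Em to
eliminate APs; APs themselves are detected in the 50 Hz highpassed trace as
events exceeding 5 mV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .signal_model import EpochSpec, IntracellularTrace, LaminarRecording, filter_trace

__all__ = [
    "CellSDMetrics",
    "correct_membrane_potential",
    "detect_action_potentials",
    "median_lowpass",
    "depolarization_metrics",
    "ap_burst_durations",
    "up_state_amplitude",
]


@dataclass
class CellSDMetrics:
    """Per-cell, per-SD depolarization summary."""

    peak_em_mv: float
    depol_from_rest_mv: float
    block_threshold_mv: Optional[float]
    ap_burst_durations_s: np.ndarray
    sustained_firing: bool
    distance_to_stop_um: Optional[float]  # cell depth - SD stop depth
    rest_mv: float


def correct_membrane_potential(
    trace: IntracellularTrace, rec: LaminarRecording
) -> IntracellularTrace:
    """Subtract the FP of the nearest probe channel from the recorded Em.

    The FP is resampled (linear interpolation) onto the Em time base; time
    bases misaligned by more than 1 ms raise.
    """
    if abs(trace.t0 - rec.t0) > 1e-3 or trace.n_samples / trace.fs > rec.duration_s + 1e-3:
        raise ValueError("Em and FP time bases misaligned beyond 1 ms")
    ch = (
        trace.nearest_channel
        if trace.nearest_channel is not None
        else rec.channel_at_depth(trace.cell_depth_um)
    )
    fp = np.interp(trace.times, rec.times, rec.data[ch])
    out = IntracellularTrace(
        em=trace.em - fp,
        fs=trace.fs,
        cell_depth_um=trace.cell_depth_um,
        nearest_channel=ch,
        t0=trace.t0,
        junction_corrected=trace.junction_corrected,
        meta={**trace.meta, "fp_corrected": True},
    )
    return out


def detect_action_potentials(
    em: np.ndarray, fs: float, threshold_mv: float = 5.0, dead_time_s: float = 2e-3
) -> np.ndarray:
    """AP peak times: 50 Hz-highpassed events exceeding ``threshold_mv``."""
    if fs < 1000.0:
        raise ValueError("AP detection needs fs >= 1 kHz")
    xf = filter_trace(np.asarray(em, float), fs, 50.0, fs / 2.0)
    peaks, _ = sps.find_peaks(xf, height=threshold_mv, distance=max(int(dead_time_s * fs), 1))
    return peaks / fs


def median_lowpass(em: np.ndarray, fs: float, window_s: float = 5.0) -> np.ndarray:
    """Sliding-median slow trend (window ~ 1/0.2 Hz), AP-immune.

    Computed on a 50 Hz decimated copy and linearly re-interpolated; APs
    (ms-scale) cannot shift a 5 s median.
    """
    em = np.asarray(em, float)
    step = max(int(fs // 50), 1)
    n_blk = em.size // step
    # block medians (not subsampling) so ms-scale APs cannot leak through
    sub = np.median(em[: n_blk * step].reshape(n_blk, step), axis=1)
    w = max(int(round(window_s * fs / step)) | 1, 3)  # odd
    med = pd.Series(sub).rolling(w, center=True, min_periods=1).median().to_numpy()
    t_sub = (np.arange(n_blk) + 0.5) * step / fs
    t = np.arange(em.size) / fs
    return np.interp(t, t_sub, med)


def ap_burst_durations(ap_times_s: np.ndarray, rate_threshold_hz: float = 5.0) -> np.ndarray:
    """Durations of AP bursts: runs whose instantaneous rate (1/ISI) stays
    at or above ``rate_threshold_hz``; duration = last minus first AP."""
    t = np.asarray(ap_times_s, float)
    if t.size < 2:
        return np.asarray([])
    isi = np.diff(t)
    breaks = np.nonzero(isi > 1.0 / rate_threshold_hz)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    durs = t[ends] - t[starts]
    return durs[durs > 0]


def depolarization_metrics(
    em_corr: IntracellularTrace,
    ap_times_s: np.ndarray,
    sd_window_s: Tuple[float, float],
    cell_depth_um: Optional[float] = None,
    stop_depth_um: Optional[float] = None,
    baseline_s: Optional[Tuple[float, float]] = None,
    silence_s: float = 5.0,
    sustained_fraction: float = 0.8,
) -> CellSDMetrics:
    """SD depolarization metrics from the corrected membrane potential.

    ``peak_em`` is the maximum of the median-filtered Em inside the SD
    window.  The depolarization-block threshold is the filtered Em at the
    last AP before a silence of at least ``silence_s`` that begins while Em
    is still rising; it is absent when no such silence occurs.
    ``sustained_firing`` is set when APs span at least 80% of the SD window.
    """
    slow = median_lowpass(em_corr.em, em_corr.fs)
    t = em_corr.times - em_corr.t0
    lo, hi = sd_window_s
    in_sd = (t >= lo) & (t <= hi)
    if not in_sd.any():
        raise ValueError("SD window outside the trace")
    if baseline_s is None:
        baseline_s = (0.0, max(lo - 5.0, 1.0))
    base = slow[(t >= baseline_s[0]) & (t <= baseline_s[1])]
    rest = float(np.median(base))
    peak = float(slow[in_sd].max())

    ap = np.asarray(ap_times_s, float)
    block = None
    if ap.size:
        gaps = np.diff(np.concatenate([ap, [t[-1]]]))
        idx = np.clip((ap * em_corr.fs).astype(int), 0, slow.size - 1)
        dslow = np.gradient(slow, 1.0 / em_corr.fs)
        for i in np.nonzero(gaps >= silence_s)[0]:
            if lo <= ap[i] <= hi and dslow[idx[i]] > 0:
                block = float(slow[idx[i]])
                break
        in_win = ap[(ap >= lo) & (ap <= hi)]
        sustained = in_win.size >= 2 and (in_win[-1] - in_win[0]) >= sustained_fraction * (hi - lo)
    else:
        sustained = False

    dist = None
    if cell_depth_um is not None and stop_depth_um is not None:
        dist = float(cell_depth_um - stop_depth_um)
    return CellSDMetrics(
        peak_em_mv=peak,
        depol_from_rest_mv=peak - rest,
        block_threshold_mv=block,
        ap_burst_durations_s=ap_burst_durations(ap),
        sustained_firing=bool(sustained),
        distance_to_stop_um=dist,
        rest_mv=rest,
    )


def up_state_amplitude(
    em_corr: IntracellularTrace,
    up_times_s: np.ndarray,
    window: EpochSpec = EpochSpec(-0.5, 1.0),
    baseline: Tuple[float, float] = (-0.5, -0.2),
):
    """UP-state-triggered Em amplitude.

    The Em is averaged across triggers over ``window`` and the amplitude is
    the peak depolarization of that average minus its ``baseline`` mean.
    With >= 5 usable triggers returns ``(amplitude, per_event)``; with
    fewer, the amplitude is NaN and per-event values are still returned.
    """
    segs = []
    fs = em_corr.fs
    n_w = int(round(window.duration_s * fs))
    tt = window.start_s + np.arange(n_w) / fs
    in_base = (tt >= baseline[0]) & (tt <= baseline[1])
    for ut in np.asarray(up_times_s, float):
        i0 = int(round((ut + window.start_s - em_corr.t0) * fs))
        if i0 < 0 or i0 + n_w > em_corr.n_samples:
            continue
        segs.append(em_corr.em[i0 : i0 + n_w])
    per = np.asarray([seg.max() - seg[in_base].mean() for seg in segs])
    if len(segs) >= 5:
        avg = np.mean(segs, axis=0)
        amp = float(avg.max() - avg[in_base].mean())
    else:
        amp = float("nan")
    return amp, per
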