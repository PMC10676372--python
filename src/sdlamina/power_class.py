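"""Spectral power around SD onsets and the depression / no-change / boom call.

Power is estimated in 5 s sliding windows with 1 s hop over a 30 s pre-SD
epoch and a 30 s SD epoch.  Human (ECoG) mode uses a Hann periodogram per
window; rat (laminar) mode uses a direct multitaper estimator (5 s window,
half-bandwidth 0.5 Hz -> NW = 2.5, 3 tapers).  The SD/pre-SD power ratio is
the mean of the SD-epoch band powers over the mean of the pre-SD band
powers, and the label is decided by a two-sided Wilcoxon rank-sum test at
alpha = 0.05:

* ``no_change``  iff p > 0.05
* ``depression`` iff p <= 0.05 and ratio < 1
* ``boom``       iff p <= 0.05 and ratio > 1
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal.windows import dpss

from .signal_model import ECoGRecording, EpochSpec, LaminarRecording, epoch_extract

__all__ = [
    "ActivityChange",
    "BANDS",
    "PRE_EPOCH",
    "SD_EPOCH",
    "sliding_band_power",
    "sliding_psd",
    "epoch_power",
    "classify_sd_change",
    "band_ratios",
    "normalized_spectrum",
    "ratio_stopdepth_relation",
]

logger = logging.getLogger(__name__)

#: Analysis bands (Hz): full AC, delta, alpha-beta, gamma, fast.
BANDS: Dict[str, Tuple[float, float]] = {
    "ac": (0.5, 45.0),
    "delta": (0.5, 4.0),
    "alpha_beta": (8.0, 30.0),
    "gamma": (30.0, 45.0),
    "fast": (8.0, 45.0),
}

#: Pre-SD and SD epochs relative to the SD onset, per recording mode.
PRE_EPOCH = {"human": EpochSpec(-120.0, -90.0), "rat": EpochSpec(-40.0, -10.0)}
SD_EPOCH = EpochSpec(10.0, 40.0)

WINDOW_S = 5.0
HOP_S = 1.0
MT_NW = 2.5  # 5 s window x 0.5 Hz half-bandwidth
MT_K = 3


@dataclass
class ActivityChange:
    """Pre/SD power comparison for one SD and one band."""

    band: Tuple[float, float]
    pre_powers: np.ndarray
    sd_powers: np.ndarray
    ratio: float
    p_value: float
    label: str


@lru_cache(maxsize=8)
def _tapers(n: int, nw: float, k: int):
    t = dpss(n, nw, Kmax=k)
    return t


def sliding_psd(x: np.ndarray, fs: float, mode: str = "rat"):
    """Per-window power spectral density; returns ``(freqs, P[window, freq])``.

    ``P`` integrates (sum * df) to the variance contribution per window.
    """
    x = np.asarray(x, dtype=float)
    nwin = int(round(WINDOW_S * fs))
    hop = int(round(HOP_S * fs))
    if x.size < nwin:
        raise ValueError("epoch shorter than the spectral window")
    starts = np.arange(0, x.size - nwin + 1, hop)
    segs = np.stack([x[s : s + nwin] for s in starts])
    segs = segs - segs.mean(axis=1, keepdims=True)
    df = fs / nwin
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    if mode == "human":
        w = np.hanning(nwin)
        scale = 1.0 / (fs * (w**2).sum())
        spec = np.abs(np.fft.rfft(segs * w, axis=1)) ** 2 * scale
    elif mode == "rat":
        tapers = _tapers(nwin, MT_NW, MT_K)
        # (window, taper, freq) -> average over tapers
        tf = np.fft.rfft(segs[:, None, :] * tapers[None, :, :], axis=2)
        spec = (np.abs(tf) ** 2).mean(axis=1) / fs
    else:
        raise ValueError(f"unknown mode {mode!r}")
    spec[:, 1:-1] *= 2.0  # one-sided
    return freqs, spec


def _band_slice(freqs: np.ndarray, band: Tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs <= band[1])


def sliding_band_power(x: np.ndarray, fs: float, band=BANDS["ac"], mode: str = "rat"):
    """Band-integrated power per sliding window (mV^2)."""
    freqs, P = sliding_psd(x, fs, mode=mode)
    df = freqs[1] - freqs[0]
    return P[:, _band_slice(freqs, band)].sum(axis=1) * df


def _epoch_trace(rec, ref_onset_s: float, spec: EpochSpec, channel: int):
    seg = epoch_extract(rec, ref_onset_s, spec)
    if isinstance(seg, LaminarRecording):
        return seg.data[channel]
    return seg.data


def epoch_power(
    rec,
    ref_onset_s: float,
    mode: str = "rat",
    band=BANDS["ac"],
    channel: int = 0,
):
    """Per-window band power in the pre-SD and SD epochs; ``(pre, sd)``."""
    if band[0] < 0.5 or band[1] > 45.0:
        logger.warning("band %s outside the default 0.5-45 Hz analysis range", band)
    pre_trace = _epoch_trace(rec, ref_onset_s, PRE_EPOCH[mode], channel)
    sd_trace = _epoch_trace(rec, ref_onset_s, SD_EPOCH, channel)
    pre = sliding_band_power(pre_trace, rec.fs, band, mode)
    sd = sliding_band_power(sd_trace, rec.fs, band, mode)
    return pre, sd


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum; exact when both n <= 25 and untied."""
    method = "auto"
    if max(len(a), len(b)) <= 25 and np.unique(np.concatenate([a, b])).size == len(a) + len(b):
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def classify_sd_change(pre_powers, sd_powers, alpha: float = 0.05) -> ActivityChange:
    """Depression / no-change / boom classification of one SD."""
    pre = np.asarray(pre_powers, dtype=float)
    sd = np.asarray(sd_powers, dtype=float)
    if len(pre) < 5 or len(sd) < 5:
        raise ValueError("need at least 5 power windows per epoch")
    if not (pre.any() or sd.any()):
        raise ValueError("all-zero powers: nothing to classify")
    ratio = float(sd.mean() / pre.mean())
    p = _rank_sum_p(pre, sd)
    if p > alpha:
        label = "no_change"
    else:
        label = "depression" if ratio < 1.0 else "boom"
    return ActivityChange((np.nan, np.nan), pre, sd, ratio, p, label)


def band_ratios(
    rec,
    ref_onset_s: float,
    mode: str = "rat",
    channel: int = 0,
    bands: Optional[Dict[str, Tuple[float, float]]] = None,
) -> Dict[str, ActivityChange]:
    """Classify one SD in each analysis band (single PSD pass per epoch)."""
    bands = BANDS if bands is None else bands
    pre_trace = _epoch_trace(rec, ref_onset_s, PRE_EPOCH[mode], channel)
    sd_trace = _epoch_trace(rec, ref_onset_s, SD_EPOCH, channel)
    freqs, P_pre = sliding_psd(pre_trace, rec.fs, mode)
    _, P_sd = sliding_psd(sd_trace, rec.fs, mode)
    df = freqs[1] - freqs[0]
    out = {}
    for name, band in bands.items():
        sel = _band_slice(freqs, band)
        pre = P_pre[:, sel].sum(axis=1) * df
        sd = P_sd[:, sel].sum(axis=1) * df
        ac = classify_sd_change(pre, sd)
        ac.band = band
        out[name] = ac
    return out


def normalized_spectrum(items, mode: str = "rat", channel: int = 0):
    """Population SD/pre spectrum ratio with per-frequency signed-rank p.

    ``items`` is a sequence of ``(recording, onset_s)`` pairs (one per SD).
    Returns a dict with the frequency axis, per-SD ratio matrix, the median
    and quartiles across SDs, and per-frequency p-values (omitted when fewer
    than 6 SDs are supplied).
    """
    ratios = []
    freqs = None
    for rec, onset in items:
        pre_trace = _epoch_trace(rec, onset, PRE_EPOCH[mode], channel)
        sd_trace = _epoch_trace(rec, onset, SD_EPOCH, channel)
        freqs, P_pre = sliding_psd(pre_trace, rec.fs, mode)
        _, P_sd = sliding_psd(sd_trace, rec.fs, mode)
        ratios.append(P_sd.mean(axis=0) / P_pre.mean(axis=0))
    ratios = np.asarray(ratios)
    sel = (freqs >= 0.5) & (freqs <= 45.0)
    freqs = freqs[sel]
    ratios = ratios[:, sel]
    out = {
        "freqs": freqs,
        "ratios": ratios,
        "median": np.median(ratios, axis=0),
        "q1": np.percentile(ratios, 25, axis=0),
        "q3": np.percentile(ratios, 75, axis=0),
        "p": None,
    }
    if ratios.shape[0] >= 6:
        logr = np.log(ratios)
        p = np.ones(freqs.size)
        for i in range(freqs.size):
            if np.allclose(logr[:, i], 0):
                p[i] = 1.0
            else:
                p[i] = stats.wilcoxon(logr[:, i]).pvalue
        out["p"] = p
    return out


def ratio_stopdepth_relation(
    events: pd.DataFrame, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Relationship between SD stop depth and top-channel power ratio.

    ``events`` needs columns ``stop_depth_um``, ``ratio`` (AC band, top
    channel) and ``label``; optional ``ratio_delta`` / ``ratio_fast`` enable
    the band comparison.  Returns Spearman R with exact p, a permutation p,
    the Kruskal-Wallis p of stop depths across labels, and (when the band
    columns are present) per-band Spearman Rs and a per-depth rank-sum p
    between delta and fast ratios.
    """
    if len(events) < 10:
        raise ValueError("need at least 10 SD events")
    stops = events["stop_depth_um"].to_numpy(float)
    ratios = events["ratio"].to_numpy(float)
    if np.unique(stops).size < 3:
        raise ValueError("need at least 3 distinct stop depths")
    out: dict = {}
    if np.allclose(ratios, ratios[0]):
        out["spearman_r"] = np.nan
        out["spearman_p"] = np.nan
        out["undefined"] = True
        return out
    r, p = stats.spearmanr(stops, ratios)
    out["spearman_r"], out["spearman_p"] = float(r), float(p)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stats.spearmanr(stops, rng.permutation(ratios)).statistic
    out["perm_p"] = float((np.abs(null) >= abs(r)).mean())
    groups = [g["stop_depth_um"].to_numpy(float) for _, g in events.groupby("label")]
    if len(groups) >= 2:
        out["kruskal_p"] = float(stats.kruskal(*groups).pvalue)
    if {"ratio_delta", "ratio_fast"} <= set(events.columns):
        out["spearman_r_delta"] = float(
            stats.spearmanr(stops, events["ratio_delta"]).statistic
        )
        out["spearman_r_fast"] = float(
            stats.spearmanr(stops, events["ratio_fast"]).statistic
        )
        by_depth = {}
        for depth, g in events.groupby("stop_depth_um"):
            if len(g) >= 3:
                by_depth[float(depth)] = _rank_sum_p(
                    g["ratio_delta"].to_numpy(float), g["ratio_fast"].to_numpy(float)
                )
        out["delta_vs_fast_p_by_depth"] = by_depth
    return out
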