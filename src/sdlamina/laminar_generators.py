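"""CSD, UP-state / gamma-trough detection, and ICA generator decomposition.

The laminar FP is modelled as a weighted sum of N spatially fixed
generators, u_m(t) = sum_n V_mn s_n(t).  The decomposition recovers the
mixing profiles V and time courses s by PCA reduction (5-6 components)
followed by ICA, after removing the DC/infraslow content by subtracting a
0.6 s moving-average replica of the signal.  Components carrying less than
1% of total variance are discarded.  Sign/scale ambiguity is fixed by
storing unit-norm profiles whose largest-magnitude weight is positive.

CSD is the second spatial difference along the probe smoothed across depth
with a triangular kernel (1, 2, 1)/4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d
from sklearn.decomposition import FastICA

from .signal_model import LaminarRecording, filter_trace

__all__ = [
    "CSDMap",
    "GeneratorDecomposition",
    "compute_csd",
    "detect_up_states",
    "detect_gamma_troughs",
    "decompose_generators",
    "generator_power_change",
    "align_profiles",
]


@dataclass
class CSDMap:
    """Current source density over interior channels, mV/um^2 (unscaled)."""

    csd: np.ndarray  # (channels - 2, samples)
    depths_um: np.ndarray
    spacing_um: float
    fs: float


@dataclass
class GeneratorDecomposition:
    """ICA generator decomposition: profiles (channels x N) and sources (N x T)."""

    profiles: np.ndarray
    sources: np.ndarray
    variance_fraction: np.ndarray
    mean: np.ndarray  # per-channel mean removed before decomposition
    fs: float
    discarded_fraction: float
    residual_fraction: float = float("nan")  # vs the preprocessed data

    @property
    def n_components(self) -> int:
        return self.profiles.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.profiles @ self.sources + self.mean[:, None]


def compute_csd(rec: LaminarRecording) -> CSDMap:
    """Second spatial derivative of the FP, triangular-smoothed across depth."""
    if rec.n_channels < 3:
        raise ValueError("CSD requires at least 3 channels")
    h = rec.spacing_um  # raises on non-uniform spacing
    u = rec.data
    d2 = (u[:-2] - 2.0 * u[1:-1] + u[2:]) / h**2
    # triangular kernel (1,2,1)/4 across depth, edge-replicated so a
    # depth-constant CSD is preserved
    padded = np.concatenate([d2[:1], d2, d2[-1:]], axis=0)
    csd = (padded[:-2] + 2.0 * padded[1:-1] + padded[2:]) / 4.0
    return CSDMap(csd=csd, depths_um=rec.depths_um[1:-1], spacing_um=h, fs=rec.fs)


def _negative_events(
    x: np.ndarray,
    fs: float,
    band: Tuple[float, float],
    baseline_s: Optional[Tuple[float, float]] = None,
    n_std: float = 1.0,
):
    """Times of negative local extrema below -n_std x STD of the filtered trace."""
    if x.size / fs < 60.0:
        raise ValueError("recording too short (need >= 60 s for the STD estimate)")
    xf = filter_trace(x, fs, band[0], min(band[1], 0.45 * fs))
    if baseline_s is None:
        base = xf
    else:
        lo, hi = baseline_s
        if hi - lo < 30.0:
            raise ValueError("baseline period shorter than 30 s")
        base = xf[int(lo * fs) : int(hi * fs)]
    std = base.std()
    if std == 0:
        return np.asarray([])
    peaks, _ = sps.find_peaks(-xf, height=n_std * std)
    return peaks / fs


def detect_up_states(
    rec: LaminarRecording,
    channel_ref: int = -1,
    baseline_s: Optional[Tuple[float, float]] = None,
    n_std: float = 1.0,
) -> np.ndarray:
    """UP states: negative deflections of the 0.5-4 Hz filtered deep (L6) trace
    exceeding ``n_std`` standard deviations."""
    t = _negative_events(rec.data[channel_ref], rec.fs, (0.5, 4.0), baseline_s, n_std)
    return t + rec.t0


def detect_gamma_troughs(
    rec: LaminarRecording,
    channel: int,
    baseline_s: Optional[Tuple[float, float]] = None,
    n_std: float = 1.0,
) -> np.ndarray:
    """Gamma troughs: negative 30-150 Hz deflections exceeding ``n_std`` STD."""
    t = _negative_events(rec.data[channel], rec.fs, (30.0, 150.0), baseline_s, n_std)
    return t + rec.t0


def _remove_dc_replica(data: np.ndarray, fs: float) -> np.ndarray:
    """Subtract a smooth (0.6 s moving-average) replica of each channel."""
    w = max(int(round(0.6 * fs)), 1)
    return data - uniform_filter1d(data, size=w, axis=1, mode="nearest")


def decompose_generators(
    rec: LaminarRecording,
    epoch_s: Optional[Tuple[float, float]] = None,
    n_pca: int = 5,
    seed: int = 0,
    variance_cutoff: float = 0.01,
    stim_mask_s: Optional[Sequence[Tuple[float, float]]] = None,
    max_retries: int = 3,
) -> GeneratorDecomposition:
    """ICA decomposition of the laminar FP into spatial generators.

    ``epoch_s`` selects the analysis segment (absolute seconds); the paper's
    workflow uses ~160 s epochs containing one SD.  ``stim_mask_s`` excises
    stimulus-evoked intervals before the decomposition.
    """
    data = rec.data
    fs = rec.fs
    if epoch_s is not None:
        lo, hi = epoch_s
        data = data[:, int((lo - rec.t0) * fs) : int((hi - rec.t0) * fs)]
    if data.shape[1] / fs < 60.0:
        raise ValueError("decomposition epoch must be at least 60 s")
    if rec.n_channels < n_pca:
        raise ValueError("need at least n_pca channels")
    data = _remove_dc_replica(data, fs)
    if stim_mask_s:
        keep = np.ones(data.shape[1], dtype=bool)
        for lo, hi in stim_mask_s:
            keep[int(lo * fs) : int(hi * fs)] = False
        data = data[:, keep]
    mean = data.mean(axis=1)
    X = (data - mean[:, None]).T  # samples x channels
    total_var = X.var(axis=0).sum()
    # cap the reduction at the effective rank (degenerate, e.g. rank-1, data)
    eig = np.linalg.eigvalsh(np.cov(X.T))
    if total_var > 0:
        n_pca = min(n_pca, int(np.sum(eig > 1e-10 * eig.max())))
    if total_var == 0 or n_pca < 1:  # silent recording: nothing to separate
        return GeneratorDecomposition(
            profiles=np.zeros((rec.n_channels, 0)),
            sources=np.zeros((0, X.shape[0])),
            variance_fraction=np.zeros(0),
            mean=mean,
            fs=fs,
            discarded_fraction=1.0,
            residual_fraction=0.0,
        )

    last_err = None
    for attempt in range(max_retries):
        ica = FastICA(
            n_components=n_pca,
            whiten="unit-variance",
            random_state=seed + attempt,
            max_iter=1000,
            tol=1e-5,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            S = ica.fit_transform(X)  # samples x n_pca, unit variance
            if not any("did not converge" in str(w.message) for w in caught):
                break
            last_err = caught[-1].message
    else:
        raise RuntimeError(f"ICA failed to converge after {max_retries} seeds: {last_err}")

    A = ica.mixing_  # channels x n_pca
    # variance carried by each component in channel space (sources are
    # independent, so cross terms vanish in expectation)
    comp_var = (A**2).sum(axis=0) * S.var(axis=0)
    frac = comp_var / total_var
    order = np.argsort(frac)[::-1]
    keep = [i for i in order if frac[i] >= variance_cutoff]
    discarded = float(frac[[i for i in order if i not in keep]].sum()) + max(
        0.0, 1.0 - float(frac.sum())
    )

    profiles = A[:, keep].copy()
    sources = S[:, keep].T.copy()
    for j in range(profiles.shape[1]):
        norm = np.linalg.norm(profiles[:, j])
        sgn = np.sign(profiles[np.argmax(np.abs(profiles[:, j])), j]) or 1.0
        profiles[:, j] *= sgn / norm
        sources[j] *= sgn * norm
    residual = float(np.var(X.T - profiles @ sources) * X.shape[1] / total_var)
    return GeneratorDecomposition(
        profiles=profiles,
        sources=sources,
        variance_fraction=frac[keep],
        mean=mean,
        fs=fs,
        discarded_fraction=discarded,
        residual_fraction=residual,
    )


def generator_power_change(
    decomp: GeneratorDecomposition,
    pre_epoch_s: Tuple[float, float],
    sd_epoch_s: Tuple[float, float],
    sd_onset_s: Optional[float] = None,
    guard_s: float = 5.0,
) -> np.ndarray:
    """Per-generator SD/pre power ratio (variance of the source time course).

    Epochs are given in seconds relative to the decomposed segment.  When
    ``sd_onset_s`` is supplied, epochs overlapping +-``guard_s`` around it
    (the high-frequency burst heralding the DC shift) are rejected.
    """
    fs = decomp.fs
    n = decomp.sources.shape[1]
    out = np.empty(decomp.n_components)
    for lo, hi in (pre_epoch_s, sd_epoch_s):
        if not (0 <= lo < hi <= n / fs):
            raise ValueError("epoch outside the decomposed segment")
        if sd_onset_s is not None and lo < sd_onset_s + guard_s and hi > sd_onset_s - guard_s:
            raise ValueError("epoch overlaps the SD rise (+-guard around onset)")
    pre = decomp.sources[:, int(pre_epoch_s[0] * fs) : int(pre_epoch_s[1] * fs)]
    sd = decomp.sources[:, int(sd_epoch_s[0] * fs) : int(sd_epoch_s[1] * fs)]
    return sd.var(axis=1) / pre.var(axis=1)


def group_ratios_by_stop_depth(events, ratio_columns=None):
    """Generator power ratios grouped by SD stop depth.

    ``events`` is a DataFrame with a ``stop_depth_um`` column and one ratio
    column per generator.  SDs are grouped into surface partial (< 1 mm),
    intermediate partial (1-1.5 mm) and full (> 1.5 mm); per generator the
    group medians and a Kruskal-Wallis p across groups are returned.
    """
    import pandas as pd
    from scipy import stats as _st

    if ratio_columns is None:
        ratio_columns = [c for c in events.columns if c != "stop_depth_um"]
    edges = [-np.inf, 1000.0, 1500.0, np.inf]
    labels = ["lt_1mm", "1_to_1.5mm", "gt_1.5mm"]
    grp = pd.cut(events["stop_depth_um"], bins=edges, labels=labels)
    out = {}
    for col in ratio_columns:
        med = {lab: float(events.loc[grp == lab, col].median()) for lab in labels}
        samples = [
            events.loc[grp == lab, col].dropna().to_numpy(float) for lab in labels
        ]
        samples = [s for s in samples if s.size >= 2]
        p = float(_st.kruskal(*samples).pvalue) if len(samples) >= 2 else float("nan")
        out[col] = {"medians": med, "kruskal_p": p}
    return out


def align_profiles(est: np.ndarray, true: np.ndarray):
    """Greedy sign/permutation alignment of estimated to planted profiles.

    Returns ``(perm, corrs)``: for each true profile the matched estimated
    column index and the absolute Pearson correlation.
    """
    n_true = true.shape[1]
    used = set()
    perm = np.full(n_true, -1, dtype=int)
    corrs = np.zeros(n_true)
    c = np.zeros((n_true, est.shape[1]))
    for i in range(n_true):
        for j in range(est.shape[1]):
            if true[:, i].std() == 0 or est[:, j].std() == 0:
                c[i, j] = 0.0  # flat profile: correlation undefined
            else:
                c[i, j] = abs(np.corrcoef(true[:, i], est[:, j])[0, 1])
    c = np.nan_to_num(c)
    for _ in range(min(n_true, est.shape[1])):
        i, j = np.unravel_index(
            np.argmax(np.where(np.isfinite(c), c, -1)), c.shape
        )
        if c[i, j] < 0:
            break
        perm[i] = j
        corrs[i] = c[i, j]
        c[i, :] = -1
        c[:, j] = -1
    return perm, corrs
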