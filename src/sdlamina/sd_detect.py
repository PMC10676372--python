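"""SD onset detection and vertical stop-depth determination.

An SD appears as a slow negative DC shift.  Onsets are localized as peaks
of the first derivative of the slow potential (SD'): the signal is lowpass
filtered (1 Hz, rat mode) or bandpass filtered (0.001-45 Hz, human mode),
differentiated, and local maxima of the *negative-going* rate of change
exceeding a threshold (default 1 mV/s) are taken as candidate onsets.
Candidates below threshold are discarded.  On a laminar probe the SD stop
depth is the depth of the deepest channel whose SD' peak exceeds the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import signal as sps

from .signal_model import ECoGRecording, LaminarRecording, filter_trace

__all__ = ["SDEvent", "sd_prime", "detect_sd_onsets", "determine_stop_depth"]

#: Default refractory period between SDs on one channel (s).  SDs in a
#: cluster are minutes apart; each analysis fragment holds a single SD.
REFRACTORY_S = 120.0
#: Window for merging per-channel candidates into one event (s).
GROUP_WINDOW_S = 60.0


@dataclass
class SDEvent:
    """One detected SD: per-channel onsets and derivative peaks."""

    event_id: int
    onsets_s: Dict[int, float]  # channel -> derivative-peak time (s)
    sdprime_peaks: Dict[int, float]  # channel -> SD' peak (mV/s)
    stop_depth_um: Optional[float] = None
    full_sd: bool = False

    @property
    def earliest_onset_s(self) -> float:
        return min(self.onsets_s.values())

    @property
    def deepest_onset_s(self) -> float:
        return max(self.onsets_s.values())

    @property
    def channels(self):
        return sorted(self.onsets_s)


def sd_prime(x: np.ndarray, fs: float, mode: str = "rat") -> np.ndarray:
    """Negative-going derivative (mV/s) of the slow-filtered trace.

    Positive values correspond to a negative DC shift in progress.  In human
    mode (0.001-45 Hz band at 200 Hz) the central-difference derivative is
    additionally smoothed over 1 s to localize the SD slope: the fall of an
    SD lives below ~0.2 Hz and passes intact, while the derivative of the
    in-band AC activity averages out.
    """
    if mode == "rat":
        xf = filter_trace(x, fs, 0.0, 1.0)
        return -np.gradient(xf, 1.0 / fs, axis=-1)
    if mode == "human":
        xf = filter_trace(x, fs, 0.001, 45.0, order=2)
        d = -np.gradient(xf, 1.0 / fs, axis=-1)
        from scipy.ndimage import uniform_filter1d

        return uniform_filter1d(d, size=max(int(fs), 1), axis=-1, mode="nearest")
    raise ValueError(f"unknown mode {mode!r}")


#: Zero-phase filtering has boundary transients; candidates this close to
#: the record edges are not trusted.
EDGE_GUARD_S = 5.0


def _channel_candidates(d: np.ndarray, fs: float, threshold: float, refractory_s: float):
    peaks, props = sps.find_peaks(d, height=threshold, distance=max(int(refractory_s * fs), 1))
    guard = int(EDGE_GUARD_S * fs)
    keep = (peaks >= guard) & (peaks < d.size - guard)
    return peaks[keep] / fs, props["peak_heights"][keep]


def detect_sd_onsets(
    rec,
    mode: str = "rat",
    threshold_mv_per_s: float = 1.0,
    refractory_s: float = REFRACTORY_S,
    group_window_s: float = GROUP_WINDOW_S,
):
    """Detect SD events; returns a list of :class:`SDEvent`.

    Candidate onsets on each channel are derivative peaks above threshold;
    candidates across channels within ``group_window_s`` of an event's first
    onset are merged into one event.  An empty list is a valid result.
    """
    if isinstance(rec, LaminarRecording):
        if mode == "rat" and rec.coupling != "DC":
            raise ValueError("rat-mode SD detection requires a DC-coupled recording")
        data = rec.data
    elif isinstance(rec, ECoGRecording):
        data = rec.data[None, :]
    else:
        raise TypeError(f"unsupported recording type {type(rec)!r}")
    fs = rec.fs
    if data.shape[-1] / fs < 20.0:
        raise ValueError("recording too short for SD detection")

    d = sd_prime(data, fs, mode=mode)
    cands = []  # (time, channel, peak)
    for ci in range(data.shape[0]):
        times, heights = _channel_candidates(d[ci], fs, threshold_mv_per_s, refractory_s)
        cands.extend((t + rec.t0, ci, h) for t, h in zip(times, heights))
    cands.sort()

    events = []
    for t, ci, h in cands:
        placed = False
        for ev in events:
            if abs(t - ev.earliest_onset_s) <= group_window_s:
                # keep the largest peak per channel (earliest wins on ties)
                if ci not in ev.onsets_s or h > ev.sdprime_peaks[ci]:
                    ev.onsets_s[ci] = t
                    ev.sdprime_peaks[ci] = h
                placed = True
                break
        if not placed:
            events.append(SDEvent(len(events), {ci: t}, {ci: h}))
    for ev in events:
        if isinstance(rec, LaminarRecording):
            determine_stop_depth(ev, rec, threshold_mv_per_s)
    return events


def determine_stop_depth(
    event: SDEvent, rec: LaminarRecording, threshold_mv_per_s: float = 1.0
):
    """Stop depth = depth of the deepest channel with SD' peak > threshold.

    Re-evaluates the SD' peak of every channel inside the event's window so
    that channels missed by the grouping stage are still considered.
    Returns ``(stop_depth_um, invaded_flags)`` and updates the event.
    """
    if not event.onsets_s:
        raise ValueError("event has no invaded channel")
    t_lo = event.earliest_onset_s - 15.0
    t_hi = event.deepest_onset_s + 15.0
    i0 = max(int((t_lo - rec.t0) * rec.fs), 0)
    i1 = min(int((t_hi - rec.t0) * rec.fs), rec.n_samples)
    d = sd_prime(rec.data, rec.fs, mode="rat")[:, i0:i1]
    peaks = d.max(axis=1)
    invaded = peaks > threshold_mv_per_s
    if not invaded.any():
        raise ValueError("no channel exceeds the SD' threshold in the event window")
    for ci in np.nonzero(invaded)[0]:
        event.sdprime_peaks.setdefault(int(ci), float(peaks[ci]))
        if int(ci) not in event.onsets_s:
            event.onsets_s[int(ci)] = rec.t0 + (i0 + int(np.argmax(d[ci]))) / rec.fs
    # drop channels that do not pass the threshold on re-evaluation
    for ci in list(event.onsets_s):
        if not invaded[ci]:
            del event.onsets_s[ci]
            del event.sdprime_peaks[ci]
    stop = float(rec.depths_um[np.nonzero(invaded)[0].max()])
    event.stop_depth_um = stop
    event.full_sd = bool(invaded[-1])
    return stop, invaded
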