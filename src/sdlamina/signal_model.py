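"""Core containers and signal primitives for laminar SD analysis.

Recordings are held in plain dataclasses: a multichannel DC-coupled laminar
field potential (:class:`LaminarRecording`), a single-channel clinical ECoG
fragment (:class:`ECoGRecording`) and a whole-cell membrane-potential trace
(:class:`IntracellularTrace`).  All times are seconds, voltages millivolts,
positive polarity up; probe depths are micrometres below the pia, positive
downward, with channel index increasing with depth.

Filtering uses zero-phase (forward-backward) 4th-order Butterworth sections
throughout: the downstream analyses (derivative-based SD onset detection,
triggered averaging, Hilbert phase) all require phase-preserving filters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EpochSpec",
    "LaminarRecording",
    "ECoGRecording",
    "IntracellularTrace",
    "filter_trace",
    "bandpass_filter",
    "epoch_extract",
    "triggered_average",
    "save_recording",
    "load_recording",
    "save_events_csv",
    "load_events_csv",
    "EVENT_TABLE_COLUMNS",
]

#: Schema of the on-disk SD event table.
EVENT_TABLE_COLUMNS = [
    "event_id",
    "channel",
    "onset_s",
    "sdprime_peak_mv_per_s",
    "stop_depth_um",
    "label",
    "p_value",
    "ratio",
]


@dataclass(frozen=True)
class EpochSpec:
    """Time window relative to a reference event, ``[start_s, end_s)`` seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"EpochSpec requires end > start, got {self}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _validate_common(fs: float, data: np.ndarray) -> None:
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if not np.isfinite(data).all():
        raise ValueError("recording contains non-finite samples")


@dataclass
class LaminarRecording:
    """Multichannel laminar field potential (channels x samples, mV).

    ``depths_um`` must be strictly increasing (channel 1 shallowest).  DC
    coupling means the absolute slow potential is carried, so the large
    negative SD shifts (tens of mV) are representable.
    """

    data: np.ndarray
    depths_um: np.ndarray
    fs: float
    t0: float = 0.0
    coupling: str = "DC"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.depths_um.ndim != 1 or len(self.depths_um) != self.data.shape[0]:
            raise ValueError("depths_um length must equal channel count")
        if np.any(np.diff(self.depths_um) <= 0):
            raise ValueError("depths_um must be strictly increasing")
        if self.coupling not in ("DC", "AC"):
            raise ValueError(f"coupling must be 'DC' or 'AC', got {self.coupling!r}")
        _validate_common(self.fs, self.data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def spacing_um(self) -> float:
        d = np.diff(self.depths_um)
        if not np.allclose(d, d[0]):
            raise ValueError("non-uniform electrode spacing")
        return float(d[0])

    def copy(self, data: Optional[np.ndarray] = None, **changes) -> "LaminarRecording":
        if data is not None:
            changes["data"] = data
        return dataclasses.replace(self, **{"meta": dict(self.meta), **changes})

    def channel_at_depth(self, depth_um: float) -> int:
        """Index of the channel nearest ``depth_um`` (ties -> shallower)."""
        d = np.abs(self.depths_um - depth_um)
        return int(np.argmin(d))  # argmin returns first (shallower) on ties


@dataclass
class ECoGRecording:
    """Single-channel subdural ECoG fragment (mV), nominally 200 Hz / 9 min."""

    data: np.ndarray
    fs: float = 200.0
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("ECoG recording must be single channel (1-D)")
        _validate_common(self.fs, self.data)

    @property
    def n_samples(self) -> int:
        return self.data.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self, data: Optional[np.ndarray] = None, **changes) -> "ECoGRecording":
        if data is not None:
            changes["data"] = data
        return dataclasses.replace(self, **{"meta": dict(self.meta), **changes})


@dataclass
class IntracellularTrace:
    """Whole-cell membrane potential (mV), junction-corrected (+15 mV applied)."""

    em: np.ndarray
    fs: float
    cell_depth_um: float
    nearest_channel: Optional[int] = None
    t0: float = 0.0
    junction_corrected: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.em = np.asarray(self.em, dtype=float)
        if self.em.ndim != 1:
            raise ValueError("membrane potential trace must be 1-D")
        _validate_common(self.fs, self.em)

    @property
    def n_samples(self) -> int:
        return self.em.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


# ---------------------------------------------------------------------------
# filtering


def _design_sos(low_hz: float, high_hz: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not (0 <= low_hz < high_hz <= nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz outside [0, Nyquist={nyq}] or inverted"
        )
    if low_hz <= 0 and high_hz >= nyq:
        raise ValueError("band covers the whole spectrum; nothing to filter")
    if low_hz <= 0:
        return signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    if high_hz >= nyq:
        return signal.butter(order, low_hz, btype="highpass", fs=fs, output="sos")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def filter_trace(
    x: np.ndarray,
    fs: float,
    low_hz: float,
    high_hz: float,
    zero_phase: bool = True,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Butterworth band/low/highpass of an array along ``axis``.

    ``low_hz = 0`` means lowpass, ``high_hz >= fs/2`` means highpass.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite samples")
    sos = _design_sos(low_hz, high_hz, fs, order=order)
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=axis)
    return signal.sosfilt(sos, x, axis=axis)


def bandpass_filter(rec, low_hz: float, high_hz: float, zero_phase: bool = True, order: int = 4):
    """Filtered copy of a recording; shape and metadata preserved."""
    if isinstance(rec, LaminarRecording):
        out = filter_trace(rec.data, rec.fs, low_hz, high_hz, zero_phase, order, axis=1)
        new = rec.copy(data=out)
    elif isinstance(rec, (ECoGRecording,)):
        out = filter_trace(rec.data, rec.fs, low_hz, high_hz, zero_phase, order)
        new = rec.copy(data=out)
    elif isinstance(rec, IntracellularTrace):
        out = filter_trace(rec.em, rec.fs, low_hz, high_hz, zero_phase, order)
        new = dataclasses.replace(rec, em=out, meta=dict(rec.meta))
    else:
        raise TypeError(f"unsupported recording type {type(rec)!r}")
    new.meta["filter"] = {
        "low_hz": low_hz,
        "high_hz": high_hz,
        "zero_phase": zero_phase,
        "order": order,
    }
    return new


# ---------------------------------------------------------------------------
# epoching


def _rec_array(rec) -> np.ndarray:
    if isinstance(rec, LaminarRecording):
        return rec.data
    if isinstance(rec, ECoGRecording):
        return rec.data
    if isinstance(rec, IntracellularTrace):
        return rec.em
    raise TypeError(f"unsupported recording type {type(rec)!r}")


def _epoch_indices(rec, ref_time_s: float, spec: EpochSpec):
    n = _rec_array(rec).shape[-1]
    i0 = int(round((ref_time_s + spec.start_s - rec.t0) * rec.fs))
    length = int(round(spec.duration_s * rec.fs))
    if i0 < 0 or i0 + length > n:
        raise ValueError(
            f"epoch [{ref_time_s + spec.start_s}, {ref_time_s + spec.end_s}] s "
            f"exceeds record bounds [{rec.t0}, {rec.t0 + n / rec.fs}] s"
        )
    return i0, length


def epoch_extract(rec, ref_time_s: float, spec: EpochSpec):
    """Extract the segment ``[ref + start, ref + end)``; errors if out of range."""
    i0, length = _epoch_indices(rec, ref_time_s, spec)
    arr = _rec_array(rec)
    seg = arr[..., i0 : i0 + length].copy()
    t0 = rec.t0 + i0 / rec.fs
    if isinstance(rec, IntracellularTrace):
        new = dataclasses.replace(rec, em=seg, t0=t0, meta=dict(rec.meta))
    else:
        new = rec.copy(data=seg, t0=t0)
    new.meta["epoch"] = {"ref_time_s": ref_time_s, "start_s": spec.start_s, "end_s": spec.end_s}
    return new


def triggered_average(rec, trigger_times, window: EpochSpec):
    """Average the recording around each trigger; returns ``(avg, n_used)``.

    Triggers whose window falls outside the record are dropped; raises if no
    trigger is usable.
    """
    arr = _rec_array(rec)
    segs = []
    for t in np.asarray(trigger_times, dtype=float):
        try:
            i0, length = _epoch_indices(rec, float(t), window)
        except ValueError:
            continue
        segs.append(arr[..., i0 : i0 + length])
    if not segs:
        raise ValueError("no trigger with a full window inside the record")
    avg = np.mean(np.stack(segs, axis=0), axis=0)
    return avg, len(segs)


# ---------------------------------------------------------------------------
# on-disk container (HDF5) and event tables (CSV)


def save_recording(path, rec) -> None:
    """Write a recording to an HDF5 container (/data, /depths_um, attrs)."""
    with h5py.File(path, "w") as f:
        if isinstance(rec, LaminarRecording):
            f.create_dataset("data", data=rec.data.astype(np.float32))
            f.create_dataset("depths_um", data=rec.depths_um.astype(np.float32))
            f.attrs["kind"] = "laminar"
        elif isinstance(rec, ECoGRecording):
            f.create_dataset("data", data=rec.data.astype(np.float32))
            f.attrs["kind"] = "ecog"
        elif isinstance(rec, IntracellularTrace):
            f.create_dataset("data", data=rec.em.astype(np.float32))
            f.attrs["kind"] = "intracellular"
            f.attrs["cell_depth_um"] = rec.cell_depth_um
            if rec.nearest_channel is not None:
                f.attrs["nearest_channel"] = rec.nearest_channel
        else:
            raise TypeError(f"unsupported recording type {type(rec)!r}")
        f.attrs["fs"] = rec.fs
        f.attrs["t0"] = rec.t0
        f.attrs["coupling"] = getattr(rec, "coupling", "DC")


def load_recording(path):
    with h5py.File(path, "r") as f:
        kind = f.attrs.get("kind", "laminar")
        data = np.asarray(f["data"], dtype=float)
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs.get("t0", 0.0))
        if kind == "laminar":
            return LaminarRecording(
                data=data,
                depths_um=np.asarray(f["depths_um"], dtype=float),
                fs=fs,
                t0=t0,
                coupling=str(f.attrs.get("coupling", "DC")),
            )
        if kind == "ecog":
            return ECoGRecording(data=data, fs=fs, t0=t0)
        if kind == "intracellular":
            return IntracellularTrace(
                em=data,
                fs=fs,
                t0=t0,
                cell_depth_um=float(f.attrs["cell_depth_um"]),
                nearest_channel=(
                    int(f.attrs["nearest_channel"]) if "nearest_channel" in f.attrs else None
                ),
            )
    raise ValueError(f"unknown container kind {kind!r}")


def save_events_csv(path, rows) -> None:
    df = pd.DataFrame(list(rows), columns=EVENT_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def load_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
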