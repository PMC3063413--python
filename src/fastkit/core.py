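"""Recording data model with a windowed-access contract.

A :class:`Recording` never holds its sample payload in memory.  Data live
behind a :class:`SampleSource`; :func:`read_window` pulls exactly the
``channels x samples`` block needed for the operation at hand, already
scaled to microvolts.  This is what makes multi-hour, multi-GB continuous
recordings workable on an ordinary machine.

Display-style transforms (rereferencing, bandpass filtering) are pure
functions on blocks: the stored data are never modified.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _sig

from .errors import (
    ChannelNotFoundError,
    ConfigurationError,
    ParameterError,
    WindowBoundsError,
)

__all__ = [
    "ChannelKind",
    "ChannelInfo",
    "Event",
    "SampleSource",
    "ArraySource",
    "BinaryFileSource",
    "Recording",
    "read_window",
    "rereference",
    "bandpass",
    "lowpass",
    "highpass",
    "compute_psd",
    "storage_bytes",
]


class ChannelKind(str, enum.Enum):
    EEG = "EEG"
    EOG = "EOG"
    EMG = "EMG"
    ECG = "ECG"
    OTHER = "OTHER"


@dataclass(frozen=True)
class ChannelInfo:
    """Channel definition: name, type, unit and optional 2D scalp location."""

    name: str
    kind: ChannelKind = ChannelKind.EEG
    unit: str = "uV"
    scale_group: Optional[str] = None
    position2d: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ParameterError("channel name must be nonempty")


@dataclass
class Event:
    """Typed marker with 0-based sample onset and duration in samples."""

    label: str
    onset: int
    duration: int = 0
    payload: object = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ParameterError(f"event onset must be >= 0, got {self.onset}")
        if self.duration < 0:
            raise ParameterError(f"event duration must be >= 0, got {self.duration}")


class SampleSource:
    """Abstract provider of sample blocks, already scaled to microvolts."""

    n_channels: int
    n_samples: int

    def read(self, channel_indices: Sequence[int], start: int, length: int) -> np.ndarray:
        """Return a ``(len(channel_indices), length)`` float64 block in uV."""
        raise NotImplementedError


class ArraySource(SampleSource):
    """In-memory source; used by the synthetic generators and small files."""

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 2:
            raise ParameterError("data must be 2-D (channels x samples)")
        self._data = data
        self.n_channels, self.n_samples = data.shape

    def read(self, channel_indices, start, length):
        idx = np.asarray(list(channel_indices), dtype=np.intp)
        return self._data[idx, start : start + length].copy()


class BinaryFileSource(SampleSource):
    """Raw binary file of sampled frames, read lazily with seek/read.

    ``orientation='multiplexed'`` means frame-major layout (all channels for
    sample t, then t+1); ``'vectorized'`` means channel-major.  Per-channel
    ``resolutions`` convert stored integer counts to microvolts on the fly.
    Only the requested window is ever materialized.
    """

    def __init__(
        self,
        path,
        n_channels: int,
        dtype: str = "<f4",
        orientation: str = "multiplexed",
        resolutions: Optional[Sequence[float]] = None,
        offset: int = 0,
    ):
        import os

        self.path = str(path)
        self.n_channels = int(n_channels)
        self.dtype = np.dtype(dtype)
        if orientation not in ("multiplexed", "vectorized"):
            raise ParameterError(f"unknown orientation {orientation!r}")
        self.orientation = orientation
        self.offset = int(offset)
        if resolutions is None:
            resolutions = np.ones(self.n_channels)
        self.resolutions = np.asarray(resolutions, dtype=np.float64)
        if np.any(self.resolutions <= 0):
            raise ParameterError("channel resolutions must be > 0")
        payload = os.path.getsize(self.path) - self.offset
        frame_bytes = self.dtype.itemsize * self.n_channels
        self.n_samples = payload // frame_bytes

    def read(self, channel_indices, start, length):
        idx = list(channel_indices)
        out = np.empty((len(idx), length), dtype=np.float64)
        if length == 0:
            return out
        item = self.dtype.itemsize
        with open(self.path, "rb") as fh:
            if self.orientation == "multiplexed":
                fh.seek(self.offset + start * self.n_channels * item)
                raw = np.frombuffer(
                    fh.read(length * self.n_channels * item), dtype=self.dtype
                ).reshape(length, self.n_channels)
                for row, ci in enumerate(idx):
                    out[row] = raw[:, ci]
            else:  # vectorized: one contiguous run per channel
                for row, ci in enumerate(idx):
                    fh.seek(self.offset + (ci * self.n_samples + start) * item)
                    out[row] = np.frombuffer(fh.read(length * item), dtype=self.dtype)
        out *= self.resolutions[idx][:, None]
        return out


@dataclass
class Recording:
    """Continuous multichannel recording: header in memory, data on demand."""

    sampling_rate: float
    channels: list[ChannelInfo]
    source: SampleSource
    start_clock_time: Optional[_dt.datetime] = None
    events: list[Event] = field(default_factory=list)
    scores: list = field(default_factory=list)  # list[ScoreSet]
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ParameterError("channel names must be unique")
        if self.source.n_channels != len(self.channels):
            raise ParameterError(
                f"source has {self.source.n_channels} channels, "
                f"header lists {len(self.channels)}"
            )

    @property
    def n_samples(self) -> int:
        return self.source.n_samples

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def end_clock_time(self) -> Optional[_dt.datetime]:
        if self.start_clock_time is None:
            return None
        return self.start_clock_time + _dt.timedelta(seconds=self.duration_s)

    def channel_index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise ChannelNotFoundError(name)

    def channel_info(self, name: str) -> ChannelInfo:
        return self.channels[self.channel_index(name)]

    def with_source(self, source: SampleSource, **updates) -> "Recording":
        """Shallow header copy backed by a new sample source."""
        rec = replace(
            self,
            source=source,
            events=[replace(e) for e in self.events],
            scores=list(self.scores),
            history=list(self.history),
            **updates,
        )
        return rec

    def log(self, entry: str) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        self.history.append(f"{stamp} {entry}")


def read_window(
    rec: Recording, channel_names: Sequence[str], start: int, length: int
) -> np.ndarray:
    """Read a ``(channels x samples)`` block in uV; pure, bounds-checked."""
    if start < 0 or length < 0 or start + length > rec.n_samples:
        raise WindowBoundsError(
            f"window [{start}, {start + length}) outside recording "
            f"of {rec.n_samples} samples"
        )
    indices = [rec.channel_index(n) for n in channel_names]
    return rec.source.read(indices, start, length)


# ---------------------------------------------------------------------------
# on-display transforms (pure; stored data never touched)
# ---------------------------------------------------------------------------

def rereference(
    block: np.ndarray,
    channel_infos: Sequence[ChannelInfo],
    mode: str = "none",
    ref_channel: Optional[str] = None,
    mastoids: tuple[str, str] = ("M1", "M2"),
    bipolar_pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> np.ndarray:
    """Re-express a block against a new reference.

    Modes: ``none``, ``single_channel`` (ref_channel required), ``mean_eeg``
    (mean of all EEG channels), ``mastoids`` (mean of the two mastoid
    channels), ``bipolar`` (declared EOG/EMG anode-cathode pairs; channels
    outside a pair pass through unchanged).  Only EEG channels are
    rereferenced in the scalar-reference modes; other kinds pass through.
    """
    block = np.asarray(block, dtype=np.float64)
    infos = list(channel_infos)
    if block.shape[0] != len(infos):
        raise ParameterError("block row count must match channel_infos")
    names = [c.name for c in infos]
    out = block.copy()

    if mode == "none":
        return out
    if mode == "single_channel":
        if ref_channel is None or ref_channel not in names:
            raise ChannelNotFoundError(ref_channel)
        ref = block[names.index(ref_channel)]
        for i, info in enumerate(infos):
            if info.kind in (ChannelKind.EEG, ChannelKind.EOG, ChannelKind.EMG):
                out[i] = block[i] - ref
        return out
    if mode == "mean_eeg":
        eeg = [i for i, c in enumerate(infos) if c.kind is ChannelKind.EEG]
        if not eeg:
            raise ConfigurationError("mean_eeg reference requires EEG channels")
        ref = block[eeg].mean(axis=0)
        for i in eeg:
            out[i] = block[i] - ref
        return out
    if mode == "mastoids":
        m1, m2 = mastoids
        if m1 not in names or m2 not in names:
            raise ConfigurationError(
                f"mastoid reference needs both {m1!r} and {m2!r}"
            )
        ref = 0.5 * (block[names.index(m1)] + block[names.index(m2)])
        for i, info in enumerate(infos):
            if info.kind is ChannelKind.EEG:
                out[i] = block[i] - ref
        return out
    if mode == "bipolar":
        if not bipolar_pairs:
            raise ConfigurationError("bipolar mode requires declared pairs")
        for anode, cathode in bipolar_pairs:
            if anode not in names or cathode not in names:
                continue  # pair not present in this selection
            ia, ic = names.index(anode), names.index(cathode)
            for i in (ia, ic):
                if infos[i].kind not in (ChannelKind.EOG, ChannelKind.EMG):
                    raise ConfigurationError(
                        f"bipolar pair ({anode},{cathode}) includes "
                        f"non-EOG/EMG channel {infos[i].name!r}"
                    )
            out[ia] = block[ia] - block[ic]
        return out
    raise ParameterError(f"unknown rereference mode {mode!r}")


def _butter_sos(fs: float, low_hz: float, high_hz: float, order: int = 4):
    nyq = fs / 2.0
    if low_hz < 0 or high_hz <= low_hz or high_hz > nyq:
        raise ParameterError(
            f"invalid band [{low_hz}, {high_hz}] Hz at fs={fs} Hz"
        )
    if low_hz == 0 and high_hz >= nyq:
        return None  # all-pass
    if low_hz == 0:
        return _sig.butter(order, high_hz, btype="low", fs=fs, output="sos")
    if high_hz >= nyq:
        return _sig.butter(order, low_hz, btype="high", fs=fs, output="sos")
    return _sig.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")


def bandpass(
    block: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward, order 4).

    ``low_hz == 0`` degenerates to a low-pass, ``high_hz >= fs/2`` to a
    high-pass; both at once is an all-pass (identity).  Zero phase keeps
    peak latencies intact for artefact templates and slow-wave timing.
    """
    block = np.atleast_2d(np.asarray(block, dtype=np.float64))
    sos = _butter_sos(fs, low_hz, high_hz, order)
    if sos is None:
        out = block.copy()
    else:
        out = _sig.sosfiltfilt(sos, block, axis=-1)
    return out


def lowpass(block: np.ndarray, fs: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    return bandpass(block, fs, 0.0, cutoff_hz, order=order)


def highpass(block: np.ndarray, fs: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    return bandpass(block, fs, cutoff_hz, fs / 2.0, order=order)


def compute_psd(
    rec: Recording,
    channel: str,
    start: int = 0,
    length: Optional[int] = None,
    subwindow_s: float = 4.0,
    overlap_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of one channel window, in uV^2/Hz."""
    if length is None:
        length = rec.n_samples - start
    nper = int(round(subwindow_s * rec.sampling_rate))
    if length < nper:
        raise ParameterError(
            f"interval of {length} samples shorter than one "
            f"{subwindow_s} s subwindow"
        )
    if not 0 <= overlap_frac < 1:
        raise ParameterError("overlap_frac must be in [0, 1)")
    x = read_window(rec, [channel], start, length)[0]
    freqs, pxx = _sig.welch(
        x,
        fs=rec.sampling_rate,
        window="hamming",
        nperseg=nper,
        noverlap=int(round(nper * overlap_frac)),
    )
    return freqs, pxx


def storage_bytes(
    n_channels: int, duration_hours: float, fs_hz: float, bytes_per_sample: int = 2
) -> int:
    """Disk footprint of a continuous recording's sample payload."""
    return int(n_channels * duration_hours * 3600 * fs_hz * bytes_per_sample)
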