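"""Whole-recording Welch spectrogram and score-aware band power.

The spectrogram is computed over consecutive outer windows (matching the
scoring window length when scores are present), each estimated by Welch
averaging of overlapping tapered subwindows.  Windows scored as movement
time or flagged as artefacted are left out: their power is set to zero
and they are masked, and all statistics honour the mask.

Band power comes in three scalings: absolute (uV^2), relative (band over
whole-spectrum power at the same instant) and the deep-sleep-normalized
view (band power divided by its mean over deep-sleep windows).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _sig

from .core import Recording, bandpass, read_window
from .errors import ParameterError, StageNotFoundError
from .scoring import STAGE_MOVEMENT, ScoreSet

__all__ = [
    "Spectrogram",
    "spectrogram",
    "band_power",
    "stage_mean_spectrum",
    "save_spectrogram",
    "load_spectrogram",
]

DEEP_SLEEP_STAGES = frozenset({3, 4})


@dataclass
class Spectrogram:
    channel_names: list[str]
    window_centers_s: np.ndarray
    frequencies_hz: np.ndarray
    power: np.ndarray  # channels x windows x frequencies, uV^2/Hz
    window_length_s: float
    subwindow_s: float
    overlap_frac: float
    excluded: np.ndarray = field(default=None)  # bool per window
    excluded_reason: list = field(default_factory=list)  # '' | movement | artefact
    stages: Optional[np.ndarray] = None  # stage code per window, if scored

    def __post_init__(self):
        if self.excluded is None:
            self.excluded = np.zeros(len(self.window_centers_s), dtype=bool)
        if not self.excluded_reason:
            self.excluded_reason = [""] * len(self.window_centers_s)

    @property
    def n_windows(self) -> int:
        return len(self.window_centers_s)


def spectrogram(
    rec: Recording,
    channels: Sequence[str],
    band_hz: Optional[tuple[float, float]] = None,
    window_s: Optional[float] = None,
    subwindow_s: float = 4.0,
    overlap_frac: float = 0.5,
    scores: Optional[ScoreSet] = None,
) -> Spectrogram:
    """Welch spectrogram of a whole recording, optionally score-aware.

    ``window_s`` defaults to the scoring window length when ``scores`` is
    given, else 30 s.  Outer windows overlapping a movement-time stage or
    an artefact flag are zeroed and masked.
    """
    if window_s is None:
        window_s = scores.window_length_s if scores is not None else 30.0
    if window_s < subwindow_s:
        raise ParameterError("window_s must be >= subwindow_s")
    fs = rec.sampling_rate
    win = int(round(window_s * fs))
    nper = int(round(subwindow_s * fs))
    n_windows = rec.n_samples // win
    if n_windows == 0:
        raise ParameterError("recording shorter than one outer window")

    channels = list(channels)
    centers = (np.arange(n_windows) + 0.5) * window_s
    # probe welch once for the actual frequency grid
    freqs, _ = _sig.welch(np.zeros(win), fs=fs, window="hamming", nperseg=nper,
                          noverlap=int(round(nper * overlap_frac)))

    excluded = np.zeros(n_windows, dtype=bool)
    reasons = [""] * n_windows
    stages_per_window = None
    if scores is not None:
        stages_per_window = np.full(n_windows, -1, dtype=np.int64)
        for w in range(n_windows):
            t0, t1 = w * window_s, (w + 1) * window_s
            s0 = int(t0 / scores.window_length_s)
            s1 = max(s0 + 1, int(np.ceil(t1 / scores.window_length_s)))
            s1 = min(s1, scores.n_windows)
            if s0 >= scores.n_windows:
                continue
            seg = scores.stages[s0:s1]
            flg = scores.artefact_flags[s0:s1]
            stages_per_window[w] = seg[0]
            if np.any(seg == STAGE_MOVEMENT):
                excluded[w] = True
                reasons[w] = "movement"
            elif np.any(flg):
                excluded[w] = True
                reasons[w] = "artefact"

    power = np.zeros((len(channels), n_windows, len(freqs)))
    if channels:
        data = read_window(rec, channels, 0, n_windows * win)
        if band_hz is not None:
            data = bandpass(data, fs, band_hz[0], band_hz[1])
        for w in range(n_windows):
            if excluded[w]:
                continue  # power stays zero for excluded windows
            seg = data[:, w * win : (w + 1) * win]
            _, pxx = _sig.welch(
                seg, fs=fs, window="hamming", nperseg=nper,
                noverlap=int(round(nper * overlap_frac)), axis=-1,
            )
            power[:, w, :] = pxx

    return Spectrogram(
        channel_names=channels,
        window_centers_s=centers,
        frequencies_hz=freqs,
        power=power,
        window_length_s=window_s,
        subwindow_s=subwindow_s,
        overlap_frac=overlap_frac,
        excluded=excluded,
        excluded_reason=reasons,
        stages=stages_per_window,
    )


def _band_integral(spec: Spectrogram, band_hz: tuple[float, float]) -> np.ndarray:
    """Rectangle-rule band integral per (channel, window), half-open bins."""
    f = spec.frequencies_hz
    if len(f) < 2:
        raise ParameterError("spectrogram has no frequency resolution")
    df = f[1] - f[0]
    lo, hi = band_hz
    if lo < f[0] - 1e-12 or hi > f[-1] + df + 1e-12:
        raise ParameterError(f"band [{lo}, {hi}] outside computed frequencies")
    mask = (f >= lo) & (f < hi)
    return spec.power[:, :, mask].sum(axis=2) * df


def band_power(
    spec: Spectrogram,
    band_hz: tuple[float, float],
    mode: str = "absolute",
    hypnogram: Optional[ScoreSet] = None,
) -> np.ndarray:
    """Per-window band power (channels x windows); excluded windows are NaN.

    ``mode='mongrain'`` divides by the mean band power over deep-sleep
    (stage 3/4) windows and requires score information.
    """
    vals = _band_integral(spec, band_hz)
    vals = vals.astype(float)
    vals[:, spec.excluded] = np.nan
    if mode == "absolute":
        return vals
    if mode == "relative":
        f = spec.frequencies_hz
        full = _band_integral(spec, (f[0], f[-1] + (f[1] - f[0])))
        full[:, spec.excluded] = np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            return vals / full
    if mode == "mongrain":
        stages = spec.stages
        if stages is None and hypnogram is not None:
            stages = np.array([
                hypnogram.stages[min(int(c / hypnogram.window_length_s),
                                     hypnogram.n_windows - 1)]
                for c in spec.window_centers_s
            ])
        if stages is None:
            raise ParameterError("mongrain scaling requires scores")
        deep = np.isin(stages, list(DEEP_SLEEP_STAGES)) & ~spec.excluded
        if not deep.any():
            raise ParameterError("no deep-sleep (stage 3/4) windows available")
        ref = np.nanmean(vals[:, deep], axis=1, keepdims=True)
        return vals / ref
    raise ParameterError(f"unknown band power mode {mode!r}")


def stage_mean_spectrum(
    spec: Spectrogram,
    hypnogram: ScoreSet,
    stage_code: int,
    channel: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean PSD of one channel over a stage's valid windows."""
    if channel not in spec.channel_names:
        raise ParameterError(f"channel {channel!r} not in spectrogram")
    ci = spec.channel_names.index(channel)
    stages = spec.stages
    if stages is None:
        stages = np.array([
            hypnogram.stages[min(int(c / hypnogram.window_length_s),
                                 hypnogram.n_windows - 1)]
            for c in spec.window_centers_s
        ])
    sel = (stages == stage_code) & ~spec.excluded
    if not sel.any():
        available = sorted(set(int(s) for s in stages[~spec.excluded]))
        raise StageNotFoundError(
            f"no valid windows for stage {stage_code}; available: {available}"
        )
    return spec.frequencies_hz.copy(), spec.power[ci, sel, :].mean(axis=0)


def save_spectrogram(spec: Spectrogram, basename) -> tuple[Path, Path]:
    """Store in the header+binary container layout with a kind tag."""
    base = Path(basename)
    json_path, bin_path = base.with_suffix(".json"), base.with_suffix(".bin")
    with open(bin_path, "wb") as fh:
        fh.write(np.ascontiguousarray(spec.power, dtype="<f4").tobytes())
    header = {
        "format": "fastkit-internal",
        "kind": "spectrogram",
        "channel_names": spec.channel_names,
        "window_centers_s": list(map(float, spec.window_centers_s)),
        "frequencies_hz": list(map(float, spec.frequencies_hz)),
        "shape": list(spec.power.shape),
        "window_length_s": spec.window_length_s,
        "subwindow_s": spec.subwindow_s,
        "overlap_frac": spec.overlap_frac,
        "excluded": [bool(v) for v in spec.excluded],
        "excluded_reason": list(spec.excluded_reason),
        "stages": None if spec.stages is None else [int(v) for v in spec.stages],
        "binary": {"path": bin_path.name, "dtype": "<f4"},
    }
    with open(json_path, "w") as fh:
        json.dump(header, fh, indent=1)
    return json_path, bin_path


def load_spectrogram(basename) -> Spectrogram:
    base = Path(basename)
    json_path = base if base.suffix == ".json" else base.with_suffix(".json")
    with open(json_path) as fh:
        h = json.load(fh)
    bin_path = json_path.parent / h["binary"]["path"]
    power = np.fromfile(bin_path, dtype=h["binary"]["dtype"]).reshape(h["shape"]).astype(float)
    return Spectrogram(
        channel_names=h["channel_names"],
        window_centers_s=np.asarray(h["window_centers_s"]),
        frequencies_hz=np.asarray(h["frequencies_hz"]),
        power=power,
        window_length_s=h["window_length_s"],
        subwindow_s=h["subwindow_s"],
        overlap_frac=h["overlap_frac"],
        excluded=np.asarray(h["excluded"], dtype=bool),
        excluded_reason=list(h["excluded_reason"]),
        stages=None if h["stages"] is None else np.asarray(h["stages"]),
    )
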