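"""MR gradient-artefact rejection by averaged artefact subtraction (AAS).

The gradient artefact repeats with the fMRI repetition time (TR), so for
each volume epoch a template is estimated as the moving average of the
surrounding epochs (30 by default) and subtracted.  Volume onsets come
from scanner triggers when available (the safest option) or from the TR
plus an automatically detected scanning episode.  The corrected signal is
finally anti-alias filtered and downsampled (to 500 Hz by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _sig

from .core import ArraySource, Recording, read_window
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "detect_scan_episode",
    "epoch_onsets",
    "aas_templates",
    "aas_correct",
    "downsample",
]


@dataclass
class GAConfig:
    """Gradient-artefact correction settings (all defaults per the method)."""

    tr_s: float = 2.0
    n_average_volumes: int = 30
    trigger_label: Optional[str] = None
    auto_detect: bool = False
    detect_window_s: float = 1.0
    detect_channel: Optional[str] = None  # None = first channel
    detect_threshold_uv: float = 350.0
    target_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ParameterError("tr_s must be > 0")
        if self.n_average_volumes < 1:
            raise ParameterError("n_average_volumes must be >= 1")
        if self.detect_window_s <= 0 or self.detect_threshold_uv <= 0:
            raise ParameterError("detection window/threshold must be > 0")


def detect_scan_episode(
    rec: Recording, cfg: GAConfig
) -> list[tuple[int, int]]:
    """Detect scanning episodes by a simple amplitude criterion.

    The detect channel is tiled into non-overlapping windows (1 s default);
    windows whose mean absolute amplitude strictly exceeds the threshold
    (350 uV default) are merged into contiguous episodes, with boundaries
    snapped to whole windows.  Returns half-open sample intervals.
    """
    name = cfg.detect_channel or rec.channels[0].name
    win = int(round(cfg.detect_window_s * rec.sampling_rate))
    n_tiles = rec.n_samples // win
    if n_tiles == 0:
        return []
    x = read_window(rec, [name], 0, n_tiles * win)[0]
    means = np.abs(x).reshape(n_tiles, win).mean(axis=1)
    hot = means > cfg.detect_threshold_uv
    episodes: list[tuple[int, int]] = []
    i = 0
    while i < n_tiles:
        if hot[i]:
            j = i
            while j + 1 < n_tiles and hot[j + 1]:
                j += 1
            episodes.append((i * win, (j + 1) * win))
            i = j + 1
        i += 1
    return episodes


def epoch_onsets(
    rec: Recording,
    cfg: GAConfig,
    episode: Optional[tuple[int, int]] = None,
) -> list[int]:
    """Volume-epoch onset samples, from triggers or TR within an episode."""
    if cfg.trigger_label is not None:
        onsets = sorted(
            e.onset for e in rec.events if e.label == cfg.trigger_label
        )
        if onsets:
            diffs = np.diff(onsets)
            if diffs.size and np.ptp(diffs) > 1:
                logger.warning(
                    "volume triggers jitter by %d samples; EEG/MR clocks "
                    "are probably not synchronized and GA rejection may be "
                    "improper",
                    int(diffs.ptp()),
                )
            return [int(o) for o in onsets]
    if episode is None:
        episodes = detect_scan_episode(rec, cfg) if cfg.auto_detect else []
        if not episodes:
            raise ParameterError(
                "no triggers found and no scanning episode given/detected"
            )
        episode = episodes[0]
    start, end = episode
    tr_samples = int(round(cfg.tr_s * rec.sampling_rate))
    n = (end - start) // tr_samples
    return [start + k * tr_samples for k in range(n)]


def _template_window(i: int, n_epochs: int, navg: int) -> tuple[int, int]:
    """Half-open epoch-index window for the moving-average template.

    Centered on epoch ``i`` and shifted (not shrunk) at the edges so that
    exactly ``min(navg, n_epochs)`` epochs always contribute.
    """
    size = min(navg, n_epochs)
    lo = i - (size - 1) // 2
    lo = max(0, min(lo, n_epochs - size))
    return lo, lo + size


def aas_templates(
    x: np.ndarray, onsets: Sequence[int], epoch_len: int, navg: int
) -> np.ndarray:
    """Per-epoch artefact templates (n_epochs x epoch_len moving averages).

    The final epoch may be truncated by the end of the signal; its missing
    tail simply does not contribute to any average.
    """
    onsets = list(onsets)
    n_epochs = len(onsets)
    epochs = np.zeros((n_epochs, epoch_len))
    valid = np.zeros((n_epochs, epoch_len), dtype=bool)
    for k, on in enumerate(onsets):
        ln = min(epoch_len, len(x) - on)
        epochs[k, :ln] = x[on : on + ln]
        valid[k, :ln] = True
    templates = np.zeros_like(epochs)
    for i in range(n_epochs):
        lo, hi = _template_window(i, n_epochs, navg)
        counts = valid[lo:hi].sum(axis=0)
        sums = np.where(valid[lo:hi], epochs[lo:hi], 0.0).sum(axis=0)
        templates[i] = np.divide(sums, counts, out=np.zeros(epoch_len), where=counts > 0)
    return templates


def downsample(
    data: np.ndarray, fs: float, target_hz: float
) -> tuple[np.ndarray, float]:
    """Anti-alias low-pass (zero-phase FIR, cutoff 0.4 * target) + decimate."""
    if target_hz > fs:
        raise ParameterError("target rate exceeds sampling rate")
    if target_hz == fs:
        return np.asarray(data, dtype=np.float64), fs
    ratio = fs / target_hz
    q = int(round(ratio))
    if abs(ratio - q) < 1e-9:
        numtaps = 20 * q + 1
        b = _sig.firwin(numtaps, 0.4 * target_hz, fs=fs)
        filtered = _sig.filtfilt(b, [1.0], data, axis=-1)
        return filtered[..., ::q], target_hz
    logger.warning(
        "sampling rate %.6g is not an integer multiple of %.6g; "
        "resampling by rational factor", fs, target_hz,
    )
    from fractions import Fraction

    frac = Fraction(target_hz / fs).limit_denominator(10000)
    out = _sig.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    return out, fs * frac.numerator / frac.denominator


def aas_correct(
    rec: Recording,
    cfg: GAConfig,
    episode: Optional[tuple[int, int]] = None,
) -> Recording:
    """Remove the gradient artefact and downsample.

    For every channel and every volume epoch, the moving-average template
    over ``n_average_volumes`` neighbouring epochs is subtracted; samples
    outside the epoched region are untouched.  The corrected signal is then
    downsampled to ``target_rate_hz`` and all events/scores re-indexed.
    """
    onsets = epoch_onsets(rec, cfg, episode=episode)
    if not onsets:
        raise ParameterError("no volume epochs resolved")
    if len(onsets) > 1:
        diffs = np.diff(onsets)
        vals, counts = np.unique(diffs, return_counts=True)
        epoch_len = int(vals[np.argmax(counts)])  # modal inter-trigger interval
    else:
        epoch_len = int(round(cfg.tr_s * rec.sampling_rate))

    names = rec.channel_names
    fs = rec.sampling_rate
    corrected = np.empty((len(names), rec.n_samples))
    for ci, name in enumerate(names):
        x = read_window(rec, [name], 0, rec.n_samples)[0]
        templates = aas_templates(x, onsets, epoch_len, cfg.n_average_volumes)
        y = x.copy()
        for k, on in enumerate(onsets):
            ln = min(epoch_len, len(x) - on)
            y[on : on + ln] -= templates[k, :ln]
        corrected[ci] = y

    out_data, out_fs = downsample(corrected, fs, cfg.target_rate_hz)
    scale = out_fs / fs
    events = [
        replace(e, onset=int(round(e.onset * scale)),
                duration=int(round(e.duration * scale)))
        for e in rec.events
    ]
    out = Recording(
        sampling_rate=out_fs,
        channels=list(rec.channels),
        source=ArraySource(out_data),
        start_clock_time=rec.start_clock_time,
        events=events,
        scores=[replace(s, stages=s.stages.copy(),
                        artefact_flags=s.artefact_flags.copy(),
                        fpl_sample=None if s.fpl_sample is None else int(round(s.fpl_sample * scale)),
                        opl_sample=None if s.opl_sample is None else int(round(s.opl_sample * scale)))
                for s in rec.scores],
        history=list(rec.history),
    )
    out.log(
        f"aas_correct navg={cfg.n_average_volumes} epochs={len(onsets)} "
        f"fs {fs:g}->{out_fs:g} Hz"
    )
    return out
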