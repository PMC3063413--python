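"""Ballistocardiogram / pulse-artefact rejection.

The pulse artefact is heartbeat-locked but varies from beat to beat, so
correction is anchored on R peaks detected from the ECG channel.  Three
correction methods are provided:

* ``gaussian_mean`` — beat-locked moving average with Gaussian weights;
* ``obs_pca`` — per-channel principal-component basis of beat epochs,
  fitted to and subtracted from every beat (optimal basis set);
* ``combined`` — Gaussian-mean on the low-pass (<= 4 Hz) part of the
  signal and OBS-PCA on the complementary high-pass part, recombined.

The QRS detector follows the classic complex-lead recipe: band-pass,
Teager energy, adaptive threshold with RR plausibility, polarity
invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _sig

from .core import ArraySource, ChannelKind, Recording, lowpass, read_window
from .errors import DetectionError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "HeartbeatSeries",
    "PAConfig",
    "detect_qrs",
    "correct_gaussian_mean",
    "correct_obs_pca",
    "correct_combined",
    "correct_pulse",
    "branch_filters",
    "beat_locked_average",
]


@dataclass
class HeartbeatSeries:
    """Detected R-peak sample indices on one ECG channel."""

    r_peaks: np.ndarray

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if self.r_peaks.size and np.any(np.diff(self.r_peaks) <= 0):
            raise ParameterError("r_peaks must be strictly increasing")

    @property
    def median_rr(self) -> int:
        if self.r_peaks.size < 2:
            raise ParameterError("need >= 2 beats for an RR interval")
        return int(np.median(np.diff(self.r_peaks)))

    def __len__(self) -> int:
        return len(self.r_peaks)


@dataclass
class PAConfig:
    method: str = "combined"  # gaussian_mean | obs_pca | combined
    n_obs_components: int = 4
    gm_window_beats: int = 21
    gm_sigma_beats: float = 5.0
    epoch_pre_frac: float = 0.25
    epoch_post_frac: float = 0.75
    split_hz: float = 4.0

    def __post_init__(self) -> None:
        if self.n_obs_components < 1:
            raise ParameterError("n_obs_components must be >= 1")
        if self.gm_window_beats % 2 == 0:
            raise ParameterError("gm_window_beats must be odd")
        if self.split_hz <= 0:
            raise ParameterError("split_hz must be > 0")


# ---------------------------------------------------------------------------
# QRS detection
# ---------------------------------------------------------------------------

def detect_qrs(rec: Recording, ecg_channel: str) -> HeartbeatSeries:
    """Detect R peaks on one ECG channel.

    Pipeline: 7-40 Hz zero-phase band-pass, Teager energy operator,
    smoothing, adaptive-threshold peak picking with a refractory period,
    then peak refinement on the band-passed lead (polarity invariant).
    Raises :class:`DetectionError` when no plausible rhythm (30-180 bpm)
    is found.
    """
    fs = rec.sampling_rate
    if rec.n_samples < 10 * fs:
        raise ParameterError("need at least 10 s of ECG for QRS detection")
    x = read_window(rec, [ecg_channel], 0, rec.n_samples)[0]

    hi = min(40.0, 0.45 * fs)
    sos = _sig.butter(4, [7.0, hi], btype="band", fs=fs, output="sos")
    bp = _sig.sosfiltfilt(sos, x)

    teo = np.zeros_like(bp)
    teo[1:-1] = bp[1:-1] ** 2 - bp[:-2] * bp[2:]
    teo = np.abs(teo)
    smooth_n = max(3, int(round(0.05 * fs)))
    sm = np.convolve(teo, np.ones(smooth_n) / smooth_n, mode="same")

    top = np.percentile(sm, 99.5)
    if top <= 0:
        raise DetectionError("flat ECG channel: no heartbeats detectable")
    peaks, _ = _sig.find_peaks(sm, height=0.15 * top, distance=int(round(0.3 * fs)))
    if peaks.size < 2:
        raise DetectionError("too few QRS candidates")

    # refine in two steps: coarse snap on the band-passed lead, then a fine
    # snap on the drift-removed raw ECG so asymmetric QRS morphology does
    # not bias the R-peak latency
    raw_hp = _sig.sosfiltfilt(
        _sig.butter(2, 1.0, btype="high", fs=fs, output="sos"), x
    )
    half = int(round(0.05 * fs))
    fine = int(round(0.02 * fs))
    refined = []
    for p in peaks:
        lo, hi_ = max(0, p - half), min(len(bp), p + half + 1)
        q = lo + int(np.argmax(np.abs(bp[lo:hi_])))
        lo2, hi2 = max(0, q - fine), min(len(x), q + fine + 1)
        refined.append(lo2 + int(np.argmax(np.abs(raw_hp[lo2:hi2]))))
    refined = np.unique(refined)

    # RR plausibility: drop the weaker of two peaks closer than 0.25 s
    keep = []
    for p in refined:
        if keep and p - keep[-1] < 0.25 * fs:
            if np.abs(bp[p]) > np.abs(bp[keep[-1]]):
                keep[-1] = p
        else:
            keep.append(p)
    r_peaks = np.asarray(keep, dtype=np.int64)

    rate_bpm = 60.0 * (len(r_peaks) - 1) / ((r_peaks[-1] - r_peaks[0]) / fs)
    if not 30.0 <= rate_bpm <= 180.0:
        raise DetectionError(
            f"estimated heart rate {rate_bpm:.1f} bpm outside 30-180 bpm"
        )
    return HeartbeatSeries(r_peaks)


# ---------------------------------------------------------------------------
# epoch bookkeeping shared by the correction methods
# ---------------------------------------------------------------------------

def _epoch_spans(peaks: np.ndarray, pre: int, post: int, n: int):
    """Per-beat subtraction spans, truncated at midpoints when overlapping."""
    spans = [[r - pre, r + post] for r in peaks]
    for i in range(len(spans) - 1):
        overlap = spans[i][1] - spans[i + 1][0]
        if overlap > 0:  # truncate both at the middle of the overlap
            c = (spans[i][1] + spans[i + 1][0]) // 2
            spans[i][1] = c
            spans[i + 1][0] = c
    spans = [(max(0, a), min(n, b)) for a, b in spans]
    # RR rounding can leave sliver gaps between consecutive epochs; tile
    # them (template values are edge-held there) so full-amplitude artefact
    # never survives in a crack a few samples wide
    max_gap = max(2, (pre + post) // 20)
    for i in range(len(spans) - 1):
        gap = spans[i + 1][0] - spans[i][1]
        if 0 < gap <= max_gap:
            spans[i] = (spans[i][0], spans[i + 1][0])
    return spans


def _gm_weights(i: int, n_beats: int, window: int, sigma: float) -> tuple[int, np.ndarray]:
    """Centered (edge-shifted) Gaussian weight window; returns (lo, weights)."""
    size = min(window, n_beats)
    lo = i - (size - 1) // 2
    lo = max(0, min(lo, n_beats - size))
    d = np.arange(lo, lo + size) - i
    w = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return lo, w / w.sum()


def beat_locked_average(x: np.ndarray, peaks: Sequence[int], pre: int, post: int) -> np.ndarray:
    """Plain average of beat epochs; used for QC of artefact reduction."""
    rows = [
        x[r - pre : r + post]
        for r in peaks
        if r - pre >= 0 and r + post <= len(x)
    ]
    if not rows:
        raise ParameterError("no complete beat epochs")
    return np.mean(rows, axis=0)


def _gm_correct_channel(x: np.ndarray, peaks: np.ndarray, cfg: PAConfig) -> np.ndarray:
    med_rr = int(np.median(np.diff(peaks)))
    pre = int(round(cfg.epoch_pre_frac * med_rr))
    post = int(round(cfg.epoch_post_frac * med_rr))
    L = pre + post
    n_beats = len(peaks)

    epochs = np.zeros((n_beats, L))
    valid = np.zeros((n_beats, L), dtype=bool)
    for k, r in enumerate(peaks):
        a, b = r - pre, r + post
        ca, cb = max(0, a), min(len(x), b)
        epochs[k, ca - a : cb - a] = x[ca:cb]
        valid[k, ca - a : cb - a] = True

    y = x.copy()
    spans = _epoch_spans(peaks, pre, post, len(x))
    for i, r in enumerate(peaks):
        lo, w = _gm_weights(i, n_beats, cfg.gm_window_beats, cfg.gm_sigma_beats)
        wv = w[:, None] * valid[lo : lo + len(w)]
        denom = wv.sum(axis=0)
        template = np.divide(
            (wv * epochs[lo : lo + len(w)]).sum(axis=0),
            denom,
            out=np.zeros(L),
            where=denom > 0,
        )
        a, b = spans[i]
        idx = np.clip(np.arange(a, b) - (r - pre), 0, L - 1)
        y[a:b] -= template[idx]
    return y


def _normalize_epoch(x: np.ndarray, r: int, pre_i: int, post_i: int, pre: int, post: int):
    """Linearly resample an epoch with local RR onto the median-RR grid."""
    jj = np.arange(pre + post, dtype=np.float64)
    t = np.where(
        jj < pre,
        r - pre_i * (pre - jj) / pre,
        r + post_i * (jj - pre) / post,
    )
    return np.interp(t, np.arange(len(x)), x)


def _obs_correct_channel(x: np.ndarray, peaks: np.ndarray, cfg: PAConfig) -> np.ndarray:
    med_rr = int(np.median(np.diff(peaks)))
    pre = int(round(cfg.epoch_pre_frac * med_rr))
    post = int(round(cfg.epoch_post_frac * med_rr))
    L = pre + post
    n_beats = len(peaks)
    rr = np.diff(peaks)

    # local per-beat epoch extents scale with the adjacent RR intervals
    pre_i = np.empty(n_beats, dtype=np.int64)
    post_i = np.empty(n_beats, dtype=np.int64)
    for i in range(n_beats):
        rr_prev = rr[i - 1] if i > 0 else med_rr
        rr_next = rr[i] if i < n_beats - 1 else med_rr
        pre_i[i] = max(1, int(round(cfg.epoch_pre_frac * rr_prev)))
        post_i[i] = max(1, int(round(cfg.epoch_post_frac * rr_next)))

    usable = np.array(
        [peaks[i] - pre_i[i] >= 0 and peaks[i] + post_i[i] <= len(x) for i in range(n_beats)]
    )
    idx = np.flatnonzero(usable)
    if idx.size < cfg.n_obs_components + 2:
        raise ParameterError(
            f"need >= {cfg.n_obs_components + 2} complete beats, got {idx.size}"
        )

    E = np.stack(
        [_normalize_epoch(x, peaks[i], pre_i[i], post_i[i], pre, post) for i in idx]
    )
    D = E - E.mean(axis=1, keepdims=True)  # demean each epoch
    _, s, vt = np.linalg.svd(D, full_matrices=False)
    tol = max(D.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > max(tol, 1e-12)))
    k = min(cfg.n_obs_components, rank)
    if k < cfg.n_obs_components:
        logger.warning(
            "epoch matrix rank %d < requested %d components; using %d",
            rank, cfg.n_obs_components, k,
        )
    comps = vt[:k]
    for c in comps:  # deterministic sign: largest-|.| coefficient positive
        if c[np.argmax(np.abs(c))] < 0:
            c *= -1.0

    basis = np.column_stack([comps.T, np.ones(L)])
    fits = basis @ np.linalg.lstsq(basis, E.T, rcond=None)[0]  # L x n_usable

    y = x.copy()
    spans = _epoch_spans(peaks, pre, post, len(x))
    grid = np.arange(L, dtype=np.float64)
    for col, i in enumerate(idx):
        r = peaks[i]
        a, b = spans[i]
        a = max(a, r - pre_i[i])
        if b <= a:
            continue
        t = np.arange(a, b, dtype=np.float64)
        # inverse of the normalization map: native sample -> grid index
        j = np.where(
            t < r,
            pre - (r - t) * pre / pre_i[i],
            pre + (t - r) * post / post_i[i],
        )
        y[a:b] -= np.interp(j, grid, fits[:, col])
    return y


def branch_filters(x: np.ndarray, fs: float, split_hz: float = 4.0):
    """Complementary low/high split used by the combined method.

    ``low`` is an order-4 zero-phase Butterworth low-pass at ``split_hz``;
    ``high = x - low``, so the two branches reconstruct the input exactly
    and their magnitude responses cross at the cutoff.
    """
    low = lowpass(np.atleast_2d(x), fs, split_hz)
    high = np.atleast_2d(x) - low
    if np.ndim(x) == 1:
        return low[0], high[0]
    return low, high


def _target_channels(rec: Recording, channels: Optional[Sequence[str]]) -> list[str]:
    if channels is not None:
        return list(channels)
    return [c.name for c in rec.channels if c.kind is not ChannelKind.ECG]


def _apply_per_channel(rec, beats, channels, fn) -> Recording:
    names = rec.channel_names
    data = read_window(rec, names, 0, rec.n_samples)
    targets = set(channels)
    for ci, name in enumerate(names):
        if name in targets:
            data[ci] = fn(data[ci], beats.r_peaks)
    out = rec.with_source(ArraySource(data))
    return out


def correct_gaussian_mean(
    rec: Recording,
    beats: HeartbeatSeries,
    cfg: Optional[PAConfig] = None,
    channels: Optional[Sequence[str]] = None,
) -> Recording:
    """Subtract a Gaussian-weighted moving average of beat-locked epochs."""
    cfg = cfg or PAConfig(method="gaussian_mean")
    if len(beats) < cfg.gm_window_beats:
        raise ParameterError(
            f"need >= {cfg.gm_window_beats} beats, got {len(beats)}"
        )
    out = _apply_per_channel(
        rec, beats, _target_channels(rec, channels),
        lambda x, p: _gm_correct_channel(x, p, cfg),
    )
    out.log(f"pulse_correct gaussian_mean beats={len(beats)}")
    return out


def correct_obs_pca(
    rec: Recording,
    beats: HeartbeatSeries,
    cfg: Optional[PAConfig] = None,
    channels: Optional[Sequence[str]] = None,
) -> Recording:
    """Fit and subtract an optimal basis set of beat-epoch components."""
    cfg = cfg or PAConfig(method="obs_pca")
    if len(beats) < cfg.n_obs_components + 2:
        raise ParameterError(
            f"need >= {cfg.n_obs_components + 2} beats, got {len(beats)}"
        )
    out = _apply_per_channel(
        rec, beats, _target_channels(rec, channels),
        lambda x, p: _obs_correct_channel(x, p, cfg),
    )
    out.log(f"pulse_correct obs_pca beats={len(beats)}")
    return out


def correct_combined(
    rec: Recording,
    beats: HeartbeatSeries,
    cfg: Optional[PAConfig] = None,
    channels: Optional[Sequence[str]] = None,
) -> Recording:
    """Gaussian-mean on the <= split_hz band, OBS-PCA above, recombined."""
    cfg = cfg or PAConfig(method="combined")
    if len(beats) < max(cfg.gm_window_beats, cfg.n_obs_components + 2):
        raise ParameterError("not enough beats for the combined method")
    targets = set(_target_channels(rec, channels))
    names = rec.channel_names
    data = read_window(rec, names, 0, rec.n_samples)
    fs = rec.sampling_rate
    for ci, name in enumerate(names):
        if name not in targets:
            continue
        low, high = branch_filters(data[ci], fs, cfg.split_hz)
        low_c = _gm_correct_channel(low, beats.r_peaks, cfg)
        high_c = _obs_correct_channel(high, beats.r_peaks, cfg)
        data[ci] = low_c + high_c
    out = rec.with_source(ArraySource(data))
    out.log(f"pulse_correct combined beats={len(beats)}")
    return out


def correct_pulse(
    rec: Recording,
    beats: HeartbeatSeries,
    cfg: PAConfig,
    channels: Optional[Sequence[str]] = None,
) -> Recording:
    """Dispatch on ``cfg.method``; seam where further methods can plug in."""
    methods = {
        "gaussian_mean": correct_gaussian_mean,
        "obs_pca": correct_obs_pca,
        "combined": correct_combined,
    }
    if cfg.method not in methods:
        raise ParameterError(
            f"unknown method {cfg.method!r}; available: {sorted(methods)}"
        )
    return methods[cfg.method](rec, beats, cfg, channels=channels)
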