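"""Slow-wave detection and scalp trajectory extraction.

Detection runs on signals averaged within four scalp regions of interest
(around Fz, C3, C4 and Pz by default) after band-pass filtering.  A wave
must satisfy five criteria:

1. a down-going then an up-going zero crossing separated by 0.25-1.25 s
   (inclusive);
2. a negative peak between the crossings with voltage < -80 uV (strict);
3. negative-to-positive peak-to-peak amplitude > 140 uV (strict);
4. maximum positive slope > 90 % of the maximum slope among the
   episode's candidates passing criteria 1-3;
5. the positive peak follows the up-crossing by at most 2 s (inclusive).

The trajectory of a detected wave is the map of per-electrode negative
peak delays relative to the first electrode where the wave appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import Event, Recording, bandpass, read_window
from .errors import ConfigurationError, ParameterError
from .scoring import ScoreSet

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ROI_MAP",
    "SWConfig",
    "SlowWave",
    "extract_episode",
    "roi_average",
    "detect_sw",
    "sw_trajectory",
    "dedupe_across_rois",
    "detect_slow_waves",
]

# extended 10-20 neighbourhoods of the four detection regions
DEFAULT_ROI_MAP: dict[str, list[str]] = {
    "frontal": ["Fp1", "Fp2", "AF3", "AF4", "F3", "Fz", "F4"],
    "central_left": ["FC3", "C3", "CP3"],
    "central_right": ["FC4", "C4", "CP4"],
    "parietal": ["P3", "Pz", "P4", "POz"],
}


@dataclass
class SWConfig:
    roi_map: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_ROI_MAP.items()})
    band_hz: tuple[float, float] = (0.25, 4.0)
    zx_separation_s: tuple[float, float] = (0.25, 1.25)
    neg_peak_uv: float = -80.0
    p2p_uv: float = 140.0
    slope_frac: float = 0.90
    pos_peak_max_lag_s: float = 2.0
    electrode_match_window_s: float = 0.3

    def __post_init__(self) -> None:
        if not self.roi_map or any(not v for v in self.roi_map.values()):
            raise ConfigurationError("roi_map needs nonempty electrode lists")
        if self.p2p_uv <= 0 or self.neg_peak_uv >= 0:
            raise ParameterError("amplitude thresholds have fixed signs")


@dataclass
class SlowWave:
    roi: str
    down_zx_s: float
    up_zx_s: float
    neg_peak_s: float
    neg_peak_uv: float
    pos_peak_s: float
    pos_peak_uv: float
    p2p_uv: float
    max_slope_uv_per_s: float
    electrode_delays: dict = field(default_factory=dict)  # electrode -> s (min 0)
    origin_electrode: Optional[str] = None
    origin_time_s: Optional[float] = None  # absolute neg-peak time at origin


def extract_episode(
    rec: Recording,
    *,
    whole: bool = False,
    time: Optional[tuple[float, float]] = None,
    stages: Optional[tuple[ScoreSet, set]] = None,
) -> list[tuple[int, int]]:
    """Half-open sample intervals of the episode(s) to analyse."""
    given = sum((whole, time is not None, stages is not None))
    if given != 1:
        raise ParameterError("specify exactly one of whole/time/stages")
    fs = rec.sampling_rate
    if whole:
        return [(0, rec.n_samples)] if rec.n_samples else []
    if time is not None:
        t0, t1 = time
        if t1 <= t0:
            raise ParameterError(f"empty interval: t1={t1} <= t0={t0}")
        s0, s1 = int(round(t0 * fs)), int(round(t1 * fs))
        if s0 < 0 or s1 > rec.n_samples:
            raise ParameterError("interval outside recording")
        return [(s0, s1)]
    scoreset, wanted = stages
    win = scoreset.window_length_s * fs
    intervals: list[tuple[int, int]] = []
    run_start = None
    for w in range(scoreset.n_windows):
        if int(scoreset.stages[w]) in wanted:
            if run_start is None:
                run_start = w
        elif run_start is not None:
            intervals.append((int(run_start * win), int(w * win)))
            run_start = None
    if run_start is not None:
        intervals.append((int(run_start * win),
                          min(rec.n_samples, int(scoreset.n_windows * win))))
    return intervals


def roi_average(
    rec: Recording,
    roi_map: dict,
    start: int = 0,
    length: Optional[int] = None,
) -> dict[str, np.ndarray]:
    """Unweighted mean signal of each ROI's present electrodes.

    Electrodes missing from the recording are silently dropped (logged);
    a ROI with no present electrode at all is a configuration error.
    """
    if length is None:
        length = rec.n_samples - start
    present = set(rec.channel_names)
    out: dict[str, np.ndarray] = {}
    for roi, members in roi_map.items():
        used = [m for m in members if m in present]
        missing = [m for m in members if m not in present]
        if missing:
            logger.info("ROI %s: dropping absent electrodes %s", roi, missing)
        if not used:
            raise ConfigurationError(f"ROI {roi!r} has no present electrode")
        block = read_window(rec, used, start, length)
        out[roi] = block.mean(axis=0)
    return out


def _interp_crossing(x: np.ndarray, i: int) -> float:
    """Sub-sample zero-crossing location between samples i-1 and i."""
    a, b = x[i - 1], x[i]
    if a == b:
        return float(i - 1)
    return (i - 1) + a / (a - b)


def detect_sw(
    roi_signal: np.ndarray,
    fs: float,
    cfg: Optional[SWConfig] = None,
    roi: str = "",
    t_offset_s: float = 0.0,
) -> list[SlowWave]:
    """Detect slow waves on one (already band-passed) ROI signal.

    Two passes: candidates are gathered on the zero-crossing and amplitude
    criteria (1-3), the episode's maximum positive slope is taken over
    that population, then the slope (4) and positive-peak-lag (5) criteria
    prune the final list, returned in time order.
    """
    cfg = cfg or SWConfig()
    x = np.asarray(roi_signal, dtype=np.float64)
    n = len(x)
    neg = x < 0
    down_idx = np.flatnonzero(~neg[:-1] & neg[1:]) + 1  # first negative sample
    up_idx = np.flatnonzero(neg[:-1] & ~neg[1:]) + 1    # first nonnegative sample

    candidates = []
    for d in down_idx:
        ups = up_idx[up_idx > d]
        if not ups.size:
            continue
        u = ups[0]
        t_down = _interp_crossing(x, d) / fs
        t_up = _interp_crossing(x, u) / fs
        sep = t_up - t_down
        if not cfg.zx_separation_s[0] <= sep <= cfg.zx_separation_s[1]:
            continue
        seg = x[d:u]
        neg_k = d + int(np.argmin(seg))
        neg_v = x[neg_k]
        if not neg_v < cfg.neg_peak_uv:  # criterion 2, strict
            continue
        # positive phase: up to the next down-crossing (or signal end)
        nxt = down_idx[down_idx > u]
        end = int(nxt[0]) if nxt.size else n
        if end <= u:
            continue
        pos_k = u + int(np.argmax(x[u:end]))
        pos_v = x[pos_k]
        p2p = pos_v - neg_v
        if not p2p > cfg.p2p_uv:  # criterion 3, strict
            continue
        lo, hi = min(neg_k, pos_k), max(neg_k, pos_k)
        slope = float(np.max(np.diff(x[lo : hi + 1])) * fs) if hi > lo else 0.0
        candidates.append(
            SlowWave(
                roi=roi,
                down_zx_s=t_down + t_offset_s,
                up_zx_s=t_up + t_offset_s,
                neg_peak_s=neg_k / fs + t_offset_s,
                neg_peak_uv=float(neg_v),
                pos_peak_s=pos_k / fs + t_offset_s,
                pos_peak_uv=float(pos_v),
                p2p_uv=float(p2p),
                max_slope_uv_per_s=slope,
            )
        )
    if not candidates:
        return []
    max_slope = max(w.max_slope_uv_per_s for w in candidates)
    out = []
    for w in candidates:
        # strict > with an ulp-scale guard so exact-ratio probes stay rejected
        if w.max_slope_uv_per_s <= cfg.slope_frac * max_slope * (1 + 1e-9):
            continue
        if w.pos_peak_s - w.up_zx_s > cfg.pos_peak_max_lag_s + 1e-9:
            continue
        out.append(w)
    return out


def sw_trajectory(
    signals: dict[str, np.ndarray],
    fs: float,
    wave: SlowWave,
    cfg: Optional[SWConfig] = None,
    t_offset_s: float = 0.0,
) -> Optional[SlowWave]:
    """Attach per-electrode negative-peak delays to a detected wave.

    ``signals`` maps electrode name to its band-passed trace (same filter
    as detection).  An electrode participates when it shows a local
    negative peak below the negative-peak threshold within the match
    window around the ROI negative-peak time; delays are relative to the
    earliest participating electrode.  Returns None (with a warning) if no
    electrode participates.
    """
    cfg = cfg or SWConfig()
    half = int(round(cfg.electrode_match_window_s * fs))
    center = int(round((wave.neg_peak_s - t_offset_s) * fs))
    times: dict[str, float] = {}
    for name, x in signals.items():
        lo = max(1, center - half)
        hi = min(len(x) - 1, center + half + 1)
        if hi <= lo:
            continue
        seg = x[lo:hi]
        is_min = (seg <= x[lo - 1 : hi - 1]) & (seg <= x[lo + 1 : hi + 1])
        is_min &= seg < cfg.neg_peak_uv
        if not is_min.any():
            continue
        k = lo + int(np.argmin(np.where(is_min, seg, np.inf)))
        times[name] = k / fs + t_offset_s
    if not times:
        logger.warning("slow wave at %.2f s: no participating electrode", wave.neg_peak_s)
        return None
    t0 = min(times.values())
    origin = min(times, key=times.get)
    return replace(
        wave,
        electrode_delays={e: t - t0 for e, t in times.items()},
        origin_electrode=origin,
        origin_time_s=t0,
    )


def dedupe_across_rois(waves: Sequence[SlowWave], merge_window_s: float = 0.5) -> list[SlowWave]:
    """Merge the same physical wave seen by several ROI streams.

    Input must be time-sorted.  Waves whose negative peaks lie within the
    merge window collapse to the one with the most negative peak; their
    electrode delay maps are unioned and re-zeroed to the new minimum.
    """
    out: list[SlowWave] = []
    for w in waves:
        if out and w.neg_peak_s - out[-1].neg_peak_s <= merge_window_s:
            keep, other = (w, out[-1]) if w.neg_peak_uv < out[-1].neg_peak_uv else (out[-1], w)
            merged = {}
            for src in (other, keep):  # keep's entries win on collision
                if src.origin_time_s is None:
                    continue
                base = src.origin_time_s
                for e, d in src.electrode_delays.items():
                    merged[e] = base + d
            if merged:
                t0 = min(merged.values())
                keep = replace(
                    keep,
                    electrode_delays={e: t - t0 for e, t in merged.items()},
                    origin_electrode=min(merged, key=merged.get),
                    origin_time_s=t0,
                )
            out[-1] = keep
        else:
            out.append(w)
    return out


def detect_slow_waves(
    rec: Recording,
    cfg: Optional[SWConfig] = None,
    *,
    scoreset: Optional[ScoreSet] = None,
    stages: set = frozenset({3, 4}),
    time: Optional[tuple[float, float]] = None,
    write_events: bool = True,
) -> list[SlowWave]:
    """Full pipeline: episode extraction, filtering, ROI detection,
    per-electrode trajectory, cross-ROI deduplication.

    Detected waves are also written back to ``rec.events`` (label
    ``slow_wave``) so the data can be epoched on them.
    """
    cfg = cfg or SWConfig()
    if scoreset is not None:
        episodes = extract_episode(rec, stages=(scoreset, set(stages)))
    elif time is not None:
        episodes = extract_episode(rec, time=time)
    else:
        episodes = extract_episode(rec, whole=True)

    fs = rec.sampling_rate
    electrodes = sorted({e for members in cfg.roi_map.values() for e in members}
                        & set(rec.channel_names))
    all_waves: list[SlowWave] = []
    for s0, s1 in episodes:
        rois = roi_average(rec, cfg.roi_map, s0, s1 - s0)
        filtered_rois = {
            name: bandpass(sig, fs, cfg.band_hz[0], cfg.band_hz[1])[0]
            for name, sig in rois.items()
        }
        elec_block = read_window(rec, electrodes, s0, s1 - s0)
        elec_filtered = dict(zip(
            electrodes, bandpass(elec_block, fs, cfg.band_hz[0], cfg.band_hz[1])
        ))
        t_off = s0 / fs
        episode_waves: list[SlowWave] = []
        for roi, sig in filtered_rois.items():
            episode_waves.extend(detect_sw(sig, fs, cfg, roi=roi, t_offset_s=t_off))
        with_delays = []
        for w in sorted(episode_waves, key=lambda w: w.neg_peak_s):
            traced = sw_trajectory(elec_filtered, fs, w, cfg, t_offset_s=t_off)
            if traced is not None:
                with_delays.append(traced)
        all_waves.extend(dedupe_across_rois(with_delays))

    all_waves.sort(key=lambda w: w.neg_peak_s)
    if write_events:
        for w in all_waves:
            rec.events.append(
                Event(label="slow_wave", onset=int(round(w.neg_peak_s * fs)),
                      payload=w.roi)
            )
    return all_waves
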