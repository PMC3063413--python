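"""Append, chunk and align continuous recordings.

Appending respects real-world clock time: when both files carry a start
timestamp the order is determined automatically and any gap between them
is filled with zeros; otherwise the files are concatenated as given.
Chunking cuts a half-open sample interval out of a recording.  Both are
lazy — no sample payload is copied until something reads a window.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .core import Event, Recording, SampleSource
from .errors import (
    CompatibilityError,
    MarkerNotFoundError,
    OverlapError,
    ParameterError,
    WindowBoundsError,
)
from .scoring import STAGE_UNSCORED, ScoreSet

__all__ = ["append", "chunk", "align_for_comparison", "ConcatSource", "SliceSource"]


class ConcatSource(SampleSource):
    """Sequence of sources (``None`` = zero fill) presented as one timeline."""

    def __init__(self, parts: Sequence[tuple[Optional[SampleSource], int]], n_channels: int):
        self.parts = list(parts)
        self.n_channels = n_channels
        self.n_samples = sum(n for _, n in self.parts)

    def read(self, channel_indices, start, length):
        out = np.zeros((len(list(channel_indices)), length))
        idx = list(channel_indices)
        pos = 0  # start of current part in the output timeline
        for src, n in self.parts:
            lo = max(start, pos)
            hi = min(start + length, pos + n)
            if lo < hi and src is not None:
                out[:, lo - start : hi - start] = src.read(idx, lo - pos, hi - lo)
            pos += n
        return out


class SliceSource(SampleSource):
    """Half-open sample window of another source."""

    def __init__(self, source: SampleSource, start: int, length: int):
        if start < 0 or length < 0 or start + length > source.n_samples:
            raise WindowBoundsError("slice outside source")
        self.source = source
        self.start = start
        self.n_channels = source.n_channels
        self.n_samples = length

    def read(self, channel_indices, start, length):
        return self.source.read(channel_indices, self.start + start, length)


def _check_compatible(a: Recording, b: Recording) -> None:
    if a.sampling_rate != b.sampling_rate:
        raise CompatibilityError(
            f"sampling rates differ: {a.sampling_rate} vs {b.sampling_rate}"
        )
    ka = [(c.name, c.kind) for c in a.channels]
    kb = [(c.name, c.kind) for c in b.channels]
    if ka != kb:
        raise CompatibilityError("channel lists differ (names/order/kinds)")


def _shift_scoreset(s: ScoreSet, shift_windows: int, total_windows: int) -> ScoreSet:
    stages = np.full(total_windows, STAGE_UNSCORED, dtype=np.int64)
    flags = np.zeros(total_windows, dtype=bool)
    n = min(s.n_windows, total_windows - shift_windows)
    if n > 0:
        stages[shift_windows : shift_windows + n] = s.stages[:n]
        flags[shift_windows : shift_windows + n] = s.artefact_flags[:n]
    return replace(s, stages=stages, artefact_flags=flags)


def append(rec_a: Recording, rec_b: Recording) -> Recording:
    """Append two recordings into one, zero-filling any clock gap.

    With both start times present the earlier file goes first and the gap
    (rounded to the nearest sample; sub-sample disagreement collapses to
    zero) is zero-filled.  Overlapping clock ranges are an error.  Without
    clocks, concatenation follows argument order with no gap.
    """
    _check_compatible(rec_a, rec_b)
    fs = rec_a.sampling_rate
    if rec_a.start_clock_time is not None and rec_b.start_clock_time is not None:
        first, second = sorted(
            (rec_a, rec_b), key=lambda r: r.start_clock_time
        )
        gap_s = (second.start_clock_time - first.end_clock_time).total_seconds()
        gap = int(round(gap_s * fs))
        if gap < 0:
            raise OverlapError(
                f"recordings overlap in clock time by {-gap_s:.3f} s"
            )
        start_clock = first.start_clock_time
    else:
        first, second, gap = rec_a, rec_b, 0
        start_clock = rec_a.start_clock_time

    offset = first.n_samples + gap
    parts = [(first.source, first.n_samples)]
    if gap:
        parts.append((None, gap))
    parts.append((second.source, second.n_samples))
    source = ConcatSource(parts, len(first.channels))

    events = [replace(e) for e in first.events] + [
        replace(e, onset=e.onset + offset) for e in second.events
    ]
    total = source.n_samples
    scores = []
    for s in first.scores:
        scores.append(_shift_scoreset(s, 0, math.ceil(total / fs / s.window_length_s)))
    for s in second.scores:
        win_samples = s.window_length_s * fs
        scores.append(
            _shift_scoreset(
                s,
                int(round(offset / win_samples)),
                math.ceil(total / fs / s.window_length_s),
            )
        )

    rec = Recording(
        sampling_rate=fs,
        channels=list(first.channels),
        source=source,
        start_clock_time=start_clock,
        events=events,
        scores=scores,
        history=list(first.history) + list(second.history),
    )
    rec.log(f"append gap={gap} samples")
    return rec


def _resolve_interval(rec: Recording, *, by_markers=None, by_time=None, by_clock=None):
    given = sum(x is not None for x in (by_markers, by_time, by_clock))
    if given != 1:
        raise ParameterError("specify exactly one of by_markers/by_time/by_clock")
    if by_markers is not None:
        label_start, label_end = by_markers
        starts = [e.onset for e in rec.events if e.label == label_start]
        if not starts:
            raise MarkerNotFoundError(label_start)
        s0 = min(starts)
        ends = [e.onset for e in rec.events if e.label == label_end and e.onset > s0]
        if not ends:
            raise MarkerNotFoundError(label_end)
        return s0, min(ends)
    if by_time is not None:
        t0, t1 = by_time
    else:
        if rec.start_clock_time is None:
            raise ParameterError("by_clock requires start_clock_time")
        T0, T1 = by_clock
        t0 = (T0 - rec.start_clock_time).total_seconds()
        t1 = (T1 - rec.start_clock_time).total_seconds()
    if t1 <= t0:
        raise ParameterError(f"empty interval: t1={t1} <= t0={t0}")
    s0 = int(round(t0 * rec.sampling_rate))
    s1 = int(round(t1 * rec.sampling_rate))
    if s0 < 0 or s1 > rec.n_samples:
        raise WindowBoundsError(f"interval [{s0}, {s1}) outside recording")
    return s0, s1


def chunk(rec: Recording, *, by_markers=None, by_time=None, by_clock=None) -> Recording:
    """Cut a half-open interval out of a recording as a new recording.

    The interval is given by a marker label pair, by seconds relative to
    the file start, or by real-world clock instants.  Events inside the
    interval are shifted; an event at exactly the end sample is excluded.
    Score windows whose start lies inside the interval are kept.
    """
    s0, s1 = _resolve_interval(rec, by_markers=by_markers, by_time=by_time, by_clock=by_clock)
    fs = rec.sampling_rate
    length = s1 - s0

    events = [
        replace(e, onset=e.onset - s0)
        for e in rec.events
        if s0 <= e.onset < s1
    ]
    scores = []
    for s in rec.scores:
        win_samples = s.window_length_s * fs
        first_w = math.ceil(s0 / win_samples) if s0 % win_samples else s0 // win_samples
        first_w = int(first_w)
        kept = [
            w for w in range(s.n_windows)
            if s0 <= w * win_samples < s1
        ]
        n_out = math.ceil(length / fs / s.window_length_s)
        stages = np.full(n_out, STAGE_UNSCORED, dtype=np.int64)
        flags = np.zeros(n_out, dtype=bool)
        for j, w in enumerate(kept[:n_out]):
            stages[j] = s.stages[w]
            flags[j] = s.artefact_flags[w]
        fpl = s.fpl_sample - s0 if s.fpl_sample is not None and s0 <= s.fpl_sample < s1 else None
        opl = s.opl_sample - s0 if s.opl_sample is not None and s0 <= s.opl_sample < s1 else None
        scores.append(replace(s, stages=stages, artefact_flags=flags,
                              fpl_sample=fpl, opl_sample=opl))

    start_clock = None
    if rec.start_clock_time is not None:
        start_clock = rec.start_clock_time + _dt.timedelta(seconds=s0 / fs)
    out = Recording(
        sampling_rate=fs,
        channels=list(rec.channels),
        source=SliceSource(rec.source, s0, length),
        start_clock_time=start_clock,
        events=events,
        scores=scores,
        history=list(rec.history),
    )
    out.log(f"chunk [{s0}, {s1})")
    return out


def align_for_comparison(recs: Sequence[Recording]) -> list[int]:
    """Per-recording sample offsets aligning identical clock instants.

    Returns nonnegative offsets (earliest start has offset 0).  If any
    recording lacks a start time, all recordings are assumed to begin
    together and every offset is 0.
    """
    if len(recs) < 2:
        raise ParameterError("need at least two recordings to align")
    shared = set(recs[0].channel_names)
    for r in recs[1:]:
        shared &= set(r.channel_names)
    if not shared:
        raise CompatibilityError("recordings share no channel name")
    if any(r.start_clock_time is None for r in recs):
        return [0] * len(recs)
    t0 = min(r.start_clock_time for r in recs)
    return [
        int(round((r.start_clock_time - t0).total_seconds() * r.sampling_rate))
        for r in recs
    ]
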