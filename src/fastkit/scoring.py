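"""Sleep scoring model, hypnogram and sleep statistics.

Stage codes follow the classical convention: 0 wake, 1-4 NREM stages,
5 REM, 6 movement time, -1 unscored.  Several scorers may score the same
recording; each gets their own :class:`ScoreSet` keyed by ``scorer_id``.
Sleep statistics are computed over the windows fully inside the
[FPL, OPL) interval (the "lights off" / "lights on" boundary markers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ParameterError

__all__ = [
    "STAGE_WAKE",
    "STAGE_REM",
    "STAGE_MOVEMENT",
    "STAGE_UNSCORED",
    "SLEEP_STAGES",
    "VALID_STAGES",
    "ScoreSet",
    "new_scoreset",
    "set_stage",
    "hypnogram",
    "sleep_statistics",
    "read_score_table",
    "write_score_table",
]

STAGE_WAKE = 0
STAGE_REM = 5
STAGE_MOVEMENT = 6
STAGE_UNSCORED = -1
SLEEP_STAGES = frozenset({1, 2, 3, 4, 5})
VALID_STAGES = frozenset({-1, 0, 1, 2, 3, 4, 5, 6})


@dataclass
class ScoreSet:
    """One scorer's per-window stages, artefact flags and boundary markers."""

    scorer_id: str
    window_length_s: float
    stages: np.ndarray  # int per window
    artefact_flags: np.ndarray  # bool per window
    fpl_sample: Optional[int] = None
    opl_sample: Optional[int] = None
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.window_length_s <= 0:
            raise ParameterError("window_length_s must be > 0")
        self.stages = np.asarray(self.stages, dtype=np.int64)
        self.artefact_flags = np.asarray(self.artefact_flags, dtype=bool)
        if self.stages.shape != self.artefact_flags.shape:
            raise ParameterError("stages and artefact_flags length mismatch")
        bad = set(np.unique(self.stages)) - VALID_STAGES
        if bad:
            raise ParameterError(f"invalid stage codes: {sorted(bad)}")

    @property
    def n_windows(self) -> int:
        return len(self.stages)

    def window_of_sample(self, sample: int, fs: float) -> int:
        return int(sample / fs // self.window_length_s)


def new_scoreset(
    scorer_id: str, duration_s: float, window_length_s: float = 30.0
) -> ScoreSet:
    """Fresh all-unscored score set covering ceil(duration / window) windows."""
    n = math.ceil(duration_s / window_length_s) if duration_s > 0 else 0
    return ScoreSet(
        scorer_id=scorer_id,
        window_length_s=window_length_s,
        stages=np.full(n, STAGE_UNSCORED, dtype=np.int64),
        artefact_flags=np.zeros(n, dtype=bool),
    )


def set_stage(scoreset: ScoreSet, window_index: int, code: int) -> ScoreSet:
    """Pure update: return a copy with one window's stage assigned."""
    if code not in VALID_STAGES:
        raise ParameterError(f"invalid stage code {code}")
    if not 0 <= window_index < scoreset.n_windows:
        raise ParameterError(
            f"window index {window_index} out of range [0, {scoreset.n_windows})"
        )
    stages = scoreset.stages.copy()
    stages[window_index] = code
    return replace(scoreset, stages=stages, artefact_flags=scoreset.artefact_flags.copy())


def hypnogram(scoreset: ScoreSet) -> tuple[np.ndarray, np.ndarray]:
    """Return (window start times in seconds, stage codes)."""
    t = np.arange(scoreset.n_windows) * scoreset.window_length_s
    return t, scoreset.stages.copy()


def sleep_statistics(scoreset: ScoreSet, fs: float) -> dict:
    """Sleep statistics over windows fully inside [FPL, OPL).

    Returns a dict with seconds-valued durations:

    - ``time_in_bed``, ``total_sleep_time`` (stages 1-5), ``sleep_efficiency``
    - ``sleep_latency`` (FPL to first sleep window; None if never asleep)
    - ``rem_latency`` (sleep onset to first REM window; None if no REM)
    - ``stage_duration_s`` / ``stage_pct_tst`` per stage code
    - ``n_awakenings`` (wake runs after sleep onset)
    """
    if scoreset.fpl_sample is None:
        raise ParameterError("FPL marker not set")
    if scoreset.opl_sample is None:
        raise ParameterError("OPL marker not set")
    if scoreset.fpl_sample >= scoreset.opl_sample:
        raise ParameterError("FPL must precede OPL")

    win_s = scoreset.window_length_s
    win_samples = win_s * fs
    # windows fully inside [FPL, OPL)
    first = math.ceil(scoreset.fpl_sample / win_samples)
    last = math.floor(scoreset.opl_sample / win_samples)  # exclusive
    stages = scoreset.stages[first:last]
    n = len(stages)

    time_in_bed = n * win_s
    is_sleep = np.isin(stages, list(SLEEP_STAGES))
    tst = float(is_sleep.sum() * win_s)
    efficiency = tst / time_in_bed if time_in_bed > 0 else 0.0

    onset_idx = int(np.argmax(is_sleep)) if is_sleep.any() else None
    sleep_latency = None if onset_idx is None else onset_idx * win_s

    rem_latency = None
    if onset_idx is not None:
        rem = np.flatnonzero(stages[onset_idx:] == STAGE_REM)
        if rem.size:
            rem_latency = float(rem[0] * win_s)

    per_stage = {
        code: float(np.sum(stages == code) * win_s) for code in sorted(VALID_STAGES)
    }
    pct = {
        code: (per_stage[code] / tst * 100.0 if tst > 0 and code in SLEEP_STAGES else None)
        for code in sorted(VALID_STAGES)
    }

    n_awakenings = 0
    if onset_idx is not None:
        wake = stages[onset_idx:] == STAGE_WAKE
        # count rising edges of wake runs
        n_awakenings = int(np.sum(wake[1:] & ~wake[:-1]) + (1 if wake[0] else 0))

    return {
        "scorer_id": scoreset.scorer_id,
        "time_in_bed": float(time_in_bed),
        "total_sleep_time": tst,
        "sleep_efficiency": float(efficiency),
        "sleep_latency": sleep_latency,
        "rem_latency": rem_latency,
        "stage_duration_s": per_stage,
        "stage_pct_tst": pct,
        "n_awakenings": n_awakenings,
    }


def write_score_table(scoreset: ScoreSet, path) -> None:
    """Export as plain TSV: header + one row per window."""
    with open(path, "w") as fh:
        fh.write("window_index\tstage\tartefact_flag\n")
        for i, (s, a) in enumerate(zip(scoreset.stages, scoreset.artefact_flags)):
            fh.write(f"{i}\t{int(s)}\t{int(a)}\n")


def read_score_table(
    path, scorer_id: str, window_length_s: float = 30.0
) -> ScoreSet:
    """Import external scores (e.g. automatic scorers) from a TSV table."""
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        has_flag = "artefact_flag" in header
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rows.append((int(parts[0]), int(parts[1]), int(parts[2]) if has_flag else 0))
    if not rows:
        return new_scoreset(scorer_id, 0.0, window_length_s)
    n = max(r[0] for r in rows) + 1
    stages = np.full(n, STAGE_UNSCORED, dtype=np.int64)
    flags = np.zeros(n, dtype=bool)
    for idx, stage, flag in rows:
        stages[idx] = stage
        flags[idx] = bool(flag)
    return ScoreSet(scorer_id, window_length_s, stages, flags)
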