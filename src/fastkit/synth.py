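"""Synthetic recordings with known ground truth.

Everything downstream — artefact correctors, the QRS detector, the
slow-wave detector — is validated against signals generated here, so the
generators return both the contaminated recording and the exact truth
(trigger onsets, templates, beat times, injected delays).  All of them
are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ArraySource, ChannelInfo, ChannelKind, Event, Recording

__all__ = [
    "DEFAULT_CHANNEL_NAMES",
    "gen_background",
    "empty_recording",
    "inject_gradient_artefact",
    "inject_pulse_artefact",
    "SlowWaveSpec",
    "sw_waveform",
    "inject_slow_waves",
    "write_truth",
]

DEFAULT_CHANNEL_NAMES = [
    "Fp1", "Fp2", "AF3", "AF4", "F3", "Fz", "F4",
    "FC3", "C3", "CP3", "FC4", "C4", "CP4",
    "P3", "Pz", "P4", "POz", "O1", "O2", "M1", "M2",
    "EOG1", "EOG2", "EMG1", "EMG2",
]

_KIND_BY_PREFIX = {"EOG": ChannelKind.EOG, "EMG": ChannelKind.EMG, "ECG": ChannelKind.ECG}


def _make_channels(n_channels: int, names: Optional[Sequence[str]]) -> list[ChannelInfo]:
    if names is None:
        names = list(DEFAULT_CHANNEL_NAMES)
        while len(names) < n_channels:
            names.append(f"Ch{len(names) + 1}")
        names = names[:n_channels]
    kinds = []
    for nm in names:
        kind = ChannelKind.EEG
        for prefix, k in _KIND_BY_PREFIX.items():
            if nm.upper().startswith(prefix):
                kind = k
        kinds.append(kind)
    return [ChannelInfo(name=nm, kind=k) for nm, k in zip(names, kinds)]


def gen_background(
    n_channels: int,
    fs: float,
    duration_s: float,
    seed: int,
    rms_uv: float = 15.0,
    channel_names: Optional[Sequence[str]] = None,
) -> Recording:
    """1/f-shaped Gaussian background EEG, RMS ~= 15 uV per channel."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    data = np.zeros((n_channels, n))
    if rms_uv > 0 and n > 1:
        freqs = np.fft.rfftfreq(n, 1 / fs)
        shaping = np.zeros_like(freqs)
        shaping[1:] = 1.0 / np.sqrt(freqs[1:])
        for c in range(n_channels):
            spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
            x = np.fft.irfft(spec * shaping, n=n)
            x *= rms_uv / np.sqrt(np.mean(x ** 2))
            data[c] = x
    return Recording(
        sampling_rate=fs,
        channels=_make_channels(n_channels, channel_names),
        source=ArraySource(data),
        history=[f"gen_background seed={seed}"],
    )


def empty_recording(
    n_channels: int, fs: float, duration_s: float,
    channel_names: Optional[Sequence[str]] = None,
) -> Recording:
    """All-zero recording; convenient substrate for boundary sweeps."""
    return gen_background(n_channels, fs, duration_s, seed=0, rms_uv=0.0,
                          channel_names=channel_names)


def _smooth_template(rng: np.random.Generator, n: int, n_knots: int = 24) -> np.ndarray:
    """Zero-mean smooth random waveform (cubic-interpolated knots)."""
    from scipy.interpolate import CubicSpline

    knots_t = np.linspace(0, n, n_knots, endpoint=False)
    knots_v = rng.standard_normal(n_knots)
    cs = CubicSpline(np.append(knots_t, n), np.append(knots_v, knots_v[0]),
                     bc_type="periodic")
    w = cs(np.arange(n))
    w -= w.mean()
    return w / np.max(np.abs(w))


def inject_gradient_artefact(
    rec: Recording,
    tr_s: float,
    amplitude_uv: float = 5000.0,
    episode_s: Optional[tuple[float, float]] = None,
    waveform_seed: int = 0,
    trigger_label: str = "fmri_volume_trigger",
) -> tuple[Recording, dict]:
    """Add a strictly TR-periodic gradient-artefact waveform.

    The identical seeded template is added for every volume inside the
    episode (whole recording by default); volume trigger events are
    written.  Returns the contaminated recording plus truth
    ``{"onsets", "template", "tr_samples"}``.
    """
    fs = rec.sampling_rate
    rng = np.random.default_rng(waveform_seed)
    tr_samples = int(round(tr_s * fs))
    s0, s1 = (0, rec.n_samples) if episode_s is None else (
        int(round(episode_s[0] * fs)), int(round(episode_s[1] * fs))
    )
    n_volumes = (s1 - s0) // tr_samples
    template = _smooth_template(rng, tr_samples) * amplitude_uv

    data = rec.source.read(range(len(rec.channels)), 0, rec.n_samples)
    onsets = [s0 + k * tr_samples for k in range(n_volumes)]
    for on in onsets:
        data[:, on : on + tr_samples] += template
    events = list(rec.events) + [Event(label=trigger_label, onset=on) for on in onsets]
    out = rec.with_source(ArraySource(data))
    out.events = events
    out.log(f"inject_gradient_artefact tr={tr_s} amp={amplitude_uv}")
    truth = {"onsets": onsets, "template": template, "tr_samples": tr_samples}
    return out, truth


def _ecg_waveform(fs: float, rr_s: float) -> np.ndarray:
    """One cardiac cycle: P, QRS and T bumps; R peak at sample 0."""
    n = int(round(rr_s * fs))
    t = np.arange(n) / fs
    def bump(center, sigma, amp):
        return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    x = (
        bump(0.0, 0.012, 800.0)        # R
        - bump(0.035, 0.015, 120.0)    # S
        - bump(rr_s - 0.045, 0.015, 80.0)  # Q of next beat's complex tail
        + bump(0.30, 0.05, 150.0)      # T
        + bump(rr_s - 0.20, 0.04, 60.0)  # P preceding next beat
    )
    return x


def inject_pulse_artefact(
    rec: Recording,
    bpm: float = 60.0,
    variability: float = 0.1,
    seed: int = 0,
    artefact_amp_uv: float = 30.0,
    ecg_name: str = "ECG",
) -> tuple[Recording, dict]:
    """Add a synthetic ECG channel and a beat-locked pulse artefact.

    The artefact template is a per-channel sum of Gaussian bumps over the
    cardiac cycle (a few tens of uV, energy around 1-2 Hz); each beat's
    instance is scaled by multiplicative lognormal jitter so the artefact
    varies from heartbeat to heartbeat.  Returns the recording (ECG channel
    appended) and truth ``{"beats", "beat_scales", "templates"}``.
    """
    rng = np.random.default_rng(seed)
    fs = rec.sampling_rate
    n = rec.n_samples
    rr_mean = 60.0 / bpm

    beats = []
    t = 0.05 * rr_mean
    while t < n / fs - rr_mean:
        beats.append(int(round(t * fs)))
        # variability drives per-beat amplitude jitter; keep timing jitter
        # small (sub-sample scale) so the artefact stays beat-locked
        t += rr_mean * (1 + 0.01 * variability * rng.standard_normal())
    beats = np.asarray(beats, dtype=np.int64)

    n_eeg = len(rec.channels)
    cycle = int(round(rr_mean * fs))
    tt = np.arange(cycle) / fs
    templates = np.zeros((n_eeg, cycle))
    for c in range(n_eeg):
        n_bumps = rng.integers(2, 4)
        for _ in range(n_bumps):
            center = rng.uniform(0.1, 0.8) * rr_mean
            sigma = rng.uniform(0.05, 0.15) * rr_mean
            amp = rng.uniform(0.4, 1.0) * artefact_amp_uv * rng.choice([-1, 1])
            templates[c] += amp * np.exp(-0.5 * ((tt - center) / sigma) ** 2)

    scales = np.exp(variability * rng.standard_normal(len(beats)))
    if variability == 0:
        scales = np.ones(len(beats))

    data = rec.source.read(range(n_eeg), 0, n)
    ecg = np.zeros(n)
    ecg_cycle = _ecg_waveform(fs, rr_mean)
    for k, b in enumerate(beats):
        ln = min(cycle, n - b)
        data[:, b : b + ln] += scales[k] * templates[:, :ln]
        ecg[b : b + ln] += ecg_cycle[:ln]

    channels = list(rec.channels) + [ChannelInfo(name=ecg_name, kind=ChannelKind.ECG, scale_group="ecg")]
    out = Recording(
        sampling_rate=fs,
        channels=channels,
        source=ArraySource(np.vstack([data, ecg[None, :]])),
        start_clock_time=rec.start_clock_time,
        events=[e for e in rec.events],
        scores=list(rec.scores),
        history=list(rec.history),
    )
    out.log(f"inject_pulse_artefact bpm={bpm} variability={variability}")
    truth = {"beats": beats, "beat_scales": scales, "templates": templates}
    return out, truth


@dataclass
class SlowWaveSpec:
    """Ground-truth description of one injected biphasic wave."""

    time_s: float                      # down-crossing time
    neg_peak_uv: float = -100.0        # negative lobe amplitude (signed)
    p2p_uv: float = 160.0
    zx_separation_s: float = 0.5
    pos_peak_lag_s: float = 0.4        # up-crossing to positive peak
    channels: Optional[list[str]] = None  # None = all EEG channels
    delays_s: dict = field(default_factory=dict)  # per-electrode extra delay


def sw_waveform(
    fs: float,
    neg_peak_uv: float,
    p2p_uv: float,
    zx_separation_s: float,
    pos_peak_lag_s: float,
) -> np.ndarray:
    """Biphasic pulse: negative half-sine then positive half-sine.

    Starts at the down-going zero crossing; the negative lobe spans
    ``zx_separation_s``, the positive lobe peaks ``pos_peak_lag_s`` after
    the up-crossing and returns to zero symmetrically.
    """
    n_neg = int(round(zx_separation_s * fs))
    n_pos = int(round(2 * pos_peak_lag_s * fs))
    a = abs(neg_peak_uv)
    p = p2p_uv - a
    t_neg = np.arange(n_neg)
    t_pos = np.arange(n_pos)
    wave = np.concatenate([
        -a * np.sin(np.pi * t_neg / n_neg),
        p * np.sin(np.pi * t_pos / n_pos) if n_pos else np.zeros(0),
    ])
    return wave


def inject_slow_waves(
    rec: Recording, wave_specs: Sequence[SlowWaveSpec]
) -> tuple[Recording, list[dict]]:
    """Add biphasic waves at known times/amplitudes/per-electrode delays."""
    fs = rec.sampling_rate
    data = rec.source.read(range(len(rec.channels)), 0, rec.n_samples)
    names = rec.channel_names
    truth = []
    for spec in wave_specs:
        wave = sw_waveform(fs, spec.neg_peak_uv, spec.p2p_uv,
                           spec.zx_separation_s, spec.pos_peak_lag_s)
        targets = spec.channels
        if targets is None:
            targets = [c.name for c in rec.channels if c.kind is ChannelKind.EEG]
        entry = {"spec": asdict(spec), "onsets": {}}
        for name in targets:
            ci = names.index(name)
            delay = spec.delays_s.get(name, 0.0)
            on = int(round((spec.time_s + delay) * fs))
            ln = min(len(wave), rec.n_samples - on)
            if on < 0 or ln <= 0:
                continue
            data[ci, on : on + ln] += wave[:ln]
            entry["onsets"][name] = on
        truth.append(entry)
    out = rec.with_source(ArraySource(data))
    out.log(f"inject_slow_waves n={len(wave_specs)}")
    return out, truth


def write_truth(truth, path) -> None:
    """Serialize a truth object beside its recording (JSON, arrays -> lists)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(truth, fh, default=default)
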