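"""Shared fixtures: generated BrainVision files and brute-force oracles."""

import numpy as np
import pytest


def write_brainvision(
    tmpdir,
    data_int16,
    fs=500.0,
    resolutions=None,
    channel_names=None,
    markers=(),
    orientation="MULTIPLEXED",
    binary_format="INT_16",
    marker_file=True,
):
    """Write a .vhdr/.vmrk/.eeg triple from an int16 (channels x samples) array.

    ``markers`` is a list of (type, description, position_1based, points,
    channel, date) tuples; trailing fields may be omitted.
    """
    data = np.asarray(data_int16)
    n_channels, n_samples = data.shape
    if resolutions is None:
        resolutions = [1.0] * n_channels
    if channel_names is None:
        channel_names = [f"Ch{i + 1}" for i in range(n_channels)]
    base = tmpdir / "rec"
    eeg = base.with_suffix(".eeg")
    vhdr = base.with_suffix(".vhdr")
    vmrk = base.with_suffix(".vmrk")

    if binary_format == "INT_16":
        arr = data.astype("<i2")
    else:
        arr = data.astype("<f4")
    if orientation == "MULTIPLEXED":
        arr = np.ascontiguousarray(arr.T)
    eeg.write_bytes(arr.tobytes())

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
    ]
    if marker_file:
        lines.append(f"MarkerFile={vmrk.name}")
    lines += [
        "DataFormat=BINARY",
        f"DataOrientation={orientation}",
        f"NumberOfChannels={n_channels}",
        f"SamplingInterval={1e6 / fs:g}",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "[Channel Infos]",
    ]
    for i, (name, res) in enumerate(zip(channel_names, resolutions)):
        lines.append(f"Ch{i + 1}={name},,{res},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    if marker_file:
        mlines = [
            "Brain Vision Data Exchange Marker File, Version 1.0",
            "[Common Infos]",
            f"DataFile={eeg.name}",
            "[Marker Infos]",
        ]
        for k, m in enumerate(markers):
            fields = list(m) + [""] * (6 - len(m))
            mlines.append(
                f"Mk{k + 1}={fields[0]},{fields[1]},{fields[2]},{fields[3]},"
                f"{fields[4]},{fields[5]}".rstrip(",")
            )
        vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr


@pytest.fixture
def bv_writer(tmp_path):
    def _write(data_int16, **kw):
        return write_brainvision(tmp_path, data_int16, **kw)

    return _write


def brute_force_sw_validate(
    x,
    fs,
    down_idx,
    up_idx,
    *,
    episode_max_slope,
    sep_range=(0.25, 1.25),
    neg_thresh=-80.0,
    p2p_thresh=140.0,
    slope_frac=0.90,
    max_lag=2.0,
):
    """Independent per-sample re-check of the five criteria for one wave.

    Works directly on the raw samples with explicit loops — deliberately
    naive and separate from the detector's implementation.
    """
    # criterion 1: zero-crossing separation (interpolated)
    def cross_t(i):
        a, b = x[i - 1], x[i]
        return (i - 1 + (a / (a - b) if a != b else 0.0)) / fs

    sep = cross_t(up_idx) - cross_t(down_idx)
    if not sep_range[0] <= sep <= sep_range[1]:
        return False, "separation"
    # criterion 2: negative peak strictly below threshold
    neg_v = min(x[down_idx:up_idx])
    if not neg_v < neg_thresh:
        return False, "neg_peak"
    # positive peak: scan forward until signal goes negative again
    j = up_idx
    while j < len(x) and x[j] >= 0:
        j += 1
    if j == up_idx:
        return False, "no_positive_phase"
    pos_k = up_idx + int(np.argmax(x[up_idx:j]))
    # criterion 3
    if not (x[pos_k] - neg_v) > p2p_thresh:
        return False, "p2p"
    # criterion 5 (inclusive)
    if pos_k / fs - cross_t(up_idx) > max_lag + 1e-9:
        return False, "pos_lag"
    # criterion 4 vs supplied episode reference
    neg_k = down_idx + int(np.argmin(x[down_idx:up_idx]))
    slopes = [
        (x[k + 1] - x[k]) * fs for k in range(min(neg_k, pos_k), max(neg_k, pos_k))
    ]
    if not slopes or max(slopes) <= slope_frac * episode_max_slope * (1 + 1e-9):
        return False, "slope"
    return True, "ok"
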