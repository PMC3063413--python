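"""Lab defaults: channel scales, bipolar pairs, ROI lists, method defaults.

Everything a site would normally tweak lives in one editable YAML file;
:func:`load_config` merges it over the built-in defaults.  Resolution
order used by the CLI is config file < environment < command-line flags.
"""

from __future__ import annotations

import copy
import os
from pathlib import Path
from typing import Optional

import yaml

from .slow_waves import DEFAULT_ROI_MAP

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    "scales_uv": {"EEG": 75.0, "EOG": 150.0, "EMG": 150.0, "ECG": 1000.0, "OTHER": 100.0},
    "bipolar_pairs": [["EOG1", "EOG2"], ["EMG1", "EMG2"]],
    "roi_map": {k: list(v) for k, v in DEFAULT_ROI_MAP.items()},
    "mastoids": ["M1", "M2"],
    "ga": {
        "n_average_volumes": 30,
        "detect_window_s": 1.0,
        "detect_threshold_uv": 350.0,
        "target_rate_hz": 500.0,
    },
    "pa": {
        "method": "combined",
        "n_obs_components": 4,
        "gm_window_beats": 21,
        "gm_sigma_beats": 5.0,
        "split_hz": 4.0,
    },
    "spectrogram": {"subwindow_s": 4.0, "overlap_frac": 0.5, "window_s": 30.0},
    "scoring": {"window_length_s": 30.0},
    "sw": {
        "band_hz": [0.25, 4.0],
        "zx_separation_s": [0.25, 1.25],
        "neg_peak_uv": -80.0,
        "p2p_uv": 140.0,
        "slope_frac": 0.90,
        "pos_peak_max_lag_s": 2.0,
        "electrode_match_window_s": 0.3,
    },
}

ENV_VAR = "FASTKIT_CONFIG"


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: Optional[str] = None) -> dict:
    """Built-in defaults, overridden by a YAML file (arg or $FASTKIT_CONFIG)."""
    cfg = copy.deepcopy(DEFAULTS)
    path = path or os.environ.get(ENV_VAR)
    if path:
        with open(Path(path)) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg
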