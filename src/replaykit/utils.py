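"""Shared numeric helpers used across the pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def compute_speed(t: np.ndarray, x_cm: np.ndarray, smooth_s: float = 0.4) -> np.ndarray:
    """Running speed (cm/s) from tracked positions.

    Central difference of position followed by a boxcar average of width
    ``smooth_s``. Both the 10 cm/s running gate and the 3 cm/s immobility gate
    are applied to this smoothed estimate.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x_cm, dtype=float)
    if t.size < 2:
        return np.zeros_like(t)
    speed = np.abs(np.gradient(x, t))
    dt = np.median(np.diff(t))
    win = max(1, int(round(smooth_s / dt)))
    if win > 1:
        kernel = np.ones(win) / win
        # edge-renormalized boxcar so boundary samples are unbiased
        num = np.convolve(speed, kernel, mode="same")
        den = np.convolve(np.ones_like(speed), kernel, mode="same")
        speed = num / den
    return speed


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
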