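"""Dynamic (time-series) SpO2 estimation with smoothing filters.

Frames arrive at the sensor cadence (0.7 s per reading: 0.6 s integration
plus 0.1 s compute).  Each frame is normalized, classified, and
expectation-decoded to a raw SpO2 value; a median filter removes isolated
spikes and a trailing moving average suppresses residual jitter, in that
order.  Both filters are length-preserving with truncated windows at the
edges, which keeps the output causal enough for a live display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import model as model_mod
from .preprocess import RegionSpec, normalize, select_region
from .simulator import SpectralFrame

__all__ = ["StreamConfig", "median_filter", "moving_average", "stream_estimate"]


@dataclass(frozen=True)
class StreamConfig:
    median_window: int = 5
    ma_window: int = 5
    sampling_interval_s: float = 0.7

    def __post_init__(self):
        if self.median_window < 1 or self.ma_window < 1:
            raise ValueError("filter windows must be >= 1")
        if self.median_window % 2 == 0:
            raise ValueError("median_window must be odd")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")


def median_filter(series: Sequence[float], window: int) -> np.ndarray:
    """Sliding median, window truncated at the edges; length preserved."""
    x = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("median window must be odd")
    if window < 1 or window > len(x):
        raise ValueError("window must be in [1, len(series)]")
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        # shrink symmetrically at the edges so the window stays odd
        h = min(half, i, len(x) - 1 - i)
        out[i] = np.median(x[i - h : i + h + 1])
    return out


def moving_average(series: Sequence[float], window: int) -> np.ndarray:
    """Trailing mean with truncated warm-up; length preserved."""
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(x):
        raise ValueError("window must not exceed the series length")
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty_like(x)
    for i in range(len(x)):
        lo = max(0, i - window + 1)
        out[i] = (c[i + 1] - c[lo]) / (i + 1 - lo)
    return out


def stream_estimate(
    model: "model_mod.TrainedModel",
    frames: Sequence[SpectralFrame],
    region: RegionSpec,
    cfg: StreamConfig | None = None,
) -> pd.DataFrame:
    """Per-frame raw and filtered SpO2 over a time-ordered frame sequence.

    Returns a DataFrame with columns ``timestamp``, ``raw``, ``filtered``;
    timestamps are spaced by the configured sampling interval starting at
    the first frame's timestamp.
    """
    cfg = cfg or StreamConfig()
    if len(region) != model.input_length:
        raise ValueError("frame region width does not match the model input")
    X = normalize(select_region(frames, region))
    raw = model_mod.decode_batch(model, X)
    filtered = moving_average(median_filter(raw, cfg.median_window), cfg.ma_window)
    t0 = frames[0].timestamp if frames else 0.0
    ts = t0 + cfg.sampling_interval_s * np.arange(len(raw))
    return pd.DataFrame({"timestamp": ts, "raw": raw, "filtered": filtered})
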