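"""Time-normalized, ensemble-averaged tangential-speed profiles.

Speed profiles of the hand and of each whip marker are resampled onto a
common normalized-time grid and averaged across the trials of one
participant and style.  Whip profiles span the throw interval (throw onset
to minimum distance); hand profiles span the full trial.  All trials are
aligned at the moment of minimum distance, which maps to the last sample
(normalized time 0, with time running backwards toward -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Trial

__all__ = ["SpeedProfile", "time_normalize", "average_profiles", "profiles_table"]

N_SAMPLES = 500
MIN_SPAN_FRAMES = 10


@dataclass
class SpeedProfile:
    """Mean +- SD speed curve on the normalized-time grid [-1, 0]."""

    normalized_time: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_trials: int
    span: str  # "throw" | "trial"
    marker: str = ""

    def peak_sample(self) -> int:
        """Grid index of the mean profile's maximum (earliest on ties)."""
        return int(np.nanargmax(self.mean))


def time_normalize(
    series: np.ndarray, start: int, end: int, n_samples: int = N_SAMPLES
) -> np.ndarray:
    """Linearly resample ``series[start:end+1]`` onto ``n_samples`` points.

    Endpoint values are preserved exactly; interior NaN runs are bridged by
    linear interpolation (a trial with fully gapped speed should be skipped
    by the caller).
    """
    if end - start < 1:
        raise ValueError("span must cover at least 2 frames")
    seg = np.asarray(series[start : end + 1], dtype=float)
    nan = np.isnan(seg)
    if nan.all():
        raise ValueError("speed series fully gapped on span")
    idx = np.arange(len(seg))
    if nan.any():
        seg = seg.copy()
        seg[nan] = np.interp(idx[nan], idx[~nan], seg[~nan])
    grid = np.linspace(0, len(seg) - 1, n_samples)
    return np.interp(grid, idx, seg)


def _trial_span(trial: Trial, span: str) -> tuple[int, int]:
    if span == "throw":
        if trial.landmarks is None:
            raise ValueError("throw span requires landmarks")
        return trial.landmarks.throw_onset, trial.end_frame
    return trial.start_frame, trial.end_frame


def average_profiles(
    trials: list[Trial],
    speed: np.ndarray,
    span: str = "throw",
    n_samples: int = N_SAMPLES,
    marker: str = "",
) -> SpeedProfile:
    """Per-sample mean and sample SD of speed across eligible trials.

    Trials flagged ``excluded`` or ``profile_excluded`` and spans shorter
    than 10 frames are skipped.  With zero eligible trials an empty profile
    (``n_trials=0``) is returned.
    """
    grid = np.linspace(-1.0, 0.0, n_samples)
    rows = []
    for t in trials:
        if t.excluded or t.profile_excluded:
            continue
        s, e = _trial_span(t, span)
        if e - s < MIN_SPAN_FRAMES:
            continue
        try:
            rows.append(time_normalize(speed, s, e, n_samples))
        except ValueError:
            continue
    if not rows:
        nanrow = np.full(n_samples, np.nan)
        return SpeedProfile(grid, nanrow, nanrow, 0, span, marker)
    stack = np.asarray(rows)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(n_samples)
    return SpeedProfile(grid, mean, sd, len(rows), span, marker)


def profiles_table(profiles: list[SpeedProfile], **keys: str) -> pd.DataFrame:
    """Long-format export of a set of profiles (one row per grid sample)."""
    frames = []
    for p in profiles:
        df = pd.DataFrame(
            {
                "marker": p.marker,
                "span": p.span,
                "normalized_time": p.normalized_time,
                "mean": p.mean,
                "sd": p.sd,
                "n_trials": p.n_trials,
            }
        )
        for k, v in keys.items():
            df[k] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
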