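"""Per-trial and per-block outcome metrics for the whip task.

Per trial: error (minimum whip-to-target distance), hit (target-spring
oscillation), whip extension and azimuth at peak hand speed, hand azimuth,
peak hand and tip speeds, inter-trial interval.  Per block: success rate
(percent hits) and rhythmicity (coefficient of variation of the
inter-trial interval).

Conventions: azimuth 0 deg = whip/hand axis pointing straight backward
(away from the target), positive toward the participant's right; extension
is the h1 -> w1 Euclidean distance at the peak-hand-speed landmark (the
w1 -> w10 chord divided by arclength is exposed as an alternative ratio);
tip speed is measured on w2 (the tip marker w1 is too noisy to
differentiate reliably).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .geometry import azimuth_of_direction, fit_line_svd
from .mocap_io import MarkerDataset
from .segmentation import Trial, whip_target_distance

__all__ = [
    "TrialMetrics",
    "MetricUndefinedError",
    "minimum_distance_error",
    "detect_hit",
    "whip_extension",
    "whip_azimuth",
    "hand_azimuth",
    "peak_speeds",
    "inter_trial_intervals",
    "rhythmicity",
    "success_rate",
    "metrics_table",
    "summarize_blocks",
]

LANDMARK_FALLBACK = 5  # frames either side for landmark-instant averaging
HAND_AXIS_WINDOW = 15  # frames either side for the short hand-handle axis
HIT_BAND_HZ = (1.0, 8.0)  # band around the target spring's free frequency
HIT_THRESHOLD = 0.005  # m, post-contact oscillation amplitude above baseline
HIT_WINDOW = 0.8  # s, analysis window after trial end


class MetricUndefinedError(ValueError):
    """Required markers are gapped so the metric is undefined."""


@dataclass
class TrialMetrics:
    """Scalar outcomes of a single trial."""

    error: float
    hit: bool
    extension: float
    extension_ratio: float
    whip_azimuth: float
    hand_azimuth: float
    peak_hand_speed: float
    peak_tip_speed: float
    inter_trial_interval: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _valid_at(series: np.ndarray, frame: int, fallback: int = LANDMARK_FALLBACK) -> np.ndarray:
    """Value at ``frame``, or the nearest valid frame within ``fallback``."""
    if not np.isnan(series[frame]).any():
        return series[frame]
    for off in range(1, fallback + 1):
        for f in (frame - off, frame + off):
            if 0 <= f < len(series) and not np.isnan(series[f]).any():
                return series[f]
    raise MetricUndefinedError(f"no valid sample within +-{fallback} frames of {frame}")


def _mean_window(series: np.ndarray, frame: int, half: int) -> np.ndarray:
    """Mean position over the valid frames within ``frame +- half``.

    Landmark-instant geometry is estimated from a short symmetric window
    rather than a single frame: marker noise averages out, while a
    symmetric window is unbiased under the locally constant rotation rate
    that holds around the peak-hand-speed landmark.
    """
    lo, hi = max(0, frame - half), min(len(series), frame + half + 1)
    seg = series[lo:hi]
    valid = ~np.isnan(seg).any(axis=1)
    if not valid.any():
        raise MetricUndefinedError(
            f"no valid sample within +-{half} frames of {frame}"
        )
    return seg[valid].mean(axis=0)


def minimum_distance_error(
    dataset: MarkerDataset,
    trial: Trial,
    span: str = "trial",
    distance: np.ndarray | None = None,
) -> float:
    """Minimum distance between the interpolated distal whip and the target.

    The whip between its three distal markers (w1-w3) and the target
    between its two distal markers (t1-t2) are treated as continuous
    chains; the minimum pairwise distance over the frames of the trial (or
    of the throw interval when ``span="throw"`` and landmarks are set) is
    returned in metres.
    """
    d = distance if distance is not None else whip_target_distance(dataset)
    s, e = trial.start_frame, trial.end_frame
    if span == "throw":
        if trial.landmarks is None:
            raise ValueError("throw span requires landmarks")
        s = trial.landmarks.throw_onset
    seg = d[s : e + 1]
    if np.isnan(seg).all():
        raise MetricUndefinedError("distal whip markers gapped for entire trial")
    return float(np.nanmin(seg))


def detect_hit(
    dataset: MarkerDataset,
    trial: Trial,
    band_hz: tuple[float, float] = HIT_BAND_HZ,
    threshold: float = HIT_THRESHOLD,
    window: float = HIT_WINDOW,
) -> bool:
    """Detect a target hit from post-contact oscillation of marker t1.

    The t1 trajectory is band-passed around the spring's free oscillation
    band; a hit is declared when the oscillation envelope in the ``window``
    seconds after the trial end exceeds the pre-trial baseline envelope by
    ``threshold`` metres.
    """
    fs = dataset.sampling_rate
    t1 = dataset.marker("t1")
    if np.isnan(t1).all():
        raise MetricUndefinedError("target marker t1 fully gapped")
    # displacement magnitude about the quasi-static position
    idx = np.arange(len(t1))
    t1f = t1.copy()
    for k in range(3):
        nan = np.isnan(t1f[:, k])
        if nan.any():
            t1f[nan, k] = np.interp(idx[nan], idx[~nan], t1f[~nan, k])
    sos = _sig.butter(2, band_hz, btype="bandpass", fs=fs, output="sos")
    osc = np.linalg.norm(_sig.sosfiltfilt(sos, t1f, axis=0), axis=1)
    w = int(round(window * fs))
    e = trial.end_frame
    post = osc[e : min(e + w, len(osc))]
    pre_start = max(0, trial.start_frame - w)
    pre = osc[pre_start : max(pre_start + 1, trial.start_frame)]
    if len(post) == 0:
        raise MetricUndefinedError("no frames after trial end for hit detection")
    baseline = float(np.max(pre)) if len(pre) else 0.0
    return bool(np.max(post) - baseline > threshold)


def _landmark_frame(trial: Trial) -> int:
    if trial.landmarks is None:
        raise ValueError("trial has no landmarks; run find_landmarks first")
    return trial.landmarks.peak_hand_speed


def whip_extension(dataset: MarkerDataset, trial: Trial) -> tuple[float, float]:
    """Whip extension at peak hand speed.

    Returns ``(extension, ratio)``: the h1 -> w1 Euclidean distance in
    metres, and the alternative w1 -> w10 chord divided by the whip
    arclength (dimensionless).  Nearby valid frames (within +-5) substitute
    for gapped endpoints.
    """
    frame = _landmark_frame(trial)
    h1 = _mean_window(dataset.marker("h1"), frame, LANDMARK_FALLBACK)
    w1 = _mean_window(dataset.marker("w1"), frame, LANDMARK_FALLBACK)
    w10 = _mean_window(dataset.marker("w10"), frame, LANDMARK_FALLBACK)
    ext = float(np.linalg.norm(w1 - h1))
    ratio = float(np.linalg.norm(w1 - w10) / dataset.schema.whip_arclength)
    return ext, ratio


def whip_azimuth(dataset: MarkerDataset, trial: Trial) -> float:
    """Whip azimuth at peak hand speed, in degrees.

    A line is fitted through the whip and handle markers (w1..w10 and h1)
    by singular value decomposition; its horizontal projection is oriented
    handle -> tip and measured against the target direction (0 deg =
    straight backward, positive to the right).
    """
    frame = _landmark_frame(trial)
    pts = []
    for name in [f"w{i}" for i in range(1, 11)] + ["h1"]:
        try:
            pts.append(_mean_window(dataset.marker(name), frame, LANDMARK_FALLBACK))
        except MetricUndefinedError:
            continue
    _, direction = fit_line_svd(np.asarray(pts))
    # orient handle -> tip: positive along (w1-ish minus h1-ish) span
    chain = np.asarray(pts)
    span = chain[0] - chain[-1]  # first entry is most distal available
    if np.dot(direction, span) < 0:
        direction = -direction
    return azimuth_of_direction(direction)


def hand_azimuth(dataset: MarkerDataset, trial: Trial) -> float:
    """Hand-handle azimuth at peak hand speed, in degrees.

    The hand and handle markers define a rigid body whose long axis runs
    from the proximal cluster (h2 and the hand markers) toward the handle
    front (mean of w10 and h1); the angle of its horizontal projection is
    measured relative to the sagittal line from the target to the body,
    with the same sign convention as the whip azimuth.
    """
    frame = _landmark_frame(trial)
    # the hand-handle axis is short (~0.25 m) and built from few markers,
    # so its orientation needs a wider averaging window than the whip fit
    half = HAND_AXIS_WINDOW
    front = 0.5 * (
        _mean_window(dataset.marker("w10"), frame, half)
        + _mean_window(dataset.marker("h1"), frame, half)
    )
    back_names = ["h2"] + [
        n for n in dataset.schema.marker_names if n.startswith("hand")
    ]
    back = np.mean(
        [_mean_window(dataset.marker(n), frame, half) for n in back_names], axis=0
    )
    return azimuth_of_direction(front - back)


def peak_speeds(
    trial: Trial, hand_speed: np.ndarray, tip_speed: np.ndarray
) -> tuple[float, float]:
    """Peak hand and whip-tip (w2) tangential speeds over the trial."""
    s, e = trial.start_frame, trial.end_frame
    hs = hand_speed[s : e + 1]
    ts = tip_speed[s : e + 1]
    if np.isnan(hs).all() or np.isnan(ts).all():
        raise MetricUndefinedError("speed series fully gapped within trial")
    return float(np.nanmax(hs)), float(np.nanmax(ts))


def inter_trial_intervals(trials: list[Trial], sampling_rate: float) -> np.ndarray:
    """Start-to-start times between consecutive trials, in seconds.

    In the rhythmic style these coincide with trial durations; in the
    discrete style they include the return and pause between throws.
    """
    starts = np.array([t.start_frame for t in trials], dtype=float)
    return np.diff(np.sort(starts)) / sampling_rate


def rhythmicity(trials: list[Trial], sampling_rate: float) -> float:
    """Coefficient of variation (sample SD / mean) of inter-trial intervals."""
    iti = inter_trial_intervals(trials, sampling_rate)
    if len(iti) < 2:
        raise MetricUndefinedError("need >=2 intervals (>=3 trials) for CoV")
    return float(np.std(iti, ddof=1) / np.mean(iti))


def success_rate(hits: list[bool] | np.ndarray) -> float:
    """Percentage of trials in a block that hit the target."""
    hits = np.asarray(hits, dtype=bool)
    if len(hits) == 0:
        raise MetricUndefinedError("no trials")
    return float(100.0 * hits.mean())


def metrics_table(
    dataset: MarkerDataset,
    trials: list[Trial],
    hand_speed: np.ndarray,
    tip_speed: np.ndarray,
) -> pd.DataFrame:
    """Compute :class:`TrialMetrics` for every non-excluded trial.

    Returns a tidy DataFrame with one row per trial (excluded trials keep
    their identity columns with NaN metrics).
    """
    distance = whip_target_distance(dataset)
    starts = np.array([t.start_frame for t in trials], dtype=float)
    rows = []
    for i, t in enumerate(trials):
        row: dict = {
            "participant": t.participant_id,
            "style": t.style,
            "block": t.block_index,
            "trial": t.trial_index,
            "start_frame": t.start_frame,
            "end_frame": t.end_frame,
            "excluded": t.excluded,
            "profile_excluded": t.profile_excluded,
        }
        if not t.excluded:
            try:
                ext, ratio = whip_extension(dataset, t)
                phs, pts_ = peak_speeds(t, hand_speed, tip_speed)
                span = "throw" if t.landmarks is not None else "trial"
                row.update(
                    error=minimum_distance_error(dataset, t, span=span, distance=distance),
                    error_trial=minimum_distance_error(dataset, t, distance=distance),
                    hit=detect_hit(dataset, t),
                    extension=ext,
                    extension_ratio=ratio,
                    whip_azimuth=whip_azimuth(dataset, t),
                    hand_azimuth=hand_azimuth(dataset, t),
                    peak_hand_speed=phs,
                    peak_tip_speed=pts_,
                )
            except (MetricUndefinedError, ValueError) as exc:
                row["metric_error"] = str(exc)
        if i + 1 < len(trials):
            row["inter_trial_interval"] = (
                (starts[i + 1] - starts[i]) / dataset.sampling_rate
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_blocks(table: pd.DataFrame, sampling_rate: float | None = None) -> pd.DataFrame:
    """Per participant/style/block summary of the trial metrics.

    Error and extension are summarized by median/IQR (skewed); azimuths,
    speeds and intervals by mean/SD; plus success rate and rhythmicity.
    """
    out = []
    for (pid, style, block), g in table.groupby(["participant", "style", "block"]):
        g = g[~g["excluded"].astype(bool)]
        row = {"participant": pid, "style": style, "block": block, "n_trials": len(g)}
        if len(g) == 0:
            out.append(row)
            continue
        for col in ("error", "extension"):
            if col in g:
                row[f"{col}_median"] = g[col].median()
                row[f"{col}_iqr"] = g[col].quantile(0.75) - g[col].quantile(0.25)
        for col in (
            "whip_azimuth",
            "hand_azimuth",
            "peak_hand_speed",
            "peak_tip_speed",
            "inter_trial_interval",
        ):
            if col in g:
                row[f"{col}_mean"] = g[col].mean()
                row[f"{col}_sd"] = g[col].std(ddof=1)
        if "hit" in g and g["hit"].notna().any():
            row["success_rate"] = 100.0 * g["hit"].astype(bool).mean()
        iti = g["inter_trial_interval"].dropna() if "inter_trial_interval" in g else []
        if len(iti) >= 2:
            row["rhythmicity"] = float(np.std(iti, ddof=1) / np.mean(iti))
        out.append(row)
    return pd.DataFrame(out)
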