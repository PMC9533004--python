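"""Trial parsing, temporal landmarks and exclusion rules.

A recording block is parsed into trials using the distance between the
distal whip and the target: the instant of minimum whip-to-target distance
ends a trial in both styles.  Discrete trials begin at the last upward
crossing of hand speed through 0.5 m/s just before the whip lifts off the
floor (the three most distal whip markers w1-w3 exceeding 2 cm height);
rhythmic trials begin where the previous one ended.

Three temporal landmarks are located per trial: throw onset (hand at
maximum distance from the target, pointing backward), peak hand speed, and
minimum distance (trial end).  The landmark order
``throw_onset <= peak_hand_speed <= minimum_distance`` is enforced.

Note on marker naming: w1 is the tip marker and w1-w3 are treated as the
distal (tip-side) markers everywhere in this package, for lift detection,
event detection and the error metric alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .geometry import polyline_segment_distance
from .mocap_io import MarkerDataset, gap_report, simultaneous_gap_counts

__all__ = [
    "Trial",
    "Landmarks",
    "LandmarkError",
    "whip_target_distance",
    "detect_minimum_distance_events",
    "parse_discrete",
    "parse_rhythmic",
    "find_landmarks",
    "apply_exclusions",
]

HAND_SPEED_THRESHOLD = 0.5  # m/s, discrete-trial start
LIFT_HEIGHT = 0.02  # m, whip-off-floor criterion on w1-w3
ONSET_SEARCH_WINDOW = 1.0  # s before lift, for the speed crossing
EVENT_REFRACTORY = 0.3  # s between minimum-distance events
MAX_SIMULTANEOUS_GAPS = 5  # markers; more -> trial excluded
MAX_PROFILE_GAP = 200  # frames (0.4 s); longer -> excluded from profiles


class LandmarkError(ValueError):
    """Landmarks could not be located or violate their ordering."""


@dataclass
class Landmarks:
    throw_onset: int
    peak_hand_speed: int
    minimum_distance: int

    def __post_init__(self) -> None:
        if not (self.throw_onset <= self.peak_hand_speed <= self.minimum_distance):
            raise LandmarkError(
                "landmark order violated: "
                f"onset={self.throw_onset}, peak={self.peak_hand_speed}, "
                f"min_dist={self.minimum_distance}"
            )


@dataclass
class Trial:
    """One throw (discrete) or cycle (rhythmic)."""

    style: str  # "discrete" | "rhythmic"
    start_frame: int
    end_frame: int
    participant_id: str = ""
    block_index: int = 1
    trial_index: int = 0
    excluded: bool = False
    exclusion_reason: str = ""
    profile_excluded: bool = False
    landmarks: Landmarks | None = field(default=None)

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("trial start_frame must precede end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def whip_target_distance(dataset: MarkerDataset) -> np.ndarray:
    """Per-frame minimum distance between the distal whip and the target.

    The whip polyline through w1, w2, w3 and the target segment through the
    two distal target markers (t1, t2) are compared exactly (continuous
    closest approach of the interpolated chains).  NaN where the required
    markers are all gapped.
    """
    w = np.stack([dataset.marker(m) for m in ("w1", "w2", "w3")], axis=1)
    return polyline_segment_distance(w, dataset.marker("t1"), dataset.marker("t2"))


def detect_minimum_distance_events(
    distance: np.ndarray,
    sampling_rate: float,
    refractory: float = EVENT_REFRACTORY,
    prominence: float = 0.1,
    max_distance: float | None = None,
) -> np.ndarray:
    """Frames of local minima of a whip-to-target distance series.

    Minima are separated by at least ``refractory`` seconds and must have a
    prominence of at least ``prominence`` metres; ``max_distance``
    optionally rejects minima farther than that from the target.  Returns
    an ordered integer array (possibly empty).
    """
    d = np.asarray(distance, dtype=float)
    filled = d.copy()
    nan = np.isnan(filled)
    if nan.all():
        return np.array([], dtype=int)
    if nan.any():
        idx = np.arange(len(filled))
        filled[nan] = np.interp(idx[nan], idx[~nan], filled[~nan])
    peaks, _ = find_peaks(
        -filled,
        distance=max(1, int(round(refractory * sampling_rate))),
        prominence=prominence,
    )
    if max_distance is not None:
        peaks = peaks[filled[peaks] <= max_distance]
    return peaks.astype(int)


def _upward_crossings(series: np.ndarray, threshold: float) -> np.ndarray:
    s = np.asarray(series, dtype=float)
    below = s[:-1] < threshold
    above = s[1:] >= threshold
    return np.flatnonzero(below & above) + 1


def parse_discrete(
    dataset: MarkerDataset,
    hand_speed: np.ndarray,
    events: np.ndarray,
    speed_threshold: float = HAND_SPEED_THRESHOLD,
    lift_height: float = LIFT_HEIGHT,
    search_window: float = ONSET_SEARCH_WINDOW,
) -> list[Trial]:
    """Parse a discrete-style block into trials.

    Each minimum-distance event ends one trial; the trial starts at the
    last upward crossing of ``hand_speed`` through ``speed_threshold``
    within ``search_window`` seconds before the whip lift (first frame at
    which w1, w2 and w3 all exceed ``lift_height``).  A lift without a
    preceding crossing yields a trial flagged excluded.
    """
    z = np.stack([dataset.marker(m)[:, 2] for m in ("w1", "w2", "w3")], axis=1)
    with np.errstate(invalid="ignore"):
        airborne = np.all(z > lift_height, axis=1)
    lift_edges = np.flatnonzero(np.diff(airborne.astype(int)) == 1) + 1
    if airborne[:1].any():
        lift_edges = np.concatenate(([0], lift_edges))
    crossings = _upward_crossings(hand_speed, speed_threshold)
    window = int(round(search_window * dataset.sampling_rate))

    trials: list[Trial] = []
    prev_end = 0
    for event in np.asarray(events, dtype=int):
        lifts = lift_edges[(lift_edges > prev_end) & (lift_edges <= event)]
        if len(lifts) == 0:
            continue
        lift = int(lifts[0])
        in_window = crossings[(crossings >= max(prev_end, lift - window)) & (crossings <= lift)]
        if len(in_window) == 0:
            trials.append(
                Trial(
                    style="discrete",
                    start_frame=max(prev_end, lift - window),
                    end_frame=int(event),
                    excluded=True,
                    exclusion_reason="no hand-speed crossing before whip lift",
                )
            )
        else:
            trials.append(
                Trial(style="discrete", start_frame=int(in_window[-1]), end_frame=int(event))
            )
        prev_end = int(event)
    for i, t in enumerate(trials):
        t.trial_index = i
    return trials


def parse_rhythmic(events: np.ndarray) -> list[Trial]:
    """Consecutive minimum-distance events bound consecutive trials.

    ``n`` events yield ``n - 1`` trials exactly tiling the inter-event
    span; fewer than 2 events yield an empty list.
    """
    events = np.asarray(events, dtype=int)
    trials = [
        Trial(style="rhythmic", start_frame=int(a), end_frame=int(b), trial_index=i)
        for i, (a, b) in enumerate(zip(events[:-1], events[1:]))
    ]
    return trials


def find_landmarks(
    trial: Trial,
    hand_position: np.ndarray,
    hand_speed: np.ndarray,
    target_position: np.ndarray,
) -> Landmarks:
    """Locate throw onset, peak hand speed and minimum distance for a trial.

    ``hand_position`` is (frames, 3); ``target_position`` is a fixed
    reference point (3,) or a (frames, 3) series.  Ties at equal extrema
    are broken toward the earliest frame; a stationary hand raises
    :class:`LandmarkError`.
    """
    s, e = trial.start_frame, trial.end_frame
    hand = hand_position[s : e + 1]
    target = np.asarray(target_position, dtype=float)
    if target.ndim == 2:
        target = target[s : e + 1]
    dist = np.linalg.norm(hand - target, axis=-1)
    speed = np.asarray(hand_speed[s : e + 1], dtype=float)
    if np.isnan(dist).all() or np.isnan(speed).all():
        raise LandmarkError("hand or target fully gapped within trial")
    if np.nanmax(speed) - np.nanmin(speed) < 1e-9:
        raise LandmarkError("hand is stationary within trial; no speed landmark")
    onset = int(np.nanargmax(dist)) + s
    peak = int(np.nanargmax(speed)) + s
    return Landmarks(throw_onset=onset, peak_hand_speed=peak, minimum_distance=e)


def apply_exclusions(
    trials: list[Trial],
    dataset: MarkerDataset,
    max_simultaneous: int = MAX_SIMULTANEOUS_GAPS,
    max_profile_gap: int = MAX_PROFILE_GAP,
) -> list[Trial]:
    """Flag trials per the gap-based exclusion rules.

    ``excluded`` when any frame within the trial has more than
    ``max_simultaneous`` markers missing at once (trial dropped from all
    analyses); ``profile_excluded`` when any single-marker gap run longer
    than ``max_profile_gap`` frames overlaps the trial (dropped from
    profile averaging only).  The mask of the *raw* dataset should be used.
    """
    counts = simultaneous_gap_counts(dataset)
    report = gap_report(dataset)
    long_runs = report[report["length"] > max_profile_gap]
    for t in trials:
        if counts[t.start_frame : t.end_frame + 1].max(initial=0) > max_simultaneous:
            t.excluded = True
            t.exclusion_reason = (
                f"more than {max_simultaneous} markers simultaneously missing"
            )
        for _, row in long_runs.iterrows():
            g0, g1 = row["start_frame"], row["start_frame"] + row["length"] - 1
            if g0 <= t.end_frame and g1 >= t.start_frame:
                t.profile_excluded = True
                break
    return trials
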