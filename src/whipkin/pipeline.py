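"""End-to-end orchestration: preprocess -> segment -> metrics -> profiles -> models.

A study layout lists marker files (or in-memory datasets) per participant,
style and block.  ``run_study`` processes every block with the study's
standard settings (20 Hz cutoff for hand and target markers, 40 Hz for whip
and handle; 0.5 m/s hand-speed threshold and 2 cm lift height for discrete
parsing; gap-exclusion rules of >5 simultaneous markers / >200-frame gaps),
assembles trial metrics, block summaries and speed profiles, and fits the
style-by-block and error-correlation mixed models.  Every run is
deterministic given inputs and configuration, and each excluded trial is
logged with its reason.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import mixed_models, preprocess, profiles, segmentation, whip_metrics
from .mocap_io import MarkerDataset, read_markers

__all__ = [
    "PipelineConfig",
    "BlockRef",
    "StudyLayout",
    "BlockResult",
    "StudyResult",
    "process_block",
    "run_study",
    "rank_participants",
]

WHIP_CHANNEL = tuple(f"w{i}" for i in range(1, 11)) + ("h1", "h2")


@dataclass
class PipelineConfig:
    """All tunable thresholds; defaults are the study's stated values."""

    body_cutoff: float = 20.0  # Hz, hand and target markers
    whip_cutoff: float = 40.0  # Hz, whip and handle markers
    speed_threshold: float = 0.5  # m/s, discrete trial start
    lift_height: float = 0.02  # m, whip-off-floor criterion
    onset_search_window: float = 1.0  # s before lift
    event_refractory: float = 0.3  # s
    event_prominence: float = 0.1  # m
    event_max_distance: float = 0.6  # m
    max_interpolated_gap: int = 50  # frames bridged before filtering
    max_simultaneous_gaps: int = 5  # markers; more -> trial excluded
    max_profile_gap: int = 200  # frames; longer -> excluded from profiles
    n_profile_samples: int = 500
    hit_threshold: float = 0.005  # m
    hit_band: tuple = (1.0, 8.0)  # Hz
    model_metrics: tuple = (
        "error",
        "extension",
        "whip_azimuth",
        "hand_azimuth",
        "peak_hand_speed",
        "peak_tip_speed",
        "inter_trial_interval",
    )
    correlation_covariates: tuple = (
        "extension",
        "whip_azimuth",
        "peak_hand_speed",
        "peak_tip_speed",
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hit_band", "model_metrics", "correlation_covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class BlockRef:
    participant: str
    style: str
    block: int
    path: str | None = None
    dataset: MarkerDataset | None = None

    def load(self) -> MarkerDataset:
        if self.dataset is not None:
            return self.dataset
        return read_markers(self.path)


@dataclass
class StudyLayout:
    blocks: list[BlockRef]

    @classmethod
    def from_yaml(cls, path: str) -> "StudyLayout":
        """Layout file: {participant: {style: [block file, ...]}}."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        root = os.path.dirname(os.path.abspath(path))
        blocks = []
        for pid, styles in raw.items():
            for style, files in styles.items():
                for b, fname in enumerate(files, start=1):
                    fpath = fname if os.path.isabs(fname) else os.path.join(root, fname)
                    blocks.append(BlockRef(str(pid), style, b, path=fpath))
        return cls(blocks)


@dataclass
class BlockResult:
    ref: BlockRef
    trials: list[segmentation.Trial]
    metrics: pd.DataFrame
    speeds: dict[str, np.ndarray]
    log: list[dict] = field(default_factory=list)


@dataclass
class StudyResult:
    trial_metrics: pd.DataFrame
    block_summaries: pd.DataFrame
    profiles: pd.DataFrame
    model_results: dict
    ranking: list[str]
    log: list[dict]
    config: PipelineConfig

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.trial_metrics.to_csv(os.path.join(out_dir, "trial_metrics.csv"), index=False)
        self.block_summaries.to_csv(
            os.path.join(out_dir, "block_summaries.csv"), index=False
        )
        self.profiles.to_csv(os.path.join(out_dir, "profiles.csv"), index=False)
        rows = []
        for name, res in self.model_results.items():
            if isinstance(res, mixed_models.MixedModelResult):
                df = res.fixed.reset_index(names="term")
                df.insert(0, "model", name)
                rows.append(df)
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                os.path.join(out_dir, "model_results.csv"), index=False
            )
        with open(os.path.join(out_dir, "run.json"), "w") as fh:
            json.dump(
                {
                    "config": self.config.to_dict(),
                    "ranking": self.ranking,
                    "log": self.log,
                },
                fh,
                indent=2,
                default=str,
            )


def preprocess_block(
    dataset: MarkerDataset, config: PipelineConfig
) -> tuple[MarkerDataset, np.ndarray]:
    """Gap-bridge and zero-lag filter one block; returns (filtered, speeds).

    Whip and handle markers are filtered at the whip cutoff, hand and
    target markers at the body cutoff.  ``speeds`` is the (frames, markers)
    tangential-speed array from the filtered positions.
    """
    bridged = preprocess.interpolate_gaps(dataset, config.max_interpolated_gap)
    fs = dataset.sampling_rate
    spec_whip = preprocess.design_lowpass(config.whip_cutoff, fs)
    spec_body = preprocess.design_lowpass(config.body_cutoff, fs)
    whip = [m for m in dataset.schema.marker_names if m in WHIP_CHANNEL]
    body = [m for m in dataset.schema.marker_names if m not in WHIP_CHANNEL]
    filtered = preprocess.filter_zero_lag(bridged, spec_whip, whip)
    filtered = preprocess.filter_zero_lag(filtered, spec_body, body)
    vel = preprocess.differentiate(filtered, order=1)
    speeds = preprocess.tangential_speed(vel)
    return filtered, speeds


def process_block(ref: BlockRef, config: PipelineConfig | None = None) -> BlockResult:
    """Run one block through preprocessing, segmentation and trial metrics."""
    config = config or PipelineConfig()
    raw = ref.load()
    filtered, speeds = preprocess_block(raw, config)
    schema = raw.schema
    hand_speed = speeds[:, schema.index("hand")]
    tip_speed = speeds[:, schema.index("w2")]
    distance = segmentation.whip_target_distance(filtered)
    events = segmentation.detect_minimum_distance_events(
        distance,
        raw.sampling_rate,
        refractory=config.event_refractory,
        prominence=config.event_prominence,
        max_distance=config.event_max_distance,
    )
    log: list[dict] = []
    if ref.style == "discrete":
        trials = segmentation.parse_discrete(
            filtered,
            hand_speed,
            events,
            speed_threshold=config.speed_threshold,
            lift_height=config.lift_height,
            search_window=config.onset_search_window,
        )
    else:
        trials = segmentation.parse_rhythmic(events)
    target_ref = 0.5 * (
        np.nanmean(filtered.marker("t2"), axis=0)
        + np.nanmean(filtered.marker("t3"), axis=0)
    )
    kept = []
    for t in trials:
        t.participant_id = ref.participant
        t.block_index = ref.block
        try:
            t.landmarks = segmentation.find_landmarks(
                t, filtered.marker("hand"), hand_speed, target_ref
            )
        except segmentation.LandmarkError as exc:
            t.excluded = True
            t.exclusion_reason = f"landmark error: {exc}"
        kept.append(t)
    trials = segmentation.apply_exclusions(
        kept,
        raw,
        max_simultaneous=config.max_simultaneous_gaps,
        max_profile_gap=config.max_profile_gap,
    )
    for t in trials:
        if t.excluded or t.profile_excluded:
            log.append(
                {
                    "participant": ref.participant,
                    "style": ref.style,
                    "block": ref.block,
                    "trial": t.trial_index,
                    "excluded": t.excluded,
                    "profile_excluded": t.profile_excluded,
                    "reason": t.exclusion_reason,
                }
            )
    metrics = whip_metrics.metrics_table(filtered, trials, hand_speed, tip_speed)
    metrics["style"] = ref.style
    metrics["block"] = ref.block
    metrics["participant"] = ref.participant
    speed_map = {"hand": hand_speed}
    for name in (f"w{i}" for i in range(1, 11)):
        speed_map[name] = speeds[:, schema.index(name)]
    return BlockResult(ref, trials, metrics, speed_map, log)


def _collect_profiles(
    block_results: list[BlockResult], config: PipelineConfig
) -> pd.DataFrame:
    """Per participant/style/marker mean +- SD profiles across all blocks."""
    samples: dict[tuple, list[np.ndarray]] = {}
    for br in block_results:
        for marker, speed in br.speeds.items():
            span = "trial" if marker == "hand" else "throw"
            for t in br.trials:
                if t.excluded or t.profile_excluded or t.landmarks is None:
                    continue
                s, e = (
                    (t.start_frame, t.end_frame)
                    if span == "trial"
                    else (t.landmarks.throw_onset, t.end_frame)
                )
                if e - s < profiles.MIN_SPAN_FRAMES:
                    continue
                try:
                    row = profiles.time_normalize(
                        speed, s, e, config.n_profile_samples
                    )
                except ValueError:
                    continue
                key = (br.ref.participant, br.ref.style, marker, span)
                samples.setdefault(key, []).append(row)
    grid = np.linspace(-1.0, 0.0, config.n_profile_samples)
    frames = []
    for (pid, style, marker, span), rows in sorted(samples.items()):
        stack = np.asarray(rows)
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros_like(mean)
        frames.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "style": style,
                    "marker": marker,
                    "span": span,
                    "normalized_time": grid,
                    "mean": mean,
                    "sd": sd,
                    "n_trials": len(rows),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "participant",
                "style",
                "marker",
                "span",
                "normalized_time",
                "mean",
                "sd",
                "n_trials",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def _fit_models(table: pd.DataFrame, config: PipelineConfig, log: list[dict]) -> dict:
    results: dict = {}
    usable = table[~table["excluded"].astype(bool)]
    if usable["participant"].nunique() < 2 or usable["style"].nunique() < 2:
        log.append({"event": "models skipped", "reason": "needs >=2 participants and both styles"})
        return results
    for metric in config.model_metrics:
        if metric not in usable or usable[metric].dropna().empty:
            continue
        try:
            results[f"style_block:{metric}"] = mixed_models.fit_style_block_model(
                usable, metric
            )
        except mixed_models.ModelError as exc:
            log.append({"event": "model failed", "model": metric, "reason": str(exc)})
    if "hit" in usable and usable["hit"].notna().any():
        try:
            hit_table = usable.dropna(subset=["hit"]).assign(
                hit=lambda d: d["hit"].astype(float)
            )
            results["style_block:hit"] = mixed_models.fit_style_block_model(
                hit_table, "hit", family="binomial"
            )
        except Exception as exc:  # GLMM fits can fail on degenerate data
            log.append({"event": "model failed", "model": "hit", "reason": str(exc)})
    for cov in config.correlation_covariates:
        if cov not in usable:
            continue
        try:
            results[f"error~{cov}"] = mixed_models.fit_error_correlation(usable, cov)
        except mixed_models.ModelError as exc:
            log.append({"event": "model failed", "model": f"error~{cov}", "reason": str(exc)})
    try:
        results["peak_tip_speed~peak_hand_speed"] = mixed_models.fit_error_correlation(
            usable, "peak_hand_speed", response="peak_tip_speed"
        )
    except mixed_models.ModelError as exc:
        log.append(
            {"event": "model failed", "model": "tip~hand", "reason": str(exc)}
        )
    return results


def rank_participants(trial_metrics: pd.DataFrame) -> list[str]:
    """Participants ordered by ascending median error across both styles.

    Ties are broken by participant label.
    """
    usable = trial_metrics[~trial_metrics["excluded"].astype(bool)]
    med = usable.groupby("participant")["error"].median()
    return sorted(med.index, key=lambda p: (med[p], p))


def run_study(layout: StudyLayout, config: PipelineConfig | None = None) -> StudyResult:
    """Process every block of a study and assemble the result bundle."""
    config = config or PipelineConfig()
    log: list[dict] = []
    block_results = []
    for ref in layout.blocks:
        try:
            block_results.append(process_block(ref, config))
        except FileNotFoundError:
            log.append(
                {
                    "event": "block missing",
                    "participant": ref.participant,
                    "style": ref.style,
                    "block": ref.block,
                }
            )
    if not block_results:
        raise ValueError("no readable blocks in layout")
    for br in block_results:
        log.extend(br.log)
    trial_metrics = pd.concat([br.metrics for br in block_results], ignore_index=True)
    summaries = whip_metrics.summarize_blocks(trial_metrics)
    prof = _collect_profiles(block_results, config)
    models = _fit_models(trial_metrics, config, log)
    ranking = rank_participants(trial_metrics)
    return StudyResult(
        trial_metrics=trial_metrics,
        block_summaries=summaries,
        profiles=prof,
        model_results=models,
        ranking=ranking,
        log=log,
        config=config,
    )
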