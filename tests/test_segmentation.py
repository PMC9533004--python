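import numpy as np
import pytest

from whipkin.mocap_io import MarkerDataset, default_schema
from whipkin.segmentation import (
    Landmarks,
    LandmarkError,
    Trial,
    apply_exclusions,
    detect_minimum_distance_events,
    find_landmarks,
    parse_rhythmic,
)

FS = 500.0


class TestEvents:
    def test_two_planted_minima_found_exactly(self):
        t = np.arange(int(3 * FS)) / FS
        d = 1.0 - 0.8 * np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
        d -= 0.8 * np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2)
        events = detect_minimum_distance_events(d, FS)
        np.testing.assert_array_equal(events, [500, 1000])

    def test_monotone_distance_gives_no_events(self):
        d = np.linspace(2.0, 0.1, 1000)
        assert len(detect_minimum_distance_events(d, FS)) == 0

    def test_noisy_minima_within_two_frames(self):
        rng = np.random.default_rng(2)
        t = np.arange(int(3 * FS)) / FS
        clean = 1.0 - 0.8 * np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
        clean -= 0.8 * np.exp(-0.5 * ((t - 2.2) / 0.05) ** 2)
        noisy = clean + rng.normal(0, 0.002, size=len(t))
        events = detect_minimum_distance_events(noisy, FS)
        oracle = detect_minimum_distance_events(clean, FS)
        assert len(events) == 2
        np.testing.assert_array_equal(oracle, [500, 1100])
        assert np.abs(events - oracle).max() <= 2

    def test_refractory_suppresses_double_events(self):
        t = np.arange(int(2 * FS)) / FS
        d = 1.0 - 0.8 * np.exp(-0.5 * ((t - 1.0) / 0.02) ** 2)
        d -= 0.75 * np.exp(-0.5 * ((t - 1.05) / 0.02) ** 2)
        events = detect_minimum_distance_events(d, FS, refractory=0.3)
        assert len(events) == 1


class TestParseRhythmic:
    def test_five_events_tile_into_four_trials(self):
        events = np.array([100, 700, 1300, 1900, 2500])
        trials = parse_rhythmic(events)
        assert len(trials) == 4
        assert trials[0].start_frame == 100
        for a, b in zip(trials[:-1], trials[1:]):
            assert a.end_frame == b.start_frame  # exact tiling

    def test_second_intervals(self):
        trials = parse_rhythmic(np.array([500, 1000, 1500]))
        assert [t.n_frames for t in trials] == [500, 500]

    def test_fewer_than_two_events_empty(self):
        assert parse_rhythmic(np.array([100])) == []
        assert parse_rhythmic(np.array([], dtype=int)) == []


class TestParseDiscrete:
    def test_planted_throws_recovered(self, discrete_block_processed):
        result, gt = discrete_block_processed
        starts = np.array([t.start_frame for t in result.trials])
        assert len(result.trials) == gt.planted["n_trials"]
        np.testing.assert_array_equal(
            np.abs(starts - gt.trials["start_frame"].to_numpy()) <= 1,
            True,
        )

    def test_block_without_lift_gives_no_trials(self, static_dataset):
        from whipkin.segmentation import parse_discrete

        hand_speed = np.zeros(static_dataset.n_frames)
        trials = parse_discrete(static_dataset, hand_speed, np.array([50], dtype=int))
        assert trials == []


class TestLandmarks:
    def _toy_trial(self):
        """Hand pulls back then accelerates with a two-peak speed profile."""
        t = np.arange(int(2.0 * FS)) / FS
        vx = -1.5 * np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2)
        vx += 5.0 * np.exp(-0.5 * ((t - 1.0) / 0.07) ** 2)
        x = np.cumsum(vx) / FS
        hand = np.column_stack([x, np.zeros_like(x), np.full_like(x, 1.3)])
        speed = np.abs(vx)
        target = np.array([2.0, 0.0, 1.3])
        return hand, speed, target

    def test_planted_extrema_recovered(self):
        hand, speed, target = self._toy_trial()
        trial = Trial(style="discrete", start_frame=100, end_frame=900)
        lm = find_landmarks(trial, hand, speed, target)
        # hand-to-target distance is maximal where vx crosses zero
        onset_oracle = 100 + int(
            np.argmax(np.linalg.norm(hand[100:901] - target, axis=1))
        )
        assert lm.throw_onset == onset_oracle
        assert lm.peak_hand_speed == 100 + int(np.argmax(speed[100:901]))
        assert lm.minimum_distance == 900

    def test_second_higher_peak_wins(self):
        hand, speed, target = self._toy_trial()
        trial = Trial(style="discrete", start_frame=0, end_frame=999)
        lm = find_landmarks(trial, hand, speed, target)
        assert abs(lm.peak_hand_speed - 500) < 10  # the 5 m/s throw peak

    def test_stationary_hand_is_degenerate(self):
        hand = np.tile([0.5, 0.0, 1.3], (500, 1))
        trial = Trial(style="discrete", start_frame=0, end_frame=499)
        with pytest.raises(LandmarkError):
            find_landmarks(trial, hand, np.zeros(500), np.array([2.0, 0, 1.3]))

    def test_ordering_invariant_enforced(self):
        with pytest.raises(LandmarkError):
            Landmarks(throw_onset=50, peak_hand_speed=40, minimum_distance=100)

    def test_plateau_tie_broken_earliest(self):
        hand = np.zeros((200, 3))
        hand[:, 0] = np.concatenate([np.linspace(1, 0, 100), np.zeros(100)])
        speed = np.concatenate([np.zeros(120), np.ones(60), np.zeros(20)])
        trial = Trial(style="discrete", start_frame=0, end_frame=199)
        lm = find_landmarks(trial, hand, speed, np.array([5.0, 0, 0]))
        # both the distance and the speed maxima are plateaus; the earliest
        # frame wins in each case
        assert lm.throw_onset == 99
        assert lm.peak_hand_speed == 120


class TestExclusions:
    def _dataset_with_mask(self, mask):
        schema = default_schema()
        pos = np.ones((mask.shape[0], len(schema.marker_names), 3))
        return MarkerDataset(pos, FS, mask, schema)

    def test_six_simultaneous_gaps_exclude_trial(self):
        schema = default_schema()
        mask = np.zeros((300, len(schema.marker_names)), bool)
        mask[150, 1:7] = True  # six markers missing at one frame
        ds = self._dataset_with_mask(mask)
        trials = [Trial(style="rhythmic", start_frame=100, end_frame=200)]
        (t,) = apply_exclusions(trials, ds)
        assert t.excluded

    def test_150_frame_gap_kept_everywhere(self):
        schema = default_schema()
        mask = np.zeros((500, len(schema.marker_names)), bool)
        mask[100:250, schema.index("w4")] = True
        ds = self._dataset_with_mask(mask)
        (t,) = apply_exclusions(
            [Trial(style="rhythmic", start_frame=50, end_frame=400)], ds
        )
        assert not t.excluded and not t.profile_excluded

    def test_201_frame_gap_excludes_profiles_only(self):
        schema = default_schema()
        mask = np.zeros((500, len(schema.marker_names)), bool)
        mask[100:301, schema.index("w4")] = True
        ds = self._dataset_with_mask(mask)
        (t,) = apply_exclusions(
            [Trial(style="rhythmic", start_frame=50, end_frame=400)], ds
        )
        assert not t.excluded
        assert t.profile_excluded

    def test_gap_outside_trial_ignored(self):
        schema = default_schema()
        mask = np.zeros((800, len(schema.marker_names)), bool)
        mask[500:750, schema.index("w4")] = True
        ds = self._dataset_with_mask(mask)
        (t,) = apply_exclusions(
            [Trial(style="rhythmic", start_frame=50, end_frame=400)], ds
        )
        assert not t.excluded and not t.profile_excluded
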