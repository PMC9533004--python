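import numpy as np
import pytest

from whipkin.mocap_io import MarkerDataset, default_schema
from whipkin.segmentation import Landmarks, Trial
from whipkin.whip_metrics import (
    MetricUndefinedError,
    detect_hit,
    hand_azimuth,
    minimum_distance_error,
    peak_speeds,
    rhythmicity,
    success_rate,
    whip_azimuth,
    whip_extension,
)

FS = 500.0


def _dataset(positions_by_marker, n=300, schema=None):
    """Static dataset; positions_by_marker maps label -> (3,) position."""
    schema = schema or default_schema()
    pos = np.zeros((n, len(schema.marker_names), 3))
    for name, p in positions_by_marker.items():
        pos[:, schema.index(name), :] = p
    return MarkerDataset(pos, FS, np.zeros((n, len(schema.marker_names)), bool), schema)


def _trial(start=50, end=250, peak=150):
    t = Trial(style="discrete", start_frame=start, end_frame=end)
    t.landmarks = Landmarks(start + 10, peak, end)
    return t


def _straight_chain(schema, azimuth_deg=0.0, origin=(0.0, 0.0, 1.3)):
    """Markers laid on a straight line at the given azimuth (0 = backward)."""
    theta = np.pi + np.deg2rad(azimuth_deg)  # polar angle of the chain direction
    u = np.array([np.cos(theta), np.sin(theta), 0.0])
    seg = schema.whip_segment_lengths()
    chain = {"h1": np.asarray(origin, dtype=float)}
    arc = np.cumsum(seg)
    names = ["w10", "w9", "w8", "w7", "w6", "w5", "w4", "w3", "w2", "w1"]
    for name, s in zip(names, arc):
        chain[name] = chain["h1"] + s * u
    chain["h2"] = chain["h1"] - schema.handle_length * u
    chain["hand"] = chain["h2"] + np.array([0.0, 0.0, -0.02])
    return chain


class TestMinimumDistanceError:
    def test_tip_through_target_is_zero(self, schema):
        ds = _dataset(
            {
                "w1": [0.1, 0.05, 0.0],
                "w2": [0.0, 0.0, 0.0],
                "w3": [-0.19, 0.0, 0.0],
                "t1": [0.1, 0.05, 0.0],
                "t2": [0.25, 0.05, 0.0],
            }
        )
        assert minimum_distance_error(ds, _trial()) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_static_toy(self):
        ds = _dataset(
            {
                "w1": [0.0, 0.0, 0.0],
                "w2": [0.06, 0.0, 0.0],
                "w3": [0.25, 0.0, 0.0],
                "t1": [0.10, 0.05, 0.0],
                "t2": [0.10, 0.15, 0.0],
            }
        )
        assert minimum_distance_error(ds, _trial()) == pytest.approx(0.05, abs=1e-9)

    def test_not_larger_than_any_raw_pair(self, discrete_block_processed):
        result, _ = discrete_block_processed
        m = result.metrics
        ok = m[~m["excluded"].astype(bool)]
        assert (ok["error"] >= -1e-12).all()

    def test_all_distal_gapped_is_undefined(self, schema):
        ds = _dataset({"t1": [1.0, 0, 0], "t2": [1.2, 0, 0]})
        for w in ("w1", "w2", "w3"):
            ds.gap_mask[:, schema.index(w)] = True
            ds.positions[:, schema.index(w), :] = np.nan
        with pytest.raises(MetricUndefinedError):
            minimum_distance_error(ds, _trial())


class TestExtension:
    def test_straight_chain_full_length(self, schema):
        ds = _dataset(_straight_chain(schema))
        ext, ratio = whip_extension(ds, _trial())
        assert ext == pytest.approx(schema.chain_length(), abs=1e-9)
        # the w1-w10 chord over the 1.6 m arclength
        assert ratio == pytest.approx(1.58 / 1.60, abs=1e-9)

    def test_folded_chain(self, schema):
        chain = _straight_chain(schema)
        # fold at w5: distal markers mirrored back toward the handle
        fold = chain["w5"].copy()
        for name in ("w4", "w3", "w2", "w1"):
            chain[name] = 2 * fold - chain[name]
        ds = _dataset(chain)
        ext, _ = whip_extension(ds, _trial())
        oracle = np.linalg.norm(chain["w1"] - chain["h1"])
        assert ext == pytest.approx(oracle, abs=1e-9)
        assert ext < schema.chain_length() / 2

    def test_rigid_transform_invariance(self, schema):
        chain = _straight_chain(schema, azimuth_deg=15.0)
        ds = _dataset(chain)
        ext0, _ = whip_extension(ds, _trial())
        theta = 0.6
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = {k: rot @ v + np.array([0.3, -0.2, 0.1]) for k, v in chain.items()}
        ext1, _ = whip_extension(_dataset(moved), _trial())
        assert ext1 == pytest.approx(ext0, abs=1e-9)

    def test_gapped_endpoint_uses_nearby_frame(self, schema):
        chain = _straight_chain(schema)
        ds = _dataset(chain)
        j = schema.index("w1")
        ds.gap_mask[148:153, j] = True
        ds.positions[148:153, j, :] = np.nan
        ext, _ = whip_extension(ds, _trial(peak=150))
        assert ext == pytest.approx(schema.chain_length(), abs=1e-9)


class TestAzimuths:
    def test_straight_backward_is_zero(self, schema):
        ds = _dataset(_straight_chain(schema, azimuth_deg=0.0))
        assert whip_azimuth(ds, _trial()) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [30.0, -30.0, 120.0])
    def test_rotation_equivariance(self, schema, angle):
        ds = _dataset(_straight_chain(schema, azimuth_deg=angle))
        assert whip_azimuth(ds, _trial()) == pytest.approx(angle, abs=1e-9)

    def test_noisy_line_recovered_within_one_degree(self, schema):
        rng = np.random.default_rng(8)
        chain = _straight_chain(schema, azimuth_deg=28.0)
        ds = _dataset(chain)
        ds.positions += rng.normal(0, 0.005, size=ds.positions.shape)
        ds.gap_mask[:] = False
        assert whip_azimuth(ds, _trial()) == pytest.approx(28.0, abs=1.0)

    def test_hand_azimuth_aligned_with_sagittal_line(self, schema):
        ds = _dataset(_straight_chain(schema, azimuth_deg=0.0))
        assert hand_azimuth(ds, _trial()) == pytest.approx(0.0, abs=1e-9)

    def test_hand_azimuth_rotated(self, schema):
        ds = _dataset(_straight_chain(schema, azimuth_deg=36.0))
        assert hand_azimuth(ds, _trial()) == pytest.approx(36.0, abs=1e-9)


class TestSpeedsAndRhythm:
    def test_planted_peak_values(self):
        hand = np.zeros(400)
        hand[100:300] = 6.1 * np.exp(-0.5 * ((np.arange(200) - 100) / 30.0) ** 2)
        tip = np.full(400, 2.0)
        trial = Trial(style="discrete", start_frame=50, end_frame=350)
        phs, pts = peak_speeds(trial, hand, tip)
        assert phs == pytest.approx(6.1, abs=1e-9)
        assert pts == pytest.approx(2.0)

    def test_constant_speed_returns_constant(self):
        trial = Trial(style="discrete", start_frame=0, end_frame=99)
        phs, _ = peak_speeds(trial, np.full(100, 1.5), np.full(100, 1.5))
        assert phs == pytest.approx(1.5)

    def test_tip_exceeds_hand_on_synthetic_cascade(self, discrete_block_processed):
        result, _ = discrete_block_processed
        m = result.metrics
        ok = m[~m["excluded"].astype(bool)]
        assert (ok["peak_tip_speed"] > ok["peak_hand_speed"]).all()

    def test_perfectly_periodic_intervals_cov_zero(self):
        trials = [
            Trial(style="rhythmic", start_frame=i * 600, end_frame=(i + 1) * 600)
            for i in range(5)
        ]
        assert rhythmicity(trials, FS) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_cov(self):
        # intervals 1.0, 1.0, 2.0 s; sample SD / mean = 0.43301...
        starts = [0, 500, 1000, 2000]
        trials = [
            Trial(style="discrete", start_frame=s, end_frame=s + 400) for s in starts
        ]
        assert rhythmicity(trials, FS) == pytest.approx(0.43301270, abs=1e-6)

    def test_two_trials_insufficient(self):
        trials = [
            Trial(style="rhythmic", start_frame=0, end_frame=500),
            Trial(style="rhythmic", start_frame=500, end_frame=1000),
        ]
        with pytest.raises(MetricUndefinedError):
            rhythmicity(trials, FS)

    def test_success_rate_percentage(self):
        assert success_rate([True, False, True, True]) == pytest.approx(75.0)


class TestHitDetection:
    def _target_dataset(self, oscillation_amp, schema, n=1500, contact=800):
        rng = np.random.default_rng(12)
        pos = np.zeros((n, len(schema.marker_names), 3))
        pos[:, schema.index("t1"), :] = [2.0, 0.0, 1.3]
        t = (np.arange(n) - contact) / FS
        ring = np.where(
            t >= 0,
            oscillation_amp * np.exp(-np.maximum(t, 0) / 0.25) * np.sin(2 * np.pi * 3.5 * t),
            0.0,
        )
        pos[:, schema.index("t1"), 1] += ring
        pos += rng.normal(0, 0.0003, size=pos.shape)
        return MarkerDataset(pos, FS, np.zeros((n, len(schema.marker_names)), bool), schema)

    def test_static_target_is_miss(self, schema):
        ds = self._target_dataset(0.0, schema)
        trial = Trial(style="discrete", start_frame=300, end_frame=800)
        assert detect_hit(ds, trial) is False

    def test_planted_5cm_oscillation_is_hit(self, schema):
        ds = self._target_dataset(0.05, schema)
        trial = Trial(style="discrete", start_frame=300, end_frame=800)
        assert detect_hit(ds, trial) is True

    def test_half_millimetre_wobble_is_miss(self, schema):
        ds = self._target_dataset(0.0005, schema)
        trial = Trial(style="discrete", start_frame=300, end_frame=800)
        assert detect_hit(ds, trial) is False

    def test_planted_contacts_fully_recovered(self, discrete_block_processed):
        result, gt = discrete_block_processed
        m = result.metrics
        n = min(len(m), len(gt.trials))
        got = m["hit"].to_numpy()[:n].astype(bool)
        np.testing.assert_array_equal(got, gt.trials["hit"].to_numpy()[:n])
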