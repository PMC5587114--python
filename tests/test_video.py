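import numpy as np
import pytest

import hcasim as h
from hcasim.tracking import Track
from hcasim.video import episodes_to_frame

from conftest import stationary_truth


def scheduled_truth(xs_cm, bouts, duration_s=20.0, posture="rearing"):
    """Motionless animals at given x positions with prescribed vertical
    bouts: ``bouts[animal] = [(t0, t1), ...]`` in seconds."""
    truth = stationary_truth(0.0, 19.0, 2.0, (1.0, 0.0, 0.0), duration_s,
                             n_animals=len(xs_cm))
    code = h.POSTURES.index(posture)
    for a, x in enumerate(xs_cm):
        truth.x[a] = x
        truth.tag_x[a] = x
        for (t0, t1) in bouts.get(a, []):
            w = (truth.t >= t0) & (truth.t < t1)
            truth.posture[a, w] = code
    return truth


def expected_vertical_frames(truth, cam, n_frames):
    """Frame labels derived from the schedule alone: a frame is vertical
    when its pose (or the previous frame's) is reared — the rise is seen on
    the first reared frame, the drop on the frame after the last."""
    times = np.arange(n_frames) / cam.fps
    idx = np.minimum((times / truth.cfg.timestep_s).astype(int), len(truth.t) - 1)
    reared = (truth.posture[:, idx] >= h.POSTURES.index("rearing")).any(axis=0)
    lab = reared.copy()
    lab[1:] |= reared[:-1]
    lab[0] = False  # no difference image exists for frame 0
    return lab


@pytest.fixture(scope="module")
def cam():
    return h.CameraConfig()


@pytest.fixture(scope="module")
def line_row(cam):
    return cam.row_for_height(8.0)


class TestRenderer:
    def test_empty_cage_is_static_background(self, cam):
        truth = stationary_truth(10.0, 10.0, 2.0, (1, 0, 0), 2.0)
        truth.x = truth.x[:0]  # drop all animals
        stream = h.render_frames(truth, cam, duration_s=1.0, noise=False)
        assert (stream.frames == stream.frames[0]).all()

    def test_deterministic_given_seed(self, cam):
        truth = scheduled_truth([25.0], {0: [(0.5, 1.0)]}, duration_s=2.0)
        a = h.render_frames(truth, cam, duration_s=2.0, seed=3)
        b = h.render_frames(truth, cam, duration_s=2.0, seed=3)
        assert (a.frames == b.frames).all()

    def test_rearing_blob_crosses_line(self, cam, line_row):
        truth = scheduled_truth([25.0], {0: [(0.0, 2.0)]}, duration_s=2.0)
        stream = h.render_frames(truth, cam, duration_s=1.0, noise=False)
        top_rows = np.nonzero((stream.frames[5] > h.video.BACKGROUND + 50).any(axis=1))[0]
        assert top_rows.min() < line_row

    def test_walking_blob_stays_below_line(self, cam, line_row):
        truth = scheduled_truth([25.0], {}, duration_s=1.0)
        stream = h.render_frames(truth, cam, duration_s=1.0, noise=False)
        rat_rows = np.nonzero((stream.frames[5] >= h.video.RAT).any(axis=1))[0]
        assert rat_rows.min() > line_row


class TestPixelMotion:
    def test_identical_frames_count_zero(self):
        frames = np.full((5, 40, 60), 30, np.uint8)
        out = h.pixel_motion(frames)
        assert (out["changed_pixels"] == 0).all()

    def test_disjoint_translation_counts_twice_area(self):
        f0 = np.full((40, 60), 10, np.uint8)
        f1 = f0.copy()
        f0[5:15, 5:15] = 200   # area A = 100
        f1[25:35, 40:50] = 200  # moved with no overlap
        out = h.pixel_motion(np.stack([f0, f1]), diff_threshold=10)
        assert out["changed_pixels"].iloc[0] == 200

    def test_adding_a_blob_never_decreases_count(self):
        rng = np.random.default_rng(0)
        base0 = rng.integers(0, 40, size=(30, 40)).astype(np.uint8)
        base1 = rng.integers(0, 40, size=(30, 40)).astype(np.uint8)
        c0 = h.pixel_motion(np.stack([base0, base1]))["changed_pixels"].iloc[0]
        with_blob0, with_blob1 = base0.copy(), base1.copy()
        with_blob0[2:6, 2:6] = 250
        with_blob1[20:24, 30:34] = 250
        c1 = h.pixel_motion(np.stack([with_blob0, with_blob1]))["changed_pixels"].iloc[0]
        assert c1 >= c0

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        frames = rng.integers(0, 255, size=(6, 20, 20)).astype(np.uint8)
        fwd = h.pixel_motion(frames)["changed_pixels"].to_numpy()
        rev = h.pixel_motion(frames[::-1])["changed_pixels"].to_numpy()
        assert (fwd == rev[::-1]).all()

    def test_single_frame_empty_series(self):
        assert len(h.pixel_motion(np.zeros((1, 8, 8), np.uint8))) == 0


class TestVerticalActivity:
    def test_motion_below_line_ignored(self, cam, line_row):
        truth = scheduled_truth([25.0], {}, duration_s=4.0)
        # walking animal moving along the floor
        truth.x[0] = 10.0 + 5.0 * np.sin(truth.t)
        stream = h.render_frames(truth, cam, duration_s=4.0, noise=False)
        assert h.vertical_activity(stream.frames, line_row) == []

    def test_noise_free_bout_detected_exactly(self, cam, line_row):
        truth = scheduled_truth([25.0], {0: [(2.0, 4.0)]}, duration_s=6.0)
        stream = h.render_frames(truth, cam, duration_s=6.0, noise=False)
        episodes = h.vertical_activity(stream.frames, line_row)
        assert len(episodes) == 1
        lab_auto = h.labels_from_episodes(episodes, stream.n_frames)
        lab_expected = expected_vertical_frames(truth, cam, stream.n_frames)
        assert h.frame_accuracy(lab_auto, lab_expected) == 100.0

    def test_two_separated_bouts_give_two_episodes(self, cam, line_row):
        truth = scheduled_truth([25.0], {0: [(1.0, 2.0), (4.0, 5.0)]}, duration_s=6.0)
        stream = h.render_frames(truth, cam, duration_s=6.0, noise=False)
        assert len(h.vertical_activity(stream.frames, line_row)) == 2

    def test_min_frames_suppresses_single_frame_blips(self):
        frames = np.full((20, 40, 60), 10, np.uint8)
        frames[7, 2, 2] = 250  # one-frame sparkle above the line
        assert h.vertical_activity(frames, line_row=30, min_frames=3) == []


class TestIdentityAssignment:
    def _tracks(self, xs):
        n = 100
        t = np.arange(n) * 1.08
        out = {}
        for i, x in enumerate(xs):
            out[f"rat{i + 1}"] = Track(
                f"rat{i + 1}", t, np.zeros(n, int), np.zeros(n, int),
                np.full(n, float(x)), np.full(n, 19.0), np.zeros(n, int))
        return out

    def test_single_animal_gets_every_episode(self, cam, line_row):
        truth = scheduled_truth([25.0], {0: [(1.0, 2.0), (3.0, 4.0)]}, duration_s=6.0)
        stream = h.render_frames(truth, cam, duration_s=6.0, noise=False)
        eps = h.vertical_activity(stream.frames, line_row)
        eps = h.assign_episode_identity(eps, self._tracks([25.0]), stream.frames,
                                        stream, line_row)
        assert all(e.animal_id == "rat1" for e in eps)

    def test_equidistant_tie_left_unassigned(self, cam, line_row):
        truth = scheduled_truth([25.0], {0: [(1.0, 2.0)]}, duration_s=4.0)
        stream = h.render_frames(truth, cam, duration_s=4.0, noise=False)
        eps = h.vertical_activity(stream.frames, line_row)
        cx = h.video.episode_motion_centroid_x(stream.frames, eps[0], line_row) / cam.px_per_cm
        tracks = self._tracks([cx - 5.0, cx + 5.0])
        eps = h.assign_episode_identity(eps, tracks, stream.frames, stream, line_row)
        assert eps[0].animal_id is None

    def test_three_separated_animals_fully_assigned(self, cam, line_row):
        bouts = {0: [(1.0, 2.0)], 1: [(3.0, 4.0)], 2: [(5.0, 6.0)]}
        truth = scheduled_truth([8.0, 25.0, 42.0], bouts, duration_s=7.0)
        stream = h.render_frames(truth, cam, duration_s=7.0, noise=False)
        eps = h.vertical_activity(stream.frames, line_row)
        assert len(eps) == 3
        eps = h.assign_episode_identity(eps, self._tracks([8.0, 25.0, 42.0]),
                                        stream.frames, stream, line_row)
        expected = {0: "rat1", 1: "rat2", 2: "rat3"}
        for i, e in enumerate(sorted(eps, key=lambda e: e.start_frame)):
            assert e.animal_id == expected[i]

    def test_per_animal_counts_sum_to_cage_count(self, cam, line_row):
        bouts = {0: [(1.0, 2.0)], 1: [(3.0, 4.0)]}
        truth = scheduled_truth([10.0, 40.0], bouts, duration_s=5.0)
        stream = h.render_frames(truth, cam, duration_s=5.0, noise=False)
        eps = h.assign_episode_identity(
            h.vertical_activity(stream.frames, line_row),
            self._tracks([10.0, 40.0]), stream.frames, stream, line_row)
        df = episodes_to_frame(eps)
        assert (df["animal_id"] != "").all()
        assert df.groupby("animal_id").size().sum() == len(eps)


class TestFrameAccuracy:
    def test_identical_series_scores_100(self):
        lab = np.array([0, 1, 1, 0], bool)
        assert h.frame_accuracy(lab, lab) == 100.0

    def test_complementary_series_scores_0(self):
        lab = np.array([0, 1, 1, 0], bool)
        assert h.frame_accuracy(lab, ~lab) == 0.0

    def test_half_matching(self):
        assert h.frame_accuracy([0, 0, 1, 1], [0, 1, 0, 1]) == 50.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            h.frame_accuracy([0, 1], [0, 1, 0])
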