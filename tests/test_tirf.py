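import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from traffiq import simulate as sim
from traffiq import tirf
from traffiq.io import DegenerateInputError, TirfMovie


def gaussian_frame(shape, centers, amplitude=200.0, sigma=1.3, background=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    frame = np.full(shape, float(background))
    for r, c in centers:
        frame += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
    return frame


def match_counts(true_pos, det_pos, radius=2.0):
    """Hungarian matching oracle: number of detections within radius of truth."""
    if len(true_pos) == 0 or len(det_pos) == 0:
        return 0
    cost = np.linalg.norm(
        np.asarray(true_pos)[:, None, :] - np.asarray(det_pos)[None, :, :], axis=2
    )
    r, c = linear_sum_assignment(cost)
    return int((cost[r, c] <= radius).sum())


class TestDetectSpots:
    def test_blank_frame_detects_nothing(self):
        assert tirf.detect_spots(np.zeros((32, 32)), threshold=5.0) == []

    def test_single_blob_centroid_accuracy(self):
        frame = gaussian_frame((48, 48), [(20.0, 30.0)])
        spots = tirf.detect_spots(frame, threshold=5.0)
        assert len(spots) == 1
        r, c = spots[0].position
        assert abs(r - 20.0) <= 0.25 and abs(c - 30.0) <= 0.25

    def test_min_separation_prunes_keeping_brighter(self):
        frame = gaussian_frame((48, 48), [(20.0, 20.0)], amplitude=100.0)
        frame += gaussian_frame((48, 48), [(20.0, 22.0)], amplitude=300.0)
        spots = tirf.detect_spots(frame, threshold=5.0, min_separation=5)
        assert len(spots) == 1
        assert abs(spots[0].position[1] - 22.0) < 1.0  # brighter one survives

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2D"):
            tirf.detect_spots(np.zeros((2, 8, 8)))

    def test_translation_equivariance(self):
        centers = [(12.0, 14.0), (30.0, 9.0), (22.0, 33.0)]
        f0 = gaussian_frame((64, 64), centers)
        f1 = gaussian_frame((64, 64), [(r + 5, c + 7) for r, c in centers])
        s0 = sorted(s.position for s in tirf.detect_spots(f0, threshold=5.0))
        s1 = sorted(s.position for s in tirf.detect_spots(f1, threshold=5.0))
        assert len(s0) == len(s1) == 3
        for (r0, c0), (r1, c1) in zip(s0, s1):
            assert r1 - r0 == pytest.approx(5.0, abs=1e-6)
            assert c1 - c0 == pytest.approx(7.0, abs=1e-6)

    def test_detection_fidelity_on_synthetic_movie(self):
        movie, truth = sim.make_tirf_movie(
            shape=(160, 160), n_frames=1, n_spots=50, persistent_fraction=1.0,
            min_spacing=6.0, appearance_window=1, seed=2,
        )
        spots = tirf.detect_spots(movie.frames[0])
        true_pos = [t.positions[0] for t in truth.tracks]
        det_pos = [s.position for s in spots]
        matched = match_counts(true_pos, det_pos)
        assert matched / len(true_pos) >= 0.95   # recall
        assert matched / len(det_pos) >= 0.95    # precision


class TestCountTimecourse:
    def test_percent_of_max_arithmetic(self):
        frames = np.stack(
            [
                gaussian_frame((64, 64), [(8 + 5 * i, 8 + 5 * i) for i in range(n)])
                for n in (5, 10, 10)
            ]
        )
        movie = TirfMovie(frames=frames)
        tc = tirf.count_timecourse(movie, threshold=5.0)
        np.testing.assert_array_equal(tc.counts, [5, 10, 10])
        np.testing.assert_allclose(tc.percent_of_max, [50.0, 100.0, 100.0])

    def test_blank_movie_gives_all_zero(self):
        movie = TirfMovie(frames=np.zeros((4, 32, 32)))
        tc = tirf.count_timecourse(movie, threshold=5.0)
        assert np.all(tc.counts == 0)
        assert np.all(tc.percent_of_max == 0.0)

    def test_percent_of_max_invariant_under_rescaling(self):
        movie, _ = sim.make_tirf_movie(n_frames=8, n_spots=20, seed=4)
        tc1 = tirf.count_timecourse(movie)
        scaled = TirfMovie(frames=movie.frames * 3.0, frame_interval=movie.frame_interval)
        tc2 = tirf.count_timecourse(scaled)
        np.testing.assert_allclose(tc1.percent_of_max, tc2.percent_of_max)


class TestLinkTracks:
    @staticmethod
    def as_per_frame(positions_by_frame):
        out = []
        for t, plist in enumerate(positions_by_frame):
            out.append(
                [tirf.Spot(frame_index=t, position=p, peak_intensity=1.0) for p in plist]
            )
        return out

    def test_two_stationary_spots_two_full_tracks(self):
        per_frame = self.as_per_frame([[(10.0, 10.0), (30.0, 30.0)]] * 10)
        tracks = tirf.link_tracks(per_frame, max_displacement=3.0)
        assert len(tracks) == 2
        assert all(len(tr.spots) == 10 for tr in tracks)

    def test_moving_spot_single_track(self):
        per_frame = self.as_per_frame([[(10.0 + t, 10.0)] for t in range(10)])
        tracks = tirf.link_tracks(per_frame, max_displacement=3.0)
        assert len(tracks) == 1
        assert tracks[0].duration_min(1.0) == 9.0

    def test_gap_bridging(self):
        frames = [[(10.0, 10.0)]] * 3 + [[]] + [[(10.0, 10.0)]] * 3
        tracks = tirf.link_tracks(self.as_per_frame(frames), max_displacement=3.0, max_gap=1)
        assert len(tracks) == 1
        no_gap = tirf.link_tracks(self.as_per_frame(frames), max_displacement=3.0, max_gap=0)
        assert len(no_gap) == 2

    def test_every_spot_in_exactly_one_track(self):
        movie, _ = sim.make_tirf_movie(n_frames=15, n_spots=25, seed=3)
        per_frame = tirf.detect_movie(movie)
        n_spots = sum(len(s) for s in per_frame)
        tracks = tirf.link_tracks(per_frame, max_displacement=4.0)
        assert sum(len(tr.spots) for tr in tracks) == n_spots
        ids = [(s.frame_index, s.position) for tr in tracks for s in tr.spots]
        assert len(ids) == len(set(ids))

    def test_truth_tracks_recovered_without_splits(self):
        movie, truth = sim.make_tirf_movie(
            shape=(200, 200), n_frames=20, n_spots=30, persistent_fraction=1.0,
            diffusion_step=0.5, min_spacing=8.0, appearance_window=1, seed=6,
        )
        per_frame = tirf.detect_movie(movie)
        tracks = tirf.link_tracks(per_frame, max_displacement=4.0)
        full = [tr for tr in tracks if len(tr.spots) >= 19]
        assert len(full) >= 0.9 * len(truth.tracks)


class TestPersistence:
    def test_all_tracks_spanning_movie_give_one(self):
        per_frame = TestLinkTracks.as_per_frame([[(10.0, 10.0), (30.0, 30.0)]] * 10)
        tracks = tirf.link_tracks(per_frame, max_displacement=3.0)
        assert tirf.classify_persistence(tracks, 1.0, 9.0) == 1.0

    def test_no_track_meeting_cutoff_gives_zero(self):
        per_frame = TestLinkTracks.as_per_frame([[(10.0, 10.0)]] * 3 + [[]] * 7)
        tracks = tirf.link_tracks(per_frame, max_displacement=3.0)
        assert tirf.classify_persistence(tracks, 1.0, 60.0) == 0.0

    def test_zero_tracks_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            tirf.classify_persistence([], 1.0, 60.0)

    def test_persistent_fraction_recovered_from_simulation(self):
        ests = []
        for seed in range(3):
            movie, truth = sim.make_tirf_movie(
                shape=(200, 200), n_frames=60, n_spots=100,
                persistent_fraction=0.35, min_spacing=6.0, seed=seed,
            )
            per_frame = tirf.detect_movie(movie)
            tracks = tirf.link_tracks(per_frame, max_displacement=4.0, max_gap=1)
            ests.append(tirf.classify_persistence(tracks, movie.frame_interval, 40.0))
        assert abs(np.mean(ests) - 0.35) <= 0.05


class TestKymograph:
    def test_stationary_spot_makes_horizontal_streak(self):
        frames = np.stack([gaussian_frame((48, 48), [(24.0, 24.0)])] * 6)
        movie = TirfMovie(frames=frames)
        kymo = tirf.kymograph(movie, ((24.0, 4.0), (24.0, 44.0)))
        assert kymo.shape == (41, 6)
        peak_rows = kymo.argmax(axis=0)
        assert np.all(peak_rows == peak_rows[0])
        assert np.all(kymo.max(axis=0) > 100.0)

    def test_transient_spot_restricted_to_its_frames(self):
        blank = np.zeros((48, 48))
        spot = gaussian_frame((48, 48), [(24.0, 24.0)])
        frames = np.stack([blank, blank, blank, spot, spot, spot, blank])
        movie = TirfMovie(frames=frames)
        kymo = tirf.kymograph(movie, ((24.0, 4.0), (24.0, 44.0)))
        bright = kymo.max(axis=0) > 50.0
        np.testing.assert_array_equal(bright, [False] * 3 + [True] * 3 + [False])

    def test_moving_spot_slope_recovered(self):
        frames = np.stack(
            [gaussian_frame((64, 64), [(32.0, 10.0 + t)]) for t in range(20)]
        )
        movie = TirfMovie(frames=frames)
        kymo = tirf.kymograph(movie, ((32.0, 5.0), (32.0, 55.0)))
        peaks = kymo.argmax(axis=0)
        slope = np.polyfit(np.arange(20), peaks, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.1)

    def test_zero_length_line_rejected(self):
        movie = TirfMovie(frames=np.zeros((2, 16, 16)))
        with pytest.raises(ValueError, match="zero length"):
            tirf.kymograph(movie, ((4.0, 4.0), (4.0, 4.0)))

    def test_width_projection_catches_off_line_spot(self):
        frames = np.stack([gaussian_frame((48, 48), [(26.0, 24.0)])] * 3)
        movie = TirfMovie(frames=frames)
        narrow = tirf.kymograph(movie, ((24.0, 4.0), (24.0, 44.0)), width=1)
        wide = tirf.kymograph(movie, ((24.0, 4.0), (24.0, 44.0)), width=5)
        assert wide.max() > narrow.max()
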