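import numpy as np
import pytest

from centriomig import SceneConfig, generate_timelapse
from centriomig.grouping import CentrioleGroup
from centriomig.io import VoxelGrid
from centriomig.synthetic import groups_from_truth
from centriomig.tracking import (
    FiducialError,
    GeometryError,
    GroupTrack,
    build_kymograph,
    classify_direction,
    kymograph_ridge_slope,
    link_tracks,
    project_side_view,
)


def group_at(gid, centroid):
    return CentrioleGroup(gid, (), tuple(centroid), 0.0, 1)


class TestProjection:
    def test_delta_projection(self):
        data = np.zeros((1, 1, 8, 8, 8), np.float32)
        data[0, 0, 3, 4, 5] = 7.0
        proj = project_side_view(VoxelGrid(data), axis="x")
        assert proj.data.shape == (1, 1, 8, 8, 1)
        assert proj.data[0, 0, 3, 4, 0] == 7.0

    def test_constant_image_projection_constant(self):
        grid = VoxelGrid(np.full((1, 1, 4, 4, 4), 3.0, np.float32))
        proj = project_side_view(grid, axis="y")
        assert np.all(proj.data == 3.0)

    def test_matches_elementwise_max(self, rng):
        data = rng.random((1, 1, 4, 4, 4)).astype(np.float32)
        proj = project_side_view(VoxelGrid(data), axis="x")
        for z in range(4):
            for y in range(4):
                assert proj.data[0, 0, z, y, 0] == max(data[0, 0, z, y, :])

    def test_projecting_apical_axis_refused(self):
        with pytest.raises(ValueError):
            project_side_view(VoxelGrid(np.zeros((4, 4, 4))), axis="z")


class TestGroupTrack:
    def test_rate_consistency(self):
        tr = GroupTrack(0, (0, 3, 9), (1.0, 2.0, 4.0), elapsed_min=90.0)
        assert tr.rate_um_per_min == pytest.approx(tr.net_displacement_um / 90.0, abs=1e-12)

    def test_frames_strictly_increasing(self):
        with pytest.raises(ValueError):
            GroupTrack(0, (0, 0, 1), (1.0, 2.0, 3.0), elapsed_min=10.0)


class TestLinkTracks:
    def test_noiseless_constant_velocity_exact(self):
        cfg = SceneConfig(seed=1, image_shape=(100, 64, 64))
        _, truth = generate_timelapse(cfg, 1, [0.18], 10, 10.0, 0.0, render=False)
        tracks = link_tracks(
            groups_from_truth(truth), fiducial_id=truth.fiducial_index,
            frame_interval_min=10.0,
        )
        assert len(tracks) == 1
        assert tracks[0].rate_um_per_min == pytest.approx(0.18, abs=1e-9)
        assert tracks[0].direction == "apical"

    def test_fiducial_cancels_common_drift(self):
        frames = []
        for t in range(10):
            drift = np.array([0.05 * 10 * t, 0.0, 0.0])
            frames.append(
                [
                    group_at(0, np.array([10.0, 5, 5]) + drift),
                    group_at(9, np.array([20.0, 8, 8]) + drift),
                ]
            )
        tracks = link_tracks(frames, fiducial_id=9, frame_interval_min=10.0)
        assert len(tracks) == 1
        assert tracks[0].rate_um_per_min == pytest.approx(0.0, abs=1e-12)
        assert tracks[0].direction == "none"

    def test_sign_recovery_with_jitter(self):
        cfg = SceneConfig(seed=21, image_shape=(100, 72, 72))
        _, truth = generate_timelapse(
            cfg, 3, [0.1, -0.05, 0.0], 10, 10.0, positional_noise_um=0.05, render=False
        )
        tracks = link_tracks(
            groups_from_truth(truth), fiducial_id=truth.fiducial_index,
            frame_interval_min=10.0,
        )
        assert len(tracks) == 3
        rates = sorted(tr.rate_um_per_min for tr in tracks)
        for got, want in zip(rates, sorted([0.1, -0.05, 0.0])):
            assert got == pytest.approx(want, abs=0.02)

    def test_gap_bridged(self):
        frames = []
        for t in range(6):
            frame = [group_at(0, [10.0 - 0.1 * t, 5, 5])]
            if t == 3:
                frame = []  # group lost for one frame
            frames.append(frame)
        tracks = link_tracks(frames, frame_interval_min=10.0, max_gap=2)
        assert len(tracks) == 1
        assert tracks[0].frames == (0, 1, 2, 4, 5)

    def test_linking_invariant_to_frame_ordering(self, rng):
        frames, frames_shuffled = [], []
        for t in range(5):
            groups = [
                group_at(i, [10.0 + 3 * i - 0.05 * t, 5, 5]) for i in range(3)
            ]
            frames.append(groups)
            frames_shuffled.append([groups[i] for i in rng.permutation(3)])
        r1 = sorted(tr.rate_um_per_min for tr in link_tracks(frames, frame_interval_min=10.0))
        r2 = sorted(tr.rate_um_per_min for tr in link_tracks(frames_shuffled, frame_interval_min=10.0))
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_fiducial_missing_too_often(self):
        frames = [[group_at(0, [5.0, 5, 5])] for _ in range(6)]
        with pytest.raises(FiducialError):
            link_tracks(frames, fiducial_id=9, frame_interval_min=10.0)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "disp,expected",
        [(3.0, "apical"), (-0.2, "none"), (-3.0, "basal"), (0.4, "none")],
    )
    def test_threshold_rule(self, disp, expected):
        tr = GroupTrack(0, (0, 9), (0.0, disp), elapsed_min=90.0)
        assert classify_direction(tr, displacement_threshold_um=0.5) == expected

    def test_cohort_proportion(self):
        # 14 apical, 8 without net apical movement, as in explant imaging
        tracks = [GroupTrack(i, (0, 9), (0.0, 3.0), 90.0) for i in range(14)]
        tracks += [GroupTrack(i + 14, (0, 9), (0.0, -0.1), 90.0) for i in range(8)]
        labels = [classify_direction(t) for t in tracks]
        assert labels.count("apical") == 14
        assert len(labels) == 22


class TestKymograph:
    def make_movie(self, velocity=0.15, n_frames=8, seed=2):
        cfg = SceneConfig(seed=seed, image_shape=(100, 72, 72), snr=10)
        movie, truth = generate_timelapse(
            cfg, 1, [velocity], n_frames, 10.0, positional_noise_um=0.05
        )
        return cfg, project_side_view(movie, axis="x"), truth

    def test_ridge_slope_matches_velocity(self):
        cfg, side, truth = self.make_movie()
        start, end = truth.track_positions_um[0, 0], truth.track_positions_um[0, -1]
        zmax = (cfg.image_shape[0] - 1) * cfg.voxel_spacing_um[0]
        line = np.array(
            [
                [max(0.0, min(start[0], end[0]) - 3), start[1]],
                [min(zmax, max(start[0], end[0]) + 3), start[1]],
            ]
        )
        kymo = build_kymograph(side, line, width_um=1.0)
        slope = abs(kymograph_ridge_slope(kymo, frame_interval_min=10.0))
        assert slope == pytest.approx(0.15, rel=0.1)

    def test_static_group_vertical_ridge(self):
        cfg, side, truth = self.make_movie(velocity=0.0, seed=3)
        pos = truth.track_positions_um[0, 0]
        zmax = (cfg.image_shape[0] - 1) * cfg.voxel_spacing_um[0]
        line = np.array([[max(0.0, pos[0] - 4), pos[1]], [min(zmax, pos[0] + 4), pos[1]]])
        kymo = build_kymograph(side, line, width_um=1.0)
        ridge = kymo.data.argmax(axis=1) * kymo.pixel_size_um
        assert ridge.max() - ridge.min() < 0.5

    def test_blank_movie_background_kymograph(self):
        cfg = SceneConfig(seed=4, image_shape=(32, 32, 32), snr=None)
        data = np.full((3, 1, 32, 32, 1), cfg.background_level, np.float32)
        side = VoxelGrid(data)
        line = np.array([[0.5, 0.5], [6.0, 2.0]])
        kymo = build_kymograph(side, line)
        assert np.allclose(kymo.data, cfg.background_level)
        assert kymo.data.shape[0] == 3

    def test_line_outside_image(self):
        side = VoxelGrid(np.zeros((1, 1, 16, 16, 1), np.float32))
        with pytest.raises(GeometryError):
            build_kymograph(side, np.array([[0.0, 0.0], [100.0, 0.0]]))
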