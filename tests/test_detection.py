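import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from centriomig import SceneConfig
from centriomig.detection import (
    Cilium,
    Spot,
    associate,
    count_centrioles,
    detect_cilia,
    detect_spots,
)
from centriomig.io import VoxelGrid
from centriomig.synthetic import render_scene


def render_spots(positions, seed=0, snr=None, shape=(48, 96, 96)):
    cfg = SceneConfig(seed=seed, image_shape=shape, snr=snr)
    return cfg, render_scene(cfg, np.asarray(positions, dtype=float))


class TestDetectSpots:
    def test_noiseless_single_punctum_localized(self):
        _, grid = render_spots([[6.3, 5.07, 5.03]])
        spots = detect_spots(grid, channel="centrin")
        assert len(spots) == 1
        assert np.linalg.norm(np.array(spots[0].position_um) - [6.3, 5.07, 5.03]) < 0.05

    def test_knob_recovery_and_localization(self, knob_scene, knob_spots):
        _, _, truth = knob_scene
        assert abs(len(knob_spots) - truth.n_spots) <= 2
        det = np.array([s.position_um for s in knob_spots])
        d = cdist(truth.spot_positions_um, det)
        # each detection near a distinct true punctum
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(d)
        matched = d[rows, cols]
        assert np.median(matched) < 0.3

    def test_pure_noise_yields_no_spots(self):
        hits = 0
        for seed in range(20):
            cfg = SceneConfig(seed=seed, image_shape=(32, 64, 64), snr=10.0)
            grid = render_scene(cfg, np.zeros((0, 3)))
            hits += len(detect_spots(grid, channel="centrin")) == 0
        assert hits >= 19

    def test_all_zero_image_empty_list(self):
        grid = VoxelGrid(np.zeros((1, 1, 16, 16, 16), np.float32))
        assert detect_spots(grid, channel=0) == []

    def test_unknown_channel(self, knob_scene):
        _, grid, _ = knob_scene
        with pytest.raises(ValueError):
            detect_spots(grid, channel="nope")

    def test_count_monotone_in_threshold(self, knob_scene):
        _, grid, _ = knob_scene
        counts = []
        for thr in (0.05, 0.15, 0.3, 0.6):
            spots = detect_spots(
                grid, channel="centrin", threshold_policy="absolute", threshold_abs=thr
            )
            counts.append(len(spots))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_translation_equivariance(self):
        base = np.array([[6.0, 4.0, 4.0], [6.0, 7.0, 7.0]])
        shift_vox = np.array([3, 5, 5])
        spacing = np.array([0.27, 0.11, 0.11])
        _, g1 = render_spots(base, seed=1)
        _, g2 = render_spots(base + shift_vox * spacing, seed=1)
        s1 = detect_spots(g1, channel="centrin")
        s2 = detect_spots(g2, channel="centrin")
        assert len(s1) == len(s2) == 2
        p1 = np.sort(np.array([s.position_um for s in s1]), axis=0)
        p2 = np.sort(np.array([s.position_um for s in s2]), axis=0)
        np.testing.assert_allclose(p2 - p1, np.broadcast_to(shift_vox * spacing, p1.shape), atol=0.05)

    def test_review_table_filters(self, knob_scene, knob_spots):
        import pandas as pd

        _, grid, _ = knob_scene
        review = pd.DataFrame({"id": [s.id for s in knob_spots[:3]], "keep": [False, True, False]})
        kept = detect_spots(grid, channel="centrin", review=review)
        kept_ids = {s.id for s in kept}
        assert knob_spots[0].id not in kept_ids
        assert knob_spots[1].id in kept_ids


class TestCountCentrioles:
    def test_containment(self, knob_spots):
        counts, outside = count_centrioles(knob_spots)
        assert counts[1] == len(knob_spots) and outside == 0

    def test_empty(self):
        counts, outside = count_centrioles([])
        assert counts == {1: 0} and outside == 0

    def test_roi_breakdown(self):
        roi = np.zeros((10, 10, 10), dtype=int)
        roi[:, :5, :] = 1
        roi[:, 5:, :] = 2
        spots = [
            Spot(0, (0.5, 2.2, 0.5), 0.5, 1.0),
            Spot(1, (0.5, 7.4, 0.5), 0.5, 1.0),
            Spot(2, (0.5, 6.8, 0.2), 0.5, 1.0),
        ]
        counts, outside = count_centrioles(spots, roi, spacing_um=(1, 1, 1))
        assert counts == {1: 1, 2: 2} and outside == 0


class TestDetectCilia:
    def test_straight_filament_length(self):
        cfg = SceneConfig(seed=0, image_shape=(64, 96, 96), snr=None)
        base = np.array([12.0, 5.0, 5.0])
        tip = base + np.array([-4.0, 3.0, 0.0]) / 5.0 * 5.0  # length 5 µm
        line = np.linspace(base, tip, 40)
        grid = render_scene(cfg, np.zeros((0, 3)), [line])
        cilia = detect_cilia(grid, channel="cilia", base_reference_um=base)
        assert len(cilia) == 1
        assert cilia[0].length_um == pytest.approx(5.0, abs=0.3)

    def test_short_filament_dropped_by_min_length(self):
        # sharp optics (no expansion) so a 1 µm filament is resolved as such
        cfg = SceneConfig(seed=0, image_shape=(48, 64, 64), snr=None,
                          expansion_factor=1.0)
        base = np.array([8.0, 3.0, 3.0])
        line = np.linspace(base, base + [-0.6, 0.8, 0.0], 15)  # 1 µm
        grid = render_scene(cfg, np.zeros((0, 3)), [line])
        assert detect_cilia(grid, channel="cilia", min_length_um=2.0,
                            base_reference_um=base) == []

    def test_blank_channel_no_cilia(self):
        grid = VoxelGrid(np.zeros((1, 2, 16, 16, 16), np.float32),
                         channel_names=("centrin", "cilia"))
        assert detect_cilia(grid, channel="cilia") == []

    def test_knob_cilium_recovery(self, knob_scene, knob_spots):
        _, grid, truth = knob_scene
        cloud = np.array([s.position_um for s in knob_spots])
        cilia = detect_cilia(grid, channel="cilia", base_reference_um=cloud)
        assert abs(len(cilia) - truth.n_cilia) <= 3


def brute_force_matching(spot_pos, base_pos, radius):
    """Max-cardinality, then min-total-distance matching within radius."""
    n_s, n_c = len(spot_pos), len(base_pos)
    d = cdist(spot_pos, base_pos)
    k_max = min(n_s, n_c)
    best_count, best_cost = -1, np.inf
    for k in range(k_max, -1, -1):
        for srows in itertools.combinations(range(n_s), k):
            for perm in itertools.permutations(range(n_c), k):
                dd = [d[i, j] for i, j in zip(srows, perm)]
                if all(x <= radius for x in dd):
                    cost = sum(dd)
                    if k > best_count or (k == best_count and cost < best_cost):
                        best_count, best_cost = k, cost
        if best_count == k:
            break
    return max(best_count, 0), (best_cost if best_count > 0 else 0.0)


class TestAssociate:
    def make_cilium(self, cid, base):
        poly = np.vstack([base, np.asarray(base) + [-2.0, 0.0, 0.0]])
        return Cilium(id=cid, polyline_um=poly, length_um=2.0)

    def test_perfect_geometry_fraction(self, rng):
        spots = [Spot(i, tuple(p), 0.5, 1.0) for i, p in enumerate(rng.random((36, 3)) * 30)]
        cilia = [
            self.make_cilium(i, np.array(spots[i].position_um) + 0.1)
            for i in range(31)
        ]
        res = associate(spots, cilia, capture_radius_um=0.5)
        assert res.fraction_associated == pytest.approx(31 / 36)

    def test_no_cilia(self):
        spots = [Spot(0, (1, 1, 1), 0.5, 1.0)]
        res = associate(spots, [], capture_radius_um=0.5)
        assert res.fraction_associated == 0.0

    def test_matches_brute_force_on_small_instances(self, rng):
        for _ in range(25):
            n_s, n_c = rng.integers(1, 7), rng.integers(1, 7)
            spot_pos = rng.random((n_s, 3)) * 4
            base_pos = rng.random((n_c, 3)) * 4
            spots = [Spot(i, tuple(p), 0.5, 1.0) for i, p in enumerate(spot_pos)]
            cilia = [self.make_cilium(i, p) for i, p in enumerate(base_pos)]
            res = associate(spots, cilia, capture_radius_um=1.0)
            n_opt, cost_opt = brute_force_matching(spot_pos, base_pos, 1.0)
            assert len(res.pairs) == n_opt
            d = cdist(spot_pos, base_pos)
            cost = sum(d[i, j] for i, j in res.pairs)
            assert cost == pytest.approx(cost_opt, abs=1e-9)

    def test_invariant_to_id_relabeling(self, rng):
        spot_pos = rng.random((5, 3)) * 3
        base_pos = rng.random((4, 3)) * 3
        spots = [Spot(i, tuple(p), 0.5, 1.0) for i, p in enumerate(spot_pos)]
        cilia = [self.make_cilium(i, p) for i, p in enumerate(base_pos)]
        res = associate(spots, cilia, capture_radius_um=1.5)
        spots_r = [Spot(i + 10, s.position_um, 0.5, 1.0) for i, s in enumerate(spots)]
        cilia_r = [Cilium(c.id + 100, c.polyline_um, c.length_um) for c in cilia]
        res_r = associate(spots_r, cilia_r, capture_radius_um=1.5)
        assert res.fraction_associated == res_r.fraction_associated
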