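"""OPTICS correctness against a brute-force reference, disc removal and
vessel segmentation quality on generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from retinopipe import segmentation as seg
from retinopipe import synthetic as syn
from retinopipe.experiments import brute_force_optics


class TestCoreDistance:
    def test_line_of_points(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        # 2nd-nearest neighbor of point 1 (counting the point itself) is at distance 1
        assert seg.core_distance(pts, 1, min_pts=2, eps=5.0) == pytest.approx(1.0)

    def test_isolated_point_undefined(self):
        pts = np.array([[0.0], [10.0]])
        assert not np.isfinite(seg.core_distance(pts, 0, min_pts=2, eps=1.0))

    def test_duplicate_points_give_zero(self):
        pts = np.array([[1.0], [1.0], [5.0]])
        assert seg.core_distance(pts, 0, min_pts=2, eps=5.0) == 0.0

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            seg.core_distance(np.zeros((3, 2)), 5, 2, 1.0)


class TestReachabilityDistance:
    def test_max_of_core_and_euclidean(self):
        pts = np.array([[0.0], [1.0], [2.0], [7.0]])
        # core(1) = 1; d(3,1) = 6 -> reach = 6
        assert seg.reachability_distance(3, 1, pts, 2, 10.0) == pytest.approx(6.0)
        # d(2,1) = 1 = core(1) -> reach = core
        assert seg.reachability_distance(2, 1, pts, 2, 10.0) == pytest.approx(1.0)

    def test_non_core_center_undefined(self):
        pts = np.array([[0.0], [10.0], [20.0]])
        assert not np.isfinite(seg.reachability_distance(0, 1, pts, 2, 1.0))


class TestOpticsOrder:
    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(3)
        x = rng.random((120, 2))
        params = seg.OpticsParams(min_pts=4, eps=0.2, extraction_threshold=0.1)
        prof = seg.optics_order(x, params)
        o_ref, r_ref, c_ref = brute_force_optics(x, 4, 0.2)
        assert np.array_equal(prof.order, o_ref)
        finite = np.isfinite(r_ref)
        assert np.allclose(prof.reach[finite], r_ref[finite], atol=1e-9)
        cf = np.isfinite(c_ref)
        assert np.allclose(prof.core[cf], c_ref[cf], atol=1e-9)

    def test_every_sample_appears_once(self):
        rng = np.random.default_rng(4)
        x = rng.random((50, 2))
        prof = seg.optics_order(x, seg.OpticsParams(min_pts=3, eps=0.3))
        assert sorted(prof.order.tolist()) == list(range(50))

    def test_reach_bounded_below_by_generating_neighbor(self):
        # reach(p) = max(core(o), d(o, p)) for some core point o, so it can
        # never drop below the smallest such value over all core points
        rng = np.random.default_rng(5)
        x = rng.random((80, 2))
        prof = seg.optics_order(x, seg.OpticsParams(min_pts=3, eps=0.25))
        dist = np.linalg.norm(x[:, None] - x[None], axis=2)
        for pos, idx in enumerate(prof.order):
            r = prof.reach[pos]
            if not np.isfinite(r):
                continue
            bounds = [
                max(prof.core[o], dist[o, idx])
                for o in range(len(x))
                if o != idx and np.isfinite(prof.core[o])
            ]
            assert r >= min(bounds) - 1e-12

    def test_single_point(self):
        prof = seg.optics_order(np.array([[0.3, 0.7]]), seg.OpticsParams(min_pts=2, eps=0.1))
        assert prof.order.tolist() == [0]
        assert not np.isfinite(prof.reach[0])

    def test_two_separated_blobs_one_spike(self):
        rng = np.random.default_rng(6)
        pts = np.vstack(
            [rng.normal(0, 0.05, (100, 2)), rng.normal(0, 0.05, (100, 2)) + [1, 0]]
        )
        prof = seg.optics_order(pts, seg.OpticsParams(min_pts=5, eps=0.3))
        # one restart (undefined reach) between the blobs, none within them
        breaks = sum(
            1 for k in range(1, len(prof.reach))
            if not np.isfinite(prof.reach[k]) or prof.reach[k] > 0.2
        )
        assert breaks == 1
        finite = prof.reach[np.isfinite(prof.reach)]
        assert finite.max() < 0.2


class TestExtractClusters:
    def test_two_blob_ari(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [rng.normal(0, 0.05, (100, 2)), rng.normal(0, 0.05, (100, 2)) + [1, 0]]
        )
        truth = np.repeat([0, 1], 100)
        prof = seg.optics_order(pts, seg.OpticsParams(min_pts=5, eps=0.3))
        labels = seg.extract_clusters(prof, 0.1)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_low_threshold_fragments_or_noise(self):
        rng = np.random.default_rng(2)
        x = rng.random((60, 2))
        prof = seg.optics_order(x, seg.OpticsParams(min_pts=3, eps=0.5))
        labels = seg.extract_clusters(prof, 0.0)
        # threshold 0: only exact duplicates could share a cluster
        for lab in set(labels) - {-1}:
            members = x[labels == lab]
            assert np.allclose(members, members[0])

    def test_high_threshold_single_cluster(self):
        rng = np.random.default_rng(7)
        x = rng.random((60, 2)) * 0.1
        prof = seg.optics_order(x, seg.OpticsParams(min_pts=3, eps=1.0))
        labels = seg.extract_clusters(prof, 10.0)
        assert set(labels) == {0}

    def test_idempotent_on_profile(self):
        rng = np.random.default_rng(8)
        x = rng.random((80, 2))
        prof = seg.optics_order(x, seg.OpticsParams(min_pts=4, eps=0.3))
        a = seg.extract_clusters(prof, 0.15)
        b = seg.extract_clusters(prof, 0.15)
        assert np.array_equal(a, b)


class TestJaccardDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [({1, 2}, {1, 2}, 0.0), ({1}, {2}, 1.0), ({1}, {1, 2}, 0.5), (set(), set(), 0.0)],
    )
    def test_known_values(self, a, b, expected):
        assert seg.jaccard_distance(a, b) == pytest.approx(expected)

    @given(
        st.sets(st.integers(0, 20), max_size=10),
        st.sets(st.integers(0, 20), max_size=10),
        st.sets(st.integers(0, 20), max_size=10),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_metric_properties(self, a, b, c):
        dab = seg.jaccard_distance(a, b)
        assert dab == seg.jaccard_distance(b, a)
        assert seg.jaccard_distance(a, a) == 0.0
        assert dab <= seg.jaccard_distance(a, c) + seg.jaccard_distance(c, b) + 1e-12


class TestDiscRemoval:
    def test_iou_against_ground_truth(self):
        ious = []
        for s in range(8):
            lf = syn.generate_fundus(syn.FundusSpec(seed=s))
            _, disc = seg.remove_optic_disc(lf.image)
            inter = (disc & lf.disc_mask).sum()
            union = (disc | lf.disc_mask).sum()
            ious.append(inter / union if union else 0.0)
        assert min(ious) >= 0.6

    def test_flat_image_yields_empty_mask(self):
        img = np.full((64, 64, 3), 90, dtype=np.uint8)
        _, disc = seg.remove_optic_disc(img)
        assert not disc.any()

    def test_deterministic(self):
        lf = syn.generate_fundus(syn.FundusSpec(seed=9))
        a = seg.remove_optic_disc(lf.image)
        b = seg.remove_optic_disc(lf.image)
        assert np.array_equal(a[1], b[1]) and np.array_equal(a[0], b[0])


class TestPixelFeatures:
    def test_flat_image_yields_no_samples(self):
        img = np.full((64, 64, 3), 90, dtype=np.uint8)
        samples, coords = seg.pixel_features(img, np.zeros((64, 64), bool))
        assert len(samples) == 0

    def test_sample_cap(self):
        lf = syn.generate_fundus(syn.FundusSpec(seed=1, noise_density=0))
        params = seg.OpticsParams(max_samples=500)
        samples, _ = seg.pixel_features(lf.image, np.zeros(lf.image.shape[:2], bool), params)
        assert len(samples) <= 500

    def test_vessel_pixels_score_higher_vesselness(self):
        lf = syn.generate_fundus(syn.FundusSpec(seed=2, noise_density=0))
        vess = seg.vesselness_map(lf.image)
        assert vess[lf.vessel_mask].mean() > vess[~lf.vessel_mask].mean()


class TestSegmentVessels:
    def test_dice_against_ground_truth(self):
        dices = []
        for s in range(3):
            lf = syn.generate_fundus(
                syn.FundusSpec(height=128, width=128, seed=s, noise_density=0)
            )
            result = seg.segment_vessels(lf.image)
            vm, gt = result.vessel_mask, lf.vessel_mask
            dices.append(2 * (vm & gt).sum() / max(vm.sum() + gt.sum(), 1))
            assert not (result.vessel_mask & result.disc_mask).any()
        assert min(dices) >= 0.6

    def test_flat_image_yields_empty_mask(self):
        result = seg.segment_vessels(np.full((64, 64, 3), 90, dtype=np.uint8))
        assert not result.vessel_mask.any()

    def test_deterministic(self):
        lf = syn.generate_fundus(
            syn.FundusSpec(height=96, width=96, seed=3, noise_density=0)
        )
        a = seg.segment_vessels(lf.image)
        b = seg.segment_vessels(lf.image)
        assert np.array_equal(a.vessel_mask, b.vessel_mask)
        assert np.array_equal(a.cluster_labels, b.cluster_labels)
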