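"""Waypoint dissection, probability scoring, cleaning, lesion screening."""
import warnings

import numpy as np
import pytest

import tractometry as tm


@pytest.fixture(scope="module")
def scene_tractogram(small_scene, scene_field):
    field, masks = scene_field
    maps = field.scalar_maps()
    params = tm.TrackingParams(step_mm=0.75, min_len_mm=20.0, max_len_mm=120.0)
    return tm.track_whole_brain(field, maps, params), masks


class TestSlfRoiDefinitions:
    def test_planes_and_disjointness(self):
        rois = tm.define_slf_rois()
        for hemi in ("L", "R"):
            ii = rois[f"{hemi}_SLF_II_anterior"].plane
            iii = rois[f"{hemi}_SLF_III_anterior"].plane
            post = rois[f"{hemi}_posterior"].plane
            assert ii.y_mm == iii.y_mm == 2.0  # anterior-commissure plane
            assert post.y_mm == -25.0  # posterior-commissure plane
            # dorsal/ventral boxes share the plane but not in-plane area
            assert ii.z_range[0] >= iii.z_range[1]

    def test_left_right_mirror_symmetry(self):
        rois = tm.define_slf_rois()
        for tag in ("SLF_II_anterior", "SLF_III_anterior", "posterior"):
            left = rois[f"L_{tag}"].plane
            right = rois[f"R_{tag}"].plane
            assert left.x_range == (-right.x_range[1], -right.x_range[0])
            assert left.z_range == right.z_range

    def test_merged_anterior_covers_both_boxes(self):
        rois = tm.define_slf_rois()
        merged = tm.merged_anterior_roi(rois["L_SLF_II_anterior"],
                                        rois["L_SLF_III_anterior"])
        pt_dorsal = np.array([[-30.0, 2.0, 30.0]])
        pt_ventral = np.array([[-30.0, 2.0, 5.0]])
        assert merged.contains(pt_dorsal)[0]
        assert merged.contains(pt_ventral)[0]


class TestTransformRois:
    def test_identity_leaves_planes_unchanged(self):
        rois = tm.define_slf_rois()
        moved = tm.transform_rois(rois, np.eye(4))
        for key in rois:
            assert moved[key].plane == rois[key].plane

    def test_translation_shifts_plane_y(self):
        rois = tm.define_slf_rois()
        A = np.eye(4)
        A[:3, 3] = [5.0, -7.0, 3.0]
        moved = tm.transform_rois(rois, A)
        assert moved["L_posterior"].plane.y_mm == -32.0
        assert moved["L_SLF_II_anterior"].plane.y_mm == -5.0

    def test_mask_roundtrip_preserves_voxel_count(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[5:14, 6:13, 4:16] = True
        roi = tm.WaypointRoi(name="m", space="native", mask=mask,
                             affine=np.diag([1.5, 1.5, 1.5, 1.0]))
        A = np.eye(4)
        A[:3, 3] = [3.0, -4.5, 1.5]
        fwd = tm.transform_rois([roi], A)[0]
        back = tm.transform_rois([fwd], np.linalg.inv(A))[0]
        grid_affine = np.diag([1.5, 1.5, 1.5, 1.0])
        n0 = roi.to_mask(grid_affine, mask.shape).sum()
        n2 = back.to_mask(grid_affine, mask.shape).sum()
        assert abs(n2 - n0) / n0 < 0.02

    def test_shear_affine_rejected_for_planes(self):
        rois = tm.define_slf_rois()
        A = np.eye(4)
        A[1, 0] = 0.3  # mixes x into the coronal coordinate
        with pytest.raises(tm.DataError):
            tm.transform_rois(rois, A)


class TestWaypointAssignment:
    def test_two_bundle_phantom_fully_correctly_labeled(
            self, small_scene, scene_tractogram):
        """Every streamline landing in an anterior box belongs to the bundle
        constructed to thread it — segmentation accuracy 1.0."""
        tractogram, masks = scene_tractogram
        rois = small_scene.rois
        for hemi in ("L", "R"):
            post = rois[f"{hemi}_posterior"]
            for tract, other in (("SLF_II", "SLF_III"),
                                 ("SLF_III", "SLF_II")):
                bundle = tm.assign_by_waypoints(
                    tractogram, rois[f"{hemi}_{tract}_anterior"], post,
                    name=tract, hemisphere=hemi)
                assert len(bundle) > 50
                own = masks[f"{hemi}_{tract}"]
                inv = tm.inverse_affine(small_scene.affine)
                for s in bundle.streamlines:
                    vox = np.rint(tm.apply_affine(inv, s)).astype(int)
                    in_own = own[vox[:, 0], vox[:, 1], vox[:, 2]]
                    # generated inside its own tube, never the sibling's
                    sib = masks[f"{hemi}_{other}"]
                    assert in_own.mean() > 0.9
                    assert not sib[vox[:, 0], vox[:, 1], vox[:, 2]].any()

    def test_membership_needs_both_rois(self, small_scene, scene_tractogram):
        tractogram, _ = scene_tractogram
        rois = small_scene.rois
        post_only = tm.assign_by_waypoints(
            tractogram, rois["L_posterior"], rois["L_posterior"])
        both = tm.assign_by_waypoints(
            tractogram, rois["L_SLF_II_anterior"], rois["L_posterior"])
        # posterior-only membership is a superset; anterior pairing prunes it
        assert set(both.indices) < set(post_only.indices)

    def test_assignment_invariant_to_point_reversal(
            self, small_scene, scene_tractogram):
        tractogram, _ = scene_tractogram
        reversed_tg = tm.Tractogram(
            [s[::-1].copy() for s in tractogram.streamlines],
            tractogram.reference_affine, tractogram.reference_shape)
        rois = small_scene.rois
        a = tm.assign_by_waypoints(tractogram, rois["R_SLF_II_anterior"],
                                   rois["R_posterior"])
        b = tm.assign_by_waypoints(reversed_tg, rois["R_SLF_II_anterior"],
                                   rois["R_posterior"])
        assert np.array_equal(a.indices, b.indices)

    def test_sub_bundles_disjoint(self, small_scene, scene_tractogram):
        tractogram, _ = scene_tractogram
        rois = small_scene.rois
        ii = tm.assign_by_waypoints(tractogram, rois["L_SLF_II_anterior"],
                                    rois["L_posterior"])
        iii = tm.assign_by_waypoints(tractogram, rois["L_SLF_III_anterior"],
                                     rois["L_posterior"])
        assert not set(ii.indices) & set(iii.indices)


class TestProbabilityScoring:
    def _bundle(self, scene_tractogram):
        tractogram, _ = scene_tractogram
        return tm.TractBundle(name="all", hemisphere="",
                              tractogram=tractogram,
                              indices=np.arange(len(tractogram)))

    def test_uniform_maps(self, small_scene, scene_tractogram):
        bundle = self._bundle(scene_tractogram)
        ones = np.ones(small_scene.shape)
        zeros = np.zeros(small_scene.shape)
        assert np.allclose(tm.score_against_probability_map(
            bundle, ones, small_scene.affine), 1.0)
        assert np.allclose(tm.score_against_probability_map(
            bundle, zeros, small_scene.affine), 0.0)

    def test_half_and_half_scores_near_half(self, small_scene):
        # straight streamline crossing the boundary of a p=1 / p=0 split
        shape = small_scene.shape
        prob = np.zeros(shape)
        prob[:, : shape[1] // 2, :] = 1.0
        inv_y = (shape[1] - 1) / 2 * 1.5
        s = np.column_stack([np.zeros(41), np.linspace(-inv_y, inv_y, 41),
                             np.zeros(41)])
        tg = tm.Tractogram([s], small_scene.affine, shape)
        bundle = tm.TractBundle(name="b", hemisphere="", tractogram=tg,
                                indices=[0])
        score = tm.score_against_probability_map(bundle, prob,
                                                 small_scene.affine)[0]
        assert abs(score - 0.5) < 0.05


class TestCleaning:
    def _uniform_bundle(self, n=100, length=50.0):
        sl = [np.column_stack([np.linspace(0, length, 60),
                               np.full(60, 10.0 + 0.01 * i),
                               np.full(60, 10.0)]) for i in range(n)]
        tg = tm.Tractogram(sl, np.eye(4), (60, 30, 30))
        return tm.TractBundle(name="u", hemisphere="", tractogram=tg,
                              indices=np.arange(n))

    def test_homogeneous_bundle_retains_at_least_95_percent(self):
        bundle = self._uniform_bundle(100)
        rng = np.random.default_rng(0)
        scores = rng.uniform(0.8, 1.0, 100)
        cleaned = tm.clean_bundle(bundle, scores)
        assert len(cleaned) >= 95

    def test_doubled_length_outlier_removed(self):
        bundle = self._uniform_bundle(100)
        doubled = np.column_stack([np.linspace(0, 100.0, 60),
                                   np.full(60, 9.0), np.full(60, 10.0)])
        tg = tm.Tractogram(bundle.tractogram.streamlines + [doubled],
                           np.eye(4), (80, 30, 30))
        bundle = tm.TractBundle(name="u", hemisphere="", tractogram=tg,
                                indices=np.arange(101))
        cleaned = tm.clean_bundle(bundle, scores=None)
        assert 100 not in cleaned.indices
        assert len(cleaned) == 100

    def test_identity_under_disabled_thresholds(self):
        bundle = self._uniform_bundle(50)
        scores = np.linspace(0.1, 1.0, 50)
        cleaned = tm.clean_bundle(bundle, scores, score_quantile=0.0,
                                  length_z_max=np.inf)
        assert np.array_equal(cleaned.indices, bundle.indices)

    def test_cleaned_is_subset(self, small_scene, scene_tractogram):
        tractogram, _ = scene_tractogram
        rois = small_scene.rois
        bundle = tm.assign_by_waypoints(tractogram, rois["L_SLF_II_anterior"],
                                        rois["L_posterior"])
        scores = tm.score_against_probability_map(
            bundle, small_scene.prob_maps["L_SLF_II"], small_scene.affine)
        cleaned = tm.clean_bundle(bundle, scores)
        assert set(cleaned.indices) <= set(bundle.indices)

    def test_empty_bundle_fatal(self):
        tg = tm.Tractogram([], np.eye(4), (10, 10, 10))
        bundle = tm.TractBundle(name="e", hemisphere="", tractogram=tg,
                                indices=[])
        with pytest.raises(tm.EmptyBundleError):
            tm.clean_bundle(bundle)


class TestLesionScreen:
    def test_probability_rule(self, small_scene):
        prob = small_scene.prob_maps["L_SLF_II"]
        assert tm.lesion_overlap_screen(
            small_scene.lesions["left_dorsal_hit"], prob) == "affected"
        assert tm.lesion_overlap_screen(
            small_scene.lesions["background_miss"], prob) == "not_affected"

    def test_single_boundary_voxel_just_over_threshold(self):
        prob = np.full((5, 5, 5), 0.1)
        prob[2, 2, 2] = 0.51
        lesion = np.zeros((5, 5, 5), dtype=bool)
        lesion[2, 2, 2] = True
        assert tm.lesion_overlap_screen(lesion, prob) == "affected"
        prob[2, 2, 2] = 0.5  # strict inequality: exactly 0.5 is not enough
        assert tm.lesion_overlap_screen(lesion, prob) == "not_affected"

    def test_empty_lesion_warns_not_affected(self):
        prob = np.ones((4, 4, 4))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            verdict = tm.lesion_overlap_screen(np.zeros((4, 4, 4)), prob)
        assert verdict == "not_affected"
        assert any("empty lesion" in str(w.message) for w in rec)

    def test_majority_mode(self):
        prob = np.zeros((4, 4, 4))
        prob[0, 0, 0] = 0.9
        lesion = np.ones((4, 4, 4), dtype=bool)
        assert tm.lesion_overlap_screen(lesion, prob, mode="any") == "affected"
        assert tm.lesion_overlap_screen(lesion, prob,
                                        mode="majority") == "not_affected"
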