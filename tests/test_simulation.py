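import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from capfuse.geometry import CapFootprint, RigidTransform
from capfuse.raycast import ray_intersects
from capfuse.simulation import (CYLINDER_CATALOG_MM, make_costal_graft,
                                make_cylindrical_graft, place_graft,
                                plan_drilling, simulate_resection)
from capfuse.simulation import _footprint_grid


@pytest.fixture(scope="module")
def resected(lesion_result, lesion_case):
    """Fused scene with the true lesion footprint resected (in the CT frame
    of the estimated transform)."""
    fp_mri = lesion_case.truth.footprint
    frame_ct = lesion_case.truth.anatomical_frame.transformed(
        lesion_result.transform)
    fp = CapFootprint(frame_ct, fp_mri.alpha_v_deg, fp_mri.alpha_h_deg,
                      fp_mri.surface_radius, fp_mri.center_rotation)
    return simulate_resection(lesion_result.scene, fp), fp


def oracle_coverage(grafts, fp, resolution=0.2):
    """Independent coverage oracle: cast an AP-axis ray through each
    footprint cell centre and count graft hits."""
    frame = fp.frame
    cells, inside, _ = _footprint_grid(fp, resolution)
    pts = cells[inside]
    origins = (frame.origin + pts[:, 0, None] * frame.mediolateral
               + pts[:, 1, None] * frame.proximodistal
               + 2 * fp.surface_radius * frame.anteroposterior)
    covered = np.zeros(len(origins), dtype=bool)
    for g in grafts:
        m = g.posed_mesh()
        covered |= ray_intersects(m.vertices, m.faces, origins,
                                  -frame.anteroposterior)
    return float(covered.mean())


def _pose_on_cap(fp, offset_u=0.0, offset_v=0.0, depth=3.0, tilt=None,
                 rng=None):
    frame = fp.frame
    target_axis = frame.anteroposterior.copy()
    if tilt is not None:
        target_axis = target_axis + tilt
    rot, _ = Rotation.align_vectors(target_axis[None] /
                                    np.linalg.norm(target_axis),
                                    np.array([[0.0, 0.0, 1.0]]))
    c = (frame.origin + (fp.surface_radius - depth) * frame.anteroposterior
         + offset_u * frame.mediolateral + offset_v * frame.proximodistal)
    return RigidTransform(rot.as_matrix(), c)


class TestGraftModels:
    def test_costal_block_volume(self):
        g = make_costal_graft(15.0, 11.0, 10.0)
        assert g.mesh.volume() == pytest.approx(15 * 11 * 10, rel=0.02)

    def test_cylinder_volume(self):
        g = make_cylindrical_graft(7.0, 12.0)
        assert g.mesh.volume() == pytest.approx(np.pi * 3.5 ** 2 * 12, rel=0.02)

    @pytest.mark.parametrize("d", CYLINDER_CATALOG_MM)
    def test_catalog_diameters_accepted(self, d):
        g = make_cylindrical_graft(d, catalog=CYLINDER_CATALOG_MM)
        assert g.dims["diameter"] == d

    def test_off_catalog_rejected(self):
        with pytest.raises(ValueError, match="catalog"):
            make_cylindrical_graft(6.0, catalog=CYLINDER_CATALOG_MM)

    def test_zero_dimension_rejected(self):
        with pytest.raises(ValueError):
            make_costal_graft(0.0, 10, 10)
        with pytest.raises(ValueError):
            make_cylindrical_graft(-5.0)


class TestResection:
    def test_partition_and_visibility(self, resected, lesion_result):
        scene, fp = resected
        orig = lesion_result.scene.models["cartilage"]
        assert scene.models["resection"].visible is False
        assert (scene.models["resection"].n_faces
                + scene.models["cartilage"].n_faces == orig.n_faces)
        # toggling visibility restores the full render set
        scene.models["resection"].visible = True
        labels = {m.label for m in scene.visible_models()}
        assert "resection" in labels and "cartilage" in labels

    def test_lesion_faces_removed(self, resected, lesion_result):
        """The resection contains at least 95% of the faces whose centroids
        fall in the true footprint."""
        scene, fp = resected
        orig = lesion_result.scene.models["cartilage"]
        centroids = orig.vertices[orig.faces].mean(axis=1)
        in_fp = fp.contains_points(centroids)
        assert scene.models["resection"].n_faces >= 0.95 * in_fp.sum()

    def test_empty_footprint_rejected(self, lesion_result):
        with pytest.raises(ValueError):
            simulate_resection(lesion_result.scene, None)


class TestPlacement:
    def test_congruent_block_covers_footprint(self, resected, lesion_result):
        scene, fp = resected
        block = make_costal_graft(length=18.0, width=16.0, height=10.0)
        res = place_graft(scene, block.with_pose(_pose_on_cap(fp, depth=4.0)),
                          host_bone_mask=lesion_result.masks["bone_ct"])
        assert res.coverage_fraction == pytest.approx(1.0, abs=0.02)

    def test_graft_off_footprint_zero_coverage(self, resected, lesion_result):
        scene, fp = resected
        g = make_cylindrical_graft(7.0, 12.0)
        pose = _pose_on_cap(fp, offset_u=40.0, offset_v=40.0)
        with pytest.warns(UserWarning, match="does not cover"):
            res = place_graft(scene, g.with_pose(pose),
                              host_bone_mask=lesion_result.masks["bone_ct"])
        assert res.coverage_fraction == 0.0

    def test_two_cylinders_match_voxel_oracle(self, resected, lesion_result):
        scene, fp = resected
        grafts = [
            make_cylindrical_graft(7.0, 12.0).with_pose(
                _pose_on_cap(fp, offset_u=-3.2)),
            make_cylindrical_graft(7.0, 12.0).with_pose(
                _pose_on_cap(fp, offset_u=3.2)),
        ]
        res = place_graft(scene, grafts,
                          host_bone_mask=lesion_result.masks["bone_ct"])
        assert abs(res.coverage_fraction - oracle_coverage(grafts, fp)) <= 0.02

    def test_coverage_monotone_in_graft_count(self, resected, lesion_result):
        scene, fp = resected
        g1 = make_cylindrical_graft(5.0, 12.0).with_pose(
            _pose_on_cap(fp, offset_u=-2.5))
        g2 = make_cylindrical_graft(5.0, 12.0).with_pose(
            _pose_on_cap(fp, offset_u=2.5))
        c1 = place_graft(scene, g1,
                         host_bone_mask=lesion_result.masks["bone_ct"])
        c12 = place_graft(scene, [g1, g2],
                          host_bone_mask=lesion_result.masks["bone_ct"])
        assert c12.coverage_fraction >= c1.coverage_fraction - 1e-12

    def test_seated_graft_reports_depth_and_no_offsite_collision(
            self, resected, lesion_result):
        scene, fp = resected
        g = make_cylindrical_graft(7.0, 12.0).with_pose(
            _pose_on_cap(fp, depth=4.0))
        res = place_graft(scene, g,
                          host_bone_mask=lesion_result.masks["bone_ct"])
        assert res.seat_depth_mm > 0
        assert res.collision_volume_mm3 < 50.0  # graft stays at the site

    def test_isometry_invariance_of_coverage(self, resected, lesion_result):
        """Moving the whole scene rigidly leaves the metrics unchanged."""
        scene, fp = resected
        M = RigidTransform.from_axis_angle((1, 0.5, -0.2), 25.0, (8, -5, 12))
        g = make_cylindrical_graft(7.0, 12.0).with_pose(_pose_on_cap(fp))
        base = place_graft(scene, g, footprint=fp)
        frame2 = fp.frame.transformed(M)
        fp2 = CapFootprint(frame2, fp.alpha_v_deg, fp.alpha_h_deg,
                           fp.surface_radius, fp.center_rotation)
        g2 = g.with_pose(M.compose(g.pose))
        moved = place_graft(scene, g2, footprint=fp2)
        assert moved.coverage_fraction == pytest.approx(
            base.coverage_fraction, abs=1e-9)
        assert moved.step_off_mm == pytest.approx(base.step_off_mm, abs=1e-6)


class TestDrilling:
    def test_posteroanterior_path_spares_cartilage(self, lesion_result,
                                                   lesion_case):
        frame = lesion_case.truth.anatomical_frame.transformed(
            lesion_result.transform)
        Rb = lesion_case.config.bone_radius
        entry = frame.origin - (Rb - 0.2) * frame.anteroposterior
        target = frame.origin + (Rb - 5.0) * frame.anteroposterior
        plan = plan_drilling(lesion_result.scene, entry, target,
                             "posteroanterior",
                             bone_mask=lesion_result.masks["bone_ct"],
                             sclerosis_mask=lesion_result.masks["sclerosis"])
        assert plan.cartilage_breach is False
        assert plan.valid is True
        assert plan.depth_mm == pytest.approx(2 * Rb - 5.2, abs=1e-6)

    def test_path_through_articular_surface_breaches(self, lesion_result,
                                                     lesion_case):
        frame = lesion_case.truth.anatomical_frame.transformed(
            lesion_result.transform)
        Rb = lesion_case.config.bone_radius
        # offset mediolaterally so the path meets intact cartilage rather
        # than slipping through the fissure slit at the pole
        off = 2.5 * frame.mediolateral
        entry = frame.origin + (Rb + 6.0) * frame.anteroposterior + off
        target = frame.origin + (Rb - 5.0) * frame.anteroposterior + off
        plan = plan_drilling(lesion_result.scene, entry, target,
                             "anteroposterior")
        assert plan.cartilage_breach is True
        # a posteroanterior label on a breaching path is flagged invalid
        bad = plan_drilling(lesion_result.scene, entry, target,
                            "posteroanterior")
        assert bad.valid is False

    def test_sclerotic_rim_penetration_flagged(self, lesion_result,
                                               lesion_case):
        frame = lesion_case.truth.anatomical_frame.transformed(
            lesion_result.transform)
        Rb = lesion_case.config.bone_radius
        entry = frame.origin - (Rb - 0.2) * frame.anteroposterior
        through = frame.origin + (Rb - 2.0) * frame.anteroposterior
        plan = plan_drilling(lesion_result.scene, entry, through,
                             "posteroanterior",
                             bone_mask=lesion_result.masks["bone_ct"],
                             sclerosis_mask=lesion_result.masks["sclerosis"])
        assert plan.sclerosis_penetrated is True
        # a short path stopping before the sclerotic band does not reach it
        short = plan_drilling(
            lesion_result.scene, entry,
            frame.origin - (Rb - 4.0) * frame.anteroposterior,
            "posteroanterior", bone_mask=lesion_result.masks["bone_ct"],
            sclerosis_mask=lesion_result.masks["sclerosis"])
        assert short.sclerosis_penetrated is False

    def test_target_outside_bone_rejected(self, lesion_result, lesion_case):
        frame = lesion_case.truth.anatomical_frame.transformed(
            lesion_result.transform)
        Rb = lesion_case.config.bone_radius
        entry = frame.origin - (Rb - 0.2) * frame.anteroposterior
        with pytest.raises(ValueError, match="outside the bone"):
            plan_drilling(lesion_result.scene, entry,
                          frame.origin + 3 * Rb * frame.anteroposterior,
                          "posteroanterior",
                          bone_mask=lesion_result.masks["bone_ct"])

    def test_unknown_approach_rejected(self, lesion_result):
        with pytest.raises(ValueError, match="approach"):
            plan_drilling(lesion_result.scene, (0, 0, 0), (1, 1, 1), "oblique")
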