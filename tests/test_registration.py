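import numpy as np
import pytest

from capfuse import segmentation as seg
from capfuse.geometry import RigidTransform
from capfuse.image_io import LandmarkSet
from capfuse.registration import (build_mcfi, icp_refine, npoint_register,
                                  set_transparency)
from capfuse.segmentation import ThresholdSpec
from capfuse.surface import TriMeshModel, extract_surface


@pytest.fixture(scope="module")
def four_points():
    return np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                     [0.0, 10.0, 0.0], [3.0, 3.0, 9.0]])


class TestNPointRegistration:
    def test_identity_on_equal_sets(self, four_points):
        T, rmsd = npoint_register(four_points, four_points)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0, atol=1e-12)

    def test_recovers_known_transform_exactly(self, four_points):
        """17 degrees about an arbitrary axis plus (3, -2, 5) mm, noiseless:
        applying the recovered transform reproduces the targets to 1e-9."""
        T_true = RigidTransform.from_axis_angle((0.7, -0.2, 1.0), 17.0, (3, -2, 5))
        dst = T_true.apply(four_points)
        T, rmsd = npoint_register(four_points, dst)
        assert rmsd < 1e-9
        assert np.abs(T.apply(four_points) - dst).max() < 1e-9
        assert T.rotation_angle_to(T_true) < 1e-9

    def test_inverse_composition_is_identity(self, four_points):
        T_true = RigidTransform.from_axis_angle((1, 1, 1), 40.0, (1, 2, 3))
        T, _ = npoint_register(four_points, T_true.apply(four_points))
        comp = T.compose(T_true.inverse())
        assert comp.rotation_angle_to(RigidTransform.identity()) < 1e-9

    def test_four_point_protocol_with_names(self, four_points):
        names = ["lat_epicondyle_a", "lat_epicondyle_b", "shaft", "pole"]
        src = LandmarkSet(names, four_points, "MRI")
        dst = LandmarkSet(names, four_points + (1, 2, 3), "CT")
        T, rmsd = npoint_register(src, dst)
        assert rmsd < 1e-9
        assert np.allclose(T.translation, (1, 2, 3))

    def test_count_mismatch(self, four_points):
        with pytest.raises(ValueError, match="count mismatch"):
            npoint_register(four_points, four_points[:3])

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            npoint_register(np.zeros((2, 3)), np.ones((2, 3)))

    def test_collinear_points(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            npoint_register(line, line)

    def test_name_mismatch(self, four_points):
        src = LandmarkSet(list("abcd"), four_points, "MRI")
        dst = LandmarkSet(list("abdc"), four_points, "CT")
        with pytest.raises(ValueError, match="names"):
            npoint_register(src, dst)

    def test_no_reflection_on_mirrored_targets(self, four_points):
        mirrored = four_points * np.array([-1.0, 1.0, 1.0])
        T, _ = npoint_register(four_points, mirrored)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def humerus_meshes(lesion_case):
    bone_m = seg.segment_by_threshold(
        lesion_case.mri, ThresholdSpec(40, 79, min_volume_mm3=5), "humerus")
    bone_c = seg.segment_by_threshold(
        lesion_case.ct, ThresholdSpec(200, 1e9, min_volume_mm3=5), "humerus")
    return (extract_surface(bone_m, frame="MRI"),
            extract_surface(bone_c, frame="CT"))


class TestICP:
    def test_fixed_point_on_aligned_meshes(self, humerus_meshes):
        mri_mesh, _ = humerus_meshes
        T, trace = icp_refine(mri_mesh, mri_mesh, None)
        assert T.rotation_angle_to(RigidTransform.identity()) < 1e-6
        assert np.linalg.norm(T.translation) < 1e-6
        assert len(trace) <= 2

    def test_tight_recovery_on_identical_geometry(self, humerus_meshes):
        """A 2 deg / 1 mm perturbation between two copies of the same mesh
        is recovered almost exactly."""
        _, ct_mesh = humerus_meshes
        pert = RigidTransform.from_axis_angle((1, 0.3, 0), 2.0, (0.6, -0.5, 0.6))
        moving = pert.inverse().apply(ct_mesh.vertices)
        T, trace = icp_refine(moving, ct_mesh.vertices, None)
        assert T.rotation_angle_to(pert) < 0.1
        assert T.translation_distance_to(pert) < 0.05

    def test_rmsd_trace_monotone_nonincreasing(self, humerus_meshes,
                                               true_transform):
        mri_mesh, ct_mesh = humerus_meshes
        init = RigidTransform.from_axis_angle((0, 1, 0), 2.0, (1, 0, 0)).compose(
            true_transform)
        _, trace = icp_refine(mri_mesh, ct_mesh, init, subsample=3000)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_nonfinite_vertices_rejected(self, humerus_meshes):
        _, ct_mesh = humerus_meshes
        bad = ct_mesh.vertices.copy()
        bad[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            icp_refine(bad, ct_mesh.vertices)


class TestFusion:
    def _scene(self, humerus_meshes, transform):
        mri_mesh, ct_mesh = humerus_meshes
        cartilage = TriMeshModel(mri_mesh.vertices + (0, 0, 2), mri_mesh.faces,
                                 "cartilage", frame="MRI")
        ssb = TriMeshModel(ct_mesh.vertices[:30] if False else ct_mesh.vertices,
                           ct_mesh.faces, "ssb", frame="CT")
        return build_mcfi(ct_mesh, mri_mesh, cartilage, ssb, transform)

    def test_identity_transform_leaves_cartilage(self, humerus_meshes):
        mri_mesh, ct_mesh = humerus_meshes
        cartilage = TriMeshModel(mri_mesh.vertices.copy(), mri_mesh.faces,
                                 "cartilage", frame="MRI")
        scene = build_mcfi(ct_mesh, mri_mesh, cartilage, None,
                           RigidTransform.identity())
        assert np.allclose(scene.models["cartilage"].vertices, cartilage.vertices)

    def test_rigid_link_preserved(self, humerus_meshes, true_transform):
        """Cartilage-to-MRI-humerus vertex distances are identical before
        and after fusion (the linked models move together)."""
        scene = self._scene(humerus_meshes, true_transform)
        mri_mesh, _ = humerus_meshes
        before = np.linalg.norm((mri_mesh.vertices + (0, 0, 2))[:500]
                                - mri_mesh.vertices[:500], axis=1)
        after = np.linalg.norm(scene.models["cartilage"].vertices[:500]
                               - scene.models["humerus_mri"].vertices[:500], axis=1)
        assert np.abs(after - before).max() < 1e-9

    def test_visibility_and_color_conventions(self, humerus_meshes,
                                              true_transform):
        scene = self._scene(humerus_meshes, true_transform)
        assert scene.models["humerus_mri"].visible is False
        assert scene.models["ssb"].color[:3] == (220, 30, 30)
        assert scene.models["humerus_ct"].visible is True

    def test_missing_ct_humerus_rejected(self, humerus_meshes):
        mri_mesh, _ = humerus_meshes
        cartilage = TriMeshModel(mri_mesh.vertices, mri_mesh.faces,
                                 "cartilage", frame="MRI")
        with pytest.raises(ValueError, match="CT humerus"):
            build_mcfi(None, mri_mesh, cartilage)


class TestTransparency:
    def test_alpha_changes_only_named_model(self, humerus_meshes,
                                            true_transform):
        mri_mesh, ct_mesh = humerus_meshes
        cartilage = TriMeshModel(mri_mesh.vertices, mri_mesh.faces,
                                 "cartilage", frame="MRI")
        ssb = TriMeshModel(ct_mesh.vertices, ct_mesh.faces, "ssb", frame="CT")
        scene = build_mcfi(ct_mesh, mri_mesh, cartilage, ssb, true_transform)
        set_transparency(scene, "cartilage", 0.3)
        assert scene.models["cartilage"].transparency == 0.3
        assert scene.models["ssb"].transparency == 1.0

    def test_alpha_zero_hides_from_render_set(self, humerus_meshes,
                                              true_transform):
        mri_mesh, ct_mesh = humerus_meshes
        cartilage = TriMeshModel(mri_mesh.vertices, mri_mesh.faces,
                                 "cartilage", frame="MRI")
        scene = build_mcfi(ct_mesh, mri_mesh, cartilage, None, true_transform)
        set_transparency(scene, "cartilage", 0.0)
        assert all(m.label != "cartilage" for m in scene.visible_models())

    def test_alpha_out_of_range(self, humerus_meshes, true_transform):
        mri_mesh, ct_mesh = humerus_meshes
        cartilage = TriMeshModel(mri_mesh.vertices, mri_mesh.faces,
                                 "cartilage", frame="MRI")
        scene = build_mcfi(ct_mesh, mri_mesh, cartilage, None, true_transform)
        with pytest.raises(ValueError):
            set_transparency(scene, "cartilage", 1.2)
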