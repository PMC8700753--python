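import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capfuse.geometry import Frame
from capfuse.lesion import (EllipseModel, Finding, LesionReport, assign_area,
                            classify_stability, fit_capitellar_ellipse,
                            localize_finding, measure_diameters, predict_icrs,
                            predict_icrs_from_flags, recommend_procedure)


FRAME = Frame.standard()
CIRCLE = EllipseModel(center=(0.0, 0.0), a=10.0, b=10.0)


class TestEllipseFit:
    def test_projected_circle_radius(self):
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        # project_ap maps x->u (ML), y->v (PD): a circle of radius 10
        pts = np.stack([10 * np.cos(theta), 10 * np.sin(theta),
                        np.zeros_like(theta)], axis=1)
        model = fit_capitellar_ellipse(pts, FRAME)
        assert model.a == pytest.approx(10.0, rel=0.01)
        assert model.b == pytest.approx(10.0, rel=0.01)

    def test_phantom_cap_center_recovered(self, lesion_result, lesion_case):
        model = fit_capitellar_ellipse(lesion_result.scene.models["cartilage"]
                                       .transformed(lesion_result.transform.inverse()),
                                       lesion_case.truth.anatomical_frame)
        assert np.linalg.norm(model.center) <= 1.0  # within ~2 voxels of truth

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_capitellar_ellipse(np.zeros((0, 3)), FRAME)


class TestAssignArea:
    @pytest.mark.parametrize("uv,expected", [
        ((3.0, 4.0), 1),    # medial-proximal: anteromedial
        ((3.0, -4.0), 2),   # medial-distal
        ((-3.0, -4.0), 3),  # lateral-distal
        ((-3.0, 4.0), 4),   # lateral-proximal
        ((0.0, 5.0), 1),    # boundary 1|4 -> lower number
        ((0.0, -5.0), 2),   # boundary 2|3
        ((5.0, 0.0), 1),    # boundary 1|2
        ((-5.0, 0.0), 3),   # boundary 3|4
        ((0.0, 0.0), 1),    # exact centre
    ])
    def test_quadrants_and_tie_breaks(self, uv, expected):
        point = uv[0] * FRAME.mediolateral + uv[1] * FRAME.proximodistal
        assert assign_area(point, CIRCLE, FRAME) == expected

    def test_outside_point_rejected_with_distance(self):
        point = 15.0 * FRAME.mediolateral
        with pytest.raises(ValueError, match="outside"):
            assign_area(point, CIRCLE, FRAME)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(-0.99, 0.99), st.floats(-0.99, 0.99))
    def test_partition_every_interior_point_has_one_area(self, fu, fv):
        point = 10 * fu * FRAME.mediolateral + 10 * fv * FRAME.proximodistal
        if fu ** 2 + fv ** 2 >= 1:
            return
        area = assign_area(point, CIRCLE, FRAME)
        assert area in (1, 2, 3, 4)

    def test_dense_grid_hits_all_four_areas(self):
        g = np.linspace(-6, 6, 25)
        areas = set()
        for u in g:
            for v in g:
                p = u * FRAME.mediolateral + v * FRAME.proximodistal
                areas.add(assign_area(p, CIRCLE, FRAME))
        assert areas == {1, 2, 3, 4}

    def test_mirrored_side_keeps_anteromedial_area_1(self):
        """For a left elbow the ML axis still points medial; the
        anteromedial quadrant stays area 1 under mirroring."""
        left = Frame((0, 0, 0), (0, 0, 1), (0, 1, 0), (-1, 0, 0), "left")
        p_right = 3.0 * FRAME.mediolateral + 4.0 * FRAME.proximodistal
        p_left = 3.0 * left.mediolateral + 4.0 * left.proximodistal
        assert assign_area(p_right, CIRCLE, FRAME) == 1
        assert assign_area(p_left, CIRCLE, left) == 1


class TestLocalizeAndMeasure:
    def test_full_cap_patch_covers_all_areas(self):
        theta = np.linspace(0, 2 * np.pi, 200)
        r = np.linspace(0.5, 9.0, 20)
        pts = np.concatenate([
            (ri * np.cos(theta))[:, None] * FRAME.mediolateral
            + (ri * np.sin(theta))[:, None] * FRAME.proximodistal
            for ri in r])
        f = localize_finding(Finding("ACD", points_mm=pts), CIRCLE, FRAME)
        assert f.areas == {1, 2, 3, 4}

    def test_point_like_finding_single_area(self):
        f = Finding("ACF", points_mm=(2.0 * FRAME.mediolateral
                                      + 2.0 * FRAME.proximodistal)[None])
        assert localize_finding(f, CIRCLE, FRAME).areas == {1}

    def test_single_point_diameters_zero(self):
        dv, dh = measure_diameters(np.array([[1.0, 2.0, 3.0]]), FRAME)
        assert dv == 0.0 and dh == 0.0

    def test_empty_footprint_absent(self):
        assert measure_diameters(None, FRAME) == (None, None)
        assert measure_diameters(np.zeros((0, 3)), FRAME) == (None, None)

    def test_phantom_footprint_diameters(self, lesion_case):
        dv, dh = measure_diameters(lesion_case.truth.lesion_footprint,
                                   lesion_case.truth.anatomical_frame)
        tol = max(lesion_case.mri.spacing)
        assert abs(dv - 14.0) <= tol
        assert abs(dh - 12.0) <= tol


def _f(kind, ssb=False, subtype=None):
    return Finding(kind, points_mm=np.zeros((1, 3)), asd_subtype=subtype,
                   ssb_underneath=ssb)


class TestStabilityAndICRS:
    def test_no_findings_stable_class_i(self):
        assert classify_stability([]) == "stable"
        assert predict_icrs([]) == "I"

    def test_fissure_without_ssb_stable_class_ii(self):
        fs = [_f("ACF")]
        assert classify_stability(fs) == "stable"
        assert predict_icrs(fs) == "II"

    def test_fissure_with_ssb_unstable_class_iii(self):
        fs = [_f("ACF", ssb=True), _f("ASD", ssb=True, subtype="protrusion")]
        assert classify_stability(fs) == "unstable"
        assert predict_icrs(fs) == "III"

    def test_defect_always_class_iv_unstable(self):
        fs = [_f("ACD")]
        assert classify_stability(fs) == "unstable"
        assert predict_icrs(fs) == "IV"

    @pytest.mark.parametrize("acf,acd,asd,expected", [
        (True, False, False, "II"),   # lone fissure (table case 1)
        (True, False, True, "III"),   # fissure + deformity (case 2)
        (False, True, False, "IV"),   # defect (case 3)
        (False, False, False, "I"),
    ])
    def test_findings_only_rule(self, acf, acd, asd, expected):
        assert predict_icrs_from_flags(acf, acd, asd) == expected

    @settings(deadline=None, max_examples=64, derandomize=True)
    @given(st.booleans(), st.booleans(), st.booleans(), st.booleans(),
           st.booleans())
    def test_stability_icrs_consistency(self, acf, acf_ssb, asd, asd_ssb, acd):
        """Grades III/IV coincide exactly with instability on every
        reachable finding combination."""
        fs = []
        if acf:
            fs.append(_f("ACF", ssb=acf_ssb))
        if asd:
            fs.append(_f("ASD", ssb=asd_ssb, subtype="protrusion"))
        if acd:
            fs.append(_f("ACD"))
        grade = predict_icrs(fs)
        stability = classify_stability(fs)
        assert (grade in ("III", "IV")) == (stability == "unstable")


class TestProcedureRule:
    def _report(self, stability, icrs, dv=None, dh=None):
        return LesionReport(stability=stability, icrs_class=icrs,
                            vertical_diameter_mm=dv, horizontal_diameter_mm=dh)

    def test_large_unstable_lesion_reconstruction(self):
        rep = self._report("unstable", "III", 14.8, 13.1)
        assert recommend_procedure(rep) == ["reconstruction"]

    def test_small_class_iv_drilling(self):
        rep = self._report("unstable", "IV", 8.0, 9.0)
        assert recommend_procedure(rep) == ["drilling"]

    def test_stable_refractory_drilling(self):
        rep = self._report("stable", "II", 6.0, 5.0)
        assert recommend_procedure(rep, refractory_to_conservative=True) == \
            ["drilling"]

    def test_free_bodies_appended(self):
        rep = self._report("unstable", "III", 14.0, 12.0)
        assert recommend_procedure(rep, free_bodies=True) == \
            ["reconstruction", "free_body_removal"]

    def test_stable_untreated_none(self):
        rep = self._report("stable", "I")
        assert recommend_procedure(rep) == ["none"]

    def test_unstable_without_diameters_rejected(self):
        rep = self._report("unstable", "III")
        with pytest.raises(ValueError, match="diameters"):
            recommend_procedure(rep)
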