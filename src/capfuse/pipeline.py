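"""End-to-end pipeline: volumes -> segmentation -> meshes -> registration
-> fusion -> lesion report.

`run_case` drives the whole chain on a phantom case (or any case object
exposing the same fields) with explicit, overridable per-stage parameters.
Intensity thresholds default to the phantom's synthetic intensity classes;
for clinical data they must be supplied per scanner.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import segmentation as seg
from .geometry import Frame, RigidTransform
from .image_io import LandmarkSet
from .lesion import (LesionReport, classify_stability, fit_capitellar_ellipse,
                     localize_finding, measure_diameters, predict_icrs,
                     recommend_procedure)
from .phantom import PhantomCase
from .registration import build_mcfi, icp_refine, npoint_register
from .surface import extract_surface, smooth_mesh

__all__ = ["PipelineParams", "PipelineResult", "run_case"]


@dataclass
class PipelineParams:
    cartilage_threshold: tuple = (80.0, 130.0)
    bone_mri_threshold: tuple = (40.0, 79.0)
    bone_ct_threshold: tuple = (200.0, 1e9)
    min_component_mm3: float = 5.0
    fissure: seg.FissureParams = field(default_factory=seg.FissureParams)
    surface: seg.SurfaceParams = field(default_factory=seg.SurfaceParams)
    icp_max_iter: int = 100
    icp_rel_tol: float = 1e-7
    icp_subsample: int = 6000
    icp_trim_fraction: float = 0.05  # cut faces at the FOV edge lack counterparts
    bone_mesh_smooth_iterations: int = 10
    sclerosis_percentile: float = 90.0
    landmark_noise_sd: float = 0.0     # mm, emulates manual point picking
    seed: int = 0


@dataclass
class PipelineResult:
    transform: RigidTransform
    npoint_rmsd: float
    icp_trace: list
    scene: object
    report: LesionReport
    masks: dict
    findings: list


def run_case(case: PhantomCase, params: PipelineParams = None,
             frame: Frame = None) -> PipelineResult:
    """Run segmentation, registration, fusion and lesion analysis."""
    p = params or PipelineParams()
    rng = np.random.default_rng(p.seed)
    frame = frame or case.truth.anatomical_frame

    # --- segmentation ------------------------------------------------------
    cart_spec = seg.ThresholdSpec(*p.cartilage_threshold,
                                  min_volume_mm3=p.min_component_mm3)
    bone_mri_spec = seg.ThresholdSpec(*p.bone_mri_threshold,
                                      min_volume_mm3=p.min_component_mm3)
    bone_ct_spec = seg.ThresholdSpec(*p.bone_ct_threshold,
                                     min_volume_mm3=p.min_component_mm3)
    cartilage = seg.segment_by_threshold(case.mri, cart_spec, "cartilage")
    bone_mri = seg.segment_by_threshold(case.mri, bone_mri_spec, "humerus")
    bone_ct = seg.segment_by_threshold(case.ct, bone_ct_spec, "humerus")

    findings = []
    findings += seg.detect_fissures(cartilage, case.mri, p.fissure)
    findings += seg.detect_surface_deformity(cartilage, frame, p.surface)
    findings += seg.detect_cartilage_defect(cartilage, frame, p.surface)
    ssb = seg.detect_ssb(bone_ct)
    sclerosis = seg.highlight_sclerosis(case.ct, bone_ct, p.sclerosis_percentile)

    # --- surfaces ----------------------------------------------------------
    mesh_ct = smooth_mesh(extract_surface(bone_ct, frame="CT"),
                          p.bone_mesh_smooth_iterations)
    mesh_mri = smooth_mesh(extract_surface(bone_mri, frame="MRI"),
                           p.bone_mesh_smooth_iterations)
    mesh_cart = extract_surface(cartilage, frame="MRI")
    mesh_ssb = extract_surface(ssb, frame="CT") if ssb.data.any() else None

    # --- registration ------------------------------------------------------
    lm_mri = case.landmarks_mri.points
    if p.landmark_noise_sd > 0:
        lm_mri = lm_mri + rng.normal(0.0, p.landmark_noise_sd, lm_mri.shape)
    T0, rmsd = npoint_register(
        LandmarkSet(case.landmarks_mri.names, lm_mri, "MRI"), case.landmarks_ct)
    T, trace = icp_refine(mesh_mri, mesh_ct, T0, max_iter=p.icp_max_iter,
                          rel_tol=p.icp_rel_tol, subsample=p.icp_subsample,
                          seed=p.seed, trim_fraction=p.icp_trim_fraction)
    scene = build_mcfi(mesh_ct, mesh_mri, mesh_cart, mesh_ssb, T)

    # --- lesion analysis ---------------------------------------------------
    ellipse = fit_capitellar_ellipse(mesh_cart, frame)
    frame_ct = frame.transformed(T)
    for f in findings:
        localize_finding(f, ellipse, frame)
        f.ssb_underneath = seg.ssb_underneath(f, ssb, frame_ct, transform=T)
    footprint_pts = _lesion_footprint_points(findings)
    dv, dh = measure_diameters(footprint_pts, frame)
    stability = classify_stability(findings)
    icrs = predict_icrs(findings)
    report = LesionReport(findings=findings, ssb_present=bool(ssb.data.any()),
                          vertical_diameter_mm=dv, horizontal_diameter_mm=dh,
                          stability=stability, icrs_class=icrs)
    if report.max_diameter_mm is not None or stability == "stable":
        report.recommended_procedure = recommend_procedure(report)[0]

    masks = {"cartilage": cartilage, "bone_mri": bone_mri, "bone_ct": bone_ct,
             "ssb": ssb, "sclerosis": sclerosis}
    return PipelineResult(T, rmsd, trace, scene, report, masks, findings)


def _lesion_footprint_points(findings):
    """The measurable lesion footprint: defects and surface deformities
    first (the lesion proper), fissure traces otherwise."""
    prim = [f.points_mm for f in findings if f.kind in ("ACD", "ASD")
            and f.points_mm is not None]
    if prim:
        return np.vstack(prim)
    acf = [f.points_mm for f in findings if f.points_mm is not None]
    return np.vstack(acf) if acf else None
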