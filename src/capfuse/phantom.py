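"""Synthetic capitellum phantom imaged in two modalities.

The phantom is a geometric stand-in for the distal humerus: a spherical
capitellum carrying a cartilage shell over an anterior cap, a proximal
shaft and a lateral epicondylar protuberance (the latter two break the
rotational symmetry that pure spheres would leave unconstrained during
registration). A parameterized osteochondral lesion can be switched on
feature by feature:

* a thin low-intensity fissure slab oriented along the local surface
  normal (ACF), with a tangential mid-depth slab available as a negative
  control that a fissure detector must reject;
* a surface protrusion or flattening of the cartilage outline (ASD);
* a full-thickness cartilage defect (ACD);
* a lens-shaped subchondral fragment separated from the parent bone by a
  low-intensity cleft (SSB), with an optional bridge that keeps the
  fragment connected as a counterexample for the three-plane
  discontinuity criterion;
* a sclerotic band of elevated CT intensity beneath the cleft floor.

The two volumes live in different world frames related by a known rigid
transform, and every derived quantity (footprint, diameters, findings,
masks) is emitted as ground truth so the downstream stages can be tested
without clinical data. Intensity classes are synthetic constants, not
calibrated HU or MR units; anatomical realism is a non-goal, geometric
ground truth is the goal.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import CapFootprint, Frame, RigidTransform
from .image_io import ImageVolume, LabelMask, LandmarkSet

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "PhantomCase",
    "generate_phantom",
    "truth_report",
    "angular_extent_for_extents",
    "MRI_INTENSITY",
    "CT_INTENSITY",
]

# synthetic intensity classes (arbitrary units)
MRI_INTENSITY = {"background": 0.0, "bone": 60.0, "cartilage": 100.0, "fissure": 5.0}
CT_INTENSITY = {"background": 0.0, "bone": 400.0, "cartilage": 40.0,
                "cleft": 30.0, "sclerosis": 650.0}


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple = (96, 96, 96)
    spacing_mri: tuple = (0.4, 0.4, 0.4)
    spacing_ct: tuple = (0.5, 0.5, 0.5)
    bone_radius: float = 11.0          # mm
    cartilage_thickness: float = 2.5   # mm
    cap_half_angle: float = 65.0       # deg, cartilage cap around the AP axis
    lesion_center_angles: tuple = (0.0, 0.0)   # (polar from AP, azimuth) deg
    lesion_angular_extent: tuple = (31.0, 26.0)  # (alpha_v, alpha_h) half-extents deg
    fissure_enabled: bool = False
    fissure_orientation: str = "radial"  # "radial" | "tangential" (negative control)
    fissure_thickness_mm: float = 0.6
    defect_enabled: bool = False
    protrusion_height_mm: float = 0.0
    flattening_depth_mm: float = 0.0
    ssb_enabled: bool = False
    ssb_cleft_planes: int = 3          # <3 leaves a bridge (counterexample)
    ssb_fragment_depth_mm: float = 3.0
    ssb_cleft_width_mm: float = 1.5
    sclerosis_enabled: bool = False
    sclerosis_band_mm: float = 1.5
    true_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    landmark_count: int = 4
    noise_sd: float = 0.0
    seed: int = 0
    side: str = "right"
    traction_applied: bool = True  # metadata only: cartilage outline is visible

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_mri) or any(s <= 0 for s in self.spacing_ct):
            raise ValueError("voxel spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.landmark_count < 3:
            raise ValueError("landmark_count must be >= 3")
        if self.fissure_orientation not in ("radial", "tangential"):
            raise ValueError("fissure_orientation must be 'radial' or 'tangential'")
        polar = abs(self.lesion_center_angles[0])
        if polar + max(self.lesion_angular_extent) > self.cap_half_angle:
            raise ValueError(
                "lesion extent exceeds the cartilage cap: centre polar angle "
                f"{polar:g} deg + half-extent {max(self.lesion_angular_extent):g} deg "
                f"> cap half-angle {self.cap_half_angle:g} deg")
        outer = self.bone_radius + self.cartilage_thickness + self.protrusion_height_mm
        half_extent = min(n * s for n, s in zip(self.grid_shape, self.spacing_mri)) / 2.0
        if outer + 1.0 > half_extent:
            raise ValueError(
                f"grid too small: outer radius {outer:g} mm (+1 mm margin) exceeds "
                f"half grid extent {half_extent:g} mm")

    @property
    def lesion_present(self) -> bool:
        return ((self.fissure_enabled and self.fissure_orientation == "radial")
                or self.defect_enabled or self.protrusion_height_mm > 0
                or self.flattening_depth_mm > 0)

    @property
    def lesion_surface_radius(self) -> float:
        """Radius of the surface the lesion footprint lives on."""
        if self.defect_enabled:
            return self.bone_radius
        return (self.bone_radius + self.cartilage_thickness
                + self.protrusion_height_mm - self.flattening_depth_mm)


@dataclass
class PhantomTruth:
    true_transform: RigidTransform
    anatomical_frame: Frame                 # MRI-frame
    footprint: CapFootprint | None          # MRI-frame, None when no lesion
    lesion_footprint: np.ndarray | None     # dense surface sample, mm
    true_vertical_diameter: float | None
    true_horizontal_diameter: float | None
    true_findings: list
    ssb_present: bool
    ssb_mask: LabelMask | None              # CT grid
    sclerosis_mask: LabelMask | None        # CT grid
    cartilage_mask: LabelMask | None        # MRI grid
    bone_mask_mri: LabelMask | None         # MRI grid
    bone_mask_ct: LabelMask | None          # CT grid


@dataclass
class PhantomCase:
    config: PhantomConfig
    mri: ImageVolume
    ct: ImageVolume
    landmarks_mri: LandmarkSet
    landmarks_ct: LandmarkSet
    truth: PhantomTruth


def angular_extent_for_extents(vertical_mm: float, horizontal_mm: float,
                               config: PhantomConfig) -> tuple:
    """Half-extents (deg) whose analytic AP-projected chords match the
    requested footprint extents, given the config's lesion surface radius.

    Inverse of ``extent = 2 R sin(alpha)``.
    """
    R = config.lesion_surface_radius
    for name, v in (("vertical", vertical_mm), ("horizontal", horizontal_mm)):
        if not 0 < v < 2 * R:
            raise ValueError(f"{name} extent {v:g} mm not achievable on radius {R:g} mm")
    a_v = np.rad2deg(np.arcsin(vertical_mm / (2.0 * R)))
    a_h = np.rad2deg(np.arcsin(horizontal_mm / (2.0 * R)))
    return float(a_v), float(a_h)


def _center_rotation(config: PhantomConfig, frame: Frame):
    """Rotation taking the lesion-centre direction onto the AP axis, or None."""
    polar, azim = config.lesion_center_angles
    if polar == 0.0:
        return None
    p, z = np.deg2rad(polar), np.deg2rad(azim)
    c = (np.sin(p) * (np.cos(z) * frame.mediolateral + np.sin(z) * frame.proximodistal)
         + np.cos(p) * frame.anteroposterior)
    rot, _ = Rotation.align_vectors(frame.anteroposterior[None], c[None])
    return rot.as_matrix()


class _Anatomy:
    """Vectorized tissue evaluation in the anatomical (MRI) frame."""

    def __init__(self, config: PhantomConfig):
        self.cfg = config
        self.frame = Frame.standard(side=config.side)
        self.rot = _center_rotation(config, self.frame)
        cfg = config
        R_surf = cfg.lesion_surface_radius
        self.footprint = CapFootprint(self.frame, cfg.lesion_angular_extent[0],
                                      cfg.lesion_angular_extent[1], R_surf, self.rot)
        # angular dilation for the cleft / sclerosis shells
        margin = np.rad2deg(cfg.ssb_cleft_width_mm / cfg.bone_radius)
        self.footprint_dilated = CapFootprint(
            self.frame, cfg.lesion_angular_extent[0] + margin,
            cfg.lesion_angular_extent[1] + margin, R_surf, self.rot)
        self.epi_center = np.array([-1.05 * cfg.bone_radius, 0.25 * cfg.bone_radius, 0.0])
        self.epi_radius = 0.30 * cfg.bone_radius
        self.shaft_radius = 0.45 * cfg.bone_radius

    def _fields(self, pts: np.ndarray):
        cfg = self.cfg
        f = self.frame
        r = np.linalg.norm(pts, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.nan_to_num(pts / r[:, None])
        cap = u @ f.anteroposterior >= np.cos(np.deg2rad(cfg.cap_half_angle))
        m = self.footprint.membership(pts)
        inside = m <= 1.0
        Rb = cfg.bone_radius
        R_out = np.full(len(pts), Rb + cfg.cartilage_thickness)
        if cfg.protrusion_height_mm > 0:
            R_out = np.where(inside, R_out + cfg.protrusion_height_mm, R_out)
        if cfg.flattening_depth_mm > 0:
            R_out = np.where(inside, R_out - cfg.flattening_depth_mm, R_out)
        cartilage = cap & (r > Rb) & (r <= R_out)
        if cfg.defect_enabled:
            cartilage &= ~inside
        sphere = r <= Rb
        shaft_d = np.sqrt((pts @ f.mediolateral) ** 2 + (pts @ f.anteroposterior) ** 2)
        shaft = (shaft_d <= self.shaft_radius) & (pts @ f.proximodistal >= 0.4 * Rb)
        epi = np.linalg.norm(pts - self.epi_center, axis=1) <= self.epi_radius
        bone = sphere | shaft | epi
        return r, m, inside, sphere, bone, cartilage

    def _fissure(self, pts, r, inside, cartilage):
        cfg = self.cfg
        if not cfg.fissure_enabled:
            return np.zeros(len(pts), dtype=bool)
        if cfg.fissure_orientation == "radial":
            q = pts if self.rot is None else pts @ self.rot
            d = np.abs(q @ self.frame.mediolateral)
            return cartilage & inside & (d <= cfg.fissure_thickness_mm / 2.0)
        Rb, t = cfg.bone_radius, cfg.cartilage_thickness
        return cartilage & inside & (r > Rb + 0.35 * t) & (r <= Rb + 0.50 * t)

    def _ssb_parts(self, pts, r, m, sphere):
        cfg = self.cfg
        Rb = cfg.bone_radius
        depth, width = cfg.ssb_fragment_depth_mm, cfg.ssb_cleft_width_mm
        frag = sphere & (m <= 1.0) & (r > Rb - depth)
        md = self.footprint_dilated.membership(pts)
        cleft = sphere & (md <= 1.0) & (r > Rb - depth - width) & ~frag
        if cfg.ssb_cleft_planes < 3:
            bridge = (m <= 0.04) & (r > Rb - depth - width) & (r <= Rb - depth)
            cleft &= ~bridge
        return frag, cleft, md

    def _sclerosis(self, r, md, sphere):
        cfg = self.cfg
        base = cfg.bone_radius - cfg.ssb_fragment_depth_mm - cfg.ssb_cleft_width_mm
        return sphere & (md <= 1.0) & (r > base - cfg.sclerosis_band_mm) & (r <= base)

    def mri_intensity(self, pts: np.ndarray) -> np.ndarray:
        r, m, inside, sphere, bone, cartilage = self._fields(pts)
        img = np.zeros(len(pts))
        img[bone] = MRI_INTENSITY["bone"]
        img[cartilage] = MRI_INTENSITY["cartilage"]
        img[self._fissure(pts, r, inside, cartilage)] = MRI_INTENSITY["fissure"]
        return img

    def ct_intensity(self, pts: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        r, m, inside, sphere, bone, cartilage = self._fields(pts)
        img = np.zeros(len(pts))
        img[bone] = CT_INTENSITY["bone"]
        img[cartilage & ~bone] = CT_INTENSITY["cartilage"]
        md = self.footprint_dilated.membership(pts)
        if cfg.ssb_enabled:
            frag, cleft, md = self._ssb_parts(pts, r, m, sphere)
            img[cleft] = CT_INTENSITY["cleft"]
        if cfg.sclerosis_enabled:
            img[self._sclerosis(r, md, sphere)] = CT_INTENSITY["sclerosis"]
        return img

    def masks(self, pts: np.ndarray) -> dict:
        cfg = self.cfg
        r, m, inside, sphere, bone, cartilage = self._fields(pts)
        out = {"bone": bone, "cartilage": cartilage}
        md = self.footprint_dilated.membership(pts)
        if cfg.ssb_enabled:
            frag, cleft, md = self._ssb_parts(pts, r, m, sphere)
            out["ssb"] = frag
            out["bone"] = bone & ~cleft
        if cfg.sclerosis_enabled:
            out["sclerosis"] = self._sclerosis(r, md, sphere)
        return out


def _grid_points(shape, spacing, origin, axes=np.eye(3)):
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                   axis=-1).reshape(-1, 3).astype(float)
    return idx * np.asarray(spacing) @ axes.T + origin


def _landmarks(config: PhantomConfig) -> np.ndarray:
    Rb = config.bone_radius
    base = np.array([
        [-1.35 * Rb, 0.25 * Rb, 0.0],   # epicondylar tip
        [0.0, 0.0, Rb],                 # capitellar pole (bone surface)
        [0.0, 1.4 * Rb, 0.45 * Rb],     # anterior shaft cortex
        [Rb, 0.0, 0.0],                 # medial equator
    ])
    n = config.landmark_count
    if n <= 4:
        return base[:n]
    # extra points on the posterior hemisphere, golden-angle spiral
    k = np.arange(n - 4)
    phi = k * np.deg2rad(137.507764)
    z = -0.3 - 0.6 * (k + 0.5) / max(n - 4, 1)
    rho = np.sqrt(1 - z ** 2)
    extra = Rb * np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    return np.vstack([base, extra])


def generate_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate a paired MRI-like / CT-like phantom with full ground truth.

    Deterministic for a fixed seed: the two volumes are produced by
    evaluating the same analytic anatomy at each grid's world coordinates
    (the CT grid is pulled back through the inverse of the true transform),
    then adding seeded Gaussian noise.
    """
    config.validate()
    anatomy = _Anatomy(config)
    T = config.true_transform
    rng = np.random.default_rng(config.seed)

    shape = tuple(int(n) for n in config.grid_shape)
    sp_m = np.asarray(config.spacing_mri, dtype=float)
    sp_c = np.asarray(config.spacing_ct, dtype=float)
    origin_mri = -(np.asarray(shape) - 1) * sp_m / 2.0
    pts_mri = _grid_points(shape, sp_m, origin_mri)
    mri_img = anatomy.mri_intensity(pts_mri).reshape(shape)

    # centre the CT grid on the transformed capitellum
    origin_ct = T.apply(np.zeros(3)) - (np.asarray(shape) - 1) * sp_c / 2.0
    pts_ct_world = _grid_points(shape, sp_c, origin_ct)
    pts_ct_anat = T.inverse().apply(pts_ct_world)
    ct_img = anatomy.ct_intensity(pts_ct_anat).reshape(shape)

    if config.noise_sd > 0:
        mri_img = mri_img + rng.normal(0.0, config.noise_sd, mri_img.shape)
        ct_img = ct_img + rng.normal(0.0, config.noise_sd, ct_img.shape)

    mri = ImageVolume(mri_img.astype(np.float32), sp_m, origin_mri, np.eye(3), "MRI")
    ct = ImageVolume(ct_img.astype(np.float32), sp_c, origin_ct, np.eye(3), "CT")

    lm = _landmarks(config)
    names = [f"L{i+1}" for i in range(len(lm))]
    landmarks_mri = LandmarkSet(names, lm, "MRI")
    landmarks_ct = LandmarkSet(names, T.apply(lm), "CT")

    truth = _build_truth(config, anatomy, mri, ct, pts_mri, pts_ct_anat)
    return PhantomCase(config, mri, ct, landmarks_mri, landmarks_ct, truth)


def _build_truth(config, anatomy, mri, ct, pts_mri, pts_ct_anat) -> PhantomTruth:
    from .lesion import Finding

    shape = mri.shape
    masks_mri = anatomy.masks(pts_mri)
    masks_ct = anatomy.masks(pts_ct_anat)
    cart_mask = LabelMask.like(mri, masks_mri["cartilage"].reshape(shape), "cartilage")
    bone_mri = LabelMask.like(mri, masks_mri["bone"].reshape(shape), "humerus")
    bone_ct = LabelMask.like(ct, masks_ct["bone"].reshape(ct.shape), "humerus")
    ssb_present = bool(config.ssb_enabled and config.ssb_cleft_planes >= 3)
    ssb_mask = None
    if config.ssb_enabled:
        ssb_mask = LabelMask.like(ct, masks_ct["ssb"].reshape(ct.shape), "ssb")
    scl_mask = None
    if config.sclerosis_enabled:
        scl_mask = LabelMask.like(ct, masks_ct["sclerosis"].reshape(ct.shape), "sclerosis")

    footprint = lesion_pts = dv = dh = None
    findings = []
    if config.lesion_present:
        footprint = anatomy.footprint
        lesion_pts = footprint.sample_surface_points()
        dv = footprint.vertical_extent_mm
        dh = footprint.horizontal_extent_mm
        under = ssb_present  # fragment sits directly beneath the footprint
        if config.fissure_enabled and config.fissure_orientation == "radial":
            findings.append(Finding("ACF", points_mm=_fissure_trace(config, anatomy),
                                    ssb_underneath=under))
        if config.defect_enabled:
            findings.append(Finding("ACD", points_mm=lesion_pts, ssb_underneath=under))
        if config.protrusion_height_mm > 0:
            findings.append(Finding("ASD", points_mm=lesion_pts,
                                    asd_subtype="protrusion", ssb_underneath=under))
        if config.flattening_depth_mm > 0:
            findings.append(Finding("ASD", points_mm=lesion_pts,
                                    asd_subtype="flattening", ssb_underneath=under))

    return PhantomTruth(
        true_transform=config.true_transform,
        anatomical_frame=anatomy.frame,
        footprint=footprint,
        lesion_footprint=lesion_pts,
        true_vertical_diameter=dv,
        true_horizontal_diameter=dh,
        true_findings=findings,
        ssb_present=ssb_present,
        ssb_mask=ssb_mask,
        sclerosis_mask=scl_mask,
        cartilage_mask=cart_mask,
        bone_mask_mri=bone_mri,
        bone_mask_ct=bone_ct,
    )


def _fissure_trace(config: PhantomConfig, anatomy: _Anatomy) -> np.ndarray:
    """Dense sample of the fissure plane's trace on the articular surface."""
    a_v = np.deg2rad(config.lesion_angular_extent[0])
    phi = np.linspace(-a_v, a_v, 200)
    R = config.lesion_surface_radius
    f = anatomy.frame
    u = np.sin(phi)[:, None] * f.proximodistal + np.cos(phi)[:, None] * f.anteroposterior
    if anatomy.rot is not None:
        u = u @ anatomy.rot.T
    return f.origin + R * u


def rasterize_footprint(footprint: CapFootprint, volume: ImageVolume) -> LabelMask:
    """Voxelize an analytic surface footprint onto a volume's grid.

    Marks every voxel the patch passes through by sampling the analytic
    surface at sub-voxel density and binning the samples into voxel
    indices. Each end of the patch then lands inside its voxel, so the
    projected extents of the discrete mask deviate from the analytic
    chords by at most one voxel spacing in total.
    """
    pts = footprint.sample_surface_points(n_radial=180, n_angular=900)
    idx = np.round(volume.indices_of(pts)).astype(int)
    shape = np.array(volume.shape)
    valid = np.all((idx >= 0) & (idx < shape), axis=1)
    mask = np.zeros(volume.shape, dtype=bool)
    mask[tuple(idx[valid].T)] = True
    return LabelMask.like(volume, mask, "lesion_footprint")


def truth_report(case: PhantomCase):
    """Ground-truth LesionReport derived from the phantom's true findings
    using the same codified stability / ICRS rules as the analysis stage."""
    from .lesion import (EllipseModel, LesionReport, assign_area,
                         classify_stability, predict_icrs)

    cfg = case.config
    frame = case.truth.anatomical_frame
    radius = cfg.bone_radius + cfg.cartilage_thickness + cfg.protrusion_height_mm
    ellipse = EllipseModel(center=np.zeros(2), a=radius * 1.01, b=radius * 1.01,
                           theta=0.0)
    findings = []
    for f in case.truth.true_findings:
        areas = {assign_area(p, ellipse, frame) for p in f.points_mm}
        findings.append(replace_finding(f, areas))
    stability = classify_stability(findings)
    icrs = predict_icrs(findings)
    return LesionReport(
        findings=findings,
        ssb_present=case.truth.ssb_present,
        vertical_diameter_mm=case.truth.true_vertical_diameter,
        horizontal_diameter_mm=case.truth.true_horizontal_diameter,
        stability=stability,
        icrs_class=icrs,
    )


def replace_finding(f, areas):
    return _dc_replace(f, areas=set(areas))
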