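"""Tissue segmentation and finding detection.

The clinical workflow this package models relied on an operator adjusting
intensity thresholds on screen; here operator judgement is replaced by
explicit, configurable criteria:

* a fissure (ACF) is a connected low-intensity component inside the
  cartilage whose principal axis is within ``angle_tol`` of the local
  outer-surface normal OR which spans at least ``span_frac`` of the local
  cartilage thickness;
* a surface deformity (ASD) is a contiguous patch whose outer cartilage
  surface deviates from a reference cap by more than ``h_tol`` mm
  (positive: protrusion, negative: flattening);
* a cartilage defect (ACD) is a patch of the cap where cartilage thickness
  falls below ``thickness_min`` over at least ``area_min`` mm^2;
* segmented subchondral bone (SSB) is a bone fragment whose continuity to
  the parent bone is lost in all three orthogonal planes;
* sclerosis is the brightest fraction of the bone intensity distribution.

All detectors are deterministic given the volume and parameters.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .geometry import Frame, fit_sphere
from .image_io import ImageVolume, LabelMask
from .lesion import Finding

log = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "FissureParams",
    "SurfaceParams",
    "segment_by_threshold",
    "detect_fissures",
    "detect_surface_deformity",
    "detect_cartilage_defect",
    "detect_ssb",
    "highlight_sclerosis",
    "ssb_underneath",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ThresholdSpec:
    lower: float
    upper: float
    connectivity: int = 26
    min_volume_mm3: float = 0.0

    def __post_init__(self):
        if self.lower >= self.upper:
            raise ValueError("lower threshold must be below upper")
        if self.connectivity not in _STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.min_volume_mm3 < 0:
            raise ValueError("min_volume_mm3 must be >= 0")


@dataclass(frozen=True)
class FissureParams:
    low_max: float = 30.0        # intensity below which a voxel is "low"
    angle_tol_deg: float = 30.0
    span_frac: float = 0.8
    min_voxels: int = 8
    close_radius_vox: int = 2    # morphological closing to build the envelope


@dataclass(frozen=True)
class SurfaceParams:
    h_tol_mm: float = 0.5
    thickness_min_mm: float = 0.5
    area_min_mm2: float = 3.0
    bin_size_sine: float = None  # default: mean spacing / fitted radius


def segment_by_threshold(volume: ImageVolume, spec: ThresholdSpec,
                         tissue: str) -> LabelMask:
    """Voxels within [lower, upper], minus components below the minimum
    volume under the configured connectivity. Empty results warn, they do
    not raise — the caller decides."""
    data = volume.data
    mask = (data >= spec.lower) & (data <= spec.upper)
    if spec.min_volume_mm3 > 0 and mask.any():
        labels, n = ndimage.label(mask, structure=_STRUCTS[spec.connectivity])
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes * volume.voxel_volume() >= spec.min_volume_mm3) + 1
        mask = np.isin(labels, keep)
    if not mask.any():
        warnings.warn(f"threshold segmentation for {tissue!r} produced an "
                      f"empty mask", stacklevel=2)
    return LabelMask.like(volume, mask, tissue)


# ---------------------------------------------------------------------------
# cap map: per-direction radial summary of the cartilage shell
# ---------------------------------------------------------------------------

class _CapMap:
    """Angular-bin summary of a cartilage mask around a fitted cap centre.

    Directions are binned by their (mediolateral, proximodistal) direction
    sines; each bin records the outer and inner radius of the cartilage
    voxels falling in it.
    """

    def __init__(self, cartilage: LabelMask, frame: Frame = None,
                 bin_size: float = None):
        if not cartilage.data.any():
            raise ValueError("cartilage mask is empty")
        pts = cartilage.points_mm()
        if frame is not None:
            # the anatomical frame's origin is the cap centre by definition;
            # an algebraic sphere fit on a partial, thick shell is biased
            # toward the cap, so prefer the frame when one is supplied
            center = frame.origin
        else:
            try:
                center, _ = fit_sphere(pts)
            except ValueError as exc:
                raise ValueError(f"reference cap fit failed: {exc}") from exc
            frame = Frame.standard(origin=center)
        self.frame = frame
        self.center = np.asarray(center, dtype=float)
        rel = pts - center
        self.r = np.linalg.norm(rel, axis=1)
        u = rel / self.r[:, None]
        self.sh = u @ frame.mediolateral
        self.sv = u @ frame.proximodistal
        self.mean_spacing = float(np.mean(cartilage.spacing))
        self.radius_guess = float(np.median(self.r))
        if bin_size is None:
            bin_size = self.mean_spacing / self.radius_guess
        self.bin_size = bin_size
        self.half_bins = int(np.ceil(1.0 / bin_size))
        n = 2 * self.half_bins + 1
        self.ih = np.clip(np.round(self.sh / bin_size).astype(int)
                          + self.half_bins, 0, n - 1)
        self.iv = np.clip(np.round(self.sv / bin_size).astype(int)
                          + self.half_bins, 0, n - 1)
        self.shape2d = (n, n)
        flat = self.iv * n + self.ih
        self.flat = flat
        self.outer_r = np.full(n * n, -np.inf)
        np.maximum.at(self.outer_r, flat, self.r)
        self.inner_r = np.full(n * n, np.inf)
        np.minimum.at(self.inner_r, flat, self.r)
        self.populated = np.isfinite(self.outer_r)
        self.thickness = np.where(
            self.populated, self.outer_r - self.inner_r + self.mean_spacing, 0.0)
        self.points = pts
        # interior bins: away from the cap rim, where partially filled bins
        # and the shell's cut face would fake surface irregularities
        ih_g, iv_g = np.meshgrid(np.arange(n), np.arange(n), indexing="xy")
        sh_g = (ih_g.ravel() - self.half_bins) * bin_size
        sv_g = (iv_g.ravel() - self.half_bins) * bin_size
        # note meshgrid xy: rows iv, cols ih -> flat index iv * n + ih
        self.s_norm = np.sqrt(sh_g ** 2 + sv_g ** 2)
        rim = np.percentile(self.s_norm[self.populated], 98.0)
        self.interior = self.s_norm <= rim - 3.0 * bin_size

    def bin_area_mm2(self) -> float:
        # small-angle approximation on the cap; adequate for area gating
        return (self.bin_size * self.radius_guess) ** 2

    def reference_radius(self) -> float:
        """Robust reference cap radius: median of per-bin outer radii.

        A median keeps large protrusions/flattenings from dragging the
        reference surface toward themselves, which a plain least-squares
        sphere does when the deformity covers a sizeable cap fraction.
        """
        return float(np.median(self.outer_r[self.populated]))

    def voxels_in_bins(self, bin_mask_flat: np.ndarray, outer_only=True):
        """World points of cartilage voxels in the given flat bins."""
        sel = bin_mask_flat[self.flat]
        if outer_only:
            sel &= self.r >= self.outer_r[self.flat] - 1.5 * self.mean_spacing
        return self.points[sel]

    def bin_directions(self, bin_mask_flat: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(bin_mask_flat)
        iv, ih = np.divmod(idx, self.shape2d[1])
        sh = (ih - self.half_bins) * self.bin_size
        sv = (iv - self.half_bins) * self.bin_size
        sz2 = np.clip(1.0 - sh ** 2 - sv ** 2, 0.0, None)
        f = self.frame
        return (sh[:, None] * f.mediolateral + sv[:, None] * f.proximodistal
                + np.sqrt(sz2)[:, None] * f.anteroposterior)


def _components_2d(mask2d: np.ndarray, min_bins: int):
    labels, n = ndimage.label(mask2d, structure=np.ones((3, 3), dtype=bool))
    comps = []
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() >= min_bins:
            comps.append(comp)
    return comps


def detect_surface_deformity(cartilage: LabelMask, frame: Frame = None,
                             params: SurfaceParams = SurfaceParams()):
    """Protrusion/flattening patches of the outer cartilage surface."""
    cm = _CapMap(cartilage, frame, params.bin_size_sine)
    ref = cm.reference_radius()
    residual = np.where(cm.populated, cm.outer_r - ref, 0.0)
    valid = cm.populated & cm.interior & (cm.thickness >= params.thickness_min_mm)
    min_bins = max(1, int(np.ceil(params.area_min_mm2 / cm.bin_area_mm2())))
    findings = []
    for sign, subtype in ((1.0, "protrusion"), (-1.0, "flattening")):
        flagged = valid & (sign * residual > params.h_tol_mm)
        # bridge one-to-two-bin gaps (e.g. where a fissure interrupts the
        # surface map) so one deformity is reported as one patch
        closed = ndimage.binary_closing(flagged.reshape(cm.shape2d),
                                        structure=np.ones((3, 3), dtype=bool))
        closed &= cm.interior.reshape(cm.shape2d)
        for comp in _components_2d(closed, min_bins):
            pts = cm.voxels_in_bins((comp.ravel()) & cm.populated)
            if len(pts):
                findings.append(Finding("ASD", points_mm=pts, asd_subtype=subtype))
    return findings


def detect_cartilage_defect(cartilage: LabelMask, frame: Frame = None,
                            params: SurfaceParams = SurfaceParams()):
    """Full-thickness cartilage loss over the reference cap.

    Defect bins are interior holes of the populated cap map plus bins whose
    cartilage is thinner than ``thickness_min_mm``.
    """
    cm = _CapMap(cartilage, frame, params.bin_size_sine)
    pop = cm.populated.reshape(cm.shape2d)
    filled = ndimage.binary_fill_holes(pop)
    thin = (cm.populated & (cm.thickness < params.thickness_min_mm)).reshape(cm.shape2d)
    candidate = ((filled & ~pop) | thin) & cm.interior.reshape(cm.shape2d)
    # a defect is an areal loss: opening rejects line-like gaps such as the
    # surface trace of a fissure
    candidate = ndimage.binary_opening(candidate, structure=np.ones((3, 3), dtype=bool))
    min_bins = max(1, int(np.ceil(params.area_min_mm2 / cm.bin_area_mm2())))
    ref = cm.reference_radius()
    findings = []
    for comp in _components_2d(candidate, min_bins):
        u = cm.bin_directions(comp.ravel())
        pts = cm.center + ref * u  # defect floor localized on the reference cap
        findings.append(Finding("ACD", points_mm=pts))
    return findings


def detect_fissures(cartilage: LabelMask, mri: ImageVolume,
                    params: FissureParams = FissureParams()):
    """Low-intensity lines inside the cartilage that penetrate or are
    perpendicular to the articular surface."""
    if not cartilage.data.any():
        raise ValueError("cartilage mask is empty")
    cart = cartilage.data
    envelope = ndimage.binary_closing(
        cart, structure=ball(params.close_radius_vox))
    candidates = envelope & ~cart & (mri.data < params.low_max)
    labels, n = ndimage.label(candidates, structure=_STRUCTS[26])
    if n == 0:
        return []
    center, _ = fit_sphere(cartilage.points_mm())
    spacing = cartilage.spacing
    findings = []
    for i in range(1, n + 1):
        idx = np.argwhere(labels == i)
        if len(idx) < params.min_voxels:
            continue
        pts = cartilage.world_coordinates(idx)
        rel = pts - center
        centroid_dir = rel.mean(axis=0)
        centroid_dir /= np.linalg.norm(centroid_dir)
        # principal axis of the component
        _, _, Vt = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)
        axis = Vt[0]
        cosang = abs(float(axis @ centroid_dir))
        angle = np.rad2deg(np.arccos(np.clip(cosang, 0.0, 1.0)))
        # radial span of the component vs local cartilage thickness
        r = np.linalg.norm(rel, axis=1)
        span = r.max() - r.min() + float(np.mean(spacing))
        thickness = _local_thickness(cartilage, center, centroid_dir)
        if angle <= params.angle_tol_deg or span >= params.span_frac * thickness:
            findings.append(Finding("ACF", points_mm=pts, voxels=idx))
    return findings


def _local_thickness(cartilage: LabelMask, center, direction,
                     cone_deg: float = 12.0) -> float:
    pts = cartilage.points_mm()
    rel = pts - center
    r = np.linalg.norm(rel, axis=1)
    u = rel / r[:, None]
    near = u @ direction >= np.cos(np.deg2rad(cone_deg))
    if not near.any():
        return float(np.ptp(r) + np.mean(cartilage.spacing))
    return float(r[near].max() - r[near].min() + np.mean(cartilage.spacing))


def detect_ssb(bone: LabelMask, min_voxels: int = 10) -> LabelMask:
    """Subchondral fragments disconnected from the parent bone.

    A candidate is a 3D 26-connected component disjoint from the largest
    bone component; it is accepted only if, in every axial, sagittal and
    coronal slice it occupies, it is 2D-disconnected (8-connectivity) from
    the main bone in that slice. The test is symmetric under axis
    relabelling.
    """
    if not bone.data.any():
        raise ValueError("bone mask is empty")
    labels, n = ndimage.label(bone.data, structure=_STRUCTS[26])
    out = np.zeros(bone.shape, dtype=bool)
    if n <= 1:
        return LabelMask(out, bone.spacing, bone.origin, bone.axes, "ssb")
    sizes = ndimage.sum_labels(bone.data, labels, index=np.arange(1, n + 1))
    main_label = int(np.argmax(sizes)) + 1
    main = labels == main_label
    for i in range(1, n + 1):
        if i == main_label:
            continue
        frag = labels == i
        if frag.sum() < min_voxels:
            continue
        if _disconnected_in_all_planes(frag, main):
            out |= frag
    return LabelMask(out, bone.spacing, bone.origin, bone.axes, "ssb")


def _disconnected_in_all_planes(frag: np.ndarray, main: np.ndarray) -> bool:
    struct2d = np.ones((3, 3), dtype=bool)
    for axis in range(3):
        occupied = np.flatnonzero(frag.any(axis=tuple(a for a in range(3) if a != axis)))
        for k in occupied:
            sl = [slice(None)] * 3
            sl[axis] = k
            plane_frag = frag[tuple(sl)]
            plane_bone = plane_frag | main[tuple(sl)]
            lab, _ = ndimage.label(plane_bone, structure=struct2d)
            frag_labels = np.unique(lab[plane_frag])
            main_labels = np.unique(lab[main[tuple(sl)]])
            if np.intersect1d(frag_labels, main_labels).size:
                return False
    return True


def highlight_sclerosis(ct: ImageVolume, bone: LabelMask,
                        percentile: float = 90.0) -> LabelMask:
    """Bone voxels above the given percentile of the bone intensity
    distribution; the largest connected component is retained."""
    if not bone.data.any():
        raise ValueError("bone mask is empty")
    vals = ct.data[bone.data]
    thr = np.percentile(vals, percentile)
    mask = bone.data & (ct.data > thr)
    if mask.any():
        labels, n = ndimage.label(mask, structure=_STRUCTS[26])
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return LabelMask(mask, bone.spacing, bone.origin, bone.axes, "sclerosis")


def ssb_underneath(finding: Finding, ssb: LabelMask, frame: Frame,
                   transform=None, tol_deg: float = 2.0) -> bool:
    """True when the radial projection (toward the cap centre) of the
    finding's footprint intersects the SSB fragment's projected footprint.

    ``transform`` maps the finding's (MRI-frame) points into the SSB's
    (CT) frame when the two are not already fused; ``frame`` is the
    anatomical frame in the SSB's coordinate system.
    """
    if ssb is None or not ssb.data.any():
        return False
    if finding.points_mm is None or len(finding.points_mm) == 0:
        return False
    pts = finding.points_mm
    if transform is not None:
        pts = transform.apply(pts)

    def _dirs(points):
        rel = np.atleast_2d(points) - frame.origin
        r = np.linalg.norm(rel, axis=1)
        u = rel / np.maximum(r, 1e-12)[:, None]
        front = u @ frame.anteroposterior > 0  # the cap side; the radial
        # projection toward the centre only meets the fragment from there
        return np.stack([u @ frame.mediolateral,
                         u @ frame.proximodistal], axis=1)[front]

    bin_size = np.sin(np.deg2rad(tol_deg))
    fd = _dirs(pts)
    sd = _dirs(ssb.points_mm())
    if len(fd) == 0 or len(sd) == 0:
        return False
    fb = np.round(fd / bin_size).astype(int)
    sb = np.round(sd / bin_size).astype(int)
    ssb_cells = set(map(tuple, sb))
    # dilate the SSB cells by one bin
    for cell in map(tuple, fb):
        for dh in (-1, 0, 1):
            for dv in (-1, 0, 1):
                if (cell[0] + dh, cell[1] + dv) in ssb_cells:
                    return True
    return False
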