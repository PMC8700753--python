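"""Geometric surgical simulation on the fused scene.

Three procedures are modelled: lesion resection (hiding the diseased
cartilage patch), osteochondral graft placement (a costal block or
cylindrical OATS plugs posed freely in the scene) and drilling (a
zero-width entry-to-target segment, optionally widened to the physical
drill diameter for the breach test).

Placement quality is reported as metrics, not verdicts: the covered
fraction of the resected footprint in the anteroposterior projection, the
step-off of the graft surface against the reference cap, the seating depth
into host bone, and any collision volume outside the prepared site. All
in-plane computation happens in the anatomical frame, so rigid motions of
the whole scene leave the metrics unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import trimesh

from .geometry import CapFootprint, Frame, RigidTransform
from .image_io import LabelMask
from .registration import FusionScene
from .surface import TriMeshModel, separate_region

__all__ = [
    "GraftModel",
    "PlacementResult",
    "DrillPlan",
    "make_costal_graft",
    "make_cylindrical_graft",
    "simulate_resection",
    "place_graft",
    "plan_drilling",
    "CYLINDER_CATALOG_MM",
]

CYLINDER_CATALOG_MM = (5.0, 7.0)


@dataclass
class GraftModel:
    """Osteochondral graft: a costal block or a cylindrical OATS plug."""

    shape: str                      # "costal_block" | "cylinder"
    dims: dict
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    mesh: TriMeshModel = None

    def posed_mesh(self) -> TriMeshModel:
        return self.mesh.transformed(self.pose)

    def with_pose(self, pose: RigidTransform) -> "GraftModel":
        return GraftModel(self.shape, dict(self.dims), pose, self.mesh)

    def contains(self, points_world: np.ndarray) -> np.ndarray:
        """Exact containment test in the graft's local frame."""
        local = self.pose.inverse().apply(np.atleast_2d(points_world))
        if self.shape == "cylinder":
            r = self.dims["diameter"] / 2.0
            h = self.dims["length"] / 2.0
            return ((local[:, 0] ** 2 + local[:, 1] ** 2 <= r ** 2)
                    & (np.abs(local[:, 2]) <= h))
        hx = self.dims["width"] / 2.0
        hy = self.dims["length"] / 2.0
        hz = self.dims["height"] / 2.0
        return ((np.abs(local[:, 0]) <= hx) & (np.abs(local[:, 1]) <= hy)
                & (np.abs(local[:, 2]) <= hz))


@dataclass
class PlacementResult:
    coverage_fraction: float
    step_off_mm: float
    seat_depth_mm: float
    collision_volume_mm3: float

    def __post_init__(self):
        if not 0.0 <= self.coverage_fraction <= 1.0 + 1e-9:
            raise ValueError("coverage fraction outside [0, 1]")
        if self.seat_depth_mm < 0 or self.collision_volume_mm3 < 0:
            raise ValueError("depth/volume metrics must be non-negative")


@dataclass
class DrillPlan:
    entry: np.ndarray
    direction: np.ndarray
    depth_mm: float
    approach: str
    target: np.ndarray
    cartilage_breach: bool
    sclerosis_penetrated: bool
    valid: bool


def make_costal_graft(length: float = 15.0, width: float = 11.0,
                      height: float = 10.0,
                      cartilage_cap_thickness: float = 1.5) -> GraftModel:
    """Rectangular costal osteochondral block with a cartilage cap layer.

    The default dimensions are this package's template for an average-sized
    rib graft; the cap thickness marks the top ``cartilage_cap_thickness``
    mm of the block as cartilage. Local frame: x width (ML), y length (PD),
    z height with the cartilage cap toward +z.
    """
    for name, v in (("length", length), ("width", width), ("height", height),
                    ("cartilage_cap_thickness", cartilage_cap_thickness)):
        if v <= 0:
            raise ValueError(f"graft {name} must be positive")
    if cartilage_cap_thickness >= height:
        raise ValueError("cartilage cap cannot exceed the block height")
    tm = trimesh.creation.box(extents=(width, length, height))
    mesh = TriMeshModel.from_trimesh(tm, "graft")
    return GraftModel("costal_block",
                      {"length": length, "width": width, "height": height,
                       "cartilage_cap_thickness": cartilage_cap_thickness},
                      mesh=mesh)


def make_cylindrical_graft(diameter: float, length: float = 12.0,
                           catalog=None) -> GraftModel:
    """Cylindrical OATS plug; ``catalog`` (an iterable of diameters in mm)
    restricts the size when catalog mode is on. Local axis along z."""
    if diameter <= 0 or length <= 0:
        raise ValueError("graft dimensions must be positive")
    if catalog is not None and diameter not in tuple(catalog):
        raise ValueError(f"diameter {diameter:g} mm not in catalog {tuple(catalog)}")
    tm = trimesh.creation.cylinder(radius=diameter / 2.0, height=length, sections=96)
    mesh = TriMeshModel.from_trimesh(tm, "graft")
    return GraftModel("cylinder", {"diameter": diameter, "length": length}, mesh=mesh)


def simulate_resection(scene: FusionScene, footprint: CapFootprint) -> FusionScene:
    """Separate the lesion footprint from the cartilage model and hide it."""
    if footprint is None:
        raise ValueError("resection footprint is empty")
    cartilage = scene.models["cartilage"]
    resection, remainder = separate_region(cartilage, footprint)
    resection.visible = False
    models = dict(scene.models)
    models["cartilage"] = remainder
    models["resection"] = resection
    return FusionScene(models=models, transform_mri_to_ct=scene.transform_mri_to_ct,
                       resection_footprint=footprint)


# ---------------------------------------------------------------------------
# graft placement metrics
# ---------------------------------------------------------------------------

def _footprint_grid(footprint: CapFootprint, resolution: float):
    """AP-plane cell centres covering the footprint, plus the inside mask."""
    frame = footprint.frame
    pts = footprint.sample_surface_points(80)
    uv = frame.project_ap(pts)
    lo = uv.min(axis=0) - 2 * resolution
    hi = uv.max(axis=0) + 2 * resolution
    us = np.arange(lo[0], hi[0] + resolution, resolution)
    vs = np.arange(lo[1], hi[1] + resolution, resolution)
    U, V = np.meshgrid(us, vs, indexing="ij")
    cells = np.stack([U.ravel(), V.ravel()], axis=1)
    R = footprint.surface_radius
    w2 = R ** 2 - cells[:, 0] ** 2 - cells[:, 1] ** 2
    ok = w2 > 0
    surf = np.full((len(cells), 3), np.nan)
    surf[ok] = (frame.origin
                + cells[ok, 0, None] * frame.mediolateral
                + cells[ok, 1, None] * frame.proximodistal
                + np.sqrt(w2[ok])[:, None] * frame.anteroposterior)
    inside = np.zeros(len(cells), dtype=bool)
    inside[ok] = footprint.contains_points(surf[ok])
    return cells, inside, surf


def _silhouette(cells_uv: np.ndarray, mesh: TriMeshModel, frame: Frame) -> np.ndarray:
    """Cells whose centre lies inside the AP projection of the mesh.

    Point-in-projected-triangle test over all faces; equivalent to casting
    an AP-axis ray through the closed mesh at each cell centre.
    """
    tri2d = frame.project_ap(mesh.vertices)[mesh.faces]  # (F, 3, 2)
    covered = np.zeros(len(cells_uv), dtype=bool)
    for a, b, c in tri2d:
        lo = np.minimum(np.minimum(a, b), c)
        hi = np.maximum(np.maximum(a, b), c)
        box = np.all((cells_uv >= lo - 1e-12) & (cells_uv <= hi + 1e-12), axis=1)
        box &= ~covered
        if not box.any():
            continue
        p = cells_uv[box]
        d = (b - a)[0] * (c - a)[1] - (b - a)[1] * (c - a)[0]
        if abs(d) < 1e-14:
            continue
        w1 = ((p[:, 0] - a[0]) * (c - a)[1] - (p[:, 1] - a[1]) * (c - a)[0]) / d
        w2 = ((p[:, 1] - a[1]) * (b - a)[0] - (p[:, 0] - a[0]) * (b - a)[1]) / d
        hit = (w1 >= -1e-12) & (w2 >= -1e-12) & (w1 + w2 <= 1 + 1e-12)
        covered[np.flatnonzero(box)[hit]] = True
    return covered


def place_graft(scene: FusionScene, grafts, footprint: CapFootprint = None,
                resolution: float = 0.2, host_bone_mask: LabelMask = None,
                volume_resolution: float = 0.5) -> PlacementResult:
    """Quantify one or more posed grafts against the resected footprint.

    ``grafts`` is a GraftModel or a list of them (multi-plug plans).
    Metrics are computed on an AP-plane raster at ``resolution`` mm;
    volumetric overlap uses ``volume_resolution``. ``host_bone_mask``
    enables the seating/collision metrics without mesh containment tests.
    """
    if footprint is None:
        footprint = scene.resection_footprint
    if footprint is None:
        raise ValueError("no resection footprint: run simulate_resection first "
                         "or pass footprint=")
    if isinstance(grafts, GraftModel):
        grafts = [grafts]
    frame = footprint.frame
    cells, inside, _ = _footprint_grid(footprint, resolution)
    n_inside = int(inside.sum())
    covered = np.zeros(len(cells), dtype=bool)
    for g in grafts:
        covered |= _silhouette(cells, g.posed_mesh(), frame)
    coverage = float((covered & inside).sum() / n_inside) if n_inside else 0.0
    if coverage == 0.0:
        warnings.warn("graft placement does not cover the footprint at all",
                      stacklevel=2)

    # step-off: radial deviation of graft vertices over the footprint
    step_off = 0.0
    for g in grafts:
        verts = g.posed_mesh().vertices
        uv = frame.project_ap(verts)
        r2 = footprint.surface_radius ** 2 - uv[:, 0] ** 2 - uv[:, 1] ** 2
        ok = r2 > 0
        if not ok.any():
            continue
        over = footprint.contains_points(verts[ok])
        if not over.any():
            continue
        rel = verts[ok][over] - frame.origin
        dev = np.linalg.norm(rel, axis=1) - footprint.surface_radius
        cand = dev[np.argmax(np.abs(dev))]
        if abs(cand) > abs(step_off):
            step_off = float(cand)

    seat_depth, collision = _volumetric_metrics(
        scene, grafts, footprint, host_bone_mask, volume_resolution)
    return PlacementResult(coverage, step_off, seat_depth, collision)


def _volumetric_metrics(scene, grafts, footprint, bone_mask, res):
    if bone_mask is None:
        # seating/collision need a voxel occupancy of the host bone; without
        # one only the in-plane metrics are reported
        return 0.0, 0.0

    def bone_contains(pts):
        return _mask_lookup(bone_mask, pts)
    frame = footprint.frame
    seat = 0.0
    collision = 0.0
    for g in grafts:
        lo, hi = g.posed_mesh().as_trimesh().bounds
        axes = [np.arange(l + res / 2, h, res) for l, h in zip(lo, hi)]
        if any(len(a) == 0 for a in axes):
            continue
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        pts = pts[g.contains(pts)]
        if len(pts) == 0:
            continue
        in_bone = bone_contains(pts)
        if not in_bone.any():
            continue
        embedded = pts[in_bone]
        rel = embedded - frame.origin
        # depth below the (spherical) subchondral surface of the cap
        depth = footprint.surface_radius - np.linalg.norm(rel, axis=1)
        seat = max(seat, float(depth.max()))
        outside_site = ~footprint.contains_points(embedded)
        collision += float(outside_site.sum()) * res ** 3
    return seat, collision


def _indices(mask: LabelMask, pts: np.ndarray) -> np.ndarray:
    rel = np.atleast_2d(pts) - mask.origin
    return (rel @ mask.axes) / mask.spacing


# ---------------------------------------------------------------------------
# drilling
# ---------------------------------------------------------------------------

def plan_drilling(scene: FusionScene, entry, target, approach: str,
                  bone_mask: LabelMask = None,
                  sclerosis_mask: LabelMask = None,
                  drill_diameter: float = 0.0,
                  surface_tol_mm: float = 1.5) -> DrillPlan:
    """Plan a drill path from a cortical entry point to a target in bone.

    The path is the entry->target segment. ``cartilage_breach`` is a
    ray-mesh test against the scene cartilage; posteroanterior plans that
    breach cartilage are flagged invalid (the approach exists precisely to
    avoid iatrogenic cartilage damage). ``sclerosis_penetrated`` samples
    the sclerosis mask along the path.
    """
    if approach not in ("anteroposterior", "posteroanterior"):
        raise ValueError(f"unknown approach {approach!r}")
    entry = np.asarray(entry, dtype=float).reshape(3)
    target = np.asarray(target, dtype=float).reshape(3)
    if bone_mask is not None:
        if not _mask_lookup(bone_mask, target[None])[0]:
            raise ValueError("drill target lies outside the bone")
        if not _near_surface(bone_mask, entry, surface_tol_mm):
            raise ValueError("drill entry point is not on the bone surface")
    vec = target - entry
    depth = float(np.linalg.norm(vec))
    if depth <= 0:
        raise ValueError("entry and target coincide")
    direction = vec / depth

    breach = _segment_hits_mesh(scene.models.get("cartilage"), entry, direction,
                                depth, drill_diameter)
    sclerosis = False
    if sclerosis_mask is not None and sclerosis_mask.data.any():
        step = float(min(sclerosis_mask.spacing)) / 2.0
        ts = np.arange(0.0, depth + step, step)
        pts = entry + ts[:, None] * direction
        sclerosis = bool(_mask_lookup(sclerosis_mask, pts).any())
    valid = not (approach == "posteroanterior" and breach)
    return DrillPlan(entry, direction, depth, approach, target, breach,
                     sclerosis, valid)


def _segment_hits_mesh(mesh: TriMeshModel, entry, direction, depth,
                       drill_diameter) -> bool:
    if mesh is None or mesh.n_faces == 0:
        return False
    from .raycast import ray_intersects

    origins = [entry]
    if drill_diameter > 0:
        # widen to a capsule: four perimeter rays at the drill radius
        a = np.array([1.0, 0.0, 0.0])
        if abs(a @ direction) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(direction, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(direction, e1)
        r = drill_diameter / 2.0
        origins += [entry + r * e1, entry - r * e1, entry + r * e2, entry - r * e2]
    hits = ray_intersects(mesh.vertices, mesh.faces, np.asarray(origins),
                          direction, t_max=depth)
    return bool(hits.any())


def _mask_lookup(mask: LabelMask, pts: np.ndarray) -> np.ndarray:
    idx = np.round(_indices(mask, pts)).astype(int)
    valid = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=1)
    out = np.zeros(len(np.atleast_2d(pts)), dtype=bool)
    out[valid] = mask.data[tuple(idx[valid].T)]
    return out


def _near_surface(mask: LabelMask, point, tol_mm: float) -> bool:
    """Point within ``tol_mm`` of the mask boundary (either side)."""
    idx = np.round(_indices(mask, point[None])[0]).astype(int)
    rad = int(np.ceil(tol_mm / float(min(mask.spacing))))
    lo = np.maximum(idx - rad, 0)
    hi = np.minimum(idx + rad + 1, mask.shape)
    patch = mask.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return bool(patch.any() and not patch.all())
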