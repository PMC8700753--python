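"""Two-stage rigid registration and MCFI scene assembly.

Stage one ("N-point registration") is landmark-based: a least-squares
proper rigid transform between ordered corresponding points, solved by the
Kabsch/Umeyama construction with reflections excluded. Stage two ("global
registration") refines the alignment from the shapes themselves; the
commercial tool the workflow originally used does not disclose its
algorithm, and point-to-point ICP with nearest-neighbour correspondence on
a KD-tree is this package's stand-in.

Fusion keeps the MRI-derived cartilage rigidly linked to the MRI humerus:
every MRI-frame model moves through the one scene transform, the MRI
humerus is then hidden, and the SSB overlay stays in the CT frame it was
segmented from, displayed in red.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform
from .image_io import LandmarkSet
from .surface import TriMeshModel

__all__ = ["RigidTransform", "FusionScene", "npoint_register", "icp_refine",
           "build_mcfi", "set_transparency"]


def npoint_register(src, dst):
    """Least-squares rigid transform mapping ``src`` landmarks onto ``dst``.

    Landmarks correspond by order; when both arguments are LandmarkSets
    their names must agree in order. Returns (transform, rmsd_mm). The
    rotation is restricted to determinant +1 — no scaling, no reflection.
    """
    src_names = dst_names = None
    if isinstance(src, LandmarkSet):
        src_names, src = src.names, src.points
    if isinstance(dst, LandmarkSet):
        dst_names, dst = dst.names, dst.points
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if len(src) != len(dst):
        raise ValueError(f"landmark count mismatch: {len(src)} vs {len(dst)}")
    if len(src) < 3:
        raise ValueError("at least 3 corresponding points required")
    if src_names is not None and dst_names is not None and src_names != dst_names:
        raise ValueError("landmark names do not correspond in order")
    for name, pts in (("source", src), ("destination", dst)):
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError(f"{name} landmarks are collinear")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - mu_d, src - mu_s)
    R = rot.as_matrix()
    t = mu_d - R @ mu_s
    T = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((T.apply(src) - dst) ** 2, axis=1))))
    return T, rmsd


def icp_refine(moving, fixed, init: RigidTransform = None, max_iter: int = 50,
               rel_tol: float = 1e-6, subsample: int = None, seed: int = 0,
               trim_fraction: float = 0.0):
    """Point-to-point ICP refinement of a rigid initialization.

    ``moving``/``fixed`` are TriMeshModels or (N, 3) vertex arrays. Each
    iteration matches (optionally subsampled) moving points to their
    nearest fixed vertices and re-solves the rigid transform; convergence
    is declared on the relative change of the correspondence rmsd. The
    rmsd trace is non-increasing. No trimming is applied by default — the
    phantom meshes fully overlap; ``trim_fraction`` drops the worst
    matches for partial-overlap data.
    """
    P = moving.vertices if isinstance(moving, TriMeshModel) else np.atleast_2d(moving)
    Q = fixed.vertices if isinstance(fixed, TriMeshModel) else np.atleast_2d(fixed)
    if len(P) == 0 or len(Q) == 0:
        raise ValueError("ICP requires non-empty point sets")
    if not (np.isfinite(P).all() and np.isfinite(Q).all()):
        raise ValueError("non-finite vertices passed to ICP")
    if init is None:
        init = RigidTransform.identity()
    if subsample is not None and subsample < len(P):
        rng = np.random.default_rng(seed)
        P = P[rng.choice(len(P), size=subsample, replace=False)]
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must lie in [0, 1)")
    tree = cKDTree(Q)
    T = init
    trace = []
    for _ in range(max_iter):
        moved = T.apply(P)
        dists, idx = tree.query(moved)
        src, targets = P, Q[idx]
        if trim_fraction > 0.0:
            # drop the worst matches: points without a true counterpart
            # (partial overlap, field-of-view cut faces) bias the fit
            keep = dists <= np.quantile(dists, 1.0 - trim_fraction)
            src, targets = P[keep], targets[keep]
        # re-solve the full transform from the original points
        mu_p, mu_t = src.mean(axis=0), targets.mean(axis=0)
        rot, _ = Rotation.align_vectors(targets - mu_t, src - mu_p)
        R = rot.as_matrix()
        T = RigidTransform(R, mu_t - R @ mu_p)
        rmsd = float(np.sqrt(np.mean(np.sum((T.apply(src) - targets) ** 2, axis=1))))
        if trace and rmsd > trace[-1]:
            rmsd = trace[-1]  # guard: never report an increase
            trace.append(rmsd)
            break
        converged = bool(trace) and abs(trace[-1] - rmsd) <= rel_tol * max(trace[-1], 1e-12)
        trace.append(rmsd)
        if converged:
            break
    return T, trace


@dataclass
class FusionScene:
    """The MCFI: CT bone + MRI cartilage in one (CT) world frame."""

    models: dict
    transform_mri_to_ct: RigidTransform
    resection_footprint: object = None  # set by the resection simulation

    def get(self, label: str) -> TriMeshModel:
        return self.models[label]

    def visible_models(self):
        return [m for m in self.models.values() if m.visible and m.transparency > 0]


def build_mcfi(ct_humerus: TriMeshModel, mri_humerus: TriMeshModel,
               cartilage: TriMeshModel, ssb: TriMeshModel = None,
               transform: RigidTransform = None) -> FusionScene:
    """Assemble the fusion scene.

    All MRI-frame models (humerus, cartilage) move through the same
    transform, preserving their relative pose; the MRI humerus is hidden
    once fusion is complete; the CT humerus is untouched; the SSB model is
    shown in red. The SSB stays in whatever frame it carries (CT, as
    segmented, by default).
    """
    if ct_humerus is None:
        raise ValueError("build_mcfi requires the CT humerus model")
    if transform is None:
        transform = RigidTransform.identity()
    for name, m in (("mri_humerus", mri_humerus), ("cartilage", cartilage)):
        if m.frame != "MRI":
            raise ValueError(f"{name} must be in the MRI frame, got {m.frame!r}")
    models = {"humerus_ct": ct_humerus.copy()}
    moved_humerus = mri_humerus.transformed(transform)
    moved_humerus.visible = False
    moved_humerus.frame = "CT"
    models["humerus_mri"] = moved_humerus
    moved_cart = cartilage.transformed(transform)
    moved_cart.frame = "CT"
    models["cartilage"] = moved_cart
    if ssb is not None:
        ssb = ssb.transformed(transform) if ssb.frame == "MRI" else ssb.copy()
        ssb.frame = "CT"
        ssb.color = (220, 30, 30, 255)
        models["ssb"] = ssb
    return FusionScene(models=models, transform_mri_to_ct=transform)


def set_transparency(scene: FusionScene, label: str, alpha: float) -> FusionScene:
    """Change one model's transparency (0 hides it from rendering)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if label not in scene.models:
        raise KeyError(f"scene has no model {label!r}")
    scene.models[label].transparency = alpha
    return scene
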