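"""Lesion quantification on the fused scene.

The articular surface of the capitellum is treated as elliptical in the
anteroposterior (AP) view and divided into four areas, numbered clockwise
from the anteromedial quadrant. Findings (fissures, defects, surface
deformities) are localized into those areas, lesion diameters are taken as
straight-line extents of the AP-projected footprint, and severity is
graded by an explicit, codified rule set:

* stability — a lesion is unstable when a fissure or surface deformity has
  segmented subchondral bone (SSB) underneath it, or when the cartilage is
  frankly defective;
* ICRS grade — defect => IV; surface deformity, or fissure with SSB
  underneath => III; fissure alone => II; otherwise I. Grades III/IV are
  the unstable grades.

The precedence order (ACD > ASD / ACF+SSB > ACF > none) is this package's
codification of a judgement call that is otherwise made by eye; it is
validated against the packaged case tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Frame

__all__ = [
    "Finding",
    "EllipseModel",
    "LesionReport",
    "fit_capitellar_ellipse",
    "assign_area",
    "localize_finding",
    "measure_diameters",
    "classify_stability",
    "predict_icrs",
    "predict_icrs_from_flags",
    "recommend_procedure",
]

FINDING_KINDS = ("ACF", "ACD", "ASD")
ASD_SUBTYPES = ("protrusion", "flattening")


@dataclass
class Finding:
    """One cartilage/bone finding: fissure (ACF), defect (ACD) or surface
    deformity (ASD), carried as a surface patch in world mm."""

    kind: str
    points_mm: np.ndarray = None
    voxels: np.ndarray = None            # optional (N, 3) grid indices
    areas: set = field(default_factory=set)
    asd_subtype: str = None
    ssb_underneath: bool = False

    def __post_init__(self):
        if self.kind not in FINDING_KINDS:
            raise ValueError(f"unknown finding kind {self.kind!r}")
        if self.kind == "ASD":
            if self.asd_subtype not in ASD_SUBTYPES:
                raise ValueError("ASD finding requires subtype protrusion|flattening")
        elif self.asd_subtype is not None:
            raise ValueError("asd_subtype only valid for ASD findings")
        if self.points_mm is not None:
            self.points_mm = np.atleast_2d(np.asarray(self.points_mm, dtype=float))


@dataclass
class EllipseModel:
    """Ellipse in the AP-projection plane: center (u, v) in mm, semi-axis
    ``a`` along mediolateral, ``b`` along proximodistal, rotated by theta."""

    center: np.ndarray
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def normalized_radius(self, uv: np.ndarray) -> np.ndarray:
        """sqrt((x/a)^2 + (y/b)^2) in the ellipse-aligned frame; 1 on the rim."""
        p = np.atleast_2d(np.asarray(uv, dtype=float)) - self.center
        c, s = np.cos(-self.theta), np.sin(-self.theta)
        x = c * p[:, 0] - s * p[:, 1]
        y = s * p[:, 0] + c * p[:, 1]
        return np.sqrt((x / self.a) ** 2 + (y / self.b) ** 2)


@dataclass
class LesionReport:
    findings: list = field(default_factory=list)
    ssb_present: bool = False
    vertical_diameter_mm: float = None
    horizontal_diameter_mm: float = None
    stability: str = None             # "stable" | "unstable"
    icrs_class: str = None            # "I".."IV"
    recommended_procedure: str = None

    @property
    def max_diameter_mm(self):
        vals = [v for v in (self.vertical_diameter_mm, self.horizontal_diameter_mm)
                if v is not None]
        return max(vals) if vals else None


def fit_capitellar_ellipse(cartilage_mesh, frame: Frame) -> EllipseModel:
    """Least-squares ellipse fit to the AP-plane silhouette of the cartilage.

    The silhouette is the convex outline of the projected vertices; the
    skimage ellipse estimator runs on the hull boundary.
    """
    from scipy.spatial import ConvexHull
    from skimage.measure import EllipseModel as _SkEllipse

    verts = _mesh_vertices(cartilage_mesh)
    if verts is None or len(verts) == 0:
        raise ValueError("cannot fit ellipse: cartilage mesh is empty")
    uv = frame.project_ap(verts)
    try:
        hull = ConvexHull(uv)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate AP projection: {exc}") from exc
    boundary = uv[hull.vertices]
    # resample the hull polygon densely so the fit is not dominated by
    # vertex clustering
    boundary = _resample_polygon(boundary, 360)
    try:
        model = _SkEllipse.from_estimate(boundary)
        ok = bool(model)
    except AttributeError:  # scikit-image < 0.26
        model = _SkEllipse()
        ok = model.estimate(boundary)
    if not ok:
        raise ValueError("ellipse fit failed on the projected boundary")
    xc, yc, a, b, theta = (*model.center, *model.axis_lengths, model.theta) \
        if hasattr(model, "center") else model.params
    # orient semi-axis "a" along mediolateral (u): fold theta into [0, pi)
    theta = theta % np.pi
    if theta > np.pi / 2:   # closer to the v axis: swap roles
        a, b = b, a
        theta -= np.pi / 2
    return EllipseModel(center=(xc, yc), a=float(a), b=float(b), theta=float(theta))


def _resample_polygon(poly: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n, endpoint=False)
    out = np.empty((n, 2))
    for d in range(2):
        out[:, d] = np.interp(t, s, closed[:, d])
    return out


def _mesh_vertices(mesh):
    if hasattr(mesh, "vertices"):
        v = np.asarray(mesh.vertices)
        return v if len(v) else None
    return np.atleast_2d(np.asarray(mesh, dtype=float))


def assign_area(point_mm, ellipse: EllipseModel, frame: Frame,
                rim_tol: float = 0.02) -> int:
    """Map a world point to capitellar area 1-4.

    Quadrants are delimited by the proximodistal and mediolateral axes
    through the ellipse centre. Numbering runs clockwise in the AP view
    starting anteromedial: 1 medial-proximal, 2 medial-distal,
    3 lateral-distal, 4 lateral-proximal (the mediolateral axis points
    medial on either side, so area 1 stays anteromedial for left elbows).
    Boundary points go to the lower-numbered adjacent area.
    """
    uv = frame.project_ap(np.asarray(point_mm, dtype=float))[0]
    rho = float(ellipse.normalized_radius(uv)[0])
    if rho > 1.0 + rim_tol:
        raise ValueError(
            f"point projects outside the capitellar ellipse "
            f"(normalized distance {rho:.3f}, {ellipse.a * (rho - 1):.2f} mm past the rim)")
    u, v = uv - ellipse.center
    if u > 0 and v > 0:
        return 1
    if u > 0 and v < 0:
        return 2
    if u < 0 and v < 0:
        return 3
    if u < 0 and v > 0:
        return 4
    # ties: lower-numbered adjacent area
    if u == 0 and v > 0:
        return 1          # between areas 1 and 4
    if u == 0 and v < 0:
        return 2          # between areas 2 and 3
    if v == 0 and u > 0:
        return 1          # between areas 1 and 2
    if v == 0 and u < 0:
        return 3          # between areas 3 and 4
    return 1              # exact centre


def localize_finding(finding: Finding, ellipse: EllipseModel, frame: Frame) -> Finding:
    """Fill ``finding.areas`` from its projected surface patch.

    Patch points marginally outside the fitted rim (detection jitter) are
    ignored; at least one point must project inside.
    """
    if finding.points_mm is None or len(finding.points_mm) == 0:
        raise ValueError("finding has no surface patch to localize")
    uv = frame.project_ap(finding.points_mm)
    rho = ellipse.normalized_radius(uv)
    inside = rho <= 1.0 + 0.05
    if not inside.any():
        raise ValueError("finding patch projects entirely outside the ellipse")
    areas = {assign_area(p, ellipse, frame) for p in finding.points_mm[inside]}
    finding.areas = areas
    return finding


def measure_diameters(footprint_points, frame: Frame):
    """(vertical, horizontal) extents in mm of the AP-projected footprint.

    Vertical is the proximodistal extent, horizontal the mediolateral one.
    An empty footprint yields (None, None) — the unmeasurable-lesion case.
    """
    if footprint_points is None:
        return None, None
    pts = np.atleast_2d(np.asarray(footprint_points, dtype=float))
    if len(pts) == 0:
        return None, None
    uv = frame.project_ap(pts)
    horizontal = float(uv[:, 0].max() - uv[:, 0].min())
    vertical = float(uv[:, 1].max() - uv[:, 1].min())
    return vertical, horizontal


def classify_stability(findings) -> str:
    """Unstable when any fissure/deformity has SSB underneath, or any
    cartilage defect exists; stable otherwise."""
    for f in findings:
        if f.kind == "ACD":
            return "unstable"
        if f.kind in ("ACF", "ASD") and f.ssb_underneath:
            return "unstable"
    return "stable"


def predict_icrs(findings, use_ssb: bool = True) -> str:
    """Codified ICRS grade from findings.

    With ``use_ssb=False`` the SSB-underneath flag is ignored (the
    findings-only variant used for table records where SSB was not
    recorded per finding).
    """
    has = {k: False for k in FINDING_KINDS}
    with_ssb = {"ACF": False, "ASD": False}
    for f in findings:
        has[f.kind] = True
        if f.kind in with_ssb and f.ssb_underneath:
            with_ssb[f.kind] = True
    if not use_ssb:
        with_ssb = {"ACF": False, "ASD": has["ASD"]}
    return predict_icrs_from_flags(
        acf=has["ACF"], acd=has["ACD"], asd=has["ASD"],
        acf_ssb=with_ssb["ACF"], asd_ssb=with_ssb["ASD"])


def predict_icrs_from_flags(acf: bool, acd: bool, asd: bool,
                            acf_ssb: bool = False, asd_ssb: bool = None) -> str:
    """Findings-only ICRS rule on presence flags.

    Without SSB information a lone fissure grades II (an intact but
    fissured surface) while any surface deformity grades III — the
    deformity itself is the instability sign; ``asd_ssb`` therefore
    defaults to the ASD presence flag, ``acf_ssb`` to False. With
    per-finding SSB flags, grades III/IV coincide exactly with the
    unstable lesions of :func:`classify_stability`.
    """
    if asd_ssb is None:
        asd_ssb = asd
    if acd:
        return "IV"
    if asd_ssb or acf_ssb:
        return "III"
    if acf or asd:
        return "II"
    return "I"


def recommend_procedure(report: LesionReport,
                        refractory_to_conservative: bool = False,
                        free_bodies: bool = False) -> list:
    """Surgical recommendation rule.

    Reconstruction when the lesion is unstable and its maximum diameter
    exceeds 10 mm; drilling for small grade-IV lesions or stable lesions
    refractory to conservative therapy; free-body removal is appended
    whenever free bodies are present.
    """
    procedures = []
    unstable = report.stability == "unstable"
    d = report.max_diameter_mm
    if unstable and d is None:
        raise ValueError("unstable lesion requires measured diameters "
                         "before a procedure can be recommended")
    if unstable and d > 10.0:
        procedures.append("reconstruction")
    elif (report.icrs_class == "IV" and d is not None and d <= 10.0) or \
            (report.stability == "stable" and refractory_to_conservative):
        procedures.append("drilling")
    if free_bodies:
        procedures.append("free_body_removal")
    if not procedures:
        procedures.append("none")
    return procedures
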