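"""Core geometric primitives shared across the pipeline.

Everything lives in a right-handed world frame measured in millimetres.
The anatomical frame of the capitellum is described by three orthonormal
axes: anteroposterior (AP, pointing anterior), proximodistal (PD, pointing
proximal) and mediolateral (ML, pointing medial).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "Frame",
    "CapFootprint",
    "fit_sphere",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` in mm world space.

    ``rotation`` must be orthonormal with determinant +1; reflections are
    rejected because a mirrored solution would silently flip anatomy.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection rejected)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array (or single point) through the transform."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self after other``: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    # -- error metrics against another transform ------------------------------
    def rotation_angle_to(self, other: "RigidTransform") -> float:
        """Geodesic rotation distance to ``other`` in degrees.

        Computed via the quaternion magnitude, which keeps full precision
        for near-identity differences where arccos of the trace would not.
        """
        dR = self.rotation.T @ other.rotation
        return float(np.rad2deg(Rotation.from_matrix(dR).magnitude()))

    def translation_distance_to(self, other: "RigidTransform") -> float:
        return float(np.linalg.norm(self.translation - other.translation))

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
            "units": "mm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"], dtype=float).reshape(3, 3),
                   np.asarray(d["translation"], dtype=float))


@dataclass(frozen=True)
class Frame:
    """Anatomical frame of the capitellar cap.

    ``origin`` is the centre of the (approximately spherical) capitellum.
    The three axes are orthonormal unit vectors; ``side`` records which
    elbow the frame describes so that area numbering can keep the
    anteromedial quadrant as area 1 on either side.
    """

    origin: np.ndarray
    anteroposterior: np.ndarray
    proximodistal: np.ndarray
    mediolateral: np.ndarray
    side: str = "right"

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        axes = [np.asarray(v, dtype=float).reshape(3)
                for v in (self.anteroposterior, self.proximodistal, self.mediolateral)]
        M = np.stack(axes)
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-6):
            raise ValueError("frame axes must be orthonormal")
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "anteroposterior", axes[0])
        object.__setattr__(self, "proximodistal", axes[1])
        object.__setattr__(self, "mediolateral", axes[2])

    @classmethod
    def standard(cls, origin=(0.0, 0.0, 0.0), side: str = "right") -> "Frame":
        """ML = +x (medial), PD = +y (proximal), AP = +z (anterior)."""
        return cls(origin, (0, 0, 1), (0, 1, 0), (1, 0, 0), side)

    def project_ap(self, points: np.ndarray) -> np.ndarray:
        """Project world points onto the anteroposterior view plane.

        Returns (N, 2) in-plane coordinates (u, v): u along mediolateral,
        v along proximodistal, both relative to ``origin``.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return np.stack([pts @ self.mediolateral, pts @ self.proximodistal], axis=1)

    def transformed(self, T: RigidTransform) -> "Frame":
        R = T.rotation
        return Frame(T.apply(self.origin), R @ self.anteroposterior,
                     R @ self.proximodistal, R @ self.mediolateral, self.side)

    def to_dict(self) -> dict:
        return {
            "origin": [float(v) for v in self.origin],
            "anteroposterior": [float(v) for v in self.anteroposterior],
            "proximodistal": [float(v) for v in self.proximodistal],
            "mediolateral": [float(v) for v in self.mediolateral],
            "side": self.side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Frame":
        return cls(d["origin"], d["anteroposterior"], d["proximodistal"],
                   d["mediolateral"], d.get("side", "right"))


@dataclass(frozen=True)
class CapFootprint:
    """Elliptic angular region on a spherical cap.

    Membership is decided in angle space: a direction ``u`` from the sphere
    centre belongs to the footprint when

        (asin(u·PD)/alpha_v)^2 + (asin(u·ML)/alpha_h)^2 <= 1

    after rotating ``u`` into the footprint-centred frame. The straight-line
    (chord) extent of the footprint in the AP projection at surface radius
    ``R`` is ``2 R sin(alpha)`` per half-angle, which is the closed form the
    phantom's ground-truth diameters use.
    """

    frame: Frame
    alpha_v_deg: float  # angular half-extent toward proximodistal
    alpha_h_deg: float  # angular half-extent toward mediolateral
    surface_radius: float  # mm, radius of the surface the footprint lives on
    center_rotation: np.ndarray = field(default=None)  # optional 3x3, pole -> lesion centre

    def _angles(self, points: np.ndarray):
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.frame.origin
        r = np.linalg.norm(pts, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = pts / r[:, None]
        u = np.nan_to_num(u)
        if self.center_rotation is not None:
            u = u @ self.center_rotation  # rotate into footprint-centred frame
        s_h = np.clip(u @ self.frame.mediolateral, -1, 1)
        s_v = np.clip(u @ self.frame.proximodistal, -1, 1)
        front = u @ self.frame.anteroposterior > 0
        return np.arcsin(s_v), np.arcsin(s_h), front, r

    def membership(self, points: np.ndarray) -> np.ndarray:
        """Squared elliptic angular measure; <= 1 means inside (on the front cap)."""
        phi_v, phi_h, front, _ = self._angles(points)
        av = np.deg2rad(self.alpha_v_deg)
        ah = np.deg2rad(self.alpha_h_deg)
        m = (phi_v / av) ** 2 + (phi_h / ah) ** 2
        m[~front] = np.inf
        return m

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        return self.membership(points) <= 1.0

    @property
    def vertical_extent_mm(self) -> float:
        return 2.0 * self.surface_radius * np.sin(np.deg2rad(self.alpha_v_deg))

    @property
    def horizontal_extent_mm(self) -> float:
        return 2.0 * self.surface_radius * np.sin(np.deg2rad(self.alpha_h_deg))

    def sample_surface_points(self, n_radial: int = 60,
                              n_angular: int = 240) -> np.ndarray:
        """Dense analytic sample of the footprint patch on its surface (mm).

        Polar sampling of the unit angle-disc, including the boundary rim
        and the axis extremes, so projected extents of the sample match the
        closed-form chords exactly.
        """
        av = np.deg2rad(self.alpha_v_deg)
        ah = np.deg2rad(self.alpha_h_deg)
        rad = np.linspace(0.0, 1.0, n_radial)
        ang = np.linspace(0.0, 2.0 * np.pi, n_angular, endpoint=False)
        rr, aa = np.meshgrid(rad, ang, indexing="ij")
        tv = (rr * np.sin(aa)).ravel()
        th = (rr * np.cos(aa)).ravel()
        phi_v = tv * av
        phi_h = th * ah
        sv, sh = np.sin(phi_v), np.sin(phi_h)
        sz = np.sqrt(np.clip(1.0 - sv ** 2 - sh ** 2, 0.0, None))
        f = self.frame
        u = (sh[:, None] * f.mediolateral + sv[:, None] * f.proximodistal
             + sz[:, None] * f.anteroposterior)
        if self.center_rotation is not None:
            u = u @ self.center_rotation.T
        return f.origin + self.surface_radius * u


def fit_sphere(points: np.ndarray):
    """Least-squares sphere fit (algebraic/Coope form).

    Solves ``|x|^2 = 2 c·x + (R^2 - |c|^2)`` linearly. Returns (center, radius).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 4:
        raise ValueError("sphere fit needs at least 4 points")
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.sum(pts ** 2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0 or not np.isfinite(r2):
        raise ValueError("degenerate point set: sphere fit failed")
    return center, float(np.sqrt(r2))
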