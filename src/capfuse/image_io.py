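"""Readers and writers for the standard formats the pipeline touches.

Internal convention: right-handed RAS-style world coordinates in mm.
DICOM/ITK use LPS; the first two axes are flipped on read so that one
internal convention holds everywhere. Voxel indices are 0-based and the
world coordinate of voxel (i, j, k) is ``origin + axes @ (spacing * ijk)``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"
VALID_ICRS = ("I", "II", "III", "IV")
_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])


@dataclass
class ImageVolume:
    """3D scalar grid with voxel spacing, origin and direction axes (mm)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    modality: str = "MRI"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-6):
            raise ValueError("direction axes must be orthonormal")

    @property
    def shape(self):
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine."""
        A = np.eye(4)
        A[:3, :3] = self.axes * self.spacing[None, :]
        A[:3, 3] = self.origin
        return A

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(indices, dtype=float))
        return ijk * self.spacing @ self.axes.T + self.origin

    def indices_of(self, world_points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points (no rounding)."""
        pts = np.atleast_2d(np.asarray(world_points, dtype=float)) - self.origin
        return (pts @ self.axes) / self.spacing

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMask:
    """Binary tissue mask aligned to a parent :class:`ImageVolume` grid."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes: np.ndarray
    label: str

    VALID_LABELS = ("humerus", "cartilage", "ssb", "sclerosis", "lesion_footprint")

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if self.label not in self.VALID_LABELS:
            raise ValueError(f"unknown tissue label {self.label!r}")

    @classmethod
    def like(cls, volume: ImageVolume, data: np.ndarray, label: str) -> "LabelMask":
        if data.shape != volume.shape:
            raise ValueError("mask shape does not match parent volume")
        return cls(data, volume.spacing, volume.origin, volume.axes, label)

    @property
    def shape(self):
        return self.data.shape

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(indices, dtype=float))
        return ijk * self.spacing @ self.axes.T + self.origin

    def points_mm(self) -> np.ndarray:
        """World coordinates of all set voxels."""
        idx = np.argwhere(self.data)
        return self.world_coordinates(idx)

    def count(self) -> int:
        return int(self.data.sum())

    def as_volume(self, modality: str = "CT") -> ImageVolume:
        return ImageVolume(self.data.astype(np.uint8), self.spacing,
                           self.origin, self.axes, modality)


@dataclass
class LandmarkSet:
    """Ordered, named 3D points in mm world coordinates."""

    names: list
    points: np.ndarray
    frame: str  # "MRI" or "CT"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.names) != len(self.points):
            raise ValueError("names and points length mismatch")
        if len(self.points) < 3:
            raise ValueError("at least 3 landmarks required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if _collinear(self.points):
            raise ValueError("landmarks must not all be collinear")
        if self.frame not in ("MRI", "CT"):
            raise ValueError("frame tag must be 'MRI' or 'CT'")

    def __len__(self):
        return len(self.points)


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def read_volume(path, fmt: str = None, modality: str = None) -> ImageVolume:
    """Read NIfTI / NRRD / a DICOM series directory into an ImageVolume.

    ``fmt`` may be 'nifti', 'nrrd' or 'dicom'; inferred from the path when
    omitted. DICOM and NRRD headers (LPS) are converted to the internal RAS
    convention.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read volume: {path} does not exist")
    if fmt is None:
        name = path.name.lower()
        if path.is_dir():
            fmt = "dicom"
        elif name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith(".nrrd"):
            fmt = "nrrd"
        else:
            raise IOError(f"cannot infer format of {path}")

    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        A = img.affine  # nibabel affines are already RAS
        spacing = np.linalg.norm(A[:3, :3], axis=0)
        axes = A[:3, :3] / spacing[None, :]
        origin = A[:3, 3]
    elif fmt in ("nrrd", "dicom"):
        if fmt == "dicom":
            img = _read_dicom_series(path)
        else:
            img = sitk.ReadImage(str(path))
        # sitk arrays are (k, j, i); transpose to (i, j, k)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing())
        axes = _LPS_TO_RAS @ np.asarray(img.GetDirection()).reshape(3, 3)
        origin = _LPS_TO_RAS @ np.asarray(img.GetOrigin())
    else:
        raise IOError(f"unknown format {fmt!r}")

    if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-4):
        raise ValueError(f"non-orthonormal direction matrix in {path}")
    # renormalize residual header rounding
    axes, _ = np.linalg.qr(axes)
    header_modality = modality or ("MRI" if fmt == "nifti" else "CT")
    return ImageVolume(data, spacing, origin, axes, header_modality)


def _read_dicom_series(directory: Path) -> sitk.Image:
    reader = sitk.ImageSeriesReader()
    ids = reader.GetGDCMSeriesIDs(str(directory))
    if len(ids) == 0:
        raise IOError(f"no DICOM series found in {directory}")
    if len(ids) > 1:
        raise IOError(
            f"directory {directory} contains mixed series UIDs: {', '.join(ids)}")
    files = reader.GetGDCMSeriesFileNames(str(directory), ids[0])
    reader.SetFileNames(files)
    return reader.Execute()


def write_volume(volume: ImageVolume, path) -> None:
    """Write NIfTI (.nii/.nii.gz) or NRRD, preserving geometry."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
        nib.save(img, str(path))
    elif name.endswith(".nrrd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.asarray(volume.data).transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(_LPS_TO_RAS @ volume.origin))
        img.SetDirection(tuple((_LPS_TO_RAS @ volume.axes).ravel()))
        sitk.WriteImage(img, str(path))
    else:
        raise IOError(f"unsupported output format: {path}")


def write_mask(mask: LabelMask, path) -> None:
    write_volume(ImageVolume(mask.data.astype(np.uint8), mask.spacing,
                             mask.origin, mask.axes, "CT"), path)


def read_mask(path, label: str, fmt: str = None) -> LabelMask:
    vol = read_volume(path, fmt)
    return LabelMask(vol.data > 0, vol.spacing, vol.origin, vol.axes, label)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def write_mesh(mesh, path, fmt: str = None) -> None:
    """Write a TriMeshModel as binary STL or PLY (PLY keeps vertex color)."""
    import trimesh

    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("stl", "ply"):
        raise IOError(f"unsupported mesh format {fmt!r}")
    tm = mesh.as_trimesh() if hasattr(mesh, "as_trimesh") else mesh
    if len(tm.vertices) == 0 or len(tm.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    if not tm.is_watertight:
        log.warning("mesh written to %s is not manifold/watertight", path)
    color = getattr(mesh, "color", None)
    if fmt == "ply" and color is not None:
        tm = trimesh.Trimesh(tm.vertices, tm.faces, process=False)
        tm.visual.vertex_colors = np.tile(
            np.asarray(color, dtype=np.uint8), (len(tm.vertices), 1))
    tm.export(str(path), file_type=fmt)


def read_mesh(path):
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    return tm


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def write_landmarks(landmarks: LandmarkSet, path) -> None:
    payload = {
        "frame": landmarks.frame,
        "points": [
            {"name": n, "x": float(p[0]), "y": float(p[1]), "z": float(p[2])}
            for n, p in zip(landmarks.names, landmarks.points)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_landmarks(path) -> LandmarkSet:
    payload = json.loads(Path(path).read_text())
    pts = payload["points"]
    if len(pts) < 3:
        raise ValueError(f"at least 3 landmarks required, file has {len(pts)}")
    names = [p["name"] for p in pts]
    coords = np.array([[p["x"], p["y"], p["z"]] for p in pts], dtype=float)
    return LandmarkSet(names, coords, payload.get("frame", "MRI"))


# ---------------------------------------------------------------------------
# lesion reports
# ---------------------------------------------------------------------------

def report_to_dict(report) -> dict:
    """Serialize a LesionReport (see :mod:`capfuse.lesion`) to plain JSON."""
    if report.icrs_class is not None and report.icrs_class not in VALID_ICRS:
        raise ValueError(f"unknown ICRS class {report.icrs_class!r}")
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "findings": [
            {
                "kind": f.kind,
                "areas": sorted(f.areas) if f.areas else [],
                "asd_subtype": f.asd_subtype,
                "ssb_underneath": bool(f.ssb_underneath),
            }
            for f in report.findings
        ],
        "ssb_present": bool(report.ssb_present),
        "vertical_diameter_mm": _opt(report.vertical_diameter_mm),
        "horizontal_diameter_mm": _opt(report.horizontal_diameter_mm),
        "stability": report.stability,
        "icrs_class": report.icrs_class,
        "recommended_procedure": report.recommended_procedure,
    }


def _opt(v):
    return None if v is None else float(v)


def write_report(report, path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2))


def read_report(path):
    from .lesion import Finding, LesionReport

    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema {d.get('schema_version')!r}")
    icrs = d.get("icrs_class")
    if icrs is not None and icrs not in VALID_ICRS:
        raise ValueError(f"unknown ICRS class {icrs!r}")
    findings = [
        Finding(kind=f["kind"], areas=set(f.get("areas") or []),
                asd_subtype=f.get("asd_subtype"),
                ssb_underneath=bool(f.get("ssb_underneath", False)))
        for f in d.get("findings", [])
    ]
    return LesionReport(
        findings=findings,
        ssb_present=bool(d.get("ssb_present", False)),
        vertical_diameter_mm=d.get("vertical_diameter_mm"),
        horizontal_diameter_mm=d.get("horizontal_diameter_mm"),
        stability=d.get("stability"),
        icrs_class=icrs,
        recommended_procedure=d.get("recommended_procedure"),
    )
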