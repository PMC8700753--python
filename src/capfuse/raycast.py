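"""Vectorized ray/segment vs triangle-mesh intersection (Moller-Trumbore).

Small, dependency-free kernel used by the drilling simulator and by
verification oracles. Meshes at this package's scale stay well below ~10^5
faces, so a broadcasted all-pairs test in ray chunks is fast enough
without a spatial index.
"""
from __future__ import annotations

import numpy as np

__all__ = ["ray_intersects", "segment_intersects"]

_EPS = 1e-12


def _hits(tri: np.ndarray, origins: np.ndarray, direction: np.ndarray,
          t_max: float | None):
    """Per-ray hit flags for a single shared direction."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = b - a
    e2 = c - a
    d = np.asarray(direction, dtype=float)
    p = np.cross(d, e2)                       # (F, 3)
    det = np.einsum("fj,fj->f", e1, p)        # (F,)
    ok = np.abs(det) > _EPS
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    hit_any = np.zeros(len(origins), dtype=bool)
    for i, o in enumerate(origins):
        s = o - a                             # (F, 3)
        u = np.einsum("fj,fj->f", s, p) * inv
        q = np.cross(s, e1)
        v = np.einsum("j,fj->f", d, q) * inv
        t = np.einsum("fj,fj->f", e2, q) * inv
        m = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t >= -1e-9)
        if t_max is not None:
            m &= t <= t_max + 1e-9
        hit_any[i] = bool(m.any())
    return hit_any


def ray_intersects(vertices: np.ndarray, faces: np.ndarray,
                   origins: np.ndarray, direction: np.ndarray,
                   t_max: float | None = None) -> np.ndarray:
    """True per origin when the ray ``origin + t * direction`` (t >= 0,
    optionally t <= t_max) meets the mesh."""
    tri = np.asarray(vertices, dtype=float)[np.asarray(faces, dtype=int)]
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    return _hits(tri, origins, direction, t_max)


def segment_intersects(vertices: np.ndarray, faces: np.ndarray,
                       start, end) -> bool:
    """True when the closed segment start->end meets the mesh."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    vec = end - start
    length = np.linalg.norm(vec)
    if length <= _EPS:
        return False
    return bool(ray_intersects(vertices, faces, start[None], vec / length,
                               t_max=length)[0])
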