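"""Planes, frames and small vector helpers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-15:
        raise ValueError("cannot normalize a zero-length vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.origin) @ self.normal

    def project(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.signed_distance(points)
        return np.squeeze(points - d[..., None] * self.normal)

    def reflect(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        d = self.signed_distance(points)
        return points - 2.0 * d[..., None] * self.normal

    @staticmethod
    def from_points(a, b, c) -> "Plane":
        a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
        n = np.cross(b - a, c - a)
        if np.linalg.norm(n) < 1e-12:
            raise ValueError("the three points are collinear; plane undefined")
        return Plane(a, n)


def plane_plane_line(a: Plane, b: Plane, eps: float = 1e-6):
    """Intersection line of two planes as ``(point, unit direction)``."""
    d = np.cross(a.normal, b.normal)
    nd = np.linalg.norm(d)
    if nd < eps:
        raise ValueError("planes are parallel; intersection line undefined")
    d = d / nd
    # point solving both plane equations with minimum norm offset
    A = np.stack([a.normal, b.normal])
    rhs = np.array([a.normal @ a.origin, b.normal @ b.origin])
    p, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return p, d


def rotation_between(a, b) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b."""
    a, b = unit(a), unit(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis perpendicular to a
        axis = unit(np.cross(a, [1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.cross(a, [0.0, 1.0, 0.0]))
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
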