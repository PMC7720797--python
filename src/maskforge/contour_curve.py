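"""The closed seal-line curve through the six control points.

A periodic cubic spline interpolates C1..C6 in cyclic order and is sampled
into a dense polyline; the polyline is then attached to the face surface
by iterated closest-point projection with light Laplacian smoothing in
between (the six control-point samples stay pinned).  The attached curve
is the base of the mask and the line along which the seal rim meets the
skin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline

from .reference_geometry import AnatomicalFrame, ControlPointSet
from .spatial import MeshQuery


class CurveError(ValueError):
    pass


@dataclass
class SampledCurve:
    """A closed polyline sampled from a periodic spline.

    ``pinned`` are sample indices that coincide exactly with the
    interpolation knots (the control points).
    """

    points: np.ndarray
    pinned: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    knot_params: np.ndarray | None = None
    spline: object | None = None

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class SurfaceCurve:
    """A closed polyline whose every sample lies on the host mesh surface."""

    points: np.ndarray
    pinned: np.ndarray
    host: trimesh.Trimesh

    ON_SURFACE_TOL = 0.1  # mm
    MAX_SPACING = 5.0  # mm

    @property
    def n(self) -> int:
        return len(self.points)

    def arc_length(self) -> float:
        return float(
            np.linalg.norm(self.points - np.roll(self.points, -1, axis=0), axis=1).sum()
        )

    def validate(self, frame: AnatomicalFrame | None = None,
                 query: MeshQuery | None = None):
        """Assert the surface-curve invariants; raise CurveError otherwise."""
        q = query or MeshQuery(self.host)
        _, dist, _ = q.closest_point(self.points)
        if dist.max() > self.ON_SURFACE_TOL:
            raise CurveError(
                f"curve leaves the surface by {dist.max():.3f} mm "
                f"(limit {self.ON_SURFACE_TOL} mm)"
            )
        spacing = np.linalg.norm(self.points - np.roll(self.points, -1, axis=0), axis=1)
        if spacing.max() >= self.MAX_SPACING:
            raise CurveError(
                f"consecutive samples {spacing.max():.2f} mm apart "
                f"(limit {self.MAX_SPACING} mm); increase the sample count"
            )
        if frame is not None:
            # no self-intersection in the anterior-view projection
            from shapely.geometry import LinearRing

            u = np.cross(frame.superior, frame.anterior)
            uv = np.column_stack([self.points @ u, self.points @ frame.superior])
            if not LinearRing(uv).is_simple:
                raise CurveError("curve self-intersects in the anterior view")


def fit_closed_spline(control_points, n: int = 200) -> SampledCurve:
    """Periodic cubic spline through the control points, densely sampled.

    Chord-length parameterization; the n samples are distributed over the
    six spline segments proportionally to parameter length, and every
    control point appears exactly as one sample (recorded in ``pinned``).
    """
    if isinstance(control_points, ControlPointSet):
        pts = control_points.as_array()
    else:
        pts = np.asarray(control_points, dtype=float)
    if len(np.unique(np.round(pts, 9), axis=0)) < 3:
        raise CurveError("need at least 3 distinct points for a closed spline")
    if n < 60:
        raise CurveError("sample count must be >= 60")

    closed = np.vstack([pts, pts[:1]])
    chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if chord.min() < 1e-12:
        raise CurveError("repeated consecutive control points")
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, closed, bc_type="periodic")

    # allocate samples per segment, keeping the knots themselves
    total = t[-1]
    counts = np.maximum(1, np.round(n * chord / total).astype(int))
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n:
        counts[np.argmin(counts)] += 1
    params = []
    pinned = []
    pos = 0
    for i, c in enumerate(counts):
        seg = np.linspace(t[i], t[i + 1], c + 1)[:-1]
        pinned.append(pos)
        params.append(seg)
        pos += c
    params = np.concatenate(params)
    return SampledCurve(
        points=spline(params),
        pinned=np.asarray(pinned, dtype=int),
        knot_params=t,
        spline=spline,
    )


def attach_to_surface(curve: SampledCurve, mesh: trimesh.Trimesh,
                      tol: float = 0.05, max_iter: int = 10,
                      max_leave_mm: float = 20.0,
                      frame: AnatomicalFrame | None = None) -> SurfaceCurve:
    """Constrain the sampled curve to lie on the face surface.

    Each iteration projects every sample to its closest surface point and
    then applies one Laplacian smoothing pass (pinned control-point
    samples excepted) to suppress projection zigzag on coarse meshes;
    iteration stops when the projection displacement falls below ``tol``.
    A final projection leaves every sample on the surface.
    """
    pts = np.array(curve.points, dtype=float)
    pinned = np.asarray(curve.pinned, dtype=int)
    query = MeshQuery(mesh)

    free = np.ones(len(pts), dtype=bool)
    free[pinned] = False

    for _ in range(max_iter):
        proj, dist, _ = query.closest_point(pts)
        if dist.max() > max_leave_mm:
            raise CurveError(
                f"curve sample drifted {dist.max():.1f} mm from the surface "
                f"(limit {max_leave_mm} mm); the curve left the face"
            )
        moved = dist.max()
        pts = proj
        if moved < tol:
            break
        smoothed = 0.5 * pts + 0.25 * (np.roll(pts, 1, axis=0) + np.roll(pts, -1, axis=0))
        pts[free] = smoothed[free]
    proj, _, _ = query.closest_point(pts)
    out = SurfaceCurve(points=proj, pinned=pinned, host=mesh)
    out.validate(frame=frame, query=query)
    return out
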