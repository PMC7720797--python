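"""Reference planes, anatomical frame and control points from the landmarks.

Nine planes are constructed from the nine landmarks:

* MF — midface (midsagittal) plane through Ra, Ntp, Pg;
* VP — vertical (coronal) plane through the lateral canthi, perpendicular
  to MF;
* HP — horizontal plane through Ra, perpendicular to MF and VP;
* LHP / CHP — horizontal planes through Pc / Pg, parallel to HP;
* HLCP / HRCP — cheek planes through Ex(l) / Ex(r), parallel to MF;
* CLP / CRP — chin planes through the canthus midpoints, parallel to MF.

The literal "plane through Ex(l), Ex(r) and perpendicular to MF" is
ill-conditioned whenever the two canthi are (nearly) mirror images of each
other — the canthus segment is then (nearly) parallel to the MF normal
and every plane through it is perpendicular to MF.  VP is therefore built
in a regularized form: it passes through the canthus midpoint with normal
``n_MF x v``, where ``v`` is the in-MF unit vector from the menton to the
radix (the facial "up").  For a mirror-symmetric canthus pair this plane
contains both canthi exactly; otherwise the residual is bounded by the
anatomical asymmetry of the canthi, which is validated to stay small.

The six control points C1..C6 then come from Table-style rules: C1 = Ra,
C4 = M, and C2/C3/C5/C6 are the intersections of one cheek/chin plane
with one horizontal plane and the face surface, taking the anterior-most
surface crossing (the mask seal runs on the facial front; posterior
crossings are scan-edge artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import trimesh

from .geometry import Plane, plane_plane_line, unit
from .io_formats import LandmarkSet
from .spatial import MeshQuery

PLANE_NAMES = ("MF", "VP", "HP", "LHP", "CHP", "HLCP", "HRCP", "CLP", "CRP")

#: largest tolerated distance of a canthus from the regularized VP (mm);
#: larger values mean the canthi asymmetry is anatomically implausible
MAX_CANTHUS_VP_RESIDUAL = 10.0


class GeometryError(ValueError):
    """Raised when a construction of the reference geometry is degenerate."""


@dataclass(frozen=True)
class PlaneSet:
    MF: Plane
    VP: Plane
    HP: Plane
    LHP: Plane
    CHP: Plane
    HLCP: Plane
    HRCP: Plane
    CLP: Plane
    CRP: Plane

    def __getitem__(self, name: str) -> Plane:
        if name not in PLANE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def items(self):
        return [(f.name, getattr(self, f.name)) for f in fields(self)]


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal triad (lateral_left, superior, anterior).

    Disambiguates signed directions such as "translated anteriorly".
    Origin at the radix.
    """

    anterior: np.ndarray
    superior: np.ndarray
    lateral_left: np.ndarray
    origin: np.ndarray


@dataclass(frozen=True)
class ControlPointSet:
    """The six seal-line control points in fixed cyclic order.

    C1 = Ra (radix), C2 right cheek, C3 right chin, C4 = M (menton),
    C5 left chin, C6 left cheek.
    """

    C1: np.ndarray
    C2: np.ndarray
    C3: np.ndarray
    C4: np.ndarray
    C5: np.ndarray
    C6: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.stack([self.C1, self.C2, self.C3, self.C4, self.C5, self.C6])

    def __post_init__(self):
        pts = self.as_array()
        d = np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1)
        if d.min() <= 5.0:
            raise GeometryError(
                f"consecutive control points closer than 5 mm (min {d.min():.2f} mm)"
            )


def compute_planes(landmarks: LandmarkSet) -> PlaneSet:
    """Construct the nine reference planes with fixed anatomical signs.

    The MF normal and the MF-parallel family point toward the anatomical
    left; HP and its parallels point superior; VP points anterior.
    """
    lm = landmarks
    n_mf = np.cross(lm.Ntp - lm.Ra, lm.Pg - lm.Ra)
    if np.linalg.norm(n_mf) < 1e-9:
        raise GeometryError("Ra, Ntp, Pg collinear; MF plane undefined")
    n_mf = unit(n_mf)

    # facial "up" within MF: menton -> radix
    v = lm.Ra - lm.M
    v = v - (v @ n_mf) * n_mf
    if np.linalg.norm(v) < 1e-6:
        raise GeometryError("Ra - M is parallel to the MF normal; frame undefined")
    v = unit(v)

    # anterior proxy within MF, orthogonal to up: nasal tip vs landmark centroid
    w = lm.Ntp - lm.as_array().mean(axis=0)
    w = w - (w @ n_mf) * n_mf - (w @ v) * v
    if np.linalg.norm(w) < 1e-6:
        raise GeometryError("cannot orient the anterior direction from landmarks")
    anterior = unit(w)
    # MF normal (and the whole MF-parallel family) points toward the
    # anatomical left, i.e. toward the Ex(l) side
    if n_mf @ (lm.Ex_l - lm.Ex_r) < 0:
        n_mf = -n_mf

    mid = 0.5 * (lm.Ex_l + lm.Ex_r)
    n_vp = unit(np.cross(n_mf, v))
    if n_vp @ anterior < 0:
        n_vp = -n_vp
    vp = Plane(mid, n_vp)
    res = max(abs(vp.signed_distance(lm.Ex_l)), abs(vp.signed_distance(lm.Ex_r)))
    if res > MAX_CANTHUS_VP_RESIDUAL:
        raise GeometryError(
            f"lateral canthi lie {res:.1f} mm from the vertical plane; "
            "canthus asymmetry too large for the VP construction"
        )

    return PlaneSet(
        MF=Plane(lm.Ra, n_mf),
        VP=vp,
        HP=Plane(lm.Ra, v),
        LHP=Plane(lm.Pc, v),
        CHP=Plane(lm.Pg, v),
        HLCP=Plane(lm.Ex_l, n_mf),
        HRCP=Plane(lm.Ex_r, n_mf),
        CLP=Plane(0.5 * (lm.Ex_l + lm.En_l), n_mf),
        CRP=Plane(0.5 * (lm.Ex_r + lm.En_r), n_mf),
    )


def build_frame(planes: PlaneSet, landmarks: LandmarkSet,
                mesh: trimesh.Trimesh) -> AnatomicalFrame:
    """Sign the plane normals into an anatomical frame.

    The anterior axis is the VP normal signed so it points from the mesh
    centroid toward the nasal tip; superior is the HP normal signed from
    the menton toward the radix.
    """
    centroid = mesh.vertices.mean(axis=0)
    ant = planes.VP.normal.copy()
    s = (landmarks.Ntp - centroid) @ ant
    if abs(s) < 1e-6:
        raise GeometryError("nasal tip coincides with the mesh centroid; "
                            "anterior sign undecidable")
    if s < 0:
        ant = -ant
    sup = planes.HP.normal.copy()
    if (landmarks.Ra - landmarks.M) @ sup < 0:
        sup = -sup
    # lateral axis points toward the anatomical left (the Ex(l) side);
    # it equals +-MF normal since anterior and superior span the MF plane
    left = planes.MF.normal.copy()
    if left @ (landmarks.Ex_l - landmarks.Ex_r) < 0:
        left = -left
    return AnatomicalFrame(anterior=ant, superior=sup, lateral_left=left,
                           origin=landmarks.Ra.copy())


def plane_pair_surface_point(a: Plane, b: Plane, mesh, frame: AnatomicalFrame,
                             names: tuple = ("a", "b")) -> np.ndarray:
    """Anterior-most point where the line ``a ∩ b`` crosses the face surface.

    ``mesh`` may be a trimesh or a prebuilt :class:`MeshQuery`.
    """
    query = mesh if isinstance(mesh, MeshQuery) else MeshQuery(mesh)
    try:
        p0, d = plane_plane_line(a, b)
    except ValueError as exc:
        raise GeometryError(f"planes {names[0]} and {names[1]}: {exc}") from exc
    _, pts, _ = query.line_hits(p0, d)
    if len(pts) == 0:
        raise GeometryError(
            f"intersection line of planes {names[0]} and {names[1]} misses the face surface"
        )
    return pts[np.argmax(pts @ frame.anterior)]


def compute_control_points(landmarks: LandmarkSet, planes: PlaneSet,
                           mesh: trimesh.Trimesh,
                           frame: AnatomicalFrame) -> ControlPointSet:
    """Derive the six seal-line control points."""
    query = MeshQuery(mesh)

    def surf(pa: str, pb: str, label: str):
        try:
            return plane_pair_surface_point(planes[pa], planes[pb], query,
                                            frame, names=(pa, pb))
        except GeometryError as exc:
            raise GeometryError(f"control point {label}: {exc}") from exc

    return ControlPointSet(
        C1=landmarks.Ra.copy(),
        C2=surf("HRCP", "LHP", "C2"),
        C3=surf("CRP", "CHP", "C3"),
        C4=landmarks.M.copy(),
        C5=surf("CLP", "CHP", "C5"),
        C6=surf("HLCP", "LHP", "C6"),
    )


def export_debug_overlay(planes: PlaneSet, control_points: ControlPointSet, path):
    """Write planes and control points as a JSON overlay for inspection."""
    import json
    from pathlib import Path

    obj = {
        "planes": {
            name: {"origin": plane.origin.tolist(), "normal": plane.normal.tolist()}
            for name, plane in planes.items()
        },
        "control_points": {
            f"C{i + 1}": p.tolist() for i, p in enumerate(control_points.as_array())
        },
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
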