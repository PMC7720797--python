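"""Reading face scans and landmark files; writing STL parts and the build report.

All geometry is in millimetres.  Units are never auto-detected: a face scan
in metres fails the landmark-proximity validation loudly rather than being
silently rescaled.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import trimesh

from .spatial import MeshQuery

#: canonical landmark identifiers in fixed order
LANDMARK_NAMES = ("Ex_r", "En_r", "Ra", "En_l", "Ex_l", "Ntp", "Pc", "Pg", "M")

#: file-facing aliases (clinical notation) -> canonical identifiers
LANDMARK_ALIASES = {
    "Ex(r)": "Ex_r",
    "En(r)": "En_r",
    "En(l)": "En_l",
    "Ex(l)": "Ex_l",
}
_CANONICAL_TO_ALIAS = {v: k for k, v in LANDMARK_ALIASES.items()}


class LandmarkError(ValueError):
    """Raised when a landmark file violates the nine-landmark schema."""


class MeshFormatError(ValueError):
    """Raised when a mesh file violates the structural contract."""


@dataclass(frozen=True)
class LandmarkSet:
    """The nine facial soft-tissue landmarks driving the mask design.

    Ex/En are the lateral/medial canthi (eye corners, right and left),
    Ra the radix, Ntp the nasal tip, Pc the philtral crest, Pg the
    pogonion and M the menton.  Coordinates are millimetres.
    """

    points: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = {}
        for name in LANDMARK_NAMES:
            if name not in self.points:
                raise LandmarkError(f"missing landmark: {name}")
            p = np.asarray(self.points[name], dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise LandmarkError(f"landmark {name} is not a finite 3D point")
            pts[name] = p
        extra = set(self.points) - set(LANDMARK_NAMES)
        if extra:
            raise LandmarkError(f"unknown landmark name(s): {sorted(extra)}")
        object.__setattr__(self, "points", pts)
        # midsagittal triangle must be non-degenerate
        area = 0.5 * np.linalg.norm(
            np.cross(pts["Ntp"] - pts["Ra"], pts["Pg"] - pts["Ra"])
        )
        if area <= 1.0:
            raise LandmarkError(
                f"Ra, Ntp, Pg are (near-)collinear (triangle area {area:.3g} mm^2 <= 1);"
                " the midface plane is undefined"
            )
        if np.linalg.norm(pts["Ex_l"] - pts["Ex_r"]) < 1e-9:
            raise LandmarkError("Ex_l and Ex_r coincide")

    def __getattr__(self, name):
        pts = object.__getattribute__(self, "points")
        if name in pts:
            return pts[name]
        raise AttributeError(name)

    def __getitem__(self, name):
        return self.points[name]

    def as_array(self) -> np.ndarray:
        """(9, 3) array in canonical landmark order."""
        return np.stack([self.points[n] for n in LANDMARK_NAMES])

    def transformed(self, fn) -> "LandmarkSet":
        """New set with ``fn`` applied to every point."""
        return LandmarkSet({n: np.asarray(fn(p), dtype=float) for n, p in self.points.items()})

    def validate_on_surface(self, mesh: trimesh.Trimesh, max_dist_mm: float = 5.0):
        """Require every landmark to lie within ``max_dist_mm`` of the mesh."""
        q = MeshQuery(mesh)
        _, dist, _ = q.closest_point(self.as_array())
        for name, d in zip(LANDMARK_NAMES, dist):
            if d > max_dist_mm:
                raise LandmarkError(
                    f"landmark {name} lies {d:.2f} mm off the face surface"
                    f" (limit {max_dist_mm} mm); check units (mm expected)"
                )


def _canonical_name(raw: str) -> str:
    name = raw.strip()
    name = LANDMARK_ALIASES.get(name, name)
    if name not in LANDMARK_NAMES:
        raise LandmarkError(f"unknown landmark name: {raw!r}")
    return name


def read_landmarks(path, mesh: trimesh.Trimesh | None = None) -> LandmarkSet:
    """Read landmarks from JSON ``{"Ra": [x,y,z], ...}`` or CSV ``name,x,y,z``.

    Clinical aliases like ``Ex(r)`` are accepted.  If ``mesh`` is given the
    landmarks are additionally validated to lie within 5 mm of its surface.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw: dict[str, list] = {}
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        data = json.loads(text)
        if not isinstance(data, dict):
            raise LandmarkError("landmark JSON must be an object of name -> [x, y, z]")
        items = data.items()
    else:
        rows = [r for r in csv.reader(text.splitlines()) if r and any(c.strip() for c in r)]
        if rows and rows[0] and rows[0][1].strip().lower() in ("x", "y", "z"):
            rows = rows[1:]  # tolerate a header line
        items = [(r[0], [float(r[1]), float(r[2]), float(r[3])]) for r in rows]
    for name, xyz in items:
        canon = _canonical_name(name)
        if canon in raw:
            raise LandmarkError(f"duplicate landmark: {name}")
        raw[canon] = xyz
    lm = LandmarkSet(raw)
    if mesh is not None:
        lm.validate_on_surface(mesh)
    return lm


def write_landmarks(landmarks: LandmarkSet, path):
    """Write landmarks as JSON using the clinical alias names."""
    path = Path(path)
    out = {
        _CANONICAL_TO_ALIAS.get(n, n): [float(c) for c in landmarks[n]]
        for n in LANDMARK_NAMES
    }
    path.write_text(json.dumps(out, indent=2) + "\n")


# ----------------------------------------------------------------------
# meshes
# ----------------------------------------------------------------------

def boundary_edge_count(mesh: trimesh.Trimesh) -> int:
    """Number of edges referenced by exactly one face."""
    if len(mesh.faces) == 0:
        return 0
    edges = mesh.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts == 1).sum())


def nonmanifold_edge_count(mesh: trimesh.Trimesh) -> int:
    """Number of edges shared by more than two faces."""
    if len(mesh.faces) == 0:
        return 0
    _, counts = np.unique(mesh.edges_sorted, axis=0, return_counts=True)
    return int((counts > 2).sum())


def read_face_mesh(path, max_nonmanifold_edges: int = 0) -> trimesh.Trimesh:
    """Load a face scan from OBJ (polygons fan-triangulated, mm units).

    Unreferenced vertices and degenerate (area < 1e-9 mm^2) triangles are
    dropped.  An edge-manifold open shell is expected; meshes with more
    than ``max_nonmanifold_edges`` over-shared edges are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mesh = trimesh.load(str(path), file_type="obj", force="mesh", process=False)
    mesh = trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=int),
        process=False,
    )
    keep = mesh.area_faces > 1e-9
    mesh.update_faces(keep)
    mesh.remove_unreferenced_vertices()
    nm = nonmanifold_edge_count(mesh)
    if nm > max_nonmanifold_edges:
        raise MeshFormatError(
            f"mesh has {nm} non-manifold edges (limit {max_nonmanifold_edges})"
        )
    mesh.metadata["name"] = path.stem
    return mesh


def write_obj(mesh: trimesh.Trimesh, path):
    """Write an OBJ at full float precision (round-trips to 1e-6 mm)."""
    path = Path(path)
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def write_stl(mesh: trimesh.Trimesh, path, printable: bool = True):
    """Write a binary little-endian STL.

    A printable component must be watertight; an open shell is refused
    with a boundary-edge diagnostic.
    """
    path = Path(path)
    if printable:
        nb = boundary_edge_count(mesh)
        if nb > 0:
            raise MeshFormatError(
                f"refusing to write non-watertight printable component "
                f"{path.name}: {nb} boundary edges"
            )
    data = mesh.export(file_type="stl")  # binary by default
    path.write_bytes(data)


def read_stl(path) -> trimesh.Trimesh:
    # STL stores a triangle soup; merging duplicate vertices restores the
    # connectivity that watertightness checks need
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return trimesh.load(str(path), file_type="stl", force="mesh", process=True)


# ----------------------------------------------------------------------
# build manifest
# ----------------------------------------------------------------------

@dataclass
class MaskBuildManifest:
    """Machine-readable record of one mask build: parts, order and metrics."""

    components: dict  # component name -> STL path (str)
    metrics: dict  # metric name -> float/int
    assembly_order: list
    config: dict
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def to_json(self, path=None) -> str:
        obj = {
            "components": {k: str(v) for k, v in self.components.items()},
            "metrics": self.metrics,
            "assembly_order": list(self.assembly_order),
            "config": self.config,
            "timestamp": self.timestamp,
        }
        text = json.dumps(obj, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(path) -> "MaskBuildManifest":
        obj = json.loads(Path(path).read_text())
        return MaskBuildManifest(
            components=obj["components"],
            metrics=obj["metrics"],
            assembly_order=obj["assembly_order"],
            config=obj["config"],
            timestamp=obj.get("timestamp", ""),
        )

    def validate(self):
        """Check files exist and parse as STL; metrics finite and positive."""
        problems = []
        for name, p in self.components.items():
            p = Path(p)
            if not p.exists():
                problems.append(f"{name}: missing file {p}")
                continue
            try:
                read_stl(p)
            except Exception as exc:  # noqa: BLE001 - report, do not mask
                problems.append(f"{name}: unreadable STL ({exc})")
        for key, val in self.metrics.items():
            if isinstance(val, (int, float)) and not (np.isfinite(val) and val > 0):
                problems.append(f"metric {key} not finite/positive: {val}")
        return problems
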