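"""Building the mask solid: lofts, shell, soft rim and strap anchors.

The mask body is built CAD-style from three closed profile curves — the
surface-attached base curve, an anteriorly translated copy of it (which
creates the clearance over the nasal dorsum), and the circular filter-port
boundary — joined by ruled loft surfaces, shelled to a fixed wall
thickness, and completed with a swept soft seal rim and four strap-anchor
tabs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import trimesh

from . import voxels
from .contour_curve import SampledCurve, SurfaceCurve
from .geometry import Plane, rotation_between, unit
from .io_formats import LandmarkSet, boundary_edge_count
from .reference_geometry import AnatomicalFrame, GeometryError, PlaneSet
from .spatial import MeshQuery, ensure_outward

log = logging.getLogger(__name__)


class BuildError(RuntimeError):
    pass


@dataclass(frozen=True)
class DesignConfig:
    """Tunable design constants (lengths in mm).

    The defaults are the published design values: filter base 20 mm
    anterior of the nasal tip, a 2 mm shell, and a translated curve at
    half the radix-to-nasal-tip distance.
    """

    filter_standoff_mm: float = 20.0
    shell_thickness_mm: float = 2.0
    translation_ratio: float = 0.5
    rim_tube_radius_mm: float = 3.0
    filter_opening_radius_mm: float = 30.0
    n_samples: int = 200
    connection_positions: tuple = (0.26, 0.375, 0.625, 0.74)
    rim_sections: int = 32
    voxel_pitch_mm: float = 0.5
    tab_outer_mm: tuple = (16.0, 12.0)
    tab_bar_mm: float = 3.5
    tab_depth_mm: float = 3.0

    def __post_init__(self):
        for name in ("filter_standoff_mm", "shell_thickness_mm",
                     "rim_tube_radius_mm", "filter_opening_radius_mm",
                     "voxel_pitch_mm", "tab_bar_mm", "tab_depth_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.translation_ratio <= 1.0:
            raise ValueError("translation_ratio must be in (0, 1]")
        if len(self.connection_positions) != 4:
            raise ValueError("exactly 4 connection positions required")
        if len(set(self.connection_positions)) != 4:
            raise ValueError("connection positions must be distinct")
        object.__setattr__(self, "connection_positions",
                           tuple(float(p) % 1.0 for p in self.connection_positions))
        object.__setattr__(self, "tab_outer_mm", tuple(self.tab_outer_mm))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["connection_positions"] = list(self.connection_positions)
        d["tab_outer_mm"] = list(self.tab_outer_mm)
        return d

    @staticmethod
    def from_dict(d: dict) -> "DesignConfig":
        d = dict(d)
        if "connection_positions" in d:
            d["connection_positions"] = tuple(d["connection_positions"])
        if "tab_outer_mm" in d:
            d["tab_outer_mm"] = tuple(d["tab_outer_mm"])
        return DesignConfig(**d)

    @staticmethod
    def from_yaml(path) -> "DesignConfig":
        import yaml
        from pathlib import Path

        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("design config must be a mapping")
        return DesignConfig.from_dict(data)


@dataclass(frozen=True)
class FilterBase:
    """Placement of the filter port: a circle on a VP-parallel plane."""

    plane: Plane
    center: np.ndarray
    boundary: np.ndarray  # (n, 3) closed circle polyline
    port: trimesh.Trimesh  # collar solid around the opening


# ----------------------------------------------------------------------
# curves
# ----------------------------------------------------------------------

def translate_curve(base: SurfaceCurve, landmarks: LandmarkSet,
                    frame: AnatomicalFrame, ratio: float = 0.5) -> SampledCurve:
    """Rigidly translate the base curve anteriorly by ratio * |Ra - Ntp|."""
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must be in (0, 1]")
    d = float(np.linalg.norm(landmarks.Ra - landmarks.Ntp))
    if d < 1e-9:
        raise GeometryError("Ra and Ntp coincide; translation distance undefined")
    offset = ratio * d * frame.anterior
    return SampledCurve(points=base.points + offset, pinned=base.pinned.copy())


def place_filter_base(landmarks: LandmarkSet, planes: PlaneSet,
                      frame: AnatomicalFrame, config: DesignConfig) -> FilterBase:
    """Filter-port circle on the plane parallel to VP, ``standoff`` mm
    anterior of the nasal tip."""
    center = landmarks.Ntp + config.filter_standoff_mm * frame.anterior
    normal = planes.VP.normal.copy()
    if normal @ frame.anterior < 0:
        normal = -normal
    plane = Plane(center, normal)
    u = frame.superior - (frame.superior @ normal) * normal
    u = unit(u)
    v = np.cross(normal, u)
    theta = np.linspace(0.0, 2.0 * np.pi, config.n_samples, endpoint=False)
    r = config.filter_opening_radius_mm
    boundary = center + r * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)

    collar = trimesh.creation.annulus(r_min=r, r_max=r + 3.0, height=6.0, sections=64)
    T = np.eye(4)
    T[:3, :3] = rotation_between(np.array([0.0, 0.0, 1.0]), normal)
    T[:3, 3] = center
    collar.apply_transform(T)
    return FilterBase(plane=plane, center=center, boundary=boundary, port=collar)


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points at uniform arc length."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    closed = np.vstack([pts, pts[:1]])
    target = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(target, s, closed[:, k])
    return out


# ----------------------------------------------------------------------
# loft
# ----------------------------------------------------------------------

def _loop_normal_sign(loop: np.ndarray, axis: np.ndarray) -> float:
    """Sign of the loop's winding about ``axis`` (projected signed area)."""
    axis = unit(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(axis, ref))
    v = np.cross(axis, u)
    c = loop.mean(axis=0)
    x = (loop - c) @ u
    y = (loop - c) @ v
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(np.sign(area))


def _align_loops(a: np.ndarray, b: np.ndarray):
    """Match winding and seam of loop b to loop a (returns adjusted b)."""
    axis = b.mean(axis=0) - a.mean(axis=0)
    if np.linalg.norm(axis) < 1e-9:
        # coplanar-ish loops: use the mean cross product as axis
        axis = np.cross(np.roll(a, -1, axis=0) - a, np.roll(a, 1, axis=0) - a).sum(axis=0)
    if _loop_normal_sign(a, axis) != _loop_normal_sign(b, axis):
        b = b[::-1]
        log.info("loft: reversed second profile to match winding")
    n = len(a)
    # circular shift minimizing total rail length
    costs = np.array([np.linalg.norm(a - np.roll(b, -k, axis=0), axis=1).sum()
                      for k in range(n)])
    return np.roll(b, -int(costs.argmin()), axis=0)


def loft(curve_a, curve_b) -> trimesh.Trimesh:
    """Ruled surface between two closed curves with equal sample counts.

    Produces a strip of 2n triangles whose boundary edges reproduce the
    two input polylines exactly.
    """
    a = curve_a.points if hasattr(curve_a, "points") else np.asarray(curve_a, float)
    b = curve_b.points if hasattr(curve_b, "points") else np.asarray(curve_b, float)
    if len(a) != len(b):
        raise BuildError(f"loft profiles have {len(a)} vs {len(b)} samples")
    if np.abs(a - b).max() < 1e-9:
        raise BuildError("loft profiles coincide; degenerate zero-area strip")
    b = _align_loops(a, b)
    n = len(a)
    i = np.arange(n)
    j = (i + 1) % n
    faces = np.concatenate([
        np.column_stack([i, n + i, n + j]),
        np.column_stack([i, n + j, j]),
    ])
    mesh = trimesh.Trimesh(vertices=np.vstack([a, b]), faces=faces, process=False)
    return mesh


def _face_normals(vertices: np.ndarray, faces: np.ndarray, normalized=True):
    tri = vertices[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    if normalized:
        ln = np.linalg.norm(n, axis=1)
        ln[ln == 0] = 1.0
        n = n / ln[:, None]
    return n


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray,
                    smoothing_passes: int = 0) -> np.ndarray:
    """Area-weighted averaged vertex normals (computed from scratch; the
    trimesh caches can go stale across winding repairs).

    Optional 1-ring averaging passes regularize the normal field so a
    normal offset of a noisy surface does not fold over locally.
    """
    fn = _face_normals(vertices, faces, normalized=False)
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    for _ in range(smoothing_passes):
        acc = np.zeros_like(vn)
        cnt = np.zeros(len(vertices))
        edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        np.add.at(acc, edges[:, 0], vn[edges[:, 1]])
        np.add.at(cnt, edges[:, 0], 1.0)
        cnt[cnt == 0] = 1.0
        vn = 0.5 * vn + 0.5 * acc / cnt[:, None]
    ln = np.linalg.norm(vn, axis=1)
    ln[ln == 0] = 1.0
    return vn / ln[:, None]


def _orient_outward(mesh: trimesh.Trimesh, axis_points: np.ndarray) -> trimesh.Trimesh:
    """Flip the whole surface if its normals face the loft axis.

    Rebuilds the mesh after the winding repair: trimesh caches normals
    and a repair + invert sequence can leave them inconsistent.
    """
    trimesh.repair.fix_winding(mesh)
    vertices = mesh.vertices.view(np.ndarray).copy()
    faces = mesh.faces.view(np.ndarray).copy()
    normals = _face_normals(vertices, faces)
    centers = vertices[faces].mean(axis=1)
    # nearest point on the axis polyline for each face center
    best_d = None
    best_q = None
    for p0, p1 in zip(axis_points[:-1], axis_points[1:]):
        d = p1 - p0
        t = np.clip(((centers - p0) @ d) / (d @ d), 0.0, 1.0)
        q = p0 + t[:, None] * d
        dist = np.linalg.norm(centers - q, axis=1)
        if best_d is None:
            best_d, best_q = dist, q
        else:
            closer = dist < best_d
            best_d[closer] = dist[closer]
            best_q[closer] = q[closer]
    outward = centers - best_q
    if np.einsum("ij,ij->i", normals, outward).sum() < 0:
        faces = faces[:, ::-1]
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def build_mask_surface(base: SurfaceCurve, translated: SampledCurve,
                       filter_base: FilterBase,
                       max_edge: float = 3.0) -> trimesh.Trimesh:
    """Stitched loft chain base -> translated -> filter circle.

    Open tube surface with exactly two boundary loops (the face seal line
    and the filter opening), oriented with normals outward.  Interior
    rings keep the triangulation near-isotropic (edge length about
    ``max_edge``) so the later normal-offset shelling is well behaved;
    the two boundary polylines are reproduced exactly.
    """
    a = np.asarray(base.points, float)
    b = np.asarray(translated.points, float)
    c = np.asarray(filter_base.boundary, float)
    n = len(a)
    if len(b) != n or len(c) != n:
        raise BuildError("all three profiles must share the sample count")
    b = _align_loops(a, b)
    c = _align_loops(b, c)

    rings = [a]
    for lo, hi in ((a, b), (b, c)):
        rail = np.linalg.norm(hi - lo, axis=1).max()
        k = max(1, int(np.ceil(rail / max_edge)))
        for t in np.linspace(0.0, 1.0, k + 1)[1:]:
            rings.append(lo + t * (hi - lo))
    nr = len(rings)
    i = np.arange(n)
    j = (i + 1) % n
    strips = []
    for r in range(nr - 1):
        off = r * n
        strips.append(np.column_stack([off + i, off + n + i, off + n + j]))
        strips.append(np.column_stack([off + i, off + n + j, off + j]))
    mesh = trimesh.Trimesh(vertices=np.vstack(rings),
                           faces=np.concatenate(strips), process=False)
    if boundary_edge_count(mesh) != 2 * n:
        raise BuildError("stitching failed: unmatched seam vertices")
    axis = np.stack([a.mean(axis=0), b.mean(axis=0), c.mean(axis=0)])
    return _orient_outward(mesh, axis)


# ----------------------------------------------------------------------
# shell
# ----------------------------------------------------------------------

def _boundary_loops(mesh: trimesh.Trimesh):
    """Ordered boundary loops as vertex-index cycles (winding direction
    consistent with the face orientation)."""
    edges = mesh.edges  # directed, per-face winding
    keys = np.sort(edges, axis=1)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]
    succ = {int(u): int(w) for u, w in boundary}
    loops = []
    seen = set()
    for start in sorted(succ):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = succ[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            cur = succ[cur]
        loops.append(loop)
    return loops


def thicken(surface: trimesh.Trimesh, thickness: float) -> trimesh.Trimesh:
    """Shell an open surface into a watertight solid of given thickness.

    The offset copy is displaced outward along averaged vertex normals
    (so the seal-line geometry against the skin is untouched) and the
    boundary loops are closed with side walls.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if boundary_edge_count(surface) == 0:
        raise BuildError("thicken expects an open surface, got a closed solid")
    vertices = surface.vertices.view(np.ndarray)
    f = surface.faces.view(np.ndarray)
    nv = len(vertices)
    normals = _vertex_normals(vertices, f, smoothing_passes=2)
    outer = vertices + thickness * normals

    # reject offsets that fold the surface over itself
    n_in = _face_normals(vertices, f)
    n_out = _face_normals(outer, f, normalized=False)
    if np.einsum("ij,ij->i", n_in, n_out).min() <= 0:
        raise BuildError(
            f"offset at thickness {thickness} mm self-intersects; "
            "use a smaller thickness"
        )

    faces = [np.fliplr(f), f + nv]
    for loop in _boundary_loops(surface):
        u = np.asarray(loop)
        w = np.roll(u, -1)
        faces.append(np.column_stack([u, w, w + nv]))
        faces.append(np.column_stack([u, w + nv, u + nv]))
    solid = trimesh.Trimesh(vertices=np.vstack([vertices, outer]),
                            faces=np.concatenate(faces), process=False)
    solid = ensure_outward(solid)
    if boundary_edge_count(solid) != 0:
        raise BuildError("shelling produced an open mesh")
    return solid


# ----------------------------------------------------------------------
# rim
# ----------------------------------------------------------------------

def sweep_tube(centers: np.ndarray, radius: float, sections: int = 32) -> trimesh.Trimesh:
    """Closed tube of circular cross-section swept along a closed polyline.

    Cross-section frames are parallel-transported along the path and the
    residual holonomy twist is distributed uniformly so the tube closes
    seamlessly.
    """
    c = np.asarray(centers, dtype=float)
    n = len(c)
    if n < 3:
        raise ValueError("sweep path needs at least 3 points")
    tangents = unit_rows(np.roll(c, -1, axis=0) - np.roll(c, 1, axis=0))
    e = np.empty_like(tangents)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e[0] = unit(np.cross(tangents[0], ref))
    for i in range(1, n):
        v = e[i - 1] - (e[i - 1] @ tangents[i]) * tangents[i]
        e[i] = unit(v)
    # holonomy: mismatch between transported frame and start frame
    wrapped = unit(e[n - 1] - (e[n - 1] @ tangents[0]) * tangents[0])
    f0 = np.cross(tangents[0], e[0])
    phi = np.arctan2(wrapped @ f0, wrapped @ e[0])
    twist = -phi * np.arange(n) / n
    f = np.cross(tangents, e)
    ca, sa = np.cos(twist), np.sin(twist)
    e_c = ca[:, None] * e + sa[:, None] * f
    f_c = np.cross(tangents, e_c)

    theta = np.linspace(0.0, 2.0 * np.pi, sections, endpoint=False)
    ring = (np.cos(theta)[None, :, None] * e_c[:, None, :]
            + np.sin(theta)[None, :, None] * f_c[:, None, :])
    verts = (c[:, None, :] + radius * ring).reshape(-1, 3)

    i = np.arange(n)[:, None]
    j = np.arange(sections)[None, :]
    v00 = (i * sections + j).ravel()
    v01 = (i * sections + (j + 1) % sections).ravel()
    v10 = (((i + 1) % n) * sections + j).ravel()
    v11 = (((i + 1) % n) * sections + (j + 1) % sections).ravel()
    faces = np.concatenate([
        np.column_stack([v00, v10, v11]),
        np.column_stack([v00, v11, v01]),
    ])
    tube = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return ensure_outward(tube)


def unit_rows(a: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(a, axis=1, keepdims=True)
    if n.min() < 1e-12:
        raise ValueError("degenerate segment in polyline")
    return a / n


def build_rim(base: SurfaceCurve, mask_body: trimesh.Trimesh,
              tube_radius: float = 3.0, sections: int = 32,
              voxel_pitch: float = 0.5) -> trimesh.Trimesh:
    """Soft seal rim: circular tube swept along the base curve, minus the
    mask body (voxel boolean)."""
    tube = sweep_tube(base.points, tube_radius, sections)
    try:
        rim = voxels.subtract(tube, mask_body, pitch=voxel_pitch)
    except ValueError:
        rng = np.random.default_rng(0)
        jittered = tube.copy()
        jittered.vertices += rng.normal(scale=1e-4, size=jittered.vertices.shape)
        try:
            rim = voxels.subtract(jittered, mask_body, pitch=voxel_pitch)
        except ValueError as exc:
            raise BuildError(f"rim boolean subtraction failed: {exc}") from exc
    if boundary_edge_count(rim) != 0:
        raise BuildError("rim subtraction produced an open mesh")
    return rim


# ----------------------------------------------------------------------
# connection parts
# ----------------------------------------------------------------------

def _rect_frame(outer_x: float, outer_y: float, bar: float, depth: float) -> trimesh.Trimesh:
    """Slotted tab: one solid extruded rectangular annulus (16 vertices,
    32 triangles, edge-manifold by construction)."""
    if bar * 2 >= min(outer_x, outer_y):
        raise ValueError("bar too wide for the tab outline")
    ox, oy = outer_x / 2.0, outer_y / 2.0
    ix, iy = ox - bar, oy - bar
    outer = np.array([[-ox, -oy], [ox, -oy], [ox, oy], [-ox, oy]])
    inner = np.array([[-ix, -iy], [ix, -iy], [ix, iy], [-ix, iy]])
    zt, zb = depth / 2.0, -depth / 2.0
    verts = np.vstack([
        np.column_stack([outer, np.full(4, zt)]),   # 0-3 top outer
        np.column_stack([inner, np.full(4, zt)]),   # 4-7 top inner
        np.column_stack([outer, np.full(4, zb)]),   # 8-11 bottom outer
        np.column_stack([inner, np.full(4, zb)]),   # 12-15 bottom inner
    ])
    faces = []
    for i in range(4):
        j = (i + 1) % 4
        faces += [[i, j, 4 + j], [i, 4 + j, 4 + i]]            # top ring
        faces += [[8 + j, 8 + i, 12 + j], [12 + j, 8 + i, 12 + i]]  # bottom
        faces += [[j, i, 8 + i], [j, 8 + i, 8 + j]]            # outer wall
        faces += [[4 + i, 4 + j, 12 + j], [4 + i, 12 + j, 12 + i]]  # inner wall
    tab = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                          process=False)
    return ensure_outward(tab)


def curve_point_at(base: SurfaceCurve, fraction: float):
    """Point and tangent on the closed base curve at an arc-length fraction."""
    pts = base.points
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = (fraction % 1.0) * s[-1]
    k = int(np.searchsorted(s, target, side="right") - 1)
    k = min(k, len(pts) - 1)
    t = (target - s[k]) / seg[k]
    p = pts[k] + t * (pts[(k + 1) % len(pts)] - pts[k])
    tangent = unit(pts[(k + 1) % len(pts)] - pts[k])
    return p, tangent


def add_connection_parts(mask_body: trimesh.Trimesh, base: SurfaceCurve,
                         positions, config: DesignConfig,
                         frame: AnatomicalFrame,
                         filter_center: np.ndarray | None = None):
    """Attach four slotted strap-anchor tabs to the outer shell.

    Returns ``(combined_mesh, tab_meshes)``.  The union is a multi-solid
    concatenation: each tab is itself watertight and tangent to the shell,
    so the combined mesh has zero boundary edges and its enclosed volume
    is exactly the body volume plus the tab volumes.
    """
    positions = list(positions)
    if len(positions) != 4 or len(set(positions)) != 4:
        raise ValueError("exactly 4 distinct connection positions required")
    centroid = base.points.mean(axis=0)
    ox, oy = config.tab_outer_mm
    tabs = []
    for frac in positions:
        p, tangent = curve_point_at(base, frac)
        radial = p - centroid
        radial = radial - (radial @ frame.anterior) * frame.anterior
        n_out = unit(radial)
        if filter_center is not None:
            if np.linalg.norm(p - filter_center) < config.filter_opening_radius_mm + max(ox, oy):
                raise BuildError(
                    f"connection part at fraction {frac:.2f} collides with the filter port"
                )
        x_axis = unit(tangent - (tangent @ n_out) * n_out)
        y_axis = np.cross(n_out, x_axis)
        tab = _rect_frame(ox, oy, config.tab_bar_mm, config.tab_depth_mm)
        T = np.eye(4)
        T[:3, 0] = x_axis
        T[:3, 1] = y_axis
        T[:3, 2] = n_out
        T[:3, 3] = p + (config.tab_depth_mm / 2 - 0.05) * n_out
        tab.apply_transform(T)
        tabs.append(tab)
    combined = trimesh.util.concatenate([mask_body] + tabs)
    if boundary_edge_count(combined) != 0:
        raise BuildError("connection-part union is not watertight")
    return combined, tabs


# ----------------------------------------------------------------------
# measurement
# ----------------------------------------------------------------------

def measure_shell_thickness(body: trimesh.Trimesh, n_samples: int = 500,
                            seed: int = 0) -> float:
    """Median wall thickness from inward ray casting at random surface points."""
    points, face_idx = trimesh.sample.sample_surface(body, n_samples, seed=seed)
    normals = body.face_normals[face_idx]
    query = MeshQuery(body)
    vals = []
    for p, n in zip(points, normals):
        t, _, _ = query.ray_hits(p + 0.01 * n, -n)
        # first hit is the sampled surface itself; the next is the far wall
        t = t[t > 1e-6]
        if len(t) >= 2:
            vals.append(t[1] - t[0])
    if not vals:
        raise BuildError("thickness measurement found no wall crossings")
    return float(np.median(vals))
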