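"""Deterministic parametric face meshes with analytically known landmarks.

The generator emulates the input a stereophotogrammetric face scan provides:
an open anterior shell (not a closed head) in millimetre units.  The shell
is a height field over an elliptical domain — an anterior half-ellipsoid
with a smooth Gaussian nose ridge peaking at the nasal tip and a chin
bulge peaking at the pogonion.  All nine design landmarks are snapped to
exact mesh vertices, so on-surface invariants hold exactly rather than to
a tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import sparse
from scipy.spatial import cKDTree

from .io_formats import LANDMARK_NAMES, LandmarkSet

log = logging.getLogger(__name__)

#: landmark anchor positions as fractions of the half-axes (x/a, y/b);
#: x is lateral (anatomical left positive), y superior, z anterior
_ANCHOR_FRACTIONS = {
    "Ex_r": (-0.64, 0.33),
    "En_r": (-0.23, 0.33),
    "Ra": (0.0, 0.39),
    "En_l": (0.23, 0.33),
    "Ex_l": (0.64, 0.33),
    "Ntp": (0.0, 0.06),
    "Pc": (0.0, -0.28),
    "Pg": (0.0, -0.61),
    "M": (0.0, -0.83),
}

_DOMAIN_MARGIN = 0.92  # fraction of the ellipse actually meshed


@dataclass(frozen=True)
class FaceParams:
    """Shape parameters of the synthetic face (all lengths in mm)."""

    half_width: float = 70.0
    half_height: float = 90.0
    half_depth: float = 80.0
    nose_height: float = 25.0
    nose_length: float = 30.0
    chin_prominence: float = 10.0
    asymmetry: float = 0.0
    resolution: int = 101
    seed: int = 0

    def __post_init__(self):
        for name in ("half_width", "half_height", "half_depth", "nose_height",
                     "nose_length", "chin_prominence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resolution < 20:
            raise ValueError("resolution must be >= 20")
        if not 0.0 <= self.asymmetry <= 0.2:
            raise ValueError("asymmetry must be in [0, 0.2]")


def _height_field(x, y, p: FaceParams, shear: bool = True):
    """Anterior coordinate z(x, y) of the face shell."""
    a, b, c = p.half_width, p.half_height, p.half_depth
    rr = (x / a) ** 2 + (y / b) ** 2
    z = c * np.sqrt(np.clip(1.0 - rr, 0.0, None))
    # nose ridge: Gaussian bump peaking at the nasal-tip anchor
    y_ntp = _ANCHOR_FRACTIONS["Ntp"][1] * b
    sx = 0.13 * a
    sy = p.nose_length / 2.5
    z = z + p.nose_height * np.exp(-(x**2 / (2 * sx**2) + (y - y_ntp) ** 2 / (2 * sy**2)))
    # chin bulge peaking at the pogonion anchor
    y_pg = _ANCHOR_FRACTIONS["Pg"][1] * b
    z = z + p.chin_prominence * np.exp(-(x**2 / (2 * 18.0**2) + (y - y_pg) ** 2 / (2 * 15.0**2)))
    if p.asymmetry:
        z = z * (1.0 + p.asymmetry * x / a)
    if shear:
        # vertical shear levelling the radix and menton depths, so the
        # face "looks" along +z the way an upright scan subject does
        # (a bare half-ellipsoid would tuck the chin far posteriorly)
        y_ra = _ANCHOR_FRACTIONS["Ra"][1] * b
        y_m = _ANCHOR_FRACTIONS["M"][1] * b
        z_ra = _height_field(np.array(0.0), np.array(y_ra), p, shear=False)
        z_m = _height_field(np.array(0.0), np.array(y_m), p, shear=False)
        z = z + float(z_m - z_ra) / (y_ra - y_m) * y
    return z


def generate_face(params: FaceParams = FaceParams()):
    """Build the synthetic face shell and its landmark set.

    Returns ``(mesh, landmarks)``.  The mesh is an open, edge-manifold
    triangle shell; with ``asymmetry == 0`` it is mirror-symmetric about
    the midsagittal plane x = 0 and every midline landmark has x == 0.
    Deterministic for fixed parameters.
    """
    p = params
    a, b = p.half_width, p.half_height
    n = p.resolution if p.resolution % 2 == 1 else p.resolution + 1
    m = _DOMAIN_MARGIN
    xs = np.linspace(-m * a, m * a, n)
    xs = 0.5 * (xs - xs[::-1])  # bitwise mirror-symmetric grid
    ys = np.linspace(-m * b, m * b, n)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    inside = (gx / a) ** 2 + (gy / b) ** 2 <= m**2

    idx = -np.ones((n, n), dtype=int)
    idx[inside] = np.arange(int(inside.sum()))
    gz = _height_field(gx, gy, p)
    vertices = np.column_stack([gx[inside], gy[inside], gz[inside]])

    # two triangles per grid cell whose four corners are all inside
    i0 = idx[:-1, :-1]
    i1 = idx[1:, :-1]
    i2 = idx[1:, 1:]
    i3 = idx[:-1, 1:]
    ok = (i0 >= 0) & (i1 >= 0) & (i2 >= 0) & (i3 >= 0)
    faces = np.concatenate(
        [
            np.column_stack([i0[ok], i1[ok], i2[ok]]),
            np.column_stack([i0[ok], i2[ok], i3[ok]]),
        ]
    )
    # drop grid vertices that ended up in no complete cell
    referenced = np.zeros(len(vertices), dtype=bool)
    referenced[faces.ravel()] = True
    remap = -np.ones(len(vertices), dtype=int)
    remap[referenced] = np.arange(int(referenced.sum()))
    vertices = vertices[referenced]
    faces = remap[faces]
    idx[inside] = remap[idx[inside]]

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.metadata["name"] = "synthetic_face"

    # snap landmarks to exact grid vertices
    points = {}
    snapped = {}
    for name in LANDMARK_NAMES:
        fx, fy = _ANCHOR_FRACTIONS[name]
        ix = int(np.argmin(np.abs(xs - fx * a)))
        iy = int(np.argmin(np.abs(ys - fy * b)))
        if idx[ix, iy] < 0:
            raise ValueError(f"landmark {name} falls outside the meshed domain")
        snapped[name] = (ix, iy)
        points[name] = vertices[idx[ix, iy]]
    # the nasal tip is by definition the most anterior point of the nose;
    # the vertical shear shifts the analytic bump peak slightly, so snap
    # Ntp to the actual anterior-most vertex (midline by symmetry)
    points["Ntp"] = vertices[int(np.argmax(vertices[:, 2]))]
    arr = np.stack([points[n] for n in LANDMARK_NAMES])
    if len(np.unique(arr, axis=0)) < len(LANDMARK_NAMES):
        raise ValueError(
            "resolution too low: distinct landmarks snap to the same vertex"
        )
    return mesh, LandmarkSet(points)


def jitter_landmarks(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                     magnitude_mm: float, seed: int) -> LandmarkSet:
    """Emulate manual landmark-placement error on a fixed scan.

    Each landmark is re-placed at a uniformly chosen mesh vertex within
    ``magnitude_mm`` of its true position (the reported accuracy of
    placing cephalometric landmarks is about 2 mm).  The surface itself
    is untouched.  Deterministic for a fixed seed.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be >= 0")
    if magnitude_mm == 0:
        return landmarks
    rng = np.random.default_rng(seed)
    tree = cKDTree(mesh.vertices)
    points = {}
    for name in LANDMARK_NAMES:
        cand = tree.query_ball_point(landmarks[name], magnitude_mm)
        i = int(rng.choice(cand)) if cand else int(tree.query(landmarks[name])[1])
        points[name] = mesh.vertices[i]
    return LandmarkSet(points)


def _smooth_field(mesh: trimesh.Trimesh, field: np.ndarray, passes: int = 5):
    """Average a per-vertex field over the 1-ring, ``passes`` times."""
    e = mesh.edges_unique
    nv = len(mesh.vertices)
    adj = sparse.coo_matrix(
        (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(nv, nv),
    ).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    out = field.astype(float)
    for _ in range(passes):
        out = 0.5 * out + 0.5 * (adj @ out) / deg
    return out


def perturb_face(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                 noise_mm: float, seed: int):
    """Jitter the shell along vertex normals by a smooth random field.

    The field is white noise averaged over vertex neighbourhoods (so the
    perturbed surface stays scan-like rather than rough) and rescaled to a
    standard deviation of ``noise_mm``.  Landmarks ride along with their
    host vertex, emulating the ~2 mm placement error reported for manual
    cephalometric annotation.  Deterministic for a fixed seed.
    """
    if noise_mm < 0:
        raise ValueError("noise_mm must be >= 0")
    if noise_mm == 0:
        return mesh.copy(), landmarks
    rng = np.random.default_rng(seed)
    field = rng.standard_normal(len(mesh.vertices))
    # ~10 averaging passes give the centimetre-scale spatial correlation
    # of stereophotogrammetric reconstruction error
    field = _smooth_field(mesh, field, passes=10)
    std = field.std()
    if std > 0:
        field = field * (noise_mm / std)
    new_vertices = mesh.vertices + field[:, None] * mesh.vertex_normals
    out = trimesh.Trimesh(vertices=new_vertices, faces=mesh.faces.copy(), process=False)
    out.metadata["name"] = mesh.metadata.get("name", "face")

    # landmarks track the vertex they were snapped to
    new_points = {}
    for name in LANDMARK_NAMES:
        i = int(np.argmin(np.linalg.norm(mesh.vertices - landmarks[name], axis=1)))
        new_points[name] = new_vertices[i]
    return out, LandmarkSet(new_points)
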