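"""Voxel-based solid booleans for watertight meshes.

Robust exact-arithmetic mesh booleans need a dedicated backend; here the
subtraction the rim design needs is done on a regular occupancy grid:
both solids are rasterized (surface sampling + cavity fill), combined as
boolean arrays, and the result is re-meshed with marching cubes.  The
price is voxel-scale (default 0.5 mm) surface accuracy, which is well
below the print tolerance of the parts this package emits.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes
from trimesh.remesh import subdivide_to_size

from .spatial import ensure_outward

_CROSS = ndimage.generate_binary_structure(3, 1)


def _rasterize_surface(mesh: trimesh.Trimesh, origin: np.ndarray, pitch: float,
                       shape: tuple) -> np.ndarray:
    """Mark every voxel touched by the mesh surface.

    The mesh is subdivided until no edge exceeds half the voxel pitch, so
    marking the vertices leaves no pinholes after a one-voxel closing.
    """
    v, f = subdivide_to_size(
        np.asarray(mesh.vertices, dtype=float),
        np.asarray(mesh.faces, dtype=int),
        max_edge=pitch * 0.5,
    )
    ijk = np.floor((v - origin) / pitch).astype(int)
    ok = np.all((ijk >= 0) & (ijk < np.asarray(shape)), axis=1)
    grid = np.zeros(shape, dtype=bool)
    ijk = ijk[ok]
    grid[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    return grid


def solid_occupancy(mesh: trimesh.Trimesh, origin: np.ndarray, pitch: float,
                    shape: tuple) -> np.ndarray:
    """Occupancy grid of a watertight solid on the given grid.

    Surface voxels are dilated one step before cavity filling (sealing
    any diagonal pinholes) and eroded back afterwards, so the boundary
    stays within one voxel of the true surface.
    """
    surf = _rasterize_surface(mesh, origin, pitch, shape)
    sealed = ndimage.binary_dilation(surf, structure=_CROSS)
    filled = ndimage.binary_fill_holes(sealed, structure=_CROSS)
    return ndimage.binary_erosion(filled, structure=_CROSS) | surf


def _grid_for(meshes, pitch: float, pad_voxels: int = 3):
    bounds = np.array([m.bounds for m in meshes])
    lo = bounds[:, 0, :].min(axis=0) - pad_voxels * pitch
    hi = bounds[:, 1, :].max(axis=0) + pad_voxels * pitch
    shape = tuple(np.ceil((hi - lo) / pitch).astype(int) + 1)
    return lo, shape


def mesh_from_occupancy(occ: np.ndarray, origin: np.ndarray, pitch: float,
                        min_component_volume: float = 1.0) -> trimesh.Trimesh:
    """Re-mesh an occupancy grid with marching cubes (watertight output)."""
    if not occ.any():
        raise ValueError("empty occupancy grid; nothing to mesh")
    occ = np.pad(occ, 1)
    verts, faces, _, _ = marching_cubes(occ.astype(np.float32), level=0.5)
    verts = (verts - 1.0) * pitch + origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh = ensure_outward(mesh)
    # drop marching-cubes dust (isolated specks below the volume floor)
    parts = mesh.split(only_watertight=True)
    if len(parts) > 1:
        parts = [p for p in parts if abs(p.volume) >= min_component_volume]
        if not parts:
            raise ValueError("boolean result vanished below the volume floor")
        mesh = trimesh.util.concatenate(parts)
    return mesh


def subtract(minuend: trimesh.Trimesh, subtrahend: trimesh.Trimesh,
             pitch: float = 0.5, clearance_voxels: int = 1) -> trimesh.Trimesh:
    """Voxel boolean ``minuend - subtrahend`` as a watertight mesh.

    The subtrahend is dilated ``clearance_voxels`` steps before removal,
    biasing the result toward a strict (non-overlapping) difference.
    """
    origin, shape = _grid_for([minuend, subtrahend], pitch)
    occ_a = solid_occupancy(minuend, origin, pitch, shape)
    occ_b = solid_occupancy(subtrahend, origin, pitch, shape)
    if clearance_voxels:
        occ_b = ndimage.binary_dilation(occ_b, structure=_CROSS,
                                        iterations=clearance_voxels)
    occ = occ_a & ~occ_b
    return mesh_from_occupancy(occ, origin, pitch)


def intersection_volume(a: trimesh.Trimesh, b: trimesh.Trimesh,
                        pitch: float = 0.5) -> float:
    """Approximate volume of ``a ∩ b`` in mm^3 (voxel counting)."""
    lo_a, hi_a = a.bounds
    lo_b, hi_b = b.bounds
    lo = np.maximum(lo_a, lo_b)
    hi = np.minimum(hi_a, hi_b)
    if np.any(hi <= lo):
        return 0.0
    pad = 2 * pitch
    lo -= pad
    hi += pad
    shape = tuple(np.ceil((hi - lo) / pitch).astype(int) + 1)
    occ_a = solid_occupancy(a, lo, pitch, shape)
    occ_b = solid_occupancy(b, lo, pitch, shape)
    return float((occ_a & occ_b).sum()) * pitch**3


def symmetric_difference_fraction(a: trimesh.Trimesh, b: trimesh.Trimesh,
                                  pitch: float = 0.5) -> float:
    """|a Δ b| / |a| by voxel counting, on a common grid."""
    origin, shape = _grid_for([a, b], pitch)
    occ_a = solid_occupancy(a, origin, pitch, shape)
    occ_b = solid_occupancy(b, origin, pitch, shape)
    na = occ_a.sum()
    if na == 0:
        raise ValueError("first solid rasterizes to nothing")
    return float((occ_a ^ occ_b).sum()) / float(na)
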