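"""Spatial queries on triangle meshes.

Closest-point projection, line/ray intersection and point-in-solid tests,
accelerated with a k-d tree over triangle centroids.  All queries are pure
numpy/scipy and deterministic.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from trimesh.triangles import closest_point as _tri_closest


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector cannot be normalized")
    return v / n


def ensure_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Return a rebuilt mesh with consistent winding and positive volume.

    The mesh is reconstructed from raw arrays after the winding repair:
    trimesh caches face normals, and repair + invert sequences can leave
    the cache inconsistent with the actual winding.
    """
    trimesh.repair.fix_winding(mesh)
    out = trimesh.Trimesh(
        vertices=mesh.vertices.view(np.ndarray).copy(),
        faces=mesh.faces.view(np.ndarray).copy(),
        process=False,
    )
    if out.volume < 0:
        out.invert()
        out = trimesh.Trimesh(
            vertices=out.vertices.view(np.ndarray),
            faces=out.faces.view(np.ndarray),
            process=False,
        )
    return out


class MeshQuery:
    """Accelerated geometric queries against a fixed triangle mesh.

    Candidate triangles for closest-point queries come from the k nearest
    triangle centroids, padded by the largest triangle radius so the true
    nearest triangle is never missed for points within ``safe_radius`` of
    the surface (practically: anywhere near the face).
    """

    def __init__(self, mesh: trimesh.Trimesh, leafsize: int = 16):
        self.mesh = mesh
        self.triangles = mesh.triangles.view(np.ndarray).astype(float)
        self._centroids = self.triangles.mean(axis=1)
        # circumradius bound per triangle: max vertex distance from centroid
        d = self.triangles - self._centroids[:, None, :]
        self._tri_radius = float(np.sqrt((d**2).sum(axis=2)).max())
        self._tree = cKDTree(self._centroids, leafsize=leafsize)

    # ------------------------------------------------------------------
    # closest point
    # ------------------------------------------------------------------
    def closest_point(self, points: np.ndarray, k: int = 16):
        """Closest point on the mesh surface for each query point.

        Returns ``(surface_points, distances, triangle_ids)``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(k, len(self.triangles))
        dist_c, idx = self._tree.query(points, k=k)
        if k == 1:
            dist_c = dist_c[:, None]
            idx = idx[:, None]
        # Guarantee correctness: any triangle whose centroid lies within
        # (best candidate distance + tri_radius) could host the true minimum.
        need = dist_c[:, -1] < dist_c[:, 0] + 2.0 * self._tri_radius
        out_pts = np.empty_like(points)
        out_dist = np.empty(len(points))
        out_tid = np.empty(len(points), dtype=int)

        flat_pts = np.repeat(points, k, axis=0)
        flat_tris = self.triangles[idx.ravel()]
        cp = _tri_closest(flat_tris, flat_pts).reshape(len(points), k, 3)
        d = np.linalg.norm(cp - points[:, None, :], axis=2)
        best = d.argmin(axis=1)
        rows = np.arange(len(points))
        out_pts = cp[rows, best]
        out_dist = d[rows, best]
        out_tid = idx[rows, best]

        # exhaustive fallback for points where the candidate ring may clip
        # the true minimum (rare; only triggered far from the surface)
        bad = np.flatnonzero(need & (out_dist > dist_c[:, -1] - self._tri_radius))
        for i in bad:
            cand = self._tree.query_ball_point(points[i], out_dist[i] + self._tri_radius)
            if not cand:
                continue
            cand = np.asarray(cand)
            cp_i = _tri_closest(self.triangles[cand], np.tile(points[i], (len(cand), 1)))
            d_i = np.linalg.norm(cp_i - points[i], axis=1)
            j = d_i.argmin()
            if d_i[j] < out_dist[i]:
                out_pts[i] = cp_i[j]
                out_dist[i] = d_i[j]
                out_tid[i] = cand[j]
        return out_pts, out_dist, out_tid

    # ------------------------------------------------------------------
    # ray / line intersection (Moller-Trumbore, vectorized over triangles)
    # ------------------------------------------------------------------
    def ray_hits(self, origin: np.ndarray, direction: np.ndarray, eps: float = 1e-12):
        """All intersections of the ray origin + t*direction (t >= 0).

        Returns ``(t_values, points, triangle_ids)`` sorted by t.
        """
        t, pts, tid = self.line_hits(origin, direction, eps=eps)
        keep = t >= 0.0
        return t[keep], pts[keep], tid[keep]

    def line_hits(self, origin: np.ndarray, direction: np.ndarray, eps: float = 1e-12):
        """All intersections of the infinite line origin + t*direction."""
        origin = np.asarray(origin, dtype=float)
        direction = _unit(direction)
        v0 = self.triangles[:, 0]
        e1 = self.triangles[:, 1] - v0
        e2 = self.triangles[:, 2] - v0
        h = np.cross(direction, e2)
        a = (e1 * h).sum(axis=1)
        ok = np.abs(a) > eps
        f = np.zeros_like(a)
        f[ok] = 1.0 / a[ok]
        s = origin - v0
        u = f * (s * h).sum(axis=1)
        q = np.cross(s, e1)
        v = f * (q * direction[None, :]).sum(axis=1)
        t = f * (q * e2).sum(axis=1)
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1.0 + 1e-9)
        tid = np.flatnonzero(hit)
        t = t[hit]
        order = np.argsort(t)
        t = t[order]
        tid = tid[order]
        pts = origin[None, :] + t[:, None] * direction[None, :]
        return t, pts, tid

    # ------------------------------------------------------------------
    # containment (parity of crossings; mesh must be watertight)
    # ------------------------------------------------------------------
    def contains(self, points: np.ndarray, direction=(0.57735, 0.57735, 0.57735)):
        """Point-in-solid test by ray-crossing parity.

        The slightly irrational default direction avoids edge-on hits for
        axis-aligned geometry.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        direction = _unit(np.asarray(direction, dtype=float))
        v0 = self.triangles[:, 0]
        e1 = self.triangles[:, 1] - v0
        e2 = self.triangles[:, 2] - v0
        h = np.cross(direction, e2)
        a = (e1 * h).sum(axis=1)
        ok = np.abs(a) > 1e-12
        f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        out = np.zeros(len(points), dtype=bool)
        # chunk over points; triangles handled fully vectorized
        chunk = max(1, int(4e6 / max(len(self.triangles), 1)))
        for lo in range(0, len(points), chunk):
            p = points[lo : lo + chunk]
            s = p[:, None, :] - v0[None, :, :]
            u = f[None, :] * (s * h[None, :, :]).sum(axis=2)
            q = np.cross(s, e1[None, :, :])
            v = f[None, :] * (q * direction[None, None, :]).sum(axis=2)
            t = f[None, :] * (q * e2[None, :, :]).sum(axis=2)
            hit = ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1.0) & (t > 1e-9)
            out[lo : lo + chunk] = (hit.sum(axis=1) % 2) == 1
        return out
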