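"""Shared independent oracles for the test suite."""

import numpy as np

from maskforge.geometry import plane_plane_line


def line_t_range(p0, d, bounds, pad=5.0):
    """Parameter range over which the line can intersect the mesh bounds."""
    lo, hi = bounds
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    t = (corners - p0) @ d
    return float(t.min() - pad), float(t.max() + pad)


def brute_force_plane_pair_point(plane_a, plane_b, query, frame,
                                 coarse=1.0, fine=0.02):
    """Anterior-most line/surface crossing by dense line sampling.

    Walks the intersection line of the two planes, finds clusters where
    the point-to-mesh distance dips toward zero, refines each cluster and
    returns the anterior-most crossing.  Independent of the ray-casting
    implementation under test.
    """
    p0, d = plane_plane_line(plane_a, plane_b)
    t_lo, t_hi = line_t_range(p0, d, query.mesh.bounds)
    ts = np.arange(t_lo, t_hi, coarse)
    _, dist, _ = query.closest_point(p0 + ts[:, None] * d)
    near = dist < 1.5 * coarse
    if not near.any():
        return None
    # contiguous near-surface runs -> candidate crossings
    idx = np.flatnonzero(near)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    crossings = []
    for run in runs:
        a, b = ts[run[0]] - coarse, ts[run[-1]] + coarse
        tt = np.arange(a, b, fine)
        _, dd, _ = query.closest_point(p0 + tt[:, None] * d)
        k = int(np.argmin(dd))
        if dd[k] < 5 * fine:
            crossings.append(p0 + tt[k] * d)
    if not crossings:
        return None
    crossings = np.asarray(crossings)
    return crossings[np.argmax(crossings @ frame.anterior)]
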