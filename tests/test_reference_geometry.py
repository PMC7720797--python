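import numpy as np
import pytest
import trimesh

from helpers import brute_force_plane_pair_point
from maskforge.geometry import Plane
from maskforge.io_formats import LANDMARK_NAMES, LandmarkSet
from maskforge.reference_geometry import (GeometryError, build_frame,
                                          compute_control_points,
                                          compute_planes,
                                          plane_pair_surface_point)
from maskforge.spatial import MeshQuery


def mirror_landmarks(lm, swap_labels=False):
    """Reflect landmark coordinates across x = 0.

    With ``swap_labels`` the left/right canthus labels are exchanged too,
    which is the anatomically valid mirror of a face.
    """
    pts = {n: p * [-1, 1, 1] for n, p in lm.points.items()}
    if swap_labels:
        for a, b in (("Ex_l", "Ex_r"), ("En_l", "En_r")):
            pts[a], pts[b] = pts[b], pts[a]
    return LandmarkSet(pts)


def random_landmark_set(base, rng, scale=3.0):
    """A plausible random face: the default landmarks jittered per-point."""
    while True:
        pts = {n: base[n] + rng.uniform(-scale, scale, 3) for n in LANDMARK_NAMES}
        try:
            return LandmarkSet(pts)
        except ValueError:
            continue


class TestComputePlanes:
    def test_midline_points_force_mf_normal(self):
        lm = LandmarkSet({
            "Ra": [0, 50, 0], "Ntp": [0, 0, 40], "Pg": [0, -40, 20],
            "M": [0, -60, 10], "Pc": [0, -20, 30],
            "Ex_r": [-40, 30, 5], "En_r": [-15, 30, 8],
            "En_l": [15, 30, 8], "Ex_l": [40, 30, 5],
        })
        n = compute_planes(lm).MF.normal
        assert min(np.abs(n - [1, 0, 0]).max(), np.abs(n + [1, 0, 0]).max()) < 1e-9

    def test_invariants_hold_on_random_faces(self, face, rng):
        _, lm0 = face
        for _ in range(100):
            lm = random_landmark_set(lm0.points, rng)
            ps = compute_planes(lm)
            for _, plane in ps.items():
                assert abs(np.linalg.norm(plane.normal) - 1.0) < 1e-9
            # MF through the three midline landmarks
            for p in (lm.Ra, lm.Ntp, lm.Pg):
                assert abs(ps.MF.signed_distance(p)) < 1e-6
            # HP perpendicular to MF and VP, through Ra
            assert abs(ps.HP.normal @ ps.MF.normal) < 1e-9
            assert abs(ps.HP.normal @ ps.VP.normal) < 1e-9
            assert abs(ps.HP.signed_distance(lm.Ra)) < 1e-9
            assert abs(ps.VP.normal @ ps.MF.normal) < 1e-9
            # horizontal family: parallel to HP through their landmarks
            for plane, anchor in ((ps.LHP, lm.Pc), (ps.CHP, lm.Pg)):
                assert np.linalg.norm(np.cross(plane.normal, ps.HP.normal)) < 1e-9
                assert abs(plane.signed_distance(anchor)) < 1e-9
            # MF-parallel family through canthi / canthus midpoints
            anchors = {
                "HLCP": lm.Ex_l, "HRCP": lm.Ex_r,
                "CLP": 0.5 * (lm.Ex_l + lm.En_l),
                "CRP": 0.5 * (lm.Ex_r + lm.En_r),
            }
            for name, anchor in anchors.items():
                plane = ps[name]
                assert np.linalg.norm(np.cross(plane.normal, ps.MF.normal)) < 1e-9
                assert abs(plane.signed_distance(anchor)) < 1e-9
            # anatomical orientation of the normals
            assert ps.MF.normal @ (lm.Ex_l - lm.Ex_r) > 0
            assert ps.HP.normal @ (lm.Ra - lm.M) > 0
            # VP holds the canthi up to their own asymmetry about MF
            d = lm.Ex_l - lm.Ex_r
            asym = np.linalg.norm(d - (d @ ps.MF.normal) * ps.MF.normal)
            res = max(abs(ps.VP.signed_distance(lm.Ex_l)),
                      abs(ps.VP.signed_distance(lm.Ex_r)))
            assert res <= 0.5 * asym + 1e-9

    def test_vp_contains_symmetric_canthi_exactly(self, face):
        _, lm = face
        ps = compute_planes(lm)
        assert abs(ps.VP.signed_distance(lm.Ex_l)) < 1e-9
        assert abs(ps.VP.signed_distance(lm.Ex_r)) < 1e-9

    def test_collinear_midline_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            LandmarkSet({
                "Ra": [0, 0, 0], "Ntp": [0, 0, 50], "Pg": [0, 0, 100],
                "M": [0, -60, 10], "Pc": [0, -20, 30],
                "Ex_r": [-40, 30, 5], "En_r": [-15, 30, 8],
                "En_l": [15, 30, 8], "Ex_l": [40, 30, 5],
            })


class TestAnatomicalFrame:
    def test_orthonormal_right_handed(self, ref):
        f = ref["frame"]
        M = np.stack([f.lateral_left, f.superior, f.anterior])
        assert np.abs(M @ M.T - np.eye(3)).max() < 1e-9
        assert np.linalg.det(M) > 0.99

    def test_anterior_matches_generator_gaze(self, ref):
        # the generator's face looks along +z
        assert ref["frame"].anterior @ [0, 0, 1] > 0.99

    def test_mirrored_input_flips_lateral_axis(self, face, ref):
        mesh, lm = face
        mirrored = trimesh.Trimesh(mesh.vertices * [-1, 1, 1],
                                   mesh.faces[:, ::-1], process=False)
        lm_m = mirror_landmarks(lm)
        planes_m = compute_planes(lm_m)
        frame_m = build_frame(planes_m, lm_m, mirrored)
        f = ref["frame"]
        assert np.abs(frame_m.anterior - f.anterior).max() < 1e-9
        assert np.abs(frame_m.lateral_left + f.lateral_left).max() < 1e-9


class TestPlanePairSurfacePoint:
    def test_unit_sphere_analytic(self, ref):
        sphere = trimesh.creation.icosphere(subdivisions=4)
        p = plane_pair_surface_point(
            Plane([0, 0, 0], [1, 0, 0]), Plane([0, 0, 0], [0, 1, 0]),
            sphere, ref["frame"])
        assert np.linalg.norm(p - [0, 0, 1]) < 0.01  # within chord sag

    def test_result_lies_on_both_planes(self, face, ref):
        a = Plane(ref["frame"].origin + 10 * ref["planes"].MF.normal,
                  ref["planes"].MF.normal)
        b = Plane(ref["frame"].origin - 40 * ref["frame"].superior,
                  ref["planes"].HP.normal)
        p = plane_pair_surface_point(a, b, ref["query"], ref["frame"])
        assert abs(a.signed_distance(p)) < 1e-6
        assert abs(b.signed_distance(p)) < 1e-6

    def test_matches_brute_force_line_walk(self, face, ref, rng):
        planes, frame, query = ref["planes"], ref["frame"], ref["query"]
        checked = 0
        while checked < 20:
            u = rng.uniform(-40, 40)
            v = rng.uniform(-95, -10)
            if (u / 65) ** 2 + ((34.8 + v) / 80) ** 2 > 0.7:
                continue  # line would graze or miss the shell
            a = Plane(frame.origin + u * planes.MF.normal, planes.MF.normal)
            b = Plane(frame.origin + v * frame.superior, planes.HP.normal)
            got = plane_pair_surface_point(a, b, query, frame)
            want = brute_force_plane_pair_point(a, b, query, frame)
            assert want is not None
            assert np.linalg.norm(got - want) <= 0.1
            checked += 1

    def test_parallel_planes_error_names_pair(self, ref):
        planes = ref["planes"]
        with pytest.raises(GeometryError, match="HLCP.*HRCP"):
            plane_pair_surface_point(planes.HLCP, planes.HRCP, ref["query"],
                                     ref["frame"], names=("HLCP", "HRCP"))

    def test_missing_surface_error(self, ref):
        # the line x = 500, y = 0 passes nowhere near the face
        a = Plane([500.0, 0, 0], [1, 0, 0])
        b = Plane([0, 0, 0], [0, 1, 0])
        with pytest.raises(GeometryError, match="misses"):
            plane_pair_surface_point(a, b, ref["query"], ref["frame"])


class TestControlPoints:
    def test_exactly_six_anchored_at_ra_and_menton(self, face, ref):
        _, lm = face
        cps = ref["cps"]
        assert cps.as_array().shape == (6, 3)
        assert np.array_equal(cps.C1, lm.Ra)
        assert np.array_equal(cps.C4, lm.M)

    def test_lateral_points_on_surface(self, ref):
        pts = np.stack([ref["cps"].C2, ref["cps"].C3,
                        ref["cps"].C5, ref["cps"].C6])
        _, dist, _ = ref["query"].closest_point(pts)
        assert dist.max() < 0.1

    def test_symmetric_face_gives_mirror_pairs(self, ref):
        cps, mf = ref["cps"], ref["planes"].MF
        assert np.linalg.norm(mf.reflect(cps.C6) - cps.C2) < 0.5
        assert np.linalg.norm(mf.reflect(cps.C5) - cps.C3) < 0.5

    def test_reflection_equivariance(self, face, ref):
        # anatomical mirror: reflect coordinates and swap the l/r labels
        mesh, lm = face
        mirrored = trimesh.Trimesh(mesh.vertices * [-1, 1, 1],
                                   mesh.faces[:, ::-1], process=False)
        lm_m = mirror_landmarks(lm, swap_labels=True)
        planes_m = compute_planes(lm_m)
        frame_m = build_frame(planes_m, lm_m, mirrored)
        cps_m = compute_control_points(lm_m, planes_m, mirrored, frame_m)
        cps = ref["cps"]
        flip = np.array([-1, 1, 1])
        assert np.linalg.norm(cps_m.C2 - cps.C6 * flip) < 0.5
        assert np.linalg.norm(cps_m.C3 - cps.C5 * flip) < 0.5
        assert np.linalg.norm(cps_m.C1 - cps.C1 * flip) < 1e-9
        assert np.linalg.norm(cps_m.C4 - cps.C4 * flip) < 1e-9
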