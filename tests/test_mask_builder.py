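import numpy as np
import pytest
import trimesh

from maskforge import mask_builder as mb
from maskforge.io_formats import boundary_edge_count
from maskforge.mask_builder import (BuildError, DesignConfig, _boundary_loops,
                                    add_connection_parts, build_mask_surface,
                                    loft, measure_shell_thickness,
                                    place_filter_base, sweep_tube, thicken,
                                    translate_curve)
from maskforge.spatial import MeshQuery


def circle(radius=1.0, n=100, z=0.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(th), radius * np.sin(th),
                            np.full(n, z)])


class TestTranslateCurve:
    def test_rigid_anterior_translation(self, face, ref, base_curve):
        _, lm = face
        out = translate_curve(base_curve, lm, ref["frame"], 0.5)
        disp = out.points - base_curve.points
        assert np.abs(disp - disp[0]).max() < 1e-9
        want = 0.5 * np.linalg.norm(lm.Ra - lm.Ntp)
        assert abs(np.linalg.norm(disp[0]) - want) < 1e-9
        assert abs(disp[0] @ ref["frame"].anterior
                   - np.linalg.norm(disp[0])) < 1e-9

    def test_invalid_ratio_rejected(self, face, ref, base_curve):
        _, lm = face
        for ratio in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                translate_curve(base_curve, lm, ref["frame"], ratio)


class TestPlaceFilterBase:
    def test_standoff_exact_and_parallel_to_vp(self, face, ref):
        _, lm = face
        fb = place_filter_base(lm, ref["planes"], ref["frame"], DesignConfig())
        assert abs(abs(fb.plane.signed_distance(lm.Ntp)) - 20.0) < 1e-9
        assert abs(abs(fb.plane.normal @ ref["planes"].VP.normal) - 1.0) < 1e-9

    def test_boundary_is_circle_in_carrier_plane(self, face, ref):
        _, lm = face
        cfg = DesignConfig()
        fb = place_filter_base(lm, ref["planes"], ref["frame"], cfg)
        r = np.linalg.norm(fb.boundary - fb.center, axis=1)
        assert np.abs(r - cfg.filter_opening_radius_mm).max() < 1e-6
        assert np.abs(fb.plane.signed_distance(fb.boundary)).max() < 1e-9
        assert len(fb.boundary) == cfg.n_samples


class TestLoft:
    def test_cylinder_area_oracle(self):
        m = loft(circle(n=100, z=0.0), circle(n=100, z=1.0))
        assert len(m.faces) == 200
        assert abs(m.area - 2 * np.pi) / (2 * np.pi) < 0.01

    def test_boundary_reproduces_profiles(self):
        a, b = circle(n=80, z=0.0), circle(radius=2.0, n=80, z=5.0)
        m = loft(a, b)
        assert boundary_edge_count(m) == 160
        for pts in (a, b):
            d = np.linalg.norm(m.vertices[:, None, :] - pts[None], axis=2)
            assert d.min(axis=0).max() < 1e-12

    def test_opposite_winding_auto_reversed(self):
        m = loft(circle(n=100, z=0.0), circle(n=100, z=1.0)[::-1])
        assert abs(m.area - 2 * np.pi) / (2 * np.pi) < 0.01

    def test_mismatched_counts_rejected(self):
        with pytest.raises(BuildError, match="samples"):
            loft(circle(n=100), circle(n=90, z=1.0))

    def test_degenerate_identical_profiles_rejected(self):
        with pytest.raises(BuildError, match="degenerate"):
            loft(circle(n=100), circle(n=100))


class TestMaskSurface:
    def test_two_boundary_loops_and_annulus_topology(self, design):
        surf = design["mask_surface"]
        assert len(_boundary_loops(surf)) == 2
        assert surf.euler_number == 0

    def test_contains_base_curve_vertices(self, design):
        base = design["base_curve"].points
        d = np.linalg.norm(surfv := design["mask_surface"].vertices[:, None, :]
                           - base[None], axis=2).min(axis=0)
        assert d.max() < 1e-12

    def test_normals_point_away_from_face(self, design, ref):
        surf = design["mask_surface"]
        # probe point in the air pocket between face and mask: outward
        # normals must point away from it almost everywhere
        probe = design["filter_base"].center - 30.0 * ref["frame"].anterior
        centers = surf.triangles_center
        normals = surf.face_normals
        out = centers - probe
        out /= np.linalg.norm(out, axis=1)[:, None]
        dots = np.einsum("ij,ij->i", normals, out)
        assert (dots > 0).mean() > 0.95


class TestThicken:
    def _planar_patch(self, w=100.0, n=21):
        g = np.linspace(-w / 2, w / 2, n)
        xx, yy = np.meshgrid(g, g)
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        idx = np.arange(xx.size).reshape(n, n)
        faces = np.concatenate([
            np.column_stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(),
                             idx[1:, 1:].ravel()]),
            np.column_stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(),
                             idx[:-1, 1:].ravel()]),
        ])
        return trimesh.Trimesh(verts, faces, process=False)

    def test_slab_volume(self):
        solid = thicken(self._planar_patch(), 2.0)
        assert boundary_edge_count(solid) == 0
        assert abs(solid.volume - 20000.0) / 20000.0 < 0.01

    def test_closed_input_rejected(self):
        with pytest.raises(BuildError, match="open"):
            thicken(trimesh.creation.box(extents=[10, 10, 10]), 1.0)

    def test_foldover_detected(self):
        # a corrugated sheet whose concave radius is smaller than the offset
        g = np.linspace(0, 20, 60)
        xx, yy = np.meshgrid(g, g)
        patch = self._planar_patch()
        verts = np.column_stack([xx.ravel(), yy.ravel(),
                                 1.5 * np.sin(xx.ravel() * 2.0)])
        wavy = trimesh.Trimesh(verts, patch.faces[:0], process=False)
        idx = np.arange(xx.size).reshape(60, 60)
        faces = np.concatenate([
            np.column_stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(),
                             idx[1:, 1:].ravel()]),
            np.column_stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(),
                             idx[:-1, 1:].ravel()]),
        ])
        wavy = trimesh.Trimesh(verts, faces, process=False)
        with pytest.raises(BuildError, match="thickness"):
            thicken(wavy, 5.0)

    def test_mask_body_watertight_with_2mm_median(self, design):
        body = design["mask_body_plain"]
        assert boundary_edge_count(body) == 0
        assert body.is_winding_consistent
        assert body.volume > 0
        assert 1.8 <= measure_shell_thickness(body) <= 2.2


class TestRim:
    def test_torus_volume_oracle(self):
        tor = sweep_tube(circle(radius=40.0, n=200), 3.0, 32)
        want = 2 * np.pi**2 * 40.0 * 9.0
        assert boundary_edge_count(tor) == 0
        assert abs(tor.volume - want) / want < 0.02

    def test_rim_watertight_and_clear_of_body(self, design, rng):
        rim = design["soft_rim"]
        body = design["mask_body_plain"]
        assert boundary_edge_count(rim) == 0
        lo, hi = rim.bounds
        pts = rng.uniform(lo, hi, size=(20000, 3))
        inside_rim = MeshQuery(rim).contains(pts)
        pin = pts[inside_rim]
        assert len(pin) > 200
        overlap = MeshQuery(body).contains(pin).sum() / len(pin)
        assert overlap < 0.01

    def test_rim_stays_on_seal_line(self, design):
        base = design["base_curve"].points
        _, dist, _ = MeshQuery(design["soft_rim"]).closest_point(base[::10])
        assert dist.min() <= design["config"].rim_tube_radius_mm


class TestConnectionParts:
    def test_four_tabs_watertight_exact_volume(self, design):
        body = design["mask_body_plain"]
        combined = design["mask_body"]
        tabs = design["tabs"]
        assert len(tabs) == 4
        assert boundary_edge_count(combined) == 0
        tab_vol = sum(t.volume for t in tabs)
        assert abs((combined.volume - tab_vol) - body.volume) < 1e-3 * body.volume

    def test_collision_with_filter_port_detected(self, design, ref, face):
        from maskforge.mask_builder import curve_point_at
        cfg = design["config"]
        base = design["base_curve"]
        # a filter port sitting right on the first tab position collides
        tab_point, _ = curve_point_at(base, cfg.connection_positions[0])
        with pytest.raises(BuildError, match="collides"):
            add_connection_parts(design["mask_body_plain"], base,
                                 cfg.connection_positions, cfg, ref["frame"],
                                 filter_center=tab_point)

    def test_distinct_positions_required(self, design, ref):
        cfg = design["config"]
        with pytest.raises(ValueError):
            add_connection_parts(design["mask_body_plain"],
                                 design["base_curve"],
                                 (0.1, 0.1, 0.5, 0.9), cfg, ref["frame"])


class TestScaling:
    def test_landmark_lengths_scale_but_configured_lengths_do_not(self, face):
        from maskforge.contour_curve import attach_to_surface, fit_closed_spline
        from maskforge.reference_geometry import (build_frame,
                                                  compute_control_points,
                                                  compute_planes)
        mesh, lm = face
        s = 1.6
        scaled = trimesh.Trimesh(mesh.vertices * s, mesh.faces, process=False)
        lm_s = lm.transformed(lambda p: p * s)
        planes = compute_planes(lm_s)
        frame = build_frame(planes, lm_s, scaled)
        cps = compute_control_points(lm_s, planes, scaled, frame)
        base = attach_to_surface(fit_closed_spline(cps, 200), scaled,
                                 frame=frame)
        cfg = DesignConfig()
        trans = translate_curve(base, lm_s, frame, cfg.translation_ratio)
        mag = np.linalg.norm(trans.points[0] - base.points[0])
        assert abs(mag - s * 0.5 * np.linalg.norm(lm.Ra - lm.Ntp)) < 1e-6
        fb = place_filter_base(lm_s, planes, frame, cfg)
        assert abs(abs(fb.plane.signed_distance(lm_s.Ntp)) - 20.0) < 1e-9
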