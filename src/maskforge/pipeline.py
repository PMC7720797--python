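"""One-command driver: landmarks + face scan -> printable mask components.

Executes the design steps in order — reference planes and control points,
base components (surface-attached contour curve, filter base), mask
building (translated curve, lofts, shell, soft rim) and mask completion
(connection parts, filter housing) — then exports every printable part
as binary STL together with a machine-readable build report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import trimesh
import yaml

from . import mask_builder as mb
from .contour_curve import attach_to_surface, fit_closed_spline
from .filter_housing import (ASSEMBLY_ORDER, HousingParams, assemble_manifest,
                             generate_housing)
from .io_formats import (LandmarkSet, MaskBuildManifest, boundary_edge_count,
                         read_face_mesh, read_landmarks, read_stl, write_stl)
from .reference_geometry import (ControlPointSet, build_frame,
                                 compute_control_points, compute_planes)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


def load_config(path=None):
    """Read the YAML design config; a ``housing:`` sub-mapping feeds the
    filter-housing parameters."""
    if path is None:
        return mb.DesignConfig(), HousingParams()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("design config must be a mapping")
    housing = data.pop("housing", {})
    return mb.DesignConfig.from_dict(data), HousingParams(**housing)


def _component_filename(name: str, user_id: str | None) -> str:
    stem = name.lower().replace(" ", "_")
    return f"id{user_id}_{stem}.stl" if user_id else f"{stem}.stl"


def design_mask(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                config: mb.DesignConfig | None = None,
                housing_params: HousingParams | None = None,
                control_point_overrides: dict | None = None) -> dict:
    """Run the full design on in-memory inputs.

    Returns a dict with the part meshes (keyed by component name), the
    metrics, and the intermediate geometry (planes, frame, control
    points, curves, filter base).  ``control_point_overrides`` may remap
    any of C1..C6 to designer-chosen coordinates before the contour
    curve is built.
    """
    config = config or mb.DesignConfig()
    housing_params = housing_params or HousingParams()
    stage = "reference geometry"
    result: dict = {"config": config}
    try:
        t0 = time.perf_counter()
        planes = compute_planes(landmarks)
        frame = build_frame(planes, landmarks, mesh)
        control_points = compute_control_points(landmarks, planes, mesh, frame)
        if control_point_overrides:
            pts = {f"C{i + 1}": p for i, p in
                   enumerate(control_points.as_array())}
            for name, xyz in control_point_overrides.items():
                if name not in pts:
                    raise ValueError(f"unknown control point {name!r}")
                pts[name] = np.asarray(xyz, dtype=float)
            control_points = ControlPointSet(**pts)
        log.info("stage %-20s %6.2f s (6 control points)", stage,
                 time.perf_counter() - t0)

        stage = "base components"
        t0 = time.perf_counter()
        sampled = fit_closed_spline(control_points, config.n_samples)
        base = attach_to_surface(sampled, mesh, frame=frame)
        filter_base = mb.place_filter_base(landmarks, planes, frame, config)
        log.info("stage %-20s %6.2f s (curve %d samples)", stage,
                 time.perf_counter() - t0, base.n)

        stage = "mask building"
        t0 = time.perf_counter()
        translated = mb.translate_curve(base, landmarks, frame,
                                        config.translation_ratio)
        surface = mb.build_mask_surface(base, translated, filter_base)
        body = mb.thicken(surface, config.shell_thickness_mm)
        rim = mb.build_rim(base, body, config.rim_tube_radius_mm,
                           config.rim_sections, config.voxel_pitch_mm)
        log.info("stage %-20s %6.2f s (body %.0f mm^3)", stage,
                 time.perf_counter() - t0, body.volume)

        stage = "mask completion"
        t0 = time.perf_counter()
        body_with_tabs, tabs = mb.add_connection_parts(
            body, base, config.connection_positions, config, frame,
            filter_base.center)
        housing = generate_housing(housing_params)
        log.info("stage %-20s %6.2f s (%d housing parts)", stage,
                 time.perf_counter() - t0, len(housing["meshes"]))
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    translation = config.translation_ratio * float(
        np.linalg.norm(landmarks.Ra - landmarks.Ntp))
    metrics = {
        "filter_standoff_mm": float(abs(filter_base.plane.signed_distance(landmarks.Ntp))),
        "translation_magnitude_mm": translation,
        "ra_ntp_distance_mm": float(np.linalg.norm(landmarks.Ra - landmarks.Ntp)),
        "shell_thickness_median_mm": mb.measure_shell_thickness(body),
        "n_control_points": 6,
        "n_connection_parts": len(tabs),
        "grating_open_fraction": housing["open_fraction"],
    }
    result.update(
        planes=planes, frame=frame, control_points=control_points,
        base_curve=base, translated_curve=translated,
        filter_base=filter_base, mask_surface=surface,
        mask_body=body_with_tabs, mask_body_plain=body, soft_rim=rim,
        tabs=tabs, housing=housing, metrics=metrics,
    )
    return result


def run_design(face_path, landmarks_path, out_dir, config_path=None,
               control_point_overrides_path=None,
               user_id: str | None = None) -> MaskBuildManifest:
    """File-level pipeline: read inputs, design, export STLs + report.json.

    Deterministic for fixed inputs and config.  On failure no partial
    outputs are left behind.
    """
    out_dir = Path(out_dir)
    stage = "input validation"
    try:
        config, housing_params = load_config(config_path)
        mesh = read_face_mesh(face_path)
        landmarks = read_landmarks(landmarks_path, mesh=mesh)
        overrides = None
        if control_point_overrides_path:
            overrides = json.loads(Path(control_point_overrides_path).read_text())
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    result = design_mask(mesh, landmarks, config, housing_params,
                         control_point_overrides=overrides)

    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "export"
    try:
        parts = dict(result["housing"]["meshes"])
        parts["Mask body"] = result["mask_body"]
        parts["Soft rim"] = result["soft_rim"]
        paths = {}
        for name in ASSEMBLY_ORDER:
            p = out_dir / _component_filename(name, user_id)
            write_stl(parts[name], p, printable=True)
            written.append(p)
            paths[name] = p
        config_echo = {
            "design": config.to_dict(),
            "housing": {k: v for k, v in vars(housing_params).items()},
            "landmarks": {k: v.tolist() for k, v in landmarks.points.items()},
            "frame": {
                "anterior": result["frame"].anterior.tolist(),
                "superior": result["frame"].superior.tolist(),
            },
            "user_id": user_id,
        }
        manifest = assemble_manifest(
            result["mask_body"], result["soft_rim"], result["housing"]["meshes"],
            paths=paths, metrics=result["metrics"], config=config_echo)
        manifest.to_json(out_dir / "report.json")
        written.append(out_dir / "report.json")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return manifest


# ----------------------------------------------------------------------
# output validation
# ----------------------------------------------------------------------

def _check(checks: list, name: str, passed: bool, detail: str = ""):
    checks.append({"name": name, "passed": bool(passed), "detail": detail})


def validate_outputs(out_dir) -> dict:
    """Re-check a build directory against its own report.

    Verifies that every listed STL parses and is watertight, recomputes
    the filter standoff and shell thickness from the exported geometry,
    and flags drift from the manifest.  Returns a report dict; never
    raises on a failed check.
    """
    out_dir = Path(out_dir)
    checks: list = []
    report_path = out_dir / "report.json"
    if not report_path.exists():
        _check(checks, "report.json present", False, str(report_path))
        return {"checks": checks, "passed": False}
    manifest = MaskBuildManifest.from_json(report_path)

    _check(checks, "component count", len(manifest.components) == 7,
           f"{len(manifest.components)} components listed")
    meshes = {}
    for name, path in manifest.components.items():
        try:
            m = read_stl(path)
            meshes[name] = m
        except Exception as exc:  # noqa: BLE001
            _check(checks, f"{name}: parses as STL", False, str(exc))
            continue
        _check(checks, f"{name}: parses as STL", True)
        # a truncated binary STL can parse as an empty mesh: require an
        # actual solid before calling it watertight
        _check(checks, f"{name}: non-empty solid",
               len(m.faces) >= 4 and m.volume > 0.0,
               f"{len(m.faces)} faces")
        _check(checks, f"{name}: watertight", boundary_edge_count(m) == 0)

    body = meshes.get("Mask body")
    cfg = manifest.config
    if body is not None:
        try:
            thickness = mb.measure_shell_thickness(body)
            want = manifest.metrics.get("shell_thickness_median_mm", 0.0)
            _check(checks, "shell thickness recomputed",
                   abs(thickness - want) < 0.2,
                   f"recomputed {thickness:.3f} mm vs manifest {want:.3f} mm")
        except Exception as exc:  # noqa: BLE001
            _check(checks, "shell thickness recomputed", False, str(exc))
        if "landmarks" in cfg and "frame" in cfg:
            ntp = np.asarray(cfg["landmarks"]["Ntp"], dtype=float)
            ant = np.asarray(cfg["frame"]["anterior"], dtype=float)
            sup = np.asarray(cfg["frame"]["superior"], dtype=float)
            r = float(cfg["design"]["filter_opening_radius_mm"])
            standoff_cfg = manifest.metrics.get("filter_standoff_mm", 0.0)
            center = ntp + standoff_cfg * ant
            v = body.vertices.view(np.ndarray)
            lat = np.cross(sup, ant)
            rel = v - center
            radial = np.sqrt((rel @ lat) ** 2 + (rel @ sup) ** 2)
            # the inner-skin port ring sits bitwise on the opening circle;
            # a tight radial band plus the median shrugs off stray loft
            # vertices that graze the same cylinder elsewhere
            ant_rel = v @ ant - ntp @ ant
            near_port = (np.abs(radial - r) <= 0.01) & (np.abs(ant_rel - standoff_cfg) <= 3.0)
            if near_port.any():
                standoff_geom = float(np.median(ant_rel[near_port]))
                _check(checks, "filter standoff recomputed",
                       abs(standoff_geom - standoff_cfg) < 0.1,
                       f"recomputed {standoff_geom:.3f} mm vs manifest "
                       f"{standoff_cfg:.3f} mm")
            else:
                _check(checks, "filter standoff recomputed", False,
                       "no vertices found on the filter port ring")
    return {"checks": checks, "passed": all(c["passed"] for c in checks)}
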