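import numpy as np
import pytest

from maskforge.contour_curve import attach_to_surface, fit_closed_spline
from maskforge.io_formats import write_landmarks, write_obj
from maskforge.mask_builder import DesignConfig
from maskforge.pipeline import design_mask, run_design
from maskforge.reference_geometry import (build_frame, compute_control_points,
                                          compute_planes)
from maskforge.spatial import MeshQuery
from maskforge.synthetic_face import generate_face


@pytest.fixture(scope="session")
def face():
    """Default symmetric synthetic face scan with its landmark set."""
    return generate_face()


@pytest.fixture(scope="session")
def ref(face):
    """Reference geometry derived from the default face."""
    mesh, lm = face
    planes = compute_planes(lm)
    frame = build_frame(planes, lm, mesh)
    cps = compute_control_points(lm, planes, mesh, frame)
    return {"planes": planes, "frame": frame, "cps": cps,
            "query": MeshQuery(mesh)}


@pytest.fixture(scope="session")
def base_curve(face, ref):
    mesh, _ = face
    sampled = fit_closed_spline(ref["cps"], 200)
    return attach_to_surface(sampled, mesh, frame=ref["frame"])


@pytest.fixture(scope="session")
def design(face):
    """Full in-memory design run with default configuration."""
    mesh, lm = face
    return design_mask(mesh, lm, DesignConfig())


@pytest.fixture(scope="session")
def build_dir(tmp_path_factory, face):
    """File-level pipeline run: STL components plus report.json."""
    mesh, lm = face
    d = tmp_path_factory.mktemp("inputs")
    write_obj(mesh, d / "face.obj")
    write_landmarks(lm, d / "landmarks.json")
    out = d / "out"
    run_design(d / "face.obj", d / "landmarks.json", out)
    return out


@pytest.fixture(scope="session")
def determinism_pair(tmp_path_factory, face):
    """The same design run twice into different directories.

    A coarser rim voxel pitch keeps the double build quick; determinism
    is a property of the whole pipeline, not of the grid resolution.
    """
    mesh, lm = face
    d = tmp_path_factory.mktemp("det")
    write_obj(mesh, d / "face.obj")
    write_landmarks(lm, d / "landmarks.json")
    (d / "config.yaml").write_text("voxel_pitch_mm: 1.0\n")
    outs = []
    for sub in ("a", "b"):
        out = d / sub
        run_design(d / "face.obj", d / "landmarks.json", out,
                   config_path=d / "config.yaml")
        outs.append(out)
    return tuple(outs)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
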