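"""Simplified parametric seven-part screw-drive filter housing.

The printed mask assembly has seven parts: washer, soft rim, mask body,
grating, inner filter cover, outer filter cover and female locking ring.
The five housing parts generated here are dimensioned to nest
concentrically inside the mask's filter opening with a configurable
radial clearance; screw threads are approximated by smooth press-fit
cylinders (the original housing came from an online STL with no printed
dimensions, so the thread geometry is not reproducible and is not part
of the design algorithm).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import trimesh

from .io_formats import boundary_edge_count, MaskBuildManifest
from .spatial import ensure_outward

#: the seven printed components in assembly order
ASSEMBLY_ORDER = (
    "Washer",
    "Soft rim",
    "Mask body",
    "Grating",
    "Inner filter cover",
    "Outer filter cover",
    "Female",
)

#: how the screw-drive system goes together, step by step
ASSEMBLY_STEPS = (
    "insert the washer into the mask opening until it locks",
    "screw the grating onto the washer to fixate it to the mask",
    "insert the inner cover into the washer",
    "place the filter",
    "place the outer cover",
    "screw the female part onto the washer to close the system",
)


class HousingError(ValueError):
    pass


@dataclass(frozen=True)
class HousingParams:
    """Dimensions of the filter housing (mm).

    ``washer_outer_radius`` must clear the mask's filter opening; the
    remaining parts nest inward from the washer bore, each separated by
    ``clearance``.
    """

    washer_outer_radius: float = 26.0
    washer_wall: float = 5.0
    washer_height: float = 8.0
    grating_thickness: float = 2.0
    grating_rim_width: float = 2.7
    grating_hub_radius: float = 4.0
    grating_spokes: int = 8
    grating_spoke_width: float = 2.5
    cover_disc_thickness: float = 2.0
    cover_skirt_height: float = 6.0
    cover_skirt_wall: float = 1.5
    female_wall: float = 2.7
    female_height: float = 6.0
    clearance: float = 0.3
    sections: int = 128

    def __post_init__(self):
        if self.clearance <= 0:
            raise HousingError("clearance must be positive")
        for name, val in asdict(self).items():
            if name != "sections" and val <= 0:
                raise HousingError(f"{name} must be positive")
        if self.washer_wall >= self.washer_outer_radius:
            raise HousingError("washer wall swallows the bore")

    # nested radii, outermost to innermost
    @property
    def washer_inner_radius(self) -> float:
        return self.washer_outer_radius - self.washer_wall

    @property
    def grating_outer_radius(self) -> float:
        return self.washer_inner_radius - self.clearance

    @property
    def inner_cover_radius(self) -> float:
        return self.grating_outer_radius - self.clearance

    @property
    def outer_cover_radius(self) -> float:
        return self.inner_cover_radius - self.clearance

    @property
    def female_inner_radius(self) -> float:
        return self.washer_outer_radius + self.clearance

    @property
    def female_outer_radius(self) -> float:
        return self.female_inner_radius + self.female_wall

    def nested_pairs(self):
        """(name, bore radius, inserted part radius) for clearance checks."""
        return (
            ("washer/grating", self.washer_inner_radius, self.grating_outer_radius),
            ("grating/inner cover", self.grating_outer_radius, self.inner_cover_radius),
            ("inner cover/outer cover", self.inner_cover_radius, self.outer_cover_radius),
            ("female/washer", self.female_inner_radius, self.washer_outer_radius),
        )

    def validate_nesting(self):
        radii = [
            self.female_outer_radius,
            self.female_inner_radius,
            self.washer_outer_radius,
            self.washer_inner_radius,
            self.grating_outer_radius,
            self.inner_cover_radius,
            self.outer_cover_radius,
        ]
        if not all(a > b for a, b in zip(radii, radii[1:])):
            raise HousingError(
                f"nested radii must decrease strictly inward, got {radii}"
            )
        if self.grating_hub_radius >= self.grating_outer_radius - self.grating_rim_width:
            raise HousingError("grating hub reaches its rim; no aperture left")


def _annulus(r_in: float, r_out: float, height: float, sections: int) -> trimesh.Trimesh:
    return trimesh.creation.annulus(r_min=r_in, r_max=r_out, height=height,
                                    sections=sections)


def _grating(p: HousingParams) -> tuple[trimesh.Trimesh, float]:
    """Perforated disc: outer rim + hub + radial spokes.

    Returns the mesh and the open-area fraction of the disc footprint.
    """
    r_out = p.grating_outer_radius
    r_ap = r_out - p.grating_rim_width  # aperture outer radius
    h = p.grating_thickness
    parts = [_annulus(r_ap, r_out, h, p.sections)]
    hub = trimesh.creation.cylinder(radius=p.grating_hub_radius, height=h,
                                    sections=p.sections)
    parts.append(hub)
    span = r_ap - p.grating_hub_radius
    # spokes reach one radius-step into hub and rim so the printed part is
    # solidly connected (plain tangency would join only along a line)
    reach = 1.0
    for k in range(p.grating_spokes):
        spoke = trimesh.creation.box(
            extents=[span + 2 * reach, p.grating_spoke_width, h])
        ang = 2.0 * np.pi * k / p.grating_spokes
        T = trimesh.transformations.rotation_matrix(ang, [0, 0, 1])
        spoke.apply_translation([p.grating_hub_radius + span / 2.0, 0, 0])
        spoke.apply_transform(T)
        parts.append(spoke)
    solid_area = (
        np.pi * (r_out**2 - r_ap**2)
        + np.pi * p.grating_hub_radius**2
        + p.grating_spokes * p.grating_spoke_width * span
    )
    open_fraction = 1.0 - solid_area / (np.pi * r_out**2)
    return trimesh.util.concatenate(parts), float(open_fraction)


def _capped_disc(radius: float, p: HousingParams) -> trimesh.Trimesh:
    """Cover: flat disc with a cylindrical skirt, as one revolved solid
    (concatenating disc and skirt would leave a non-manifold seam)."""
    r_in = radius - p.cover_skirt_wall
    profile = np.array([
        [0.0, p.cover_disc_thickness],
        [radius, p.cover_disc_thickness],
        [radius, -p.cover_skirt_height],
        [r_in, -p.cover_skirt_height],
        [r_in, 0.0],
        [0.0, 0.0],
    ])
    cover = trimesh.creation.revolve(profile, sections=p.sections)
    return ensure_outward(cover)


def generate_housing(params: HousingParams = HousingParams()) -> dict:
    """Generate the five housing solids.

    Returns ``{"meshes": {name: Trimesh}, "open_fraction": float,
    "radii": {...}}``; every mesh is watertight.
    """
    p = params
    p.validate_nesting()
    grating, open_fraction = _grating(p)
    meshes = {
        "Washer": _annulus(p.washer_inner_radius, p.washer_outer_radius,
                           p.washer_height, p.sections),
        "Grating": grating,
        "Inner filter cover": _capped_disc(p.inner_cover_radius, p),
        "Outer filter cover": _capped_disc(p.outer_cover_radius, p),
        "Female": _annulus(p.female_inner_radius, p.female_outer_radius,
                           p.female_height, p.sections),
    }
    for name, mesh in meshes.items():
        if boundary_edge_count(mesh) != 0:
            raise HousingError(f"{name} generated non-watertight")
    return {
        "meshes": meshes,
        "open_fraction": open_fraction,
        "radii": {
            "washer_outer": p.washer_outer_radius,
            "washer_inner": p.washer_inner_radius,
            "grating_outer": p.grating_outer_radius,
            "inner_cover": p.inner_cover_radius,
            "outer_cover": p.outer_cover_radius,
            "female_inner": p.female_inner_radius,
            "female_outer": p.female_outer_radius,
        },
    }


def assemble_manifest(mask_body: trimesh.Trimesh, soft_rim: trimesh.Trimesh,
                      housing_parts: dict, paths: dict | None = None,
                      metrics: dict | None = None,
                      config: dict | None = None) -> MaskBuildManifest:
    """Validate the seven printed parts and build the ordered manifest.

    ``housing_parts`` maps the five housing names to meshes.  Raises if a
    part is missing or not watertight.
    """
    all_parts = dict(housing_parts)
    all_parts["Mask body"] = mask_body
    all_parts["Soft rim"] = soft_rim
    for name in ASSEMBLY_ORDER:
        mesh = all_parts.get(name)
        if mesh is None:
            raise HousingError(f"missing component: {name}")
        if boundary_edge_count(mesh) != 0:
            raise HousingError(f"component not watertight: {name}")
    metrics = dict(metrics or {})
    metrics["n_components"] = len(ASSEMBLY_ORDER)
    paths = paths or {}
    return MaskBuildManifest(
        components={name: str(paths.get(name, "")) for name in ASSEMBLY_ORDER},
        metrics=metrics,
        assembly_order=list(ASSEMBLY_ORDER),
        config=dict(config or {}),
    )
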