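# maskforge

Fully automatic design of 3D-printable **face-specific respirator masks**
from a facial surface scan and nine anatomical landmarks.

Universal masks leak: a rigid standard shape cannot seal both the nasal
bridge and the chin of an individual face, and continuous wear causes
pressure sores. `maskforge` implements an automatic CAD pipeline for
patient-specific masks: given a stereophotogrammetric face scan (OBJ, mm)
and nine soft-tissue landmarks — the four eye canthi Ex(r)/En(r)/En(l)/Ex(l),
radix Ra, nasal tip Ntp, philtral crest Pc, pogonion Pg, menton M — it

1. constructs nine reference planes (midsagittal MF through Ra, Ntp, Pg;
   a vertical plane VP through the canthi ⊥ MF; a horizontal plane HP
   through Ra ⊥ MF, VP; and parallels of these through Pc, Pg, the
   canthi and the canthus midpoints),
2. derives six seal-line control points (C1 = Ra, C4 = M, and four
   plane-pair ∧ face-surface intersections on the cheeks and chin),
3. fits a closed periodic spline through C1…C6 and attaches it to the
   face surface (the seal line),
4. lofts the mask body from the seal line over an anteriorly translated
   copy (offset = ½·‖Ra − Ntp‖, clearing the nasal dorsum) to a circular
   filter port 20 mm anterior of the nasal tip, shells it to 2 mm,
5. builds a soft seal rim (tube sweep along the seal line minus the
   body) and four strap-anchor tabs, and
6. generates a simplified seven-part screw-drive filter housing,

exporting every printable component as watertight binary STL together
with a machine-readable `report.json`. A parametric synthetic-face
generator with analytically known landmarks makes the whole pipeline
testable without any scan data.

See `docs/methods.md` for the geometry and the design decisions.

## Worked example

```bash
# a synthetic face scan with known landmarks
maskforge synth-face --out face.obj --landmarks lm.json --seed 1

# design the mask
maskforge -v design --face face.obj --landmarks lm.json --out build/
```

which prints:

```
wrote 7 components to build/
  filter_standoff_mm = 20.000
  translation_magnitude_mm = 24.284
  shell_thickness_median_mm = 2.000
```

`build/` now holds `washer.stl`, `soft_rim.stl`, `mask_body.stl`,
`grating.stl`, `inner_filter_cover.stl`, `outer_filter_cover.stl`,
`female.stl` and `report.json`. The metrics mean: the filter-port plane
sits exactly 20 mm anterior of the nasal tip; the translated seal curve
was moved 24.284 mm — half of this face's 48.57 mm radix-to-nasal-tip
distance; and the median wall thickness of the shelled body, re-measured
by inward ray casting, is 2.000 mm. `report.json` lists the seven
components in assembly order (washer, soft rim, mask body, grating,
inner cover, outer cover, female locking ring) with these metrics.

`maskforge validate build/` re-opens the outputs and re-derives the
metrics from the exported geometry; `maskforge housing` regenerates the
filter-housing parts alone. Designer interaction is available through a
YAML config (shell thickness, standoff, rim radius, tab positions, …)
and `--override-control-points` for relocating any of C1…C6.

The same API is available from Python:

```python
from maskforge import FaceParams, generate_face, design_mask

mesh, landmarks = generate_face(FaceParams(seed=1))
result = design_mask(mesh, landmarks)
print(result["metrics"]["filter_standoff_mm"])   # 20.0
```

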