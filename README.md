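# lidckit

Convert multi-reader lung-nodule annotations in the LIDC XML dialect into
standard DICOM objects: one **Segmentation (SEG)** and one **SR TID 1500
measurement report** per annotation.

The LIDC-IDRI CT collection ships its nodule annotations as
project-specific XML — per reading session, per nodule, per slice, an
ordered list of contour points tracing the pixels *just outside* the
nodule, plus nine subjective ratings (subtlety, internal structure,
calcification, sphericity, margin, lobulation, spiculation, texture,
malignancy) encoded as bare numbers.  That representation is not
self-describing and is easy to misread (a common bug is counting the
contour pixels as nodule).  This package re-encodes it into standard,
self-contained DICOM: masks aligned to the CT frame of reference, coded
semantics for every score, measurements with UCUM units, and tracking
identifiers linking every object describing the same physical nodule.

It is aimed at imaging researchers who want LIDC-style annotations usable
by generic DICOM tools (viewers, archives, query layers) without
collection-specific parsing code.

## What it computes

- **Strict-interior rasterization.** A pixel is nodule iff its center is
  inside the closed contour polygon (even-odd rule) and not exactly on the
  contour path; per slice the region is ∪(included interiors) ∖
  ∪(excluded interiors).  Evaluated in exact integer arithmetic.
- **Nodule clustering.** Single-linkage connected components over the
  minimum patient-space distance between annotations' contour point sets,
  at tolerance τ (default: one slice step).  Each cluster = one nodule,
  numbered by first appearance, with one tracking UID shared by all
  members.
- **Measurements** per annotation mask *M* with voxel spacing
  (s_r, s_c, s_z):
  - diameter = max over slices of max pairwise in-plane distance between
    boundary pixel centers (coded M-02550/SRT, unit mm/UCUM);
  - surface area = Σ triangle areas of the marching-cubes isosurface at
    level 0.5 (C0JK/IBSI "Surface area of mesh", mm2/UCUM);
  - volume = |M| · s_r s_c s_z (G-D705/SRT, mm3/UCUM).
- **Encoding.** Binary single-segment SEG (frames only for non-empty
  slices, per-frame plane positions and source-slice references, CIELab
  display colors, segment semantics *Morphologically Altered
  Structure / Nodule / Lung*) and a TID 1500 SR with one measurement group
  carrying the coded evaluations and the three measurements.

See `docs/methods.md` for conventions and `docs/codes.md` for the full
coding dictionary.

## Worked example

Generate a synthetic scan (two spherical nodules annotated by three
readers each, plus one center-only mark), convert it, and validate:

```python
from lidckit.synthetic import PhantomSpec, NoduleSpec, generate_ct_series, generate_annotations
from lidckit.geometry import build_geometry
from lidckit.pipeline import convert_scan, validate_collection, ConversionParams

spec = PhantomSpec(
    image_shape=(128, 128), pixel_spacing=(0.7, 0.7), slice_step=2.5, n_slices=20,
    nodules=(
        NoduleSpec(center_mm=(30, 30, 20), radius_mm=8, n_readers=3, jitter_mm=0.5),
        NoduleSpec(center_mm=(62, 62, 30), radius_mm=6, n_readers=3, jitter_mm=0.5),
    ),
    center_only_marks=((45.0, 20.0, 25.0),),
    seed=7,
)
generate_ct_series(spec, "scan/ct")
g = build_geometry("scan/ct")
generate_annotations(spec, g, "scan/annotations.xml")

m = convert_scan("scan/ct", "scan/annotations.xml", "scan/out", ConversionParams(seed=3))
print(m.n_annotations_parsed, m.n_volumetric, m.n_clusters, m.n_seg_written, m.n_sr_written)
print(validate_collection("scan/out", ct_dirs={m.subject: "scan/ct"}).checks)
```

prints

```
7 6 2 6 6
{'correspondence': True, 'code_dictionary_closure': True, 'tracking_consistency': True, 'decode_roundtrip': True, 'iod_conformance': True}
```

i.e. 7 annotations parsed, 6 volumetric (the center-only mark is excluded),
2 nodule clusters, 6 SEG + 6 SR objects written — one pair per annotation —
and all five collection-level consistency checks pass.  Each SEG's
SeriesDescription reads e.g. `Nodule 1 - Annotation 101`, and its SR
carries the same tracking UID plus 9 coded evaluations and 3 measurements.

The same pipeline is available from a shell:

```sh
lidckit phantom --spec spec.json --out scan
lidckit convert --ct-dir scan/ct --xml scan/annotations.xml --out scan/out --seed 3
lidckit validate --dir scan/out
```

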