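# Methods

## The conversion problem

Multi-reader lung-nodule annotations in the LIDC dialect are stored as
project-specific XML: per reading session (one per radiologist, identity
withheld), per nodule, per CT slice, an ordered list of image-relative
contour points plus nine subjective characteristic ratings.  The contours
follow a convention that is easy to get wrong downstream: the listed points
trace the pixels *just outside* the nodule, so the contour pixels must
never be counted as nodule tissue.  `lidckit` converts these files into
self-describing standard objects: one DICOM Segmentation (SEG) and one
DICOM SR TID 1500 measurement report per annotation, aligned to the source
CT frame of reference and linked to each other and to the source images by
explicit identifiers.

Only volumetrically contoured nodules are converted.  Findings marked by a
single center-of-mass point (nodules under 3 mm and non-nodules) are parsed
structurally but never encoded; the manifest counts them as exclusions.

## Rasterization: the strict interior

A pixel belongs to a contour's region when its center lies inside the
closed polygon through the contour pixel centers (even-odd rule) **and**
the center is not exactly on any polygon edge.  Both conditions are
evaluated in exact integer arithmetic (cross/dot products on integer
coordinates for the on-edge test; the half-open `[y1, y2)` rule per edge
for crossing parity), so there are no floating-point boundary surprises.
Per slice, the region is the union of included strict interiors minus the
union of excluded strict interiors.  Exclusion contours mirror the
inclusion convention — their own pixels lie outside the excluded region —
which the source convention does not state explicitly; it is this package's
documented choice.  Slices carrying only excluded contours contribute
nothing rather than erroring.  A self-intersecting contour is filled under
the even-odd rule with a warning; a contour whose distinct points are
collinear is rejected as degenerate.  A closing repeat of the first point
is accepted and ignored.

## Geometry

Voxel index convention, fixed package-wide: `(i, j, k)` = (column, row,
slice).  Column index advances along the row direction cosines with the
column spacing, row index along the column cosines with the row spacing;
slices are sorted by patient-space position along the slice normal, never
by file name or instance number.  Series that are non-axial, tilted,
inconsistently spaced, or that have a non-uniform slice step (tolerance
0.01 mm, configurable) are rejected: silent contour mis-binding is worse
than refusal.  The voxel-to-patient mapping round-trips to better than
1e-6 mm.

## Clustering into nodules

The public annotations carry no nodule identity, so annotations of one
scan are grouped by spatial proximity: single-linkage connected components
of the graph joining annotation pairs whose minimum patient-space distance
between contour point sets is at or below a tolerance.  The tolerance
defaults to the scan's slice step — proximity on the order of one slice
separation is the natural scale when no threshold is prescribed — and is a
CLI parameter.  Clusters are numbered 1..K by first appearance in document
order and each receives one freshly minted tracking UID shared by all
members.  Clusters larger than four members (more than the maximum reader
count) are legal; they are flagged in the manifest as possibly needing
manual regrouping, never split automatically.  Equivalence with the
clustering used to produce the published collection is not guaranteed,
since that threshold and metric are not printed anywhere we can verify.

## Measurements

* **Diameter** (mm): maximal in-plane dimension — per slice, the maximum
  pairwise patient-space distance between foreground boundary pixel
  centers, maximized over slices.  Boundary pixels suffice because the
  farthest pair of a finite pixel set lies on its boundary; a convex hull
  prunes the pair search.  The in-plane framing matches how the source
  collection defines nodule size (greatest in-plane dimension, 3–30 mm);
  a result above 30 mm warns but does not fail.
* **Surface area** (mm²): triangle-area sum of a marching-cubes isosurface
  extracted at level 0.5 from the zero-padded binary volume with voxel
  spacing applied.  On digitized spheres this estimator carries a known
  positive bias of roughly 6–8% that is scale-free, so its relative error
  plateaus rather than vanishing with radius; it stays within ±10% for
  radii ≥ 5 mm at 1 mm voxels.
* **Volume** (mm³): foreground voxel count × voxel volume.  The simplest
  defensible estimator; accurate to ~2% for spheres of radius ≥ 5 mm at
  1 mm voxels, with error decreasing as the radius grows.

The estimators behind the published collection's numbers are not fully
specified, so exact numeric agreement with distributed SR values is not
claimed; the coded concepts and units are.

## Encoding conventions

One annotation → one binary single-segment SEG plus one SR.  Annotations
are never merged into multi-segment objects because reader identity is
unknown.  SeriesDescription, SegmentLabel, SegmentDescription and
TrackingID all read `Nodule <n> - Annotation <id>`.  Segment semantics are
constant — category *Morphologically Altered Structure*, type *Nodule*,
anatomy *Lung* — emitted as SRT identifiers by default (matching the
published collection, which predates the SRT→SCT transition) with an
option for SCT numeric codes.  Only non-empty slices become frames; each
frame stores its plane position and a reference to its source CT slice.
The further cuboid bounding-box crop permitted by the standard is not
performed.  Display colors come from a fixed 12-color high-saturation
palette indexed by the annotation's ordinal within its cluster; they are
pairwise distinct within a nodule and carry no meaning beyond
visualization.  Colors are stored as 16-bit scaled CIELab with D50
reference white, computed from sRGB via Bradford chromatic adaptation
(D65→D50), so white maps exactly to (0xFFFF, 0x8080, 0x8080).

The SR content tree is a TID 1500 measurement report with exactly one
measurement group carrying: the SEG's tracking ID/UID, an IMAGE reference
to the SEG instance and segment number, a UIDREF to the source CT series,
finding type *Nodule* (set on the group; the SEG's anatomy code carries
the site), all present qualitative evaluations as coded name-value pairs
(never free text — self-contained score semantics are the point of the
conversion), and the three measurements with UCUM units.  Numeric values
are serialized at up to 6 significant digits, and measurement groups carry
values at that precision so encode/decode round-trips are exact.

Coding dictionary: nine characteristics with the documented rating scales
(1–5 ordinals; 1–4 internal structure; 1–6 calcification), value meanings
in the `"n out of 5 (<label>)"` style, private codes under the
`99LIDCQIICR` scheme, standard codes (SRT/SCT, UCUM, IBSI) where they
exist.  The dictionary ships as editable YAML (`src/lidckit/data/codes.yaml`,
schema in its header) and is rendered as a reference table in
`docs/codes.md`.  It is semantically faithful to the published collection's
private-code table but not byte-identical to it, which is documented
rather than guessed.  The characteristic names follow the XML attribute
names (`calcification`, `texture`, …) where prose descriptions of the nine
attributes sometimes use synonyms ("shape", "solidity").

UIDs are hierarchical, minted under a configurable root; with a seed the
UID sequence is a pure function of (root, seed), making conversions
reproducible.

## Validation

Two layers.  `validate_seg` / `validate_sr` are an attribute-level IOD and
template checker, independent of the writer code paths: explicit
requirement tables (required attributes, binary-segmentation pixel
constraints, frame/functional-group consistency, code-triplet
completeness, UID validity, content-tree structure, UCUM-only units).
`validate_collection` then checks a converted output tree: 1:1
annotation↔SEG↔SR correspondence against each scan's manifest, dictionary
closure of every emitted evaluation code, SEG↔SR tracking-pair agreement,
decode round-trips on a sample, and zero IOD-checker errors for every
object.  Conversion uses per-annotation fault isolation: a defective
annotation is skipped with a warning tallied in the manifest so one bad
record cannot mask the rest of a batch.

## The synthetic phantom

The generator emulates exactly what the converter consumes: a
geometrically consistent per-slice CT series (uniform −1000 HU background,
+40 HU spheres; intensity is irrelevant to conversion correctness) and a
dialect-faithful XML file.  Contours are produced the way the collection
drew them: for each slice cross-section of a digitized sphere, the ring of
pixels 8-adjacent to—but outside—the disc, ordered by angle, so the strict
interior recovers the digitized disc.  Reader variability is a seeded
uniform radius perturbation (± jitter, default 0.5 mm in the standard
study scan), i.e. a small dilation/erosion of the ring.  Characteristics
are taken from the phantom spec or sampled uniformly over each documented range,
seeded.  Center-only marks exercise the volumetric-selection rule.  A
fixed seed yields byte-identical DICOM and XML output.

What the phantom does **not** emulate: real lung texture and anatomy,
non-spherical or lobulated nodule shapes, inter-reader disagreement beyond
radius jitter, multi-part contours, excluded-region annotations (those are
covered by construction in unit fixtures rather than the phantom), and
non-axial acquisitions.  Passing tests therefore demonstrate the
correctness of the conversion machinery on geometrically known input, not
robustness to the full variability of clinical data.

Standard problem sizes used by the test suite and the acceptance script:
a 128×128×20 scan at (0.7, 0.7, 2.5) mm with two nodules (8 and 6 mm
radius) × three readers plus one center-only mark, and 64×64×40 scans at
1 mm isotropic voxels with single spheres of radius 5, 8 and 12 mm.

## Known limitations

* Non-nodule and sub-3 mm center-only marks are parsed but never encoded.
* Clustering equivalence with the published collection is not guaranteed
  (threshold unpublished); headline collection statistics (875 subjects,
  6859 annotations, 2651 nodules) require the full TCIA download and are
  out of desk-scale test scope.
* The conformance checker is structural; it does not re-implement every
  conditional rule of the standard's IOD tables.
* One SEG series per annotation object is emitted; whether the published
  collection shared series across objects is not fully specified.
* Fractional (probability-map) segmentations and compressed transfer
  syntaxes are out of scope.
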