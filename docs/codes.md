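# Coding reference

Reference table of every coded concept the converter emits, generated
from the shipped dictionary (`src/lidckit/data/codes.yaml`).

## Segmentation semantics (constant for every segment)

| Role | SRT form | SCT form | Meaning |
|---|---|---|---|
| Category | (M-01000, SRT) | (49755003, SCT) | Morphologically Altered Structure |
| Type | (M-03010, SRT) | (27925004, SCT) | Nodule |
| Anatomy | (T-28000, SRT) | (39607008, SCT) | Lung |

## Measurements

| Measurement | Concept | Unit |
|---|---|---|
| diameter | (M-02550, SRT, "Diameter") | (mm, UCUM) |
| surface_area | (C0JK, IBSI, "Surface area of mesh") | (mm2, UCUM) |
| volume | (G-D705, SRT, "Volume") | (mm3, UCUM) |

## Qualitative evaluations

Concepts and value sets use the private `99LIDCQIICR` scheme (the `99`
prefix marks a nonstandard coding scheme in DICOM).

### subtlety — concept (C45992, 99LIDCQIICR, "Subtlety score")

| Rating | Value code | Meaning |
|---|---|---|
| 1 | 300 | 1 out of 5 (Extremely Subtle) |
| 2 | 301 | 2 out of 5 (Moderately Subtle) |
| 3 | 302 | 3 out of 5 (Fairly Subtle) |
| 4 | 303 | 4 out of 5 (Moderately Obvious) |
| 5 | 304 | 5 out of 5 (Obvious) |

### internalStructure — concept (C45993, 99LIDCQIICR, "Internal structure")

| Rating | Value code | Meaning |
|---|---|---|
| 1 | 310 | Soft Tissue |
| 2 | 311 | Fluid |
| 3 | 312 | Fat |
| 4 | 313 | Air |

### calcification — concept (C45994, 99LIDCQIICR, "Calcification")

| Rating | Value code | Meaning |
|---|---|---|
| 1 | 320 | Popcorn |
| 2 | 321 | Laminated |
| 3 | 322 | Solid |
| 4 | 323 | Non-central |
| 5 | 324 | Central |
| 6 | 325 | Absent |

### sphericity — concept (C45995, 99LIDCQIICR, "Sphericity")

| Rating | Value code | Meaning |
|---|---|---|
| 1 | 330 | 1 out of 5 (Linear) |
| 2 | 331 | 2 out of 5 (Ovoid/Linear) |
| 3 | 332 | 3 out of 5 (Ovoid) |
| 4 | 333 | 4 out of 5 (Ovoid/Round) |
| 5 | 334 | 5 out of 5 (Round) |

### margin — concept (C45996, 99LIDCQIICR, "Margin")

| Rating | Value code | Meaning |
|---|---|---|
| 1 | 340 | 1 out of 5 (Poorly Defined) |
| 2 | 341 | 2 out of 5 (Near Poorly Defined) |
| 3 | 342 | 3 out of 5 (Medium Margin) |
| 4 | 343 | 4 out of 5 (Near Sharp) |
| 5 | 344 | 5 out of 5 (Sharp) |

### lobulation — concept (C45997, 99LIDCQIICR, "Lobulation")

| Rating | Value code | Meaning |
|---|---|---|
| 1 | 350 | 1 out of 5 (No Lobulation) |
| 2 | 351 | 2 out of 5 (Nearly No Lobulation) |
| 3 | 352 | 3 out of 5 (Medium Lobulation) |
| 4 | 353 | 4 out of 5 (Near Marked Lobulation) |
| 5 | 354 | 5 out of 5 (Marked Lobulation) |

### spiculation — concept (C45998, 99LIDCQIICR, "Spiculation")

| Rating | Value code | Meaning |
|---|---|---|
| 1 | 360 | 1 out of 5 (No Spiculation) |
| 2 | 361 | 2 out of 5 (Nearly No Spiculation) |
| 3 | 362 | 3 out of 5 (Medium Spiculation) |
| 4 | 363 | 4 out of 5 (Near Marked Spiculation) |
| 5 | 364 | 5 out of 5 (Marked Spiculation) |

### texture — concept (C45999, 99LIDCQIICR, "Texture")

| Rating | Value code | Meaning |
|---|---|---|
| 1 | 370 | 1 out of 5 (Non-Solid/Ground-Glass Opacity) |
| 2 | 371 | 2 out of 5 (Non-Solid/Mixed) |
| 3 | 372 | 3 out of 5 (Part Solid/Mixed) |
| 4 | 373 | 4 out of 5 (Solid/Mixed) |
| 5 | 374 | 5 out of 5 (Solid) |

### malignancy — concept (C46000, 99LIDCQIICR, "Malignancy")

| Rating | Value code | Meaning |
|---|---|---|
| 1 | 380 | 1 out of 5 (Highly Unlikely for Cancer) |
| 2 | 381 | 2 out of 5 (Moderately Unlikely for Cancer) |
| 3 | 382 | 3 out of 5 (Indeterminate Likelihood) |
| 4 | 383 | 4 out of 5 (Moderately Suspicious for Cancer) |
| 5 | 384 | 5 out of 5 (Highly Suspicious for Cancer) |

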