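# Coding dictionary for nodule segmentation semantics, qualitative
# evaluations and quantitative measurements.
#
# Schema
# ------
# Every coded item is a triplet {value, scheme, meaning}.
#   segmentation_semantics: category/type/anatomy triple, each with an
#     "srt" and an "sct" form of the same SNOMED concept.
#   measurements: per measurement, a concept triplet and a UCUM unit triplet.
#   characteristics: per XML attribute name, a concept triplet plus an
#     ordered value set, one coded value per documented rating.  Private
#     concepts/values use the 99LIDCQIICR scheme ("99" marks a nonstandard
#     coding scheme in DICOM).
#
# The rating scales follow the collection's documented ranges: 1-5 ordinals
# for subtlety, sphericity, margin, lobulation, spiculation, texture and
# malignancy; 1-4 categories for internal structure; 1-6 for calcification.

segmentation_semantics:
  category:
    srt: {value: "M-01000", scheme: "SRT", meaning: "Morphologically Altered Structure"}
    sct: {value: "49755003", scheme: "SCT", meaning: "Morphologically Altered Structure"}
  type:
    srt: {value: "M-03010", scheme: "SRT", meaning: "Nodule"}
    sct: {value: "27925004", scheme: "SCT", meaning: "Nodule"}
  anatomy:
    srt: {value: "T-28000", scheme: "SRT", meaning: "Lung"}
    sct: {value: "39607008", scheme: "SCT", meaning: "Lung"}

measurements:
  diameter:
    concept: {value: "M-02550", scheme: "SRT", meaning: "Diameter"}
    unit: {value: "mm", scheme: "UCUM", meaning: "millimeter"}
  surface_area:
    concept: {value: "C0JK", scheme: "IBSI", meaning: "Surface area of mesh"}
    unit: {value: "mm2", scheme: "UCUM", meaning: "square millimeter"}
  volume:
    concept: {value: "G-D705", scheme: "SRT", meaning: "Volume"}
    unit: {value: "mm3", scheme: "UCUM", meaning: "cubic millimeter"}

characteristics:
  subtlety:
    concept: {value: "C45992", scheme: "99LIDCQIICR", meaning: "Subtlety score"}
    values:
      1: {value: "300", scheme: "99LIDCQIICR", meaning: "1 out of 5 (Extremely Subtle)"}
      2: {value: "301", scheme: "99LIDCQIICR", meaning: "2 out of 5 (Moderately Subtle)"}
      3: {value: "302", scheme: "99LIDCQIICR", meaning: "3 out of 5 (Fairly Subtle)"}
      4: {value: "303", scheme: "99LIDCQIICR", meaning: "4 out of 5 (Moderately Obvious)"}
      5: {value: "304", scheme: "99LIDCQIICR", meaning: "5 out of 5 (Obvious)"}
  internalStructure:
    concept: {value: "C45993", scheme: "99LIDCQIICR", meaning: "Internal structure"}
    values:
      1: {value: "310", scheme: "99LIDCQIICR", meaning: "Soft Tissue"}
      2: {value: "311", scheme: "99LIDCQIICR", meaning: "Fluid"}
      3: {value: "312", scheme: "99LIDCQIICR", meaning: "Fat"}
      4: {value: "313", scheme: "99LIDCQIICR", meaning: "Air"}
  calcification:
    concept: {value: "C45994", scheme: "99LIDCQIICR", meaning: "Calcification"}
    values:
      1: {value: "320", scheme: "99LIDCQIICR", meaning: "Popcorn"}
      2: {value: "321", scheme: "99LIDCQIICR", meaning: "Laminated"}
      3: {value: "322", scheme: "99LIDCQIICR", meaning: "Solid"}
      4: {value: "323", scheme: "99LIDCQIICR", meaning: "Non-central"}
      5: {value: "324", scheme: "99LIDCQIICR", meaning: "Central"}
      6: {value: "325", scheme: "99LIDCQIICR", meaning: "Absent"}
  sphericity:
    concept: {value: "C45995", scheme: "99LIDCQIICR", meaning: "Sphericity"}
    values:
      1: {value: "330", scheme: "99LIDCQIICR", meaning: "1 out of 5 (Linear)"}
      2: {value: "331", scheme: "99LIDCQIICR", meaning: "2 out of 5 (Ovoid/Linear)"}
      3: {value: "332", scheme: "99LIDCQIICR", meaning: "3 out of 5 (Ovoid)"}
      4: {value: "333", scheme: "99LIDCQIICR", meaning: "4 out of 5 (Ovoid/Round)"}
      5: {value: "334", scheme: "99LIDCQIICR", meaning: "5 out of 5 (Round)"}
  margin:
    concept: {value: "C45996", scheme: "99LIDCQIICR", meaning: "Margin"}
    values:
      1: {value: "340", scheme: "99LIDCQIICR", meaning: "1 out of 5 (Poorly Defined)"}
      2: {value: "341", scheme: "99LIDCQIICR", meaning: "2 out of 5 (Near Poorly Defined)"}
      3: {value: "342", scheme: "99LIDCQIICR", meaning: "3 out of 5 (Medium Margin)"}
      4: {value: "343", scheme: "99LIDCQIICR", meaning: "4 out of 5 (Near Sharp)"}
      5: {value: "344", scheme: "99LIDCQIICR", meaning: "5 out of 5 (Sharp)"}
  lobulation:
    concept: {value: "C45997", scheme: "99LIDCQIICR", meaning: "Lobulation"}
    values:
      1: {value: "350", scheme: "99LIDCQIICR", meaning: "1 out of 5 (No Lobulation)"}
      2: {value: "351", scheme: "99LIDCQIICR", meaning: "2 out of 5 (Nearly No Lobulation)"}
      3: {value: "352", scheme: "99LIDCQIICR", meaning: "3 out of 5 (Medium Lobulation)"}
      4: {value: "353", scheme: "99LIDCQIICR", meaning: "4 out of 5 (Near Marked Lobulation)"}
      5: {value: "354", scheme: "99LIDCQIICR", meaning: "5 out of 5 (Marked Lobulation)"}
  spiculation:
    concept: {value: "C45998", scheme: "99LIDCQIICR", meaning: "Spiculation"}
    values:
      1: {value: "360", scheme: "99LIDCQIICR", meaning: "1 out of 5 (No Spiculation)"}
      2: {value: "361", scheme: "99LIDCQIICR", meaning: "2 out of 5 (Nearly No Spiculation)"}
      3: {value: "362", scheme: "99LIDCQIICR", meaning: "3 out of 5 (Medium Spiculation)"}
      4: {value: "363", scheme: "99LIDCQIICR", meaning: "4 out of 5 (Near Marked Spiculation)"}
      5: {value: "364", scheme: "99LIDCQIICR", meaning: "5 out of 5 (Marked Spiculation)"}
  texture:
    concept: {value: "C45999", scheme: "99LIDCQIICR", meaning: "Texture"}
    values:
      1: {value: "370", scheme: "99LIDCQIICR", meaning: "1 out of 5 (Non-Solid/Ground-Glass Opacity)"}
      2: {value: "371", scheme: "99LIDCQIICR", meaning: "2 out of 5 (Non-Solid/Mixed)"}
      3: {value: "372", scheme: "99LIDCQIICR", meaning: "3 out of 5 (Part Solid/Mixed)"}
      4: {value: "373", scheme: "99LIDCQIICR", meaning: "4 out of 5 (Solid/Mixed)"}
      5: {value: "374", scheme: "99LIDCQIICR", meaning: "5 out of 5 (Solid)"}
  malignancy:
    concept: {value: "C46000", scheme: "99LIDCQIICR", meaning: "Malignancy"}
    values:
      1: {value: "380", scheme: "99LIDCQIICR", meaning: "1 out of 5 (Highly Unlikely for Cancer)"}
      2: {value: "381", scheme: "99LIDCQIICR", meaning: "2 out of 5 (Moderately Unlikely for Cancer)"}
      3: {value: "382", scheme: "99LIDCQIICR", meaning: "3 out of 5 (Indeterminate Likelihood)"}
      4: {value: "383", scheme: "99LIDCQIICR", meaning: "4 out of 5 (Moderately Suspicious for Cancer)"}
      5: {value: "384", scheme: "99LIDCQIICR", meaning: "5 out of 5 (Highly Suspicious for Cancer)"}
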