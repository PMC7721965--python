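"""DICOM Segmentation (SEG) encoding and decoding.

One annotation becomes one binary, single-segment SEG object.  Conventions:

* SeriesDescription, SegmentDescription and SegmentLabel all read
  ``Nodule <nodule number> - Annotation <annotation id>``;
* the segment carries the constant category/type/anatomy semantics
  (morphologically altered structure / nodule / lung), the cluster's
  tracking ID/UID, and a recommended display color — distinct per
  annotation within a nodule, carrying no meaning beyond visualization;
* only non-empty slices are stored as frames (slices above and below the
  nodule are omitted); each frame records its plane position and a
  reference to the source CT slice;
* patient/study composite context is copied from the source series so the
  object files correctly alongside the CT.

Segmentations are never grouped across annotations into one object: reader
identity is withheld in the source data, so content that may come from
different readers stays in separate objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.pixels import pack_bits, unpack_bits
from pydicom.uid import ExplicitVRLittleEndian

from lidckit.codes import CodedConcept, load_dictionary
from lidckit.geometry import ScanGeometry
from lidckit.rasterize import MaskVolume
from lidckit.uid import UidFactory

__all__ = [
    "SegConventions",
    "SegEncodeError",
    "SegDecodeError",
    "DISPLAY_PALETTE",
    "annotation_color",
    "rgb_to_cielab16",
    "cielab16_to_rgb",
    "encode_seg",
    "decode_seg",
    "composite_context_from",
]

SEGMENTATION_STORAGE = "1.2.840.10008.5.1.4.1.1.66.4"

#: Fixed cycle of high-saturation display colors; an annotation's color is
#: the palette entry at its ordinal within its cluster (mod palette size).
DISPLAY_PALETTE: tuple[tuple[int, int, int], ...] = (
    (230, 25, 75),
    (60, 180, 75),
    (255, 225, 25),
    (0, 130, 200),
    (245, 130, 48),
    (145, 30, 180),
    (70, 240, 240),
    (240, 50, 230),
    (210, 245, 60),
    (170, 110, 40),
    (128, 0, 128),
    (0, 128, 128),
)


class SegEncodeError(ValueError):
    pass


class SegDecodeError(ValueError):
    pass


@dataclass(frozen=True)
class SegConventions:
    """Naming, tracking and color conventions of one SEG object."""

    nodule_number: int
    annotation_id: str
    tracking_uid: str
    display_color: tuple[int, int, int]

    @property
    def series_description(self) -> str:
        return f"Nodule {self.nodule_number} - Annotation {self.annotation_id}"

    @property
    def segment_label(self) -> str:
        return self.series_description

    @property
    def tracking_id(self) -> str:
        return self.series_description


def annotation_color(ordinal_in_cluster: int) -> tuple[int, int, int]:
    """Palette color for the n-th annotation of a nodule (0-based)."""
    return DISPLAY_PALETTE[ordinal_in_cluster % len(DISPLAY_PALETTE)]


# --- sRGB -> CIELab (D50) per the DICOM color convention -------------------

_SRGB_TO_XYZ_D65 = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)
_WHITE_D65 = np.array([0.95047, 1.0, 1.08883])
_WHITE_D50 = np.array([0.96422, 1.0, 0.82521])
# chromatic adaptation D65 -> D50 (Bradford)
_ADAPT = np.linalg.inv(_BRADFORD) @ np.diag(
    (_BRADFORD @ _WHITE_D50) / (_BRADFORD @ _WHITE_D65)
) @ _BRADFORD


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _linear_to_srgb(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)


def _lab_f(t: np.ndarray) -> np.ndarray:
    d = 6.0 / 29.0
    return np.where(t > d**3, np.cbrt(t), t / (3 * d * d) + 4.0 / 29.0)


def _lab_f_inv(t: np.ndarray) -> np.ndarray:
    d = 6.0 / 29.0
    return np.where(t > d, t**3, 3 * d * d * (t - 4.0 / 29.0))


def _srgb_to_lab_d50(rgb: tuple[int, int, int]) -> np.ndarray:
    c = np.asarray(rgb, dtype=float) / 255.0
    xyz = _ADAPT @ (_SRGB_TO_XYZ_D65 @ _srgb_to_linear(c))
    fx, fy, fz = _lab_f(xyz / _WHITE_D50)
    return np.array([116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)])


def _lab_d50_to_srgb(lab: np.ndarray) -> tuple[int, int, int]:
    L, a, b = lab
    fy = (L + 16) / 116
    fx = fy + a / 500
    fz = fy - b / 200
    xyz = _lab_f_inv(np.array([fx, fy, fz])) * _WHITE_D50
    rgb_lin = np.linalg.solve(_SRGB_TO_XYZ_D65, np.linalg.solve(_ADAPT, xyz))
    rgb = np.rint(_linear_to_srgb(rgb_lin) * 255).astype(int)
    return tuple(int(v) for v in np.clip(rgb, 0, 255))


def rgb_to_cielab16(rgb: tuple[int, int, int]) -> tuple[int, int, int]:
    """sRGB bytes -> DICOM 16-bit scaled CIELab (D50 reference white).

    L* 0..100 maps to 0..0xFFFF; a*, b* -128..127 map to 0..0xFFFF with
    0 at 0x8080.
    """
    if any(not 0 <= v <= 255 for v in rgb):
        raise ValueError(f"RGB components must be in 0..255: {rgb}")
    L, a, b = _srgb_to_lab_d50(rgb)
    L16 = int(round(np.clip(L, 0, 100) * 65535 / 100))
    a16 = int(round((np.clip(a, -128, 127) + 128) * 65535 / 255))
    b16 = int(round((np.clip(b, -128, 127) + 128) * 65535 / 255))
    return (L16, a16, b16)


def cielab16_to_rgb(lab16: tuple[int, int, int]) -> tuple[int, int, int]:
    """Inverse of :func:`rgb_to_cielab16` (to nearest representable sRGB)."""
    L = lab16[0] * 100 / 65535
    a = lab16[1] * 255 / 65535 - 128
    b = lab16[2] * 255 / 65535 - 128
    return _lab_d50_to_srgb(np.array([L, a, b]))


# --- composite context ------------------------------------------------------

_CONTEXT_ATTRS = [
    "PatientName",
    "PatientID",
    "PatientBirthDate",
    "PatientSex",
    "StudyInstanceUID",
    "StudyID",
    "StudyDate",
    "StudyTime",
    "AccessionNumber",
    "ReferringPhysicianName",
]


def composite_context_from(ds: Dataset) -> Dataset:
    """Patient/study identification attributes copied from a source slice."""
    ctx = Dataset()
    for attr in _CONTEXT_ATTRS:
        setattr(ctx, attr, getattr(ds, attr, ""))
    return ctx


def _code_item(c: CodedConcept) -> Dataset:
    item = Dataset()
    item.CodeValue = c.value
    item.CodingSchemeDesignator = c.scheme
    item.CodeMeaning = c.meaning
    return item


def _concept_from_item(item: Dataset) -> CodedConcept:
    return CodedConcept(
        str(item.CodeValue), str(item.CodingSchemeDesignator), str(item.CodeMeaning)
    )


def encode_seg(
    mask: MaskVolume,
    conv: SegConventions,
    ct_refs: dict[int, str],
    composite_context: Dataset,
    *,
    uid_factory: UidFactory | None = None,
    code_scheme: str = "SRT",
    series_number: int = 100,
    content_datetime: tuple[str, str] = ("20200101", "120000"),
) -> pydicom.dataset.FileDataset:
    """Encode one mask volume as a binary single-segment SEG object.

    ``ct_refs`` maps slice index -> source CT SOPInstanceUID and must cover
    every non-empty slice.  Instance and series UIDs are freshly minted from
    ``uid_factory``.
    """
    if uid_factory is None:
        uid_factory = UidFactory()
    g = mask.geometry
    frames_idx = mask.nonempty_slices
    if not frames_idx:
        raise SegEncodeError("refusing to encode an empty mask")
    missing = [k for k in frames_idx if k not in ct_refs]
    if missing:
        raise SegEncodeError(f"ct_refs lacks source slices for frame indices {missing}")

    rows, cols = g.image_shape
    dictionary = load_dictionary()
    category, seg_type, anatomy = dictionary.segmentation_semantics(code_scheme)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = SEGMENTATION_STORAGE
    sop_instance_uid = uid_factory.new_uid()
    file_meta.MediaStorageSOPInstanceUID = sop_instance_uid
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.dataset.FileDataset(None, {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SpecificCharacterSet = "ISO_IR 192"
    ds.SOPClassUID = SEGMENTATION_STORAGE
    ds.SOPInstanceUID = sop_instance_uid
    for attr in _CONTEXT_ATTRS:
        setattr(ds, attr, getattr(composite_context, attr, ""))

    ds.Modality = "SEG"
    ds.SeriesInstanceUID = uid_factory.new_uid()
    ds.SeriesNumber = series_number
    ds.SeriesDescription = conv.series_description
    ds.FrameOfReferenceUID = g.frame_of_reference_uid or uid_factory.new_uid()
    ds.PositionReferenceIndicator = ""

    ds.Manufacturer = "lidckit"
    ds.ManufacturerModelName = "lidckit SEG converter"
    ds.DeviceSerialNumber = "1"
    ds.SoftwareVersions = "0.1.0"

    ds.ImageType = ["DERIVED", "PRIMARY"]
    ds.ContentDate, ds.ContentTime = content_datetime
    ds.SeriesDate, ds.SeriesTime = content_datetime
    ds.InstanceNumber = 1
    ds.ContentLabel = "SEGMENTATION"
    ds.ContentDescription = conv.series_description
    ds.ContentCreatorName = "lidckit"
    ds.LossyImageCompression = "00"

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = rows, cols
    ds.BitsAllocated = 1
    ds.BitsStored = 1
    ds.HighBit = 0
    ds.PixelRepresentation = 0
    ds.SegmentationType = "BINARY"
    ds.NumberOfFrames = len(frames_idx)

    # segment
    seg = Dataset()
    seg.SegmentNumber = 1
    seg.SegmentLabel = conv.segment_label
    seg.SegmentDescription = conv.segment_label
    seg.SegmentAlgorithmType = "MANUAL"
    seg.SegmentedPropertyCategoryCodeSequence = [_code_item(category)]
    seg.SegmentedPropertyTypeCodeSequence = [_code_item(seg_type)]
    seg.AnatomicRegionSequence = [_code_item(anatomy)]
    seg.TrackingID = conv.tracking_id
    seg.TrackingUID = conv.tracking_uid
    seg.RecommendedDisplayCIELabValue = list(rgb_to_cielab16(conv.display_color))
    ds.SegmentSequence = [seg]

    # dimensions
    dim_org_uid = uid_factory.new_uid()
    dim_org = Dataset()
    dim_org.DimensionOrganizationUID = dim_org_uid
    ds.DimensionOrganizationSequence = [dim_org]
    dim_seg = Dataset()
    dim_seg.DimensionOrganizationUID = dim_org_uid
    dim_seg.DimensionIndexPointer = pydicom.tag.Tag(0x0062, 0x000B)
    dim_seg.FunctionalGroupPointer = pydicom.tag.Tag(0x0062, 0x000A)
    dim_seg.DimensionDescriptionLabel = "ReferencedSegmentNumber"
    dim_pos = Dataset()
    dim_pos.DimensionOrganizationUID = dim_org_uid
    dim_pos.DimensionIndexPointer = pydicom.tag.Tag(0x0020, 0x0032)
    dim_pos.FunctionalGroupPointer = pydicom.tag.Tag(0x0020, 0x9113)
    dim_pos.DimensionDescriptionLabel = "ImagePositionPatient"
    ds.DimensionIndexSequence = [dim_seg, dim_pos]

    # shared functional groups
    shared = Dataset()
    orient = Dataset()
    orient.ImageOrientationPatient = [float(v) for v in g.orientation]
    shared.PlaneOrientationSequence = [orient]
    measures = Dataset()
    measures.PixelSpacing = [g.pixel_spacing[0], g.pixel_spacing[1]]
    step = g.slice_step or 1.0
    measures.SliceThickness = step
    measures.SpacingBetweenSlices = step
    shared.PixelMeasuresSequence = [measures]
    ds.SharedFunctionalGroupsSequence = [shared]

    derivation_code = CodedConcept("113076", "DCM", "Segmentation")
    purpose_code = CodedConcept(
        "121322", "DCM", "Source image for image processing operation"
    )

    per_frame = []
    for frame_number, k in enumerate(frames_idx, start=1):
        fg = Dataset()
        pos = Dataset()
        pos.ImagePositionPatient = [float(v) for v in g.slice_origin(k)]
        fg.PlanePositionSequence = [pos]
        content = Dataset()
        content.DimensionIndexValues = [1, frame_number]
        fg.FrameContentSequence = [content]
        ident = Dataset()
        ident.ReferencedSegmentNumber = 1
        fg.SegmentIdentificationSequence = [ident]
        src = Dataset()
        src.ReferencedSOPClassUID = g.sop_class_uid or "1.2.840.10008.5.1.4.1.1.2"
        src.ReferencedSOPInstanceUID = ct_refs[k]
        src.PurposeOfReferenceCodeSequence = [_code_item(purpose_code)]
        deriv = Dataset()
        deriv.SourceImageSequence = [src]
        deriv.DerivationCodeSequence = [_code_item(derivation_code)]
        fg.DerivationImageSequence = [deriv]
        per_frame.append(fg)
    ds.PerFrameFunctionalGroupsSequence = per_frame

    # common instance reference: the full set of referenced CT instances
    ref_series = Dataset()
    ref_series.SeriesInstanceUID = g.series_instance_uid or ""
    ref_instances = []
    for k in frames_idx:
        ref = Dataset()
        ref.ReferencedSOPClassUID = g.sop_class_uid or "1.2.840.10008.5.1.4.1.1.2"
        ref.ReferencedSOPInstanceUID = ct_refs[k]
        ref_instances.append(ref)
    ref_series.ReferencedInstanceSequence = ref_instances
    ds.ReferencedSeriesSequence = [ref_series]

    bits = np.concatenate([mask.slice_mask(k).ravel() for k in frames_idx])
    packed = pack_bits(bits.astype(np.uint8))
    if len(packed) % 2:
        packed += b"\x00"
    ds.PixelData = packed
    return ds


def _as_dataset(obj) -> Dataset:
    if isinstance(obj, Dataset):
        return obj
    if isinstance(obj, (str, Path)):
        return pydicom.dcmread(str(obj))
    if isinstance(obj, (bytes, bytearray)):
        from io import BytesIO

        return pydicom.dcmread(BytesIO(obj))
    raise TypeError(f"cannot interpret {type(obj)} as a DICOM dataset")


def decode_seg(seg, g: ScanGeometry) -> tuple[MaskVolume, SegConventions]:
    """Reconstruct the mask volume and conventions from a SEG object.

    Frames are realigned to the CT frame via their per-frame plane
    positions; the SEG must be binary, single-segment and share the scan's
    frame of reference.
    """
    ds = _as_dataset(seg)
    if str(getattr(ds, "SOPClassUID", "")) != SEGMENTATION_STORAGE:
        raise SegDecodeError("not a DICOM Segmentation object")
    if str(getattr(ds, "SegmentationType", "")) != "BINARY":
        raise SegDecodeError("only binary segmentations are supported")
    if len(ds.SegmentSequence) != 1:
        raise SegDecodeError("expected exactly one segment")
    if g.frame_of_reference_uid and str(ds.FrameOfReferenceUID) != g.frame_of_reference_uid:
        raise SegDecodeError(
            "SEG frame of reference does not match the scan geometry"
        )

    rows, cols = int(ds.Rows), int(ds.Columns)
    if (rows, cols) != g.image_shape:
        raise SegDecodeError(
            f"SEG frame shape {(rows, cols)} does not match CT {g.image_shape}"
        )
    n_frames = int(ds.NumberOfFrames)
    bits = unpack_bits(ds.PixelData)[: n_frames * rows * cols]
    frames = bits.reshape(n_frames, rows, cols).astype(bool)

    normal = g.slice_normal
    tol = (g.slice_step or 1.0) / 2
    vol = np.zeros((g.n_slices, rows, cols), dtype=bool)
    for frame, fg in zip(frames, ds.PerFrameFunctionalGroupsSequence):
        ipp = np.asarray([float(v) for v in fg.PlanePositionSequence[0].ImagePositionPatient])
        z = float(ipp @ normal)
        k = g.slice_index_for_position(z, tol=tol)
        vol[k] |= frame

    seg_item = ds.SegmentSequence[0]
    lab16 = tuple(int(v) for v in seg_item.RecommendedDisplayCIELabValue)
    label = str(seg_item.SegmentLabel)
    # label convention: "Nodule <n> - Annotation <id>"
    nodule_number, annotation_id = 0, label
    parts = label.split(" - Annotation ")
    if len(parts) == 2 and parts[0].startswith("Nodule "):
        try:
            nodule_number = int(parts[0].removeprefix("Nodule "))
            annotation_id = parts[1]
        except ValueError:
            pass
    conv = SegConventions(
        nodule_number=nodule_number,
        annotation_id=annotation_id,
        tracking_uid=str(seg_item.TrackingUID),
        display_color=cielab16_to_rgb(lab16),
    )
    return MaskVolume(voxels=vol.transpose(2, 1, 0), geometry=g), conv


def seg_semantics(seg) -> tuple[CodedConcept, CodedConcept, CodedConcept]:
    """(category, type, anatomy) coded triple carried by a SEG object."""
    ds = _as_dataset(seg)
    seg_item = ds.SegmentSequence[0]
    return (
        _concept_from_item(seg_item.SegmentedPropertyCategoryCodeSequence[0]),
        _concept_from_item(seg_item.SegmentedPropertyTypeCodeSequence[0]),
        _concept_from_item(seg_item.AnatomicRegionSequence[0]),
    )
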