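"""Structural DICOM conformance checks for SEG and SR objects.

An attribute-level IOD checker, deliberately independent of the encoder
code paths: it inspects finished datasets (files or in-memory) against
explicit requirement tables transcribed from the Segmentation and Enhanced
SR IODs, and against the measurement-report template profile this package
emits.  Each finding is an error or a warning with the offending attribute
named; a conformant object yields zero errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydicom.dataset import Dataset
from pydicom.uid import UID

__all__ = ["ValidationFinding", "ValidationResult", "validate_seg", "validate_sr"]


@dataclass(frozen=True)
class ValidationFinding:
    severity: str  # "error" | "warning"
    attribute: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity.upper()}: {self.attribute}: {self.message}"


@dataclass
class ValidationResult:
    findings: list[ValidationFinding] = field(default_factory=list)

    def error(self, attribute: str, message: str) -> None:
        self.findings.append(ValidationFinding("error", attribute, message))

    def warn(self, attribute: str, message: str) -> None:
        self.findings.append(ValidationFinding("warning", attribute, message))

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def ok(self) -> bool:
        return not self.errors


# Type 1 attributes (must be present, non-empty) per module.
_COMMON_REQUIRED = [
    "SOPClassUID",
    "SOPInstanceUID",
    "StudyInstanceUID",
    "SeriesInstanceUID",
    "Modality",
    "PatientID",
    "Manufacturer",
]

_SEG_REQUIRED = _COMMON_REQUIRED + [
    "FrameOfReferenceUID",
    "ImageType",
    "SamplesPerPixel",
    "PhotometricInterpretation",
    "Rows",
    "Columns",
    "BitsAllocated",
    "BitsStored",
    "HighBit",
    "PixelRepresentation",
    "NumberOfFrames",
    "SegmentationType",
    "SegmentSequence",
    "SharedFunctionalGroupsSequence",
    "PerFrameFunctionalGroupsSequence",
    "DimensionIndexSequence",
    "ContentLabel",
    "LossyImageCompression",
    "PixelData",
]

_SR_REQUIRED = _COMMON_REQUIRED + [
    "CompletionFlag",
    "VerificationFlag",
    "ContentDate",
    "ContentTime",
    "ValueType",
    "ConceptNameCodeSequence",
    "ContinuityOfContent",
    "ContentSequence",
]

_CODE_ITEM_FIELDS = ("CodeValue", "CodingSchemeDesignator", "CodeMeaning")


def _check_required(ds: Dataset, names: list[str], result: ValidationResult) -> None:
    for name in names:
        value = getattr(ds, name, None)
        if value is None:
            result.error(name, "required attribute absent")
        elif value in ("", []):
            result.error(name, "required attribute empty")


def _check_uid(result: ValidationResult, attribute: str, value) -> None:
    if value is None:
        return
    uid = UID(str(value))
    if not uid.is_valid:
        result.error(attribute, f"invalid UID {value!r}")


def _check_code_item(item: Dataset, where: str, result: ValidationResult) -> None:
    for f in _CODE_ITEM_FIELDS:
        if not str(getattr(item, f, "")):
            result.error(where, f"code item lacks {f}")


def validate_seg(ds: Dataset) -> ValidationResult:
    """Check one Segmentation object; zero errors means conformant."""
    result = ValidationResult()
    _check_required(ds, _SEG_REQUIRED, result)
    if result.errors:
        return result

    if str(ds.Modality) != "SEG":
        result.error("Modality", f"expected SEG, got {ds.Modality!r}")
    if str(ds.SOPClassUID) != "1.2.840.10008.5.1.4.1.1.66.4":
        result.error("SOPClassUID", "not the Segmentation Storage SOP class")
    for attr in ("SOPInstanceUID", "SeriesInstanceUID", "StudyInstanceUID", "FrameOfReferenceUID"):
        _check_uid(result, attr, getattr(ds, attr, None))

    seg_type = str(ds.SegmentationType)
    if seg_type not in ("BINARY", "FRACTIONAL"):
        result.error("SegmentationType", f"invalid value {seg_type!r}")
    if seg_type == "BINARY":
        if int(ds.BitsAllocated) != 1 or int(ds.BitsStored) != 1 or int(ds.HighBit) != 0:
            result.error(
                "BitsAllocated",
                "binary segmentation requires BitsAllocated=BitsStored=1, HighBit=0",
            )

    n_frames = int(ds.NumberOfFrames)
    rows, cols = int(ds.Rows), int(ds.Columns)
    per_frame = list(ds.PerFrameFunctionalGroupsSequence)
    if len(per_frame) != n_frames:
        result.error(
            "PerFrameFunctionalGroupsSequence",
            f"{len(per_frame)} items for NumberOfFrames={n_frames}",
        )

    if seg_type == "BINARY":
        expected = int(np.ceil(n_frames * rows * cols / 8))
        actual = len(ds.PixelData)
        if actual not in (expected, expected + expected % 2, expected + 1):
            result.error(
                "PixelData",
                f"bit-packed length {actual} inconsistent with "
                f"{n_frames}x{rows}x{cols} frames (expected ~{expected})",
            )

    segment_numbers = set()
    for seg in ds.SegmentSequence:
        num = getattr(seg, "SegmentNumber", None)
        if num is None:
            result.error("SegmentNumber", "segment lacks a number")
            continue
        if num in segment_numbers:
            result.error("SegmentNumber", f"duplicate segment number {num}")
        segment_numbers.add(num)
        if not str(getattr(seg, "SegmentLabel", "")):
            result.error("SegmentLabel", f"segment {num} lacks a label")
        if str(getattr(seg, "SegmentAlgorithmType", "")) not in (
            "MANUAL",
            "SEMIAUTOMATIC",
            "AUTOMATIC",
        ):
            result.error("SegmentAlgorithmType", f"segment {num}: invalid value")
        for seq_name in (
            "SegmentedPropertyCategoryCodeSequence",
            "SegmentedPropertyTypeCodeSequence",
            "AnatomicRegionSequence",
        ):
            seq = getattr(seg, seq_name, None)
            if not seq:
                result.error(seq_name, f"segment {num} lacks {seq_name}")
            else:
                _check_code_item(seq[0], f"segment {num} {seq_name}", result)
        tracking_id = str(getattr(seg, "TrackingID", ""))
        tracking_uid = getattr(seg, "TrackingUID", None)
        if bool(tracking_id) != (tracking_uid is not None):
            result.error("TrackingID", f"segment {num}: TrackingID/UID must pair")
        if tracking_uid is not None:
            _check_uid(result, "TrackingUID", tracking_uid)
        lab = getattr(seg, "RecommendedDisplayCIELabValue", None)
        if lab is not None and (
            len(lab) != 3 or any(not 0 <= int(v) <= 0xFFFF for v in lab)
        ):
            result.error(
                "RecommendedDisplayCIELabValue",
                f"segment {num}: must be three 16-bit unsigned values",
            )

    shared = ds.SharedFunctionalGroupsSequence[0]
    if not getattr(shared, "PixelMeasuresSequence", None):
        result.error("PixelMeasuresSequence", "missing from shared functional groups")
    if not getattr(shared, "PlaneOrientationSequence", None):
        result.error("PlaneOrientationSequence", "missing from shared functional groups")

    for idx, fg in enumerate(per_frame):
        pos = getattr(fg, "PlanePositionSequence", None)
        if not pos or getattr(pos[0], "ImagePositionPatient", None) is None:
            result.error("PlanePositionSequence", f"frame {idx + 1} lacks a plane position")
        ident = getattr(fg, "SegmentIdentificationSequence", None)
        if not ident:
            result.error(
                "SegmentIdentificationSequence", f"frame {idx + 1} lacks segment identification"
            )
        elif int(ident[0].ReferencedSegmentNumber) not in segment_numbers:
            result.error(
                "ReferencedSegmentNumber",
                f"frame {idx + 1} references unknown segment "
                f"{ident[0].ReferencedSegmentNumber}",
            )
    return result


def _walk_content(items, result: ValidationResult, path: str = "root") -> None:
    for idx, item in enumerate(items, start=1):
        where = f"{path}.{idx}"
        rel = str(getattr(item, "RelationshipType", ""))
        vt = str(getattr(item, "ValueType", ""))
        if not rel:
            result.error("RelationshipType", f"{where}: content item lacks relationship")
        if not vt:
            result.error("ValueType", f"{where}: content item lacks value type")
            continue
        name_seq = getattr(item, "ConceptNameCodeSequence", None)
        if name_seq:
            _check_code_item(name_seq[0], f"{where} concept name", result)
        elif vt != "CONTAINER":
            result.error("ConceptNameCodeSequence", f"{where}: unnamed {vt} item")
        if vt == "CODE":
            seq = getattr(item, "ConceptCodeSequence", None)
            if not seq:
                result.error("ConceptCodeSequence", f"{where}: CODE item lacks a value")
            else:
                _check_code_item(seq[0], f"{where} value", result)
        elif vt == "NUM":
            mvs = getattr(item, "MeasuredValueSequence", None)
            if not mvs:
                result.error("MeasuredValueSequence", f"{where}: NUM item lacks a value")
            else:
                mv = mvs[0]
                try:
                    float(mv.NumericValue)
                except Exception:
                    result.error("NumericValue", f"{where}: not numeric")
                units = getattr(mv, "MeasurementUnitsCodeSequence", None)
                if not units:
                    result.error("MeasurementUnitsCodeSequence", f"{where}: units absent")
                else:
                    _check_code_item(units[0], f"{where} units", result)
                    if str(units[0].CodingSchemeDesignator) != "UCUM":
                        result.error(
                            "MeasurementUnitsCodeSequence",
                            f"{where}: units must use UCUM",
                        )
        elif vt == "UIDREF":
            _check_uid(result, f"{where} UID", getattr(item, "UID", None))
        elif vt == "TEXT":
            if not str(getattr(item, "TextValue", "")):
                result.error("TextValue", f"{where}: TEXT item empty")
        elif vt == "IMAGE":
            refs = getattr(item, "ReferencedSOPSequence", None)
            if not refs:
                result.error("ReferencedSOPSequence", f"{where}: IMAGE item lacks reference")
            else:
                _check_uid(
                    result, f"{where} ref", getattr(refs[0], "ReferencedSOPInstanceUID", None)
                )
        elif vt == "CONTAINER":
            if str(getattr(item, "ContinuityOfContent", "")) not in ("SEPARATE", "CONTINUOUS"):
                result.error("ContinuityOfContent", f"{where}: container lacks continuity")
        if vt == "CONTAINER":
            _walk_content(getattr(item, "ContentSequence", []), result, where)


def validate_sr(ds: Dataset) -> ValidationResult:
    """Check one SR measurement report; zero errors means conformant."""
    result = ValidationResult()
    _check_required(ds, _SR_REQUIRED, result)
    if result.errors:
        return result

    if str(ds.Modality) != "SR":
        result.error("Modality", f"expected SR, got {ds.Modality!r}")
    for attr in ("SOPInstanceUID", "SeriesInstanceUID", "StudyInstanceUID"):
        _check_uid(result, attr, getattr(ds, attr, None))
    if str(ds.ValueType) != "CONTAINER":
        result.error("ValueType", "document root must be a CONTAINER")
    _check_code_item(ds.ConceptNameCodeSequence[0], "document title", result)

    templates = getattr(ds, "ContentTemplateSequence", None)
    if not templates:
        result.error("ContentTemplateSequence", "template identification absent")
    else:
        t = templates[0]
        if str(getattr(t, "TemplateIdentifier", "")).strip() != "1500" or str(
            getattr(t, "MappingResource", "")
        ) != "DCMR":
            result.error(
                "ContentTemplateSequence", "root template is not DCMR TID 1500"
            )

    # template profile: exactly one measurement group under Imaging Measurements
    container_values = []

    def collect(items):
        for item in items:
            seq = getattr(item, "ConceptNameCodeSequence", None)
            if seq and str(getattr(item, "ValueType", "")) == "CONTAINER":
                container_values.append(str(seq[0].CodeValue))
                collect(getattr(item, "ContentSequence", []))

    collect(ds.ContentSequence)
    if "126010" not in container_values:
        result.error("ContentSequence", "no Imaging Measurements container (DCM 126010)")
    if "125007" not in container_values:
        result.error("ContentSequence", "no Measurement Group container (DCM 125007)")

    _walk_content(ds.ContentSequence, result)
    return result
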