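"""DICOM SR measurement reports (TID 1500 profile) for nodule annotations.

Each annotation yields one SR document whose content tree is an Imaging
Measurement Report containing a single measurement group.  The group
carries the same tracking ID/UID as the annotation's SEG object, an
explicit reference to that SEG (SOP instance + segment number) and to the
source CT series, the coded qualitative evaluations (name-value pairs from
the coding dictionary — never free text, so the score semantics travel with
the data), and the three numeric measurements with UCUM units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from lidckit.codes import CodedConcept, load_dictionary
from lidckit.seg_writer import _as_dataset, _code_item, _concept_from_item, _CONTEXT_ATTRS
from lidckit.uid import UidFactory

__all__ = [
    "MeasurementGroup",
    "SrEncodeError",
    "SrDecodeError",
    "encode_sr",
    "decode_sr",
    "flatten_evaluations",
]

ENHANCED_SR_STORAGE = "1.2.840.10008.5.1.4.1.1.88.22"

# DCM-coded concepts structuring the TID 1500 tree
_ROOT = CodedConcept("126000", "DCM", "Imaging Measurement Report")
_LANGUAGE = CodedConcept("121049", "DCM", "Language of Content Item and Descendants")
_ENGLISH = CodedConcept("en-US", "RFC5646", "English (United States)")
_OBSERVER = CodedConcept("121008", "DCM", "Person Observer Name")
_PROCEDURE = CodedConcept("121058", "DCM", "Procedure reported")
_IMAGING_PROCEDURE = CodedConcept("P0-0099A", "SRT", "Imaging procedure")
_MEASUREMENTS_CONTAINER = CodedConcept("126010", "DCM", "Imaging Measurements")
_GROUP = CodedConcept("125007", "DCM", "Measurement Group")
_TRACKING_ID = CodedConcept("112039", "DCM", "Tracking Identifier")
_TRACKING_UID = CodedConcept("112040", "DCM", "Tracking Unique Identifier")
_FINDING = CodedConcept("121071", "DCM", "Finding")
_REFERENCED_SEGMENT = CodedConcept("121191", "DCM", "Referenced Segment")
_SOURCE_SERIES = CodedConcept("121232", "DCM", "Source series for segmentation")


class SrEncodeError(ValueError):
    pass


class SrDecodeError(ValueError):
    """Non-conforming content tree; the message names the missing node."""


@dataclass(frozen=True)
class MeasurementGroup:
    """The content of one annotation's measurement report.

    ``evaluations`` are (concept, value) coded pairs; ``measurements`` are
    (concept, numeric value, unit) triples.  Tracking ID/UID are identical
    to the corresponding SEG's.
    """

    tracking_id: str
    tracking_uid: str
    referenced_segment_uid: str
    referenced_segment_number: int
    referenced_source_series: str
    finding_type: CodedConcept = field(
        default_factory=lambda: load_dictionary().segmentation_semantics("SRT")[1]
    )
    evaluations: tuple[tuple[CodedConcept, CodedConcept], ...] = ()
    measurements: tuple[tuple[CodedConcept, float, CodedConcept], ...] = ()

    def __post_init__(self) -> None:
        if len(self.evaluations) > 9:
            raise ValueError("at most nine qualitative evaluations per annotation")
        normalized = []
        for concept, value, unit in self.measurements:
            if not (value > 0 and value == value and value != float("inf")):
                raise ValueError(
                    f"measurement {concept.meaning!r} must be finite and positive"
                )
            # values are carried at the serialized precision (6 significant
            # digits) so encode/decode round-trips are exact
            normalized.append((concept, float(f"{value:.6g}"), unit))
        object.__setattr__(self, "measurements", tuple(normalized))


def _named_item(value_type: str, concept: CodedConcept, relationship: str) -> Dataset:
    item = Dataset()
    item.RelationshipType = relationship
    item.ValueType = value_type
    item.ConceptNameCodeSequence = [_code_item(concept)]
    return item


def _text_item(concept: CodedConcept, text: str, relationship: str) -> Dataset:
    item = _named_item("TEXT", concept, relationship)
    item.TextValue = text
    return item


def _uidref_item(concept: CodedConcept, uid: str, relationship: str) -> Dataset:
    item = _named_item("UIDREF", concept, relationship)
    item.UID = uid
    return item


def _code_value_item(
    concept: CodedConcept, value: CodedConcept, relationship: str
) -> Dataset:
    item = _named_item("CODE", concept, relationship)
    item.ConceptCodeSequence = [_code_item(value)]
    return item


def _num_item(
    concept: CodedConcept, value: float, unit: CodedConcept, relationship: str
) -> Dataset:
    if unit.scheme != "UCUM":
        raise SrEncodeError(f"measurement units must use UCUM, got {unit.scheme!r}")
    item = _named_item("NUM", concept, relationship)
    mv = Dataset()
    # DS limits to 16 characters; 6 significant digits are retained
    mv.NumericValue = f"{value:.6g}"
    mv.MeasurementUnitsCodeSequence = [_code_item(unit)]
    item.MeasuredValueSequence = [mv]
    return item


def encode_sr(
    group: MeasurementGroup,
    composite_context: Dataset,
    *,
    uid_factory: UidFactory | None = None,
    series_description: str = "",
    series_number: int = 200,
    content_datetime: tuple[str, str] = ("20200101", "120000"),
) -> pydicom.dataset.FileDataset:
    """Encode one measurement group as an Enhanced SR measurement report."""
    if uid_factory is None:
        uid_factory = UidFactory()
    if not group.referenced_segment_uid:
        raise SrEncodeError("measurement group must reference a SEG instance")

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = ENHANCED_SR_STORAGE
    sop_instance_uid = uid_factory.new_uid()
    file_meta.MediaStorageSOPInstanceUID = sop_instance_uid
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.dataset.FileDataset(None, {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SpecificCharacterSet = "ISO_IR 192"
    ds.SOPClassUID = ENHANCED_SR_STORAGE
    ds.SOPInstanceUID = sop_instance_uid
    for attr in _CONTEXT_ATTRS:
        setattr(ds, attr, getattr(composite_context, attr, ""))

    ds.Modality = "SR"
    ds.SeriesInstanceUID = uid_factory.new_uid()
    ds.SeriesNumber = series_number
    ds.SeriesDescription = series_description or f"Measurements - {group.tracking_id}"
    ds.Manufacturer = "lidckit"
    ds.ManufacturerModelName = "lidckit SR converter"
    ds.DeviceSerialNumber = "1"
    ds.SoftwareVersions = "0.1.0"
    ds.ContentDate, ds.ContentTime = content_datetime
    ds.SeriesDate, ds.SeriesTime = content_datetime
    ds.InstanceNumber = 1
    ds.CompletionFlag = "COMPLETE"
    ds.VerificationFlag = "UNVERIFIED"
    ds.PreliminaryFlag = "FINAL"

    ds.ValueType = "CONTAINER"
    ds.ConceptNameCodeSequence = [_code_item(_ROOT)]
    ds.ContinuityOfContent = "SEPARATE"
    template = Dataset()
    template.MappingResource = "DCMR"
    template.TemplateIdentifier = "1500"
    ds.ContentTemplateSequence = [template]

    content: list[Dataset] = []
    content.append(_code_value_item(_LANGUAGE, _ENGLISH, "HAS CONCEPT MOD"))
    observer = _named_item("PNAME", _OBSERVER, "HAS OBS CONTEXT")
    observer.PersonName = "Reader^Anonymous"
    content.append(observer)
    content.append(_code_value_item(_PROCEDURE, _IMAGING_PROCEDURE, "CONTAINS"))

    group_items: list[Dataset] = [
        _text_item(_TRACKING_ID, group.tracking_id, "HAS OBS CONTEXT"),
        _uidref_item(_TRACKING_UID, group.tracking_uid, "HAS OBS CONTEXT"),
        _code_value_item(_FINDING, group.finding_type, "CONTAINS"),
    ]

    seg_ref = _named_item("IMAGE", _REFERENCED_SEGMENT, "CONTAINS")
    ref = Dataset()
    ref.ReferencedSOPClassUID = "1.2.840.10008.5.1.4.1.1.66.4"
    ref.ReferencedSOPInstanceUID = group.referenced_segment_uid
    ref.ReferencedSegmentNumber = group.referenced_segment_number
    seg_ref.ReferencedSOPSequence = [ref]
    group_items.append(seg_ref)
    group_items.append(
        _uidref_item(_SOURCE_SERIES, group.referenced_source_series, "CONTAINS")
    )

    for concept, value in group.evaluations:
        group_items.append(_code_value_item(concept, value, "CONTAINS"))
    for concept, value, unit in group.measurements:
        group_items.append(_num_item(concept, float(value), unit, "CONTAINS"))

    group_container = _named_item("CONTAINER", _GROUP, "CONTAINS")
    group_container.ContinuityOfContent = "SEPARATE"
    group_container.ContentSequence = group_items

    measurements_container = _named_item(
        "CONTAINER", _MEASUREMENTS_CONTAINER, "CONTAINS"
    )
    measurements_container.ContinuityOfContent = "SEPARATE"
    measurements_container.ContentSequence = [group_container]
    content.append(measurements_container)

    ds.ContentSequence = content
    return ds


def _concept_of(item: Dataset) -> CodedConcept | None:
    seq = getattr(item, "ConceptNameCodeSequence", None)
    if not seq:
        return None
    return _concept_from_item(seq[0])


def _find_child(items, concept: CodedConcept, what: str) -> Dataset:
    for item in items:
        c = _concept_of(item)
        if c is not None and c.value == concept.value and c.scheme == concept.scheme:
            return item
    raise SrDecodeError(f"content tree lacks {what} ({concept.scheme} {concept.value})")


def decode_sr(sr) -> MeasurementGroup:
    """Recover the measurement group from an emitted SR document."""
    ds = _as_dataset(sr)
    if str(getattr(ds, "Modality", "")) != "SR":
        raise SrDecodeError("not an SR document")
    root_name = _concept_of(ds)
    if root_name is None or root_name.value != _ROOT.value:
        raise SrDecodeError("root is not an Imaging Measurement Report container")
    content = list(getattr(ds, "ContentSequence", []))
    measurements_node = _find_child(content, _MEASUREMENTS_CONTAINER, "Imaging Measurements container")
    groups = [
        item
        for item in getattr(measurements_node, "ContentSequence", [])
        if _concept_of(item) is not None and _concept_of(item).value == _GROUP.value
    ]
    if not groups:
        raise SrDecodeError("content tree lacks a Measurement Group container")
    group = groups[0]
    items = list(getattr(group, "ContentSequence", []))

    tracking_id = str(_find_child(items, _TRACKING_ID, "Tracking Identifier").TextValue)
    tracking_uid = str(_find_child(items, _TRACKING_UID, "Tracking Unique Identifier").UID)
    finding = _concept_from_item(
        _find_child(items, _FINDING, "Finding").ConceptCodeSequence[0]
    )
    seg_item = _find_child(items, _REFERENCED_SEGMENT, "Referenced Segment")
    seg_ref = seg_item.ReferencedSOPSequence[0]
    source_series = str(
        _find_child(items, _SOURCE_SERIES, "Source series for segmentation").UID
    )

    known = {
        c.value
        for c in (_TRACKING_ID, _TRACKING_UID, _FINDING, _REFERENCED_SEGMENT, _SOURCE_SERIES)
    }
    evaluations = []
    measurements = []
    for item in items:
        concept = _concept_of(item)
        if concept is None or concept.value in known:
            continue
        if item.ValueType == "CODE":
            evaluations.append(
                (concept, _concept_from_item(item.ConceptCodeSequence[0]))
            )
        elif item.ValueType == "NUM":
            mv = item.MeasuredValueSequence[0]
            unit = _concept_from_item(mv.MeasurementUnitsCodeSequence[0])
            measurements.append((concept, float(mv.NumericValue), unit))

    return MeasurementGroup(
        tracking_id=tracking_id,
        tracking_uid=tracking_uid,
        referenced_segment_uid=str(seg_ref.ReferencedSOPInstanceUID),
        referenced_segment_number=int(seg_ref.ReferencedSegmentNumber),
        referenced_source_series=source_series,
        finding_type=finding,
        evaluations=tuple(evaluations),
        measurements=tuple(measurements),
    )


def flatten_evaluations(srs: list, *, subjects: list[str] | None = None) -> pd.DataFrame:
    """Tabulate a collection of SR documents, one row per annotation.

    Columns: subject, nodule number, annotation id, tracking UID, nine
    evaluation columns (attribute names; null when absent) and the three
    measurement columns.  ``subjects`` optionally supplies the subject label
    per SR (defaults to each document's PatientID).
    """
    dictionary = load_dictionary()
    meas_codes = {
        concept.value: name
        for name, (concept, _) in dictionary.all_measurement_codes().items()
    }
    from lidckit.lidc_xml import CHARACTERISTIC_NAMES

    rows = []
    seen: set[tuple[str, str]] = set()
    for idx, sr in enumerate(srs):
        ds = _as_dataset(sr)
        group = decode_sr(ds)
        nodule_number, annotation_id = None, group.tracking_id
        parts = group.tracking_id.split(" - Annotation ")
        if len(parts) == 2 and parts[0].startswith("Nodule "):
            nodule_number = int(parts[0].removeprefix("Nodule "))
            annotation_id = parts[1]
        key = (group.tracking_uid, annotation_id)
        if key in seen:
            raise ValueError(f"duplicate (tracking UID, annotation) pair: {key}")
        seen.add(key)
        row: dict = {
            "subject": subjects[idx] if subjects else str(getattr(ds, "PatientID", "")),
            "nodule_number": nodule_number,
            "annotation_id": annotation_id,
            "tracking_uid": group.tracking_uid,
        }
        for name in CHARACTERISTIC_NAMES:
            row[name] = None
        for concept, value in group.evaluations:
            attr = dictionary.concept_to_attribute(concept)
            if attr is not None:
                row[attr] = value.meaning
        for name in ("diameter", "surface_area", "volume"):
            row[name] = None
        for concept, value, _unit in group.measurements:
            name = meas_codes.get(concept.value)
            if name is not None:
                row[name] = value
        rows.append(row)
    columns = (
        ["subject", "nodule_number", "annotation_id", "tracking_uid"]
        + list(CHARACTERISTIC_NAMES)
        + ["diameter", "surface_area", "volume"]
    )
    return pd.DataFrame(rows, columns=columns)
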