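"""End-to-end conversion of one scan and collection-level consistency checks.

``convert_scan`` runs the full pipeline — parse the annotation XML, keep the
volumetric annotations, derive the CT geometry, rasterize, cluster into
nodules, measure, and encode one SEG plus one SR per annotation — with
per-annotation fault isolation: a defective annotation is skipped with a
warning tallied in the manifest, never aborting the scan.

``validate_collection`` re-reads a converted output directory and checks the
consistency contract: 1:1 annotation/SEG/SR correspondence, dictionary
closure of every coded evaluation, SEG/SR tracking-pair agreement, decode
round-trips on a sample, and structural IOD conformance of every object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pydicom

from lidckit import __version__
from lidckit.cluster import cluster_annotations
from lidckit.codes import load_dictionary
from lidckit.geometry import build_geometry
from lidckit.lidc_xml import parse_annotation_file, select_volumetric
from lidckit.measure import measure_mask
from lidckit.rasterize import build_mask
from lidckit.seg_writer import (
    SegConventions,
    annotation_color,
    composite_context_from,
    decode_seg,
    encode_seg,
)
from lidckit.sr_writer import MeasurementGroup, decode_sr, encode_sr
from lidckit.uid import DEFAULT_UID_ROOT, UidFactory
from lidckit.validation import validate_seg, validate_sr

__all__ = ["ConversionParams", "ConversionManifest", "convert_scan", "validate_collection"]

logger = logging.getLogger("lidckit")


@dataclass(frozen=True)
class ConversionParams:
    tol_mm: float | None = None  # default: the scan's slice step
    uid_root: str = DEFAULT_UID_ROOT
    seed: int | None = None
    dictionary_path: str | None = None
    code_scheme: str = "SRT"


@dataclass
class ConversionManifest:
    subject: str
    series_uid: str
    n_annotations_parsed: int = 0
    n_volumetric: int = 0
    n_excluded_nonvolumetric: int = 0
    n_clusters: int = 0
    n_clusters_oversized: int = 0
    n_seg_written: int = 0
    n_sr_written: int = 0
    warnings: list[str] = field(default_factory=list)
    objects: list[dict] = field(default_factory=list)
    tool_version: str = __version__
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _dictionary_hash(path: str | None) -> str:
    if path is None:
        text = (resources.files("lidckit") / "data" / "codes.yaml").read_text()
    else:
        text = Path(path).read_text()
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def convert_scan(
    ct_dir: str | Path,
    xml_path: str | Path,
    out_dir: str | Path,
    params: ConversionParams = ConversionParams(),
) -> ConversionManifest:
    """Convert one scan's annotations into DICOM SEG + SR objects.

    Output layout: ``<out>/<subject>/<series>/SEG_<nodule>_<annotation>.dcm``
    and ``SR_<nodule>_<annotation>.dcm`` plus ``manifest.json``.  The run is
    deterministic given the parameters and seed.
    """
    ct_dir, xml_path, out_dir = Path(ct_dir), Path(xml_path), Path(out_dir)
    g = build_geometry(ct_dir)
    uid_factory = UidFactory(root=params.uid_root, seed=params.seed)
    dictionary = load_dictionary(params.dictionary_path)

    first_slice = next(
        f for f in sorted(ct_dir.iterdir()) if f.is_file() and f.suffix.lower() == ".dcm"
    )
    source_ds = pydicom.dcmread(str(first_slice), stop_before_pixels=True)
    context = composite_context_from(source_ds)
    subject = str(getattr(source_ds, "PatientID", "UNKNOWN")) or "UNKNOWN"

    annotations = parse_annotation_file(xml_path)
    volumetric = select_volumetric(annotations)

    manifest = ConversionManifest(
        subject=subject,
        series_uid=g.series_instance_uid,
        n_annotations_parsed=len(annotations),
        n_volumetric=len(volumetric),
        n_excluded_nonvolumetric=len(annotations) - len(volumetric),
        parameters={
            "tol_mm": params.tol_mm if params.tol_mm is not None else g.slice_step,
            "uid_root": params.uid_root,
            "seed": params.seed,
            "code_scheme": params.code_scheme,
            "dictionary_sha256_16": _dictionary_hash(params.dictionary_path),
            "palette": "fixed 12-color high-saturation cycle",
        },
    )

    clusters = cluster_annotations(
        volumetric, g, tol=params.tol_mm, uid_factory=uid_factory
    )
    manifest.n_clusters = len(clusters)
    manifest.n_clusters_oversized = sum(1 for c in clusters if c.size > 4)
    for c in clusters:
        if c.size > 4:
            manifest.warnings.append(
                f"cluster {c.nodule_number} has {c.size} members (> 4 readers); "
                "may need manual regrouping"
            )

    scan_dir = out_dir / subject / (g.series_instance_uid or "series")
    scan_dir.mkdir(parents=True, exist_ok=True)
    ct_refs = {idx: uid for uid, idx in g.slice_table.items()}

    for cluster in clusters:
        for ordinal, ann in enumerate(cluster.members):
            label = f"Nodule {cluster.nodule_number} - Annotation {ann.annotation_id}"
            try:
                mask = build_mask(ann, g)
                measurements = measure_mask(mask)
                conv = SegConventions(
                    nodule_number=cluster.nodule_number,
                    annotation_id=ann.annotation_id,
                    tracking_uid=cluster.tracking_uid,
                    display_color=annotation_color(ordinal),
                )
                seg = encode_seg(
                    mask,
                    conv,
                    ct_refs,
                    context,
                    uid_factory=uid_factory,
                    code_scheme=params.code_scheme,
                    series_number=100 + manifest.n_seg_written,
                )
                evaluations = tuple(
                    dictionary.evaluation_code(attr, rating)
                    for attr, rating in ann.characteristics.as_dict().items()
                )
                meas_entries = []
                for name, value in (
                    ("diameter", measurements.diameter_mm),
                    ("surface_area", measurements.surface_area_mm2),
                    ("volume", measurements.volume_mm3),
                ):
                    concept, unit = dictionary.measurement_codes(name)
                    meas_entries.append((concept, float(value), unit))
                group = MeasurementGroup(
                    tracking_id=conv.tracking_id,
                    tracking_uid=cluster.tracking_uid,
                    referenced_segment_uid=str(seg.SOPInstanceUID),
                    referenced_segment_number=1,
                    referenced_source_series=g.series_instance_uid,
                    finding_type=dictionary.segmentation_semantics(params.code_scheme)[1],
                    evaluations=evaluations,
                    measurements=tuple(meas_entries),
                )
                sr = encode_sr(
                    group,
                    context,
                    uid_factory=uid_factory,
                    series_number=200 + manifest.n_sr_written,
                )
                stem = f"{cluster.nodule_number}_{ann.annotation_id}"
                seg.save_as(scan_dir / f"SEG_{stem}.dcm", enforce_file_format=True)
                sr.save_as(scan_dir / f"SR_{stem}.dcm", enforce_file_format=True)
                manifest.n_seg_written += 1
                manifest.n_sr_written += 1
                manifest.objects.append(
                    {
                        "label": label,
                        "tracking_uid": cluster.tracking_uid,
                        "seg": f"SEG_{stem}.dcm",
                        "sr": f"SR_{stem}.dcm",
                        "diameter_mm": measurements.diameter_mm,
                        "surface_area_mm2": measurements.surface_area_mm2,
                        "volume_mm3": measurements.volume_mm3,
                    }
                )
                logger.info("wrote %s (tracking UID %s)", label, cluster.tracking_uid)
            except Exception as exc:  # fault isolation: skip and tally
                msg = f"{subject}/{g.series_instance_uid}/{label}: {exc}"
                manifest.warnings.append(msg)
                logger.warning("skipped %s", msg)

    (scan_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


@dataclass
class CollectionReport:
    checks: dict[str, bool] = field(default_factory=dict)
    details: dict[str, list[str]] = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(self.checks.values())

    def record(self, name: str, failures: list[str]) -> None:
        self.checks[name] = not failures
        self.details[name] = failures

    def to_json(self) -> str:
        return json.dumps(
            {"checks": self.checks, "details": self.details, "all_passed": self.all_passed},
            indent=2,
            sort_keys=True,
        )


def validate_collection(
    out_dir: str | Path,
    *,
    sample: int = 5,
    ct_dirs: dict[str, Path] | None = None,
) -> CollectionReport:
    """Consistency-check a converted collection (read-only).

    Checks: (1) 1:1 annotation/SEG/SR correspondence against each scan's
    manifest; (2) every coded evaluation value is in the dictionary;
    (3) tracking ID/UID agree between each SEG/SR pair; (4) SEG decode
    round-trip frame consistency on up to ``sample`` objects per scan
    (mask-level equality when the source CT directories are supplied);
    (5) structural IOD conformance of every object.
    """
    out_dir = Path(out_dir)
    report = CollectionReport()
    dictionary = load_dictionary()

    correspondence: list[str] = []
    closure: list[str] = []
    tracking: list[str] = []
    roundtrip: list[str] = []
    conformance: list[str] = []

    manifests = sorted(out_dir.glob("*/*/manifest.json"))
    if not manifests:
        correspondence.append(f"no converted scans under {out_dir}")

    for mpath in manifests:
        scan_dir = mpath.parent
        manifest = json.loads(mpath.read_text())
        segs = {p.name for p in scan_dir.glob("SEG_*.dcm")}
        srs = {p.name for p in scan_dir.glob("SR_*.dcm")}
        for obj in manifest["objects"]:
            if obj["seg"] not in segs:
                correspondence.append(f"{scan_dir}: missing SEG for {obj['label']}")
            if obj["sr"] not in srs:
                correspondence.append(f"{scan_dir}: missing SR for {obj['label']}")
        if len(segs) != manifest["n_seg_written"]:
            correspondence.append(
                f"{scan_dir}: {len(segs)} SEG files vs manifest {manifest['n_seg_written']}"
            )
        if len(srs) != manifest["n_sr_written"]:
            correspondence.append(
                f"{scan_dir}: {len(srs)} SR files vs manifest {manifest['n_sr_written']}"
            )
        if manifest["n_seg_written"] != manifest["n_sr_written"]:
            correspondence.append(f"{scan_dir}: SEG/SR count mismatch")

        geometry = None
        if ct_dirs and manifest["subject"] in ct_dirs:
            geometry = build_geometry(ct_dirs[manifest["subject"]])

        n_sampled = 0
        for obj in manifest["objects"]:
            seg_path = scan_dir / obj["seg"]
            sr_path = scan_dir / obj["sr"]
            if not (seg_path.exists() and sr_path.exists()):
                continue
            seg_ds = pydicom.dcmread(str(seg_path))
            sr_ds = pydicom.dcmread(str(sr_path))

            for f in validate_seg(seg_ds).errors:
                conformance.append(f"{obj['seg']}: {f}")
            for f in validate_sr(sr_ds).errors:
                conformance.append(f"{obj['sr']}: {f}")

            seg_item = seg_ds.SegmentSequence[0]
            group = decode_sr(sr_ds)
            if str(seg_item.TrackingUID) != group.tracking_uid:
                tracking.append(f"{obj['label']}: SEG/SR tracking UID mismatch")
            if str(seg_item.TrackingID) != group.tracking_id:
                tracking.append(f"{obj['label']}: SEG/SR tracking ID mismatch")
            if group.referenced_segment_uid != str(seg_ds.SOPInstanceUID):
                tracking.append(f"{obj['label']}: SR does not reference its SEG")

            for concept, value in group.evaluations:
                if not dictionary.is_known_pair(concept, value):
                    closure.append(
                        f"{obj['label']}: evaluation ({concept.value}, {value.value}) "
                        "not in the code dictionary"
                    )
            for concept, _value, unit in group.measurements:
                if unit.scheme != "UCUM":
                    closure.append(f"{obj['label']}: non-UCUM unit {unit.as_tuple()}")

            if geometry is not None and n_sampled < sample:
                n_sampled += 1
                try:
                    mask, conv = decode_seg(seg_ds, geometry)
                    if mask.foreground_count == 0:
                        roundtrip.append(f"{obj['label']}: decoded mask empty")
                    if len(mask.nonempty_slices) != int(seg_ds.NumberOfFrames):
                        roundtrip.append(
                            f"{obj['label']}: decoded non-empty slices != frame count"
                        )
                    if conv.tracking_uid != obj["tracking_uid"]:
                        roundtrip.append(f"{obj['label']}: tracking UID lost in decode")
                except Exception as exc:
                    roundtrip.append(f"{obj['label']}: decode failed: {exc}")

    report.record("correspondence", correspondence)
    report.record("code_dictionary_closure", closure)
    report.record("tracking_consistency", tracking)
    report.record("decode_roundtrip", roundtrip)
    report.record("iod_conformance", conformance)
    return report
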