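"""Synthetic CT series and annotations with analytic ground truth.

Every other module is testable without any external download: this module
writes a geometrically consistent per-slice CT series (uniform background
plus hyperdense spherical nodules — intensity content is irrelevant to
conversion correctness) and a matching annotation XML file in the supported
dialect.  Contours are emitted the way the source collection drew them:
ordered integer pixel rings tracing the pixels *just outside* each digitized
sphere cross-section, so the strict-interior rasterization convention
recovers the digitized sphere.  Per-reader variability is emulated by a
seeded radius perturbation (a small dilation/erosion of the ring).

A machine-readable ground-truth sidecar (JSON) records the analytic
centers, radii, volumes, surface areas and diameters for parameter-recovery
tests.  A fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from lxml import etree
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian
from scipy.ndimage import binary_dilation

from lidckit.geometry import ScanGeometry
from lidckit.lidc_xml import (
    CHARACTERISTIC_NAMES,
    CHARACTERISTIC_RANGES,
    NoduleAnnotation,
)
from lidckit.uid import UidFactory

__all__ = [
    "NoduleSpec",
    "PhantomSpec",
    "generate_ct_series",
    "generate_annotations",
    "write_annotation_xml",
]


@dataclass(frozen=True)
class NoduleSpec:
    """One synthetic spherical nodule and how its readers annotate it."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    n_readers: int = 4
    jitter_mm: float = 0.0
    characteristics: tuple[dict, ...] = ()  # one dict per reader; sampled if empty

    @property
    def analytic_volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_mm**3

    @property
    def analytic_surface_mm2(self) -> float:
        return 4.0 * np.pi * self.radius_mm**2

    @property
    def analytic_diameter_mm(self) -> float:
        return 2.0 * self.radius_mm


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and content of one synthetic scan."""

    image_shape: tuple[int, int] = (128, 128)
    pixel_spacing: tuple[float, float] = (0.7, 0.7)
    slice_step: float = 2.5
    n_slices: int = 20
    nodules: tuple[NoduleSpec, ...] = ()
    center_only_marks: tuple[tuple[float, float, float], ...] = ()
    seed: int = 0
    subject_id: str = "SYN-0001"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self) -> None:
        rows, cols = self.image_shape
        if self.n_slices < 2:
            raise ValueError("phantom needs at least 2 slices")
        if self.slice_step <= 0 or min(self.pixel_spacing) <= 0:
            raise ValueError("spacings must be positive")
        extent = (
            cols * self.pixel_spacing[1],
            rows * self.pixel_spacing[0],
            self.n_slices * self.slice_step,
        )
        min_voxel = max(max(self.pixel_spacing), self.slice_step)
        for nod in self.nodules:
            if nod.radius_mm < 2 * min_voxel:
                raise ValueError(
                    f"nodule radius {nod.radius_mm} mm below 2 voxels "
                    f"({2 * min_voxel} mm)"
                )
            for axis in range(3):
                lo = nod.center_mm[axis] - nod.radius_mm - self.origin[axis]
                hi = nod.center_mm[axis] + nod.radius_mm - self.origin[axis]
                if lo < 0 or hi > extent[axis]:
                    raise ValueError(
                        f"nodule at {nod.center_mm} (r={nod.radius_mm}) protrudes "
                        f"outside the volume along axis {axis}"
                    )

    def slice_z(self, k: int) -> float:
        return self.origin[2] + k * self.slice_step


def _ct_dataset(
    spec: PhantomSpec,
    k: int,
    pixels: np.ndarray,
    uids: dict,
) -> pydicom.dataset.FileDataset:
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = CTImageStorage
    file_meta.MediaStorageSOPInstanceUID = uids["sop"][k]
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.dataset.FileDataset(None, {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SpecificCharacterSet = "ISO_IR 192"
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = uids["sop"][k]
    ds.PatientName = f"Synthetic^{spec.subject_id}"
    ds.PatientID = spec.subject_id
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"
    ds.StudyInstanceUID = uids["study"]
    ds.SeriesInstanceUID = uids["series"]
    ds.FrameOfReferenceUID = uids["for"]
    ds.PositionReferenceIndicator = ""
    ds.StudyID = "1"
    ds.StudyDate = "20200101"
    ds.StudyTime = "000000"
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.Modality = "CT"
    ds.SeriesNumber = 1
    ds.InstanceNumber = k + 1
    ds.Manufacturer = "lidckit"
    ds.KVP = 120
    ds.ImagePositionPatient = [spec.origin[0], spec.origin[1], spec.slice_z(k)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [spec.pixel_spacing[0], spec.pixel_spacing[1]]
    ds.SliceThickness = spec.slice_step
    ds.Rows, ds.Columns = spec.image_shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.RescaleIntercept = 0
    ds.RescaleSlope = 1
    ds.PixelData = pixels.astype(np.int16).tobytes()
    return ds


def generate_ct_series(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Write the synthetic CT series and its ground-truth sidecar.

    Returns the ground-truth record (also written as ``ground_truth.json``
    in ``out_dir``).  Identical spec (including seed) yields byte-identical
    files.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    uid_factory = UidFactory(seed=spec.seed)
    uids = {
        "study": uid_factory.new_uid(),
        "series": uid_factory.new_uid(),
        "for": uid_factory.new_uid(),
        "sop": [uid_factory.new_uid() for _ in range(spec.n_slices)],
    }

    rows, cols = spec.image_shape
    row_sp, col_sp = spec.pixel_spacing
    yy, xx = np.mgrid[0:rows, 0:cols]
    px = spec.origin[0] + xx * col_sp
    py = spec.origin[1] + yy * row_sp

    for k in range(spec.n_slices):
        img = np.full((rows, cols), -1000, dtype=np.int16)
        z = spec.slice_z(k)
        for nod in spec.nodules:
            dz2 = (z - nod.center_mm[2]) ** 2
            r2 = nod.radius_mm**2 - dz2
            if r2 <= 0:
                continue
            disc = (px - nod.center_mm[0]) ** 2 + (py - nod.center_mm[1]) ** 2 <= r2
            img[disc] = 40
        _ct_dataset(spec, k, img, uids).save_as(
            out_dir / f"ct_{k:03d}.dcm", enforce_file_format=True
        )

    truth = {
        "subject_id": spec.subject_id,
        "seed": spec.seed,
        "image_shape": list(spec.image_shape),
        "pixel_spacing": list(spec.pixel_spacing),
        "slice_step": spec.slice_step,
        "n_slices": spec.n_slices,
        "series_instance_uid": uids["series"],
        "sop_instance_uids": uids["sop"],
        "nodules": [
            {
                "center_mm": list(nod.center_mm),
                "radius_mm": nod.radius_mm,
                "n_readers": nod.n_readers,
                "jitter_mm": nod.jitter_mm,
                "analytic_volume_mm3": nod.analytic_volume_mm3,
                "analytic_surface_mm2": nod.analytic_surface_mm2,
                "analytic_diameter_mm": nod.analytic_diameter_mm,
            }
            for nod in spec.nodules
        ],
        "center_only_marks": [list(m) for m in spec.center_only_marks],
    }
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True)
    )
    return truth


def _digitized_disc(
    spec: PhantomSpec, center_mm, radius_mm: float, z: float
) -> np.ndarray | None:
    """Pixel membership of one sphere cross-section on one slice."""
    r2 = radius_mm**2 - (z - center_mm[2]) ** 2
    if r2 <= 0:
        return None
    rows, cols = spec.image_shape
    row_sp, col_sp = spec.pixel_spacing
    yy, xx = np.mgrid[0:rows, 0:cols]
    px = spec.origin[0] + xx * col_sp
    py = spec.origin[1] + yy * row_sp
    disc = (px - center_mm[0]) ** 2 + (py - center_mm[1]) ** 2 <= r2
    return disc if disc.any() else None


def _ring_contour(disc: np.ndarray) -> list[tuple[int, int]]:
    """Ordered integer ring through the pixels just outside a convex disc."""
    ring = binary_dilation(disc, structure=np.ones((3, 3))) & ~disc
    ys, xs = np.nonzero(ring)
    cy, cx = (float(np.mean(c)) for c in np.nonzero(disc))
    order = np.argsort(np.arctan2(ys - cy, xs - cx))
    return [(int(xs[i]), int(ys[i])) for i in order]


def _sample_characteristics(rng: np.random.Generator) -> dict:
    return {
        name: int(rng.integers(lo, hi + 1))
        for name, (lo, hi) in CHARACTERISTIC_RANGES.items()
    }


def generate_annotations(
    spec: PhantomSpec,
    g: ScanGeometry,
    out_path: str | Path | None = None,
) -> tuple[str, list[NoduleAnnotation]]:
    """Emit the annotation XML matching a generated series.

    For each nodule and reader, per-slice rings of the pixels just outside
    the (jittered) digitized sphere; characteristics from the phantom spec or
    sampled uniformly over each attribute's documented range (seeded).
    Center-only marks, when present in the phantom spec, are emitted as single-point
    ROIs in the first reading session.

    Returns the XML text and the structurally equivalent annotation records.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    sorted_uids = sorted(g.slice_table, key=g.slice_table.get)

    max_readers = max((nod.n_readers for nod in spec.nodules), default=1)
    sessions: list[list[dict]] = [[] for _ in range(max(max_readers, 1))]

    for n_idx, nod in enumerate(spec.nodules):
        for reader in range(nod.n_readers):
            jitter = (
                float(rng.uniform(-nod.jitter_mm, nod.jitter_mm))
                if nod.jitter_mm > 0
                else 0.0
            )
            radius = max(nod.radius_mm + jitter, max(spec.pixel_spacing))
            if nod.characteristics:
                chars = dict(nod.characteristics[reader % len(nod.characteristics)])
            else:
                chars = _sample_characteristics(rng)
            rois = []
            for k in range(spec.n_slices):
                disc = _digitized_disc(spec, nod.center_mm, radius, spec.slice_z(k))
                if disc is None:
                    continue
                rois.append(
                    {
                        "z": spec.slice_z(k),
                        "sop": sorted_uids[k],
                        "inclusion": True,
                        "points": _ring_contour(disc),
                    }
                )
            if not rois:
                continue
            sessions[reader].append(
                {
                    "id": f"{100 * (reader + 1) + n_idx + 1}",
                    "characteristics": chars,
                    "rois": rois,
                }
            )

    for m_idx, mark in enumerate(spec.center_only_marks):
        k = int(round((mark[2] - spec.origin[2]) / spec.slice_step))
        k = min(max(k, 0), spec.n_slices - 1)
        x = int(round((mark[0] - spec.origin[0]) / spec.pixel_spacing[1]))
        y = int(round((mark[1] - spec.origin[1]) / spec.pixel_spacing[0]))
        sessions[0].append(
            {
                "id": f"CM{m_idx + 1}",
                "characteristics": {},
                "rois": [
                    {
                        "z": spec.slice_z(k),
                        "sop": sorted_uids[k],
                        "inclusion": True,
                        "points": [(x, y)],
                    }
                ],
            }
        )

    xml_text = _sessions_to_xml(sessions)
    if out_path is not None:
        Path(out_path).write_text(xml_text)
    from lidckit.lidc_xml import parse_annotation_string

    return xml_text, parse_annotation_string(xml_text)


def _sessions_to_xml(sessions: list[list[dict]]) -> str:
    root = etree.Element("LidcReadMessage")
    header = etree.SubElement(root, "ResponseHeader")
    etree.SubElement(header, "Version").text = "1.0"
    for session in sessions:
        sess_el = etree.SubElement(root, "readingSession")
        for nod in session:
            nod_el = etree.SubElement(sess_el, "unblindedReadNodule")
            etree.SubElement(nod_el, "noduleID").text = nod["id"]
            if nod["characteristics"]:
                chars_el = etree.SubElement(nod_el, "characteristics")
                for name in CHARACTERISTIC_NAMES:
                    if name in nod["characteristics"]:
                        etree.SubElement(chars_el, name).text = str(
                            nod["characteristics"][name]
                        )
            for roi in nod["rois"]:
                roi_el = etree.SubElement(nod_el, "roi")
                etree.SubElement(roi_el, "imageZposition").text = f"{roi['z']:.4f}"
                etree.SubElement(roi_el, "imageSOP_UID").text = roi["sop"]
                etree.SubElement(roi_el, "inclusion").text = (
                    "TRUE" if roi["inclusion"] else "FALSE"
                )
                for x, y in roi["points"]:
                    em = etree.SubElement(roi_el, "edgeMap")
                    etree.SubElement(em, "xCoord").text = str(x)
                    etree.SubElement(em, "yCoord").text = str(y)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def write_annotation_xml(
    annotations: list[NoduleAnnotation], out_path: str | Path | None = None
) -> str:
    """Serialize annotation records back to the supported XML dialect.

    Supports the parser round-trip: parse -> write -> parse yields
    structurally equal annotations.
    """
    n_sessions = max((a.session_index for a in annotations), default=-1) + 1
    sessions: list[list[dict]] = [[] for _ in range(max(n_sessions, 1))]
    for ann in annotations:
        sessions[ann.session_index].append(
            {
                "id": ann.annotation_id,
                "characteristics": ann.characteristics.as_dict(),
                "rois": [
                    {
                        "z": roi.z_pos,
                        "sop": roi.slice_ref,
                        "inclusion": roi.inclusion,
                        "points": list(roi.points),
                    }
                    for roi in ann.rois
                ],
            }
        )
    xml_text = _sessions_to_xml(sessions)
    if out_path is not None:
        Path(out_path).write_text(xml_text)
    return xml_text
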