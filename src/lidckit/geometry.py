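"""CT series geometry: the voxel <-> patient coordinate frame.

A CT series is one DICOM file per slice.  The mapping between voxel indices
and patient-space millimetres is defined, per the DICOM convention, by the
first slice's ImagePositionPatient (origin), the shared
ImageOrientationPatient direction cosines, the in-plane PixelSpacing and the
ordered per-slice positions along the slice normal.

Voxel index convention, fixed once for the whole package: ``(i, j, k)`` =
(column, row, slice).  Column index ``i`` advances along the row direction
cosines with the column spacing; row index ``j`` advances along the column
direction cosines with the row spacing; ``k`` indexes slices sorted by their
patient-space position along the slice normal, never by file name or
instance number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom

__all__ = ["ScanGeometry", "GeometryError", "build_geometry"]


class GeometryError(ValueError):
    """Series whose geometry cannot be established unambiguously."""


@dataclass(frozen=True)
class ScanGeometry:
    """Voxel/patient frame of one CT series plus the slice lookup table.

    Attributes
    ----------
    pixel_spacing : (row_spacing, column_spacing) in mm.
    slice_positions : patient-space z of each slice along the slice normal,
        strictly monotonic, one entry per slice in sorted order.
    origin : ImagePositionPatient of the first (sorted) slice.
    orientation : 6 direction cosines (row then column), DICOM order.
    slice_table : slice identifier (SOPInstanceUID) -> sorted slice index.
    image_shape : (rows, columns).
    """

    pixel_spacing: tuple[float, float]
    slice_positions: tuple[float, ...]
    origin: tuple[float, float, float]
    orientation: tuple[float, float, float, float, float, float]
    slice_table: dict[str, int]
    image_shape: tuple[int, int]
    frame_of_reference_uid: str = ""
    series_instance_uid: str = ""
    sop_class_uid: str = ""
    slice_origins: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        steps = np.diff(self.slice_positions)
        if len(self.slice_positions) > 1 and not (
            np.all(steps > 0) or np.all(steps < 0)
        ):
            raise GeometryError("slice positions are not strictly monotonic")
        if min(self.pixel_spacing) <= 0:
            raise GeometryError("pixel spacing must be positive")
        n = len(self.slice_positions)
        if sorted(self.slice_table.values()) != list(range(n)):
            raise GeometryError("slice_table is not a bijection onto 0..n-1")

    @property
    def n_slices(self) -> int:
        return len(self.slice_positions)

    @property
    def row_cosines(self) -> np.ndarray:
        return np.asarray(self.orientation[:3], dtype=float)

    @property
    def col_cosines(self) -> np.ndarray:
        return np.asarray(self.orientation[3:], dtype=float)

    @property
    def slice_normal(self) -> np.ndarray:
        return np.cross(self.row_cosines, self.col_cosines)

    @property
    def slice_step(self) -> float:
        """Median absolute spacing between consecutive slices in mm."""
        if self.n_slices < 2:
            return 0.0
        return float(np.median(np.abs(np.diff(self.slice_positions))))

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1] * (self.slice_step or 1.0)

    def slice_origin(self, k: int) -> np.ndarray:
        """Patient-space position of voxel (0, 0, k)."""
        if self.slice_origins:
            return np.asarray(self.slice_origins[k], dtype=float)
        return np.asarray(self.origin, dtype=float) + self.slice_normal * (
            self.slice_positions[k] - self.slice_positions[0]
        )

    def voxel_to_patient(self, ijk) -> np.ndarray:
        """Map voxel indices (column i, row j, slice k) to patient mm.

        Accepts a single (i, j, k) triple or an (n, 3) array; fractional
        indices are allowed (contour points live on pixel centers).
        """
        single = np.asarray(ijk).ndim == 1
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        k = np.rint(ijk[:, 2]).astype(int)
        if np.any(k < 0) or np.any(k >= self.n_slices):
            raise IndexError(f"slice index out of bounds (0..{self.n_slices - 1})")
        rows, cols = self.image_shape
        if np.any(ijk[:, 0] < -0.5) or np.any(ijk[:, 0] > cols - 0.5):
            raise IndexError("column index out of image bounds")
        if np.any(ijk[:, 1] < -0.5) or np.any(ijk[:, 1] > rows - 0.5):
            raise IndexError("row index out of image bounds")
        row_sp, col_sp = self.pixel_spacing
        origins = np.stack([self.slice_origin(kk) for kk in k])
        out = (
            origins
            + ijk[:, [0]] * col_sp * self.row_cosines
            + ijk[:, [1]] * row_sp * self.col_cosines
        )
        return out[0] if single else out

    def patient_to_voxel(self, xyz) -> np.ndarray:
        """Inverse of :meth:`voxel_to_patient` (round-trip < 1e-6 mm)."""
        single = np.asarray(xyz).ndim == 1
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        rel0 = xyz - np.asarray(self.origin, dtype=float)
        z = rel0 @ self.slice_normal + self.slice_positions[0]
        positions = np.asarray(self.slice_positions)
        k = np.abs(positions[None, :] - z[:, None]).argmin(axis=1)
        origins = np.stack([self.slice_origin(kk) for kk in k])
        rel = xyz - origins
        row_sp, col_sp = self.pixel_spacing
        i = (rel @ self.row_cosines) / col_sp
        j = (rel @ self.col_cosines) / row_sp
        out = np.stack([i, j, k.astype(float)], axis=1)
        return out[0] if single else out

    def slice_index_for_position(self, z: float, tol: float | None = None) -> int:
        """Sorted slice index whose normal-position is nearest to ``z``."""
        positions = np.asarray(self.slice_positions)
        k = int(np.abs(positions - z).argmin())
        if tol is not None and abs(positions[k] - z) > tol:
            raise GeometryError(
                f"no slice within {tol} mm of position {z} "
                f"(nearest: {positions[k]})"
            )
        return k


_GEOMETRY_TAGS = [
    "SOPInstanceUID",
    "SeriesInstanceUID",
    "ImagePositionPatient",
    "ImageOrientationPatient",
    "PixelSpacing",
    "Rows",
    "Columns",
]


def build_geometry(
    ct_series_dir: str | Path,
    *,
    step_tolerance: float = 0.01,
    require_axial: bool = True,
) -> ScanGeometry:
    """Derive the :class:`ScanGeometry` of a per-slice CT series directory.

    Slices are sorted by patient-space position along the slice normal.
    The series must be single, axial (unless ``require_axial`` is False),
    consistently oriented and spaced, with a uniform slice step within
    ``step_tolerance`` mm, and no duplicate slice positions.
    """
    ct_series_dir = Path(ct_series_dir)
    files = sorted(p for p in ct_series_dir.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in ct_series_dir.iterdir() if p.is_file())
    if len(files) < 2:
        raise GeometryError(f"need >= 2 CT slices in {ct_series_dir}, found {len(files)}")

    datasets = []
    for f in files:
        ds = pydicom.dcmread(str(f), stop_before_pixels=True)
        for tag in _GEOMETRY_TAGS:
            if getattr(ds, tag, None) is None:
                raise GeometryError(f"{f.name} lacks required attribute {tag}")
        datasets.append(ds)

    series_uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(series_uids) != 1:
        raise GeometryError(f"mixed series in directory: {sorted(series_uids)}")

    orientations = {tuple(round(float(v), 6) for v in ds.ImageOrientationPatient) for ds in datasets}
    if len(orientations) != 1:
        raise GeometryError("inconsistent ImageOrientationPatient across slices")
    orientation = tuple(float(v) for v in datasets[0].ImageOrientationPatient)

    spacings = {tuple(round(float(v), 6) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) != 1:
        raise GeometryError(f"inconsistent in-plane PixelSpacing: {sorted(spacings)}")
    row_sp, col_sp = (float(v) for v in datasets[0].PixelSpacing)

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise GeometryError(f"inconsistent image shape: {sorted(shapes)}")

    row_c = np.asarray(orientation[:3])
    col_c = np.asarray(orientation[3:])
    normal = np.cross(row_c, col_c)
    if require_axial:
        axis_aligned = (
            np.allclose(np.abs(row_c), [1, 0, 0], atol=1e-3)
            and np.allclose(np.abs(col_c), [0, 1, 0], atol=1e-3)
        )
        if not axis_aligned:
            raise GeometryError(
                "non-axial or gantry-tilted series: refusing rather than "
                "risking silent contour mis-binding"
            )

    records = []
    for ds in datasets:
        ipp = np.asarray([float(v) for v in ds.ImagePositionPatient])
        records.append((float(ipp @ normal), str(ds.SOPInstanceUID), tuple(ipp)))
    records.sort(key=lambda r: r[0])

    positions = [r[0] for r in records]
    dupes = [
        (records[i][1], records[i + 1][1])
        for i in range(len(records) - 1)
        if abs(positions[i + 1] - positions[i]) < 1e-6
    ]
    if dupes:
        raise GeometryError(f"duplicate slice positions between instances: {dupes}")

    steps = np.diff(positions)
    if np.ptp(steps) > step_tolerance:
        raise GeometryError(
            f"non-uniform slice step (range {steps.min():.4f}..{steps.max():.4f} mm "
            f"exceeds tolerance {step_tolerance} mm); series may have gaps"
        )

    return ScanGeometry(
        pixel_spacing=(row_sp, col_sp),
        slice_positions=tuple(positions),
        origin=records[0][2],
        orientation=orientation,
        slice_table={uid: idx for idx, (_, uid, _) in enumerate(records)},
        image_shape=shapes.pop(),
        frame_of_reference_uid=str(getattr(datasets[0], "FrameOfReferenceUID", "")),
        series_instance_uid=str(datasets[0].SeriesInstanceUID),
        sop_class_uid=str(getattr(datasets[0], "SOPClassUID", "")),
        slice_origins=tuple(r[2] for r in records),
    )
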