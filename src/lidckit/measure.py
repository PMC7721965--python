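"""The three per-annotation measurements reported in the SR documents.

* diameter — maximal in-plane dimension: the largest patient-space distance
  between two foreground boundary pixel centers on any single slice (the
  in-plane framing matches how the source collection defines a nodule's
  size, 3–30 mm greatest in-plane dimension);
* surface area — total triangle area of an isosurface mesh extracted from
  the binary volume at level 0.5 with voxel spacing applied;
* volume — foreground voxel count times the voxel volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

from lidckit.rasterize import MaskVolume

__all__ = ["MeasurementSet", "EmptyMaskError", "diameter", "surface_area", "volume", "measure_mask"]

#: in-scope nodules have greatest in-plane dimension <= 30 mm
MAX_EXPECTED_DIAMETER_MM = 30.0


class EmptyMaskError(ValueError):
    """Measurement requested on a mask with no foreground."""


@dataclass(frozen=True)
class MeasurementSet:
    diameter_mm: float
    surface_area_mm2: float
    volume_mm3: float

    def __post_init__(self) -> None:
        for name in ("diameter_mm", "surface_area_mm2", "volume_mm3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


def _require_nonempty(mask: MaskVolume) -> None:
    if mask.foreground_count == 0:
        raise EmptyMaskError("measurement requires a non-empty mask")


def _boundary_pixels_2d(sl: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of foreground pixels on the component boundary."""
    interior = binary_erosion(sl, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(sl & ~interior)


def diameter(mask: MaskVolume) -> float:
    """Maximal in-plane diameter in mm.

    Per slice, the maximum pairwise patient-space distance between
    foreground boundary pixel centers; the result is the maximum over
    slices.  Boundary pixels suffice: the diameter endpoints of a finite
    pixel set always lie on its boundary.  A single foreground pixel has
    diameter 0.
    """
    _require_nonempty(mask)
    g = mask.geometry
    row_sp, col_sp = g.pixel_spacing
    best = 0.0
    for k in mask.nonempty_slices:
        pts = _boundary_pixels_2d(mask.slice_mask(k))
        if len(pts) < 2:
            continue
        xy = np.column_stack([pts[:, 1] * col_sp, pts[:, 0] * row_sp])
        if len(xy) > 16:
            # the farthest pair lies on the convex hull
            try:
                xy = xy[ConvexHull(xy).vertices]
            except Exception:
                pass  # degenerate (collinear) sets: fall through to all pairs
        best = max(best, float(pdist(xy).max()))
    if best > MAX_EXPECTED_DIAMETER_MM:
        warnings.warn(
            f"diameter {best:.1f} mm exceeds the expected 30 mm for "
            "in-scope nodules",
            stacklevel=2,
        )
    return best


def surface_area(mask: MaskVolume) -> float:
    """Mesh surface area in mm².

    Marching-cubes isosurface of the zero-padded binary volume at level
    0.5, with voxel spacing applied, summed over triangle areas.  Padding
    closes the surface at the volume faces.
    """
    _require_nonempty(mask)
    g = mask.geometry
    # (col,row,slice) -> (slice,row,col) with matching spacing order
    vol = mask.voxels.transpose(2, 1, 0).astype(np.float32)
    vol = np.pad(vol, 1)
    spacing = (g.slice_step or 1.0, g.pixel_spacing[0], g.pixel_spacing[1])
    verts, faces, _, _ = marching_cubes(vol, level=0.5, spacing=spacing)
    return float(mesh_surface_area(verts, faces))


def volume(mask: MaskVolume) -> float:
    """Volume in mm³: foreground voxel count × voxel volume."""
    _require_nonempty(mask)
    return mask.foreground_count * mask.geometry.voxel_volume_mm3


def measure_mask(mask: MaskVolume) -> MeasurementSet:
    """All three measurements of one mask."""
    return MeasurementSet(
        diameter_mm=diameter(mask),
        surface_area_mm2=surface_area(mask),
        volume_mm3=volume(mask),
    )
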