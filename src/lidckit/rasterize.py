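"""Contour-to-mask rasterization with the contour-exterior convention.

The annotation contours trace the pixels *just outside* the nodule: the
contour pixels themselves must never be counted as nodule.  A naive polygon
fill that includes the boundary therefore systematically inflates every
mask — a known error mode in downstream re-implementations.  The rule used
here is the strict interior: a pixel belongs to the region when its center
is inside the closed polygon through the contour pixel centers (even-odd
rule) AND the center does not lie exactly on any polygon edge.

Per slice, the nodule region is the union of the strict interiors of the
included contours minus the union of the strict interiors of the excluded
contours.  Exclusion contours mirror the inclusion convention: their own
pixels lie outside the excluded region, so only the strict interior is
removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from lidckit.geometry import ScanGeometry
from lidckit.lidc_xml import ContourRoi, NoduleAnnotation

__all__ = [
    "MaskVolume",
    "DegenerateContourError",
    "MaskBuildError",
    "rasterize_roi",
    "build_mask",
]


class DegenerateContourError(ValueError):
    """Contour with fewer than 3 points or zero enclosed area."""


class MaskBuildError(ValueError):
    """Annotation that cannot be bound to the scan geometry."""


@dataclass(frozen=True)
class MaskVolume:
    """Binary voxel mask of one annotation, aligned to a CT geometry.

    ``voxels[i, j, k]`` is indexed (column, row, slice), matching the
    package-wide voxel convention.
    """

    voxels: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        if self.voxels.dtype != bool:
            object.__setattr__(self, "voxels", self.voxels.astype(bool))

    @property
    def nonempty_slices(self) -> list[int]:
        """Sorted slice indices containing at least one foreground voxel."""
        return [int(k) for k in np.flatnonzero(self.voxels.any(axis=(0, 1)))]

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def slice_mask(self, k: int) -> np.ndarray:
        """The (rows, columns) binary mask of slice ``k``."""
        return self.voxels[:, :, k].T


def _polygon_edges(points: np.ndarray) -> np.ndarray:
    """Closed edge list (n, 2, 2); the last point connects back to the first."""
    nxt = np.roll(points, -1, axis=0)
    edges = np.stack([points, nxt], axis=1)
    keep = ~np.all(edges[:, 0] == edges[:, 1], axis=1)
    return edges[keep]


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _is_self_intersecting(points: np.ndarray) -> bool:
    """Proper (interior) crossing test between non-adjacent edges."""
    edges = _polygon_edges(points).astype(float)
    n = len(edges)
    for a in range(n):
        p, p2 = edges[a]
        r = p2 - p
        for b in range(a + 1, n):
            q, q2 = edges[b]
            s = q2 - q
            # skip edges that share an endpoint (adjacent in the ring)
            if (
                np.array_equal(p, q) or np.array_equal(p, q2)
                or np.array_equal(p2, q) or np.array_equal(p2, q2)
            ):
                continue
            denom = _cross2(r, s)
            if denom == 0:
                continue
            t = _cross2(q - p, s) / denom
            u = _cross2(q - p, r) / denom
            if 0 < t < 1 and 0 < u < 1:
                return True
    return False


def _points_on_edges(px: np.ndarray, py: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Exact integer test: does pixel center (px, py) lie on any edge segment?"""
    on = np.zeros(px.shape, dtype=bool)
    for (x1, y1), (x2, y2) in edges:
        dx, dy = x2 - x1, y2 - y1
        cross = (px - x1) * dy - (py - y1) * dx
        dot = (px - x1) * dx + (py - y1) * dy
        seg_len2 = dx * dx + dy * dy
        on |= (cross == 0) & (dot >= 0) & (dot <= seg_len2)
    return on


def _points_in_polygon_evenodd(
    px: np.ndarray, py: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Even-odd crossing-number containment for pixel centers.

    Uses the half-open rule [y1, y2) on each edge so ray-through-vertex
    cases count exactly once; points exactly on an edge are resolved
    separately by the on-edge test.
    """
    inside = np.zeros(px.shape, dtype=bool)
    fx, fy = px.astype(float), py.astype(float)
    for (x1, y1), (x2, y2) in edges.astype(float):
        if y1 == y2:
            continue
        cond = (y1 <= fy) != (y2 <= fy)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (fy - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (fx < x_at)
    return inside


def strict_interior(
    points: list[tuple[int, int]] | np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Strict-interior fill of one closed contour on a (rows, cols) grid.

    Returns a (rows, cols) boolean mask: True where the pixel center is
    inside the polygon (even-odd rule) and not on any edge through the
    contour pixel centers.
    """
    pts = np.asarray(points, dtype=np.int64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateContourError(
            f"contour needs >= 3 (x, y) points, got {np.atleast_2d(pts).shape}"
        )
    # drop an explicit closing repeat of the first point
    if np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3 or len(np.unique(pts, axis=0)) < 3:
        raise DegenerateContourError("contour collapses to fewer than 3 distinct points")
    edges = _polygon_edges(pts)
    if _is_self_intersecting(pts):
        # a self-crossing contour can have zero signed area yet enclose
        # pixels; fill it anyway under the even-odd rule
        warnings.warn(
            "self-intersecting contour; applying even-odd fill rule",
            stacklevel=2,
        )
    else:
        area2 = np.sum(
            pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1]
        )
        if area2 == 0:
            raise DegenerateContourError(
                "degenerate contour: zero enclosed area (collinear points)"
            )
    rows, cols = shape
    x_lo = max(int(pts[:, 0].min()), 0)
    x_hi = min(int(pts[:, 0].max()), cols - 1)
    y_lo = max(int(pts[:, 1].min()), 0)
    y_hi = min(int(pts[:, 1].max()), rows - 1)
    mask = np.zeros((rows, cols), dtype=bool)
    if x_lo > x_hi or y_lo > y_hi:
        return mask
    gx, gy = np.meshgrid(
        np.arange(x_lo, x_hi + 1), np.arange(y_lo, y_hi + 1), indexing="xy"
    )
    inside = _points_in_polygon_evenodd(gx, gy, edges)
    on_edge = _points_on_edges(gx, gy, edges)
    mask[y_lo : y_hi + 1, x_lo : x_hi + 1] = inside & ~on_edge
    return mask


def rasterize_roi(roi: ContourRoi, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one contour to a (rows, cols) strict-interior mask.

    The contour-path pixels themselves are always background; pixels whose
    centers fall exactly on a segment between contour points are likewise
    excluded.
    """
    pts = np.asarray(roi.points, dtype=np.int64)
    rows, cols = shape
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] >= cols) or np.any(
        pts[:, 1] < 0
    ) or np.any(pts[:, 1] >= rows):
        raise MaskBuildError("contour points outside image bounds")
    return strict_interior(pts, shape)


def build_mask(ann: NoduleAnnotation, g: ScanGeometry) -> MaskVolume:
    """Rasterize a full annotation into a mask volume in the CT frame.

    Per slice the region is (union of included strict interiors) minus
    (union of excluded strict interiors); slices carrying only excluded
    contours contribute nothing.  An annotation whose mask comes out empty
    is an error: a volumetric annotation is expected to enclose pixels.
    """
    rows, cols = g.image_shape
    vol = np.zeros((g.n_slices, rows, cols), dtype=bool)
    exclusions: dict[int, np.ndarray] = {}
    for roi in ann.rois:
        if not roi.is_volumetric:
            continue
        if roi.slice_ref not in g.slice_table:
            raise MaskBuildError(
                f"annotation {ann.annotation_id!r}: slice reference "
                f"{roi.slice_ref!r} not found in the CT series"
            )
        k = g.slice_table[roi.slice_ref]
        m = rasterize_roi(roi, (rows, cols))
        if roi.inclusion:
            vol[k] |= m
        else:
            exclusions[k] = exclusions.get(k, np.zeros((rows, cols), dtype=bool)) | m
    for k, excl in exclusions.items():
        vol[k] &= ~excl
    if not vol.any():
        raise MaskBuildError(
            f"annotation {ann.annotation_id!r} produced an empty mask; "
            "a volumetric annotation is expected"
        )
    # (slice, row, col) -> (col, row, slice)
    return MaskVolume(voxels=vol.transpose(2, 1, 0), geometry=g)
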