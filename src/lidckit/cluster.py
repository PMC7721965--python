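"""Grouping per-reader annotations into physical nodules.

The public annotations carry no nodule identity linking one reader's
annotation to another's, so annotations are clustered by spatial proximity:
single-linkage connected components of the graph whose edges join
annotation pairs with minimum patient-space contour distance at or below a
tolerance.  Each resulting cluster is one nodule; it receives a 1-based
nodule number (first-appearance order) and one globally unique tracking
identifier shared by all of its member annotations.

Because up to four readers annotated any scan, a cluster of more than four
members signals nodules too close to separate automatically; such clusters
are permitted and flagged, never split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from lidckit.geometry import ScanGeometry
from lidckit.lidc_xml import NoduleAnnotation
from lidckit.uid import UidFactory

__all__ = ["NoduleCluster", "annotation_distance", "cluster_annotations"]


@dataclass
class NoduleCluster:
    """One physical nodule: its number, tracking UID, and member annotations."""

    nodule_number: int
    tracking_uid: str
    members: list[NoduleAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a nodule cluster must have at least one member")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def tracking_id(self) -> str:
        """Human-readable tracking label, unique within a scan."""
        return f"Nodule {self.nodule_number}"


def _contour_points_patient(ann: NoduleAnnotation, g: ScanGeometry) -> np.ndarray:
    pts = []
    for roi in ann.rois:
        if roi.slice_ref not in g.slice_table:
            raise ValueError(
                f"annotation {ann.annotation_id!r}: slice reference "
                f"{roi.slice_ref!r} not in geometry"
            )
        k = g.slice_table[roi.slice_ref]
        for x, y in roi.points:
            pts.append((x, y, k))
    if not pts:
        raise ValueError(f"annotation {ann.annotation_id!r} has no contour points")
    return g.voxel_to_patient(np.asarray(pts, dtype=float))


def annotation_distance(
    a: NoduleAnnotation, b: NoduleAnnotation, g: ScanGeometry
) -> float:
    """Minimum patient-space distance (mm) between two annotations' contours.

    Zero when the contour point sets share or overlap points; symmetric by
    construction.
    """
    pa = np.atleast_2d(_contour_points_patient(a, g))
    pb = np.atleast_2d(_contour_points_patient(b, g))
    tree = cKDTree(pb)
    d, _ = tree.query(pa, k=1)
    return float(np.min(d))


def cluster_annotations(
    anns: list[NoduleAnnotation],
    g: ScanGeometry,
    tol: float | None = None,
    *,
    uid_factory: UidFactory | None = None,
) -> list[NoduleCluster]:
    """Single-linkage clustering of annotations into nodules.

    Parameters
    ----------
    anns : annotations of one scan (document order defines numbering).
    g : the scan geometry both annotations are bound to.
    tol : linkage tolerance in mm; annotations at distance <= tol are the
        same nodule.  Defaults to the scan's slice step — proximity on the
        order of one slice separation is the natural scale when no
        threshold is prescribed.
    uid_factory : source of tracking UIDs (fresh default if omitted).

    Returns clusters numbered 1..K by first appearance of any member, each
    with a distinct tracking UID shared by its members.
    """
    if tol is None:
        tol = g.slice_step
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    if uid_factory is None:
        uid_factory = UidFactory()
    if not anns:
        return []

    n = len(anns)
    points = [np.atleast_2d(_contour_points_patient(a, g)) for a in anns]
    trees = [cKDTree(p) for p in points]

    # union-find over pairs within tolerance (single linkage == connected
    # components of the thresholded distance graph)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d, _ = trees[j].query(points[i], k=1)
            if float(np.min(d)) <= tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for number, root in enumerate(sorted(groups, key=lambda r: min(groups[r])), start=1):
        clusters.append(
            NoduleCluster(
                nodule_number=number,
                tracking_uid=uid_factory.new_uid(),
                members=[anns[i] for i in sorted(groups[root])],
            )
        )
    return clusters
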