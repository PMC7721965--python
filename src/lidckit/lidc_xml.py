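"""Parsing of the LIDC annotation XML dialect.

One annotation file describes every reading session for one CT scan.  Each
session contains zero or more nodule annotations; each annotation carries an
identifier, optional characteristic ratings and one or more per-slice ROIs.
An ROI is an ordered list of (x, y) pixel coordinates (the "edge map"), a
patient-space z position, a reference to the CT slice it was drawn on, and
an inclusion flag distinguishing included from excluded regions.

Reader identity is intentionally absent from the public data; the reading
session ordinal is kept for bookkeeping only and must never be interpreted
as a reader.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

from lxml import etree

__all__ = [
    "ContourRoi",
    "Characteristics",
    "NoduleAnnotation",
    "CHARACTERISTIC_NAMES",
    "CHARACTERISTIC_RANGES",
    "LidcXmlError",
    "UnsupportedDialectError",
    "parse_annotation_file",
    "parse_annotation_string",
    "select_volumetric",
]

#: XML attribute names of the nine per-nodule characteristics, in the
#: order they conventionally appear in the characteristics block.
CHARACTERISTIC_NAMES = (
    "subtlety",
    "internalStructure",
    "calcification",
    "sphericity",
    "margin",
    "lobulation",
    "spiculation",
    "texture",
    "malignancy",
)

#: Documented rating range per characteristic (inclusive integer bounds).
CHARACTERISTIC_RANGES = {
    "subtlety": (1, 5),
    "internalStructure": (1, 4),
    "calcification": (1, 6),
    "sphericity": (1, 5),
    "margin": (1, 5),
    "lobulation": (1, 5),
    "spiculation": (1, 5),
    "texture": (1, 5),
    "malignancy": (1, 5),
}


class LidcXmlError(ValueError):
    """Malformed or structurally invalid annotation XML."""


class UnsupportedDialectError(LidcXmlError):
    """Well-formed XML whose root element is not the supported dialect."""


@dataclass(frozen=True)
class ContourRoi:
    """A single planar contour on one CT slice.

    ``points`` are 0-based integer pixel indices, ``x`` = column and
    ``y`` = row.  ``inclusion`` is True for an included region, False for an
    excluded region carved out of an enclosing included region.  The contour
    pixels themselves lie just outside the region they delimit.
    """

    slice_ref: str
    z_pos: float
    inclusion: bool
    points: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise LidcXmlError("ROI must contain at least one contour point")

    @property
    def is_volumetric(self) -> bool:
        """True when the contour is a genuine polygon (>= 3 points)."""
        return len(self.points) >= 3


@dataclass(frozen=True)
class Characteristics:
    """The nine subjective ratings of one annotation; each may be unset."""

    subtlety: Optional[int] = None
    internalStructure: Optional[int] = None
    calcification: Optional[int] = None
    sphericity: Optional[int] = None
    margin: Optional[int] = None
    lobulation: Optional[int] = None
    spiculation: Optional[int] = None
    texture: Optional[int] = None
    malignancy: Optional[int] = None

    def as_dict(self) -> dict[str, int]:
        """Present ratings as a name -> value mapping (unset fields omitted)."""
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) is not None
        }

    def n_present(self) -> int:
        return len(self.as_dict())


@dataclass(frozen=True)
class NoduleAnnotation:
    """One reader's complete volumetric annotation of one nodule."""

    annotation_id: str
    rois: tuple[ContourRoi, ...]
    characteristics: Characteristics = field(default_factory=Characteristics)
    session_index: int = 0

    @property
    def included_rois(self) -> tuple[ContourRoi, ...]:
        return tuple(r for r in self.rois if r.inclusion)

    @property
    def excluded_rois(self) -> tuple[ContourRoi, ...]:
        return tuple(r for r in self.rois if not r.inclusion)

    def contour_points_3d(self) -> list[tuple[int, int, str]]:
        """All contour points as (x, y, slice_ref) tuples."""
        return [(x, y, r.slice_ref) for r in self.rois for (x, y) in r.points]


def _local(tag: str) -> str:
    """Strip any XML namespace from a tag name."""
    return tag.rsplit("}", 1)[-1]


def _find_children(elem, name: str):
    return [c for c in elem if isinstance(c.tag, str) and _local(c.tag) == name]


def _child_text(elem, name: str) -> Optional[str]:
    for c in elem:
        if isinstance(c.tag, str) and _local(c.tag) == name:
            return (c.text or "").strip()
    return None


def _parse_characteristics(elem) -> Characteristics:
    values: dict[str, int] = {}
    for child in elem:
        if not isinstance(child.tag, str):
            continue
        name = _local(child.tag)
        if name not in CHARACTERISTIC_RANGES:
            continue
        text = (child.text or "").strip()
        if not text:
            continue
        try:
            rating = int(float(text))
        except ValueError:
            warnings.warn(
                f"non-numeric {name} rating {text!r}; treating as unset",
                stacklevel=2,
            )
            continue
        lo, hi = CHARACTERISTIC_RANGES[name]
        if not lo <= rating <= hi:
            warnings.warn(
                f"{name} rating {rating} outside documented range "
                f"[{lo}, {hi}]; treating as unset",
                stacklevel=2,
            )
            continue
        values[name] = rating
    return Characteristics(**values)


def _parse_roi(elem) -> ContourRoi:
    z_text = _child_text(elem, "imageZposition")
    sop = _child_text(elem, "imageSOP_UID")
    if sop is None:
        raise LidcXmlError("roi element lacks an imageSOP_UID slice reference")
    incl_text = (_child_text(elem, "inclusion") or "TRUE").upper()
    points = []
    for em in _find_children(elem, "edgeMap"):
        x = _child_text(em, "xCoord")
        y = _child_text(em, "yCoord")
        if x is None or y is None:
            raise LidcXmlError("edgeMap lacks xCoord/yCoord")
        points.append((int(x), int(y)))
    return ContourRoi(
        slice_ref=sop,
        z_pos=float(z_text) if z_text else 0.0,
        inclusion=incl_text == "TRUE",
        points=tuple(points),
    )


def _parse_nodule(elem, session_index: int) -> NoduleAnnotation:
    ann_id = _child_text(elem, "noduleID")
    if ann_id is None:
        raise LidcXmlError("nodule element lacks a noduleID")
    characteristics = Characteristics()
    for ch in _find_children(elem, "characteristics"):
        characteristics = _parse_characteristics(ch)
    rois = tuple(_parse_roi(r) for r in _find_children(elem, "roi"))
    return NoduleAnnotation(
        annotation_id=ann_id,
        rois=rois,
        characteristics=characteristics,
        session_index=session_index,
    )


def parse_annotation_string(text: str | bytes) -> list[NoduleAnnotation]:
    """Parse annotation XML from an in-memory string; see parse_annotation_file."""
    if isinstance(text, str):
        text = text.encode()
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise LidcXmlError(f"malformed XML: {exc}") from exc
    return _parse_root(root)


def parse_annotation_file(path: str | Path) -> list[NoduleAnnotation]:
    """Parse one LIDC-dialect annotation file.

    Returns every nodule annotation from every reading session in document
    order, including non-volumetric (center-only) marks; use
    :func:`select_volumetric` to filter those out.

    Raises
    ------
    LidcXmlError
        On malformed XML (the message names the line) or structural defects.
    UnsupportedDialectError
        When the root element is not a LIDC read message.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise LidcXmlError(f"malformed XML in {path.name}: {exc}") from exc
    return _parse_root(tree.getroot())


def _parse_root(root) -> list[NoduleAnnotation]:
    if _local(root.tag) != "LidcReadMessage":
        raise UnsupportedDialectError(
            f"unsupported annotation dialect: root element {_local(root.tag)!r} "
            "(expected LidcReadMessage)"
        )
    annotations: list[NoduleAnnotation] = []
    session_index = 0
    for session in root:
        if not isinstance(session.tag, str):
            continue
        if _local(session.tag) != "readingSession":
            continue
        for nod in session:
            if isinstance(nod.tag, str) and _local(nod.tag) == "unblindedReadNodule":
                annotations.append(_parse_nodule(nod, session_index))
        session_index += 1
    seen: dict[str, int] = {}
    for ann in annotations:
        seen[ann.annotation_id] = seen.get(ann.annotation_id, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        warnings.warn(
            f"annotation identifiers not unique within file: {dupes}",
            stacklevel=2,
        )
    return annotations


def select_volumetric(
    annotations: list[NoduleAnnotation],
) -> list[NoduleAnnotation]:
    """Keep only volumetrically contoured annotations, preserving order.

    An annotation qualifies when at least one *included* ROI is a polygon of
    three or more points.  Center-of-mass marks (single-point ROIs, used for
    nodules < 3 mm and non-nodules) and degenerate two-point contours are
    dropped: only nodules that were contoured volumetrically are converted.
    """
    return [
        ann
        for ann in annotations
        if any(r.is_volumetric for r in ann.included_rois)
    ]
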