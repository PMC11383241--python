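"""Pascal VOC-style annotated image handling.

Reads and writes per-image XML annotation files in the ``object/name/bndbox``
dialect, enforces the ``<datetime>-<landscape>`` naming convention used for
top-view relevée photographs, applies the minimum-FCU-size annotation filter,
and computes dataset summary statistics.

Coordinate conventions
----------------------
Internally every box is 0-based and half-open: a box covers the pixel grid
cells ``[xmin, xmax) x [ymin, ymax)`` so that ``area = (xmax-xmin)*(ymax-ymin)``.
On disk, VOC XML is treated as 1-based with inclusive corners (the common
reading of the format), so the conversion is ``xmin_int = xmin_voc - 1`` and
``xmax_int = xmax_voc``.  The conversion is centralized in :func:`read_voc`
and :func:`write_voc`; nothing else in the package touches it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "LANDSCAPES",
    "DEFAULT_MM_PER_PX",
    "Box",
    "Annotation",
    "AnnotatedImage",
    "DatasetSummary",
    "VocError",
    "parse_image_id",
    "format_image_id",
    "read_voc",
    "write_voc",
    "filter_min_size",
    "summarize",
]

#: The five landscape types sampled by the survey protocol.
LANDSCAPES = ("roadside", "urban_green", "cropland", "grassland", "marsh")

#: Default ground-sampling distance.  A ~1 m^2 relevée photographed at
#: 6720 px across gives roughly 0.15 mm per pixel; override where known.
DEFAULT_MM_PER_PX = 0.15

#: Filename timestamp layout: date, then time, then the landscape token.
_DATETIME_FMT = "%Y%m%d-%H%M"


class VocError(ValueError):
    """Raised for malformed VOC files, invalid boxes, or bad image ids."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned pixel box, 0-based half-open ``[xmin,xmax) x [ymin,ymax)``."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise VocError(
                f"degenerate box [{self.xmin},{self.xmax})x[{self.ymin},{self.ymax})"
            )

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    @property
    def height(self) -> int:
        return self.ymax - self.ymin

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "Box") -> int:
        w = min(self.xmax, other.xmax) - max(self.xmin, other.xmin)
        h = min(self.ymax, other.ymax) - max(self.ymin, other.ymin)
        return w * h if w > 0 and h > 0 else 0

    def shift(self, dx: int, dy: int) -> "Box":
        return Box(self.xmin + dx, self.ymin + dy, self.xmax + dx, self.ymax + dy)

    def clip(self, xmin: int, ymin: int, xmax: int, ymax: int) -> Optional["Box"]:
        """Clip to a rectangle; ``None`` if nothing remains."""
        x0, y0 = max(self.xmin, xmin), max(self.ymin, ymin)
        x1, y1 = min(self.xmax, xmax), min(self.ymax, ymax)
        if x0 >= x1 or y0 >= y1:
            return None
        return Box(x0, y0, x1, y1)


@dataclass(frozen=True)
class Annotation:
    """A ground-truth floral count unit: species label plus its tight box."""

    species_label: str
    box: Box
    annotation_id: str

    def __post_init__(self) -> None:
        if not self.species_label:
            raise VocError("annotation with empty species label")


@dataclass
class AnnotatedImage:
    """One annotated relevée photograph.

    ``pixels`` is an optional ``(height, width, 3)`` uint8 raster; all
    geometric operations work on boxes alone, so it may be ``None``.
    """

    image_id: str
    width: int
    height: int
    annotations: list[Annotation] = field(default_factory=list)
    landscape: Optional[str] = None
    capture_datetime: Optional[datetime] = None
    pixels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise VocError(f"invalid image size {self.width}x{self.height}")
        for ann in self.annotations:
            self._check_bounds(ann)
        ids = [a.annotation_id for a in self.annotations]
        if len(set(ids)) != len(ids):
            raise VocError(f"duplicate annotation ids in image {self.image_id!r}")

    def _check_bounds(self, ann: Annotation) -> None:
        b = ann.box
        if b.xmin < 0 or b.ymin < 0 or b.xmax > self.width or b.ymax > self.height:
            raise VocError(
                f"annotation {ann.annotation_id!r} box "
                f"[{b.xmin},{b.xmax})x[{b.ymin},{b.ymax}) outside image "
                f"{self.image_id!r} ({self.width}x{self.height})"
            )

    @property
    def species_present(self) -> set[str]:
        return {a.species_label for a in self.annotations}


def parse_image_id(name: str) -> tuple[datetime, str]:
    """Split an image id into capture datetime and landscape token.

    The grammar is ``YYYYMMDD-HHMM-<landscape>`` with the landscape drawn
    from the five survey types.
    """
    parts = name.split("-")
    if len(parts) != 3:
        raise VocError(f"image id {name!r} does not match YYYYMMDD-HHMM-<landscape>")
    stamp, landscape = f"{parts[0]}-{parts[1]}", parts[2]
    if landscape not in LANDSCAPES:
        raise VocError(
            f"unknown landscape {landscape!r} in image id {name!r}; "
            f"expected one of {LANDSCAPES}"
        )
    try:
        dt = datetime.strptime(stamp, _DATETIME_FMT)
    except ValueError as exc:
        raise VocError(f"unparseable datetime {stamp!r} in image id {name!r}") from exc
    return dt, landscape


def format_image_id(dt: datetime, landscape: str) -> str:
    """Inverse of :func:`parse_image_id`."""
    if landscape not in LANDSCAPES:
        raise VocError(f"unknown landscape {landscape!r}")
    return f"{dt.strftime(_DATETIME_FMT)}-{landscape}"


def _int_text(elem, tag: str, path: str) -> int:
    child = elem.find(tag)
    if child is None or child.text is None:
        raise VocError(f"{path}: missing <{tag}>")
    try:
        # labelImg sometimes writes floats; accept and round.
        return int(round(float(child.text)))
    except ValueError as exc:
        raise VocError(f"{path}: bad integer in <{tag}>: {child.text!r}") from exc


def read_voc(xml_path) -> AnnotatedImage:
    """Read a VOC annotation file into an :class:`AnnotatedImage` (no raster).

    On-disk 1-based inclusive coordinates become internal 0-based half-open.
    Boxes outside the image extent or with non-positive area are rejected.
    """
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise VocError(f"cannot parse VOC file {xml_path}: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise VocError(f"{xml_path}: missing <size> block")
    width = _int_text(size, "width", str(xml_path))
    height = _int_text(size, "height", str(xml_path))

    image_id = xml_path.stem
    fn = root.findtext("filename")
    if fn:
        image_id = Path(fn).stem

    annotations = []
    for k, obj in enumerate(root.findall("object")):
        label = (obj.findtext("name") or "").strip()
        bnd = obj.find("bndbox")
        if bnd is None:
            raise VocError(f"{xml_path}: object {k} ({label!r}) missing <bndbox>")
        xmin = _int_text(bnd, "xmin", str(xml_path)) - 1
        ymin = _int_text(bnd, "ymin", str(xml_path)) - 1
        xmax = _int_text(bnd, "xmax", str(xml_path))
        ymax = _int_text(bnd, "ymax", str(xml_path))
        try:
            box = Box(xmin, ymin, xmax, ymax)
        except VocError as exc:
            raise VocError(f"{xml_path}: object {k} ({label!r}): {exc}") from exc
        annotations.append(Annotation(label, box, annotation_id=f"{image_id}#{k}"))

    landscape = capture = None
    try:
        capture, landscape = parse_image_id(image_id)
    except VocError:
        pass  # foreign VOC files need not follow the naming convention

    try:
        return AnnotatedImage(
            image_id=image_id,
            width=width,
            height=height,
            annotations=annotations,
            landscape=landscape,
            capture_datetime=capture,
        )
    except VocError as exc:
        raise VocError(f"{xml_path}: {exc}") from exc


def write_voc(image: AnnotatedImage, path, write_pixels: bool = True) -> Path:
    """Write ``<image_id>.xml`` (and ``.jpg`` when pixels are attached) under ``path``.

    ``path`` may be a directory or an explicit ``.xml`` file path.  Returns the
    XML path.  ``read_voc(write_voc(x))`` preserves boxes, labels and size.
    """
    path = Path(path)
    if path.suffix.lower() == ".xml":
        xml_path = path
    else:
        path.mkdir(parents=True, exist_ok=True)
        xml_path = path / f"{image.image_id}.xml"

    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = xml_path.parent.name
    etree.SubElement(root, "filename").text = f"{image.image_id}.jpg"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(image.width)
    etree.SubElement(size, "height").text = str(image.height)
    etree.SubElement(size, "depth").text = "3"
    etree.SubElement(root, "segmented").text = "0"
    for ann in image.annotations:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = ann.species_label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(ann.box.xmin + 1)
        etree.SubElement(bnd, "ymin").text = str(ann.box.ymin + 1)
        etree.SubElement(bnd, "xmax").text = str(ann.box.xmax)
        etree.SubElement(bnd, "ymax").text = str(ann.box.ymax)
    xml_path.write_bytes(etree.tostring(root, pretty_print=True))

    if write_pixels and image.pixels is not None:
        from PIL import Image as PILImage

        PILImage.fromarray(image.pixels).save(
            xml_path.with_suffix(".jpg"), quality=95
        )
    return xml_path


def filter_min_size(
    image: AnnotatedImage,
    min_size_mm: float = 10.0,
    mm_per_px: float = DEFAULT_MM_PER_PX,
) -> AnnotatedImage:
    """Drop annotations whose larger box side is not above ``min_size_mm``.

    Mirrors the annotation rule that only floral count units larger than
    10 mm are kept; "size" is the longer side of the tight box.  Idempotent;
    never alters surviving annotations.
    """
    if mm_per_px <= 0:
        raise VocError(f"mm_per_px must be positive, got {mm_per_px}")
    kept = [
        a
        for a in image.annotations
        if max(a.box.width, a.box.height) * mm_per_px > min_size_mm
    ]
    return replace(image, annotations=kept)


@dataclass(frozen=True)
class DatasetSummary:
    n_images: int
    n_annotations: int
    n_species: int
    per_species_counts: dict[str, int]
    annotations_per_image: dict[str, Optional[float]]
    species_per_image: dict[str, Optional[float]]

    def to_frame(self):
        """Per-species counts as a sorted pandas DataFrame."""
        import pandas as pd

        return (
            pd.DataFrame(
                sorted(self.per_species_counts.items(), key=lambda kv: (-kv[1], kv[0])),
                columns=["species", "n_annotations"],
            )
        )


def summarize(images: Iterable[AnnotatedImage]) -> DatasetSummary:
    """Dataset-level counts: totals, per-species tallies, per-image spreads."""
    images = list(images)
    per_species: dict[str, int] = {}
    ann_counts: list[int] = []
    sp_counts: list[int] = []
    for img in images:
        ann_counts.append(len(img.annotations))
        sp_counts.append(len(img.species_present))
        for ann in img.annotations:
            per_species[ann.species_label] = per_species.get(ann.species_label, 0) + 1

    n_images = len(images)
    n_annotations = sum(ann_counts)

    def _stats(values: Sequence[int], with_mean: bool) -> dict[str, Optional[float]]:
        if not values:
            out = {"min": 0, "max": 0, "median": None}
            if with_mean:
                out["mean"] = None
            return out
        out = {
            "min": int(min(values)),
            "max": int(max(values)),
            "median": float(np.median(values)),
        }
        if with_mean:
            out["mean"] = sum(values) / len(values)
        return out

    return DatasetSummary(
        n_images=n_images,
        n_annotations=n_annotations,
        n_species=len(per_species),
        per_species_counts=per_species,
        annotations_per_image=_stats(ann_counts, with_mean=True),
        species_per_image=_stats(sp_counts, with_mean=False),
    )
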