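"""PASCAL-VOC annotation I/O, annotation-quality filters and dataset splits.

Boxes are stored 0-based half-open ``[xmin, xmax) x [ymin, ymax)`` in memory
and written 1-based inclusive in XML, matching the LabelImg dialect that the
rest of the VOC ecosystem reads.  The filtering rules mirror common
annotation practice for occluded greenhouse scenes: boxes more than an
occlusion-fraction threshold covered by foreground clutter, and boxes at the
image border retaining less than a minimum fraction of their area, are
dropped rather than labeled.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


class VocParseError(ValueError):
    pass


@dataclass
class BoundingBox:
    class_label: str
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    occlusion_fraction: float = 0.0
    difficult: bool = False

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate box {self.class_label}: "
                f"({self.xmin},{self.ymin},{self.xmax},{self.ymax})"
            )
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must lie in [0, 1]")

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def as_xyxy(self) -> np.ndarray:
        return np.array([self.xmin, self.ymin, self.xmax, self.ymax], dtype=np.float64)

    def clipped(self, width: int, height: int) -> "BoundingBox | None":
        x1, y1 = max(self.xmin, 0.0), max(self.ymin, 0.0)
        x2, y2 = min(self.xmax, float(width)), min(self.ymax, float(height))
        if x2 <= x1 or y2 <= y1:
            return None
        return replace(self, xmin=x1, ymin=y1, xmax=x2, ymax=y2)


@dataclass
class LabeledImage:
    image: np.ndarray  # H x W x 3 uint8
    boxes: list[BoundingBox] = field(default_factory=list)
    source_path: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


def write_voc(xml_path, sample: LabeledImage, image_path: str = "") -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "VOC"  # location-independent output
    name = Path(image_path or sample.source_path or xml_path).name
    if name.endswith(".xml"):  # fall back to the sibling-image convention
        name = name[: -len(".xml")] + ".png"
    ET.SubElement(root, "filename").text = name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(sample.width)
    ET.SubElement(size, "height").text = str(sample.height)
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"
    for b in sample.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.class_label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "1" if b.difficult else "0"
        ET.SubElement(obj, "occlusion").text = f"{b.occlusion_fraction:.4f}"
        bb = ET.SubElement(obj, "bndbox")
        # stored half-open 0-based -> written inclusive 1-based
        ET.SubElement(bb, "xmin").text = str(int(round(b.xmin)) + 1)
        ET.SubElement(bb, "ymin").text = str(int(round(b.ymin)) + 1)
        ET.SubElement(bb, "xmax").text = str(int(round(b.xmax)))
        ET.SubElement(bb, "ymax").text = str(int(round(b.ymax)))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(xml_path, encoding="unicode")


def read_voc(xml_path, image: np.ndarray | None = None) -> LabeledImage:
    """Parse one VOC XML.  If ``image`` is None, the raster next to the XML
    (same stem, .png/.jpg) is loaded; failing that a blank canvas of the
    declared size is used."""
    xml_path = Path(xml_path)
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise VocParseError(f"malformed VOC XML {xml_path}: {exc}") from exc
    size = root.find("size")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    boxes = []
    for obj in root.findall("object"):
        bb = obj.find("bndbox")
        xmin = float(bb.findtext("xmin")) - 1
        ymin = float(bb.findtext("ymin")) - 1
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        if xmin >= xmax or ymin >= ymax:
            raise VocParseError(
                f"invalid box in {xml_path}: ({xmin},{ymin},{xmax},{ymax})"
            )
        boxes.append(
            BoundingBox(
                class_label=obj.findtext("name"),
                xmin=xmin,
                ymin=ymin,
                xmax=xmax,
                ymax=ymax,
                occlusion_fraction=float(obj.findtext("occlusion", default="0")),
                difficult=obj.findtext("difficult", default="0").strip() == "1",
            )
        )
    if image is None:
        image = _load_sibling_image(xml_path, width, height)
    return LabeledImage(image=image, boxes=boxes, source_path=str(xml_path))


def _load_sibling_image(xml_path: Path, width: int, height: int) -> np.ndarray:
    from PIL import Image

    for ext in (".png", ".jpg", ".jpeg"):
        candidate = xml_path.with_suffix(ext)
        if candidate.exists():
            return np.asarray(Image.open(candidate).convert("RGB"))
    return np.zeros((height, width, 3), dtype=np.uint8)


# ---------------------------------------------------------------------------
# annotation filters
# ---------------------------------------------------------------------------

def filter_annotations(
    sample: LabeledImage,
    occlusion_max: float = 0.85,
    edge_min_area: float = 0.15,
) -> LabeledImage:
    """Drop boxes occluded beyond ``occlusion_max`` and border boxes whose
    in-image (clipped) area fraction falls below ``edge_min_area``."""
    for f in (occlusion_max, edge_min_area):
        if not 0.0 <= f <= 1.0:
            raise ValueError("filter fractions must lie in [0, 1]")
    kept = []
    w, h = sample.width, sample.height
    for b in sample.boxes:
        if b.occlusion_fraction > occlusion_max:
            continue
        touches_border = b.xmin <= 0 or b.ymin <= 0 or b.xmax >= w or b.ymax >= h
        if touches_border:
            clipped = b.clipped(w, h)
            if clipped is None or clipped.area / b.area < edge_min_area:
                continue
        kept.append(b)
    return LabeledImage(image=sample.image, boxes=kept, source_path=sample.source_path)


# ---------------------------------------------------------------------------
# manifests and splits
# ---------------------------------------------------------------------------

def write_manifest(path, records: list[dict]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_manifest(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def split_dataset(
    records: list[dict],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[dict], list[dict], list[dict]]:
    """Class-stratified train/val/test partition of manifest records.

    Per class, items are shuffled with the seed and cut at the cumulative
    fractions, so per-class proportions are within one item of exact.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[dict]] = {}
    for rec in records:
        by_class.setdefault(rec.get("class", ""), []).append(rec)
    splits: tuple[list[dict], ...] = ([], [], [])
    for label in sorted(by_class):
        items = by_class[label]
        order = rng.permutation(len(items))
        n = len(items)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_val = min(n_val, n - n_train)
        bounds = [0, n_train, n_train + n_val, n]
        for si in range(3):
            for j in order[bounds[si] : bounds[si + 1]]:
                splits[si].append(items[j])
    return splits


def load_class_list(path) -> list[str]:
    """Read a class-names file: one label per line, or a YAML list."""
    text = Path(path).read_text()
    if text.lstrip().startswith("-"):
        import yaml

        return list(yaml.safe_load(text))
    return [line.strip() for line in text.splitlines() if line.strip()]
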