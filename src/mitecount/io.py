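"""Readers and writers: PNG/JPEG images, VOC-style XML and CSV
annotations, detection tables, and JSON reports.

Coordinate conventions.  Internally every box is 0-based, continuous and
half-open, ``[x1, x2) x [y1, y2)``.  VOC XML stores 1-based *inclusive*
integer pixel coordinates, so the converters subtract 1 from the minima on
read and add 1 on write, leaving the maxima alone:
``xmin = x1 + 1, xmax = x2``.  The CSV dialect
(``image_id,x1,y1,x2,y2,class``) carries internal coordinates verbatim.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image

from .data import AnnotatedImage

DEFAULT_CLASS_NAMES = {1: "mite"}


def class_name(cls: int) -> str:
    return DEFAULT_CLASS_NAMES.get(int(cls), f"class{int(cls)}")


def class_id(name: str) -> int:
    for k, v in DEFAULT_CLASS_NAMES.items():
        if v == name:
            return k
    if name.startswith("class"):
        return int(name[5:])
    raise ValueError(f"unknown class name {name!r}")


# -- images -----------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """(H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


# -- VOC XML ----------------------------------------------------------------

def write_voc_xml(path, ann: AnnotatedImage, scores=None) -> None:
    """VOC-dialect annotation; optional per-box ``score`` elements."""
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "3"
    for i, (box, cls) in enumerate(zip(ann.boxes, ann.classes)):
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = class_name(cls)
        etree.SubElement(obj, "difficult").text = "0"
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = str(int(round(box[0])) + 1)
        etree.SubElement(bb, "ymin").text = str(int(round(box[1])) + 1)
        etree.SubElement(bb, "xmax").text = str(int(round(box[2])))
        etree.SubElement(bb, "ymax").text = str(int(round(box[3])))
        if scores is not None:
            etree.SubElement(obj, "score").text = f"{scores[i]:.6f}"
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


def read_voc_xml(path, image: np.ndarray | None = None) -> AnnotatedImage:
    """Parse a VOC-dialect XML; ``image`` may be supplied separately."""
    root = etree.parse(str(path)).getroot()
    w = int(root.findtext("size/width"))
    h = int(root.findtext("size/height"))
    image_id = Path(root.findtext("filename", default=Path(path).stem)).stem
    boxes, classes = [], []
    for obj in root.findall("object"):
        bb = obj.find("bndbox")
        boxes.append([float(bb.findtext("xmin")) - 1,
                      float(bb.findtext("ymin")) - 1,
                      float(bb.findtext("xmax")),
                      float(bb.findtext("ymax"))])
        classes.append(class_id(obj.findtext("name")))
    if image is None:
        image = np.zeros((h, w, 3), dtype=np.uint8)
    return AnnotatedImage(image=image, boxes=np.asarray(boxes).reshape(-1, 4),
                          classes=np.asarray(classes, dtype=np.int64),
                          image_id=image_id)


# -- CSV dialect ------------------------------------------------------------

CSV_HEADER = ["image_id", "x1", "y1", "x2", "y2", "class"]


def write_annotation_csv(path, anns: list[AnnotatedImage]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for ann in anns:
            for box, cls in zip(ann.boxes, ann.classes):
                w.writerow([ann.image_id, *(f"{v:.3f}" for v in box),
                            class_name(cls)])


def read_annotation_csv(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """-> {image_id: (boxes, classes)}; ids with zero boxes are absent."""
    out: dict[str, list] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["image_id"], []).append(
                ([float(row[k]) for k in ("x1", "y1", "x2", "y2")],
                 class_id(row["class"])))
    return {k: (np.asarray([b for b, _ in v]),
                np.asarray([c for _, c in v], dtype=np.int64))
            for k, v in out.items()}


DET_HEADER = ["image_id", "x1", "y1", "x2", "y2", "class", "score"]


def write_detection_csv(path, rows) -> None:
    """``rows``: iterable of (image_id, DetectionSet)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DET_HEADER)
        for image_id, dets in rows:
            for box, cls, score in zip(dets.boxes, dets.classes, dets.scores):
                w.writerow([image_id, *(f"{v:.3f}" for v in box),
                            class_name(cls), f"{score:.6f}"])


# -- datasets ---------------------------------------------------------------

def load_split(split_dir) -> list[AnnotatedImage]:
    """Load a dataset split written by the generator (PNG + XML)."""
    split_dir = Path(split_dir)
    anns = []
    for xml in sorted((split_dir / "annotations").glob("*.xml")):
        img_path = split_dir / "images" / f"{xml.stem}.png"
        anns.append(read_voc_xml(xml, read_image(img_path)))
    return anns


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
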