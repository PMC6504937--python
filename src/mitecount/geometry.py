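"""Box algebra: IoU, anchor lattices, regression encoding.

Boxes are axis-aligned rectangles ``(x1, y1, x2, y2)`` in continuous image
pixel coordinates, origin at the top-left corner, x rightward, y downward,
with the half-open convention ``[x1, x2) x [y1, y2)``.  A valid box has
strictly positive width and height.  Throughout the package boxes travel as
``(N, 4)`` float arrays; single boxes are 1-d arrays of length 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# exp(delta) clamp: keeps decoded sizes finite for adversarial deltas
MAX_LOG_SCALE = float(np.log(1000.0))


def as_boxes(boxes) -> np.ndarray:
    """Coerce input to an (N, 4) float64 array of boxes."""
    arr = np.asarray(boxes, dtype=np.float64)
    if arr.size == 0:
        return arr.reshape(0, 4)
    if arr.ndim == 1:
        arr = arr.reshape(1, 4)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError(f"expected (N, 4) boxes, got shape {arr.shape}")
    return arr


def validate_boxes(boxes: np.ndarray) -> np.ndarray:
    """Raise ValueError on any degenerate (non-positive area) box."""
    arr = as_boxes(boxes)
    w = arr[:, 2] - arr[:, 0]
    h = arr[:, 3] - arr[:, 1]
    if np.any(w <= 0) or np.any(h <= 0):
        bad = np.where((w <= 0) | (h <= 0))[0]
        raise ValueError(f"degenerate box(es) at index {bad.tolist()}: "
                         "width and height must be strictly positive")
    return arr


def box_area(boxes) -> np.ndarray:
    arr = as_boxes(boxes)
    return (arr[:, 2] - arr[:, 0]) * (arr[:, 3] - arr[:, 1])


def iou(a, b) -> float:
    """Intersection-over-union of two boxes (area of overlap / area of union)."""
    a = validate_boxes(a)[0]
    b = validate_boxes(b)[0]
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = box_area(a)[0] + box_area(b)[0] - inter
    return float(inter / union)


def iou_matrix(a, b) -> np.ndarray:
    """Pairwise IoU between (N, 4) and (M, 4) box arrays -> (N, M)."""
    a = as_boxes(a)
    b = as_boxes(b)
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ix = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0)
    iy = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0)
    inter = ix * iy
    union = box_area(a)[:, None] + box_area(b)[None, :] - inter
    return inter / union


@dataclass
class AnchorGrid:
    """Regular lattice of reference boxes tied to a feature-map stride.

    One anchor per (row, col, anchor-index); ``boxes`` is flattened
    row-major over (row, col, anchor) into an (W*H*A, 4) array, with
    A = len(scales) * len(ratios).
    """

    feature_w: int
    feature_h: int
    stride: float
    scales: tuple
    ratios: tuple
    boxes: np.ndarray = field(repr=False)

    @property
    def anchors_per_position(self) -> int:
        return len(self.scales) * len(self.ratios)

    def __len__(self) -> int:
        return self.boxes.shape[0]


def generate_anchors(feature_w: int, feature_h: int, stride: float,
                     scales: Sequence[float] = (4.0, 8.0, 16.0),
                     ratios: Sequence[float] = (0.8, 1.0, 1.5)) -> AnchorGrid:
    """Build the anchor lattice for a ``feature_w x feature_h`` feature map.

    Anchors are centred at cell centres ``((col + 0.5) * stride,
    (row + 0.5) * stride)``.  ``scales`` multiply the stride to give the base
    side length; ``ratios`` are height-to-width ratios applied
    area-preservingly: for scale s and ratio r, ``w = s*stride/sqrt(r)`` and
    ``h = s*stride*sqrt(r)``.  Defaults are three scales (4, 8, 16) and
    three height/width ratios (0.8, 1, 1.5) — nine anchors per position.
    Anchors may extend past the image; clipping is a separate operation.
    """
    if feature_w <= 0 or feature_h <= 0:
        raise ValueError("feature map dimensions must be positive")
    scales = tuple(float(s) for s in scales)
    ratios = tuple(float(r) for r in ratios)
    if not scales or not ratios:
        raise ValueError("scales and ratios must be non-empty")
    if any(s <= 0 for s in scales) or any(r <= 0 for r in ratios):
        raise ValueError("scales and ratios must be positive")

    # per-position anchor shapes, scale-major then ratio (A, 2)
    ws, hs = [], []
    for s in scales:
        base = s * stride
        for r in ratios:
            ws.append(base / np.sqrt(r))
            hs.append(base * np.sqrt(r))
    ws = np.asarray(ws)
    hs = np.asarray(hs)

    cx = (np.arange(feature_w) + 0.5) * stride
    cy = (np.arange(feature_h) + 0.5) * stride
    cyy, cxx = np.meshgrid(cy, cx, indexing="ij")          # (H, W)
    centers = np.stack([cxx, cyy], axis=-1).reshape(-1, 1, 2)  # (H*W, 1, 2)
    half = np.stack([ws, hs], axis=-1) / 2.0                   # (A, 2)
    mins = centers - half
    maxs = centers + half
    boxes = np.concatenate([mins, maxs], axis=-1).reshape(-1, 4)
    return AnchorGrid(feature_w=feature_w, feature_h=feature_h, stride=stride,
                      scales=scales, ratios=ratios, boxes=boxes)


def encode(anchors, targets) -> np.ndarray:
    """Parameterize target boxes relative to anchors.

    Returns (N, 4) deltas ``(dx, dy, dw, dh)`` with centre offsets
    normalized by anchor size and log-scale size ratios:
    ``dx = (cx_t - cx_a)/w_a``, ``dw = log(w_t/w_a)`` (same for y/h).
    """
    a = validate_boxes(anchors)
    t = validate_boxes(targets)
    wa, ha = a[:, 2] - a[:, 0], a[:, 3] - a[:, 1]
    wt, ht = t[:, 2] - t[:, 0], t[:, 3] - t[:, 1]
    cxa, cya = a[:, 0] + wa / 2, a[:, 1] + ha / 2
    cxt, cyt = t[:, 0] + wt / 2, t[:, 1] + ht / 2
    return np.stack([(cxt - cxa) / wa, (cyt - cya) / ha,
                     np.log(wt / wa), np.log(ht / ha)], axis=1)


def decode(anchors, deltas) -> np.ndarray:
    """Invert :func:`encode`; ``|dw|, |dh|`` clamped to log(1000)."""
    a = as_boxes(anchors)
    d = np.asarray(deltas, dtype=np.float64).reshape(-1, 4)
    wa, ha = a[:, 2] - a[:, 0], a[:, 3] - a[:, 1]
    cxa, cya = a[:, 0] + wa / 2, a[:, 1] + ha / 2
    dw = np.clip(d[:, 2], -MAX_LOG_SCALE, MAX_LOG_SCALE)
    dh = np.clip(d[:, 3], -MAX_LOG_SCALE, MAX_LOG_SCALE)
    cx = cxa + d[:, 0] * wa
    cy = cya + d[:, 1] * ha
    w = wa * np.exp(dw)
    h = ha * np.exp(dh)
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def clip_to_image(boxes, width: float, height: float):
    """Clamp boxes to ``[0, width] x [0, height]``.

    Returns ``(clipped, valid)`` where ``valid`` flags boxes that retain
    positive area; boxes entirely outside collapse to zero area and are
    flagged for removal.
    """
    arr = as_boxes(boxes).copy()
    arr[:, 0::2] = arr[:, 0::2].clip(0, width)
    arr[:, 1::2] = arr[:, 1::2].clip(0, height)
    valid = (arr[:, 2] > arr[:, 0]) & (arr[:, 3] > arr[:, 1])
    return arr, valid


def inflate_boxes(boxes, factor: float, width: float, height: float) -> np.ndarray:
    """Scale boxes about their centres by ``factor`` and clip to the image.

    Used to pool classification evidence over a context window around a
    small candidate box; the candidate itself is left untouched.
    """
    arr = as_boxes(boxes)
    cx = (arr[:, 0] + arr[:, 2]) / 2
    cy = (arr[:, 1] + arr[:, 3]) / 2
    hw = (arr[:, 2] - arr[:, 0]) * factor / 2
    hh = (arr[:, 3] - arr[:, 1]) * factor / 2
    out = np.stack([cx - hw, cy - hh, cx + hw, cy + hh], axis=1)
    out, _ = clip_to_image(out, width, height)
    return out


def nms_indices(boxes, scores, thresh: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first.

    Repeatedly keeps the highest-scoring box and suppresses every remaining
    box whose IoU with it is strictly greater than ``thresh`` (so
    ``thresh = 0`` forbids any positive overlap).  Score ties are broken by
    (x1 ascending, then y1 ascending) for determinism.
    """
    b = as_boxes(boxes)
    s = np.asarray(scores, dtype=np.float64)
    if len(b) == 0:
        return np.zeros(0, dtype=np.intp)
    order = np.lexsort((b[:, 1], b[:, 0], -s))
    x1, y1, x2, y2 = (b[order, i] for i in range(4))
    areas = (x2 - x1) * (y2 - y1)
    keep = []
    idx = np.arange(len(order))
    while idx.size:
        i = idx[0]
        keep.append(order[i])
        rest = idx[1:]
        ix = (np.minimum(x2[i], x2[rest]) - np.maximum(x1[i], x1[rest])).clip(min=0)
        iy = (np.minimum(y2[i], y2[rest]) - np.maximum(y1[i], y1[rest])).clip(min=0)
        inter = ix * iy
        ovr = inter / (areas[i] + areas[rest] - inter)
        idx = rest[ovr <= thresh]
    return np.asarray(keep, dtype=np.intp)


def flip_box_horizontal(boxes, width: float) -> np.ndarray:
    """Mirror boxes across the image's vertical centreline (x -> width - x)."""
    arr = as_boxes(boxes).copy()
    x1 = width - arr[:, 2]
    x2 = width - arr[:, 0]
    arr[:, 0], arr[:, 2] = x1, x2
    return arr
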