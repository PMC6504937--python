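"""Final-stage thresholding, NMS and pest counting.

Two knobs govern what is counted: the score threshold ``sth`` (minimum
classification probability for a detection to survive) and the NMS
threshold ``nth`` (maximum IoU allowed between two kept detections of the
same class; suppression uses strict ``IoU > nth``, so ``nth = 0`` forbids
any positive overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry, proposals, psroi

DEFAULT_SCORE_THRESHOLD = 0.5
DEFAULT_NMS_THRESHOLD = 0.5


def nms(dets, nth: float):
    """Greedy non-maximum suppression over ``(box, score)`` pairs.

    Returns the kept pairs in descending score order; a lower-scoring box
    is removed when its IoU with a kept box exceeds ``nth``.
    """
    if not 0.0 <= nth <= 1.0:
        raise ValueError("nth must lie in [0, 1]")
    dets = list(dets)
    if not dets:
        return []
    boxes = geometry.as_boxes([d[0] for d in dets])
    scores = np.asarray([d[1] for d in dets], dtype=np.float64)
    keep = geometry.nms_indices(boxes, scores, nth)
    return [(boxes[i], float(scores[i])) for i in keep]


@dataclass
class DetectionSet:
    """Detections surviving all filters, plus the thresholds that made them."""

    boxes: np.ndarray                     # (N, 4)
    classes: np.ndarray                   # (N,) foreground class ids (>= 1)
    scores: np.ndarray                    # (N,)
    sth: float = DEFAULT_SCORE_THRESHOLD
    nth: float = DEFAULT_NMS_THRESHOLD
    proposal_counters: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.boxes)

    def __len__(self) -> int:
        return len(self.boxes)


def apply_thresholds(scored_rois, sth: float, nth: float) -> DetectionSet:
    """Filter classified RoIs into the final detection set.

    ``scored_rois`` is an iterable of ``(box, class_id, prob)`` with class 0
    meaning background.  Background RoIs and RoIs with ``prob <= sth`` are
    dropped, then greedy NMS at ``nth`` runs per class; the detection count
    is the number of survivors.
    """
    rois = [(b, c, p) for (b, c, p) in scored_rois if c != 0 and p > sth]
    out_boxes, out_classes, out_scores = [], [], []
    for cls in sorted({c for _, c, _ in rois}):
        cls_rois = [(b, p) for (b, c, p) in rois if c == cls]
        for b, p in nms(cls_rois, nth):
            out_boxes.append(b)
            out_classes.append(cls)
            out_scores.append(p)
    order = np.argsort([-s for s in out_scores], kind="stable")
    boxes = (geometry.as_boxes([out_boxes[i] for i in order])
             if out_boxes else np.zeros((0, 4)))
    return DetectionSet(
        boxes=boxes,
        classes=np.asarray([out_classes[i] for i in order], dtype=np.int64),
        scores=np.asarray([out_scores[i] for i in order], dtype=np.float64),
        sth=sth, nth=nth)


@dataclass
class PipelineConfig:
    """End-to-end inference settings (anchors, proposal stage, thresholds).

    Defaults are tuned to the tiny stride-8 preset and the synthetic scene
    statistics (anchor sides 8-20 px); the zf-like preset uses the
    stride-multiplier scales (4, 8, 16).
    """

    scales: tuple = (1.0, 1.5, 2.5)
    ratios: tuple = (0.8, 1.0, 1.5)
    proposal_score_th: float = 0.5
    pre_nms_n: int = 6000
    post_nms_n: int = 200
    # strict proposal NMS: two 10 px boxes offset by 3 px overlap at only
    # ~IoU 0.3, so duplicates around one small target survive any looser
    # setting and surface as double counts
    proposal_nms_th: float = 0.2
    # classification pools a context window this many times the proposal's
    # size: a 6-14 px target spans barely one stride-8 feature cell, so
    # pooling the bare box would leave most position-sensitive bins empty
    roi_context: float = 2.5
    sth: float = DEFAULT_SCORE_THRESHOLD
    nth: float = DEFAULT_NMS_THRESHOLD


def image_to_chw(image: np.ndarray) -> np.ndarray:
    """(H, W, 3) uint8/float image -> (3, H, W) float32 in [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[0] == 3 and arr.shape[2] != 3:
        chw = arr.astype(np.float32)
    elif arr.ndim == 3 and arr.shape[2] == 3:
        chw = arr.transpose(2, 0, 1).astype(np.float32)
    else:
        raise ValueError(f"expected an RGB image, got shape {arr.shape}")
    if chw.max() > 1.5:
        chw = chw / 255.0
    return chw


def score_rois(image, net, pipe: PipelineConfig | None = None):
    """Forward pass + proposal stage + RoI classification for one image.

    Returns ``(scored, counters)`` where ``scored`` is a list of
    ``(box, class_id, prob)`` triples, one per (proposal, foreground
    class); thresholding and final NMS are left to
    :func:`apply_thresholds` so threshold sweeps can reuse one pass.
    """
    pipe = pipe or PipelineConfig()
    chw = image_to_chw(image)
    h, w = chw.shape[1:]
    out = net.forward(chw)
    hf, wf = out.rpn_cls.shape[1:]
    anchors = geometry.generate_anchors(wf, hf, net.stride,
                                        pipe.scales, pipe.ratios)
    props = proposals.select_proposals(
        out, anchors, (w, h), score_th=pipe.proposal_score_th,
        pre_nms_n=pipe.pre_nms_n, post_nms_n=pipe.post_nms_n,
        nms_th=pipe.proposal_nms_th)
    pool_boxes = geometry.inflate_boxes(props.boxes, pipe.roi_context, w, h) \
        if len(props.boxes) else props.boxes
    integral = psroi.integral_maps(out.score_maps)
    scored = []
    for box, pool_box in zip(props.boxes, pool_boxes):
        resp = psroi.psroi_pool(out.score_maps, pool_box, net.k, net.stride,
                                integral=integral)
        score = psroi.classify_roi(resp)
        for cls in range(1, net.num_classes + 1):
            scored.append((box, cls, float(score.probs[cls])))
    return scored, props.counters


def detect_image(image, net, pipe: PipelineConfig | None = None,
                 sth: float | None = None, nth: float | None = None) -> DetectionSet:
    """Run the full detector on one image of any size >= one stride."""
    pipe = pipe or PipelineConfig()
    sth = pipe.sth if sth is None else sth
    nth = pipe.nth if nth is None else nth
    scored, counters = score_rois(image, net, pipe)
    dets = apply_thresholds(scored, sth, nth)
    dets.proposal_counters = counters
    return dets


def count_pests(image, net, sth: float = DEFAULT_SCORE_THRESHOLD,
                nth: float = DEFAULT_NMS_THRESHOLD,
                pipe: PipelineConfig | None = None):
    """Full pipeline on one image (any size): detections plus their count."""
    dets = detect_image(image, net, pipe, sth=sth, nth=nth)
    return dets, dets.count
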