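"""Anchor labeling, the RPN multi-task loss, and proposal selection.

The RPN objective is the standard two-term sum

    L = (1/N_cls) * sum_i L_cls(p_i, p*_i)
        + lambda * (1/N_reg) * sum_i p*_i L_reg(t_i, t*_i)

over a sampled anchor minibatch: a two-class log loss on objectness plus a
smooth-L1 loss on the parameterized box deltas, gated to positive anchors
by the ground-truth indicator p*_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .network import NetOutputs


@dataclass
class LossConfig:
    """Thresholds and normalizers of the RPN objective.

    pos_iou / neg_iou: anchor labeling thresholds (anchors between the two
    are ignored).  lam weights the regression term; n_cls defaults to the
    sampled minibatch size and n_reg to the number of anchor positions.
    """

    pos_iou: float = 0.7
    neg_iou: float = 0.3
    lam: float = 10.0
    batch_size: int = 256
    pos_fraction: float = 0.5
    smooth_l1_sigma: float = 3.0   # quadratic/linear transition at 1/sigma^2
    n_cls: int | None = None
    n_reg: int | None = None

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        for v in (self.n_cls, self.n_reg):
            if v is not None and v <= 0:
                raise ValueError("normalizers must be positive")


@dataclass
class AnchorLabels:
    """Per-anchor training labels: 1 positive, 0 negative, -1 ignore."""

    labels: np.ndarray                    # (N,) int8
    target_deltas: np.ndarray             # (N, 4); valid where label == 1
    matched_gt: np.ndarray                # (N,) gt index or -1

    @property
    def positive_indices(self) -> np.ndarray:
        return np.where(self.labels == 1)[0]

    @property
    def negative_indices(self) -> np.ndarray:
        return np.where(self.labels == 0)[0]


def label_anchors(anchors: geometry.AnchorGrid, gts, cfg: LossConfig,
                  image_size: tuple[int, int] | None = None) -> AnchorLabels:
    """Assign positive/negative/ignore labels to every anchor.

    An anchor is positive when its IoU with some ground-truth box reaches
    ``cfg.pos_iou`` *or* it is the highest-IoU anchor for that box (so every
    ground truth with any overlapping in-image anchor owns at least one
    positive).  Anchors whose best IoU falls below ``cfg.neg_iou`` are
    negative; the rest, and anchors crossing the image boundary, are
    ignored.  ``image_size`` is (width, height); defaults to the nominal
    extent of the anchor grid.
    """
    boxes = anchors.boxes
    n = len(boxes)
    if image_size is None:
        image_size = (anchors.feature_w * anchors.stride,
                      anchors.feature_h * anchors.stride)
    width, height = image_size
    inside = ((boxes[:, 0] >= 0) & (boxes[:, 1] >= 0)
              & (boxes[:, 2] <= width) & (boxes[:, 3] <= height))

    labels = np.full(n, -1, dtype=np.int8)
    matched = np.full(n, -1, dtype=np.int64)
    deltas = np.zeros((n, 4))
    gts = geometry.as_boxes(gts)
    if len(gts) == 0:
        labels[inside] = 0
        return AnchorLabels(labels, deltas, matched)

    ious = geometry.iou_matrix(boxes, gts)
    ious[~inside] = -1.0                      # cross-boundary never labeled
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(n), best_gt]

    labels[inside & (best_iou < cfg.neg_iou)] = 0
    pos = inside & (best_iou >= cfg.pos_iou)
    # argmax rule: every gt claims its best in-image anchor(s); when two
    # gts share a best anchor, each still claims its own runner-up so no
    # overlapped gt is left without a positive
    gt_best = ious.max(axis=0)
    claimed_for = np.full(n, -1, dtype=np.int64)
    for j in np.argsort(-gt_best):               # strongest claims first
        if gt_best[j] <= 0:
            continue
        order = np.argsort(-ious[:, j], kind="stable")
        for a_idx in order:
            if ious[a_idx, j] <= 0:
                break
            if claimed_for[a_idx] == -1:
                claimed_for[a_idx] = j
                pos[a_idx] = True
                best_gt[a_idx] = j
                break
        # claim every co-maximal anchor as well (deterministic ties)
        tie = np.where(ious[:, j] == gt_best[j])[0]
        free = tie[claimed_for[tie] == -1]
        claimed_for[free] = j
        pos[free] = True
        best_gt[free] = j
    labels[pos] = 1
    matched[pos] = best_gt[pos]
    pos_idx = np.where(pos)[0]
    if pos_idx.size:
        deltas[pos_idx] = geometry.encode(boxes[pos_idx], gts[best_gt[pos_idx]])
    return AnchorLabels(labels, deltas, matched)


def sample_minibatch(labels: AnchorLabels, cfg: LossConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample a balanced (up to pos_fraction) anchor minibatch."""
    pos = labels.positive_indices
    neg = labels.negative_indices
    n_pos = min(len(pos), int(cfg.batch_size * cfg.pos_fraction))
    if len(pos) > n_pos:
        pos = rng.choice(pos, size=n_pos, replace=False)
    n_neg = min(len(neg), cfg.batch_size - n_pos)
    if len(neg) > n_neg:
        neg = rng.choice(neg, size=n_neg, replace=False)
    return np.sort(pos), np.sort(neg)


def _softmax2(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _smooth_l1(x: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    s2 = sigma * sigma
    ax = np.abs(x)
    return np.where(ax < 1.0 / s2, 0.5 * s2 * x * x, ax - 0.5 / s2)


def rpn_loss(outputs: NetOutputs, labels: AnchorLabels, cfg: LossConfig,
             sample: tuple[np.ndarray, np.ndarray] | None = None,
             with_grad: bool = False):
    """Evaluate the RPN objective on a sampled anchor minibatch.

    ``sample`` is (positive indices, negative indices); when omitted every
    labeled anchor participates.  Returns ``(total, l_cls, l_reg)``, or with
    ``with_grad`` additionally the gradients with respect to the raw
    ``rpn_cls`` / ``rpn_reg`` head maps.
    """
    cls_flat = outputs.rpn_cls_flat()
    reg_flat = outputs.rpn_reg_flat()
    if sample is None:
        sample = (labels.positive_indices, labels.negative_indices)
    pos_idx, neg_idx = (np.asarray(s, dtype=np.intp) for s in sample)
    batch = np.concatenate([pos_idx, neg_idx])
    if batch.size == 0:
        raise ValueError("degenerate minibatch: no sampled anchors")

    n_cls = cfg.n_cls if cfg.n_cls is not None else batch.size
    n_positions = outputs.rpn_cls.shape[1] * outputs.rpn_cls.shape[2]
    n_reg = cfg.n_reg if cfg.n_reg is not None else n_positions

    probs = _softmax2(cls_flat[batch])
    targets = np.zeros(batch.size, dtype=np.intp)
    targets[:pos_idx.size] = 1
    eps = 1e-12
    l_cls = float(-np.log(probs[np.arange(batch.size), targets] + eps).sum()
                  / n_cls)

    if pos_idx.size:
        diff = reg_flat[pos_idx] - labels.target_deltas[pos_idx]
        l_reg = float(cfg.lam * _smooth_l1(diff, cfg.smooth_l1_sigma).sum()
                      / n_reg)
    else:
        diff = None
        l_reg = 0.0
    total = l_cls + l_reg
    if not with_grad:
        return total, l_cls, l_reg

    a = outputs.rpn_cls.shape[0] // 2
    hf, wf = outputs.rpn_cls.shape[1:]
    d_cls_flat = np.zeros_like(cls_flat, dtype=np.float64)
    g = probs.copy()
    g[np.arange(batch.size), targets] -= 1.0
    d_cls_flat[batch] = g / n_cls
    d_reg_flat = np.zeros_like(reg_flat, dtype=np.float64)
    if pos_idx.size:
        s2 = cfg.smooth_l1_sigma ** 2
        d_reg_flat[pos_idx] = cfg.lam * np.clip(s2 * diff, -1.0, 1.0) / n_reg
    # invert the (row, col, anchor) flattening back to head-map layout
    d_cls = d_cls_flat.reshape(hf, wf, a, 2).transpose(2, 3, 0, 1) \
                      .reshape(2 * a, hf, wf).astype(np.float32)
    d_reg = d_reg_flat.reshape(hf, wf, a, 4).transpose(2, 3, 0, 1) \
                      .reshape(4 * a, hf, wf).astype(np.float32)
    return total, l_cls, l_reg, d_cls, d_reg


@dataclass
class ProposalSet:
    """Scored candidate boxes, best first, with pipeline counters."""

    boxes: np.ndarray                       # (N, 4)
    scores: np.ndarray                      # (N,)
    counters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.boxes)

    def to_csv(self, path) -> None:
        header = "x1,y1,x2,y2,score"
        data = np.column_stack([self.boxes, self.scores]) \
            if len(self) else np.zeros((0, 5))
        np.savetxt(path, data, delimiter=",", header=header, comments="")

    @staticmethod
    def from_csv(path) -> "ProposalSet":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if data.size == 0:
            return ProposalSet(np.zeros((0, 4)), np.zeros(0))
        return ProposalSet(data[:, :4], data[:, 4])


def select_proposals(outputs: NetOutputs, anchors: geometry.AnchorGrid,
                     image_size: tuple[int, int],
                     score_th: float = 0.0, pre_nms_n: int = 6000,
                     post_nms_n: int = 200, nms_th: float = 0.7,
                     min_size: float = 2.0) -> ProposalSet:
    """Decode, filter and rank RPN outputs into the proposal set.

    Pipeline: decode deltas against the anchors -> clip to the image ->
    drop boxes smaller than ``min_size`` on either side -> drop objectness
    below ``score_th`` -> keep the top ``pre_nms_n`` by score -> greedy NMS
    at ``nms_th`` -> keep the top ``post_nms_n``.  Counters record the
    survivor count after every stage.
    """
    width, height = image_size
    scores = _softmax2(outputs.rpn_cls_flat())[:, 1]
    boxes = geometry.decode(anchors.boxes, outputs.rpn_reg_flat())
    counters = {"generated": len(boxes)}

    boxes, valid = geometry.clip_to_image(boxes, width, height)
    big = (boxes[:, 2] - boxes[:, 0] >= min_size) \
        & (boxes[:, 3] - boxes[:, 1] >= min_size)
    keep = valid & big
    boxes, scores = boxes[keep], scores[keep]
    counters["after_clip"] = len(boxes)

    keep = scores > score_th
    boxes, scores = boxes[keep], scores[keep]
    counters["after_score"] = len(boxes)

    order = np.lexsort((boxes[:, 1], boxes[:, 0], -scores))[:pre_nms_n]
    boxes, scores = boxes[order], scores[order]
    counters["after_pre_nms_top"] = len(boxes)

    keep = geometry.nms_indices(boxes, scores, nms_th)
    counters["after_nms"] = len(keep)
    keep = keep[:post_nms_n]
    boxes, scores = boxes[keep], scores[keep]
    counters["kept"] = len(boxes)
    return ProposalSet(boxes, scores, counters)
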