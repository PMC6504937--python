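"""Detection evaluation: precision / recall / miss rate / F1, average
precision, counting error, and the threshold / RoI-size sweep studies.

Box-level matching follows standard VOC practice: detections are taken in
descending score order and a detection is a true positive when its IoU
with a not-yet-matched ground-truth box reaches the match threshold
(default 0.5); every unmatched ground truth is a false negative.  An
image-level verdict ("does the image contain any mites?") is also
computed, since field protocols often score presence per image.

Metric identities:  miss rate = 1 - recall;  F1 = 2PR/(P+R).  Empty
denominators: with zero detections, precision is 1 when there are no
ground truths and 0 otherwise (recall symmetrically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry, postprocess
from .data import AnnotatedImage
from .postprocess import DetectionSet, PipelineConfig


@dataclass
class MatchResult:
    """Per-detection TP/FP assignment against one image's ground truth."""

    tp_flags: np.ndarray      # (N_det,) bool, in descending-score order
    scores: np.ndarray        # (N_det,)
    classes: np.ndarray       # (N_det,)
    n_gt: int
    gt_matched: np.ndarray    # (N_gt,) bool

    @property
    def tp(self) -> int:
        return int(self.tp_flags.sum())

    @property
    def fp(self) -> int:
        return int((~self.tp_flags).sum())

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp

    @property
    def image_verdict(self) -> str:
        """Presence-level verdict: does the image contain any mites?"""
        has_gt, has_det = self.n_gt > 0, len(self.tp_flags) > 0
        if has_det and has_gt:
            return "TP"
        if has_det:
            return "FP"
        if has_gt:
            return "FN"
        return "TN"


def match_detections(dets: DetectionSet, gts, iou_th: float = 0.5,
                     gt_classes=None) -> MatchResult:
    """Greedily match detections to ground truth in descending score order."""
    gts = geometry.as_boxes(gts)
    if gt_classes is None:
        gt_classes = np.ones(len(gts), dtype=np.int64)
    order = np.argsort(-dets.scores, kind="stable")
    tp_flags = np.zeros(len(order), dtype=bool)
    gt_matched = np.zeros(len(gts), dtype=bool)
    ious = geometry.iou_matrix(dets.boxes, gts) if len(gts) else None
    for rank, i in enumerate(order):
        if ious is None:
            continue
        cand = np.where((~gt_matched) & (gt_classes == dets.classes[i])
                        & (ious[i] >= iou_th))[0]
        if cand.size:
            j = cand[np.argmax(ious[i][cand])]
            gt_matched[j] = True
            tp_flags[rank] = True
    return MatchResult(tp_flags=tp_flags, scores=dets.scores[order],
                       classes=dets.classes[order], n_gt=len(gts),
                       gt_matched=gt_matched)


@dataclass
class MetricsReport:
    precision: float
    recall: float
    miss_rate: float
    f1: float
    tp: int
    fp: int
    fn: int
    ap: dict = field(default_factory=dict)        # per foreground class
    map: float = float("nan")
    mean_count_error: float = float("nan")        # mean(predicted - true)
    mean_abs_count_error: float = float("nan")
    image_level: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "miss_rate": self.miss_rate, "f1": self.f1,
                "tp": self.tp, "fp": self.fp, "fn": self.fn,
                "ap": {str(k): v for k, v in self.ap.items()},
                "mAP": self.map,
                "mean_count_error": self.mean_count_error,
                "mean_abs_count_error": self.mean_abs_count_error,
                "image_level": self.image_level}


def compute_metrics(tp: int, fp: int, fn: int) -> MetricsReport:
    """Precision/recall/miss-rate/F1 from aggregate counts."""
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MetricsReport(precision=precision, recall=recall,
                         miss_rate=1.0 - recall, f1=f1, tp=tp, fp=fp, fn=fn)


def average_precision(matches: list[MatchResult], cls: int = 1) -> float:
    """All-point interpolated AP for one foreground class.

    Detections from all images are pooled, ranked by score, and the area
    under the interpolated precision-recall curve is accumulated over
    recall increments.  AP is 0 when there are no ground truths.
    """
    scores, flags = [], []
    n_gt = 0
    for m in matches:
        sel = m.classes == cls
        scores.append(m.scores[sel])
        flags.append(m.tp_flags[sel])
        n_gt += m.n_gt
    if n_gt == 0:
        return 0.0
    scores = np.concatenate(scores) if scores else np.zeros(0)
    flags = np.concatenate(flags) if flags else np.zeros(0, bool)
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp_cum = np.cumsum(flags[order])
    fp_cum = np.cumsum(~flags[order])
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope from the right, then sum over recall steps
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - r_prev) * prec_env))


def mean_average_precision(matches: list[MatchResult],
                           num_classes: int = 1) -> tuple[dict, float]:
    ap = {c: average_precision(matches, c) for c in range(1, num_classes + 1)}
    return ap, float(np.mean(list(ap.values())))


def evaluate_detections(per_image: list[tuple[DetectionSet, AnnotatedImage]],
                        iou_th: float = 0.5,
                        num_classes: int = 1) -> MetricsReport:
    """Aggregate box-level, image-level and counting metrics."""
    matches, count_err = [], []
    verdicts = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for dets, ann in per_image:
        m = match_detections(dets, ann.boxes, iou_th, ann.classes)
        matches.append(m)
        verdicts[m.image_verdict] += 1
        count_err.append(dets.count - ann.num_boxes)
    tp = sum(m.tp for m in matches)
    fp = sum(m.fp for m in matches)
    fn = sum(m.fn for m in matches)
    report = compute_metrics(tp, fp, fn)
    report.ap, report.map = mean_average_precision(matches, num_classes)
    err = np.asarray(count_err, dtype=float)
    report.mean_count_error = float(err.mean()) if err.size else float("nan")
    report.mean_abs_count_error = (float(np.abs(err).mean())
                                   if err.size else float("nan"))
    itp, ifp, ifn = verdicts["TP"], verdicts["FP"], verdicts["FN"]
    img_report = compute_metrics(itp, ifp, ifn)
    report.image_level = {"tp": itp, "fp": ifp, "fn": ifn,
                          "tn": verdicts["TN"],
                          "precision": img_report.precision,
                          "recall": img_report.recall,
                          "miss_rate": img_report.miss_rate,
                          "f1": img_report.f1}
    return report


def evaluate_model(net, scenes: list[AnnotatedImage],
                   pipe: PipelineConfig | None = None,
                   sth: float = postprocess.DEFAULT_SCORE_THRESHOLD,
                   nth: float = postprocess.DEFAULT_NMS_THRESHOLD,
                   iou_th: float = 0.5) -> MetricsReport:
    """Run the detector over a scene list and score it."""
    pipe = pipe or PipelineConfig()
    per_image = [(postprocess.detect_image(s.image, net, pipe, sth, nth), s)
                 for s in scenes]
    return evaluate_detections(per_image, iou_th, net.num_classes)


# ---------------------------------------------------------------------------
# Sweep studies

def sweep_score_threshold(net, scenes, sth_values, nth: float = 0.5,
                          pipe: PipelineConfig | None = None,
                          iou_th: float = 0.5) -> list[dict]:
    """One MetricsReport row per score threshold (single network pass).

    Also records total detection counts versus ground truth, the counting
    comparison behind the threshold studies.
    """
    pipe = pipe or PipelineConfig()
    cached = [(postprocess.score_rois(s.image, net, pipe)[0], s)
              for s in scenes]
    rows = []
    for sth in sth_values:
        per_image = [(postprocess.apply_thresholds(scored, sth, nth), s)
                     for scored, s in cached]
        report = evaluate_detections(per_image, iou_th, net.num_classes)
        rows.append({"sth": float(sth),
                     "total_detections": sum(d.count for d, _ in per_image),
                     "total_gt": sum(s.num_boxes for _, s in per_image),
                     **report.to_dict()})
    return rows


def sweep_nms_threshold(net, scenes, nth_values, sth: float = 0.0,
                        pipe: PipelineConfig | None = None,
                        iou_th: float = 0.5) -> list[dict]:
    """mAP and kept-box count per NMS threshold (single network pass)."""
    pipe = pipe or PipelineConfig()
    cached = [(postprocess.score_rois(s.image, net, pipe)[0], s)
              for s in scenes]
    rows = []
    for nth in nth_values:
        per_image = [(postprocess.apply_thresholds(scored, sth, nth), s)
                     for scored, s in cached]
        report = evaluate_detections(per_image, iou_th, net.num_classes)
        rows.append({"nth": float(nth), "mAP": report.map,
                     "kept_boxes": sum(d.count for d, _ in per_image),
                     **report.to_dict()})
    return rows


def sweep_roi_size(train_scenes, test_scenes, k_values=(1, 3, 5, 7),
                   iterations: int = 300, seed: int = 0,
                   pipe: PipelineConfig | None = None,
                   train_config=None) -> list[dict]:
    """Train one tiny model per RoI grid size k and compare AP@0.5.

    k = 1 collapses position-sensitive pooling to global average pooling
    within each RoI, discarding all spatial evidence.
    """
    from .network import PestNet
    from .train import TrainConfig, replace_config, train as run_training

    rows = []
    for k in k_values:
        cfg = train_config or TrainConfig(roi_batch=64, roi_fg_cap=16)
        cfg = replace_config(cfg, iterations=iterations, seed=seed,
                             step_size=max(1, (3 * iterations) // 4))
        net = PestNet(k=int(k), seed=seed)
        net, _ = run_training(net, train_scenes, cfg)
        report = evaluate_model(net, test_scenes, pipe)
        rows.append({"k": int(k), "mAP": report.map, **report.to_dict()})
    return rows
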