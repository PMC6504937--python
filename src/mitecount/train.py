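"""Training loop: joint RPN + RoI-classification objective, Adam, staged
learning-rate decay.

One image per step.  Each iteration evaluates the RPN multi-task loss on a
sampled anchor minibatch plus a softmax cross-entropy on sampled RoIs
pooled through the position-sensitive score maps, backpropagates the sum,
and takes an Adam step (first-moment decay 0.9, L2 weight decay 0.0005).
The learning rate starts at 0.001 and drops by a factor of 10 every
``step_size`` iterations.  The first backbone stage is frozen by default,
mirroring fine-tuning practice where the earliest features transfer as-is.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry, proposals, psroi
from .data import AnnotatedImage
from .network import PestNet
from .nn import Adam
from .postprocess import PipelineConfig


@dataclass
class TrainConfig:
    """Optimization settings (defaults sized for the tiny CPU preset)."""

    learning_rate: float = 1e-3
    decay_factor: float = 10.0
    step_size: int = 600          # iterations between 10x lr drops
    iterations: int = 800
    weight_decay: float = 5e-4
    beta1: float = 0.9            # Adam first-moment decay
    beta2: float = 0.999
    seed: int = 0
    freeze: tuple = ("conv1",)
    # pos_iou 0.5: a 6-14 px target rarely reaches 0.7 IoU with any lattice
    # anchor, so the full-scale 0.7/0.3 labeling starves the tiny preset of
    # positives (the thresholds are configuration, not contract)
    # n_reg 256 (the minibatch size) rather than the number of anchor
    # positions: counting AP hinges on sub-pixel box regression for these
    # small targets, which needs the stronger per-positive weight
    loss: proposals.LossConfig = field(
        default_factory=lambda: proposals.LossConfig(pos_iou=0.5, n_reg=256))
    pipe: PipelineConfig = field(default_factory=PipelineConfig)
    # RoI-classification sampling
    # background RoIs are drawn from a wide proposal pool (not just the
    # top-scoring few) so far-field background stays represented even once
    # the RPN has concentrated its top proposals around the targets
    roi_batch: int = 96
    roi_fg_cap: int = 24
    roi_fg_iou: float = 0.5
    train_pre_nms_n: int = 1000
    train_post_nms_n: int = 256
    gt_jitter_copies: int = 2     # perturbed gt boxes added as fg RoIs
    gt_jitter: float = 0.15
    # hard negatives: strongly offset gt copies (IoU well under roi_fg_iou)
    # teach the classifier to reject near-miss boxes around each target
    gt_neg_jitter_copies: int = 2
    gt_neg_jitter: float = 0.6
    # optionally train each step on a random window of the scene
    # (multi-scale-crop practice); the network is fully convolutional, so
    # the model applies unchanged to full scenes at inference.  None (the
    # default) trains on whole scenes.
    train_crop: tuple | None = None
    checkpoint_dir: str | None = None
    checkpoint_interval: int = 0  # 0 = only at the end
    val_interval: int = 0

    @staticmethod
    def full_scale_preset() -> "TrainConfig":
        """Full-scale field settings: 5000 iterations, decay step 2500,
        the stride-multiplier anchor scales of the zf-like preset."""
        return TrainConfig(iterations=5000, step_size=2500,
                           pipe=PipelineConfig(scales=(4.0, 8.0, 16.0)))

    def lr_at(self, iteration: int) -> float:
        d = iteration // self.step_size
        return self.learning_rate * self.decay_factor ** (-d)


def replace_config(cfg: TrainConfig, **kw) -> TrainConfig:
    return dataclasses.replace(cfg, **kw)


@dataclass
class TrainLog:
    """Per-iteration losses and learning rates, plus validation points."""

    entries: list = field(default_factory=list)
    validations: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_losses(self) -> np.ndarray:
        return np.asarray([e["total"] for e in self.entries])

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e) + "\n")


def _random_crop(ann: AnnotatedImage, crop: tuple,
                 rng: np.random.Generator) -> AnnotatedImage:
    """Random training window; boxes kept iff >= half their area remains."""
    ch, cw = crop
    if ch >= ann.height and cw >= ann.width:
        return ann
    ch, cw = min(ch, ann.height), min(cw, ann.width)
    y0 = int(rng.integers(0, ann.height - ch + 1))
    x0 = int(rng.integers(0, ann.width - cw + 1))
    boxes = np.zeros((0, 4))
    classes = np.zeros(0, dtype=np.int64)
    if ann.num_boxes:
        clipped = ann.boxes.copy()
        clipped[:, 0::2] = clipped[:, 0::2].clip(x0, x0 + cw)
        clipped[:, 1::2] = clipped[:, 1::2].clip(y0, y0 + ch)
        inside = geometry.box_area(clipped)
        keep = inside >= 0.5 * geometry.box_area(ann.boxes)
        boxes = clipped[keep] - np.array([x0, y0, x0, y0], dtype=float)
        classes = ann.classes[keep]
    return AnnotatedImage(image=ann.image[y0:y0 + ch, x0:x0 + cw],
                          boxes=boxes, classes=classes,
                          image_id=f"{ann.image_id}@{x0},{y0}")


def _sample_rois(out, anchors, ann: AnnotatedImage, cfg: TrainConfig,
                 rng: np.random.Generator):
    """Candidate RoIs for the classification head: RPN proposals plus the
    ground-truth boxes, labeled foreground at IoU >= roi_fg_iou."""
    w, h = ann.width, ann.height
    props = proposals.select_proposals(
        out, anchors, (w, h), score_th=0.0,
        pre_nms_n=cfg.train_pre_nms_n, post_nms_n=cfg.train_post_nms_n,
        nms_th=cfg.pipe.proposal_nms_th)
    rois = props.boxes
    if ann.num_boxes:
        extra = [ann.boxes]
        # jittered gt copies: fg examples that look like real proposals,
        # plus strongly offset copies that land in the background label band
        w_ = ann.boxes[:, 2] - ann.boxes[:, 0]
        h_ = ann.boxes[:, 3] - ann.boxes[:, 1]
        scale = np.stack([w_, h_, w_, h_], axis=1)
        for amp, copies in ((cfg.gt_jitter, cfg.gt_jitter_copies),
                            (cfg.gt_neg_jitter, cfg.gt_neg_jitter_copies)):
            for _ in range(copies):
                jit = ann.boxes + rng.normal(0, amp, ann.boxes.shape) * scale
                jit, ok = geometry.clip_to_image(jit, w, h)
                extra.append(jit[ok])
        rois = np.vstack([rois, *extra]) if len(rois) else np.vstack(extra)
    if len(rois) == 0:
        return np.zeros((0, 4)), np.zeros(0, dtype=np.intp)
    if ann.num_boxes:
        ious = geometry.iou_matrix(rois, ann.boxes)
        best = ious.argmax(axis=1)
        labels = np.where(ious.max(axis=1) >= cfg.roi_fg_iou,
                          ann.classes[best], 0).astype(np.intp)
    else:
        labels = np.zeros(len(rois), dtype=np.intp)
    fg = np.where(labels > 0)[0]
    bg = np.where(labels == 0)[0]
    if len(fg) > cfg.roi_fg_cap:
        fg = rng.choice(fg, cfg.roi_fg_cap, replace=False)
    n_bg = min(len(bg), cfg.roi_batch - len(fg))
    if len(bg) > n_bg:
        bg = rng.choice(bg, n_bg, replace=False)
    sel = np.concatenate([fg, bg])
    return rois[sel], labels[sel]


def train(net: PestNet, scenes: list[AnnotatedImage], cfg: TrainConfig,
          val_scenes: list[AnnotatedImage] | None = None):
    """Optimize ``net`` on annotated scenes; returns ``(net, TrainLog)``.

    Deterministic for a fixed seed (single-threaded, fixed iteration
    order).  Raises RuntimeError naming the iteration if the loss turns
    NaN.  ``cfg.iterations == 0`` leaves the model untouched.
    """
    if not scenes:
        raise ValueError("training requires a non-empty dataset")
    log = TrainLog()
    if cfg.iterations == 0:
        return net, log

    rng = np.random.default_rng(cfg.seed)
    net.freeze(cfg.freeze)
    opt = Adam(net.params(), lr=cfg.learning_rate, beta1=cfg.beta1,
               beta2=cfg.beta2, weight_decay=cfg.weight_decay)
    anchor_cache: dict[tuple, geometry.AnchorGrid] = {}
    label_cache: dict[int, proposals.AnchorLabels] = {}
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    order = rng.permutation(len(scenes))
    cursor = 0
    for it in range(cfg.iterations):
        if cursor >= len(order):
            order = rng.permutation(len(scenes))
            cursor = 0
        ann = scenes[order[cursor]]
        cursor += 1
        t0 = time.perf_counter()
        if cfg.train_crop is not None:
            ann = _random_crop(ann, cfg.train_crop, rng)

        chw = ann.image.transpose(2, 0, 1).astype(np.float32) / 255.0
        out = net.forward(chw)
        hf, wf = out.rpn_cls.shape[1:]
        key = (wf, hf)
        if key not in anchor_cache:
            anchor_cache[key] = geometry.generate_anchors(
                wf, hf, net.stride, cfg.pipe.scales, cfg.pipe.ratios)
        anchors = anchor_cache[key]
        if cfg.train_crop is None:
            ckey = id(ann)
            if ckey not in label_cache:
                label_cache[ckey] = proposals.label_anchors(
                    anchors, ann.boxes, cfg.loss, (ann.width, ann.height))
            labels = label_cache[ckey]
        else:
            labels = proposals.label_anchors(
                anchors, ann.boxes, cfg.loss, (ann.width, ann.height))

        sample = proposals.sample_minibatch(labels, cfg.loss, rng)
        total_rpn, l_cls, l_reg, d_cls, d_reg = proposals.rpn_loss(
            out, labels, cfg.loss, sample, with_grad=True)

        rois, roi_labels = _sample_rois(out, anchors, ann, cfg, rng)
        d_score = np.zeros_like(out.score_maps, dtype=np.float64)
        l_roi = 0.0
        if len(rois):
            n_roi = len(rois)
            pool_rois = geometry.inflate_boxes(rois, cfg.pipe.roi_context,
                                               ann.width, ann.height)
            integral = psroi.integral_maps(out.score_maps)
            for box, target in zip(pool_rois, roi_labels):
                resp = psroi.psroi_pool(out.score_maps, box, net.k,
                                        net.stride, integral=integral)
                sc = psroi.classify_roi(resp)
                l_roi -= np.log(sc.probs[target] + 1e-12) / n_roi
                d_probs = sc.probs.copy()
                d_probs[target] -= 1.0
                psroi.psroi_backward(resp, d_probs / n_roi, d_score)

        total = total_rpn + l_roi
        if not np.isfinite(total):
            raise RuntimeError(f"loss diverged (NaN/inf) at iteration {it}")

        lr = cfg.lr_at(it)
        opt.lr = lr
        opt.zero_grad()
        net.backward(d_cls.astype(np.float32), d_reg.astype(np.float32),
                     d_score.astype(np.float32))
        opt.step()

        log.entries.append({
            "iteration": it, "total": float(total), "rpn_cls": float(l_cls),
            "rpn_reg": float(l_reg), "roi_cls": float(l_roi), "lr": lr,
            "seconds": time.perf_counter() - t0})

        if ckpt_dir and cfg.checkpoint_interval \
                and (it + 1) % cfg.checkpoint_interval == 0:
            net.save(ckpt_dir / f"ckpt_{it + 1:06d}.npz",
                     meta={"iteration": it + 1})
        if cfg.val_interval and val_scenes \
                and (it + 1) % cfg.val_interval == 0:
            from . import evaluate
            report = evaluate.evaluate_model(net, val_scenes, cfg.pipe)
            log.validations.append({"iteration": it + 1, "mAP": report.map})

    if ckpt_dir:
        net.save(ckpt_dir / "ckpt_final.npz",
                 meta={"iteration": cfg.iterations})
    return net, log


def resume(path, scenes, cfg: TrainConfig, remaining: int):
    """Continue training from a checkpoint for ``remaining`` iterations.

    Restores the weights (optimizer moments restart from zero, which is
    documented behaviour of the single-file checkpoint format)."""
    net = PestNet.load(path)
    cfg = replace_config(cfg, iterations=remaining)
    return train(net, scenes, cfg)
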