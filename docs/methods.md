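# Methods

## Pipeline

`mitecount` is a two-stage, fully convolutional detector for very small,
low-contrast targets in cluttered field imagery. A truncated ZF-style
backbone produces shared feature maps; a region proposal network (RPN)
scores and regresses a dense lattice of anchor boxes; proposals are
classified by position-sensitive RoI pooling over a k²(C+1)-channel score
map; thresholding plus greedy per-class NMS yields the detections, and the
detection count is the pest count. Final boxes are the proposals
themselves: localization is routed entirely through the RPN's regression
head, and the RoI stage only classifies (a deliberate simplification —
no second-stage class-agnostic box refinement).

Two backbone presets exist. `zf-like` keeps the first four convolutions of
the Zeiler–Fergus layer plan (7×7/96 s2, 3×3 max-pool s2, 5×5/256 s2,
pool, 3×3/384, 3×3/384; stride 16), then a 3×3 256-d "conv5" and 1×1
1024-d "conv6" neck. `tiny` (the default everywhere in the tests and the
synthetic experiments) is a three-conv stride-8 backbone
(3→16→24→32 channels, all 3×3), neck 48→96, small enough that a full
training run takes minutes on one CPU core. ReLU follows every
convolution; the literature the architecture derives from does not name
activations, so this is a design choice. All layers — convolution via
im2col + GEMM, pooling, backprop, Adam — are implemented directly in
numpy; the package has no deep-learning-framework dependency.

## Anchors and coordinates

Boxes are continuous, 0-based, half-open `[x1,x2)×[y1,y2)`; VOC-XML
readers/writers convert to/from that format's 1-based inclusive integers
(subtract 1 from minima on read, add 1 on write). Anchors sit at feature
cell centres (`(col+0.5)·stride`); scales multiply the stride to give the
base side, and height/width ratios (0.8, 1, 1.5) are applied
area-preservingly (`w = s·stride/√r`, `h = s·stride·√r`). The printed
anchor "areas 4, 8 and 16" of the source architecture are read as stride
multipliers (literal 4-pixel² anchors would be meaningless); at stride 16
that gives sides 64/128/256. The tiny preset instead uses scales
(1.0, 1.5, 2.5) at stride 8 — sides 8/12/20 px — sized to the synthetic
targets (boxes ≈ 6–25 px). Scales are configuration, not contract.

## Training objective

Per image (batch size 1):

* **RPN.** Anchors are labeled positive at IoU ≥ `pos_iou` with any
  ground-truth box *or* by the per-gt argmax rule (with conflict-aware
  claiming, so every overlapped gt owns at least one positive even when
  two gts share a best anchor); negative below `neg_iou`; cross-boundary
  anchors are ignored. The multi-task loss uses a 256-anchor minibatch
  sampled up to 1:1 positive:negative, λ = 10, log loss normalized by the
  minibatch size, smooth-L1 (σ = 3) on the parameterized deltas.
  Full-scale preset: `pos_iou/neg_iou` = 0.7/0.3 and N_reg = number of
  anchor positions (the convention of the two-stage-detector literature).
  Tiny preset: `pos_iou` = 0.5 — a 6–14 px target rarely reaches 0.7 IoU
  with any lattice anchor, and 0.7 starves training of positives — and
  N_reg = 256, because counting accuracy hinges on sub-pixel regression
  of small boxes and the per-position normalization makes that term ~7×
  weaker than standard practice.
* **RoI classification.** Candidate RoIs = RPN proposals (wide pool:
  top 256 after NMS, so far-field background stays represented even once
  the RPN concentrates on the targets) + the gt boxes + two lightly
  jittered gt copies (foreground examples that look like real proposals)
  + two strongly jittered copies (hard negatives: near-miss boxes around
  each target). Label foreground at IoU ≥ 0.5; sample ≤ 16 fg + bg to 64;
  softmax cross-entropy on the pooled per-class scores.

Adam (β₁ = 0.9, β₂ = 0.999) with L2 weight decay 5·10⁻⁴, learning rate
10⁻³ decaying ×10 every `step_size` iterations. A numerical detail that
matters on CPU: Adam's moments for units with vanishing gradients decay
geometrically and cross into float32 subnormal range within ~10³ steps,
after which subnormal arithmetic slows every array operation by orders of
magnitude; the optimizer therefore flushes magnitudes below 10⁻³⁰ in its
state and in the weights to exact zero each step (no measurable effect on
the learned model, large effect on wall-clock). The full-scale preset
freezes the first conv stage (the fine-tuning convention when conv1 is
pre-trained); with random initialization this freeze turned out to also
*stabilize* tiny-preset training, so it is kept there too. Checkpoints are
single-file `.npz` archives (versioned name→array maps); resuming restores
weights, with optimizer moments restarting from zero.

## Position-sensitive pooling of very small RoIs

Bin boundaries are half-up roundings of the fractional edges
`x₀ + i·w/k`; bins emptied by rounding pool to 0, and the per-class score
divides by k² regardless. At stride 8 a 6–14 px target spans barely one
feature cell, which would collapse the k×k grid to one or two non-empty
bins; classification therefore pools a **context window 2.5× the
proposal's size** (clipped to the image). This keeps most bins populated
and restores the point of position sensitivity: an offset proposal places
the target in the wrong bins of its window and scores lower. The window
factor is configuration (`PipelineConfig.roi_context`); 2.5 outperformed
2.0 and 3.0 on held-out synthetic scenes. The reported detection box is
always the un-inflated proposal.

## Inference pipeline and defaults

decode → clip → drop boxes under 2 px → objectness filter
(`proposal_score_th` 0.5) → top 6,000 → greedy NMS → top 200 → classify →
drop background and probability ≤ `sth` → per-class NMS at `nth` → count.
Defaults `sth = 0.5`, `nth = 0.5`, `k = 7`. Proposal-stage NMS uses
threshold 0.2 rather than the customary 0.7: two 10 px boxes offset by
3 px overlap at only ~IoU 0.3, so anything looser leaves duplicate
proposals per target that later surface as double counts. Final NMS
suppresses on strict `IoU > nth`, so `nth = 0` forbids any positive
overlap. Ranking ties break by (score desc, x1 asc, y1 asc) everywhere,
making the pipeline permutation-invariant to input order. Inference is
fully convolutional, so a model trained on small scenes runs directly on
larger images.

## Synthetic scenes

The generator emulates the statistical shape of wheat-field pest
photography: a dry-wheat background built from low-frequency tonal drift
plus vertically elongated streak texture (straw) and fine speckle, with a
Poisson-distributed number (mean 12) of small dark elliptical targets
(minor axis 6–14 px, aspect 1–1.8, random rotation, 0.15–0.35 intensity
contrast, ≥ 14 px centre separation enforced by rejection sampling with a
documented retry limit). Scenes default to 288×480 — the 3:5 aspect ratio
of multi-scale field-image crops. Ground-truth boxes are the extent of
each target's rendered half-coverage mask, so annotations are tight
around what is actually visible. Everything is deterministic per
(spec, seed) and datasets regenerate bit-identically from their manifest.

What the generator does *not* model: perspective and defocus, occlusion
and touching pests, leaf/ear structures that cast pest-like shadows,
illumination colour shifts, and multiple species. Passing the end-to-end
checks therefore demonstrates that the pipeline can learn to localize and
count small low-contrast blobs in clutter — not field-grade robustness.

## Evaluation

Box-level matching is greedy in descending score at IoU ≥ 0.5 (VOC
practice); each gt matches at most one detection, extra detections on a
matched gt count as false positives. Metrics: precision, recall,
miss rate = 1 − recall, F1, all-point-interpolated AP@0.5, mAP over
foreground classes, and per-image counting error (mean and mean
absolute). An image-level presence verdict (does the image contain any
pests?) is also reported, since field protocols often score presence per
image. Empty-denominator conventions: with zero detections, precision is
1 if there are also zero gts, else 0; recall with zero gts is 1.

## Problem sizes

The end-to-end suite trains the tiny preset for 5,000 iterations on
200 scenes (288×480) and evaluates 50 held-out scenes; the RoI-grid-size
study trains one model per k ∈ {1, 3, 5, 7} for 1,800 iterations on 80
reduced scenes (144×240, mean 6 targets) — sizes chosen so the whole
suite runs on a single CPU core in well under half an hour while leaving
the learning signal unambiguous. The `full_scale_preset` training
configuration (5,000 iterations, decay step 2,500, stride-multiplier
anchor scales) reflects the full-scale field recipe.

## Known limitations

* No second-stage box refinement: localization accuracy is bounded by the
  RPN regression head.
* The numpy engine is single-image SGD; there is no batching across
  images and no GPU path.
* k = 7 with stride-8 features on 10 px targets relies on the context
  window; without it position-sensitive pooling degenerates (this is
  visible in the k-study, where k = 1 — global RoI pooling — trails every
  position-sensitive grid).
* Salt-and-pepper augmentation draws exactly ⌊density·N⌋ pixel positions
  without replacement (50/50 black/white); a drawn pixel that is already
  extreme is counted as transformed.
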