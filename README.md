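# mitecount

Localization and counting of small agricultural pests (wheat mites and
similar) in field photographs, built as a CPU-scale two-stage detector:

1. a truncated ZF-style convolutional backbone computes shared feature
   maps;
2. a **region proposal network (RPN)** slides a 3×3 window over the
   features and emits, per anchor box, an objectness score and a box
   offset;
3. a **k²(C+1)-channel position-sensitive score map** head feeds
   position-sensitive RoI pooling, which classifies each proposal with no
   per-RoI fully connected layers;
4. score thresholding (`sth`) and greedy non-maximum suppression (`nth`)
   turn classified proposals into the final detections, whose number *is*
   the pest count.

The package is aimed at agricultural-vision practitioners who need a
trainable, inspectable counting pipeline that runs end-to-end on a single
CPU — including a synthetic field-scene generator with exact ground truth,
so the whole system can be exercised and regression-tested without any
proprietary imagery.

## The model

Anchors: 3 scales × 3 height/width ratios (0.8, 1, 1.5) → 9 anchors per
feature-map position; a W×H map carries W·H·9 anchors. The RPN is trained
with the standard two-term objective

```
L = (1/N_cls) Σᵢ L_cls(pᵢ, pᵢ*) + λ (1/N_reg) Σᵢ pᵢ* L_reg(tᵢ, tᵢ*)
```

(log loss on objectness over a sampled anchor minibatch; smooth-L1 on the
`(dx, dy, dw, dh)` box parameterization, gated to positive anchors).
Position-sensitive pooling follows

```
r_c(i, j) = Σ_{(x,y)∈bin(i,j)} Z_{i,j,c}(x + x₀, y + y₀) / n
```

— bin (i, j) of an RoI's k×k grid averages only its dedicated channel; the
per-class RoI score is the mean of the k² bins, softmaxed over C+1 classes.
Evaluation reports precision, recall, miss rate (= 1 − recall), F1, VOC-style
AP@0.5, and per-image counting error.

Everything — conv layers, backprop, Adam — is implemented in numpy; there
is no GPU or deep-learning-framework dependency.

## Worked example

```bash
# 1. generate a synthetic dataset (100 train / 20 test scenes, 288×480)
mitecount generate --out data --n-train 100 --n-test 20 --seed 7

# 2. train the tiny detector (stride-8 backbone, k = 7)
mitecount train --data data --out model.npz --iterations 5000 --seed 7

# 3. detect and count on the held-out images
mitecount detect --model model.npz --images data/test/images --out dets

# 4. score the model
mitecount evaluate --model model.npz --data data --out report.json
```

A run of steps 1–4 at these settings printed:

```
INFO mitecount: wrote 100 train / 20 test scenes to data
INFO mitecount: final loss 0.5464 after 5000 iterations
INFO mitecount: test_0000.png: 13 pests
INFO mitecount: test_0001.png: 14 pests
...
INFO mitecount: mAP 0.873 precision 0.868 miss-rate 0.103
```

The detector finds nearly all mites (miss rate 0.10) with few spurious
boxes (precision 0.87), so the per-image counts track the true counts
closely — on this run the evaluation report put the mean absolute
counting error at 1.25 mites per scene of ~12.

`detect` writes one overlay image per input (red boxes, blue score tags
and a total-count banner), a `detections.csv`
(`image_id,x1,y1,x2,y2,class,score`) and per-image VOC-style XML.
`evaluate`'s JSON report carries box-level and image-level metrics, AP per
class, and the mean (absolute) counting error. `mitecount sweep` reruns
the score-threshold (0.5–0.9), NMS-threshold (0–0.8) and RoI-grid-size
(k ∈ {1,3,5,7}) studies and plots them.

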