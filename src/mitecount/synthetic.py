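"""Synthetic field-scene generator with exact ground truth.

Emulates the statistical shape of wheat-field pest photographs: many small,
dark, low-contrast elliptical targets ("mites") scattered over a cluttered
straw-textured background.  Scenes default to a 3:5 aspect ratio (288 x 480)
matching multi-scale field-image crops, with a Poisson-distributed target
count (mean 12) and target minor axes of 6-14 px.  Everything is
deterministic per (spec, seed), so datasets regenerate bit-identically from
a manifest of seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import AnnotatedImage

MAX_PLACEMENT_RETRIES = 200


@dataclass
class SceneSpec:
    """Knobs of the scene generator (sizes in pixels, intensities in [0,1]).

    ``mean_count`` parameterizes the Poisson target count; ``minor_axis``
    and ``aspect`` bound the ellipse minor diameter and major/minor ratio;
    ``contrast`` bounds how far below the local background a target's
    intensity sits; ``min_separation`` is the minimum centre-to-centre
    distance enforced by rejection sampling.
    """

    width: int = 480
    height: int = 288
    mean_count: float = 12.0
    minor_axis: tuple = (6.0, 14.0)
    aspect: tuple = (1.0, 1.8)
    contrast: tuple = (0.15, 0.35)
    min_separation: float = 14.0
    num_classes: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "SceneSpec":
        d = dict(d)
        for key in ("minor_axis", "aspect", "contrast"):
            if key in d:
                d[key] = tuple(d[key])
        return SceneSpec(**d)


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Cluttered field background: low-frequency tonal drift plus
    vertically elongated streaks imitating wheat straw."""
    h, w = spec.height, spec.width
    base = np.array([0.62, 0.56, 0.38])          # dry-wheat tone
    coarse = rng.normal(0.0, 1.0, (h // 24 + 2, w // 24 + 2))
    drift = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]),
                         order=1)[:h, :w]
    drift = ndimage.gaussian_filter(drift, 6.0) * 0.35
    streaks = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)),
                                      sigma=(7.0, 1.2)) * 0.9
    speckle = rng.normal(0.0, 0.02, (h, w))
    lum = drift + streaks + speckle
    img = base[None, None, :] * (1.0 + lum[:, :, None])
    # straw is slightly yellower where bright
    img[:, :, 2] -= 0.05 * lum.clip(min=0)
    return img.clip(0.0, 1.0)


def _ellipse_alpha(h, w, cx, cy, a, b, theta, sharpness=2.0) -> np.ndarray:
    """Soft-edged rotated-ellipse coverage mask; alpha = 0.5 exactly on the
    ellipse boundary, so thresholding at 0.5 recovers the analytic extent."""
    y, x = np.mgrid[0:h, 0:w]
    dx, dy = x - cx, y - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    r = np.sqrt(u * u + v * v)
    return np.clip((1.0 - r) * sharpness + 0.5, 0.0, 1.0)


def generate_scene(spec: SceneSpec, seed: int,
                   return_layers: bool = False):
    """Render one annotated scene, deterministically per (spec, seed).

    Targets are placed by rejection sampling honouring
    ``spec.min_separation``; a scene whose targets cannot be placed within
    ``MAX_PLACEMENT_RETRIES`` attempts each raises ValueError (infeasible
    spec).  With ``return_layers`` the noiseless target coverage layer is
    returned as well (used by the box-tightness oracle).
    """
    rng = np.random.default_rng(seed)
    img = _background(spec, rng)
    h, w = spec.height, spec.width
    n_targets = int(rng.poisson(spec.mean_count))

    centers: list[tuple[float, float]] = []
    boxes, classes = [], []
    target_layer = np.zeros((h, w))
    for _ in range(n_targets):
        for attempt in range(MAX_PLACEMENT_RETRIES + 1):
            if attempt == MAX_PLACEMENT_RETRIES:
                raise ValueError(
                    f"could not place {n_targets} targets with separation "
                    f"{spec.min_separation} in {w}x{h} after "
                    f"{MAX_PLACEMENT_RETRIES} retries; spec is infeasible")
            minor = rng.uniform(*spec.minor_axis)
            aspect = rng.uniform(*spec.aspect)
            b = minor / 2.0
            a = b * aspect
            theta = rng.uniform(0.0, np.pi)
            margin = a + 1.0
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            if all((cx - px) ** 2 + (cy - py) ** 2 >= spec.min_separation ** 2
                   for px, py in centers):
                break
        centers.append((cx, cy))
        alpha = _ellipse_alpha(h, w, cx, cy, a, b, theta)
        target_layer = np.maximum(target_layer, alpha)
        contrast = rng.uniform(*spec.contrast)
        tint = np.array([0.30, 0.22, 0.15]) * rng.uniform(0.85, 1.15)
        mite_color = np.minimum(img * (1.0 - contrast * 2.0), tint)
        img = img * (1.0 - alpha[:, :, None]) + mite_color * alpha[:, :, None]
        # ground truth is the rendered half-coverage extent, so annotation
        # boxes are tight around what is actually visible in the pixels
        ys, xs = np.nonzero(alpha >= 0.5)
        boxes.append(np.array([xs.min(), ys.min(),
                               xs.max() + 1, ys.max() + 1], dtype=float))
        classes.append(1 if spec.num_classes == 1
                       else int(rng.integers(1, spec.num_classes + 1)))

    ann = AnnotatedImage(
        image=(img.clip(0, 1) * 255).round().astype(np.uint8),
        boxes=np.asarray(boxes).reshape(-1, 4),
        classes=np.asarray(classes, dtype=np.int64),
        image_id=f"scene_{seed}")
    if return_layers:
        return ann, target_layer
    return ann


def generate_scenes(spec: SceneSpec, n: int, seed: int) -> list[AnnotatedImage]:
    """n scenes with per-scene seeds ``seed + i`` (kept below 2**31)."""
    return [generate_scene(spec, (seed + i) % (2 ** 31)) for i in range(n)]


def generate_dataset(spec: SceneSpec, n_train: int, n_test: int, seed: int,
                     out_dir) -> dict:
    """Write a train/test dataset (PNG + VOC-XML + CSV + JSON manifest).

    Train and test scenes use disjoint seed ranges, so the split is
    disjoint by construction; the manifest records every per-image seed and
    the spec, which makes regeneration bit-identical.
    """
    from . import io as mio

    out = Path(out_dir)
    manifest = {"spec": spec.to_dict(), "seed": seed,
                "splits": {"train": [], "test": []}}
    offsets = {"train": 0, "test": 1_000_000}
    for split, n in (("train", n_train), ("test", n_test)):
        img_dir = out / split / "images"
        ann_dir = out / split / "annotations"
        img_dir.mkdir(parents=True, exist_ok=True)
        ann_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i in range(n):
            s = (seed + offsets[split] + i) % (2 ** 31)
            ann = generate_scene(spec, s)
            ann.image_id = f"{split}_{i:04d}"
            mio.write_image(img_dir / f"{ann.image_id}.png", ann.image)
            mio.write_voc_xml(ann_dir / f"{ann.image_id}.xml", ann)
            rows.append(ann)
            manifest["splits"][split].append(
                {"image_id": ann.image_id, "seed": s,
                 "n_boxes": int(ann.num_boxes)})
        mio.write_annotation_csv(out / split / "annotations.csv", rows)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
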