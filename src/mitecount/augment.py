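"""Dataset expansion: multi-scale cropping at a fixed aspect ratio,
horizontal flipping, and salt-and-pepper noise, with exact bookkeeping.

The canonical recipe crops 3:5 windows at several sizes (150x250, 240x400,
300x500, 600x1000 for 1440x1080 field images), then emits per crop one
horizontally flipped copy and two independently seeded noise copies, so a
set of 850 crops expands to 850 * (1 + 1 + 2) = 3400 training images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .data import AnnotatedImage

DEFAULT_CROP_SIZES = ((150, 250), (240, 400), (300, 500), (600, 1000))
DEFAULT_ASPECT = (3, 5)


@dataclass
class CropPlan:
    """Sliding-window crop layout: (height, width) targets of one aspect
    ratio, stepping by ``(1 - overlap)`` of the window size."""

    crop_sizes: tuple = DEFAULT_CROP_SIZES
    aspect: tuple = DEFAULT_ASPECT
    overlap: float = 0.5
    min_box_inside: float = 0.5    # keep a straddling box iff this area
    min_boxes_per_crop: int = 0    # fraction lies inside the window

    def __post_init__(self):
        ah, aw = self.aspect
        for h, w in self.crop_sizes:
            if h * aw != w * ah:
                raise ValueError(f"crop {h}x{w} violates aspect "
                                 f"{ah}:{aw}")

    def windows(self, src_h: int, src_w: int):
        """All (x1, y1, x2, y2) integer windows over a src_h x src_w image."""
        wins = []
        for ch, cw in self.crop_sizes:
            if ch > src_h or cw > src_w:
                continue
            step_y = max(1, int(round(ch * (1.0 - self.overlap))))
            step_x = max(1, int(round(cw * (1.0 - self.overlap))))
            ys = list(range(0, src_h - ch + 1, step_y))
            xs = list(range(0, src_w - cw + 1, step_x))
            if ys[-1] != src_h - ch:
                ys.append(src_h - ch)
            if xs[-1] != src_w - cw:
                xs.append(src_w - cw)
            wins += [(x, y, x + cw, y + ch) for y in ys for x in xs]
        return wins


@dataclass
class AugmentationLedger:
    """Exact counts of what the augmentation pipeline emitted."""

    originals: int = 0
    flipped: int = 0
    noised: int = 0
    flips_per_image: int = 0
    noise_copies_per_image: int = 0
    densities: tuple = ()
    by_transform: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.originals + self.flipped + self.noised

    def check(self) -> None:
        expect = self.originals * (1 + self.flips_per_image
                                   + self.noise_copies_per_image)
        if self.total != expect:
            raise AssertionError(f"ledger total {self.total} != {expect}")

    def to_dict(self) -> dict:
        return {"originals": self.originals, "flipped": self.flipped,
                "noised": self.noised, "total": self.total,
                "flips_per_image": self.flips_per_image,
                "noise_copies_per_image": self.noise_copies_per_image,
                "densities": list(self.densities),
                "by_transform": self.by_transform}


def crop_multiscale(img: AnnotatedImage, plan: CropPlan) -> list[AnnotatedImage]:
    """Slide the plan's windows over the image and remap ground truth.

    A box straddling a crop edge is kept (and clipped) iff at least
    ``plan.min_box_inside`` of its area lies inside the window; crops with
    fewer than ``plan.min_boxes_per_crop`` surviving boxes are dropped.
    """
    out = []
    areas = geometry.box_area(img.boxes) if img.num_boxes else None
    for n, (x1, y1, x2, y2) in enumerate(plan.windows(img.height, img.width)):
        if img.num_boxes:
            clipped = img.boxes.copy()
            clipped[:, 0::2] = clipped[:, 0::2].clip(x1, x2)
            clipped[:, 1::2] = clipped[:, 1::2].clip(y1, y2)
            inside = geometry.box_area(clipped)
            keep = inside >= plan.min_box_inside * areas
            boxes = clipped[keep] - np.array([x1, y1, x1, y1], dtype=float)
            classes = img.classes[keep]
        else:
            boxes = np.zeros((0, 4))
            classes = np.zeros(0, dtype=np.int64)
        if len(boxes) < plan.min_boxes_per_crop:
            continue
        out.append(AnnotatedImage(
            image=img.image[y1:y2, x1:x2].copy(), boxes=boxes,
            classes=classes,
            image_id=f"{img.image_id}_crop{x2 - x1}x{y2 - y1}_{n:03d}"))
    return out


def flip_horizontal(img: AnnotatedImage) -> AnnotatedImage:
    """Mirror pixels and boxes left-right; applying twice restores input."""
    return AnnotatedImage(
        image=img.image[:, ::-1].copy(),
        boxes=geometry.flip_box_horizontal(img.boxes, img.width),
        classes=img.classes.copy(),
        image_id=f"{img.image_id}_flip")


def salt_pepper(img: AnnotatedImage, density: float, seed: int) -> AnnotatedImage:
    """Set exactly ``floor(density * N)`` pixels to pure black or white.

    Positions are drawn without replacement from the seeded RNG; each
    chosen pixel goes black or white with probability 1/2.  Boxes are
    unchanged.  Same seed, same image: bit-identical output.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = img.image.shape[:2]
    n_noise = int(density * h * w)
    noisy = img.image.copy()
    if n_noise:
        flat = rng.choice(h * w, size=n_noise, replace=False)
        salt = rng.random(n_noise) < 0.5
        ys, xs = np.unravel_index(flat, (h, w))
        noisy[ys[salt], xs[salt]] = 255
        noisy[ys[~salt], xs[~salt]] = 0
    return AnnotatedImage(image=noisy, boxes=img.boxes.copy(),
                          classes=img.classes.copy(),
                          image_id=f"{img.image_id}_sp{seed}")


def build_augmented_set(images: list[AnnotatedImage], flips: int = 1,
                        noise_copies: int = 2,
                        densities: tuple = (0.02, 0.02),
                        seed: int = 0):
    """Originals + flipped copies + seeded noise copies, with a ledger.

    ``densities`` gives the noise density of each copy (length
    ``noise_copies``); distinct per-copy seeds are derived from ``seed``.
    Returns ``(augmented list, AugmentationLedger)``; the ledger satisfies
    total = originals * (1 + flips + noise_copies) exactly.
    """
    if flips not in (0, 1):
        raise ValueError("flips per image must be 0 or 1 (flipping twice "
                         "reproduces the original)")
    if len(densities) != noise_copies:
        raise ValueError("one density per noise copy required")
    out: list[AnnotatedImage] = []
    ledger = AugmentationLedger(flips_per_image=flips,
                                noise_copies_per_image=noise_copies,
                                densities=tuple(densities))
    for idx, img in enumerate(images):
        out.append(img)
        ledger.originals += 1
        if flips:
            out.append(flip_horizontal(img))
            ledger.flipped += 1
        for c in range(noise_copies):
            out.append(salt_pepper(img, densities[c],
                                   seed=(seed + idx * 31 + c) % (2 ** 31)))
            ledger.noised += 1
    ledger.by_transform = {"original": ledger.originals,
                           "flip": ledger.flipped,
                           "salt_pepper": ledger.noised}
    ledger.check()
    return out, ledger
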