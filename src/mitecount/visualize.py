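"""Overlay rendering and sweep plots.

Detection overlays mirror the field-report style: red bounding boxes, a
blue score tag above each box, and a banner with the total count in the
top-left corner.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np               # noqa: E402
from PIL import Image, ImageDraw  # noqa: E402

from .postprocess import DetectionSet  # noqa: E402


def draw_detections(image: np.ndarray, dets: DetectionSet,
                    class_names=None) -> Image.Image:
    """Annotated copy of the image: boxes, per-box scores, count banner."""
    im = Image.fromarray(np.asarray(image, dtype=np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(im)
    for box, score in zip(dets.boxes, dets.scores):
        x1, y1, x2, y2 = (float(v) for v in box)
        draw.rectangle([x1, y1, x2 - 1, y2 - 1], outline=(255, 0, 0), width=1)
        tag = f"{score:.2f}"
        ty = max(y1 - 11, 0)
        draw.rectangle([x1, ty, x1 + 7 * len(tag), ty + 10], fill=(0, 0, 255))
        draw.text((x1 + 1, ty), tag, fill=(255, 255, 255))
    banner = f"count: {dets.count}"
    draw.rectangle([0, 0, 8 * len(banner) + 6, 14], fill=(0, 0, 0))
    draw.text((3, 2), banner, fill=(255, 255, 0))
    return im


def plot_threshold_sweep(rows: list[dict], x_key: str, y_keys, path) -> None:
    """Line plot of sweep metrics (e.g. precision/F1/miss-rate vs sth)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    xs = [r[x_key] for r in rows]
    for key in y_keys:
        ax.plot(xs, [r[key] for r in rows], marker="o", label=key)
    ax.set_xlabel(x_key)
    ax.legend()
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
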