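"""The annotated-image container shared by the data, training and
evaluation modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry


@dataclass
class AnnotatedImage:
    """An RGB image with its ground-truth boxes.

    ``image`` is (H, W, 3) uint8; ``boxes`` is (N, 4) in the 0-based
    half-open pixel convention; ``classes`` holds foreground class ids
    (>= 1), one per box.
    """

    image: np.ndarray
    boxes: np.ndarray
    classes: np.ndarray = field(default=None)
    image_id: str = ""

    def __post_init__(self):
        self.boxes = geometry.as_boxes(self.boxes)
        if self.classes is None:
            self.classes = np.ones(len(self.boxes), dtype=np.int64)
        self.classes = np.asarray(self.classes, dtype=np.int64)
        if len(self.classes) != len(self.boxes):
            raise ValueError("one class per box required")

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def num_boxes(self) -> int:
        return len(self.boxes)
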