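"""Position-sensitive RoI pooling and RoI classification.

Each RoI is divided into a regular k x k grid of bins; bin (i, j) of class
c averages *only* the dedicated score-map channel ``c*k^2 + i*k + j`` over
the bin's feature cells (division by the bin pixel count n).  The per-class
RoI score is the mean of the k^2 bin responses, turned into class
probabilities by a softmax over the C+1 classes (class 0 = background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _bin_edges(lo: float, extent: float, k: int, limit: int) -> list[tuple[int, int]]:
    """Integer [start, stop) spans of the k bins along one axis."""
    spans = []
    for i in range(k):
        a = _round_half_up(lo + i * extent / k)
        b = _round_half_up(lo + (i + 1) * extent / k)
        spans.append((max(a, 0), min(b, limit)))
    return spans


@dataclass
class RoIBinResponse:
    """Pooled bin responses r_c(i, j) for one RoI.

    ``responses`` is (C+1, k, k); ``counts`` holds each bin's pixel count
    (0 for bins that vanish after rounding, whose response is 0).
    """

    responses: np.ndarray
    counts: np.ndarray
    k: int
    x_spans: list
    y_spans: list

    @property
    def num_classes(self) -> int:
        return self.responses.shape[0] - 1


def integral_maps(maps: np.ndarray) -> np.ndarray:
    """Per-channel 2-d summed-area table, zero-padded on top/left.

    Computing this once per image and passing it to :func:`psroi_pool`
    turns each bin sum into four lookups instead of a slice reduction.
    """
    ch, hf, wf = maps.shape
    ii = np.zeros((ch, hf + 1, wf + 1), dtype=np.float64)
    ii[:, 1:, 1:] = maps.astype(np.float64).cumsum(axis=1).cumsum(axis=2)
    return ii


def psroi_pool(maps: np.ndarray, roi, k: int, stride: float,
               integral: np.ndarray | None = None) -> RoIBinResponse:
    """Pool the k^2(C+1)-channel score maps over one RoI.

    ``maps`` is (k^2*(C+1), Hf, Wf) in the class-major layout; ``roi`` is a
    box in image pixels, projected to feature coordinates by dividing by
    ``stride``.  Bin boundaries are half-up roundings of the fractional
    edges ``x0 + i*w/k``; bins left empty by rounding pool to 0.
    ``integral`` may carry :func:`integral_maps` of ``maps`` to amortize
    the sum over many RoIs of one image.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    ch, hf, wf = maps.shape
    if ch % (k * k) != 0:
        raise ValueError(f"{ch} channels do not factor as k^2*(C+1) for k={k}")
    n_classes = ch // (k * k)
    x1, y1, x2, y2 = np.asarray(roi, dtype=np.float64).ravel()[:4]
    x0f, y0f = x1 / stride, y1 / stride
    wfpx, hfpx = (x2 - x1) / stride, (y2 - y1) / stride
    x_spans = _bin_edges(x0f, wfpx, k, wf)
    y_spans = _bin_edges(y0f, hfpx, k, hf)
    if integral is None:
        integral = integral_maps(maps)

    ya = np.asarray([max(s[0], 0) for s in y_spans])
    yb = np.asarray([max(s[1], s[0], 0) for s in y_spans])
    xa = np.asarray([max(s[0], 0) for s in x_spans])
    xb = np.asarray([max(s[1], s[0], 0) for s in x_spans])
    counts = ((yb - ya)[:, None] * (xb - xa)[None, :]).astype(np.int64)

    # channel of bin (i, j) for class c is c*k^2 + i*k + j
    chan = (np.arange(n_classes)[:, None, None] * k * k
            + np.arange(k)[None, :, None] * k
            + np.arange(k)[None, None, :])
    ya2, yb2 = ya[None, :, None], yb[None, :, None]
    xa2, xb2 = xa[None, None, :], xb[None, None, :]
    sums = (integral[chan, yb2, xb2] - integral[chan, ya2, xb2]
            - integral[chan, yb2, xa2] + integral[chan, ya2, xa2])
    responses = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return RoIBinResponse(responses, counts, k, x_spans, y_spans)


@dataclass
class RoIScore:
    """Per-class RoI scores and softmax probabilities (sum to 1)."""

    scores: np.ndarray   # (C+1,)
    probs: np.ndarray    # (C+1,)


def classify_roi(resp: RoIBinResponse) -> RoIScore:
    """Average the k^2 bin responses per class and apply a softmax."""
    scores = resp.responses.mean(axis=(1, 2))
    z = scores - scores.max()
    e = np.exp(z)
    return RoIScore(scores=scores, probs=e / e.sum())


def psroi_backward(resp: RoIBinResponse, d_scores: np.ndarray,
                   d_maps: np.ndarray) -> None:
    """Accumulate into ``d_maps`` the score-map gradient of one RoI's
    per-class scores (the mean-over-bins path through :func:`classify_roi`).
    """
    k = resp.k
    n_classes = resp.responses.shape[0]
    ch, hf, wf = d_maps.shape
    d3 = d_maps.reshape(n_classes, k, k, hf, wf)
    for i, (ya, yb) in enumerate(resp.y_spans):
        for j, (xa, xb) in enumerate(resp.x_spans):
            n = resp.counts[i, j]
            if n:
                g = d_scores / (k * k * n)
                d3[:, i, j, ya:yb, xa:xb] += g[:, None, None]
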