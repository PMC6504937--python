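"""Detection matching, the four counting metrics, and average precision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitecount import evaluate as ev
from mitecount.postprocess import DetectionSet


def det_set(boxes, scores, classes=None):
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    return DetectionSet(
        boxes=boxes,
        classes=(np.asarray(classes, dtype=np.int64) if classes is not None
                 else np.ones(len(boxes), dtype=np.int64)),
        scores=np.asarray(scores, dtype=float))


class TestMatchDetections:
    def test_exact_detections_all_tp(self):
        gts = [[0, 0, 10, 10], [20, 20, 30, 30]]
        m = ev.match_detections(det_set(gts, [0.9, 0.8]), gts)
        assert m.tp == 2 and m.fp == 0 and m.fn == 0
        assert m.image_verdict == "TP"

    def test_no_detections_all_fn(self):
        gts = [[0, 0, 10, 10], [20, 20, 30, 30]]
        m = ev.match_detections(det_set([], []), gts)
        assert m.tp == 0 and m.fn == 2
        assert m.image_verdict == "FN"

    def test_double_detection_counts_one_fp(self):
        gt = [[0.0, 0, 10, 10]]
        dets = det_set([[0, 0, 10, 10], [1, 0, 11, 10]], [0.9, 0.8])
        m = ev.match_detections(dets, gt)
        assert m.tp == 1 and m.fp == 1 and m.fn == 0

    def test_tp_plus_fn_equals_gt_count(self, rng):
        for _ in range(20):
            n_gt = int(rng.integers(0, 6))
            pts = rng.uniform(0, 50, (n_gt, 2))
            gts = np.hstack([pts, pts + rng.uniform(4, 10, (n_gt, 2))])
            n_det = int(rng.integers(0, 6))
            dpts = rng.uniform(0, 50, (n_det, 2))
            dets = det_set(np.hstack([dpts, dpts + 6]), rng.random(n_det))
            m = ev.match_detections(dets, gts)
            assert m.tp + m.fn == n_gt
            assert m.tp + m.fp == n_det

    def test_empty_empty_is_true_negative_image(self):
        m = ev.match_detections(det_set([], []), [])
        assert m.image_verdict == "TN"


class TestComputeMetrics:
    def test_worked_example(self):
        r = ev.compute_metrics(tp=9, fp=1, fn=1)
        assert r.precision == pytest.approx(0.9)
        assert r.recall == pytest.approx(0.9)
        assert r.f1 == pytest.approx(0.9)
        assert r.miss_rate == pytest.approx(0.1)

    def test_balanced_tp_fp_gives_half_precision(self):
        assert ev.compute_metrics(5, 5, 0).precision == pytest.approx(0.5)

    def test_empty_denominator_conventions(self):
        r = ev.compute_metrics(0, 0, 0)
        assert r.precision == 1.0 and r.recall == 1.0
        assert ev.compute_metrics(0, 0, 3).precision == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 10_000), fp=st.integers(0, 10_000),
           fn=st.integers(0, 10_000))
    def test_identities_hold_to_1e12(self, tp, fp, fn):
        r = ev.compute_metrics(tp, fp, fn)
        assert abs(r.miss_rate - (1.0 - r.recall)) < 1e-12
        if r.precision + r.recall > 0:
            harmonic = 2 * r.precision * r.recall / (r.precision + r.recall)
            assert abs(r.f1 - harmonic) < 1e-12
        assert 0.0 <= r.precision <= 1.0 and 0.0 <= r.recall <= 1.0


def match_from_flags(flags, scores, n_gt):
    flags = np.asarray(flags, dtype=bool)
    return ev.MatchResult(tp_flags=flags, scores=np.asarray(scores, float),
                          classes=np.ones(len(flags), dtype=np.int64),
                          n_gt=n_gt, gt_matched=np.zeros(n_gt, dtype=bool))


class TestAveragePrecision:
    def test_perfect_ranking_gives_one(self):
        m = match_from_flags([1, 1, 1], [0.9, 0.8, 0.7], n_gt=3)
        assert ev.average_precision([m]) == pytest.approx(1.0)

    def test_all_false_positives_give_zero(self):
        m = match_from_flags([0, 0], [0.9, 0.8], n_gt=2)
        assert ev.average_precision([m]) == pytest.approx(0.0)

    def test_three_detection_worked_example(self):
        # ranked TP, FP, TP over 2 gts:
        # r=0.5 at p=1; r=1.0 at p=2/3 -> AP = 0.5*1 + 0.5*(2/3) = 5/6
        m = match_from_flags([1, 0, 1], [0.9, 0.8, 0.7], n_gt=2)
        assert ev.average_precision([m]) == pytest.approx(5 / 6)

    def test_brute_force_enumeration_agreement(self, rng):
        """AP equals the trapezoid-free sum over recall increments computed
        by explicit enumeration of every prefix of the ranked list."""
        for _ in range(50):
            n = int(rng.integers(1, 12))
            flags = rng.random(n) < 0.5
            scores = np.sort(rng.random(n))[::-1]
            n_gt = int(flags.sum() + rng.integers(0, 4))
            if n_gt == 0:
                continue
            m = match_from_flags(flags, scores, n_gt)
            got = ev.average_precision([m])
            # oracle: max precision at recall >= r, summed over steps
            tp_cum = np.cumsum(flags)
            fp_cum = np.cumsum(~flags)
            recalls = tp_cum / n_gt
            precs = tp_cum / (tp_cum + fp_cum)
            want = 0.0
            prev_r = 0.0
            for i in range(n):
                if recalls[i] > prev_r:
                    pmax = max(precs[j] for j in range(n)
                               if recalls[j] >= recalls[i])
                    want += (recalls[i] - prev_r) * pmax
                    prev_r = recalls[i]
            assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_under_monotone_score_transform(self, rng):
        n = 20
        flags = rng.random(n) < 0.4
        scores = np.sort(rng.random(n))[::-1]
        m1 = match_from_flags(flags, scores, n_gt=int(flags.sum()) + 2)
        for f in (lambda s: 10 * s + 3, np.exp, lambda s: s ** 3):
            m2 = match_from_flags(flags, f(scores), n_gt=m1.n_gt)
            assert ev.average_precision([m2]) == pytest.approx(
                ev.average_precision([m1]), abs=1e-12)

    def test_zero_ground_truth_is_zero(self):
        assert ev.average_precision(
            [match_from_flags([], [], n_gt=0)]) == 0.0


class TestEvaluateDetections:
    def test_counting_errors_aggregate(self, rng):
        from mitecount.data import AnnotatedImage
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        gts = [[0.0, 0, 8, 8], [8.0, 8, 16, 16]]
        ann = AnnotatedImage(image=img, boxes=gts)
        per_image = [
            (det_set(gts, [0.9, 0.8]), ann),                    # exact
            (det_set([[0.0, 0, 8, 8]], [0.9]), ann),            # one miss
        ]
        r = ev.evaluate_detections(per_image)
        assert r.tp == 3 and r.fn == 1
        assert r.mean_count_error == pytest.approx(-0.5)
        assert r.mean_abs_count_error == pytest.approx(0.5)
        assert r.image_level["tp"] == 2
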