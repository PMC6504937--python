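"""Anchor labeling, the RPN multi-task loss, and proposal selection."""

import numpy as np
import pytest

from mitecount import geometry, proposals
from mitecount.network import NetOutputs


def make_outputs(rng, a=9, hf=6, wf=8, cls=None, reg=None):
    return NetOutputs(
        features=None,
        rpn_cls=(cls if cls is not None
                 else rng.normal(0, 1, (2 * a, hf, wf))).astype(np.float32),
        rpn_reg=(reg if reg is not None
                 else rng.normal(0, 0.2, (4 * a, hf, wf))).astype(np.float32),
        score_maps=None, stride=8)


class TestLabelAnchors:
    def setup_method(self):
        self.anchors = geometry.generate_anchors(8, 6, 8, (1.0, 1.5, 2.5),
                                                 (0.8, 1.0, 1.5))
        self.cfg = proposals.LossConfig(pos_iou=0.7, neg_iou=0.3)

    def test_no_ground_truth_all_inside_negative(self):
        lab = proposals.label_anchors(self.anchors, [], self.cfg, (64, 48))
        assert len(lab.positive_indices) == 0
        inside = lab.labels != -1
        assert np.all(lab.labels[inside] == 0) and inside.sum() > 0

    def test_anchor_equal_to_gt_positive_with_zero_delta(self):
        gt = self.anchors.boxes[100:101]
        lab = proposals.label_anchors(self.anchors, gt, self.cfg, (64, 48))
        assert lab.labels[100] == 1
        assert np.allclose(lab.target_deltas[100], 0.0)

    def test_low_overlap_gt_still_claims_argmax_anchor(self):
        # gt overlapping nothing above the positive threshold: max IoU ~0.4
        gt = np.array([[18.0, 14.0, 27.0, 23.0]])
        lab = proposals.label_anchors(self.anchors, gt, self.cfg, (64, 48))
        ious = geometry.iou_matrix(self.anchors.boxes, gt)[:, 0]
        assert ious.max() < self.cfg.pos_iou
        assert lab.labels[np.argmax(ious)] == 1

    def test_cross_boundary_anchors_ignored(self):
        lab = proposals.label_anchors(self.anchors, [], self.cfg, (64, 48))
        outside = ~((self.anchors.boxes[:, 0] >= 0)
                    & (self.anchors.boxes[:, 1] >= 0)
                    & (self.anchors.boxes[:, 2] <= 64)
                    & (self.anchors.boxes[:, 3] <= 48))
        assert np.all(lab.labels[outside] == -1)

    def test_every_overlapped_gt_gets_a_positive(self, rng):
        for _ in range(20):
            pts = rng.uniform(4, 40, (5, 2))
            gts = np.hstack([pts, pts + rng.uniform(4, 12, (5, 2))])
            lab = proposals.label_anchors(self.anchors, gts, self.cfg,
                                          (64, 48))
            assert len(lab.positive_indices) >= 1
            claimed = set(lab.matched_gt[lab.positive_indices])
            ious = geometry.iou_matrix(self.anchors.boxes, gts)
            ious[lab.labels == -1] = 0  # only in-image anchors count
            for j in range(len(gts)):
                if ious[:, j].max() > 0:
                    assert j in claimed


class TestRpnLoss:
    def test_perfect_predictions_give_zero_loss(self, rng):
        anchors = geometry.generate_anchors(8, 6, 8, (1.0, 1.5, 2.5),
                                            (0.8, 1.0, 1.5))
        cfg = proposals.LossConfig(pos_iou=0.5, neg_iou=0.3)
        gt = anchors.boxes[150:151] + 1.0
        lab = proposals.label_anchors(anchors, gt, cfg, (64, 48))
        big = 50.0
        cls = np.zeros((18, 6, 8))
        reg = np.zeros((36, 6, 8))
        flat_cls = np.zeros((len(anchors), 2))
        flat_cls[:, 0] = big
        flat_cls[lab.positive_indices, 0] = 0.0
        flat_cls[lab.positive_indices, 1] = big
        flat_reg = lab.target_deltas.copy()
        cls = flat_cls.reshape(6, 8, 9, 2).transpose(2, 3, 0, 1).reshape(18, 6, 8)
        reg = flat_reg.reshape(6, 8, 9, 4).transpose(2, 3, 0, 1).reshape(36, 6, 8)
        out = make_outputs(rng, cls=cls, reg=reg)
        total, l_cls, l_reg = proposals.rpn_loss(out, lab, cfg)
        assert l_cls == pytest.approx(0.0, abs=1e-8)
        assert l_reg == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_all_negative_batch_gives_ln2(self, rng):
        anchors = geometry.generate_anchors(8, 8, 8)
        cfg = proposals.LossConfig()
        lab = proposals.label_anchors(anchors, [], cfg, (64, 64))
        out = make_outputs(rng, hf=8, wf=8,
                           cls=np.zeros((18, 8, 8)), reg=np.zeros((36, 8, 8)))
        neg = lab.negative_indices[:256]
        total, l_cls, l_reg = proposals.rpn_loss(
            out, lab, cfg, sample=(np.zeros(0, np.intp), neg))
        assert l_cls == pytest.approx(np.log(2))
        assert l_reg == 0.0
        assert total == pytest.approx(np.log(2))

    def test_no_positives_total_is_cls_only(self, rng):
        anchors = geometry.generate_anchors(6, 6, 8)
        cfg = proposals.LossConfig()
        lab = proposals.label_anchors(anchors, [], cfg, (48, 48))
        out = make_outputs(rng, hf=6, wf=6)
        total, l_cls, l_reg = proposals.rpn_loss(out, lab, cfg)
        assert l_reg == 0.0 and total == pytest.approx(l_cls)
        assert total >= 0.0

    def test_empty_minibatch_rejected(self, rng):
        anchors = geometry.generate_anchors(6, 6, 8)
        cfg = proposals.LossConfig()
        lab = proposals.label_anchors(anchors, [], cfg, (48, 48))
        out = make_outputs(rng, hf=6, wf=6)
        with pytest.raises(ValueError, match="minibatch"):
            proposals.rpn_loss(out, lab, cfg,
                               sample=(np.zeros(0, np.intp),
                                       np.zeros(0, np.intp)))


class TestSelectProposals:
    def run(self, rng, **kw):
        anchors = geometry.generate_anchors(8, 6, 8, (1.0, 1.5, 2.5),
                                            (0.8, 1.0, 1.5))
        out = make_outputs(rng)
        defaults = dict(score_th=0.0, pre_nms_n=500, post_nms_n=200,
                        nms_th=0.7)
        defaults.update(kw)
        return proposals.select_proposals(out, anchors, (64, 48), **defaults)

    def test_counters_monotone_along_pipeline(self, rng):
        ps = self.run(rng)
        c = ps.counters
        assert (c["generated"] >= c["after_clip"] >= c["after_score"]
                >= c["after_pre_nms_top"] >= c["after_nms"] >= c["kept"])

    def test_raising_score_threshold_never_adds_proposals(self, rng):
        counts = [len(self.run(rng, score_th=s))
                  for s in (0.0, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_all_below_threshold_yields_empty_set(self, rng):
        ps = self.run(rng, score_th=1.0)
        assert len(ps) == 0 and ps.counters["after_score"] == 0

    def test_sorted_by_score_descending(self, rng):
        ps = self.run(rng)
        assert np.all(np.diff(ps.scores) <= 0)

    def test_csv_round_trip(self, rng, tmp_path):
        ps = self.run(rng)
        ps.to_csv(tmp_path / "p.csv")
        back = proposals.ProposalSet.from_csv(tmp_path / "p.csv")
        assert np.allclose(back.boxes, ps.boxes, atol=1e-9)
        assert np.allclose(back.scores, ps.scores, atol=1e-9)
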