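"""Multi-scale cropping, flipping, salt-and-pepper noise and ledger
bookkeeping."""

import numpy as np
import pytest

from mitecount import augment
from mitecount.data import AnnotatedImage


def make_image(rng, h=60, w=100, boxes=None):
    return AnnotatedImage(
        image=rng.integers(0, 255, (h, w, 3), dtype=np.uint8).astype(np.uint8),
        boxes=np.asarray(boxes if boxes is not None else []).reshape(-1, 4),
        image_id="img0")


class TestCropPlan:
    def test_aspect_violation_rejected(self):
        with pytest.raises(ValueError, match="aspect"):
            augment.CropPlan(crop_sizes=((30, 40),))

    def test_default_sizes_all_three_to_five(self):
        plan = augment.CropPlan()
        for h, w in plan.crop_sizes:
            assert h * 5 == w * 3

    def test_windows_stay_inside_source(self):
        plan = augment.CropPlan(crop_sizes=((30, 50),), overlap=0.5)
        for x1, y1, x2, y2 in plan.windows(90, 160):
            assert 0 <= x1 < x2 <= 160 and 0 <= y1 < y2 <= 90
            assert (x2 - x1, y2 - y1) == (50, 30)


class TestCropMultiscale:
    def test_whole_image_crop_preserves_boxes(self, rng):
        img = make_image(rng, 30, 50, [[5, 5, 15, 20], [30, 2, 45, 12]])
        plan = augment.CropPlan(crop_sizes=((30, 50),))
        crops = augment.crop_multiscale(img, plan)
        assert len(crops) == 1
        assert np.allclose(crops[0].boxes, img.boxes)
        assert np.array_equal(crops[0].image, img.image)

    def test_box_fully_outside_crop_absent(self, rng):
        img = make_image(rng, 60, 100, [[80, 40, 95, 55]])
        plan = augment.CropPlan(crop_sizes=((30, 50),), overlap=0.0)
        first = augment.crop_multiscale(img, plan)[0]   # window at (0,0)
        assert first.num_boxes == 0

    def test_majority_inside_box_kept_and_clipped(self, rng):
        # box 10 wide; 6 columns inside the 50-px window -> 60% >= 50%
        img = make_image(rng, 30, 100, [[44, 10, 54, 20]])
        plan = augment.CropPlan(crop_sizes=((30, 50),), overlap=0.0)
        first = augment.crop_multiscale(img, plan)[0]
        assert first.num_boxes == 1
        assert np.allclose(first.boxes[0], [44, 10, 50, 20])

    def test_minority_inside_box_dropped(self, rng):
        # only 4 of 10 columns inside -> 40% < 50%
        img = make_image(rng, 30, 100, [[46, 10, 56, 20]])
        plan = augment.CropPlan(crop_sizes=((30, 50),), overlap=0.0)
        first = augment.crop_multiscale(img, plan)[0]
        assert first.num_boxes == 0

    def test_emitted_boxes_satisfy_invariants(self, rng):
        boxes = np.hstack([rng.uniform(0, 80, (10, 2)),
                           np.zeros((10, 2))])
        boxes[:, 2:] = boxes[:, :2] + rng.uniform(2, 15, (10, 2))
        img = make_image(rng, 60, 100, boxes)
        plan = augment.CropPlan(crop_sizes=((30, 50),), overlap=0.5)
        for crop in augment.crop_multiscale(img, plan):
            if crop.num_boxes:
                assert np.all(crop.boxes[:, 2] > crop.boxes[:, 0])
                assert np.all(crop.boxes[:, 3] > crop.boxes[:, 1])
                assert np.all(crop.boxes[:, 0] >= 0)
                assert np.all(crop.boxes[:, 2] <= crop.width)


class TestFlip:
    def test_involution(self, rng):
        img = make_image(rng, 20, 30, [[2, 3, 10, 12]])
        back = augment.flip_horizontal(augment.flip_horizontal(img))
        assert np.array_equal(back.image, img.image)
        assert np.allclose(back.boxes, img.boxes)

    def test_pixels_and_boxes_mirror_together(self, rng):
        img = make_image(rng, 20, 30, [[0, 0, 5, 5]])
        flipped = augment.flip_horizontal(img)
        assert np.allclose(flipped.boxes[0], [25, 0, 30, 5])
        assert np.array_equal(flipped.image[:, -1], img.image[:, 0])


class TestSaltPepper:
    def test_zero_density_identical(self, rng):
        img = make_image(rng)
        out = augment.salt_pepper(img, 0.0, seed=1)
        assert np.array_equal(out.image, img.image)

    def test_full_density_pure_black_or_white(self, rng):
        img = make_image(rng)
        out = augment.salt_pepper(img, 1.0, seed=1)
        assert np.all((out.image == 0) | (out.image == 255))

    def test_exact_pixel_count(self, rng):
        img = make_image(rng, 100, 100)
        out = augment.salt_pepper(img, 0.02, seed=3)
        changed = np.any(out.image != img.image, axis=2)
        extreme = np.all(out.image == 0, axis=2) | np.all(out.image == 255,
                                                          axis=2)
        assert extreme.sum() >= changed.sum()
        assert changed.sum() <= 200         # exactly 200 positions drawn
        assert changed.sum() >= 190         # a few may already be extreme

    def test_same_seed_bit_identical(self, rng):
        img = make_image(rng)
        a = augment.salt_pepper(img, 0.05, seed=9)
        b = augment.salt_pepper(img, 0.05, seed=9)
        assert np.array_equal(a.image, b.image)

    def test_boxes_unchanged(self, rng):
        img = make_image(rng, 30, 50, [[1, 2, 9, 8]])
        out = augment.salt_pepper(img, 0.1, seed=2)
        assert np.allclose(out.boxes, img.boxes)


class TestLedger:
    def test_canonical_bookkeeping_850_to_3400(self, rng):
        images = [make_image(rng, 15, 25) for _ in range(850)]
        out, ledger = augment.build_augmented_set(images, flips=1,
                                                  noise_copies=2)
        assert ledger.total == 3400
        assert len(out) == 3400
        assert ledger.originals == 850
        assert ledger.flipped == 850
        assert ledger.noised == 1700
        ledger.check()

    def test_no_transforms_total_equals_input(self, rng):
        images = [make_image(rng, 10, 10) for _ in range(7)]
        out, ledger = augment.build_augmented_set(images, flips=0,
                                                  noise_copies=0,
                                                  densities=())
        assert ledger.total == len(out) == 7

    def test_small_example_10_to_40(self, rng):
        images = [make_image(rng, 10, 10) for _ in range(10)]
        out, ledger = augment.build_augmented_set(images, flips=1,
                                                  noise_copies=2)
        assert ledger.total == len(out) == 40

    def test_multiplicative_invariant_random_cases(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 12))
            flips = int(rng.integers(0, 2))
            copies = int(rng.integers(0, 4))
            images = [make_image(rng, 10, 10) for _ in range(n)]
            _, ledger = augment.build_augmented_set(
                images, flips=flips, noise_copies=copies,
                densities=(0.01,) * copies)
            assert ledger.total == n * (1 + flips + copies)

    def test_density_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="density"):
            augment.build_augmented_set([make_image(rng, 10, 10)],
                                        noise_copies=2, densities=(0.1,))
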