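"""Augmentation planning arithmetic, box-aware transforms, and Mosaic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import transform as sktransform

from vegdet.augment import (
    apply_geometric,
    apply_photometric,
    apply_random_transform,
    equalize_by_deletion,
    mosaic,
    plan_offline_augmentation,
)
from vegdet.voc import BoundingBox, LabeledImage


def make_sample(boxes, size=(100, 100), rng=None):
    img = (
        (rng.integers(0, 255, (*size, 3), dtype=np.uint8))
        if rng is not None
        else np.zeros((*size, 3), dtype=np.uint8)
    )
    return LabeledImage(image=img, boxes=boxes)


class TestPlanning:
    def test_already_balanced_plan_is_identity(self):
        plan = plan_offline_augmentation({"A": 100, "B": 100}, 100)
        assert plan.copies_per_image == {"A": 0, "B": 0}
        assert plan.delete_after == {"A": 0, "B": 0}

    def test_published_extreme_counts(self):
        # the dataset's most and least frequent training classes
        plan = plan_offline_augmentation({"minority": 424, "majority": 1344}, 1344)
        assert plan.copies_per_image == {"minority": 3, "majority": 0}
        assert plan.delete_after == {"minority": 424 * 4 - 1344, "majority": 0}
        assert plan.delete_after["minority"] == 352

    def test_exact_multiple_needs_no_deletion(self):
        plan = plan_offline_augmentation({"A": 50}, 200)
        assert plan.copies_per_image["A"] == 3
        assert plan.delete_after["A"] == 0

    def test_target_below_max_class_rejected(self):
        with pytest.raises(ValueError):
            plan_offline_augmentation({"A": 10, "B": 100}, 50)

    @given(
        counts=st.dictionaries(
            st.sampled_from(list("ABCDEF")), st.integers(1, 500), min_size=1
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_plan_invariant_holds_for_any_distribution(self, counts):
        plan = plan_offline_augmentation(counts, "max-class")
        for label, n in counts.items():
            total = n * (1 + plan.copies_per_image[label]) - plan.delete_after[label]
            assert total == plan.target_count


class TestGeometric:
    def test_hflip_maps_box_coordinates(self):
        sample = make_sample([BoundingBox("x", 10, 10, 20, 20)])
        out = apply_geometric(sample, "hflip")
        b = out.boxes[0]
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (80, 10, 90, 20)

    def test_hflip_is_an_involution(self, rng):
        sample = make_sample([BoundingBox("x", 12, 30, 44, 70)], rng=rng)
        back = apply_geometric(apply_geometric(sample, "hflip"), "hflip")
        np.testing.assert_array_equal(back.image, sample.image)
        assert back.boxes == sample.boxes

    def test_rotate_zero_is_identity(self, rng):
        sample = make_sample([BoundingBox("x", 10, 20, 40, 50)], rng=rng)
        out = apply_geometric(sample, "rotate", angle=0.0)
        np.testing.assert_array_equal(out.image, sample.image)
        b = out.boxes[0]
        np.testing.assert_allclose(b.as_xyxy(), sample.boxes[0].as_xyxy(), atol=1e-6)

    @pytest.mark.parametrize("angle", [17.0, -33.0, 90.0])
    def test_rotated_box_matches_mask_extent(self, angle):
        # render the box as a mask, rotate it with the image path, and compare
        # its pixel extent against the analytic corner-mapped box
        h = w = 120
        box = BoundingBox("x", 30, 40, 70, 80)
        mask = np.zeros((h, w))
        mask[int(box.ymin) : int(box.ymax), int(box.xmin) : int(box.xmax)] = 1.0
        rot = sktransform.rotate(mask, angle, order=0)
        ys, xs = np.nonzero(rot > 0.5)
        sample = LabeledImage(image=np.zeros((h, w, 3), np.uint8), boxes=[box])
        out = apply_geometric(sample, "rotate", angle=angle)
        b = out.boxes[0]
        assert abs(b.xmin - xs.min()) <= 1.5
        assert abs(b.xmax - (xs.max() + 1)) <= 1.5
        assert abs(b.ymin - ys.min()) <= 1.5
        assert abs(b.ymax - (ys.max() + 1)) <= 1.5

    def test_border_expand_shifts_boxes(self, rng):
        sample = make_sample([BoundingBox("x", 10, 10, 20, 20)], rng=rng)
        out = apply_geometric(sample, "border_expand", pad=7)
        assert out.image.shape[:2] == (114, 114)
        b = out.boxes[0]
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (17, 17, 27, 27)

    def test_fragment_below_visibility_threshold_dropped(self):
        # rotating a corner box by 45 deg pushes most of it off-canvas
        sample = make_sample([BoundingBox("x", -40, -40, 5, 5)], size=(100, 100))
        out = apply_geometric(sample, "hflip")
        # visible sliver is 5x5=25 of 45x45=2025 -> ~1.2% < 15%
        assert out.boxes == []


class TestPhotometric:
    @pytest.mark.parametrize("op", ["gamma", "contrast_stretch", "brightness", "gaussian_blur"])
    def test_boxes_never_move(self, op, rng):
        boxes = [BoundingBox("x", 5, 6, 50, 60)]
        sample = make_sample(boxes, rng=rng)
        out = apply_photometric(sample, op, seed=1)
        assert out.boxes == boxes
        assert out.image.dtype == np.uint8

    def test_gamma_one_is_identity(self, rng):
        sample = make_sample([], rng=rng)
        out = apply_photometric(sample, "gamma", gamma=1.0)
        np.testing.assert_array_equal(out.image, sample.image)

    def test_blur_sigma_zero_is_identity(self, rng):
        sample = make_sample([], rng=rng)
        out = apply_photometric(sample, "gaussian_blur", sigma=1e-6)
        np.testing.assert_array_equal(out.image, sample.image)

    def test_random_transform_is_seed_deterministic(self, rng):
        sample = make_sample([BoundingBox("x", 10, 10, 40, 40)], rng=rng)
        a = apply_random_transform(sample, seed=3)
        b = apply_random_transform(sample, seed=3)
        np.testing.assert_array_equal(a.image, b.image)
        assert a.boxes == b.boxes


class TestMosaic:
    @staticmethod
    def sources(rng, with_boxes=True):
        out = []
        for _ in range(4):
            boxes = [BoundingBox("x", 30, 30, 70, 70)] if with_boxes else []
            out.append(
                LabeledImage(
                    image=rng.integers(0, 255, (100, 100, 3), dtype=np.uint8),
                    boxes=boxes,
                )
            )
        return out

    def test_output_size_and_interior_boxes_survive(self, rng):
        out = mosaic(self.sources(rng), out_size=160, center_jitter=(0.5, 0.5), seed=0)
        assert out.image.shape == (160, 160, 3)
        # centered boxes of each source may clip at quadrant borders but the
        # bulk survives; all four must be represented
        assert len(out.boxes) == 4

    def test_empty_sources_give_empty_boxes(self, rng):
        out = mosaic(self.sources(rng, with_boxes=False), out_size=128, seed=1)
        assert out.boxes == []

    def test_wrong_arity_rejected(self, rng):
        with pytest.raises(ValueError):
            mosaic(self.sources(rng)[:3], out_size=128)

    def test_quadrant_pixels_match_recorded_affine(self, rng):
        sources = self.sources(rng)
        out = mosaic(sources, out_size=160, seed=5)
        for src, tf in zip(sources, out.meta["mosaic_transforms"]):
            qx0, qy0, qx1, qy1 = tf["quad"]
            ox, oy, ox1, oy1 = tf["crop"]
            qw, qh = qx1 - qx0, qy1 - qy0
            cw, ch = ox1 - ox, oy1 - oy
            for u, v in [(qx0, qy0), (qx1 - 1, qy1 - 1)]:  # outer + inner corners
                sx_idx = min(int((u - qx0) * cw / qw) + ox, ox1 - 1)
                sy_idx = min(int((v - qy0) * ch / qh) + oy, oy1 - 1)
                np.testing.assert_array_equal(
                    out.image[v, u], src.image[sy_idx, sx_idx]
                )

    def test_total_box_area_bounded_by_scaled_sources(self, rng):
        sources = self.sources(rng)
        out = mosaic(sources, out_size=160, seed=2)
        scaled = 0.0
        for src, tf in zip(sources, out.meta["mosaic_transforms"]):
            sx, _, sy, _ = tf["affine"]
            scaled += sum(b.area * sx * sy for b in src.boxes)
        assert sum(b.area for b in out.boxes) <= scaled + 1e-6


class TestEqualizeByDeletion:
    @staticmethod
    def manifest(label, n_orig, n_aug):
        recs = [{"class": label, "path": f"{label}{i}", "augmented": False} for i in range(n_orig)]
        recs += [{"class": label, "path": f"{label}a{i}", "augmented": True} for i in range(n_aug)]
        return recs

    def test_published_worked_example_balances_exactly(self):
        plan = plan_offline_augmentation({"A": 424, "B": 1344}, 1344)
        recs = self.manifest("A", 424, 424 * 3) + self.manifest("B", 1344, 0)
        out = equalize_by_deletion(recs, plan, seed=0)
        counts = {}
        for r in out:
            counts[r["class"]] = counts.get(r["class"], 0) + 1
        assert counts == {"A": 1344, "B": 1344}
        assert all(not r["augmented"] for r in out if r["class"] == "B")
        # originals are never deleted
        assert sum(not r["augmented"] for r in out if r["class"] == "A") == 424

    def test_zero_deletion_plan_is_identity(self):
        plan = plan_offline_augmentation({"A": 50}, 200)
        recs = self.manifest("A", 50, 150)
        assert equalize_by_deletion(recs, plan, seed=1) == recs

    def test_deletion_is_seed_deterministic(self):
        plan = plan_offline_augmentation({"A": 30}, 40)
        recs = self.manifest("A", 30, 30)
        a = equalize_by_deletion(recs, plan, seed=9)
        b = equalize_by_deletion(recs, plan, seed=9)
        assert a == b

    def test_inconsistent_manifest_rejected(self):
        plan = plan_offline_augmentation({"A": 30}, 40)
        with pytest.raises(ValueError):
            equalize_by_deletion(self.manifest("A", 30, 5), plan, seed=0)
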