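"""Model assembly, target assignment, composite loss, decoding and accounting."""

import numpy as np
import pytest

from vegdet import nn
from vegdet.csaam import CSAAM
from vegdet.detector import (
    Assignment,
    PRIOR_SCALE,
    STRIDES,
    assign_targets,
    build_model,
    compute_loss,
    count_flops,
    count_parameters,
    decode_and_nms,
    decode_boxes,
    encode_boxes,
    level_grid_centers,
    nms_greedy,
    _iou_matrix,
)


@pytest.fixture(scope="module")
def tiny():
    return build_model(num_classes=4, width_multiple=0.25, seed=0)


class TestAssembly:
    def test_three_prediction_maps_at_expected_strides(self, tiny, rng):
        x = rng.random((1, 3, 128, 128), dtype=np.float32)
        preds = tiny(x)
        assert [(p.shape[2], p.shape[3]) for p in preds] == [(16, 16), (8, 8), (4, 4)]
        assert all(p.shape[1] == 4 + 1 + 4 for p in preds)

    def test_csaam_flag_controls_module_presence(self):
        with_att = build_model(4, 0.25, use_csaam=True)
        without = build_model(4, 0.25, use_csaam=False)
        assert any(isinstance(m, CSAAM) for m in with_att.modules())
        assert not any(isinstance(m, CSAAM) for m in without.modules())

    def test_csaam_toggle_changes_params_by_closed_form(self):
        with_att = build_model(4, 0.25, use_csaam=True)
        without = build_model(4, 0.25, use_csaam=False)

        def csaam_params(c):
            h = max(c // 16, 4)
            channel = (c * h + h) + (h * c + c)
            sh = 4
            spatial = (2 * sh * 9 + sh) + (sh * sh * 9 + sh) + (sh * 1 * 9 + 1)
            return channel + spatial

        expected = sum(csaam_params(m.channels) for m in with_att.modules() if isinstance(m, CSAAM))
        assert count_parameters(with_att) - count_parameters(without) == expected

    def test_ablation_monotonicity_of_size(self):
        full = count_parameters(build_model(4, 0.25, use_dat=True, use_csaam=True))
        no_att = count_parameters(build_model(4, 0.25, use_dat=True, use_csaam=False))
        neither = count_parameters(build_model(4, 0.25, use_dat=False, use_csaam=False))
        assert full > no_att > neither

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            build_model(0)
        with pytest.raises(ValueError):
            build_model(4, width_multiple=-1.0)

    def test_every_parameter_receives_gradient(self, rng):
        model = build_model(num_classes=3, width_multiple=0.25, seed=1)
        # 128 px keeps the stride-32 sampling grid non-degenerate (>1 point)
        x = rng.random((1, 3, 128, 128), dtype=np.float32)
        preds = model(x)
        shapes = [(p.shape[2], p.shape[3]) for p in preds]
        boxes = [np.array([[8.0, 8.0, 80.0, 80.0]])]
        labels = [np.array([0])]
        assignments = [assign_targets(shapes, b) for b in boxes]
        loss = compute_loss(preds, assignments, boxes, labels, num_classes=3)
        loss.total_tensor.backward()
        dead = [
            name
            for name, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad)
        ]
        assert dead == []


class TestAccounting:
    def test_linear_and_conv_closed_forms(self):
        nn.set_init_seed(0)
        lin = nn.Linear(7, 3)
        assert count_parameters(lin) == 7 * 3 + 3
        conv = nn.Conv2d(5, 9, 3, bias=True)
        assert count_parameters(conv) == 9 * 5 * 9 + 9
        with nn.count_macs() as c:
            conv(nn.Tensor(np.zeros((1, 5, 8, 8), np.float32)))
        assert c[0] == 9 * 5 * 9 * 6 * 6  # k^2 Cin Cout Hout Wout

    def test_default_model_within_lightweight_budget(self):
        model = build_model(num_classes=30)
        assert count_parameters(model) <= 2_830_000

    def test_flops_positive_and_scale_with_input(self, tiny):
        small = count_flops(tiny, 64)
        large = count_flops(tiny, 128)
        assert 0 < small < large


class TestAssignment:
    shapes = [(8, 8), (4, 4), (2, 2)]

    def test_no_ground_truth_means_no_positives(self):
        asg = assign_targets(self.shapes, np.zeros((0, 4)))
        assert asg.num_positives == 0

    def test_coincident_prior_is_positive(self):
        # ground truth exactly equal to the stride-8 prior at cell (1, 1)
        s = STRIDES[0]
        half = PRIOR_SCALE * s / 2
        cx, cy = (1 + 0.5) * s, (1 + 0.5) * s
        gt = np.array([[cx - half, cy - half, cx + half, cy + half]])
        asg = assign_targets(self.shapes, gt)
        assert asg.match[0][1 * 8 + 1] == 0

    def test_every_gt_gets_at_least_one_positive(self, rng):
        for _ in range(10):
            gt = np.sort(rng.uniform(0, 64, (3, 4)), axis=-1)
            gt = gt[(gt[:, 2] - gt[:, 0] > 2) & (gt[:, 3] - gt[:, 1] > 2)]
            asg = assign_targets(self.shapes, gt)
            matched = np.concatenate(asg.match)
            for k in range(len(gt)):
                assert (matched == k).any()

    def test_matches_brute_force_iou_oracle(self, rng):
        gt = np.array(
            [[4.0, 4.0, 30.0, 28.0], [30.0, 34.0, 62.0, 60.0], [10.0, 40.0, 22.0, 56.0]]
        )
        asg = assign_targets(self.shapes, gt, iou_threshold=0.2)
        # oracle: enumerate every cell of every level independently
        got = {}
        for li, (h, w) in enumerate(self.shapes):
            for idx in range(h * w):
                if asg.match[li][idx] >= 0:
                    got[(li, idx)] = int(asg.match[li][idx])
        expected = {}
        for li, ((h, w), s) in enumerate(zip(self.shapes, STRIDES)):
            centers = level_grid_centers(h, w, s)
            half = PRIOR_SCALE * s / 2
            for idx, (cx, cy) in enumerate(centers):
                prior = np.array([[cx - half, cy - half, cx + half, cy + half]])
                ious = _iou_matrix(prior, gt).ravel()
                if ious.max() >= 0.2:
                    expected[(li, idx)] = int(ious.argmax())
        # forced best-matches may add cells beyond the threshold set
        for key, val in expected.items():
            assert got[key] == val
        extra = set(got) - set(expected)
        assert len(extra) <= len(gt)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            assign_targets(self.shapes, np.zeros((0, 4)), iou_threshold=0.0)


class TestLoss:
    def make_preds(self, rng, n=1, num_classes=3):
        shapes = [(8, 8), (4, 4), (2, 2)]
        return [
            nn.Tensor(rng.standard_normal((n, 5 + num_classes, h, w)).astype(np.float32))
            for h, w in shapes
        ], shapes

    def test_no_positives_zeroes_box_and_cls_terms(self, rng):
        preds, shapes = self.make_preds(rng)
        asg = [assign_targets(shapes, np.zeros((0, 4)))]
        loss = compute_loss(preds, asg, [np.zeros((0, 4))], [np.zeros(0, int)], 3)
        assert loss.box_loss == 0.0
        assert loss.cls_loss == 0.0
        assert loss.obj_loss > 0.0

    def test_perfect_box_prediction_has_zero_box_term(self, rng):
        preds, shapes = self.make_preds(rng)
        gt = np.array([[8.0, 8.0, 40.0, 48.0]])
        asg = assign_targets(shapes, gt)
        # keep only positives whose centers fall inside the box (the encoding
        # is exact there) and write the exact codes into those cells
        for li, (h, w) in enumerate(shapes):
            pos = np.nonzero(asg.match[li] >= 0)[0]
            centers = level_grid_centers(h, w, STRIDES[li])
            for idx in pos:
                cx, cy = centers[idx]
                if not (gt[0, 0] < cx < gt[0, 2] and gt[0, 1] < cy < gt[0, 3]):
                    asg.match[li][idx] = -1
                    continue
                codes = encode_boxes(gt, centers[idx : idx + 1], STRIDES[li])[0]
                preds[li].data[0, :4, idx // w, idx % w] = codes
        assert asg.num_positives > 0
        loss = compute_loss(preds, [asg], [gt], [np.array([1])], 3)
        assert loss.box_loss == pytest.approx(0.0, abs=1e-5)

    def test_total_is_weighted_sum_of_terms(self, rng):
        preds, shapes = self.make_preds(rng)
        gt = np.array([[8.0, 8.0, 40.0, 48.0]])
        asg = [assign_targets(shapes, gt)]
        loss = compute_loss(preds, asg, [gt], [np.array([0])], 3)
        assert loss.total == pytest.approx(
            0.05 * loss.box_loss + 0.5 * loss.cls_loss + 1.0 * loss.obj_loss, rel=1e-6
        )
        assert float(loss.total_tensor.data) == pytest.approx(loss.total, rel=1e-6)


class TestDecode:
    def test_encode_decode_round_trip(self):
        centers = level_grid_centers(4, 4, 16)
        boxes = np.array([[10.0, 12.0, 50.0, 40.0]] * len(centers))
        codes = encode_boxes(boxes, centers, 16)
        inside = (
            (centers[:, 0] > boxes[:, 0])
            & (centers[:, 0] < boxes[:, 2])
            & (centers[:, 1] > boxes[:, 1])
            & (centers[:, 1] < boxes[:, 3])
        )
        decoded = decode_boxes(codes, centers, 16)
        np.testing.assert_allclose(decoded[inside], boxes[inside], atol=1e-4)

    def test_duplicate_boxes_suppressed_keeping_best(self):
        boxes = np.array([[0.0, 0.0, 10.0, 10.0], [0.0, 0.0, 10.0, 10.0]])
        keep = nms_greedy(boxes, np.array([0.8, 0.9]), 0.45)
        assert keep == [1]

    def test_nms_matches_quadratic_reference(self, rng):
        boxes = np.sort(rng.uniform(0, 100, (20, 4)), axis=-1)
        ok = (boxes[:, 2] - boxes[:, 0] > 1) & (boxes[:, 3] - boxes[:, 1] > 1)
        boxes, scores = boxes[ok], rng.uniform(0.1, 1.0, ok.sum())
        got = set(nms_greedy(boxes, scores, 0.5))
        # reference: independent O(n^2) greedy sweep
        order = np.argsort(-scores, kind="stable")
        kept = []
        for i in order:
            if all(
                _iou_matrix(boxes[i : i + 1], boxes[j : j + 1])[0, 0] <= 0.5 for j in kept
            ):
                kept.append(int(i))
        assert got == set(kept)

    def test_all_below_confidence_gives_empty_output(self, rng):
        preds = [
            nn.Tensor(np.full((1, 8, h, w), -10.0, dtype=np.float32))
            for h, w in [(8, 8), (4, 4), (2, 2)]
        ]
        assert decode_and_nms(preds, conf_threshold=0.25) == []

    def test_detections_sorted_by_confidence(self, rng):
        preds = [
            nn.Tensor(rng.standard_normal((1, 8, h, w)).astype(np.float32))
            for h, w in [(8, 8), (4, 4), (2, 2)]
        ]
        dets = decode_and_nms(preds, conf_threshold=0.05, nms_iou=0.9)
        confs = [d.confidence for d in dets]
        assert confs == sorted(confs, reverse=True)
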