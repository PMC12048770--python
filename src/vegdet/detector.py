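"""VegetableDet model assembly, target assignment, loss, decoding and accounting.

The detector is an anchor-free, center-based single-stage network over
strides {8, 16, 32}:

* backbone — convolutional stem + CSP-style blocks, with one
  window-attention + deformable-attention transformer pair inserted at the
  stride-16 and stride-32 stages (the stride-8 path stays convolutional to
  keep small-lesion detail cheap);
* neck — top-down + bottom-up feature pyramid, with a CSAAM block after
  every fusion node;
* head — shared-structure per-level branches predicting 4 box distances,
  an objectness logit and per-class logits.  The objectness branch is kept
  alongside the anchor-free head so the composite loss carries separate
  box / cls / obj terms with gains (0.05, 0.5, 1.0).

Boxes are parameterized as log-distances from the cell center to the four
edges, scaled by the level stride, so encoding and decoding are exact
inverses for any positive distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import nn
from .nn import functional as F
from .csaam import CSAAM
from .dat import DATConfig, window_block, deformable_block
from .voc import BoundingBox

STRIDES = (8, 16, 32)
DEFAULT_LOSS_GAINS = (0.05, 0.5, 1.0)  # box, cls, obj
PRIOR_SCALE = 4.0  # prior side length in strides, used for IoU-based assignment


class Bottleneck(nn.Module):
    def __init__(self, c: int):
        super().__init__()
        self.cv1 = nn.ConvBnAct(c, c, 3)
        self.cv2 = nn.ConvBnAct(c, c, 3)

    def forward(self, x):
        return x + self.cv2(self.cv1(x))


class CSPBlock(nn.Module):
    """Cross-stage partial block: split, run bottlenecks on one path, re-merge."""

    def __init__(self, c_in: int, c_out: int, n: int = 1):
        super().__init__()
        ch = c_out // 2
        self.cv1 = nn.ConvBnAct(c_in, ch, 1)
        self.cv2 = nn.ConvBnAct(c_in, ch, 1)
        self.blocks = nn.Sequential(nn.ModuleList([Bottleneck(ch) for _ in range(n)]))
        self.cv3 = nn.ConvBnAct(2 * ch, c_out, 1)

    def forward(self, x):
        return self.cv3(nn.concatenate([self.blocks(self.cv1(x)), self.cv2(x)], axis=1))


class Backbone(nn.Module):
    def __init__(self, widths, depths, use_dat: bool, dat_cfg: DATConfig):
        super().__init__()
        w1, w2, w3, w4, w5 = widths
        self.stem1 = nn.ConvBnAct(3, w1, 3, stride=2)
        self.stem2 = nn.ConvBnAct(w1, w2, 3, stride=2)
        self.stage3 = nn.Sequential(
            nn.ModuleList([nn.ConvBnAct(w2, w3, 3, stride=2), CSPBlock(w3, w3, depths[0])])
        )
        s16 = [nn.ConvBnAct(w3, w4, 3, stride=2), CSPBlock(w4, w4, depths[1])]
        s32 = [nn.ConvBnAct(w4, w5, 3, stride=2), CSPBlock(w5, w5, depths[2])]
        if use_dat:
            s16 += [
                window_block(w4, dat_cfg.window_size, _heads(w4), 0, dat_cfg.mlp_ratio),
                deformable_block(w4, _heads(w4), dat_cfg.offset_range_factor, dat_cfg.mlp_ratio),
            ]
            s32 += [
                window_block(w5, dat_cfg.window_size, _heads(w5), 0, dat_cfg.mlp_ratio),
                deformable_block(w5, _heads(w5), dat_cfg.offset_range_factor, dat_cfg.mlp_ratio),
            ]
        self.stage4 = nn.Sequential(nn.ModuleList(s16))
        self.stage5 = nn.Sequential(nn.ModuleList(s32))

    def forward(self, x):
        x = self.stem2(self.stem1(x))
        p3 = self.stage3(x)
        p4 = self.stage4(p3)
        p5 = self.stage5(p4)
        return p3, p4, p5


def _heads(dim: int) -> int:
    for h in (8, 4, 2, 1):
        if dim % h == 0 and dim // h >= 8:
            return h
    return 1


class Neck(nn.Module):
    """PAN-style pyramid; one CSAAM after each of the four fusion nodes."""

    def __init__(self, w3: int, w4: int, w5: int, use_csaam: bool):
        super().__init__()
        att = (lambda c: CSAAM(c)) if use_csaam else (lambda c: nn.Identity())
        self.lat5 = nn.ConvBnAct(w5, w4, 1)
        self.fuse4 = CSPBlock(2 * w4, w4, 1)
        self.att4 = att(w4)
        self.lat4 = nn.ConvBnAct(w4, w3, 1)
        self.fuse3 = CSPBlock(2 * w3, w3, 1)
        self.att3 = att(w3)
        self.down3 = nn.ConvBnAct(w3, w3, 3, stride=2)
        self.fuse4b = CSPBlock(w3 + w4, w4, 1)
        self.att4b = att(w4)
        self.down4 = nn.ConvBnAct(w4, w4, 3, stride=2)
        self.fuse5b = CSPBlock(2 * w4, w4, 1)
        self.att5b = att(w4)

    def forward(self, p3, p4, p5):
        t5 = self.lat5(p5)
        n4 = self.att4(self.fuse4(nn.concatenate([F.upsample2x_nearest(t5), p4], axis=1)))
        t4 = self.lat4(n4)
        n3 = self.att3(self.fuse3(nn.concatenate([F.upsample2x_nearest(t4), p3], axis=1)))
        m4 = self.att4b(self.fuse4b(nn.concatenate([self.down3(n3), n4], axis=1)))
        m5 = self.att5b(self.fuse5b(nn.concatenate([self.down4(m4), t5], axis=1)))
        return n3, m4, m5


class Head(nn.Module):
    """Per-level prediction: channels = [4 box distances, 1 obj, num_classes]."""

    def __init__(self, in_channels, num_classes: int, hidden: int):
        super().__init__()
        self.num_classes = num_classes
        self.stems = nn.ModuleList([nn.ConvBnAct(c, hidden, 3) for c in in_channels])
        self.preds = nn.ModuleList(
            [nn.Conv2d(hidden, 5 + num_classes, 1) for _ in in_channels]
        )

    def forward(self, feats):
        return [pred(stem(f)) for stem, pred, f in zip(self.stems, self.preds, feats)]


@dataclass
class ModelConfig:
    num_classes: int = 30
    width_multiple: float = 1.0
    base_widths: tuple[int, ...] = (16, 32, 64, 128, 192)
    csp_depths: tuple[int, int, int] = (1, 2, 2)
    use_dat: bool = True
    use_csaam: bool = True
    dat: DATConfig = field(default_factory=DATConfig)


class VegetableDet(nn.Module):
    """Lightweight disease detector: DAT-augmented backbone, CSAAM neck, coupled head."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        if cfg.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if cfg.width_multiple <= 0:
            raise ValueError("width_multiple must be positive")
        self.cfg = cfg
        widths = tuple(max(8, int(round(w * cfg.width_multiple / 8)) * 8) for w in cfg.base_widths)
        self.widths = widths
        self.backbone = Backbone(widths, cfg.csp_depths, cfg.use_dat, cfg.dat)
        self.neck = Neck(widths[2], widths[3], widths[4], cfg.use_csaam)
        self.head = Head((widths[2], widths[3], widths[3]), cfg.num_classes, widths[2])
        self.strides = STRIDES

    def forward(self, x):
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=np.float32))
        p3, p4, p5 = self.backbone(x)
        feats = self.neck(p3, p4, p5)
        return self.head(feats)


def build_model(
    num_classes: int = 30,
    width_multiple: float = 1.0,
    dat_cfg: DATConfig | None = None,
    use_csaam: bool = True,
    use_dat: bool = True,
    seed: int = 0,
) -> VegetableDet:
    nn.set_init_seed(seed)
    cfg = ModelConfig(
        num_classes=num_classes,
        width_multiple=width_multiple,
        use_dat=use_dat,
        use_csaam=use_csaam,
        dat=dat_cfg or DATConfig(),
    )
    return VegetableDet(cfg)


def tiny_model(num_classes: int, seed: int = 0) -> VegetableDet:
    """Reduced-width instantiation for CPU-scale experiments and tests."""
    return build_model(num_classes, width_multiple=0.5, seed=seed)


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def count_parameters(model: nn.Module) -> int:
    """Exact trainable parameter count (sum of array sizes)."""
    return int(sum(p.size for p in model.parameters()))


def count_flops(model: VegetableDet, input_size: int = 640) -> int:
    """Analytic multiply-accumulate count of one forward at the given size."""
    model.eval()
    with nn.no_grad(), nn.count_macs() as counter:
        model(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
    model.train()
    return counter[0]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def level_grid_centers(h: int, w: int, stride: int) -> np.ndarray:
    """(h*w, 2) pixel coordinates of cell centers for one prediction level."""
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.stack([(xs.ravel() + 0.5) * stride, (ys.ravel() + 0.5) * stride], axis=-1)


def encode_boxes(boxes: np.ndarray, centers: np.ndarray, stride: int) -> np.ndarray:
    """ltrb log-distance encoding of (M,4) xyxy boxes at (M,2) cell centers."""
    boxes = np.asarray(boxes, dtype=np.float64)
    d = np.stack(
        [
            centers[:, 0] - boxes[:, 0],
            centers[:, 1] - boxes[:, 1],
            boxes[:, 2] - centers[:, 0],
            boxes[:, 3] - centers[:, 1],
        ],
        axis=-1,
    )
    return np.log(np.maximum(d, 0.01 * stride) / stride)


def decode_boxes(codes: np.ndarray, centers: np.ndarray, stride: int) -> np.ndarray:
    """Inverse of :func:`encode_boxes`."""
    d = np.exp(np.asarray(codes, dtype=np.float64)) * stride
    return np.stack(
        [
            centers[:, 0] - d[:, 0],
            centers[:, 1] - d[:, 1],
            centers[:, 0] + d[:, 2],
            centers[:, 1] + d[:, 3],
        ],
        axis=-1,
    )


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (M,4) and (K,4) xyxy boxes."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

@dataclass
class Assignment:
    """Per-level positive assignments for one image.

    ``match`` maps each level to an int array of length h*w holding the index
    of the assigned ground-truth box (or -1 for negatives).
    """

    match: list[np.ndarray]
    shapes: list[tuple[int, int]]

    @property
    def num_positives(self) -> int:
        return int(sum((m >= 0).sum() for m in self.match))


def assign_targets(
    level_shapes: list[tuple[int, int]],
    gt_boxes: np.ndarray,
    iou_threshold: float = 0.2,
    strides: tuple[int, ...] = STRIDES,
    prior_scale: float = PRIOR_SCALE,
) -> Assignment:
    """IoU-threshold assignment of ground truth to pyramid cells.

    Each cell carries a square prior of side ``prior_scale * stride``; cells
    whose prior overlaps a box with IoU >= threshold become positives for the
    best-overlapping box (ties broken by nearest center).  Every ground-truth
    box is additionally forced onto its single best cell so no target is lost.
    """
    if not 0 < iou_threshold < 1:
        raise ValueError("iou_threshold must lie in (0, 1)")
    gt = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    match = [np.full(h * w, -1, dtype=np.int64) for h, w in level_shapes]
    if len(gt) == 0:
        return Assignment(match, list(level_shapes))
    centers_all, priors_all, level_of, idx_in_level = [], [], [], []
    for li, ((h, w), s) in enumerate(zip(level_shapes, strides)):
        centers = level_grid_centers(h, w, s)
        half = prior_scale * s / 2.0
        priors = np.concatenate([centers - half, centers + half], axis=-1)
        centers_all.append(centers)
        priors_all.append(priors)
        level_of.append(np.full(len(centers), li))
        idx_in_level.append(np.arange(len(centers)))
    centers_all = np.concatenate(centers_all)
    priors_all = np.concatenate(priors_all)
    level_of = np.concatenate(level_of)
    idx_in_level = np.concatenate(idx_in_level)

    iou = _iou_matrix(priors_all, gt)  # (cells, K)
    gt_centers = (gt[:, :2] + gt[:, 2:]) / 2.0
    dist = np.linalg.norm(centers_all[:, None, :] - gt_centers[None, :, :], axis=-1)
    # best box per cell among those above threshold; nearest center tie-break
    score = np.where(iou >= iou_threshold, iou - 1e-9 * dist, -1.0)
    best_gt = score.argmax(axis=1)
    pos = score.max(axis=1) >= 0
    # forced best match: each box claims its highest-IoU cell
    forced = iou.argmax(axis=0)
    assigned = np.where(pos, best_gt, -1)
    for k, cell in enumerate(forced):
        assigned[cell] = k
    for cell in np.nonzero(assigned >= 0)[0]:
        match[level_of[cell]][idx_in_level[cell]] = assigned[cell]
    return Assignment(match, list(level_shapes))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

@dataclass
class LossBreakdown:
    box_loss: float
    cls_loss: float
    obj_loss: float
    gains: tuple[float, float, float]
    total_tensor: nn.Tensor | None = None

    @property
    def total(self) -> float:
        gb, gc, go = self.gains
        return gb * self.box_loss + gc * self.cls_loss + go * self.obj_loss


def _pairwise_iou_t(pred: nn.Tensor, gt: np.ndarray) -> nn.Tensor:
    """Differentiable elementwise IoU of predicted vs target (M,4) boxes."""
    gt = np.asarray(gt, dtype=np.float32)
    x1 = nn.maximum(pred[:, 0], gt[:, 0])
    y1 = nn.maximum(pred[:, 1], gt[:, 1])
    x2 = nn.minimum(pred[:, 2], gt[:, 2])
    y2 = nn.minimum(pred[:, 3], gt[:, 3])
    inter = nn.maximum(x2 - x1, 0.0) * nn.maximum(y2 - y1, 0.0)
    area_p = nn.maximum(pred[:, 2] - pred[:, 0], 0.0) * nn.maximum(pred[:, 3] - pred[:, 1], 0.0)
    area_g = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
    union = area_p + area_g - inter
    return inter / (union + 1e-7)


def compute_loss(
    predictions: list[nn.Tensor],
    assignments: list[Assignment],
    gt_boxes: list[np.ndarray],
    gt_labels: list[np.ndarray],
    num_classes: int,
    gains: tuple[float, float, float] = DEFAULT_LOSS_GAINS,
    pos_weights: tuple[float, float] = (1.0, 1.0),
    class_weights: np.ndarray | None = None,
    strides: tuple[int, ...] = STRIDES,
) -> LossBreakdown:
    """Composite detection loss.

    box term: mean (1 - IoU) over positive cells; cls and obj terms: BCE with
    the configured positive-sample weights.  With no positives in the batch
    the box and cls terms are exactly zero.
    """
    n = predictions[0].shape[0]
    if len(assignments) != n:
        raise ValueError("one assignment per image required")
    cls_pw, obj_pw = pos_weights
    box_terms: list[nn.Tensor] = []
    cls_logits: list[nn.Tensor] = []
    cls_targets: list[np.ndarray] = []
    cls_elem_weights: list[np.ndarray] = []
    obj_parts: list[nn.Tensor] = []
    obj_targets: list[np.ndarray] = []
    for li, pred in enumerate(predictions):
        _, ch, h, w = pred.shape
        stride = strides[li]
        flat = pred.reshape(n, ch, h * w)
        obj_parts.append(flat[:, 4, :])
        obj_t = np.zeros((n, h * w), dtype=np.float32)
        centers = level_grid_centers(h, w, stride)
        for bi in range(n):
            m = assignments[bi].match[li]
            pos_idx = np.nonzero(m >= 0)[0]
            if len(pos_idx) == 0:
                continue
            obj_t[bi, pos_idx] = 1.0
            gsel = np.asarray(gt_boxes[bi], dtype=np.float32).reshape(-1, 4)[m[pos_idx]]
            codes = flat[bi, :4, :].transpose(1, 0)[pos_idx]  # (P, 4)
            c = centers[pos_idx].astype(np.float32)
            # clamp keeps exp() finite for wild early predictions
            d = nn.minimum(codes, 8.0).exp() * float(stride)
            px1 = c[:, 0] - d[:, 0]
            py1 = c[:, 1] - d[:, 1]
            px2 = c[:, 0] + d[:, 2]
            py2 = c[:, 1] + d[:, 3]
            pbox = nn.stack([px1, py1, px2, py2], axis=1)
            box_terms.append(1.0 - _pairwise_iou_t(pbox, gsel))
            labels = np.asarray(gt_labels[bi], dtype=np.int64)[m[pos_idx]]
            onehot = np.zeros((len(pos_idx), num_classes), dtype=np.float32)
            onehot[np.arange(len(pos_idx)), labels] = 1.0
            cls_logits.append(flat[bi, 5:, :].transpose(1, 0)[pos_idx])
            cls_targets.append(onehot)
            if class_weights is not None:
                cls_elem_weights.append(
                    np.broadcast_to(
                        np.asarray(class_weights, dtype=np.float32)[labels][:, None],
                        (len(pos_idx), num_classes),
                    )
                )
        obj_targets.append(obj_t)

    obj_all = nn.concatenate([o.reshape(-1) for o in obj_parts], axis=0)
    obj_t_all = np.concatenate([t.reshape(-1) for t in obj_targets])
    obj_loss = F.binary_cross_entropy_with_logits(obj_all, obj_t_all, pos_weight=obj_pw)

    if box_terms:
        box_loss = nn.concatenate(box_terms, axis=0).mean()
        cls_loss = F.binary_cross_entropy_with_logits(
            nn.concatenate(cls_logits, axis=0),
            np.concatenate(cls_targets),
            pos_weight=cls_pw,
            weight=np.concatenate(cls_elem_weights) if cls_elem_weights else None,
        )
    else:
        box_loss = nn.Tensor(0.0)
        cls_loss = nn.Tensor(0.0)

    gb, gc, go = gains
    total = gb * box_loss + gc * cls_loss + go * obj_loss
    return LossBreakdown(
        box_loss=float(box_loss.data),
        cls_loss=float(cls_loss.data),
        obj_loss=float(obj_loss.data),
        gains=gains,
        total_tensor=total,
    )


# ---------------------------------------------------------------------------
# decoding and NMS
# ---------------------------------------------------------------------------

@dataclass
class Detection:
    box: BoundingBox
    class_id: int
    confidence: float


def nms_greedy(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, score-descending."""
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        if len(boxes) > 1:
            ious = _iou_matrix(boxes[i : i + 1], boxes).ravel()
            suppressed |= ious > iou_threshold
            suppressed[i] = True
    return keep


def decode_and_nms(
    predictions: list[nn.Tensor | np.ndarray],
    conf_threshold: float = 0.25,
    nms_iou: float = 0.45,
    class_names: list[str] | None = None,
    strides: tuple[int, ...] = STRIDES,
    image_index: int = 0,
) -> list[Detection]:
    """Decode raw prediction maps into a confidence-sorted, NMS-filtered list."""
    if not 0 < conf_threshold < 1 or not 0 < nms_iou < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    all_boxes, all_scores, all_cls = [], [], []
    for pred, stride in zip(predictions, strides):
        arr = pred.data if isinstance(pred, nn.Tensor) else np.asarray(pred)
        _, ch, h, w = arr.shape
        flat = arr[image_index].reshape(ch, h * w)
        centers = level_grid_centers(h, w, stride)
        boxes = decode_boxes(flat[:4].T, centers, stride)
        obj = expit(flat[4])
        cls = expit(flat[5:])
        conf = obj[None, :] * cls
        cls_id = conf.argmax(axis=0)
        score = conf.max(axis=0)
        keep = score >= conf_threshold
        all_boxes.append(boxes[keep])
        all_scores.append(score[keep])
        all_cls.append(cls_id[keep])
    boxes = np.concatenate(all_boxes) if all_boxes else np.zeros((0, 4))
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    cls_ids = np.concatenate(all_cls) if all_cls else np.zeros(0, dtype=int)
    detections: list[Detection] = []
    for c in np.unique(cls_ids):
        sel = np.nonzero(cls_ids == c)[0]
        for i in nms_greedy(boxes[sel], scores[sel], nms_iou):
            gi = sel[i]
            name = class_names[int(c)] if class_names else str(int(c))
            detections.append(
                Detection(
                    box=BoundingBox(name, *[float(v) for v in boxes[gi]]),
                    class_id=int(c),
                    confidence=float(scores[gi]),
                )
            )
    detections.sort(key=lambda d: -d.confidence)
    return detections
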