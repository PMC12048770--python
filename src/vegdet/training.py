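"""Hierarchical progressive transfer learning: two stages, tiered learning rates.

Stage 1 ("init", domain initialization) starts from any compatible source
checkpoint, copies backbone and neck, re-initializes the detection head,
and trains on a single-crop subset with rates (backbone 0.0003, neck 0.001,
head 0.001).  Stage 2 ("diversity", diversity adaptation) carries *all*
weights over and trains on the full multi-crop label space with the
three-tier rates (0.0001, 0.0005, 0.001), plus inverse-frequency balanced
sampling and class-weighted classification loss.

The schedule warms up linearly for the first 3 epochs from 0.1x the base
rate (momentum ramping 0.8 -> 0.937) and afterwards decays every 30 epochs
by a factor 0.8.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .detector import (
    VegetableDet,
    assign_targets,
    compute_loss,
    decode_and_nms,
    DEFAULT_LOSS_GAINS,
)
from .evaluation import evaluate
from .voc import read_voc


@dataclass
class StageConfig:
    stage: str = "init"  # {"init", "diversity"}
    lr_backbone: float = 0.0003
    lr_neck: float = 0.001
    lr_head: float = 0.001
    epochs: int = 200
    dataset_scope: list[str] | None = None  # class subset; None = all
    decay_factor: float = 0.8
    decay_every: int = 30
    warmup_epochs: int = 3
    warmup_lr_factor: float = 0.1
    warmup_momentum: float = 0.8
    momentum: float = 0.937
    weight_decay: float = 0.0005
    batch_size: int = 32
    input_size: int = 640
    seed: int = 0
    iou_threshold: float = 0.2
    loss_gains: tuple[float, float, float] = DEFAULT_LOSS_GAINS
    conf_threshold: float = 0.25
    use_balanced_sampling: bool = False
    use_class_weights: bool = False
    use_mosaic: bool = False

    def __post_init__(self):
        if self.stage not in ("init", "diversity"):
            raise ValueError("stage must be 'init' or 'diversity'")
        for lr in (self.lr_backbone, self.lr_neck, self.lr_head):
            if lr <= 0:
                raise ValueError("learning rates must be positive")

    @classmethod
    def stage_defaults(cls, stage: str, **overrides) -> "StageConfig":
        rates = {
            "init": (0.0003, 0.001, 0.001),
            "diversity": (0.0001, 0.0005, 0.001),
        }[stage]
        extras = {"use_balanced_sampling": True, "use_class_weights": True} if stage == "diversity" else {}
        return cls(
            stage=stage,
            lr_backbone=rates[0],
            lr_neck=rates[1],
            lr_head=rates[2],
            **{**extras, **overrides},
        )


# ---------------------------------------------------------------------------
# parameter groups and weight transfer
# ---------------------------------------------------------------------------

PARTITIONS = ("backbone", "neck", "head")


def make_param_groups(model: VegetableDet, cfg: StageConfig) -> list[dict]:
    """Three disjoint, exhaustive parameter groups with the stage's rates."""
    rates = {"backbone": cfg.lr_backbone, "neck": cfg.lr_neck, "head": cfg.lr_head}
    groups = {name: [] for name in PARTITIONS}
    for pname, p in model.named_parameters():
        part = pname.split(".", 1)[0]
        if part not in groups:
            raise ValueError(f"parameter {pname!r} not attributable to backbone/neck/head")
        groups[part].append(p)
    return [{"name": n, "params": groups[n], "lr": rates[n]} for n in PARTITIONS]


def transfer_weights(source: VegetableDet, target: VegetableDet, stage: str) -> VegetableDet:
    """Copy partitions from source into target according to the stage.

    init: backbone + neck copied, head keeps its fresh random initialization.
    diversity: every partition copied (stage-1 knowledge fully preserved).
    """
    parts = {"init": ("backbone", "neck"), "diversity": PARTITIONS}[stage]
    src = source.state_dict()
    dst = target.state_dict()
    mismatched = [
        k
        for k in src
        if k.split(".", 1)[0] in parts and (k not in dst or dst[k].shape != src[k].shape)
    ]
    if mismatched:
        raise ValueError(f"incompatible arrays for transfer: {sorted(mismatched)}")
    for k in src:
        if k.split(".", 1)[0] in parts:
            dst[k] = src[k].copy()
    target.load_state_dict(dst)
    return target


def lr_at_epoch(cfg: StageConfig, epoch: int) -> dict[str, float]:
    """Per-group learning rates (and momentum) at a given epoch.

    Warm-up: linear ramp from ``warmup_lr_factor * base`` to ``base`` over
    ``warmup_epochs`` (momentum ramps warmup_momentum -> momentum).
    Afterwards: ``base * decay_factor ** floor(epoch / decay_every)``.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    bases = {"backbone": cfg.lr_backbone, "neck": cfg.lr_neck, "head": cfg.lr_head}
    if cfg.warmup_epochs > 0 and epoch < cfg.warmup_epochs:
        t = epoch / cfg.warmup_epochs
        scale = cfg.warmup_lr_factor + (1.0 - cfg.warmup_lr_factor) * t
        momentum = cfg.warmup_momentum + (cfg.momentum - cfg.warmup_momentum) * t
    else:
        scale = cfg.decay_factor ** (epoch // cfg.decay_every)
        momentum = cfg.momentum
    out = {name: base * scale for name, base in bases.items()}
    out["momentum"] = momentum
    return out


# ---------------------------------------------------------------------------
# balanced sampling and class weighting
# ---------------------------------------------------------------------------

def balanced_sample_weights(dist: dict[str, int], image_classes: list[str]) -> np.ndarray:
    """Per-image sampling weights proportional to 1/count(class), sum 1."""
    if any(n <= 0 for n in dist.values()):
        raise ValueError("class counts must be positive")
    w = np.array([1.0 / dist[c] for c in image_classes], dtype=np.float64)
    return w / w.sum()


def class_loss_weights(dist: dict[str, int], class_names: list[str]) -> np.ndarray:
    """Per-class loss weights proportional to 1/count, normalized to mean 1."""
    if any(dist.get(c, 0) <= 0 for c in class_names):
        raise ValueError("every class needs a positive count")
    w = np.array([1.0 / dist[c] for c in class_names], dtype=np.float64)
    return w / w.mean()


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------

@dataclass
class TrainingSample:
    image: np.ndarray  # (3, S, S) float32 in [0, 1]
    boxes: np.ndarray  # (K, 4) xyxy at network scale
    labels: np.ndarray  # (K,) int class ids
    class_label: str


def load_training_samples(
    records: list[dict], class_names: list[str], input_size: int
) -> list[TrainingSample]:
    name_to_id = {c: i for i, c in enumerate(class_names)}
    out = []
    for rec in records:
        sample = read_voc(rec["annotation"])
        img = Image.fromarray(sample.image).resize((input_size, input_size), Image.BILINEAR)
        sx = input_size / sample.width
        sy = input_size / sample.height
        boxes = np.array(
            [[b.xmin * sx, b.ymin * sy, b.xmax * sx, b.ymax * sy] for b in sample.boxes]
        ).reshape(-1, 4)
        labels = np.array([name_to_id[b.class_label] for b in sample.boxes], dtype=np.int64)
        arr = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
        out.append(TrainingSample(arr, boxes, labels, rec["class"]))
    return out


# ---------------------------------------------------------------------------
# evaluation helper
# ---------------------------------------------------------------------------

def evaluate_model(
    model: VegetableDet,
    samples: list[TrainingSample],
    class_names: list[str],
    iou_thresholds=(0.5,),
    conf_threshold: float = 0.25,
    nms_iou: float = 0.45,
    batch_size: int = 8,
):
    model.eval()
    dets_per_image, gts_per_image = [], []
    from .voc import BoundingBox

    with nn.no_grad():
        for start in range(0, len(samples), batch_size):
            chunk = samples[start : start + batch_size]
            batch = np.stack([s.image for s in chunk])
            preds = model(batch)
            for bi, s in enumerate(chunk):
                dets = decode_and_nms(
                    preds,
                    conf_threshold=conf_threshold,
                    nms_iou=nms_iou,
                    class_names=class_names,
                    image_index=bi,
                )
                dets_per_image.append(dets)
                gts = [
                    BoundingBox(class_names[c], *b)
                    for b, c in zip(s.boxes, s.labels)
                ]
                gts_per_image.append(gts)
    model.train()
    return evaluate(
        dets_per_image,
        gts_per_image,
        class_names,
        iou_thresholds=iou_thresholds,
        conf_threshold=conf_threshold,
    )


# ---------------------------------------------------------------------------
# stage driver
# ---------------------------------------------------------------------------

class DivergenceError(RuntimeError):
    pass


def run_stage(
    model: VegetableDet,
    cfg: StageConfig,
    train_records: list[dict],
    val_records: list[dict],
    class_names: list[str],
    log_path=None,
) -> tuple[VegetableDet, list[dict]]:
    """Optimize the composite loss for one transfer-learning stage.

    Fully seeded: sampling order is the only stochastic element.  Logs loss
    components and validation mAP@0.5 per epoch; the best-mAP weights are
    restored into the model before returning.
    """
    if not train_records or not val_records:
        raise ValueError("train and val manifests must be non-empty")
    if cfg.dataset_scope is not None:
        train_records = [r for r in train_records if r["class"] in cfg.dataset_scope]
        scoped_val = [r for r in val_records if r["class"] in cfg.dataset_scope]
        val_records = scoped_val or val_records
    rng = np.random.default_rng(cfg.seed)
    train = load_training_samples(train_records, class_names, cfg.input_size)
    val = load_training_samples(val_records, class_names, cfg.input_size)
    dist: dict[str, int] = {}
    for r in train_records:
        dist[r["class"]] = dist.get(r["class"], 0) + 1
    cls_w = (
        class_loss_weights(dist, [c for c in class_names if c in dist])
        if cfg.use_class_weights
        else None
    )
    if cls_w is not None:
        full = np.ones(len(class_names))
        present = [c for c in class_names if c in dist]
        for c, w in zip(present, cls_w):
            full[class_names.index(c)] = w
        cls_w = full
    sample_w = (
        balanced_sample_weights(dist, [r["class"] for r in train_records])
        if cfg.use_balanced_sampling
        else None
    )

    groups = make_param_groups(model, cfg)
    opt = nn.Adam(groups, beta1=cfg.momentum, weight_decay=cfg.weight_decay)
    logs: list[dict] = []
    best_map, best_state = -1.0, None
    n = len(train)
    steps = max(n // cfg.batch_size, 1)
    for epoch in range(cfg.epochs):
        rates = lr_at_epoch(cfg, epoch)
        for g in opt.groups:
            g["lr"] = rates[g["name"]]
        opt.beta1 = rates["momentum"]
        ep_loss = np.zeros(3)
        model.train()
        for _ in range(steps):
            if sample_w is not None:
                idx = rng.choice(n, size=cfg.batch_size, replace=True, p=sample_w)
            else:
                idx = rng.choice(n, size=cfg.batch_size, replace=n < cfg.batch_size)
            chunk = [train[i] for i in idx]
            batch = np.stack([s.image for s in chunk])
            preds = model(batch)
            shapes = [(p.shape[2], p.shape[3]) for p in preds]
            assignments = [
                assign_targets(shapes, s.boxes, iou_threshold=cfg.iou_threshold)
                for s in chunk
            ]
            loss = compute_loss(
                preds,
                assignments,
                [s.boxes for s in chunk],
                [s.labels for s in chunk],
                num_classes=len(class_names),
                gains=cfg.loss_gains,
                class_weights=cls_w,
            )
            if not np.isfinite(loss.total):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: box={loss.box_loss} "
                    f"cls={loss.cls_loss} obj={loss.obj_loss}"
                )
            opt.zero_grad()
            loss.total_tensor.backward()
            opt.step()
            ep_loss += (loss.box_loss, loss.cls_loss, loss.obj_loss)
        ep_loss /= steps
        res = evaluate_model(
            model, val, class_names, iou_thresholds=(0.5,), conf_threshold=cfg.conf_threshold
        )[0]
        entry = {
            "epoch": epoch,
            "lr_backbone": rates["backbone"],
            "lr_neck": rates["neck"],
            "lr_head": rates["head"],
            "box_loss": float(ep_loss[0]),
            "cls_loss": float(ep_loss[1]),
            "obj_loss": float(ep_loss[2]),
            "val_map50": res.mAP,
        }
        logs.append(entry)
        if res.mAP >= best_map:
            best_map = res.mAP
            best_state = copy.deepcopy(model.state_dict())
    if best_state is not None:
        model.load_state_dict(best_state)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in logs:
                fh.write(json.dumps(entry) + "\n")
    return model, logs


def save_checkpoint(model: VegetableDet, path) -> None:
    """Single-file weights checkpoint (compressed npz of the state dict)."""
    np.savez_compressed(Path(path), **model.state_dict())


def load_checkpoint(model: VegetableDet, path) -> VegetableDet:
    with np.load(Path(path)) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
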