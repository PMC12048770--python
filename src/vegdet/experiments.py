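"""Self-contained desk-scale experiments on synthetic greenhouse scenes.

These drivers wire the full pipeline — scene generation, training, and
mAP evaluation — at sizes a single CPU handles in minutes.  They are used
by the example scripts, the test suite and the reproduction script alike.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detector import build_model
from .synthetic import generate_dataset
from .training import (
    StageConfig,
    load_training_samples,
    run_stage,
    evaluate_model,
)

SMOKE_CLASSES = [
    "tomato early blight",
    "tomato late blight",
    "cucumber downy mildew",
    "pepper leaf spot",
]


@dataclass
class SmokeResult:
    trained_map50: float
    untrained_map50: float
    logs: list[dict]
    n_train: int
    n_val: int


def synthetic_smoke(
    seed: int = 0,
    n_train_per_class: int = 50,
    n_val_per_class: int = 12,
    epochs: int = 10,
    input_size: int = 128,
    batch_size: int = 8,
    work_dir: str | Path | None = None,
) -> SmokeResult:
    """Train a tiny-width detector from scratch on a 4-class synthetic task.

    Scenes use mid/late-stage lesions with distinct per-class colorations,
    no occlusion and normal lighting, so the task probes the training loop
    end to end rather than fine-grained appearance modeling.  Returns
    held-out mAP@0.5 of the trained model and of an untrained copy.
    """
    classes = SMOKE_CLASSES
    ctx = tempfile.TemporaryDirectory() if work_dir is None else None
    root = Path(ctx.name if ctx else work_dir)
    try:
        spec_defaults = {
            "canvas_size": (input_size, input_size),
            "n_leaves": 2,
            "lesions_per_leaf": (1, 2),
            "stage": "late",
            "occlusion_level": 0.0,
            "lighting": "normal",
        }
        train_recs = generate_dataset(
            {c: n_train_per_class for c in classes},
            root / "train",
            spec_defaults=spec_defaults,
            seed=seed,
        )
        val_recs = generate_dataset(
            {c: n_val_per_class for c in classes},
            root / "val",
            spec_defaults=spec_defaults,
            seed=seed + 1,
            split="val",
        )
        model = build_model(
            num_classes=len(classes), width_multiple=0.25, seed=seed
        )
        untrained = build_model(
            num_classes=len(classes), width_multiple=0.25, seed=seed
        )
        cfg = StageConfig(
            stage="init",
            lr_backbone=0.002,
            lr_neck=0.002,
            lr_head=0.002,
            epochs=epochs,
            batch_size=batch_size,
            input_size=input_size,
            seed=seed,
            conf_threshold=0.25,
        )
        model, logs = run_stage(model, cfg, train_recs, val_recs, classes)
        val = load_training_samples(val_recs, classes, input_size)
        trained = evaluate_model(model, val, classes)[0].mAP
        baseline = evaluate_model(untrained, val, classes)[0].mAP
        return SmokeResult(
            trained_map50=trained,
            untrained_map50=baseline,
            logs=logs,
            n_train=len(train_recs),
            n_val=len(val_recs),
        )
    finally:
        if ctx is not None:
            ctx.cleanup()


def overfit_probe(seed: int = 0, n_images: int = 8, steps: int = 200,
                  input_size: int = 96) -> tuple[float, float]:
    """Memorization check: loss on a fixed tiny batch must collapse.

    Returns (initial_loss, final_loss) over ``steps`` updates on ``n_images``
    synthetic scenes.
    """
    from . import nn
    from .detector import assign_targets, compute_loss
    from .synthetic import generate_dataset

    classes = SMOKE_CLASSES[:2]
    with tempfile.TemporaryDirectory() as td:
        recs = generate_dataset(
            {c: n_images // len(classes) for c in classes},
            td,
            spec_defaults={
                "canvas_size": (input_size, input_size),
                "n_leaves": 2,
                "stage": "late",
            },
            seed=seed,
        )
        samples = load_training_samples(recs, classes, input_size)
        model = build_model(num_classes=len(classes), width_multiple=0.25, seed=seed)
        opt = nn.Adam(
            [{"params": model.parameters(), "lr": 0.002}], weight_decay=0.0
        )
        batch = np.stack([s.image for s in samples])
        first = last = None
        for _ in range(steps):
            preds = model(batch)
            shapes = [(p.shape[2], p.shape[3]) for p in preds]
            assignments = [
                assign_targets(shapes, s.boxes) for s in samples
            ]
            loss = compute_loss(
                preds,
                assignments,
                [s.boxes for s in samples],
                [s.labels for s in samples],
                num_classes=len(classes),
            )
            opt.zero_grad()
            loss.total_tensor.backward()
            opt.step()
            if first is None:
                first = loss.total
            last = loss.total
        return float(first), float(last)
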