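"""Run configuration: published hyperparameter defaults, YAML files, overrides.

Defaults reproduce the model's training recipe: batch 32, 200 epochs, Adam
with momentum 0.937 and weight decay 5e-4, initial learning rate 1e-3
(tunable up to 3e-3 for scratch training), 3 warm-up epochs starting at
0.1x the base rate with momentum 0.8, 640-px input, loss gains
box/cls/obj = 0.05/0.5/1.0 and a 0.2 IoU threshold for training-time target
assignment.  The epoch decay factor defaults to 0.8 every 30 epochs; a
steeper 0.2 coefficient is available via ``lr_decay_coefficient``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    batch_size: int = 32
    epochs: int = 200
    lr0: float = 0.001
    lr0_max: float = 0.003
    lr_decay_factor: float = 0.8
    lr_decay_every: int = 30
    lr_decay_coefficient: float = 0.2  # alternative single-step decay option
    optimizer: str = "adam"
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: int = 3
    warmup_momentum: float = 0.8
    warmup_lr_factor: float = 0.1
    input_size: int = 640
    box_loss_gain: float = 0.05
    cls_loss_gain: float = 0.5
    cls_pos_weight: float = 1.0
    obj_loss_gain: float = 1.0
    obj_pos_weight: float = 1.0
    iou_threshold: float = 0.2
    conf_threshold: float = 0.25
    nms_iou: float = 0.45
    num_classes: int = 30
    width_multiple: float = 1.0
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(
    path: str | Path | None = None, overrides: list[str] | None = None
) -> RunConfig:
    """Merge precedence: defaults < YAML file < dotted-path flag overrides.

    Overrides use ``key=value`` (e.g. ``batch_size=8`` or ``paths.out=run1``).
    """
    cfg = RunConfig()
    data = cfg.to_dict()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(data, loaded)
    for item in overrides or []:
        if "=" not in item:
            raise ValueError(f"override {item!r} must be key=value")
        key, raw = item.split("=", 1)
        node = data
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = yaml.safe_load(raw)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
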