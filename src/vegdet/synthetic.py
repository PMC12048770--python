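"""Synthetic greenhouse scene generator with exact ground truth.

Scenes emulate the conditions protected-vegetable disease photos are taken
under: leaf-colored elliptical foliage over a soil-toned noise background,
colored textured lesions whose size tracks disease progression (early
lesions are small spots; late-stage disease covers most of a leaf),
foreground occlusion, and four lighting regimes (normal, low light, strong
direct light, strong reflection).  Every lesion yields one tight bounding
box, and the exact occlusion fraction applied to each lesion is recorded in
its box metadata, so annotation-filter rules are testable against known
truth.

The generator is fully seeded: an identical ``SceneSpec`` reproduces a
byte-identical image and annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .voc import BoundingBox, LabeledImage, write_voc, write_manifest

STAGES = ("early", "mid", "late")
LIGHTING_MODES = ("normal", "low", "direct", "reflection")

# lesion-box area as a fraction of the carrying leaf's area, per stage
STAGE_FRACTIONS: dict[str, tuple[float, float]] = {
    "early": (0.005, 0.05),
    "mid": (0.05, 0.40),
    "late": (0.40, 0.80),
}

# 31-class label space of the emulated protected-vegetable dataset
# (5 vegetables x healthy + diseases), with the published per-class
# training-set imbalance
PVDD_TRAIN_COUNTS: dict[str, int] = {
    "A1 Tomato health": 1344,
    "A2 Tomato gray mold": 656,
    "A3 Tomato gray leaf spot": 904,
    "A4 Tomato black spot": 520,
    "A5 Tomato late blight": 952,
    "A6 Tomato brown rot": 1016,
    "A7 Tomato bacterial canker": 784,
    "A8 Tomato early blight": 992,
    "A9 Tomato bacterial spot": 680,
    "A10 Tomato leaf mold": 768,
    "B1 Cucumber health": 1304,
    "B2 Cucumber target spot": 704,
    "B3 Cucumber powdery mildew": 632,
    "B4 Cucumber angular spot": 600,
    "B5 Cucumber downy mildew": 552,
    "C1 Pepper health": 1328,
    "C2 Pepper leaf spot": 664,
    "C3 Pepper powdery mildew": 680,
    "C4 Pepper black spot": 424,
    "C5 Pepper early blight": 768,
    "D1 Eggplant health": 1336,
    "D2 Eggplant yellow wilt": 448,
    "D3 Eggplant brown spot": 648,
    "D4 Cucumber angular spot (eggplant)": 744,
    "D5 Eggplant brown rot": 768,
    "E1 Squash health": 1224,
    "E2 Squash viral disease": 760,
    "E3 Squash silver leaf": 512,
    "E4 Squash downy mildew": 600,
    "E5 Eggplant brown rot (squash)": 688,
}

DEFAULT_CLASSES = list(PVDD_TRAIN_COUNTS)

# saturated lesion palette; classes cycle through it so small label spaces
# get visually distinct diseases
_PALETTE = np.array(
    [
        (170, 40, 30),
        (200, 160, 40),
        (90, 50, 140),
        (30, 90, 170),
        (200, 90, 160),
        (120, 80, 30),
        (220, 220, 210),
        (40, 160, 160),
        (240, 120, 40),
        (90, 20, 60),
        (160, 200, 60),
        (20, 40, 90),
    ],
    dtype=np.float64,
)


class ConfigError(ValueError):
    pass


@dataclass
class SceneSpec:
    class_label: str
    canvas_size: tuple[int, int] = (256, 256)  # (H, W)
    n_leaves: int = 3
    lesions_per_leaf: tuple[int, int] = (1, 2)  # inclusive count range
    stage: str = "mid"
    occlusion_level: float = 0.0
    lighting: str = "normal"
    seed: int = 0
    class_index: int | None = None  # palette index; defaults to position in DEFAULT_CLASSES
    lesion_rects: list[tuple[float, float, float, float]] | None = None

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.lighting not in LIGHTING_MODES:
            raise ConfigError(
                f"unknown lighting {self.lighting!r}; expected one of {LIGHTING_MODES}"
            )
        if self.canvas_size[0] < 64 or self.canvas_size[1] < 64:
            raise ConfigError("canvas must be at least 64x64")
        if not 0.0 <= self.occlusion_level <= 1.0:
            raise ConfigError("occlusion_level must lie in [0, 1]")

    @property
    def is_healthy(self) -> bool:
        label = self.class_label.lower()
        return label == "healthy" or label.endswith("health")


def _ellipse_mask(h, w, cy, cx, ay, ax, angle) -> np.ndarray:
    ys, xs = np.mgrid[0:h, 0:w]
    dy, dx = ys - cy, xs - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (dx * ca + dy * sa) / max(ax, 1e-6)
    v = (-dx * sa + dy * ca) / max(ay, 1e-6)
    return u * u + v * v <= 1.0


def _mask_extent(mask: np.ndarray) -> tuple[int, int, int, int] | None:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    if len(rows) == 0:
        return None
    return int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1


def class_palette_color(label: str, index: int | None = None) -> np.ndarray:
    if index is None:
        index = (
            DEFAULT_CLASSES.index(label)
            if label in DEFAULT_CLASSES
            else abs(hash(label))
        )
    return _PALETTE[index % len(_PALETTE)]


def generate_scene(spec: SceneSpec) -> LabeledImage:
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas_size
    # soil-toned noise background
    img = np.empty((h, w, 3), dtype=np.float64)
    soil = np.array([110.0, 85.0, 60.0]) + rng.normal(0, 8, 3)
    img[:] = soil
    img += rng.normal(0, 12, (h, w, 1))
    img += rng.normal(0, 6, (h, w, 3))

    # leaves: the first is the primary (largest) one carrying the lesions
    leaf_masks = []
    for i in range(max(spec.n_leaves, 1)):
        frac = 0.33 if i == 0 else rng.uniform(0.12, 0.22)
        ax_ = frac * w * rng.uniform(0.85, 1.15)
        ay_ = frac * h * rng.uniform(0.7, 1.0)
        if i == 0:
            cy, cx = h / 2 + rng.uniform(-h * 0.08, h * 0.08), w / 2 + rng.uniform(
                -w * 0.08, w * 0.08
            )
        else:
            cy, cx = rng.uniform(0.15 * h, 0.85 * h), rng.uniform(0.15 * w, 0.85 * w)
        mask = _ellipse_mask(h, w, cy, cx, ay_, ax_, rng.uniform(0, np.pi))
        green = np.array([45.0, 120.0, 50.0]) + rng.normal(0, 12, 3)
        shade = 1.0 + rng.normal(0, 0.08, (h, w, 1))
        img = np.where(mask[:, :, None], green * shade, img)
        leaf_masks.append(mask)
    primary = leaf_masks[0]
    leaf_area = float(primary.sum())

    boxes: list[BoundingBox] = []
    lesion_union = np.zeros((h, w), dtype=bool)
    color = class_palette_color(spec.class_label, spec.class_index)

    if spec.lesion_rects is not None:
        for x1, y1, x2, y2 in spec.lesion_rects:
            mask = np.zeros((h, w), dtype=bool)
            mask[int(y1) : int(y2), int(x1) : int(x2)] = True
            img = _stamp_lesion(img, mask, color, rng)
            lesion_union |= mask
            ext = _mask_extent(mask)
            boxes.append(BoundingBox(spec.class_label, *ext))
    elif not spec.is_healthy:
        lo, hi = STAGE_FRACTIONS[spec.stage]
        n_lesions = int(rng.integers(spec.lesions_per_leaf[0], spec.lesions_per_leaf[1] + 1))
        for _ in range(max(n_lesions, 1)):
            # sample the box-area fraction strictly inside the stage band so
            # pixel quantization cannot push it over a boundary
            frac = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
            aspect = rng.uniform(0.7, 1.4)
            bw = np.sqrt(frac * leaf_area * aspect)
            bh = frac * leaf_area / bw
            bw, bh = min(bw, w * 0.9), min(bh, h * 0.9)
            ys, xs = np.nonzero(primary)
            j = rng.integers(len(xs))
            cx = float(np.clip(xs[j], bw / 2 + 1, w - bw / 2 - 1))
            cy = float(np.clip(ys[j], bh / 2 + 1, h - bh / 2 - 1))
            mask = _ellipse_mask(h, w, cy, cx, bh / 2, bw / 2, 0.0)
            if not mask.any():
                continue
            img = _stamp_lesion(img, mask, color, rng)
            lesion_union |= mask
            ext = _mask_extent(mask)
            boxes.append(BoundingBox(spec.class_label, *ext))

    # occlusion: overdraw a foreground leaf strip across each lesion box and
    # record the exact fraction of lesion pixels it covers
    if spec.occlusion_level > 0 and boxes:
        occluder_color = np.array([30.0, 90.0, 35.0])
        new_boxes = []
        for b in boxes:
            bw = b.xmax - b.xmin
            cover_w = spec.occlusion_level * bw
            occ = np.zeros((h, w), dtype=bool)
            occ[int(b.ymin) : int(b.ymax), int(b.xmin) : int(b.xmin + cover_w)] = True
            lesion_mask = np.zeros((h, w), dtype=bool)
            lesion_mask[int(b.ymin) : int(b.ymax), int(b.xmin) : int(b.xmax)] = True
            lesion_mask &= lesion_union
            covered = float((occ & lesion_mask).sum()) / max(float(lesion_mask.sum()), 1.0)
            img = np.where(
                occ[:, :, None], occluder_color + rng.normal(0, 5, (h, w, 3)), img
            )
            new_boxes.append(
                BoundingBox(
                    b.class_label,
                    b.xmin,
                    b.ymin,
                    b.xmax,
                    b.ymax,
                    occlusion_fraction=covered,
                )
            )
        boxes = new_boxes

    raster = np.clip(img, 0, 255).astype(np.uint8)
    raster = apply_lighting(raster, spec.lighting, spec.seed)
    return LabeledImage(
        image=raster,
        boxes=boxes,
        source_path="",
        meta={"leaf_area": leaf_area, "spec": spec},
    )


def _stamp_lesion(img, mask, color, rng) -> np.ndarray:
    h, w = mask.shape
    texture = 1.0 + rng.normal(0, 0.15, (h, w, 1))
    return np.where(mask[:, :, None], color * texture, img)


def apply_lighting(img: np.ndarray, mode: str, seed: int = 0) -> np.ndarray:
    """Photometric lighting model; geometry (and hence boxes) is untouched."""
    if mode not in LIGHTING_MODES:
        raise ConfigError(f"unknown lighting {mode!r}")
    img = np.asarray(img)
    if mode == "normal":
        return img.copy()
    x = img.astype(np.float64)
    if mode == "low":
        out = x * 0.45
    elif mode == "direct":
        out = x * 1.6 + 15.0
    else:  # reflection: seeded specular highlight blobs
        rng = np.random.default_rng(seed)
        h, w = x.shape[:2]
        out = x * 1.1
        for _ in range(rng.integers(2, 5)):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            r = rng.uniform(0.06, 0.16) * min(h, w)
            ys, xs = np.mgrid[0:h, 0:w]
            blob = np.exp(-(((ys - cy) ** 2 + (xs - cx) ** 2) / (2 * r * r)))
            out += 180.0 * blob[:, :, None]
    return np.clip(out, 0, 255).astype(np.uint8)


def generate_dataset(
    dist: dict[str, int],
    out_dir,
    spec_defaults: dict | None = None,
    seed: int = 0,
    split: str = "train",
    image_format: str = "png",
) -> list[dict]:
    """Write one scene per requested image; returns (and writes) the manifest.

    Per-class counts in the written manifest exactly match ``dist``; every
    image's own seed derives from (seed, class index, item index) so the
    whole dataset is reproducible file-for-file.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    spec_defaults = dict(spec_defaults or {})
    records = []
    for ci, label in enumerate(sorted(dist)):
        count = dist[label]
        if count < 0:
            raise ValueError(f"negative count for class {label!r}")
        for i in range(count):
            img_seed = int(np.random.SeedSequence([seed, ci, i]).generate_state(1)[0] % (2**31))
            spec = SceneSpec(class_label=label, seed=img_seed, class_index=ci, **spec_defaults)
            sample = generate_scene(spec)
            stem = f"{_slug(label)}_{i:05d}"
            img_path = out_dir / f"{stem}.{image_format}"
            xml_path = out_dir / f"{stem}.xml"
            Image.fromarray(sample.image).save(img_path)
            sample.source_path = str(img_path)
            write_voc(xml_path, sample, image_path=str(img_path))
            records.append(
                {
                    "path": str(img_path),
                    "annotation": str(xml_path),
                    "class": label,
                    "split": split,
                    "seed": img_seed,
                    "augmented": False,
                }
            )
    write_manifest(out_dir / "manifest.jsonl", records)
    return records


def _slug(label: str) -> str:
    return "".join(ch if ch.isalnum() else "-" for ch in label.lower()).strip("-")
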