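"""Class-balanced offline augmentation and online Mosaic composition.

Offline balancing works in two passes: every image of a minority class is
augmented ``ceil(target/n) - 1`` times (one randomly chosen transform per
copy from a pool of seven box-aware transforms), overshooting the target,
and the surplus is then removed by randomly deleting *augmented* copies
only, so every class ends at exactly the target count.

Geometric transforms move boxes through the same map as the pixels and drop
boxes whose surviving (clipped) area falls below 15% of the transformed
area — the same visibility threshold the annotation filter uses.
Photometric transforms never touch geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import transform as sktransform

from .voc import BoundingBox, LabeledImage, write_voc

TRANSFORMS = (
    "flip",
    "rotate",
    "border_expand",
    "gamma",
    "contrast_stretch",
    "brightness",
    "gaussian_blur",
)
GEOMETRIC = {"flip", "hflip", "vflip", "rotate", "border_expand"}
MIN_VISIBLE_FRACTION = 0.15

DEFAULT_PARAM_RANGES = {
    "rotate_deg": (-30.0, 30.0),
    "pad_frac": (0.03, 0.12),
    "gamma": (0.6, 1.5),
    "contrast_percentiles": (2.0, 98.0),
    "brightness": (0.8, 1.4),
    "blur_sigma": (0.5, 1.5),
}


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

@dataclass
class AugmentationPlan:
    target_count: int
    copies_per_image: dict[str, int]
    delete_after: dict[str, int]

    def check(self, dist: dict[str, int]) -> None:
        for label, n in dist.items():
            total = n * (1 + self.copies_per_image[label]) - self.delete_after[label]
            if total != self.target_count:
                raise ValueError(f"plan inconsistent for class {label!r}: {total}")


def plan_offline_augmentation(
    dist: dict[str, int], target_count: int | str = "max-class"
) -> AugmentationPlan:
    """Per-class copy counts and post-hoc deletions that equalize all classes.

    ``copies = ceil(target/n) - 1`` augmented copies per original image, then
    ``n*(1+copies) - target`` random augmented images are deleted.
    """
    if any(n <= 0 for n in dist.values()):
        raise ValueError("all class counts must be positive")
    if target_count == "max-class":
        target_count = max(dist.values())
    target = int(target_count)
    if target < max(dist.values()):
        raise ValueError(
            f"target {target} below the largest class ({max(dist.values())}); "
            "originals are never deleted"
        )
    copies = {label: math.ceil(target / n) - 1 for label, n in dist.items()}
    delete = {label: n * (1 + copies[label]) - target for label, n in dist.items()}
    plan = AugmentationPlan(target, copies, delete)
    plan.check(dist)
    return plan


# ---------------------------------------------------------------------------
# geometric transforms
# ---------------------------------------------------------------------------

def _map_boxes_affine(boxes, fn, width, height, min_visible=MIN_VISIBLE_FRACTION):
    """Push box corners through a point map, re-extent, clip, drop fragments."""
    out = []
    for b in boxes:
        corners = np.array(
            [
                [b.xmin, b.ymin],
                [b.xmax, b.ymin],
                [b.xmin, b.ymax],
                [b.xmax, b.ymax],
            ]
        )
        mapped = np.array([fn(x, y) for x, y in corners])
        x1, y1 = mapped.min(axis=0)
        x2, y2 = mapped.max(axis=0)
        full = (x2 - x1) * (y2 - y1)
        cx1, cy1 = max(x1, 0.0), max(y1, 0.0)
        cx2, cy2 = min(x2, float(width)), min(y2, float(height))
        if cx2 <= cx1 or cy2 <= cy1:
            continue
        if (cx2 - cx1) * (cy2 - cy1) < min_visible * full:
            continue
        out.append(
            BoundingBox(
                b.class_label, cx1, cy1, cx2, cy2,
                occlusion_fraction=b.occlusion_fraction, difficult=b.difficult,
            )
        )
    return out


def apply_geometric(
    sample: LabeledImage,
    op: str,
    seed: int = 0,
    angle: float | None = None,
    pad: int | None = None,
    param_ranges: dict | None = None,
) -> LabeledImage:
    """One of {hflip, vflip, flip, rotate, border_expand}, pixel/box consistent."""
    rng = np.random.default_rng(seed)
    ranges = {**DEFAULT_PARAM_RANGES, **(param_ranges or {})}
    h, w = sample.image.shape[:2]
    if op == "flip":
        op = "hflip" if rng.random() < 0.5 else "vflip"
    if op == "hflip":
        img = sample.image[:, ::-1].copy()
        boxes = _map_boxes_affine(sample.boxes, lambda x, y: (w - x, y), w, h)
    elif op == "vflip":
        img = sample.image[::-1].copy()
        boxes = _map_boxes_affine(sample.boxes, lambda x, y: (x, h - y), w, h)
    elif op == "rotate":
        if angle is None:
            angle = float(rng.uniform(*ranges["rotate_deg"]))
        img = (
            sktransform.rotate(
                sample.image.astype(np.float64) / 255.0, angle, preserve_range=True
            )
            * 255.0
        ).astype(np.uint8)
        theta = math.radians(angle)
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        ca, sa = math.cos(theta), math.sin(theta)

        def rot(x, y):
            # image-coordinate (y down) counter-clockwise rotation about center
            dx, dy = x - cx, y - cy
            return cx + ca * dx + sa * dy, cy - sa * dx + ca * dy

        boxes = _map_boxes_affine(sample.boxes, rot, w, h)
    elif op == "border_expand":
        if pad is None:
            pad = int(rng.uniform(*ranges["pad_frac"]) * min(h, w))
        if pad < 0:
            raise ValueError("pad must be non-negative")
        img = np.pad(sample.image, ((pad, pad), (pad, pad), (0, 0)), mode="edge")
        boxes = _map_boxes_affine(
            sample.boxes, lambda x, y: (x + pad, y + pad), w + 2 * pad, h + 2 * pad
        )
    else:
        raise ValueError(f"unknown geometric op {op!r}")
    return LabeledImage(image=img, boxes=boxes, source_path=sample.source_path)


# ---------------------------------------------------------------------------
# photometric transforms
# ---------------------------------------------------------------------------

def apply_photometric(
    sample: LabeledImage,
    op: str,
    seed: int = 0,
    param_ranges: dict | None = None,
    **params,
) -> LabeledImage:
    """Gamma / contrast-stretch / brightness / Gaussian blur; boxes untouched."""
    rng = np.random.default_rng(seed)
    ranges = {**DEFAULT_PARAM_RANGES, **(param_ranges or {})}
    x = sample.image.astype(np.float64)
    if op == "gamma":
        g = params.get("gamma", float(rng.uniform(*ranges["gamma"])))
        out = 255.0 * (x / 255.0) ** g
    elif op == "contrast_stretch":
        lo_p, hi_p = params.get("percentiles", ranges["contrast_percentiles"])
        lo, hi = np.percentile(x, [lo_p, hi_p])
        out = (x - lo) / max(hi - lo, 1e-6) * 255.0
    elif op == "brightness":
        f = params.get("factor", float(rng.uniform(*ranges["brightness"])))
        out = x * f
    elif op == "gaussian_blur":
        sigma = params.get("sigma", float(rng.uniform(*ranges["blur_sigma"])))
        out = ndimage.gaussian_filter(x, sigma=(sigma, sigma, 0))
    else:
        raise ValueError(f"unknown photometric op {op!r}")
    img = np.clip(out, 0, 255).astype(np.uint8)
    return LabeledImage(
        image=img, boxes=list(sample.boxes), source_path=sample.source_path
    )


def apply_random_transform(sample: LabeledImage, seed: int) -> LabeledImage:
    """One transform drawn uniformly from the seven-op pool."""
    rng = np.random.default_rng(seed)
    op = TRANSFORMS[rng.integers(len(TRANSFORMS))]
    sub = int(rng.integers(2**31))
    if op in GEOMETRIC:
        return apply_geometric(sample, op, seed=sub)
    return apply_photometric(sample, op, seed=sub)


# ---------------------------------------------------------------------------
# mosaic
# ---------------------------------------------------------------------------

def _nearest_resize(img: np.ndarray, crop, out_h: int, out_w: int):
    """Nearest-neighbour resize of a crop region; returns pixels + the affine
    (sx, tx, sy, ty) mapping source coords to output coords."""
    x0, y0, x1, y1 = crop
    ch, cw = y1 - y0, x1 - x0
    sx, sy = out_w / cw, out_h / ch
    src_x = np.minimum((np.arange(out_w) / sx).astype(int) + x0, x1 - 1)
    src_y = np.minimum((np.arange(out_h) / sy).astype(int) + y0, y1 - 1)
    return img[np.ix_(src_y, src_x)], (sx, -x0 * sx, sy, -y0 * sy)


def mosaic(
    samples: list[LabeledImage],
    out_size: int = 640,
    center_jitter: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
    min_visible: float = MIN_VISIBLE_FRACTION,
) -> LabeledImage:
    """Compose four labeled images into one out_size x out_size scene.

    A seeded center point splits the canvas into four quadrants; each source
    is randomly scale-jittered, cropped and nearest-resized into its
    quadrant.  Boxes follow each region's affine map, get clipped to the
    quadrant, and sub-threshold fragments are dropped.  The per-quadrant
    affine maps are recorded in ``meta['mosaic_transforms']``.
    """
    if len(samples) != 4:
        raise ValueError(f"mosaic requires exactly 4 images, got {len(samples)}")
    rng = np.random.default_rng(seed)
    s = out_size
    cx = int(rng.uniform(*center_jitter) * s)
    cy = int(rng.uniform(*center_jitter) * s)
    quads = [(0, 0, cx, cy), (cx, 0, s, cy), (0, cy, cx, s), (cx, cy, s, s)]
    canvas = np.zeros((s, s, 3), dtype=np.uint8)
    boxes: list[BoundingBox] = []
    transforms = []
    for sample, (qx0, qy0, qx1, qy1) in zip(samples, quads):
        qw, qh = qx1 - qx0, qy1 - qy0
        ih, iw = sample.image.shape[:2]
        zoom = float(rng.uniform(1.0, 1.3))
        cw = max(int(iw / zoom), 2)
        ch = max(int(ih / zoom), 2)
        ox = int(rng.integers(0, iw - cw + 1))
        oy = int(rng.integers(0, ih - ch + 1))
        crop = (ox, oy, ox + cw, oy + ch)
        patch, (sx, tx, sy, ty) = _nearest_resize(sample.image, crop, qh, qw)
        canvas[qy0:qy1, qx0:qx1] = patch
        affine = (sx, tx + qx0, sy, ty + qy0)
        transforms.append({"affine": affine, "quad": (qx0, qy0, qx1, qy1), "crop": crop})
        for b in sample.boxes:
            x1 = sx * b.xmin + affine[1]
            y1 = sy * b.ymin + affine[3]
            x2 = sx * b.xmax + affine[1]
            y2 = sy * b.ymax + affine[3]
            full = (x2 - x1) * (y2 - y1)
            nx1, ny1 = max(x1, qx0), max(y1, qy0)
            nx2, ny2 = min(x2, qx1), min(y2, qy1)
            if nx2 <= nx1 or ny2 <= ny1:
                continue
            if (nx2 - nx1) * (ny2 - ny1) < min_visible * full:
                continue
            boxes.append(
                BoundingBox(
                    b.class_label, nx1, ny1, nx2, ny2,
                    occlusion_fraction=b.occlusion_fraction,
                )
            )
    return LabeledImage(
        image=canvas, boxes=boxes, meta={"mosaic_transforms": transforms}
    )


# ---------------------------------------------------------------------------
# offline pipeline
# ---------------------------------------------------------------------------

def equalize_by_deletion(
    records: list[dict], plan: AugmentationPlan, seed: int = 0
) -> list[dict]:
    """Randomly drop augmented (never original) records down to the target."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_class.setdefault(rec["class"], []).append(i)
    drop: set[int] = set()
    for label, idxs in by_class.items():
        n_del = plan.delete_after.get(label, 0)
        if len(idxs) - n_del != plan.target_count:
            raise ValueError(
                f"class {label!r} has {len(idxs)} records; plan expects "
                f"{plan.target_count + n_del}"
            )
        aug = [i for i in idxs if records[i].get("augmented")]
        if n_del > len(aug):
            raise ValueError(f"class {label!r}: cannot delete {n_del} of {len(aug)} augmented")
        chosen = rng.choice(len(aug), size=n_del, replace=False) if n_del else []
        drop.update(aug[int(j)] for j in chosen)
    return [rec for i, rec in enumerate(records) if i not in drop]


def augment_dataset(
    records: list[dict],
    out_dir,
    target_count: int | str = "max-class",
    seed: int = 0,
) -> list[dict]:
    """Offline pipeline: plan, write augmented copies, equalize by deletion."""
    from .voc import read_voc

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dist: dict[str, int] = {}
    for rec in records:
        dist[rec["class"]] = dist.get(rec["class"], 0) + 1
    plan = plan_offline_augmentation(dist, target_count)
    augmented = list(records)
    for i, rec in enumerate(records):
        n_copies = plan.copies_per_image[rec["class"]]
        if not n_copies:
            continue
        sample = read_voc(rec["annotation"])
        for c in range(n_copies):
            copy_seed = int(np.random.SeedSequence([seed, i, c]).generate_state(1)[0] % (2**31))
            out = apply_random_transform(sample, copy_seed)
            stem = f"{Path(rec['path']).stem}_aug{c}"
            img_path = out_dir / f"{stem}.png"
            xml_path = out_dir / f"{stem}.xml"
            Image.fromarray(out.image).save(img_path)
            write_voc(xml_path, out, image_path=str(img_path))
            augmented.append(
                {
                    **rec,
                    "path": str(img_path),
                    "annotation": str(xml_path),
                    "augmented": True,
                    "seed": copy_seed,
                }
            )
    return equalize_by_deletion(augmented, plan, seed=seed)
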