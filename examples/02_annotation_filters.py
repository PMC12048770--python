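"""Annotation-quality filters used when labeling occluded greenhouse scenes.

Boxes occluded beyond 85% and border boxes retaining under 15% of their
area are not annotated; the filter drops them from a labeled image.
"""

import numpy as np

from vegdet.voc import BoundingBox, LabeledImage, filter_annotations

sample = LabeledImage(
    image=np.zeros((100, 100, 3), dtype=np.uint8),
    boxes=[
        BoundingBox("leaf spot", 10, 10, 30, 30, occlusion_fraction=0.90),
        BoundingBox("leaf spot", 40, 40, 60, 60, occlusion_fraction=0.50),
        BoundingBox("leaf spot", -90, 0, 10, 10),   # 10% visible at the border
        BoundingBox("leaf spot", -5, 60, 45, 90),   # 90% visible at the border
    ],
)
kept = filter_annotations(sample, occlusion_max=0.85, edge_min_area=0.15)
print(f"{len(sample.boxes)} boxes before filtering, {len(kept.boxes)} after:")
for b in kept.boxes:
    print(f"  kept ({b.xmin:.0f},{b.ymin:.0f},{b.xmax:.0f},{b.ymax:.0f}) "
          f"occlusion={b.occlusion_fraction:.2f}")
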