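"""Generate synthetic greenhouse scenes with exact ground-truth boxes.

Builds one scene per disease stage and prints the lesion boxes and the
lesion-to-leaf area fraction each stage produces: early disease is small
isolated spots, late disease covers most of the leaf.
"""

from vegdet.synthetic import SceneSpec, generate_scene

for stage in ("early", "mid", "late"):
    spec = SceneSpec(
        class_label="tomato early blight",
        canvas_size=(256, 256),
        stage=stage,
        seed=7,
    )
    scene = generate_scene(spec)
    print(f"stage={stage}: {len(scene.boxes)} lesion box(es)")
    for b in scene.boxes:
        frac = b.area / scene.meta["leaf_area"]
        print(
            f"  box=({b.xmin:.0f},{b.ymin:.0f},{b.xmax:.0f},{b.ymax:.0f})"
            f"  lesion/leaf area = {frac:.3f}"
        )
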