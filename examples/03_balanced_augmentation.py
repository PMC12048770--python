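"""Class-balanced offline augmentation planning.

With per-class counts spanning 424 to 1344 images, the planner augments
every minority image ceil(target/n)-1 times and then deletes the random
surplus of augmented copies so every class lands exactly on the target.
"""

from vegdet.augment import plan_offline_augmentation

counts = {"pepper black spot": 424, "tomato health": 1344, "cucumber target spot": 704}
plan = plan_offline_augmentation(counts, target_count="max-class")
print(f"target per class: {plan.target_count}")
for label, n in counts.items():
    copies = plan.copies_per_image[label]
    delete = plan.delete_after[label]
    print(
        f"  {label:22s} n={n:5d} -> {copies} augmented copies/image "
        f"({n * (1 + copies)} total), delete {delete} -> {n * (1 + copies) - delete}"
    )
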