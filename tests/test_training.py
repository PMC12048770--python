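"""Transfer-learning contracts: groups, weight transfer, schedule, sampling."""

import numpy as np
import pytest

from vegdet.detector import build_model
from vegdet.training import (
    StageConfig,
    balanced_sample_weights,
    class_loss_weights,
    lr_at_epoch,
    make_param_groups,
    run_stage,
    transfer_weights,
)


class TestParamGroups:
    def test_stage_one_rates(self):
        cfg = StageConfig.stage_defaults("init")
        assert (cfg.lr_backbone, cfg.lr_neck, cfg.lr_head) == (0.0003, 0.001, 0.001)
        model = build_model(3, 0.25)
        groups = {g["name"]: g for g in make_param_groups(model, cfg)}
        assert groups["backbone"]["lr"] == 0.0003
        assert groups["neck"]["lr"] == 0.001
        assert groups["head"]["lr"] == 0.001

    def test_stage_two_rates(self):
        cfg = StageConfig.stage_defaults("diversity")
        assert (cfg.lr_backbone, cfg.lr_neck, cfg.lr_head) == (0.0001, 0.0005, 0.001)

    def test_groups_partition_all_parameters(self):
        model = build_model(3, 0.25)
        groups = make_param_groups(model, StageConfig.stage_defaults("init"))
        grouped = [id(p) for g in groups for p in g["params"]]
        assert len(grouped) == len(set(grouped))
        assert sorted(grouped) == sorted(id(p) for p in model.parameters())

    def test_invalid_stage_rejected(self):
        with pytest.raises(ValueError):
            StageConfig(stage="finetune")


class TestTransferWeights:
    def test_init_stage_copies_backbone_and_neck_only(self):
        src = build_model(3, 0.25, seed=1)
        dst = build_model(3, 0.25, seed=2)
        head_before = {
            k: v.copy() for k, v in dst.state_dict().items() if k.startswith("head.")
        }
        transfer_weights(src, dst, "init")
        src_state, dst_state = src.state_dict(), dst.state_dict()
        for k in src_state:
            if k.startswith(("backbone.", "neck.")):
                np.testing.assert_array_equal(dst_state[k], src_state[k])
        # the head keeps its own fresh initialization (differs from source)
        assert any(
            not np.array_equal(dst_state[k], src_state[k]) for k in head_before
        )
        for k, v in head_before.items():
            np.testing.assert_array_equal(dst_state[k], v)

    def test_diversity_stage_copies_everything(self):
        src = build_model(3, 0.25, seed=1)
        dst = build_model(3, 0.25, seed=2)
        transfer_weights(src, dst, "diversity")
        for k, v in src.state_dict().items():
            np.testing.assert_array_equal(dst.state_dict()[k], v)

    def test_diversity_forward_bitwise_matches_source(self, rng):
        src = build_model(3, 0.25, seed=1)
        dst = build_model(3, 0.25, seed=2)
        transfer_weights(src, dst, "diversity")
        src.eval(), dst.eval()
        x = rng.random((1, 3, 64, 64), dtype=np.float32)
        for a, b in zip(src(x), dst(x)):
            np.testing.assert_array_equal(a.data, b.data)

    def test_backbone_activations_equal_after_init_transfer(self, rng):
        src = build_model(3, 0.25, seed=1)
        dst = build_model(3, 0.25, seed=2)
        transfer_weights(src, dst, "init")
        src.eval(), dst.eval()
        x = rng.random((1, 3, 64, 64), dtype=np.float32)
        from vegdet import nn

        a = src.backbone(nn.Tensor(x))
        b = dst.backbone(nn.Tensor(x))
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.data, fb.data)

    def test_shape_mismatch_names_offending_arrays(self):
        src = build_model(3, 0.25, seed=1)
        dst = build_model(3, 0.5, seed=2)
        with pytest.raises(ValueError, match="backbone"):
            transfer_weights(src, dst, "init")


class TestSchedule:
    def test_decay_value_at_epoch_65(self):
        cfg = StageConfig(stage="init", lr_backbone=0.001, lr_neck=0.001, lr_head=0.001)
        rates = lr_at_epoch(cfg, 65)
        assert rates["head"] == pytest.approx(0.001 * 0.8**2)
        assert rates["head"] == pytest.approx(0.00064)

    def test_warmup_starts_at_tenth_of_base(self):
        cfg = StageConfig.stage_defaults("init")
        rates = lr_at_epoch(cfg, 0)
        assert rates["head"] == pytest.approx(0.1 * cfg.lr_head)
        assert rates["backbone"] == pytest.approx(0.1 * cfg.lr_backbone)
        assert rates["momentum"] == pytest.approx(0.8)

    def test_momentum_reaches_nominal_after_warmup(self):
        cfg = StageConfig.stage_defaults("init")
        assert lr_at_epoch(cfg, 3)["momentum"] == pytest.approx(0.937)

    def test_rates_non_increasing_after_warmup(self):
        cfg = StageConfig.stage_defaults("diversity")
        rates = [lr_at_epoch(cfg, e)["head"] for e in range(3, 200)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(StageConfig.stage_defaults("init"), -1)


class TestBalancing:
    def test_inverse_frequency_image_weights(self):
        w = balanced_sample_weights({"A": 10, "B": 30}, ["A"] * 10 + ["B"] * 30)
        assert w.sum() == pytest.approx(1.0)
        assert w[0] / w[-1] == pytest.approx(3.0)

    def test_equal_counts_give_uniform_weights(self):
        w = balanced_sample_weights({"A": 5, "B": 5}, ["A"] * 5 + ["B"] * 5)
        np.testing.assert_allclose(w, np.full(10, 0.1))

    def test_expected_class_frequency_is_uniform(self):
        dist = {"A": 40, "B": 10, "C": 5}
        labels = ["A"] * 40 + ["B"] * 10 + ["C"] * 5
        w = balanced_sample_weights(dist, labels)
        for label in dist:
            mass = sum(wi for wi, li in zip(w, labels) if li == label)
            assert mass == pytest.approx(1 / 3)

    def test_class_loss_weights_normalized_to_mean_one(self):
        w = class_loss_weights({"A": 10, "B": 30}, ["A", "B"])
        assert w.mean() == pytest.approx(1.0)
        assert w[0] / w[1] == pytest.approx(3.0)

    def test_zero_count_class_rejected(self):
        with pytest.raises(ValueError):
            class_loss_weights({"A": 0}, ["A"])


class TestRunStage:
    @staticmethod
    def tiny_cfg(**kw):
        base = dict(
            stage="init",
            lr_backbone=0.002,
            lr_neck=0.002,
            lr_head=0.002,
            epochs=2,
            batch_size=4,
            input_size=64,
            seed=3,
            warmup_epochs=0,
        )
        base.update(kw)
        return StageConfig(**base)

    def test_same_seed_gives_identical_loss_trajectories(self, small_dataset):
        classes = ["tomato early blight", "cucumber downy mildew"]
        logs = []
        for _ in range(2):
            model = build_model(len(classes), 0.25, seed=5)
            _, log = run_stage(
                model, self.tiny_cfg(), small_dataset, small_dataset[:4], classes
            )
            logs.append([(e["box_loss"], e["cls_loss"], e["obj_loss"]) for e in log])
        assert logs[0] == logs[1]

    def test_dataset_scope_restricts_training_classes(self, small_dataset):
        classes = ["tomato early blight", "cucumber downy mildew"]
        model = build_model(len(classes), 0.25, seed=5)
        cfg = self.tiny_cfg(epochs=1, dataset_scope=["tomato early blight"])
        _, log = run_stage(model, cfg, small_dataset, small_dataset[:4], classes)
        assert len(log) == 1

    def test_empty_manifest_rejected(self, small_dataset):
        model = build_model(2, 0.25)
        with pytest.raises(ValueError):
            run_stage(model, self.tiny_cfg(), [], small_dataset, ["a", "b"])


class TestBalancedSamplingEffect:
    """On a 10:1 two-class task, balanced sampling must shrink the
    majority-minus-minority recall gap relative to plain sampling at equal
    step budgets (seeded, averaged over three seeds)."""

    @staticmethod
    def recall_gap(seed: int, balanced: bool) -> float:
        import tempfile
        from pathlib import Path

        from vegdet.synthetic import generate_dataset
        from vegdet.training import evaluate_model, load_training_samples

        classes = ["tomato early blight", "cucumber downy mildew"]
        with tempfile.TemporaryDirectory() as td:
            sd = {"canvas_size": (96, 96), "n_leaves": 2, "stage": "late"}
            train = generate_dataset(
                {classes[0]: 40, classes[1]: 4}, Path(td) / "tr",
                spec_defaults=sd, seed=seed,
            )
            val = generate_dataset(
                {classes[0]: 15, classes[1]: 15}, Path(td) / "va",
                spec_defaults=sd, seed=seed + 100, split="val",
            )
            model = build_model(len(classes), 0.25, seed=seed)
            cfg = StageConfig(
                stage="init",
                lr_backbone=0.002, lr_neck=0.002, lr_head=0.002,
                epochs=10, batch_size=8, input_size=96, seed=seed,
                warmup_epochs=1,
                use_balanced_sampling=balanced, use_class_weights=balanced,
            )
            model, _ = run_stage(model, cfg, train, val, classes)
            res = evaluate_model(
                model, load_training_samples(val, classes, 96), classes
            )[0]
            return res.per_class[classes[0]].recall - res.per_class[classes[1]].recall

    def test_balanced_sampling_shrinks_recall_gap(self):
        seeds = (0, 1, 2)
        unbalanced = np.mean([self.recall_gap(s, False) for s in seeds])
        balanced = np.mean([self.recall_gap(s, True) for s in seeds])
        assert balanced < unbalanced - 0.1
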