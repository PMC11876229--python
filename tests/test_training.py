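"""Training loops: determinism, degenerate configs, protocol enforcement."""

import numpy as np
import pandas as pd
import pytest

from mammojig.jigsaw import GridSpec, PermutationSet
from mammojig.models import EncoderSpec, build_cfn, build_classifier
from mammojig.training import (PipelineArm, ProtocolError, StudyData, TrainConfig,
                               evaluate_jigsaw_accuracy, pretrain_rotation,
                               run_arm, score_images, standard_arms,
                               train_classifier, train_jigsaw)
from mammojig.evaluation import SplitPlan, grouped_kfold

TINY = EncoderSpec(name="tiny_cnn", feature_dim=8, input_pool=2)
GRID_SMALL = GridSpec(image_size=96, grid=3, cell_size=32, patch_size=28)


@pytest.fixture(scope="module")
def tiny_images():
    """Small (96 px) phantom crops: structured enough that the tiny
    pretext task is learnable, cheap enough for per-test training."""
    from mammojig.synthetic import SyntheticConfig, generate_record

    cfg = SyntheticConfig(n_patients=10, seed=55, image_size=96,
                          exclusion_rates={})
    return [generate_record(cfg, i)[0].astype(float) for i in range(12)]


@pytest.fixture(scope="module")
def tiny_permset():
    return PermutationSet(permutations=[tuple(range(9)), (4, 5, 3, 7, 8, 6, 1, 2, 0)])


class TestTrainConfig:
    def test_task_specific_defaults(self):
        assert TrainConfig.jigsaw().batch_size == 128
        assert TrainConfig.finetune().batch_size == 64
        assert TrainConfig.jigsaw().learning_rate == 1e-3
        assert TrainConfig.jigsaw().weight_decay == 0.0

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(task="pretrain")
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0)


class TestTrainJigsaw:
    def test_zero_epochs_leaves_parameters_unchanged(self, tiny_images, tiny_permset):
        model = build_cfn(TINY, n_classes=2, seed=0)
        before = [p.value.copy() for p in model.params()]
        model, history = train_jigsaw(
            model, tiny_images, tiny_permset,
            TrainConfig.jigsaw(epochs=0, seed=0), grid=GRID_SMALL)
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)
        assert history["loss"] == []

    def test_seeded_determinism(self, tiny_images, tiny_permset):
        runs = []
        for _ in range(2):
            model = build_cfn(TINY, n_classes=2, seed=1)
            _, history = train_jigsaw(
                model, tiny_images, tiny_permset,
                TrainConfig.jigsaw(epochs=2, batch_size=4, seed=5), grid=GRID_SMALL)
            runs.append(history["loss"])
        assert runs[0] == runs[1]

    def test_loss_decreases_on_overfit_fixture(self, tiny_images, tiny_permset):
        model = build_cfn(TINY, n_classes=2, seed=2)
        _, history = train_jigsaw(
            model, tiny_images[:10], tiny_permset,
            TrainConfig.jigsaw(epochs=15, batch_size=5, seed=0), grid=GRID_SMALL)
        loss = history["loss"]
        assert all(np.isfinite(loss))
        assert np.mean(loss[-3:]) < np.mean(loss[:3])

    def test_empty_images_rejected(self, tiny_permset):
        model = build_cfn(TINY, n_classes=2, seed=0)
        with pytest.raises(ValueError):
            train_jigsaw(model, [], tiny_permset, TrainConfig.jigsaw(epochs=1))


class TestEvaluateJigsawAccuracy:
    def test_constant_model_scores_chance(self, tiny_images, tiny_permset):
        """A model that always answers class 0 is right exactly as often
        as class 0 is drawn: 1/n_classes in expectation."""

        class Constant:
            def forward(self, batch):
                out = np.zeros((len(batch), 2))
                out[:, 0] = 1.0
                return out

        acc = evaluate_jigsaw_accuracy(Constant(), tiny_images, tiny_permset,
                                       n_samples=400, seed=0, grid=GRID_SMALL)
        assert acc == pytest.approx(0.5, abs=0.08)

    def test_same_seed_identical(self, tiny_images, tiny_permset):
        model = build_cfn(TINY, n_classes=2, seed=3)
        a = evaluate_jigsaw_accuracy(model, tiny_images, tiny_permset,
                                     n_samples=50, seed=9, grid=GRID_SMALL)
        b = evaluate_jigsaw_accuracy(model, tiny_images, tiny_permset,
                                     n_samples=50, seed=9, grid=GRID_SMALL)
        assert a == b


class TestTrainClassifier:
    def make_separable(self, n=16):
        rng = np.random.default_rng(4)
        images, labels = [], []
        for i in range(n):
            label = i % 2
            img = rng.normal(0, 1, (40, 40))
            if label:
                img[10:30, 10:30] += 6.0  # bright square: the positive cue
            images.append(img)
            labels.append(label)
        return images, np.array(labels)

    def test_zero_epochs_unchanged(self):
        images, labels = self.make_separable()
        model = build_classifier(TINY, seed=0)
        before = [p.value.copy() for p in model.params()]
        model, _ = train_classifier(model, images, labels,
                                    TrainConfig.finetune(epochs=0))
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_separable_toy_reaches_full_training_auc(self):
        from mammojig.evaluation import roc_auc

        images, labels = self.make_separable()
        model = build_classifier(TINY, seed=1)
        model, history = train_classifier(
            model, images, labels,
            TrainConfig.finetune(epochs=10, batch_size=8, seed=0))
        scores = score_images(model, images)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(1.0, abs=1e-9)
        assert history["loss"][-1] < history["loss"][0]

    def test_single_class_rejected(self):
        images, _ = self.make_separable()
        model = build_classifier(TINY, seed=0)
        with pytest.raises(ValueError):
            train_classifier(model, images, np.zeros(len(images), dtype=int),
                             TrainConfig.finetune(epochs=1))

    def test_seeded_determinism(self):
        images, labels = self.make_separable()
        finals = []
        for _ in range(2):
            model = build_classifier(TINY, seed=2)
            _, history = train_classifier(
                model, images, labels,
                TrainConfig.finetune(epochs=3, batch_size=8, seed=7))
            finals.append(history["loss"][-1])
        assert finals[0] == finals[1]


class TestPipelineArms:
    def test_arm_validation(self):
        with pytest.raises(ValueError):
            PipelineArm("IN", "random", False)
        with pytest.raises(ValueError):
            PipelineArm("Scratch", "file:x.npz", False)
        arms = standard_arms()
        assert [a.name for a in arms] == ["Scratch-Jig", "Scratch"]
        arms4 = standard_arms("w.npz")
        assert [a.name for a in arms4] == ["IN-Jig", "Scratch-Jig", "IN", "Scratch"]

    @pytest.fixture()
    def toy_study(self, tiny_images):
        table = pd.DataFrame({
            "image_id": [f"I{i}" for i in range(12)],
            "patient_id": [f"P{i // 2}" for i in range(12)],
            "cancer": [i % 2 for i in range(12)],
            "finding": ["mass" if i % 2 else "normal" for i in range(12)],
            "density": ["DB"] * 12,
        })
        images = {f"I{i}": tiny_images[i] for i in range(12)}
        return StudyData(images=images, table=table)

    def test_zero_epoch_jig_equals_scratch(self, toy_study, tiny_permset):
        splits = grouped_kfold(toy_study.table.patient_id, k=3, trials=1, seed=0)
        common = dict(
            data=toy_study, permset=tiny_permset,
            cfg_pretext=TrainConfig.jigsaw(epochs=0, seed=3),
            cfg_finetune=TrainConfig.finetune(epochs=2, batch_size=4, seed=3),
            splits=splits, spec=TINY, grid=GRID_SMALL,
        )
        jig = run_arm(PipelineArm("Scratch-Jig", "random", True), **common)
        scratch = run_arm(PipelineArm("Scratch", "random", False), **common)
        pd.testing.assert_frame_equal(
            jig.drop(columns="arm"), scratch.drop(columns="arm"))

    def test_every_image_scored_once_per_trial(self, toy_study, tiny_permset):
        splits = grouped_kfold(toy_study.table.patient_id, k=3, trials=2, seed=1)
        table = run_arm(
            PipelineArm("Scratch", "random", False), toy_study, tiny_permset,
            TrainConfig.jigsaw(epochs=0), TrainConfig.finetune(epochs=1, batch_size=4, seed=0),
            splits, spec=TINY, grid=GRID_SMALL)
        for trial, sub in table.groupby("trial"):
            assert sorted(sub.image_id) == sorted(toy_study.table.image_id)
            assert sub.image_id.is_unique

    def test_unassigned_patient_aborts(self, toy_study, tiny_permset):
        """A split plan that does not cover every patient in the table
        would silently route the orphans into every training split (they
        could pre-train on themselves across folds); the runner refuses."""
        partial = grouped_kfold(
            [p for p in toy_study.table.patient_id if p != "P0"],
            k=3, trials=1, seed=0)
        with pytest.raises(ProtocolError):
            run_arm(
                PipelineArm("Scratch", "random", False), toy_study, tiny_permset,
                TrainConfig.jigsaw(epochs=0),
                TrainConfig.finetune(epochs=1, batch_size=4, seed=0),
                partial, spec=TINY, grid=GRID_SMALL)


class TestRotationPretext:
    def test_writes_loadable_checkpoint(self, tiny_images, tmp_path):
        from mammojig.models import load_encoder

        path = tmp_path / "rot.npz"
        enc = pretrain_rotation(TINY, tiny_images, epochs=1, batch_size=6,
                                seed=0, out_path=path)
        spec, state = load_encoder(path)
        assert spec.name == "tiny_cnn"
        for key, value in enc.state_dict().items():
            np.testing.assert_array_equal(state[key], value)

    def test_in_arm_uses_checkpoint(self, tiny_images, tmp_path):
        path = tmp_path / "rot.npz"
        pretrain_rotation(TINY, tiny_images, epochs=1, batch_size=6, seed=0,
                          out_path=path)
        arm = PipelineArm("IN", f"file:{path}", False)
        clf_spec = EncoderSpec(name="tiny_cnn", feature_dim=8, input_pool=2,
                               init=f"file:{path}")
        clf = build_classifier(clf_spec, seed=5)
        from mammojig.models import load_encoder

        _, state = load_encoder(path)
        for key, value in clf.encoder.state_dict().items():
            np.testing.assert_array_equal(state[key], value)
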