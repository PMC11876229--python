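"""Training loops for the pretext and downstream tasks, and the study arms.

Four pipeline arms are compared, differing only in how the classifier's
encoder is initialized:

* ``IN-Jig``   — externally pre-initialized weights, then jigsaw pretext,
  then fine-tuning;
* ``Scratch-Jig`` — random init, jigsaw pretext, fine-tuning;
* ``IN``       — externally pre-initialized weights, fine-tuning only;
* ``Scratch``  — random init, fine-tuning only.

"Externally pre-initialized" means any weight checkpoint supplied
through ``EncoderSpec.init = "file:..."``; :func:`pretrain_rotation`
produces such a checkpoint from a brief rotation-prediction pretext on
synthetic crops so the four-arm structure can be exercised end to end
without any download.

The patient-grouping protocol is enforced, not advisory: within a fold,
pretext training, fine-tuning and validation see disjoint patient sets,
and any overlap aborts the run with :class:`ProtocolError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .jigsaw import GridSpec, PermutationSet, sample_puzzle
from .models import (ClassifierModel, EncoderSpec, build_cfn, build_classifier,
                     save_encoder, transfer_encoder)

__all__ = [
    "TrainConfig", "PipelineArm", "standard_arms", "TrainingError",
    "ProtocolError", "train_jigsaw", "evaluate_jigsaw_accuracy",
    "train_classifier", "pretrain_rotation", "run_arm", "standardize_image",
]


class TrainingError(RuntimeError):
    """Raised on non-finite loss; carries the epoch index."""

    def __init__(self, message: str, epoch: int):
        super().__init__(f"{message} (epoch {epoch})")
        self.epoch = epoch


class ProtocolError(RuntimeError):
    """Patient-level leakage between training and validation."""


@dataclass
class TrainConfig:
    """Optimization settings (Adam + cross-entropy throughout).

    Reference settings: learning rate 1e-3, weight decay 0, batch size
    128 for the jigsaw pretext / 64 for fine-tuning, 100 epochs; the
    epoch count scales down for desk-scale runs.
    """

    task: str = "finetune"
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("jigsaw", "finetune"):
            raise ValueError("task must be 'jigsaw' or 'finetune'")
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("learning_rate/batch_size must be positive, epochs >= 0")

    @classmethod
    def jigsaw(cls, **kw) -> "TrainConfig":
        kw.setdefault("batch_size", 128)
        return cls(task="jigsaw", **kw)

    @classmethod
    def finetune(cls, **kw) -> "TrainConfig":
        kw.setdefault("batch_size", 64)
        return cls(task="finetune", **kw)


@dataclass(frozen=True)
class PipelineArm:
    """One pre-training pipeline of the four-arm comparison."""

    name: str
    encoder_init: str  # "random" or "file:<path>"
    jigsaw_pretraining: bool

    def __post_init__(self) -> None:
        if self.name in ("IN-Jig", "IN") and not self.encoder_init.startswith("file:"):
            raise ValueError(f"arm {self.name} requires encoder_init='file:<path>'")
        if self.name in ("Scratch-Jig", "Scratch") and self.encoder_init != "random":
            raise ValueError(f"arm {self.name} requires encoder_init='random'")


def standard_arms(weights_path: str | None = None) -> list[PipelineArm]:
    """The four study arms. ``weights_path`` supplies the pre-initialized
    encoder checkpoint for the IN-Jig / IN arms; without it only the two
    scratch arms are returned."""
    arms = [
        PipelineArm("Scratch-Jig", "random", True),
        PipelineArm("Scratch", "random", False),
    ]
    if weights_path is not None:
        arms = [
            PipelineArm("IN-Jig", f"file:{weights_path}", True),
            arms[0],
            PipelineArm("IN", f"file:{weights_path}", False),
            arms[1],
        ]
    return arms


def standardize_image(image: np.ndarray) -> np.ndarray:
    """Whole-image zero-mean/unit-variance scaling used for the
    classification input (constant image maps to zeros)."""
    img = np.asarray(image, dtype=np.float64)
    sd = img.std()
    return np.zeros_like(img) if sd == 0 else (img - img.mean()) / sd


# ---------------------------------------------------------------------------
# Jigsaw pretext
# ---------------------------------------------------------------------------

def _puzzle_batch(images: list[np.ndarray], idxs: np.ndarray,
                  labels: np.ndarray, seeds: np.ndarray,
                  permset: PermutationSet, grid: GridSpec) -> np.ndarray:
    return np.stack([
        sample_puzzle(images[i], int(lab), permset, grid, seed=int(s)).patches
        for i, lab, s in zip(idxs, labels, seeds)
    ])


def train_jigsaw(model, images: list[np.ndarray], permset: PermutationSet,
                 cfg: TrainConfig, grid: GridSpec | None = None):
    """Train the CFN to recognise which permutation scrambled the patches.

    Every optimisation step draws images (each epoch visits each image
    once, shuffled), a uniform permutation label per image and a fresh
    jitter seed, so the gaps are re-randomized continually. Returns the
    trained model and a history with per-epoch mean loss and accuracy.
    """
    if len(images) == 0:
        raise ValueError("no images for jigsaw pretraining")
    if cfg.task != "jigsaw":
        raise ValueError("config task must be 'jigsaw'")
    grid = grid or GridSpec()
    history = {"loss": [], "accuracy": []}
    if cfg.epochs == 0:
        return model, history
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 11])
    opt = nn.Adam(model.params(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)
    n_classes = len(permset)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(images))
        losses, correct, seen = [], 0, 0
        for start in range(0, len(order), cfg.batch_size):
            idxs = order[start:start + cfg.batch_size]
            labels = rng.integers(0, n_classes, len(idxs))
            seeds = rng.integers(0, 2 ** 31 - 1, len(idxs))
            batch = _puzzle_batch(images, idxs, labels, seeds, permset, grid)
            logits = model.forward(batch)
            loss, grad = nn.softmax_cross_entropy(logits, labels)
            if not np.isfinite(loss):
                raise TrainingError("non-finite jigsaw loss", epoch)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
            correct += int(np.sum(np.argmax(logits, axis=1) == labels))
            seen += len(idxs)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / seen)
    return model, history


def evaluate_jigsaw_accuracy(model, images: list[np.ndarray],
                             permset: PermutationSet, n_samples: int = 200,
                             seed: int = 0, grid: GridSpec | None = None,
                             batch_size: int = 64) -> float:
    """Fraction of freshly sampled puzzles whose argmax logit is the true
    permutation label; fully seeded."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    grid = grid or GridSpec()
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 13])
    idxs = rng.integers(0, len(images), n_samples)
    labels = rng.integers(0, len(permset), n_samples)
    seeds = rng.integers(0, 2 ** 31 - 1, n_samples)
    correct = 0
    for start in range(0, n_samples, batch_size):
        sl = slice(start, start + batch_size)
        batch = _puzzle_batch(images, idxs[sl], labels[sl], seeds[sl], permset, grid)
        logits = model.forward(batch)
        correct += int(np.sum(np.argmax(logits, axis=1) == labels[sl]))
    return correct / n_samples


# ---------------------------------------------------------------------------
# Downstream fine-tuning
# ---------------------------------------------------------------------------

def train_classifier(model: ClassifierModel, images: list[np.ndarray],
                     labels: np.ndarray, cfg: TrainConfig):
    """Binary cross-entropy fine-tuning on the cancer label.

    Images are standardized whole-image before the encoder. Returns the
    trained model and per-epoch history (mean loss, accuracy at 0.5).
    """
    labels = np.asarray(labels, dtype=int)
    if len(images) != len(labels):
        raise ValueError("images and labels length mismatch")
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present in training data")
    if cfg.task != "finetune":
        raise ValueError("config task must be 'finetune'")
    history = {"loss": [], "accuracy": []}
    if cfg.epochs == 0:
        return model, history
    std = np.stack([standardize_image(im) for im in images])
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 17])
    opt = nn.Adam(model.params(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(std))
        losses, correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            idxs = order[start:start + cfg.batch_size]
            logits = model.forward(std[idxs])
            loss, grad = nn.bce_with_logits(logits, labels[idxs])
            if not np.isfinite(loss):
                raise TrainingError("non-finite classification loss", epoch)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
            correct += int(np.sum((logits >= 0) == (labels[idxs] == 1)))
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / len(order))
    return model, history


def score_images(model: ClassifierModel, images: list[np.ndarray],
                 batch_size: int = 64) -> np.ndarray:
    std = np.stack([standardize_image(im) for im in images])
    return model.predict_scores(std, batch_size=batch_size)


# ---------------------------------------------------------------------------
# Stand-in pre-initialized weights (rotation pretext)
# ---------------------------------------------------------------------------

def pretrain_rotation(spec: EncoderSpec, images: list[np.ndarray],
                      epochs: int = 5, batch_size: int = 32,
                      learning_rate: float = 1e-3, seed: int = 0,
                      out_path: str | None = None):
    """Brief 4-way rotation-prediction pretext producing an encoder
    checkpoint usable as the pre-initialized weights of the IN-Jig / IN
    arms. A lightweight self-supervised warm start, not a claim of
    equivalence to large-scale natural-image pretraining."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 19])
    enc_spec = EncoderSpec(name=spec.name, feature_dim=spec.feature_dim,
                           input_channels=spec.input_channels,
                           input_pool=spec.input_pool)
    model = build_classifier(enc_spec, seed=seed)
    head = nn.Linear(spec.feature_dim, 4, rng=np.random.default_rng([seed, 23]))
    opt = nn.Adam(model.encoder.params() + head.params(), lr=learning_rate)
    std = np.stack([standardize_image(im) for im in images])
    for _ in range(epochs):
        order = rng.permutation(len(std))
        for start in range(0, len(order), batch_size):
            idxs = order[start:start + batch_size]
            ks = rng.integers(0, 4, len(idxs))
            batch = np.stack([np.rot90(std[i], k=int(k)) for i, k in zip(idxs, ks)])
            feats = model.encoder.forward(batch[:, None, :, :])
            logits = head.forward(feats)
            loss, grad = nn.softmax_cross_entropy(logits, ks)
            if not np.isfinite(loss):
                raise TrainingError("non-finite rotation loss", 0)
            opt.zero_grad()
            model.encoder.backward(head.backward(grad))
            opt.step()
    if out_path is not None:
        save_encoder(out_path, enc_spec, model.encoder)
    return model.encoder


# ---------------------------------------------------------------------------
# The study arms
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """In-memory dataset for the arm runner: per-image arrays keyed by
    image id plus the metadata table."""

    images: dict[str, np.ndarray]
    table: pd.DataFrame  # image_id, patient_id, cancer, finding, density

    def __post_init__(self) -> None:
        missing = set(self.table.image_id) - set(self.images)
        if missing:
            raise ValueError(f"missing image arrays for {sorted(missing)[:5]}")


def run_arm(arm: PipelineArm, data: StudyData, permset: PermutationSet,
            cfg_pretext: TrainConfig, cfg_finetune: TrainConfig,
            splits, spec: EncoderSpec | None = None,
            grid: GridSpec | None = None,
            trials: list[int] | None = None,
            folds: list[int] | None = None) -> pd.DataFrame:
    """Run one pipeline arm through patient-grouped cross-validation.

    Per fold: (optionally) jigsaw-pretrain on that fold's *training*
    images only, transfer the encoder, fine-tune on the training images,
    then score the validation images. Validation patients are never seen
    by either training stage; any overlap raises :class:`ProtocolError`.
    Returns one row per scored image with trial and fold indices.
    """
    spec = spec or EncoderSpec()
    base_spec = spec
    if arm.encoder_init.startswith("file:"):
        base_spec = EncoderSpec(
            name=spec.name, feature_dim=spec.feature_dim,
            input_channels=spec.input_channels, init=arm.encoder_init,
            input_pool=spec.input_pool,
        )
    rows = []
    trial_list = trials if trials is not None else list(range(splits.trials))
    fold_list = folds if folds is not None else list(range(splits.k))
    for trial in trial_list:
        unknown = set(data.table.patient_id) - splits.patients(trial)
        if unknown:
            raise ProtocolError(
                "patients without a fold assignment would silently join every "
                f"training split: {sorted(unknown)[:5]}"
            )
        for fold in fold_list:
            val_patients = splits.patients_in_fold(trial, fold)
            tab = data.table
            is_val = tab.patient_id.isin(val_patients)
            train_tab, val_tab = tab[~is_val], tab[is_val]
            overlap = set(train_tab.patient_id) & set(val_tab.patient_id)
            if overlap:
                raise ProtocolError(f"patients in both splits: {sorted(overlap)[:5]}")
            if len(val_tab) == 0 or len(train_tab) == 0:
                continue
            train_images = [data.images[i] for i in train_tab.image_id]
            arm_seed = (cfg_finetune.seed * 1009 + trial * 101 + fold) & 0x7FFFFFFF

            if arm.jigsaw_pretraining:
                cfn = build_cfn(base_spec, n_classes=len(permset), seed=arm_seed)
                pre_cfg = TrainConfig(
                    task="jigsaw", learning_rate=cfg_pretext.learning_rate,
                    weight_decay=cfg_pretext.weight_decay,
                    batch_size=cfg_pretext.batch_size,
                    epochs=cfg_pretext.epochs, seed=arm_seed,
                )
                cfn, _ = train_jigsaw(cfn, train_images, permset, pre_cfg, grid=grid)
                clf = build_classifier(base_spec, seed=arm_seed)
                transfer_encoder(cfn, clf)
            else:
                clf = build_classifier(base_spec, seed=arm_seed)

            fit_cfg = TrainConfig(
                task="finetune", learning_rate=cfg_finetune.learning_rate,
                weight_decay=cfg_finetune.weight_decay,
                batch_size=cfg_finetune.batch_size,
                epochs=cfg_finetune.epochs, seed=arm_seed,
            )
            clf, _ = train_classifier(
                clf, train_images, train_tab.cancer.to_numpy(int), fit_cfg
            )
            val_images = [data.images[i] for i in val_tab.image_id]
            scores = score_images(clf, val_images)
            for rec, score in zip(val_tab.itertuples(), scores):
                rows.append({
                    "image_id": rec.image_id, "patient_id": rec.patient_id,
                    "trial": trial, "fold": fold, "score": float(score),
                    "label": int(rec.cancer), "finding": rec.finding,
                    "density": rec.density, "arm": arm.name,
                })
    return pd.DataFrame(rows)
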