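"""Architecture contracts: shared-weight CFN and the downstream classifier.

The context-free network (CFN) applies one encoder — a single shared
parameter set — to each of the 9 puzzle patches independently, projects
each patch's pooled features, concatenates the projections in slot
order and classifies the permutation with a fully connected head. The
downstream classifier reuses the *same* encoder architecture on the full
512x512 crop (global average pooling makes the encoder input-size
agnostic, which is what makes the weights transferable between the
150x150-patch pretext and the 512x512 fine-tuning input) and ends in a
single cancer logit.

Encoders are built from an :class:`EncoderSpec` through a registry; the
package ships small CPU-friendly CNNs. Each encoder starts with a fixed
average-pooling downsampling stage so that desk-scale training remains
fast at native crop resolution; the convolutional trunk then operates on
the pooled map. Weight checkpoints are ``.npz`` files embedding the spec
for compatibility checking.

Initialization is split into independent streams (encoder from
``[seed, 0]``, heads from ``[seed, 1]``) so that a CFN and a classifier
built from the same seed start from the *same* encoder parameters — the
property that makes "jigsaw pretraining with 0 epochs" exactly
equivalent to training from scratch.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "EncoderSpec", "CFNModel", "ClassifierModel",
    "build_cfn", "build_classifier", "transfer_encoder",
    "save_encoder", "load_encoder",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Declarative description of the patch/image encoder.

    ``init`` is either ``"random"`` or ``"file:<path>"`` pointing at a
    checkpoint written by :func:`save_encoder` (used for the arms that
    start from externally pre-initialized weights). ``input_pool`` is the
    fixed downsampling factor of the input stage.
    """

    name: str = "small_cnn"
    feature_dim: int = 32
    input_channels: int = 1
    init: str = "random"
    input_pool: int = 8

    def __post_init__(self) -> None:
        if self.name not in _ENCODERS:
            raise ValueError(
                f"unknown encoder {self.name!r}; available: {sorted(_ENCODERS)}"
            )
        if self.input_channels not in (1, 3):
            raise ValueError("input_channels must be 1 or 3")
        if not (self.init == "random" or self.init.startswith("file:")):
            raise ValueError("init must be 'random' or 'file:<path>'")


def _build_small_cnn(spec: EncoderSpec, rng: np.random.Generator) -> nn.Sequential:
    c = spec.input_channels
    f = spec.feature_dim
    return nn.Sequential([
        nn.AvgPool2d(spec.input_pool),
        nn.Conv2d(c, 8, 3, pad=1, rng=rng), nn.ReLU(), nn.AvgPool2d(2),
        nn.Conv2d(8, 16, 3, pad=1, rng=rng), nn.ReLU(), nn.AvgPool2d(2),
        nn.Conv2d(16, f, 3, pad=1, rng=rng), nn.ReLU(),
        nn.GlobalAvgPool(), nn.FeatureNorm(),
    ])


def _build_tiny_cnn(spec: EncoderSpec, rng: np.random.Generator) -> nn.Sequential:
    c = spec.input_channels
    f = spec.feature_dim
    return nn.Sequential([
        nn.AvgPool2d(spec.input_pool),
        nn.Conv2d(c, 8, 3, pad=1, rng=rng), nn.ReLU(), nn.AvgPool2d(2),
        nn.Conv2d(8, f, 3, pad=1, rng=rng), nn.ReLU(),
        nn.GlobalAvgPool(), nn.FeatureNorm(),
    ])


_ENCODERS = {
    "small_cnn": _build_small_cnn,
    "tiny_cnn": _build_tiny_cnn,
}


def _build_encoder(spec: EncoderSpec, seed: int) -> nn.Sequential:
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0])
    enc = _ENCODERS[spec.name](spec, rng)
    if spec.init.startswith("file:"):
        path = spec.init[len("file:"):]
        file_spec, state = load_encoder(path)
        if (file_spec.name, file_spec.feature_dim, file_spec.input_channels) != (
            spec.name, spec.feature_dim, spec.input_channels
        ):
            raise ValueError(
                f"checkpoint encoder {file_spec} incompatible with spec {spec}"
            )
        enc.load_state_dict(state)
    return enc


def _head_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, 1])


def _prep_batch(images: np.ndarray, channels: int) -> np.ndarray:
    """(N, H, W) or (N, C, H, W) float batch with the declared channels."""
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None, :, :]
    if x.shape[1] != channels:
        if x.shape[1] == 1 and channels == 3:
            x = np.repeat(x, 3, axis=1)
        else:
            raise ValueError(f"expected {channels} channels, got {x.shape[1]}")
    return x


class CFNModel:
    """Shared-encoder permutation classifier (9 patches -> n_classes logits)."""

    def __init__(self, spec: EncoderSpec, n_classes: int = 31,
                 n_patches: int = 9, proj_dim: int = 32, seed: int = 0):
        self.spec = spec
        self.n_classes = n_classes
        self.n_patches = n_patches
        self.proj_dim = proj_dim
        self.encoder = _build_encoder(spec, seed)
        hrng = _head_rng(seed)
        self.proj = nn.Linear(spec.feature_dim, proj_dim, rng=hrng)
        self.proj_act = nn.ReLU()
        self.head = nn.Linear(n_patches * proj_dim, n_classes, rng=hrng)

    def params(self) -> list[nn.Param]:
        return self.encoder.params() + self.proj.params() + self.head.params()

    def patch_features(self, patches: np.ndarray) -> np.ndarray:
        """Per-patch encoder features, shape (N, n_patches, feature_dim)."""
        n, p = patches.shape[:2]
        flat = patches.reshape(n * p, *patches.shape[2:])
        feats = self.encoder.forward(_prep_batch(flat, self.spec.input_channels))
        return feats.reshape(n, p, -1)

    def forward(self, patches: np.ndarray) -> np.ndarray:
        """``patches``: (N, n_patches, H, W) -> logits (N, n_classes)."""
        n, p = patches.shape[:2]
        if p != self.n_patches:
            raise ValueError(f"expected {self.n_patches} patches, got {p}")
        flat = patches.reshape(n * p, *patches.shape[2:])
        feats = self.encoder.forward(_prep_batch(flat, self.spec.input_channels))
        proj = self.proj_act.forward(self.proj.forward(feats))
        concat = proj.reshape(n, p * self.proj_dim)
        return self.head.forward(concat)

    def backward(self, dlogits: np.ndarray) -> None:
        n = dlogits.shape[0]
        dconcat = self.head.backward(dlogits)
        dproj = self.proj_act.backward(dconcat.reshape(n * self.n_patches, self.proj_dim))
        dfeat = self.proj.backward(dproj)
        self.encoder.backward(dfeat)


class ClassifierModel:
    """Single-stream binary classifier: full crop -> one cancer logit."""

    def __init__(self, spec: EncoderSpec, seed: int = 0):
        self.spec = spec
        self.encoder = _build_encoder(spec, seed)
        self.head = nn.Linear(spec.feature_dim, 1, rng=_head_rng(seed))

    def params(self) -> list[nn.Param]:
        return self.encoder.params() + self.head.params()

    def forward(self, images: np.ndarray, keep_activations: bool = False
                ) -> np.ndarray:
        x = _prep_batch(images, self.spec.input_channels)
        feats = self.encoder.forward(x, keep_activations=keep_activations)
        return self.head.forward(feats)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits[:, None])
        self.encoder.backward(dfeat)

    def predict_scores(self, images: np.ndarray, batch_size: int = 64
                       ) -> np.ndarray:
        """Logistic probabilities, order-preserving, no gradient bookkeeping."""
        images = np.asarray(images, dtype=np.float64)
        out = []
        for i in range(0, len(images), batch_size):
            out.append(nn.sigmoid(self.forward(images[i:i + batch_size])))
        return np.concatenate(out)


def build_cfn(spec: EncoderSpec, n_classes: int = 31, seed: int = 0,
              proj_dim: int = 32) -> CFNModel:
    """CFN for permutation classification (one logit per permutation class)."""
    return CFNModel(spec, n_classes=n_classes, seed=seed, proj_dim=proj_dim)


def build_classifier(spec: EncoderSpec, seed: int = 0) -> ClassifierModel:
    return ClassifierModel(spec, seed=seed)


def transfer_encoder(source: CFNModel | str | Path, target: ClassifierModel,
                     head_seed: int | None = None) -> ClassifierModel:
    """Copy encoder weights from a (trained) CFN or checkpoint into the
    classifier; the classification head is freshly initialized."""
    if isinstance(source, (str, Path)):
        spec, state = load_encoder(source)
        if (spec.name, spec.feature_dim, spec.input_channels) != (
            target.spec.name, target.spec.feature_dim, target.spec.input_channels
        ):
            raise ValueError("encoder specs do not match; cannot transfer")
    else:
        if (source.spec.name, source.spec.feature_dim, source.spec.input_channels) != (
            target.spec.name, target.spec.feature_dim, target.spec.input_channels
        ):
            raise ValueError("encoder specs do not match; cannot transfer")
        state = source.encoder.state_dict()
    target.encoder.load_state_dict(state)
    if head_seed is not None:
        target.head = nn.Linear(target.spec.feature_dim, 1, rng=_head_rng(head_seed))
    return target


def save_encoder(path: str | Path, spec: EncoderSpec, encoder: nn.Sequential
                 ) -> None:
    """Single-file checkpoint: parameter arrays + embedded spec JSON."""
    state = encoder.state_dict()
    meta = json.dumps(dataclasses.asdict(spec))
    np.savez(path, __spec__=np.array(meta), **state)


def save_classifier(path: str | Path, model: ClassifierModel) -> None:
    """Checkpoint the full classifier (encoder + head) with its spec."""
    state = model.encoder.state_dict()
    state["head.W"] = model.head.W.value.copy()
    state["head.b"] = model.head.b.value.copy()
    meta = json.dumps(dataclasses.asdict(model.spec))
    np.savez(path, __spec__=np.array(meta), **state)


def load_classifier(path: str | Path) -> ClassifierModel:
    spec, state = load_encoder(path)
    head_w = state.pop("head.W")
    head_b = state.pop("head.b")
    model = ClassifierModel(spec, seed=0)
    model.encoder.load_state_dict(state)
    model.head.W.value = np.asarray(head_w, dtype=np.float64).copy()
    model.head.b.value = np.asarray(head_b, dtype=np.float64).copy()
    return model


def load_encoder(path: str | Path) -> tuple[EncoderSpec, dict[str, np.ndarray]]:
    path = Path(path)
    if not path.exists() and path.with_suffix(".npz").exists():
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        meta = json.loads(str(data["__spec__"]))
        state = {k: data[k] for k in data.files if k != "__spec__"}
    return EncoderSpec(**meta), state
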