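"""Fusion classifier families, the split protocol, and the train loop.

Three model families cover the two instruments:

* ``poleno_holo`` — each holography view is encoded by the same
  convolutional encoder (weight-shared by default), the two feature vectors
  are concatenated, layer-normalized and passed through a feedforward stack
  into the classifier;
* ``poleno_holo_fluor`` — adds a feedforward encoder of the flattened,
  per-source-normalized 3x5 fluorescence matrix whose embedding is
  concatenated before the classifier;
* ``rapide_multibranch`` — four residual convolutional branches (lifetime /
  scattering / spectrum / infrared with 4 / 3 / 5 / 2 block-layers; each
  block-layer holds 3 convolutions, 4 in the first, around an identity
  shortcut; the first convolution of a branch uses a 5x5 kernel, 2x2
  padding and no stride), embeddings concatenated into a feedforward
  classifier.

``backbone_scale="tiny"`` keeps the exact fusion topology at desk-scale
widths so end-to-end runs finish in minutes on one CPU;
``backbone_scale="paper"`` widens and deepens the encoders following the
EfficientNet-B0 stage-width geometry. All weights are freshly initialized —
training is always end-to-end from scratch.

The 80/10/10 split is stratified per class (within one event of the exact
fractions) and keyed on the dataset content hash and the seed only, so every
model family trains, validates and tests on identical partitions.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn
from .evaluation import confusion, macro_f1
from .events import EventDataset
from .preprocessing import PreprocessConfig, preprocess_poleno, preprocess_rapide

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "Model",
    "split_dataset",
    "dataset_hash",
    "build_model",
    "train",
    "predict",
]

Family = Literal["poleno_holo", "poleno_holo_fluor", "rapide_multibranch"]

_DEFAULT_BLOCKS = {"lifetime": 4, "scattering": 3, "spectrum": 5, "infrared": 2}


@dataclass
class ModelConfig:
    family: Family
    n_classes: int
    backbone_scale: Literal["tiny", "paper"] = "tiny"
    branch_blocks: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_BLOCKS))
    fusion_hidden_sizes: tuple[int, ...] | None = None
    #: Side length holography images are resampled to before encoding.
    image_input_size: int = 24
    share_image_encoder: bool = True
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    #: Per-modality (channels, height, width) for the Rapid-E+ branches.
    rapide_shapes: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {
            "spectrum": (1, 30, 30),
            "lifetime": (1, 30, 30),
            "scattering": (2, 14, 64),
            "infrared": (1, 16, 16),
        }
    )

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(v <= 0 for v in self.branch_blocks.values()):
            raise ValueError("branch block counts must be positive")
        if self.fusion_hidden_sizes is None:
            self.fusion_hidden_sizes = (
                (32, 32) if self.backbone_scale == "tiny" else (256, 128)
            )


@dataclass
class TrainConfig:
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stopping_metric: Literal["val_macro_f1", "val_loss"] = "val_macro_f1"

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.epochs, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


# ------------------------------------------------------------------ split

def dataset_hash(dataset: EventDataset) -> str:
    """Content hash over labels and event arrays (order-sensitive)."""
    h = hashlib.sha256()
    for ev in dataset.events:
        h.update(repr(ev.label).encode())
        for name in ("image_a", "image_b", "fluorescence", "scattering",
                     "spectrum", "lifetime", "infrared"):
            arr = getattr(ev, name, None)
            if arr is not None:
                a = np.ascontiguousarray(arr)
                h.update(str(a.shape).encode())
                h.update(a.tobytes())
    return h.hexdigest()


def _allocate(n: int, fractions: tuple[float, ...]) -> list[int]:
    # largest-remainder allocation; ties broken toward earlier splits
    quotas = [f * n for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def split_dataset(
    dataset: EventDataset, config: TrainConfig
) -> tuple[EventDataset, EventDataset, EventDataset]:
    """Label-stratified train/validation/test partition.

    Disjoint and exhaustive; per-class counts are within one event of the
    exact fractions; the permutation is keyed on (dataset content hash,
    seed) only, so the same data and seed give the same partition to every
    model family.
    """
    labels = dataset.labels
    if any(lab is None for lab in labels):
        raise ValueError("split_dataset requires a fully labelled dataset")
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    for lab, idx in by_class.items():
        if len(idx) < 10:
            raise ValueError(
                f"class {lab!r} has only {len(idx)} events; stratified "
                f"splitting requires at least 10 per class"
            )
    key = int(dataset_hash(dataset)[:16], 16)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, key]))
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for lab in sorted(by_class):
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        n_tr, n_va, n_te = _allocate(len(idx), config.split_fractions)
        parts[0].extend(idx[:n_tr])
        parts[1].extend(idx[n_tr : n_tr + n_va])
        parts[2].extend(idx[n_tr + n_va :])
    return tuple(dataset.subset(sorted(p)) for p in parts)  # type: ignore[return-value]


# ------------------------------------------------------------ featurization

def _poleno_inputs(dataset: EventDataset, config: ModelConfig) -> dict[str, np.ndarray]:
    s = config.image_input_size
    imgs_a, imgs_b, fluor = [], [], []
    for ev in dataset.events:
        mi = preprocess_poleno(ev)
        imgs_a.append(resize(mi["image_a"], (s, s), anti_aliasing=True,
                             preserve_range=True))
        imgs_b.append(resize(mi["image_b"], (s, s), anti_aliasing=True,
                             preserve_range=True))
        fluor.append(mi["fluorescence"].ravel())
    return {
        "image_a": np.asarray(imgs_a)[:, None, :, :],
        "image_b": np.asarray(imgs_b)[:, None, :, :],
        "fluorescence": np.asarray(fluor),
    }


def _rapide_inputs(dataset: EventDataset, config: ModelConfig) -> dict[str, np.ndarray]:
    mods: dict[str, list[np.ndarray]] = {k: [] for k in _DEFAULT_BLOCKS}
    for ev in dataset.events:
        mi = preprocess_rapide(ev, config.preprocess)
        mods["spectrum"].append(mi["spectrum"][None])
        mods["lifetime"].append(mi["lifetime"][None])
        mods["scattering"].append(mi["scattering"])
        mods["infrared"].append(mi["infrared"][None])
    return {k: np.asarray(v) for k, v in mods.items()}


# ------------------------------------------------------------- architectures

def _image_encoder(config: ModelConfig, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    if config.backbone_scale == "tiny":
        return (
            nn.Sequential([
                nn.Conv2d(1, 8, 3, rng, stride=2, pad=1), nn.ReLU(),
                nn.Conv2d(8, 16, 3, rng, stride=2, pad=1), nn.ReLU(),
                nn.Conv2d(16, 32, 3, rng, stride=2, pad=1), nn.ReLU(),
                nn.GlobalAvgPool(),
            ]),
            32,
        )
    # "paper": plain-conv residual encoder following the B0 stage widths
    stages = [(16, 1), (24, 2), (40, 2), (80, 1), (112, 2), (192, 2), (320, 1)]
    layers: list[nn.Layer] = [nn.Conv2d(1, 32, 3, rng, stride=2, pad=1), nn.ReLU()]
    prev = 32
    for width, stride in stages:
        layers += [nn.Conv2d(prev, width, 3, rng, stride=stride, pad=1), nn.ReLU()]
        layers += [
            nn.Residual(nn.Sequential([
                nn.Conv2d(width, width, 3, rng, stride=1, pad=1), nn.ReLU(),
                nn.Conv2d(width, width, 3, rng, stride=1, pad=1),
            ])),
            nn.ReLU(),
        ]
        prev = width
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(layers), prev


def _ffn(sizes: tuple[int, ...], n_in: int, n_out: int,
         rng: np.random.Generator, prepend_layernorm: bool) -> nn.Sequential:
    layers: list[nn.Layer] = []
    if prepend_layernorm:
        layers.append(nn.LayerNorm(n_in))
    prev = n_in
    for h in sizes:
        layers += [nn.Dense(prev, h, rng), nn.ReLU()]
        prev = h
    layers.append(nn.Dense(prev, n_out, rng))
    return nn.Sequential(layers)


def _residual_branch(
    in_ch: int, n_blocks: int, width: int, hw: tuple[int, int],
    rng: np.random.Generator,
) -> nn.Sequential:
    layers: list[nn.Layer] = [
        nn.Conv2d(in_ch, width, 5, rng, stride=1, pad=2), nn.ReLU(),
    ]
    h, w = hw
    for b in range(n_blocks):
        n_convs = 4 if b == 0 else 3
        inner: list[nn.Layer] = []
        for i in range(n_convs):
            inner.append(nn.Conv2d(width, width, 3, rng, stride=1, pad=1))
            if i < n_convs - 1:
                inner.append(nn.ReLU())
        layers += [nn.Residual(nn.Sequential(inner)), nn.ReLU()]
        if min(h, w) >= 8:
            layers.append(nn.MaxPool2())
            h, w = h // 2, w // 2
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(layers)


class Model:
    """A built (and possibly trained) fusion classifier."""

    def __init__(self, config: ModelConfig, net: nn.FusionModel,
                 classes: list[str] | None = None):
        self.config = config
        self.net = net
        self.classes = classes

    # -- data plumbing -------------------------------------------------
    def featurize(self, dataset: EventDataset) -> dict[str, np.ndarray]:
        if self.config.family == "rapide_multibranch":
            if dataset.instrument != "rapid_e":
                raise ValueError("rapide_multibranch expects a rapid_e dataset")
            return _rapide_inputs(dataset, self.config)
        if dataset.instrument != "poleno":
            raise ValueError(f"{self.config.family} expects a poleno dataset")
        return _poleno_inputs(dataset, self.config)

    def labels_to_indices(self, labels: list[str | None]) -> np.ndarray:
        if self.classes is None:
            raise RuntimeError("model has no class vocabulary yet (train first)")
        index = {c: i for i, c in enumerate(self.classes)}
        try:
            return np.array([index[lab] for lab in labels])
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in the model's classes") from None

    def predict_proba_arrays(self, inputs: dict[str, np.ndarray],
                             batch_size: int = 64) -> np.ndarray:
        n = next(iter(inputs.values())).shape[0]
        out = []
        for lo in range(0, n, batch_size):
            batch = {k: v[lo : lo + batch_size] for k, v in inputs.items()}
            out.append(nn.softmax(self.net.forward(batch)))
        return np.concatenate(out, axis=0)

    # -- persistence ---------------------------------------------------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez(
            os.path.join(directory, "weights.npz"),
            **{f"p{i:04d}": w for i, w in enumerate(self.net.get_weights())},
        )
        meta = {
            "family": self.config.family,
            "n_classes": self.config.n_classes,
            "backbone_scale": self.config.backbone_scale,
            "branch_blocks": self.config.branch_blocks,
            "fusion_hidden_sizes": list(self.config.fusion_hidden_sizes or ()),
            "image_input_size": self.config.image_input_size,
            "share_image_encoder": self.config.share_image_encoder,
            "classes": self.classes,
        }
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, directory: str) -> "Model":
        with open(os.path.join(directory, "model.json")) as fh:
            meta = json.load(fh)
        config = ModelConfig(
            family=meta["family"],
            n_classes=meta["n_classes"],
            backbone_scale=meta["backbone_scale"],
            branch_blocks=meta["branch_blocks"],
            fusion_hidden_sizes=tuple(meta["fusion_hidden_sizes"]) or None,
            image_input_size=meta["image_input_size"],
            share_image_encoder=meta["share_image_encoder"],
        )
        model = build_model(config)
        with np.load(os.path.join(directory, "weights.npz")) as z:
            model.net.set_weights([z[k] for k in sorted(z.files)])
        model.classes = meta["classes"]
        return model


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Instantiate a freshly initialized network for the configured family."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    hidden = config.fusion_hidden_sizes or ()
    if config.family in ("poleno_holo", "poleno_holo_fluor"):
        enc_a, feat = _image_encoder(config, rng)
        enc_b = enc_a.share() if config.share_image_encoder else _image_encoder(config, rng)[0]
        branches: dict[str, nn.Sequential] = {"image_a": enc_a, "image_b": enc_b}
        order = ["image_a", "image_b"]
        fused = 2 * feat
        if config.family == "poleno_holo_fluor":
            fl_dim = 16 if config.backbone_scale == "tiny" else 64
            branches["fluorescence"] = nn.Sequential(
                [nn.Dense(15, fl_dim, rng), nn.ReLU()]
            )
            order.append("fluorescence")
            fused += fl_dim
        head = _ffn(tuple(hidden), fused, config.n_classes, rng, prepend_layernorm=True)
        return Model(config, nn.FusionModel(branches, head, order))
    if config.family == "rapide_multibranch":
        width = 4 if config.backbone_scale == "tiny" else 32
        branches = {}
        for name, blocks in config.branch_blocks.items():
            ch, h, w = config.rapide_shapes[name]
            branches[name] = _residual_branch(ch, blocks, width, (h, w), rng)
        order = ["lifetime", "scattering", "spectrum", "infrared"]
        head = _ffn(tuple(hidden), width * len(branches), config.n_classes, rng,
                    prepend_layernorm=True)
        return Model(config, nn.FusionModel(branches, head, order))
    raise ValueError(f"unknown model family {config.family!r}")


# ------------------------------------------------------------------ training

def _evaluate(model: Model, inputs: dict[str, np.ndarray], y: np.ndarray) -> tuple[float, float]:
    probs = model.predict_proba_arrays(inputs)
    loss = float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())
    pred = probs.argmax(axis=1)
    classes = list(range(len(model.classes)))
    mat = confusion([str(t) for t in y], [str(p) for p in pred], [str(c) for c in classes])
    return loss, macro_f1(mat)


def train(
    model: Model,
    train_ds: EventDataset,
    val_ds: EventDataset,
    config: TrainConfig,
) -> tuple[Model, pd.DataFrame]:
    """Cross-entropy training with validation-based model selection.

    Runs ``config.epochs`` epochs of Adam on shuffled minibatches; after
    each epoch the validation loss and macro F1 are recorded and the weights
    achieving the best value of ``early_stopping_metric`` are kept and
    restored at the end. Deterministic for a fixed seed (single-threaded).
    """
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train and validation splits must be non-empty")
    classes = sorted({lab for lab in train_ds.labels if lab is not None})
    if len(classes) != model.config.n_classes:
        raise ValueError(
            f"model configured for {model.config.n_classes} classes but the "
            f"training data has {len(classes)}"
        )
    model.classes = classes
    x_train = model.featurize(train_ds)
    y_train = model.labels_to_indices(train_ds.labels)
    x_val = model.featurize(val_ds)
    y_val = model.labels_to_indices(val_ds.labels)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7EA1]))
    params = model.net.params()
    opt = nn.Adam(params, lr=config.learning_rate)
    n = len(y_train)
    history: list[dict] = []
    best_score = -np.inf
    best_weights = model.net.get_weights()
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            sel = perm[lo : lo + config.batch_size]
            batch = {k: v[sel] for k, v in x_train.items()}
            logits = model.net.forward(batch)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_train[sel])
            nn.zero_grad(params)
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(sel)
        val_loss, val_f1 = _evaluate(model, x_val, y_val)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n,
                "val_loss": val_loss,
                "val_macro_f1": val_f1,
            }
        )
        score = val_f1 if config.early_stopping_metric == "val_macro_f1" else -val_loss
        if score > best_score:
            best_score = score
            best_weights = model.net.get_weights()
    model.net.set_weights(best_weights)
    return model, pd.DataFrame(history)


def predict(model: Model, dataset: EventDataset) -> pd.DataFrame:
    """Per-event argmax label and class probabilities (rows sum to 1)."""
    if model.classes is None:
        raise RuntimeError("model must be trained (or loaded) before predicting")
    inputs = model.featurize(dataset)
    probs = model.predict_proba_arrays(inputs)
    frame = pd.DataFrame(probs, columns=[f"p_{c}" for c in model.classes])
    frame.insert(0, "pred", [model.classes[i] for i in probs.argmax(axis=1)])
    return frame
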