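"""Deep-feature extraction backbone.

A ResNet-style convolutional backbone implemented directly on numpy: the
full ResNet101 bottleneck graph (stem 7×7/2 conv, 3×3/2 max pool, bottleneck
stages [3, 4, 23, 3], global average pool) whose pool5 layer emits the
standard 2048-wide descriptor per image, plus a small ``resnet_micro``
registry entry for fast desk-scale runs.  Convolutions run as im2col matrix
products; batch-norm layers apply stored statistics (identity at random
initialization), so a fixed model is a deterministic function of its input.

Transfer learning here means retraining the classification head: the
convolutional body acts as a frozen feature extractor and the head — a
softmax layer on the pool5 descriptor — is trained with SGD + momentum under
cross-entropy.  Weight checkpoints are ``.npz`` files; ``pretrained=True``
loads one from disk and never downloads anything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataio import FeatureMatrix, LabeledImageSet, to_model_input

logger = logging.getLogger(__name__)

#: stage plan per architecture: (stem_filters, [(n_blocks, planes, stride), ...], expansion)
ARCHITECTURES = {
    "resnet101": (64, [(3, 64, 1), (4, 128, 2), (23, 256, 2), (3, 512, 2)], 4),
    "resnet50": (64, [(3, 64, 1), (4, 128, 2), (6, 256, 2), (3, 512, 2)], 4),
    "resnet_micro": (8, [(1, 8, 1), (1, 16, 2)], 2),
}

FEATURE_LAYERS = ("pool5",)


@dataclass
class BackboneConfig:
    architecture: str = "resnet101"
    input_shape: tuple[int, int, int] = (224, 224, 3)
    feature_layer: str = "pool5"
    num_classes: int = 4
    pretrained: bool = False
    weights_path: str | None = None
    normalization: str = "unit"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"registry: {sorted(ARCHITECTURES)}")
        if self.feature_layer not in FEATURE_LAYERS:
            raise ValueError(f"feature_layer {self.feature_layer!r} does not "
                             f"resolve; available: {FEATURE_LAYERS}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass
class TrainConfig:
    """Head-training hyperparameters: SGD + momentum under cross-entropy."""

    epochs: int = 10
    learning_rate: float = 1e-4
    batch_size: int = 32
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")

    @classmethod
    def preset(cls, name: str) -> "TrainConfig":
        """Named presets: the transfer-step setting (``paper-s3``: lr 1e-4,
        batch 32) and the experiment setting (``paper-s4``: 100 epochs,
        lr 0.05, momentum 0.7)."""
        if name == "paper-s3":
            return cls(epochs=10, learning_rate=1e-4, batch_size=32)
        if name == "paper-s4":
            return cls(epochs=100, learning_rate=0.05, batch_size=32,
                       momentum=0.7)
        raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# numpy layer primitives (NHWC)
# ---------------------------------------------------------------------------

def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """x: (N,H,W,C), w: (kh,kw,C,F) → (N,H',W',F) via im2col."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    kh, kw, c, f = w.shape
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]          # (N, oh, ow, C, kh, kw)
    n, oh, ow = win.shape[:3]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, kh * kw * c)
    out = cols @ w.reshape(kh * kw * c, f)
    return out.reshape(n, oh, ow, f)


def _batchnorm(x: np.ndarray, p: dict) -> np.ndarray:
    inv = p["gamma"] / np.sqrt(p["var"] + 1e-5)
    return x * inv + (p["beta"] - p["mean"] * inv)


def _maxpool(x: np.ndarray, size: int = 3, stride: int = 2,
             pad: int = 1) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)),
                   constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(x, (size, size), axis=(1, 2))
    return win[:, ::stride, ::stride].max(axis=(-2, -1))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _he_conv(rng: np.random.Generator, kh: int, kw: int, c: int,
             f: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (kh * kw * c))
    return (rng.standard_normal((kh, kw, c, f)) * scale).astype(np.float32)


def _bn_params(f: int) -> dict:
    return {"gamma": np.ones(f, np.float32), "beta": np.zeros(f, np.float32),
            "mean": np.zeros(f, np.float32), "var": np.ones(f, np.float32)}


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class Model:
    """A backbone with a replaceable softmax classification head."""

    config: BackboneConfig
    params: dict = field(repr=False, default_factory=dict)
    head_w: np.ndarray | None = field(repr=False, default=None)
    head_b: np.ndarray | None = field(repr=False, default=None)
    classes: list[str] | None = None
    training_log: list[float] = field(default_factory=list)

    @property
    def feature_width(self) -> int:
        stem, stages, expansion = ARCHITECTURES[self.config.architecture]
        return stages[-1][1] * expansion

    # -- forward ------------------------------------------------------------
    def _block(self, x: np.ndarray, p: dict, stride: int) -> np.ndarray:
        out = _relu(_batchnorm(_conv2d(x, p["w1"], 1, 0), p["bn1"]))
        out = _relu(_batchnorm(_conv2d(out, p["w2"], stride, 1), p["bn2"]))
        out = _batchnorm(_conv2d(out, p["w3"], 1, 0), p["bn3"])
        if "wd" in p:
            x = _batchnorm(_conv2d(x, p["wd"], stride, 0), p["bnd"])
        return _relu(out + x)

    def forward_features(self, batch: np.ndarray) -> np.ndarray:
        """(N,H,W,3) → (N, feature_width): the pool5 descriptor."""
        x = np.asarray(batch, dtype=np.float32)
        p = self.params
        x = _relu(_batchnorm(_conv2d(x, p["stem_w"], 2, p["stem_pad"]),
                             p["stem_bn"]))
        x = _maxpool(x)
        for si, blocks in enumerate(p["stages"]):
            for bi, bp in enumerate(blocks):
                stride = bp["stride"] if bi == 0 else 1
                x = self._block(x, bp, stride)
        return x.mean(axis=(1, 2))  # global average pool = pool5

    def forward_logits(self, batch: np.ndarray) -> np.ndarray:
        feats = self.forward_features(batch)
        return feats @ self.head_w.T + self.head_b

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        flat = {"head_w": self.head_w, "head_b": self.head_b,
                "stem_w": self.params["stem_w"], "stem_pad":
                    np.array(self.params["stem_pad"])}
        for k, v in self.params["stem_bn"].items():
            flat[f"stem_bn.{k}"] = v
        for si, blocks in enumerate(self.params["stages"]):
            for bi, bp in enumerate(blocks):
                for k, v in bp.items():
                    if isinstance(v, dict):
                        for kk, vv in v.items():
                            flat[f"s{si}.b{bi}.{k}.{kk}"] = vv
                    else:
                        flat[f"s{si}.b{bi}.{k}"] = np.asarray(v)
        np.savez_compressed(path, **flat)
        return path

    def load(self, path: str | Path) -> "Model":
        data = np.load(Path(path), allow_pickle=False)
        self.head_w = data["head_w"]
        self.head_b = data["head_b"]
        self.params["stem_w"] = data["stem_w"]
        self.params["stem_pad"] = int(data["stem_pad"])
        for k in self.params["stem_bn"]:
            self.params["stem_bn"][k] = data[f"stem_bn.{k}"]
        for si, blocks in enumerate(self.params["stages"]):
            for bi, bp in enumerate(blocks):
                for k, v in bp.items():
                    if isinstance(v, dict):
                        for kk in v:
                            v[kk] = data[f"s{si}.b{bi}.{k}.{kk}"]
                    elif k != "stride":
                        bp[k] = data[f"s{si}.b{bi}.{k}"]
        return self


def build_model(cfg: BackboneConfig) -> Model:
    """Construct a backbone from the registry with seeded He initialization.

    ``pretrained=True`` requires ``weights_path`` (a local ``.npz``
    checkpoint); construction never touches the network.
    """
    stem_f, stages_plan, expansion = ARCHITECTURES[cfg.architecture]
    rng = np.random.default_rng(cfg.init_seed)
    big = cfg.architecture.startswith("resnet1") or cfg.architecture == "resnet50"
    stem_k, stem_pad = (7, 3) if big else (3, 1)

    params: dict = {
        "stem_w": _he_conv(rng, stem_k, stem_k, cfg.input_shape[2], stem_f),
        "stem_pad": stem_pad,
        "stem_bn": _bn_params(stem_f),
        "stages": [],
    }
    in_ch = stem_f
    for n_blocks, planes, stride in stages_plan:
        blocks = []
        out_ch = planes * expansion
        for bi in range(n_blocks):
            s = stride if bi == 0 else 1
            bp = {
                "stride": s,
                "w1": _he_conv(rng, 1, 1, in_ch, planes), "bn1": _bn_params(planes),
                "w2": _he_conv(rng, 3, 3, planes, planes), "bn2": _bn_params(planes),
                "w3": _he_conv(rng, 1, 1, planes, out_ch), "bn3": _bn_params(out_ch),
            }
            if s != 1 or in_ch != out_ch:
                bp["wd"] = _he_conv(rng, 1, 1, in_ch, out_ch)
                bp["bnd"] = _bn_params(out_ch)
            blocks.append(bp)
            in_ch = out_ch
        params["stages"].append(blocks)

    model = Model(config=cfg, params=params)
    width = model.feature_width
    model.head_w = (rng.standard_normal((cfg.num_classes, width))
                    * np.sqrt(1.0 / width)).astype(np.float32)
    model.head_b = np.zeros(cfg.num_classes, np.float32)

    if cfg.pretrained:
        if not cfg.weights_path or not Path(cfg.weights_path).exists():
            raise FileNotFoundError(
                "pretrained=True needs a local checkpoint at weights_path; "
                "no download is ever attempted")
        model.load(cfg.weights_path)
    return model


def _batched_inputs(images: LabeledImageSet, cfg: BackboneConfig,
                    batch_size: int = 8):
    h, w, _ = cfg.input_shape
    batch, meta = [], []
    for im in images.images:
        batch.append(to_model_input(im, (h, w), cfg.normalization))
        meta.append((im.label, im.source_id))
        if len(batch) == batch_size:
            yield np.stack(batch), meta
            batch, meta = [], []
    if batch:
        yield np.stack(batch), meta


def extract_features(model: Model, images: LabeledImageSet,
                     cfg: BackboneConfig | None = None,
                     batch_size: int = 8) -> FeatureMatrix:
    """Pool5 descriptors, one row per image in input order (never shuffled)."""
    cfg = cfg or model.config
    width = model.feature_width
    rows, labels = [], []
    for batch, meta in _batched_inputs(images, cfg, batch_size):
        rows.append(model.forward_features(batch))
        labels.extend(m[0] for m in meta)
    X = np.vstack(rows) if rows else np.empty((0, width))
    return FeatureMatrix(X=X.astype(float), y=np.array(labels, dtype=object),
                         feature_ids=[f"{cfg.feature_layer}_{j:04d}"
                                      for j in range(width)])


def finetune(model: Model, trainset: LabeledImageSet,
             cfg: TrainConfig) -> Model:
    """Adapt the model to the target classes by training its softmax head.

    The convolutional body is the frozen transfer-learning feature extractor;
    pool5 descriptors are computed once, then the head is trained with
    mini-batch SGD (momentum, cross-entropy).  Per-epoch mean loss is logged
    and stored on ``model.training_log``; a fixed seed fixes the shuffle
    order, so the loss trajectory is reproducible.
    """
    if len(trainset) == 0:
        raise ValueError("empty training set")
    counts = trainset.class_counts()
    missing = [c for c, k in counts.items() if k == 0]
    if missing:
        raise ValueError(f"classes absent from trainset: {missing} "
                         "(cross-entropy target coverage undefined)")
    if len(trainset.classes) != model.config.num_classes:
        raise ValueError(f"trainset has {len(trainset.classes)} classes; "
                         f"model head expects {model.config.num_classes}")

    feats = extract_features(model, trainset).X.astype(np.float32)
    class_index = {c: i for i, c in enumerate(trainset.classes)}
    targets = np.array([class_index[im.label] for im in trainset.images])

    rng = np.random.default_rng(cfg.seed)
    w = model.head_w.astype(np.float64).copy()
    b = model.head_b.astype(np.float64).copy()
    vw = np.zeros_like(w)
    vb = np.zeros_like(b)
    n = feats.shape[0]

    model.training_log = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x, t = feats[idx], targets[idx]
            logits = x @ w.T + b
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            losses.append(float(-np.mean(np.log(p[np.arange(len(t)), t] + 1e-12))))
            grad = p
            grad[np.arange(len(t)), t] -= 1.0
            grad /= len(t)
            gw = grad.T @ x
            gb = grad.sum(axis=0)
            vw = cfg.momentum * vw - cfg.learning_rate * gw
            vb = cfg.momentum * vb - cfg.learning_rate * gb
            w += vw
            b += vb
        epoch_loss = float(np.mean(losses))
        model.training_log.append(epoch_loss)
        logger.info("epoch %d/%d: training loss %.6f",
                    epoch + 1, cfg.epochs, epoch_loss)

    model.head_w = w.astype(np.float32)
    model.head_b = b.astype(np.float32)
    model.classes = list(trainset.classes)
    return model
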