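"""The compact EEG-image CNN and its ablation variants.

The classifier stacks ``n_blocks`` feature-extraction blocks — valid 3x3
convolution (32 filters), ReLU, 2x1 max-pool — with 25% dropout after
blocks 2 and 4, then flatten, 50% dropout, and a 3-way softmax head. The
asymmetric 2x1 pool halves the time axis each block while leaving the
19-electrode axis to shrink only by convolution margins, which is what
keeps a 4-block stack viable on a 1280x19 input. Training uses Adam on
categorical cross-entropy with early stopping on validation loss
(min_delta 0.001, patience 15) and best-weight restoration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _nn
from .montage import LABELS

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "LayerSpec",
    "Architecture",
    "TrainedModel",
    "build_model",
    "ablation_configs",
    "train",
    "predict",
    "predict_labels",
    "save_model",
    "load_model",
]


class ShapeUnderflowError(ValueError):
    """Pooling/convolution exhausted a spatial dimension."""


class DegenerateLabelsError(ValueError):
    """Training data covers fewer than two classes."""


def _default_block_dropouts() -> dict[int, float]:
    return {2: 0.25, 4: 0.25}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters (defaults are the baseline network)."""

    n_blocks: int = 4
    filters: int = 32
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 1)
    block_dropouts: dict[int, float] = field(default_factory=_default_block_dropouts)
    head_dropout: float = 0.50
    n_classes: int = 3
    input_shape: tuple[int, int, int] = (1280, 19, 1)

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("need at least one feature-extraction block")
        if min(self.kernel) < 1 or min(self.pool) < 1:
            raise ValueError("kernel and pool dimensions must be >= 1")
        for p in list(self.block_dropouts.values()) + [self.head_dropout]:
            if not 0.0 <= p < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; ``seed`` pins every source of randomness."""

    batch_size: int = 128
    max_epochs: int = 100
    learning_rate: float = 1e-3
    early_stop_min_delta: float = 0.001
    early_stop_patience: int = 15
    val_fraction: float = 0.1
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must lie in (0, 0.5)")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str
    output_shape: tuple[int, ...]
    n_params: int


@dataclass(frozen=True)
class Architecture:
    """Static descriptor: config, per-layer output shapes and parameter counts."""

    config: ModelConfig
    layers: tuple[LayerSpec, ...]

    @property
    def n_params(self) -> int:
        return sum(s.n_params for s in self.layers)

    def summary(self) -> str:
        lines = [f"{'layer':<14}{'kind':<10}{'output shape':<18}params"]
        for s in self.layers:
            lines.append(f"{s.name:<14}{s.kind:<10}{str(s.output_shape):<18}{s.n_params}")
        lines.append(f"total trainable parameters: {self.n_params}")
        return "\n".join(lines)

    # -- instantiation -----------------------------------------------------
    def instantiate(self, rng: np.random.Generator) -> _nn.Network:
        cfg = self.config
        kh, kw = cfg.kernel
        ph, pw = cfg.pool
        h, w, c = cfg.input_shape
        layers: list[_nn.Layer] = []
        for b in range(1, cfg.n_blocks + 1):
            layers.append(_nn.Conv2D(kh, kw, c, cfg.filters, rng, input_grad=(b > 1)))
            layers.append(_nn.ReLU())
            layers.append(_nn.MaxPool(ph, pw))
            h, w, c = (h - kh + 1) // ph, (w - kw + 1) // pw, cfg.filters
            if b in cfg.block_dropouts:
                layers.append(_nn.Dropout(cfg.block_dropouts[b]))
        layers.append(_nn.Flatten())
        layers.append(_nn.Dropout(cfg.head_dropout))
        layers.append(_nn.Dense(h * w * c, cfg.n_classes, rng))
        return _nn.Network(layers)


def build_model(cfg: ModelConfig | None = None) -> Architecture:
    """Validate a configuration and derive the full layer descriptor.

    Raises :class:`ShapeUnderflowError` if any spatial dimension is
    exhausted before the head.
    """
    cfg = cfg or ModelConfig()
    kh, kw = cfg.kernel
    ph, pw = cfg.pool
    h, w, c = cfg.input_shape
    specs: list[LayerSpec] = []
    for b in range(1, cfg.n_blocks + 1):
        h2, w2 = h - kh + 1, w - kw + 1
        if h2 < 1 or w2 < 1:
            raise ShapeUnderflowError(
                f"conv of block {b} underflows: input {h}x{w}, kernel {kh}x{kw}"
            )
        n_par = kh * kw * c * cfg.filters + cfg.filters
        specs.append(LayerSpec(f"block{b}_conv", "conv", (h2, w2, cfg.filters), n_par))
        specs.append(LayerSpec(f"block{b}_relu", "relu", (h2, w2, cfg.filters), 0))
        h, w, c = h2 // ph, w2 // pw, cfg.filters
        if h < 1 or w < 1:
            raise ShapeUnderflowError(
                f"pool of block {b} underflows: {h2}x{w2} pooled by {ph}x{pw}"
            )
        specs.append(LayerSpec(f"block{b}_pool", "maxpool", (h, w, c), 0))
        if b in cfg.block_dropouts:
            specs.append(
                LayerSpec(f"block{b}_dropout", "dropout", (h, w, c), 0)
            )
    flat = h * w * c
    specs.append(LayerSpec("flatten", "flatten", (flat,), 0))
    specs.append(LayerSpec("head_dropout", "dropout", (flat,), 0))
    specs.append(
        LayerSpec("dense_softmax", "dense", (cfg.n_classes,), flat * cfg.n_classes + cfg.n_classes)
    )
    return Architecture(config=cfg, layers=tuple(specs))


def ablation_configs(base: ModelConfig | None = None) -> dict[str, ModelConfig]:
    """The baseline plus the five single-change architecture variants."""
    base = base or ModelConfig()
    return {
        "baseline": base,
        "add_block": replace(base, n_blocks=base.n_blocks + 1),
        "remove_block": replace(base, n_blocks=base.n_blocks - 1),
        "half_filters": replace(base, filters=base.filters // 2),
        "double_filters": replace(base, filters=base.filters * 2),
        "kernel_5x5": replace(base, kernel=(5, 5)),
    }


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    architecture: Architecture
    weights: list[np.ndarray]
    history: dict[str, list[float]]
    epochs_run: int
    classes: tuple[str, ...] = LABELS

    def network(self) -> _nn.Network:
        net = self.architecture.instantiate(np.random.default_rng(0))
        net.set_weights(self.weights)
        return net


def _as_tensor(images: np.ndarray) -> np.ndarray:
    """8-bit images to centred float tensors: pixel 0 -> -1, pixel 255 -> +1.

    Centring the input (rather than feeding raw [0, 1] intensities) keeps
    the first conv layer's pre-activations balanced and speeds up early
    convergence; float inputs are assumed already scaled and pass through.
    """
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[..., None]
    if x.dtype == np.uint8:
        x = x.astype(np.float32) * np.float32(2.0 / 255.0) - np.float32(1.0)
    return np.ascontiguousarray(x, dtype=np.float32)


def encode_labels(labels) -> np.ndarray:
    """Map HS/MCI/AD strings (or integer indices) to class indices."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    lut = {name: i for i, name in enumerate(LABELS)}
    try:
        return np.array([lut[str(v)] for v in arr], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}") from None


def train(
    arch: Architecture,
    images: np.ndarray,
    labels,
    cfg: TrainConfig | None = None,
) -> TrainedModel:
    """Fit the network; returns the model with its best-validation weights.

    A ``val_fraction`` share of the provided data (never any external test
    fold) is held out to monitor the early-stopping signal. Identical seed,
    data and config give an identical training history.
    """
    cfg = cfg or TrainConfig()
    x = _as_tensor(images)
    y = encode_labels(labels)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("training data must contain at least two classes")

    rng = np.random.default_rng(cfg.seed)
    net = arch.instantiate(rng)
    opt = _nn.Adam(net.parameters(), lr=cfg.learning_rate)

    n = x.shape[0]
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    xtr, ytr = x[tr_idx], y[tr_idx]
    xval, yval = x[val_idx], y[val_idx]

    history: dict[str, list[float]] = {"loss": [], "acc": [], "val_loss": [], "val_acc": []}
    best_loss = np.inf
    best_weights = net.get_weights()
    patience_left = cfg.early_stop_patience
    epochs_run = 0

    for _epoch in range(cfg.max_epochs):
        perm = rng.permutation(xtr.shape[0])
        run_loss = 0.0
        run_hits = 0
        for start in range(0, xtr.shape[0], cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            logits = net.forward(xb, train=True, rng=rng)
            loss, dlogits = _nn.softmax_xent(logits, yb)
            net.backward(dlogits)
            opt.step(net.gradients())
            run_loss += loss * xb.shape[0]
            run_hits += int((logits.argmax(axis=1) == yb).sum())
        epochs_run += 1
        history["loss"].append(run_loss / xtr.shape[0])
        history["acc"].append(run_hits / xtr.shape[0])

        vprob = net.predict_proba(xval, batch_size=max(cfg.batch_size, 64))
        vloss = float(-np.mean(np.log(vprob[np.arange(yval.size), yval] + 1e-12)))
        history["val_loss"].append(vloss)
        history["val_acc"].append(float((vprob.argmax(axis=1) == yval).mean()))

        if best_loss - vloss >= cfg.early_stop_min_delta:
            best_loss = vloss
            best_weights = net.get_weights()
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    return TrainedModel(
        architecture=arch,
        weights=best_weights,
        history=history,
        epochs_run=epochs_run,
    )


def predict(model: TrainedModel, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Per-image class-probability rows (softmax outputs, rows sum to 1)."""
    net = model.network()
    return net.predict_proba(_as_tensor(images), batch_size=batch_size)


def predict_labels(model: TrainedModel, images: np.ndarray) -> np.ndarray:
    """Hard labels; argmax with ties broken toward the lower class index."""
    proba = predict(model, images)
    return np.array([model.classes[i] for i in proba.argmax(axis=1)])


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: TrainedModel, path: str | Path) -> Path:
    path = Path(path)
    cfg = model.architecture.config
    meta = {
        "config": {
            "n_blocks": cfg.n_blocks,
            "filters": cfg.filters,
            "kernel": list(cfg.kernel),
            "pool": list(cfg.pool),
            "block_dropouts": {str(k): v for k, v in cfg.block_dropouts.items()},
            "head_dropout": cfg.head_dropout,
            "n_classes": cfg.n_classes,
            "input_shape": list(cfg.input_shape),
        },
        "classes": list(model.classes),
        "epochs_run": model.epochs_run,
        "history": model.history,
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.weights)}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)
    return path


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    c = meta["config"]
    cfg = ModelConfig(
        n_blocks=c["n_blocks"],
        filters=c["filters"],
        kernel=tuple(c["kernel"]),
        pool=tuple(c["pool"]),
        block_dropouts={int(k): v for k, v in c["block_dropouts"].items()},
        head_dropout=c["head_dropout"],
        n_classes=c["n_classes"],
        input_shape=tuple(c["input_shape"]),
    )
    return TrainedModel(
        architecture=build_model(cfg),
        weights=weights,
        history=meta["history"],
        epochs_run=meta["epochs_run"],
        classes=tuple(meta["classes"]),
    )
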