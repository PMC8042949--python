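"""CNN classifiers over SSC tensors (2D) and one-hot baselines (1D).

The 2D architecture follows the published design: four same-padded
convolutional layers with leaky-ReLU activations, the first two with f1
filters and the last two with 2*f1 ("kernel-scale groups" 32/64, 64/128,
128/256, 256/512), one max-pooling stage after each pair of convolutions
(windows 2x2 then 3x3, so a 60x60 input is reduced to a 10x10 feature map),
dropout 0.25, then a small dense head with a sigmoid output.  Training uses
uniform (Glorot) initialization, the Adam optimizer and binary cross-entropy.

The pooling windows realise the stated 60 -> 10 reduction exactly; the
convolution strides stay configurable for experimentation but default to 1.

The 1D baseline mirrors the same layer plan with 1D kernels over an L x 20
one-hot input.

Everything runs on numpy (see :mod:`sscppi.nn`); at the published data scale
(hundreds of thousands of pairs) a GPU framework would be the right tool,
but the architecture itself is small enough that desk-scale experiments
train in minutes on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .encoding import CHANNEL_ORDER

__all__ = [
    "KERNEL_SCALE_GROUPS",
    "CHANNEL_VARIANTS",
    "ModelConfig",
    "TrainedClassifier",
    "build_cnn_2d",
    "build_cnn_1d_onehot",
    "train",
    "predict",
    "predict_labels",
]

#: The four published kernel-scale groups: (filters of layers 1-2, of layers 3-4).
KERNEL_SCALE_GROUPS = {
    "32/64": (32, 64),
    "64/128": (64, 128),
    "128/256": (128, 256),
    "256/512": (256, 512),
}

#: The four channel-ablation variants.
CHANNEL_VARIANTS = (("S1",), ("S1", "S2"), ("S1", "C"), ("S1", "S2", "C"))


def _parse_kernel_group(group: str | Tuple[int, int]) -> Tuple[int, int]:
    if isinstance(group, str):
        if group in KERNEL_SCALE_GROUPS:
            return KERNEL_SCALE_GROUPS[group]
        try:
            f1, f2 = (int(x) for x in group.split("/"))
            return f1, f2
        except Exception:
            raise ValueError(
                f"kernel_scale_group {group!r} not of the form 'f1/f2'"
            ) from None
    f1, f2 = group
    return int(f1), int(f2)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the CNN classifiers.

    ``kernel_scale_group`` names the filter counts of the four conv layers
    as "f1/f2" meaning (f1, f1, f2, f2); the published groups are 32/64,
    64/128, 128/256 and 256/512 (smaller ad-hoc groups such as "16/32" are
    accepted for scaled-down runs).  ``pool_sizes`` (2, 3) gives the 60->30
    ->10 reduction.  ``input_length`` only applies to the 1D baseline.
    """

    kernel_scale_group: str = "128/256"
    conv_kernel_size: int = 3
    conv_strides: Tuple[int, int, int, int] = (1, 1, 1, 1)
    pool_sizes: Tuple[int, int] = (2, 3)
    dropout_rate: float = 0.25
    leaky_relu_alpha: float = 0.3
    grid_side: int = 60
    input_channels: int = 3
    input_length: int = 1800  # 1D baseline only
    hidden_units: int = 64
    seed: int = 0
    epochs: int = 20
    batch_size: int = 128
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    init: str = "uniform"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 1 <= self.input_channels <= 3:
            raise ValueError("input_channels must be 1..3")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.init != "uniform":
            raise ValueError("only uniform initialization is supported")
        _parse_kernel_group(self.kernel_scale_group)

    @property
    def filters(self) -> Tuple[int, int, int, int]:
        f1, f2 = _parse_kernel_group(self.kernel_scale_group)
        return (f1, f1, f2, f2)


class TrainedClassifier:
    """A (possibly untrained) CNN: layer stack + config + training history."""

    def __init__(self, layers: List[nn.Layer], config: ModelConfig, kind: str) -> None:
        self.layers = layers
        self.config = config
        self.kind = kind  # "cnn2d" | "cnn1d"
        self.history: Dict[str, List[float]] = {"loss": []}
        self.trained = False

    # -- introspection -------------------------------------------------
    def parameter_count(self) -> int:
        return int(sum(p.size for l in self.layers for p in l.params))

    def summary(self) -> str:
        lines = [f"{self.kind} ({self.config.kernel_scale_group} kernels)"]
        for l in self.layers:
            n = sum(p.size for p in l.params)
            lines.append(f"  {type(l).__name__:<10} params={n}")
        lines.append(f"  total params: {self.parameter_count()}")
        return "\n".join(lines)

    def feature_map_side(self) -> int:
        """Spatial side of the representation after the final pooling stage."""
        side = self.config.grid_side
        for s in self.config.conv_strides[:2]:
            side = -(-side // s)
        side //= self.config.pool_sizes[0]
        for s in self.config.conv_strides[2:]:
            side = -(-side // s)
        side //= self.config.pool_sizes[1]
        return side

    # -- forward -------------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return out.reshape(-1)

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = grad_logits.reshape(-1, 1).astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {}
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params):
                arrays[f"layer{li}_param{pi}"] = p
        np.savez_compressed(
            path,
            __meta__=np.frombuffer(
                json.dumps(
                    {"kind": self.kind, "config": asdict(self.config),
                     "history": self.history, "trained": self.trained}
                ).encode(),
                dtype=np.uint8,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["config"]
            for key in ("conv_strides", "pool_sizes"):
                cfg_dict[key] = tuple(cfg_dict[key])
            config = ModelConfig(**cfg_dict)
            clf = (
                build_cnn_2d(config)
                if meta["kind"] == "cnn2d"
                else build_cnn_1d_onehot(config)
            )
            for li, layer in enumerate(clf.layers):
                for pi in range(len(layer.params)):
                    layer.params[pi][...] = data[f"layer{li}_param{pi}"]
        clf.history = meta["history"]
        clf.trained = meta["trained"]
        return clf


def build_cnn_2d(config: ModelConfig) -> TrainedClassifier:
    """Assemble the untrained 2D CNN over grid_side x grid_side x C input.

    Raises before any training if the configured geometry cannot reach a
    whole-numbered feature map (e.g. pooling windows that do not divide the
    input side).
    """
    rng = np.random.default_rng(config.seed)
    f = config.filters
    k = config.conv_kernel_size
    a = config.leaky_relu_alpha
    s = config.conv_strides
    p1, p2 = config.pool_sizes
    side = config.grid_side
    for stride in s[:2]:
        side = -(-side // stride)
    if side % p1:
        raise ValueError(f"pool size {p1} does not divide feature side {side}")
    side //= p1
    for stride in s[2:]:
        side = -(-side // stride)
    if side % p2:
        raise ValueError(f"pool size {p2} does not divide feature side {side}")
    side //= p2
    layers: List[nn.Layer] = [
        nn.Conv2D(config.input_channels, f[0], k, rng, stride=s[0], input_layer=True),
        nn.LeakyReLU(a),
        nn.Conv2D(f[0], f[1], k, rng, stride=s[1]),
        nn.LeakyReLU(a),
        nn.MaxPool2D(p1),
        nn.Conv2D(f[1], f[2], k, rng, stride=s[2]),
        nn.LeakyReLU(a),
        nn.Conv2D(f[2], f[3], k, rng, stride=s[3]),
        nn.LeakyReLU(a),
        nn.MaxPool2D(p2),
        nn.Dropout(config.dropout_rate, rng),
        nn.Flatten(),
        nn.Dense(side * side * f[3], config.hidden_units, rng),
        nn.LeakyReLU(a),
        nn.Dense(config.hidden_units, 1, rng),
    ]
    return TrainedClassifier(layers, config, "cnn2d")


def build_cnn_1d_onehot(config: ModelConfig) -> TrainedClassifier:
    """Assemble the untrained 1D baseline CNN over L x 20 one-hot input."""
    rng = np.random.default_rng(config.seed)
    f = config.filters
    k = config.conv_kernel_size
    a = config.leaky_relu_alpha
    p1, p2 = config.pool_sizes
    length = config.input_length
    lo = (length // p1) // p2
    layers: List[nn.Layer] = [
        nn.Conv1D(20, f[0], k, rng),
        nn.LeakyReLU(a),
        nn.Conv1D(f[0], f[1], k, rng),
        nn.LeakyReLU(a),
        nn.MaxPool1D(p1),
        nn.Conv1D(f[1], f[2], k, rng),
        nn.LeakyReLU(a),
        nn.Conv1D(f[2], f[3], k, rng),
        nn.LeakyReLU(a),
        nn.MaxPool1D(p2),
        nn.Dropout(config.dropout_rate, rng),
        nn.Flatten(),
        nn.Dense(lo * f[3], config.hidden_units, rng),
        nn.LeakyReLU(a),
        nn.Dense(config.hidden_units, 1, rng),
    ]
    return TrainedClassifier(layers, config, "cnn1d")


def train(
    classifier: TrainedClassifier,
    tensors: np.ndarray,
    labels: Sequence[int],
    epochs: Optional[int] = None,
    validation: Optional[Tuple[np.ndarray, Sequence[int]]] = None,
    verbose: bool = False,
) -> TrainedClassifier:
    """Fit with Adam on binary cross-entropy; records per-epoch loss.

    ``tensors`` is (N, H, W, C) for the 2D model or (N, L, 20) for the 1D
    baseline.  A NaN loss aborts with diagnostics rather than training on.
    """
    cfg = classifier.config
    x = np.ascontiguousarray(tensors, dtype=np.float32)
    y = np.asarray(labels, dtype=np.float32)
    if x.shape[0] != y.shape[0]:
        raise ValueError("tensors and labels must have equal length")
    n_epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(classifier.layers, lr=cfg.learning_rate)
    n = x.shape[0]
    for epoch in range(n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = classifier.forward_logits(x[idx], training=True)
            loss = nn.bce_with_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: loss={loss} at epoch {epoch}, "
                    f"batch starting {start} (lr={cfg.learning_rate})"
                )
            losses.append(loss)
            classifier.backward(nn.bce_with_logits_grad(logits, y[idx]))
            opt.step()
        epoch_loss = float(np.mean(losses))
        classifier.history["loss"].append(epoch_loss)
        if validation is not None:
            vx, vy = validation
            vscores = predict(classifier, vx)
            vacc = float(np.mean((vscores > 0.5) == (np.asarray(vy) == 1)))
            classifier.history.setdefault("val_acc", []).append(vacc)
        if verbose:
            msg = f"epoch {epoch + 1}/{n_epochs} loss={epoch_loss:.4f}"
            if validation is not None:
                msg += f" val_acc={classifier.history['val_acc'][-1]:.4f}"
            print(msg)
    classifier.trained = True
    return classifier


def predict(
    classifier: TrainedClassifier, tensors: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Per-pair interaction scores in [0, 1] (deterministic at inference)."""
    x = np.ascontiguousarray(tensors, dtype=np.float32)
    expected_ndim = 4 if classifier.kind == "cnn2d" else 3
    if x.ndim == expected_ndim - 1:  # single item convenience
        x = x[None]
    scores = []
    for start in range(0, x.shape[0], batch_size):
        logits = classifier.forward_logits(x[start : start + batch_size], training=False)
        scores.append(nn.sigmoid(logits))
    return np.concatenate(scores)


def predict_labels(
    classifier: TrainedClassifier, tensors: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Hard calls: positive iff score > threshold (strictly)."""
    return (predict(classifier, tensors) > threshold).astype(np.int64)
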