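"""The factorized pseudo-3D CNN for spatial-spectral EEG images.

Architecture (two convolution blocks, then a dense head):

    block b:  spatial conv (5 x 5 x 1) -> ReLU
              -> spectral conv (1 x 1 x 5)
              -> square -> conv-pool (2 x 2 x 2, stride 2, no padding)
              -> log
    head:     dropout(0.5) -> flatten -> FC(256, ReLU) -> FC(2) -> softmax

Batch normalization follows the 2nd and 6th convolution layers (conv
layers are counted spatial, spectral, conv-pool per block, so these are
the first block's spectral conv and the second block's conv-pool).  The
square -> pool -> log sequence turns each block into a log-power feature
extractor: with uniform pool weights it computes the log of a local mean
of squared activations.

The spatial and spectral convolutions use same-padding so that both
blocks accept the (5,5,1)/(1,1,5) kernel pair; only the stride-2
conv-pool (a learnable strided convolution, not max/average pooling)
shrinks the feature map.  Training is shuffled minibatch SGD on the
negative log-likelihood; everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .eeg_io import LEFT_FIST, RIGHT_FIST

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "forward",
    "nll_loss",
    "train",
    "P3DCNNClassifier",
    "reduced_configs",
]

CLASS_ORDER = (LEFT_FIST, RIGHT_FIST)


def mirror_lr(tensors: np.ndarray) -> np.ndarray:
    """Mirror feature tensors about the scalp midline (left <-> right).

    The electrode columns 1..9 of the 11 x 10 grid are symmetric about
    the midline column 5, which in the 100-pixel axis spans indices
    0..88; those are reversed, and the off-cap right-edge band (indices
    89..99, structurally near zero) is kept as is.  Because left- and
    right-fist imagery are mirror conditions, a mirrored trial is a
    physiologically valid sample of the opposite class — usable for
    augmentation and for symmetrized prediction.
    """
    tensors = np.asarray(tensors)
    out = tensors.copy()
    out[..., :89, :] = tensors[..., 88::-1, :]
    return out

#: Activation stages exposed for export / embedding visualization.
ACTIVATION_TAGS = ("raw", "conv1", "pool1", "pool2", "fc", "softmax")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``bn_after_layers`` indexes convolution layers 1..6 in forward
    order; ``input_transform`` is an optional feature preconditioning
    ('none', 'log', 'zscore', or 'log-zscore') applied identically at
    train and predict time.
    """

    input_shape: tuple[int, int, int] = (110, 100, 10)
    spatial_kernel: tuple[int, int, int] = (5, 5, 1)
    spectral_kernel: tuple[int, int, int] = (1, 1, 5)
    pool_kernel: tuple[int, int, int] = (2, 2, 2)
    pool_stride: int = 2
    n_filters_block1: int = 16
    n_filters_block2: int = 32
    fc_units: int = 256
    n_classes: int = 2
    dropout_p: float = 0.5
    bn_after_layers: tuple[int, ...] = (2, 6)
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5
    log_eps: float = 1e-6
    conv_padding: str = "same"
    input_transform: str = "none"
    #: average class probabilities with those of the left-right mirrored
    #: input (labels swapped) at predict time; valid because the two
    #: imagery classes are mirror conditions
    mirror_symmetrize: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.input_transform not in ("none", "log", "zscore", "log-zscore"):
            raise ValueError(f"unknown input_transform {self.input_transform!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (stock values: 500 epochs, lr 1e-3, batch 64)."""

    epochs: int = 500
    learning_rate: float = 0.001
    batch_size: int = 64
    momentum: float = 0.0
    weight_decay: float = 0.0
    clip_norm: float | None = None
    lr_decay_epochs: tuple[int, ...] = ()
    lr_decay_factor: float = 0.1
    #: extend the training set with left-right mirrored trials carrying
    #: the opposite label (hemispheric symmetry of the binary task)
    augment_mirror: bool = False
    #: average the weights of the final k epochs (0 = off); damps the
    #: late-phase SGD bounce
    average_tail: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")


class TrainedModel:
    """Layer stack plus configs, class order, and training history."""

    def __init__(self, layers, config: ModelConfig, tag_index: dict[str, int],
                 layer_shapes: list[tuple[str, tuple[int, ...]]]) -> None:
        self.layers = layers
        self.config = config
        self.tag_index = tag_index
        self.layer_shapes = layer_shapes
        self.classes: tuple[str, ...] = CLASS_ORDER[: config.n_classes]
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        self._norm_stats: tuple[np.ndarray, np.ndarray] | None = None

    # -- plumbing -----------------------------------------------------
    def params(self) -> list[nn.Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def _transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 4:
            x = x[..., None]  # add channel axis
        mode = self.config.input_transform
        if mode in ("log", "log-zscore"):
            x = np.log10(np.maximum(x, 1e-12))
        if mode in ("zscore", "log-zscore"):
            if self._norm_stats is None:
                raise RuntimeError("z-score transform requires fitting first")
            mean, std = self._norm_stats
            x = (x - mean) / std
        return x

    def fit_transform_stats(self, x: np.ndarray) -> None:
        """Record per-pixel standardization stats from the training set."""
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 4:
            x = x[..., None]
        if self.config.input_transform in ("log", "log-zscore"):
            x = np.log10(np.maximum(x, 1e-12))
        self._norm_stats = (x.mean(axis=0), x.std(axis=0) + nn.DTYPE(1e-6))

    # -- inference ----------------------------------------------------
    def logits(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._transform(batch)
        expected = self.config.input_shape
        if x.shape[1:4] != expected:
            raise ValueError(f"batch shaped {x.shape[1:4]}, model expects {expected}")
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def predict_proba(self, batch: np.ndarray, chunk: int = 32) -> np.ndarray:
        out = [
            nn.softmax(self.logits(batch[i : i + chunk]))
            for i in range(0, len(batch), chunk)
        ]
        probs = np.concatenate(out, axis=0)
        if self.config.mirror_symmetrize and self.config.n_classes == 2:
            mirrored = np.asarray(batch)
            mirrored = mirror_lr(mirrored if mirrored.ndim == 4 else mirrored[..., 0])
            flipped = self.predict_proba_raw(mirrored, chunk)[:, ::-1]
            probs = 0.5 * (probs + flipped)
        return probs

    def predict_proba_raw(self, batch: np.ndarray, chunk: int = 32) -> np.ndarray:
        """Probabilities without mirror symmetrization."""
        out = [
            nn.softmax(self.logits(batch[i : i + chunk]))
            for i in range(0, len(batch), chunk)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.predict_proba(batch), axis=1)
        return np.asarray(self.classes)[idx]

    def activations(self, batch: np.ndarray, tag: str) -> np.ndarray:
        """Flattened activations at a named stage, ``[n x d]``."""
        if tag not in ACTIVATION_TAGS:
            raise ValueError(f"unknown tag {tag!r}; valid tags: {ACTIVATION_TAGS}")
        x = self._transform(batch)
        if tag == "raw":
            return x.reshape(x.shape[0], -1)
        stop = self.tag_index[tag]
        for layer in self.layers[: stop + 1]:
            x = layer.forward(x, training=False)
        if tag == "softmax":
            x = nn.softmax(x)
        return x.reshape(x.shape[0], -1)

    # -- persistence --------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, nn.BatchNorm):
                arrays[f"bn_{i}_mean"] = layer.running_mean
                arrays[f"bn_{i}_var"] = layer.running_var
        if self._norm_stats is not None:
            arrays["norm_mean"], arrays["norm_std"] = self._norm_stats
        arrays["config"] = np.array(repr(self.config))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as data:
            config: ModelConfig = eval(  # noqa: S307 - our own repr round-trip
                str(data["config"]), {"ModelConfig": ModelConfig}
            )
            model = build_model(config)
            for i, p in enumerate(model.params()):
                p.value = data[f"param_{i}"]
            for i, layer in enumerate(model.layers):
                if isinstance(layer, nn.BatchNorm):
                    layer.running_mean = data[f"bn_{i}_mean"]
                    layer.running_var = data[f"bn_{i}_var"]
            if "norm_mean" in data:
                model._norm_stats = (data["norm_mean"], data["norm_std"])
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0) -> TrainedModel:
    """Assemble an untrained network, validating layer shapes as it goes."""
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    shapes: list[tuple[str, tuple[int, ...]]] = []
    tag_index: dict[str, int] = {}
    shape = (*config.input_shape, 1)
    conv_counter = 0

    def add(layer: nn.Layer, tag: str | None = None) -> None:
        nonlocal shape
        shape = layer.output_shape(shape)
        layers.append(layer)
        shapes.append((layer.name, shape))
        if tag:
            tag_index[tag] = len(layers) - 1

    pool_stride = (config.pool_stride,) * 3
    filters = (config.n_filters_block1, config.n_filters_block2)
    for block, n_filters in enumerate(filters, start=1):
        cin = shape[-1]
        for kind, kernel, stride, padding, cout in (
            ("spatial", config.spatial_kernel, (1, 1, 1), config.conv_padding, n_filters),
            ("spectral", config.spectral_kernel, (1, 1, 1), config.conv_padding, n_filters),
            ("pool", config.pool_kernel, pool_stride, "valid", n_filters),
        ):
            conv_counter += 1
            conv = nn.Conv3D(
                cin, cout, kernel, stride=stride, padding=padding, rng=rng,
                name=f"conv{conv_counter}_{kind}{block}",
                # Conv-pool layers start as jittered average pooling so the
                # square -> pool -> log chain begins as a well-conditioned
                # log-power feature (positive log inputs, live gradients).
                init="averaging" if kind == "pool" else "glorot",
            )
            tag = None
            if kind == "spatial" and block == 1:
                tag = "conv1"
            add(conv, tag)
            cin = cout
            # BN attached to a conv-pool goes after the log: centering
            # the strictly positive pooled squares before the log would
            # clamp half the units at log(eps) and kill their gradients.
            wants_bn = conv_counter in config.bn_after_layers
            if wants_bn and kind != "pool":
                add(nn.BatchNorm(cout, config.bn_momentum, config.bn_eps,
                                 name=f"bn{conv_counter}"))
            if kind == "spatial":
                add(nn.ReLU())
            elif kind == "spectral":
                add(nn.Square())
            else:
                add(nn.Log(config.log_eps), tag=f"pool{block}")
                if wants_bn:
                    add(nn.BatchNorm(cout, config.bn_momentum, config.bn_eps,
                                     name=f"bn{conv_counter}"))

    add(nn.Dropout(config.dropout_p, rng=np.random.default_rng(seed + 1)))
    add(nn.Flatten())
    add(nn.Dense(shape[0], config.fc_units, rng=rng, name="fc"))
    add(nn.ReLU(), tag="fc")
    out = nn.Dense(config.fc_units, config.n_classes, rng=rng, name="out")
    # Zero-init the output layer: logits start at 0, so a balanced
    # problem starts at the chance loss ln(K) and no class is preferred.
    out.weight.value[:] = 0.0
    add(out, tag="softmax")
    return TrainedModel(layers, config, tag_index, shapes)


def forward(model: TrainedModel, batch: np.ndarray) -> np.ndarray:
    """Eval-mode class probabilities, ``[n x K]`` rows summing to 1."""
    return model.predict_proba(batch)


def nll_loss(probabilities: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log-likelihood of the true class.

    ``labels`` are integer class indices.  Zero probabilities at the
    true class are clamped to ``eps`` (with a warning) rather than
    producing an infinite loss.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    p_true = probabilities[np.arange(len(labels)), labels]
    if np.any(p_true <= 0):
        warnings.warn("zero probability at true class; clamping", RuntimeWarning)
        p_true = np.maximum(p_true, eps)
    return float(-np.log(p_true).mean())


def _encode_labels(labels: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lookup[l] for l in labels])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in {classes}") from None


def train(
    model: TrainedModel,
    tensors: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Shuffled minibatch SGD on the NLL loss; records per-epoch history."""
    config = config or TrainConfig()
    y = _encode_labels(labels, model.classes)
    if config.batch_size > len(y):
        raise ValueError("batch_size exceeds training-set size")
    if config.augment_mirror:
        if model.config.n_classes != 2:
            raise ValueError("mirror augmentation requires the binary task")
        tensors = np.concatenate([tensors, mirror_lr(tensors)])
        y = np.concatenate([y, 1 - y])
    if model.config.input_transform in ("zscore", "log-zscore"):
        model.fit_transform_stats(tensors)

    rng = np.random.default_rng(config.seed)
    optimizer = nn.SGD(model.params(), config.learning_rate, config.momentum,
                       weight_decay=config.weight_decay)
    n = len(y)
    tail_sum, tail_count = None, 0
    for epoch in range(config.epochs):
        if epoch in config.lr_decay_epochs:
            optimizer.lr *= config.lr_decay_factor
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.logits(tensors[idx], training=True)
            loss, grad = nn.cross_entropy_with_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}; last finite "
                    f"losses: {model.history['loss'][-3:]}"
                )
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
            dy = grad
            for layer in reversed(model.layers):
                dy = layer.backward(dy)
            if config.clip_norm is not None:
                params = model.params()
                total = np.sqrt(sum(float((p.grad**2).sum()) for p in params))
                if total > config.clip_norm:
                    scale = config.clip_norm / total
                    for p in params:
                        p.grad *= scale
            optimizer.step()
        model.history["loss"].append(epoch_loss / n)
        model.history["accuracy"].append(correct / n)
        if config.average_tail and epoch >= config.epochs - config.average_tail:
            if tail_sum is None:
                tail_sum = [p.value.copy() for p in model.params()]
            else:
                for acc_p, p in zip(tail_sum, model.params()):
                    acc_p += p.value
            tail_count += 1
    if tail_sum is not None:
        for acc_p, p in zip(tail_sum, model.params()):
            p.value = acc_p / tail_count
    return model


def reduced_configs(
    seed: int = 0, epochs: int = 10
) -> tuple[ModelConfig, TrainConfig]:
    """Desk-scale preset: fewer filters, shorter schedule, log-z input.

    Used for simulation studies and the band scan, where the full
    500-epoch / 16-32-filter network is unnecessarily large.
    """
    model_cfg = ModelConfig(
        n_filters_block1=4,
        n_filters_block2=8,
        fc_units=64,
        input_transform="log-zscore",
        mirror_symmetrize=True,
    )
    train_cfg = TrainConfig(
        epochs=epochs, learning_rate=0.01, batch_size=16, momentum=0.9,
        weight_decay=1e-3, clip_norm=5.0,
        lr_decay_epochs=(max(1, 2 * epochs // 3),),
        augment_mirror=True, average_tail=3, seed=seed,
    )
    return model_cfg, train_cfg


class P3DCNNClassifier:
    """Scikit-learn-style facade: build + train on fit, labels on predict."""

    def __init__(self, model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None, seed: int = 0) -> None:
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.seed = seed
        self.model: TrainedModel | None = None

    @classmethod
    def reduced(cls, seed: int = 0, epochs: int = 10) -> "P3DCNNClassifier":
        model_cfg, train_cfg = reduced_configs(seed=seed, epochs=epochs)
        return cls(model_cfg, train_cfg, seed=seed)

    def fit(self, tensors: np.ndarray, labels: np.ndarray) -> "P3DCNNClassifier":
        self.model = build_model(self.model_config, seed=self.seed)
        train(self.model, tensors, labels, self.train_config)
        return self

    def predict(self, tensors: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit before predict")
        return self.model.predict(tensors)
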