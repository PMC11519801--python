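"""The spectral classifiers and their training/evaluation recipe.

The principal model is a 1-D CNN sized for 1015-point spectra:

    Conv1D(32 filters, kernel 3, stride 1, valid) -> ReLU -> Dropout ->
    MaxPool1D(pool 2, stride 2) -> Flatten -> Dense(32, ReLU, L2) ->
    Dense(1, sigmoid)

trained for 50 epochs of mini-batch (32) SGD with learning rate 0.01 and
momentum 0.9 on binary cross-entropy, with a reduce-on-plateau scheduler
(patience 10, floor 1e-5) watching the validation loss. Fully connected DNN
and MLP baselines share the recipe. ``mature`` is the positive class, so
sensitivity is mature-class recall and specificity immature-class recall.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.metrics import roc_curve

from . import _nn
from ._nn import (
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    Network,
    ReLU,
    ReduceLROnPlateau,
    SGDMomentum,
    bce_grad,
    bce_with_logits,
    conv_output_length,
    count_conv_params,
    count_dense_params,
    pool_output_length,
)
from .dataset import SpectraDataset
from .errors import ConfigError, DesignError, ShapeError
from .io import read_json, write_json

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainingResult",
    "EvaluationReport",
    "ARCHITECTURES",
    "conv_output_length",
    "pool_output_length",
    "count_conv_params",
    "build_model",
    "train",
    "predict",
    "evaluate",
    "labels_to_binary",
    "trapezoidal_auc",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

ARCHITECTURES = ("cnn", "dnn", "mlp")
POSITIVE_LABEL = "mature"
NEGATIVE_LABEL = "immature"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults = the published CNN)."""

    conv_filters: int = 32
    conv_kernel: int = 3
    conv_stride: int = 1
    dropout_rate: float = 0.25
    pool_size: int = 2
    pool_stride: int = 2
    dense_units: int = 32
    l2_coeff: float = 1e-4
    # fully connected baselines
    mlp_hidden: tuple[int, ...] = (64,)
    dnn_hidden: tuple[int, ...] = (128, 128, 128)

    def validate(self, input_len: int | None = None) -> "ModelConfig":
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.l2_coeff < 0:
            raise ConfigError(f"l2_coeff must be >= 0, got {self.l2_coeff}")
        if min(self.conv_filters, self.conv_kernel, self.conv_stride,
               self.pool_size, self.pool_stride, self.dense_units) < 1:
            raise ConfigError("all layer sizes/strides must be >= 1")
        if input_len is not None and self.conv_kernel > input_len:
            raise ShapeError(
                f"kernel {self.conv_kernel} exceeds input length {input_len}"
            )
        return self


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe (defaults = the published protocol)."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    scheduler_patience: int = 10
    scheduler_factor: float = 0.5
    min_learning_rate: float = 1e-5
    seed: int = 0
    decision_threshold: float = 0.5

    def validate(self) -> "TrainConfig":
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.min_learning_rate > self.learning_rate:
            raise ConfigError("min_learning_rate must not exceed learning_rate")
        if not 0.0 < self.scheduler_factor <= 1.0:
            raise ConfigError("scheduler_factor must be in (0, 1]")
        return self


@dataclass
class TrainingResult:
    """Per-epoch curves plus the effective learning-rate trajectory."""

    train_loss: list[float]
    val_loss: list[float]
    train_accuracy: list[float]
    val_accuracy: list[float]
    learning_rates: list[float]
    epochs_run: int
    model: Network

    def to_dict(self) -> dict[str, Any]:
        return {
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "train_accuracy": self.train_accuracy,
            "val_accuracy": self.val_accuracy,
            "learning_rates": self.learning_rates,
            "epochs_run": self.epochs_run,
        }


@dataclass
class EvaluationReport:
    """Confusion counts (mature = positive), rates, ROC points and AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    probabilities: np.ndarray
    true_labels: np.ndarray
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict[str, Any]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n": self.n,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "threshold": self.threshold,
            "roc_fpr": np.asarray(self.roc_fpr).tolist(),
            "roc_tpr": np.asarray(self.roc_tpr).tolist(),
            "probabilities": np.asarray(self.probabilities).tolist(),
            "true_labels": np.asarray(self.true_labels).tolist(),
        }


# ---------------------------------------------------------------------------
# model construction


def build_model(
    arch: str,
    config: ModelConfig,
    input_len: int,
    seed: int = 0,
) -> tuple[Network, list[dict[str, Any]]]:
    """Construct a classifier and its layer-shape report.

    The shape report lists, per layer, the per-sample output shape and the
    trainable-parameter count. The batch dimension is omitted (framework
    shape listings often prepend the batch size, here 32, to these shapes).
    """
    config.validate(input_len)
    if arch not in ARCHITECTURES:
        raise ConfigError(f"unknown architecture {arch!r}; expected one of {ARCHITECTURES}")
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    report: list[dict[str, Any]] = []

    def add(layer: _nn.Layer, name: str, out_shape: tuple[int, ...]) -> None:
        layers.append(layer)
        report.append({"layer": name, "output_shape": out_shape, "params": layer.n_params})

    if arch == "cnn":
        conv_len = conv_output_length(input_len, config.conv_kernel, config.conv_stride)
        pool_len = pool_output_length(conv_len, config.pool_size, config.pool_stride)
        flat = pool_len * config.conv_filters
        add(Conv1D(config.conv_filters, config.conv_kernel, config.conv_stride, rng),
            "conv1d", (conv_len, config.conv_filters))
        add(ReLU(), "relu", (conv_len, config.conv_filters))
        add(Dropout(config.dropout_rate), "dropout", (conv_len, config.conv_filters))
        add(MaxPool1D(config.pool_size, config.pool_stride),
            "maxpool1d", (pool_len, config.conv_filters))
        add(Flatten(), "flatten", (flat,))
        add(Dense(flat, config.dense_units, rng, l2=config.l2_coeff),
            "dense_relu_l2", (config.dense_units,))
        add(ReLU(), "relu", (config.dense_units,))
        add(Dense(config.dense_units, 1, rng), "dense_sigmoid", (1,))
    else:
        hidden = config.mlp_hidden if arch == "mlp" else config.dnn_hidden
        width_in = input_len
        for units in hidden:
            add(Dense(width_in, units, rng), "dense", (units,))
            add(ReLU(), "relu", (units,))
            if arch == "dnn":
                add(Dropout(config.dropout_rate), "dropout", (units,))
            width_in = units
        add(Dense(width_in, 1, rng), "dense_sigmoid", (1,))

    return Network(layers, input_len, arch=arch), report


# ---------------------------------------------------------------------------
# label handling


def labels_to_binary(dataset: SpectraDataset, *, context: str) -> np.ndarray:
    labels = dataset.labels
    unknown = labels == "unknown"
    if unknown.any():
        sid = dataset.spectrum_ids[unknown][0]
        raise DesignError(f"{context}: spectrum {sid!r} is unlabeled")
    return (labels == POSITIVE_LABEL).astype(np.float32)


# ---------------------------------------------------------------------------
# training


def train(
    model: Network,
    train_set: SpectraDataset,
    val_set: SpectraDataset,
    config: TrainConfig = TrainConfig(),
) -> TrainingResult:
    """Mini-batch SGD-with-momentum training on binary cross-entropy.

    Deterministic for a fixed seed (one numpy Generator drives shuffling and
    dropout). Reported losses include the L2 penalty; the learning-rate
    trajectory is non-increasing and floored at ``min_learning_rate``.
    Spectra outside [0, 1] trigger a warning (the recipe assumes max-min
    normalized input) but training proceeds.
    """
    config.validate()
    if train_set.n_spectra == 0 or val_set.n_spectra == 0:
        raise DesignError("training and validation sets must both be non-empty")
    y_train = labels_to_binary(train_set, context="training set")
    y_val = labels_to_binary(val_set, context="validation set")
    if len(np.unique(y_train)) < 2:
        raise DesignError("training set contains a single class; need both labels")

    X_train = train_set.intensities.astype(np.float32)
    X_val = val_set.intensities.astype(np.float32)
    if X_train.size and (X_train.min() < -1e-6 or X_train.max() > 1 + 1e-6):
        warnings.warn(
            "training spectra fall outside [0, 1]; the recipe expects "
            "max-min normalized input",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    optimizer = SGDMomentum(model, config.learning_rate, config.momentum)
    scheduler = ReduceLROnPlateau(
        optimizer, config.scheduler_patience, config.scheduler_factor,
        config.min_learning_rate,
    )

    curves: dict[str, list[float]] = {
        "train_loss": [], "val_loss": [], "train_acc": [], "val_acc": [], "lr": [],
    }
    n = X_train.shape[0]
    for _ in range(config.epochs):
        lr_in_effect = optimizer.lr
        perm = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            logits = model.forward(xb, train=True, rng=rng)
            loss = bce_with_logits(logits, yb)
            model.backward(bce_grad(logits, yb).astype(np.float32))
            optimizer.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int(np.sum((logits >= 0.0) == (yb >= 0.5)))
        penalty = model.l2_penalty()
        p_val = model.predict_proba(X_val)
        val_logit_loss = float(
            np.mean(-(y_val * np.log(np.clip(p_val, 1e-12, 1.0))
                      + (1 - y_val) * np.log(np.clip(1 - p_val, 1e-12, 1.0))))
        )
        val_loss = val_logit_loss + penalty
        curves["train_loss"].append(epoch_loss / n + penalty)
        curves["train_acc"].append(epoch_correct / n)
        curves["val_loss"].append(val_loss)
        curves["val_acc"].append(float(np.mean((p_val >= 0.5) == (y_val >= 0.5))))
        curves["lr"].append(lr_in_effect)
        scheduler.step(val_loss)

    model.trained = True
    logger.info(
        "trained %s: %d epochs, final val_loss=%.4g val_acc=%.4f",
        model.arch, config.epochs, curves["val_loss"][-1], curves["val_acc"][-1],
    )
    return TrainingResult(
        curves["train_loss"], curves["val_loss"],
        curves["train_acc"], curves["val_acc"], curves["lr"],
        epochs_run=config.epochs, model=model,
    )


def predict(model: Network, dataset: SpectraDataset) -> np.ndarray:
    """Per-spectrum mature-class probability, in input order."""
    if dataset.n_points != model.input_len:
        raise ShapeError(
            f"dataset axis length {dataset.n_points} != model input {model.input_len}"
        )
    return model.predict_proba(dataset.intensities)


# ---------------------------------------------------------------------------
# evaluation


def trapezoidal_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under an ROC polyline by the trapezoidal rule."""
    return float(np.trapezoid(tpr, fpr))


def evaluate(
    model: Network,
    test_set: SpectraDataset,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Confusion counts, accuracy/sensitivity/specificity, ROC and AUC.

    Ties at the threshold predict the positive (mature) class. With a
    single-class test set the AUC is undefined and reported as ``None``;
    the threshold metrics are still returned.
    """
    y = labels_to_binary(test_set, context="evaluation set")
    probs = predict(model, test_set)
    pred = probs >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    n = len(y)
    accuracy = (tp + tn) / n if n else float("nan")
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    if len(np.unique(y)) < 2:
        logger.warning("single-class evaluation set: AUC undefined")
        fpr = tpr = np.array([])
        auc = None
    else:
        fpr, tpr, _ = roc_curve(y, probs, drop_intermediate=False)
        auc = trapezoidal_auc(fpr, tpr)
    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        auc=auc, roc_fpr=fpr, roc_tpr=tpr,
        probabilities=probs, true_labels=test_set.labels.copy(),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# persistence


def save_model(model: Network, config: ModelConfig, path: str | Path) -> Path:
    """Persist weights (npz) plus an architecture sidecar (json)."""
    path = Path(path)
    np.savez(path, **model.state_arrays())
    meta = {
        "arch": model.arch,
        "input_len": model.input_len,
        "trained": model.trained,
        "config": config.__dict__ | {
            "mlp_hidden": list(config.mlp_hidden), "dnn_hidden": list(config.dnn_hidden)
        },
    }
    write_json(meta, path.with_suffix(".json"))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> tuple[Network, ModelConfig]:
    path = Path(path)
    meta = read_json(path.with_suffix(".json"))
    cfg_dict = dict(meta["config"])
    cfg_dict["mlp_hidden"] = tuple(cfg_dict["mlp_hidden"])
    cfg_dict["dnn_hidden"] = tuple(cfg_dict["dnn_hidden"])
    config = ModelConfig(**cfg_dict)
    model, _ = build_model(meta["arch"], config, meta["input_len"])
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    with np.load(npz_path) as data:
        model.load_state_arrays({k: data[k] for k in data.files})
    model.trained = bool(meta["trained"])
    return model, config


def clone_untrained(model_config: ModelConfig, arch: str, input_len: int, seed: int) -> Network:
    """Fresh, reinitialized network of the same architecture."""
    net, _ = build_model(arch, model_config, input_len, seed=seed)
    return net


def with_seed(config: TrainConfig, seed: int) -> TrainConfig:
    return replace(config, seed=int(seed))
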