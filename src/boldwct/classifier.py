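"""A small 3-block convolutional network for scalogram classification.

Architecture: three blocks of [3x3 same-padding
convolution -> ReLU -> 2x2 max pooling], followed by flattening and a dense
softmax head over 2 or 4 classes.  Default training settings: batch size 32,
20 epochs, learning rate 5e-4, Adam (SGDM and RMSprop are available for the
optimizer-comparison harness).

The network is implemented directly on NumPy arrays, which keeps training
fully deterministic for a given seed: identical data and seed give bit-
identical weights.  Inputs are (N, H, W, 3) float arrays scaled to [0, 1];
smaller image sizes and filter counts preserve every interface contract and
are what the test-scale experiments use.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ClassifierError(ValueError):
    """Raised for invalid model configuration or data."""


OPTIMIZERS = ("adam", "sgdm", "rmsprop")


@dataclasses.dataclass(frozen=True)
class CnnConfig:
    """Shape of the network. Exactly three conv blocks; filter counts and
    input size are configurable (defaults: 8/16/32 filters on 224x224x3)."""

    filters_per_block: tuple[int, int, int] = (8, 16, 32)
    kernel_size: int = 3
    pool_size: int = 2
    input_shape: tuple[int, int, int] = (224, 224, 3)

    def __post_init__(self) -> None:
        if len(self.filters_per_block) != 3:
            raise ClassifierError("exactly three conv blocks are required")
        if any(f < 1 for f in self.filters_per_block):
            raise ClassifierError("filter counts must be >= 1")
        if self.kernel_size != 3 or self.pool_size != 2:
            raise ClassifierError("only 3x3 kernels with 2x2 pooling are supported")
        h, w, c = self.input_shape
        if h < 8 or w < 8 or c < 1:
            raise ClassifierError("input_shape too small for three pooling stages")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 20
    learning_rate: float = 5e-4
    optimizer: str = "adam"
    rng_seed: int = 0
    momentum: float = 0.9  # SGDM
    rms_decay: float = 0.9  # RMSprop

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ClassifierError("batch_size, epochs, learning_rate must be positive")
        if self.optimizer not in OPTIMIZERS:
            raise ClassifierError(f"optimizer must be one of {OPTIMIZERS}")


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class CnnModel:
    """Forward/backward passes of the 3-block CNN on NumPy arrays."""

    def __init__(self, config: CnnConfig, n_classes: int, rng_seed: int = 0) -> None:
        if n_classes not in (2, 4):
            raise ClassifierError("n_classes must be 2 (binary) or 4 (subtype) ")
        self.config = config
        self.n_classes = n_classes
        rng = np.random.default_rng(rng_seed)

        h, w, c_in = config.input_shape
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        for f in config.filters_per_block:
            fan_in = 9 * c_in
            self.conv_w.append(_he_init(rng, (3, 3, c_in, f), fan_in))
            self.conv_b.append(np.zeros(f))
            c_in = f
            h, w = h // 2, w // 2
        self.flat_dim = h * w * c_in
        self.dense_w = _he_init(rng, (self.flat_dim, n_classes), self.flat_dim)
        self.dense_b = np.zeros(n_classes)

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        for w, b in zip(self.conv_w, self.conv_b):
            params.extend((w, b))
        params.extend((self.dense_w, self.dense_b))
        return params

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- layers -----------------------------------------------------------
    @staticmethod
    def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, h, wd, _ = x.shape
        f = w.shape[3]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.tile(b, (n, h, wd, 1)).astype(float)
        for ki in range(3):
            for kj in range(3):
                patch = xp[:, ki:ki + h, kj:kj + wd, :]
                out += patch.reshape(-1, patch.shape[3]).dot(w[ki, kj]).reshape(n, h, wd, f)
        return out, xp

    @staticmethod
    def _conv_backward(dout: np.ndarray, xp: np.ndarray, w: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n, h, wd, f = dout.shape
        dw = np.zeros_like(w)
        dxp = np.zeros_like(xp)
        dflat = dout.reshape(-1, f)
        for ki in range(3):
            for kj in range(3):
                patch = xp[:, ki:ki + h, kj:kj + wd, :]
                dw[ki, kj] = patch.reshape(-1, patch.shape[3]).T.dot(dflat)
                dxp[:, ki:ki + h, kj:kj + wd, :] += dflat.dot(w[ki, kj].T).reshape(
                    n, h, wd, w.shape[2]
                )
        db = dout.sum(axis=(0, 1, 2))
        dx = dxp[:, 1:-1, 1:-1, :]
        return dx, dw, db

    @staticmethod
    def _pool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
        n, h, wd, c = x.shape
        h2, w2 = h // 2, wd // 2
        r = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        r = r.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        idx = np.argmax(r, axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        return out, idx, x.shape

    @staticmethod
    def _pool_backward(dout: np.ndarray, idx: np.ndarray, x_shape: tuple[int, ...]) -> np.ndarray:
        n, h, wd, c = x_shape
        h2, w2 = h // 2, wd // 2
        dr = np.zeros((n, h2, w2, c, 4))
        np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(x_shape)
        dx[:, : 2 * h2, : 2 * w2, :] = dr.reshape(n, 2 * h2, 2 * w2, c)
        return dx

    # -- full passes -------------------------------------------------------
    def forward(self, x: np.ndarray, with_cache: bool = False):
        if x.ndim != 4 or x.shape[1:] != self.config.input_shape:
            raise ClassifierError(
                f"input shape {x.shape[1:]} does not match configured "
                f"{self.config.input_shape}"
            )
        cache: list = []
        a = np.asarray(x, dtype=float)
        for w, b in zip(self.conv_w, self.conv_b):
            z, xp = self._conv_forward(a, w, b)
            relu_mask = z > 0
            a = z * relu_mask
            a, idx, shp = self._pool_forward(a)
            cache.append((xp, relu_mask, idx, shp))
        flat = a.reshape(a.shape[0], -1)
        logits = flat.dot(self.dense_w) + self.dense_b
        logits -= logits.max(axis=1, keepdims=True) if logits.size else 0
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True) if logits.size else exp
        if with_cache:
            return probs, (cache, flat, a.shape)
        return probs

    def backward(self, probs: np.ndarray, labels: np.ndarray, fwd_cache) -> list[np.ndarray]:
        cache, flat, last_shape = fwd_cache
        n = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        d_dense_w = flat.T.dot(dlogits)
        d_dense_b = dlogits.sum(axis=0)
        da = dlogits.dot(self.dense_w.T).reshape(last_shape)

        grads_conv: list[tuple[np.ndarray, np.ndarray]] = []
        for (xp, relu_mask, idx, shp), w in zip(reversed(cache), reversed(self.conv_w)):
            dz = self._pool_backward(da, idx, shp)
            dz *= relu_mask
            da, dw, db = self._conv_backward(dz, xp, w)
            grads_conv.append((dw, db))
        grads: list[np.ndarray] = []
        for dw, db in reversed(grads_conv):
            grads.extend((dw, db))
        grads.extend((d_dense_w, d_dense_b))
        return grads


class _Optimizer:
    def __init__(self, params: list[np.ndarray], config: TrainConfig) -> None:
        self.params = params
        self.lr = config.learning_rate
        self.kind = config.optimizer
        self.momentum = config.momentum
        self.rms_decay = config.rms_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        eps = 1e-8
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.kind == "adam":
                m *= 0.9
                m += 0.1 * g
                v *= 0.999
                v += 0.001 * g * g
                m_hat = m / (1 - 0.9**self.t)
                v_hat = v / (1 - 0.999**self.t)
                p -= self.lr * m_hat / (np.sqrt(v_hat) + eps)
            elif self.kind == "sgdm":
                m *= self.momentum
                m += g
                p -= self.lr * m
            else:  # rmsprop
                v *= self.rms_decay
                v += (1 - self.rms_decay) * g * g
                p -= self.lr * g / (np.sqrt(v) + eps)


@dataclasses.dataclass
class TrainedModel:
    """Trained network, class-label ordering and per-epoch history."""

    model: CnnModel
    class_names: list[str]
    history: dict[str, list[float]]

    def save(self, path: str | Path) -> Path:
        """Checkpoint: .npz of weights + JSON history sidecar."""
        path = Path(path)
        arrays = {f"param_{i}": p for i, p in enumerate(self.model.parameters())}
        np.savez(
            path.with_suffix(".npz"),
            **arrays,
            meta=json.dumps(
                {
                    "class_names": self.class_names,
                    "n_classes": self.model.n_classes,
                    "config": dataclasses.asdict(self.model.config),
                }
            ),
        )
        hist_path = path.with_suffix(".history.json")
        hist_path.write_text(json.dumps(self.history, indent=1))
        return path.with_suffix(".npz")

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        data = np.load(Path(path), allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg = meta["config"]
        cfg["filters_per_block"] = tuple(cfg["filters_per_block"])
        cfg["input_shape"] = tuple(cfg["input_shape"])
        model = CnnModel(CnnConfig(**cfg), meta["n_classes"])
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"param_{i}"]
        hist_path = Path(path).with_suffix("").with_suffix(".history.json")
        history = json.loads(hist_path.read_text()) if hist_path.exists() else {}
        return TrainedModel(model=model, class_names=meta["class_names"], history=history)


def build_model(config: CnnConfig, n_classes: int, rng_seed: int = 0) -> CnnModel:
    """Untrained 3-block CNN emitting ``n_classes`` softmax probabilities."""
    return CnnModel(config, n_classes, rng_seed)


def _check_images(images: np.ndarray, config: CnnConfig) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if images.ndim != 4 or images.shape[1:] != config.input_shape:
        raise ClassifierError(
            f"images have shape {images.shape}, expected (N, {config.input_shape})"
        )
    return images


def train(
    model: CnnModel,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: Optional[np.ndarray] = None,
    val_labels: Optional[np.ndarray] = None,
    config: TrainConfig = TrainConfig(),
    class_names: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Mini-batch training with seeded shuffling; history length == epochs."""
    x = _check_images(train_images, model.config)
    y = np.asarray(train_labels, dtype=int)
    if x.shape[0] != y.size or x.shape[0] == 0:
        raise ClassifierError("empty training set or image/label count mismatch")
    present = np.unique(y)
    if present.size < 2:
        raise ClassifierError("training set covers a single class; need all classes")
    if present.min() < 0 or present.max() >= model.n_classes:
        raise ClassifierError("labels out of range for model's class count")

    rng = np.random.default_rng(config.rng_seed)
    opt = _Optimizer(model.parameters(), config)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    has_val = val_images is not None and val_labels is not None
    if has_val:
        xv = _check_images(val_images, model.config)
        yv = np.asarray(val_labels, dtype=int)
        history["val_loss"] = []
        history["val_accuracy"] = []

    n = x.shape[0]
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses, hits, seen = 0.0, 0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            probs, cache = model.forward(xb, with_cache=True)
            eps = 1e-12
            losses += -np.log(probs[np.arange(yb.size), yb] + eps).sum()
            hits += int((probs.argmax(axis=1) == yb).sum())
            seen += yb.size
            grads = model.backward(probs, yb, cache)
            opt.step(grads)
        history["loss"].append(losses / seen)
        history["accuracy"].append(hits / seen)
        if has_val:
            pv = _predict_probs(model, xv)
            history["val_loss"].append(
                float(-np.log(pv[np.arange(yv.size), yv] + 1e-12).mean())
            )
            history["val_accuracy"].append(float((pv.argmax(axis=1) == yv).mean()))

    names = list(class_names) if class_names is not None else [
        str(i) for i in range(model.n_classes)
    ]
    return TrainedModel(model=model, class_names=names, history=history)


def _predict_probs(model: CnnModel, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    if images.shape[0] == 0:
        return np.empty((0, model.n_classes))
    chunks = [
        model.forward(images[i:i + batch_size])
        for i in range(0, images.shape[0], batch_size)
    ]
    return np.vstack(chunks)


def predict(
    trained: TrainedModel | CnnModel,
    images: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (rows sum to 1) and argmax labels.

    Ties resolve to the lowest class index.  An empty batch yields empty
    outputs.
    """
    model = trained.model if isinstance(trained, TrainedModel) else trained
    images = _check_images(
        images if images.size else np.empty((0, *model.config.input_shape)),
        model.config,
    )
    probs = _predict_probs(model, images)
    labels = probs.argmax(axis=1) if probs.size else np.empty(0, dtype=int)
    return probs, labels


def optimizer_sweep(
    cnn_config: CnnConfig,
    n_classes: int,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    base_config: TrainConfig = TrainConfig(),
    optimizers: Sequence[str] = OPTIMIZERS,
) -> pd.DataFrame:
    """Train one model per optimizer under otherwise identical settings.

    Returns a comparable report with final training and validation accuracy
    per optimizer (the optimizer-comparison harness).
    """
    rows = []
    for opt in optimizers:
        cfg = dataclasses.replace(base_config, optimizer=opt)
        model = build_model(cnn_config, n_classes, rng_seed=cfg.rng_seed)
        trained = train(model, train_images, train_labels, val_images, val_labels, cfg)
        rows.append(
            {
                "optimizer": opt,
                "final_train_accuracy": trained.history["accuracy"][-1],
                "final_val_accuracy": trained.history["val_accuracy"][-1],
                "final_train_loss": trained.history["loss"][-1],
            }
        )
    return pd.DataFrame(rows)
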