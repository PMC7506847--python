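"""A 1D convolutional fall/non-fall classifier with a GAP head.

Architecture: three 1D convolutional layers (32, 64, 128 output channels,
kernel length 3, ReLU), max pooling (kernel 2, stride 2) after the first
two conv layers only, global average pooling over the temporal axis, and a
single linear layer mapping the 128 pooled values to 2 class logits
followed by softmax.  The first convolution spans all six input channels
(early fusion of accelerometer and gyroscope).

Keeping the last conv layer unpooled preserves a temporal feature sequence
``S_k(x)`` of length L (21 for a 100-sample input with valid convolutions)
from which the class activation map is formed; because the head consumes
only the GAP vector, the model is agnostic to the exact value of L.

The network, its backpropagation and the Adam optimizer are implemented
directly on NumPy arrays; the model is small enough (~32k parameters) that
desk-scale training runs in seconds per epoch on one CPU core.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imu import LABEL_FALL, LABEL_NON_FALL, ClassifierWindow

#: class index convention: fall is the positive class everywhere
CLASS_NON_FALL = 0
CLASS_FALL = 1
CLASS_NAMES = (LABEL_NON_FALL, LABEL_FALL)


@dataclass(frozen=True)
class NetworkConfig:
    channel_widths: tuple[int, int, int] = (32, 64, 128)
    kernel_len: int = 3
    pool_size: int = 2
    pool_stride: int = 2
    input_channels: int = 6
    input_len: int = 100
    n_classes: int = 2

    @property
    def final_len(self) -> int:
        """Temporal length L after the third conv layer (no padding)."""
        l = self.input_len
        for i in range(3):
            l = l - self.kernel_len + 1
            if l < 1:
                raise ValueError("config collapses temporal length below 1")
            if i < 2:
                l = (l - self.pool_size) // self.pool_stride + 1
                if l < 1:
                    raise ValueError(
                        "pooling collapses temporal length below 1"
                    )
        return l

    def validate(self) -> None:
        if len(self.channel_widths) != 3:
            raise ValueError("exactly 3 conv layers are required")
        if self.kernel_len < 1 or self.input_len < 1:
            raise ValueError("kernel_len and input_len must be >= 1")
        self.final_len  # raises if degenerate


@dataclass
class TrainSpec:
    """Training recipe: Adam, lr 1e-4, batch 4, cross-entropy loss."""

    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 50
    seed: int = 0
    split_ratio: float = 2.3  # train : test

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class FeatureMaps:
    """Per-window artifacts of a forward pass needed for the CAM.

    ``S`` has shape (128, L): the last conv layer's output sequence per
    channel.  ``f`` is its temporal mean (the GAP output) and ``logits``
    the pre-softmax class scores ``g_c = b_c + sum_k w_kc f_k``.
    """

    S: np.ndarray
    f: np.ndarray
    logits: np.ndarray


@dataclass
class TrainedClassifier:
    config: NetworkConfig
    params: dict[str, np.ndarray]
    history: list[dict] = field(default_factory=list)
    #: per-channel input standardization (fitted on the training set)
    norm_mean: np.ndarray = field(default_factory=lambda: np.zeros(6))
    norm_std: np.ndarray = field(default_factory=lambda: np.ones(6))

    @property
    def fc_weights(self) -> np.ndarray:
        """(n_classes, 128) head weights w_kc."""
        return self.params["fcW"]

    @property
    def fc_bias(self) -> np.ndarray:
        return self.params["fcb"]


def build_classifier(
    config: NetworkConfig | None = None, seed: int = 0
) -> TrainedClassifier:
    """He-initialized classifier; identical seeds give identical params."""
    config = config or NetworkConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    c1, c2, c3 = config.channel_widths
    k = config.kernel_len
    cin = config.input_channels

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    params = {
        "W1": he((c1, cin, k), cin * k),
        "b1": np.zeros(c1),
        "W2": he((c2, c1, k), c1 * k),
        "b2": np.zeros(c2),
        "W3": he((c3, c2, k), c2 * k),
        "b3": np.zeros(c3),
        "fcW": he((config.n_classes, c3), c3),
        "fcb": np.zeros(config.n_classes),
    }
    return TrainedClassifier(
        config=config,
        params=params,
        norm_mean=np.zeros(cin),
        norm_std=np.ones(cin),
    )


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _conv1d(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 1D convolution. X (B,Cin,L) x W (Cout,Cin,K) -> (B,Cout,L-K+1)."""
    K = W.shape[2]
    cols = np.lib.stride_tricks.sliding_window_view(X, K, axis=2)
    # cols: (B, Cin, Lout, K) -> (B, Cin*K, Lout)
    B, Cin, Lout, _ = cols.shape
    cols2 = cols.transpose(0, 1, 3, 2).reshape(B, Cin * K, Lout)
    Y = np.einsum("of,bfl->bol", W.reshape(W.shape[0], -1), cols2)
    return Y + b[None, :, None], cols2


def _conv1d_backward(dY, cols2, W, Lin):
    B, Cout, Lout = dY.shape
    K = W.shape[2]
    Wm = W.reshape(Cout, -1)
    dW = np.einsum("bol,bfl->of", dY, cols2).reshape(W.shape)
    db = dY.sum(axis=(0, 2))
    dcols = np.einsum("of,bol->bfl", Wm, dY)  # (B, Cin*K, Lout)
    dcols = dcols.reshape(B, W.shape[1], K, Lout)
    dX = np.zeros((B, W.shape[1], Lin))
    for k in range(K):
        dX[:, :, k : k + Lout] += dcols[:, :, k, :]
    return dX, dW, db


def _maxpool(X: np.ndarray, size: int, stride: int):
    B, C, L = X.shape
    Lout = (L - size) // stride + 1
    idx = stride * np.arange(Lout)[:, None] + np.arange(size)[None, :]
    windows = X[:, :, idx]  # (B, C, Lout, size)
    arg = windows.argmax(axis=3)
    Y = np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]
    return Y, (arg, idx, L)


def _maxpool_backward(dY, cache):
    arg, idx, L = cache
    B, C, Lout = dY.shape
    dX = np.zeros((B, C, L))
    # source index of each pooled max within the unpooled layer
    src = idx[np.arange(Lout)[None, None, :], arg]  # (B, C, Lout)
    b_i = np.repeat(np.arange(B), C * Lout)
    c_i = np.tile(np.repeat(np.arange(C), Lout), B)
    np.add.at(dX, (b_i, c_i, src.ravel()), dY.ravel())
    return dX


def _forward_batch(model: TrainedClassifier, X: np.ndarray, want_cache=False):
    """X (B, 6, 100) -> logits (B, 2); optionally the full cache."""
    p = model.params
    cfg = model.config
    Xn = (X - model.norm_mean[None, :, None]) / model.norm_std[None, :, None]
    z1, cols1 = _conv1d(Xn, p["W1"], p["b1"])
    a1 = np.maximum(z1, 0.0)
    p1, mp1 = _maxpool(a1, cfg.pool_size, cfg.pool_stride)
    z2, cols2 = _conv1d(p1, p["W2"], p["b2"])
    a2 = np.maximum(z2, 0.0)
    p2, mp2 = _maxpool(a2, cfg.pool_size, cfg.pool_stride)
    z3, cols3 = _conv1d(p2, p["W3"], p["b3"])
    S = np.maximum(z3, 0.0)  # (B, 128, L)
    f = S.mean(axis=2)
    logits = f @ p["fcW"].T + p["fcb"]
    if not want_cache:
        return logits, S, f
    cache = dict(
        Xn=Xn, z1=z1, cols1=cols1, p1=p1, mp1=mp1,
        z2=z2, cols2=cols2, p2=p2, mp2=mp2,
        z3=z3, cols3=cols3, S=S, f=f,
    )
    return logits, S, f, cache


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(
    model: TrainedClassifier, window: ClassifierWindow | np.ndarray
) -> tuple[FeatureMaps, np.ndarray]:
    """Run one window through the network.

    Returns the retained feature maps (for the CAM) and the softmax class
    probabilities ``(P(non_fall), P(fall))``.
    """
    data = window.data if isinstance(window, ClassifierWindow) else np.asarray(window)
    cfg = model.config
    if data.shape != (cfg.input_channels, cfg.input_len):
        raise ValueError(
            f"window shape {data.shape} != "
            f"({cfg.input_channels}, {cfg.input_len})"
        )
    logits, S, f = _forward_batch(model, data[None])
    fm = FeatureMaps(S=S[0], f=f[0], logits=logits[0])
    return fm, _softmax(logits[0])


def _loss_and_grads(model: TrainedClassifier, X, y):
    p = model.params
    cfg = model.config
    logits, S, f, c = _forward_batch(model, X, want_cache=True)
    B = len(y)
    probs = _softmax(logits)
    loss = -np.log(probs[np.arange(B), y] + 1e-12).mean()

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    g = {}
    g["fcW"] = dlogits.T @ c["f"]
    g["fcb"] = dlogits.sum(axis=0)
    df = dlogits @ p["fcW"]  # (B, 128)
    L3 = S.shape[2]
    dS = np.repeat(df[:, :, None] / L3, L3, axis=2)
    dz3 = dS * (c["z3"] > 0)
    dp2, g["W3"], g["b3"] = _conv1d_backward(
        dz3, c["cols3"], p["W3"], c["p2"].shape[2]
    )
    da2 = _maxpool_backward(dp2, c["mp2"])
    dz2 = da2 * (c["z2"] > 0)
    dp1, g["W2"], g["b2"] = _conv1d_backward(
        dz2, c["cols2"], p["W2"], c["p1"].shape[2]
    )
    da1 = _maxpool_backward(dp1, c["mp1"])
    dz1 = da1 * (c["z1"] > 0)
    _, g["W1"], g["b1"] = _conv1d_backward(
        dz1, c["cols1"], p["W1"], c["Xn"].shape[2]
    )
    return loss, g


def windows_to_arrays(
    windows: list[ClassifierWindow],
) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([w.data for w in windows])
    y = np.array([CLASS_FALL if w.label == LABEL_FALL else CLASS_NON_FALL
                  for w in windows])
    return X, y


def split_windows(
    windows: list[ClassifierWindow], ratio: float = 2.3, seed: int = 0
) -> tuple[list[ClassifierWindow], list[ClassifierWindow]]:
    """Stratified train/test split at ``ratio``:1 with a seeded shuffle."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    labels = np.array([w.label for w in windows])
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        n_train = round(len(idx) * ratio / (ratio + 1.0))
        train.extend(windows[i] for i in idx[:n_train])
        test.extend(windows[i] for i in idx[n_train:])
    return train, test


def train(
    model: TrainedClassifier,
    windows: list[ClassifierWindow],
    spec: TrainSpec | None = None,
    val_windows: list[ClassifierWindow] | None = None,
) -> TrainedClassifier:
    """Train with Adam on cross-entropy; returns the best checkpoint.

    Deterministic for a fixed seed and window order.  When a validation
    set is supplied, the parameters of the best-validation-accuracy epoch
    are restored at the end; otherwise the final epoch is kept.  Per-epoch
    loss/accuracy history is appended to ``model.history``.
    """
    spec = spec or TrainSpec()
    spec.validate()
    X, y = windows_to_arrays(windows)
    if len(np.unique(y)) < 2:
        raise ValueError(
            "training set is degenerate: both classes are required"
        )
    # per-channel standardization fitted on the training inputs
    model.norm_mean = X.mean(axis=(0, 2))
    model.norm_std = X.std(axis=(0, 2)) + 1e-8

    rng = np.random.default_rng(spec.seed)
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_acc, best_params = -1.0, None

    for epoch in range(spec.epochs):
        order = rng.permutation(len(y))
        losses = []
        for i in range(0, len(order), spec.batch_size):
            batch = order[i : i + spec.batch_size]
            loss, grads = _loss_and_grads(model, X[batch], y[batch])
            losses.append(loss)
            step += 1
            for k in model.params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                model.params[k] -= (
                    spec.learning_rate * mhat / (np.sqrt(vhat) + eps)
                )
        rec = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if val_windows:
            rec["val_accuracy"] = _accuracy(model, val_windows)
            if rec["val_accuracy"] > best_acc:
                best_acc = rec["val_accuracy"]
                best_params = copy.deepcopy(model.params)
        model.history.append(rec)

    if best_params is not None:
        model.params = best_params
    return model


def predict(
    model: TrainedClassifier, windows: list[ClassifierWindow]
) -> np.ndarray:
    """Predicted class indices (0 = non_fall, 1 = fall)."""
    X, _ = windows_to_arrays(windows)
    out = []
    for i in range(0, len(X), 64):
        logits, _, _ = _forward_batch(model, X[i : i + 64])
        out.append(logits.argmax(axis=1))
    return np.concatenate(out)


def _accuracy(model, windows) -> float:
    _, y = windows_to_arrays(windows)
    return float((predict(model, windows) == y).mean())


def evaluate_classifier(
    model: TrainedClassifier, windows: list[ClassifierWindow]
) -> "MetricsReport":
    """Confusion counts and metrics on a test set (fall = positive)."""
    from .metrics import metrics_from_counts

    if not windows:
        raise ValueError("cannot evaluate on an empty test set")
    _, y = windows_to_arrays(windows)
    pred = predict(model, windows)
    tp = int(np.sum((pred == CLASS_FALL) & (y == CLASS_FALL)))
    fn = int(np.sum((pred == CLASS_NON_FALL) & (y == CLASS_FALL)))
    tn = int(np.sum((pred == CLASS_NON_FALL) & (y == CLASS_NON_FALL)))
    fp = int(np.sum((pred == CLASS_FALL) & (y == CLASS_NON_FALL)))
    return metrics_from_counts(tp=tp, fn=fn, tn=tn, fp=fp)


# ---------------------------------------------------------------------------
# checkpoint I/O (format version 1)
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: TrainedClassifier, path: str | Path) -> None:
    """Single-file .npz checkpoint: config + parameters + history."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": {
            "channel_widths": list(model.config.channel_widths),
            "kernel_len": model.config.kernel_len,
            "pool_size": model.config.pool_size,
            "pool_stride": model.config.pool_stride,
            "input_channels": model.config.input_channels,
            "input_len": model.config.input_len,
            "n_classes": model.config.n_classes,
        },
        "history": model.history,
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        norm_mean=model.norm_mean,
        norm_std=model.norm_std,
        **model.params,
    )


def load_checkpoint(path: str | Path) -> TrainedClassifier:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta['version']}"
            )
        cfg_d = meta["config"]
        cfg_d["channel_widths"] = tuple(cfg_d["channel_widths"])
        config = NetworkConfig(**cfg_d)
        params = {
            k: z[k]
            for k in ("W1", "b1", "W2", "b2", "W3", "b3", "fcW", "fcb")
        }
        return TrainedClassifier(
            config=config,
            params=params,
            history=meta["history"],
            norm_mean=z["norm_mean"],
            norm_std=z["norm_std"],
        )
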