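"""Single-convolutional-layer CNN over raw EMG windows.

Architecture (default shapes for a 30 x 8 window): valid (unpadded) 3 x 3
convolution with 32 filters -> 28 x 6 x 32, ReLU, 3 x 1 max pooling with
stride equal to the pool size (floor division, remainder rows dropped)
-> 9 x 6 x 32, flatten, fully connected to 7 logits, softmax.  Parameter
counts at those shapes: conv 3*3*1*32 + 32 = 320, FC 9*6*32*7 + 7 = 12103.

Training is plain stochastic gradient descent with classical momentum
(v <- momentum*v - lr*grad; w <- w + v) on cross-entropy plus L2 weight
decay, shuffled mini-batches, and a fixed epoch budget — no early stopping
and no validation split.  Defaults: lr 0.1, L2 0.001, momentum 0.95,
batch 256, 25 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..dataset import ValidationError
from .ssae import softmax


class DivergenceError(RuntimeError):
    pass


@dataclass
class CNNConfig:
    n_filters: int = 32
    filter_shape: tuple[int, int] = (3, 3)
    pool_shape: tuple[int, int] = (3, 1)
    lr: float = 0.1
    l2: float = 0.001
    momentum: float = 0.95
    batch_size: int = 256
    max_epochs: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_filters, self.batch_size, self.max_epochs) < 1:
            raise ValidationError("n_filters, batch_size, max_epochs must be >= 1")
        if self.lr <= 0 or self.l2 < 0 or not 0 <= self.momentum < 1:
            raise ValidationError("require lr > 0, l2 >= 0, 0 <= momentum < 1")
        if min(self.filter_shape) < 1 or min(self.pool_shape) < 1:
            raise ValidationError("filter and pool shapes must be >= 1")


@dataclass
class CNNModel:
    conv_w: np.ndarray  # fh x fw x n_filters
    conv_b: np.ndarray  # n_filters
    fc_w: np.ndarray  # flat_dim x K
    fc_b: np.ndarray  # K
    classes: np.ndarray
    input_shape: tuple[int, int]  # L x C
    channel_mean: np.ndarray  # C (training-set statistics)
    channel_std: np.ndarray  # C
    config: CNNConfig
    loss_history: list[float] = field(default_factory=list)

    @property
    def pooled_shape(self) -> tuple[int, int]:
        fh, fw = self.conv_w.shape[:2]
        ph, pw = self.config.pool_shape
        oh = self.input_shape[0] - fh + 1
        ow = self.input_shape[1] - fw + 1
        return oh // ph, ow // pw

    def n_parameters(self) -> int:
        return sum(
            a.size for a in (self.conv_w, self.conv_b, self.fc_w, self.fc_b)
        )


def _normalize(model: CNNModel, X: np.ndarray) -> np.ndarray:
    return (X - model.channel_mean[None, None, :]) / model.channel_std[None, None, :]


def _forward(model: CNNModel, X: np.ndarray, cache: bool = False):
    """Batch forward pass; X is B x L x C, already normalized."""
    fh, fw = model.conv_w.shape[:2]
    nf = model.conv_w.shape[2]
    ph, pw = model.config.pool_shape
    b = X.shape[0]
    patches = sliding_window_view(X, (fh, fw), axis=(1, 2))  # B,oh,ow,fh,fw
    oh, ow = patches.shape[1], patches.shape[2]
    flat_patches = np.ascontiguousarray(patches.reshape(b, oh, ow, fh * fw))
    conv = (
        flat_patches.reshape(-1, fh * fw) @ model.conv_w.reshape(fh * fw, nf)
    ).reshape(b, oh, ow, nf) + model.conv_b
    relu = np.maximum(conv, 0.0)
    nh, nw = oh // ph, ow // pw
    if nh < 1 or nw < 1:
        raise ValidationError(
            f"pool {model.config.pool_shape} does not fit conv output "
            f"({oh} x {ow})"
        )
    # group into pool cells: B,nh,nw,nf,ph*pw ; floor discards remainder
    r = relu[:, : nh * ph, : nw * pw, :]
    r = r.reshape(b, nh, ph, nw, pw, nf).transpose(0, 1, 3, 5, 2, 4)
    r = r.reshape(b, nh, nw, nf, ph * pw)
    arg = np.argmax(r, axis=-1)  # first max wins on ties
    pooled = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]
    flat = pooled.reshape(b, nh * nw * nf)
    logits = flat @ model.fc_w + model.fc_b
    probs = softmax(logits)
    if not cache:
        return probs
    return probs, {
        "flat_patches": flat_patches,
        "conv": conv,
        "relu_shape": relu.shape,
        "arg": arg,
        "flat": flat,
        "dims": (oh, ow, nh, nw, ph, pw, fh, fw, nf),
    }


def _backward(model: CNNModel, cache: dict, probs: np.ndarray, y_onehot: np.ndarray):
    """Gradients of mean cross-entropy + L2 w.r.t. all parameters."""
    oh, ow, nh, nw, ph, pw, fh, fw, nf = cache["dims"]
    b = probs.shape[0]
    l2 = model.config.l2
    dlogits = (probs - y_onehot) / b
    d_fc_w = cache["flat"].T @ dlogits + l2 * model.fc_w
    d_fc_b = dlogits.sum(axis=0)
    dflat = dlogits @ model.fc_w.T
    dpooled = dflat.reshape(b, nh, nw, nf)
    # scatter through the max-pool argmax
    dcells = np.zeros((b, nh, nw, nf, ph * pw))
    np.put_along_axis(dcells, cache["arg"][..., None], dpooled[..., None], axis=-1)
    drelu = np.zeros(cache["relu_shape"])
    drelu[:, : nh * ph, : nw * pw, :] = (
        dcells.reshape(b, nh, nw, nf, ph, pw)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(b, nh * ph, nw * pw, nf)
    )
    dconv = drelu * (cache["conv"] > 0)
    d_conv_w = (
        cache["flat_patches"].reshape(-1, fh * fw).T @ dconv.reshape(-1, nf)
    ).reshape(fh, fw, nf) + l2 * model.conv_w
    d_conv_b = dconv.sum(axis=(0, 1, 2))
    return d_conv_w, d_conv_b, d_fc_w, d_fc_b


def cnn_loss_grad(model: CNNModel, X: np.ndarray, y_onehot: np.ndarray):
    """Loss and parameter gradients on one (normalized) batch."""
    probs, cache = _forward(model, X, cache=True)
    n = len(X)
    loss = -float(np.sum(y_onehot * np.log(np.clip(probs, 1e-12, None)))) / n
    loss += 0.5 * model.config.l2 * (
        float(np.sum(model.conv_w**2)) + float(np.sum(model.fc_w**2))
    )
    return loss, _backward(model, cache, probs, y_onehot)


def cnn_init(
    input_shape: tuple[int, int],
    n_classes: int,
    cfg: CNNConfig,
    rng: np.random.Generator,
) -> CNNModel:
    """Seeded random initialization, zero-mean Gaussians scaled by fan-in."""
    fh, fw = cfg.filter_shape
    l, c = input_shape
    oh, ow = l - fh + 1, c - fw + 1
    if oh < 1 or ow < 1:
        raise ValidationError(
            f"filter {cfg.filter_shape} does not fit input {input_shape}"
        )
    nh, nw = oh // cfg.pool_shape[0], ow // cfg.pool_shape[1]
    if nh < 1 or nw < 1:
        raise ValidationError(
            f"pool {cfg.pool_shape} does not fit conv output ({oh} x {ow})"
        )
    flat_dim = nh * nw * cfg.n_filters
    conv_w = rng.normal(0.0, 1.0 / np.sqrt(fh * fw), size=(fh, fw, cfg.n_filters))
    fc_w = rng.normal(0.0, 1.0 / np.sqrt(flat_dim), size=(flat_dim, n_classes))
    return CNNModel(
        conv_w=conv_w,
        conv_b=np.zeros(cfg.n_filters),
        fc_w=fc_w,
        fc_b=np.zeros(n_classes),
        classes=np.arange(n_classes),
        input_shape=(l, c),
        channel_mean=np.zeros(c),
        channel_std=np.ones(c),
        config=cfg,
    )


def cnn_train(X: np.ndarray, y: np.ndarray, cfg: CNNConfig) -> CNNModel:
    """Train by SGD with momentum on shuffled mini-batches.

    ``X`` is W x L x C raw windows; per-channel z-scoring statistics are
    computed on the training set and stored in the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 3 or len(X) != len(y):
        raise ValidationError("X must be W x L x C and aligned with y")
    rng = np.random.default_rng(cfg.seed)
    classes = np.unique(y)
    model = cnn_init(X.shape[1:], len(classes), cfg, rng)
    model.classes = classes
    model.channel_mean = X.mean(axis=(0, 1))
    model.channel_std = X.std(axis=(0, 1))
    model.channel_std[model.channel_std == 0] = 1.0

    xn = _normalize(model, X)
    y_onehot = (y[:, None] == classes[None, :]).astype(float)
    params = ["conv_w", "conv_b", "fc_w", "fc_b"]
    vel = {p: np.zeros_like(getattr(model, p)) for p in params}
    w = len(X)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(w)
        for start in range(0, w, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = cnn_loss_grad(model, xn[idx], y_onehot[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"training loss became non-finite (lr={cfg.lr}); "
                    "reduce the learning rate"
                )
            model.loss_history.append(loss)
            for p, g in zip(params, grads):
                vel[p] = cfg.momentum * vel[p] - cfg.lr * g
                setattr(model, p, getattr(model, p) + vel[p])
    return model


def cnn_predict_proba(model: CNNModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1:] != model.input_shape:
        raise ValidationError(
            f"X must be B x {model.input_shape[0]} x {model.input_shape[1]}, "
            f"got {X.shape}"
        )
    return _forward(model, _normalize(model, X))


def cnn_forward(model: CNNModel, window: np.ndarray) -> np.ndarray:
    """Class-probability vector for a single L x C window."""
    window = np.asarray(window, dtype=float)
    if window.shape != model.input_shape:
        raise ValidationError(
            f"window must be {model.input_shape}, got {window.shape}"
        )
    return cnn_predict_proba(model, window[None])[0]


def cnn_predict(model: CNNModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0, dtype=model.classes.dtype)
    return model.classes[np.argmax(cnn_predict_proba(model, X), axis=1)]
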