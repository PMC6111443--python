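"""Stacked sparse autoencoders with greedy layer-wise pretraining.

Each layer is a sparse autoencoder with a sigmoid encoder and a linear
decoder, trained to reconstruct its input under three penalties: an L2
weight decay, and a KL-divergence sparsity penalty pushing every hidden
unit's mean activation rho_hat toward the sparsity proportion sp,

    J = 1/(2W) sum ||x - x_hat||^2
        + l2r/2 (||W_enc||^2 + ||W_dec||^2)
        + sr * sum_j KL(sp || rho_hat_j),

    KL(p || q) = p ln(p/q) + (1-p) ln((1-p)/(1-q)).

Layers are pretrained greedily (layer 2 on layer 1's encodings), then a
softmax head is trained supervised with cross-entropy on the layer-2
encodings; encoder weights stay frozen by default.  All optimization uses
scaled conjugate gradient.

Two stacks are used in the pipeline: SSAE-f on the 32 time-domain features
(hidden sizes 32, 16) and SSAE-r on the 240 raw window samples (hidden
sizes 100, 50); both share l2r = 1e-4, sr = 0.01, sp = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dataset import ValidationError
from .scg import scg_minimize

_RHO_EPS = 1e-8


@dataclass
class SSAEConfig:
    layer_sizes: tuple[int, int] = (32, 16)
    l2r: float = 1e-4
    sr: float = 0.01
    sp: float = 0.5
    max_iters: int = 400
    grad_tol: float = 1e-6
    fine_tune: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.layer_sizes):
            raise ValidationError("layer sizes must be >= 1")
        if not 0 < self.sp < 1:
            raise ValidationError("sparsity proportion sp must lie in (0, 1)")
        if self.l2r < 0 or self.sr < 0:
            raise ValidationError("l2r and sr must be >= 0")


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def kl_bernoulli(p: float, q: np.ndarray) -> np.ndarray:
    q = np.clip(q, _RHO_EPS, 1.0 - _RHO_EPS)
    return p * np.log(p / q) + (1.0 - p) * np.log((1.0 - p) / (1.0 - q))


def _pack(*arrays: np.ndarray) -> np.ndarray:
    return np.concatenate([a.ravel() for a in arrays])


def _unpack(w: np.ndarray, shapes: list[tuple[int, ...]]) -> list[np.ndarray]:
    out, i = [], 0
    for s in shapes:
        n = int(np.prod(s))
        out.append(w[i : i + n].reshape(s))
        i += n
    return out


def sae_loss_grad(
    w: np.ndarray, X: np.ndarray, hidden: int, cfg: SSAEConfig
) -> tuple[float, np.ndarray]:
    """Sparse-autoencoder objective J and its analytic gradient.

    Parameter vector packs (W1: D x H, b1: H, W2: H x D, b2: D); encoder
    sigmoid, decoder linear.
    """
    n, d = X.shape
    w1, b1, w2, b2 = _unpack(w, [(d, hidden), (hidden,), (hidden, d), (d,)])
    a = sigmoid(X @ w1 + b1)  # n x h
    xhat = a @ w2 + b2
    resid = xhat - X
    rho = a.mean(axis=0)
    rho_c = np.clip(rho, _RHO_EPS, 1.0 - _RHO_EPS)

    loss = (
        0.5 / n * float(np.sum(resid**2))
        + 0.5 * cfg.l2r * (float(np.sum(w1**2)) + float(np.sum(w2**2)))
        + cfg.sr * float(np.sum(kl_bernoulli(cfg.sp, rho)))
    )

    r = resid / n
    dw2 = a.T @ r + cfg.l2r * w2
    db2 = r.sum(axis=0)
    da = r @ w2.T
    dkl = cfg.sr * (-cfg.sp / rho_c + (1.0 - cfg.sp) / (1.0 - rho_c))
    da = da + dkl[None, :] / n
    dz = da * a * (1.0 - a)
    dw1 = X.T @ dz + cfg.l2r * w1
    db1 = dz.sum(axis=0)
    return loss, _pack(dw1, db1, dw2, db2)


def _init_ae(d: int, h: int, rng: np.random.Generator) -> np.ndarray:
    lim1 = np.sqrt(6.0 / (d + h))
    w1 = rng.uniform(-lim1, lim1, size=(d, h))
    w2 = rng.uniform(-lim1, lim1, size=(h, d))
    return _pack(w1, np.zeros(h), w2, np.zeros(d))


def sae_pretrain_layer(
    X: np.ndarray, hidden: int, cfg: SSAEConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Train one sparse-autoencoder layer; returns encoder (weights, biases)
    and the optimizer info dict."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    w0 = _init_ae(d, hidden, rng)
    w, info = scg_minimize(
        lambda v: sae_loss_grad(v, X, hidden, cfg),
        w0,
        max_iters=cfg.max_iters,
        grad_tol=cfg.grad_tol,
    )
    w1, b1, _, _ = _unpack(w, [(d, hidden), (hidden,), (hidden, d), (d,)])
    return w1, b1, info


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_loss_grad(
    w: np.ndarray, X: np.ndarray, y_onehot: np.ndarray, l2r: float
) -> tuple[float, np.ndarray]:
    """Cross-entropy + L2 for a softmax layer; packs (W: D x K, b: K)."""
    n, d = X.shape
    k = y_onehot.shape[1]
    wmat, b = _unpack(w, [(d, k), (k,)])
    p = softmax(X @ wmat + b)
    loss = -np.sum(y_onehot * np.log(np.clip(p, 1e-12, None))) / n
    loss += 0.5 * l2r * float(np.sum(wmat**2))
    dlogits = (p - y_onehot) / n
    dw = X.T @ dlogits + l2r * wmat
    db = dlogits.sum(axis=0)
    return float(loss), _pack(dw, db)


@dataclass
class SSAEModel:
    """Frozen two-layer sigmoid encoder plus softmax head."""

    encoders: list[tuple[np.ndarray, np.ndarray]]  # [(W, b), ...]
    head_w: np.ndarray  # m x K
    head_b: np.ndarray  # K
    classes: np.ndarray
    config: SSAEConfig
    pretrain_info: list[dict] = field(default_factory=list)

    def encode(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        for w, b in self.encoders:
            a = sigmoid(a @ w + b)
        return a

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.encode(X) @ self.head_w + self.head_b)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return np.empty(0, dtype=self.classes.dtype)
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]


def ssae_train(X: np.ndarray, y: np.ndarray, cfg: SSAEConfig) -> SSAEModel:
    """Greedy layer-wise pretraining, then a supervised softmax head.

    ``X`` must already be scaled to the sigmoid encoder's operating range
    (min-max for features, z-scores for raw samples); scaling is owned by
    the pipeline wrappers so its parameters come from training data only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("X must be 2-D and aligned with y")
    rng = np.random.default_rng(cfg.seed)
    classes = np.unique(y)

    encoders: list[tuple[np.ndarray, np.ndarray]] = []
    infos: list[dict] = []
    a = X
    for hidden in cfg.layer_sizes:
        w1, b1, info = sae_pretrain_layer(a, hidden, cfg, rng)
        encoders.append((w1, b1))
        infos.append(info)
        a = sigmoid(a @ w1 + b1)

    y_onehot = (y[:, None] == classes[None, :]).astype(float)
    d, k = a.shape[1], len(classes)
    lim = np.sqrt(6.0 / (d + k))
    w0 = _pack(rng.uniform(-lim, lim, size=(d, k)), np.zeros(k))
    w, head_info = scg_minimize(
        lambda v: softmax_loss_grad(v, a, y_onehot, cfg.l2r),
        w0,
        max_iters=cfg.max_iters,
        grad_tol=cfg.grad_tol,
    )
    head_w, head_b = _unpack(w, [(d, k), (k,)])
    infos.append(head_info)
    model = SSAEModel(
        encoders=encoders,
        head_w=head_w,
        head_b=head_b,
        classes=classes,
        config=cfg,
        pretrain_info=infos,
    )
    if cfg.fine_tune:
        _fine_tune(model, X, y_onehot)
    return model


def _fine_tune(model: SSAEModel, X: np.ndarray, y_onehot: np.ndarray) -> None:
    """Optional joint cross-entropy refinement of encoders + head (off by
    default; greedy pretraining plus a supervised head is the standard
    configuration here)."""
    cfg = model.config
    shapes: list[tuple[int, ...]] = []
    arrays: list[np.ndarray] = []
    for w, b in model.encoders:
        shapes += [w.shape, b.shape]
        arrays += [w, b]
    shapes += [model.head_w.shape, model.head_b.shape]
    arrays += [model.head_w, model.head_b]
    n = len(X)

    def loss_grad(v: np.ndarray) -> tuple[float, np.ndarray]:
        parts = _unpack(v, shapes)
        encs = [(parts[2 * i], parts[2 * i + 1]) for i in range(len(model.encoders))]
        hw, hb = parts[-2], parts[-1]
        acts = [X]
        for w, b in encs:
            acts.append(sigmoid(acts[-1] @ w + b))
        p = softmax(acts[-1] @ hw + hb)
        loss = -np.sum(y_onehot * np.log(np.clip(p, 1e-12, None))) / n
        loss += 0.5 * cfg.l2r * (
            sum(float(np.sum(w**2)) for w, _ in encs) + float(np.sum(hw**2))
        )
        dlogits = (p - y_onehot) / n
        grads: list[np.ndarray] = [
            acts[-1].T @ dlogits + cfg.l2r * hw,
            dlogits.sum(axis=0),
        ]
        da = dlogits @ hw.T
        for i in range(len(encs) - 1, -1, -1):
            w, _ = encs[i]
            dz = da * acts[i + 1] * (1.0 - acts[i + 1])
            grads = [acts[i].T @ dz + cfg.l2r * w, dz.sum(axis=0)] + grads
            da = dz @ w.T
        return float(loss), _pack(*grads)

    v, info = scg_minimize(
        loss_grad, _pack(*arrays), max_iters=cfg.max_iters, grad_tol=cfg.grad_tol
    )
    parts = _unpack(v, shapes)
    model.encoders = [
        (parts[2 * i], parts[2 * i + 1]) for i in range(len(model.encoders))
    ]
    model.head_w, model.head_b = parts[-2], parts[-1]
    model.pretrain_info.append(info)
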