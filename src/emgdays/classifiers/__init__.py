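"""The three classifier families behind one train/predict contract.

Every wrapper exposes ``fit(session_data...)``-compatible primitives through
``extract`` (pull its input representation out of a
:class:`~emgdays.evaluation.SessionData`), ``fit(X, y)`` and ``predict(X)``,
so the evaluation protocols can treat LDA, the two stacked sparse
autoencoders and the CNN interchangeably.

Input contracts (scaling parameters always come from training data only):

* ``lda``    — 32 time-domain features, unscaled (LDA is scale-invariant)
* ``ssae_f`` — 32 time-domain features, min-max scaled to [0, 1]
* ``ssae_r`` — flattened raw windows (240 values), per-channel z-scored
* ``cnn``    — raw 30 x 8 windows, per-channel z-scored inside the model
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..dataset import ValidationError
from .cnn import (
    CNNConfig,
    CNNModel,
    cnn_forward,
    cnn_init,
    cnn_loss_grad,
    cnn_predict,
    cnn_predict_proba,
    cnn_train,
)
from .lda import LDAModel, lda_discriminants, lda_predict, lda_train
from .scg import scg_minimize
from .ssae import (
    SSAEConfig,
    SSAEModel,
    sae_loss_grad,
    sae_pretrain_layer,
    softmax_loss_grad,
    ssae_train,
)

__all__ = [
    "CNNConfig",
    "CNNModel",
    "LDAModel",
    "SSAEConfig",
    "SSAEModel",
    "CLASSIFIER_NAMES",
    "cnn_forward",
    "cnn_init",
    "cnn_loss_grad",
    "cnn_predict",
    "cnn_predict_proba",
    "cnn_train",
    "lda_discriminants",
    "lda_predict",
    "lda_train",
    "make_classifier",
    "sae_pretrain_layer",
    "sae_loss_grad",
    "scg_minimize",
    "softmax_loss_grad",
    "ssae_train",
    "save_model",
    "load_model",
]


class LDAClassifier:
    name = "lda"
    input_kind = "features"

    def __init__(self, ridge: float = 1e-6, seed: int = 0):
        self.ridge = ridge
        self.seed = seed  # unused: LDA is deterministic
        self.model: LDAModel | None = None

    def extract(self, sd) -> np.ndarray:
        return sd.features.matrix()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LDAClassifier":
        self.model = lda_train(X, y, ridge=self.ridge)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return lda_predict(self.model, X)


class _MinMaxScaler:
    def fit(self, X: np.ndarray) -> "_MinMaxScaler":
        self.lo = X.min(axis=0)
        rng = X.max(axis=0) - self.lo
        rng[rng == 0] = 1.0
        self.range = rng
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.lo) / self.range


class _ChannelZScorer:
    """z-score per channel over all windows and samples (W x L x C input)."""

    def fit(self, X: np.ndarray) -> "_ChannelZScorer":
        self.mean = X.mean(axis=(0, 1))
        std = X.std(axis=(0, 1))
        std[std == 0] = 1.0
        self.std = std
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean[None, None, :]) / self.std[None, None, :]


class SSAEFClassifier:
    """SSAE-f: stacked sparse autoencoder on the 4 x 8 feature input."""

    name = "ssae_f"
    input_kind = "features"

    def __init__(self, seed: int = 0, **cfg_overrides):
        cfg_overrides.setdefault("layer_sizes", (32, 16))
        self.cfg = SSAEConfig(seed=seed, **cfg_overrides)
        self.model: SSAEModel | None = None
        self.scaler = _MinMaxScaler()

    def extract(self, sd) -> np.ndarray:
        return sd.features.matrix()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SSAEFClassifier":
        self.scaler.fit(X)
        self.model = ssae_train(self.scaler.transform(X), y, self.cfg)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self.scaler.transform(X))


class SSAERClassifier:
    """SSAE-r: stacked sparse autoencoder on flattened raw windows."""

    name = "ssae_r"
    input_kind = "raw"

    def __init__(self, seed: int = 0, **cfg_overrides):
        cfg_overrides.setdefault("layer_sizes", (100, 50))
        self.cfg = SSAEConfig(seed=seed, **cfg_overrides)
        self.model: SSAEModel | None = None
        self.scaler = _ChannelZScorer()

    def extract(self, sd) -> np.ndarray:
        return sd.windows.windows

    def _flat(self, X: np.ndarray) -> np.ndarray:
        return self.scaler.transform(X).reshape(len(X), -1)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SSAERClassifier":
        self.scaler.fit(X)
        self.model = ssae_train(self._flat(X), y, self.cfg)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self._flat(X))


class CNNClassifier:
    name = "cnn"
    input_kind = "raw"

    def __init__(self, seed: int = 0, **cfg_overrides):
        self.cfg = CNNConfig(seed=seed, **cfg_overrides)
        self.model: CNNModel | None = None

    def extract(self, sd) -> np.ndarray:
        return sd.windows.windows

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNClassifier":
        self.model = cnn_train(X, y, self.cfg)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return cnn_predict(self.model, X)


_REGISTRY = {
    "lda": LDAClassifier,
    "ssae_f": SSAEFClassifier,
    "ssae_r": SSAERClassifier,
    "cnn": CNNClassifier,
}

CLASSIFIER_NAMES = tuple(_REGISTRY)


def make_classifier(name: str, seed: int = 0, **overrides):
    """Instantiate a classifier by registry name with a fresh seed."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}"
        ) from None
    return cls(seed=seed, **overrides)


def save_model(clf, path: str | Path) -> Path:
    """Serialize a fitted wrapper: JSON header + float32 arrays (.npz)."""
    path = Path(path)
    header = {"name": clf.name}
    arrays: dict[str, np.ndarray] = {}

    def put(key: str, a: np.ndarray) -> None:
        arrays[key] = np.asarray(a, dtype=np.float32)

    if isinstance(clf, LDAClassifier):
        m = clf.model
        header["ridge"] = m.ridge
        put("classes", m.classes)
        put("class_means", m.class_means)
        put("cov_inv", m.pooled_covariance_inverse)
        put("log_priors", m.log_priors)
    elif isinstance(clf, (SSAEFClassifier, SSAERClassifier)):
        m = clf.model
        header["config"] = {
            "layer_sizes": list(clf.cfg.layer_sizes),
            "l2r": clf.cfg.l2r,
            "sr": clf.cfg.sr,
            "sp": clf.cfg.sp,
            "seed": clf.cfg.seed,
        }
        put("classes", m.classes)
        for i, (w, b) in enumerate(m.encoders):
            put(f"enc_w{i}", w)
            put(f"enc_b{i}", b)
        put("head_w", m.head_w)
        put("head_b", m.head_b)
        if isinstance(clf, SSAEFClassifier):
            put("scale_lo", clf.scaler.lo)
            put("scale_range", clf.scaler.range)
        else:
            put("scale_mean", clf.scaler.mean)
            put("scale_std", clf.scaler.std)
    elif isinstance(clf, CNNClassifier):
        m = clf.model
        header["config"] = {
            "n_filters": clf.cfg.n_filters,
            "filter_shape": list(clf.cfg.filter_shape),
            "pool_shape": list(clf.cfg.pool_shape),
            "seed": clf.cfg.seed,
        }
        header["input_shape"] = list(m.input_shape)
        put("classes", m.classes)
        put("conv_w", m.conv_w)
        put("conv_b", m.conv_b)
        put("fc_w", m.fc_w)
        put("fc_b", m.fc_b)
        put("channel_mean", m.channel_mean)
        put("channel_std", m.channel_std)
    else:
        raise ValidationError(f"cannot serialize {type(clf).__name__}")
    np.savez(path, header=json.dumps(header), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path):
    """Inverse of :func:`save_model`; returns a fitted wrapper."""
    with np.load(Path(path), allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        arrays = {k: z[k] for k in z.files if k != "header"}
    name = header["name"]
    classes = arrays["classes"].astype(int)
    if name == "lda":
        clf = LDAClassifier(ridge=header["ridge"])
        clf.model = LDAModel(
            classes=classes,
            class_means=arrays["class_means"].astype(float),
            pooled_covariance_inverse=arrays["cov_inv"].astype(float),
            log_priors=arrays["log_priors"].astype(float),
            ridge=header["ridge"],
        )
        return clf
    if name in ("ssae_f", "ssae_r"):
        cfgd = dict(header["config"])
        cfgd["layer_sizes"] = tuple(cfgd["layer_sizes"])
        seed = cfgd.pop("seed")
        cls = SSAEFClassifier if name == "ssae_f" else SSAERClassifier
        clf = cls(seed=seed, **cfgd)
        n_layers = len(clf.cfg.layer_sizes)
        encoders = [
            (arrays[f"enc_w{i}"].astype(float), arrays[f"enc_b{i}"].astype(float))
            for i in range(n_layers)
        ]
        clf.model = SSAEModel(
            encoders=encoders,
            head_w=arrays["head_w"].astype(float),
            head_b=arrays["head_b"].astype(float),
            classes=classes,
            config=clf.cfg,
        )
        if name == "ssae_f":
            clf.scaler.lo = arrays["scale_lo"].astype(float)
            clf.scaler.range = arrays["scale_range"].astype(float)
        else:
            clf.scaler.mean = arrays["scale_mean"].astype(float)
            clf.scaler.std = arrays["scale_std"].astype(float)
        return clf
    if name == "cnn":
        cfgd = dict(header["config"])
        cfgd["filter_shape"] = tuple(cfgd["filter_shape"])
        cfgd["pool_shape"] = tuple(cfgd["pool_shape"])
        seed = cfgd.pop("seed")
        clf = CNNClassifier(seed=seed, **cfgd)
        clf.model = CNNModel(
            conv_w=arrays["conv_w"].astype(float),
            conv_b=arrays["conv_b"].astype(float),
            fc_w=arrays["fc_w"].astype(float),
            fc_b=arrays["fc_b"].astype(float),
            classes=classes,
            input_shape=tuple(header["input_shape"]),
            channel_mean=arrays["channel_mean"].astype(float),
            channel_std=arrays["channel_std"].astype(float),
            config=clf.cfg,
        )
        return clf
    raise ValidationError(f"unknown serialized classifier {name!r}")
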