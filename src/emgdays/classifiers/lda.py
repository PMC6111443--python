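"""Multiclass linear discriminant analysis with pooled covariance.

The classical Gaussian-equal-covariance discriminant used as the reference
classifier in myoelectric control: per class c,

    g_c(x) = x' S^-1 mu_c - 0.5 mu_c' S^-1 mu_c + ln pi_c

with S the pooled within-class covariance (ridge-stabilized) and pi_c the
class frequencies.  Prediction is the argmax of g_c with ties broken toward
the lower class index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dataset import ValidationError


@dataclass
class LDAModel:
    classes: np.ndarray  # class labels, ascending
    class_means: np.ndarray  # K x D
    pooled_covariance_inverse: np.ndarray  # D x D
    log_priors: np.ndarray  # K
    ridge: float

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


def lda_train(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> LDAModel:
    """Fit pooled-covariance LDA.

    ``ridge`` is a fractional regularizer: ``ridge * trace(S)/D`` is added
    to the diagonal of the pooled covariance, keeping the stabilization
    invariant to overall amplitude scale.  ``ridge=0`` disables it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (samples x features)")
    if len(X) != len(y):
        raise ValidationError("X and y lengths differ")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("lda_train requires at least 2 classes")
    w, d = X.shape
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    scatter = np.zeros((d, d))
    for i, c in enumerate(classes):
        xc = X[y == c] - means[i]
        scatter += xc.T @ xc
    cov = scatter / (w - len(classes))
    if ridge > 0:
        cov = cov + np.eye(d) * (ridge * np.trace(cov) / d)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "pooled covariance is singular; pass a positive ridge"
        ) from exc
    if not np.all(np.isfinite(cov_inv)):
        raise ValidationError(
            "pooled covariance is numerically singular; increase ridge"
        )
    counts = np.array([(y == c).sum() for c in classes], dtype=float)
    return LDAModel(
        classes=classes,
        class_means=means,
        pooled_covariance_inverse=cov_inv,
        log_priors=np.log(counts / w),
        ridge=ridge,
    )


def lda_discriminants(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Per-class discriminant scores g_c(x), shape N x K."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValidationError(
            f"X must be N x {model.n_features}, got {X.shape}"
        )
    a = model.pooled_covariance_inverse @ model.class_means.T  # D x K
    const = -0.5 * np.sum(model.class_means.T * a, axis=0) + model.log_priors
    return X @ a + const


def lda_predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Argmax-discriminant labels; empty X yields empty labels."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0, dtype=model.classes.dtype)
    g = lda_discriminants(model, X)
    return model.classes[np.argmax(g, axis=1)]
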