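"""Hudgins time-domain features: MAV, WL, SSC, ZC.

The four classic time-domain descriptors of a surface-EMG window, computed
per channel, giving the 4 x 8 representation consumed by LDA and by the
feature-input stacked sparse autoencoder:

* MAV — mean absolute value, ``(1/L) * sum |x_i|``
* WL  — waveform length, ``sum |x_i - x_{i-1}|``
* SSC — slope-sign-change count: interior samples where the two adjacent
  slopes have strictly opposite signs and the larger slope magnitude
  reaches the threshold
* ZC  — zero-crossing count: adjacent pairs with a strictly negative
  product whose amplitude step reaches the threshold

The threshold defaults to 0 (the zero-threshold convention), which makes
both amplitude conditions vacuous; with strict inequalities, samples that
are exactly zero never contribute a crossing or a slope change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ValidationError
from .preprocess import WindowSet

#: Canonical feature order in every FeatureSet.
FEATURE_NAMES = ("MAV", "WL", "SSC", "ZC")


def mav(x: np.ndarray) -> float:
    """Mean absolute value of a 1-D window."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValidationError("mav requires at least 1 sample")
    return float(np.mean(np.abs(x)))


def wl(x: np.ndarray) -> float:
    """Waveform length (total variation) of a 1-D window."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("wl requires at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def zc(x: np.ndarray, threshold: float = 0.0) -> int:
    """Zero-crossing count of a 1-D window."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("zc requires at least 2 samples")
    cross = x[:-1] * x[1:] < 0
    amp = np.abs(x[:-1] - x[1:]) >= threshold
    return int(np.sum(cross & amp))


def ssc(x: np.ndarray, threshold: float = 0.0) -> int:
    """Slope-sign-change count of a 1-D window."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError("ssc requires at least 3 samples")
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    change = left * right > 0
    amp = np.maximum(np.abs(left), np.abs(right)) >= threshold
    return int(np.sum(change & amp))


@dataclass
class FeatureSet:
    """W x 4 x C time-domain feature tensors aligned to a WindowSet."""

    features: np.ndarray  # W x F x C, F = len(FEATURE_NAMES)
    labels: np.ndarray
    meta: pd.DataFrame
    threshold: float = 0.0

    def __len__(self) -> int:
        return len(self.features)

    def matrix(self) -> np.ndarray:
        """Flatten to W x (C*F), channel-major: per channel, the four
        features in canonical order."""
        w, f, c = self.features.shape
        return self.features.transpose(0, 2, 1).reshape(w, c * f)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per window: provenance columns then the flat features
        named like ``MAV_ch1 ... ZC_ch8`` (channel-major)."""
        _, f, c = self.features.shape
        cols = [
            f"{FEATURE_NAMES[j]}_ch{k + 1}" for k in range(c) for j in range(f)
        ]
        out = self.meta.copy()
        out["label"] = self.labels
        return pd.concat(
            [out, pd.DataFrame(self.matrix(), columns=cols, index=out.index)],
            axis=1,
        )


def featurize(ws: WindowSet, threshold: float = 0.0) -> FeatureSet:
    """Compute MAV/WL/SSC/ZC per channel for every window (vectorized)."""
    x = ws.windows  # W x L x C
    if x.shape[1] < 3:
        raise ValidationError("windows must have at least 3 samples for SSC")
    d = np.diff(x, axis=1)
    mav_ = np.mean(np.abs(x), axis=1)
    wl_ = np.sum(np.abs(d), axis=1)

    cross = x[:, :-1, :] * x[:, 1:, :] < 0
    zc_amp = np.abs(d) >= threshold
    zc_ = np.sum(cross & zc_amp, axis=1)

    left = x[:, 1:-1, :] - x[:, :-2, :]
    right = x[:, 1:-1, :] - x[:, 2:, :]
    change = left * right > 0
    ssc_amp = np.maximum(np.abs(left), np.abs(right)) >= threshold
    ssc_ = np.sum(change & ssc_amp, axis=1)

    feats = np.stack([mav_, wl_, ssc_, zc_], axis=1)  # W x 4 x C
    return FeatureSet(
        features=feats.astype(np.float64),
        labels=ws.labels.copy(),
        meta=ws.meta.copy(),
        threshold=threshold,
    )
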