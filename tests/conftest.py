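"""Shared fixtures: scaled-down synthetic study configs and stub classifiers.

Fixture sizes (few days, short contractions, coarse window step) are chosen
to exercise every protocol quickly; the generator's drift and noise defaults
are never altered except where a test explicitly studies drift = 0.
"""

import numpy as np
import pandas as pd
import pytest

from emgdays.evaluation import SessionData, prepare_session
from emgdays.synth import SynthConfig, generate_recording

#: preprocessing for the short-contraction fixtures: keep 0.5 s per segment
TINY_PREP = dict(trim_s=0.25, step_ms=50.0)


@pytest.fixture(scope="session")
def tiny_cfg() -> SynthConfig:
    """2 days x 2 sessions, 3 reps, 1 s contractions: fast but structurally
    complete (every protocol can run)."""
    return SynthConfig(
        n_days=2,
        reps_per_movement=3,
        contraction_s=1.0,
        relax_s=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_recording(tiny_cfg):
    return generate_recording(tiny_cfg, 1, 1, 1)


@pytest.fixture(scope="session")
def tiny_session(tiny_recording) -> SessionData:
    return prepare_session(tiny_recording, **TINY_PREP)


@pytest.fixture(scope="session")
def tiny_sessions(tiny_cfg) -> list[SessionData]:
    """All four sessions (2 days x 2) of the tiny study."""
    return [
        prepare_session(generate_recording(tiny_cfg, 1, d, s), **TINY_PREP)
        for d in (1, 2)
        for s in (1, 2)
    ]


class OracleStub:
    """Cheating stub: looks labels up by window content; CE must be 0
    under any leakage-free protocol run on sessions it has seen."""

    name = "oracle_stub"
    input_kind = "raw"

    def __init__(self, sessions: list[SessionData]):
        self.lookup = {}
        for sd in sessions:
            for w, lab in zip(sd.windows.windows, sd.labels):
                self.lookup[w.tobytes()] = lab

    def extract(self, sd):
        return sd.windows.windows

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.lookup[w.tobytes()] for w in X])


class UniformRandomStub:
    """Predicts uniformly over the 7 classes; expected CE is 6/7."""

    name = "random_stub"
    input_kind = "features"

    def __init__(self, seed: int = 0, n_classes: int = 7):
        self.rng = np.random.default_rng(seed)
        self.n_classes = n_classes

    def extract(self, sd):
        return sd.features.matrix()

    def fit(self, X, y):
        return self

    def predict(self, X):
        return self.rng.integers(0, self.n_classes, size=len(X))


class ConstantStub:
    """Always predicts the first training label's class."""

    name = "constant_stub"
    input_kind = "features"

    def __init__(self, seed: int = 0):
        self.label = None

    def extract(self, sd):
        return sd.features.matrix()

    def fit(self, X, y):
        self.label = y[0]
        return self

    def predict(self, X):
        return np.full(len(X), self.label)


class SpyStub:
    """Records train/test provenance metadata for leakage audits."""

    name = "spy_stub"
    input_kind = "features"

    def __init__(self, log: list):
        self.log = log
        self._pending: pd.DataFrame | None = None

    def extract(self, sd):
        # called once for the training SessionData, once for the test one
        if self._pending is None:
            self._pending = sd.meta.copy()
        else:
            self.log.append((self._pending, sd.meta.copy()))
            self._pending = None
        return sd.features.matrix()

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.zeros(len(X), dtype=int)
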