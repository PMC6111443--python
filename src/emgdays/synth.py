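"""Synthetic multiday surface-EMG generator.

Emulates a wearable 8-electrode forearm ring sampled at 200 Hz: each of the
seven movement classes (rest plus six active motions) drives a class-specific
pattern of muscle activation across the ring (a *synergy* row), modulated by
a trapezoidal contraction envelope riding on band-limited Gaussian carrier
noise.  Day-to-day nonstationarity is modeled as (a) a fractional circular
rotation of the synergy rows — electrode-donning displacement around the
forearm circumference — and (b) per-channel multiplicative gain drift.
Same-day sessions receive the same day-level perturbation plus a smaller
session-level jitter, so days differ more than same-day sessions do.

The session protocol matches the multiday study design this package
evaluates: per session, 10 repetitions of each of 7 movements, each cue a
4 s contraction followed by 4 s of relaxation, cue order randomized per
session; 2 sessions per day over 15 days.

All amplitudes are arbitrary units; no attempt is made to match physical
millivolt ranges, motor-unit physiology, force proportionality or fatigue.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import signal

from .dataset import (
    MOVEMENTS,
    DatasetManifest,
    Recording,
    SegmentAnnotation,
    ValidationError,
    write_session,
)


def default_synergy(channels: int = 8, sigma: float = 1.0) -> np.ndarray:
    """Class-by-channel activation matrix (7 x channels), rest row zero.

    The six active movements get unit-height circular Gaussian bumps
    (width ``sigma`` channels) at evenly spaced positions around the
    electrode ring, mimicking distinct forearm muscle groups under an
    8-electrode armband.
    """
    syn = np.zeros((len(MOVEMENTS), channels))
    centers = np.arange(6) * channels / 6.0
    k = np.arange(channels)
    for row, c in enumerate(centers, start=1):  # row 0 = RT stays zero
        d = np.minimum(np.abs(k - c), channels - np.abs(k - c))
        syn[row] = np.exp(-(d**2) / (2 * sigma**2))
    return syn


@dataclass
class SynthConfig:
    """Generator parameters; defaults reproduce the multiday study protocol."""

    n_subjects: int = 1
    n_days: int = 15
    sessions_per_day: int = 2
    reps_per_movement: int = 10
    contraction_s: float = 4.0
    relax_s: float = 4.0
    fs: float = 200.0
    channels: int = 8
    synergy: np.ndarray | None = None  # 7 x channels; None -> default_synergy
    carrier_band: tuple[float, float] = (20.0, 95.0)
    envelope_ramp_s: float = 0.5
    noise_floor_sd: float = 0.2
    day_shift_sd: float = 0.6
    day_gain_sd: float = 0.2
    session_jitter_scale: float = 0.3
    rep_amp_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synergy is None:
            self.synergy = default_synergy(self.channels)
        self.synergy = np.asarray(self.synergy, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in (
            "noise_floor_sd",
            "day_shift_sd",
            "day_gain_sd",
            "rep_amp_jitter_sd",
            "session_jitter_scale",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "n_subjects",
            "n_days",
            "sessions_per_day",
            "reps_per_movement",
            "channels",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.synergy.shape != (len(MOVEMENTS), self.channels):
            raise ValidationError(
                f"synergy must be {len(MOVEMENTS)} x {self.channels}, "
                f"got {self.synergy.shape}"
            )
        if np.any(self.synergy < 0):
            raise ValidationError("synergy entries must be nonnegative")
        if not 0 < self.envelope_ramp_s <= self.contraction_s / 2:
            raise ValidationError(
                "envelope_ramp_s must lie in (0, contraction_s/2]"
            )
        lo, hi = self.carrier_band
        if not 0 < lo < hi < self.fs / 2:
            raise ValidationError(
                f"carrier_band {self.carrier_band} must lie within (0, fs/2)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synergy"] = np.asarray(self.synergy).tolist()
        d["carrier_band"] = list(self.carrier_band)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "carrier_band" in d:
            d["carrier_band"] = tuple(d["carrier_band"])
        if d.get("synergy") is not None:
            d["synergy"] = np.asarray(d["synergy"], dtype=float)
        return cls(**d)


def _rotate_fractional(row: np.ndarray, delta: float) -> np.ndarray:
    """Circular shift of a channel profile by a fractional number of channels
    (linear interpolation between the two adjacent integer shifts)."""
    c = row.shape[0]
    i = int(np.floor(delta))
    f = delta - i
    k = np.arange(c)
    return (1.0 - f) * row[(k + i) % c] + f * row[(k + i + 1) % c]


def _trapezoid(n: int, ramp: int) -> np.ndarray:
    env = np.ones(n)
    ramp = min(ramp, n // 2)
    if ramp > 0:
        up = np.arange(1, ramp + 1) / ramp
        env[:ramp] = up
        env[n - ramp:] = up[::-1]
    return env


def _day_params(cfg: SynthConfig, subject: int, day: int, session: int):
    """Drift parameters for one session: day-level draw, plus session-level
    jitter (scaled-down SDs) for sessions after the first."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, subject, day, 101])
    )
    shift = rng.normal(0.0, cfg.day_shift_sd)
    log_gain = rng.normal(0.0, cfg.day_gain_sd, size=cfg.channels)
    if session > 1:
        rng_s = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, subject, day, session, 102])
        )
        shift += rng_s.normal(0.0, cfg.day_shift_sd * cfg.session_jitter_scale)
        log_gain += rng_s.normal(
            0.0,
            cfg.day_gain_sd * cfg.session_jitter_scale,
            size=cfg.channels,
        )
    return shift, np.exp(log_gain)


def generate_recording(
    cfg: SynthConfig, subject: int, day: int, session: int
) -> Recording:
    """Generate one session for 1-based subject/day/session indices."""
    cfg.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, subject, day, session, 103])
    )
    n_contr = round(cfg.contraction_s * cfg.fs)
    n_relax = round(cfg.relax_s * cfg.fs)
    per_cue = n_contr + n_relax
    n_cues = len(MOVEMENTS) * cfg.reps_per_movement
    t_total = n_cues * per_cue

    # band-limited Gaussian carrier, unit variance per channel
    sos = signal.butter(
        4, cfg.carrier_band, btype="bandpass", fs=cfg.fs, output="sos"
    )
    carrier = signal.sosfiltfilt(
        sos, rng.standard_normal((t_total, cfg.channels)), axis=0
    )
    carrier = carrier / carrier.std(axis=0, keepdims=True)

    shift, gains = _day_params(cfg, subject, day, session)
    syn = np.stack(
        [_rotate_fractional(row, shift) for row in cfg.synergy], axis=0
    )

    cues = [
        (m_idx, rep)
        for m_idx in range(len(MOVEMENTS))
        for rep in range(cfg.reps_per_movement)
    ]
    order = rng.permutation(len(cues))
    env = _trapezoid(n_contr, round(cfg.envelope_ramp_s * cfg.fs))

    activation = np.zeros((t_total, cfg.channels))
    annotations: list[SegmentAnnotation] = []
    rep_counter = np.zeros(len(MOVEMENTS), dtype=int)
    for slot, cue_i in enumerate(order):
        m_idx, _ = cues[cue_i]
        rep_counter[m_idx] += 1
        t0 = slot * per_cue
        amp = np.exp(rng.normal(0.0, cfg.rep_amp_jitter_sd))
        activation[t0 : t0 + n_contr] = amp * env[:, None] * syn[m_idx][None, :]
        annotations.append(
            SegmentAnnotation(
                movement=MOVEMENTS[m_idx],
                repetition=int(rep_counter[m_idx]),
                start_sample=t0,
                end_sample=t0 + n_contr,
            )
        )

    samples = carrier * activation
    samples *= gains[None, :]
    samples += rng.normal(0.0, cfg.noise_floor_sd, size=samples.shape)

    return Recording(
        samples=samples.astype(np.float32),
        fs=cfg.fs,
        subject_id=f"S{subject}",
        day_index=day,
        session_index=session,
        annotations=annotations,
    )


def generate_sessions(cfg: SynthConfig) -> Iterator[Recording]:
    """Yield every session of the configured study, in grid order."""
    for subject in range(1, cfg.n_subjects + 1):
        for day in range(1, cfg.n_days + 1):
            for session in range(1, cfg.sessions_per_day + 1):
                yield generate_recording(cfg, subject, day, session)


def generate_dataset(cfg: SynthConfig, root: str | Path) -> DatasetManifest:
    """Generate the full study and write it in the dataset on-disk format."""
    cfg.validate()
    root = Path(root)
    manifest = DatasetManifest(
        fs=cfg.fs,
        channels=cfg.channels,
        provenance={
            "generator": "emgdays.synth",
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
        },
    )
    manifest.save(root)
    for rec in generate_sessions(cfg):
        write_session(rec, root, manifest=manifest)
    return manifest


def drift_sweep(
    cfg: SynthConfig,
    shift_values: list[float],
    classifier: str = "lda",
    prep_kwargs: dict | None = None,
):
    """Mean pairwise-day classification error versus electrode-shift SD.

    For each value in ``shift_values`` the dataset is regenerated with
    ``day_shift_sd`` set to that value (all other parameters fixed) and the
    pairwise-days protocol is run with the given baseline classifier
    (default LDA).  Returns a DataFrame with columns ``shift_sd`` and
    ``mean_pairwise_ce``.
    """
    import pandas as pd

    from .classifiers import make_classifier
    from .evaluation import pairwise_days_cv, prepare_session

    if len(shift_values) == 0:
        raise ValidationError("shift_values must be non-empty")
    if any(v < 0 for v in shift_values):
        raise ValidationError("shift_values must be nonnegative")
    if list(shift_values) != sorted(shift_values):
        raise ValidationError("shift_values must be ascending")

    prep_kwargs = prep_kwargs or {}
    rows = []
    for s in shift_values:
        c = replace(cfg, day_shift_sd=float(s), synergy=np.asarray(cfg.synergy))
        sessions = [
            prepare_session(rec, **prep_kwargs) for rec in generate_sessions(c)
        ]
        pairs = pairwise_days_cv(
            sessions, lambda seed: make_classifier(classifier, seed=seed)
        )
        rows.append(
            {"shift_sd": float(s), "mean_pairwise_ce": float(pairs["ce"].mean())}
        )
    return pd.DataFrame(rows)
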