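"""High-pass filtering, transition trimming and overlapping-window extraction.

The pipeline mirrors real-time myoelectric-control preprocessing: a causal
third-order Butterworth high-pass at 2 Hz removes movement artifact and
baseline drift; the first and last 0.5 s of every movement segment are
trimmed to avoid transition artifacts; windows of 150 ms are slid in 25 ms
steps inside each trimmed segment (30 x 8 samples at 200 Hz / 8 channels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .dataset import MOVEMENT_INDEX, Recording, SegmentAnnotation, ValidationError

logger = logging.getLogger(__name__)

#: Per-window provenance columns carried through the whole pipeline.
META_COLUMNS = (
    "subject",
    "day",
    "session",
    "movement",
    "repetition",
    "start_sample",
)


@dataclass
class WindowSet:
    """Stack of labeled windows with per-window provenance.

    ``windows`` is W x L x C (L = window length in samples, C = channels);
    ``labels`` are class indices into :data:`emgdays.dataset.MOVEMENTS`;
    ``meta`` has one row per window with columns :data:`META_COLUMNS`.
    """

    windows: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame
    fs: float

    def __post_init__(self) -> None:
        if self.windows.ndim != 3:
            raise ValidationError("windows must be W x L x C")
        if len(self.labels) != len(self.windows) or len(self.meta) != len(
            self.windows
        ):
            raise ValidationError("windows, labels and meta lengths differ")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def window_length(self) -> int:
        return self.windows.shape[1]

    @property
    def channels(self) -> int:
        return self.windows.shape[2]


def concat_windowsets(sets: list[WindowSet]) -> WindowSet:
    if not sets:
        raise ValidationError("no WindowSets to concatenate")
    fs = sets[0].fs
    if any(s.fs != fs for s in sets):
        raise ValidationError("cannot concatenate WindowSets with different fs")
    return WindowSet(
        windows=np.concatenate([s.windows for s in sets], axis=0),
        labels=np.concatenate([s.labels for s in sets]),
        meta=pd.concat([s.meta for s in sets], ignore_index=True),
        fs=fs,
    )


def highpass(
    recording: Recording,
    order: int = 3,
    cutoff_hz: float = 2.0,
    zero_phase: bool = False,
) -> Recording:
    """Butterworth high-pass each channel; annotations are unchanged.

    The default is a causal single-pass filter of the stated order, matching
    online prosthesis use; filter state is initialized to the steady-state
    response to the first sample to suppress the startup transient.
    ``zero_phase=True`` applies the same design forward-backward instead
    (doubling the effective order, zero phase lag).
    """
    if not 0 < cutoff_hz < recording.fs / 2:
        raise ValidationError(
            f"cutoff_hz must lie in (0, fs/2) = (0, {recording.fs / 2}), "
            f"got {cutoff_hz}"
        )
    sos = signal.butter(
        order, cutoff_hz, btype="highpass", fs=recording.fs, output="sos"
    )
    x = recording.samples.astype(np.float64)
    if zero_phase:
        y = signal.sosfiltfilt(sos, x, axis=0)
    else:
        zi = signal.sosfilt_zi(sos)  # steady-state unit-step response
        y = np.empty_like(x)
        for c in range(x.shape[1]):
            y[:, c], _ = signal.sosfilt(sos, x[:, c], zi=zi * x[0, c])
    return replace(recording, samples=y, annotations=list(recording.annotations))


def trim_transitions(recording: Recording, trim_s: float = 0.5) -> Recording:
    """Shrink every annotated segment by ``trim_s`` at each end.

    Removes movement-transition artifacts at segment boundaries; samples are
    untouched, only the annotations move.
    """
    if trim_s < 0:
        raise ValidationError("trim_s must be >= 0")
    k = round(trim_s * recording.fs)
    trimmed = []
    for a in recording.annotations:
        if a.n_samples <= 2 * k:
            raise ValidationError(
                f"segment {a.movement} rep {a.repetition} "
                f"[{a.start_sample}, {a.end_sample}) is too short to trim "
                f"{trim_s} s from each end"
            )
        trimmed.append(
            SegmentAnnotation(
                movement=a.movement,
                repetition=a.repetition,
                start_sample=a.start_sample + k,
                end_sample=a.end_sample - k,
            )
        )
    return replace(recording, annotations=trimmed)


def extract_windows(
    recording: Recording, window_ms: float = 150.0, step_ms: float = 25.0
) -> WindowSet:
    """Slide overlapping windows over each annotated segment.

    Window offsets within a segment are 0, s, 2s, ... while the window lies
    fully inside the segment, giving ``floor((N - L)/s) + 1`` windows per
    segment of N samples.  Windows never cross segment boundaries.  Segments
    shorter than one window are skipped with a warning.
    """
    length = round(window_ms * recording.fs / 1000.0)
    step = round(step_ms * recording.fs / 1000.0)
    if length < 1 or step < 1:
        raise ValidationError(
            f"window_ms={window_ms} / step_ms={step_ms} map to <1 sample "
            f"at fs={recording.fs}"
        )
    windows, labels, meta_rows = [], [], []
    for a in recording.annotations:
        n = a.n_samples
        if n < length:
            logger.warning(
                "segment %s rep %d has %d samples < window length %d; skipped",
                a.movement,
                a.repetition,
                n,
                length,
            )
            continue
        for off in range(0, n - length + 1, step):
            start = a.start_sample + off
            windows.append(recording.samples[start : start + length])
            labels.append(MOVEMENT_INDEX[a.movement])
            meta_rows.append(
                (
                    recording.subject_id,
                    recording.day_index,
                    recording.session_index,
                    a.movement,
                    a.repetition,
                    start,
                )
            )
    if windows:
        w = np.stack(windows).astype(np.float64)
    else:
        w = np.empty((0, length, recording.channels))
    return WindowSet(
        windows=w,
        labels=np.asarray(labels, dtype=int),
        meta=pd.DataFrame(meta_rows, columns=list(META_COLUMNS)),
        fs=recording.fs,
    )
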