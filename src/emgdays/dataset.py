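"""Data model and on-disk format for multiday, multi-session labeled EMG recordings.

A *Recording* holds one session of continuous multichannel surface EMG
(time x channel, arbitrary units) together with segment annotations that
mark each movement repetition.  Sample intervals are 0-based half-open
``[start, end)``.  A *DatasetManifest* (JSON) enumerates the
subject x day x session grid and points at one samples file and one
annotations file per session.

Samples are stored either as raw little-endian float32 (``f32le``, the
default) or as delimited text (``csv``, one row per time step); the layout
is declared in the manifest.  Annotations are CSV with columns
``movement, repetition, start_sample, end_sample``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The seven movement classes: rest, close hand, open hand, wrist flexion,
#: wrist extension, pronation, supination.
MOVEMENTS = ("RT", "CH", "OH", "WF", "WE", "PRO", "SUP")

MOVEMENT_INDEX = {m: i for i, m in enumerate(MOVEMENTS)}

MANIFEST_NAME = "manifest.json"


class ValidationError(ValueError):
    """A Recording, annotation or manifest violates an invariant."""


class SchemaError(ValueError):
    """On-disk data does not match the manifest schema."""


class ParseError(ValueError):
    """A samples or annotations file is malformed or truncated."""


@dataclass(frozen=True)
class SegmentAnnotation:
    """One labeled movement segment, ``[start_sample, end_sample)``."""

    movement: str
    repetition: int
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.movement not in MOVEMENTS:
            raise ValidationError(
                f"movement {self.movement!r} not in {MOVEMENTS}"
            )
        if self.end_sample <= self.start_sample:
            raise ValidationError(
                f"end_sample ({self.end_sample}) must exceed start_sample "
                f"({self.start_sample})"
            )
        if self.start_sample < 0:
            raise ValidationError(f"start_sample ({self.start_sample}) < 0")
        if self.repetition < 1:
            raise ValidationError(f"repetition ({self.repetition}) must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class Recording:
    """One session of continuous EMG with segment annotations.

    Parameters
    ----------
    samples
        2-D array, time x channel, arbitrary units.
    fs
        Sampling rate in Hz.
    subject_id, day_index, session_index
        Provenance identifiers; ``day_index`` is 1-based, ``session_index``
        is 1 or 2.
    annotations
        Non-overlapping segments sorted by ``start_sample``, all within
        ``[0, T)``.
    """

    samples: np.ndarray
    fs: float
    subject_id: str
    day_index: int
    session_index: int
    annotations: list[SegmentAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def channels(self) -> int:
        return self.samples.shape[1]

    def validate(self) -> None:
        if self.samples.ndim != 2:
            raise ValidationError(
                f"samples must be 2-D (time x channel), got {self.samples.ndim}-D"
            )
        if not self.fs > 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.day_index < 1:
            raise ValidationError(f"day_index ({self.day_index}) must be >= 1")
        if self.session_index < 1:
            raise ValidationError(
                f"session_index ({self.session_index}) must be >= 1"
            )
        t = self.n_samples
        prev_end = 0
        for i, ann in enumerate(sorted(self.annotations, key=lambda a: a.start_sample)):
            if ann.end_sample > t:
                raise ValidationError(
                    f"annotation {i} ({ann.movement} rep {ann.repetition}): "
                    f"end_sample {ann.end_sample} exceeds recording length {t}"
                )
            if ann.start_sample < prev_end:
                raise ValidationError(
                    f"annotation {i} ({ann.movement} rep {ann.repetition}) "
                    f"overlaps the previous segment"
                )
            prev_end = ann.end_sample
        self.annotations = sorted(self.annotations, key=lambda a: a.start_sample)

    def with_annotations(self, annotations: list[SegmentAnnotation]) -> "Recording":
        return replace(self, annotations=list(annotations))


def _session_stem(subject_id: str, day_index: int, session_index: int) -> str:
    return f"sub{subject_id}_day{day_index:02d}_ses{session_index}"


@dataclass
class DatasetManifest:
    """Index of a multiday dataset: the subject x day x session grid.

    ``sessions`` is a list of dicts with keys subject_id, day_index,
    session_index, n_samples, samples_file, annotations_file (paths
    relative to the manifest's directory).
    """

    fs: float
    channels: int
    class_names: tuple[str, ...] = MOVEMENTS
    sample_format: str = "f32le"
    sessions: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    root: Path | None = None

    @property
    def subjects(self) -> list[str]:
        return sorted({s["subject_id"] for s in self.sessions})

    def grid(self) -> dict[str, dict[int, list[int]]]:
        """subject -> day -> sorted session indices."""
        g: dict[str, dict[int, list[int]]] = {}
        for s in self.sessions:
            g.setdefault(s["subject_id"], {}).setdefault(s["day_index"], []).append(
                s["session_index"]
            )
        for days in g.values():
            for d in days:
                days[d] = sorted(days[d])
        return g

    def entry(self, subject_id: str, day_index: int, session_index: int) -> dict:
        for s in self.sessions:
            if (
                s["subject_id"] == subject_id
                and s["day_index"] == day_index
                and s["session_index"] == session_index
            ):
                return s
        raise KeyError(
            f"no session for subject {subject_id!r} day {day_index} "
            f"session {session_index}"
        )

    def to_dict(self) -> dict:
        return {
            "fs": self.fs,
            "channels": self.channels,
            "class_names": list(self.class_names),
            "sample_format": self.sample_format,
            "sessions": self.sessions,
            "provenance": self.provenance,
        }

    def save(self, root: str | Path) -> Path:
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        path = root / MANIFEST_NAME
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        self.root = root
        return path

    @classmethod
    def load(cls, root: str | Path) -> "DatasetManifest":
        root = Path(root)
        path = root if root.name == MANIFEST_NAME else root / MANIFEST_NAME
        try:
            with open(path) as fh:
                d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed manifest {path}: {exc}") from exc
        m = cls(
            fs=d["fs"],
            channels=d["channels"],
            class_names=tuple(d["class_names"]),
            sample_format=d.get("sample_format", "f32le"),
            sessions=d["sessions"],
            provenance=d.get("provenance", {}),
            root=path.parent,
        )
        return m

    def content_hash(self) -> str:
        """Deterministic hash of the manifest contents (not the root path)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_session(
    recording: Recording,
    root: str | Path,
    manifest: DatasetManifest | None = None,
    sample_format: str | None = None,
) -> Path:
    """Write one session (samples + annotations) and update the manifest.

    Returns the samples-file path.  Round-trips losslessly at float32
    precision through :func:`read_session`.
    """
    recording.validate()
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        mpath = root / MANIFEST_NAME
        if mpath.exists():
            manifest = DatasetManifest.load(root)
        else:
            manifest = DatasetManifest(fs=recording.fs, channels=recording.channels)
    if sample_format is not None:
        manifest.sample_format = sample_format
    if recording.fs != manifest.fs or recording.channels != manifest.channels:
        raise ValidationError(
            f"recording fs/channels ({recording.fs}/{recording.channels}) do not "
            f"match manifest ({manifest.fs}/{manifest.channels})"
        )

    stem = _session_stem(
        recording.subject_id, recording.day_index, recording.session_index
    )
    x = recording.samples.astype("<f4")
    if manifest.sample_format == "f32le":
        samples_file = f"{stem}.f32"
        x.tofile(root / samples_file)
    elif manifest.sample_format == "csv":
        samples_file = f"{stem}.csv"
        np.savetxt(root / samples_file, x, delimiter=",", fmt="%.8e")
    else:
        raise ValidationError(
            f"unknown sample_format {manifest.sample_format!r} (f32le or csv)"
        )

    ann_file = f"{stem}_ann.csv"
    ann_df = pd.DataFrame(
        [
            {
                "movement": a.movement,
                "repetition": a.repetition,
                "start_sample": a.start_sample,
                "end_sample": a.end_sample,
            }
            for a in recording.annotations
        ],
        columns=["movement", "repetition", "start_sample", "end_sample"],
    )
    ann_df.to_csv(root / ann_file, index=False)

    entry = {
        "subject_id": recording.subject_id,
        "day_index": recording.day_index,
        "session_index": recording.session_index,
        "n_samples": int(recording.n_samples),
        "samples_file": samples_file,
        "annotations_file": ann_file,
    }
    manifest.sessions = [
        s
        for s in manifest.sessions
        if (s["subject_id"], s["day_index"], s["session_index"])
        != (recording.subject_id, recording.day_index, recording.session_index)
    ]
    manifest.sessions.append(entry)
    manifest.sessions.sort(
        key=lambda s: (s["subject_id"], s["day_index"], s["session_index"])
    )
    manifest.save(root)
    return root / samples_file


def read_session(
    root: str | Path,
    subject_id: str,
    day_index: int,
    session_index: int,
    manifest: DatasetManifest | None = None,
) -> Recording:
    """Read and validate one session listed in the manifest."""
    root = Path(root)
    if manifest is None:
        manifest = DatasetManifest.load(root)
    entry = manifest.entry(subject_id, day_index, session_index)

    spath = root / entry["samples_file"]
    n = entry["n_samples"]
    c = manifest.channels
    if manifest.sample_format == "f32le":
        raw = np.fromfile(spath, dtype="<f4")
        if raw.size != n * c:
            raise ParseError(
                f"{spath}: expected {n * c} float32 values "
                f"({n} x {c}), found {raw.size}"
            )
        samples = raw.reshape(n, c)
    elif manifest.sample_format == "csv":
        try:
            samples = np.loadtxt(spath, delimiter=",", dtype=np.float32, ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{spath}: {exc}") from exc
        if samples.shape != (n, c):
            raise SchemaError(
                f"{spath}: shape {samples.shape} does not match manifest "
                f"({n} x {c})"
            )
    else:
        raise SchemaError(f"unknown sample_format {manifest.sample_format!r}")

    apath = root / entry["annotations_file"]
    try:
        ann_df = pd.read_csv(apath)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{apath}: {exc}") from exc
    required = {"movement", "repetition", "start_sample", "end_sample"}
    if not required.issubset(ann_df.columns):
        raise SchemaError(
            f"{apath}: missing columns {sorted(required - set(ann_df.columns))}"
        )
    annotations = [
        SegmentAnnotation(
            movement=str(r.movement),
            repetition=int(r.repetition),
            start_sample=int(r.start_sample),
            end_sample=int(r.end_sample),
        )
        for r in ann_df.itertuples()
    ]
    return Recording(
        samples=samples,
        fs=manifest.fs,
        subject_id=subject_id,
        day_index=day_index,
        session_index=session_index,
        annotations=annotations,
    )


def iter_recordings(root: str | Path):
    """Yield every Recording listed in the manifest at ``root``, in grid order."""
    manifest = DatasetManifest.load(root)
    for s in manifest.sessions:
        yield read_session(
            root, s["subject_id"], s["day_index"], s["session_index"], manifest
        )
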