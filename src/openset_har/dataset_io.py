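"""Reading recordings, sliding-window segmentation, and label-space bookkeeping.

Windows are raw sensor samples: no filtering, resampling or normalization is
applied anywhere in this module, so the classifier always sees the signal as
recorded.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .synthetic_cohort import (
    CHANNEL_NAMES,
    MANIFEST_COLUMNS,
    N_CHANNELS,
    Recording,
)


@dataclass(frozen=True)
class LabelSpace:
    """Ordered known classes plus the disjoint unknown classes.

    The index of a label in ``known_classes`` is the class index used by the
    backbone; the ordering is therefore stable across training and test.
    """

    known_classes: tuple[str, ...]
    unknown_classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "known_classes", tuple(self.known_classes))
        object.__setattr__(self, "unknown_classes", tuple(self.unknown_classes))
        if len(self.known_classes) < 2:
            raise ConfigurationError("at least 2 known classes are required")
        if len(set(self.known_classes)) != len(self.known_classes):
            raise ConfigurationError("known classes must be unique")
        overlap = set(self.known_classes) & set(self.unknown_classes)
        if overlap:
            raise ConfigurationError(f"known and unknown classes overlap: {overlap}")

    @property
    def n_known(self) -> int:
        return len(self.known_classes)

    def index_of(self, label: str) -> int:
        try:
            return self.known_classes.index(label)
        except ValueError:
            raise ConfigurationError(f"label {label!r} is not a known class") from None

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        """Map labels to class indices; unknown labels raise."""
        return np.array([self.index_of(lab) for lab in labels], dtype=np.int64)


def split_label_space(all_labels: Sequence[str], excluded: str) -> LabelSpace:
    """Hold out one activity as unknown, keeping the order of the rest.

    This is the outer (leave-one-activity-out) step of the open-set protocol.
    """
    all_labels = list(all_labels)
    if excluded not in all_labels:
        raise ConfigurationError(
            f"excluded class {excluded!r} not among labels {all_labels}"
        )
    if len(all_labels) < 3:
        raise ConfigurationError("need at least 3 labels to hold one out")
    known = tuple(lab for lab in all_labels if lab != excluded)
    return LabelSpace(known_classes=known, unknown_classes=(excluded,))


@dataclass
class WindowSet:
    """Fixed-length labelled windows: an (n, T, 6) array with aligned
    per-window activity labels and subject identifiers."""

    windows: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subjects = np.asarray(self.subjects, dtype=object)
        if self.windows.ndim != 3 or self.windows.shape[2] != N_CHANNELS:
            raise DataError(
                f"windows must be (n, T, {N_CHANNELS}), got {self.windows.shape}"
            )
        n = self.windows.shape[0]
        if len(self.labels) != n or len(self.subjects) != n:
            raise DataError("labels and subjects must align with windows")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def window_samples(self) -> int:
        return self.windows.shape[1]

    def select(self, mask: np.ndarray) -> "WindowSet":
        """Row subset (boolean mask or index array), preserving order."""
        return WindowSet(
            windows=self.windows[mask],
            labels=self.labels[mask],
            subjects=self.subjects[mask],
            fs_hz=self.fs_hz,
        )

    def with_labels_in(self, labels: Iterable[str]) -> "WindowSet":
        labels = set(labels)
        return self.select(np.array([lab in labels for lab in self.labels], dtype=bool))

    def with_subjects_in(self, subjects: Iterable[str]) -> "WindowSet":
        subjects = set(subjects)
        return self.select(
            np.array([s in subjects for s in self.subjects], dtype=bool)
        )

    def unique_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return list(seen)

    def unique_subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(s)
        return list(seen)

    def save(self, path: str | os.PathLike, window_s: float | None = None,
             overlap_frac: float | None = None) -> None:
        """Persist as a single .npz container with arrays and metadata."""
        np.savez_compressed(
            path,
            windows=self.windows,
            labels=self.labels.astype(str),
            subjects=self.subjects.astype(str),
            fs_hz=np.float64(self.fs_hz),
            window_s=np.float64(np.nan if window_s is None else window_s),
            overlap=np.float64(np.nan if overlap_frac is None else overlap_frac),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "WindowSet":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                windows=data["windows"],
                labels=data["labels"].astype(object),
                subjects=data["subjects"].astype(object),
                fs_hz=float(data["fs_hz"]),
            )


def concat_window_sets(sets: Sequence[WindowSet]) -> WindowSet:
    if not sets:
        raise ConfigurationError("cannot concatenate zero window sets")
    fs = {ws.fs_hz for ws in sets}
    if len(fs) > 1:
        warnings.warn(f"concatenating window sets with mixed sampling rates {fs}")
    return WindowSet(
        windows=np.concatenate([ws.windows for ws in sets], axis=0),
        labels=np.concatenate([ws.labels for ws in sets]),
        subjects=np.concatenate([ws.subjects for ws in sets]),
        fs_hz=sets[0].fs_hz,
    )


def segment(recording: Recording, window_s: float = 3.0,
            overlap_frac: float = 0.5) -> WindowSet:
    """Slide a fixed-length window over one recording.

    The window holds ``W = round(window_s * fs)`` samples and advances by
    ``step = round(window_s * (1 - overlap_frac) * fs)`` samples (the step is
    defined in seconds first, then converted: 3 s / 50% at 26 Hz gives a
    39-sample step).  Trailing samples that do not fill a window are
    discarded; every window inherits the recording's activity and subject.
    """
    if window_s <= 0:
        raise ConfigurationError(f"window_s must be positive, got {window_s}")
    if not 0 <= overlap_frac < 1:
        raise ConfigurationError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    if not np.isfinite(recording.samples).all():
        bad = np.argwhere(~np.isfinite(recording.samples))[0]
        raise DataError(
            f"non-finite sample in recording {recording.subject_id}/"
            f"{recording.activity} at row {bad[0]}, channel {CHANNEL_NAMES[bad[1]]}"
        )

    w = int(round(window_s * recording.fs_hz))
    step = max(1, int(round(window_s * (1.0 - overlap_frac) * recording.fs_hz)))
    n = recording.n_samples
    if n < w:
        windows = np.empty((0, w, N_CHANNELS))
    else:
        n_windows = (n - w) // step + 1
        starts = np.arange(n_windows) * step
        windows = np.stack([recording.samples[s:s + w] for s in starts])
    count = windows.shape[0]
    return WindowSet(
        windows=windows,
        labels=np.array([recording.activity] * count, dtype=object),
        subjects=np.array([recording.subject_id] * count, dtype=object),
        fs_hz=recording.fs_hz,
    )


def segment_cohort(recordings: Sequence[Recording], window_s: float = 3.0,
                   overlap_frac: float = 0.5) -> WindowSet:
    """Segment every recording and concatenate; windows never span recordings."""
    parts = [segment(rec, window_s, overlap_frac) for rec in recordings]
    parts = [p for p in parts if len(p) > 0]
    if not parts:
        raise DataError("no recording was long enough to produce a single window")
    return concat_window_sets(parts)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_cohort(manifest: str | os.PathLike) -> list[Recording]:
    """Read a cohort from a manifest CSV (columns file,subject_id,activity,fs_hz).

    Recording files must carry the header ``time_s,ax,ay,az,gx,gy,gz``; the
    channel order is normalized to (ax, ay, az, gx, gy, gz) regardless of the
    column order in the file.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise DataError(f"manifest not found: {manifest}")
    table = pd.read_csv(manifest)
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"manifest {manifest} is missing columns {sorted(missing)}")
    if table["fs_hz"].nunique() > 1:
        warnings.warn(
            f"manifest {manifest} mixes sampling rates; per-recording fs honoured"
        )

    recordings = []
    for row in table.itertuples(index=False):
        path = manifest.parent / row.file
        if not path.exists():
            raise DataError(f"recording file referenced by manifest not found: {path}")
        frame = pd.read_csv(path)
        missing_cols = set(CHANNEL_NAMES) - set(frame.columns)
        if missing_cols:
            raise DataError(f"{path} is missing channel columns {sorted(missing_cols)}")
        samples = frame[list(CHANNEL_NAMES)].to_numpy(dtype=np.float64)
        recordings.append(
            Recording(
                subject_id=str(row.subject_id),
                activity=str(row.activity),
                fs_hz=float(row.fs_hz),
                samples=samples,
            )
        )
    return recordings


#: mapping from UCA-EHAR activity labels to this package's label set;
#: sitting and standing are merged into a single low-motion "still" class.
UCA_EHAR_LABEL_MAP = {
    "WALKING": "walking",
    "RUNNING": "running",
    "LYING": "lying",
    "STAIRS": "stairs",
    "DRINKING": "drinking",
    "SITTING": "still",
    "STANDING": "still",
}

UCA_EHAR_FS_HZ = 26.0
_UCA_CHANNELS = ("Ax", "Ay", "Az", "Gx", "Gy", "Gz")


def read_uca_ehar(directory: str | os.PathLike,
                  fs_hz: float = UCA_EHAR_FS_HZ) -> list[Recording]:
    """Read per-subject CSV files laid out like the UCA-EHAR smart-glasses
    dataset (26 Hz, columns Ax..Gz plus an Activity label column).

    Each maximal run of consecutive rows sharing an activity label becomes
    one Recording; labels outside the six selected activities are dropped.
    File stem = subject identifier.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    if not files:
        raise DataError(f"no CSV files found in {directory}")
    recordings = []
    for path in files:
        frame = pd.read_csv(path)
        cols = {c.lower(): c for c in frame.columns}
        try:
            chan_cols = [cols[c.lower()] for c in _UCA_CHANNELS]
            act_col = cols["activity"]
        except KeyError as exc:
            raise DataError(f"{path} lacks expected UCA-EHAR column {exc}") from None
        labels = frame[act_col].astype(str).str.upper().to_numpy()
        samples = frame[chan_cols].to_numpy(dtype=np.float64)
        # split into maximal constant-label runs
        boundaries = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        for chunk_idx, (start, stop) in enumerate(
            zip(np.r_[0, boundaries], np.r_[boundaries, len(labels)])
        ):
            mapped = UCA_EHAR_LABEL_MAP.get(labels[start])
            if mapped is None:
                continue
            recordings.append(
                Recording(
                    subject_id=path.stem,
                    activity=mapped,
                    fs_hz=fs_hz,
                    samples=samples[start:stop],
                )
            )
    if not recordings:
        raise DataError(f"no recognized activity labels in {directory}")
    return recordings
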