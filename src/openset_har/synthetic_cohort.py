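"""Reproducible synthetic multi-subject IMU cohorts.

Emulates a cohort of subjects wearing a head-mounted 6-axis IMU (3-axis
accelerometer in g, 3-axis gyroscope in deg/s) while performing a set of
activities.  Three motion profiles are modelled:

* ``baseline`` — low-motion activities (quiet breathing, sitting still):
  sensor noise plus a constant gravity offset only.
* ``gesture`` — head gestures (nodding, shaking): band-limited oscillatory
  bursts on the gyroscope channels, gated by a 50%-duty on/off envelope.
* ``locomotion`` — whole-body periodic activities (walking, stairs, running):
  a harmonic series at the gait fundamental on the accelerometer channels.

The activity signal is sum_{k=1..H} (A/k) * sin(2*pi*k*f*t + phi) with the
phase phi drawn independently per recording and channel.  Per-subject
variability enters as log-normal multiplicative factors on amplitude and
frequency, drawn once per subject, which creates the inter-subject
generalization gap that subject-wise evaluation protocols probe.  Class
imbalance is reproduced through unequal per-activity durations, the way it
arises in real acquisition protocols, rather than by dropping windows.

Generated signals are never filtered or normalized; the classifier consumes
raw samples.  A cohort is a pure function of its :class:`CohortConfig`
(including the seed): identical configs yield bit-identical sample arrays.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

N_CHANNELS = 6
CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")
ACCEL_CHANNELS = (0, 1, 2)
GYRO_CHANNELS = (3, 4, 5)

#: period of the on/off envelope gating gesture bursts (seconds, 50% duty)
GESTURE_BURST_PERIOD_S = 4.0

#: amplitude ceiling below which a "baseline" profile is considered
#: noise-dominated (g for accel, deg/s for gyro, relative to default noise)
BASELINE_ACCEL_CEILING_G = 0.05
BASELINE_GYRO_CEILING_DPS = 3.0

MOTION_PROFILES = ("baseline", "gesture", "locomotion")


@dataclass(frozen=True)
class ActivitySpec:
    """Parametric description of one activity class.

    Amplitudes apply to the channel family the profile excites: gestures put
    ``gyro_amplitude`` on the gyroscope channels, locomotion puts
    ``accel_amplitude`` on the accelerometer channels, baselines add nothing.
    """

    name: str
    motion_profile: str
    fundamental_freq_hz: float
    accel_amplitude: float = 0.0
    gyro_amplitude: float = 0.0
    duration_s: float = 60.0
    harmonics: int = 3

    def __post_init__(self) -> None:
        if self.motion_profile not in MOTION_PROFILES:
            raise ConfigurationError(
                f"motion_profile must be one of {MOTION_PROFILES}, "
                f"got {self.motion_profile!r}"
            )
        if self.duration_s <= 0:
            raise ConfigurationError(f"duration_s must be positive, got {self.duration_s}")
        if self.harmonics < 1:
            raise ConfigurationError("harmonics must be a positive integer")
        if self.accel_amplitude < 0 or self.gyro_amplitude < 0:
            raise ConfigurationError("amplitudes must be non-negative")
        if self.motion_profile == "baseline":
            if self.fundamental_freq_hz != 0:
                raise ConfigurationError(
                    f"baseline activity {self.name!r} must have fundamental_freq_hz = 0"
                )
            if (
                self.accel_amplitude > BASELINE_ACCEL_CEILING_G
                or self.gyro_amplitude > BASELINE_GYRO_CEILING_DPS
            ):
                raise ConfigurationError(
                    f"baseline activity {self.name!r} amplitudes exceed the "
                    "noise-dominated ceiling"
                )
        elif self.fundamental_freq_hz <= 0:
            raise ConfigurationError(
                f"{self.motion_profile} activity {self.name!r} needs a positive "
                "fundamental frequency"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; the seed covers all randomness."""

    n_subjects: int
    activities: tuple[ActivitySpec, ...]
    fs_hz: float = 26.0
    subject_variability: float = 0.12
    noise_sd: tuple[float, ...] = (0.03, 0.03, 0.03, 1.5, 1.5, 1.5)
    gravity_axis: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be a positive integer")
        if not self.activities:
            raise ConfigurationError("at least one activity is required")
        if self.fs_hz <= 0:
            raise ConfigurationError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.subject_variability < 0:
            raise ConfigurationError("subject_variability must be non-negative")
        noise = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if noise.size == 1:
            noise = np.repeat(noise, N_CHANNELS)
        if noise.size != N_CHANNELS or (noise < 0).any():
            raise ConfigurationError(
                "noise_sd must be a non-negative scalar or length-6 vector"
            )
        object.__setattr__(self, "noise_sd", tuple(float(v) for v in noise))
        object.__setattr__(self, "activities", tuple(self.activities))
        if not 0 <= self.gravity_axis < N_CHANNELS:
            raise ConfigurationError("gravity_axis must index one of the 6 channels")
        names = [a.name for a in self.activities]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate activity names: {names}")


@dataclass
class Recording:
    """One continuous subject x activity 6-channel inertial time series.

    ``samples`` is an (N, 6) float array in channel order
    (ax, ay, az, gx, gy, gz); accelerometer in g, gyroscope in deg/s.
    """

    subject_id: str
    activity: str
    fs_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise DataError(
                f"recording {self.subject_id}/{self.activity}: samples must be "
                f"(N, {N_CHANNELS}), got {self.samples.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def _synthesize(
    spec: ActivitySpec,
    fs_hz: float,
    noise_sd: np.ndarray,
    gravity_axis: int,
    amp_mult: float,
    freq_mult: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one recording's sample array. Draw order is fixed for determinism."""
    n = int(round(spec.duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    x = rng.normal(0.0, 1.0, size=(n, N_CHANNELS)) * noise_sd[None, :]
    x[:, gravity_axis] += 1.0  # constant gravity offset, +1 g

    if spec.motion_profile == "baseline":
        return x

    if spec.motion_profile == "gesture":
        channels, amplitude = GYRO_CHANNELS, spec.gyro_amplitude
    else:  # locomotion
        channels, amplitude = ACCEL_CHANNELS, spec.accel_amplitude

    f0 = spec.fundamental_freq_hz * freq_mult
    a0 = amplitude * amp_mult
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(len(channels), spec.harmonics))
    signal = np.zeros((n, len(channels)))
    for k in range(1, spec.harmonics + 1):
        signal += (a0 / k) * np.sin(
            2.0 * np.pi * k * f0 * t[:, None] + phases[:, k - 1][None, :]
        )

    if spec.motion_profile == "gesture":
        offset = rng.uniform(0.0, GESTURE_BURST_PERIOD_S)
        envelope = ((t + offset) % GESTURE_BURST_PERIOD_S) < GESTURE_BURST_PERIOD_S / 2
        signal *= envelope[:, None]

    x[:, list(channels)] += signal
    return x


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """Generate ``n_subjects * len(activities)`` recordings.

    Per-subject log-normal amplitude/frequency multipliers are drawn once per
    subject; phases, envelope offsets and sensor noise are drawn per
    recording.  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    noise_sd = np.asarray(config.noise_sd, dtype=float)
    sv = config.subject_variability
    # one (amplitude, frequency) multiplier pair per subject
    mults = np.exp(rng.normal(0.0, sv, size=(config.n_subjects, 2)))

    recordings: list[Recording] = []
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        for spec in config.activities:
            samples = _synthesize(
                spec,
                config.fs_hz,
                noise_sd,
                config.gravity_axis,
                amp_mult=mults[s, 0],
                freq_mult=mults[s, 1],
                rng=rng,
            )
            recordings.append(
                Recording(
                    subject_id=subject_id,
                    activity=spec.name,
                    fs_hz=config.fs_hz,
                    samples=samples,
                )
            )
    return recordings


# ---------------------------------------------------------------------------
# canonical configurations
# ---------------------------------------------------------------------------

def default_activities() -> tuple[ActivitySpec, ...]:
    """The default 6-class activity set: one low-motion baseline, two head
    gestures and three locomotion classes with distinct gait signatures.

    Durations are deliberately unequal (breathing longest, gestures shortest)
    to reproduce the class imbalance typical of wearable acquisition
    protocols.
    """
    return (
        ActivitySpec("breathing", "baseline", 0.0, duration_s=180.0),
        ActivitySpec("nodding", "gesture", 1.2, gyro_amplitude=40.0,
                     duration_s=45.0, harmonics=2),
        ActivitySpec("shaking", "gesture", 2.4, gyro_amplitude=70.0,
                     duration_s=45.0, harmonics=2),
        ActivitySpec("walking", "locomotion", 1.8, accel_amplitude=0.35,
                     duration_s=150.0),
        ActivitySpec("stairs", "locomotion", 1.1, accel_amplitude=0.5,
                     duration_s=60.0),
        ActivitySpec("running", "locomotion", 2.8, accel_amplitude=0.9,
                     duration_s=100.0),
    )


def default_cohort_config(seed: int = 0, n_subjects: int = 8) -> CohortConfig:
    """The default synthetic cohort: 8 subjects x 6 activities at 26 Hz."""
    return CohortConfig(n_subjects=n_subjects, activities=default_activities(), seed=seed)


def null_cohort_config(
    seed: int = 0,
    n_subjects: int = 6,
    n_classes: int = 4,
    duration_s: float = 90.0,
) -> CohortConfig:
    """A null cohort in which every class has identical generative parameters.

    All classes are the same locomotion signal under different names, so class
    labels carry no signal: any open-set score should separate an excluded
    class from the knowns at chance level (AUROC ~ 0.5).
    """
    activities = tuple(
        ActivitySpec(f"null_{i + 1}", "locomotion", 1.5, accel_amplitude=0.4,
                     duration_s=duration_s)
        for i in range(n_classes)
    )
    return CohortConfig(n_subjects=n_subjects, activities=activities, seed=seed)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.csv"
MANIFEST_COLUMNS = ("file", "subject_id", "activity", "fs_hz")


def _safe_name(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9_-]+", "-", text)


def write_cohort(
    recordings: Sequence[Recording],
    directory: str | os.PathLike,
    overwrite: bool = False,
) -> Path:
    """Write one CSV per recording plus a manifest; returns the manifest path.

    Recording files have a header row ``time_s,ax,ay,az,gx,gy,gz``; the
    manifest maps each file to its subject, activity and sampling rate.
    Refuses to clobber an existing manifest unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / MANIFEST_NAME
    if manifest_path.exists() and not overwrite:
        raise ConfigurationError(
            f"manifest already exists at {manifest_path}; pass overwrite=True to replace"
        )

    rows = []
    for rec in recordings:
        fname = f"{_safe_name(rec.subject_id)}_{_safe_name(rec.activity)}.csv"
        t = np.arange(rec.n_samples) / rec.fs_hz
        frame = pd.DataFrame(rec.samples, columns=list(CHANNEL_NAMES))
        frame.insert(0, "time_s", t)
        frame.to_csv(directory / fname, index=False, float_format="%.8g")
        rows.append((fname, rec.subject_id, rec.activity, rec.fs_hz))

    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest_path, index=False)
    return manifest_path
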