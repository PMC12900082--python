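"""Shared fixtures: small synthetic cohorts and logit sets.

Heavy artifacts (segmented cohorts, a trained backbone) are session-scoped so
the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from openset_har import (
    ActivitySpec,
    BackboneConfig,
    CohortConfig,
    LabelSpace,
    LogitSet,
    default_cohort_config,
    generate_cohort,
    segment_cohort,
    split_label_space,
    train_backbone,
)


def tiny_activities() -> tuple[ActivitySpec, ...]:
    """Three well-separated classes, one per motion profile, short durations."""
    return (
        ActivitySpec("breathing", "baseline", 0.0, duration_s=60.0),
        ActivitySpec("shaking", "gesture", 2.4, gyro_amplitude=70.0,
                     duration_s=45.0, harmonics=2),
        ActivitySpec("walking", "locomotion", 1.8, accel_amplitude=0.35,
                     duration_s=60.0),
    )


def tiny_cohort_config(seed: int = 0, n_subjects: int = 4) -> CohortConfig:
    return CohortConfig(n_subjects=n_subjects, activities=tiny_activities(),
                        seed=seed)


def make_logitset(rng: np.random.Generator, n_per_class: int = 40,
                  n_classes: int = 3, scale: float = 6.0,
                  spread: float = 1.0) -> LogitSet:
    """Synthetic well-clustered logits: class c centred at scale * e_c."""
    logits, labels, subjects = [], [], []
    for c in range(n_classes):
        mean = np.zeros(n_classes)
        mean[c] = scale
        logits.append(mean + rng.normal(0, spread, (n_per_class, n_classes)))
        labels += [f"c{c}"] * n_per_class
        subjects += [f"S{1 + i % 3}" for i in range(n_per_class)]
    z = np.concatenate(logits)
    return LogitSet(
        logits=z,
        predicted=z.argmax(axis=1),
        true_labels=np.array(labels, dtype=object),
        subjects=np.array(subjects, dtype=object),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_windows():
    """Segmented 4-subject, 3-class cohort (seed 0)."""
    return segment_cohort(generate_cohort(tiny_cohort_config(seed=0)))


@pytest.fixture(scope="session")
def default_windows():
    """Segmented default 8-subject, 6-class cohort (seed 0)."""
    return segment_cohort(generate_cohort(default_cohort_config(seed=0)))


@pytest.fixture(scope="session")
def tiny_model(tiny_windows):
    """A backbone trained on two subjects of the tiny cohort (fast, separable)."""
    label_space = LabelSpace(known_classes=tuple(tiny_windows.unique_labels()))
    train = tiny_windows.with_subjects_in(["S01", "S02", "S03"])
    cfg = BackboneConfig(seed=0)
    return train_backbone(train, label_space, cfg), train


@pytest.fixture(scope="session")
def binary_model(tiny_windows):
    """A backbone on two well-separated classes (~200 windows each); the
    small batch size gives the short run enough gradient updates."""
    train = tiny_windows.with_labels_in(["breathing", "shaking"])
    label_space = LabelSpace(known_classes=("breathing", "shaking"))
    cfg = BackboneConfig(batch_size=16, seed=0)
    return train_backbone(train, label_space, cfg), train
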