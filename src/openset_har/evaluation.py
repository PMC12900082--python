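"""Evaluation protocols: closed-set subject-wise k-fold CV and the nested
leave-one-activity-out (LOAO) x leave-one-subject-out (LOSO) open-set scheme.

Both protocols enforce strict subject independence: no subject contributes
windows to both the training and test side of any fold.  Under LOAO the
excluded activity is additionally absent from every training partition; its
windows appear only as ground-truth unknowns in the test partitions, and
only from the held-out subject of each inner fold.  Discrimination between
known and unknown test windows is summarized by the AUROC in its
Mann-Whitney formulation (ties counted 1/2); the headline number per
excluded class pools the scores of all inner folds, with per-fold AUROCs
reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_fscore_support

from .backbone import BackboneConfig, TrainedBackbone, compute_logits, train_backbone
from .dataset_io import LabelSpace, WindowSet, split_label_space
from .errors import ConfigurationError, DataError
from .osr_scoring import METHODS, fit_scorer, score_batch

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(scores_known: Sequence[float], scores_unknown: Sequence[float]) -> float:
    """Probability that a random unknown outscores a random known, ties 1/2.

    Equivalent to the normalized Mann-Whitney U statistic, computed via
    midranks so tied scores contribute half a concordant pair.
    """
    known = np.asarray(scores_known, dtype=float)
    unknown = np.asarray(scores_unknown, dtype=float)
    if known.size == 0 or unknown.size == 0:
        raise DataError("auroc requires at least one known and one unknown score")
    ranks = rankdata(np.concatenate([unknown, known]))
    r_unknown = ranks[: unknown.size].sum()
    n_u, n_k = unknown.size, known.size
    return float((r_unknown - n_u * (n_u + 1) / 2.0) / (n_u * n_k))


# ---------------------------------------------------------------------------
# closed-set subject-wise k-fold CV
# ---------------------------------------------------------------------------

@dataclass
class ClosedSetResult:
    """Per-class precision/recall/F1 and accuracy, mean +- sd across folds."""

    classes: tuple[str, ...]
    per_class: pd.DataFrame      # index=class, columns precision/recall/f1 _mean/_sd
    accuracy_mean: float
    accuracy_sd: float
    macro_f1_mean: float
    macro_f1_sd: float
    fold_subjects: list[tuple[str, ...]] = field(default_factory=list)


def _subject_folds(subjects: list[str], k: int, seed: int) -> list[tuple[str, ...]]:
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    if len(subjects) < k:
        raise ConfigurationError(
            f"cannot make {k} subject folds from {len(subjects)} subjects"
        )
    rng = np.random.default_rng(seed)
    order = list(np.array(subjects, dtype=object)[rng.permutation(len(subjects))])
    return [tuple(part) for part in np.array_split(order, k)]


PredictFn = Callable[[WindowSet, WindowSet, LabelSpace], np.ndarray]


def _default_predict(train_ws: WindowSet, test_ws: WindowSet,
                     label_space: LabelSpace,
                     config: BackboneConfig) -> np.ndarray:
    model = train_backbone(train_ws, label_space, config)
    logits = compute_logits(model, test_ws)
    return np.array(
        [label_space.known_classes[i] for i in logits.predicted], dtype=object
    )


def closed_set_cv(windows: WindowSet, k: int = 5,
                  config: BackboneConfig | None = None,
                  predict_fn: PredictFn | None = None) -> ClosedSetResult:
    """Subject-wise k-fold cross-validation of the closed-set classifier.

    Subjects are partitioned into k disjoint groups (seeded shuffle); each
    fold trains on k-1 groups and evaluates on the held-out group, so every
    subject is tested exactly once.  ``predict_fn`` may replace the default
    backbone training, e.g. for protocol self-tests.
    """
    config = config or BackboneConfig()
    subjects = windows.unique_subjects()
    folds = _subject_folds(subjects, k, config.seed)
    classes = tuple(windows.unique_labels())
    label_space = LabelSpace(known_classes=classes)

    rows, accs, f1s = [], [], []
    for fold_idx, test_subjects in enumerate(folds):
        test_ws = windows.with_subjects_in(test_subjects)
        train_ws = windows.select(
            np.array([s not in set(test_subjects) for s in windows.subjects])
        )
        if predict_fn is not None:
            predicted = predict_fn(train_ws, test_ws, label_space)
        else:
            predicted = _default_predict(train_ws, test_ws, label_space, config)
        y_true = label_space.encode(test_ws.labels)
        y_pred = label_space.encode(predicted)
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list(range(len(classes))), zero_division=0
        )
        accs.append(float(np.mean(y_true == y_pred)))
        f1s.append(float(np.mean(f1)))
        rows.append((prec, rec, f1))
        logger.info("closed-set fold %d/%d: accuracy %.3f macro-F1 %.3f",
                    fold_idx + 1, k, accs[-1], f1s[-1])

    prec = np.array([r[0] for r in rows])
    rec = np.array([r[1] for r in rows])
    f1 = np.array([r[2] for r in rows])
    per_class = pd.DataFrame(
        {
            "precision_mean": prec.mean(0), "precision_sd": prec.std(0, ddof=0),
            "recall_mean": rec.mean(0), "recall_sd": rec.std(0, ddof=0),
            "f1_mean": f1.mean(0), "f1_sd": f1.std(0, ddof=0),
        },
        index=list(classes),
    )
    return ClosedSetResult(
        classes=classes,
        per_class=per_class,
        accuracy_mean=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=0)),
        macro_f1_mean=float(np.mean(f1s)),
        macro_f1_sd=float(np.std(f1s, ddof=0)),
        fold_subjects=folds,
    )


# ---------------------------------------------------------------------------
# nested LOAO x LOSO open-set protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """One inner fold of the nested protocol: which activity is unknown and
    which subject is held out; train/test subject sets are disjoint."""

    excluded_activity: str
    test_subject: str
    train_subjects: tuple[str, ...]


@dataclass
class FoldScore:
    subject: str
    n_known: int
    n_unknown: int
    auroc: float


@dataclass
class OpenSetResult:
    """Open-set discrimination for one (excluded class, method) pair."""

    excluded_class: str
    method: str
    per_fold: list[FoldScore]
    pooled_auroc: float
    degenerate_subjects: list[str] = field(default_factory=list)


@dataclass
class FoldAudit:
    """Index bookkeeping for the leakage audit: positions (into the source
    WindowSet) of each partition of one inner fold."""

    plan: FoldPlan
    train_idx: np.ndarray
    test_known_idx: np.ndarray
    test_unknown_idx: np.ndarray


def plan_loao_loso(windows: WindowSet, excluded: str) -> list[FoldPlan]:
    """Enumerate the inner LOSO folds for one excluded activity."""
    subjects = windows.unique_subjects()
    labels = np.asarray(windows.labels, dtype=object)
    subs = np.asarray(windows.subjects, dtype=object)
    usable = [
        s for s in subjects
        if ((subs == s) & (labels == excluded)).any()
        and ((subs == s) & (labels != excluded)).any()
    ]
    if len(usable) < 3:
        raise ConfigurationError(
            f"need at least 3 subjects with both known and {excluded!r} windows, "
            f"found {len(usable)}"
        )
    return [
        FoldPlan(
            excluded_activity=excluded,
            test_subject=s,
            train_subjects=tuple(t for t in subjects if t != s),
        )
        for s in subjects
    ]


def aggregate_open_set(
    excluded: str,
    method: str,
    fold_entries: Sequence[tuple[str, np.ndarray, np.ndarray]],
) -> OpenSetResult:
    """Combine per-fold (subject, known scores, unknown scores) into per-fold
    AUROCs plus a pooled AUROC over the union of all folds' scores.  Folds
    with no unknown (or no known) test windows are flagged degenerate and
    excluded from pooling."""
    per_fold: list[FoldScore] = []
    degenerate: list[str] = []
    pool_known: list[np.ndarray] = []
    pool_unknown: list[np.ndarray] = []
    for subject, s_known, s_unknown in fold_entries:
        s_known = np.asarray(s_known, dtype=float)
        s_unknown = np.asarray(s_unknown, dtype=float)
        if s_known.size == 0 or s_unknown.size == 0:
            logger.warning(
                "degenerate fold (excluded=%s, subject=%s): %d known, %d unknown"
                " test windows; skipped in pooling",
                excluded, subject, s_known.size, s_unknown.size,
            )
            degenerate.append(subject)
            continue
        per_fold.append(FoldScore(
            subject=subject,
            n_known=int(s_known.size),
            n_unknown=int(s_unknown.size),
            auroc=auroc(s_known, s_unknown),
        ))
        pool_known.append(s_known)
        pool_unknown.append(s_unknown)
    if not pool_known:
        raise DataError(
            f"every inner fold for excluded={excluded!r} was degenerate"
        )
    pooled = auroc(np.concatenate(pool_known), np.concatenate(pool_unknown))
    return OpenSetResult(
        excluded_class=excluded,
        method=method,
        per_fold=per_fold,
        pooled_auroc=pooled,
        degenerate_subjects=degenerate,
    )


def loao_loso_evaluate(
    windows: WindowSet,
    excluded: str,
    methods: Sequence[str] | None = None,
    config: BackboneConfig | None = None,
    scorer_options: Mapping[str, Mapping] | None = None,
    collect_audit: bool = False,
):
    """Run the nested protocol for one excluded activity.

    For each held-out subject s: a backbone is trained from scratch on the
    known-class windows of all other subjects, every scorer is calibrated on
    that fold's training logits, and subject s's known-class and
    excluded-class windows are scored.  Returns one OpenSetResult per method
    (and the per-fold index audit when ``collect_audit`` is set).
    """
    methods = list(methods) if methods is not None else list(METHODS)
    unknown_methods = set(methods) - set(METHODS)
    if unknown_methods:
        raise ConfigurationError(f"unknown scoring methods: {sorted(unknown_methods)}")
    config = config or BackboneConfig()
    scorer_options = scorer_options or {}

    label_space = split_label_space(windows.unique_labels(), excluded)
    known_set = set(label_space.known_classes)
    plans = plan_loao_loso(windows, excluded)

    fold_entries: dict[str, list[tuple[str, np.ndarray, np.ndarray]]] = {
        m: [] for m in methods
    }
    audits: list[FoldAudit] = []

    labels_arr = windows.labels
    subjects_arr = windows.subjects
    for fold_idx, plan in enumerate(plans):
        is_test_subject = np.array(
            [s == plan.test_subject for s in subjects_arr], dtype=bool
        )
        is_known = np.array([lab in known_set for lab in labels_arr], dtype=bool)
        train_idx = np.flatnonzero(~is_test_subject & is_known)
        test_known_idx = np.flatnonzero(is_test_subject & is_known)
        test_unknown_idx = np.flatnonzero(
            is_test_subject & (labels_arr == excluded)
        )
        if collect_audit:
            audits.append(FoldAudit(plan, train_idx, test_known_idx,
                                    test_unknown_idx))
        if test_unknown_idx.size == 0 or test_known_idx.size == 0:
            for m in methods:
                fold_entries[m].append(
                    (plan.test_subject, np.empty(0), np.empty(0))
                )
            continue

        fold_config = replace(config, seed=config.seed + fold_idx)
        train_ws = windows.select(train_idx)
        model = train_backbone(train_ws, label_space, fold_config)
        train_logits = compute_logits(model, train_ws)
        train_classes = label_space.encode(train_ws.labels)
        test_logits_known = compute_logits(model, windows.select(test_known_idx))
        test_logits_unknown = compute_logits(model, windows.select(test_unknown_idx))

        for m in methods:
            scorer = fit_scorer(m, train_logits,
                                options=scorer_options.get(m),
                                class_indices=train_classes)
            fold_tag = f"{excluded}|{plan.test_subject}"
            s_known = score_batch(scorer, test_logits_known, fold_tag).scores
            s_unknown = score_batch(scorer, test_logits_unknown, fold_tag).scores
            fold_entries[m].append((plan.test_subject, s_known, s_unknown))
        logger.info("LOAO %s fold %d/%d (subject %s) done",
                    excluded, fold_idx + 1, len(plans), plan.test_subject)

    results = [
        aggregate_open_set(excluded, m, fold_entries[m]) for m in methods
    ]
    if collect_audit:
        return results, audits
    return results


def open_set_results_frame(results: Sequence[OpenSetResult]) -> pd.DataFrame:
    """Tidy per-fold results: excluded_class,method,subject,auroc,n_known,n_unknown."""
    rows = []
    for res in results:
        for fold in res.per_fold:
            rows.append({
                "excluded_class": res.excluded_class,
                "method": res.method,
                "subject": fold.subject,
                "auroc": fold.auroc,
                "n_known": fold.n_known,
                "n_unknown": fold.n_unknown,
            })
    return pd.DataFrame(
        rows, columns=["excluded_class", "method", "subject", "auroc",
                       "n_known", "n_unknown"]
    )


def pooled_auroc_table(results: Sequence[OpenSetResult]) -> pd.DataFrame:
    """Pivot of pooled AUROC: rows = excluded class, columns = method."""
    rows = [
        {"excluded_class": r.excluded_class, "method": r.method,
         "pooled_auroc": r.pooled_auroc}
        for r in results
    ]
    frame = pd.DataFrame(rows)
    return frame.pivot(index="excluded_class", columns="method",
                       values="pooled_auroc")
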