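"""Post hoc open-set scores defined on the classifier's logit vectors.

Each method maps a C-dimensional logit vector z(x) to a scalar score S(x),
with the convention that higher scores indicate a higher likelihood that the
window belongs to an unknown activity class.  All methods operate strictly in
logit space and leave the classifier untouched:

* ``mls``     — negative maximum logit, S = -max_c z_c.
* ``energy``  — the energy score S = -T * log sum_c exp(z_c / T); at T -> 0
  it recovers the negative maximum logit.
* ``nndr``    — nearest-neighbor distance ratio: Euclidean distance to the
  closest stored training logit of the predicted class over the distance to
  the closest logit of any other class.
* ``gmm``     — negative log-likelihood under one full-covariance Gaussian
  per known class, mixed with empirical class priors.
* ``kde``     — negative log-likelihood under per-class Gaussian kernel
  density estimates mixed with empirical class priors.
* ``openmax`` — extreme-value recalibration: per-class mean activation
  vectors (MAVs) over correctly classified training logits, Weibull tails
  fitted to the largest combined Euclidean+cosine distances, activation mass
  of the top-alpha classes shifted to an explicit unknown class; the score is
  the softmax probability of that unknown class.

Calibration (``fit_scorer``) sees only known-class training logits; scoring
never updates state.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import joblib
import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from scipy.stats import multivariate_normal, weibull_min
from sklearn.neighbors import KernelDensity

from .backbone import LogitSet
from .errors import CalibrationError, ConfigurationError

METHODS = ("mls", "energy", "nndr", "gmm", "kde", "openmax")

#: clamp for otherwise unbounded scores (keeps AUROC well-defined)
SCORE_CAP = 1e6

DEFAULT_OPTIONS: dict[str, dict[str, Any]] = {
    "mls": {},
    "energy": {"temperature": 1.0},
    "nndr": {"cap": SCORE_CAP},
    "gmm": {"covariance_regularization": 1e-6},
    "kde": {"bandwidth": "scott", "bandwidth_floor": 1e-3},
    "openmax": {"tail_size": 20, "alpha": None},  # alpha None -> min(3, C)
}


@dataclass
class ScorerModel:
    """Calibration state for one scoring method (a pure function of the
    training logits and options)."""

    method: str
    n_classes: int
    state: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)


@dataclass
class ScoreVector:
    """Scores for a batch of windows, higher = more likely unknown."""

    scores: np.ndarray
    method: str
    fold_id: str = ""


def _merged_options(method: str, options: Mapping[str, Any] | None) -> dict:
    if method not in METHODS:
        raise ConfigurationError(f"unknown scoring method {method!r}; use one of {METHODS}")
    merged = dict(DEFAULT_OPTIONS[method])
    for key, value in (options or {}).items():
        if key not in merged:
            raise ConfigurationError(f"unknown option {key!r} for method {method!r}")
        merged[key] = value
    return merged


def _combined_distance(z: np.ndarray, mav: np.ndarray) -> float:
    """Euclidean plus cosine distance between a logit vector and a MAV."""
    eu = float(np.linalg.norm(z - mav))
    denom = np.linalg.norm(z) * np.linalg.norm(mav)
    cos = 1.0 - float(z @ mav) / denom if denom > 0 else 1.0
    return eu + cos


def fit_scorer(method: str, train_logits: LogitSet,
               options: Mapping[str, Any] | None = None,
               class_indices: np.ndarray | None = None) -> ScorerModel:
    """Calibrate one scoring method on known-class training logits.

    ``class_indices`` gives the true class index of each row; if omitted it
    is derived by sorting the distinct labels, which matches the encoding
    only when labels sort in class-index order — callers inside the
    evaluation protocol always pass it explicitly.
    """
    opts = _merged_options(method, options)
    z = np.asarray(train_logits.logits, dtype=float)
    n, c = z.shape
    if class_indices is None:
        order = {lab: i for i, lab in enumerate(sorted(set(map(str, train_logits.true_labels))))}
        class_indices = np.array([order[str(lab)] for lab in train_logits.true_labels])
    class_indices = np.asarray(class_indices)
    counts = np.bincount(class_indices, minlength=c)
    if (counts == 0).any():
        raise CalibrationError(
            f"classes with no training logits: {np.flatnonzero(counts == 0).tolist()}"
        )
    priors = counts / counts.sum()
    model = ScorerModel(method=method, n_classes=c, options=opts)

    if method == "mls":
        return model

    if method == "energy":
        t = float(opts["temperature"])
        if t <= 0:
            raise ConfigurationError(f"energy temperature must be positive, got {t}")
        model.state = {"temperature": t}
        return model

    if method == "nndr":
        model.state = {
            "class_logits": {int(k): z[class_indices == k] for k in range(c)},
            "cap": float(opts["cap"]),
        }
        return model

    if method == "gmm":
        reg = float(opts["covariance_regularization"])
        if (counts < c + 1).any():
            short = np.flatnonzero(counts < c + 1).tolist()
            raise CalibrationError(
                f"gmm needs at least {c + 1} samples per class; too few in classes {short}"
            )
        means, covs = [], []
        for k in range(c):
            zk = z[class_indices == k]
            means.append(zk.mean(axis=0))
            cov = np.cov(zk, rowvar=False) + reg * np.eye(c)
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                raise CalibrationError(
                    f"covariance of class {k} singular even after regularization"
                ) from None
            covs.append(cov)
        model.state = {"means": np.array(means), "covs": np.array(covs),
                       "priors": priors}
        return model

    if method == "kde":
        floor = float(opts["bandwidth_floor"])
        kdes, bandwidths = {}, {}
        for k in range(c):
            zk = z[class_indices == k]
            if opts["bandwidth"] == "scott":
                # Scott's rule: n^(-1/(d+4)) times the average marginal spread
                spread = float(np.sqrt(np.mean(np.var(zk, axis=0, ddof=1))
                                       )) if len(zk) > 1 else 0.0
                h = max(spread * len(zk) ** (-1.0 / (c + 4)), floor)
            else:
                h = float(opts["bandwidth"])
                if h <= 0:
                    raise ConfigurationError("kde bandwidth must be positive")
            kde = KernelDensity(kernel="gaussian", bandwidth=h).fit(zk)
            kdes[k] = kde
            bandwidths[k] = h
        model.state = {"kdes": kdes, "bandwidths": bandwidths, "priors": priors}
        return model

    # openmax
    tail_size = int(opts["tail_size"])
    alpha = opts["alpha"]
    alpha = min(3, c) if alpha is None else int(alpha)
    if not 1 <= alpha <= c:
        raise ConfigurationError(f"openmax alpha must be in [1, {c}], got {alpha}")
    correct = train_logits.predicted == class_indices
    mavs, weibulls = [], []
    for k in range(c):
        zk = z[(class_indices == k) & correct]
        if len(zk) == 0:
            raise CalibrationError(
                f"openmax: class {k} has zero correctly classified training samples"
            )
        mav = zk.mean(axis=0)
        dists = np.array([_combined_distance(row, mav) for row in zk])
        eff_tail = min(tail_size, len(dists))
        if eff_tail < tail_size:
            warnings.warn(
                f"openmax tail_size {tail_size} exceeds class {k} sample count; "
                f"truncated to {eff_tail}"
            )
        tail = np.sort(dists)[-eff_tail:]
        # degenerate tails (all-equal distances) get a tiny jitter-free fallback
        if np.ptp(tail) == 0:
            shape_, scale_ = 1.0, max(float(tail[-1]), 1e-8)
        else:
            shape_, _, scale_ = weibull_min.fit(tail, floc=0)
        if scale_ <= 0 or shape_ <= 0:
            raise CalibrationError(f"openmax: degenerate Weibull fit for class {k}")
        mavs.append(mav)
        weibulls.append((float(shape_), float(scale_)))
    model.state = {"mavs": np.array(mavs), "weibulls": weibulls,
                   "alpha": alpha, "tail_size": tail_size}
    return model


def save_scorer(model: ScorerModel, path: str | os.PathLike) -> None:
    """Persist a calibrated scorer as a single-file archive."""
    joblib.dump(model, path)


def load_scorer(path: str | os.PathLike) -> ScorerModel:
    model = joblib.load(path)
    if not isinstance(model, ScorerModel):
        raise ConfigurationError(f"{path} does not hold a scorer model")
    return model


# ---------------------------------------------------------------------------
# per-sample scores
# ---------------------------------------------------------------------------

def score_mls(z: np.ndarray) -> float:
    """Negative maximum logit."""
    z = np.asarray(z, dtype=float)
    return float(-np.max(z))


def score_energy(z: np.ndarray, temperature: float = 1.0) -> float:
    """Energy score, -T * log sum exp(z/T), overflow-safe."""
    if temperature <= 0:
        raise ConfigurationError(f"temperature must be positive, got {temperature}")
    z = np.asarray(z, dtype=float)
    return float(-temperature * logsumexp(z / temperature))


def score_nndr(model: ScorerModel, z: np.ndarray) -> float:
    """Distance to nearest stored logit of the predicted class over distance
    to the nearest logit of any other class."""
    z = np.asarray(z, dtype=float)
    pred = int(np.argmax(z))
    store = model.state["class_logits"]
    d_same = float(np.min(np.linalg.norm(store[pred] - z, axis=1)))
    others = np.concatenate([v for k, v in store.items() if k != pred])
    d_diff = float(np.min(np.linalg.norm(others - z, axis=1)))
    if d_diff == 0.0:
        return 1.0 if d_same == 0.0 else model.state["cap"]
    return d_same / d_diff


def _gmm_log_density(model: ScorerModel, z: np.ndarray) -> np.ndarray:
    """Log of sum_c pi_c N(z | mu_c, Sigma_c) for a batch of rows."""
    means, covs, priors = (model.state[k] for k in ("means", "covs", "priors"))
    parts = np.stack([
        np.log(priors[k])
        + np.atleast_1d(multivariate_normal.logpdf(z, means[k], covs[k]))
        for k in range(model.n_classes)
    ])
    return logsumexp(parts, axis=0)


def score_gmm(model: ScorerModel, z: np.ndarray) -> float:
    """Negative log-likelihood under the class-conditional Gaussian mixture."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return float(-_gmm_log_density(model, z)[0])


def _kde_log_density(model: ScorerModel, z: np.ndarray) -> np.ndarray:
    kdes, priors = model.state["kdes"], model.state["priors"]
    parts = np.stack([
        np.log(priors[k]) + kdes[k].score_samples(z)
        for k in range(model.n_classes)
    ])
    return logsumexp(parts, axis=0)


def score_kde(model: ScorerModel, z: np.ndarray) -> float:
    """Negative log-likelihood under the per-class kernel density mixture."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return float(np.clip(-_kde_log_density(model, z)[0], -SCORE_CAP, SCORE_CAP))


def _openmax_probs(model: ScorerModel, z: np.ndarray) -> np.ndarray:
    """The revised (C+1)-class softmax vector; the last slot is 'unknown'."""
    z = np.asarray(z, dtype=float)
    mavs = model.state["mavs"]
    weibulls = model.state["weibulls"]
    alpha = model.state["alpha"]
    c = model.n_classes
    # rank classes by activation, highest first; rank 1 gets the full factor
    ranked = np.argsort(-z, kind="stable")
    z_hat = z.copy()
    unknown = 0.0
    for rank, k in enumerate(ranked[:alpha], start=1):
        shape_, scale_ = weibulls[k]
        delta = _combined_distance(z, mavs[k])
        omega = (alpha - rank + 1) / alpha * float(
            weibull_min.cdf(delta, shape_, loc=0, scale=scale_)
        )
        z_hat[k] = z[k] * (1.0 - omega)
        unknown += z[k] * omega
    full = np.append(z_hat, unknown)
    full = full - full.max()
    e = np.exp(full)
    return e / e.sum()


def score_openmax(model: ScorerModel, z: np.ndarray) -> float:
    """Probability mass assigned to the explicit unknown class."""
    return float(_openmax_probs(model, z)[-1])


# ---------------------------------------------------------------------------
# batch application
# ---------------------------------------------------------------------------

def score_batch(model: ScorerModel, logits: LogitSet, fold_id: str = "") -> ScoreVector:
    """Score every row of a LogitSet; order-preserving and vectorized where
    the method allows."""
    z = np.asarray(logits.logits, dtype=float)
    if z.ndim != 2 or z.shape[1] != model.n_classes:
        raise ConfigurationError(
            f"logit width {z.shape} does not match model C={model.n_classes}"
        )
    m = model.method
    if m == "mls":
        scores = -z.max(axis=1)
    elif m == "energy":
        t = model.state.get("temperature", 1.0)
        scores = -t * logsumexp(z / t, axis=1)
    elif m == "nndr":
        store = model.state["class_logits"]
        cap = model.state["cap"]
        pred = z.argmax(axis=1)
        scores = np.empty(len(z))
        for k in np.unique(pred):
            rows = np.flatnonzero(pred == k)
            d_same = cdist(z[rows], store[int(k)]).min(axis=1)
            others = np.concatenate(
                [v for kk, v in store.items() if kk != int(k)]
            )
            d_diff = cdist(z[rows], others).min(axis=1)
            s = np.where(
                d_diff == 0, np.where(d_same == 0, 1.0, cap), d_same / np.maximum(d_diff, 1e-300)
            )
            scores[rows] = s
    elif m == "gmm":
        scores = -_gmm_log_density(model, z)
    elif m == "kde":
        scores = np.clip(-_kde_log_density(model, z), -SCORE_CAP, SCORE_CAP)
    else:  # openmax
        scores = np.array([score_openmax(model, row) for row in z])
    scores = np.clip(np.nan_to_num(scores, nan=SCORE_CAP, posinf=SCORE_CAP,
                                   neginf=-SCORE_CAP), -SCORE_CAP, SCORE_CAP)
    return ScoreVector(scores=scores, method=m, fold_id=fold_id)
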