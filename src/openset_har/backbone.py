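"""The closed-set classifier: a lightweight two-block 1D CNN over raw IMU windows.

Architecture (per window of shape T x 6):

    Conv1D(6 -> 16, same padding) - ReLU - MaxPool(2)
    Conv1D(16 -> 32, same padding) - ReLU - MaxPool(2)
    global average pooling over time  -> 32-d feature
    layer normalization
    fully connected (32 -> fc_hidden) - ReLU - dropout
    linear (fc_hidden -> C)  -> logit vector z(x)

The global average pool makes the network agnostic to the window length T
(and hence to the sampling rate), always yielding the compact 32-dimensional
representation.  Classification is argmax over logits (ties broken by lowest
class index); open-set scoring consumes the raw logits, never the softmax.

Training: class-weighted cross-entropy, Adam with weight decay, a stratified
80/20 train/validation split of the known-class windows, reduce-on-plateau
learning-rate scheduling and early stopping driven by validation macro-F1;
the returned model is the epoch with the best validation macro-F1.  The
network is small enough that forward and backward passes are implemented
directly on numpy arrays, keeping the package free of deep-learning
framework dependencies and making runs bit-reproducible from a single seed.
"""

from __future__ import annotations

import copy
import io
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split

from .dataset_io import LabelSpace, WindowSet
from .errors import ConfigurationError, DataError
from .synthetic_cohort import N_CHANNELS


@dataclass(frozen=True)
class BackboneConfig:
    """Hyperparameters of the CNN backbone and its training loop."""

    conv_channels: tuple[int, int] = (16, 32)
    kernel_size: int = 7
    pool_size: int = 2
    fc_hidden: int = 64
    dropout_rate: float = 0.3
    lr: float = 1e-3
    weight_decay: float = 1e-5
    max_epochs: int = 50
    batch_size: int = 64
    val_fraction: float = 0.2
    early_stop_patience: int = 10
    scheduler_patience: int = 3
    scheduler_factor: float = 0.5
    seed: int = 0

    @property
    def feature_dim(self) -> int:
        # the post-pooling representation width equals the second conv block
        return self.conv_channels[1]

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.weight_decay < 0:
            raise ConfigurationError("lr must be positive, weight_decay non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if not 0 < self.val_fraction < 1:
            raise ConfigurationError("val_fraction must be in (0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("max_epochs and batch_size must be positive")
        object.__setattr__(self, "conv_channels", tuple(self.conv_channels))


# ---------------------------------------------------------------------------
# layer primitives (forward + backward on numpy arrays)
# ---------------------------------------------------------------------------

def _conv1d_forward(x, w, b):
    """x: (B, Cin, T); w: (Cout, Cin, K); same padding. Returns (out, cache)."""
    k = w.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    patches = sliding_window_view(xp, k, axis=2)  # (B, Cin, T, K)
    out = np.einsum("bctk,ock->bot", patches, w, optimize=True) + b[None, :, None]
    return out, (xp, patches, w, pad, x.shape[2])


def _conv1d_backward(dout, cache):
    xp, patches, w, pad, t_in = cache
    dw = np.einsum("bot,bctk->ock", dout, patches, optimize=True)
    db = dout.sum(axis=(0, 2))
    dxp = np.zeros_like(xp)
    t_out = dout.shape[2]
    for k in range(w.shape[2]):
        dxp[:, :, k:k + t_out] += np.einsum("bot,oc->bct", dout, w[:, :, k],
                                            optimize=True)
    dx = dxp[:, :, pad:pad + t_in] if pad else dxp
    return dx, dw, db


def _maxpool_forward(x, p):
    """Non-overlapping max pool along time; trailing remainder dropped."""
    b, c, t = x.shape
    tp = t - (t % p)
    xr = x[:, :, :tp].reshape(b, c, tp // p, p)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
    return out, (idx, x.shape, p)


def _maxpool_backward(dout, cache):
    idx, shape, p = cache
    b, c, t = shape
    tp = t - (t % p)
    dxr = np.zeros((b, c, tp // p, p), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=3)
    dx = np.zeros(shape, dtype=dout.dtype)
    dx[:, :, :tp] = dxr.reshape(b, c, tp)
    return dx


_LN_EPS = 1e-5


def _layernorm_forward(x, gamma, beta):
    """Normalize each row over the feature axis. x: (B, D)."""
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return gamma * xhat + beta, (xhat, inv, gamma)


def _layernorm_backward(dout, cache):
    xhat, inv, gamma = cache
    d = xhat.shape[1]
    dgamma = (dout * xhat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    dxhat = dout * gamma
    dx = (inv / d) * (
        d * dxhat
        - dxhat.sum(axis=1, keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
    )
    return dx, dgamma, dbeta


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Net:
    """Parameter container with forward/backward passes for the backbone."""

    PARAM_NAMES = ("w1", "b1", "w2", "b2", "ln_g", "ln_b", "w3", "b3", "w4", "b4")

    def __init__(self, config: BackboneConfig, n_classes: int,
                 rng: np.random.Generator):
        c1, c2 = config.conv_channels
        k, h = config.kernel_size, config.fc_hidden

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "w1": he((c1, N_CHANNELS, k), N_CHANNELS * k),
            "b1": np.zeros(c1),
            "w2": he((c2, c1, k), c1 * k),
            "b2": np.zeros(c2),
            "ln_g": np.ones(c2),
            "ln_b": np.zeros(c2),
            "w3": he((c2, h), c2),
            "b3": np.zeros(h),
            "w4": he((h, n_classes), h),
            "b4": np.zeros(n_classes),
        }
        self.config = config
        self.n_classes = n_classes

    def forward(self, x, dropout_rng=None):
        """x: (B, T, 6) -> logits (B, C). Dropout active iff a rng is given."""
        p = self.params
        cfg = self.config
        x = np.ascontiguousarray(x.transpose(0, 2, 1))  # (B, 6, T)
        cache = {}
        a1, cache["c1"] = _conv1d_forward(x, p["w1"], p["b1"])
        r1 = np.maximum(a1, 0.0)
        cache["r1"] = a1 > 0
        m1, cache["m1"] = _maxpool_forward(r1, cfg.pool_size)
        a2, cache["c2"] = _conv1d_forward(m1, p["w2"], p["b2"])
        r2 = np.maximum(a2, 0.0)
        cache["r2"] = a2 > 0
        m2, cache["m2"] = _maxpool_forward(r2, cfg.pool_size)
        cache["t2"] = m2.shape[2]
        g = m2.mean(axis=2)  # global average pool -> (B, c2)
        ln, cache["ln"] = _layernorm_forward(g, p["ln_g"], p["ln_b"])
        h_pre = ln @ p["w3"] + p["b3"]
        h = np.maximum(h_pre, 0.0)
        cache["r3"] = h_pre > 0
        cache["ln_out"] = ln
        if dropout_rng is not None and cfg.dropout_rate > 0:
            mask = (dropout_rng.random(h.shape) >= cfg.dropout_rate) / (
                1.0 - cfg.dropout_rate
            )
            h = h * mask
            cache["drop"] = mask
        cache["h"] = h
        logits = h @ p["w4"] + p["b4"]
        self._cache = cache
        return logits

    def backward(self, dlogits):
        """Gradient of the loss w.r.t. every parameter; input grad discarded."""
        p, cfg, cache = self.params, self.config, self._cache
        grads = {}
        grads["w4"] = cache["h"].T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dh = dlogits @ p["w4"].T
        if "drop" in cache:
            dh = dh * cache["drop"]
        dh_pre = dh * cache["r3"]
        grads["w3"] = cache["ln_out"].T @ dh_pre
        grads["b3"] = dh_pre.sum(axis=0)
        dln = dh_pre @ p["w3"].T
        dg, grads["ln_g"], grads["ln_b"] = _layernorm_backward(dln, cache["ln"])
        dm2 = np.repeat(dg[:, :, None] / cache["t2"], cache["t2"], axis=2)
        dr2 = _maxpool_backward(dm2, cache["m2"])
        da2 = dr2 * cache["r2"]
        dm1, grads["w2"], grads["b2"] = _conv1d_backward(da2, cache["c2"])
        dr1 = _maxpool_backward(dm1, cache["m1"])
        da1 = dr1 * cache["r1"]
        _, grads["w1"], grads["b1"] = _conv1d_backward(da1, cache["c1"])
        return grads


class _Adam:
    """Adam with decoupled-free (classic L2) weight decay on the gradient."""

    def __init__(self, params, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if self.wd and k.startswith("w"):
                g = g + self.wd * params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def class_weights(labels, label_space: LabelSpace) -> np.ndarray:
    """Inverse-frequency class weights, w_c = n_total / (C * n_c), rescaled to
    average 1 over classes.  Used to counter class imbalance in the loss."""
    y = label_space.encode(labels)
    c = label_space.n_known
    counts = np.bincount(y, minlength=c)
    if (counts == 0).any():
        empty = [label_space.known_classes[i] for i in np.flatnonzero(counts == 0)]
        raise ConfigurationError(f"known classes with no windows: {empty}")
    w = len(y) / (c * counts.astype(float))
    return w / w.mean()


@dataclass
class LogitSet:
    """Per-window raw logit vectors z(x) with argmax predictions and metadata."""

    logits: np.ndarray        # (n, C)
    predicted: np.ndarray     # (n,) class indices
    true_labels: np.ndarray   # (n,) label strings
    subjects: np.ndarray      # (n,) subject ids

    def __len__(self) -> int:
        return self.logits.shape[0]

    @property
    def n_classes(self) -> int:
        return self.logits.shape[1]


@dataclass
class TrainedBackbone:
    """A fitted backbone: weights, label space, and the training history."""

    net: _Net
    label_space: LabelSpace
    config: BackboneConfig
    training_log: list[dict] = field(default_factory=list)
    best_val_macro_f1: float = 0.0

    def predict_logits(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        windows = np.asarray(windows, dtype=np.float64)
        if windows.ndim != 3 or windows.shape[2] != N_CHANNELS:
            raise DataError(
                f"expected (n, T, {N_CHANNELS}) windows, got shape {windows.shape}"
            )
        out = [
            self.net.forward(windows[i:i + batch_size])
            for i in range(0, len(windows), batch_size)
        ]
        return np.concatenate(out, axis=0) if out else np.empty(
            (0, self.label_space.n_known)
        )

    def save(self, path: str | os.PathLike) -> None:
        """Single-file checkpoint: weights plus JSON-encoded metadata."""
        meta = {
            "config": asdict(self.config),
            "known_classes": list(self.label_space.known_classes),
            "unknown_classes": list(self.label_space.unknown_classes),
            "training_log": self.training_log,
            "best_val_macro_f1": self.best_val_macro_f1,
        }
        np.savez_compressed(
            path,
            _meta=np.array(json.dumps(meta)),
            **self.net.params,
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TrainedBackbone":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["_meta"]))
            cfg = BackboneConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in meta["config"].items()
            })
            label_space = LabelSpace(
                tuple(meta["known_classes"]), tuple(meta["unknown_classes"])
            )
            net = _Net(cfg, len(meta["known_classes"]),
                       np.random.default_rng(0))
            for name in _Net.PARAM_NAMES:
                net.params[name] = data[name]
        return cls(net, label_space, cfg, meta["training_log"],
                   float(meta["best_val_macro_f1"]))


def macro_f1(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    """Unweighted mean of per-class F1 over all declared classes."""
    return float(
        f1_score(y_true, y_pred, labels=list(range(n_classes)),
                 average="macro", zero_division=0)
    )


def _weighted_ce_grad(logits, y, weights):
    """Class-weighted cross-entropy loss and its logit gradient.

    Follows the usual convention: loss = sum_i w_{y_i} * nll_i / sum_i w_{y_i}.
    """
    probs = _softmax(logits)
    n = len(y)
    wv = weights[y]
    nll = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None))
    loss = float((wv * nll).sum() / wv.sum())
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (wv / wv.sum())[:, None]
    return loss, dlogits


def train_backbone(train: WindowSet, label_space: LabelSpace,
                   config: BackboneConfig | None = None) -> TrainedBackbone:
    """Fit the CNN on known-class windows only.

    The windows are split 80/20 into train/validation with per-class
    stratification; model selection keeps the epoch with the best validation
    macro-F1, which also drives learning-rate reduction and early stopping.
    All randomness (init, split, shuffling, dropout) derives from config.seed.
    """
    config = config or BackboneConfig()
    c = label_space.n_known
    y = label_space.encode(train.labels)  # raises on unknown-class windows
    counts = np.bincount(y, minlength=c)
    if (counts == 0).any():
        empty = [label_space.known_classes[i] for i in np.flatnonzero(counts == 0)]
        raise ConfigurationError(f"known classes absent from training set: {empty}")
    if (counts < 2).any():
        few = [label_space.known_classes[i] for i in np.flatnonzero(counts < 2)]
        raise ConfigurationError(f"classes with fewer than 2 windows: {few}")

    rng = np.random.default_rng(config.seed)
    split_seed = int(rng.integers(0, 2**31 - 1))
    try:
        idx_tr, idx_val = train_test_split(
            np.arange(len(y)), test_size=config.val_fraction,
            stratify=y, random_state=split_seed,
        )
    except ValueError as exc:
        raise ConfigurationError(
            f"stratified validation split failed ({exc}); lower val_fraction"
        ) from None
    val_counts = np.bincount(y[idx_val], minlength=c)
    if (val_counts == 0).any():
        raise ConfigurationError(
            "validation split left a class empty; lower val_fraction"
        )

    x_tr, y_tr = train.windows[idx_tr], y[idx_tr]
    x_val, y_val = train.windows[idx_val], y[idx_val]
    weights = class_weights(train.labels[idx_tr], label_space)

    net = _Net(config, c, rng)
    opt = _Adam(net.params, config.lr, config.weight_decay)
    dropout_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    shuffle_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))

    best_f1 = -np.inf
    best_params = None
    epochs_since_best = 0
    plateau = 0
    log: list[dict] = []

    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(len(y_tr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            logits = net.forward(x_tr[batch], dropout_rng=dropout_rng)
            loss, dlogits = _weighted_ce_grad(logits, y_tr[batch], weights)
            grads = net.backward(dlogits)
            opt.step(net.params, grads)
            losses.append(loss)

        val_logits = np.concatenate([
            net.forward(x_val[i:i + 256]) for i in range(0, len(x_val), 256)
        ])
        val_pred = val_logits.argmax(axis=1)
        val_f1 = macro_f1(y_val, val_pred, c)
        log.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_macro_f1": val_f1,
            "lr": opt.lr,
        })

        if val_f1 > best_f1 + 1e-6:
            best_f1 = val_f1
            best_params = {k: v.copy() for k, v in net.params.items()}
            epochs_since_best = 0
            plateau = 0
        else:
            epochs_since_best += 1
            plateau += 1
            if plateau > config.scheduler_patience:
                opt.lr *= config.scheduler_factor
                plateau = 0
            if epochs_since_best >= config.early_stop_patience:
                break

    if best_params is not None:
        net.params = best_params
    return TrainedBackbone(
        net=net,
        label_space=label_space,
        config=config,
        training_log=log,
        best_val_macro_f1=float(max(e["val_macro_f1"] for e in log)),
    )


def compute_logits(model: TrainedBackbone, windows: WindowSet) -> LogitSet:
    """Raw pre-softmax logit vectors for every window, with argmax predictions."""
    logits = model.predict_logits(windows.windows)
    return LogitSet(
        logits=logits,
        predicted=logits.argmax(axis=1) if len(logits) else np.empty(0, dtype=int),
        true_labels=np.asarray(windows.labels, dtype=object),
        subjects=np.asarray(windows.subjects, dtype=object),
    )
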