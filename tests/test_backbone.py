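"""Backbone contracts: class weights, training behaviour, logit properties."""

import numpy as np
import pytest

from openset_har import (
    BackboneConfig,
    ConfigurationError,
    DataError,
    LabelSpace,
    TrainedBackbone,
    class_weights,
    compute_logits,
    macro_f1,
    train_backbone,
)

from conftest import tiny_cohort_config
from openset_har import generate_cohort, segment_cohort


# ---------------------------------------------------------------------------
# class weights
# ---------------------------------------------------------------------------

def test_class_weights_balanced_is_unit():
    ls = LabelSpace(("a", "b"))
    w = class_weights(["a"] * 10 + ["b"] * 10, ls)
    np.testing.assert_allclose(w, [1.0, 1.0])


def test_class_weights_formula_and_normalization():
    ls = LabelSpace(("a", "b"))
    labels = ["a"] * 90 + ["b"] * 10
    w = class_weights(labels, ls)
    # before mean-normalization: (100/(2*90), 100/(2*10)) = (0.556, 5.0);
    # the raw weights satisfy sum_c n_c * w_c = n_total
    raw = np.array([100 / 180, 100 / 20])
    assert raw @ np.array([90, 10]) == pytest.approx(100)
    np.testing.assert_allclose(w, raw / raw.mean())
    assert w.mean() == pytest.approx(1.0)


def test_class_weights_empty_class_errors():
    ls = LabelSpace(("a", "b"))
    with pytest.raises(ConfigurationError):
        class_weights(["a"] * 5, ls)


def test_macro_f1_matches_brute_force(rng):
    """Repo metric equals per-class precision/recall F1 from raw counts."""
    for _ in range(20):
        c = int(rng.integers(2, 6))
        y_true = rng.integers(0, c, size=200)
        y_pred = rng.integers(0, c, size=200)
        f1s = []
        for k in range(c):
            tp = np.sum((y_true == k) & (y_pred == k))
            fp = np.sum((y_true != k) & (y_pred == k))
            fn = np.sum((y_true == k) & (y_pred != k))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert macro_f1(y_true, y_pred, c) == pytest.approx(np.mean(f1s))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_separable_classes_reach_high_val_f1(binary_model):
    """Two spectrally disjoint classes (still vs. head-shake) are learned to
    near-perfect validation macro-F1."""
    model, _ = binary_model
    assert model.best_val_macro_f1 >= 0.95


def test_training_is_deterministic(tiny_windows):
    ls = LabelSpace(tuple(tiny_windows.unique_labels()))
    sub = tiny_windows.with_subjects_in(["S01"])
    cfg = BackboneConfig(max_epochs=3, seed=5)
    a = train_backbone(sub, ls, cfg)
    b = train_backbone(sub, ls, cfg)
    assert a.training_log == b.training_log
    for k in a.net.params:
        np.testing.assert_array_equal(a.net.params[k], b.net.params[k])


def test_best_val_f1_is_max_of_series(tiny_model):
    model, _ = tiny_model
    series = [e["val_macro_f1"] for e in model.training_log]
    assert model.best_val_macro_f1 == pytest.approx(max(series))


def test_unknown_class_window_rejected(tiny_windows):
    ls = LabelSpace(("breathing", "shaking"))  # walking not declared known
    with pytest.raises(ConfigurationError):
        train_backbone(tiny_windows, ls, BackboneConfig(max_epochs=1))


def test_missing_known_class_rejected(tiny_windows):
    ls = LabelSpace(tuple(tiny_windows.unique_labels()) + ("cycling",))
    sub = tiny_windows.with_subjects_in(["S01"])
    with pytest.raises(ConfigurationError, match="cycling"):
        train_backbone(sub, ls, BackboneConfig(max_epochs=1))


# ---------------------------------------------------------------------------
# logits
# ---------------------------------------------------------------------------

def test_logit_shapes_and_softmax_simplex(tiny_model):
    model, train = tiny_model
    logits = compute_logits(model, train)
    c = model.label_space.n_known
    assert logits.logits.shape == (len(train), c)
    probs = np.exp(logits.logits - logits.logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(logits.predicted, logits.logits.argmax(axis=1))


def test_argmax_tie_breaks_to_lowest_index():
    z = np.array([[2.0, 2.0, 1.0]])
    assert z.argmax(axis=1)[0] == 0


def test_inference_deterministic_and_dropout_off(tiny_model):
    model, train = tiny_model
    a = model.predict_logits(train.windows[:16])
    b = model.predict_logits(train.windows[:16])
    np.testing.assert_array_equal(a, b)


def test_bias_shift_equivariance(tiny_model):
    """Adding a constant to the output bias shifts all logits by it and
    leaves predictions unchanged."""
    model, train = tiny_model
    x = train.windows[:32]
    base = model.predict_logits(x)
    model.net.params["b4"] = model.net.params["b4"] + 2.5
    try:
        shifted = model.predict_logits(x)
    finally:
        model.net.params["b4"] = model.net.params["b4"] - 2.5
    np.testing.assert_allclose(shifted, base + 2.5, atol=1e-9)
    np.testing.assert_array_equal(shifted.argmax(axis=1), base.argmax(axis=1))


def test_logits_reproduce_validation_f1_bookkeeping(binary_model):
    """Re-scoring the training windows with the returned model must be at
    least as good as the reported best validation macro-F1 (the model is the
    best-epoch snapshot, scored here on data it saw)."""
    model, train = binary_model
    ls = model.label_space
    logits = compute_logits(model, train)
    f1 = macro_f1(ls.encode(train.labels), logits.predicted, ls.n_known)
    assert f1 >= model.best_val_macro_f1 - 0.05


def test_wrong_channel_count_rejected(tiny_model):
    model, _ = tiny_model
    with pytest.raises(DataError):
        model.predict_logits(np.zeros((4, 78, 5)))


def test_checkpoint_round_trip(tiny_model, tmp_path):
    model, train = tiny_model
    path = tmp_path / "model.ckpt.npz"
    model.save(path)
    back = TrainedBackbone.load(path)
    np.testing.assert_array_equal(
        back.predict_logits(train.windows[:8]),
        model.predict_logits(train.windows[:8]),
    )
    assert back.label_space == model.label_space
    assert back.best_val_macro_f1 == model.best_val_macro_f1


def test_backbone_generalizes_across_subjects():
    """Train subject-wise on 6 of 8 subjects of the default cohort and score
    the 2 held-out subjects: macro-F1 stays high despite per-subject
    amplitude/frequency variability."""
    from openset_har import default_cohort_config

    ws = segment_cohort(generate_cohort(default_cohort_config(seed=0)))
    ls = LabelSpace(tuple(ws.unique_labels()))
    train = ws.with_subjects_in([f"S{i:02d}" for i in range(1, 7)])
    test = ws.with_subjects_in(["S07", "S08"])
    model = train_backbone(train, ls, BackboneConfig(seed=0))
    logits = compute_logits(model, test)
    f1 = macro_f1(ls.encode(test.labels), logits.predicted, ls.n_known)
    assert f1 >= 0.85
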