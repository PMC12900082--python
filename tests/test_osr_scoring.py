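"""Open-set scorer correctness: closed forms, brute-force oracles, properties.

The oracles here are written independently of the implementation: explicit
double loops over stored logits (nndr), explicit per-class quadratic forms
(gmm), and explicit kernel sums (kde).
"""

import numpy as np
import pytest

from openset_har import (
    CalibrationError,
    ConfigurationError,
    LogitSet,
    METHODS,
    ScorerModel,
    fit_scorer,
    score_batch,
    score_energy,
    score_gmm,
    score_kde,
    score_mls,
    score_nndr,
    score_openmax,
)
from openset_har.osr_scoring import _openmax_probs, _combined_distance

from conftest import make_logitset


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def nndr_oracle(class_logits, z):
    pred = int(np.argmax(z))
    d_same = min(np.linalg.norm(z - u) for u in class_logits[pred])
    d_diff = min(
        np.linalg.norm(z - u)
        for k, store in class_logits.items() if k != pred
        for u in store
    )
    return d_same / d_diff


def gmm_oracle(means, covs, priors, z):
    total = 0.0
    for mu, cov, pi in zip(means, covs, priors):
        d = len(mu)
        diff = z - mu
        quad = diff @ np.linalg.solve(cov, diff)
        det = np.linalg.det(cov)
        total += pi * np.exp(-0.5 * quad) / np.sqrt((2 * np.pi) ** d * det)
    return -np.log(total)


def kde_oracle(class_logits, bandwidths, priors, z):
    total = 0.0
    for k, store in class_logits.items():
        h, d = bandwidths[k], len(z)
        dens = 0.0
        for u in store:
            dens += np.exp(-0.5 * np.sum((z - u) ** 2) / h**2) / (
                (2 * np.pi) ** (d / 2) * h**d
            )
        total += priors[k] * dens / len(store)
    return -np.log(total)


def _class_indices(ls: LogitSet):
    order = sorted(set(map(str, ls.true_labels)))
    return np.array([order.index(str(t)) for t in ls.true_labels])


# ---------------------------------------------------------------------------
# closed-form spot checks
# ---------------------------------------------------------------------------

def test_mls_examples():
    assert score_mls([0.0, 0.0, 0.0]) == 0.0
    assert score_mls([3.0, 1.0, -2.0]) == -3.0
    z = np.array([1.2, -0.7, 0.4])
    assert score_mls(z + 5.0) == pytest.approx(score_mls(z) - 5.0)


def test_energy_closed_forms():
    assert score_energy([0.0, 0.0], 1.0) == pytest.approx(-np.log(2.0))
    assert score_energy([2.0, 0.0], 1.0) == pytest.approx(
        -np.log(np.exp(2.0) + 1.0)
    )
    with pytest.raises(ConfigurationError):
        score_energy([1.0, 0.0], 0.0)


def test_energy_limits_to_mls(rng):
    for _ in range(50):
        z = rng.normal(0, 3, size=5)
        assert abs(score_energy(z, 1e-4) - score_mls(z)) < 1e-6


def test_gmm_standard_normal_closed_form():
    model = ScorerModel(method="gmm", n_classes=1, state={
        "means": np.array([[0.0]]),
        "covs": np.array([[[1.0]]]),
        "priors": np.array([1.0]),
    })
    assert score_gmm(model, [0.0]) == pytest.approx(0.5 * np.log(2 * np.pi))


def test_gmm_monotone_along_ray():
    model = ScorerModel(method="gmm", n_classes=1, state={
        "means": np.array([[0.0, 0.0]]),
        "covs": np.array([np.eye(2)]),
        "priors": np.array([1.0]),
    })
    scores = [score_gmm(model, [t, t]) for t in np.linspace(0, 5, 20)]
    assert all(b >= a for a, b in zip(scores, scores[1:]))


def test_kde_single_point_closed_form():
    from sklearn.neighbors import KernelDensity

    kde = KernelDensity(kernel="gaussian", bandwidth=1.0).fit([[0.0]])
    model = ScorerModel(method="kde", n_classes=1, state={
        "kdes": {0: kde}, "bandwidths": {0: 1.0}, "priors": np.array([1.0]),
    })
    assert score_kde(model, [0.0]) == pytest.approx(0.5 * np.log(2 * np.pi))


def test_kde_symmetry_two_points():
    from sklearn.neighbors import KernelDensity

    kde = KernelDensity(kernel="gaussian", bandwidth=0.7).fit([[-2.0], [2.0]])
    model = ScorerModel(method="kde", n_classes=1, state={
        "kdes": {0: kde}, "bandwidths": {0: 0.7}, "priors": np.array([1.0]),
    })
    for z in (0.3, 1.1, 2.9):
        assert score_kde(model, [z]) == pytest.approx(score_kde(model, [-z]))


def test_nndr_hand_geometry():
    model = ScorerModel(method="nndr", n_classes=2, state={
        "class_logits": {0: np.array([[2.0, 0.0]]), 1: np.array([[0.0, 2.0]])},
        "cap": 1e6,
    })
    # z = (1, 0): predicted class 0, d_same = 1, d_diff = sqrt(5)
    assert score_nndr(model, [1.0, 0.0]) == pytest.approx(
        1.0 / np.sqrt(5.0), abs=1e-12
    )
    # z equal to a stored logit of its class -> 0
    assert score_nndr(model, [2.0, 0.0]) == 0.0


def test_nndr_zero_distance_policies():
    store = {0: np.array([[1.0, 0.0]]), 1: np.array([[1.0, 0.0], [0.0, 3.0]])}
    model = ScorerModel(method="nndr", n_classes=2, state={
        "class_logits": store, "cap": 1e6,
    })
    # z equals a point stored in BOTH classes: d_same = d_diff = 0 -> 1
    assert score_nndr(model, [1.0, 0.0]) == 1.0
    store2 = {0: np.array([[5.0, 0.0]]), 1: np.array([[1.0, 0.0]])}
    model2 = ScorerModel(method="nndr", n_classes=2, state={
        "class_logits": store2, "cap": 1e6,
    })
    # d_diff = 0 with d_same > 0 -> configured cap
    assert score_nndr(model2, [1.0, 0.0]) == 1e6


# ---------------------------------------------------------------------------
# oracle equivalence on random instances
# ---------------------------------------------------------------------------

def test_nndr_matches_brute_force(rng):
    for trial in range(25):
        ls = make_logitset(rng, n_per_class=15, n_classes=4, spread=2.0)
        model = fit_scorer("nndr", ls, class_indices=_class_indices(ls))
        queries = rng.normal(0, 4, size=(5, 4))
        store = model.state["class_logits"]
        for z in queries:
            assert score_nndr(model, z) == pytest.approx(
                nndr_oracle(store, z), rel=1e-8
            )


def test_gmm_matches_brute_force(rng):
    for trial in range(25):
        ls = make_logitset(rng, n_per_class=30, n_classes=3, spread=1.5)
        model = fit_scorer("gmm", ls, class_indices=_class_indices(ls))
        for z in rng.normal(0, 4, size=(5, 3)):
            assert score_gmm(model, z) == pytest.approx(
                gmm_oracle(model.state["means"], model.state["covs"],
                           model.state["priors"], z),
                rel=1e-8,
            )


def test_kde_matches_brute_force(rng):
    for trial in range(25):
        ls = make_logitset(rng, n_per_class=20, n_classes=3, spread=1.5)
        model = fit_scorer("kde", ls, class_indices=_class_indices(ls))
        store = {k: ls.logits[_class_indices(ls) == k] for k in range(3)}
        for z in rng.normal(0, 3, size=(5, 3)):
            assert score_kde(model, z) == pytest.approx(
                kde_oracle(store, model.state["bandwidths"],
                           model.state["priors"], z),
                rel=1e-8,
            )


# ---------------------------------------------------------------------------
# openmax
# ---------------------------------------------------------------------------

def _openmax_fixture(rng, n_classes=3):
    ls = make_logitset(rng, n_per_class=40, n_classes=n_classes, spread=0.8)
    return fit_scorer("openmax", ls, class_indices=_class_indices(ls))


def test_openmax_simplex(rng):
    model = _openmax_fixture(rng)
    for z in rng.normal(0, 5, size=(200, 3)):
        probs = _openmax_probs(model, z)
        assert probs.shape == (4,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= probs[-1] <= 1.0


def test_openmax_low_at_mav(rng):
    """A logit vector sitting exactly on its class MAV scores lower than
    perturbed copies pushed away from the MAV."""
    model = _openmax_fixture(rng)
    mav = model.state["mavs"][0]
    p_at_mav = score_openmax(model, mav)
    for scale in (2.0, 4.0, 8.0):
        away = mav + scale * (mav / np.linalg.norm(mav))[::-1]
        assert score_openmax(model, away) >= p_at_mav


def test_openmax_monotone_in_weibull_cdf():
    """With fixed positive logits, the unknown probability is non-decreasing
    as the Weibull outlier weights grow (enumerated 3-point scan against the
    direct formula)."""
    z = np.array([3.0, 1.0])
    alpha = 2
    p_prev = -1.0
    for cdf in (0.0, 0.5, 1.0):
        # direct formula evaluation with omega_c = rank_factor * cdf
        z_hat = z.copy()
        unknown = 0.0
        for rank, k in enumerate(np.argsort(-z)[:alpha], start=1):
            omega = (alpha - rank + 1) / alpha * cdf
            z_hat[k] = z[k] * (1 - omega)
            unknown += z[k] * omega
        full = np.append(z_hat, unknown)
        probs = np.exp(full - full.max())
        probs /= probs.sum()
        assert probs[-1] >= p_prev
        p_prev = probs[-1]


def test_openmax_tail_truncation_warns(rng):
    ls = make_logitset(rng, n_per_class=8, n_classes=3, spread=0.5)
    with pytest.warns(UserWarning, match="tail_size"):
        model = fit_scorer("openmax", ls, options={"tail_size": 50},
                           class_indices=_class_indices(ls))
    assert model.state["mavs"].shape == (3, 3)


def test_openmax_requires_correct_samples():
    z = np.array([[1.0, 0.0], [2.0, 0.5]] * 4)
    ls = LogitSet(
        logits=z,
        predicted=z.argmax(axis=1),            # all predicted class 0
        true_labels=np.array(["c0", "c1"] * 4, dtype=object),
        subjects=np.array(["S1"] * 8, dtype=object),
    )
    with pytest.raises(CalibrationError, match="class 1"):
        fit_scorer("openmax", ls, class_indices=np.array([0, 1] * 4))


# ---------------------------------------------------------------------------
# fit + batch behaviour
# ---------------------------------------------------------------------------

def test_fit_gmm_priors_normalized(rng):
    ls = make_logitset(rng, n_per_class=30, n_classes=3)
    model = fit_scorer("gmm", ls, class_indices=_class_indices(ls))
    assert model.state["priors"].sum() == pytest.approx(1.0)
    assert (model.state["priors"] > 0).all()
    assert model.state["means"].shape == (3, 3)


def test_gmm_too_few_samples_rejected(rng):
    ls = make_logitset(rng, n_per_class=3, n_classes=4)
    with pytest.raises(CalibrationError):
        fit_scorer("gmm", ls, class_indices=_class_indices(ls))


def test_unknown_method_and_option_rejected(rng):
    ls = make_logitset(rng)
    with pytest.raises(ConfigurationError):
        fit_scorer("softmax", ls)
    with pytest.raises(ConfigurationError):
        fit_scorer("energy", ls, options={"temp": 2.0})


def test_calibration_is_deterministic(rng):
    ls = make_logitset(rng, n_per_class=25, n_classes=3)
    idx = _class_indices(ls)
    for method in ("nndr", "gmm", "kde", "openmax"):
        a = fit_scorer(method, ls, class_indices=idx)
        b = fit_scorer(method, ls, class_indices=idx)
        za = score_batch(a, ls).scores
        zb = score_batch(b, ls).scores
        np.testing.assert_array_equal(za, zb)


@pytest.mark.parametrize("method", METHODS)
def test_batch_matches_scalar_and_permutes(method, rng):
    ls = make_logitset(rng, n_per_class=25, n_classes=3)
    idx = _class_indices(ls)
    model = fit_scorer(method, ls, class_indices=idx)
    test = make_logitset(rng, n_per_class=10, n_classes=3, spread=3.0)
    scores = score_batch(model, test).scores
    # batch of one equals the scalar path
    single = LogitSet(test.logits[:1], test.predicted[:1],
                      test.true_labels[:1], test.subjects[:1])
    assert score_batch(model, single).scores[0] == pytest.approx(scores[0])
    # permutation of rows permutes scores identically
    perm = rng.permutation(len(test))
    permuted = LogitSet(test.logits[perm], test.predicted[perm],
                        test.true_labels[perm], test.subjects[perm])
    np.testing.assert_allclose(score_batch(model, permuted).scores,
                               scores[perm], rtol=1e-12)


def test_all_methods_finite_on_fuzzed_logits(rng):
    ls = make_logitset(rng, n_per_class=30, n_classes=4)
    idx = _class_indices(ls)
    extreme = rng.normal(0, 50, size=(1000, 4))
    fuzz = LogitSet(extreme, extreme.argmax(axis=1),
                    np.array(["c0"] * 1000, dtype=object),
                    np.array(["S1"] * 1000, dtype=object))
    for method in METHODS:
        model = fit_scorer(method, ls, class_indices=idx)
        scores = score_batch(model, fuzz).scores
        assert np.isfinite(scores).all(), method


def test_scorer_save_load_round_trip(rng, tmp_path):
    from openset_har import load_scorer, save_scorer

    ls = make_logitset(rng, n_per_class=25, n_classes=3)
    idx = _class_indices(ls)
    for method in METHODS:
        model = fit_scorer(method, ls, class_indices=idx)
        path = tmp_path / f"{method}.joblib"
        save_scorer(model, path)
        back = load_scorer(path)
        np.testing.assert_allclose(score_batch(back, ls).scores,
                                   score_batch(model, ls).scores, rtol=1e-12)


def test_batch_width_mismatch_rejected(rng):
    ls = make_logitset(rng, n_classes=3)
    model = fit_scorer("mls", ls)
    wrong = make_logitset(rng, n_classes=4)
    with pytest.raises(ConfigurationError):
        score_batch(model, wrong)
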