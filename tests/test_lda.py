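"""Linear discriminant: closed form, evaluation metrics, serialization."""

import numpy as np
import pandas as pd
import pytest

import circawarn as cw
from circawarn.errors import SchemaError, UnfittableError
from circawarn.lda import (
    ConfusionMatrix,
    LDAModel,
    classify,
    discriminant_score,
    evaluate,
    fit_lda,
    metrics,
    rank_coefficients,
)


def test_one_feature_toy_closed_form():
    """Class 0 at {0, 1}, class 1 at {10, 11}: pooled variance 0.5,
    positive coefficient, midpoint threshold, perfect separation."""
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    y = np.array([False, False, True, True])
    model = fit_lda(X, y, ridge=0.0, standardize=False)
    assert model.coef[0] == pytest.approx(10.0 / 0.5)  # (mu1-mu0)/s2
    assert model.threshold == pytest.approx(model.coef[0] * 5.5)
    assert (classify(model, X) == y).all()
    # a row at the class-means midpoint scores exactly the threshold
    assert discriminant_score(model, np.array([[5.5]]))[0] == pytest.approx(
        model.threshold
    )
    # ... and a threshold tie is classified negative
    assert not classify(model, np.array([[5.5]]))[0]


def test_two_feature_matrix_algebra_oracle():
    """Coefficients match a direct solve of S_pooled^-1 (mu1 - mu0)."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        n0, n1 = rng.integers(8, 30, 2)
        X0 = rng.normal(0, 1, (n0, 2)) @ rng.normal(0, 1, (2, 2))
        X1 = rng.normal(0.5, 1, (n1, 2))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n0, bool), np.ones(n1, bool)]
        model = fit_lda(X, y, ridge=0.0, standardize=False)
        mu0, mu1 = X0.mean(0), X1.mean(0)
        d0, d1 = X0 - mu0, X1 - mu1
        S = (d0.T @ d0 + d1.T @ d1) / (n0 + n1 - 2)
        expected = np.linalg.solve(S, mu1 - mu0)
        np.testing.assert_allclose(model.coef, expected, rtol=1e-9)


def test_regularized_closed_form_with_ridge():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 5))
    y = rng.random(40) < 0.4
    ridge = 0.01
    model = fit_lda(X, y, ridge=ridge, standardize=False)
    mu0, mu1 = X[~y].mean(0), X[y].mean(0)
    d0, d1 = X[~y] - mu0, X[y] - mu1
    S = (d0.T @ d0 + d1.T @ d1) / (len(X) - 2)
    reg = S + ridge * np.mean(np.diag(S)) * np.eye(5)
    np.testing.assert_allclose(
        model.coef, np.linalg.solve(reg, mu1 - mu0), rtol=1e-9
    )


def test_identical_class_means_degenerate():
    X = np.array([[1.0, 2.0], [3.0, 0.0], [1.0, 2.0], [3.0, 0.0]])
    y = np.array([False, False, True, True])
    model = fit_lda(X, y, standardize=False)
    assert model.degenerate
    np.testing.assert_allclose(model.coef, 0.0, atol=1e-9)


def test_single_class_unfittable():
    X = np.zeros((10, 2))
    with pytest.raises(UnfittableError):
        fit_lda(X, np.zeros(10, dtype=bool))


def test_score_linearity_and_vectorized_equivalence():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(50, 4))
    y = rng.random(50) < 0.3
    model = fit_lda(X, y)
    row = X[7].copy()
    s0 = discriminant_score(model, row[None, :])[0]
    c = 2.5
    j = 2
    bumped = row.copy()
    bumped[j] += c * model.scale[j]
    s1 = discriminant_score(model, bumped[None, :])[0]
    assert s1 - s0 == pytest.approx(c * model.coef[j])
    # feature-by-feature sum equals the vectorized score
    manual = sum(
        (row[k] - model.center[k]) / model.scale[k] * model.coef[k]
        for k in range(4)
    )
    assert manual == pytest.approx(s0)


def test_prediction_invariant_under_affine_rescaling():
    """With standardization on, rescaling/shifting raw features leaves
    predictions unchanged."""
    rng = np.random.default_rng(9)
    X = rng.normal(size=(60, 3))
    y = np.r_[np.zeros(40, bool), np.ones(20, bool)]
    X[y] += [1.0, -0.5, 0.3]
    model_a = fit_lda(X, y, standardize=True)
    scale = np.array([3.0, 0.2, 40.0])
    shift = np.array([-5.0, 100.0, 0.01])
    model_b = fit_lda(X * scale + shift, y, standardize=True)
    np.testing.assert_array_equal(
        classify(model_a, X), classify(model_b, X * scale + shift)
    )


def test_agrees_with_reference_lda_on_separable_problems():
    """Cross-check: predictions match scikit-learn's LDA on random
    well-separated problems (reference used as oracle only)."""
    sklearn_lda = pytest.importorskip(
        "sklearn.discriminant_analysis"
    ).LinearDiscriminantAnalysis
    rng = np.random.default_rng(21)
    for _ in range(10):
        n0, n1 = int(rng.integers(20, 60)), int(rng.integers(20, 60))
        shift = rng.normal(0, 3, 4)
        X = np.vstack([rng.normal(0, 1, (n0, 4)), rng.normal(0, 1, (n1, 4)) + shift])
        y = np.r_[np.zeros(n0, bool), np.ones(n1, bool)]
        ours = fit_lda(X, y, standardize=False,
                       priors=(n0 / (n0 + n1), n1 / (n0 + n1)))
        ref = sklearn_lda(solver="lsqr").fit(X, y)
        agreement = (classify(ours, X) == ref.predict(X).astype(bool)).mean()
        assert agreement >= 0.97


def test_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
    y = rng.random(30) < 0.5
    model = fit_lda(X, y, ridge=1e-4, priors=(0.8, 0.2))
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = LDAModel.from_json(path)
    assert loaded.feature_names == model.feature_names
    np.testing.assert_array_equal(loaded.coef, model.coef)
    np.testing.assert_array_equal(loaded.center, model.center)
    np.testing.assert_array_equal(loaded.scale, model.scale)
    assert loaded.threshold == model.threshold
    assert loaded.priors == model.priors


def test_evaluate_examples():
    y = np.array([True, False, True, False, False])
    cm = evaluate(y, y)
    assert (cm.fp, cm.fn) == (0, 0) and cm.tp + cm.tn == 5
    cm = evaluate(~y, y)  # swapped predictions swap tp<->fn, tn<->fp
    assert (cm.tp, cm.tn) == (0, 0) and cm.fn == 2 and cm.fp == 3
    with pytest.raises(SchemaError):
        evaluate([True], [True, False])


def test_metrics_zero_denominators_reported_missing():
    rep = metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
    assert rep.sensitivity is None and rep.ppv is None
    assert rep.specificity == pytest.approx(100.0)
    assert rep.npv == pytest.approx(100.0)


def test_metrics_match_direct_formula_oracle():
    rng = np.random.default_rng(3)
    for _ in range(30):
        tp, fp, fn, tn = (int(v) for v in rng.integers(0, 50, 4))
        if tp + fp + fn + tn == 0:
            continue
        rep = metrics(ConfusionMatrix(tp, fp, fn, tn))
        if tp + fn:
            assert rep.sensitivity == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert rep.specificity == pytest.approx(100 * tn / (tn + fp))
        if tp + fp:
            assert rep.ppv == pytest.approx(100 * tp / (tp + fp))
        if tn + fn:
            assert rep.npv == pytest.approx(100 * tn / (tn + fn))
        assert rep.accuracy == pytest.approx(100 * (tp + tn) / (tp + fp + fn + tn))


def test_rank_coefficients_order_and_ties():
    model = LDAModel(
        feature_names=("a", "b", "c", "d"),
        center=np.zeros(4),
        scale=np.ones(4),
        coef=np.array([0.2, -0.9, 0.5, -0.5]),
        threshold=0.0,
    )
    ranked = rank_coefficients(model)
    assert list(ranked["parameter"]) == ["b", "c", "d", "a"]  # tie c/d by order
    assert ranked["coefficient"].iloc[0] == pytest.approx(-0.9)


def test_run_experiment_modes(bench_cohort):
    _, _, fs = bench_cohort
    whole = cw.run_experiment(fs, mode="whole")
    split = cw.run_experiment(fs, mode="split")
    rows = fs.valid_rows()
    assert whole.confusion.total == len(rows)
    assert split.confusion.total == int((rows["day"] > 30).sum())
    # whole on a training-only span equals in-sample evaluation
    train_only = cw.FeatureSet(fs.matrix[fs.matrix["day"] <= 30].reset_index(drop=True))
    insample = cw.run_experiment(train_only, mode="whole")
    assert insample.confusion.total == int((rows["day"] <= 30).sum())


def test_run_experiment_without_training_positives_raises(tiny_config):
    import dataclasses

    cfg = dataclasses.replace(tiny_config, event_probability_per_course=0.0, seed=3)
    cohort = cw.simulate_cohort(cfg)
    fs = cw.assemble_features(cw.assemble_timeline(cohort), cohort.events)
    with pytest.raises(UnfittableError):
        cw.run_experiment(fs)
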