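import numpy as np
import pandas as pd
import pytest

from gpgraze.discriminant import (
    ConfusionMatrix,
    GenotypeDiscriminant,
    QdaModel,
    backward_stepwise_select,
    boxm_test,
    compute_vif,
    evaluate,
    fit_lda,
    fit_qda,
    lda_classify,
    standardize,
)

CLASSES = ["AB", "AC", "BB", "BC", "CC"]


def make_classes(rng, n_per=30, d=6, shift=2.0, informative=3, classes=CLASSES):
    """Gaussian classes separated on the first ``informative`` variables."""
    frames = []
    for k, c in enumerate(classes):
        mu = np.zeros(d)
        mu[:informative] = shift * np.sin(np.arange(informative) + k)
        X = rng.normal(size=(n_per, d)) + mu
        df = pd.DataFrame(X, columns=[f"v{j}" for j in range(d)])
        df["genotype"] = c
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------ standardization
def test_standardize_centres_and_scales():
    train = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
    test = pd.DataFrame({"v": [2.0]})
    strain, stest, params = standardize(train, test, ["v"])
    assert strain.v.tolist() == pytest.approx([-1.0, 0.0, 1.0])
    assert stest.v.iloc[0] == pytest.approx(0.0)  # equals training mean


def test_standardize_rejects_constant_column():
    train = pd.DataFrame({"v": [1.0, 1.0, 1.0], "w": [1.0, 2.0, 4.0]})
    with pytest.raises(ValueError, match="v"):
        standardize(train, None, ["v", "w"])


# ----------------------------------------------------------------------- LDA
def test_five_classes_give_four_axes():
    rng = np.random.default_rng(0)
    df = make_classes(rng)
    fit = fit_lda(df, df.genotype, [f"v{j}" for j in range(6)])
    assert fit.n_axes == 4
    assert (fit.pooled_scores >= 0).all()
    assert fit.proportion_of_variation.sum() == pytest.approx(1.0)


def test_one_dimensional_two_class_case():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"v": np.r_[rng.normal(0, 1, 500), rng.normal(5, 1, 500)]})
    df["genotype"] = ["a"] * 500 + ["b"] * 500
    fit = fit_lda(df, df.genotype, ["v"])
    assert fit.n_axes == 1
    assert fit.coefficients[0, 0] > 0  # first nonzero coefficient positive


def test_pure_noise_variable_ranks_last():
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        df = make_classes(rng, n_per=40, d=4, shift=3.0, informative=3)
        fit = fit_lda(df, df.genotype, ["v0", "v1", "v2", "v3"])
        scores = fit.pooled_scores
        if scores["v3"] == scores.min():
            wins += 1
    assert wins >= 15  # noise variable at the bottom in a clear majority


# ----------------------------------------------------------------------- VIF
def test_vif_orthogonal_columns_one():
    rng = np.random.default_rng(2)
    X = np.linalg.qr(rng.normal(size=(100, 3)))[0]
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    assert np.allclose(compute_vif(df, ["a", "b", "c"]), 1.0, atol=1e-3)


def test_vif_duplicate_column_infinite():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"a": rng.normal(size=50)})
    df["b"] = df["a"]
    vif = compute_vif(df, ["a", "b"])
    assert np.isinf(vif).all()


def test_vif_matches_regression_oracle():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(200, 2)), columns=["x1", "x2"])
    df["x3"] = df.x1 + df.x2 + 0.5 * rng.normal(size=200)
    vif = compute_vif(df, ["x1", "x2", "x3"])
    # independent least-squares fit of x3 on (x1, x2)
    A = np.column_stack([df.x1, df.x2, np.ones(200)])
    beta, *_ = np.linalg.lstsq(A, df.x3, rcond=None)
    resid = df.x3 - A @ beta
    r2 = 1 - resid.var() / df.x3.var()
    assert vif["x3"] == pytest.approx(1 / (1 - r2), rel=1e-8)


# ------------------------------------------------------------------ stepwise
def test_stepwise_keeps_informative_drops_noise():
    informative = ["v0", "v1", "v2"]
    noise = ["v3", "v4", "v5"]
    kept_informative, dropped_noise = 0, 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        df = make_classes(rng, n_per=40, d=6, shift=3.0, informative=3)
        sdf, _, _ = standardize(df, None, informative + noise)
        trace, final = backward_stepwise_select(sdf, df.genotype, informative + noise)
        if set(informative) <= set(final):
            kept_informative += 1
        if len(set(noise) - set(final)) >= 2:
            dropped_noise += 1
    assert kept_informative >= 15
    assert dropped_noise >= 12  # clear majority of seeds exclude >= 2 noise vars


def test_duplicated_column_removed_by_vif_stage():
    rng = np.random.default_rng(5)
    df = make_classes(rng, n_per=40, d=3, shift=3.0, informative=3)
    df["v0_copy"] = df["v0"] + 1e-9 * rng.normal(size=len(df))
    sdf, _, _ = standardize(df, None, ["v0", "v1", "v2", "v0_copy"])
    _, final = backward_stepwise_select(sdf, df.genotype, ["v0", "v1", "v2", "v0_copy"])
    assert not {"v0", "v0_copy"} <= set(final)


def test_single_variable_returned_unchanged():
    rng = np.random.default_rng(6)
    df = make_classes(rng, n_per=30, d=1, shift=2.0, informative=1, classes=["a", "b"])
    sdf, _, _ = standardize(df, None, ["v0"])
    trace, final = backward_stepwise_select(sdf, df.genotype, ["v0"])
    assert final == ["v0"]
    assert len(trace) == 1


def test_trace_accuracy_monotone_in_score_phase():
    rng = np.random.default_rng(7)
    df = make_classes(rng, n_per=40, d=6, shift=2.0, informative=3)
    sdf, _, _ = standardize(df, None, [f"v{j}" for j in range(6)])
    trace, _ = backward_stepwise_select(sdf, df.genotype, [f"v{j}" for j in range(6)])
    score_phase = trace[trace.action.isin(["start", "drop_score"])]
    assert (np.diff(score_phase.accuracy) >= -1e-12).all()


# -------------------------------------------------------------------- Box M
def test_boxm_zero_for_identical_class_data():
    rng = np.random.default_rng(8)
    block = rng.normal(size=(50, 3))
    df = pd.DataFrame(np.vstack([block, block]), columns=["a", "b", "c"])
    labels = ["g1"] * 50 + ["g2"] * 50
    stat, df_, p = boxm_test(df, labels, ["a", "b", "c"])
    assert stat == pytest.approx(0.0, abs=1e-8)
    assert p == pytest.approx(1.0)


def test_boxm_detects_unequal_covariance():
    rejections = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(100, 3))
        b = 2.0 * rng.normal(size=(100, 3))  # covariance 4x
        df = pd.DataFrame(np.vstack([a, b]), columns=["a", "b", "c"])
        _, _, p = boxm_test(df, ["g1"] * 100 + ["g2"] * 100, ["a", "b", "c"])
        rejections += p < 0.05
    assert rejections > 45


def test_boxm_requires_enough_observations():
    df = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)), columns=list("abc"))
    with pytest.raises(ValueError, match="g1"):
        boxm_test(df, ["g1"] * 3 + ["g2"] * 3, list("abc"))


# ----------------------------------------------------------------------- QDA
def _hand_qda_1d():
    return QdaModel(
        classes=["c1", "c2"],
        variables=["v"],
        means={"c1": np.array([0.0]), "c2": np.array([4.0])},
        covariances={"c1": np.array([[1.0]]), "c2": np.array([[1.0]])},
        priors={"c1": 0.5, "c2": 0.5},
    )


def test_qda_closed_form_boundary():
    model = _hand_qda_1d()
    # x = 2 is equidistant: discriminants tie, lowest label wins
    at_tie = model.predict(pd.DataFrame({"v": [2.0]}))
    assert at_tie[0] == "c1"
    d = model.discriminants(pd.DataFrame({"v": [2.0]}))
    assert d.c1.iloc[0] == pytest.approx(d.c2.iloc[0])
    assert model.predict(pd.DataFrame({"v": [2.1]}))[0] == "c2"


def test_class_mean_classified_to_its_class():
    rng = np.random.default_rng(9)
    df = make_classes(rng, n_per=40, d=4, shift=3.0, informative=4)
    model = fit_qda(df, df.genotype, [f"v{j}" for j in range(4)])
    means = pd.DataFrame([model.means[c] for c in model.classes],
                         columns=model.variables)
    assert list(model.predict(means)) == model.classes


def test_qda_matches_sklearn_reference():
    from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

    rng = np.random.default_rng(10)
    train = make_classes(rng, n_per=60, d=4, shift=1.5, informative=4)
    test = make_classes(rng, n_per=60, d=4, shift=1.5, informative=4)
    vars_ = [f"v{j}" for j in range(4)]
    mine = fit_qda(train, train.genotype, vars_)
    ref = QuadraticDiscriminantAnalysis(priors=np.full(5, 0.2), store_covariance=True)
    ref.fit(train[vars_], train.genotype)
    agree = np.mean(mine.predict(test) == ref.predict(test[vars_]))
    assert agree > 0.99


def test_pooled_qda_reproduces_lda_boundaries():
    rng = np.random.default_rng(11)
    train = make_classes(rng, n_per=50, d=3, shift=2.0, informative=3)
    grid = make_classes(rng, n_per=200, d=3, shift=2.0, informative=3)
    vars_ = ["v0", "v1", "v2"]
    model = fit_qda(train, train.genotype, vars_)
    model.pooled = True
    qda_pred = model.predict(grid)
    lda_pred = lda_classify(train, train.genotype, vars_, newdata=grid)
    assert np.mean(qda_pred == lda_pred) > 0.99


def test_variable_order_permutation_changes_nothing():
    rng = np.random.default_rng(12)
    df = make_classes(rng, n_per=40, d=5, shift=2.0, informative=3)
    vars_a = [f"v{j}" for j in range(5)]
    vars_b = vars_a[::-1]
    fit_a = GenotypeDiscriminant(df, variables=vars_a).fit(select=False)
    fit_b = GenotypeDiscriminant(df, variables=vars_b).fit(select=False)
    assert fit_a.confusion_train.accuracy == pytest.approx(fit_b.confusion_train.accuracy)
    assert sorted(fit_a.lda.pooled_scores.round(10)) == pytest.approx(
        sorted(fit_b.lda.pooled_scores.round(10))
    )


# ---------------------------------------------------------------- evaluation
def test_confusion_matrix_arithmetic():
    table = pd.DataFrame([[9, 1], [2, 8]], index=["a", "b"], columns=["a", "b"])
    cm = ConfusionMatrix(table, "test")
    assert cm.accuracy == pytest.approx(0.85)
    assert cm.per_class_recall.tolist() == pytest.approx([0.9, 0.8])


def test_evaluate_perfect_and_degenerate():
    model = _hand_qda_1d()
    train = pd.DataFrame({"v": [-0.2, 0.1, 3.9, 4.2]})
    labels = ["c1", "c1", "c2", "c2"]
    resub, pred = evaluate(model, train, labels, train, labels)
    assert resub.accuracy == 1.0
    assert np.array_equal(np.diag(resub.table), [2, 2])
    with pytest.raises(ValueError, match="missing"):
        evaluate(model, pd.DataFrame({"w": [1.0]}), ["c1"])


# --------------------------------------------------- Model/Results interface
def test_model_results_roundtrip_and_summary():
    rng = np.random.default_rng(13)
    train = make_classes(rng, n_per=40, d=5, shift=2.5, informative=3)
    test = make_classes(rng, n_per=20, d=5, shift=2.5, informative=3)
    res = GenotypeDiscriminant.from_dataframe(train).fit(select=True)
    assert set(res.selected_variables) <= {f"v{j}" for j in range(5)}
    conf = res.evaluate(test)
    assert conf.accuracy > 0.5
    text = res.summary()
    assert "Box's M" in text and "Training accuracy" in text
    # serialization roundtrip predicts identically
    qda, params = type(res).load_qda(res.to_json())
    assert np.array_equal(
        qda.predict(params.transform(test)), res.predict(test)
    )
    scores = res.class_score_table()
    assert list(scores.columns) == CLASSES
    assert set(scores.index) == set(res.selected_variables)
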