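"""Equal-prior QDA, leave-one-out, and clade-transfer validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from dentopo.classify import (
    ConfusionTable,
    OverlapError,
    SingularClassError,
    cross_clade_validate,
    loo_accuracy,
    predict_table,
    qda_fit,
    qda_predict,
)

FEATS = ("rfi", "ariadne", "lnoa")


def make_table(means, cov, n, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    rows = []
    labels = labels or [f"class{i}" for i in range(len(means))]
    for mu, lab in zip(means, labels):
        X = rng.multivariate_normal(mu, cov, n)
        for x in X:
            rows.append(dict(zip(FEATS, x), diet=lab))
    return pd.DataFrame(rows)


def test_equal_priors_exact():
    df = pd.concat(
        [
            make_table([[0, 0, 0]], np.eye(3), 10, seed=1, labels=["a"]),
            make_table([[5, 5, 5]], np.eye(3), 90, seed=2, labels=["b"]),
        ]
    )
    model = qda_fit(df, FEATS, priors="equal")
    np.testing.assert_array_equal(model.priors, [0.5, 0.5])
    prop = qda_fit(df, FEATS, priors="proportional")
    np.testing.assert_allclose(prop.priors, [0.1, 0.9])


def test_singular_class_errors_loudly():
    df = make_table([[0, 0, 0], [3, 3, 3]], np.eye(3), 3, seed=0)
    with pytest.raises(SingularClassError, match="class0"):
        qda_fit(df, FEATS)


def test_well_separated_resubstitution_perfect():
    df = make_table([[-5, -5, -5], [5, 5, 5]], np.eye(3), 50, seed=4)
    model = qda_fit(df, FEATS)
    preds = predict_table(model, df)
    assert (np.array(preds) == df["diet"].to_numpy()).all()


def test_predict_matches_bruteforce_gaussian_densities():
    """Dual route: the discriminant shortcut must agree with exhaustive
    per-class Gaussian log-density evaluation on every row."""
    df = make_table(
        [[0, 0, 0], [2, 1, -1], [-1, 3, 1]],
        np.diag([1.0, 2.0, 0.5]),
        25,
        seed=11,
    )
    model = qda_fit(df, FEATS)
    X = df[list(FEATS)].to_numpy()
    for x in X:
        dens = [
            multivariate_normal.logpdf(x, model.means[k], model.covariances[k])
            + np.log(model.priors[k])
            for k in range(len(model.classes))
        ]
        oracle = model.classes[int(np.argmax(dens))]
        label, post = qda_predict(model, x)
        assert label == oracle
        assert post.sum() == pytest.approx(1.0, abs=1e-12)


def test_predict_matches_sklearn():
    from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

    df = make_table([[0, 0, 0], [2, 2, 0]], np.eye(3), 40, seed=5)
    X = df[list(FEATS)].to_numpy()
    y = df["diet"].to_numpy()
    model = qda_fit(df, FEATS)
    sk = QuadraticDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
    assert (np.array(predict_table(model, df)) == sk.predict(X)).all()


def test_tie_broken_lexicographically():
    """A point equidistant between two identical-covariance class means goes
    to the lexicographically first label with posterior ~ (0.5, 0.5)."""
    rng = np.random.default_rng(0)
    noise = rng.multivariate_normal([0, 0, 0], np.eye(3), 30)
    df_a = pd.DataFrame(noise + np.array([2, 0, 0]), columns=FEATS)
    df_a["diet"] = "alpha"
    df_b = pd.DataFrame(noise + np.array([-2, 0, 0]), columns=FEATS)
    df_b["diet"] = "beta"
    model = qda_fit(pd.concat([df_a, df_b]), FEATS)
    mid = 0.5 * (model.means[0] + model.means[1])
    label, post = qda_predict(model, mid)
    assert label == "alpha"
    np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-9)


_FIXED_MODEL = qda_fit(
    make_table([[0, 0, 0], [3, 1, -2], [-2, 2, 2]], np.diag([1.0, 0.5, 2.0]),
               20, seed=21),
    FEATS,
)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.lists(st.floats(-10.0, 10.0), min_size=3, max_size=3))
def test_posterior_is_a_probability_vector(x):
    """For any query point, posteriors are non-negative, sum to one, and the
    predicted label carries the largest posterior."""
    label, post = qda_predict(_FIXED_MODEL, np.asarray(x))
    assert post.sum() == pytest.approx(1.0, abs=1e-12)
    assert (post >= 0).all()
    assert label == _FIXED_MODEL.classes[int(np.argmax(post))]


def test_predict_rejects_missing_feature():
    df = make_table([[0, 0, 0], [4, 4, 4]], np.eye(3), 10, seed=0)
    model = qda_fit(df, FEATS)
    with pytest.raises(ValueError):
        qda_predict(model, [0.1, np.nan, 0.2])
    with pytest.raises(ValueError):
        qda_predict(model, [0.1, 0.2])


def test_loo_high_accuracy_when_separated():
    df = make_table(
        [[0, 0, 0], [10, 0, 0], [0, 10, 0]], np.eye(3), 20, seed=8
    )
    acc, conf = loo_accuracy(df, FEATS)
    assert acc >= 0.95
    assert conf.counts.sum() == len(df)
    assert (conf.counts.sum(axis=1) == 20).all()


def test_loo_near_chance_under_null():
    """Four classes drawn from one common distribution: accuracy ~ 25%."""
    accs = []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.standard_normal((100, 3)), columns=FEATS)
        df["diet"] = np.repeat(["a", "b", "c", "d"], 25)
        accs.append(loo_accuracy(df, FEATS)[0])
    assert 0.15 < np.mean(accs) < 0.35


def test_loo_singular_after_holdout():
    df = make_table([[0, 0, 0], [5, 5, 5]], np.eye(3), 4, seed=0)
    with pytest.raises(SingularClassError, match="holding out"):
        loo_accuracy(df, FEATS)


def test_equal_priors_immune_to_imbalance():
    """Tripling one class's rows must not move equal-prior predictions."""
    df = make_table([[0, 0, 0], [3, 3, 3]], np.eye(3), 30, seed=2)
    model_bal = qda_fit(df, FEATS)
    class0 = df[df["diet"] == "class0"]
    df_imb = pd.concat([df, class0, class0], ignore_index=True)
    # refit on resampled-but-identical per-class distributions: exact class
    # stats are unchanged because duplicated rows don't move mean/cov of class0
    model_imb = qda_fit(df_imb, FEATS)
    probe = np.linspace([-2, -2, -2], [5, 5, 5], 40)
    for x in probe:
        assert qda_predict(model_bal, x)[0] == qda_predict(model_imb, x)[0]


def test_cross_clade_shared_accuracy_arithmetic():
    """Per-category results 10/12, 7/14, 6/7 give 23/33 shared accuracy, and
    the scalar always equals the value recomputed from the confusion table."""
    conf = ConfusionTable(
        counts=np.array([[10, 2, 0], [4, 7, 3], [1, 0, 6]]),
        true_classes=("folivore", "frugivore-insectivore", "insectivore"),
        predicted_classes=("folivore", "frugivore-insectivore", "insectivore"),
    )
    shared = ("folivore", "frugivore-insectivore", "insectivore")
    assert conf.shared_accuracy(shared) == pytest.approx(23 / 33)


def test_cross_clade_validate_end_to_end():
    train = make_table([[0, 0, 0], [6, 0, 0]], np.eye(3), 20, seed=1,
                       labels=["folivore", "insectivore"])
    test = make_table([[0.5, 0, 0], [6.5, 0, 0], [20, 20, 20]], np.eye(3), 10,
                      seed=2, labels=["folivore", "insectivore", "omnivore"])
    acc, conf, per_cat = cross_clade_validate(train, test, FEATS)
    # omnivore is not in the training set: excluded from the accuracy but
    # present in the confusion table
    assert set(per_cat) == {"folivore", "insectivore"}
    assert "omnivore" in conf.true_classes
    assert "omnivore" not in conf.predicted_classes
    recomputed = conf.shared_accuracy(tuple(per_cat))
    assert acc == pytest.approx(recomputed)
    assert acc >= 0.9


def test_cross_clade_train_equals_test_is_resubstitution():
    df = make_table([[0, 0, 0], [4, 4, 4]], np.eye(3), 15, seed=3)
    model = qda_fit(df, FEATS)
    resub = np.mean(np.array(predict_table(model, df)) == df["diet"].to_numpy())
    acc, _, _ = cross_clade_validate(df, df, FEATS)
    assert acc == pytest.approx(resub)


def test_disjoint_categories_error():
    a = make_table([[0, 0, 0], [4, 4, 4]], np.eye(3), 10, seed=0,
                   labels=["folivore", "insectivore"])
    b = make_table([[0, 0, 0], [4, 4, 4]], np.eye(3), 10, seed=1,
                   labels=["omnivore", "frugivore"])
    with pytest.raises(OverlapError):
        cross_clade_validate(a, b, FEATS)
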