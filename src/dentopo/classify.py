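"""Equal-prior quadratic discriminant analysis for diet inference.

A QDA models each diet class k as a multivariate Gaussian with its own
mean mu_k and covariance Sigma_k; an observation x is assigned to the
class maximising the discriminant

    delta_k(x) = -1/2 ln|Sigma_k| - 1/2 (x - mu_k)^T Sigma_k^{-1} (x - mu_k)
                 + ln pi_k.

Class-specific covariances matter here because dietary groups differ in
variance (Levene preflight), which rules out LDA.  Priors default to equal
across classes rather than training proportions, so rare diets are not
penalised.  Validation is by leave-one-out, and by the clade-transfer
design: fit on one clade's species means, score the other clade's, and
compute accuracy only over test rows whose true category exists in the
training set ("shared-category accuracy").

Covariances are unbiased (n-1) sample covariances.  Singular classes
(n_k <= p) raise loudly rather than being silently regularised; an
optional ridge term exists for exploratory use but defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FEATURES = ("rfi", "ariadne", "lnoa")


class SingularClassError(ValueError):
    """A class has too few observations for an invertible covariance."""


class OverlapError(ValueError):
    """Train and test share no dietary category."""


@dataclass(frozen=True)
class DietModel:
    """Fitted per-class Gaussian parameters."""

    classes: tuple
    features: tuple
    means: np.ndarray  # (K, p)
    covariances: np.ndarray  # (K, p, p)
    priors: np.ndarray  # (K,)

    def __post_init__(self):
        assert abs(self.priors.sum() - 1.0) < 1e-12


@dataclass(frozen=True)
class ConfusionTable:
    """counts[true][predicted]; row and column category sets may differ."""

    counts: np.ndarray
    true_classes: tuple
    predicted_classes: tuple

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.true_classes),
            columns=list(self.predicted_classes),
        )

    def shared_accuracy(self, shared: tuple) -> float:
        """Accuracy over rows whose true class is in ``shared``."""
        correct = total = 0
        for i, t in enumerate(self.true_classes):
            if t not in shared:
                continue
            row = self.counts[i]
            total += row.sum()
            if t in self.predicted_classes:
                correct += row[self.predicted_classes.index(t)]
        return correct / total if total else float("nan")


def _design(table: pd.DataFrame, features) -> np.ndarray:
    X = table[list(features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = table.index[np.isnan(X).any(axis=1)][0]
        raise ValueError(f"row {bad}: missing feature value")
    return X


def qda_fit(
    table: pd.DataFrame,
    features=DEFAULT_FEATURES,
    priors: str = "equal",
    ridge: float = 0.0,
) -> DietModel:
    """Fit per-class Gaussians on a (species-mean) table with a `diet` column.

    ``priors="equal"`` sets pi_k = 1/K exactly; ``"proportional"`` uses the
    training class frequencies.  A class with n_k <= p observations raises
    :class:`SingularClassError` naming the class (undersampled categories
    should be excluded explicitly upstream, not shrunk silently).
    """
    features = tuple(features)
    p = len(features)
    classes = tuple(sorted(table["diet"].unique()))
    X = _design(table, features)
    y = table["diet"].to_numpy()

    means = np.empty((len(classes), p))
    covs = np.empty((len(classes), p, p))
    counts = np.empty(len(classes))
    for k, cls in enumerate(classes):
        Xk = X[y == cls]
        n_k = len(Xk)
        counts[k] = n_k
        if n_k <= p:
            raise SingularClassError(
                f"class {cls!r} has n={n_k} <= p={p}; covariance is singular "
                "(exclude the category or reduce the feature set)"
            )
        means[k] = Xk.mean(axis=0)
        covs[k] = np.cov(Xk, rowvar=False, ddof=1) + ridge * np.eye(p)
    if priors == "equal":
        pri = np.full(len(classes), 1.0 / len(classes))
    elif priors == "proportional":
        pri = counts / counts.sum()
    else:
        raise ValueError(f"priors must be 'equal' or 'proportional', got {priors!r}")
    return DietModel(classes, features, means, covs, pri)


def _discriminants(model: DietModel, X: np.ndarray) -> np.ndarray:
    """delta_k(x) for each row of X; shape (n, K)."""
    n, K = len(X), len(model.classes)
    out = np.empty((n, K))
    for k in range(K):
        S = model.covariances[k]
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise SingularClassError(
                f"class {model.classes[k]!r} covariance is not positive definite"
            )
        diff = X - model.means[k]
        maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(S), diff)
        out[:, k] = -0.5 * logdet - 0.5 * maha + np.log(model.priors[k])
    return out


def qda_predict(model: DietModel, x) -> tuple:
    """(label, posterior vector) for one feature vector.

    Ties in the discriminant are broken by class-label lexicographic order
    (classes are stored sorted, so the first argmax wins).  Posteriors are
    the softmax of the discriminants and sum to 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(model.features):
        raise ValueError(
            f"expected {len(model.features)} features {model.features}, "
            f"got {x.shape[1]}"
        )
    if np.isnan(x).any():
        raise ValueError("missing feature value")
    d = _discriminants(model, x)[0]
    # lexicographic tie-break with tolerance: classes sorted, first near-max wins
    near = d >= d.max() - 1e-12
    label = model.classes[int(np.argmax(near))]
    shifted = d - d.max()
    post = np.exp(shifted)
    post /= post.sum()
    return label, post


def predict_table(model: DietModel, table: pd.DataFrame) -> list:
    X = _design(table, model.features)
    d = _discriminants(model, X)
    labels = []
    for row in d:
        near = row >= row.max() - 1e-12
        labels.append(model.classes[int(np.argmax(near))])
    return labels


def _confusion(true, pred, true_classes, pred_classes) -> ConfusionTable:
    counts = np.zeros((len(true_classes), len(pred_classes)), dtype=np.int64)
    ti = {c: i for i, c in enumerate(true_classes)}
    pi = {c: i for i, c in enumerate(pred_classes)}
    for t, p in zip(true, pred):
        counts[ti[t], pi[p]] += 1
    return ConfusionTable(counts, tuple(true_classes), tuple(pred_classes))


def loo_accuracy(
    table: pd.DataFrame,
    features=DEFAULT_FEATURES,
    priors: str = "equal",
    ridge: float = 0.0,
) -> tuple[float, ConfusionTable]:
    """Leave-one-out accuracy: each row predicted by a model fitted on the
    others.  Exactly n fits; deterministic given the table."""
    features = tuple(features)
    table = table.reset_index(drop=True)
    preds = []
    for i in range(len(table)):
        train = table.drop(index=i)
        try:
            model = qda_fit(train, features, priors=priors, ridge=ridge)
        except SingularClassError as exc:
            raise SingularClassError(
                f"holding out row {i} ({table.loc[i, 'diet']}): {exc}"
            ) from exc
        label, _ = qda_predict(model, table.loc[i, list(features)].to_numpy(float))
        preds.append(label)
    true = table["diet"].tolist()
    classes = tuple(sorted(set(true) | set(preds)))
    conf = _confusion(true, preds, classes, classes)
    acc = float(np.mean([t == p for t, p in zip(true, preds)]))
    return acc, conf


def cross_clade_validate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    features=DEFAULT_FEATURES,
    priors: str = "equal",
    ridge: float = 0.0,
) -> tuple[float, ConfusionTable, dict]:
    """Clade-transfer validation with shared-category accuracy.

    Fits on ``train``, predicts every ``test`` row, and scores only the
    test rows whose TRUE category also occurs in the training set.  The
    returned confusion table includes all true categories (shared or not)
    for inspection; ``per_category`` maps each shared category to
    (n_correct, n_total).
    """
    features = tuple(features)
    model = qda_fit(train, features, priors=priors, ridge=ridge)
    preds = predict_table(model, test)
    true = test["diet"].tolist()
    shared = tuple(c for c in sorted(set(true)) if c in model.classes)
    if not shared:
        raise OverlapError(
            f"no dietary category shared between train {model.classes} "
            f"and test {tuple(sorted(set(true)))}"
        )
    conf = _confusion(true, preds, tuple(sorted(set(true))), model.classes)
    per_category = {}
    for c in shared:
        idx = [i for i, t in enumerate(true) if t == c]
        n_correct = sum(preds[i] == c for i in idx)
        per_category[c] = (n_correct, len(idx))
    correct = sum(v[0] for v in per_category.values())
    total = sum(v[1] for v in per_category.values())
    return correct / total, conf, per_category
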