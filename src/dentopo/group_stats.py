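"""Normality-gated univariate comparisons and unit-variance PCA.

The comparison procedures follow a fixed decision rule rather than leaving
the test choice to the analyst:

* paired two-sample: Shapiro-Wilk on each group; both normal -> paired
  t-test, else Wilcoxon signed-rank;
* unpaired two-sample: same gate -> Welch t-test vs Wilcoxon rank-sum;
* multi-group: Shapiro-Wilk on the ANOVA residuals -> one-way ANOVA with
  Tukey HSD post-hoc, else Kruskal-Wallis with Dunn post-hoc (emitted both
  unadjusted and Bonferroni-adjusted).

Every result records which branch fired, so downstream reports are
auditable.  Levene's test (mean-centred) is the documented preflight for
homogeneity of variance that motivates QDA over LDA.  The PCA standardises
columns to unit variance (correlation-matrix PCA), matching the usual
scaled-PCA convention for mixed-unit morphometric variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    normality_p: tuple = ()
    posthoc: tuple = ()  # rows: (pair, p_unadjusted, p_adjusted, method)
    notes: tuple = ()

    def __post_init__(self):
        assert 0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)


def _shapiro_p(x: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def paired_compare(x, y, alpha_normality: float = 0.05) -> ComparisonResult:
    """Paired t-test or Wilcoxon signed-rank, gated on per-group normality."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired samples must have equal length >= 3")
    px, py = _shapiro_p(x), _shapiro_p(y)
    diffs = x - y
    if np.allclose(diffs, 0.0):
        return ComparisonResult(
            "paired-t", 0.0, 1.0, (px, py), notes=("all differences zero",)
        )
    if px >= alpha_normality and py >= alpha_normality:
        res = stats.ttest_rel(x, y)
        return ComparisonResult("paired-t", float(res.statistic), float(res.pvalue),
                                (px, py))
    method = "exact" if len(x) <= 25 else "approx"
    res = stats.wilcoxon(x, y, correction=(method == "approx"), method=method)
    return ComparisonResult("wilcoxon-signed-rank", float(res.statistic),
                            float(res.pvalue), (px, py))


def two_group_compare(x, y, alpha_normality: float = 0.05) -> ComparisonResult:
    """Welch t-test or Wilcoxon rank-sum, gated on per-group normality."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("both groups need n >= 3")
    px, py = _shapiro_p(x), _shapiro_p(y)
    if px >= alpha_normality and py >= alpha_normality:
        res = stats.ttest_ind(x, y, equal_var=False)
        return ComparisonResult("welch-t", float(res.statistic), float(res.pvalue),
                                (px, py))
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if len(x) + len(y) <= 25 else "asymptotic")
    return ComparisonResult("wilcoxon-rank-sum", float(res.statistic),
                            float(res.pvalue), (px, py))


def _dunn_posthoc(groups: dict) -> list:
    """Dunn's rank-based pairwise z tests with tie correction.

    Returns rows (pair, p_unadjusted, p_bonferroni, "dunn").
    """
    labels = sorted(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks = {}
    i = 0
    for g in labels:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[i : i + n_g].mean()
        i += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum() / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a_i in range(len(labels)):
        for b_i in range(a_i + 1, len(labels)):
            a, b = labels[a_i], labels[b_i]
            se = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append(((a, b), float(p), float(min(1.0, p * m)), "dunn"))
    return rows


def multi_group_compare(
    values, groups, alpha_normality: float = 0.05, alpha_omnibus: float = 0.05
) -> ComparisonResult:
    """ANOVA + Tukey HSD or Kruskal-Wallis + Dunn, gated on residual normality.

    Groups of n = 1 are excluded with a warning (their single observation
    cannot support a within-group variance).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    by = {}
    notes = []
    for g in np.unique(groups):
        sample = values[groups == g]
        if len(sample) < 2:
            notes.append(f"group {str(g)!r} excluded (n={len(sample)})")
            warnings.warn(notes[-1])
            continue
        by[g] = sample
    if len(by) < 2:
        raise ValueError("need >= 2 groups with n >= 2")
    labels = sorted(by)
    residuals = np.concatenate([by[g] - by[g].mean() for g in labels])
    p_resid = _shapiro_p(residuals)
    if p_resid >= alpha_normality:
        res = stats.f_oneway(*[by[g] for g in labels])
        posthoc = []
        if res.pvalue < alpha_omnibus:
            tk = stats.tukey_hsd(*[by[g] for g in labels])
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    p = float(tk.pvalue[i, j])
                    posthoc.append(((labels[i], labels[j]), p, p, "tukey"))
        return ComparisonResult("anova", float(res.statistic), float(res.pvalue),
                                (p_resid,), tuple(posthoc), tuple(notes))
    res = stats.kruskal(*[by[g] for g in labels])
    posthoc = tuple(_dunn_posthoc(by)) if res.pvalue < alpha_omnibus else ()
    return ComparisonResult("kruskal-wallis", float(res.statistic),
                            float(res.pvalue), (p_resid,), posthoc, tuple(notes))


def variance_homogeneity(values, groups) -> float:
    """Levene's test (mean-centred) p-value across groups."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    return float(stats.levene(*samples, center="mean").pvalue)


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray  # columns = components
    variance_explained: np.ndarray  # eigenvalues; sums to n_features
    proportions: np.ndarray = field(default=None)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.proportions)


def pca_scores(table, features) -> PcaResult:
    """Unit-variance (correlation-matrix) PCA of the selected feature columns.

    Columns are standardised to zero mean and unit variance (ddof=1);
    ``variance_explained`` are the correlation-matrix eigenvalues, which sum
    to the number of features, and ``proportions`` sum to 1.  A constant
    column cannot be standardised and raises naming the column.
    """
    features = list(features)
    if len(features) < 2:
        raise ValueError("need >= 2 features")
    X = np.asarray(table[features], dtype=float) if hasattr(table, "__getitem__") \
        else np.asarray(table, float)
    if len(X) < 3:
        raise ValueError("need >= 3 rows")
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"constant column {features[j]!r} cannot be standardised")
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = S**2 / (len(X) - 1)
    scores = U * S
    props = eigvals / eigvals.sum()
    return PcaResult(scores=scores, loadings=Vt.T, variance_explained=eigvals,
                     proportions=props)
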