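"""Ensemble validation, univariate logistic baselines, and group statistics.

Covers the tooling around the classifier: bootstrap-aggregation ensembles
(bagging) of the Gaussian Bayes model, univariate logistic regressions as a
per-feature baseline, the Hosmer-Lemeshow calibration test, routed
two-group comparisons (t / Mann-Whitney / chi-square with KS normality
routing), Pearson correlation, and the feature-selection frequency tally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes
from .registry import LABEL_FALL_RISK

__all__ = [
    "BootstrapEnsemble",
    "TestReport",
    "LogisticFit",
    "bag_ensemble",
    "ensemble_score",
    "evaluate_ensemble",
    "univariate_logistic",
    "hosmer_lemeshow",
    "group_compare",
    "correlate",
    "feature_frequency",
]


@dataclass
class TestReport:
    """One statistical test: statistic, p-value and group summaries."""

    test_name: str
    statistic: float
    p_value: float
    summaries: dict = field(default_factory=dict)


# --- bootstrap aggregation --------------------------------------------------

@dataclass
class BootstrapEnsemble:
    """B Gaussian Bayes members trained on with-replacement resamples."""

    models: list
    features: list[str]
    indices: list[np.ndarray]
    seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.models)


def bag_ensemble(table: pd.DataFrame, train_idx, features, B: int = 150,
                 seed: int | None = None,
                 resample_indices=None) -> BootstrapEnsemble:
    """Fit a bagged ensemble on the training rows.

    Each member is fitted on a with-replacement resample of the training
    rows of the same size; resamples without any at-risk row are redrawn
    (logged). ``resample_indices`` overrides the resampling entirely (used
    for degenerate-bagging checks).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    features = list(features)
    rng = np.random.default_rng(seed)
    train_idx = np.asarray(train_idx)
    labels = table.loc[train_idx, "label"].to_numpy()
    models, used = [], []
    for b in range(B):
        if resample_indices is not None:
            take = np.asarray(resample_indices[b])
        else:
            take = rng.integers(len(train_idx), size=len(train_idx))
            redraws = 0
            while not (labels[take] == LABEL_FALL_RISK).any():
                take = rng.integers(len(train_idx), size=len(train_idx))
                redraws += 1
            if redraws:
                warnings.warn(f"member {b}: redrew {redraws} resamples with "
                              "no at-risk rows", stacklevel=2)
        rows = table.loc[train_idx[take]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models.append(bayes.fit(rows, features))
        used.append(take)
    return BootstrapEnsemble(models=models, features=features,
                             indices=used, seed=seed)


def ensemble_score(ensemble: BootstrapEnsemble, X,
                   aggregate: str = "mean") -> np.ndarray:
    """Aggregate member scores.

    ``"mean"`` (default) is soft voting: the mean member PFR, which keeps
    the AUC well defined. ``"vote"`` returns the fraction of members
    predicting at-risk (PFR > 0.5), for majority-vote comparisons.
    """
    X = np.asarray(X, dtype=float)
    member = np.array([np.atleast_1d(bayes.score(m, X))
                       for m in ensemble.models])
    if aggregate == "mean":
        return member.mean(axis=0)
    if aggregate == "vote":
        return (member > 0.5).mean(axis=0)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def evaluate_ensemble(ensemble: BootstrapEnsemble, table: pd.DataFrame,
                      split, aggregate: str = "mean"
                      ) -> dict[str, dict[str, float]]:
    """Ensemble sensitivity/specificity/AUC on each hold-out set."""
    out = {}
    for name, idx in split.sets().items():
        rows = table.loc[idx]
        s = ensemble_score(ensemble, rows[ensemble.features].to_numpy(),
                           aggregate=aggregate)
        y = rows["label"].to_numpy()
        pred = np.where(s > 0.5, LABEL_FALL_RISK, "other")
        se, sp = bayes.sens_spec(pred, y)
        out[name] = {"sensitivity": se, "specificity": sp,
                     "auc": bayes.roc_auc(s, y)}
    return out


# --- univariate logistic baseline -------------------------------------------

@dataclass
class LogisticFit:
    intercept: float
    slope: float
    auc: float
    separated: bool
    probabilities: np.ndarray = field(repr=False, default=None)


_COEF_CAP = 25.0


def univariate_logistic(x, y, tol: float = 1e-8,
                        max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood univariate logistic regression by IRLS.

    ``y`` may be 0/1 or class labels (at-risk = 1). Perfect separation is
    flagged and the coefficients capped (the likelihood has no finite
    maximizer there); the AUC of the fitted probabilities is reported
    either way.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        y = (y == LABEL_FALL_RISK).astype(float)
    y = y.astype(float)
    if x.std() == 0:
        raise ValueError("feature is constant")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    separated = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_COEF_CAP * 2, _COEF_CAP * 2)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-10)
        z = eta + (y - p) / w
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            separated = True
            break
        step = np.abs(beta_new - beta).max()
        beta = beta_new
        if step < tol:
            break
        if np.abs(beta).max() > _COEF_CAP:
            separated = True
            break
    if separated:
        beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
    eta = np.clip(X @ beta, -500, 500)
    p = 1.0 / (1.0 + np.exp(-eta))
    auc = bayes.roc_auc(p, np.where(y == 1, LABEL_FALL_RISK, "other"))
    return LogisticFit(intercept=float(beta[0]), slope=float(beta[1]),
                       auc=auc, separated=separated, probabilities=p)


# --- Hosmer-Lemeshow --------------------------------------------------------

def hosmer_lemeshow(probabilities, y, g: int = 10) -> TestReport:
    """Hosmer-Lemeshow goodness-of-fit over g risk groups.

    Rows are grouped into g near-equal groups by fitted probability (tied
    probabilities share the lower group); groups whose expected event or
    non-event count is zero are merged with their neighbour. The statistic
    is chi-square with g_effective - 2 degrees of freedom.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(p)
    if n < 2 * g:
        raise ValueError(f"need at least {2 * g} rows for g={g}")
    ranks = stats.rankdata(p, method="min")
    groups = np.minimum(((ranks - 1) * g) // n, g - 1).astype(int)

    rows = []
    for gi in np.unique(groups):
        m = groups == gi
        rows.append([y[m].sum(), (1 - y[m]).sum(), p[m].sum(),
                     (1 - p[m]).sum()])
    # merge groups with a zero expected count into the previous group
    merged = [rows[0]]
    for r in rows[1:]:
        if r[2] <= 0 or r[3] <= 0 or merged[-1][2] <= 0 or merged[-1][3] <= 0:
            merged[-1] = [a + b for a, b in zip(merged[-1], r)]
        else:
            merged.append(r)
    g_eff = len(merged)
    chi2 = 0.0
    for o1, o0, e1, e0 in merged:
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = max(g_eff - 2, 1)
    p_value = float(stats.chi2.sf(chi2, df))
    return TestReport(test_name="hosmer-lemeshow", statistic=float(chi2),
                      p_value=p_value,
                      summaries={"groups": g_eff, "df": df})


# --- routed group comparisons -----------------------------------------------

def group_compare(values, groups, kind: str = "continuous",
                  normality_alpha: float = 0.05,
                  yates: bool = False) -> TestReport:
    """Two-group comparison with test routing.

    Continuous/discrete variables: a Kolmogorov-Smirnov normality check on
    the z-scored pooled values routes to a two-sample t-test (normal) or a
    Mann-Whitney U test (non-normal). Categorical variables: chi-square on
    the contingency table (no continuity correction by default). Summaries
    report mean +/- SD per group, or n (%) for categorical.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    names = np.unique(groups)
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    a = values[groups == names[0]]
    b = values[groups == names[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")

    if kind == "categorical":
        table = pd.crosstab(groups, values).to_numpy()
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        summaries = {
            str(g): {str(v): int(((groups == g) & (values == v)).sum())
                     for v in np.unique(values)}
            for g in names}
        return TestReport(test_name="chi-square", statistic=float(chi2),
                          p_value=float(p), summaries=summaries)

    vals = values.astype(float)
    z = (vals - vals.mean()) / vals.std(ddof=1)
    ks_p = stats.kstest(z, "norm").pvalue
    summaries = {str(g): {"mean": float(values[groups == g].mean()),
                          "sd": float(values[groups == g].std(ddof=1)),
                          "n": int((groups == g).sum())}
                 for g in names}
    summaries["ks_normality_p"] = float(ks_p)
    a = a.astype(float)
    b = b.astype(float)
    if ks_p < normality_alpha:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney"
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(a, b)
            if np.isnan(p):
                stat, p = 0.0, 1.0
        name = "t-test"
    return TestReport(test_name=name, statistic=float(stat),
                      p_value=float(p), summaries=summaries)


def correlate(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series of at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(stats.pearsonr(x, y).statistic)


def feature_frequency(sweep) -> pd.DataFrame:
    """Absolute selection count per feature across a dimension sweep."""
    tally = sweep.feature_frequency
    df = pd.DataFrame(sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])),
                      columns=["feature", "count"])
    return df
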