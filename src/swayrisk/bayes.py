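"""Gaussian Bayes fall-risk classifier and its evaluation metrics.

The classifier parameterizes only the at-risk class: from the standardized
training rows of that class it estimates the mean vector mu and sample
covariance S over the k selected features, and scores a feature vector x as

    PFR = P * (2*pi)^(-k/2) * |S|^(-1/2) * exp(-1/2 (x-mu)' S^-1 (x-mu)),

with prior P = 0.5 (equiprobable classes). PFR is a prior-weighted density,
not a normalized posterior — it can exceed 1 — but the decision rule
"at risk iff PFR > 1 - PFR" reduces to thresholding PFR at 0.5, and ROC
analysis uses PFR as a continuous score, so the unnormalized form is used
as the default (a normalized two-Gaussian posterior mode is available via
``fit(..., normalized=True)``). Evaluation is by sensitivity, specificity
and AUC; the AUC uses the rank (Mann-Whitney) formulation with ties
counting one half, which equals trapezoidal integration of the empirical
ROC curve.

All density evaluation is done in the log domain through a Cholesky
factorization of S (ridge-regularized when near-singular), so it is stable
up to the full 47-feature space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import rankdata

from .registry import LABEL_FALL_RISK, LABEL_NON_FALL_RISK

__all__ = [
    "GaussianClassModel",
    "fit",
    "score",
    "predict",
    "roc_auc",
    "sens_spec",
    "evaluate",
]

_RIDGE = 1e-6
_EIG_TOL = 1e-8
_EXP_CAP = 700.0  # exp() overflow guard; reached only for pathological |S|


@dataclass
class GaussianClassModel:
    """Single-class Gaussian density model over k selected features."""

    features: list[str]
    mu: np.ndarray
    cov: np.ndarray
    prior: float = 0.5
    ridge: float = 0.0
    normalized: bool = False
    #: Non-risk class parameters, only set in normalized mode.
    mu0: np.ndarray | None = None
    cov0: np.ndarray | None = None
    _chol: tuple = field(default=None, repr=False, compare=False)

    @property
    def k(self) -> int:
        return len(self.features)

    def to_json(self) -> str:
        return json.dumps({
            "features": list(self.features),
            "mu": self.mu.tolist(),
            "cov": self.cov.tolist(),
            "prior": self.prior,
            "ridge": self.ridge,
            "normalized": self.normalized,
        })

    @classmethod
    def from_json(cls, text: str) -> "GaussianClassModel":
        d = json.loads(text)
        return cls(features=d["features"], mu=np.array(d["mu"]),
                   cov=np.array(d["cov"]), prior=d["prior"],
                   ridge=d["ridge"], normalized=d.get("normalized", False))


def _fit_gaussian(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    if X.shape[0] > 1:
        S = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    else:
        S = np.eye(X.shape[1])
    return mu, S


def _regularize(S: np.ndarray, force: bool) -> tuple[np.ndarray, float]:
    S = 0.5 * (S + S.T)
    eps = 0.0
    if force or np.linalg.eigvalsh(S).min() < _EIG_TOL:
        eps = _RIDGE
        while np.linalg.eigvalsh(S + eps * np.eye(len(S))).min() < _EIG_TOL:
            eps *= 10.0
        warnings.warn(f"near-singular covariance: ridge {eps:g} applied",
                      stacklevel=3)
        S = S + eps * np.eye(len(S))
    return S, eps


def fit(table: pd.DataFrame, features, prior: float = 0.5,
        normalized: bool = False) -> GaussianClassModel:
    """Estimate the at-risk class Gaussian from standardized training rows.

    ``table`` must hold the (already standardized) training rows with a
    ``label`` column. A ridge is added to the covariance diagonal when its
    smallest eigenvalue falls below 1e-8, or whenever there are fewer than
    k + 2 at-risk rows.
    """
    features = list(features)
    risk = table[table["label"] == LABEL_FALL_RISK]
    if len(risk) == 0:
        raise ValueError("no at-risk rows to fit on")
    X = risk[features].to_numpy(dtype=float)
    if len(X) < len(features) + 2:
        warnings.warn(f"only {len(X)} at-risk rows for k={len(features)} "
                      "features; covariance will be ridge-regularized",
                      stacklevel=2)
        force = True
    else:
        force = False
    mu, S = _fit_gaussian(X)
    S, eps = _regularize(S, force)
    model = GaussianClassModel(features=features, mu=mu, cov=S, prior=prior,
                               ridge=eps, normalized=normalized)
    if normalized:
        other = table[table["label"] == LABEL_NON_FALL_RISK]
        if len(other) == 0:
            raise ValueError("normalized mode needs non-risk rows")
        mu0, S0 = _fit_gaussian(other[features].to_numpy(dtype=float))
        S0, _ = _regularize(S0, len(other) < len(features) + 2)
        model.mu0, model.cov0 = mu0, S0
    return model


def _log_density(x: np.ndarray, mu: np.ndarray, S: np.ndarray) -> np.ndarray:
    c, low = cho_factor(S, lower=True)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    diff = np.atleast_2d(x) - mu
    sol = cho_solve((c, low), diff.T)
    maha = np.einsum("ij,ji->i", diff, sol)
    k = len(mu)
    return -0.5 * (k * np.log(2.0 * np.pi) + logdet + maha)


def score(model: GaussianClassModel, x) -> np.ndarray | float:
    """PFR for one feature vector or a 2-D batch (rows = observations)."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("feature vector contains non-finite values")
    single = x.ndim == 1
    logp = _log_density(x, model.mu, model.cov)
    if model.normalized:
        logp0 = _log_density(x, model.mu0, model.cov0)
        m = np.maximum(logp, logp0)
        p1 = model.prior * np.exp(logp - m)
        p0 = (1.0 - model.prior) * np.exp(logp0 - m)
        pfr = p1 / (p1 + p0)
    else:
        pfr = model.prior * np.exp(np.minimum(logp, _EXP_CAP))
    return float(pfr[0]) if single else pfr


def predict(model: GaussianClassModel, x) -> np.ndarray | str:
    """Class label(s): at risk iff PFR > PNFR = 1 - PFR, i.e. PFR > 0.5.

    An exact tie (PFR = 0.5) goes to the non-risk class per the rule's
    else branch.
    """
    pfr = np.atleast_1d(score(model, x))
    labels = np.where(pfr > 0.5, LABEL_FALL_RISK, LABEL_NON_FALL_RISK)
    return labels[0] if np.asarray(x).ndim == 1 else labels


def roc_auc(scores, labels) -> float:
    """AUC via the rank (Mann-Whitney) formulation, ties counting 1/2.

    Equals the probability that a random at-risk score exceeds a random
    non-risk score, and the trapezoidal area under the empirical ROC.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == LABEL_FALL_RISK
    n_pos = int(pos.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def sens_spec(predictions, labels) -> tuple[float, float]:
    """Sensitivity and specificity with the at-risk class as positive."""
    pred_pos = np.asarray(predictions) == LABEL_FALL_RISK
    actual_pos = np.asarray(labels) == LABEL_FALL_RISK
    n_pos = int(actual_pos.sum())
    n_neg = int((~actual_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("sensitivity/specificity need both classes present")
    tp = int((pred_pos & actual_pos).sum())
    tn = int((~pred_pos & ~actual_pos).sum())
    return tp / n_pos, tn / n_neg


def evaluate(model: GaussianClassModel, table: pd.DataFrame,
             split) -> dict[str, dict[str, float]]:
    """Sensitivity, specificity and AUC on each set of a hold-out split."""
    out = {}
    for name, idx in split.sets().items():
        rows = table.loc[idx]
        X = rows[model.features].to_numpy(dtype=float)
        y = rows["label"].to_numpy()
        pfr = score(model, X)
        se, sp = sens_spec(
            np.where(np.atleast_1d(pfr) > 0.5, LABEL_FALL_RISK,
                     LABEL_NON_FALL_RISK), y)
        out[name] = {"sensitivity": se, "specificity": sp,
                     "auc": roc_auc(pfr, y)}
    return out
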