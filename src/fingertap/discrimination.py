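"""Composite impairment score: age-adjusted stepwise logistic regression,
ROC analysis with DeLong confidence intervals, and leave-one-out
cross-validation.

The fitted score is the linear predictor over the *selected motor features*
(intercept included, forced covariates such as age excluded), so a higher
score means a more patient-like, i.e. more impaired, performance. ROC
evaluation uses the full model's predicted probabilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ScoreModel",
    "ROCResult",
    "stepwise_logistic",
    "fmi_score",
    "roc_auc",
    "loo_cv_auc",
    "CANDIDATE_FEATURES",
]

#: candidate motor features for the selection step (log-scale IHI)
CANDIDATE_FEATURES = ["rate_sv", "rate_mv", "td_2hz", "iti_2hz", "log_ihi"]

Z_95 = 1.959963984540054


class ModelFitError(RuntimeError):
    """Raised when a logistic fit fails to converge."""


@dataclass
class ScoreModel:
    """Fitted logistic model over selected motor features plus forced
    covariates."""

    features: list[str]                 # selected motor features
    forced: list[str]                   # always-in adjustment covariates
    coef: dict[str, float]              # includes "const"
    se: dict[str, float]
    odds_ratios: dict[str, float]
    or_ci: dict[str, tuple[float, float]]
    transforms: dict[str, str] = field(default_factory=dict)
    entry_pvalues: dict[str, float] = field(default_factory=dict)
    separation: bool = False

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "forced": self.forced,
            "coefficients": self.coef,
            "standard_errors": self.se,
            "odds_ratios": self.odds_ratios,
            "odds_ratio_ci95": {k: list(v) for k, v in self.or_ci.items()},
            "transforms": self.transforms,
            "entry_pvalues": self.entry_pvalues,
            "separation": self.separation,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            features=d["features"],
            forced=d["forced"],
            coef=d["coefficients"],
            se=d["standard_errors"],
            odds_ratios=d["odds_ratios"],
            or_ci={k: tuple(v) for k, v in d["odds_ratio_ci95"].items()},
            transforms=d.get("transforms", {}),
            entry_pvalues=d.get("entry_pvalues", {}),
            separation=d.get("separation", False),
        )


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float          # vs AUC = 0.5, DeLong variance
    fpr: np.ndarray
    tpr: np.ndarray
    n_positive: int
    n_negative: int
    failed_folds: int = 0


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """Fit a logistic regression, falling back to a ridge-penalized fit
    under (quasi-)separation. Returns (result, separation_flag)."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            separated = not res.mle_retvals.get("converged", False) or np.any(
                np.abs(res.params) > 50
            )
        except Exception:
            res, separated = None, True
    if separated:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_regularized(
                alpha=1.0, L1_wt=0.0, disp=0, maxiter=500
            )
        return res, True
    return res, False


def stepwise_logistic(
    features: pd.DataFrame,
    labels,
    candidates: Sequence[str] | None = None,
    forced: Sequence[str] = ("age",),
    alpha_enter: float = 0.05,
) -> ScoreModel:
    """Forward stepwise logistic regression with likelihood-ratio entry.

    ``labels`` codes patients as 1 and controls as 0. Covariates in
    ``forced`` (age by default) stay in the model throughout and are never
    tested. Candidates enter one at a time while the best likelihood-ratio
    entry p value is below ``alpha_enter``.
    """
    candidates = list(candidates if candidates is not None else CANDIDATE_FEATURES)
    forced = list(forced)
    y = np.asarray(labels, dtype=float)
    cols = forced + candidates
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    if features[cols].isna().any().any():
        raise ValueError("candidate/forced features must have no missing values")

    selected: list[str] = []
    entry_p: dict[str, float] = {}
    separation = False

    def _design(names: list[str]) -> pd.DataFrame:
        X = features[names].astype(float).copy()
        X.insert(0, "const", 1.0)
        return X

    current, sep0 = _fit_logit(_design(forced), y)
    separation |= sep0
    remaining = list(candidates)
    while remaining:
        best_name, best_p, best_fit = None, np.inf, None
        for name in remaining:
            fit, sep = _fit_logit(_design(forced + selected + [name]), y)
            if sep:
                # LR test unreliable under separation; use a large LLR proxy
                p = 0.0 if not separation else np.nan
                separation = True
            else:
                lr = 2.0 * (fit.llf - current.llf)
                p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if p < best_p:
                best_name, best_p, best_fit = name, p, fit
        if best_name is None or not (best_p < alpha_enter):
            break
        selected.append(best_name)
        entry_p[best_name] = best_p
        remaining.remove(best_name)
        current = best_fit

    final_fit, sep_final = _fit_logit(_design(forced + selected), y)
    separation |= sep_final
    names = ["const"] + forced + selected
    params = np.asarray(final_fit.params, dtype=float)
    try:
        bse = np.asarray(final_fit.bse, dtype=float)
    except Exception:
        bse = np.full_like(params, np.nan)
    coef = dict(zip(names, params))
    se = dict(zip(names, bse))
    ors = {n: float(np.exp(coef[n])) for n in forced + selected}
    or_ci = {
        n: (
            float(np.exp(coef[n] - Z_95 * se[n])),
            float(np.exp(coef[n] + Z_95 * se[n])),
        )
        for n in forced + selected
    }
    transforms = {"log_ihi": "ln(ihi)"} if "log_ihi" in selected else {}
    if separation:
        warnings.warn(
            "separation detected; coefficients from ridge-penalized fallback",
            stacklevel=2,
        )
    return ScoreModel(
        features=selected,
        forced=forced,
        coef={k: float(v) for k, v in coef.items()},
        se={k: float(v) for k, v in se.items()},
        odds_ratios=ors,
        or_ci=or_ci,
        transforms=transforms,
        entry_pvalues=entry_p,
        separation=separation,
    )


def fmi_score(model: ScoreModel, features: pd.DataFrame) -> pd.Series:
    """Impairment score: linear predictor over the selected motor features
    (forced covariates excluded). Higher = more impaired."""
    for name in model.features:
        if name not in features.columns:
            raise KeyError(f"missing feature: {name}")
        if features[name].isna().any():
            raise ValueError(f"feature {name} has missing values")
    score = pd.Series(model.coef.get("const", 0.0), index=features.index, dtype=float)
    for name in model.features:
        score = score + model.coef[name] * features[name].astype(float)
    return score


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance from placement values."""
    m, n = pos.size, neg.size
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y]
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float)
    cmp_mat += 0.5 * (pos[:, None] == neg[None, :])
    auc = cmp_mat.mean()
    v10 = cmp_mat.mean(axis=1)  # per-positive placements
    v01 = cmp_mat.mean(axis=0)  # per-negative placements
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC with midpoint tie handling; AUC via the rank identity;
    DeLong 95% CI and p value against 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    # AUC via the rank (Mann-Whitney) identity with midranks
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2.0) / (
        pos.size * neg.size
    )

    auc_d, var = _delong_variance(pos, neg)
    assert abs(auc_d - auc) < 1e-10
    se = np.sqrt(var)
    if se > 0:
        ci = (max(0.0, auc - Z_95 * se), min(1.0, auc + Z_95 * se))
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        ci = (auc, auc)
        p = 0.0 if auc != 0.5 else 1.0

    # empirical curve over descending thresholds (trapezoidal / midrank ties)
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], sorted_labels.size - 1]
    tp = np.cumsum(sorted_labels)[distinct]
    fp = np.cumsum(1 - sorted_labels)[distinct]
    tpr = np.r_[0.0, tp / pos.size]
    fpr = np.r_[0.0, fp / neg.size]

    return ROCResult(
        auc=float(auc),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=p,
        fpr=fpr,
        tpr=tpr,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )


def loo_cv_auc(
    features: pd.DataFrame,
    labels,
    feature_names: Sequence[str],
    forced: Sequence[str] = ("age",),
    reselect: bool = False,
    candidates: Sequence[str] | None = None,
    alpha_enter: float = 0.05,
) -> ROCResult:
    """Leave-one-out cross-validated ROC.

    By default the *final* feature set is held fixed and only the
    coefficients are refitted per fold; ``reselect=True`` reruns the full
    stepwise selection inside every fold instead.
    """
    y = np.asarray(labels, dtype=float)
    n = len(features)
    if n < 10:
        raise ValueError("need n >= 10 for leave-one-out evaluation")
    cols = list(forced) + list(feature_names)
    oof = np.full(n, np.nan)
    failed = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = features.iloc[mask]
        try:
            if reselect:
                model = stepwise_logistic(
                    train, y[mask],
                    candidates=candidates, forced=forced,
                    alpha_enter=alpha_enter,
                )
                use = list(forced) + model.features
            else:
                use = cols
            X = train[use].astype(float).copy()
            X.insert(0, "const", 1.0)
            fit, _ = _fit_logit(X, y[mask])
            x_i = features.iloc[[i]][use].astype(float).copy()
            x_i.insert(0, "const", 1.0)
            oof[i] = float((x_i.to_numpy() @ np.asarray(fit.params))[0])
        except Exception:
            failed += 1
    ok = ~np.isnan(oof)
    if failed:
        warnings.warn(f"{failed} leave-one-out fold(s) failed", stacklevel=2)
    result = roc_auc(oof[ok], y[ok].astype(int))
    result.failed_folds = failed
    return result
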