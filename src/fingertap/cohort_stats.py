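"""Group comparisons, covariate-adjusted rank correlations and ordered
strata trend tests for the extracted motor parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "PartialCorrelation",
    "StrataTrend",
    "mann_whitney",
    "partial_spearman",
    "compare_groups",
    "correlation_table",
    "edss_strata_trend",
    "assign_edss_stratum",
    "CLINICAL_SCORES",
    "EDSS_STRATA",
]

#: clinical score columns correlated against the motor parameters
CLINICAL_SCORES = [
    "edss", "msfc", "nhpt_s", "t25w_s", "pasat",
    "mfis_total", "mfis_physical", "mfis_cognitive", "mfis_psychosocial",
]

#: ordered disability strata: controls, then patients binned on EDSS
EDSS_STRATA = ["HC", "EDSS 0", "EDSS 1-2", "EDSS 2.5-4", "EDSS >4"]

#: motor parameters entering the group comparison / correlation grids
COMPARISON_PARAMETERS = ["rate_sv", "rate_mv", "td_2hz", "iti_2hz", "ihi"]


@dataclass
class GroupComparison:
    parameter: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    u_statistic: float
    p_value: float
    direction: str  # "a>b", "a<b" or "a=b" on the means
    degenerate: bool = False


@dataclass
class PartialCorrelation:
    parameter: str
    clinical: str
    r: float
    p_value: float
    n: int


@dataclass
class StrataTrend:
    strata: list[str]
    n: list[int]
    means: list[float]
    sems: list[float]
    trend_t: float
    trend_p: float
    pairwise_vs_first: dict[str, float] = field(default_factory=dict)


def mann_whitney(a, b, parameter: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two samples.

    Uses exact enumeration for small tie-free samples (n1 + n2 <= 12),
    otherwise the tie-corrected normal approximation. The reported U is the
    statistic for sample ``a`` (number of (a, b) pairs with a > b, ties
    counted half), so U / (n1 * n2) equals the ROC AUC of ``a`` against
    ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    degenerate = np.unique(pooled).size == 1
    if degenerate:
        u1 = a.size * b.size / 2.0
        p = 1.0
    else:
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u1, p = float(res.statistic), float(res.pvalue)
    diff = a.mean() - b.mean()
    direction = "a>b" if diff > 0 else ("a<b" if diff < 0 else "a=b")
    return GroupComparison(
        parameter=parameter,
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else np.nan,
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else np.nan,
        n_b=int(b.size),
        u_statistic=u1,
        p_value=min(p, 1.0),
        direction=direction,
        degenerate=degenerate,
    )


def partial_spearman(x, y, covariate, parameter: str = "", clinical: str = "") -> PartialCorrelation:
    """Rank (Spearman) correlation of x and y partialling out a covariate.

    All three variables are rank-transformed; the partial Pearson
    correlation of the ranks is returned with a t-based p value on n - 3
    degrees of freedom. A constant covariate reduces to the plain Spearman
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y and covariate must have equal length")
    n = x.size
    if n < 5:
        raise ValueError("need n >= 5")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant variable: correlation undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = stats.rankdata(z)

    def _corr(u, v):
        return float(np.corrcoef(u, v)[0, 1])

    r_xy = _corr(rx, ry)
    if np.unique(z).size == 1:
        r = r_xy
    else:
        r_xz = _corr(rx, rz)
        r_yz = _corr(ry, rz)
        denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        if denom == 0:
            raise ValueError("covariate explains x or y exactly")
        r = (r_xy - r_xz * r_yz) / denom

    df = n - 3
    r_clip = np.clip(r, -1.0, 1.0)
    if abs(r_clip) == 1.0:
        p = 0.0
    else:
        t = r_clip * np.sqrt(df / (1 - r_clip**2))
        p = 2 * stats.t.sf(abs(t), df)
    return PartialCorrelation(parameter, clinical, float(r_clip), float(p), n)


def compare_groups(
    params: pd.DataFrame,
    groups: pd.Series,
    parameters: list[str] | None = None,
    group_a: str = "MS",
    group_b: str = "HC",
) -> list[GroupComparison]:
    """Mann-Whitney comparison of every motor parameter between two groups.

    ``params`` is the wide per-subject parameter table (one session);
    ``groups`` maps subject_id -> group label.
    """
    parameters = parameters or COMPARISON_PARAMETERS
    merged = params.set_index("subject_id").join(groups.rename("group"))
    out = []
    for name in parameters:
        sub = merged[[name, "group"]].dropna()
        a = sub.loc[sub["group"] == group_a, name].to_numpy()
        b = sub.loc[sub["group"] == group_b, name].to_numpy()
        out.append(mann_whitney(a, b, parameter=name))
    return out


def correlation_table(
    params: pd.DataFrame,
    cohort: pd.DataFrame,
    parameters: list[str] | None = None,
    clinical_scores: list[str] | None = None,
    covariate: str = "age",
    min_n: int = 5,
) -> list[PartialCorrelation]:
    """Age-adjusted rank correlations between motor parameters and clinical
    scores (patients only), pairwise-complete per cell.

    ``params``: wide per-subject parameter table; ``cohort``: frame indexed
    by subject_id with the clinical columns and the covariate. Cells with
    fewer than ``min_n`` complete pairs are returned with NaN.
    """
    parameters = parameters or COMPARISON_PARAMETERS
    clinical_scores = clinical_scores or CLINICAL_SCORES
    merged = params.set_index("subject_id").join(cohort, how="inner")
    out = []
    for p_name in parameters:
        for c_name in clinical_scores:
            sub = merged[[p_name, c_name, covariate]].dropna()
            if len(sub) < min_n:
                warnings.warn(
                    f"{p_name} x {c_name}: only {len(sub)} complete pairs; "
                    "cell unavailable",
                    stacklevel=2,
                )
                out.append(
                    PartialCorrelation(p_name, c_name, np.nan, np.nan, len(sub))
                )
                continue
            out.append(
                partial_spearman(
                    sub[p_name], sub[c_name], sub[covariate],
                    parameter=p_name, clinical=c_name,
                )
            )
    return out


def correlation_frame(cells: list[PartialCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": c.parameter,
                "clinical": c.clinical,
                "r": c.r,
                "p": c.p_value,
                "n": c.n,
                "significant": bool(c.p_value < 0.05) if np.isfinite(c.p_value) else False,
            }
            for c in cells
        ]
    )


def assign_edss_stratum(group: str, edss: float | None) -> str:
    """Map a subject to an ordered disability stratum."""
    if group == "HC":
        return "HC"
    if edss is None or (isinstance(edss, float) and np.isnan(edss)):
        raise ValueError("patient without EDSS cannot be stratified")
    if edss == 0:
        return "EDSS 0"
    if edss <= 2:
        return "EDSS 1-2"
    if edss <= 4:
        return "EDSS 2.5-4"
    return "EDSS >4"


def edss_strata_trend(scores, strata, order: list[str] | None = None) -> StrataTrend:
    """Linear-trend ANOVA contrast across ordered strata plus pairwise
    comparisons of each stratum against the first (reference) stratum.

    The trend contrast uses equally spaced stratum scores; pairwise tests
    are two-sample t tests sharing the pooled within-stratum variance.
    Empty strata are dropped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    strata = np.asarray(strata, dtype=object)
    order = order or EDSS_STRATA
    present = [s for s in order if (strata == s).sum() > 0]
    dropped = [s for s in order if s not in present]
    if dropped:
        warnings.warn(f"dropping empty strata: {dropped}", stacklevel=2)
    if len(present) < 2:
        raise ValueError("need at least two non-empty strata")

    groups = [scores[strata == s] for s in present]
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_err = int(ns.sum() - len(groups))
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = sse / df_err

    w = np.arange(len(present), dtype=float)
    w -= w.mean()
    contrast = float(np.dot(w, means))
    se = np.sqrt(mse * np.sum(w**2 / ns))
    t_stat = contrast / se if se > 0 else np.inf
    trend_p = float(2 * stats.t.sf(abs(t_stat), df_err))

    pairwise = {}
    for i in range(1, len(present)):
        diff = means[i] - means[0]
        se_pair = np.sqrt(mse * (1 / ns[i] + 1 / ns[0]))
        t_pair = diff / se_pair if se_pair > 0 else np.inf
        pairwise[present[i]] = float(2 * stats.t.sf(abs(t_pair), df_err))

    return StrataTrend(
        strata=present,
        n=[int(n) for n in ns],
        means=[float(m) for m in means],
        sems=[
            float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else np.nan
            for g in groups
        ],
        trend_t=float(t_stat),
        trend_p=trend_p,
        pairwise_vs_first=pairwise,
    )
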