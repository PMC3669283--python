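"""Test-retest agreement statistics: ICC, SEM, SRD.

The intraclass correlation is the two-way random-effects, absolute-agreement
form for a single measurement, ICC(A,1), and for the average of k
measurements, ICC(A,k), computed from the ANOVA mean squares of the
subjects x sessions matrix. Negative estimates are reported as computed.

The smallest real difference is SRD = 1.96 * sqrt(2) * SEM with
SEM = pooled_SD * sqrt(1 - ICC(A,1)); the pooled SD is the root-mean-square
of the per-session SDs. The inter-hand interval enters this analysis on the
natural-log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityResult",
    "icc_agreement",
    "spearman_brown",
    "sem_srd",
    "srd_percent",
    "reliability_report",
    "REPORT_PARAMETERS",
]

#: parameters reported by :func:`reliability_report`, in order; the IHI is
#: log-transformed before analysis
REPORT_PARAMETERS = ["rate_sv", "rate_mv", "td_2hz", "iti_2hz", "log_ihi"]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedICCError(ValueError):
    """Raised when the data matrix carries no variance at all."""


@dataclass
class ReliabilityResult:
    parameter: str
    session_means: tuple[float, ...]
    session_sds: tuple[float, ...]
    icc_single: float
    icc_average: float
    sem: float
    srd: float
    srd_percent: float
    n_subjects: int


def icc_agreement(data: np.ndarray) -> tuple[float, float]:
    """Absolute-agreement intraclass correlations ICC(A,1) and ICC(A,k).

    ``data`` is an (n subjects) x (k sessions) matrix with no missing cells.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D subjects x sessions matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 sessions, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0:
        raise UndefinedICCError("constant matrix: ICC undefined")

    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    denom_average = msr + (msc - mse) / n
    icc_single = (msr - mse) / denom_single
    icc_average = (msr - mse) / denom_average
    return float(icc_single), float(icc_average)


def spearman_brown(icc_single: float, k: int = 2) -> float:
    """Step up a single-measurement reliability to the average of k."""
    if not (-1.0 < icc_single <= 1.0):
        raise ValueError(f"icc_single must be in (-1, 1], got {icc_single}")
    if k < 1:
        raise ValueError("k must be >= 1")
    return k * icc_single / (1.0 + (k - 1) * icc_single)


def sem_srd(pooled_sd: float, icc_single: float) -> tuple[float, float]:
    """Standard error of measurement and smallest real difference.

    SEM = pooled_sd * sqrt(1 - icc); SRD = 1.96 * sqrt(2) * SEM.
    """
    if pooled_sd < 0:
        raise ValueError("pooled_sd must be non-negative")
    if icc_single > 1:
        raise ValueError("icc_single cannot exceed 1")
    sem = pooled_sd * np.sqrt(1.0 - icc_single)
    srd = Z_95 * np.sqrt(2.0) * sem
    return float(sem), float(srd)


def srd_percent(srd: float, grand_mean: float) -> float:
    """SRD as a percentage of the grand mean (report rounds to integer)."""
    if grand_mean <= 0:
        raise ValueError("grand mean must be positive")
    return 100.0 * srd / grand_mean


def reliability_report(
    params: pd.DataFrame,
    parameters: list[str] | None = None,
) -> list[ReliabilityResult]:
    """Per-parameter test-retest report from a long parameter table.

    ``params`` is the wide per-(subject, session) table produced by
    :func:`fingertap.kinematics.parameter_table`. Subjects missing any
    session are dropped with a warning.
    """
    parameters = parameters or REPORT_PARAMETERS
    results = []
    for name in parameters:
        wide = params.pivot_table(
            index="subject_id", columns="session", values=name, aggfunc="mean"
        )
        complete = wide.dropna()
        dropped = len(wide) - len(complete)
        if dropped:
            warnings.warn(
                f"{name}: dropped {dropped} subject(s) with a missing session",
                stacklevel=2,
            )
        x = complete.to_numpy(dtype=float)
        n, k = x.shape
        icc_s, icc_a = icc_agreement(x)
        session_means = tuple(float(m) for m in x.mean(axis=0))
        session_sds = tuple(float(s) for s in x.std(axis=0, ddof=1))
        pooled_sd = float(np.sqrt(np.mean(np.square(session_sds))))
        sem, srd = sem_srd(pooled_sd, icc_s)
        grand = float(np.mean(session_means))
        results.append(
            ReliabilityResult(
                parameter=name,
                session_means=session_means,
                session_sds=session_sds,
                icc_single=icc_s,
                icc_average=icc_a,
                sem=sem,
                srd=srd,
                srd_percent=srd_percent(srd, grand),
                n_subjects=n,
            )
        )
    return results


def report_frame(results: list[ReliabilityResult]) -> pd.DataFrame:
    """Reliability results as a table with one row per parameter."""
    rows = []
    for r in results:
        row: dict[str, object] = {"parameter": r.parameter, "n": r.n_subjects}
        for i, (m, s) in enumerate(zip(r.session_means, r.session_sds), start=1):
            row[f"mean_s{i}"] = m
            row[f"sd_s{i}"] = s
        row.update(
            sem=r.sem,
            srd=r.srd,
            srd_pct=r.srd_percent,
            srd_pct_rounded=int(round(r.srd_percent)),
            icc_single=r.icc_single,
            icc_average=r.icc_average,
        )
        rows.append(row)
    return pd.DataFrame(rows)
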