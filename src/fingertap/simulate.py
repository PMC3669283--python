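"""Synthetic cohort and glove-trial simulator.

Generates subjects (two groups: healthy controls and patients) with latent
motor traits and clinical covariates linked through a Gaussian copula, then
renders each subject's per-condition 60-s trials as validated touch-event
streams.

Generative model
----------------
* Self-paced conditions: a latent subject rate (Hz) splits a cycle into a
  touch duration and a gap; cycle elements get multiplicative lognormal
  jitter (unit mean).
* Paced conditions: metronome tones every 500 ms; right-hand touch onsets
  follow the subject's own paced period with Gaussian tone-locking error.
* Bimanual condition: left-hand onsets differ from the right-hand onsets by
  a signed zero-mean Gaussian with subject-specific scale sigma, so the
  mean absolute asynchrony per trial is sigma * sqrt(2/pi) (half-normal).
* Test-retest structure: each configured total SD is split into between-
  and within-subject parts via a per-parameter reliability target
  (between = total * sqrt(icc), within = total * sqrt(1 - icc)); the
  within part is redrawn per trial, acting as the between-session random
  effect.
* Copula targets for motor-trait x clinical-score cells are *observed-scale*
  rank correlations; they are converted to Gaussian-scale correlations
  (2 sin(pi r / 6)) and inflated by 1 / sqrt(icc) to undo measurement
  attenuation, so correlations measured on extracted single-trial
  parameters land on target.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .glove_io import (
    Condition,
    Group,
    Hand,
    SubjectRecord,
    Trial,
    TouchEvent,
    write_cohort,
    write_trials,
)

__all__ = [
    "SimulationConfig",
    "GroupSpec",
    "SelfPacedSpec",
    "PacedSpec",
    "AsynchronySpec",
    "ClinicalMarginal",
    "ClinicalSpec",
    "LatentSubject",
    "ConfigurationError",
    "copula_matrix",
    "nearest_correlation",
    "reference_config",
    "simulate_subjects",
    "simulate_trial",
    "simulate_dataset",
    "simulate_cohort",
    "load_config",
    "save_config",
]

HALF_NORMAL_MEAN = np.sqrt(2.0 / np.pi)  # E|N(0, 1)|

#: copula variable order: latent motor traits then clinical covariates
MOTOR_TRAITS = ["rate_sv", "rate_mv", "td_2hz", "iti_2hz", "asynchrony"]
CLINICAL_VARS = [
    "age", "edss", "msfc", "nhpt_s", "t25w_s", "pasat",
    "mfis_total", "mfis_physical", "mfis_cognitive", "mfis_psychosocial",
]
COPULA_VARS = MOTOR_TRAITS + CLINICAL_VARS

FINGER_CYCLE = (2, 3, 4, 5)


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SelfPacedSpec:
    """Self-paced condition: latent movement rate in Hz."""

    rate_mean: float
    rate_sd: float
    td_fraction: float = 0.45
    retest_icc: float = 0.6
    cycle_jitter_cv: float = 0.08

    def validate(self, name: str) -> None:
        if self.rate_mean <= 0 or self.rate_sd < 0:
            raise ConfigurationError(f"{name}: invalid rate moments")
        if not 0 < self.td_fraction < 1:
            raise ConfigurationError(f"{name}: td_fraction must be in (0, 1)")
        if not 0 <= self.retest_icc <= 1:
            raise ConfigurationError(f"{name}: retest_icc must be in [0, 1]")
        if self.cycle_jitter_cv < 0:
            raise ConfigurationError(f"{name}: jitter must be >= 0")


@dataclass
class PacedSpec:
    """Metronome-paced condition: latent touch duration and gap in ms."""

    td_mean: float
    td_sd: float
    gap_mean: float
    gap_sd: float
    retest_icc_td: float = 0.53
    retest_icc_gap: float = 0.39
    cycle_jitter_cv: float = 0.08
    tone_jitter_sd: float = 20.0

    def validate(self, name: str) -> None:
        if self.td_mean <= 0 or self.gap_mean <= 0:
            raise ConfigurationError(f"{name}: latent means must be positive")
        if min(self.td_sd, self.gap_sd, self.cycle_jitter_cv,
               self.tone_jitter_sd) < 0:
            raise ConfigurationError(f"{name}: sigmas must be >= 0")
        for icc in (self.retest_icc_td, self.retest_icc_gap):
            if not 0 <= icc <= 1:
                raise ConfigurationError(f"{name}: retest_icc must be in [0, 1]")


@dataclass
class AsynchronySpec:
    """Bimanual asynchrony: moments of the mean |left-right| onset
    difference (ms); lognormal across subjects."""

    ihi_mean: float
    ihi_sd: float
    retest_icc: float = 0.75

    def validate(self, name: str) -> None:
        if self.ihi_mean < 0 or self.ihi_sd < 0:
            raise ConfigurationError(f"{name}: invalid asynchrony moments")
        if self.ihi_mean == 0 and self.ihi_sd > 0:
            raise ConfigurationError(f"{name}: zero mean requires zero sd")
        if not 0 <= self.retest_icc <= 1:
            raise ConfigurationError(f"{name}: retest_icc must be in [0, 1]")

    @property
    def log_sigma(self) -> float:
        if self.ihi_mean == 0:
            return 0.0
        return float(np.sqrt(np.log1p((self.ihi_sd / self.ihi_mean) ** 2)))

    @property
    def log_mu(self) -> float:
        if self.ihi_mean == 0:
            return float(-np.inf)  # exp -> exactly zero asynchrony
        return float(np.log(self.ihi_mean) - 0.5 * self.log_sigma**2)


@dataclass
class ClinicalMarginal:
    mean: float
    sd: float
    lo: float | None = None
    hi: float | None = None


@dataclass
class GroupSpec:
    age_mean: float
    age_sd: float
    p_female: float
    sv: SelfPacedSpec
    mv: SelfPacedSpec
    paced: PacedSpec
    asynchrony: AsynchronySpec

    def validate(self, name: str) -> None:
        if self.age_sd < 0 or not 0 <= self.p_female <= 1:
            raise ConfigurationError(f"{name}: bad demographics")
        self.sv.validate(f"{name}.sv")
        self.mv.validate(f"{name}.mv")
        self.paced.validate(f"{name}.paced")
        self.asynchrony.validate(f"{name}.asynchrony")


@dataclass
class ClinicalSpec:
    """Patient-group clinical covariate marginals."""

    edss_probs: dict[float, float]
    marginals: dict[str, ClinicalMarginal]
    disease_duration: ClinicalMarginal

    def validate(self) -> None:
        total = sum(self.edss_probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"EDSS probabilities sum to {total}, not 1")
        for level, p in self.edss_probs.items():
            if p < 0 or not 0 <= level <= 7 or (2 * level) != int(2 * level):
                raise ConfigurationError(f"bad EDSS table entry {level}: {p}")


@dataclass
class SimulationConfig:
    n_hc: int
    n_ms: int
    hc: GroupSpec
    ms: GroupSpec
    clinical: ClinicalSpec
    #: observed-scale rank-correlation targets, keys "trait:clinical"
    rank_targets: dict[str, float] = field(default_factory=dict)
    #: latent Gaussian correlations between motor traits, keys "trait:trait"
    trait_corr: dict[str, float] = field(default_factory=dict)
    sessions: int = 1
    duration_ms: int = 60000
    attenuation_correction: bool = True

    def validate(self) -> None:
        if self.n_hc < 0 or self.n_ms < 0 or self.n_hc + self.n_ms == 0:
            raise ConfigurationError("need at least one subject")
        if self.sessions < 1 or self.duration_ms <= 0:
            raise ConfigurationError("bad sessions/duration")
        self.hc.validate("hc")
        self.ms.validate("ms")
        self.clinical.validate()
        for key, r in {**self.rank_targets, **self.trait_corr}.items():
            a, _, b = key.partition(":")
            if a not in COPULA_VARS or b not in COPULA_VARS:
                raise ConfigurationError(f"unknown copula variable in {key!r}")
            if not -1 < r < 1:
                raise ConfigurationError(f"correlation target {key}={r} out of range")
        # the target matrix must be realizable as a correlation matrix: the
        # nearest-correlation projection may not displace any cell too far
        raw = _target_matrix(self, inflate=False)
        projected = nearest_correlation(raw)
        shift = np.abs(projected - raw).max()
        if shift > MAX_PROJECTION_SHIFT:
            raise ConfigurationError(
                "correlation targets are jointly infeasible: nearest valid "
                f"correlation matrix moves a cell by {shift:.3f} "
                f"(> {MAX_PROJECTION_SHIFT})"
            )


def reference_config(
    n_hc: int = 80, n_ms: int = 40, sessions: int = 1, duration_ms: int = 60000
) -> SimulationConfig:
    """Default profile calibrated to the published group statistics.

    Group means are the printed per-group means; SDs are SEM * sqrt(n) with
    the published group sizes (80 controls, 40 patients); reliability splits
    use the published single-measure ICCs; copula targets reproduce the
    significant clinical correlation cells.
    """
    hc = GroupSpec(
        age_mean=41.0, age_sd=10.0, p_female=0.61,
        sv=SelfPacedSpec(rate_mean=2.40, rate_sd=0.05 * np.sqrt(80), retest_icc=0.46),
        mv=SelfPacedSpec(rate_mean=3.25, rate_sd=0.06 * np.sqrt(80), retest_icc=0.71),
        paced=PacedSpec(
            td_mean=213.82, td_sd=4.68 * np.sqrt(80),
            gap_mean=279.63, gap_sd=5.10 * np.sqrt(80),
        ),
        asynchrony=AsynchronySpec(ihi_mean=18.87, ihi_sd=0.87 * np.sqrt(80)),
    )
    ms = GroupSpec(
        age_mean=42.0, age_sd=9.0, p_female=0.67,
        sv=SelfPacedSpec(rate_mean=1.93, rate_sd=0.09 * np.sqrt(40), retest_icc=0.46),
        mv=SelfPacedSpec(rate_mean=2.67, rate_sd=0.10 * np.sqrt(40), retest_icc=0.71),
        paced=PacedSpec(
            td_mean=246.67, td_sd=10.30 * np.sqrt(40),
            gap_mean=269.24, gap_sd=10.92 * np.sqrt(40),
        ),
        asynchrony=AsynchronySpec(ihi_mean=41.92, ihi_sd=4.48 * np.sqrt(40)),
    )
    clinical = ClinicalSpec(
        edss_probs={
            0.0: 0.10, 0.5: 0.05, 1.0: 0.10, 1.5: 0.10, 2.0: 0.17,
            2.5: 0.10, 3.0: 0.09, 3.5: 0.07, 4.0: 0.06, 4.5: 0.04,
            5.0: 0.04, 5.5: 0.02, 6.0: 0.03, 6.5: 0.02, 7.0: 0.01,
        },
        marginals={
            "msfc": ClinicalMarginal(-0.71, 1.4),
            "nhpt_s": ClinicalMarginal(25.0, 8.0, lo=10.0),
            "t25w_s": ClinicalMarginal(6.0, 2.5, lo=3.0),
            "pasat": ClinicalMarginal(45.0, 10.0, lo=0.0, hi=60.0),
            "mfis_total": ClinicalMarginal(26.8, 13.7, lo=0.0, hi=84.0),
            "mfis_physical": ClinicalMarginal(13.0, 7.0, lo=0.0, hi=36.0),
            "mfis_cognitive": ClinicalMarginal(10.0, 6.0, lo=0.0, hi=40.0),
            "mfis_psychosocial": ClinicalMarginal(3.5, 2.0, lo=0.0, hi=8.0),
        },
        disease_duration=ClinicalMarginal(160.0, 100.0, lo=8.0, hi=504.0),
    )
    rank_targets = {
        # motor-clinical cells that reached significance
        "asynchrony:edss": 0.56,
        "asynchrony:msfc": -0.40,
        "asynchrony:pasat": -0.38,
        "rate_mv:edss": -0.39,
        "rate_mv:msfc": 0.47,
        "rate_mv:nhpt_s": -0.45,
        "rate_mv:mfis_physical": -0.38,
        "td_2hz:msfc": -0.40,
        "td_2hz:nhpt_s": 0.45,
        "iti_2hz:nhpt_s": -0.37,
        # clinical-clinical structure (plausible values; the scales overlap
        # by construction, and a diagonal clinical block would make the
        # motor-clinical targets jointly infeasible)
        "edss:msfc": -0.60,
        "edss:t25w_s": 0.55,
        "edss:nhpt_s": 0.45,
        "edss:pasat": -0.30,
        "edss:mfis_total": 0.25,
        "edss:mfis_physical": 0.30,
        "msfc:nhpt_s": -0.70,
        "msfc:t25w_s": -0.65,
        "msfc:pasat": 0.60,
        "msfc:mfis_physical": -0.25,
        "nhpt_s:t25w_s": 0.40,
        "nhpt_s:pasat": -0.30,
        "t25w_s:pasat": -0.25,
        "mfis_total:mfis_physical": 0.85,
        "mfis_total:mfis_cognitive": 0.85,
        "mfis_total:mfis_psychosocial": 0.70,
        "mfis_physical:mfis_cognitive": 0.55,
        "mfis_physical:mfis_psychosocial": 0.55,
        "mfis_cognitive:mfis_psychosocial": 0.50,
        # secondary motor-clinical cells keeping the grid coherent
        "asynchrony:nhpt_s": 0.30,
        "asynchrony:t25w_s": 0.30,
        "rate_mv:pasat": 0.31,
        "rate_mv:t25w_s": -0.18,
        "rate_mv:mfis_total": -0.21,
    }
    trait_corr = {
        "rate_sv:rate_mv": 0.75,
        "rate_sv:asynchrony": -0.15,
        "rate_mv:asynchrony": -0.45,
        "rate_mv:td_2hz": -0.30,
        "td_2hz:iti_2hz": -0.30,
        "td_2hz:asynchrony": 0.30,
    }
    config = SimulationConfig(
        n_hc=n_hc, n_ms=n_ms, hc=hc, ms=ms, clinical=clinical,
        rank_targets=rank_targets, trait_corr=trait_corr,
        sessions=sessions, duration_ms=duration_ms,
    )
    config.validate()
    return config


# --- YAML round-trip -------------------------------------------------------


def _plain(obj):
    """Recursively coerce numpy scalars so YAML can represent the tree."""
    if isinstance(obj, dict):
        return {_plain(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(asdict(config)), fh, sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)

    def group(g: dict) -> GroupSpec:
        return GroupSpec(
            age_mean=g["age_mean"], age_sd=g["age_sd"], p_female=g["p_female"],
            sv=SelfPacedSpec(**g["sv"]), mv=SelfPacedSpec(**g["mv"]),
            paced=PacedSpec(**g["paced"]),
            asynchrony=AsynchronySpec(**g["asynchrony"]),
        )

    clinical = ClinicalSpec(
        edss_probs={float(k): float(v) for k, v in d["clinical"]["edss_probs"].items()},
        marginals={
            k: ClinicalMarginal(**v) for k, v in d["clinical"]["marginals"].items()
        },
        disease_duration=ClinicalMarginal(**d["clinical"]["disease_duration"]),
    )
    config = SimulationConfig(
        n_hc=d["n_hc"], n_ms=d["n_ms"],
        hc=group(d["hc"]), ms=group(d["ms"]), clinical=clinical,
        rank_targets=d.get("rank_targets", {}) or {},
        trait_corr=d.get("trait_corr", {}) or {},
        sessions=d.get("sessions", 1),
        duration_ms=d.get("duration_ms", 60000),
        attenuation_correction=d.get("attenuation_correction", True),
    )
    config.validate()
    return config


# ---------------------------------------------------------------------------
# copula


def _trait_icc(config: SimulationConfig, trait: str) -> float:
    paced = config.ms.paced
    return {
        "rate_sv": config.ms.sv.retest_icc,
        "rate_mv": config.ms.mv.retest_icc,
        "td_2hz": paced.retest_icc_td,
        "iti_2hz": paced.retest_icc_gap,
        "asynchrony": config.ms.asynchrony.retest_icc,
    }[trait]


def _target_matrix(config: SimulationConfig, inflate: bool) -> np.ndarray:
    """Gaussian-copula correlation matrix from the configured targets."""
    idx = {name: i for i, name in enumerate(COPULA_VARS)}
    C = np.eye(len(COPULA_VARS))
    for key, r in config.rank_targets.items():
        a, _, b = key.partition(":")
        rho = 2.0 * np.sin(np.pi * r / 6.0)  # Spearman -> Gaussian scale
        if inflate and config.attenuation_correction:
            for v in (a, b):
                if v in MOTOR_TRAITS:
                    rho /= np.sqrt(max(_trait_icc(config, v), 1e-6))
            rho = float(np.clip(rho, -0.95, 0.95))
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = rho
    for key, rho in config.trait_corr.items():
        a, _, b = key.partition(":")
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = rho
    return C


#: largest admissible displacement of a single cell when projecting the
#: target matrix onto the correlation-matrix cone
MAX_PROJECTION_SHIFT = 0.2


def nearest_correlation(A: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projections."""
    Y = A.copy()
    dS = np.zeros_like(A)
    for _ in range(max_iter):
        R = Y - dS
        w, V = np.linalg.eigh(R)
        X = V @ np.diag(np.clip(w, 0.0, None)) @ V.T
        dS = X - R
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        if np.linalg.eigvalsh(Y).min() > -tol:
            break
    w, V = np.linalg.eigh(Y)
    Y = V @ np.diag(np.clip(w, 1e-8, None)) @ V.T
    d = np.sqrt(np.diag(Y))
    Y = Y / np.outer(d, d)
    np.fill_diagonal(Y, 1.0)
    return Y


def copula_matrix(config: SimulationConfig) -> np.ndarray:
    """Final Gaussian-copula correlation matrix (inflated and, if needed,
    projected); variable order is :data:`COPULA_VARS`."""
    C = _target_matrix(config, inflate=True)
    if np.linalg.eigvalsh(C).min() < 1e-8:
        C = nearest_correlation(C)
    return C


def _copula_cholesky(config: SimulationConfig) -> np.ndarray:
    C = _target_matrix(config, inflate=True)
    if np.linalg.eigvalsh(C).min() < 1e-8:
        projected = nearest_correlation(C)
        shift = np.abs(projected - C).max()
        if shift > MAX_PROJECTION_SHIFT:
            raise ConfigurationError(
                "copula targets jointly infeasible after attenuation "
                f"correction (projection shift {shift:.3f})"
            )
        C = projected
    return np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))


# ---------------------------------------------------------------------------
# subjects


@dataclass
class LatentSubject:
    """Per-subject latent motor traits plus the clinical record."""

    subject_id: str
    group: Group
    record: SubjectRecord
    rate_sv: float      # latent spontaneous rate, Hz
    rate_mv: float      # latent maximal rate, Hz
    td_2hz: float       # latent paced touch duration, ms
    gap_2hz: float      # latent paced gap, ms
    ihi_log_latent: float  # latent part of ln(mean |asynchrony|)
    spec: GroupSpec

    def __post_init__(self) -> None:
        if min(self.rate_sv, self.rate_mv, self.td_2hz, self.gap_2hz) <= 0:
            raise ConfigurationError("latent means must be strictly positive")


def _between_within(total_sd: float, icc: float) -> tuple[float, float]:
    return total_sd * np.sqrt(icc), total_sd * np.sqrt(1.0 - icc)


def simulate_subjects(
    config: SimulationConfig, rng: np.random.Generator
) -> list[LatentSubject]:
    """Draw the full cohort of latent subjects (controls then patients)."""
    config.validate()
    chol = _copula_cholesky(config)
    edss_levels = np.array(sorted(config.clinical.edss_probs))
    edss_cum = np.cumsum([config.clinical.edss_probs[l] for l in edss_levels])

    subjects: list[LatentSubject] = []
    for group, n, spec in (
        (Group.HC, config.n_hc, config.hc),
        (Group.MS, config.n_ms, config.ms),
    ):
        if n == 0:
            continue
        z = rng.standard_normal((n, len(COPULA_VARS))) @ chol.T
        zcol = {name: z[:, i] for i, name in enumerate(COPULA_VARS)}

        b_sv, _ = _between_within(spec.sv.rate_sd, spec.sv.retest_icc)
        b_mv, _ = _between_within(spec.mv.rate_sd, spec.mv.retest_icc)
        b_td, _ = _between_within(spec.paced.td_sd, spec.paced.retest_icc_td)
        b_gap, _ = _between_within(spec.paced.gap_sd, spec.paced.retest_icc_gap)
        asy = spec.asynchrony
        b_log = asy.log_sigma * np.sqrt(asy.retest_icc)

        rate_sv = np.maximum(spec.sv.rate_mean + b_sv * zcol["rate_sv"], 0.2)
        rate_mv = np.maximum(spec.mv.rate_mean + b_mv * zcol["rate_mv"], 0.2)
        td = np.maximum(spec.paced.td_mean + b_td * zcol["td_2hz"], 30.0)
        gap = np.maximum(spec.paced.gap_mean + b_gap * zcol["iti_2hz"], 10.0)
        ihi_log = asy.log_mu + b_log * zcol["asynchrony"]

        ages = np.clip(spec.age_mean + spec.age_sd * zcol["age"], 18.0, 85.0)
        sexes = np.where(rng.random(n) < spec.p_female, "F", "M")

        for i in range(n):
            sid = f"{group.value}{i + 1:03d}"
            clin: dict[str, float | None] = {}
            if group is Group.MS:
                u = stats.norm.cdf(zcol["edss"][i])
                clin["edss"] = float(
                    edss_levels[min(np.searchsorted(edss_cum, u), len(edss_levels) - 1)]
                )
                for name, marg in config.clinical.marginals.items():
                    val = marg.mean + marg.sd * zcol[name][i]
                    lo = marg.lo if marg.lo is not None else -np.inf
                    hi = marg.hi if marg.hi is not None else np.inf
                    clin[name] = float(np.clip(val, lo, hi))
                dd = config.clinical.disease_duration
                val = rng.normal(dd.mean, dd.sd)
                clin["disease_duration_months"] = float(
                    np.clip(val, dd.lo or -np.inf, dd.hi or np.inf)
                )
            record = SubjectRecord(
                subject_id=sid,
                group=group,
                age=float(np.round(ages[i], 1)),
                sex=str(sexes[i]),
                **clin,
            )
            subjects.append(
                LatentSubject(
                    subject_id=sid,
                    group=group,
                    record=record,
                    rate_sv=float(rate_sv[i]),
                    rate_mv=float(rate_mv[i]),
                    td_2hz=float(td[i]),
                    gap_2hz=float(gap[i]),
                    ihi_log_latent=float(ihi_log[i]),
                    spec=spec,
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# trials


def _lognormal_jitter(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal jitter with coefficient of
    variation ``cv``."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _assemble_events(
    onsets: np.ndarray, durations: np.ndarray, hand: Hand, duration_ms: int
) -> list[TouchEvent]:
    """Build non-overlapping integer-ms events cycling through the fingers."""
    events: list[TouchEvent] = []
    prev_off = None
    for k, (on, dur) in enumerate(zip(onsets, durations)):
        on_i = int(round(on))
        if prev_off is not None:
            on_i = max(on_i, prev_off)
        on_i = max(on_i, 0)
        off_i = on_i + max(int(round(dur)), 1)
        if off_i > duration_ms:
            break
        events.append(
            TouchEvent(
                t_on=on_i,
                t_off=off_i,
                hand=hand,
                finger=FINGER_CYCLE[k % 4],
            )
        )
        prev_off = off_i
    return events


def simulate_trial(
    subject: LatentSubject,
    condition: Condition,
    session: int = 1,
    duration: int = 60000,
    rng: np.random.Generator | None = None,
) -> Trial:
    """Render one trial for a latent subject.

    Every call draws a fresh between-session perturbation of the latent
    means (the test-retest random effect) followed by per-cycle jitter.
    """
    rng = rng if rng is not None else np.random.default_rng()
    condition = Condition(condition)
    spec = subject.spec
    trial_id = f"{subject.subject_id}_s{session}_{condition.value}"

    if condition in (Condition.SV, Condition.MV):
        cspec = spec.sv if condition is Condition.SV else spec.mv
        latent_rate = subject.rate_sv if condition is Condition.SV else subject.rate_mv
        _, w_sd = _between_within(cspec.rate_sd, cspec.retest_icc)
        rate_s = max(latent_rate + w_sd * rng.standard_normal(), 0.2)
        period = 1000.0 / rate_s
        td_s = cspec.td_fraction * period
        gap_s = period - td_s
        n_max = int(duration / max(period, 1.0)) + 8
        tds = td_s * _lognormal_jitter(rng, cspec.cycle_jitter_cv, n_max)
        gaps = gap_s * _lognormal_jitter(rng, cspec.cycle_jitter_cv, n_max)
        tds_i = np.maximum(np.round(tds), 1.0)
        gaps_i = np.maximum(np.round(gaps), 0.0)
        onsets = np.concatenate([[0.0], np.cumsum(tds_i + gaps_i)[:-1]])
        events = _assemble_events(onsets, tds_i, Hand.R, duration)
        if not events:
            warnings.warn(f"trial {trial_id}: duration too short, no events",
                          stacklevel=2)
        return Trial(
            trial_id=trial_id, subject_id=subject.subject_id, session=session,
            condition=condition, events=events, tones=[], duration=duration,
        )

    # metronome-paced
    pspec = spec.paced
    tones = list(range(0, duration, 500))
    _, w_td = _between_within(pspec.td_sd, pspec.retest_icc_td)
    _, w_gap = _between_within(pspec.gap_sd, pspec.retest_icc_gap)
    td_s = max(subject.td_2hz + w_td * rng.standard_normal(), 20.0)
    gap_s = max(subject.gap_2hz + w_gap * rng.standard_normal(), 5.0)
    period = td_s + gap_s
    n = len(tones)
    eps = rng.normal(0.0, pspec.tone_jitter_sd, size=n) if pspec.tone_jitter_sd > 0 else np.zeros(n)
    r_on = np.arange(n) * period + eps
    r_td = td_s * _lognormal_jitter(rng, pspec.cycle_jitter_cv, n)
    # keep the touch shorter than the available slot
    slot = np.diff(np.append(r_on, r_on[-1] + period)) - 1.0
    r_td = np.minimum(r_td, np.maximum(slot, 1.0))
    events = _assemble_events(r_on, r_td, Hand.R, duration)

    if condition is Condition.HZ2_BIM:
        asy = spec.asynchrony
        w_log = asy.log_sigma * np.sqrt(1.0 - asy.retest_icc)
        m_s = float(np.exp(subject.ihi_log_latent + w_log * rng.standard_normal()))
        sigma = m_s / HALF_NORMAL_MEAN
        delta = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
        l_on = r_on + delta
        l_td = td_s * _lognormal_jitter(rng, pspec.cycle_jitter_cv, n)
        l_td = np.minimum(l_td, np.maximum(np.diff(np.append(l_on, l_on[-1] + period)) - 1.0, 1.0))
        left_events = _assemble_events(l_on, l_td, Hand.L, duration)
        events = events + left_events
        if not events:
            warnings.warn(f"trial {trial_id}: duration too short, no events",
                          stacklevel=2)

    return Trial(
        trial_id=trial_id, subject_id=subject.subject_id, session=session,
        condition=condition, events=events, tones=tones, duration=duration,
    )


ALL_CONDITIONS = (Condition.SV, Condition.MV, Condition.HZ2, Condition.HZ2_BIM)


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator,
    conditions: tuple[Condition, ...] = ALL_CONDITIONS,
) -> tuple[list[SubjectRecord], list[LatentSubject], list[Trial]]:
    """Simulate the whole cohort in memory: one trial per subject x session
    x condition."""
    latents = simulate_subjects(config, rng)
    trials = [
        simulate_trial(sub, cond, session=sess, duration=config.duration_ms, rng=rng)
        for sub in latents
        for sess in range(1, config.sessions + 1)
        for cond in conditions
    ]
    return [s.record for s in latents], latents, trials


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
    rng: np.random.Generator,
    provenance: dict | None = None,
) -> dict:
    """Simulate and write the cohort CSV, event/tone CSVs and a manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, _, trials = simulate_dataset(config, rng)

    cohort_path = out / "cohort.csv"
    events_path = out / "events.csv"
    tones_path = out / "tones.csv"
    write_cohort(records, cohort_path, provenance=provenance)
    write_trials(trials, events_path, tones_path=tones_path, provenance=provenance)

    manifest = {
        "n_subjects": len(records),
        "n_trials": len(trials),
        "sessions": config.sessions,
        "conditions": [c.value for c in ALL_CONDITIONS],
        "files": {
            "cohort": cohort_path.name,
            "events": events_path.name,
            "tones": tones_path.name,
        },
    }
    if provenance:
        manifest["provenance"] = {k: str(v) for k, v in provenance.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
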