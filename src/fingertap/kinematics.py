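"""Extraction of motor performance parameters from validated trials.

Four parameters summarize a trial:

* touch duration (TD)      -- contact time of each thumb-to-finger touch, ms
* inter-tap interval (ITI) -- gap between the end of one contact and the
                              start of the next on the same hand, ms
* movement rate (RATE)     -- 1000 / (mean TD + mean ITI), Hz
* inter-hand interval (IHI, bimanual trials only) -- mean absolute onset
  difference between corresponding left- and right-hand touches, ms; larger
  values mean worse bimanual coordination.

RATE is computed from the trial-mean TD and trial-mean ITI (literal form of
the definition), not as touch count over elapsed time; the alternative is
available via :func:`movement_rate` ``method="count"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .glove_io import Condition, Hand, Trial

__all__ = [
    "MotorParams",
    "touch_durations",
    "inter_tap_intervals",
    "movement_rate",
    "inter_hand_interval",
    "summarize_trial",
    "summarize_trials",
    "parameter_table",
    "PARAMETER_NAMES",
]

#: analysis parameter names, in reporting order
PARAMETER_NAMES = ["rate_sv", "rate_mv", "td_2hz", "iti_2hz", "ihi"]

#: below this many left/right pairs the IHI estimate is flagged as unstable
MIN_IHI_PAIRS = 3


class DegenerateTrialError(ValueError):
    """Raised when a trial has too few events to define a parameter."""


@dataclass
class MotorParams:
    """Per-trial summary of the motor performance parameters."""

    trial_id: str
    subject_id: str
    session: int
    condition: Condition
    mean_td: float
    mean_iti: float
    rate: float
    ihi: float | None
    n_touches: int
    n_excluded: int
    unstable_ihi: bool = False

    def __post_init__(self) -> None:
        if self.mean_td <= 0 or self.mean_iti < 0 or self.rate <= 0:
            raise ValueError("invalid motor parameter summary")
        if abs(self.rate * (self.mean_td + self.mean_iti) - 1000.0) > 1e-6:
            raise ValueError("rate inconsistent with mean TD + mean ITI")
        if (self.ihi is None) != (self.condition is not Condition.HZ2_BIM):
            raise ValueError("IHI must be present exactly for bimanual trials")
        if self.ihi is not None and self.ihi < 0:
            raise ValueError("IHI must be non-negative")


def touch_durations(trial: Trial, hand: Hand = Hand.R) -> np.ndarray:
    """Contact time t_off - t_on per event on ``hand``, in event order (ms)."""
    return np.array([e.duration for e in trial.events_for(hand)], dtype=float)


def inter_tap_intervals(trial: Trial, hand: Hand = Hand.R) -> np.ndarray:
    """Gaps t_on[i+1] - t_off[i] between consecutive same-hand contacts (ms).

    Negative gaps (overlaps surviving repair) are clamped to zero.
    """
    evs = trial.events_for(hand)
    if len(evs) < 2:
        warnings.warn(
            f"trial {trial.trial_id}: fewer than 2 events on hand "
            f"{Hand(hand).value}; no inter-tap intervals",
            stacklevel=2,
        )
        return np.empty(0, dtype=float)
    gaps = np.array(
        [nxt.t_on - cur.t_off for cur, nxt in zip(evs, evs[1:])], dtype=float
    )
    return np.clip(gaps, 0.0, None)


def movement_rate(trial: Trial, hand: Hand = Hand.R, method: str = "mean") -> float:
    """Movement rate in Hz.

    ``method="mean"`` (default): 1000 / (mean TD + mean ITI).
    ``method="count"``: touches per second of spanned time.
    """
    tds = touch_durations(trial, hand)
    if tds.size < 2:
        raise DegenerateTrialError(
            f"trial {trial.trial_id}: need >= 2 events on hand {Hand(hand).value} "
            "to define a movement rate"
        )
    if method == "count":
        evs = trial.events_for(hand)
        span = evs[-1].t_on - evs[0].t_on  # n - 1 complete cycles
        return 1000.0 * (len(evs) - 1) / span
    itis = inter_tap_intervals(trial, hand)
    denom = tds.mean() + itis.mean()
    if denom <= 0:
        raise DegenerateTrialError(f"trial {trial.trial_id}: degenerate cycle time")
    return 1000.0 / denom


def _pair_onsets(trial: Trial) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair left/right touches by cycle position, re-aligning on finger
    identity after a dropped touch. Returns (left onsets, right onsets,
    number of unpaired touches)."""
    left = trial.events_for(Hand.L)
    right = trial.events_for(Hand.R)
    li = ri = 0
    l_on, r_on = [], []
    excluded = 0
    while li < len(left) and ri < len(right):
        if left[li].finger == right[ri].finger:
            l_on.append(left[li].t_on)
            r_on.append(right[ri].t_on)
            li += 1
            ri += 1
        elif left[li].t_on <= right[ri].t_on:
            li += 1
            excluded += 1
        else:
            ri += 1
            excluded += 1
    excluded += (len(left) - li) + (len(right) - ri)
    return np.array(l_on, dtype=float), np.array(r_on, dtype=float), excluded


def inter_hand_interval(trial: Trial) -> tuple[float, int, bool]:
    """Mean |left onset - right onset| over paired touches, in ms.

    Returns ``(ihi, n_excluded, unstable)`` where ``unstable`` flags fewer
    than :data:`MIN_IHI_PAIRS` pairs.
    """
    if trial.condition is not Condition.HZ2_BIM:
        raise ValueError(
            f"trial {trial.trial_id}: IHI is defined for bimanual trials only"
        )
    if not trial.events_for(Hand.L) or not trial.events_for(Hand.R):
        raise DegenerateTrialError(
            f"trial {trial.trial_id}: both hands must have events for IHI"
        )
    l_on, r_on, excluded = _pair_onsets(trial)
    unstable = l_on.size < MIN_IHI_PAIRS
    if unstable:
        warnings.warn(
            f"trial {trial.trial_id}: only {l_on.size} left/right pairs; "
            "IHI estimate unstable",
            stacklevel=2,
        )
    if l_on.size == 0:
        raise DegenerateTrialError(
            f"trial {trial.trial_id}: no alignable left/right touch pairs"
        )
    return float(np.abs(l_on - r_on).mean()), excluded, unstable


def summarize_trial(trial: Trial) -> MotorParams:
    """Extract all parameters for one trial.

    The right (dominant) hand supplies TD/ITI/RATE in every condition; the
    inter-hand interval is added for bimanual trials.
    """
    tds = touch_durations(trial, Hand.R)
    if tds.size < 2:
        raise DegenerateTrialError(
            f"trial {trial.trial_id}: need >= 2 right-hand events"
        )
    itis = inter_tap_intervals(trial, Hand.R)
    raw_gaps = np.array(
        [
            nxt.t_on - cur.t_off
            for cur, nxt in zip(trial.events_for(Hand.R), trial.events_for(Hand.R)[1:])
        ],
        dtype=float,
    )
    n_excluded = int((raw_gaps < 0).sum())
    mean_td = float(tds.mean())
    mean_iti = float(itis.mean())
    rate = 1000.0 / (mean_td + mean_iti)

    ihi: float | None = None
    unstable = False
    if trial.condition is Condition.HZ2_BIM:
        ihi, ihi_excluded, unstable = inter_hand_interval(trial)
        n_excluded += ihi_excluded

    return MotorParams(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        session=trial.session,
        condition=trial.condition,
        mean_td=mean_td,
        mean_iti=mean_iti,
        rate=rate,
        ihi=ihi,
        n_touches=tds.size,
        n_excluded=n_excluded,
        unstable_ihi=unstable,
    )


def summarize_trials(trials: Iterable[Trial]) -> pd.DataFrame:
    """Batch extraction; one row per trial."""
    rows = []
    for trial in trials:
        p = summarize_trial(trial)
        rows.append(
            {
                "trial_id": p.trial_id,
                "subject_id": p.subject_id,
                "session": p.session,
                "condition": p.condition.value,
                "mean_td": p.mean_td,
                "mean_iti": p.mean_iti,
                "rate": p.rate,
                "ihi": p.ihi if p.ihi is not None else np.nan,
                "n_touches": p.n_touches,
                "n_excluded": p.n_excluded,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id", "subject_id", "session", "condition",
            "mean_td", "mean_iti", "rate", "ihi", "n_touches", "n_excluded",
        ],
    )


def parameter_table(params: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-trial summaries to one row per (subject, session) with the
    five analysis parameters as columns: rate_sv, rate_mv, td_2hz, iti_2hz,
    ihi (raw ms) and log_ihi (natural log)."""
    pieces = {
        "rate_sv": ("SV", "rate"),
        "rate_mv": ("MV", "rate"),
        "td_2hz": ("2HZ", "mean_td"),
        "iti_2hz": ("2HZ", "mean_iti"),
        "ihi": ("2HZ_BIM", "ihi"),
    }
    out: pd.DataFrame | None = None
    for name, (cond, col) in pieces.items():
        part = (
            params.loc[params["condition"] == cond, ["subject_id", "session", col]]
            .rename(columns={col: name})
            .set_index(["subject_id", "session"])
        )
        out = part if out is None else out.join(part, how="outer")
    assert out is not None
    out["log_ihi"] = np.log(out["ihi"])
    return out.reset_index()
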