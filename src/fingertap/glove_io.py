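"""Data model and CSV I/O for sensor-glove touch-event recordings.

A recording is a sequence of thumb-to-finger contacts ("touch events"),
each carrying the hand, the opposed finger (index=2 .. little=5) and the
contact onset/offset in integer milliseconds from trial start (1 kHz
acquisition; fractional timestamps are rejected rather than rounded).

File formats (all plain CSV, ``#`` lines are provenance comments):

* event CSV      -- ``trial_id,subject_id,session,condition,hand,finger,t_on_ms,t_off_ms``
* tone CSV       -- ``trial_id,t_tone_ms``
* cohort CSV     -- one row per subject, clinical columns optional for controls
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Hand",
    "Finger",
    "Condition",
    "Group",
    "TouchEvent",
    "Trial",
    "SubjectRecord",
    "GloveFormatError",
    "GloveValidationError",
    "read_trial",
    "read_trials",
    "write_trial",
    "write_trials",
    "read_tones",
    "read_cohort",
    "write_cohort",
]

EVENT_COLUMNS = [
    "trial_id", "subject_id", "session", "condition",
    "hand", "finger", "t_on_ms", "t_off_ms",
]
TONE_COLUMNS = ["trial_id", "t_tone_ms"]
COHORT_COLUMNS = [
    "subject_id", "group", "age", "sex", "edss", "disease_duration_months",
    "msfc", "nhpt_s", "t25w_s", "pasat",
    "mfis_total", "mfis_physical", "mfis_cognitive", "mfis_psychosocial",
]

#: metronome period expected in paced conditions (ms)
TONE_PERIOD_MS = 500
#: maximum same-hand contact overlap repairable as a sensor glitch (ms)
MAX_REPAIR_OVERLAP_MS = 5


class GloveFormatError(ValueError):
    """Raised when a file does not conform to the expected CSV dialect."""


class GloveValidationError(ValueError):
    """Raised when well-formed input violates a domain invariant."""


class Hand(str, enum.Enum):
    L = "L"
    R = "R"


class Finger(enum.IntEnum):
    INDEX = 2
    MEDIUM = 3
    RING = 4
    LITTLE = 5


class Condition(str, enum.Enum):
    """Trial condition; values are the CSV spellings."""

    SV = "SV"            # self-paced, spontaneous velocity
    MV = "MV"            # self-paced, maximal velocity
    HZ2 = "2HZ"          # metronome-paced at 2 Hz, dominant hand
    HZ2_BIM = "2HZ_BIM"  # metronome-paced at 2 Hz, both hands

    @property
    def paced(self) -> bool:
        return self in (Condition.HZ2, Condition.HZ2_BIM)

    @property
    def bimanual(self) -> bool:
        return self is Condition.HZ2_BIM


class Group(str, enum.Enum):
    HC = "HC"
    MS = "MS"


def _as_int_ms(value, what: str, row: int | None = None) -> int:
    """Coerce to integer milliseconds, rejecting fractional input."""
    where = f" (row {row})" if row is not None else ""
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise GloveFormatError(f"non-numeric {what}{where}: {value!r}") from None
    if not math.isfinite(f) or f != int(f):
        raise GloveValidationError(
            f"{what} must be integer milliseconds{where}, got {value!r}"
        )
    return int(f)


@dataclass(frozen=True, order=True)
class TouchEvent:
    """One thumb-to-finger contact: closed interval [t_on, t_off] in ms."""

    t_on: int
    t_off: int
    hand: Hand = Hand.R
    finger: Finger = Finger.INDEX

    def __post_init__(self) -> None:
        object.__setattr__(self, "hand", Hand(self.hand))
        object.__setattr__(self, "finger", Finger(self.finger))
        t_on = _as_int_ms(self.t_on, "t_on")
        t_off = _as_int_ms(self.t_off, "t_off")
        object.__setattr__(self, "t_on", t_on)
        object.__setattr__(self, "t_off", t_off)
        if t_on < 0:
            raise GloveValidationError(f"t_on must be >= 0, got {t_on}")
        if t_off <= t_on:
            raise GloveValidationError(
                f"t_off must exceed t_on, got [{t_on}, {t_off}]"
            )

    @property
    def duration(self) -> int:
        return self.t_off - self.t_on


@dataclass
class Trial:
    """One 60-s recording of a finger-opposition sequence.

    Events are kept sorted by onset; same-hand contacts must not overlap.
    Paced conditions carry the metronome tone track.
    """

    trial_id: str
    subject_id: str
    session: int
    condition: Condition
    events: list[TouchEvent] = field(default_factory=list)
    tones: list[int] = field(default_factory=list)
    duration: int = 60000

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.session = int(self.session)
        if self.session < 1:
            raise GloveValidationError(f"session must be >= 1, got {self.session}")
        if self.duration <= 0:
            raise GloveValidationError("duration must be positive")
        self.events = sorted(self.events, key=lambda e: (e.t_on, e.hand.value))
        self.tones = [_as_int_ms(t, "tone time") for t in self.tones]
        self.validate()

    def validate(self, repair: bool = False) -> "Trial":
        """Check all trial invariants; optionally repair small same-hand
        overlaps (<= 5 ms sensor glitches) by truncating the earlier contact.
        """
        if not self.condition.bimanual:
            bad = [e for e in self.events if e.hand is not Hand.R]
            if bad:
                raise GloveValidationError(
                    f"trial {self.trial_id}: condition {self.condition.value} "
                    f"permits right-hand events only; found {len(bad)} left-hand"
                )
        for hand in (Hand.L, Hand.R):
            evs = self.events_for(hand)
            for i in range(len(evs) - 1):
                overlap = evs[i].t_off - evs[i + 1].t_on
                if overlap > 0:
                    if repair and overlap <= MAX_REPAIR_OVERLAP_MS:
                        fixed = replace(evs[i], t_off=evs[i + 1].t_on)
                        idx = self.events.index(evs[i])
                        self.events[idx] = fixed
                        evs = self.events_for(hand)
                    else:
                        raise GloveValidationError(
                            f"trial {self.trial_id}: overlapping {hand.value}-hand "
                            f"contacts at t_on={evs[i + 1].t_on} "
                            f"(previous t_off={evs[i].t_off}, overlap {overlap} ms)"
                        )
        if self.condition.paced:
            if not self.tones:
                raise GloveValidationError(
                    f"trial {self.trial_id}: paced condition requires a tone track"
                )
            gaps = [b - a for a, b in zip(self.tones, self.tones[1:])]
            if gaps and not all(
                0.8 * TONE_PERIOD_MS <= g <= 1.2 * TONE_PERIOD_MS for g in gaps
            ):
                warnings.warn(
                    f"trial {self.trial_id}: tone track deviates from "
                    f"{TONE_PERIOD_MS} ms spacing",
                    stacklevel=2,
                )
        return self

    def events_for(self, hand: Hand) -> list[TouchEvent]:
        hand = Hand(hand)
        return [e for e in self.events if e.hand is hand]

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class SubjectRecord:
    """Per-subject metadata and clinical scores (optional for controls)."""

    subject_id: str
    group: Group
    age: float
    sex: str = "F"
    edss: float | None = None
    disease_duration_months: float | None = None
    msfc: float | None = None
    nhpt_s: float | None = None
    t25w_s: float | None = None
    pasat: float | None = None
    mfis_total: float | None = None
    mfis_physical: float | None = None
    mfis_cognitive: float | None = None
    mfis_psychosocial: float | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.group is Group.HC and self.edss is not None:
            raise GloveValidationError(
                f"subject {self.subject_id}: controls must not carry an EDSS"
            )
        if self.edss is not None:
            if not (0.0 <= self.edss <= 7.0):
                raise GloveValidationError(
                    f"subject {self.subject_id}: EDSS {self.edss} outside [0, 7]"
                )
            if (2 * self.edss) != int(2 * self.edss):
                raise GloveValidationError(
                    f"subject {self.subject_id}: EDSS {self.edss} not on the "
                    "half-point grid"
                )


# ---------------------------------------------------------------------------
# event / tone CSV


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


def write_trials(
    trials: Iterable[Trial],
    path: str | Path,
    tones_path: str | Path | None = None,
    provenance: dict | None = None,
) -> None:
    """Write trials to an event CSV (and, optionally, their tone tracks)."""
    trials = list(trials)
    rows = [
        {
            "trial_id": t.trial_id,
            "subject_id": t.subject_id,
            "session": t.session,
            "condition": t.condition.value,
            "hand": e.hand.value,
            "finger": int(e.finger),
            "t_on_ms": e.t_on,
            "t_off_ms": e.t_off,
        }
        for t in trials
        for e in t.events
    ]
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_lines(provenance))
        frame.to_csv(fh, index=False)
    if tones_path is not None:
        tone_rows = [
            {"trial_id": t.trial_id, "t_tone_ms": tone}
            for t in trials
            for tone in t.tones
        ]
        tframe = pd.DataFrame(tone_rows, columns=TONE_COLUMNS)
        with open(tones_path, "w", newline="") as fh:
            fh.write(_provenance_lines(provenance))
            tframe.to_csv(fh, index=False)


def write_trial(
    trial: Trial,
    path: str | Path,
    tones_path: str | Path | None = None,
    provenance: dict | None = None,
) -> None:
    write_trials([trial], path, tones_path=tones_path, provenance=provenance)


def read_tones(path: str | Path) -> dict[str, list[int]]:
    """Read a tone CSV into a mapping trial_id -> sorted tone times (ms)."""
    frame = pd.read_csv(path, comment="#", dtype={"trial_id": str})
    missing = set(TONE_COLUMNS) - set(frame.columns)
    if missing:
        raise GloveFormatError(f"tone CSV {path}: missing columns {sorted(missing)}")
    out: dict[str, list[int]] = {}
    for row in frame.itertuples(index=True):
        out.setdefault(str(row.trial_id), []).append(
            _as_int_ms(row.t_tone_ms, "t_tone_ms", row.Index)
        )
    return {k: sorted(v) for k, v in out.items()}


def read_trials(
    path: str | Path,
    tones_path: str | Path | None = None,
    duration: int = 60000,
    repair: bool = False,
) -> list[Trial]:
    """Read all trials from an event CSV, validating each one."""
    frame = pd.read_csv(
        path, comment="#", dtype={"trial_id": str, "subject_id": str}
    )
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise GloveFormatError(f"event CSV {path}: missing columns {sorted(missing)}")
    tones = read_tones(tones_path) if tones_path is not None else {}

    trials: list[Trial] = []
    for trial_id, part in frame.groupby("trial_id", sort=False):
        meta = part.iloc[0]
        events = []
        for row in part.itertuples(index=True):
            try:
                events.append(
                    TouchEvent(
                        t_on=_as_int_ms(row.t_on_ms, "t_on_ms", row.Index),
                        t_off=_as_int_ms(row.t_off_ms, "t_off_ms", row.Index),
                        hand=Hand(row.hand),
                        finger=Finger(int(row.finger)),
                    )
                )
            except GloveValidationError as err:
                raise GloveValidationError(
                    f"event CSV {path}, row {row.Index}: {err}"
                ) from None
        trial = Trial.__new__(Trial)
        trial.trial_id = str(trial_id)
        trial.subject_id = str(meta.subject_id)
        trial.session = int(meta.session)
        trial.condition = Condition(str(meta.condition))
        trial.events = sorted(events, key=lambda e: (e.t_on, e.hand.value))
        trial.tones = tones.get(str(trial_id), [])
        trial.duration = duration
        if trial.session < 1:
            raise GloveValidationError(f"trial {trial_id}: session must be >= 1")
        trial.validate(repair=repair)
        trials.append(trial)
    return trials


def read_trial(
    path: str | Path,
    tones_path: str | Path | None = None,
    duration: int = 60000,
    repair: bool = False,
) -> Trial:
    """Read a single-trial event CSV."""
    trials = read_trials(path, tones_path=tones_path, duration=duration, repair=repair)
    if len(trials) != 1:
        raise GloveFormatError(
            f"event CSV {path}: expected exactly one trial, found {len(trials)}"
        )
    return trials[0]


# ---------------------------------------------------------------------------
# cohort CSV

_OPTIONAL_FLOATS = [
    "edss", "disease_duration_months", "msfc", "nhpt_s", "t25w_s", "pasat",
    "mfis_total", "mfis_physical", "mfis_cognitive", "mfis_psychosocial",
]


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort metadata CSV into validated subject records."""
    frame = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise GloveFormatError(
            f"cohort CSV {path}: missing columns {sorted(missing)}"
        )
    dupes = frame["subject_id"][frame["subject_id"].duplicated()]
    if not dupes.empty:
        raise GloveValidationError(
            f"cohort CSV {path}: duplicate subject_id {sorted(set(dupes))}"
        )
    records = []
    for row in frame.itertuples(index=True):
        kwargs = {
            c: (None if pd.isna(v := getattr(row, c)) else float(v))
            for c in _OPTIONAL_FLOATS
        }
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=Group(str(row.group)),
                age=float(row.age),
                sex=str(row.sex),
                **kwargs,
            )
        )
    return records


def write_cohort(
    records: Sequence[SubjectRecord],
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in COHORT_COLUMNS if c != "group"}
        row["group"] = r.group.value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_lines(provenance))
        frame.to_csv(fh, index=False)


def cohort_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Subject records as a DataFrame indexed by subject_id."""
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in COHORT_COLUMNS if c != "group"}
        row["group"] = r.group.value
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS).set_index("subject_id")
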