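"""Shared fixtures and builders for the test suite.

All fixture data is generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from fingertap.glove_io import Condition, Group, Hand, TouchEvent, Trial
from fingertap.simulate import (
    AsynchronySpec,
    GroupSpec,
    LatentSubject,
    PacedSpec,
    SelfPacedSpec,
)
from fingertap.glove_io import SubjectRecord


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_trial(
    durations,
    gaps,
    condition: Condition = Condition.SV,
    hand: Hand = Hand.R,
    start: int = 0,
    trial_id: str = "t1",
    subject_id: str = "s1",
    session: int = 1,
    tones=None,
    extra_events=(),
    duration: int = 60000,
) -> Trial:
    """Build a trial from touch durations and the gaps between touches."""
    events = list(extra_events)
    t = start
    fingers = [2, 3, 4, 5]
    for k, dur in enumerate(durations):
        events.append(
            TouchEvent(t_on=t, t_off=t + dur, hand=hand, finger=fingers[k % 4])
        )
        t += dur
        if k < len(gaps):
            t += gaps[k]
    if tones is None and Condition(condition).paced:
        tones = list(range(0, duration, 500))
    return Trial(
        trial_id=trial_id,
        subject_id=subject_id,
        session=session,
        condition=condition,
        events=events,
        tones=tones or [],
        duration=duration,
    )


def make_bimanual_trial(
    right_onsets,
    left_offsets_ms,
    td: int = 100,
    trial_id: str = "bim1",
    subject_id: str = "s1",
    duration: int = 60000,
) -> Trial:
    """Bimanual paced trial: right touches at given onsets, left touches at
    right onset + signed per-touch offset."""
    fingers = [2, 3, 4, 5]
    events = []
    for k, on in enumerate(right_onsets):
        events.append(
            TouchEvent(t_on=int(on), t_off=int(on) + td, hand=Hand.R,
                       finger=fingers[k % 4])
        )
        l_on = int(on + left_offsets_ms[k])
        events.append(
            TouchEvent(t_on=l_on, t_off=l_on + td, hand=Hand.L,
                       finger=fingers[k % 4])
        )
    return Trial(
        trial_id=trial_id,
        subject_id=subject_id,
        session=1,
        condition=Condition.HZ2_BIM,
        events=events,
        tones=list(range(0, duration, 500)),
        duration=duration,
    )


def make_noise_free_spec(
    rate: float = 2.0,
    td_ms: float = 250.0,
    gap_ms: float = 250.0,
    ihi_mean: float = 0.0,
    tone_jitter_sd: float = 0.0,
) -> GroupSpec:
    """Group spec with every noise source switched off."""
    return GroupSpec(
        age_mean=40.0,
        age_sd=0.0,
        p_female=0.5,
        sv=SelfPacedSpec(rate_mean=rate, rate_sd=0.0, td_fraction=0.5,
                         retest_icc=1.0, cycle_jitter_cv=0.0),
        mv=SelfPacedSpec(rate_mean=rate, rate_sd=0.0, td_fraction=0.5,
                         retest_icc=1.0, cycle_jitter_cv=0.0),
        paced=PacedSpec(td_mean=td_ms, td_sd=0.0, gap_mean=gap_ms, gap_sd=0.0,
                        retest_icc_td=1.0, retest_icc_gap=1.0,
                        cycle_jitter_cv=0.0, tone_jitter_sd=tone_jitter_sd),
        asynchrony=AsynchronySpec(ihi_mean=ihi_mean, ihi_sd=0.0, retest_icc=1.0),
    )


def make_latent(spec: GroupSpec | None = None, subject_id: str = "HC001",
                group: Group = Group.HC) -> LatentSubject:
    spec = spec or make_noise_free_spec()
    record = SubjectRecord(subject_id=subject_id, group=group, age=40.0)
    return LatentSubject(
        subject_id=subject_id,
        group=group,
        record=record,
        rate_sv=spec.sv.rate_mean,
        rate_mv=spec.mv.rate_mean,
        td_2hz=spec.paced.td_mean,
        gap_2hz=spec.paced.gap_mean,
        ihi_log_latent=spec.asynchrony.log_mu,
        spec=spec,
    )
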