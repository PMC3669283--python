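"""Unit and property tests for the glove event data model and CSV I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fingertap.glove_io import (
    Condition,
    Finger,
    GloveFormatError,
    GloveValidationError,
    Group,
    Hand,
    SubjectRecord,
    TouchEvent,
    Trial,
    read_cohort,
    read_trial,
    read_trials,
    write_cohort,
    write_trial,
    write_trials,
)


# ---------------------------------------------------------------------------
# TouchEvent


class TestTouchEvent:
    def test_duration(self):
        ev = TouchEvent(t_on=100, t_off=350, hand=Hand.R, finger=Finger.INDEX)
        assert ev.duration == 250

    def test_inverted_interval_rejected(self):
        with pytest.raises(GloveValidationError):
            TouchEvent(t_on=500, t_off=400)

    def test_zero_length_rejected(self):
        with pytest.raises(GloveValidationError):
            TouchEvent(t_on=10, t_off=10)

    def test_negative_onset_rejected(self):
        with pytest.raises(GloveValidationError):
            TouchEvent(t_on=-1, t_off=10)

    def test_fractional_timestamp_rejected(self):
        with pytest.raises(GloveValidationError):
            TouchEvent(t_on=0.5, t_off=10)

    def test_integral_float_accepted(self):
        assert TouchEvent(t_on=1.0, t_off=5.0).t_on == 1

    def test_bad_finger_rejected(self):
        with pytest.raises(ValueError):
            TouchEvent(t_on=0, t_off=10, finger=6)


# ---------------------------------------------------------------------------
# Trial validation


class TestTrialValidation:
    def test_events_sorted_on_construction(self):
        evs = [
            TouchEvent(t_on=400, t_off=650, finger=3),
            TouchEvent(t_on=0, t_off=250, finger=2),
        ]
        trial = Trial("t1", "s1", 1, Condition.SV, events=evs)
        assert [e.t_on for e in trial.events] == [0, 400]

    def test_same_hand_overlap_rejected(self):
        evs = [
            TouchEvent(t_on=0, t_off=260, finger=2),
            TouchEvent(t_on=250, t_off=500, finger=3),
        ]
        with pytest.raises(GloveValidationError, match="overlap"):
            Trial("t1", "s1", 1, Condition.SV, events=evs)

    def test_small_overlap_repairable(self):
        evs = [
            TouchEvent(t_on=0, t_off=253, finger=2),
            TouchEvent(t_on=250, t_off=500, finger=3),
        ]
        trial = Trial.__new__(Trial)
        trial.trial_id, trial.subject_id, trial.session = "t1", "s1", 1
        trial.condition = Condition.SV
        trial.events = sorted(evs, key=lambda e: e.t_on)
        trial.tones = []
        trial.duration = 60000
        trial.validate(repair=True)
        assert trial.events[0].t_off == 250

    def test_touching_contacts_allowed(self):
        evs = [
            TouchEvent(t_on=0, t_off=250, finger=2),
            TouchEvent(t_on=250, t_off=500, finger=3),
        ]
        trial = Trial("t1", "s1", 1, Condition.SV, events=evs)
        assert trial.n_events == 2

    def test_left_hand_rejected_in_unimanual(self):
        evs = [TouchEvent(t_on=0, t_off=100, hand=Hand.L)]
        with pytest.raises(GloveValidationError, match="right-hand"):
            Trial("t1", "s1", 1, Condition.SV, events=evs)

    def test_paced_requires_tones(self):
        evs = [TouchEvent(t_on=0, t_off=100)]
        with pytest.raises(GloveValidationError, match="tone"):
            Trial("t1", "s1", 1, Condition.HZ2, events=evs, tones=[])

    def test_paced_with_tones_ok(self):
        evs = [TouchEvent(t_on=0, t_off=100)]
        trial = Trial(
            "t1", "s1", 1, Condition.HZ2, events=evs,
            tones=list(range(0, 60000, 500)),
        )
        assert len(trial.tones) == 120

    def test_irregular_tones_warn(self):
        evs = [TouchEvent(t_on=0, t_off=100)]
        with pytest.warns(UserWarning, match="tone track"):
            Trial("t1", "s1", 1, Condition.HZ2, events=evs, tones=[0, 900, 1400])

    def test_session_must_be_positive(self):
        with pytest.raises(GloveValidationError):
            Trial("t1", "s1", 0, Condition.SV)


# ---------------------------------------------------------------------------
# event CSV round trips


class TestEventCSV:
    def test_minimal_two_row_file(self, tmp_path):
        path = tmp_path / "events.csv"
        path.write_text(
            "trial_id,subject_id,session,condition,hand,finger,t_on_ms,t_off_ms\n"
            "t1,s1,1,SV,R,2,0,250\n"
            "t1,s1,1,SV,R,3,400,650\n"
        )
        trial = read_trial(path)
        assert trial.n_events == 2
        assert [e.t_on for e in trial.events] == [0, 400]
        assert trial.condition is Condition.SV

    def test_inverted_interval_cites_row(self, tmp_path):
        path = tmp_path / "events.csv"
        path.write_text(
            "trial_id,subject_id,session,condition,hand,finger,t_on_ms,t_off_ms\n"
            "t1,s1,1,SV,R,2,500,400\n"
        )
        with pytest.raises(GloveValidationError, match="row 0"):
            read_trial(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "events.csv"
        path.write_text("trial_id,subject_id,session\n" "t1,s1,1\n")
        with pytest.raises(GloveFormatError, match="missing columns"):
            read_trials(path)

    def test_empty_trial_writes_header_only(self, tmp_path):
        trial = Trial("t1", "s1", 1, Condition.SV, events=[])
        path = tmp_path / "events.csv"
        write_trial(trial, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("trial_id,")

    def test_row_count_equals_event_count(self, tmp_path):
        events = [
            TouchEvent(t_on=500 * k, t_off=500 * k + 250, finger=2 + k % 4)
            for k in range(120)
        ]
        trial = Trial("t1", "s1", 1, Condition.SV, events=events)
        path = tmp_path / "events.csv"
        write_trial(trial, path)
        frame = pd.read_csv(path)
        assert len(frame) == 120

    def test_provenance_comments_ignored_on_read(self, tmp_path):
        trial = Trial(
            "t1", "s1", 1, Condition.SV, events=[TouchEvent(t_on=0, t_off=9)]
        )
        path = tmp_path / "events.csv"
        write_trial(trial, path, provenance={"seed": 7})
        assert path.read_text().startswith("# seed=7\n")
        assert read_trial(path).n_events == 1

    def test_read_trial_rejects_multi_trial_file(self, tmp_path):
        trials = [
            Trial(f"t{i}", "s1", 1, Condition.SV,
                  events=[TouchEvent(t_on=0, t_off=10)])
            for i in range(2)
        ]
        path = tmp_path / "events.csv"
        write_trials(trials, path)
        with pytest.raises(GloveFormatError, match="exactly one"):
            read_trial(path)


# hypothesis strategy: a valid unimanual trial


@st.composite
def unimanual_trials(draw):
    n = draw(st.integers(min_value=0, max_value=30))
    durations = draw(
        st.lists(st.integers(1, 500), min_size=n, max_size=n)
    )
    gaps = draw(st.lists(st.integers(0, 500), min_size=n, max_size=n))
    events = []
    t = draw(st.integers(0, 1000))
    for k in range(n):
        events.append(
            TouchEvent(t_on=t, t_off=t + durations[k], hand=Hand.R,
                       finger=2 + k % 4)
        )
        t += durations[k] + gaps[k]
    condition = draw(st.sampled_from([Condition.SV, Condition.MV]))
    return Trial(
        trial_id=draw(st.sampled_from(["a", "b9", "x_1"])),
        subject_id="s1",
        session=draw(st.integers(1, 3)),
        condition=condition,
        events=events,
    )


class TestRoundTrip:
    @settings(max_examples=40, deadline=None)
    @given(trial=unimanual_trials())
    def test_event_round_trip(self, trial, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        path = tmp / "events.csv"
        write_trial(trial, path)
        if trial.n_events == 0:
            return  # a trial with no rows has no identity in the file
        back = read_trial(path)
        assert back.trial_id == trial.trial_id
        assert back.subject_id == trial.subject_id
        assert back.session == trial.session
        assert back.condition == trial.condition
        assert back.events == trial.events

    def test_tone_round_trip(self, tmp_path):
        tones = list(range(0, 60000, 500))
        trial = Trial(
            "t1", "s1", 1, Condition.HZ2,
            events=[TouchEvent(t_on=0, t_off=100)], tones=tones,
        )
        epath, tpath = tmp_path / "e.csv", tmp_path / "t.csv"
        write_trial(trial, epath, tones_path=tpath)
        back = read_trial(epath, tones_path=tpath)
        assert back.tones == tones


# ---------------------------------------------------------------------------
# cohort CSV


COHORT_HEADER = (
    "subject_id,group,age,sex,edss,disease_duration_months,msfc,nhpt_s,"
    "t25w_s,pasat,mfis_total,mfis_physical,mfis_cognitive,mfis_psychosocial\n"
)


class TestCohortCSV:
    def test_three_row_file(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(
            COHORT_HEADER
            + "h1,HC,40,F,,,,,,,,,,\n"
            + "m1,MS,45,M,2.0,120,-0.5,22,5.5,48,30,14,11,4\n"
            + "m2,MS,50,F,4.5,200,-1.2,28,8.1,40,35,18,12,5\n"
        )
        records = read_cohort(path)
        assert [r.group for r in records] == [Group.HC, Group.MS, Group.MS]
        assert records[1].edss == 2.0
        assert records[0].edss is None

    def test_edss_out_of_range(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(COHORT_HEADER + "m1,MS,45,M,7.5,,,,,,,,,\n")
        with pytest.raises(GloveValidationError, match="EDSS"):
            read_cohort(path)

    def test_edss_off_grid(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(COHORT_HEADER + "m1,MS,45,M,2.3,,,,,,,,,\n")
        with pytest.raises(GloveValidationError, match="half-point"):
            read_cohort(path)

    def test_hc_with_edss_rejected(self):
        with pytest.raises(GloveValidationError, match="controls"):
            SubjectRecord(subject_id="h1", group=Group.HC, age=40, edss=1.0)

    def test_duplicate_subject_id(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(
            COHORT_HEADER + "m1,MS,45,M,2,,,,,,,,,\n" + "m1,MS,46,F,3,,,,,,,,,\n"
        )
        with pytest.raises(GloveValidationError, match="duplicate"):
            read_cohort(path)

    def test_round_trip(self, tmp_path):
        records = [
            SubjectRecord("h1", Group.HC, 40.0, "F"),
            SubjectRecord("m1", Group.MS, 45.0, "M", edss=2.5, msfc=-0.7,
                          nhpt_s=24.5, pasat=41.0),
        ]
        path = tmp_path / "cohort.csv"
        write_cohort(records, path)
        back = read_cohort(path)
        assert back == records

    def test_paper_scale_cohort_from_simulator(self, tmp_path, rng):
        from fingertap.simulate import reference_config, simulate_subjects

        config = reference_config(n_hc=80, n_ms=40)
        subjects = simulate_subjects(config, rng)
        path = tmp_path / "cohort.csv"
        write_cohort([s.record for s in subjects], path)
        records = read_cohort(path)
        assert len(records) == 120
        edss = sorted(r.edss for r in records if r.group is Group.MS)
        assert len(edss) == 40
        median = (edss[19] + edss[20]) / 2
        # configured EDSS table has median 2
        assert 1.0 <= median <= 3.0
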