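"""Goal setting, weekly evaluation, feedback, adherence, and the journey
state machine."""

import dataclasses
import datetime as dt
import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from heartcoach import (
    BehaviorId,
    BehaviorJourney,
    DiaryEntry,
    Effort,
    EventType,
    IllegalTransitionError,
    JourneyEvent,
    JourneyState,
    MinutesBand,
    Outcome,
    ValidationError,
    WeekEvaluation,
    detect_struggle,
    evaluate_week,
    place_in_matrix,
    replay_events,
    schedule_followup,
    select_feedback,
    set_goal,
    simulate_cohort,
    step,
    update_adherence,
)
from heartcoach.coaching import legal_events
from heartcoach.simulate import CohortParams

PA = BehaviorId.PHYSICAL_ACTIVITY
SALT = BehaviorId.LOW_SALT_DIET
MED = BehaviorId.MEDICATION_INTAKE
MONDAY = dt.date(2012, 3, 5)

A, M = Outcome.ACHIEVED, Outcome.MISSED


def _pa_entry(day_offset, band, effort=Effort.JUST_RIGHT):
    return DiaryEntry("p1", PA, MONDAY + dt.timedelta(days=day_offset),
                      minutes_band=band, effort=effort)


class TestSetGoal:
    def test_example_activity_goal(self):
        goal = set_goal(PA, MONDAY, days=3, band=MinutesBand.MIN_15_30)
        assert goal.planned_days == 3
        assert goal.week_end == MONDAY + dt.timedelta(days=6)

    def test_one_gram_sodium_goal(self):
        goal = set_goal(SALT, MONDAY, sodium_target=1)
        assert goal.sodium_target_g == 1

    @pytest.mark.parametrize(
        "behavior,kwargs",
        [
            (PA, dict(days=8, band=MinutesBand.MIN_15_30)),
            (PA, dict(days=0, band=MinutesBand.MIN_15_30)),
            (PA, dict(days=3)),
            (SALT, dict(sodium_target=6)),
            (BehaviorId.FLUID_RESTRICTION, dict(max_intake=3.0)),
            (MED, dict(doses=0)),
        ],
    )
    def test_out_of_range_parameters_rejected(self, behavior, kwargs):
        with pytest.raises(ValidationError):
            set_goal(behavior, MONDAY, **kwargs)


class TestEvaluateWeek:
    def test_exact_satisfaction_is_achieved(self):
        goal = set_goal(PA, MONDAY, days=3, band=MinutesBand.MIN_15_30)
        entries = [_pa_entry(i, MinutesBand.MIN_15_30) for i in range(3)]
        ev = evaluate_week(goal, entries)
        assert ev.outcome is A
        assert ev.feedback_id == "congratulate"

    def test_fewer_shorter_harder_week_is_missed(self):
        goal = set_goal(PA, MONDAY, days=5, band=MinutesBand.MIN_30_45)
        entries = [_pa_entry(i, MinutesBand.MIN_15_30, Effort.TOO_HARD) for i in range(3)]
        ev = evaluate_week(goal, entries)
        assert ev.outcome is M
        assert ev.dominant_effort is Effort.TOO_HARD
        assert ev.feedback_id == "reduce_goal"

    def test_days_above_band_count_toward_goal(self):
        goal = set_goal(PA, MONDAY, days=2, band=MinutesBand.MIN_15_30)
        entries = [_pa_entry(0, MinutesBand.MIN_45_60), _pa_entry(3, MinutesBand.MIN_30_45)]
        assert evaluate_week(goal, entries).outcome is A

    def test_salt_week_needs_target_met_every_day(self):
        goal = set_goal(SALT, MONDAY, sodium_target=2)
        met = [DiaryEntry("p1", SALT, MONDAY + dt.timedelta(days=i), met_target=True)
               for i in range(7)]
        assert evaluate_week(goal, met).outcome is A
        assert evaluate_week(goal, met[:6]).outcome is M  # a missing day counts as unmet

    def test_medication_week_requires_exact_doses_daily(self):
        goal = set_goal(MED, MONDAY, doses=2)
        entries = [DiaryEntry("p1", MED, MONDAY + dt.timedelta(days=i), doses_taken=2)
                   for i in range(7)]
        assert evaluate_week(goal, entries).outcome is A
        off = entries[:6] + [dataclasses.replace(entries[6], doses_taken=1)]
        assert evaluate_week(goal, off).outcome is M

    def test_entry_outside_window_rejected(self):
        goal = set_goal(PA, MONDAY, days=1, band=MinutesBand.LE_15)
        with pytest.raises(ValidationError, match="outside goal week"):
            evaluate_week(goal, [_pa_entry(7, MinutesBand.LE_15)])

    def test_duplicate_day_rejected(self):
        goal = set_goal(PA, MONDAY, days=1, band=MinutesBand.LE_15)
        with pytest.raises(ValidationError, match="duplicate"):
            evaluate_week(goal, [_pa_entry(0, MinutesBand.LE_15)] * 2)

    def test_random_weeks_match_day_counting_oracle(self):
        rng = random.Random(424242)
        bands = list(MinutesBand)
        efforts = list(Effort)
        for _ in range(300):
            days = rng.randint(1, 7)
            band = rng.choice(bands)
            goal = set_goal(PA, MONDAY, days=days, band=band)
            active = rng.sample(range(7), rng.randint(0, 7))
            entries = [_pa_entry(d, rng.choice(bands), rng.choice(efforts)) for d in active]
            ev = evaluate_week(goal, entries)
            on_target = sum(1 for e in entries if e.minutes_band >= band)
            assert ev.days_achieved == len(entries)
            assert ev.days_on_target_band == on_target
            assert (ev.outcome is A) == (on_target >= days)


class TestSelectFeedback:
    def _eval(self, outcome, days_achieved, on_target, effort, planned_days=5):
        goal = set_goal(PA, MONDAY, days=planned_days, band=MinutesBand.MIN_15_30)
        return WeekEvaluation(1, goal, days_achieved, on_target, effort, outcome, "")

    def test_table_is_total_over_all_keys(self):
        """Every (outcome, fewer-days, band-shortfall, effort) combination maps
        to a message."""
        known = {"reduce_goal", "encourage_retry", "encourage_retry_or_raise",
                 "congratulate", "consider_raising"}
        for outcome, fewer, shorter, effort in itertools.product(
            (A, M), (False, True), (False, True), (*Effort, None)
        ):
            days_achieved = 3 if fewer else 5
            on_target = days_achieved - 1 if shorter else days_achieved
            ev = self._eval(outcome, days_achieved, on_target, effort)
            assert select_feedback(ev) in known

    def test_spec_examples(self):
        assert select_feedback(self._eval(M, 3, 2, Effort.TOO_HARD)) == "reduce_goal"
        assert select_feedback(self._eval(A, 5, 5, Effort.JUST_RIGHT)) == "congratulate"
        assert select_feedback(self._eval(A, 5, 5, Effort.TOO_EASY)) == "consider_raising"
        assert select_feedback(self._eval(M, 3, 3, Effort.TOO_EASY)) == "encourage_retry_or_raise"
        assert select_feedback(self._eval(M, 5, 4, Effort.JUST_RIGHT)) == "encourage_retry"

    def test_effort_ties_resolve_toward_harder(self):
        goal = set_goal(PA, MONDAY, days=2, band=MinutesBand.MIN_15_30)
        entries = [_pa_entry(0, MinutesBand.MIN_15_30, Effort.TOO_EASY),
                   _pa_entry(1, MinutesBand.MIN_15_30, Effort.TOO_HARD)]
        assert evaluate_week(goal, entries).dominant_effort is Effort.TOO_HARD


class TestAdherenceDetector:
    @pytest.mark.parametrize(
        "history,expected",
        [([A, A], True), ([A, M, A], False), ([], False), ([A], False),
         ([M, M, A, A], True), ([A, A, M], False)],
    )
    def test_two_consecutive_weeks_rule(self, history, expected):
        assert update_adherence(history) is expected

    @settings(max_examples=1000, derandomize=True)
    @given(st.lists(st.sampled_from([A, M]), max_size=30))
    def test_equals_sliding_window_oracle(self, history):
        windows = [history[i:i + 2] for i in range(len(history) - 1)]
        oracle = bool(windows) and windows[-1] == [A, A]
        assert update_adherence(history) is oracle


class TestStruggleDetector:
    def test_three_consecutive_missed_weeks_alert(self):
        alert = detect_struggle([M, M, M], "p1", PA)
        assert alert is not None and alert.trigger_week == 3

    @pytest.mark.parametrize("history", [[M, A, M, M], [A] * 5, [M, M], []])
    def test_broken_or_short_streaks_do_not_alert(self, history):
        assert detect_struggle(history, "p1", PA) is None

    def test_one_alert_per_streak(self):
        assert detect_struggle([M, M, M, M], "p1", PA) is None
        assert detect_struggle([M, M, M, A, M, M, M], "p1", PA) is not None


class TestFollowupScheduling:
    def test_two_months_after_stopping(self):
        stop = dt.date(2012, 6, 9)  # study day 100
        assert schedule_followup(stop) == stop + dt.timedelta(days=60)

    def test_recurring_while_maintained(self):
        first = schedule_followup(dt.date(2012, 6, 9))
        assert schedule_followup(first) == first + dt.timedelta(days=60)


# --------------------------------------------------------------------------
# State machine


def _journey(state):
    placement = place_in_matrix(PA, False, True)
    journey = BehaviorJourney("p1", PA, state, placement)
    journey.state_log.append((MONDAY, state))
    return journey


def _event(etype, payload=None, behavior=PA.value, date=MONDAY):
    return JourneyEvent("p1", date, behavior, etype, payload or {})


_PAYLOADS = {
    EventType.IC_RATING: {"importance": 8, "confidence": 8},
    EventType.EDUCATION_VIEWED: {"content_id": "video_physical_activity"},
    EventType.GOAL_SET: {"days": 3, "band": "min_15_30"},
    EventType.DIARY_ENTRY: {"minutes_band": "min_15_30", "effort": "just_right"},
    EventType.CONTINUE_CHOICE: {"continue": True},
    EventType.FOLLOWUP_RESPONSE: {"answer": "maintained"},
    EventType.NON_START_REASON: {"reason": "unknown"},
}


class TestStateMachine:
    def test_goal_set_while_adherent_at_assessment_is_illegal(self, catalog):
        journey = _journey(JourneyState.ADHERENT_AT_ASSESSMENT)
        with pytest.raises(IllegalTransitionError, match="goal_set"):
            step(journey, _event(EventType.GOAL_SET, _PAYLOADS[EventType.GOAL_SET]),
                 catalog=catalog)

    def test_every_non_graph_pair_is_rejected(self, catalog, config):
        """Exhaustively: any event not on a state's outgoing edges raises."""
        passive = {EventType.EDUCATION_VIEWED, EventType.STUDY_END,
                   EventType.QUESTIONNAIRE_RESPONSE}
        for state in JourneyState:
            allowed = legal_events(state)
            for etype in EventType:
                if etype in allowed or etype in passive:
                    continue
                journey = _journey(state)
                with pytest.raises(IllegalTransitionError) as exc:
                    journey.apply(_event(etype, _PAYLOADS.get(etype)), config, catalog)
                assert state.value in str(exc.value)
                assert etype.value in str(exc.value)

    def test_second_consecutive_achieved_week_yields_adherent(self, catalog, config):
        journey = _journey(JourneyState.IC_ASSESSED)
        day = MONDAY
        for _ in range(2):
            journey.apply(_event(EventType.GOAL_SET, _PAYLOADS[EventType.GOAL_SET], date=day),
                          config, catalog)
            for j in range(3):
                journey.apply(
                    _event(EventType.DIARY_ENTRY, _PAYLOADS[EventType.DIARY_ENTRY],
                           date=day + dt.timedelta(days=j)),
                    config, catalog,
                )
            day += dt.timedelta(days=7)
        state = journey.apply(
            _event(EventType.CONTINUE_CHOICE, {"continue": False}, date=day), config, catalog
        )
        assert JourneyState.ADHERENT in journey.states_entered()
        assert state is JourneyState.STOPPED_AFTER_ADHERENT
        assert journey.next_followup == day + dt.timedelta(days=60)

    def test_followup_maintained_remains_stopped(self, catalog, config):
        journey = _journey(JourneyState.STOPPED_AFTER_ADHERENT)
        state = journey.apply(
            _event(EventType.FOLLOWUP_RESPONSE, {"answer": "maintained"}), config, catalog
        )
        assert state is JourneyState.FOLLOWUP_MAINTAINED
        state = journey.apply(
            _event(EventType.FOLLOWUP_RESPONSE, {"answer": "relapsed_retry"},
                   date=MONDAY + dt.timedelta(days=60)),
            config, catalog,
        )
        assert state is JourneyState.RELAPSED_RECOACHING

    def test_goal_while_week_open_rejected(self, catalog, config):
        journey = _journey(JourneyState.IC_ASSESSED)
        journey.apply(_event(EventType.GOAL_SET, _PAYLOADS[EventType.GOAL_SET]), config, catalog)
        with pytest.raises(ValidationError, match="still open"):
            journey.apply(
                _event(EventType.GOAL_SET, _PAYLOADS[EventType.GOAL_SET],
                       date=MONDAY + dt.timedelta(days=3)),
                config, catalog,
            )

    def test_education_gate_blocks_goal_until_viewed(self, catalog, config):
        placement = place_in_matrix(PA, False, False)  # area 1
        journey = BehaviorJourney(
            "p1", PA, JourneyState.IC_ASSESSED, placement,
            required_education=("video_physical_activity",),
        )
        journey.state_log.append((MONDAY, JourneyState.IC_ASSESSED))
        with pytest.raises(IllegalTransitionError, match="education"):
            journey.apply(_event(EventType.GOAL_SET, _PAYLOADS[EventType.GOAL_SET]),
                          config, catalog)
        journey.apply(_event(EventType.EDUCATION_VIEWED,
                             {"content_id": "video_physical_activity"}), config, catalog)
        state = journey.apply(_event(EventType.GOAL_SET, _PAYLOADS[EventType.GOAL_SET]),
                              config, catalog)
        assert state is JourneyState.COACHING

    def test_diary_outside_any_week_rejected(self, catalog, config):
        journey = _journey(JourneyState.COACHING)
        with pytest.raises(ValidationError, match="outside any coaching week"):
            journey.apply(_event(EventType.DIARY_ENTRY, _PAYLOADS[EventType.DIARY_ENTRY]),
                          config, catalog)

    def test_weeks_partition_days(self, catalog, config):
        """No diary entry is counted in two weekly evaluations."""
        journey = _journey(JourneyState.IC_ASSESSED)
        day = MONDAY
        total_entries = 0
        for _ in range(3):
            journey.apply(_event(EventType.GOAL_SET, _PAYLOADS[EventType.GOAL_SET], date=day),
                          config, catalog)
            for j in range(2):
                journey.apply(
                    _event(EventType.DIARY_ENTRY, _PAYLOADS[EventType.DIARY_ENTRY],
                           date=day + dt.timedelta(days=j)),
                    config, catalog,
                )
                total_entries += 1
            day += dt.timedelta(days=7)
        journey.apply(_event(EventType.STUDY_END, behavior="global", date=day), config, catalog)
        assert sum(e.days_achieved for e in journey.evaluations) == total_entries


class TestReplay:
    def test_replay_is_deterministic(self):
        events = simulate_cohort(CohortParams(n_patients=40, horizon_days=120, seed=11))
        r1 = replay_events(events)
        r2 = replay_events(events)
        assert {k: j.state for k, j in r1.journeys.items()} == {
            k: j.state for k, j in r2.journeys.items()
        }
        f1 = [e.feedback_id for j in r1.journeys.values() for e in j.evaluations]
        f2 = [e.feedback_id for j in r2.journeys.values() for e in j.evaluations]
        assert f1 == f2
        assert [a for a in r1.alerts] == [a for a in r2.alerts]

    def test_behaviors_progress_independently(self, fixture_replay):
        """One patient can hold different states for different behaviors."""
        states = {
            behavior: journey.state
            for (pid, behavior), journey in fixture_replay.journeys.items()
            if pid == "P040"
        }
        assert states[PA] is JourneyState.NEVER_STARTED_COACHING
        assert states[BehaviorId.FLUID_RESTRICTION] is JourneyState.NEVER_STARTED_COACHING
        assert states[SALT] is JourneyState.NONADHERENT
        assert states[MED] is JourneyState.ADHERENT_AT_ASSESSMENT

    def test_every_journey_state_is_reachable(self, fixture_replay):
        reached = set()
        for journey in fixture_replay.journeys.values():
            reached |= journey.states_entered()
        assert reached == set(JourneyState)
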