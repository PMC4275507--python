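"""Synthetic patient cohorts: a stochastic event-log simulator driven by
transition probabilities, and a deterministic 123-patient study fixture
whose replay reproduces the published journey tables.

The fixture is hand-scripted data, not sampled: every patient-behavior
journey is written out as an engine-legal event sequence whose replay lands
in exactly the scripted terminal state.  Weekly outcome sequences for
adherent patients end with two consecutive achieved weeks; starters who
never became adherent get sequences without two consecutive achieved weeks
and are censored in coaching at study end.  Study-end censoring is an
explicit end-of-study event at a fixed 210-day horizon, which also stages
which stopped patients have a 60-day follow-up due before the study closes.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assessment import ItemBank, default_item_bank
from .coaching import Goal, ReplayResult, goal_payload, set_goal
from .config import DEFAULT_CONFIG
from .model import (
    BehaviorId,
    COACHABLE_BEHAVIORS,
    EventType,
    FollowupAnswer,
    JourneyEvent,
    JourneyState,
    MinutesBand,
    NON_START_REASONS,
    Outcome,
    ValidationError,
)

#: First study day of the synthetic cohort calendar.
STUDY_START = dt.date(2012, 3, 1)
#: Fixture horizon in days (~7 months): long enough for every scripted
#: journey, short enough that late stoppers have no follow-up due.
FIXTURE_HORIZON_DAYS = 210

N_FIXTURE_PATIENTS = 123


def _day(n: int) -> dt.date:
    return STUDY_START + dt.timedelta(days=int(n))


# ==========================================================================
# Event-emitting helpers


class _Log:
    """Per-patient event collector; sorts by date (stable) at the end."""

    def __init__(self, patient_id: str) -> None:
        self.patient_id = patient_id
        self.events: list[JourneyEvent] = []

    def add(self, day: int, behavior: str, etype: EventType, payload: dict | None = None) -> None:
        self.events.append(
            JourneyEvent(self.patient_id, _day(day), behavior, etype, payload or {})
        )

    def goal(self, day: int, goal: Goal) -> None:
        self.add(day, goal.behavior.value, EventType.GOAL_SET, goal_payload(goal))

    def diary(self, day: int, behavior: BehaviorId, payload: dict) -> None:
        self.add(day, behavior.value, EventType.DIARY_ENTRY, payload)

    def sorted_events(self) -> list[JourneyEvent]:
        return sorted(self.events, key=lambda e: e.date)  # stable


def _week_entries(
    log: _Log, behavior: BehaviorId, goal: Goal, start_day: int, achieved: bool,
    n_days: int | None = None,
) -> None:
    """Emit the diary entries of one week.

    Achieved weeks satisfy the goal exactly; missed weeks fall short (one
    short too-hard session for activity, three on-target days for diet and
    fluid goals).  ``n_days`` truncates the entries (censored final week).
    """
    if behavior is BehaviorId.PHYSICAL_ACTIVITY:
        if achieved:
            days = goal.planned_days if n_days is None else min(n_days, goal.planned_days)
            for j in range(days):
                log.diary(start_day + j, behavior, {
                    "minutes_band": goal.planned_band.name.lower(),
                    "effort": "just_right",
                })
        else:
            log.diary(start_day, behavior, {"minutes_band": "le_15", "effort": "too_hard"})
    elif behavior is BehaviorId.MEDICATION_INTAKE:
        days = 7 if n_days is None else n_days
        if not achieved and n_days is None:
            days = 4
        for j in range(days):
            log.diary(start_day + j, behavior, {"doses_taken": goal.planned_doses})
    else:  # low-salt diet / fluid restriction: met-target flags
        days = (7 if achieved else 3) if n_days is None else n_days
        for j in range(days):
            log.diary(start_day + j, behavior, {"met_target": True})


def _coached_journey(
    log: _Log,
    behavior: BehaviorId,
    goal_params: dict,
    start_day: int,
    choices: Sequence[bool],
    followup_script: str | None,
    horizon_day: int,
    followup_interval: int = 60,
) -> None:
    """Script one coached journey that reaches adherence at least once.

    Each adherence cycle is two consecutive achieved weeks followed by a
    continue/stop prompt; ``choices`` gives the prompt answers.  If every
    answer is ``True`` the patient coaches until study end (one more
    achieved week plus a censored partial week).  After a stop,
    ``followup_script`` is one of ``maintained`` (answer maintained at every
    due follow-up), ``relapse_stop``, or ``relapse_retry`` (re-enter
    coaching, never adherent again).
    """
    day = start_day
    for choice in choices:
        goal = set_goal(behavior, _day(day), **goal_params)
        log.goal(day, goal)
        _week_entries(log, behavior, goal, day, achieved=True)
        goal2 = set_goal(behavior, _day(day + 7), **goal_params)
        log.goal(day + 7, goal2)
        _week_entries(log, behavior, goal2, day + 7, achieved=True)
        prompt_day = day + 14
        log.add(prompt_day, behavior.value, EventType.CONTINUE_CHOICE, {"continue": choice})
        day = prompt_day
        if not choice:
            _followups(log, behavior, goal_params, day, followup_script, horizon_day,
                       followup_interval)
            return
    # all prompts answered "continue": coach until the study closes
    goal = set_goal(behavior, _day(day), **goal_params)
    log.goal(day, goal)
    _week_entries(log, behavior, goal, day, achieved=True)
    tail_day = day + 7
    if tail_day < horizon_day:
        goal = set_goal(behavior, _day(tail_day), **goal_params)
        log.goal(tail_day, goal)
        _week_entries(log, behavior, goal, tail_day, achieved=True,
                      n_days=min(horizon_day - tail_day - 1, 4))


def _followups(
    log: _Log,
    behavior: BehaviorId,
    goal_params: dict,
    stop_day: int,
    script: str | None,
    horizon_day: int,
    interval: int,
) -> None:
    fu_day = stop_day + interval
    if fu_day > horizon_day or script is None:
        return
    if script == "maintained":
        while fu_day <= horizon_day:
            log.add(fu_day, behavior.value, EventType.FOLLOWUP_RESPONSE,
                    {"answer": FollowupAnswer.MAINTAINED.value})
            fu_day += interval
    elif script == "relapse_stop":
        log.add(fu_day, behavior.value, EventType.FOLLOWUP_RESPONSE,
                {"answer": FollowupAnswer.RELAPSED_STOP.value})
    elif script == "relapse_retry":
        log.add(fu_day, behavior.value, EventType.FOLLOWUP_RESPONSE,
                {"answer": FollowupAnswer.RELAPSED_RETRY.value})
        _censored_coaching(log, behavior, goal_params, fu_day + 1, n_missed=3)
    else:  # pragma: no cover - internal scripting error
        raise ValueError(f"unknown follow-up script {script!r}")


def _censored_coaching(
    log: _Log, behavior: BehaviorId, goal_params: dict, start_day: int, n_missed: int = 3
) -> None:
    """Weeks that never reach two consecutive achieved; stays in coaching."""
    day = start_day
    for _ in range(n_missed):
        goal = set_goal(behavior, _day(day), **goal_params)
        log.goal(day, goal)
        _week_entries(log, behavior, goal, day, achieved=False)
        day += 7


# ==========================================================================
# The deterministic 123-patient study fixture
#
# Patient numbers (1-based) are grouped per behavior so that replay
# reproduces the published transition, follow-up, goal, and non-start
# tables.  Sets overlap across behaviors; journeys are independent.

_R = lambda lo, hi: frozenset(range(lo, hi + 1))  # noqa: E731 - inclusive range

FIXTURE_ROLES: dict[BehaviorId, dict[str, frozenset[int]]] = {
    BehaviorId.PHYSICAL_ACTIVITY: {
        "nonadherent": _R(1, 50),
        "starters": _R(1, 35),
        "adherent": _R(1, 28),
        "immediate_stop": _R(1, 11),
        "fu_maintained": _R(1, 8),
        "fu_retry": frozenset({9, 10, 11}),
        "fu_relapse_stop": frozenset({13}),
        "stop_second_cycle": frozenset({12, 13}),
        "stop_late": _R(14, 20),
        "until_end": _R(21, 28),
        "censored": _R(29, 35),
        "nonstart": _R(36, 50),
        "ic_only_nonstart": _R(45, 50),
    },
    BehaviorId.LOW_SALT_DIET: {
        "nonadherent": _R(30, 85),
        "starters": _R(30, 35) | _R(43, 50) | _R(53, 85),
        "adherent": _R(30, 35) | _R(43, 50) | _R(53, 74),
        "immediate_stop": _R(30, 35) | _R(43, 50) | _R(53, 61),
        "fu_maintained": _R(30, 35) | _R(43, 50),
        "fu_relapse_stop": frozenset({53}),
        "late_start": _R(54, 61),
        "stop_late": _R(62, 67),
        "until_end": _R(68, 74),
        "censored": _R(75, 85),
        "nonstart": _R(36, 42) | frozenset({51, 52}),
        "ic_only_nonstart": frozenset({51}),
    },
    BehaviorId.FLUID_RESTRICTION: {
        "nonadherent": frozenset({10, 11, 12, 13, 40, 41}),
        "starters": frozenset({10, 11, 12, 13}),
        "adherent": frozenset({10, 11}),
        "immediate_stop": frozenset({10}),
        "fu_maintained": frozenset({10}),
        "until_end": frozenset({11}),
        "censored": frozenset({12, 13}),
        "nonstart": frozenset({40, 41}),
        "ic_only_nonstart": frozenset({40}),
    },
    BehaviorId.MEDICATION_INTAKE: {
        "nonadherent": frozenset({44, 45, 70, 71, 72, 73}),
        "starters": frozenset({70, 71, 72, 73}),
        "adherent": frozenset({70, 71, 72, 73}),
        "immediate_stop": frozenset({70}),
        "fu_maintained": frozenset({70, 71}),
        "stop_second_cycle": frozenset({71}),
        "until_end": frozenset({72, 73}),
        "censored": frozenset(),
        "nonstart": frozenset({44, 45}),
        "ic_only_nonstart": frozenset({45}),
    },
}

#: Reason records for not proceeding to goal setting: 20 records over 17
#: distinct patients (some patients gave a reason for more than one
#: behavior).  Tally: death 1, too busy 3, impairment 5, motivation 1,
#: system 4, goal setting 1, unknown 1, technical 4.
FIXTURE_NONSTART_REASONS: tuple[tuple[int, BehaviorId, str], ...] = (
    (36, BehaviorId.PHYSICAL_ACTIVITY, "death"),
    (37, BehaviorId.PHYSICAL_ACTIVITY, "patient_too_busy"),
    (38, BehaviorId.PHYSICAL_ACTIVITY, "patient_too_busy"),
    (39, BehaviorId.PHYSICAL_ACTIVITY, "patient_too_busy"),
    (40, BehaviorId.PHYSICAL_ACTIVITY, "severe_impairment"),
    (41, BehaviorId.PHYSICAL_ACTIVITY, "severe_impairment"),
    (42, BehaviorId.PHYSICAL_ACTIVITY, "severe_impairment"),
    (43, BehaviorId.PHYSICAL_ACTIVITY, "severe_impairment"),
    (44, BehaviorId.PHYSICAL_ACTIVITY, "severe_impairment"),
    (45, BehaviorId.PHYSICAL_ACTIVITY, "lack_of_motivation"),
    (46, BehaviorId.PHYSICAL_ACTIVITY, "difficulties_understanding_system"),
    (47, BehaviorId.PHYSICAL_ACTIVITY, "difficulties_understanding_system"),
    (48, BehaviorId.PHYSICAL_ACTIVITY, "difficulties_understanding_system"),
    (49, BehaviorId.PHYSICAL_ACTIVITY, "difficulties_understanding_system"),
    (50, BehaviorId.PHYSICAL_ACTIVITY, "difficulties_understanding_goal_setting"),
    (51, BehaviorId.LOW_SALT_DIET, "unknown"),
    (52, BehaviorId.LOW_SALT_DIET, "technical_problems"),
    (40, BehaviorId.FLUID_RESTRICTION, "technical_problems"),
    (41, BehaviorId.FLUID_RESTRICTION, "technical_problems"),
    (44, BehaviorId.MEDICATION_INTAKE, "technical_problems"),
)

#: Physical-activity goals reached when becoming adherent, per patient, in
#: patient order over the 28 adherent patients.
_B = MinutesBand
FIXTURE_ACTIVITY_GOALS: dict[int, tuple[int, MinutesBand]] = {
    1: (2, _B.MIN_15_30),
    2: (3, _B.MIN_15_30), 3: (3, _B.MIN_15_30), 4: (3, _B.MIN_15_30),
    5: (3, _B.MIN_15_30), 6: (3, _B.MIN_15_30),
    7: (4, _B.MIN_15_30), 8: (4, _B.MIN_15_30),
    9: (5, _B.MIN_15_30), 10: (5, _B.MIN_15_30), 11: (5, _B.MIN_15_30),
    12: (6, _B.MIN_15_30), 13: (6, _B.MIN_15_30),
    14: (7, _B.MIN_15_30), 15: (7, _B.MIN_15_30),
    16: (7, _B.MIN_15_30), 17: (7, _B.MIN_15_30),
    18: (5, _B.MIN_30_45), 19: (5, _B.MIN_30_45),
    20: (6, _B.MIN_30_45),
    21: (7, _B.MIN_30_45),
    22: (2, _B.LE_15),
    23: (3, _B.LE_15), 24: (3, _B.LE_15), 25: (3, _B.LE_15), 26: (3, _B.LE_15),
    27: (4, _B.LE_15),
    28: (7, _B.LE_15),
}

#: Low-salt sodium goals (g/day) reached when becoming adherent: 12 patients
#: at 1 g, 8 at 2 g, 7 at 3 g, 8 at 4 g, 1 at >=5 g, assigned in patient
#: order over the 36 adherent patients.
def _salt_goal_map() -> dict[int, int]:
    adherent = sorted(FIXTURE_ROLES[BehaviorId.LOW_SALT_DIET]["adherent"])
    targets = [1] * 12 + [2] * 8 + [3] * 7 + [4] * 8 + [5] * 1
    return dict(zip(adherent, targets))


FIXTURE_SALT_GOALS: dict[int, int] = _salt_goal_map()


def _patient_id(number: int) -> str:
    return f"P{number:03d}"


def _fixture_questionnaire(
    log: _Log, number: int, bank: ItemBank, nonadherent_for: set[BehaviorId]
) -> None:
    """Day-0 answers to all 27 items.

    Nonadherent behaviors get one behavior item below the cutoff; patients
    with even numbers additionally answer one knowledge item of each
    nonadherent behavior with "I don't know" (area 1: education gates
    coaching); odd numbers know but do not do (area 3).
    """
    knowledge_gap = number % 2 == 0
    for item in bank.items:
        behavior = item.behavior
        is_nonadherent = any(b.value == behavior for b in nonadherent_for)
        if item.kind == "behavior":
            low = is_nonadherent and item.item_id.endswith("_1")
            answer = 1 if low else 4
        else:
            dont_know = knowledge_gap and is_nonadherent and item.item_id.endswith("_1")
            answer = item.dont_know_index if dont_know else item.correct_index
        log.add(0, "global", EventType.QUESTIONNAIRE_RESPONSE,
                {"item_id": item.item_id, "answer_index": int(answer)})


_FIXTURE_GOAL_PARAMS = {
    BehaviorId.FLUID_RESTRICTION: {10: {"max_intake": 1.5}, 11: {"max_intake": 2.0},
                                   12: {"max_intake": 1.5}, 13: {"max_intake": 2.0}},
    BehaviorId.MEDICATION_INTAKE: {},  # everyone plans 2 doses/day
}


def _fixture_goal_params(behavior: BehaviorId, number: int) -> dict:
    if behavior is BehaviorId.PHYSICAL_ACTIVITY:
        if number in FIXTURE_ACTIVITY_GOALS:
            days, band = FIXTURE_ACTIVITY_GOALS[number]
            return {"days": days, "band": band}
        return {"days": 3, "band": MinutesBand.MIN_15_30}
    if behavior is BehaviorId.LOW_SALT_DIET:
        return {"sodium_target": FIXTURE_SALT_GOALS.get(number, 2)}
    if behavior is BehaviorId.FLUID_RESTRICTION:
        return _FIXTURE_GOAL_PARAMS[behavior].get(number, {"max_intake": 1.5})
    return {"doses": 2}


def _fixture_behavior_events(
    log: _Log, number: int, behavior: BehaviorId, roles: Mapping[str, frozenset[int]],
) -> None:
    if number not in roles["nonadherent"]:
        return  # adherent at assessment: no coaching events
    horizon = FIXTURE_HORIZON_DAYS
    goal_params = _fixture_goal_params(behavior, number)
    is_starter = number in roles["starters"]
    if not is_starter:
        if number in roles.get("ic_only_nonstart", frozenset()):
            log.add(2, behavior.value, EventType.IC_RATING, {"importance": 8, "confidence": 8})
        for pnum, pbehavior, reason in FIXTURE_NONSTART_REASONS:
            if pnum == number and pbehavior is behavior:
                log.add(5, behavior.value, EventType.NON_START_REASON, {"reason": reason})
        return

    log.add(2, behavior.value, EventType.IC_RATING, {"importance": 8, "confidence": 8})
    if number % 2 == 0:  # area 1: required education before coaching
        log.add(2, behavior.value, EventType.EDUCATION_VIEWED,
                {"content_id": f"video_{behavior.value}"})

    start_day = 160 if number in roles.get("late_start", frozenset()) else 3
    if number in roles.get("censored", frozenset()):
        _censored_coaching(log, behavior, goal_params, start_day)
        return
    # choices: one False for immediate stop; [True, False] for a stop after a
    # second cycle; ten Trues then False for late stoppers (stop day 157,
    # follow-up never due); all-True for until-study-end patients.
    if number in roles.get("immediate_stop", frozenset()):
        choices: list[bool] = [False]
    elif number in roles.get("stop_second_cycle", frozenset()):
        choices = [True, False]
    elif number in roles.get("stop_late", frozenset()):
        choices = [True] * 10 + [False]
    else:  # until end: prompts every 14 days from day 17 through day 199
        choices = [True] * 14
    if number in roles.get("fu_retry", frozenset()):
        script = "relapse_retry"
    elif number in roles.get("fu_relapse_stop", frozenset()):
        script = "relapse_stop"
    else:
        script = "maintained"  # any due follow-up defaults to maintained
    _coached_journey(log, behavior, goal_params, start_day, choices, script, horizon)


def fixture_study_cohort(bank: ItemBank | None = None) -> list[JourneyEvent]:
    """The deterministic 123-patient fixture event log.

    Replay through the engine reproduces the published journey tables:
    per-behavior transition counts (nonadherent 50/56/6/6, starters
    35/47/4/4, adherent 28/36/2/4, immediate stop 11/23/1/1, continued
    17/13/1/3, stopped later 9/6/0/1, until study end 8/7/1/2), the
    follow-up tallies, the reached-goal distributions, and the 20 non-start
    reason records covering 17 patients.
    """
    bank = bank if bank is not None else default_item_bank()
    events: list[JourneyEvent] = []
    for number in range(1, N_FIXTURE_PATIENTS + 1):
        log = _Log(_patient_id(number))
        nonadherent_for = {
            behavior
            for behavior, roles in FIXTURE_ROLES.items()
            if number in roles["nonadherent"]
        }
        _fixture_questionnaire(log, number, bank, nonadherent_for)
        for behavior in COACHABLE_BEHAVIORS:
            _fixture_behavior_events(log, number, behavior, FIXTURE_ROLES[behavior])
        log.add(FIXTURE_HORIZON_DAYS, "global", EventType.STUDY_END)
        events.extend(log.sorted_events())
    return events


def fixture_demographics() -> pd.DataFrame:
    """Per-patient demographic header fields for cohort reports.

    Deterministic values whose summaries match the study population: 123
    patients, 97 men (79%), mean age 66.2 years with 49 patients over 70,
    and 81 patients (66%) in NYHA class III.
    """
    rows = []
    old_ages = [74] * 25 + [72] + [71] * 23          # 49 patients aged >70
    young_ages = [62] * 74                            # sum of all ages = 8143
    ages = old_ages + young_ages
    for number in range(1, N_FIXTURE_PATIENTS + 1):
        rows.append(
            {
                "patient_id": _patient_id(number),
                "sex": "male" if number <= 97 else "female",
                "age_years": ages[number - 1],
                "nyha": 3 if number <= 81 else 2,
            }
        )
    return pd.DataFrame(rows)


# ==========================================================================
# Stochastic cohort simulation


@dataclass(frozen=True)
class TransitionProbs:
    """Per-behavior journey transition probabilities."""

    p_nonadherent: float = 0.4
    p_start_coaching: float = 0.7
    p_weekly_achieve: float = 0.8
    p_continue_after_adherent: float = 0.6
    p_stop_later: float = 0.3
    p_relapse_at_followup: float = 0.3
    p_retry_after_relapse: float = 0.75

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{f.name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class CohortParams:
    n_patients: int
    horizon_days: int = 120
    seed: int = 0
    behaviors: Mapping[BehaviorId, TransitionProbs] = field(
        default_factory=lambda: {b: TransitionProbs() for b in COACHABLE_BEHAVIORS}
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.horizon_days < 21:
            raise ValidationError("horizon_days must allow at least two coaching weeks")


def study_calibrated_params(n_patients: int = N_FIXTURE_PATIENTS, seed: int = 0) -> CohortParams:
    """Transition probabilities calibrated to the observed study shares.

    Nonadherence, coaching-start, and first continue/stop shares are the
    published per-behavior fractions; the weekly achievement probability is
    set so that roughly 80% of starters reach two consecutive achieved
    weeks early, matching the adherent shares for the two common behaviors.
    """
    shares = {
        BehaviorId.PHYSICAL_ACTIVITY: TransitionProbs(
            p_nonadherent=50 / 123, p_start_coaching=35 / 50, p_weekly_achieve=0.8,
            p_continue_after_adherent=17 / 28, p_stop_later=0.3,
            p_relapse_at_followup=4 / 13, p_retry_after_relapse=3 / 4,
        ),
        BehaviorId.LOW_SALT_DIET: TransitionProbs(
            p_nonadherent=56 / 123, p_start_coaching=47 / 56, p_weekly_achieve=0.8,
            p_continue_after_adherent=13 / 36, p_stop_later=0.3,
            p_relapse_at_followup=1 / 15, p_retry_after_relapse=0.0,
        ),
        BehaviorId.FLUID_RESTRICTION: TransitionProbs(
            p_nonadherent=6 / 123, p_start_coaching=4 / 6, p_weekly_achieve=0.7,
            p_continue_after_adherent=1 / 2, p_stop_later=0.3,
            p_relapse_at_followup=0.0, p_retry_after_relapse=0.0,
        ),
        BehaviorId.MEDICATION_INTAKE: TransitionProbs(
            p_nonadherent=6 / 123, p_start_coaching=4 / 6, p_weekly_achieve=0.9,
            p_continue_after_adherent=3 / 4, p_stop_later=0.3,
            p_relapse_at_followup=0.0, p_retry_after_relapse=0.0,
        ),
    }
    return CohortParams(n_patients=n_patients, horizon_days=210, seed=seed, behaviors=shares)


_SIM_GOALS: dict[BehaviorId, dict] = {
    BehaviorId.PHYSICAL_ACTIVITY: {"days": 3, "band": MinutesBand.MIN_15_30},
    BehaviorId.LOW_SALT_DIET: {"sodium_target": 2},
    BehaviorId.FLUID_RESTRICTION: {"max_intake": 1.5},
    BehaviorId.MEDICATION_INTAKE: {"doses": 2},
}


def _simulate_questionnaire(
    log: _Log, bank: ItemBank, nonadherent: dict[BehaviorId, bool], gap: dict[BehaviorId, bool]
) -> None:
    for item in bank.items:
        behavior = next((b for b in COACHABLE_BEHAVIORS if b.value == item.behavior), None)
        if item.kind == "behavior":
            low = behavior is not None and nonadherent[behavior] and item.item_id.endswith("_1")
            answer = 1 if low else 4
        else:
            dk = (
                behavior is not None
                and nonadherent[behavior]
                and gap[behavior]
                and item.item_id.endswith("_1")
            )
            answer = item.dont_know_index if dk else item.correct_index
        log.add(0, "global", EventType.QUESTIONNAIRE_RESPONSE,
                {"item_id": item.item_id, "answer_index": int(answer)})


def _simulate_behavior(
    log: _Log,
    behavior: BehaviorId,
    probs: TransitionProbs,
    gap: bool,
    horizon: int,
    rng: np.random.Generator,
    interval: int = DEFAULT_CONFIG.followup_interval_days,
) -> None:
    if rng.random() >= probs.p_start_coaching:
        if rng.random() < 0.5:
            log.add(2, behavior.value, EventType.IC_RATING,
                    {"importance": int(rng.integers(0, 11)), "confidence": int(rng.integers(0, 11))})
        reason = NON_START_REASONS[int(rng.integers(0, len(NON_START_REASONS)))]
        log.add(5, behavior.value, EventType.NON_START_REASON, {"reason": reason})
        return
    log.add(2, behavior.value, EventType.IC_RATING,
            {"importance": int(rng.integers(7, 11)), "confidence": int(rng.integers(7, 11))})
    if gap:
        log.add(2, behavior.value, EventType.EDUCATION_VIEWED,
                {"content_id": f"video_{behavior.value}"})
    goal_params = _SIM_GOALS[behavior]
    day = 3
    outcomes: list[bool] = []
    first_prompt = True
    while True:
        # coaching weeks until adherence or horizon
        while day + 7 <= horizon:
            goal = set_goal(behavior, _day(day), **goal_params)
            log.goal(day, goal)
            achieved = bool(rng.random() < probs.p_weekly_achieve)
            _week_entries(log, behavior, goal, day, achieved=achieved)
            outcomes.append(achieved)
            day += 7
            if len(outcomes) >= 2 and outcomes[-1] and outcomes[-2]:
                break
        else:
            return  # horizon reached while coaching
        # adherent: continue/stop prompt
        p_continue = probs.p_continue_after_adherent if first_prompt else 1.0 - probs.p_stop_later
        first_prompt = False
        cont = bool(rng.random() < p_continue)
        log.add(day, behavior.value, EventType.CONTINUE_CHOICE, {"continue": cont})
        outcomes = []
        if cont:
            continue
        # stopped: follow-up questionnaires every `interval` days
        fu_day = day + interval
        while fu_day <= horizon:
            if rng.random() < probs.p_relapse_at_followup:
                if rng.random() < probs.p_retry_after_relapse:
                    log.add(fu_day, behavior.value, EventType.FOLLOWUP_RESPONSE,
                            {"answer": FollowupAnswer.RELAPSED_RETRY.value})
                    day = fu_day + 1
                    break
                log.add(fu_day, behavior.value, EventType.FOLLOWUP_RESPONSE,
                        {"answer": FollowupAnswer.RELAPSED_STOP.value})
                return
            log.add(fu_day, behavior.value, EventType.FOLLOWUP_RESPONSE,
                    {"answer": FollowupAnswer.MAINTAINED.value})
            fu_day += interval
        else:
            return  # horizon reached while stopped
        # relapsed and retrying: loop back into coaching


def simulate_cohort(params: CohortParams, bank: ItemBank | None = None) -> list[JourneyEvent]:
    """Sample an engine-legal event log for a synthetic cohort.

    Reproducible for a fixed ``params.seed``; every patient's journey is a
    draw from the journey graph with the configured transition
    probabilities.
    """
    bank = bank if bank is not None else default_item_bank()
    rng = np.random.default_rng(params.seed)
    events: list[JourneyEvent] = []
    for i in range(params.n_patients):
        log = _Log(f"S{i + 1:05d}")
        nonadherent = {
            b: bool(rng.random() < params.behaviors[b].p_nonadherent)
            for b in COACHABLE_BEHAVIORS
        }
        gap = {b: bool(rng.random() < 0.5) for b in COACHABLE_BEHAVIORS}
        _simulate_questionnaire(log, bank, nonadherent, gap)
        for behavior in COACHABLE_BEHAVIORS:
            if nonadherent[behavior]:
                _simulate_behavior(
                    log, behavior, params.behaviors[behavior], gap[behavior],
                    params.horizon_days, rng,
                )
        log.add(params.horizon_days, "global", EventType.STUDY_END)
        events.extend(log.sorted_events())
    return events


# ==========================================================================
# Empirical transition frequencies (for parameter recovery checks)


def transition_frequencies(result: ReplayResult) -> dict[BehaviorId, dict[str, tuple[int, int]]]:
    """Observed (numerator, denominator) pairs per transition probability.

    Weekly achievement pools all evaluated weeks; the continue share uses
    each patient's first prompt; relapse/retry pool all follow-up answers.
    """
    out: dict[BehaviorId, dict[str, tuple[int, int]]] = {}
    n_patients = len(result.patient_ids)
    for behavior in COACHABLE_BEHAVIORS:
        journeys = result.journeys_for(behavior)
        nonadherent = [j for j in journeys if JourneyState.NONADHERENT in j.states_entered()]
        starters = [j for j in nonadherent if JourneyState.COACHING in j.states_entered()]
        adherent = [j for j in starters if JourneyState.ADHERENT in j.states_entered()]
        weeks = [e.outcome for j in starters for e in j.evaluations]
        achieved = sum(1 for o in weeks if o is Outcome.ACHIEVED)
        continued = sum(1 for j in adherent if j.continue_choices and j.continue_choices[0])
        answers = [a for j in journeys for a in j.followup_answers]
        relapsed = sum(1 for a in answers if a is not FollowupAnswer.MAINTAINED)
        retried = sum(1 for a in answers if a is FollowupAnswer.RELAPSED_RETRY)
        out[behavior] = {
            "p_nonadherent": (len(nonadherent), n_patients),
            "p_start_coaching": (len(starters), len(nonadherent)),
            "p_weekly_achieve": (achieved, len(weeks)),
            "p_continue_after_adherent": (continued, len(adherent)),
            "p_relapse_at_followup": (relapsed, len(answers)),
            "p_retry_after_relapse": (retried, relapsed),
        }
    return out
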