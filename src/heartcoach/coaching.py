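"""The coaching loop and journey state machine.

Per behavior, a nonadherent patient rates importance and confidence, sets a
personal weekly goal, keeps a daily diary, and receives tailored feedback
when the 7-day week closes.  Reaching the goal for 2 consecutive weeks makes
the patient adherent; the patient then chooses to continue coaching (fresh
goal, and another continue/stop prompt after the next 2 achieved weeks) or
to stop.  Stopped patients receive a relapse follow-up questionnaire every
60 days; relapsed patients may re-enter coaching.  Three consecutive missed
weeks raise an alert for the heart-failure nurse.

Journeys are independent across behaviors: one patient holds one state per
behavior.  Replaying the same event log always yields identical states,
evaluations, feedback ids, and alerts.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .assessment import (
    ImportanceConfidence,
    ItemBank,
    MatrixPlacement,
    QuestionnaireResponse,
    assess_importance_confidence,
    default_item_bank,
    place_in_matrix,
    score_behavior,
    score_knowledge,
)
from .catalog import ContentCatalog, default_catalog
from .config import DEFAULT_CONFIG, ProgramConfig
from .eventlog import iter_patients
from .model import (
    BehaviorId,
    COACHABLE_BEHAVIORS,
    Effort,
    EventType,
    FollowupAnswer,
    IllegalTransitionError,
    JourneyEvent,
    JourneyState,
    MinutesBand,
    Outcome,
    ValidationError,
)

#: Sodium goals in g/day; 5 encodes ">=5".
SODIUM_TARGETS = (1, 2, 3, 4, 5)
#: Fluid-restriction goals in L/day.
FLUID_LIMITS = (1.5, 2.0)


# --------------------------------------------------------------------------
# Goals and diary entries


@dataclass(frozen=True)
class Goal:
    """A personal goal for one 7-day coaching week.

    Exactly the variant fields for ``behavior`` are set: planned days and
    minutes band for physical activity, a sodium target (g/day) for the
    low-salt diet, a maximum intake (L/day) for fluid restriction, and
    planned doses/day for medication intake.
    """

    behavior: BehaviorId
    week_start: dt.date
    planned_days: int | None = None
    planned_band: MinutesBand | None = None
    sodium_target_g: int | None = None
    max_intake_l: float | None = None
    planned_doses: int | None = None

    @property
    def week_end(self) -> dt.date:
        """Last day inside the goal window (inclusive)."""
        return self.week_start + dt.timedelta(days=6)

    @property
    def window_close(self) -> dt.date:
        """First day after the window, when evaluation is due."""
        return self.week_start + dt.timedelta(days=7)


def set_goal(
    behavior: BehaviorId,
    week_start: dt.date,
    *,
    days: int | None = None,
    band: MinutesBand | None = None,
    sodium_target: int | None = None,
    max_intake: float | None = None,
    doses: int | None = None,
) -> Goal:
    """Validate goal parameters and build the active goal for one week."""
    behavior = BehaviorId(behavior)
    if behavior is BehaviorId.PHYSICAL_ACTIVITY:
        if days is None or band is None:
            raise ValidationError("physical activity goal needs days and minutes band")
        if not 1 <= days <= 7:
            raise ValidationError(f"planned days must be in 1..7, got {days}")
        return Goal(behavior, week_start, planned_days=days, planned_band=MinutesBand(band))
    if behavior is BehaviorId.LOW_SALT_DIET:
        if sodium_target not in SODIUM_TARGETS:
            raise ValidationError(f"sodium target must be in {SODIUM_TARGETS}, got {sodium_target}")
        return Goal(behavior, week_start, sodium_target_g=sodium_target)
    if behavior is BehaviorId.FLUID_RESTRICTION:
        if max_intake not in FLUID_LIMITS:
            raise ValidationError(f"max intake must be one of {FLUID_LIMITS}, got {max_intake}")
        return Goal(behavior, week_start, max_intake_l=max_intake)
    # medication intake
    if doses is None or doses < 1:
        raise ValidationError(f"planned doses/day must be >= 1, got {doses}")
    return Goal(behavior, week_start, planned_doses=doses)


def goal_from_payload(behavior: BehaviorId, week_start: dt.date, payload: Mapping) -> Goal:
    """Build a goal from an event-log ``goal_set`` payload."""
    try:
        if behavior is BehaviorId.PHYSICAL_ACTIVITY:
            band = MinutesBand[str(payload["band"]).upper()]
            return set_goal(behavior, week_start, days=payload["days"], band=band)
        if behavior is BehaviorId.LOW_SALT_DIET:
            return set_goal(behavior, week_start, sodium_target=payload["sodium_target"])
        if behavior is BehaviorId.FLUID_RESTRICTION:
            return set_goal(behavior, week_start, max_intake=payload["max_intake"])
        return set_goal(behavior, week_start, doses=payload["doses"])
    except KeyError as exc:
        raise ValidationError(f"goal_set payload missing field {exc}") from None


def goal_payload(goal: Goal) -> dict:
    """Inverse of :func:`goal_from_payload` (used by the simulator)."""
    if goal.behavior is BehaviorId.PHYSICAL_ACTIVITY:
        return {"days": goal.planned_days, "band": goal.planned_band.name.lower()}
    if goal.behavior is BehaviorId.LOW_SALT_DIET:
        return {"sodium_target": goal.sodium_target_g}
    if goal.behavior is BehaviorId.FLUID_RESTRICTION:
        return {"max_intake": goal.max_intake_l}
    return {"doses": goal.planned_doses}


@dataclass(frozen=True)
class DiaryEntry:
    """One day's self-reported progress for one behavior."""

    patient_id: str
    behavior: BehaviorId
    date: dt.date
    minutes_band: MinutesBand | None = None
    effort: Effort | None = None
    met_target: bool | None = None
    doses_taken: int | None = None


def diary_from_payload(
    patient_id: str, behavior: BehaviorId, date: dt.date, payload: Mapping
) -> DiaryEntry:
    try:
        if behavior is BehaviorId.PHYSICAL_ACTIVITY:
            return DiaryEntry(
                patient_id,
                behavior,
                date,
                minutes_band=MinutesBand[str(payload["minutes_band"]).upper()],
                effort=Effort[str(payload["effort"]).upper()],
            )
        if behavior is BehaviorId.MEDICATION_INTAKE:
            return DiaryEntry(patient_id, behavior, date, doses_taken=int(payload["doses_taken"]))
        return DiaryEntry(patient_id, behavior, date, met_target=bool(payload["met_target"]))
    except KeyError as exc:
        raise ValidationError(f"diary_entry payload missing field {exc}") from None


# --------------------------------------------------------------------------
# Weekly evaluation and feedback


@dataclass(frozen=True)
class WeekEvaluation:
    week_index: int
    goal: Goal
    days_achieved: int
    days_on_target_band: int
    dominant_effort: Effort | None
    outcome: Outcome
    feedback_id: str


def _dominant_effort(entries: Sequence[DiaryEntry]) -> Effort | None:
    """Modal effort over active days; ties resolve toward the harder rating."""
    efforts = [e.effort for e in entries if e.effort is not None]
    if not efforts:
        return None
    counts = Counter(efforts)
    best = max(counts.values())
    return max(e for e, c in counts.items() if c == best)


def evaluate_week(
    goal: Goal,
    entries: Iterable[DiaryEntry],
    config: ProgramConfig = DEFAULT_CONFIG,
    week_index: int = 1,
) -> WeekEvaluation:
    """Judge one coaching week against its goal and pick the feedback.

    Physical activity: an entry on a day counts as activity; the week is
    achieved iff the number of days at or above the planned minutes band
    reaches the planned day count.  Salt/fluid: achieved iff the target was
    met on the configured fraction of week days (default: all 7; days
    without an entry count as not met).  Medication: achieved iff the
    planned doses were taken on every day of the week.
    """
    entries = list(entries)
    seen: set[dt.date] = set()
    for entry in entries:
        if entry.behavior != goal.behavior:
            raise ValidationError(
                f"diary entry for {entry.behavior} cannot score a {goal.behavior.value} goal"
            )
        if not goal.week_start <= entry.date <= goal.week_end:
            raise ValidationError(
                f"diary entry on {entry.date} outside goal week "
                f"{goal.week_start}..{goal.week_end}"
            )
        if entry.date in seen:
            raise ValidationError(f"duplicate diary entry on {entry.date}")
        seen.add(entry.date)

    week_days = config.week_length_days
    dominant = None
    if goal.behavior is BehaviorId.PHYSICAL_ACTIVITY:
        days_achieved = len(entries)
        days_on_target = sum(1 for e in entries if e.minutes_band >= goal.planned_band)
        achieved = days_on_target >= goal.planned_days
        dominant = _dominant_effort(entries)
    elif goal.behavior is BehaviorId.MEDICATION_INTAKE:
        on_plan = sum(1 for e in entries if e.doses_taken == goal.planned_doses)
        days_achieved = days_on_target = on_plan
        achieved = on_plan == week_days and len(entries) == week_days
    else:  # low-salt diet / fluid restriction
        met = sum(1 for e in entries if e.met_target)
        days_achieved = days_on_target = met
        achieved = met >= math.ceil(config.target_met_fraction * week_days)

    outcome = Outcome.ACHIEVED if achieved else Outcome.MISSED
    evaluation = WeekEvaluation(
        week_index=week_index,
        goal=goal,
        days_achieved=days_achieved,
        days_on_target_band=days_on_target,
        dominant_effort=dominant,
        outcome=outcome,
        feedback_id="",
    )
    return dataclasses.replace(evaluation, feedback_id=select_feedback(evaluation))


def select_feedback(evaluation: WeekEvaluation) -> str:
    """Deterministic feedback lookup keyed by outcome, shortfalls, and effort.

    The table is total: a missed week with fewer active days than planned,
    sessions below the planned band, and a too-hard dominant effort advises
    a less ambitious goal; a missed week that felt too easy invites a retry
    (or a different plan); an achieved week that felt too easy suggests
    raising the goal; any other achieved week is congratulated; any other
    missed week gets an encouraging retry message.
    """
    goal = evaluation.goal
    if goal.behavior is BehaviorId.PHYSICAL_ACTIVITY:
        fewer_days = evaluation.days_achieved < (goal.planned_days or 0)
        band_shortfall = evaluation.days_on_target_band < evaluation.days_achieved
    else:
        fewer_days = band_shortfall = False
    effort = evaluation.dominant_effort
    if evaluation.outcome is Outcome.MISSED:
        if fewer_days and band_shortfall and effort is Effort.TOO_HARD:
            return "reduce_goal"
        if effort is Effort.TOO_EASY:
            return "encourage_retry_or_raise"
        return "encourage_retry"
    if effort is Effort.TOO_EASY:
        return "consider_raising"
    return "congratulate"


# --------------------------------------------------------------------------
# Adherence, struggle, follow-up scheduling


def update_adherence(
    outcome_history: Sequence[Outcome], weeks: int = DEFAULT_CONFIG.adherence_weeks
) -> bool:
    """True iff the most recent ``weeks`` consecutive weeks were all achieved."""
    if len(outcome_history) < weeks:
        return False
    return all(o is Outcome.ACHIEVED for o in outcome_history[-weeks:])


@dataclass(frozen=True)
class NurseAlert:
    patient_id: str
    behavior: BehaviorId
    trigger_week: int
    reason: str = "persistent_goal_difficulty"


def detect_struggle(
    outcome_history: Sequence[Outcome],
    patient_id: str = "",
    behavior: BehaviorId = BehaviorId.PHYSICAL_ACTIVITY,
    k: int = DEFAULT_CONFIG.struggle_weeks,
) -> NurseAlert | None:
    """Alert the nurse when the last ``k`` consecutive weeks were all missed.

    At most one alert per missed streak: the alert fires exactly when the
    trailing missed streak reaches length ``k``, and not again until the
    streak is broken and a fresh one builds up.
    """
    streak = 0
    for outcome in reversed(outcome_history):
        if outcome is Outcome.MISSED:
            streak += 1
        else:
            break
    if streak == k:
        return NurseAlert(patient_id, behavior, trigger_week=len(outcome_history))
    return None


def schedule_followup(
    stop_date: dt.date, interval_days: int = DEFAULT_CONFIG.followup_interval_days
) -> dt.date:
    """Next relapse follow-up: 2 months (60 days) after stopping, recurring."""
    return stop_date + dt.timedelta(days=interval_days)


# --------------------------------------------------------------------------
# Journey state machine


#: Event types applicable per state (Fig-3-shaped edge set).  Education
#: viewing is passive and allowed in any state; study end is global.
_LEGAL_EVENTS: dict[JourneyState, frozenset[EventType]] = {
    JourneyState.ADHERENT_AT_ASSESSMENT: frozenset(),
    JourneyState.NONADHERENT: frozenset({EventType.IC_RATING, EventType.NON_START_REASON}),
    JourneyState.IC_ASSESSED: frozenset({EventType.GOAL_SET, EventType.NON_START_REASON}),
    JourneyState.COACHING: frozenset({EventType.GOAL_SET, EventType.DIARY_ENTRY}),
    JourneyState.ADHERENT: frozenset({EventType.CONTINUE_CHOICE}),
    JourneyState.CONTINUED_COACHING: frozenset({EventType.GOAL_SET, EventType.DIARY_ENTRY}),
    JourneyState.STOPPED_AFTER_ADHERENT: frozenset({EventType.FOLLOWUP_RESPONSE}),
    JourneyState.FOLLOWUP_MAINTAINED: frozenset({EventType.FOLLOWUP_RESPONSE}),
    JourneyState.RELAPSED_RECOACHING: frozenset({EventType.GOAL_SET}),
    JourneyState.RELAPSED_STOPPED: frozenset(),
    JourneyState.NEVER_STARTED_COACHING: frozenset(),
}

_ALWAYS_LEGAL = frozenset({EventType.EDUCATION_VIEWED, EventType.STUDY_END})


def legal_events(state: JourneyState) -> frozenset[EventType]:
    """The event types applicable in ``state`` (plus passive/global events)."""
    return _LEGAL_EVENTS[state] | _ALWAYS_LEGAL


@dataclass
class BehaviorJourney:
    """The evolving coaching journey of one patient for one behavior."""

    patient_id: str
    behavior: BehaviorId
    state: JourneyState
    placement: MatrixPlacement
    required_education: tuple[str, ...] = ()
    viewed: set[str] = field(default_factory=set)
    state_log: list[tuple[dt.date, JourneyState]] = field(default_factory=list)
    ic: ImportanceConfidence | None = None
    ic_messages: tuple[str, ...] = ()
    open_goal: Goal | None = None
    week_entries: list[DiaryEntry] = field(default_factory=list)
    total_weeks: int = 0
    outcomes: list[Outcome] = field(default_factory=list)  # current stint
    evaluations: list[WeekEvaluation] = field(default_factory=list)
    adherence_dates: list[dt.date] = field(default_factory=list)
    first_adherence_goal: Goal | None = None
    continue_choices: list[bool] = field(default_factory=list)
    followup_answers: list[FollowupAnswer] = field(default_factory=list)
    stop_date: dt.date | None = None
    next_followup: dt.date | None = None
    alerts: list[NurseAlert] = field(default_factory=list)
    non_start_reasons: list[str] = field(default_factory=list)
    ended: bool = False

    def states_entered(self) -> set[JourneyState]:
        return {s for _, s in self.state_log}

    def _enter(self, date: dt.date, state: JourneyState) -> None:
        self.state = state
        self.state_log.append((date, state))

    # -- weekly evaluation ------------------------------------------------

    def _close_week(self, config: ProgramConfig) -> None:
        goal = self.open_goal
        assert goal is not None
        self.total_weeks += 1
        evaluation = evaluate_week(goal, self.week_entries, config, week_index=self.total_weeks)
        self.evaluations.append(evaluation)
        self.outcomes.append(evaluation.outcome)
        self.open_goal = None
        self.week_entries = []
        if update_adherence(self.outcomes, config.adherence_weeks):
            if self.first_adherence_goal is None:
                self.first_adherence_goal = goal
            self.adherence_dates.append(goal.window_close)
            self.outcomes = []  # a new continue/stop cycle needs 2 fresh weeks
            self._enter(goal.window_close, JourneyState.ADHERENT)
        elif self.state is JourneyState.COACHING:
            alert = detect_struggle(
                self.outcomes, self.patient_id, self.behavior, config.struggle_weeks
            )
            if alert is not None:
                self.alerts.append(alert)

    def _close_due_weeks(self, as_of: dt.date, config: ProgramConfig) -> None:
        if self.open_goal is not None and as_of >= self.open_goal.window_close:
            self._close_week(config)

    # -- event application -------------------------------------------------

    def apply(
        self,
        event: JourneyEvent,
        config: ProgramConfig,
        catalog: ContentCatalog,
    ) -> JourneyState:
        """Apply one event; returns the successor state.

        Raises :class:`IllegalTransitionError` for any (state, event) pair
        outside the journey graph and :class:`ValidationError` for payload
        problems (out-of-range goal, duplicate diary day, ...).
        """
        self._close_due_weeks(event.date, config)
        etype = event.type
        if etype not in legal_events(self.state):
            raise IllegalTransitionError(self.state, etype)

        if etype is EventType.EDUCATION_VIEWED:
            self.viewed.add(event.payload["content_id"])
        elif etype is EventType.IC_RATING:
            self.ic, self.ic_messages = assess_importance_confidence(
                self.behavior,
                event.payload["importance"],
                event.payload["confidence"],
                config,
                catalog,
            )
            self._enter(event.date, JourneyState.IC_ASSESSED)
        elif etype is EventType.GOAL_SET:
            if self.open_goal is not None:
                raise ValidationError(
                    f"goal set on {event.date} while the week starting "
                    f"{self.open_goal.week_start} is still open"
                )
            if self.state is JourneyState.IC_ASSESSED:
                unwatched = [c for c in self.required_education if c not in self.viewed]
                if unwatched:
                    raise IllegalTransitionError(
                        self.state,
                        etype,
                        f"required education not yet viewed: {unwatched}",
                    )
            self.open_goal = goal_from_payload(self.behavior, event.date, event.payload)
            if self.state in (JourneyState.IC_ASSESSED, JourneyState.RELAPSED_RECOACHING):
                self._enter(event.date, JourneyState.COACHING)
        elif etype is EventType.DIARY_ENTRY:
            if self.open_goal is None:
                raise ValidationError(f"diary entry on {event.date} outside any coaching week")
            entry = diary_from_payload(self.patient_id, self.behavior, event.date, event.payload)
            if not self.open_goal.week_start <= entry.date <= self.open_goal.week_end:
                raise ValidationError(
                    f"diary entry on {entry.date} outside the open week "
                    f"{self.open_goal.week_start}..{self.open_goal.week_end}"
                )
            if any(e.date == entry.date for e in self.week_entries):
                raise ValidationError(f"duplicate diary entry on {entry.date}")
            self.week_entries.append(entry)
        elif etype is EventType.CONTINUE_CHOICE:
            choice = bool(event.payload["continue"])
            self.continue_choices.append(choice)
            if choice:
                self._enter(event.date, JourneyState.CONTINUED_COACHING)
            else:
                self.stop_date = event.date
                self.next_followup = schedule_followup(event.date, config.followup_interval_days)
                self._enter(event.date, JourneyState.STOPPED_AFTER_ADHERENT)
        elif etype is EventType.FOLLOWUP_RESPONSE:
            answer = FollowupAnswer(event.payload["answer"])
            self.followup_answers.append(answer)
            if answer is FollowupAnswer.MAINTAINED:
                self.next_followup = schedule_followup(event.date, config.followup_interval_days)
                self._enter(event.date, JourneyState.FOLLOWUP_MAINTAINED)
            elif answer is FollowupAnswer.RELAPSED_RETRY:
                self.next_followup = None
                self._enter(event.date, JourneyState.RELAPSED_RECOACHING)
            else:
                self.next_followup = None
                self._enter(event.date, JourneyState.RELAPSED_STOPPED)
        elif etype is EventType.NON_START_REASON:
            self.non_start_reasons.append(event.payload["reason"])
            self._enter(event.date, JourneyState.NEVER_STARTED_COACHING)
        elif etype is EventType.STUDY_END:
            self._close_due_weeks(event.date + dt.timedelta(days=1), config)
            self.ended = True
        return self.state


def step(
    journey: BehaviorJourney,
    event: JourneyEvent,
    config: ProgramConfig = DEFAULT_CONFIG,
    catalog: ContentCatalog | None = None,
) -> JourneyState:
    """Apply one event to a journey; the unique successor state, or an
    :class:`IllegalTransitionError` naming the state and event."""
    return journey.apply(event, config, catalog if catalog is not None else default_catalog())


# --------------------------------------------------------------------------
# Event-log replay


@dataclass
class ReplayResult:
    """All journeys reconstructed from an event log."""

    journeys: dict[tuple[str, BehaviorId], BehaviorJourney]
    patient_ids: tuple[str, ...]

    def journeys_for(self, behavior: BehaviorId) -> list[BehaviorJourney]:
        return [j for (pid, b), j in self.journeys.items() if b is behavior]

    @property
    def alerts(self) -> list[NurseAlert]:
        return [a for j in self.journeys.values() for a in j.alerts]


def _finalize_assessment(
    patient_id: str,
    responses: list[QuestionnaireResponse],
    bank: ItemBank,
    catalog: ContentCatalog,
    config: ProgramConfig,
    date: dt.date,
) -> dict[BehaviorId, BehaviorJourney]:
    does = score_behavior(responses, bank, config)
    knows = score_knowledge(responses, bank, config)
    topic_gaps = [t for t, ok in knows.items() if not ok and t not in {b.value for b in BehaviorId}]
    journeys: dict[BehaviorId, BehaviorJourney] = {}
    for behavior in COACHABLE_BEHAVIORS:
        placement = place_in_matrix(behavior, does[behavior], knows.get(behavior.value, True))
        plan = catalog.education_plan(placement, topic_gaps)
        initial = (
            JourneyState.ADHERENT_AT_ASSESSMENT
            if placement.does_behavior
            else JourneyState.NONADHERENT
        )
        journey = BehaviorJourney(
            patient_id=patient_id,
            behavior=behavior,
            state=initial,
            placement=placement,
            required_education=plan.required,
        )
        journey.state_log.append((date, initial))
        journeys[behavior] = journey
    return journeys


def replay_events(
    events: Iterable[JourneyEvent],
    bank: ItemBank | None = None,
    catalog: ContentCatalog | None = None,
    config: ProgramConfig = DEFAULT_CONFIG,
) -> ReplayResult:
    """Replay a validated event stream through the journey engine.

    Questionnaire responses accumulate while the assessment is open; the
    first coaching event (or study end) closes it, scores the responses, and
    opens one journey per behavior.  Subsequent behavior events drive the
    state machine.  Scoring raises :class:`IncompleteAssessmentError` if a
    behavior's items are not fully answered by then.  Deterministic: the
    same log always yields the same result.
    """
    bank = bank if bank is not None else default_item_bank()
    catalog = catalog if catalog is not None else default_catalog()

    journeys: dict[tuple[str, BehaviorId], BehaviorJourney] = {}
    patient_ids: list[str] = []
    for patient_id, patient_events in iter_patients(events):
        patient_ids.append(patient_id)
        responses: list[QuestionnaireResponse] = []
        assessed = False
        mine: dict[BehaviorId, BehaviorJourney] = {}

        def _finalize(date: dt.date) -> None:
            nonlocal assessed, mine
            mine = _finalize_assessment(patient_id, responses, bank, catalog, config, date)
            for behavior, journey in mine.items():
                journeys[(patient_id, behavior)] = journey
            assessed = True

        for event in patient_events:
            if event.type is EventType.QUESTIONNAIRE_RESPONSE:
                if assessed:
                    raise ValidationError(
                        f"patient {patient_id}: questionnaire response after assessment closed"
                    )
                responses.append(
                    QuestionnaireResponse(
                        patient_id, event.payload["item_id"], event.payload["answer_index"],
                        event.date,
                    )
                )
            elif event.type is EventType.STUDY_END:
                if not assessed and responses:
                    _finalize(event.date)
                for journey in mine.values():
                    journey.apply(event, config, catalog)
            else:
                if not assessed:
                    _finalize(event.date)
                behavior = BehaviorId(event.behavior)
                mine[behavior].apply(event, config, catalog)
    return ReplayResult(journeys=journeys, patient_ids=tuple(patient_ids))
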