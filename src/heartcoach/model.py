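"""Shared domain vocabulary: behaviors, journey states, events, errors.

The program coaches four heart-failure self-care behaviors (physical
activity, low-salt diet, fluid restriction, medication intake).  A few
further topics (symptom monitoring, alcohol, sleep) receive education and
tips only and never enter the coaching loop.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Any, Mapping


class BehaviorId(str, Enum):
    """The four coachable self-care behaviors."""

    PHYSICAL_ACTIVITY = "physical_activity"
    LOW_SALT_DIET = "low_salt_diet"
    FLUID_RESTRICTION = "fluid_restriction"
    MEDICATION_INTAKE = "medication_intake"


#: Education-only topics: present in questionnaires and the content catalog,
#: never coached.
EDUCATION_ONLY_TOPICS = ("symptom_monitoring", "alcohol", "sleep")

COACHABLE_BEHAVIORS = tuple(BehaviorId)


class MinutesBand(IntEnum):
    """Ordered daily-activity duration bands (minutes per day)."""

    LE_15 = 0
    MIN_15_30 = 1
    MIN_30_45 = 2
    MIN_45_60 = 3

    @property
    def label(self) -> str:
        return {0: "<=15 min", 1: "15-30 min", 2: "30-45 min", 3: "45-60 min"}[self.value]


class Effort(IntEnum):
    """Patient-rated session effort; higher value = harder."""

    TOO_EASY = 0
    JUST_RIGHT = 1
    TOO_HARD = 2


class Outcome(str, Enum):
    ACHIEVED = "achieved"
    MISSED = "missed"


class JourneyState(str, Enum):
    """Per patient-behavior position in the coaching process."""

    ADHERENT_AT_ASSESSMENT = "adherent_at_assessment"
    NONADHERENT = "nonadherent"
    IC_ASSESSED = "ic_assessed"
    COACHING = "coaching"
    ADHERENT = "adherent"
    CONTINUED_COACHING = "continued_coaching"
    STOPPED_AFTER_ADHERENT = "stopped_after_adherent"
    FOLLOWUP_MAINTAINED = "followup_maintained"
    RELAPSED_RECOACHING = "relapsed_recoaching"
    RELAPSED_STOPPED = "relapsed_stopped"
    NEVER_STARTED_COACHING = "never_started_coaching"


class EventType(str, Enum):
    QUESTIONNAIRE_RESPONSE = "questionnaire_response"
    IC_RATING = "ic_rating"
    EDUCATION_VIEWED = "education_viewed"
    GOAL_SET = "goal_set"
    DIARY_ENTRY = "diary_entry"
    CONTINUE_CHOICE = "continue_choice"
    FOLLOWUP_RESPONSE = "followup_response"
    NON_START_REASON = "non_start_reason"
    STUDY_END = "study_end"


class FollowupAnswer(str, Enum):
    MAINTAINED = "maintained"
    RELAPSED_RETRY = "relapsed_retry"
    RELAPSED_STOP = "relapsed_stop"


#: Reason codes for not proceeding to goal setting after assessment.
NON_START_REASONS = (
    "death",
    "patient_too_busy",
    "severe_impairment",
    "lack_of_motivation",
    "difficulties_understanding_system",
    "difficulties_understanding_goal_setting",
    "unknown",
    "technical_problems",
)

NON_START_REASON_LABELS = {
    "death": "Death",
    "patient_too_busy": "Patient too busy",
    "severe_impairment": "Severe physical or mental impairment",
    "lack_of_motivation": "Lack of motivation",
    "difficulties_understanding_system": "Difficulties in understanding the system",
    "difficulties_understanding_goal_setting": "Difficulties in understanding goal setting",
    "unknown": "Unknown",
    "technical_problems": "Technical problems with the system",
}


@dataclass(frozen=True)
class JourneyEvent:
    """One timestamped record in a patient event log.

    ``behavior`` is a :class:`BehaviorId` value or ``"global"`` for events
    that are not behavior-specific (questionnaire responses, study end).
    ``payload`` carries the event-type-specific fields.
    """

    patient_id: str
    date: dt.date
    behavior: str
    type: EventType
    payload: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.behavior != "global" and self.behavior not in {b.value for b in BehaviorId}:
            raise ValidationError(f"unknown behavior {self.behavior!r}")


# --------------------------------------------------------------------------
# Errors


class HeartcoachError(Exception):
    """Base class for all package errors."""


class ValidationError(HeartcoachError):
    """Malformed input, out-of-range value, or schema violation."""


class IncompleteAssessmentError(ValidationError):
    """Questionnaire responses do not cover a behavior's items."""

    def __init__(self, behavior: str, missing: tuple[str, ...] = ()) -> None:
        self.behavior = behavior
        self.missing = missing
        super().__init__(f"incomplete assessment for {behavior}: missing items {list(missing)}")


class IllegalTransitionError(ValidationError):
    """An event is not applicable in the journey's current state."""

    def __init__(self, state: JourneyState, event: EventType, detail: str = "") -> None:
        self.state = state
        self.event = event
        msg = f"event {event.value!r} is illegal in state {state.value!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class UnknownContentError(ValidationError):
    """A message or content id does not resolve in the catalog."""


class EventLogError(ValidationError):
    """Malformed event-log record; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str) -> None:
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")
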