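"""Questionnaire scoring, knowledge/behavior matrix placement, readiness
(importance/confidence) assessment, and trial eligibility screening.

The assessment places each patient, per behavior, in a 2x2 grid spanned by
"does the behavior" and "knows why it matters":

====  ====  =====  ========================
area  does  knows  prescribed path
====  ====  =====  ========================
1     no    no     education, then coaching
2     yes   no     education only
3     no    yes    coaching only
4     yes   yes    none
====  ====  =====  ========================

Behavior items use a 5-point agree scale; any item answered below the
configured cutoff flags the behavior as not performed (conservative: coaching
is low-harm).  Knowledge items always offer "I don't know", which is scored
as not correct; more wrong-or-don't-know answers than the configured
tolerance flag knowledge as insufficient.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .config import ProgramConfig, DEFAULT_CONFIG
from .model import (
    BehaviorId,
    COACHABLE_BEHAVIORS,
    EDUCATION_ONLY_TOPICS,
    IncompleteAssessmentError,
    ValidationError,
)

DONT_KNOW = "I don't know"


# --------------------------------------------------------------------------
# Item bank


@dataclass(frozen=True)
class QuestionnaireItem:
    """One behavior or knowledge question.

    ``behavior`` is a coachable behavior id or an education-only topic.
    Knowledge items carry ``correct_index`` and must offer a final
    "I don't know" option.
    """

    item_id: str
    behavior: str
    kind: str  # "behavior" | "knowledge"
    text: str
    options: tuple[str, ...]
    correct_index: int | None = None

    def __post_init__(self) -> None:
        valid_behaviors = {b.value for b in BehaviorId} | set(EDUCATION_ONLY_TOPICS)
        if self.behavior not in valid_behaviors:
            raise ValidationError(f"item {self.item_id}: unknown behavior {self.behavior!r}")
        if self.kind not in ("behavior", "knowledge"):
            raise ValidationError(f"item {self.item_id}: kind must be behavior or knowledge")
        if self.kind == "knowledge":
            if self.options[-1] != DONT_KNOW:
                raise ValidationError(
                    f"knowledge item {self.item_id} must offer {DONT_KNOW!r} as last option"
                )
            if self.correct_index is None or not 0 <= self.correct_index < len(self.options) - 1:
                raise ValidationError(f"item {self.item_id}: invalid correct_index")
        elif self.correct_index is not None:
            raise ValidationError(f"behavior item {self.item_id} must not set correct_index")

    @property
    def dont_know_index(self) -> int | None:
        return len(self.options) - 1 if self.kind == "knowledge" else None


@dataclass(frozen=True)
class QuestionnaireResponse:
    patient_id: str
    item_id: str
    answer_index: int
    timestamp: dt.date | None = None


class ItemBank:
    """The questionnaire item collection with per-behavior lookups."""

    def __init__(self, items: Sequence[QuestionnaireItem]) -> None:
        self.items: tuple[QuestionnaireItem, ...] = tuple(items)
        self.by_id: dict[str, QuestionnaireItem] = {}
        for item in self.items:
            if item.item_id in self.by_id:
                raise ValidationError(f"duplicate item id {item.item_id!r}")
            self.by_id[item.item_id] = item

    def items_for(self, behavior: str, kind: str) -> tuple[QuestionnaireItem, ...]:
        return tuple(i for i in self.items if i.behavior == behavior and i.kind == kind)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ItemBank":
        raw = yaml.safe_load(Path(path).read_text())
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: dict) -> "ItemBank":
        items = []
        for spec in raw["items"]:
            items.append(
                QuestionnaireItem(
                    item_id=spec["item_id"],
                    behavior=spec["behavior"],
                    kind=spec["kind"],
                    text=spec.get("text", ""),
                    options=tuple(spec["options"]),
                    correct_index=spec.get("correct_index"),
                )
            )
        return cls(items)


def default_item_bank() -> ItemBank:
    """The packaged default bank: 12 behavior and 15 knowledge items."""
    raw = yaml.safe_load(
        resources.files("heartcoach.data").joinpath("items.yaml").read_text()
    )
    return ItemBank._from_raw(raw)


# --------------------------------------------------------------------------
# Scoring


def _collect_answers(
    responses: Iterable[QuestionnaireResponse], bank: ItemBank
) -> dict[str, int]:
    """Map item_id -> answer_index, validating ids and ranges.

    A repeated answer to the same item keeps the latest occurrence.
    """
    answers: dict[str, int] = {}
    for resp in responses:
        item = bank.by_id.get(resp.item_id)
        if item is None:
            raise ValidationError(f"response to unknown item {resp.item_id!r}")
        if not 0 <= resp.answer_index < len(item.options):
            raise ValidationError(
                f"answer_index {resp.answer_index} out of range for item {resp.item_id}"
            )
        answers[resp.item_id] = resp.answer_index
    return answers


def score_behavior(
    responses: Iterable[QuestionnaireResponse],
    bank: ItemBank,
    config: ProgramConfig = DEFAULT_CONFIG,
) -> dict[BehaviorId, bool]:
    """Score behavior items: does the patient perform each behavior?

    A behavior is flagged not performed iff any of its behavior items is
    answered below the cutoff (answer value = index + 1 on the 5-point
    scale).  Missing items raise :class:`IncompleteAssessmentError`.
    """
    answers = _collect_answers(responses, bank)
    result: dict[BehaviorId, bool] = {}
    for behavior in COACHABLE_BEHAVIORS:
        items = bank.items_for(behavior.value, "behavior")
        if not items:
            raise IncompleteAssessmentError(behavior.value, ())
        missing = tuple(i.item_id for i in items if i.item_id not in answers)
        if missing:
            raise IncompleteAssessmentError(behavior.value, missing)
        result[behavior] = all(
            answers[i.item_id] + 1 >= config.behavior_cutoff for i in items
        )
    return result


def score_knowledge(
    responses: Iterable[QuestionnaireResponse],
    bank: ItemBank,
    config: ProgramConfig = DEFAULT_CONFIG,
) -> dict[str, bool]:
    """Score knowledge items per behavior/topic.

    Knowledge is sufficient iff the count of wrong-or-"don't know" answers
    is at most the configured tolerance (default 0).  "I don't know" is
    always scored as not correct.  Keys cover every behavior or topic with
    knowledge items in the bank.
    """
    answers = _collect_answers(responses, bank)
    groups = {b.value for b in COACHABLE_BEHAVIORS} | set(EDUCATION_ONLY_TOPICS)
    result: dict[str, bool] = {}
    for group in groups:
        items = bank.items_for(group, "knowledge")
        if not items:
            continue
        missing = tuple(i.item_id for i in items if i.item_id not in answers)
        if missing:
            raise IncompleteAssessmentError(group, missing)
        wrong = sum(1 for i in items if answers[i.item_id] != i.correct_index)
        result[group] = wrong <= config.knowledge_tolerance
    return result


# --------------------------------------------------------------------------
# Matrix placement


@dataclass(frozen=True)
class MatrixPlacement:
    behavior: BehaviorId
    does_behavior: bool
    has_knowledge: bool
    area: int
    #: prescribed path: ordered steps among ("education", "coaching")
    path: tuple[str, ...]


_AREA = {(False, False): 1, (True, False): 2, (False, True): 3, (True, True): 4}
_PATH = {
    1: ("education", "coaching"),
    2: ("education",),
    3: ("coaching",),
    4: (),
}


def place_in_matrix(behavior: BehaviorId, does: bool, knows: bool) -> MatrixPlacement:
    """Place a patient in the knowledge x behavior grid for one behavior."""
    area = _AREA[(bool(does), bool(knows))]
    return MatrixPlacement(behavior, bool(does), bool(knows), area, _PATH[area])


# --------------------------------------------------------------------------
# Importance / confidence (readiness) assessment


@dataclass(frozen=True)
class ImportanceConfidence:
    behavior: BehaviorId
    importance: int
    confidence: int
    category: str  # low_importance | low_confidence | ready


def assess_importance_confidence(
    behavior: BehaviorId,
    importance: int,
    confidence: int,
    config: ProgramConfig = DEFAULT_CONFIG,
    catalog=None,
) -> tuple[ImportanceConfidence, tuple[str, ...]]:
    """Classify readiness on 0-10 rulers and pick the feedback messages.

    Importance is checked before confidence: low importance yields the
    behavior's myth/truth messages, low confidence its barrier tips, and
    ready an encouragement message.  Exactly one category fires per
    assessment.  ``catalog`` defaults to the packaged content catalog.
    """
    for name, value in (("importance", importance), ("confidence", confidence)):
        if not isinstance(value, int) or not 0 <= value <= 10:
            raise ValidationError(f"{name} rating must be an integer in 0..10, got {value!r}")
    if catalog is None:
        from .catalog import default_catalog

        catalog = default_catalog()
    if importance < config.importance_threshold:
        category = "low_importance"
        messages = catalog.myth_ids(behavior)
    elif confidence < config.confidence_threshold:
        category = "low_confidence"
        messages = catalog.barrier_ids(behavior)
    else:
        category = "ready"
        messages = (catalog.encouragement_id(behavior),)
    return ImportanceConfidence(behavior, importance, confidence, category), tuple(messages)


# --------------------------------------------------------------------------
# Eligibility screening


#: mg/day of each loop diuretic equivalent to 1 mg/day furosemide-equivalents
#: scale: 40 mg furosemide = 1 mg bumetanide = 10 mg torasemide.
FUROSEMIDE_EQUIVALENCE = {
    "furosemide": 1.0,
    "bumetanide": 40.0,
    "torasemide": 4.0,
}

MIN_FUROSEMIDE_EQUIV_MG = 40.0


@dataclass(frozen=True)
class EligibilityRecord:
    """Screening data for one candidate patient."""

    ntprobnp: float  # pg/mL, most recent within 3 months
    sinus_rhythm: bool
    loop_diuretic: str
    diuretic_mg_per_day: float
    nyha: int
    hf_diagnosis: bool
    rapidly_reversible_cause: bool
    age_years: int
    can_operate_system: bool
    speaks_local_language: bool
    hf_admission_within_days: int | None = None

    def __post_init__(self) -> None:
        if self.ntprobnp < 0:
            raise ValidationError("ntprobnp must be >= 0")
        if self.nyha not in (1, 2, 3, 4):
            raise ValidationError("nyha must be in 1..4")


def furosemide_equivalent_mg(drug: str, mg_per_day: float) -> float:
    """Convert a loop-diuretic dose to furosemide-equivalent mg/day."""
    try:
        factor = FUROSEMIDE_EQUIVALENCE[drug.lower()]
    except KeyError:
        raise ValidationError(f"unknown loop diuretic {drug!r}") from None
    return mg_per_day * factor


def check_eligibility(rec: EligibilityRecord) -> tuple[bool, tuple[str, ...]]:
    """Evaluate trial inclusion/exclusion; reasons list every failed criterion.

    Inclusion: clinical HF diagnosis from a non-rapidly-reversible cause;
    >=40 mg/day furosemide-equivalent loop diuretic; advanced or unstable
    disease (HF admission within 60 days OR NYHA >= III); NT-proBNP >= 1000
    pg/mL in sinus rhythm or >= 2000 pg/mL otherwise.  Exclusion: age < 18,
    inability to operate the system, inability to communicate in the local
    language.
    """
    reasons: list[str] = []
    if not rec.hf_diagnosis:
        reasons.append("no clinical diagnosis of heart failure")
    if rec.rapidly_reversible_cause:
        reasons.append("heart failure from a rapidly reversible cause")
    if furosemide_equivalent_mg(rec.loop_diuretic, rec.diuretic_mg_per_day) < MIN_FUROSEMIDE_EQUIV_MG:
        reasons.append("loop diuretic below 40 mg/day furosemide equivalent")
    recent_admission = (
        rec.hf_admission_within_days is not None and rec.hf_admission_within_days <= 60
    )
    if not (recent_admission or rec.nyha >= 3):
        reasons.append("no evidence of advanced or unstable disease "
                       "(no HF admission within 60 days and NYHA < III)")
    threshold = 1000.0 if rec.sinus_rhythm else 2000.0
    if rec.ntprobnp < threshold:
        rhythm = "sinus" if rec.sinus_rhythm else "non-sinus"
        reasons.append(f"NT-proBNP below {threshold:.0f} for {rhythm} rhythm")
    if rec.age_years < 18:
        reasons.append("aged under 18 years")
    if not rec.can_operate_system:
        reasons.append("unable to operate the telehealth system")
    if not rec.speaks_local_language:
        reasons.append("unable to communicate in the local language")
    return (not reasons), tuple(reasons)
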