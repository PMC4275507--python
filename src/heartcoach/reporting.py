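"""Journey classification and the cohort results tables.

All counts derive solely from replayed engine states, never from fixture
metadata.  Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Mapping

import pandas as pd

from .coaching import BehaviorJourney, ReplayResult
from .model import (
    BehaviorId,
    COACHABLE_BEHAVIORS,
    FollowupAnswer,
    JourneyState,
    MinutesBand,
    NON_START_REASONS,
    NON_START_REASON_LABELS,
)

BEHAVIOR_LABELS = {
    BehaviorId.PHYSICAL_ACTIVITY: "Physical activity",
    BehaviorId.LOW_SALT_DIET: "Low-salt diet",
    BehaviorId.FLUID_RESTRICTION: "Fluid restriction",
    BehaviorId.MEDICATION_INTAKE: "Medication intake",
}


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Half-up percentage rounding, exact in decimal arithmetic.

    ``percentage(50, 123)`` is 40.7; zero denominators yield 0.0.
    """
    numerator, denominator = int(numerator), int(denominator)
    if denominator == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Journey classification


@dataclass(frozen=True)
class JourneyClass:
    """Row flags for one patient-behavior journey ("entered at least once")."""

    were_nonadherent: bool
    started_coaching: bool
    became_adherent: bool
    stopped_immediately: bool
    continued_coaching: bool
    stopped_later: bool
    continued_until_end: bool
    censored_in_coaching: bool


def classify_journey(journey: BehaviorJourney) -> JourneyClass:
    entered = journey.states_entered()
    nonadherent = JourneyState.NONADHERENT in entered
    started = JourneyState.COACHING in entered
    adherent = JourneyState.ADHERENT in entered
    continued = JourneyState.CONTINUED_COACHING in entered
    stopped = JourneyState.STOPPED_AFTER_ADHERENT in entered
    return JourneyClass(
        were_nonadherent=nonadherent,
        started_coaching=started,
        became_adherent=adherent,
        stopped_immediately=adherent
        and bool(journey.continue_choices)
        and journey.continue_choices[0] is False,
        continued_coaching=continued,
        stopped_later=continued and stopped,
        continued_until_end=continued and not stopped,
        censored_in_coaching=started and not adherent,
    )


# --------------------------------------------------------------------------
# Transition table


TRANSITION_ROWS = (
    "were_nonadherent",
    "started_coaching",
    "became_adherent",
    "stopped_coaching_immediately",
    "continued_coaching",
    "stopped_coaching_later",
    "continued_until_study_end",
)

TRANSITION_ROW_LABELS = {
    "were_nonadherent": "Were nonadherent",
    "started_coaching": "Started coaching",
    "became_adherent": "Became adherent",
    "stopped_coaching_immediately": "Stopped coaching immediately",
    "continued_coaching": "Continued coaching",
    "stopped_coaching_later": "Stopped coaching later on",
    "continued_until_study_end": "Continued coaching until study end",
}

#: Row chaining: each row's denominator is its parent row's numerator.
_ROW_PARENT = {
    "were_nonadherent": None,  # denominator: all enrolled patients
    "started_coaching": "were_nonadherent",
    "became_adherent": "started_coaching",
    "stopped_coaching_immediately": "became_adherent",
    "continued_coaching": "became_adherent",
    "stopped_coaching_later": "continued_coaching",
    "continued_until_study_end": "continued_coaching",
}

_CLASS_FIELD = {
    "were_nonadherent": "were_nonadherent",
    "started_coaching": "started_coaching",
    "became_adherent": "became_adherent",
    "stopped_coaching_immediately": "stopped_immediately",
    "continued_coaching": "continued_coaching",
    "stopped_coaching_later": "stopped_later",
    "continued_until_study_end": "continued_until_end",
}


@dataclass
class TransitionTable:
    """Per-behavior counts of patients who entered each coaching state.

    ``counts``/``denominators``/``percentages`` are DataFrames indexed by
    the row names above with one column per behavior.  Patients still in
    coaching at study end without ever becoming adherent are reported
    separately in ``censored_in_coaching``.
    """

    counts: pd.DataFrame
    denominators: pd.DataFrame
    percentages: pd.DataFrame
    censored_in_coaching: pd.Series
    n_patients: int

    def formatted(self) -> pd.DataFrame:
        """Printable "n/den (pct)" cells with study-style labels."""
        data = {}
        for behavior in COACHABLE_BEHAVIORS:
            col = []
            for row in TRANSITION_ROWS:
                n = self.counts.loc[row, behavior.value]
                d = self.denominators.loc[row, behavior.value]
                p = self.percentages.loc[row, behavior.value]
                col.append(f"{n}/{d} ({p})")
            data[BEHAVIOR_LABELS[behavior]] = col
        return pd.DataFrame(
            data, index=[TRANSITION_ROW_LABELS[r] for r in TRANSITION_ROWS]
        )


def transition_table(result: ReplayResult) -> TransitionTable:
    """Count patients entering each state per behavior (printed-table rows)."""
    n_patients = len(result.patient_ids)
    counts: dict[str, dict[str, int]] = {row: {} for row in TRANSITION_ROWS}
    censored: dict[str, int] = {}
    for behavior in COACHABLE_BEHAVIORS:
        classes = [classify_journey(j) for j in result.journeys_for(behavior)]
        for row in TRANSITION_ROWS:
            field = _CLASS_FIELD[row]
            counts[row][behavior.value] = sum(1 for c in classes if getattr(c, field))
        censored[behavior.value] = sum(1 for c in classes if c.censored_in_coaching)
    count_df = pd.DataFrame(counts).T.reindex(TRANSITION_ROWS)
    denom = {}
    for row in TRANSITION_ROWS:
        parent = _ROW_PARENT[row]
        denom[row] = (
            {b.value: n_patients for b in COACHABLE_BEHAVIORS}
            if parent is None
            else counts[parent]
        )
    denom_df = pd.DataFrame(denom).T.reindex(TRANSITION_ROWS)
    pct_df = pd.DataFrame(
        {
            b.value: [
                percentage(count_df.loc[row, b.value], denom_df.loc[row, b.value])
                for row in TRANSITION_ROWS
            ]
            for b in COACHABLE_BEHAVIORS
        },
        index=TRANSITION_ROWS,
    )
    return TransitionTable(
        counts=count_df,
        denominators=denom_df,
        percentages=pct_df,
        censored_in_coaching=pd.Series(censored),
        n_patients=n_patients,
    )


# --------------------------------------------------------------------------
# Follow-up table


FOLLOWUP_ROWS = ("received_followup", "maintained", "relapsed_retry", "relapsed_no_retry")

_FOLLOWUP_LABELS = {
    "received_followup": "Received follow-up questionnaire",
    "maintained": "Maintained behavior",
    "relapsed_retry": "Relapsed and started coaching again",
    "relapsed_no_retry": "Relapsed but did not retry coaching",
}


def followup_table(result: ReplayResult) -> pd.DataFrame:
    """Responses to relapse follow-up questionnaires per behavior.

    A patient is counted once per behavior, at the first follow-up response.
    """
    data: dict[str, list[int]] = {}
    for behavior in COACHABLE_BEHAVIORS:
        firsts = [
            j.followup_answers[0]
            for j in result.journeys_for(behavior)
            if j.followup_answers
        ]
        data[behavior.value] = [
            len(firsts),
            sum(1 for a in firsts if a is FollowupAnswer.MAINTAINED),
            sum(1 for a in firsts if a is FollowupAnswer.RELAPSED_RETRY),
            sum(1 for a in firsts if a is FollowupAnswer.RELAPSED_STOP),
        ]
    return pd.DataFrame(data, index=FOLLOWUP_ROWS)


def format_followup_table(table: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for behavior in COACHABLE_BEHAVIORS:
        received = int(table.loc["received_followup", behavior.value])
        col = [str(received)]
        for row in FOLLOWUP_ROWS[1:]:
            n = int(table.loc[row, behavior.value])
            col.append(f"{n} ({percentage(n, received, 0):.0f}%)")
        out[BEHAVIOR_LABELS[behavior]] = col
    return pd.DataFrame(out, index=[_FOLLOWUP_LABELS[r] for r in FOLLOWUP_ROWS])


# --------------------------------------------------------------------------
# Goal distributions


@dataclass(frozen=True)
class ActivityGoalMatrix:
    """Days x minutes-band grid of physical-activity goals reached when
    patients became adherent (goal of the second consecutive achieved week,
    at first adherence)."""

    cells: Mapping[tuple[int, MinutesBand], int]

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    def day_subtotals(self) -> dict[int, int]:
        return {d: sum(n for (days, _), n in self.cells.items() if days == d)
                for d in range(1, 8)}

    def band_subtotals(self) -> dict[MinutesBand, int]:
        return {b: sum(n for (_, band), n in self.cells.items() if band == b)
                for b in MinutesBand}

    def to_frame(self) -> pd.DataFrame:
        bands = [MinutesBand.MIN_45_60, MinutesBand.MIN_30_45,
                 MinutesBand.MIN_15_30, MinutesBand.LE_15]
        rows = []
        for band in bands:
            row = {f"{d} d": self.cells.get((d, band), 0) for d in range(1, 8)}
            row["Subtotal"] = self.band_subtotals()[band]
            rows.append(row)
        frame = pd.DataFrame(rows, index=[b.label for b in bands])
        subtotal = {f"{d} d": self.day_subtotals()[d] for d in range(1, 8)}
        subtotal["Subtotal"] = self.total
        frame.loc["Subtotal"] = subtotal
        return frame


@dataclass(frozen=True)
class SaltGoalDistribution:
    """Counts of sodium goals (g/day, 5 = ">=5") reached at adherence."""

    counts: Mapping[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        labels = {1: "1 g/d", 2: "2 g/d", 3: "3 g/d", 4: "4 g/d", 5: ">=5 g/d"}
        rows = [{"Goal": labels[t], "Patients": self.counts.get(t, 0)}
                for t in (5, 4, 3, 2, 1)]
        rows.append({"Goal": "Total", "Patients": self.total})
        return pd.DataFrame(rows).set_index("Goal")


def goal_distribution(
    result: ReplayResult, behavior: BehaviorId
) -> ActivityGoalMatrix | SaltGoalDistribution:
    """Distribution of the goal reached in the second of the two consecutive
    achieved weeks, over patients who became adherent to ``behavior``."""
    goals = [
        j.first_adherence_goal
        for j in result.journeys_for(behavior)
        if j.first_adherence_goal is not None
    ]
    if behavior is BehaviorId.PHYSICAL_ACTIVITY:
        cells: dict[tuple[int, MinutesBand], int] = {}
        for goal in goals:
            key = (goal.planned_days, goal.planned_band)
            cells[key] = cells.get(key, 0) + 1
        return ActivityGoalMatrix(cells)
    if behavior is BehaviorId.LOW_SALT_DIET:
        counts: dict[int, int] = {}
        for goal in goals:
            counts[goal.sodium_target_g] = counts.get(goal.sodium_target_g, 0) + 1
        return SaltGoalDistribution(counts)
    raise ValueError(f"no goal distribution defined for {behavior.value}")


def aggregate_goal_share(
    dist: ActivityGoalMatrix | SaltGoalDistribution,
    predicate: Callable[..., bool],
) -> tuple[int, int, float]:
    """(count, total, percent) of reached goals satisfying ``predicate``.

    For the activity matrix the predicate receives ``(days, band)``; for the
    sodium distribution it receives the target in g/day.
    """
    if isinstance(dist, ActivityGoalMatrix):
        count = sum(n for (days, band), n in dist.cells.items() if predicate(days, band))
    else:
        count = sum(n for target, n in dist.counts.items() if predicate(target))
    total = dist.total
    return count, total, percentage(count, total, 0)


# --------------------------------------------------------------------------
# Non-start reasons


def nonstart_reason_table(result: ReplayResult) -> pd.DataFrame:
    """Reasons for not proceeding to goal setting, as counted reason records.

    One patient may contribute records for more than one behavior;
    ``n_patients`` in the summary row counts distinct patients.
    """
    counts = {reason: 0 for reason in NON_START_REASONS}
    patients: set[str] = set()
    for journey in result.journeys.values():
        for reason in journey.non_start_reasons:
            counts[reason] += 1
            patients.add(journey.patient_id)
    frame = pd.DataFrame(
        {"Reason": [NON_START_REASON_LABELS[r] for r in NON_START_REASONS],
         "n": [counts[r] for r in NON_START_REASONS]}
    ).set_index("Reason")
    frame.attrs["n_records"] = int(frame["n"].sum())
    frame.attrs["n_patients"] = len(patients)
    return frame
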