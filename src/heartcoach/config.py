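"""Program configuration: every tunable threshold in one place.

Defaults reflect the study conditions: a 5-point agree scale with answers of
4 or 5 counted as performing the behavior, zero tolerated knowledge errors,
motivational-interviewing 0-10 rulers with a readiness threshold of 7, 7-day
coaching weeks, a nurse alert after 3 consecutive missed weeks, and 2-month
(60-day) relapse follow-ups.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .model import ValidationError


@dataclass(frozen=True)
class ProgramConfig:
    #: Minimum answer value (1-5 scale) on a behavior item that still counts
    #: as performing the behavior.
    behavior_cutoff: int = 4
    #: Maximum number of wrong-or-don't-know knowledge answers per behavior
    #: before knowledge is flagged insufficient.
    knowledge_tolerance: int = 0
    #: Importance ruler value below which feedback targets misconceptions.
    importance_threshold: int = 7
    #: Confidence ruler value below which feedback targets barriers.
    confidence_threshold: int = 7
    #: Length of a coaching week in days.
    week_length_days: int = 7
    #: Fraction of week days on which a salt/fluid target must be met for an
    #: achieved week (1.0 = every day; unreported days count as not met).
    target_met_fraction: float = 1.0
    #: Consecutive achieved weeks that define adherence.
    adherence_weeks: int = 2
    #: Consecutive missed weeks that trigger a nurse alert.
    struggle_weeks: int = 3
    #: Days between stopping coaching and a relapse follow-up questionnaire
    #: (and between successive follow-ups).
    followup_interval_days: int = 60

    def __post_init__(self) -> None:
        if not 1 <= self.behavior_cutoff <= 5:
            raise ValidationError("behavior_cutoff must be in 1..5")
        if self.knowledge_tolerance < 0:
            raise ValidationError("knowledge_tolerance must be >= 0")
        for name in ("importance_threshold", "confidence_threshold"):
            if not 0 <= getattr(self, name) <= 10:
                raise ValidationError(f"{name} must be in 0..10")
        if not 0.0 <= self.target_met_fraction <= 1.0:
            raise ValidationError("target_met_fraction must be in [0, 1]")
        for name in ("week_length_days", "adherence_weeks", "struggle_weeks",
                     "followup_interval_days"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")


DEFAULT_CONFIG = ProgramConfig()


def load_config(path: str | Path) -> ProgramConfig:
    """Read a config YAML file; absent keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(ProgramConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return ProgramConfig(**raw)


def dump_config(config: ProgramConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))
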