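"""Content catalog: education items, myth/truth and barrier messages, and
feedback templates, addressed by stable ids.

The catalog ships as a YAML data file so deployments can swap content; the
engine only depends on ids resolving (referential closure is tested).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .assessment import MatrixPlacement
from .model import BehaviorId, EDUCATION_ONLY_TOPICS, UnknownContentError, ValidationError

CONTENT_KINDS = ("video", "tip", "myth_truth", "barrier_tip", "feedback_template")


@dataclass(frozen=True)
class ContentItem:
    content_id: str
    behavior: str  # behavior id, education-only topic, or "global"
    kind: str
    title: str

    def __post_init__(self) -> None:
        valid = {b.value for b in BehaviorId} | set(EDUCATION_ONLY_TOPICS) | {"global"}
        if self.behavior not in valid:
            raise ValidationError(f"content {self.content_id}: unknown behavior {self.behavior!r}")
        if self.kind not in CONTENT_KINDS:
            raise ValidationError(f"content {self.content_id}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class EducationPlan:
    """Ordered content for one behavior placement.

    ``required`` must be viewed before coaching may start (area 1 only);
    ``optional`` is the open library for the behavior.
    """

    behavior: BehaviorId
    required: tuple[str, ...]
    optional: tuple[str, ...]

    @property
    def gates_coaching(self) -> bool:
        return bool(self.required)


class ContentCatalog:
    def __init__(self, items: Sequence[ContentItem]) -> None:
        self.items = tuple(items)
        self.by_id: dict[str, ContentItem] = {}
        for item in self.items:
            if item.content_id in self.by_id:
                raise ValidationError(f"duplicate content id {item.content_id!r}")
            self.by_id[item.content_id] = item

    # -- lookups ----------------------------------------------------------

    def resolve_message(self, message_id: str) -> ContentItem:
        try:
            return self.by_id[message_id]
        except KeyError:
            raise UnknownContentError(f"unknown content id {message_id!r}") from None

    def _ids(self, behavior: str, kind: str) -> tuple[str, ...]:
        return tuple(i.content_id for i in self.items if i.behavior == behavior and i.kind == kind)

    def myth_ids(self, behavior: BehaviorId) -> tuple[str, ...]:
        return self._ids(behavior.value, "myth_truth")

    def barrier_ids(self, behavior: BehaviorId) -> tuple[str, ...]:
        return self._ids(behavior.value, "barrier_tip")

    def encouragement_id(self, behavior: BehaviorId) -> str:
        ids = tuple(
            i.content_id
            for i in self.items
            if i.behavior == behavior.value and i.kind == "feedback_template"
        )
        if not ids:
            raise UnknownContentError(f"no encouragement message for {behavior.value}")
        return ids[0]

    def feedback_template_ids(self) -> tuple[str, ...]:
        return tuple(
            i.content_id for i in self.items
            if i.kind == "feedback_template" and i.behavior == "global"
        )

    # -- education plan ---------------------------------------------------

    def education_plan(
        self,
        placement: MatrixPlacement,
        knowledge_gaps: Iterable[str] = (),
    ) -> EducationPlan:
        """Select education content for a behavior placement.

        Area 1 (neither knows nor does): the behavior's gap-matched videos
        and tips are required before coaching.  Area 2 (does, does not
        know): same items, but nothing is gated.  Areas 3 and 4: optional
        library only.  ``knowledge_gaps`` may list education-only topics
        whose items are appended (never gating).
        """
        behavior = placement.behavior
        videos = self._ids(behavior.value, "video")
        tips = self._ids(behavior.value, "tip")
        if not videos and not tips:
            raise UnknownContentError(f"no education content for {behavior.value}")
        topic_items: list[str] = []
        for topic in knowledge_gaps:
            if topic == behavior.value:
                continue
            topic_items.extend(self._ids(topic, "video"))
            topic_items.extend(self._ids(topic, "tip"))
        gap_matched = videos + tips + tuple(topic_items)
        if placement.area == 1:
            return EducationPlan(behavior, required=videos, optional=gap_matched)
        if placement.area == 2:
            return EducationPlan(behavior, required=(), optional=gap_matched)
        return EducationPlan(behavior, required=(), optional=videos + tips)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ContentCatalog":
        raw = yaml.safe_load(Path(path).read_text())
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: dict) -> "ContentCatalog":
        return cls(
            [
                ContentItem(
                    content_id=spec["content_id"],
                    behavior=spec["behavior"],
                    kind=spec["kind"],
                    title=spec.get("title", ""),
                )
                for spec in raw["items"]
            ]
        )


def default_catalog() -> ContentCatalog:
    raw = yaml.safe_load(
        resources.files("heartcoach.data").joinpath("catalog.yaml").read_text()
    )
    return ContentCatalog._from_raw(raw)
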