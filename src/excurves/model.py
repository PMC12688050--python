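"""Shared domain types and time conventions.

Tabular event data (encounters, treatment-team events, shifts,
attributions) lives in pandas DataFrames with documented column names;
the reference vocabularies (topic catalog, concept lexicon, crosswalk)
are small validated objects defined here.

Time convention: all timestamps are timezone-naive local time.  Training
time is resident-relative: day 0 is the resident's ``start_date`` and
postgraduate year *n* covers days ``[(n-1)*365, n*365)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime

from .errors import (
    CrosswalkError,
    DanglingCategoryError,
    DuplicateTopicError,
    SynonymCollisionError,
)

DAYS_PER_PGY = 365
N_PGY = 4

#: note sections carrying resident diagnostic reasoning, in canonical order
NOTE_SECTIONS = ("HPI", "MDM", "ED_COURSE")

_WS = re.compile(r"\s+")


def normalize_term(text: str) -> str:
    """Lowercase and collapse whitespace — the lexicon's matching key."""
    return _WS.sub(" ", text.strip().lower())


@dataclass(frozen=True)
class Topic:
    topic_id: str
    category_id: str
    label: str


@dataclass(frozen=True)
class Category:
    category_id: str
    label: str


@dataclass
class TopicCatalog:
    """The practice-model taxonomy: leaf topics under broad categories.

    The default catalog carries 895 leaf topics, the size of the 2022
    emergency-medicine practice model.
    """

    categories: list[Category]
    topics: list[Topic]
    _by_id: dict[str, Topic] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        cat_ids = {c.category_id for c in self.categories}
        if len(cat_ids) != len(self.categories):
            raise DuplicateTopicError("duplicate category_id in catalog")
        seen: dict[str, Topic] = {}
        for t in self.topics:
            if t.topic_id in seen:
                raise DuplicateTopicError(f"duplicate topic_id {t.topic_id!r}")
            if t.category_id not in cat_ids:
                raise DanglingCategoryError(
                    f"topic {t.topic_id!r} references unknown category "
                    f"{t.category_id!r}"
                )
            seen[t.topic_id] = t
        self._by_id = seen

    def __len__(self) -> int:
        return len(self.topics)

    def __contains__(self, topic_id: str) -> bool:
        return topic_id in self._by_id

    @property
    def topic_ids(self) -> list[str]:
        return [t.topic_id for t in self.topics]


@dataclass(frozen=True)
class Concept:
    concept_id: str
    preferred_term: str
    synonyms: tuple[str, ...]


@dataclass
class ConceptLexicon:
    """Concept dictionary: id -> preferred term + synonyms.

    Synonyms are stored normalized (lowercase, collapsed whitespace); a
    normalized synonym mapping to two concepts is a load-time error
    because the matcher must be a function of surface text.
    """

    concepts: list[Concept]
    _syn_to_concept: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [c.concept_id for c in self.concepts]
        if len(set(ids)) != len(ids):
            raise SynonymCollisionError("duplicate concept_id in lexicon")
        normed: list[Concept] = []
        mapping: dict[str, str] = {}
        for c in self.concepts:
            syns = tuple(dict.fromkeys(normalize_term(s) for s in c.synonyms))
            for s in syns:
                prior = mapping.get(s)
                if prior is not None and prior != c.concept_id:
                    raise SynonymCollisionError(
                        f"synonym {s!r} maps to both {prior!r} and "
                        f"{c.concept_id!r}"
                    )
                mapping[s] = c.concept_id
            normed.append(Concept(c.concept_id, c.preferred_term, syns))
        self.concepts = normed
        self._syn_to_concept = mapping

    def __len__(self) -> int:
        return len(self.concepts)

    @property
    def concept_ids(self) -> list[str]:
        return [c.concept_id for c in self.concepts]

    @property
    def synonym_map(self) -> dict[str, str]:
        """normalized synonym -> concept_id"""
        return self._syn_to_concept


@dataclass
class Crosswalk:
    """Total map concept_id -> topic_id (many concepts per topic)."""

    mapping: dict[str, str]

    def validate(self, lexicon: ConceptLexicon, catalog: TopicCatalog) -> None:
        missing = [c for c in lexicon.concept_ids if c not in self.mapping]
        if missing:
            raise CrosswalkError(
                f"crosswalk not total: {len(missing)} concepts unmapped "
                f"(first: {missing[:3]})"
            )
        unknown_c = [c for c in self.mapping if c not in set(lexicon.concept_ids)]
        if unknown_c:
            raise CrosswalkError(f"crosswalk references unknown concepts {unknown_c[:3]}")
        unknown_t = sorted({t for t in self.mapping.values() if t not in catalog})
        if unknown_t:
            raise CrosswalkError(f"crosswalk references unknown topics {unknown_t[:3]}")

    def topic_for(self, concept_id: str) -> str:
        return self.mapping[concept_id]

    def concepts_for_topic(self, topic_id: str) -> list[str]:
        return [c for c, t in self.mapping.items() if t == topic_id]


@dataclass(frozen=True)
class Resident:
    """One trainee.  ``start_date`` is training day 0; ``class_year`` is
    the graduating year."""

    resident_id: str
    class_year: int
    start_date: date


def assign_pgy(resident: Resident, t: datetime | date) -> int | None:
    """Postgraduate year at time ``t``, or None outside training.

    PGY n covers resident-relative days [(n-1)*365, n*365); the rule is
    resident-relative rather than calendar (July 1) so exposure curves
    line up across classes.
    """
    d = t.date() if isinstance(t, datetime) else t
    days = (d - resident.start_date).days
    if days < 0 or days >= N_PGY * DAYS_PER_PGY:
        return None
    return days // DAYS_PER_PGY + 1


def training_day(resident: Resident, t: datetime | date) -> int:
    """Whole days since the resident's start date (may be negative)."""
    d = t.date() if isinstance(t, datetime) else t
    return (d - resident.start_date).days


# Column contracts for the tabular formats (pandas DataFrames).
ENCOUNTER_COLUMNS = ["encounter_id", "patient_id", "arrival_time", "esi", "disposition"]
TEAM_EVENT_COLUMNS = ["encounter_id", "resident_id", "doc_time"]
SHIFT_COLUMNS = ["shift_id", "resident_id", "start", "end", "kind"]
ROSTER_COLUMNS = ["resident_id", "class_year", "start_date"]
ATTRIBUTION_COLUMNS = ["encounter_id", "resident_id", "role", "doc_time", "shift_id"]

DISPOSITIONS = ("admitted", "discharged", "other")
SHIFT_KINDS = ("clinical", "nonclinical")
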