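"""Core event-log record types.

Times are stored as float days since the start of the simulation/analysis
horizon; day-resolution timestamps with fractional parts are allowed
everywhere. All identifiers are opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RISK_LEVELS = ("high", "medium", "low")
GRADES = ("Pass", "PassWithConditions", "Fail")
GROUPS = ("FINDER", "COMPLAINT", "ROUTINE")

#: Concept label under which foodborne-illness topicality is recorded in
#: page prominence maps and query concept tags.
FOODBORNE_CONCEPT = "foodborne_illness"


@dataclass(frozen=True)
class Restaurant:
    """A registered venue with an a-priori inspection risk level and a
    latent (ground-truth, never observed by the detector) safety state."""

    id: str
    city: str
    risk_level: str
    latent_unsafe: bool
    p_transmit: float  # per-visit probability of causing infection


@dataclass(frozen=True)
class VisitEvent:
    """One (user, restaurant, time) record from the location history."""

    user_id: str
    restaurant_id: str
    time: float


@dataclass(frozen=True)
class InfectionEvent:
    """A ground-truth infection: exposure at a restaurant followed by
    symptom onset within the incubation window."""

    user_id: str
    source_restaurant_id: str
    exposure_time: float
    symptom_onset_time: float


@dataclass
class QueryEvent:
    """One search interaction.

    ``truth_label`` is the hidden is-this-query-about-foodborne-illness
    label. It exists only for evaluation of the classifier and the rater
    simulator; the training pipeline never reads it.
    """

    query_id: str
    user_id: str
    time: float
    query_text: str
    result_urls: list[str] = field(default_factory=list)
    result_titles: list[str] = field(default_factory=list)
    result_snippets: list[str] = field(default_factory=list)
    clicks: list[tuple[str, float]] = field(default_factory=list)  # (url, dwell s)
    concept_tags: list[str] = field(default_factory=list)
    truth_label: bool = False


@dataclass(frozen=True)
class Page:
    """A web page in the result catalog, with per-concept prominence
    scores in [0, 1]."""

    url: str
    title: str
    concept_tags: tuple[str, ...]
    prominence: dict  # concept -> score in [0, 1]


@dataclass(frozen=True)
class InspectionRecord:
    """A graded restaurant inspection with its trigger group and
    severity-coded violation counts."""

    restaurant_id: str
    date: float
    group: str  # FINDER | COMPLAINT | ROUTINE
    grade: str  # Pass | PassWithConditions | Fail
    critical_count: int
    major_count: int
    city: str
    risk_level: str


@dataclass
class World:
    """The synthetic registry: restaurants plus the user population."""

    restaurants: list[Restaurant]
    users: list[str]

    def restaurant_map(self) -> dict[str, Restaurant]:
        return {r.id: r for r in self.restaurants}
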