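"""The location model: link illness-indicative queries to prior restaurant
visits, aggregate user-level incidence per restaurant under differential
privacy, flag high-signal venues, and attribute cases to a source.

A user becomes a case at their first query scoring at or above the cutoff;
every restaurant they visited within the closed incubation window
``[t - W, t]`` is a candidate source. Per restaurant, the signal is the
proportion of distinct visitors who later showed search evidence of illness
(a user contributes at most once per restaurant regardless of how many
queries they issued). Counts are released through the Laplace mechanism
(sensitivity 1 on user counts), clamped at zero. A case is attributed to
the candidate with the maximal signal proportion; ties go to the most
recent visit. The recency rank records how far back the attributed
restaurant sits in the case's visit history (1 = most recent distinct
restaurant, 2 = penultimate, ...).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from foodwatch.exceptions import DegenerateDataError, ParameterError
from foodwatch.types import QueryEvent, VisitEvent


@dataclass
class IllnessCase:
    user_id: str
    first_illness_query_time: float
    #: (restaurant_id, visit_time), ordered most-recent-first; nonempty.
    candidate_visits: list[tuple[str, float]]

    def distinct_candidates(self) -> list[str]:
        """Candidate restaurants in recency order (first appearance wins)."""
        seen: list[str] = []
        for rid, _ in self.candidate_visits:
            if rid not in seen:
                seen.append(rid)
        return seen


@dataclass
class RestaurantSignal:
    restaurant_id: str
    n_visitors: int
    n_flagged: int
    proportion: float
    epsilon: float | None = None
    noisy_n_visitors: float | None = None
    noisy_n_flagged: float | None = None
    noisy_proportion: float | None = None

    def ranking_proportion(self) -> float:
        """Noisy proportion when privacy is on, true proportion otherwise."""
        return (self.noisy_proportion if self.noisy_proportion is not None
                else self.proportion)


@dataclass
class AttributionResult:
    case: IllnessCase
    attributed_restaurant_id: str
    recency_rank: int


def link_cases(scored_queries: list[tuple[QueryEvent, float]],
               score_cutoff: float, visit_log: list[VisitEvent],
               window_days: float) -> tuple[list[IllnessCase], int]:
    """Turn scored queries into illness cases.

    Returns (cases, n_dropped) where n_dropped counts users whose first
    qualifying query had no restaurant visit within the closed window.
    """
    if window_days <= 0:
        raise ParameterError("window_days must be > 0")
    if not 0.0 <= score_cutoff <= 1.0:
        raise ParameterError("score_cutoff must lie in [0, 1]")
    first_hit: dict[str, float] = {}
    for q, s in sorted(scored_queries,
                       key=lambda t: (t[0].time, t[0].query_id)):
        if s >= score_cutoff and q.user_id not in first_hit:
            first_hit[q.user_id] = q.time
    visits_by_user: dict[str, list[VisitEvent]] = defaultdict(list)
    for v in visit_log:
        visits_by_user[v.user_id].append(v)
    cases: list[IllnessCase] = []
    dropped = 0
    for user in sorted(first_hit):
        t = first_hit[user]
        in_window = [(v.restaurant_id, v.time)
                     for v in visits_by_user.get(user, [])
                     if t - window_days <= v.time <= t]
        if not in_window:
            dropped += 1
            continue
        in_window.sort(key=lambda rv: (-rv[1], rv[0]))
        cases.append(IllnessCase(user_id=user, first_illness_query_time=t,
                                 candidate_visits=in_window))
    return cases, dropped


def aggregate_signal(cases: list[IllnessCase], visit_log: list[VisitEvent],
                     period: tuple[float, float]) -> list[RestaurantSignal]:
    """Per-restaurant distinct-visitor and flagged-visitor counts over an
    analysis period. Restaurants with zero visitors in the period are
    omitted."""
    t0, t1 = period
    visitors: dict[str, set[str]] = defaultdict(set)
    for v in visit_log:
        if t0 <= v.time < t1:
            visitors[v.restaurant_id].add(v.user_id)
    flagged: dict[str, set[str]] = defaultdict(set)
    for case in cases:
        for rid, vt in case.candidate_visits:
            if t0 <= vt < t1:
                flagged[rid].add(case.user_id)
    out = []
    for rid in sorted(visitors):
        n_vis = len(visitors[rid])
        n_flag = len(flagged[rid] & visitors[rid])
        out.append(RestaurantSignal(
            restaurant_id=rid, n_visitors=n_vis, n_flagged=n_flag,
            proportion=n_flag / n_vis))
    return out


def privatize_counts(signals: list[RestaurantSignal], epsilon: float,
                     rng: np.random.Generator) -> list[RestaurantSignal]:
    """Release per-restaurant user counts through the Laplace mechanism.

    Independent Laplace(scale = 1/epsilon) noise is added to each count
    (sensitivity 1: one user changes each count by at most one), the noisy
    counts are clamped at zero, and the noisy proportion is recomputed and
    clipped to [0, 1] (0 when the noisy visitor count is 0).
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    scale = 1.0 / epsilon
    out = []
    for s in signals:
        nv = max(0.0, s.n_visitors + float(rng.laplace(0.0, scale)))
        nf = max(0.0, s.n_flagged + float(rng.laplace(0.0, scale)))
        prop = min(1.0, nf / nv) if nv > 0 else 0.0
        out.append(RestaurantSignal(
            restaurant_id=s.restaurant_id, n_visitors=s.n_visitors,
            n_flagged=s.n_flagged, proportion=s.proportion, epsilon=epsilon,
            noisy_n_visitors=nv, noisy_n_flagged=nf, noisy_proportion=prop))
    return out


def flag_restaurants(signals: list[RestaurantSignal],
                     signal_cutoff: float = 0.0, min_visitors: int = 0,
                     top_k: int | None = None) -> list[RestaurantSignal]:
    """Ranked flag list: keep signals with enough visitors and proportion at
    or above the cutoff; order by proportion (desc), then flagged count
    (desc), then id (asc); truncate to ``top_k``."""
    if min_visitors < 0:
        raise ParameterError("min_visitors must be >= 0")
    kept = [s for s in signals
            if s.n_visitors >= min_visitors
            and s.ranking_proportion() >= signal_cutoff]
    kept.sort(key=lambda s: (-s.ranking_proportion(), -s.n_flagged,
                             s.restaurant_id))
    return kept if top_k is None else kept[:top_k]


def attribute_case(case: IllnessCase,
                   signals: dict[str, RestaurantSignal] | list[RestaurantSignal],
                   ) -> AttributionResult:
    """Attribute a case to the candidate restaurant with the strongest
    relative signal; ties resolve to the most recent visit."""
    if not case.candidate_visits:
        raise DegenerateDataError("case has no candidate visits")
    smap = ({s.restaurant_id: s for s in signals}
            if not isinstance(signals, dict) else signals)
    order = case.distinct_candidates()

    def prop(rid: str) -> float:
        s = smap.get(rid)
        return s.ranking_proportion() if s is not None else 0.0

    best = max(order, key=lambda rid: (prop(rid), -order.index(rid)))
    return AttributionResult(case=case, attributed_restaurant_id=best,
                             recency_rank=order.index(best) + 1)


def attribution_histogram(results: list[AttributionResult]) -> dict[str, float]:
    """Distribution of attribution recency ranks over bins 1, 2, 3, 4+."""
    if not results:
        raise DegenerateDataError("no attribution results to summarize")
    bins = {"1": 0, "2": 0, "3": 0, "4+": 0}
    for r in results:
        key = str(r.recency_rank) if r.recency_rank <= 3 else "4+"
        bins[key] += 1
    n = len(results)
    return {k: v / n for k, v in bins.items()}
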