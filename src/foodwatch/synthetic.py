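"""Seeded synthetic world: restaurants, users, visits, infections, queries,
pages, raters, and inspections.

The simulator emulates the statistical structure the detection pipeline
assumes: a minority of latently unsafe restaurants with elevated per-visit
transmission probability, symptom onset within the incubation window after
exposure, noisy and ambiguous query text (typos, off-topic lookalikes),
click-dwell behavior that anchors weak labels, six-rater judgement panels
with role-specific error rates, and inspection outcomes correlated with the
latent safety state.

Reproducibility contract: one master seed; each stage draws from its own
substream derived from (seed, fixed stage offset), so stages are
independently reproducible and inserting a new stage does not perturb the
others.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from foodwatch.config import PipelineConfig
from foodwatch.exceptions import ParameterError
from foodwatch.types import (
    FOODBORNE_CONCEPT,
    RISK_LEVELS,
    InfectionEvent,
    InspectionRecord,
    Page,
    QueryEvent,
    Restaurant,
    VisitEvent,
    World,
)

# Fixed substream offsets (stage name -> offset mixed into the seed).
STAGE_OFFSETS = {
    "world": 11,
    "visits": 23,
    "infections": 37,
    "queries": 41,
    "raters": 53,
    "inspections": 67,
    "privacy": 71,
    "labels": 83,
    "eval": 97,
}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Stage-specific random generator derived from the master seed."""
    return np.random.default_rng([int(seed) % (2**31), STAGE_OFFSETS[stage]])


# ---------------------------------------------------------------------------
# Query vocabulary. Phrases are composed from parts so the synthetic stream
# contains thousands of distinct strings, mimicking the open-ended variety
# of real health-related search language.
# ---------------------------------------------------------------------------

ILLNESS_CORES = (
    "food poisoning", "foodborne illness", "stomach cramps", "diarrhea",
    "vomiting", "nausea", "upset stomach", "stomach bug", "salmonella",
    "e coli", "norovirus", "listeria", "stomach pain", "throwing up",
    "stomach flu",
)
ILLNESS_PREFIXES = (
    "", "signs of", "how long does", "what to do about", "remedies for",
    "treatment for", "can you get", "my kid has", "severe", "sudden",
    "home remedy for", "medicine for", "urgent care for", "is it",
)
ILLNESS_SUFFIXES = (
    "", "after eating", "after eating out", "after restaurant",
    "after eating chicken", "after eating sushi", "last night", "wont stop",
    "and fever", "and chills", "how long", "when to see a doctor",
    "contagious", "treatment",
)

BACKGROUND_TOPICS = (
    "weather", "football scores", "cheap flights", "movie showtimes",
    "tax return", "apartment for rent", "car repair", "phone deals",
    "homework help", "guitar chords", "running shoes", "haircut styles",
    "job openings", "bus schedule", "lottery numbers", "crossword clues",
    "wedding venues", "dog training", "garden tips", "paint colors",
    "computer parts", "credit score", "resume template", "road trip ideas",
    "language classes", "fitness plan", "cookie recipe", "board games",
    "summer camp", "museum hours",
)
BACKGROUND_PREFIXES = (
    "", "best", "cheap", "how to find", "top rated", "local", "compare",
    "easy", "free", "new", "good", "find",
)
BACKGROUND_SUFFIXES = (
    "", "near me", "today", "2016", "reviews", "online", "for beginners",
    "this weekend", "downtown", "open now", "with kids", "deals", "coupons",
    "tips",
)

# Benign phrases that share surface tokens with the illness vocabulary;
# these exercise the classifier's false-positive path.
LOOKALIKE_PHRASES = (
    "food network recipes", "street food festival", "fast food near me",
    "food truck catering", "stomach exercises", "flat stomach workout",
    "stomach sleeper pillow", "flu shot locations", "cold and flu season",
    "sick day email", "sick beats playlist", "eating contest records",
    "restaurant week menu", "diary of a wimpy kid", "comfort food recipes",
)


def _compose(rng: np.random.Generator, prefixes, cores, suffixes) -> str:
    parts = (
        prefixes[rng.integers(len(prefixes))],
        cores[rng.integers(len(cores))],
        suffixes[rng.integers(len(suffixes))],
    )
    return " ".join(p for p in parts if p)


_TYPO_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def inject_typo(text: str, rng: np.random.Generator) -> str:
    """Perturb one character (substitute / delete / transpose / duplicate),
    guaranteeing the result differs from the input."""
    if not text:
        return text
    for _ in range(10):
        i = int(rng.integers(len(text)))
        op = int(rng.integers(4))
        if op == 0:
            c = _TYPO_ALPHABET[rng.integers(26)]
            out = text[:i] + c + text[i + 1:]
        elif op == 1 and len(text) > 1:
            out = text[:i] + text[i + 1:]
        elif op == 2 and i + 1 < len(text):
            out = text[:i] + text[i + 1] + text[i] + text[i + 2:]
        else:
            out = text[:i] + text[i] + text[i:]
        if out != text:
            return out
    return text + "q"


# ---------------------------------------------------------------------------
# Page catalog
# ---------------------------------------------------------------------------

def build_page_catalog() -> list[Page]:
    """Fixed catalog of result pages: topical foodborne-illness pages,
    food-themed lookalikes, and general background pages."""
    pages: list[Page] = []
    topical = (
        ("https://en.wikipedia.org/wiki/Foodborne_illness",
         "Foodborne illness - Wikipedia", 0.95),
        ("https://www.cdc.gov/foodsafety/symptoms.html",
         "Food Poisoning Symptoms | CDC", 0.90),
        ("https://www.mayoclinic.org/diseases/food-poisoning",
         "Food poisoning - Symptoms and causes", 0.85),
        ("https://www.webmd.com/food-poisoning-treatment",
         "Food Poisoning Treatments and Remedies", 0.80),
        ("https://www.healthline.com/health/norovirus",
         "Norovirus Stomach Bug: Symptoms and Treatment", 0.75),
        ("https://www.nhs.uk/conditions/food-poisoning",
         "Food poisoning - NHS", 0.70),
        ("https://www.fda.gov/food/foodborne-pathogens",
         "Foodborne Pathogens and Illness | FDA", 0.65),
        ("https://www.poison.org/articles/food-poisoning",
         "Food Poisoning First Aid - Poison Control", 0.60),
    )
    for url, title, score in topical:
        pages.append(Page(
            url=url, title=title,
            concept_tags=(FOODBORNE_CONCEPT, "health"),
            prominence={FOODBORNE_CONCEPT: score, "health": 0.5},
        ))
    lookalikes = (
        ("https://www.foodnetwork.com/recipes",
         "Recipes and Cooking Shows - Food Network"),
        ("https://www.yelp.com/search?find=restaurants",
         "Best Restaurants Near Me - Yelp"),
        ("https://www.menshealth.com/stomach-workout",
         "Flat Stomach Workout Plan"),
        ("https://www.walgreens.com/flu-shot",
         "Flu Shots and Immunizations"),
        ("https://www.allrecipes.com/comfort-food",
         "Comfort Food Recipes - Allrecipes"),
        ("https://www.eventbrite.com/street-food-festival",
         "Street Food Festival Tickets"),
    )
    for url, title in lookalikes:
        pages.append(Page(
            url=url, title=title, concept_tags=("food",),
            prominence={"food": 0.9, FOODBORNE_CONCEPT: 0.1},
        ))
    for i, topic in enumerate(BACKGROUND_TOPICS[:24]):
        slug = topic.replace(" ", "-")
        pages.append(Page(
            url=f"https://www.example{i:02d}.com/{slug}",
            title=f"{topic.title()} - Official Guide",
            concept_tags=("general",),
            prominence={"general": 0.8},
        ))
    return pages


# ---------------------------------------------------------------------------
# World and event generation
# ---------------------------------------------------------------------------

def generate_world(cfg: PipelineConfig, seed: int) -> World:
    """Create the restaurant registry and user population.

    Exactly ``round(n_restaurants * unsafe_fraction)`` restaurants are
    latently unsafe, chosen uniformly at random; the exact count (rather
    than per-restaurant Bernoulli) keeps small-world tests deterministic.
    """
    cfg.validate()
    rng = substream(seed, "world")
    n = cfg.n_restaurants
    n_unsafe = round(n * cfg.unsafe_fraction)
    unsafe_idx = set(rng.permutation(n)[:n_unsafe].tolist()) if n else set()
    risk_p = (cfg.risk_high, cfg.risk_medium, cfg.risk_low)
    risks = rng.choice(len(RISK_LEVELS), size=n, p=risk_p) if n else []
    cities = rng.integers(len(cfg.cities), size=n) if n else []
    restaurants = []
    for i in range(n):
        unsafe = i in unsafe_idx
        base = cfg.p_transmit_unsafe if unsafe else cfg.p_transmit_safe
        # +-20% multiplicative jitter; classes stay separated as long as
        # 1.2 * p_safe < 0.8 * p_unsafe, which holds for the defaults.
        p = float(np.clip(base * rng.uniform(0.8, 1.2), 0.0, 1.0))
        restaurants.append(Restaurant(
            id=f"r{i:04d}",
            city=cfg.cities[int(cities[i])],
            risk_level=RISK_LEVELS[int(risks[i])],
            latent_unsafe=unsafe,
            p_transmit=p,
        ))
    users = [f"u{i:05d}" for i in range(cfg.n_users)]
    return World(restaurants=restaurants, users=users)


def zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def simulate_visits(world: World, horizon_days: float, visit_rate: float,
                    seed: int, zipf_exponent: float = 1.0) -> list[VisitEvent]:
    """Per-user homogeneous Poisson visit process with restaurant choice by
    Zipf popularity weights over the registry order."""
    if horizon_days < 1:
        raise ParameterError("horizon_days must be >= 1")
    if visit_rate < 0:
        raise ParameterError("visit_rate must be >= 0")
    rng = substream(seed, "visits")
    n_rest = len(world.restaurants)
    if not world.users or not n_rest or visit_rate == 0:
        return []
    counts = rng.poisson(visit_rate * horizon_days, size=len(world.users))
    total = int(counts.sum())
    times = rng.uniform(0.0, horizon_days, size=total)
    weights = zipf_weights(n_rest, zipf_exponent)
    rest_idx = rng.choice(n_rest, size=total, p=weights)
    visits = []
    pos = 0
    for u, c in zip(world.users, counts):
        for k in range(pos, pos + int(c)):
            visits.append(VisitEvent(
                user_id=u,
                restaurant_id=world.restaurants[int(rest_idx[k])].id,
                time=float(times[k]),
            ))
        pos += int(c)
    visits.sort(key=lambda v: (v.time, v.user_id))
    return visits


def _incubation_delays(rng: np.random.Generator, size: int,
                       cfg: PipelineConfig) -> np.ndarray:
    W = cfg.incubation_window_days
    if cfg.incubation_distribution == "uniform":
        return rng.uniform(0.0, W, size=size)
    # Log-normal truncated to [0, W] by inverse-CDF sampling.
    dist = stats.lognorm(s=cfg.incubation_lognorm_sigma,
                         scale=cfg.incubation_lognorm_median_days)
    u = rng.uniform(0.0, dist.cdf(W), size=size)
    return np.clip(dist.ppf(u), 0.0, W)


def simulate_infections(visits: list[VisitEvent], world: World, seed: int,
                        cfg: PipelineConfig) -> list[InfectionEvent]:
    """Each visit independently transmits with the restaurant's per-visit
    probability; symptom onset follows after a delay drawn from the
    incubation distribution truncated to [0, W]."""
    rng = substream(seed, "infections")
    if not visits:
        return []
    pmap = {r.id: r.p_transmit for r in world.restaurants}
    p = np.array([pmap[v.restaurant_id] for v in visits])
    hits = rng.random(len(visits)) < p
    idx = np.flatnonzero(hits)
    delays = _incubation_delays(rng, len(idx), cfg)
    out = []
    for j, i in enumerate(idx):
        v = visits[int(i)]
        out.append(InfectionEvent(
            user_id=v.user_id,
            source_restaurant_id=v.restaurant_id,
            exposure_time=v.time,
            symptom_onset_time=v.time + float(delays[j]),
        ))
    out.sort(key=lambda e: (e.symptom_onset_time, e.user_id))
    return out


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def _illness_query(rng, cfg, pages_topical, pages_background, user_id, time):
    text = _compose(rng, ILLNESS_PREFIXES, ILLNESS_CORES, ILLNESS_SUFFIXES)
    if rng.random() < cfg.typo_rate:
        text = inject_typo(text, rng)
    res = [pages_topical[int(i)] for i in
           rng.choice(len(pages_topical), size=2, replace=False)]
    res += [pages_background[int(i)] for i in
            rng.choice(len(pages_background), size=2, replace=False)]
    clicks = []
    if rng.random() < cfg.illness_click_rate:
        page = res[int(rng.integers(2))]  # one of the topical results
        dwell = float(rng.exponential(cfg.illness_dwell_mean_s))
        clicks.append((page.url, dwell))
    tags = [FOODBORNE_CONCEPT] if rng.random() < cfg.concept_tag_rate else []
    return QueryEvent(
        query_id="", user_id=user_id, time=time, query_text=text,
        result_urls=[p.url for p in res],
        result_titles=[p.title for p in res],
        result_snippets=[_snippet(p) for p in res],
        clicks=clicks, concept_tags=tags, truth_label=True,
    )


def _benign_query(rng, cfg, pages_topical, pages_lookalike, pages_background,
                  user_id, time):
    lookalike = rng.random() < cfg.lookalike_fraction
    if lookalike:
        text = LOOKALIKE_PHRASES[int(rng.integers(len(LOOKALIKE_PHRASES)))]
        if rng.random() < 0.5:
            suffix = BACKGROUND_SUFFIXES[int(rng.integers(len(BACKGROUND_SUFFIXES)))]
            if suffix:
                text = f"{text} {suffix}"
        res = [pages_lookalike[int(rng.integers(len(pages_lookalike)))]]
        if rng.random() < 0.5:
            res.append(pages_topical[int(rng.integers(len(pages_topical)))])
        tags = ["food"] if rng.random() < 0.5 else []
    else:
        text = _compose(rng, BACKGROUND_PREFIXES, BACKGROUND_TOPICS,
                        BACKGROUND_SUFFIXES)
        res = []
        tags = []
    if rng.random() < cfg.typo_rate:
        text = inject_typo(text, rng)
    res += [pages_background[int(i)] for i in
            rng.choice(len(pages_background), size=3, replace=False)]
    clicks = []
    if rng.random() < cfg.benign_click_rate:
        page = res[0]
        clicks.append((page.url, float(rng.exponential(cfg.benign_dwell_mean_s))))
    if lookalike and len(res) > 1 and rng.random() < cfg.lookalike_topical_click_rate:
        topical_in_res = [p for p in res if p.prominence.get(FOODBORNE_CONCEPT, 0) > 0.5]
        if topical_in_res:
            clicks.append((topical_in_res[0].url,
                           float(rng.exponential(cfg.lookalike_topical_dwell_mean_s))))
    return QueryEvent(
        query_id="", user_id=user_id, time=time, query_text=text,
        result_urls=[p.url for p in res],
        result_titles=[p.title for p in res],
        result_snippets=[_snippet(p) for p in res],
        clicks=clicks, concept_tags=tags, truth_label=False,
    )


def _snippet(page: Page) -> str:
    if page.prominence.get(FOODBORNE_CONCEPT, 0.0) >= 0.5:
        return f"{page.title} symptoms causes treatment and prevention"
    return f"{page.title} official site and guide"


def simulate_queries(world: World, infections: list[InfectionEvent],
                     cfg: PipelineConfig, seed: int,
                     ) -> tuple[list[QueryEvent], list[Page]]:
    """Emit the full query stream plus the page catalog.

    Three sources: (1) infected users report their illness with probability
    ``q_report`` starting shortly after symptom onset; (2) uninfected users
    issue illness-topic queries at a small background rate (the classifier's
    false-positive path); (3) all users issue benign queries, a fraction of
    which are off-topic lookalikes sharing tokens with illness vocabulary.
    Hidden ``truth_label`` marks topical relevance, not infection status.

    Query times may extend past the visit horizon by up to the incubation
    window plus the reporting delay, since symptom onset trails exposure.
    """
    rng = substream(seed, "queries")
    pages = build_page_catalog()
    topical = [p for p in pages if p.prominence.get(FOODBORNE_CONCEPT, 0) >= 0.5]
    lookalike = [p for p in pages if p.concept_tags == ("food",)]
    background = [p for p in pages if p.concept_tags == ("general",)]
    queries: list[QueryEvent] = []

    for inf in infections:
        if rng.random() >= cfg.q_report:
            continue
        t0 = inf.symptom_onset_time + float(rng.uniform(0.0, 0.5))
        queries.append(_illness_query(rng, cfg, topical, background,
                                      inf.user_id, t0))
        for _ in range(int(rng.poisson(cfg.extra_illness_queries_rate))):
            t = t0 + float(rng.uniform(0.0, 1.5))
            queries.append(_illness_query(rng, cfg, topical, background,
                                          inf.user_id, t))

    horizon = cfg.horizon_days
    n_bg_ill = rng.poisson(cfg.background_illness_rate * horizon,
                           size=len(world.users))
    n_benign = rng.poisson(cfg.background_query_rate * horizon,
                           size=len(world.users))
    for u, k_ill, k_ben in zip(world.users, n_bg_ill, n_benign):
        for _ in range(int(k_ill)):
            t = float(rng.uniform(0.0, horizon))
            queries.append(_illness_query(rng, cfg, topical, background, u, t))
        for _ in range(int(k_ben)):
            t = float(rng.uniform(0.0, horizon))
            queries.append(_benign_query(rng, cfg, topical, lookalike,
                                         background, u, t))

    queries.sort(key=lambda q: (q.time, q.user_id, q.query_text))
    for i, q in enumerate(queries):
        q.query_id = f"q{i:07d}"
    return queries, pages


# ---------------------------------------------------------------------------
# Raters
# ---------------------------------------------------------------------------

RATER_IDS = ("md_0", "md_1", "md_2", "nm_0", "nm_1", "nm_2")


def simulate_raters(queries: list[QueryEvent], md_error_rate: float,
                    nonmd_error_rate: float, seed: int) -> pd.DataFrame:
    """Six independent judgements per query (three MDs, three non-MDs);
    each judgement flips the hidden truth label with its role's error rate.

    Returns a long-format table: query_id, rater_id, role, judgement.
    """
    for name, e in (("md_error_rate", md_error_rate),
                    ("nonmd_error_rate", nonmd_error_rate)):
        if not 0.0 <= e <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1]")
    rng = substream(seed, "raters")
    rows = []
    for q in queries:
        for rid in RATER_IDS:
            role = "MD" if rid.startswith("md") else "nonMD"
            err = md_error_rate if role == "MD" else nonmd_error_rate
            judgement = q.truth_label ^ (rng.random() < err)
            rows.append((q.query_id, rid, role, bool(judgement)))
    return pd.DataFrame(rows, columns=["query_id", "rater_id", "role",
                                       "judgement"])


# ---------------------------------------------------------------------------
# Inspections
# ---------------------------------------------------------------------------

def simulate_inspections(world: World, flagged_ids: list[str],
                         visits: list[VisitEvent],
                         infections: list[InfectionEvent],
                         cfg: PipelineConfig, seed: int,
                         ) -> list[InspectionRecord]:
    """Inspection outcomes for three trigger groups.

    FINDER: every flagged restaurant is inspected at the end of the period.
    ROUTINE: each restaurant is inspected once with probability
    ``routine_coverage`` at a uniform date. COMPLAINT: each infection
    generates a complaint with probability ``p_complaint``; the complainant
    names their most recently visited restaurant (rather than the true
    source) with probability ``misattribution_rate``. The recorded outcome
    is unsafe with probability ``inspect_sensitivity`` for latently unsafe
    restaurants and ``1 - inspect_specificity`` otherwise; grades and
    violation counts are drawn conditionally on the recorded outcome.
    """
    rng = substream(seed, "inspections")
    rmap = world.restaurant_map()
    unknown = [f for f in flagged_ids if f not in rmap]
    if unknown:
        raise ParameterError(f"flagged ids not in registry: {unknown[:3]}")

    jobs: list[tuple[str, str, float]] = []  # (restaurant_id, group, date)
    for rid in flagged_ids:
        jobs.append((rid, "FINDER", cfg.horizon_days))
    for r in world.restaurants:
        if rng.random() < cfg.routine_coverage:
            jobs.append((r.id, "ROUTINE", float(rng.uniform(0, cfg.horizon_days))))

    visits_by_user: dict[str, list[VisitEvent]] = {}
    for v in visits:
        visits_by_user.setdefault(v.user_id, []).append(v)
    for vs in visits_by_user.values():
        vs.sort(key=lambda v: v.time)
    for inf in infections:
        if rng.random() >= cfg.p_complaint:
            continue
        if rng.random() < cfg.misattribution_rate:
            prior = [v for v in visits_by_user.get(inf.user_id, [])
                     if v.time <= inf.symptom_onset_time]
            target = prior[-1].restaurant_id if prior else inf.source_restaurant_id
        else:
            target = inf.source_restaurant_id
        date = min(inf.symptom_onset_time + float(rng.uniform(0, 2)),
                   cfg.horizon_days)
        jobs.append((target, "COMPLAINT", date))

    records = []
    for rid, group, date in jobs:
        r = rmap[rid]
        p_unsafe = (cfg.inspect_sensitivity if r.latent_unsafe
                    else 1.0 - cfg.inspect_specificity)
        unsafe = rng.random() < p_unsafe
        if unsafe:
            grade = "Fail" if rng.random() < 0.35 else "PassWithConditions"
            critical = int(rng.poisson(1.2))
            major = int(rng.poisson(1.5))
        else:
            grade = "Pass"
            critical = 0
            major = int(rng.poisson(0.4))
        records.append(InspectionRecord(
            restaurant_id=rid, date=float(date), group=group, grade=grade,
            critical_count=critical, major_count=major,
            city=r.city, risk_level=r.risk_level,
        ))
    records.sort(key=lambda x: (x.date, x.restaurant_id, x.group))
    return records


__all__ = [
    "substream", "STAGE_OFFSETS", "generate_world", "simulate_visits",
    "simulate_infections", "simulate_queries", "simulate_raters",
    "simulate_inspections", "build_page_catalog", "inject_typo",
    "zipf_weights", "ILLNESS_CORES", "ILLNESS_PREFIXES", "ILLNESS_SUFFIXES",
    "LOOKALIKE_PHRASES", "BACKGROUND_TOPICS", "RATER_IDS",
]
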