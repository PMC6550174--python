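"""Unit and distributional tests for the synthetic-world simulator."""

import math

import numpy as np
import pytest

from foodwatch.config import PipelineConfig
from foodwatch.exceptions import ParameterError
from foodwatch.inspection_stats import label_outcome
from foodwatch.synthetic import (
    BACKGROUND_PREFIXES,
    BACKGROUND_SUFFIXES,
    BACKGROUND_TOPICS,
    ILLNESS_CORES,
    ILLNESS_PREFIXES,
    ILLNESS_SUFFIXES,
    LOOKALIKE_PHRASES,
    generate_world,
    inject_typo,
    simulate_infections,
    simulate_inspections,
    simulate_queries,
    simulate_raters,
    simulate_visits,
)
from foodwatch.types import InfectionEvent, VisitEvent, World


def _world(seed=0, **kw):
    cfg = PipelineConfig(**kw)
    return cfg, generate_world(cfg, seed)


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def test_empty_registry_is_valid():
    _, world = _world(n_restaurants=0, n_users=0)
    assert world.restaurants == [] and world.users == []


def test_unsafe_count_is_exact():
    _, world = _world(n_restaurants=100, unsafe_fraction=0.2, n_users=10)
    assert sum(r.latent_unsafe for r in world.restaurants) == 20


def test_world_determinism_and_seed_sensitivity():
    cfg = PipelineConfig(n_restaurants=50, n_users=20)
    a = generate_world(cfg, 7)
    b = generate_world(cfg, 7)
    c = generate_world(cfg, 8)
    assert a.restaurants == b.restaurants and a.users == b.users
    assert a.restaurants != c.restaurants


def test_transmission_separation_under_defaults():
    _, world = _world(n_restaurants=200, n_users=10)
    unsafe = [r.p_transmit for r in world.restaurants if r.latent_unsafe]
    safe = [r.p_transmit for r in world.restaurants if not r.latent_unsafe]
    assert min(unsafe) > max(safe)
    assert all(0.0 <= r.p_transmit <= 1.0 for r in world.restaurants)


@pytest.mark.parametrize("bad", [
    {"n_restaurants": -1}, {"n_users": -5}, {"unsafe_fraction": 1.5},
    {"unsafe_fraction": -0.1}, {"visit_rate": -0.2},
])
def test_invalid_world_parameters_rejected(bad):
    with pytest.raises(ParameterError):
        generate_world(PipelineConfig(**bad), 0)


# ---------------------------------------------------------------------------
# Visits
# ---------------------------------------------------------------------------

def test_zero_visit_rate_gives_empty_log():
    cfg, world = _world(n_restaurants=10, n_users=50)
    assert simulate_visits(world, 10, 0.0, 0) == []


def test_visit_total_matches_poisson_model():
    cfg, world = _world(n_restaurants=50, n_users=1000)
    visits = simulate_visits(world, 30, 0.5, 3)
    mean = 1000 * 30 * 0.5
    assert abs(len(visits) - mean) < 3 * math.sqrt(mean)
    assert all(0 <= v.time < 30 for v in visits)


def test_visit_referential_integrity(small_cfg):
    world = generate_world(small_cfg, 1)
    visits = simulate_visits(world, small_cfg.horizon_days,
                             small_cfg.visit_rate, 1)
    ids = {r.id for r in world.restaurants}
    users = set(world.users)
    assert all(v.restaurant_id in ids and v.user_id in users for v in visits)


# ---------------------------------------------------------------------------
# Infections
# ---------------------------------------------------------------------------

def test_zero_transmission_no_infections(small_cfg):
    cfg = PipelineConfig(n_restaurants=20, n_users=200, horizon_days=15,
                         p_transmit_unsafe=0.0, p_transmit_safe=0.0)
    world = generate_world(cfg, 2)
    visits = simulate_visits(world, 15, 0.5, 2)
    assert simulate_infections(visits, world, 2, cfg) == []


@pytest.mark.parametrize("dist", ["uniform", "lognormal"])
@pytest.mark.parametrize("seed", range(4))
def test_incubation_delay_bounded(seed, dist):
    cfg = PipelineConfig(n_restaurants=20, n_users=300, horizon_days=15,
                         p_transmit_unsafe=0.3, p_transmit_safe=0.05,
                         incubation_distribution=dist)
    world = generate_world(cfg, seed)
    visits = simulate_visits(world, 15, 0.5, seed)
    infections = simulate_infections(visits, world, seed, cfg)
    assert infections
    for inf in infections:
        assert 0.0 <= inf.symptom_onset_time - inf.exposure_time <= 3.0


def test_infection_count_near_poisson_binomial_mean(small_cfg):
    world = generate_world(small_cfg, 5)
    visits = simulate_visits(world, 20, 0.5, 5)
    infections = simulate_infections(visits, world, 5, small_cfg)
    pmap = {r.id: r.p_transmit for r in world.restaurants}
    p = np.array([pmap[v.restaurant_id] for v in visits])
    mean, var = p.sum(), (p * (1 - p)).sum()
    assert abs(len(infections) - mean) < 3 * math.sqrt(var)


def test_every_infection_has_one_source(small_cfg):
    world = generate_world(small_cfg, 6)
    visits = simulate_visits(world, 20, 0.5, 6)
    infections = simulate_infections(visits, world, 6, small_cfg)
    ids = {r.id for r in world.restaurants}
    assert all(inf.source_restaurant_id in ids for inf in infections)


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def _illness_vocab():
    out = set()
    for p in ILLNESS_PREFIXES:
        for c in ILLNESS_CORES:
            for s in ILLNESS_SUFFIXES:
                out.add(" ".join(x for x in (p, c, s) if x))
    return out


def test_reporting_users_match_infected_users_exactly():
    cfg = PipelineConfig(n_restaurants=20, n_users=300, horizon_days=15,
                         p_transmit_unsafe=0.3, p_transmit_safe=0.05,
                         q_report=1.0, background_illness_rate=0.0)
    world = generate_world(cfg, 3)
    visits = simulate_visits(world, 15, 0.5, 3)
    infections = simulate_infections(visits, world, 3, cfg)
    queries, _ = simulate_queries(world, infections, cfg, 3)
    illness_users = {q.user_id for q in queries if q.truth_label}
    assert illness_users == {inf.user_id for inf in infections}


def test_zero_typo_rate_gives_verbatim_phrases(small_cfg):
    cfg = PipelineConfig(n_restaurants=20, n_users=300, horizon_days=15,
                         typo_rate=0.0, p_transmit_unsafe=0.2)
    world = generate_world(cfg, 4)
    visits = simulate_visits(world, 15, 0.5, 4)
    infections = simulate_infections(visits, world, 4, cfg)
    queries, _ = simulate_queries(world, infections, cfg, 4)
    vocab = _illness_vocab()
    for q in queries:
        if q.truth_label:
            assert q.query_text in vocab


def test_typo_fraction_matches_configured_rate():
    rate = 0.3
    cfg = PipelineConfig(n_restaurants=20, n_users=500, horizon_days=20,
                         typo_rate=rate, p_transmit_unsafe=0.3,
                         background_illness_rate=0.01)
    world = generate_world(cfg, 9)
    visits = simulate_visits(world, 20, 0.5, 9)
    infections = simulate_infections(visits, world, 9, cfg)
    queries, _ = simulate_queries(world, infections, cfg, 9)
    vocab = _illness_vocab()
    illness = [q for q in queries if q.truth_label]
    n = len(illness)
    assert n > 100
    perturbed = sum(1 for q in illness if q.query_text not in vocab)
    assert abs(perturbed - rate * n) < 3 * math.sqrt(n * rate * (1 - rate))


def test_inject_typo_always_changes_string():
    rng = np.random.default_rng(0)
    for text in ("food poisoning", "a", "diarrhea after eating"):
        for _ in range(50):
            assert inject_typo(text, rng) != text


def test_dwell_times_nonnegative(sim):
    for q in sim["queries"]:
        for _, dwell in q.clicks:
            assert dwell >= 0.0


# ---------------------------------------------------------------------------
# Raters
# ---------------------------------------------------------------------------

def _fake_queries(n, rng, pos_rate=0.3):
    from foodwatch.types import QueryEvent
    return [QueryEvent(query_id=f"q{i}", user_id="u", time=0.0,
                       query_text=f"t{i}",
                       truth_label=bool(rng.random() < pos_rate))
            for i in range(n)]


def test_rater_panel_structure_and_zero_error():
    rng = np.random.default_rng(1)
    queries = _fake_queries(200, rng)
    table = simulate_raters(queries, 0.0, 0.0, 5)
    per_query = table.groupby("query_id")
    assert (per_query.size() == 6).all()
    assert (per_query["role"].apply(lambda r: (r == "MD").sum()) == 3).all()
    truth = {q.query_id: q.truth_label for q in queries}
    assert all(row.judgement == truth[row.query_id]
               for row in table.itertuples())


def test_rater_flip_fraction_matches_error_rate():
    rng = np.random.default_rng(2)
    queries = _fake_queries(1000, rng)
    err = 0.2
    table = simulate_raters(queries, err, err, 6)
    truth = {q.query_id: q.truth_label for q in queries}
    flips = sum(1 for row in table.itertuples()
                if row.judgement != truth[row.query_id])
    n = len(table)
    assert abs(flips - err * n) < 3 * math.sqrt(n * err * (1 - err))


# ---------------------------------------------------------------------------
# Inspections
# ---------------------------------------------------------------------------

def test_perfect_inspection_accuracy_recovers_latent_state():
    cfg = PipelineConfig(n_restaurants=60, n_users=100, horizon_days=15,
                         inspect_sensitivity=1.0, inspect_specificity=1.0,
                         routine_coverage=1.0, p_complaint=0.0)
    world = generate_world(cfg, 8)
    records = simulate_inspections(world, [], [], [], cfg, 8)
    rmap = world.restaurant_map()
    assert len(records) == 60
    for rec in records:
        expected = "unsafe" if rmap[rec.restaurant_id].latent_unsafe else "safe"
        assert label_outcome(rec) == expected


def test_complaints_name_last_visited_restaurant():
    cfg = PipelineConfig(n_restaurants=5, n_users=3, horizon_days=10,
                         p_complaint=1.0, misattribution_rate=1.0,
                         routine_coverage=0.0)
    world = generate_world(cfg, 1)
    rids = [r.id for r in world.restaurants]
    # one user with a single prior visit: the complaint must name it
    visits = [VisitEvent("u00000", rids[2], 1.0)]
    infections = [InfectionEvent("u00000", rids[0], 1.0, 2.0)]
    records = simulate_inspections(world, [], visits, infections, cfg, 1)
    assert [r.restaurant_id for r in records] == [rids[2]]
    assert records[0].group == "COMPLAINT"


def test_routine_unsafe_fraction_matches_mixture_mean():
    sens, spec, frac = 0.85, 0.90, 0.2
    cfg = PipelineConfig(n_restaurants=1000, n_users=10, horizon_days=15,
                         unsafe_fraction=frac, inspect_sensitivity=sens,
                         inspect_specificity=spec, routine_coverage=1.0,
                         p_complaint=0.0)
    world = generate_world(cfg, 11)
    records = simulate_inspections(world, [], [], [], cfg, 11)
    routine = [r for r in records if r.group == "ROUTINE"]
    p = frac * sens + (1 - frac) * (1 - spec)
    n = len(routine)
    n_unsafe = sum(1 for r in routine if label_outcome(r) == "unsafe")
    assert abs(n_unsafe - p * n) < 3 * math.sqrt(n * p * (1 - p))


def test_unknown_flagged_restaurant_rejected(small_cfg):
    world = generate_world(small_cfg, 0)
    with pytest.raises(ParameterError):
        simulate_inspections(world, ["nope"], [], [], small_cfg, 0)
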