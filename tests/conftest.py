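"""Shared fixtures: the default synthetic world (the package's reference
study conditions) is generated once per session and reused by the
end-to-end and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from foodwatch.classifier import sample_evaluation_set, score_queries, train_wsm
from foodwatch.config import PipelineConfig
from foodwatch.synthetic import (
    generate_world,
    simulate_infections,
    simulate_queries,
    simulate_visits,
    substream,
)
from foodwatch.weak_labels import (
    collect_positive_queries,
    identify_topical_pages,
    sample_negative_queries,
)

settings.register_profile(
    "foodwatch",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("foodwatch")

#: Seed of the reference regression world used across end-to-end tests.
REFERENCE_SEED = 7


@pytest.fixture(scope="session")
def default_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def sim(default_cfg):
    """Default-scale synthetic world: ~200 restaurants (20% unsafe),
    ~5,000 users, 60 days."""
    cfg = default_cfg
    world = generate_world(cfg, REFERENCE_SEED)
    visits = simulate_visits(world, cfg.horizon_days, cfg.visit_rate,
                             REFERENCE_SEED, cfg.zipf_exponent)
    infections = simulate_infections(visits, world, REFERENCE_SEED, cfg)
    queries, pages = simulate_queries(world, infections, cfg, REFERENCE_SEED)
    return {
        "cfg": cfg, "seed": REFERENCE_SEED, "world": world,
        "visits": visits, "infections": infections, "queries": queries,
        "pages": pages,
    }


@pytest.fixture(scope="session")
def trained(sim):
    """Weak labels, trained classifier, stream scores, and the stratified
    evaluation sample for the reference world."""
    cfg = sim["cfg"]
    seed = sim["seed"]
    topical = identify_topical_pages(sim["pages"], cfg.prominence_threshold)
    positives = collect_positive_queries(sim["queries"], topical,
                                         cfg.min_dwell_seconds)
    negatives = sample_negative_queries(sim["queries"], positives,
                                        cfg.negative_ratio,
                                        substream(seed, "labels"))
    labeled = positives + negatives
    model = train_wsm(labeled, cfg.feature_dim, cfg.l2_lambda,
                      cfg.max_iter, cfg.tol)
    scores = score_queries(model, sim["queries"])
    train_strings = {lq.query.query_text for lq in labeled}
    eval_queries = sample_evaluation_set(sim["queries"],
                                         cfg.eval_sample_size, topical,
                                         train_strings, substream(seed, "eval"))
    eval_scores = score_queries(model, eval_queries)
    return {
        "topical": topical, "positives": positives, "negatives": negatives,
        "labeled": labeled, "model": model, "scores": scores,
        "train_strings": train_strings, "eval_queries": eval_queries,
        "eval_scores": np.asarray(eval_scores),
    }


@pytest.fixture()
def small_cfg() -> PipelineConfig:
    """A fast small world for unit-level simulation tests."""
    return PipelineConfig(n_restaurants=30, n_users=400, horizon_days=20)
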