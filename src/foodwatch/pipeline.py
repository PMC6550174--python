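"""End-to-end batch pipeline: simulate -> weak-label -> train -> score ->
link -> aggregate -> privatize -> flag -> attribute -> inspect -> evaluate.

The pipeline emulates the daily operational cadence in one batch pass over
the horizon and is fully reproducible from (config, seed). Each stage logs
its record counts; the resolved configuration and its hash are written
next to the outputs. Degenerate worlds (no users, no illness queries) run
to completion with empty flags rather than crashing; statistics that their
data cannot support are recorded as notes instead of estimates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from foodwatch import io as fwio
from foodwatch.agreement import alpha_from_judgements, ground_truth_from_judgements
from foodwatch.attribution import (
    attribute_case,
    attribution_histogram,
    flag_restaurants,
    aggregate_signal,
    link_cases,
    privatize_counts,
)
from foodwatch.classifier import (
    evaluate_wsm,
    sample_evaluation_set,
    score_queries,
    train_wsm,
)
from foodwatch.config import PipelineConfig
from foodwatch.exceptions import (
    DegenerateDataError,
    FoodwatchError,
    SeparationError,
    ShortfallError,
)
from foodwatch.inspection_stats import (
    OutcomeMapping,
    adjusted_mean_violations,
    adjusted_odds_ratio,
    contingency_summary,
    inspections_frame,
    risk_distribution_test,
)
from foodwatch.synthetic import (
    generate_world,
    simulate_infections,
    simulate_inspections,
    simulate_queries,
    simulate_raters,
    simulate_visits,
    substream,
)
from foodwatch.weak_labels import (
    collect_positive_queries,
    identify_topical_pages,
    sample_negative_queries,
    weak_label_quality,
)

log = logging.getLogger("foodwatch.pipeline")


class StageError(FoodwatchError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig, seed: int,
                 out_dir: str | Path) -> dict:
    """Run every stage, write all artifacts under ``out_dir``, and return
    the metrics dictionary (also written as metrics.json)."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    meta = dict(seed=seed, config_hash=chash)
    tf = dict(time_format=cfg.time_format, epoch=cfg.epoch)
    metrics: dict = {"seed": seed, "config_hash": chash}
    cfg.to_yaml(out / "resolved_config.yaml")

    def stage(name):
        log.info("stage %s", name)
        return name

    # --- simulate -------------------------------------------------------
    try:
        stage("simulate")
        world = generate_world(cfg, seed)
        visits = simulate_visits(world, cfg.horizon_days, cfg.visit_rate,
                                 seed, cfg.zipf_exponent)
        infections = simulate_infections(visits, world, seed, cfg)
        queries, pages = simulate_queries(world, infections, cfg, seed)
        fwio.write_restaurants_csv(out / "restaurants.csv",
                                   world.restaurants, **meta)
        fwio.write_visits_csv(out / "visits.csv", visits, **meta, **tf)
        fwio.write_queries_jsonl(out / "queries.jsonl", queries, **meta)
        fwio.write_pages_jsonl(out / "pages.jsonl", pages, **meta)
        metrics["counts"] = {
            "restaurants": len(world.restaurants), "users": len(world.users),
            "visits": len(visits), "infections": len(infections),
            "queries": len(queries),
        }
        log.info("simulated %d visits, %d infections, %d queries",
                 len(visits), len(infections), len(queries))
    except FoodwatchError as exc:
        raise StageError("simulate", exc) from exc

    # --- weak labels and training --------------------------------------
    try:
        stage("build-labels")
        topical = identify_topical_pages(pages, cfg.prominence_threshold)
        positives = collect_positive_queries(queries, topical,
                                             cfg.min_dwell_seconds)
        model = None
        scores = np.zeros(len(queries))
        labeled = []
        if positives:
            rng_labels = substream(seed, "labels")
            negatives = sample_negative_queries(queries, positives,
                                                cfg.negative_ratio,
                                                rng_labels)
            labeled = positives + negatives
            metrics["weak_labels"] = weak_label_quality(labeled)
            stage("train")
            model = train_wsm(labeled, cfg.feature_dim, cfg.l2_lambda,
                              cfg.max_iter, cfg.tol)
            model.save(out / "wsm_model.json")
            metrics["wsm_training"] = model.meta
            stage("score")
            scores = score_queries(model, queries)
        else:
            metrics["weak_labels"] = {"n_labeled": 0, "note":
                                      "no dwell-anchored positives; "
                                      "classifier not trained"}
        score_rows = [(q.query_id, repr(float(s)))
                      for q, s in zip(queries, scores)]
        fwio._write_csv(out / "scores.csv", ("query_id", "score"),
                        score_rows, **meta)
    except FoodwatchError as exc:
        raise StageError("build-labels/train", exc) from exc

    # --- evaluation against raters -------------------------------------
    train_strings = {lq.query.query_text for lq in labeled}
    if model is not None:
        try:
            eval_queries = sample_evaluation_set(
                queries, cfg.eval_sample_size, topical, train_strings,
                substream(seed, "eval"))
            judgements = simulate_raters(eval_queries, cfg.md_error_rate,
                                         cfg.nonmd_error_rate, seed)
            fwio.write_judgements_csv(out / "judgements.csv", judgements,
                                      **meta)
            truth = ground_truth_from_judgements(judgements)
            eval_scores = score_queries(model, eval_queries)
            rater_truth = np.array([bool(truth[q.query_id])
                                    for q in eval_queries])
            hidden_truth = np.array([q.truth_label for q in eval_queries])
            report_rater = evaluate_wsm(eval_scores, rater_truth,
                                        cfg.threshold_policy)
            report_hidden = evaluate_wsm(eval_scores, hidden_truth,
                                         cfg.threshold_policy)
            metrics["wsm_eval"] = {
                "n_eval": len(eval_queries),
                "vs_rater_ground_truth": report_rater.to_dict(),
                "vs_hidden_truth": report_hidden.to_dict(),
                "krippendorff_alpha": alpha_from_judgements(judgements),
            }
        except (ShortfallError, DegenerateDataError) as exc:
            metrics["wsm_eval"] = {"note": f"evaluation skipped: {exc}"}
    else:
        metrics["wsm_eval"] = {"note": "no trained model"}

    # --- location model -------------------------------------------------
    try:
        stage("flag")
        scored = list(zip(queries, scores.tolist()))
        cases, dropped = link_cases(scored, cfg.score_cutoff, visits,
                                    cfg.incubation_window_days)
        signals = aggregate_signal(cases, visits, (0.0, cfg.horizon_days))
        if cfg.epsilon > 0 and signals:
            signals = privatize_counts(signals, cfg.epsilon,
                                       substream(seed, "privacy"))
        flags = flag_restaurants(signals, cfg.signal_cutoff,
                                 cfg.min_visitors, cfg.top_k)
        _write_signals(out / "signals.csv", signals, meta)
        _write_signals(out / "flags.csv", flags, meta)
        unsafe_ids = {r.id for r in world.restaurants if r.latent_unsafe}
        metrics["location_model"] = {
            "cases": len(cases), "cases_dropped_no_visit": dropped,
            "restaurants_with_signal": len(signals),
            "flagged": len(flags),
            "flag_precision_vs_latent": (
                sum(1 for s in flags if s.restaurant_id in unsafe_ids)
                / len(flags) if flags else float("nan")),
        }
        log.info("%d cases (%d dropped), %d flagged", len(cases), dropped,
                 len(flags))
    except FoodwatchError as exc:
        raise StageError("flag", exc) from exc

    # --- attribution ----------------------------------------------------
    try:
        stage("attribute")
        smap = {s.restaurant_id: s for s in signals}
        results = [attribute_case(c, smap) for c in cases]
        if results:
            hist = attribution_histogram(results)
            source_map = _case_sources(cases, infections,
                                       cfg.incubation_window_days)
            attributed_correct = [
                r for r in results
                if r.case.user_id in source_map
                and r.attributed_restaurant_id == source_map[r.case.user_id]]
            with_source = [r for r in results if r.case.user_id in source_map]
            metrics["attribution"] = {
                "n_attributed": len(results),
                "rank_histogram": hist,
                "source_recovery_rate": (
                    len(attributed_correct) / len(with_source)
                    if with_source else float("nan")),
            }
            rows = [(r.case.user_id, r.attributed_restaurant_id,
                     r.recency_rank) for r in results]
            fwio._write_csv(out / "attribution.csv",
                            ("user_id", "attributed_restaurant_id",
                             "recency_rank"), rows, **meta)
        else:
            metrics["attribution"] = {"n_attributed": 0}
    except FoodwatchError as exc:
        raise StageError("attribute", exc) from exc

    # --- inspections and policy evaluation ------------------------------
    try:
        stage("evaluate-inspections")
        flagged_ids = [s.restaurant_id for s in flags]
        inspections = simulate_inspections(world, flagged_ids, visits,
                                           infections, cfg, seed)
        fwio.write_inspections_csv(out / "inspections.csv", inspections,
                                   **meta, **tf)
        mapping = OutcomeMapping(unsafe_grades=tuple(cfg.unsafe_grades),
                                 critical_threshold=cfg.unsafe_critical_threshold)
        df = inspections_frame(inspections, mapping)
        stats: dict = {}
        if not df.empty:
            summary = contingency_summary(df)
            summary.to_csv(out / "inspection_summary.csv", index=False)
            stats["summary"] = summary.to_dict(orient="records")
            stats.update(_inspection_effects(df))
        metrics["inspections"] = {"n": len(inspections), **stats}
    except FoodwatchError as exc:
        raise StageError("evaluate-inspections", exc) from exc

    fwio.write_json(out / "metrics.json", metrics, **meta)
    return metrics


def _case_sources(cases, infections, window):
    """Ground-truth source restaurant per case user: the most recent
    infection whose exposure falls inside the case's window."""
    by_user: dict[str, list] = {}
    for inf in infections:
        by_user.setdefault(inf.user_id, []).append(inf)
    out = {}
    for case in cases:
        t = case.first_illness_query_time
        eligible = [inf for inf in by_user.get(case.user_id, [])
                    if t - window <= inf.exposure_time <= t]
        if eligible:
            out[case.user_id] = max(
                eligible, key=lambda i: i.exposure_time).source_restaurant_id
    return out


def _inspection_effects(df: pd.DataFrame) -> dict:
    """Adjusted odds ratio, adjusted violation means, and the risk-level
    chi-square for flagged vs baseline inspections, with graceful notes
    when the data cannot support a model."""
    out: dict = {}
    base = df[df["group"].isin(("COMPLAINT", "ROUTINE"))]
    finder = df[df["group"] == "FINDER"]
    if finder.empty or base.empty:
        out["note"] = "need both FINDER and baseline inspections for effects"
        return out
    work = pd.concat([finder, base], ignore_index=True)
    work["exposure"] = (work["group"] == "FINDER").astype(int)
    covs = tuple(c for c in ("city", "risk_level") if work[c].nunique() > 1)
    try:
        est = adjusted_odds_ratio(work, "exposure", "unsafe", covs)
        out["adjusted_or_finder_vs_baseline"] = est.to_dict()
    except (SeparationError, DegenerateDataError) as exc:
        out["adjusted_or_finder_vs_baseline"] = {"note": str(exc)}
    for severity in ("critical", "major"):
        try:
            out[f"adjusted_mean_{severity}"] = adjusted_mean_violations(
                work, severity, "exposure", covs)
        except (FoodwatchError, ValueError) as exc:
            out[f"adjusted_mean_{severity}"] = {"note": str(exc)}
    try:
        ca = [int((finder["risk_level"] == r).sum())
              for r in ("high", "medium", "low")]
        cb = [int((base["risk_level"] == r).sum())
              for r in ("high", "medium", "low")]
        stat, dof, p = risk_distribution_test(ca, cb)
        out["risk_distribution_chi2"] = {"statistic": stat, "df": dof, "p": p}
    except (FoodwatchError, ValueError) as exc:
        out["risk_distribution_chi2"] = {"note": str(exc)}
    return out


def _write_signals(path, signals, meta):
    rows = []
    for rank, s in enumerate(signals, start=1):
        rows.append((rank, s.restaurant_id, s.n_visitors, s.n_flagged,
                     repr(s.proportion),
                     "" if s.noisy_n_visitors is None else repr(s.noisy_n_visitors),
                     "" if s.noisy_n_flagged is None else repr(s.noisy_n_flagged),
                     "" if s.noisy_proportion is None else repr(s.noisy_proportion),
                     "" if s.epsilon is None else repr(s.epsilon)))
    fwio._write_csv(path, ("rank", "restaurant_id", "n_visitors", "n_flagged",
                           "proportion", "noisy_n_visitors",
                           "noisy_n_flagged", "noisy_proportion", "epsilon"),
                    rows, **meta)
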