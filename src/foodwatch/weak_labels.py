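"""Automatic (weak) training labels from click-dwell behavior.

No human labels are used anywhere in training. Queries that led to
significant time spent on pages where foodborne-illness concepts are
prominently mentioned become positive examples; negatives are sampled from
the remaining search stream in proportion to traffic. Query strings are
unique across the combined labeled pool, and the train/eval split is
disjoint at the string level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from foodwatch.exceptions import ParameterError, ShortfallError
from foodwatch.types import FOODBORNE_CONCEPT, Page, QueryEvent


@dataclass
class LabeledQuery:
    query: QueryEvent
    label: bool  # True = positive (illness)
    provenance: str  # dwell_anchor | stream_sample


def identify_topical_pages(pages: list[Page],
                           prominence_threshold: float = 0.5,
                           concept: str = FOODBORNE_CONCEPT) -> set[str]:
    """URLs of pages whose prominence for the target concept reaches the
    threshold."""
    return {p.url for p in pages
            if p.prominence.get(concept, 0.0) >= prominence_threshold}


def collect_positive_queries(query_log: list[QueryEvent],
                             topical_pages: set[str],
                             min_dwell_seconds: float = 30.0,
                             ) -> list[LabeledQuery]:
    """Positive examples: queries with at least one click on a topical page
    with dwell >= the threshold. Duplicate strings collapse to the first
    occurrence."""
    if min_dwell_seconds < 0:
        raise ParameterError("min_dwell_seconds must be >= 0")
    seen: dict[str, LabeledQuery] = {}
    for q in query_log:
        if q.query_text in seen:
            continue
        if any(url in topical_pages and dwell >= min_dwell_seconds
               for url, dwell in q.clicks):
            seen[q.query_text] = LabeledQuery(query=q, label=True,
                                              provenance="dwell_anchor")
    return list(seen.values())


def sample_negative_queries(query_log: list[QueryEvent],
                            positives: list[LabeledQuery],
                            ratio: float, rng: np.random.Generator,
                            ) -> list[LabeledQuery]:
    """Negative examples sampled from stream occurrences (traffic-weighted)
    excluding positive strings, de-duplicated to unique strings.

    The target count is ``round(ratio * len(positives))``; a stream too
    small to supply it raises :class:`ShortfallError`.
    """
    if ratio <= 0:
        raise ParameterError("negative ratio must be > 0")
    target = round(ratio * len(positives))
    pos_strings = {lq.query.query_text for lq in positives}
    freqs: dict[str, int] = {}
    first: dict[str, QueryEvent] = {}
    for q in query_log:
        s = q.query_text
        if s in pos_strings:
            continue
        freqs[s] = freqs.get(s, 0) + 1
        first.setdefault(s, q)
    strings = sorted(freqs)
    if len(strings) < target:
        raise ShortfallError(
            f"stream supplies {len(strings)} unique negative strings, "
            f"{target} requested", requested=target, available=len(strings))
    if target == 0:
        return []
    w = np.array([freqs[s] for s in strings], dtype=float)
    picked = rng.choice(len(strings), size=target, replace=False, p=w / w.sum())
    return [LabeledQuery(query=first[strings[int(i)]], label=False,
                         provenance="stream_sample") for i in picked]


def split_train_eval(pool: list[LabeledQuery], eval_fraction: float,
                     rng: np.random.Generator,
                     ) -> tuple[list[LabeledQuery], list[LabeledQuery]]:
    """String-disjoint train/eval split of a labeled pool."""
    if not 0.0 < eval_fraction < 1.0:
        raise ParameterError("eval_fraction must lie in (0, 1)")
    order = rng.permutation(len(pool))
    n_eval = round(eval_fraction * len(pool))
    eval_idx = set(order[:n_eval].tolist())
    train = [pool[i] for i in range(len(pool)) if i not in eval_idx]
    eval_ = [pool[i] for i in range(len(pool)) if i in eval_idx]
    return train, eval_


def weak_label_quality(labeled: list[LabeledQuery]) -> dict:
    """Precision/recall of the weak labels against the hidden truth labels
    (diagnostic only; never used for training)."""
    tp = sum(1 for lq in labeled if lq.label and lq.query.truth_label)
    fp = sum(1 for lq in labeled if lq.label and not lq.query.truth_label)
    fn = sum(1 for lq in labeled if not lq.label and lq.query.truth_label)
    n_pos = tp + fp
    return {
        "n_labeled": len(labeled),
        "n_weak_positive": n_pos,
        "weak_precision": tp / n_pos if n_pos else float("nan"),
        "weak_recall": tp / (tp + fn) if (tp + fn) else float("nan"),
    }
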