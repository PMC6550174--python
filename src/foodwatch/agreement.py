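"""Multi-rater aggregation and inter-rater agreement.

Ground truth for classifier evaluation is the majority vote over six
judgements per query (three medical doctors, three non-MDs); 3-3 ties are
broken by the majority of the three MD votes, which is always defined.
Agreement is quantified by Krippendorff's alpha with the nominal metric,
computed from the standard coincidence-matrix formulation, which handles
missing judgements; items with fewer than two judgements are excluded.
"""

from __future__ import annotations

from collections import Counter
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from foodwatch.exceptions import DegenerateDataError, ParameterError


def aggregate_votes(judgements: Sequence[tuple[str, bool]]) -> bool:
    """Majority vote over (role, judgement) pairs; MD-majority tie-break.

    Requires exactly six judgements of which exactly three carry role
    ``"MD"``.
    """
    if len(judgements) != 6:
        raise ParameterError(f"expected 6 judgements, got {len(judgements)}")
    md = [j for role, j in judgements if role == "MD"]
    if len(md) != 3:
        raise ParameterError(f"expected 3 MD judgements, got {len(md)}")
    votes = sum(1 for _, j in judgements if j)
    if votes > 3:
        return True
    if votes < 3:
        return False
    return sum(md) >= 2


def ground_truth_from_judgements(table: pd.DataFrame) -> pd.Series:
    """Per-item ground truth from a long-format judgement table with
    columns query_id, role, judgement."""
    out = {}
    for qid, grp in table.groupby("query_id", sort=True):
        out[qid] = aggregate_votes(
            list(zip(grp["role"].tolist(), grp["judgement"].tolist())))
    return pd.Series(out, name="truth")


def krippendorff_alpha(matrix: pd.DataFrame | np.ndarray) -> float:
    """Krippendorff's alpha, nominal metric.

    ``matrix`` is items x raters; missing judgements are NaN/None. With
    coincidence matrix o_ck (each co-judged pair within an item weighted by
    1/(m_u - 1)), marginals n_c and total n:

        D_o = sum_{c != k} o_ck / n
        D_e = sum_{c != k} n_c n_k / (n (n - 1))
        alpha = 1 - D_o / D_e

    Raises :class:`DegenerateDataError` when no item has two or more
    judgements (alpha undefined).
    """
    values = np.asarray(pd.DataFrame(matrix), dtype=object)
    rows = []
    for row in values:
        obs = [v for v in row if v is not None and not _is_nan(v)]
        if len(obs) >= 2:
            rows.append(obs)
    if not rows:
        raise DegenerateDataError(
            "alpha undefined: no item has two or more judgements")
    categories: dict[Hashable, int] = {}
    for obs in rows:
        for v in obs:
            categories.setdefault(v, len(categories))
    k = len(categories)
    o = np.zeros((k, k))
    for obs in rows:
        m = len(obs)
        counts = Counter(categories[v] for v in obs)
        for c, nc in counts.items():
            for d, nd in counts.items():
                pairs = nc * (nc - 1) if c == d else nc * nd
                o[c, d] += pairs / (m - 1)
    n_c = o.sum(axis=1)
    n = n_c.sum()
    d_o = (o.sum() - np.trace(o)) / n
    d_e = (n_c[:, None] * n_c[None, :]).sum() - (n_c * n_c).sum()
    d_e /= n * (n - 1)
    if d_e == 0:  # a single category observed -> perfect agreement
        return 1.0
    return float(1.0 - d_o / d_e)


def alpha_from_judgements(table: pd.DataFrame) -> float:
    """Alpha over a long-format judgement table (query_id, rater_id,
    judgement), both rater groups pooled."""
    wide = table.pivot_table(index="query_id", columns="rater_id",
                             values="judgement", aggfunc="first")
    return krippendorff_alpha(wide)


def _is_nan(v) -> bool:
    try:
        return bool(np.isnan(v))
    except TypeError:
        return False
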