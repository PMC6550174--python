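"""Published reference counts from a two-city field deployment.

A search-and-location-based restaurant flagging system was field-tested in
Las Vegas (May-Aug 2016) and Chicago (Nov 2016-Mar 2017); health
departments inspected the flagged venues alongside their usual
complaint-driven and routine inspections, and the published summary counts
below record how many inspections in each trigger group (and risk stratum)
were deemed unsafe. These counts serve as reference inputs for the
tabulation and effect-estimation tools in
:mod:`foodwatch.inspection_stats`; only group-level aggregates were
published, so per-restaurant covariate microdata are not available.
"""

from __future__ import annotations

#: group -> stratum -> (n, n_unsafe). BASELINE is all non-flagged
#: inspections; COMPLAINT and ROUTINE are its two subsets (risk-stratified
#: denominators were published only for FINDER and BASELINE).
FIELD_TRIAL_UNSAFE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "FINDER": {
        "overall": (132, 69),
        "high": (84, 42),
        "medium": (39, 23),
        "low": (9, 4),
    },
    "BASELINE": {
        "overall": (10786, 2662),
        "high": (5702, 1909),
        "medium": (2325, 536),
        "low": (2759, 217),
    },
    "COMPLAINT": {
        "overall": (1291, 508),
    },
    "ROUTINE": {
        "overall": (9495, 2154),
    },
}

#: Chicago-only flagged-venue inspections (complaint-driven inspections
#: were analysed for Chicago alone).
FIELD_TRIAL_CHICAGO_FINDER: tuple[int, int] = (71, 37)

#: Risk-level distribution (high, medium, low) of flagged vs other
#: inspections, as published in the deployment's inspection-count table.
FIELD_TRIAL_RISK_DISTRIBUTION: dict[str, tuple[int, int, int]] = {
    "FINDER": (84, 39, 9),
    "BASELINE": (5702, 2325, 2759),
}

#: Inspections per city: total non-flagged, and the complaint-driven subset
#: (Chicago only; Las Vegas complaints were excluded from analysis).
FIELD_TRIAL_CITY_COUNTS: dict[str, dict[str, int]] = {
    "las_vegas": {"baseline": 4977, "complaint": 0},
    "chicago": {"baseline": 5809, "complaint": 1291},
}


def complaint_share_chicago() -> float:
    """Fraction of Chicago non-flagged inspections that were
    complaint-driven."""
    c = FIELD_TRIAL_CITY_COUNTS["chicago"]
    return c["complaint"] / c["baseline"]
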