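"""Event-log file formats.

Flat tables are CSV with a header row; nested event records (queries,
pages) are JSON Lines. All files are UTF-8. Every file starts with a
metadata block — ``#``-prefixed comment lines for CSV, a ``{"_meta": ...}``
first line for JSONL — carrying the code version, master seed, and
configuration hash, so outputs are traceable to the run that produced
them. Times are written as float days by default, or as ISO-8601
timestamps relative to a configured epoch date.

Readers validate each row against the documented schema and report the
file, line number, and field of the first violation.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from pathlib import Path

import pandas as pd

import foodwatch
from foodwatch.exceptions import SchemaError
from foodwatch.types import (
    InspectionRecord,
    Page,
    QueryEvent,
    Restaurant,
    VisitEvent,
)


def _meta(seed=None, config_hash=None) -> dict:
    out = {"foodwatch_version": foodwatch.__version__}
    if seed is not None:
        out["seed"] = int(seed)
    if config_hash is not None:
        out["config_hash"] = config_hash
    return out


def _time_out(t: float, time_format: str, epoch: str):
    if time_format == "days":
        return repr(float(t))
    base = dt.datetime.fromisoformat(epoch)
    return (base + dt.timedelta(days=float(t))).isoformat()


def _time_in(raw: str, epoch: str) -> float:
    try:
        return float(raw)
    except ValueError:
        pass
    base = dt.datetime.fromisoformat(epoch)
    moment = dt.datetime.fromisoformat(raw)
    return (moment - base).total_seconds() / 86400.0


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------

def _write_csv(path, header, rows, seed=None, config_hash=None):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in _meta(seed, config_hash).items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def _read_csv(path, expected_header):
    """Yield (line_number, row) for data rows; validate the header."""
    path = str(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lineno = 0
        header_seen = False
        for raw in fh:
            lineno += 1
            if raw.startswith("#"):
                continue
            row = next(csv.reader([raw]))
            if not header_seen:
                if row != list(expected_header):
                    raise SchemaError(path, lineno, "header",
                                      f"expected columns {expected_header}, "
                                      f"got {row}")
                header_seen = True
                continue
            if not row or all(cell == "" for cell in row):
                continue
            if len(row) != len(expected_header):
                raise SchemaError(path, lineno, "row",
                                  f"expected {len(expected_header)} fields, "
                                  f"got {len(row)}")
            yield lineno, row
        if not header_seen:
            raise SchemaError(path, lineno or 1, "header", "missing header row")


def _require(path, lineno, field, value, caster):
    if value == "":
        raise SchemaError(str(path), lineno, field, "missing value")
    try:
        return caster(value)
    except (ValueError, TypeError) as exc:
        raise SchemaError(str(path), lineno, field, str(exc)) from exc


# ---------------------------------------------------------------------------
# Restaurants
# ---------------------------------------------------------------------------

RESTAURANT_HEADER = ("id", "city", "risk_level", "latent_unsafe", "p_transmit")


def write_restaurants_csv(path, restaurants: list[Restaurant], seed=None,
                          config_hash=None) -> None:
    rows = [(r.id, r.city, r.risk_level, int(r.latent_unsafe),
             repr(r.p_transmit)) for r in restaurants]
    _write_csv(path, RESTAURANT_HEADER, rows, seed, config_hash)


def read_restaurants_csv(path) -> list[Restaurant]:
    out = []
    for lineno, row in _read_csv(path, RESTAURANT_HEADER):
        rid, city, risk, unsafe, p = row
        out.append(Restaurant(
            id=_require(path, lineno, "id", rid, str),
            city=_require(path, lineno, "city", city, str),
            risk_level=_require(path, lineno, "risk_level", risk, str),
            latent_unsafe=bool(_require(path, lineno, "latent_unsafe",
                                        unsafe, int)),
            p_transmit=_require(path, lineno, "p_transmit", p, float),
        ))
    return out


# ---------------------------------------------------------------------------
# Visits
# ---------------------------------------------------------------------------

VISIT_HEADER = ("user_id", "restaurant_id", "time")


def write_visits_csv(path, visits: list[VisitEvent], seed=None,
                     config_hash=None, time_format="days",
                     epoch="2016-05-01") -> None:
    rows = [(v.user_id, v.restaurant_id,
             _time_out(v.time, time_format, epoch)) for v in visits]
    _write_csv(path, VISIT_HEADER, rows, seed, config_hash)


def read_visits_csv(path, epoch="2016-05-01") -> list[VisitEvent]:
    out = []
    for lineno, row in _read_csv(path, VISIT_HEADER):
        uid, rid, t = row
        if not rid:
            raise SchemaError(str(path), lineno, "restaurant_id",
                              "missing value")
        if not uid:
            raise SchemaError(str(path), lineno, "user_id", "missing value")
        out.append(VisitEvent(
            user_id=uid, restaurant_id=rid,
            time=_require(path, lineno, "time", t,
                          lambda v: _time_in(v, epoch)),
        ))
    return out


# ---------------------------------------------------------------------------
# Inspections
# ---------------------------------------------------------------------------

INSPECTION_HEADER = ("restaurant_id", "date", "group", "grade",
                     "critical_count", "major_count", "city", "risk_level")


def write_inspections_csv(path, records: list[InspectionRecord], seed=None,
                          config_hash=None, time_format="days",
                          epoch="2016-05-01") -> None:
    rows = [(r.restaurant_id, _time_out(r.date, time_format, epoch), r.group,
             r.grade, r.critical_count, r.major_count, r.city, r.risk_level)
            for r in records]
    _write_csv(path, INSPECTION_HEADER, rows, seed, config_hash)


def read_inspections_csv(path, epoch="2016-05-01") -> list[InspectionRecord]:
    out = []
    for lineno, row in _read_csv(path, INSPECTION_HEADER):
        rid, date, group, grade, crit, major, city, risk = row
        if not rid:
            raise SchemaError(str(path), lineno, "restaurant_id",
                              "missing value")
        out.append(InspectionRecord(
            restaurant_id=rid,
            date=_require(path, lineno, "date", date,
                          lambda v: _time_in(v, epoch)),
            group=_require(path, lineno, "group", group, str),
            grade=_require(path, lineno, "grade", grade, str),
            critical_count=_require(path, lineno, "critical_count", crit, int),
            major_count=_require(path, lineno, "major_count", major, int),
            city=city, risk_level=risk,
        ))
    return out


# ---------------------------------------------------------------------------
# Judgements
# ---------------------------------------------------------------------------

JUDGEMENT_HEADER = ("query_id", "rater_id", "role", "judgement")


def write_judgements_csv(path, table: pd.DataFrame, seed=None,
                         config_hash=None) -> None:
    rows = [(r.query_id, r.rater_id, r.role, int(r.judgement))
            for r in table.itertuples(index=False)]
    _write_csv(path, JUDGEMENT_HEADER, rows, seed, config_hash)


def read_judgements_csv(path) -> pd.DataFrame:
    rows = []
    for lineno, row in _read_csv(path, JUDGEMENT_HEADER):
        qid, rater, role, judgement = row
        rows.append((qid, rater, role,
                     bool(_require(path, lineno, "judgement", judgement,
                                   int))))
    return pd.DataFrame(rows, columns=list(JUDGEMENT_HEADER))


# ---------------------------------------------------------------------------
# JSONL: queries and pages
# ---------------------------------------------------------------------------

def _write_jsonl(path, records: list[dict], seed=None, config_hash=None):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"_meta": _meta(seed, config_hash)},
                            sort_keys=True) + "\n")
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _read_jsonl(path):
    path = str(path)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                rec = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise SchemaError(path, lineno, "json", str(exc)) from exc
            if isinstance(rec, dict) and "_meta" in rec:
                continue
            yield lineno, rec


def write_queries_jsonl(path, queries: list[QueryEvent], seed=None,
                        config_hash=None) -> None:
    records = [{
        "query_id": q.query_id, "user_id": q.user_id, "time": q.time,
        "query_text": q.query_text, "result_urls": q.result_urls,
        "result_titles": q.result_titles,
        "result_snippets": q.result_snippets,
        "clicks": [[url, dwell] for url, dwell in q.clicks],
        "concept_tags": q.concept_tags, "truth_label": bool(q.truth_label),
    } for q in queries]
    _write_jsonl(path, records, seed, config_hash)


def read_queries_jsonl(path) -> list[QueryEvent]:
    out = []
    for lineno, rec in _read_jsonl(path):
        for fieldname in ("query_id", "user_id", "time", "query_text"):
            if fieldname not in rec:
                raise SchemaError(str(path), lineno, fieldname,
                                  "missing field")
        out.append(QueryEvent(
            query_id=str(rec["query_id"]), user_id=str(rec["user_id"]),
            time=float(rec["time"]), query_text=str(rec["query_text"]),
            result_urls=list(rec.get("result_urls", [])),
            result_titles=list(rec.get("result_titles", [])),
            result_snippets=list(rec.get("result_snippets", [])),
            clicks=[(str(u), float(d)) for u, d in rec.get("clicks", [])],
            concept_tags=list(rec.get("concept_tags", [])),
            truth_label=bool(rec.get("truth_label", False)),
        ))
    return out


def write_pages_jsonl(path, pages: list[Page], seed=None,
                      config_hash=None) -> None:
    records = [{
        "url": p.url, "title": p.title,
        "concept_tags": list(p.concept_tags), "prominence": p.prominence,
    } for p in pages]
    _write_jsonl(path, records, seed, config_hash)


def read_pages_jsonl(path) -> list[Page]:
    out = []
    for lineno, rec in _read_jsonl(path):
        if "url" not in rec:
            raise SchemaError(str(path), lineno, "url", "missing field")
        out.append(Page(
            url=str(rec["url"]), title=str(rec.get("title", "")),
            concept_tags=tuple(rec.get("concept_tags", [])),
            prominence={k: float(v)
                        for k, v in rec.get("prominence", {}).items()},
        ))
    return out


# ---------------------------------------------------------------------------
# Generic JSON metrics
# ---------------------------------------------------------------------------

def write_json(path, payload: dict, seed=None, config_hash=None) -> None:
    body = {"_meta": _meta(seed, config_hash)}
    body.update(payload)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(body, fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
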