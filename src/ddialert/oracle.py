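"""Independent brute-force recomputation of alert counts.

This module mirrors the study methodology's validation arm: alongside the
rule engine, an independently written query path recomputes daily alert
counts per DDI straight from the raw tables and the JSON rule/concept-set
documents, and the two outputs must be concordant before a rule is trusted.

To keep the two paths independent, this module deliberately imports nothing
from :mod:`ddialert.concept_sets`, :mod:`ddialert.exposure` or
:mod:`ddialert.rules` (an import-boundary test enforces this): concept-set
closure, overlap scanning, factor extraction and tree descent are all
re-implemented here as plain nested scans over the store's row lists and
recursive descent over the raw JSON documents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from importlib import resources

from .cdm import PatientStore

__all__ = [
    "DailyCounts", "ConcordanceReport", "ComparisonError",
    "load_rule_documents", "load_concept_set_documents", "load_config_document",
    "oracle_daily_counts", "oracle_all_daily_counts", "compare",
]

_MISSING = object()  # oracle-local missing marker


class ComparisonError(Exception):
    pass


@dataclass
class DailyCounts:
    ddi_id: str
    counts: dict[date, int] = field(default_factory=dict)          # basic pairs/day
    leaf_counts: dict[tuple[date, str], int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# Document loading (raw dicts; no shared parser)
# ---------------------------------------------------------------------------

def load_rule_documents() -> list[dict]:
    root = resources.files("ddialert").joinpath("data/rules")
    return [json.loads(f.read_text()) for f in sorted(root.iterdir(),
                                                      key=lambda p: p.name)
            if f.name.endswith(".json")]


def load_concept_set_documents() -> dict[str, dict]:
    root = resources.files("ddialert").joinpath("data/concept_sets")
    out = {}
    for f in sorted(root.iterdir(), key=lambda p: p.name):
        if not f.name.endswith(".json") or f.name == "manifest.json":
            continue
        doc = json.loads(f.read_text())
        out[doc["set_id"]] = doc
    return out


def load_config_document() -> dict:
    return json.loads(
        resources.files("ddialert").joinpath("data/context_config.json").read_text())


# ---------------------------------------------------------------------------
# Concept-set closure by hand-rolled breadth-first traversal
# ---------------------------------------------------------------------------

def _resolve_members(set_doc: dict, store: PatientStore) -> set[int]:
    members = set(set_doc["seed_concept_ids"])
    if set_doc.get("include_descendants"):
        children: dict[int, list[int]] = {}
        for parent, child in store.concept_ancestry:
            children.setdefault(parent, []).append(child)
        frontier = list(members)
        while frontier:
            nxt = []
            for cid in frontier:
                for child in children.get(cid, ()):
                    if child not in members:
                        members.add(child)
                        nxt.append(child)
            frontier = nxt
    members -= set(set_doc.get("excluded_concept_ids", ()))
    return members


# ---------------------------------------------------------------------------
# Factor extraction from raw rows
# ---------------------------------------------------------------------------

def _units_equal(u1: str, u2: str, config: dict) -> bool:
    if u1 == u2:
        return True
    return any(u1 in g and u2 in g for g in config.get("unit_equivalences", []))


def _lab_lookback_days(params: dict, set_id: str, config: dict) -> float:
    if "lookback_hours" in params:
        return float(params["lookback_hours"]) / 24.0
    if "lookback_days" in params:
        return float(params["lookback_days"])
    hours = config.get("lab_lookback_hours", {})
    if set_id in hours:
        return float(hours[set_id]) / 24.0
    return float(config.get("default_lab_lookback_days", 30.0))


def _factor_values(store: PatientStore, person, obj, prec, as_of: datetime,
                   tree_doc: dict, sets: dict[str, set[int]],
                   config: dict) -> dict:
    values: dict[str, object] = {}
    for f in tree_doc["factors"]:
        name, extractor = f["name"], f["extractor"]
        params = f.get("params", {})
        if extractor == "sex":
            values[name] = person.sex.value
        elif extractor == "age":
            b = person.birth_date
            d = as_of.date()
            values[name] = d.year - b.year - ((d.month, d.day) < (b.month, b.day))
        elif extractor == "latest_lab":
            members = sets[params["set"]]
            lookback = _lab_lookback_days(params, params["set"], config)
            horizon = as_of - timedelta(days=lookback)
            best = None
            for m in store.measurements:
                if m.person_id != person.person_id:
                    continue
                if m.measurement_concept_id not in members:
                    continue
                if not (horizon <= m.taken_datetime <= as_of):
                    continue
                if "unit" in params and not _units_equal(m.unit, params["unit"],
                                                         config):
                    continue
                if best is None or (m.taken_datetime, m.measurement_id) > (
                        best.taken_datetime, best.measurement_id):
                    best = m
            values[name] = best.value if best is not None else _MISSING
        elif extractor == "condition_present":
            members = sets[params["set"]]
            mode = params.get("mode", "EVER")
            hit = False
            for c in store.conditions:
                if c.person_id != person.person_id:
                    continue
                if c.condition_concept_id not in members:
                    continue
                if c.start_date > as_of.date():
                    continue
                if mode == "EVER" or c.end_date is None or c.end_date >= as_of.date():
                    hit = True
                    break
            values[name] = hit
        elif extractor == "concomitant_drug":
            members = sets[params["set"]]
            own = {obj.exposure_id, prec.exposure_id}
            hit = False
            for e in store.drug_exposures:
                if (e.person_id == person.person_id
                        and e.exposure_id not in own
                        and e.drug_concept_id in members
                        and e.start_datetime <= as_of <= e.end_datetime):
                    hit = True
                    break
            values[name] = hit
        elif extractor == "drug_discontinued":
            members = sets[params["set"]]
            window = float(params.get("window_days",
                                      config.get("discontinuation_window_days", 7)))
            horizon = as_of - timedelta(days=window)
            ongoing = False
            recent_end = False
            for e in store.drug_exposures:
                if e.person_id != person.person_id or \
                        e.drug_concept_id not in members:
                    continue
                if e.start_datetime <= as_of < e.end_datetime:
                    ongoing = True
                if horizon <= e.end_datetime <= as_of:
                    recent_end = True
            values[name] = recent_end and not ongoing
        elif extractor == "drug_dose":
            e = obj if params["which"] == "object" else prec
            values[name] = e.daily_dose_value if e.daily_dose_value is not None \
                else _MISSING
        elif extractor == "drug_route":
            e = obj if params["which"] == "object" else prec
            values[name] = e.route.value if e.route is not None else _MISSING
        elif extractor == "drug_in_set":
            e = obj if params["which"] == "object" else prec
            values[name] = e.drug_concept_id in sets[params["set"]]
        elif extractor == "dose_tier":
            e = obj if params["which"] == "object" else prec
            if e.daily_dose_value is None:
                values[name] = _MISSING
            else:
                tier_value = _MISSING
                for tier in params.get("tiers", []):
                    if e.drug_concept_id in sets[tier["set"]]:
                        tier_value = "HIGH" if e.daily_dose_value >= \
                            float(tier["high_at"]) else "LOW"
                        break
                values[name] = tier_value
        elif extractor == "visit_context":
            containing = [v for v in store.visits
                          if v.person_id == person.person_id
                          and v.start_datetime <= as_of <= v.end_datetime]
            if not containing:
                values[name] = _MISSING
            else:
                inpatient = any(
                    (v.visit_kind is not None and v.visit_kind.value == "INPATIENT")
                    or (v.end_datetime - v.start_datetime) >= timedelta(hours=24)
                    for v in containing)
                values[name] = "INPATIENT" if inpatient else "OUTPATIENT"
        elif extractor == "threshold_flag":
            src = values[params["source"]]
            if src is _MISSING:
                values[name] = _MISSING
            else:
                cmp_ = params["comparator"]
                t = params["threshold"]
                values[name] = {"LT": src < t, "LE": src <= t, "GT": src > t,
                                "GE": src >= t, "EQ": src == t}[cmp_]
        elif extractor == "equals_flag":
            src = values[params["source"]]
            values[name] = _MISSING if src is _MISSING else src == params["value"]
        elif extractor == "count_true":
            count_missing = params.get("count_missing", True)
            n = 0
            for source in params["sources"]:
                v = values[source]
                if v is _MISSING:
                    n += 1 if count_missing else 0
                elif v is True:
                    n += 1
            values[name] = n
        else:
            raise ComparisonError(f"oracle does not support extractor {extractor!r}")
    return values


def _descend(tree_doc: dict, values: dict) -> str:
    """Recursive descent over the raw node dicts; returns the leaf_id."""
    node = tree_doc["nodes"][tree_doc["root"]]
    while node["kind"] != "LEAF":
        v = values[node["factor"]]
        comparator = node["comparator"]
        if comparator == "PRESENT":
            outcome = v is not _MISSING
        elif comparator == "ABSENT":
            outcome = v is _MISSING
        elif v is _MISSING:
            outcome = node.get("missing_branch", "TRUE_BRANCH") == "TRUE_BRANCH"
        elif comparator == "EQ":
            outcome = v == node["threshold"]
        elif comparator == "IN_SET":
            outcome = v in node["threshold"]
        elif comparator == "LT":
            outcome = v < node["threshold"]
        elif comparator == "LE":
            outcome = v <= node["threshold"]
        elif comparator == "GT":
            outcome = v > node["threshold"]
        elif comparator == "GE":
            outcome = v >= node["threshold"]
        else:
            raise ComparisonError(f"oracle: unknown comparator {comparator!r}")
        node = tree_doc["nodes"][node["true_branch" if outcome else "false_branch"]]
    return node["leaf_id"]


# ---------------------------------------------------------------------------
# Daily counts
# ---------------------------------------------------------------------------

def oracle_daily_counts(store: PatientStore, tree_doc: dict,
                        set_docs: dict[str, dict], config: dict) -> DailyCounts:
    """Daily alert counts for one DDI by exhaustive nested scans: every pair
    of overlapping in-set exposures per person is found, classified by
    descending the raw rule document, and grouped by the calendar date of the
    trigger (start of the later-starting exposure)."""
    set_ids = {tree_doc["object_set"], tree_doc["precipitant_set"]}
    for f in tree_doc["factors"]:
        params = f.get("params", {})
        if "set" in params:
            set_ids.add(params["set"])
        for tier in params.get("tiers", []):
            set_ids.add(tier["set"])
    missing_sets = set_ids - set_docs.keys()
    if missing_sets:
        raise ComparisonError(
            f"{tree_doc['ddi_id']}: no concept-set document for {sorted(missing_sets)}")
    sets = {sid: _resolve_members(set_docs[sid], store) for sid in set_ids}

    persons = {p.person_id: p for p in store.persons}
    exposures_by_person: dict[int, list] = {}
    for e in store.drug_exposures:
        exposures_by_person.setdefault(e.person_id, []).append(e)

    result = DailyCounts(ddi_id=tree_doc["ddi_id"])
    obj_members = sets[tree_doc["object_set"]]
    prec_members = sets[tree_doc["precipitant_set"]]
    for person_id, exposures in exposures_by_person.items():
        person = persons[person_id]
        for ea in exposures:
            if ea.drug_concept_id not in obj_members:
                continue
            for eb in exposures:
                if eb.drug_concept_id not in prec_members:
                    continue
                if ea.exposure_id == eb.exposure_id:
                    continue
                if not (ea.start_datetime <= eb.end_datetime
                        and eb.start_datetime <= ea.end_datetime):
                    continue
                trigger = max(ea.start_datetime, eb.start_datetime)
                values = _factor_values(store, person, ea, eb, trigger,
                                        tree_doc, sets, config)
                leaf_id = _descend(tree_doc, values)
                day = trigger.date()
                result.counts[day] = result.counts.get(day, 0) + 1
                key = (day, leaf_id)
                result.leaf_counts[key] = result.leaf_counts.get(key, 0) + 1
    return result


def oracle_all_daily_counts(store: PatientStore,
                            tree_docs: list[dict] | None = None,
                            set_docs: dict[str, dict] | None = None,
                            config: dict | None = None) -> list[DailyCounts]:
    tree_docs = tree_docs if tree_docs is not None else load_rule_documents()
    set_docs = set_docs if set_docs is not None else load_concept_set_documents()
    config = config if config is not None else load_config_document()
    return [oracle_daily_counts(store, doc, set_docs, config) for doc in tree_docs]


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

@dataclass
class Discrepancy:
    ddi_id: str
    day: date
    leaf_id: str | None  # None: basic daily total; else per-leaf daily count
    engine: int
    oracle: int

    def __str__(self):
        what = "basic" if self.leaf_id is None else f"leaf {self.leaf_id}"
        return (f"{self.ddi_id} {self.day.isoformat()} [{what}]: "
                f"engine={self.engine} oracle={self.oracle}")


@dataclass
class ConcordanceReport:
    discrepancies: list[Discrepancy]
    engine_totals: dict[str, int]
    oracle_totals: dict[str, int]

    @property
    def concordant(self) -> bool:
        return not self.discrepancies

    def to_text(self) -> str:
        lines = [f"{'DDI':35s} {'engine':>8s} {'oracle':>8s}"]
        for ddi in sorted(self.engine_totals):
            lines.append(f"{ddi:35s} {self.engine_totals[ddi]:8d} "
                         f"{self.oracle_totals[ddi]:8d}")
        if self.concordant:
            lines.append("CONCORDANT: engine and query outputs agree on every "
                         "per-DDI daily count")
        else:
            lines.append(f"DISCORDANT: {len(self.discrepancies)} discrepancies")
            lines += [f"  {d}" for d in self.discrepancies]
        return "\n".join(lines)


def compare(engine_report, oracle_counts: list[DailyCounts]) -> ConcordanceReport:
    """Enumerate per-(DDI, date) differences between the engine run report and
    the oracle's daily counts; both basic totals and per-leaf daily counts are
    compared."""
    oracle_by_ddi = {c.ddi_id: c for c in oracle_counts}
    engine_by_ddi = engine_report.per_ddi
    if set(oracle_by_ddi) != set(engine_by_ddi):
        raise ComparisonError(
            f"ddi_id sets differ: engine={sorted(engine_by_ddi)} "
            f"oracle={sorted(oracle_by_ddi)}")
    discrepancies: list[Discrepancy] = []
    for ddi_id in sorted(engine_by_ddi):
        engine_daily = engine_by_ddi[ddi_id].daily_counts
        oracle_daily = oracle_by_ddi[ddi_id].counts
        for day in sorted(set(engine_daily) | set(oracle_daily)):
            ne, no = engine_daily.get(day, 0), oracle_daily.get(day, 0)
            if ne != no:
                discrepancies.append(Discrepancy(ddi_id, day, None, ne, no))
        engine_leaf = engine_by_ddi[ddi_id].daily_leaf_counts
        oracle_leaf = oracle_by_ddi[ddi_id].leaf_counts
        for key in sorted(set(engine_leaf) | set(oracle_leaf)):
            ne, no = engine_leaf.get(key, 0), oracle_leaf.get(key, 0)
            if ne != no:
                discrepancies.append(Discrepancy(ddi_id, key[0], key[1], ne, no))
    return ConcordanceReport(
        discrepancies=discrepancies,
        engine_totals={d: sum(engine_by_ddi[d].daily_counts.values())
                       for d in engine_by_ddi},
        oracle_totals={d: oracle_by_ddi[d].total() for d in oracle_by_ddi},
    )
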