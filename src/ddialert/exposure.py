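"""Concomitant-exposure triggers and patient-context extraction.

A *basic concomitant exposure* — the event that would fire a conventional,
uncontextualized DDI alert — is a pair of drug exposures, one from the
object-drug set and one from the precipitant set, whose start/stop periods
overlap (inclusive endpoints).  The trigger time is the start of the
later-starting exposure, emulating the order-entry moment at which a CDS
alert would fire.

For each trigger, :func:`build_context` snapshots the factors a decision tree
declares in its factor manifest: demographics, most-recent lab values within
a lookback window, active or historical conditions, concomitant drug classes,
recent discontinuations, dose/route of the paired exposures, and the visit
setting.  A factor that cannot be determined is ``MISSING`` rather than an
error; each predicate node of a tree states which branch a MISSING value
takes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

from .cdm import DrugExposure, PatientStore, Person, VisitKind

__all__ = [
    "MISSING", "Missing", "ConcomitantPair", "PatientContext", "ContextConfig",
    "exposures_overlap", "find_concomitant_pairs", "latest_measurement",
    "age_at", "has_active_condition", "detect_discontinuation", "build_context",
    "compute_derived_factors", "BASE_EXTRACTORS", "DERIVED_EXTRACTORS",
    "ContextError",
]


class Missing:
    """Singleton marker for a factor value that cannot be determined."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        return False


MISSING = Missing()


class ContextError(Exception):
    """A tree declares a factor no extractor supports, or params are invalid."""


@dataclass(frozen=True)
class ConcomitantPair:
    person_id: int
    object_exposure_id: int
    precipitant_exposure_id: int
    trigger_datetime: datetime
    overlap_start: datetime
    overlap_end: datetime


@dataclass
class PatientContext:
    person_id: int
    as_of: datetime
    age_years: int
    sex: str
    factor_values: dict[str, object] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)


@dataclass
class ContextConfig:
    """Lookback windows, the discontinuation window and unit equivalences.

    ``lab_lookbacks`` maps a lab concept-set id to a window in hours; a lab
    set without an entry uses ``default_lab_lookback_days``.  Defaults: serum
    potassium 72 h (an inpatient-style recency requirement), QTc 30 days.
    mEq/L and mmol/L are numerically identical for potassium and are declared
    equivalent.
    """

    default_lab_lookback_days: float = 30.0
    lab_lookback_hours: dict[str, float] = field(
        default_factory=lambda: {"serum_potassium": 72.0, "qtc_interval": 720.0})
    discontinuation_window_days: float = 7.0
    unit_equivalences: list[list[str]] = field(
        default_factory=lambda: [["mEq/L", "mmol/L"]])

    @classmethod
    def from_json(cls, path: str | Path) -> "ContextConfig":
        doc = json.loads(Path(path).read_text())
        return cls(
            default_lab_lookback_days=float(doc.get("default_lab_lookback_days", 30.0)),
            lab_lookback_hours={k: float(v) for k, v in
                                doc.get("lab_lookback_hours", {}).items()},
            discontinuation_window_days=float(doc.get("discontinuation_window_days", 7.0)),
            unit_equivalences=[list(g) for g in doc.get("unit_equivalences", [])],
        )

    def units_equivalent(self, u1: str, u2: str) -> bool:
        if u1 == u2:
            return True
        return any(u1 in group and u2 in group for group in self.unit_equivalences)


# ---------------------------------------------------------------------------
# Trigger detection
# ---------------------------------------------------------------------------

def exposures_overlap(e1: DrugExposure, e2: DrugExposure) -> bool:
    """True iff the closed intervals [start, end] of the two exposures
    intersect.  Inclusive endpoints: a drug stopped the day another starts
    still counts as concomitant (the alert-retaining reading)."""
    return e1.start_datetime <= e2.end_datetime and e2.start_datetime <= e1.end_datetime


def find_concomitant_pairs(store: PatientStore, set_a, set_b) -> list[ConcomitantPair]:
    """All (object, precipitant) exposure pairs with overlapping periods.

    One pair per unique exposure combination: two same-drug orders entered at
    an identical start timestamp but with different sig directions are
    distinct exposures and yield distinct pairs.  Self-pairs (the same
    exposure row on both sides) are excluded.  Output is sorted by
    (person_id, trigger, exposure ids), so it is invariant under permutation
    of the input rows.
    """
    by_person: dict[int, list[DrugExposure]] = {}
    for e in store.drug_exposures:
        by_person.setdefault(e.person_id, []).append(e)

    pairs: list[ConcomitantPair] = []
    for person_id, exposures in by_person.items():
        objs = [e for e in exposures if e.drug_concept_id in set_a.member_concept_ids]
        precs = [e for e in exposures if e.drug_concept_id in set_b.member_concept_ids]
        for ea in objs:
            for eb in precs:
                if ea.exposure_id == eb.exposure_id:
                    continue
                if not exposures_overlap(ea, eb):
                    continue
                start = max(ea.start_datetime, eb.start_datetime)
                end = min(ea.end_datetime, eb.end_datetime)
                pairs.append(ConcomitantPair(
                    person_id=person_id,
                    object_exposure_id=ea.exposure_id,
                    precipitant_exposure_id=eb.exposure_id,
                    trigger_datetime=start,
                    overlap_start=start,
                    overlap_end=end,
                ))
    pairs.sort(key=lambda p: (p.person_id, p.trigger_datetime,
                              p.object_exposure_id, p.precipitant_exposure_id))
    return pairs


# ---------------------------------------------------------------------------
# Factor primitives
# ---------------------------------------------------------------------------

def latest_measurement(store: PatientStore, person_id: int, lab_set, as_of: datetime,
                       lookback_days: float, expected_unit: str | None = None,
                       config: ContextConfig | None = None):
    """Most recent in-window measurement from ``lab_set``: greatest
    ``taken_datetime`` with ``as_of - lookback <= taken <= as_of``.

    Never peeks into the future.  When ``expected_unit`` is given,
    measurements in a non-equivalent unit are ignored.  Returns the
    :class:`~ddialert.cdm.Measurement` or ``MISSING``.
    """
    if lookback_days <= 0:
        raise ValueError("lookback_days must be positive")
    config = config or ContextConfig()
    horizon = as_of - timedelta(days=lookback_days)
    best = None
    for m in store.measurements:
        if m.person_id != person_id:
            continue
        if m.measurement_concept_id not in lab_set.member_concept_ids:
            continue
        if not (horizon <= m.taken_datetime <= as_of):
            continue
        if expected_unit is not None and not config.units_equivalent(m.unit, expected_unit):
            continue
        if best is None or (m.taken_datetime, m.measurement_id) > (
                best.taken_datetime, best.measurement_id):
            best = m
    return best if best is not None else MISSING


def age_at(person: Person, as_of: datetime) -> int:
    """Completed years at ``as_of`` (birthday-anniversary convention:
    the anniversary day itself counts)."""
    d = as_of.date()
    if d < person.birth_date:
        raise ValueError(f"as_of {d} precedes birth_date {person.birth_date}")
    b = person.birth_date
    return d.year - b.year - ((d.month, d.day) < (b.month, b.day))


def has_active_condition(store: PatientStore, person_id: int, cond_set,
                         as_of: datetime, mode: str = "EVER") -> bool:
    """EVER ("history of …"): any occurrence started on or before ``as_of``.
    ACTIVE ("has diagnosis of …"): an occurrence whose [start, end-or-open]
    interval contains ``as_of``."""
    if mode not in ("EVER", "ACTIVE"):
        raise ValueError(f"mode must be EVER or ACTIVE, got {mode!r}")
    d = as_of.date()
    for c in store.conditions:
        if c.person_id != person_id:
            continue
        if c.condition_concept_id not in cond_set.member_concept_ids:
            continue
        if c.start_date > d:
            continue
        if mode == "EVER":
            return True
        if c.end_date is None or c.end_date >= d:
            return True
    return False


def detect_discontinuation(store: PatientStore, person_id: int, drug_set,
                           as_of: datetime, window_days: float) -> bool:
    """True iff an exposure from ``drug_set`` ended within
    ``[as_of - window_days, as_of]`` and none is still ongoing.

    Ongoing means ``start <= as_of < end``: an exposure ending exactly at
    ``as_of`` counts as just-discontinued, so a withdrawal can be detected at
    the very trigger that the stopping drug still (inclusively) overlaps.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    horizon = as_of - timedelta(days=window_days)
    ended_recently = False
    for e in store.drug_exposures:
        if e.person_id != person_id or e.drug_concept_id not in drug_set.member_concept_ids:
            continue
        if e.start_datetime <= as_of < e.end_datetime:
            return False  # still ongoing
        if horizon <= e.end_datetime <= as_of:
            ended_recently = True
    return ended_recently


# ---------------------------------------------------------------------------
# Extractors
# ---------------------------------------------------------------------------
# A base extractor reads the store; a derived extractor is a pure function of
# factors computed earlier in the manifest (so the branch-coverage generator
# and the monotonicity property suites can recompute them on hypothetical
# factor assignments without a store).

def _pair_exposures(store: PatientStore, pair: ConcomitantPair):
    idx = {e.exposure_id: e for e in store.drug_exposures}
    return idx[pair.object_exposure_id], idx[pair.precipitant_exposure_id]


def _which(pair_exposures, params):
    which = params.get("which")
    if which == "object":
        return pair_exposures[0]
    if which == "precipitant":
        return pair_exposures[1]
    raise ContextError(f"extractor params need which=object|precipitant, got {which!r}")


def _x_sex(env, params):
    return env["person"].sex.value, env["person"].person_id


def _x_age(env, params):
    return age_at(env["person"], env["as_of"]), env["person"].person_id


def _x_latest_lab(env, params):
    set_id = params["set"]
    config: ContextConfig = env["config"]
    if "lookback_hours" in params:
        lookback_days = float(params["lookback_hours"]) / 24.0
    elif "lookback_days" in params:
        lookback_days = float(params["lookback_days"])
    elif set_id in config.lab_lookback_hours:
        lookback_days = config.lab_lookback_hours[set_id] / 24.0
    else:
        lookback_days = config.default_lab_lookback_days
    m = latest_measurement(env["store"], env["person"].person_id,
                           env["resolve"](set_id), env["as_of"], lookback_days,
                           expected_unit=params.get("unit"), config=config)
    if m is MISSING:
        return MISSING, MISSING
    return m.value, m.measurement_id


def _x_condition_present(env, params):
    value = has_active_condition(env["store"], env["person"].person_id,
                                 env["resolve"](params["set"]), env["as_of"],
                                 mode=params.get("mode", "EVER"))
    return value, env["person"].person_id


def _x_concomitant_drug(env, params):
    members = env["resolve"](params["set"]).member_concept_ids
    own = {env["object"].exposure_id, env["precipitant"].exposure_id}
    for e in env["store"].drug_exposures:
        if (e.person_id == env["person"].person_id
                and e.exposure_id not in own
                and e.drug_concept_id in members
                and e.start_datetime <= env["as_of"] <= e.end_datetime):
            return True, e.exposure_id
    return False, MISSING


def _x_drug_discontinued(env, params):
    window = float(params.get("window_days",
                              env["config"].discontinuation_window_days))
    value = detect_discontinuation(env["store"], env["person"].person_id,
                                   env["resolve"](params["set"]), env["as_of"], window)
    return value, env["person"].person_id


def _x_drug_dose(env, params):
    e = _which((env["object"], env["precipitant"]), params)
    if e.daily_dose_value is None:
        return MISSING, MISSING
    return e.daily_dose_value, e.exposure_id


def _x_drug_route(env, params):
    e = _which((env["object"], env["precipitant"]), params)
    if e.route is None:
        return MISSING, MISSING
    return e.route.value, e.exposure_id


def _x_drug_in_set(env, params):
    e = _which((env["object"], env["precipitant"]), params)
    return e.drug_concept_id in env["resolve"](params["set"]).member_concept_ids, \
        e.exposure_id


def _x_dose_tier(env, params):
    """LOW/HIGH dose tier for the object or precipitant exposure; the tier
    threshold depends on which drug set the exposure's concept falls in
    (e.g. oxycodone mg/day vs fentanyl mcg/hr scales)."""
    e = _which((env["object"], env["precipitant"]), params)
    if e.daily_dose_value is None:
        return MISSING, MISSING
    for tier in params.get("tiers", []):
        if e.drug_concept_id in env["resolve"](tier["set"]).member_concept_ids:
            return ("HIGH" if e.daily_dose_value >= float(tier["high_at"]) else "LOW"), \
                e.exposure_id
    return MISSING, MISSING


def _x_visit_context(env, params):
    """INPATIENT if any visit containing the trigger is flagged inpatient or
    lasts >= 24 h; otherwise OUTPATIENT if some visit contains the trigger;
    MISSING when the trigger falls outside every visit."""
    containing = [v for v in env["store"].visits
                  if v.person_id == env["person"].person_id
                  and v.start_datetime <= env["as_of"] <= v.end_datetime]
    if not containing:
        return MISSING, MISSING
    for v in containing:
        if v.visit_kind == VisitKind.INPATIENT or v.duration_hours >= 24.0:
            return "INPATIENT", v.visit_id
    return "OUTPATIENT", containing[0].visit_id


BASE_EXTRACTORS = {
    "sex": _x_sex,
    "age": _x_age,
    "latest_lab": _x_latest_lab,
    "condition_present": _x_condition_present,
    "concomitant_drug": _x_concomitant_drug,
    "drug_discontinued": _x_drug_discontinued,
    "drug_dose": _x_drug_dose,
    "drug_route": _x_drug_route,
    "drug_in_set": _x_drug_in_set,
    "dose_tier": _x_dose_tier,
    "visit_context": _x_visit_context,
}

_COMPARATORS = {
    "LT": lambda v, t: v < t,
    "LE": lambda v, t: v <= t,
    "GT": lambda v, t: v > t,
    "GE": lambda v, t: v >= t,
    "EQ": lambda v, t: v == t,
}


def _d_threshold_flag(values, params):
    v = values[params["source"]]
    if v is MISSING:
        return MISSING
    return _COMPARATORS[params["comparator"]](v, params["threshold"])


def _d_equals_flag(values, params):
    v = values[params["source"]]
    if v is MISSING:
        return MISSING
    return v == params["value"]


def _d_count_true(values, params):
    """Count of risk factors present; a MISSING component counts as present
    unless ``count_missing`` is false (the sensitivity-preserving reading)."""
    count_missing = params.get("count_missing", True)
    n = 0
    for name in params["sources"]:
        v = values[name]
        if v is MISSING:
            n += 1 if count_missing else 0
        elif v is True:
            n += 1
    return n


DERIVED_EXTRACTORS = {
    "threshold_flag": _d_threshold_flag,
    "equals_flag": _d_equals_flag,
    "count_true": _d_count_true,
}


def compute_derived_factors(tree, values: dict) -> dict:
    """Fill in the derived factors of ``tree``'s manifest from the base factor
    values already present in ``values`` (in manifest order).  Pure; shared by
    the live context builder, the branch-coverage generator and the
    monotonicity test suites."""
    out = dict(values)
    for f in tree.factor_manifest:
        if f.extractor in DERIVED_EXTRACTORS:
            for src in f.source_factors():
                if src not in out:
                    raise ContextError(
                        f"factor {f.name!r}: derived source {src!r} not computed yet "
                        f"(manifest order matters)")
            out[f.name] = DERIVED_EXTRACTORS[f.extractor](out, f.params)
    return out


def build_context(store: PatientStore, pair: ConcomitantPair, tree,
                  config: ContextConfig, library=None) -> PatientContext:
    """Snapshot every factor the tree declares, as of the pair's trigger.

    ``library`` is a :class:`~ddialert.concept_sets.ConceptSetLibrary`; by
    default the bundled one.  Deterministic: the same pair always yields an
    identical context.
    """
    if library is None:
        from .concept_sets import load_bundled_library
        library = load_bundled_library()
    person = store.person(pair.person_id)
    obj, prec = _pair_exposures(store, pair)
    env = {
        "store": store, "person": person, "as_of": pair.trigger_datetime,
        "object": obj, "precipitant": prec, "config": config,
        "resolve": lambda set_id: library.resolve(set_id, store),
    }
    values: dict[str, object] = {}
    provenance: dict[str, object] = {}
    for f in tree.factor_manifest:
        if f.extractor in BASE_EXTRACTORS:
            value, source = BASE_EXTRACTORS[f.extractor](env, f.params)
            values[f.name] = value
            provenance[f.name] = source
        elif f.extractor in DERIVED_EXTRACTORS:
            values[f.name] = DERIVED_EXTRACTORS[f.extractor](values, f.params)
            provenance[f.name] = "derived"
        else:
            raise ContextError(
                f"factor {f.name!r}: no extractor named {f.extractor!r}")
    return PatientContext(
        person_id=person.person_id,
        as_of=pair.trigger_datetime,
        age_years=age_at(person, pair.trigger_datetime),
        sex=person.sex.value,
        factor_values=values,
        provenance=provenance,
    )
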