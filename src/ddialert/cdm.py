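"""Minimal OMOP-CDM-v5-style patient data model.

An in-memory :class:`PatientStore` holds the seven tables every other module
queries: persons, drug exposures, lab measurements, condition occurrences,
visits, the concept vocabulary and the concept ancestry.  Tables are read and
written as comma-delimited text files with OMOP-style column names (see
``COLUMNS``); ISO-8601 timestamps, date-only values promoted to midnight.

All event times are stored as naive timestamps at minute resolution so that
the duplicate-timestamp counting rule (two orders of the same drug entered at
the same instant with different sig directions count separately) can be an
exact equality test.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "Vocabulary", "Sex", "Route", "VisitKind",
    "Concept", "Person", "DrugExposure", "Measurement",
    "ConditionOccurrence", "VisitOccurrence", "PatientStore",
    "IntegrityViolation", "StoreLoadError", "StoreIntegrityError",
    "load_store", "write_store", "validate_store", "filter_visits_min_duration",
]


class Vocabulary(str, enum.Enum):
    RXNORM = "RXNORM"
    LOINC = "LOINC"
    SNOMED = "SNOMED"


class Sex(str, enum.Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"


class Route(str, enum.Enum):
    ORAL = "ORAL"
    IV = "IV"
    TOPICAL = "TOPICAL"
    OPHTHALMIC = "OPHTHALMIC"
    TRANSDERMAL = "TRANSDERMAL"
    LOCAL_INJECTION = "LOCAL_INJECTION"
    OTHER = "OTHER"


class VisitKind(str, enum.Enum):
    INPATIENT = "INPATIENT"
    OUTPATIENT = "OUTPATIENT"
    UNKNOWN = "UNKNOWN"


class StoreLoadError(Exception):
    """A table file is missing or unreadable."""


class StoreIntegrityError(Exception):
    """A loaded store violates referential integrity."""

    def __init__(self, violations: list["IntegrityViolation"]):
        self.violations = violations
        super().__init__(
            "store integrity check failed:\n"
            + "\n".join(f"  - {v}" for v in violations)
        )


@dataclass(frozen=True)
class Concept:
    concept_id: int
    code: str
    vocabulary: Vocabulary
    name: str


@dataclass(frozen=True)
class Person:
    person_id: int
    birth_date: date
    sex: Sex
    ethnicity: str | None = None


@dataclass(frozen=True)
class DrugExposure:
    exposure_id: int
    person_id: int
    drug_concept_id: int
    start_datetime: datetime
    end_datetime: datetime
    daily_dose_value: float | None = None
    daily_dose_unit: str | None = None
    route: Route | None = None
    dose_direction: str | None = None


@dataclass(frozen=True)
class Measurement:
    measurement_id: int
    person_id: int
    measurement_concept_id: int
    taken_datetime: datetime
    value: float
    unit: str


@dataclass(frozen=True)
class ConditionOccurrence:
    person_id: int
    condition_concept_id: int
    start_date: date
    end_date: date | None = None


@dataclass(frozen=True)
class VisitOccurrence:
    visit_id: int
    person_id: int
    start_datetime: datetime
    end_datetime: datetime
    visit_kind: VisitKind | None = None

    @property
    def duration_hours(self) -> float:
        return (self.end_datetime - self.start_datetime).total_seconds() / 3600.0


@dataclass
class PatientStore:
    """In-memory population: the seven CDM-style tables plus lookup indexes."""

    persons: list[Person] = field(default_factory=list)
    drug_exposures: list[DrugExposure] = field(default_factory=list)
    measurements: list[Measurement] = field(default_factory=list)
    conditions: list[ConditionOccurrence] = field(default_factory=list)
    visits: list[VisitOccurrence] = field(default_factory=list)
    concepts: list[Concept] = field(default_factory=list)
    concept_ancestry: list[tuple[int, int]] = field(default_factory=list)

    # -- indexes -------------------------------------------------------------
    def person(self, person_id: int) -> Person:
        return self._person_index()[person_id]

    def _person_index(self) -> dict[int, Person]:
        return {p.person_id: p for p in self.persons}

    def concept_index(self) -> dict[int, Concept]:
        return {c.concept_id: c for c in self.concepts}

    def exposures_of(self, person_id: int) -> list[DrugExposure]:
        return [e for e in self.drug_exposures if e.person_id == person_id]

    def measurements_of(self, person_id: int) -> list[Measurement]:
        return [m for m in self.measurements if m.person_id == person_id]

    def conditions_of(self, person_id: int) -> list[ConditionOccurrence]:
        return [c for c in self.conditions if c.person_id == person_id]

    def visits_of(self, person_id: int) -> list[VisitOccurrence]:
        return [v for v in self.visits if v.person_id == person_id]

    def census(self) -> dict[str, int]:
        """Row counts per table (the fixture manifest quantity)."""
        return {
            "persons": len(self.persons),
            "drug_exposures": len(self.drug_exposures),
            "measurements": len(self.measurements),
            "conditions": len(self.conditions),
            "visits": len(self.visits),
            "concepts": len(self.concepts),
            "concept_ancestor": len(self.concept_ancestry),
        }


# ---------------------------------------------------------------------------
# Delimited-text dialect
# ---------------------------------------------------------------------------

COLUMNS: dict[str, list[str]] = {
    "person": ["person_id", "birth_date", "sex", "ethnicity"],
    "drug_exposure": [
        "drug_exposure_id", "person_id", "drug_concept_id",
        "drug_exposure_start_datetime", "drug_exposure_end_datetime",
        "daily_dose_value", "daily_dose_unit", "route", "dose_direction",
    ],
    "measurement": [
        "measurement_id", "person_id", "measurement_concept_id",
        "measurement_datetime", "value_as_number", "unit",
    ],
    "condition_occurrence": [
        "person_id", "condition_concept_id",
        "condition_start_date", "condition_end_date",
    ],
    "visit_occurrence": [
        "visit_occurrence_id", "person_id",
        "visit_start_datetime", "visit_end_datetime", "visit_kind",
    ],
    "concept": ["concept_id", "concept_code", "vocabulary_id", "concept_name"],
    "concept_ancestor": ["ancestor_concept_id", "descendant_concept_id"],
}

TABLE_FILES = {name: f"{name}.csv" for name in COLUMNS}


def _parse_ts(raw: object) -> datetime:
    """Parse an ISO-8601 timestamp or date; dates promote to midnight;
    sub-minute precision is truncated."""
    ts = pd.Timestamp(str(raw))
    return ts.to_pydatetime().replace(second=0, microsecond=0)


def _parse_date(raw: object) -> date:
    return pd.Timestamp(str(raw)).date()


def _opt(raw: object):
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    return raw


def _read_table(directory: Path, name: str) -> pd.DataFrame:
    path = directory / TABLE_FILES[name]
    if not path.exists():
        raise StoreLoadError(f"missing table file: {path.name} (expected in {directory})")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = COLUMNS[name]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise StoreLoadError(f"{path.name}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        warnings.warn(f"{path.name}: ignoring unknown columns {extra}", stacklevel=3)
    return df[expected]


def load_store(directory_path: str | Path) -> PatientStore:
    """Load a store from a directory of delimited table files.

    Raises :class:`StoreLoadError` for a missing file and
    :class:`StoreIntegrityError` when references do not resolve or a
    type invariant is broken.
    """
    directory = Path(directory_path)
    tables = {name: _read_table(directory, name) for name in COLUMNS}

    store = PatientStore()
    for row in tables["person"].itertuples(index=False):
        store.persons.append(Person(
            person_id=int(row.person_id),
            birth_date=_parse_date(row.birth_date),
            sex=Sex(row.sex),
            ethnicity=_opt(row.ethnicity),
        ))
    for row in tables["drug_exposure"].itertuples(index=False):
        dose = _opt(row.daily_dose_value)
        route = _opt(row.route)
        store.drug_exposures.append(DrugExposure(
            exposure_id=int(row.drug_exposure_id),
            person_id=int(row.person_id),
            drug_concept_id=int(row.drug_concept_id),
            start_datetime=_parse_ts(row.drug_exposure_start_datetime),
            end_datetime=_parse_ts(row.drug_exposure_end_datetime),
            daily_dose_value=float(dose) if dose is not None else None,
            daily_dose_unit=_opt(row.daily_dose_unit),
            route=Route(route) if route is not None else None,
            dose_direction=_opt(row.dose_direction),
        ))
    for row in tables["measurement"].itertuples(index=False):
        store.measurements.append(Measurement(
            measurement_id=int(row.measurement_id),
            person_id=int(row.person_id),
            measurement_concept_id=int(row.measurement_concept_id),
            taken_datetime=_parse_ts(row.measurement_datetime),
            value=float(row.value_as_number),
            unit=str(row.unit),
        ))
    for row in tables["condition_occurrence"].itertuples(index=False):
        end = _opt(row.condition_end_date)
        store.conditions.append(ConditionOccurrence(
            person_id=int(row.person_id),
            condition_concept_id=int(row.condition_concept_id),
            start_date=_parse_date(row.condition_start_date),
            end_date=_parse_date(end) if end is not None else None,
        ))
    for row in tables["visit_occurrence"].itertuples(index=False):
        kind = _opt(row.visit_kind)
        store.visits.append(VisitOccurrence(
            visit_id=int(row.visit_occurrence_id),
            person_id=int(row.person_id),
            start_datetime=_parse_ts(row.visit_start_datetime),
            end_datetime=_parse_ts(row.visit_end_datetime),
            visit_kind=VisitKind(kind) if kind is not None else None,
        ))
    for row in tables["concept"].itertuples(index=False):
        store.concepts.append(Concept(
            concept_id=int(row.concept_id),
            code=str(row.concept_code),
            vocabulary=Vocabulary(row.vocabulary_id),
            name=str(row.concept_name),
        ))
    for row in tables["concept_ancestor"].itertuples(index=False):
        store.concept_ancestry.append(
            (int(row.ancestor_concept_id), int(row.descendant_concept_id))
        )

    violations = validate_store(store)
    if violations:
        raise StoreIntegrityError(violations)
    return store


def _fmt_ts(ts: datetime) -> str:
    return ts.strftime("%Y-%m-%dT%H:%M")


def _s(value) -> str:
    if value is None:
        return ""
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def write_store(store: PatientStore, directory_path: str | Path) -> None:
    """Write all seven tables as delimited text; inverse of :func:`load_store`."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)

    frames = {
        "person": pd.DataFrame(
            [(p.person_id, p.birth_date.isoformat(), p.sex.value, _s(p.ethnicity))
             for p in store.persons],
            columns=COLUMNS["person"]),
        "drug_exposure": pd.DataFrame(
            [(e.exposure_id, e.person_id, e.drug_concept_id,
              _fmt_ts(e.start_datetime), _fmt_ts(e.end_datetime),
              _s(e.daily_dose_value), _s(e.daily_dose_unit), _s(e.route),
              _s(e.dose_direction))
             for e in store.drug_exposures],
            columns=COLUMNS["drug_exposure"]),
        "measurement": pd.DataFrame(
            [(m.measurement_id, m.person_id, m.measurement_concept_id,
              _fmt_ts(m.taken_datetime), repr(m.value), m.unit)
             for m in store.measurements],
            columns=COLUMNS["measurement"]),
        "condition_occurrence": pd.DataFrame(
            [(c.person_id, c.condition_concept_id, c.start_date.isoformat(),
              c.end_date.isoformat() if c.end_date else "")
             for c in store.conditions],
            columns=COLUMNS["condition_occurrence"]),
        "visit_occurrence": pd.DataFrame(
            [(v.visit_id, v.person_id, _fmt_ts(v.start_datetime),
              _fmt_ts(v.end_datetime), _s(v.visit_kind))
             for v in store.visits],
            columns=COLUMNS["visit_occurrence"]),
        "concept": pd.DataFrame(
            [(c.concept_id, c.code, c.vocabulary.value, c.name)
             for c in store.concepts],
            columns=COLUMNS["concept"]),
        "concept_ancestor": pd.DataFrame(
            store.concept_ancestry, columns=COLUMNS["concept_ancestor"]),
    }
    for name, frame in frames.items():
        frame.to_csv(directory / TABLE_FILES[name], index=False)


# ---------------------------------------------------------------------------
# Integrity checking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegrityViolation:
    entity: str
    entity_id: object
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.entity}[{self.entity_id}].{self.field}: {self.rule}"


def validate_store(store: PatientStore) -> list[IntegrityViolation]:
    """Check every type invariant; violations are returned, never raised."""
    out: list[IntegrityViolation] = []

    def bad(entity, entity_id, field_, rule):
        out.append(IntegrityViolation(entity, entity_id, field_, rule))

    persons = {}
    for p in store.persons:
        if p.person_id in persons:
            bad("Person", p.person_id, "person_id", "duplicate person_id")
        persons[p.person_id] = p

    concept_ids = set()
    for c in store.concepts:
        if c.concept_id in concept_ids:
            bad("Concept", c.concept_id, "concept_id", "duplicate concept_id")
        concept_ids.add(c.concept_id)

    seen_exp = set()
    for e in store.drug_exposures:
        if e.exposure_id in seen_exp:
            bad("DrugExposure", e.exposure_id, "exposure_id", "duplicate exposure_id")
        seen_exp.add(e.exposure_id)
        if e.person_id not in persons:
            bad("DrugExposure", e.exposure_id, "person_id",
                f"dangling reference to person {e.person_id}")
        elif persons[e.person_id].birth_date > e.start_datetime.date():
            bad("Person", e.person_id, "birth_date",
                f"birth_date after drug exposure {e.exposure_id} start")
        if e.drug_concept_id not in concept_ids:
            bad("DrugExposure", e.exposure_id, "drug_concept_id",
                f"dangling reference to concept {e.drug_concept_id}")
        if e.start_datetime > e.end_datetime:
            bad("DrugExposure", e.exposure_id, "start_datetime",
                "start_datetime after end_datetime")
        if e.daily_dose_value is not None and not (
                e.daily_dose_value >= 0 and e.daily_dose_value == e.daily_dose_value
                and abs(e.daily_dose_value) != float("inf")):
            bad("DrugExposure", e.exposure_id, "daily_dose_value",
                "daily dose must be finite and >= 0")

    seen_meas = set()
    for m in store.measurements:
        if m.measurement_id in seen_meas:
            bad("Measurement", m.measurement_id, "measurement_id",
                "duplicate measurement_id")
        seen_meas.add(m.measurement_id)
        if m.person_id not in persons:
            bad("Measurement", m.measurement_id, "person_id",
                f"dangling reference to person {m.person_id}")
        elif persons[m.person_id].birth_date > m.taken_datetime.date():
            bad("Person", m.person_id, "birth_date",
                f"birth_date after measurement {m.measurement_id}")
        if m.measurement_concept_id not in concept_ids:
            bad("Measurement", m.measurement_id, "measurement_concept_id",
                f"dangling reference to concept {m.measurement_concept_id}")
        if not (m.value == m.value and abs(m.value) != float("inf")):
            bad("Measurement", m.measurement_id, "value", "value must be finite")
        if not m.unit:
            bad("Measurement", m.measurement_id, "unit",
                "unit required when a value is present")

    for i, c in enumerate(store.conditions):
        if c.person_id not in persons:
            bad("ConditionOccurrence", i, "person_id",
                f"dangling reference to person {c.person_id}")
        elif persons[c.person_id].birth_date > c.start_date:
            bad("Person", c.person_id, "birth_date",
                f"birth_date after condition occurrence row {i}")
        if c.condition_concept_id not in concept_ids:
            bad("ConditionOccurrence", i, "condition_concept_id",
                f"dangling reference to concept {c.condition_concept_id}")
        if c.end_date is not None and c.end_date < c.start_date:
            bad("ConditionOccurrence", i, "end_date", "end_date before start_date")

    seen_vis = set()
    for v in store.visits:
        if v.visit_id in seen_vis:
            bad("VisitOccurrence", v.visit_id, "visit_id", "duplicate visit_id")
        seen_vis.add(v.visit_id)
        if v.person_id not in persons:
            bad("VisitOccurrence", v.visit_id, "person_id",
                f"dangling reference to person {v.person_id}")
        if v.start_datetime > v.end_datetime:
            bad("VisitOccurrence", v.visit_id, "start_datetime",
                "start_datetime after end_datetime")

    for i, (anc, desc) in enumerate(store.concept_ancestry):
        for cid, field_ in ((anc, "ancestor_concept_id"), (desc, "descendant_concept_id")):
            if cid not in concept_ids:
                bad("ConceptAncestor", i, field_, f"dangling reference to concept {cid}")
    graph = nx.DiGraph(store.concept_ancestry)
    if graph.number_of_edges() and not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        bad("ConceptAncestor", "-", "concept_ancestry",
            f"ancestry contains a cycle: {cycle}")

    return out


def filter_visits_min_duration(
    store: PatientStore,
    min_hours: float,
    restrict_events_to_visits: bool = False,
) -> PatientStore:
    """Return a copy keeping only visits of duration >= ``min_hours`` (inclusive).

    With ``restrict_events_to_visits`` the drug exposures and measurements are
    additionally restricted to those starting/taken inside a retained visit;
    by default events outside any visit are retained.  The input store is not
    modified.
    """
    if min_hours < 0:
        raise ValueError(f"min_hours must be >= 0, got {min_hours}")
    kept_visits = [v for v in store.visits if v.duration_hours >= min_hours]
    new = replace(
        store,
        persons=list(store.persons),
        drug_exposures=list(store.drug_exposures),
        measurements=list(store.measurements),
        conditions=list(store.conditions),
        visits=kept_visits,
        concepts=list(store.concepts),
        concept_ancestry=list(store.concept_ancestry),
    )
    if restrict_events_to_visits:
        spans = {}
        for v in kept_visits:
            spans.setdefault(v.person_id, []).append((v.start_datetime, v.end_datetime))

        def inside(person_id, ts):
            return any(s <= ts <= e for s, e in spans.get(person_id, []))

        new.drug_exposures = [e for e in new.drug_exposures
                              if inside(e.person_id, e.start_datetime)]
        new.measurements = [m for m in new.measurements
                            if inside(m.person_id, m.taken_datetime)]
    return new
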