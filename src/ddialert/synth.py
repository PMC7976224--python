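"""Synthetic population generators.

Three generators, all seeded and fully deterministic:

* :func:`generate_paper_replica` — the bundled validation population: 93
  persons with 24 lab measurements, 12 condition occurrences and 208 drug
  exposures.  One scripted person per reachable leaf of each bundled DDI
  tree, one negative control (a lone interacting drug, no partner) per tree,
  and non-interacting background persons padding the census to those exact
  totals.  Demographics and dates are invented (synthetic), the census and
  per-leaf coverage are guaranteed.
* :func:`generate_branch_coverage` — for one tree, a population with exactly
  one concomitant pair per leaf, found by exhaustively enumerating factor
  assignments over a candidate grid around every threshold the tree
  references; an unreachable leaf is a generation error, which doubles as a
  tree lint.
* :func:`generate_random` — randomized populations for property and
  concordance testing.  Per-person event counts are Poisson draws around the
  spec's means; demographic and lab-abnormality prevalences follow the spec's
  probabilities.  Defaults: 1.27 visits, 17.3 drug exposures and 16.8 lab
  measurements per person, 53.5 % female, and the 15.6 / 55.7 / 28.7 %
  under-18 / 18-60 / over-60 age mix of a tertiary-care population.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from importlib import resources

import numpy as np

from .cdm import (
    Concept, ConditionOccurrence, DrugExposure, Measurement, PatientStore,
    Person, Route, Sex, VisitKind, VisitOccurrence, Vocabulary,
)
from .concept_sets import ConceptSetLibrary, load_bundled_library
from .exposure import MISSING, PatientContext, compute_derived_factors
from .rules import DecisionTree, evaluate_tree

__all__ = [
    "GeneratorSpec", "CoverageFixture", "GenerationError",
    "vocabulary_store", "generate_paper_replica", "generate_branch_coverage",
    "generate_random",
]


class GenerationError(Exception):
    pass


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

def _load_vocabulary() -> tuple[list[Concept], list[tuple[int, int]]]:
    doc = json.loads(
        resources.files("ddialert").joinpath("data/vocabulary.json").read_text())
    concepts = [Concept(c["concept_id"], c["code"], Vocabulary(c["vocabulary"]),
                        c["name"]) for c in doc["concepts"]]
    edges = [(e["parent"], e["child"]) for e in doc["ancestry"]]
    return concepts, edges


def vocabulary_store() -> PatientStore:
    """An otherwise-empty store holding the bundled synthetic vocabulary."""
    concepts, edges = _load_vocabulary()
    return PatientStore(concepts=concepts, concept_ancestry=edges)


# typical daily dose, unit, and route per (leaf) drug concept
DRUG_DEFAULTS: dict[int, tuple[float, str, Route]] = {
    1101: (20, "mg/day", Route.ORAL), 1102: (50, "mg/day", Route.ORAL),
    1103: (20, "mg/day", Route.ORAL), 1201: (75, "mg/day", Route.ORAL),
    1202: (60, "mg/day", Route.ORAL), 1301: (25, "mg/day", Route.ORAL),
    1302: (25, "mg/day", Route.ORAL), 1401: (150, "mg/day", Route.ORAL),
    1402: (15, "mg/day", Route.ORAL), 1501: (200, "mg/day", Route.ORAL),
    1502: (5, "mg/day", Route.ORAL), 1503: (8, "mg/day", Route.ORAL),
    1504: (20, "mg/day", Route.ORAL), 1611: (50, "mg/day", Route.ORAL),
    1612: (50, "mg/day", Route.ORAL), 1621: (80, "mg/day", Route.ORAL),
    1622: (40, "mg/day", Route.ORAL), 1623: (20, "mg/day", Route.ORAL),
    1624: (0.5, "mg/day", Route.OPHTHALMIC), 1631: (25, "mg/day", Route.ORAL),
    1632: (200, "mg/day", Route.ORAL), 1701: (0.2, "mg/day", Route.ORAL),
    1801: (0.5, "mg/day", Route.IV), 1901: (200, "mg/day", Route.ORAL),
    1950: (5, "mg/day", Route.ORAL), 2001: (20, "mg/day", Route.ORAL),
    2002: (25, "mcg/hr", Route.TRANSDERMAL), 2101: (4, "mg/day", Route.ORAL),
    2102: (200, "mg/day", Route.ORAL), 2103: (2, "mg/day", Route.ORAL),
    2104: (100, "mg/day", Route.ORAL), 2201: (40, "mEq/day", Route.ORAL),
    2301: (25, "mg/day", Route.ORAL), 2302: (5, "mg/day", Route.ORAL),
    2303: (75, "mg/day", Route.ORAL), 2401: (40, "mg/day", Route.ORAL),
    2402: (1, "mg/day", Route.ORAL), 2501: (1200, "mg/day", Route.ORAL),
    2502: (500, "mg/day", Route.ORAL), 2601: (81, "mg/day", Route.ORAL),
    2701: (20, "mg/day", Route.ORAL), 2702: (4, "mg/day", Route.ORAL),
    2801: (75, "mg/day", Route.ORAL), 2902: (1500, "mg/day", Route.ORAL),
    2903: (1500, "mg/day", Route.ORAL), 2904: (100, "mg/day", Route.TOPICAL),
}

# drugs that are not an object or precipitant of any bundled tree; safe as
# background exposures that can never create a concomitant pair
_BACKGROUND_DRUGS = [2401, 2402, 2501, 2502, 2701, 2702, 2801]
_BACKGROUND_CONDITIONS = [4999, 4001, 4003, 4005]
_CONDITION_CONCEPTS = [4001, 4002, 4003, 4004, 4005, 4006, 4008, 4009, 4011, 4999]

_LAB_UNITS = {3001: "mEq/L", 3002: "ms"}


def _leaf_members(member_ids: frozenset[int], ancestry) -> list[int]:
    """Members that are not an ancestor of anything (orderable drug products,
    not classes)."""
    parents = {p for p, _ in ancestry}
    return sorted(cid for cid in member_ids if cid not in parents)


# ---------------------------------------------------------------------------
# Store-builder helper
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self):
        concepts, edges = _load_vocabulary()
        self.store = PatientStore(concepts=concepts, concept_ancestry=edges)
        self._exp_id = 0
        self._meas_id = 0
        self._visit_id = 0

    def person(self, person_id: int, birth: date, sex: Sex,
               ethnicity: str | None = None) -> int:
        self.store.persons.append(Person(person_id, birth, sex, ethnicity))
        return person_id

    def exposure(self, person_id: int, concept_id: int, start: datetime,
                 end: datetime, dose: float | None = "default",
                 route: Route | None = "default",
                 dose_direction: str | None = None) -> int:
        default = DRUG_DEFAULTS.get(concept_id, (None, None, Route.ORAL))
        if dose == "default":
            dose = default[0]
        unit = default[1] if dose is not None else None
        if route == "default":
            route = default[2]
        self._exp_id += 1
        self.store.drug_exposures.append(DrugExposure(
            self._exp_id, person_id, concept_id, start, end,
            daily_dose_value=float(dose) if dose is not None else None,
            daily_dose_unit=unit, route=route, dose_direction=dose_direction))
        return self._exp_id

    def measurement(self, person_id: int, concept_id: int, taken: datetime,
                    value: float, unit: str | None = None) -> int:
        self._meas_id += 1
        self.store.measurements.append(Measurement(
            self._meas_id, person_id, concept_id, taken, float(value),
            unit or _LAB_UNITS.get(concept_id, "1")))
        return self._meas_id

    def condition(self, person_id: int, concept_id: int, start: date,
                  end: date | None = None) -> None:
        self.store.conditions.append(
            ConditionOccurrence(person_id, concept_id, start, end))

    def visit(self, person_id: int, start: datetime, end: datetime,
              kind: VisitKind | None = VisitKind.UNKNOWN) -> int:
        self._visit_id += 1
        self.store.visits.append(
            VisitOccurrence(self._visit_id, person_id, start, end, kind))
        return self._visit_id


# ---------------------------------------------------------------------------
# Paper-replica population
# ---------------------------------------------------------------------------

_REPLICA_CENSUS = {"persons": 93, "measurements": 24, "conditions": 12,
                   "drug_exposures": 208}


def _scripted_scenarios():
    """One scenario per reachable leaf of each bundled tree.

    Each entry: (expected ddi_id, expected leaf_id, age, sex, exposures,
    labs, conditions, visits); offsets are relative to the person's trigger
    time; exposure tuples are (concept, start_days, end_days, dose, route).
    """
    D = "default"
    return [
        # --- citalopram / QT-prolonging agent ---
        ("citalopram_qt", "red_qtc_prolonged", 45, Sex.MALE,
         [(1101, -5, 5, 20, D), (1501, 0, 7, D, D)],
         [(3002, 520)], [], []),
        ("citalopram_qt", "red_multiple_risk_factors", 45, Sex.FEMALE,
         [(1101, -5, 5, 20, D), (1501, 0, 7, D, D)],
         [(3002, 440)], [], []),  # female + potassium unknown => 2 risk factors
        ("citalopram_qt", "yellow_single_risk_factor", 45, Sex.FEMALE,
         [(1101, -5, 5, 20, D), (1501, 0, 7, D, D)],
         [(3002, 440), (3001, 4.2)], [], []),
        ("citalopram_qt", "yellow_high_dose_citalopram", 45, Sex.MALE,
         [(1101, -5, 5, 60, D), (1501, 0, 7, D, D)],
         [(3002, 440), (3001, 4.2)], [], []),
        ("citalopram_qt", "green_no_risk_factors", 45, Sex.MALE,
         [(1101, -5, 5, 20, D), (1501, 0, 7, D, D)],
         [(3002, 440), (3001, 4.2)], [], []),
        # --- clonidine / beta-blocker ---
        ("clonidine_beta_blocker", "green_ophthalmic_timolol", 45, Sex.MALE,
         [(1701, -5, 5, D, D), (1624, 0, 7, D, Route.OPHTHALMIC)], [], [], []),
        ("clonidine_beta_blocker", "green_alpha_blocking", 45, Sex.MALE,
         [(1701, -5, 5, D, D), (1631, 0, 7, D, D)], [], [], []),
        ("clonidine_beta_blocker", "red_withdrawal_nonselective", 45, Sex.MALE,
         [(1701, -7, 0, D, D), (1621, 0, 7, D, D)], [], [], []),
        ("clonidine_beta_blocker", "yellow_withdrawal_selective", 45, Sex.MALE,
         [(1701, -7, 0, D, D), (1611, 0, 7, D, D)], [], [], []),
        ("clonidine_beta_blocker", "yellow_continued_combination", 45, Sex.MALE,
         [(1701, -5, 5, D, D), (1611, 0, 7, D, D)], [], [], []),
        # --- epinephrine / beta-blocker ---
        ("epinephrine_beta_blocker", "red_anaphylaxis_nonselective", 45, Sex.MALE,
         [(1801, -5, 5, D, Route.IV), (1621, 0, 7, D, D)],
         [], [(4004, -30, None)], []),
        ("epinephrine_beta_blocker", "red_systemic_epinephrine_nonselective",
         45, Sex.MALE,
         [(1801, -5, 5, D, Route.IV), (1621, 0, 7, D, D)], [], [], []),
        ("epinephrine_beta_blocker", "yellow_nonsystemic_epinephrine", 45, Sex.MALE,
         [(1801, -5, 5, D, Route.OTHER), (1621, 0, 7, D, D)], [], [], []),
        ("epinephrine_beta_blocker", "yellow_selective_or_alpha_blocking",
         45, Sex.MALE,
         [(1801, -5, 5, D, Route.IV), (1611, 0, 7, D, D)], [], [], []),
        # --- fluconazole / opioid ---
        ("fluconazole_opioid", "green_inpatient_low_dose", 45, Sex.MALE,
         [(1901, -5, 5, 100, D), (2001, 0, 7, 20, D)],
         [], [], [(VisitKind.INPATIENT, -48, 48)]),
        ("fluconazole_opioid", "yellow_outpatient_low_dose", 45, Sex.MALE,
         [(1901, -5, 5, 100, D), (2001, 0, 7, 20, D)],
         [], [], [(VisitKind.OUTPATIENT, -2, 2)]),
        ("fluconazole_opioid", "red_high_dose_combination", 45, Sex.MALE,
         [(1901, -5, 5, 400, D), (2001, 0, 7, 60, D)], [], [], []),
        ("fluconazole_opioid", "yellow_high_dose_fluconazole", 45, Sex.MALE,
         [(1901, -5, 5, 400, D), (2001, 0, 7, 20, D)], [], [], []),
        # --- immunosuppressant / fluconazole ---
        ("immunosuppressant_fluconazole", "green_nonsystemic_fluconazole",
         45, Sex.MALE,
         [(2101, -5, 5, D, D), (1901, 0, 7, 100, Route.TOPICAL)], [], [], []),
        ("immunosuppressant_fluconazole", "green_low_dose_fluconazole",
         45, Sex.MALE,
         [(2101, -5, 5, D, D), (1901, 0, 7, 100, D)], [], [], []),
        ("immunosuppressant_fluconazole", "red_nti_high_dose", 45, Sex.MALE,
         [(2101, -5, 5, D, D), (1901, 0, 7, 400, D)], [], [], []),
        ("immunosuppressant_fluconazole", "red_elderly_high_dose", 70, Sex.MALE,
         [(2104, -5, 5, D, D), (1901, 0, 7, 400, D)], [], [], []),
        ("immunosuppressant_fluconazole", "yellow_high_dose_fluconazole",
         45, Sex.MALE,
         [(2104, -5, 5, D, D), (1901, 0, 7, 400, D)], [], [], []),
        # --- potassium / potassium-sparing diuretic ---
        ("potassium_k_sparing_diuretic", "red_hyperkalemia", 45, Sex.MALE,
         [(2201, -5, 5, D, D), (2301, 0, 7, D, D)], [(3001, 5.5)], [], []),
        ("potassium_k_sparing_diuretic", "green_normokalemia", 45, Sex.MALE,
         [(2201, -5, 5, D, D), (2301, 0, 7, D, D)], [(3001, 4.0)], [], []),
        ("potassium_k_sparing_diuretic", "yellow_no_recent_potassium", 45, Sex.MALE,
         [(2201, -5, 5, D, D), (2301, 0, 7, D, D)], [], [], []),
        # --- warfarin / antidepressant ---
        ("warfarin_antidepressant", "red_serotonergic_with_bleeding_risk",
         70, Sex.MALE,
         [(1950, -5, 5, D, D), (1101, 0, 7, D, D)], [], [], []),
        ("warfarin_antidepressant", "yellow_serotonergic", 45, Sex.MALE,
         [(1950, -5, 5, D, D), (1102, 0, 7, D, D)], [], [], []),
        ("warfarin_antidepressant", "yellow_other_antidepressant_with_risk",
         45, Sex.MALE,
         [(1950, -5, 5, D, D), (1401, 0, 7, D, D), (2501, -3, 3, D, D)],
         [], [], []),
        ("warfarin_antidepressant", "green_low_risk_antidepressant", 45, Sex.MALE,
         [(1950, -5, 5, D, D), (1402, 0, 7, D, D)], [], [], []),
        # --- warfarin / salicylate ---
        ("warfarin_salicylate", "green_topical_salicylate", 45, Sex.MALE,
         [(1950, -5, 5, D, D), (2904, 0, 7, D, Route.TOPICAL)], [], [], []),
        ("warfarin_salicylate", "yellow_high_dose_nonacetylated", 45, Sex.MALE,
         [(1950, -5, 5, D, D), (2902, 0, 7, 3000, D)], [], [], []),
        ("warfarin_salicylate", "green_low_dose_nonacetylated", 45, Sex.MALE,
         [(1950, -5, 5, D, D), (2902, 0, 7, 1500, D)], [], [], []),
        ("warfarin_salicylate", "yellow_deliberate_combination", 45, Sex.MALE,
         [(1950, -5, 5, D, D), (2601, 0, 7, 81, D)],
         [], [(4008, -200, -100)], []),
        ("warfarin_salicylate", "red_aspirin_no_indication", 45, Sex.MALE,
         [(1950, -5, 5, D, D), (2601, 0, 7, 325, D)], [], [], []),
    ]


# one lone interacting drug per tree; no partner, so no alert may fire
_NEGATIVE_CONTROLS = [1101, 1701, 1801, 1901, 2201, 1950, 2101, 2902]


def _birth_for_age(trigger: datetime, age: int) -> date:
    d = trigger.date()
    try:
        return d.replace(year=d.year - age)
    except ValueError:  # Feb 29
        return d.replace(year=d.year - age, day=d.day - 1)


def replica_leaf_manifest() -> dict[int, tuple[str, str]]:
    """person_id -> (ddi_id, expected leaf) for the scripted replica persons."""
    return {pid: (ddi, leaf) for pid, (ddi, leaf, *_)
            in enumerate(_scripted_scenarios(), start=1)}


def generate_paper_replica(seed: int) -> PatientStore:
    """The bundled synthetic validation population.

    The census is fixed by construction for every seed (93 persons, 24 lab
    measurements, 12 condition occurrences, 208 drug exposures); the seed
    varies only the invented background demographics and dates.
    """
    rng = np.random.default_rng(seed)
    b = _Builder()
    scenarios = _scripted_scenarios()

    pid = 0
    for ddi, leaf_id, age, sex, exposures, labs, conds, visits in scenarios:
        pid += 1
        trigger = datetime(2016, 1, 4, 10, 0) + timedelta(days=2 * (pid - 1))
        b.person(pid, _birth_for_age(trigger, age), sex)
        for concept, s_off, e_off, dose, route in exposures:
            b.exposure(pid, concept, trigger + timedelta(days=s_off),
                       trigger + timedelta(days=e_off), dose=dose, route=route)
        for concept, value in labs:
            b.measurement(pid, concept, trigger - timedelta(hours=1), value)
        for concept, s_off, e_off in conds:
            b.condition(pid, concept, (trigger + timedelta(days=s_off)).date(),
                        (trigger + timedelta(days=e_off)).date()
                        if e_off is not None else None)
        for kind, s_h, e_h in visits:
            b.visit(pid, trigger + timedelta(hours=s_h),
                    trigger + timedelta(hours=e_h), kind)

    for concept in _NEGATIVE_CONTROLS:
        pid += 1
        start = datetime(2016, 1, 4, 10, 0) + timedelta(days=2 * (pid - 1))
        b.person(pid, _birth_for_age(start, 50), Sex.FEMALE)
        b.exposure(pid, concept, start, start + timedelta(days=7))

    # background padding to the exact census; background drugs belong to no
    # object/precipitant set, so they can never add a concomitant pair
    n_pad = _REPLICA_CENSUS["persons"] - pid
    remaining_exp = _REPLICA_CENSUS["drug_exposures"] - len(b.store.drug_exposures)
    remaining_meas = _REPLICA_CENSUS["measurements"] - len(b.store.measurements)
    remaining_cond = _REPLICA_CENSUS["conditions"] - len(b.store.conditions)
    base_exp, extra = divmod(remaining_exp, n_pad)
    pad_ids = []
    for i in range(n_pad):
        pid += 1
        pad_ids.append(pid)
        birth = date(int(rng.integers(1940, 1991)), int(rng.integers(1, 13)),
                     int(rng.integers(1, 29)))
        b.person(pid, birth, Sex.FEMALE if rng.random() < 0.535 else Sex.MALE)
        n_exp = base_exp + (1 if i < extra else 0)
        for _ in range(n_exp):
            concept = int(rng.choice(_BACKGROUND_DRUGS))
            start = datetime(2016, 1, 5, 8, 0) + timedelta(
                days=int(rng.integers(0, 75)), hours=int(rng.integers(0, 12)))
            b.exposure(pid, concept, start,
                       start + timedelta(days=int(rng.integers(3, 11))))
        if i % 3 == 0:
            vs = datetime(2016, 1, 10, 7, 0) + timedelta(days=int(rng.integers(0, 60)))
            b.visit(pid, vs, vs + timedelta(hours=int(rng.integers(5, 200))),
                    VisitKind(["INPATIENT", "OUTPATIENT", "UNKNOWN"][(i // 3) % 3]))
    for i in range(remaining_meas):
        who = pad_ids[i % len(pad_ids)]
        taken = datetime(2016, 2, 1, 9, 0) + timedelta(days=int(rng.integers(0, 40)))
        b.measurement(who, 3001, taken, round(float(rng.uniform(3.2, 5.2)), 1))
    for i in range(remaining_cond):
        who = pad_ids[(i + 7) % len(pad_ids)]
        concept = int(rng.choice(_BACKGROUND_CONDITIONS))
        b.condition(who, concept,
                    date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 400))))
    return b.store


# ---------------------------------------------------------------------------
# Branch-coverage generator
# ---------------------------------------------------------------------------

@dataclass
class CoverageFixture:
    store: PatientStore
    manifest: dict[int, str]  # person_id -> expected leaf_id


_TRIGGER = datetime(2016, 2, 15, 12, 0)


def _numeric_candidates(tree: DecisionTree, factor_name: str,
                        default: float) -> list[float]:
    """Values straddling every threshold this factor is compared against,
    directly in predicates or through a derived threshold flag."""
    thresholds: set[float] = set()
    for node in tree.nodes.values():
        if node.kind == "PREDICATE" and node.factor == factor_name and \
                node.comparator in ("LT", "LE", "GT", "GE"):
            thresholds.add(float(node.threshold))
    for f in tree.factor_manifest:
        if f.extractor == "threshold_flag" and f.params["source"] == factor_name:
            thresholds.add(float(f.params["threshold"]))
    if not thresholds:
        return [default]
    out: set[float] = set()
    for t in thresholds:
        out.update((t - 1, t, t + 1))
    return sorted(out)


def _route_candidates(tree: DecisionTree, factor_name: str) -> list[str]:
    routes: set[str] = {"ORAL"}
    for node in tree.nodes.values():
        if node.kind != "PREDICATE" or node.factor != factor_name:
            continue
        if node.comparator == "IN_SET":
            routes.update(node.threshold)
        elif node.comparator == "EQ" and isinstance(node.threshold, str):
            routes.add(node.threshold)
    return sorted(routes)


def _factor_domains(tree: DecisionTree, library: ConceptSetLibrary,
                    vocab: PatientStore):
    """(variable name -> candidate values) for the exhaustive search.
    ``drug_in_set`` factors are not free variables: they derive from the
    chosen object/precipitant concepts."""
    ancestry = vocab.concept_ancestry
    obj_members = _leaf_members(
        library.resolve(tree.object_set, vocab).member_concept_ids, ancestry)
    prec_members = _leaf_members(
        library.resolve(tree.precipitant_set, vocab).member_concept_ids, ancestry)
    domains: dict[str, list] = {
        "__object__": obj_members, "__precipitant__": prec_members}
    for f in tree.factor_manifest:
        if f.extractor == "sex":
            domains[f.name] = ["FEMALE", "MALE"]
        elif f.extractor == "age":
            domains[f.name] = [int(v) for v in _numeric_candidates(tree, f.name, 45)]
        elif f.extractor == "latest_lab":
            domains[f.name] = _numeric_candidates(tree, f.name, 4.0) + [MISSING]
        elif f.extractor in ("condition_present", "concomitant_drug",
                             "drug_discontinued"):
            domains[f.name] = [True, False]
        elif f.extractor == "drug_dose":
            domains[f.name] = _numeric_candidates(tree, f.name, 100.0) + [MISSING]
        elif f.extractor == "drug_route":
            domains[f.name] = _route_candidates(tree, f.name) + [MISSING]
        elif f.extractor == "dose_tier":
            domains[f.name] = ["HIGH", "LOW", MISSING]
        elif f.extractor == "visit_context":
            domains[f.name] = ["INPATIENT", "OUTPATIENT", MISSING]
        # drug_in_set and derived extractors: computed, not enumerated
    return domains


def _context_for_assignment(tree: DecisionTree, library: ConceptSetLibrary,
                            vocab: PatientStore, assignment: dict) -> PatientContext:
    values: dict[str, object] = {}
    for f in tree.factor_manifest:
        if f.extractor == "drug_in_set":
            which = assignment["__object__"] if f.params["which"] == "object" \
                else assignment["__precipitant__"]
            members = library.resolve(f.params["set"], vocab).member_concept_ids
            values[f.name] = which in members
        elif f.name in assignment:
            values[f.name] = assignment[f.name]
    values = compute_derived_factors(tree, values)
    age = next((values[f.name] for f in tree.factor_manifest
                if f.extractor == "age"), 45)
    sex = next((values[f.name] for f in tree.factor_manifest
                if f.extractor == "sex"), "MALE")
    return PatientContext(person_id=0, as_of=_TRIGGER, age_years=age, sex=sex,
                          factor_values=values, provenance={})


_MAX_COMBINATIONS = 2_000_000


def _solve_leaves(tree: DecisionTree, library: ConceptSetLibrary,
                  vocab: PatientStore) -> dict[str, dict]:
    """Exhaustively search the candidate grid for one assignment per leaf."""
    domains = _factor_domains(tree, library, vocab)
    names = list(domains)
    total = 1
    for v in domains.values():
        total *= len(v)
    if total > _MAX_COMBINATIONS:
        raise GenerationError(
            f"{tree.ddi_id}: candidate grid too large ({total} combinations)")
    wanted = set(tree.leaf_ids())
    found: dict[str, dict] = {}
    for combo in itertools.product(*domains.values()):
        assignment = dict(zip(names, combo))
        context = _context_for_assignment(tree, library, vocab, assignment)
        leaf_id, _, _ = evaluate_tree(tree, context)
        if leaf_id not in found:
            found[leaf_id] = assignment
            if wanted <= found.keys():
                break
    missing = wanted - found.keys()
    if missing:
        raise GenerationError(
            f"{tree.ddi_id}: leaf(es) unreachable under the factor manifest: "
            f"{sorted(missing)}")
    return found


def _realize_person(b: _Builder, pid: int, tree: DecisionTree,
                    library: ConceptSetLibrary, vocab: PatientStore,
                    assignment: dict) -> None:
    """Materialize CDM records for one factor assignment, producing exactly
    one concomitant pair at the fixed trigger time."""
    t = _TRIGGER
    age = 45
    sex = Sex.MALE
    for f in tree.factor_manifest:
        if f.extractor == "age":
            age = int(assignment[f.name])
        elif f.extractor == "sex":
            sex = Sex(assignment[f.name])
    b.person(pid, _birth_for_age(t, age), sex)

    def resolved(set_id):
        return library.resolve(set_id, vocab).member_concept_ids

    obj_concept = assignment["__object__"]
    prec_concept = assignment["__precipitant__"]

    # the object is discontinued at the trigger when a withdrawal factor over
    # a set containing it is asserted; the pair still overlaps at the shared
    # inclusive endpoint
    obj_span = (t - timedelta(days=5), t + timedelta(days=5))
    for f in tree.factor_manifest:
        if f.extractor == "drug_discontinued" and assignment[f.name] \
                and obj_concept in resolved(f.params["set"]):
            obj_span = (t - timedelta(days=5), t)

    dose = {"object": "default", "precipitant": "default"}
    route = {"object": "default", "precipitant": "default"}
    for f in tree.factor_manifest:
        if f.extractor == "drug_dose":
            v = assignment[f.name]
            dose[f.params["which"]] = None if v is MISSING else float(v)
        elif f.extractor == "drug_route":
            v = assignment[f.name]
            route[f.params["which"]] = None if v is MISSING else Route(v)
        elif f.extractor == "dose_tier":
            v = assignment[f.name]
            which = f.params["which"]
            concept = obj_concept if which == "object" else prec_concept
            if v is MISSING:
                dose[which] = None
            else:
                high_at = next(float(tier["high_at"]) for tier in f.params["tiers"]
                               if concept in resolved(tier["set"]))
                dose[which] = high_at * 1.5 if v == "HIGH" else high_at * 0.5

    b.exposure(pid, obj_concept, obj_span[0], obj_span[1],
               dose=dose["object"], route=route["object"])
    b.exposure(pid, prec_concept, t, t + timedelta(days=7),
               dose=dose["precipitant"], route=route["precipitant"])

    for f in tree.factor_manifest:
        value = assignment.get(f.name)
        if f.extractor == "latest_lab" and value is not MISSING and value is not None:
            members = sorted(resolved(f.params["set"]))
            b.measurement(pid, members[0], t - timedelta(hours=1), float(value),
                          unit=f.params.get("unit"))
        elif f.extractor == "condition_present" and value:
            if f.params.get("mode", "EVER") == "ACTIVE":
                b.condition(pid, sorted(resolved(f.params["set"]))[0],
                            (t - timedelta(days=30)).date(), None)
            else:
                b.condition(pid, sorted(resolved(f.params["set"]))[0],
                            (t - timedelta(days=400)).date(),
                            (t - timedelta(days=300)).date())
        elif f.extractor == "concomitant_drug" and value:
            members = _leaf_members(frozenset(resolved(f.params["set"])),
                                    vocab.concept_ancestry)
            b.exposure(pid, members[0], t - timedelta(days=3), t + timedelta(days=3))
        elif f.extractor == "drug_discontinued" and value \
                and obj_concept not in resolved(f.params["set"]) \
                and prec_concept not in resolved(f.params["set"]):
            members = _leaf_members(frozenset(resolved(f.params["set"])),
                                    vocab.concept_ancestry)
            b.exposure(pid, members[0], t - timedelta(days=10), t - timedelta(days=2))
        elif f.extractor == "visit_context" and value is not MISSING and value is not None:
            if value == "INPATIENT":
                b.visit(pid, t - timedelta(days=2), t + timedelta(days=2),
                        VisitKind.INPATIENT)
            else:
                b.visit(pid, t - timedelta(hours=2), t + timedelta(hours=2),
                        VisitKind.OUTPATIENT)


def generate_branch_coverage(tree: DecisionTree, seed: int = 0) -> CoverageFixture:
    """A population in which every leaf of ``tree`` fires exactly once, with a
    manifest mapping person_id to the expected leaf.

    Raises :class:`GenerationError` naming any leaf no factor assignment can
    reach (a lint for contradictory trees).  Deterministic; the seed is
    accepted for interface uniformity but the search itself is exhaustive and
    ordered.
    """
    library = load_bundled_library()
    vocab = vocabulary_store()
    found = _solve_leaves(tree, library, vocab)
    b = _Builder()
    manifest: dict[int, str] = {}
    for pid, leaf_id in enumerate(sorted(found), start=1):
        _realize_person(b, pid, tree, library, vocab, found[leaf_id])
        manifest[pid] = leaf_id
    return CoverageFixture(store=b.store, manifest=manifest)


# ---------------------------------------------------------------------------
# Randomized populations
# ---------------------------------------------------------------------------

# (object concept choices, precipitant concept choices) per DDI, for the
# deliberately co-exposed persons
_PAIR_POOL = [
    ([1101], [1501, 1502, 1503, 1504]),
    ([1701], [1611, 1612, 1621, 1622, 1623, 1624, 1631, 1632]),
    ([1801], [1611, 1621, 1631]),
    ([1901], [2001, 2002]),
    ([2101, 2102, 2103, 2104], [1901]),
    ([2201], [2301, 2302, 2303]),
    ([1950], [1101, 1102, 1201, 1301, 1401, 1402]),
    ([1950], [2601, 2902, 2903, 2904]),
]

@dataclass
class GeneratorSpec:
    """Reproducible recipe for a randomized population.

    ``event_rates`` are per-person Poisson means; ``factor_prevalences`` are
    probabilities of demographic/lab risk features and of deliberate
    co-exposure to an interacting pair.
    """

    seed: int = 0
    n_persons: int = 100
    event_rates: dict[str, float] = field(default_factory=lambda: {
        "drug_exposures": 17.3, "measurements": 16.8,
        "conditions": 1.0, "visits": 1.27})
    factor_prevalences: dict[str, float] = field(default_factory=lambda: {
        "female": 0.535, "age_under_18": 0.156, "age_18_60": 0.557,
        "hypokalemia": 0.15, "hyperkalemia": 0.10, "qtc_prolonged": 0.10,
        "co_exposure": 0.30})
    date_range: tuple[date, date] = (date(2016, 1, 1), date(2016, 3, 31))

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        for k, v in self.event_rates.items():
            if v < 0:
                raise ValueError(f"event rate {k!r} must be >= 0")
        for k, v in self.factor_prevalences.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence {k!r} must be in [0, 1]")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start after end")


def generate_random(spec: GeneratorSpec) -> PatientStore:
    """Draw a population per ``spec``; deterministic given the seed.

    Per-person counts are Poisson.  Background exposures are uniform over the
    drugs that belong to no object/precipitant set (loop diuretics, NSAIDs,
    corticosteroids, antiplatelets), so interacting pairs arise only through
    the ``co_exposure`` mechanism: with that probability, the first two drawn
    exposures are replaced by a deliberately overlapping object/precipitant
    pair of a random DDI (keeping the count distribution intact).  With
    ``co_exposure`` 0 the population therefore triggers no alerts at all.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    p = spec.factor_prevalences
    r = spec.event_rates
    d0 = datetime.combine(spec.date_range[0], datetime.min.time())
    span_days = (spec.date_range[1] - spec.date_range[0]).days

    def random_start():
        return d0 + timedelta(days=int(rng.integers(0, span_days + 1)),
                              hours=int(rng.integers(6, 20)))

    for pid in range(1, spec.n_persons + 1):
        u = rng.random()
        if u < p.get("age_under_18", 0.0):
            birth_year = int(rng.integers(1999, 2015))
        elif u < p.get("age_under_18", 0.0) + p.get("age_18_60", 0.0):
            birth_year = int(rng.integers(1956, 1999))
        else:
            birth_year = int(rng.integers(1926, 1956))
        sex = Sex.FEMALE if rng.random() < p.get("female", 0.5) else Sex.MALE
        b.person(pid, date(birth_year, int(rng.integers(1, 13)),
                           int(rng.integers(1, 29))), sex)

        n_exp = int(rng.poisson(r.get("drug_exposures", 0.0)))
        drugs = [int(c) for c in rng.choice(_BACKGROUND_DRUGS, size=n_exp)] \
            if n_exp else []
        forced_overlap = False
        if n_exp >= 2 and rng.random() < p.get("co_exposure", 0.0):
            objs, precs = _PAIR_POOL[int(rng.integers(0, len(_PAIR_POOL)))]
            drugs[0] = int(rng.choice(objs))
            drugs[1] = int(rng.choice(precs))
            forced_overlap = True
        for i, concept in enumerate(drugs):
            if forced_overlap and i == 1:
                start = prev_start + timedelta(days=2)  # noqa: F821
                end = prev_start + timedelta(days=9)
            else:
                start = random_start()
                end = start + timedelta(days=int(rng.integers(1, 15)))
            if i == 0:
                prev_start = start  # noqa: F841
            b.exposure(pid, concept, start, end)

        for _ in range(int(rng.poisson(r.get("measurements", 0.0)))):
            taken = random_start()
            if rng.random() < 0.7:
                u2 = rng.random()
                if u2 < p.get("hypokalemia", 0.0):
                    value = round(float(rng.uniform(2.8, 3.4)), 1)
                elif u2 < p.get("hypokalemia", 0.0) + p.get("hyperkalemia", 0.0):
                    value = round(float(rng.uniform(5.0, 6.2)), 1)
                else:
                    value = round(float(rng.uniform(3.6, 4.9)), 1)
                b.measurement(pid, 3001, taken, value)
            else:
                if rng.random() < p.get("qtc_prolonged", 0.0):
                    value = round(float(rng.uniform(485, 540)))
                else:
                    value = round(float(rng.uniform(390, 470)))
                b.measurement(pid, 3002, taken, value)

        birth = b.store.persons[-1].birth_date
        for _ in range(int(rng.poisson(r.get("conditions", 0.0)))):
            concept = int(rng.choice(_CONDITION_CONCEPTS))
            start = date(2010, 1, 1) + timedelta(days=int(rng.integers(0, 2200)))
            start = max(start, birth + timedelta(days=30))  # onset after birth
            end = None if rng.random() < 0.7 else start + timedelta(
                days=int(rng.integers(10, 400)))
            b.condition(pid, concept, start, end)

        for _ in range(int(rng.poisson(r.get("visits", 0.0)))):
            start = random_start()
            b.visit(pid, start, start + timedelta(hours=int(rng.integers(6, 193))),
                    VisitKind(["INPATIENT", "OUTPATIENT", "UNKNOWN"][
                        int(rng.choice([0, 1, 2], p=[0.3, 0.5, 0.2]))]))
    return b.store
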