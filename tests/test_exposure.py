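"""Overlap detection, concomitant pairs, and context-factor primitives."""

import itertools
from datetime import date, datetime, timedelta

import numpy as np
import pytest

import ddialert as d
from ddialert.cdm import (
    Concept, ConditionOccurrence, DrugExposure, Measurement, PatientStore,
    Person, Sex, Vocabulary,
)
from ddialert.exposure import MISSING

T0 = datetime(2016, 1, 1)


def _exp(eid, start_day, end_day, pid=1, concept=1950, **kw):
    return DrugExposure(eid, pid, concept, T0 + timedelta(days=start_day - 1),
                        T0 + timedelta(days=end_day - 1), **kw)


def _person(pid=1, birth=date(1970, 5, 1), sex=Sex.MALE):
    return Person(pid, birth, sex)


class TestOverlap:
    def test_shared_inclusive_endpoint_counts(self):
        assert d.exposures_overlap(_exp(1, 1, 5), _exp(2, 5, 10))

    def test_adjacent_days_do_not_overlap(self):
        assert not d.exposures_overlap(_exp(1, 1, 4), _exp(2, 5, 10))

    def test_exhaustive_against_point_membership_oracle(self):
        """All interval pairs with endpoints in 1..6 agree with brute-force
        shared-point membership (closed intervals at day resolution)."""
        spans = [(a, b) for a in range(1, 7) for b in range(a, 7)]
        for (a1, b1), (a2, b2) in itertools.product(spans, spans):
            expected = bool(set(range(a1, b1 + 1)) & set(range(a2, b2 + 1)))
            assert d.exposures_overlap(_exp(1, a1, b1), _exp(2, a2, b2)) == expected

    def test_symmetric_and_reflexive(self):
        e1, e2 = _exp(1, 1, 3), _exp(2, 2, 8)
        assert d.exposures_overlap(e1, e2) == d.exposures_overlap(e2, e1)
        assert d.exposures_overlap(e1, e1)


def _sets(vocab, library, a, b):
    return library.resolve(a, vocab), library.resolve(b, vocab)


class TestConcomitantPairs:
    def test_single_overlap_triggers_at_later_start(self, vocab, library):
        store = vocab
        store = PatientStore(concepts=store.concepts,
                             concept_ancestry=store.concept_ancestry)
        store.persons.append(_person())
        store.drug_exposures += [_exp(1, 1, 31, concept=1950),
                                 _exp(2, 10, 20, concept=1101)]
        set_a, set_b = _sets(store, library, "warfarin", "antidepressants")
        pairs = d.find_concomitant_pairs(store, set_a, set_b)
        assert len(pairs) == 1
        assert pairs[0].trigger_datetime == T0 + timedelta(days=9)

    def test_same_start_different_sig_directions_counted_separately(
            self, vocab, library):
        """Two same-drug orders at an identical start timestamp but different
        dosage directions are distinct exposures, hence distinct pairs."""
        store = PatientStore(concepts=vocab.concepts,
                             concept_ancestry=vocab.concept_ancestry)
        store.persons.append(_person())
        store.drug_exposures += [
            _exp(1, 1, 31, concept=1950),
            _exp(2, 10, 20, concept=1101, dose_direction="take in the morning"),
            _exp(3, 10, 15, concept=1101, dose_direction="take at bedtime"),
        ]
        set_a, set_b = _sets(store, library, "warfarin", "antidepressants")
        pairs = d.find_concomitant_pairs(store, set_a, set_b)
        assert len(pairs) == 2
        assert all(p.trigger_datetime == T0 + timedelta(days=9) for p in pairs)

    def test_random_population_matches_nested_loop_oracle(self, vocab, library):
        rng = np.random.default_rng(3)
        store = PatientStore(concepts=vocab.concepts,
                             concept_ancestry=vocab.concept_ancestry)
        eid = 0
        for pid in range(1, 51):
            store.persons.append(_person(pid))
            for _ in range(int(rng.integers(0, 8))):
                eid += 1
                start = int(rng.integers(1, 60))
                concept = int(rng.choice([1950, 1101, 1102, 1401, 2501]))
                store.drug_exposures.append(
                    _exp(eid, start, start + int(rng.integers(0, 15)),
                         pid=pid, concept=concept))
        set_a, set_b = _sets(store, library, "warfarin", "antidepressants")
        pairs = d.find_concomitant_pairs(store, set_a, set_b)
        # independent quadratic scan
        expected = set()
        for ea in store.drug_exposures:
            for eb in store.drug_exposures:
                if ea.person_id != eb.person_id or ea.exposure_id == eb.exposure_id:
                    continue
                if ea.drug_concept_id not in set_a.member_concept_ids:
                    continue
                if eb.drug_concept_id not in set_b.member_concept_ids:
                    continue
                if max(ea.start_datetime, eb.start_datetime) <= \
                        min(ea.end_datetime, eb.end_datetime):
                    expected.add((ea.person_id, ea.exposure_id, eb.exposure_id))
        got = {(p.person_id, p.object_exposure_id, p.precipitant_exposure_id)
               for p in pairs}
        assert got == expected

    def test_invariant_under_row_permutation(self, vocab, library):
        store = PatientStore(concepts=vocab.concepts,
                             concept_ancestry=vocab.concept_ancestry)
        store.persons.append(_person())
        store.drug_exposures += [_exp(1, 1, 31, concept=1950),
                                 _exp(2, 10, 20, concept=1101),
                                 _exp(3, 5, 12, concept=1102)]
        set_a, set_b = _sets(store, library, "warfarin", "antidepressants")
        forward = d.find_concomitant_pairs(store, set_a, set_b)
        store.drug_exposures.reverse()
        assert d.find_concomitant_pairs(store, set_a, set_b) == forward


class TestLatestMeasurement:
    def _store_with(self, values, vocab):
        store = PatientStore(concepts=vocab.concepts,
                             concept_ancestry=vocab.concept_ancestry)
        store.persons.append(_person())
        for i, (day, value) in enumerate(values, start=1):
            store.measurements.append(Measurement(
                i, 1, 3001, T0 + timedelta(days=day - 1), value, "mEq/L"))
        return store

    def test_most_recent_in_window_wins(self, vocab, library):
        store = self._store_with([(1, 4.0), (5, 3.2)], vocab)
        k = library.resolve("serum_potassium", store)
        m = d.latest_measurement(store, 1, k, T0 + timedelta(days=5), 30)
        assert m.value == 3.2

    def test_no_future_peeking(self, vocab, library):
        store = self._store_with([(7, 3.2)], vocab)
        k = library.resolve("serum_potassium", store)
        assert d.latest_measurement(store, 1, k, T0 + timedelta(days=5), 30) is MISSING

    def test_lookback_window_excludes_stale_values(self, vocab, library):
        store = self._store_with([(1, 4.0)], vocab)
        k = library.resolve("serum_potassium", store)
        assert d.latest_measurement(store, 1, k, T0 + timedelta(days=40), 30) is MISSING

    def test_equivalent_units_accepted_others_ignored(self, vocab, library):
        store = self._store_with([(1, 4.0)], vocab)
        store.measurements.append(
            Measurement(2, 1, 3001, T0 + timedelta(days=2), 4.4, "mmol/L"))
        store.measurements.append(
            Measurement(3, 1, 3001, T0 + timedelta(days=3), 123.0, "mg/dL"))
        k = library.resolve("serum_potassium", store)
        m = d.latest_measurement(store, 1, k, T0 + timedelta(days=5), 30,
                                 expected_unit="mEq/L")
        assert m.value == 4.4  # mmol/L is 1:1 equivalent; mg/dL row ignored

    def test_matches_full_scan_oracle_on_random_measurements(self, vocab, library):
        rng = np.random.default_rng(9)
        store = PatientStore(concepts=vocab.concepts,
                             concept_ancestry=vocab.concept_ancestry)
        store.persons.append(_person())
        for i in range(1, 201):
            store.measurements.append(Measurement(
                i, 1, int(rng.choice([3001, 3002])),
                T0 + timedelta(days=int(rng.integers(0, 90)),
                               hours=int(rng.integers(0, 24))),
                float(rng.uniform(2, 7)), "mEq/L"))
        k = library.resolve("serum_potassium", store)
        as_of = T0 + timedelta(days=45)
        horizon = as_of - timedelta(days=10)
        candidates = [m for m in store.measurements
                      if m.measurement_concept_id == 3001
                      and horizon <= m.taken_datetime <= as_of]
        got = d.latest_measurement(store, 1, k, as_of, 10)
        if not candidates:
            assert got is MISSING
        else:
            best = max(candidates, key=lambda m: (m.taken_datetime, m.measurement_id))
            assert got == best


class TestAge:
    def test_anniversary_day_counts(self):
        p = _person(birth=date(1948, 1, 15))
        assert d.age_at(p, datetime(2016, 1, 15)) == 68
        assert d.age_at(p, datetime(2016, 1, 14)) == 67

    def test_before_birth_is_an_error(self):
        with pytest.raises(ValueError):
            d.age_at(_person(birth=date(1990, 1, 1)), datetime(1980, 1, 1))

    def test_matches_calendar_counting_oracle(self):
        """Random (birth, as_of) pairs agree with explicit anniversary
        counting."""
        rng = np.random.default_rng(4)
        for _ in range(300):
            birth = date(1930, 1, 1) + timedelta(days=int(rng.integers(0, 25000)))
            as_of = datetime(2016, 1, 1) + timedelta(days=int(rng.integers(0, 90)))
            # count the anniversaries that have passed, one year at a time
            years = 0
            while True:
                try:
                    anniversary = birth.replace(year=birth.year + years + 1)
                except ValueError:  # Feb 29
                    anniversary = date(birth.year + years + 1, 3, 1)
                if anniversary <= as_of.date():
                    years += 1
                else:
                    break
            assert d.age_at(_person(birth=birth), as_of) == years


class TestConditionsAndDiscontinuation:
    def _store(self, vocab, conditions=(), exposures=()):
        store = PatientStore(concepts=vocab.concepts,
                             concept_ancestry=vocab.concept_ancestry)
        store.persons.append(_person())
        store.conditions += list(conditions)
        store.drug_exposures += list(exposures)
        return store

    def test_history_of_condition_is_ever(self, vocab, library):
        store = self._store(vocab, conditions=[
            ConditionOccurrence(1, 4001, date(2010, 3, 1), date(2010, 4, 1))])
        mi = library.resolve("myocardial_infarction", store)
        as_of = datetime(2016, 2, 1)
        assert d.has_active_condition(store, 1, mi, as_of, "EVER")
        assert not d.has_active_condition(store, 1, mi, as_of, "ACTIVE")

    def test_resolved_condition_not_active(self, vocab, library):
        store = self._store(vocab, conditions=[
            ConditionOccurrence(1, 4002, date(2016, 1, 1), date(2016, 1, 20))])
        sepsis = library.resolve("sepsis", store)
        assert not d.has_active_condition(store, 1, sepsis,
                                          datetime(2016, 2, 1), "ACTIVE")
        assert d.has_active_condition(store, 1, sepsis,
                                      datetime(2016, 1, 10), "ACTIVE")

    def test_no_conditions_false_in_both_modes(self, vocab, library):
        store = self._store(vocab)
        mi = library.resolve("myocardial_infarction", store)
        assert not d.has_active_condition(store, 1, mi, datetime(2016, 1, 1), "EVER")
        assert not d.has_active_condition(store, 1, mi, datetime(2016, 1, 1), "ACTIVE")

    def test_discontinuation_detected_only_after_stop(self, vocab, library):
        clonidine = None
        as_of = T0 + timedelta(days=20)
        store = self._store(vocab, exposures=[_exp(1, 10, 19, concept=1701)])
        clonidine = library.resolve("clonidine", store)
        assert d.detect_discontinuation(store, 1, clonidine, as_of, 7)
        # ongoing exposure suppresses the withdrawal flag
        store.drug_exposures.append(_exp(2, 15, 40, concept=1701))
        assert not d.detect_discontinuation(store, 1, clonidine, as_of, 7)

    def test_exposure_ending_exactly_at_as_of_counts_as_discontinued(
            self, vocab, library):
        store = self._store(vocab, exposures=[_exp(1, 10, 20, concept=1701)])
        clonidine = library.resolve("clonidine", store)
        assert d.detect_discontinuation(store, 1, clonidine,
                                        T0 + timedelta(days=19), 7)

    def test_old_stop_outside_window_not_flagged(self, vocab, library):
        store = self._store(vocab, exposures=[_exp(1, 1, 5, concept=1701)])
        clonidine = library.resolve("clonidine", store)
        assert not d.detect_discontinuation(store, 1, clonidine,
                                            T0 + timedelta(days=30), 7)


class TestBuildContext:
    def _citalopram_pair_store(self, vocab):
        store = PatientStore(concepts=vocab.concepts,
                             concept_ancestry=vocab.concept_ancestry)
        store.persons.append(_person(birth=date(1946, 1, 1), sex=Sex.FEMALE))
        store.drug_exposures += [
            _exp(1, 1, 31, concept=1101, daily_dose_value=20.0,
                 daily_dose_unit="mg/day"),
            _exp(2, 10, 20, concept=1501),
        ]
        store.measurements.append(Measurement(
            1, 1, 3001, T0 + timedelta(days=9, hours=-2), 3.2, "mEq/L"))
        return store

    def test_citalopram_context_factors(self, vocab, library, tree_by_id, config):
        store = self._citalopram_pair_store(vocab)
        tree = tree_by_id["citalopram_qt"]
        set_a = library.resolve("citalopram", store)
        set_b = library.resolve("qt_prolonging_agents", store)
        pair, = d.find_concomitant_pairs(store, set_a, set_b)
        ctx = d.build_context(store, pair, tree, config, library)
        assert ctx.sex == "FEMALE"
        assert ctx.factor_values["female"] is True
        assert ctx.factor_values["age_years"] == 70
        assert ctx.factor_values["serum_potassium"] == 3.2
        assert ctx.factor_values["k_below_3_5"] is True
        assert ctx.factor_values["qtc"] is MISSING
        assert ctx.factor_values["citalopram_dose"] == 20.0
        # provenance points at the source measurement
        assert ctx.provenance["serum_potassium"] == 1

    def test_exactly_the_declared_factors_no_more_no_fewer(
            self, vocab, library, tree_by_id, config):
        store = self._citalopram_pair_store(vocab)
        tree = tree_by_id["citalopram_qt"]
        pair, = d.find_concomitant_pairs(
            store, library.resolve("citalopram", store),
            library.resolve("qt_prolonging_agents", store))
        ctx = d.build_context(store, pair, tree, config, library)
        assert set(ctx.factor_values) == {f.name for f in tree.factor_manifest}

    def test_context_is_pure(self, vocab, library, tree_by_id, config):
        store = self._citalopram_pair_store(vocab)
        tree = tree_by_id["citalopram_qt"]
        pair, = d.find_concomitant_pairs(
            store, library.resolve("citalopram", store),
            library.resolve("qt_prolonging_agents", store))
        c1 = d.build_context(store, pair, tree, config, library)
        c2 = d.build_context(store, pair, tree, config, library)
        assert c1 == c2

    def test_no_labs_means_missing_lab_factors(self, vocab, library, tree_by_id,
                                               config):
        store = self._citalopram_pair_store(vocab)
        store.measurements.clear()
        tree = tree_by_id["citalopram_qt"]
        pair, = d.find_concomitant_pairs(
            store, library.resolve("citalopram", store),
            library.resolve("qt_prolonging_agents", store))
        ctx = d.build_context(store, pair, tree, config, library)
        assert ctx.factor_values["serum_potassium"] is MISSING
        assert ctx.factor_values["k_below_3_5"] is MISSING
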