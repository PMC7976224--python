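"""Tree parsing/validation, predicate evaluation, and run aggregation."""

import copy
import json
from datetime import datetime

import pytest

import ddialert as d
from ddialert.exposure import MISSING, PatientContext
from ddialert.rules import (
    Color, EvaluationError, RECOMMENDATIONS, TreeParseError, serialize_tree,
)


def _ctx(values, age=45, sex="MALE"):
    return PatientContext(person_id=1, as_of=datetime(2016, 2, 1), age_years=age,
                          sex=sex, factor_values=values)


SINGLE_LEAF = {
    "ddi_id": "demo", "object_set": "warfarin", "precipitant_set": "aspirin",
    "factors": [], "root": "r", "nodes": {"r": {"kind": "LEAF", "leaf_id": "g",
                                                "color": "GREEN"}},
}


class TestParsing:
    def test_single_green_leaf_tree_is_valid(self):
        tree = d.parse_tree(SINGLE_LEAF)
        leaf_id, cls, path = d.evaluate_tree(tree, _ctx({}))
        assert (leaf_id, cls.color, path) == ("g", Color.GREEN, ["r"])
        assert cls.recommendation == "No Special Precautions"

    def test_undeclared_factor_is_a_parse_error_naming_the_node(self):
        doc = copy.deepcopy(SINGLE_LEAF)
        doc["nodes"] = {
            "r": {"kind": "PREDICATE", "factor": "qtc", "comparator": "GT",
                  "threshold": 480, "true_branch": "a", "false_branch": "b"},
            "a": {"kind": "LEAF", "leaf_id": "a", "color": "RED"},
            "b": {"kind": "LEAF", "leaf_id": "b", "color": "GREEN"},
        }
        with pytest.raises(TreeParseError, match=r"'r'.*'qtc'"):
            d.parse_tree(doc)

    def test_dangling_branch_and_cycle_are_rejected(self):
        doc = copy.deepcopy(SINGLE_LEAF)
        doc["factors"] = [{"name": "x", "type": "boolean",
                           "extractor": "condition_present",
                           "params": {"set": "sepsis"}}]
        doc["nodes"] = {
            "r": {"kind": "PREDICATE", "factor": "x", "comparator": "EQ",
                  "threshold": True, "true_branch": "nowhere",
                  "false_branch": "r"},
        }
        with pytest.raises(TreeParseError):
            d.parse_tree(doc)
        # a two-node cycle back to the root
        doc["nodes"] = {
            "r": {"kind": "PREDICATE", "factor": "x", "comparator": "EQ",
                  "threshold": True, "true_branch": "s", "false_branch": "s"},
            "s": {"kind": "PREDICATE", "factor": "x", "comparator": "EQ",
                  "threshold": True, "true_branch": "r", "false_branch": "r"},
        }
        with pytest.raises(TreeParseError):
            d.parse_tree(doc)

    def test_all_eight_bundled_documents_parse_with_distinct_ids(self, trees):
        assert len(trees) == 8
        assert len({t.ddi_id for t in trees}) == 8

    def test_serialization_round_trips(self, trees):
        for tree in trees:
            doc = serialize_tree(tree)
            again = d.parse_tree(json.dumps(doc))
            assert serialize_tree(again) == doc

    def test_recommendation_texts_are_fixed(self):
        assert RECOMMENDATIONS[Color.RED] == "Avoid Combination"
        assert RECOMMENDATIONS[Color.YELLOW] == \
            "Usually Avoid Combination or Minimize Risk"
        assert RECOMMENDATIONS[Color.GREEN] == "No Special Precautions"


class TestEvaluation:
    @pytest.fixture()
    def threshold_tree(self):
        return d.parse_tree({
            "ddi_id": "demo", "object_set": "s", "precipitant_set": "t",
            "factors": [{"name": "serum_potassium", "type": "number",
                         "extractor": "latest_lab",
                         "params": {"set": "serum_potassium"}}],
            "root": "n",
            "nodes": {
                "n": {"kind": "PREDICATE", "factor": "serum_potassium",
                      "comparator": "LT", "threshold": 3.5,
                      "missing_branch": "TRUE_BRANCH",
                      "true_branch": "low", "false_branch": "ok"},
                "low": {"kind": "LEAF", "leaf_id": "low", "color": "RED"},
                "ok": {"kind": "LEAF", "leaf_id": "ok", "color": "GREEN"},
            },
        })

    def test_hypokalemia_takes_true_branch(self, threshold_tree):
        leaf, _, _ = d.evaluate_tree(threshold_tree, _ctx({"serum_potassium": 3.2}))
        assert leaf == "low"
        leaf, _, _ = d.evaluate_tree(threshold_tree, _ctx({"serum_potassium": 3.5}))
        assert leaf == "ok"

    def test_missing_follows_declared_branch(self, threshold_tree):
        with_missing, _, _ = d.evaluate_tree(threshold_tree,
                                             _ctx({"serum_potassium": MISSING}))
        when_true, _, _ = d.evaluate_tree(threshold_tree,
                                          _ctx({"serum_potassium": 3.0}))
        assert with_missing == when_true

    def test_age_threshold_is_inclusive(self, tree_by_id):
        """'age 68 or older' counts as a risk factor at exactly 68."""
        tree = tree_by_id["citalopram_qt"]
        base = {"sex": "MALE", "qtc": 440.0, "serum_potassium": 4.2,
                "loop_diuretic": False, "hx_mi": False, "dx_sepsis": False,
                "dx_heart_failure": False, "citalopram_dose": 20.0}
        from ddialert.exposure import compute_derived_factors
        at_68 = compute_derived_factors(tree, {**base, "age_years": 68})
        at_67 = compute_derived_factors(tree, {**base, "age_years": 67})
        leaf_68, _, _ = d.evaluate_tree(tree, _ctx(at_68, age=68))
        leaf_67, _, _ = d.evaluate_tree(tree, _ctx(at_67, age=67))
        assert leaf_68 == "yellow_single_risk_factor"
        assert leaf_67 == "green_no_risk_factors"

    def test_type_mismatch_is_an_evaluation_error(self, threshold_tree):
        with pytest.raises(EvaluationError):
            d.evaluate_tree(threshold_tree, _ctx({"serum_potassium": "high"}))

    def test_missing_context_factor_is_an_evaluation_error(self, threshold_tree):
        with pytest.raises(EvaluationError, match="serum_potassium"):
            d.evaluate_tree(threshold_tree, _ctx({}))


class TestRunAggregation:
    def test_empty_store_yields_no_events_and_zero_report(self, trees, config,
                                                          library, vocab):
        events = d.run_algorithm(vocab, trees[0], config, library)
        assert events == []
        report = d.run_all(vocab, trees, config, library)
        for r in report.per_ddi.values():
            assert r.n_basic_concomitant == 0
            assert r.filtered_fraction == 0.0

    def test_duplicate_ddi_id_rejected(self, trees, config, library, vocab):
        with pytest.raises(ValueError, match="duplicate"):
            d.run_all(vocab, [trees[0], trees[0]], config, library)

    def test_one_event_per_pair_and_counts_conserve(self, trees, config, library):
        store = d.generate_random(d.GeneratorSpec(seed=5, n_persons=120))
        report = d.run_all(store, trees, config, library)
        for tree in trees:
            r = report.per_ddi[tree.ddi_id]
            set_a = library.resolve(tree.object_set, store)
            set_b = library.resolve(tree.precipitant_set, store)
            n_pairs = len(d.find_concomitant_pairs(store, set_a, set_b))
            assert r.n_basic_concomitant == n_pairs
            assert sum(r.leaf_counts.values()) == n_pairs
            assert sum(r.color_counts.values()) == n_pairs
            assert sum(r.daily_counts.values()) == n_pairs

    def test_events_sorted_by_person_and_time(self, trees, config, library):
        store = d.generate_random(d.GeneratorSpec(seed=6, n_persons=80))
        for tree in trees:
            events = d.run_algorithm(store, tree, config, library)
            keys = [(e.person_id, e.trigger_datetime) for e in events]
            assert keys == sorted(keys)

    def test_identical_inputs_give_byte_identical_reports(self, trees, config,
                                                          library, replica):
        r1 = d.run_all(replica, trees, config, library).to_json()
        r2 = d.run_all(replica, trees, config, library).to_json()
        assert r1 == r2

    def test_filtered_fraction_is_green_over_basic(self, trees, config, library,
                                                   replica):
        report = d.run_all(replica, trees, config, library)
        r = report.per_ddi["potassium_k_sparing_diuretic"]
        assert r.n_basic_concomitant == 3
        assert r.color_counts == {"RED": 1, "YELLOW": 1, "GREEN": 1}
        assert r.filtered_fraction == pytest.approx(1 / 3)

    def test_event_paths_start_at_root_and_end_at_leaf(self, trees, config,
                                                       library, replica):
        for tree in trees:
            for ev in d.run_algorithm(replica, tree, config, library):
                assert ev.path[0] == tree.root
                last = tree.nodes[ev.path[-1]]
                assert last.kind == "LEAF" and last.leaf_id == ev.leaf_id
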