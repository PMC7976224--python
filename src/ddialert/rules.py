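"""Decision-tree DDI algorithms: document parsing, evaluation, and run reports.

Each of the eight bundled DDI algorithms is a declarative JSON document (one
file per DDI under ``ddialert/data/rules/``): an object/precipitant
concept-set pair, a factor manifest, and a rooted binary tree of predicate
nodes terminating in Red/Yellow/Green leaves.  Leaf colors carry the fixed
operational recommendations:

* RED    — "Avoid Combination"
* YELLOW — "Usually Avoid Combination or Minimize Risk"
* GREEN  — "No Special Precautions"

GREEN is the filtering classification: a GREEN-classified concomitant
exposure is one the contextualized algorithm says need not interrupt the
ordering clinician's workflow.

The bundled trees use exactly the drug/patient factors published for the
eight interactions; branch thresholds are named values inside the documents,
so reconciling them against an institution's own policies is a data edit, not
a code change.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from importlib import resources
from pathlib import Path

from .cdm import PatientStore
from .concept_sets import ConceptSetLibrary, load_bundled_library
from .exposure import (
    MISSING, ConcomitantPair, ContextConfig, PatientContext,
    BASE_EXTRACTORS, DERIVED_EXTRACTORS, build_context, find_concomitant_pairs,
)

__all__ = [
    "Color", "LeafClassification", "RECOMMENDATIONS",
    "FactorDeclaration", "DecisionNode", "DecisionTree", "AlertEvent",
    "DDIReport", "RunReport", "TreeParseError", "EvaluationError",
    "parse_tree", "serialize_tree", "evaluate_tree",
    "run_algorithm", "run_all", "load_bundled_trees",
]


class Color(enum.Enum):
    """Operational classification; ordered by severity (GREEN < YELLOW < RED)."""

    GREEN = 0
    YELLOW = 1
    RED = 2

    def __lt__(self, other):
        if isinstance(other, Color):
            return self.value < other.value
        return NotImplemented

    def __le__(self, other):
        if isinstance(other, Color):
            return self.value <= other.value
        return NotImplemented


RECOMMENDATIONS = {
    Color.RED: "Avoid Combination",
    Color.YELLOW: "Usually Avoid Combination or Minimize Risk",
    Color.GREEN: "No Special Precautions",
}


@dataclass(frozen=True)
class LeafClassification:
    color: Color

    @property
    def recommendation(self) -> str:
        return RECOMMENDATIONS[self.color]


class TreeParseError(Exception):
    pass


class EvaluationError(Exception):
    pass


@dataclass(frozen=True)
class FactorDeclaration:
    name: str
    type: str  # "number" | "boolean" | "enum" | "count"
    extractor: str
    params: dict = field(default_factory=dict)

    def source_factors(self) -> list[str]:
        """Names of earlier factors a derived extractor reads."""
        if self.extractor == "count_true":
            return list(self.params.get("sources", []))
        if self.extractor in ("threshold_flag", "equals_flag"):
            return [self.params["source"]]
        return []

    def concept_set_ids(self) -> list[str]:
        ids = []
        if "set" in self.params:
            ids.append(self.params["set"])
        for tier in self.params.get("tiers", []):
            ids.append(tier["set"])
        return ids


_COMPARATORS = {"LT", "LE", "GT", "GE", "EQ", "IN_SET", "PRESENT", "ABSENT"}


@dataclass(frozen=True)
class DecisionNode:
    node_id: str
    kind: str  # "PREDICATE" | "LEAF"
    # predicate fields
    factor: str | None = None
    comparator: str | None = None
    threshold: object = None
    missing_branch: str | None = None  # "TRUE_BRANCH" | "FALSE_BRANCH"
    true_branch: str | None = None
    false_branch: str | None = None
    # leaf fields
    leaf_id: str | None = None
    classification: LeafClassification | None = None


@dataclass
class DecisionTree:
    ddi_id: str
    name: str
    object_set: str
    precipitant_set: str
    factor_manifest: list[FactorDeclaration]
    nodes: dict[str, DecisionNode]
    root: str
    monotone_severity: bool = False

    def leaves(self) -> list[DecisionNode]:
        return [n for n in self.nodes.values() if n.kind == "LEAF"]

    def leaf_ids(self) -> list[str]:
        return [n.leaf_id for n in self.leaves()]

    def factor(self, name: str) -> FactorDeclaration:
        for f in self.factor_manifest:
            if f.name == name:
                return f
        raise KeyError(name)

    def referenced_set_ids(self) -> set[str]:
        ids = {self.object_set, self.precipitant_set}
        for f in self.factor_manifest:
            ids.update(f.concept_set_ids())
        return ids


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_tree(document: dict | str) -> DecisionTree:
    """Parse and validate a rule document (a dict or JSON text).

    Raises :class:`TreeParseError` naming the offending node for schema
    violations, cycles, dangling branches, and undeclared factors.  Parsing is
    loss-free: :func:`serialize_tree` round-trips.
    """
    doc = json.loads(document) if isinstance(document, str) else document
    for key in ("ddi_id", "object_set", "precipitant_set", "factors", "root", "nodes"):
        if key not in doc:
            raise TreeParseError(f"rule document missing required field {key!r}")
    ddi_id = str(doc["ddi_id"])

    manifest: list[FactorDeclaration] = []
    seen_names: set[str] = set()
    for f in doc["factors"]:
        decl = FactorDeclaration(
            name=str(f["name"]), type=str(f["type"]),
            extractor=str(f["extractor"]), params=dict(f.get("params", {})))
        if decl.name in seen_names:
            raise TreeParseError(f"{ddi_id}: duplicate factor {decl.name!r}")
        if decl.extractor not in BASE_EXTRACTORS and decl.extractor not in DERIVED_EXTRACTORS:
            raise TreeParseError(
                f"{ddi_id}: factor {decl.name!r} uses unknown extractor "
                f"{decl.extractor!r}")
        for src in decl.source_factors():
            if src not in seen_names:
                raise TreeParseError(
                    f"{ddi_id}: factor {decl.name!r} derives from {src!r}, which is "
                    f"not declared earlier in the manifest")
        seen_names.add(decl.name)
        manifest.append(decl)

    nodes: dict[str, DecisionNode] = {}
    for node_id, spec in doc["nodes"].items():
        kind = spec.get("kind")
        if kind == "LEAF":
            try:
                color = Color[spec["color"]]
            except KeyError:
                raise TreeParseError(
                    f"{ddi_id}: node {node_id!r} has invalid leaf color "
                    f"{spec.get('color')!r}") from None
            nodes[node_id] = DecisionNode(
                node_id=node_id, kind="LEAF",
                leaf_id=str(spec.get("leaf_id", node_id)),
                classification=LeafClassification(color))
        elif kind == "PREDICATE":
            comparator = spec.get("comparator")
            if comparator not in _COMPARATORS:
                raise TreeParseError(
                    f"{ddi_id}: node {node_id!r} has invalid comparator {comparator!r}")
            factor = spec.get("factor")
            if factor not in seen_names:
                raise TreeParseError(
                    f"{ddi_id}: node {node_id!r} references undeclared factor {factor!r}")
            missing_branch = spec.get("missing_branch", "TRUE_BRANCH")
            if missing_branch not in ("TRUE_BRANCH", "FALSE_BRANCH"):
                raise TreeParseError(
                    f"{ddi_id}: node {node_id!r} has invalid missing_branch "
                    f"{missing_branch!r}")
            nodes[node_id] = DecisionNode(
                node_id=node_id, kind="PREDICATE", factor=factor,
                comparator=comparator, threshold=spec.get("threshold"),
                missing_branch=missing_branch,
                true_branch=spec.get("true_branch"),
                false_branch=spec.get("false_branch"))
        else:
            raise TreeParseError(f"{ddi_id}: node {node_id!r} has invalid kind {kind!r}")

    root = str(doc["root"])
    if root not in nodes:
        raise TreeParseError(f"{ddi_id}: root {root!r} is not a node")

    # structural validation: rooted tree, single parent, all paths hit a leaf
    parent_count: dict[str, int] = {nid: 0 for nid in nodes}
    for node in nodes.values():
        if node.kind != "PREDICATE":
            continue
        for branch in (node.true_branch, node.false_branch):
            if branch not in nodes:
                raise TreeParseError(
                    f"{ddi_id}: node {node.node_id!r} has dangling branch {branch!r}")
            parent_count[branch] += 1
    if parent_count[root] != 0:
        raise TreeParseError(f"{ddi_id}: root {root!r} has a parent (cycle)")
    multi = [nid for nid, n in parent_count.items() if n > 1]
    if multi:
        raise TreeParseError(f"{ddi_id}: nodes {multi} have multiple parents")
    # reachability from root; since each non-root node has exactly one parent
    # and the root none, reachability of all nodes implies acyclicity
    seen: set[str] = set()
    stack = [root]
    while stack:
        nid = stack.pop()
        if nid in seen:
            raise TreeParseError(f"{ddi_id}: cycle detected at node {nid!r}")
        seen.add(nid)
        node = nodes[nid]
        if node.kind == "PREDICATE":
            stack.extend([node.true_branch, node.false_branch])
    unreachable = set(nodes) - seen
    if unreachable:
        raise TreeParseError(f"{ddi_id}: nodes {sorted(unreachable)} unreachable from root")
    leaf_ids = [n.leaf_id for n in nodes.values() if n.kind == "LEAF"]
    if len(set(leaf_ids)) != len(leaf_ids):
        raise TreeParseError(f"{ddi_id}: duplicate leaf_id in {sorted(leaf_ids)}")

    return DecisionTree(
        ddi_id=ddi_id,
        name=str(doc.get("name", ddi_id)),
        object_set=str(doc["object_set"]),
        precipitant_set=str(doc["precipitant_set"]),
        factor_manifest=manifest,
        nodes=nodes,
        root=root,
        monotone_severity=bool(doc.get("monotone_severity", False)),
    )


def serialize_tree(tree: DecisionTree) -> dict:
    """Inverse of :func:`parse_tree` (loss-free round-trip)."""
    nodes = {}
    for nid, n in tree.nodes.items():
        if n.kind == "LEAF":
            nodes[nid] = {"kind": "LEAF", "leaf_id": n.leaf_id,
                          "color": n.classification.color.name}
        else:
            nodes[nid] = {"kind": "PREDICATE", "factor": n.factor,
                          "comparator": n.comparator, "threshold": n.threshold,
                          "missing_branch": n.missing_branch,
                          "true_branch": n.true_branch,
                          "false_branch": n.false_branch}
    return {
        "ddi_id": tree.ddi_id,
        "name": tree.name,
        "object_set": tree.object_set,
        "precipitant_set": tree.precipitant_set,
        "monotone_severity": tree.monotone_severity,
        "factors": [{"name": f.name, "type": f.type, "extractor": f.extractor,
                     "params": f.params} for f in tree.factor_manifest],
        "root": tree.root,
        "nodes": nodes,
    }


def load_bundled_trees() -> list[DecisionTree]:
    """The eight bundled DDI algorithm documents, sorted by ddi_id."""
    root = resources.files("ddialert").joinpath("data/rules")
    trees = []
    with resources.as_file(root) as path:
        for doc_path in sorted(Path(path).glob("*.json")):
            trees.append(parse_tree(doc_path.read_text()))
    return trees


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _apply_predicate(node: DecisionNode, value) -> bool | None:
    """Returns the branch outcome, or None when MISSING routing applies."""
    comparator = node.comparator
    if comparator == "PRESENT":
        return value is not MISSING
    if comparator == "ABSENT":
        return value is MISSING
    if value is MISSING:
        return None
    if comparator == "EQ":
        return value == node.threshold
    if comparator == "IN_SET":
        return value in node.threshold
    # ordered comparators require numbers on both sides
    if not isinstance(value, (int, float)) or isinstance(value, bool) or \
            not isinstance(node.threshold, (int, float)):
        raise EvaluationError(
            f"node {node.node_id!r}: comparator {comparator} needs numeric "
            f"value and threshold, got {value!r} vs {node.threshold!r}")
    if comparator == "LT":
        return value < node.threshold
    if comparator == "LE":
        return value <= node.threshold
    if comparator == "GT":
        return value > node.threshold
    if comparator == "GE":
        return value >= node.threshold
    raise EvaluationError(f"unknown comparator {comparator!r}")


def evaluate_tree(tree: DecisionTree, context: PatientContext):
    """Deterministic descent from the root; MISSING factor values follow each
    node's declared ``missing_branch``.  Returns (leaf_id, classification,
    path of node_ids from root to leaf)."""
    path: list[str] = []
    node = tree.nodes[tree.root]
    while True:
        path.append(node.node_id)
        if node.kind == "LEAF":
            return node.leaf_id, node.classification, path
        if node.factor not in context.factor_values:
            raise EvaluationError(
                f"{tree.ddi_id}: context lacks factor {node.factor!r} required "
                f"by node {node.node_id!r}")
        outcome = _apply_predicate(node, context.factor_values[node.factor])
        if outcome is None:
            outcome = node.missing_branch == "TRUE_BRANCH"
        node = tree.nodes[node.true_branch if outcome else node.false_branch]


@dataclass(frozen=True)
class AlertEvent:
    ddi_id: str
    person_id: int
    trigger_datetime: datetime
    object_exposure_id: int
    precipitant_exposure_id: int
    leaf_id: str
    classification: LeafClassification
    path: tuple[str, ...]
    context_snapshot: PatientContext


def run_algorithm(store: PatientStore, tree: DecisionTree, config: ContextConfig,
                  library: ConceptSetLibrary | None = None) -> list[AlertEvent]:
    """Classify every basic concomitant exposure for one DDI.

    Exactly one event per concomitant pair; events sorted by
    (person_id, trigger time, exposure ids).
    """
    if library is None:
        library = load_bundled_library()
    set_a = library.resolve(tree.object_set, store)
    set_b = library.resolve(tree.precipitant_set, store)
    events: list[AlertEvent] = []
    for pair in find_concomitant_pairs(store, set_a, set_b):
        context = build_context(store, pair, tree, config, library)
        leaf_id, classification, path = evaluate_tree(tree, context)
        events.append(AlertEvent(
            ddi_id=tree.ddi_id,
            person_id=pair.person_id,
            trigger_datetime=pair.trigger_datetime,
            object_exposure_id=pair.object_exposure_id,
            precipitant_exposure_id=pair.precipitant_exposure_id,
            leaf_id=leaf_id,
            classification=classification,
            path=tuple(path),
            context_snapshot=context,
        ))
    return events


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class DDIReport:
    ddi_id: str
    n_basic_concomitant: int
    leaf_counts: dict[str, int]
    color_counts: dict[str, int]
    filtered_fraction: float
    daily_counts: dict[date, int]
    daily_leaf_counts: dict[tuple[date, str], int]

    def to_json_dict(self) -> dict:
        return {
            "ddi_id": self.ddi_id,
            "n_basic_concomitant": self.n_basic_concomitant,
            "leaf_counts": dict(sorted(self.leaf_counts.items())),
            "color_counts": {c: self.color_counts.get(c, 0)
                             for c in ("RED", "YELLOW", "GREEN")},
            "filtered_fraction": self.filtered_fraction,
            "daily_counts": {d.isoformat(): n
                             for d, n in sorted(self.daily_counts.items())},
            "daily_leaf_counts": {f"{d.isoformat()}|{leaf}": n for (d, leaf), n
                                  in sorted(self.daily_leaf_counts.items())},
        }


@dataclass
class RunReport:
    per_ddi: dict[str, DDIReport]
    events: dict[str, list[AlertEvent]]

    def to_json(self) -> str:
        doc = {"ddis": [self.per_ddi[k].to_json_dict() for k in sorted(self.per_ddi)]}
        total = sum(r.n_basic_concomitant for r in self.per_ddi.values())
        green = sum(r.color_counts.get("GREEN", 0) for r in self.per_ddi.values())
        doc["overall"] = {
            "n_basic_concomitant": total,
            "n_green_filtered": green,
            "filtered_fraction": (green / total) if total else 0.0,
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def summarize(tree: DecisionTree, events: list[AlertEvent]) -> DDIReport:
    leaf_counts = {leaf: 0 for leaf in tree.leaf_ids()}
    color_counts = {"RED": 0, "YELLOW": 0, "GREEN": 0}
    daily: dict[date, int] = {}
    daily_leaf: dict[tuple[date, str], int] = {}
    for ev in events:
        leaf_counts[ev.leaf_id] = leaf_counts.get(ev.leaf_id, 0) + 1
        color_counts[ev.classification.color.name] += 1
        day = ev.trigger_datetime.date()
        daily[day] = daily.get(day, 0) + 1
        key = (day, ev.leaf_id)
        daily_leaf[key] = daily_leaf.get(key, 0) + 1
    n = len(events)
    return DDIReport(
        ddi_id=tree.ddi_id,
        n_basic_concomitant=n,
        leaf_counts=leaf_counts,
        color_counts=color_counts,
        filtered_fraction=(color_counts["GREEN"] / n) if n else 0.0,
        daily_counts=daily,
        daily_leaf_counts=daily_leaf,
    )


def run_all(store: PatientStore, trees: list[DecisionTree], config: ContextConfig,
            library: ConceptSetLibrary | None = None) -> RunReport:
    """Run every tree and aggregate the two-bar quantities per DDI:
    basic concomitant count, per-leaf/per-color breakdowns, and the filtered
    fraction (GREEN / basic)."""
    if not trees:
        raise ValueError("trees must be non-empty")
    ids = [t.ddi_id for t in trees]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate ddi_id among trees: {sorted(ids)}")
    if library is None:
        library = load_bundled_library()
    per_ddi: dict[str, DDIReport] = {}
    events: dict[str, list[AlertEvent]] = {}
    for tree in trees:
        evs = run_algorithm(store, tree, config, library)
        events[tree.ddi_id] = evs
        per_ddi[tree.ddi_id] = summarize(tree, evs)
    return RunReport(per_ddi=per_ddi, events=events)
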