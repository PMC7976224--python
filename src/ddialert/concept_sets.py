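"""Named concept sets over RxNorm / LOINC / SNOMED vocabularies.

A :class:`ConceptSetDefinition` mirrors a Value Set Authority Center-style
export: seed concepts, an ``include_descendants`` switch that pulls in the
transitive closure of the store's concept ancestry, and explicit exclusions.
Bundled definitions live as one JSON document per set under
``ddialert/data/concept_sets/`` with a manifest mapping each DDI algorithm to
the sets it uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx

from .cdm import PatientStore, Vocabulary

__all__ = [
    "ConceptSetDefinition", "ResolvedConceptSet", "ConceptSetResolutionError",
    "resolve", "is_member", "ConceptSetLibrary", "load_bundled_library",
    "load_library",
]


class ConceptSetResolutionError(Exception):
    pass


@dataclass(frozen=True)
class ConceptSetDefinition:
    set_id: str
    name: str
    vocabulary: Vocabulary
    seed_concept_ids: tuple[int, ...]
    include_descendants: bool = False
    excluded_concept_ids: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.seed_concept_ids:
            raise ValueError(f"concept set {self.set_id!r}: seed list must be non-empty")


@dataclass(frozen=True)
class ResolvedConceptSet:
    set_id: str
    member_concept_ids: frozenset[int]

    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self.member_concept_ids


def is_member(concept_id: int, resolved: ResolvedConceptSet) -> bool:
    """Pure membership test; ids absent from the vocabulary are simply non-members."""
    return concept_id in resolved.member_concept_ids


def resolve(definition: ConceptSetDefinition, store: PatientStore) -> ResolvedConceptSet:
    """Resolve a definition against a store's vocabulary.

    membership = seeds ∪ (transitive descendants, if requested) − exclusions.
    The ancestry table holds direct parent→child edges; descendants are the
    transitive closure.
    """
    known = {c.concept_id for c in store.concepts}
    for seed in definition.seed_concept_ids:
        if seed not in known:
            raise ConceptSetResolutionError(
                f"concept set {definition.set_id!r}: seed concept {seed} "
                f"not present in store vocabulary")
    members = set(definition.seed_concept_ids)
    if definition.include_descendants:
        graph = nx.DiGraph(store.concept_ancestry)
        for seed in definition.seed_concept_ids:
            if seed in graph:
                members |= nx.descendants(graph, seed)
    members -= set(definition.excluded_concept_ids)
    if not members:
        raise ConceptSetResolutionError(
            f"concept set {definition.set_id!r}: resolution produced an empty set")
    return ResolvedConceptSet(definition.set_id, frozenset(members))


# ---------------------------------------------------------------------------
# Bundled library
# ---------------------------------------------------------------------------

def _parse_definition(doc: dict, source: str) -> ConceptSetDefinition:
    required = {"set_id", "name", "vocabulary", "seed_concept_ids"}
    missing = required - doc.keys()
    if missing:
        raise ValueError(f"{source}: concept-set document missing fields {sorted(missing)}")
    return ConceptSetDefinition(
        set_id=str(doc["set_id"]),
        name=str(doc["name"]),
        vocabulary=Vocabulary(doc["vocabulary"]),
        seed_concept_ids=tuple(int(x) for x in doc["seed_concept_ids"]),
        include_descendants=bool(doc.get("include_descendants", False)),
        excluded_concept_ids=tuple(int(x) for x in doc.get("excluded_concept_ids", ())),
    )


@dataclass
class ConceptSetLibrary:
    """All concept-set definitions plus the per-DDI manifest; caches resolutions."""

    definitions: dict[str, ConceptSetDefinition]
    manifest: dict[str, list[str]]  # ddi_id -> set_ids
    _cache: dict[tuple[int, str], ResolvedConceptSet] = field(default_factory=dict)

    def definition(self, set_id: str) -> ConceptSetDefinition:
        try:
            return self.definitions[set_id]
        except KeyError:
            raise ConceptSetResolutionError(f"unknown concept set {set_id!r}") from None

    def resolve(self, set_id: str, store: PatientStore) -> ResolvedConceptSet:
        key = (id(store), set_id)
        if key not in self._cache:
            self._cache[key] = resolve(self.definition(set_id), store)
        return self._cache[key]


def load_library(directory: str | Path) -> ConceptSetLibrary:
    """Load a concept-set library from a directory of one-JSON-per-set documents
    plus a ``manifest.json`` mapping DDI ids to set ids."""
    directory = Path(directory)
    definitions: dict[str, ConceptSetDefinition] = {}
    for path in sorted(directory.glob("*.json")):
        if path.name == "manifest.json":
            continue
        doc = json.loads(path.read_text())
        d = _parse_definition(doc, path.name)
        if d.set_id in definitions:
            raise ValueError(f"duplicate concept set id {d.set_id!r} in {path.name}")
        definitions[d.set_id] = d
    manifest_path = directory / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    return ConceptSetLibrary(definitions, manifest)


def load_bundled_library() -> ConceptSetLibrary:
    """The concept sets shipped with the package (synthetic stand-in memberships;
    set ids are stable so real VSAC exports can be dropped in)."""
    root = resources.files("ddialert").joinpath("data/concept_sets")
    with resources.as_file(root) as path:
        return load_library(path)
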