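"""Entity vocabulary, term resolution, and taxonomy-based subclass expansion.

Entities are ``(id, type)`` pairs drawn from a controlled vocabulary, e.g.
``(D019821, Drug)`` for simvastatin.  The vocabulary maps free-text terms
(preferred names and synonyms) to sets of entities; a separate taxonomy (a DAG
of parent/child edges, as in MeSH or ATC) supports transitive subclass
expansion so that a query for a class entity also retrieves its subclasses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ENTITY_TYPES",
    "TYPE_ALL",
    "Entity",
    "VocabularyEntry",
    "EntityVocabulary",
    "Taxonomy",
    "load_entity_vocabulary",
    "normalize_term",
]

#: Default entity-type labels of the pharmaceutical vocabulary.
ENTITY_TYPES = frozenset(
    {
        "Drug",
        "Disease",
        "Chemical",
        "DosageForm",
        "Excipient",
        "PlantFamily",
        "Method",
        "LabMethod",
        "Gene",
        "Species",
        "Vaccine",
    }
)

#: Pseudo-type used by query variables to match entities of any type.
TYPE_ALL = "All"

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Lowercase, strip surrounding whitespace, collapse internal whitespace.

    No stemming is applied: chemical and drug names are easily conflated by
    stemmers, so matching is exact after normalization.
    """
    return _WS.sub(" ", term.strip().lower())


@dataclass(frozen=True, order=True)
class Entity:
    """A vocabulary entity: unique identifier plus entity-type label."""

    id: str
    type: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("entity id must be non-empty")
        if not self.type:
            raise ValueError("entity type must be non-empty")


@dataclass(frozen=True)
class VocabularyEntry:
    """One vocabulary row: an entity, its preferred name, and its synonyms.

    The preferred name is always a member of the searchable term set.
    """

    entity: Entity
    preferred_name: str
    synonyms: frozenset[str]

    @property
    def terms(self) -> frozenset[str]:
        return self.synonyms | {self.preferred_name}


class VocabularyError(ValueError):
    """Raised for malformed vocabulary or taxonomy input."""


class EntityVocabulary:
    """In-memory entity vocabulary with a normalized term index.

    The term index maps each normalized term to the set of entities having
    that term as preferred name or synonym; it is prebuilt at load time so
    term resolution is a dictionary lookup.
    """

    def __init__(
        self,
        entries: Iterable[VocabularyEntry] = (),
        allowed_types: frozenset[str] | None = None,
    ) -> None:
        self.allowed_types = allowed_types
        self._entries: dict[Entity, VocabularyEntry] = {}
        self._term_index: dict[str, set[Entity]] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: VocabularyEntry) -> None:
        if self.allowed_types is not None and entry.entity.type not in self.allowed_types:
            raise VocabularyError(
                f"entity type {entry.entity.type!r} not in configured type set"
            )
        existing = self._entries.get(entry.entity)
        if existing is not None:
            # Duplicate (id, type) rows are merged; synonym sets are unioned.
            entry = VocabularyEntry(
                entity=entry.entity,
                preferred_name=existing.preferred_name,
                synonyms=existing.synonyms | entry.synonyms | {entry.preferred_name},
            )
        self._entries[entry.entity] = entry
        for term in entry.terms:
            norm = normalize_term(term)
            if norm:
                self._term_index.setdefault(norm, set()).add(entry.entity)

    @property
    def entries(self) -> list[VocabularyEntry]:
        return list(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, entity: Entity) -> bool:
        return entity in self._entries

    def entity_types(self) -> set[str]:
        return {e.type for e in self._entries}

    def type_of(self, entity_id: str) -> str | None:
        """Type of the (first) entity with this id, or None if unknown."""
        for entity in self._entries:
            if entity.id == entity_id:
                return entity.type
        return None

    def resolve_term(self, term: str) -> set[Entity]:
        """All entities having ``term`` (after normalization) as a synonym."""
        return set(self._term_index.get(normalize_term(term), set()))

    def term_index(self) -> Mapping[str, set[Entity]]:
        return self._term_index

    @classmethod
    def load(
        cls, path: str | Path, allowed_types: frozenset[str] | None = None
    ) -> "EntityVocabulary":
        return load_entity_vocabulary(path, allowed_types=allowed_types)


def load_entity_vocabulary(
    path: str | Path, allowed_types: frozenset[str] | None = None
) -> EntityVocabulary:
    """Load a 4-column TSV entity vocabulary.

    Columns: entity id, entity type, preferred name, semicolon-separated
    synonym list (may be empty).  Malformed rows fail with their row number;
    duplicate (id, type) rows are merged with synonyms unioned.
    """
    vocab = EntityVocabulary(allowed_types=allowed_types)
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise VocabularyError(
                    f"{path}: row {lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            entity_id, entity_type, name, synonyms = (f.strip() for f in fields)
            if not entity_id or not entity_type or not name:
                raise VocabularyError(f"{path}: row {lineno}: empty mandatory field")
            syn_set = frozenset(s.strip() for s in synonyms.split(";") if s.strip())
            try:
                vocab.add(
                    VocabularyEntry(
                        entity=Entity(entity_id, entity_type),
                        preferred_name=name,
                        synonyms=syn_set | {name},
                    )
                )
            except VocabularyError as err:
                raise VocabularyError(f"{path}: row {lineno}: {err}") from err
    return vocab


class Taxonomy:
    """Subclass DAG over entity identifiers (multiple parents allowed).

    ``subclasses`` returns every identifier reachable via child edges; for an
    identifier with no subclasses it returns the identifier itself, so the
    function is total over all ids.  ``expansion_set`` is the id plus all of
    its transitive subclasses — the set a query entity is rewritten to.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self._children: dict[str, set[str]] = {}
        self._parents: dict[str, set[str]] = {}
        for parent, child in edges:
            self.add_edge(parent, child)
        self._check_acyclic()

    def add_edge(self, parent: str, child: str) -> None:
        if not parent or not child:
            raise VocabularyError("taxonomy edge endpoints must be non-empty")
        self._children.setdefault(parent, set()).add(child)
        self._children.setdefault(child, set())
        self._parents.setdefault(child, set()).add(parent)
        self._parents.setdefault(parent, set())

    def _check_acyclic(self) -> None:
        # Iterative DFS with colors; cycles are rejected with a diagnostic.
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {node: WHITE for node in self._children}
        for start in self._children:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(start, iter(sorted(self._children[start])))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if color[child] == GRAY:
                        raise VocabularyError(
                            f"taxonomy contains a cycle through {child!r}"
                        )
                    if color[child] == WHITE:
                        color[child] = GRAY
                        stack.append((child, iter(sorted(self._children[child]))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {
            (parent, child)
            for parent, children in self._children.items()
            for child in children
        }

    @property
    def nodes(self) -> set[str]:
        return set(self._children)

    @property
    def roots(self) -> set[str]:
        return {node for node, parents in self._parents.items() if not parents}

    def children(self, node: str) -> set[str]:
        return set(self._children.get(node, set()))

    def parents(self, node: str) -> set[str]:
        return set(self._parents.get(node, set()))

    def __contains__(self, node: str) -> bool:
        return node in self._children

    def subclasses(self, entity_id: str) -> set[str]:
        """All direct and transitive subclasses; ``{entity_id}`` for a leaf.

        An identifier unknown to the taxonomy is treated as a leaf.
        """
        if entity_id not in self._children or not self._children[entity_id]:
            return {entity_id}
        seen: set[str] = set()
        frontier = [entity_id]
        while frontier:
            node = frontier.pop()
            for child in self._children.get(node, ()):  # diamond-safe
                if child not in seen:
                    seen.add(child)
                    frontier.append(child)
        return seen

    def expansion_set(self, entity_id: str) -> set[str]:
        """The entity itself plus all of its transitive subclasses."""
        return {entity_id} | self.subclasses(entity_id)

    def ancestors(self, entity_id: str) -> set[str]:
        """All direct and transitive superclasses (empty for roots/unknown)."""
        seen: set[str] = set()
        frontier = [entity_id]
        while frontier:
            node = frontier.pop()
            for parent in self._parents.get(node, ()):
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return seen

    @classmethod
    def load(cls, path: str | Path) -> "Taxonomy":
        """Load a 2-column TSV edge list (parent_id TAB child_id)."""
        edges = []
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise VocabularyError(
                        f"{path}: row {lineno}: expected 2 tab-separated fields"
                    )
                edges.append((fields[0].strip(), fields[1].strip()))
        return cls(edges)
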