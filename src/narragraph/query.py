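"""Narrative query graphs: parsing, subclass expansion, and index matching.

A narrative query graph is a set of fact patterns — RDF-style triples whose
subject and object are either entity sets (after term resolution and
transitive subclass expansion) or typed variable nodes written ``?X(Type)``.
A document matches when *all* patterns are satisfied by its stored
predications under one consistent substitution μ binding the query's
variables to entities.  Matching is in-memory and hash-based: patterns with
concrete entities are evaluated first, then variable patterns are joined on
document and shared-variable bindings.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .store import DocKey, InvertedIndex
from .vocab import Entity, EntityVocabulary, Taxonomy, TYPE_ALL

__all__ = [
    "VariableNode",
    "FactPattern",
    "NarrativeQueryGraph",
    "QueryResult",
    "QueryError",
    "parse_query",
    "resolve_and_expand",
    "match_pattern",
    "match_query",
]


class QueryError(ValueError):
    """Raised for unparsable queries or unresolvable terms."""


@dataclass(frozen=True, order=True)
class VariableNode:
    """A typed query variable, written ``?Name(Type)``; type All matches any."""

    name: str
    type: str = TYPE_ALL

    def __str__(self) -> str:
        return f"?{self.name}({self.type})"


@dataclass(frozen=True)
class FactPattern:
    """One query triple over entity sets and/or variables."""

    subject: frozenset[Entity] | VariableNode
    relation: str
    object: frozenset[Entity] | VariableNode

    def __post_init__(self) -> None:
        for role in (self.subject, self.object):
            if isinstance(role, frozenset) and not role:
                raise QueryError("entity role resolved to the empty set")

    @property
    def variables(self) -> set[VariableNode]:
        return {r for r in (self.subject, self.object) if isinstance(r, VariableNode)}

    @property
    def is_concrete(self) -> bool:
        return not self.variables


@dataclass
class NarrativeQueryGraph:
    """An ordered set of fact patterns sharing a variable namespace."""

    patterns: list[FactPattern]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise QueryError("a query needs at least one fact pattern")

    @property
    def variables(self) -> set[VariableNode]:
        return set().union(*(p.variables for p in self.patterns))


@dataclass
class QueryResult:
    """One matching document with its substitution μ and provenance.

    ``substitution`` maps variable names to bound entities (defined exactly
    on the query's variables); ``provenance`` maps each pattern position to
    the predication ids supporting it within this document.
    """

    doc_key: DocKey
    substitution: dict[str, Entity]
    provenance: dict[int, list[int]]
    date: int = 0

    @property
    def collection(self) -> str:
        return self.doc_key[0]

    @property
    def doc_id(self) -> str:
        return self.doc_key[1]

    def to_dict(self) -> dict:
        return {
            "collection": self.collection,
            "document": self.doc_id,
            "date": self.date,
            "substitution": {
                name: {"id": e.id, "type": e.type}
                for name, e in sorted(self.substitution.items())
            },
            "provenance": {
                str(i): ids for i, ids in sorted(self.provenance.items())
            },
        }


# -- parsing ---------------------------------------------------------------


def _parse_role(
    token: str, entity_types: Iterable[str]
) -> str | VariableNode:
    types = set(entity_types)
    if token.startswith("?"):
        body = token[1:]
        if "(" in body:
            name, _, rest = body.partition("(")
            vtype = rest.rstrip(")")
        else:
            name, vtype = body, TYPE_ALL
        if not name:
            raise QueryError(f"variable {token!r} needs a name")
        return VariableNode(name=name, type=vtype or TYPE_ALL)
    if token in types or token == TYPE_ALL:
        # a bare type name queries for an arbitrary entity of that type
        return VariableNode(name=token, type=token)
    return token


def parse_query(
    text: str,
    relations: Iterable[str],
    entity_types: Iterable[str] = (),
) -> list[tuple[str | VariableNode, str, str | VariableNode]]:
    """Parse a query string into unresolved (subject, relation, object) tuples.

    One triple per non-empty line; multiword terms are double-quoted;
    ``?Name(Type)`` and bare entity-type names parse as variable nodes.
    An unknown relation raises an error naming the allowed relation set Σ.
    """
    relation_set = set(relations)
    patterns: list[tuple[str | VariableNode, str, str | VariableNode]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            tokens = shlex.split(line)
        except ValueError as err:
            raise QueryError(f"line {lineno}: {err}") from err
        if len(tokens) != 3:
            raise QueryError(
                f"line {lineno}: expected 'subject relation object', got "
                f"{len(tokens)} tokens"
            )
        subject_tok, relation, object_tok = tokens
        if relation not in relation_set:
            raise QueryError(
                f"line {lineno}: unknown relation {relation!r}; allowed "
                f"relations: {sorted(relation_set)}"
            )
        patterns.append(
            (
                _parse_role(subject_tok, entity_types),
                relation,
                _parse_role(object_tok, entity_types),
            )
        )
    if not patterns:
        raise QueryError("empty query")
    return patterns


def resolve_and_expand(
    patterns: Sequence[tuple[str | VariableNode, str, str | VariableNode]],
    vocabulary: EntityVocabulary,
    taxonomy: Taxonomy | None = None,
) -> NarrativeQueryGraph:
    """Resolve terms to entity sets and expand every entity by its subclasses.

    Each free-text term resolves to all entities having it as a synonym;
    each resolved entity is replaced by its expansion set (itself plus all
    direct and transitive subclasses).  Variables pass through untouched.
    A term resolving to no entity raises an error naming the term.
    """

    def resolve(role: str | VariableNode) -> frozenset[Entity] | VariableNode:
        if isinstance(role, VariableNode):
            return role
        entities = vocabulary.resolve_term(role)
        if not entities:
            raise QueryError(f"term {role!r} does not resolve to any entity")
        expanded: set[Entity] = set()
        for entity in entities:
            if taxonomy is None:
                expanded.add(entity)
                continue
            for sub_id in taxonomy.expansion_set(entity.id):
                sub_type = vocabulary.type_of(sub_id) or entity.type
                expanded.add(Entity(sub_id, sub_type))
        return frozenset(expanded)

    return NarrativeQueryGraph(
        patterns=[
            FactPattern(subject=resolve(s), relation=r, object=resolve(o))
            for s, r, o in patterns
        ]
    )


# -- matching --------------------------------------------------------------

Binding = tuple[tuple[str, Entity], ...]  # sorted (variable name, entity) pairs


def _role_matches(
    role: frozenset[Entity] | VariableNode, entity_id: str, entity_type: str
) -> dict[str, Entity] | None:
    """Binding fragment if the posting's entity fits the role, else None."""
    if isinstance(role, VariableNode):
        if role.type == TYPE_ALL or role.type == entity_type:
            return {role.name: Entity(entity_id, entity_type)}
        return None
    if any(e.id == entity_id for e in role):
        return {}
    return None


def match_pattern(
    fp: FactPattern, index: InvertedIndex
) -> dict[DocKey, list[tuple[dict[str, Entity], list[int]]]]:
    """Match one fact pattern against the index.

    Returns, per qualifying document, the list of (variable bindings,
    supporting predication ids) pairs.  Entity roles match by id membership
    in the pattern's entity set; variable roles match by type equality
    (type All matches every type).
    """
    matches: dict[DocKey, list[tuple[dict[str, Entity], list[int]]]] = {}
    for posting in index.postings_for_relation(fp.relation):
        s_id, s_type, _, o_id, o_type = posting.key
        s_bind = _role_matches(fp.subject, s_id, s_type)
        if s_bind is None:
            continue
        o_bind = _role_matches(fp.object, o_id, o_type)
        if o_bind is None:
            continue
        if (
            s_bind
            and o_bind
            and set(s_bind) & set(o_bind)
            and any(s_bind[n] != o_bind[n] for n in set(s_bind) & set(o_bind))
        ):
            continue  # same variable on both roles must bind consistently
        bindings = {**s_bind, **o_bind}
        for doc_key, pred_ids in posting.payload.items():
            matches.setdefault(doc_key, []).append((bindings, list(pred_ids)))
    return matches


def _candidate_order(pattern_matches: list[tuple[int, FactPattern, dict]]):
    """Concrete patterns first, then ascending candidate-set size."""
    return sorted(
        pattern_matches,
        key=lambda item: (not item[1].is_concrete, len(item[2]), item[0]),
    )


def match_query(
    q: NarrativeQueryGraph,
    index: InvertedIndex,
    dates: Mapping[DocKey, int] | None = None,
) -> list[QueryResult]:
    """Match a narrative query graph; every pattern must hold in one document.

    Produces one result per (document, consistent substitution μ) pair, with
    per-pattern provenance predication ids attached.  Results are ordered by
    document date descending (ties: document id descending); fixtures carry
    insertion-order dates.
    """
    per_pattern = [
        (i, fp, match_pattern(fp, index)) for i, fp in enumerate(q.patterns)
    ]
    ordered = _candidate_order(per_pattern)

    # state: (doc, binding) -> {pattern position -> predication ids}
    state: dict[tuple[DocKey, Binding], dict[int, set[int]]] | None = None
    for pos, _, matches in ordered:
        new_state: dict[tuple[DocKey, Binding], dict[int, set[int]]] = {}
        if state is None:
            for doc_key, entries in matches.items():
                for bindings, pred_ids in entries:
                    key = (doc_key, tuple(sorted(bindings.items())))
                    prov = new_state.setdefault(key, {})
                    prov.setdefault(pos, set()).update(pred_ids)
        else:
            for (doc_key, binding), prov in state.items():
                bound = dict(binding)
                for bindings, pred_ids in matches.get(doc_key, ()):
                    if any(
                        name in bound and bound[name] != entity
                        for name, entity in bindings.items()
                    ):
                        continue
                    merged = {**bound, **bindings}
                    key = (doc_key, tuple(sorted(merged.items())))
                    new_prov = new_state.setdefault(
                        key, {p: set(ids) for p, ids in prov.items()}
                    )
                    for p, ids in prov.items():
                        new_prov.setdefault(p, set()).update(ids)
                    new_prov.setdefault(pos, set()).update(pred_ids)
        state = new_state
        if not state:
            return []

    assert state is not None
    # Partial bindings (a variable unseen by some evaluation branch cannot
    # occur here: every variable appears in at least one pattern, and each
    # pattern was joined), so each surviving binding covers all variables.
    results = []
    for (doc_key, binding), prov in state.items():
        date = dates.get(doc_key, 0) if dates else 0
        results.append(
            QueryResult(
                doc_key=doc_key,
                substitution=dict(binding),
                provenance={p: sorted(ids) for p, ids in prov.items()},
                date=date,
            )
        )
    # deterministic order: date desc, then doc id desc, then substitution
    results.sort(key=lambda r: sorted(r.substitution.items()))
    results.sort(key=lambda r: (r.date, r.doc_key[0], r.doc_key[1]), reverse=True)
    return results
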