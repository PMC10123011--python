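"""Predicate canonicalization to a closed relation vocabulary Σ.

Raw PathIE phrases (``treats``, ``therapy``, ``aids`` …) are unified to ten
precise relations via exact synonym lookup, optionally backed by word-vector
similarity for near-synonym verb phrases.  Per-relation domain/range type
constraints then repair or filter statements:

* strict mode removes statements violating their relation's constraints;
* service mode instead remaps violators to ``associated`` (the entities are
  still *in some way* associated in the sentence), and applies two further
  remapping rules — any statement touching a Method/LabMethod entity becomes
  ``method``, and any statement touching a DosageForm entity becomes
  ``administered``.  Precedence is method ≻ administered ≻ type check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .pathie import RawStatement
from .vocab import Entity, normalize_term

__all__ = [
    "DEFAULT_RELATIONS",
    "RelationVocabulary",
    "Predication",
    "WordEmbedding",
    "canonicalize_predicate",
    "apply_type_rules",
    "canonicalize_statements",
    "dedupe",
]

#: The ten canonical relations of the pharmaceutical interaction vocabulary.
DEFAULT_RELATIONS = (
    "associated",
    "administered",
    "compares",
    "decreases",
    "induces",
    "inhibits",
    "interacts",
    "metabolizes",
    "method",
    "treats",
)

_DEFAULT_SYNONYMS: dict[str, set[str]] = {
    "treats": {"treats", "treat", "treatment", "therapy", "prevents", "prevent"},
    "inhibits": {"inhibits", "inhibit", "inhibition", "suppresses", "suppress"},
    "metabolizes": {"metabolizes", "metabolize", "metabolism"},
    "induces": {"induces", "induce", "induction", "causes", "cause"},
    "decreases": {"decreases", "decrease", "reduction", "reduces", "reduce",
                  "lowers", "lower"},
    "interacts": {"interacts", "interact", "interaction"},
    "administered": {"administered", "administer", "administration"},
    "compares": {"compares", "compare", "comparison", "versus"},
    "method": {"method"},
    "associated": {"associated", "associate", "association"},
}

# Directed relations carry domain/range constraints; the general relations
# (induces, decreases, interacts, compares, associated, …) are unconstrained.
_DEFAULT_CONSTRAINTS: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "treats": (frozenset({"Drug", "Chemical"}), frozenset({"Disease", "Species"})),
    "inhibits": (frozenset({"Drug", "Chemical"}), frozenset({"Gene"})),
    "metabolizes": (frozenset({"Gene"}), frozenset({"Drug", "Chemical"})),
}


class RelationVocabularyError(ValueError):
    """Raised for malformed relation vocabularies or unknown relations."""


@dataclass
class RelationVocabulary:
    """Relation set Σ with synonym terms and optional type constraints.

    ``synonyms`` maps each relation to its lowercase synonym terms (always
    including the relation name itself); ``constraints`` maps constrained
    relations to ``(domain types, range types)``.
    """

    synonyms: dict[str, frozenset[str]]
    constraints: dict[str, tuple[frozenset[str], frozenset[str]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self._term_map: dict[str, str] = {}
        for relation in sorted(self.synonyms):
            terms = {normalize_term(t) for t in self.synonyms[relation]}
            terms.add(normalize_term(relation))
            self.synonyms[relation] = frozenset(terms)
            for term in terms:
                other = self._term_map.get(term)
                if other is not None and other != relation:
                    raise RelationVocabularyError(
                        f"term {term!r} maps to both {other!r} and {relation!r}"
                    )
                self._term_map[term] = relation
        for relation in self.constraints:
            if relation not in self.synonyms:
                raise RelationVocabularyError(
                    f"constraint for unknown relation {relation!r}"
                )

    @property
    def relations(self) -> frozenset[str]:
        return frozenset(self.synonyms)

    def all_terms(self) -> set[str]:
        return set(self._term_map)

    def relation_of_term(self, term: str) -> str | None:
        return self._term_map.get(normalize_term(term))

    def subset(self, relations: Iterable[str]) -> "RelationVocabulary":
        keep = set(relations)
        unknown = keep - set(self.synonyms)
        if unknown:
            raise RelationVocabularyError(f"unknown relations: {sorted(unknown)}")
        return RelationVocabulary(
            synonyms={r: set(self.synonyms[r]) for r in keep},
            constraints={r: c for r, c in self.constraints.items() if r in keep},
        )

    @classmethod
    def default(cls) -> "RelationVocabulary":
        return cls(
            synonyms={r: set(s) for r, s in _DEFAULT_SYNONYMS.items()},
            constraints=dict(_DEFAULT_CONSTRAINTS),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RelationVocabulary":
        """Load a TSV relation vocabulary.

        Columns: relation, semicolon-separated synonyms, optional
        comma-separated domain types, optional comma-separated range types.
        Domain and range must both be present or both absent.
        """
        synonyms: dict[str, set[str]] = {}
        constraints: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) not in (2, 4):
                    raise RelationVocabularyError(
                        f"{path}: row {lineno}: expected 2 or 4 fields"
                    )
                relation = fields[0].strip()
                terms = {t.strip() for t in fields[1].split(";") if t.strip()}
                synonyms.setdefault(relation, set()).update(terms)
                if len(fields) == 4 and (fields[2].strip() or fields[3].strip()):
                    domain = frozenset(
                        t.strip() for t in fields[2].split(",") if t.strip()
                    )
                    rng = frozenset(
                        t.strip() for t in fields[3].split(",") if t.strip()
                    )
                    if not domain or not rng:
                        raise RelationVocabularyError(
                            f"{path}: row {lineno}: domain and range must both "
                            "be given for a constrained relation"
                        )
                    constraints[relation] = (domain, rng)
        return cls(synonyms=synonyms, constraints=constraints)


@dataclass
class Predication:
    """A canonicalized, stored statement with provenance.

    ``sentence_id`` is the MD5 sentence identifier once the statement is
    bound to a stored sentence; ``predication_id`` is a surrogate assigned
    deterministically at dedup/insert time.
    """

    subject: Entity
    relation: str
    object: Entity
    predicate_phrase: str
    doc_id: str
    sentence_id: str
    predication_id: int | None = None
    collection: str = "default"

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        """The inverted-index key: ids and types of both entities + relation."""
        return (
            self.subject.id,
            self.subject.type,
            self.relation,
            self.object.id,
            self.object.type,
        )


class WordEmbedding:
    """Word vectors in text word2vec format, for near-synonym canonicalization."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        self._vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def vector(self, phrase: str) -> np.ndarray | None:
        """Mean vector of the phrase's in-vocabulary words, or None."""
        vecs = [self._vectors[w] for w in phrase.lower().split() if w in self._vectors]
        if not vecs:
            return None
        return np.mean(vecs, axis=0)

    def similarity(self, a: str, b: str) -> float | None:
        va, vb = self.vector(a), self.vector(b)
        if va is None or vb is None:
            return None
        denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
        if denom == 0.0 or math.isnan(denom):
            return None
        return float(np.dot(va, vb) / denom)

    @classmethod
    def load_word2vec_text(cls, path: str | Path) -> "WordEmbedding":
        """Read the standard text word2vec format (optional count header)."""
        vectors: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as handle:
            first = handle.readline().split()
            if len(first) == 2 and all(p.isdigit() for p in first):
                pass  # header line: vocab size, dimensionality
            elif first:
                vectors[first[0]] = np.array([float(x) for x in first[1:]])
            for line in handle:
                parts = line.split()
                if parts:
                    vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        return cls(vectors)


def canonicalize_predicate(
    phrase: str,
    vocab: RelationVocabulary,
    embedding: WordEmbedding | None = None,
    threshold: float = 0.7,
    lemma: str | None = None,
) -> str | None:
    """Map a predicate phrase to its canonical relation, or None.

    An exact (lowercased, lemmatized) vocabulary hit wins.  Otherwise, when
    an embedding is supplied, the phrase maps to the relation whose synonym
    maximizes cosine similarity, provided the similarity reaches the
    threshold.  ``None`` means the raw statement is discarded before storage.
    """
    if not phrase:
        raise ValueError("predicate phrase must be non-empty")
    for candidate in (phrase, lemma):
        if candidate:
            relation = vocab.relation_of_term(candidate)
            if relation is not None:
                return relation
    if embedding is None:
        return None
    best: tuple[float, str] | None = None
    for relation in sorted(vocab.synonyms):
        for term in sorted(vocab.synonyms[relation]):
            sim = embedding.similarity(phrase, term)
            if sim is None or sim < threshold:
                continue
            if best is None or sim > best[0]:
                best = (sim, relation)
    return best[1] if best else None


def apply_type_rules(
    subject: Entity,
    relation: str,
    obj: Entity,
    vocab: RelationVocabulary,
    mode: str = "service",
    method_types: frozenset[str] = frozenset({"Method", "LabMethod"}),
    dosage_form_type: str = "DosageForm",
) -> tuple[Entity, str, Entity] | None:
    """Enforce domain/range constraints and the service remapping rules.

    Precedence: (a) a Method/LabMethod participant forces relation
    ``method``; (b) a DosageForm participant forces ``administered``;
    (c) a satisfied constraint passes; a constraint satisfied only under the
    swapped orientation swaps subject and object (PathIE's direction is
    unreliable by design); (d) a genuine violation is dropped in strict mode
    and remapped to ``associated`` in service mode.
    """
    if relation not in vocab.relations:
        raise RelationVocabularyError(f"unknown relation {relation!r}")
    if mode not in ("strict", "service"):
        raise ValueError(f"mode must be 'strict' or 'service', got {mode!r}")

    if mode == "service":
        if subject.type in method_types or obj.type in method_types:
            if "method" in vocab.relations:
                return subject, "method", obj
        if subject.type == dosage_form_type or obj.type == dosage_form_type:
            if "administered" in vocab.relations:
                return subject, "administered", obj

    constraint = vocab.constraints.get(relation)
    if constraint is None:
        return subject, relation, obj
    domain, rng = constraint
    if subject.type in domain and obj.type in rng:
        return subject, relation, obj
    if obj.type in domain and subject.type in rng:
        return obj, relation, subject  # orientation repair
    if mode == "service":
        return subject, "associated", obj
    return None


def canonicalize_statements(
    statements: Iterable[RawStatement],
    vocab: RelationVocabulary,
    sentence_ids: Mapping[tuple[str, int], str] | None = None,
    embedding: WordEmbedding | None = None,
    threshold: float = 0.7,
    mode: str = "service",
    collection: str = "default",
) -> list[Predication]:
    """Canonicalize raw statements into predications (without surrogate ids).

    ``sentence_ids`` maps ``(doc_id, sent_index)`` to stored sentence ids;
    when absent, the sentence index is used verbatim.  Statements whose
    phrase cannot be canonicalized are discarded; type rules are then applied
    per ``mode``.
    """
    predications: list[Predication] = []
    for stmt in statements:
        relation = canonicalize_predicate(
            stmt.predicate_phrase,
            vocab,
            embedding=embedding,
            threshold=threshold,
            lemma=stmt.predicate_lemma or None,
        )
        if relation is None:
            continue
        typed = apply_type_rules(stmt.subject, relation, stmt.object, vocab, mode=mode)
        if typed is None:
            continue
        subject, relation, obj = typed
        key = (stmt.doc_id, stmt.sent_index)
        sentence_id = (
            sentence_ids[key] if sentence_ids is not None else str(stmt.sent_index)
        )
        predications.append(
            Predication(
                subject=subject,
                relation=relation,
                object=obj,
                predicate_phrase=stmt.predicate_phrase,
                doc_id=stmt.doc_id,
                sentence_id=sentence_id,
                collection=collection,
            )
        )
    return dedupe(predications)


def dedupe(predications: Iterable[Predication]) -> list[Predication]:
    """One predication per distinct (doc, sentence, subject, relation, object).

    Output order is sorted on that tuple, so downstream surrogate ids are
    stable across reruns and insensitive to input order.
    """
    unique: dict[tuple, Predication] = {}
    for pred in predications:
        key = (
            pred.collection,
            pred.doc_id,
            pred.sentence_id,
            pred.subject,
            pred.relation,
            pred.object,
        )
        if key not in unique:
            unique[key] = pred
    return [unique[k] for k in sorted(unique)]
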