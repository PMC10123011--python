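"""Deterministic synthetic corpora with gold document graphs.

The generator emits everything the pipeline consumes — PubTator documents,
CoNLL-U parses, entity/relation vocabularies, a taxonomy — together with the
gold statements planted in the text and query/answer pairs, so every stage
is testable without downloads or parser models.  Sentences come from a
small template grammar whose dependency parses are constructed alongside
the tokens (hence always consistent and single-rooted); distractor
sentences carry no extractable statement.  Gold query answers are computed
by a brute-force substitution-enumeration matcher that is independent of
the inverted-index query engine.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .canon import Predication, RelationVocabulary, dedupe
from .linker import Document, EntityAnnotation, write_pubtator
from .pathie import ParsedSentence, Token, write_conllu
from .query import FactPattern, NarrativeQueryGraph, QueryResult, VariableNode
from .store import DocKey, SentenceRecord, Storage, sentence_id
from .vocab import Entity, EntityVocabulary, Taxonomy, TYPE_ALL, VocabularyEntry

__all__ = [
    "FixtureConfig",
    "FixtureBundle",
    "QuerySpec",
    "generate_corpus",
    "worked_example",
    "brute_force_match",
]

_ID_PREFIX = {
    "Drug": "DR",
    "Disease": "DI",
    "Chemical": "CH",
    "Gene": "GE",
    "Species": "SP",
    "DosageForm": "DF",
    "Excipient": "EX",
    "PlantFamily": "PF",
    "Method": "ME",
    "LabMethod": "LM",
    "Vaccine": "VA",
}

_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "ha", "ki", "lo",
    "mu", "ne", "pa", "re", "si", "to", "vu", "ze",
)

#: (surface, lemma) of the template verb per relation.
_VERBS = {
    "treats": ("treats", "treat"),
    "induces": ("induces", "induce"),
    "decreases": ("decreases", "decrease"),
    "inhibits": ("inhibits", "inhibit"),
    "metabolizes": ("metabolizes", "metabolize"),
    "interacts": ("interacts", "interact"),
    "compares": ("compares", "compare"),
    "administered": ("administered", "administer"),
    "associated": ("associated", "associate"),
}

#: Noun keyword per relation for the keyword template.
_KEYWORDS = {
    "treats": "therapy",
    "induces": "induction",
    "decreases": "reduction",
    "inhibits": "inhibition",
    "metabolizes": "metabolism",
    "interacts": "interaction",
    "compares": "comparison",
    "administered": "administration",
    "associated": "association",
    "method": "method",
}

#: (subject type, object type) pools per relation; chosen so planted
#: statements survive canonicalization and type rules unchanged.
_PARTICIPANTS = {
    "treats": ("Drug", "Disease"),
    "induces": ("Drug", "Disease"),
    "decreases": ("Drug", "Chemical"),
    "inhibits": ("Drug", "Gene"),
    "metabolizes": ("Gene", "Drug"),
    "interacts": ("Drug", "Drug"),
    "compares": ("Drug", "Drug"),
    "associated": ("Drug", "Disease"),
    "method": ("Method", "Drug"),
    "administered": ("DosageForm", "Drug"),
}


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic corpus (seed fixed ⇒ byte-identical)."""

    n_docs: int = 20
    entities_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"Drug": 6, "Disease": 6, "Gene": 3, "Chemical": 3}
    )
    relations: tuple[str, ...] = ("treats", "induces", "inhibits", "metabolizes")
    taxonomy_branching: int = 2
    sentences_per_doc: tuple[int, int] = (2, 4)
    distractor_rate: float = 0.3
    n_queries: int = 0
    seed: int = 0
    collection: str = "fixture"

    def __post_init__(self) -> None:
        if not 0.0 <= self.distractor_rate <= 1.0:
            raise ValueError("distractor rate must lie in [0, 1]")


@dataclass
class QuerySpec:
    """A generated query with its gold answer set (brute-force computed)."""

    text: str
    graph: NarrativeQueryGraph
    expected: list[QueryResult]


@dataclass
class FixtureBundle:
    """A synthetic corpus with gold annotations, statements, and answers."""

    config: FixtureConfig
    documents: list[Document]
    annotations: dict[str, list[EntityAnnotation]]
    sentences: dict[str, list[ParsedSentence]]
    vocabulary: EntityVocabulary
    relation_vocab: RelationVocabulary
    taxonomy: Taxonomy
    gold_predications: list[Predication]
    queries: list[QuerySpec] = field(default_factory=list)

    @property
    def dates(self) -> dict[DocKey, int]:
        """Insertion-order dates, as the store will assign them."""
        return {
            (doc.collection, doc.doc_id): i + 1
            for i, doc in enumerate(self.documents)
        }

    def sentence_records(self, doc: Document) -> list[SentenceRecord]:
        return [
            SentenceRecord(
                sentence_id=sentence_id(sent.text, doc.collection),
                collection=doc.collection,
                doc_id=doc.doc_id,
                text=sent.text,
                char_span=sent.char_span,
            )
            for sent in self.sentences[doc.doc_id]
        ]

    def build_storage(self, path: str = ":memory:") -> Storage:
        """Load documents, gold tags, sentences, and gold statements."""
        storage = Storage(path)
        by_doc: dict[str, list[Predication]] = {}
        for pred in self.gold_predications:
            by_doc.setdefault(pred.doc_id, []).append(pred)
        for doc in self.documents:
            preds = [replace(p, predication_id=None) for p in by_doc.get(doc.doc_id, [])]
            storage.insert_document_graph(
                doc,
                self.annotations[doc.doc_id],
                preds,
                self.sentence_records(doc),
            )
        return storage

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit all corpus files in the formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pubtator": outdir / "corpus.pubtator",
            "conllu": outdir / "corpus.conllu",
            "vocabulary": outdir / "vocabulary.tsv",
            "relations": outdir / "relations.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "gold": outdir / "gold_predications.tsv",
            "queries": outdir / "queries.txt",
        }
        write_pubtator(
            paths["pubtator"],
            [(doc, self.annotations[doc.doc_id]) for doc in self.documents],
        )
        write_conllu(
            paths["conllu"],
            [s for doc in self.documents for s in self.sentences[doc.doc_id]],
        )
        with open(paths["vocabulary"], "w", encoding="utf-8") as handle:
            handle.write(f"# seed = {self.config.seed}\n")
            for entry in sorted(self.vocabulary.entries, key=lambda e: e.entity):
                synonyms = ";".join(sorted(entry.terms))
                handle.write(
                    f"{entry.entity.id}\t{entry.entity.type}"
                    f"\t{entry.preferred_name}\t{synonyms}\n"
                )
        with open(paths["relations"], "w", encoding="utf-8") as handle:
            handle.write(f"# seed = {self.config.seed}\n")
            for relation in sorted(self.relation_vocab.synonyms):
                terms = ";".join(sorted(self.relation_vocab.synonyms[relation]))
                constraint = self.relation_vocab.constraints.get(relation)
                domain = ",".join(sorted(constraint[0])) if constraint else ""
                rng_ = ",".join(sorted(constraint[1])) if constraint else ""
                handle.write(f"{relation}\t{terms}\t{domain}\t{rng_}\n")
        with open(paths["taxonomy"], "w", encoding="utf-8") as handle:
            handle.write(f"# seed = {self.config.seed}\n")
            for parent, child in sorted(self.taxonomy.edges):
                handle.write(f"{parent}\t{child}\n")
        with open(paths["gold"], "w", encoding="utf-8") as handle:
            handle.write(f"# seed = {self.config.seed}\n")
            for pred in self.gold_predications:
                handle.write(
                    f"{pred.doc_id}\t{pred.sentence_id}\t{pred.subject.id}"
                    f"\t{pred.subject.type}\t{pred.relation}\t{pred.object.id}"
                    f"\t{pred.object.type}\t{pred.predicate_phrase}\n"
                )
        with open(paths["queries"], "w", encoding="utf-8") as handle:
            handle.write(f"# seed = {self.config.seed}\n")
            for spec in self.queries:
                handle.write(spec.text.replace("\n", " AND ") + "\n")
        return paths


def _make_names(rng: random.Random, count: int, taken: set[str]) -> list[str]:
    names = []
    while len(names) < count:
        name = "".join(rng.choice(_SYLLABLES) for _ in range(3))
        if name not in taken:
            taken.add(name)
            names.append(name)
    return names


def _verb_sentence(
    subject: tuple[Entity, str], verb: tuple[str, str], obj: tuple[Entity, str]
) -> tuple[list[Token], list[tuple[int, Entity, str]]]:
    (s_ent, s_name), (o_ent, o_name) = subject, obj
    tokens = [
        Token(1, s_name, s_name, "NOUN", 2, "nsubj"),
        Token(2, verb[0], verb[1], "VERB", 0, "root"),
        Token(3, o_name, o_name, "NOUN", 2, "obj"),
        Token(4, ".", ".", "PUNCT", 2, "punct"),
    ]
    return tokens, [(1, s_ent, s_name), (3, o_ent, o_name)]


def _keyword_sentence(
    subject: tuple[Entity, str], keyword: str, obj: tuple[Entity, str]
) -> tuple[list[Token], list[tuple[int, Entity, str]]]:
    (s_ent, s_name), (o_ent, o_name) = subject, obj
    tokens = [
        Token(1, s_name, s_name, "NOUN", 2, "nsubj"),
        Token(2, "shows", "show", "VERB", 0, "root"),
        Token(3, "the", "the", "DET", 4, "det"),
        Token(4, keyword, keyword, "NOUN", 2, "obj"),
        Token(5, "with", "with", "ADP", 6, "case"),
        Token(6, o_name, o_name, "NOUN", 4, "nmod"),
        Token(7, ".", ".", "PUNCT", 2, "punct"),
    ]
    return tokens, [(1, s_ent, s_name), (6, o_ent, o_name)]


def _distractor_single(ent: tuple[Entity, str]):
    entity, name = ent
    tokens = [
        Token(1, name, name, "NOUN", 3, "nsubj:pass"),
        Token(2, "was", "be", "AUX", 3, "aux:pass"),
        Token(3, "studied", "study", "VERB", 0, "root"),
        Token(4, ".", ".", "PUNCT", 3, "punct"),
    ]
    return tokens, [(1, entity, name)]


def _distractor_pair(a: tuple[Entity, str], b: tuple[Entity, str]):
    (a_ent, a_name), (b_ent, b_name) = a, b
    tokens = [
        Token(1, a_name, a_name, "NOUN", 2, "nsubj"),
        Token(2, "resembles", "resemble", "VERB", 0, "root"),
        Token(3, b_name, b_name, "NOUN", 2, "obj"),
        Token(4, ".", ".", "PUNCT", 2, "punct"),
    ]
    return tokens, [(1, a_ent, a_name), (3, b_ent, b_name)]


def generate_corpus(config: FixtureConfig) -> FixtureBundle:
    """Generate a deterministic synthetic corpus with gold document graphs.

    Raises on inconsistent configurations, e.g. a configured relation whose
    participating entity types carry no entities.
    """
    rng = random.Random(config.seed)

    relation_vocab = RelationVocabulary.default().subset(config.relations)
    for relation in config.relations:
        s_type, o_type = _PARTICIPANTS[relation]
        if (
            config.entities_per_type.get(s_type, 0) == 0
            or config.entities_per_type.get(o_type, 0) == 0
        ):
            raise ValueError(
                f"relation {relation!r} needs entities of types "
                f"({s_type}, {o_type}) but the config provides none"
            )
        if s_type == o_type and config.entities_per_type.get(s_type, 0) < 2:
            raise ValueError(
                f"relation {relation!r} needs two distinct {s_type} entities"
            )

    # entity vocabulary: unique pronounceable single-token names + a synonym
    taken: set[str] = set(_KEYWORDS.values()) | {
        v for pair in _VERBS.values() for v in pair
    }
    entities: dict[str, list[Entity]] = {}
    names: dict[Entity, str] = {}
    vocabulary = EntityVocabulary()
    for etype in sorted(config.entities_per_type):
        count = config.entities_per_type[etype]
        prefix = _ID_PREFIX.get(etype, etype[:2].upper())
        for i, name in enumerate(_make_names(rng, count, taken)):
            entity = Entity(f"{prefix}{i:04d}", etype)
            entities.setdefault(etype, []).append(entity)
            names[entity] = name
            vocabulary.add(
                VocabularyEntry(
                    entity=entity,
                    preferred_name=name,
                    synonyms=frozenset({name, name + "ex"}),
                )
            )

    # disease taxonomy: complete b-ary tree over the disease entities
    edges = []
    diseases = entities.get("Disease", [])
    for i in range(1, len(diseases)):
        parent = diseases[(i - 1) // config.taxonomy_branching]
        edges.append((parent.id, diseases[i].id))
    taxonomy = Taxonomy(edges)

    def pick_pair(relation: str) -> tuple[tuple[Entity, str], tuple[Entity, str]]:
        s_type, o_type = _PARTICIPANTS[relation]
        subject = rng.choice(entities[s_type])
        obj = rng.choice([e for e in entities[o_type] if e.id != subject.id])
        return (subject, names[subject]), (obj, names[obj])

    all_entities = [e for group in entities.values() for e in group]

    documents: list[Document] = []
    annotations: dict[str, list[EntityAnnotation]] = {}
    sentences: dict[str, list[ParsedSentence]] = {}
    gold: list[Predication] = []

    for d in range(config.n_docs):
        doc_id = f"{d + 1}"
        n_sent = rng.randint(*config.sentences_per_doc)
        sent_texts: list[str] = []
        sent_tokens: list[list[Token]] = []
        sent_mentions: list[list[tuple[int, Entity, str]]] = []
        sent_gold: list[tuple[Entity, str, Entity, str] | None] = []
        for _ in range(n_sent):
            if rng.random() < config.distractor_rate:
                if rng.random() < 0.5:
                    ent = rng.choice(all_entities)
                    tokens, mentions = _distractor_single((ent, names[ent]))
                else:
                    a = rng.choice(all_entities)
                    b = rng.choice([e for e in all_entities if e.id != a.id])
                    tokens, mentions = _distractor_pair((a, names[a]), (b, names[b]))
                planted = None
            else:
                relation = rng.choice(config.relations)
                subject, obj = pick_pair(relation)
                if relation in _VERBS and rng.random() < 0.6:
                    verb = _VERBS[relation]
                    tokens, mentions = _verb_sentence(subject, verb, obj)
                    phrase = verb[0]
                else:
                    keyword = _KEYWORDS[relation]
                    tokens, mentions = _keyword_sentence(subject, keyword, obj)
                    phrase = keyword
                planted = (subject[0], relation, obj[0], phrase)
            sent_texts.append(" ".join(t.surface for t in tokens))
            sent_tokens.append(tokens)
            sent_mentions.append(mentions)
            sent_gold.append(planted)

        title = sent_texts[0]
        abstract = " ".join(sent_texts[1:])
        doc = Document(
            doc_id=doc_id, title=title, abstract=abstract,
            collection=config.collection,
        )
        documents.append(doc)
        annotations[doc_id] = []
        sentences[doc_id] = []

        offset = 0
        for idx, (text, tokens, mentions, planted) in enumerate(
            zip(sent_texts, sent_tokens, sent_mentions, sent_gold)
        ):
            sent = ParsedSentence(
                doc_id=doc_id,
                sent_index=idx,
                text=text,
                tokens=tuple(tokens),
                char_span=(offset, offset + len(text)),
            )
            sentences[doc_id].append(sent)
            for token_idx, entity, mention in mentions:
                local_start, local_end = sent.token_span(token_idx)
                annotations[doc_id].append(
                    EntityAnnotation(
                        doc_id=doc_id,
                        start=offset + local_start,
                        end=offset + local_end,
                        mention=mention,
                        entity=entity,
                    )
                )
            if planted is not None:
                subject, relation, obj, phrase = planted
                gold.append(
                    Predication(
                        subject=subject,
                        relation=relation,
                        object=obj,
                        predicate_phrase=phrase,
                        doc_id=doc_id,
                        sentence_id=sentence_id(text, config.collection),
                        collection=config.collection,
                    )
                )
            offset += len(text) + 1  # single joining space

    gold = dedupe(gold)
    bundle = FixtureBundle(
        config=config,
        documents=documents,
        annotations=annotations,
        sentences=sentences,
        vocabulary=vocabulary,
        relation_vocab=relation_vocab,
        taxonomy=taxonomy,
        gold_predications=gold,
    )
    if config.n_queries:
        bundle.queries = [
            random_query_spec(rng, bundle) for _ in range(config.n_queries)
        ]
    return bundle


def random_query_spec(rng: random.Random, bundle: FixtureBundle) -> QuerySpec:
    """A random 1–3 pattern query (shared variables, type-All) plus gold answer.

    Most patterns are seeded from the gold statements of one document so a
    substantial share of queries is answerable; the rest draw relation and
    entities uniformly, covering the empty-result paths as well.
    """
    vocabulary = bundle.vocabulary
    taxonomy = bundle.taxonomy
    corpus_entities = sorted(
        {e for p in bundle.gold_predications for e in (p.subject, p.object)}
    ) or sorted({entry.entity for entry in bundle.vocabulary.entries})
    entity_types = sorted({e.type for e in corpus_entities})
    relations = sorted(bundle.relation_vocab.relations)
    n_patterns = rng.randint(1, 3)
    var_names = ["X", "Y", "Z", "U", "V", "W"]
    used_vars: list[VariableNode] = []

    by_doc: dict[str, list[Predication]] = {}
    for pred in bundle.gold_predications:
        by_doc.setdefault(pred.doc_id, []).append(pred)
    seed_preds = by_doc[rng.choice(sorted(by_doc))] if by_doc else []

    def concrete_role(entity: Entity) -> tuple[frozenset[Entity], str]:
        name = next(
            entry.preferred_name
            for entry in vocabulary.entries
            if entry.entity == entity
        )
        expanded = {
            Entity(i, vocabulary.type_of(i) or entity.type)
            for i in taxonomy.expansion_set(entity.id)
        }
        return frozenset(expanded), f'"{name}"'

    def variable_role(hint_type: str) -> tuple[VariableNode, str]:
        if used_vars and rng.random() < 0.5:
            var = rng.choice(used_vars)
        else:
            name = var_names[len(used_vars) % len(var_names)]
            vtype = rng.choice([hint_type, TYPE_ALL, rng.choice(entity_types)])
            var = VariableNode(name=name, type=vtype)
            used_vars.append(var)
        return var, f"?{var.name}({var.type})"

    patterns: list[FactPattern] = []
    lines: list[str] = []
    for _ in range(n_patterns):
        if seed_preds and rng.random() < 0.7:
            seed = rng.choice(seed_preds)
            relation = seed.relation
            role_entities = (seed.subject, seed.object)
        else:
            relation = rng.choice(relations)
            role_entities = (
                rng.choice(corpus_entities),
                rng.choice(corpus_entities),
            )
        roles = []
        texts = []
        for entity in role_entities:
            if rng.random() < 0.5:
                role, text = concrete_role(entity)
            else:
                role, text = variable_role(entity.type)
            roles.append(role)
            texts.append(text)
        patterns.append(
            FactPattern(subject=roles[0], relation=relation, object=roles[1])
        )
        lines.append(f"{texts[0]} {relation} {texts[1]}")
    graph = NarrativeQueryGraph(patterns=patterns)
    expected = brute_force_match(bundle.gold_predications, graph, bundle.dates)
    return QuerySpec(text="\n".join(lines), graph=graph, expected=expected)


def brute_force_match(
    predications: Sequence[Predication],
    q: NarrativeQueryGraph,
    dates: Mapping[DocKey, int] | None = None,
) -> list[QueryResult]:
    """Exhaustive substitution enumeration — the independent query oracle.

    For every document, every assignment of the query's variables to
    entities occurring in that document's statements is tested against all
    patterns; each satisfying (document, μ) pair yields one result.  Results
    are ordered date-descending with doc-id-descending tie-break, mirroring
    the engine's contract.
    """
    by_doc: dict[DocKey, list[Predication]] = {}
    for pred in predications:
        by_doc.setdefault((pred.collection, pred.doc_id), []).append(pred)

    # Substitutions are keyed by variable *name*: two variables sharing a
    # name must bind one entity satisfying both type restrictions.
    type_filters: dict[str, set[str]] = {}
    for var in q.variables:
        type_filters.setdefault(var.name, set()).add(var.type)
    var_names = sorted(type_filters)

    results: list[QueryResult] = []
    for doc_key, preds in by_doc.items():
        doc_entities = sorted({e for p in preds for e in (p.subject, p.object)})
        candidate_lists = []
        for name in var_names:
            required = type_filters[name] - {TYPE_ALL}
            candidates = [
                e for e in doc_entities if all(e.type == t for t in required)
            ]
            candidate_lists.append(candidates)
        for assignment in product(*candidate_lists):
            mu = dict(zip(var_names, assignment))
            provenance: dict[int, list[int]] = {}
            ok = True
            for pos, fp in enumerate(q.patterns):
                supporting = [
                    p.predication_id
                    for p in preds
                    if p.relation == fp.relation
                    and _brute_role(fp.subject, p.subject, mu)
                    and _brute_role(fp.object, p.object, mu)
                ]
                if not supporting:
                    ok = False
                    break
                provenance[pos] = sorted(
                    i for i in supporting if i is not None
                )
            if ok:
                results.append(
                    QueryResult(
                        doc_key=doc_key,
                        substitution=mu,
                        provenance=provenance,
                        date=dates.get(doc_key, 0) if dates else 0,
                    )
                )
    results.sort(key=lambda r: sorted(r.substitution.items()))
    results.sort(key=lambda r: (r.date, r.doc_key[0], r.doc_key[1]), reverse=True)
    return results


def _brute_role(
    role: frozenset[Entity] | VariableNode, entity: Entity, mu: Mapping[str, Entity]
) -> bool:
    if isinstance(role, VariableNode):
        return mu[role.name] == entity
    return any(e.id == entity.id for e in role)


def worked_example() -> FixtureBundle:
    """The metformin/type-2-diabetes bundle with a hand-written parse.

    One document whose title reads "Metformin is the mainstay therapy for
    type 2 diabetes"; PathIE finds the relation-vocabulary keyword *therapy*
    on the dependency path between the two entities and canonicalization
    maps it to *treats*.
    """
    collection = "example"
    doc = Document(
        doc_id="wex1",
        title="Metformin is the mainstay therapy for type 2 diabetes",
        abstract="",
        collection=collection,
    )
    tokens = (
        Token(1, "Metformin", "metformin", "PROPN", 5, "nsubj"),
        Token(2, "is", "be", "AUX", 5, "cop"),
        Token(3, "the", "the", "DET", 5, "det"),
        Token(4, "mainstay", "mainstay", "NOUN", 5, "compound"),
        Token(5, "therapy", "therapy", "NOUN", 0, "root"),
        Token(6, "for", "for", "ADP", 9, "case"),
        Token(7, "type", "type", "NOUN", 9, "compound"),
        Token(8, "2", "2", "NUM", 9, "nummod"),
        Token(9, "diabetes", "diabetes", "NOUN", 5, "nmod"),
    )
    sentence = ParsedSentence(
        doc_id=doc.doc_id,
        sent_index=0,
        text=doc.text,
        tokens=tokens,
        char_span=(0, len(doc.text)),
    )
    metformin = Entity("D008687", "Drug")
    t2dm = Entity("D003924", "Disease")
    vocabulary = EntityVocabulary(
        [
            VocabularyEntry(
                entity=metformin,
                preferred_name="Metformin",
                synonyms=frozenset({"Metformin", "metformin"}),
            ),
            VocabularyEntry(
                entity=t2dm,
                preferred_name="type 2 diabetes",
                synonyms=frozenset(
                    {"type 2 diabetes", "diabetes mellitus type 2"}
                ),
            ),
        ]
    )
    annotations = [
        EntityAnnotation(
            doc_id=doc.doc_id, start=0, end=9, mention="Metformin", entity=metformin
        ),
        EntityAnnotation(
            doc_id=doc.doc_id,
            start=38,
            end=53,
            mention="type 2 diabetes",
            entity=t2dm,
        ),
    ]
    gold = [
        Predication(
            subject=metformin,
            relation="treats",
            object=t2dm,
            predicate_phrase="therapy",
            doc_id=doc.doc_id,
            sentence_id=sentence_id(doc.text, collection),
            collection=collection,
        )
    ]
    return FixtureBundle(
        config=FixtureConfig(n_docs=1, seed=0, collection=collection),
        documents=[doc],
        annotations={doc.doc_id: annotations},
        sentences={doc.doc_id: [sentence]},
        vocabulary=vocabulary,
        relation_vocab=RelationVocabulary.default(),
        taxonomy=Taxonomy(),
        gold_predications=gold,
    )
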