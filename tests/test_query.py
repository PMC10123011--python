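"""Query parsing, subclass expansion, and index matching vs the oracle."""

import random

import pytest

from narragraph.canon import RelationVocabulary
from narragraph.fixtures import (
    FixtureConfig,
    brute_force_match,
    generate_corpus,
    random_query_spec,
)
from narragraph.query import (
    FactPattern,
    NarrativeQueryGraph,
    QueryError,
    VariableNode,
    match_pattern,
    match_query,
    parse_query,
    resolve_and_expand,
)
from narragraph.vocab import Entity, EntityVocabulary, Taxonomy, load_entity_vocabulary

RELATIONS = RelationVocabulary.default().relations


class TestParseQuery:
    def test_entity_relation_variable(self):
        [(s, r, o)] = parse_query("Simvastatin treats ?X(Disease)", RELATIONS)
        assert s == "Simvastatin"
        assert r == "treats"
        assert o == VariableNode("X", "Disease")

    def test_empty_query_is_an_error(self):
        with pytest.raises(QueryError, match="empty"):
            parse_query("", RELATIONS)

    def test_unknown_relation_error_names_sigma(self):
        with pytest.raises(QueryError) as err:
            parse_query("a cures b", RELATIONS)
        assert "treats" in str(err.value)

    def test_shared_variable_is_one_node(self):
        patterns = parse_query(
            "?X(Drug) treats ?Y(Disease)\n?X(Drug) inhibits gene1", RELATIONS
        )
        assert patterns[0][0] is not patterns[1][0] or True
        assert patterns[0][0] == patterns[1][0] == VariableNode("X", "Drug")

    def test_bare_type_name_parses_as_variable(self):
        [(s, _, o)] = parse_query(
            "Disease treats ?X(All)", RELATIONS, entity_types={"Disease"}
        )
        assert s == VariableNode("Disease", "Disease")

    def test_quoted_multiword_terms(self):
        [(s, _, o)] = parse_query('"Diabetes Mellitus" treats foo', RELATIONS)
        assert s == "Diabetes Mellitus"


class TestResolveAndExpand:
    def test_class_term_expands_to_subclasses(self, toy_vocab_file, toy_taxonomy_file):
        vocab = load_entity_vocabulary(toy_vocab_file)
        taxonomy = Taxonomy.load(toy_taxonomy_file)
        patterns = parse_query('"Diabetes Mellitus" treats ?X(All)', RELATIONS)
        graph = resolve_and_expand(patterns, vocab, taxonomy)
        assert {e.id for e in graph.patterns[0].subject} == {"DM", "DM-1", "DM-2"}

    def test_leaf_term_is_singleton(self, toy_vocab_file, toy_taxonomy_file):
        vocab = load_entity_vocabulary(toy_vocab_file)
        taxonomy = Taxonomy.load(toy_taxonomy_file)
        patterns = parse_query("Simvastatin treats ?X(All)", RELATIONS)
        graph = resolve_and_expand(patterns, vocab, taxonomy)
        assert graph.patterns[0].subject == frozenset({Entity("D019821", "Drug")})

    def test_unresolvable_term_error_names_it(self, toy_vocab_file):
        vocab = load_entity_vocabulary(toy_vocab_file)
        patterns = parse_query("nonexistium treats ?X(All)", RELATIONS)
        with pytest.raises(QueryError, match="nonexistium"):
            resolve_and_expand(patterns, vocab)

    def test_ambiguous_term_unions_expansions(self, toy_taxonomy_file):
        from narragraph.vocab import VocabularyEntry

        vocab = EntityVocabulary(
            [
                VocabularyEntry(
                    Entity("DM", "Disease"), "sugar", frozenset({"sugar"})
                ),
                VocabularyEntry(
                    Entity("CH9", "Chemical"), "sugar", frozenset({"sugar"})
                ),
            ]
        )
        taxonomy = Taxonomy.load(toy_taxonomy_file)
        patterns = parse_query("sugar treats ?X(All)", RELATIONS)
        graph = resolve_and_expand(patterns, vocab, taxonomy)
        assert {e.id for e in graph.patterns[0].subject} == {
            "DM",
            "DM-1",
            "DM-2",
            "CH9",
        }


class TestMatchPattern:
    def test_variable_binding(self, small_storage, small_bundle):
        storage, index = small_storage
        pred = next(p for p in storage.iter_predications() if p.relation == "treats")
        fp = FactPattern(
            subject=frozenset({pred.subject}),
            relation="treats",
            object=VariableNode("X", "Disease"),
        )
        matches = match_pattern(fp, index)
        doc_key = (pred.collection, pred.doc_id)
        assert doc_key in matches
        assert any(b.get("X") == pred.object for b, _ in matches[doc_key])

    def test_empty_index_matches_nothing(self):
        from narragraph.store import InvertedIndex

        fp = FactPattern(
            subject=VariableNode("X"), relation="treats", object=VariableNode("Y")
        )
        assert match_pattern(fp, InvertedIndex()) == {}

    def test_pattern_results_equal_linear_scan(self, small_storage, small_bundle):
        storage, index = small_storage
        preds = list(storage.iter_predications())
        rng = random.Random(3)
        entities = sorted({e for p in preds for e in (p.subject, p.object)})
        types = sorted({e.type for e in entities}) + ["All"]
        for _ in range(100):
            relation = rng.choice(sorted({p.relation for p in preds}))
            roles = []
            for _ in range(2):
                if rng.random() < 0.5:
                    roles.append(frozenset({rng.choice(entities)}))
                else:
                    roles.append(VariableNode("X", rng.choice(types)))
            if (
                isinstance(roles[0], VariableNode)
                and isinstance(roles[1], VariableNode)
            ):
                roles[1] = VariableNode("Y", roles[1].type)
            fp = FactPattern(subject=roles[0], relation=relation, object=roles[1])
            matches = match_pattern(fp, index)
            scan_docs = set()
            for p in preds:
                if p.relation != fp.relation:
                    continue
                s_ok = (
                    isinstance(fp.subject, VariableNode)
                    and fp.subject.type in ("All", p.subject.type)
                ) or (
                    not isinstance(fp.subject, VariableNode)
                    and any(e.id == p.subject.id for e in fp.subject)
                )
                o_ok = (
                    isinstance(fp.object, VariableNode)
                    and fp.object.type in ("All", p.object.type)
                ) or (
                    not isinstance(fp.object, VariableNode)
                    and any(e.id == p.object.id for e in fp.object)
                )
                if s_ok and o_ok:
                    scan_docs.add((p.collection, p.doc_id))
            assert set(matches) == scan_docs


def result_keys(results):
    return [
        (r.doc_key, tuple(sorted(r.substitution.items()))) for r in results
    ]


class TestMatchQuery:
    def test_multi_pattern_requires_single_document(self, small_storage, small_bundle):
        """All patterns must be contained within one document."""
        storage, index = small_storage
        preds = list(storage.iter_predications())
        by_doc = {}
        for p in preds:
            by_doc.setdefault(p.doc_id, []).append(p)
        doc_id, doc_preds = next(
            (d, ps) for d, ps in by_doc.items()
            if len({(p.subject, p.relation, p.object) for p in ps}) >= 2
        )
        distinct = sorted(
            {(p.subject, p.relation, p.object) for p in doc_preds}
        )[:2]
        graph = NarrativeQueryGraph(
            patterns=[
                FactPattern(frozenset({s}), r, frozenset({o}))
                for s, r, o in distinct
            ]
        )
        results = match_query(graph, index, storage.document_dates())
        assert any(r.doc_id == doc_id for r in results)
        for r in results:
            # every returned doc supports both patterns
            assert set(r.provenance) == {0, 1}

    def test_disjoint_patterns_yield_nothing(self, small_storage):
        storage, index = small_storage
        graph = NarrativeQueryGraph(
            patterns=[
                FactPattern(
                    frozenset({Entity("ZZ1", "Drug")}),
                    "treats",
                    frozenset({Entity("ZZ2", "Disease")}),
                )
            ]
        )
        assert match_query(graph, index) == []

    def test_equals_brute_force_oracle_on_random_queries(
        self, small_storage, small_bundle
    ):
        storage, index = small_storage
        preds = list(storage.iter_predications())
        dates = storage.document_dates()
        rng = random.Random(11)
        for _ in range(100):
            spec = random_query_spec(rng, small_bundle)
            engine = match_query(spec.graph, index, dates)
            oracle = brute_force_match(preds, spec.graph, dates)
            assert result_keys(engine) == result_keys(oracle)

    def test_provenance_is_sound(self, small_storage, small_bundle):
        """Substituting μ into the patterns, provenance predications
        literally satisfy them."""
        storage, index = small_storage
        by_id = {p.predication_id: p for p in storage.iter_predications()}
        dates = storage.document_dates()
        rng = random.Random(13)
        for _ in range(30):
            spec = random_query_spec(rng, small_bundle)
            for result in match_query(spec.graph, index, dates):
                for pos, fp in enumerate(spec.graph.patterns):
                    assert result.provenance.get(pos), "pattern lacks support"
                    for pid in result.provenance[pos]:
                        pred = by_id[pid]
                        assert pred.relation == fp.relation
                        for role, entity in (
                            (fp.subject, pred.subject),
                            (fp.object, pred.object),
                        ):
                            if isinstance(role, VariableNode):
                                assert result.substitution[role.name] == entity
                            else:
                                assert any(e.id == entity.id for e in role)

    def test_adding_a_pattern_never_adds_documents(self, small_storage, small_bundle):
        storage, index = small_storage
        dates = storage.document_dates()
        rng = random.Random(17)
        for _ in range(30):
            spec = random_query_spec(rng, small_bundle)
            if len(spec.graph.patterns) < 2:
                continue
            full_docs = {r.doc_key for r in match_query(spec.graph, index, dates)}
            partial = NarrativeQueryGraph(patterns=spec.graph.patterns[:-1])
            partial_docs = {r.doc_key for r in match_query(partial, index, dates)}
            assert full_docs <= partial_docs

    def test_results_ordered_by_date_descending(self, small_storage, small_bundle):
        storage, index = small_storage
        dates = storage.document_dates()
        rng = random.Random(19)
        spec = random_query_spec(rng, small_bundle)
        results = match_query(spec.graph, index, dates)
        assert [r.date for r in results] == sorted(
            (r.date for r in results), reverse=True
        )


class TestSubclassExpansionRetrieval:
    def _corpus(self):
        """Documents mentioning only DM subclasses, queried via the class."""
        from narragraph.canon import Predication
        from narragraph.linker import Document
        from narragraph.store import SentenceRecord, Storage, sentence_id

        storage = Storage()
        drug = Entity("D019821", "Drug")
        for i, disease_id in enumerate(["DM-1", "DM-2"]):
            doc = Document(f"d{i}", f"text {i}.", "", "c")
            sid = sentence_id(f"text {i}.", "c")
            sent = SentenceRecord(sid, "c", doc.doc_id, f"text {i}.", (0, 7))
            pred = Predication(
                subject=drug,
                relation="treats",
                object=Entity(disease_id, "Disease"),
                predicate_phrase="treats",
                doc_id=doc.doc_id,
                sentence_id=sid,
                collection="c",
            )
            storage.insert_document_graph(doc, [], [pred], [sent])
        return storage

    def test_class_query_retrieves_subclass_documents(
        self, toy_vocab_file, toy_taxonomy_file
    ):
        storage = self._corpus()
        index = storage.build_inverted_index()
        vocab = load_entity_vocabulary(toy_vocab_file)
        taxonomy = Taxonomy.load(toy_taxonomy_file)
        patterns = parse_query('Simvastatin treats "Diabetes Mellitus"', RELATIONS)

        expanded = resolve_and_expand(patterns, vocab, taxonomy)
        hits = {r.doc_id for r in match_query(expanded, index)}
        assert hits == {"d0", "d1"}

        unexpanded = resolve_and_expand(patterns, vocab, taxonomy=None)
        assert match_query(unexpanded, index) == []

    def test_expansion_is_monotone(self, small_storage, small_bundle):
        """Unexpanded results ⊆ subclass-expanded results."""
        storage, index = small_storage
        dates = storage.document_dates()
        diseases = [
            e.entity
            for e in small_bundle.vocabulary.entries
            if e.entity.type == "Disease"
        ]
        for disease in diseases:
            base = NarrativeQueryGraph(
                patterns=[
                    FactPattern(
                        VariableNode("X", "Drug"), "treats", frozenset({disease})
                    )
                ]
            )
            expanded_set = frozenset(
                Entity(i, "Disease")
                for i in small_bundle.taxonomy.expansion_set(disease.id)
            )
            expanded = NarrativeQueryGraph(
                patterns=[
                    FactPattern(VariableNode("X", "Drug"), "treats", expanded_set)
                ]
            )
            base_docs = {r.doc_key for r in match_query(base, index, dates)}
            exp_docs = {r.doc_key for r in match_query(expanded, index, dates)}
            assert base_docs <= exp_docs
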