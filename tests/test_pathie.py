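"""Sentence splitting, CoNLL-U round trip, path finding, and extraction."""

import random
from collections import deque

import pytest
from hypothesis import given, strategies as st

from narragraph.linker import Document, EntityAnnotation
from narragraph.pathie import (
    ParsedSentence,
    Token,
    extract_statements,
    read_conllu,
    shortest_paths,
    split_sentences,
    write_conllu,
)
from narragraph.vocab import Entity


def bfs_distances(n_tokens, edges, source):
    """Independent all-pairs BFS oracle over the undirected token graph."""
    adj = {i: set() for i in range(1, n_tokens + 1)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nxt in adj[node]:
            if nxt not in dist:
                dist[nxt] = dist[node] + 1
                queue.append(nxt)
    return dist


def random_tree_sentence(rng, n):
    """A random dependency tree of n tokens (token i attaches to a prior one)."""
    tokens = []
    for i in range(1, n + 1):
        head = 0 if i == 1 else rng.randint(1, i - 1)
        tokens.append(Token(i, f"w{i}", f"w{i}", "NOUN", head, "dep"))
    text = " ".join(t.surface for t in tokens)
    return ParsedSentence("d", 0, text, tuple(tokens), (0, len(text)))


class TestSplitSentences:
    def test_two_sentences(self):
        spans = split_sentences(Document("d", "A rat. B cat."))
        assert len(spans) == 2

    def test_spans_tile_the_text(self, small_bundle):
        for doc in small_bundle.documents:
            spans = split_sentences(doc)
            assert spans[0][0] == 0
            assert spans[-1][1] == len(doc.text)
            for (_, e1), (s2, _) in zip(spans, spans[1:]):
                assert e1 == s2

    def test_empty_abstract_gives_title_only_span(self):
        doc = Document("d", "Only a title without punctuation")
        assert split_sentences(doc) == [(0, len(doc.text))]

    def test_template_sentence_count(self, small_bundle):
        for doc in small_bundle.documents:
            expected = len(small_bundle.sentences[doc.doc_id])
            assert len(split_sentences(doc)) == expected


class TestConllu:
    def test_round_trip(self, tmp_path, small_bundle):
        sentences = [
            s for d in small_bundle.documents for s in small_bundle.sentences[d.doc_id]
        ]
        path = tmp_path / "parses.conllu"
        write_conllu(path, sentences)
        restored = read_conllu(path)
        assert len(restored) == len(sentences)
        for a, b in zip(sentences, restored):
            assert (a.doc_id, a.sent_index, a.text, a.tokens, a.char_span) == (
                b.doc_id,
                b.sent_index,
                b.text,
                b.tokens,
                b.char_span,
            )

    def test_multi_root_parse_rejected(self):
        with pytest.raises(ValueError, match="root"):
            ParsedSentence(
                "d",
                0,
                "a b",
                (
                    Token(1, "a", "a", "NOUN", 0, "root"),
                    Token(2, "b", "b", "NOUN", 0, "root"),
                ),
            )


class TestShortestPaths:
    def test_chain(self):
        sent = ParsedSentence(
            "d",
            0,
            "a b c",
            (
                Token(1, "a", "a", "NOUN", 2, "dep"),
                Token(2, "b", "b", "NOUN", 3, "dep"),
                Token(3, "c", "c", "VERB", 0, "root"),
            ),
        )
        assert shortest_paths(sent, 1, 3) == {(1, 2, 3)}

    def test_same_token_yields_zero_length_path(self):
        sent = random_tree_sentence(random.Random(0), 5)
        assert shortest_paths(sent, 3, 3) == {(3,)}

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_agrees_with_bfs_oracle_on_random_trees(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 12)
        sent = random_tree_sentence(rng, n)
        edges = [(t.index, t.head) for t in sent.tokens if t.head != 0]
        a, b = rng.sample(range(1, n + 1), 2)
        dist = bfs_distances(n, edges, a)
        paths = shortest_paths(sent, a, b)
        assert paths, "trees are connected"
        for path in paths:
            assert path[0] == a and path[-1] == b
            assert len(path) - 1 == dist[b]
            # path membership: consecutive hops are tree edges
            for x, y in zip(path, path[1:]):
                assert (x, y) in edges or (y, x) in edges


def _simple_sentence():
    tokens = (
        Token(1, "drug", "drug", "NOUN", 2, "nsubj"),
        Token(2, "treats", "treat", "VERB", 0, "root"),
        Token(3, "illness", "illness", "NOUN", 2, "obj"),
    )
    return ParsedSentence("d", 0, "drug treats illness", tokens, (0, 19))


class TestExtractStatements:
    DRUG = Entity("D1", "Drug")
    DISEASE = Entity("I1", "Disease")

    def _annotations(self):
        return [
            EntityAnnotation("d", 0, 4, "drug", self.DRUG),
            EntityAnnotation("d", 12, 19, "illness", self.DISEASE),
        ]

    def test_verb_on_path_yields_statement(self):
        [stmt] = extract_statements(_simple_sentence(), self._annotations(), set())
        assert (stmt.subject, stmt.predicate_phrase, stmt.object) == (
            self.DRUG,
            "treats",
            self.DISEASE,
        )

    def test_keyword_on_path_yields_statement(self, example_bundle):
        """The metformin sentence: keyword 'therapy' sits on the path."""
        doc = example_bundle.documents[0]
        sent = example_bundle.sentences[doc.doc_id][0]
        stmts = extract_statements(
            sent,
            example_bundle.annotations[doc.doc_id],
            example_bundle.relation_vocab.all_terms(),
        )
        phrases = {s.predicate_phrase for s in stmts}
        assert "therapy" in phrases
        therapy = next(s for s in stmts if s.predicate_phrase == "therapy")
        assert therapy.subject.id == "D008687"
        assert therapy.object.id == "D003924"

    def test_single_entity_yields_nothing(self):
        anns = [EntityAnnotation("d", 0, 4, "drug", self.DRUG)]
        assert extract_statements(_simple_sentence(), anns, {"treats"}) == []

    def test_path_without_verb_or_keyword_yields_nothing(self):
        # appositive parse: the connecting path holds two nouns only
        tokens = (
            Token(1, "drug", "drug", "NOUN", 0, "root"),
            Token(2, "illness", "illness", "NOUN", 1, "appos"),
        )
        sent = ParsedSentence("d", 0, "drug illness", tokens, (0, 12))
        anns = [
            EntityAnnotation("d", 0, 4, "drug", self.DRUG),
            EntityAnnotation("d", 5, 12, "illness", self.DISEASE),
        ]
        assert extract_statements(sent, anns, {"therapy"}) == []

    def test_insensitive_to_annotation_order(self):
        forward = extract_statements(_simple_sentence(), self._annotations(), set())
        backward = extract_statements(
            _simple_sentence(), list(reversed(self._annotations())), set()
        )
        assert forward == backward

    def test_statement_count_upper_bound(self, small_bundle):
        keywords = small_bundle.relation_vocab.all_terms()
        for doc in small_bundle.documents:
            for sent in small_bundle.sentences[doc.doc_id]:
                anns = [
                    a
                    for a in small_bundle.annotations[doc.doc_id]
                    if a.start >= sent.char_span[0] and a.end <= sent.char_span[1]
                ]
                stmts = extract_statements(sent, anns, keywords)
                entities = {a.entity for a in anns}
                n_pairs = len(entities) * (len(entities) - 1) // 2
                harvestable = sum(
                    1
                    for t in sent.tokens
                    if t.upos in ("VERB", "AUX") or t.lemma.lower() in keywords
                )
                assert len(stmts) <= n_pairs * max(harvestable, 1)

    def test_planted_template_statements_recovered(self, small_bundle):
        """Recall 1.0 on template sentences with gold parses."""
        keywords = small_bundle.relation_vocab.all_terms()
        recovered = set()
        for doc in small_bundle.documents:
            for sent in small_bundle.sentences[doc.doc_id]:
                anns = [
                    a
                    for a in small_bundle.annotations[doc.doc_id]
                    if a.start >= sent.char_span[0] and a.end <= sent.char_span[1]
                ]
                for stmt in extract_statements(sent, anns, keywords):
                    recovered.add(
                        (stmt.doc_id, stmt.subject, stmt.predicate_phrase, stmt.object)
                    )
        for gold in small_bundle.gold_predications:
            assert (
                gold.doc_id,
                gold.subject,
                gold.predicate_phrase,
                gold.object,
            ) in recovered
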