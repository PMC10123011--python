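"""PathIE: recall-oriented statement extraction over dependency paths.

For every sentence mentioning at least two different entities, the shortest
path between the entities in the dependency graph of the sentence is
computed.  Every verb phrase and every relation-vocabulary keyword lying on
such a path is harvested, yielding raw ``(subject, phrase, object)``
statements.  Extraction is deliberately recall-oriented: direction and
precision are repaired downstream during canonicalization.

Sentences arrive pre-parsed in CoNLL-U; the reader here handles the plain
10-column dialect plus ``# doc_id``, ``# sent_index`` and ``# text``
metadata comments, so tests and fixtures need no parser model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .linker import Document, EntityAnnotation
from .vocab import Entity

__all__ = [
    "Token",
    "ParsedSentence",
    "RawStatement",
    "split_sentences",
    "shortest_paths",
    "extract_statements",
    "read_conllu",
    "write_conllu",
]

#: Universal POS tags harvested as verbal predicates.  AUX is included so
#: copula-only paths still yield a (low-value) statement for canonicalization
#: to accept or discard.
VERBAL_POS = frozenset({"VERB", "AUX"})

#: Dependency labels of tokens folded into a verb phrase (phrasal verbs).
PARTICLE_DEPRELS = frozenset({"compound:prt", "prt"})


@dataclass(frozen=True)
class Token:
    """One CoNLL-U token: 1-based index, surface, lemma, UPOS, head, deprel."""

    index: int
    surface: str
    lemma: str
    upos: str
    head: int  # 0 marks the root
    deprel: str


@dataclass
class ParsedSentence:
    """A dependency-parsed sentence anchored in its document.

    ``char_span`` locates the sentence text within ``Document.text``;
    token character offsets are recovered by greedy left-to-right alignment
    of token surfaces against the sentence text.
    """

    doc_id: str
    sent_index: int
    text: str
    tokens: tuple[Token, ...]
    char_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        n = len(self.tokens)
        roots = [t for t in self.tokens if t.head == 0]
        if n and len(roots) != 1:
            raise ValueError(
                f"sentence {self.doc_id}/{self.sent_index}: expected exactly one "
                f"root token, found {len(roots)}"
            )
        for t in self.tokens:
            if t.head < 0 or t.head > n:
                raise ValueError(
                    f"sentence {self.doc_id}/{self.sent_index}: head index "
                    f"{t.head} out of range"
                )
        self._spans = self._align_tokens()

    def _align_tokens(self) -> tuple[tuple[int, int], ...]:
        spans: list[tuple[int, int]] = []
        pos = 0
        for t in self.tokens:
            found = self.text.find(t.surface, pos)
            if found < 0:
                raise ValueError(
                    f"sentence {self.doc_id}/{self.sent_index}: token "
                    f"{t.surface!r} not found in sentence text"
                )
            spans.append((found, found + len(t.surface)))
            pos = found + len(t.surface)
        return tuple(spans)

    def token_span(self, index: int) -> tuple[int, int]:
        """Character span of a token (1-based index) within the sentence."""
        return self._spans[index - 1]

    def token(self, index: int) -> Token:
        return self.tokens[index - 1]

    def dependency_graph(self) -> nx.Graph:
        """Undirected token graph over head/dependent edges."""
        graph = nx.Graph()
        graph.add_nodes_from(t.index for t in self.tokens)
        graph.add_edges_from(
            (t.index, t.head) for t in self.tokens if t.head != 0
        )
        return graph

    def tokens_in_char_range(self, start: int, end: int) -> list[int]:
        """Indices of tokens overlapping a sentence-local character range."""
        return [
            t.index
            for t, (s, e) in zip(self.tokens, self._spans)
            if s < end and e > start
        ]


@dataclass(frozen=True)
class RawStatement:
    """An uncanonicalized extraction: two entities plus a predicate phrase.

    The predicate phrase is either a verb phrase found on the dependency
    path or a relation-vocabulary keyword; ``predicate_lemma`` carries the
    lemmatized form for exact vocabulary matching downstream.
    """

    subject: Entity
    predicate_phrase: str
    object: Entity
    doc_id: str
    sent_index: int
    path_tokens: tuple[int, ...] = ()
    predicate_lemma: str = ""

    def __post_init__(self) -> None:
        if self.subject.id == self.object.id:
            raise ValueError("subject and object must be distinct entities")
        if not self.predicate_phrase:
            raise ValueError("predicate phrase must be non-empty")


_SENT_BOUNDARY = re.compile(r"[.!?]+(\s+|$)")


def split_sentences(doc: Document) -> list[tuple[int, int]]:
    """Split ``doc.text`` into sentence character spans that tile the text.

    Boundaries fall after terminal punctuation followed by whitespace; the
    trailing whitespace belongs to the preceding span so spans are contiguous
    and cover the whole text.  Deterministic for fixed input.
    """
    text = doc.text
    if not text:
        return []
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _SENT_BOUNDARY.finditer(text):
        end = match.end()
        if end < len(text) or end == len(text):
            if text[start:end].strip():
                spans.append((start, end))
                start = end
    if start < len(text):
        if text[start:].strip():
            spans.append((start, len(text)))
        elif spans:
            # trailing whitespace joins the final span to preserve tiling
            spans[-1] = (spans[-1][0], len(text))
    return spans


def shortest_paths(
    sentence: ParsedSentence, token_a: int, token_b: int
) -> set[tuple[int, ...]]:
    """All minimum-length paths between two tokens in the dependency graph.

    Dependency edges are treated as undirected.  ``token_a == token_b``
    yields the single zero-length path; disconnected tokens (malformed
    parses) yield the empty set.
    """
    if token_a == token_b:
        return {(token_a,)}
    graph = sentence.dependency_graph()
    try:
        return {tuple(p) for p in nx.all_shortest_paths(graph, token_a, token_b)}
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return set()


def _verb_phrase(sentence: ParsedSentence, index: int) -> tuple[str, str]:
    """Verb token plus directly attached particles, as (surface, lemma)."""
    token = sentence.token(index)
    parts = [(token.index, token.surface, token.lemma)]
    for t in sentence.tokens:
        if t.head == index and t.deprel in PARTICLE_DEPRELS:
            parts.append((t.index, t.surface, t.lemma))
    parts.sort()
    surface = " ".join(p[1] for p in parts)
    lemma = " ".join(p[2] for p in parts)
    return surface, lemma


def _anchor_token(sentence: ParsedSentence, span_tokens: Sequence[int]) -> int | None:
    """Syntactic head of a mention's token span (head points outside span)."""
    if not span_tokens:
        return None
    span = set(span_tokens)
    for idx in span_tokens:
        head = sentence.token(idx).head
        if head == 0 or head not in span:
            return idx
    return span_tokens[0]


def extract_statements(
    sentence: ParsedSentence,
    annotations: Iterable[EntityAnnotation],
    relation_keywords: Iterable[str],
    sentence_offset: int | None = None,
) -> list[RawStatement]:
    """PathIE extraction for one sentence.

    ``annotations`` carry document-level character offsets; they are mapped
    to sentence-local token spans via ``sentence.char_span`` (or an explicit
    ``sentence_offset``).  For every unordered pair of distinct entities and
    every shortest dependency path between their anchor tokens, each verbal
    token and each keyword token on the path yields one raw statement.  The
    first-mentioned entity becomes the subject; canonicalization may later
    swap the pair to satisfy type constraints.
    """
    offset = sentence.char_span[0] if sentence_offset is None else sentence_offset
    keywords = {k.lower() for k in relation_keywords}

    # entity -> (anchor token, first mention offset), earliest mention wins
    anchors: dict[Entity, tuple[int, int]] = {}
    for ann in annotations:
        local_start = ann.start - offset
        local_end = ann.end - offset
        span_tokens = sentence.tokens_in_char_range(local_start, local_end)
        anchor = _anchor_token(sentence, span_tokens)
        if anchor is None:
            continue
        prev = anchors.get(ann.entity)
        if prev is None or local_start < prev[1]:
            anchors[ann.entity] = (anchor, local_start)

    entities = sorted(anchors, key=lambda e: (anchors[e][1], e.id))
    statements: set[RawStatement] = set()
    for i, first in enumerate(entities):
        for second in entities[i + 1 :]:
            if first.id == second.id:
                continue
            for path in shortest_paths(
                sentence, anchors[first][0], anchors[second][0]
            ):
                for idx in path:
                    token = sentence.token(idx)
                    emitted: list[tuple[str, str]] = []
                    if token.upos in VERBAL_POS:
                        emitted.append(_verb_phrase(sentence, idx))
                    if (
                        token.lemma.lower() in keywords
                        or token.surface.lower() in keywords
                    ):
                        emitted.append((token.surface, token.lemma))
                    for phrase, lemma in emitted:
                        statements.add(
                            RawStatement(
                                subject=first,
                                predicate_phrase=phrase,
                                object=second,
                                doc_id=sentence.doc_id,
                                sent_index=sentence.sent_index,
                                path_tokens=tuple(path),
                                predicate_lemma=lemma,
                            )
                        )
    return sorted(
        statements,
        key=lambda s: (s.subject, s.object, s.predicate_phrase, s.path_tokens),
    )


def read_conllu(source: str | Path) -> list[ParsedSentence]:
    """Read CoNLL-U sentences (path or raw string).

    Metadata comments ``# doc_id = …``, ``# sent_index = …``, ``# text = …``
    and optionally ``# char_start/char_end`` anchor each sentence in its
    document.  Multiword-token ranges and empty nodes are skipped.
    """
    if isinstance(source, Path) or "\n" not in str(source):
        with open(source, encoding="utf-8") as handle:
            content = handle.read()
    else:
        content = str(source)

    sentences: list[ParsedSentence] = []
    meta: dict[str, str] = {}
    rows: list[Token] = []

    def flush() -> None:
        nonlocal meta, rows
        if rows:
            text = meta.get("text", " ".join(t.surface for t in rows))
            char_start = int(meta.get("char_start", 0))
            char_end = int(meta.get("char_end", char_start + len(text)))
            sentences.append(
                ParsedSentence(
                    doc_id=meta.get("doc_id", ""),
                    sent_index=int(meta.get("sent_index", len(sentences))),
                    text=text,
                    tokens=tuple(rows),
                    char_span=(char_start, char_end),
                )
            )
        meta, rows = {}, []

    for line in content.splitlines():
        line = line.rstrip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            key, eq, value = line[1:].partition("=")
            if eq:
                meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ValueError(f"malformed CoNLL-U line: {line!r}")
        if "-" in fields[0] or "." in fields[0]:
            continue  # multiword-token range or empty node
        rows.append(
            Token(
                index=int(fields[0]),
                surface=fields[1],
                lemma=fields[2],
                upos=fields[3],
                head=int(fields[6]),
                deprel=fields[7],
            )
        )
    flush()
    return sentences


def write_conllu(path: str | Path, sentences: Iterable[ParsedSentence]) -> None:
    """Serialize sentences in the CoNLL-U dialect understood by ``read_conllu``."""
    with open(path, "w", encoding="utf-8") as handle:
        for sent in sentences:
            handle.write(f"# doc_id = {sent.doc_id}\n")
            handle.write(f"# sent_index = {sent.sent_index}\n")
            handle.write(f"# text = {sent.text}\n")
            handle.write(f"# char_start = {sent.char_span[0]}\n")
            handle.write(f"# char_end = {sent.char_span[1]}\n")
            for t in sent.tokens:
                handle.write(
                    f"{t.index}\t{t.surface}\t{t.lemma}\t{t.upos}\t_\t_"
                    f"\t{t.head}\t{t.deprel}\t_\t_\n"
                )
            handle.write("\n")
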