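"""Embedded relational storage and the subject–predicate–object inverted index.

The store mirrors the service's relational schema: a central document table,
a tag table for entity annotations, a sentence table (sentences are
identified by an MD5 hash scoped per document collection, since several
statements may share one sentence), and a predication table for extracted
statements.  The inverted index maps each distinct
``(subject_id, subject_type, relation, object_id, object_type)`` key to a
denormalized JSON payload grouping supporting predication ids by document,
so a fact pattern needs a single index lookup and matches stay explainable.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .canon import Predication
from .linker import Document, EntityAnnotation
from .vocab import Entity

__all__ = [
    "sentence_id",
    "SentenceRecord",
    "IndexPosting",
    "InvertedIndex",
    "Storage",
    "make_sentence_records",
]

IndexKey = tuple[str, str, str, str, str]
DocKey = tuple[str, str]  # (collection, doc_id)


def sentence_id(text: str, collection: str) -> str:
    """MD5 hex digest identifying a sentence within a collection."""
    if not text:
        raise ValueError("sentence text must be non-empty")
    return hashlib.md5(f"{collection}|{text}".encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class SentenceRecord:
    """A stored sentence: MD5 id, owning document, text, and char span."""

    sentence_id: str
    collection: str
    doc_id: str
    text: str
    char_span: tuple[int, int]


def make_sentence_records(
    doc: Document, spans: Iterable[tuple[int, int]]
) -> list[SentenceRecord]:
    """Sentence records for a document from character spans of its text."""
    records = []
    for start, end in spans:
        text = doc.text[start:end].strip()
        if not text:
            continue
        records.append(
            SentenceRecord(
                sentence_id=sentence_id(text, doc.collection),
                collection=doc.collection,
                doc_id=doc.doc_id,
                text=text,
                char_span=(start, end),
            )
        )
    return records


@dataclass
class IndexPosting:
    """One inverted-index entry: a triple key plus per-document provenance."""

    key: IndexKey
    payload: dict[DocKey, list[int]] = field(default_factory=dict)

    @property
    def doc_keys(self) -> set[DocKey]:
        return set(self.payload)


class InvertedIndex:
    """In-memory triple index with per-relation buckets for pattern matching."""

    def __init__(self, postings: Iterable[IndexPosting] = ()):
        self._by_key: dict[IndexKey, IndexPosting] = {}
        self._by_relation: dict[str, list[IndexPosting]] = {}
        for posting in postings:
            self.add(posting)

    def add(self, posting: IndexPosting) -> None:
        if posting.key in self._by_key:
            raise ValueError(f"duplicate index key {posting.key}")
        self._by_key[posting.key] = posting
        self._by_relation.setdefault(posting.key[2], []).append(posting)

    def lookup(self, key: IndexKey) -> IndexPosting | None:
        return self._by_key.get(key)

    def postings_for_relation(self, relation: str) -> list[IndexPosting]:
        return list(self._by_relation.get(relation, ()))

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[IndexPosting]:
        return iter(self._by_key.values())

    @property
    def total_predications(self) -> int:
        return sum(
            len(ids) for p in self._by_key.values() for ids in p.payload.values()
        )


class StorageError(RuntimeError):
    """Raised on referential-integrity violations at insert time."""


_SCHEMA = """
CREATE TABLE IF NOT EXISTS document (
    collection TEXT NOT NULL,
    doc_id TEXT NOT NULL,
    title TEXT NOT NULL,
    abstract TEXT NOT NULL,
    date INTEGER NOT NULL,
    PRIMARY KEY (collection, doc_id)
);
CREATE TABLE IF NOT EXISTS tag (
    collection TEXT NOT NULL,
    doc_id TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    mention TEXT NOT NULL,
    entity_id TEXT NOT NULL,
    entity_type TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS sentence (
    collection TEXT NOT NULL,
    sentence_id TEXT NOT NULL,
    doc_id TEXT NOT NULL,
    text TEXT NOT NULL,
    char_start INTEGER NOT NULL,
    char_end INTEGER NOT NULL,
    PRIMARY KEY (collection, sentence_id, doc_id)
);
CREATE TABLE IF NOT EXISTS predication (
    predication_id INTEGER PRIMARY KEY,
    collection TEXT NOT NULL,
    doc_id TEXT NOT NULL,
    sentence_id TEXT NOT NULL,
    subject_id TEXT NOT NULL,
    subject_type TEXT NOT NULL,
    relation TEXT NOT NULL,
    object_id TEXT NOT NULL,
    object_type TEXT NOT NULL,
    predicate_phrase TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS inverted_index (
    subject_id TEXT NOT NULL,
    subject_type TEXT NOT NULL,
    relation TEXT NOT NULL,
    object_id TEXT NOT NULL,
    object_type TEXT NOT NULL,
    payload TEXT NOT NULL,
    PRIMARY KEY (subject_id, subject_type, relation, object_id, object_type)
);
CREATE INDEX IF NOT EXISTS idx_pred_doc ON predication (collection, doc_id);
CREATE INDEX IF NOT EXISTS idx_inv_relation ON inverted_index (relation);
"""


class Storage:
    """SQLite-backed store for documents, tags, sentences, and predications."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    # -- insertion ---------------------------------------------------------

    def insert_document_graph(
        self,
        doc: Document,
        annotations: Sequence[EntityAnnotation],
        predications: Sequence[Predication],
        sentences: Sequence[SentenceRecord],
        date: int | None = None,
    ) -> dict[str, int]:
        """Insert one document with its graph; re-insertion replaces prior rows.

        Every predication must reference one of the supplied sentences,
        otherwise the whole document is rejected.  Returns per-table counts.
        Documents without a real publication date receive an increasing
        insertion-order date, so result ordering is well defined.
        """
        known_sentences = {s.sentence_id for s in sentences}
        for pred in predications:
            if pred.sentence_id not in known_sentences:
                raise StorageError(
                    f"document {doc.doc_id}: predication references unknown "
                    f"sentence {pred.sentence_id!r}"
                )
            if pred.doc_id != doc.doc_id:
                raise StorageError(
                    f"document {doc.doc_id}: predication belongs to "
                    f"{pred.doc_id!r}"
                )

        cur = self._conn.cursor()
        if date is None:
            row = cur.execute(
                "SELECT date FROM document WHERE collection=? AND doc_id=?",
                (doc.collection, doc.doc_id),
            ).fetchone()
            if row is not None:
                date = row[0]  # keep the original date on re-insert
            else:
                row = cur.execute("SELECT MAX(date) FROM document").fetchone()
                date = (row[0] or 0) + 1
        # Remember ids of the rows being replaced so a re-insert of the same
        # document graph keeps its predication ids (idempotent upsert).
        prior_ids = {
            tuple(row[:6]): row[6]
            for row in cur.execute(
                "SELECT sentence_id, subject_id, subject_type, relation,"
                " object_id, object_type, predication_id FROM predication"
                " WHERE collection=? AND doc_id=?",
                (doc.collection, doc.doc_id),
            )
        }
        for table in ("document", "tag", "sentence", "predication"):
            cur.execute(
                f"DELETE FROM {table} WHERE collection=? AND doc_id=?",
                (doc.collection, doc.doc_id),
            )
        cur.execute(
            "INSERT INTO document VALUES (?,?,?,?,?)",
            (doc.collection, doc.doc_id, doc.title, doc.abstract, date),
        )
        for ann in annotations:
            cur.execute(
                "INSERT INTO tag VALUES (?,?,?,?,?,?,?)",
                (
                    doc.collection,
                    doc.doc_id,
                    ann.start,
                    ann.end,
                    ann.mention,
                    ann.entity.id,
                    ann.entity.type,
                ),
            )
        for sent in sentences:
            cur.execute(
                "INSERT OR REPLACE INTO sentence VALUES (?,?,?,?,?,?)",
                (
                    sent.collection,
                    sent.sentence_id,
                    sent.doc_id,
                    sent.text,
                    sent.char_span[0],
                    sent.char_span[1],
                ),
            )
        ordered = sorted(
            predications,
            key=lambda p: (p.sentence_id, p.subject, p.relation, p.object),
        )
        next_id = (
            cur.execute("SELECT MAX(predication_id) FROM predication").fetchone()[0]
            or 0
        ) + 1
        for pred in ordered:
            pid = pred.predication_id
            if pid is None:
                triple = (
                    pred.sentence_id,
                    pred.subject.id,
                    pred.subject.type,
                    pred.relation,
                    pred.object.id,
                    pred.object.type,
                )
                pid = prior_ids.get(triple)
            if pid is None:
                pid, next_id = next_id, next_id + 1
            pred.predication_id = pid
            cur.execute(
                "INSERT INTO predication VALUES (?,?,?,?,?,?,?,?,?,?)",
                (
                    pid,
                    pred.collection,
                    pred.doc_id,
                    pred.sentence_id,
                    pred.subject.id,
                    pred.subject.type,
                    pred.relation,
                    pred.object.id,
                    pred.object.type,
                    pred.predicate_phrase,
                ),
            )
        self._conn.commit()
        return {
            "documents": 1,
            "tags": len(annotations),
            "sentences": len(sentences),
            "predications": len(predications),
        }

    # -- retrieval ---------------------------------------------------------

    def counts(self) -> dict[str, int]:
        cur = self._conn.cursor()
        return {
            table: cur.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]
            for table in ("document", "tag", "sentence", "predication")
        }

    def document_dates(self) -> dict[DocKey, int]:
        cur = self._conn.execute("SELECT collection, doc_id, date FROM document")
        return {(c, d): date for c, d, date in cur.fetchall()}

    def iter_predications(self) -> Iterator[Predication]:
        cur = self._conn.execute(
            "SELECT predication_id, collection, doc_id, sentence_id, subject_id,"
            " subject_type, relation, object_id, object_type, predicate_phrase"
            " FROM predication ORDER BY predication_id"
        )
        for row in cur:
            yield Predication(
                predication_id=row[0],
                collection=row[1],
                doc_id=row[2],
                sentence_id=row[3],
                subject=Entity(row[4], row[5]),
                relation=row[6],
                object=Entity(row[7], row[8]),
                predicate_phrase=row[9],
            )

    def sentence_text(self, collection: str, sid: str) -> str | None:
        row = self._conn.execute(
            "SELECT text FROM sentence WHERE collection=? AND sentence_id=?",
            (collection, sid),
        ).fetchone()
        return row[0] if row else None

    def predication_by_id(self, predication_id: int) -> Predication | None:
        for pred in self.iter_predications():
            if pred.predication_id == predication_id:
                return pred
        return None

    # -- inverted index ----------------------------------------------------

    def build_inverted_index(self) -> InvertedIndex:
        """(Re)build the triple index from the predication table.

        The index is a pure function of the stored predication multiset; it
        is also persisted to the ``inverted_index`` table with the payload
        serialized as a JSON object mapping document keys to predication-id
        arrays.
        """
        postings: dict[IndexKey, IndexPosting] = {}
        for pred in self.iter_predications():
            posting = postings.setdefault(pred.key, IndexPosting(key=pred.key))
            doc_key = (pred.collection, pred.doc_id)
            posting.payload.setdefault(doc_key, []).append(pred.predication_id)
        for posting in postings.values():
            for ids in posting.payload.values():
                ids.sort()

        cur = self._conn.cursor()
        cur.execute("DELETE FROM inverted_index")
        for key in sorted(postings):
            posting = postings[key]
            payload = {
                f"{c}|{d}": ids for (c, d), ids in sorted(posting.payload.items())
            }
            cur.execute(
                "INSERT INTO inverted_index VALUES (?,?,?,?,?,?)",
                (*key, json.dumps(payload)),
            )
        self._conn.commit()
        return InvertedIndex(postings[k] for k in sorted(postings))

    def load_inverted_index(self) -> InvertedIndex:
        """Load the persisted index (falls back to a rebuild when empty)."""
        cur = self._conn.execute(
            "SELECT subject_id, subject_type, relation, object_id, object_type,"
            " payload FROM inverted_index"
        )
        rows = cur.fetchall()
        if not rows:
            return self.build_inverted_index()
        postings = []
        for *key, payload in rows:
            decoded: dict[DocKey, list[int]] = {}
            for doc_key, ids in json.loads(payload).items():
                collection, _, doc_id = doc_key.partition("|")
                decoded[(collection, doc_id)] = list(ids)
            postings.append(IndexPosting(key=tuple(key), payload=decoded))
        return InvertedIndex(postings)
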