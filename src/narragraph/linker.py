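"""Dictionary-based entity linking and PubTator document I/O.

A document is a title plus an abstract; for linking and extraction both are
concatenated into a single text (``title + " " + abstract``).  The linker
scans the tokenized text left-to-right for the longest vocabulary synonym
starting at each token, which is the standard dictionary-NER convention.
Cleaning removes annotations of stoplisted entities and keeps plant-family
annotations only when a trigger expression (e.g. ``phytotherap*``) occurs
somewhere in the document — plant-family names like *Paris* are otherwise
frequent false links.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .vocab import Entity, EntityVocabulary, normalize_term

__all__ = [
    "Document",
    "EntityAnnotation",
    "CleaningRules",
    "read_pubtator",
    "write_pubtator",
    "link_entities",
    "apply_cleaning_rules",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Document:
    """A title/abstract document; ``text`` is the concatenation of both."""

    doc_id: str
    title: str
    abstract: str = ""
    collection: str = "default"

    @property
    def text(self) -> str:
        if not self.abstract:
            return self.title
        return f"{self.title} {self.abstract}"


@dataclass(frozen=True, order=True)
class EntityAnnotation:
    """An entity mention: character span into ``Document.text`` plus entity.

    Offsets are 0-based and half-open; ``text[start:end] == mention``.
    """

    doc_id: str
    start: int
    end: int
    mention: str
    entity: Entity

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


def read_pubtator(path: str | Path) -> list[tuple[Document, list[EntityAnnotation]]]:
    """Read a PubTator file into documents with their entity annotations.

    Dialect: ``PMID|t|title`` and ``PMID|a|abstract`` lines followed by
    TAB-separated tag lines ``pmid  start  end  mention  type  id``.  Tags
    whose mention does not equal the text slice are dropped with a warning;
    documents missing a title line are skipped with a warning.
    """
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    tags: dict[str, list[tuple[int, int, str, str, str]]] = {}
    order: list[str] = []

    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "|t|" in line and line.split("|t|", 1)[0].count("\t") == 0:
                doc_id, title = line.split("|t|", 1)
                if doc_id not in titles:
                    order.append(doc_id)
                titles[doc_id] = title
            elif "|a|" in line and line.split("|a|", 1)[0].count("\t") == 0:
                doc_id, abstract = line.split("|a|", 1)
                if doc_id not in titles and doc_id not in abstracts:
                    order.append(doc_id)
                abstracts[doc_id] = abstract
            else:
                fields = line.split("\t")
                if len(fields) < 6:
                    logger.warning("skipping malformed tag line: %r", line)
                    continue
                doc_id, start, end, mention, etype, eid = fields[:6]
                tags.setdefault(doc_id, []).append(
                    (int(start), int(end), mention, etype, eid)
                )

    results: list[tuple[Document, list[EntityAnnotation]]] = []
    for doc_id in order:
        if doc_id not in titles:
            logger.warning("document %s has no title line; skipped", doc_id)
            continue
        doc = Document(
            doc_id=doc_id, title=titles[doc_id], abstract=abstracts.get(doc_id, "")
        )
        annotations: list[EntityAnnotation] = []
        for start, end, mention, etype, eid in tags.get(doc_id, ()):
            if doc.text[start:end] != mention:
                logger.warning(
                    "document %s: tag [%d,%d) %r does not match text slice %r; dropped",
                    doc_id,
                    start,
                    end,
                    mention,
                    doc.text[start:end],
                )
                continue
            annotations.append(
                EntityAnnotation(
                    doc_id=doc_id,
                    start=start,
                    end=end,
                    mention=mention,
                    entity=Entity(eid, etype),
                )
            )
        annotations.sort()
        results.append((doc, annotations))
    return results


def write_pubtator(
    path: str | Path,
    documents: Iterable[tuple[Document, Sequence[EntityAnnotation]]],
) -> None:
    """Write documents and annotations in PubTator format (offsets unchanged)."""
    with open(path, "w", encoding="utf-8") as handle:
        for doc, annotations in documents:
            handle.write(f"{doc.doc_id}|t|{doc.title}\n")
            handle.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for ann in sorted(annotations):
                handle.write(
                    f"{doc.doc_id}\t{ann.start}\t{ann.end}\t{ann.mention}"
                    f"\t{ann.entity.type}\t{ann.entity.id}\n"
                )
            handle.write("\n")


_TOKEN = re.compile(r"\w+", re.UNICODE)


def link_entities(
    doc: Document,
    vocabulary: EntityVocabulary,
    min_term_length: int = 3,
    max_tokens: int | None = None,
) -> list[EntityAnnotation]:
    """Link vocabulary terms in ``doc.text`` by longest token-sequence match.

    The text is tokenized at word boundaries; at each token position the
    longest normalized token span found in the vocabulary's term index is
    annotated (one annotation per entity sharing that synonym) and the scan
    resumes after it, so matched spans never overlap.  Terms shorter than
    ``min_term_length`` characters are ignored to suppress spurious
    short-token matches (trade-name noise like "man" or "power").
    """
    text = doc.text
    tokens = [(m.start(), m.end()) for m in _TOKEN.finditer(text)]
    if not tokens:
        return []
    index = vocabulary.term_index()
    if max_tokens is None:
        max_tokens = max((t.count(" ") + 1 for t in index), default=1)

    annotations: list[EntityAnnotation] = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(max_tokens, len(tokens) - i), 0, -1):
            start = tokens[i][0]
            end = tokens[i + n - 1][1]
            term = normalize_term(text[start:end])
            if len(term) < min_term_length:
                continue
            entities = index.get(term)
            if entities:
                mention = text[start:end]
                for entity in sorted(entities):
                    annotations.append(
                        EntityAnnotation(
                            doc_id=doc.doc_id,
                            start=start,
                            end=end,
                            mention=mention,
                            entity=entity,
                        )
                    )
                i += n
                matched = True
                break
        if not matched:
            i += 1
    annotations.sort()
    return annotations


@dataclass
class CleaningRules:
    """Post-linking cleaning configuration.

    ``stoplist`` holds entity ids whose annotations are always removed (the
    manually curated list of frequently mis-linked entities).  Plant-family
    annotations are kept only if at least one ``plant_family_triggers``
    expression matches the document text.
    """

    stoplist: frozenset[str] = frozenset()
    plant_family_triggers: tuple[re.Pattern, ...] = ()
    plant_family_type: str = "PlantFamily"

    @classmethod
    def from_config(
        cls,
        stoplist: Iterable[str] = (),
        trigger_patterns: Iterable[str] = (),
        plant_family_type: str = "PlantFamily",
    ) -> "CleaningRules":
        compiled = []
        for pattern in trigger_patterns:
            try:
                compiled.append(re.compile(pattern, re.IGNORECASE))
            except re.error as err:
                raise ValueError(f"invalid trigger regex {pattern!r}: {err}") from err
        return cls(
            stoplist=frozenset(stoplist),
            plant_family_triggers=tuple(compiled),
            plant_family_type=plant_family_type,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CleaningRules":
        """Load rules from a two-section text file.

        Lines ``stop<TAB>entity_id`` add to the stoplist; lines
        ``trigger<TAB>regex`` add a plant-family trigger expression.
        """
        stop: list[str] = []
        triggers: list[str] = []
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                kind, _, value = line.partition("\t")
                if kind == "stop":
                    stop.append(value.strip())
                elif kind == "trigger":
                    triggers.append(value.strip())
                else:
                    raise ValueError(f"{path}: row {lineno}: unknown rule kind {kind!r}")
        return cls.from_config(stop, triggers)


def apply_cleaning_rules(
    annotations: Iterable[EntityAnnotation],
    doc: Document,
    rules: CleaningRules,
) -> list[EntityAnnotation]:
    """Filter annotations by the stoplist and the plant-family trigger rule.

    Never adds annotations; all non-stoplisted, non-plant-family annotations
    pass through unchanged.
    """
    plant_ok = any(p.search(doc.text) for p in rules.plant_family_triggers)
    kept: list[EntityAnnotation] = []
    for ann in annotations:
        if ann.entity.id in rules.stoplist:
            continue
        if ann.entity.type == rules.plant_family_type and not plant_ok:
            continue
        kept.append(ann)
    return kept
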