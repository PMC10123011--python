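# Methods

## Data model

An entity is a pair `(id, type)` from a controlled vocabulary; a vocabulary
entry adds a preferred name and a synonym set. A statement `(s, p, o)` pairs
two entities with a relation from the closed interaction set Σ (ten
relations by default). The set of statements extracted from one document's
concatenated title + abstract is its document graph. A narrative query graph
is a set of fact patterns whose subject/object slots hold either an entity
set (after term resolution and subclass expansion) or a typed variable node;
a match requires all patterns to hold inside a single document under one
substitution μ, on the assumption that context is stable within an abstract
but not across documents.

## Entity linking

Matching is dictionary-based: the document text is tokenized at word
boundaries and scanned left to right; at each position the longest token
span whose normalized form (lowercase, whitespace-collapsed — no stemming,
which would conflate chemical names) is a vocabulary term is annotated, one
annotation per entity sharing the term. Matched spans never overlap; a
single span may carry entities of several types. Terms shorter than three
characters are ignored (`min_term_length`), suppressing trade-name-style
noise ("man", "power"). Cleaning removes stoplisted entity ids and keeps
plant-family annotations only when one of a configurable list of trigger
regular expressions (e.g. `phytotherap*`) matches the document; both lists
ship as small test defaults and are configuration inputs, since curated
production lists are corpus-specific.

## PathIE extraction

For every sentence with at least two distinct entities, each entity mention
is anchored at the syntactic head of its token span (the token whose head
lies outside the span), and all shortest paths between the two anchors are
computed on the undirected dependency graph (networkx). Every token on any
such path with verbal POS (VERB, and AUX so copula-only paths surface for
canonicalization to reject) contributes a verb phrase — the token plus its
directly attached particles — and every token whose lemma or surface occurs
in the relation vocabulary contributes a keyword statement. When several
equal-length paths exist, the harvested phrases are unioned: the method is
deliberately recall-oriented, and precision is recovered downstream. The
pair is emitted in sentence order (first mention as subject); orientation
is provisional. Parses arrive in CoNLL-U; any external parser can feed the
pipeline by emitting that format, and all tests run on generated parses so
no model download is involved.

## Canonicalization and type rules

A raw predicate maps to a relation by exact lookup of its lowercased phrase
or lemma in the relation vocabulary's synonym terms. If no exact hit exists
and word vectors are supplied (text word2vec format; phrase vector = mean
of in-vocabulary word vectors), the relation whose synonym maximizes cosine
similarity wins, provided the similarity reaches the threshold (default
0.7 — high enough that unrelated verbs rarely pass, low enough to catch
near-synonyms; configurable). Unmapped statements are discarded.

Type handling distinguishes two modes. In **strict** mode a statement
violating its relation's domain/range constraint is removed. In **service**
mode three remapping rules apply instead: a statement touching a
Method/LabMethod entity becomes `method`; otherwise a statement touching a
DosageForm entity becomes `administered`; otherwise a constraint violation
becomes `associated` (the entities are still associated in the sentence).
A constraint satisfied only under the swapped orientation swaps subject and
object first — shortest-path extraction loses direction by design, and the
swap recovers directed relations cheaply. The method ≻ administered ≻
type-check precedence is a deliberate total order (the interaction of the
special rules is otherwise underdetermined); service mode therefore never
changes statement cardinality, only labels. Default constraints:
`treats` Drug/Chemical → Disease/Species, `inhibits` Drug/Chemical → Gene,
`metabolizes` Gene → Drug/Chemical; the remaining relations are general and
unconstrained. All constraints are overridable in the relation-vocabulary
file.

## Storage and index

SQLite holds the document, tag, sentence, and predication tables. Sentences
are keyed by `md5(collection + "|" + text)` — content-addressed so repeated
extraction is idempotent and several statements share one sentence row; the
collection prefix scopes hashes per corpus. Predication surrogate ids are
assigned in sorted triple order at insert, and a re-inserted document reuses
the ids of identical triples, so provenance ids are stable across reruns.
Duplicate extractions collapse to one predication per
(document, sentence, subject, relation, object).

The inverted index maps each distinct (subject id, subject type, relation,
object id, object type) key to a JSON payload grouping supporting
predication ids by document. It is a pure function of the predication
multiset: total payload size equals the number of stored predications, and
lookups are insensitive to insertion order.

## Query processing

Parsing accepts one `subject relation object` triple per line, quoted
multiword terms, `?Name(Type)` variables, and bare type names (which read as
a variable of that type). Unknown relations fail with the allowed Σ; terms
resolving to no entity fail naming the term. Each resolved entity is
replaced by itself plus all transitive subclasses from the taxonomy DAG
(cycles are rejected at load; diamonds are handled set-wise).

Matching evaluates patterns concrete-first, then in ascending candidate-set
size, and joins per document on shared variable names (SPARQL BGP
semantics: one binding per variable name per document match). Each
consistent (document, μ) pair yields one result carrying, per pattern, all
supporting predication ids. Results order by publication date descending
with document-id descending tie-break; fixture documents carry
insertion-order dates, since synthetic corpora have no real publication
dates. Every distinct μ is kept as its own result row — the
substitution-centric aggregation needs them.

## Aggregation

Substitution-centric grouping buckets result documents per substitution
entity of a chosen variable (a document with several substitutions appears
in each bucket), ordered by group size descending (or ascending), ties
broken by entity id. The hierarchical view attaches each bucket at the
entity's position(s) in the taxonomy, propagates counts to ancestors, and
prunes nodes whose subtree holds no documents. Ancestor counts are
**distinct-document** unions, not sums over children, so siblings sharing a
document never double-count; entities absent from the taxonomy collect
under a synthetic `unclassified` root, and multi-parent entities attach at
every position.

## Synthetic corpora

The fixture generator emulates the input formats end to end: an entity
vocabulary of unique pronounceable single-token names (with one synonym
each), a b-ary disease taxonomy, and documents of 2–4 template sentences.
Statement templates are either a transitive-verb sentence
(`<s> treats <o> .`) or a keyword sentence
(`<s> shows the therapy with <o> .`) whose dependency parse is constructed
together with the tokens, so parses are always single-rooted and
token-consistent. Distractor sentences (default rate 0.3; a single-entity
passive or an out-of-vocabulary verb between two entities) produce no gold
statement — the unknown verb is discarded at canonicalization, which is
itself part of what the recovery tests exercise. Participating entity types
per relation are chosen so planted statements survive the type rules
unchanged. Everything derives from one seed; identical seeds give
byte-identical files.

What the generator does **not** emulate: lexical variation and paraphrase,
parser errors, nested/overlapping mentions, abbreviations, cross-sentence
interactions, and realistic corpus statistics. Perfect precision/recall on
these corpora therefore demonstrates that the chain is implemented
correctly (every stage does exactly what it claims on unambiguous input),
not that dictionary linking or PathIE reach that quality on real abstracts
— on real biomedical text both are known to trade precision for coverage.

Gold query answers are computed by a brute-force matcher that enumerates
all substitutions per document — an implementation independent of the
inverted-index engine, so engine-vs-oracle tests compare two separate
routes.

## Problem sizes and numerical choices

The acceptance script uses 20 corpora × 25 queries (≤ 50 documents,
8 entities, 4 relations each) for the engine/oracle comparison, 200
template sentences at distractor rate 0.5 for pipeline recovery, and 500
random trees (≤ 12 tokens) for the path check — sizes at which the
brute-force oracles are exact yet the run completes in seconds. Sentence
splitting assigns inter-sentence whitespace to the preceding span so spans
tile the text exactly. Degenerate inputs behave conservatively: empty
vocabularies and empty corpora are valid, a zero-length path is returned
for identical anchor tokens, disconnected parse fragments yield no path,
and unknown taxonomy ids act as leaves.

## Known limitations

Extraction is sentence-local by construction; no coreference or
abbreviation resolution; no relevance ranking beyond date ordering (a match
is a binary decision); the in-memory index targets desk-scale corpora, not
the multi-hundred-million-statement scale a client-server deployment would
need; embedding-based canonicalization requires externally trained vectors.
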