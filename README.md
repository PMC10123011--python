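# narragraph

Entity-interaction-aware document retrieval with **narrative query graphs**.

Keyword search over biomedical literature forces researchers to phrase an
information need like "which diseases are treated with simvastatin?" as a
bag of unconnected terms. `narragraph` instead transforms each document
(title + abstract) into a **document graph** — a set of canonicalized
statements *(s, p, o)* with *s, o ∈ 𝓔* (a controlled entity vocabulary:
drugs, diseases, genes, dosage forms, …) and *p ∈ Σ* (a closed set of ten
interactions: `associated`, `method`, `compares`, `induces`, `treats`,
`administered`, `decreases`, `interacts`, `inhibits`, `metabolizes`) — and
answers **narrative query graphs**: sets of fact patterns
*fp = (s, p, o)* with *s, o ∈ 𝓔 ∪ 𝓥*, where 𝓥 are typed variable nodes
written `?X(Disease)`. A document matches a query *q* iff all patterns of
*q* hold in that one document under a single substitution
*μ : 𝓥 → 𝓔*, with sentence-level provenance explaining each match.

The extraction chain is nearly unsupervised:

1. **Entity linking** — dictionary lookup of vocabulary synonyms
   (longest-match, left-to-right) plus cleaning rules (an entity stoplist
   and a plant-family trigger-expression filter).
2. **PathIE** — for each sentence mentioning ≥ 2 entities, every verb
   phrase and relation-vocabulary keyword on a shortest dependency path
   between the entity pair yields a raw statement (recall-oriented).
3. **Canonicalization** — raw predicates map to Σ by synonym lookup
   (optionally word-embedding similarity); domain/range type constraints
   repair orientation and remap violations (`associated`), statements
   touching Method/LabMethod entities (`method`), and statements touching
   DosageForm entities (`administered`).
4. **Indexing** — documents, tags, MD5-identified sentences, and
   predications land in an embedded SQLite store; an inverted index maps
   each (subject id, subject type, relation, object id, object type) key
   to per-document predication ids.
5. **Retrieval** — query terms resolve to entity sets, expand by all
   transitive taxonomy subclasses (MeSH/ATC-style DAG), and are matched
   hash-join style against the index; results for variable queries can be
   aggregated substitution-centrically or as a pruned taxonomy tree.

## Worked example

```python
from narragraph.cli import build_store, run_query
from narragraph.fixtures import worked_example

bundle = worked_example()   # "Metformin is the mainstay therapy for type 2 diabetes"
docs = [(d, bundle.annotations[d.doc_id]) for d in bundle.documents]
parses = [s for d in bundle.documents for s in bundle.sentences[d.doc_id]]
storage, totals = build_store(docs, parses, bundle.vocabulary, bundle.relation_vocab)
print(totals)
result = run_query('"Metformin" treats ?X(Disease)', storage,
                   bundle.vocabulary, bundle.relation_vocab)
print(result["results"])
```

prints

```
{'documents': 1, 'annotations': 2, 'sentences': 1, 'raw_statements': 1, 'predications': 1}
[{'collection': 'example', 'document': 'wex1', 'date': 1,
  'substitution': {'X': {'id': 'D003924', 'type': 'Disease'}},
  'provenance': {'0': [1]}}]
```

The keyword *therapy* lies on the dependency path between *Metformin* and
*type 2 diabetes*, is canonicalized to `treats`, and the variable query
binds `μ(?X) = (D003924, Disease)` with predication 1 as provenance — an
extraction a clause-based open-IE system misses, because the copula *is*
cannot be canonicalized.

The same pipeline is scriptable from a shell:

```bash
narragraph fixtures --out corpus --seed 7
narragraph build corpus/corpus.pubtator corpus/corpus.conllu \
    --vocab corpus/vocabulary.tsv --relations corpus/relations.tsv \
    --store graph.db --collection fixture
narragraph query '?X(Drug) treats ?Y(Disease)' --store graph.db \
    --vocab corpus/vocabulary.tsv --relations corpus/relations.tsv \
    --taxonomy corpus/taxonomy.tsv --group-by Y --tree
```

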