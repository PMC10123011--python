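"""Result aggregation for variable queries: substitution groups and trees.

Documents matching a query with variables are aggregated by their variable
substitution: each distinct substitution entity forms a group of documents
(a document with several substitutions appears in each of its groups),
sorted by group size.  The hierarchical view places those groups into the
entity taxonomy (e.g. the MeSH tree): documents attach at their
substitution's node(s), counts propagate to ancestors, and taxonomy nodes
whose subtree holds no documents are pruned away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .query import QueryResult
from .store import DocKey
from .vocab import Entity, Taxonomy

__all__ = [
    "SubstitutionGroup",
    "TreeNode",
    "group_by_substitution",
    "hierarchical_groups",
    "UNCLASSIFIED_ROOT",
]

#: Synthetic root collecting substitution entities absent from the taxonomy.
UNCLASSIFIED_ROOT = "unclassified"


@dataclass(frozen=True)
class SubstitutionGroup:
    """Documents sharing one substitution entity for one variable."""

    variable: str
    entity: Entity
    doc_keys: frozenset[DocKey]

    @property
    def size(self) -> int:
        return len(self.doc_keys)


def _substitution_map(
    results: Sequence[QueryResult], variable: str
) -> dict[Entity, set[DocKey]]:
    groups: dict[Entity, set[DocKey]] = {}
    for result in results:
        if variable not in result.substitution:
            raise KeyError(
                f"variable {variable!r} is not bound by the query results"
            )
        entity = result.substitution[variable]
        groups.setdefault(entity, set()).add(result.doc_key)
    return groups


def group_by_substitution(
    results: Sequence[QueryResult],
    variable: str,
    order: str = "desc",
) -> list[SubstitutionGroup]:
    """Group result documents by their substitution for ``variable``.

    Groups are sorted by document count (descending by default; ascending
    puts rare substitutions first), with a stable tie-break on entity id.
    Groups jointly cover all result documents.
    """
    if order not in ("desc", "asc"):
        raise ValueError(f"order must be 'desc' or 'asc', got {order!r}")
    if not results:
        return []
    groups = [
        SubstitutionGroup(variable=variable, entity=entity, doc_keys=frozenset(docs))
        for entity, docs in _substitution_map(results, variable).items()
    ]
    groups.sort(key=lambda g: g.entity.id)
    groups.sort(key=lambda g: g.size, reverse=(order == "desc"))
    return groups


@dataclass
class TreeNode:
    """A taxonomy node of the hierarchical view.

    ``attached_docs`` are documents whose substitution sits exactly here;
    ``subtree_docs`` is the distinct-document union over the node and all of
    its descendants (so ancestor counts never double-count documents shared
    by sibling branches).
    """

    node_id: str
    attached_docs: set[DocKey] = field(default_factory=set)
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def subtree_docs(self) -> set[DocKey]:
        docs = set(self.attached_docs)
        for child in self.children:
            docs |= child.subtree_docs
        return docs

    def to_dict(self) -> dict:
        return {
            "node": self.node_id,
            "count": len(self.subtree_docs),
            "documents": sorted("|".join(k) for k in self.attached_docs),
            "children": [c.to_dict() for c in self.children],
        }


def hierarchical_groups(
    results: Sequence[QueryResult],
    variable: str,
    taxonomy: Taxonomy,
) -> list[TreeNode]:
    """Build the pruned taxonomy forest over substitution entities.

    Steps: aggregate documents by substitution; attach each document set at
    the entity's taxonomy position(s); propagate distinct-document counts to
    all ancestors; prune every node whose subtree carries no documents.
    Entities with several taxonomy positions attach at all of them; entities
    unknown to the taxonomy are collected under a synthetic ``unclassified``
    root.
    """
    if not results:
        return []
    groups = _substitution_map(results, variable)

    attached: dict[str, set[DocKey]] = {}
    orphans: dict[str, set[DocKey]] = {}
    for entity, docs in groups.items():
        if entity.id in taxonomy:
            attached.setdefault(entity.id, set()).update(docs)
        else:
            orphans.setdefault(entity.id, set()).update(docs)

    # nodes worth keeping: doc-bearing nodes plus their ancestor paths
    needed: set[str] = set(attached)
    for node in attached:
        needed |= taxonomy.ancestors(node)

    def build(node: str) -> TreeNode | None:
        children = [
            built
            for child in sorted(taxonomy.children(node))
            if child in needed and (built := build(child)) is not None
        ]
        tree_node = TreeNode(
            node_id=node,
            attached_docs=set(attached.get(node, set())),
            children=children,
        )
        if not tree_node.subtree_docs:
            return None
        return tree_node

    forest = [
        node
        for root in sorted(taxonomy.roots & needed)
        if (node := build(root)) is not None
    ]
    if orphans:
        forest.append(
            TreeNode(
                node_id=UNCLASSIFIED_ROOT,
                children=[
                    TreeNode(node_id=eid, attached_docs=set(docs))
                    for eid, docs in sorted(orphans.items())
                ],
            )
        )
    return forest
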