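"""Per-document disambiguation graphs.

Nodes are (mention, candidate-concept) pairs; edges join candidates of
*different* mentions that are adjacent in the ontology (kb mode), occur
together in a text-derived relation (corpus mode), or either
(kb_corpus).  Edges between candidates of the same mention are never
created — only one candidate per mention can be the correct link, so
such edges would be pure noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .candidates import CandidateList
from .corpus import RelationSet
from .kb import KnowledgeBase, directly_linked

LINK_MODES = ("kb", "corpus", "kb_corpus")


@dataclass(frozen=True)
class DisambigNode:
    mention_index: int
    concept_id: str
    fixed: bool = False  # exact-match mentions keep their concept


@dataclass
class DisambiguationGraph:
    doc_id: str
    link_mode: str
    nodes: list[DisambigNode] = field(default_factory=list)
    edges: set[frozenset] = field(default_factory=set)  # frozensets of node indices

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for edge in self.edges:
            if i in edge:
                (j,) = edge - {i}
                out.append(j)
        return sorted(out)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.nodes]
        for edge in self.edges:
            i, j = sorted(edge)
            adj[i].append(j)
            adj[j].append(i)
        return [sorted(n) for n in adj]

    def nodes_of_mention(self, mention_index: int) -> list[int]:
        return [i for i, n in enumerate(self.nodes) if n.mention_index == mention_index]


def expand_shared_entity_relations(
    cid_pairs: RelationSet, type_map: dict[str, str] | None = None
) -> RelationSet:
    """Derive same-type relations from chemical–disease interactions.

    Two diseases are related if the same chemical plays a role in both;
    two chemicals are related if they are involved with the same
    disease.  Original pairs are retained; derived pairs carry
    provenance ``derived_shared_entity``.  Entity types come from
    ``type_map`` or, failing that, the relation set's own hints /
    CURIE-prefix heuristics.
    """
    types = dict(cid_pairs.type_hints)
    if type_map:
        types.update(type_map)

    def type_of(cid: str) -> str:
        if cid in types:
            return types[cid]
        if cid.startswith("CHEBI:"):
            return "Chemical"
        raise ValueError(f"cannot resolve entity type of {cid}; supply a type map")

    out = RelationSet(dict(cid_pairs.pairs), types)
    chem_to_dis: dict[str, set[str]] = {}
    dis_to_chem: dict[str, set[str]] = {}
    for pair in cid_pairs.pairs:
        a, b = sorted(pair)
        ta, tb = type_of(a), type_of(b)
        if {ta, tb} != {"Chemical", "Disease"}:
            continue
        chem, dis = (a, b) if ta == "Chemical" else (b, a)
        chem_to_dis.setdefault(chem, set()).add(dis)
        dis_to_chem.setdefault(dis, set()).add(chem)

    for partners in itertools.chain(chem_to_dis.values(), dis_to_chem.values()):
        for x, y in itertools.combinations(sorted(partners), 2):
            out.pairs.setdefault(frozenset((x, y)), "derived_shared_entity")
    return out


def build_graph(
    candidate_lists: list[CandidateList],
    kb: KnowledgeBase,
    relations: RelationSet | None,
    mode: str,
    doc_id: str = "",
) -> DisambiguationGraph:
    """Assemble the disambiguation graph for one document.

    ``candidate_lists`` is indexed by mention position.  One node is
    created per (mention, distinct candidate concept); exact-matched
    mentions contribute a single fixed node, anchoring the walks.  Nodes
    are ordered by (mention_index, concept_id), making the graph fully
    deterministic.
    """
    if mode not in LINK_MODES:
        raise ValueError(f"unknown link mode {mode!r}; expected one of {LINK_MODES}")
    if relations is None:
        relations = RelationSet()

    nodes: list[DisambigNode] = []
    for m_idx, cl in enumerate(candidate_lists):
        canon_ids = set()
        for cid in cl.concept_ids():
            canon = kb.canonical_id(cid)
            if canon not in kb.concepts:
                raise KeyError(f"candidate {cid} absent from knowledge base")
            canon_ids.add(canon)
        for canon in sorted(canon_ids):
            nodes.append(DisambigNode(m_idx, canon, fixed=cl.is_exact))
    nodes.sort(key=lambda n: (n.mention_index, n.concept_id))

    def kb_linked(c1: str, c2: str) -> bool:
        return directly_linked(kb, c1, c2)

    def corpus_linked(c1: str, c2: str) -> bool:
        return c1 != c2 and (c1, c2) in relations

    edges: set[frozenset] = set()
    for i, j in itertools.combinations(range(len(nodes)), 2):
        ni, nj = nodes[i], nodes[j]
        if ni.mention_index == nj.mention_index:
            continue
        linked = False
        if mode in ("kb", "kb_corpus"):
            linked = kb_linked(ni.concept_id, nj.concept_id)
        if not linked and mode in ("corpus", "kb_corpus"):
            linked = corpus_linked(ni.concept_id, nj.concept_id)
        if linked:
            edges.add(frozenset((i, j)))
    return DisambiguationGraph(doc_id=doc_id, link_mode=mode, nodes=nodes, edges=edges)


def edge_hints(
    candidate_lists: list[CandidateList],
    kb: KnowledgeBase,
    relations: RelationSet | None,
) -> dict[str, list[tuple[int, int]]]:
    """Edge lists for the kb and corpus modes, as sorted node-index pairs.

    Node indices follow the same (mention_index, concept_id) ordering as
    :func:`build_graph`, so a graph can later be rebuilt from the hints
    alone; the kb_corpus edge set is their union.
    """
    hints = {}
    for mode in ("kb", "corpus"):
        g = build_graph(candidate_lists, kb, relations, mode)
        hints[mode] = sorted(tuple(sorted(e)) for e in g.edges)
    return hints


def graph_from_hints(
    n_nodes_per_mention: list[list[str]],
    hints: dict[str, list[tuple[int, int]]],
    mode: str,
    doc_id: str = "",
    fixed_mentions: set[int] = frozenset(),
) -> DisambiguationGraph:
    """Rebuild a graph from candidate concept ids and precomputed hints."""
    if mode not in LINK_MODES:
        raise ValueError(f"unknown link mode {mode!r}; expected one of {LINK_MODES}")
    nodes = [
        DisambigNode(m_idx, cid, fixed=m_idx in fixed_mentions)
        for m_idx, cids in enumerate(n_nodes_per_mention)
        for cid in cids
    ]
    pair_source = hints.get("kb", []) + hints.get("corpus", []) if mode == "kb_corpus" else hints.get(mode, [])
    edges = {frozenset(p) for p in pair_source}
    for edge in edges:
        i, j = sorted(edge)
        if j >= len(nodes):
            raise ValueError(f"edge hint ({i},{j}) outside node range 0..{len(nodes) - 1}")
    return DisambiguationGraph(doc_id=doc_id, link_mode=mode, nodes=nodes, edges=edges)
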