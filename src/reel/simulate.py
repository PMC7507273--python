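"""Synthetic knowledge bases and corpora for controlled experiments.

The generator reproduces, at a small and fully seeded scale, the regime
the linking method is designed for: a lexically ambiguous corpus whose
correct concepts are recoverable only through document-level coherence.
A complete branching-tree is-a vocabulary provides the gold concepts;
each gold concept is shadowed by *decoy* concepts whose names sit a
single edit away but which have no is-a relations at all, so nothing in
the ontology structure distinguishes them.  Mention surfaces perturb
the gold name so that gold and decoys tie exactly on lexical score —
string matching then resolves the tie arbitrarily (by concept id, which
decoys win), while the relation set preferentially connects gold
concepts of the same document and lets graph coherence recover them.

Also builds the three-mention worked example in which an exact-matched
chemical anchors two ambiguous neighbours through extracted relations.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .corpus import Document, Mention, RelationSet
from .kb import Concept, KnowledgeBase

_LETTERS = string.ascii_lowercase


@dataclass(frozen=True)
class SynthConfig:
    n_concepts: int = 50
    branching: int = 3
    n_synonyms: int = 1
    n_docs: int = 100
    mentions_per_doc: int = 4
    ambiguity: int = 2  # decoy concepts per gold concept
    relation_coverage: float = 1.0  # P(inject a same-document gold pair)
    perturb_prob: float = 0.7  # P(mention surface is 1 edit off the gold name)
    name_length: int = 8
    seed: int = 7

    def __post_init__(self) -> None:
        if min(self.n_concepts, self.branching, self.n_synonyms,
               self.n_docs, self.mentions_per_doc) < 1:
            raise ValueError("all counts must be >= 1")
        if self.ambiguity < 0:
            raise ValueError("ambiguity must be >= 0")
        if not 0.0 <= self.relation_coverage <= 1.0:
            raise ValueError("relation_coverage must lie in [0, 1]")


def _random_name(rng: np.random.Generator, length: int, taken: set[str]) -> str:
    while True:
        name = "".join(rng.choice(list(_LETTERS), size=length))
        if name not in taken:
            taken.add(name)
            return name


def make_ontology(config: SynthConfig) -> KnowledgeBase:
    """Complete branching-tree vocabulary plus lexical decoys.

    Concept i's parent is concept (i−1)//branching, giving n_concepts−1
    is-a edges.  Every non-root tree concept is a *gold* concept and
    receives ``ambiguity`` decoy concepts: each decoy name substitutes
    one letter of the gold name at a per-concept pivot position, so the
    decoy is exactly one edit from the gold name; decoys carry no is-a
    relations.  Gold ids sort after decoy ids on purpose, so purely
    lexical ties resolve to a decoy.  Deterministic per seed; the gold
    ids, the decoy map and each concept's pivot position are recorded in
    ``kb.metadata``.
    """
    rng = np.random.default_rng(config.seed)
    kb = KnowledgeBase()
    taken: set[str] = set()

    tree_ids = [f"SYNT:1{i:05d}" for i in range(config.n_concepts)]
    names = {}
    for cid in tree_ids:
        name = _random_name(rng, config.name_length, taken)
        names[cid] = name
        synonyms = [_random_name(rng, config.name_length + 2, taken)
                    for _ in range(config.n_synonyms)]
        kb.add_concept(Concept(id=cid, primary_name=name, synonyms=synonyms))
    for i in range(1, config.n_concepts):
        kb.add_relation(tree_ids[i], tree_ids[(i - 1) // config.branching])

    gold_ids = tree_ids[1:]
    decoys: dict[str, list[str]] = {}
    pivots: dict[str, int] = {}
    counter = 0
    for gid in gold_ids:
        gold_name = names[gid]
        pivot = int(rng.integers(0, len(gold_name)))
        pivots[gid] = pivot
        used_letters = {gold_name[pivot]}
        decoys[gid] = []
        for _ in range(config.ambiguity):
            letter = rng.choice([c for c in _LETTERS if c not in used_letters])
            used_letters.add(letter)
            decoy_name = gold_name[:pivot] + letter + gold_name[pivot + 1:]
            if decoy_name in taken:
                continue
            taken.add(decoy_name)
            did = f"SYNT:0{counter:05d}"
            counter += 1
            synonyms = [_random_name(rng, config.name_length + 2, taken)
                        for _ in range(config.n_synonyms)]
            kb.add_concept(Concept(id=did, primary_name=decoy_name, synonyms=synonyms))
            decoys[gid].append(did)

    kb.metadata.update(
        gold_concepts=list(gold_ids),
        decoys=decoys,
        pivots=pivots,
        decoy_letters={gid: [kb.concepts[d].primary_name[pivots[gid]] for d in ds]
                       for gid, ds in decoys.items()},
        root=tree_ids[0],
    )
    return kb


def make_corpus(kb: KnowledgeBase, config: SynthConfig) -> tuple[list[Document], RelationSet]:
    """Documents with gold annotations plus a gold-connecting relation set.

    Each document samples ``mentions_per_doc`` distinct gold concepts.
    With probability ``perturb_prob`` a mention's surface substitutes the
    pivot letter of its gold name with a letter used by no decoy — one
    edit from gold and from every decoy, never an exact match to either;
    otherwise the surface is the gold name itself (exercising the
    exact-match path).  Every same-document gold pair enters the
    relation set independently with probability ``relation_coverage``.
    """
    rng = np.random.default_rng(config.seed + 1)
    gold_ids = kb.metadata["gold_concepts"]
    pivots = kb.metadata["pivots"]
    decoy_letters = kb.metadata["decoy_letters"]

    documents: list[Document] = []
    relations = RelationSet()
    for d in range(config.n_docs):
        chosen = list(rng.choice(gold_ids, size=min(config.mentions_per_doc, len(gold_ids)),
                                 replace=False))
        surfaces = []
        for gid in chosen:
            name = kb.concepts[gid].primary_name
            if rng.random() < config.perturb_prob:
                pivot = pivots[gid]
                banned = set(decoy_letters[gid]) | {name[pivot]}
                letter = rng.choice([c for c in _LETTERS if c not in banned])
                surfaces.append(name[:pivot] + letter + name[pivot + 1:])
            else:
                surfaces.append(name)

        title = "synthetic document %d" % d
        abstract = " ".join(surfaces)
        doc = Document(doc_id=f"SD{d:04d}", title=title, abstract=abstract)
        offset = len(title) + 1
        for gid, surface in zip(chosen, surfaces):
            start = offset
            offset += len(surface) + 1
            doc.mentions.append(
                Mention(doc_id=doc.doc_id, start=start, end=start + len(surface),
                        surface=surface, entity_type="Synthetic", gold_id=gid)
            )
        doc.validate_offsets()
        documents.append(doc)

        for i in range(len(chosen)):
            for j in range(i + 1, len(chosen)):
                if rng.random() < config.relation_coverage:
                    relations.add(chosen[i], chosen[j], "re_tool")
    return documents, relations


def make_fig3_fixture() -> tuple[Document, KnowledgeBase, RelationSet]:
    """Three-mention fixture: an exact-matched anchor rescues two neighbours.

    The document carries the mentions "Cl", "sodium vanate" and
    "sodium deoxycholate".  Only the third matches a knowledge-base name
    exactly (CHEBI:9177); the other two have ambiguous candidate lists
    containing the correct CHEBI:17996 and CHEBI:35607 alongside lexical
    decoys.  No two candidates are adjacent in the ontology, so the
    kb-mode graph is edgeless; the relation set links CHEBI:17996 and
    CHEBI:35607 to the anchor, adding exactly two corpus-mode edges that
    make coherence pick the correct concepts.
    """
    kb = KnowledgeBase()
    concepts = [
        # anchor, exact match for "sodium deoxycholate"
        Concept(id="CHEBI:9177", primary_name="sodium deoxycholate"),
        # correct candidate for "Cl" — chloride
        Concept(id="CHEBI:17996", primary_name="Cl-", synonyms=["chloride"]),
        # lexical decoy for "Cl"; same score as "Cl-", smaller id wins ties
        Concept(id="CHEBI:17603", primary_name="Clx"),
        # correct candidate for "sodium vanate"
        Concept(id="CHEBI:35607", primary_name="sodium vanadate"),
        # lexical decoy for "sodium vanate": one edit from the mention,
        # beating the correct candidate on pure lexical score
        Concept(id="CHEBI:26961", primary_name="sodium banate"),
        # unrelated parent giving the ontology some is-a structure, at
        # path length 2 between anchor and correct candidates
        Concept(id="CHEBI:24866", primary_name="salt"),
    ]
    # Filler concepts crowd each ambiguous mention's lexical neighbourhood
    # so its top-10 candidate list excludes the other mentions' concepts,
    # as it would against a full-size ontology.
    for i, letter in enumerate("abdefghijk"):
        concepts.append(Concept(id=f"CHEBI:9{i:04d}", primary_name=f"C{letter}"))
    for i, letter in enumerate("cdefghij"):
        concepts.append(Concept(id=f"CHEBI:8{i:04d}", primary_name=f"sodium {letter}anate"))
    for c in concepts:
        kb.add_concept(c)
    kb.add_relation("CHEBI:9177", "CHEBI:24866")
    kb.add_relation("CHEBI:35607", "CHEBI:24866")

    title = "synthetic abstract"
    abstract = "Cl sodium vanate sodium deoxycholate"
    doc = Document(doc_id="15630473", title=title, abstract=abstract)
    base = len(title) + 1
    for surface in ("Cl", "sodium vanate", "sodium deoxycholate"):
        start = base + abstract.index(surface)
        doc.mentions.append(
            Mention(doc_id=doc.doc_id, start=start, end=start + len(surface),
                    surface=surface, entity_type="Chemical")
        )
    doc.mentions[0].gold_id = "CHEBI:17996"
    doc.mentions[1].gold_id = "CHEBI:35607"
    doc.mentions[2].gold_id = "CHEBI:9177"
    doc.validate_offsets()

    relations = RelationSet()
    relations.add("CHEBI:17996", "CHEBI:9177", "re_tool")
    relations.add("CHEBI:35607", "CHEBI:9177", "re_tool")
    return doc, kb, relations
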