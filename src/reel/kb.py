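"""Knowledge-base loading and information content.

A knowledge base is the tuple <C, R>: a set of concepts and a set of
is-a relations between them.  Two loaders are provided — OBO ontologies
(ChEBI, MEDIC) and the CTD-Chemicals tab-separated vocabulary — both
producing the same uniform :class:`KnowledgeBase` structure, plus the
extrinsic information-content table used to weight candidate coherence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

_CURIE_RE = re.compile(r"^[^:\s]+:[^:\s]+")


class OboFormatError(ValueError):
    """Raised when an OBO file violates the minimal structure we rely on."""


class KBLookupError(KeyError):
    """Raised when a concept id is not present in the knowledge base."""


def normalize_curie(concept_id: str, default_prefix: str = "MESH") -> str:
    """Return ``concept_id`` as a prefixed CURIE.

    BC5CDR annotation lines carry bare MeSH unique ids (``D003072``);
    internally every id carries its prefix, so bare ids receive
    ``default_prefix``.  Already-prefixed ids pass through unchanged.
    """
    concept_id = concept_id.strip()
    if ":" in concept_id:
        return concept_id
    return f"{default_prefix}:{concept_id}"


@dataclass
class Concept:
    """A single knowledge-base concept.

    ``id`` is a CURIE (``CHEBI:17996``, ``MESH:D003072``); ``synonyms``
    never repeats the primary name (case-folded comparison); obsolete
    concepts stay resolvable by id but are excluded from name search.
    """

    id: str
    primary_name: str
    synonyms: list[str] = field(default_factory=list)
    alt_ids: list[str] = field(default_factory=list)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not _CURIE_RE.match(self.id):
            raise ValueError(f"concept id {self.id!r} is not a CURIE")
        if not self.obsolete and not self.primary_name:
            raise ValueError(f"concept {self.id} has an empty primary name")
        folded = self.primary_name.casefold()
        self.synonyms = [s for s in self.synonyms if s.casefold() != folded]

    @property
    def names(self) -> list[str]:
        return [self.primary_name] + self.synonyms if self.primary_name else list(self.synonyms)


@dataclass
class KnowledgeBase:
    """Concepts C plus directed is-a relations R (child, parent).

    ``name_index`` maps case-folded names and synonyms of non-obsolete
    concepts to the set of ids bearing them; ``alt_index`` canonicalises
    secondary ids.  ``metadata`` is free-form (the synthetic generator
    tags its gold concepts there).
    """

    concepts: dict[str, Concept] = field(default_factory=dict)
    relations: set[tuple[str, str]] = field(default_factory=set)
    name_index: dict[str, set[str]] = field(default_factory=dict)
    alt_index: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add_concept(self, concept: Concept) -> None:
        self.concepts[concept.id] = concept
        for alt in concept.alt_ids:
            self.alt_index[alt] = concept.id
        if concept.obsolete:
            return
        for name in concept.names:
            self.name_index.setdefault(name.casefold(), set()).add(concept.id)

    def add_relation(self, child: str, parent: str) -> None:
        if child == parent:
            raise ValueError(f"self relation on {child}")
        for endpoint in (child, parent):
            if endpoint not in self.concepts:
                raise KBLookupError(endpoint)
        self.relations.add((child, parent))

    def canonical_id(self, concept_id: str) -> str:
        """Resolve alt_ids to the canonical concept id (identity otherwise)."""
        if concept_id in self.concepts:
            return concept_id
        return self.alt_index.get(concept_id, concept_id)

    def __contains__(self, concept_id: str) -> bool:
        return self.canonical_id(concept_id) in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def neighbors(self, concept_id: str) -> set[str]:
        """Concepts at undirected is-a distance exactly 1."""
        cid = self.canonical_id(concept_id)
        if cid not in self.concepts:
            raise KBLookupError(concept_id)
        out = set()
        for child, parent in self.relations:
            if child == cid:
                out.add(parent)
            elif parent == cid:
                out.add(child)
        return out

    def to_digraph(self) -> nx.DiGraph:
        """Child→parent is-a digraph over all concepts."""
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        g.add_edges_from(self.relations)
        return g


def directly_linked(kb: KnowledgeBase, c1: str, c2: str) -> bool:
    """True iff the undirected is-a path length between c1 and c2 is 1.

    A concept is never directly linked to itself.
    """
    c1 = kb.canonical_id(c1)
    c2 = kb.canonical_id(c2)
    for c in (c1, c2):
        if c not in kb.concepts:
            raise KBLookupError(c)
    if c1 == c2:
        return False
    return (c1, c2) in kb.relations or (c2, c1) in kb.relations


_SYNONYM_RE = re.compile(r'^\s*"(.*)"')


def _validate_obo_stanzas(text: str, path: str) -> None:
    # obonet reports no positions; locate [Term] stanzas lacking an id line.
    for match in re.finditer(r"^\[Term\]\s*$", text, flags=re.MULTILINE):
        start = match.end()
        next_stanza = re.search(r"^\[", text[start:], flags=re.MULTILINE)
        body = text[start : start + next_stanza.start()] if next_stanza else text[start:]
        if not re.search(r"^id:", body, flags=re.MULTILINE):
            raise OboFormatError(
                f"{path}: [Term] stanza at byte offset {match.start()} has no id: line"
            )


def load_obo(path: str | Path, prefix_filter: str | None = None) -> KnowledgeBase:
    """Load an OBO 1.2/1.4 ontology into a :class:`KnowledgeBase`.

    Every ``[Term]`` stanza whose id matches ``prefix_filter`` (a CURIE
    prefix such as ``"CHEBI"``; ``None`` keeps everything) becomes a
    concept; ``is_a`` targets become relations; obsolete terms are kept
    in ``concepts`` but left out of the name index.  Only ``is_a`` edges
    are treated as relations — typed ``relationship:`` lines are ignored.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    _validate_obo_stanzas(text, str(path))
    graph = obonet.read_obo(path, ignore_obsolete=False)

    def keep(cid: str) -> bool:
        return prefix_filter is None or cid.startswith(prefix_filter + ":")

    kb = KnowledgeBase()
    for cid, data in graph.nodes(data=True):
        if not keep(cid):
            continue
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            if m:
                synonyms.append(m.group(1))
        kb.add_concept(
            Concept(
                id=cid,
                primary_name=data.get("name", ""),
                synonyms=synonyms,
                alt_ids=list(data.get("alt_id", [])),
                obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
            )
        )
    for cid, data in graph.nodes(data=True):
        if not keep(cid):
            continue
        for parent in data.get("is_a", []):
            parent = parent.split("!")[0].strip()
            if parent in kb.concepts and parent != cid:
                kb.add_relation(cid, parent)
            elif parent not in kb.concepts:
                logger.warning("dropping is_a %s -> %s: parent not loaded", cid, parent)
    return kb


CTD_CHEMICAL_COLUMNS = [
    "ChemicalName",
    "ChemicalID",
    "CasRN",
    "Definition",
    "ParentIDs",
    "TreeNumbers",
    "ParentTreeNumbers",
    "Synonyms",
]


def load_ctd_chemicals_tsv(path: str | Path) -> KnowledgeBase:
    """Load the CTD-Chemicals vocabulary (tab-separated, '#' header lines).

    One concept per row; pipe-separated ``ParentIDs`` become is-a
    relations; pipe-separated ``Synonyms`` populate the synonym list.
    Ids are normalised to ``MESH:Dxxxxxx``.  A parent id absent from the
    file drops that relation with a warning rather than failing.
    """
    import pandas as pd

    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        dtype=str,
        keep_default_na=False,
    )
    if df.shape[1] < len(CTD_CHEMICAL_COLUMNS):
        raise ValueError(
            f"{path}: expected ≥{len(CTD_CHEMICAL_COLUMNS)} columns "
            f"({', '.join(CTD_CHEMICAL_COLUMNS)}), found {df.shape[1]}"
        )
    df.columns = CTD_CHEMICAL_COLUMNS + [
        f"extra_{i}" for i in range(df.shape[1] - len(CTD_CHEMICAL_COLUMNS))
    ]

    kb = KnowledgeBase()
    parents: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        cid = normalize_curie(row.ChemicalID)
        synonyms = [s for s in row.Synonyms.split("|") if s] if row.Synonyms else []
        kb.add_concept(Concept(id=cid, primary_name=row.ChemicalName, synonyms=synonyms))
        for pid in row.ParentIDs.split("|"):
            if pid:
                parents.append((cid, normalize_curie(pid)))
    for child, parent in parents:
        if parent in kb.concepts:
            kb.add_relation(child, parent)
        else:
            logger.warning("dropping relation %s -> %s: parent not in file", child, parent)
    return kb


@dataclass
class ICTable:
    """Extrinsic information content per concept, natural-log units.

    IC(c) = −ln p(c) with p(c) = (n(c)+1) / (N+|C|), where n(c)
    accumulates the external frequency of c and all of its is-a
    descendants.  Add-one smoothing keeps every value finite and
    strictly positive; rarer concepts score higher.
    """

    values: dict[str, float]

    def __getitem__(self, concept_id: str) -> float:
        try:
            return self.values[concept_id]
        except KeyError:
            raise KBLookupError(concept_id) from None

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.values

    @classmethod
    def unit(cls, concept_ids: Iterable[str]) -> "ICTable":
        """IC ≡ 1: reduces IC-weighted coherence to plain PPR coherence."""
        return cls({cid: 1.0 for cid in concept_ids})


def compute_ic(kb: KnowledgeBase, freq: Mapping[str, float] | None = None) -> ICTable:
    """Extrinsic information content for every concept in ``kb``.

    ``freq`` maps concept ids to nonnegative external counts (missing
    ids count 0; ``None`` means the uniform table, all counts 1).
    Counts are accumulated up the is-a DAG with set semantics, so a
    descendant reachable by two paths is counted once.
    """
    import math

    if freq is None:
        freq = {cid: 1.0 for cid in kb.concepts}
    freq = {kb.canonical_id(k): v for k, v in freq.items()}
    for cid, count in freq.items():
        if count < 0:
            raise ValueError(f"negative frequency for {cid}: {count}")

    down = kb.to_digraph().reverse()  # parent -> child
    try:
        order = list(nx.topological_sort(down))
    except nx.NetworkXUnfeasible as exc:
        raise ValueError("cycle detected in is-a relations") from exc

    # Reverse-topological accumulation of descendant-id sets.
    descendants: dict[str, set[str]] = {}
    for cid in reversed(order):
        acc: set[str] = set()
        for child in down.successors(cid):
            acc.add(child)
            acc |= descendants[child]
        descendants[cid] = acc

    total = sum(freq.get(cid, 0.0) for cid in kb.concepts)
    denom = total + len(kb.concepts)
    values = {}
    for cid in kb.concepts:
        n_c = freq.get(cid, 0.0) + sum(freq.get(d, 0.0) for d in descendants[cid])
        values[cid] = -math.log((n_c + 1.0) / denom)
    return ICTable(values)


def read_frequency_tsv(path: str | Path) -> dict[str, float]:
    """Read a two-column ``concept_id<TAB>count`` frequency table."""
    freq: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated fields")
        freq[parts[0]] = float(parts[1])
    return freq


def write_frequency_tsv(freq: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid in sorted(freq):
            fh.write(f"{cid}\t{freq[cid]:g}\n")


def write_obo(kb: KnowledgeBase, path: str | Path) -> None:
    """Serialise a knowledge base as a minimal OBO 1.2 file.

    Emits ``[Term]`` stanzas with id, name, synonym, alt_id, is_a and
    is_obsolete tags; round-trips through :func:`load_obo`.
    """
    parents: dict[str, list[str]] = {}
    for child, parent in sorted(kb.relations):
        parents.setdefault(child, []).append(parent)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for cid in sorted(kb.concepts):
            c = kb.concepts[cid]
            fh.write(f"\n[Term]\nid: {c.id}\nname: {c.primary_name}\n")
            for syn in c.synonyms:
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for alt in c.alt_ids:
                fh.write(f"alt_id: {alt}\n")
            for parent in parents.get(cid, []):
                fh.write(f"is_a: {parent}\n")
            if c.obsolete:
                fh.write("is_obsolete: true\n")
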