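"""Corpus input/output.

Reads annotated corpora in the PubTator dialect (pipe-separated
title/abstract lines, tab-separated annotation lines, optional 4-field
chemical-induced-disease relation lines), relation-extraction output
TSVs, and the per-document candidate files that carry everything needed
to build a disambiguation graph.

Offsets are 0-based half-open over ``title + " " + abstract``; the
readers validate each annotated surface against its text slice and fail
loudly on mismatch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .kb import normalize_curie


class CorpusFormatError(ValueError):
    """Malformed corpus, relation or candidate file."""


@dataclass
class Mention:
    doc_id: str
    surface: str
    entity_type: str = ""
    start: int | None = None
    end: int | None = None
    gold_id: str | None = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and not 0 <= self.start < self.end:
            raise ValueError(f"bad offsets [{self.start}, {self.end}) for {self.surface!r}")


@dataclass
class Document:
    """One corpus document: title, abstract and its entity-mention set E."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    mentions: list[Mention] = field(default_factory=list)

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract if self.abstract else self.title

    def validate_offsets(self) -> None:
        text = self.text
        for m in self.mentions:
            if m.doc_id != self.doc_id:
                raise CorpusFormatError(f"mention doc id {m.doc_id} != document {self.doc_id}")
            if m.start is None:
                continue
            if m.end > len(text):
                raise CorpusFormatError(
                    f"doc {self.doc_id}: offsets [{m.start},{m.end}) beyond text length {len(text)}"
                )
            if text[m.start : m.end] != m.surface:
                raise CorpusFormatError(
                    f"doc {self.doc_id}: surface {m.surface!r} != slice "
                    f"{text[m.start:m.end]!r} at [{m.start},{m.end})"
                )


@dataclass
class RelationSet:
    """Unordered concept-id pairs with a provenance tag per pair.

    Provenances: ``gold_cid`` (annotated chemical-induced-disease
    interactions), ``re_tool`` (relation-extraction output),
    ``derived_shared_entity`` (shared-chemical / shared-disease
    expansion).  ``type_hints`` remembers the entity type of ids seen in
    typed sources, which the shared-entity expansion needs.
    """

    pairs: dict[frozenset, str] = field(default_factory=dict)
    type_hints: dict[str, str] = field(default_factory=dict)

    def add(self, c1: str, c2: str, provenance: str) -> None:
        if c1 == c2:
            raise ValueError(f"self pair {{{c1}}}")
        self.pairs.setdefault(frozenset((c1, c2)), provenance)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __or__(self, other: "RelationSet") -> "RelationSet":
        merged = RelationSet(dict(self.pairs), dict(self.type_hints))
        for pair, prov in other.pairs.items():
            merged.pairs.setdefault(pair, prov)
        merged.type_hints.update(other.type_hints)
        return merged


def _iter_pubtator_blocks(path: str | Path):
    block: list[str] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if raw.strip():
            block.append(raw)
        elif block:
            yield block
            block = []
    if block:
        yield block


def read_pubtator(path: str | Path, id_prefix: str = "MESH") -> list[Document]:
    """Parse a PubTator file into Documents.

    Annotation lines (``PMID<TAB>start<TAB>end<TAB>surface<TAB>type<TAB>id``)
    become mentions with gold ids normalised to prefixed CURIEs
    (``id_prefix`` supplies the prefix for bare MeSH ids).  Composite
    annotations carrying two pipe- or comma-joined gold ids become two
    mentions sharing offsets.  4-field CID relation lines are skipped
    here — see :func:`read_gold_relations`.
    """
    docs: list[Document] = []
    for block in _iter_pubtator_blocks(path):
        doc: Document | None = None
        for line in block:
            if "|t|" in line or "|a|" in line:
                doc_id, kind, text = line.split("|", 2)
                if doc is None:
                    doc = Document(doc_id=doc_id)
                if kind == "t":
                    doc.title = text
                else:
                    doc.abstract = text
                continue
            fields = line.split("\t")
            if doc is None:
                raise CorpusFormatError(f"{path}: annotation before title line: {line!r}")
            if len(fields) == 4 and fields[1] == "CID":
                continue
            if len(fields) < 6:
                raise CorpusFormatError(f"{path}: unrecognised line shape: {line!r}")
            _, start, end, surface, etype, concept_id = fields[:6]
            gold_ids = [g for g in concept_id.replace(",", "|").split("|") if g]
            if not gold_ids:
                gold_ids = ["-1"]
            for gid in gold_ids:
                doc.mentions.append(
                    Mention(
                        doc_id=doc.doc_id,
                        start=int(start),
                        end=int(end),
                        surface=surface,
                        entity_type=etype,
                        gold_id=None if gid == "-1" else normalize_curie(gid, id_prefix),
                    )
                )
        if doc is not None:
            doc.validate_offsets()
            docs.append(doc)
    return docs


def write_pubtator(documents: list[Document], path: str | Path) -> None:
    """Inverse of :func:`read_pubtator` for fixtures and simulation output."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(f"{doc.doc_id}|t|{doc.title}\n")
            fh.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for m in doc.mentions:
                gold = m.gold_id if m.gold_id is not None else "-1"
                fh.write(
                    f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.entity_type}\t{gold}\n"
                )
            fh.write("\n")


def read_gold_relations(path: str | Path, id_prefix: str = "MESH") -> RelationSet:
    """Collect CID lines (``PMID<TAB>CID<TAB>chemID<TAB>diseaseID``) corpus-wide.

    The pair set is pooled over all documents; the chemical/disease roles
    of the ids are remembered in ``type_hints`` for the shared-entity
    expansion.
    """
    rels = RelationSet()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if "|t|" in line or "|a|" in line or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 4:
            if fields[1] != "CID":
                raise CorpusFormatError(f"{path}:{lineno}: expected CID relation line")
            chem = normalize_curie(fields[2], id_prefix)
            dis = normalize_curie(fields[3], id_prefix)
            if chem == dis:
                raise CorpusFormatError(f"{path}:{lineno}: degenerate relation {chem}")
            rels.add(chem, dis, "gold_cid")
            rels.type_hints[chem] = "Chemical"
            rels.type_hints[dis] = "Disease"
    return rels


def read_re_output(path: str | Path) -> RelationSet:
    """Read relation-extraction output: ``doc_id  id1  id2  label`` TSV.

    Only rows labelled ``effect`` contribute pairs; ``noeffect`` rows are
    dropped.  Pairs are unordered and pooled over the whole corpus.
    """
    rels = RelationSet()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise CorpusFormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
        _, c1, c2, label = fields
        if label not in ("effect", "noeffect"):
            raise CorpusFormatError(f"{path}:{lineno}: unknown label {label!r}")
        if label == "effect" and c1 != c2:
            rels.add(normalize_curie(c1), normalize_curie(c2), "re_tool")
    return rels


@dataclass
class CandidateEntry:
    concept_id: str
    matched_name: str
    lexical_score: float
    is_exact: bool


@dataclass
class CandidateRecord:
    """Per-mention block of a candidate file."""

    doc_id: str
    mention_index: int
    surface: str
    entity_type: str = ""
    gold_id: str | None = None
    candidates: list[CandidateEntry] = field(default_factory=list)


@dataclass
class DocumentCandidates:
    """All candidate records of one document plus precomputed edge hints.

    Edge hints are pairs of node indices per link mode, where node index
    i counts (record, candidate) pairs flattened in document order — all
    the information needed to rebuild the disambiguation graph without
    the ontology at ranking time.
    """

    doc_id: str
    records: list[CandidateRecord] = field(default_factory=list)
    edge_hints: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return sum(len(r.candidates) for r in self.records)

    def validate(self) -> None:
        n = self.n_nodes
        for mode, pairs in self.edge_hints.items():
            for i, j in pairs:
                if not (0 <= i < n and 0 <= j < n):
                    raise CorpusFormatError(
                        f"doc {self.doc_id}: edge hint ({i},{j}) in mode {mode} "
                        f"references a node outside 0..{n - 1}"
                    )


def _record_to_json(rec: CandidateRecord) -> dict:
    return {
        "mention_index": rec.mention_index,
        "surface": rec.surface,
        "entity_type": rec.entity_type,
        "gold_id": rec.gold_id,
        "candidates": [
            {
                "concept_id": c.concept_id,
                "matched_name": c.matched_name,
                "lexical_score": c.lexical_score,
                "is_exact": c.is_exact,
            }
            for c in rec.candidates
        ],
    }


def write_candidate_files(doc_candidates: list[DocumentCandidates], out_dir: str | Path) -> list[Path]:
    """One JSON file per document, UTF-8, sorted keys, deterministic."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for dc in doc_candidates:
        dc.validate()
        payload = {
            "doc_id": dc.doc_id,
            "records": [_record_to_json(r) for r in dc.records],
            "edge_hints": {
                mode: [list(p) for p in sorted(pairs)] for mode, pairs in dc.edge_hints.items()
            },
        }
        path = out_dir / f"{dc.doc_id}.json"
        path.write_text(
            json.dumps(payload, indent=1, sort_keys=True, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
        written.append(path)
    return written


def read_candidate_files(in_dir: str | Path) -> list[DocumentCandidates]:
    """Inverse of :func:`write_candidate_files`; validates edge hints."""
    in_dir = Path(in_dir)
    if not in_dir.is_dir():
        raise FileNotFoundError(f"candidate directory {in_dir} does not exist")
    out = []
    for path in sorted(in_dir.glob("*.json")):
        payload = json.loads(path.read_text(encoding="utf-8"))
        records = [
            CandidateRecord(
                doc_id=payload["doc_id"],
                mention_index=r["mention_index"],
                surface=r["surface"],
                entity_type=r.get("entity_type", ""),
                gold_id=r.get("gold_id"),
                candidates=[
                    CandidateEntry(
                        concept_id=c["concept_id"],
                        matched_name=c["matched_name"],
                        lexical_score=c["lexical_score"],
                        is_exact=c["is_exact"],
                    )
                    for c in r["candidates"]
                ],
            )
            for r in payload["records"]
        ]
        dc = DocumentCandidates(
            doc_id=payload["doc_id"],
            records=records,
            edge_hints={
                mode: [tuple(p) for p in pairs]
                for mode, pairs in payload.get("edge_hints", {}).items()
            },
        )
        dc.validate()
        out.append(dc)
    return out
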