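"""Candidate generation.

Each mention receives a ranked list of knowledge-base candidates by
normalised Levenshtein similarity over case-folded, whitespace-collapsed
strings.  A mention that exactly matches a KB name or synonym
short-circuits to a single fixed candidate; otherwise the ten best
distinct concepts are kept and their remaining synonyms appended as
extra entries for the same concepts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib

from .kb import KnowledgeBase

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def fold(s: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return _WS.sub(" ", s.strip()).casefold()


def levenshtein(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def lexical_similarity(a: str, b: str) -> float:
    """1 − d(a,b)/max(|a|,|b|) on folded strings; 1.0 when both empty."""
    fa, fb = fold(a), fold(b)
    longest = max(len(fa), len(fb))
    if longest == 0:
        return 1.0
    return 1.0 - levenshtein(fa, fb) / longest


@dataclass
class Candidate:
    concept_id: str
    matched_name: str
    lexical_score: float
    is_exact: bool = False


@dataclass
class CandidateList:
    """Ranked candidates CL(e) for one mention, best first."""

    surface: str
    entries: list[Candidate] = field(default_factory=list)

    @property
    def is_exact(self) -> bool:
        return bool(self.entries) and self.entries[0].is_exact

    def concept_ids(self) -> list[str]:
        seen, out = set(), []
        for c in self.entries:
            if c.concept_id not in seen:
                seen.add(c.concept_id)
                out.append(c.concept_id)
        return out


def generate_candidates(
    surface: str,
    kb: KnowledgeBase,
    k: int = 10,
    min_score: float | None = None,
) -> CandidateList:
    """Build the ranked candidate list for a surface form.

    An exact (case-insensitive) hit on a concept name or synonym yields a
    single exact candidate and no further ranking.  Otherwise every
    (name-or-synonym, concept) pair of the non-obsolete KB is scored, the
    top ``k`` distinct concepts are retained, and for those concepts any
    additional KB synonyms are appended as further entries for the same
    concept.  Obsolete concepts never enter.  Ties break by higher
    score, then shorter matched name, then lexicographic concept id.
    ``min_score`` optionally floors the admissible similarity (off by
    default).
    """
    if not surface or not surface.strip():
        raise ValueError("empty surface form")
    if k < 1:
        raise ValueError("k must be >= 1")

    folded = fold(surface)
    exact_ids = kb.name_index.get(folded)
    if exact_ids:
        cid = min(exact_ids)
        if len(exact_ids) > 1:
            logger.warning("surface %r exactly matches %d concepts; keeping %s",
                           surface, len(exact_ids), cid)
        concept = kb.concepts[cid]
        matched = next((n for n in concept.names if fold(n) == folded), concept.primary_name)
        return CandidateList(surface, [Candidate(cid, matched, 1.0, is_exact=True)])

    # Best-scoring name per concept over all names and synonyms.
    best: dict[str, tuple[float, int, str]] = {}
    for concept in kb.concepts.values():
        if concept.obsolete:
            continue
        for name in concept.names:
            score = lexical_similarity(surface, name)
            if min_score is not None and score < min_score:
                continue
            key = (score, -len(name))
            cur = best.get(concept.id)
            if cur is None or key > (cur[0], -cur[1]):
                best[concept.id] = (score, len(name), name)

    ranked = sorted(
        best.items(), key=lambda item: (-item[1][0], item[1][1], item[0])
    )[:k]

    entries: list[Candidate] = []
    for cid, (score, _, name) in ranked:
        entries.append(Candidate(cid, name, score))
    # Synonym expansion: remaining names of the selected concepts join the
    # list as extra entries pointing at the same concept.
    for cid, (_, _, best_name) in ranked:
        for name in kb.concepts[cid].names:
            if name == best_name:
                continue
            score = lexical_similarity(surface, name)
            if min_score is not None and score < min_score:
                continue
            entries.append(Candidate(cid, name, score))
    entries.sort(key=lambda c: (-c.lexical_score, len(c.matched_name), c.concept_id, c.matched_name))
    return CandidateList(surface, entries)
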