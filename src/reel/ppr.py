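"""Candidate ranking by IC-weighted Personalized PageRank coherence.

For every node s of the disambiguation graph, a truncated personalized
random walk is started: at each of the 5 steps the walker teleports back
to s with probability 0.2 and otherwise moves to a uniformly random
neighbour (a neighbourless node returns to s).  PPR(s→n) is the
probability of ending at n, estimated either exactly by power iteration
or by endpoint sampling over 2000 independent walks in the Monte-Carlo
fashion of Fogaras.  A node's coherence is the PPR mass it receives
from sources of *other* mentions, weighted by the information content
of its concept; per mention, the candidate of maximal coherence wins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .candidates import CandidateList
from .corpus import DocumentCandidates, Document, RelationSet
from .graph import DisambiguationGraph, build_graph, graph_from_hints
from .kb import ICTable, KnowledgeBase, compute_ic

MODELS = ("string_matching", "ppr_ic", "reel_corpus", "reel_kb_corpus")
_MODEL_MODES = {"ppr_ic": "kb", "reel_corpus": "corpus", "reel_kb_corpus": "kb_corpus"}


@dataclass(frozen=True)
class PPRConfig:
    """Walk parameters: 2000 walks of 5 steps, teleport probability 0.2."""

    n_walks: int = 2000
    n_steps: int = 5
    teleport: float = 0.2
    seed: int = 0
    engine: str = "monte_carlo"  # or "exact"
    estimator: str = "endpoint"  # or "visits"

    def __post_init__(self) -> None:
        if self.n_walks < 1:
            raise ValueError("n_walks must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0.0 < self.teleport < 1.0:
            raise ValueError("teleport must lie in (0, 1)")
        if self.engine not in ("monte_carlo", "exact"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.estimator not in ("endpoint", "visits"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class PPRDistribution:
    source: int
    probs: dict[int, float]

    def __getitem__(self, node: int) -> float:
        return self.probs.get(node, 0.0)


def _check_source(graph: DisambiguationGraph, source: int) -> None:
    if not 0 <= source < graph.n_nodes:
        raise KeyError(f"source {source} not a node of the graph (n={graph.n_nodes})")


def _csr_adjacency(graph: DisambiguationGraph) -> tuple[np.ndarray, np.ndarray]:
    adj = graph.adjacency()
    indptr = np.zeros(len(adj) + 1, dtype=np.int64)
    for i, nbrs in enumerate(adj):
        indptr[i + 1] = indptr[i] + len(nbrs)
    indices = np.fromiter(
        (j for nbrs in adj for j in nbrs), dtype=np.int64, count=int(indptr[-1])
    )
    return indptr, indices


def ppr_exact(graph: DisambiguationGraph, source: int, config: PPRConfig) -> PPRDistribution:
    """Truncated personalized distribution by power iteration.

    p_0 = e_source; p_{t+1} = ε·e_source + (1−ε)·p_t·W, with W the
    row-stochastic transition over undirected edges and a neighbourless
    node transitioning to the source with probability 1.  Returns p_T
    after T = n_steps iterations.
    """
    _check_source(graph, source)
    n = graph.n_nodes
    adj = graph.adjacency()
    eps = config.teleport
    p = np.zeros(n)
    p[source] = 1.0
    visits = np.zeros(n)
    for _ in range(config.n_steps):
        moved = np.zeros(n)
        for i in range(n):
            if p[i] == 0.0:
                continue
            nbrs = adj[i]
            if nbrs:
                share = p[i] / len(nbrs)
                for j in nbrs:
                    moved[j] += share
            else:
                moved[source] += p[i]
        p = (1.0 - eps) * moved
        p[source] += eps
        visits += p
    if config.estimator == "visits":
        p = visits / config.n_steps
    return PPRDistribution(source, {i: float(p[i]) for i in range(n) if p[i] > 0.0})


def ppr_monte_carlo(
    graph: DisambiguationGraph,
    source: int,
    config: PPRConfig,
    rng: np.random.Generator | None = None,
) -> PPRDistribution:
    """Monte-Carlo PPR by independent fixed-length walks.

    Simulates ``n_walks`` walks of exactly ``n_steps`` steps from the
    source; each step teleports home with probability ε, else moves to a
    uniform neighbour (home if none).  With the default ``endpoint``
    estimator, probs(n) = #walks ending at n / n_walks — an unbiased
    estimate of the truncated distribution :func:`ppr_exact` computes.
    The ``visits`` estimator averages occupancy over all steps instead.
    """
    _check_source(graph, source)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    indptr, indices = _csr_adjacency(graph)
    deg = (indptr[1:] - indptr[:-1]).astype(np.int64)

    current = np.full(config.n_walks, source, dtype=np.int64)
    counts = np.zeros(graph.n_nodes, dtype=np.int64)
    for _ in range(config.n_steps):
        jump = rng.random(config.n_walks) < config.teleport
        pick = rng.random(config.n_walks)
        d = deg[current]
        dangling = d == 0
        step_idx = indptr[current] + np.minimum((pick * np.maximum(d, 1)).astype(np.int64),
                                                np.maximum(d - 1, 0))
        moved = indices[np.minimum(step_idx, len(indices) - 1)] if len(indices) else current
        nxt = np.where(dangling, source, moved)
        current = np.where(jump, source, nxt)
        if config.estimator == "visits":
            counts += np.bincount(current, minlength=graph.n_nodes)
    if config.estimator == "endpoint":
        counts = np.bincount(current, minlength=graph.n_nodes)
        total = config.n_walks
    else:
        total = config.n_walks * config.n_steps
    return PPRDistribution(
        source, {i: counts[i] / total for i in np.nonzero(counts)[0].tolist()}
    )


def ppr_all_sources(
    graph: DisambiguationGraph,
    config: PPRConfig,
    seed_seq: np.random.SeedSequence | None = None,
) -> dict[int, PPRDistribution]:
    """One distribution per source node, with per-source derived seeds."""
    out = {}
    for s in range(graph.n_nodes):
        if config.engine == "exact":
            out[s] = ppr_exact(graph, s, config)
        else:
            if seed_seq is not None:
                rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=seed_seq.entropy, spawn_key=(*seed_seq.spawn_key, s)))
            else:
                rng = np.random.default_rng(np.random.SeedSequence([config.seed, s]))
            out[s] = ppr_monte_carlo(graph, s, config, rng=rng)
    return out


@dataclass
class CoherenceTable:
    scores: dict[int, float]

    def __getitem__(self, node: int) -> float:
        return self.scores.get(node, 0.0)


def coherence_scores(
    graph: DisambiguationGraph,
    ppr_all: dict[int, PPRDistribution],
    ic: ICTable,
) -> CoherenceTable:
    """IC-weighted coherence of every node.

    Coherence(n) = Σ_{s: mention(s) ≠ mention(n)} PPR(s→n) · IC(concept(n)).
    Sources competing for n's own mention — n itself included — are
    excluded: at most one candidate per mention is correct, so mass from
    rivals is not evidence.
    """
    scores: dict[int, float] = {}
    for n_idx, node in enumerate(graph.nodes):
        weight = ic[node.concept_id]
        total = 0.0
        for s_idx, dist in ppr_all.items():
            if graph.nodes[s_idx].mention_index == node.mention_index:
                continue
            total += dist[n_idx] * weight
        scores[n_idx] = total
    return CoherenceTable(scores)


@dataclass
class LinkingResult:
    doc_id: str
    model: str
    assignments: dict[int, str | None] = field(default_factory=dict)


def disambiguate_document(
    graph: DisambiguationGraph,
    coherence: CoherenceTable,
    candidate_lists: list[CandidateList],
    doc_id: str = "",
    model: str = "",
) -> LinkingResult:
    """Pick the maximal-coherence candidate per mention.

    Exact-matched mentions keep their fixed concept; a mention whose
    candidates all score zero (e.g. an edgeless graph) falls back to
    lexical order; empty candidate lists yield NIL.  Coherence ties
    break by lexical score, then concept id.
    """
    best_lex: dict[tuple[int, str], float] = {}
    for m_idx, cl in enumerate(candidate_lists):
        for c in cl.entries:
            key = (m_idx, c.concept_id)
            if c.lexical_score > best_lex.get(key, -1.0):
                best_lex[key] = c.lexical_score

    result = LinkingResult(doc_id=doc_id, model=model)
    for m_idx, cl in enumerate(candidate_lists):
        if not cl.entries:
            result.assignments[m_idx] = None
            continue
        if cl.is_exact:
            result.assignments[m_idx] = cl.entries[0].concept_id
            continue
        node_ids = graph.nodes_of_mention(m_idx)
        scored = [
            (coherence[i],
             best_lex.get((m_idx, graph.nodes[i].concept_id), 0.0),
             graph.nodes[i].concept_id)
            for i in node_ids
        ]
        if not scored or all(s[0] == 0.0 for s in scored):
            result.assignments[m_idx] = cl.entries[0].concept_id
            continue
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        result.assignments[m_idx] = scored[0][2]
    return result


def _link_one_document(
    candidate_lists: list[CandidateList],
    graph: DisambiguationGraph,
    ic: ICTable,
    config: PPRConfig,
    doc_id: str,
    model: str,
    seed_seq: np.random.SeedSequence | None,
) -> LinkingResult:
    ppr = ppr_all_sources(graph, config, seed_seq=seed_seq)
    coh = coherence_scores(graph, ppr, ic)
    return disambiguate_document(graph, coh, candidate_lists, doc_id=doc_id, model=model)


def string_match_document(candidate_lists: list[CandidateList], doc_id: str) -> LinkingResult:
    """Baseline: top lexical candidate per mention, NIL when empty."""
    result = LinkingResult(doc_id=doc_id, model="string_matching")
    for m_idx, cl in enumerate(candidate_lists):
        result.assignments[m_idx] = cl.entries[0].concept_id if cl.entries else None
    return result


def run_model(
    documents: list[Document],
    kb: KnowledgeBase,
    relations: RelationSet | None,
    ic: ICTable | None,
    model: str,
    config: PPRConfig | None = None,
    top_k: int = 10,
) -> list[LinkingResult]:
    """End-to-end linking of a corpus with one of the four models.

    ``string_matching`` takes the top lexical candidate; the three PPR
    models share the coherence pipeline and differ only in link mode —
    kb (``ppr_ic``), corpus (``reel_corpus``) or their union
    (``reel_kb_corpus``).  ``ic=None`` computes the uniform-frequency
    table from the knowledge base.
    """
    from .candidates import generate_candidates

    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    config = config or PPRConfig()
    if ic is None:
        ic = compute_ic(kb)

    results = []
    root_seq = np.random.SeedSequence(config.seed)
    for d_idx, doc in enumerate(documents):
        cls = [generate_candidates(m.surface, kb, k=top_k) for m in doc.mentions]
        if model == "string_matching":
            results.append(string_match_document(cls, doc.doc_id))
            continue
        graph = build_graph(cls, kb, relations, _MODEL_MODES[model], doc_id=doc.doc_id)
        doc_seq = np.random.SeedSequence(entropy=root_seq.entropy, spawn_key=(d_idx,))
        results.append(
            _link_one_document(cls, graph, ic, config, doc.doc_id, model, doc_seq)
        )
    return results


def run_model_from_candidates(
    doc_candidates: list[DocumentCandidates],
    ic: ICTable | None,
    model: str,
    config: PPRConfig | None = None,
) -> list[LinkingResult]:
    """Link from pre-computed candidate files (no knowledge base needed).

    Graphs are rebuilt from the files' edge hints; with ``ic=None`` every
    concept weighs 1 (plain PPR coherence).
    """
    from .candidates import Candidate, CandidateList

    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    config = config or PPRConfig()

    results = []
    root_seq = np.random.SeedSequence(config.seed)
    for d_idx, dc in enumerate(doc_candidates):
        cls = [
            CandidateList(
                rec.surface,
                [Candidate(c.concept_id, c.matched_name, c.lexical_score, c.is_exact)
                 for c in rec.candidates],
            )
            for rec in dc.records
        ]
        if model == "string_matching":
            results.append(string_match_document(cls, dc.doc_id))
            continue
        # Same (mention_index, concept_id) node ordering as the hint writer.
        per_mention = [sorted(set(cl.concept_ids())) for cl in cls]
        fixed = {i for i, cl in enumerate(cls) if cl.is_exact}
        graph = graph_from_hints(per_mention, dc.edge_hints, _MODEL_MODES[model],
                                 doc_id=dc.doc_id, fixed_mentions=fixed)
        table = ic if ic is not None else ICTable.unit(
            {n.concept_id for n in graph.nodes}
        )
        doc_seq = np.random.SeedSequence(entropy=root_seq.entropy, spawn_key=(d_idx,))
        results.append(
            _link_one_document(cls, graph, table, config, dc.doc_id, model, doc_seq)
        )
    return results
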