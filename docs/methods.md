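# Methods

## Problem and model

Named-entity linking (normalisation) maps each entity mention *e* in a
document to the knowledge-base concept that denotes it. A knowledge
base here is a pair ⟨C, R⟩: concepts with names/synonyms and directed
is-a relations. Purely lexical linking — pick the concept whose name
minimises edit distance to the mention — ignores document context and
fails on ambiguous surface forms. This package implements a collective
(global) approach: all mentions of a document are disambiguated
jointly, through a *disambiguation graph* whose nodes are
(mention, candidate) pairs and whose edges carry evidence that two
candidates belong together.

Edges are added under three link modes:

- **kb** — candidates are adjacent in the ontology (undirected is-a
  distance exactly 1);
- **corpus** — the candidate pair occurs in a relation extracted from
  text (a relation-extraction tool's `effect` classifications, or
  annotated chemical-induced-disease interactions), pooled over the
  whole corpus;
- **kb_corpus** — the union of both edge sets on the same nodes.

Candidates competing for the same mention are never connected: at most
one of them is the correct link, so such edges are noise by
construction. From annotated chemical–disease interactions, additional
same-type pairs can be derived: two diseases are related when the same
chemical plays a role in both, and symmetrically for chemicals sharing
a disease.

Candidates are scored by Personalized-PageRank coherence. For a source
node *s*, PPR(s→n) is the probability that a teleporting random walk
from *s* is at *n* after T steps; a node's coherence is

    Coherence(n) = Σ_{s : mention(s) ≠ mention(n)} PPR(s→n) · IC(concept(n))

and each mention links to its candidate of maximal coherence. IC is
the extrinsic information content −ln p(c), where p(c) is the smoothed
probability of observing c or any of its is-a descendants in an
external frequency table — rare concepts weigh more, which
counteracts the walk's bias toward structurally central concepts.

Four model variants share this pipeline: `string_matching` (top
lexical candidate, the local baseline), `ppr_ic` (kb edges only),
`reel_corpus` (extracted-relation edges only) and `reel_kb_corpus`
(union). The package's central claim, which the synthetic study
exercises, is that relation edges rescue documents whose kb-mode
graphs are too sparse for the walk to express any preference.

## Candidate generation

Similarity is the normalised Levenshtein ratio
`1 − d(a,b) / max(|a|,|b|)` over case-folded, whitespace-collapsed
strings (edit distance via edlib). A mention that equals a name or
synonym exactly (case-insensitive) short-circuits to that single
candidate, marked *fixed*: it still joins the graph, where it acts as
an anchor for its neighbours. Otherwise every (name-or-synonym,
concept) pair is scored, the best ten distinct concepts are kept, and
the remaining synonyms of those concepts are appended as extra entries
for the same concepts (they matter only for bookkeeping — graph nodes
are deduplicated per (mention, concept)). Obsolete concepts never
enter candidate lists, but gold ids pointing at them still resolve.
There is no similarity floor by default (an optional `min_score`
exists); mentions with no valid candidate link to NIL and count as
false negatives.

Ties are broken deterministically everywhere: candidates by (higher
score, shorter matched name, lexicographic id); coherence by (higher
score, higher lexical score, lexicographic id). An exact surface
matching several concepts resolves to the lexicographically smallest
id, with a warning.

## Walk engines and parameters

The estimand is the T-step truncated personalized distribution

    p_0 = e_s,   p_{t+1} = ε·e_s + (1−ε)·p_t·W,

with W the row-stochastic transition over undirected edges and a
neighbourless node transitioning to the source with probability 1
(keeping the chain stochastic). Defaults: T = 5 steps, teleport
ε = 0.2, and 2000 independent walks per source for the Monte-Carlo
engine, which simulates the chain directly and estimates p_T by
endpoint frequency — an unbiased estimator that converges to the exact
power-iteration engine (`engine="exact"`, kept as the reference
oracle). A `visits` estimator (occupancy averaged over steps) is also
exposed, since endpoint counting is only one reasonable reading of a
walk-based estimate; `endpoint` is the default because it estimates
exactly the truncated distribution the oracle computes. On a two-node
graph the recurrence gives PPR(s→n) = 0.59008 after five steps, used
as a closed-form regression value.

All randomness flows from a single user seed through numpy
`SeedSequence` spawning, one child per (document, source node), so
results are deterministic and independent of iteration order.

If every candidate of a mention scores zero coherence (typically an
edgeless graph), the mention falls back to lexical order, making every
PPR variant degrade exactly to `string_matching` — the behaviour the
degeneracy tests pin down.

## Information content

IC(c) = −ln((n(c)+1)/(N+|C|)) with n(c) the frequency of c plus all
its is-a descendants (set semantics: a descendant reachable twice is
counted once), N the total frequency mass and |C| the concept count.
Add-one smoothing keeps every value finite and strictly positive and
gives unobserved leaves the maximal IC. With no frequency table, all
counts default to 1, so IC degrades to a structure-only weight and
the coherence ranking remains well defined. Frequencies are read from
a two-column `concept_id<TAB>count` TSV.

## Synthetic data: what it emulates, and what it does not

The generator builds a complete branching-tree vocabulary
(defaults: 50 concepts, branching 3, one synonym each; random 8-letter
names) in which every non-root concept is a potential gold concept.
Each gold concept is shadowed by `ambiguity` decoys whose names
substitute one letter at a per-concept pivot position and which carry
*no* is-a relations. Documents (default 100, 4 mentions each) sample
distinct gold concepts; with probability 0.7 a mention's surface
substitutes the pivot letter with one no decoy uses — putting the
surface at edit distance 1 from the gold name *and* from every decoy
name, never equal to either — and otherwise keeps the exact gold name,
exercising the short-circuit path. Same-document gold pairs enter the
relation set independently with probability `relation_coverage`.

The tie construction is deliberate: gold and decoys receive identical
lexical scores, and decoy ids sort first, so the lexical baseline
reliably picks a decoy while the relation edges (decoys being
graph-isolated) make the gold candidate the only coherent choice.
This isolates the mechanism under test — relations rescuing sparse
graphs — rather than testing lexical robustness.

What the generator does not emulate: natural language context,
abbreviations and acronyms, relation-extraction errors beyond the
coverage parameter, realistic name morphology, and vocabulary scale.
The scale point has a visible consequence: with 50 concepts and no
similarity floor, the ten-deep candidate lists pad with lexically
distant concepts, occasionally including another same-document gold
concept — against a full-size ontology these paddings would be crowded
out by near names. Passing the synthetic study therefore demonstrates
the coherence mechanism and the engine contracts, not corpus-level
accuracy on real data.

## Problem sizes used by the test suite and acceptance script

Engine agreement runs 10 random graphs of up to 12 nodes at edge
probability 0.4 with 50 000 walks per source (total-variation distance
against the exact engine ≤ 0.02); the closed-form two-node check uses
200 000 walks. The synthetic study uses the generator defaults above
(400 mentions over 100 documents). These sizes keep the full suite in
well under a minute of compute while leaving the Monte-Carlo
tolerances many standard errors wide.

## Known limitations and observed behaviour

- On the synthetic study, adding ontology edges on top of relation
  edges (`reel_kb_corpus`) measures slightly *below* `reel_corpus`
  (micro-precision 83.0 vs 83.25 at seed 1 of the acceptance script):
  ontology edges between padding candidates occasionally lend
  coherence to a wrong candidate. The same inversion appears in
  published evaluations of this model family on disease corpora, so it
  is treated as a real property of the method at small vocabulary
  scale, not an implementation artifact; both directions of flip occur
  and the net effect is fractions of a point.
- Truncated (5-step) PPR is not stationary PageRank; scores depend on
  T, and the two estimators can rank asymmetric graphs differently.
- Relation pooling is corpus-global: a relation extracted anywhere
  contributes edges in every document (a per-document option exists on
  the shared-entity expansion path). This matches the intent of
  densifying sparse graphs but can import cross-document noise.
- Only is-a relations are read from ontologies; typed relationships
  (e.g. chemical roles) are ignored, which thins kb-mode graphs for
  chemistry vocabularies.
- Evaluation deduplicates by case-folded surface within a document and
  counts each gold id of a composite annotation as its own unit; a
  mention can therefore contribute both a true positive and a false
  positive when annotated with two gold ids.
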