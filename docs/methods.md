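# Methods

## Model of an ontology

The package approximates an ontology as a conceptualization {C, R, I}:
a set of classes C, relation types R, and instances I, organized around a
taxonomy — a rooted directed acyclic graph of *isA* (subsumption) edges
over lemma-normalized term keys.  The root is always the universal concept
`Thing`.  A node may specialize several broader concepts, so the structure
is a DAG, not a tree.  Taxonomy leaves are treated as instances (they have
no children, hence are the lowest-level concepts); non-leaf nodes,
including the root, are classes.  A knowledge graph over this schema is a
set of subject–predicate–object triples whose endpoints are vocabulary
concepts, plus the instance-of links induced by leaf-parent edges.

This is deliberately a computational approximation: no description-logic
axioms, no upper-level ontology alignment, no reasoning.  The goal is a
structure good enough for organization and graph-based retrieval that can
be extracted automatically.

## Pipeline assumptions and mechanics

**Verification, not trust.** The text backend is assumed unreliable.  Every
proposed surface form and acronym pair is checked against the source text
(case-folded, hyphen→space, whitespace-collapsed matching by default; an
exact-substring mode exists) and discarded on failure.  This yields a hard
guarantee — no surface form in the vocabulary is absent from its source
papers — at the price of missing terms the backend paraphrases.

**Lemmatization.** Surface forms reduce to lemma keys by punctuation
removal, case folding, and a deterministic rule-based English inflection
normalizer (suffix rules plus a small irregular table: *gases→gas*,
*analyses→analysis*, …).  The function is idempotent, which the test suite
property-checks; rare irregular plurals outside the table normalize to a
stable but imperfect root, which only costs a merge opportunity, never a
false merge of distinct planted terms.

**Incremental placement.** Taxonomy construction makes K full corpus
passes.  A pair (s, t) is accepted only if s is already a taxonomy node and
t is in the querying paper's vocabulary; accepted pairs insert as
(child = t, parent = s) through a cycle guard (reachability check before
insertion, full topological audit after each pass).  Pairs are inserted in
a canonical order (children already present first, then lexicographic) so
runs are reproducible regardless of backend set ordering.  A term already
placed that is proposed under a second parent gains an additional edge —
re-parenting and pruning are deliberately out of scope.  Terms never placed
after K passes are reported, not force-attached.  K is always honored; the
per-iteration growth statistics let a user judge convergence.

**Self-consistency.** Sampled roles aggregate m responses by strict
majority (> m/2), m odd enforced.  The threshold is configurable; strict
majority is the default because it gives the clean binomial calibration:
an item with per-sample probability p survives with P(Bin(m, p) > m/2).
The planted backend's hallucination model draws spurious candidates from a
pool that depends on the request but not the sample index — the regime in
which voting provably suppresses them; if each sample invented fresh items,
majority voting would remove them trivially and calibration would be
untestable.

## Tunable parameters

| Parameter | Meaning | Default | Why |
|---|---|---|---|
| K | corpus passes in taxonomy construction | 3 | matches the observed plateau on staged worlds of depth 4 (level 1 is seeded by categories) |
| m | self-consistency samples per query | 3 | smallest odd m with real voting; raise to 9 for noisy backends |
| S_G | category generation samples (shuffled orders) | 5 | enough distinct permutations for order-robustness on small corpora |
| S_R | category refinement runs (majority-voted) | 3 | odd, small; refinement answers are near-deterministic given the samples |
| matching | verification mode | normalized | hyphenation variants denote the same term |
| vote threshold | majority cutoff | 0.5 (strict) | binomial calibration; configurable |

Planted-world generator (the study conditions for all recovery tests):
depth 4, mean branching 3, ~60 terms, 12 papers, 6 isA assertions per
paper, coverage 1.0, multi-parent rate 0 (tree) unless a test exercises
DAG recovery, noise rates 0.  Facts are distributed `by_level` — each
paper asserts edges of exactly one hierarchy depth and papers are ordered
deepest-first — because that is the adversarial schedule for incremental
placement: each pass can attach only one further level, so recovery
genuinely requires the iterations rather than succeeding in one pass.

## What the synthetic corpus does and does not emulate

It emulates: per-paper partial views of the hierarchy, spelling variation
(plural/title-case/hyphenated surfaces of one concept), acronym
definitions, relation statements, configurable omission and hallucination
noise, and partial corpus coverage.  It does not emulate free prose,
negation, hedged or context-dependent claims, ambiguous term placement, or
semantically redundant near-synonyms.  Passing recovery tests therefore
demonstrates that the *mechanics* — verification, voting, incremental
guarded insertion, evaluation — are correct, not that a live model would
reconstruct a real field's ontology at any particular accuracy; real-corpus
accuracy depends on the backend model and is outside what an offline suite
can certify.

## Metric definitions and numerical choices

All hierarchical metrics average over ground-truth root paths, so a
multi-parent node contributes once per path.  Conventions (each a config
switch on `MetricsConfig`):

- path node sets exclude the root and include the endpoint;
- an unmatched ground-truth path contributes recall 0;
- precision averages per matched path (macro); a micro variant divides the
  summed overlap by the summed matched-path sizes;
- the ancestor error counts symmetric discrepancies; a one-sided
  (missing-only) variant exists;
- path matching maximizes shared-node count with ties broken toward the
  shorter path, then the lexicographically smaller node sequence — fully
  deterministic.

Under the defaults a matched path always shares its endpoint, so
hierarchical accuracy reduces to the path-multiplicity-weighted fraction of
ground-truth terms present in the reconstruction — the reading under which
hierarchical accuracy tracks term accuracy closely, which is the observed
behaviour of these metrics in practice and is property-checked in the test
suite.  In a DAG "the" lowest common ancestor is a set (deepest common
ancestors, a node counting as its own ancestor); LCA preservation asks that
the ground-truth and reconstructed sets intersect, and is vacuously 1 when
fewer than two non-root nodes exist.  Degenerate inputs: a root-only
reconstruction scores 0 recall/accuracy with zero matched paths (precision
reported as 0, not NaN); identical taxonomies score exactly 1.0 everywhere
with zero ancestor error.

## Design choices that were genuinely open

- **Edge orientation**: backend pairs (s, t) store as (child = t,
  parent = s), since s is required to exist in the taxonomy and the goal is
  to place new terms under existing ones (top-down construction).
- **Root as a class**: the root is never an instance even in a root-only
  taxonomy; classes = non-leaves including the root, so classes and
  instances partition the node set.
- **Acronyms as aliases**: an acronym never becomes a taxonomy node; its
  lemma resolves to the expansion's entry everywhere (including relation
  endpoints).
- **Duplicate edges and triples** are idempotent no-ops; only exact
  duplicates deduplicate — near-synonymous predicates are kept distinct.
- **Canonical serialization** sorts nodes and edges lexicographically so
  run artifacts diff cleanly and end-to-end digests are stable.
- **Refinement input**: the refinement prompt receives the raw sample
  lists (not frequency summaries); the planted refiner ranks by frequency
  itself, and both forms are available in the payload.
- **Checkpointing**: stage artifacts are the checkpoint; `resume` reloads
  any stage whose artifact exists.  Mid-stage checkpointing was judged not
  worth the complexity at these corpus sizes.

## Problem sizes

Default test and acceptance runs use worlds of ≤ 61 nodes, 12-paper
corpora (100 papers for the adversarial vocabulary audit), 200 random DAG
pairs of ≤ 12 nodes for oracle equivalence, 10⁴ candidate edges for the
cycle-guard fuzz, and 2000 trials for the voting calibration.  These sizes
were chosen so every stochastic check has comfortable statistical margin
(±0.03 on a 0.90 binomial mean at n = 2000) while the whole suite stays
interactive.

## Known limitations

- The rule-based lemmatizer is English-only and intentionally small;
  irregular plurals outside its table do not merge with their singulars.
- The live backend's line-delimited parser is tolerant but minimal; it is
  exercised only through its parsing unit, not against a real endpoint.
- Vocabulary verification is substring-based: a term mentioned only inside
  a longer term's span still verifies.
- Hierarchical precision does not penalize extra correct-but-absent
  structure in the reconstruction beyond path dilution; this is by design
  (extra knowledge is not an error) but means precision alone cannot detect
  bloat — the ancestor error count covers that.
- The category stage's character budget truncates papers lead-first;
  corpora whose category-bearing content sits late in each document would
  need a different sectioning rule.
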