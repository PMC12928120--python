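"""Stage 3: incremental taxonomy construction over the corpus.

Starting from the root concept with the curated categories as its children,
the builder makes K full passes over the corpus.  For each paper it asks
the backend for isA pairs (s, t) — s an existing taxonomy term, t a term
from that paper's vocabulary — aggregates the samples by self-consistency,
and inserts each accepted pair as the edge (child=t, parent=s) unless the
insertion would create a directed cycle.  Cycle-inducing pairs are
discarded, so the taxonomy is a DAG at every step; a term whose parent only
appears in a later pass finds its place in a later iteration, which is why
multiple passes are needed.

A term proposed under a second parent gains an additional edge rather than
being re-parented: concepts may specialize several broader concepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

from .backend import (
    GenerationBackend,
    GenerationRequest,
    ParseError,
    TransportError,
    self_consistent,
)
from .model import Taxonomy, ValidationError
from .vocabulary import Document, Vocabulary, normalize_term

logger = logging.getLogger("litkg")


@dataclass
class IterationStats:
    """Taxonomy size and acceptance counters after one corpus pass."""

    iteration: int
    node_count: int
    edge_count: int
    leaf_count: int
    new_edges: int = 0
    rejected_cycles: int = 0
    rejected_unknown_parent: int = 0
    rejected_not_in_vocabulary: int = 0

    def to_row(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.iteration,
                self.node_count,
                self.edge_count,
                self.leaf_count,
                self.new_edges,
                self.rejected_cycles,
                self.rejected_unknown_parent,
                self.rejected_not_in_vocabulary,
            )
        )


STATS_HEADER = (
    "iteration\tnodes\tisa_edges\tleaves\taccepted\t"
    "rejected_cycles\trejected_unknown_parent\trejected_not_in_vocabulary"
)


def stats_tsv(stats: list[IterationStats]) -> str:
    return "\n".join([STATS_HEADER] + [s.to_row() for s in stats]) + "\n"


def query_relationships(
    paper: Document,
    taxonomy: Taxonomy,
    vocab_i: set[str] | Vocabulary,
    backend: GenerationBackend,
    m: int = 1,
    seed: int = 0,
    reject_counts: dict[str, int] | None = None,
) -> set[tuple[str, str]]:
    """Self-consistent isA pairs (s, t) for one paper, contract-filtered.

    The prompt payload carries the paper text, the complete current
    taxonomy term inventory, and the paper's vocabulary.  Returned pairs
    are lemma-normalized; any pair whose s is not an existing taxonomy node
    or whose t is not in the paper vocabulary is filtered out and counted.
    Backend failures degrade to an empty set so the corpus pass continues.
    """
    if isinstance(vocab_i, Vocabulary):
        vocab_keys = vocab_i.paper_vocab(paper.paper_id)
        resolve = vocab_i.resolve
    else:
        vocab_keys = set(vocab_i)
        resolve = lambda k: k  # noqa: E731
    if not vocab_keys:
        raise ValidationError(f"paper {paper.paper_id!r} has an empty vocabulary")
    request = GenerationRequest(
        prompt_role="relationship_query",
        payload={
            "paper_id": paper.paper_id,
            "text": paper.text,
            "taxonomy_terms": sorted(taxonomy.nodes),
            "vocabulary": sorted(vocab_keys),
        },
        seed=seed,
    )
    try:
        raw_pairs = self_consistent(backend, request, m)
    except (ParseError, TransportError) as err:
        logger.warning(
            "relationship query failed for paper %s: %s", paper.paper_id, err
        )
        return set()
    accepted: set[tuple[str, str]] = set()
    for item in raw_pairs:
        if not (isinstance(item, (list, tuple)) and len(item) == 2):
            continue
        s, t = (str(item[0]).strip(), str(item[1]).strip())
        if not s or not t:
            continue
        s, t = resolve(normalize_term(s)), resolve(normalize_term(t))
        if not taxonomy.has_node(s):
            if reject_counts is not None:
                reject_counts["unknown-parent"] = (
                    reject_counts.get("unknown-parent", 0) + 1
                )
            logger.debug("rejected pair (%s, %s): unknown parent", s, t)
            continue
        if t not in vocab_keys and t not in taxonomy.nodes:
            if reject_counts is not None:
                reject_counts["not-in-vocabulary"] = (
                    reject_counts.get("not-in-vocabulary", 0) + 1
                )
            logger.debug("rejected pair (%s, %s): not in vocabulary", s, t)
            continue
        accepted.add((s, t))
    return accepted


def _insertion_order(
    pairs: set[tuple[str, str]], taxonomy: Taxonomy
) -> list[tuple[str, str]]:
    """Canonical order: pairs whose child is already a node first, then lexicographic."""
    return sorted(pairs, key=lambda p: (not taxonomy.has_node(p[1]), p))


def build_taxonomy(
    corpus: list[Document],
    vocabulary: Vocabulary,
    categories: list[str],
    backend: GenerationBackend,
    k_iterations: int,
    m: int = 1,
    seed: int = 0,
    on_iteration: Callable[[int, Taxonomy, IterationStats], None] | None = None,
) -> tuple[Taxonomy, list[IterationStats]]:
    """K incremental corpus passes of guarded isA insertion.

    The returned stats sequence starts with the seeded state (iteration 0:
    root plus categories) followed by one entry per pass.  The taxonomy is
    audited acyclic and root-connected after every pass.
    """
    if not categories:
        raise ValidationError("build_taxonomy requires a non-empty category set")
    if k_iterations < 0:
        raise ValidationError("iteration count K must be >= 0")
    taxonomy = Taxonomy()
    for cat in categories:
        taxonomy.add_is_a(normalize_term(cat), taxonomy.root)
    stats: list[IterationStats] = [
        IterationStats(
            iteration=0,
            node_count=taxonomy.node_count,
            edge_count=taxonomy.edge_count,
            leaf_count=len(taxonomy.leaves()),
        )
    ]
    for k in range(1, k_iterations + 1):
        accepted = 0
        rejected_cycles = 0
        reject_counts: dict[str, int] = {}
        for paper in corpus:
            if not vocabulary.paper_vocab(paper.paper_id):
                logger.debug("paper %s has no vocabulary; skipped", paper.paper_id)
                continue
            pairs = query_relationships(
                paper,
                taxonomy,
                vocabulary,
                backend,
                m=m,
                seed=seed,
                reject_counts=reject_counts,
            )
            for s, t in _insertion_order(pairs, taxonomy):
                if t == taxonomy.root:
                    rejected_cycles += 1
                    continue
                if taxonomy.would_create_cycle(child=t, parent=s):
                    rejected_cycles += 1
                    logger.debug(
                        "iteration %d: rejected (%s isA %s): cycle", k, t, s
                    )
                    continue
                if taxonomy.add_is_a(child=t, parent=s):
                    accepted += 1
        taxonomy.validate()  # full acyclicity + connectivity audit per pass
        entry = IterationStats(
            iteration=k,
            node_count=taxonomy.node_count,
            edge_count=taxonomy.edge_count,
            leaf_count=len(taxonomy.leaves()),
            new_edges=accepted,
            rejected_cycles=rejected_cycles,
            rejected_unknown_parent=reject_counts.get("unknown-parent", 0),
            rejected_not_in_vocabulary=reject_counts.get("not-in-vocabulary", 0),
        )
        stats.append(entry)
        if on_iteration is not None:
            on_iteration(k, taxonomy, entry)
        logger.info(
            "iteration %d: %d nodes, %d edges, %d accepted, %d cycle-rejected",
            k,
            taxonomy.node_count,
            taxonomy.edge_count,
            accepted,
            rejected_cycles,
        )
    return taxonomy, stats


def unplaced_terms(vocabulary: Vocabulary, taxonomy: Taxonomy) -> set[str]:
    """Vocabulary lemmas that found no place in the taxonomy (reported, never
    force-attached)."""
    placed = taxonomy.nodes
    return {
        k
        for k in vocabulary.lemma_keys()
        if vocabulary.resolve(k) not in placed
    }
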