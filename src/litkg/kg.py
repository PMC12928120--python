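"""Stages 4–5: knowledge-graph instantiation and relation-triple extraction.

Taxonomy leaves — the lowest-level concepts, with no children of their own —
become KG instances; every leaf→parent isA edge becomes an instance-of
link; non-leaf nodes (the root included) are the ontology classes.
Relation triples are then extracted per paper with open-vocabulary
predicates and filtered so both endpoints lemma-match the extracted
vocabulary (acronym aliases resolve to their expansion's concept).  The
merged export overlays the relation triples and the isA backbone in one
labeled graph, the structure used by graph-based retrieval downstream.
"""

from __future__ import annotations

import logging

import networkx as nx

from .backend import (
    GenerationBackend,
    GenerationRequest,
    ParseError,
    TransportError,
    self_consistent,
)
from .model import (
    ISA_PREDICATE,
    KnowledgeGraph,
    OntologySchema,
    Taxonomy,
    Triple,
    ValidationError,
    term_uri,
    uri_term,
)
from .vocabulary import Document, Vocabulary, normalize_term

logger = logging.getLogger("litkg")


def instantiate_kg(taxonomy: Taxonomy) -> tuple[OntologySchema, KnowledgeGraph]:
    """Split a taxonomy into schema classes and KG instances.

    Instances are the leaves; each leaf contributes one instance-of pair
    per parent (a leaf under two parents is an instance of both classes).
    """
    if taxonomy.node_count < 2:
        raise ValidationError("instantiation requires at least one non-root node")
    schema = OntologySchema.from_taxonomy(taxonomy)
    kg = KnowledgeGraph(
        instances=set(schema.instances),
        instance_of={
            (leaf, parent)
            for leaf in schema.instances
            for parent in taxonomy.parents(leaf)
        },
    )
    schema.validate()
    kg.validate(schema)
    return schema, kg


def _normalize_predicate(predicate: str) -> str:
    return " ".join(predicate.casefold().split())


def extract_relations(
    paper: Document,
    vocabulary: Vocabulary,
    backend: GenerationBackend,
    m: int = 1,
    seed: int = 0,
) -> set[Triple]:
    """Vocabulary-filtered relation triples from one paper.

    Subjects and objects must lemma-match vocabulary entries (aliases
    resolved); predicates are case-folded and whitespace-collapsed.
    Malformed triple lines are skipped and counted; exact duplicates
    deduplicate.
    """
    if len(vocabulary) == 0:
        return set()
    request = GenerationRequest(
        prompt_role="triple_extract",
        payload={
            "paper_id": paper.paper_id,
            "text": paper.text,
            "vocabulary": sorted(vocabulary.lemma_keys()),
        },
        seed=seed,
    )
    try:
        raw = self_consistent(backend, request, m)
    except (ParseError, TransportError) as err:
        logger.warning("triple extraction failed for %s: %s", paper.paper_id, err)
        return set()
    triples: set[Triple] = set()
    malformed = 0
    dropped = 0
    for item in raw:
        if not (isinstance(item, (list, tuple)) and len(item) == 3):
            malformed += 1
            continue
        subj, pred, obj = (str(x).strip() for x in item)
        if not (subj and pred and obj):
            malformed += 1
            continue
        subj = vocabulary.resolve(normalize_term(subj))
        obj = vocabulary.resolve(normalize_term(obj))
        if subj not in vocabulary.entries or obj not in vocabulary.entries:
            dropped += 1
            continue
        triples.add(Triple(subj, _normalize_predicate(pred), obj))
    if malformed:
        logger.warning(
            "paper %s: skipped %d malformed triple lines", paper.paper_id, malformed
        )
    if dropped:
        logger.debug(
            "paper %s: dropped %d out-of-vocabulary triples", paper.paper_id, dropped
        )
    return triples


def extract_corpus_relations(
    corpus: list[Document],
    vocabulary: Vocabulary,
    backend: GenerationBackend,
    m: int = 1,
    seed: int = 0,
) -> set[Triple]:
    """Union of per-paper relation triples over the whole corpus."""
    out: set[Triple] = set()
    for paper in corpus:
        out |= extract_relations(paper, vocabulary, backend, m=m, seed=seed)
    return out


# ---------------------------------------------------------------------------
# Merged KG + ontology graph
# ---------------------------------------------------------------------------


def merge_kg_ontology(kg: KnowledgeGraph, taxonomy: Taxonomy) -> nx.MultiDiGraph:
    """Overlay relation triples and the isA backbone in one labeled graph.

    Edges carry ``predicate`` and ``edge_type`` ("relation" vs "isA")
    attributes; the edge multiset is the disjoint union of the two edge
    sets, and the node set is their union.
    """
    g = nx.MultiDiGraph()
    g.add_nodes_from(sorted(taxonomy.nodes))
    g.add_nodes_from(sorted(kg.instances))
    for child, parent in sorted(taxonomy.edges()):
        g.add_edge(child, parent, predicate=ISA_PREDICATE, edge_type="isA")
    for t in sorted(kg.relations):
        g.add_edge(
            t.subject, t.object, predicate=t.predicate, edge_type="relation"
        )
    return g


def merged_edge_multiset(g: nx.MultiDiGraph) -> list[tuple[str, str, str]]:
    """Sorted (subject, predicate, object) multiset of a merged graph."""
    return sorted(
        (u, data["predicate"], v) for u, v, data in g.edges(data=True)
    )


def merged_to_ntriples(g: nx.MultiDiGraph) -> str:
    from rdflib import Graph as RdfGraph

    rg = RdfGraph()
    for u, pred, v in merged_edge_multiset(g):
        rg.add((term_uri(u), term_uri(pred), term_uri(v)))
    return rg.serialize(format="nt")


def merged_from_ntriples(text: str) -> nx.MultiDiGraph:
    from rdflib import Graph as RdfGraph

    rg = RdfGraph()
    rg.parse(data=text, format="nt")
    g = nx.MultiDiGraph()
    for s, p, o in rg:
        subj, pred, obj = uri_term(s), uri_term(p), uri_term(o)
        g.add_edge(
            subj,
            obj,
            predicate=pred,
            edge_type="isA" if pred == ISA_PREDICATE else "relation",
        )
    return g


def merged_to_graphml(g: nx.MultiDiGraph, path: str) -> None:
    nx.write_graphml(g, path)
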