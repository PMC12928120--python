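"""Core domain types: taxonomies as rooted isA DAGs, knowledge graphs, rooted paths.

A taxonomy is a rooted directed acyclic graph whose edges are child–parent
*isA* (subsumption) pairs over lemma-normalized term keys.  The distinguished
root concept is ``Thing``; every other node is reachable from the root by at
least one directed parent→child path.  Multiple parents are allowed (a concept
may specialize several broader concepts), so the structure is a DAG, not a
tree.

Leaves of the taxonomy become knowledge-graph *instances*; non-leaf nodes
(including the root) are ontology *classes*.  A :class:`KnowledgeGraph` holds
those instances, their instance-of links, and free-predicate relation triples.

All hierarchical evaluation is phrased in terms of :class:`RootedPath` —
an ordered node sequence from the root to an endpoint.
"""

from __future__ import annotations

import json
import urllib.parse
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

#: Lemma key of the universal root concept of every taxonomy.
ROOT_TERM = "thing"
#: Display surface form of the root.
ROOT_SURFACE = "Thing"
#: Predicate label used for subsumption edges in exports.
ISA_PREDICATE = "isA"


class LitkgError(Exception):
    """Base class for all package errors."""


class NodeNotFoundError(LitkgError, KeyError):
    """A queried term key is not a node of the taxonomy."""


class CycleError(LitkgError, ValueError):
    """An edge insertion would create a directed cycle."""


class ValidationError(LitkgError, ValueError):
    """A structural invariant is violated."""


# ---------------------------------------------------------------------------
# Value types
# ---------------------------------------------------------------------------


@dataclass
class Term:
    """A lemma-normalized concept key with its observed surface forms.

    ``lemma_key`` is the canonical identity used everywhere in the pipeline;
    ``surface_forms`` preserves the raw spellings in first-seen corpus order,
    so ``surface_forms[0]`` is the canonical display form.
    """

    lemma_key: str
    surface_forms: list[str] = field(default_factory=list)
    is_acronym_alias: bool = False

    def __post_init__(self) -> None:
        if not self.lemma_key:
            raise ValidationError("Term lemma_key must be non-empty")

    @property
    def canonical_surface(self) -> str:
        return self.surface_forms[0] if self.surface_forms else self.lemma_key


@dataclass(frozen=True, order=True)
class Triple:
    """A subject–predicate–object relation over term keys."""

    subject: str
    predicate: str
    object: str

    def __post_init__(self) -> None:
        if not self.predicate:
            raise ValidationError("Triple predicate must be non-empty")


@dataclass(frozen=True)
class RootedPath:
    """An ordered node sequence from the root to an endpoint node.

    The unit of all hierarchical reconstruction metrics.  ``node_set``
    excludes the root and includes the endpoint, matching the convention of
    the hierarchical precision/recall definitions.
    """

    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValidationError("RootedPath must contain at least the root")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("RootedPath must not repeat nodes")

    @property
    def endpoint(self) -> str:
        return self.nodes[-1]

    @property
    def node_set(self) -> frozenset[str]:
        """Path nodes excluding the root (first element)."""
        return frozenset(self.nodes[1:])

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


class Taxonomy:
    """A rooted DAG of isA edges over normalized term keys.

    Edges are conceptually (child, parent) subsumption pairs; internally the
    graph is stored parent→child so that root-to-node reachability is plain
    directed reachability.  Insertion through :meth:`add_is_a` is guarded:
    duplicate edges are idempotent no-ops and cycle-inducing edges raise
    :class:`CycleError` (use :meth:`would_create_cycle` to pre-check).
    """

    def __init__(self, root: str = ROOT_TERM) -> None:
        if not root:
            raise ValidationError("root term must be non-empty")
        self.root = root
        self._g = nx.DiGraph()
        self._g.add_node(root)

    # -- basic queries ------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def node_count(self) -> int:
        return self._g.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, term: str) -> bool:
        return self._g.has_node(term)

    def has_edge(self, child: str, parent: str) -> bool:
        return self._g.has_edge(parent, child)

    def edges(self) -> set[tuple[str, str]]:
        """All (child, parent) isA pairs."""
        return {(c, p) for p, c in self._g.edges}

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self._g.predecessors(term))

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self._g.successors(term))

    def ancestors(self, term: str, include_self: bool = False) -> set[str]:
        """Nodes with a directed path down to ``term`` (optionally ``term`` itself)."""
        self._require(term)
        anc = nx.ancestors(self._g, term)
        if include_self:
            anc = anc | {term}
        return anc

    def descendants(self, term: str) -> set[str]:
        self._require(term)
        return nx.descendants(self._g, term)

    def leaves(self) -> set[str]:
        """Nodes with no children; the root only if the taxonomy is root-only."""
        return {n for n in self._g.nodes if self._g.out_degree(n) == 0}

    def non_leaf_nodes(self) -> set[str]:
        return {n for n in self._g.nodes if self._g.out_degree(n) > 0}

    def _require(self, term: str) -> None:
        if not self._g.has_node(term):
            raise NodeNotFoundError(term)

    # -- guarded growth -----------------------------------------------------

    def would_create_cycle(self, child: str, parent: str) -> bool:
        """True iff inserting (child isA parent) would create a directed cycle.

        A self-pair is reported as a cycle.  A child that is not yet a node
        can never create a cycle.  The taxonomy is not modified.
        """
        if child == parent:
            return True
        if not self._g.has_node(child) or not self._g.has_node(parent):
            return False
        # parent→child edge cycles iff parent is already reachable from child
        return nx.has_path(self._g, child, parent)

    def add_is_a(self, child: str, parent: str) -> bool:
        """Insert the isA edge (child, parent).

        Returns True if a new edge was added, False for an idempotent
        duplicate.  Raises :class:`CycleError` if the edge would create a
        cycle and :class:`ValidationError` for empty keys or a root child.
        """
        if not child or not parent:
            raise ValidationError("edge endpoints must be non-empty term keys")
        if child == self.root:
            raise ValidationError("the root cannot be given a parent")
        if self.has_edge(child, parent):
            return False
        if self.would_create_cycle(child, parent):
            raise CycleError(f"edge ({child!r} isA {parent!r}) would create a cycle")
        self._g.add_edge(parent, child)
        return True

    # -- paths --------------------------------------------------------------

    def enumerate_root_paths(self, node: str) -> list[RootedPath]:
        """Every distinct root→node path, ordered by node-sequence lexicographic order.

        For a tree there is exactly one path per node; for the root the single
        path is the root alone.
        """
        self._require(node)
        if node == self.root:
            return [RootedPath((self.root,))]
        paths = [
            RootedPath(tuple(p))
            for p in nx.all_simple_paths(self._g, self.root, node)
        ]
        return sorted(paths, key=lambda p: p.nodes)

    def all_root_paths(self) -> list[RootedPath]:
        """Root paths to every non-root node, canonically ordered."""
        out: list[RootedPath] = []
        for n in sorted(self.nodes - {self.root}):
            out.extend(self.enumerate_root_paths(n))
        return out

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check acyclicity and root-connectivity; raise on violation."""
        if not nx.is_directed_acyclic_graph(self._g):
            raise ValidationError("taxonomy contains a directed cycle")
        if self._g.in_degree(self.root) != 0:
            raise ValidationError("root must have no parent")
        reachable = nx.descendants(self._g, self.root) | {self.root}
        orphans = set(self._g.nodes) - reachable
        if orphans:
            raise ValidationError(f"nodes unreachable from root: {sorted(orphans)}")

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self._g))

    # -- construction helpers ----------------------------------------------

    def copy(self) -> "Taxonomy":
        t = Taxonomy(self.root)
        t._g = self._g.copy()
        return t

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], root: str = ROOT_TERM
    ) -> "Taxonomy":
        """Build from (child, parent) pairs; order-insensitive, validated."""
        t = cls(root)
        pending = list(edges)
        # parents may be introduced by later pairs: insert in passes
        while pending:
            rest: list[tuple[str, str]] = []
            progressed = False
            for child, parent in pending:
                if t.has_node(parent):
                    t.add_is_a(child, parent)
                    progressed = True
                else:
                    rest.append((child, parent))
            if not progressed:
                raise ValidationError(
                    f"edges unreachable from root {root!r}: {sorted(rest)}"
                )
            pending = rest
        t.validate()
        return t

    # -- serialization ------------------------------------------------------

    def to_dict(
        self,
        instances: Iterable[str] | None = None,
        surface_forms: Mapping[str, Sequence[str]] | None = None,
    ) -> dict:
        """Canonical ontology mapping; nodes and edges sorted for stable diffs."""
        d: dict = {
            "root": self.root,
            "nodes": sorted(self.nodes),
            "edges": sorted([list(e) for e in self.edges()]),
        }
        if instances is not None:
            d["instances"] = sorted(instances)
        if surface_forms is not None:
            d["surface_forms"] = {
                k: list(v) for k, v in sorted(surface_forms.items())
            }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(**kw), indent=2, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Taxonomy":
        t = cls.from_edges([tuple(e) for e in d["edges"]], root=d["root"])
        for n in d.get("nodes", []):
            if not t.has_node(n) and n != t.root:
                raise ValidationError(f"node {n!r} listed but not attached to root")
        return t

    @classmethod
    def from_json(cls, text: str) -> "Taxonomy":
        return cls.from_dict(json.loads(text))

    def to_tsv(self) -> str:
        """Edge-list TSV: one header line, then child <TAB> parent rows."""
        lines = ["child\tparent"]
        lines += [f"{c}\t{p}" for c, p in sorted(self.edges())]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, root: str = ROOT_TERM) -> "Taxonomy":
        rows = [ln for ln in text.splitlines() if ln.strip()]
        edges = []
        for ln in rows[1:]:  # skip header
            child, parent = ln.split("\t")
            edges.append((child, parent))
        return cls.from_edges(edges, root=root)

    def to_graphml(self, path: str) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for c, p in sorted(self.edges()):
            g.add_edge(p, c, edge_type=ISA_PREDICATE)
        nx.write_graphml(g, path)

    def to_ntriples(self) -> str:
        from rdflib import Graph as RdfGraph

        g = RdfGraph()
        for c, p in sorted(self.edges()):
            g.add((term_uri(c), term_uri(ISA_PREDICATE), term_uri(p)))
        return g.serialize(format="nt")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Taxonomy(root={self.root!r}, nodes={self.node_count}, "
            f"edges={self.edge_count})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return (
            self.root == other.root
            and self.nodes == other.nodes
            and self.edges() == other.edges()
        )


def term_uri(term: str):
    """Mint a stable URI for a term key (spaces percent-encoded)."""
    from rdflib import URIRef

    return URIRef("urn:litkg:" + urllib.parse.quote(term, safe=""))


def uri_term(uri) -> str:
    return urllib.parse.unquote(str(uri).removeprefix("urn:litkg:"))


# ---------------------------------------------------------------------------
# Ontology schema and knowledge graph
# ---------------------------------------------------------------------------


@dataclass
class OntologySchema:
    """A taxonomy split into classes (non-leaves, including the root) and
    instances (leaves)."""

    taxonomy: Taxonomy
    classes: set[str]
    instances: set[str]

    def validate(self) -> None:
        self.taxonomy.validate()
        if self.classes & self.instances:
            raise ValidationError("classes and instances must be disjoint")
        if self.classes | self.instances != self.taxonomy.nodes:
            raise ValidationError("classes ∪ instances must cover all nodes")

    @classmethod
    def from_taxonomy(cls, taxonomy: Taxonomy) -> "OntologySchema":
        inst = taxonomy.leaves() - {taxonomy.root}
        return cls(
            taxonomy=taxonomy, classes=taxonomy.nodes - inst, instances=inst
        )


@dataclass
class KnowledgeGraph:
    """Instances, instance-of links, and free-predicate relation triples."""

    instances: set[str] = field(default_factory=set)
    instance_of: set[tuple[str, str]] = field(default_factory=set)
    relations: set[Triple] = field(default_factory=set)

    def validate(self, schema: OntologySchema | None = None) -> None:
        for inst, cls_ in self.instance_of:
            if inst not in self.instances:
                raise ValidationError(f"instance_of references unknown instance {inst!r}")
            if schema is not None and cls_ not in schema.classes:
                raise ValidationError(f"instance_of references non-class {cls_!r}")
        if schema is not None:
            known = schema.classes | schema.instances
            for t in self.relations:
                for end in (t.subject, t.object):
                    if end not in known:
                        raise ValidationError(
                            f"relation endpoint {end!r} not in ontology"
                        )
        orphan = {i for i in self.instances if not any(p[0] == i for p in self.instance_of)}
        if self.instance_of and orphan:
            raise ValidationError(f"instances without instance_of link: {sorted(orphan)}")

    def to_dict(self) -> dict:
        return {
            "instances": sorted(self.instances),
            "instance_of": sorted([list(p) for p in self.instance_of]),
            "relations": sorted(
                [[t.subject, t.predicate, t.object] for t in self.relations]
            ),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "KnowledgeGraph":
        return cls(
            instances=set(d.get("instances", [])),
            instance_of={tuple(p) for p in d.get("instance_of", [])},
            relations={Triple(*t) for t in d.get("relations", [])},
        )

    @classmethod
    def from_json(cls, text: str) -> "KnowledgeGraph":
        return cls.from_dict(json.loads(text))

    def relations_tsv(self) -> str:
        lines = ["subject\tpredicate\tobject"]
        lines += [
            f"{t.subject}\t{t.predicate}\t{t.object}"
            for t in sorted(self.relations)
        ]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Module-level operation aliases (functional surface)
# ---------------------------------------------------------------------------


def would_create_cycle(taxonomy: Taxonomy, candidate: tuple[str, str]) -> bool:
    """True iff adding the (child, parent) candidate edge creates a cycle."""
    child, parent = candidate
    return taxonomy.would_create_cycle(child, parent)


def enumerate_root_paths(taxonomy: Taxonomy, node: str) -> list[RootedPath]:
    return taxonomy.enumerate_root_paths(node)


def leaves(taxonomy: Taxonomy) -> set[str]:
    return taxonomy.leaves()
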