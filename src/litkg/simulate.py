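"""Planted-ontology worlds and rendered synthetic corpora.

The generator builds a known ground-truth ontology — a rooted isA DAG of
chemistry-flavored concepts with controllable depth, branching and
multi-parent rate — instantiates its KG, and renders a corpus of short
plain-text "papers" that assert term mentions, acronym definitions, isA
facts and relation facts in templated sentences.  Together with
:class:`~litkg.backend.PlantedWorldBackend` this makes every pipeline stage
exercisable offline, with recovery measurable against the planted truth.

What the corpus emulates: per-paper subsets of isA assertions (each paper
sees only part of the hierarchy), spelling variation (plural, title-case
and hyphenated surface forms of the same concept), acronym usage, and a
configurable share of ground-truth edges asserted anywhere (coverage).
What it does not emulate: free prose, negation, context-dependent meaning,
or terms whose correct placement is genuinely ambiguous — real literature
is harder in all four ways.

Fact distribution modes:

* ``random`` — covered edges are dealt to papers uniformly;
* ``by_level`` — each paper asserts edges of exactly one hierarchy depth,
  and papers are ordered deepest-first.  This is the adversarial schedule
  for the incremental builder: an edge at depth d can only attach after its
  parent (asserted by a *later* paper in the pass) is present, so full
  recovery needs as many corpus passes as the hierarchy is deep.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .backend import PaperFacts, PlantedWorld
from .model import (
    KnowledgeGraph,
    OntologySchema,
    Taxonomy,
    Triple,
    ValidationError,
)
from .vocabulary import Document, normalize_term

_PREFIXES = [
    "fluoro", "chloro", "nitro", "oxo", "hydroxy", "amino", "ferro",
    "cupro", "sulfo", "phospho", "boro", "silico", "titano", "zirco",
    "vanado", "molybdo", "stanno", "plumbo", "argento", "aurato",
]
_HEADS = [
    "alkane", "alkene", "alkyne", "oxide", "catalyst", "support", "ligand",
    "cluster", "complex", "site", "carbide", "nitride", "zeolite",
    "framework", "dopant", "precursor", "adsorbate", "facet", "vacancy",
    "interface",
]
_PREDICATES = [
    "supported on", "synthesized from", "characterized by",
    "derived from", "bound to",
]


@dataclass
class PlantedSpec:
    """Parameters of a planted ontology and its rendered corpus.

    ``branching`` is the mean number of children per class; ``coverage`` the
    fraction of ground-truth isA edges asserted somewhere in the corpus;
    ``multiparent_rate`` the probability a non-category node gains a second
    parent from a strictly shallower level (keeping the graph acyclic).
    """

    depth: int = 4
    branching: float = 3.0
    multiparent_rate: float = 0.0
    n_terms: int = 60
    n_papers: int = 12
    facts_per_paper: int = 6
    coverage: float = 1.0
    relations_per_paper: int = 1
    fact_distribution: str = "by_level"  # "by_level" | "random"
    omission_rate: float = 0.0
    hallucination_rate: float = 0.0
    acronym_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValidationError("depth must be >= 2")
        if not 0.0 < self.coverage <= 1.0:
            raise ValidationError("coverage must be in (0, 1]")
        if not 0.0 <= self.multiparent_rate <= 1.0:
            raise ValidationError("multiparent_rate must be in [0, 1]")
        if self.n_terms < self.depth + 1:
            raise ValidationError("n_terms must allow one node per level")
        if self.n_papers < 1 or self.facts_per_paper < 1:
            raise ValidationError("n_papers and facts_per_paper must be >= 1")
        if self.fact_distribution not in ("by_level", "random"):
            raise ValidationError(
                f"unknown fact_distribution {self.fact_distribution!r}"
            )


@dataclass
class PlantedWorldResult:
    """A planted world plus its rendered corpus and bookkeeping."""

    world: PlantedWorld
    corpus: list[Document]
    node_levels: dict[str, int] = field(default_factory=dict)

    @property
    def schema(self) -> OntologySchema:
        return self.world.schema

    @property
    def kg(self) -> KnowledgeGraph:
        return self.world.kg


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def _term_names(n: int, rng: random.Random) -> list[str]:
    combos = [(p, h) for p in _PREFIXES for h in _HEADS]
    rng.shuffle(combos)
    names = [f"{p} {h}" for p, h in combos[:n]]
    i = 0
    while len(names) < n:  # exhausted the lexicon; extend deterministically
        p, h = combos[i % len(combos)]
        names.append(f"{p} {h} variant {i}")
        i += 1
    assert all(normalize_term(x) == x for x in names)
    return names


def _level_sizes(spec: PlantedSpec) -> list[int]:
    """Node counts per level 1..depth, geometric in branching, summing to n_terms."""
    weights = [spec.branching**lvl for lvl in range(1, spec.depth + 1)]
    total = sum(weights)
    sizes = [max(1, round(spec.n_terms * w / total)) for w in weights]
    # adjust the largest level so the sizes sum exactly
    diff = spec.n_terms - sum(sizes)
    order = sorted(range(len(sizes)), key=lambda i: -sizes[i])
    for idx in order:
        take = max(diff, 1 - sizes[idx]) if diff < 0 else diff
        sizes[idx] += take
        diff -= take
        if diff == 0:
            break
    sizes[0] = max(2, sizes[0])  # at least two top categories
    return sizes


def _build_taxonomy(
    spec: PlantedSpec, rng: random.Random
) -> tuple[Taxonomy, dict[str, int]]:
    sizes = _level_sizes(spec)
    names = _term_names(sum(sizes), rng)
    taxonomy = Taxonomy()
    levels: dict[str, int] = {taxonomy.root: 0}
    by_level: list[list[str]] = [[taxonomy.root]]
    cursor = 0
    for lvl, size in enumerate(sizes, start=1):
        nodes = names[cursor : cursor + size]
        cursor += size
        for node in nodes:
            parent = (
                taxonomy.root if lvl == 1 else rng.choice(by_level[lvl - 1])
            )
            taxonomy.add_is_a(node, parent)
            levels[node] = lvl
            if lvl >= 2 and rng.random() < spec.multiparent_rate:
                shallower = [
                    c
                    for l2 in range(1, lvl)
                    for c in by_level[l2]
                    if c not in taxonomy.parents(node)
                ]
                if shallower:
                    taxonomy.add_is_a(node, rng.choice(shallower))
        by_level.append(nodes)
    taxonomy.validate()
    return taxonomy, levels


# ---------------------------------------------------------------------------
# Corpus rendering
# ---------------------------------------------------------------------------


def _surface_variant(term: str, rng: random.Random) -> str:
    """A rendering of a lemma that normalizes back to it (plural / title /
    hyphenated)."""
    kind = rng.randrange(4)
    if kind == 0:
        return term
    if kind == 1:
        return term.title()
    if kind == 2 and not term.endswith(("s", "x", "y")):
        return term + "s"
    if " " in term:
        head, _, tail = term.partition(" ")
        return f"{head.title()}-{tail.title()}"
    return term.title()


def _make_acronyms(
    terms: list[str], fraction: float, rng: random.Random
) -> dict[str, str]:
    """lemma -> acronym surface, unique, initials-based."""
    out: dict[str, str] = {}
    used: set[str] = set()
    for term in terms:
        words = term.split()
        if len(words) < 2 or rng.random() >= fraction:
            continue
        base = "".join(w[0] for w in words).upper()
        acronym = base
        n = 2
        while acronym in used:
            acronym = f"{base}{n}"
            n += 1
        if len(acronym) < len(term):
            used.add(acronym)
            out[term] = acronym
    return out


def _assign_edges(
    spec: PlantedSpec,
    edges: list[tuple[str, str]],
    levels: dict[str, int],
    rng: random.Random,
) -> list[list[tuple[str, str]]]:
    """Partition covered edges into per-paper fact lists."""
    n_cov = math.ceil(spec.coverage * len(edges))
    covered = rng.sample(edges, n_cov) if n_cov < len(edges) else list(edges)
    if spec.fact_distribution == "random":
        rng.shuffle(covered)
        buckets: list[list[tuple[str, str]]] = [[] for _ in range(spec.n_papers)]
        for i, edge in enumerate(covered):
            buckets[i % spec.n_papers].append(edge)
        return buckets
    # by_level: group by child depth, deepest papers first
    depth_of = lambda e: levels[e[0]]  # noqa: E731
    level_groups: dict[int, list[tuple[str, str]]] = {}
    for e in covered:
        level_groups.setdefault(depth_of(e), []).append(e)
    lvls = sorted(level_groups, reverse=True)
    if spec.n_papers < len(lvls):
        raise ValidationError(
            f"by_level distribution needs n_papers >= {len(lvls)} levels"
        )
    # papers per level proportional to that level's edge count, >= 1 each
    remaining = spec.n_papers
    alloc: dict[int, int] = {}
    for i, lvl in enumerate(lvls):
        rest_lvls = len(lvls) - i - 1
        share = max(
            1,
            round(
                len(level_groups[lvl])
                / max(1, sum(len(level_groups[x]) for x in lvls[i:]))
                * (remaining - rest_lvls)
            ),
        )
        share = min(share, remaining - rest_lvls)
        alloc[lvl] = share
        remaining -= share
    buckets = []
    for lvl in lvls:
        group = sorted(level_groups[lvl])
        rng.shuffle(group)
        k = alloc[lvl]
        lvl_buckets: list[list[tuple[str, str]]] = [[] for _ in range(k)]
        for i, edge in enumerate(group):
            lvl_buckets[i % k].append(edge)
        buckets.extend(lvl_buckets)
    while len(buckets) < spec.n_papers:
        buckets.append([])
    return buckets


def _render_paper(
    pid: str,
    isa_facts: list[tuple[str, str]],
    relations: list[Triple],
    acronyms: dict[str, str],
    defined_acronyms: set[str],
    root: str,
    rng: random.Random,
) -> tuple[str, PaperFacts]:
    sentences: list[str] = [
        "This work reports structured findings on catalytic materials."
    ]
    term_surfaces: dict[str, str] = {}
    paper_acronyms: list[tuple[str, str]] = []

    def surface(term: str) -> str:
        if term not in term_surfaces:
            term_surfaces[term] = (
                "Thing" if term == root else _surface_variant(term, rng)
            )
        return term_surfaces[term]

    for term in sorted(
        {t for e in isa_facts for t in e}
        | {t for r in relations for t in (r.subject, r.object)}
    ):
        if term == root:
            continue
        surf = surface(term)
        if term in acronyms and term not in defined_acronyms:
            acr = acronyms[term]
            sentences.append(f"{surf} ({acr}) are examined in detail.")
            paper_acronyms.append((acr, surf))
            defined_acronyms.add(term)
        else:
            sentences.append(f"The role of {surf} is investigated here.")
    for child, parent in isa_facts:
        if parent == root:
            sentences.append(
                f"{surface(child)} is a fundamental category of this field."
            )
        else:
            sentences.append(
                f"{surface(child)} is a type of {surface(parent)}."
            )
    for rel in relations:
        sentences.append(
            f"{surface(rel.subject)} is {rel.predicate} {surface(rel.object)}."
        )
    text = " ".join(sentences)
    facts = PaperFacts(
        paper_id=pid,
        term_surfaces={k: v for k, v in term_surfaces.items() if k != root},
        isa_facts=list(isa_facts),
        acronyms=paper_acronyms,
        relations=list(relations),
    )
    return text, facts


def generate_planted_world(spec: PlantedSpec) -> PlantedWorldResult:
    """Deterministically generate ontology, KG, corpus and per-paper facts."""
    rng = random.Random(spec.seed)
    taxonomy, levels = _build_taxonomy(spec, rng)
    schema = OntologySchema.from_taxonomy(taxonomy)
    leaf_pool = sorted(schema.instances)
    relations: set[Triple] = set()
    want = spec.n_papers * spec.relations_per_paper
    attempts = 0
    while len(relations) < want and attempts < want * 10 and len(leaf_pool) >= 2:
        a, b = rng.sample(leaf_pool, 2)
        relations.add(Triple(a, rng.choice(_PREDICATES), b))
        attempts += 1
    kg = KnowledgeGraph(
        instances=set(schema.instances),
        instance_of={
            (leaf, parent)
            for leaf in schema.instances
            for parent in taxonomy.parents(leaf)
        },
        relations=relations,
    )

    edges = sorted(taxonomy.edges())
    buckets = _assign_edges(spec, edges, levels, rng)
    rel_list = sorted(relations)
    acronyms = _make_acronyms(sorted(levels), spec.acronym_fraction, rng)
    defined: set[str] = set()
    corpus: list[Document] = []
    paper_facts: dict[str, PaperFacts] = {}
    for i, bucket in enumerate(buckets):
        pid = f"paper-{i:03d}"
        rels = [
            rel_list[j]
            for j in range(
                i * spec.relations_per_paper,
                min((i + 1) * spec.relations_per_paper, len(rel_list)),
            )
        ]
        text, facts = _render_paper(
            pid, bucket, rels, acronyms, defined, taxonomy.root, rng
        )
        corpus.append(Document(paper_id=pid, text=text))
        paper_facts[pid] = facts

    world = PlantedWorld(
        schema=schema,
        kg=kg,
        paper_facts=paper_facts,
        omission_rate=spec.omission_rate,
        hallucination_rate=spec.hallucination_rate,
        rng_seed=spec.seed,
    )
    return PlantedWorldResult(world=world, corpus=corpus, node_levels=levels)
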