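"""Taxonomy-reconstruction metrics over rooted DAGs.

Hierarchical precision/recall/F1/accuracy compare a reconstructed taxonomy
against a ground truth path-by-path: every ground-truth root→node path is
matched to the most similar reconstructed path ending at the same term, and
credit is the overlap of their node sets.  Because nodes may have multiple
parents, a node can contribute several paths; all metrics are averages over
ground-truth paths, so multi-parent nodes weigh proportionally to their
path multiplicity.

Conventions (each switchable via :class:`MetricsConfig`):

* path node sets exclude the root and include the endpoint;
* an unmatched ground-truth path (endpoint absent from the reconstruction)
  contributes recall 0;
* hierarchical precision averages over matched paths only (macro); a micro
  variant dividing by the summed matched-path sizes is available;
* the ancestor error counts symmetric set discrepancies; a one-sided
  (missing-only) variant is available.

With the defaults, a matched path always shares at least its endpoint, so
hierarchical accuracy equals the path-multiplicity-weighted fraction of
ground-truth terms present in the reconstruction.

Complementary set metrics: term / leaf / KG-instance accuracy (fractions of
ground-truth terms, leaves, instances recovered) and lowest-common-ancestor
preservation, where the LCA of a node pair in a DAG is the *set* of deepest
common ancestors and preservation means the ground-truth and reconstructed
LCA sets intersect.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

from .model import (
    KnowledgeGraph,
    RootedPath,
    Taxonomy,
    ValidationError,
)


@dataclass(frozen=True)
class MetricsConfig:
    """Switches for the open readings of the hierarchical metrics."""

    exclude_root: bool = True
    include_endpoint: bool = True
    no_match_zero_recall: bool = True
    precision_average: str = "macro"  # "macro" (per matched path) | "micro"
    aec_symmetric: bool = True

    def __post_init__(self) -> None:
        if self.precision_average not in ("macro", "micro"):
            raise ValidationError(
                "precision_average must be 'macro' or 'micro'"
            )

    def node_set(self, path: RootedPath) -> frozenset[str]:
        nodes = path.nodes
        if self.exclude_root:
            nodes = nodes[1:]
        if not self.include_endpoint and nodes:
            nodes = nodes[:-1]
        return frozenset(nodes)


DEFAULT_CONFIG = MetricsConfig()


@dataclass
class MetricsReport:
    """All reconstruction metrics for one ground-truth/reconstruction pair."""

    term_accuracy: float
    hierarchical_precision: float
    hierarchical_recall: float
    hierarchical_f1: float
    hierarchical_accuracy: float
    ancestor_error_count: float
    lca_preservation: float
    leaf_accuracy: float
    kg_accuracy: float
    gt_path_count: int = 0
    matched_path_count: int = 0

    ROW_NAMES = {
        "term_accuracy": "Term accuracy",
        "hierarchical_precision": "Hierarchical precision",
        "hierarchical_recall": "Hierarchical recall",
        "hierarchical_f1": "Hierarchical F1",
        "hierarchical_accuracy": "Hierarchical accuracy",
        "ancestor_error_count": "Ancestor error count",
        "lca_preservation": "Lowest common ancestor",
        "leaf_accuracy": "Leaf nodes accuracy",
        "kg_accuracy": "KG accuracy",
    }

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def format_table(self) -> str:
        width = max(len(v) for v in self.ROW_NAMES.values())
        lines = []
        for attr, name in self.ROW_NAMES.items():
            lines.append(f"{name:<{width}}  {getattr(self, attr):.3f}")
        lines.append(
            f"{'Matched paths':<{width}}  "
            f"{self.matched_path_count}/{self.gt_path_count}"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Path matching
# ---------------------------------------------------------------------------


def match_path(
    gt_path: RootedPath,
    reconstructed: Taxonomy,
    config: MetricsConfig = DEFAULT_CONFIG,
) -> RootedPath | None:
    """The reconstructed root-path most similar to ``gt_path``.

    Candidates are the reconstructed root-paths ending at the same lemma key;
    similarity is the shared-node count of the configured node sets.  Ties
    break toward the shorter path, then the lexicographically smallest node
    sequence, so matching is deterministic.  Returns ``None`` iff the
    endpoint is absent from the reconstruction.
    """
    endpoint = gt_path.endpoint
    if not reconstructed.has_node(endpoint):
        return None
    gt_set = config.node_set(gt_path)
    best: RootedPath | None = None
    best_key: tuple | None = None
    for cand in reconstructed.enumerate_root_paths(endpoint):
        shared = len(gt_set & config.node_set(cand))
        key = (-shared, len(cand), cand.nodes)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best


# ---------------------------------------------------------------------------
# Hierarchical metrics
# ---------------------------------------------------------------------------


def _check_roots(ground_truth: Taxonomy, reconstructed: Taxonomy) -> None:
    if ground_truth.root != reconstructed.root:
        raise ValidationError(
            f"taxonomies must share the root term: "
            f"{ground_truth.root!r} != {reconstructed.root!r}"
        )


def hierarchical_metrics(
    ground_truth: Taxonomy,
    reconstructed: Taxonomy,
    config: MetricsConfig = DEFAULT_CONFIG,
) -> tuple[float, float, float, float]:
    """(hP, hR, hF1, hAcc) over all ground-truth root paths.

    hR averages shared/|gt path| over every ground-truth path (unmatched →
    0); hP averages shared/|matched path| over matched paths only; hAcc is
    the fraction of ground-truth paths whose match shares ≥1 node; hF1 is
    the harmonic mean (0 when hP + hR = 0).
    """
    _check_roots(ground_truth, reconstructed)
    gt_paths = ground_truth.all_root_paths()
    recall_sum = 0.0
    recall_n = 0
    precision_terms: list[float] = []
    shared_total = 0
    matched_size_total = 0
    acc_hits = 0
    for gt_path in gt_paths:
        gt_set = config.node_set(gt_path)
        matched = match_path(gt_path, reconstructed, config)
        if matched is None:
            if config.no_match_zero_recall:
                recall_n += 1
            continue
        m_set = config.node_set(matched)
        shared = len(gt_set & m_set)
        recall_sum += shared / len(gt_set) if gt_set else 1.0
        recall_n += 1
        if m_set:
            precision_terms.append(shared / len(m_set))
        else:
            precision_terms.append(1.0 if not gt_set else 0.0)
        shared_total += shared
        matched_size_total += len(m_set)
        if shared >= 1:
            acc_hits += 1
    h_recall = recall_sum / recall_n if recall_n else 0.0
    if config.precision_average == "micro":
        h_precision = (
            shared_total / matched_size_total if matched_size_total else 0.0
        )
    else:
        h_precision = (
            sum(precision_terms) / len(precision_terms)
            if precision_terms
            else 0.0
        )
    h_f1 = (
        2 * h_precision * h_recall / (h_precision + h_recall)
        if (h_precision + h_recall) > 0
        else 0.0
    )
    h_acc = acc_hits / len(gt_paths) if gt_paths else 0.0
    return h_precision, h_recall, h_f1, h_acc


def ancestor_error_count(
    ground_truth: Taxonomy,
    reconstructed: Taxonomy,
    config: MetricsConfig = DEFAULT_CONFIG,
) -> float:
    """Mean per-path node discrepancy against the most similar matched path.

    Per ground-truth path the discrepancy is the size of the symmetric
    difference of the (root-excluded) node sets; an unmatched path counts
    all its nodes as discrepancies.  One-sided (missing-only) counting is
    available via ``config.aec_symmetric = False``.
    """
    _check_roots(ground_truth, reconstructed)
    gt_paths = ground_truth.all_root_paths()
    if not gt_paths:
        return 0.0
    total = 0.0
    for gt_path in gt_paths:
        gt_set = config.node_set(gt_path)
        matched = match_path(gt_path, reconstructed, config)
        if matched is None:
            total += len(gt_set)
            continue
        m_set = config.node_set(matched)
        if config.aec_symmetric:
            total += len(gt_set ^ m_set)
        else:
            total += len(gt_set - m_set)
    return total / len(gt_paths)


# ---------------------------------------------------------------------------
# Lowest common ancestors
# ---------------------------------------------------------------------------


def lca_set(taxonomy: Taxonomy, a: str, b: str) -> set[str]:
    """Deepest common ancestors of ``a`` and ``b`` (a set in a DAG).

    A node counts as its own ancestor, so the LCA of a node and its
    descendant is the node itself.  A common ancestor is *lowest* when no
    other common ancestor descends from it.
    """
    common = taxonomy.ancestors(a, include_self=True) & taxonomy.ancestors(
        b, include_self=True
    )
    return {
        c
        for c in common
        if not (taxonomy.descendants(c) & (common - {c}))
    }


def lca_preservation(
    ground_truth: Taxonomy,
    reconstructed: Taxonomy,
    config: MetricsConfig = DEFAULT_CONFIG,
) -> float:
    """Fraction of non-root ground-truth node pairs whose LCA set survives.

    A pair is preserved iff both nodes exist in the reconstruction and the
    ground-truth and reconstructed LCA sets intersect.  Vacuously 1.0 when
    fewer than two non-root nodes exist.
    """
    _check_roots(ground_truth, reconstructed)
    nodes = sorted(ground_truth.nodes - {ground_truth.root})
    pairs = list(itertools.combinations(nodes, 2))
    if not pairs:
        return 1.0
    preserved = 0
    for a, b in pairs:
        if not (reconstructed.has_node(a) and reconstructed.has_node(b)):
            continue
        if lca_set(ground_truth, a, b) & lca_set(reconstructed, a, b):
            preserved += 1
    return preserved / len(pairs)


# ---------------------------------------------------------------------------
# Set accuracies
# ---------------------------------------------------------------------------


def set_accuracies(
    ground_truth: Taxonomy,
    reconstructed: Taxonomy,
    gt_kg: KnowledgeGraph | None = None,
    rec_kg: KnowledgeGraph | None = None,
) -> tuple[float, float, float]:
    """(term_accuracy, leaf_accuracy, kg_accuracy).

    Term accuracy is the fraction of non-root ground-truth terms present in
    the reconstruction; leaf accuracy the same over taxonomy leaves; KG
    accuracy the fraction of ground-truth instances that are instances of
    the reconstructed KG (leaves stand in when no KG is supplied, so a
    ground-truth instance surviving only as an internal class does not
    count).
    """
    _check_roots(ground_truth, reconstructed)
    gt_terms = ground_truth.nodes - {ground_truth.root}
    rec_terms = reconstructed.nodes - {reconstructed.root}
    term_acc = len(gt_terms & rec_terms) / len(gt_terms) if gt_terms else 1.0

    gt_leaves = ground_truth.leaves() - {ground_truth.root}
    rec_leaves = reconstructed.leaves() - {reconstructed.root}
    leaf_acc = (
        len(gt_leaves & rec_leaves) / len(gt_leaves) if gt_leaves else 1.0
    )

    gt_inst = gt_kg.instances if gt_kg is not None else gt_leaves
    rec_inst = rec_kg.instances if rec_kg is not None else rec_leaves
    kg_acc = len(gt_inst & rec_inst) / len(gt_inst) if gt_inst else 1.0
    return term_acc, leaf_acc, kg_acc


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


def evaluate(
    ground_truth: Taxonomy,
    reconstructed: Taxonomy,
    gt_kg: KnowledgeGraph | None = None,
    rec_kg: KnowledgeGraph | None = None,
    config: MetricsConfig = DEFAULT_CONFIG,
) -> MetricsReport:
    """Compute the full metric suite for one reconstruction."""
    h_p, h_r, h_f1, h_acc = hierarchical_metrics(
        ground_truth, reconstructed, config
    )
    aec = ancestor_error_count(ground_truth, reconstructed, config)
    lca = lca_preservation(ground_truth, reconstructed, config)
    term_acc, leaf_acc, kg_acc = set_accuracies(
        ground_truth, reconstructed, gt_kg, rec_kg
    )
    gt_paths = ground_truth.all_root_paths()
    matched = sum(
        1
        for p in gt_paths
        if match_path(p, reconstructed, config) is not None
    )
    return MetricsReport(
        term_accuracy=term_acc,
        hierarchical_precision=h_p,
        hierarchical_recall=h_r,
        hierarchical_f1=h_f1,
        hierarchical_accuracy=h_acc,
        ancestor_error_count=aec,
        lca_preservation=lca,
        leaf_accuracy=leaf_acc,
        kg_accuracy=kg_acc,
        gt_path_count=len(gt_paths),
        matched_path_count=matched,
    )
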