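"""Brute-force reference implementations for the hierarchical metric suite.

Everything here works on a bare ``(root, edge-set)`` representation with
hand-rolled recursion — no networkx, no litkg internals — so it is an
independent oracle for the optimized implementations.  Definitions are
applied literally: enumerate every root path exhaustively, try every
candidate match, recompute reachability by DFS on demand.
"""

from __future__ import annotations

import random

ROOT = "thing"

Edge = tuple[str, str]  # (child, parent)


def nodes_of(edges: set[Edge], root: str = ROOT) -> set[str]:
    out = {root}
    for c, p in edges:
        out.add(c)
        out.add(p)
    return out


def children_map(edges: set[Edge]) -> dict[str, list[str]]:
    cm: dict[str, list[str]] = {}
    for c, p in edges:
        cm.setdefault(p, []).append(c)
    return cm


def all_paths(edges: set[Edge], node: str, root: str = ROOT) -> list[tuple[str, ...]]:
    """Every root→node path by exhaustive DFS."""
    cm = children_map(edges)
    found: list[tuple[str, ...]] = []

    def walk(current: str, trail: tuple[str, ...]) -> None:
        if current == node:
            found.append(trail)
            return
        for child in cm.get(current, []):
            if child not in trail:
                walk(child, trail + (child,))

    walk(root, (root,))
    return sorted(found)


def reachable(edges: set[Edge], src: str, dst: str) -> bool:
    """Directed parent→child reachability by recursive DFS."""
    cm = children_map(edges)
    seen: set[str] = set()

    def walk(n: str) -> bool:
        if n == dst:
            return True
        seen.add(n)
        return any(walk(c) for c in cm.get(n, []) if c not in seen)

    return walk(src)


def would_cycle(edges: set[Edge], child: str, parent: str) -> bool:
    if child == parent:
        return True
    return reachable(edges, child, parent)


def leaves_of(edges: set[Edge], root: str = ROOT) -> set[str]:
    parents = {p for _, p in edges}
    return {n for n in nodes_of(edges, root) if n not in parents}


def ancestors_of(edges: set[Edge], node: str, root: str = ROOT) -> set[str]:
    """Nodes occurring on any root path to ``node``, the node included."""
    return {x for path in all_paths(edges, node, root) for x in path}


def _node_set(path: tuple[str, ...]) -> frozenset[str]:
    return frozenset(path[1:])  # root excluded, endpoint included


def best_match(
    gt_path: tuple[str, ...], rec_edges: set[Edge], root: str = ROOT
) -> tuple[str, ...] | None:
    endpoint = gt_path[-1]
    if endpoint != root and endpoint not in nodes_of(rec_edges, root):
        return None
    candidates = all_paths(rec_edges, endpoint, root)
    if not candidates:
        return None
    gt_set = _node_set(gt_path)
    return min(
        candidates,
        key=lambda p: (-len(gt_set & _node_set(p)), len(p), p),
    )


def brute_metrics(
    gt_edges: set[Edge], rec_edges: set[Edge], root: str = ROOT
) -> dict[str, float]:
    gt_nodes = sorted(nodes_of(gt_edges, root) - {root})
    gt_paths = [p for n in gt_nodes for p in all_paths(gt_edges, n, root)]

    recall_terms: list[float] = []
    precision_terms: list[float] = []
    acc_hits = 0
    aec_total = 0.0
    matched = 0
    for gp in gt_paths:
        gt_set = _node_set(gp)
        mp = best_match(gp, rec_edges, root)
        if mp is None:
            recall_terms.append(0.0)
            aec_total += len(gt_set)
            continue
        matched += 1
        m_set = _node_set(mp)
        shared = gt_set & m_set
        recall_terms.append(len(shared) / len(gt_set))
        precision_terms.append(len(shared) / len(m_set))
        aec_total += len(gt_set ^ m_set)
        if shared:
            acc_hits += 1

    h_r = sum(recall_terms) / len(recall_terms) if recall_terms else 0.0
    h_p = (
        sum(precision_terms) / len(precision_terms) if precision_terms else 0.0
    )
    h_f1 = 2 * h_p * h_r / (h_p + h_r) if (h_p + h_r) > 0 else 0.0
    h_acc = acc_hits / len(gt_paths) if gt_paths else 0.0
    aec = aec_total / len(gt_paths) if gt_paths else 0.0

    rec_nodes = nodes_of(rec_edges, root) - {root}
    term_acc = (
        len(set(gt_nodes) & rec_nodes) / len(gt_nodes) if gt_nodes else 1.0
    )
    gt_lv = leaves_of(gt_edges, root) - {root}
    rec_lv = leaves_of(rec_edges, root) - {root}
    leaf_acc = len(gt_lv & rec_lv) / len(gt_lv) if gt_lv else 1.0

    # LCA preservation over unordered pairs of non-root ground-truth nodes
    pairs = [
        (a, b)
        for i, a in enumerate(gt_nodes)
        for b in gt_nodes[i + 1 :]
    ]
    preserved = 0
    for a, b in pairs:
        if a not in rec_nodes or b not in rec_nodes:
            continue
        if lca_brute(gt_edges, a, b, root) & lca_brute(rec_edges, a, b, root):
            preserved += 1
    lca = preserved / len(pairs) if pairs else 1.0

    return {
        "term_accuracy": term_acc,
        "hierarchical_precision": h_p,
        "hierarchical_recall": h_r,
        "hierarchical_f1": h_f1,
        "hierarchical_accuracy": h_acc,
        "ancestor_error_count": aec,
        "lca_preservation": lca,
        "leaf_accuracy": leaf_acc,
        "kg_accuracy": (
            len(gt_lv & rec_lv) / len(gt_lv) if gt_lv else 1.0
        ),
        "matched_path_count": matched,
        "gt_path_count": len(gt_paths),
    }


def lca_brute(
    edges: set[Edge], a: str, b: str, root: str = ROOT
) -> set[str]:
    common = ancestors_of(edges, a, root) & ancestors_of(edges, b, root)
    return {
        c
        for c in common
        if not any(c2 != c and reachable(edges, c, c2) for c2 in common)
    }


# ---------------------------------------------------------------------------
# Random rooted-DAG generation (sequential attachment => always acyclic)
# ---------------------------------------------------------------------------


def random_dag(
    rng: random.Random,
    node_pool: list[str],
    max_nodes: int = 12,
    multiparent_rate: float = 0.3,
    root: str = ROOT,
) -> set[Edge]:
    n = rng.randint(1, max(1, max_nodes - 1))
    picked = rng.sample(node_pool, min(n, len(node_pool)))
    placed = [root]
    edges: set[Edge] = set()
    for name in picked:
        parent = rng.choice(placed)
        edges.add((name, parent))
        if len(placed) > 1 and rng.random() < multiparent_rate:
            second = rng.choice(placed)
            if second != parent and second != name:
                edges.add((name, second))
        placed.append(name)
    return edges


def random_dag_pair(
    rng: random.Random, max_nodes: int = 12, multiparent_rate: float = 0.3
) -> tuple[set[Edge], set[Edge]]:
    """A ground-truth DAG and an overlapping 'reconstruction' DAG."""
    pool = [f"n{i}" for i in range(max_nodes + 4)]
    gt = random_dag(rng, pool, max_nodes, multiparent_rate)
    # reconstruction draws mostly from ground-truth nodes plus a few extras
    gt_nodes = sorted(nodes_of(gt) - {ROOT})
    extras = [x for x in pool if x not in gt_nodes]
    rng.shuffle(gt_nodes)
    rec_pool = gt_nodes + extras[: rng.randint(0, 3)]
    rec = random_dag(rng, rec_pool, max_nodes, multiparent_rate)
    return gt, rec
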