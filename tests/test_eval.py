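"""Hierarchical metric suite vs hand-derived values and the brute-force oracle."""

import random

import pytest

from litkg import (
    KnowledgeGraph,
    MetricsConfig,
    Taxonomy,
    ValidationError,
    ancestor_error_count,
    evaluate,
    hierarchical_metrics,
    lca_preservation,
    lca_set,
    match_path,
    set_accuracies,
)

from .oracle import ROOT, brute_metrics, nodes_of, random_dag_pair, reachable


def taxonomy_of(edges) -> Taxonomy:
    return Taxonomy.from_edges(edges)


CHAIN_GT = [("a", "thing"), ("b", "a"), ("c", "b")]
CHAIN_REC = [("a", "thing"), ("c", "a")]  # b missing, c lifted under a


class TestMatchPath:
    def test_absent_endpoint_gives_no_match(self):
        gt = taxonomy_of(CHAIN_GT)
        rec = taxonomy_of([("a", "thing")])
        path = gt.enumerate_root_paths("c")[0]
        assert match_path(path, rec) is None

    def test_identity_returns_identical_path(self, diamond_taxonomy):
        for node in diamond_taxonomy.nodes - {"thing"}:
            for path in diamond_taxonomy.enumerate_root_paths(node):
                assert match_path(path, diamond_taxonomy).nodes == path.nodes

    def test_diamond_prefers_branch_with_larger_overlap(self):
        gt = taxonomy_of([("a", "thing"), ("x", "a"), ("c", "x")])
        rec = taxonomy_of(
            [("a", "thing"), ("b", "thing"), ("x", "a"), ("c", "x"), ("c", "b")]
        )
        gt_path = gt.enumerate_root_paths("c")[0]  # thing,a,x,c shares 3 vs 1
        assert match_path(gt_path, rec).nodes == ("thing", "a", "x", "c")


class TestHierarchicalMetrics:
    def test_identity_is_all_ones(self, planted_small):
        gt = planted_small.schema.taxonomy
        h_p, h_r, h_f1, h_acc = hierarchical_metrics(gt, gt)
        assert (h_p, h_r, h_f1, h_acc) == (1.0, 1.0, 1.0, 1.0)
        assert ancestor_error_count(gt, gt) == 0.0
        assert lca_preservation(gt, gt) == 1.0

    def test_root_only_reconstruction_vacuity(self):
        gt = taxonomy_of(CHAIN_GT)
        report = evaluate(gt, Taxonomy())
        assert report.hierarchical_recall == 0.0
        assert report.hierarchical_accuracy == 0.0
        assert report.term_accuracy == 0.0
        assert report.hierarchical_precision == 0.0
        assert report.matched_path_count == 0
        # gt paths have root-excluded sizes 1, 2, 3
        assert report.ancestor_error_count == pytest.approx(2.0)

    def test_chain_example_hand_derived_values(self):
        """gt thing->a->b->c vs rec {a isA thing, c isA a}.

        Paths: a:{a} matched exactly; b: unmatched; c:{a,b,c} matched
        {a,c} -> recall 2/3, precision 1.  Hence hR = (1+0+2/3)/3, hP = 1,
        hAcc = 2/3, AEC = (0+2+1)/3.
        """
        gt, rec = taxonomy_of(CHAIN_GT), taxonomy_of(CHAIN_REC)
        h_p, h_r, h_f1, h_acc = hierarchical_metrics(gt, rec)
        assert h_r == pytest.approx(5 / 9)
        assert h_p == pytest.approx(1.0)
        assert h_acc == pytest.approx(2 / 3)
        assert h_f1 == pytest.approx(2 * (5 / 9) / (1 + 5 / 9))
        assert ancestor_error_count(gt, rec) == pytest.approx(1.0)
        # and the brute-force oracle agrees
        brute = brute_metrics(set(CHAIN_GT), set(CHAIN_REC))
        assert brute["hierarchical_recall"] == pytest.approx(h_r)
        assert brute["hierarchical_precision"] == pytest.approx(h_p)
        assert brute["ancestor_error_count"] == pytest.approx(1.0)

    def test_differing_roots_rejected(self):
        gt = taxonomy_of(CHAIN_GT)
        with pytest.raises(ValidationError):
            hierarchical_metrics(gt, Taxonomy(root="entity"))

    def test_micro_precision_variant_and_identity(self):
        cfg = MetricsConfig(precision_average="micro")
        gt, rec = taxonomy_of(CHAIN_GT), taxonomy_of(CHAIN_REC)
        h_p_micro, *_ = hierarchical_metrics(gt, rec, cfg)
        assert h_p_micro == pytest.approx(3 / 3)  # shared 1+2 over sizes 1+2
        assert hierarchical_metrics(gt, gt, cfg)[0] == 1.0

    def test_one_sided_aec_never_exceeds_symmetric(self):
        cfg = MetricsConfig(aec_symmetric=False)
        rng = random.Random(2)
        for _ in range(20):
            gt_e, rec_e = random_dag_pair(rng)
            gt, rec = taxonomy_of(gt_e), taxonomy_of(rec_e)
            assert ancestor_error_count(gt, rec, cfg) <= ancestor_error_count(
                gt, rec
            )


class TestLca:
    def test_sibling_pair_not_preserved_when_nested(self):
        gt = taxonomy_of([("a", "thing"), ("b", "thing")])
        rec = taxonomy_of([("a", "thing"), ("b", "a")])
        assert lca_set(gt, "a", "b") == {"thing"}
        assert lca_set(rec, "a", "b") == {"a"}
        assert lca_preservation(gt, rec) == 0.0

    def test_missing_node_breaks_preservation(self):
        gt = taxonomy_of([("a", "thing"), ("b", "thing")])
        rec = taxonomy_of([("a", "thing")])
        assert lca_preservation(gt, rec) == 0.0

    def test_node_is_its_own_ancestor(self, chain_taxonomy):
        assert lca_set(chain_taxonomy, "a", "c") == {"a"}

    def test_dag_lca_is_a_set(self):
        t = taxonomy_of(
            [
                ("a", "thing"),
                ("b", "thing"),
                ("x", "a"),
                ("x", "b"),
                ("y", "a"),
                ("y", "b"),
            ]
        )
        assert lca_set(t, "x", "y") == {"a", "b"}


class TestSetAccuracies:
    def test_missing_one_of_four_terms(self):
        gt = taxonomy_of(
            [("a", "thing"), ("b", "thing"), ("c", "a"), ("d", "a")]
        )
        rec = taxonomy_of([("a", "thing"), ("b", "thing"), ("c", "a")])
        term, _, _ = set_accuracies(gt, rec)
        assert term == pytest.approx(0.75)

    def test_instance_surviving_as_class_counts_for_terms_not_kg(self):
        # 6-node fixture: gt leaf 'd' is internal in the reconstruction
        gt = taxonomy_of(
            [("a", "thing"), ("b", "a"), ("c", "a"), ("d", "b")]
        )
        rec = taxonomy_of(
            [("a", "thing"), ("b", "a"), ("c", "a"), ("d", "b"), ("e", "d")]
        )
        term, leaf, kg = set_accuracies(gt, rec)
        assert term == 1.0
        assert kg == pytest.approx(0.5)  # of gt instances {c, d}, only c
        assert leaf == pytest.approx(0.5)

    def test_explicit_kg_objects_override_leaves(self):
        gt = taxonomy_of([("a", "thing"), ("b", "a")])
        gt_kg = KnowledgeGraph(instances={"b"}, instance_of={("b", "a")})
        rec_kg = KnowledgeGraph(instances=set())
        _, _, kg_acc = set_accuracies(gt, gt, gt_kg, rec_kg)
        assert kg_acc == 0.0


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force_on_random_dag_pairs(self):
        rng = random.Random(41)
        for _ in range(60):
            gt_e, rec_e = random_dag_pair(rng, max_nodes=10)
            report = evaluate(taxonomy_of(gt_e), taxonomy_of(rec_e))
            brute = brute_metrics(gt_e, rec_e)
            for key, expected in brute.items():
                assert getattr(report, key) == pytest.approx(
                    expected, abs=1e-9
                ), key

    def test_hacc_equals_path_weighted_term_presence(self):
        rng = random.Random(43)
        for _ in range(30):
            gt_e, rec_e = random_dag_pair(rng)
            gt, rec = taxonomy_of(gt_e), taxonomy_of(rec_e)
            paths = gt.all_root_paths()
            weighted = sum(
                1 for p in paths if rec.has_node(p.endpoint)
            ) / len(paths)
            _, _, _, h_acc = hierarchical_metrics(gt, rec)
            assert h_acc == pytest.approx(weighted)

    def test_deleting_an_edge_never_increases_recall(self):
        """Pruning a correct subtree edge can only lose hierarchy credit."""
        rng = random.Random(47)
        for _ in range(15):
            gt_e, _ = random_dag_pair(rng, multiparent_rate=0.0)
            gt = taxonomy_of(gt_e)
            base_recall = hierarchical_metrics(gt, gt)[1]
            victim = rng.choice(sorted(gt_e))
            keep = {e for e in gt_e if e != victim}
            # drop whatever became unreachable from the root
            still = {
                e
                for e in keep
                if reachable(keep | {(victim[0], victim[0])}, ROOT, e[1])
                or e[1] == ROOT
            }
            reachable_nodes = {
                n for n in nodes_of(still) if n == ROOT or reachable(still, ROOT, n)
            }
            still = {
                (c, p)
                for c, p in still
                if c in reachable_nodes and p in reachable_nodes
            }
            rec = taxonomy_of(still)
            assert hierarchical_metrics(gt, rec)[1] <= base_recall


class TestReportShape:
    def test_fractions_bounded_and_table_renders(self):
        rng = random.Random(53)
        for _ in range(20):
            gt_e, rec_e = random_dag_pair(rng)
            report = evaluate(taxonomy_of(gt_e), taxonomy_of(rec_e))
            for name in (
                "term_accuracy",
                "hierarchical_precision",
                "hierarchical_recall",
                "hierarchical_f1",
                "hierarchical_accuracy",
                "lca_preservation",
                "leaf_accuracy",
                "kg_accuracy",
            ):
                assert 0.0 <= getattr(report, name) <= 1.0
            assert report.ancestor_error_count >= 0.0
            assert "Hierarchical F1" in report.format_table()
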