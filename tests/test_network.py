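"""Co-expression networks: gating, correlation, thresholding, centralities."""

import numpy as np
import pandas as pd
import pytest

import uskit
from uskit.dgea import NormalizedExpression
from uskit.network import (
    CorrelationMatrix,
    betweenness_centrality,
    build_graph,
    centrality_table,
    compare_groups,
    correlation_matrix,
    degree_centrality,
    normality_gate,
    rank_hubs_bottlenecks,
    threshold_edges,
)

from _oracles import betweenness_by_path_enumeration, spearman_rank_then_pearson


def _norm(values: np.ndarray, genes, groups):
    frame = pd.DataFrame(
        values, index=[f"s{i}" for i in range(len(values))], columns=list(genes)
    )
    return NormalizedExpression(
        values=frame, groups=pd.Series(list(groups), index=frame.index)
    )


class TestNormalityGate:
    def test_lognormal_noise_selects_spearman(self, rng):
        values = np.exp(rng.normal(0, 1.5, size=(40, 6)))
        norm = _norm(values, "abcdef", ["responder"] * 20 + ["non_responder"] * 20)
        method, report = normality_gate(norm)
        assert method == "spearman"
        assert not report["normal"].all()

    def test_clean_gaussian_can_pass_as_pearson(self, rng):
        # positive near-Gaussian data with ample Shapiro-Wilk margin
        values = 10 + rng.normal(0, 0.05, size=(30, 2))
        norm = _norm(values, "ab", ["responder"] * 15 + ["non_responder"] * 15)
        method, report = normality_gate(norm, alpha=1e-6)
        assert method == "pearson"
        assert report["normal"].all()

    def test_constant_gene_counts_as_non_normal(self, rng):
        values = np.column_stack(
            [np.ones(12), 10 + rng.normal(0, 1, 12)]
        )
        norm = _norm(values, "ab", ["responder"] * 6 + ["non_responder"] * 6)
        with pytest.warns(RuntimeWarning, match="constant"):
            method, _ = normality_gate(norm)
        assert method == "spearman"


class TestCorrelationMatrix:
    def test_monotone_pair_is_perfectly_correlated(self):
        x = np.arange(1.0, 9.0)
        values = np.column_stack([x, np.exp(x), 100 - x]) + 0.0
        norm = _norm(values, "abc", ["responder"] * 8)
        corr = correlation_matrix(norm, ["a"], "spearman", "responder")
        assert corr.rho.at["a", "b"] == pytest.approx(1.0)
        assert corr.rho.at["a", "c"] == pytest.approx(-1.0)

    def test_known_rank_correlation_value(self):
        values = np.column_stack([[1, 2, 3, 4, 5], [3, 1, 2, 5, 4]]).astype(float)
        norm = _norm(values, "ab", ["responder"] * 5)
        corr = correlation_matrix(norm, ["a"], "spearman", "responder")
        assert corr.rho.at["a", "b"] == pytest.approx(0.6)

    def test_spearman_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            values = np.column_stack([np.exp(-x), np.exp(-y)])
            norm = _norm(values, "ab", ["responder"] * n)
            corr = correlation_matrix(norm, ["a"], "spearman", "responder")
            expected = spearman_rank_then_pearson(np.exp(-x), np.exp(-y))
            assert corr.rho.at["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_spearman_invariant_under_monotone_expression_transform(self, cohort, panel):
        # rank correlation ignores any strictly monotone per-gene rescaling,
        # so dCt-scale and expression-scale analyses agree
        norm = uskit.normalize_delta_ct(cohort, panel)
        genes = ["BCL6", "CRP", "IL23A"]
        corr_expr = correlation_matrix(norm, genes, "spearman", "responder")
        # cube is strictly increasing on positives: same ranks, same rho
        raw = NormalizedExpression(values=norm.values ** 3, groups=cohort.groups)
        corr_ct = correlation_matrix(raw, genes, "spearman", "responder")
        assert np.allclose(
            corr_expr.rho.to_numpy(), corr_ct.rho.to_numpy(), atol=1e-12
        )

    def test_too_few_samples_rejected(self):
        values = np.ones((4, 2)) + np.arange(8).reshape(4, 2)
        norm = _norm(values, "ab", ["responder"] * 2 + ["non_responder"] * 2)
        with pytest.raises(ValueError, match="fewer than 3"):
            correlation_matrix(norm, ["a"], "spearman", "responder")


class TestThresholdEdges:
    def _corr(self, rho):
        genes = [f"g{i}" for i in range(len(rho))]
        frame = pd.DataFrame(rho, index=genes, columns=genes)
        return CorrelationMatrix(rho=frame, method="spearman", group="responder")

    def test_exact_cutoff_excluded_by_strict_rule(self):
        rho = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert threshold_edges(self._corr(rho)) == []
        inclusive = threshold_edges(self._corr(rho), strict=False)
        assert [(a, b) for a, b, _ in inclusive] == [("g0", "g1")]

    def test_negative_correlation_kept_with_sign(self):
        rho = np.array([[1.0, -0.95], [-0.95, 1.0]])
        edges = threshold_edges(self._corr(rho))
        assert edges == [("g0", "g1", -0.95)]

    def test_identity_matrix_yields_no_edges(self):
        assert threshold_edges(self._corr(np.eye(4))) == []

    def test_edge_count_monotone_in_cutoff(self, rng):
        raw = rng.uniform(-1, 1, size=(6, 6))
        rho = (raw + raw.T) / 2
        np.fill_diagonal(rho, 1.0)
        counts = [
            len(threshold_edges(self._corr(rho), cutoff=c))
            for c in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCentralities:
    def test_star_center_degree_and_betweenness(self):
        edges = [("HUB", f"leaf{i}", 0.95) for i in range(9)]
        graph = build_graph(edges)
        assert degree_centrality(graph)["HUB"] == 9
        assert betweenness_centrality(graph)["HUB"] == pytest.approx(1.0)

    def test_triangle_all_degree_two(self):
        graph = build_graph([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        assert set(degree_centrality(graph).values()) == {2}
        assert set(betweenness_centrality(graph).values()) == {0.0}

    def test_path_graph_middle_node(self):
        graph = build_graph([("A", "B", 1), ("B", "C", 1)])
        bc = betweenness_centrality(graph)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_four_cycle_betweenness(self):
        graph = build_graph(
            [("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("d", "a", 1)]
        )
        bc = betweenness_centrality(graph)
        for v in "abcd":
            assert bc[v] == pytest.approx(1 / 6)

    def test_isolated_nodes_do_not_enter_graph(self):
        graph = build_graph([("a", "b", 1)])
        assert set(graph.nodes()) == {"a", "b"}

    def test_matches_path_enumeration_oracle_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 8))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.45
            ]
            graph = build_graph([(a, b, 1.0) for a, b in edges])
            got = betweenness_centrality(graph)
            expected = betweenness_by_path_enumeration(list(graph.nodes()), edges)
            for v in graph.nodes():
                assert got[v] == pytest.approx(expected[v], abs=1e-12)


class TestRankingAndComparison:
    def test_tied_hubs_share_rank_one(self):
        edges = (
            [("BCL6", f"x{i}", 1) for i in range(9)]
            + [("CRP", f"y{i}", 1) for i in range(9)]
        )
        table = centrality_table(build_graph(edges))
        report = rank_hubs_bottlenecks(table, k=2)
        top = [e for e in report["hubs"] if e["rank"] == 1]
        assert {e["gene"] for e in top} == {"BCL6", "CRP"}
        assert all(e["tied"] for e in top)

    def test_empty_graph_empty_report(self):
        table = centrality_table(build_graph([]))
        assert rank_hubs_bottlenecks(table) == {"hubs": [], "bottlenecks": []}

    def test_k_one_on_star_returns_center(self):
        table = centrality_table(build_graph([("HUB", f"l{i}", 1) for i in range(4)]))
        report = rank_hubs_bottlenecks(table, k=1)
        assert report["hubs"][0]["gene"] == "HUB"

    def test_identical_tables_have_no_unique_genes(self):
        table = centrality_table(build_graph([("a", "b", 1), ("b", "c", 1)]))
        out = compare_groups(table, table)
        assert out["hubs"]["unique_a"] == out["hubs"]["unique_b"] == []
        assert (out["deltas"]["DC_delta"] == 0).all()

    def test_disjoint_graphs_have_empty_intersection(self):
        ta = centrality_table(build_graph([("a", "b", 1)]))
        tb = centrality_table(build_graph([("x", "y", 1)]))
        out = compare_groups(ta, tb)
        assert out["hubs"]["shared"] == []

    def test_planted_modules_recovered_as_group_specific_hubs(self, panel):
        # two-gene modules per group: their genes should top their own
        # group's hub list and not the other's
        from dataclasses import replace

        from uskit.simulate import CoexpressionModule

        spec = uskit.default_cohort_spec(panel)
        spec = replace(
            spec,
            modules=(
                CoexpressionModule(
                    ("BCL6", "CRP"), scope="responder", loading=3.5, anchor_factor=1.0
                ),
                CoexpressionModule(
                    ("CCL11", "CCL22"), scope="non_responder",
                    loading=3.5, anchor_factor=1.0,
                ),
            ),
        )
        cohort = uskit.generate_cohort(spec, seed=2)
        norm = uskit.normalize_delta_ct(cohort, panel)
        table = uskit.run_dgea(cohort, panel)
        cand = uskit.select_candidates(table, ("TNFSF14",))
        tables = {}
        for group in ("responder", "non_responder"):
            corr = correlation_matrix(norm, cand, "spearman", group)
            tables[group] = centrality_table(build_graph(threshold_edges(corr)))
        out = compare_groups(tables["responder"], tables["non_responder"], k=3)
        assert {"BCL6", "CRP"} <= set(out["hubs"]["unique_a"])
        assert {"CCL11", "CCL22"} <= set(out["hubs"]["unique_b"])
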