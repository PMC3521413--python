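"""Edge-type weight learning: chi-square, log-odds, normalization, contrast,
boundary suppression."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from betop._constants import AMINO_ACIDS, EPITOPE, NON_EPITOPE, BOUNDARY
from betop.surface_graph import NodeData, SurfaceGraph
from betop.weights import (
    ALL_PAIR_TYPES, BoundaryModel, ContrastParams, apply_weights,
    boundary_model, build_weight_table, chi2_stat, contrast, count_edge_types,
    log_odds, normalize_and_combine,
)


def _graph(node_specs, edge_pairs):
    """node_specs: list of (aa, label); edges by node index."""
    g = SurfaceGraph()
    keys = []
    for i, (aa, label) in enumerate(node_specs):
        key = ("A", i + 1, "")
        g.nodes[key] = NodeData(aa, np.zeros(3), label)
        keys.append(key)
    for i, j in edge_pairs:
        g.add_edge(keys[i], keys[j])
    return g


class TestCounting:
    def test_triangle_counts_by_edge_class(self):
        g = _graph([("Q", EPITOPE), ("Q", EPITOPE), ("R", NON_EPITOPE)],
                   [(0, 1), (0, 2), (1, 2)])
        epi = count_edge_types([g], (EPITOPE, NON_EPITOPE))
        assert epi.counts[("Q", "Q")] == (1, 0)
        bnd = count_edge_types([g], (BOUNDARY, EPITOPE))
        assert bnd.counts[("Q", "R")] == (2, 0)
        assert bnd.counts[("Q", "Q")] == (0, 1)

    def test_exactly_210_keys(self):
        g = _graph([("Q", EPITOPE), ("Q", EPITOPE)], [(0, 1)])
        counts = count_edge_types([g], (EPITOPE, NON_EPITOPE))
        assert len(counts.counts) == 210 == len(ALL_PAIR_TYPES)

    def test_empty_graph_list_errors(self):
        with pytest.raises(ValueError):
            count_edge_types([], (EPITOPE, NON_EPITOPE))

    def test_single_class_graph_zero_other_column(self):
        g = _graph([("Q", EPITOPE), ("Y", EPITOPE)], [(0, 1)])
        counts = count_edge_types([g], (EPITOPE, NON_EPITOPE))
        assert counts.totals() == (1, 0)


class TestChi2:
    def test_hand_contingency_example(self):
        # N=(10,10), class totals (100,300) -> E=(5,15)
        assert chi2_stat(10, 10, 100, 300) == pytest.approx(25 / 5 + 25 / 15)
        assert chi2_stat(10, 10, 100, 300) == pytest.approx(6.667, abs=1e-3)

    def test_observed_equals_expected_is_zero(self):
        assert chi2_stat(5, 15, 100, 300) == pytest.approx(0.0)

    def test_absent_type_is_zero(self):
        assert chi2_stat(0, 0, 100, 300) == 0.0

    @given(st.integers(0, 50), st.integers(0, 50))
    @settings(deadline=None)
    def test_nonnegative_and_class_order_symmetric(self, n1, n2):
        v = chi2_stat(n1, n2, 100, 200)
        assert v >= 0.0
        assert v == pytest.approx(chi2_stat(n2, n1, 200, 100))


class TestLogOdds:
    def test_simple_ratio(self):
        # frequencies 0.02 vs 0.01 with negligible smoothing
        v = log_odds(2000, 1000, 100000, 100000, pseudocount=0.0)
        assert v == pytest.approx(math.log(2), rel=1e-9)

    def test_equal_frequencies_zero(self):
        assert log_odds(10, 10, 100, 100) == pytest.approx(0.0)

    def test_zero_count_finite_negative(self):
        v = log_odds(0, 50, 1000, 1000)
        assert math.isfinite(v) and v < 0


class TestNormalizeCombine:
    def _tables(self):
        rng = np.random.default_rng(0)
        keys = ALL_PAIR_TYPES
        return ({k: float(v) for k, v in zip(keys, rng.uniform(0, 9, 210))},
                {k: float(v) for k, v in zip(keys, rng.normal(0, 2, 210))})

    def test_alpha_endpoints(self):
        c, l = self._tables()
        only_chi = normalize_and_combine(c, l, alpha=1.0)
        only_lo = normalize_and_combine(c, l, alpha=0.0)
        cmin, cmax = min(c.values()), max(c.values())
        k = ALL_PAIR_TYPES[7]
        assert only_chi[k] == pytest.approx((c[k] - cmin) / (cmax - cmin))
        lmin, lmax = min(l.values()), max(l.values())
        assert only_lo[k] == pytest.approx((l[k] - lmin) / (lmax - lmin))

    def test_joint_maximum_is_one(self):
        c, l = self._tables()
        k = ALL_PAIR_TYPES[0]
        c[k] = max(c.values()) + 1
        l[k] = max(l.values()) + 1
        assert normalize_and_combine(c, l, 0.3)[k] == pytest.approx(1.0)

    def test_convex_between_components(self):
        c, l = self._tables()
        nc = normalize_and_combine(c, l, 1.0)
        nl = normalize_and_combine(c, l, 0.0)
        mixed = normalize_and_combine(c, l, 0.3)
        for k in ALL_PAIR_TYPES:
            lo, hi = sorted((nc[k], nl[k]))
            assert lo - 1e-12 <= mixed[k] <= hi + 1e-12

    def test_constant_table_becomes_half(self):
        c = {k: 2.0 for k in ALL_PAIR_TYPES}
        _, l = self._tables()
        out = normalize_and_combine(c, l, 1.0)
        assert all(v == pytest.approx(0.5) for v in out.values())


class TestContrast:
    def test_midpoint(self):
        assert contrast(0.5, ContrastParams(3, 3)) == pytest.approx(0.25)

    def test_three_quarters(self):
        assert contrast(0.75, ContrastParams(3, 3)) == pytest.approx(0.9)

    def test_limits(self):
        assert contrast(0.0) == pytest.approx(0.0, abs=1e-8)
        assert contrast(1.0) == pytest.approx(1.0, abs=1e-8)

    def test_strictly_monotone_on_grid(self):
        grid = np.linspace(0.0005, 0.9995, 1000)
        vals = [contrast(w) for w in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))


def _labeled_training_graphs(seed=0, n_graphs=6):
    """Small labeled graphs with planted QQ/DD enrichment in epitope edges."""
    rng = np.random.default_rng(seed)
    graphs = []
    enriched = list("QD")
    background = [a for a in AMINO_ACIDS]
    for _ in range(n_graphs):
        specs = []
        for i in range(10):
            specs.append((rng.choice(enriched), EPITOPE))
        for i in range(20):
            specs.append((rng.choice(background), NON_EPITOPE))
        edges = set()
        # dense epitope block, sparse background, a few boundary edges
        for i in range(10):
            for j in range(i + 1, 10):
                if rng.random() < 0.6:
                    edges.add((i, j))
        for i in range(10, 30):
            for j in range(i + 1, 30):
                if rng.random() < 0.15:
                    edges.add((i, j))
        for i in range(10):
            edges.add((i, int(rng.integers(10, 30))))
        graphs.append(_graph(specs, edges))
    return graphs


class TestBoundaryModel:
    def test_score_is_max_of_contrasts(self):
        graphs = _labeled_training_graphs()
        bm = boundary_model(graphs)
        assert all(0.0 <= v <= 1.0 for v in bm.boundary_score.values())

    def test_percentile_100_suppresses_nothing(self):
        graphs = _labeled_training_graphs()
        bm = boundary_model(graphs, w0_percentile=100.0)
        assert bm.suppressed_types() == set()

    def test_no_boundary_edges_errors(self):
        g = _graph([("Q", EPITOPE), ("Q", EPITOPE)], [(0, 1)])
        with pytest.raises(ValueError):
            boundary_model([g])


class TestApplyWeights:
    def test_suppressed_type_removed(self):
        graphs = _labeled_training_graphs()
        wt = build_weight_table(graphs)
        bm = boundary_model(graphs, w0_percentile=60.0)
        suppressed = bm.suppressed_types()
        assert suppressed  # study conditions do produce suppressible types
        g = graphs[0]
        out = apply_weights(g, wt, bm, suppress=True)
        assert all(d.edge_type not in suppressed for d in out.edges.values())

    def test_no_suppression_keeps_topology_and_sets_weights(self):
        graphs = _labeled_training_graphs()
        wt = build_weight_table(graphs)
        g = graphs[1]
        out = apply_weights(g, wt, boundary=None)
        assert set(out.edges) == set(g.edges)
        assert all(d.weight is not None and 0 <= d.weight <= 1
                   for d in out.edges.values())

    def test_infinite_threshold_equals_no_suppression(self):
        graphs = _labeled_training_graphs()
        wt = build_weight_table(graphs)
        bm = boundary_model(graphs)
        bm_inf = BoundaryModel(boundary_score=bm.boundary_score, w0=float("inf"))
        g = graphs[2]
        a = apply_weights(g, wt, bm_inf, suppress=True)
        b = apply_weights(g, wt, boundary=None)
        assert set(a.edges) == set(b.edges)
        assert all(a.edges[k].weight == b.edges[k].weight for k in a.edges)


class TestParameterRecovery:
    def test_log_odds_sign_recovers_planted_enrichment(self):
        """Types planted as epitope-enriched should learn positive log-odds."""
        graphs = _labeled_training_graphs(seed=3, n_graphs=12)
        wt = build_weight_table(graphs)
        enriched_types = [("D", "Q"), ("Q", "Q"), ("D", "D")]
        signs = [wt.log_odds[t] > 0 for t in enriched_types]
        assert sum(signs) >= len(signs) - 0  # all planted pair types positive

    def test_weight_table_has_210_pairs_and_20_singles(self):
        wt = build_weight_table(_labeled_training_graphs())
        assert len(wt.combined) == 210
        assert len(wt.singles) == 20
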