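"""Correlation primitives, pair screening, regulator attribution, assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hiergrn.expression import ExpressionMatrix
from hiergrn.grn import (
    GRNParams,
    HierarchicalGRN,
    HierarchicalGRNModel,
    TripleTestResult,
    assemble_three_layer_grn,
    attribute_pairs_to_regulators,
    edges_from_triples,
    find_coexpressed_pairs,
    partial_correlation,
    pearson_with_p,
    summarize_grn,
)
from hiergrn.simulate import PlantedGRN, SimulationConfig, simulate_time_course

from conftest import make_passing_triple


def residual_partial_correlation(x, y, z):
    """Independent route: correlation of least-squares residuals on z."""
    zc = np.column_stack([np.ones_like(z), z])
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def matrix_from_rows(rows: dict) -> ExpressionMatrix:
    genes = list(rows)
    vals = np.array([rows[g] for g in genes], dtype=float)
    n = vals.shape[1]
    tp = [float(i) for i in range(n)]
    return ExpressionMatrix.from_arrays(genes, vals, tp, [1] * n)


class TestPearsonWithP:
    def test_identity_and_antisymmetry(self):
        x = np.arange(7, dtype=float)
        r, p = pearson_with_p(x, x)
        assert r == pytest.approx(1.0, abs=1e-12) and p == 0.0
        r, p = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0, abs=1e-12) and p == 0.0

    def test_matches_closed_form_definitions(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7], dtype=float)
        y = np.array([2, 1, 4, 3, 6, 5, 8], dtype=float)
        r, p = pearson_with_p(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_ref = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        t_ref = r_ref * math.sqrt(5 / (1 - r_ref**2))
        p_ref = 2 * stats.t.sf(abs(t_ref), df=5)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_with_p([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialCorrelation:
    def test_constructed_cancellation(self):
        # numerator vanishes up to the rounding of 0.8 * 0.8
        assert partial_correlation(0.64, 0.8, 0.8) == pytest.approx(0.0, abs=1e-15)
        # when the numerator arguments share the same rounding, exactly zero
        assert partial_correlation(0.8 * 0.8, 0.8, 0.8) == 0.0

    def test_independent_conditioner_is_identity(self):
        assert partial_correlation(0.73, 0.0, 0.0) == 0.73

    def test_worked_value(self):
        assert partial_correlation(0.9, 0.8, 0.7) == pytest.approx(0.7935, abs=5e-5)

    def test_exchange_symmetry(self, rng):
        for _ in range(50):
            r_xy, r_xz, r_yz = rng.uniform(-0.9, 0.9, 3)
            assert partial_correlation(r_xy, r_xz, r_yz) == pytest.approx(
                partial_correlation(r_xy, r_yz, r_xz))

    def test_equals_residual_correlation_on_random_data(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 51))
            x, y, z = rng.normal(size=(3, n))
            r_xy = np.corrcoef(x, y)[0, 1]
            r_xz = np.corrcoef(x, z)[0, 1]
            r_yz = np.corrcoef(y, z)[0, 1]
            assert partial_correlation(r_xy, r_xz, r_yz) == pytest.approx(
                residual_partial_correlation(x, y, z), abs=1e-10)

    def test_degenerate_conditioner_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation(0.5, 1.0, 0.3)
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation(0.5, 0.3, -1.0)

    def test_clipped_against_overshoot(self):
        assert -1.0 <= partial_correlation(-0.999, 0.9, -0.9) <= 1.0


class TestFindCoexpressedPairs:
    def test_identical_profiles_returned_with_r_one(self, rng):
        prof = rng.normal(size=8)
        m = matrix_from_rows({"a": prof, "b": prof, "c": rng.normal(size=8)})
        pairs = find_coexpressed_pairs(m, ["a", "b", "c"])
        assert [(x, y) for x, y, _, _ in pairs] == [("a", "b")]
        assert pairs[0][2] == pytest.approx(1.0)

    def test_threshold_is_inclusive(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        m = matrix_from_rows({"a": x, "b": y})
        r, p = pearson_with_p(x, y)
        params = GRNParams(r_min=abs(r), p_max=0.999999, partial_max=0.0,
                           use_absolute_r=True)
        pairs = find_coexpressed_pairs(m, ["a", "b"], params)
        assert len(pairs) == 1  # r == r_min retained, per the >= rule

    def test_matches_bruteforce_scan_on_noise_genes(self, rng):
        rows = {f"g{i}": rng.normal(size=10) for i in range(10)}
        m = matrix_from_rows(rows)
        params = GRNParams()
        got = {(x, y) for x, y, _, _ in find_coexpressed_pairs(m, rows, params)}
        expected = set()
        names = sorted(rows)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                r, p = stats.pearsonr(rows[a], rows[b])
                if r >= params.r_min and p < params.p_max:
                    expected.add((a, b))
        assert got == expected

    def test_absolute_mode_adds_anticorrelated_pairs(self, rng):
        prof = rng.normal(size=9)
        m = matrix_from_rows({"a": prof, "b": -prof})
        assert find_coexpressed_pairs(m, ["a", "b"]) == []
        pairs = find_coexpressed_pairs(m, ["a", "b"], GRNParams(use_absolute_r=True))
        assert len(pairs) == 1 and pairs[0][2] == pytest.approx(-1.0)

    def test_missing_genes_reported(self, rng):
        m = matrix_from_rows({"a": rng.normal(size=6), "b": rng.normal(size=6)})
        with pytest.raises(KeyError, match="ghost"):
            find_coexpressed_pairs(m, ["a", "ghost"])

    def test_raising_r_min_never_adds_pairs(self, rng):
        rows = {f"g{i}": rng.normal(size=8) for i in range(8)}
        m = matrix_from_rows(rows)
        loose = {(x, y) for x, y, _, _ in find_coexpressed_pairs(
            m, rows, GRNParams(r_min=0.3, p_max=0.9, partial_max=0.1))}
        tight = {(x, y) for x, y, _, _ in find_coexpressed_pairs(
            m, rows, GRNParams(r_min=0.6, p_max=0.9, partial_max=0.1))}
        assert tight <= loose


class TestAttributePairs:
    def test_independent_conditioner_fails(self, rng):
        shared = rng.normal(size=30)
        x = shared + rng.normal(0, 0.3, 30)
        y = shared + rng.normal(0, 0.3, 30)
        z = rng.normal(size=30)
        m = matrix_from_rows({"x": x, "y": y, "z": z})
        pairs = find_coexpressed_pairs(m, ["x", "y"], GRNParams(r_min=0.5, p_max=0.5))
        triples = attribute_pairs_to_regulators(pairs, ["z"], m, GRNParams())
        (t,) = triples
        assert t.r_xy_given_z == pytest.approx(t.r_xy, abs=0.25)
        assert not t.passes

    def test_empty_tf_set_gives_empty_result(self, rng):
        m = matrix_from_rows({"x": rng.normal(size=6), "y": rng.normal(size=6)})
        assert attribute_pairs_to_regulators(
            [("x", "y", 0.9, 1e-5)], [], m, GRNParams()) == []

    def test_true_regulator_passes_on_planted_children(self):
        grn = PlantedGRN(("g",), ("z",), ("x", "y"),
                         {("g", "z"): 1.0, ("z", "x"): 1.0, ("z", "y"): 0.9},
                         seed=0)
        m = simulate_time_course(
            grn, SimulationConfig(seed=11, noise_sd=0.05, intrinsic_sd=0.0))
        pairs = find_coexpressed_pairs(m, ["x", "y"])
        triples = attribute_pairs_to_regulators(pairs, ["z"], m)
        assert len(triples) == 1
        assert abs(triples[0].r_xy_given_z) < 0.3 and triples[0].passes

    def test_larger_partial_max_never_removes_passing_triples(self, rng):
        rows = {f"g{i}": rng.normal(size=12) for i in range(6)}
        m = matrix_from_rows(rows)
        pairs = find_coexpressed_pairs(m, list(rows)[:4],
                                       GRNParams(r_min=0.1, p_max=0.99, partial_max=0.05))
        tfs = list(rows)[4:]
        loose_params = GRNParams(r_min=0.1, p_max=0.99, partial_max=0.09)
        tight_params = GRNParams(r_min=0.1, p_max=0.99, partial_max=0.02)
        loose = {(t.x, t.y, t.z) for t in attribute_pairs_to_regulators(
            pairs, tfs, m, loose_params) if t.passes}
        tight = {(t.x, t.y, t.z) for t in attribute_pairs_to_regulators(
            pairs, tfs, m, tight_params) if t.passes}
        assert tight <= loose


class TestEdgesFromTriples:
    def test_one_triple_two_edges(self):
        edges = edges_from_triples([make_passing_triple("x", "y", "z")])
        assert set(edges) == {("z", "x"), ("z", "y")}

    def test_duplicate_edges_merge_and_accumulate(self):
        t1 = make_passing_triple("x", "y", "z")
        t2 = make_passing_triple("x", "w", "z")
        edges = edges_from_triples([t1, t2])
        assert set(edges) == {("z", "x"), ("z", "y"), ("z", "w")}
        assert len(edges[("z", "x")]) == 2

    def test_empty_input(self):
        assert edges_from_triples([]) == {}

    def test_rejects_non_passing(self):
        bad = TripleTestResult("x", "y", "z", 0.9, 1e-5, 0.5, 0.5, 0.9, passes=False)
        with pytest.raises(ValueError, match="non-passing"):
            edges_from_triples([bad])


class TestAssembleThreeLayerGRN:
    def chain_instance(self, seed=10):
        # noise/intrinsic levels chosen so the chain is identifiable: the
        # middle TFs stay mutually separated below the pair screen while
        # their own pair remains correlated enough for the top-layer pass
        grn = PlantedGRN(
            ("z1",), ("z2a", "z2b"), ("s1", "s2", "s3", "s4"),
            {("z1", "z2a"): 1.0, ("z1", "z2b"): -1.0,
             ("z2a", "s1"): 1.0, ("z2a", "s2"): 0.8,
             ("z2b", "s3"): 1.0, ("z2b", "s4"): 1.2},
            seed=0)
        m = simulate_time_course(
            grn, SimulationConfig(seed=seed, noise_sd=0.35, intrinsic_sd=0.25))
        return grn, m

    def test_two_level_chain_fully_recovered(self):
        grn, m = self.chain_instance()
        out = assemble_three_layer_grn(
            m, ["z1", "z2a", "z2b"], ["s1", "s2", "s3", "s4"],
            GRNParams(use_absolute_r=True))
        assert out.layer1 == {"z1"}
        assert out.layer2 == {"z2a", "z2b"}
        assert out.layer3 == {"s1", "s2", "s3", "s4"}
        assert out.edges_12 == {("z1", "z2a"), ("z1", "z2b")}
        assert out.edges_23 == grn.edges_23
        assert not out.two_layer_warning

    @pytest.mark.parametrize("seed", [3, 10, 17])
    def test_chain_minimum_guarantee_across_seeds(self, seed):
        # regardless of realization, the middle TFs acquire their targets
        grn, m = self.chain_instance(seed)
        out = assemble_three_layer_grn(
            m, ["z1", "z2a", "z2b"], ["s1", "s2", "s3", "s4"],
            GRNParams(use_absolute_r=True))
        assert {"z2a", "z2b"} <= out.layer2
        assert {("z2a", "s1"), ("z2a", "s2"),
                ("z2b", "s3"), ("z2b", "s4")} <= out.edges_23

    def test_independent_structural_genes_give_empty_network(self, rng):
        rows = {f"s{i}": rng.normal(size=21) for i in range(8)}
        rows["tf"] = rng.normal(size=21)
        m = matrix_from_rows(rows)
        out = assemble_three_layer_grn(m, ["tf"], [g for g in rows if g != "tf"])
        assert out.edges == ()
        assert out.layer1 == out.layer2 == out.layer3 == frozenset()
        assert out.two_layer_warning  # fewer than 2 layer-2 TFs

    def test_layering_is_disjoint_and_supported(self):
        grn, m = self.chain_instance()
        out = assemble_three_layer_grn(
            m, ["z1", "z2a", "z2b"], ["s1", "s2", "s3", "s4"],
            GRNParams(use_absolute_r=True))
        assert not (out.layer1 & out.layer2)
        for e in out.edges:
            assert e.triples and all(t.passes and t.z == e.source for t in e.triples)

    def test_deterministic_under_input_order(self):
        grn, m = self.chain_instance()
        a = assemble_three_layer_grn(m, ["z2b", "z1", "z2a"], ["s4", "s1", "s3", "s2"],
                                     GRNParams(use_absolute_r=True))
        b = assemble_three_layer_grn(m, ["z1", "z2a", "z2b"], ["s1", "s2", "s3", "s4"],
                                     GRNParams(use_absolute_r=True))
        assert a.edges_12 == b.edges_12 and a.edges_23 == b.edges_23
        assert (a.layer1, a.layer2, a.layer3) == (b.layer1, b.layer2, b.layer3)

    def test_rejects_overlapping_gene_groups(self, rng):
        m = matrix_from_rows({"a": rng.normal(size=6), "b": rng.normal(size=6)})
        with pytest.raises(ValueError, match="overlap"):
            assemble_three_layer_grn(m, ["a"], ["a", "b"])


class TestModelSurface:
    def test_fit_returns_results_with_summary(self):
        grn = PlantedGRN(
            ("z1",), ("z2a", "z2b"), ("s1", "s2", "s3", "s4"),
            {("z1", "z2a"): 1.0, ("z1", "z2b"): 1.0,
             ("z2a", "s1"): 1.0, ("z2a", "s2"): 1.0,
             ("z2b", "s3"): 1.0, ("z2b", "s4"): 1.0},
            seed=0)
        m = simulate_time_course(
            grn, SimulationConfig(seed=10, noise_sd=0.35, intrinsic_sd=0.25))
        model = HierarchicalGRNModel(m, ["z1", "z2a", "z2b"], ["s1", "s2", "s3", "s4"])
        res = model.fit()
        text = res.summary()
        assert "r_min=0.8" in text and "total edges" in text
        rep = res.score_against(grn)
        assert rep.recall_23 == 1.0 and rep.precision_23 == 1.0

    def test_invalid_thresholds_rejected_before_fitting(self, rng):
        m = matrix_from_rows({"a": rng.normal(size=6), "b": rng.normal(size=6),
                              "t": rng.normal(size=6)})
        model = HierarchicalGRNModel(m, ["t"], ["a", "b"])
        with pytest.raises(ValueError):
            model.fit(r_min=1.5)


def build_synthetic_grn(n12: int, n23: int, n3: int = 158) -> HierarchicalGRN:
    """Network with prescribed edge counts for bookkeeping checks (synthetic)."""
    layer1 = [f"A{i}" for i in range(11)]
    layer2 = [f"B{i}" for i in range(19)]
    layer3 = [f"C{i}" for i in range(n3)]
    from hiergrn.grn import GRNEdge

    edges = []
    k = 0
    for i in range(n12):
        s, t = layer1[i % 11], layer2[i % 19]
        while any(e.source == s and e.target == t for e in edges):
            k += 1
            t = layer2[(i + k) % 19]
        edges.append(GRNEdge(s, t, "1->2",
                             (make_passing_triple(t, f"B{(i+1) % 19}", s),)))
    k = 0
    for i in range(n23):
        s, t = layer2[i % 19], layer3[i % n3]
        while any(e.source == s and e.target == t for e in edges):
            k += 1
            t = layer3[(i + k) % n3]
        edges.append(GRNEdge(s, t, "2->3",
                             (make_passing_triple(t, f"C{(i+1) % n3}", s),)))
    return HierarchicalGRN(frozenset(layer1), frozenset(layer2), frozenset(layer3),
                           tuple(edges))


class TestSummarizeGRN:
    def test_edge_totals_add_up(self):
        grn = build_synthetic_grn(65, 1804)
        s = summarize_grn(grn)
        assert (s.n_edges_12, s.n_edges_23, s.total_edges) == (65, 1804, 1869)
        assert (s.n_layer1, s.n_layer2, s.n_layer3) == (11, 19, 158)

    def test_go_subset_percentage(self):
        grn = build_synthetic_grn(10, 158)
        layer3 = sorted(grn.layer3)
        terms = ["hormoneA", "hormoneB", "hormoneC"]
        annotation = {g: {terms[i % 3]} for i, g in enumerate(layer3[:45])}
        for g in layer3[45:]:
            annotation[g] = {"other"}
        s = summarize_grn(grn, annotation, subset_terms=terms)
        assert s.subset_count == 45
        assert s.subset_pct == 28.5

    def test_empty_network_gives_zero_counts(self):
        grn = HierarchicalGRN(frozenset(), frozenset(), frozenset(), ())
        s = summarize_grn(grn, annotation={}, subset_terms=["x"])
        assert s.total_edges == 0
        assert math.isnan(s.subset_pct)
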