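"""Network feature extraction and association statistics."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from paraloc import network as net


@pytest.fixture
def gi_table():
    return pd.DataFrame(
        [
            {"gene_a": "a", "gene_b": "b", "epsilon": -0.15, "p": 0.01},
            {"gene_a": "c", "gene_b": "d", "epsilon": 0.10, "p": 0.2},
            {"gene_a": "e", "gene_b": "f", "epsilon": -0.40, "p": 0.01},
            {"gene_a": "g", "gene_b": "h", "epsilon": 0.20, "p": 0.04},
            {"gene_a": "i", "gene_b": "j", "epsilon": -0.10, "p": 0.03},
        ]
    )


class TestGISubsets:
    def test_rule_application(self, gi_table):
        stringent = net.gi_subset(gi_table, "stringent")
        assert set(zip(stringent.gene_a, stringent.gene_b)) == {("a", "b"), ("e", "f"), ("g", "h")}

    def test_p_gate_excludes(self, gi_table):
        lenient = net.gi_subset(gi_table, "lenient")
        assert ("c", "d") not in set(zip(lenient.gene_a, lenient.gene_b))

    def test_strong_negative_in_all_four(self, gi_table):
        for level in net.GI_LEVELS:
            sub = net.gi_subset(gi_table, level)
            assert ("e", "f") in set(zip(sub.gene_a, sub.gene_b))

    def test_nesting(self, gi_table):
        def keys(level):
            sub = net.gi_subset(gi_table, level)
            return set(zip(sub.gene_a, sub.gene_b))

        assert keys("stringent") <= keys("intermediate") <= keys("lenient")
        assert keys("synthetic_lethal") <= keys("stringent")

    def test_unknown_level_rejected(self, gi_table):
        with pytest.raises(ValueError):
            net.gi_subset(gi_table, "strictest")


class TestSharedInteractors:
    def test_disjoint_neighborhoods(self):
        g = nx.Graph([("a", "x"), ("b", "y")])
        assert net.shared_interactors(g, ("a", "b")) == 0

    def test_set_intersection(self):
        g = nx.Graph([("a", "x"), ("a", "y"), ("a", "z"), ("b", "y"), ("b", "z"), ("b", "w")])
        assert net.shared_interactors(g, ("a", "b")) == 2

    def test_pair_members_excluded(self):
        g = nx.Graph([("a", "b"), ("a", "x"), ("b", "x")])
        assert net.shared_interactors(g, ("a", "b")) == 1

    def test_absent_gene_counts_zero(self):
        assert net.shared_interactors(nx.Graph(), ("a", "b")) == 0

    def test_median_binning_ties_low(self):
        bins = net.bin_by_median({"p": 0, "q": 0, "r": 2, "s": 4})
        # median of {0,0,2,4} is 1 -> counts > 1 are high
        assert bins == {"p": "low", "q": "low", "r": "high", "s": "high"}
        tied = net.bin_by_median({"p": 1, "q": 1, "r": 1})
        assert set(tied.values()) == {"low"}


class TestShortestPath:
    def test_direct_edge_class_one(self):
        g = nx.Graph([("a", "b")])
        assert net.shortest_path_class(g, ("a", "b")) == ("1", 1.0)

    def test_two_hop_path(self):
        g = nx.Graph([("a", "x"), ("x", "b")])
        assert net.shortest_path_class(g, ("a", "b")) == ("1+", 2.0)

    def test_disconnected_components(self):
        g = nx.Graph([("a", "x"), ("b", "y")])
        cls, length = net.shortest_path_class(g, ("a", "b"))
        assert cls == "1+" and math.isinf(length)

    def test_absent_gene_logged_as_missing(self):
        cls, length = net.shortest_path_class(nx.Graph([("x", "y")]), ("a", "b"))
        assert cls == "1+" and math.isnan(length)


class TestJaccard:
    def test_identical_sets(self):
        assert net.jaccard_colocalized({"er"}, {"er"}) == (100.0, True)

    def test_partial_overlap(self):
        idx, coloc = net.jaccard_colocalized({"a", "b"}, {"b", "c"})
        assert idx == pytest.approx(100 / 3)
        assert not coloc

    def test_boundary_inclusive(self):
        idx, coloc = net.jaccard_colocalized({"a"}, {"a", "b"})
        assert idx == 50.0 and coloc

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        universe = list("abcdefgh")
        for _ in range(20):
            sa = set(rng.choice(universe, rng.integers(1, 6), replace=False))
            sb = set(rng.choice(universe, rng.integers(1, 6), replace=False))
            i1, _ = net.jaccard_colocalized(sa, sb)
            i2, _ = net.jaccard_colocalized(sb, sa)
            assert i1 == i2 and 0.0 <= i1 <= 100.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            net.jaccard_colocalized(set(), {"a"})


class TestPrivateInteractors:
    def test_identical_neighborhoods_empty(self):
        g = nx.Graph([("a", "x"), ("b", "x")])
        assert net.private_interactors(g, ("a", "b")) == (set(), set())

    def test_set_difference(self):
        g = nx.Graph([("a", "x"), ("a", "y"), ("b", "y"), ("b", "z")])
        assert net.private_interactors(g, ("a", "b")) == ({"x"}, {"z"})

    def test_sister_excluded(self):
        g = nx.Graph([("a", "b"), ("a", "x")])
        priv_a, priv_b = net.private_interactors(g, ("a", "b"))
        assert "b" not in priv_a and "a" not in priv_b


class TestFisher:
    def test_perfect_association_infinite_or(self):
        from scipy.stats import hypergeom

        flags = [True] * 10 + [False] * 10
        res = net.enrichment_fisher(flags, flags)
        assert res.odds_ratio == math.inf
        # oracle: P(X = 10) * 2 under the hypergeometric null, clipped at 1
        oracle = min(1.0, 2 * hypergeom.pmf(10, 20, 10, 10))
        assert res.p == pytest.approx(oracle, rel=1e-9)

    def test_no_association(self):
        x = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5
        y = [True] * 10 + [False] * 10
        res = net.enrichment_fisher(x, y)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_margin_undefined(self):
        res = net.enrichment_fisher([True, True, False], [False, False, False])
        assert res.odds_ratio is None

    def test_transpose_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(size=50) < 0.4, rng.uniform(size=50) < 0.6
        r1, r2 = net.enrichment_fisher(x, y), net.enrichment_fisher(y, x)
        assert r1.p == pytest.approx(r2.p)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio)

    def test_null_calibration(self):
        # independence: p should not be systematically small
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(300):
            x, y = rng.uniform(size=100) < 0.5, rng.uniform(size=100) < 0.5
            ps.append(net.enrichment_fisher(x, y).p)
        assert np.mean(np.asarray(ps) < 0.05) < 0.1


class TestGroupCompare:
    def test_identical_bins_p_near_one(self):
        scores = {f"p{i}": 1.0 for i in range(10)}
        bins = {f"p{i}": ("a" if i < 5 else "b") for i in range(10)}
        out = net.group_compare(scores, bins)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_shifted_bins_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        for trial in range(40):
            scores = {}
            bins = {}
            for i in range(30):
                scores[f"a{i}"] = rng.normal(0, 1)
                bins[f"a{i}"] = "low"
                scores[f"b{i}"] = rng.normal(2, 1)  # 2 SD shift
                bins[f"b{i}"] = "high"
            if net.group_compare(scores, bins).loc[0, "p"] < 0.01:
                hits += 1
        assert hits / 40 >= 0.95

    def test_empty_bin_skipped(self):
        out = net.group_compare({"x": 1.0}, {"x": "low", "y_unscored": "high"})
        assert out.empty

    def test_planted_association_detected_via_pipeline_tables(self):
        from paraloc import synthetic as syn

        design = syn.demo_design(n_effect_pairs=4, n_control_pairs=4)
        truth = syn.default_truth(design, 0)
        ppi, _, _ = syn.generate_networks(design, truth, seed=9, planted_association=True)
        graph = net.ppi_graph(net.filter_ppi(ppi))
        shared = {}
        scores = {}
        truth_df = truth.to_frame().set_index("protein")
        for pair in design.all_pairs:
            n_shared = net.shared_interactors(graph, pair)
            for p in pair:
                shared[p] = n_shared
                scores[p] = 1.0 if truth_df.loc[p, "label_redistributed"] else 0.0
        out = net.group_compare(scores, net.bin_by_median(shared))
        assert out.loc[0, "p"] < 0.05


class TestMorphologyCorrelation:
    def test_identical_feature_perfect_rank_correlation(self):
        rng = np.random.default_rng(4)
        area = rng.uniform(100, 900, 200)
        morph = pd.DataFrame({"area": area})
        emb = pd.DataFrame({"f0": area, "f1": rng.normal(size=200)})
        out = net.morphology_correlation(morph, emb)
        assert out["rho"].loc["area", "f0"] == pytest.approx(1.0)

    def test_monotone_transform_rank_invariant(self):
        rng = np.random.default_rng(5)
        area = rng.uniform(100, 900, 100)
        out = net.morphology_correlation(
            pd.DataFrame({"area": area}), pd.DataFrame({"f0": np.log(area) ** 3})
        )
        assert out["rho"].loc["area", "f0"] == pytest.approx(1.0)

    def test_independent_columns_mostly_uncorrelated(self):
        rng = np.random.default_rng(6)
        morph = pd.DataFrame(rng.normal(size=(1000, 3)), columns=["a", "b", "c"])
        emb = pd.DataFrame(rng.normal(size=(1000, 10)), columns=[f"f{i}" for i in range(10)])
        out = net.morphology_correlation(morph, emb)
        assert (np.abs(out["rho"].to_numpy()) < 0.1).mean() >= 0.95

    def test_constant_column_missing(self):
        out = net.morphology_correlation(
            pd.DataFrame({"a": [1.0, 1.0, 1.0]}), pd.DataFrame({"f0": [1.0, 2.0, 3.0]})
        )
        assert np.isnan(out["rho"].loc["a", "f0"])

    def test_misaligned_tables_rejected(self):
        with pytest.raises(ValueError):
            net.morphology_correlation(
                pd.DataFrame({"a": [1.0]}), pd.DataFrame({"f0": [1.0, 2.0]})
            )
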