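import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tuba
from tuba.extremal import _pair_pvalues

from conftest import hypergeom_tail_oracle


class TestExtremalSetSize:
    def test_five_percent_of_200_is_10(self):
        assert tuba.extremal_set_size(0.05, 200) == 10

    @pytest.mark.parametrize("pct,n,expected", [(0.05, 50, 3), (0.5, 4, 2), (0.1, 25, 3)])
    def test_round_half_up(self, pct, n, expected):
        assert tuba.extremal_set_size(pct, n) == expected

    @pytest.mark.parametrize("pct,n", [(0.05, 20), (0.6, 100), (0.0, 100)])
    def test_degenerate_inputs_rejected(self, pct, n):
        with pytest.raises(ValueError):
            tuba.extremal_set_size(pct, n)


class TestComputeExtremalSets:
    def test_forced_ordering(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"], columns=list("abcd"))
        sets = tuba.compute_extremal_sets(m, 0.5, "high")
        assert sets.sets["g"] == {"c", "d"}
        assert tuba.compute_extremal_sets(m, 0.5, "low").sets["g"] == {"a", "b"}

    def test_all_equal_values_tie_break_is_canonical_order(self):
        m = pd.DataFrame([[7.0] * 10], index=["g"], columns=[f"S{j}" for j in range(10)])
        sets = tuba.compute_extremal_sets(m, 0.3, "high")
        assert sets.k == 3
        assert sets.sets["g"] == {"S0", "S1", "S2"}

    def test_every_set_has_exactly_k_members(self, tiny_matrix):
        sets = tuba.compute_extremal_sets(tiny_matrix, 0.5, "high")
        assert all(s.sum() == sets.k for s in sets.membership)


class TestOverlapPvalue:
    def test_published_complete_overlap_value(self):
        # complete overlap of two 10-sets in a 200-sample cohort
        p = tuba.overlap_pvalue(10, 10, 10, 200)
        assert p == pytest.approx(1 / math.comb(200, 10), rel=1e-12)
        assert f"{p:.2e}" == "4.45e-17"

    def test_half_overlap_of_20_sets_is_between_bounds(self):
        p = tuba.overlap_pvalue(10, 20, 20, 200)
        assert 1e-10 < p < 1e-5

    def test_zero_overlap_is_one(self):
        assert tuba.overlap_pvalue(0, 10, 15, 100) == 1.0

    def test_complete_overlap_closed_form(self):
        assert tuba.overlap_pvalue(5, 5, 5, 20) == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_bounds_are_enforced(self):
        with pytest.raises(ValueError):
            tuba.overlap_pvalue(11, 10, 10, 200)
        with pytest.raises(ValueError):
            tuba.overlap_pvalue(1, 10, 300, 200)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_exact_tail_oracle(self, data):
        N = data.draw(st.integers(4, 60))
        k1 = data.draw(st.integers(1, N))
        k2 = data.draw(st.integers(1, N))
        m = data.draw(st.integers(0, min(k1, k2)))
        expected = hypergeom_tail_oracle(m, k1, k2, N)
        assert tuba.overlap_pvalue(m, k1, k2, N) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(4, 80), st.data())
    def test_symmetric_and_monotone_in_m(self, N, data):
        k1 = data.draw(st.integers(2, N))
        k2 = data.draw(st.integers(2, N))
        lo = min(k1, k2)
        ps = tuba.overlap_pvalue(np.arange(lo + 1), k1, k2, N)
        ps_swap = tuba.overlap_pvalue(np.arange(lo + 1), k2, k1, N)
        assert np.allclose(ps, ps_swap, rtol=1e-12)
        assert np.all(np.diff(ps) <= 1e-15)  # non-increasing in m

    def test_extreme_values_do_not_underflow_to_zero(self):
        # overlaps this extreme appear in real cohorts; must stay positive
        p = tuba.overlap_pvalue(100, 100, 100, 2000)
        assert 0.0 < p < 1e-165


class TestBuildGraph:
    def test_identical_sets_make_a_triangle(self):
        m = pd.DataFrame(np.random.default_rng(3).normal(size=(3, 40)),
                         index=list("ABC"), columns=[f"S{j}" for j in range(40)])
        m.iloc[:, :4] += 50.0
        sets = tuba.compute_extremal_sets(m, 0.1, "high")
        g = tuba.build_graph(sets, 1e-3, "raw")
        assert g.number_of_edges() == 3
        common = frozenset({"S0", "S1", "S2", "S3"})
        assert all(d["shared_samples"] == common for _, _, d in g.edges(data=True))

    def test_disjoint_sets_give_zero_edges(self):
        values = np.zeros((4, 40))
        for i in range(4):
            values[i, 4 * i: 4 * i + 4] = 10.0
        m = pd.DataFrame(values, index=list("ABCD"), columns=[f"S{j}" for j in range(40)])
        sets = tuba.compute_extremal_sets(m, 0.1, "high")
        with pytest.warns(UserWarning):
            g = tuba.build_graph(sets, 1e-6, "raw")
        assert g.number_of_edges() == 0

    def test_equals_brute_force_all_pairs_scan(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(10, 60)),
                         index=[f"G{i}" for i in range(10)],
                         columns=[f"S{j}" for j in range(60)])
        m.iloc[:4, :6] += 8.0
        sets = tuba.compute_extremal_sets(m, 0.1, "high")
        cutoff = 1e-4
        g = tuba.build_graph(sets, cutoff, "raw")
        expected = set()
        d = sets.sets
        genes = sets.gene_ids
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                ov = len(d[genes[i]] & d[genes[j]])
                if hypergeom_tail_oracle(ov, sets.k, sets.k, 60) <= cutoff:
                    expected.add(frozenset((genes[i], genes[j])))
        assert {frozenset(e) for e in g.edges} == expected

    def test_edge_set_invariant_to_gene_and_sample_permutation(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(8, 50)),
                         index=[f"G{i}" for i in range(8)],
                         columns=[f"S{j}" for j in range(50)])
        m.iloc[:3, :5] += 9.0
        perm_g = rng.permutation(8)
        perm_s = rng.permutation(50)
        m2 = m.iloc[perm_g, perm_s]
        e1 = {frozenset(e) for e in tuba.build_graph(
            tuba.compute_extremal_sets(m, 0.1, "high"), 1e-4, "raw").edges}
        e2 = {frozenset(e) for e in tuba.build_graph(
            tuba.compute_extremal_sets(m2, 0.1, "high"), 1e-4, "raw").edges}
        assert e1 == e2

    def test_bh_family_is_all_pairs(self):
        # with G genes the BH denominator is G(G-1)/2 even for m=0 pairs
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(6, 40)),
                         index=[f"G{i}" for i in range(6)],
                         columns=[f"S{j}" for j in range(40)])
        sets = tuba.compute_extremal_sets(m, 0.1, "high")
        mvec, p_raw, p_adj = _pair_pvalues(sets)
        assert len(p_raw) == 15
        # the smallest adjusted p follows the BH step-up over the full family
        order = np.argsort(p_raw)
        expected_min = min(p_raw[order[i]] * 15 / (i + 1) for i in range(15))
        assert p_adj.min() == pytest.approx(min(expected_min, 1.0))


class TestTuningCurveAndSuggestion:
    @pytest.fixture
    def sets(self):
        rng = np.random.default_rng(21)
        values = rng.normal(size=(30, 100))
        values[:6, :5] += 8.0
        values[6:12, 5:10] += 8.0
        m = pd.DataFrame(values, index=[f"G{i:02d}" for i in range(30)],
                         columns=[f"S{j:03d}" for j in range(100)])
        return tuba.compute_extremal_sets(m, 0.05, "high")

    def test_single_cutoff_matches_build_graph(self, sets):
        curve = tuba.tuning_curve(sets, [1e-6], cutoff_mode="raw")
        g = tuba.build_graph(sets, 1e-6, "raw")
        row = curve.table.iloc[0]
        assert row["n_edges"] == g.number_of_edges()
        assert row["n_genes_in_graph"] == g.number_of_nodes()
        on_edges = frozenset().union(*(d["shared_samples"] for _, _, d in g.edges(data=True)))
        assert row["n_samples_on_edges"] == len(on_edges)

    def test_counts_non_decreasing_with_leniency(self, sets):
        curve = tuba.tuning_curve(sets, [10.0 ** -e for e in range(12, 2, -1)], cutoff_mode="raw")
        for col in ("n_edges", "n_genes_in_graph", "n_samples_on_edges"):
            assert (curve.table[col].diff().dropna() >= 0).all()

    def test_suggest_prefers_ratio_in_band(self):
        table = pd.DataFrame({
            "cutoff": [1e-12, 1e-11, 1e-10, 1e-9],
            "n_edges": [100, 120, 180, 540],
            "n_genes_in_graph": [10, 12, 18, 54],
            "n_samples_on_edges": [10, 12, 18, 54],
        })
        curve = tuba.TuningCurve(cutoff_mode="raw", table=table)
        cutoff, diag, approx = tuba.suggest_cutoff(curve)
        assert cutoff == 1e-11  # 180/120 = 1.5
        assert not approx

    def test_two_qualifying_cutoffs_pick_less_stringent(self):
        table = pd.DataFrame({
            "cutoff": [1e-12, 1e-11, 1e-10],
            "n_edges": [100, 150, 225],
            "n_genes_in_graph": [1, 2, 3],
            "n_samples_on_edges": [1, 2, 3],
        })
        cutoff, _, approx = tuba.suggest_cutoff(tuba.TuningCurve("raw", table))
        assert cutoff == 1e-11 and not approx

    def test_fallback_flags_approximate(self):
        table = pd.DataFrame({
            "cutoff": [1e-12, 1e-11, 1e-10],
            "n_edges": [1, 10, 100],
            "n_genes_in_graph": [1, 2, 3],
            "n_samples_on_edges": [1, 2, 3],
        })
        cutoff, _, approx = tuba.suggest_cutoff(tuba.TuningCurve("raw", table))
        assert approx

    def test_all_zero_edges_is_an_error(self):
        table = pd.DataFrame({
            "cutoff": [1e-12, 1e-11], "n_edges": [0, 0],
            "n_genes_in_graph": [0, 0], "n_samples_on_edges": [0, 0],
        })
        with pytest.raises(ValueError):
            tuba.suggest_cutoff(tuba.TuningCurve("raw", table))


class TestPermutationNull:
    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(20, 60)),
                         index=[f"G{i}" for i in range(20)],
                         columns=[f"S{j}" for j in range(60)])
        s1, h1 = tuba.permutation_null(m, 0.1, 2, rng_seed=99)
        s2, h2 = tuba.permutation_null(m, 0.1, 2, rng_seed=99)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_overlap_histogram_tracks_hypergeometric_null(self):
        # mean permuted overlap should match the hypergeometric mean k^2/N
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(50, 100)),
                         index=[f"G{i}" for i in range(50)],
                         columns=[f"S{j}" for j in range(100)])
        _, hist = tuba.permutation_null(m, 0.1, 4, rng_seed=5)
        mean_overlap = (hist["overlap_m"] * hist["n_pairs"]).sum() / hist["n_pairs"].sum()
        assert mean_overlap == pytest.approx(100 * (0.1 ** 2), rel=0.15)
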