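"""Variable reduction: correlations, normality screen, graph, dominating set."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from exposcreen import (
    DataModelError,
    ExposomeTable,
    VariableMeta,
    benjamini_hochberg,
    build_autocorrelation_graph,
    correlation_matrix,
    minimum_dominating_set,
    name_pattern_filter,
    pearson,
    reduce_table,
    shapiro_wilk_screen,
)
from exposcreen.reduction import is_dominating_set
from exposcreen.synthetic_data import plant_moe_variables


def brute_force_mds_size(g: nx.Graph) -> int:
    """Smallest dominating set by exhaustive search over subset sizes."""
    nodes = list(g.nodes)
    for k in range(0, len(nodes) + 1):
        for subset in itertools.combinations(nodes, k):
            if is_dominating_set(g, set(subset)):
                return k
    return len(nodes)


def _table(vals: dict, domain="social") -> ExposomeTable:
    df = pd.DataFrame(vals, index=[f"{i + 1:05d}" for i in
                                   range(len(next(iter(vals.values()))))])
    return ExposomeTable(df, {n: VariableMeta(n, domain) for n in vals})


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        # Σxcyc=3, Σxc²=2, Σyc²=14/3 ⇒ r = 9/√84
        r = pearson(np.array([1, 2, 3.0]), np.array([1, 2, 4.0]))
        assert r == pytest.approx(0.981981, abs=1e-6)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(DataModelError, match="mismatch"):
            pearson(np.ones(3), np.ones(4))

    def test_undefined_cases_return_none(self):
        assert pearson(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])) is None
        x = np.array([1.0, 2.0, np.nan, np.nan])
        y = np.array([2.0, 1.0, 1.0, 1.0])
        assert pearson(x, y, min_pairs=3) is None

    def test_pairwise_deletion_uses_complete_pairs_only(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        y = np.array([2.0, 4.0, np.nan, 1.0, 9.0])
        expect = scipy.stats.pearsonr([1, 2, 5], [2, 4, 9]).statistic
        assert pearson(x, y, min_pairs=3) == pytest.approx(expect, abs=1e-12)

    def test_agrees_with_scipy_on_complete_data(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 50))
            assert pearson(x, y) == pytest.approx(
                scipy.stats.pearsonr(x, y).statistic, abs=1e-12
            )


class TestCorrelationMatrix:
    def test_matches_per_pair_pearson_with_missingness(self, rng):
        X = rng.standard_normal((80, 6))
        X[rng.random(X.shape) < 0.15] = np.nan
        df = pd.DataFrame(X, columns=list("abcdef"))
        cm = correlation_matrix(df, min_pairs=10)
        for i, a in enumerate(df.columns):
            for b in df.columns[i + 1:]:
                expect = pearson(df[a].to_numpy(), df[b].to_numpy(),
                                 min_pairs=10)
                got = cm.loc[a, b]
                if expect is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=1e-10)

    def test_diagonal_is_one_and_symmetric(self, rng):
        df = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("abcd"))
        cm = correlation_matrix(df, min_pairs=5)
        assert np.allclose(np.diag(cm), 1.0)
        assert np.allclose(cm, cm.T, equal_nan=True)


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_identity(self):
        assert benjamini_hochberg(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataModelError):
            benjamini_hochberg(np.array([0.5, 1.2]))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    def test_adjusted_dominates_raw_and_is_monotone(self, pvals):
        p = np.array(pvals)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=60)
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(benjamini_hochberg(p), sm_adj, atol=1e-12)


class TestNormalityScreen:
    def test_gaussian_variables_mostly_unflagged(self, rng):
        df = pd.DataFrame(rng.standard_normal((500, 20)),
                          columns=[f"v{i}" for i in range(20)])
        t = ExposomeTable(
            df.set_axis([f"{i + 1:05d}" for i in range(500)]),
            {c: VariableMeta(c, "social") for c in df.columns},
        )
        screen = shapiro_wilk_screen(t)
        # BH controls FDR at 0.05 under the null; expect (almost) no flags
        assert screen.flagged.sum() <= 1

    def test_extreme_two_point_distribution_is_flagged(self, rng):
        # raw Shapiro-Wilk p for a 500-draw two-point variable is < 1e-10
        bimodal = rng.choice([0.0, 100.0], size=500)
        assert scipy.stats.shapiro(bimodal).pvalue < 1e-10
        cols = {"bimodal": bimodal}
        cols.update({f"g{i}": rng.standard_normal(500) for i in range(5)})
        t = _table(cols)
        screen = shapiro_wilk_screen(t)
        assert bool(screen.flagged["bimodal"])

    def test_too_few_values_is_unevaluable_not_fatal(self):
        t = _table({"ok": [1.0, 2.0, 3.5, 4.0],
                    "thin": [1.0, np.nan, np.nan, 2.0]})
        screen = shapiro_wilk_screen(t)
        assert "thin" in screen.unevaluable
        assert "ok" in screen.pvalues.index


class TestAutocorrelationGraph:
    def test_exact_copies_form_a_triangle(self, rng):
        x = rng.standard_normal(50)
        t = _table({"a": x, "b": x.copy(), "c": x.copy()})
        cg = build_autocorrelation_graph(t, min_pairs=10)
        assert set(map(frozenset, cg.graph.edges)) == {
            frozenset({"a", "b"}), frozenset({"a", "c"}), frozenset({"b", "c"})
        }

    def test_boundary_r_is_inclusive(self):
        # r(a,b) = 0.9 exactly: b = 0.9·a + √(1−0.81)·e with orthonormal a,e
        a = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        e = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        b = 0.9 * a + np.sqrt(1 - 0.81) * e
        t = _table({"a": a, "b": b})
        cg = build_autocorrelation_graph(t, threshold=0.9, min_pairs=4)
        assert cg.graph.has_edge("a", "b")

    def test_signed_mode_ignores_strong_negative_correlates(self, rng):
        x = rng.standard_normal(60)
        t = _table({"a": x, "b": -x})
        signed = build_autocorrelation_graph(t, min_pairs=10)
        absolute = build_autocorrelation_graph(t, threshold_mode="absolute",
                                               min_pairs=10)
        assert not signed.graph.has_edge("a", "b")
        assert absolute.graph.has_edge("a", "b")

    def test_planted_blocks_become_connected_components(self, small_data):
        table, _, truth = small_data
        cg = build_autocorrelation_graph(table, min_pairs=30)
        components = [c for c in nx.connected_components(cg.graph)
                      if len(c) > 1]
        assert sorted(map(sorted, components)) == sorted(
            sorted(m) for m in truth.blocks.values()
        )

    def test_every_variable_is_a_vertex(self, small_data):
        table, _, _ = small_data
        cg = build_autocorrelation_graph(table, min_pairs=30)
        assert set(cg.graph.nodes) == set(table.variables)


class TestMinimumDominatingSet:
    def test_star_hub_suffices(self):
        g = nx.star_graph(4)  # hub 0, leaves 1..4
        assert minimum_dominating_set(g) == {0}

    def test_edgeless_graph_needs_every_vertex(self):
        g = nx.empty_graph(5)
        assert minimum_dominating_set(g) == set(range(5))

    @pytest.mark.parametrize(
        "graph,expected_size",
        [(nx.cycle_graph(6), 2), (nx.path_graph(4), 2)],
    )
    def test_small_named_graphs(self, graph, expected_size):
        mds = minimum_dominating_set(graph)
        assert len(mds) == expected_size == brute_force_mds_size(graph)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, float(rng.choice([0.2, 0.4])),
                                    seed=int(rng.integers(1 << 30)))
            mds = minimum_dominating_set(g)
            assert is_dominating_set(g, mds)
            assert len(mds) == brute_force_mds_size(g)

    def test_greedy_fallback_yields_a_dominating_set(self, rng):
        g = nx.gnp_random_graph(40, 0.1, seed=5)
        greedy = minimum_dominating_set(g, method="greedy")
        assert is_dominating_set(g, greedy)

    def test_deterministic_alphabetical_preference(self):
        # K2: either endpoint dominates; the earlier name must be chosen
        g = nx.Graph([("apple", "zebra")])
        assert minimum_dominating_set(g) == {"apple"}
        assert minimum_dominating_set(g) == {"apple"}


class TestNamePatternFilter:
    def test_removes_matching_retains_others(self, rng):
        t = _table({
            "Median income margin of error": rng.standard_normal(10),
            "Percent in poverty": rng.standard_normal(10),
            "Rate 95% CI lower bound": rng.standard_normal(10),
        })
        filtered, removed = name_pattern_filter(t)
        assert removed == {"Median income margin of error",
                           "Rate 95% CI lower bound"}
        assert filtered.variables == ["Percent in poverty"]

    def test_short_token_needs_word_boundary(self, rng):
        t = _table({"smoother estimate": rng.standard_normal(5),
                    "income MOE": rng.standard_normal(5)})
        _, removed = name_pattern_filter(t)
        assert removed == {"income MOE"}

    def test_empty_pattern_list_is_a_noop(self, rng, caplog):
        t = _table({"a": rng.standard_normal(5)})
        with caplog.at_level("WARNING", logger="exposcreen"):
            same, removed = name_pattern_filter(t, patterns=())
        assert removed == set() and same.variables == t.variables
        assert "no-op" in caplog.text

    def test_removes_exactly_the_planted_set(self, small_data):
        table, _, _ = small_data
        planted_table, planted = plant_moe_variables(table, 0.1, seed=99)
        _, removed = name_pattern_filter(planted_table)
        assert removed == set(planted)


class TestReduceTable:
    def test_one_representative_per_block_and_idempotence(self, small_data):
        table, _, truth = small_data
        reduced, report = reduce_table(table, run_normality_screen=False)
        for members in truth.blocks.values():
            assert len(set(reduced.variables) & set(members)) == 1
        # a second pass finds no further autocorrelates to collapse
        again, report2 = reduce_table(reduced, run_normality_screen=False)
        assert again.variables == reduced.variables
        assert report2.n_after_mds == report.n_after_name_filter

    def test_counts_are_consistent(self, small_data):
        table, _, _ = small_data
        planted_table, planted = plant_moe_variables(table, 0.05, seed=3)
        reduced, report = reduce_table(planted_table,
                                       run_normality_screen=False)
        assert report.n_input == len(planted_table.variables)
        assert report.n_after_mds == len(report.dominating_set)
        assert report.n_after_name_filter == len(reduced.variables)
        assert report.n_after_name_filter <= report.n_after_mds
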