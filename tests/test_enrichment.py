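from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvar.enrichment import adjust_pvalues, enrich, expand_gene_set, hypergeom_test
from famvar.types import CohortError, GeneSetTerm


def enumeration_upper_tail(universe_n, term_n, query_n, observed):
    """Independent oracle: P(overlap >= observed) by exact counting of draws
    of |query| genes from the universe."""
    total = comb(universe_n, query_n)
    favorable = sum(
        comb(term_n, k) * comb(universe_n - term_n, query_n - k)
        for k in range(observed, min(term_n, query_n) + 1)
        if query_n - k <= universe_n - term_n
    )
    return float(Fraction(favorable, total))


class TestExpand:
    def test_no_network_returns_query(self):
        assert expand_gene_set({"A", "b"}, None) == {"A", "B"}

    def test_one_hop_only(self):
        g = nx.Graph()
        g.add_edge("MAST4", "X", combined_score=800)
        g.add_edge("X", "Z", combined_score=900)  # neighbor-of-neighbor
        expanded = expand_gene_set({"MAST4", "PITX2"}, g)
        assert expanded == {"MAST4", "PITX2", "X"}

    def test_query_always_subset(self, bundle):
        query = {v.gene for v in bundle.cohort.variants}
        assert query <= expand_gene_set(query, bundle.ppi)

    def test_sub_threshold_edges_absent_from_fixture_graph(self, bundle):
        # the below-700 edges never entered the fixture graph
        assert not bundle.ppi.has_edge("MAST4", "APC")
        assert not bundle.ppi.has_edge("PITX2", "WNT10A")


class TestHypergeom:
    def test_forced_overlap_gives_one(self):
        u = {f"g{i}" for i in range(10)}
        assert hypergeom_test(u, u, u) == 1.0

    def test_zero_overlap_gives_one(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        query = {f"g{i}" for i in range(10, 15)}
        assert hypergeom_test(term, query, universe) == 1.0

    def test_matches_enumeration_oracle(self):
        universe = [f"g{i}" for i in range(20)]
        term = set(universe[:5])
        query = set(universe[:4]) | {universe[10]}
        p = hypergeom_test(term, query, universe)
        assert p == pytest.approx(enumeration_upper_tail(20, 5, 5, 4), abs=1e-12)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.integers(1, 12), st.data())
    def test_property_sweep_small_universes(self, universe_n, data):
        term_n = data.draw(st.integers(0, universe_n))
        query_n = data.draw(st.integers(0, universe_n))
        universe = [f"g{i}" for i in range(universe_n)]
        term = set(universe[:term_n])
        # overlap forced by construction: first `k` genes shared
        k = data.draw(st.integers(max(0, term_n + query_n - universe_n), min(term_n, query_n)))
        query = set(universe[:k]) | set(universe[universe_n - (query_n - k):] if query_n > k else [])
        assert len(query) == query_n
        p = hypergeom_test(term, query, universe)
        overlap = len(term & query)
        assert p == pytest.approx(
            enumeration_upper_tail(universe_n, term_n, query_n, overlap), abs=1e-9
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(CohortError):
            hypergeom_test({"A"}, {"A"}, set())


class TestAdjust:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03]).tolist() == [0.03]

    def test_hand_computed_step_up(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert adjust_pvalues([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_hand_step_up_and_dominates_raw(self, pvals):
        out = adjust_pvalues(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        staircase = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, pvals[idx] * m / rank)
            staircase[idx] = running
        assert out == pytest.approx(staircase, abs=1e-12)
        assert np.all(out >= np.asarray(pvals) - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(CohortError):
            adjust_pvalues([0.5, 1.5])


class TestEnrich:
    def make_terms(self):
        universe = [f"g{i}" for i in range(40)]
        match = GeneSetTerm("T:match", "GO:BP", "matching", frozenset(universe[:5]))
        other = GeneSetTerm("T:other", "KEGG", "other", frozenset(universe[20:30]))
        return universe, [match, other]

    def test_perfectly_matching_term_ranks_first(self):
        universe, terms = self.make_terms()
        results = enrich(set(universe[:5]), terms, universe=universe, padj_threshold=0.05)
        assert results[0].term_id == "T:match"
        assert results[0].overlap == 5
        assert results[0].significant

    def test_empty_query_yields_no_significance(self):
        universe, terms = self.make_terms()
        results = enrich(set(), terms, universe=universe)
        assert all(not r.significant for r in results)
        assert all(r.p_value == 1.0 for r in results)

    def test_sorted_by_adjusted_p_then_term_id(self, bundle):
        results = enrich({v.gene for v in bundle.cohort.variants}, bundle.terms)
        keys = [(r.p_adjusted, r.term_id) for r in results]
        assert keys == sorted(keys)

    def test_significance_flag_matches_threshold(self, bundle):
        query = expand_gene_set({v.gene for v in bundle.cohort.variants}, bundle.ppi)
        results = enrich(query, bundle.terms, padj_threshold=0.01)
        for r in results:
            assert r.significant == (r.p_adjusted < 0.01)
            assert r.p_adjusted >= r.p_value - 1e-15
            assert r.overlap <= r.term_size

    def test_universe_defaults_to_term_union(self, bundle):
        universe = set().union(*(t.genes for t in bundle.terms))
        r1 = enrich({"CACNA1S"}, bundle.terms)
        r2 = enrich({"CACNA1S"}, bundle.terms, universe=universe)
        assert [(r.term_id, r.p_value) for r in r1] == [(r.term_id, r.p_value) for r in r2]
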