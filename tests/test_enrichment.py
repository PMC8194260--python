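"""Enrichment against exact rational-arithmetic enumeration oracles."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megadeg.enrichment import bh_fdr, build_ggi, fisher_enrichment
from megadeg.io import GeneSet


def hypergeom_tail_exact(N, K, n, k):
    """P(X >= k) by exact enumeration over draw compositions."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return total


def brute_force_tail(N, K, n, k):
    """P(X >= k) by enumerating every C(N, n) draw (N small)."""
    universe = list(range(N))
    hits = set(range(K))
    favorable = sum(
        1 for draw in combinations(universe, n) if len(hits & set(draw)) >= k
    )
    return Fraction(favorable, comb(N, n))


def naive_bh(pvals):
    m = len(pvals)
    return [
        min(
            1.0,
            min(
                m * pj / sum(1 for x in pvals if x <= pj)
                for pj in pvals
                if pj >= pi
            ),
        )
        for pi in pvals
    ]


class TestFisher:
    def test_empty_query_overlap_p_one(self):
        sets = [GeneSet("S1", "s", frozenset(f"x{i}" for i in range(5)))]
        bg = {f"x{i}" for i in range(10)}
        res = fisher_enrichment(set(), sets, background=bg)
        assert res[0].p == 1.0

    def test_full_containment_hand_value(self):
        # N=20, K=5, n=5, k=5 -> 1/C(20,5)
        members = frozenset(f"g{i}" for i in range(5))
        bg = {f"g{i}" for i in range(20)}
        res = fisher_enrichment(set(members), [GeneSet("S", "s", members)], bg)
        assert res[0].p == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_hand_enumeration_small_case(self):
        # N=10, K=4, n=3, k=2 -> 40/120
        members = frozenset(f"g{i}" for i in range(4))
        bg = {f"g{i}" for i in range(10)}
        query = {"g0", "g1", "g9"}
        res = fisher_enrichment(query, [GeneSet("S", "s", members)], bg)
        assert res[0].k == 2
        assert res[0].p == pytest.approx(1 / 3, rel=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(40):
            N = int(rng.integers(4, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            bg = {f"g{i}" for i in range(N)}
            members = frozenset(f"g{i}" for i in range(K))
            query = set(rng.choice(sorted(bg), size=n, replace=False))
            res = fisher_enrichment(query, [GeneSet("S", "s", members)], bg)
            expect = brute_force_tail(N, K, n, res[0].k)
            assert res[0].p == pytest.approx(float(expect), rel=1e-10)

    def test_default_background_and_sorting(self):
        s1 = GeneSet("B", "b", frozenset(["a", "b", "c"]))
        s2 = GeneSet("A", "a", frozenset(["a", "b", "c"]))
        s3 = GeneSet("C", "c", frozenset(["x", "y", "z"]))
        res = fisher_enrichment({"a", "b"}, [s1, s2, s3])
        assert res[0].N == 6  # union of members + query (query already inside)
        assert [r.set_id for r in res][:2] == ["A", "B"]  # tie broken by id
        assert res[-1].set_id == "C"

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment({"q"}, [GeneSet("S", "s", frozenset("ab"))], {"a", "b"})


class TestBH:
    def test_single_and_tied_values(self):
        assert bh_fdr([0.02]) == [0.02]
        assert bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_stepup_hand_case(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [float("nan"), 0.1]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_definition_and_monotone(self, pvals):
        q = bh_fdr(pvals)
        expect = naive_bh(pvals)
        assert q == pytest.approx(expect, rel=1e-9)
        order = np.argsort(pvals, kind="mergesort")
        assert all(np.diff(np.array(q)[order]) >= -1e-12)
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, pvals))


class TestGGI:
    def _results(self, overlaps, ps):
        sets = [
            GeneSet(f"S{i}", "s", frozenset(o) | {f"pad{i}"})
            for i, o in enumerate(overlaps)
        ]
        bg = set().union(*(s.members for s in sets)) | {"q"}
        res = fisher_enrichment(set().union(*overlaps), sets, bg)
        # replace p-values with controlled ones, keeping overlap structure
        from dataclasses import replace

        by_id = {r.set_id: r for r in res}
        return [replace(by_id[f"S{i}"], p=p) for i, p in enumerate(ps)]

    def test_shared_count_accumulates(self):
        res = self._results([{"A", "B"}, {"A", "B", "C"}], [1e-5, 1e-5])
        edges = build_ggi(res, threshold=0.001)
        lookup = {(e.gene_a, e.gene_b): e.shared for e in edges}
        assert lookup[("A", "B")] == 2
        assert lookup[("A", "C")] == 1

    def test_threshold_excludes_sets(self):
        res = self._results([{"A", "B"}], [0.5])
        assert build_ggi(res, threshold=0.001) == []

    def test_triangle_from_single_set(self):
        res = self._results([{"A", "B", "C"}], [1e-6])
        edges = build_ggi(res, threshold=0.001)
        assert [(e.gene_a, e.gene_b, e.shared) for e in edges] == [
            ("A", "B", 1), ("A", "C", 1), ("B", "C", 1),
        ]

    def test_matches_pairwise_enumeration_and_permutation_invariance(self, rng):
        genes = [f"g{i}" for i in range(8)]
        overlaps = [
            set(rng.choice(genes, size=int(rng.integers(2, 5)), replace=False))
            for _ in range(6)
        ]
        ps = rng.uniform(1e-6, 2e-3, 6)
        res = self._results(overlaps, list(ps))
        edges = build_ggi(res, threshold=0.001)
        expect = {}
        for o, p in zip(overlaps, ps):
            if p < 0.001:
                for a, b in combinations(sorted(o), 2):
                    expect[(a, b)] = expect.get((a, b), 0) + 1
        assert {(e.gene_a, e.gene_b): e.shared for e in edges} == expect
        perm = list(res)[::-1]
        assert build_ggi(perm, threshold=0.001) == edges
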