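import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import hypergeom, kstest

import phenolscreen.enrich as en
from phenolscreen.errors import ConfigError
from phenolscreen.screenio import GeneAnnotation
from phenolscreen.synthdata import simulate_annotation_universe


def exact_upper_tail(k, n, K, N):
    """Independent oracle: exact rational tail sum over the support."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


class TestUpperTail:
    def test_whole_support_is_one(self):
        assert en.hypergeom_upper_tail(0, 4, 5, 10) == 1.0

    def test_empty_support_is_zero(self):
        assert en.hypergeom_upper_tail(5, 4, 5, 10) == 0.0

    def test_draw_enumeration_example(self):
        """P(X>=3) for n=4, K=5, N=10 by enumerating all C(10,4) draws."""
        hits = 0
        total = 0
        for draw in combinations(range(10), 4):
            total += 1
            if sum(1 for g in draw if g < 5) >= 3:
                hits += 1
        assert hits / total == pytest.approx(11 / 42)
        assert en.hypergeom_upper_tail(3, 4, 5, 10) == pytest.approx(
            11 / 42, abs=1e-12
        )

    def test_matches_exact_enumeration_small_universes(self):
        for N in range(1, 21):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(min(n, K) + 1):
                        got = en.hypergeom_upper_tail(k, n, K, N)
                        assert abs(got - exact_upper_tail(k, n, K, N)) <= 1e-12

    def test_matches_scipy_survival_function(self):
        import random

        rng = random.Random(17)
        for _ in range(200):
            N = rng.randint(2, 2000)
            n = rng.randint(0, N)
            K = rng.randint(0, N)
            k = rng.randint(0, min(n, K))
            got = en.hypergeom_upper_tail(k, n, K, N)
            ref = hypergeom.sf(k - 1, N, K, n)
            assert got == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize(
        "N,K,n,tol",
        [(30, 11, 7, 1e-12), (100, 40, 25, 1e-12), (500, 150, 100, 1e-12),
         (2000, 150, 300, 1e-11)],  # log-gamma rounding grows with N
    )
    def test_pmf_sums_to_one(self, N, K, n, tol):
        lo, hi = max(0, n + K - N), min(n, K)
        total = sum(
            math.exp(en.hypergeom_log_pmf(i, n, K, N))
            for i in range(lo, hi + 1)
        )
        assert total == pytest.approx(1.0, abs=tol)

    def test_monotone_decreasing_in_k(self):
        vals = [en.hypergeom_upper_tail(k, 50, 80, 500) for k in range(0, 30)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            en.hypergeom_upper_tail(1, 5, 20, 10)  # K > N


class TestCorrections:
    def test_bonferroni(self):
        out = en.correct_pvalues([0.01] * 10)
        np.testing.assert_allclose(out, 0.1)

    def test_single_test_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert en.correct_pvalues([0.03], method=method)[0] == pytest.approx(0.03)

    def test_bh_monotone_in_sorted_p(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.uniform(1e-6, 1, 50))
        out = en.correct_pvalues(p, method="bh")
        assert (np.diff(out) >= -1e-12).all()

    def test_corrected_at_least_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, 30)
        for method in ("bonferroni", "bh"):
            assert (en.correct_pvalues(p, method=method) >= p - 1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            en.correct_pvalues([0.0, 0.5])


class TestEnrichGeneSets:
    def test_full_term_query_closed_form(self):
        """Query exactly equal to a term: p = C(N-K, 0)*C(K,K)/C(N,K)."""
        universe = {f"g{i}" for i in range(12)}
        term = frozenset(list(sorted(universe))[:4])
        ann = GeneAnnotation(universe=universe,
                             term_map={"T": ("t", term)})
        res = en.enrich_gene_sets(set(term), ann, include_flags=False)
        expected = 1 / math.comb(12, 4)
        assert res[0].p_raw == pytest.approx(expected, abs=1e-12)

    def test_planted_fold4_term_significant(self):
        hits = 0
        for seed in range(20):
            ann, truth = simulate_annotation_universe(
                n_genes=2000, n_terms=50, term_size_range=(50, 50),
                planted=[("term0000", 4.0)], query_size=300, seed=seed,
            )
            res = en.enrich_gene_sets(truth["query"], ann, include_flags=False)
            if res[0].term_id == "term0000" and res[0].significant:
                hits += 1
        assert hits / 20 >= 0.95

    def test_null_pvalues_uniform(self):
        """With no planted terms and a fine-grained geometry the raw
        upper-tail p-values are indistinguishable from uniform."""
        ann, truth = simulate_annotation_universe(
            n_genes=20000, n_terms=500, term_size_range=(1000, 5000),
            query_size=5000, seed=1,
        )
        res = en.enrich_gene_sets(truth["query"], ann, include_flags=False)
        p = np.array([r.p_raw for r in res])
        assert kstest(p, "uniform").pvalue > 0.01

    def test_disjoint_query_not_significant(self):
        universe = {f"g{i}" for i in range(100)}
        ann = GeneAnnotation(
            universe=universe,
            term_map={"T": ("t", frozenset({"g0", "g1", "g2"}))},
        )
        res = en.enrich_gene_sets({"g50", "g51"}, ann, include_flags=False)
        assert not any(r.significant for r in res)

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigError):
            en.enrich_gene_sets({"g1"}, GeneAnnotation(universe=set()))

    def test_flags_tested_alongside_terms(self):
        universe = {f"g{i}" for i in range(50)}
        ann = GeneAnnotation(
            universe=universe,
            flags={f"g{i}": {"kinase"} for i in range(10)},
            term_map={"T": ("t", frozenset({"g0", "g20"}))},
        )
        res = en.enrich_gene_sets({"g0", "g1", "g2"}, ann)
        assert {r.term_id for r in res} == {"T", "flag:kinase"}


class TestBubbleLayout:
    def _result(self, term_id, k, p=1e-4):
        return en.EnrichmentResult(
            term_id, term_id, en.EnrichmentInput(N=2000, K=100, n=300, k=k),
            p, p, "bonferroni", True,
        )

    def test_radius_and_distance_proportional_to_gene_count(self):
        lay = en.bubble_layout([self._result("a", 10), self._result("b", 20)])
        by_id = {e.term_id: e for e in lay.entries}
        assert by_id["b"].radius == pytest.approx(2 * by_id["a"].radius)
        assert by_id["b"].radial_distance == pytest.approx(
            2 * by_id["a"].radial_distance
        )

    def test_empty_input_gives_empty_layout(self):
        assert en.bubble_layout([]).entries == []

    def test_twelve_terms_no_boundary_overlap(self):
        rng = np.random.default_rng(4)
        results = [
            self._result(f"t{i:02d}", int(k))
            for i, k in enumerate(rng.integers(5, 40, 12))
        ]
        lay = en.bubble_layout(results)
        for a, b in combinations(lay.entries, 2):
            ax = a.radial_distance * math.cos(a.angle_rad)
            ay = a.radial_distance * math.sin(a.angle_rad)
            bx = b.radial_distance * math.cos(b.angle_rad)
            by = b.radial_distance * math.sin(b.angle_rad)
            assert math.hypot(ax - bx, ay - by) >= a.radius + b.radius - 1e-6

    def test_non_significant_input_rejected(self):
        bad = self._result("x", 5)
        bad.significant = False
        with pytest.raises(ValueError):
            en.bubble_layout([bad])
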