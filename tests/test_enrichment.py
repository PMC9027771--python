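"""Fisher exact / ORA / GSEA against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodshift import enrichment
from bloodshift.datatypes import GeneSetCollection


def hypergeom_p_enumerated(a, b, c, d, sided):
    """Exact conditional p by summing hypergeometric point masses over all
    tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point_mass(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    obs = point_mass(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if sided == "greater":
        return sum(point_mass(x) for x in range(a, hi + 1))
    if sided == "less":
        return sum(point_mass(x) for x in range(lo, a + 1))
    # tables as or more extreme: point mass no larger than the observed one
    # (small relative slack guards against floating-point ties)
    return sum(point_mass(x) for x in range(lo, hi + 1) if point_mass(x) <= obs * (1 + 1e-7))


class TestFisherExact:
    def test_balanced_table(self):
        odds, p = enrichment.fisher_exact_2x2(2, 2, 2, 2, sided="two-sided")
        assert odds == 1.0
        assert p == 1.0

    def test_extreme_table_complete_association(self):
        k, m = 4, 5
        odds, p = enrichment.fisher_exact_2x2(0, k, m, 0, sided="two-sided")
        assert odds == 0.0
        expect = hypergeom_p_enumerated(0, k, m, 0, "two-sided")
        np.testing.assert_allclose(p, expect, rtol=1e-9)

    def test_undefined_odds_flagged_nan(self):
        odds, _ = enrichment.fisher_exact_2x2(0, 3, 0, 4)
        assert math.isnan(odds)
        odds, _ = enrichment.fisher_exact_2x2(2, 0, 0, 3)
        assert math.isinf(odds)

    def test_worked_example_matches_enumeration(self):
        odds, p = enrichment.fisher_exact_2x2(8, 2, 1, 5, sided="two-sided")
        np.testing.assert_allclose(p, hypergeom_p_enumerated(8, 2, 1, 5, "two-sided"), rtol=1e-9)
        np.testing.assert_allclose(odds, 20.0)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_matches_enumeration_for_small_margins(self, a, b, c, d):
        for sided in ("two-sided", "greater", "less"):
            _, p = enrichment.fisher_exact_2x2(a, b, c, d, sided=sided)
            np.testing.assert_allclose(
                p, hypergeom_p_enumerated(a, b, c, d, sided), rtol=1e-9, atol=1e-12
            )

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            enrichment.fisher_exact_2x2(-1, 2, 3, 4)


class TestOra:
    def _collection(self, sets):
        return GeneSetCollection(sets=sets, source_tag="t")

    def test_disjoint_set_no_enrichment(self):
        universe = [f"G{i}" for i in range(50)]
        query = universe[:10]
        coll = self._collection({"S": universe[30:40]})
        res = enrichment.ora(query, universe, coll)
        assert res.iloc[0]["overlap_size"] == 0
        assert res.iloc[0]["odds_ratio"] == 0.0
        assert res.iloc[0]["p_value"] == 1.0

    def test_query_equals_universe_trivial(self):
        universe = [f"G{i}" for i in range(20)]
        coll = self._collection({"S": universe[:5]})
        res = enrichment.ora(universe, universe, coll)
        assert res.iloc[0]["overlap_size"] == 5
        assert res.iloc[0]["p_value"] == 1.0

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enrichment.ora(["X"], ["G1"], self._collection({"S": ["G1"]}))

    def test_p_matches_enumeration(self):
        universe = [f"G{i}" for i in range(12)]
        query = universe[:5]
        coll = self._collection({"S": universe[2:8]})
        res = enrichment.ora(query, universe, coll)
        a = len(set(query) & set(universe[2:8]))
        b = len(query) - a
        c = 6 - a
        d = 12 - 5 - c
        np.testing.assert_allclose(
            res.iloc[0]["p_value"], hypergeom_p_enumerated(a, b, c, d, "greater"), rtol=1e-9
        )

    def test_set_outside_universe_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            res = enrichment.ora(["G1"], ["G1", "G2"], self._collection({"S": ["X1", "X2"]}))
        assert res.empty


def gsea_es_brute_force(ranked_scores, hit_positions, weight=1.0):
    """Straightforward gene-by-gene running sum; independent of the
    vectorized implementation under test."""
    n = len(ranked_scores)
    hits = set(hit_positions)
    total = sum(abs(ranked_scores[i]) ** weight for i in hits)
    running = 0.0
    best = 0.0
    miss_step = 1.0 / (n - len(hits))
    for i in range(n):
        if i in hits:
            running += (abs(ranked_scores[i]) ** weight) / total if total > 0 else 1.0 / len(hits)
        else:
            running -= miss_step
        if abs(running) > abs(best):
            best = running
    return best


class TestGsea:
    def _ranking(self, n, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:03d}" for i in range(n)]
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        return genes, scores

    def test_single_gene_set_at_top_es_one(self):
        genes, scores = self._ranking(30, seed=1)
        coll = GeneSetCollection(sets={"S": [genes[0]]}, source_tag="t")
        res = enrichment.gsea(list(zip(genes, scores)), coll, n_perm=50, seed=0)
        np.testing.assert_allclose(res.iloc[0]["es"], 1.0)

    def test_single_gene_set_at_bottom_es_minus_one(self):
        genes, scores = self._ranking(30, seed=2)
        coll = GeneSetCollection(sets={"S": [genes[-1]]}, source_tag="t")
        res = enrichment.gsea(list(zip(genes, scores)), coll, n_perm=50, seed=0)
        np.testing.assert_allclose(res.iloc[0]["es"], -1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_es_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        genes, scores = self._ranking(20, seed=seed % (2**16))
        k = int(rng.integers(1, 8))
        members = list(rng.choice(genes, size=k, replace=False))
        coll = GeneSetCollection(sets={"S": members}, source_tag="t")
        res = enrichment.gsea(list(zip(genes, scores)), coll, n_perm=20, seed=0)
        positions = [genes.index(g) for g in members]
        expect = gsea_es_brute_force(scores, positions)
        np.testing.assert_allclose(res.iloc[0]["es"], expect, atol=1e-12)
        assert -1.0 <= res.iloc[0]["es"] <= 1.0

    def test_reversed_ranking_negates_es(self):
        genes, scores = self._ranking(40, seed=3)
        members = [genes[i] for i in (1, 5, 8)]
        coll = GeneSetCollection(sets={"S": members}, source_tag="t")
        res_fwd = enrichment.gsea(list(zip(genes, scores)), coll, n_perm=20, seed=0)
        res_rev = enrichment.gsea(list(zip(genes[::-1], -scores[::-1])), coll, n_perm=20, seed=0)
        np.testing.assert_allclose(res_rev.iloc[0]["es"], -res_fwd.iloc[0]["es"], atol=1e-12)

    def test_leading_edge_subset_of_set(self):
        genes, scores = self._ranking(50, seed=4)
        members = [genes[i] for i in (0, 3, 9, 30, 45)]
        coll = GeneSetCollection(sets={"S": members}, source_tag="t")
        res = enrichment.gsea(list(zip(genes, scores)), coll, n_perm=50, seed=0)
        leading = res.iloc[0]["leading_edge"].split(",")
        assert set(leading) <= set(members)
        assert len(leading) >= 1

    def test_duplicate_genes_rejected(self):
        coll = GeneSetCollection(sets={"S": ["G1"]}, source_tag="t")
        with pytest.raises(ValueError, match="duplicates"):
            enrichment.gsea([("G1", 1.0), ("G1", 0.5)], coll)

    def test_marker_sets_detected_on_synthetic_de(self, de_results, sc_reference):
        """Planted marker sets of strongly shifted types rank at the top on
        the default synthetic cohort's DE ranking."""
        _, _, truth = sc_reference
        coll = GeneSetCollection(
            sets={f"{ct}_markers": list(g) for ct, g in truth.planted_markers.items()},
            source_tag="markers",
        )
        ranking = enrichment.ranking_from_de(de_results)
        res = enrichment.gsea(ranking, coll, n_perm=200, seed=5)
        top = res.iloc[0]
        assert top["p_value"] < 0.05
        strong = {"neutrophils_markers", "CD8_T_markers", "NK_cells_markers",
                  "CD4_memory_T_markers", "erythrocytes_markers"}
        assert top["set_name"] in strong
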