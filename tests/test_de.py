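"""Paired differential expression and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bloodshift import de
from bloodshift.datatypes import SampleRecord

from conftest import make_counts, make_paired_meta


def bh_brute_force(p):
    """Independent textbook implementation: sort, scale, cumulative min, unsort."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(n)
    for pos, idx in enumerate(order):
        rank = pos + 1
        candidates = [p[j] * n / (list(order).index(j) + 1) for j in order[pos:]]
        out[idx] = min(1.0, min(candidates))
    return out


class TestBhAdjust:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(de.bh_adjust([0.05]), [0.05])

    def test_stepwise_example(self):
        np.testing.assert_allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_equal(self):
        np.testing.assert_allclose(de.bh_adjust([0.3] * 7), [0.3] * 7)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 30))
        np.testing.assert_allclose(de.bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.2])


class TestPairedDe:
    def _counts_from_norm(self, before, after, n_donors=7):
        """Build a count matrix with the given per-gene before/after values."""
        before = np.asarray(before, dtype=float)
        after = np.asarray(after, dtype=float)
        cols, ids = [], []
        for d in range(n_donors):
            cols += [before, after]
            ids += [f"D{d + 1}_before", f"D{d + 1}_after"]
        return make_counts(np.column_stack(cols), sample_ids=ids), make_paired_meta(n_donors)

    def test_null_identity(self):
        base = np.array([50.0, 200.0, 1000.0])
        counts, meta = self._counts_from_norm(base, base)
        res = de.paired_de(counts, meta)
        np.testing.assert_allclose(res["log2fc"], 0.0)
        assert (res["status"] == "ns").all()

    def test_exact_doubling_gives_log2fc_one(self):
        rng = np.random.default_rng(0)
        base = rng.integers(100, 5000, 20).astype(float)
        counts, meta = self._counts_from_norm(base, 2 * base)
        # size factors differ between conditions here, so add stable anchor
        # genes to keep the median-of-ratios reference near 1
        anchor = np.full(200, 1000.0)
        vals = np.vstack([counts.values, np.tile(anchor[:, None], (1, 14))])
        counts = make_counts(vals, sample_ids=counts.sample_ids)
        res = de.paired_de(counts, meta)
        np.testing.assert_allclose(res["log2fc"][:20], 1.0, atol=0.05)

    def test_t_statistic_matches_hand_formula_without_moderation(self):
        rng = np.random.default_rng(5)
        n_donors = 7
        counts_vals = rng.integers(10, 2000, (40, 14)).astype(float)
        meta = make_paired_meta(n_donors)
        counts = make_counts(counts_vals, sample_ids=[m.sample_id for m in meta])
        res = de.paired_de(counts, meta, moderate=False, min_mean_norm_count=0.0)
        # recompute by hand for one gene
        from bloodshift.normalize import median_of_ratios_size_factors

        sf = median_of_ratios_size_factors(counts)
        logv = np.log2(counts_vals / sf[None, :] + 1)
        d_hand = logv[:, 1::2] - logv[:, 0::2]
        g = 13
        t_hand = d_hand[g].mean() / (d_hand[g].std(ddof=1) / np.sqrt(n_donors))
        p_hand = 2 * stats.t.sf(abs(t_hand), n_donors - 1)
        np.testing.assert_allclose(res["log2fc"][g], d_hand[g].mean(), atol=1e-12)
        np.testing.assert_allclose(res["p_value"][g], p_hand, rtol=1e-9)

    def test_label_swap_negates_log2fc_preserves_p(self):
        rng = np.random.default_rng(6)
        counts = make_counts(rng.integers(0, 500, (60, 8)).astype(float),
                             sample_ids=[f"D{d}_{c}" for d in range(4) for c in ("before", "after")])
        meta = make_paired_meta(4)
        swapped = [
            SampleRecord(m.sample_id, m.donor_id, "after" if m.condition == "before" else "before")
            for m in meta
        ]
        res = de.paired_de(counts, meta)
        res_sw = de.paired_de(counts, swapped)
        np.testing.assert_allclose(res_sw["log2fc"], -res["log2fc"], atol=1e-12)
        np.testing.assert_allclose(res_sw["p_value"], res["p_value"], atol=1e-12)

    def test_no_complete_pairs_errors(self):
        counts = make_counts([[1.0, 2.0]], sample_ids=["S1", "S2"])
        meta = [SampleRecord("S1", "D1", "before"), SampleRecord("S2", "D2", "after")]
        with pytest.raises(ValueError, match="pair"):
            de.paired_de(counts, meta)

    def test_low_expression_genes_flagged_untested(self):
        vals = np.vstack([np.full((5, 6), 100.0), np.full((1, 6), 0.5)])
        counts = make_counts(vals, sample_ids=[f"D{d}_{c}" for d in (1, 2, 3) for c in ("before", "after")])
        res = de.paired_de(counts, make_paired_meta(3))
        assert res["tested"].tolist() == [True] * 5 + [False]
        assert np.isnan(res["p_value"].iloc[-1])
        assert res["status"].iloc[-1] == "ns"


class TestSummaries:
    def _results(self):
        return pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(6)],
                "log2fc": [2.0, 1.0, -1.5, 0.4, -3.0, 0.9],
                "p_value": [0.001] * 6,
                "fdr": [0.01, 0.01, 0.01, 0.01, 0.5, 0.01],
                "mean_tpm": [150.0, 20.0, 5.0, 150.0, 500.0, 0.5],
                "status": ["up", "up", "down", "up", "ns", "up"],
                "tested": [True] * 6,
            }
        )

    def test_stratification_cutoffs(self):
        res = self._results()
        strat = de.stratify_by_expression(res, [0, 100, 1000])
        assert strat.loc[0, ["n_up", "n_down"]].tolist() == [4, 1]
        assert strat.loc[1, ["n_up", "n_down"]].tolist() == [2, 0]
        assert strat.loc[2, ["n_up", "n_down"]].tolist() == [0, 0]

    def test_fold_change_strictly_greater_than_twofold(self):
        counts = de.fold_change_summary(self._results(), fc_threshold=1.0)
        # G1 sits exactly at log2fc = 1 and is excluded; G4 is not a DEG
        assert counts == {"n_up": 1, "n_down": 1}

    def test_planted_counts_recovered(self, bulk_cohort, de_results):
        _, _, truth = bulk_cohort
        planted = truth.planted_de.set_index("gene")["true_log2fc"]
        hits = de.degs(de_results)
        detected_planted = hits[hits["gene"].isin(planted.index)]
        # directions agree with the planted signs
        signs = np.sign(planted.loc[detected_planted["gene"]].to_numpy())
        np.testing.assert_array_equal(np.sign(detected_planted["log2fc"].to_numpy()), signs)
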