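"""Cross-study uniqueness filter, marker enrichment, signature selection."""

import numpy as np
import pandas as pd
import pytest

from bloodshift import specificity
from bloodshift.datatypes import ExternalDETable, MarkerCatalog
from bloodshift.enrichment import fisher_exact_2x2

from conftest import make_counts, make_paired_meta


def _de_table(genes, statuses=None, log2fc=None, mean_tpm=None):
    n = len(genes)
    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc if log2fc is not None else [1.0] * n,
            "p_value": [0.001] * n,
            "fdr": [0.01] * n,
            "mean_tpm": mean_tpm if mean_tpm is not None else [50.0] * n,
            "status": statuses if statuses is not None else ["up"] * n,
            "tested": [True] * n,
        }
    )


def _external(dataset_id, sig_genes, all_genes):
    rows = [(g, 0.5, 0.01 if g in sig_genes else 0.5) for g in all_genes]
    return ExternalDETable(
        dataset_id=dataset_id,
        table=pd.DataFrame(rows, columns=["gene", "log2fc", "p"]),
    )


class TestUniquenessFilter:
    def test_no_externals_everything_unique(self, caplog):
        degs = _de_table([f"G{i}" for i in range(5)])
        with caplog.at_level("WARNING"):
            res = specificity.uniqueness_filter(degs, [])
        assert len(res.unique_degs) == 5
        assert res.previously_seen.empty

    def test_total_removal(self):
        genes = [f"G{i}" for i in range(5)]
        res = specificity.uniqueness_filter(
            _de_table(genes), [_external("d1", set(genes), genes)]
        )
        assert res.unique_degs.empty
        assert len(res.previously_seen) == 5

    def test_partition_constructed_case(self):
        genes = [f"G{i}" for i in range(10)]
        flagged = {"G1", "G3", "G5", "G7"}
        res = specificity.uniqueness_filter(
            _de_table(genes), [_external("d1", flagged, genes)]
        )
        assert set(res.unique_degs["gene"]) == set(genes) - flagged
        assert set(res.previously_seen["gene"]) == flagged
        # set identity holds exactly
        assert set(res.unique_degs["gene"]) | set(res.previously_seen["gene"]) == set(genes)
        assert set(res.unique_degs["gene"]) & set(res.previously_seen["gene"]) == set()

    def test_per_dataset_attribution(self):
        genes = ["G0", "G1", "G2"]
        res = specificity.uniqueness_filter(
            _de_table(genes),
            [_external("d1", {"G0", "G1"}, genes), _external("d2", {"G1"}, genes)],
        )
        seen = res.previously_seen.set_index("gene")
        assert seen.loc["G0", "flagged_by"] == "d1"
        assert seen.loc["G1", "flagged_by"] == "d1,d2"

    def test_raising_threshold_never_grows_unique_set(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(50)]
        table = pd.DataFrame(
            {"gene": genes, "log2fc": 0.3, "p": rng.uniform(0, 1, 50)}
        )
        ext = ExternalDETable(dataset_id="d", table=table)
        degs = _de_table(genes)
        prev = None
        for thresh in (0.01, 0.05, 0.2, 0.8, 1.0):
            unique = set(specificity.uniqueness_filter(degs, [ext], p_thresh=thresh).unique_degs["gene"])
            if prev is not None:
                assert unique <= prev
            prev = unique

    def test_direction_ignored_in_removal(self):
        degs = _de_table(["G0"], statuses=["down"], log2fc=[-1.0])
        ext = ExternalDETable(
            dataset_id="d", table=pd.DataFrame({"gene": ["G0"], "log2fc": [2.0], "p": [0.001]})
        )
        res = specificity.uniqueness_filter(degs, [ext])
        assert res.unique_degs.empty


class TestMarkerEnrichment:
    def _catalog(self, marker_map):
        return MarkerCatalog(cell_types=sorted(marker_map), markers=marker_map)

    def test_proportional_markers_null(self):
        # markers split proportionally between unique and seen
        genes = [f"G{i}" for i in range(40)]
        markers = {"T": genes[:10], "U": []}
        flagged = set(genes[0:5]) | set(genes[10:25])  # half the markers, half the rest
        res = specificity.uniqueness_filter(_de_table(genes), [_external("d", flagged, genes)])
        enr = specificity.marker_specificity_enrichment(res, self._catalog(markers)).set_index("cell_type")
        np.testing.assert_allclose(enr.loc["T", "odds_ratio"], 1.0)
        assert enr.loc["T", "p_value"] > 0.5

    def test_all_markers_unique_extreme(self):
        genes = [f"G{i}" for i in range(30)]
        markers = {"T": genes[:6]}
        flagged = set(genes[6:20])
        res = specificity.uniqueness_filter(_de_table(genes), [_external("d", flagged, genes)])
        enr = specificity.marker_specificity_enrichment(res, self._catalog(markers)).set_index("cell_type")
        assert np.isinf(enr.loc["T", "odds_ratio"])
        a, b = 6, 10  # markers/non-markers among unique
        c, d = 0, 14
        _, expect = fisher_exact_2x2(a, b, c, d, sided="greater")
        np.testing.assert_allclose(enr.loc["T", "p_value"], expect, rtol=1e-9)

    def test_no_markers_among_degs_p_one(self):
        genes = [f"G{i}" for i in range(10)]
        res = specificity.uniqueness_filter(_de_table(genes), [])
        enr = specificity.marker_specificity_enrichment(
            res, self._catalog({"T": ["X1", "X2"]})
        ).set_index("cell_type")
        assert enr.loc["T", "p_value"] == 1.0

    def test_planted_platelet_specific_uniqueness(self, sc_reference):
        """When external studies flag every DEG except platelet markers, the
        platelet odds ratio dominates all 12 cell types."""
        _, _, truth = sc_reference
        catalog = MarkerCatalog(
            cell_types=truth.cell_types,
            markers={ct: list(g) for ct, g in truth.planted_markers.items()},
        )
        rng = np.random.default_rng(1)
        marker_degs = [g for ct in truth.cell_types for g in truth.planted_markers[ct][:10]]
        other = [g for g in truth.gene_ids if g not in set(marker_degs)][:80]
        genes = marker_degs + other
        platelet = set(truth.planted_markers["platelets"])
        flagged = {g for g in genes if g not in platelet and rng.random() < 0.8}
        res = specificity.uniqueness_filter(_de_table(genes), [_external("d", flagged, genes)])
        enr = specificity.marker_specificity_enrichment(res, catalog).set_index("cell_type")
        finite_or = enr["odds_ratio"].replace(np.inf, 1e9)
        assert finite_or.idxmax() == "platelets"


class TestSignature:
    def test_threshold_boundaries(self):
        genes = ["GA", "GB", "GC", "GD"]
        degs = _de_table(
            genes,
            log2fc=[0.5, 0.49, 2.0, 1.0],
            mean_tpm=[10.0, 50.0, 9.99, 50.0],
        )
        res = specificity.uniqueness_filter(degs, [])
        sig = specificity.prioritize_signature(res)
        # GA: both thresholds inclusive -> kept; GB fails lfc; GC fails tpm
        assert set(sig["gene"]) == {"GA", "GD"}

    def test_constructed_conjunction(self):
        genes = [f"G{i}" for i in range(10)]
        lfc = [1.0] * 3 + [0.1] * 7
        tpm = [100.0] * 5 + [1.0] * 5
        res = specificity.uniqueness_filter(_de_table(genes, log2fc=lfc, mean_tpm=tpm), [])
        sig = specificity.prioritize_signature(res)
        assert set(sig["gene"]) == {"G0", "G1", "G2"}

    def test_sorted_by_cell_type_then_log2fc(self):
        genes = ["M1", "M2", "N1", "N2"]
        degs = _de_table(genes, log2fc=[0.8, 1.6, 2.5, 0.9])
        res = specificity.uniqueness_filter(degs, [])
        cat = MarkerCatalog(cell_types=["T"], markers={"T": ["M1", "M2"]})
        sig = specificity.prioritize_signature(res, cat)
        assert sig["gene"].tolist() == ["M2", "M1", "N1", "N2"]
        assert sig["cell_type"].tolist() == ["T", "T", "", ""]


class TestMicroarrayReanalysis:
    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(2)
        n_genes, n_donors = 200, 6
        base = rng.normal(8, 1, (n_genes, 1))
        donor_offset = rng.normal(0, 1, (1, n_donors))
        vals = np.repeat(base, 2 * n_donors, axis=1) + np.repeat(donor_offset, 2, axis=1)
        vals += rng.normal(0, 0.2, vals.shape)
        vals[:10, 1::2] += 1.5  # first 10 genes up after exercise
        meta = make_paired_meta(n_donors)
        m = make_counts(np.abs(vals), sample_ids=[x.sample_id for x in meta])
        m = m.with_values(vals, unit="log_normalized")
        table = specificity.microarray_paired_de(m, meta, "study_x").table
        assert (table["p"].iloc[:10] < 0.001).all()
        np.testing.assert_allclose(table["log2fc"].iloc[:10], 1.5, atol=0.4)
        assert (table["p"].iloc[10:] < 0.05).mean() < 0.15
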