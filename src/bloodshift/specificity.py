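"""Cross-study specificity: which DEGs are unique to the altitude cohort?

Taking a conservative stance, a DEG is considered "previously seen" if any
of the supplied external exercise datasets reports it at unadjusted
p < ``p_thresh`` (default 0.05), in either direction. The remaining,
altitude-specific DEGs are tested per cell type for enrichment of marker
genes (one-sided Fisher exact on unique-vs-seen x marker-vs-non-marker),
and finally filtered into a high-confidence signature of well-expressed
(mean TPM >= 10), clearly regulated (|log2FC| >= 0.5) genes, annotated by
marker cell type.

A small helper re-analyzes microarray-style log-intensity matrices with a
donor-paired t test so the full loop (re-analysis -> DE table -> filter)
can be exercised on synthetic data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ExpressionMatrix,
    ExternalDETable,
    MarkerCatalog,
    SampleRecord,
    SpecificityResult,
    paired_layout,
)
from .de import STATUS_DOWN, STATUS_UP, bh_adjust, degs
from .enrichment import fisher_exact_2x2

logger = logging.getLogger("bloodshift")


def uniqueness_filter(
    de_results: pd.DataFrame,
    externals: list[ExternalDETable],
    p_thresh: float = 0.05,
) -> SpecificityResult:
    """Partition DEGs into unique vs previously-seen.

    A DEG is removed iff at least one external table reports it below the
    unadjusted ``p_thresh`` (any direction); removal is attributed per
    dataset. With no external tables every DEG is unique (warning).
    """
    if not 0 < p_thresh <= 1:
        raise ValueError("p_thresh must be in (0, 1]")
    all_degs = degs(de_results)[["gene", "status", "log2fc", "mean_tpm"]].rename(
        columns={"status": "direction"}
    )
    if not externals:
        logger.warning("no external DE tables supplied; every DEG is reported as unique")
    flagged_sets = {t.dataset_id: t.significant_genes(p_thresh) for t in externals}
    if externals:
        overlap = set.union(*(set(t.table["gene"]) for t in externals)) & set(all_degs["gene"])
        logger.info("gene ID overlap between DEGs and external tables: %d genes", len(overlap))

    flagged_by = []
    for g in all_degs["gene"]:
        hits = sorted(ds for ds, genes in flagged_sets.items() if g in genes)
        flagged_by.append(",".join(hits))
    all_degs = all_degs.assign(flagged_by=flagged_by)
    seen_mask = all_degs["flagged_by"] != ""
    previously_seen = all_degs[seen_mask].reset_index(drop=True)
    unique_degs = all_degs[~seen_mask].drop(columns="flagged_by").reset_index(drop=True)
    return SpecificityResult(
        all_degs=all_degs.drop(columns="flagged_by").reset_index(drop=True),
        previously_seen=previously_seen,
        unique_degs=unique_degs,
        p_thresh=p_thresh,
    )


def marker_specificity_enrichment(
    result: SpecificityResult, catalog: MarkerCatalog
) -> pd.DataFrame:
    """Per-cell-type marker enrichment among unique DEGs.

    For each cell type the 2x2 table crosses {unique DEG, previously-seen
    DEG} with {marker of this type, not}; the one-sided Fisher exact test
    asks whether the type's markers are over-represented among the unique
    DEGs. BH FDR across cell types. Types without any marker among the
    DEGs are reported with p = 1.
    """
    unique = set(result.unique_degs["gene"])
    seen = set(result.previously_seen["gene"])
    rows = []
    for ct in catalog.cell_types:
        markers = set(catalog.markers.get(ct, []))
        a = len(unique & markers)
        b = len(unique - markers)
        c = len(seen & markers)
        d = len(seen - markers)
        if a + c == 0:
            odds, p = np.nan, 1.0
        else:
            odds, p = fisher_exact_2x2(a, b, c, d, sided="greater")
        rows.append(
            {
                "cell_type": ct,
                "markers_in_unique": a,
                "markers_in_all_degs": a + c,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    result.enrichment = out
    return out


def prioritize_signature(
    result: SpecificityResult,
    catalog: MarkerCatalog | None = None,
    tpm_min: float = 10.0,
    lfc_min: float = 0.5,
) -> pd.DataFrame:
    """High-confidence signature: well-expressed, clearly regulated unique DEGs.

    Keeps unique DEGs with ``mean_tpm >= tpm_min`` and ``|log2fc| >=
    lfc_min`` (both inclusive), annotates each with its marker cell type
    (or empty), and sorts rows by cell type (catalog order, unannotated
    last) then by decreasing log2fc.
    """
    sig = result.unique_degs.copy()
    sig = sig[(sig["mean_tpm"] >= tpm_min) & (sig["log2fc"].abs() >= lfc_min)]
    g2t = catalog.gene_to_type() if catalog is not None else {}
    sig = sig.assign(cell_type=[g2t.get(g, "") for g in sig["gene"]])
    type_order = {ct: i for i, ct in enumerate(catalog.cell_types)} if catalog else {}
    sig = sig.assign(_ord=[type_order.get(ct, len(type_order)) for ct in sig["cell_type"]])
    sig = (
        sig.sort_values(["_ord", "log2fc"], ascending=[True, False], kind="mergesort")
        .drop(columns="_ord")
        .reset_index(drop=True)
    )
    sig = sig[["gene", "direction", "log2fc", "mean_tpm", "cell_type"]]
    result.signature = sig
    return sig


def signature_summary(signature: pd.DataFrame) -> dict[str, int]:
    return {
        "n_genes": len(signature),
        "n_up": int((signature["direction"] == STATUS_UP).sum()),
        "n_down": int((signature["direction"] == STATUS_DOWN).sum()),
        "n_unassigned": int((signature["cell_type"] == "").sum()),
    }


def microarray_paired_de(
    matrix: ExpressionMatrix, meta: list[SampleRecord], dataset_id: str
) -> ExternalDETable:
    """Donor-paired re-analysis of a microarray-style log-intensity matrix.

    Values are assumed to already be on a log2 scale, so the per-donor
    after-minus-before differences are log2 fold changes; a two-sided
    one-sample t test on those differences yields the per-gene p-value.
    """
    donors, b_idx, a_idx = paired_layout(meta, matrix.sample_ids)
    n = len(donors)
    if n < 3:
        raise ValueError(f"paired re-analysis requires >= 3 complete pairs, found {n}")
    d = matrix.values[:, a_idx] - matrix.values[:, b_idx]
    lfc = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    p = np.ones(matrix.n_genes)
    ok = sd > 0
    t = np.zeros(matrix.n_genes)
    t[ok] = lfc[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), n - 1)
    p[~ok & (lfc != 0)] = np.finfo(float).tiny
    table = pd.DataFrame({"gene": matrix.gene_ids, "log2fc": lfc, "p": p})
    return ExternalDETable(dataset_id=dataset_id, table=table)
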