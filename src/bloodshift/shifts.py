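"""Infer cell-type abundance changes from bulk data via marker expression.

A change in the abundance of a cell type moves the bulk expression of its
marker genes coherently, so the markers act as a proxy for the (relative)
population change without full deconvolution. For each cell type the
observations ``corrected[g, s]`` over its markers ``g`` and the bulk samples
``s`` of one condition are pooled and compared between conditions with a
two-sided Wilcoxon rank-sum test. Because markers differ hugely in absolute
expression, each marker row is centered at its own grand mean before
pooling; donor centering has already removed the per-donor offsets, so the
pooled observations are per-marker deviations in which only the condition
effect remains. The direction is the sign of (mean after - mean before)
when the test is significant at 0.05, otherwise "no_change".

With exactly two samples per donor, donor centering makes the before and
after pools exact mirror images of each other, which breaks the
independence assumption of an unpaired rank-sum comparison and makes it
anticonservative. The default test is therefore the ``paired`` variant: a
Wilcoxon signed-rank test on the per-marker per-donor (after - before)
differences, which respects the pairing while still pooling all markers of
a type. The pooled unpaired rank-sum reading remains available as
``variant="pooled_unpaired"``.

Star notation: ``***`` p < 0.001, ``**`` p < 0.01, ``*`` p < 0.05, ``-``
otherwise. No multiplicity correction is applied across cell types (raw
stars are reported; stated in the output header).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AFTER, BEFORE, ExpressionMatrix, MarkerCatalog, SampleRecord, condition_columns, paired_layout

logger = logging.getLogger("bloodshift")

INCREASE = "increase"
DECREASE = "decrease"
NO_CHANGE = "no_change"

SHIFT_COLUMNS = ["cell_type", "n_markers_used", "p_value", "stars", "direction", "mean_delta", "flag"]


def stars_for(p: float) -> str:
    if not np.isfinite(p):
        return "-"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "-"


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small untied groups, else
    normal approximation with tie correction."""
    if len(x) <= 8 and len(y) <= 8 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y):
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def marker_shift_test(
    corrected: ExpressionMatrix,
    meta: list[SampleRecord],
    catalog: MarkerCatalog,
    variant: str = "paired",
    min_markers: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cell-type abundance shift report from a donor-centered log matrix.

    ``variant`` selects the test on the pooled marker observations:
    ``paired`` (default) runs a Wilcoxon signed-rank test on the per-marker
    per-donor (after - before) differences; ``pooled_unpaired`` compares
    the before and after pools with a rank-sum test. Types with fewer
    than ``min_markers`` markers present in the matrix are reported with
    direction ``no_change`` and flag ``insufficient_markers``.
    """
    if corrected.unit != "log_normalized":
        raise ValueError("marker_shift_test expects a log-normalized (donor-centered) matrix")
    if variant not in ("pooled_unpaired", "paired"):
        raise ValueError(f"unknown shift test variant {variant!r}")
    gene_idx = corrected.gene_index()
    b_cols = condition_columns(meta, corrected.sample_ids, BEFORE)
    a_cols = condition_columns(meta, corrected.sample_ids, AFTER)
    if len(b_cols) == 0 or len(a_cols) == 0:
        raise ValueError("both conditions must be present among the samples")
    if variant == "paired":
        _, b_cols, a_cols = paired_layout(meta, corrected.sample_ids)

    rows = []
    for ct in catalog.cell_types:
        present = [g for g in catalog.markers.get(ct, []) if g in gene_idx]
        n_total = len(catalog.markers.get(ct, []))
        if len(present) < n_total:
            logger.info(
                "cell type %s: %d of %d markers present in the bulk matrix",
                ct, len(present), n_total,
            )
        if len(present) < min_markers:
            rows.append(
                {
                    "cell_type": ct,
                    "n_markers_used": len(present),
                    "p_value": np.nan,
                    "stars": "-",
                    "direction": NO_CHANGE,
                    "mean_delta": np.nan,
                    "flag": "insufficient_markers",
                }
            )
            continue
        g = np.asarray([gene_idx[x] for x in present])
        block = corrected.values[g]
        block = block - block.mean(axis=1, keepdims=True)  # per-marker centering
        before = block[:, b_cols].ravel()
        after = block[:, a_cols].ravel()
        if variant == "pooled_unpaired":
            p = _rank_sum_p(after, before)
        else:
            diffs = (block[:, a_cols] - block[:, b_cols]).ravel()
            if np.allclose(diffs, 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
        delta = float(after.mean() - before.mean())
        if p < alpha:
            direction = INCREASE if delta > 0 else DECREASE
        else:
            direction = NO_CHANGE
        rows.append(
            {
                "cell_type": ct,
                "n_markers_used": len(present),
                "p_value": p,
                "stars": stars_for(p),
                "direction": direction,
                "mean_delta": delta,
                "flag": "",
            }
        )
    return pd.DataFrame(rows, columns=SHIFT_COLUMNS)


def shift_heatmap_table(
    corrected: ExpressionMatrix,
    meta: list[SampleRecord],
    catalog: MarkerCatalog,
) -> pd.DataFrame:
    """Marker x sample table of donor-corrected log expression for plotting.

    Rows are ordered by cell type (catalog order) then marker rank; columns
    by condition (before first) then donor ID. The output is independent of
    the input sample order.
    """
    gene_idx = corrected.gene_index()
    by_sample = {m.sample_id: m for m in meta}
    ordered_samples = []
    for cond in (BEFORE, AFTER):
        members = [
            s for s in corrected.sample_ids
            if s in by_sample and by_sample[s].condition == cond
        ]
        members.sort(key=lambda s: (by_sample[s].donor_id, s))
        ordered_samples.extend(members)
    col_idx = {s: i for i, s in enumerate(corrected.sample_ids)}

    rows, row_labels, row_types = [], [], []
    for ct in catalog.cell_types:
        for g in catalog.markers.get(ct, []):
            if g in gene_idx:
                rows.append([corrected.values[gene_idx[g], col_idx[s]] for s in ordered_samples])
                row_labels.append(g)
                row_types.append(ct)
    out = pd.DataFrame(rows, index=row_labels, columns=ordered_samples)
    out.insert(0, "cell_type", row_types)
    out.index.name = "gene"
    return out
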