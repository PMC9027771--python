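"""Derive cell-type marker genes from a labeled single-cell matrix.

"Most discriminating" is operationalized as the one-vs-rest Wilcoxon
rank-sum AUC on normalized expression — the de-facto standard score for
single-cell marker ranking. Every gene is assigned uniquely to the cell type
where it scores highest, so the resulting marker lists are pairwise
disjoint; within a type the genes are ranked by AUC and the list truncated
to ``max_markers`` (default 20). Genes below ``auc_min`` (default 0.7) are
dropped so that weak markers do not pollute the bulk shift tests.

Cell clustering is out of scope: labels come with the data (public
references ship them; the synthetic generator produces them).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, MarkerCatalog

logger = logging.getLogger("bloodshift")


def normalize_cells(matrix: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then log2(x + 1)."""
    totals = matrix.values.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts cannot be normalized")
    vals = np.log2(matrix.values / totals[None, :] * target_sum + 1.0)
    return matrix.with_values(vals, unit="log_normalized")


def score_markers(
    sc_matrix: ExpressionMatrix,
    cell_labels: list[str],
    min_cells: int = 10,
) -> pd.DataFrame:
    """One-vs-rest discrimination scores for every (gene, cell type).

    Returns a long DataFrame with columns ``gene, cell_type, auc, log2fc,
    detection_delta``:

    - ``auc``: Wilcoxon rank-sum AUC of normalized expression, in-type vs
      all other cells (1 = perfectly elevated, 0.5 = uninformative);
    - ``log2fc``: log2 ratio of mean normalized counts (+1 pseudo-count);
    - ``detection_delta``: difference in the fraction of cells with nonzero
      counts.

    Cell types with fewer than ``min_cells`` cells are excluded (warning).
    """
    if len(cell_labels) != sc_matrix.n_samples:
        raise ValueError("one label per cell required")
    labels = np.asarray(cell_labels)
    types = sorted(set(cell_labels))
    kept_types = []
    for ct in types:
        n_ct = int((labels == ct).sum())
        if n_ct < min_cells:
            logger.warning("cell type %s has %d < %d cells; excluded from scoring", ct, n_ct, min_cells)
        else:
            kept_types.append(ct)
    if len(kept_types) < 2:
        raise ValueError("marker scoring requires at least 2 cell types with enough cells")
    keep_cells = np.isin(labels, kept_types)
    if not keep_cells.all():
        sc_matrix = sc_matrix.subset_samples(keep_cells)
        labels = labels[keep_cells]

    if sc_matrix.unit == "counts":
        norm = normalize_cells(sc_matrix)
    else:
        norm = sc_matrix
    vals = norm.values
    n_cells = vals.shape[1]
    # linear counts for fold changes / detection, recovered from the log scale
    lin = np.exp2(vals) - 1.0
    detected = vals > 0

    ranks = stats.rankdata(vals, axis=1)  # midranks handle ties
    frames = []
    for ct in kept_types:
        in_ct = labels == ct
        n1 = int(in_ct.sum())
        n2 = n_cells - n1
        r1 = ranks[:, in_ct].sum(axis=1)
        auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)
        m_in = lin[:, in_ct].mean(axis=1)
        m_out = lin[:, ~in_ct].mean(axis=1)
        log2fc = np.log2((m_in + 1.0) / (m_out + 1.0))
        det_delta = detected[:, in_ct].mean(axis=1) - detected[:, ~in_ct].mean(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "gene": norm.gene_ids,
                    "cell_type": ct,
                    "auc": auc,
                    "log2fc": log2fc,
                    "detection_delta": det_delta,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def assign_and_rank(
    scores: pd.DataFrame,
    max_markers: int = 20,
    auc_min: float = 0.7,
) -> MarkerCatalog:
    """Uniquely assign genes to their best type and keep the top markers.

    Each gene goes to the type with the highest AUC (ties broken by larger
    log2fc, then lexicographic type label). Within a type, markers are
    ranked by AUC (ties: larger log2fc, then lexicographic gene ID),
    truncated to ``max_markers``; genes below ``auc_min`` are dropped. Types
    ending up with no markers are retained with an empty list (warning).
    """
    cell_types = sorted(scores["cell_type"].unique())
    # best type per gene
    best = scores.sort_values(
        ["gene", "auc", "log2fc", "cell_type"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).drop_duplicates("gene", keep="first")
    best = best[best["auc"] >= auc_min]

    markers: dict[str, list[str]] = {}
    rows = []
    for ct in cell_types:
        sub = best[best["cell_type"] == ct].sort_values(
            ["auc", "log2fc", "gene"], ascending=[False, False, True], kind="mergesort"
        )
        kept = sub.head(max_markers).reset_index(drop=True)
        if kept.empty:
            logger.warning("cell type %s has no markers with AUC >= %.2f", ct, auc_min)
        markers[ct] = kept["gene"].tolist()
        kept = kept.copy()
        kept.insert(1, "rank", np.arange(1, len(kept) + 1))
        rows.append(kept[["cell_type", "rank", "gene", "auc", "log2fc", "detection_delta"]])
    score_table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["cell_type", "rank", "gene", "auc", "log2fc", "detection_delta"]
    )
    return MarkerCatalog(cell_types=cell_types, markers=markers, scores=score_table)


def derive_markers(
    sc_matrix: ExpressionMatrix,
    cell_labels: list[str],
    max_markers: int = 20,
    auc_min: float = 0.7,
    min_cells: int = 10,
) -> MarkerCatalog:
    """Score + assign in one call."""
    scores = score_markers(sc_matrix, cell_labels, min_cells=min_cells)
    return assign_and_rank(scores, max_markers=max_markers, auc_min=auc_min)
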