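"""Paired (donor-matched) per-gene differential expression.

Each gene is tested with a one-sample t statistic on the per-donor log2
fold changes ``d_i = log2(after_i/sf + 1) - log2(before_i/sf + 1)``. With
seven pairs the per-gene variance estimate is unstable, so it is moderated:
shrunk toward a prior variance with weight equivalent to ``prior_df`` extra
degrees of freedom, in the spirit of empirical-Bayes moderated t tests. The
prior follows the mean-variance trend (a trimmed-mean variance within bins
of mean log expression) rather than a single global value, because log-count
variance in RNA-seq depends strongly on expression level; a global prior
would be dominated by noisy low-count genes and penalize exactly the
well-measured genes a blood signature is built from.

Multiplicity is handled with Benjamini-Hochberg FDR; genes are called up- or
down-regulated at ``fdr < alpha`` (default 0.1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, SampleRecord, paired_layout
from .normalize import counts_to_tpm, drop_all_zero_genes, median_of_ratios_size_factors

logger = logging.getLogger("bloodshift")

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"

DE_COLUMNS = ["gene", "log2fc", "p_value", "fdr", "mean_tpm", "status", "tested"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, input order preserved.

    ``adjusted_(i) = min_{j: p_(j) >= p_(i)} p_(j) * n / rank_j``, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def _trend_prior_variance(
    s2: np.ndarray, mean_log: np.ndarray, n_bins: int = 20, trim: float = 0.1
) -> np.ndarray:
    """Trimmed-mean variance within quantile bins of mean log expression.

    Returns a per-gene prior variance that tracks the mean-variance trend.
    """
    n = s2.size
    n_bins = max(1, min(n_bins, n // 50)) if n >= 100 else 1
    if n_bins == 1:
        prior = stats.trim_mean(s2, trim) if n > 2 else float(np.mean(s2))
        return np.full(n, max(prior, 1e-12))
    # equal-occupancy bins by mean expression (stable sort; ties split
    # deterministically, which keeps every bin populated)
    order = np.argsort(mean_log, kind="mergesort")
    bins = np.empty(n, dtype=int)
    bins[order] = np.arange(n) * n_bins // n
    prior = np.empty(n)
    for b in range(n_bins):
        mask = bins == b
        prior[mask] = stats.trim_mean(s2[mask], trim)
    return np.maximum(prior, 1e-12)


def paired_de(
    counts: ExpressionMatrix,
    meta: list[SampleRecord],
    alpha: float = 0.1,
    moderate: bool = True,
    prior_df: float = 3.0,
    min_mean_norm_count: float = 1.0,
) -> pd.DataFrame:
    """Donor-paired differential expression on a count matrix.

    Returns a DataFrame with one row per gene (input order) and columns
    ``gene, log2fc, p_value, fdr, mean_tpm, status, tested``. log2fc is
    after-vs-before (positive = higher after exercise). Genes whose mean
    normalized count falls below ``min_mean_norm_count`` are excluded from
    testing (``tested`` False, p/fdr NaN, status ``ns``). ``mean_tpm`` is
    TPM when gene lengths are available, otherwise counts-per-million.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    counts = drop_all_zero_genes(counts)
    donors, b_idx, a_idx = paired_layout(meta, counts.sample_ids)
    n = len(donors)
    if n == 0:
        raise ValueError("no donor has a complete before/after pair")
    if n < 3:
        raise ValueError(f"paired test requires at least 3 complete pairs, found {n}")

    sf = median_of_ratios_size_factors(counts)
    norm = counts.values / sf[None, :]
    mean_norm = norm.mean(axis=1)
    tested = mean_norm >= min_mean_norm_count
    n_excluded = int((~tested).sum())
    if n_excluded:
        logger.info(
            "expression filter: %d genes below mean normalized count %.3g excluded from testing",
            n_excluded,
            min_mean_norm_count,
        )

    logv = np.log2(norm + 1.0)
    d = logv[:, a_idx] - logv[:, b_idx]  # genes x pairs
    lfc = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)

    if moderate:
        prior = _trend_prior_variance(s2[tested], np.log2(mean_norm[tested] + 1.0))
        s2_post = np.full_like(s2, np.nan)
        s2_post[tested] = (prior_df * prior + (n - 1) * s2[tested]) / (prior_df + n - 1)
        df = prior_df + n - 1
    else:
        s2_post = s2.copy()
        df = float(n - 1)

    p = np.full(counts.n_genes, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post / n)
        t = lfc / se
    ok = tested & (s2_post > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    degenerate = tested & (s2_post == 0)
    if degenerate.any():
        # zero variance: p = 1 when there is also no mean difference, else
        # the difference is deterministic at machine precision
        p[degenerate] = np.where(lfc[degenerate] == 0, 1.0, np.finfo(float).tiny)

    fdr = np.full(counts.n_genes, np.nan)
    fdr[tested] = bh_adjust(p[tested])

    if counts.gene_lengths_bp is not None:
        mean_expr = counts_to_tpm(counts).values.mean(axis=1)
    else:
        logger.info("no gene lengths: reporting counts-per-million in mean_tpm")
        mean_expr = (1e6 * counts.values / counts.values.sum(axis=0)[None, :]).mean(axis=1)

    status = np.full(counts.n_genes, STATUS_NS, dtype=object)
    sig = tested & (fdr < alpha)
    status[sig & (lfc > 0)] = STATUS_UP
    status[sig & (lfc < 0)] = STATUS_DOWN

    return pd.DataFrame(
        {
            "gene": counts.gene_ids,
            "log2fc": lfc,
            "p_value": p,
            "fdr": fdr,
            "mean_tpm": mean_expr,
            "status": status,
            "tested": tested,
        }
    )


def degs(results: pd.DataFrame) -> pd.DataFrame:
    """Rows called differentially expressed (status up or down)."""
    return results[results["status"].isin([STATUS_UP, STATUS_DOWN])].copy()


def stratify_by_expression(results: pd.DataFrame, tpm_cutoffs) -> pd.DataFrame:
    """Counts of up/down DEGs among genes with mean_tpm >= cutoff, per cutoff."""
    rows = []
    for c in tpm_cutoffs:
        sub = results[results["mean_tpm"] >= c]
        rows.append(
            {
                "tpm_cutoff": c,
                "n_up": int((sub["status"] == STATUS_UP).sum()),
                "n_down": int((sub["status"] == STATUS_DOWN).sum()),
            }
        )
    return pd.DataFrame(rows)


def fold_change_summary(results: pd.DataFrame, fc_threshold: float = 1.0) -> dict[str, int]:
    """DEGs changing strictly more than ``2**fc_threshold``-fold, by direction."""
    d = degs(results)
    strong = d[np.abs(d["log2fc"]) > fc_threshold]
    return {
        "n_up": int((strong["status"] == STATUS_UP).sum()),
        "n_down": int((strong["status"] == STATUS_DOWN).sum()),
    }
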