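"""Overrepresentation analysis (ORA) and gene set enrichment analysis (GSEA).

ORA tests, per gene set, whether the query genes (e.g. up-regulated DEGs)
overlap the set more than expected under the hypergeometric null, via a
one-sided Fisher exact test on the 2x2 membership table within the tested
universe. GSEA implements the classic weighted running-sum enrichment score
over a ranked gene list, with significance from gene-label permutation (the
paired 7-donor design offers too few sample permutations). Both report
Benjamini-Hochberg FDR across the sets of a collection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection
from .de import bh_adjust

logger = logging.getLogger("bloodshift")


def fisher_exact_2x2(a: int, b: int, c: int, d: int, sided: str = "two-sided") -> tuple[float, float]:
    """Conditional (hypergeometric) Fisher exact test on ``[[a, b], [c, d]]``.

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample estimate
    ``(a*d)/(b*c)`` (``inf`` when only the numerator is positive, ``nan``
    for 0/0). ``sided`` is ``two-sided``, ``greater`` or ``less``.
    """
    table = np.asarray([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("2x2 table entries must be non-negative")
    if not np.all(table == np.floor(table)):
        raise ValueError("2x2 table entries must be integers")
    table = table.astype(int)
    a, b, c, d = table.ravel().tolist()
    num, den = a * d, b * c
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = np.inf
    else:
        odds = np.nan
    p = float(stats.fisher_exact(table, alternative=sided).pvalue)
    return odds, p


def ora(
    query_genes,
    universe_genes,
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact overrepresentation across a collection.

    ``query_genes`` must be a subset of ``universe_genes``; sets are
    intersected with the universe before testing and skipped (with a
    warning) when the intersection is empty. Returns a DataFrame ranked by
    p with columns ``set_name, overlap_size, set_size, odds_ratio, p_value,
    fdr, overlap`` (comma-joined genes).
    """
    universe = set(universe_genes)
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = universe.intersection(members)
        if not in_universe:
            logger.warning("gene set %s has no overlap with the universe; skipped", name)
            continue
        overlap = sorted(query.intersection(in_universe))
        a = len(overlap)
        b = n_query - a
        c = len(in_universe) - a
        d = n_universe - n_query - c
        odds, p = fisher_exact_2x2(a, b, c, d, sided="greater")
        rows.append(
            {
                "set_name": name,
                "overlap_size": a,
                "set_size": len(in_universe),
                "odds_ratio": odds,
                "p_value": p,
                "overlap": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows, columns=["set_name", "overlap_size", "set_size", "odds_ratio", "p_value", "overlap"])
    if not out.empty:
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out[["set_name", "overlap_size", "set_size", "odds_ratio", "p_value", "fdr", "overlap"]]


def _es_from_hits(weights: np.ndarray, hits: np.ndarray, mstep: float):
    """Enrichment score given sorted hit positions (1-D) in a ranked list.

    Returns ``(es, extremum_hit_index, after, before)`` where ``after[i]``
    is the running sum just after processing hit ``i`` and ``before[i]``
    just before it.
    """
    hw = weights[hits]
    tot = hw.sum()
    k = hits.size
    if tot == 0:  # all hit scores exactly zero: fall back to equal increments
        inc = np.full(k, 1.0 / k)
    else:
        inc = hw / tot
    cum = np.cumsum(inc)
    misses = hits - np.arange(k)
    after = cum - misses * mstep
    before = after - inc
    mx = max(after.max(), 0.0)
    mn = min(before.min(), 0.0)
    if mx >= -mn:
        return mx, int(np.argmax(after)), after, before
    return mn, int(np.argmin(before)), after, before


def _perm_es(weights: np.ndarray, k: int, mstep: float, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null enrichment scores from random gene-label permutations (size-k sets)."""
    n = weights.size
    out = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(4e6 / max(n, 1)) or 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # k smallest of m x n uniforms = uniform random subset of positions
        u = rng.random((m, n))
        hits = np.sort(np.argpartition(u, k - 1, axis=1)[:, :k], axis=1)
        hw = weights[hits]
        tot = hw.sum(axis=1, keepdims=True)
        inc = np.where(tot > 0, hw / np.where(tot == 0, 1, tot), 1.0 / k)
        cum = np.cumsum(inc, axis=1)
        misses = hits - np.arange(k)[None, :]
        after = cum - misses * mstep
        before = after - inc
        mx = np.maximum(after.max(axis=1), 0.0)
        mn = np.minimum(before.min(axis=1), 0.0)
        out[done : done + m] = np.where(mx >= -mn, mx, mn)
        done += m
    return out


def gsea(
    ranked_genes,
    collection: GeneSetCollection,
    n_perm: int = 10000,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Weighted running-sum GSEA over a ranked gene list.

    ``ranked_genes`` is a sequence of ``(gene, score)`` pairs or a pandas
    Series (index = genes). Genes are ordered by decreasing score (ties
    broken by gene ID for determinism). For a set of size ``n`` in a
    universe of ``N``, hits increment the running sum by
    ``|score|**weight / sum_hits`` and misses decrement by ``1/(N - n)``;
    the enrichment score ES is the maximum deviation from zero. p-values
    come from ``n_perm`` gene-label permutations, one-sided within the sign
    of the observed ES; NES divides ES by the mean same-sign null |ES|.
    The leading edge is the set members at or before the extremum (after it
    for negative ES).
    """
    if isinstance(ranked_genes, pd.Series):
        genes = ranked_genes.index.to_numpy(dtype=object)
        scores = ranked_genes.to_numpy(dtype=float)
    else:
        genes = np.asarray([g for g, _ in ranked_genes], dtype=object)
        scores = np.asarray([s for _, s in ranked_genes], dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked gene list contains duplicates")
    if not np.isfinite(scores).all():
        raise ValueError("ranking scores must be finite")
    order = np.lexsort((genes, -scores))
    genes, scores = genes[order], scores[order]
    n_genes = genes.size
    pos = {g: i for i, g in enumerate(genes)}
    weights = np.abs(scores) ** weight

    rng = np.random.default_rng(seed)
    rows = []
    for name, members in collection.sets.items():
        hits = np.sort([pos[g] for g in members if g in pos])
        k = hits.size
        if k == 0:
            logger.warning("gene set %s has no overlap with the ranking; skipped", name)
            continue
        if k > n_genes - 1:
            logger.warning("gene set %s covers the whole ranking; skipped", name)
            continue
        mstep = 1.0 / (n_genes - k)
        es, ext, after, before = _es_from_hits(weights, hits, mstep)
        if es >= 0:
            leading = [genes[i] for i in hits[: ext + 1]]
        else:
            leading = [genes[i] for i in hits[ext:]]
        null = _perm_es(weights, k, mstep, n_perm, rng)
        if es >= 0:
            pool = null[null >= 0]
            n_extreme = int((pool >= es).sum())
        else:
            pool = null[null < 0]
            n_extreme = int((pool <= es).sum())
        p = (1.0 + n_extreme) / (1.0 + pool.size)
        denom = np.abs(pool).mean() if pool.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append(
            {
                "set_name": name,
                "set_size": k,
                "es": es,
                "nes": nes,
                "p_value": p,
                "direction": "up" if es >= 0 else "down",
                "leading_edge": ",".join(map(str, leading)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "set_size", "es", "nes", "p_value", "direction", "leading_edge"],
    )
    if not out.empty:
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out[["set_name", "set_size", "es", "nes", "p_value", "fdr", "direction", "leading_edge"]]


def ranking_from_de(results: pd.DataFrame, metric: str = "signed_logp") -> pd.Series:
    """Build the GSEA ranking from a DE table.

    ``signed_logp`` (default): ``sign(log2fc) * -log10(p)``, capped at 300;
    ``log2fc``: the fold change itself. Only tested genes enter the ranking.
    """
    tested = results[results["tested"]].copy() if "tested" in results else results.copy()
    if metric == "signed_logp":
        p = np.clip(tested["p_value"].to_numpy(dtype=float), 1e-300, 1.0)
        score = np.sign(tested["log2fc"].to_numpy()) * (-np.log10(p))
    elif metric == "log2fc":
        score = tested["log2fc"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    return pd.Series(score, index=tested["gene"].to_numpy())


def top_k_report(result: pd.DataFrame, k: int = 10, fdr_max: float = 0.05) -> pd.DataFrame:
    """Top-k significant sets per direction, mirroring a two-panel summary."""
    sig = result[result["fdr"] < fdr_max]
    parts = []
    for direction in ("up", "down"):
        if "direction" in sig.columns:
            sub = sig[sig["direction"] == direction]
        else:
            sub = sig
        parts.append(sub.head(k))
    return pd.concat(parts, ignore_index=True) if parts else sig.head(k)
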